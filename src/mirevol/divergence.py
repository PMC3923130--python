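"""Region-partitioned sequence divergence between orthologous hairpins.

For every ortholog pair the hairpin is partitioned — relative to the
reference sequence's ungapped coordinates — into the mature arm(s), the
6-mer seed (positions 2-7 of each arm), and everything outside the mature
arms (loop plus stem extension). Two divergence estimates are computed per
region: plain substitutions per site (a p-distance over non-gap columns) and
the Kimura two-parameter distance, which corrects the observed transition
(P) and transversion (Q) fractions for multiple hits:

    d = -1/2 * ln(1 - 2P - Q) - 1/4 * ln(1 - 2Q)

Mature arms are additionally summarised by their integer substitution count
(mature sequences are of nearly equal length, so counts are comparable) and
binned into the classes "0", "1-2", and ">=3".

Conventions: gap columns and columns containing N are excluded from both the
numerator and denominator of every rate, which keeps the hairpin =
mature + outside-mature partition of substitution counts exact on gap-free
alignments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from mirevol.alignment import Scoring, align_global, normalize_seq

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

REGIONS = ("hairpin", "mature", "seed", "outside_mature")

SEED_START = 2  # 1-based position within the mature arm
SEED_END = 7

MATURE_TYPICAL_MIN = 19
MATURE_TYPICAL_MAX = 24


class K2PSaturationError(ValueError):
    """Observed substitution fractions exceed the model's invertible range."""


@dataclass(frozen=True)
class RegionAnnotation:
    """Mature-arm annotation on a hairpin (1-based inclusive coordinates).

    ``arms`` maps an arm name ('5p'/'3p') to its (start, end) interval on the
    hairpin. Arms must not overlap and must lie inside the hairpin.
    """

    hairpin_length: int
    arms: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        prev: list[tuple[int, int]] = []
        for name, start, end in self.arms:
            if not (1 <= start <= end <= self.hairpin_length):
                raise ValueError(f"arm {name} [{start},{end}] outside hairpin 1..{self.hairpin_length}")
            for s0, e0 in prev:
                if start <= e0 and s0 <= end:
                    raise ValueError("mature arms overlap")
            prev.append((start, end))

    @property
    def atypical_arms(self) -> tuple[str, ...]:
        """Arms whose length falls outside the typical 19-24 nt range."""
        return tuple(
            name for name, s, e in self.arms
            if not (MATURE_TYPICAL_MIN <= e - s + 1 <= MATURE_TYPICAL_MAX)
        )


@dataclass
class DivergenceRecord:
    """Per-ortholog-pair divergence, region by region."""

    pair_id: str
    regions: dict[str, dict[str, float]] = field(default_factory=dict)
    # regions[name] keys: sites, substitutions, rate, k2p, P, Q
    mature_substitution_count: int | None = None
    mature_class: str | None = None
    per_arm: dict[str, tuple[int, str]] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)


def region_slice(regions: RegionAnnotation, which: str) -> np.ndarray:
    """Boolean mask over hairpin positions (length = hairpin_length).

    seed = positions 2-7 within each mature arm; outside_mature = hairpin
    minus all arms. mature and outside_mature partition the hairpin; seed is
    a subset of mature.
    """
    if which not in REGIONS:
        raise ValueError(f"unknown region {which!r}; expected one of {REGIONS}")
    n = regions.hairpin_length
    mask = np.zeros(n, dtype=bool)
    if which == "hairpin":
        mask[:] = True
        return mask
    if which == "outside_mature":
        mask[:] = True
        for _, s, e in regions.arms:
            mask[s - 1:e] = False
        return mask
    for name, s, e in regions.arms:
        if which == "mature":
            mask[s - 1:e] = True
        else:  # seed
            if e - s + 1 < SEED_END:
                raise ValueError(f"arm {name} shorter than {SEED_END} nt: seed undefined")
            mask[s - 1 + SEED_START - 1:s - 1 + SEED_END] = True
    return mask


def align_orthologs(seq_a: str, seq_b: str, scoring: Scoring | None = None) -> tuple[str, str, float]:
    """Optimal global alignment of two hairpins; see :func:`mirevol.alignment.align_global`."""
    return align_global(seq_a, seq_b, scoring)


def _columns(aln_a: str, aln_b: str, mask: np.ndarray | None):
    """Yield (char_a, char_b) for alignment columns that are non-gap, non-N,
    and (if a mask over sequence A's ungapped positions is given) inside the
    masked region of A. Columns where A is gapped have no A-coordinate and
    are excluded whenever a mask is supplied."""
    if len(aln_a) != len(aln_b):
        raise ValueError("aligned sequences differ in length")
    pos_a = -1  # 0-based ungapped position in A
    for ca, cb in zip(aln_a, aln_b):
        in_region = True
        if ca != "-":
            pos_a += 1
            if mask is not None:
                if pos_a >= len(mask):
                    raise ValueError("region mask shorter than ungapped sequence A")
                in_region = bool(mask[pos_a])
        elif mask is not None:
            continue
        if ca == "-" or cb == "-" or ca == "N" or cb == "N":
            continue
        if in_region:
            yield ca, cb


def p_distance(aln_a: str, aln_b: str, mask: np.ndarray | None = None) -> tuple[float, int, int]:
    """Substitutions per site over (optionally masked) non-gap columns.

    Returns (rate, substitutions, sites). A region with zero usable columns
    yields rate = nan (flagged by the caller).
    """
    subs = sites = 0
    for ca, cb in _columns(aln_a, aln_b, mask):
        sites += 1
        if ca != cb:
            subs += 1
    rate = subs / sites if sites else math.nan
    return rate, subs, sites


def _is_transition(ca: str, cb: str) -> bool:
    return (ca in PURINES and cb in PURINES) or (ca in PYRIMIDINES and cb in PYRIMIDINES)


def kimura2p_from_pq(P: float, Q: float) -> float:
    """Kimura two-parameter distance from transition/transversion fractions."""
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise K2PSaturationError(f"K2P undefined for P={P}, Q={Q} (saturated)")
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def kimura2p(aln_a: str, aln_b: str, mask: np.ndarray | None = None) -> tuple[float, float, float]:
    """K2P distance over a region: returns (d, P, Q).

    P and Q are the transition and transversion fractions over usable
    columns. Raises :class:`K2PSaturationError` when the observed fractions
    leave the model's invertible range.
    """
    ts = tv = sites = 0
    for ca, cb in _columns(aln_a, aln_b, mask):
        sites += 1
        if ca != cb:
            if _is_transition(ca, cb):
                ts += 1
            else:
                tv += 1
    if sites == 0:
        return math.nan, math.nan, math.nan
    P = ts / sites
    Q = tv / sites
    return kimura2p_from_pq(P, Q), P, Q


def classify_mature_count(count: int) -> str:
    if count == 0:
        return "0"
    if count <= 2:
        return "1-2"
    return ">=3"


def mature_substitutions(aln_a: str, aln_b: str, regions: RegionAnnotation) -> dict[str, tuple[int, str]]:
    """Integer substitution count and class per mature arm (arms are separate)."""
    out: dict[str, tuple[int, str]] = {}
    for name, s, e in regions.arms:
        mask = np.zeros(regions.hairpin_length, dtype=bool)
        mask[s - 1:e] = True
        _, subs, _ = p_distance(aln_a, aln_b, mask)
        out[name] = (subs, classify_mature_count(subs))
    return out


def divergence_record(
    pair_id: str,
    seq_a: str,
    seq_b: str,
    regions: RegionAnnotation,
    scoring: Scoring | None = None,
) -> DivergenceRecord:
    """Align two orthologous hairpins and compute the full divergence record.

    Region coordinates are anchored on sequence A (the reference ortholog).
    """
    a = normalize_seq(seq_a)
    if len(a) != regions.hairpin_length:
        raise ValueError(
            f"annotation length {regions.hairpin_length} != sequence length {len(a)}"
        )
    aln_a, aln_b, _score = align_orthologs(seq_a, seq_b, scoring)
    rec = DivergenceRecord(pair_id=pair_id)
    if regions.atypical_arms:
        rec.flags.append(f"atypical-arm-length:{','.join(regions.atypical_arms)}")
    for which in REGIONS:
        try:
            mask = region_slice(regions, which)
        except ValueError:
            rec.flags.append(f"{which}:undefined")
            continue
        rate, subs, sites = p_distance(aln_a, aln_b, mask)
        entry = {"sites": sites, "substitutions": subs, "rate": rate}
        if sites == 0:
            rec.flags.append(f"{which}:zero-sites")
            entry.update({"k2p": math.nan, "P": math.nan, "Q": math.nan})
        else:
            try:
                d, P, Q = kimura2p(aln_a, aln_b, mask)
                entry.update({"k2p": d, "P": P, "Q": Q})
            except K2PSaturationError:
                rec.flags.append(f"{which}:k2p-saturated")
                entry.update({"k2p": math.nan, "P": math.nan, "Q": math.nan})
        rec.regions[which] = entry
    rec.per_arm = mature_substitutions(aln_a, aln_b, regions)
    total = sum(c for c, _ in rec.per_arm.values())
    rec.mature_substitution_count = total
    rec.mature_class = classify_mature_count(total)
    return rec
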