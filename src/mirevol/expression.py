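"""Small-RNA read processing: filtering, counting, normalization, breadth.

Reads are assigned to microRNA hairpins by windowed string matching allowing
at most one substitution (no genome aligner: loci are matched directly,
which is deterministic and sufficient for hairpin-level counting). The
filtering rules mirror standard small-RNA practice: keep reads of 19-24 nt
mapping to fewer than five loci, allowing one mismatch; known contaminant
sequences (rRNA/tRNA fragments etc.) can be removed via a blocklist.

Counts are normalized to reads per million (RPM) against either the total
reads mapping to microRNAs in the library or the total reads mapping to the
genome. Paralogous loci sharing an identical mature sequence cannot be
distinguished by the reads, so their read total is divided equally among the
loci.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MIN_READ_LEN = 19
MAX_READ_LEN = 24
MAX_LOCI = 4  # "fewer than five loci"
MAX_MISMATCHES = 1

_ENC = {c: i for i, c in enumerate("ACGTN")}


@dataclass(frozen=True)
class ReadRecord:
    """One (collapsed) small-RNA read after mapping."""

    sequence: str
    count: int
    loci: tuple[str, ...]
    mismatches: int  # mismatches used by the best placement(s); -1 = unmapped

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class ExpressionMatrix:
    """MicroRNA x library counts with per-library totals.

    ``counts`` holds raw read counts (microRNA rows, ordered developmental
    libraries as columns). ``mirna_mapped`` / ``genome_mapped`` are the
    per-library normalization denominators.
    """

    counts: pd.DataFrame
    mirna_mapped: pd.Series | None = None
    genome_mapped: pd.Series | None = None
    per_arm: pd.DataFrame | None = None
    unassigned: pd.Series | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("raw counts must be non-negative")
        if self.mirna_mapped is None:
            self.mirna_mapped = self.counts.sum(axis=0)

    @property
    def stages(self) -> list[str]:
        return list(self.counts.columns)


class _LocusIndex:
    """Hairpin set indexed for exact-substring and 1-substitution lookup."""

    def __init__(self, loci: dict[str, str]):
        self.loci = {k: v.upper().replace("U", "T") for k, v in loci.items()}
        self._arr = {
            k: np.frombuffer(v.encode(), dtype=np.uint8) for k, v in self.loci.items()
        }

    def hits(self, seq: str, max_mm: int = MAX_MISMATCHES) -> tuple[tuple[str, ...], int]:
        """All loci containing *seq* within ``max_mm`` substitutions.

        Returns (locus ids, mismatches of the best placement). Placement is
        substitution-only (windows of the read's length; no indels).
        """
        seq = seq.upper().replace("U", "T")
        q = np.frombuffer(seq.encode(), dtype=np.uint8)
        L = len(q)
        best = max_mm + 1
        hit_mm: dict[str, int] = {}
        for lid, t in self._arr.items():
            n = len(t) - L + 1
            if n <= 0:
                continue
            if seq in self.loci[lid]:
                hit_mm[lid] = 0
                best = 0
                continue
            if max_mm == 0:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(t, L)
            mm = (windows != q).sum(axis=1).min()
            if mm <= max_mm:
                hit_mm[lid] = int(mm)
                best = min(best, int(mm))
        if not hit_mm:
            return (), -1
        return tuple(sorted(hit_mm)), best


def map_read(seq: str, loci: dict[str, str], max_mm: int = MAX_MISMATCHES) -> tuple[tuple[str, ...], int]:
    """Map a single read sequence against hairpin loci (convenience wrapper)."""
    return _LocusIndex(loci).hits(seq, max_mm)


def _collapse(reads) -> Counter:
    c = Counter()
    for r in reads:
        c[r.upper().replace("U", "T")] += 1
    return c


def map_reads(
    reads,
    loci: dict[str, str],
    max_mm: int = MAX_MISMATCHES,
) -> list[ReadRecord]:
    """Collapse identical reads and map each unique sequence to loci."""
    index = _LocusIndex(loci)
    records = []
    for seq, count in sorted(_collapse(reads).items()):
        hit, mm = index.hits(seq, max_mm)
        records.append(ReadRecord(sequence=seq, count=count, loci=hit, mismatches=mm))
    return records


def filter_reads(
    records: list[ReadRecord],
    min_len: int = MIN_READ_LEN,
    max_len: int = MAX_READ_LEN,
    max_loci: int = MAX_LOCI,
    max_mm: int = MAX_MISMATCHES,
    blocklist: set[str] | None = None,
) -> tuple[list[ReadRecord], dict[str, int]]:
    """Apply the read-survival rules; returns (survivors, per-rule drop log).

    A read survives iff its length is within [min_len, max_len], it maps to
    at most ``max_loci`` loci with at most ``max_mm`` mismatches, and its
    sequence is not on the contaminant blocklist. Idempotent. Unmapped reads
    are kept (they are counted as unassigned downstream), matching a
    hairpin-set mapping where "locus count" constrains only mapped reads.
    """
    blocklist = {s.upper().replace("U", "T") for s in (blocklist or set())}
    survivors = []
    dropped = {"length": 0, "multimap": 0, "mismatches": 0, "blocklist": 0}
    for r in records:
        if not (min_len <= r.length <= max_len):
            dropped["length"] += r.count
        elif r.sequence in blocklist:
            dropped["blocklist"] += r.count
        elif len(r.loci) > max_loci:
            dropped["multimap"] += r.count
        elif r.mismatches > max_mm:
            dropped["mismatches"] += r.count
        else:
            survivors.append(r)
    return survivors, dropped


def count_to_hairpins(
    library_records: dict[str, list[ReadRecord]],
    loci: dict[str, str],
    arms: dict[str, dict[str, tuple[int, int]]] | None = None,
    stages: list[str] | None = None,
) -> ExpressionMatrix:
    """Build the raw count matrix from filtered, mapped reads.

    A read mapping to k loci contributes its full count to each of them
    (paralog sharing is resolved afterwards by :func:`split_paralog_reads`,
    which divides by k). Reads matching no locus are tallied as unassigned.
    When mature-arm coordinates are supplied, per-arm counts (placement of
    the read's best match inside an arm interval) are retained.
    """
    stages = stages or list(library_records)
    mirnas = sorted(loci)
    counts = pd.DataFrame(0.0, index=mirnas, columns=stages)
    unassigned = pd.Series(0, index=stages, dtype=int)
    arm_rows: dict[tuple[str, str], dict[str, float]] = {}
    index = _LocusIndex(loci)
    for stage in stages:
        for rec in library_records.get(stage, []):
            if not rec.loci:
                unassigned[stage] += rec.count
                continue
            share = rec.count  # full count per locus; paralog split divides later
            for lid in rec.loci:
                counts.at[lid, stage] += share
                if arms and lid in arms:
                    pos = index.loci[lid].find(rec.sequence)
                    if pos >= 0:
                        for arm, (s, e) in arms[lid].items():
                            if s - 1 <= pos and pos + rec.length <= e:
                                arm_rows.setdefault((lid, arm), {}).setdefault(stage, 0)
                                arm_rows[(lid, arm)][stage] += share
    per_arm = None
    if arm_rows:
        per_arm = pd.DataFrame(arm_rows).T.reindex(columns=stages).fillna(0.0)
    return ExpressionMatrix(counts=counts, per_arm=per_arm, unassigned=unassigned)


def identity_groups(mature: dict[str, str]) -> list[list[str]]:
    """Group loci sharing an identical mature sequence."""
    by_seq: dict[str, list[str]] = {}
    for lid, seq in mature.items():
        by_seq.setdefault(seq.upper().replace("U", "T"), []).append(lid)
    return [sorted(v) for v in by_seq.values() if len(v) > 1]


def split_paralog_reads(matrix: ExpressionMatrix, groups: list[list[str]]) -> ExpressionMatrix:
    """Divide reads of identical-mature paralog groups equally among loci.

    Because counting credited each locus with the full shared count, dividing
    every group member's counts by the group size conserves the true read
    total.
    """
    counts = matrix.counts.copy()
    for group in groups:
        unknown = [g for g in group if g not in counts.index]
        if unknown:
            raise ValueError(f"identity group references unknown loci: {unknown}")
        counts.loc[group] = counts.loc[group] / len(group)
    return ExpressionMatrix(
        counts=counts,
        mirna_mapped=counts.sum(axis=0),
        genome_mapped=matrix.genome_mapped,
        per_arm=matrix.per_arm,
        unassigned=matrix.unassigned,
        meta=dict(matrix.meta),
    )


def normalize(matrix: ExpressionMatrix, denominator: str = "mirna_mapped") -> pd.DataFrame:
    """Reads-per-million normalization: raw * 1e6 / per-library denominator."""
    if denominator == "mirna_mapped":
        denom = matrix.mirna_mapped
    elif denominator == "genome_mapped":
        if matrix.genome_mapped is None:
            raise ValueError("genome-mapped totals unavailable")
        denom = matrix.genome_mapped
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    denom = denom.reindex(matrix.counts.columns)
    zero = denom[denom <= 0]
    if len(zero):
        raise ValueError(f"zero denominator for libraries: {list(zero.index)}")
    rpm = matrix.counts * 1e6 / denom
    rpm.attrs["denominator"] = denominator
    return rpm


def detect_and_breadth(matrix: ExpressionMatrix, threshold: float = 1.0) -> pd.Series:
    """Number of libraries detecting each microRNA (raw count >= threshold)."""
    return (matrix.counts >= threshold).sum(axis=1)


def flag_outliers(matrix: ExpressionMatrix, fold: float = 10.0) -> set[str]:
    """MicroRNAs whose count is >= fold x the next-highest count in any library.

    Operationalizes the manual exclusion of single-microRNA-dominated
    libraries; flagged entries stay in the raw output but are excluded from
    composition/correlation analyses downstream.
    """
    if len(matrix.counts.index) < 2:
        raise ValueError("need at least two microRNAs per library")
    flagged = set()
    for stage in matrix.counts.columns:
        col = matrix.counts[stage].sort_values(ascending=False)
        top, second = col.iloc[0], col.iloc[1]
        if second >= 0 and top >= fold * second and top > 0:
            flagged.add(col.index[0])
    return flagged


def high_expression_filter(rpm: pd.DataFrame, threshold: float = 1000.0) -> tuple[list[str], list[str]]:
    """Partition microRNAs by summed RPM across libraries (high: >= threshold)."""
    total = rpm.sum(axis=1)
    high = sorted(total.index[total >= threshold])
    low = sorted(total.index[total < threshold])
    return high, low
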