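"""Phylogeny-aware synthetic microRNA data with known ground truth.

The generator emulates every input of the study design end to end:

* microRNA families are born on branches of a ranked species tree (8 taxa,
  7 age ranks by default, mirroring a Drosophilid-to-Bilateria ladder) and
  inherited by all descendant species, yielding a noise-free
  presence/absence table and a true origin node per family;
* for each family present in both focal species, the reference hairpin is
  evolved into its ortholog under a Kimura two-parameter substitution
  process with region-specific rates (seed slowest, mature intermediate,
  loop/stem-extension fastest) scaled by an age-dependent family factor, so
  older families evolve slower, as observed between distant congeners;
* stage-structured small-RNA libraries (default 11: nine embryonic
  timepoints, larva, adult) draw negative-binomial counts whose log-means
  couple divergence to expression twice: a stage-independent conservation
  bias (conserved microRNAs are more highly expressed overall) and an
  early-stage boost for fast-evolving microRNAs, reproducing the decline of
  fast-evolving microRNA expression as development progresses;
* reads can be emitted per library (the mature arm sequence, repeated count
  times), optionally spiked with length and multimapping contaminants for
  filter testing.

All randomness flows from the single integer seed in the configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mirevol.divergence import RegionAnnotation, region_slice
from mirevol.expression import ExpressionMatrix
from mirevol.homology import SpeciesTree

# Ladder tree: each internal node Nk carries age rank k (1 = Drosophilid
# crown, 7 = bilaterian root). Leaf branches inherit the parent's rank.
DEFAULT_TREE = (
    "((((((('D.virilis','D.melanogaster')'N1|rank=1','A.gambiae')'N2|rank=2',"
    "'B.mori')'N3|rank=3','T.castaneum')'N4|rank=4','D.pulex')'N5|rank=5',"
    "'I.scapularis')'N6|rank=6','B.floridae')'N7|rank=7';"
)

DEFAULT_STAGES = ("e0", "e2", "e4", "e6", "e8", "e10", "e12", "e14", "e16",
                  "larva", "adult")

# birth probabilities per branch (node name): youngest and oldest branches
# carry most families, as in deep microRNA phylostratigraphies
DEFAULT_BIRTH_RATES = {
    "N1": 0.30, "N2": 0.08, "N3": 0.08, "N4": 0.10,
    "N5": 0.06, "N6": 0.08, "N7": 0.30,
}

_BASES = np.frombuffer(b"AGCT", dtype=np.uint8)  # transition pairs (A,G), (C,T)
_IDX = {c: i for i, c in enumerate("AGCT")}


@dataclass(frozen=True)
class ContaminantSpec:
    """Contaminant read fractions (relative to each library's clean total)."""

    frac_short: float = 0.0   # 18 nt, fails the length filter
    frac_long: float = 0.0    # 30 nt, fails the length filter
    frac_multimap: float = 0.0  # 22 nt implanted in 5 decoy loci


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; defaults are the study-like conditions."""

    tree_newick: str = DEFAULT_TREE
    reference: str = "D.virilis"
    partner: str = "D.melanogaster"
    n_families: int = 300
    birth_rates: dict = field(default_factory=lambda: dict(DEFAULT_BIRTH_RATES))
    # expected substitutions per site on the reference-partner path, for a
    # family rate factor of 1 (youngest age class)
    region_rates: dict = field(default_factory=lambda: {
        "seed": 0.06, "mature": 0.12, "outside": 0.35})
    ts_tv_ratio: float = 2.0
    stages: tuple = DEFAULT_STAGES
    assoc_strength: float = 6.0       # early-stage boost of fast evolvers (log scale)
    conservation_bias: float = 6.5    # stage-independent penalty on divergence (log scale)
    baseline_sd: float = 0.8          # sd of per-microRNA baseline log expression
    nb_dispersion: float = 0.3
    library_depth: int = 1_000_000
    background_fraction: float = 1.5  # extra genome-mapped (non-microRNA) reads
    hairpin_length: int = 90
    arm_5p: tuple = (10, 31)
    arm_3p: tuple = (60, 81)
    age_rate_floor: float = 0.2       # rate factor at the oldest rank (rank 1 -> 1.0)
    rate_lognorm_sd: float = 0.4      # family-to-family rate scatter
    n_duplicates: int = 0
    seed: int = 0

    def validate(self) -> None:
        if any(v < 0 for v in self.region_rates.values()):
            raise ValueError("region_rates must be >= 0")
        if len(self.stages) < 2:
            raise ValueError("need >= 2 stages")
        if self.library_depth <= 0:
            raise ValueError("library_depth must be positive")
        if self.nb_dispersion < 0:
            raise ValueError("negative dispersion")
        if sum(self.birth_rates.values()) <= 0:
            raise ValueError("total birth rate is zero")

    def regions(self) -> RegionAnnotation:
        return RegionAnnotation(
            hairpin_length=self.hairpin_length,
            arms=(("5p",) + self.arm_5p, ("3p",) + self.arm_3p),
        )

    def earliness(self) -> pd.Series:
        """Linear stage-earliness score: 1 at the first stage, 0 at the last."""
        s = len(self.stages)
        return pd.Series(
            [(s - 1 - i) / (s - 1) for i in range(s)], index=list(self.stages))


@dataclass
class SyntheticDataset:
    """A complete synthetic study with ground truth for every entity."""

    config: SimulationConfig
    tree: SpeciesTree
    families: pd.DataFrame       # family_id, origin_node, age_rank, rate_factor
    presence: pd.DataFrame       # family x species, 0/1
    loci_ref: dict               # locus id -> reference hairpin sequence
    loci_partner: dict           # locus id -> partner hairpin (orthologs only)
    regions: RegionAnnotation
    truth: pd.DataFrame          # per locus: true region distances, age, etc.
    matrix: ExpressionMatrix
    true_means: pd.DataFrame     # expected counts per locus x stage
    stage_slopes: pd.Series      # true log-slope of expression on divergence per stage

    @property
    def mature(self) -> dict:
        """Reference-species mature (5p arm) sequence per locus."""
        s, e = self.config.arm_5p
        return {lid: seq[s - 1:e] for lid, seq in self.loci_ref.items()}


def k2p_transition_matrix(d: float, ts_tv_ratio: float) -> np.ndarray:
    """Site substitution probabilities after expected distance *d*.

    Closed-form Kimura two-parameter transition matrix (base order A,G,C,T)
    with transition:transversion expectation ratio ``ts_tv_ratio``.
    """
    kappa = ts_tv_ratio
    a = d * kappa / (kappa + 1.0)          # alpha * t
    b = d / (2.0 * (kappa + 1.0))          # beta * t
    p_same = 0.25 + 0.25 * math.exp(-4 * b) + 0.5 * math.exp(-2 * (a + b))
    p_ts = 0.25 + 0.25 * math.exp(-4 * b) - 0.5 * math.exp(-2 * (a + b))
    p_tv = 0.25 - 0.25 * math.exp(-4 * b)  # each of two transversion targets
    m = np.full((4, 4), p_tv)
    for i, j in ((0, 1), (1, 0), (2, 3), (3, 2)):
        m[i, j] = p_ts
    np.fill_diagonal(m, p_same)
    return m


def random_hairpin(length: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list("AGCT"))[rng.integers(0, 4, size=length)])


def evolve_sequence(seq: str, d: float, ts_tv_ratio: float,
                    rng: np.random.Generator) -> str:
    """Evolve a sequence at a uniform expected distance *d* (no regions)."""
    s = seq.upper().replace("U", "T")
    codes = np.array([_IDX[c] for c in s])
    cum = np.cumsum(k2p_transition_matrix(d, ts_tv_ratio), axis=1)
    u = rng.random(len(codes))
    out = np.minimum((u[:, None] > cum[codes]).sum(axis=1), 3)
    return "".join("AGCT"[i] for i in out)


def simulate_families(config: SimulationConfig, rng: np.random.Generator | None = None):
    """Draw family origins from per-branch birth probabilities.

    Returns (families DataFrame, presence/absence DataFrame, SpeciesTree).
    Presence is noise-free: all species descending from the origin carry the
    family.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    tree = SpeciesTree.from_newick(config.tree_newick)
    names = list(config.birth_rates)
    probs = np.array([config.birth_rates[n] for n in names], dtype=float)
    if probs.sum() <= 0:
        raise ValueError("total birth rate is zero")
    probs = probs / probs.sum()
    # resolve node names to clades once
    clades = {}
    for name in names:
        label = name
        try:
            leaves = tree.leaves_under(label)
        except KeyError:
            # allow short names for labelled internal nodes ('N3' for 'N3|rank=3')
            matches = [lbl for lbl in _all_labels(tree) if lbl.split("|")[0] == name]
            if len(matches) != 1:
                raise ValueError(f"birth-rate key {name!r} matches {len(matches)} tree nodes")
            label = matches[0]
            leaves = tree.leaves_under(label)
        clades[name] = (label, tree.rank_of(label), leaves)
    draws = rng.choice(len(names), size=config.n_families, p=probs)
    rows, pres_rows = [], []
    species = tree.species
    for i, k in enumerate(draws):
        name = names[k]
        label, rank, leaves = clades[name]
        fid = f"mir-{i + 1:04d}"
        rows.append({"family_id": fid, "origin_node": label, "age_rank": rank})
        pres_rows.append({sp: int(sp in leaves) for sp in species})
    families = pd.DataFrame(rows).set_index("family_id")
    presence = pd.DataFrame(pres_rows, index=families.index)
    return families, presence, tree


def _all_labels(tree: SpeciesTree):
    return list(tree._labels.values())


def evolve_ortholog_pair(
    hairpin: str,
    regions: RegionAnnotation,
    config: SimulationConfig,
    rng: np.random.Generator,
    rate_scale: float = 1.0,
) -> tuple[str, dict[str, float]]:
    """Evolve a hairpin into its ortholog under region-specific K2P rates.

    Substitutions only (the alignment stays gap-free); each position draws
    its new base from the closed-form K2P transition matrix at that
    region's expected distance. Returns the ortholog plus the true expected
    distances per reporting region (hairpin, mature, seed, outside_mature).
    """
    seq = hairpin.upper().replace("U", "T")
    if len(seq) != regions.hairpin_length:
        raise ValueError("annotation does not match hairpin length")
    mature = region_slice(regions, "mature")
    seed_m = region_slice(regions, "seed")
    outside = region_slice(regions, "outside_mature")
    per_site = np.empty(regions.hairpin_length)
    per_site[outside] = config.region_rates["outside"] * rate_scale
    per_site[mature & ~seed_m] = config.region_rates["mature"] * rate_scale
    per_site[seed_m] = config.region_rates["seed"] * rate_scale
    codes = np.array([_IDX[c] for c in seq])
    out = codes.copy()
    for rate in np.unique(per_site):
        mask = per_site == rate
        m = k2p_transition_matrix(float(rate), config.ts_tv_ratio)
        cum = np.cumsum(m, axis=1)
        u = rng.random(mask.sum())
        out[mask] = np.minimum((u[:, None] > cum[codes[mask]]).sum(axis=1), 3)
    ortholog = "".join("AGCT"[i] for i in out)
    true = {
        "hairpin": float(per_site.mean()),
        "mature": float(per_site[mature].mean()),
        "seed": float(per_site[seed_m].mean()),
        "outside_mature": float(per_site[outside].mean()),
    }
    return ortholog, true


def age_rate_factor(age_rank: int, max_rank: int, config: SimulationConfig,
                    rng: np.random.Generator) -> float:
    """Family rate factor: linear decline with age rank, lognormal scatter."""
    base = 1.0 - (1.0 - config.age_rate_floor) * (age_rank - 1) / max(max_rank - 1, 1)
    return float(base * rng.lognormal(0.0, config.rate_lognorm_sd))


def simulate_expression(
    truth: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    mean_zero: set | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Stage-structured negative-binomial counts coupled to divergence.

    ``truth`` needs a ``true_hairpin_rate`` column (expected substitutions
    per site). The log mean of microRNA i at stage s is

        b_i - conservation_bias * q_i + assoc_strength * q_i * earliness_s

    with q_i the divergence quantile (rank scaled to [0, 1]; a monotone
    transform of the substitution rate that spreads the coupling evenly
    across the divergence spectrum), b_i a Gaussian baseline, and earliness
    falling linearly from 1 (first stage) to 0 (last stage). Means are
    scaled so each library's expected total equals ``library_depth``.
    Returns (ExpressionMatrix with genome-mapped totals, expected means).
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed + 1)
    mean_zero = mean_zero or set()
    ids = list(truth.index)
    rate = truth["true_hairpin_rate"].to_numpy(dtype=float)
    if len(ids) > 1 and np.nanstd(rate) > 0:
        z = rate.argsort().argsort() / (len(rate) - 1)
    else:
        z = np.zeros_like(rate)
    b = rng.normal(0.0, config.baseline_sd, size=len(ids))
    earliness = config.earliness().to_numpy()
    logw = (b[:, None]
            - config.conservation_bias * z[:, None]
            + config.assoc_strength * z[:, None] * earliness[None, :])
    w = np.exp(logw)
    w[[i for i, lid in enumerate(ids) if lid in mean_zero], :] = 0.0
    mu = w / w.sum(axis=0, keepdims=True) * config.library_depth
    if config.nb_dispersion == 0:
        counts = rng.poisson(mu)
    else:
        n = 1.0 / config.nb_dispersion
        counts = rng.negative_binomial(n, n / (n + mu))
    counts = pd.DataFrame(counts, index=ids, columns=list(config.stages))
    means = pd.DataFrame(mu, index=ids, columns=list(config.stages))
    mirna_mapped = counts.sum(axis=0)
    genome_mapped = (mirna_mapped * (1.0 + config.background_fraction)).round().astype(int)
    matrix = ExpressionMatrix(
        counts=counts.astype(float),
        mirna_mapped=mirna_mapped.astype(float),
        genome_mapped=genome_mapped.astype(float),
        meta={"seed": config.seed, "stages": list(config.stages)},
    )
    return matrix, means


def emit_reads(
    matrix: ExpressionMatrix,
    mature: dict[str, str],
    rng: np.random.Generator | None = None,
    contaminants: ContaminantSpec | None = None,
) -> tuple[dict[str, list[str]], dict[str, str]]:
    """Emit per-library read multisets reproducing the count matrix exactly.

    Each microRNA contributes its mature sequence, repeated its (rounded)
    count times. Optional contaminants are injected per library: 18/30-nt
    random sequences (length-filter fodder) and a 22-mer implanted in five
    decoy hairpin loci (multimapping fodder); decoys are returned so the
    mapping stage can see them.
    """
    rng = rng or np.random.default_rng(0)
    for lid in matrix.counts.index:
        if lid not in mature:
            raise ValueError(f"no mature sequence for locus {lid}")
        if not (19 <= len(mature[lid]) <= 24):
            raise ValueError(f"mature sequence of {lid} outside 19-24 nt")
    contaminants = contaminants or ContaminantSpec()
    decoys: dict[str, str] = {}
    multi_seq = None
    if contaminants.frac_multimap > 0:
        multi_seq = random_hairpin(22, rng)
        for k in range(5):
            flank_l = random_hairpin(30, rng)
            flank_r = random_hairpin(30, rng)
            decoys[f"decoy-{k + 1}"] = flank_l + multi_seq + flank_r
    libraries: dict[str, list[str]] = {}
    for stage in matrix.counts.columns:
        reads: list[str] = []
        for lid, c in matrix.counts[stage].items():
            reads.extend([mature[lid]] * int(round(c)))
        total = len(reads)
        reads.extend(random_hairpin(18, rng) for _ in range(int(round(total * contaminants.frac_short))))
        reads.extend(random_hairpin(30, rng) for _ in range(int(round(total * contaminants.frac_long))))
        if multi_seq is not None:
            reads.extend([multi_seq] * int(round(total * contaminants.frac_multimap)))
        libraries[stage] = reads
    return libraries, decoys


def simulate_dataset(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Run the full generator: families, sequences, orthologs, counts, truth."""
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    families, presence, tree = simulate_families(config, rng)
    regions = config.regions()
    max_rank = tree.max_rank

    loci_ref: dict[str, str] = {}
    loci_partner: dict[str, str] = {}
    truth_rows = []
    for fid, row in families.iterrows():
        hairpin = random_hairpin(config.hairpin_length, rng)
        loci_ref[fid] = hairpin
        factor = age_rate_factor(int(row.age_rank), max_rank, config, rng)
        has_partner = bool(presence.at[fid, config.partner]) if config.partner in presence.columns else False
        rec = {
            "family_id": fid, "locus_id": fid,
            "origin_node": row.origin_node, "age_rank": int(row.age_rank),
            "rate_factor": factor, "has_ortholog": has_partner,
        }
        if has_partner:
            ortholog, true_d = evolve_ortholog_pair(hairpin, regions, config, rng, factor)
            loci_partner[fid] = ortholog
            for reg, d in true_d.items():
                rec[f"true_{reg}_rate"] = d
        else:
            # the underlying evolutionary speed exists even without an
            # observable ortholog; expression still couples to it
            base = {reg: config.region_rates[k] * factor for reg, k in
                    (("seed", "seed"), ("mature", "mature"), ("outside_mature", "outside"))}
            mature_mask = region_slice(regions, "mature")
            n = regions.hairpin_length
            n_mat = int(mature_mask.sum())
            seed_n = int(region_slice(regions, "seed").sum())
            hp = (base["seed"] * seed_n + base["mature"] * (n_mat - seed_n)
                  + base["outside_mature"] * (n - n_mat)) / n
            rec.update({"true_hairpin_rate": hp, "true_mature_rate": np.nan,
                        "true_seed_rate": np.nan, "true_outside_mature_rate": np.nan})
        truth_rows.append(rec)
    truth = pd.DataFrame(truth_rows).set_index("locus_id")
    truth = truth.rename(columns={"true_hairpin_rate": "true_hairpin_rate"})

    # optional late duplicates: same family, younger presence
    if config.n_duplicates > 0:
        old = truth.index[truth.age_rank > 1][: config.n_duplicates]
        for fid in old:
            did = f"{fid}.dup"
            src = loci_ref[fid]
            dup, _ = evolve_ortholog_pair(src, regions, config, rng, 0.05)
            loci_ref[did] = dup
            row = presence.loc[fid].copy() * 0
            for sp in tree.leaves_under(_short_to_label(tree, "N1")):
                row[sp] = 1
            presence.loc[did] = row
            families.loc[did] = {"origin_node": _short_to_label(tree, "N1"), "age_rank": 1}
            t = truth.loc[fid].copy()
            t["age_rank"] = 1
            t["origin_node"] = _short_to_label(tree, "N1")
            t["family_id"] = fid
            t["has_ortholog"] = False
            truth.loc[did] = t

    matrix, means = simulate_expression(truth, config, np.random.default_rng(config.seed + 1))
    earliness = config.earliness()
    slopes = pd.Series(
        config.assoc_strength * earliness - config.conservation_bias,
        index=earliness.index,
    )
    families = families.loc[truth.index.intersection(families.index)]
    return SyntheticDataset(
        config=config, tree=tree, families=families, presence=presence,
        loci_ref=loci_ref, loci_partner=loci_partner, regions=regions,
        truth=truth, matrix=matrix, true_means=means, stage_slopes=slopes,
    )


def _short_to_label(tree: SpeciesTree, short: str) -> str:
    for lbl in _all_labels(tree):
        if lbl.split("|")[0] == short:
            return lbl
    raise KeyError(short)
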