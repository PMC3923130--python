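"""Orchestration: simulate -> homology/age -> divergence -> expression -> analysis.

One YAML/JSON configuration drives the whole run. Each stage writes its
outputs under its own subdirectory of the run directory and records a
``.done`` marker with a digest of the stage-relevant configuration; reruns
skip stages whose marker matches (delete a stage directory to recompute it
and its dependents). A manifest lists every output file with its SHA-256
digest, so identical config + seed reproduces identical tabular outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from mirevol import io as mio
from mirevol.alignment import Scoring
from mirevol.analysis import (
    breadth_contrast,
    expression_divergence_scatter_stats,
    stage_composition,
    stage_index_profile,
    tertile_bins,
)
from mirevol.divergence import RegionAnnotation, divergence_record
from mirevol.expression import (
    ExpressionMatrix,
    count_to_hairpins,
    detect_and_breadth,
    filter_reads,
    flag_outliers,
    high_expression_filter,
    identity_groups,
    map_reads,
    normalize,
    split_paralog_reads,
)
from mirevol.homology import SpeciesTree, assign_age, family_age_propagation, reciprocal_best_hits
from mirevol.simulate import ContaminantSpec, SimulationConfig, emit_reads, simulate_dataset

log = logging.getLogger("mirevol")

STAGES = ("simulate", "homology", "divergence", "expression", "analyze")

DEFAULT_CONFIG = {
    "seed": 0,
    "simulate": {
        "n_families": 300,
        "library_depth": 500_000,
        "emit_reads": False,
        "contaminants": {"frac_short": 0.0, "frac_long": 0.0, "frac_multimap": 0.0},
    },
    "expression": {
        "min_len": 19, "max_len": 24, "max_loci": 4, "max_mismatches": 1,
        "detect_threshold": 1, "outlier_fold": 10, "denominator": "mirna_mapped",
    },
    "analyze": {"bins": 3, "bootstrap": 1000, "high_rpm": 1000, "plots": False},
}


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(path_or_dict or {})
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    _validate_config(cfg)
    return cfg


def _validate_config(cfg: dict) -> None:
    errors = []
    if not isinstance(cfg.get("seed"), int):
        errors.append("seed must be an integer")
    sim = cfg.get("simulate", {})
    if sim.get("n_families", 1) < 1:
        errors.append("simulate.n_families must be >= 1")
    expr = cfg.get("expression", {})
    if expr.get("denominator") not in ("mirna_mapped", "genome_mapped"):
        errors.append("expression.denominator must be mirna_mapped or genome_mapped")
    if cfg.get("analyze", {}).get("bins", 3) < 2:
        errors.append("analyze.bins must be >= 2")
    if errors:
        raise ValueError("invalid configuration: " + "; ".join(errors))


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_key(cfg: dict, stage: str) -> str:
    relevant = {"seed": cfg["seed"], stage: cfg.get(stage, {})}
    if stage != "simulate":
        relevant["simulate"] = cfg.get("simulate", {})
    return hashlib.sha256(json.dumps(relevant, sort_keys=True).encode()).hexdigest()


def _done(stage_dir: Path, key: str) -> bool:
    marker = stage_dir / ".done"
    return marker.exists() and marker.read_text().strip() == key


def _mark(stage_dir: Path, key: str) -> None:
    (stage_dir / ".done").write_text(key + "\n")


def _sim_config(cfg: dict) -> SimulationConfig:
    sim = dict(cfg.get("simulate", {}))
    sim.pop("emit_reads", None)
    sim.pop("contaminants", None)
    known = set(SimulationConfig.__dataclass_fields__)
    unknown = set(sim) - known
    if unknown:
        raise ValueError(f"unknown simulate keys: {sorted(unknown)}")
    if "stages" in sim:
        sim["stages"] = tuple(sim["stages"])
    return SimulationConfig(seed=cfg["seed"], **sim)


def run_pipeline(config, outdir) -> dict:
    """Run all stages; returns the manifest (also written to manifest.json)."""
    cfg = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    for stage in STAGES:
        t0 = time.time()
        stage_dir = outdir / stage
        key = _stage_key(cfg, stage)
        if _done(stage_dir, key):
            log.info("stage %s: cached, skipping", stage)
            continue
        stage_dir.mkdir(parents=True, exist_ok=True)
        log.info("stage %s: running", stage)
        _RUNNERS[stage](cfg, outdir, stage_dir)
        _mark(stage_dir, key)
        timings[stage] = round(time.time() - t0, 3)

    manifest = {
        "tool": "mirevol",
        "version": _version(),
        "seed": cfg["seed"],
        "config": cfg,
        "timings_s": timings,
        "outputs": {
            str(p.relative_to(outdir)): _digest(p)
            for p in sorted(outdir.rglob("*"))
            if p.is_file() and p.name not in (".done", "manifest.json")
            and p.suffix not in (".png", ".pdf", ".svg")
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def _version() -> str:
    from mirevol import __version__
    return __version__


# ---------------------------------------------------------------- stages

def _run_simulate(cfg: dict, outdir: Path, stage_dir: Path) -> None:
    ds = simulate_dataset(_sim_config(cfg))
    mio.write_fasta(ds.loci_ref, stage_dir / "hairpins_ref.fasta")
    mio.write_fasta(ds.loci_partner, stage_dir / "hairpins_partner.fasta")
    mio.write_gff3({lid: ds.regions for lid in ds.loci_ref}, stage_dir / "arms.gff3")
    mio.write_tsv(ds.presence, stage_dir / "presence.tsv", "family_id")
    mio.write_newick(ds.tree.as_newick(), stage_dir / "tree.nwk")
    mio.write_tsv(ds.matrix.counts, stage_dir / "counts.tsv", "locus_id")
    totals = pd.DataFrame({"mirna_mapped": ds.matrix.mirna_mapped,
                           "genome_mapped": ds.matrix.genome_mapped})
    mio.write_tsv(totals, stage_dir / "totals.tsv", "library")
    mio.write_tsv(ds.truth, stage_dir / "truth.tsv", "locus_id")
    sim = cfg.get("simulate", {})
    if sim.get("emit_reads"):
        cont = ContaminantSpec(**sim.get("contaminants", {}))
        libs, decoys = emit_reads(ds.matrix, ds.mature,
                                  np.random.default_rng(cfg["seed"] + 2), cont)
        reads_dir = stage_dir / "reads"
        reads_dir.mkdir(exist_ok=True)
        for stage_name, reads in libs.items():
            mio.write_reads_fasta(reads, reads_dir / f"{stage_name}.fasta")
        if decoys:
            mio.write_fasta(decoys, stage_dir / "decoys.fasta")
    mature = ds.mature
    mio.write_fasta(mature, stage_dir / "mature_ref.fasta")


def _run_homology(cfg: dict, outdir: Path, stage_dir: Path) -> None:
    sim_dir = outdir / "simulate"
    loci_ref = mio.read_fasta(sim_dir / "hairpins_ref.fasta")
    loci_partner = mio.read_fasta(sim_dir / "hairpins_partner.fasta")
    presence = mio.read_tsv(sim_dir / "presence.tsv")
    tree = SpeciesTree.from_file(sim_dir / "tree.nwk")
    sim = _sim_config(cfg)

    pairs = reciprocal_best_hits(loci_ref, loci_partner, Scoring())
    pd.DataFrame(
        [{"locus_ref": p.locus_a, "locus_partner": p.locus_b,
          "forward_score": p.forward_score, "reverse_score": p.reverse_score}
         for p in pairs]
    ).to_csv(stage_dir / "ortholog_pairs.tsv", sep="\t", index=False)

    ages = {}
    for fid in presence.index:
        present = set(presence.columns[presence.loc[fid] == 1])
        if sim.reference not in present:
            continue
        ages[fid] = assign_age(present, tree, sim.reference, family_id=fid)
    families: dict[str, list[str]] = {}
    for lid in ages:
        families.setdefault(lid.split(".")[0], []).append(lid)
    propagated = family_age_propagation(ages, families)
    pd.DataFrame(
        [{"locus_id": lid, "family_id": a.family_id, "origin_node": a.origin_node,
          "age_rank": a.age_rank, "duplication_inflated": a.duplication_inflated}
         for lid, a in sorted(propagated.items())]
    ).set_index("locus_id").to_csv(stage_dir / "ages.tsv", sep="\t")


def _run_divergence(cfg: dict, outdir: Path, stage_dir: Path) -> None:
    sim_dir = outdir / "simulate"
    loci_ref = mio.read_fasta(sim_dir / "hairpins_ref.fasta")
    loci_partner = mio.read_fasta(sim_dir / "hairpins_partner.fasta")
    annotations = mio.read_gff3(sim_dir / "arms.gff3")
    pairs = pd.read_csv(outdir / "homology" / "ortholog_pairs.tsv", sep="\t")
    rows = []
    for _, p in pairs.iterrows():
        rec = divergence_record(
            p.locus_ref, loci_ref[p.locus_ref], loci_partner[p.locus_partner],
            annotations[p.locus_ref])
        for region, vals in rec.regions.items():
            rows.append({"pair_id": rec.pair_id, "region": region, **vals,
                         "mature_count": rec.mature_substitution_count,
                         "mature_class": rec.mature_class,
                         "flags": ";".join(rec.flags)})
    pd.DataFrame(rows).to_csv(stage_dir / "divergence.tsv", sep="\t", index=False)


def _load_matrix(cfg: dict, outdir: Path) -> ExpressionMatrix:
    sim_dir = outdir / "simulate"
    ecfg = cfg["expression"]
    totals = mio.read_tsv(sim_dir / "totals.tsv")
    reads_dir = sim_dir / "reads"
    loci = mio.read_fasta(sim_dir / "hairpins_ref.fasta")
    decoy_path = sim_dir / "decoys.fasta"
    if reads_dir.is_dir():
        mapping_loci = dict(loci)
        if decoy_path.exists():
            mapping_loci.update(mio.read_fasta(decoy_path))
        stages = list(mio.read_tsv(sim_dir / "counts.tsv").columns)
        libraries = {}
        drop_totals: dict[str, int] = {}
        for stage_name in stages:
            reads = mio.read_reads(reads_dir / f"{stage_name}.fasta")
            records = map_reads(reads, mapping_loci, ecfg["max_mismatches"])
            survivors, dropped = filter_reads(
                records, ecfg["min_len"], ecfg["max_len"],
                ecfg["max_loci"], ecfg["max_mismatches"])
            for rule, n in dropped.items():
                drop_totals[rule] = drop_totals.get(rule, 0) + n
                if n:
                    log.info("stage %s: dropped %d reads by %s rule", stage_name, n, rule)
            libraries[stage_name] = survivors
        matrix = count_to_hairpins(libraries, loci, stages=stages)
        matrix.meta["dropped"] = drop_totals
        mature = mio.read_fasta(sim_dir / "mature_ref.fasta")
        matrix = split_paralog_reads(matrix, identity_groups(mature))
        matrix.genome_mapped = totals["genome_mapped"].astype(float)
        return matrix
    counts = mio.read_tsv(sim_dir / "counts.tsv")
    return ExpressionMatrix(
        counts=counts,
        mirna_mapped=totals["mirna_mapped"].astype(float),
        genome_mapped=totals["genome_mapped"].astype(float),
    )


def _run_expression(cfg: dict, outdir: Path, stage_dir: Path) -> None:
    ecfg = cfg["expression"]
    matrix = _load_matrix(cfg, outdir)
    mio.write_tsv(matrix.counts, stage_dir / "counts_raw.tsv", "locus_id")
    for denom in ("mirna_mapped", "genome_mapped"):
        rpm = normalize(matrix, denom)
        mio.write_tsv(rpm, stage_dir / f"rpm_{denom.split('_')[0]}.tsv", "locus_id")
    breadth = detect_and_breadth(matrix, ecfg["detect_threshold"])
    breadth.rename("breadth").to_csv(stage_dir / "breadth.tsv", sep="\t",
                                     index_label="locus_id")
    flagged = flag_outliers(matrix, ecfg["outlier_fold"])
    pd.Series(sorted(flagged), name="locus_id").to_csv(
        stage_dir / "flags.tsv", sep="\t", index=False)


def _run_analyze(cfg: dict, outdir: Path, stage_dir: Path) -> None:
    acfg = cfg["analyze"]
    ecfg = cfg["expression"]
    expr_dir = outdir / "expression"
    counts = mio.read_tsv(expr_dir / "counts_raw.tsv")
    totals = mio.read_tsv(outdir / "simulate" / "totals.tsv")
    matrix = ExpressionMatrix(counts=counts,
                              mirna_mapped=totals["mirna_mapped"].astype(float),
                              genome_mapped=totals["genome_mapped"].astype(float))
    div_long = pd.read_csv(outdir / "divergence" / "divergence.tsv", sep="\t")
    divergence = (div_long[div_long.region == "hairpin"]
                  .set_index("pair_id")["rate"])
    ages = mio.read_tsv(outdir / "homology" / "ages.tsv")["age_rank"]
    flagged = set(pd.read_csv(expr_dir / "flags.tsv", sep="\t")["locus_id"].astype(str))
    divergence = divergence[~divergence.index.isin(flagged)]

    denom = ecfg["denominator"]
    rpm = normalize(matrix, denom)
    bins, ranges = tertile_bins(divergence, acfg["bins"])
    comp = {d: stage_composition(normalize(matrix, d), bins)
            for d in ("mirna_mapped", "genome_mapped")}
    comp[denom].to_csv(stage_dir / "composition.tsv", sep="\t", index_label="stage")

    profile = stage_index_profile(
        matrix, ages, divergence, rpm=rpm,
        n_boot=acfg["bootstrap"], seed=cfg["seed"],
        detection_threshold=ecfg["detect_threshold"])
    profile.table.to_csv(stage_dir / "stage_indices.tsv", sep="\t")

    breadth = mio.read_tsv(expr_dir / "breadth.tsv")["breadth"]
    try:
        contrast = breadth_contrast(divergence, breadth)
    except ValueError as exc:  # e.g. everything expressed at all stages
        log.warning("breadth contrast unavailable: %s", exc)
        contrast = {"flag": str(exc)}
    scatter = {s: expression_divergence_scatter_stats(rpm, divergence, s)
               for s in ("sum", "max", "mean-over-expressed")}
    high, low = high_expression_filter(normalize(matrix, "mirna_mapped"),
                                       acfg["high_rpm"])
    results = {
        "schema_version": 1,
        "seed": cfg["seed"],
        "bins": [{"members": b, "range": r} for b, r in zip(bins, ranges)],
        "composition": {d: comp[d].to_dict(orient="index") for d in comp},
        "stage_indices": profile.table.to_dict(orient="index"),
        "breadth_contrast": contrast,
        "scatter": {k: {"r": v[0], "p": v[1]} for k, v in scatter.items()},
        "n_high_expression": len(high), "n_low_expression": len(low),
        "outliers_excluded": sorted(flagged),
    }
    (stage_dir / "results.json").write_text(
        json.dumps(results, indent=2, default=_json_default) + "\n")
    if acfg.get("plots"):
        from mirevol.plotting import plot_composition, plot_stage_profiles
        plot_composition(comp[denom], stage_dir / "composition.png")
        plot_stage_profiles(profile.table, stage_dir / "stage_indices.png")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return None if math.isnan(o) else float(o)
    raise TypeError(type(o))


_RUNNERS = {
    "simulate": _run_simulate,
    "homology": _run_homology,
    "divergence": _run_divergence,
    "expression": _run_expression,
    "analyze": _run_analyze,
}


# ---------------------------------------------------------------- validation

def validate_inputs(paths: dict) -> list[str]:
    """Check that declared input files parse and are mutually consistent.

    ``paths`` may contain: hairpins (FASTA), gff (GFF3), tree (Newick),
    presence (TSV). Returns a list of human-readable problems (empty =
    clean).
    """
    report: list[str] = []
    hairpins = annotations = tree = presence = None
    if "hairpins" in paths:
        try:
            hairpins = mio.read_fasta(paths["hairpins"])
            if not hairpins:
                report.append("hairpins FASTA contains no sequences")
        except Exception as exc:
            report.append(f"hairpins FASTA unreadable: {exc}")
    if "gff" in paths:
        try:
            annotations = mio.read_gff3(paths["gff"])
        except Exception as exc:
            report.append(f"GFF3 unreadable: {exc}")
    if hairpins and annotations:
        for lid, ann in annotations.items():
            if lid in hairpins and ann.hairpin_length != len(hairpins[lid]):
                report.append(
                    f"{lid}: GFF3 length {ann.hairpin_length} != FASTA length "
                    f"{len(hairpins[lid])}")
            for arm, s, e in ann.arms:
                if lid in hairpins and e > len(hairpins[lid]):
                    report.append(f"{lid}-{arm}: mature arm [{s},{e}] outside hairpin")
    if "tree" in paths:
        try:
            tree = SpeciesTree.from_file(paths["tree"])
        except Exception as exc:
            report.append(f"tree unreadable: {exc}")
    if "presence" in paths:
        try:
            presence = mio.read_tsv(paths["presence"])
        except Exception as exc:
            report.append(f"presence table unreadable: {exc}")
    if tree is not None and presence is not None:
        missing = set(presence.columns) - set(tree.species)
        if missing:
            report.append(f"species in presence table absent from tree: {sorted(missing)}")
    return report
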