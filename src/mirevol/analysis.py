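"""Stage-resolved conservation-expression statistics and TAI/TDI indices.

The transcriptome age index (TAI) at developmental stage s is the
expression-weighted mean age rank of the microRNAs expressed at that stage:

    TAI_s = sum_i a_i * e_is / sum_i e_is

with a_i the family age rank (1 = youngest .. 7 = oldest) and e_is the
expression of microRNA i at stage s; high TAI means an older microRNA
transcriptome. The transcriptome divergence index (TDI) replaces a_i with
the substitutions per site n_i of the ortholog pair, so high TDI means the
stage expresses fast-evolving microRNAs. Bootstrap standard deviations
resample microRNAs with replacement.

Stage-wise association between divergence and expression is measured by
Spearman rank correlation over the microRNAs detected at the stage; ranks
within a stage do not depend on the per-library normalization denominator,
so these correlations are normalization-invariant.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from mirevol.expression import ExpressionMatrix


@dataclass
class StageIndexResult:
    """Per-stage weighted indices and correlations."""

    table: pd.DataFrame  # index: stage; columns: tai, tai_sd, tdi, tdi_sd, rho, rho_p, m

    def __getitem__(self, stage):
        return self.table.loc[stage]


def tertile_bins(divergence: pd.Series, n_bins: int = 3) -> tuple[list[list[str]], list[tuple[float, float]]]:
    """Split microRNAs into equally sized divergence bins (default tertiles).

    Sorting is ascending by divergence with a stable tie-break on the
    identifier; remainders go to the lower (more conserved) bins, so bin
    sizes differ by at most one. Returns (member lists low..high, per-bin
    (min, max) divergence ranges).
    """
    div = divergence.dropna()
    if len(div) < n_bins:
        raise ValueError(f"need >= {n_bins} divergence values, got {len(div)}")
    if div.nunique() == 1:
        warnings.warn("all divergence values identical; bins follow input order")
    order = sorted(div.index, key=lambda i: (div[i], str(i)))
    n = len(order)
    base, rem = divmod(n, n_bins)
    bins, ranges, start = [], [], 0
    for b in range(n_bins):
        size = base + (1 if b < rem else 0)
        members = order[start:start + size]
        bins.append(members)
        ranges.append((float(div[members[0]]), float(div[members[-1]])))
        start += size
    return bins, ranges


def stage_composition(rpm: pd.DataFrame, bins: list[list[str]]) -> pd.DataFrame:
    """Fraction of summed expression contributed by each bin at each stage.

    Rows are stages, columns bins (low..high); fractions sum to 1 at every
    stage with nonzero total. A stage whose included total is zero gets NaN.
    """
    included = [m for b in bins for m in b]
    sub = rpm.loc[included]
    totals = sub.sum(axis=0)
    out = pd.DataFrame(index=rpm.columns,
                       columns=[f"bin{i+1}" for i in range(len(bins))], dtype=float)
    for i, members in enumerate(bins):
        out[f"bin{i+1}"] = rpm.loc[members].sum(axis=0) / totals.where(totals > 0)
    return out


def stage_correlation(
    matrix: ExpressionMatrix,
    divergence: pd.Series,
    stage: str,
    method: str = "spearman",
    detection_threshold: float = 1.0,
    values: pd.DataFrame | None = None,
) -> tuple[float, float, int]:
    """Rank (or Pearson) correlation of divergence vs expression at a stage.

    Computed over microRNAs detected at the stage (raw count >=
    detection_threshold) that have a divergence value. ``values`` selects
    the expression values to correlate (defaults to raw counts; for Spearman
    the choice of normalization does not change the result).
    Returns (coefficient, two-sided p, m).
    """
    detected = matrix.counts.index[matrix.counts[stage] >= detection_threshold]
    common = [i for i in detected if i in divergence.index and not math.isnan(divergence[i])]
    if len(common) < 3:
        raise ValueError(f"fewer than 3 microRNAs detected at stage {stage!r}")
    expr = (values if values is not None else matrix.counts).loc[common, stage]
    div = divergence[common]
    if expr.nunique() == 1 or div.nunique() == 1:
        raise ValueError(f"zero variance at stage {stage!r}: correlation undefined")
    if method == "spearman":
        rho, p = stats.spearmanr(div, expr)
    elif method == "pearson":
        rho, p = stats.pearsonr(div, expr)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(rho), float(p), len(common)


def breadth_contrast(
    divergence: pd.Series,
    breadth: pd.Series,
    welch: bool = True,
) -> dict:
    """Divergence of broadly vs narrowly expressed microRNAs.

    Groups: breadth equal to the maximum (expressed at all stages) vs the
    rest. Returns group means, the two-sample t statistic and p-value
    (Welch by default), and Spearman rho of breadth vs divergence.
    """
    common = divergence.dropna().index.intersection(breadth.index)
    div = divergence[common]
    br = breadth[common]
    full = div[br == br.max()]
    partial = div[br < br.max()]
    if len(full) < 2 or len(partial) < 2:
        raise ValueError("each breadth group needs >= 2 members")
    if full.var() == 0 and partial.var() == 0 and full.mean() != partial.mean():
        t, p = math.inf, 0.0
        flag = "degenerate-zero-variance"
    else:
        t, p = stats.ttest_ind(full, partial, equal_var=not welch)
        flag = None
    rho, rho_p = stats.spearmanr(br, div)
    return {
        "mean_full_breadth": float(full.mean()),
        "mean_partial_breadth": float(partial.mean()),
        "t": float(t), "p": float(p),
        "rho": float(rho), "rho_p": float(rho_p),
        "n_full": len(full), "n_partial": len(partial),
        "flag": flag,
    }


def expression_divergence_scatter_stats(
    rpm: pd.DataFrame,
    divergence: pd.Series,
    summary: str = "sum",
) -> tuple[float, float]:
    """Pearson correlation of summarized expression with hairpin divergence.

    ``summary`` is 'sum', 'mean-over-expressed' (mean over libraries with a
    nonzero value), or 'max'. Expression is log10(x + 1) transformed, since
    expression levels span orders of magnitude.
    """
    common = divergence.dropna().index.intersection(rpm.index)
    if len(common) < 3:
        raise ValueError("need >= 3 microRNAs")
    sub = rpm.loc[common]
    if summary == "sum":
        x = sub.sum(axis=1)
    elif summary == "max":
        x = sub.max(axis=1)
    elif summary == "mean-over-expressed":
        x = sub.where(sub > 0).mean(axis=1).fillna(0.0)
    else:
        raise ValueError(f"unknown summary {summary!r}")
    div = divergence[common]
    if x.nunique() == 1 or div.nunique() == 1:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(np.log10(x + 1.0), div)
    return float(r), float(p)


def tai_tdi(expression: pd.Series, weights: pd.Series) -> float:
    """Expression-weighted mean of per-microRNA weights at one stage.

    With age ranks as weights this is TAI_s; with substitutions per site it
    is TDI_s. Only microRNAs with a defined weight enter numerator and
    denominator.
    """
    w = weights.dropna()
    common = w.index.intersection(expression.index)
    e = expression[common].to_numpy(dtype=float)
    w = w[common].to_numpy(dtype=float)
    total = e.sum()
    if total <= 0:
        raise ValueError("stage total expression is zero")
    # centering the weights keeps the constant-weight case exact in floats
    w0 = w.mean()
    return float(w0 + ((w - w0) * e).sum() / total)


def bootstrap_sd(
    expression: pd.Series,
    weights: pd.Series,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Bootstrap SD of the weighted index: resample microRNAs with replacement."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w = weights.dropna()
    common = w.index.intersection(expression.index)
    if len(common) < 2:
        raise ValueError("need >= 2 microRNAs to bootstrap")
    e = expression[common].to_numpy(dtype=float)
    w = w[common].to_numpy(dtype=float)
    n = len(e)
    idx = rng.integers(0, n, size=(n_boot, n))
    eb = e[idx]
    tot = eb.sum(axis=1)
    w0 = w.mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = w0 + ((w[idx] - w0) * eb).sum(axis=1) / tot
    vals = vals[np.isfinite(vals)]
    return float(np.std(vals))


def stage_index_profile(
    matrix: ExpressionMatrix,
    ages: pd.Series,
    divergence: pd.Series,
    rpm: pd.DataFrame | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    detection_threshold: float = 1.0,
) -> StageIndexResult:
    """Per-stage TAI/TDI with bootstrap SDs and Spearman correlations.

    At each stage the index is computed over the microRNAs detected there
    (raw count >= detection_threshold) that carry both an age rank and a
    divergence value; species-specific microRNAs without ortholog weights
    are excluded.
    """
    rng = np.random.default_rng(seed)
    expr = rpm if rpm is not None else matrix.counts
    rows = []
    for stage in matrix.stages:
        detected = matrix.counts.index[matrix.counts[stage] >= detection_threshold]
        common = [i for i in detected
                  if i in ages.index and i in divergence.index
                  and not math.isnan(divergence[i])]
        e = expr.loc[common, stage]
        tai = tai_tdi(e, ages[common])
        tdi = tai_tdi(e, divergence[common])
        tai_sd = bootstrap_sd(e, ages[common], n_boot, rng)
        tdi_sd = bootstrap_sd(e, divergence[common], n_boot, rng)
        rho, p, m = stage_correlation(matrix, divergence, stage,
                                      detection_threshold=detection_threshold)
        rows.append({"stage": stage, "tai": tai, "tai_sd": tai_sd,
                     "tdi": tdi, "tdi_sd": tdi_sd, "rho": rho, "rho_p": p, "m": m})
    table = pd.DataFrame(rows).set_index("stage")
    return StageIndexResult(table=table)
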