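"""Fold-change recalibration by genetic dosage variance, and the
comparison statistics used to evaluate the resulting shift in gene
prioritisation.

The core transformation rescales a gene's nominal differential-expression
log fold change by the standard deviation of its genetically regulated
expression in the population:

    recal_fc_g = nominal_fc_g / sqrt(V_g)

where ``V_g`` is the gene's dosage variance estimate (V^G), expressed in
squared log-fold-change units. The recalibrated value is the observed
change measured in standard deviations of natural genetic dosage
variation, which puts genes with very different dosage constraint on a
common, biologically interpretable scale. Nominal and recalibrated fold
changes must share one log base; the tool never converts bases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationResult",
    "recalibrate",
    "select_top_n",
    "select_top_half_rounded",
    "round_to_nearest_100",
    "abs_pearson",
    "spearman_bootstrap_ci",
    "filter_by_tpm",
    "compare_gene_sets_mwu",
]

#: Columns of the recalibration result table.
RECAL_COLUMNS = ["gene_id", "nominal_fc", "vg", "recal_fc", "rank_nominal", "rank_recal"]


@dataclass
class CorrelationResult:
    """A correlation estimate with an optional confidence interval."""

    estimate: float
    ci_low: float | None
    ci_high: float | None
    method: str
    n: int


def recalibrate(
    de: pd.DataFrame,
    vg: Mapping[str, float],
    fdr_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Recalibrate significant DE genes by their dosage variance.

    Parameters
    ----------
    de
        DE table with columns ``gene_id``, ``log_fc``, ``adj_p`` (see
        :func:`recalde.io.read_de_table`).
    vg
        Mapping gene id -> V^G estimate (strictly positive). Genes without
        an estimate are excluded from the analysis.
    fdr_cutoff
        Genes with ``adj_p < fdr_cutoff`` are retained; a missing adjusted
        p-value counts as non-significant.

    Returns
    -------
    pandas.DataFrame
        One row per retained gene with ``nominal_fc``, ``vg``,
        ``recal_fc = nominal_fc / sqrt(vg)`` and dense ranks 1..n by
        descending absolute value under each ordering (ties broken by
        ascending gene id).
    """
    if not 0 < fdr_cutoff <= 1:
        raise ValueError(f"fdr_cutoff must be in (0, 1], got {fdr_cutoff}")
    sig = de[de["adj_p"].notna() & (de["adj_p"] < fdr_cutoff)]
    kept = sig[sig["gene_id"].isin(vg)]
    if kept.empty:
        raise ValueError(
            "no significant gene has a V^G estimate "
            f"({len(sig)} significant, {len(vg)} genes with estimates)"
        )
    vg_vals = np.array([float(vg[g]) for g in kept["gene_id"]])
    if (vg_vals <= 0).any() or not np.isfinite(vg_vals).all():
        bad = kept["gene_id"].iloc[int(np.flatnonzero(~(vg_vals > 0))[0])]
        raise ValueError(f"non-positive V^G estimate for gene {bad!r}")

    table = pd.DataFrame(
        {
            "gene_id": kept["gene_id"].to_numpy(),
            "nominal_fc": kept["log_fc"].to_numpy(dtype=float),
            "vg": vg_vals,
        }
    )
    table["recal_fc"] = table["nominal_fc"] / np.sqrt(table["vg"])
    table["rank_nominal"] = _abs_rank(table, "nominal_fc")
    table["rank_recal"] = _abs_rank(table, "recal_fc")
    return table[RECAL_COLUMNS].reset_index(drop=True)


def _abs_rank(table: pd.DataFrame, column: str) -> np.ndarray:
    """Rank 1..n by descending |column|, ties broken by ascending gene id."""
    order = np.lexsort(
        (table["gene_id"].to_numpy(), -np.abs(table[column].to_numpy()))
    )
    ranks = np.empty(len(table), dtype=int)
    ranks[order] = np.arange(1, len(table) + 1)
    return ranks


def select_top_n(table: pd.DataFrame, n: int, by: str = "recal") -> list[str]:
    """The *n* genes of largest absolute fold change under one ordering.

    ``by`` is ``"nominal"`` or ``"recal"``; ties at the boundary are broken
    by ascending gene id so the selection is deterministic.
    """
    if by not in ("nominal", "recal"):
        raise ValueError(f"by must be 'nominal' or 'recal', got {by!r}")
    if not 1 <= n <= len(table):
        raise ValueError(f"n={n} outside 1..{len(table)}")
    col = f"rank_{by}"
    ordered = table.sort_values(col)
    return ordered["gene_id"].head(n).tolist()


def round_to_nearest_100(x: float) -> int:
    """Round to the nearest multiple of 100 with half-up ties (750 -> 800)."""
    return int(math.floor(x / 100.0 + 0.5)) * 100


def select_top_half_rounded(table: pd.DataFrame, by: str = "recal") -> list[str]:
    """Select the top ~50% of genes, rounded to the nearest 100.

    The selection size is ``round_to_nearest_100(0.5 * n)``, floored at 100
    and capped at the table size (a literal 50% of a small table would
    round to 0 genes).
    """
    if table.empty:
        raise ValueError("empty recalibration table")
    n = len(table)
    size = round_to_nearest_100(0.5 * n)
    size = max(size, 100)
    size = min(size, n)
    return select_top_n(table, size, by=by)


def abs_pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson correlation of absolute values.

    Used to compare nominal and recalibrated fold changes without the
    inflation caused by directionality (which recalibration never changes).
    """
    ax, ay = np.abs(np.asarray(x, dtype=float)), np.abs(np.asarray(y, dtype=float))
    if ax.shape != ay.shape or ax.ndim != 1 or len(ax) < 3:
        raise ValueError("x and y must be equal-length 1-d vectors of length >= 3")
    if not (np.isfinite(ax).all() and np.isfinite(ay).all()):
        raise ValueError("non-finite values in correlation input")
    if np.ptp(ax) == 0 or np.ptp(ay) == 0:
        raise ValueError("correlation undefined: zero variance in |x| or |y|")
    r = stats.pearsonr(ax, ay).statistic
    return CorrelationResult(float(r), None, None, "pearson_abs", len(ax))


def spearman_bootstrap_ci(
    x: Sequence[float],
    y: Sequence[float],
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> CorrelationResult:
    """Spearman rank correlation with a percentile bootstrap CI.

    Pairs are resampled with replacement ``n_boot`` times; the interval is
    the (1-level)/2 and 1-(1-level)/2 percentiles of the resampled
    estimates. Reproducible for a fixed seed.
    """
    ax, ay = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if ax.shape != ay.shape or ax.ndim != 1 or len(ax) < 3:
        raise ValueError("x and y must be equal-length 1-d vectors of length >= 3")
    if np.ptp(ax) == 0 or np.ptp(ay) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    est = float(stats.spearmanr(ax, ay).statistic)
    rng = np.random.default_rng(seed)
    n = len(ax)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        bx, by = ax[idx], ay[idx]
        if np.ptp(bx) == 0 or np.ptp(by) == 0:
            boots[b] = np.nan
            continue
        boots[b] = stats.spearmanr(bx, by).statistic
    boots = boots[~np.isnan(boots)]
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    return CorrelationResult(est, float(lo), float(hi), "spearman", n)


def filter_by_tpm(
    genes: Sequence[str],
    tpm: Mapping[str, float],
    min_tpm: float = 1.0,
) -> list[str]:
    """Drop lowly expressed genes: keep genes with ``tpm >= min_tpm``.

    Genes absent from the TPM map are dropped (no expression evidence).
    """
    return [g for g in genes if g in tpm and tpm[g] >= min_tpm]


def compare_gene_sets_mwu(
    values: Mapping[str, float],
    set_a: set[str],
    set_b: set[str],
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U comparison of a metric between two gene sets.

    Each set is intersected with the value map first. The exact null
    distribution is enumerated when the combined sample size is at most 20
    and there are no ties; otherwise the normal approximation with tie
    correction is used.

    Returns
    -------
    (statistic, p_value)
    """
    a = np.array([values[g] for g in sorted(set_a) if g in values], dtype=float)
    b = np.array([values[g] for g in sorted(set_b) if g in values], dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("a gene set has no overlap with the value map")
    combined = np.concatenate([a, b])
    exact = len(combined) <= 20 and len(np.unique(combined)) == len(combined)
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.statistic), float(res.pvalue)
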