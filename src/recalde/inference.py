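"""Tissue-specific V^G inference from correlated tissues.

Dosage-variance estimates derived from allelic expression are undefined
for many (gene, tissue) cells because lowly expressed genes lack usable
allelic reads. This module fills those gaps from tissues with correlated
variance profiles, in a fixed sequence of deterministic steps:

1. ``apply_pseudocount`` — add the smallest positive expression value
   observed anywhere in the TPM matrix, so logs are defined:
   ``E_bar = E + min{E > 0}``.
2. ``fit_expression_variance_model`` — per tissue, ordinary least squares
   of ``log(E_bar)`` on ``log(V)`` over genes with both defined, giving an
   intercept/slope pair (beta0_t, beta1_t) for the expression-variance
   relationship.
3. ``adjust_to_mean_expression`` — rescale each measured estimate to the
   variance expected if the tissue expressed the gene at its cross-tissue
   mean: ``V_hat_{g,t} = V_{g,t} * (mean_r E_bar_{g,r} / E_bar_{g,t}) ** beta1_t``.
4. ``tissue_similarity`` — pairwise Spearman correlation of the raw V
   columns over genes defined in both tissues (pairwise-complete, minimum
   3 shared genes).
5. ``select_similar_tissues`` — for a (gene, target) cell, the (up to) k
   most similar tissues with positive similarity where the gene has a
   measured estimate.
6. ``infer_weighted_mean`` — similarity-weighted mean of the neighbours'
   adjusted estimates: ``V_dot = sum(rho * V_hat) / sum(rho)``.
7. ``readjust_to_tissue_expression`` — map the mean-expression-level
   estimate back to the target tissue's expression:
   ``V_tilde = (E_bar_{g,t} / mean_r E_bar_{g,r}) ** beta1_t * V_dot``
   (the exact inverse of step 3 at the target tissue).

``infer_all`` runs the sequence for every cell and combines measured with
inferred values, measured estimates taking precedence. Natural logarithms
are used throughout; the slope beta1 is invariant to a common change of
log base, so the adjustment factors are base-independent. Inference is
fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TissueFit",
    "InferenceResult",
    "RecoveryResult",
    "apply_pseudocount",
    "fit_expression_variance_model",
    "adjust_to_mean_expression",
    "tissue_similarity",
    "select_similar_tissues",
    "infer_weighted_mean",
    "readjust_to_tissue_expression",
    "infer_all",
    "weighted_harmonic_mean_vg",
    "lowest_vg_tissue",
    "evaluate_recovery",
]

#: Minimum number of shared genes for a pairwise tissue similarity.
MIN_SHARED_GENES = 3


@dataclass
class TissueFit:
    """Per-tissue intercept/slope of the log expression - log variance fit."""

    tissue_id: str
    beta0: float
    beta1: float
    n_genes_fit: int


@dataclass
class InferenceResult:
    """All intermediate and final matrices of one inference run."""

    v_hat: pd.DataFrame  #: measured estimates adjusted to mean expression
    v_dot: pd.DataFrame  #: unadjusted inferred estimates (weighted neighbour mean)
    v_tilde: pd.DataFrame  #: inferred estimates readjusted to tissue expression
    v_hi: pd.DataFrame  #: measured where present, otherwise inferred
    neighbor_sets: dict[tuple[str, str], list[str]]
    fits: dict[str, TissueFit]
    similarity: pd.DataFrame
    pseudocount: float


@dataclass
class RecoveryResult:
    """Held-out recovery evaluation of the inference pipeline."""

    spearman_inferred: float
    spearman_baseline: float
    n_cells: int


def _min_positive(expression: pd.DataFrame) -> float:
    values = expression.to_numpy(dtype=float)
    positive = values[np.isfinite(values) & (values > 0)]
    if positive.size == 0:
        raise ValueError("expression matrix has no positive entry")
    return float(positive.min())


def apply_pseudocount(expression: pd.DataFrame) -> pd.DataFrame:
    """Add the smallest positive observed value to every present cell.

    Keeps zero-expression cells from producing undefined logs. Missing
    cells stay missing; the pseudocount is computed over present cells
    only. Raises if no positive value exists.
    """
    out = expression + _min_positive(expression)
    out.attrs["kind"] = "expression_tpm"
    return out


def fit_expression_variance_model(
    e_bar_t: Mapping[str, float] | pd.Series,
    v_t: Mapping[str, float] | pd.Series,
    tissue_id: str = "",
) -> TissueFit:
    """OLS of log(E_bar) on log(V) over the gene intersection of one tissue."""
    e = pd.Series(e_bar_t, dtype=float).dropna()
    v = pd.Series(v_t, dtype=float).dropna()
    shared = e.index.intersection(v.index)
    if len(shared) < MIN_SHARED_GENES:
        raise ValueError(
            f"tissue {tissue_id!r}: {len(shared)} genes shared between "
            f"expression and variance, need >= {MIN_SHARED_GENES}"
        )
    log_v = np.log(v[shared].to_numpy())
    log_e = np.log(e[shared].to_numpy())
    if np.ptp(log_v) == 0:
        raise ValueError(f"tissue {tissue_id!r}: zero variance of log(V), fit undefined")
    fit = stats.linregress(log_v, log_e)
    return TissueFit(tissue_id, float(fit.intercept), float(fit.slope), len(shared))


def _row_mean_expression(e_bar: pd.DataFrame) -> pd.Series:
    # cross-tissue mean over tissues with a present value for the gene
    return e_bar.mean(axis=1, skipna=True)


def adjust_to_mean_expression(
    v: pd.DataFrame,
    e_bar: pd.DataFrame,
    fits: Mapping[str, TissueFit],
) -> pd.DataFrame:
    """Rescale measured estimates to the gene's cross-tissue mean expression.

    ``V_hat_{g,t} = V_{g,t} * (mean_r E_bar_{g,r} / E_bar_{g,t}) ** beta1_t``.
    Defined exactly where V is defined; a cell whose own expression is
    missing cannot be adjusted and carries V through unchanged.
    """
    row_mean = _row_mean_expression(e_bar)
    v_hat = v.copy()
    for t in v.columns:
        if v[t].notna().sum() == 0:
            continue
        if t not in fits:
            raise ValueError(f"no expression-variance fit for tissue {t!r}")
        ratio = row_mean / e_bar[t]
        factor = np.power(ratio, fits[t].beta1)
        v_hat[t] = v[t] * factor.where(factor.notna(), 1.0)
    v_hat.attrs["kind"] = "vg"
    return v_hat


def tissue_similarity(v: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman correlation of tissue V^G profiles.

    Computed over genes defined in both tissues (pairwise-complete);
    entries with fewer than 3 shared genes are missing. Diagonal is 1.
    """
    tissues = list(v.columns)
    if len(tissues) < 2:
        raise ValueError("similarity needs at least 2 tissues")
    values = v.to_numpy(dtype=float)
    defined = np.isfinite(values)
    rho = pd.DataFrame(np.eye(len(tissues)), index=tissues, columns=tissues)
    for i in range(len(tissues)):
        for j in range(i + 1, len(tissues)):
            both = defined[:, i] & defined[:, j]
            if both.sum() < MIN_SHARED_GENES:
                rho.iloc[i, j] = rho.iloc[j, i] = np.nan
                continue
            r = stats.spearmanr(values[both, i], values[both, j]).statistic
            rho.iloc[i, j] = rho.iloc[j, i] = r
    return rho


def _ranked_candidates(target: str, sim: pd.DataFrame) -> list[tuple[str, float]]:
    """Tissues ordered by descending similarity to *target*, positive-rho only,
    ties broken by ascending tissue id."""
    out = []
    for s in sim.columns:
        if s == target:
            continue
        r = sim.at[target, s]
        if pd.notna(r) and r > 0:
            out.append((s, float(r)))
    out.sort(key=lambda sr: (-sr[1], sr[0]))
    return out


def select_similar_tissues(
    gene: str,
    target: str,
    v: pd.DataFrame,
    sim: pd.DataFrame,
    k: int = 5,
) -> list[str]:
    """The up-to-*k* most similar tissues with a measured estimate for *gene*.

    Only tissues with positive, defined similarity to the target qualify;
    if the gene is measured in fewer than *k* such tissues, all of them
    are returned. An empty list means the cell cannot be inferred.
    """
    if target not in v.columns:
        raise KeyError(f"tissue {target!r} not in matrix")
    row = v.loc[gene]
    return [s for s, _ in _ranked_candidates(target, sim) if pd.notna(row[s])][:k]


def infer_weighted_mean(
    gene: str,
    target: str,
    neighbors: Sequence[str],
    v_hat: pd.DataFrame,
    sim: pd.DataFrame,
) -> float:
    """Similarity-weighted mean of the neighbours' adjusted estimates."""
    if not neighbors:
        raise ValueError("no neighbour tissues to infer from")
    weights = np.array([sim.at[target, s] for s in neighbors], dtype=float)
    vals = np.array([v_hat.at[gene, s] for s in neighbors], dtype=float)
    wsum = weights.sum()
    if wsum <= 0:
        raise ValueError("non-positive similarity weight sum")
    return float((weights * vals).sum() / wsum)


def readjust_to_tissue_expression(
    v_dot: float,
    gene: str,
    target: str,
    e_bar: pd.DataFrame,
    fits: Mapping[str, TissueFit],
) -> float:
    """Map a mean-expression-level estimate back to the target tissue.

    Exact multiplicative inverse of :func:`adjust_to_mean_expression` at
    the target tissue; requires the gene's expression there.
    """
    e_gt = e_bar.at[gene, target]
    if pd.isna(e_gt):
        raise ValueError(f"expression missing for gene {gene!r} in tissue {target!r}")
    mean_g = float(_row_mean_expression(e_bar).at[gene])
    return float((e_gt / mean_g) ** fits[target].beta1 * v_dot)


def infer_all(v: pd.DataFrame, expression: pd.DataFrame, k: int = 5) -> InferenceResult:
    """Run the complete inference sequence for every (gene, tissue) cell.

    Parameters
    ----------
    v
        Gene x tissue matrix of measured V^G estimates (missing allowed).
    expression
        Gene x tissue TPM matrix over the same genes and tissues.
    k
        Number of neighbour tissues used per cell (default 5).

    Returns
    -------
    InferenceResult
        Inferred values ``v_tilde`` are computed for every cell with at
        least one qualifying neighbour (including cells that already have
        a measured value, which supports held-out validation); the
        combined matrix ``v_hi`` keeps measured values where present and
        falls back to inferred ones.
    """
    if not v.index.equals(expression.index):
        raise ValueError("V^G and expression matrices must share the same gene index")
    if list(v.columns) != list(expression.columns):
        raise ValueError("V^G and expression matrices must share the same tissues")
    if len(v.columns) < 2:
        raise ValueError("inference needs at least 2 tissues")

    e_bar = apply_pseudocount(expression)
    fits: dict[str, TissueFit] = {}
    for t in v.columns:
        both = v[t].notna() & e_bar[t].notna()
        if both.sum() >= MIN_SHARED_GENES:
            log_v = np.log(v.loc[both, t].to_numpy(dtype=float))
            if np.ptp(log_v) > 0:
                fits[t] = fit_expression_variance_model(e_bar.loc[both, t], v.loc[both, t], t)
            else:
                fits[t] = TissueFit(t, float(np.log(e_bar.loc[both, t]).mean()), 0.0, int(both.sum()))
    missing_fit = [t for t in v.columns if v[t].notna().any() and t not in fits]
    if missing_fit:
        raise ValueError(f"cannot fit expression-variance model for tissues {missing_fit}")

    v_hat = adjust_to_mean_expression(v, e_bar, fits)
    sim = tissue_similarity(v)

    genes = list(v.index)
    tissues = list(v.columns)
    vnp = v.to_numpy(dtype=float)
    vhat_np = v_hat.to_numpy(dtype=float)
    ebar_np = e_bar.to_numpy(dtype=float)
    row_mean = np.nanmean(ebar_np, axis=1)
    col_index = {t: i for i, t in enumerate(tissues)}

    v_dot = np.full_like(vnp, np.nan)
    v_tilde = np.full_like(vnp, np.nan)
    neighbor_sets: dict[tuple[str, str], list[str]] = {}

    for t in tissues:
        if t not in fits:
            continue  # tissue without measured data anywhere: no model, no inference
        ti = col_index[t]
        cands = _ranked_candidates(t, sim)
        if not cands:
            continue
        cand_idx = np.array([col_index[s] for s, _ in cands])
        cand_rho = np.array([r for _, r in cands])
        beta1 = fits[t].beta1
        defined = np.isfinite(vnp[:, cand_idx])
        for gi, gene in enumerate(genes):
            sel = np.flatnonzero(defined[gi])[:k]
            if sel.size == 0:
                continue
            w = cand_rho[sel]
            vd = float((w * vhat_np[gi, cand_idx[sel]]).sum() / w.sum())
            v_dot[gi, ti] = vd
            neighbor_sets[(gene, t)] = [cands[s][0] for s in sel]
            e_gt = ebar_np[gi, ti]
            if np.isfinite(e_gt):
                v_tilde[gi, ti] = (e_gt / row_mean[gi]) ** beta1 * vd

    v_dot_df = pd.DataFrame(v_dot, index=v.index, columns=v.columns)
    v_tilde_df = pd.DataFrame(v_tilde, index=v.index, columns=v.columns)
    v_hi = v.where(v.notna(), v_tilde_df)
    for df in (v_dot_df, v_tilde_df, v_hi):
        df.attrs["kind"] = "vg"
    return InferenceResult(
        v_hat=v_hat,
        v_dot=v_dot_df,
        v_tilde=v_tilde_df,
        v_hi=v_hi,
        neighbor_sets=neighbor_sets,
        fits=fits,
        similarity=sim,
        pseudocount=_min_positive(expression),
    )


def weighted_harmonic_mean_vg(
    v: pd.DataFrame,
    weights: pd.DataFrame,
) -> pd.Series:
    """Aggregate tissue-specific estimates into one value per gene.

    The weighted harmonic mean ``sum_t w / sum_t (w / V)`` over tissues
    where both the estimate and a positive weight (typically TPM
    expression) are present. The harmonic mean emphasises the most
    constrained tissues; genes with no usable tissue are omitted.
    """
    if not v.index.equals(weights.index) or list(v.columns) != list(weights.columns):
        raise ValueError("value and weight matrices must be aligned")
    vals = v.to_numpy(dtype=float)
    w = weights.to_numpy(dtype=float)
    usable = np.isfinite(vals) & np.isfinite(w) & (w > 0)
    w = np.where(usable, w, 0.0)
    num = w.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        den = np.where(usable, w / vals, 0.0).sum(axis=1)
    keep = num > 0
    return pd.Series(num[keep] / den[keep], index=v.index[keep], name="vg")


def lowest_vg_tissue(v_hi: pd.DataFrame, gene: str) -> str:
    """The tissue with the smallest estimate for *gene* (ties: ascending id)."""
    row = v_hi.loc[gene].dropna()
    if row.empty:
        raise ValueError(f"gene {gene!r} has no defined V^G in any tissue")
    best = row.min()
    return sorted(row.index[row == best])[0]


def evaluate_recovery(
    vg_true: pd.DataFrame,
    vg_observed: pd.DataFrame,
    expression: pd.DataFrame,
    holdout_fraction: float = 0.2,
    seed: int = 0,
    k: int = 5,
) -> RecoveryResult:
    """Held-out evaluation: mask observed cells, infer, score against truth.

    A *holdout_fraction* of the currently observed cells is masked
    uniformly at random, the inference pipeline is run on the masked
    matrix, and the Spearman correlation between inferred and true values
    is computed over the held-out cells. The baseline copies, for each
    held-out cell, the gene's measured value from the single most similar
    tissue — i.e. the first inference neighbour without any adjustment or
    averaging.
    """
    if not 0 < holdout_fraction < 1:
        raise ValueError("holdout_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    obs = np.argwhere(vg_observed.notna().to_numpy())
    n_hold = int(round(holdout_fraction * len(obs)))
    if n_hold == 0 or n_hold == len(obs):
        raise ValueError("holdout selects no cells or all cells")
    picked = obs[rng.choice(len(obs), size=n_hold, replace=False)]

    masked = vg_observed.copy()
    masked_np = masked.to_numpy()
    masked_np[picked[:, 0], picked[:, 1]] = np.nan
    result = infer_all(masked, expression, k=k)

    truth, inferred, baseline = [], [], []
    for gi, ti in picked:
        gene, target = vg_true.index[gi], vg_true.columns[ti]
        vt = result.v_tilde.iat[gi, ti]
        if pd.isna(vt):
            continue
        nearest = select_similar_tissues(gene, target, masked, result.similarity, k=1)
        if not nearest:
            continue
        truth.append(vg_true.iat[gi, ti])
        inferred.append(vt)
        baseline.append(masked.at[gene, nearest[0]])
    if len(truth) < MIN_SHARED_GENES:
        raise ValueError("too few recoverable held-out cells to score")
    return RecoveryResult(
        spearman_inferred=float(stats.spearmanr(inferred, truth).statistic),
        spearman_baseline=float(stats.spearmanr(baseline, truth).statistic),
        n_cells=len(truth),
    )
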