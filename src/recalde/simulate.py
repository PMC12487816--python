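"""Synthetic gene x tissue data with the statistical structure the
recalibration and inference methods assume.

The generator emulates, at desk scale, the properties of population
dosage-variance (V^G) resources and stimulus-response DE experiments:

* lognormal per-gene dosage variance with correlated tissues (tissues are
  grouped into blocks that share per-gene effects, so within-block
  Spearman similarity exceeds between-block similarity);
* a per-tissue log-log linear relationship between expression and
  variance (lowly expressed genes are more variable), with noise;
* missing-not-at-random V^G entries concentrated in lowly expressed genes
  (allelic reads are too sparse there to estimate variance);
* a DE table whose absolute fold changes are positively correlated with
  V^G, containing designated low-variance "driver" genes (small but
  biologically meaningful shifts), high-variance "responder" genes (large
  shifts proportional to their natural variability) and null genes.

Adjusted p-values in the DE table are assigned, not computed from a test:
the consumer of these tables never re-derives significance. All draws
come from one seeded generator in a fixed order (genes outer, tissues
inner), so outputs are bit-identical across runs and platforms.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .inference import weighted_harmonic_mean_vg
from .io import write_de_table, write_matrix

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "generate",
    "mask_additional",
    "write_truth",
    "generate_equalization_sets",
]


@dataclass
class SimulationConfig:
    """Parameters of one synthetic dataset.

    Defaults are chosen to resemble a small stimulus-response study against
    a multi-tissue variance resource: ~2000 genes, 10 tissues in 2
    correlated blocks, typical V^G around 0.01 (squared log-fold-change
    units) with a heavy right tail, an inverse expression-variance slope
    of -0.5, and 20% missing variance estimates concentrated in the
    lowest-expressed quartile.
    """

    seed: int = 0
    n_genes: int = 2000
    n_tissues: int = 10
    log_vg_mean: float = math.log(0.01)
    log_vg_sd: float = 1.0
    tissue_block_count: int = 2
    tissue_effect_sd: float = 0.3
    cell_noise_sd: float = 0.3
    beta0: float = 2.0
    beta1: float = -0.5
    expr_noise_sd: float = 0.3
    missing_rate: float = 0.2
    low_expr_missing_boost: float = 2.0
    frac_drivers: float = 0.05
    frac_responders: float = 0.15
    fc_scale: float = 1.0

    def validate(self) -> None:
        if self.n_genes < 2 or self.n_tissues < 2:
            raise ValueError("n_genes and n_tissues must be >= 2")
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate must be in [0, 1]")
        for name in ("log_vg_sd", "tissue_effect_sd", "cell_noise_sd", "expr_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.low_expr_missing_boost < 0:
            raise ValueError("low_expr_missing_boost must be >= 0")
        if not 0 <= self.frac_drivers <= 1 or not 0 <= self.frac_responders <= 1:
            raise ValueError("gene-set fractions must be in [0, 1]")
        if self.frac_drivers + self.frac_responders > 0.5:
            raise ValueError("drivers + responders must leave a null majority")
        if self.fc_scale <= 0:
            raise ValueError("fc_scale must be positive")
        if not 1 <= self.tissue_block_count <= self.n_tissues:
            raise ValueError("tissue_block_count outside 1..n_tissues")


@dataclass
class SyntheticTruth:
    """A generated dataset together with its ground truth."""

    vg_true: pd.DataFrame  #: complete gene x tissue dosage variance
    vg_observed: pd.DataFrame  #: the same with MNAR cells masked
    expression: pd.DataFrame  #: gene x tissue TPM
    de: pd.DataFrame  #: DE result table (gene_id, log_fc, p_value, adj_p, base_mean)
    labels: dict[str, str]  #: gene -> driver | responder | null
    gene_vg: pd.Series  #: TPM-weighted harmonic mean of vg_true per gene
    config: SimulationConfig


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _tissue_ids(n: int) -> list[str]:
    return [f"T{i:02d}" for i in range(1, n + 1)]


def generate(config: SimulationConfig) -> SyntheticTruth:
    """Generate one synthetic dataset from *config* (see module docstring)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_g, n_t = config.n_genes, config.n_tissues
    genes = _gene_ids(n_g)
    tissues = _tissue_ids(n_t)
    # contiguous tissue blocks, sizes as even as possible
    block_of = np.array([t * config.tissue_block_count // n_t for t in range(n_t)])

    base = rng.normal(config.log_vg_mean, config.log_vg_sd, size=n_g)
    block_eff = rng.normal(0.0, config.tissue_effect_sd, size=(n_g, config.tissue_block_count))
    cell_noise = rng.normal(0.0, config.cell_noise_sd, size=(n_g, n_t))
    log_vg = base[:, None] + block_eff[:, block_of] + cell_noise
    vg_true = pd.DataFrame(np.exp(log_vg), index=genes, columns=tissues)
    vg_true.index.name = "gene_id"
    vg_true.attrs["kind"] = "vg"

    log_expr = config.beta0 + config.beta1 * log_vg + rng.normal(
        0.0, config.expr_noise_sd, size=(n_g, n_t)
    )
    expression = pd.DataFrame(np.exp(log_expr), index=genes, columns=tissues)
    expression.index.name = "gene_id"
    expression.attrs["kind"] = "expression_tpm"

    # missing-not-at-random mask: the bottom expression quartile of cells is
    # low_expr_missing_boost times as likely to be masked, with the base rate
    # renormalised so the expected overall masked fraction is missing_rate
    q = 0.25
    boost = config.low_expr_missing_boost
    p_base = config.missing_rate / ((1 - q) + q * boost)
    cutoff = np.quantile(expression.to_numpy(), q)
    low = expression.to_numpy() <= cutoff
    p_cell = np.where(low, min(boost * p_base, 1.0), p_base)
    mask = rng.random(size=(n_g, n_t)) < p_cell
    vg_observed = vg_true.mask(mask)
    vg_observed.attrs["kind"] = "vg"

    gene_vg = weighted_harmonic_mean_vg(vg_true, expression)

    labels = _assign_labels(rng, genes, gene_vg, config)
    de = _make_de_table(rng, genes, gene_vg, labels, expression, config)
    return SyntheticTruth(
        vg_true=vg_true,
        vg_observed=vg_observed,
        expression=expression,
        de=de,
        labels=labels,
        gene_vg=gene_vg,
        config=config,
    )


def _assign_labels(
    rng: np.random.Generator,
    genes: list[str],
    gene_vg: pd.Series,
    config: SimulationConfig,
) -> dict[str, str]:
    """Drivers drawn from the bottom vg quartile, responders from the top."""
    n_g = len(genes)
    n_drv = int(round(config.frac_drivers * n_g))
    n_rsp = int(round(config.frac_responders * n_g))
    order = np.argsort(gene_vg.to_numpy(), kind="stable")
    quartile = max(n_g // 4, 1)
    bottom = order[:quartile]
    top = order[-quartile:]
    if n_drv > len(bottom) or n_rsp > len(top):
        raise ValueError("gene-set fractions exceed a vg quartile")
    drivers = rng.choice(bottom, size=n_drv, replace=False)
    responders = rng.choice(top, size=n_rsp, replace=False)
    labels = {g: "null" for g in genes}
    for i in drivers:
        labels[genes[i]] = "driver"
    for i in responders:
        labels[genes[i]] = "responder"
    return labels


def _make_de_table(
    rng: np.random.Generator,
    genes: list[str],
    gene_vg: pd.Series,
    labels: dict[str, str],
    expression: pd.DataFrame,
    config: SimulationConfig,
) -> pd.DataFrame:
    n_g = len(genes)
    log_fc = np.empty(n_g)
    adj_p = np.empty(n_g)
    signs = rng.choice([-1.0, 1.0], size=n_g)
    driver_mag = np.abs(rng.normal(0.3, 0.1, size=n_g))
    responder_mult = np.abs(rng.normal(1.0, 0.3, size=n_g))
    null_fc = rng.normal(0.0, 0.05, size=n_g)
    sig_p = rng.uniform(0.0, 0.001, size=n_g)
    null_p = rng.uniform(0.1, 1.0, size=n_g)
    p_frac = rng.uniform(0.1, 1.0, size=n_g)
    for i, g in enumerate(genes):
        lab = labels[g]
        if lab == "driver":
            log_fc[i] = signs[i] * driver_mag[i]
            adj_p[i] = sig_p[i]
        elif lab == "responder":
            log_fc[i] = signs[i] * config.fc_scale * math.sqrt(gene_vg[g]) * responder_mult[i]
            adj_p[i] = sig_p[i]
        else:
            log_fc[i] = null_fc[i]
            adj_p[i] = null_p[i]
    de = pd.DataFrame(
        {
            "gene_id": genes,
            "log_fc": log_fc,
            "p_value": adj_p * p_frac,  # raw p never exceeds its adjusted value
            "adj_p": adj_p,
            "base_mean": expression.mean(axis=1).to_numpy(),
        }
    )
    return de


def generate_equalization_sets(
    seed: int,
    n_per_set: int = 300,
    median_vg_low: float = 0.005,
    median_ratio: float = 4.0,
    log_vg_sd: float = 0.5,
    fc_noise_sd: float = 0.3,
) -> tuple[dict[str, float], dict[str, float], set[str], set[str]]:
    """Two gene sets whose fold changes scale with their dosage variance.

    Emulates the contrast between a constrained gene set and a highly
    variable one: set A has lognormal V^G with median ``median_vg_low``,
    set B a ``median_ratio``-fold higher median, and every gene's absolute
    nominal fold change is ``sqrt(vg) * |Normal(1, fc_noise_sd)|``. The
    nominal magnitudes therefore differ strongly between the sets while
    the recalibrated magnitudes are identically distributed — the
    structure under which recalibration should equalise the two sets.

    Returns
    -------
    (nominal_values, recalibrated_values, set_a, set_b)
        Per-gene absolute fold changes before and after division by
        ``sqrt(vg)``, and the two gene-id sets.
    """
    rng = np.random.default_rng(seed)
    vg_a = np.exp(rng.normal(math.log(median_vg_low), log_vg_sd, n_per_set))
    vg_b = np.exp(rng.normal(math.log(median_vg_low * median_ratio), log_vg_sd, n_per_set))
    mult_a = np.abs(rng.normal(1.0, fc_noise_sd, n_per_set))
    mult_b = np.abs(rng.normal(1.0, fc_noise_sd, n_per_set))
    fc_a = np.sqrt(vg_a) * mult_a
    fc_b = np.sqrt(vg_b) * mult_b
    nominal = {f"A{i:04d}": float(fc_a[i]) for i in range(n_per_set)}
    nominal |= {f"B{i:04d}": float(fc_b[i]) for i in range(n_per_set)}
    recal = {f"A{i:04d}": float(fc_a[i] / np.sqrt(vg_a[i])) for i in range(n_per_set)}
    recal |= {f"B{i:04d}": float(fc_b[i] / np.sqrt(vg_b[i])) for i in range(n_per_set)}
    set_a = {f"A{i:04d}" for i in range(n_per_set)}
    set_b = {f"B{i:04d}" for i in range(n_per_set)}
    return nominal, recal, set_a, set_b


def mask_additional(truth: SyntheticTruth, fraction: float, seed: int) -> SyntheticTruth:
    """Mask an extra *fraction* of the currently observed vg cells.

    Used for held-out evaluation: the returned dataset has the same truth
    matrices but a sparser ``vg_observed``; newly masked cells were all
    previously observed, and the true values remain available in
    ``vg_true`` for scoring.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    obs = np.argwhere(truth.vg_observed.notna().to_numpy())
    if len(obs) == 0:
        raise ValueError("no observed cells left to mask")
    n_new = int(round(fraction * len(obs)))
    if n_new == 0:
        raise ValueError(f"fraction {fraction} of {len(obs)} observed cells masks nothing")
    rng = np.random.default_rng(seed)
    picked = obs[rng.choice(len(obs), size=n_new, replace=False)]
    vg_observed = truth.vg_observed.copy()
    arr = vg_observed.to_numpy()
    arr[picked[:, 0], picked[:, 1]] = np.nan
    vg_observed.attrs["kind"] = "vg"
    return dataclasses.replace(truth, vg_observed=vg_observed)


def write_truth(truth: SyntheticTruth, out_dir: str | Path) -> None:
    """Write all matrices, the DE table, labels and the resolved config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_matrix(truth.vg_true, out / "vg_true.tsv")
    write_matrix(truth.vg_observed, out / "vg_observed.tsv")
    write_matrix(truth.expression, out / "tpm.tsv")
    write_de_table(truth.de, out / "de.tsv")
    pd.Series(truth.labels, name="label").rename_axis("gene_id").to_csv(
        out / "labels.tsv", sep="\t"
    )
    cfg = dataclasses.asdict(truth.config)
    with open(out / "config.yaml", "w") as fh:
        for key, value in cfg.items():
            fh.write(f"{key}: {value}\n")
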