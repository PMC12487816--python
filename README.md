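# recalde

Recalibrate differential-expression (DE) fold changes by population
genetic dosage variance.

## The problem

Standard DE analysis ranks statistically significant genes by nominal
fold change, implicitly assuming all genes are equally sensitive to
dosage changes of their transcripts. They are not: a 1.5-fold shift in a
tightly constrained transcription factor can be biologically drastic,
while the same shift in a highly variable effector gene sits well inside
its natural population range. Nominal ranking therefore favors variable
"responder" genes over constrained "driver" genes.

`recalde` rescales each gene's log fold change by the standard deviation
of its genetically regulated expression. Given a per-gene estimate
*V<sup>G</sup><sub>g</sub>* of the population variance in expression
attributable to cis-regulatory genetic variation (in squared
log-fold-change units, e.g. from allelic-expression models fit to
population RNA-seq):

> FC̄<sub>g</sub> = FC<sub>g</sub> / √V<sup>G</sup><sub>g</sub>

so the recalibrated fold change FC̄ is the observed change measured in
standard deviations of natural genetic dosage variation — a unit that is
comparable across genes. The package is for transcriptomics analysts who
already have DE results (DESeq2-style tables) and a V^G resource, and
want to rank or select genes by biological rather than purely nominal
effect size.

Beyond the core rescaling, the package provides:

* **Cross-tissue V^G inference** — tissue-specific estimates are missing
  for many lowly expressed genes. Missing cells are imputed from the most
  similar tissues: per-tissue log-log fits of expression on variance,
  adjustment of measured estimates to each gene's mean expression level, a
  Spearman tissue-similarity-weighted mean over up to 5 neighbour
  tissues, and readjustment to the target tissue's expression. Measured
  estimates always take precedence in the combined matrix.
* **Aggregation** — a TPM-weighted harmonic mean across tissues collapses
  the matrix to one V^G per gene; a lowest-V^G-tissue assignment plus a
  one-sided binomial test probes tissue-specific constraint of a gene set.
* **Comparison statistics** — Pearson correlation of absolute fold
  changes, bootstrap Spearman confidence intervals, Mann-Whitney gene-set
  comparisons, top-N and top-half-rounded-to-100 selectors, and a
  hypergeometric/Benjamini-Hochberg enrichment engine that compares the
  enrichment profiles of two selections (with p = 1 imputation for terms
  enriched on only one side and keyword-based grouping).
* **Synthetic data** — a seeded generator producing expression and V^G
  matrices, DE tables and driver/responder labels with the statistical
  structure above, so the whole pipeline is testable end to end without
  external resources.

## Worked example

```python
import pandas as pd
from recalde import recalibrate

de = pd.DataFrame({
    "gene_id":  ["CONSTRAINED", "VARIABLE", "MODEST", "NOISY"],
    "log_fc":   [0.60, 1.80, 0.90, 1.20],
    "p_value":  [1e-6, 1e-8, 1e-5, 1e-4],
    "adj_p":    [1e-5, 1e-7, 1e-4, 1e-3],
    "base_mean":[50.0, 200.0, 80.0, 30.0],
})
vg = {"CONSTRAINED": 0.002, "VARIABLE": 0.250, "MODEST": 0.010, "NOISY": 0.090}
print(recalibrate.recalibrate(de, vg, fdr_cutoff=0.05).to_string(index=False))
```

prints

```
    gene_id  nominal_fc    vg  recal_fc  rank_nominal  rank_recal
CONSTRAINED       0.600 0.002    13.416             4           1
   VARIABLE       1.800 0.250     3.600             1           4
     MODEST       0.900 0.010     9.000             3           2
      NOISY       1.200 0.090     4.000             2           3
```

`CONSTRAINED` has the smallest nominal change but the largest
recalibrated one: a 0.6 log-fold shift is 13 standard deviations of its
natural dosage variation, whereas `VARIABLE`'s 1.8 log-fold shift is only
3.6. The `examples/` directory has narrative scripts for each capability
(recalibration, tissue inference, enrichment shift, aggregation); each
prints its numbers with a line on what they mean.

The same operations are available from the shell:

```bash
recalde simulate --seed 1 --out-dir data/
recalde infer-vg --vg data/vg_observed.tsv --tpm data/tpm.tsv --out vg_hi.tsv
recalde recalibrate --de data/de.tsv --vg vg_hi.tsv --tpm data/tpm.tsv \
    --fdr 0.05 --out recal.tsv
```

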