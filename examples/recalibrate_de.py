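"""Recalibrate a small DE experiment by dosage variance.

Builds a six-gene DE table and a per-gene V^G map, rescales each nominal
log fold change by sqrt(V^G), and shows how the ranking changes: a
constrained gene (tiny V^G) with a modest shift overtakes a highly
variable gene with a large one.
"""

import pandas as pd

from recalde import recalibrate

de = pd.DataFrame(
    {
        "gene_id": ["CONSTRAINED", "VARIABLE", "MODEST", "NOISY", "FLAT", "UNSEEN"],
        "log_fc": [0.60, 1.80, 0.90, 1.20, 0.05, 2.50],
        "p_value": [1e-6, 1e-8, 1e-5, 1e-4, 0.4, 1e-9],
        "adj_p": [1e-5, 1e-7, 1e-4, 1e-3, 0.6, 1e-8],
        "base_mean": [50.0, 200.0, 80.0, 30.0, 10.0, 5.0],
    }
)
# squared log-fold-change units; UNSEEN has no estimate and is excluded
vg = {"CONSTRAINED": 0.002, "VARIABLE": 0.250, "MODEST": 0.010, "NOISY": 0.090, "FLAT": 0.010}

table = recalibrate.recalibrate(de, vg, fdr_cutoff=0.05)
print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print()
print(
    "recal_fc = log_fc / sqrt(vg): the change measured in standard deviations\n"
    "of natural genetic dosage variation. CONSTRAINED moves from rank",
    int(table.set_index("gene_id").at["CONSTRAINED", "rank_nominal"]),
    "(nominal) to rank",
    int(table.set_index("gene_id").at["CONSTRAINED", "rank_recal"]),
    "(recalibrated);\nVARIABLE's large shift is within its natural range and drops to rank",
    int(table.set_index("gene_id").at["VARIABLE", "rank_recal"]),
)
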