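"""How recalibration shifts gene-set enrichment.

On synthetic data with a low-variance "driver" gene set (small,
biologically meaningful shifts) and a high-variance "responder" set
(large shifts that merely track the stimulus), compares hypergeometric
enrichment of the two sets in the top gene selections before and after
recalibration.
"""

import numpy as np

from recalde import enrichment, recalibrate, simulate
from recalde.io import GeneSetCollection

truth = simulate.generate(simulate.SimulationConfig(seed=1))
table = recalibrate.recalibrate(truth.de, truth.gene_vg.to_dict(), fdr_cutoff=0.05)
universe = set(truth.gene_vg.index)
terms = GeneSetCollection(
    sets={
        "DRIVER": {g for g, l in truth.labels.items() if l == "driver"},
        "RESPONDER": {g for g, l in truth.labels.items() if l == "responder"},
    },
    descriptions={"DRIVER": "constrained driver genes", "RESPONDER": "variable responder genes"},
)

sel_nom = set(recalibrate.select_top_half_rounded(table, by="nominal"))
sel_rec = set(recalibrate.select_top_half_rounded(table, by="recal"))
nom = enrichment.hypergeometric_ora(sel_nom, universe, terms).set_index("term_id")
rec = enrichment.hypergeometric_ora(sel_rec, universe, terms).set_index("term_id")

print(f"top selection size: {len(sel_nom)} of {len(table)} significant genes")
for term in ("DRIVER", "RESPONDER"):
    print(
        f"{term:9s} adj_p: {nom.at[term, 'adj_p']:.2e} (nominal selection)  "
        f"{rec.at[term, 'adj_p']:.2e} (recalibrated selection)"
    )
print()
print(
    "Recalibration makes the driver term more enriched and the responder term\n"
    "less enriched: ranking by standardized change prioritizes constrained\n"
    "regulators over highly variable stimulus-response genes."
)
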