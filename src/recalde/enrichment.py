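"""Over-representation testing and enrichment comparison between two gene
selections.

The engine is a one-sided hypergeometric test per term (probability of
observing at least the realised overlap between the selection and the
term's genes, both restricted to the analysis universe) with
Benjamini-Hochberg adjustment across tested terms. Comparing the
enrichment profiles of two selections — e.g. the top genes by nominal
versus recalibrated fold change — uses the union of terms enriched in
either selection, imputing an adjusted p-value of 1 for the side where a
term was not enriched, plus a keyword-based grouping of term names with
geometric-mean summaries per group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection

__all__ = [
    "hypergeometric_ora",
    "compare_selections",
    "keyword_group_logmean",
    "assign_rarest_label",
    "binomial_lowest_tissue_test",
]

#: Columns of an enrichment result table.
ORA_COLUMNS = [
    "term_id",
    "term_name",
    "universe_size",
    "term_size",
    "selection_size",
    "overlap",
    "p",
    "adj_p",
    "enriched",
]


def hypergeometric_ora(
    selection: set[str],
    universe: set[str],
    terms: GeneSetCollection,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each term in a gene selection.

    Parameters
    ----------
    selection
        Genes of interest; must be a subset of *universe*.
    universe
        Background set (e.g. all genes with expression and V^G estimates).
    terms
        Gene sets to test. Memberships are intersected with the universe
        before computing term sizes; terms with no member in the universe
        are not tested.
    alpha
        Terms with BH-adjusted p <= alpha are flagged enriched.

    Returns
    -------
    pandas.DataFrame
        One row per tested term, sorted by ascending adjusted p then term
        id, with upper-tail p-values ``P[X >= overlap]`` and BH-adjusted
        values.
    """
    if not universe:
        raise ValueError("empty universe")
    if not selection:
        raise ValueError("empty selection")
    extra = selection - universe
    if extra:
        raise ValueError(
            f"selection contains {len(extra)} genes outside the universe "
            f"(e.g. {sorted(extra)[0]!r})"
        )
    restricted = terms.restricted(universe)
    rows = []
    m = len(universe)
    n_sel = len(selection)
    for term_id in sorted(restricted):
        members = restricted[term_id]
        overlap = len(members & selection)
        # upper tail P[X >= overlap] for overlap drawn without replacement
        p = float(stats.hypergeom.sf(overlap - 1, m, len(members), n_sel))
        rows.append(
            {
                "term_id": term_id,
                "term_name": restricted.descriptions.get(term_id, "") or term_id,
                "universe_size": m,
                "term_size": len(members),
                "selection_size": n_sel,
                "overlap": overlap,
                "p": min(p, 1.0),
            }
        )
    result = pd.DataFrame(rows, columns=ORA_COLUMNS[:-2])
    if result.empty:
        result["adj_p"] = pd.Series(dtype=float)
        result["enriched"] = pd.Series(dtype=bool)
        return result
    result["adj_p"] = multipletests(result["p"], method="fdr_bh")[1]
    result["enriched"] = result["adj_p"] <= alpha
    return result.sort_values(["adj_p", "term_id"]).reset_index(drop=True)


def compare_selections(
    sel_a: Sequence[str],
    sel_b: Sequence[str],
    universe: set[str],
    terms: GeneSetCollection,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Compare the enrichment profiles of two gene selections.

    Runs :func:`hypergeometric_ora` on each selection and joins the terms
    enriched (adjusted p <= alpha) in either; a term not enriched on one
    side gets an imputed adjusted p of 1 there, with the corresponding
    ``imputed_*`` flag set.
    """
    ora_a = hypergeometric_ora(set(sel_a), universe, terms, alpha=alpha)
    ora_b = hypergeometric_ora(set(sel_b), universe, terms, alpha=alpha)
    enr_a = ora_a[ora_a["enriched"]].set_index("term_id")
    enr_b = ora_b[ora_b["enriched"]].set_index("term_id")
    term_ids = sorted(set(enr_a.index) | set(enr_b.index))
    names = {**enr_b["term_name"].to_dict(), **enr_a["term_name"].to_dict()}
    rows = []
    for tid in term_ids:
        in_a, in_b = tid in enr_a.index, tid in enr_b.index
        rows.append(
            {
                "term_id": tid,
                "term_name": names[tid],
                "adj_p_a": float(enr_a.at[tid, "adj_p"]) if in_a else 1.0,
                "adj_p_b": float(enr_b.at[tid, "adj_p"]) if in_b else 1.0,
                "imputed_a": not in_a,
                "imputed_b": not in_b,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["term_id", "term_name", "adj_p_a", "adj_p_b", "imputed_a", "imputed_b"],
    )


def keyword_group_logmean(
    comparison: pd.DataFrame,
    keywords: Sequence[str],
) -> pd.DataFrame:
    """Group compared terms by name keywords and summarise per group.

    A term belongs to the first keyword (in the given order) that is a
    case-insensitive substring of its name; later keywords never steal a
    term. The per-group summary is the geometric mean of the adjusted
    p-values on each side. Keywords matching no term are reported with
    ``n_terms = 0``.
    """
    if not keywords:
        raise ValueError("keywords must be non-empty")
    groups: dict[str, list[int]] = {kw: [] for kw in keywords}
    lowered = [kw.lower() for kw in keywords]
    for idx, name in enumerate(comparison["term_name"].astype(str)):
        low = name.lower()
        for kw, kw_low in zip(keywords, lowered):
            if kw_low in low:
                groups[kw].append(idx)
                break
    rows = []
    for kw in keywords:
        idx = groups[kw]
        if idx:
            sub = comparison.iloc[idx]
            lm_a = float(np.exp(np.mean(np.log(sub["adj_p_a"]))))
            lm_b = float(np.exp(np.mean(np.log(sub["adj_p_b"]))))
        else:
            lm_a = lm_b = float("nan")
        rows.append({"keyword": kw, "logmean_a": lm_a, "logmean_b": lm_b, "n_terms": len(idx)})
    return pd.DataFrame(rows, columns=["keyword", "logmean_a", "logmean_b", "n_terms"])


def assign_rarest_label(
    gene_labels: Mapping[str, set[str]],
    label_freq: Mapping[str, int],
) -> dict[str, str]:
    """Assign each gene its least frequent label.

    Genes carrying several functional-category labels get the one that is
    rarest overall (frequency ties broken by ascending label); genes with
    an empty label set are omitted.
    """
    out = {}
    for gene, labels in gene_labels.items():
        if not labels:
            continue
        missing = [lab for lab in labels if lab not in label_freq]
        if missing:
            raise KeyError(f"label {missing[0]!r} (gene {gene!r}) has no frequency")
        out[gene] = min(sorted(labels), key=lambda lab: (label_freq[lab], lab))
    return out


def binomial_lowest_tissue_test(
    assignments: Mapping[str, str],
    focal_tissues: set[str],
    n_total_tissues: int,
) -> tuple[int, int, float, float]:
    """One-sided binomial test for concentration in a focal tissue group.

    Given per-gene tissue assignments (e.g. the tissue of lowest V^G per
    gene) and a focal group (e.g. brain tissues), tests whether more genes
    land in the focal group than the group's share of tissues predicts:
    upper-tail ``P[X >= k]`` for ``X ~ Binomial(n, p0)`` with
    ``p0 = |focal| / n_total_tissues``.

    Returns
    -------
    (k, n, p0, p)
    """
    if not assignments:
        raise ValueError("no gene assignments")
    if not 1 <= len(focal_tissues) <= n_total_tissues:
        raise ValueError("focal tissue set size outside 1..n_total_tissues")
    n = len(assignments)
    k = sum(1 for t in assignments.values() if t in focal_tissues)
    p0 = len(focal_tissues) / n_total_tissues
    p = float(stats.binom.sf(k - 1, n, p0))
    return k, n, p0, min(p, 1.0)
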