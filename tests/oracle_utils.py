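"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately written from first principles (explicit
formulas, exhaustive enumeration, per-cell loops) and shares no code with
the implementation under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------- statistics


def pearson_formula(x, y) -> float:
    """Textbook covariance / (sd_x * sd_y)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    mx, my = x.mean(), y.mean()
    cov = ((x - mx) * (y - my)).sum()
    return cov / math.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum())


def ranks_with_ties(values) -> np.ndarray:
    """Average ranks (1-based), ties receiving the mean of their positions."""
    values = np.asarray(values, float)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values))
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def spearman_formula(x, y) -> float:
    """Rank-transform then Pearson."""
    return pearson_formula(ranks_with_ties(x), ranks_with_ties(y))


def ols_normal_equations(x, y) -> tuple[float, float]:
    """(intercept, slope) of y on x via (X'X)^-1 X'y."""
    x = np.asarray(x, float)
    design = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(design.T @ design, design.T @ np.asarray(y, float))
    return float(beta[0]), float(beta[1])


def hypergeom_upper_tail(overlap, universe, term_size, selection) -> float:
    """P[X >= overlap] by summing the point probabilities."""
    total = math.comb(universe, selection)
    acc = 0
    for k in range(overlap, min(term_size, selection) + 1):
        if selection - k > universe - term_size:
            continue
        acc += math.comb(term_size, k) * math.comb(universe - term_size, selection - k)
    return acc / total


def hypergeom_by_enumeration(overlap, universe, term_size, selection) -> float:
    """P[X >= overlap] by exhaustively enumerating every possible draw."""
    hits = 0
    total = 0
    items = range(universe)
    term = set(range(term_size))
    for draw in itertools.combinations(items, selection):
        total += 1
        if len(term.intersection(draw)) >= overlap:
            hits += 1
    return hits / total


def bh_stepup(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values with monotonicity enforcement."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        idx = order[rank_from_top]
        value = p[idx] * m / (rank_from_top + 1)
        running_min = min(running_min, value)
        adjusted[idx] = min(running_min, 1.0)
    return adjusted


def mwu_exact_two_sided(a, b) -> float:
    """Exact two-sided Mann-Whitney p by enumerating group assignments.

    Assumes no ties. The p-value is the fraction of all C(n_a+n_b, n_a)
    labelings whose U statistic is at least as extreme (in either
    direction) as the observed one.
    """
    a, b = list(a), list(b)
    combined = a + b
    assert len(set(combined)) == len(combined), "oracle requires tie-free data"
    n_a = len(a)

    def u_stat(group_a, group_b):
        return sum(1 for x in group_a for y in group_b if x > y)

    u_obs = u_stat(a, b)
    mean_u = n_a * len(b) / 2.0
    dev = abs(u_obs - mean_u)
    hits = 0
    total = 0
    for idx in itertools.combinations(range(len(combined)), n_a):
        ga = [combined[i] for i in idx]
        gb = [combined[i] for i in range(len(combined)) if i not in set(idx)]
        total += 1
        if abs(u_stat(ga, gb) - mean_u) >= dev - 1e-12:
            hits += 1
    return hits / total


def binom_upper_tail(k, n, p0) -> float:
    """P[X >= k] by direct summation of the binomial pmf."""
    return sum(math.comb(n, i) * p0**i * (1 - p0) ** (n - i) for i in range(k, n + 1))


# ------------------------------------------------- per-cell inference oracle


def oracle_infer_matrix(v_df, e_df, k=5):
    """Straight-line per-cell re-computation of the inference pipeline.

    Takes pandas gene x tissue DataFrames (NaN = missing) and returns a
    dict {(gene, tissue): inferred value} for every cell with at least one
    qualifying neighbour, computed with explicit loops and the formula
    sequence: pseudocount, per-tissue OLS of log expression on log
    variance, adjustment to mean expression, Spearman tissue similarity on
    raw values, top-k positive-similarity neighbours with measured values,
    similarity-weighted mean, readjustment to the target tissue's
    expression.
    """
    genes = list(v_df.index)
    tissues = list(v_df.columns)
    v = {(g, t): v_df.at[g, t] for g in genes for t in tissues}
    e = {(g, t): e_df.at[g, t] for g in genes for t in tissues}

    present_e = [x for x in e.values() if not _isnan(x) and x > 0]
    pc = min(present_e)
    e_bar = {gt: (x + pc if not _isnan(x) else float("nan")) for gt, x in e.items()}

    fits = {}
    for t in tissues:
        xs, ys = [], []
        for g in genes:
            if not _isnan(v[(g, t)]) and not _isnan(e_bar[(g, t)]):
                xs.append(math.log(v[(g, t)]))
                ys.append(math.log(e_bar[(g, t)]))
        if len(xs) >= 3:
            if max(xs) - min(xs) > 0:
                b0, b1 = ols_normal_equations(xs, ys)
            else:
                b0, b1 = float(np.mean(ys)), 0.0
            fits[t] = (b0, b1)

    def mean_expr(g):
        vals = [e_bar[(g, t)] for t in tissues if not _isnan(e_bar[(g, t)])]
        return sum(vals) / len(vals)

    v_hat = {}
    for g in genes:
        for t in tissues:
            if _isnan(v[(g, t)]):
                continue
            if _isnan(e_bar[(g, t)]):
                v_hat[(g, t)] = v[(g, t)]
            else:
                b1 = fits[t][1]
                v_hat[(g, t)] = v[(g, t)] * (mean_expr(g) / e_bar[(g, t)]) ** b1

    sim = {}
    for t1 in tissues:
        for t2 in tissues:
            if t1 == t2:
                sim[(t1, t2)] = 1.0
                continue
            xs, ys = [], []
            for g in genes:
                if not _isnan(v[(g, t1)]) and not _isnan(v[(g, t2)]):
                    xs.append(v[(g, t1)])
                    ys.append(v[(g, t2)])
            sim[(t1, t2)] = spearman_formula(xs, ys) if len(xs) >= 3 else float("nan")

    inferred = {}
    for g in genes:
        for t in tissues:
            if t not in fits:
                continue
            cands = [
                (s, sim[(t, s)])
                for s in tissues
                if s != t
                and not _isnan(sim[(t, s)])
                and sim[(t, s)] > 0
                and not _isnan(v[(g, s)])
            ]
            cands.sort(key=lambda sr: (-sr[1], sr[0]))
            neighbors = cands[:k]
            if not neighbors or _isnan(e_bar[(g, t)]):
                continue
            wsum = sum(r for _, r in neighbors)
            v_dot = sum(r * v_hat[(g, s)] for s, r in neighbors) / wsum
            b1 = fits[t][1]
            inferred[(g, t)] = (e_bar[(g, t)] / mean_expr(g)) ** b1 * v_dot
    return inferred


def _isnan(x) -> bool:
    return isinstance(x, float) and math.isnan(x)
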