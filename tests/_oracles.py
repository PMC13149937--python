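"""Independent reference implementations used as oracles in tests.

Each function here restates an algorithm from first principles (brute-force
enumeration or a literal transcription of the procedure) without importing
the corresponding pleioscan implementation internals, so agreement between
the two is a meaningful check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_force_max_clique(nodes, edges):
    """Largest subset of nodes that is pairwise connected, by enumerating
    all 2^n subsets.  Returns the maximum clique size."""
    nodes = list(nodes)
    eset = {frozenset(e) for e in edges}
    best = 1 if nodes else 0
    for r in range(2, len(nodes) + 1):
        for combo in itertools.combinations(nodes, r):
            if all(frozenset(p) in eset
                   for p in itertools.combinations(combo, 2)):
                best = max(best, r)
    return best


def greedy_clump_reference(snps, r2_lookup, p1, p2, r2, kb):
    """Literal transcription of the greedy clumping procedure.

    ``snps``: list of dicts with snp_id, chrom, pos, p.  ``r2_lookup``:
    callable (a, b) -> squared correlation.  Returns {index_snp: sorted
    member list (including the index)}.
    """
    order = sorted(snps, key=lambda s: (s["p"], s["chrom"], s["pos"]))
    assigned = set()
    clumps = {}
    for cand in order:
        if cand["p"] >= p1 or cand["snp_id"] in assigned:
            continue
        members = [cand["snp_id"]]
        for other in order:
            if other["snp_id"] in assigned or other["snp_id"] == cand["snp_id"]:
                continue
            if other["p"] >= p2 or other["chrom"] != cand["chrom"]:
                continue
            if abs(other["pos"] - cand["pos"]) > kb * 1000:
                continue
            if r2_lookup(cand["snp_id"], other["snp_id"]) >= r2:
                members.append(other["snp_id"])
        assigned.update(members)
        clumps[cand["snp_id"]] = sorted(members)
    return clumps


def merge_cascade_reference(items, window=500_000):
    """Independent re-implementation of the locus-merging fixpoint.

    ``items``: list of dicts with keys snp_id, chrom, pos, p, gene (None or
    str), n_traits, start, end.  Returns the final list of dicts sorted by
    (chrom, pos).
    """

    def pick(a, b):
        lo, hi = (a, b) if a["p"] <= b["p"] else (b, a)
        if a["gene"] is not None and a["gene"] == b["gene"]:
            return lo
        if hi["p"] / max(lo["p"], 5e-324) >= 10.0:
            return lo
        a_in, b_in = a["gene"] is not None, b["gene"] is not None
        if a_in != b_in:
            return a if a_in else b
        if a["n_traits"] != b["n_traits"]:
            return a if a["n_traits"] > b["n_traits"] else b
        if a["p"] != b["p"]:
            return lo
        return a if a["pos"] <= b["pos"] else b

    cur = sorted((dict(x) for x in items),
                 key=lambda x: (x["chrom"], x["pos"], x["snp_id"]))
    while True:
        for i in range(len(cur) - 1):
            a, b = cur[i], cur[i + 1]
            if a["chrom"] == b["chrom"] and b["pos"] - a["pos"] <= window:
                winner = dict(pick(a, b))
                winner["start"] = min(a["start"], b["start"])
                winner["end"] = max(a["end"], b["end"])
                cur = cur[:i] + [winner] + cur[i + 2:]
                cur.sort(key=lambda x: (x["chrom"], x["pos"], x["snp_id"]))
                break
        else:
            return cur


def exhaustive_best_subset(z, w):
    """Best sign-flexible subset statistic by itertools enumeration."""
    k = len(z)
    best_val, best_set = -1.0, None
    for r in range(1, k + 1):
        for combo in itertools.combinations(range(k), r):
            num = sum(w[i] * abs(z[i]) for i in combo)
            stat = num / math.sqrt(sum(w[i] ** 2 for i in combo))
            if stat > best_val + 1e-12:
                best_val, best_set = stat, set(combo)
    return best_val, best_set


def weighted_chi2_pair_sf(q, lam1, lam2, n_grid=400_000):
    """P(lam1*X1 + lam2*X2 > q) for independent 1-df chi-squares by direct
    numerical convolution, substituting x = t^2 to remove the density
    singularity at zero."""
    from scipy import stats

    t = np.linspace(0.0, np.sqrt(max(q * 4, 100.0)), n_grid)
    dt = t[1] - t[0]
    dens = np.sqrt(2.0 / (np.pi * lam1)) * np.exp(-t**2 / (2.0 * lam1))
    tail2 = stats.chi2.sf(np.maximum(q - t**2, 0.0) / lam2, df=1)
    tail2[t**2 >= q] = 1.0
    return float(np.trapezoid(dens * tail2, dx=dt))


def bh_stepup_reference(pvals):
    """Benjamini-Hochberg adjusted p-values: p_adj_i = min_{j >= i} p_j m/j
    over the sorted sequence, clipped at 1."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum.accumulate(
        (p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj_sorted, 1.0)
    return out
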