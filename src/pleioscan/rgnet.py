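"""QC, cross-trait LD-score regression, and the disease correlation network.

The analysis keeps autosomal SNPs with MAF above a threshold and outside an
excluded (MHC-like) region, estimates pairwise genetic correlations between
diseases by LD-score regression on summary z-scores, builds the graph of
nominally significant correlations, and extracts the largest fully connected
disease cluster (a maximum clique) from it.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

AUTOSOMES = set(range(1, 23))
#: MHC region excluded from all analyses (chromosome 6, 24-35 Mb).
MHC_REGION = (6, 24_000_000, 35_000_000)


def qc_filter(table: pd.DataFrame, maf_min: float = 1e-5,
              excluded_region: tuple[int, int, int] | None = MHC_REGION
              ) -> pd.DataFrame:
    """Retain autosomal SNPs with MAF > maf_min outside the excluded region.

    ``excluded_region`` is (chrom, start, end), 1-based inclusive.  Row order
    is preserved; an empty result warns but is not an error.
    """
    maf = np.minimum(table["eaf"], 1.0 - table["eaf"])
    keep = (maf > maf_min) & table["chrom"].isin(AUTOSOMES)
    if excluded_region is not None:
        chrom, start, end = excluded_region
        in_region = ((table["chrom"] == chrom) & (table["pos"] >= start)
                     & (table["pos"] <= end))
        keep &= ~in_region
    out = table[keep]
    if out.empty:
        logger.warning("qc_filter removed every SNP")
    return out


def filter_diseases(metadata: pd.DataFrame, min_cases: int = 1000) -> list[str]:
    """Diseases with strictly more than ``min_cases`` cases, input order."""
    keep = metadata[metadata["n_case"] > min_cases]
    return list(keep["disease_id"])


@dataclass
class RgEstimate:
    """One pairwise genetic-correlation estimate."""

    rg: float
    se: float
    p: float
    h2_a: float
    h2_b: float
    reason: str | None = None  # set when rg is undefined


def _slope(y: np.ndarray, x: np.ndarray) -> float:
    """OLS slope of y on x with a free intercept."""
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom <= 0:
        return np.nan
    return float(xc @ (y - y.mean())) / denom


def estimate_rg(stats_a: pd.DataFrame, stats_b: pd.DataFrame,
                ldscores: pd.DataFrame, n_jackknife_blocks: int = 20,
                min_snps: int = 200) -> RgEstimate:
    """Cross-trait LD-score regression genetic correlation.

    Per-SNP heritability slopes come from regressing z^2 on the LD score
    (free intercept) for each trait; the genetic-covariance slope from
    regressing z_a * z_b on the LD score (free intercept, absorbing sample
    overlap).  rg = cov / sqrt(h2_a * h2_b).  The standard error is a
    delete-one block jackknife over ``n_jackknife_blocks`` contiguous SNP
    blocks and the p-value a two-sided normal approximation on rg / se.
    """
    merged = stats_a.merge(stats_b, on="snp_id", suffixes=("_a", "_b"))
    merged = merged.merge(ldscores, on="snp_id")
    if len(merged) < min_snps:
        raise ValueError(f"only {len(merged)} SNPs shared with LD scores "
                         f"(need >= {min_snps})")
    za = merged["z_a"].to_numpy()
    zb = merged["z_b"].to_numpy()
    l2 = merged["l2"].to_numpy()

    def rg_of(idx: np.ndarray) -> tuple[float, float, float]:
        ha = _slope(za[idx] ** 2, l2[idx])
        hb = _slope(zb[idx] ** 2, l2[idx])
        cov = _slope(za[idx] * zb[idx], l2[idx])
        if ha <= 0 or hb <= 0:
            return np.nan, ha, hb
        return cov / math.sqrt(ha * hb), ha, hb

    all_idx = np.arange(len(merged))
    rg_full, h2a, h2b = rg_of(all_idx)
    if not np.isfinite(rg_full):
        return RgEstimate(np.nan, np.nan, np.nan, h2a, h2b,
                          reason="non_positive_heritability")

    folds = np.array_split(all_idx, n_jackknife_blocks)
    pseudo = []
    for k in range(len(folds)):
        keep = np.concatenate([f for j, f in enumerate(folds) if j != k])
        rg_k, _, _ = rg_of(keep)
        if np.isfinite(rg_k):
            pseudo.append(rg_k)
    pseudo = np.asarray(pseudo)
    B = len(pseudo)
    if B < 3:
        return RgEstimate(rg_full, np.nan, np.nan, h2a, h2b,
                          reason="jackknife_failed")
    se = math.sqrt((B - 1) / B * float(np.sum((pseudo - pseudo.mean()) ** 2)))
    if se <= 0:
        return RgEstimate(rg_full, 0.0, 0.0 if rg_full != 0 else 1.0,
                          h2a, h2b)
    p = 2.0 * stats.norm.sf(abs(rg_full) / se)
    return RgEstimate(rg_full, se, max(p, np.finfo(float).tiny), h2a, h2b)


def rg_matrix(stats_by_disease: dict[str, pd.DataFrame],
              ldscores: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """All pairwise rg estimates, long format.

    Columns: dis_a, dis_b, rg, se, p, reason.  Undefined estimates are kept
    with NaN rg and a reason code.
    """
    diseases = list(stats_by_disease)
    rows = []
    for a, b in itertools.combinations(diseases, 2):
        est = estimate_rg(stats_by_disease[a], stats_by_disease[b],
                          ldscores, **kwargs)
        rows.append((a, b, est.rg, est.se, est.p, est.reason))
    return pd.DataFrame(rows, columns=["dis_a", "dis_b", "rg", "se", "p",
                                       "reason"])


def build_graph(rg_table: pd.DataFrame, alpha: float = 0.05) -> nx.Graph:
    """Graph of diseases with an edge where rg_p <= alpha (inclusive).

    Nodes are every disease appearing in the table; edges carry the rg
    estimate, its p-value and ``neglogp`` = -log10(p).
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    G = nx.Graph()
    for row in rg_table.itertuples(index=False):
        G.add_node(row.dis_a)
        G.add_node(row.dis_b)
        if np.isfinite(row.p) and row.p <= alpha:
            G.add_edge(row.dis_a, row.dis_b, rg=row.rg, p=row.p,
                       neglogp=-math.log10(row.p))
    return G


def max_fully_connected_cluster(graph: nx.Graph) -> list[str]:
    """Maximum clique of the significance graph (exact search).

    Enumerates maximal cliques with the pivoting Bron-Kerbosch algorithm and
    returns a maximum one; ties are broken first by the larger sum over
    clique edges of -log10(rg_p), then lexicographically by member ids.
    Returns the sorted member list.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("graph has no nodes")

    def edge_weight(c):
        return sum(graph[u][v].get("neglogp", 0.0)
                   for u, v in itertools.combinations(c, 2))

    best_key = None
    best_members = None
    for clique in nx.find_cliques(graph):
        members = sorted(clique)
        key = (len(members), edge_weight(members))
        if best_key is None or key > best_key \
                or (key == best_key and members < best_members):
            best_key, best_members = key, members
    return best_members
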