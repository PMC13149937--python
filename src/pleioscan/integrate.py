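"""Integration of the three pleiotropy routes and downstream summaries.

Combines the gene-disease maps from the gene-based scan (GBA), the coding-
SNP overlap route (SNP) and the subset meta-analysis route (META) into one
provenance-carrying table, builds the disease network whose edges are shared
genes, classifies each gene's pleiotropy as within- or cross-category, and
runs local hypergeometric gene-set enrichment with Benjamini-Hochberg
correction against an explicit background.
"""

from __future__ import annotations

import itertools
import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

METHODS = ("GBA", "SNP", "META")


def combine_methods(gba: dict[str, frozenset], snp: dict[str, frozenset],
                    meta: dict[str, frozenset],
                    min_diseases: int = 2) -> pd.DataFrame:
    """Union the three gene -> disease-set maps with method provenance.

    Returns the pleiotropy table with one row per (gene, disease) pair and a
    ``methods`` column (comma-joined subset of GBA/SNP/META).  Genes whose
    unioned disease count falls below ``min_diseases`` are dropped.
    """
    maps = {"GBA": gba, "SNP": snp, "META": meta}
    pairs: dict[tuple[str, str], set] = {}
    for method, gmap in maps.items():
        for gene, diseases in gmap.items():
            for d in diseases:
                pairs.setdefault((gene, d), set()).add(method)
    rows = []
    genes = {g for g, _ in pairs}
    for gene in sorted(genes):
        ds = sorted(d for (g, d) in pairs if g == gene)
        if len(ds) < min_diseases:
            continue
        for d in ds:
            methods = ",".join(m for m in METHODS if m in pairs[(gene, d)])
            rows.append((gene, d, methods, len(ds)))
    return pd.DataFrame(rows, columns=["gene_id", "disease_id", "methods",
                                       "n_diseases"])


def method_overlap_counts(gba: dict, snp: dict, meta: dict,
                          min_diseases: int = 2) -> dict[str, dict]:
    """Venn-style counts of pleiotropic genes and of covered diseases.

    For each method, a gene counts when that method alone links it to at
    least ``min_diseases`` diseases; a disease counts when the method links
    it through at least one such gene.
    """
    maps = {"GBA": gba, "SNP": snp, "META": meta}
    gene_sets = {m: {g for g, ds in gmap.items() if len(ds) >= min_diseases}
                 for m, gmap in maps.items()}
    disease_sets = {m: set().union(*(maps[m][g] for g in gene_sets[m]))
                    if gene_sets[m] else set() for m in maps}
    venn_genes = {}
    venn_diseases = {}
    for r in range(1, 4):
        for combo in itertools.combinations(METHODS, r):
            in_these_g = set.intersection(*(gene_sets[m] for m in combo))
            out_g = set().union(*(gene_sets[m] for m in METHODS
                                  if m not in combo), set())
            venn_genes["&".join(combo)] = len(in_these_g - out_g)
            in_these_d = set.intersection(*(disease_sets[m] for m in combo))
            out_d = set().union(*(disease_sets[m] for m in METHODS
                                  if m not in combo), set())
            venn_diseases["&".join(combo)] = len(in_these_d - out_d)
    return {"genes": venn_genes, "diseases": venn_diseases,
            "per_method_genes": {m: len(s) for m, s in gene_sets.items()},
            "per_method_diseases": {m: len(s)
                                    for m, s in disease_sets.items()}}


def build_disease_network(table: pd.DataFrame,
                          metadata: pd.DataFrame) -> nx.Graph:
    """Disease network: an edge wherever two diseases share >= 1 gene.

    Edge attributes: ``genes`` (sorted shared gene list) and ``weight``
    (shared-gene count).  Every disease in the table appears as a node, so
    isolated diseases (sharing no gene) are inspectable; node attribute
    ``category`` comes from the metadata ("unknown" if absent, logged).
    """
    cat = dict(zip(metadata["disease_id"], metadata["category"]))
    G = nx.Graph()
    genes_of: dict[str, set] = {}
    for row in table.itertuples(index=False):
        genes_of.setdefault(row.disease_id, set()).add(row.gene_id)
    for d in sorted(genes_of):
        if d not in cat:
            logger.warning("disease %s missing from metadata; category set "
                           "to 'unknown'", d)
        G.add_node(d, category=cat.get(d, "unknown"))
    for d1, d2 in itertools.combinations(sorted(genes_of), 2):
        shared = sorted(genes_of[d1] & genes_of[d2])
        if shared:
            G.add_edge(d1, d2, genes=shared, weight=len(shared))
    return G


def isolated_diseases(network: nx.Graph, all_diseases=None) -> list[str]:
    """Diseases connected to no other disease through a shared gene."""
    iso = {n for n in network.nodes if network.degree(n) == 0}
    if all_diseases is not None:
        iso |= set(all_diseases) - set(network.nodes)
    return sorted(iso)


def shared_fraction(network: nx.Graph, all_diseases) -> float:
    """Fraction of ``all_diseases`` sharing >= 1 gene with another disease."""
    all_diseases = list(all_diseases)
    if not all_diseases:
        return float("nan")
    connected = [d for d in all_diseases
                 if d in network.nodes and network.degree(d) > 0]
    return len(connected) / len(all_diseases)


def classify_category_span(table: pd.DataFrame,
                           metadata: pd.DataFrame) -> pd.DataFrame:
    """Label each gene's pleiotropy as within- or cross-category.

    A gene is "within" when all its diseases belong to one nosological
    category, else "cross"; ``n_categories`` counts the distinct categories
    spanned.
    """
    cat = dict(zip(metadata["disease_id"], metadata["category"]))
    missing = set(table["disease_id"]) - set(cat)
    if missing:
        raise ValueError(f"diseases without category: {sorted(missing)}")
    rows = []
    for gene, grp in table.groupby("gene_id"):
        cats = {cat[d] for d in grp["disease_id"]}
        rows.append((gene, "within" if len(cats) == 1 else "cross",
                     len(cats)))
    return pd.DataFrame(rows, columns=["gene_id", "span", "n_categories"])


def enrich(query_genes, gene_sets: dict[str, list[str]],
           background: int | list[str], alpha: float = 0.05) -> pd.DataFrame:
    """Hypergeometric gene-set enrichment with Benjamini-Hochberg control.

    For each set, the one-sided upper-tail probability of drawing at least
    the observed overlap when ``len(query)`` genes are sampled from a
    background of size ``background`` containing ``len(set)`` set members.
    ``background`` may be a size or an explicit gene list (sets and query
    are then intersected with it).

    Returns one row per set: set_id, overlap, set_size, query_size,
    background_size, p, p_adjusted, significant (adjusted p < alpha).
    """
    query = set(query_genes)
    if not query:
        raise ValueError("empty query gene list")
    if isinstance(background, int):
        bg_size = background
        bg = None
    else:
        bg = set(background)
        bg_size = len(bg)
        query = query & bg
    rows = []
    for set_id, members in gene_sets.items():
        mem = set(members) if bg is None else set(members) & bg
        if bg_size < len(mem | query):
            raise ValueError(f"background smaller than set {set_id} plus "
                             f"query")
        overlap = len(mem & query)
        # P(X >= overlap), X ~ Hypergeom(bg, |set|, |query|)
        p = float(stats.hypergeom.sf(overlap - 1, bg_size, len(mem),
                                     len(query)))
        rows.append((set_id, overlap, len(mem), len(query), bg_size, p))
    out = pd.DataFrame(rows, columns=["set_id", "overlap", "set_size",
                                      "query_size", "background_size", "p"])
    _, p_adj, _, _ = multipletests(out["p"], method="fdr_bh")
    out["p_adjusted"] = p_adj
    out["significant"] = out["p_adjusted"] < alpha
    return out
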