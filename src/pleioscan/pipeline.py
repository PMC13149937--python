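"""End-to-end orchestration: inputs -> QC -> rg network -> three pleiotropy
routes -> integrated disease-gene network and enrichment.

The pipeline mirrors the analysis design: diseases with enough cases are
kept; SNPs pass the MAF/autosome/region QC; pairwise genetic correlations
define a significance graph whose maximum clique is the fully connected
cluster; pleiotropic genes are found by the gene-based scan, by coding
genome-wide-significant SNPs, and by subset meta-analysis with locus
merging; the three maps are unioned into the disease-gene network.

At desk scale (thousands of SNPs) LD-score regression has limited power, so
by default the downstream routes analyze every disease passing the case
filter and the fully connected cluster is reported alongside rather than
used as a gate; set ``restrict_to_cluster=True`` for the gated behaviour.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import networkx as nx
import pandas as pd

from . import crossmeta, genetest, integrate, rgnet, snppleio
from .simulate import (SimConfig, disease_metadata, simulate_annotation,
                       simulate_consequences, simulate_evidence,
                       simulate_gene_sets, simulate_ld, simulate_sumstats)

logger = logging.getLogger(__name__)


def simulate_bundle(config: SimConfig):
    """In-memory input bundle (same shape as :func:`pleioscan.io.read_bundle`)
    plus the planted ground truth."""
    ld = simulate_ld(config)
    sumstats, truth = simulate_sumstats(config, ld)
    bundle = {
        "sumstats": sumstats,
        "ld": ld,
        "ld_scores": ld.ld_score_table(),
        "annotation": simulate_annotation(config),
        "consequences": simulate_consequences(config),
        "evidence": simulate_evidence(config),
        "gene_sets": simulate_gene_sets(config),
        "metadata": disease_metadata(config),
    }
    return bundle, truth


def run_pipeline(bundle: dict, seed: int = 0, alpha: float = 0.05,
                 min_cases: int = 1000, maf_min: float = 1e-5,
                 excluded_region=rgnet.MHC_REGION,
                 gene_threshold: float | None = None,
                 restrict_to_cluster: bool = False,
                 outdir: str | Path | None = None) -> dict:
    """Run the full analysis on an input bundle.

    Returns a dict of result tables and a ``summary`` of stage-by-stage
    counts; writes TSV/GraphML/JSON outputs when ``outdir`` is given.
    """
    if gene_threshold is None:
        gene_threshold = genetest.gene_test_threshold()
    meta_tab = bundle["metadata"]

    diseases = rgnet.filter_diseases(meta_tab, min_cases=min_cases)
    logger.info("diseases passing case filter: %d of %d", len(diseases),
                len(meta_tab))
    stats = {}
    for d in diseases:
        before = len(bundle["sumstats"][d])
        stats[d] = rgnet.qc_filter(bundle["sumstats"][d], maf_min=maf_min,
                                   excluded_region=excluded_region)
        logger.info("QC %s: %d -> %d SNPs", d, before, len(stats[d]))

    # genetic correlations and the fully connected cluster
    rg_table = rgnet.rg_matrix(stats, bundle["ld_scores"])
    graph = rgnet.build_graph(rg_table, alpha=alpha)
    cluster = rgnet.max_fully_connected_cluster(graph)
    logger.info("fully connected cluster: %d diseases", len(cluster))

    analyzed = cluster if restrict_to_cluster else diseases
    stats_used = {d: stats[d] for d in analyzed}

    # route 1: gene-based scan
    scan = genetest.run_gene_scan(stats_used, bundle["annotation"],
                                  bundle["ld"], threshold=gene_threshold)
    pleio_raw = genetest.find_pleiotropic_genes(scan)
    gba_map = genetest.filter_ld_gene_clusters(pleio_raw,
                                               bundle["annotation"],
                                               bundle["evidence"])

    # route 2: coding genome-wide-significant SNPs
    snp_map_snps = snppleio.select_pleiotropic_snps(stats_used)
    snp_map, snp_prov = snppleio.assign_coding_genes(
        snp_map_snps, bundle["consequences"])

    # route 3: subset meta-analysis, clumping, locus merging
    trait_corr = crossmeta.estimate_trait_corr(stats_used)
    meta = crossmeta.run_meta(stats_used, trait_corr=trait_corr, seed=seed)
    clumps = crossmeta.clump(meta, bundle["ld"])
    loci = crossmeta.build_loci(clumps, meta, bundle["annotation"])
    loci = crossmeta.merge_loci(loci)
    meta_map = crossmeta.locus_gene_map(loci, bundle["annotation"])

    # integration
    table = integrate.combine_methods(gba_map, snp_map, meta_map)
    network = integrate.build_disease_network(table, meta_tab)
    span = integrate.classify_category_span(table, meta_tab)
    overlap = integrate.method_overlap_counts(gba_map, snp_map, meta_map)
    genes_union = sorted(table["gene_id"].unique())
    enrichment = None
    if genes_union and bundle.get("gene_sets"):
        enrichment = integrate.enrich(genes_union, bundle["gene_sets"],
                                      list(bundle["annotation"]["gene_id"]))

    meta_sig = meta[(meta["p_meta"] < crossmeta.GENOME_WIDE_P)
                    & (meta["subset"].str.contains(","))]
    summary = {
        "n_diseases_input": int(len(meta_tab)),
        "n_diseases_analyzed": int(len(analyzed)),
        "cluster_size": int(len(cluster)),
        "n_rg_edges": int(graph.number_of_edges()),
        "n_genes_gba_any": int(scan.loc[scan["significant"],
                                        "gene_id"].nunique()),
        "n_genes_gba_pleio": int(len(pleio_raw)),
        "n_genes_gba_filtered": int(len(gba_map)),
        "n_pleio_snps": int(len(snp_map_snps)),
        "n_genes_snp": int(len(snp_map)),
        "n_meta_sig_snps": int(len(meta_sig)),
        "n_clumps": int(len(clumps)),
        "n_loci": int(len(loci)),
        "n_loci_with_gene": int(sum(L.assigned_gene is not None
                                    for L in loci)),
        "n_genes_meta": int(len(meta_map)),
        "n_genes_total": int(len(genes_union)),
        "n_isolated_diseases": int(len(
            integrate.isolated_diseases(network, analyzed))),
        "shared_fraction": float(integrate.shared_fraction(network,
                                                           analyzed)),
        "n_within_category": int((span["span"] == "within").sum())
        if len(span) else 0,
        "n_cross_category": int((span["span"] == "cross").sum())
        if len(span) else 0,
    }

    results = {
        "diseases": diseases, "stats": stats, "rg_table": rg_table,
        "graph": graph, "cluster": cluster, "scan": scan,
        "gba_map": gba_map, "snp_map": snp_map, "snp_provenance": snp_prov,
        "meta": meta, "clumps": clumps, "loci": loci, "meta_map": meta_map,
        "pleiotropy_table": table, "network": network, "span": span,
        "enrichment": enrichment, "overlap_counts": overlap,
        "summary": summary,
    }
    if outdir is not None:
        _write_outputs(results, Path(outdir))
    return results


def _write_outputs(results: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    rg = results["rg_table"]
    pd.DataFrame({"DIS_A": rg["dis_a"], "DIS_B": rg["dis_b"],
                  "RG": rg["rg"], "SE": rg["se"], "P": rg["p"]}).to_csv(
        outdir / "rg_matrix.tsv", sep="\t", index=False)
    pd.DataFrame({"DISEASE_ID": results["cluster"]}).to_csv(
        outdir / "cluster.tsv", sep="\t", index=False)
    nx.to_pandas_edgelist(results["graph"]).to_csv(
        outdir / "rg_graph_edges.tsv", sep="\t", index=False)

    scan = results["scan"]
    pd.DataFrame({"GENE_ID": scan["gene_id"],
                  "DISEASE_ID": scan["disease_id"],
                  "N_SNP": scan["n_snps"], "P_SKATO": scan["p_skato"],
                  "P_PCA": scan["p_pca"], "P_ACAT": scan["p_combined"],
                  "SIGNIFICANT": scan["significant"].astype(int)}).to_csv(
        outdir / "gene_scan.tsv", sep="\t", index=False)
    _write_gene_map(results["gba_map"], outdir / "pleio_genes_gba.tsv")
    _write_gene_map(results["snp_map"], outdir / "pleio_genes_snp.tsv")
    _write_gene_map(results["meta_map"], outdir / "pleio_genes_meta.tsv")

    meta = results["meta"]
    pd.DataFrame({"SNPID": meta["snp_id"], "P_META": meta["p_meta"],
                  "SUBSET": meta["subset"],
                  "N_SIG_TRAITS": meta["n_sig_traits"]}).to_csv(
        outdir / "meta.tsv", sep="\t", index=False)
    cl = results["clumps"]
    pd.DataFrame({"INDEX_SNP": cl["index_snp"],
                  "MEMBERS": cl["members"]}).to_csv(
        outdir / "clumps.tsv", sep="\t", index=False)
    loci_rows = [(L.chrom, L.start, L.end, L.index_snp, L.p_meta,
                  ",".join(sorted(L.trait_set)), L.assigned_gene or "")
                 for L in results["loci"]]
    pd.DataFrame(loci_rows, columns=["CHROM", "START", "END", "INDEX_SNP",
                                     "P_META", "TRAITS", "GENE_ID"]).to_csv(
        outdir / "loci.tsv", sep="\t", index=False)

    tab = results["pleiotropy_table"]
    pd.DataFrame({"GENE_ID": tab["gene_id"], "DISEASE_ID": tab["disease_id"],
                  "METHODS": tab["methods"],
                  "N_DISEASES": tab["n_diseases"]}).to_csv(
        outdir / "pleiotropy_table.tsv", sep="\t", index=False)
    net = results["network"]
    edge_rows = [(u, v, d["weight"], ",".join(d["genes"]))
                 for u, v, d in net.edges(data=True)]
    pd.DataFrame(edge_rows, columns=["D1", "D2", "WEIGHT", "GENES"]).to_csv(
        outdir / "network_edges.tsv", sep="\t", index=False)
    export = nx.Graph()
    export.add_nodes_from((n, dict(d)) for n, d in net.nodes(data=True))
    export.add_edges_from((u, v, {"weight": d["weight"],
                                  "genes": ",".join(d["genes"])})
                          for u, v, d in net.edges(data=True))
    nx.write_graphml(export, outdir / "disease_network.graphml")
    if results["enrichment"] is not None:
        results["enrichment"].to_csv(outdir / "enrichment.tsv", sep="\t",
                                     index=False)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(results["summary"], fh, indent=2, sort_keys=True)


def _write_gene_map(gmap: dict, path: Path) -> None:
    rows = [(g, ",".join(sorted(ds))) for g, ds in sorted(gmap.items())]
    pd.DataFrame(rows, columns=["GENE_ID", "DISEASES"]).to_csv(
        path, sep="\t", index=False)
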