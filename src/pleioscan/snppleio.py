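"""SNP-level pleiotropy: genome-wide significant SNPs shared by diseases.

A SNP is pleiotropic when its association p-value is below the genome-wide
threshold (5e-8, strict) in at least two diseases.  Pleiotropic SNPs with a
coding consequence (stop-gained, missense or synonymous) implicate their
gene in every disease the SNP is significant for.
"""

from __future__ import annotations

import logging

import pandas as pd

logger = logging.getLogger(__name__)

GENOME_WIDE_P = 5e-8
CODING_CONSEQUENCES = frozenset({"stop_gained", "missense", "synonymous"})


def select_pleiotropic_snps(stats_by_disease: dict[str, pd.DataFrame],
                            threshold: float = GENOME_WIDE_P,
                            min_diseases: int = 2) -> dict[str, frozenset]:
    """SNPs with p < threshold (strict) in at least ``min_diseases`` diseases.

    Returns {snp_id: frozenset of qualifying diseases}.
    """
    hits: dict[str, set] = {}
    for disease, tab in stats_by_disease.items():
        for snp in tab.loc[tab["p"] < threshold, "snp_id"]:
            hits.setdefault(snp, set()).add(disease)
    return {snp: frozenset(ds) for snp, ds in sorted(hits.items())
            if len(ds) >= min_diseases}


def assign_coding_genes(snp_map: dict[str, frozenset],
                        consequences: pd.DataFrame
                        ) -> tuple[dict[str, frozenset], pd.DataFrame]:
    """Map pleiotropic coding SNPs to genes.

    Each selected SNP with a coding consequence passes its disease set to the
    gene; per gene, disease sets are unioned over its SNPs.  Consequence
    "other" contributes nothing; SNPs absent from the table are treated as
    non-coding (logged).  A SNP coding in several overlapping genes
    contributes to each.

    Returns the gene -> disease-set map and a provenance table with columns
    gene_id, snp_id, consequence, diseases.
    """
    cons = consequences[consequences["consequence"].isin(CODING_CONSEQUENCES)]
    by_snp = cons.groupby("snp_id")
    genes: dict[str, set] = {}
    prov = []
    known_snps = set(consequences["snp_id"])
    for snp, diseases in snp_map.items():
        if snp not in known_snps:
            logger.info("pleiotropic SNP %s absent from consequence table; "
                        "treated as non-coding", snp)
            continue
        if snp not in by_snp.groups:
            continue  # annotated, but no coding consequence
        for row in by_snp.get_group(snp).itertuples(index=False):
            genes.setdefault(row.gene_id, set()).update(diseases)
            prov.append((row.gene_id, snp, row.consequence,
                         ",".join(sorted(diseases))))
    gene_map = {g: frozenset(ds) for g, ds in sorted(genes.items())}
    prov_table = pd.DataFrame(prov, columns=["gene_id", "snp_id",
                                             "consequence", "diseases"])
    return gene_map, prov_table
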