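"""Readers and writers for the pipeline's external file formats.

All formats are plain TSV (SAIGE-like summary statistics, square LD-block
matrices with a SNP-id header row, BED-like but 1-based-inclusive gene
annotation, VEP-like consequences, gene-disease evidence scores, disease
metadata) plus standard GMT gene sets.  Readers return the in-memory
containers the analysis modules consume; writers invert them bit-identically.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import LDBlock, LDCollection

_SUMSTATS_COLS = ["CHR", "POS", "SNPID", "Allele1", "Allele2", "AF_Allele2",
                  "BETA", "SE", "p.value", "N_case", "N_ctrl"]


def write_sumstats(table: pd.DataFrame, path: str | Path) -> None:
    """Write a summary-statistics table in SAIGE-like TSV layout."""
    out = pd.DataFrame({
        "CHR": table["chrom"], "POS": table["pos"], "SNPID": table["snp_id"],
        "Allele1": table["allele1"], "Allele2": table["allele2"],
        "AF_Allele2": table["eaf"], "BETA": table["beta"], "SE": table["se"],
        "p.value": table["p"], "N_case": table["n_case"],
        "N_ctrl": table["n_ctrl"],
    })
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_sumstats(path: str | Path) -> pd.DataFrame:
    """Read SAIGE-like summary statistics into the internal layout.

    Adds the derived z = beta / se column.
    """
    raw = pd.read_csv(path, sep="\t")
    missing = set(_SUMSTATS_COLS) - set(raw.columns)
    if missing:
        raise ValueError(f"summary-statistics file {path} lacks columns "
                         f"{sorted(missing)}")
    tab = pd.DataFrame({
        "snp_id": raw["SNPID"], "chrom": raw["CHR"], "pos": raw["POS"],
        "allele1": raw["Allele1"], "allele2": raw["Allele2"],
        "eaf": raw["AF_Allele2"], "beta": raw["BETA"], "se": raw["SE"],
        "p": raw["p.value"], "n_case": raw["N_case"], "n_ctrl": raw["N_ctrl"],
    })
    tab["z"] = tab["beta"] / tab["se"]
    return tab


def write_ld_blocks(ld: LDCollection, outdir: str | Path) -> None:
    """One TSV per block: SNPID header row, then the square matrix."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for k, block in enumerate(ld.blocks):
        path = outdir / f"block_{k:04d}.tsv"
        with open(path, "w") as fh:
            fh.write("\t".join(block.snp_ids) + "\n")
            for row in block.R:
                fh.write("\t".join(f"{v:.10g}" for v in row) + "\n")


def read_ld_blocks(indir: str | Path,
                   chrom_of: dict[str, int] | None = None) -> LDCollection:
    """Read every ``block_*.tsv`` file in a directory."""
    blocks = []
    for path in sorted(Path(indir).glob("block_*.tsv")):
        with open(path) as fh:
            snp_ids = fh.readline().rstrip("\n").split("\t")
            R = np.loadtxt(fh, delimiter="\t", ndmin=2)
        chrom = chrom_of.get(snp_ids[0]) if chrom_of else None
        blocks.append(LDBlock(snp_ids, R, chrom=chrom))
    if not blocks:
        raise FileNotFoundError(f"no block_*.tsv files under {indir}")
    return LDCollection(blocks)


def write_ld_scores(scores: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame({"SNPID": scores["snp_id"], "L2": scores["l2"]})
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_ld_scores(path: str | Path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t")
    return pd.DataFrame({"snp_id": raw["SNPID"], "l2": raw["L2"]})


def write_annotation(genes: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame({
        "CHR": genes["chrom"], "TX_START": genes["tx_start"],
        "TX_END": genes["tx_end"], "GENE_ID": genes["gene_id"],
        "SYMBOL": genes["symbol"], "CODING": genes["coding"],
    })
    out.to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t")
    return pd.DataFrame({
        "gene_id": raw["GENE_ID"], "symbol": raw["SYMBOL"],
        "chrom": raw["CHR"], "tx_start": raw["TX_START"],
        "tx_end": raw["TX_END"], "coding": raw["CODING"],
    })


def write_consequences(cons: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame({"SNPID": cons["snp_id"], "GENE_ID": cons["gene_id"],
                        "CONSEQUENCE": cons["consequence"]})
    out.to_csv(path, sep="\t", index=False)


def read_consequences(path: str | Path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t")
    return pd.DataFrame({"snp_id": raw["SNPID"], "gene_id": raw["GENE_ID"],
                         "consequence": raw["CONSEQUENCE"]})


def write_evidence(evidence: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame({"GENE_ID": evidence["gene_id"],
                        "DISEASE_ID": evidence["disease_id"],
                        "SCORE": evidence["score"]})
    out.to_csv(path, sep="\t", index=False)


def read_evidence(path: str | Path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t")
    return pd.DataFrame({"gene_id": raw["GENE_ID"],
                         "disease_id": raw["DISEASE_ID"],
                         "score": raw["SCORE"]})


def write_disease_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame({"DISEASE_ID": meta["disease_id"],
                        "NAME": meta["name"], "CATEGORY": meta["category"],
                        "N_case": meta["n_case"], "N_total": meta["n_total"]})
    out.to_csv(path, sep="\t", index=False)


def read_disease_metadata(path: str | Path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t")
    return pd.DataFrame({"disease_id": raw["DISEASE_ID"], "name": raw["NAME"],
                         "category": raw["CATEGORY"],
                         "n_case": raw["N_case"], "n_total": raw["N_total"]})


def write_gmt(sets: dict[str, list[str]], path: str | Path) -> None:
    """GMT: set name, description, then member genes, tab-separated."""
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = parts[2:]
    return sets


def read_bundle(indir: str | Path) -> dict:
    """Read a complete fixture bundle written by ``write_fixture_bundle``.

    Returns a dict with keys: sumstats (disease -> table), ld, ld_scores,
    annotation, consequences, evidence, gene_sets, metadata.
    """
    indir = Path(indir)
    meta = read_disease_metadata(indir / "diseases.tsv")
    sumstats = {d: read_sumstats(indir / f"sumstats_{d}.tsv")
                for d in meta["disease_id"]}
    any_tab = next(iter(sumstats.values()))
    chrom_of = dict(zip(any_tab["snp_id"], any_tab["chrom"]))
    return {
        "sumstats": sumstats,
        "ld": read_ld_blocks(indir / "ld_blocks", chrom_of),
        "ld_scores": read_ld_scores(indir / "ldscores.tsv"),
        "annotation": read_annotation(indir / "genes.tsv"),
        "consequences": read_consequences(indir / "consequences.tsv"),
        "evidence": read_evidence(indir / "evidence.tsv"),
        "gene_sets": read_gmt(indir / "genesets.gmt"),
        "metadata": meta,
    }
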