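"""Synthetic multi-disease GWAS generator with planted pleiotropic genes.

Summary statistics are simulated directly at the z-score level — no
individual genotypes — because every downstream method (LD-score regression,
gene-based tests, subset meta-analysis, clumping) consumes summary statistics
only.  For each LD block with correlation matrix R the disease-d z vector is

    z_d = R (lambda_d + u_d) + L eps_d,      L = chol(R),

where lambda_d is the per-SNP noncentrality (nonzero only inside planted
genes whose disease subset contains d), u is a polygenic background drawn
per SNP with cross-disease covariance sigma_g^2 * rg_target, and eps is unit
noise whose cross-disease correlation models sample overlap.  This gives the
LD-score-regression moment structure

    E[z_dj^2]      = 1 + sigma_g^2 * l_j,
    E[z_dj z_d'j]  = sigma_g^2 * rg_dd' * l_j  +  overlap_dd',

with l_j the LD score of SNP j, so cross-trait LD-score regression recovers
rg_target and a free intercept absorbs the overlap term.  By default the
overlap correlation equals rg_target (all diseases measured on one cohort,
as in a biobank), which also makes the marginal null z correlation across
diseases equal to rg_target.

Genome layout: ``n_chromosomes`` x ``blocks_per_chrom`` independent AR(1) LD
blocks of ``snps_per_block`` SNPs each, SNPs 2 kb apart, blocks 1 Mb apart.
One gene per block occupies a contiguous run of SNPs in the middle of the
block, leaving intergenic flanks so nearest-gene assignment is exercised.
An MHC-like region covering one whole block exercises the region filter, and
a configurable fraction of SNPs carries allele frequencies below 1e-5 to
exercise the MAF filter.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import LDBlock, LDCollection

SNP_SPACING = 2_000          # bp between SNPs within a block
BLOCK_SPACING = 1_000_000    # bp between block starts
GENE_FIRST_SNP = 10          # gene occupies SNP indices [10, 29] of its block
GENE_LAST_SNP = 29


@dataclass(frozen=True)
class PlantedGene:
    """A causal gene: its id, the disease subset it affects, and the per-SNP
    noncentrality added (before LD smearing) to the z-scores of its SNPs."""

    gene_id: str
    diseases: tuple[str, ...]
    lam: float


@dataclass
class SimConfig:
    """Configuration of the synthetic multi-disease study."""

    n_diseases: int = 6
    n_chromosomes: int = 4
    blocks_per_chrom: int = 15
    snps_per_block: int = 50
    ld_decay: float = 0.6
    maf_range: tuple[float, float] = (0.01, 0.5)
    low_maf_fraction: float = 0.02
    n_genes: int = 60
    planted_genes: tuple[PlantedGene, ...] = ()
    sample_sizes: tuple[tuple[int, int], ...] = ()
    rg_target: np.ndarray | None = None
    overlap_corr: np.ndarray | None = None   # None -> same as rg_target
    polygenic_var: float = 0.25              # sigma_g^2 per SNP
    mhc_like_region: tuple[int, int, int] = (1, 2_000_001, 3_000_000)
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.ld_decay < 1.0):
            raise ValueError("ld_decay must lie in [0, 1)")
        if self.snps_per_block <= 0 or self.blocks_per_chrom <= 0 \
                or self.n_chromosomes <= 0:
            raise ValueError("block layout counts must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be an interval in (0, 0.5]")
        if not self.sample_sizes:
            base = [(20_000, 380_000), (15_000, 385_000), (12_000, 388_000),
                    (9_000, 391_000), (6_000, 394_000), (3_000, 397_000)]
            self.sample_sizes = tuple(base[i % len(base)]
                                      for i in range(self.n_diseases))
        if len(self.sample_sizes) != self.n_diseases:
            raise ValueError("sample_sizes must have one entry per disease")
        if self.rg_target is None:
            self.rg_target = np.full((self.n_diseases, self.n_diseases), 0.5)
            np.fill_diagonal(self.rg_target, 1.0)
        self.rg_target = np.asarray(self.rg_target, dtype=float)
        D = self.n_diseases
        if self.rg_target.shape != (D, D):
            raise ValueError("rg_target must be n_diseases x n_diseases")
        if not np.allclose(self.rg_target, self.rg_target.T):
            raise ValueError("rg_target must be symmetric")
        if not np.allclose(np.diag(self.rg_target), 1.0):
            raise ValueError("rg_target must have unit diagonal")
        if np.linalg.eigvalsh(self.rg_target)[0] < -1e-8:
            raise ValueError("rg_target must be positive semidefinite")
        if self.overlap_corr is not None:
            self.overlap_corr = np.asarray(self.overlap_corr, dtype=float)
        dis = set(self.disease_ids)
        for pg in self.planted_genes:
            if not set(pg.diseases) <= dis:
                raise ValueError(
                    f"planted gene {pg.gene_id} names unknown diseases")

    # -- layout helpers ----------------------------------------------------

    @property
    def disease_ids(self) -> list[str]:
        return [f"D{i + 1}" for i in range(self.n_diseases)]

    @property
    def n_blocks(self) -> int:
        return self.n_chromosomes * self.blocks_per_chrom

    @property
    def n_snps(self) -> int:
        return self.n_blocks * self.snps_per_block


@dataclass
class GroundTruth:
    """Planted structure of a simulated study."""

    causal_gene_to_diseases: dict[str, frozenset]
    null_pairs: dict[tuple[str, str], bool]

    def planted_pleiotropic(self, min_diseases: int = 2) -> dict[str, frozenset]:
        return {g: d for g, d in self.causal_gene_to_diseases.items()
                if len(d) >= min_diseases}


def default_planted_genes(lam: float = 4.0) -> tuple[PlantedGene, ...]:
    """Default planted causal genes for the 6-disease fixture.

    The per-SNP noncentrality lam = 4 is smeared by the AR(1) LD to an
    expected peak z of roughly lam * (1 + ld_decay) / (1 - ld_decay) = 16,
    giving essentially complete single-SNP power at the 5e-8 threshold
    (Phi(16 - 5.45) ~ 1).
    """
    return (
        PlantedGene("G0006", ("D1", "D2"), lam),
        PlantedGene("G0013", ("D2", "D3"), lam),
        PlantedGene("G0021", ("D1", "D3", "D4"), lam),
        PlantedGene("G0034", ("D4", "D5"), lam),
        PlantedGene("G0042", ("D5", "D6"), lam),
        PlantedGene("G0053", ("D1", "D2", "D5", "D6"), lam),
    )


def default_config(seed: int = 0, lam: float = 4.0, **overrides) -> SimConfig:
    """The default desk-scale fixture: 6 diseases, 3,000 SNPs, 60 genes."""
    cfg = SimConfig(planted_genes=default_planted_genes(lam), seed=seed)
    return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# layout


def snp_layout(config: SimConfig) -> pd.DataFrame:
    """Genomic coordinates of every simulated SNP.

    Columns: snp_id, chrom, pos, block (global index), idx (within block).
    """
    rows = []
    sid = 0
    for k in range(config.n_blocks):
        chrom = k // config.blocks_per_chrom + 1
        local = k % config.blocks_per_chrom
        base = local * BLOCK_SPACING + 1
        for i in range(config.snps_per_block):
            rows.append((f"rs{sid:06d}", chrom, base + i * SNP_SPACING, k, i))
            sid += 1
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "block",
                                       "idx"])


def simulate_annotation(config: SimConfig) -> pd.DataFrame:
    """Gene annotation: one gene per block, covering a middle run of SNPs.

    1-based inclusive transcription bounds.  A fixed subset of genes is
    flagged non-coding so the protein-coding restriction is exercised.
    Columns: gene_id, symbol, chrom, tx_start, tx_end, coding.
    """
    if config.n_genes > config.n_blocks:
        raise ValueError("at most one gene per LD block is supported")
    layout = snp_layout(config)
    noncoding = {4, 17, 30, 43, 56}
    last = min(GENE_LAST_SNP, config.snps_per_block - 1)
    first = min(GENE_FIRST_SNP, max(config.snps_per_block - 2, 0))
    rows = []
    for k in range(config.n_genes):
        blk = layout[layout["block"] == k]
        tx_start = int(blk.iloc[first]["pos"])
        tx_end = int(blk.iloc[last]["pos"])
        rows.append((f"G{k + 1:04d}", f"SYM{k + 1:04d}",
                     int(blk.iloc[0]["chrom"]), tx_start, tx_end,
                     0 if k in noncoding else 1))
    return pd.DataFrame(rows, columns=["gene_id", "symbol", "chrom",
                                       "tx_start", "tx_end", "coding"])


# ---------------------------------------------------------------------------
# LD


def simulate_ld(config: SimConfig) -> LDCollection:
    """First-order autoregressive LD blocks: corr(i, j) = ld_decay^|i-j|."""
    layout = snp_layout(config)
    p = config.snps_per_block
    idx = np.arange(p)
    R = config.ld_decay ** np.abs(idx[:, None] - idx[None, :])
    blocks = []
    for k, grp in layout.groupby("block", sort=True):
        blocks.append(LDBlock(list(grp["snp_id"]), R.copy(),
                              chrom=int(grp["chrom"].iloc[0])))
    return LDCollection(blocks)


# ---------------------------------------------------------------------------
# summary statistics


def _chol_psd(M: np.ndarray) -> np.ndarray:
    """Cholesky-like factor tolerant of semidefinite matrices."""
    try:
        return np.linalg.cholesky(M)
    except np.linalg.LinAlgError:
        evals, evecs = np.linalg.eigh(M)
        return evecs * np.sqrt(np.clip(evals, 0.0, None))


def simulate_maf(config: SimConfig) -> np.ndarray:
    """Per-SNP minor allele frequency, with a low-frequency tail below 1e-5."""
    rng = np.random.default_rng([config.seed, 11])
    lo, hi = config.maf_range
    maf = rng.uniform(lo, hi, size=config.n_snps)
    n_low = int(round(config.low_maf_fraction * config.n_snps))
    if n_low:
        low_idx = rng.choice(config.n_snps, size=n_low, replace=False)
        maf[low_idx] = rng.uniform(1e-7, 1e-5, size=n_low)
    return maf


def simulate_sumstats(config: SimConfig, ld: LDCollection
                      ) -> tuple[dict[str, pd.DataFrame], GroundTruth]:
    """Simulate per-disease SAIGE-like summary statistics.

    Returns a mapping disease id -> table with columns snp_id, chrom, pos,
    allele1, allele2, eaf, beta, se, z, p, n_case, n_ctrl, plus the planted
    ground truth.
    """
    layout = snp_layout(config)
    if sum(len(b.snp_ids) for b in ld.blocks) != len(layout):
        raise ValueError("LD blocks do not match the configured SNP count")
    genes = simulate_annotation(config)
    gene_bounds = genes.set_index("gene_id")
    D = config.n_diseases
    diseases = config.disease_ids
    d_index = {d: i for i, d in enumerate(diseases)}

    # per-SNP noncentrality matrix (n_snps x D)
    lam = np.zeros((config.n_snps, D))
    truth_map: dict[str, frozenset] = {}
    for pg in config.planted_genes:
        if pg.gene_id not in gene_bounds.index:
            raise ValueError(f"planted gene {pg.gene_id} not in annotation")
        row = gene_bounds.loc[pg.gene_id]
        in_gene = ((layout["chrom"] == row["chrom"])
                   & (layout["pos"] >= row["tx_start"])
                   & (layout["pos"] <= row["tx_end"])).to_numpy()
        for d in pg.diseases:
            lam[in_gene, d_index[d]] += pg.lam
        truth_map[pg.gene_id] = frozenset(pg.diseases)

    overlap = config.overlap_corr if config.overlap_corr is not None \
        else config.rg_target
    L_overlap = _chol_psd(overlap)
    L_rg = _chol_psd(config.rg_target)
    sigma_g = np.sqrt(config.polygenic_var)

    rng = np.random.default_rng([config.seed, 22])
    z = np.empty((config.n_snps, D))
    start = 0
    for block in ld.blocks:
        p = len(block.snp_ids)
        R = block.R
        L_R = _chol_psd(R)
        eps = rng.standard_normal((p, D)) @ L_overlap.T
        u = sigma_g * rng.standard_normal((p, D)) @ L_rg.T
        z[start:start + p] = R @ (lam[start:start + p] + u) + L_R @ eps
        start += p

    maf = simulate_maf(config)
    rng_al = np.random.default_rng([config.seed, 33])
    flip = rng_al.random(config.n_snps) < 0.5
    eaf = np.where(flip, 1.0 - maf, maf)
    alleles = np.array(["A", "C", "G", "T"])
    a1 = alleles[rng_al.integers(0, 4, config.n_snps)]
    shift = rng_al.integers(1, 4, config.n_snps)
    a2 = alleles[(np.searchsorted(alleles, a1) + shift) % 4]

    from scipy import stats as sps
    tables = {}
    for i, d in enumerate(diseases):
        n_case, n_ctrl = config.sample_sizes[i]
        n_eff = 4.0 / (1.0 / n_case + 1.0 / n_ctrl)
        f = np.clip(eaf, 1e-8, 1 - 1e-8)
        se = 1.0 / np.sqrt(2.0 * f * (1.0 - f) * n_eff)
        zi = z[:, i]
        pval = 2.0 * sps.norm.sf(np.abs(zi))
        pval = np.clip(pval, np.finfo(float).tiny, 1.0)
        tables[d] = pd.DataFrame({
            "snp_id": layout["snp_id"],
            "chrom": layout["chrom"],
            "pos": layout["pos"],
            "allele1": a1,
            "allele2": a2,
            "eaf": eaf,
            "beta": zi * se,
            "se": se,
            "z": zi,
            "p": pval,
            "n_case": n_case,
            "n_ctrl": n_ctrl,
        })

    null_pairs = {}
    for i, a in enumerate(diseases):
        for b in diseases[i + 1:]:
            shared = any({a, b} <= set(ds) for ds in truth_map.values())
            null_pairs[(a, b)] = not shared
    return tables, GroundTruth(truth_map, null_pairs)


# ---------------------------------------------------------------------------
# annotation side-tables


def simulate_consequences(config: SimConfig) -> pd.DataFrame:
    """VEP-like consequence table for SNPs located inside genes.

    Columns: snp_id, gene_id, consequence in {stop_gained, missense,
    synonymous, other}.
    """
    rng = np.random.default_rng([config.seed, 44])
    layout = snp_layout(config)
    genes = simulate_annotation(config)
    cats = np.array(["stop_gained", "missense", "synonymous", "other"])
    probs = np.array([0.02, 0.15, 0.15, 0.68])
    rows = []
    for g in genes.itertuples(index=False):
        mask = ((layout["chrom"] == g.chrom) & (layout["pos"] >= g.tx_start)
                & (layout["pos"] <= g.tx_end))
        for snp in layout.loc[mask, "snp_id"]:
            rows.append((snp, g.gene_id, rng.choice(cats, p=probs)))
    return pd.DataFrame(rows, columns=["snp_id", "gene_id", "consequence"])


def simulate_evidence(config: SimConfig) -> pd.DataFrame:
    """Open-Targets-like gene-disease evidence scores in [0, 1].

    Planted gene-disease pairs receive strong scores; a random sprinkling of
    other pairs receives weak scores; everything else is absent (treated as
    score 0 by consumers).
    """
    rng = np.random.default_rng([config.seed, 55])
    genes = simulate_annotation(config)
    planted = {(pg.gene_id, d) for pg in config.planted_genes
               for d in pg.diseases}
    rows = []
    for g in genes["gene_id"]:
        for d in config.disease_ids:
            if (g, d) in planted:
                rows.append((g, d, round(rng.uniform(0.5, 0.95), 3)))
            elif rng.random() < 0.3:
                rows.append((g, d, round(rng.uniform(0.0, 0.25), 3)))
    return pd.DataFrame(rows, columns=["gene_id", "disease_id", "score"])


def simulate_gene_sets(config: SimConfig) -> dict[str, list[str]]:
    """GMT-style gene sets; one set is enriched for the planted genes."""
    rng = np.random.default_rng([config.seed, 66])
    genes = list(simulate_annotation(config)["gene_id"])
    planted = [pg.gene_id for pg in config.planted_genes]
    others = [g for g in genes if g not in planted]
    n_extra = min(4, len(others))
    sets = {"shared_etiology_pathway":
            sorted(planted + list(rng.choice(others, n_extra,
                                             replace=False)))}
    size = min(8, len(genes))
    for i in range(4):
        sets[f"random_set_{i + 1}"] = sorted(
            rng.choice(genes, size, replace=False))
    return sets


def disease_metadata(config: SimConfig) -> pd.DataFrame:
    """Disease metadata: id, name, nosological category, case counts."""
    categories = ["circulatory system", "endocrine/metabolic", "digestive",
                  "respiratory"]
    rows = []
    for i, d in enumerate(config.disease_ids):
        n_case, n_ctrl = config.sample_sizes[i]
        rows.append((d, f"synthetic disease {i + 1}",
                     categories[min(i // 2, len(categories) - 1)]
                     if i < 4 else categories[2 + (i % 2)],
                     n_case, n_case + n_ctrl))
    return pd.DataFrame(rows, columns=["disease_id", "name", "category",
                                       "n_case", "n_total"])


def write_fixture_bundle(config: SimConfig, outdir: str | Path) -> Path:
    """Write the full input bundle (all external formats) to ``outdir``.

    Deterministic given the config seed; file contents round-trip through the
    readers in :mod:`pleioscan.io` bit-identically.
    """
    from . import io as pio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ld = simulate_ld(config)
    tables, truth = simulate_sumstats(config, ld)
    for d, tab in tables.items():
        pio.write_sumstats(tab, outdir / f"sumstats_{d}.tsv")
    pio.write_ld_blocks(ld, outdir / "ld_blocks")
    pio.write_ld_scores(ld.ld_score_table(), outdir / "ldscores.tsv")
    pio.write_annotation(simulate_annotation(config), outdir / "genes.tsv")
    pio.write_consequences(simulate_consequences(config),
                           outdir / "consequences.tsv")
    pio.write_evidence(simulate_evidence(config), outdir / "evidence.tsv")
    pio.write_gmt(simulate_gene_sets(config), outdir / "genesets.gmt")
    pio.write_disease_metadata(disease_metadata(config),
                               outdir / "diseases.tsv")
    truth_rows = [(g, ",".join(sorted(ds)))
                  for g, ds in sorted(truth.causal_gene_to_diseases.items())]
    pd.DataFrame(truth_rows, columns=["GENE_ID", "DISEASES"]).to_csv(
        outdir / "ground_truth.tsv", sep="\t", index=False)
    return outdir
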