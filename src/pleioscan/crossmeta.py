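"""Subset-based cross-trait meta-analysis and locus definition.

For every SNP, traits passing a lenient single-trait pre-filter (p < 0.1)
enter an exhaustive search over nonempty trait subsets S for the largest
standardized combined statistic

    Z(S) = | sum_{k in S} s_k w_k z_k | / sqrt( sum_{k in S} w_k^2 ),

with per-trait signs s_k free so that traits with opposite effect directions
can join one subset (the two-sided subset search); the optimum therefore
takes s_k = sign(z_k) and searches over which traits to include.  Weights
default to sqrt of the effective sample size.  The multiplicity of the
subset search is absorbed into the p-value by Monte Carlo: the null
distribution of the max-over-subsets statistic (including the pre-filter
step) is sampled once per trait panel with common random numbers, and the
extreme tail beyond Monte-Carlo resolution is extended with an
effective-number-of-tests normal tail matched to the empirical upper
quantiles.  Null trait correlation (sample overlap) is configurable.

Downstream, genome-wide significant meta SNPs are grouped into clumps with
PLINK-1.9 greedy semantics, clumps are merged into independent loci with a
500-kb window and a deterministic index-selection cascade, and each locus is
assigned the gene containing its index SNP or the nearest gene within the
locus bounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import LDCollection

GENOME_WIDE_P = 5e-8


# ---------------------------------------------------------------------------
# subset meta-analysis


@dataclass
class MetaResult:
    """Subset meta-analysis outcome for one SNP."""

    snp_id: str
    p_meta: float
    best_subset: frozenset
    subset_z: float
    n_sig_traits: int


def _best_subset(az: np.ndarray, w: np.ndarray) -> tuple[float, int]:
    """Maximize sum(w * |z|) / sqrt(sum w^2) over nonempty subsets.

    Returns (best statistic, bitmask of the best subset).  Ties go to the
    smallest bitmask (deterministic).
    """
    k = len(az)
    best_val, best_mask = -1.0, 0
    for mask in range(1, 1 << k):
        idx = [i for i in range(k) if mask >> i & 1]
        num = float(np.sum(w[idx] * az[idx]))
        stat = num / math.sqrt(float(np.sum(w[idx] ** 2)))
        if stat > best_val + 1e-12:
            best_val, best_mask = stat, mask
    return best_val, best_mask


class SubsetMeta:
    """Subset meta-analysis engine for a fixed trait panel.

    Parameters
    ----------
    traits
        Ordered trait ids of the panel.
    weights
        Per-trait meta weights (default: all equal); conventionally
        proportional to sqrt(effective sample size).
    prefilter_p
        Single-trait two-sided p-value below which a trait enters the
        subset search (0.1).
    max_traits
        Cap on retained traits; when exceeded, the smallest-p traits are
        kept.  Keeps the exhaustive search tractable, standing in for the
        trait-partitioning device of the fast subset-search literature.
    trait_corr
        Null correlation of z across traits (sample overlap); identity
        assumes independent cohorts.
    n_null
        Monte-Carlo draws for the max-statistic null.
    seed
        Seed for the common-random-number null sample.
    """

    def __init__(self, traits: list[str], weights: dict[str, float] | None
                 = None, prefilter_p: float = 0.1, max_traits: int = 10,
                 trait_corr: np.ndarray | None = None, n_null: int = 200_000,
                 seed: int = 0):
        self.traits = list(traits)
        D = len(self.traits)
        if weights is None:
            self.w = np.ones(D)
        else:
            self.w = np.array([weights[t] for t in self.traits], dtype=float)
        self.prefilter_p = prefilter_p
        self.max_traits = max_traits
        if trait_corr is None:
            trait_corr = np.eye(D)
        self.trait_corr = np.asarray(trait_corr, dtype=float)
        if self.trait_corr.shape != (D, D):
            raise ValueError("trait_corr must match the trait panel")
        self.n_null = n_null
        self.seed = seed
        self._zcrit = stats.norm.isf(prefilter_p / 2.0)
        self._null_sorted: np.ndarray | None = None
        self._tail_t0 = None
        self._tail_meff = None

    # -- observed statistic ------------------------------------------------

    def _retained(self, z: np.ndarray) -> np.ndarray:
        idx = np.flatnonzero(np.abs(z) >= self._zcrit)
        if len(idx) > self.max_traits:
            order = np.argsort(-np.abs(z[idx]), kind="stable")
            idx = np.sort(idx[order[:self.max_traits]])
        return idx

    def max_statistic(self, z: np.ndarray) -> tuple[float, tuple[int, ...]]:
        """Max-over-subsets statistic and the selected trait indices."""
        idx = self._retained(z)
        if len(idx) == 0:
            return 0.0, ()
        az = np.abs(z[idx])
        stat, mask = _best_subset(az, self.w[idx])
        chosen = tuple(idx[i] for i in range(len(idx)) if mask >> i & 1)
        return stat, chosen

    # -- null distribution -------------------------------------------------

    def _null_sample(self) -> np.ndarray:
        if self._null_sorted is not None:
            return self._null_sorted
        rng = np.random.default_rng([self.seed, 77])
        D = len(self.traits)
        L = np.linalg.cholesky(self.trait_corr + 1e-10 * np.eye(D))
        z = rng.standard_normal((self.n_null, D)) @ L.T
        az = np.abs(z)
        stat = np.zeros(self.n_null)
        pass_mask = az >= self._zcrit
        k = pass_mask.sum(axis=1)
        # k == 1: statistic is that trait's |z| (any single-trait subset)
        one = np.flatnonzero(k == 1)
        stat[one] = (az[one] * pass_mask[one]).max(axis=1)
        for i in np.flatnonzero(k >= 2):
            idx = np.flatnonzero(pass_mask[i])
            if len(idx) > self.max_traits:
                order = np.argsort(-az[i, idx], kind="stable")
                idx = np.sort(idx[order[:self.max_traits]])
            stat[i], _ = _best_subset(az[i, idx], self.w[idx])
        # condition on the pre-filter: the null for analyzed SNPs is the
        # max statistic given >= 1 surviving trait, which makes null p_meta
        # uniform among SNPs that return a result
        positive = np.sort(stat[stat > 0.0])
        if len(positive) < 100:
            positive = np.sort(stat)
        self._null_sorted = positive
        # parametric tail calibration at the empirical k0/n quantile
        k0 = min(100, max(10, len(positive) // 2000))
        t0 = positive[-k0]
        p0 = k0 / len(positive)
        self._tail_t0 = t0
        self._tail_meff = p0 / (2.0 * stats.norm.sf(t0))
        return self._null_sorted

    def pvalue(self, observed_stat: float) -> float:
        """P(max-over-subsets null statistic >= observed).

        Monte-Carlo estimate with the add-one correction; beyond the
        Monte-Carlo tail the p-value follows the matched
        effective-number-of-tests normal tail m_eff * 2 * Phi(-t).
        """
        null = self._null_sample()
        n_ge = len(null) - np.searchsorted(null, observed_stat, side="left")
        if observed_stat > self._tail_t0 and n_ge < 10:
            return float(min(1.0, self._tail_meff
                             * 2.0 * stats.norm.sf(observed_stat)))
        return float((1 + n_ge) / (len(null) + 1))

    # -- public per-SNP API ------------------------------------------------

    def subset_meta(self, z_by_trait: dict[str, float],
                    sig_p: float = GENOME_WIDE_P) -> MetaResult | None:
        """Run the subset search for one SNP; None when no trait passes the
        pre-filter."""
        z = np.array([z_by_trait[t] for t in self.traits], dtype=float)
        stat, chosen = self.max_statistic(z)
        if not chosen:
            return None
        p_meta = self.pvalue(stat)
        subset = frozenset(self.traits[i] for i in chosen)
        zcrit_sig = stats.norm.isf(sig_p / 2.0)
        n_sig = int(sum(abs(z[i]) > zcrit_sig for i in chosen))
        return MetaResult("", p_meta, subset, stat, n_sig)


def estimate_trait_corr(stats_by_disease: dict[str, pd.DataFrame],
                        z_max: float = 2.0) -> np.ndarray:
    """Null z-score correlation across traits from sub-significant SNPs.

    The empirical correlation of z restricted to SNPs with |z| < z_max in
    every trait approximates the null (overlap plus polygenic) correlation
    used by the subset-search null sampler.
    """
    traits = list(stats_by_disease)
    zs = pd.DataFrame({t: stats_by_disease[t].set_index("snp_id")["z"]
                       for t in traits}).dropna()
    mask = (zs.abs() < z_max).all(axis=1)
    C = np.corrcoef(zs[mask].to_numpy().T)
    C = np.atleast_2d(C)
    np.fill_diagonal(C, 1.0)
    return C


#: Median of the 1-df chi-square distribution (genomic-control reference).
_CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, df=1))


def run_meta(stats_by_disease: dict[str, pd.DataFrame],
             engine: SubsetMeta | None = None,
             weights: dict[str, float] | None = None,
             trait_corr: np.ndarray | None = None,
             gc_correct: bool = True,
             seed: int = 0) -> pd.DataFrame:
    """Subset meta-analysis of every SNP across the disease panel.

    With ``gc_correct`` (default), each trait's z-scores are divided by the
    square root of its genomic-control lambda (median z^2 over the 1-df
    chi-square median, floored at 1) before the subset search.  Polygenic
    signal inflates the marginal null variance of z, and the subset-search
    null assumes unit variance; the correction restores tail calibration
    at the cost of slightly shrinking true signals.

    Returns a DataFrame with columns snp_id, chrom, pos, p_meta, subset
    (comma-joined), subset_z, n_sig_traits for SNPs where at least one trait
    passed the pre-filter.
    """
    traits = list(stats_by_disease)
    if engine is None:
        if weights is None:
            first = {t: tab.iloc[0] for t, tab in stats_by_disease.items()}
            weights = {t: math.sqrt(4.0 / (1.0 / first[t]["n_case"]
                                           + 1.0 / first[t]["n_ctrl"]))
                       for t in traits}
        engine = SubsetMeta(traits, weights, trait_corr=trait_corr, seed=seed)
    zmat = pd.DataFrame({t: stats_by_disease[t].set_index("snp_id")["z"]
                         for t in traits})
    if gc_correct:
        lam_gc = (zmat**2).median() / _CHI2_1_MEDIAN
        zmat = zmat / np.sqrt(np.maximum(lam_gc, 1.0))
    layout = stats_by_disease[traits[0]][["snp_id", "chrom", "pos"]]
    rows = []
    for snp, chrom, pos in layout.itertuples(index=False):
        z = zmat.loc[snp]
        res = engine.subset_meta(dict(z))
        if res is None:
            continue
        rows.append((snp, chrom, pos, res.p_meta,
                     ",".join(sorted(res.best_subset)), res.subset_z,
                     res.n_sig_traits))
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "p_meta",
                                       "subset", "subset_z", "n_sig_traits"])


# ---------------------------------------------------------------------------
# clumping


def clump(meta: pd.DataFrame, ld: LDCollection, p1: float = 5e-8,
          p2: float = 1e-5, r2: float = 0.1, kb: int = 1000) -> pd.DataFrame:
    """Greedy PLINK-1.9 clumping of meta-analysis results.

    Index candidates are SNPs with p_meta < p1, processed in ascending
    p order; each still-unassigned SNP with p_meta < p2, within ``kb``
    kilobases of the index on the same chromosome, and with LD r^2 >= ``r2``
    joins the index's clump.  Assigned SNPs can neither seed nor join later
    clumps.

    Returns a DataFrame with one row per clump: index_snp, chrom, pos,
    p_meta, members (comma-joined, including the index).
    """
    tab = meta.sort_values(["p_meta", "chrom", "pos"],
                           kind="stable").reset_index(drop=True)
    assigned: set[str] = set()
    window = kb * 1000
    cand = tab[tab["p_meta"] < p1]
    joinable = tab[tab["p_meta"] < p2]
    out = []
    for row in cand.itertuples(index=False):
        if row.snp_id in assigned:
            continue
        near = joinable[(joinable["chrom"] == row.chrom)
                        & ((joinable["pos"] - row.pos).abs() <= window)
                        & (~joinable["snp_id"].isin(assigned))
                        & (joinable["snp_id"] != row.snp_id)]
        members = [row.snp_id]
        for other in near.itertuples(index=False):
            if ld.r2(row.snp_id, other.snp_id) >= r2:
                members.append(other.snp_id)
        assigned.update(members)
        out.append((row.snp_id, row.chrom, row.pos, row.p_meta,
                    ",".join(members)))
    return pd.DataFrame(out, columns=["index_snp", "chrom", "pos", "p_meta",
                                      "members"])


# ---------------------------------------------------------------------------
# locus merging


@dataclass
class Locus:
    """An independent locus: its index SNP and the merged region."""

    index_snp: str
    chrom: int
    pos: int                 # index SNP position
    start: int
    end: int
    p_meta: float
    gene_id: str | None      # gene containing the index SNP, if any
    n_traits: int
    member_snps: list[str] = field(default_factory=list)
    trait_set: frozenset = frozenset()
    assigned_gene: str | None = None

    @property
    def in_gene(self) -> bool:
        return self.gene_id is not None


def containing_gene(chrom: int, pos: int,
                    annotation: pd.DataFrame) -> str | None:
    """Gene whose transcription bounds (1-based inclusive) cover a position.

    If several genes overlap, the one with the smallest span wins, then the
    lexicographically smallest id.
    """
    hit = annotation[(annotation["chrom"] == chrom)
                     & (annotation["tx_start"] <= pos)
                     & (annotation["tx_end"] >= pos)]
    if hit.empty:
        return None
    hit = hit.assign(span=hit["tx_end"] - hit["tx_start"])
    hit = hit.sort_values(["span", "gene_id"], kind="stable")
    return str(hit.iloc[0]["gene_id"])


def _pick_index(a: Locus, b: Locus) -> Locus:
    """Index-selection cascade when two loci merge."""
    lo, hi = (a, b) if a.p_meta <= b.p_meta else (b, a)
    if a.gene_id is not None and a.gene_id == b.gene_id:
        return lo                                     # same gene: smallest p
    ratio = hi.p_meta / max(lo.p_meta, 5e-324)
    if ratio >= 10.0:
        return lo                                     # order-of-magnitude gap
    if a.in_gene != b.in_gene:
        return a if a.in_gene else b                  # prefer the genic SNP
    if a.n_traits != b.n_traits:
        return a if a.n_traits > b.n_traits else b    # more traits
    if a.p_meta != b.p_meta:
        return lo
    return a if a.pos <= b.pos else b


def merge_loci(loci: list[Locus], window: int = 500_000) -> list[Locus]:
    """Merge index SNPs closer than ``window`` bp into single loci.

    Scans index SNPs in position order and merges the leftmost adjacent pair
    within the window, repeating to a fixpoint, so chained merges are
    deterministic.  The merged locus unions members, trait sets and region
    bounds; its index SNP follows the cascade: same gene -> smaller p;
    p-values an order of magnitude apart (ratio >= 10) -> smaller p;
    otherwise prefer the genic SNP, then the larger trait count, then the
    smaller p, then the smaller position.
    """
    current = sorted(loci, key=lambda L: (L.chrom, L.pos, L.index_snp))
    changed = True
    while changed:
        changed = False
        for i in range(len(current) - 1):
            a, b = current[i], current[i + 1]
            if a.chrom == b.chrom and abs(b.pos - a.pos) <= window:
                idx = _pick_index(a, b)
                merged = Locus(
                    index_snp=idx.index_snp, chrom=a.chrom, pos=idx.pos,
                    start=min(a.start, b.start), end=max(a.end, b.end),
                    p_meta=idx.p_meta, gene_id=idx.gene_id,
                    n_traits=idx.n_traits,
                    member_snps=sorted(set(a.member_snps) | set(b.member_snps)),
                    trait_set=a.trait_set | b.trait_set,
                )
                current = current[:i] + [merged] + current[i + 2:]
                current.sort(key=lambda L: (L.chrom, L.pos, L.index_snp))
                changed = True
                break
    return current


def assign_gene(locus: Locus, annotation: pd.DataFrame) -> str | None:
    """Gene for a locus: the gene containing the index SNP, else the nearest
    gene overlapping the locus bounds, else None (locus kept without gene)."""
    inside = containing_gene(locus.chrom, locus.pos, annotation)
    if inside is not None:
        return inside
    cand = annotation[(annotation["chrom"] == locus.chrom)
                      & (annotation["tx_end"] >= locus.start)
                      & (annotation["tx_start"] <= locus.end)]
    if cand.empty:
        return None
    dist = np.where(
        cand["tx_end"] < locus.pos, locus.pos - cand["tx_end"],
        np.where(cand["tx_start"] > locus.pos,
                 cand["tx_start"] - locus.pos, 0))
    cand = cand.assign(dist=dist).sort_values(["dist", "gene_id"],
                                              kind="stable")
    return str(cand.iloc[0]["gene_id"])


def build_loci(clumps: pd.DataFrame, meta: pd.DataFrame,
               annotation: pd.DataFrame,
               sig_p: float = GENOME_WIDE_P) -> list[Locus]:
    """Turn clump rows into Locus objects with bounds and trait sets.

    Locus bounds are the min/max positions of member SNPs; the trait set is
    the union of best subsets over member SNPs with p_meta below ``sig_p``.
    """
    pos_of = dict(zip(meta["snp_id"], meta["pos"]))
    meta_idx = meta.set_index("snp_id")
    loci = []
    for row in clumps.itertuples(index=False):
        members = row.members.split(",")
        positions = [pos_of[s] for s in members]
        traits: set[str] = set()
        nt = 0
        for s in members:
            m = meta_idx.loc[s]
            if m["p_meta"] < sig_p and m["subset"]:
                traits.update(m["subset"].split(","))
            if s == row.index_snp:
                nt = int(m["n_sig_traits"])
        loci.append(Locus(
            index_snp=row.index_snp, chrom=int(row.chrom), pos=int(row.pos),
            start=int(min(positions)), end=int(max(positions)),
            p_meta=float(row.p_meta),
            gene_id=containing_gene(int(row.chrom), int(row.pos), annotation),
            n_traits=nt, member_snps=sorted(members),
            trait_set=frozenset(traits),
        ))
    return loci


def locus_gene_map(loci: list[Locus], annotation: pd.DataFrame,
                   min_diseases: int = 2) -> dict[str, frozenset]:
    """Gene -> disease-set map from final loci (pleiotropic loci only).

    Assigns each locus its gene, keeps loci whose trait set names at least
    ``min_diseases`` diseases, and unions trait sets per gene.
    """
    out: dict[str, set] = {}
    for locus in loci:
        locus.assigned_gene = assign_gene(locus, annotation)
        if locus.assigned_gene is None:
            continue
        if len(locus.trait_set) >= min_diseases:
            out.setdefault(locus.assigned_gene, set()).update(locus.trait_set)
    return {g: frozenset(d) for g, d in sorted(out.items())}
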