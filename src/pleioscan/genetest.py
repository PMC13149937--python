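"""Gene-based association tests from GWAS summary statistics.

Implements the summary-statistic forms of three classic gene tests and the
pleiotropy selection logic built on them:

* :func:`skato_test` — the optimal unified variance-component/burden test
  (SKAT-O) over a grid of mixing parameters rho, with the min-p omnibus
  correction computed by one-dimensional integration over the shared burden
  direction;
* :func:`pca_test` — chi-square test on the leading principal components of
  the gene's LD matrix that explain a required share of variance;
* :func:`acat_combine` — the Cauchy combination of p-values;
* :func:`run_gene_scan` — the per-disease scan over protein-coding genes,
  :func:`find_pleiotropic_genes` and :func:`filter_ld_gene_clusters` — the
  downstream selection of genes associated with two or more diseases and the
  external-evidence filter for LD-driven gene clusters.

The null model throughout is z ~ N(0, R) for the vector of single-SNP
z-scores of a gene, with R the local LD (genotype correlation) matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._quadform import chi2_mixture_sf, liu_params, liu_quantile
from .containers import LDCollection

logger = logging.getLogger(__name__)

#: Default rho grid for SKAT-O (the standard 8-point grid).
DEFAULT_RHO_GRID = (0.0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1.0)

#: Genome-wide gene-based significance threshold: Bonferroni correction of
#: alpha = 0.05 for ~20,000 protein-coding genes.
GENE_TEST_ALPHA = 0.05
GENE_TEST_N_GENES = 20_000


def gene_test_threshold(alpha: float = GENE_TEST_ALPHA,
                        n_genes: int = GENE_TEST_N_GENES) -> float:
    """Bonferroni gene-based significance threshold (0.05 / 20,000 = 2.5e-6)."""
    return alpha / n_genes


@dataclass(frozen=True)
class WeightSpec:
    """Beta-density MAF weights w_j = Beta(maf_j; a, b).

    The flat default (a=1, b=1) weights every SNP equally.
    """

    a: float = 1.0
    b: float = 1.0

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ValueError("beta weight shape parameters must be positive")

    def weights(self, maf: np.ndarray) -> np.ndarray:
        return stats.beta.pdf(np.asarray(maf, dtype=float), self.a, self.b)


class SingularLDError(ValueError):
    """LD matrix not usable even after diagonal regularization."""


def _regularize(R: np.ndarray, delta: float) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    R = 0.5 * (R + R.T)
    return R + delta * np.eye(R.shape[0])


class SkatO:
    """Precomputed SKAT-O machinery for one gene (fixed R, weights, grid).

    Splitting setup from evaluation lets a caller test the same gene against
    many z vectors (many diseases, or many null draws) at the cost of a single
    set of eigendecompositions.
    """

    def __init__(self, R: np.ndarray, w: np.ndarray,
                 rho_grid=DEFAULT_RHO_GRID, accuracy: float = 1e-9,
                 ridge: float = 1e-6):
        R = np.asarray(R, dtype=float)
        w = np.asarray(w, dtype=float)
        p = R.shape[0]
        if R.shape != (p, p) or w.shape != (p,):
            raise ValueError("dimension mismatch between R and weights")
        if not np.allclose(np.diag(R), 1.0, atol=1e-6):
            raise ValueError("LD matrix must have unit diagonal")
        self.p = p
        self.w = w
        self.rho_grid = tuple(float(r) for r in rho_grid)
        self.accuracy = accuracy

        Rr = _regularize(R, ridge)
        # Psi = cov of the weighted score vector s = W z under z ~ N(0, R)
        Psi = (w[:, None] * Rr) * w[None, :]
        evals, evecs = np.linalg.eigh(Psi)
        if evals[-1] <= 0:
            raise SingularLDError("LD matrix has no positive eigenvalue")
        cond = evals[-1] / max(evals[0], 1e-300)
        if evals[0] <= 0 or cond > 1e12:
            Rr = _regularize(R, 1e-4)
            Psi = (w[:, None] * Rr) * w[None, :]
            evals, evecs = np.linalg.eigh(Psi)
            cond = evals[-1] / max(evals[0], 1e-300)
            if evals[0] <= 0:
                raise SingularLDError(
                    f"LD matrix singular after regularization "
                    f"(condition number {cond:.3g})")
        # symmetric square root B = Psi^(1/2); Q_rho = u' B A_rho B u, u~N(0,I)
        B = (evecs * np.sqrt(np.clip(evals, 0, None))) @ evecs.T
        self._B = B

        # per-rho eigenvalues of the null mixture
        ones = np.ones(p)
        self._lam_rho = []
        for rho in self.rho_grid:
            A = (1.0 - rho) * np.eye(p) + rho * np.outer(ones, ones)
            M = B @ A @ B
            lam = np.linalg.eigvalsh(M)
            lam = lam[lam > 1e-10 * lam.max()]
            self._lam_rho.append(lam)

        # Decomposition along the burden direction for the omnibus null.
        # With v the unit vector along zb = B 1 and u = eta v + u_perp
        # (eta ~ N(0,1)), the statistics decompose exactly as
        #   Q_rho = (1-rho) (T + eta^2 r2) + rho m2 eta^2,
        # where m2 = 1'Psi 1, T | eta is the noncentral mixture
        # sum_i lam_i chi2_1(eta^2 a_i^2 / lam_i) with lam_i the eigenvalues
        # of B (I - v v') B, a the coordinates of B v in its eigenbasis, and
        # r2 the part of ||B v||^2 outside that eigenspace.  The min-p
        # crossing probability is then a one-dimensional integral over eta^2.
        zb = B @ np.ones(p)
        m2 = float(zb @ zb)
        self._m2 = m2
        v = zb / np.sqrt(m2) if m2 > 0 else np.zeros(p)
        W22 = B @ (np.eye(p) - np.outer(v, v)) @ B
        evals_t, evecs_t = np.linalg.eigh(W22)
        keep = evals_t > 1e-10 * max(evals_t.max(initial=0.0), 1.0)
        self._lam_T = evals_t[keep]
        b_vec = B @ v
        a = evecs_t[:, keep].T @ b_vec
        self._d0 = a**2 / self._lam_T if len(self._lam_T) else a[:0]
        self._r2 = max(float(b_vec @ b_vec) - float(a @ a), 0.0)
        self._rho_interps = None  # lazy per-rho survival interpolants
        self._q_negligible = None
        self._n_pvalue_calls = 0

    # -- per-rho machinery -------------------------------------------------

    def statistics(self, z: np.ndarray) -> np.ndarray:
        """Q_rho = (1-rho) * sum(w z)^2_j + rho * (sum w z)^2 for each rho."""
        s = self.w * np.asarray(z, dtype=float)
        q_skat = float(s @ s)
        q_burden = float(s.sum()) ** 2
        return np.array([(1.0 - r) * q_skat + r * q_burden
                         for r in self.rho_grid])

    def rho_pvalues(self, z: np.ndarray) -> np.ndarray:
        qs = self.statistics(z)
        return np.array([
            chi2_mixture_sf(q, lam, accuracy=self.accuracy)
            for q, lam in zip(qs, self._lam_rho)
        ])

    @staticmethod
    def _build_interp(lam: np.ndarray):
        """Log-survival interpolant of a central chi-square mixture.

        The bulk uses the moment approximation (accurate near sf ~ 1), the
        mid-range and tail use the inversion integral at increasing
        tolerances; beyond the grid the log survival is extended linearly.
        """
        from ._quadform import imhof_sf
        if len(lam) == 1:
            grid = np.linspace(1e-9, 90.0 * lam[0], 400)
            vals = stats.chi2.sf(grid / lam[0], df=1)
        else:
            q_hi = max(liu_quantile(1e-16, lam), 2.0 * lam.sum())
            grid = np.linspace(1e-9, q_hi, 400)
            cut_bulk = liu_quantile(0.95, lam)
            cut_tail = liu_quantile(1e-3, lam)
            vals = np.empty_like(grid)
            bulk = grid <= cut_bulk
            mid = (grid > cut_bulk) & (grid <= cut_tail)
            tail = grid > cut_tail
            pars = liu_params(lam)
            muX = pars["df"] + pars["ncp"]
            sigmaX = np.sqrt(2.0 * (pars["df"] + 2.0 * pars["ncp"]))

            def liu_vec(qq):
                qn = (qq - pars["muQ"]) / pars["sigmaQ"] * sigmaX + muX
                return stats.ncx2.sf(qn, pars["df"], pars["ncp"])

            if bulk.any():
                vals[bulk] = liu_vec(grid[bulk])
            if mid.any():
                vals[mid] = imhof_sf(grid[mid], lam, epsabs=1e-7)
            if tail.any():
                vals[tail] = imhof_sf(grid[tail], lam, epsabs=1e-11)
            bad = ~np.isfinite(vals) | (vals < 1e-13) | (vals > 1.0 + 1e-7)
            if bad.any():
                vals[bad] = liu_vec(grid[bad])
        logs = np.log(np.clip(vals, 1e-300, 1.0))
        slope = (logs[-1] - logs[-2]) / (grid[-1] - grid[-2])
        return grid, logs, slope

    def _rho_quantiles(self, pmin: float) -> np.ndarray:
        """Per-rho upper-tail quantiles of Q_rho at probability pmin.

        Inverted from the survival interpolants once they exist; one-shot
        callers use direct root-finding on the inversion integral instead,
        avoiding the interpolant construction cost.
        """
        if self._rho_interps is not None:
            log_p = np.log(max(pmin, 1e-300))
            out = np.empty(len(self.rho_grid))
            for i, (grid, logs, slope) in enumerate(self._rho_interps):
                if log_p < logs[-1]:
                    out[i] = grid[-1] + (log_p - logs[-1]) / slope
                else:
                    out[i] = np.interp(log_p, logs[::-1], grid[::-1])
            return out
        from scipy.optimize import brentq
        out = np.empty(len(self.rho_grid))
        for i, lam in enumerate(self._lam_rho):
            guess = liu_quantile(pmin, lam)
            lo, hi = 0.3 * guess, 3.0 * guess

            def f(q, lam=lam):
                return chi2_mixture_sf(q, lam, accuracy=1e-8) - pmin

            for _ in range(30):
                if f(lo) > 0 >= f(hi):
                    break
                lo *= 0.5
                hi *= 1.6
            out[i] = brentq(f, lo, hi, xtol=1e-8 * max(guess, 1.0))
        return out

    def _cross_prob(self, bounds: np.ndarray, xs: np.ndarray) -> np.ndarray:
        """P(T > bound | eta^2 = x): tail of the conditional noncentral
        chi-square mixture.  Nodes whose crossing probability is provably
        negligible are skipped."""
        from ._quadform import imhof_sf_noncentral
        lam = self._lam_T
        out = np.ones_like(bounds)
        if len(lam) == 0:
            return np.where(bounds > 0, 0.0, 1.0)
        if len(lam) == 1:
            pos = bounds > 0
            out[pos] = stats.ncx2.sf(bounds[pos] / lam[0], df=1,
                                     nc=xs[pos] * self._d0[0])
            return out
        if self._q_negligible is None:
            self._q_negligible = liu_quantile(1e-13, lam)
        shift = float((lam * self._d0).sum()) if len(self._d0) else 0.0
        pos = (bounds > 0) & (bounds <= self._q_negligible
                              + 4.0 * (1.0 + shift) * xs + 4.0 * shift)
        far = bounds > self._q_negligible + 4.0 * (1.0 + shift) * xs \
            + 4.0 * shift
        out[far] = 0.0
        if pos.any():
            from ._quadform import liu_sf_noncentral
            # the bulk (large crossing probability) is served by the moment
            # approximation; the tail, where relative accuracy matters, by
            # the inversion integral, which converges quickly there
            p_liu = liu_sf_noncentral(bounds[pos], lam, self._d0, xs[pos])
            vals = p_liu.copy()
            deep = p_liu <= 0.02
            if deep.any():
                idx = np.flatnonzero(pos)[deep]
                vals[deep] = imhof_sf_noncentral(bounds[idx], lam, self._d0,
                                                 xs[idx], epsabs=1e-9)
            out[pos] = np.clip(vals, 0.0, 1.0)
        return out

    # per-segment quadrature for the omnibus integral over the burden
    # chi2_1 variable, substituting x = y^2 to remove the density singularity
    _Y_NODES, _Y_WEIGHTS = np.polynomial.legendre.leggauss(24)

    def pvalue(self, z: np.ndarray) -> float:
        """SKAT-O omnibus p-value for one z vector.

        The min-p over the rho grid is corrected by integrating the exact
        conditional crossing probability over the shared burden component
        x = eta^2: for rho < 1 the boundary on the conditional mixture T is
        a lower envelope of straight lines in x (integrated piecewise
        between its kinks), while rho = 1 contributes a hard cutoff in x.
        """
        z = np.asarray(z, dtype=float)
        if z.shape != (self.p,):
            raise ValueError("z has wrong length")
        if self.p == 1:
            return max(float(stats.chi2.sf(z[0] ** 2, df=1)), 1e-300)
        if len(self.rho_grid) == 1:
            return float(self.rho_pvalues(z)[0])
        # interpolants pay off only for engines evaluated many times
        self._n_pvalue_calls += 1
        if self._rho_interps is None and self._n_pvalue_calls >= 7:
            self._rho_interps = [self._build_interp(lam)
                                 for lam in self._lam_rho]
        qs = self.statistics(z)
        if self._rho_interps is not None:
            p_interp = np.empty(len(qs))
            for i, (grid, logs, slope) in enumerate(self._rho_interps):
                if qs[i] > grid[-1]:
                    p_interp[i] = np.exp(logs[-1]
                                         + slope * (qs[i] - grid[-1]))
                else:
                    p_interp[i] = np.exp(np.interp(qs[i], grid, logs))
            amin = int(np.argmin(p_interp))
        else:
            amin = int(np.argmin(self.rho_pvalues(z)))
        # refine the leading p-value with the full inversion integral
        pmin = chi2_mixture_sf(qs[amin], self._lam_rho[amin],
                               accuracy=self.accuracy)
        if pmin >= 1.0:
            return 1.0
        if pmin < 1e-14:
            # far below the quadrature's resolution the integral equals the
            # Bonferroni bound over the grid to within its own error
            return float(max(pmin * len(self.rho_grid), 1e-300))
        q_rho = self._rho_quantiles(pmin)

        rhos = np.array(self.rho_grid)
        burden_like = rhos >= 0.999
        x_hi = 40.0
        if burden_like.any() and self._m2 > 0:
            x_hi = min(x_hi, float((q_rho[burden_like]
                                    / (rhos[burden_like] * self._m2)).min()))
        lines = ~burden_like
        if not lines.any():
            p_cut = float(stats.chi2.sf(x_hi, df=1))
            return float(min(max(p_cut, pmin, 1e-300),
                             pmin * len(self.rho_grid), 1.0))
        # bound(x) = min_rho [intercept_rho + slope_rho * x], piecewise linear
        slope = -(rhos[lines] * self._m2) / (1.0 - rhos[lines]) - self._r2
        intercept = q_rho[lines] / (1.0 - rhos[lines])

        # segment the integral at the kinks of the lower envelope of the
        # boundary lines (and at its zero crossing); the envelope of k lines
        # has at most k pieces, found by a sweep in slope order
        brk = {0.0, x_hi}
        order = np.argsort(slope)[::-1]  # steepest decrease last
        env = [order[0]]
        starts = [0.0]
        for idx in order[1:]:
            while env:
                top = env[-1]
                ds = slope[top] - slope[idx]
                if ds <= 0:
                    break
                xij = (intercept[idx] - intercept[top]) / ds
                if xij > starts[-1]:
                    if xij < x_hi:
                        env.append(idx)
                        starts.append(float(xij))
                        brk.add(float(xij))
                    break
                env.pop()
                starts.pop()
            if not env:
                env.append(idx)
                starts.append(0.0)
        for i in set(env):
            if slope[i] < 0:
                x0 = -intercept[i] / slope[i]
                if 0.0 < x0 < x_hi:
                    brk.add(float(x0))
        edges_y = np.sqrt(np.sort(np.fromiter(brk, dtype=float)))
        mid = 0.5 * (edges_y[1:] + edges_y[:-1])
        half = 0.5 * (edges_y[1:] - edges_y[:-1])
        y = (mid[:, None] + half[:, None] * self._Y_NODES[None, :]).ravel()
        wy = (half[:, None] * self._Y_WEIGHTS[None, :]).ravel()
        x = y**2
        bounds = (intercept[:, None] + slope[:, None] * x[None, :]).min(axis=0)
        cross = self._cross_prob(bounds, x)
        val = float(np.sum(cross * np.exp(-0.5 * x) * wy)) \
            * np.sqrt(2.0 / np.pi)
        pvalue = val + float(stats.chi2.sf(x_hi, df=1))
        # the omnibus p can never exceed the Bonferroni bound over the grid
        pvalue = min(pvalue, pmin * len(self.rho_grid))
        return float(min(max(pvalue, pmin, 1e-300), 1.0))


def skato_test(z: np.ndarray, R: np.ndarray, w: np.ndarray | None = None,
               rho_grid=DEFAULT_RHO_GRID, accuracy: float = 1e-9) -> float:
    """SKAT-O p-value for one gene from summary statistics.

    Parameters
    ----------
    z
        Single-SNP z-scores of the gene's SNPs.
    R
        LD (genotype correlation) matrix of the same SNPs, unit diagonal.
    w
        Per-SNP weights; defaults to equal weights.
    rho_grid
        Grid of variance-component/burden mixing parameters searched.
    """
    z = np.atleast_1d(np.asarray(z, dtype=float))
    if w is None:
        w = np.ones_like(z)
    return SkatO(np.atleast_2d(R), np.asarray(w, float), rho_grid,
                 accuracy).pvalue(z)


def pca_test(z: np.ndarray, R: np.ndarray, var_explained: float = 0.85) -> float:
    """Principal-component gene test.

    Projects the z vector onto the leading eigenvectors of R that jointly
    explain at least ``var_explained`` of the total variance and refers the
    sum of standardized squared projections to chi-square with k df.
    """
    z = np.atleast_1d(np.asarray(z, dtype=float))
    R = np.atleast_2d(np.asarray(R, dtype=float))
    evals, evecs = np.linalg.eigh(R)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = 1e-10 * max(evals[0], 1.0)
    if evals[0] <= tol:
        raise SingularLDError("all LD eigenvalues below tolerance")
    share = np.cumsum(evals) / evals.sum()
    k = int(np.searchsorted(share, var_explained) + 1)
    k = min(k, int(np.sum(evals > tol)))
    proj = evecs[:, :k].T @ z
    T = float(np.sum(proj**2 / evals[:k]))
    return max(float(stats.chi2.sf(T, df=k)), 1e-300)


def acat_combine(p_list, eps: float = 1e-15) -> float:
    """Cauchy combination (ACAT) of p-values with equal weights.

    T = mean_i tan((0.5 - p_i) * pi);  combined p = 0.5 - arctan(T) / pi.
    p-values of exactly 1 are clipped to 1 - eps to avoid an infinite tangent.
    """
    p = np.asarray(list(p_list), dtype=float)
    if p.size == 0:
        raise ValueError("acat_combine requires at least one p-value")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    p = np.minimum(p, 1.0 - eps)
    T = np.mean(np.tan((0.5 - p) * np.pi))
    out = 0.5 - np.arctan(T) / np.pi
    return float(min(max(out, 1e-300), 1.0))


# ---------------------------------------------------------------------------
# scan and selection


def gene_snp_map(genes: pd.DataFrame, stats_table: pd.DataFrame) -> dict:
    """SNPs per gene: tx_start <= pos <= tx_end on the gene's chromosome.

    Transcription bounds are 1-based inclusive; boundary SNPs belong to the
    gene.  Returns {gene_id: list of snp ids} in position order.
    """
    out = {}
    by_chrom = {c: g.sort_values("pos") for c, g in
                stats_table.groupby("chrom")}
    for row in genes.itertuples(index=False):
        tab = by_chrom.get(row.chrom)
        if tab is None:
            out[row.gene_id] = []
            continue
        mask = (tab["pos"] >= row.tx_start) & (tab["pos"] <= row.tx_end)
        out[row.gene_id] = list(tab.loc[mask, "snp_id"])
    return out


def run_gene_scan(stats_by_disease: dict, genes: pd.DataFrame,
                  ld: LDCollection, weights: WeightSpec = WeightSpec(1, 1),
                  var_explained: float = 0.85,
                  rho_grid=DEFAULT_RHO_GRID,
                  threshold: float | None = None,
                  accuracy: float = 1e-9) -> pd.DataFrame:
    """Per-disease gene-based scan over protein-coding genes with >= 2 SNPs.

    Parameters
    ----------
    stats_by_disease
        Mapping disease id -> QC-filtered summary-statistics table with
        columns snp_id, chrom, pos, eaf, z.
    genes
        Gene annotation with columns gene_id, symbol, chrom, tx_start,
        tx_end, coding.
    ld
        LD blocks covering the SNPs.
    threshold
        Significance threshold on the combined p (strict <); defaults to the
        Bonferroni 0.05/20,000 = 2.5e-6.

    Returns
    -------
    DataFrame with columns gene_id, disease_id, n_snps, p_skato, p_pca,
    p_combined, significant.
    """
    if threshold is None:
        threshold = gene_test_threshold()
    coding = genes[genes["coding"] == 1]
    records = []
    per_disease = {}
    for disease, tab in stats_by_disease.items():
        per_disease[disease] = {
            "snp_map": gene_snp_map(coding, tab),
            "z": dict(zip(tab["snp_id"], tab["z"])),
            "maf": dict(zip(tab["snp_id"],
                            np.minimum(tab["eaf"], 1 - tab["eaf"]))),
        }
    # iterate genes outermost so one SkatO decomposition serves every
    # disease that carries the same SNP set for the gene
    for gene_id in coding["gene_id"]:
        engines: dict[tuple, SkatO] = {}
        for disease, info in per_disease.items():
            snps = info["snp_map"].get(gene_id, [])
            if len(snps) < 2:
                continue
            key = tuple(snps)
            if key not in engines:
                try:
                    R = ld.submatrix(snps)
                except KeyError as exc:
                    logger.warning("gene %s skipped for %s: SNP missing "
                                   "from LD (%s)", gene_id, disease, exc)
                    engines[key] = None
                    continue
                maf = np.array([info["maf"][s] for s in snps])
                try:
                    engines[key] = SkatO(R, weights.weights(maf), rho_grid,
                                         accuracy)
                except SingularLDError as exc:
                    logger.warning("gene %s skipped for %s: %s", gene_id,
                                   disease, exc)
                    engines[key] = None
                    continue
                engines[key].R_matrix = R
            engine = engines[key]
            if engine is None:
                continue
            z = np.array([info["z"][s] for s in snps])
            p_sk = engine.pvalue(z)
            p_pc = pca_test(z, engine.R_matrix, var_explained)
            p_comb = acat_combine([p_sk, p_pc])
            records.append((gene_id, disease, len(snps), p_sk, p_pc, p_comb,
                            p_comb < threshold))
    return pd.DataFrame(records, columns=[
        "gene_id", "disease_id", "n_snps", "p_skato", "p_pca", "p_combined",
        "significant",
    ])


def find_pleiotropic_genes(scan: pd.DataFrame,
                           min_diseases: int = 2) -> dict[str, frozenset]:
    """Genes significant in at least ``min_diseases`` diseases.

    Accepts the scan table from :func:`run_gene_scan` and returns a
    gene -> frozenset-of-diseases map, ordered by gene id.
    """
    sig = scan[scan["significant"]]
    out = {}
    for gene_id, grp in sig.groupby("gene_id"):
        ds = frozenset(grp["disease_id"])
        if len(ds) >= min_diseases:
            out[gene_id] = ds
    return dict(sorted(out.items()))


def filter_ld_gene_clusters(pleio: dict, annotation: pd.DataFrame,
                            evidence: pd.DataFrame,
                            window: int = 500_000,
                            score_min: float = 0.3) -> dict[str, frozenset]:
    """External-evidence filter for LD-driven clusters of pleiotropic genes.

    Neighbouring genes (boundary-to-boundary gap <= ``window`` on one
    chromosome) with an identical set of associated diseases cannot be
    disentangled from LD alone.  Within each such cluster a member is dropped
    when its external gene-disease evidence score is below ``score_min`` for
    every disease shared by the whole cluster.  Genes forming singleton
    clusters pass unfiltered.  Missing evidence rows count as score 0.
    """
    ann = annotation.set_index("gene_id")
    escore = {(r.gene_id, r.disease_id): r.score
              for r in evidence.itertuples(index=False)}
    items = []
    for g, ds in pleio.items():
        row = ann.loc[g]
        items.append((int(row["chrom"]), int(row["tx_start"]),
                      int(row["tx_end"]), g, ds))
    items.sort()

    clusters: list[list] = []
    for it in items:
        if clusters:
            pc, _, pe, _, pds = clusters[-1][-1]
            gap = it[1] - pe
            if it[0] == pc and gap <= window and it[4] == pds:
                clusters[-1].append(it)
                continue
        clusters.append([it])

    kept = {}
    for cluster in clusters:
        if len(cluster) == 1:
            _, _, _, g, ds = cluster[0]
            kept[g] = ds
            continue
        shared = frozenset.intersection(*(c[4] for c in cluster))
        for _, _, _, g, ds in cluster:
            scores = [escore.get((g, d), 0.0) for d in shared]
            if shared and all(s < score_min for s in scores):
                continue
            kept[g] = ds
    return dict(sorted(kept.items()))
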