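"""Gene-based tests: SKAT-O, PCA, ACAT, and the scan/selection logic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pleioscan import genetest
from pleioscan.containers import LDBlock, LDCollection
from pleioscan.genetest import (SkatO, WeightSpec, acat_combine,
                                filter_ld_gene_clusters,
                                find_pleiotropic_genes, gene_test_threshold,
                                pca_test, skato_test)

from _oracles import weighted_chi2_pair_sf


def ar1(n, r):
    idx = np.arange(n)
    return r ** np.abs(np.subtract.outer(idx, idx))


class TestSkatO:
    def test_single_snp_zero_z_gives_one(self):
        assert skato_test(np.array([0.0]), np.array([[1.0]])) == 1.0

    def test_single_snp_reduces_to_chi2_1df(self):
        p = skato_test(np.array([1.959964]), np.array([[1.0]]))
        assert p == pytest.approx(0.05, rel=1e-5)

    def test_two_independent_snps_rho_zero_closed_form(self):
        # Q = z1^2 + z2^2 ~ chi2_2 so sf = exp(-Q/2)
        p = skato_test(np.array([1.0, 2.0]), np.eye(2), rho_grid=[0.0])
        assert p == pytest.approx(np.exp(-2.5), rel=1e-4)

    def test_weighted_identity_rho_zero_matches_convolution_oracle(self):
        z = np.array([1.5, 1.0])
        w = np.array([1.0, 2.0])
        p = skato_test(z, np.eye(2), w, rho_grid=[0.0])
        q = float(np.sum(w**2 * z**2))
        assert p == pytest.approx(weighted_chi2_pair_sf(q, 1.0, 4.0),
                                  rel=1e-3)

    def test_burden_rho_one_is_scaled_chi2(self):
        z = np.array([1.0, 2.0, 0.5])
        R = ar1(3, 0.4)
        p = skato_test(z, R, rho_grid=[1.0])
        q = float(z.sum()) ** 2
        scale = float(np.ones(3) @ (R + 1e-6 * np.eye(3)) @ np.ones(3))
        assert p == pytest.approx(stats.chi2.sf(q / scale, df=1), rel=1e-6)

    def test_sign_flip_invariance(self):
        z = np.array([1.2, -0.7, 2.1, 0.0, -1.5])
        R = ar1(5, 0.6)
        assert skato_test(z, R) == pytest.approx(skato_test(-z, R), rel=1e-9)

    def test_omnibus_p_between_min_p_and_bonferroni(self):
        rng = np.random.default_rng(11)
        R = ar1(6, 0.5)
        eng = SkatO(R, np.ones(6))
        L = np.linalg.cholesky(R)
        for _ in range(20):
            z = L @ rng.standard_normal(6)
            p_rho = eng.rho_pvalues(z)
            p = eng.pvalue(z)
            assert p_rho.min() <= p <= min(1.0,
                                           p_rho.min() * len(eng.rho_grid)
                                           + 1e-12)

    def test_null_calibration_moderate(self):
        rng = np.random.default_rng(5)
        R = ar1(5, 0.6)
        eng = SkatO(R, np.ones(5))
        L = np.linalg.cholesky(R)
        ps = np.array([eng.pvalue(L @ rng.standard_normal(5))
                       for _ in range(800)])
        lo, hi = stats.binom.interval(0.999, 800, 0.05)
        assert lo <= (ps < 0.05).sum() <= hi


class TestPcaTest:
    def test_zero_z_gives_one(self):
        assert pca_test(np.zeros(3), ar1(3, 0.5)) == 1.0

    def test_high_ld_pair_uses_single_component(self):
        # eigenvalues (1.9, 0.1): first share 0.95 >= 0.85 so k = 1
        R = np.array([[1.0, 0.9], [0.9, 1.0]])
        z = np.array([1.0, 2.0])
        evals, evecs = np.linalg.eigh(R)
        v1 = evecs[:, -1]
        T = (v1 @ z) ** 2 / evals[-1]
        assert pca_test(z, R, 0.85) == pytest.approx(stats.chi2.sf(T, 1),
                                                     rel=1e-10)

    def test_cumulative_share_rule_takes_two_components(self):
        # eigenvalues (1.6, 0.4): first share 0.8 < 0.85 <= 1.0 so k = 2 and
        # the statistic is the full Mahalanobis form z' R^-1 z
        R = np.array([[1.0, 0.6], [0.6, 1.0]])
        z = np.array([0.5, 1.5])
        T = float(z @ np.linalg.solve(R, z))
        assert pca_test(z, R, 0.85) == pytest.approx(stats.chi2.sf(T, 2),
                                                     rel=1e-10)

    def test_sign_flip_invariance(self):
        z = np.array([0.3, -1.0, 2.0])
        R = ar1(3, 0.7)
        assert pca_test(z, R) == pytest.approx(pca_test(-z, R), rel=1e-12)


class TestAcat:
    def test_all_half_gives_half(self):
        assert acat_combine([0.5, 0.5, 0.5]) == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize("p", [0.001, 0.2, 0.97])
    def test_single_p_is_identity(self, p):
        assert acat_combine([p]) == pytest.approx(p, rel=1e-10)

    def test_two_value_case_matches_high_precision_oracle(self):
        # sympy evaluation of the Cauchy-combination formula at 30 digits
        assert acat_combine([0.01, 0.04]) == pytest.approx(
            0.0160075928259523899428392847371, rel=1e-10)

    def test_p_equal_one_clipped_not_infinite(self):
        assert 0.0 < acat_combine([1.0, 0.5]) <= 1.0

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            acat_combine([])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(1e-8, 1.0 - 1e-8), min_size=1, max_size=8),
           st.randoms(use_true_random=False))
    def test_permutation_invariant_and_in_unit_interval(self, ps, rnd):
        shuffled = list(ps)
        rnd.shuffle(shuffled)
        a, b = acat_combine(ps), acat_combine(shuffled)
        assert a == pytest.approx(b, rel=1e-9)
        assert 0.0 < a < 1.0


def _scan_inputs(z_by_disease, n_snps=4, decay=0.5):
    """Small single-gene scan setup: one block, gene covering SNPs 1..n-2."""
    R = ar1(n_snps, decay)
    snps = [f"rs{i}" for i in range(n_snps)]
    ld = LDCollection([LDBlock(snps, R, chrom=1)])
    genes = pd.DataFrame([("G1", "S1", 1, 100, 100 * n_snps, 1)],
                         columns=["gene_id", "symbol", "chrom", "tx_start",
                                  "tx_end", "coding"])
    stats_by = {}
    for d, z in z_by_disease.items():
        stats_by[d] = pd.DataFrame({
            "snp_id": snps, "chrom": 1,
            "pos": [100 * (i + 1) for i in range(n_snps)],
            "eaf": 0.3, "z": z,
        })
    return stats_by, genes, ld


class TestGeneScan:
    def test_gene_with_one_snp_absent_from_results(self):
        stats_by, genes, ld = _scan_inputs({"D1": np.zeros(4)})
        genes.loc[0, "tx_start"] = 400
        genes.loc[0, "tx_end"] = 400
        scan = genetest.run_gene_scan(stats_by, genes, ld)
        assert scan.empty

    def test_noncoding_gene_excluded(self):
        stats_by, genes, ld = _scan_inputs({"D1": np.zeros(4)})
        genes.loc[0, "coding"] = 0
        assert genetest.run_gene_scan(stats_by, genes, ld).empty

    def test_combined_p_is_acat_of_skato_and_pca(self):
        z = np.array([2.0, 1.0, -0.5, 1.5])
        stats_by, genes, ld = _scan_inputs({"D1": z})
        scan = genetest.run_gene_scan(stats_by, genes, ld)
        assert len(scan) == 1
        row = scan.iloc[0]
        assert row["p_combined"] == pytest.approx(
            acat_combine([row["p_skato"], row["p_pca"]]), rel=1e-12)
        assert row["n_snps"] == 4

    def test_strong_signal_significant_null_disease_not(self):
        strong = np.full(4, 9.0)
        null = np.array([0.2, -0.4, 1.0, 0.1])
        stats_by, genes, ld = _scan_inputs({"D1": strong, "D2": null})
        scan = genetest.run_gene_scan(stats_by, genes, ld)
        sig = dict(zip(scan["disease_id"], scan["significant"]))
        assert sig == {"D1": True, "D2": False}

    def test_threshold_is_strict(self):
        stats_by, genes, ld = _scan_inputs({"D1": np.full(4, 9.0)})
        scan = genetest.run_gene_scan(stats_by, genes, ld, threshold=1e-300)
        assert not scan["significant"].any()


class TestPleioSelection:
    def scan_frame(self, sig_pairs):
        rows = [(g, d, 5, 1e-8, 1e-8, 1e-8, True) for g, d in sig_pairs]
        rows += [("GX", "D9", 5, 0.5, 0.5, 0.5, False)]
        return pd.DataFrame(rows, columns=["gene_id", "disease_id", "n_snps",
                                           "p_skato", "p_pca", "p_combined",
                                           "significant"])

    def test_single_disease_gene_dropped(self):
        assert find_pleiotropic_genes(self.scan_frame([("G1", "A")])) == {}

    def test_two_disease_gene_kept(self):
        got = find_pleiotropic_genes(self.scan_frame([("G1", "A"),
                                                      ("G1", "B")]))
        assert got == {"G1": frozenset({"A", "B"})}

    def test_random_map_matches_counting_oracle(self, rng):
        pairs = {(f"G{rng.integers(6)}", f"D{rng.integers(5)}")
                 for _ in range(40)}
        got = find_pleiotropic_genes(self.scan_frame(sorted(pairs)))
        counts = {}
        for g, d in pairs:
            counts.setdefault(g, set()).add(d)
        expected = {g: frozenset(ds) for g, ds in counts.items()
                    if len(ds) >= 2}
        assert got == expected


class TestClusterFilter:
    def annotation(self, positions):
        rows = [(g, g, 1, s, e, 1) for g, (s, e) in positions.items()]
        return pd.DataFrame(rows, columns=["gene_id", "symbol", "chrom",
                                           "tx_start", "tx_end", "coding"])

    def evidence(self, scores):
        rows = [(g, d, s) for (g, d), s in scores.items()]
        return pd.DataFrame(rows, columns=["gene_id", "disease_id", "score"])

    def test_distant_genes_form_separate_clusters_and_pass(self):
        ann = self.annotation({"G1": (1000, 2000), "G2": (700_000, 800_000)})
        pleio = {"G1": frozenset({"A", "B"}), "G2": frozenset({"A", "B"})}
        got = filter_ld_gene_clusters(pleio, ann, self.evidence({}))
        assert got == pleio  # gap 698 kb > 500 kb: singletons, unfiltered

    def test_weak_evidence_member_excluded(self):
        ann = self.annotation({"G1": (1000, 2000), "G2": (100_000, 200_000)})
        pleio = {"G1": frozenset({"A", "B"}), "G2": frozenset({"A", "B"})}
        ev = self.evidence({("G1", "A"): 0.5, ("G2", "A"): 0.1,
                            ("G2", "B"): 0.2})
        got = filter_ld_gene_clusters(pleio, ann, ev)
        assert got == {"G1": frozenset({"A", "B"})}

    def test_different_patterns_not_clustered(self):
        ann = self.annotation({"G1": (1000, 2000), "G2": (100_000, 200_000)})
        pleio = {"G1": frozenset({"A", "B"}), "G2": frozenset({"A", "C"})}
        got = filter_ld_gene_clusters(pleio, ann, self.evidence({}))
        assert got == pleio

    def test_missing_evidence_treated_as_zero(self):
        ann = self.annotation({"G1": (1000, 2000), "G2": (100_000, 200_000)})
        pleio = {"G1": frozenset({"A"}), "G2": frozenset({"A"})}
        ev = self.evidence({("G1", "A"): 0.9})
        got = filter_ld_gene_clusters(pleio, ann, ev)
        assert got == {"G1": frozenset({"A"})}

    def test_random_instances_match_rule_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 7))
            pos = {}
            start = 1000
            for i in range(n):
                end = start + int(rng.integers(1000, 5000))
                pos[f"G{i}"] = (start, end)
                start = end + int(rng.integers(10_000, 900_000))
            diseases = ["A", "B", "C"]
            pleio = {g: frozenset(rng.choice(diseases,
                                             size=int(rng.integers(1, 3)),
                                             replace=False))
                     for g in pos}
            scores = {(g, d): float(rng.random())
                      for g in pos for d in diseases if rng.random() < 0.7}
            got = filter_ld_gene_clusters(pleio, self.annotation(pos),
                                          self.evidence(scores))

            # oracle: independent chain construction + literal rule
            order = sorted(pos, key=lambda g: pos[g][0])
            clusters, cur = [], [order[0]]
            for g_prev, g_next in zip(order, order[1:]):
                linked = (pos[g_next][0] - pos[g_prev][1] <= 500_000
                          and pleio[g_next] == pleio[g_prev])
                if linked:
                    cur.append(g_next)
                else:
                    clusters.append(cur)
                    cur = [g_next]
            clusters.append(cur)
            expected = {}
            for cl in clusters:
                if len(cl) == 1:
                    expected[cl[0]] = pleio[cl[0]]
                    continue
                shared = frozenset.intersection(*(pleio[g] for g in cl))
                for g in cl:
                    if all(scores.get((g, d), 0.0) < 0.3 for d in shared):
                        continue
                    expected[g] = pleio[g]
            assert got == expected


def test_gene_test_threshold_value():
    assert gene_test_threshold() == 0.05 / 20_000


def test_flat_beta_weights_are_constant():
    w = WeightSpec(1, 1).weights(np.array([0.01, 0.2, 0.5]))
    assert np.allclose(w, 1.0)
    w2 = WeightSpec(1, 25).weights(np.array([0.01, 0.1]))
    assert w2[0] > w2[1]  # rare variants upweighted under beta(1,25)
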