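"""Subset meta-analysis, clumping, locus merging and gene assignment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pleioscan.containers import LDBlock, LDCollection
from pleioscan.crossmeta import (Locus, SubsetMeta, assign_gene, build_loci,
                                 clump, containing_gene, merge_loci)

from _oracles import (exhaustive_best_subset, greedy_clump_reference,
                      merge_cascade_reference)


class TestSubsetSearch:
    def test_single_retained_trait(self):
        eng = SubsetMeta(["A", "B", "C"], seed=1)
        res = eng.subset_meta({"A": 6.0, "B": 0.1, "C": -0.2})
        assert res.best_subset == frozenset({"A"})
        assert res.subset_z == pytest.approx(6.0)

    def test_pair_beats_triple_with_weak_opposite_trait(self):
        # z = (3, 3, -1), equal weights: (3+3)/sqrt(2) = 4.243 beats the
        # sign-flipped triple (3+3+1)/sqrt(3) = 4.041
        eng = SubsetMeta(["A", "B", "C"], prefilter_p=0.999, seed=1)
        stat, chosen = eng.max_statistic(np.array([3.0, 3.0, -1.0]))
        assert stat == pytest.approx(6.0 / np.sqrt(2.0))
        assert chosen == (0, 1)

    def test_no_trait_passes_prefilter_returns_none(self):
        eng = SubsetMeta(["A", "B"], seed=1)
        assert eng.subset_meta({"A": 0.5, "B": -1.0}) is None

    def test_chosen_subset_matches_exhaustive_enumeration(self, rng):
        traits = [f"T{i}" for i in range(8)]
        w = {t: float(rng.uniform(0.5, 2.0)) for t in traits}
        eng = SubsetMeta(traits, w, prefilter_p=0.999, seed=1)
        for _ in range(50):
            z = rng.standard_normal(8) * 2
            stat, chosen = eng.max_statistic(z)
            ev, es = exhaustive_best_subset(z, [w[t] for t in traits])
            assert stat == pytest.approx(ev)
            assert set(chosen) == es

    def test_p_meta_at_least_unadjusted_best_subset_tail(self, rng):
        eng = SubsetMeta(list("ABCD"), n_null=50_000, seed=2)
        for _ in range(20):
            z = rng.standard_normal(4) * 2.5
            res = eng.subset_meta(dict(zip("ABCD", z)))
            if res is None:
                continue
            assert res.p_meta >= 2 * stats.norm.sf(res.subset_z) - 1e-12

    def test_null_p_meta_uniform(self):
        eng = SubsetMeta(list("ABCDEF"), n_null=100_000, seed=3)
        rng = np.random.default_rng(17)
        ps = []
        for _ in range(1200):
            res = eng.subset_meta(dict(zip("ABCDEF",
                                           rng.standard_normal(6))))
            if res is not None:
                ps.append(res.p_meta)
        assert len(ps) > 300
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_n_sig_traits_counts_genome_wide_members(self):
        eng = SubsetMeta(["A", "B", "C"], seed=1)
        res = eng.subset_meta({"A": 12.0, "B": 6.0, "C": 2.0})
        # A and B exceed the 5e-8 critical value (5.45); C does not
        assert "A" in res.best_subset and "B" in res.best_subset
        assert res.n_sig_traits == 2

    def test_max_traits_cap_keeps_smallest_p(self):
        traits = [f"T{i}" for i in range(6)]
        eng = SubsetMeta(traits, prefilter_p=0.999, max_traits=3, seed=1)
        z = np.array([1.0, 5.0, 2.0, 4.0, 3.0, 0.5])
        _, chosen = eng.max_statistic(z)
        assert set(chosen) <= {1, 3, 4}  # the three largest |z|


def _ld_two_blocks():
    R = np.array([[1.0, 0.7, 0.2], [0.7, 1.0, 0.4], [0.2, 0.4, 1.0]])
    b1 = LDBlock(["rs1", "rs2", "rs3"], R, chrom=1)
    b2 = LDBlock(["rs4", "rs5"], np.array([[1.0, 0.8], [0.8, 1.0]]), chrom=1)
    return LDCollection([b1, b2])


def meta_frame(rows):
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "p_meta",
                                       "subset", "subset_z", "n_sig_traits"])


class TestClump:
    def test_lone_significant_snp_forms_singleton_clump(self):
        meta = meta_frame([("rs1", 1, 100, 1e-10, "A,B", 7.0, 2)])
        got = clump(meta, _ld_two_blocks())
        assert len(got) == 1
        assert got.iloc[0]["members"] == "rs1"

    def test_pair_in_ld_clumps_under_smaller_p(self):
        meta = meta_frame([("rs1", 1, 100, 1e-9, "A", 6.5, 1),
                           ("rs2", 1, 10_100, 1e-10, "A", 7.0, 1)])
        got = clump(meta, _ld_two_blocks())
        assert len(got) == 1
        assert got.iloc[0]["index_snp"] == "rs2"
        assert sorted(got.iloc[0]["members"].split(",")) == ["rs1", "rs2"]

    def test_cross_block_r2_zero_prevents_joining(self):
        meta = meta_frame([("rs1", 1, 100, 1e-10, "A", 7.0, 1),
                           ("rs4", 1, 200, 1e-9, "A", 6.5, 1)])
        got = clump(meta, _ld_two_blocks())
        assert len(got) == 2

    def test_random_regions_match_greedy_reference(self, rng):
        for _ in range(30):
            n = 40
            idx = np.arange(n)
            R = 0.9 ** np.abs(np.subtract.outer(idx, idx))
            snps = [f"rs{i}" for i in range(n)]
            ld = LDCollection([LDBlock(snps, R, chrom=1)])
            pos = np.sort(rng.integers(1, 2_000_000, size=n))
            logp = rng.uniform(-12, -3, size=n)
            pvals = 10.0 ** logp
            meta = meta_frame([(snps[i], 1, int(pos[i]), float(pvals[i]),
                                "A", 6.0, 1) for i in range(n)])
            got = clump(meta, ld, p1=5e-8, p2=1e-5, r2=0.1, kb=1000)
            got_map = {r.index_snp: sorted(r.members.split(","))
                       for r in got.itertuples()}
            expected = greedy_clump_reference(
                [{"snp_id": snps[i], "chrom": 1, "pos": int(pos[i]),
                  "p": float(pvals[i])} for i in range(n)],
                ld.r2, p1=5e-8, p2=1e-5, r2=0.1, kb=1000)
            assert got_map == expected


def mk_locus(snp, pos, p, gene=None, n_traits=1, chrom=1, traits=()):
    return Locus(index_snp=snp, chrom=chrom, pos=pos, start=pos - 1000,
                 end=pos + 1000, p_meta=p, gene_id=gene, n_traits=n_traits,
                 member_snps=[snp], trait_set=frozenset(traits))


class TestMergeLoci:
    def test_beyond_window_unchanged(self):
        loci = [mk_locus("a", 1_000_000, 1e-9),
                mk_locus("b", 1_600_001, 1e-10)]
        got = merge_loci(loci)
        assert [L.index_snp for L in got] == ["a", "b"]

    def test_order_of_magnitude_gap_forces_smallest_p(self):
        loci = [mk_locus("a", 1_000_000, 1e-12),
                mk_locus("b", 1_300_000, 1e-9)]
        got = merge_loci(loci)
        assert len(got) == 1
        assert got[0].index_snp == "a"
        assert got[0].member_snps == ["a", "b"]

    def test_comparable_p_prefers_genic_snp(self):
        loci = [mk_locus("a", 1_000_000, 2e-10, gene="G1"),
                mk_locus("b", 1_300_000, 5e-10)]
        got = merge_loci(loci)
        assert len(got) == 1
        assert got[0].index_snp == "a"

    def test_comparable_p_both_intergenic_prefers_more_traits(self):
        loci = [mk_locus("a", 1_000_000, 5e-10, n_traits=2),
                mk_locus("b", 1_300_000, 2e-10, n_traits=4)]
        got = merge_loci(loci)
        assert got[0].index_snp == "b"

    def test_same_gene_uses_smallest_p_even_if_comparable(self):
        loci = [mk_locus("a", 1_000_000, 5e-10, gene="G1", n_traits=5),
                mk_locus("b", 1_300_000, 2e-10, gene="G1", n_traits=1)]
        got = merge_loci(loci)
        assert got[0].index_snp == "b"

    def test_idempotent_and_final_spacing(self, rng):
        loci = [mk_locus(f"s{i}", int(p), float(10.0 ** rng.uniform(-12, -8)),
                         gene=(f"G{i // 2}" if rng.random() < 0.5 else None),
                         n_traits=int(rng.integers(1, 5)))
                for i, p in enumerate(np.sort(rng.integers(1, 5_000_000,
                                                           size=12)))]
        once = merge_loci(loci)
        twice = merge_loci(once)
        assert [(L.index_snp, L.start, L.end) for L in once] == \
            [(L.index_snp, L.start, L.end) for L in twice]
        for a, b in zip(once, once[1:]):
            if a.chrom == b.chrom:
                assert b.pos - a.pos > 500_000

    def test_randomized_instances_match_cascade_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 9))
            positions = np.sort(rng.integers(1, 4_000_000, size=n))
            items = []
            for i, pos in enumerate(positions):
                gene = f"G{rng.integers(3)}" if rng.random() < 0.6 else None
                items.append({"snp_id": f"s{i}", "chrom": 1, "pos": int(pos),
                              "p": float(10.0 ** rng.uniform(-13, -8)),
                              "gene": gene,
                              "n_traits": int(rng.integers(1, 6)),
                              "start": int(pos) - 500, "end": int(pos) + 500})
            loci = [Locus(index_snp=it["snp_id"], chrom=1, pos=it["pos"],
                          start=it["start"], end=it["end"], p_meta=it["p"],
                          gene_id=it["gene"], n_traits=it["n_traits"],
                          member_snps=[it["snp_id"]])
                    for it in items]
            got = merge_loci(loci)
            expected = merge_cascade_reference(items)
            assert [(L.index_snp, L.start, L.end) for L in got] == \
                [(e["snp_id"], e["start"], e["end"]) for e in expected]


class TestAssignGene:
    ann = pd.DataFrame([
        ("GA", "GA", 1, 100_000, 200_000, 1),
        ("GB", "GB", 1, 260_000, 300_000, 1),
        ("GC", "GC", 2, 100_000, 200_000, 1),
    ], columns=["gene_id", "symbol", "chrom", "tx_start", "tx_end",
                "coding"])

    def test_index_inside_gene(self):
        locus = mk_locus("s", 150_000, 1e-9)
        assert assign_gene(locus, self.ann) == "GA"

    def test_intergenic_index_takes_nearest_gene_in_bounds(self):
        locus = Locus(index_snp="s", chrom=1, pos=210_000, start=90_000,
                      end=310_000, p_meta=1e-9, gene_id=None, n_traits=1)
        # GA ends 10 kb left of the index, GB starts 50 kb right
        assert assign_gene(locus, self.ann) == "GA"

    def test_no_overlapping_gene_returns_none(self):
        locus = Locus(index_snp="s", chrom=1, pos=500_000, start=480_000,
                      end=520_000, p_meta=1e-9, gene_id=None, n_traits=1)
        assert assign_gene(locus, self.ann) is None

    def test_containing_gene_smallest_span_tie_break(self):
        ann = pd.DataFrame([
            ("GBIG", "GBIG", 1, 50_000, 500_000, 1),
            ("GSMALL", "GSMALL", 1, 140_000, 160_000, 1),
        ], columns=["gene_id", "symbol", "chrom", "tx_start", "tx_end",
                    "coding"])
        assert containing_gene(1, 150_000, ann) == "GSMALL"
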