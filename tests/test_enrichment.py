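"""Noteworthy-gene declaration and gene-set over-representation."""

import math

import numpy as np
import pandas as pd
import pytest

from triorank.enrichment import (
    declare_noteworthy,
    overrepresentation_test,
    rank_gene_sets,
    resampling_null,
)
from triorank.ranking import RankedSnpList, rank_snps, top_n


def make_instance(n_snps=100, n_genes=20, snps_per_gene=None, seed=0):
    """Random mapping + ranking over a shared SNP namespace."""
    rng = np.random.default_rng(seed)
    snps = [f"s{i}" for i in range(n_snps)]
    ranked = rank_snps(pd.DataFrame({
        "snp": snps, "chrom": 1, "pos": np.arange(n_snps) * 10 + 1,
        "p": rng.uniform(size=n_snps)}))
    if snps_per_gene is None:
        gene_of = rng.integers(0, n_genes, size=n_snps)
        mapping = pd.DataFrame({"snp": snps,
                                "gene": [f"g{k}" for k in gene_of],
                                "distance": 0})
    else:
        rows, start = [], 0
        for gi, k in enumerate(snps_per_gene):
            for s in snps[start:start + k]:
                rows.append((s, f"g{gi}", 0))
            start += k
        mapping = pd.DataFrame(rows, columns=["snp", "gene", "distance"])
    return mapping, ranked


class TestDeclareNoteworthy:
    def test_all_genes_when_n_is_total(self):
        mapping, ranked = make_instance()
        got = declare_noteworthy(mapping, ranked, len(ranked))
        assert got == set(mapping["gene"])

    def test_boundary_rank(self):
        mapping, ranked = make_instance(n_snps=10, n_genes=10,
                                        snps_per_gene=[1] * 10)
        n = 4
        top = top_n(ranked, n)
        got = declare_noteworthy(mapping, ranked, n)
        # one-SNP genes: noteworthy iff their SNP is in the top set
        assert got == {mapping.set_index("snp").loc[s, "gene"] for s in top}

    def test_best_snp_equivalence(self):
        """'Best SNP in top-n' equals 'any SNP in top-n', since the best SNP
        is the gene's minimum-p SNP."""
        mapping, ranked = make_instance(seed=3)
        for n in (5, 20, 60):
            top = top_n(ranked, n)
            via_any = set(mapping.loc[mapping["snp"].isin(top), "gene"])
            pmap = ranked.p_map()
            via_best = set()
            for g, sub in mapping.groupby("gene"):
                best = min(sub["snp"], key=lambda s: pmap[s])
                if best in top:
                    via_best.add(g)
            assert declare_noteworthy(mapping, ranked, n) == via_any == via_best

    def test_matches_double_loop_oracle(self):
        mapping, ranked = make_instance(seed=9)
        n = 30
        top = top_n(ranked, n)
        want = set()
        for g in mapping["gene"].unique():
            for s in mapping.loc[mapping["gene"] == g, "snp"]:
                if s in top:
                    want.add(g)
        assert declare_noteworthy(mapping, ranked, n) == want


class TestOverrepresentation:
    UNIVERSE = {f"g{i}" for i in range(100)}

    def test_zero_observed_gives_one(self):
        obs, p = overrepresentation_test(set(), {"g1", "g2"}, self.UNIVERSE)
        assert obs == 0 and p == 1.0

    def test_set_equals_universe_gives_one(self):
        note = {f"g{i}" for i in range(20)}
        obs, p = overrepresentation_test(note, set(self.UNIVERSE),
                                         self.UNIVERSE)
        assert obs == 20 and p == pytest.approx(1.0)

    def test_matches_combinatorial_enumeration(self):
        """Hypergeometric tail equals direct combinatorial summation."""
        note = {f"g{i}" for i in range(20)}
        gset = {f"g{i}" for i in range(15, 25)}  # overlap 5, size 10
        obs, p = overrepresentation_test(note, gset, self.UNIVERSE)
        assert obs == 5
        M, K, n = 100, 10, 20
        want = sum(math.comb(K, k) * math.comb(M - K, n - k) / math.comb(M, n)
                   for k in range(5, min(K, n) + 1))
        assert p == pytest.approx(want, rel=1e-12)

    def test_unknown_genes_dropped(self, caplog):
        with caplog.at_level("INFO"):
            obs, p = overrepresentation_test({"g1", "zzz"}, {"g1"},
                                             self.UNIVERSE)
        assert obs == 1


class TestResamplingNull:
    def test_deterministic_under_seed(self):
        mapping, ranked = make_instance(seed=5)
        sets = {"A": ["g1", "g2", "g3"], "B": ["g4", "g5"]}
        a = resampling_null(mapping, ranked, 20, sets, reps=100, seed=7)
        b = resampling_null(mapping, ranked, 20, sets, reps=100, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_empirical_p_floor_and_range(self):
        mapping, ranked = make_instance(seed=6)
        sets = {f"S{i}": [f"g{i % 20}"] for i in range(10)}
        out = resampling_null(mapping, ranked, 50, sets, reps=49, seed=1)
        assert (out["emp_p"] >= 1 / 50).all()
        assert (out["emp_p"] <= 1.0).all()

    def test_zero_observed_gives_p_one(self):
        mapping, ranked = make_instance(n_snps=40, n_genes=10, seed=8)
        sets = {"EMPTYISH": ["g_not_in_universe"]}
        out = resampling_null(mapping, ranked, 5, sets, reps=50, seed=2)
        assert out["emp_p"].iloc[0] == pytest.approx(1.0)

    def test_modes_agree_when_one_snp_per_gene(self):
        """With exactly one SNP per gene the snp- and gene-resampling nulls
        target the same distribution."""
        mapping, ranked = make_instance(n_snps=60, n_genes=60,
                                        snps_per_gene=[1] * 60, seed=10)
        sets = {f"S{i}": [f"g{j}" for j in range(i, i + 10)] for i in range(10)}
        a = resampling_null(mapping, ranked, 20, sets, reps=800, mode="snp",
                            seed=3).set_index("set")["emp_p"]
        b = resampling_null(mapping, ranked, 20, sets, reps=800, mode="gene",
                            seed=4).set_index("set")["emp_p"]
        # Monte-Carlo error of an empirical p at 800 reps is ~0.018 at p=0.5
        assert (np.abs(a - b.loc[a.index]) < 6 * 0.018 + 0.02).all()

    def test_snp_mode_preserves_gene_size_bias(self):
        """Genes with more SNPs enter snp-mode null lists more often; the
        inclusion frequency is monotone in SNP count."""
        sizes = [1, 4, 16]
        mapping, ranked = make_instance(n_snps=sum(sizes) * 10,
                                        snps_per_gene=sizes * 10, seed=11)
        # one singleton set per gene; null inclusion freq = 1 - emp survival
        sets = {f"S_{g}": [g] for g in mapping["gene"].unique()}
        rng = np.random.default_rng(0)
        from triorank.enrichment import _SnpGeneCsr, _first_m_distinct

        csr = _SnpGeneCsr(mapping, ranked.snp_ids)
        m = 10
        freq = np.zeros(len(csr.genes))
        for _ in range(400):
            seq = csr.genes_in_order(rng.permutation(csr.n_snps))
            freq[_first_m_distinct(seq, m)] += 1
        size_of = mapping.groupby("gene").size()
        mean_by_size = {k: freq[[list(csr.genes).index(g)
                                 for g in size_of[size_of == k].index]].mean()
                        for k in sizes}
        assert mean_by_size[1] < mean_by_size[4] < mean_by_size[16]

    def test_bad_mode(self):
        mapping, ranked = make_instance()
        with pytest.raises(ValueError):
            resampling_null(mapping, ranked, 5, {"A": ["g1"]}, reps=10,
                            mode="bogus")


class TestRankGeneSets:
    def frame(self, order):
        return pd.DataFrame({"set": order,
                             "emp_p": np.linspace(0.01, 0.9, len(order)),
                             "hyper_p": np.linspace(0.01, 0.9, len(order))})

    def test_identical_tables(self):
        f = self.frame(list("ABCDE"))
        out = rank_gene_sets({"X": f, "Y": f.copy()}, k_grid=[1, 3, 5])
        assert list(out["shared"]) == [1, 3, 5]

    def test_disjoint_top_lists(self):
        a = self.frame(list("ABCDE"))
        b = self.frame(list("FGHIJ"))
        out = rank_gene_sets({"X": a, "Y": b}, k_grid=[2, 5])
        assert list(out["shared"]) == [0, 0]

    def test_matches_intersection_oracle(self):
        rng = np.random.default_rng(13)
        names = [f"S{i}" for i in range(30)]
        frames = {p: self.frame(list(rng.permutation(names))) for p in "XYZ"}
        out = rank_gene_sets(frames, k_grid=[5, 10, 20]).set_index("k")
        for k in (5, 10, 20):
            tops = [set(f.sort_values(["emp_p", "hyper_p", "set"])["set"][:k])
                    for f in frames.values()]
            assert out.loc[k, "shared"] == len(set.intersection(*tops))
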