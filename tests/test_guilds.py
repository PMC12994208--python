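import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import stats as sps

from sedtaph.guilds import (
    CorrelationMatrix,
    Guild,
    GuildDistanceMatrix,
    GuildProfile,
    classify_guild_type,
    corr_to_distance,
    embed_mds,
    guild_distance,
    guild_enrichment,
    guild_profile,
    guild_profiles,
    hypercube_cluster,
    pair_association_pvalues,
    pairwise_pmcc,
)
from sedtaph.profiles_io import TaxonCountTable


def corr_of(values, taxa=None):
    values = np.asarray(values, dtype=float)
    taxa = taxa or [f"t{i}" for i in range(values.shape[0])]
    return CorrelationMatrix(taxa=list(taxa), values=values)


class TestPairwisePmcc:
    def test_proportional_vectors_correlate_perfectly(self, toy_table):
        c = pairwise_pmcc(toy_table).as_frame()
        assert c.loc["alder", "willow"] == pytest.approx(1.0)
        assert c.loc["zostera", "eelgrass_kin"] == pytest.approx(1.0)

    def test_antilinear_frequencies(self):
        # frequencies (0.1,0.2,0.3) vs (0.3,0.2,0.1) within each sample
        counts = pd.DataFrame(
            {"a": [10, 20, 30], "b": [30, 20, 10], "pad": [60, 60, 60]},
            index=["s1", "s2", "s3"])
        c = pairwise_pmcc(TaxonCountTable(counts)).as_frame()
        assert c.loc["a", "b"] == pytest.approx(-1.0)

    def test_matches_textbook_pearson(self):
        counts = pd.DataFrame(
            {"a": [5, 10, 20, 40], "b": [7, 13, 22, 31], "pad": [88, 77, 58, 29]},
            index=list("wxyz"))
        table = TaxonCountTable(counts)
        freq = table.frequencies()
        expected = sps.pearsonr(freq["a"], freq["b"]).statistic
        got = pairwise_pmcc(table).as_frame().loc["a", "b"]
        assert got == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_taxon_excluded(self):
        counts = pd.DataFrame(
            {"a": [10, 20, 30], "flat": [10, 10, 10], "b": [80, 70, 60]},
            index=["s1", "s2", "s3"])
        # totals are constant, so 'flat' has constant frequency 0.1
        c = pairwise_pmcc(TaxonCountTable(counts))
        assert c.dropped == ["flat"]
        assert "flat" not in c.taxa

    def test_needs_three_samples(self, toy_table):
        small = TaxonCountTable(toy_table.counts.iloc[:2])
        with pytest.raises(ValueError):
            pairwise_pmcc(small)


class TestCorrToDistance:
    @pytest.mark.parametrize("pmcc,expected", [(1.0, 0.0), (-1.0, 1.0), (0.0, 0.5)])
    def test_fixed_points(self, pmcc, expected):
        c = corr_of([[1.0, pmcc], [pmcc, 1.0]])
        d = corr_to_distance(c)
        assert d.values[0, 1] == pytest.approx(expected)
        assert d.values[0, 0] == 0.0

    @given(hst.lists(hst.floats(-1, 1), min_size=1, max_size=10))
    @settings(deadline=None, max_examples=50)
    def test_affine_bijection_round_trip(self, vals):
        pmcc = np.array(vals)
        d = 1 - (pmcc + 1) / 2
        back = 1 - 2 * d
        assert np.allclose(back, pmcc, atol=1e-12)


class TestEmbedMds:
    def test_two_points_on_a_line(self):
        d = np.array([[0, 0.6, 0.3], [0.6, 0, 0.3], [0.3, 0.3, 0]])
        emb = embed_mds(GuildDistanceMatrix(["a", "b", "c"], d), dims=2)
        got = np.linalg.norm(emb.coordinates[0] - emb.coordinates[1])
        assert got == pytest.approx(0.6, abs=1e-9)

    def test_equilateral_triangle(self):
        d = np.ones((3, 3)) - np.eye(3)
        emb = embed_mds(GuildDistanceMatrix(list("abc"), d), dims=2)
        for i, j in itertools.combinations(range(3), 2):
            dist = np.linalg.norm(emb.coordinates[i] - emb.coordinates[j])
            assert dist == pytest.approx(1.0, abs=1e-9)

    def test_reproduces_euclidean_distances(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(12, 4))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        emb = embed_mds(GuildDistanceMatrix([f"t{i}" for i in range(12)], d), dims=10)
        d2 = np.linalg.norm(emb.coordinates[:, None] - emb.coordinates[None, :], axis=-1)
        assert np.max(np.abs(d2 - d)) < 1e-8

    def test_matches_reference_pcoa(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(9, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        emb = embed_mds(GuildDistanceMatrix([f"t{i}" for i in range(9)], d), dims=3)
        ref = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(d))
        ref_coords = ref.samples.to_numpy()[:, :3]
        # axes agree up to sign
        for k in range(3):
            assert (np.allclose(emb.coordinates[:, k], ref_coords[:, k], atol=1e-8)
                    or np.allclose(emb.coordinates[:, k], -ref_coords[:, k], atol=1e-8))

    def test_invariant_under_taxon_reordering(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(8, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        names = [f"t{i}" for i in range(8)]
        emb = embed_mds(GuildDistanceMatrix(names, d), dims=3)
        perm = rng.permutation(8)
        emb_p = embed_mds(
            GuildDistanceMatrix([names[i] for i in perm], d[np.ix_(perm, perm)]), dims=3)
        # pairwise embedded distances identical regardless of input order
        d1 = np.linalg.norm(emb.coordinates[:, None] - emb.coordinates[None, :], axis=-1)
        d2 = np.linalg.norm(emb_p.coordinates[:, None] - emb_p.coordinates[None, :], axis=-1)
        inv = np.argsort(perm)
        assert np.allclose(d2[np.ix_(inv, inv)], d1, atol=1e-9)

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            embed_mds(GuildDistanceMatrix(["a", "b"], np.zeros((2, 2))), dims=1)


class TestHypercubeCluster:
    def embed(self, coords):
        coords = np.asarray(coords, dtype=float)
        return_names = [f"t{i}" for i in range(coords.shape[0])]
        from sedtaph.guilds import Embedding
        return Embedding(return_names, coords, np.ones(coords.shape[1]))

    def test_identical_coordinates_one_guild(self):
        emb = self.embed(np.tile([[0.2, 0.1, 0.0]], (6, 1)) + [[0, 0, 0]] * 6)
        guilds, unassigned = hypercube_cluster(emb, start_dims=3)
        assert len(guilds) == 1 and len(guilds[0].members) == 6
        assert unassigned == []

    def test_two_separated_blobs(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 0.01, size=(5, 3))
        b = rng.normal(0.0, 0.01, size=(5, 3)) + [1.0, 0, 0]
        emb = self.embed(np.vstack([a, b]))
        guilds, unassigned = hypercube_cluster(emb, start_dims=3)
        assert len(guilds) == 2
        assert {len(g.members) for g in guilds} == {5}

    def test_singletons_unassigned(self):
        coords = np.vstack([np.zeros((4, 3)), [[1.0, 1.0, 1.0]]])
        emb = self.embed(coords)
        guilds, unassigned = hypercube_cluster(emb, start_dims=3)
        assert len(guilds) == 1
        assert unassigned == ["t4"]

    def test_partition_no_taxon_in_two_guilds(self):
        rng = np.random.default_rng(1)
        emb = self.embed(rng.normal(size=(30, 5)))
        guilds, unassigned = hypercube_cluster(emb, start_dims=3)
        seen = [t for g in guilds for t in g.members] + unassigned
        assert sorted(seen) == sorted(emb.taxa)
        assert len(seen) == len(set(seen))


class TestPairAssociation:
    def test_identical_vectors_significant(self):
        rng = np.random.default_rng(8)
        a = rng.integers(5, 200, size=10)
        counts = pd.DataFrame(
            {"alder": a, "willow": 2 * a,
             "pad": rng.integers(50, 300, size=10)},
            index=[f"s{i}" for i in range(10)])
        p = pair_association_pvalues(TaxonCountTable(counts), n_perm=999, seed=0)
        assert p[("alder", "willow")] <= 0.01

    def test_null_pvalues_roughly_uniform(self):
        # constant sample totals make the 12 focal frequencies independent
        rng = np.random.default_rng(42)
        x = rng.integers(1, 200, size=(30, 12))
        counts = pd.DataFrame(x, index=[f"s{i}" for i in range(30)],
                              columns=[f"t{i}" for i in range(12)])
        counts["pad"] = 3000 - x.sum(axis=1)
        p = pair_association_pvalues(TaxonCountTable(counts), n_perm=999, seed=1)
        focal = [v for (a, b), v in p.items() if a != "pad" and b != "pad"]
        ks = sps.kstest(focal, "uniform")
        assert ks.pvalue > 0.01

    def test_too_few_permutations_rejected(self, toy_table):
        with pytest.raises(ValueError):
            pair_association_pvalues(toy_table, n_perm=0)

    def test_constant_taxon_gets_p_one(self):
        counts = pd.DataFrame(
            {"a": [10, 20, 30], "flat": [10, 10, 10], "b": [80, 70, 60]},
            index=["s1", "s2", "s3"])
        p = pair_association_pvalues(TaxonCountTable(counts), n_perm=99, seed=0)
        assert p[("a", "flat")] == 1.0


class TestGuildType:
    def pvals(self, mapping):
        return {tuple(sorted(k)): v for k, v in mapping.items()}

    def test_all_pairs_significant_is_simple(self):
        g = Guild(1, frozenset("abc"))
        p = self.pvals({("a", "b"): 0.01, ("a", "c"): 0.02, ("b", "c"): 0.03})
        out = classify_guild_type(g, p)
        assert out.guild_type == "simple" and out.anchor is None

    def test_anchor_is_most_connected(self):
        g = Guild(1, frozenset("abc"))
        p = self.pvals({("a", "b"): 0.01, ("a", "c"): 0.02, ("b", "c"): 0.5})
        out = classify_guild_type(g, p)
        assert out.guild_type == "complex" and out.anchor == "a"

    def test_degenerate_pair_tie_lexicographic(self):
        g = Guild(1, frozenset("ab"))
        out = classify_guild_type(g, self.pvals({("a", "b"): 0.2}))
        assert out.guild_type == "complex" and out.anchor == "a"

    def test_missing_pair_raises(self):
        g = Guild(1, frozenset("abc"))
        with pytest.raises(KeyError):
            classify_guild_type(g, self.pvals({("a", "b"): 0.01}))


class TestEnrichment:
    @pytest.mark.parametrize(
        "m,x,p0,expected",
        [
            (10, 10, 0.05, 0.05 ** 10),
            (10, 0, 0.05, 1.0),
            (10, 1, 0.05, 1 - 0.95 ** 10),
        ],
    )
    def test_closed_form(self, m, x, p0, expected):
        assert guild_enrichment(m, x, p0) == pytest.approx(expected, rel=1e-10)

    def test_matches_exhaustive_enumeration(self):
        # brute force over all outcomes for m <= 12
        from math import comb
        for m in range(1, 13):
            for x in range(0, m + 1):
                exact = sum(comb(m, k) * 0.05 ** k * 0.95 ** (m - k)
                            for k in range(x, m + 1))
                assert guild_enrichment(m, x, 0.05) == pytest.approx(exact, rel=1e-9)

    def test_invalid_rate(self):
        with pytest.raises(ValueError):
            guild_enrichment(10, 2, 0.0)


class TestProfilesAndDistance:
    def guilds(self):
        return [Guild(1, frozenset({"alder", "willow"})),
                Guild(2, frozenset({"zostera", "eelgrass_kin"}))]

    def test_profile_arithmetic(self):
        s = pd.Series({"a": 30, "b": 20, "c": 50}, name="s1")
        gs = [Guild(1, frozenset({"a", "b"})), Guild(2, frozenset({"c", "d"}))]
        p = guild_profile(s, gs)
        assert p.proportions == {1: 0.5, 2: 0.5}
        assert p.unassigned == pytest.approx(0.0)

    def test_unassigned_bucket(self):
        s = pd.Series({"a": 25, "x": 75}, name="s1")
        p = guild_profile(s, [Guild(1, frozenset({"a", "b"}))])
        assert p.proportions[1] == 0.25
        assert p.unassigned == 0.75

    def test_empty_sample_rejected(self):
        s = pd.Series({"a": 0}, name="s1")
        with pytest.raises(ValueError):
            guild_profile(s, [Guild(1, frozenset({"a", "b"}))])

    @pytest.mark.parametrize(
        "p1,p2,expected",
        [
            ({1: 0.5, 2: 0.5}, {1: 0.5, 2: 0.5}, 0.0),
            ({1: 1.0, 2: 0.0}, {1: 0.0, 2: 1.0}, np.sqrt(2)),
            ({1: 0.5, 2: 0.5}, {1: 0.25, 2: 0.75}, np.sqrt(0.125)),
        ],
    )
    def test_distance_examples(self, p1, p2, expected):
        a = GuildProfile("a", p1, 1 - sum(p1.values()))
        b = GuildProfile("b", p2, 1 - sum(p2.values()))
        assert guild_distance(a, b) == pytest.approx(expected, abs=1e-9)

    def test_mismatched_guild_lists_rejected(self):
        a = GuildProfile("a", {1: 1.0}, 0.0)
        b = GuildProfile("b", {2: 1.0}, 0.0)
        with pytest.raises(ValueError):
            guild_distance(a, b)

    @given(hst.lists(hst.floats(0, 1), min_size=3, max_size=3),
           hst.lists(hst.floats(0, 1), min_size=3, max_size=3),
           hst.lists(hst.floats(0, 1), min_size=3, max_size=3))
    @settings(deadline=None, max_examples=100)
    def test_metric_properties(self, u, v, w):
        def norm(vals):
            s = sum(vals) or 1.0
            scaled = [x / s for x in vals]
            return GuildProfile("p", dict(enumerate(scaled)), 0.0)
        a, b, c = norm(u), norm(v), norm(w)
        dab, dba = guild_distance(a, b), guild_distance(b, a)
        assert dab >= 0 and dab == pytest.approx(dba)
        assert dab <= np.sqrt(2) + 1e-12
        assert dab <= guild_distance(a, c) + guild_distance(c, b) + 1e-12

    def test_profiles_frame_columns(self, toy_table):
        df = guild_profiles(toy_table, self.guilds())
        assert list(df.columns) == ["G1", "G2", "unassigned"]
        assert np.allclose(df.sum(axis=1), 1.0)
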