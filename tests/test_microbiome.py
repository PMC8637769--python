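import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.diversity.alpha import chao1 as skbio_chao1
from skbio.diversity.alpha import shannon as skbio_shannon
from skbio.stats.ordination import pcoa as skbio_pcoa

import oracles
from colitiskit.microbiome import (
    FeatureTable,
    alpha_diversity,
    composition_profile,
    cophenetic_distances,
    filter_low_abundance,
    jaccard_distance_matrix,
    lefse,
    nmds,
    pcoa,
    rarefaction_curve,
    upgma,
)
from colitiskit.synth import gen_feature_table


def table(counts, groups=None, taxonomy=None):
    df = pd.DataFrame(counts)
    df.index = [f"s{i}" for i in range(df.shape[0])]
    df.columns = [f"f{i}" for i in range(df.shape[1])]
    g = pd.Series(groups or ["A"] * df.shape[0], index=df.index)
    tax = pd.Series(taxonomy, index=df.columns) if taxonomy else None
    return FeatureTable(df, g, tax)


class TestFiltration:
    def test_boundary_at_0005_percent(self):
        # grand total 1e6: 49-read feature removed, 50-read feature kept
        counts = np.zeros((1, 3), dtype=int)
        counts[0] = [999_901, 49, 50]
        t = filter_low_abundance(table(counts))
        assert list(t.counts.columns) == ["f0", "f2"]

    def test_zero_fraction_is_identity(self):
        t = table([[3, 1], [0, 2]])
        assert filter_low_abundance(t, 0.0).counts.equals(t.counts)

    def test_all_below_threshold_warns(self):
        with pytest.warns(UserWarning, match="below"):
            out = filter_low_abundance(table([[1, 1]]), min_fraction=0.9)
        assert out.counts.shape[1] == 0


class TestComposition:
    def test_top10_plus_others_columns_sum_to_one(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 50, size=(4, 24))
        tax = [f"k__B;p__P{i % 3};c__;o__;f__;g__G{i % 12}" for i in range(24)]
        prof = composition_profile(table(counts, taxonomy=tax), rank="genus")
        assert prof.shape[0] == 11 and "Others" in prof.index
        assert prof.sum(axis=0).to_numpy() == pytest.approx(np.ones(4))

    def test_few_taxa_no_others(self):
        tax = ["k__B;p__P1;c__;o__;f__;g__G1", "k__B;p__P1;c__;o__;f__;g__G2"]
        prof = composition_profile(table([[3, 1]], taxonomy=tax), rank="genus")
        assert "Others" not in prof.index

    def test_single_taxon_all_ones(self):
        tax = ["k__B;p__P1;c__;o__;f__;g__G1"] * 2
        prof = composition_profile(table([[3, 1], [0, 5]], taxonomy=tax))
        assert prof.to_numpy() == pytest.approx(np.ones((1, 2)))

    def test_missing_rank_rejected(self):
        with pytest.raises(ValueError, match="rank"):
            composition_profile(table([[1]], taxonomy=["k__B"]), rank="genus")


class TestAlphaDiversity:
    def test_chao1_classic_worked_example(self):
        out = alpha_diversity([5, 3, 1, 1, 1, 2, 2], chao1_bias_corrected=False)
        assert out["chao1"] == pytest.approx(9.25, abs=1e-9)

    def test_uniform_four_species(self):
        out = alpha_diversity([5, 5, 5, 5])
        assert out["shannon"] == pytest.approx(np.log(4), abs=1e-9)
        assert out["simpson"] == pytest.approx(0.75, abs=1e-9)

    def test_ace_worked_example(self):
        assert alpha_diversity([1, 1, 2, 12])["ace"] == pytest.approx(7.0, abs=1e-9)

    def test_no_singletons(self):
        out = alpha_diversity([2, 3, 4], chao1_bias_corrected=False)
        assert out["coverage"] == 1.0 and out["chao1"] == 3.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            alpha_diversity([0, 0])

    def test_matches_skbio_where_definitions_agree(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            c = rng.integers(0, 40, size=25)
            c[rng.integers(0, 25)] += 1  # ensure nonzero
            ours = alpha_diversity(c)
            assert ours["chao1"] == pytest.approx(skbio_chao1(c), abs=1e-9)
            assert ours["shannon"] == pytest.approx(
                skbio_shannon(c, base=np.e), abs=1e-9
            )

    def test_estimator_bounds(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            c = rng.integers(0, 30, size=15)
            if c.sum() == 0:
                continue
            out = alpha_diversity(c)
            s_obs = int((c > 0).sum())
            assert out["chao1"] >= s_obs
            assert 0.0 <= out["coverage"] <= 1.0
            assert 0.0 <= out["simpson"] < 1.0


class TestRarefaction:
    def test_full_depth_returns_observed_richness(self):
        c = [4, 3, 2]
        assert rarefaction_curve(c, [9])[0] == pytest.approx(3.0, abs=1e-9)

    def test_depth_one(self):
        assert rarefaction_curve([3, 5, 7], [1])[0] == pytest.approx(1.0, abs=1e-9)

    def test_worked_two_by_two(self):
        assert rarefaction_curve([2, 2], [2])[0] == pytest.approx(5 / 3, abs=1e-9)

    def test_matches_exhaustive_enumeration(self):
        c = [3, 2, 1]
        for n in (1, 2, 3, 4):
            expect = oracles.expected_richness_by_enumeration(c, n)
            assert rarefaction_curve(c, [n])[0] == pytest.approx(expect, abs=1e-9)

    def test_monotone_and_bounded(self):
        c = [10, 4, 2, 1, 1]
        vals = rarefaction_curve(c, list(range(1, 19)))
        assert np.all(np.diff(vals) >= -1e-12)
        assert vals[-1] == pytest.approx(5.0)

    def test_depth_above_total_rejected(self):
        with pytest.raises(ValueError):
            rarefaction_curve([2, 2], [5])


class TestJaccard:
    def test_identical_disjoint_and_half(self):
        t = table([[1, 1, 1, 0], [1, 1, 1, 0], [0, 0, 0, 5]])
        d = jaccard_distance_matrix(t)
        assert d["s0", "s1"] == 0.0
        assert d["s0", "s2"] == 1.0
        t2 = table([[1, 1, 1, 0], [0, 1, 1, 1]])
        assert jaccard_distance_matrix(t2)["s0", "s1"] == pytest.approx(0.5)

    def test_both_empty_samples_distance_zero(self):
        d = jaccard_distance_matrix(table([[0, 0], [0, 0], [1, 0]]))
        assert d["s0", "s1"] == 0.0

    def test_metric_axioms_on_fuzzed_tables(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            t = table(rng.integers(0, 3, size=(6, 12)))
            d = jaccard_distance_matrix(t).data
            assert np.allclose(d, d.T) and np.all(np.diag(d) == 0)
            for i in range(6):
                for j in range(6):
                    for k in range(6):
                        assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


class TestPCoA:
    def test_equilateral_triangle_eigenvalues(self):
        d = DistanceMatrix(1 - np.eye(3), ids=list("abc"))
        r = pcoa(d)
        assert r.eigenvalues == pytest.approx([0.5, 0.5, 0.0], abs=1e-9)

    def test_one_dimensional_points_reconstructed(self):
        pts = np.array([[0.0], [1.0], [3.0]])
        d = squareform(pdist(pts))
        r = pcoa(d)
        rec = squareform(pdist(r.coordinates.to_numpy()))
        assert rec == pytest.approx(d, abs=1e-9)

    def test_two_samples(self):
        r = pcoa(np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert sorted(r.coordinates.to_numpy().ravel()) == pytest.approx([-0.5, 0.5])

    def test_planted_points_in_r3_reconstructed(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(9, 3))
        d = squareform(pdist(pts))
        rec = squareform(pdist(pcoa(d).coordinates.to_numpy()))
        assert rec == pytest.approx(d, abs=1e-9)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            pcoa(np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_agrees_with_skbio(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(7, 3))
        dm = DistanceMatrix(squareform(pdist(pts)),
                            ids=[f"s{i}" for i in range(7)])
        ours = pcoa(dm)
        ref = skbio_pcoa(dm, number_of_dimensions=3)
        assert ours.eigenvalues[:3] == pytest.approx(
            ref.eigvals.to_numpy()[:3], abs=1e-8
        )


class TestNMDS:
    def test_perfectly_embeddable_data_near_zero_stress(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(8, 2))
        d = squareform(pdist(pts))
        r = nmds(d, k=2, seed=0)
        assert r.stress < 0.01 and r.valid

    def test_stress_sequence_non_increasing(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(10, 4))  # not embeddable in 2-D
        r = nmds(squareform(pdist(pts)), k=2, seed=1)
        seq = r.stress_sequence
        assert all(a >= b - 1e-12 for a, b in zip(seq, seq[1:]))

    def test_group_separation_on_planted_tables(self):
        t, _ = gen_feature_table(seed=3)
        d = jaccard_distance_matrix(t)
        r = nmds(d, seed=3)
        assert r.stress < 0.2
        coords = r.coordinates
        g = t.groups
        labels = g.unique()
        a = coords.loc[g == labels[0]].mean()
        b = coords.loc[g == labels[1]].mean()
        between = np.linalg.norm(a - b)
        within = np.mean([
            coords.loc[g == lab].sub(coords.loc[g == lab].mean()).pow(2)
            .sum(axis=1).pow(0.5).mean()
            for lab in labels
        ])
        assert between > within

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            nmds(np.zeros((3, 3)), k=2)


class TestUPGMA:
    def test_worked_three_leaf_tree(self):
        d = DistanceMatrix(np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float),
                           ids=["A", "B", "C"])
        newick, merges = upgma(d)
        assert newick == "((A:1,B:1):1,C:2);"
        assert merges.shape[0] == 2

    def test_two_samples(self):
        d = DistanceMatrix(np.array([[0, 3], [3, 0]], float), ids=["A", "B"])
        newick, _ = upgma(d)
        assert newick == "(A:1.5,B:1.5);"

    def test_ultrametric_input_reproduced_exactly(self):
        # build an ultrametric from a known tree: ((a,b):, (c,d):) heights 1, 3
        d = np.array(
            [[0, 2, 6, 6], [2, 0, 6, 6], [6, 6, 0, 2], [6, 6, 2, 0]], float
        )
        dm = DistanceMatrix(d, ids=list("abcd"))
        coph = cophenetic_distances(dm)
        assert coph.data == pytest.approx(d, abs=1e-9)

    def test_random_ultrametrics_recovered(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            # random agglomeration with increasing heights -> ultrametric
            n = 6
            heights = np.sort(rng.uniform(1, 10, n - 1))
            import scipy.cluster.hierarchy as sch

            z = []
            clusters = {i: [i] for i in range(n)}
            next_id = n
            ids = list(range(n))
            d = np.zeros((n, n))
            for h, _ in zip(heights, range(n - 1)):
                i, j = sorted(rng.choice(len(ids), 2, replace=False))
                a, b = ids[i], ids[j]
                for x in clusters[a]:
                    for y in clusters[b]:
                        d[x, y] = d[y, x] = 2 * h
                clusters[next_id] = clusters[a] + clusters[b]
                ids = [x for x in ids if x not in (a, b)] + [next_id]
                next_id += 1
            dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(n)])
            assert cophenetic_distances(dm).data == pytest.approx(d, abs=1e-9)


class TestLefse:
    def test_identical_feature_not_significant(self):
        # same composition in every sample (library size varies): every
        # relative abundance is constant, so nothing can be significant
        counts = np.array([[50, 10], [100, 20], [150, 30],
                           [50, 10], [200, 40], [250, 50]])
        t = table(counts, groups=["A"] * 3 + ["B"] * 3)
        res = lefse(t, seed=0)
        assert (res["kw_p"] == 1.0).all()
        assert not res["significant"].any()

    def test_planted_shift_detected(self):
        t, planted = gen_feature_table(seed=1)
        res = lefse(t, seed=1)
        sig = set(res.index[res.significant])
        assert len(sig & set(planted)) >= 4
        assert (res.loc[sorted(sig & set(planted)), "lda_effect"] >= 2).all()

    def test_enriched_group_matches_planted_direction(self):
        t, planted = gen_feature_table(seed=2)
        res = lefse(t, seed=2)
        rel = t.counts.div(t.counts.sum(axis=1), axis=0)
        for f in planted:
            means = rel.groupby(t.groups)[f].mean()
            assert res.loc[f, "enriched_group"] == means.idxmax()

    def test_requires_two_groups_and_group_size(self):
        t = table([[1, 2]] * 4, groups=["A", "B", "C", "A"])
        with pytest.raises(ValueError, match="2 groups"):
            lefse(t)
        t2 = table([[1, 2]] * 4, groups=["A", "A", "B", "B"])
        with pytest.raises(ValueError, match="3 samples"):
            lefse(t2)
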