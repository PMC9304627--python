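"""Diversity indices, distances, ordination and PERMANOVA against
independent closed forms, enumeration oracles and scikit-bio cross-checks."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova
from skbio.stats.ordination import pcoa as skbio_pcoa

from microconet.cohort import generate_tree
from microconet.diversity import (
    alpha_diversity,
    bray_curtis,
    pc1_paired_test,
    pcoa,
    permanova,
    rarefaction_curves,
    unweighted_unifrac,
)
from microconet.io import CountTable, tree_from_newick

from conftest import random_count_table


class TestAlphaDiversity:
    def test_uniform_closed_form(self):
        t = CountTable(pd.DataFrame([[5] * 8], index=["s"], columns=list("abcdefgh")))
        res = alpha_diversity(t)
        assert res.loc["s", "shannon"] == pytest.approx(np.log(8))
        assert res.loc["s", "simpson"] == pytest.approx(0.875)
        assert res.loc["s", "observed_otus"] == 8

    def test_single_taxon(self):
        t = CountTable(pd.DataFrame([[7, 0]], index=["s"], columns=["a", "b"]))
        res = alpha_diversity(t)
        assert res.loc["s"].tolist() == [0.0, 0.0, 1]

    def test_log2_base(self):
        t = CountTable(pd.DataFrame([[5] * 8], index=["s"], columns=list("abcdefgh")))
        assert alpha_diversity(t, base=2).loc["s", "shannon"] == pytest.approx(3.0)

    def test_random_rows_match_direct_formula(self, rng):
        for _ in range(20):
            t = random_count_table(rng, n_samples=3, n_taxa=10)
            if (t.sample_totals() == 0).any():
                continue
            res = alpha_diversity(t)
            for i, s in enumerate(t.sample_ids):
                p = t.counts[i] / t.counts[i].sum()
                p = p[p > 0]
                assert res.loc[s, "shannon"] == pytest.approx(-(p * np.log(p)).sum(), abs=1e-12)
                assert res.loc[s, "simpson"] == pytest.approx(1 - (p**2).sum(), abs=1e-12)
                assert res.loc[s, "observed_otus"] == (t.counts[i] > 0).sum()

    def test_zero_sum_sample_error(self):
        t = CountTable(pd.DataFrame([[0, 0]], index=["s"], columns=["a", "b"]))
        with pytest.raises(ValueError, match="'s'"):
            alpha_diversity(t)


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        t = CountTable(pd.DataFrame([[3, 4], [3, 4]], index=["a", "b"], columns=["x", "y"]))
        assert bray_curtis(t)["a", "b"] == 0.0

    def test_disjoint_support_one(self):
        t = CountTable(pd.DataFrame([[3, 0], [0, 9]], index=["a", "b"], columns=["x", "y"]))
        assert bray_curtis(t)["a", "b"] == 1.0

    def test_hand_worked_value(self):
        t = CountTable(pd.DataFrame([[2, 0, 1], [1, 1, 0]], index=["a", "b"],
                                     columns=["x", "y", "z"]))
        # sum of minima 1, totals 3 and 2 -> 1 - 2*1/5 = 0.6
        assert bray_curtis(t)["a", "b"] == pytest.approx(0.6)

    def test_matches_scipy_pdist(self, rng):
        t = random_count_table(rng, n_samples=6, n_taxa=12)
        t = CountTable(pd.DataFrame(t.counts + 1, index=t.sample_ids, columns=t.taxon_ids))
        ours = bray_curtis(t).data
        ref = squareform(pdist(t.counts.astype(float), metric="braycurtis"))
        assert np.allclose(ours, ref, atol=1e-12)


def unifrac_branch_enumeration(table, tree):
    """Independent per-branch oracle for unweighted UniFrac."""
    present = {
        s: {t for t, c in zip(table.taxon_ids, row) if c > 0}
        for s, row in zip(table.sample_ids, table.counts)
    }
    branches = []
    for node in tree.traverse(include_self=False):
        leaves = {t.name for t in node.tips()} or {node.name}
        branches.append((node.length or 0.0, leaves))
    n = len(table.sample_ids)
    d = np.zeros((n, n))
    for i, a in enumerate(table.sample_ids):
        for j, b in enumerate(table.sample_ids):
            if j <= i:
                continue
            unique = union = 0.0
            for length, leaves in branches:
                in_a = bool(leaves & present[a])
                in_b = bool(leaves & present[b])
                if in_a or in_b:
                    union += length
                    if in_a != in_b:
                        unique += length
            d[i, j] = d[j, i] = unique / union if union else 0.0
    return d


class TestUnweightedUnifrac:
    def test_identical_presence_zero(self):
        tree = tree_from_newick("((A:1,B:2):1,C:3):0;")
        t = CountTable(pd.DataFrame([[1, 5, 0], [9, 1, 0]], index=["s1", "s2"],
                                     columns=["A", "B", "C"]))
        assert unweighted_unifrac(t, tree)["s1", "s2"] == 0.0

    def test_star_tree_disjoint_is_one(self):
        tree = tree_from_newick("(A:1,B:1,C:1,D:1):0;")
        t = CountTable(pd.DataFrame([[1, 1, 0, 0], [0, 0, 1, 1]],
                                     index=["s1", "s2"], columns=list("ABCD")))
        assert unweighted_unifrac(t, tree)["s1", "s2"] == pytest.approx(1.0)

    def test_missing_taxon_named(self):
        tree = tree_from_newick("(A:1,B:1):0;")
        t = CountTable(pd.DataFrame([[1, 1]], index=["s"], columns=["A", "Z"]))
        with pytest.raises(KeyError, match="Z"):
            unweighted_unifrac(t, tree)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_tree_matches_branch_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        taxa = [f"t{i}" for i in range(8)]
        tree = generate_tree(taxa, seed=seed)
        counts = rng.integers(0, 3, size=(5, 8))
        counts[:, 0] += 1  # avoid empty samples
        t = CountTable(pd.DataFrame(counts, index=[f"s{i}" for i in range(5)], columns=taxa))
        ours = unweighted_unifrac(t, tree).data
        oracle = unifrac_branch_enumeration(t, tree)
        assert np.allclose(ours, oracle, atol=1e-10)

    def test_matches_skbio(self):
        rng = np.random.default_rng(3)
        taxa = [f"t{i}" for i in range(8)]
        tree = generate_tree(taxa, seed=11)
        counts = rng.integers(0, 4, size=(4, 8))
        counts[:, 0] += 1
        t = CountTable(pd.DataFrame(counts, index=[f"s{i}" for i in range(4)], columns=taxa))
        ours = unweighted_unifrac(t, tree).data
        from skbio.diversity import beta_diversity

        ref = beta_diversity(
            "unweighted_unifrac", t.counts, ids=t.sample_ids,
            taxa=t.taxon_ids, tree=tree,
        ).data
        assert np.allclose(ours, ref, atol=1e-10)


class TestPcoa:
    def test_recovers_planar_configuration(self, rng):
        pts = rng.normal(size=(7, 2))
        d = DistanceMatrix(squareform(pdist(pts)), ids=[f"s{i}" for i in range(7)])
        res = pcoa(d)
        rec = squareform(pdist(res.coordinates[["PC1", "PC2"]].to_numpy()))
        assert np.allclose(rec, d.data, atol=1e-8)

    def test_duplicated_sample_identical_coordinates(self):
        pts = np.array([[0.0, 0], [1, 0], [1, 0], [0, 2]])
        d = DistanceMatrix(squareform(pdist(pts)), ids=list("abcd"))
        res = pcoa(d)
        assert np.allclose(res.coordinates.loc["b"], res.coordinates.loc["c"], atol=1e-9)

    def test_percent_variance(self, rng):
        pts = rng.normal(size=(6, 3))
        d = DistanceMatrix(squareform(pdist(pts)), ids=[f"s{i}" for i in range(6)])
        res = pcoa(d)
        assert res.proportion_explained.sum() <= 100 + 1e-9
        assert (np.diff(res.eigenvalues) <= 1e-9).all()

    def test_sign_convention(self, rng):
        pts = rng.normal(size=(6, 2))
        d = DistanceMatrix(squareform(pdist(pts)), ids=[f"s{i}" for i in range(6)])
        coords = pcoa(d).coordinates.to_numpy()
        for k in range(coords.shape[1]):
            assert coords[np.argmax(np.abs(coords[:, k])), k] > 0

    def test_matches_skbio_eigenvalues(self, rng):
        t = random_count_table(rng, n_samples=6, n_taxa=10)
        t = CountTable(pd.DataFrame(t.counts + 1, index=t.sample_ids, columns=t.taxon_ids))
        dm = bray_curtis(t)
        ours = pcoa(dm)
        ref = skbio_pcoa(dm, number_of_dimensions=0)
        pos = ours.eigenvalues[ours.eigenvalues > 1e-10]
        assert np.allclose(pos, ref.eigvals.to_numpy()[: len(pos)], atol=1e-8)

    def test_nan_rejected(self):
        d = DistanceMatrix(np.zeros((3, 3)), ids=list("abc"))
        d.data[0, 1] = d.data[1, 0] = np.nan
        with pytest.raises(ValueError):
            pcoa(d)


def permanova_direct_f(d, labels):
    """Brute-force pseudo-F from the distance-based SS decomposition."""
    labels = np.asarray(labels)
    n = len(labels)
    groups = np.unique(labels)
    ss_total = sum(d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        ss_within += sum(
            d[i, j] ** 2 for i in idx for j in idx if i < j
        ) / len(idx)
    ss_among = ss_total - ss_within
    k = len(groups)
    return (ss_among / (k - 1)) / (ss_within / (n - k))


class TestPermanova:
    def test_f_matches_direct_oracle_n6(self, rng):
        pts = rng.normal(size=(6, 2))
        dm = DistanceMatrix(squareform(pdist(pts)), ids=[f"s{i}" for i in range(6)])
        labels = ["a", "a", "a", "b", "b", "b"]
        res = permanova(dm, labels, n_perm=99, seed=0)
        assert res.pseudo_f == pytest.approx(permanova_direct_f(dm.data, labels), abs=1e-10)

    def test_f_matches_skbio(self, rng):
        pts = rng.normal(size=(10, 3))
        dm = DistanceMatrix(squareform(pdist(pts)), ids=[f"s{i}" for i in range(10)])
        labels = ["a"] * 5 + ["b"] * 5
        ours = permanova(dm, labels, n_perm=9, seed=0)
        ref = skbio_permanova(dm, grouping=np.array(labels), permutations=9)
        assert ours.pseudo_f == pytest.approx(ref["test statistic"], abs=1e-10)

    def test_maximal_separation_minimal_p(self):
        d = np.full((20, 20), 10.0)
        d[:10, :10] = 0.01
        d[10:, 10:] = 0.01
        np.fill_diagonal(d, 0)
        dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(20)])
        res = permanova(dm, ["a"] * 10 + ["b"] * 10, n_perm=1000, seed=1)
        assert res.p_value == pytest.approx(1 / 1001)

    def test_seed_reproducible(self, rng):
        pts = rng.normal(size=(10, 2))
        dm = DistanceMatrix(squareform(pdist(pts)), ids=[f"s{i}" for i in range(10)])
        labels = ["a"] * 5 + ["b"] * 5
        a = permanova(dm, labels, n_perm=200, seed=7)
        b = permanova(dm, labels, n_perm=200, seed=7)
        assert a.p_value == b.p_value

    def test_single_group_error(self, rng):
        pts = rng.normal(size=(4, 2))
        dm = DistanceMatrix(squareform(pdist(pts)), ids=list("abcd"))
        with pytest.raises(ValueError):
            permanova(dm, ["x"] * 4, n_perm=10, seed=0)


class TestRarefactionCurves:
    def test_depth_equal_total_recovers_richness(self, meta_paired, rng):
        # all samples share the same total, so subsampling at that depth is
        # the identity and observed richness must equal the unrarefied value
        counts = rng.multinomial(200, np.full(6, 1 / 6), size=9)
        t = CountTable(pd.DataFrame(counts, index=meta_paired.index,
                                     columns=[f"t{j}" for j in range(6)]))
        curves = rarefaction_curves(t, meta_paired, [200], reps=1, seed=0)
        obs = curves[curves["index"] == "observed_otus"].set_index("stratum")
        richness = pd.Series((t.counts > 0).sum(axis=1), index=t.data.index, dtype=float)
        from microconet.io import strata

        for stratum, idx in strata(meta_paired).items():
            assert obs.loc[stratum, "mean"] == pytest.approx(richness[idx].mean())

    def test_monotone_observed_with_depth(self, meta_paired, rng):
        counts = rng.integers(0, 60, size=(9, 15))
        counts[:, 0] += 50
        t = CountTable(pd.DataFrame(counts, index=meta_paired.index,
                                     columns=[f"t{j}" for j in range(15)]))
        dmax = int(t.sample_totals().min())
        curves = rarefaction_curves(t, meta_paired, [dmax // 4, dmax // 2, dmax],
                                    reps=20, seed=5)
        for (stratum, _), block in curves[curves["index"] == "observed_otus"].groupby(
            ["stratum", "index"]
        ):
            means = block.sort_values("depth")["mean"].to_numpy()
            assert (np.diff(means) >= -0.5).all()  # nondecreasing within MC noise

    def test_reproducible_with_seed(self, meta_paired, rng):
        counts = rng.integers(1, 30, size=(9, 8))
        t = CountTable(pd.DataFrame(counts, index=meta_paired.index,
                                     columns=[f"t{j}" for j in range(8)]))
        d = int(t.sample_totals().min())
        a = rarefaction_curves(t, meta_paired, [d // 2], reps=1, seed=9)
        b = rarefaction_curves(t, meta_paired, [d // 2], reps=1, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestPc1PairedTest:
    def _ordination(self, coords, ids):
        from microconet.diversity import OrdinationResult

        return OrdinationResult(
            coordinates=pd.DataFrame({"PC1": coords}, index=ids),
            eigenvalues=np.array([1.0]),
            proportion_explained=np.array([100.0]),
        )

    def test_identical_timepoints_error(self, meta_paired):
        ids = list(meta_paired.index)
        ordn = self._ordination(np.ones(len(ids)), ids)
        with pytest.raises(ValueError, match="nonzero"):
            pc1_paired_test(ordn, meta_paired)

    def test_hand_built_case_matches_direct_wilcoxon(self):
        from microconet.stats import wilcoxon_signed_rank

        rows = []
        pc1 = {}
        rng = np.random.default_rng(4)
        for i in range(6):
            rows.append((f"e{i}t0", "ERA", "T0", f"E{i}"))
            rows.append((f"e{i}t1", "ERA", "T1", f"E{i}"))
            pc1[f"e{i}t0"] = rng.normal()
            pc1[f"e{i}t1"] = rng.normal(1.0)
        meta = pd.DataFrame(rows, columns=["sample_id", "group", "timepoint", "subject_id"])
        meta = meta.set_index("sample_id")
        ids = list(meta.index)
        ordn = self._ordination(np.array([pc1[s] for s in ids]), ids)
        w, p = pc1_paired_test(ordn, meta)
        diffs = [pc1[f"e{i}t1"] - pc1[f"e{i}t0"] for i in range(6)]
        w_ref, p_ref = wilcoxon_signed_rank(np.array(diffs))
        assert (w, p) == (w_ref, p_ref)

    def test_unpaired_subject_dropped_with_warning(self, meta_paired):
        meta = meta_paired.drop(index="e2t1")
        ids = list(meta.index)
        rng = np.random.default_rng(8)
        ordn = self._ordination(rng.normal(size=len(ids)), ids)
        with pytest.warns(UserWarning, match="E2"):
            pc1_paired_test(ordn, meta)
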