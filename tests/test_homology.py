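"""Correlation, RBH matching, complete linkage and multiscale bootstrap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.cluster import hierarchy as sch

from orthotype import (
    build_dendrogram,
    complete_linkage,
    correlate_celltypes,
    correlation_distance,
    bootstrap_support,
    joint_profiles,
    reciprocal_best_hits,
)
from orthotype.errors import DataError
from orthotype.homology import fit_au, DEFAULT_SCALES, _linkage_clades
from orthotype.preprocess import SpecificityMatrix


def _spec(values: pd.DataFrame, sizes=None) -> SpecificityMatrix:
    sizes = sizes if sizes is not None else pd.Series(10, index=values.columns)
    # rescale columns so the weighted-mean identity holds (not needed for
    # correlation, but keeps the container honest)
    return SpecificityMatrix(
        values=values.clip(lower=0),
        cluster_sizes=sizes,
        N=int(sizes.sum()),
        normalization_tag="test",
    )


class TestCorrelation:
    def test_identical_vectors_correlate_at_one(self):
        v = pd.DataFrame({"a": [1.0, 2, 3, 4]}, index=list("wxyz"))
        corr = correlate_celltypes(_spec(v), _spec(v.rename(columns={"a": "b"})))
        assert corr.loc["a", "b"] == pytest.approx(1.0)

    def test_affine_negation_correlates_at_minus_one(self):
        x = np.array([0.5, 1.5, 3.0, 4.0])
        v1 = pd.DataFrame({"a": x}, index=list("wxyz"))
        v2 = pd.DataFrame({"b": 5.0 - x}, index=list("wxyz"))
        corr = correlate_celltypes(_spec(v1), _spec(v2))
        assert corr.loc["a", "b"] == pytest.approx(-1.0)

    def test_species_swap_transposes(self):
        rng = np.random.default_rng(0)
        v1 = pd.DataFrame(rng.random((20, 3)), columns=["a", "b", "c"],
                          index=[str(i) for i in range(20)])
        v2 = pd.DataFrame(rng.random((20, 4)), columns=list("wxyz"),
                          index=[str(i) for i in range(20)])
        c12 = correlate_celltypes(_spec(v1), _spec(v2))
        c21 = correlate_celltypes(_spec(v2), _spec(v1))
        pd.testing.assert_frame_equal(c12, c21.T, atol=1e-12)

    def test_too_few_shared_genes_is_an_error(self):
        v1 = pd.DataFrame({"a": [1.0, 2]}, index=["1", "2"])
        v2 = pd.DataFrame({"b": [1.0, 2]}, index=["2", "3"])
        with pytest.raises(DataError, match="shared orthogroups"):
            correlate_celltypes(_spec(v1), _spec(v2))

    def test_zero_variance_vector_excluded_from_matching(self):
        v1 = pd.DataFrame({"flat": [1.0, 1, 1, 1], "var": [0.0, 1, 2, 3]},
                          index=list("wxyz"))
        v2 = pd.DataFrame({"t": [0.0, 1, 2, 3]}, index=list("wxyz"))
        corr = correlate_celltypes(_spec(v1), _spec(v2))
        assert np.isnan(corr.loc["flat", "t"])
        rbh = reciprocal_best_hits(corr)
        assert list(rbh["s1_type"]) == ["var"]

    def test_gene_set_restriction(self):
        rng = np.random.default_rng(5)
        idx = [str(i) for i in range(30)]
        v1 = pd.DataFrame(rng.random((30, 2)), columns=["a", "b"], index=idx)
        v2 = pd.DataFrame(rng.random((30, 2)), columns=["x", "y"], index=idx)
        full = correlate_celltypes(_spec(v1), _spec(v2))
        sub = correlate_celltypes(_spec(v1), _spec(v2), gene_set=idx[:10])
        assert not np.allclose(full.to_numpy(), sub.to_numpy())


class TestRBH:
    def test_mutual_best_pairs(self):
        corr = pd.DataFrame([[0.9, 0.1], [0.2, 0.8]], index=["a1", "a2"],
                            columns=["b1", "b2"])
        rbh = reciprocal_best_hits(corr)
        assert set(zip(rbh.s1_type, rbh.s2_type)) == {("a1", "b1"), ("a2", "b2")}

    def test_non_mutual_leaves_type_unmatched(self):
        corr = pd.DataFrame([[0.9, 0.95], [0.2, 0.1]], index=["a1", "a2"],
                            columns=["b1", "b2"])
        rbh = reciprocal_best_hits(corr)
        assert set(zip(rbh.s1_type, rbh.s2_type)) == {("a1", "b2")}

    def test_exact_ties_flagged_and_lexicographic(self):
        corr = pd.DataFrame([[0.5, 0.5]], index=["a1"], columns=["b2", "b1"])
        rbh = reciprocal_best_hits(corr)
        assert list(rbh.s2_type) == ["b1"]
        assert bool(rbh.tie.iloc[0])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 6), st.integers(2, 6))
    def test_output_is_a_partial_matching(self, seed, n1, n2):
        rng = np.random.default_rng(seed)
        corr = pd.DataFrame(
            rng.uniform(-1, 1, size=(n1, n2)),
            index=[f"a{i}" for i in range(n1)],
            columns=[f"b{j}" for j in range(n2)],
        )
        rbh = reciprocal_best_hits(corr)
        assert rbh.s1_type.is_unique and rbh.s2_type.is_unique


class TestCompleteLinkage:
    def test_forced_topology(self):
        d = np.array([[0.0, 0.1, 0.9], [0.1, 0.0, 0.9], [0.9, 0.9, 0.0]])
        tree = complete_linkage(d, ["A", "B", "C"])
        assert tree.clades() == [frozenset("AB"), frozenset("ABC")]
        assert [h for _, _, h in tree.merges] == pytest.approx([0.1, 0.9])

    def test_duplicated_leaf_merges_first_at_height_zero(self):
        x = np.array([[1.0, 1.0, 5.0], [2.0, 2.0, 1.0], [3.0, 3.0, 0.5]])
        tree = build_dendrogram(pd.DataFrame(x, columns=["dupA", "dupB", "other"]))
        assert tree.clades()[0] == frozenset({"dupA", "dupB"})
        assert tree.merges[0][2] == pytest.approx(0.0, abs=1e-12)

    def test_agrees_with_scipy_oracle_on_random_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            pts = rng.random((8, 5))
            d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            labels = [f"L{i}" for i in range(8)]
            tree = complete_linkage(d, labels)
            z = sch.linkage(d[np.triu_indices(8, 1)], method="complete")
            # same merge heights and same clades
            assert np.allclose(sorted(h for _, _, h in tree.merges), sorted(z[:, 2]))
            assert _scipy_clades(z, labels) == set(tree.clades())

    def test_nan_distance_is_an_error_naming_the_pair(self):
        profiles = pd.DataFrame(
            {"flat": [1.0, 1.0, 1.0], "a": [0.0, 1, 2], "b": [2.0, 1, 0]}
        )
        with pytest.raises(DataError, match="flat"):
            build_dendrogram(profiles)

    def test_deterministic_tie_break(self):
        # three equidistant leaves: the lexicographically smallest pair merges
        d = np.ones((3, 3)) - np.eye(3)
        tree = complete_linkage(d, ["C", "A", "B"])
        assert tree.clades()[0] == frozenset({"A", "B"})

    def test_newick_contains_all_leaves(self):
        d = np.array([[0.0, 0.2, 0.7], [0.2, 0.0, 0.7], [0.7, 0.7, 0.0]])
        nwk = complete_linkage(d, ["x", "y", "z"]).to_newick()
        for leaf in ("x", "y", "z"):
            assert leaf in nwk
        assert nwk.endswith(";")


def _scipy_clades(z, labels):
    n = len(labels)
    sets = {i: frozenset([labels[i]]) for i in range(n)}
    out = set()
    for k, (a, b, _, _) in enumerate(z):
        s = sets[int(a)] | sets[int(b)]
        sets[n + k] = s
        out.add(s)
    return out


class TestBootstrap:
    def test_duplicated_profiles_get_full_support_at_every_scale(self):
        rng = np.random.default_rng(7)
        base = rng.random((60, 4))
        profiles = pd.DataFrame(
            np.column_stack([base[:, 0], base[:, 0], base[:, 1:]]),
            columns=["twinA", "twinB", "u", "v", "w"],
        )
        support = bootstrap_support(profiles, n_boot=100, seed=1)
        row = support.for_clade(frozenset({"twinA", "twinB"}))
        assert row is not None
        assert row["bp"] == 100.0
        for r in support.scales:
            assert row[f"bp_{r:g}"] == 1.0
        assert row["au"] == 100.0 and row["flag"] == "degenerate_bp"

    def test_constant_half_bp_fits_to_au_fifty(self):
        au, flag = fit_au(np.full(len(DEFAULT_SCALES), 0.5), DEFAULT_SCALES, 1000)
        assert au == pytest.approx(50.0, abs=1e-9)
        assert flag == ""

    def test_degenerate_and_unavailable_flags(self):
        au, flag = fit_au(np.zeros(10), DEFAULT_SCALES, 1000)
        assert (au, flag) == (0.0, "degenerate_bp")
        bp = np.zeros(10)
        bp[5] = 0.4  # single usable scale
        au, flag = fit_au(bp, DEFAULT_SCALES, 1000)
        assert np.isnan(au) and flag == "au_unavailable"

    def test_bp_invariant_to_leaf_permutation(self):
        rng = np.random.default_rng(9)
        profiles = pd.DataFrame(
            rng.random((80, 5)) + np.arange(5) * 0.2, columns=list("abcde")
        )
        s1 = bootstrap_support(profiles, n_boot=60, seed=4)
        s2 = bootstrap_support(profiles[["d", "b", "a", "e", "c"]], n_boot=60, seed=4)
        bp1 = dict(zip(s1.table["clade"], s1.table["bp"]))
        bp2 = dict(zip(s2.table["clade"], s2.table["bp"]))
        assert bp1 == bp2

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(10)
        profiles = pd.DataFrame(rng.random((40, 4)), columns=list("abcd"))
        a = bootstrap_support(profiles, n_boot=50, seed=3)
        b = bootstrap_support(profiles, n_boot=50, seed=3)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_root_clade_always_supported(self):
        rng = np.random.default_rng(11)
        profiles = pd.DataFrame(rng.random((40, 4)), columns=list("abcd"))
        s = bootstrap_support(profiles, n_boot=50, seed=5)
        root = s.for_clade(frozenset("abcd"))
        assert root["bp"] == 100.0

    def test_linkage_clades_matches_full_builder(self):
        rng = np.random.default_rng(12)
        x = rng.random((30, 6))
        d = correlation_distance(x, strict=False)
        fast = set(_linkage_clades(d))
        labels = [str(i) for i in range(6)]
        slow = {
            frozenset(int(l) for l in cl)
            for cl in complete_linkage(d, labels).clades()
        }
        assert fast == slow


class TestJointProfiles:
    def test_prefixed_columns_over_shared_genes(self):
        idx = [str(i) for i in range(10)]
        v1 = pd.DataFrame(np.random.default_rng(0).random((10, 2)),
                          columns=["a", "b"], index=idx)
        v2 = pd.DataFrame(np.random.default_rng(1).random((10, 2)),
                          columns=["x", "y"], index=idx)
        joint = joint_profiles(_spec(v1), _spec(v2))
        assert list(joint.columns) == ["s1.a", "s1.b", "s2.x", "s2.y"]

    def test_monotone_degradation_with_divergence(self):
        # increasing simulator divergence never increases mean true-pair r
        from orthotype import (
            SimConfig,
            cluster_means,
            collapse_to_metagenes,
            normalize,
            simulate_atlas_pair,
            specificity_index,
        )

        mean_rs = []
        for div in (0.0, 0.5, 1.0):
            cfg = SimConfig(
                n_orthogroups=300, n_shared_families=4, n_private_s1=0,
                n_private_s2=0, cells_per_type=40, baseline_mean=1.0,
                divergence=div, seed=21,
            )
            data, truth = simulate_atlas_pair(cfg)
            specs = {}
            for sp in ("s1", "s2"):
                cm, ann = data[sp]
                meta, _ = collapse_to_metagenes(cm, truth.orthomap, sp)
                nm = normalize(meta)
                means, sizes = cluster_means(nm, ann)
                specs[sp] = specificity_index(means, sizes)
            corr = correlate_celltypes(specs["s1"], specs["s2"])
            mean_rs.append(np.mean([corr.loc[a, b] for a, b in truth.true_pairs]))
        assert mean_rs[0] >= mean_rs[1] >= mean_rs[2]
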