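"""Bray-Curtis distances, normalised functional distance, and NMDS."""

import numpy as np
import pytest
from scipy.spatial.distance import braycurtis as scipy_bc
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr

import tpsevo as t
from tpsevo.errors import InputError, UndefinedDistanceError


class TestBrayCurtis:
    def test_identity_and_disjoint(self):
        assert t.bray_curtis([0.3, 0.7], [0.3, 0.7]) == 0.0
        assert t.bray_curtis([1.0, 0.0], [0.0, 1.0]) == 1.0

    def test_matches_scipy_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p, q = rng.random(6), rng.random(6)
            assert t.bray_curtis(p, q) == pytest.approx(scipy_bc(p, q), rel=1e-12)

    def test_half_l1_on_unit_sum_compositions(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            p = rng.dirichlet(np.ones(5))
            q = rng.dirichlet(np.ones(5))
            assert t.bray_curtis(p, q) == pytest.approx(
                0.5 * np.abs(p - q).sum(), rel=1e-12)

    def test_name_union_vocabulary(self):
        # hand computation on a 2-product toy with disjoint vocabularies
        assert t.bray_curtis({"ISO": 1.0}, {"SAN": 1.0}) == 1.0
        assert t.bray_curtis({"ISO": 0.5, "SAN": 0.5},
                             {"SAN": 0.5, "PIM": 0.5}) == pytest.approx(0.5)

    def test_both_all_zero_is_undefined(self):
        with pytest.raises(UndefinedDistanceError):
            t.bray_curtis({}, {})

    def test_profile_inputs(self, make_profile):
        anc = make_profile({"SAN": 1.0})
        mut = make_profile({"ISO": 0.9, "SAN": 0.1})
        assert t.bray_curtis(mut, anc) == pytest.approx(0.9)


class TestFunctionalDistance:
    def test_identity_and_self_normalisation(self, make_profile):
        anc = make_profile({"SAN": 1.0})
        assert t.functional_distance(anc, anc) == 0.0
        ref = {t.FOCAL_PRODUCT: 1.0}
        assert t.functional_distance(ref, anc, ref) == pytest.approx(1.0)

    def test_hand_computed_example(self, make_profile):
        anc = make_profile({"SAN": 1.0})
        mut = make_profile({t.FOCAL_PRODUCT: 0.9, "SAN": 0.1})
        assert t.functional_distance(mut, anc) == pytest.approx(0.9)

    def test_reference_equal_to_ancestor_is_undefined(self, make_profile):
        anc = make_profile({t.FOCAL_PRODUCT: 1.0})
        with pytest.raises(UndefinedDistanceError):
            t.functional_distance(anc, anc)


class TestDistanceMatrix:
    def test_identical_pair_gives_single_zero_off_diagonal(self, make_profile):
        profs = [make_profile({"ISO": 0.8, "SAN": 0.2}, "a"),
                 make_profile({"ISO": 0.8, "SAN": 0.2}, "b"),
                 make_profile({"SAN": 1.0}, "c")]
        dm = t.distance_matrix(profs)
        off = dm.values[np.triu_indices(3, 1)]
        assert (off == 0).sum() == 1
        assert np.allclose(dm.values, dm.values.T)
        assert np.all(np.diag(dm.values) == 0)

    def test_inactive_profiles_excluded(self, make_profile):
        inactive = t.ProductProfile("dead", (), np.array([]), np.array([]),
                                    n=0, active=False)
        profs = [make_profile({"ISO": 1.0}, "a"), make_profile({"SAN": 1.0}, "b"),
                 make_profile({"PIM": 1.0}, "c"), inactive]
        dm = t.distance_matrix(profs)
        assert "dead" not in dm.ids and len(dm.ids) == 3

    def test_fewer_than_three_active_is_error(self, make_profile):
        with pytest.raises(InputError):
            t.distance_matrix([make_profile({"ISO": 1.0}, "a"),
                               make_profile({"SAN": 1.0}, "b")])

    def test_union_vocabulary_matches_manual(self, make_profile):
        profs = [make_profile({"ISO": 1.0}, "a"),
                 make_profile({"SAN": 0.5, "PIM": 0.5}, "b"),
                 make_profile({"ISO": 0.5, "PIM": 0.5}, "c")]
        dm = t.distance_matrix(profs)
        i, j = dm.ids.index("a"), dm.ids.index("b")
        assert dm.values[i, j] == pytest.approx(1.0)
        assert dm.values[dm.ids.index("a"), dm.ids.index("c")] == pytest.approx(0.5)


class TestIsotonic:
    def test_already_monotone_unchanged(self):
        d = np.array([1.0, 2.0, 5.0])
        np.testing.assert_allclose(
            t.isotonic_disparities([0.1, 0.2, 0.3], d), d)

    def test_pava_pools_violators(self):
        np.testing.assert_allclose(
            t.isotonic_disparities([0.1, 0.2, 0.3], [3.0, 1.0, 2.0]),
            [2.0, 2.0, 2.0])

    def test_constant_input_constant_output(self):
        np.testing.assert_allclose(
            t.isotonic_disparities([0.3, 0.1, 0.2], [4.0, 4.0, 4.0]), 4.0)


def embeddable_dm(n=10, dims=3, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, dims))
    D = squareform(pdist(X))
    return t.DistanceMatrix(tuple(f"p{i}" for i in range(n)), D / D.max()), X


class TestNMDS:
    def test_exact_euclidean_distances_recover_zero_stress(self):
        dm, _ = embeddable_dm()
        emb = t.nmds(dm, dims=3, n_starts=5, seed=0)
        assert emb.stress <= 1e-4

    def test_regular_tetrahedron(self):
        vals = np.ones((4, 4)) - np.eye(4)
        dm = t.DistanceMatrix(("a", "b", "c", "d"), vals)
        emb = t.nmds(dm, dims=3, n_starts=5, seed=0)
        assert emb.stress <= 1e-4

    def test_monotone_transform_recovers_rank_structure(self):
        # distances pushed through a monotone transform: NMDS should recover
        # the planted configuration's distance ranks
        dm, X = embeddable_dm(10, 3, seed=3)
        warped = t.DistanceMatrix(dm.ids, np.sqrt(dm.values))
        emb = t.nmds(warped, dims=3, n_starts=10, seed=1)
        rho = spearmanr(pdist(X), pdist(emb.coords)).statistic
        assert rho >= 0.99

    def test_stress_history_non_increasing(self):
        dm, _ = embeddable_dm(8, 2, seed=5)
        emb = t.nmds(dm, dims=3, n_starts=3, seed=2)
        hist = emb.stress_history
        assert all(a >= b for a, b in zip(hist, hist[1:]))

    def test_bit_reproducible_given_seed(self):
        dm, _ = embeddable_dm(9, 3, seed=6)
        e1 = t.nmds(dm, dims=3, n_starts=4, seed=11)
        e2 = t.nmds(dm, dims=3, n_starts=4, seed=11)
        assert e1.stress == e2.stress
        assert np.array_equal(e1.coords, e2.coords)

    def test_coords_centred(self):
        dm, _ = embeddable_dm(7, 3, seed=7)
        emb = t.nmds(dm, dims=2, n_starts=3, seed=0)
        np.testing.assert_allclose(emb.coords.mean(axis=0), 0.0, atol=1e-10)

    def test_stress_invariant_to_similarity_transforms(self):
        dm, _ = embeddable_dm(8, 3, seed=8)
        emb = t.nmds(dm, dims=3, n_starts=3, seed=3)
        delta = dm.condensed()
        base = t.stress1(delta, emb.coords)
        rng = np.random.default_rng(0)
        M = np.linalg.qr(rng.standard_normal((3, 3)))[0]  # random rotation
        transformed = 2.5 * emb.coords @ M + rng.standard_normal(3)
        assert t.stress1(delta, transformed) == pytest.approx(base, abs=1e-10)

    def test_dims_must_be_below_n_points(self):
        dm, _ = embeddable_dm(4, 3)
        with pytest.raises(InputError):
            t.nmds(dm, dims=4)


# ---------------------------------------------------------------------------
# Property-based checks
# ---------------------------------------------------------------------------

from hypothesis import given, settings, strategies as st


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.floats(0.01, 10.0), min_size=2, max_size=8),
       st.lists(st.floats(0.01, 10.0), min_size=2, max_size=8))
def test_bray_curtis_bounded_symmetric(p, q):
    n = min(len(p), len(q))
    p, q = np.asarray(p[:n]), np.asarray(q[:n])
    d = t.bray_curtis(p, q)
    assert 0.0 <= d <= 1.0
    assert d == pytest.approx(t.bray_curtis(q, p))
    assert t.bray_curtis(p, p) == 0.0


@settings(derandomize=True, max_examples=30)
@given(st.lists(st.floats(0.0, 5.0), min_size=2, max_size=20),
       st.lists(st.floats(0.0, 5.0), min_size=2, max_size=20))
def test_isotonic_output_monotone_in_rank(diss, dist):
    n = min(len(diss), len(dist))
    diss, dist = np.asarray(diss[:n]), np.asarray(dist[:n])
    out = t.isotonic_disparities(diss, dist)
    order = np.argsort(diss, kind="stable")
    assert np.all(np.diff(out[order]) >= -1e-12)
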