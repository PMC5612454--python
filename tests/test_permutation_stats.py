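"""Condition-relabelling permutation null and quantile thresholds."""

import numpy as np
import pytest

from ssrsa.core_rdm import DynamicRDM, RDM, upper_triangle_vector
from ssrsa.feature_space import FeatureMatrix
from ssrsa.machine_states import PhoneModelSet
from ssrsa.permutation_stats import (
    FeatureFitMap,
    NullDistribution,
    build_null,
    most_conservative_quantiles,
    observed_feature_fits,
    permutation_matrix_indices,
    permute_conditions,
    threshold_feature_maps,
)
from tests.conftest import conditions, random_rdm


@pytest.fixture
def small_fm():
    return FeatureMatrix(
        features=("f1", "f2", "f3", "f4"),
        categories=("broad",) * 4,
        phones=("a", "b", "c"),
        indicator=np.array(
            [[1, 0, 0], [1, 1, 0], [0, 1, 1], [1, 1, 1]]
        ),
    )


def make_setup(rng, n_cond=7, n_vert=3, n_win=2, phones=("a", "b", "c")):
    cs = conditions(n_cond)
    model_drdms = {
        p: DynamicRDM(
            tuple(
                RDM(cs, random_rdm(n_cond, rng).values)
                for _ in range(n_win)
            ),
            60,
            10,
        )
        for p in phones
    }
    ms = PhoneModelSet(tuple(phones), model_drdms)
    data = {
        v: DynamicRDM(
            tuple(
                RDM(cs, random_rdm(n_cond, rng).values)
                for _ in range(n_win)
            ),
            60,
            10,
        )
        for v in range(n_vert)
    }
    return data, ms


class TestPermuteConditions:
    def test_identity_permutation_is_noop(self, rng):
        rdm = random_rdm(6, rng)
        out = permute_conditions(rdm, range(6))
        assert np.allclose(out.values, rdm.values)

    def test_perm_then_inverse_restores(self, rng):
        rdm = random_rdm(6, rng)
        perm = np.random.default_rng(1).permutation(6)
        inv = np.argsort(perm)
        back = permute_conditions(permute_conditions(rdm, perm), inv)
        assert np.allclose(back.values, rdm.values, atol=0)

    def test_preserves_symmetry_and_zero_diagonal(self, rng):
        rdm = random_rdm(8, rng)
        out = permute_conditions(rdm, np.random.default_rng(2).permutation(8))
        assert np.allclose(out.values, out.values.T)
        assert np.allclose(np.diag(out.values), 0)

    def test_invalid_permutation_rejected(self, rng):
        with pytest.raises(ValueError):
            permute_conditions(random_rdm(5, rng), [0, 1, 2, 3, 3])

    def test_pair_index_map_matches_matrix_permutation(self, rng):
        rdm = random_rdm(9, rng)
        perm = np.random.default_rng(3).permutation(9)
        idx = permutation_matrix_indices(perm, 9)
        via_index = upper_triangle_vector(rdm)[idx]
        via_matrix = upper_triangle_vector(permute_conditions(rdm, perm))
        assert np.allclose(via_index, via_matrix, atol=0)


class TestBuildNull:
    def test_sample_counts(self, rng, small_fm):
        data, ms = make_setup(rng)
        with pytest.warns(UserWarning, match="below the recommended"):
            nulls = build_null(data, ms, small_fm, n_perm=2, seed=0)
        assert set(nulls) == {"f1", "f2", "f3", "f4"}
        assert all(nd.samples.size == 2 * 3 for nd in nulls.values())

    def test_seed_determinism(self, rng, small_fm):
        data, ms = make_setup(rng)
        with pytest.warns(UserWarning):
            a = build_null(data, ms, small_fm, n_perm=5, seed=42)
            b = build_null(data, ms, small_fm, n_perm=5, seed=42)
            c = build_null(data, ms, small_fm, n_perm=5, seed=43)
        for f in small_fm.features:
            assert np.array_equal(a[f].samples, b[f].samples)
        assert not all(
            np.array_equal(a[f].samples, c[f].samples)
            for f in small_fm.features
        )

    def test_independent_per_vertex_permutations_supported(
        self, rng, small_fm
    ):
        data, ms = make_setup(rng)
        with pytest.warns(UserWarning):
            shared = build_null(
                data, ms, small_fm, n_perm=4, seed=7,
                shared_permutation=True,
            )
            indep = build_null(
                data, ms, small_fm, n_perm=4, seed=7,
                shared_permutation=False,
            )
        assert all(
            indep[f].samples.size == shared[f].samples.size
            for f in small_fm.features
        )

    def test_null_matches_explicit_refit_loop(self, rng, small_fm):
        """Each null sample equals permuting the data RDMs and refitting."""
        from ssrsa.feature_space import all_feature_fits
        from ssrsa.glm_fitting import epoch_average_betas, fit_drdms

        data, ms = make_setup(rng, n_vert=2)
        n = ms.conditions.n
        with pytest.warns(UserWarning):
            nulls = build_null(data, ms, small_fm, n_perm=3, seed=11)
        # replay the generator's permutation stream
        replay = np.random.default_rng(11)
        for it in range(3):
            perm = replay.permutation(n)
            permuted = {
                v: DynamicRDM(
                    tuple(
                        permute_conditions(f, perm) for f in data[v].frames
                    ),
                    60,
                    10,
                )
                for v in data
            }
            glm = fit_drdms(permuted, ms)
            for j, v in enumerate(permuted):
                fits = all_feature_fits(
                    epoch_average_betas(glm[v]).betas, small_fm
                )
                for f in small_fm.features:
                    got = nulls[f].samples.reshape(3, 2)[it, j]
                    assert got == pytest.approx(fits[f], abs=1e-9)


class TestThresholding:
    def test_theta_monotone_in_quantile(self, rng):
        nd = NullDistribution("f", rng.standard_normal(5000))
        qs = [0.5, 0.9, 0.95, 0.99, 0.999]
        thetas = [nd.quantile(q) for q in qs]
        assert all(a <= b for a, b in zip(thetas, thetas[1:]))

    def test_no_survivors_when_fits_below_max_null(self, rng):
        samples = rng.standard_normal(1000)
        nd = NullDistribution("f", samples)
        fmap = FeatureFitMap("f", {0: samples.max() - 1e-9, 1: -5.0})
        out = threshold_feature_maps(
            {"f": fmap}, {"f": nd}, q=0.999999
        )
        # top order statistic: nothing exceeds the empirical supremum
        assert out["f"].surviving == ()

    def test_survivors_strictly_exceed_theta(self, rng):
        nd = NullDistribution("f", rng.standard_normal(1000))
        theta = nd.quantile(0.95)
        fits = {0: theta + 0.1, 1: theta, 2: theta - 0.1}
        out = threshold_feature_maps(
            {"f": FeatureFitMap("f", fits)}, {"f": nd}, 0.95
        )
        assert out["f"].surviving == (0,)

    def test_most_conservative_quantile_reporting(self, rng):
        samples = np.linspace(0, 1, 10_000)
        nd = NullDistribution("f", samples)
        high = {"f": FeatureFitMap("f", {0: 0.9995})}
        mid = {"f": FeatureFitMap("f", {0: 0.97})}
        none = {"f": FeatureFitMap("f", {0: 0.5})}
        assert most_conservative_quantiles(high, {"f": nd})["f"] == 0.999
        assert most_conservative_quantiles(mid, {"f": nd})["f"] == 0.95
        assert most_conservative_quantiles(none, {"f": nd})["f"] is None

    def test_empty_null_raises(self):
        nd = NullDistribution("f", np.array([]))
        with pytest.raises(ValueError, match="empty"):
            threshold_feature_maps(
                {"f": FeatureFitMap("f", {0: 1.0})}, {"f": nd}, 0.95
            )


class TestObservedFits:
    def test_matches_glm_plus_aggregation_path(self, rng, small_fm):
        from ssrsa.feature_space import all_feature_fits
        from ssrsa.glm_fitting import epoch_average_betas, fit_drdms

        data, ms = make_setup(rng)
        fits = observed_feature_fits(data, ms, small_fm)
        glm = fit_drdms(data, ms)
        for v in data:
            expected = all_feature_fits(
                epoch_average_betas(glm[v]).betas, small_fm
            )
            for f in small_fm.features:
                assert fits[f].fits[v] == pytest.approx(
                    expected[f], abs=1e-9
                )

    def test_relabelling_equivariance_of_whole_chain(self, rng, small_fm):
        """Permuting conditions identically everywhere changes nothing."""
        data, ms = make_setup(rng)
        perm = np.random.default_rng(9).permutation(7)
        data2 = {
            v: DynamicRDM(
                tuple(permute_conditions(f, perm) for f in d.frames),
                60,
                10,
            )
            for v, d in data.items()
        }
        ms2 = PhoneModelSet(
            ms.phones,
            {
                p: DynamicRDM(
                    tuple(
                        permute_conditions(f, perm)
                        for f in ms.drdms[p].frames
                    ),
                    60,
                    10,
                )
                for p in ms.phones
            },
        )
        a = observed_feature_fits(data, ms, small_fm)
        b = observed_feature_fits(data2, ms2, small_fm)
        for f in small_fm.features:
            for v in data:
                assert a[f].fits[v] == pytest.approx(
                    b[f].fits[v], abs=1e-9
                )
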