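"""Ground-truth synthetic generators for streams, meshes and epochs."""

import numpy as np
import pytest

from ssrsa.brain_states import SearchlightConfig, build_data_drdms
from ssrsa.core_rdm import RDM, rdm_from_response_matrix
from ssrsa.machine_states import build_model_set
from ssrsa.synthetic_data import (
    Implant,
    SyntheticSpec,
    embed_target_rdm,
    gen_likelihood_streams,
    gen_source_epochs,
    h0_spec,
    make_grid_mesh,
)
from tests.conftest import conditions


def small_spec(**kw):
    defaults = dict(
        n_conditions=10,
        n_subjects=2,
        grid_shape=(3, 3, 3),
        grid_spacing_mm=20.0,
        seed=5,
    )
    defaults.update(kw)
    return SyntheticSpec(**defaults)


class TestLikelihoodStreams:
    def test_same_seed_is_bit_identical(self):
        s1, _ = gen_likelihood_streams(small_spec())
        s2, _ = gen_likelihood_streams(small_spec())
        assert np.array_equal(s1.values, s2.values)
        assert s1.triphones == s2.triphones

    def test_different_seed_differs(self):
        s1, _ = gen_likelihood_streams(small_spec(seed=1))
        s2, _ = gen_likelihood_streams(small_spec(seed=2))
        assert not np.array_equal(s1.values, s2.values)

    def test_identical_phone_strings_give_zero_model_distance(self):
        from ssrsa.machine_states import build_phone_drdm

        spec = small_spec(stream_noise_sd=0.0)
        strings = [("p", "t", "k")] * 10
        streams, _ = gen_likelihood_streams(spec, strings)
        # onset 40 ms spans the p->t segment boundary, so the noiseless
        # likelihood vectors vary within the window (constant vectors are
        # rejected by the degenerate-input guard by design)
        for phone in ("p", "t"):
            drdm = build_phone_drdm(streams, phone, [40])
            assert drdm[0].values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_strings_far_in_unshared_phones(self):
        spec = small_spec(stream_noise_sd=0.1)
        strings = [("p", "t", "k")] * 5 + [("m", "n", "l")] * 5
        streams, _ = gen_likelihood_streams(spec, strings)
        ms = build_model_set(streams, ("p", "m"), [0])
        # conditions 0-4 carry phone p activity, 5-9 do not: distances
        # between the groups dominate within-group distances
        rdm = ms.drdms["p"][0].values
        within = rdm[:5, :5][np.triu_indices(5, 1)].mean()
        between = rdm[:5, 5:].mean()
        assert between > within

    def test_unknown_phone_rejected(self):
        spec = small_spec()
        with pytest.raises(ValueError, match="not in the declared"):
            gen_likelihood_streams(spec, [("zz", "p", "t")] * 10)

    def test_ground_truth_records_strings(self):
        strings = [("p", "t", "k")] * 10
        _, gt = gen_likelihood_streams(small_spec(), strings)
        assert gt.condition_phones == tuple(strings)


class TestEmbedTargetRdm:
    def test_zero_target_rows_nearly_identical(self, rng):
        target = np.zeros((5, 5))
        X = embed_target_rdm(target, 5000, rng)
        emp = rdm_from_response_matrix(X, conditions(5))
        assert np.abs(emp.values).max() < 0.05

    def test_random_target_recovered_at_large_m(self, rng):
        resp = rng.standard_normal((8, 30))
        target = rdm_from_response_matrix(resp, conditions(8))
        X = embed_target_rdm(target, 10_000, rng)
        emp = rdm_from_response_matrix(X, target.conditions)
        assert np.abs(emp.values - target.values).max() < 0.05

    def test_seed_reproducibility(self, rng):
        target = np.zeros((4, 4)) + 0.5 - 0.5 * np.eye(4)
        a = embed_target_rdm(target, 100, 7)
        b = embed_target_rdm(target, 100, 7)
        assert np.array_equal(a, b)

    def test_invalid_target_rejected(self, rng):
        with pytest.raises(ValueError, match="\\[0, 2\\]"):
            embed_target_rdm(np.full((3, 3), 5.0) - 5 * np.eye(3), 10, rng)


class TestGridMesh:
    def test_shape_and_spacing(self):
        mesh = make_grid_mesh((2, 3, 4), 5.0)
        assert mesh.n_vertices == 24
        assert mesh.mask.all()
        assert np.allclose(mesh.coords.max(axis=0), [5.0, 10.0, 15.0])


class TestSourceEpochs:
    def test_same_seed_identical_epochs(self):
        spec = small_spec()
        e1, _, _ = gen_source_epochs(spec)
        e2, _, _ = gen_source_epochs(spec)
        assert np.array_equal(e1.data, e2.data)

    def test_time_axis_covers_lagged_epoch(self):
        spec = small_spec()
        epochs, _, _ = gen_source_epochs(spec)
        assert epochs.n_samples == spec.lag_ms + spec.epoch_ms

    def test_amplitude_zero_is_pure_noise(self):
        strings = [("p", "t", "k")] * 10
        spec0 = small_spec(implants=())
        streams, _ = gen_likelihood_streams(spec0, strings)
        cfg = SearchlightConfig()
        ms = build_model_set(streams, ("p", "t", "k"), cfg.window_onsets)
        spec_implant = small_spec(
            implants=(Implant(13, 20.0, "p", amplitude=0.0),)
        )
        e_implant, _, _ = gen_source_epochs(spec_implant, ms)
        e_noise, _, _ = gen_source_epochs(small_spec(implants=()), ms)
        # amplitude 0 adds nothing; only the rng draw for the embed blocks
        # differs, so compare statistics rather than bits
        assert np.std(e_implant.data) == pytest.approx(
            np.std(e_noise.data), rel=0.05
        )
        assert np.abs(e_implant.data.mean()) < 0.01

    def test_overlapping_implants_rejected(self):
        strings = [("p", "t", "k")] * 10
        spec0 = small_spec()
        streams, _ = gen_likelihood_streams(spec0, strings)
        cfg = SearchlightConfig()
        ms = build_model_set(streams, ("p", "t", "k"), cfg.window_onsets)
        spec = small_spec(
            implants=(
                Implant(13, 20.0, "p"),
                Implant(14, 20.0, "t"),
            )
        )
        with pytest.raises(ValueError, match="overlap"):
            gen_source_epochs(spec, ms)

    def test_implanted_geometry_visible_at_centre(self):
        """The data RDM at the implant centre correlates with the target."""
        strings = [("p", "t", "k")] * 5 + [("m", "n", "l")] * 5
        spec = small_spec(
            implants=(Implant(13, 20.0, "p", amplitude=2.0),),
            epoch_noise_sd=0.5,
        )
        streams, _ = gen_likelihood_streams(spec, strings)
        cfg = SearchlightConfig()
        ms = build_model_set(
            streams, ("p", "t", "k", "m", "n", "l"), cfg.window_onsets
        )
        epochs, mesh, gt = gen_source_epochs(spec, ms)
        drdms = build_data_drdms(epochs, mesh, cfg)
        from ssrsa.core_rdm import spearman_correlation

        rhos = [
            spearman_correlation(drdms[13][w], ms.drdms["p"][w])
            for w in range(0, 21, 5)
        ]
        assert np.mean(rhos) > 0.3

    def test_effect_amplitude_monotonicity(self):
        """Recovered implant beta grows with implant amplitude."""
        from scipy.stats import spearmanr

        from ssrsa.glm_fitting import epoch_average_betas, fit_drdms

        strings = [("p", "t", "k")] * 5 + [("m", "n", "l")] * 5
        cfg = SearchlightConfig()
        amplitudes = [0.0, 0.5, 1.0, 2.0, 4.0]
        betas = []
        for amp in amplitudes:
            spec = small_spec(
                implants=(Implant(13, 20.0, "p", amplitude=amp),),
                seed=77,
            )
            streams, _ = gen_likelihood_streams(spec, strings)
            ms = build_model_set(
                streams, ("p", "t", "k", "m", "n", "l"), cfg.window_onsets
            )
            epochs, mesh, _ = gen_source_epochs(spec, ms)
            drdms = build_data_drdms(epochs, mesh, cfg)
            avg = epoch_average_betas(fit_drdms({13: drdms[13]}, ms)[13])
            betas.append(avg.betas["p"])
        rho = spearmanr(amplitudes, betas).statistic
        assert rho > 0.9


class TestSpecValidation:
    def test_h0_spec_meets_calibration_scale(self):
        spec = h0_spec()
        assert spec.n_conditions >= 24
        assert spec.n_subjects >= 2
        assert np.prod(spec.grid_shape) >= 100
        assert spec.implants == ()

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            small_spec(epoch_noise_sd=-1.0)

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            Implant(0, 10.0, "p", amplitude=-0.1)
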