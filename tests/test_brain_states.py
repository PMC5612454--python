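"""Spatiotemporal searchlight over source-space epochs."""

import numpy as np
import pytest

from ssrsa.brain_states import (
    SearchlightConfig,
    SourceEpochSet,
    SourceMesh,
    build_data_drdms,
    count_searchlight_rdms,
    patch_members,
    searchlight_data_rdm,
    window_positions,
)
from ssrsa.core_rdm import correlation_distance
from ssrsa.synthetic_data import make_grid_mesh
from tests.conftest import conditions


@pytest.fixture
def grid_mesh():
    return make_grid_mesh((4, 4, 4), 5.0)


def make_epochs(rng, n_subj=2, n_cond=5, n_vert=64, n_samples=370):
    return SourceEpochSet(
        subjects=tuple(f"s{k}" for k in range(n_subj)),
        conditions=conditions(n_cond),
        data=rng.standard_normal((n_subj, n_cond, n_vert, n_samples)),
        t_start_ms=0,
    )


class TestPatchMembers:
    def test_radius_zero_keeps_centre_only(self, grid_mesh):
        assert patch_members(grid_mesh, 0, 1e-9) == (0,)

    def test_huge_radius_covers_all_masked(self, grid_mesh):
        assert set(patch_members(grid_mesh, 0, 1e6)) == set(
            grid_mesh.vertex_ids
        )

    def test_matches_brute_force_distance_scan(self, grid_mesh):
        centre = 21
        got = set(patch_members(grid_mesh, centre, 20.0))
        ci = grid_mesh.index_of(centre)
        expected = {
            v
            for v, xyz in zip(grid_mesh.vertex_ids, grid_mesh.coords)
            if np.linalg.norm(xyz - grid_mesh.coords[ci]) <= 20.0
        }
        assert got == expected

    def test_membership_is_symmetric(self, grid_mesh):
        for u, v in [(0, 1), (5, 21), (63, 42)]:
            in_u = v in patch_members(grid_mesh, u, 12.0)
            in_v = u in patch_members(grid_mesh, v, 12.0)
            assert in_u == in_v

    def test_masked_out_centre_raises(self):
        mesh = make_grid_mesh((2, 2, 2), 5.0)
        mask = mesh.mask.copy()
        mask[0] = False
        masked = SourceMesh(
            vertex_ids=mesh.vertex_ids,
            coords=mesh.coords,
            hemispheres=mesh.hemispheres,
            mask=mask,
        )
        with pytest.raises(ValueError, match="outside the mask"):
            patch_members(masked, 0, 10.0)

    def test_excludes_out_of_mask_vertices(self):
        mesh = make_grid_mesh((3, 1, 1), 5.0)
        mask = np.array([True, False, True])
        masked = SourceMesh(
            vertex_ids=mesh.vertex_ids,
            coords=mesh.coords,
            hemispheres=mesh.hemispheres,
            mask=mask,
        )
        assert patch_members(masked, 0, 100.0) == (0, 2)


class TestWindowPositions:
    def test_trimmed_convention_gives_21_for_270ms(self):
        assert len(window_positions(270, 60, 10, "trimmed")) == 21

    def test_formula_convention_gives_22_for_270ms(self):
        onsets = window_positions(270, 60, 10, "formula")
        assert len(onsets) == 22
        assert onsets[-1] == 210

    def test_single_fitting_window(self):
        assert window_positions(60, 60, 10) == (0,)

    def test_formula_matches_brute_force_enumeration(self, rng):
        for _ in range(20):
            w = int(rng.integers(1, 20)) * 10
            s = int(rng.integers(1, 6)) * 10
            t = w + int(rng.integers(0, 30)) * 10
            got = window_positions(t, w, s, "formula")
            expected = tuple(
                o for o in range(0, t, s) if o + w <= t
            )
            assert got == expected

    def test_window_longer_than_epoch_raises(self):
        with pytest.raises(ValueError):
            window_positions(50, 60, 10)


class TestSearchlightRdm:
    def test_identical_conditions_give_zero_rdm(self, grid_mesh, rng):
        epochs = make_epochs(rng, n_cond=4)
        data = epochs.data.copy()
        for c in range(1, 4):
            data[:, c] = data[:, 0]
        same = SourceEpochSet(
            subjects=epochs.subjects,
            conditions=conditions(4),
            data=data,
        )
        cfg = SearchlightConfig(radius_mm=8.0)
        patch = patch_members(grid_mesh, 21, 8.0)
        rdm = searchlight_data_rdm(same, patch, 0, cfg, grid_mesh)
        assert np.allclose(rdm.values, 0, atol=1e-12)

    def test_single_subject_matches_direct_oracle(self, grid_mesh, rng):
        epochs = make_epochs(rng, n_subj=1, n_cond=3)
        cfg = SearchlightConfig()
        patch = (5, 21)  # 2-vertex patch, 60 samples -> 120-length vectors
        rdm = searchlight_data_rdm(epochs, patch, 40, cfg, grid_mesh)
        t0 = 40 + cfg.lag_ms
        for i in range(3):
            for j in range(i + 1, 3):
                vi = epochs.data[0, i][[5, 21], t0 : t0 + 60].reshape(-1)
                vj = epochs.data[0, j][[5, 21], t0 : t0 + 60].reshape(-1)
                assert vi.size == 120
                assert rdm.values[i, j] == pytest.approx(
                    correlation_distance(vi, vj), abs=1e-12
                )

    def test_subject_averaging_matches_manual_mean(self, grid_mesh, rng):
        from ssrsa.core_rdm import average_rdms, rdm_from_response_matrix

        epochs = make_epochs(rng, n_subj=3, n_cond=4)
        cfg = SearchlightConfig(radius_mm=8.0)
        patch = patch_members(grid_mesh, 21, 8.0)
        rdm = searchlight_data_rdm(epochs, patch, 100, cfg, grid_mesh)
        idx = [grid_mesh.index_of(v) for v in patch]
        t0 = 100 + cfg.lag_ms
        per_subj = []
        for s in range(3):
            resp = epochs.data[s][:, idx, :][:, :, t0 : t0 + 60].reshape(4, -1)
            per_subj.append(
                rdm_from_response_matrix(resp, epochs.conditions)
            )
        assert np.allclose(
            rdm.values, average_rdms(per_subj).values, atol=1e-12
        )

    def test_lagged_window_outside_epoch_raises(self, grid_mesh, rng):
        epochs = make_epochs(rng, n_samples=200)
        cfg = SearchlightConfig()
        with pytest.raises(ValueError, match="outside the epoch"):
            searchlight_data_rdm(epochs, (0,), 100, cfg, grid_mesh)


class TestBuildDataDrdms:
    def test_counts_vertices_times_windows(self, rng):
        mesh = make_grid_mesh((2, 2, 1), 5.0)
        epochs = make_epochs(rng, n_vert=4, n_samples=130)
        cfg = SearchlightConfig(epoch_ms=30, lag_ms=100, window_ms=10)
        drdms = build_data_drdms(epochs, mesh, cfg)
        assert len(drdms) == 4
        assert all(d.n_frames == cfg.n_windows for d in drdms.values())

    def test_matches_per_vertex_oracle_loop(self, grid_mesh, rng):
        epochs = make_epochs(rng, n_cond=4)
        cfg = SearchlightConfig(radius_mm=7.0, epoch_ms=120)
        drdms = build_data_drdms(epochs, grid_mesh, cfg)
        for centre in (0, 21, 63):
            patch = patch_members(grid_mesh, centre, cfg.radius_mm)
            for w, onset in enumerate(cfg.window_onsets):
                direct = searchlight_data_rdm(
                    epochs, patch, onset, cfg, grid_mesh
                )
                assert np.allclose(
                    drdms[centre][w].values, direct.values, atol=1e-12
                )

    def test_amplitude_scaling_leaves_rdms_unchanged(self, rng):
        mesh = make_grid_mesh((2, 2, 1), 5.0)
        epochs = make_epochs(rng, n_vert=4, n_samples=370)
        doubled = SourceEpochSet(
            subjects=epochs.subjects,
            conditions=epochs.conditions,
            data=epochs.data * 2.0,
        )
        cfg = SearchlightConfig(epoch_ms=100)
        a = build_data_drdms(epochs, mesh, cfg)
        b = build_data_drdms(doubled, mesh, cfg)
        for v in a:
            for w in range(cfg.n_windows):
                assert np.allclose(
                    a[v][w].values, b[v][w].values, atol=1e-10
                )

    def test_entries_bounded_and_symmetric(self, rng):
        mesh = make_grid_mesh((2, 2, 1), 5.0)
        epochs = make_epochs(rng, n_vert=4, n_samples=370)
        cfg = SearchlightConfig(epoch_ms=80)
        for drdm in build_data_drdms(epochs, mesh, cfg).values():
            for frame in drdm.frames:
                assert (frame.values >= 0).all()
                assert (frame.values <= 2).all()


class TestSearchlightBudget:
    def test_full_scale_rdm_count(self):
        # two-hemisphere mask sized like a bilateral temporal-lobe mask
        n_lh, n_rh = 661, 613
        mesh = make_grid_mesh((38, 6, 6), 5.0)  # 1368 vertices
        mask = np.zeros(mesh.n_vertices, dtype=bool)
        mask[: n_lh + n_rh] = True
        masked = SourceMesh(
            vertex_ids=mesh.vertex_ids,
            coords=mesh.coords,
            hemispheres=tuple(
                "lh" if k < n_lh else "rh"
                for k in range(mesh.n_vertices)
            ),
            mask=mask,
        )
        cfg = SearchlightConfig()
        assert count_searchlight_rdms(masked, cfg) == 26_754
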