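"""Data dynamic RDMs from source-space epochs via a spatiotemporal searchlight.

The searchlight is a spatial patch (all in-mask vertices within a fixed
radius of a centre vertex, Euclidean distance in mm) combined with a sliding
temporal window.  For each subject and condition, the patch's vertex x time
block is flattened into a response vector; pairwise correlation distances
give a per-subject RDM, and subject RDMs are averaged into one data RDM per
(centre vertex, window position).

The model epoch and the neural epoch are offset by a fixed lag: model window
onsets at t (ms from acoustic onset) are paired with neural data at
t + lag, so a 0-270 ms model epoch reads neural data at 100-370 ms for the
default 100 ms lag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ssrsa.core_rdm import (
    ConditionSet,
    DynamicRDM,
    RDM,
    average_rdms,
    rdm_from_response_matrix,
)


@dataclass(frozen=True)
class SourceMesh:
    """Source-space vertex geometry with an analysis mask.

    Coordinates are in mm.  The mask restricts the searchlight to a region
    of interest (e.g. bilateral superior temporal cortex).
    """

    vertex_ids: tuple[int, ...]
    coords: np.ndarray = field(repr=False)  # (n_vertices, 3) mm
    hemispheres: tuple[str, ...] = ()
    mask: np.ndarray = field(default=None, repr=False)  # bool per vertex

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=np.float64)
        n = len(self.vertex_ids)
        if c.shape != (n, 3):
            raise ValueError(f"coords must be ({n}, 3), got {c.shape}")
        if not np.all(np.isfinite(c)):
            raise ValueError("coordinates must be finite")
        if len(set(self.vertex_ids)) != n:
            raise ValueError("vertex ids must be unique")
        hemis = self.hemispheres or tuple("lh" for _ in range(n))
        if len(hemis) != n:
            raise ValueError("need one hemisphere label per vertex")
        m = (
            np.ones(n, dtype=bool)
            if self.mask is None
            else np.asarray(self.mask, dtype=bool)
        )
        if m.shape != (n,):
            raise ValueError("mask must be one boolean per vertex")
        if not m.any():
            raise ValueError("mask must contain at least one vertex")
        object.__setattr__(self, "vertex_ids", tuple(int(v) for v in self.vertex_ids))
        object.__setattr__(self, "coords", c)
        object.__setattr__(self, "hemispheres", tuple(hemis))
        object.__setattr__(self, "mask", m)

    @property
    def n_vertices(self) -> int:
        return len(self.vertex_ids)

    @property
    def masked_vertex_ids(self) -> tuple[int, ...]:
        """In-mask vertex ids in stored (deterministic) order."""
        return tuple(
            v for v, m in zip(self.vertex_ids, self.mask) if m
        )

    def index_of(self, vertex_id: int) -> int:
        return self.vertex_ids.index(vertex_id)


def save_mesh_tsv(mesh: SourceMesh, path: str | Path) -> None:
    """Write a mesh as TSV (vertex_id, hemisphere, x_mm, y_mm, z_mm, in_mask)."""
    df = pd.DataFrame(
        {
            "vertex_id": mesh.vertex_ids,
            "hemisphere": mesh.hemispheres,
            "x_mm": mesh.coords[:, 0],
            "y_mm": mesh.coords[:, 1],
            "z_mm": mesh.coords[:, 2],
            "in_mask": mesh.mask.astype(int),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def load_mesh_tsv(path: str | Path) -> SourceMesh:
    df = pd.read_csv(path, sep="\t")
    return SourceMesh(
        vertex_ids=tuple(df["vertex_id"].astype(int)),
        coords=df[["x_mm", "y_mm", "z_mm"]].to_numpy(),
        hemispheres=tuple(df["hemisphere"].astype(str)),
        mask=df["in_mask"].to_numpy().astype(bool),
    )


@dataclass(frozen=True)
class SourceEpochSet:
    """Per-subject, per-condition source epochs at 1 ms sampling.

    ``data`` has shape (n_subjects, n_conditions, n_vertices, n_samples);
    the time axis starts at ``t_start_ms`` relative to stimulus onset and
    must cover the lagged analysis epoch.
    """

    subjects: tuple[str, ...]
    conditions: ConditionSet
    data: np.ndarray = field(repr=False)
    t_start_ms: int = 0
    sample_ms: int = 1

    def __post_init__(self) -> None:
        d = np.asarray(self.data)
        expected = (len(self.subjects), self.conditions.n)
        if d.ndim != 4 or d.shape[:2] != expected:
            raise ValueError(
                "data must be (subject, condition, vertex, time) with "
                f"leading shape {expected}, got {d.shape}"
            )
        if self.sample_ms != 1:
            raise ValueError("only 1 ms sampling is supported")
        object.__setattr__(self, "subjects", tuple(self.subjects))
        object.__setattr__(self, "data", d)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_samples(self) -> int:
        return self.data.shape[3]

    @property
    def t_end_ms(self) -> int:
        return self.t_start_ms + self.n_samples


@dataclass(frozen=True)
class SearchlightConfig:
    """Geometry of the spatiotemporal searchlight.

    radius_mm: spatial patch radius (default 20 mm).
    window_ms / step_ms: sliding temporal window width and step (60 / 10 ms).
    lag_ms: fixed model-to-brain processing lag (default 100 ms).
    epoch_ms: model analysis epoch length (default 270 ms).
    window_mode: 'trimmed' drops the final flush window onset so a 270 ms
        epoch yields 21 positions; 'formula' keeps every fitting onset (22).
    """

    radius_mm: float = 20.0
    window_ms: int = 60
    step_ms: int = 10
    lag_ms: int = 100
    epoch_ms: int = 270
    window_mode: str = "trimmed"

    def __post_init__(self) -> None:
        if min(self.radius_mm, self.window_ms, self.step_ms) <= 0:
            raise ValueError("radius, window and step must be positive")
        if self.lag_ms < 0:
            raise ValueError("lag must be non-negative")
        if self.window_mode not in ("trimmed", "formula"):
            raise ValueError("window_mode must be 'trimmed' or 'formula'")

    @property
    def window_onsets(self) -> tuple[int, ...]:
        return window_positions(
            self.epoch_ms, self.window_ms, self.step_ms, self.window_mode
        )

    @property
    def n_windows(self) -> int:
        return len(self.window_onsets)


def window_positions(
    epoch_len_ms: int, window_ms: int, step_ms: int, mode: str = "trimmed"
) -> tuple[int, ...]:
    """Window onset times for a sliding window over an epoch.

    mode 'formula': every onset 0, step, ..., floor((T-w)/s)*s that fits.
    mode 'trimmed' (default): the same, minus the final onset when more than
    one window fits and the last window ends flush with the epoch — the
    convention under which a 270 ms epoch with 60 ms windows at 10 ms steps
    has 21 positions.
    """
    if window_ms > epoch_len_ms:
        raise ValueError(
            f"window ({window_ms} ms) longer than epoch ({epoch_len_ms} ms)"
        )
    if window_ms <= 0 or step_ms <= 0:
        raise ValueError("window and step must be positive")
    onsets = list(range(0, epoch_len_ms - window_ms + 1, step_ms))
    if (
        mode == "trimmed"
        and len(onsets) > 1
        and onsets[-1] + window_ms == epoch_len_ms
    ):
        onsets = onsets[:-1]
    elif mode not in ("trimmed", "formula"):
        raise ValueError(f"unknown window mode '{mode}'")
    return tuple(onsets)


def patch_members(
    mesh: SourceMesh, centre: int, radius_mm: float
) -> tuple[int, ...]:
    """All in-mask vertices within `radius_mm` of the centre vertex.

    Distance is 3D Euclidean between vertex coordinates (not geodesic along
    the cortical surface).  The centre is always a member.  Output order
    follows the mesh's stored vertex order (deterministic).
    """
    ci = mesh.index_of(centre)
    if not mesh.mask[ci]:
        raise ValueError(f"centre vertex {centre} is outside the mask")
    d = np.linalg.norm(mesh.coords - mesh.coords[ci], axis=1)
    sel = (d <= radius_mm) & mesh.mask
    return tuple(v for v, s in zip(mesh.vertex_ids, sel) if s)


def _patch_response_block(
    epochs: SourceEpochSet,
    patch_idx: np.ndarray,
    t0: int,
    n_samp: int,
) -> np.ndarray:
    """(subject, condition, patch-vertex * time) flattened response patterns.

    Flattening is vertex-major then time; correlation distance is invariant
    to the order, which is fixed for reproducibility.
    """
    block = epochs.data[:, :, patch_idx, t0 : t0 + n_samp]
    return block.reshape(epochs.n_subjects, epochs.conditions.n, -1)


def searchlight_data_rdm(
    epochs: SourceEpochSet,
    patch: Sequence[int],
    window_onset_ms: int,
    cfg: SearchlightConfig,
    mesh: SourceMesh,
) -> RDM:
    """Subject-averaged data RDM for one patch and one window position.

    The window onset is in model-epoch time; the neural window read is
    [onset + lag, onset + lag + window_ms) relative to stimulus onset.
    """
    t0 = window_onset_ms + cfg.lag_ms - epochs.t_start_ms
    if t0 < 0 or t0 + cfg.window_ms > epochs.n_samples:
        raise ValueError(
            f"lagged window [{window_onset_ms + cfg.lag_ms}, "
            f"{window_onset_ms + cfg.lag_ms + cfg.window_ms}) ms lies "
            f"outside the epoch [{epochs.t_start_ms}, {epochs.t_end_ms}) ms"
        )
    patch_idx = np.array([mesh.index_of(v) for v in patch], dtype=np.intp)
    resp = _patch_response_block(epochs, patch_idx, t0, cfg.window_ms)
    per_subject = []
    for s in range(epochs.n_subjects):
        try:
            per_subject.append(
                rdm_from_response_matrix(resp[s], epochs.conditions)
            )
        except Exception as e:
            raise type(e)(
                f"subject '{epochs.subjects[s]}', patch centre {patch[0]}, "
                f"window onset {window_onset_ms} ms: {e}"
            ) from e
    return average_rdms(per_subject)


def build_data_drdms(
    epochs: SourceEpochSet,
    mesh: SourceMesh,
    cfg: SearchlightConfig,
) -> dict[int, DynamicRDM]:
    """Subject-averaged dynamic data RDM for every in-mask vertex.

    The searchlight patch is centred on each masked vertex in stored mesh
    order; for each window onset the lagged neural window is read.  Output:
    vertex id -> DynamicRDM with one frame per window position.
    """
    onsets = cfg.window_onsets
    out: dict[int, DynamicRDM] = {}
    vid_to_idx = {v: i for i, v in enumerate(mesh.vertex_ids)}
    coords = mesh.coords
    masked = mesh.masked_vertex_ids
    for centre in masked:
        ci = vid_to_idx[centre]
        d = np.linalg.norm(coords - coords[ci], axis=1)
        sel = (d <= cfg.radius_mm) & mesh.mask
        patch_idx = np.flatnonzero(sel)
        frames = []
        for onset in onsets:
            t0 = onset + cfg.lag_ms - epochs.t_start_ms
            if t0 < 0 or t0 + cfg.window_ms > epochs.n_samples:
                raise ValueError(
                    f"lagged window at onset {onset} ms outside epoch"
                )
            resp = _patch_response_block(
                epochs, patch_idx, t0, cfg.window_ms
            )
            subj_rdms = [
                rdm_from_response_matrix(resp[s], epochs.conditions)
                for s in range(epochs.n_subjects)
            ]
            frames.append(average_rdms(subj_rdms))
        out[centre] = DynamicRDM(
            tuple(frames), window_ms=cfg.window_ms, step_ms=cfg.step_ms
        )
    return out


def count_searchlight_rdms(mesh: SourceMesh, cfg: SearchlightConfig) -> int:
    """Number of (vertex, window) data RDMs a searchlight run produces.

    One RDM per in-mask vertex per window position (e.g. 1,274 vertices x
    21 windows = 26,754).
    """
    return int(mesh.mask.sum()) * cfg.n_windows
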