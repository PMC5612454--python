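"""Synthetic inputs with known ground truth for the whole pipeline.

No public dataset accompanies this analysis, so every input is emulated
with controllable structure:

* likelihood streams — each condition (word) has a phone string laid out
  over the epoch in equal-duration segments; the triphone matching the
  active (previous, current, next) phone context receives a high
  log-likelihood baseline, all other triphones a low baseline, plus i.i.d.
  Gaussian noise.  Conditions sharing a centre phone in a window are
  therefore more correlated within that phone's column group, giving the
  phone-driven block structure the model RDMs are built from.

* source epochs — a regular 3D millimetre grid stands in for the cortical
  mesh (Euclidean patch geometry is all the searchlight needs); background
  activity is i.i.d. Gaussian noise, and chosen representational
  geometries are implanted at chosen patches: for each implant and each
  window, a response block whose condition-pair correlation structure
  approximates the implanted phone's model RDM frame is added into the
  patch's lagged window samples, scaled by the effect amplitude.  Implant
  structure is shared across subjects; noise is per-subject independent.

Every generator is a pure function of its spec, including the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from ssrsa.brain_states import SearchlightConfig, SourceEpochSet, SourceMesh
from ssrsa.core_rdm import ConditionSet, RDM
from ssrsa.machine_states import (
    LikelihoodStreamSet,
    PhoneModelSet,
    TriphoneLabel,
)

#: Default phone inventory for small synthetic runs (subset of the packaged
#: 40-phone matrix: plosives, fricatives, nasals, approximants and vowels).
DEFAULT_INVENTORY = (
    "p", "b", "t", "d", "k", "g", "s", "z", "f", "v",
    "m", "n", "l", "r", "w", "y",
    "aa", "ae", "eh", "ih", "iy", "uh", "uw", "ah",
)


@dataclass(frozen=True)
class Implant:
    """One patch of implanted representational geometry.

    ``source`` is a phone symbol (the implanted model dRDM) or
    ``feature:<name>`` for the average of that feature's phone model dRDMs.
    """

    centre_vertex: int
    radius_mm: float
    source: str
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("implant amplitude must be >= 0")
        if self.radius_mm <= 0:
            raise ValueError("implant radius must be positive")


@dataclass(frozen=True)
class SyntheticSpec:
    """Study-condition parameters for the synthetic generators.

    Defaults mirror the full-scale study (400 words, 16 subjects, a 270 ms
    model epoch at 10 ms frames with a 100 ms lag); validation experiments
    construct reduced-scale specs explicitly.
    """

    n_conditions: int = 400
    inventory: tuple[str, ...] = DEFAULT_INVENTORY
    phones_per_word: int = 3
    epoch_ms: int = 270
    frame_ms: int = 10
    high_loglik: float = -2.0
    low_loglik: float = -12.0
    stream_noise_sd: float = 1.0
    grid_shape: tuple[int, int, int] = (7, 7, 7)
    grid_spacing_mm: float = 10.0
    n_subjects: int = 16
    epoch_noise_sd: float = 1.0
    implants: tuple[Implant, ...] = ()
    lag_ms: int = 100
    window_ms: int = 60
    step_ms: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_conditions < 3:
            raise ValueError("need >= 3 conditions")
        if self.phones_per_word < 1:
            raise ValueError("phones_per_word must be >= 1")
        if self.epoch_ms % self.frame_ms:
            raise ValueError("epoch must be a whole number of frames")
        if self.stream_noise_sd < 0 or self.epoch_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        object.__setattr__(self, "inventory", tuple(self.inventory))
        object.__setattr__(self, "implants", tuple(self.implants))

    @property
    def conditions(self) -> ConditionSet:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return ConditionSet(
                [f"word{i:04d}" for i in range(self.n_conditions)]
            )

    @property
    def n_frames(self) -> int:
        return self.epoch_ms // self.frame_ms


@dataclass(frozen=True)
class GroundTruth:
    """Everything needed to score recovery without re-deriving it."""

    condition_phones: tuple[tuple[str, ...], ...] = ()
    implants: tuple[Implant, ...] = ()
    implant_patches: Mapping[int, tuple[int, ...]] = field(
        default_factory=dict
    )
    target_rdms: Mapping[int, tuple[RDM, ...]] = field(default_factory=dict)


def _phone_strings(
    spec: SyntheticSpec, rng: np.random.Generator
) -> list[tuple[str, ...]]:
    return [
        tuple(rng.choice(spec.inventory, size=spec.phones_per_word))
        for _ in range(spec.n_conditions)
    ]


def _frame_contexts(
    phones: Sequence[str], n_frames: int
) -> list[TriphoneLabel]:
    """Active (previous, current, next) context per frame, equal durations.

    Word-edge contexts use the silence symbol 'sil'.
    """
    k = len(phones)
    out = []
    for f in range(n_frames):
        seg = min(f * k // n_frames, k - 1)
        left = phones[seg - 1] if seg > 0 else "sil"
        right = phones[seg + 1] if seg < k - 1 else "sil"
        out.append(TriphoneLabel(left, phones[seg], right))
    return out


def gen_likelihood_streams(
    spec: SyntheticSpec,
    condition_phones: Sequence[Sequence[str]] | None = None,
) -> tuple[LikelihoodStreamSet, GroundTruth]:
    """Generate triphone log-likelihood streams with phone-driven structure.

    The triphone inventory is the set of contexts occurring in any
    condition's phone layout; the active triphone of each frame gets the
    high baseline, all others the low baseline, plus Gaussian noise.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    if condition_phones is None:
        strings = _phone_strings(spec, rng)
    else:
        strings = [tuple(p) for p in condition_phones]
        if len(strings) != spec.n_conditions:
            raise ValueError("need one phone string per condition")
        for s in strings:
            bad = [p for p in s if p not in spec.inventory]
            if bad:
                raise ValueError(
                    f"phone(s) {bad} not in the declared inventory"
                )
    n_frames = spec.n_frames
    contexts = [_frame_contexts(s, n_frames) for s in strings]
    triphones = sorted(
        {t for row in contexts for t in row},
        key=lambda t: (t.centre, t.left, t.right),
    )
    tri_index = {t: k for k, t in enumerate(triphones)}
    values = np.full(
        (spec.n_conditions, n_frames, len(triphones)), spec.low_loglik
    )
    for c, row in enumerate(contexts):
        for f, t in enumerate(row):
            values[c, f, tri_index[t]] = spec.high_loglik
    values += rng.normal(0.0, spec.stream_noise_sd, size=values.shape)
    streams = LikelihoodStreamSet(
        conditions=spec.conditions,
        triphones=tuple(triphones),
        values=values,
        frame_ms=spec.frame_ms,
    )
    return streams, GroundTruth(condition_phones=tuple(strings))


def embed_target_rdm(
    target: RDM | np.ndarray,
    m: int,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Draw a condition x m response matrix whose geometry matches a target.

    Converts the target dissimilarities to similarities S = 1 - target,
    projects S to the nearest positive semidefinite matrix by clipping
    negative eigenvalues at zero, and returns X = L G where L L' equals the
    projected S and G is standard Gaussian.  Rows of X then have expected
    pairwise correlation approximately S, so the empirical RDM of X
    converges to the target as m grows.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    t = target.values if isinstance(target, RDM) else np.asarray(target)
    n = t.shape[0]
    if t.shape != (n, n) or not np.allclose(t, t.T, atol=1e-9):
        raise ValueError("target must be a symmetric square matrix")
    if np.any(t < -1e-9) or np.any(t > 2 + 1e-9):
        raise ValueError("target entries must lie in [0, 2]")
    if m < 3:
        raise ValueError("need m >= 3 response dimensions")
    s = 1.0 - t
    np.fill_diagonal(s, 1.0)
    evals, evecs = np.linalg.eigh(s)
    evals = np.clip(evals, 0.0, None)
    L = evecs * np.sqrt(evals)
    return L @ rng.standard_normal((n, m))


def make_grid_mesh(
    shape: tuple[int, int, int], spacing_mm: float
) -> SourceMesh:
    """Regular 3D grid mesh with every vertex in the mask."""
    nx, ny, nz = shape
    ids, coords = [], []
    v = 0
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                ids.append(v)
                coords.append(
                    (i * spacing_mm, j * spacing_mm, k * spacing_mm)
                )
                v += 1
    return SourceMesh(
        vertex_ids=tuple(ids),
        coords=np.asarray(coords, dtype=np.float64),
        hemispheres=tuple("lh" for _ in ids),
        mask=np.ones(len(ids), dtype=bool),
    )


def _implant_target_drdm(
    implant: Implant, model_set: PhoneModelSet
) -> list[RDM]:
    """The per-window target RDMs an implant injects."""
    if implant.source.startswith("feature:"):
        from ssrsa.core_rdm import average_rdms

        name = implant.source.split(":", 1)[1]
        from ssrsa.feature_space import default_feature_matrix

        fm = default_feature_matrix()
        members = [
            p for p in fm.phones_with(name) if p in model_set.phones
        ]
        if not members:
            raise ValueError(
                f"feature '{name}' has no phone with a model dRDM"
            )
        return [
            average_rdms([model_set.drdms[p][w] for p in members])
            for w in range(model_set.n_windows)
        ]
    if implant.source not in model_set.phones:
        raise ValueError(f"no model dRDM for phone '{implant.source}'")
    d = model_set.drdms[implant.source]
    return [d[w] for w in range(d.n_frames)]


def gen_source_epochs(
    spec: SyntheticSpec,
    model_set: PhoneModelSet | None = None,
    mesh: SourceMesh | None = None,
) -> tuple[SourceEpochSet, SourceMesh, GroundTruth]:
    """Generate source epochs: Gaussian background plus implanted geometry.

    The epoch time axis runs from stimulus onset to lag + epoch length
    (370 ms by default) so every lagged searchlight window fits.  For each
    implant and each sliding-window position w, the patch x window block of
    every condition's response gains an amplitude-scaled sample from
    :func:`embed_target_rdm` of the implanted model's frame w, placed at
    the lagged window (model window at t pairs with neural data at
    t + lag).  Adjacent windows overlap in time, so their contributions
    add; the injected geometry at any one window is then a mixture
    dominated by that window's target frame.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    if mesh is None:
        mesh = make_grid_mesh(spec.grid_shape, spec.grid_spacing_mm)
    if spec.implants and model_set is None:
        raise ValueError("implants require a PhoneModelSet")
    n_samples = spec.lag_ms + spec.epoch_ms
    subjects = tuple(f"subj{k:02d}" for k in range(spec.n_subjects))
    data = rng.normal(
        0.0,
        spec.epoch_noise_sd,
        size=(
            spec.n_subjects,
            spec.n_conditions,
            mesh.n_vertices,
            n_samples,
        ),
    )
    from ssrsa.brain_states import patch_members, window_positions

    onsets = window_positions(
        spec.epoch_ms, spec.window_ms, spec.step_ms, "trimmed"
    )
    patches: dict[int, tuple[int, ...]] = {}
    targets: dict[int, tuple[RDM, ...]] = {}
    claimed: set[int] = set()
    for implant in spec.implants:
        patch = patch_members(mesh, implant.centre_vertex, implant.radius_mm)
        overlap = claimed & set(patch)
        if overlap:
            raise ValueError(
                f"implant at vertex {implant.centre_vertex} overlaps "
                f"previously implanted vertices {sorted(overlap)[:5]}"
            )
        claimed |= set(patch)
        patches[implant.centre_vertex] = patch
        frames = _implant_target_drdm(implant, model_set)
        if len(frames) != len(onsets):
            raise ValueError(
                f"model dRDM has {len(frames)} frames but the window "
                f"config implies {len(onsets)}"
            )
        targets[implant.centre_vertex] = tuple(frames)
        pidx = np.array([mesh.index_of(v) for v in patch], dtype=np.intp)
        for w, onset in enumerate(onsets):
            t0 = onset + spec.lag_ms
            block = embed_target_rdm(
                frames[w], len(pidx) * spec.window_ms, rng
            )  # shared across subjects
            shaped = implant.amplitude * block.reshape(
                spec.n_conditions, len(pidx), spec.window_ms
            )
            data[:, :, pidx, t0 : t0 + spec.window_ms] += shaped[None]
    epochs = SourceEpochSet(
        subjects=subjects,
        conditions=spec.conditions,
        data=data,
        t_start_ms=0,
    )
    gt = GroundTruth(
        implants=spec.implants,
        implant_patches=patches,
        target_rdms=targets,
    )
    return epochs, mesh, gt


def h0_spec(**overrides) -> SyntheticSpec:
    """A reduced-scale pure-noise (no-implant) spec for calibration runs."""
    base = SyntheticSpec(
        n_conditions=24,
        phones_per_word=3,
        n_subjects=2,
        grid_shape=(7, 7, 7),
        grid_spacing_mm=20.0,
        implants=(),
    )
    return replace(base, **overrides)
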