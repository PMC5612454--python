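"""Reusable validation experiments run on synthetic ground-truth data.

These experiments exercise the full pipeline under controlled conditions
and return scalar summaries:

* null calibration — on pure-noise data the fraction of (feature, vertex)
  cells whose observed epoch-averaged fit exceeds the 0.95 permutation
  threshold should sit near the nominal 5%;
* implant recovery — a single patch carrying one phone model's geometry
  should put that phone's beta on top at the implant centre, let the
  centre survive thresholding, and leave distant vertices at the nominal
  false-positive rate;
* feature-space separation — model sets built with two distinct classes
  should yield a Davies-Bouldin index beating shuffled labels and a large
  eta squared, while structureless sets stay below the medium benchmark.

Experiment scales (conditions, subjects, mesh size, permutation count) are
reduced relative to a full study so a complete validation pass runs on a
single CPU in minutes; grid spacing at validation scale equals the patch
radius so neighbouring searchlights overlap only weakly and the survival
fraction is estimated from quasi-independent cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ssrsa.brain_states import SearchlightConfig, build_data_drdms
from ssrsa.core_rdm import DynamicRDM, RDM, rdm_from_response_matrix
from ssrsa.feature_space import FeatureMatrix, default_feature_matrix
from ssrsa.glm_fitting import epoch_average_betas, fit_drdms
from ssrsa.machine_states import PhoneModelSet, build_model_set
from ssrsa.model_validation import davies_bouldin, eta_squared, model_points, second_order_matrix
from ssrsa.permutation_stats import (
    build_null,
    observed_feature_fits,
    threshold_feature_maps,
)
from ssrsa.synthetic_data import (
    Implant,
    SyntheticSpec,
    gen_likelihood_streams,
    gen_source_epochs,
    h0_spec,
    make_grid_mesh,
)


def _fitted_features(fm: FeatureMatrix, model_set: PhoneModelSet):
    """Features with at least one modelled phone (others fit 0 identically)."""
    modelled = set(model_set.phones)
    return [
        f for f in fm.features
        if any(p in modelled for p in fm.phones_with(f))
    ]


@dataclass(frozen=True)
class CalibrationResult:
    survived: int
    cells: int

    @property
    def rate(self) -> float:
        return self.survived / self.cells


def calibration_experiment(
    seed: int, *, n_perm: int = 100, quantile: float = 0.95
) -> CalibrationResult:
    """False-positive calibration of the permutation threshold under H0.

    Pure-noise synthetic data (24 conditions, 2 subjects, 343 masked
    vertices): the observed fits are exchangeable with the null samples,
    so the expected survival fraction equals 1 - quantile.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        spec = h0_spec(seed=seed)
        fm = default_feature_matrix()
        cfg = SearchlightConfig()
        streams, _gt = gen_likelihood_streams(spec)
        model_set = build_model_set(
            streams, spec.inventory, cfg.window_onsets
        )
        epochs, mesh, _gt2 = gen_source_epochs(spec, model_set)
        drdms = build_data_drdms(epochs, mesh, cfg)
        fits = observed_feature_fits(drdms, model_set, fm)
        nulls = build_null(drdms, model_set, fm, n_perm, seed + 10_000)
        thresholded = threshold_feature_maps(fits, nulls, quantile)
    feats = _fitted_features(fm, model_set)
    cells = sum(len(thresholded[f].fits) for f in feats)
    survived = sum(len(thresholded[f].surviving) for f in feats)
    return CalibrationResult(survived, cells)


@dataclass(frozen=True)
class RecoveryResult:
    implanted_phone: str
    top_phone: str
    centre_survives: bool
    far_rate: float

    @property
    def top_correct(self) -> bool:
        return self.top_phone == self.implanted_phone


def recovery_experiment(
    seed: int,
    *,
    phone: str = "s",
    amplitude: float = 1.0,
    n_perm: int = 60,
    quantile: float = 0.95,
) -> RecoveryResult:
    """Recover a single implanted phone-model patch.

    A 7x7x7 grid at 20 mm spacing carries one implant (20 mm radius) of
    the given phone's model dRDM at the grid centre.  Reported: the phone
    with the largest epoch-averaged beta at the centre, whether the centre
    survives the per-feature q-threshold for any feature of the implanted
    phone, and the surviving fraction of (far vertex, implanted-phone
    feature) cells at least three patch radii from the centre.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mesh = make_grid_mesh((7, 7, 7), 20.0)
        centre = 3 * 49 + 3 * 7 + 3  # grid midpoint
        cfg = SearchlightConfig()
        spec = SyntheticSpec(
            n_conditions=24,
            n_subjects=2,
            grid_shape=(7, 7, 7),
            grid_spacing_mm=20.0,
            implants=(
                Implant(centre, cfg.radius_mm, phone, amplitude),
            ),
            seed=seed,
        )
        rng = np.random.default_rng(seed)
        strings = [
            tuple(rng.choice(spec.inventory, size=spec.phones_per_word))
            for _ in range(spec.n_conditions)
        ]
        # guarantee the implanted phone is modelled and informative:
        # present in half the words, absent from the other half
        strings = [
            (phone,) + s[1:] if i % 2 == 0
            else tuple(x for x in s if x != phone) or ("t",)
            for i, s in enumerate(strings)
        ]
        strings = [s if len(s) == spec.phones_per_word else s + ("t",) * (
            spec.phones_per_word - len(s)) for s in strings]
        streams, _gt = gen_likelihood_streams(spec, strings)
        model_set = build_model_set(
            streams, spec.inventory, cfg.window_onsets
        )
        epochs, mesh, _gt2 = gen_source_epochs(spec, model_set, mesh)
        drdms = build_data_drdms(epochs, mesh, cfg)
        avg = epoch_average_betas(fit_drdms({centre: drdms[centre]},
                                            model_set)[centre])
        top_phone = max(avg.betas, key=avg.betas.get)
        fm = default_feature_matrix()
        fits = observed_feature_fits(drdms, model_set, fm)
        nulls = build_null(drdms, model_set, fm, n_perm, seed + 20_000)
        thresholded = threshold_feature_maps(fits, nulls, quantile)
    phone_feats = [f for f in fm.features if fm.chi(f, phone)]
    centre_survives = any(
        centre in thresholded[f].surviving for f in phone_feats
    )
    ci = mesh.index_of(centre)
    dist = np.linalg.norm(mesh.coords - mesh.coords[ci], axis=1)
    far = [
        v for v, d in zip(mesh.vertex_ids, dist)
        if d >= 3 * cfg.radius_mm
    ]
    far_cells = sum(
        1 for f in phone_feats for v in far
        if v in set(thresholded[f].surviving)
    )
    far_rate = far_cells / (len(phone_feats) * len(far))
    return RecoveryResult(phone, top_phone, centre_survives, far_rate)


def _conditions(n):
    from ssrsa.core_rdm import ConditionSet

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ConditionSet([f"w{i}" for i in range(n)])


def two_class_model_set(
    seed: int,
    *,
    n_models: int = 40,
    n_cond: int = 10,
    n_windows: int = 3,
    within_noise: float = 0.2,
) -> tuple[PhoneModelSet, np.ndarray]:
    """Model set whose RDMs fall into two well-separated classes.

    Each class has a prototype response pattern per window; a model's
    frame is the RDM of the prototype plus small independent perturbation.
    Returns the set and the binary class labels (model order).
    """
    rng = np.random.default_rng(seed)
    cs = _conditions(n_cond)
    labels = np.arange(n_models) % 2
    protos = rng.standard_normal((2, n_windows, n_cond, 24))
    drdms = {}
    for k in range(n_models):
        frames = []
        for w in range(n_windows):
            resp = (
                protos[labels[k], w]
                + within_noise * rng.standard_normal((n_cond, 24))
            )
            frames.append(rdm_from_response_matrix(resp, cs))
        drdms[f"m{k}"] = DynamicRDM(tuple(frames), 60, 10)
    return PhoneModelSet(tuple(drdms), drdms), labels.astype(bool)


def structureless_model_set(
    seed: int, *, n_models: int = 40, n_cond: int = 10, n_windows: int = 1
) -> PhoneModelSet:
    """Model set with fully independent random RDMs (no class structure)."""
    rng = np.random.default_rng(seed)
    cs = _conditions(n_cond)
    drdms = {
        f"m{k}": DynamicRDM(
            tuple(
                rdm_from_response_matrix(
                    rng.standard_normal((n_cond, 24)), cs
                )
                for _ in range(n_windows)
            ),
            60,
            10,
        )
        for k in range(n_models)
    }
    return PhoneModelSet(tuple(drdms), drdms)


@dataclass(frozen=True)
class SeparationResult:
    db_true: float
    db_shuffled_median: float
    eta_structured: float
    eta_structureless_median: float


def feature_separation_experiment(
    seed: int, *, n_shuffles: int = 100
) -> SeparationResult:
    """Cluster diagnostics on structured vs structureless model spaces."""
    rng = np.random.default_rng(seed)
    ms, labels = two_class_model_set(seed)
    pts = model_points(ms, 0)
    som = second_order_matrix(ms, 0)
    db_true = davies_bouldin(pts, labels)
    shuffled = []
    for _ in range(n_shuffles):
        shuffled.append(davies_bouldin(pts, labels[rng.permutation(labels.size)]))
    eta_structured = eta_squared(som.distances, labels)

    ms0 = structureless_model_set(seed + 1)
    som0 = second_order_matrix(ms0, 0)
    etas = []
    n = len(ms0.phones)
    for _ in range(n_shuffles):
        lab = np.zeros(n, dtype=bool)
        lab[rng.choice(n, n // 2, replace=False)] = True
        etas.append(eta_squared(som0.distances, lab))
    return SeparationResult(
        db_true=db_true,
        db_shuffled_median=float(np.median(shuffled)),
        eta_structured=eta_structured,
        eta_structureless_median=float(np.median(etas)),
    )
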