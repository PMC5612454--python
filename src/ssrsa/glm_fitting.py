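"""Simultaneous GLM fit of all phone model RDMs to each data RDM.

For a data RDM D and phone model RDMs M_phone, ordinary least squares on the
upper-triangle vectors solves

    D = beta_1 * M_1 + sum over phones of beta_phone * M_phone + E

with M_1 the constant (all-ones) predictor and E the residual, minimising
the summed squared error.  Predictors enter raw — no z-scoring or demeaning
beyond the explicit intercept — because the feature fits downstream sum raw
phone coefficients, and rescaling predictors would silently reweight
features.  Rank-deficient designs (collinear models of acoustically similar
'competitor' phones) are solved by the minimum-norm solution with a logged
condition-number warning; the remedy for competitor ambiguity is the
feature aggregation, which is preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from ssrsa.core_rdm import RDM, upper_triangle_vector
from ssrsa.machine_states import PhoneModelSet

logger = logging.getLogger(__name__)

#: Relative condition-number threshold above which a design is reported.
COND_WARN = 1e8


@dataclass(frozen=True)
class GLMResult:
    """Coefficients of one GLM fit.

    ``window`` is the window index, or the string 'epoch' for an
    epoch-averaged summary.  ``betas`` maps phone -> beta_phone; the
    intercept beta_1 is separate and never enters feature fits.
    """

    vertex: int | None
    window: int | str
    betas: dict[str, float]
    intercept: float
    residual_ss: float
    condition_number: float = float("nan")

    def __post_init__(self) -> None:
        if self.residual_ss < -1e-9:
            raise ValueError("residual sum of squares must be >= 0")
        if not all(np.isfinite(list(self.betas.values()))):
            raise ValueError("betas must be finite")


def design_matrix(
    models: Mapping[str, RDM], phone_order: Sequence[str]
) -> np.ndarray:
    """Design: constant column then one upper-triangle column per phone."""
    cols = [np.ones(upper_triangle_vector(models[phone_order[0]]).size)]
    cols += [upper_triangle_vector(models[p]) for p in phone_order]
    return np.column_stack(cols)


def _solve(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Minimum-norm least squares; returns (coef, residual_ss, cond)."""
    coef, _, rank, sv = np.linalg.lstsq(X, y, rcond=None)
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else float("inf")
    if rank < X.shape[1]:
        logger.warning(
            "rank-deficient design (rank %d of %d, cond %.3g); "
            "minimum-norm solution used",
            rank,
            X.shape[1],
            cond,
        )
    elif cond > COND_WARN:
        logger.warning("ill-conditioned design (cond %.3g)", cond)
    resid = y - X @ coef
    return coef, float(resid @ resid), cond


def fit_phone_glm(
    data: RDM,
    models: Mapping[str, RDM],
    *,
    vertex: int | None = None,
    window: int | str = 0,
) -> GLMResult:
    """Fit all phone model RDMs plus a constant to one data RDM."""
    if not models:
        raise ValueError("need at least one model RDM")
    phone_order = list(models)
    for p, m in models.items():
        if m.conditions.labels != data.conditions.labels:
            raise ValueError(f"model '{p}' has mismatched conditions")
    y = upper_triangle_vector(data)
    X = design_matrix(models, phone_order)
    coef, rss, cond = _solve(X, y)
    return GLMResult(
        vertex=vertex,
        window=window,
        betas=dict(zip(phone_order, coef[1:].astype(float))),
        intercept=float(coef[0]),
        residual_ss=rss,
        condition_number=cond,
    )


def fit_drdms(
    data_drdms: Mapping[int, "DynamicRDM"],
    model_set: PhoneModelSet,
    *,
    window_indices: Sequence[int] | None = None,
) -> dict[int, list[GLMResult]]:
    """Fit every window of every vertex's data dRDM.

    Window w of the data dRDM is fitted against window w of every phone
    model dRDM (lag alignment happens upstream when the data dRDMs are
    built).  Fits are independent across vertices — no spatial pooling.
    """
    n_model_windows = model_set.n_windows
    out: dict[int, list[GLMResult]] = {}
    engines: dict[int, _WindowEngine] = {}
    for vertex, drdm in data_drdms.items():
        if drdm.n_frames != n_model_windows:
            raise ValueError(
                f"vertex {vertex}: {drdm.n_frames} data windows but "
                f"{n_model_windows} model windows"
            )
        windows = (
            range(n_model_windows) if window_indices is None else window_indices
        )
        results = []
        for w in windows:
            if w not in engines:
                engines[w] = _WindowEngine(model_set, w)
            eng = engines[w]
            y = upper_triangle_vector(drdm[w])
            coef, rss, cond = eng.solve(y)
            results.append(
                GLMResult(
                    vertex=vertex,
                    window=w,
                    betas=dict(zip(model_set.phones, coef[1:])),
                    intercept=float(coef[0]),
                    residual_ss=rss,
                    condition_number=cond,
                )
            )
        out[vertex] = results
    return out


def epoch_average_betas(results: Sequence[GLMResult]) -> GLMResult:
    """Arithmetic mean of each beta (and the intercept) across windows.

    The epoch-averaged coefficients summarise the whole analysis epoch;
    feature fits are computed from these averaged betas.
    """
    if len(results) == 0:
        raise ValueError("cannot average an empty result list")
    phones = list(results[0].betas)
    for r in results:
        if list(r.betas) != phones:
            raise ValueError("results have mismatched phone sets")
    betas = {
        p: float(np.mean([r.betas[p] for r in results])) for p in phones
    }
    return GLMResult(
        vertex=results[0].vertex,
        window="epoch",
        betas=betas,
        intercept=float(np.mean([r.intercept for r in results])),
        residual_ss=float(np.mean([r.residual_ss for r in results])),
        condition_number=float(
            np.nanmax([r.condition_number for r in results])
        ),
    )


class _WindowEngine:
    """Precomputed least-squares solver for one model window.

    Caches the design matrix and its pseudo-inverse so that thousands of
    data vectors (vertices x permutations) can be fitted by matrix
    multiplication.  Solutions coincide with numpy lstsq (minimum-norm for
    rank-deficient designs) to numerical precision.
    """

    def __init__(self, model_set: PhoneModelSet, window: int) -> None:
        self.phones = model_set.phones
        models = {p: model_set.drdms[p][window] for p in self.phones}
        self.X = design_matrix(models, list(self.phones))
        sv = np.linalg.svd(self.X, compute_uv=False)
        self.cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else float("inf")
        self.pinv = np.linalg.pinv(self.X)

    def solve(self, y: np.ndarray) -> tuple[np.ndarray, float, float]:
        coef = self.pinv @ y
        resid = y - self.X @ coef
        return coef, float(resid @ resid), self.cond

    def solve_many(self, Y: np.ndarray) -> np.ndarray:
        """Coefficients for a (n_pairs, n_fits) stack of data vectors."""
        return self.pinv @ Y
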