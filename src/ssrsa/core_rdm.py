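"""RDM construction, vectorization and comparison primitives.

The representational dissimilarity matrix (RDM) is the shared currency of the
pipeline: a symmetric condition-by-condition matrix of pairwise response
dissimilarities with a zero diagonal.  All dissimilarities here are
correlation distances (1 - Pearson's r), bounded in [0, 2].

Upper-triangle vectorization uses a single fixed traversal order — row-major
over the strict upper triangle, i.e. (0,1), (0,2), ..., (0,n-1), (1,2), ... —
everywhere in the package.  Consistency of this order is what the GLM and
rank-correlation comparisons rely on; the order itself is arbitrary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats


class DegenerateInputError(ValueError):
    """Raised when a response vector has zero variance.

    Correlation distance is undefined for constant vectors; raising instead
    of propagating NaN keeps degenerate patterns from silently corrupting
    downstream GLM fits.
    """


@dataclass(frozen=True)
class ConditionSet:
    """Ordered set of condition (stimulus) identifiers.

    Conditions index the rows and columns of every RDM.  At least 3 are
    required (correlation distance needs length >= 3 response vectors and
    permutation tests need a non-trivial label space); fewer than 10 draws a
    warning because permutation nulls become coarse.
    """

    labels: tuple[str, ...]

    def __init__(self, labels: Iterable[str]) -> None:
        object.__setattr__(self, "labels", tuple(str(x) for x in labels))
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("condition labels must be unique")
        if len(self.labels) < 3:
            raise ValueError(
                f"need at least 3 conditions, got {len(self.labels)}"
            )
        if len(self.labels) < 10:
            warnings.warn(
                f"only {len(self.labels)} conditions; permutation nulls will "
                "be coarse",
                stacklevel=2,
            )

    @property
    def n(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        return self.labels.index(label)


@dataclass(frozen=True)
class RDM:
    """Symmetric condition-pair dissimilarity matrix with zero diagonal."""

    conditions: ConditionSet
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        n = self.conditions.n
        if v.shape != (n, n):
            raise ValueError(f"expected {n}x{n} matrix, got {v.shape}")
        if not np.allclose(v, v.T, atol=1e-10, equal_nan=False):
            raise ValueError("RDM must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-10):
            raise ValueError("RDM diagonal must be zero")
        if not np.all(np.isfinite(v)):
            raise ValueError("RDM entries must be finite")
        # store an exactly-symmetric, exactly-zero-diagonal copy
        v = (v + v.T) / 2.0
        np.fill_diagonal(v, 0.0)
        v.flags.writeable = False
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.conditions.n


@dataclass(frozen=True)
class DynamicRDM:
    """A time-indexed sequence of RDMs, one per sliding-window position."""

    frames: tuple[RDM, ...]
    window_ms: int
    step_ms: int

    def __post_init__(self) -> None:
        if len(self.frames) == 0:
            raise ValueError("DynamicRDM needs at least one frame")
        if self.window_ms <= 0 or self.step_ms <= 0:
            raise ValueError("window_ms and step_ms must be positive")
        cs = self.frames[0].conditions
        for k, f in enumerate(self.frames):
            if f.conditions.labels != cs.labels:
                raise ValueError(f"frame {k} has mismatched conditions")

    @property
    def conditions(self) -> ConditionSet:
        return self.frames[0].conditions

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, k: int) -> RDM:
        return self.frames[k]


def upper_triangle_length(n: int) -> int:
    """Number of strictly-upper-triangular entries of an n x n matrix."""
    return n * (n - 1) // 2


def _check_variance(x: np.ndarray, name: str) -> None:
    if np.ptp(x) == 0:
        raise DegenerateInputError(
            f"{name} has zero variance; correlation distance is undefined"
        )


def correlation_distance(x: Sequence[float], y: Sequence[float]) -> float:
    """Correlation distance 1 - Pearson's r between two response vectors.

    Both vectors must have length >= 3 and nonzero variance.  The result lies
    in [0, 2]: 0 for perfectly correlated, 2 for perfectly anticorrelated.
    """
    xv = np.asarray(x, dtype=np.float64)
    yv = np.asarray(y, dtype=np.float64)
    if xv.ndim != 1 or yv.ndim != 1 or xv.shape != yv.shape:
        raise ValueError("inputs must be 1-D vectors of equal length")
    if xv.size < 3:
        raise ValueError("vectors must have length >= 3")
    _check_variance(xv, "first vector")
    _check_variance(yv, "second vector")
    xc = xv - xv.mean()
    yc = yv - yv.mean()
    r = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    return float(np.clip(1.0 - r, 0.0, 2.0))


def rdm_from_response_matrix(
    responses: np.ndarray, conditions: ConditionSet
) -> RDM:
    """Build an RDM from a condition x feature response matrix.

    Entry (i, j) is the correlation distance between response rows i and j.
    Constant rows raise :class:`DegenerateInputError` naming the condition.
    """
    r = np.asarray(responses, dtype=np.float64)
    if r.ndim != 2:
        raise ValueError("responses must be a 2-D condition x feature matrix")
    if r.shape[0] != conditions.n:
        raise ValueError(
            f"expected {conditions.n} response rows, got {r.shape[0]}"
        )
    if r.shape[1] < 3:
        raise ValueError("response vectors must have >= 3 components")
    ranges = np.ptp(r, axis=1)
    if np.any(ranges == 0):
        bad = [conditions.labels[i] for i in np.flatnonzero(ranges == 0)]
        raise DegenerateInputError(
            f"constant response pattern for condition(s): {', '.join(bad)}"
        )
    with np.errstate(invalid="raise"):
        c = np.corrcoef(r)
    d = np.clip(1.0 - c, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    return RDM(conditions, d)


def upper_triangle_vector(rdm: RDM) -> np.ndarray:
    """Vectorize the strict upper triangle of an RDM in row-major order.

    Length is n(n-1)/2; the traversal order is the global package convention
    (see module docstring).
    """
    iu = np.triu_indices(rdm.n, k=1)
    return rdm.values[iu]


def rdm_from_upper_triangle(
    vec: np.ndarray, conditions: ConditionSet
) -> RDM:
    """Inverse of :func:`upper_triangle_vector` (lossless round trip)."""
    v = np.asarray(vec, dtype=np.float64)
    n = conditions.n
    if v.shape != (upper_triangle_length(n),):
        raise ValueError(
            f"expected vector of length {upper_triangle_length(n)}, "
            f"got {v.shape}"
        )
    m = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    m[iu] = v
    m = m + m.T
    return RDM(conditions, m)


def spearman_correlation(a: RDM, b: RDM) -> float:
    """Spearman rank correlation of two RDMs' upper-triangle vectors."""
    if a.conditions.labels != b.conditions.labels:
        raise ValueError("RDMs must share the same ConditionSet")
    va = upper_triangle_vector(a)
    vb = upper_triangle_vector(b)
    for v, name in ((va, "first"), (vb, "second")):
        if np.ptp(v) == 0:
            raise DegenerateInputError(
                f"{name} RDM has a constant upper triangle; Spearman "
                "correlation is undefined"
            )
    rho = stats.spearmanr(va, vb).statistic
    return float(rho)


def average_rdms(rdms: Sequence[RDM]) -> RDM:
    """Entrywise arithmetic mean of RDMs over a matching condition set.

    Used to average per-subject data RDMs into a single group RDM.
    """
    if len(rdms) == 0:
        raise ValueError("cannot average an empty list of RDMs")
    cs = rdms[0].conditions
    for k, r in enumerate(rdms):
        if r.conditions.labels != cs.labels:
            raise ValueError(f"RDM {k} has mismatched conditions")
    mean = np.mean([r.values for r in rdms], axis=0)
    return RDM(cs, mean)
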