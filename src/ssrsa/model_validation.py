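"""Second-order analysis of the phone model space.

Before re-expressing phone GLM coefficients in articulatory-feature terms,
the feature set itself is validated against the second-order similarity
structure of the phone models: the Spearman rank correlations between the
upper-triangle vectors of every pair of model RDMs at a given window.  Two
diagnostics quantify how well a binary feature partitions that structure:

* the Davies-Bouldin index of the 2-cluster labelling (lower = better
  separated), computed with models represented as the rank-transformed
  upper-triangle vectors of their RDM frames (Euclidean geometry matching
  the Spearman geometry of the second-order matrix);
* eta squared, the proportion of pairwise-dissimilarity variance explained
  by the partition, computed directly on the second-order distances
  (1 - rho) and comparable against the conventional 0.01 / 0.06 / 0.14
  small / medium / large benchmarks.

A non-metric MDS embedding visualises the model arrangement; the Pearson
correlation between embedded distances and input dissimilarities reports
how faithful the planar picture is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from scipy.stats import rankdata
from sklearn.manifold import MDS

from ssrsa.core_rdm import (
    DegenerateInputError,
    spearman_correlation,
    upper_triangle_vector,
)
from ssrsa.feature_space import FeatureMatrix
from ssrsa.machine_states import PhoneModelSet

#: Conventional eta-squared effect-size benchmarks (small, medium, large).
ETA_SQ_BENCHMARKS = (0.01, 0.06, 0.14)


@dataclass(frozen=True)
class SecondOrderMatrix:
    """Model-by-model Spearman similarity at one window position."""

    models: tuple[str, ...]
    rho: np.ndarray = field(repr=False)
    window_index: int = 0

    def __post_init__(self) -> None:
        r = np.asarray(self.rho, dtype=np.float64)
        m = len(self.models)
        if r.shape != (m, m):
            raise ValueError(f"rho must be {m}x{m}")
        if not np.allclose(np.diag(r), 1.0):
            raise ValueError("rho diagonal must be 1")
        if np.any(np.abs(r) > 1 + 1e-9):
            raise ValueError("rho entries must be in [-1, 1]")
        object.__setattr__(self, "rho", r)
        object.__setattr__(self, "models", tuple(self.models))

    @property
    def distances(self) -> np.ndarray:
        """The associated Spearman correlation distances 1 - rho."""
        d = 1.0 - self.rho
        np.fill_diagonal(d, 0.0)
        return d


def second_order_matrix(
    models: PhoneModelSet, window_index: int
) -> SecondOrderMatrix:
    """Pairwise Spearman correlations between model RDMs at one window."""
    phones = models.phones
    if len(phones) < 2:
        raise ValueError("need at least 2 models")
    m = len(phones)
    rho = np.eye(m)
    frames = {p: models.drdms[p][window_index] for p in phones}
    for i in range(m):
        for j in range(i + 1, m):
            try:
                r = spearman_correlation(frames[phones[i]], frames[phones[j]])
            except DegenerateInputError as e:
                raise DegenerateInputError(
                    f"phone '{phones[i]}' or '{phones[j]}' at window "
                    f"{window_index}: {e}"
                ) from e
            rho[i, j] = rho[j, i] = r
    return SecondOrderMatrix(phones, rho, window_index)


def davies_bouldin(points: np.ndarray, labels: np.ndarray) -> float:
    """Davies-Bouldin index for a 2-cluster labelling.

    (s1 + s2) / d12 with s_i the mean Euclidean distance of cluster i's
    points to their centroid and d12 the centroid separation.  Lower means
    better separated clusters; 0 when both clusters collapse onto their
    centroids.  Requires both classes present with >= 2 points each for a
    meaningful dispersion.
    """
    pts = np.asarray(points, dtype=np.float64)
    lab = np.asarray(labels).astype(bool)
    if pts.ndim != 2 or lab.shape != (pts.shape[0],):
        raise ValueError("points must be 2-D with one label per row")
    n1, n0 = int(lab.sum()), int((~lab).sum())
    if min(n0, n1) == 0:
        raise ValueError("both label classes must be non-empty")
    if min(n0, n1) < 2:
        raise ValueError(
            "each class needs >= 2 points for a meaningful dispersion"
        )
    c1 = pts[lab].mean(axis=0)
    c0 = pts[~lab].mean(axis=0)
    s1 = float(np.linalg.norm(pts[lab] - c1, axis=1).mean())
    s0 = float(np.linalg.norm(pts[~lab] - c0, axis=1).mean())
    d = float(np.linalg.norm(c1 - c0))
    if d == 0:
        if s0 == s1 == 0:
            return 0.0
        raise ValueError("coincident centroids: index undefined")
    return (s0 + s1) / d


def eta_squared(distances: np.ndarray, labels: np.ndarray) -> float:
    """Proportion of pairwise squared dissimilarity variance explained.

    Distance-based variance partition over a binary labelling:
    SS_total = (1/N) * sum over all pairs i<j of d_ij^2,
    SS_within = sum over groups g of (1/n_g) * sum over pairs within g,
    eta^2 = (SS_total - SS_within) / SS_total, clipped to [0, 1].
    Returns 0 (with a warning) when all points coincide (0/0 case).
    """
    d = np.asarray(distances, dtype=np.float64)
    lab = np.asarray(labels).astype(bool)
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T):
        raise ValueError("distances must be a symmetric square matrix")
    if lab.shape != (n,):
        raise ValueError("need one label per point")
    if lab.all() or (~lab).all():
        raise ValueError("both label classes must be non-empty")
    iu = np.triu_indices(n, k=1)
    d2 = d[iu] ** 2
    ss_total = d2.sum() / n
    if ss_total == 0:
        warnings.warn(
            "all points coincide; eta squared defined as 0", stacklevel=2
        )
        return 0.0
    ss_within = 0.0
    for group in (lab, ~lab):
        ng = int(group.sum())
        sub = d[np.ix_(group, group)]
        iug = np.triu_indices(ng, k=1)
        ss_within += (sub[iug] ** 2).sum() / ng
    return float(np.clip((ss_total - ss_within) / ss_total, 0.0, 1.0))


def model_points(models: PhoneModelSet, window_index: int) -> np.ndarray:
    """Rank-transformed upper-triangle vectors of the model RDM frames.

    Rank transformation matches the Spearman geometry of the second-order
    matrix while giving the Davies-Bouldin index the point space with
    centroids it requires.
    """
    rows = []
    for p in models.phones:
        v = upper_triangle_vector(models.drdms[p][window_index])
        rows.append(rankdata(v))
    return np.asarray(rows)


def mds_embed(
    distances: np.ndarray,
    dim: int = 2,
    *,
    metric: bool = False,
    seed: int = 0,
    n_init: int = 8,
) -> tuple[np.ndarray, float]:
    """Stress-minimising MDS embedding of a dissimilarity matrix.

    Non-metric by default (rank-based input matches Spearman distances);
    multiple restarts with a fixed seed.  Returns the coordinates and the
    distance-dissimilarity correlation: Pearson r between embedded pairwise
    distances and the input dissimilarities, a measure of how little the
    planar compression distorts the true arrangement.
    """
    d = np.asarray(distances, dtype=np.float64)
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distances must be a symmetric square matrix")
    mds = MDS(
        n_components=dim,
        metric=metric,
        dissimilarity="precomputed",
        n_init=n_init,
        random_state=seed,
        normalized_stress="auto",
        max_iter=500,
    )
    with warnings.catch_warnings():
        # scikit-learn is migrating the MDS keyword names; the settings
        # above are equivalent under both APIs
        warnings.simplefilter("ignore", FutureWarning)
        coords = mds.fit_transform(d)
    emb = pdist(coords)
    iu = np.triu_indices(n, k=1)
    corr = float(np.corrcoef(emb, d[iu])[0, 1])
    return coords, corr


@dataclass(frozen=True)
class ClusterDiagnostics:
    """Per-feature separation diagnostics aggregated over the epoch."""

    feature: str
    category: str
    db_index_mean: float
    db_index_sd: float
    eta_sq_mean: float
    eta_sq_sd: float
    n_windows: int


def feature_cluster_diagnostics(
    models: PhoneModelSet,
    fm: FeatureMatrix,
    window_indices: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Davies-Bouldin and eta-squared for every feature, per window.

    Diagnostics are aggregated by mean with standard deviation across the
    epoch's windows.  Features whose presence/absence classes have fewer
    than 2 modelled phones are skipped (no meaningful dispersion).
    """
    windows = (
        list(range(models.n_windows))
        if window_indices is None
        else list(window_indices)
    )
    fitted = [p for p in fm.phones if p in models.phones]
    order = [models.phones.index(p) for p in fitted]
    # second-order structure is shared by all features at a given window
    per_window = []
    for w in windows:
        pts = model_points(models, w)[order]
        dist = second_order_matrix(models, w).distances[np.ix_(order, order)]
        per_window.append((pts, dist))
    rows = []
    for f in fm.features:
        lab = np.array([fm.chi(f, p) for p in fitted], dtype=bool)
        if min(lab.sum(), (~lab).sum()) < 2:
            continue
        dbs, etas = [], []
        for pts, dist in per_window:
            dbs.append(davies_bouldin(pts, lab))
            etas.append(eta_squared(dist, lab))
        rows.append(
            ClusterDiagnostics(
                feature=f,
                category=fm.category_of(f),
                db_index_mean=float(np.mean(dbs)),
                db_index_sd=float(np.std(dbs)),
                eta_sq_mean=float(np.mean(etas)),
                eta_sq_sd=float(np.std(etas)),
                n_windows=len(windows),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])
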