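"""Per-follow-up k-means in the (MMSE score, MMSE decline) plane.

Clustering is done on standardized coordinates (both axes scaled to unit
variance; MMSE spans 0-30 while declines span roughly ±15, so unscaled
Euclidean distance would let the score dominate), with centroids reported back
in original units. The number of clusters is chosen by combining three
diagnostics — the inertia elbow, the mean silhouette, and the Tibshirani gap
statistic with uniform bounding-box references — and a four-cluster solution is
mapped onto the four canonical cognitive archetypes so that cluster identities
are comparable across Monte-Carlo runs and follow-ups:

1. high MMSE score, improvement or no decline
2. high MMSE score with cognitive decline
3. low MMSE score with little/variable decline
4. high decliners
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .exceptions import InputError

logger = logging.getLogger(__name__)

CANONICAL_LABELS = {
    1: "high MMSE, no decline",
    2: "high MMSE, decline",
    3: "low MMSE, variable decline",
    4: "high decliners",
}

# archetype reference points in centroid z-score space (score_z, decline_z)
_ARCHETYPES = {
    1: np.array([1.0, 1.0]),
    2: np.array([1.0, -1.0]),
    3: np.array([-1.0, 0.5]),
    4: np.array([-1.0, -1.5]),
}


@dataclass
class ClusterResult:
    """A fitted k-means solution for one follow-up table."""

    k: int
    centroids: np.ndarray  # (k, 2), original (mmse_score, mmse_decline) units
    assignment: np.ndarray  # (n,) raw cluster index 0..k-1
    inertia: float  # within-cluster SSQ in scaled space
    seed: int
    followup_index: int | None = None
    scale_mean: np.ndarray = field(default=None)
    scale_std: np.ndarray = field(default=None)


@dataclass
class KSelectionDiagnostics:
    """Elbow / silhouette / gap curves over a candidate k range."""

    k_range: np.ndarray
    inertia: np.ndarray
    silhouette: np.ndarray  # NaN where undefined (k < 2)
    gap: np.ndarray
    gap_se: np.ndarray


@dataclass
class CanonicalLabelMap:
    """Bijection raw cluster index (0-based) -> canonical archetype label (1-4)."""

    mapping: dict[int, int]

    def apply(self, assignment: np.ndarray) -> np.ndarray:
        lut = np.empty(max(self.mapping) + 1, dtype=int)
        for raw, label in self.mapping.items():
            lut[raw] = label
        return lut[assignment]


def _scaled(points: np.ndarray, scale: bool) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise InputError("points must be an n x 2 array of (mmse_score, mmse_decline)")
    if scale:
        mean = points.mean(axis=0)
        std = points.std(axis=0)
        if (std == 0).any():
            raise InputError("cannot standardize: a clustering variable is constant")
        return (points - mean) / std, mean, std
    return points, np.zeros(2), np.ones(2)


def fit_kmeans(
    points: np.ndarray,
    k: int,
    seed: int,
    followup_index: int | None = None,
    scale: bool = True,
    n_init: int = 10,
) -> ClusterResult:
    """Lloyd's k-means with k-means++ starts on standardized coordinates.

    ``n_init`` restarts are run and the best-inertia solution kept; convergence
    tolerance is 1e-4 on centroid movement with at most 300 iterations.
    Centroids are reported in original units. Identical (points, k, seed) give
    identical results.
    """
    X, mean, std = _scaled(points, scale)
    n = len(X)
    if n < k:
        raise InputError(f"need at least k={k} points, got {n}")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_init,
        max_iter=300,
        tol=1e-4,
        random_state=int(seed) % (2**32),
    )
    assignment = km.fit_predict(X)
    sizes = np.bincount(assignment, minlength=k)
    if (sizes == 0).any():  # scikit-learn relocates empty clusters; guard anyway
        raise InputError("k-means produced an empty cluster")
    centroids = km.cluster_centers_ * std + mean
    return ClusterResult(
        k=k,
        centroids=centroids,
        assignment=assignment,
        inertia=float(km.inertia_),
        seed=int(seed),
        followup_index=followup_index,
        scale_mean=mean,
        scale_std=std,
    )


def k_diagnostics(
    points: np.ndarray,
    k_range: range | tuple[int, ...] = range(1, 9),
    seed: int = 0,
    n_reference: int = 10,
    scale: bool = True,
    silhouette_sample_size: int = 5000,
) -> KSelectionDiagnostics:
    """Inertia, mean silhouette and gap statistic over ``k_range``.

    The gap statistic follows the Tibshirani construction: for each k,
    ``gap(k) = mean_b log(W*_kb) − log(W_k)`` over ``n_reference`` datasets
    drawn uniformly over the bounding box of the (scaled) data, with standard
    error ``sd_b(log W*) · sqrt(1 + 1/B)``. Silhouette is computed on a
    subsample when n exceeds ``silhouette_sample_size``.
    """
    X, _, _ = _scaled(points, scale)
    if np.ptp(X, axis=0).max() == 0:
        raise InputError("all points identical; k-selection is undefined")
    ks = np.asarray(sorted(k_range), dtype=int)
    if len(X) < ks.max():
        raise InputError("more candidate clusters than points")
    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    references = [rng.uniform(lo, hi, size=X.shape) for _ in range(n_reference)]

    def _wk(data: np.ndarray, k: int, rs: int) -> float:
        if k == 1:
            return float(((data - data.mean(axis=0)) ** 2).sum())
        km = KMeans(n_clusters=k, n_init=5, max_iter=300, tol=1e-4, random_state=rs)
        km.fit(data)
        return float(km.inertia_)

    inertia = np.empty(len(ks))
    sil = np.full(len(ks), np.nan)
    gap = np.empty(len(ks))
    gap_se = np.empty(len(ks))
    for i, k in enumerate(ks):
        rs = int(rng.integers(2**31))
        if k == 1:
            inertia[i] = _wk(X, 1, rs)
        else:
            km = KMeans(n_clusters=k, n_init=10, max_iter=300, tol=1e-4, random_state=rs)
            labels = km.fit_predict(X)
            inertia[i] = float(km.inertia_)
            if k <= len(X) - 1:  # silhouette needs at least one multi-point cluster
                kwargs = {}
                if len(X) > silhouette_sample_size:
                    kwargs = {
                        "sample_size": silhouette_sample_size,
                        "random_state": rs,
                    }
                sil[i] = float(silhouette_score(X, labels, **kwargs))
        log_wstar = np.array(
            [np.log(_wk(ref, k, rs + b + 1)) for b, ref in enumerate(references)]
        )
        gap[i] = float(log_wstar.mean() - np.log(inertia[i]))
        gap_se[i] = float(log_wstar.std(ddof=1) * np.sqrt(1.0 + 1.0 / n_reference))
    return KSelectionDiagnostics(ks, inertia, sil, gap, gap_se)


def _elbow_knee(ks: np.ndarray, inertia: np.ndarray) -> int:
    """Maximum-curvature point of the inertia curve (chord-distance rule).

    Normalizes both axes to [0, 1] and returns the k whose point lies farthest
    below the straight line joining the two endpoints of the curve.
    """
    x = (ks - ks.min()) / max(ks.max() - ks.min(), 1)
    span = inertia.max() - inertia.min()
    y = (inertia - inertia.min()) / (span if span > 0 else 1.0)
    chord = 1.0 - x  # line from (0, 1) to (1, 0)
    return int(ks[np.argmax(chord - y)])


def select_k(
    diagnostics: KSelectionDiagnostics, return_candidates: bool = False
) -> int | tuple[int, dict[str, int | None]]:
    """Choose k by combining the gap 1-SE rule, the elbow knee, and silhouette.

    The gap candidate is the smallest k with ``gap(k) >= gap(k+1) − SE(k+1)``.
    A gap candidate of 1 means no cluster structure and is returned as is.
    Otherwise the chosen k is the smallest k satisfying the gap rule that lies
    within ±1 of the elbow knee; when several such k exist and the
    silhouette-maximizing k is among them, it wins the tie. If no k satisfies
    the joint rule, the gap candidate is returned with a logged warning.
    With ``return_candidates=True`` the three per-method candidates are also
    returned.
    """
    ks = diagnostics.k_range
    if len(ks) < 3:
        raise InputError("k-selection needs at least three candidate k values")
    gap_ok = [
        int(ks[i])
        for i in range(len(ks) - 1)
        if diagnostics.gap[i] >= diagnostics.gap[i + 1] - diagnostics.gap_se[i + 1]
    ]
    gap_k = gap_ok[0] if gap_ok else int(ks[-1])
    knee = _elbow_knee(ks, diagnostics.inertia)
    sil_k = (
        int(ks[np.nanargmax(diagnostics.silhouette)])
        if np.isfinite(diagnostics.silhouette).any()
        else None
    )
    candidates = {"gap": gap_k, "elbow": knee, "silhouette": sil_k}

    if gap_k == 1:
        chosen = 1
    else:
        joint = [k for k in gap_ok if abs(k - knee) <= 1]
        if not joint:
            logger.warning(
                "no k satisfies both the gap 1-SE rule and the elbow knee; "
                "falling back to the gap candidate k=%d",
                gap_k,
            )
            chosen = gap_k
        elif sil_k in joint:
            chosen = sil_k
        else:
            chosen = min(joint)
    return (chosen, candidates) if return_candidates else chosen


def canonicalize(result: ClusterResult) -> CanonicalLabelMap:
    """Map the four raw clusters onto the canonical cognitive archetypes.

    The four centroids are z-scored among themselves per axis (making the map
    invariant to units and to permutations of raw indices) and matched to four
    fixed archetype reference points by minimum-cost perfect matching, so the
    resulting map is always a bijection onto labels 1-4.
    """
    if result.k != 4:
        raise InputError("canonical archetype labels are defined only for k = 4")
    c = np.asarray(result.centroids, dtype=float)
    std = c.std(axis=0)
    std[std == 0] = 1.0
    z = (c - c.mean(axis=0)) / std
    refs = np.stack([_ARCHETYPES[label] for label in (1, 2, 3, 4)])
    cost = ((z[:, None, :] - refs[None, :, :]) ** 2).sum(axis=2)
    rows, cols = linear_sum_assignment(cost)
    return CanonicalLabelMap({int(r): int(cols[i]) + 1 for i, r in enumerate(rows)})
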