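"""Spatially regularized fuzzy c-means segmentation.

Voxels of ~2 mm in a 3-4 mm aqueduct mix CSF and tissue signal (partial
volume), so crisp thresholding misplaces the lumen boundary. Fuzzy c-means
(FCM) assigns each voxel graded memberships u_ik to c intensity clusters by
minimizing sum_ik u_ik^m ||x_i - c_k||^2; the spatial variant additionally
pulls each voxel's memberships toward those of its neighborhood, suppressing
isolated misclassified voxels:

    u'_ik  proportional to  u_ik^p * h_ik^q,

where h_ik is the sum of cluster-k memberships over the voxel's
neighborhood. With q = 0 the update reduces to classic FCM.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve, label
from sklearn.base import BaseEstimator

__all__ = ["MembershipMap", "SpatialFuzzyCMeans", "spatial_fcm", "mask_from_membership"]


@dataclass
class MembershipMap:
    """Per-voxel cluster memberships and the fitted intensity centroids.

    ``memberships`` has shape ``(c, nx, ny, nz)`` and sums to 1 over clusters
    at every voxel; ``centroids`` are sorted ascending, so the CSF cluster of
    a T2-like image is the last one.
    """

    memberships: np.ndarray
    centroids: np.ndarray
    n_iter: int
    converged: bool

    @property
    def n_clusters(self) -> int:
        return self.centroids.size

    def hard_labels(self) -> np.ndarray:
        return np.argmax(self.memberships, axis=0)


class SpatialFuzzyCMeans(BaseEstimator):
    """Spatial fuzzy c-means on a 3D scalar volume, sklearn-estimator style.

    Parameters
    ----------
    n_clusters : int, default 3
        Intensity classes; 3 covers background / brain / CSF.
    m : float, default 2.0
        Fuzzifier (> 1); 2 is the standard choice.
    p, q : float, defaults 1.0, 1.0
        Exponents of the membership and spatial terms. ``q=0`` recovers
        classic FCM.
    neighborhood_radius : int, default 1
        Chebyshev radius of the cubic neighborhood (1 -> 3x3x3).
    tol : float, default 1e-5
        Convergence threshold on the maximum centroid change.
    max_iter : int, default 200
    init : 'percentile' or 'random'
        'percentile' places centroids at evenly spaced intensity percentiles
        (deterministic); 'random' samples voxel intensities.
    random_state : int or None
        Used only for 'random' init and empty-cluster reseeding.

    Attributes (after ``fit``)
    --------------------------
    cluster_centers_ : ndarray (n_clusters,), sorted ascending
    memberships_ : ndarray (n_clusters, nx, ny, nz)
    n_iter_ : int
    converged_ : bool
    """

    def __init__(
        self,
        n_clusters: int = 3,
        m: float = 2.0,
        p: float = 1.0,
        q: float = 1.0,
        neighborhood_radius: int = 1,
        tol: float = 1e-5,
        max_iter: int = 200,
        init: str = "percentile",
        random_state: int | None = None,
    ):
        self.n_clusters = n_clusters
        self.m = m
        self.p = p
        self.q = q
        self.neighborhood_radius = neighborhood_radius
        self.tol = tol
        self.max_iter = max_iter
        self.init = init
        self.random_state = random_state

    # -- internals ---------------------------------------------------------
    def _init_centroids(self, x: np.ndarray) -> np.ndarray:
        if self.init == "percentile":
            qs = np.linspace(10, 90, self.n_clusters)
            return np.percentile(x, qs)
        if self.init == "random":
            rng = np.random.default_rng(self.random_state)
            return np.sort(rng.choice(x, size=self.n_clusters, replace=False))
        raise ValueError(f"unknown init {self.init!r}")

    def _memberships(self, x: np.ndarray, centroids: np.ndarray) -> np.ndarray:
        """Closed-form FCM memberships from centroid distances, (c, n)."""
        d2 = (x[None, :] - centroids[:, None]) ** 2
        zero = d2 < 1e-30
        any_zero = zero.any(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = d2 ** (-1.0 / (self.m - 1.0))
            soft = inv / inv.sum(axis=0)
        crisp = zero / np.maximum(zero.sum(axis=0), 1)
        return np.where(any_zero[None, :], crisp, soft)

    def fit(self, X: np.ndarray, y=None) -> "SpatialFuzzyCMeans":
        """Cluster the volume ``X`` (3D array of finite intensities)."""
        vol = np.asarray(X, dtype=float)
        if vol.ndim != 3:
            raise ValueError("X must be a 3D scalar volume")
        if not np.all(np.isfinite(vol)):
            raise ValueError("X must be finite")
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if self.m <= 1:
            raise ValueError("fuzzifier m must be > 1")
        x = vol.ravel()
        c = self.n_clusters
        centroids = self._init_centroids(x)
        rng = np.random.default_rng(self.random_state)
        k_size = 2 * self.neighborhood_radius + 1
        kernel = np.ones((k_size,) * 3)

        converged = False
        u = self._memberships(x, centroids)
        for it in range(1, self.max_iter + 1):
            u = self._memberships(x, centroids)
            if self.q != 0.0:
                h = np.empty_like(u)
                for k in range(c):
                    h[k] = convolve(
                        u[k].reshape(vol.shape), kernel, mode="constant", cval=0.0
                    ).ravel()
                num = (u ** self.p) * (h ** self.q)
                u = num / num.sum(axis=0)
            um = u ** self.m
            weights = um.sum(axis=1)
            empty = weights < 1e-12
            if np.any(empty):
                warnings.warn(
                    f"{int(empty.sum())} empty cluster(s); reinitializing from "
                    "data quantiles", RuntimeWarning,
                )
                for k in np.flatnonzero(empty):
                    centroids[k] = np.quantile(x, rng.uniform(0.05, 0.95))
                continue
            new_centroids = um @ x / weights
            order = np.argsort(new_centroids)
            new_centroids = new_centroids[order]
            u = u[order]
            shift = np.max(np.abs(new_centroids - centroids[np.argsort(centroids)]))
            centroids = new_centroids
            if shift < self.tol:
                converged = True
                break

        self.cluster_centers_ = centroids
        self.memberships_ = u.reshape((c,) + vol.shape)
        self.n_iter_ = it
        self.converged_ = converged
        self._shape_ = vol.shape
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Hard labels (index into sorted centroids) for a volume."""
        vol = np.asarray(X, dtype=float)
        u = self._memberships(vol.ravel(), self.cluster_centers_)
        return np.argmax(u, axis=0).reshape(vol.shape)

    def fit_predict(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X).membership_map().hard_labels()

    def membership_map(self) -> MembershipMap:
        return MembershipMap(
            memberships=self.memberships_,
            centroids=self.cluster_centers_,
            n_iter=self.n_iter_,
            converged=self.converged_,
        )


def spatial_fcm(
    image: np.ndarray,
    c: int = 3,
    m: float = 2.0,
    spatial_p: float = 1.0,
    spatial_q: float = 1.0,
    neighborhood_radius: int = 1,
    tol: float = 1e-5,
    max_iter: int = 200,
    seed: int | None = None,
    init: str = "percentile",
) -> MembershipMap:
    """Functional wrapper around :class:`SpatialFuzzyCMeans`."""
    est = SpatialFuzzyCMeans(
        n_clusters=c, m=m, p=spatial_p, q=spatial_q,
        neighborhood_radius=neighborhood_radius, tol=tol, max_iter=max_iter,
        init=init, random_state=seed,
    )
    return est.fit(image).membership_map()


def mask_from_membership(
    mm: MembershipMap, cluster: int, threshold: float = 0.5
) -> np.ndarray:
    """Boolean mask of voxels with u_cluster >= threshold, largest connected
    component only (6-connectivity).

    ``cluster`` indexes the ascending-sorted centroids (CSF of a T2-like
    image is ``mm.n_clusters - 1``). Raises if the mask comes out empty.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    raw = mm.memberships[cluster] >= threshold
    if not raw.any():
        raise ValueError(
            f"empty mask: no voxel reaches membership threshold {threshold} "
            f"for cluster {cluster}"
        )
    structure = np.zeros((3, 3, 3), dtype=bool)
    structure[1, 1, :] = structure[1, :, 1] = structure[:, 1, 1] = True
    labels, n = label(raw, structure=structure)
    if n == 1:
        return raw
    sizes = np.bincount(labels.ravel())[1:]
    return labels == (int(np.argmax(sizes)) + 1)
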