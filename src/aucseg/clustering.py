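"""Interchangeable 1-D intensity clustering backends.

Each segmentation stage clusters the normalized intensities of a single
modality (a 1-D feature per voxel) into a small number of subclasses and
then selects the subclass with the highest mean intensity. Four backends
share one result contract:

* ``kmeans`` — full-batch Lloyd iterations minimizing the within-cluster
  sum of squares J = sum_j sum_{i in j} (x_i - c_j)^2, k-means++ seeded.
* ``minibatch_kmeans`` — stochastic mini-batch updates of the same
  objective (scikit-learn).
* ``fcm`` — fuzzy c-means: soft memberships u_ij with sum_j u_ij = 1,
  alternating the Lagrange-condition updates for memberships and
  centroids.
* ``gmm`` — a univariate Gaussian mixture fit by EM, hard labels by
  maximum posterior responsibility.

All backends are deterministic given (samples, hyper-parameters, seed),
and all return centroids sorted in ascending intensity order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import MiniBatchKMeans

from .io_model import AucsegError

__all__ = [
    "ClusterResult",
    "FuzzyMembership",
    "GaussianMixtureParams",
    "fit_kmeans",
    "fit_fcm",
    "fit_gmm",
    "fit_backend",
    "fcm_memberships",
    "highest_intensity_cluster_mask",
    "BACKENDS",
]

BACKENDS = ("kmeans", "minibatch_kmeans", "fcm", "gmm")

DEFAULT_TOL = 1e-4
DEFAULT_MAX_ITER = 300
DEFAULT_FUZZIFIER = 2.0
DEFAULT_VAR_FLOOR = 1e-6
DEFAULT_BATCH_SIZE = 1024
_N_INIT = 10  # k-means restarts; best objective kept


@dataclass
class ClusterResult:
    """Hard clustering of 1-D samples into ``k`` subclasses."""

    labels: np.ndarray
    k: int
    centroids: np.ndarray
    method: str
    n_iter: int
    converged: bool
    #: objective value after each assignment step (full-batch k-means only)
    objective_trace: Optional[np.ndarray] = None

    @property
    def counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)


@dataclass
class FuzzyMembership:
    """FCM soft memberships: rows (samples) sum to one."""

    memberships: np.ndarray
    fuzzifier: float
    #: max |row-sum - 1| observed at each iteration (constraint audit)
    row_sum_error_trace: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def hard_labels(self) -> np.ndarray:
        return np.argmax(self.memberships, axis=1)


@dataclass
class GaussianMixtureParams:
    """Univariate mixture parameters and the per-iteration EM trace."""

    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    log_likelihood_trace: np.ndarray


def _prepare_samples(samples: np.ndarray) -> np.ndarray:
    x = np.asarray(samples, dtype=np.float64).ravel()
    if x.size == 0:
        raise AucsegError("no samples to cluster")
    if not np.all(np.isfinite(x)):
        raise AucsegError("samples must be finite")
    return x


def _effective_k(x: np.ndarray, k: int) -> int:
    if k < 1:
        raise AucsegError("number of subclasses must be >= 1")
    n_distinct = np.unique(x).size
    if k > n_distinct:
        warnings.warn(
            f"requested {k} subclasses but only {n_distinct} distinct values; "
            f"reducing to {n_distinct}",
            stacklevel=3,
        )
        return n_distinct
    return k


def _kmeans_pp_init(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding: next center drawn with probability proportional
    to squared distance from the nearest chosen center."""
    centers = np.empty(k)
    centers[0] = x[rng.integers(x.size)]
    d2 = (x - centers[0]) ** 2
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:  # all remaining mass on chosen points
            centers[j] = x[rng.integers(x.size)]
            continue
        centers[j] = x[rng.choice(x.size, p=d2 / total)]
        d2 = np.minimum(d2, (x - centers[j]) ** 2)
    return centers


def _lloyd(
    x: np.ndarray, k: int, rng: np.random.Generator, tol: float, max_iter: int
) -> tuple[np.ndarray, np.ndarray, float, list[float], int, bool]:
    centers = _kmeans_pp_init(x, k, rng)
    trace: list[float] = []
    labels = np.zeros(x.size, dtype=np.intp)
    converged = False
    j_prev = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        d2 = (x[:, None] - centers[None, :]) ** 2
        labels = np.argmin(d2, axis=1)
        obj = float(d2[np.arange(x.size), labels].sum())
        trace.append(obj)
        if j_prev - obj <= tol * max(abs(j_prev), 1e-12) and np.isfinite(j_prev):
            converged = True
            break
        j_prev = obj
        counts = np.bincount(labels, minlength=k)
        sums = np.bincount(labels, weights=x, minlength=k)
        nonempty = counts > 0
        centers[nonempty] = sums[nonempty] / counts[nonempty]
        # empty cluster: relocate to the farthest point from its center
        for j in np.nonzero(~nonempty)[0]:
            far = np.argmax((x - centers[labels]) ** 2)
            centers[j] = x[far]
    return labels, centers, trace[-1], trace, it, converged


def _sorted_by_centroid(
    labels: np.ndarray, centroids: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    order = np.argsort(centroids, kind="stable")
    remap = np.empty_like(order)
    remap[order] = np.arange(order.size)
    return remap[labels], centroids[order], order


def fit_kmeans(
    samples: np.ndarray,
    k: int,
    batch_size: Optional[int] = None,
    seed: int = 0,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> ClusterResult:
    """Fit k-means (full-batch Lloyd, or mini-batch when ``batch_size``
    is given) to 1-D samples.

    The full-batch path records the objective after every assignment
    step; the objective is non-increasing across iterations. If ``k``
    exceeds the number of distinct values it is reduced with a warning.
    """
    x = _prepare_samples(samples)
    k = _effective_k(x, k)
    if batch_size is not None:
        est = MiniBatchKMeans(
            n_clusters=k,
            init="k-means++",
            n_init=1,
            batch_size=int(batch_size),
            max_iter=max_iter,
            random_state=seed,
        ).fit(x[:, None])
        labels, centroids, _ = _sorted_by_centroid(
            est.labels_.astype(np.intp), est.cluster_centers_.ravel()
        )
        return ClusterResult(
            labels=labels,
            k=k,
            centroids=centroids,
            method="minibatch_kmeans",
            n_iter=int(est.n_iter_),
            converged=True,
        )

    best = None
    for restart in range(_N_INIT):
        rng = np.random.default_rng([seed, restart])
        result = _lloyd(x, k, rng, tol, max_iter)
        if best is None or result[2] < best[2]:
            best = result
    labels, centroids, _, trace, n_iter, converged = best  # type: ignore[misc]
    labels, centroids, _ = _sorted_by_centroid(labels, centroids)
    return ClusterResult(
        labels=labels,
        k=k,
        centroids=centroids,
        method="kmeans",
        n_iter=n_iter,
        converged=converged,
        objective_trace=np.asarray(trace),
    )


def fcm_memberships(
    samples: np.ndarray, centroids: np.ndarray, m: float
) -> np.ndarray:
    """FCM membership update: u_ij = 1 / sum_l (d_ij / d_il)^(2/(m-1)).

    A sample coincident with a centroid receives membership 1 for that
    centroid (zero-distance rule).
    """
    x = np.asarray(samples, dtype=np.float64).ravel()
    c = np.asarray(centroids, dtype=np.float64).ravel()
    d = np.abs(x[:, None] - c[None, :])
    u = np.zeros((x.size, c.size))
    zero_rows = (d == 0).any(axis=1)
    if zero_rows.any():
        hits = np.argmax(d[zero_rows] == 0, axis=1)
        u[np.nonzero(zero_rows)[0], hits] = 1.0
    reg = ~zero_rows
    if reg.any():
        inv = d[reg] ** (-2.0 / (m - 1.0))
        u[reg] = inv / inv.sum(axis=1, keepdims=True)
    return u


def fit_fcm(
    samples: np.ndarray,
    c: int,
    m: float = DEFAULT_FUZZIFIER,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    seed: int = 0,
) -> tuple[ClusterResult, FuzzyMembership]:
    """Fuzzy c-means by alternating membership/centroid updates.

    Converges when the max absolute membership change drops below
    ``tol``; non-convergence at ``max_iter`` returns ``converged=False``
    with a warning. The fuzzifier ``m`` must exceed 1 (m -> 1 recovers
    hard k-means).
    """
    if m <= 1:
        raise AucsegError("FCM fuzzifier m must be > 1")
    x = _prepare_samples(samples)
    c = _effective_k(x, c)
    rng = np.random.default_rng([seed, 0])
    centroids = np.sort(_kmeans_pp_init(x, c, rng))
    u = fcm_memberships(x, centroids, m)
    row_err: list[float] = [float(np.abs(u.sum(axis=1) - 1.0).max())]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        um = u**m
        denom = um.sum(axis=0)
        nonzero = denom > 0
        centroids[nonzero] = (um.T @ x)[nonzero] / denom[nonzero]
        u_new = fcm_memberships(x, centroids, m)
        row_err.append(float(np.abs(u_new.sum(axis=1) - 1.0).max()))
        delta = float(np.abs(u_new - u).max())
        u = u_new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"FCM did not converge in {max_iter} iterations", stacklevel=2)
    labels = np.argmax(u, axis=1)
    labels, centroids_sorted, order = _sorted_by_centroid(labels, centroids)
    u = u[:, order]
    result = ClusterResult(
        labels=labels,
        k=c,
        centroids=centroids_sorted,
        method="fcm",
        n_iter=it,
        converged=converged,
    )
    membership = FuzzyMembership(
        memberships=u, fuzzifier=m, row_sum_error_trace=np.asarray(row_err)
    )
    return result, membership


def _gmm_log_prob(
    x: np.ndarray, weights: np.ndarray, means: np.ndarray, variances: np.ndarray
) -> np.ndarray:
    return (
        np.log(weights)[None, :]
        - 0.5 * np.log(2.0 * np.pi * variances)[None, :]
        - 0.5 * (x[:, None] - means[None, :]) ** 2 / variances[None, :]
    )


def fit_gmm(
    samples: np.ndarray,
    k: int,
    seed: int = 0,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    var_floor: float = DEFAULT_VAR_FLOOR,
) -> tuple[ClusterResult, GaussianMixtureParams]:
    """Fit a univariate k-component Gaussian mixture by EM.

    Initialization comes from a full-batch k-means fit. The
    log-likelihood is recorded every iteration and is non-decreasing (up
    to round-off); component variances are clamped to ``var_floor`` with
    a warning when a component collapses. Hard labels are the maximum
    posterior responsibility.
    """
    x = _prepare_samples(samples)
    if k > x.size:
        raise AucsegError(f"k={k} exceeds the number of samples n={x.size}")
    init = fit_kmeans(x, k, seed=seed, tol=tol, max_iter=max_iter)
    k = init.k  # may have been reduced for degenerate data
    counts = np.maximum(init.counts, 1)
    weights = counts / counts.sum()
    means = init.centroids.copy()
    variances = np.empty(k)
    clamped = False
    for j in range(k):
        members = x[init.labels == j]
        v = float(members.var()) if members.size else 0.0
        variances[j] = v
    if np.any(variances < var_floor):
        clamped = True
    variances = np.maximum(variances, var_floor)

    trace: list[float] = []
    converged = False
    it = 0
    resp = np.zeros((x.size, k))
    for it in range(1, max_iter + 1):
        log_prob = _gmm_log_prob(x, weights, means, variances)
        log_norm = logsumexp(log_prob, axis=1)
        ll = float(log_norm.sum())
        trace.append(ll)
        resp = np.exp(log_prob - log_norm[:, None])
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) <= tol * max(1.0, abs(ll)):
            converged = True
            break
        nj = resp.sum(axis=0)
        nj = np.maximum(nj, 1e-300)
        weights = nj / x.size
        means = (resp.T @ x) / nj
        new_var = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nj
        if np.any(new_var < var_floor):
            clamped = True
        variances = np.maximum(new_var, var_floor)
    if clamped:
        warnings.warn(
            f"GMM component variance clamped to floor {var_floor}", stacklevel=2
        )
    labels = np.argmax(resp, axis=1)
    labels, means_sorted, order = _sorted_by_centroid(labels, means)
    params = GaussianMixtureParams(
        weights=weights[order],
        means=means_sorted,
        variances=variances[order],
        log_likelihood_trace=np.asarray(trace),
    )
    result = ClusterResult(
        labels=labels,
        k=k,
        centroids=means_sorted,
        method="gmm",
        n_iter=it,
        converged=converged,
    )
    return result, params


def fit_backend(
    method: str,
    samples: np.ndarray,
    k: int,
    seed: int = 0,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    fuzzifier: float = DEFAULT_FUZZIFIER,
    var_floor: float = DEFAULT_VAR_FLOOR,
    batch_size: int = DEFAULT_BATCH_SIZE,
) -> ClusterResult:
    """Dispatch to a clustering backend by name and return its hard labels."""
    if method == "kmeans":
        return fit_kmeans(samples, k, seed=seed, tol=tol, max_iter=max_iter)
    if method == "minibatch_kmeans":
        return fit_kmeans(
            samples, k, batch_size=batch_size, seed=seed, tol=tol, max_iter=max_iter
        )
    if method == "fcm":
        return fit_fcm(samples, k, m=fuzzifier, tol=tol, max_iter=max_iter, seed=seed)[0]
    if method == "gmm":
        return fit_gmm(
            samples, k, seed=seed, tol=tol, max_iter=max_iter, var_floor=var_floor
        )[0]
    raise AucsegError(f"unknown clustering method {method!r}; choose from {BACKENDS}")


def highest_intensity_cluster_mask(
    result: ClusterResult, support_mask: np.ndarray
) -> np.ndarray:
    """Binary volume selecting the subclass with the highest centroid.

    ``support_mask`` is the boolean volume whose True voxels correspond,
    in C order, to the samples that were clustered. Ties on centroid
    intensity are broken toward the subclass with more members, then the
    lower index.
    """
    support_mask = np.asarray(support_mask, dtype=bool)
    n_support = int(support_mask.sum())
    if result.labels.size != n_support:
        raise AucsegError(
            f"cluster result covers {result.labels.size} samples but support has {n_support} voxels"
        )
    counts = result.counts
    # lexsort: last key is primary
    order = np.lexsort((np.arange(result.k), -counts, -result.centroids))
    best = int(order[0])
    if result.k == 1:
        warnings.warn("single subclass: selected mask equals entire support", stacklevel=2)
    mask = np.zeros(support_mask.shape, dtype=bool)
    mask[support_mask] = result.labels == best
    return mask
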