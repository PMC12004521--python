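"""Density-peaks clustering with adaptive k-NN density estimation.

This is a self-contained implementation of the *advanced density peaks*
family of algorithms: estimate the data's intrinsic dimension, estimate each
point's log-density (with an error bar) from an adaptively chosen number of
nearest neighbours, find density peaks, and merge statistically
indistinguishable clusters.

Pipeline:

1. **Intrinsic dimension** by the two-nearest-neighbour maximum-likelihood
   estimator: with mu_i = r2_i / r1_i, d = n / sum(ln mu_i).
2. **Adaptive k-NN density.**  For each point the neighbourhood is grown
   from ``k_min`` while the point's log-density estimate stays statistically
   compatible with that of its k-th neighbour (likelihood-ratio statistic
   (F_i - F_j)^2 / (2/k) below ``D_THRESHOLD``), capped at ``k_max``.  The
   log-density is F_i = ln k_i - d ln r_{i,k_i} (constants dropped; only
   differences matter) with error 1/sqrt(k_i).
3. **Peaks and assignment.**  A point is a provisional peak if no
   higher-density point lies within its adaptive neighbourhood; every other
   point inherits the label of its nearest higher-density point, processed
   in decreasing-density order.  Ties break on the lowest observation index.
4. **Z-gated merging.**  For each cluster pair the saddle is the highest
   min(F_i, F_j) over cross-cluster neighbour pairs; two clusters merge when
   the lower peak minus the saddle is below Z times the propagated error
   (peak and saddle errors summed in quadrature).  Merging repeats, least
   significant gap first, until every remaining gap is significant, so the
   cluster count is non-increasing in Z.

Distances support three metrics: plain Euclidean, periodic-angular (degrees;
per-coordinate minimal angular difference combined Euclidean-wise) for
dihedral features, and Manhattan for integer interface maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "ClusteringParams",
    "ClusterResult",
    "pairwise_distances",
    "twonn_dimension",
    "adp_cluster",
    "ZeroDistanceError",
]

# likelihood-ratio stopping threshold for neighbourhood growth (chi-square
# scale; high value favours large, smooth neighbourhoods)
D_THRESHOLD = 23.928


class ZeroDistanceError(ValueError):
    """Duplicate-only input: nearest-neighbour distances vanish."""


@dataclass(frozen=True)
class ClusteringParams:
    """Knobs of the density-peaks clustering.

    ``Z`` is the merging significance: larger Z merges more aggressively
    (cluster peaks must stand Z propagated-errors above their connecting
    saddle to survive).  ``metric`` is one of ``euclidean``,
    ``periodic-angular`` (degrees) or ``manhattan``.
    """

    Z: float = 3.0
    k_max: int = 100
    k_min: int = 4
    metric: str = "euclidean"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.Z <= 0:
            raise ValueError("Z must be positive")
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ValueError("need 2 <= k_min <= k_max")


@dataclass
class ClusterResult:
    """Labels, centers (highest-density member of each cluster), per-point
    log-density and optional per-observation provenance."""

    labels: np.ndarray
    centers: np.ndarray
    log_density: np.ndarray
    log_density_err: np.ndarray
    intrinsic_dimension: float
    k_per_point: np.ndarray
    provenance: list | None = None

    @property
    def n_clusters(self) -> int:
        return len(self.centers)


def pairwise_distances(X: np.ndarray, metric: str = "euclidean") -> np.ndarray:
    """Full pairwise distance matrix under the chosen metric."""
    X = np.asarray(X, dtype=float)
    if metric == "euclidean":
        return cdist(X, X)
    if metric == "manhattan":
        return cdist(X, X, metric="cityblock")
    if metric == "periodic-angular":
        # minimal per-coordinate angular difference (degrees), Euclidean combine
        diff = X[:, None, :] - X[None, :, :]
        diff = (diff + 180.0) % 360.0 - 180.0
        return np.sqrt((diff ** 2).sum(axis=2))
    raise ValueError(f"unknown metric {metric!r}")


def twonn_dimension(distances: np.ndarray) -> float:
    """Two-NN maximum-likelihood intrinsic dimension from a distance matrix."""
    n = distances.shape[0]
    if n < 3:
        raise ValueError("need at least 3 observations")
    order = np.sort(distances, axis=1)
    r1, r2 = order[:, 1], order[:, 2]
    if np.any(r1 == 0):
        raise ZeroDistanceError("duplicate observations give zero NN distances")
    mu = r2 / r1
    log_mu = np.log(mu)
    total = log_mu.sum()
    if total <= 0:
        raise ZeroDistanceError("degenerate neighbour ratios")
    return float(n / total)


def _adaptive_density(distances: np.ndarray, neighbors: np.ndarray,
                      sorted_d: np.ndarray, dim: float, k_min: int,
                      k_max: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Adaptive-k log-density per point.

    ``neighbors``/``sorted_d`` are the argsorted neighbour indices/distances
    (column 0 = the point itself).  Returns (log_density, err, k_hat).
    """
    n = distances.shape[0]
    k_cap = min(k_max, n - 1)

    def logF(k, r):
        return np.log(k) - dim * np.log(r)

    k_hat = np.full(n, k_min, dtype=int)
    for i in range(n):
        k = k_min
        while k < k_cap:
            j = neighbors[i, k]  # the k-th neighbour (1-based shells)
            r_i = sorted_d[i, k]
            r_j = sorted_d[j, k]
            if r_i == 0 or r_j == 0:
                raise ZeroDistanceError("zero neighbour distance during density estimation")
            fi = logF(k, r_i)
            fj = logF(k, r_j)
            stat = (fi - fj) ** 2 / (2.0 / k)
            if stat > D_THRESHOLD:
                break
            k += 1
        k_hat[i] = k
    r_k = sorted_d[np.arange(n), k_hat]
    if np.any(r_k == 0):
        raise ZeroDistanceError("zero neighbour distance at selected k")
    log_rho = np.log(k_hat) - dim * np.log(r_k)
    err = 1.0 / np.sqrt(k_hat)
    return log_rho, err, k_hat


def adp_cluster(observations: np.ndarray | None = None,
                params: ClusteringParams | None = None,
                distances: np.ndarray | None = None,
                provenance: list | None = None) -> ClusterResult:
    """Cluster observations by adaptive density peaks with Z-gated merging.

    Either ``observations`` (feature matrix; distances computed under
    ``params.metric``) or a precomputed symmetric ``distances`` matrix must
    be given.  Deterministic for a given input order; density ties break on
    the lowest observation index.
    """
    params = params or ClusteringParams()
    if distances is None:
        if observations is None:
            raise ValueError("provide observations or a distance matrix")
        observations = np.asarray(observations, dtype=float)
        if observations.ndim == 1:
            observations = observations[:, None]
        if len(observations) < 10:
            raise ValueError("need at least 10 observations")
        distances = pairwise_distances(observations, params.metric)
    n = distances.shape[0]
    if provenance is not None and len(provenance) != n:
        raise ValueError("provenance must have one entry per observation")

    neighbors = np.argsort(distances, kind="stable", axis=1)
    sorted_d = np.take_along_axis(distances, neighbors, axis=1)
    dim = twonn_dimension(distances)
    log_rho, err, k_hat = _adaptive_density(distances, neighbors, sorted_d, dim,
                                            params.k_min, params.k_max)

    # density order: decreasing density, ties by lowest index
    density_order = np.lexsort((np.arange(n), -log_rho))
    rank = np.empty(n, dtype=int)
    rank[density_order] = np.arange(n)

    # provisional peaks: no denser point within the adaptive neighbourhood
    labels = np.full(n, -1, dtype=int)
    parents = np.full(n, -1, dtype=int)
    peaks: list[int] = []
    for i in density_order:
        neigh = neighbors[i, 1: k_hat[i] + 1]
        denser = neigh[rank[neigh] < rank[i]]
        if len(denser) == 0:
            peaks.append(i)
            labels[i] = len(peaks) - 1
        else:
            parents[i] = denser[np.argmin(distances[i, denser])]
            labels[i] = labels[parents[i]]
        if labels[i] == -1:  # parent not labeled yet cannot happen (density order)
            raise RuntimeError("assignment order violated")

    n_clusters = len(peaks)
    peak_idx = np.asarray(peaks)

    if n_clusters > 1:
        labels, peak_idx = _merge_clusters(labels, peak_idx, neighbors, k_hat,
                                           log_rho, err, params.Z, distances)

    # relabel clusters by decreasing peak density, centers = peak points
    order = np.argsort([-log_rho[p] for p in peak_idx], kind="stable")
    remap = {old: new for new, old in enumerate(order)}
    labels = np.asarray([remap[l] for l in labels])
    centers = peak_idx[order]
    return ClusterResult(labels=labels, centers=centers, log_density=log_rho,
                         log_density_err=err, intrinsic_dimension=dim,
                         k_per_point=k_hat, provenance=provenance)


def _merge_clusters(labels, peak_idx, neighbors, k_hat, log_rho, err, Z, distances):
    """Iteratively merge cluster pairs whose peak-saddle gap is insignificant."""
    n = len(labels)
    # saddle per pair: highest min(F_i, F_j) over cross-cluster neighbour pairs
    saddle: dict[tuple[int, int], tuple[float, float]] = {}
    for i in range(n):
        for j in neighbors[i, 1: k_hat[i] + 1]:
            a, b = labels[i], labels[int(j)]
            if a == b:
                continue
            key = (min(a, b), max(a, b))
            f = min(log_rho[i], log_rho[int(j)])
            e = np.hypot(err[i], err[int(j)]) / np.sqrt(2.0)
            if key not in saddle or f > saddle[key][0]:
                saddle[key] = (f, e)

    clusters = {c: {"peak": int(p), "members": set(np.flatnonzero(labels == c))}
                for c, p in enumerate(peak_idx)}

    def fallback_saddle(a, b):
        # clusters without adjacent neighbourhoods: take the closest
        # cross-cluster pair as the (low-density) saddle point
        ia = np.fromiter(clusters[a]["members"], dtype=int)
        ib = np.fromiter(clusters[b]["members"], dtype=int)
        sub = distances[np.ix_(ia, ib)]
        flat = np.argmin(sub)
        i, j = int(ia[flat // len(ib)]), int(ib[flat % len(ib)])
        return (float(min(log_rho[i], log_rho[j])),
                float(np.hypot(err[i], err[j]) / np.sqrt(2.0)))

    def gap(a, b):
        key = (min(a, b), max(a, b))
        f_s, e_s = saddle[key] if key in saddle else fallback_saddle(a, b)
        pa, pb = clusters[a]["peak"], clusters[b]["peak"]
        low_peak = min(log_rho[pa], log_rho[pb])
        delta = low_peak - f_s
        etot = np.sqrt(err[pa] ** 2 + err[pb] ** 2 + e_s ** 2)
        return delta, etot

    while len(clusters) > 1:
        best = None
        for a in clusters:
            for b in clusters:
                if a >= b:
                    continue
                delta, etot = gap(a, b)
                score = delta / etot
                if best is None or score < best[0] or (score == best[0] and (a, b) < best[1:]):
                    best = (score, a, b)
        if best is None or best[0] >= Z:
            break
        _, a, b = best
        pa, pb = clusters[a]["peak"], clusters[b]["peak"]
        keep, drop = (a, b) if log_rho[pa] >= log_rho[pb] else (b, a)
        clusters[keep]["members"] |= clusters[drop]["members"]
        if log_rho[clusters[drop]["peak"]] > log_rho[clusters[keep]["peak"]]:
            clusters[keep]["peak"] = clusters[drop]["peak"]
        del clusters[drop]
        # re-route saddles of the dropped cluster to the kept one
        for key in list(saddle):
            if drop in key:
                other = key[0] if key[1] == drop else key[1]
                if other == keep:
                    del saddle[key]
                    continue
                new_key = (min(keep, other), max(keep, other))
                f, e = saddle.pop(key)
                if new_key not in saddle or f > saddle[new_key][0]:
                    saddle[new_key] = (f, e)

    new_labels = np.empty(n, dtype=int)
    new_peaks = []
    for new_c, (old_c, info) in enumerate(sorted(clusters.items())):
        for m in info["members"]:
            new_labels[m] = new_c
        new_peaks.append(info["peak"])
    return new_labels, np.asarray(new_peaks)
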