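"""Diagnostics: parameter RMSE, histogram mutual information, and k-means
cluster summaries over estimated parameters."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .inversion import ParameterVector

DEFAULT_MI_BINS = 16


@dataclass
class ClusterResult:
    k: int
    assignments: np.ndarray
    within_sse: float
    center_distances: float       # mean pairwise distance, per-parameter RMS
    composition: np.ndarray       # percentage of population per cluster
    cluster_means: np.ndarray     # (k, n_params)
    cluster_modes: np.ndarray
    cluster_sds: np.ndarray

    def __post_init__(self):
        if not np.isclose(self.composition.sum(), 100.0):
            raise ValueError("composition must sum to 100%")


def parameter_rmse(theta: ParameterVector, theta_hat: ParameterVector) -> float:
    """Root mean squared elementwise difference between two named vectors."""
    if theta.names != theta_hat.names:
        for a, b in zip(theta.names, theta_hat.names):
            if a != b:
                raise ValueError(f"parameter index mismatch at {a!r} vs {b!r}")
        raise ValueError("parameter vectors differ in length")
    diff = theta_hat.values - theta.values
    return float(np.sqrt(np.mean(diff ** 2)))


def mutual_information(x, y, n_bins: int = DEFAULT_MI_BINS) -> float:
    """Plug-in mutual information (nats) on an equal-width joint histogram.

    Zero-probability cells contribute 0; a constant input yields MI = 0 with
    a warning.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("signals must have equal length")
    if x.size < n_bins:
        raise ValueError("need at least n_bins samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant signal: MI is 0")
        return 0.0
    joint, _, _ = np.histogram2d(x, y, bins=n_bins)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))


def binned_entropy(x, n_bins: int = DEFAULT_MI_BINS) -> float:
    """Entropy (nats) of the equal-width marginal histogram of ``x``."""
    counts, _ = np.histogram(np.asarray(x, dtype=float).ravel(), bins=n_bins)
    p = counts / counts.sum()
    nz = p > 0
    return float(-np.sum(p[nz] * np.log(p[nz])))


def _bin_mode(col: np.ndarray, n_bins: int = DEFAULT_MI_BINS) -> float:
    # midpoint of the modal histogram bin (continuous-data "mode")
    counts, edges = np.histogram(col, bins=n_bins)
    j = int(np.argmax(counts))
    return 0.5 * (edges[j] + edges[j + 1])


def kmeans_cluster(params: np.ndarray, k: int, seed=None,
                   n_restarts: int = 10) -> ClusterResult:
    """Lloyd's k-means (best of ``n_restarts``) with the summary statistics
    used for population structure: total within-cluster SSE, mean pairwise
    center distance (RMS per parameter), composition percentages, and
    per-cluster mean/mode/sd."""
    params = np.asarray(params, dtype=float)
    n_subj, n_par = params.shape
    if k > n_subj:
        raise ValueError("k cannot exceed the number of subjects")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(params)
    centers = km.cluster_centers_

    if k > 1:
        dists = [np.sqrt(np.mean((centers[a] - centers[b]) ** 2))
                 for a in range(k) for b in range(a + 1, k)]
        center_dist = float(np.mean(dists))
    else:
        center_dist = 0.0

    comp = np.array([100.0 * np.mean(labels == c) for c in range(k)])
    means = np.vstack([params[labels == c].mean(axis=0) for c in range(k)])
    sds = np.vstack([params[labels == c].std(axis=0) for c in range(k)])
    modes = np.vstack([[_bin_mode(params[labels == c][:, j])
                        for j in range(n_par)] for c in range(k)])
    return ClusterResult(k=k, assignments=labels,
                         within_sse=float(km.inertia_),
                         center_distances=center_dist, composition=comp,
                         cluster_means=means, cluster_modes=modes,
                         cluster_sds=sds)
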