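"""Missing-node estimation: zero-, mean-, noise-, and EM-Gaussian filling.

All fill operations return a copy of the series with only the masked columns
replaced; unmasked data is preserved bit-exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .forward import DEFAULT_BASELINE, NodeTimeSeries

DEFAULT_NOISE_FILL_SD_FRAC = 0.0005  # 0.05% of mean signal level


@dataclass
class GaussianEstimate:
    """Multivariate-Gaussian fit with missing entries marginalized."""

    mean: np.ndarray
    cov: np.ndarray
    loglik_trace: np.ndarray
    n_iter: int
    converged: bool

    def marginal(self, node: int) -> tuple[float, float]:
        return float(self.mean[node]), float(np.sqrt(self.cov[node, node]))


def _node_mask(series: NodeTimeSeries, mask) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (series.n_nodes,):
        raise ValueError(
            f"mask has shape {mask.shape}, expected ({series.n_nodes},)")
    return mask


def fill_zero(series: NodeTimeSeries, mask) -> NodeTimeSeries:
    """Replace masked columns with zeros."""
    mask = _node_mask(series, mask)
    out = series.copy()
    out.bold[:, mask] = 0.0
    return out


def fill_mean(series: NodeTimeSeries, mask, cohort,
              subject_index: int | None = None) -> NodeTimeSeries:
    """Replace each masked column by the time-point-wise average of that node
    over donor subjects (subjects in ``cohort`` where the node is available,
    excluding the subject itself)."""
    mask = _node_mask(series, mask)
    if subject_index is None:
        for k, s in enumerate(cohort.subjects):
            if s is series or s.bold is series.bold:
                subject_index = k
                break
    out = series.copy()
    for node in np.flatnonzero(mask):
        donors = [k for k in range(cohort.n_subjects)
                  if k != subject_index and not cohort.missing_mask[k, node]]
        if not donors:
            raise ValueError(f"no donor subjects with node {node} available")
        out.bold[:, node] = np.mean(
            [cohort.subjects[k].bold[:, node] for k in donors], axis=0)
    return out


def _mean_signal_level(series: NodeTimeSeries, mask,
                       baseline=DEFAULT_BASELINE) -> float:
    """Mean over unmasked entries plus the implicit percent-signal baseline."""
    return float(np.mean(series.bold[:, ~mask])) + baseline


def fill_noise(series: NodeTimeSeries, mask,
               sd_frac: float = DEFAULT_NOISE_FILL_SD_FRAC,
               seed=None) -> NodeTimeSeries:
    """Replace masked columns with i.i.d. Gaussian noise of sd =
    ``sd_frac`` x mean signal level (default 0.05%)."""
    if sd_frac <= 0:
        raise ValueError("sd_frac must be positive")
    mask = _node_mask(series, mask)
    rng = np.random.default_rng(seed)
    out = series.copy()
    sd = sd_frac * abs(_mean_signal_level(series, mask))
    for node in np.flatnonzero(mask):
        out.bold[:, node] = rng.normal(0.0, sd, size=series.n_samples)
    return out


def em_fit_gaussian(series: NodeTimeSeries, mask, tol: float = 1e-6,
                    max_iter: int = 500, ridge: float = 1e-8,
                    missing: np.ndarray | None = None) -> GaussianEstimate:
    """Fit a multivariate Gaussian over node channels by EM, treating each
    time point as one observation and masked entries as missing at random.

    ``mask`` flags whole nodes; an explicit (samples x nodes) boolean
    ``missing`` matrix may be supplied instead for partial missingness.
    The E-step computes conditional moments of the missing entries given the
    observed ones; the M-step updates (mean, cov) from the completed
    sufficient statistics.  Iteration stops when the relative gain in
    observed-data log-likelihood drops below ``tol``.
    """
    X = np.asarray(series.bold, dtype=float)
    T, n = X.shape
    if missing is None:
        mask = _node_mask(series, mask)
        missing = np.broadcast_to(mask, (T, n)).copy()
    missing = np.asarray(missing, dtype=bool)
    if missing.all(axis=0).all():
        raise ValueError("at least one node must be observed")
    if T <= n:
        raise ValueError("need more time points than nodes")

    obs_any = ~missing.all(axis=0)
    pooled = X[:, obs_any][~missing[:, obs_any]]
    pooled_mean = float(np.mean(pooled))
    pooled_var = float(np.var(pooled))

    mu = np.empty(n)
    var0 = np.empty(n)
    for j in range(n):
        col_obs = X[~missing[:, j], j]
        if col_obs.size:
            mu[j] = col_obs.mean()
            var0[j] = col_obs.var() if col_obs.size > 1 else pooled_var
        else:
            mu[j] = pooled_mean
            var0[j] = pooled_var
    cov = np.diag(np.maximum(var0, 1e-12))

    patterns = {}
    for i in range(T):
        patterns.setdefault(tuple(missing[i]), []).append(i)

    loglik_trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        ex = X.copy()
        exx_corr = np.zeros((n, n))   # sum of conditional covariances
        loglik = 0.0
        for pat, rows in patterns.items():
            m = np.array(pat, dtype=bool)
            o = ~m
            rows = np.asarray(rows)
            Xo = X[np.ix_(rows, np.flatnonzero(o))]
            Soo = cov[np.ix_(o, o)]
            try:
                cho = linalg.cho_factor(Soo, lower=True)
            except linalg.LinAlgError:
                warnings.warn("singular covariance; applying ridge")
                Soo = Soo + ridge * np.trace(Soo) / max(o.sum(), 1) * np.eye(o.sum())
                cho = linalg.cho_factor(Soo, lower=True)
            dev = Xo - mu[o]
            solved = linalg.cho_solve(cho, dev.T)  # (n_o, rows)
            logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
            quad = np.einsum("ij,ji->i", dev, solved)
            loglik += -0.5 * np.sum(quad) - 0.5 * rows.size * (
                logdet + o.sum() * np.log(2.0 * np.pi))
            if m.any():
                Smo = cov[np.ix_(m, o)]
                cond_mean = mu[m] + (Smo @ solved).T
                ex[np.ix_(rows, np.flatnonzero(m))] = cond_mean
                cond_cov = cov[np.ix_(m, m)] - Smo @ linalg.cho_solve(
                    cho, Smo.T)
                exx_corr[np.ix_(m, m)] += rows.size * cond_cov
        loglik_trace.append(loglik)

        mu_new = ex.mean(axis=0)
        centered = ex - mu_new
        cov_new = (centered.T @ centered + exx_corr) / T
        cov_new = 0.5 * (cov_new + cov_new.T)
        mu, cov = mu_new, cov_new

        if it >= 2:
            prev, cur = loglik_trace[-2], loglik_trace[-1]
            if cur - prev < tol * (abs(prev) + 1e-12):
                converged = True
                break

    return GaussianEstimate(mean=mu, cov=cov,
                            loglik_trace=np.asarray(loglik_trace),
                            n_iter=it, converged=converged)


def fill_em(series: NodeTimeSeries, mask, seed=None, *,
            tol: float = 1e-6, max_iter: int = 500,
            conditional: bool = False) -> NodeTimeSeries:
    """Replace masked columns by i.i.d. Gaussian draws with EM-estimated
    marginal mean and variance (``conditional=True`` instead fills with the
    time-point conditional means given the observed nodes)."""
    mask = _node_mask(series, mask)
    out = series.copy()
    if not mask.any():
        return out
    est = em_fit_gaussian(series, mask, tol=tol, max_iter=max_iter)
    rng = np.random.default_rng(seed)
    if conditional:
        o = ~mask
        Soo = est.cov[np.ix_(o, o)]
        for node in np.flatnonzero(mask):
            w = np.linalg.solve(Soo, est.cov[np.flatnonzero(o), node])
            out.bold[:, node] = est.mean[node] + (
                series.bold[:, o] - est.mean[o]) @ w
    else:
        for node in np.flatnonzero(mask):
            m, sd = est.marginal(node)
            out.bold[:, node] = rng.normal(m, sd, size=series.n_samples)
    return out
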