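"""Bayesian inversion of a candidate model against a (filled) BOLD series.

The scheme is variational Laplace: Gauss-Newton updates of the posterior
mean with trust-region step halving, an analytic posterior-covariance
update, and EM updates of per-node noise precisions, maximizing the free
energy

    F = E_q[log p(y | theta)] - KL(q || prior)

which serves as the log-evidence approximation for model comparison.

Parameterization (see ``default_priors``): off-diagonal A entries are the
coupling weights themselves; modulatory entries are scaled by the neural
decay rate ``alpha`` (matching the generator); direct-input entries are in
units of the generator's input scale; hemodynamic entries are log-space
multipliers of the prior-mean constants, so their Gaussian priors are
log-normal priors on the constants.  Structurally absent parameters carry
prior variance 0 and are excluded from the optimization.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import linalg

from .cohort import DEFAULT_INPUT_SCALE, CandidateModel
from .forward import (DEFAULT_ALPHA_DECAY, EffectiveConnectivity,
                      HemodynamicParams, IntegrationError, NodeTimeSeries,
                      simulate_bold)

# hemodynamic constants exposed as (log-multiplier) parameters
H_NAMES = ("epsilon", "tau", "tau_s", "tau_f")
DEFAULT_FREE_H = ("epsilon", "tau", "tau_s", "tau_f")


@dataclass
class ParameterVector:
    """Named flat parameter vector; flatten/unflatten is a bijection."""

    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != self.values.size:
            raise ValueError("names and values length mismatch")

    def __len__(self) -> int:
        return self.values.size

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(name) from None

    def get(self, name: str) -> float:
        return float(self.values[self.index(name)])

    def to_dict(self) -> dict:
        return dict(zip(self.names, self.values.tolist()))

    def copy(self) -> "ParameterVector":
        return ParameterVector(self.names, self.values.copy())


@dataclass
class PriorDensity:
    mean: ParameterVector
    cov: np.ndarray

    def __post_init__(self):
        self.cov = np.asarray(self.cov, dtype=float)
        n = len(self.mean)
        if self.cov.shape != (n, n):
            raise ValueError("prior covariance shape mismatch")

    @property
    def free(self) -> np.ndarray:
        return np.diag(self.cov) > 0


@dataclass
class PosteriorDensity:
    mean: ParameterVector
    cov: np.ndarray                 # full N x N (zero rows/cols for fixed)
    free_energy: float
    n_iter: int
    converged: bool
    free: np.ndarray = None         # boolean free-parameter mask
    noise_precision: np.ndarray = None
    f_trace: np.ndarray = None
    log_lik: float = np.nan
    n_obs: int = 0

    def sd(self, name: str) -> float:
        i = self.mean.index(name)
        return float(np.sqrt(self.cov[i, i]))


def parameter_names(model: CandidateModel) -> tuple[str, ...]:
    """Deterministic name index: all off-diagonal A entries, the model's
    modulatory entries, its direct-input entries, then hemodynamic
    log-multipliers per node."""
    lab = model.node_labels
    names = [f"A:{lab[i]}->{lab[j]}" for i in range(model.n_nodes)
             for j in range(model.n_nodes) if i != j]
    names += [f"B:u{inp + 1}:{lab[i]}->{lab[j]}"
              for inp, i, j in model.modulation]
    imap = model.input_array()
    names += [f"C:u{j + 1}->{lab[i]}" for i in range(model.n_nodes)
              for j in range(model.n_inputs) if imap[i, j]]
    names += [f"h:{h}:{lab[i]}" for h in H_NAMES
              for i in range(model.n_nodes)]
    return tuple(names)


def default_priors(model: CandidateModel, *,
                   a_var: float = 0.25, b_var: float = 0.25,
                   c_var: float = 1.0, h_var: float = 0.145,
                   free_h: tuple[str, ...] = DEFAULT_FREE_H) -> PriorDensity:
    """Shrinkage Gaussian priors: free A/B/C entries have mean 0; absent
    edges are fixed at 0 (prior variance 0); hemodynamic log-multipliers are
    zero-mean (log-normal about the prior-mean constants), free only for the
    components in ``free_h``."""
    names = parameter_names(model)
    mean = np.zeros(len(names))
    var = np.zeros(len(names))
    topo = model.topology_array()
    lab = model.node_labels
    present = {f"A:{lab[i]}->{lab[j]}" for i, j in model.edges()}
    for k, name in enumerate(names):
        kind = name.split(":")[0]
        if kind == "A":
            var[k] = a_var if name in present else 0.0
        elif kind == "B":
            var[k] = b_var
        elif kind == "C":
            var[k] = c_var
        elif kind == "h":
            var[k] = h_var if name.split(":")[1] in free_h else 0.0
    return PriorDensity(ParameterVector(tuple(names), mean), np.diag(var))


def true_parameter_vector(model: CandidateModel,
                          conn: EffectiveConnectivity, h_per_node, *,
                          input_scale=DEFAULT_INPUT_SCALE,
                          h_base: HemodynamicParams | None = None
                          ) -> ParameterVector:
    """Express a generator's ground-truth (conn, hemodynamics) in the named
    parameterization used for inversion (inverse of ``_build_system``)."""
    h_base = h_base or HemodynamicParams.prior_means()
    names = parameter_names(model)
    idx = {l: i for i, l in enumerate(model.node_labels)}
    values = np.zeros(len(names))
    for k, name in enumerate(names):
        parts = name.split(":")
        if parts[0] == "A":
            i, j = (idx[x] for x in parts[1].split("->"))
            values[k] = conn.A[j, i]
        elif parts[0] == "B":
            inp = int(parts[1][1:]) - 1
            i, j = (idx[x] for x in parts[2].split("->"))
            values[k] = conn.B[inp, j, i] / conn.alpha_decay
        elif parts[0] == "C":
            inp, tgt = parts[1].split("->")
            values[k] = conn.C[idx[tgt], int(inp[1:]) - 1] / input_scale
        elif parts[0] == "h":
            node = idx[parts[2]]
            values[k] = float(np.log(getattr(h_per_node[node], parts[1])
                                     / getattr(h_base, parts[1])))
    return ParameterVector(names, values)


def _build_system(theta: ParameterVector, model: CandidateModel, *,
                  alpha_decay=DEFAULT_ALPHA_DECAY,
                  input_scale=DEFAULT_INPUT_SCALE,
                  h_base: HemodynamicParams | None = None):
    """Materialize (EffectiveConnectivity, h_per_node) from a named vector."""
    lab = model.node_labels
    n, m = model.n_nodes, model.n_inputs
    A = -np.eye(n)
    B = np.zeros((m, n, n))
    C = np.zeros((n, m))
    h_base = h_base or HemodynamicParams.prior_means()
    h_mult = {h: np.zeros(n) for h in H_NAMES}
    idx = {l: i for i, l in enumerate(lab)}
    for name, val in zip(theta.names, theta.values):
        parts = name.split(":")
        if parts[0] == "A":
            i, j = (idx[x] for x in parts[1].split("->"))
            A[j, i] = val
        elif parts[0] == "B":
            inp = int(parts[1][1:]) - 1
            i, j = (idx[x] for x in parts[2].split("->"))
            B[inp, j, i] = alpha_decay * val
        elif parts[0] == "C":
            inp, tgt = parts[1].split("->")
            C[idx[tgt], int(inp[1:]) - 1] = input_scale * val
        elif parts[0] == "h":
            h_mult[parts[1]][idx[parts[2]]] = val
    conn = EffectiveConnectivity(A, B, C, alpha_decay, node_labels=lab)
    h_per_node = [
        replace(h_base,
                epsilon=h_base.epsilon * np.exp(h_mult["epsilon"][i]),
                tau=h_base.tau * np.exp(h_mult["tau"][i]),
                tau_s=h_base.tau_s * np.exp(h_mult["tau_s"][i]),
                tau_f=h_base.tau_f * np.exp(h_mult["tau_f"][i]))
        for i in range(n)]
    return conn, h_per_node


def predict_response(theta: ParameterVector, model: CandidateModel,
                     stimulus: np.ndarray, tr: float, n_samples: int, *,
                     dt: float = 0.12, alpha_decay=DEFAULT_ALPHA_DECAY,
                     input_scale=DEFAULT_INPUT_SCALE,
                     h_base: HemodynamicParams | None = None) -> np.ndarray:
    """Noise-free forward simulation at ``theta`` sampled at TR.

    ``stimulus`` must be at resolution ``dt`` with enough steps to cover
    ``n_samples`` TRs.
    """
    conn, h_per_node = _build_system(theta, model, alpha_decay=alpha_decay,
                                     input_scale=input_scale, h_base=h_base)
    try:
        ts = simulate_bold(conn, h_per_node, stimulus, n_samples * tr,
                           dt=dt, tr=tr, noise_sd_frac=0.0)
    except IntegrationError as err:
        raise IntegrationError(err.step,
                               f"forward failure at theta={theta.to_dict()}"
                               ) from err
    return ts.bold


@dataclass
class InversionSettings:
    dt: float = 0.12             # integrator step for model predictions
    max_iter: int = 128
    tol: float = 1e-4            # relative dF convergence threshold
    patience: int = 2
    fd_step: float = 1e-5        # forward-difference step for the Jacobian
    max_halvings: int = 6
    jacobian_refresh: int = 1    # >1 reuses the FD Jacobian between iterations
    alpha_decay: float = DEFAULT_ALPHA_DECAY
    input_scale: float = DEFAULT_INPUT_SCALE
    # Equalize per-node data scale before fitting (divide each channel by
    # its sd), emulating the arbitrary per-region scale of VOI eigenvariate
    # signals; per-node gain is absorbed by the free epsilon multipliers.
    standardize: bool = True


def _jacobian(response_fn, mu, g, step):
    cols = []
    for k in range(mu.size):
        pert = mu.copy()
        pert[k] += step
        cols.append((response_fn(pert) - g) / step)
    return np.stack(cols, axis=-1)   # (T, n, N)


def _free_energy(sse, lam, trace_lam, dmu, P0, logdet_S0_free, Sigma, T):
    n_free = dmu.size
    sgn, logdet_S = np.linalg.slogdet(Sigma)
    acc = float(np.sum(-0.5 * lam * sse + 0.5 * T * np.log(lam)
                       - 0.5 * T * np.log(2.0 * np.pi)))
    acc -= 0.5 * trace_lam
    kl = 0.5 * (float(np.trace(P0 @ Sigma)) + float(dmu @ P0 @ dmu)
                - n_free + logdet_S0_free - logdet_S)
    return acc - kl


def variational_laplace(response_fn, y: np.ndarray, prior_mean: np.ndarray,
                        prior_cov: np.ndarray, *,
                        max_iter: int = 128, tol: float = 1e-4,
                        patience: int = 2, fd_step: float = 1e-5,
                        max_halvings: int = 6,
                        jacobian_refresh: int = 1,
                        noise_precision: np.ndarray | float | None = None):
    """Core variational-Laplace loop over an arbitrary response function.

    ``response_fn(theta) -> (T, n)`` prediction; ``y`` is the (T, n) data.
    If ``noise_precision`` is given it is held fixed; otherwise per-node
    precisions are updated by EM.  ``jacobian_refresh`` > 1 reuses the
    finite-difference Jacobian for that many Gauss-Newton iterations (a
    stale Jacobian only degrades the step proposal, which the trust-region
    acceptance still vets).  Returns a dict with posterior mean, covariance,
    free energy, trace, and diagnostics.
    """
    y = np.asarray(y, dtype=float)
    T, n_chan = y.shape
    mu0 = np.asarray(prior_mean, dtype=float)
    S0 = np.asarray(prior_cov, dtype=float)
    P0 = np.linalg.inv(S0)
    logdet_S0 = float(np.linalg.slogdet(S0)[1])

    fix_lambda = noise_precision is not None
    mu = mu0.copy()
    g = response_fn(mu)
    resid = y - g
    sse = np.sum(resid ** 2, axis=0)
    if fix_lambda:
        lam = np.broadcast_to(np.asarray(noise_precision, dtype=float),
                              (n_chan,)).copy()
    else:
        lam = T / np.maximum(sse, 1e-10)
    lam = np.clip(lam, 1e-8, 1e12)

    f_trace = []
    converged = False
    Sigma = S0.copy()
    n_iter = 0
    J = None
    stale = False
    for n_iter in range(1, max_iter + 1):
        if J is None or (n_iter - 1) % max(jacobian_refresh, 1) == 0:
            J = _jacobian(response_fn, mu, g, fd_step)   # (T, n, N)
            stale = False
        else:
            stale = True
        H = P0.copy()
        b = -P0 @ (mu - mu0)
        for i in range(n_chan):
            Ji = J[:, i, :]
            H += lam[i] * (Ji.T @ Ji)
            b += lam[i] * (Ji.T @ resid[:, i])
        H = 0.5 * (H + H.T)
        try:
            cho = linalg.cho_factor(H)
            Sigma = linalg.cho_solve(cho, np.eye(H.shape[0]))
        except linalg.LinAlgError:
            H += 1e-6 * np.trace(H) / H.shape[0] * np.eye(H.shape[0])
            Sigma = np.linalg.inv(H)
        Sigma = 0.5 * (Sigma + Sigma.T)
        step = Sigma @ b

        trace_lam = float(sum(
            lam[i] * np.einsum("tk,kl,tl->", J[:, i, :], Sigma, J[:, i, :])
            for i in range(n_chan)))
        f_cur = _free_energy(sse, lam, trace_lam, mu - mu0, P0,
                             logdet_S0, Sigma, T)

        accepted = False
        scale = 1.0
        for _ in range(max_halvings + 1):
            mu_try = mu + scale * step
            try:
                g_try = response_fn(mu_try)
            except (IntegrationError, FloatingPointError):
                scale *= 0.5
                continue
            resid_try = y - g_try
            sse_try = np.sum(resid_try ** 2, axis=0)
            f_try = _free_energy(sse_try, lam, trace_lam, mu_try - mu0, P0,
                                 logdet_S0, Sigma, T)
            if f_try >= f_cur or not f_trace:
                accepted = True
                break
            scale *= 0.5
        if not accepted:
            if stale:          # retry from a fresh linearization first
                J = None
                continue
            converged = True
            break

        state_prev = (mu, g, resid, sse, lam)
        mu, g, resid, sse = mu_try, g_try, resid_try, sse_try
        if not fix_lambda:
            per_chan_trace = np.array([
                np.einsum("tk,kl,tl->", J[:, i, :], Sigma, J[:, i, :])
                for i in range(n_chan)])
            lam = np.clip(T / np.maximum(sse + per_chan_trace, 1e-12),
                          1e-8, 1e12)
            trace_lam = float(np.sum(lam * per_chan_trace))
        f_new = _free_energy(sse, lam, trace_lam, mu - mu0, P0,
                             logdet_S0, Sigma, T)
        if f_trace and f_new < f_trace[-1]:
            # hyperparameter refresh decreased F: revert and stop at the
            # best recorded state
            mu, g, resid, sse, lam = state_prev
            converged = True
            break
        f_trace.append(f_new)

        if len(f_trace) > patience:
            recent = np.abs(np.diff(f_trace[-(patience + 1):]))
            if np.all(recent < tol * max(1.0, abs(f_trace[-1]))):
                converged = True
                break

    if not f_trace:   # no step could be evaluated at all
        f_trace.append(_free_energy(sse, lam, 0.0, mu - mu0, P0,
                                    logdet_S0, Sigma, T))
    log_lik = float(np.sum(-0.5 * lam * sse + 0.5 * T * np.log(lam)
                           - 0.5 * T * np.log(2.0 * np.pi)))
    return {
        "mean": mu, "cov": Sigma, "free_energy": f_trace[-1],
        "f_trace": np.asarray(f_trace), "n_iter": n_iter,
        "converged": converged, "noise_precision": lam, "log_lik": log_lik,
    }


def invert_dcm(data: NodeTimeSeries, model: CandidateModel,
               priors: PriorDensity | None = None,
               settings: InversionSettings | None = None) -> PosteriorDensity:
    """Variational-Laplace inversion of ``model`` against ``data``.

    ``data`` must carry its fine-resolution inputs; missing nodes are
    expected to have been filled already.  Non-convergence is flagged on the
    returned posterior rather than raised.
    """
    priors = priors or default_priors(model)
    settings = settings or InversionSettings()
    if data.inputs is None or data.dt is None:
        raise ValueError("data must carry inputs and their dt")
    factor = settings.dt / data.dt
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError("settings.dt must be a multiple of data dt")
    factor = int(round(factor))
    # block-average rather than point-sample so high-frequency input jitter
    # is attenuated instead of aliased into the model predictions
    n_blocks = data.inputs.shape[0] // factor
    stimulus = data.inputs[:n_blocks * factor].reshape(
        n_blocks, factor, -1).mean(axis=1)

    free = priors.free
    names = priors.mean.names
    full0 = priors.mean.values.copy()

    y = data.bold
    gain = np.ones(y.shape[1])
    if settings.standardize:
        sd = y.std(axis=0)
        ok = sd > 1e-10
        gain[ok] = 1.0 / sd[ok]     # degenerate (e.g. zero-filled) columns
        y = y * gain                # are left at their native scale

    def response_fn(theta_free):
        full = full0.copy()
        full[free] = theta_free
        pv = ParameterVector(names, full)
        pred = predict_response(pv, model, stimulus, data.tr,
                                data.n_samples, dt=settings.dt,
                                alpha_decay=settings.alpha_decay,
                                input_scale=settings.input_scale)
        return pred

    res = variational_laplace(
        response_fn, y, full0[free],
        priors.cov[np.ix_(free, free)],
        max_iter=settings.max_iter, tol=settings.tol,
        patience=settings.patience, fd_step=settings.fd_step,
        max_halvings=settings.max_halvings,
        jacobian_refresh=settings.jacobian_refresh)

    full = full0.copy()
    full[free] = res["mean"]
    cov_full = np.zeros((len(names), len(names)))
    cov_full[np.ix_(free, free)] = res["cov"]
    return PosteriorDensity(
        mean=ParameterVector(names, full), cov=cov_full,
        free_energy=res["free_energy"], n_iter=res["n_iter"],
        converged=res["converged"], free=free,
        noise_precision=res["noise_precision"], f_trace=res["f_trace"],
        log_lik=res["log_lik"], n_obs=data.bold.size)


def log_evidence(post: PosteriorDensity, kind: str = "free_energy") -> float:
    """Log-evidence approximation: variational free energy (default), or
    BIC/AIC penalized likelihoods for sensitivity analysis."""
    if kind == "free_energy":
        return float(post.free_energy)
    k = int(np.sum(post.free)) if post.free is not None else len(post.mean)
    if kind == "bic":
        return float(post.log_lik - 0.5 * k * np.log(post.n_obs))
    if kind == "aic":
        return float(post.log_lik - k)
    raise ValueError(f"unknown evidence kind {kind!r}")
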