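"""Generative forward model: bilinear neural dynamics, balloon hemodynamics,
BOLD observation, and RK4 integration.

Neural dynamics follow the bilinear state equation

    dz/dt = (alpha * A + sum_j u_j B_j) z + C u

with every diagonal entry of ``A`` fixed at -1, so ``alpha`` is the
within-node self-decay rate.  The default ``alpha = 20 / s`` realizes a mean
neural lag of ~50 ms.

Each node's activity drives a balloon model

    ds/dt = eps * z - s / tau_s - (f - 1) / tau_f
    df/dt = s
    tau * dv/dt = f - v**(1/alpha_grubb)
    tau * dq/dt = f * E(f, E0) / E0 - v**(1/alpha_grubb) * q / v

with oxygen extraction ``E(f, E0) = 1 - (1 - E0)**(1/f)``, and the BOLD
percent-signal change observation

    y = 100 * V0 * (k1 (1 - q) + k2 (1 - q/v) + k3 (1 - v)),
    k1 = 7 E0,  k2 = 2,  k3 = 2 E0 - 0.2.

Hemodynamic defaults are the conventional DCM prior means
(tau = 0.98 s, alpha_grubb = 0.32, E0 = 0.34, V0 = 0.04,
tau_s = 1/0.65 s, tau_f = 1/0.41 s, epsilon = 1).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from . import _kernels

DEFAULT_ALPHA_DECAY = 20.0  # 1/s; mean neural lag ~50 ms
DEFAULT_BASELINE = 100.0    # implicit mean intensity in percent-signal units


class IntegrationError(RuntimeError):
    """Raised when the state trajectory becomes non-finite or leaves the
    physical domain (f, v > 0); carries the offending step index."""

    def __init__(self, step: int, message: str | None = None):
        self.step = step
        super().__init__(message or f"integration diverged at step {step}")


@dataclass
class EffectiveConnectivity:
    """Bilinear parameter set (A, B_j, C, alpha) of one candidate network."""

    A: np.ndarray                      # (n, n), row = target, col = source
    B: np.ndarray                      # (m, n, n) modulatory matrices
    C: np.ndarray                      # (n, m) direct input weights
    alpha_decay: float = DEFAULT_ALPHA_DECAY
    node_labels: tuple[str, ...] = ()

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        n = self.A.shape[0]
        if self.A.shape != (n, n):
            raise ValueError(f"A must be square, got {self.A.shape}")
        if self.B.ndim != 3 or self.B.shape[1:] != (n, n):
            raise ValueError(f"B must have shape (m, {n}, {n}), got {self.B.shape}")
        if self.C.shape != (n, self.B.shape[0]):
            raise ValueError(
                f"C must have shape ({n}, {self.B.shape[0]}), got {self.C.shape}")
        if not np.allclose(np.diag(self.A), -1.0):
            raise ValueError("every diagonal entry of A must equal -1")
        if self.alpha_decay <= 0:
            raise ValueError("alpha_decay must be positive")
        if not self.node_labels:
            self.node_labels = tuple(f"n{i}" for i in range(n))

    @property
    def n_nodes(self) -> int:
        return self.A.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.B.shape[0]


@dataclass
class HemodynamicParams:
    """Balloon model constants h = {tau, alpha_grubb, E0, V0, tau_s, tau_f, epsilon}."""

    tau: float = 0.98
    alpha_grubb: float = 0.32
    E0: float = 0.34
    V0: float = 0.04
    tau_s: float = 1.0 / 0.65
    tau_f: float = 1.0 / 0.41
    epsilon: float = 1.0

    def __post_init__(self):
        for name in ("tau", "alpha_grubb", "E0", "V0", "tau_s", "tau_f", "epsilon"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not (0 < self.E0 < 1 and 0 < self.V0 < 1):
            raise ValueError("E0 and V0 must lie in (0, 1)")
        if not (0 < self.alpha_grubb < 1):
            raise ValueError("alpha_grubb must lie in (0, 1)")

    def as_array(self) -> np.ndarray:
        return np.array([self.tau, self.alpha_grubb, self.E0, self.V0,
                         self.tau_s, self.tau_f, self.epsilon])

    @classmethod
    def prior_means(cls) -> "HemodynamicParams":
        return cls()

    def jittered(self, rng: np.random.Generator,
                 sigma: float) -> "HemodynamicParams":
        """Multiplicative log-normal jitter on (tau, tau_s, tau_f).

        ``sigma`` is the log-scale sd; see ``cohort.DEFAULT_HRF_JITTER_SIGMA``
        for the value calibrated to an HRF peak-delay sd of 0.5 s.
        """
        g = np.exp(rng.normal(0.0, sigma, size=3))
        return replace(self, tau=self.tau * g[0], tau_s=self.tau_s * g[1],
                       tau_f=self.tau_f * g[2])


@dataclass
class HemodynamicState:
    """Per-node balloon state; the resting fixed point is (0, 1, 1, 1)."""

    s: float = 0.0
    f: float = 1.0
    v: float = 1.0
    q: float = 1.0


@dataclass
class NodeTimeSeries:
    """Sampled BOLD series (percent signal change about an implicit
    baseline of 100) plus the fine-resolution inputs that produced it."""

    bold: np.ndarray                  # (n_samples, n_nodes)
    tr: float
    inputs: np.ndarray | None = None  # (n_steps, m) at integrator resolution
    dt: float | None = None           # integrator step of `inputs`
    neural: np.ndarray | None = None  # (n_steps + 1, n_nodes), optional
    node_labels: tuple[str, ...] = ()

    def __post_init__(self):
        self.bold = np.asarray(self.bold, dtype=float)
        if self.bold.ndim != 2:
            raise ValueError("bold must be 2-D (samples x nodes)")

    @property
    def n_samples(self) -> int:
        return self.bold.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.bold.shape[1]

    def copy(self) -> "NodeTimeSeries":
        return NodeTimeSeries(self.bold.copy(), self.tr,
                              None if self.inputs is None else self.inputs,
                              self.dt,
                              None if self.neural is None else self.neural,
                              self.node_labels)


def neural_derivative(z: np.ndarray, u: np.ndarray,
                      conn: EffectiveConnectivity) -> np.ndarray:
    """dz/dt = (alpha A + sum_j u_j B_j) z + C u."""
    z = np.asarray(z, dtype=float)
    u = np.asarray(u, dtype=float)
    if z.shape != (conn.n_nodes,):
        raise ValueError(f"z has shape {z.shape}, expected ({conn.n_nodes},)")
    if u.shape != (conn.n_inputs,):
        raise ValueError(f"u has shape {u.shape}, expected ({conn.n_inputs},)")
    M = conn.alpha_decay * conn.A + np.tensordot(u, conn.B, axes=1)
    return M @ z + conn.C @ u


def hemodynamic_derivative(x: HemodynamicState, z: float,
                           h: HemodynamicParams) -> HemodynamicState:
    """Balloon-model state derivative at (x, z)."""
    if x.f <= 0 or x.v <= 0:
        raise ValueError("f and v must be strictly positive")
    ds = h.epsilon * z - x.s / h.tau_s - (x.f - 1.0) / h.tau_f
    df = x.s
    vout = x.v ** (1.0 / h.alpha_grubb)
    dv = (x.f - vout) / h.tau
    extraction = 1.0 - (1.0 - h.E0) ** (1.0 / x.f)
    dq = (x.f * extraction / h.E0 - vout * x.q / x.v) / h.tau
    return HemodynamicState(ds, df, dv, dq)


def bold_signal(v, q, h: HemodynamicParams):
    """Nonlinear BOLD observation in percent signal change; 0 at rest."""
    v = np.asarray(v, dtype=float)
    q = np.asarray(q, dtype=float)
    if np.any(v <= 0) or np.any(q <= 0):
        raise ValueError("v and q must be strictly positive")
    k1 = 7.0 * h.E0
    k2 = 2.0
    k3 = 2.0 * h.E0 - 0.2
    out = 100.0 * h.V0 * (k1 * (1.0 - q) + k2 * (1.0 - q / v) + k3 * (1.0 - v))
    return out if out.ndim else float(out)


def _hemo_matrix(h_per_node: Sequence[HemodynamicParams]) -> np.ndarray:
    return np.stack([h.as_array() for h in h_per_node])


def simulate_bold(conn: EffectiveConnectivity,
                  h_per_node: Sequence[HemodynamicParams],
                  stimulus: np.ndarray,
                  duration: float,
                  dt: float = 0.005,
                  tr: float = 3.0,
                  noise_sd_frac: float = 0.0,
                  seed: int | None = None,
                  *,
                  baseline: float = DEFAULT_BASELINE,
                  mean_level_convention: str = "baseline",
                  store_neural: bool = False,
                  method: str = "rk4") -> NodeTimeSeries:
    """RK4-integrate the coupled system and sample BOLD at multiples of TR.

    ``stimulus`` is an (n_steps, m) array at resolution ``dt`` (held
    piecewise-constant over each step).  Observation noise is i.i.d. Gaussian
    per node with sd = ``noise_sd_frac`` x mean signal level, where the mean
    level is ``mean(noise-free bold) + baseline`` under the default
    ``"baseline"`` convention (percent-signal-change about an implicit 100)
    or ``mean(noise-free bold)`` under ``"raw"``.
    """
    if duration < tr:
        raise ValueError("duration must be at least one TR")
    steps_per_tr = tr / dt
    if abs(steps_per_tr - round(steps_per_tr)) > 1e-9:
        raise ValueError(f"dt={dt} does not divide tr={tr}")
    steps_per_tr = round(steps_per_tr)
    n_samples = int(np.floor(duration / tr))
    n_steps = (n_samples - 1) * steps_per_tr + steps_per_tr  # cover last TR
    n_steps = max(n_steps, int(round(duration / dt)))

    stimulus = np.atleast_2d(np.asarray(stimulus, dtype=float))
    if stimulus.shape[0] < n_steps:
        raise ValueError(
            f"stimulus provides {stimulus.shape[0]} steps, need {n_steps}")
    if stimulus.shape[1] != conn.n_inputs:
        raise ValueError("stimulus channel count does not match C")
    if len(h_per_node) != conn.n_nodes:
        raise ValueError("need one HemodynamicParams per node")

    hemo = _hemo_matrix(h_per_node)
    kernel = (_kernels.rk4_integrate if method == "rk4"
              else _kernels.euler_integrate)
    z_traj, y_traj, bad = kernel(
        np.ascontiguousarray(conn.A), np.ascontiguousarray(conn.B),
        np.ascontiguousarray(conn.C), float(conn.alpha_decay),
        np.ascontiguousarray(stimulus[:n_steps]), float(dt), hemo, n_steps)
    if bad >= 0:
        raise IntegrationError(bad)

    idx = np.arange(n_samples) * steps_per_tr
    bold = y_traj[idx].copy()

    if noise_sd_frac > 0:
        rng = np.random.default_rng(seed)
        mean_level = float(np.mean(bold))
        if mean_level_convention == "baseline":
            mean_level += baseline
        elif mean_level_convention != "raw":
            raise ValueError(f"unknown convention {mean_level_convention!r}")
        bold = bold + rng.normal(0.0, noise_sd_frac * abs(mean_level),
                                 size=bold.shape)

    return NodeTimeSeries(
        bold=bold, tr=tr, inputs=stimulus[:n_steps], dt=dt,
        neural=z_traj if store_neural else None,
        node_labels=conn.node_labels)
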