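"""Synthetic Go/No-Go cohort generation.

Builds Poisson-switched two-state stimuli, a family of 16 candidate
four-node networks (V visual, A auditory, M motor, P prefrontal), randomized
connection strengths, per-node HRF jitter, and whole-cohort simulation with
missing-node masking.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .forward import (DEFAULT_ALPHA_DECAY, EffectiveConnectivity,
                      HemodynamicParams, IntegrationError, NodeTimeSeries,
                      simulate_bold)

NODE_LABELS = ("V", "A", "M", "P")

# Input scale calibrated so the cohort-mean peak BOLD amplitude is ~4% of
# mean intensity under default stimuli and truncated-normal couplings.
DEFAULT_INPUT_SCALE = 4.6

# Log-scale sd of the multiplicative jitter applied to (tau, tau_s, tau_f),
# calibrated (scripts/calibrate_hrf_jitter.py) so the realized HRF peak-delay
# sd is ~0.5 s.
DEFAULT_HRF_JITTER_SIGMA = 0.38

# Thermal observation noise as a fraction of mean signal level (0.1-1% range;
# the low end is the default).
DEFAULT_NOISE_SD_FRAC = 0.001


@dataclass
class StimulusDesign:
    """Two-state Poisson-switching box-car input."""

    mean_up: float
    mean_down: float
    noise_frac: float = 1.0 / 20.0   # sd as fraction of state-height difference
    dt: float = 0.005
    duration: float = 600.0
    low: float = 0.0
    high: float = 1.0

    def __post_init__(self):
        if self.mean_up <= 0 or self.mean_down <= 0:
            raise ValueError("dwell-time means must be positive")
        if self.noise_frac < 0:
            raise ValueError("noise_frac must be nonnegative")


AUDITORY_DESIGN = StimulusDesign(mean_up=2.5, mean_down=10.0)
VISUAL_DESIGN = StimulusDesign(mean_up=5.0, mean_down=5.0)


def generate_stimulus(design: StimulusDesign, seed=None) -> np.ndarray:
    """Sample one two-state input at resolution ``design.dt``.

    Dwell times are exponential with the design means; Gaussian jitter with
    sd = ``noise_frac`` x state-height difference is added pointwise.
    """
    rng = np.random.default_rng(seed)
    n_steps = int(round(design.duration / design.dt))
    signal = np.empty(n_steps)
    height = design.high - design.low
    t = 0
    up = False  # start in the (longer, on average) down state
    while t < n_steps:
        mean = design.mean_up if up else design.mean_down
        dwell = max(1, int(round(rng.exponential(mean) / design.dt)))
        stop = min(n_steps, t + dwell)
        signal[t:stop] = design.high if up else design.low
        t = stop
        up = not up
    if design.noise_frac > 0:
        signal = signal + rng.normal(0.0, design.noise_frac * height, n_steps)
    return signal


def dwell_times(signal: np.ndarray, dt: float, threshold: float = 0.5):
    """Segment a (possibly jittered) two-state signal into up/down dwell
    intervals; returns (up_durations, down_durations) in seconds.  Interior
    intervals only — the truncated first/last runs are dropped."""
    state = (np.asarray(signal) > threshold).astype(int)
    change = np.flatnonzero(np.diff(state)) + 1
    if len(change) < 2:
        return np.array([]), np.array([])
    runs = np.diff(change) * dt
    states = state[change[:-1]]
    return runs[states == 1], runs[states == 0]


@dataclass(frozen=True)
class CandidateModel:
    """One candidate topology.  ``topology[i, j] = 1`` means an edge from
    node i to node j.  ``modulation`` lists (input_index, source, target)
    edges whose coupling the input modulates."""

    model_id: int
    topology: tuple                    # nested tuple, n x n of 0/1
    input_map: tuple                   # n x m of 0/1 (u1 -> V, u2 -> A)
    modulation: tuple = ()
    node_labels: tuple = NODE_LABELS

    @property
    def n_nodes(self) -> int:
        return len(self.topology)

    @property
    def n_inputs(self) -> int:
        return len(self.input_map[0])

    def topology_array(self) -> np.ndarray:
        return np.array(self.topology, dtype=int)

    def input_array(self) -> np.ndarray:
        return np.array(self.input_map, dtype=int)

    def edges(self):
        T = self.topology_array()
        return [(i, j) for i in range(self.n_nodes)
                for j in range(self.n_nodes) if T[i, j]]


V, A, M, P = range(4)

# Toggle pool and mandatory base of the default 16-model family.  The base
# V->M edge keeps the motor read-out reachable in every member; the pool
# toggles the prefrontal routes and the direct auditory->motor shortcut.
EDGE_POOL = ((V, P), (A, P), (P, M), (A, M))
BASE_EDGES = ((V, M),)
DEFAULT_TRUE_MODEL_ID = 8  # base + {V->P, A->P, P->M}


def _modulation_for(edges) -> tuple:
    """u2 (auditory/stop input) modulates the most specific motor-inhibition
    route present: P->M, else A->M, else the base V->M edge."""
    for cand in ((P, M), (A, M), (V, M)):
        if cand in edges:
            return ((1, cand[0], cand[1]),)
    raise AssertionError("family invariant: a motor pathway always exists")


def model_family(edge_pool=EDGE_POOL, base_edges=BASE_EDGES) -> list[CandidateModel]:
    """Deterministic family of 16 distinct 4-node topologies.

    Members are indexed 1..16 by the subset of ``edge_pool`` included (bitmask
    order); all share u1 -> V and u2 -> A direct inputs.
    """
    input_map = tuple(tuple(row) for row in
                      ((1, 0), (0, 1), (0, 0), (0, 0)))
    family = []
    for bits in range(2 ** len(edge_pool)):
        edges = set(base_edges)
        for k, e in enumerate(edge_pool):
            if bits >> k & 1:
                edges.add(e)
        T = np.zeros((4, 4), dtype=int)
        for i, j in edges:
            T[i, j] = 1
        family.append(CandidateModel(
            model_id=bits + 1,
            topology=tuple(tuple(int(x) for x in row) for row in T),
            input_map=input_map,
            modulation=_modulation_for(edges)))
    seen = {m.topology for m in family}
    if len(seen) != len(family):
        raise ValueError("duplicate topologies in model family")
    return family


def subset_family(family, size: int, true_model_id: int) -> list[CandidateModel]:
    """Deterministic subset that always contains the true model: the true
    model plus the first ``size - 1`` other members in id order."""
    ids = [m.model_id for m in family]
    if true_model_id not in ids:
        raise ValueError(f"true model {true_model_id} not in family")
    if not (1 <= size <= len(family)):
        raise ValueError("invalid subset size")
    chosen = [m for m in family if m.model_id == true_model_id]
    for m in family:
        if len(chosen) == size:
            break
        if m.model_id != true_model_id:
            chosen.append(m)
    return sorted(chosen, key=lambda m: m.model_id)


def truncated_normal(rng, mean=0.4, sd=0.1, lo=0.2, hi=0.6, size=None):
    """Rejection-sampled truncated Gaussian (the truncation bounds are 2 sd
    from the mean, so acceptance is ~95%)."""
    shape = () if size is None else (int(size),)
    out = np.empty(shape if shape else (1,))
    n = out.size
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=n - filled)
        ok = draw[(draw >= lo) & (draw <= hi)]
        out.flat[filled:filled + ok.size] = ok
        filled += ok.size
    return float(out[0]) if size is None else out


def sample_connectivity(model: CandidateModel, seed=None, *,
                        mean=0.4, sd=0.1, lo=0.2, hi=0.6,
                        alpha_decay=DEFAULT_ALPHA_DECAY,
                        input_scale=DEFAULT_INPUT_SCALE) -> EffectiveConnectivity:
    """Draw edge strengths ~ TruncNormal(mean, sd, [lo, hi]) onto the model
    topology.  Modulatory strengths are drawn from the same law, applied with
    a negative sign (the auditory input inhibits the motor route) and scaled
    by ``alpha_decay`` so modulation is commensurate with the intrinsic
    coupling term ``alpha * A``."""
    rng = np.random.default_rng(seed)
    n = model.n_nodes
    m = model.n_inputs
    A_mat = -np.eye(n)
    for i, j in model.edges():
        A_mat[j, i] = truncated_normal(rng, mean, sd, lo, hi)
    B = np.zeros((m, n, n))
    for inp, i, j in model.modulation:
        B[inp, j, i] = -alpha_decay * truncated_normal(rng, mean, sd, lo, hi)
    C = model.input_array().astype(float) * input_scale
    return EffectiveConnectivity(A_mat, B, C, alpha_decay,
                                 node_labels=model.node_labels)


@dataclass
class Cohort:
    """A set of simulated subjects sharing TR and sample count, with a
    per-subject missing-node mask and true-model label.  The masked node's
    series is retained (``subjects`` holds full data) for ground-truth
    comparison; consumers must honour ``missing_mask``."""

    subjects: list
    true_model_id: np.ndarray          # (n_subjects,)
    missing_mask: np.ndarray           # (n_subjects, n_nodes) bool
    seeds: np.ndarray                  # per-subject seed integers
    tr: float = 3.0
    true_connectivity: list | None = None   # ground-truth EffectiveConnectivity
    true_hemo: list | None = None           # ground-truth per-node HemodynamicParams

    def __post_init__(self):
        self.true_model_id = np.asarray(self.true_model_id, dtype=int)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        ns = {s.n_samples for s in self.subjects}
        if len(ns) > 1:
            raise ValueError("subjects must share n_samples")
        if self.missing_mask.shape != (len(self.subjects), self.n_nodes):
            raise ValueError("missing_mask shape mismatch")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_nodes(self) -> int:
        return self.subjects[0].n_nodes


def _simulate_subject(model: CandidateModel, seed_seq, *,
                      duration, dt, tr, noise_sd_frac, hrf_jitter_sigma,
                      input_scale, store_neural=False):
    rng = np.random.default_rng(seed_seq)
    u1 = generate_stimulus(replace(VISUAL_DESIGN, dt=dt, duration=duration),
                           rng.integers(2 ** 63))
    u2 = generate_stimulus(replace(AUDITORY_DESIGN, dt=dt, duration=duration),
                           rng.integers(2 ** 63))
    stimulus = np.column_stack([u1, u2])
    conn = sample_connectivity(model, rng.integers(2 ** 63),
                               input_scale=input_scale)
    base = HemodynamicParams.prior_means()
    h_rng = np.random.default_rng(rng.integers(2 ** 63))
    h_per_node = [base.jittered(h_rng, hrf_jitter_sigma)
                  for _ in range(model.n_nodes)]
    series = simulate_bold(conn, h_per_node, stimulus, duration, dt=dt,
                           tr=tr, noise_sd_frac=noise_sd_frac,
                           seed=rng.integers(2 ** 63),
                           store_neural=store_neural)
    return series, conn, h_per_node


def simulate_cohort(true_model: CandidateModel, n_subjects: int, seed=None, *,
                    duration=600.0, dt=0.005, tr=3.0,
                    noise_sd_frac=DEFAULT_NOISE_SD_FRAC,
                    hrf_jitter_sigma=DEFAULT_HRF_JITTER_SIGMA,
                    input_scale=DEFAULT_INPUT_SCALE) -> Cohort:
    """Simulate ``n_subjects`` independent subjects from one true model.

    Each subject gets its own stimuli, connectivity draw, HRF jitter, and
    observation noise, all derived from per-subject children of the master
    seed (so generation order does not matter).
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    children = ss.spawn(n_subjects)
    subjects, conns, hemos = [], [], []
    for k, child in enumerate(children):
        try:
            series, conn, h = _simulate_subject(
                true_model, child, duration=duration, dt=dt, tr=tr,
                noise_sd_frac=noise_sd_frac,
                hrf_jitter_sigma=hrf_jitter_sigma, input_scale=input_scale)
        except IntegrationError as err:
            raise IntegrationError(
                err.step, f"subject {k}: {err}") from err
        subjects.append(series)
        conns.append(conn)
        hemos.append(h)
    n = true_model.n_nodes
    return Cohort(subjects=subjects,
                  true_model_id=np.full(n_subjects, true_model.model_id),
                  missing_mask=np.zeros((n_subjects, n), dtype=bool),
                  seeds=np.arange(n_subjects), tr=tr,
                  true_connectivity=conns, true_hemo=hemos)


def simulate_mixed_cohort(models, n_subjects: int, seed=None,
                          **kwargs) -> Cohort:
    """Simulate a cohort whose true models cycle round-robin through
    ``models`` (subject k is generated from ``models[k % len(models)]``)."""
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    children = ss.spawn(n_subjects)
    subjects, labels, conns, hemos = [], [], [], []
    for k, child in enumerate(children):
        model = models[k % len(models)]
        series, conn, h = _simulate_subject(
            model, child,
            duration=kwargs.get("duration", 600.0),
            dt=kwargs.get("dt", 0.005), tr=kwargs.get("tr", 3.0),
            noise_sd_frac=kwargs.get("noise_sd_frac", DEFAULT_NOISE_SD_FRAC),
            hrf_jitter_sigma=kwargs.get("hrf_jitter_sigma",
                                        DEFAULT_HRF_JITTER_SIGMA),
            input_scale=kwargs.get("input_scale", DEFAULT_INPUT_SCALE))
        subjects.append(series)
        labels.append(model.model_id)
        conns.append(conn)
        hemos.append(h)
    n = subjects[0].n_nodes
    return Cohort(subjects=subjects, true_model_id=np.array(labels),
                  missing_mask=np.zeros((n_subjects, n), dtype=bool),
                  seeds=np.arange(n_subjects),
                  tr=kwargs.get("tr", 3.0),
                  true_connectivity=conns, true_hemo=hemos)


def remove_nodes(cohort: Cohort, n_missing: int, seed=None) -> Cohort:
    """Return a copy of the cohort with ``n_missing`` distinct nodes per
    subject flagged missing (chosen uniformly at random)."""
    if not (0 <= n_missing < cohort.n_nodes):
        raise ValueError("n_missing must be in [0, n_nodes)")
    rng = np.random.default_rng(seed)
    mask = np.zeros((cohort.n_subjects, cohort.n_nodes), dtype=bool)
    for k in range(cohort.n_subjects):
        if n_missing:
            mask[k, rng.choice(cohort.n_nodes, size=n_missing,
                               replace=False)] = True
    return Cohort(subjects=cohort.subjects,
                  true_model_id=cohort.true_model_id.copy(),
                  missing_mask=mask, seeds=cohort.seeds, tr=cohort.tr,
                  true_connectivity=cohort.true_connectivity,
                  true_hemo=cohort.true_hemo)


def peak_amplitude(series: NodeTimeSeries, baseline=100.0) -> float:
    """Mean over nodes of the peak-to-baseline percent signal change relative
    to mean intensity (baseline + mean percent change)."""
    peaks = series.bold.max(axis=0)
    mean_intensity = baseline + series.bold.mean()
    return float(np.mean(peaks) / mean_intensity * 100.0)
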