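"""Evidence aggregation, posterior model probabilities, classification under
0-1 and general utilities, and bootstrap accuracy."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp


@dataclass
class EvidenceMatrix:
    """Subjects x models log evidence."""

    log_evidence: np.ndarray
    model_ids: np.ndarray
    subject_ids: np.ndarray
    fill_method: str = ""

    def __post_init__(self):
        self.log_evidence = np.asarray(self.log_evidence, dtype=float)
        self.model_ids = np.asarray(self.model_ids, dtype=int)
        self.subject_ids = np.asarray(self.subject_ids)
        s, m = self.log_evidence.shape
        if self.model_ids.shape != (m,) or self.subject_ids.shape != (s,):
            raise ValueError("id vectors do not match evidence shape")
        if not np.all(np.isfinite(self.log_evidence)):
            raise ValueError("evidence matrix must be finite for every pair")


@dataclass
class ClassificationResult:
    predicted: np.ndarray
    accuracy: float
    bootstrap_samples: np.ndarray
    n_boot: int
    seed: int | None = None

    @property
    def bootstrap_sd(self) -> float:
        return float(np.std(self.bootstrap_samples))


def posterior_model_probs(log_ev: np.ndarray,
                          model_prior: np.ndarray | None = None) -> np.ndarray:
    """Softmax of log evidence + log prior, stabilized by max subtraction."""
    log_ev = np.asarray(log_ev, dtype=float)
    if model_prior is None:
        model_prior = np.full(log_ev.shape[-1], 1.0 / log_ev.shape[-1])
    model_prior = np.asarray(model_prior, dtype=float)
    if np.any(model_prior < 0):
        raise ValueError("model prior must be nonnegative")
    if not np.isclose(model_prior.sum(), 1.0):
        raise ValueError("model prior must sum to 1")
    with np.errstate(divide="ignore"):
        score = log_ev + np.log(model_prior)
    if np.all(np.isneginf(score)):
        raise ValueError("all log evidences are -inf")
    return np.exp(score - logsumexp(score, axis=-1, keepdims=True))


def ffx_group(ev: EvidenceMatrix,
              model_prior: np.ndarray | None = None) -> np.ndarray:
    """Fixed-effects group comparison: sum log evidence over subjects, then
    convert to posterior model probabilities."""
    return posterior_model_probs(ev.log_evidence.sum(axis=0), model_prior)


def classify(log_ev_row: np.ndarray, model_ids: np.ndarray | None = None,
             model_prior: np.ndarray | None = None) -> int:
    """Model id with the highest posterior probability (0-1 loss); exact ties
    break toward the lowest model id."""
    probs = posterior_model_probs(np.asarray(log_ev_row, dtype=float),
                                  model_prior)
    if model_ids is None:
        model_ids = np.arange(1, probs.size + 1)
    model_ids = np.asarray(model_ids)
    order = np.argsort(model_ids)
    best = order[np.argmax(probs[order])]
    return int(model_ids[best])


def decide_with_utility(log_ev_row: np.ndarray, model_prior: np.ndarray,
                        utility: np.ndarray) -> int:
    """Expected-utility maximizing decision index.

    ``utility[m, d]`` is the payoff of decision d when model m holds; ties
    break toward the lowest decision index.  With a 0-1 utility (identity
    matrix) this reduces to ``classify``.
    """
    utility = np.asarray(utility, dtype=float)
    if not np.all(np.isfinite(utility)):
        raise ValueError("utility must be finite")
    probs = posterior_model_probs(np.asarray(log_ev_row, dtype=float),
                                  model_prior)
    eu = probs @ utility
    return int(np.argmax(eu))


def accuracy_with_bootstrap(truth, predicted, n_boot: int = 1000,
                            seed=None) -> ClassificationResult:
    """Point accuracy over scored pairs plus a bootstrap resample (with
    replacement over pairs) of the accuracy distribution."""
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape:
        raise ValueError("truth and predicted must have equal length")
    correct = (truth == predicted).astype(float)
    rng = np.random.default_rng(seed)
    n = correct.size
    idx = rng.integers(0, n, size=(n_boot, n))
    samples = correct[idx].mean(axis=1)
    return ClassificationResult(
        predicted=predicted, accuracy=float(correct.mean()),
        bootstrap_samples=samples, n_boot=n_boot,
        seed=seed)


def classify_matrix(ev: EvidenceMatrix,
                    model_prior: np.ndarray | None = None) -> np.ndarray:
    """Per-subject argmax classification over an evidence matrix."""
    return np.array([classify(row, ev.model_ids, model_prior)
                     for row in ev.log_evidence])
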