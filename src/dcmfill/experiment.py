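"""End-to-end experiment runner: simulate -> remove -> fill -> invert ->
compare -> score, over a (fill, n_missing, noise, subset-size) grid.

Every random draw derives from the master seed through a fixed spawning
order (cohorts per noise level, then node removal per missing count, then
fills per subject, then bootstrap), so re-running a config byte-reproduces
all seeded outputs.
"""

from __future__ import annotations

import json
import time
import traceback
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .cohort import (DEFAULT_NOISE_SD_FRAC, Cohort, model_family,
                     remove_nodes, simulate_mixed_cohort, subset_family)
from .comparison import EvidenceMatrix, accuracy_with_bootstrap, classify
from .imputation import fill_em, fill_mean, fill_noise, fill_zero
from .inversion import InversionSettings, default_priors, invert_dcm

FILL_METHODS = ("zero", "mean", "noise", "em")


@dataclass
class ExperimentConfig:
    n_subjects: int = 5
    family_size: int = 16              # size of the candidate set inverted
    subset_sizes: tuple = (16,)        # evaluation subsets (16/8/4)
    fills: tuple = FILL_METHODS
    n_missing: tuple = (0, 1)
    noise_levels: tuple = (DEFAULT_NOISE_SD_FRAC,)
    n_boot: int = 1000
    seed: int = 0
    duration: float = 600.0
    tr: float = 3.0
    sim_dt: float = 0.005
    max_iter: int = 16                 # inversion budget per model
    inv_dt: float = 0.12
    inv_tol: float = 1e-3
    out_dir: str | None = None

    def validate(self):
        if self.family_size < max(self.subset_sizes):
            raise ValueError("subset sizes cannot exceed family size")
        unknown = set(self.fills) - set(FILL_METHODS)
        if unknown:
            raise ValueError(f"unknown fill methods: {sorted(unknown)}")
        if any(m < 0 or m > 3 for m in self.n_missing):
            raise ValueError("n_missing entries must be in [0, 3]")
        return self

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        path = Path(path)
        with open(path) as f:
            payload = (yaml.safe_load(f) if path.suffix in {".yaml", ".yml"}
                       else json.load(f))
        cfg = cls(**payload)
        for name in ("subset_sizes", "fills", "n_missing", "noise_levels"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg.validate()

    def to_file(self, path) -> None:
        payload = asdict(self)
        for k, v in payload.items():
            if isinstance(v, tuple):
                payload[k] = list(v)
        with open(path, "w") as f:
            yaml.safe_dump(payload, f)


def _fill_subject(method, series, mask, cohort, subject_index, seed):
    if not mask.any():
        return series.copy()
    if method == "zero":
        return fill_zero(series, mask)
    if method == "mean":
        return fill_mean(series, mask, cohort, subject_index)
    if method == "noise":
        return fill_noise(series, mask, seed=seed)
    if method == "em":
        return fill_em(series, mask, seed=seed)
    raise ValueError(f"unknown fill method {method!r}")


def evidence_for_cohort(cohort: Cohort, candidates, settings, *,
                        fill_method: str = "full",
                        fill_seeds=None, progress=None) -> EvidenceMatrix:
    """Fill each subject's missing nodes and invert every candidate model,
    returning the subjects x models log-evidence matrix."""
    rows = []
    for k, series in enumerate(cohort.subjects):
        mask = cohort.missing_mask[k]
        seed = None if fill_seeds is None else fill_seeds[k]
        filled = (series.copy() if fill_method == "full"
                  else _fill_subject(fill_method, series, mask, cohort,
                                     k, seed))
        row = []
        for model in candidates:
            post = invert_dcm(filled, model, default_priors(model), settings)
            row.append(post.free_energy)
            if progress is not None:
                progress()
        rows.append(row)
    return EvidenceMatrix(np.asarray(rows),
                          model_ids=np.array([m.model_id
                                              for m in candidates]),
                          subject_ids=np.arange(cohort.n_subjects),
                          fill_method=fill_method)


def subset_accuracy(ev: EvidenceMatrix, truth: np.ndarray, family,
                    subset_size: int, n_boot: int, seed):
    """Score classification restricted to a per-subject candidate subset
    that always contains that subject's true model."""
    preds = []
    for k, row in enumerate(ev.log_evidence):
        sub = subset_family(family, subset_size, int(truth[k]))
        ids = [m.model_id for m in sub]
        cols = [int(np.flatnonzero(ev.model_ids == i)[0]) for i in ids]
        preds.append(classify(row[cols], np.array(ids)))
    return accuracy_with_bootstrap(truth, np.array(preds), n_boot, seed)


def run_experiment(config: ExperimentConfig, *, log=print):
    """Run the full grid; returns a results bundle with a summary frame,
    per-cell evidence matrices, and isolated per-cell errors."""
    config.validate()
    family = model_family()
    candidates = subset_family(family, config.family_size,
                               true_model_id=family[0].model_id)
    cand_ids = [m.model_id for m in candidates]
    settings = InversionSettings(dt=config.inv_dt, max_iter=config.max_iter,
                                 tol=config.inv_tol)

    base = np.random.SeedSequence(config.seed)
    sim_ss, removal_ss, fill_ss, boot_ss = base.spawn(4)
    sim_seeds = sim_ss.spawn(len(config.noise_levels))
    removal_seeds = removal_ss.generate_state(len(config.n_missing))
    boot_seed = int(boot_ss.generate_state(1)[0])

    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    summary_rows = []
    evidence = {}
    errors = []
    fill_rng = np.random.default_rng(fill_ss)

    for ni, noise in enumerate(config.noise_levels):
        cohort = simulate_mixed_cohort(
            candidates, config.n_subjects, sim_seeds[ni],
            duration=config.duration, dt=config.sim_dt, tr=config.tr,
            noise_sd_frac=noise)
        truth = cohort.true_model_id
        for mi, n_miss in enumerate(config.n_missing):
            masked = (cohort if n_miss == 0 else
                      remove_nodes(cohort, n_miss,
                                   int(removal_seeds[mi]) + ni))
            fills = ("full",) if n_miss == 0 else config.fills
            for method in fills:
                cell = (noise, n_miss, method)
                t0 = time.time()
                try:
                    fill_seeds = fill_rng.integers(
                        2 ** 63, size=cohort.n_subjects)
                    ev = evidence_for_cohort(masked, candidates, settings,
                                             fill_method=method,
                                             fill_seeds=fill_seeds)
                    evidence[cell] = ev
                    for size in config.subset_sizes:
                        res = subset_accuracy(ev, truth, candidates, size,
                                              config.n_boot, boot_seed)
                        q25, q75 = np.percentile(res.bootstrap_samples,
                                                 [25, 75])
                        summary_rows.append({
                            "noise": noise, "n_missing": n_miss,
                            "fill": method, "subset_size": size,
                            "accuracy": res.accuracy,
                            "boot_mean": float(res.bootstrap_samples.mean()),
                            "boot_sd": res.bootstrap_sd,
                            "boot_q25": float(q25), "boot_q75": float(q75),
                            "n_pairs": cohort.n_subjects,
                            "seconds": time.time() - t0,
                        })
                    if out_dir:
                        tag = f"noise{noise}_miss{n_miss}_{method}"
                        dio.save_evidence(out_dir / f"evidence_{tag}.csv", ev)
                except Exception as err:  # noqa: BLE001 - cell isolation
                    errors.append({"cell": cell, "error": repr(err),
                                   "trace": traceback.format_exc()})
                    log(f"cell {cell} failed: {err!r}")

    summary = pd.DataFrame(summary_rows)
    if out_dir:
        summary.to_csv(out_dir / "summary.csv", index=False)
        manifest = {
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(config).items()},
            "candidate_ids": cand_ids,
            "n_cells": len(evidence),
            "errors": [{"cell": str(e["cell"]), "error": e["error"]}
                       for e in errors],
        }
        with open(out_dir / "manifest.json", "w") as f:
            json.dump(manifest, f, indent=2)
        dio.save_family(out_dir / "family.json", candidates)
    return {"summary": summary, "evidence": evidence, "errors": errors,
            "candidates": candidates}
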