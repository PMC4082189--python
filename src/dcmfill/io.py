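"""HDF5 cohort containers, model-family serialization, and table export."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .cohort import CandidateModel, Cohort
from .comparison import EvidenceMatrix
from .forward import NodeTimeSeries


def save_cohort(path, cohort: Cohort, *, store_inputs: bool = True) -> None:
    """Write a cohort to HDF5 (datasets /bold, /inputs, /mask; attributes
    tr, model_id)."""
    with h5py.File(path, "w") as f:
        f.attrs["tr"] = cohort.tr
        f.attrs["n_subjects"] = cohort.n_subjects
        f.create_dataset("mask", data=cohort.missing_mask)
        f.create_dataset("model_id", data=cohort.true_model_id)
        for k, s in enumerate(cohort.subjects):
            g = f.create_group(f"subject_{k:04d}")
            g.create_dataset("bold", data=s.bold)
            if store_inputs and s.inputs is not None:
                g.create_dataset("inputs", data=s.inputs)
                g.attrs["dt"] = s.dt
            if s.neural is not None:
                g.create_dataset("neural", data=s.neural)


def load_cohort(path) -> Cohort:
    with h5py.File(path, "r") as f:
        tr = float(f.attrs["tr"])
        n = int(f.attrs["n_subjects"])
        subjects = []
        for k in range(n):
            g = f[f"subject_{k:04d}"]
            subjects.append(NodeTimeSeries(
                bold=g["bold"][()], tr=tr,
                inputs=g["inputs"][()] if "inputs" in g else None,
                dt=float(g.attrs["dt"]) if "dt" in g.attrs else None,
                neural=g["neural"][()] if "neural" in g else None))
        return Cohort(subjects=subjects, true_model_id=f["model_id"][()],
                      missing_mask=f["mask"][()],
                      seeds=np.arange(n), tr=tr)


def cohort_to_csv(path, cohort: Cohort) -> None:
    """Long-format CSV export of the sampled BOLD series for inspection."""
    rows = []
    for k, s in enumerate(cohort.subjects):
        for node in range(s.n_nodes):
            for t in range(s.n_samples):
                rows.append((k, node, t * s.tr, s.bold[t, node]))
    pd.DataFrame(rows, columns=["subject", "node", "time_s", "bold"]
                 ).to_csv(path, index=False)


def _model_to_dict(model: CandidateModel) -> dict:
    return {
        "model_id": model.model_id,
        "node_labels": list(model.node_labels),
        "topology": [list(row) for row in model.topology],
        "input_map": [list(row) for row in model.input_map],
        "modulation": [list(m) for m in model.modulation],
    }


def _model_from_dict(d: dict) -> CandidateModel:
    return CandidateModel(
        model_id=int(d["model_id"]),
        topology=tuple(tuple(int(x) for x in row) for row in d["topology"]),
        input_map=tuple(tuple(int(x) for x in row) for row in d["input_map"]),
        modulation=tuple(tuple(int(x) for x in m)
                         for m in d.get("modulation", [])),
        node_labels=tuple(d.get("node_labels", ("V", "A", "M", "P"))))


def save_family(path, family) -> None:
    """Serialize a model family to JSON or YAML (by extension)."""
    payload = {"models": [_model_to_dict(m) for m in family]}
    path = Path(path)
    with open(path, "w") as f:
        if path.suffix in {".yaml", ".yml"}:
            yaml.safe_dump(payload, f)
        else:
            json.dump(payload, f, indent=2)


def load_family(path) -> list[CandidateModel]:
    path = Path(path)
    with open(path) as f:
        payload = (yaml.safe_load(f) if path.suffix in {".yaml", ".yml"}
                   else json.load(f))
    family = [_model_from_dict(d) for d in payload["models"]]
    seen = {m.topology for m in family}
    if len(seen) != len(family):
        raise ValueError("duplicate topologies in family file")
    return family


def evidence_to_frame(ev: EvidenceMatrix) -> pd.DataFrame:
    df = pd.DataFrame(ev.log_evidence,
                      columns=[f"model_{i}" for i in ev.model_ids])
    df.insert(0, "subject", ev.subject_ids)
    return df


def save_evidence(path, ev: EvidenceMatrix) -> None:
    evidence_to_frame(ev).to_csv(path, index=False)
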