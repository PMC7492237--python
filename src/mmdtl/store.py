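"""File round-trips: connectome store, weights container, run records.

On-disk layout (all text except the per-layer arrays):

* connectome store — ``connectome.csv`` (subject_id + one column per edge,
  named ``ROIi__ROIj`` in vectorization order) and ``manifest.csv``
  (subject_id, site, cohort, one column per task label); the two are
  cross-validated on read.
* weights container — a directory with ``manifest.json`` (stage, shapes,
  activations, provenance, seed) and one ``layer_XX.npz`` per layer.
* run record — ``run_record.json`` capturing config, seeds and the stage
  provenance chain.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .features import SubjectRecord, edge_names, n_edges
from .network import ArchitectureSpec, Layer, WeightSet

__all__ = [
    "write_connectome_store",
    "read_connectome_store",
    "save_weights",
    "load_weights",
    "RunRecord",
]


def write_connectome_store(
    records: list[SubjectRecord], path: str | Path, roi_names: list[str] | None = None
) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    n_roi = records[0].n_roi
    names = roi_names or [f"ROI{i + 1}" for i in range(n_roi)]
    cols = edge_names(names)
    feats = pd.DataFrame(
        np.vstack([r.connectome for r in records]),
        columns=cols,
        index=pd.Index([r.subject_id for r in records], name="subject_id"),
    )
    feats.to_csv(path / "connectome.csv", float_format="%.17g")
    task_names = sorted(
        {t for r in records if r.labels for t in r.labels}
    )
    manifest = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "site": [r.site for r in records],
            "cohort": [r.cohort for r in records],
            **{
                t: [r.labels.get(t, "") if r.labels else "" for r in records]
                for t in task_names
            },
        }
    )
    manifest.to_csv(path / "manifest.csv", index=False)


def read_connectome_store(path: str | Path) -> list[SubjectRecord]:
    path = Path(path)
    feats = pd.read_csv(
        path / "connectome.csv", index_col="subject_id",
        float_precision="round_trip",
    )
    manifest = pd.read_csv(
        path / "manifest.csv", dtype={"subject_id": str}, keep_default_na=False
    )
    if list(feats.index.astype(str)) != list(manifest["subject_id"]):
        raise ValueError("connectome.csv and manifest.csv disagree on subject ids")
    m = feats.shape[1]
    n = int(round((1 + np.sqrt(1 + 8 * m)) / 2))
    if n_edges(n) != m:
        raise ValueError(f"edge-column count {m} is not n*(n-1)/2 for integer n")
    task_cols = [c for c in manifest.columns if c not in ("subject_id", "site", "cohort")]
    records = []
    for i, row in manifest.iterrows():
        labels = {
            t: int(row[t]) for t in task_cols if str(row[t]).strip() not in ("", "nan")
        } or None
        records.append(
            SubjectRecord(
                str(row["subject_id"]), str(row["site"]), str(row["cohort"]),
                feats.iloc[i].to_numpy(float), labels=labels,
            )
        )
    return records


def save_weights(w: WeightSet, arch: ArchitectureSpec, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": arch.stage,
        "layer_sizes": arch.layer_sizes,
        "task_count": arch.task_count,
        "clinical_width": arch.clinical_width,
        "fusion_layer": arch.fusion_layer,
        "activations": arch.activations,
        "batch_norm": arch.batch_norm,
        "provenance": w.provenance,
        "seed": w.seed,
        "shapes": [list(l.W.shape) for l in w.layers],
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
    for i, layer in enumerate(w.layers):
        arrays = {"W": layer.W, "b": layer.b}
        if layer.has_bn:
            arrays |= {
                "gamma": layer.gamma, "beta": layer.beta,
                "running_mean": layer.running_mean, "running_var": layer.running_var,
            }
        np.savez(path / f"layer_{i:02d}.npz", **arrays)


def load_weights(path: str | Path) -> tuple[WeightSet, ArchitectureSpec]:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    arch = ArchitectureSpec(
        manifest["stage"], manifest["layer_sizes"], manifest["activations"],
        manifest["batch_norm"], manifest["task_count"],
        manifest["clinical_width"], manifest["fusion_layer"],
    )
    layers = []
    for i, shape in enumerate(manifest["shapes"]):
        z = np.load(path / f"layer_{i:02d}.npz")
        if list(z["W"].shape) != shape:
            raise ValueError(
                f"layer {i}: stored shape {list(z['W'].shape)} != manifest {shape}"
            )
        layers.append(
            Layer(
                z["W"], z["b"],
                z["gamma"] if "gamma" in z else None,
                z["beta"] if "beta" in z else None,
                z["running_mean"] if "running_mean" in z else None,
                z["running_var"] if "running_var" in z else None,
            )
        )
    return WeightSet(layers, manifest["provenance"], manifest["seed"]), arch


@dataclass
class RunRecord:
    """Provenance of one pipeline run, written once per output directory."""

    config: dict
    seeds: dict
    provenance_chain: list[str] = field(default_factory=list)
    version: str = __version__
    timestamp: str = field(default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.config, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    def write(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        payload = asdict(self) | {"config_hash": self.config_hash}
        (path / "run_record.json").write_text(json.dumps(payload, indent=2, default=str))
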