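"""Gradient-based feature ranking for the fitted multi-task model.

Importance of a connectome edge a_ij (or clinical feature e_i) for task c is
the absolute partial derivative of the task's positive-class probability with
respect to that input, averaged over a reference sample set (default: the
target training set).  Gradients flow through batch normalization in
evaluation mode (running statistics) so the map is deterministic.  Edge
gradients are reported with respect to the raw correlation values (the
internal [0, 1] rescaling contributes its constant Jacobian 1/2).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .features import edge_names, rescale_unit
from .network import ArchitectureSpec, WeightSet, forward_backward_input

__all__ = ["SaliencyRanking", "saliency_map", "top_k", "overlap_sets"]


@dataclass
class SaliencyRanking:
    """Per-task importance of every connectome edge and clinical feature."""

    task: str
    edge_scores: np.ndarray
    clinical_scores: np.ndarray | None
    aggregation: str
    reference_inputs: str
    roi_names: list[str] | None = None

    def __post_init__(self) -> None:
        if np.any(self.edge_scores < 0):
            raise ValueError("saliency scores are absolute values, must be >= 0")

    def edge_labels(self) -> list[str]:
        if self.roi_names is None:
            n = int(round((1 + np.sqrt(1 + 8 * len(self.edge_scores))) / 2))
            names = [f"ROI{i + 1}" for i in range(n)]
        else:
            names = self.roi_names
        return edge_names(names)


def saliency_map(
    w: WeightSet,
    arch: ArchitectureSpec,
    X_raw: np.ndarray,
    clinical: np.ndarray | None,
    task: int,
    task_name: str | None = None,
    target: str = "prob",
    roi_names: list[str] | None = None,
) -> SaliencyRanking:
    """Mean absolute input gradient of one task head over a reference set.

    ``X_raw`` holds correlation-valued edge vectors in [-1, 1]; ``target``
    may be "prob" (default) or "logit" (gradient of the positive-class
    logit margin, obtained by dividing out p(1-p)).
    """
    X_raw = np.atleast_2d(np.asarray(X_raw, dtype=float))
    if len(X_raw) == 0:
        raise ValueError("need at least one reference sample")
    if w.provenance == "random":
        raise ValueError("model is unfitted (provenance 'random')")
    X01 = rescale_unit(X_raw)
    p, dX, dClin = forward_backward_input(w, arch, X01, clinical, task)
    if target == "logit":
        denom = np.clip(p * (1.0 - p), 1e-12, None)[:, None]
        dX = dX / denom
        dClin = dClin / denom if dClin is not None else None
    elif target != "prob":
        raise ValueError("target must be 'prob' or 'logit'")
    edge = np.abs(dX * 0.5).mean(axis=0)  # chain rule of the [-1,1] -> [0,1] map
    clin = np.abs(dClin).mean(axis=0) if dClin is not None else None
    return SaliencyRanking(
        task=task_name or f"task{task}",
        edge_scores=edge,
        clinical_scores=clin,
        aggregation=f"mean |d {target} / d input| over samples",
        reference_inputs=f"{len(X_raw)} reference subjects",
        roi_names=roi_names,
    )


def top_k(r: SaliencyRanking, k: int, block: str = "edges") -> list[str]:
    """The k highest-scoring features; ties broken by fixed feature order."""
    if block == "edges":
        scores, names = r.edge_scores, r.edge_labels()
    elif block == "clinical":
        if r.clinical_scores is None:
            raise ValueError("ranking has no clinical block")
        scores = r.clinical_scores
        names = [f"clin{i}" for i in range(len(scores))]
    else:
        raise ValueError("block must be 'edges' or 'clinical'")
    if k > len(scores):
        raise ValueError(f"k={k} exceeds block size {len(scores)}")
    order = np.lexsort((np.arange(len(scores)), -scores))
    return [names[i] for i in order[:k]]


def top_k_indices(r: SaliencyRanking, k: int) -> np.ndarray:
    """Edge indices of the top-k scores (same tie rule as :func:`top_k`)."""
    order = np.lexsort((np.arange(len(r.edge_scores)), -r.edge_scores))
    return order[:k]


def overlap_sets(rankings: dict[str, list[str]]) -> dict[tuple[str, ...], list[str]]:
    """Common features of every task subset of the given top-k lists.

    Returns {(taskA, taskB, ...): sorted common features} for every subset of
    two or more tasks.  Order of the input tasks does not affect membership.
    """
    if len(rankings) < 2:
        raise ValueError("need at least two rankings to intersect")
    tasks = sorted(rankings)
    out: dict[tuple[str, ...], list[str]] = {}
    for size in range(2, len(tasks) + 1):
        for subset in combinations(tasks, size):
            common = set(rankings[subset[0]])
            for t in subset[1:]:
                common &= set(rankings[t])
            out[subset] = sorted(common)
    return out
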