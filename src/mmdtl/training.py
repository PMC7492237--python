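"""The three stage objectives and their mini-batch SGD training loops.

Stage 1 minimizes the mean binary cross-entropy of the source-task softmax
output; stage 2 the per-feature reconstruction cross-entropy of the
autoencoder (inputs rescaled to [0, 1]); stage 3 a weighted multi-task
cross-entropy

    J = -(1 / (m C)) * sum_c alpha_c * sum_i beta_ic *
        [ y_ic log p_ic + (1 - y_ic) log(1 - p_ic) ]

where alpha_c weights task c and beta_ic up-weights minority-class samples
by the majority/minority count ratio of the training split.  Optimization is
plain mini-batch stochastic gradient descent (learning rate 0.01 by default)
with an early stop once the validation loss plateaus for ``patience``
consecutive epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import SubjectRecord, rescale_unit
from .network import (
    ArchitectureSpec,
    calibrate_bn,
    TransferMap,
    WeightSet,
    backward,
    forward,
    init_weights,
    transfer_weights,
)

__all__ = [
    "TrainingConfig",
    "TaskWeights",
    "TrainingTrace",
    "stage1_loss",
    "stage2_loss",
    "stage3_loss",
    "early_stop_check",
    "sgd_epoch",
    "train_stage1",
    "train_stage2",
    "train_stage3",
    "stacked_inputs",
]


@dataclass
class TrainingConfig:
    """Hyper-parameters of one training stage.

    Stage defaults follow the published protocol where stated (learning rate
    0.01 everywhere; batch 16 / 50 epochs for the autoencoder; batch 4 /
    10 epochs for fine-tuning); the stage-1 batch/epoch defaults are package
    choices.
    """

    learning_rate: float = 0.01
    batch_size: int = 32
    max_epochs: int = 100
    early_stop_patience: int = 3
    early_stop_tolerance: float = 1e-4
    validation_fraction: float = 0.2
    seed: int = 0
    log_clip_epsilon: float = 1e-7
    # batch-norm statistics during training: "batch" (standard) or "running"
    # (frozen statistics; the usual stabilizer when fine-tuning with tiny
    # batches, where 4-sample batch statistics are mostly noise)
    bn_stats: str = "batch"
    # global gradient-norm ceiling per mini-batch (None disables); plain SGD
    # on small weighted batches occasionally produces exploding steps
    max_grad_norm: float | None = 5.0
    # L2 weight decay on weight matrices (optimizer extra, off by default);
    # decays weight components that no data gradient supports
    weight_decay: float = 0.0
    # first-layer initialization gain (see network.init_weights)
    input_gain: float = 1.0

    def __post_init__(self) -> None:
        if self.learning_rate < 0 or self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("learning rate/batch size/epochs must be positive")
        if not (0.0 < self.validation_fraction < 1.0):
            raise ValueError("validation_fraction must lie in (0, 1)")
        if self.log_clip_epsilon <= 0:
            raise ValueError("log_clip_epsilon must be positive")


STAGE2_DEFAULTS = dict(batch_size=16, max_epochs=50)
STAGE3_DEFAULTS = dict(batch_size=4, max_epochs=10)


@dataclass
class TaskWeights:
    """Per-task loss weights alpha and the minority up-weighting rule beta.

    ``beta_for`` computes, from the training-split labels of one task, the
    per-sample weight: majority/minority count ratio for minority-class
    samples, 1 otherwise.  ``use_beta=False`` disables the re-weighting
    (every beta = 1), the ablation baseline.
    """

    alpha: np.ndarray | None = None
    use_beta: bool = True

    def alphas(self, task_count: int) -> np.ndarray:
        if self.alpha is None:
            return np.ones(task_count)
        a = np.asarray(self.alpha, dtype=float)
        if len(a) != task_count or np.any(a <= 0) or not np.all(np.isfinite(a)):
            raise ValueError("alpha must be positive and finite, one per task")
        return a

    def beta_for(self, y_train: np.ndarray) -> np.ndarray:
        y = np.asarray(y_train)
        n_pos, n_neg = int(y.sum()), int(len(y) - y.sum())
        if not self.use_beta:
            return np.ones(len(y))
        if n_pos == 0 or n_neg == 0:
            raise ValueError(
                "a task has no minority-class samples in the training split; "
                "the majority/minority weight is undefined"
            )
        if n_pos <= n_neg:
            w_min, minority = n_neg / n_pos, 1
        else:
            w_min, minority = n_pos / n_neg, 0
        return np.where(y == minority, w_min, 1.0)


@dataclass
class TrainingTrace:
    """Per-epoch losses and the reason training stopped."""

    train_losses: list[float] = field(default_factory=list)
    val_losses: list[float] = field(default_factory=list)
    stop_reason: str = "max_epochs"


def _clip(p: np.ndarray, eps: float) -> np.ndarray:
    return np.clip(p, eps, 1.0 - eps)


def binary_cross_entropy(p: np.ndarray, y: np.ndarray, eps: float = 1e-7) -> float:
    """Mean over samples of -[y log p + (1-y) log(1-p)] with clipped p."""
    p = _clip(np.asarray(p, dtype=float), eps)
    y = np.asarray(y, dtype=float)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def stage1_loss(
    w: WeightSet,
    arch: ArchitectureSpec,
    X: np.ndarray,
    y: np.ndarray,
    eps: float = 1e-7,
    mode: str = "eval",
) -> float:
    """Source-domain cross-entropy J(W_s1, b | W_0) on a batch."""
    if len(y) != len(np.atleast_2d(X)):
        raise ValueError("label count does not match batch size")
    p = forward(w, arch, X, mode=mode)[:, 0]
    return binary_cross_entropy(p, y, eps)


def stage2_loss(
    w: WeightSet,
    arch: ArchitectureSpec,
    X01: np.ndarray,
    eps: float = 1e-7,
    mode: str = "eval",
) -> float:
    """Reconstruction cross-entropy J(W_s2, b | W_s1), inputs in [0, 1]."""
    X01 = np.atleast_2d(np.asarray(X01, dtype=float))
    if X01.min() < 0.0 or X01.max() > 1.0:
        raise ValueError("stage-2 inputs must be rescaled to [0, 1]")
    Xh = _clip(forward(w, arch, X01, mode=mode), eps)
    return float(
        -np.mean(X01 * np.log(Xh) + (1.0 - X01) * np.log(1.0 - Xh))
    )


def stage3_loss(
    w: WeightSet,
    arch: ArchitectureSpec,
    X: np.ndarray,
    Y: np.ndarray,
    beta: np.ndarray,
    alpha: np.ndarray,
    clinical: np.ndarray | None = None,
    eps: float = 1e-7,
    mode: str = "eval",
) -> float:
    """Weighted multi-task cross-entropy J(W_t, b | W_s2).

    ``Y`` is (m, C); ``beta`` (m, C) holds the per-sample, per-task weights
    computed from the full training split (not the batch).
    """
    X = np.atleast_2d(X)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    beta = np.atleast_2d(np.asarray(beta, dtype=float))
    if np.any(beta < 1.0):
        raise ValueError("beta weights must be >= 1")
    m, C = Y.shape
    P = _clip(forward(w, arch, X, clinical, mode=mode), eps)
    P = np.atleast_2d(P)
    per = beta * (Y * np.log(P) + (1.0 - Y) * np.log(1.0 - P))
    return float(-(per * alpha[None, :]).sum() / (m * C))


def early_stop_check(
    validation_losses: list[float], patience: int = 3, tolerance: float = 1e-4
) -> bool:
    """True when the last ``patience + 1`` losses are pairwise within tolerance.

    With ``tolerance=0`` this is the literal "same validation loss for
    ``patience`` consecutive epochs" rule; the small default tolerance makes
    the plateau detectable in floating point.
    """
    if not validation_losses:
        raise ValueError("need at least one observed loss")
    window = validation_losses[-(patience + 1):]
    if len(window) < patience + 1:
        return False
    return max(window) - min(window) <= tolerance


def _check_finite_grads(grads: list[dict]) -> None:
    for i, g in enumerate(grads):
        for key, val in g.items():
            if not np.all(np.isfinite(val)):
                raise FloatingPointError(
                    f"non-finite gradient {key} in layer {i}"
                )


def _clip_grads(grads: list[dict], max_norm: float | None) -> None:
    if max_norm is None:
        return
    total = np.sqrt(sum(float((v**2).sum()) for g in grads for v in g.values()))
    if total > max_norm:
        scale = max_norm / total
        for g in grads:
            for k in g:
                g[k] = g[k] * scale


def _apply_update(w: WeightSet, grads: list[dict], lr: float,
                  frozen: frozenset[int] = frozenset(),
                  weight_decay: float = 0.0) -> None:
    for i, (layer, g) in enumerate(zip(w.layers, grads)):
        if i in frozen:
            continue
        if weight_decay > 0.0:
            layer.W *= 1.0 - lr * weight_decay
        layer.W -= lr * g["dW"]
        layer.b -= lr * g["db"]
        if layer.has_bn and "dgamma" in g:
            layer.gamma -= lr * g["dgamma"]
            layer.beta -= lr * g["dbeta"]


def sgd_epoch(
    w: WeightSet,
    arch: ArchitectureSpec,
    data: dict,
    loss_grad_fn,
    config: TrainingConfig,
    epoch: int,
    frozen: frozenset[int] = frozenset(),
) -> float:
    """One pass of shuffled mini-batch SGD; returns the mean batch loss.

    ``loss_grad_fn(w, arch, batch)`` must return (loss, grads).  The batch
    order is a deterministic function of (config.seed, epoch); the final
    partial batch is included.
    """
    m = len(data["X"])
    rng = np.random.default_rng((config.seed, epoch))
    order = rng.permutation(m)
    losses = []
    for start in range(0, m, config.batch_size):
        idx = order[start:start + config.batch_size]
        batch = {k: (v[idx] if v is not None else None) for k, v in data.items()}
        loss, grads = loss_grad_fn(w, arch, batch)
        _check_finite_grads(grads)
        _clip_grads(grads, config.max_grad_norm)
        _apply_update(w, grads, config.learning_rate, frozen,
                      config.weight_decay)
        losses.append(loss)
    return float(np.mean(losses))


def stacked_inputs(records: list[SubjectRecord], rescale: bool = True) -> np.ndarray:
    """Stack connectome vectors, mapping correlations from [-1, 1] to [0, 1]."""
    X = np.vstack([r.connectome for r in records])
    return rescale_unit(X) if rescale else X


def _stratified_split(y: np.ndarray, frac: float, seed: int):
    """Indices (train, val) with class proportions preserved in the val split."""
    rng = np.random.default_rng(seed)
    y = np.asarray(y)
    val_idx: list[int] = []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        n_val = max(1, int(round(frac * len(idx))))
        val_idx.extend(idx[:n_val])
    val = np.sort(np.array(val_idx))
    train = np.setdiff1d(np.arange(len(y)), val)
    return train, val


def _train_loop(w, arch, train_data, val_loss_fn, loss_grad_fn, config, frozen):
    trace = TrainingTrace()
    for epoch in range(config.max_epochs):
        if config.bn_stats == "running" and epoch > 0:
            # re-estimate the frozen statistics as the weights drift
            calibrate_bn(w, arch, train_data["X"], train_data.get("clin"))
        tr = sgd_epoch(w, arch, train_data, loss_grad_fn, config, epoch, frozen)
        trace.train_losses.append(tr)
        trace.val_losses.append(val_loss_fn(w))
        if early_stop_check(
            trace.val_losses, config.early_stop_patience, config.early_stop_tolerance
        ):
            trace.stop_reason = "early_stop"
            break
    return w, trace


def train_stage1(
    records: list[SubjectRecord],
    arch: ArchitectureSpec,
    config: TrainingConfig,
    init: WeightSet | None = None,
) -> tuple[WeightSet, TrainingTrace]:
    """Supervised pre-training on the labeled source cohort."""
    y = np.array([next(iter(r.labels.values())) for r in records], dtype=float)
    X = stacked_inputs(records)
    tr_idx, va_idx = _stratified_split(y, config.validation_fraction, config.seed)
    eps = config.log_clip_epsilon
    w = (init or init_weights(arch, config.seed, config.input_gain)).copy()

    def loss_grad(w, arch, batch):
        Xb, yb = batch["X"], batch["y"]
        fmode = "train" if config.bn_stats == "batch" else "eval"
        probs, caches = forward(w, arch, Xb, mode=fmode, return_cache=True)
        p = _clip(probs[:, 0], eps)
        loss = binary_cross_entropy(p, yb, eps)
        P2 = np.column_stack([1.0 - p, p])
        Y2 = np.column_stack([1.0 - yb, yb])
        dZ = (P2 - Y2) / len(yb)
        grads, _, _ = backward(w, arch, caches, dZ_heads=[dZ])
        return loss, grads

    def val_loss(w):
        return stage1_loss(w, arch, X[va_idx], y[va_idx], eps)

    w, trace = _train_loop(
        w, arch, {"X": X[tr_idx], "y": y[tr_idx]}, val_loss, loss_grad, config,
        frozenset(),
    )
    w.provenance = "stage1"
    return w, trace


def train_stage2(
    records: list[SubjectRecord],
    w_s1: WeightSet,
    arch: ArchitectureSpec,
    tmap: TransferMap,
    config: TrainingConfig,
) -> tuple[WeightSet, TrainingTrace]:
    """Unsupervised autoencoder adaptation on the intermediate cohort."""
    X = stacked_inputs(records)
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(X))
    n_val = max(1, int(round(config.validation_fraction * len(X))))
    va_idx, tr_idx = order[:n_val], order[n_val:]
    eps = config.log_clip_epsilon
    w = transfer_weights(w_s1, arch, tmap, config.seed)

    def loss_grad(w, arch, batch):
        Xb = batch["X"]
        fmode = "train" if config.bn_stats == "batch" else "eval"
        Xh, caches = forward(w, arch, Xb, mode=fmode, return_cache=True)
        Xc = _clip(Xh, eps)
        m, n = Xb.shape
        loss = float(-np.mean(Xb * np.log(Xc) + (1 - Xb) * np.log(1 - Xc)))
        dZ_out = (Xh - Xb) / (m * n)  # sigmoid + cross-entropy shortcut
        grads, _, _ = backward(w, arch, caches, dZ_out=dZ_out)
        return loss, grads

    def val_loss(w):
        return stage2_loss(w, arch, X[va_idx], eps)

    w, trace = _train_loop(
        w, arch, {"X": X[tr_idx]}, val_loss, loss_grad, config, tmap.frozen
    )
    w.provenance = "stage2"
    return w, trace


def train_stage3(
    records: list[SubjectRecord],
    w_init: WeightSet | None,
    arch: ArchitectureSpec,
    tmap: TransferMap | None,
    config: TrainingConfig,
    task_weights: TaskWeights | None = None,
    task_names: list[str] | None = None,
) -> tuple[WeightSet, TrainingTrace]:
    """Multi-task fine-tuning on the labeled target cohort.

    ``w_init`` may be the stage-2 weights (multi-stage), stage-1 weights
    (single-stage) or None (no transfer: random initialization).  Per-task
    beta weights are computed once from the gradient-update split, never from
    a batch or from validation data.
    """
    tw = task_weights or TaskWeights()
    if task_names is None:
        task_names = sorted(records[0].labels.keys())
    Y = np.array([[r.labels[t] for t in task_names] for r in records], dtype=float)
    X = stacked_inputs(records)
    clin = None
    if arch.clinical_width > 0:
        clin = np.vstack([r.clinical for r in records])
    # stratify the early-stopping split on the rarest task's labels
    rarest = int(np.argmin(np.minimum(Y.sum(0), len(Y) - Y.sum(0))))
    tr_idx, va_idx = _stratified_split(Y[:, rarest], config.validation_fraction,
                                       config.seed)
    # the split stratifies on one task only; make sure no other task loses an
    # entire class from the gradient split (beta would be undefined)
    for c in range(Y.shape[1]):
        for cls in (0.0, 1.0):
            if not np.any(Y[tr_idx, c] == cls):
                movable = va_idx[Y[va_idx, c] == cls]
                if len(movable) == 0:
                    raise ValueError(
                        f"task {c} has no class-{int(cls)} samples at all in "
                        "the training data"
                    )
                tr_idx = np.sort(np.append(tr_idx, movable[0]))
                va_idx = va_idx[va_idx != movable[0]]
    C = arch.task_count
    alpha = tw.alphas(C)
    beta_tr = np.column_stack([tw.beta_for(Y[tr_idx, c]) for c in range(C)])
    # validation loss uses unit beta: it monitors fit, not the weighted objective
    beta_va = np.ones((len(va_idx), C))
    eps = config.log_clip_epsilon

    if w_init is None:
        w = init_weights(arch, config.seed)
        frozen: frozenset[int] = frozenset()
    else:
        if tmap is None:
            raise ValueError("transfer from prior-stage weights needs a TransferMap")
        w = transfer_weights(w_init, arch, tmap, config.seed)
        frozen = tmap.frozen

    def loss_grad(w, arch, batch):
        Xb, Yb, Bb = batch["X"], batch["Y"], batch["beta"]
        Cb = batch.get("clin")
        m = len(Xb)
        fmode = "train" if config.bn_stats == "batch" else "eval"
        probs, caches = forward(w, arch, Xb, Cb, mode=fmode, return_cache=True)
        P = _clip(np.atleast_2d(probs), eps)
        per = Bb * (Yb * np.log(P) + (1 - Yb) * np.log(1 - P))
        loss = float(-(per * alpha[None, :]).sum() / (m * C))
        dZ_heads = []
        for c in range(C):
            scale = (alpha[c] * Bb[:, c] / (m * C))[:, None]
            P2 = np.column_stack([1 - P[:, c], P[:, c]])
            Y2 = np.column_stack([1 - Yb[:, c], Yb[:, c]])
            dZ_heads.append(scale * (P2 - Y2))
        grads, _, _ = backward(w, arch, caches, dZ_heads=dZ_heads)
        return loss, grads

    def val_loss(w):
        cv = clin[va_idx] if clin is not None else None
        return stage3_loss(w, arch, X[va_idx], Y[va_idx], beta_va, alpha, cv, eps)

    data = {"X": X[tr_idx], "Y": Y[tr_idx], "beta": beta_tr}
    if clin is not None:
        data["clin"] = clin[tr_idx]
    if config.bn_stats == "running":
        # estimate batch-norm statistics from the training split once (also
        # adapting any transferred statistics to the target domain), then
        # keep them frozen throughout fine-tuning
        ctr = clin[tr_idx] if clin is not None else None
        calibrate_bn(w, arch, X[tr_idx], ctr)
    w, trace = _train_loop(w, arch, data, val_loss, loss_grad, config, frozen)
    w.provenance = "stage3"
    return w, trace
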