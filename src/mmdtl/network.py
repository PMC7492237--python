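"""Stage architectures, forward/backward computation, and weight transfer.

Three fully connected networks share one engine:

* stage 1 — a 5-layer classifier (ReLU hidden units, batch normalization,
  one 2-unit softmax head) pre-trained on the labeled source cohort;
* stage 2 — a 9-layer mirror-symmetric stacked autoencoder (ReLU hidden,
  sigmoid output the width of the input) adapted on the unlabeled
  intermediate cohort;
* stage 3 — a 7-layer multi-task classifier with C independent 2-unit
  softmax heads, optionally fusing an encoded clinical vector into the
  bottleneck representation, fine-tuned on the small target cohort.

Transfer between consecutive stages copies the shape-compatible
representation-bearing layers (source hidden layers -> autoencoder encoder;
encoder through bottleneck -> fine-tuning trunk); remaining layers are
freshly initialized.  All computation is plain numpy with hand-written
backpropagation, including the batch-normalization backward pass.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ArchitectureSpec",
    "WeightSet",
    "TransferMap",
    "Layer",
    "init_weights",
    "transfer_weights",
    "forward",
    "forward_backward_input",
    "default_architectures",
]

BN_EPS = 1e-5
BN_MOMENTUM = 0.9

_ACTS = ("relu", "sigmoid", "linear", "softmax2")


@dataclass
class ArchitectureSpec:
    """Layer sizes and activations of one stage network.

    ``layer_sizes`` lists every layer including input and output.  For the
    classifier stages the final entry is the per-head output width (2) and
    ``task_count`` heads of that width hang off the last shared layer.
    ``fusion_layer`` (stage 3) is the 0-based weight-layer index after whose
    activation the clinical block is concatenated.
    """

    stage: str
    layer_sizes: list[int]
    activations: list[str]
    batch_norm: list[bool]
    task_count: int = 1
    clinical_width: int = 0
    fusion_layer: int | None = None

    def __post_init__(self) -> None:
        if self.stage not in ("stage1", "stage2", "stage3"):
            raise ValueError(f"unknown stage {self.stage!r}")
        for a in self.activations:
            if a not in _ACTS:
                raise ValueError(f"unknown activation {a!r}")
        if self.stage == "stage1":
            if len(self.layer_sizes) != 5 or self.layer_sizes[-1] != 2:
                raise ValueError("stage1 must have 5 layers ending in a 2-unit head")
            if self.task_count != 1:
                raise ValueError("stage1 is single-task")
        elif self.stage == "stage2":
            s = self.layer_sizes
            if len(s) != 9 or s != s[::-1]:
                raise ValueError("stage2 must have 9 mirror-symmetric layers")
            if self.activations[-1] != "sigmoid":
                raise ValueError("stage2 output activation must be sigmoid")
        else:
            if len(self.layer_sizes) != 7 or self.layer_sizes[-1] != 2:
                raise ValueError("stage3 must have 7 layers ending in 2-unit heads")
            if self.task_count < 1:
                raise ValueError("stage3 needs task_count >= 1")
            if self.clinical_width > 0 and self.fusion_layer is None:
                raise ValueError("clinical_width > 0 requires a fusion_layer")
        if self.clinical_width > 0 and self.stage != "stage3":
            raise ValueError("clinical fusion exists only in stage3")

    @property
    def is_autoencoder(self) -> bool:
        return self.stage == "stage2"

    @property
    def input_size(self) -> int:
        return self.layer_sizes[0]

    def weight_layer_dims(self) -> list[tuple[int, int, str, bool]]:
        """(fan_in, fan_out, activation, batch_norm) per weight layer; heads last."""
        if self.is_autoencoder:
            sizes = self.layer_sizes
            dims = []
            for i in range(len(sizes) - 1):
                dims.append(
                    (sizes[i], sizes[i + 1], self.activations[i], self.batch_norm[i])
                )
            return dims
        trunk = self.layer_sizes[:-1]
        dims = []
        for i in range(len(trunk) - 1):
            fan_in = trunk[i]
            if self.fusion_layer is not None and i == self.fusion_layer + 1:
                fan_in += self.clinical_width
            dims.append((fan_in, trunk[i + 1], self.activations[i], self.batch_norm[i]))
        head_in = trunk[-1]
        for _ in range(self.task_count):
            dims.append((head_in, self.layer_sizes[-1], "softmax2", False))
        return dims

    @property
    def n_trunk_layers(self) -> int:
        if self.is_autoencoder:
            return len(self.layer_sizes) - 1
        return len(self.layer_sizes) - 2


@dataclass
class Layer:
    """One dense layer's parameters (plus batch-norm state when enabled)."""

    W: np.ndarray
    b: np.ndarray
    gamma: np.ndarray | None = None
    beta: np.ndarray | None = None
    running_mean: np.ndarray | None = None
    running_var: np.ndarray | None = None

    @property
    def has_bn(self) -> bool:
        return self.gamma is not None

    def copy(self) -> "Layer":
        return copy.deepcopy(self)


@dataclass
class WeightSet:
    """Ordered per-layer parameters with provenance and the seed that made them."""

    layers: list[Layer]
    provenance: str
    seed: int

    def __post_init__(self) -> None:
        for k in range(len(self.layers) - 1):
            pass  # shape chaining is architecture-dependent (heads fan out)
        for i, lay in enumerate(self.layers):
            if not np.all(np.isfinite(lay.W)) or not np.all(np.isfinite(lay.b)):
                raise ValueError(f"layer {i} contains non-finite parameters")

    def copy(self) -> "WeightSet":
        return WeightSet([l.copy() for l in self.layers], self.provenance, self.seed)


@dataclass
class TransferMap:
    """Which source layers initialize which destination layers.

    ``pairs`` maps source weight-layer index -> destination weight-layer
    index; destination layers not mapped are freshly initialized.  ``frozen``
    destination layers are excluded from gradient updates.
    """

    pairs: list[tuple[int, int]] = field(default_factory=list)
    frozen: frozenset[int] = frozenset()


def init_weights(
    arch: ArchitectureSpec, seed: int, input_gain: float = 1.0
) -> WeightSet:
    """Variance-scaled uniform initialization (limit sqrt(6/fan_in)); zero biases.

    ``input_gain`` rescales the first layer's initialization.  With batch
    normalization the network function is nearly invariant to that scale,
    but a small gain lets the gradient-driven component of the input layer
    dominate its random initialization much earlier in training — which is
    what makes input-gradient attribution reflect learned structure rather
    than the random projection it started from.
    """
    rng = np.random.default_rng(seed)
    layers = []
    for i, (fan_in, fan_out, _act, bn) in enumerate(arch.weight_layer_dims()):
        limit = np.sqrt(6.0 / fan_in) * (input_gain if i == 0 else 1.0)
        W = rng.uniform(-limit, limit, size=(fan_out, fan_in))
        b = np.zeros(fan_out)
        if bn:
            layers.append(
                Layer(W, b, np.ones(fan_out), np.zeros(fan_out),
                      np.zeros(fan_out), np.ones(fan_out))
            )
        else:
            layers.append(Layer(W, b))
    return WeightSet(layers, "random", seed)


def transfer_weights(
    src: WeightSet, dst_arch: ArchitectureSpec, tmap: TransferMap, seed: int
) -> WeightSet:
    """Copy mapped layers from ``src``; initialize the rest from ``seed``."""
    dst = init_weights(dst_arch, seed)
    for si, di in tmap.pairs:
        if si >= len(src.layers) or di >= len(dst.layers):
            raise ValueError(f"transfer pair ({si}->{di}) out of range")
        s, d = src.layers[si], dst.layers[di]
        if s.W.shape != d.W.shape:
            raise ValueError(
                f"shape mismatch transferring source layer {si} {s.W.shape} "
                f"to destination layer {di} {d.W.shape}"
            )
        dst.layers[di] = s.copy()
        if d.has_bn and not s.has_bn:
            dst.layers[di].gamma = d.gamma
            dst.layers[di].beta = d.beta
            dst.layers[di].running_mean = d.running_mean
            dst.layers[di].running_var = d.running_var
    dst.provenance = f"transfer({src.provenance})"
    return dst


def _affine(layer: Layer, A: np.ndarray) -> np.ndarray:
    return A @ layer.W.T + layer.b


def _bn_forward(
    layer: Layer, Z: np.ndarray, mode: str, cache: dict,
    momentum: float = BN_MOMENTUM,
) -> np.ndarray:
    if mode == "train":
        mu = Z.mean(axis=0)
        var = Z.var(axis=0)
        inv = 1.0 / np.sqrt(var + BN_EPS)
        Zh = (Z - mu) * inv
        layer.running_mean = momentum * layer.running_mean + (1 - momentum) * mu
        layer.running_var = momentum * layer.running_var + (1 - momentum) * var
        cache.update(bn_mode="train", Zh=Zh, inv=inv)
    else:
        inv = 1.0 / np.sqrt(layer.running_var + BN_EPS)
        Zh = (Z - layer.running_mean) * inv
        cache.update(bn_mode="eval", Zh=Zh, inv=inv)
    return layer.gamma * Zh + layer.beta


def _bn_backward(layer: Layer, dOut: np.ndarray, cache: dict) -> np.ndarray:
    Zh, inv = cache["Zh"], cache["inv"]
    cache["dgamma"] = (dOut * Zh).sum(axis=0)
    cache["dbeta"] = dOut.sum(axis=0)
    dZh = dOut * layer.gamma
    if cache["bn_mode"] == "eval":
        return dZh * inv
    m = dOut.shape[0]
    return (inv / m) * (
        m * dZh - dZh.sum(axis=0) - Zh * (dZh * Zh).sum(axis=0)
    )


def _activate(act: str, Z: np.ndarray) -> np.ndarray:
    if act == "relu":
        return np.maximum(Z, 0.0)
    if act == "sigmoid":
        return 1.0 / (1.0 + np.exp(-Z))
    if act == "linear":
        return Z
    raise ValueError(act)


def _activate_backward(act: str, dA: np.ndarray, Z: np.ndarray, A: np.ndarray):
    if act == "relu":
        return dA * (Z > 0)
    if act == "sigmoid":
        return dA * A * (1.0 - A)
    if act == "linear":
        return dA
    raise ValueError(act)


def _softmax2(Z: np.ndarray) -> np.ndarray:
    Zs = Z - Z.max(axis=1, keepdims=True)
    e = np.exp(Zs)
    return e / e.sum(axis=1, keepdims=True)


def forward(
    w: WeightSet,
    arch: ArchitectureSpec,
    x: np.ndarray,
    clinical: np.ndarray | None = None,
    mode: str = "eval",
    return_cache: bool = False,
    bn_momentum: float = BN_MOMENTUM,
):
    """Run the network on a batch (or single vector).

    Classifier stages return the positive-class probability per task, shape
    (m, task_count); the autoencoder returns the reconstruction.  With
    ``return_cache`` the per-layer caches needed for backpropagation are
    returned as well.
    """
    X = np.atleast_2d(np.asarray(x, dtype=float))
    if X.shape[1] != arch.input_size:
        raise ValueError(
            f"input width {X.shape[1]} != architecture input {arch.input_size}"
        )
    if arch.clinical_width > 0:
        if clinical is None:
            raise ValueError("architecture expects a clinical block")
        clinical = np.atleast_2d(np.asarray(clinical, dtype=float))
        if clinical.shape[1] != arch.clinical_width:
            raise ValueError(
                f"clinical width {clinical.shape[1]} != {arch.clinical_width}"
            )
    elif clinical is not None:
        raise ValueError("architecture takes no clinical block")

    dims = arch.weight_layer_dims()
    n_trunk = arch.n_trunk_layers
    caches: list[dict] = []
    A = X
    for i in range(n_trunk):
        layer = w.layers[i]
        cache: dict = {"A_in": A}
        Z = _affine(layer, A)
        Zb = (
            _bn_forward(layer, Z, mode, cache, bn_momentum)
            if layer.has_bn
            else Z
        )
        act = dims[i][2]
        A_out = _activate(act, Zb)
        cache.update(Z=Z, Zb=Zb, A_out=A_out, act=act)
        if arch.fusion_layer is not None and i == arch.fusion_layer:
            cache["fused"] = True
            cache["pre_fusion_width"] = A_out.shape[1]
            A_out = np.concatenate([A_out, clinical], axis=1)
        A = A_out
        caches.append(cache)

    if arch.is_autoencoder:
        out = A
        squeeze = np.asarray(x).ndim == 1
        result = out[0] if squeeze else out
        return (result, caches) if return_cache else result

    probs = np.empty((X.shape[0], arch.task_count))
    head_caches = []
    for c in range(arch.task_count):
        layer = w.layers[n_trunk + c]
        Z = _affine(layer, A)
        P = _softmax2(Z)
        if not np.all(np.abs(P.sum(axis=1) - 1.0) < 1e-9):
            raise FloatingPointError("softmax outputs do not normalize")
        probs[:, c] = P[:, 1]
        head_caches.append({"A_in": A, "P": P})
    caches.append({"heads": head_caches})
    squeeze = np.asarray(x).ndim == 1
    result = probs[0] if squeeze else probs
    return (result, caches) if return_cache else result


def backward(
    w: WeightSet,
    arch: ArchitectureSpec,
    caches: list[dict],
    dZ_heads: list[np.ndarray] | None = None,
    dZ_out: np.ndarray | None = None,
):
    """Backpropagate from head-logit (or output pre-activation) gradients.

    Returns (grads, dX, dClinical) where ``grads`` is a list aligned with
    ``w.layers`` of dicts holding dW, db and, for batch-norm layers, dgamma
    and dbeta.
    """
    n_trunk = arch.n_trunk_layers
    grads: list[dict] = [None] * len(w.layers)  # type: ignore[list-item]

    if arch.is_autoencoder:
        if dZ_out is None:
            raise ValueError("autoencoder backward needs dZ_out")
        dA = None
        dZ = dZ_out  # gradient w.r.t. the output layer's pre-activation
        start = n_trunk - 1
    else:
        if dZ_heads is None:
            raise ValueError("classifier backward needs dZ_heads")
        head_caches = caches[-1]["heads"]
        A_shared = head_caches[0]["A_in"]
        dA = np.zeros_like(A_shared)
        for c, dZc in enumerate(dZ_heads):
            layer = w.layers[n_trunk + c]
            grads[n_trunk + c] = {
                "dW": dZc.T @ head_caches[c]["A_in"],
                "db": dZc.sum(axis=0),
            }
            dA = dA + dZc @ layer.W
        dZ = None
        start = n_trunk - 1

    dClin = None
    for i in range(start, -1, -1):
        layer = w.layers[i]
        cache = caches[i]
        if cache.get("fused"):
            k = cache["pre_fusion_width"]
            dClin = dA[:, k:]
            dA = dA[:, :k]
        if dZ is None:
            dZb = _activate_backward(cache["act"], dA, cache["Zb"], cache["A_out"])
            dZ = _bn_backward(layer, dZb, cache) if layer.has_bn else dZb
        g = {"dW": dZ.T @ cache["A_in"], "db": dZ.sum(axis=0)}
        if layer.has_bn:
            g["dgamma"] = cache["dgamma"]
            g["dbeta"] = cache["dbeta"]
        grads[i] = g
        dA = dZ @ layer.W
        dZ = None
    return grads, dA, dClin


def forward_backward_input(
    w: WeightSet,
    arch: ArchitectureSpec,
    x: np.ndarray,
    clinical: np.ndarray | None,
    task: int,
):
    """Probability p of task ``task`` and its gradient w.r.t. every input.

    Evaluation-mode batch normalization (running statistics) is used so the
    gradient is deterministic and sample-independent.  Returns
    (p, dX, dClinical) with dX shaped like the input batch.
    """
    X = np.atleast_2d(np.asarray(x, dtype=float))
    probs, caches = forward(w, arch, X, clinical, mode="eval", return_cache=True)
    n_trunk = arch.n_trunk_layers
    p = np.atleast_2d(probs)[:, task]
    # d p1 / d logits of a 2-unit softmax: p1 (1 - p1) * [-1, +1]
    seed = (p * (1.0 - p))[:, None] * np.array([-1.0, 1.0])
    dZ_heads = [
        seed if c == task else np.zeros((X.shape[0], 2))
        for c in range(arch.task_count)
    ]
    _grads, dX, dClin = backward(w, arch, caches, dZ_heads=dZ_heads)
    return p, dX, dClin


def calibrate_bn(
    w: WeightSet,
    arch: ArchitectureSpec,
    x: np.ndarray,
    clinical: np.ndarray | None = None,
) -> None:
    """Set every batch-norm layer's running statistics from one data pass.

    In train mode each layer normalizes by the current batch statistics, so a
    single full-batch pass with momentum 0 lands the running statistics
    exactly on the data's statistics.  Used before fine-tuning with frozen
    batch-norm, which also adapts transferred statistics to the new domain.
    """
    forward(w, arch, x, clinical, mode="train", bn_momentum=0.0)


def default_architectures(
    n_input: int,
    widths: tuple[int, int, int, int] = (1024, 256, 64, 32),
    task_count: int = 3,
    clinical_width: int = 0,
    head_hidden_per_task: int = 16,
    batch_norm: bool = True,
) -> dict:
    """Build the three stage specs plus the default transfer maps.

    Layer widths are configuration choices of this package (the original
    figure-only node counts are not machine-readable); ``widths`` gives the
    four encoder widths, the last being the autoencoder bottleneck.
    """
    w1, w2, w3, w4 = widths
    shared = head_hidden_per_task * task_count
    stage1 = ArchitectureSpec(
        "stage1",
        [n_input, w1, w2, w3, 2],
        ["relu", "relu", "relu"],
        [batch_norm] * 3,
        task_count=1,
    )
    stage2 = ArchitectureSpec(
        "stage2",
        [n_input, w1, w2, w3, w4, w3, w2, w1, n_input],
        ["relu"] * 7 + ["sigmoid"],
        [batch_norm] * 7 + [False],
    )
    stage3 = ArchitectureSpec(
        "stage3",
        [n_input, w1, w2, w3, w4, shared, 2],
        ["relu"] * 5,
        [batch_norm] * 5,
        task_count=task_count,
        clinical_width=clinical_width,
        fusion_layer=3 if clinical_width > 0 else None,
    )
    return {
        "stage1": stage1,
        "stage2": stage2,
        "stage3": stage3,
        # source hidden layers seed the encoder; encoder + bottleneck seed the trunk
        "map_s1_to_s2": TransferMap([(0, 0), (1, 1), (2, 2)]),
        "map_s2_to_s3": TransferMap([(0, 0), (1, 1), (2, 2), (3, 3)]),
        "map_s1_to_s3": TransferMap([(0, 0), (1, 1), (2, 2)]),
    }
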