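"""End-to-end multiview network: per-view encoders, fusion, prototype head.

The architecture follows the hidden-layer widths of an
:class:`~mvconn.encoder.EncoderSpec` of depth P with a fusion *position*
p in 1..P:

* layers 1..p-1 are per-view affine + tanh stacks (independent parameters
  per view);
* layer p either **fuses** — per-view linear maps u_v into a common K-width
  space summed into z = sum_v u_v, no activation — or **concatenates** the
  per-view features followed by an ordinary affine + tanh layer (the
  ablation baseline);
* layers p+1..P are shared affine + tanh layers operating on the fused
  features.

The network output g(x) feeds the prototype head.  The training objective is

    L = L_DCE + lambda1 * L_MP - lambda2 * L_MV

(distance-based cross entropy, margin prototype hinge, and the NCC view
alignment term, which exists only in fuse mode).  All gradients are written
out by hand in NumPy and are validated against central finite differences in
the test suite.  Prototypes are recomputed from the full training set at the
start of every epoch and treated as constants within it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .encoder import EncoderSpec, EncoderState, pretrain_layerwise
from .fusion import ncc_batch, ncc_batch_grad
from .optim import Adam
from .prototypes import (PROB_CLAMP, LossConfig, PrototypeSet, class_prob,
                         distances, init_prototypes)

__all__ = ["FusionSpec", "TrainConfig", "MultiViewNet", "TrainedModel",
           "total_loss", "train", "predict"]


@dataclass(frozen=True)
class FusionSpec:
    """Where and how the views are merged."""

    mode: str = "fuse"          # fuse | concat
    position: int = 3           # hidden-layer index (1-based) of the merge
    K: int = 100                # fused width (fuse mode only)
    pairing: str = "consecutive"

    def __post_init__(self):
        if self.mode not in ("fuse", "concat"):
            raise ValueError(f"unknown fusion mode {self.mode!r}")
        if self.position < 1:
            raise ValueError("fusion position must be >= 1")
        if self.K < 1:
            raise ValueError("K must be >= 1")


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings (defaults: Adam, batch 96, learning rate 1e-4)."""

    batch_size: int = 96
    learning_rate: float = 1e-4
    epochs: int = 300
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be nonnegative")


def _tanh_backward(delta, A):
    return delta * (1.0 - A * A)


class MultiViewNet:
    """Parameter container + forward/backward passes for the full model."""

    def __init__(self, view_widths: list[int], spec: EncoderSpec,
                 fusion: FusionSpec, seed: int = 0,
                 pretrained: list[EncoderState] | None = None):
        if fusion.position > spec.depth:
            raise ValueError(
                f"fusion position {fusion.position} exceeds encoder depth {spec.depth}"
            )
        if spec.activation != "tanh":
            raise ValueError("MultiViewNet currently supports tanh encoders")
        self.view_widths = list(view_widths)
        self.spec = spec
        self.fusion = fusion
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}

        widths = spec.layer_widths
        p = fusion.position
        # per-view stacks: layers 1..p-1
        per_view_out = []
        for v, w_in in enumerate(self.view_widths):
            n_in = w_in
            for l in range(p - 1):
                bound = 1.0 / np.sqrt(n_in)
                self.params[f"enc{v}_W{l}"] = rng.uniform(
                    -bound, bound, size=(n_in, widths[l]))
                self.params[f"enc{v}_b{l}"] = np.zeros(widths[l])
                n_in = widths[l]
            per_view_out.append(n_in)
        # merge layer
        if fusion.mode == "fuse":
            for v, n_in in enumerate(per_view_out):
                bound = 1.0 / np.sqrt(n_in)
                self.params[f"fus{v}_W"] = rng.uniform(
                    -bound, bound, size=(n_in, fusion.K))
            merged = fusion.K
        else:
            n_in = int(sum(per_view_out))
            bound = 1.0 / np.sqrt(n_in)
            self.params["cat_W"] = rng.uniform(
                -bound, bound, size=(n_in, widths[p - 1]))
            self.params["cat_b"] = np.zeros(widths[p - 1])
            merged = widths[p - 1]
        # shared stack: layers p+1..depth
        n_in = merged
        for l in range(p, spec.depth):
            bound = 1.0 / np.sqrt(n_in)
            self.params[f"shr_W{l}"] = rng.uniform(
                -bound, bound, size=(n_in, widths[l]))
            self.params[f"shr_b{l}"] = np.zeros(widths[l])
            n_in = widths[l]
        self.out_width = n_in

        if pretrained is not None:
            self.load_pretrained(pretrained)

    @property
    def n_views(self) -> int:
        return len(self.view_widths)

    def load_pretrained(self, states: list[EncoderState]) -> None:
        """Copy the first position-1 pretrained layers of each view's encoder."""
        if len(states) != self.n_views:
            raise ValueError("one pretrained encoder per view required")
        for v, st in enumerate(states):
            for l in range(self.fusion.position - 1):
                if st.weights[l].shape != self.params[f"enc{v}_W{l}"].shape:
                    raise ValueError(
                        f"view {v} layer {l}: pretrained shape "
                        f"{st.weights[l].shape} does not match network")
                self.params[f"enc{v}_W{l}"] = st.weights[l].copy()
                self.params[f"enc{v}_b{l}"] = st.biases[l].copy()

    # ---------------------------------------------------------------- forward

    def forward(self, X_views: list[np.ndarray], return_cache: bool = False):
        """Output features g(x); optionally the activation cache for backprop."""
        if len(X_views) != self.n_views:
            raise ValueError(f"expected {self.n_views} views, got {len(X_views)}")
        p = self.fusion.position
        acts = []
        for v, X in enumerate(X_views):
            X = np.asarray(X, dtype=float)
            if X.shape[1] != self.view_widths[v]:
                raise ValueError(
                    f"view {v}: width {X.shape[1]} != expected {self.view_widths[v]}")
            A = [X]
            for l in range(p - 1):
                A.append(np.tanh(A[-1] @ self.params[f"enc{v}_W{l}"]
                                 + self.params[f"enc{v}_b{l}"]))
            acts.append(A)

        u_per_view = None
        if self.fusion.mode == "fuse":
            u_per_view = [acts[v][-1] @ self.params[f"fus{v}_W"]
                          for v in range(self.n_views)]
            merged = u_per_view[0].copy()
            for u in u_per_view[1:]:
                merged += u
            merged_pre = None
        else:
            h = np.hstack([A[-1] for A in acts])
            merged_pre = h
            merged = np.tanh(h @ self.params["cat_W"] + self.params["cat_b"])

        shared = [merged]
        for l in range(p, self.spec.depth):
            shared.append(np.tanh(shared[-1] @ self.params[f"shr_W{l}"]
                                  + self.params[f"shr_b{l}"]))
        g = shared[-1]
        if not return_cache:
            return g
        return g, {"acts": acts, "u": u_per_view, "merged_pre": merged_pre,
                   "shared": shared}

    # --------------------------------------------------------------- backward

    def backward(self, cache, dG: np.ndarray,
                 du_extra: list[np.ndarray] | None = None) -> dict[str, np.ndarray]:
        """Backpropagate dL/dg (plus any direct dL/du_v term) to all parameters."""
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        p = self.fusion.position
        shared = cache["shared"]
        delta = dG
        for l in range(self.spec.depth - 1, p - 1, -1):
            A = shared[l - p + 1]
            dz = _tanh_backward(delta, A)
            grads[f"shr_W{l}"] += shared[l - p].T @ dz
            grads[f"shr_b{l}"] += dz.sum(axis=0)
            delta = dz @ self.params[f"shr_W{l}"].T

        acts = cache["acts"]
        if self.fusion.mode == "fuse":
            d_h_per_view = []
            for v in range(self.n_views):
                du = delta.copy()
                if du_extra is not None:
                    du += du_extra[v]
                grads[f"fus{v}_W"] += acts[v][-1].T @ du
                d_h_per_view.append(du @ self.params[f"fus{v}_W"].T)
        else:
            A = shared[0]
            dz = _tanh_backward(delta, A)
            grads["cat_W"] += cache["merged_pre"].T @ dz
            grads["cat_b"] += dz.sum(axis=0)
            dh = dz @ self.params["cat_W"].T
            d_h_per_view = []
            start = 0
            for v in range(self.n_views):
                w = acts[v][-1].shape[1]
                d_h_per_view.append(dh[:, start:start + w])
                start += w

        for v in range(self.n_views):
            delta = d_h_per_view[v]
            for l in range(p - 2, -1, -1):
                A = acts[v][l + 1]
                dz = _tanh_backward(delta, A)
                grads[f"enc{v}_W{l}"] += acts[v][l].T @ dz
                grads[f"enc{v}_b{l}"] += dz.sum(axis=0)
                delta = dz @ self.params[f"enc{v}_W{l}"].T
        return grads

    def clone_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = params[k].copy()


def total_loss(net: MultiViewNet, X_views: list[np.ndarray], y: np.ndarray,
               proto: PrototypeSet, cfg: LossConfig,
               want_grads: bool = True):
    """Full objective L = L_DCE + lambda1 L_MP - lambda2 L_MV on one batch.

    Returns ``(loss, components, grads)``; ``grads`` is None when
    ``want_grads`` is False.  Prototypes are constants (no gradient flows
    into them).  Raises ``FloatingPointError`` with a component breakdown if
    the loss is non-finite.
    """
    g, cache = net.forward(X_views, return_cache=True)
    B = g.shape[0]
    P = proto.prototypes
    idx = proto.class_index(np.asarray(y))
    d = distances(g, P)
    prob = class_prob(d, cfg.gamma)
    rows = np.arange(B)
    p_true = np.maximum(prob[rows, idx], PROB_CLAMP)
    l_dce = float(np.mean(-np.log(p_true)))

    d_true = d[rows, idx]
    d_masked = d.copy()
    d_masked[rows, idx] = np.inf
    rival = np.argmin(d_masked, axis=1)
    d_rival = d_masked[rows, rival]
    hinge = d_true - d_rival + cfg.margin
    active = hinge > 0
    l_mp = float(np.mean(np.maximum(hinge, 0.0)))

    u = cache["u"]
    l_mv = 0.0
    if u is not None and net.n_views >= 2:
        if net.fusion.pairing == "all_pairs":
            pairs = [(i, j) for i in range(net.n_views)
                     for j in range(i + 1, net.n_views)]
        else:
            pairs = [(v, v + 1) for v in range(net.n_views - 1)]
        for i, j in pairs:
            l_mv += float(np.mean(ncc_batch(u[i], u[j])))
    loss = l_dce + cfg.lambda1 * l_mp - cfg.lambda2 * l_mv
    components = {"dce": l_dce, "mp": l_mp, "mv": l_mv}
    if not np.isfinite(loss):
        raise FloatingPointError(f"non-finite training loss: {components}")
    if not want_grads:
        return loss, components, None

    # dL/dd: DCE softmax term, d(-log p_y)/dd_c = gamma (1{c=y} - p_c) ...
    dd = -cfg.gamma * prob / B
    dd[rows, idx] += cfg.gamma / B
    # ... plus the active hinge terms
    if cfg.lambda1 > 0 and active.any():
        act_rows = rows[active]
        dd[act_rows, idx[active]] += cfg.lambda1 / B
        dd[act_rows, rival[active]] -= cfg.lambda1 / B
    # dd -> dG through d_c = ||g - p_c||^2
    dG = 2.0 * (dd.sum(axis=1, keepdims=True) * g - dd @ P)

    du_extra = None
    if u is not None and net.n_views >= 2 and cfg.lambda2 > 0:
        du_extra = [np.zeros_like(ui) for ui in u]
        for i, j in pairs:
            _, g1, g2 = ncc_batch_grad(u[i], u[j])
            du_extra[i] += -cfg.lambda2 * g1 / B
            du_extra[j] += -cfg.lambda2 * g2 / B

    grads = net.backward(cache, dG, du_extra)
    return loss, components, grads


@dataclass
class TrainedModel:
    """Trained network, its prototypes, and the per-epoch history."""

    net: MultiViewNet
    prototypes: PrototypeSet
    history: dict[str, list[float]] = field(default_factory=dict)
    best_epoch: int = -1


def _accuracy(net: MultiViewNet, proto: PrototypeSet,
              X_views: list[np.ndarray], y: np.ndarray) -> float:
    labels, _ = predict_with(net, proto, X_views)
    return float(np.mean(labels == np.asarray(y)))


def predict_with(net: MultiViewNet, proto: PrototypeSet,
                 X_views: list[np.ndarray]):
    """Nearest-prototype labels and class probabilities.

    Ties in the distance argmin break toward the lower class index.
    """
    g = net.forward(X_views)
    d = distances(g, proto.prototypes)
    prob = class_prob(d, proto.gamma)
    labels = proto.classes[np.argmin(d, axis=1)]
    return labels, prob


def predict(model: TrainedModel, X_views: list[np.ndarray]):
    return predict_with(model.net, model.prototypes, X_views)


def train(net: MultiViewNet, X_views: list[np.ndarray], y: np.ndarray,
          loss_cfg: LossConfig, train_cfg: TrainConfig,
          val_views: list[np.ndarray] | None = None,
          val_y: np.ndarray | None = None) -> TrainedModel:
    """Adam training with per-epoch prototype refresh and best-val checkpointing.

    Prototypes are recomputed from the full training set at the start of
    every epoch (class means of the current network outputs) and held fixed
    within the epoch.  When a validation split is supplied, the parameters
    and prototypes of the best-validation-accuracy epoch are restored at the
    end; otherwise the final epoch's state is kept.  Everything is
    deterministic given ``train_cfg.seed``.
    """
    y = np.asarray(y)
    N = y.shape[0]
    rng = np.random.default_rng(train_cfg.seed)
    opt = Adam(net.params, lr=train_cfg.learning_rate)
    history: dict[str, list[float]] = {
        "train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []}
    proto = init_prototypes(net.forward(X_views), y, gamma=loss_cfg.gamma)
    best = {"acc": -1.0, "epoch": -1, "params": net.clone_params(),
            "proto": proto}

    for epoch in range(train_cfg.epochs):
        proto = init_prototypes(net.forward(X_views), y, gamma=loss_cfg.gamma)
        order = rng.permutation(N)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, N, train_cfg.batch_size):
            sel = order[start:start + train_cfg.batch_size]
            if sel.size < 2:
                continue  # NCC and class stats need >= 2 samples
            batch = [X[sel] for X in X_views]
            try:
                loss, _, grads = total_loss(net, batch, y[sel], proto, loss_cfg)
            except FloatingPointError as exc:
                raise FloatingPointError(f"epoch {epoch}: {exc}") from None
            opt.step(grads)
            epoch_loss += loss
            n_batches += 1
        proto = init_prototypes(net.forward(X_views), y, gamma=loss_cfg.gamma)
        history["train_loss"].append(epoch_loss / max(n_batches, 1))
        history["train_acc"].append(_accuracy(net, proto, X_views, y))
        if val_views is not None and val_y is not None:
            vloss, _, _ = total_loss(net, val_views, val_y, proto, loss_cfg,
                                     want_grads=False)
            vacc = _accuracy(net, proto, val_views, val_y)
            history["val_loss"].append(vloss)
            history["val_acc"].append(vacc)
            if vacc > best["acc"]:
                best = {"acc": vacc, "epoch": epoch,
                        "params": net.clone_params(), "proto": proto}

    if val_views is not None and val_y is not None and best["epoch"] >= 0:
        net.set_params(best["params"])
        proto = best["proto"]
        best_epoch = best["epoch"]
    else:
        best_epoch = train_cfg.epochs - 1
    return TrainedModel(net=net, prototypes=proto, history=history,
                        best_epoch=best_epoch)


def build_network(view_widths: list[int], spec: EncoderSpec,
                  fusion: FusionSpec, X_views: list[np.ndarray] | None = None,
                  seed: int = 0) -> MultiViewNet:
    """Construct a network, optionally layer-wise pretraining each view's stack."""
    pretrained = None
    if spec.pretrain and X_views is not None and fusion.position > 1:
        sub = EncoderSpec(spec.layer_widths[:fusion.position - 1],
                          spec.activation, spec.pretrain,
                          spec.pretrain_epochs, spec.pretrain_lr)
        pretrained = []
        for v, X in enumerate(X_views):
            state, _ = pretrain_layerwise(np.asarray(X, float), sub,
                                          seed=seed + 1000 + v,
                                          view_id=str(v))
            pretrained.append(state)
    return MultiViewNet(view_widths, spec, fusion, seed=seed,
                        pretrained=pretrained)
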