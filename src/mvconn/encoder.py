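"""Per-view stacked-autoencoder feature extraction.

Each view's selected connectivity features pass through a stack of affine +
tanh hidden layers.  The stack can be pretrained greedily: every layer is
first trained as a one-hidden-layer autoencoder reconstructing its own input
under mean-squared error, then the whole network is fine-tuned end to end by
the supervised objective (see :mod:`mvconn.network`).  Default hidden widths
are 1000 for the first layer and 100 for deeper layers; tiny specs such as
[8, 4] are first-class so full pipelines run in seconds during testing.

All arithmetic is plain NumPy; parameter initialisation is fan-in-scaled
uniform and fully determined by the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .optim import Adam

__all__ = ["EncoderSpec", "EncoderState", "init_encoder", "pretrain_layerwise",
           "encode", "save_state", "load_state"]

DEFAULT_WIDTHS = (1000, 100, 100)

_ACTIVATIONS = {
    "tanh": (np.tanh, lambda a: 1.0 - a * a),           # derivative in terms of output
    "identity": (lambda x: x, lambda a: np.ones_like(a)),
}


@dataclass(frozen=True)
class EncoderSpec:
    """Architecture + pretraining configuration of one view's encoder."""

    layer_widths: tuple[int, ...] = DEFAULT_WIDTHS
    activation: str = "tanh"
    pretrain: bool = True
    pretrain_epochs: int = 50
    pretrain_lr: float = 1e-3

    def __post_init__(self):
        object.__setattr__(self, "layer_widths", tuple(int(w) for w in self.layer_widths))
        if len(self.layer_widths) < 1:
            raise ValueError("need at least one hidden layer")
        if any(w <= 0 for w in self.layer_widths):
            raise ValueError("layer widths must be positive")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")

    @property
    def depth(self) -> int:
        return len(self.layer_widths)


@dataclass
class EncoderState:
    """Per-layer affine parameters of one view's encoder."""

    weights: list[np.ndarray]   # layer l: (in_l, out_l)
    biases: list[np.ndarray]    # layer l: (out_l,)
    activation: str = "tanh"
    rng_seed: int = 0
    view_id: str = ""

    def __post_init__(self):
        for l in range(1, len(self.weights)):
            if self.weights[l].shape[0] != self.weights[l - 1].shape[1]:
                raise ValueError(f"layer {l} input width does not match layer {l-1} output")

    @property
    def depth(self) -> int:
        return len(self.weights)

    @property
    def widths(self) -> tuple[int, ...]:
        return tuple(w.shape[1] for w in self.weights)


def _init_affine(rng: np.random.Generator, n_in: int, n_out: int) -> tuple[np.ndarray, np.ndarray]:
    bound = 1.0 / np.sqrt(n_in)
    return rng.uniform(-bound, bound, size=(n_in, n_out)), np.zeros(n_out)


def init_encoder(input_dim: int, spec: EncoderSpec, seed: int = 0,
                 view_id: str = "") -> EncoderState:
    """Seeded fan-in-scaled uniform initialisation of the full stack."""
    if input_dim < 1:
        raise ValueError("input dimension must be >= 1")
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    n_in = input_dim
    for width in spec.layer_widths:
        W, b = _init_affine(rng, n_in, width)
        weights.append(W)
        biases.append(b)
        n_in = width
    return EncoderState(weights, biases, spec.activation, seed, view_id)


def encode(state: EncoderState, X: np.ndarray, upto_layer: int | None = None) -> np.ndarray:
    """Forward pass through the first ``upto_layer`` hidden layers."""
    depth = upto_layer if upto_layer is not None else state.depth
    if not 0 <= depth <= state.depth:
        raise ValueError(f"upto_layer {depth} outside 0..{state.depth}")
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (batch x features)")
    if X.shape[1] != state.weights[0].shape[0]:
        raise ValueError(
            f"input width {X.shape[1]} does not match encoder input "
            f"{state.weights[0].shape[0]}"
        )
    act, _ = _ACTIVATIONS[state.activation]
    h = X
    for l in range(depth):
        h = act(h @ state.weights[l] + state.biases[l])
    return h


def _pretrain_one_layer(H: np.ndarray, W: np.ndarray, b: np.ndarray,
                        activation: str, epochs: int, lr: float,
                        rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Train encoder (W, b) + throwaway linear decoder to reconstruct H."""
    act, dact = _ACTIVATIONS[activation]
    n_hidden = W.shape[1]
    Wd, bd = _init_affine(rng, n_hidden, H.shape[1])
    params = {"W": W, "b": b, "Wd": Wd, "bd": bd}
    opt = Adam(params, lr=lr)
    n = H.shape[0]
    trace = []
    for _ in range(epochs):
        A = act(H @ params["W"] + params["b"])
        R = A @ params["Wd"] + params["bd"]
        err = R - H
        loss = float(np.mean(err * err))
        trace.append(loss)
        if not np.isfinite(loss):
            raise FloatingPointError("pretraining reconstruction loss diverged")
        dR = 2.0 * err / err.size
        gWd = A.T @ dR
        gbd = dR.sum(axis=0)
        dA = dR @ params["Wd"].T
        dZ = dA * dact(A)
        gW = H.T @ dZ
        gb = dZ.sum(axis=0)
        opt.step({"W": gW, "b": gb, "Wd": gWd, "bd": gbd})
    # closing loss after the last update, so the trace ends where training did
    A = act(H @ params["W"] + params["b"])
    R = A @ params["Wd"] + params["bd"]
    trace.append(float(np.mean((R - H) ** 2)))
    return params["W"], params["b"], trace


def pretrain_layerwise(X_view: np.ndarray, spec: EncoderSpec, seed: int = 0,
                       view_id: str = "") -> tuple[EncoderState, list[list[float]]]:
    """Greedy layer-wise autoencoder pretraining.

    Layer l is trained (full batch, Adam) to reconstruct its own input —
    the activations of layer l-1 — under mean-squared error.  With
    ``spec.pretrain`` off the seeded random initialisation is returned
    untouched.  Returns the state and the per-layer reconstruction-loss
    traces (empty when pretraining is off).

    Raises
    ------
    FloatingPointError
        If a layer's reconstruction loss becomes non-finite; the message
        names the layer.
    """
    X_view = np.asarray(X_view, dtype=float)
    if X_view.size == 0:
        raise ValueError("empty training matrix")
    state = init_encoder(X_view.shape[1], spec, seed=seed, view_id=view_id)
    if not spec.pretrain:
        return state, []
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5AE]))
    act, _ = _ACTIVATIONS[spec.activation]
    H = X_view
    traces = []
    for l in range(state.depth):
        try:
            W, b, trace = _pretrain_one_layer(
                H, state.weights[l], state.biases[l], spec.activation,
                spec.pretrain_epochs, spec.pretrain_lr, rng,
            )
        except FloatingPointError as exc:
            raise FloatingPointError(f"layer {l}: {exc}") from None
        state.weights[l], state.biases[l] = W, b
        traces.append(trace)
        H = act(H @ W + b)
    return state, traces


def save_state(path, state: EncoderState) -> None:
    """Serialise an encoder stack to a single JSON archive (versioned)."""
    payload = {
        "format_version": 1,
        "activation": state.activation,
        "rng_seed": int(state.rng_seed),
        "view_id": state.view_id,
        "weights": [w.tolist() for w in state.weights],
        "biases": [b.tolist() for b in state.biases],
    }
    Path(path).write_text(json.dumps(payload))


def load_state(path) -> EncoderState:
    payload = json.loads(Path(path).read_text())
    if payload.get("format_version") != 1:
        raise ValueError("unsupported encoder archive version")
    return EncoderState(
        weights=[np.asarray(w, dtype=float) for w in payload["weights"]],
        biases=[np.asarray(b, dtype=float) for b in payload["biases"]],
        activation=payload["activation"],
        rng_seed=payload["rng_seed"],
        view_id=payload["view_id"],
    )
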