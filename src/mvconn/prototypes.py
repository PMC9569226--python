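"""Prototype-based classification head.

Each class c is represented by a single prototype p_c, the mean of the
network's output features over that class's training instances.  An instance
is scored by its squared Euclidean distance d_c to every prototype and
classified to the nearest one.  Training minimises a distance-based cross
entropy (softmax over -gamma * d_c) plus a hinge "margin prototype" term
that asks the true class to beat the nearest rival class by a margin m.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["PrototypeSet", "LossConfig", "init_prototypes", "distances",
           "class_prob", "dce_loss", "mp_loss", "PROB_CLAMP"]

PROB_CLAMP = 1e-12


@dataclass
class PrototypeSet:
    """One feature-space point per class, plus the distance scale gamma."""

    prototypes: np.ndarray   # (C, width)
    classes: np.ndarray      # class codes, sorted
    gamma: float = 1.0

    def __post_init__(self):
        self.prototypes = np.atleast_2d(np.asarray(self.prototypes, dtype=float))
        self.classes = np.asarray(self.classes)
        if self.prototypes.shape[0] != self.classes.size:
            raise ValueError("one prototype per class required")
        if self.classes.size < 2:
            raise ValueError("need at least 2 classes")
        if self.gamma < 0:
            raise ValueError("gamma must be nonnegative")

    @property
    def n_classes(self) -> int:
        return int(self.classes.size)

    def class_index(self, labels: np.ndarray) -> np.ndarray:
        """Map class codes to prototype row indices."""
        idx = np.searchsorted(self.classes, labels)
        if np.any(idx >= self.n_classes) or np.any(self.classes[idx] != labels):
            raise ValueError("label outside the declared class set")
        return idx


@dataclass(frozen=True)
class LossConfig:
    """Weights of the full training objective L = DCE + l1*MP - l2*MV."""

    gamma: float = 1.0
    margin: float = 1.0
    lambda1: float = 0.5
    lambda2: float = 0.1

    def __post_init__(self):
        if self.margin < 0 or self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("margin and loss weights must be nonnegative")
        if self.gamma < 0:
            raise ValueError("gamma must be nonnegative")


def init_prototypes(features: np.ndarray, labels: np.ndarray,
                    gamma: float = 1.0,
                    classes: np.ndarray | None = None) -> PrototypeSet:
    """Class-mean prototypes: p_c = mean of g(x_i) over class-c instances.

    ``classes`` fixes the class universe explicitly; a declared class with no
    training instance is an error (its mean is undefined).
    """
    features = np.atleast_2d(np.asarray(features, dtype=float))
    labels = np.asarray(labels)
    classes = np.unique(labels) if classes is None else np.asarray(classes)
    protos = np.empty((classes.size, features.shape[1]))
    for k, c in enumerate(classes):
        mask = labels == c
        if not mask.any():
            raise ValueError(f"class {c!r} has no training instances")
        protos[k] = features[mask].mean(axis=0)
    return PrototypeSet(protos, classes, gamma)


def distances(gx: np.ndarray, prototypes: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances d_c = ||g(x) - p_c||^2, batch x C."""
    gx = np.atleast_2d(np.asarray(gx, dtype=float))
    prototypes = np.atleast_2d(np.asarray(prototypes, dtype=float))
    if gx.shape[1] != prototypes.shape[1]:
        raise ValueError("feature width mismatch between instances and prototypes")
    diff = gx[:, None, :] - prototypes[None, :, :]
    return np.einsum("bcw,bcw->bc", diff, diff)


def class_prob(d: np.ndarray, gamma: float) -> np.ndarray:
    """P(c|x) = exp(-gamma d_c) / sum_c' exp(-gamma d_c'), max-shifted.

    gamma = 0 degenerates to the uniform distribution 1/C.
    """
    d = np.atleast_2d(np.asarray(d, dtype=float))
    logits = -gamma * d
    logits = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    return e / e.sum(axis=1, keepdims=True)


def dce_loss(prob_true: np.ndarray) -> float:
    """Distance-based cross entropy: mean of -log P(y|x) over the batch.

    Probabilities at or below zero are clamped at 1e-12 (with a warning);
    they can only arise from float underflow at extreme distances.
    """
    prob_true = np.asarray(prob_true, dtype=float)
    if np.any(prob_true <= 0.0):
        warnings.warn("clamping non-positive class probability", stacklevel=2)
        prob_true = np.maximum(prob_true, PROB_CLAMP)
    return float(np.mean(-np.log(prob_true)))


def mp_loss(d_y: np.ndarray, d_r: np.ndarray, m: float) -> float:
    """Margin prototype loss: mean of max(0, d_y - d_r + m).

    d_y is the distance to the true-class prototype and d_r the minimum
    distance over the other classes' prototypes; the hinge is inactive when
    the true class wins by at least the margin m.
    """
    return float(np.mean(np.maximum(0.0, np.asarray(d_y) - np.asarray(d_r) + m)))
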