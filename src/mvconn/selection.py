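"""Multiview feature selection by view-weighted L1 regression.

For each view in turn, that view is declared *primary* and all others
*auxiliary*, and the sparse linear model

    min_w  (1/2N) sum_i (y_i - w.x_i)^2  +  lam * (a1 ||w_1||_1 + a2 ||w_2||_1)

is solved over the concatenated feature layout, where w_1 holds the primary
view's coefficients and w_2 the auxiliary views' (a1 + a2 = 1, a1 < a2
punishes the primary view less so more of its features survive).  The solver
is plain ISTA: a fixed gradient step of size 1/L (L the Lipschitz constant
of the smooth part, i.e. the squared top singular value of X over N)
followed by the closed-form soft threshold with per-position threshold
lam * a_g / L.  Features with nonzero coefficients are the selected,
most discriminative connections of the primary view.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .connectome import MultiViewDataset, ViewFeatureMatrix

__all__ = [
    "ViewPartition",
    "SelectionModel",
    "SelectionResult",
    "objective_f",
    "objective_total",
    "grad_f",
    "lipschitz_estimate",
    "prox_step",
    "ista_solve",
    "select_support",
    "run_per_view_selection",
    "encode_labels",
    "standardize_columns",
]

#: coefficients with |w| above this count as "nonzero" (ISTA yields exact
#: zeros, so this only guards float noise)
ZERO_THRESHOLD = 1e-8
#: fallback support size when a primary view selects nothing
FALLBACK_TOP_K = 10


@dataclass(frozen=True)
class ViewPartition:
    """Primary/auxiliary split of the concatenated feature positions."""

    primary_view: int
    primary_indices: np.ndarray
    auxiliary_indices: np.ndarray
    total_dim: int

    @classmethod
    def from_widths(cls, widths: list[int], primary_view: int) -> "ViewPartition":
        if not 0 <= primary_view < len(widths):
            raise ValueError(f"primary_view {primary_view} out of range")
        offsets = np.cumsum([0] + list(widths))
        total = int(offsets[-1])
        lo, hi = offsets[primary_view], offsets[primary_view + 1]
        primary = np.arange(lo, hi)
        auxiliary = np.concatenate([np.arange(0, lo), np.arange(hi, total)])
        return cls(primary_view, primary, auxiliary, total)

    def weight_per_position(self, a1: float) -> np.ndarray:
        """Vector a_p: a1 on primary positions, a2 = 1 - a1 elsewhere."""
        a = np.full(self.total_dim, 1.0 - a1)
        a[self.primary_indices] = a1
        return a


@dataclass
class SelectionModel:
    """Fitted weight vector with the solver's bookkeeping."""

    omega: np.ndarray
    a1: float
    lam: float
    L: float
    iters_run: int
    objective_trace: np.ndarray
    converged: bool
    partition: ViewPartition

    @property
    def a2(self) -> float:
        return 1.0 - self.a1


@dataclass
class SelectionResult:
    """Per-view surviving feature positions plus the models that found them."""

    support_per_view: list[np.ndarray]
    models: list[SelectionModel] = field(default_factory=list)

    def jaccard(self, truth_per_view: list[np.ndarray]) -> float:
        """Mean Jaccard overlap between per-view supports and a ground truth."""
        scores = []
        for got, want in zip(self.support_per_view, truth_per_view):
            got, want = set(np.asarray(got).tolist()), set(np.asarray(want).tolist())
            union = got | want
            scores.append(len(got & want) / len(union) if union else 1.0)
        return float(np.mean(scores))


def objective_f(omega: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    """Smooth part: (1/2N) ||y - X w||^2."""
    omega, X, y = np.asarray(omega, float), np.asarray(X, float), np.asarray(y, float)
    if X.shape[1] != omega.shape[0] or X.shape[0] != y.shape[0]:
        raise ValueError(
            f"shape mismatch: X {X.shape}, omega {omega.shape}, y {y.shape}"
        )
    resid = y - X @ omega
    return float(resid @ resid) / (2 * X.shape[0])


def objective_total(
    omega: np.ndarray, X: np.ndarray, y: np.ndarray, a_per_pos: np.ndarray, lam: float
) -> float:
    """Full objective: smooth part plus lam * sum_p a_p |w_p|."""
    return objective_f(omega, X, y) + lam * float(a_per_pos @ np.abs(omega))


def grad_f(omega: np.ndarray, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Gradient of the smooth part: (1/N) X^T (X w - y)."""
    omega, X, y = np.asarray(omega, float), np.asarray(X, float), np.asarray(y, float)
    if X.shape[1] != omega.shape[0] or X.shape[0] != y.shape[0]:
        raise ValueError(
            f"shape mismatch: X {X.shape}, omega {omega.shape}, y {y.shape}"
        )
    return X.T @ (X @ omega - y) / X.shape[0]


def lipschitz_estimate(X: np.ndarray, tol: float = 1e-8, max_iter: int = 1000) -> float:
    """Lipschitz constant of grad_f: (top singular value of X)^2 / N.

    Power iteration on X^T X; any overestimate also yields monotone descent,
    so the tolerance only affects step-size tightness.
    """
    X = np.asarray(X, dtype=float)
    if not np.any(X):
        raise ValueError("all-zero design matrix has no Lipschitz scale")
    n, d = X.shape
    if min(n, d) == 1:
        return float(np.sum(X * X)) / n
    rng = np.random.default_rng(0)
    v = rng.standard_normal(d)
    v /= np.linalg.norm(v)
    lam_old = 0.0
    for _ in range(max_iter):
        w = X.T @ (X @ v)
        lam = float(np.linalg.norm(w))
        if lam == 0.0:
            break
        v = w / lam
        if abs(lam - lam_old) <= tol * max(lam, 1.0):
            break
        lam_old = lam
    return lam / n


def prox_step(xi: np.ndarray, a_per_pos: np.ndarray, lam: float, L: float) -> np.ndarray:
    """Soft threshold with per-position threshold theta_p = lam * a_p / L.

    Returns xi_p - theta_p where xi_p > theta_p, 0 where |xi_p| <= theta_p,
    and xi_p + theta_p where xi_p < -theta_p.
    """
    if L <= 0:
        raise ValueError("L must be positive")
    xi = np.asarray(xi, dtype=float)
    theta = lam * np.asarray(a_per_pos, dtype=float) / L
    return np.sign(xi) * np.maximum(np.abs(xi) - theta, 0.0)


def ista_solve(
    X: np.ndarray,
    y: np.ndarray,
    partition: ViewPartition,
    a1: float = 0.2,
    lam: float = 1.0,
    max_iter: int = 5000,
    tol: float = 1e-7,
    L: float | None = None,
) -> SelectionModel:
    """Proximal-gradient (ISTA) solve of the view-weighted lasso.

    Iterates xi = w_j - (1/L) grad_f(w_j); w_{j+1} = soft-threshold(xi),
    starting from w_0 = 0, stopping when max|w_{j+1} - w_j| < tol or after
    ``max_iter`` iterations.  The objective trace is recorded and is
    nonincreasing whenever L is a valid Lipschitz bound.
    """
    if not 0.0 <= a1 <= 1.0:
        raise ValueError("a1 must lie in [0, 1]")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    a_per_pos = partition.weight_per_position(a1)
    if L is None:
        L = lipschitz_estimate(X)
    omega = np.zeros(X.shape[1])
    trace = [objective_total(omega, X, y, a_per_pos, lam)]
    converged = False
    iters = 0
    for iters in range(1, max_iter + 1):
        xi = omega - grad_f(omega, X, y) / L
        new = prox_step(xi, a_per_pos, lam, L)
        if not np.all(np.isfinite(new)):
            raise FloatingPointError(
                f"ISTA diverged at iteration {iters}; L={L} is likely not a "
                "valid Lipschitz bound"
            )
        delta = float(np.max(np.abs(new - omega)))
        omega = new
        trace.append(objective_total(omega, X, y, a_per_pos, lam))
        if delta < tol:
            converged = True
            break
    return SelectionModel(
        omega=omega,
        a1=a1,
        lam=lam,
        L=L,
        iters_run=iters,
        objective_trace=np.asarray(trace),
        converged=converged,
        partition=partition,
    )


def select_support(
    model: SelectionModel,
    view_widths: list[int],
    zero_threshold: float = ZERO_THRESHOLD,
    fallback_top_k: int = FALLBACK_TOP_K,
) -> list[np.ndarray]:
    """Per-view positions (within each view) whose |w| exceeds the threshold.

    A primary view with an empty support falls back to its top-k |w|
    positions so downstream stages never receive a zero-width view; auxiliary
    views may legitimately end up empty.
    """
    offsets = np.cumsum([0] + list(view_widths))
    supports = []
    for v, (lo, hi) in enumerate(zip(offsets[:-1], offsets[1:])):
        block = model.omega[lo:hi]
        pos = np.flatnonzero(np.abs(block) > zero_threshold)
        if pos.size == 0 and v == model.partition.primary_view:
            warnings.warn(
                f"empty support for primary view {v}; falling back to the "
                f"top {fallback_top_k} |omega| positions",
                stacklevel=2,
            )
            k = min(fallback_top_k, block.size)
            pos = np.sort(np.argsort(-np.abs(block), kind="stable")[:k])
        supports.append(pos)
    return supports


def encode_labels(labels: np.ndarray) -> tuple[np.ndarray, tuple]:
    """Binary labels -> +1/-1 regression target, centred by class balance.

    The lower class code (sorted order) maps to -1, the higher to +1; the
    target is then mean-centred so no intercept is needed.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"expected exactly 2 classes, got {classes.tolist()}")
    y = np.where(labels == classes[1], 1.0, -1.0)
    return y - y.mean(), tuple(classes.tolist())


def standardize_columns(
    X: np.ndarray, mean: np.ndarray | None = None, scale: np.ndarray | None = None
):
    """Column z-scoring; constant columns get scale 1 (so they stay zero)."""
    X = np.asarray(X, dtype=float)
    if mean is None:
        mean = X.mean(axis=0)
    if scale is None:
        scale = X.std(axis=0)
        scale = np.where(scale == 0.0, 1.0, scale)
    return (X - mean) / scale, mean, scale


def run_per_view_selection(
    data: MultiViewDataset,
    a1: float = 0.2,
    lam: float = 1.0,
    max_iter: int = 5000,
    tol: float = 1e-7,
    standardize: bool = True,
    train_idx: np.ndarray | None = None,
) -> tuple[MultiViewDataset, SelectionResult]:
    """Run the weighted lasso once per primary view and reduce each view.

    The solver is fitted on ``train_idx`` rows only (all rows when None);
    each view keeps only the support found in the run where it was primary.
    Returns the reduced dataset (all rows, selected columns) and the
    per-view supports.
    """
    X_full = data.concatenated()
    rows = np.arange(data.n_subjects) if train_idx is None else np.asarray(train_idx)
    X = X_full[rows]
    if standardize:
        X, _, _ = standardize_columns(X)
    y, _ = encode_labels(data.labels[rows])
    widths = data.view_widths
    L = lipschitz_estimate(X)

    supports: list[np.ndarray] = []
    models: list[SelectionModel] = []
    for v in range(data.n_views):
        partition = ViewPartition.from_widths(widths, primary_view=v)
        model = ista_solve(X, y, partition, a1=a1, lam=lam, max_iter=max_iter,
                           tol=tol, L=L)
        supports.append(select_support(model, widths)[v])
        models.append(model)

    reduced = MultiViewDataset(
        views=[
            ViewFeatureMatrix(view.X[:, sup], view.view_id, list(view.subject_ids))
            for view, sup in zip(data.views, supports)
        ],
        labels=data.labels,
        subject_ids=list(data.subject_ids),
    )
    return reduced, SelectionResult(support_per_view=supports, models=models)
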