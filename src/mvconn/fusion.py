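"""Multiview deep-feature fusion with normalized cross-correlation alignment.

Each view's deep feature vector v_v is linearly mapped to a common K-width
space, u_v = W_v v_v (no activation before fusion), and the fused feature
vector is the elementwise sum z = sum_v u_v.  To make the per-view maps land
in a *shared* space rather than arbitrary ones, training maximises the
normalized cross correlation (NCC) between the u_v of different views — the
sample Pearson correlation of the two K-length sequences, bounded in
[-1, 1] — summed over consecutive view pairs.  NCC is computed per sample
over the K fused coordinates and averaged over the batch.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["view_transform", "fuse", "ncc", "ncc_batch", "ncc_batch_grad",
           "mv_regularizer", "concat_baseline"]


def view_transform(v_features: np.ndarray, W: np.ndarray) -> np.ndarray:
    """u_v = v_v W: the view's linear map into the fused K-width space."""
    v_features = np.asarray(v_features, dtype=float)
    W = np.asarray(W, dtype=float)
    if v_features.shape[-1] != W.shape[0]:
        raise ValueError(
            f"view width {v_features.shape[-1]} does not match transform input "
            f"{W.shape[0]}"
        )
    return v_features @ W


def fuse(u_per_view: list[np.ndarray]) -> np.ndarray:
    """Elementwise sum of the per-view transformed features."""
    if not u_per_view:
        raise ValueError("no views to fuse")
    shape = np.asarray(u_per_view[0]).shape
    for u in u_per_view[1:]:
        if np.asarray(u).shape != shape:
            raise ValueError("all u_v must share one shape")
    out = np.array(u_per_view[0], dtype=float, copy=True)
    for u in u_per_view[1:]:
        out += u
    return out


def _center_scale(u: np.ndarray):
    """Centered vector and sample std (ddof=1) along the last axis."""
    c = u - u.mean(axis=-1, keepdims=True)
    s = np.sqrt((c * c).sum(axis=-1) / (u.shape[-1] - 1))
    return c, s


def ncc(u1: np.ndarray, u2: np.ndarray) -> float:
    """Normalized cross correlation of two K-length sequences.

    Identical to the sample Pearson correlation: centred inner product over
    (K-1) times the product of sample standard deviations, so the value is
    bounded in [-1, 1].  A zero-variance input makes the correlation
    undefined; it is returned as 0 with a warning (no alignment signal).
    """
    u1 = np.asarray(u1, dtype=float).ravel()
    u2 = np.asarray(u2, dtype=float).ravel()
    if u1.shape != u2.shape:
        raise ValueError("inputs must share length")
    K = u1.size
    if K < 2:
        raise ValueError("need K >= 2 coordinates")
    c1, s1 = _center_scale(u1)
    c2, s2 = _center_scale(u2)
    if s1 == 0.0 or s2 == 0.0:
        warnings.warn("zero-variance input to ncc; returning 0", stacklevel=2)
        return 0.0
    return float(c1 @ c2 / ((K - 1) * s1 * s2))


def ncc_batch(u1: np.ndarray, u2: np.ndarray) -> np.ndarray:
    """Per-sample NCC across the feature axis for batch x K inputs.

    Degenerate (zero-variance) rows yield 0 without warning; they occur
    routinely in the first training steps.
    """
    u1 = np.atleast_2d(np.asarray(u1, dtype=float))
    u2 = np.atleast_2d(np.asarray(u2, dtype=float))
    K = u1.shape[-1]
    c1, s1 = _center_scale(u1)
    c2, s2 = _center_scale(u2)
    denom = (K - 1) * s1 * s2
    ok = denom > 0
    out = np.zeros(u1.shape[0])
    out[ok] = (c1 * c2).sum(axis=-1)[ok] / denom[ok]
    return out


def ncc_batch_grad(u1: np.ndarray, u2: np.ndarray):
    """Gradients of the per-sample NCC w.r.t. both inputs.

    For centred vectors a, b with sample stds s_a, s_b and r = NCC(a, b):
    dr/da_k = (b_k_centred - r (s_a/s_b)^{-1} ... ) — concretely
    (b_c / (s_a s_b) - r a_c / s_a^2) / (K-1); the mean-shift terms vanish
    because the centred partner sums to zero.  Degenerate rows get zero
    gradient.
    """
    u1 = np.atleast_2d(np.asarray(u1, dtype=float))
    u2 = np.atleast_2d(np.asarray(u2, dtype=float))
    K = u1.shape[-1]
    c1, s1 = _center_scale(u1)
    c2, s2 = _center_scale(u2)
    denom = (K - 1) * s1 * s2
    ok = denom > 0
    r = np.zeros(u1.shape[0])
    r[ok] = (c1 * c2).sum(axis=-1)[ok] / denom[ok]
    g1 = np.zeros_like(u1)
    g2 = np.zeros_like(u2)
    kk = K - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        g1[ok] = (c2[ok] / (s1[ok] * s2[ok])[:, None]
                  - r[ok, None] * c1[ok] / (s1[ok] ** 2)[:, None]) / kk
        g2[ok] = (c1[ok] / (s1[ok] * s2[ok])[:, None]
                  - r[ok, None] * c2[ok] / (s2[ok] ** 2)[:, None]) / kk
    return r, g1, g2


def mv_regularizer(u_per_view: list[np.ndarray], pairing: str = "consecutive") -> float:
    """Alignment term L_MV: summed NCC between views' fused features.

    ``pairing='consecutive'`` sums NCC(u_v, u_{v+1}) for v = 1..V-1 (the
    minimal well-defined reading); ``'all_pairs'`` sums over every unordered
    view pair.  Batch inputs are averaged over samples.  With fewer than two
    views there is nothing to align: returns 0 with a warning.
    """
    V = len(u_per_view)
    if V < 2:
        warnings.warn("mv_regularizer needs >= 2 views; returning 0", stacklevel=2)
        return 0.0
    if pairing == "consecutive":
        pairs = [(v, v + 1) for v in range(V - 1)]
    elif pairing == "all_pairs":
        pairs = [(i, j) for i in range(V) for j in range(i + 1, V)]
    else:
        raise ValueError(f"unknown pairing {pairing!r}")
    total = 0.0
    for i, j in pairs:
        total += float(np.mean(ncc_batch(u_per_view[i], u_per_view[j])))
    return total


def concat_baseline(v_per_view: list[np.ndarray]) -> np.ndarray:
    """Plain horizontal concatenation of per-view features (ablation baseline)."""
    if not v_per_view:
        raise ValueError("no views to concatenate")
    mats = [np.atleast_2d(np.asarray(v, dtype=float)) for v in v_per_view]
    n = mats[0].shape[0]
    if any(m.shape[0] != n for m in mats):
        raise ValueError("batch size differs across views")
    return np.hstack(mats)
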