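"""Synthetic multiview connectivity data with known ground truth.

Real multi-atlas connectivity studies are emulated at desk scale: each view
stands for one atlas (default region counts 20 / 12 / 16, scaled-down
analogues of the CC200 / AAL90 / Dosenbach160 parcellations), each feature
for one Fisher-z connectivity edge.  A small set of *planted* edges per view
carries a class-dependent mean shift of +-effect/2 (in Fisher-z units); a
subject-level latent factor perturbs a fraction of the planted edges
coherently across views, mimicking the cross-view shared signal that
multiview selection is meant to exploit.  Everything is reproducible from
the seed, and the planted truth is returned alongside the data so selection
and classification can be scored against it.

Two generation paths exist: :func:`generate_multiview` draws feature vectors
directly (the fast, exactly controllable primary path), while
:func:`generate_timeseries` draws ROI time series whose population
correlations differ between classes on planted region pairs, exercising the
connectivity-construction chain end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectome import (MultiViewDataset, RoiTimeSeries, ViewFeatureMatrix,
                         feature_count, upper_triangle_pairs)

__all__ = ["SynthConfig", "SynthTruth", "generate_multiview",
           "generate_timeseries"]


@dataclass(frozen=True)
class SynthConfig:
    """The stated world of the synthetic benchmark.

    ``effect`` is the between-class difference in mean on a planted edge
    (per-feature signal-to-noise = effect / noise_sd); ``shared_fraction``
    is the proportion of each view's planted edges tied to the cross-view
    latent driver.
    """

    N: int = 200
    region_counts: tuple[int, ...] = (20, 12, 16)
    s: int = 10                  # planted discriminative edges per view
    shared_fraction: float = 0.5
    effect: float = 1.0          # Fisher-z units
    noise_sd: float = 1.0
    latent_sd: float = 1.0       # scale of the shared cross-view driver
    seed: int = 0

    def __post_init__(self):
        if self.N < 4:
            raise ValueError("need at least 4 subjects")
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError("shared_fraction must lie in [0, 1]")
        if self.effect < 0 or self.noise_sd <= 0:
            raise ValueError("effect must be >= 0 and noise_sd > 0")
        for n in self.region_counts:
            if self.s > feature_count(n):
                raise ValueError(
                    f"cannot plant {self.s} edges in a {n}-region view with "
                    f"only {feature_count(n)} connections")


@dataclass
class SynthTruth:
    """Ground truth of one generated dataset."""

    planted_per_view: list[np.ndarray]       # edge indices within each view
    shared_per_view: list[np.ndarray]        # the subset driven by the latent factor
    class_means: list[np.ndarray] = field(default_factory=list)  # per view: (2, n_v)


def _plant_edges(rng: np.random.Generator, cfg: SynthConfig):
    planted, shared = [], []
    n_shared = int(round(cfg.shared_fraction * cfg.s))
    for n_regions in cfg.region_counts:
        n_v = feature_count(n_regions)
        idx = np.sort(rng.choice(n_v, size=cfg.s, replace=False))
        planted.append(idx)
        shared.append(idx[:n_shared])  # first n_shared planted edges share the driver
    return planted, shared


def generate_multiview(cfg: SynthConfig) -> tuple[MultiViewDataset, SynthTruth]:
    """Draw per-view feature matrices with planted class-discriminative edges.

    Features are baseline Gaussian noise (mean 0, sd ``noise_sd``); planted
    edges get a class-dependent shift of +-effect/2, and the shared planted
    edges additionally receive ``latent_sd`` times a per-subject standard
    normal factor common to all views.  Classes are balanced (labels 0/1,
    class 1 = "patients", first N//2 subjects class 0 before the stored
    order, which is subject-id sorted).
    """
    rng = np.random.default_rng(cfg.seed)
    planted, shared = _plant_edges(rng, cfg)
    n0 = cfg.N // 2
    labels = np.array([0] * n0 + [1] * (cfg.N - n0))
    latent = rng.standard_normal(cfg.N) * cfg.latent_sd
    signs = np.where(labels == 1, 0.5, -0.5) * cfg.effect

    views, class_means = [], []
    for v, n_regions in enumerate(cfg.region_counts):
        n_v = feature_count(n_regions)
        X = rng.standard_normal((cfg.N, n_v)) * cfg.noise_sd
        X[:, planted[v]] += signs[:, None]
        X[:, shared[v]] += latent[:, None]
        mu = np.zeros((2, n_v))
        mu[0, planted[v]] = -0.5 * cfg.effect
        mu[1, planted[v]] = 0.5 * cfg.effect
        class_means.append(mu)
        ids = [f"sub-{i:04d}" for i in range(cfg.N)]
        views.append(ViewFeatureMatrix(X, f"view{v}", ids))

    data = MultiViewDataset(views=views, labels=labels,
                            subject_ids=[f"sub-{i:04d}" for i in range(cfg.N)])
    return data, SynthTruth(planted, shared, class_means)


def _nearest_corr(C: np.ndarray, max_shrink: float = 0.5) -> np.ndarray:
    """Shrink toward identity until the matrix is positive definite."""
    for t in np.linspace(0.0, max_shrink, 11):
        M = (1 - t) * C + t * np.eye(C.shape[0])
        if np.linalg.eigvalsh(M).min() > 1e-8:
            return M
    raise ValueError("target correlation matrix is too far from positive definite")


def generate_timeseries(
    cfg: SynthConfig,
    T: int = 200,
    planted_pairs_per_view: int = 3,
    r_patient: float = 0.6,
    r_control: float = 0.0,
) -> tuple[list[list[RoiTimeSeries]], np.ndarray, list[list[tuple[int, int]]]]:
    """Draw ROI time series whose planted region pairs correlate class-dependently.

    Returns ``(series_per_view, labels, planted_pairs_per_view)`` where
    ``series_per_view[v][i]`` is subject i's time series under atlas v.
    Class 1 subjects carry population correlation ``r_patient`` on the
    planted pairs, class 0 subjects ``r_control``; all other region pairs
    are uncorrelated.  Non-positive-definite targets are shrunk toward the
    identity automatically (hard error past a 50% shrink).
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x75]))
    n0 = cfg.N // 2
    labels = np.array([0] * n0 + [1] * (cfg.N - n0))
    series_per_view: list[list[RoiTimeSeries]] = []
    pairs_per_view: list[list[tuple[int, int]]] = []
    for v, n_regions in enumerate(cfg.region_counts):
        all_pairs = upper_triangle_pairs(n_regions)
        chosen = [all_pairs[k] for k in
                  rng.choice(len(all_pairs), size=planted_pairs_per_view,
                             replace=False)]
        pairs_per_view.append(chosen)
        chols = {}
        for cls, r in ((0, r_control), (1, r_patient)):
            C = np.eye(n_regions)
            for i, j in chosen:
                C[i, j] = C[j, i] = r
            chols[cls] = np.linalg.cholesky(_nearest_corr(C))
        subjects = []
        for i in range(cfg.N):
            Z = rng.standard_normal((T, n_regions))
            S = Z @ chols[labels[i]].T
            subjects.append(RoiTimeSeries(f"sub-{i:04d}", S, f"view{v}"))
        series_per_view.append(subjects)
    return series_per_view, labels, pairs_per_view
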