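"""Evaluation: confusion metrics, cross-validation, and ablation harnesses.

Performance is summarised by the five standard clinical indicators derived
from the confusion counts — accuracy, sensitivity, specificity, positive and
negative predictive value, each in percent:

    ACC = (TP+TN)/(TP+TN+FP+FN),  SEN = TP/(TP+FN),  SPE = TN/(TN+FP),
    PPV = TP/(TP+FP),             NPV = TN/(TN+FN).

Cross-validation follows a 5-fold plan realising a 3:1:1
train/validation/test split: subjects are shuffled once into five near-equal
folds, round r tests on fold r, validates on fold (r+1) mod 5 and trains on
the remaining three, so test folds are disjoint and cover every subject.
Feature selection is refit inside every round on the training rows only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np

from .connectome import MultiViewDataset
from .encoder import EncoderSpec
from .network import (FusionSpec, TrainConfig, build_network, predict, total_loss,
                      train)
from .prototypes import LossConfig
from .selection import run_per_view_selection, standardize_columns

__all__ = ["ConfusionCounts", "MetricReport", "SplitPlan", "ExperimentConfig",
           "confusion", "metrics", "make_cv_splits", "run_experiment",
           "ablate_views", "ablate_a1", "ablate_fusion", "mean_report"]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class MetricReport:
    """The five indicators in percent; None flags an undefined (0/0) metric."""

    ACC: float | None
    SEN: float | None
    SPE: float | None
    PPV: float | None
    NPV: float | None

    def as_dict(self) -> dict[str, float | None]:
        return {"ACC": self.ACC, "SEN": self.SEN, "SPE": self.SPE,
                "PPV": self.PPV, "NPV": self.NPV}


@dataclass(frozen=True)
class SplitPlan:
    """Per-round train/validation/test index sets (5 rounds)."""

    rounds: tuple[tuple[np.ndarray, np.ndarray, np.ndarray], ...]
    seed: int

    @property
    def n_rounds(self) -> int:
        return len(self.rounds)


def confusion(true_labels, predicted_labels, positive_class) -> ConfusionCounts:
    """Confusion counts with the declared positive class (the patient group)."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ValueError("label vectors must share length")
    classes = set(np.unique(t).tolist()) | set(np.unique(p).tolist())
    if positive_class not in classes and len(classes) > 0:
        # positive class may legitimately be absent from a fold; only reject
        # labels outside the two-class universe when it is inferable
        pass
    tp = int(np.sum((t == positive_class) & (p == positive_class)))
    tn = int(np.sum((t != positive_class) & (p != positive_class)))
    fp = int(np.sum((t != positive_class) & (p == positive_class)))
    fn = int(np.sum((t == positive_class) & (p != positive_class)))
    return ConfusionCounts(tp, tn, fp, fn)


def _pct(num: int, den: int) -> float | None:
    return None if den == 0 else 100.0 * num / den


def metrics(c: ConfusionCounts) -> MetricReport:
    """ACC/SEN/SPE/PPV/NPV in percent; zero-denominator metrics flagged None."""
    if c.total == 0:
        raise ValueError("no evaluated instances")
    return MetricReport(
        ACC=_pct(c.TP + c.TN, c.total),
        SEN=_pct(c.TP, c.TP + c.FN),
        SPE=_pct(c.TN, c.TN + c.FP),
        PPV=_pct(c.TP, c.TP + c.FP),
        NPV=_pct(c.TN, c.TN + c.FN),
    )


def mean_report(reports: list[MetricReport]) -> MetricReport:
    """Mean of each indicator over folds, ignoring undefined entries."""
    out = {}
    for key in ("ACC", "SEN", "SPE", "PPV", "NPV"):
        vals = [r.as_dict()[key] for r in reports if r.as_dict()[key] is not None]
        out[key] = float(np.mean(vals)) if vals else None
    return MetricReport(**out)


def make_cv_splits(N: int, seed: int = 0) -> SplitPlan:
    """5-fold rotation realising the 3:1:1 train/validation/test ratio."""
    if N < 5:
        raise ValueError(f"need at least 5 subjects for 5-fold CV, got {N}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(N)
    folds = np.array_split(order, 5)
    rounds = []
    for r in range(5):
        test = np.sort(folds[r])
        val = np.sort(folds[(r + 1) % 5])
        train_folds = [folds[k] for k in range(5) if k not in (r, (r + 1) % 5)]
        tr = np.sort(np.concatenate(train_folds))
        rounds.append((tr, val, test))
    return SplitPlan(rounds=tuple(rounds), seed=seed)


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything one cross-validated experiment needs."""

    a1: float = 0.2
    lam: float = 1.0
    selection_max_iter: int = 5000
    selection_tol: float = 1e-7
    standardize: bool = True
    encoder: EncoderSpec = field(default_factory=EncoderSpec)
    fusion: FusionSpec = field(default_factory=FusionSpec)
    loss: LossConfig = field(default_factory=LossConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    positive_class: object = 1
    seed: int = 0


@dataclass
class ExperimentResult:
    per_fold: list[MetricReport]
    mean: MetricReport
    support_sizes: list[list[int]]           # per fold, per view
    mv_trace: list[float] = field(default_factory=list)  # final L_MV per fold
    config: ExperimentConfig | None = None

    def mean_acc(self) -> float:
        return float(self.mean.ACC)


def _fit_one_round(data: MultiViewDataset, tr, va, te, cfg: ExperimentConfig,
                   round_seed: int):
    reduced, selection = run_per_view_selection(
        data, a1=cfg.a1, lam=cfg.lam, max_iter=cfg.selection_max_iter,
        tol=cfg.selection_tol, standardize=cfg.standardize, train_idx=tr)
    # scale the selected features by training-set statistics
    X_views, Xv_val, Xv_test = [], [], []
    for view in reduced.views:
        Xtr, mean, scale = standardize_columns(view.X[tr])
        X_views.append(Xtr)
        Xv_val.append(standardize_columns(view.X[va], mean, scale)[0])
        Xv_test.append(standardize_columns(view.X[te], mean, scale)[0])

    net = build_network(reduced.view_widths, cfg.encoder, cfg.fusion,
                        X_views=X_views, seed=round_seed)
    model = train(net, X_views, data.labels[tr], cfg.loss,
                  replace(cfg.train, seed=round_seed),
                  val_views=Xv_val, val_y=data.labels[va])
    pred, _ = predict(model, Xv_test)
    counts = confusion(data.labels[te], pred, cfg.positive_class)
    mv_final = 0.0
    if cfg.fusion.mode == "fuse" and data.n_views >= 2:
        _, comps, _ = total_loss(model.net, X_views, data.labels[tr],
                                 model.prototypes, cfg.loss, want_grads=False)
        mv_final = comps["mv"]
    sizes = [len(s) for s in selection.support_per_view]
    return metrics(counts), sizes, mv_final


def run_experiment(data: MultiViewDataset,
                   cfg: ExperimentConfig) -> ExperimentResult:
    """Full 5-round cross-validated run of selection + training + testing.

    Selection and feature scaling are fitted on each round's training rows
    only; the validation fold drives checkpointing; metrics are reported on
    the disjoint test folds.  One master seed drives the split plan and
    every per-round random component.
    """
    plan = make_cv_splits(data.n_subjects, seed=cfg.seed)
    per_fold, sizes, mv_trace = [], [], []
    for r, (tr, va, te) in enumerate(plan.rounds):
        report, sup, mv = _fit_one_round(data, tr, va, te, cfg,
                                         round_seed=cfg.seed * 7919 + r)
        per_fold.append(report)
        sizes.append(sup)
        mv_trace.append(mv)
    return ExperimentResult(per_fold=per_fold, mean=mean_report(per_fold),
                            support_sizes=sizes, mv_trace=mv_trace, config=cfg)


def ablate_views(data: MultiViewDataset, cfg: ExperimentConfig) -> list[dict]:
    """Run every nonempty view subset (single views, pairs, ..., all views).

    Rows are sorted by (subset size, view indices); single-view rows have no
    cross-view fusion signal by construction.
    """
    V = data.n_views
    rows = []
    subsets = [c for k in range(1, V + 1) for c in combinations(range(V), k)]
    for subset in subsets:
        result = run_experiment(data.subset_views(list(subset)), cfg)
        rows.append({"views": subset, "mean": result.mean,
                     "per_fold": result.per_fold})
    return rows


def ablate_a1(data: MultiViewDataset, cfg: ExperimentConfig,
              grid: np.ndarray | None = None) -> list[dict]:
    """Sweep the primary-view weight a1 (a2 = 1 - a1), re-running everything."""
    if grid is None:
        grid = np.round(np.arange(0.0, 1.01, 0.1), 10)
    rows = []
    for a1 in grid:
        result = run_experiment(data, replace(cfg, a1=float(a1)))
        rows.append({"a1": float(a1), "mean": result.mean,
                     "support_sizes": result.support_sizes})
    return rows


def ablate_fusion(data: MultiViewDataset, cfg: ExperimentConfig) -> list[dict]:
    """Concat-i vs MvFF-i for every fusion position i = 1..depth."""
    rows = []
    for mode in ("concat", "fuse"):
        for pos in range(1, cfg.encoder.depth + 1):
            fus = FusionSpec(mode=mode, position=pos, K=cfg.fusion.K,
                             pairing=cfg.fusion.pairing)
            result = run_experiment(data, replace(cfg, fusion=fus))
            rows.append({"mode": mode, "position": pos, "mean": result.mean,
                         "mv_trace": result.mv_trace})
    return rows
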