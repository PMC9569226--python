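"""Brain functional connectivity (BFC) feature construction.

Each subject's resting-state activity is summarised per brain atlas as a
matrix of region-averaged time series (rows = timepoints, columns = regions,
the dialect used by Preprocessed Connectomes Project ``.1D`` exports).
Connectivity between two regions is the Pearson correlation of their time
series, variance-stabilised by the Fisher z transform (arctanh).  Because
the connectivity matrix is symmetric with an uninformative diagonal, the
subject's feature vector is the strictly upper triangle in row-major order,
of length n(n-1)/2 for an n-region atlas.

Several atlases applied to the same subjects yield several *views* of the
same cohort; :func:`assemble_views` aligns them by subject identifier into a
:class:`MultiViewDataset`, the container every downstream stage consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RoiTimeSeries",
    "ConnectivityMatrix",
    "ViewFeatureMatrix",
    "MultiViewDataset",
    "DegenerateSeriesError",
    "AlignmentError",
    "pearson_matrix",
    "fisher_z",
    "vectorize_upper",
    "feature_count",
    "upper_triangle_pairs",
    "connectivity_features",
    "load_timeseries",
    "assemble_views",
    "write_view_matrix",
    "read_view_matrix",
]

_SYMMETRY_TOL = 1e-10
#: clip applied to |r| before arctanh so identical series stay finite
FISHER_CLIP = 1e-7


class DegenerateSeriesError(ValueError):
    """A region's time series has zero variance; its correlations are undefined."""


class AlignmentError(ValueError):
    """Subject identifiers do not line up across views / the label table."""


@dataclass(frozen=True)
class RoiTimeSeries:
    """Region-averaged time series for one subject under one atlas."""

    subject_id: str
    series: np.ndarray  # (T timepoints, n regions)
    atlas_name: str = ""

    def __post_init__(self) -> None:
        series = np.asarray(self.series, dtype=float)
        if series.ndim != 2:
            raise ValueError("series must be a 2-D (timepoints x regions) array")
        if series.shape[0] < 2:
            raise ValueError(f"need at least 2 timepoints, got {series.shape[0]}")
        if series.shape[1] < 2:
            raise ValueError(f"need at least 2 regions, got {series.shape[1]}")
        if not np.all(np.isfinite(series)):
            raise ValueError("series contains non-finite entries")
        object.__setattr__(self, "series", series)

    @property
    def n_timepoints(self) -> int:
        return self.series.shape[0]

    @property
    def n_regions(self) -> int:
        return self.series.shape[1]


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric matrix of Fisher-z Pearson correlations for one subject."""

    values: np.ndarray
    atlas_name: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.all(np.isfinite(values)):
            raise ValueError("connectivity matrix contains non-finite entries")
        if not np.allclose(values, values.T, atol=_SYMMETRY_TOL, rtol=0.0):
            raise ValueError("connectivity matrix is not symmetric")
        object.__setattr__(self, "values", values)

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass
class ViewFeatureMatrix:
    """Feature matrix of one view: N subjects x n_v connectivity features."""

    X: np.ndarray
    view_id: str
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (subjects x features)")
        if self.subject_ids and len(self.subject_ids) != self.X.shape[0]:
            raise ValueError("subject_ids length does not match rows of X")

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


@dataclass
class MultiViewDataset:
    """Per-view feature matrices with shared subject order and binary labels."""

    views: list[ViewFeatureMatrix]
    labels: np.ndarray
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.views:
            raise ValueError("at least one view required")
        self.labels = np.asarray(self.labels)
        n = self.views[0].n_subjects
        for v in self.views:
            if v.n_subjects != n:
                raise ValueError("all views must share the subject count")
        if len(self.labels) != n:
            raise ValueError("labels length must equal the subject count")

    @property
    def n_subjects(self) -> int:
        return self.views[0].n_subjects

    @property
    def n_views(self) -> int:
        return len(self.views)

    @property
    def view_widths(self) -> list[int]:
        return [v.n_features for v in self.views]

    @property
    def total_dim(self) -> int:
        """D = sum of per-view feature counts."""
        return int(sum(self.view_widths))

    def concatenated(self) -> np.ndarray:
        """All views side by side: N x D."""
        return np.hstack([v.X for v in self.views])

    def view_slices(self) -> list[slice]:
        """Column ranges of each view within the concatenated layout."""
        out, start = [], 0
        for w in self.view_widths:
            out.append(slice(start, start + w))
            start += w
        return out

    def subset_subjects(self, idx: Sequence[int]) -> "MultiViewDataset":
        idx = np.asarray(idx, dtype=int)
        return MultiViewDataset(
            views=[
                ViewFeatureMatrix(
                    v.X[idx],
                    v.view_id,
                    [v.subject_ids[i] for i in idx] if v.subject_ids else [],
                )
                for v in self.views
            ],
            labels=self.labels[idx],
            subject_ids=[self.subject_ids[i] for i in idx] if self.subject_ids else [],
        )

    def subset_views(self, which: Sequence[int]) -> "MultiViewDataset":
        return MultiViewDataset(
            views=[self.views[i] for i in which],
            labels=self.labels,
            subject_ids=list(self.subject_ids),
        )


def feature_count(n: int) -> int:
    """Number of distinct functional connections among ``n`` regions: n(n-1)/2."""
    if n < 1:
        raise ValueError(f"region count must be >= 1, got {n}")
    return n * (n - 1) // 2


def pearson_matrix(ts: RoiTimeSeries) -> np.ndarray:
    """Pairwise Pearson correlations between region time series.

    Raises
    ------
    DegenerateSeriesError
        If any region's series has zero variance (its correlation with any
        other region is undefined; silent imputation would corrupt feature
        selection downstream).
    """
    series = ts.series
    sd = series.std(axis=0)
    dead = np.flatnonzero(sd == 0.0)
    if dead.size:
        raise DegenerateSeriesError(
            f"zero-variance region(s) {dead.tolist()} in subject "
            f"{ts.subject_id!r}: Pearson correlation undefined"
        )
    r = np.corrcoef(series, rowvar=False)
    # corrcoef can stray past +-1 by rounding; the contract is [-1, 1]
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    return r


def fisher_z(r):
    """Fisher z transform arctanh(r), with |r| clipped to 1 - 1e-7.

    Accepts scalars or arrays.  Values outside [-1, 1] (beyond a small
    rounding tolerance) raise a domain error.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) > 1.0 + 1e-9):
        raise ValueError("correlation outside [-1, 1]")
    clipped = np.clip(arr, -1.0 + FISHER_CLIP, 1.0 - FISHER_CLIP)
    out = np.arctanh(clipped)
    return float(out) if np.isscalar(r) or out.ndim == 0 else out


def upper_triangle_pairs(n: int) -> list[tuple[int, int]]:
    """Row-major strictly-upper-triangle index pairs (i < j, 0-based)."""
    return [(i, j) for i in range(n) for j in range(i + 1, n)]


def vectorize_upper(cm) -> np.ndarray:
    """Strictly upper triangular entries in row-major order (diagonal excluded)."""
    values = cm.values if isinstance(cm, ConnectivityMatrix) else np.asarray(cm, float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("expected a square matrix")
    if values.shape[0] < 2:
        raise ValueError("need at least 2 regions to extract connections")
    if not np.allclose(values, values.T, atol=_SYMMETRY_TOL, rtol=0.0):
        raise ValueError("matrix is not symmetric within tolerance")
    iu, ju = np.triu_indices(values.shape[0], k=1)
    return values[iu, ju]


def connectivity_features(ts: RoiTimeSeries) -> np.ndarray:
    """Full chain: Pearson matrix -> Fisher z -> upper-triangle vector."""
    r = pearson_matrix(ts)
    z = fisher_z(r)
    np.fill_diagonal(z, 0.0)  # excluded from the feature vector anyway
    return vectorize_upper(ConnectivityMatrix(z, ts.atlas_name))


def load_timeseries(
    path,
    subject_id: str | None = None,
    atlas_name: str = "",
    dialect: str = "1d",
) -> RoiTimeSeries:
    """Load a ROI time-series table (rows = timepoints, columns = regions).

    ``dialect='1d'`` reads whitespace-delimited text with optional leading
    ``#`` comment lines (PCP ``.1D`` exports); ``dialect='csv'`` reads
    comma-separated text, tolerating one non-numeric header line.
    """
    path = Path(path)
    if dialect not in ("1d", "csv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    sep = "," if dialect == "csv" else None
    rows: list[list[float]] = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cells = line.split(sep)
            try:
                row = [float(c) for c in cells]
            except ValueError:
                if dialect == "csv" and not rows and width is None:
                    continue  # one tolerated header line
                raise ValueError(
                    f"{path}:{lineno}: non-numeric cell in time-series body"
                ) from None
            if width is None:
                width = len(row)
            elif len(row) != width:
                raise ValueError(
                    f"{path}:{lineno}: ragged row ({len(row)} cells, expected {width})"
                )
            rows.append(row)
    if not rows:
        raise ValueError(f"{path}: no numeric rows found")
    return RoiTimeSeries(
        subject_id=subject_id or path.stem,
        series=np.asarray(rows, dtype=float),
        atlas_name=atlas_name,
    )


def write_view_matrix(path, view: ViewFeatureMatrix) -> None:
    """Write a view's feature matrix as CSV with a comment header naming it."""
    path = Path(path)
    df = pd.DataFrame(view.X)
    df.insert(0, "subject_id", view.subject_ids or [str(i) for i in range(view.n_subjects)])
    with open(path, "w") as fh:
        fh.write(f"# view={view.view_id} n_v={view.n_features}\n")
        df.to_csv(fh, index=False)


def read_view_matrix(path, view_id: str | None = None) -> ViewFeatureMatrix:
    """Read a feature matrix written by :func:`write_view_matrix` (or any CSV
    whose first column is ``subject_id``)."""
    path = Path(path)
    header_view = None
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for token in first[1:].split():
            if token.startswith("view="):
                header_view = token[5:]
    df = pd.read_csv(path, comment="#")
    if "subject_id" not in df.columns:
        raise ValueError(f"{path}: expected a subject_id column")
    ids = df["subject_id"].astype(str).tolist()
    X = df.drop(columns="subject_id").to_numpy(dtype=float)
    return ViewFeatureMatrix(X, view_id or header_view or path.stem, ids)


def assemble_views(
    view_matrices: Sequence[ViewFeatureMatrix] | Mapping[str, ViewFeatureMatrix],
    label_table: pd.DataFrame,
) -> MultiViewDataset:
    """Align views and labels by subject identifier into a MultiViewDataset.

    Subject order is taken from the label table; every view must contain
    exactly the same identifiers (file or row order is irrelevant).

    Parameters
    ----------
    view_matrices
        Per-view feature matrices carrying ``subject_ids``.
    label_table
        DataFrame with columns ``subject_id`` and ``label``.
    """
    if isinstance(view_matrices, Mapping):
        view_matrices = list(view_matrices.values())
    if not {"subject_id", "label"} <= set(label_table.columns):
        raise ValueError("label table needs columns subject_id,label")
    order = label_table["subject_id"].astype(str).tolist()
    if len(set(order)) != len(order):
        raise AlignmentError("duplicate subject_id in label table")
    wanted = set(order)
    aligned = []
    for view in view_matrices:
        have = {s: i for i, s in enumerate(view.subject_ids)}
        missing = sorted(wanted - set(have))
        extra = sorted(set(have) - wanted)
        if missing or extra:
            raise AlignmentError(
                f"view {view.view_id!r}: missing subjects {missing}, "
                f"unlabelled subjects {extra}"
            )
        rows = [have[s] for s in order]
        aligned.append(ViewFeatureMatrix(view.X[rows], view.view_id, list(order)))
    labels = label_table["label"].to_numpy()
    return MultiViewDataset(views=aligned, labels=labels, subject_ids=list(order))
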