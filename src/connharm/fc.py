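"""Functional-connectivity feature construction.

Builds subject-level FC matrices from ROI time series (pairwise Pearson
correlation), applies the Fisher z-transform, vectorises the strict lower
triangle into the model's feature vector, and transfers anatomical labels
between atlases by nearest centroid.

The lower-triangle convention is row-major over rows 2..R — feature k of the
vector corresponds to matrix entry (i, j) with i > j, row 2 first.  The same
convention indexes saliency vectors back into matrix form, so it must not
change between feature construction and biomarker mapping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PEARSON = "pearson"
FISHER_Z = "fisher_z"


@dataclass
class RoiTimeSeries:
    """T timepoints × R regions of mean ROI signal for one subject."""

    subject_id: str
    values: np.ndarray          # (T, R)
    roi_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("time series must be a T×R matrix")
        t, r = self.values.shape
        if t < 3:
            raise ValueError(f"need at least 3 timepoints, got {t}")
        if r < 2:
            raise ValueError(f"need at least 2 regions, got {r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite values in time series")
        if len(self.roi_ids) != r:
            raise ValueError("roi_ids length does not match number of columns")

    @classmethod
    def read(cls, path, subject_id: str | None = None, sep: str = "\t") -> "RoiTimeSeries":
        df = pd.read_csv(path, sep=sep)
        sid = subject_id if subject_id is not None else str(path)
        return cls(subject_id=sid, values=df.to_numpy(dtype=float),
                   roi_ids=[str(c) for c in df.columns])


@dataclass
class FCMatrix:
    """Symmetric R×R connectivity matrix on the Pearson-r or Fisher-z scale."""

    subject_id: str
    values: np.ndarray
    scale: str = PEARSON

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        r = self.values.shape[0]
        if self.values.shape != (r, r) or r < 2:
            raise ValueError("FC matrix must be square with R >= 2")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("FC matrix is not symmetric within 1e-8")
        if self.scale not in (PEARSON, FISHER_Z):
            raise ValueError(f"unknown scale {self.scale!r}")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


def compute_fc_matrix(ts: RoiTimeSeries) -> FCMatrix:
    """Pairwise Pearson correlation between every ROI pair.

    Raises if any ROI signal is constant (its correlation is undefined) —
    the error names the offending ROI.
    """
    x = ts.values
    sd = x.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"constant time series for ROI {ts.roi_ids[bad[0]]!r}: "
                         "correlation undefined")
    r = np.corrcoef(x, rowvar=False)
    np.fill_diagonal(r, 1.0)
    r = (r + r.T) / 2.0  # exact symmetry against rounding
    return FCMatrix(subject_id=ts.subject_id, values=r, scale=PEARSON)


def fisher_transform(fc: FCMatrix, clip: float = 1.0 - 1e-7) -> FCMatrix:
    """z = arctanh(r) on the off-diagonal; diagonal set to 0.

    |r| is clipped to `clip` first so numerically perfect correlations stay
    finite.
    """
    if fc.scale != PEARSON:
        raise ValueError("input is already Fisher-transformed")
    if not (0.0 < clip < 1.0):
        raise ValueError("clip must lie in (0, 1)")
    z = np.arctanh(np.clip(fc.values, -clip, clip))
    np.fill_diagonal(z, 0.0)
    return FCMatrix(subject_id=fc.subject_id, values=z, scale=FISHER_Z)


def lower_triangle_indices(n_rois: int) -> tuple[np.ndarray, np.ndarray]:
    """(row, col) indices of the strict lower triangle in row-major order."""
    return np.tril_indices(n_rois, k=-1)


def n_features(n_rois: int) -> int:
    return n_rois * (n_rois - 1) // 2


def vectorize_lower_triangle(fc: FCMatrix | np.ndarray, atol: float = 1e-8) -> np.ndarray:
    """Flatten the strict lower triangle into a length R(R-1)/2 vector."""
    m = fc.values if isinstance(fc, FCMatrix) else np.asarray(fc, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] < 2:
        raise ValueError("expected a square matrix with R >= 2")
    if not np.allclose(m, m.T, atol=atol):
        raise ValueError("matrix asymmetric beyond tolerance")
    rows, cols = lower_triangle_indices(m.shape[0])
    return m[rows, cols].copy()


def matricize_lower_triangle(vec: np.ndarray, n_rois: int | None = None,
                             diagonal: float = 0.0, symmetric: bool = True) -> np.ndarray:
    """Inverse of :func:`vectorize_lower_triangle`.

    With ``symmetric=False`` the upper triangle is left at zero — the layout
    used for saliency heatmaps.
    """
    vec = np.asarray(vec, dtype=float)
    if n_rois is None:
        n_rois = int(round((1 + np.sqrt(1 + 8 * vec.size)) / 2))
    if n_features(n_rois) != vec.size:
        raise ValueError(f"vector length {vec.size} does not match R={n_rois}")
    m = np.zeros((n_rois, n_rois))
    rows, cols = lower_triangle_indices(n_rois)
    m[rows, cols] = vec
    if symmetric:
        m[cols, rows] = vec
    np.fill_diagonal(m, diagonal)
    return m


def feature_legend(roi_ids: list[str]) -> pd.DataFrame:
    """Feature index → (roi_i, roi_j) table for the lower-triangle layout."""
    rows, cols = lower_triangle_indices(len(roi_ids))
    return pd.DataFrame({
        "feature": np.arange(rows.size),
        "roi_i": [roi_ids[i] for i in rows],
        "roi_j": [roi_ids[j] for j in cols],
    })


@dataclass
class AtlasTable:
    """ROI centroids (mm) with anatomical labels."""

    roi_id: np.ndarray
    xyz: np.ndarray             # (R, 3)
    label: np.ndarray

    def __post_init__(self):
        self.roi_id = np.asarray(self.roi_id)
        self.xyz = np.asarray(self.xyz, dtype=np.float64)
        self.label = np.asarray(self.label)
        if len(self.roi_id) == 0:
            raise ValueError("empty atlas table")
        if self.xyz.shape != (len(self.roi_id), 3):
            raise ValueError("coordinate table must be R×3")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("missing or non-finite atlas coordinates")
        if len(set(self.roi_id.tolist())) != len(self.roi_id):
            raise ValueError("duplicate roi_ids in atlas table")

    @classmethod
    def read(cls, path, sep: str = "\t") -> "AtlasTable":
        df = pd.read_csv(path, sep=sep)
        return cls(roi_id=df["roi_id"].to_numpy(),
                   xyz=df[["x", "y", "z"]].to_numpy(dtype=float),
                   label=df["label"].astype(str).to_numpy())


def map_roi_labels(src: AtlasTable, dst: AtlasTable) -> dict:
    """Label each source ROI by its nearest destination centroid.

    Distance is Euclidean in mm; exact ties go to the destination ROI with
    the lowest roi_id so repeated runs agree.
    """
    d2 = ((src.xyz[:, None, :] - dst.xyz[None, :, :]) ** 2).sum(axis=2)
    order = np.argsort(dst.roi_id, kind="stable")
    mapping = {}
    for i, rid in enumerate(src.roi_id):
        best = order[np.argmin(d2[i, order])]  # scan in roi_id order: ties → lowest id
        mapping[rid] = dst.label[best]
    return mapping
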