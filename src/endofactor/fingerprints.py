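"""Connectivity fingerprints from ROI time-series.

Each subject's resting-state signal is summarized as the mean time-series
per region of interest (ROI); series are linearly detrended, z-scored, and
all pairwise Pearson correlations are collected into one "connectional
fingerprint" vector.  For the 21-node default-mode / dorsal-attention /
salience network studied here that is 21·20/2 = 210 edges per subject.
Multi-site cohorts can additionally be residualized for additive site
effects at the edge level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

__all__ = [
    "DEFAULT_ROI_ORDER",
    "ROITimeSeries",
    "ConnectivityFingerprint",
    "CohortMatrix",
    "edge_names_for",
    "vectorize_upper",
    "devectorize",
    "extract_roi_timeseries",
    "compute_fingerprint",
    "remove_site_effects",
]

#: Fixed ordering of the 21-node DMN + DAN + SN network: four dorsomedial
#: prefrontal and four posteromedial subregions, two temporoparietal-junction
#: subregions per hemisphere, bilateral dorsolateral prefrontal cortex and
#: intraparietal sulcus (dorsal attention network), bilateral anterior insula,
#: a single midline midcingulate node, and bilateral amygdala (salience
#: network).  21 nodes -> 210 unordered edges.
DEFAULT_ROI_ORDER: tuple[str, ...] = (
    "dmPFC1", "dmPFC2", "dmPFC3", "dmPFC4",
    "PMC1", "PMC2", "PMC3", "PMC4",
    "L_TPJ1", "L_TPJ2", "R_TPJ1", "R_TPJ2",
    "L_dlPFC", "R_dlPFC",
    "L_IPS", "R_IPS",
    "L_AI", "R_AI",
    "MCC",
    "L_AM", "R_AM",
)


@dataclass
class ROITimeSeries:
    """Mean time-series per ROI for one subject (timepoints x ROIs)."""

    data: np.ndarray
    roi_names: tuple[str, ...]
    subject_id: str = "subject"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.roi_names = tuple(self.roi_names)
        if self.data.ndim != 2:
            raise ValueError("time-series data must be 2-D (timepoints x ROIs)")
        if self.data.shape[1] != len(self.roi_names):
            raise ValueError("number of ROI names must match data columns")
        if len(set(self.roi_names)) != len(self.roi_names):
            raise ValueError("ROI names must be unique")
        if self.data.shape[0] < 2:
            raise ValueError("need at least 2 timepoints")
        if np.isnan(self.data).any():
            raise ValueError("time-series contain missing values")

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


@dataclass
class ConnectivityFingerprint:
    """Upper-triangle vector of pairwise Pearson correlations for one subject."""

    values: np.ndarray
    edge_names: tuple[str, ...]
    roi_order: tuple[str, ...]
    subject_id: str = "subject"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.roi_order)
        if self.values.shape != (n * (n - 1) // 2,):
            raise ValueError(
                f"fingerprint length {self.values.size} does not match "
                f"{n} ROIs ({n * (n - 1) // 2} edges expected)")


@dataclass
class CohortMatrix:
    """Stacked fingerprints (subjects x edges) with identifiers and site labels."""

    X: np.ndarray
    subject_ids: list[str]
    edge_names: tuple[str, ...]
    site_labels: np.ndarray | None = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (subjects x edges)")
        if len(self.subject_ids) != self.X.shape[0]:
            raise ValueError("subject_ids length must match X rows")
        if len(self.edge_names) != self.X.shape[1]:
            raise ValueError("edge_names length must match X columns")
        if self.site_labels is not None:
            self.site_labels = np.asarray(self.site_labels, dtype=int)
            if self.site_labels.shape != (self.X.shape[0],):
                raise ValueError("site_labels length must match X rows")

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]


def edge_names_for(roi_order) -> tuple[str, ...]:
    """Edge labels ``"ROIa__ROIb"`` in row-major upper-triangle order."""
    roi_order = tuple(roi_order)
    return tuple(f"{roi_order[i]}__{roi_order[j]}"
                 for i in range(len(roi_order))
                 for j in range(i + 1, len(roi_order)))


def vectorize_upper(matrix: np.ndarray) -> np.ndarray:
    """Vectorize a symmetric unit-diagonal matrix in row-major upper-triangle order.

    Order for a 3x3 matrix: (1,2), (1,3), (2,3).  Exact inverse of
    :func:`devectorize`.
    """
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(M, M.T, atol=1e-10):
        raise ValueError("matrix must be symmetric")
    if not np.allclose(np.diag(M), 1.0, atol=1e-8):
        raise ValueError("matrix must have unit diagonal")
    iu = np.triu_indices(M.shape[0], k=1)
    return M[iu].copy()


def devectorize(vector: np.ndarray, n_rois: int) -> np.ndarray:
    """Rebuild the symmetric unit-diagonal matrix from its upper-triangle vector."""
    v = np.asarray(vector, dtype=float).ravel()
    expected = n_rois * (n_rois - 1) // 2
    if v.size != expected:
        raise ValueError(
            f"vector length {v.size} is not the triangular number for "
            f"{n_rois} ROIs (expected {expected})")
    M = np.eye(n_rois)
    iu = np.triu_indices(n_rois, k=1)
    M[iu] = v
    M[(iu[1], iu[0])] = v
    return M


def _as_volume(image4d) -> np.ndarray:
    if hasattr(image4d, "get_fdata"):   # nibabel image
        image4d = image4d.get_fdata()
    arr = np.asarray(image4d, dtype=float)
    if arr.ndim != 4:
        raise ValueError("expected a 4-D volume (x, y, z, time)")
    return arr


def _masks_as_dict(roi_masks, grid_shape) -> dict[str, np.ndarray]:
    """Normalize mask input: dict of 3-D masks, or an integer-labeled 3-D array.

    Probabilistic masks are thresholded at 0.5; binary/label masks pass through.
    """
    if isinstance(roi_masks, dict):
        out = {}
        for name, m in roi_masks.items():
            if hasattr(m, "get_fdata"):
                m = m.get_fdata()
            m = np.asarray(m)
            if m.shape != grid_shape:
                raise ValueError(
                    f"ROI mask '{name}' grid {m.shape} does not match image "
                    f"grid {grid_shape}")
            out[str(name)] = (m.astype(float) > 0.5)
        return out
    if hasattr(roi_masks, "get_fdata"):
        roi_masks = roi_masks.get_fdata()
    lab = np.asarray(roi_masks)
    if lab.shape != grid_shape:
        raise ValueError(
            f"label volume grid {lab.shape} does not match image grid {grid_shape}")
    labels = np.unique(lab)
    labels = labels[labels != 0]
    return {f"roi{int(v)}": (lab == v) for v in labels}


def extract_roi_timeseries(image4d, roi_masks, subject_id: str = "subject",
                           roi_order=None) -> ROITimeSeries:
    """Average the 4-D signal over each ROI mask.

    Parameters
    ----------
    image4d : ndarray or nibabel image, shape (x, y, z, t)
    roi_masks : dict of name -> 3-D mask (binary or probabilistic, thresholded
        at 0.5), or a single integer-labeled 3-D volume.
    roi_order : explicit ROI ordering; defaults to the mask dict order.

    Returns
    -------
    ROITimeSeries with, per ROI, the unweighted mean over in-mask voxels at
    each timepoint.
    """
    vol = _as_volume(image4d)
    masks = _masks_as_dict(roi_masks, vol.shape[:3])
    names = tuple(roi_order) if roi_order is not None else tuple(masks)
    series = np.empty((vol.shape[3], len(names)))
    flat = vol.reshape(-1, vol.shape[3])
    for j, name in enumerate(names):
        if name not in masks:
            raise ValueError(f"no mask provided for ROI '{name}'")
        idx = np.flatnonzero(masks[name].ravel())
        if idx.size == 0:
            raise ValueError(f"ROI '{name}' has an empty mask (zero voxels)")
        series[:, j] = flat[idx].mean(axis=0)
    return ROITimeSeries(series, names, subject_id=subject_id)


def compute_fingerprint(ts: ROITimeSeries, fisher_z: bool = False) -> ConnectivityFingerprint:
    """Detrend, z-score, and correlate every ROI pair.

    Each series is linearly detrended (first-order polynomial removed),
    standardized to zero mean / unit variance, and Pearson's r is computed
    for every unordered ROI pair, vectorized in row-major upper-triangle
    order of the ROI ordering.  With ``fisher_z=True`` the correlations are
    additionally arctanh-transformed (entries then leave [-1, 1]).
    """
    data = _signal.detrend(ts.data, axis=0, type="linear")
    sd = data.std(axis=0, ddof=0)
    dead = np.flatnonzero(sd < 1e-10)
    if dead.size:
        raise ValueError(
            "zero-variance series after detrending for ROI(s): "
            + ", ".join(ts.roi_names[i] for i in dead))
    data = (data - data.mean(axis=0)) / sd
    C = np.corrcoef(data, rowvar=False)
    C = np.clip(C, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    values = vectorize_upper(C)
    if fisher_z:
        values = np.arctanh(np.clip(values, -1 + 1e-15, 1 - 1e-15))
    return ConnectivityFingerprint(values, edge_names_for(ts.roi_names),
                                   tuple(ts.roi_names), subject_id=ts.subject_id)


def remove_site_effects(cohort: CohortMatrix) -> CohortMatrix:
    """Residualize additive site effects per edge, keeping the grand mean.

    For every edge, ordinary least squares on site indicator variables is
    solved (equivalently: the per-site mean is subtracted) and the edge's
    grand mean is added back so the residualized fingerprints stay on an
    interpretable scale.  Single-site cohorts come back unchanged.
    """
    if cohort.site_labels is None:
        raise ValueError("site_labels are required to remove site effects")
    sites, counts = np.unique(cohort.site_labels, return_counts=True)
    lone = sites[counts < 2]
    if lone.size:
        warnings.warn(
            f"site(s) {lone.tolist()} have a single subject; retained as-is",
            UserWarning, stacklevel=2)
    X = cohort.X.copy()
    grand = X.mean(axis=0)
    for s in sites:
        rows = cohort.site_labels == s
        X[rows] -= X[rows].mean(axis=0)
    X += grand
    return CohortMatrix(X, list(cohort.subject_ids), tuple(cohort.edge_names),
                        cohort.site_labels.copy())
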