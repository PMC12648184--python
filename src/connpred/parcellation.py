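"""Parcellation handling: dual regression, binarization, masks, parcel means.

A weighted parcellation assigns every voxel a (possibly signed) weight
for each parcel, as produced by group ICA. Dual regression maps the
group maps to participant-specific time courses (stage 1: spatial
regressors) and back to participant-specific spatial maps (stage 2:
temporal regressors). For single-timepoint contrast volumes the
parcellation is instead binarised with overlap removed, and parcel
values are voxel means within each label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

_RCOND = 1e-10


@dataclass
class WeightedParcellation:
    """Voxels x parcels weight matrix with parcel labels.

    Weights may be negative (ICA maps are signed); no parcel column may
    be all zero.
    """

    weights: np.ndarray
    parcel_ids: list[str] = field(default_factory=list)
    space_tag: str = ""

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2:
            raise ValueError("weights must be a voxels x parcels matrix")
        if not np.isfinite(self.weights).all():
            raise ValueError("weights must be finite")
        if (np.abs(self.weights).sum(axis=0) == 0).any():
            raise ValueError("parcellation contains an all-zero parcel column")
        if not self.parcel_ids:
            self.parcel_ids = [f"parcel_{j + 1:02d}" for j in range(self.n_parcels)]
        if len(self.parcel_ids) != self.n_parcels:
            raise ValueError("parcel_ids length must match parcel count")

    @property
    def n_voxels(self) -> int:
        return self.weights.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.weights.shape[1]


@dataclass
class ParticipantTimeCourses:
    """Timepoints x parcels matrix of one participant's parcel time courses."""

    values: np.ndarray
    participant_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time courses must be a timepoints x parcels matrix")
        if not np.isfinite(self.values).all():
            raise ValueError("time courses must be finite")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.values.shape[1]


def _check_full_column_rank(mat: np.ndarray, what: str) -> None:
    if np.linalg.matrix_rank(mat, tol=None) < mat.shape[1]:
        raise ValueError(f"{what} are rank deficient; regression is unidentifiable")


def dual_regression_stage1(
    group_maps: WeightedParcellation,
    voxel_data: np.ndarray,
    demean: bool = True,
) -> ParticipantTimeCourses:
    """Regress each timepoint's voxel vector on the group maps (spatial OLS).

    ``voxel_data`` is voxels x timepoints. Voxel time series are
    de-meaned per voxel first (the constant component is not
    identifiable jointly with signed spatial maps). Output row t holds
    the parcel regression coefficients for timepoint t.
    """
    y = np.asarray(voxel_data, dtype=float)
    w = group_maps.weights
    if y.shape[0] != w.shape[0]:
        raise ValueError("voxel_data row count must match parcellation voxel count")
    _check_full_column_rank(w, "group map columns")
    if demean:
        y = y - y.mean(axis=1, keepdims=True)
    coefs, *_ = np.linalg.lstsq(w, y, rcond=_RCOND)
    return ParticipantTimeCourses(values=coefs.T)


def dual_regression_stage2(
    timecourses: ParticipantTimeCourses,
    voxel_data: np.ndarray,
    demean: bool = True,
) -> np.ndarray:
    """Regress each voxel's time series on the participant time courses.

    Returns participant-specific spatial maps, voxels x parcels.
    """
    y = np.asarray(voxel_data, dtype=float)
    a = timecourses.values
    if a.shape[0] < a.shape[1]:
        raise ValueError("fewer timepoints than parcels: stage 2 is underdetermined")
    if y.shape[1] != a.shape[0]:
        raise ValueError("voxel_data timepoint count must match time courses")
    _check_full_column_rank(a, "time courses")
    if demean:
        y = y - y.mean(axis=1, keepdims=True)
    coefs, *_ = np.linalg.lstsq(a, y.T, rcond=_RCOND)
    return coefs.T


def binarize_parcellation(
    group_maps: WeightedParcellation,
    threshold: float = 0.0,
) -> np.ndarray:
    """Assign each voxel to one parcel, removing overlap.

    A voxel goes to the parcel with the largest absolute weight,
    provided that weight strictly exceeds ``threshold``; otherwise the
    voxel is unassigned (label 0). Ties break to the lowest parcel
    index. Labels are 1-based.
    """
    aw = np.abs(group_maps.weights)
    best = np.argmax(aw, axis=1)  # first maximum -> lowest index on ties
    labels = best + 1
    labels[aw[np.arange(aw.shape[0]), best] <= threshold] = 0
    return labels


def extract_mask(
    group_maps: WeightedParcellation,
    parcel_id: int | str,
    threshold: float = 0.0,
) -> np.ndarray:
    """Binary voxel mask of one parcel: True where |weight| > threshold.

    ``parcel_id`` is a 1-based index or a parcel label. Used to
    restrict voxel data to a region before running a local
    sub-parcellation (the local decomposition itself is external).
    """
    if isinstance(parcel_id, str):
        if parcel_id not in group_maps.parcel_ids:
            raise KeyError(f"unknown parcel id {parcel_id!r}")
        j = group_maps.parcel_ids.index(parcel_id)
    else:
        j = int(parcel_id) - 1
        if not 0 <= j < group_maps.n_parcels:
            raise KeyError(f"unknown parcel index {parcel_id}")
    mask = np.abs(group_maps.weights[:, j]) > threshold
    if not mask.any():
        warnings.warn(f"mask for parcel {parcel_id} is empty at threshold {threshold}")
    return mask


def apply_mask(voxel_data: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Restrict a voxels x timepoints matrix to masked voxels, order preserved."""
    voxel_data = np.asarray(voxel_data)
    if voxel_data.shape[0] != mask.shape[0]:
        raise ValueError("mask length must match voxel count")
    return voxel_data[np.asarray(mask, dtype=bool)]


def parcel_mean_contrast(
    contrast_volume: np.ndarray,
    labels: np.ndarray,
    n_parcels: int | None = None,
) -> np.ndarray:
    """Summarize a per-voxel contrast as the mean within each labelled parcel.

    Entry j (1-based parcel j) is the arithmetic mean of contrast
    values over voxels labelled j. Parcels with no assigned voxels
    yield NaN with a warning. Raises if no voxel is assigned at all.
    """
    values = np.asarray(contrast_volume, dtype=float).ravel()
    labels = np.asarray(labels, dtype=int).ravel()
    if values.shape != labels.shape:
        raise ValueError("contrast volume and label map shapes must match")
    if n_parcels is None:
        n_parcels = int(labels.max())
    if (labels == 0).all() or n_parcels < 1:
        raise ValueError("label map assigns no voxel to any parcel")
    out = np.full(n_parcels, np.nan)
    for j in range(1, n_parcels + 1):
        sel = labels == j
        if sel.any():
            out[j - 1] = values[sel].mean()
        else:
            warnings.warn(f"parcel {j} has no assigned voxels; contrast entry is NaN")
    return out
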