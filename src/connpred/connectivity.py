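"""Fisher-z functional-connectivity features from parcel time courses.

Per participant: standardise each parcel time series, compute the full
pairwise Pearson correlation matrix, clip, and apply the Fisher
z-transform (atanh). Across participants: vectorise the strict upper
triangle of each matrix (row-major pair order) into a participants x
P(P-1)/2 feature matrix and z-score it column-wise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from connpred.parcellation import ParticipantTimeCourses

#: correlations are clipped to |r| <= 1 - CLIP_EPS before atanh so that
#: duplicated or degenerate series stay finite while preserving ordering
CLIP_EPS = 1e-7


@dataclass
class FCMatrix:
    """Symmetric P x P Fisher-z connectivity matrix, zero diagonal."""

    values: np.ndarray
    participant_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("FC matrix must be square")
        if not np.isfinite(v).all():
            raise ValueError("FC matrix must be finite")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("FC matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("FC matrix diagonal must be zero by convention")

    @property
    def n_parcels(self) -> int:
        return self.values.shape[0]


@dataclass
class FeatureMatrix:
    """Participants x P(P-1)/2 connectivity feature matrix.

    ``column_index`` holds the (i, j) parcel pairs (1-based, i < j) in
    row-major upper-triangle order. When ``standardized``, every
    non-degenerate column has mean 0 and unit sample variance.
    """

    values: np.ndarray
    column_index: list[tuple[int, int]]
    standardized: bool = True
    participant_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[1] != len(self.column_index):
            raise ValueError("column_index length must match feature count")

    @property
    def n_participants(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"p{i}_p{j}" for i, j in self.column_index]
        idx = self.participant_ids or list(range(self.values.shape[0]))
        df = pd.DataFrame(self.values, index=idx, columns=cols)
        df.index.name = "participant_id"
        return df


def fisher_z(r):
    """Fisher z-transform: clip correlations to |r| <= 1 - 1e-7, then atanh.

    Accepts scalars or arrays; raises for |r| > 1.
    """
    arr = np.asarray(r, dtype=float)
    if (np.abs(arr) > 1.0).any():
        raise ValueError("correlations must lie in [-1, 1]")
    z = np.arctanh(np.clip(arr, -1 + CLIP_EPS, 1 - CLIP_EPS))
    return z if arr.ndim else float(z)


def compute_fc_matrix(timecourses: ParticipantTimeCourses) -> FCMatrix:
    """Pairwise Fisher-z Pearson connectivity of one participant.

    Time series are z-scored per parcel, correlated, clipped, and
    atanh-transformed; the diagonal is set to 0 by convention. Constant
    parcel series make the correlation undefined and raise.
    """
    x = timecourses.values
    if x.shape[0] < 3:
        raise ValueError("need at least 3 timepoints to estimate correlations")
    sd = x.std(axis=0)
    if (sd == 0).any():
        bad = np.where(sd == 0)[0] + 1
        raise ValueError(f"constant time course in parcel(s) {bad.tolist()}: "
                         "correlation undefined")
    r = np.corrcoef(x, rowvar=False)
    z = np.arctanh(np.clip(r, -1 + CLIP_EPS, 1 - CLIP_EPS))
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0
    return FCMatrix(values=z, participant_id=timecourses.participant_id)


def upper_triangle_pairs(n_parcels: int) -> list[tuple[int, int]]:
    """Row-major strict-upper-triangle parcel pairs: (1,2),(1,3),...,(P-1,P)."""
    return [(i + 1, j + 1) for i in range(n_parcels) for j in range(i + 1, n_parcels)]


def build_feature_matrix(
    fc_set: list[FCMatrix],
    standardize: bool = True,
) -> FeatureMatrix:
    """Stack upper-triangle FC vectors across participants and z-score columns.

    One row per participant in input order; columns follow row-major
    upper-triangle order. Standardization uses the sample standard
    deviation (N-1 denominator) across the full cohort; zero-variance
    columns are set to all zeros with a warning.
    """
    if len(fc_set) < 2:
        raise ValueError("need at least 2 participants")
    p = fc_set[0].n_parcels
    if any(fc.n_parcels != p for fc in fc_set):
        raise ValueError("all FC matrices must have the same parcel count")
    iu = np.triu_indices(p, k=1)
    rows = np.stack([fc.values[iu] for fc in fc_set])
    if standardize:
        mu = rows.mean(axis=0)
        sd = rows.std(axis=0, ddof=1)
        degenerate = sd == 0
        if degenerate.any():
            warnings.warn(f"{int(degenerate.sum())} zero-variance feature column(s) "
                          "set to zeros")
        sd_safe = np.where(degenerate, 1.0, sd)
        rows = (rows - mu) / sd_safe
        rows[:, degenerate] = 0.0
    return FeatureMatrix(
        values=rows,
        column_index=upper_triangle_pairs(p),
        standardized=standardize,
        participant_ids=[fc.participant_id for fc in fc_set],
    )
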