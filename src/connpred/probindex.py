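"""Parcel-specific probabilistic index over randomized prediction accuracies.

Two complementary summaries of a parcels x runs accuracy table:

1. Gaussian tail flagging — fit a single normal distribution to all
   pooled correlation coefficients, z-score every cell against it, and
   count per parcel how many runs fall in the top tail (z > 1.96 by
   default, the printed two-sided 5% critical value).

2. Extreme-value probabilistic index — per parcel, form a robust
   "block maximum" as the 90% trimmed mean of its top 10% of z-scores,
   fit an extreme value distribution (Gumbel for maxima by default,
   GEV optional) across the parcels' block maxima, and report each
   parcel's upper-tail probability under that fit. Low values flag
   parcels that are robust positive outliers in prediction accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from connpred.prediction import AccuracyTable

DEFAULT_Z_CUT = 1.96
DEFAULT_TOP_FRACTION = 0.10
DEFAULT_TRIM_FRACTION = 0.90


@dataclass(frozen=True)
class GaussianParams:
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")


@dataclass
class ZTable:
    """Pooled z-scores of the accuracy table (same shape, NaN preserved)."""

    values: np.ndarray
    parcel_ids: list[str]


@dataclass
class BlockMaxVector:
    """Per-parcel robust block maxima of z-scored accuracies."""

    values: np.ndarray
    parcel_ids: list[str]
    top_fraction: float = DEFAULT_TOP_FRACTION
    trim_fraction: float = DEFAULT_TRIM_FRACTION
    effective_runs: np.ndarray | None = None


@dataclass(frozen=True)
class EVDParams:
    """Fitted extreme-value distribution.

    ``family`` is "gumbel" (max-Gumbel, the zero-shape block-maxima
    limit) or "gev"; ``shape`` is the scipy genextreme ``c`` parameter
    and is None for the Gumbel family.
    """

    family: str
    location: float
    scale: float
    shape: float | None = None
    log_likelihood: float | None = None

    def __post_init__(self) -> None:
        if self.family not in ("gumbel", "gev"):
            raise ValueError("family must be 'gumbel' or 'gev'")
        if not self.scale > 0:
            raise ValueError("scale must be > 0")

    def sf(self, x) -> np.ndarray:
        """Upper-tail probability P(Z >= x) under the fitted EVD."""
        if self.family == "gumbel":
            return stats.gumbel_r.sf(x, loc=self.location, scale=self.scale)
        return stats.genextreme.sf(x, self.shape, loc=self.location, scale=self.scale)


@dataclass
class ProbIndexVector:
    """Per-parcel EVD upper-tail probabilities; low = robustly best predicted."""

    values: np.ndarray
    parcel_ids: list[str]


def fit_pooled_gaussian(table: AccuracyTable) -> tuple[GaussianParams, ZTable]:
    """Fit one normal distribution to all pooled accuracy cells; z-score.

    Missing cells are excluded from pooling and propagate as NaN
    z-scores. Moments use the sample standard deviation.
    """
    vals = np.asarray(table.values, dtype=float)
    pooled = vals[~np.isnan(vals)]
    if pooled.size < 10:
        raise ValueError("need at least 10 non-missing accuracy cells")
    mu = float(pooled.mean())
    sigma = float(pooled.std(ddof=1))
    if sigma == 0:
        raise ValueError("degenerate accuracy table: zero pooled variance")
    params = GaussianParams(mu=mu, sigma=sigma)
    z = (vals - mu) / sigma
    return params, ZTable(values=z, parcel_ids=list(table.parcel_ids))


def tail_probability(r, params: GaussianParams):
    """Upper-tail probability 1 - Phi((r - mu) / sigma) of an accuracy value."""
    return stats.norm.sf(r, loc=params.mu, scale=params.sigma)


def count_top_tail(ztable: ZTable, z_cut: float = DEFAULT_Z_CUT) -> np.ndarray:
    """Per-parcel count of runs with z strictly greater than ``z_cut``.

    The default cutoff 1.96 is, strictly speaking, the two-sided 5%
    critical value (the one-sided 95th percentile is about 1.645); it
    is kept as the conventional top-5% flagging threshold and is
    configurable.
    """
    z = np.asarray(ztable.values, dtype=float)
    with np.errstate(invalid="ignore"):
        return np.nansum(z > z_cut, axis=1).astype(int)


def trimmed_mean(values, trim_fraction: float) -> float:
    """Symmetric trimmed mean: discard floor(n * f / 2) values from each end.

    Sorts ascending and averages what remains. If trimming would
    discard everything, falls back to the median with a warning (a
    singleton is always returned as-is).
    """
    v = np.sort(np.asarray(values, dtype=float).ravel())
    if v.size == 0:
        raise ValueError("trimmed_mean of empty input")
    if not 0.0 <= trim_fraction < 1.0:
        raise ValueError("trim_fraction must lie in [0, 1)")
    k = int(np.floor(v.size * trim_fraction / 2.0))
    if 2 * k >= v.size:
        warnings.warn("trim discards all values; falling back to the median")
        return float(np.median(v))
    return float(v[k:v.size - k].mean())


def block_maxima(
    ztable: ZTable,
    top_fraction: float = DEFAULT_TOP_FRACTION,
    trim_fraction: float = DEFAULT_TRIM_FRACTION,
) -> BlockMaxVector:
    """Robust per-parcel block maxima of z-scored accuracies.

    Per parcel: take the k = max(1, round(top_fraction * R)) largest
    z-scores over its non-missing runs, then apply the trimmed mean.
    With the defaults (top 10%, 90% trimmed) and 100 runs this
    averages the middle two of the parcel's ten best z-scores.
    """
    z = np.asarray(ztable.values, dtype=float)
    n_parcels = z.shape[0]
    out = np.empty(n_parcels)
    eff = np.empty(n_parcels, dtype=int)
    for j in range(n_parcels):
        row = z[j][~np.isnan(z[j])]
        if row.size == 0:
            raise ValueError(f"parcel {ztable.parcel_ids[j]} has no non-missing runs")
        eff[j] = row.size
        k = max(1, int(round(top_fraction * row.size)))
        top = np.sort(row)[-k:]
        out[j] = trimmed_mean(top, trim_fraction) if k > 1 else float(top[0])
    return BlockMaxVector(values=out, parcel_ids=list(ztable.parcel_ids),
                          top_fraction=top_fraction, trim_fraction=trim_fraction,
                          effective_runs=eff)


def fit_evd(block_max: BlockMaxVector, family: str = "gumbel") -> EVDParams:
    """Maximum-likelihood EVD fit to the parcel block maxima.

    Gumbel (max) by default — the classical zero-shape block-maxima
    limit; "gev" fits the generalized extreme value family. Requires
    at least 5 finite values with nonzero spread.
    """
    x = np.asarray(block_max.values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 5:
        raise ValueError("need at least 5 finite block maxima")
    if np.ptp(x) == 0:
        raise ValueError("degenerate block maxima: zero spread")
    if family == "gumbel":
        loc, scale = stats.gumbel_r.fit(x)
        ll = float(stats.gumbel_r.logpdf(x, loc=loc, scale=scale).sum())
        params = EVDParams(family="gumbel", location=float(loc), scale=float(scale),
                           log_likelihood=ll)
    elif family == "gev":
        c, loc, scale = stats.genextreme.fit(x)
        ll = float(stats.genextreme.logpdf(x, c, loc=loc, scale=scale).sum())
        params = EVDParams(family="gev", location=float(loc), scale=float(scale),
                           shape=float(c), log_likelihood=ll)
    else:
        raise ValueError("family must be 'gumbel' or 'gev'")
    if not np.isfinite(params.log_likelihood):
        raise RuntimeError("EVD fit did not converge to a finite likelihood")
    return params


def probability_index(block_max: BlockMaxVector, params: EVDParams) -> ProbIndexVector:
    """Upper-tail probability of each parcel's block maximum under the EVD.

    Low values mark parcels whose best runs are higher than the fitted
    extreme-value law across parcels would predict — the robustly
    best-predicted parcels.
    """
    vals = params.sf(np.asarray(block_max.values, dtype=float))
    return ProbIndexVector(values=np.asarray(vals, dtype=float),
                           parcel_ids=list(block_max.parcel_ids))
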