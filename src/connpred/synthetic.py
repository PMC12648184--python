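"""Seeded synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a resting-state fMRI study cohort at the parcel
level: weighted, overlapping group parcel maps (ICA-style), participant
rest time courses drawn from participant-specific perturbations of a
group connectivity template, and parcel-wise task-contrast vectors in
which a configurable subset of parcels carries a planted linear signal
from the connectivity features while the remaining parcels are pure
noise. Defaults follow the study design the pipeline targets: 52
participants, 22 parcels (25 ICA components minus 3 noise components),
597 rest timepoints.

Every generator is a pure function of (config, seed): identical inputs
give bit-identical cohorts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from connpred._utils import child_seeds, nearest_correlation, validate_correlation_matrix
from connpred.connectivity import FeatureMatrix, build_feature_matrix, compute_fc_matrix
from connpred.parcellation import ParticipantTimeCourses, WeightedParcellation

#: number of nonzero entries in each planted coefficient vector
N_ACTIVE_FEATURES = 10

#: default cross-parcel spillover of the synthetic group maps
DEFAULT_OVERLAP = 0.3

#: number of shared modes of inter-individual FC variability; cohort FC
#: deviations are dominated by a few population-level patterns rather
#: than independent edge-wise noise
N_FC_MODES = 5

#: fraction of participant FC deviation variance that is idiosyncratic
#: (edge-wise) rather than carried by the shared modes
FC_IDIO_FRACTION = 0.3


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a synthetic cohort.

    ``effect_strength`` is the target fraction of contrast variance
    explained by the connectivity features in signal parcels (0..1);
    ``fc_variability`` scales the participant-specific perturbation of
    the group FC template (applied on the Fisher-z scale);
    ``noise_sd`` is the residual-noise standard deviation, and setting
    it to 0 makes signal-parcel contrasts exact linear functions of the
    features.
    """

    n_participants: int = 52
    n_parcels: int = 22
    n_timepoints: int = 597
    n_voxels: int = 500
    signal_parcels: frozenset[int] = frozenset()
    effect_strength: float = 0.6
    noise_sd: float = 1.0
    fc_variability: float = 0.1
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 8:
            raise ValueError("n_participants must be >= 8")
        if self.n_parcels < 3:
            raise ValueError("n_parcels must be >= 3")
        if not 0.0 <= self.effect_strength <= 1.0:
            raise ValueError("effect_strength must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.fc_variability < 0:
            raise ValueError("fc_variability must be >= 0")
        sp = frozenset(int(j) for j in self.signal_parcels)
        if not sp <= set(range(1, self.n_parcels + 1)):
            raise ValueError("signal_parcels must be parcel indices in 1..n_parcels")
        object.__setattr__(self, "signal_parcels", sp)

    def to_dict(self) -> dict:
        return {
            "n_participants": self.n_participants,
            "n_parcels": self.n_parcels,
            "n_timepoints": self.n_timepoints,
            "n_voxels": self.n_voxels,
            "signal_parcels": sorted(self.signal_parcels),
            "effect_strength": self.effect_strength,
            "noise_sd": self.noise_sd,
            "fc_variability": self.fc_variability,
            "master_seed": self.master_seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        known = {
            "n_participants", "n_parcels", "n_timepoints", "n_voxels",
            "signal_parcels", "effect_strength", "noise_sd",
            "fc_variability", "master_seed",
        }
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown cohort config keys: {sorted(unknown)}")
        d = dict(d)
        if "signal_parcels" in d:
            d["signal_parcels"] = frozenset(int(j) for j in d["signal_parcels"])
        return cls(**d)


@dataclass
class SyntheticCohort:
    """A complete generated cohort plus its provenance."""

    group_maps: WeightedParcellation
    rest_timecourses: list[ParticipantTimeCourses]
    features: FeatureMatrix
    true_weights: dict[int, np.ndarray]
    contrasts: pd.DataFrame  # participants x parcels
    fc_template: np.ndarray
    provenance: dict


def generate_group_maps(
    n_voxels: int,
    n_parcels: int,
    overlap: float = DEFAULT_OVERLAP,
    seed: int = 0,
) -> WeightedParcellation:
    """Generate an ICA-style weighted parcellation over a synthetic voxel grid.

    Voxels are split into ``n_parcels`` contiguous blocks; each voxel
    carries a dominant positive weight for its own block's parcel, and
    ``overlap`` controls signed weight spillover onto the neighbouring
    parcels (overlap=0 gives an exactly block-diagonal weight matrix).
    The result always has full column rank.
    """
    if n_voxels < n_parcels:
        raise ValueError("n_voxels must be >= n_parcels (rank would be deficient)")
    if not 0.0 <= overlap <= 1.0:
        raise ValueError("overlap must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    bounds = np.linspace(0, n_voxels, n_parcels + 1).astype(int)
    weights = np.zeros((n_voxels, n_parcels))
    for j in range(n_parcels):
        lo, hi = bounds[j], bounds[j + 1]
        weights[lo:hi, j] = rng.uniform(0.6, 1.0, size=hi - lo)
        if overlap > 0:
            for nb in (j - 1, j + 1):
                if 0 <= nb < n_parcels:
                    spill = overlap * rng.uniform(0.2, 0.6, size=hi - lo)
                    spill *= rng.choice([-1.0, 1.0], size=hi - lo)
                    weights[lo:hi, nb] += spill
    parcel_ids = [f"parcel_{j + 1:02d}" for j in range(n_parcels)]
    return WeightedParcellation(weights=weights, parcel_ids=parcel_ids,
                                space_tag="synthetic-1d-grid")


def default_fc_template(n_parcels: int, seed: int = 0) -> np.ndarray:
    """A plausible group-level parcel correlation template.

    Low-rank factor structure (mimicking a few shared networks) shrunk
    toward the identity, projected to the nearest correlation matrix.
    Off-diagonal magnitudes land mostly in the 0-0.5 range typical of
    parcel-level resting-state connectivity.
    """
    rng = np.random.default_rng(seed)
    k = max(2, n_parcels // 4)
    f = rng.normal(size=(n_parcels, k))
    c = f @ f.T + np.eye(n_parcels) * k
    d = np.sqrt(np.diag(c))
    c = c / np.outer(d, d)
    c = 0.6 * c + 0.4 * np.eye(n_parcels)
    return nearest_correlation(c)


def generate_rest_timecourses(
    group_fc_template: np.ndarray,
    cohort: CohortConfig,
    seed: int = 0,
) -> list[ParticipantTimeCourses]:
    """Sample per-participant rest time courses around a group FC template.

    Each participant's population correlation is the template perturbed
    by a participant-specific symmetric deviation of scale
    ``cohort.fc_variability`` applied on the Fisher-z scale, then
    projected back to a valid correlation matrix. The deviation is
    mostly low-dimensional — participant-specific loadings on
    ``N_FC_MODES`` shared edge patterns drawn once per cohort — plus an
    idiosyncratic edge-wise component (``FC_IDIO_FRACTION`` of the
    deviation variance), emulating the dominant shared modes of
    inter-individual connectivity variation seen in real cohorts. Time
    courses are i.i.d. Gaussian draws from the participant correlation,
    so empirical correlations converge to the participant target as
    the number of timepoints grows.
    """
    template = validate_correlation_matrix(group_fc_template)
    p = template.shape[0]
    if p != cohort.n_parcels:
        raise ValueError("template size must match cohort.n_parcels")
    seeds = child_seeds(seed, cohort.n_participants + 1)
    out = []
    iu = np.triu_indices(p, k=1)
    n_edges = len(iu[0])
    z_template = np.arctanh(np.clip(template[iu], -1 + 1e-7, 1 - 1e-7))
    mode_rng = np.random.default_rng(seeds[0])
    modes = mode_rng.normal(size=(N_FC_MODES, n_edges)) / np.sqrt(N_FC_MODES)
    shared_scale = np.sqrt(1.0 - FC_IDIO_FRACTION)
    idio_scale = np.sqrt(FC_IDIO_FRACTION)
    for i in range(cohort.n_participants):
        rng = np.random.default_rng(seeds[i + 1])
        loadings = rng.normal(size=N_FC_MODES)
        deviation = (shared_scale * loadings @ modes
                     + idio_scale * rng.normal(size=n_edges))
        z = z_template + cohort.fc_variability * deviation
        target = np.eye(p)
        target[iu] = np.tanh(z)
        target = target + np.triu(target, k=1).T
        target = nearest_correlation(target)
        chol = np.linalg.cholesky(target)
        data = rng.normal(size=(cohort.n_timepoints, p)) @ chol.T
        out.append(ParticipantTimeCourses(values=data, participant_id=f"sub-{i + 1:03d}"))
    return out


def plant_linear_effects(
    features: FeatureMatrix,
    cohort: CohortConfig,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[int, np.ndarray]]:
    """Build contrast vectors with planted linear effects in signal parcels.

    For each signal parcel j the contrast column is ``X @ w_j + eps``
    with a sparse unit-norm coefficient vector ``w_j`` (10 nonzero
    features) and noise variance solved analytically so the feature
    term explains ``effect_strength`` of the column variance. All other
    parcels are pure noise with matching variance. ``noise_sd = 0``
    suppresses the noise entirely, making signal columns exact linear
    functions of the features.

    Returns the participants x parcels contrast table and the planted
    coefficient vectors keyed by 1-based parcel index.
    """
    x = np.asarray(features.values, dtype=float)
    n, n_feat = x.shape
    if n != cohort.n_participants:
        raise ValueError("feature row count must equal n_participants")
    e = cohort.effect_strength
    rng = np.random.default_rng(seed)
    contrasts = np.zeros((n, cohort.n_parcels))
    true_weights: dict[int, np.ndarray] = {}
    signal_sds: list[float] = []
    for j in sorted(cohort.signal_parcels):
        k = min(N_ACTIVE_FEATURES, n_feat)
        idx = rng.choice(n_feat, size=k, replace=False)
        w = np.zeros(n_feat)
        w[idx] = rng.normal(size=k)
        w /= np.linalg.norm(w)
        s = x @ w
        vs = float(np.var(s, ddof=1))
        if cohort.noise_sd == 0 or e >= 1.0:
            col = s
        elif e == 0.0:
            col = cohort.noise_sd * rng.normal(size=n)
        else:
            vn = vs * (1.0 - e) / e
            col = s + np.sqrt(vn) * rng.normal(size=n)
        contrasts[:, j - 1] = col
        true_weights[j] = w
        signal_sds.append(float(np.std(col, ddof=1)))
    null_sd = float(np.mean(signal_sds)) if signal_sds else cohort.noise_sd
    for j in range(1, cohort.n_parcels + 1):
        if j not in cohort.signal_parcels:
            contrasts[:, j - 1] = null_sd * rng.normal(size=n)
    table = pd.DataFrame(
        contrasts,
        index=[f"sub-{i + 1:03d}" for i in range(n)],
        columns=[f"parcel_{j:02d}" for j in range(1, cohort.n_parcels + 1)],
    )
    table.index.name = "participant_id"
    return table, true_weights


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a complete cohort: maps, time courses, features, contrasts.

    Stage seeds are derived from ``config.master_seed`` by SeedSequence
    spawning (maps, template, time courses, effects, in that order), so
    the cohort is bit-identical for identical config + seed.
    """
    seeds = child_seeds(config.master_seed, 4)
    maps = generate_group_maps(config.n_voxels, config.n_parcels, seed=seeds[0])
    template = default_fc_template(config.n_parcels, seed=seeds[1])
    tcs = generate_rest_timecourses(template, config, seed=seeds[2])
    features = build_feature_matrix([compute_fc_matrix(tc) for tc in tcs])
    contrasts, true_weights = plant_linear_effects(features, config, seed=seeds[3])
    provenance = {
        "config": config.to_dict(),
        "stage_seeds": {
            "group_maps": seeds[0],
            "fc_template": seeds[1],
            "rest_timecourses": seeds[2],
            "planted_effects": seeds[3],
        },
    }
    return SyntheticCohort(
        group_maps=maps,
        rest_timecourses=tcs,
        features=features,
        true_weights=true_weights,
        contrasts=contrasts,
        fc_template=template,
        provenance=provenance,
    )


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> None:
    """Serialize a cohort: one TSV per participant time course, a contrast
    table, and a JSON provenance record."""
    out = Path(out_dir)
    tc_dir = out / "timecourses"
    tc_dir.mkdir(parents=True, exist_ok=True)
    parcel_ids = cohort.group_maps.parcel_ids
    for tc in cohort.rest_timecourses:
        df = pd.DataFrame(tc.values, columns=parcel_ids)
        df.to_csv(tc_dir / f"{tc.participant_id}_timecourses.tsv", sep="\t", index=False)
    cohort.contrasts.to_csv(out / "contrasts.tsv", sep="\t")
    with open(out / "provenance.json", "w") as fh:
        json.dump(cohort.provenance, fh, indent=2)


def read_contrasts(path: str | Path) -> pd.DataFrame:
    """Read a participants x parcels contrast table written by write_cohort."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        warnings.warn(f"empty contrast table at {path}")
    return df
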