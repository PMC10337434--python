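"""Longitudinal-table preprocessing: hourly binning, sample-and-hold
imputation, normality transform and standardization, horizon snapshots.

The pipeline mirrors common ED data-abstraction practice: dynamic variables
are binned at hourly intervals (median within a bin), statics are held
constant after initial abstraction, missing bins are filled by carrying the
last observation forward, and series never observed during the stay receive
the global population mean. Features then undergo a normality transform
(log1p for right-skewed nonnegative variables) and standardization against
a frozen reference (derivation) cohort, so external cohorts are processed
under the derivation-cohort parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .schema import SchemaError, VariableSchema, default_schema
from .simulate import CohortBundle

__all__ = [
    "HourlyGrid",
    "NormalizationParams",
    "FeatureMatrix",
    "bin_hourly",
    "impute",
    "fit_normalizer",
    "snapshot",
    "CohortPreprocessor",
    "OBSERVED",
    "HELD",
    "MEAN_IMPUTED",
]

N_BINS = 7  # hour bins [0,1), [1,2), ..., [6,7); measurements lie in [0, 6]

# imputation-mask codes
OBSERVED = 0
HELD = 1
MEAN_IMPUTED = 2
MASK_NAMES = {OBSERVED: "observed", HELD: "held", MEAN_IMPUTED: "mean_imputed"}

SKEW_THRESHOLD = 1.0
SD_FLOOR = 1e-8


@dataclass
class HourlyGrid:
    """Patients x variables x hour-bins array with an observation mask.

    ``values`` holds NaN where a bin has no observation; ``observed`` is 1
    exactly where at least one raw measurement fell in the bin (statics are
    marked observed in every bin once abstracted).
    """

    values: np.ndarray          # (n_patients, n_vars, N_BINS)
    observed: np.ndarray        # same shape, bool
    patient_ids: np.ndarray
    variables: list[str]

    @property
    def n_patients(self) -> int:
        return self.values.shape[0]

    def copy(self) -> "HourlyGrid":
        return HourlyGrid(self.values.copy(), self.observed.copy(),
                          self.patient_ids.copy(), list(self.variables))


@dataclass
class NormalizationParams:
    """Frozen per-variable preprocessing parameters.

    ``transform`` is ``"identity"`` or ``"log1p"`` (chosen by sample skewness
    of the observed raw values: log1p when skewness > 1 and the variable is
    nonnegative). ``population_mean`` is on the raw (pre-transform) scale and
    backs the never-observed/leading-bin imputation rule; ``mean``/``sd``
    standardize the transformed snapshot and are fitted on the reference
    cohort at ``fit_horizon`` only.
    """

    variables: list[str]
    transform: list[str]
    population_mean: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    fit_horizon: int = 3

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.sd) < SD_FLOOR):
            raise ValueError(f"sd below floor {SD_FLOOR}")

    def to_json(self, path) -> None:
        payload = {
            "schema_version": 1,
            "fit_horizon": int(self.fit_horizon),
            "variables": list(self.variables),
            "transform": list(self.transform),
            "population_mean": np.asarray(self.population_mean).tolist(),
            "mean": np.asarray(self.mean).tolist(),
            "sd": np.asarray(self.sd).tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "NormalizationParams":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            variables=d["variables"],
            transform=d["transform"],
            population_mean=np.asarray(d["population_mean"], float),
            mean=np.asarray(d["mean"], float),
            sd=np.asarray(d["sd"], float),
            fit_horizon=d.get("fit_horizon", 3),
        )


@dataclass
class FeatureMatrix:
    """Standardized per-horizon snapshot with an imputation mask.

    ``values`` has no missing entries. ``mask`` codes are 0=observed (a raw
    measurement fell in the snapshot bin), 1=held (carried forward from an
    earlier bin), 2=mean-imputed (no observation up to the horizon).
    """

    values: pd.DataFrame        # index patient_id, columns variables
    mask: pd.DataFrame          # same shape, int codes
    horizon: int

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("feature matrix contains missing values")


# --------------------------------------------------------------------------


def _horizon_bin(horizon: int) -> int:
    """The snapshot uses the bin *ending* at the horizon: [h-1, h)."""
    if horizon not in (3, 6):
        raise ValueError(f"horizon must be 3 or 6, got {horizon}")
    return horizon - 1


def bin_hourly(measurements: pd.DataFrame, statics: pd.DataFrame | None = None,
               schema: VariableSchema | None = None) -> HourlyGrid:
    """Bin raw longitudinal measurements onto the hourly grid.

    Bins are half-open ``[h, h+1)`` in hours since triage; a bin containing
    multiple values takes their median. Statics are broadcast to every bin
    (held constant after initial abstraction). Variables not present in the
    schema raise :class:`SchemaError`.
    """
    schema = schema or default_schema()
    names = schema.names
    name_to_col = {n: j for j, n in enumerate(names)}

    frames = [df for df in (measurements, statics) if df is not None and len(df)]
    seen = set()
    for df in frames:
        seen.update(df["variable"].unique())
    unknown = seen - set(names)
    if unknown:
        raise SchemaError(f"unknown variables: {sorted(unknown)}")

    ids = np.unique(np.concatenate([
        np.asarray(df["patient_id"]) for df in frames
    ])) if frames else np.array([], dtype=np.int64)
    id_to_row = {p: i for i, p in enumerate(ids)}
    n = len(ids)

    values = np.full((n, len(names), N_BINS), np.nan)
    observed = np.zeros((n, len(names), N_BINS), dtype=bool)

    if measurements is not None and len(measurements):
        m = measurements.copy()
        if (m["hours_since_triage"] < 0).any():
            raise ValueError("hours_since_triage must be >= 0")
        m["bin"] = np.floor(m["hours_since_triage"]).astype(int).clip(upper=N_BINS - 1)
        med = (m.groupby(["patient_id", "variable", "bin"], sort=False)["value"]
                .median().reset_index())
        r = med["patient_id"].map(id_to_row).to_numpy()
        c = med["variable"].map(name_to_col).to_numpy()
        b = med["bin"].to_numpy()
        values[r, c, b] = med["value"].to_numpy()
        observed[r, c, b] = True

    if statics is not None and len(statics):
        r = statics["patient_id"].map(id_to_row).to_numpy()
        c = statics["variable"].map(name_to_col).to_numpy()
        values[r, c, :] = statics["value"].to_numpy()[:, None]
        observed[r, c, :] = True

    return HourlyGrid(values, observed, ids, list(names))


def impute(grid: HourlyGrid, params: NormalizationParams) -> HourlyGrid:
    """Sample-and-hold plus population-mean imputation (raw units).

    Within each patient x variable series, missing bins after the first
    observation carry the last observed value forward; bins before the first
    observation — and entirely unobserved series — receive the population
    mean. Observed bins are returned unchanged; the output has no missing
    entries. Idempotent.
    """
    missing_vars = set(grid.variables) - set(params.variables)
    if missing_vars:
        raise SchemaError(f"normalizer lacks variables: {sorted(missing_vars)}")
    col = {v: i for i, v in enumerate(params.variables)}
    pop = np.asarray(params.population_mean, float)[[col[v] for v in grid.variables]]

    out = grid.copy()
    vals, obs = out.values, out.observed
    # forward-fill along the bin axis: index of last observed bin <= t
    idx = np.where(obs, np.arange(N_BINS)[None, None, :], -1)
    ffill_idx = np.maximum.accumulate(idx, axis=2)
    has_prior = ffill_idx >= 0
    filled = np.take_along_axis(vals, np.clip(ffill_idx, 0, None), axis=2)
    vals[:] = np.where(has_prior, filled, pop[None, :, None])
    return out


def fit_normalizer(reference: HourlyGrid, horizon: int = 3,
                   skew_threshold: float = SKEW_THRESHOLD) -> NormalizationParams:
    """Fit frozen preprocessing parameters on a reference cohort.

    Transform choice and population means come from the observed raw values
    (all bins pooled); the standardization moments are computed on the
    imputed, transformed snapshot at ``horizon``, so reference-cohort
    snapshot columns standardize to exactly mean 0 / SD 1.
    """
    if reference.n_patients == 0:
        raise ValueError("reference grid is empty")

    n_vars = len(reference.variables)
    transform = []
    pop_mean = np.empty(n_vars)
    for j in range(n_vars):
        observed_vals = reference.values[:, j, :][reference.observed[:, j, :]]
        if observed_vals.size == 0:
            transform.append("identity")
            pop_mean[j] = 0.0
            continue
        pop_mean[j] = float(np.mean(observed_vals))
        skew = stats.skew(observed_vals) if observed_vals.size > 2 else 0.0
        nonneg = observed_vals.min() >= 0
        transform.append("log1p" if (skew > skew_threshold and nonneg) else "identity")

    params = NormalizationParams(
        variables=list(reference.variables),
        transform=transform,
        population_mean=pop_mean,
        mean=np.zeros(n_vars),
        sd=np.ones(n_vars),
        fit_horizon=horizon,
    )
    imputed = impute(reference, params)
    snap = imputed.values[:, :, _horizon_bin(horizon)]
    snap = _apply_transform(snap, transform)
    params.mean = snap.mean(axis=0)
    params.sd = np.maximum(snap.std(axis=0, ddof=0), SD_FLOOR)
    return params


def _apply_transform(x: np.ndarray, transform: list[str]) -> np.ndarray:
    out = x.astype(float).copy()
    for j, t in enumerate(transform):
        if t == "log1p":
            out[:, j] = np.log1p(np.maximum(out[:, j], 0.0))
    return out


def snapshot(grid: HourlyGrid, params: NormalizationParams,
             horizon: int) -> FeatureMatrix:
    """Standardized feature snapshot at a 3 h or 6 h horizon.

    Takes the imputed value in the bin ending at the horizon, applies the
    fitted transform and standardization, and records per-entry imputation
    provenance (observed / held / mean-imputed).
    """
    b = _horizon_bin(horizon)
    if list(grid.variables) != list(params.variables):
        raise SchemaError("grid/normalizer variable sets differ")
    imputed = impute(grid, params)
    vals = _apply_transform(imputed.values[:, :, b], params.transform)
    vals = (vals - np.asarray(params.mean)) / np.asarray(params.sd)

    obs_now = grid.observed[:, :, b]
    obs_before = grid.observed[:, :, : b + 1].any(axis=2)
    mask = np.full(obs_now.shape, MEAN_IMPUTED, dtype=np.int8)
    mask[obs_before] = HELD
    mask[obs_now] = OBSERVED

    values_df = pd.DataFrame(vals, index=pd.Index(grid.patient_ids, name="patient_id"),
                             columns=grid.variables)
    mask_df = pd.DataFrame(mask, index=values_df.index, columns=grid.variables)
    return FeatureMatrix(values_df, mask_df, horizon)


# --------------------------------------------------------------------------


class CohortPreprocessor(BaseEstimator):
    """Estimator wrapper over the preprocessing chain.

    ``fit`` bins the reference (derivation) cohort and freezes the
    normalizer; ``transform`` maps any cohort bundle to a standardized
    :class:`FeatureMatrix` at the requested horizon under the frozen
    reference parameters (external-validation discipline).

    Parameters
    ----------
    schema : VariableSchema, optional
        Variable contract; defaults to the 40-variable schema.
    fit_horizon : int, default 3
        Horizon whose snapshot defines the standardization moments.
    skew_threshold : float, default 1.0
        Sample-skewness cutoff above which a nonnegative variable is
        log1p-transformed.
    """

    def __init__(self, schema: VariableSchema | None = None,
                 fit_horizon: int = 3, skew_threshold: float = SKEW_THRESHOLD):
        self.schema = schema
        self.fit_horizon = fit_horizon
        self.skew_threshold = skew_threshold

    def fit(self, bundle: CohortBundle, y=None) -> "CohortPreprocessor":
        grid = bin_hourly(bundle.measurements, bundle.statics,
                          self.schema or default_schema())
        self.normalizer_ = fit_normalizer(grid, self.fit_horizon,
                                          self.skew_threshold)
        return self

    def transform(self, bundle: CohortBundle, horizon: int = 3) -> FeatureMatrix:
        if not hasattr(self, "normalizer_"):
            raise RuntimeError("CohortPreprocessor is not fitted")
        grid = bin_hourly(bundle.measurements, bundle.statics,
                          self.schema or default_schema())
        return snapshot(grid, self.normalizer_, horizon)

    def fit_transform(self, bundle: CohortBundle, y=None,
                      horizon: int = 3) -> FeatureMatrix:
        return self.fit(bundle).transform(bundle, horizon)
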