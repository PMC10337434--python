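"""Synthetic emergency-department sepsis cohort generator.

Real ED sepsis cohorts of this kind are hospital EHR extracts and are not
public, so this module generates cohorts carrying the latent
structure the analysis pipeline assumes, together with ground truth for
recovery tests:

* four latent phenotypes ``z3`` (state at 3 h after triage) with the
  published prevalences and per-phenotype outcome rates;
* phenotype-dependent intervention propensities (early antibiotics, early
  fluids, >=30 mL/kg fluid volume);
* a 3 h -> 6 h latent transition ``z6`` drawn from a multinomial-logistic
  (softmax) kernel whose logits shift with the interventions received;
  the baseline logits are calibrated so that the *marginal* kernel has an
  overall transition fraction of 45% and a rarest transition (low-risk to
  high-risk phenotype) of 1.2%;
* hourly measurement series per variable, AR(1) around phenotype-specific
  means, thinned by phenotype-dependent observation gates (e.g. lactate is
  ordered far more often in the sicker phenotypes);
* a non-septic control stratum of "attenuated twins": each control is
  drawn around a phenotype mean profile pulled toward the population base
  (dysfunction scaled by ``control_attenuation``). Infection-negative ED
  patients vary along the same organ-system axes as septic ones, only less
  deranged — and this geometry forces a sepsis-vs-control classifier to
  learn every phenotype's dysfunction direction rather than a single
  discriminative axis, which is what makes its representations useful for
  phenotype clustering.

All randomness flows through one seeded :class:`numpy.random.Generator`;
identical ``(config, n, seed)`` triples yield byte-identical CSV exports.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schema import DYNAMIC, STATIC, VariableSchema, default_schema

__all__ = [
    "GeneratorConfig",
    "CohortBundle",
    "default_config",
    "generate_cohort",
    "planted_representations",
]

N_PHENOTYPES = 4
N_BINS = 7  # hour bins 0..6, each [h, h+1)

INTERVENTIONS = ("abx_3h", "fluids_3h", "fluids_ge_30mlkg")
OUTCOMES = ("mortality", "hospice", "septic_shock", "aki", "mech_vent")

# Severity score per phenotype: P2 is the healthiest, P3 the sickest,
# matching the published outcome ordering P2 < P1 < P4 < P3.
_SEVERITY = np.array([0.5, 0.0, 1.0, 0.7])


@dataclass(frozen=True)
class GeneratorConfig:
    """Full parameterisation of the synthetic cohort.

    ``transition_logits`` are *baseline* softmax logits (no interventions);
    intervention coefficients shift the destination logits additively on the
    log-odds scale. ``missingness`` holds, per variable x phenotype, the
    probability that the variable is measured at all during the 6 h window
    (measured patients are guaranteed one observation within the first
    three hour bins, mimicking the initial ED workup).
    """

    schema: VariableSchema
    prevalences: np.ndarray                    # (4,) simplex
    phenotype_means: np.ndarray                # (4, 40) model-scale means
    control_attenuation: float                 # dysfunction scale of controls
    base_locs: np.ndarray                      # (40,) model-scale centres
    unit_scales: np.ndarray                    # (40,) model-scale spreads
    within_scale: float = 1.0
    autocorr: float = 0.7
    separation: float = 8.0
    intervention_propensities: dict = field(default_factory=dict)
    abx_late_propensities: np.ndarray = None   # P(abx in (3,6] | no abx_3h)
    transition_logits: np.ndarray = None       # (4, 4) baseline logits
    intervention_coefficients: dict = field(default_factory=dict)
    outcome_rates: dict = field(default_factory=dict)
    missingness: np.ndarray = None             # (40, 4) observation gates
    control_fraction: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        p = np.asarray(self.prevalences, float)
        if p.shape != (N_PHENOTYPES,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-8:
            raise ValueError("prevalences must be a 4-point simplex")
        if not 0.0 <= self.control_fraction < 1.0:
            raise ValueError("control_fraction must be in [0, 1)")
        if not 0.0 <= self.autocorr < 1.0:
            raise ValueError("autocorr must be in [0, 1)")
        if self.missingness is not None:
            m = np.asarray(self.missingness, float)
            if np.any(m < 0) or np.any(m > 1):
                raise ValueError("missingness entries must be probabilities")
        for name, rates in self.outcome_rates.items():
            r = np.asarray(rates, float)
            if np.any(r < 0) or np.any(r > 1):
                raise ValueError(f"outcome rates for {name} outside [0, 1]")
        kernel = _softmax(np.asarray(self.transition_logits, float))
        if not np.allclose(kernel.sum(axis=1), 1.0):
            raise ValueError("transition kernel rows must sum to 1")

    def replace(self, **kwargs) -> "GeneratorConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class CohortBundle:
    """Linked long/wide tables describing one synthetic cohort.

    ``truth`` carries the latent states (``z3``, ``z6`` in 1..4; 0 for the
    control stratum) and the control indicator, for recovery tests only —
    the analysis pipeline never reads it.
    """

    measurements: pd.DataFrame  # patient_id, variable, hours_since_triage, value
    statics: pd.DataFrame       # patient_id, variable, value
    interventions: pd.DataFrame
    outcomes: pd.DataFrame
    truth: pd.DataFrame | None = None

    @property
    def patient_ids(self) -> np.ndarray:
        return self.statics["patient_id"].unique()

    def septic_ids(self) -> np.ndarray:
        if self.truth is None:
            return self.patient_ids
        t = self.truth
        return t.loc[t["is_control"] == 0, "patient_id"].to_numpy()

    def to_csv(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.measurements.to_csv(out / "measurements.csv", index=False)
        self.statics.to_csv(out / "statics.csv", index=False)
        self.interventions.to_csv(out / "interventions.csv", index=False)
        self.outcomes.to_csv(out / "outcomes.csv", index=False)
        if self.truth is not None:
            self.truth.to_csv(out / "truth.csv", index=False)

    @classmethod
    def from_csv(cls, indir) -> "CohortBundle":
        from pathlib import Path

        ind = Path(indir)
        truth = None
        if (ind / "truth.csv").exists():
            truth = pd.read_csv(ind / "truth.csv")
        return cls(
            measurements=pd.read_csv(ind / "measurements.csv"),
            statics=pd.read_csv(ind / "statics.csv"),
            interventions=pd.read_csv(ind / "interventions.csv"),
            outcomes=pd.read_csv(ind / "outcomes.csv"),
            truth=truth,
        )


# --------------------------------------------------------------------------
# default configuration (calibrated to the published cohort summaries)
# --------------------------------------------------------------------------

def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _target_kernel() -> np.ndarray:
    """Marginal 3h->6h kernel the defaults are calibrated to.

    Every diagonal is 0.55 (overall transition fraction 45% regardless of
    the prevalence mix); off-diagonal mass favours transitions between
    phenotypes of similar severity, with the low-risk -> high-risk move
    (P2 -> P3) rarest at 1.2%.
    """
    return np.array(
        [
            [0.550, 0.200, 0.050, 0.200],
            [0.360, 0.550, 0.012, 0.078],
            [0.070, 0.030, 0.550, 0.350],
            [0.220, 0.080, 0.150, 0.550],
        ]
    )


def _intervention_weights(props: dict, source: int):
    """Enumerate (abx, fluids, fluids30) combinations and their probability
    for one source phenotype. fluids30 is nested within fluids."""
    pa = props["abx_3h"][source]
    pf = props["fluids_3h"][source]
    pg = props["fluids_ge_30mlkg"][source]
    combos = []
    for a in (0, 1):
        wa = pa if a else 1.0 - pa
        combos.append(((a, 0, 0), wa * (1.0 - pf)))
        combos.append(((a, 1, 0), wa * pf * (1.0 - pg)))
        combos.append(((a, 1, 1), wa * pf * pg))
    return combos


def _calibrate_base_logits(target: np.ndarray, props: dict, coefs: dict,
                           n_iter: int = 400) -> np.ndarray:
    """Solve for baseline logits whose intervention-marginal kernel equals
    ``target`` (iterative proportional fitting on the log scale)."""
    b = np.log(target)
    betas = {k: np.asarray(v, float) for k, v in coefs.items()}
    for _ in range(n_iter):
        expected = np.empty_like(b)
        for i in range(N_PHENOTYPES):
            acc = np.zeros(N_PHENOTYPES)
            for (a, f, g), w in _intervention_weights(props, i):
                logits = (
                    b[i]
                    + a * betas["abx_3h"]
                    + f * betas["fluids_3h"]
                    + g * betas["fluids_ge_30mlkg"]
                )
                acc += w * _softmax(logits)
            expected[i] = acc
        b = b + np.log(target) - np.log(expected)
        b = b - b.mean(axis=1, keepdims=True)
    return b


def default_config(schema: VariableSchema | None = None, *,
                   separation: float = 8.0,
                   intervention_coefficients: dict | None = None,
                   control_fraction: float = 0.25,
                   seed: int = 0) -> GeneratorConfig:
    """Default generator calibrated to the published cohort summaries.

    Calibration anchors: phenotype prevalences (33.8/13.6/16.6/36.0%),
    per-phenotype mortality (4.8/1.7/9.4/7.8%) and the other adverse-outcome
    rates; early-antibiotic propensities (52.8/37.0/86.4/71.4%); lactate
    measurement fractions (67.6/35.6/97.4/88.6%); marginal transition
    fraction 45% with rarest transition P2->P3 at 1.2%; Table-3-style
    intervention effects on destination logits.
    """
    schema = schema or default_schema()
    if len(schema) == 0:
        raise ValueError("schema must contain at least one variable")

    prevalences = np.array([0.338, 0.136, 0.166, 0.360])

    # --- per-variable model-scale geometry -------------------------------
    locs = np.empty(len(schema))
    scales = np.empty(len(schema))
    base_p = {"sex_male": 0.565}  # binary statics: baseline probability
    for j, v in enumerate(schema):
        lo, hi = v.plausible_range
        if v.family == "lognormal":
            locs[j] = 0.5 * (np.log(lo) + np.log(hi))
            scales[j] = (np.log(hi) - np.log(lo)) / 10.0
        elif v.family == "binary":
            p = base_p.get(v.name, 0.5)
            locs[j] = np.log(p / (1 - p))
            scales[j] = 0.6
        else:
            locs[j] = 0.5 * (lo + hi)
            scales[j] = (hi - lo) / 10.0

    # Fixed severity loadings and phenotype-specific offsets; frozen draws
    # so the mean geometry is part of the default configuration itself.
    mean_rng = np.random.default_rng(20230623)
    loadings = mean_rng.normal(0.0, 1.0, size=len(schema))
    idiosync = mean_rng.normal(0.0, 0.6, size=(N_PHENOTYPES, len(schema)))
    amp = separation / 10.0
    phen_means = locs[None, :] + amp * scales[None, :] * (
        _SEVERITY[:, None] * loadings[None, :] + idiosync
    )

    props = {
        # early-antibiotic shares per phenotype (development-site table)
        "abx_3h": np.array([0.5283, 0.3704, 0.8640, 0.7136]),
        "fluids_3h": np.array([0.92, 0.75, 0.995, 0.98]),
        # conditional on receiving fluids; marginal ~26%
        "fluids_ge_30mlkg": np.array([0.20, 0.08, 0.50, 0.32]),
    }
    # P(abx in (3,6] | none by 3 h), matching 6 h antibiotic shares
    abx_late = np.array([0.651, 0.648, 0.727, 0.691])

    if intervention_coefficients is None:
        intervention_coefficients = {
            "abx_3h": np.log([1.024, 1.438, 0.955, 0.75]),
            "fluids_3h": np.log([0.876, 1.106, 0.801, 1.09]),
            "fluids_ge_30mlkg": np.log([1.067, 0.938, 1.227, 0.908]),
        }
    else:
        intervention_coefficients = {
            k: np.asarray(v, float) for k, v in intervention_coefficients.items()
        }

    base_logits = _calibrate_base_logits(
        _target_kernel(), props, intervention_coefficients
    )

    outcome_rates = {
        "mortality": np.array([0.048, 0.017, 0.094, 0.078]),
        "hospice": np.array([0.0051, 0.0045, 0.0099, 0.0094]),
        "septic_shock": np.array([0.0650, 0.0237, 0.2395, 0.1216]),
        "aki": np.array([0.2834, 0.2514, 0.3703, 0.3071]),
        "mech_vent": np.array([0.0797, 0.0416, 0.1177, 0.0947]),
    }

    # --- observation gates (prob. the variable is measured at all) -------
    missing = np.empty((len(schema), N_PHENOTYPES))
    sev_centered = _SEVERITY - _SEVERITY.mean()
    for j, v in enumerate(schema):
        if v.kind == STATIC:
            missing[j] = 1.0
        elif v.hourly_rate >= 0.7:          # vitals: near-universal
            missing[j] = 0.99
        elif v.hourly_rate >= 0.25:         # common panels
            missing[j] = np.clip(0.90 + 0.08 * sev_centered, 0.0, 0.995)
        else:                               # specialised labs, severity-gated
            missing[j] = np.clip(0.50 + 0.45 * sev_centered, 0.02, 0.99)
    missing[schema.index("lactate")] = [0.676, 0.3557, 0.9744, 0.8861]

    cfg = GeneratorConfig(
        schema=schema,
        prevalences=prevalences,
        phenotype_means=phen_means,
        control_attenuation=0.5,
        base_locs=locs,
        unit_scales=scales,
        separation=separation,
        intervention_propensities=props,
        abx_late_propensities=abx_late,
        transition_logits=base_logits,
        intervention_coefficients=intervention_coefficients,
        outcome_rates=outcome_rates,
        missingness=missing,
        control_fraction=control_fraction,
        seed=seed,
    )
    cfg.validate()
    return cfg


# --------------------------------------------------------------------------
# latent-state simulation
# --------------------------------------------------------------------------

def _categorical_rows(rng: np.random.Generator, probs: np.ndarray) -> np.ndarray:
    """Draw one category per row of a row-stochastic matrix (0-based)."""
    u = rng.random(probs.shape[0])
    return (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)


def simulate_latents(config: GeneratorConfig, n: int, rng: np.random.Generator):
    """Draw the latent layer only: (z3, interventions dict, z6, outcomes).

    z3/z6 are 0-based internally. Orders of magnitude faster than
    :func:`generate_cohort`; used for large-replicate statistical checks.
    """
    p = np.asarray(config.prevalences, float)
    z3 = _categorical_rows(rng, np.tile(p, (n, 1)))

    props = config.intervention_propensities
    abx = rng.random(n) < np.asarray(props["abx_3h"])[z3]
    fl = rng.random(n) < np.asarray(props["fluids_3h"])[z3]
    fl30 = fl & (rng.random(n) < np.asarray(props["fluids_ge_30mlkg"])[z3])

    coefs = config.intervention_coefficients
    logits = np.asarray(config.transition_logits, float)[z3].copy()
    logits += abx[:, None] * np.asarray(coefs["abx_3h"], float)
    logits += fl[:, None] * np.asarray(coefs["fluids_3h"], float)
    logits += fl30[:, None] * np.asarray(coefs["fluids_ge_30mlkg"], float)
    z6 = _categorical_rows(rng, _softmax(logits))

    outcomes = {}
    mort = rng.random(n) < np.asarray(config.outcome_rates["mortality"], float)[z3]
    outcomes["mortality"] = mort.astype(np.int64)
    for name in OUTCOMES:
        if name == "mortality":
            continue
        draw = rng.random(n) < np.asarray(config.outcome_rates[name], float)[z3]
        if name == "hospice":
            draw = draw & ~mort  # hospice only among survivors (exclusive)
        outcomes[name] = draw.astype(np.int64)

    interventions = {
        "abx_3h": abx.astype(np.int64),
        "fluids_3h": fl.astype(np.int64),
        "fluids_ge_30mlkg": fl30.astype(np.int64),
    }
    return z3, interventions, z6, outcomes


# --------------------------------------------------------------------------
# full cohort generation
# --------------------------------------------------------------------------

def _ar1_series(rng, mu3, mu6, sd, a, n_bins=N_BINS):
    """AR(1) trajectories: bins 0..3 revert to the 3 h phenotype mean, bins
    4..6 revert to the 6 h phenotype mean (so late snapshots carry the
    post-transition state). Stationary marginal SD equals ``sd``."""
    n = mu3.shape[0]
    innov_sd = sd * np.sqrt(1.0 - a * a)
    x = np.empty((n, n_bins))
    x[:, 0] = mu3 + sd * rng.standard_normal(n)
    for t in range(1, n_bins):
        mu = mu3 if t <= 3 else mu6
        x[:, t] = mu + a * (x[:, t - 1] - mu) + innov_sd * rng.standard_normal(n)
    return x


def generate_cohort(config: GeneratorConfig, n: int, seed: int) -> CohortBundle:
    """Generate a cohort with ``n`` septic patients (plus a control stratum).

    The control stratum size is ``n * control_fraction / (1-control_fraction)``
    so controls make up ``control_fraction`` of the full cohort. Septic
    measurement times lie in [0, 6) hours since triage.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([seed, config.seed]))

    n_ctrl = int(round(n * config.control_fraction / (1.0 - config.control_fraction)))
    z3, interventions, z6, outcomes = simulate_latents(config, n, rng)

    schema = config.schema
    names = schema.names
    septic_ids = np.arange(1, n + 1)
    control_ids = np.arange(n + 1, n + n_ctrl + 1)
    all_ids = np.concatenate([septic_ids, control_ids])
    n_all = n + n_ctrl

    # controls: attenuated twins of the phenotype profiles
    zc = _categorical_rows(rng, np.tile(np.asarray(config.prevalences, float),
                                        (n_ctrl, 1)))
    gamma = float(config.control_attenuation)
    ctrl_means = (config.base_locs[None, :]
                  + gamma * (config.phenotype_means[zc] - config.base_locs[None, :]))

    # model-scale means for every patient (row) and variable (column)
    mu3 = np.vstack([config.phenotype_means[z3], ctrl_means]) if n_all else \
        np.empty((0, len(schema)))
    mu6 = np.vstack([config.phenotype_means[z6], ctrl_means]) if n_all else \
        np.empty((0, len(schema)))

    sds = config.within_scale * np.asarray(config.unit_scales, float)

    # observation gates per patient x variable
    gate_probs = np.empty((n_all, len(schema)))
    miss = np.asarray(config.missingness, float)
    for j in range(len(schema)):
        gate_probs[:n, j] = miss[j][z3]
        gate_probs[n:, j] = miss[j][zc]   # controls: twin phenotype's ordering

    meas_frames = []
    static_frames = []
    for j, v in enumerate(schema):
        if v.kind == STATIC:
            latent = mu3[:, j] + sds[j] * rng.standard_normal(n_all)
            if v.family == "binary":
                vals = (rng.random(n_all) < 1.0 / (1.0 + np.exp(-latent))).astype(float)
            elif v.family == "lognormal":
                vals = np.exp(latent)
            else:
                vals = latent
            static_frames.append(pd.DataFrame(
                {"patient_id": all_ids, "variable": v.name, "value": vals}
            ))
            continue

        series = _ar1_series(rng, mu3[:, j], mu6[:, j], sds[j], config.autocorr)
        if v.family == "lognormal":
            series = np.exp(series)

        gated = rng.random(n_all) < gate_probs[:, j]
        obs = rng.random((n_all, 6)) < v.hourly_rate  # bins 0..5 observable
        first = rng.integers(0, 3, size=n_all)        # guaranteed early draw
        obs[np.arange(n_all), first] = True
        obs &= gated[:, None]

        pat_idx, bin_idx = np.nonzero(obs)
        if len(pat_idx) == 0:
            continue
        times = bin_idx + rng.random(len(bin_idx))    # within-bin offset
        meas_frames.append(pd.DataFrame(
            {
                "patient_id": all_ids[pat_idx],
                "variable": v.name,
                "hours_since_triage": times,
                "value": series[pat_idx, bin_idx],
            }
        ))

    cols_m = ["patient_id", "variable", "hours_since_triage", "value"]
    measurements = (
        pd.concat(meas_frames, ignore_index=True)
        .sort_values(["patient_id", "variable", "hours_since_triage"],
                     kind="mergesort")
        .reset_index(drop=True)
        if meas_frames else pd.DataFrame(columns=cols_m)
    )
    statics = (
        pd.concat(static_frames, ignore_index=True)
        .sort_values(["patient_id", "variable"], kind="mergesort")
        .reset_index(drop=True)
        if static_frames else pd.DataFrame(columns=["patient_id", "variable", "value"])
    )

    # intervention timing; controls receive no sepsis interventions
    abx = interventions["abx_3h"].astype(bool)
    late = (~abx) & (rng.random(n) < np.asarray(config.abx_late_propensities)[z3])
    t_abx = np.full(n, np.nan)
    t_abx[abx] = rng.uniform(0.25, 3.0, abx.sum())
    t_abx[late] = rng.uniform(3.0, 6.0, late.sum())
    fl = interventions["fluids_3h"].astype(bool)
    t_fl = np.full(n, np.nan)
    t_fl[fl] = rng.uniform(0.1, 3.0, fl.sum())

    interventions_df = pd.DataFrame(
        {
            "patient_id": all_ids,
            "abx_3h": np.concatenate([interventions["abx_3h"], np.zeros(n_ctrl, np.int64)]),
            "fluids_3h": np.concatenate([interventions["fluids_3h"], np.zeros(n_ctrl, np.int64)]),
            "fluids_ge_30mlkg": np.concatenate(
                [interventions["fluids_ge_30mlkg"], np.zeros(n_ctrl, np.int64)]
            ),
            "time_to_abx_h": np.concatenate([t_abx, np.full(n_ctrl, np.nan)]),
            "time_to_fluids_h": np.concatenate([t_fl, np.full(n_ctrl, np.nan)]),
        }
    )
    outcomes_df = pd.DataFrame({"patient_id": all_ids} | {
        k: np.concatenate([v, np.zeros(n_ctrl, np.int64)]) for k, v in outcomes.items()
    })
    truth = pd.DataFrame(
        {
            "patient_id": all_ids,
            "z3": np.concatenate([z3 + 1, np.zeros(n_ctrl, np.int64)]),
            "z6": np.concatenate([z6 + 1, np.zeros(n_ctrl, np.int64)]),
            "is_control": np.concatenate(
                [np.zeros(n, np.int64), np.ones(n_ctrl, np.int64)]
            ),
        }
    )
    return CohortBundle(measurements, statics, interventions_df, outcomes_df, truth)


# --------------------------------------------------------------------------
# planted representation-space blobs (clustering test harness)
# --------------------------------------------------------------------------

def planted_representations(config: GeneratorConfig, n: int, seed: int,
                            dim: int = 10):
    """Four isotropic unit-variance Gaussian blobs in ``dim`` dimensions at
    pairwise centroid distance ``config.separation``; cluster sizes follow
    ``config.prevalences``. Returns ``(X, labels)`` with labels in 1..4.

    This bypasses the encoder and gives clustering code a ground-truth
    representation space with known geometry.
    """
    if n < 4:
        raise ValueError("n must be >= 4")
    if dim < 2:
        raise ValueError("dim must be >= 2")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 77, config.seed]))
    # regular 3-simplex with unit pairwise distances, embedded in dim >= 3
    simplex = np.array(
        [
            [1.0, 1.0, 1.0],
            [1.0, -1.0, -1.0],
            [-1.0, 1.0, -1.0],
            [-1.0, -1.0, 1.0],
        ]
    ) / (2.0 * np.sqrt(2.0))
    centers = np.zeros((N_PHENOTYPES, dim))
    centers[:, :3] = simplex * config.separation
    z = _categorical_rows(rng, np.tile(np.asarray(config.prevalences), (n, 1)))
    X = centers[z] + rng.standard_normal((n, dim))
    return X, z + 1
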