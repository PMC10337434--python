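"""Phenotype transition structure and intervention-effect models.

Phenotype dynamics over the first six ED hours are modeled as a one-step
Markov decision process: the 3 h phenotype is the state, the intervention
vector (antibiotics within 3 h, fluids within 3 h, fluid volume >= 30
mL/kg) is the action, and the 6 h phenotype is the next state. Two views
are fitted:

* the empirical 4x4 transition matrix (counts, row-normalized
  probabilities, and the overall fraction of patients changing phenotype);
* logistic regressions of each possible destination ("lands in phenotype j
  at 6 h", one-vs-rest) on the three intervention indicators plus dummies
  for the source phenotype (P1 is the reference category), optionally with
  extra physiological covariates — the M1..M4 destination models — and the
  sixteen pairwise models obtained by stratifying on the source phenotype
  with interventions as the only regressors.

Because the four destination models are fitted independently, their
predicted probabilities need not sum to one and are deliberately not
renormalized. Fits are maximum likelihood via iteratively reweighted least
squares with Wald 95% confidence intervals; no multiplicity correction is
applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

__all__ = [
    "TransitionMatrix",
    "estimate_transition_matrix",
    "fit_destination_models",
    "fit_pairwise_models",
    "PhenotypeTransitionModel",
    "transition_diagram_dot",
]

N_STATES = 4
INTERVENTION_COLS = ["abx_3h", "fluids_3h", "fluids_ge_30mlkg"]
SEPARATION_BOUND = 15.0   # |coef| beyond this flags (quasi-)separation
MAX_ITER = 100
GRAD_TOL = 1e-8


@dataclass
class TransitionMatrix:
    counts: np.ndarray          # (K, K) int
    probabilities: np.ndarray   # (K, K) rows sum to 1 where occupied
    source_totals: np.ndarray   # (K,) int
    transition_fraction: float  # 1 - trace(counts) / n

    @property
    def n_states(self) -> int:
        return self.counts.shape[0]

    def to_frame(self) -> pd.DataFrame:
        idx = [f"P{i}" for i in range(1, self.n_states + 1)]
        rows = []
        for kind, mat in (("count", self.counts), ("probability", self.probabilities)):
            df = pd.DataFrame(mat, index=idx, columns=idx)
            df.insert(0, "kind", kind)
            rows.append(df.rename_axis("source").reset_index())
        return pd.concat(rows, ignore_index=True)


def _check_labels(labels, name: str, n_states: int = N_STATES) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be 1-d")
    if arr.size and (arr.min() < 1 or arr.max() > n_states):
        raise ValueError(f"{name} must lie in 1..{n_states}")
    return arr.astype(np.int64)


def _n_states(labels3, labels6, n_states: int | None) -> int:
    if n_states is not None:
        return int(n_states)
    hi = max((np.max(labels3, initial=1)), (np.max(labels6, initial=1)))
    return max(N_STATES, int(hi))


def estimate_transition_matrix(labels3, labels6,
                               n_states: int | None = None) -> TransitionMatrix:
    """Cross-tabulate paired 3 h / 6 h phenotype labels.

    Probabilities are row-normalized counts; rows with no patients stay
    zero. ``transition_fraction`` is the share of patients whose 6 h
    phenotype differs from their 3 h phenotype. The state space is 1..4 by
    default, widened automatically if larger labels are present.
    """
    K = _n_states(np.asarray(labels3), np.asarray(labels6), n_states)
    a = _check_labels(labels3, "labels3", K)
    b = _check_labels(labels6, "labels6", K)
    if a.shape != b.shape:
        raise ValueError("labels3 and labels6 must pair the same patients")
    counts = np.zeros((K, K), dtype=np.int64)
    np.add.at(counts, (a - 1, b - 1), 1)
    totals = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = np.where(totals[:, None] > 0, counts / totals[:, None], 0.0)
    frac = 1.0 - np.trace(counts) / a.size if a.size else 0.0
    return TransitionMatrix(counts, probs, totals, float(frac))


# --------------------------------------------------------------------------


def _fit_one_logit(X: pd.DataFrame, y: np.ndarray, model_id: str) -> pd.DataFrame:
    """One binomial GLM (IRLS) -> tidy coefficient table with Wald CIs."""
    design = sm.add_constant(X.astype(float), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.GLM(y, design, family=sm.families.Binomial()).fit(
            maxiter=MAX_ITER, tol=GRAD_TOL
        )
    converged = bool(fit.converged)
    params = fit.params
    sep_flag = bool(np.any(np.abs(params.to_numpy()) > SEPARATION_BOUND))
    if not converged:
        warnings.warn(f"{model_id}: IRLS did not converge in {MAX_ITER} iterations")
    if sep_flag:
        warnings.warn(f"{model_id}: possible complete separation (|coef| > "
                      f"{SEPARATION_BOUND})")
    ci = fit.conf_int(alpha=0.05)
    out = pd.DataFrame(
        {
            "model": model_id,
            "term": params.index,
            "coef": params.to_numpy(),
            "odds_ratio": np.exp(params.to_numpy()),
            "ci_low": np.exp(ci[0].to_numpy()),
            "ci_high": np.exp(ci[1].to_numpy()),
            "p_value": fit.pvalues.to_numpy(),
            "converged": converged,
            "separation_flag": sep_flag,
            "n_used": int(len(y)),
        }
    )
    return out.reset_index(drop=True)


def _design_frame(labels3: np.ndarray, interventions: pd.DataFrame,
                  covariates: pd.DataFrame | None,
                  include_source_dummies: bool,
                  n_states: int = N_STATES) -> pd.DataFrame:
    X = interventions[INTERVENTION_COLS].reset_index(drop=True).astype(float)
    if include_source_dummies:
        for s in range(2, n_states + 1):   # P1 is the reference category
            X[f"source_P{s}"] = (labels3 == s).astype(float)
    if covariates is not None:
        cov = covariates.reset_index(drop=True).astype(float)
        X = pd.concat([X, cov], axis=1)
    return X


def fit_destination_models(labels3, labels6, interventions: pd.DataFrame,
                           covariates: pd.DataFrame | None = None) -> pd.DataFrame:
    """The four one-vs-rest destination models M1..M4 as a tidy table.

    Outcome of model Mj: patient lands in phenotype j at 6 h. Regressors:
    the three intervention indicators, dummies for source phenotypes
    P2/P3/P4, and any extra covariates supplied.
    """
    K = _n_states(np.asarray(labels3), np.asarray(labels6), None)
    a = _check_labels(labels3, "labels3", K)
    b = _check_labels(labels6, "labels6", K)
    X = _design_frame(a, interventions, covariates,
                      include_source_dummies=True, n_states=K)
    if len(X) < X.shape[1] + 11:
        raise ValueError("too few observations for the number of parameters")
    tables = [
        _fit_one_logit(X, (b == j).astype(float), f"M{j}")
        for j in range(1, K + 1)
    ]
    return pd.concat(tables, ignore_index=True)


def fit_pairwise_models(labels3, labels6,
                        interventions: pd.DataFrame) -> pd.DataFrame:
    """The 16 source->destination models: within each source stratum, four
    logistic fits of "lands in j" on the interventions alone. Empty source
    strata are skipped with a warning."""
    K = _n_states(np.asarray(labels3), np.asarray(labels6), None)
    a = _check_labels(labels3, "labels3", K)
    b = _check_labels(labels6, "labels6", K)
    iv = interventions.reset_index(drop=True)
    tables = []
    for i in range(1, K + 1):
        sel = a == i
        if not sel.any():
            warnings.warn(f"source P{i} has no patients; models skipped")
            continue
        Xi = iv.loc[sel, INTERVENTION_COLS].reset_index(drop=True).astype(float)
        bi = b[sel]
        for j in range(1, K + 1):
            tables.append(_fit_one_logit(Xi, (bi == j).astype(float),
                                         f"P{i}->P{j}"))
    return pd.concat(tables, ignore_index=True)


# --------------------------------------------------------------------------


class PhenotypeTransitionModel(BaseEstimator):
    """Estimator facade: fit the transition MDP from a design frame.

    ``fit(X, y)`` expects ``X`` with a ``source`` column (3 h phenotype,
    1..4) plus the intervention columns (and optional covariate columns
    named in ``covariate_columns``), and ``y`` the 6 h phenotype labels.

    Attributes after fitting: ``transition_matrix_``,
    ``destination_models_`` (tidy M1..M4 table), ``pairwise_models_``
    (16-model table).
    """

    def __init__(self, covariate_columns: list[str] | None = None,
                 fit_pairwise: bool = True):
        self.covariate_columns = covariate_columns
        self.fit_pairwise = fit_pairwise

    def fit(self, X: pd.DataFrame, y) -> "PhenotypeTransitionModel":
        K = _n_states(np.asarray(X["source"]), np.asarray(y), None)
        labels3 = _check_labels(X["source"], "source", K)
        labels6 = _check_labels(y, "y", K)
        self.n_states_ = K
        cov = X[list(self.covariate_columns)] if self.covariate_columns else None
        self.transition_matrix_ = estimate_transition_matrix(labels3, labels6)
        self.destination_models_ = fit_destination_models(
            labels3, labels6, X, covariates=cov
        )
        if self.fit_pairwise:
            self.pairwise_models_ = fit_pairwise_models(labels3, labels6, X)
        return self

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Per-destination one-vs-rest probabilities (columns P1..P4).

        Rows need not sum to 1: the four models are independent fits.
        """
        if not hasattr(self, "destination_models_"):
            raise RuntimeError("model is not fitted")
        K = self.n_states_
        labels3 = _check_labels(X["source"], "source", K)
        cov = X[list(self.covariate_columns)] if self.covariate_columns else None
        D = _design_frame(labels3, X, cov, include_source_dummies=True, n_states=K)
        D = sm.add_constant(D.astype(float), has_constant="add")
        out = np.empty((len(D), K))
        for j in range(1, K + 1):
            tab = self.destination_models_.query(f"model == 'M{j}'")
            coefs = tab.set_index("term")["coef"].reindex(D.columns).fillna(0.0)
            eta = D.to_numpy() @ coefs.to_numpy()
            out[:, j - 1] = 1.0 / (1.0 + np.exp(-eta))
        return out


def transition_diagram_dot(tm: TransitionMatrix, min_probability: float = 0.0) -> str:
    """DOT-format transition diagram; edge penwidth scales with probability."""
    K = tm.n_states
    lines = ["digraph transitions {", "  rankdir=LR;"]
    for i in range(K):
        lines.append(f'  P{i + 1} [shape=circle];')
    for i in range(K):
        for j in range(K):
            p = tm.probabilities[i, j]
            if p >= min_probability and tm.source_totals[i] > 0:
                width = 0.5 + 6.0 * p
                lines.append(
                    f'  P{i + 1} -> P{j + 1} [penwidth={width:.2f}, '
                    f'label="{p:.3f}"];'
                )
    lines.append("}")
    return "\n".join(lines)
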