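# sepsisdyn

Dynamic sepsis phenotyping for early emergency-department (ED) care:
derive data-driven patient subgroups ("phenotypes") from the first hours
of EHR data, and model how patients move between them as a function of
the treatments they receive.

Sepsis is heterogeneous, and a single treatment bundle (timely
antibiotics, a 30 mL/kg fluid bolus) may not fit every patient. Published
work on ED sepsis cohorts derives four phenotypes P1–P4 within six hours
of triage and finds that membership is *dynamic* — roughly 45% of
patients change phenotype between 3 h and 6 h — with transitions that
correlate with early interventions. This package implements that analysis
end to end as a tested, reusable pipeline:

1. **Preprocessing** — hourly median binning of longitudinal
   measurements, sample-and-hold imputation with population-mean
   back-fill, per-variable normality transforms (`log1p` by skewness),
   and standardization frozen on the derivation cohort.
2. **Representation learning** — a feed-forward network trained to
   discriminate septic patients from non-septic controls; its
   penultimate-layer read-out is the clustering space.
3. **Consensus spectral clustering** — Ng–Jordan–Weiss spectral
   clustering with Gaussian similarity inside a Monti-style resampling
   loop; the number of clusters is chosen from the consensus CDF
   (PAC rule by default, delta-area rule available), and final labels
   come from the consensus matrix itself.
4. **Markov transition modeling** — the 4×4 3 h → 6 h transition matrix,
   plus one-vs-rest logistic models (M1–M4) of each destination on three
   intervention indicators (antibiotics ≤ 3 h, fluids ≤ 3 h,
   fluids ≥ 30 mL/kg) and source-phenotype dummies, with Wald CIs; and
   the sixteen source-stratified pairwise models.
5. **kNN phenotype transfer** — similarity-weighted k-nearest-neighbour
   assignment under the same Gaussian metric, for the 6 h snapshot and
   external-validation cohorts, with profile-concordance reporting.

The cohorts such analyses run on are not public, so the package includes
a first-class **synthetic cohort generator** calibrated to the published
cohort summaries (phenotype prevalences 33.8/13.6/16.6/36.0%, mortality
4.8/1.7/9.4/7.8%, a 45% marginal transition fraction with the rarest
transition at 1.2%, phenotype-dependent antibiotic propensities and
lactate-measurement rates), with ground-truth latent states for recovery
testing. See `docs/methods.md` for the full model and its limitations.

## Worked example

```python
import numpy as np, pandas as pd
from sepsisdyn import (default_config, planted_representations,
                       consensus_cluster, ConsensusConfig,
                       generate_cohort, estimate_transition_matrix,
                       fit_destination_models)

cfg = default_config()

# --- cluster-number selection on planted representations -------------
X, z = planted_representations(cfg, 1500, seed=1)
res = consensus_cluster(X, ConsensusConfig(n_resamples=50, seed=1))
print(res.chosen_k)                      # 4
print({k: round(v, 3) for k, v in res.pac.items()})
# {2: 0.446, 3: 0.0, 4: 0.0, 5: 0.106, 6: 0.172}

# --- transition structure on a synthetic cohort ----------------------
b = generate_cohort(cfg, 5000, seed=1)
s = b.truth[b.truth.is_control == 0]
tm = estimate_transition_matrix(s.z3.to_numpy(), s.z6.to_numpy())
print(round(tm.transition_fraction, 3))  # 0.443

# --- planted intervention effect recovered ---------------------------
from sepsisdyn.simulate import simulate_latents
planted = default_config(intervention_coefficients={
    "abx_3h": [0, np.log(1.438), 0, 0],
    "fluids_3h": [0]*4, "fluids_ge_30mlkg": [0]*4})
z3, iv, z6, _ = simulate_latents(planted, 20000, np.random.default_rng(77))
Xd = pd.DataFrame(iv); Xd.insert(0, "source", z3 + 1)
row = (fit_destination_models(Xd["source"], z6 + 1, Xd)
       .query("model=='M2' and term=='abx_3h'").iloc[0])
print(round(row.odds_ratio, 3))          # 1.355  (95% CI 1.244-1.477)
```

Reading the output: the consensus CDF is unambiguous at k = 4 and k = 3
(PAC 0.0 — every pair of patients is either always or never
co-clustered) and the rule resolves the tie toward the finer stable
partition, k = 4, matching the planted structure exactly (ARI 1.0
against the latent labels). The cohort's 3 h → 6 h phenotype-change
fraction of 44.3% reflects the calibrated 45% kernel, and the planted
antibiotics effect on the lowest-mortality destination (odds ratio
1.438) is recovered at 1.355 with a confidence interval comfortably
inside the calibration anchor's interval.

## Command-line pipeline

```bash
sepsisdyn --seed 7 --outdir run all --n 2000
```

runs simulate → preprocess → encode → cluster → assign → transitions →
report and writes plain CSV/JSON artifacts (features and masks per
horizon, representations, labels, consensus series, transition tables,
destination/pairwise model tables, characterization and missingness
tables, a DOT transition diagram, and a manifest with the seed and config
hash). Stages can be run individually; a YAML file passed via `--config`
overrides stage defaults. Exit codes: 0 success, 2 configuration error,
3 data-contract violation.

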