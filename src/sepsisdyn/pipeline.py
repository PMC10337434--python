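"""End-to-end pipeline stages over a run directory.

Each stage reads the artifacts of the previous stage from ``outdir`` and
writes its own as plain CSV/JSON, so any stage can be re-run or inspected
in isolation. The canonical order is: simulate -> preprocess -> encode ->
cluster -> assign -> transitions -> report. Phenotypes are *derived* on
the 3 h snapshot of the septic stratum only; the 6 h snapshot (and any
external cohort) receives labels by Gaussian-similarity kNN against the
3 h reference, with the preprocessing normalizer and the encoder frozen
from the derivation cohort.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assign import GaussianKNNClassifier
from .cluster import ConsensusSpectralClustering
from .encoder import SepsisRepresentationEncoder
from .preprocess import CohortPreprocessor
from .report import characterize, missingness_by_cluster, summarize_outcomes
from .simulate import CohortBundle, default_config, generate_cohort
from .transitions import (
    estimate_transition_matrix,
    fit_destination_models,
    fit_pairwise_models,
    transition_diagram_dot,
)

log = logging.getLogger("sepsisdyn")

__all__ = ["run_simulate", "run_preprocess", "run_encode", "run_cluster",
           "run_assign", "run_transitions", "run_report", "run_all",
           "write_manifest"]


def write_manifest(outdir: Path, seed: int, config: dict, files: list[str]) -> None:
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    manifest = {
        "package": "sepsisdyn",
        "version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(payload).hexdigest(),
        "files": sorted(files),
        "library_versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(Path(outdir) / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def _cfg(config: dict | None, seed: int):
    config = config or {}
    sim = config.get("simulate", {})
    gc = default_config(
        separation=sim.get("separation", 8.0),
        control_fraction=sim.get("control_fraction", 0.25),
        seed=seed,
    )
    return gc, config


def run_simulate(outdir, seed: int, n: int = 2000,
                 config: dict | None = None) -> CohortBundle:
    out = Path(outdir) / "cohort"
    gc, config = _cfg(config, seed)
    n = (config.get("simulate", {}) or {}).get("n", n)
    bundle = generate_cohort(gc, n, seed)
    bundle.to_csv(out)
    log.info("simulated %d septic + %d control patients -> %s",
             len(bundle.septic_ids()), len(bundle.patient_ids) - len(bundle.septic_ids()), out)
    return bundle


def run_preprocess(outdir, config: dict | None = None) -> None:
    out = Path(outdir)
    bundle = CohortBundle.from_csv(out / "cohort")
    gc, _ = _cfg(config, 0)
    prep = CohortPreprocessor(schema=gc.schema).fit(bundle)
    prep.normalizer_.to_json(out / "normalizer.json")
    for horizon in (3, 6):
        fm = prep.transform(bundle, horizon=horizon)
        fm.values.to_csv(out / f"features_{horizon}h.csv")
        fm.mask.to_csv(out / f"masks_{horizon}h.csv")
    log.info("preprocessed features at 3 h and 6 h horizons")


def run_encode(outdir, seed: int, config: dict | None = None) -> None:
    out = Path(outdir)
    enc_cfg = (config or {}).get("encoder", {})
    feats3 = pd.read_csv(out / "features_3h.csv", index_col="patient_id")
    feats6 = pd.read_csv(out / "features_6h.csv", index_col="patient_id")
    truth = pd.read_csv(out / "cohort" / "truth.csv").set_index("patient_id")
    is_septic = 1 - truth.loc[feats3.index, "is_control"].to_numpy()
    enc = SepsisRepresentationEncoder(
        representation_dim=enc_cfg.get("representation_dim", 10),
        epochs=enc_cfg.get("epochs", 30),
        random_state=seed,
    ).fit(feats3.to_numpy(), is_septic)
    enc.save(out / "encoder_weights.npz")
    for name, feats in (("3h", feats3), ("6h", feats6)):
        rep = enc.transform(feats.to_numpy())
        pd.DataFrame(rep, index=feats.index).to_csv(out / f"representations_{name}.csv")
    log.info("trained encoder (final loss %.4f)", enc.training_history_[-1])


def run_cluster(outdir, seed: int, config: dict | None = None) -> None:
    out = Path(outdir)
    cl_cfg = (config or {}).get("cluster", {})
    space = cl_cfg.get("space", "representations")
    src = {"representations": "representations_3h.csv",
           "features": "features_3h.csv"}[space]
    rep3 = pd.read_csv(out / src, index_col="patient_id")
    truth = pd.read_csv(out / "cohort" / "truth.csv").set_index("patient_id")
    septic = truth.loc[rep3.index, "is_control"] == 0
    X = rep3[septic].to_numpy()
    model = ConsensusSpectralClustering(
        n_resamples=cl_cfg.get("n_resamples", 50),
        k_range=tuple(cl_cfg.get("k_range", (2, 6))),
        random_state=seed,
    ).fit(X)
    labels = pd.DataFrame(
        {"patient_id": rep3.index[septic], "phenotype": model.labels_}
    )
    labels.to_csv(out / "labels_3h.csv", index=False)
    series = pd.DataFrame(
        {
            "k": model.result_.k_values,
            "area": [model.areas_[k] for k in model.result_.k_values],
            "delta": [model.deltas_[k] for k in model.result_.k_values],
            "pac": [model.pac_[k] for k in model.result_.k_values],
        }
    )
    series.to_csv(out / "consensus_series.csv", index=False)
    pd.DataFrame({"chosen_k": [model.n_clusters_]}).to_csv(
        out / "chosen_k.csv", index=False
    )
    if cl_cfg.get("write_consensus", False):
        # dense CSV of the chosen-k consensus matrix; large at big n
        M = model.result_.consensus[model.n_clusters_]
        pd.DataFrame(M, index=rep3.index[septic],
                     columns=rep3.index[septic]).to_csv(
            out / f"consensus_k{model.n_clusters_}.csv")
    log.info("consensus clustering chose k=%d", model.n_clusters_)


def run_assign(outdir, config: dict | None = None) -> None:
    out = Path(outdir)
    kn_cfg = (config or {}).get("assign", {})
    space = ((config or {}).get("cluster", {})).get("space", "representations")
    stem = "representations" if space == "representations" else "features"
    rep3 = pd.read_csv(out / f"{stem}_3h.csv", index_col="patient_id")
    rep6 = pd.read_csv(out / f"{stem}_6h.csv", index_col="patient_id")
    labels3 = pd.read_csv(out / "labels_3h.csv").set_index("patient_id")["phenotype"]
    ref = rep3.loc[labels3.index]
    clf = GaussianKNNClassifier(n_neighbors=kn_cfg.get("n_neighbors", 15))
    clf.fit(ref.to_numpy(), labels3.to_numpy())
    query = rep6.loc[labels3.index]
    lab6, conf = clf.predict(query.to_numpy(), return_confidence=True)
    pd.DataFrame(
        {"patient_id": query.index, "phenotype": lab6, "mean_topk_similarity": conf}
    ).to_csv(out / "labels_6h.csv", index=False)
    log.info("assigned 6 h phenotypes to %d patients", len(lab6))


def run_transitions(outdir, config: dict | None = None) -> None:
    out = Path(outdir)
    lab3 = pd.read_csv(out / "labels_3h.csv").set_index("patient_id")["phenotype"]
    lab6 = pd.read_csv(out / "labels_6h.csv").set_index("patient_id")["phenotype"]
    iv = pd.read_csv(out / "cohort" / "interventions.csv").set_index("patient_id")
    ids = lab3.index
    tm = estimate_transition_matrix(lab3.to_numpy(), lab6.loc[ids].to_numpy())
    tm.to_frame().to_csv(out / "transitions.csv", index=False)
    (out / "transitions.dot").write_text(transition_diagram_dot(tm))
    dest = fit_destination_models(lab3.to_numpy(), lab6.loc[ids].to_numpy(),
                                  iv.loc[ids])
    dest.to_csv(out / "models_destination.csv", index=False)
    pw = fit_pairwise_models(lab3.to_numpy(), lab6.loc[ids].to_numpy(), iv.loc[ids])
    pw.to_csv(out / "models_pairwise.csv", index=False)
    log.info("transition fraction %.3f", tm.transition_fraction)


def run_report(outdir, config: dict | None = None) -> None:
    out = Path(outdir)
    bundle = CohortBundle.from_csv(out / "cohort")
    lab3 = pd.read_csv(out / "labels_3h.csv").set_index("patient_id")["phenotype"]
    characterize(bundle, lab3).to_csv(out / "characterization.csv")
    septic_out = bundle.outcomes.set_index("patient_id").loc[lab3.index].reset_index()
    with open(out / "outcome_summary.json", "w") as fh:
        json.dump(summarize_outcomes(septic_out), fh, indent=1)
    masks = pd.read_csv(out / "masks_3h.csv", index_col="patient_id")
    missingness_by_cluster(masks.loc[lab3.index], lab3).to_csv(
        out / "missingness_by_cluster.csv"
    )
    log.info("wrote characterization, outcome summary and missingness tables")


def run_all(outdir, seed: int, n: int = 2000, config: dict | None = None) -> None:
    run_simulate(outdir, seed, n=n, config=config)
    run_preprocess(outdir, config=config)
    run_encode(outdir, seed, config=config)
    run_cluster(outdir, seed, config=config)
    run_assign(outdir, config=config)
    run_transitions(outdir, config=config)
    run_report(outdir, config=config)
    files = [p.name for p in Path(outdir).glob("*") if p.is_file()]
    write_manifest(Path(outdir), seed, config or {}, files)
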