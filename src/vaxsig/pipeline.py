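"""End-to-end pipeline: classes -> preprocess -> signatures -> NES -> model.

`run_pipeline` ties the stages together on a simulated cohort (or
datasets supplied by the caller), writes every artifact as plain text
and records a provenance JSON (versions, seeds, counts per stage).
Any stage failure is re-raised with the stage name attached.
"""

from __future__ import annotations

import json
import platform as _platform
from pathlib import Path

import numpy as np
import pandas as pd
import sklearn

from . import __version__
from .config import PipelineConfig
from .datasets import ExpressionDataset, write_response_table
from .ica import build_signature_db, make_decoy_sets, write_gmt
from .model import SignatureForestModel, build_nes_matrix
from .preprocess import preprocess_dataset
from .simulate import SimConfig, simulate_cohort, simulate_response_table
from .tcell import classify_vectors
from .validation import leave_one_out
from .utils import logger


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise StageError(f"stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


def run_pipeline(
    config: PipelineConfig,
    datasets: list[ExpressionDataset] | None = None,
    responses: pd.DataFrame | None = None,
) -> dict[str, str]:
    """Run the full pipeline; returns a dict of artifact paths.

    Without explicit inputs a synthetic cohort is simulated from
    ``config.sim`` (tetramer responses included), so the bundled demo
    preset runs end-to-end with no external data.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    prov: dict[str, object] = {
        "vaxsig": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "sklearn": sklearn.__version__,
        "python": _platform.python_version(),
        "seed": config.seed,
        "stages": {},
    }
    stages: dict = prov["stages"]  # type: ignore[assignment]

    # -- simulate (only when no datasets are supplied) ------------------
    truth = None
    if datasets is None:
        sim_cfg = SimConfig(**{**config.sim, "seed": config.stage_seed("simulate")})
        datasets, truth = _stage("simulate")(simulate_cohort)(sim_cfg)
        if responses is None:
            responses = simulate_response_table(
                sim_cfg, class_cv=config.class_cv, reference_vector=config.reference_vector
            )
        truth_path = outdir / "ground_truth.json"
        truth.to_json(truth_path)
        artifacts["ground_truth"] = str(truth_path)
        stages["simulate"] = {"n_datasets": len(datasets), "seed": sim_cfg.seed}
    if responses is None:
        raise StageError("stage 'classes' failed: no response table supplied")

    # -- T-cell classes --------------------------------------------------
    classing = _stage("classes")(classify_vectors)(
        responses, reference_vector=config.reference_vector, k=config.k_clusters
    )
    resp_path = outdir / "responses.tsv"
    write_response_table(responses, resp_path)
    classing_path = outdir / "classing.tsv"
    classing.to_csv(classing_path, sep="\t")
    artifacts["responses"] = str(resp_path)
    artifacts["classing"] = str(classing_path)
    labels = dict(classing["class"])
    missing = [ds.vector_id for ds in datasets if ds.vector_id not in labels]
    if missing:
        raise StageError(
            f"stage 'classes' failed: no T-cell class for training vectors {missing}"
        )
    stages["classes"] = {
        "n_vectors": len(classing),
        "n_weak": int((classing["class"] == "Weak").sum()),
        "n_strong": int((classing["class"] == "Strong").sum()),
    }

    # -- preprocessing ---------------------------------------------------
    pre = [
        _stage("preprocess")(preprocess_dataset)(ds, alpha=config.alpha) for ds in datasets
    ]
    stages["preprocess"] = {ds.dataset_id: int(ds.values.shape[0]) for ds in pre}

    # -- signature database ---------------------------------------------
    db = _stage("signatures")(build_signature_db)(
        pre,
        n_components=config.n_components,
        z_threshold=config.z_threshold,
        min_genes=config.min_genes,
        seed=config.stage_seed("signatures"),
    )
    gmt_path = outdir / "signatures.gmt"
    write_gmt(db, gmt_path)
    artifacts["signatures"] = str(gmt_path)
    decoys = []
    if config.n_decoys:
        universe = sorted({g for ds in pre for g in ds.values.index})
        lo, hi = config.decoy_sizes
        decoys = make_decoy_sets(
            universe,
            range(lo, min(hi, len(universe)) + 1),
            config.n_decoys,
            seed=config.stage_seed("decoys"),
        )
    stages["signatures"] = {"n_signatures": len(db), "n_decoys": len(decoys)}

    # -- NES feature matrix ----------------------------------------------
    nes = _stage("nes")(build_nes_matrix)(
        pre,
        db,
        B=config.B,
        seed=config.stage_seed("nes"),
        n_perm=config.n_perm,
        weight=config.gsea_weight,
        min_genes=config.min_genes,
        labels=labels,
        decoys=decoys,
        paired=config.paired,
    )
    nes_path = outdir / "nes_matrix.tsv"
    nes.to_tsv(nes_path)
    artifacts["nes_matrix"] = str(nes_path)
    stages["nes"] = {"rows": int(nes.values.shape[0]), "columns": int(nes.values.shape[1])}

    # -- model ------------------------------------------------------------
    results = _stage("train")(
        lambda: SignatureForestModel(
            nes, labels=labels, n_trees=config.n_trees, mtry=config.mtry
        ).fit(seed=config.stage_seed("train"))
    )()
    model_path = outdir / "model.pkl"
    results.save(model_path)
    artifacts["model"] = str(model_path)
    importance = results.importance_ranking(config.importance_threshold)
    imp_path = outdir / "importance.tsv"
    importance.to_csv(imp_path, sep="\t")
    artifacts["importance"] = str(imp_path)
    predictions = results.prediction_table(nes)
    pred_path = outdir / "predictions.tsv"
    predictions.to_csv(pred_path, sep="\t")
    artifacts["predictions"] = str(pred_path)
    metrics = results.metrics(nes, labels)
    metrics_path = outdir / "metrics.tsv"
    metrics.to_csv(metrics_path, sep="\t")
    artifacts["metrics"] = str(metrics_path)
    stages["train"] = {
        "oob_error": results.oob_error,
        "n_important": int(importance["important"].sum()),
        "accuracy": float(metrics["accuracy"].iloc[0]),
    }

    # -- optional leave-one-out ------------------------------------------
    if config.run_loo:
        loo = _stage("loo")(leave_one_out)(
            pre,
            labels,
            B=config.B,
            seed=config.stage_seed("nes"),
            n_trees=config.n_trees,
            signature_db=db,
            nes=nes,
        )
        loo_path = outdir / "loo.tsv"
        loo.table.to_csv(loo_path, sep="\t")
        artifacts["loo"] = str(loo_path)
        stages["loo"] = {
            "bootstrap_accuracy": loo.bootstrap_accuracy,
            "vector_accuracy": loo.vector_accuracy,
        }

    prov_path = outdir / "provenance.json"
    prov_path.write_text(json.dumps(prov, indent=2, sort_keys=True))
    artifacts["provenance"] = str(prov_path)
    logger.info("pipeline complete: %d artifacts in %s", len(artifacts), outdir)
    return artifacts
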