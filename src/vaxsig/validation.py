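"""Validation schemes: leave-one-out, multi-model stability, cross-context.

Leave-one-out iterates over datasets, training on the other n-1 and
predicting the left-out dataset's B bootstraps. The signature database
of each fold is restricted to signatures extracted from the retained
datasets (strict leakage avoidance); because tail-signature extraction
and NES normalization are per-dataset-independent, this is implemented
as a row subset of the full NES matrix — exactly equivalent to
re-extracting the database per fold. ``refit_signatures=False``
reproduces the laxer fixed-database reading.

The multi-model scheme trains M forests, each on one randomly chosen
representative dataset per platform, and collects every vector's mean
probability of its expected class across models — a platform-bias probe.

Cross-context prediction applies a trained model to new datasets (other
tissues or platforms) through the identical bootstrap -> rank -> NES
pipeline, refusing datasets whose gene-symbol overlap with the signature
database falls below a floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset
from .enrichment import moderated_t_rank, nes_profile
from .ica import Signature, build_signature_db
from .model import (
    NESMatrix,
    SignatureForestModel,
    SignatureForestResults,
    bootstrap_dataset,
    apply_bootstrap,
    build_nes_matrix,
)
from .utils import derive_seed, logger


def _training_rows(
    signature_db: list[Signature], exclude: set[str], refit: bool
) -> list[str]:
    if not refit:
        return [s.name for s in signature_db]
    return [s.name for s in signature_db if s.source_dataset not in exclude]


@dataclass
class LOOReport:
    """Per-fold expected/unexpected bootstrap counts."""

    table: pd.DataFrame  # index dataset_id: expected_class, n_expected, n_unexpected, B

    @property
    def bootstrap_accuracy(self) -> float:
        t = self.table
        return float(t["n_expected"].sum() / (t["n_expected"] + t["n_unexpected"]).sum())

    @property
    def vector_accuracy(self) -> float:
        t = self.table
        return float((t["n_expected"] > t["n_unexpected"]).mean())


def leave_one_out(
    datasets: list[ExpressionDataset],
    labels: dict[str, str],
    B: int = 100,
    seed: int = 0,
    n_perm: int = 1000,
    n_trees: int = 2000,
    signature_db: list[Signature] | None = None,
    nes: NESMatrix | None = None,
    refit_signatures: bool = True,
    n_components: int | None = None,
    **nes_kwargs,
) -> LOOReport:
    """Train on n-1 datasets, score the left-out dataset's bootstraps."""
    if len(datasets) < 3:
        raise ValueError("leave-one-out needs at least 3 datasets")
    if signature_db is None:
        signature_db = build_signature_db(datasets, n_components=n_components, seed=seed)
    if nes is None:
        nes = build_nes_matrix(
            datasets, signature_db, B=B, seed=seed, n_perm=n_perm, labels=labels, **nes_kwargs
        )
    rows = []
    for ds in datasets:
        held = str(ds.dataset_id)
        train_rows = _training_rows(signature_db, {held}, refit_signatures)
        if not train_rows:
            raise ValueError(f"fold {held}: no training signatures left")
        train_cols = [c for c in nes.values.columns if nes.col_meta.loc[c, "dataset_id"] != held]
        test_cols = [c for c in nes.values.columns if nes.col_meta.loc[c, "dataset_id"] == held]
        fold = nes.subset(rows=train_rows, cols=train_cols)
        results = SignatureForestModel(fold, labels=labels, n_trees=n_trees).fit(
            seed=derive_seed(seed, "loo", held)
        )
        pred = results.predict_vector(nes.values.loc[train_rows, test_cols], ds.vector_id)
        expected = labels[ds.vector_id]
        n_expected = pred.n_strong if expected == "Strong" else pred.n_weak
        rows.append(
            {
                "dataset_id": held,
                "expected_class": expected,
                "n_expected": n_expected,
                "n_unexpected": len(pred.votes) - n_expected,
                "B": len(pred.votes),
            }
        )
    return LOOReport(pd.DataFrame(rows).set_index("dataset_id"))


@dataclass
class MultiModelReport:
    """Mean expected-class probabilities per vector across M models."""

    probabilities: pd.DataFrame  # vectors x models
    rosters: list[list[str]]
    expected_votes: pd.DataFrame  # vectors x models, bool: majority as expected

    @property
    def confidence(self) -> pd.Series:
        """Fraction of models classifying each vector as expected."""
        return self.expected_votes.mean(axis=1).rename("confidence")


def multi_model(
    datasets: list[ExpressionDataset],
    labels: dict[str, str],
    M: int = 100,
    seed: int = 0,
    B: int = 100,
    n_perm: int = 1000,
    n_trees: int = 2000,
    signature_db: list[Signature] | None = None,
    nes: NESMatrix | None = None,
    refit_signatures: bool = True,
    **nes_kwargs,
) -> MultiModelReport:
    """M models, each on one representative dataset per platform."""
    by_platform: dict[str, list[ExpressionDataset]] = {}
    for ds in datasets:
        by_platform.setdefault(ds.platform, []).append(ds)
    for platform, members in by_platform.items():
        if not members:
            raise ValueError(f"platform {platform!r} has no dataset")
    if signature_db is None:
        signature_db = build_signature_db(datasets, seed=seed)
    if nes is None:
        nes = build_nes_matrix(
            datasets, signature_db, B=B, seed=seed, n_perm=n_perm, labels=labels, **nes_kwargs
        )
    rng = np.random.default_rng(derive_seed(seed, "multimodel"))
    vectors = sorted(nes.col_meta["vector_id"].unique())
    probs = pd.DataFrame(index=vectors, columns=range(1, M + 1), dtype=float)
    votes = pd.DataFrame(index=vectors, columns=range(1, M + 1), dtype=bool)
    roster_classes = {
        str(ds.dataset_id): labels[ds.vector_id] for ds in datasets
    }
    can_span = len(set(roster_classes.values())) > 1
    rosters = []
    n_redrawn = 0
    for m in range(1, M + 1):
        # a roster must span both classes to train a classifier; redraw
        # single-class rosters (they occur only at very small scales)
        for _ in range(1000):
            roster = [
                str(members[rng.integers(0, len(members))].dataset_id)
                for _, members in sorted(by_platform.items())
            ]
            if not can_span or len({roster_classes[r] for r in roster}) > 1:
                break
            n_redrawn += 1
        else:
            raise ValueError("could not draw a roster spanning both classes")
        rosters.append(roster)
        train_rows = _training_rows(signature_db, set(nes.col_meta["dataset_id"]) - set(roster), refit_signatures)
        train_cols = [c for c in nes.values.columns if nes.col_meta.loc[c, "dataset_id"] in roster]
        fold = nes.subset(rows=train_rows, cols=train_cols)
        # seed by roster content: identical rosters give identical models,
        # so a degenerate (single-representative) scheme is exactly constant
        results = SignatureForestModel(fold, labels=labels, n_trees=n_trees).fit(
            seed=derive_seed(seed, "multimodel", *roster)
        )
        for vector_id, meta in nes.col_meta.groupby("vector_id"):
            cols = list(meta.index)
            pred = results.predict_vector(nes.values.loc[train_rows, cols], vector_id)
            expected = labels[vector_id]
            p_expected = pred.p_strong if expected == "Strong" else 1.0 - pred.p_strong
            probs.loc[vector_id, m] = float(np.mean(p_expected))
            votes.loc[vector_id, m] = pred.vector_class == expected
    return MultiModelReport(probabilities=probs, rosters=rosters, expected_votes=votes)


def cross_context_predict(
    results: SignatureForestResults,
    datasets: list[ExpressionDataset],
    signature_db: list[Signature],
    B: int = 100,
    seed: int = 0,
    n_perm: int = 1000,
    weight: float = 1.0,
    min_genes: int = 7,
    min_overlap: float = 0.5,
    paired: bool = False,
) -> pd.DataFrame:
    """Classify new datasets (any tissue/platform) with a trained model.

    The pipeline is identical to training (bootstrap -> moderated-t rank
    -> NES on the model's signatures); tissue and platform tags are
    metadata only. A dataset whose genes cover less than ``min_overlap``
    of the signature database's gene universe is refused.
    """
    feature_sigs = [s for s in signature_db if s.name in set(results.feature_names)]
    db_genes = {g for s in feature_sigs for g in s.genes}
    rows = []
    for ds in datasets:
        present = set(ds.values.index)
        overlap = len(db_genes & present) / len(db_genes)
        if overlap < min_overlap:
            raise ValueError(
                f"{ds.dataset_id}: gene-symbol overlap with signature DB is "
                f"{overlap:.2f} < {min_overlap:.2f}; refusing to predict"
            )
        cols = {}
        for bs in bootstrap_dataset(ds, B=B, seed=seed, paired=paired):
            ranked = moderated_t_rank(apply_bootstrap(ds, bs))
            cols[f"{ds.dataset_id}|b{bs.replicate}"] = nes_profile(
                ranked,
                feature_sigs,
                n_perm=n_perm,
                seed=derive_seed(seed, "nes", ds.dataset_id, bs.replicate),
                weight=weight,
                min_genes=min_genes,
            )
        values = pd.DataFrame(cols)
        pred = results.predict_vector(values, ds.vector_id)
        rows.append(
            {
                "vector": ds.vector_id,
                "dataset_id": ds.dataset_id,
                "tissue": ds.tissue,
                "platform": ds.platform,
                "n_strong": pred.n_strong,
                "n_weak": pred.n_weak,
                "class": pred.vector_class,
                "overlap": overlap,
            }
        )
        logger.info("%s (%s): %d Strong / %d Weak", ds.vector_id, ds.tissue, pred.n_strong, pred.n_weak)
    return pd.DataFrame(rows).set_index("dataset_id")
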