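"""Bootstrap NES feature matrices and the random-forest vector classifier.

Every original dataset is resampled ``B`` times (with replacement, per
group, at the original group sizes); each bootstrap yields a moderated-t
ranked list whose signature NES profile becomes one column of the
feature matrix (signatures x dataset.bootstrap columns). A random forest
with Gini-split trees is trained on the labelled columns; a new vector is
classified per bootstrap by the P(class) > 0.5 rule and at the vector
level by the majority vote over its B bootstraps. Feature relevance is
the mean decrease in Gini impurity, reported on the scale of the
classical randomForest convention (summed impurity decreases weighted by
node sample counts, averaged over trees).

The classifier follows the statsmodels model/results idiom:
``SignatureForestModel(nes, labels).fit(seed)`` returns a
:class:`SignatureForestResults` carrying the fitted forest, the
out-of-bag error path, importances, and prediction/diagnostic methods.
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .datasets import ExpressionDataset
from .enrichment import moderated_t_rank, nes_profile
from .ica import Signature
from .utils import derive_seed, logger

CLASS_ORDER = ("Strong", "Weak")
SERIALIZATION_VERSION = 1


# ----------------------------------------------------------------------
# bootstrap machinery
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class BootstrapSet:
    """One resampling draw: column positions per group, replicate index."""

    dataset_id: str
    replicate: int
    positions: tuple[int, ...]
    paired: bool = False


def bootstrap_dataset(
    ds: ExpressionDataset, B: int = 100, seed: int = 0, paired: bool = False
) -> list[BootstrapSet]:
    """``B`` with-replacement draws preserving per-group sizes.

    ``paired=True`` draws subject (pair) indices and takes both members
    of each vector/control pair, matching the patient-paired resampling
    used for before/after-vaccination samples; it requires equal group
    sizes with samples pairable by within-group order.
    """
    cols = list(ds.values.columns)
    vec = [i for i, c in enumerate(cols) if ds.groups.iloc[i] == "vector"]
    ctl = [i for i, c in enumerate(cols) if ds.groups.iloc[i] == "control"]
    if len(vec) < 2 or len(ctl) < 2:
        raise ValueError(f"{ds.dataset_id}: need >= 2 samples per group to bootstrap")
    if paired and len(vec) != len(ctl):
        raise ValueError(f"{ds.dataset_id}: paired bootstrap needs matched group sizes")
    rng = np.random.default_rng(derive_seed(seed, "bootstrap", ds.dataset_id))
    out = []
    for b in range(B):
        if paired:
            pairs = rng.integers(0, len(vec), size=len(vec))
            positions = [ctl[i] for i in pairs] + [vec[i] for i in pairs]
        else:
            positions = [ctl[i] for i in rng.integers(0, len(ctl), size=len(ctl))]
            positions += [vec[i] for i in rng.integers(0, len(vec), size=len(vec))]
        out.append(
            BootstrapSet(
                dataset_id=str(ds.dataset_id),
                replicate=b + 1,
                positions=tuple(positions),
                paired=paired,
            )
        )
    return out


def apply_bootstrap(ds: ExpressionDataset, bs: BootstrapSet) -> ExpressionDataset:
    return ds.subset_positions(list(bs.positions), tag=f"b{bs.replicate}")


# ----------------------------------------------------------------------
# NES feature matrix
# ----------------------------------------------------------------------

@dataclass
class NESMatrix:
    """Signatures x (dataset x bootstrap) NES matrix with column metadata.

    ``col_meta`` is indexed by column id with fields ``dataset_id``,
    ``vector_id``, ``bootstrap`` and ``class_label`` (may be NA for
    unlabelled prediction columns).
    """

    values: pd.DataFrame
    col_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.col_meta.index):
            raise ValueError("NESMatrix column metadata misaligned")

    @property
    def signatures(self) -> pd.Index:
        return self.values.index

    def subset(
        self, rows: list[str] | None = None, cols: pd.Index | list[str] | None = None
    ) -> "NESMatrix":
        values = self.values
        if rows is not None:
            values = values.loc[rows]
        if cols is not None:
            values = values[list(cols)]
        return NESMatrix(values=values, col_meta=self.col_meta.loc[values.columns])

    def columns_of(self, dataset_ids=None, vector_ids=None) -> list[str]:
        meta = self.col_meta
        mask = pd.Series(True, index=meta.index)
        if dataset_ids is not None:
            mask &= meta["dataset_id"].isin(list(dataset_ids))
        if vector_ids is not None:
            mask &= meta["vector_id"].isin(list(vector_ids))
        return list(meta.index[mask])

    def to_tsv(self, path: str | Path) -> None:
        """TSV with two metadata header rows (dataset, class) above samples."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        header1 = "\t".join(["#dataset", *self.col_meta["dataset_id"].astype(str)])
        header2 = "\t".join(
            ["#class", *self.col_meta["class_label"].fillna("NA").astype(str)]
        )
        body = self.values.rename_axis("signature").to_csv(sep="\t")
        path.write_text(header1 + "\n" + header2 + "\n" + body)


def build_nes_matrix(
    datasets: list[ExpressionDataset],
    signature_db: list[Signature],
    B: int = 100,
    seed: int = 0,
    n_perm: int = 1000,
    weight: float = 1.0,
    min_genes: int = 7,
    labels: dict[str, str] | None = None,
    decoys: list[Signature] | None = None,
    paired: bool = False,
) -> NESMatrix:
    """Assemble the feature matrix: one NES profile per bootstrap.

    Deterministic given ``seed``: the bootstrap draws and every
    permutation null derive their seeds from it per dataset/replicate.
    """
    sig_names = [s.name for s in signature_db]
    columns: dict[str, pd.Series] = {}
    meta_rows = []
    for ds in datasets:
        for bs in bootstrap_dataset(ds, B=B, seed=seed, paired=paired):
            sub = apply_bootstrap(ds, bs)
            ranked = moderated_t_rank(sub)
            profile = nes_profile(
                ranked,
                signature_db,
                decoys=decoys,
                n_perm=n_perm,
                seed=derive_seed(seed, "nes", ds.dataset_id, bs.replicate),
                weight=weight,
                min_genes=min_genes,
            )
            col = f"{ds.dataset_id}|b{bs.replicate}"
            columns[col] = profile.reindex(sig_names)
            meta_rows.append(
                {
                    "column": col,
                    "dataset_id": ds.dataset_id,
                    "vector_id": ds.vector_id,
                    "bootstrap": bs.replicate,
                    "class_label": (labels or {}).get(ds.vector_id),
                }
            )
    if not columns:
        raise ValueError("no datasets to build an NES matrix from")
    values = pd.DataFrame(columns, index=pd.Index(sig_names, name="signature"))
    col_meta = pd.DataFrame(meta_rows).set_index("column")
    return NESMatrix(values=values, col_meta=col_meta)


# ----------------------------------------------------------------------
# predictions and metrics
# ----------------------------------------------------------------------

@dataclass
class VectorPrediction:
    """Per-bootstrap probabilities and votes, plus the majority class."""

    vector_id: str
    p_strong: np.ndarray
    votes: list[str]
    n_ties: int = 0

    @property
    def n_strong(self) -> int:
        return sum(v == "Strong" for v in self.votes)

    @property
    def n_weak(self) -> int:
        return sum(v == "Weak" for v in self.votes)

    @property
    def vector_class(self) -> str:
        # exact split defaults to Weak: never over-call immunogenicity
        return "Strong" if self.n_strong > self.n_weak else "Weak"

    @property
    def confidence(self) -> float:
        return max(self.n_strong, self.n_weak) / len(self.votes)


def votes_from_counts(n_strong: int, n_weak: int) -> str:
    """Vector class from bootstrap vote counts (majority rule)."""
    if n_strong + n_weak == 0:
        raise ValueError("no votes")
    return "Strong" if n_strong > n_weak else "Weak"


def classification_metrics(votes: pd.DataFrame) -> pd.DataFrame:
    """Sensitivity/specificity/PPV/NPV per class plus overall accuracy.

    ``votes`` needs ``truth`` and ``vote`` columns (one row per
    bootstrap). Under the two-class contract sensitivity(Strong) equals
    specificity(Weak) and PPV(Strong) equals NPV(Weak). Undefined ratios
    are reported as NaN.
    """
    if votes.empty:
        raise ValueError("no predictions to score")
    accuracy = float((votes["vote"] == votes["truth"]).mean())
    rows = {}
    for cls in CLASS_ORDER:
        tp = int(((votes["vote"] == cls) & (votes["truth"] == cls)).sum())
        fn = int(((votes["vote"] != cls) & (votes["truth"] == cls)).sum())
        fp = int(((votes["vote"] == cls) & (votes["truth"] != cls)).sum())
        tn = int(((votes["vote"] != cls) & (votes["truth"] != cls)).sum())

        def ratio(a: int, b: int) -> float:
            return a / b if b else float("nan")

        rows[cls] = {
            "sensitivity": ratio(tp, tp + fn),
            "specificity": ratio(tn, tn + fp),
            "ppv": ratio(tp, tp + fp),
            "npv": ratio(tn, tn + fn),
            "accuracy": accuracy,
        }
    return pd.DataFrame(rows).T.rename_axis("class")


# ----------------------------------------------------------------------
# the model / results pair
# ----------------------------------------------------------------------

class SignatureForestModel:
    """Random-forest classifier on the signature NES feature space.

    Parameters
    ----------
    nes : NESMatrix
        Training feature matrix; only labelled columns are used.
    labels : mapping, optional
        vector_id -> class; overrides/completes ``col_meta.class_label``.
    n_trees : int
        Forest size (default 2000).
    mtry : int, optional
        Features per split; default ``floor(sqrt(n_signatures))``.
    """

    def __init__(
        self,
        nes: NESMatrix,
        labels: dict[str, str] | None = None,
        n_trees: int = 2000,
        mtry: int | None = None,
    ):
        self.nes = nes
        meta = nes.col_meta
        y = meta["class_label"].copy()
        if labels:
            y = meta["vector_id"].map(labels).fillna(y)
        keep = y.notna()
        if keep.sum() == 0:
            raise ValueError("no labelled columns to train on")
        bad = set(y[keep].unique()) - set(CLASS_ORDER)
        if bad:
            raise ValueError(f"unknown class labels {sorted(bad)}")
        if y[keep].nunique() < 2:
            raise ValueError("training requires both classes present")
        self.feature_names = list(nes.values.index)
        X = nes.values.loc[:, keep[keep].index].T
        n_imputed = int(X.isna().to_numpy().sum())
        if n_imputed:
            logger.info("imputing %d missing NES as 0", n_imputed)
        self.X = X.fillna(0.0)
        self.y = y[keep]
        self.n_trees = int(n_trees)
        self.mtry = int(mtry) if mtry else max(1, int(np.sqrt(len(self.feature_names))))
        self.n_imputed = n_imputed

    def fit(self, seed: int = 0, oob_checkpoints: tuple[int, ...] | None = None):
        """Grow the forest, recording the OOB misclassification path."""
        if oob_checkpoints is None:
            grid = [25, 50, 100, 200, 400, 800, 1400]
            oob_checkpoints = tuple(c for c in grid if c < self.n_trees) + (self.n_trees,)
        rf = RandomForestClassifier(
            n_estimators=0,
            criterion="gini",
            max_features=self.mtry,
            oob_score=True,
            warm_start=True,
            random_state=derive_seed(seed, "rf"),
            n_jobs=1,
        )
        oob_path = {}
        with warnings.catch_warnings():
            # small forests can leave a few samples without OOB votes
            warnings.simplefilter("ignore", UserWarning)
            for ck in oob_checkpoints:
                rf.set_params(n_estimators=int(ck))
                rf.fit(self.X.to_numpy(), self.y.to_numpy())
                oob_path[int(ck)] = 1.0 - float(rf.oob_score_)
        return SignatureForestResults(self, rf, pd.Series(oob_path, name="oob_error"))


class SignatureForestResults:
    """Fitted forest with diagnostics and prediction methods."""

    def __init__(self, model: SignatureForestModel, rf: RandomForestClassifier, oob_path: pd.Series):
        self.model = model
        self.rf = rf
        self.oob_path = oob_path
        self.feature_names = model.feature_names

    # -- diagnostics ----------------------------------------------------
    @property
    def oob_error(self) -> float:
        return float(self.oob_path.iloc[-1])

    @property
    def importances(self) -> pd.Series:
        """Mean decrease in Gini impurity, randomForest-style scale.

        Per tree the impurity decreases are weighted by node sample
        counts (sklearn's unnormalized importances times the training
        size), then averaged over trees.
        """
        n = self.model.X.shape[0]
        acc = np.zeros(len(self.feature_names))
        for tree in self.rf.estimators_:
            acc += tree.tree_.compute_feature_importances(normalize=False)
        imp = acc / len(self.rf.estimators_) * n
        return pd.Series(imp, index=self.feature_names, name="gini_mean_decrease")

    def importance_ranking(self, threshold: float = 10.0) -> pd.DataFrame:
        """Signatures ranked by Gini mean decrease; >= threshold flagged."""
        imp = self.importances.sort_values(ascending=False, kind="mergesort")
        return pd.DataFrame(
            {"gini_mean_decrease": imp, "important": imp > threshold}
        ).rename_axis("signature")

    def important_signatures(self, threshold: float = 10.0) -> list[str]:
        ranking = self.importance_ranking(threshold)
        return list(ranking.index[ranking["important"]])

    # -- prediction -----------------------------------------------------
    def _align(self, values: pd.DataFrame) -> np.ndarray:
        X = values.reindex(self.feature_names).T.fillna(0.0)
        return X.to_numpy()

    def predict_proba_columns(self, values: pd.DataFrame) -> pd.Series:
        """P(Strong) per NES column."""
        idx = list(self.rf.classes_).index("Strong")
        proba = self.rf.predict_proba(self._align(values))[:, idx]
        return pd.Series(proba, index=values.columns, name="p_strong")

    def predict_vector(
        self, values: pd.DataFrame, vector_id: str, threshold: float = 0.5
    ) -> VectorPrediction:
        """Majority class over one vector's bootstrap columns.

        Per bootstrap the vote is the class whose probability exceeds
        ``threshold``; an exact tie is conservatively counted as Weak.
        """
        p_strong = self.predict_proba_columns(values)
        votes = ["Strong" if p > threshold else "Weak" for p in p_strong]
        n_ties = int((p_strong == threshold).sum())
        if n_ties:
            logger.info("%s: %d exact-tie probabilities counted as Weak", vector_id, n_ties)
        return VectorPrediction(
            vector_id=vector_id,
            p_strong=p_strong.to_numpy(),
            votes=votes,
            n_ties=n_ties,
        )

    def predict_nes(self, nes: NESMatrix, threshold: float = 0.5) -> dict[str, VectorPrediction]:
        """Vector-level predictions for every vector in an NES matrix."""
        out = {}
        for vector_id, meta in nes.col_meta.groupby("vector_id", sort=True):
            cols = list(meta.index)
            out[vector_id] = self.predict_vector(
                nes.values[cols], vector_id, threshold=threshold
            )
        return out

    def prediction_table(self, nes: NESMatrix, threshold: float = 0.5) -> pd.DataFrame:
        preds = self.predict_nes(nes, threshold=threshold)
        rows = [
            {
                "vector": p.vector_id,
                "n_strong": p.n_strong,
                "n_weak": p.n_weak,
                "class": p.vector_class,
                "confidence": p.confidence,
            }
            for p in preds.values()
        ]
        return pd.DataFrame(rows).set_index("vector")

    def metrics(self, nes: NESMatrix, truth: dict[str, str]) -> pd.DataFrame:
        """Per-bootstrap vote metrics against known classes."""
        preds = self.predict_nes(nes)
        rows = []
        for vector_id, pred in preds.items():
            if vector_id not in truth:
                continue
            for vote in pred.votes:
                rows.append({"truth": truth[vector_id], "vote": vote})
        return classification_metrics(pd.DataFrame(rows))

    # -- reporting ------------------------------------------------------
    def summary(self) -> str:
        top = self.importance_ranking().head(5)
        lines = [
            "Signature random-forest classifier",
            "==================================",
            f"training columns : {self.model.X.shape[0]}",
            f"signatures       : {len(self.feature_names)}",
            f"trees            : {self.model.n_trees}   mtry: {self.model.mtry}",
            f"OOB error        : {self.oob_error:.4f}",
            f"imputed NES      : {self.model.n_imputed}",
            "top signatures (Gini mean decrease):",
        ]
        for name, row in top.iterrows():
            lines.append(f"  {name:40s} {row['gini_mean_decrease']:8.2f}")
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        payload = {
            "format_version": SERIALIZATION_VERSION,
            "feature_names": self.feature_names,
            "rf": self.rf,
            "oob_path": self.oob_path,
            "n_trees": self.model.n_trees,
            "mtry": self.model.mtry,
        }
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "wb") as fh:
            pickle.dump(payload, fh)

    @classmethod
    def load(cls, path: str | Path) -> "SignatureForestResults":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        if payload.get("format_version") != SERIALIZATION_VERSION:
            raise ValueError("unsupported model file version")
        obj = cls.__new__(cls)
        obj.model = None  # detached from training data
        obj.rf = payload["rf"]
        obj.oob_path = payload["oob_path"]
        obj.feature_names = payload["feature_names"]
        return obj


def train_rf(
    nes: NESMatrix,
    labels: dict[str, str] | None = None,
    n_trees: int = 2000,
    mtry: int | None = None,
    seed: int = 0,
) -> SignatureForestResults:
    """Functional entry point: build the model and fit it."""
    return SignatureForestModel(nes, labels=labels, n_trees=n_trees, mtry=mtry).fit(seed=seed)


# reporting utility: cluster the important signatures' mean NES per dataset
def cluster_important_signatures(
    nes: NESMatrix, signatures: list[str]
) -> pd.DataFrame:
    """Mean NES per (signature, dataset) with Euclidean/Complete ordering.

    Returns the mean-NES table with rows ordered by complete-linkage
    hierarchical clustering on Euclidean distances.
    """
    from scipy.cluster.hierarchy import leaves_list, linkage

    mean_nes = (
        nes.values.loc[signatures]
        .T.groupby(nes.col_meta["dataset_id"])
        .mean()
        .T.fillna(0.0)
    )
    if len(signatures) > 2:
        order = leaves_list(linkage(mean_nes.to_numpy(), method="complete", metric="euclidean"))
        mean_nes = mean_nes.iloc[order]
    return mean_nes
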