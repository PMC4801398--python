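"""Molecular signature extraction by independent component analysis.

Each preprocessed dataset ``X`` (genes x samples) is decomposed as
``Y = X W`` where the columns of ``Y`` are statistically independent
gene-contribution profiles and ``W`` is the demixing matrix found by
maximizing non-gaussianity (negentropy, monitored here through the
logcosh contrast surrogate of the fixed-point algorithm). A component's
heavy tails mark the genes that dominate one latent expression program;
standardizing the contributions and cutting at |z| > 3 yields up to two
gene-set *signatures* per component (positive and negative tail), which
together form the signature database the classifier's feature space is
built on. Signatures with fewer than 7 detected genes are ignored.

Gene sets are stored in the standard GMT format; random *decoy* sets can
be generated to enlarge the collection used to stabilize enrichment-score
normalization (the role the external curated collections play when they
are available).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .datasets import ExpressionDataset
from .utils import derive_seed, logger

#: E[log cosh Z] for Z ~ N(0, 1); reference point of the negentropy proxy.
_GAUSS_LOGCOSH = 0.3745672074922053


@dataclass(frozen=True)
class Signature:
    """A named gene set with provenance.

    ``provenance`` is one of ``ica_positive_tail``, ``ica_negative_tail``,
    ``imported`` or ``decoy``; ICA tails also carry their source dataset
    and component index.
    """

    name: str
    genes: tuple[str, ...]
    provenance: str = "imported"
    source_dataset: str | None = None
    component: int | None = None

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValueError(f"signature {self.name!r} has no genes")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r} has duplicate genes")


@dataclass
class ICADecomposition:
    """Fitted ICA model of one dataset.

    ``sources`` is Y (genes x components, unit variance), ``demixing`` the
    samples x components matrix W with ``Y = X_centered W``, ``mixing``
    its pseudo-inverse counterpart used for reconstruction.
    """

    dataset_id: str
    sources: pd.DataFrame
    demixing: np.ndarray
    mixing: np.ndarray
    mean: np.ndarray
    negentropy: np.ndarray
    converged: bool
    n_iter: int
    seed: int
    tol_used: float = 1e-6

    def reconstruction_error(self, ds: ExpressionDataset) -> float:
        """Max absolute error of ``Y x mixing + mean`` against the data."""
        X = ds.values.to_numpy(dtype=float)
        Xhat = self.sources.to_numpy() @ self.mixing.T + self.mean
        return float(np.abs(X - Xhat).max())


def decompose(
    ds: ExpressionDataset,
    n_components: int | None = None,
    tol: float = 1e-6,
    seed: int = 0,
    max_iter: int = 1000,
    max_retries: int = 3,
    fallback_tol: float | None = None,
) -> ICADecomposition:
    """FastICA (logcosh contrast) on genes x samples expression.

    ``n_components`` defaults to ``min(n_samples - 1, 6)``. Non-converged
    fits are retried with a fresh seed up to ``max_retries`` times, then
    rejected. With ``fallback_tol`` set, the tolerance is relaxed in
    decade steps down to that value before giving up: at small sample
    counts the fixed point occasionally cycles with tiny amplitude just
    above a strict threshold, and the annealed solution is flagged via
    ``tol_used``.
    """
    X = ds.values.to_numpy(dtype=float)
    n_samples = X.shape[1]
    if n_components is None:
        n_components = min(n_samples - 1, 6)
    if not 1 <= n_components <= n_samples - 1:
        raise ValueError(
            f"{ds.dataset_id}: n_components={n_components} must be in [1, n_samples-1={n_samples - 1}]"
        )
    tolerances = [tol]
    while fallback_tol is not None and tolerances[-1] < fallback_tol * 0.99:
        tolerances.append(tolerances[-1] * 10)
    attempt = 0
    for current_tol in tolerances:
        # the same restart seeds are revisited at each relaxed tolerance
        for retry in range(max_retries + 1):
            attempt_seed = derive_seed(seed, "ica", ds.dataset_id, retry)
            attempt += 1
            ica = FastICA(
                n_components=n_components,
                whiten="unit-variance",
                fun="logcosh",
                tol=current_tol,
                max_iter=max_iter,
                random_state=attempt_seed,
            )
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always", ConvergenceWarning)
                Y = ica.fit_transform(X)
            converged = not any(
                issubclass(w.category, ConvergenceWarning) for w in caught
            )
            if not converged:
                logger.warning(
                    "%s: ICA attempt %d (tol=%g) did not converge; retrying",
                    ds.dataset_id, attempt, current_tol,
                )
                continue
            sources = pd.DataFrame(
                Y,
                index=ds.values.index,
                columns=[f"IC{i + 1}" for i in range(n_components)],
            )
            negentropy = (np.log(np.cosh(Y)).mean(axis=0) - _GAUSS_LOGCOSH) ** 2
            return ICADecomposition(
                dataset_id=str(ds.dataset_id),
                sources=sources,
                demixing=np.asarray(ica.components_).T,
                mixing=np.asarray(ica.mixing_),
                mean=np.asarray(ica.mean_),
                negentropy=negentropy,
                converged=True,
                n_iter=int(ica.n_iter_),
                seed=attempt_seed,
                tol_used=current_tol,
            )
    raise RuntimeError(
        f"{ds.dataset_id}: ICA failed to converge after {attempt} attempts"
    )


def extract_tail_signatures(
    decomp: ICADecomposition, z_threshold: float = 3.0
) -> list[Signature]:
    """Both tails of every component beyond ``z_threshold`` standard scores.

    Tail genes are ordered by decreasing |z|; empty tails are skipped.
    Because both tails are always emitted, the output is invariant to the
    sign indeterminacy of the decomposition.
    """
    if not decomp.converged:
        raise ValueError(f"{decomp.dataset_id}: decomposition did not converge")
    signatures: list[Signature] = []
    for idx, comp in enumerate(decomp.sources.columns):
        y = decomp.sources[comp].to_numpy()
        z = (y - y.mean()) / y.std()
        scores = pd.Series(z, index=decomp.sources.index)
        for tail, mask in (("pos", z > z_threshold), ("neg", z < -z_threshold)):
            genes = scores[mask]
            if genes.empty:
                continue
            ordered = genes.abs().sort_values(ascending=False, kind="mergesort").index
            signatures.append(
                Signature(
                    name=f"{decomp.dataset_id}.{comp}.{tail}",
                    genes=tuple(ordered),
                    provenance=f"ica_{'positive' if tail == 'pos' else 'negative'}_tail",
                    source_dataset=decomp.dataset_id,
                    component=idx,
                )
            )
    return signatures


def filter_signatures(
    signatures: list[Signature], universe, min_genes: int = 7
) -> list[Signature]:
    """Keep signatures with >= ``min_genes`` genes in the detected universe."""
    if isinstance(universe, ExpressionDataset):
        universe = universe.values.index
    present = set(universe)
    return [
        sig for sig in signatures if sum(g in present for g in sig.genes) >= min_genes
    ]


def build_signature_db(
    datasets: list[ExpressionDataset],
    n_components: int | None = None,
    z_threshold: float = 3.0,
    min_genes: int = 7,
    tol: float = 1e-6,
    seed: int = 0,
    fallback_tol: float | None = 1e-3,
) -> list[Signature]:
    """Union of filtered tail signatures over all datasets."""
    if not datasets:
        raise ValueError("build_signature_db needs at least one dataset")
    db: list[Signature] = []
    for ds in datasets:
        decomp = decompose(
            ds, n_components=n_components, tol=tol, seed=seed, fallback_tol=fallback_tol
        )
        sigs = extract_tail_signatures(decomp, z_threshold=z_threshold)
        kept = filter_signatures(sigs, ds.values.index, min_genes=min_genes)
        db.extend(kept)
    logger.info("signature DB: %d signatures from %d datasets", len(db), len(datasets))
    return db


def make_decoy_sets(
    universe, size_distribution, n_decoys: int, seed: int = 0
) -> list[Signature]:
    """Random gene sets for enrichment-normalization stability.

    Sizes are drawn from ``size_distribution`` (a sequence of candidate
    sizes); genes are drawn without replacement from ``universe``. Decoys
    never enter the model's feature space.
    """
    universe = list(universe)
    if not universe:
        raise ValueError("decoy universe is empty")
    sizes = np.asarray(list(size_distribution), dtype=int)
    if sizes.size and sizes.max() > len(universe):
        raise ValueError("requested decoy size exceeds the universe")
    rng = np.random.default_rng(derive_seed(seed, "decoys"))
    decoys = []
    for i in range(n_decoys):
        size = int(rng.choice(sizes))
        genes = tuple(rng.choice(universe, size=size, replace=False))
        decoys.append(Signature(name=f"DECOY_{i + 1:05d}", genes=genes, provenance="decoy"))
    return decoys


# -- GMT input/output ----------------------------------------------------

def write_gmt(signatures: list[Signature], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        for sig in signatures:
            desc = sig.provenance
            if sig.source_dataset is not None:
                desc += f":{sig.source_dataset}:IC{(sig.component or 0) + 1}"
            fh.write("\t".join([sig.name, desc, *sig.genes]) + "\n")


def read_gmt(path: str | Path) -> list[Signature]:
    signatures = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        name, _desc, *genes = fields
        # de-duplicate preserving order; GMT files in the wild repeat genes
        genes = tuple(dict.fromkeys(g for g in genes if g))
        signatures.append(Signature(name=name, genes=genes, provenance="imported"))
    return signatures
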