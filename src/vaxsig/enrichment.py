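"""Moderated-t ranked gene lists and a pre-ranked GSEA engine.

Differential expression between vector and control samples is scored per
gene with an empirical-Bayes moderated t-statistic: the gene-wise sample
variance ``s_g^2`` (on ``d_g`` degrees of freedom) is shrunk toward a
prior ``(d0, s0^2)`` fitted by method of moments to the scaled-F
distribution of all gene variances,

    s_tilde^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g),

and ``t = (mean_vector - mean_control) / (s_tilde * c)`` with
``c^2 = 1/n_v + 1/n_c``. Genes sorted by decreasing t form the ranked
list.

Enrichment of a gene set along a ranked list uses the weighted
Kolmogorov-Smirnov running sum: walking down the list, hitting a set
member increments the sum by ``|score|^p`` (normalized by the sum over
hits) and missing decrements by ``1/(N - N_hits)``; the enrichment score
ES is the running-sum value of maximal absolute deviation, so
ES in [-1, 1]. The normalized score NES divides ES by the mean of
same-signed ES values of random gene sets of identical size drawn from
the list's gene universe, which makes scores comparable across lists and
set sizes (E|NES| ~= 1 for random sets).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma

from .datasets import ExpressionDataset
from .ica import Signature
from .utils import derive_seed, logger


# ----------------------------------------------------------------------
# moderated t
# ----------------------------------------------------------------------

def trigamma_inverse(x: float) -> float:
    """Solve ``trigamma(y) = x`` for y > 0 (Newton on the inverse scale)."""
    if x <= 0:
        raise ValueError("trigamma_inverse needs x > 0")
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(polygamma(2, y))
        y += dif
        if -dif / y < 1e-8:
            break
    return float(y)


def fit_variance_prior(s2: np.ndarray, d_g: int) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-F prior for gene variances.

    Matches the first two moments of ``log(s2)`` against the theoretical
    log-F moments (digamma/trigamma), returning ``(d0, s0_squared)``;
    ``d0`` may be ``inf`` when the empirical spread is below the
    chi-square expectation.
    """
    s2 = np.maximum(np.asarray(s2, dtype=float), 0.0)
    if s2.size < 2:
        return np.inf, float(s2.mean()) if s2.size else 1.0
    m = float(np.median(s2))
    if m == 0:
        warnings.warn("more than half of the gene variances are zero; prior unreliable")
        m = 1.0
    s2 = np.maximum(s2, 1e-5 * m)  # offset exact zeros away from zero
    z = np.log(s2)
    e = z - digamma(d_g / 2.0) + np.log(d_g / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - float(polygamma(1, d_g / 2.0))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(s2.mean())
    return d0, s0_sq


def moderated_t(
    values: pd.DataFrame,
    groups: pd.Series,
    prior_df: float | None = None,
    prior_var: float | None = None,
) -> pd.Series:
    """Empirical-Bayes moderated t per gene (vector minus control).

    ``prior_df``/``prior_var`` override the fitted prior; ``prior_df=0``
    reduces exactly to the ordinary two-sample t.
    """
    vec = values.loc[:, groups.index[groups == "vector"]].to_numpy(dtype=float)
    ctl = values.loc[:, groups.index[groups == "control"]].to_numpy(dtype=float)
    n1, n2 = vec.shape[1], ctl.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("moderated_t needs >= 2 samples per group")
    d_g = n1 + n2 - 2
    diff = vec.mean(axis=1) - ctl.mean(axis=1)
    ss = vec.var(axis=1, ddof=1) * (n1 - 1) + ctl.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / d_g
    if not (s2 > 0).any():
        warnings.warn("zero within-group variance everywhere: ordinary t with pooled floor")
        floor = 1e-6 * max(1.0, float(np.abs(values.to_numpy()).max()))
        s_tilde2 = np.full_like(s2, floor)
    else:
        if prior_df is None:
            d0, s0_sq = fit_variance_prior(s2, d_g)
        else:
            d0 = float(prior_df)
            s0_sq = float(prior_var) if prior_var is not None else fit_variance_prior(s2, d_g)[1]
        if np.isinf(d0):
            s_tilde2 = np.full_like(s2, s0_sq)
        elif d0 == 0:
            s_tilde2 = s2
        else:
            s_tilde2 = (d0 * s0_sq + d_g * s2) / (d0 + d_g)
        # genes with zero sample variance still get the prior floor
        s_tilde2 = np.where(s_tilde2 > 0, s_tilde2, np.nan)
    c = np.sqrt(1.0 / n1 + 1.0 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / (np.sqrt(s_tilde2) * c)
    t = np.where(np.isfinite(t), t, 0.0)
    return pd.Series(t, index=values.index, name="moderated_t")


def moderated_t_rank(
    ds: ExpressionDataset,
    prior_df: float | None = None,
    prior_var: float | None = None,
) -> pd.Series:
    """Ranked gene list: moderated t, descending, ties broken by gene name."""
    t = moderated_t(ds.values, ds.groups, prior_df=prior_df, prior_var=prior_var)
    return t.sort_index(kind="mergesort").sort_values(
        ascending=False, kind="mergesort"
    )


def write_rnk(ranked: pd.Series, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    ranked.rename("score").rename_axis("gene").to_csv(path, sep="\t", header=False)


# ----------------------------------------------------------------------
# pre-ranked GSEA
# ----------------------------------------------------------------------

def _es_from_positions(
    positions: np.ndarray, weights: np.ndarray, n_total: int
) -> np.ndarray:
    """Vectorized running-sum ES for batches of hit positions.

    ``positions`` (batch x k, 0-based, sorted ascending) and ``weights``
    (batch x k, the |score|^p of each hit). The extrema of the running
    sum occur immediately after a hit or immediately before one, so only
    those 2k candidate values are evaluated.
    """
    batch, k = positions.shape
    wsum = weights.sum(axis=1, keepdims=True)
    # all-zero hit scores degenerate to equal weighting
    w = np.where(wsum > 0, weights / np.where(wsum == 0, 1, wsum), 1.0 / k)
    W = np.cumsum(w, axis=1)
    W_prev = np.concatenate([np.zeros((batch, 1)), W[:, :-1]], axis=1)
    j = np.arange(1, k + 1)
    step = 1.0 / (n_total - k)
    after = W - (positions + 1 - j) * step
    before = W_prev - (positions + 1 - j) * step
    best_pos = np.maximum(after.max(axis=1), before.max(axis=1))
    best_neg = np.minimum(after.min(axis=1), before.min(axis=1))
    best_pos = np.maximum(best_pos, 0.0)
    best_neg = np.minimum(best_neg, 0.0)
    return np.where(best_pos >= -best_neg, best_pos, best_neg)


def enrichment_score(
    ranked: pd.Series, genes, weight: float = 1.0
) -> float | None:
    """Weighted KS running-sum ES of a gene set on a ranked list.

    Returns ``None`` (flagged absent/degenerate) when the set has no
    overlap with the list, or covers the entire list.
    """
    gene_pos = {g: i for i, g in enumerate(ranked.index)}
    hits = np.array(sorted(gene_pos[g] for g in set(genes) if g in gene_pos))
    n_total = len(ranked)
    if hits.size == 0:
        return None
    if hits.size == n_total:
        warnings.warn("gene set covers the whole ranked list: ES undefined")
        return None
    w = np.abs(ranked.to_numpy(dtype=float)[hits]) ** weight
    es = _es_from_positions(hits[None, :], w[None, :], n_total)
    return float(es[0])


def _null_es(
    abs_scores_p: np.ndarray, size: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """ES of ``n_perm`` random same-size gene sets on one ranked list."""
    n_total = abs_scores_p.shape[0]
    keys = rng.random((n_perm, n_total))
    positions = np.argpartition(keys, size - 1, axis=1)[:, :size] if size < n_total else np.tile(
        np.arange(n_total), (n_perm, 1)
    )
    positions = np.sort(positions, axis=1)
    weights = abs_scores_p[positions]
    return _es_from_positions(positions, weights, n_total)


class NullCache:
    """Per-ranked-list cache of same-size permutation ES distributions.

    Each set size gets its own generator seeded from ``(seed, size)``,
    so cached results do not depend on signature evaluation order.
    """

    def __init__(self, ranked: pd.Series, weight: float, n_perm: int, seed: int):
        self.abs_scores_p = np.abs(ranked.to_numpy(dtype=float)) ** weight
        self.n_total = len(ranked)
        self.n_perm = n_perm
        self.seed = seed
        self._store: dict[int, np.ndarray] = {}

    def get(self, size: int, widen: bool = False) -> np.ndarray:
        null = self._store.get(size)
        if null is None:
            rng = np.random.default_rng(derive_seed(self.seed, "nesnull", size))
            null = _null_es(self.abs_scores_p, size, self.n_perm, rng)
            self._rngs = getattr(self, "_rngs", {})
            self._rngs[size] = rng
            self._store[size] = null
        if widen and len(null) == self.n_perm:
            extra = _null_es(self.abs_scores_p, size, self.n_perm, self._rngs[size])
            null = np.concatenate([null, extra])
            self._store[size] = null
        return null


def normalized_es(
    es: float | None,
    ranked: pd.Series,
    size: int,
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
    null_cache: NullCache | None = None,
) -> float:
    """NES = ES divided by the mean same-signed permutation ES.

    Fewer than 10 same-signed permutation scores triggers one doubling of
    the permutation count, then an error.
    """
    if es is None:
        return float("nan")
    if es == 0:
        return 0.0
    cache = null_cache or NullCache(ranked, weight, n_perm, seed)
    null = cache.get(size)
    same = null[null > 0] if es > 0 else null[null < 0]
    if same.size < 10:
        null = cache.get(size, widen=True)
        same = null[null > 0] if es > 0 else null[null < 0]
        if same.size < 10:
            raise RuntimeError(
                f"only {same.size} same-sign permutation scores for size {size}"
            )
    return float(es / abs(same.mean()))


def nes_profile(
    ranked: pd.Series,
    signature_db: list[Signature],
    decoys: list[Signature] | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
    min_genes: int = 7,
) -> pd.Series:
    """NES of every signature on one ranked list.

    Signatures with fewer than ``min_genes`` detected genes are absent
    (NaN; imputed 0 when the feature matrix is assembled). Decoy sets are
    excluded from the output but their sizes pre-warm the permutation
    null, mirroring the enlargement of the gene-set collection used for
    normalization.
    """
    cache = NullCache(ranked, weight, n_perm, seed)
    present = set(ranked.index)
    for decoy in decoys or ():
        k = sum(g in present for g in decoy.genes)
        if k >= min_genes and k < len(ranked):
            cache.get(k)
    out = {}
    n_absent = 0
    for sig in signature_db:
        k = sum(g in present for g in sig.genes)
        if k < min_genes or k >= len(ranked):
            out[sig.name] = float("nan")
            n_absent += 1
            continue
        es = enrichment_score(ranked, sig.genes, weight=weight)
        out[sig.name] = normalized_es(
            es, ranked, k, n_perm=n_perm, seed=seed, weight=weight, null_cache=cache
        )
    if n_absent:
        logger.info("nes_profile: %d/%d signatures absent from ranked list", n_absent, len(signature_db))
    return pd.Series(out, name="NES")
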