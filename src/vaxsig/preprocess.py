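"""Per-dataset microarray preprocessing.

Pipeline order: quantile normalization -> log2 -> detection-p filter ->
collapse probes to gene symbols. Each step appends to the dataset's
provenance so downstream stages can assert what was applied.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset, log_dropped


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the mean order-statistic distribution.

    After normalization all columns share the same multiset of values
    (the across-column mean of sorted values) and each column keeps its
    rank order. Ties within a column receive the mean of the quantiles
    they span (average-rank interpolation).
    """
    if matrix.isna().to_numpy().any():
        raise ValueError("quantile_normalize requires a complete matrix")
    if matrix.shape[1] < 2:
        warnings.warn("single-sample matrix: quantile normalization is a no-op")
        return matrix.copy()
    values = matrix.to_numpy(dtype=float)
    reference = np.sort(values, axis=0).mean(axis=1)
    ranks = matrix.rank(axis=0, method="average").to_numpy()
    n = values.shape[0]
    out = np.empty_like(values)
    grid = np.arange(1, n + 1, dtype=float)
    for j in range(values.shape[1]):
        out[:, j] = np.interp(ranks[:, j], grid, reference)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def log2_transform(matrix: pd.DataFrame, floor: float | None = None) -> pd.DataFrame:
    """Elementwise log2 with a deterministic floor for non-positive values.

    The floor defaults to the smallest positive value in the matrix
    (fallback 1e-3 when there is none).
    """
    values = matrix.to_numpy(dtype=float).copy()
    nonpos = values <= 0
    if nonpos.any():
        positives = values[values > 0]
        if floor is None:
            floor = float(positives.min()) if positives.size else 1e-3
        warnings.warn(f"flooring {int(nonpos.sum())} non-positive values at {floor:g}")
        values[nonpos] = floor
    return pd.DataFrame(np.log2(values), index=matrix.index, columns=matrix.columns)


def filter_undetected(
    matrix: pd.DataFrame, detection_p: pd.DataFrame | None, alpha: float = 0.05
) -> pd.DataFrame:
    """Keep probes detected (p <= alpha) in at least one sample."""
    if detection_p is None:
        warnings.warn("no detection p-values: keeping all probes")
        return matrix.copy()
    detection_p = detection_p.loc[matrix.index, matrix.columns]
    keep = (detection_p.to_numpy() <= alpha).any(axis=1)
    log_dropped("filter_undetected", int((~keep).sum()), "undetected probes")
    return matrix.loc[keep]


def collapse_to_symbols(matrix: pd.DataFrame, probe_map: pd.Series) -> pd.DataFrame:
    """One row per gene symbol, keeping the max-mean-expression probe.

    Unmapped probes are dropped (logged); probe-name order breaks exact
    mean ties for determinism.
    """
    if probe_map is None or len(probe_map) == 0:
        raise ValueError("collapse_to_symbols requires a non-empty probe map")
    mapped = matrix.index.intersection(probe_map.index)
    log_dropped("collapse_to_symbols", matrix.shape[0] - len(mapped), "unmapped probes")
    if len(mapped) == 0:
        raise ValueError("no probe of the matrix is covered by the probe map")
    sub = matrix.loc[mapped]
    stats = pd.DataFrame(
        {
            "symbol": probe_map.loc[mapped].to_numpy(),
            "mean": sub.mean(axis=1).to_numpy(),
            "probe": mapped,
        }
    )
    stats = stats.sort_values(["symbol", "mean", "probe"], ascending=[True, False, True])
    chosen = stats.drop_duplicates("symbol", keep="first")
    out = sub.loc[chosen["probe"]]
    out.index = pd.Index(chosen["symbol"], name="gene")
    return out.sort_index()


def preprocess_dataset(
    ds: ExpressionDataset,
    alpha: float = 0.05,
    floor: float | None = None,
    filter_before_normalize: bool = False,
) -> ExpressionDataset:
    """Run the full preprocessing pipeline on one dataset.

    ``filter_before_normalize`` flips the (unstated-by-convention)
    ordering of the detection filter relative to quantile normalization;
    the default filters afterwards.
    """
    values, detp = ds.values, ds.detection_p
    steps: list[str] = []
    if filter_before_normalize:
        values = filter_undetected(values, detp, alpha=alpha)
        steps.append(f"detection_filter(alpha={alpha})")
    values = quantile_normalize(values)
    steps.append("quantile_normalize")
    values = log2_transform(values, floor=floor)
    steps.append("log2")
    if not filter_before_normalize:
        values = filter_undetected(values, detp, alpha=alpha)
        steps.append(f"detection_filter(alpha={alpha})")
    if ds.probe_map is not None:
        values = collapse_to_symbols(values, ds.probe_map)
        steps.append("collapse_to_symbols(max_mean)")
    if not values.index.is_unique:
        raise ValueError(f"{ds.dataset_id}: gene identifiers not unique after collapsing")
    return replace(
        ds,
        values=values,
        detection_p=None,
        probe_map=None,
        provenance=ds.provenance + steps,
    )
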