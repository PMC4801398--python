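"""From tetramer kinetics to Weak/Strong vector classes.

The response readout is the frequency of antigen-specific (tetramer+)
CD8+ T cells measured at days 5, 7 and 10 after immunization. Per mouse
the highest of the available days is kept; per group the mouse peaks are
averaged; per experiment the group mean is divided by the mean of the
internal rAd standard group measured in parallel, giving a dimensionless
"CD8 T-cell expansion" ratio that is comparable across experiments.
Vectors are then split by hierarchical clustering (Euclidean distance,
Ward.D2 linkage, tree cut at k = 3): the cluster with the lowest mean
ratio is the "Weak" class, the other clusters together form "Strong".
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .datasets import validate_response_table


class ClassingError(ValueError):
    """Raised when vector classing cannot proceed (missing reference, ties...)."""


def peak_response(measures) -> float:
    """Highest tetramer+ % over a mouse's available days."""
    arr = np.asarray(list(measures), dtype=float)
    if arr.size == 0:
        raise ClassingError("no measures for mouse")
    return float(arr.max())


def mouse_peaks(table: pd.DataFrame) -> pd.DataFrame:
    """Per-(experiment, vector, mouse) peak response."""
    validate_response_table(table)
    peaks = (
        table.groupby(["experiment", "vector", "mouse"], sort=True)["tetramer_pct"]
        .max()
        .rename("peak")
        .reset_index()
    )
    return peaks


def normalize_to_reference(
    table: pd.DataFrame, reference_vector: str = "rAd_1"
) -> pd.DataFrame:
    """Normalized expansion ratio per vector.

    Within each experiment: group mean of per-mouse peaks divided by the
    reference group's mean of per-mouse peaks. When a vector appears in
    several experiments the per-experiment ratios are averaged afterwards
    (ratio first, then mean); the number of contributing experiments is
    reported in ``n_experiments``.
    """
    peaks = mouse_peaks(table)
    group_means = (
        peaks.groupby(["experiment", "vector"], sort=True)["peak"].mean().rename("mean_peak")
    )
    ratios = []
    for experiment, sub in group_means.groupby(level="experiment", sort=True):
        sub = sub.droplevel("experiment")
        if reference_vector not in sub.index:
            raise ClassingError(
                f"experiment {experiment!r} lacks reference group {reference_vector!r}"
            )
        ref = sub.loc[reference_vector]
        if ref == 0:
            raise ClassingError(f"experiment {experiment!r}: reference mean is zero")
        for vector, mean_peak in sub.items():
            ratios.append((experiment, vector, mean_peak / ref))
    out = pd.DataFrame(ratios, columns=["experiment", "vector", "ratio"])
    agg = out.groupby("vector", sort=True)["ratio"].agg(["mean", "size"])
    return pd.DataFrame(
        {"ratio": agg["mean"], "n_experiments": agg["size"].astype(int)}
    ).rename_axis("vector")


def cluster_classes(ratios: pd.Series, k: int = 3) -> pd.DataFrame:
    """Ward.D2 hierarchical clustering of expansion ratios into classes.

    The tree is cut at ``k`` clusters; the cluster with the lowest mean
    ratio becomes ``Weak`` and all others ``Strong``. Equal lowest means
    are refused rather than broken arbitrarily.
    """
    ratios = pd.Series(ratios, dtype=float)
    if len(ratios) < k:
        raise ClassingError(f"need at least k={k} vectors, got {len(ratios)}")
    # scipy's 'ward' on raw Euclidean observations is the Ward.D2
    # (Murtagh-Legendre) recurrence named in the clustering convention.
    order = ratios.sort_index()
    Z = linkage(order.to_numpy()[:, None], method="ward")
    clusters = fcluster(Z, t=k, criterion="maxclust")
    out = pd.DataFrame({"ratio": order, "cluster": clusters})
    means = out.groupby("cluster")["ratio"].mean().sort_values(kind="mergesort")
    if len(means) < k:
        raise ClassingError(
            f"degenerate ratios: the cut produced {len(means)} < k={k} clusters"
        )
    if np.isclose(means.iloc[0], means.iloc[1]):
        raise ClassingError("tied lowest cluster means; cannot assign Weak class")
    weak_cluster = means.index[0]
    out["class"] = np.where(out["cluster"] == weak_cluster, "Weak", "Strong")
    return out.rename_axis("vector")


def classify_vectors(
    table: pd.DataFrame, reference_vector: str = "rAd_1", k: int = 3
) -> pd.DataFrame:
    """Full classing pipeline: peaks -> ratios -> Ward.D2 classes."""
    ratios = normalize_to_reference(table, reference_vector)
    classing = cluster_classes(ratios["ratio"], k=k)
    return classing.join(ratios["n_experiments"])
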