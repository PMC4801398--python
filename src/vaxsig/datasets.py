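"""Core data containers and their plain-text serialization.

An :class:`ExpressionDataset` holds one vector-immunization experiment:
a probes/genes x samples intensity matrix with ``vector`` and ``control``
group labels, an optional per-probe detection p-value matrix of the same
shape, and a probe -> gene-symbol map. Tetramer response tables are plain
pandas DataFrames with columns ``experiment, vector, mouse, day,
tetramer_pct``.

On disk a dataset is a gzipped TSV matrix plus small TSV sidecars, so
every artifact stays text-only and diffable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .utils import logger

RESPONSE_COLUMNS = ["experiment", "vector", "mouse", "day", "tetramer_pct"]


@dataclass
class ExpressionDataset:
    """One vector experiment: genes x samples with group metadata.

    Parameters
    ----------
    values : pandas.DataFrame
        Probe/gene x sample numeric matrix (intensity or log2 scale,
        tracked through ``provenance``).
    groups : pandas.Series
        Sample -> ``"vector"`` or ``"control"``, indexed like the columns
        of ``values``.
    vector_id : str
        Vaccine vector identifier (e.g. ``"rAd_1"``).
    platform : str
        Microarray platform tag; restricts the gene panel.
    tissue : str
        One of ``DC``, ``spleen``, ``PBMC`` (metadata only; the prediction
        pipeline is identical across tissues).
    detection_p : pandas.DataFrame, optional
        Detection p-values aligned with ``values``.
    probe_map : pandas.Series, optional
        Probe -> gene symbol.
    """

    values: pd.DataFrame
    groups: pd.Series
    vector_id: str
    platform: str = "codelink"
    tissue: str = "DC"
    detection_p: pd.DataFrame | None = None
    probe_map: pd.Series | None = None
    dataset_id: str | None = None
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.dataset_id is None:
            self.dataset_id = self.vector_id
        self.groups = pd.Series(self.groups)
        if list(self.groups.index) != list(self.values.columns):
            self.groups = self.groups.reindex(self.values.columns)
        if self.groups.isna().any():
            raise ValueError(f"{self.dataset_id}: every sample needs a group label")
        bad = set(self.groups.unique()) - {"vector", "control"}
        if bad:
            raise ValueError(f"{self.dataset_id}: unknown group labels {sorted(bad)}")
        if self.detection_p is not None and self.detection_p.shape != self.values.shape:
            raise ValueError(f"{self.dataset_id}: detection_p shape mismatch")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError(f"{self.dataset_id}: non-finite expression values")

    # -- convenience ----------------------------------------------------
    @property
    def vector_samples(self) -> list[str]:
        return list(self.groups.index[self.groups == "vector"])

    @property
    def control_samples(self) -> list[str]:
        return list(self.groups.index[self.groups == "control"])

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def n_per_group(self) -> tuple[int, int]:
        return len(self.vector_samples), len(self.control_samples)

    def subset_positions(self, positions: list[int], tag: str) -> "ExpressionDataset":
        """Column subset by position; duplicates allowed (bootstrap draws).

        Duplicated columns are renamed ``<sample>.r<i>`` to keep sample
        names unique.
        """
        cols = [self.values.columns[i] for i in positions]
        names = [f"{c}.r{i}" for i, c in enumerate(cols)]
        vals = self.values.iloc[:, positions].copy()
        vals.columns = names
        grp = pd.Series(self.groups.iloc[positions].to_numpy(), index=names)
        detp = None
        if self.detection_p is not None:
            detp = self.detection_p.iloc[:, positions].copy()
            detp.columns = names
        return replace(
            self,
            values=vals,
            groups=grp,
            detection_p=detp,
            dataset_id=f"{self.dataset_id}|{tag}",
            provenance=self.provenance + [f"subset:{tag}"],
        )

    # -- serialization --------------------------------------------------
    def to_tsv(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        self.values.rename_axis("probe").to_csv(f"{prefix}.expr.tsv.gz", sep="\t")
        meta = pd.DataFrame(
            {
                "sample": self.groups.index,
                "group": self.groups.to_numpy(),
                "vector_id": self.vector_id,
                "platform": self.platform,
                "tissue": self.tissue,
                "dataset_id": self.dataset_id,
            }
        )
        meta.to_csv(f"{prefix}.samples.tsv", sep="\t", index=False)
        if self.detection_p is not None:
            self.detection_p.rename_axis("probe").to_csv(
                f"{prefix}.detp.tsv.gz", sep="\t"
            )
        if self.probe_map is not None:
            self.probe_map.rename_axis("probe").rename("symbol").to_csv(
                f"{prefix}.map.tsv", sep="\t"
            )

    @classmethod
    def from_tsv(cls, prefix: str | Path) -> "ExpressionDataset":
        prefix = Path(prefix)
        values = pd.read_csv(f"{prefix}.expr.tsv.gz", sep="\t", index_col=0)
        meta = pd.read_csv(f"{prefix}.samples.tsv", sep="\t")
        groups = pd.Series(meta["group"].to_numpy(), index=meta["sample"])
        detp = None
        if Path(f"{prefix}.detp.tsv.gz").exists():
            detp = pd.read_csv(f"{prefix}.detp.tsv.gz", sep="\t", index_col=0)
        probe_map = None
        if Path(f"{prefix}.map.tsv").exists():
            pm = pd.read_csv(f"{prefix}.map.tsv", sep="\t", index_col=0)
            probe_map = pm["symbol"]
        row = meta.iloc[0]
        return cls(
            values=values,
            groups=groups,
            vector_id=str(row["vector_id"]),
            platform=str(row["platform"]),
            tissue=str(row["tissue"]),
            detection_p=detp,
            probe_map=probe_map,
            dataset_id=str(row["dataset_id"]),
        )


def validate_response_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the tetramer kinetics table contract and return it.

    Requires the canonical columns, non-negative percentages and days in
    {5, 7, 10}.
    """
    missing = [c for c in RESPONSE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"response table missing columns {missing}")
    if (table["tetramer_pct"] < 0).any():
        raise ValueError("tetramer_pct must be >= 0")
    bad_days = set(table["day"].unique()) - {5, 7, 10}
    if bad_days:
        raise ValueError(f"days outside {{5,7,10}}: {sorted(bad_days)}")
    return table


def read_response_table(path: str | Path) -> pd.DataFrame:
    return validate_response_table(pd.read_csv(path, sep="\t"))


def write_response_table(table: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    validate_response_table(table)[RESPONSE_COLUMNS].to_csv(path, sep="\t", index=False)


def log_dropped(stage: str, n: int, what: str) -> None:
    if n:
        logger.info("%s: dropped %d %s", stage, n, what)
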