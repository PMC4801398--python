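"""Pipeline configuration, presets and seed schedules."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .utils import derive_seed

#: Named presets. "paper" carries the canonical defaults of the published
#: protocol (100 bootstraps per dataset, 2000-tree forests, z = 3 tails,
#: minimum 7 detected genes, GSEA weight 1, 1000 permutations, 3 response
#: clusters); "demo" is a minutes-scale configuration for smoke runs.
PRESETS: dict[str, dict] = {
    "paper": dict(
        B=100,
        M=100,
        n_perm=1000,
        n_trees=2000,
        z_threshold=3.0,
        min_genes=7,
        gsea_weight=1.0,
        k_clusters=3,
        alpha=0.05,
        importance_threshold=10.0,
    ),
    "demo": dict(
        B=5,
        M=5,
        n_perm=50,
        n_trees=200,
        z_threshold=3.0,
        min_genes=7,
        gsea_weight=1.0,
        k_clusters=3,
        alpha=0.05,
        importance_threshold=10.0,
        sim=dict(
            n_genes=600,
            n_sources=3,
            tail_fraction=0.03,  # 12 genes per tail, above the 7-gene floor
            n_vectors_strong=3,
            n_vectors_weak=3,
            n_mice_per_group=4,
        ),
    ),
}


@dataclass
class PipelineConfig:
    """All stage parameters plus the global seed.

    Every stochastic stage derives its own seed deterministically from
    ``seed`` + stage name + dataset id (see :func:`vaxsig.utils.derive_seed`),
    so a config fully determines the run.
    """

    seed: int = 0
    outdir: str = "vaxsig_out"
    B: int = 100
    M: int = 100
    n_perm: int = 1000
    n_trees: int = 2000
    mtry: int | None = None
    z_threshold: float = 3.0
    min_genes: int = 7
    gsea_weight: float = 1.0
    k_clusters: int = 3
    alpha: float = 0.05
    importance_threshold: float = 10.0
    n_components: int | None = None
    n_decoys: int = 0
    decoy_sizes: tuple[int, int] = (10, 200)
    reference_vector: str = "rAd_1"
    class_cv: float = 0.3
    paired: bool = False
    run_loo: bool = False
    sim: dict = field(default_factory=dict)

    def validate(self) -> "PipelineConfig":
        positive = ["B", "M", "n_perm", "n_trees", "min_genes", "k_clusters"]
        for name in positive:
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.z_threshold <= 0 or self.gsea_weight < 0:
            raise ValueError("invalid z_threshold / gsea_weight")
        return self

    def stage_seed(self, stage: str, *parts: object) -> int:
        return derive_seed(self.seed, stage, *parts)

    @classmethod
    def from_preset(cls, name: str, **overrides) -> "PipelineConfig":
        if name not in PRESETS:
            raise KeyError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
        params = {**PRESETS[name], **overrides}
        return cls(**params).validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        preset = raw.pop("preset", None)
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        if preset:
            return cls.from_preset(preset, **raw)
        return cls(**raw).validate()

    def to_yaml(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        payload = asdict(self)
        payload["decoy_sizes"] = list(self.decoy_sizes)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs).validate()
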