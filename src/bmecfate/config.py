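"""Run configuration: every threshold of the funnel and screen in one place.

The funnel is a stack of hard thresholds; an audit of any run starts from
the resolved configuration, so the config is a flat dataclass that round-
trips through YAML and is written next to every run's outputs.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .types import ValidationError


@dataclass
class RunConfig:
    """Thresholds and knobs for the full prioritization pipeline.

    Defaults follow the published funnel where it states a value
    (sensitivity > 0.1, specificity > 0.8, MI score > -1.3, recipient
    TPM < 2, capillary median AUC > 0.08, NES > 3, clustering resolution
    0.8, log2FD threshold log2(1.275)); knobs the study left unstated
    (AUC top fraction, initial-screen floors, permutation count) carry
    documented defaults here.
    """

    # --- regulon activity ---
    auc_top_fraction: float = 0.05
    mi_n_bins: int = 0  # 0 -> ceil(N ** (1/3))

    # --- initial candidate screen (floors unstated in the source study) ---
    brain_auc_floor: float = 0.0
    murine_relative_activity_floor: float = 1.0

    # --- sensitivity / specificity / MI filter ---
    sensitivity_min: float = 0.1
    specificity_min: float = 0.8
    mi_min: float = -1.3  # applied to log10(MI + mi_epsilon)
    mi_epsilon: float = 1e-6
    sensitivity_mode: str = "any"  # any | all marker sets must pass

    # --- recipient expression filter ---
    tpm_max: float = 2.0
    force_include: list[str] = field(default_factory=lambda: ["ZIC3"])

    # --- capillary / context filter ---
    capillary_auc_min: float = 0.08
    capillary_mi_min: float = 0.05
    module_filter_hard: bool = False
    fetal_filter_hard: bool = False

    # --- co-expression modules ---
    nes_min: float = 3.0
    min_module_size: int = 30
    merge_dissimilarity: float = 0.3
    soft_power_r2_target: float = 0.8
    module_score_weight: float = 0.25

    # --- marker selection ---
    de_min_pct: float = 0.25
    de_fc_threshold: float = 1.2
    marker_fold_strict: float = 4.0
    marker_fold_lenient: float = 2.0
    percentile_q: float = 0.9
    percentile_fold_strict: float = 7.0
    percentile_fold_lenient: float = 7.5
    set3_mode: str = "all"  # all | any designated sc dataset

    # --- screen / clustering ---
    n_pcs_computed: int = 50
    n_pcs_used: int = 15
    k_neighbors: int = 20
    clustering_resolution: float = 0.8
    n_hvg: int = 2000
    scale_clip: float = 10.0
    genotype_min_umis: int = 5
    genotype_dominance_fraction: float = 0.5
    genotype_max_multiplicity: int = 3
    screen_min_pct: float = 0.01
    screen_logfc_min: float = 0.25
    screen_p_max: float = 0.05
    log2fd_threshold: float = math.log2(1.275)
    permutations: int = 1000
    proportion_alpha: float = 0.05
    min_cells_per_genotype: int = 5

    # --- global ---
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("auc_top_fraction", "percentile_q"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValidationError(f"{name} must be in (0, 1], got {v}")
        if self.permutations < 100:
            raise ValidationError("permutations must be >= 100")
        if self.seed is None:
            raise ValidationError("a seed must always be set")
        if self.sensitivity_mode not in ("any", "all"):
            raise ValidationError("sensitivity_mode must be 'any' or 'all'")
        if self.set3_mode not in ("all", "any"):
            raise ValidationError("set3_mode must be 'all' or 'any'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(d) - known)
        if unknown:
            raise ValidationError(f"unknown config keys: {unknown}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True, default_flow_style=False)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def replace(self, **overrides) -> "RunConfig":
        return dataclasses.replace(self, **overrides)
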