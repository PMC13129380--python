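"""Run configuration: nested dataclasses mirroring the YAML run-config file.

Sections: ``quality.*`` (screening), ``cfcm.*`` (cell comparison),
``mil.*`` (the attention-MIL network and training loop), ``sim.*``
(synthetic cohort generation) and ``experiment.*`` (seed lists for the
ablation / K-sweep experiment runners).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .quality_screening import ScreeningConfig
from .synthetic_cohort import SimulationConfig


@dataclass
class CfcmConfig:
    """Cell-feature comparison module settings."""

    k_clusters: int = 8          # K-means prototype count; 8 is the sweet spot
    mode: str = "difference"     # 'difference', 'concat' or 'nearest_center'
    reference: str = "center_mean"   # or 'global_mean'
    tau: float = 0.1             # SupCon temperature
    seed: int = 0                # k-means++ seed
    apply_supcon_to: str = "enhanced"  # or 'raw'

    def __post_init__(self) -> None:
        if self.k_clusters < 1:
            raise ValueError("k_clusters must be >= 1")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.mode not in ("difference", "concat", "nearest_center"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.reference not in ("center_mean", "global_mean"):
            raise ValueError(f"unknown reference {self.reference!r}")
        if self.apply_supcon_to not in ("enhanced", "raw"):
            raise ValueError(f"unknown apply_supcon_to {self.apply_supcon_to!r}")


@dataclass
class MilConfig:
    """Attention-MIL architecture and optimizer settings.

    ``lam`` is the joint-loss weight: L = lam * L_bag + (1 - lam) * L_supcon.
    The three ablation switches map to the quality screening stage
    (``use_qism``), the comparison/enhancement stage (``use_cfcm``) and
    quality-score instance weighting (``use_qam``).
    """

    L: int = 128
    lam: float = 0.7
    epochs: int = 30
    lr: float = 1e-3
    batch_bags: int = 8
    use_qism: bool = True
    use_cfcm: bool = True
    use_qam: bool = True
    seed: int = 42
    include_normals_in_bag: bool = True
    supcon_batch_cap: int = 1024

    def __post_init__(self) -> None:
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")
        if self.L < 1 or self.epochs < 1 or self.batch_bags < 1:
            raise ValueError("L, epochs and batch_bags must be >= 1")
        if self.lr <= 0:
            raise ValueError("lr must be positive")


@dataclass
class ExperimentConfig:
    """Seed lists and grids for the experiment runners."""

    seeds: tuple[int, ...] = (0, 1, 2, 3, 4)
    k_values: tuple[int, ...] = (2, 4, 8, 12, 16)


@dataclass
class RunConfig:
    quality: ScreeningConfig = field(default_factory=ScreeningConfig)
    cfcm: CfcmConfig = field(default_factory=CfcmConfig)
    mil: MilConfig = field(default_factory=MilConfig)
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)


_SECTIONS = {
    "quality": ScreeningConfig,
    "cfcm": CfcmConfig,
    "mil": MilConfig,
    "sim": SimulationConfig,
    "experiment": ExperimentConfig,
}
# YAML spellings that differ from field names
_ALIASES = {"mil": {"lambda": "lam"}}


def run_config_from_dict(data: dict) -> RunConfig:
    kwargs = {}
    for section, cls in _SECTIONS.items():
        sub = dict(data.get(section) or {})
        aliases = _ALIASES.get(section, {})
        sub = {aliases.get(k, k): v for k, v in sub.items()}
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(sub) - valid
        if unknown:
            raise ValueError(f"unknown key(s) {sorted(unknown)} in section "
                             f"{section!r}")
        for f in dataclasses.fields(cls):
            if f.name in sub and isinstance(f.default, tuple):
                sub[f.name] = tuple(sub[f.name])
        kwargs[section] = cls(**sub)
    unknown_sections = set(data) - set(_SECTIONS)
    if unknown_sections:
        raise ValueError(f"unknown config section(s) {sorted(unknown_sections)}")
    return RunConfig(**kwargs)


def run_config_to_dict(cfg: RunConfig) -> dict:
    out: dict = {}
    for section in _SECTIONS:
        d = dataclasses.asdict(getattr(cfg, section))
        aliases = {v: k for k, v in _ALIASES.get(section, {}).items()}
        out[section] = {aliases.get(k, k): (list(v) if isinstance(v, tuple)
                                            else v)
                        for k, v in d.items()}
    return out


def load_run_config(path: str | None) -> RunConfig:
    """Load the YAML run-config; a missing/None path yields all defaults."""
    if path is None:
        return RunConfig()
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return run_config_from_dict(data)


def save_run_config(cfg: RunConfig, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(run_config_to_dict(cfg), fh, sort_keys=False)
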