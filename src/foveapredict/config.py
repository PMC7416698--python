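"""Run configuration: every tunable of the end-to-end pipeline, serializable
to YAML so a run is reproducible from its persisted config + seed."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "results/run"

    # cohort sizes
    n_ird: int = 26
    n_normal: int = 3
    n_bcm_deletion: int = 8
    n_bcm_c203r: int = 8

    # generator noise / coupling
    noise_fs_sd: float = 1.5  # dB
    noise_va_sd: float = 0.08  # logMAR
    onl_cos_corr: float = 0.814

    # rendering / acquisition
    lateral_extent_deg: float = 1.8
    render_n_ascans: int = 192
    downsample_target_per_15deg: int = 512
    axial_step_um: float = 2.0
    render_noise_sd: float = 0.03

    # model hyperparameters
    n_trees: int = 500
    min_leaf: int = 2
    include_ecc_in_model_ii: bool = True

    # potential
    nd_floor_db: float = 0.0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
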