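"""Run configuration: validated key-value files driving the CLI pipeline."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "load_config", "dump_config", "setup_logging"]


@dataclass
class SimulateConfig:
    scene: str = "phantom"            # phantom | retina | single_reflector
    concentration_mg_ml: float = 10.0
    pigmented: bool = True
    seed: int = 0
    n_ascans: int = 128
    repeats: int = 3
    n_pixels: int = 2048
    lam_min_nm: float = 425.0
    lam_max_nm: float = 735.0
    read_noise_sd: float = 1.5e-3
    shot_noise: bool = False
    a2_um2: float = 0.0
    a3_um3: float = 0.0
    lateral_pitch_um: float = 1.5
    reflector_z_um: float = 100.0


@dataclass
class BandsConfig:
    n_tissue: float = 1.38
    target_resolution_um: float = 6.0
    n_k: int = 2048
    estimate_dispersion: bool = False


@dataclass
class AnalysisConfig:
    min_area_um2: float = 8.0
    threshold_k: float = 3.0
    window_um: float = 50.0
    margin_um: float = 6.0
    rgb_bands_nm: tuple = (540.0, 550.0, 560.0)


@dataclass
class MieConfig:
    material: str = "melanin"
    medium: str = "rpe_medium"
    diameters_um: tuple = (0.3, 0.5, 0.7, 1.0)
    concentration_mg_ml: float = 10.0
    lam_min_nm: float = 440.0
    lam_max_nm: float = 700.0
    lam_step_nm: float = 1.0


@dataclass
class RunConfig:
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    bands: BandsConfig = field(default_factory=BandsConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    mie: MieConfig = field(default_factory=MieConfig)


def _build(cls, data: dict, path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(
            f"unknown configuration key(s) {sorted(unknown)} in section "
            f"'{path}'; known: {sorted(fields)}"
        )
    clean = {
        k: tuple(v) if isinstance(v, list) else v for k, v in data.items()
    }
    return cls(**clean)


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML config; missing file/section → defaults.

    Unknown keys are rejected with the offending key named.
    """
    if path is None:
        return RunConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    sections = {
        "simulate": SimulateConfig,
        "bands": BandsConfig,
        "analysis": AnalysisConfig,
        "mie": MieConfig,
    }
    unknown = set(data) - set(sections)
    if unknown:
        raise ValueError(f"unknown configuration section(s) {sorted(unknown)}")
    kwargs = {}
    for name, cls in sections.items():
        sec = data.get(name, {})
        if not isinstance(sec, dict):
            raise ValueError(f"section '{name}' must be a mapping")
        kwargs[name] = _build(cls, sec, name)
    return RunConfig(**kwargs)


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    """Echo the fully resolved configuration beside the outputs."""
    out = {
        name: dataclasses.asdict(getattr(cfg, name))
        for name in ("simulate", "bands", "analysis", "mie")
    }
    for sec in out.values():
        for key, val in sec.items():
            if isinstance(val, tuple):
                sec[key] = list(val)
    Path(path).write_text(yaml.safe_dump(out, sort_keys=False))


def setup_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )
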