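"""Pipeline configuration: defaults, YAML (de)serialization, validation.

An empty config file yields the full default parametrization (the measured
phase-length table, cell diameter 13.2 um, G0->G1 delay 48 h, growth
fraction 0.88, printed ABC priors).  Unknown keys are rejected by name so
typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .phases import LONG_PARAMS, SHORT_PARAMS, PhaseLengthParams
from .recruitment import SHORTENING_MODES, RecruitmentSignal
from .simulator import DEFAULT_SNAPSHOT_TIMES, SimConfig

__all__ = ["ConfigError", "PipelineConfig", "load_config", "save_config"]


class ConfigError(ValueError):
    """Raised on malformed configuration, naming the offending key."""


@dataclass(frozen=True)
class PhaseSection:
    g1_mean: float = LONG_PARAMS.g1_mean
    g1_sd: float = LONG_PARAMS.g1_sd
    s_mean: float = LONG_PARAMS.s_mean
    s_sd: float = LONG_PARAMS.s_sd
    g2m_mean: float = LONG_PARAMS.g2m_mean
    g2m_sd: float = LONG_PARAMS.g2m_sd
    t_g0_g1: float = LONG_PARAMS.t_g0_g1


@dataclass(frozen=True)
class SimSection:
    n0: int = 196
    gf: float = 0.88
    cell_diameter_um: float = 13.2
    cell_length_sd_um: float = 0.0
    dt_h: float = 1.0
    duration_h: float = 192.0


@dataclass(frozen=True)
class SignalSection:
    lam_um: float = 828.0
    tau_h: float = 85.0
    shortening_mode: str = "both"


@dataclass(frozen=True)
class AbcSection:
    population_size: int = 1000
    max_generations: int = 12
    min_acceptance_rate: float = 0.05
    n0_prior: tuple[int, int] = (100, 300)
    lam_prior: tuple[int, int] = (500, 1500)
    tau_prior: tuple[int, int] = (1, 192)


@dataclass(frozen=True)
class ZonesSection:
    population_size: int = 1000
    iterations: int = 30


@dataclass(frozen=True)
class SwitchpointTruthSection:
    n0: int = 200
    lam_um: float = 800.0
    tau_h: float = 96.0
    days: tuple[float, ...] = (4.0, 6.0, 8.0)
    sigma_um: float = 50.0
    n_replicates: int = 20


@dataclass(frozen=True)
class FucciTruthSection:
    day: float = 4.0
    border_um: float | None = -700.0
    g0g1_a: float = 85.0
    sg2_a: float = 11.0
    g0g1_p: float = 45.0
    sg2_p: float = 50.0
    n_animals: int = 4
    cells_per_animal: int = 300
    bin_width_um: float = 100.0
    ap_min_um: float = -1600.0
    ap_max_um: float = 0.0


@dataclass(frozen=True)
class PipelineConfig:
    phases_long: PhaseSection = field(default_factory=PhaseSection)
    phases_short: PhaseSection = field(
        default_factory=lambda: PhaseSection(
            g1_mean=SHORT_PARAMS.g1_mean,
            g1_sd=SHORT_PARAMS.g1_sd,
            s_mean=SHORT_PARAMS.s_mean,
            s_sd=SHORT_PARAMS.s_sd,
            g2m_mean=SHORT_PARAMS.g2m_mean,
            g2m_sd=SHORT_PARAMS.g2m_sd,
            t_g0_g1=SHORT_PARAMS.t_g0_g1,
        )
    )
    sim: SimSection = field(default_factory=SimSection)
    signal: SignalSection = field(default_factory=SignalSection)
    abc: AbcSection = field(default_factory=AbcSection)
    zones: ZonesSection = field(default_factory=ZonesSection)
    switchpoint_truth: SwitchpointTruthSection = field(
        default_factory=SwitchpointTruthSection
    )
    fucci_truth: FucciTruthSection = field(default_factory=FucciTruthSection)
    seed: int = 0
    outdir: str = "axregen-out"

    def validate(self) -> None:
        if self.signal.tau_h <= 0:
            raise ConfigError(f"signal.tau_h must be > 0, got {self.signal.tau_h}")
        if self.signal.lam_um < 0:
            raise ConfigError(f"signal.lam_um must be >= 0, got {self.signal.lam_um}")
        if self.signal.shortening_mode not in SHORTENING_MODES:
            raise ConfigError(
                f"signal.shortening_mode must be one of {SHORTENING_MODES}, "
                f"got {self.signal.shortening_mode!r}"
            )
        if not (0 <= self.sim.gf <= 1):
            raise ConfigError(f"sim.gf must be in [0, 1], got {self.sim.gf}")
        if self.sim.n0 < 1:
            raise ConfigError(f"sim.n0 must be >= 1, got {self.sim.n0}")
        if self.sim.dt_h <= 0:
            raise ConfigError(f"sim.dt_h must be > 0, got {self.sim.dt_h}")
        for name in ("phases_long", "phases_short"):
            sec = getattr(self, name)
            for key in ("g1_mean", "s_mean", "g2m_mean"):
                if getattr(sec, key) <= 0:
                    raise ConfigError(
                        f"{name}.{key} must be > 0, got {getattr(sec, key)}"
                    )
            for key in ("g1_sd", "s_sd", "g2m_sd"):
                if getattr(sec, key) < 0:
                    raise ConfigError(
                        f"{name}.{key} must be >= 0, got {getattr(sec, key)}"
                    )

    # -- conversions --------------------------------------------------------

    def phase_params(self, regime: str) -> PhaseLengthParams:
        sec = self.phases_long if regime == "long" else self.phases_short
        return PhaseLengthParams(
            g1_mean=sec.g1_mean,
            g1_sd=sec.g1_sd,
            s_mean=sec.s_mean,
            s_sd=sec.s_sd,
            g2m_mean=sec.g2m_mean,
            g2m_sd=sec.g2m_sd,
            t_g0_g1=sec.t_g0_g1,
        )

    def recruitment_signal(self) -> RecruitmentSignal:
        return RecruitmentSignal(
            lam=self.signal.lam_um,
            tau=self.signal.tau_h,
            shortening_mode=self.signal.shortening_mode,
        )

    def sim_config(self, with_signal: bool = True, snapshots: bool = False) -> SimConfig:
        return SimConfig(
            n0=self.sim.n0,
            gf=self.sim.gf,
            cell_diameter=self.sim.cell_diameter_um,
            cell_length_sd=self.sim.cell_length_sd_um,
            dt=self.sim.dt_h,
            duration=self.sim.duration_h,
            signal=self.recruitment_signal() if with_signal else None,
            long_params=self.phase_params("long"),
            short_params=self.phase_params("short"),
            snapshot_times=DEFAULT_SNAPSHOT_TIMES if snapshots else (),
            record_events=snapshots,
        )

    def to_dict(self) -> dict:
        return _asdict(self)

    def sha256(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


def _asdict(obj):
    if dataclasses.is_dataclass(obj):
        return {
            f.name: _asdict(getattr(obj, f.name)) for f in dataclasses.fields(obj)
        }
    if isinstance(obj, tuple):
        return [_asdict(v) for v in obj]
    return obj


_TUPLE_FIELDS = {"days", "n0_prior", "lam_prior", "tau_prior"}


def _build(cls, data: dict, path: str):
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"section '{path}' must be a mapping")
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in section '{path or 'top level'}'"
        )
    kwargs = {}
    for key, value in data.items():
        f = names[key]
        sub = f.type if isinstance(f.type, type) else None
        if sub is not None and dataclasses.is_dataclass(sub):
            kwargs[key] = _build(sub, value, f"{path}.{key}" if path else key)
        elif key in _TUPLE_FIELDS and isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid section '{path or 'top level'}': {exc}") from exc


_SECTION_TYPES = {
    "phases_long": PhaseSection,
    "phases_short": PhaseSection,
    "sim": SimSection,
    "signal": SignalSection,
    "abc": AbcSection,
    "zones": ZonesSection,
    "switchpoint_truth": SwitchpointTruthSection,
    "fucci_truth": FucciTruthSection,
}


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML pipeline config; empty file = all defaults."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    top_names = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - top_names
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    kwargs = {}
    for key, value in raw.items():
        if key in _SECTION_TYPES:
            kwargs[key] = _build(_SECTION_TYPES[key], value, key)
        else:
            kwargs[key] = value
    cfg = PipelineConfig(**kwargs)
    cfg.validate()
    return cfg


def save_config(cfg: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
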