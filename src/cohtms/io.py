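"""Configuration, session logs, and run manifests.

Config files are YAML with nested sections (``dsp``, ``synth``, ``mep``,
``trigger``, ``stats``, ``output``); every key has a documented default,
unknown keys are rejected by name.  Session logs are plain CSV
(comma-separated, '.' decimal, UTF-8, LF) with full-precision floats so a
write/read round trip reproduces the session exactly.  Every CLI run
writes a manifest (config hash, seed, package version) sufficient to
reproduce it bit-exactly.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .dsp import DspParams
from .synth import MEPModel, SynthConfig
from .trigger import SessionResult, StimulusEvent, TriggerConfig

__all__ = [
    "RunConfig",
    "StatsSettings",
    "TriggerSettings",
    "load_config",
    "dump_config",
    "write_session_csv",
    "read_session_csv",
    "write_manifest",
    "spawn_seeds",
]

CSV_COLUMNS = ["time_s", "coh_at_stim", "threshold_at_stim", "modified", "mep_mV"]


@dataclass(frozen=True)
class TriggerSettings:
    """Trigger section of the run config.

    ``initial_threshold`` may be left unset (None): it is then derived by
    baseline calibration at run time.
    """

    initial_threshold: float | None = None
    delta: float = 0.05
    modification_onset: float = 30.0
    pause: float = 10.0
    recharge_limit: float = 60.0
    n_stimuli: int = 10
    threshold_floor: float = 0.0
    modification_enabled: bool = True
    target_count: int = 6
    interval_low: float = 25.0
    interval_high: float = 35.0

    def __post_init__(self) -> None:
        # delegate range checks to TriggerConfig with a placeholder threshold
        thr = self.initial_threshold if self.initial_threshold is not None else 1.0
        self.to_trigger_config(thr)
        if self.target_count < 1:
            raise ValueError("target_count must be at least 1")
        if not self.interval_low < self.interval_high:
            raise ValueError("need interval_low < interval_high")

    def to_trigger_config(self, initial_threshold: float) -> TriggerConfig:
        return TriggerConfig(
            initial_threshold=initial_threshold,
            delta=self.delta,
            modification_onset=self.modification_onset,
            pause=self.pause,
            recharge_limit=self.recharge_limit,
            n_stimuli=self.n_stimuli,
            threshold_floor=self.threshold_floor,
            modification_enabled=self.modification_enabled,
        )


@dataclass(frozen=True)
class StatsSettings:
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class RunConfig:
    dsp: DspParams = field(default_factory=DspParams)
    synth: SynthConfig = field(default_factory=SynthConfig)
    mep: MEPModel = field(default_factory=MEPModel)
    trigger: TriggerSettings = field(default_factory=TriggerSettings)
    stats: StatsSettings = field(default_factory=StatsSettings)
    seed: int = 0
    output_dir: str = "results"


_SECTIONS = {
    "dsp": DspParams,
    "synth": SynthConfig,
    "mep": MEPModel,
    "trigger": TriggerSettings,
    "stats": StatsSettings,
}
_TOP_LEVEL = set(_SECTIONS) | {"seed", "output_dir"}


def _build_section(cls, section: str, mapping: dict):
    known = {f.name for f in dataclasses.fields(cls) if f.init and not f.name.startswith("_")}
    unknown = set(mapping) - known
    if unknown:
        raise ValueError(
            f"unknown key(s) in '{section}' section: {sorted(unknown)}"
        )
    # YAML reads tuples as lists; coerce for tuple-typed fields like dsp.band
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in mapping.items()
    }
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid value in '{section}' section: {exc}") from exc


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run config; an empty file means all defaults.

    Unknown keys at any level raise ``ValueError`` naming the key.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(raw) - _TOP_LEVEL
    if unknown:
        raise ValueError(f"unknown top-level key(s): {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        section = raw.get(name, {}) or {}
        if not isinstance(section, dict):
            raise ValueError(f"section '{name}' must be a mapping")
        kwargs[name] = _build_section(cls, name, section)
    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])
    if "output_dir" in raw:
        kwargs["output_dir"] = str(raw["output_dir"])
    return RunConfig(**kwargs)


def _section_dict(obj) -> dict:
    d = {}
    for f in dataclasses.fields(obj):
        if not f.init or f.name.startswith("_"):
            continue
        v = getattr(obj, f.name)
        d[f.name] = list(v) if isinstance(v, tuple) else v
    return d


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    """Write a config back to YAML (inverse of :func:`load_config`)."""
    doc = {name: _section_dict(getattr(cfg, name)) for name in _SECTIONS}
    doc["seed"] = cfg.seed
    doc["output_dir"] = cfg.output_dir
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def write_session_csv(result: SessionResult, path: str | Path) -> None:
    """Write one event per row; floats at full precision for exact reload."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(CSV_COLUMNS)
        for e in result.events:
            writer.writerow([
                repr(float(e.time)),
                repr(float(e.coh_at_stim)),
                repr(float(e.threshold_at_stim)),
                int(e.modified),
                repr(float(e.mep_amplitude)) if e.mep_amplitude is not None else "",
            ])


def read_session_csv(path: str | Path, condition: str = "coherence_triggered") -> SessionResult:
    """Reload a session log written by :func:`write_session_csv`."""
    events: list[StimulusEvent] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header != CSV_COLUMNS:
            raise ValueError(f"unexpected session CSV header: {header}")
        for row in reader:
            events.append(StimulusEvent(
                time=float(row[0]),
                coh_at_stim=float(row[1]),
                threshold_at_stim=float(row[2]),
                modified=bool(int(row[3])),
                mep_amplitude=float(row[4]) if row[4] else None,
            ))
    times = [e.time for e in events]
    intervals = tuple(np.diff([0.0] + times).tolist())
    return SessionResult(
        events=tuple(events),
        inter_stimulus_intervals=intervals,
        total_time=times[-1] if times else 0.0,
        condition=condition,
    )


def config_hash(cfg: RunConfig) -> str:
    doc = {name: _section_dict(getattr(cfg, name)) for name in _SECTIONS}
    doc["seed"] = cfg.seed
    blob = json.dumps(doc, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def write_manifest(cfg: RunConfig, path: str | Path, **extra) -> None:
    """Record everything needed to reproduce a run bit-exactly."""
    from . import __version__

    manifest = {
        "package": "cohtms",
        "version": __version__,
        "seed": cfg.seed,
        "config_sha256": config_hash(cfg),
        **extra,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def spawn_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic sub-seed fan-out (each below 2**31).

    Sub-streams for the synthetic EEG, the MEP draws, and the control
    intervals are derived from one master seed so that ablations share
    noise realizations.
    """
    state = np.random.SeedSequence(master_seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31)) for s in state]
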