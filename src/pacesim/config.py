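"""Scenario configuration files (YAML dialect).

A scenario file has four sections::

    name: study1_abbott_vac450
    device:
      mode: DDD
      lrl_ppm: 70
      mtr_ppm: 130
      sav_ms: 140
      pav_ms: 200
      pvarp_ms: 280
      vendor: abbott
      vendor_config:
        pmt_detection_rate_ppm: 95
    heart:
      vac_time_ms: 468
      retrograde_1to1: true
      atrial_myo_refractory_ms: 250
    duration_ms: 60000
    seed: 0          # reserved; the engine is deterministic and ignores it
    outputs:         # optional
      events_csv: events.csv
      ladder: ladder.txt

Unknown keys are rejected at every level, and every violated invariant is
reported (not just the first).  ``parse_config(serialize_config(cfg))``
round-trips exactly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from typing import Optional

import yaml

from .heart import HeartParams
from .timing import DeviceParams, Mode, TimingBase
from . import vendors as _vendors

__all__ = [
    "ScenarioConfig",
    "ScenarioConfigError",
    "parse_config",
    "load_config",
    "serialize_config",
]


class ScenarioConfigError(ValueError):
    """Raised with the full list of configuration problems."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("invalid scenario config:\n" + "\n".join(
            f"  - {p}" for p in self.problems
        ))


@dataclass(frozen=True)
class ScenarioConfig:
    name: str
    device: DeviceParams
    heart: HeartParams
    duration_ms: int = 60000
    seed: Optional[int] = None  # reserved for future noise models; unused
    outputs: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be > 0")


_TOP_KEYS = {"name", "device", "heart", "duration_ms", "seed", "outputs"}
_DEVICE_KEYS = {f.name for f in fields(DeviceParams)}
_HEART_KEYS = {f.name for f in fields(HeartParams)}
_OUTPUT_KEYS = {"events_csv", "ladder"}


def parse_config(text: str) -> ScenarioConfig:
    """Parse and validate a scenario config; collects every violation."""
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ScenarioConfigError([f"YAML syntax error: {exc}"]) from exc
    if not isinstance(raw, dict):
        raise ScenarioConfigError(["top level must be a mapping"])

    problems = []

    def check_keys(section: dict, allowed: set, label: str) -> None:
        unknown = set(section) - allowed
        for key in sorted(unknown):
            problems.append(f"unknown key {key!r} in {label}")

    check_keys(raw, _TOP_KEYS, "top level")
    name = raw.get("name")
    if not isinstance(name, str) or not name:
        problems.append("'name' must be a non-empty string")

    device_raw = raw.get("device")
    heart_raw = raw.get("heart", {})
    device = heart = None

    if not isinstance(device_raw, dict):
        problems.append("'device' section missing or not a mapping")
    else:
        check_keys(device_raw, _DEVICE_KEYS, "device")
        kwargs = {k: v for k, v in device_raw.items() if k in _DEVICE_KEYS}
        try:
            if "mode" in kwargs:
                kwargs["mode"] = Mode(kwargs["mode"])
            if kwargs.get("timing_base") is not None:
                kwargs["timing_base"] = TimingBase(kwargs["timing_base"])
            vendor = kwargs.get("vendor")
            if vendor is not None:
                vendor = str(vendor).lower()
                kwargs["vendor"] = vendor
                vc = kwargs.get("vendor_config") or {}
                if not isinstance(vc, dict):
                    raise ValueError("vendor_config must be a mapping")
                kwargs["vendor_config"] = _vendors.config_from_dict(vendor, vc)
            elif kwargs.get("vendor_config"):
                raise ValueError("vendor_config given without a vendor")
            device = DeviceParams(**kwargs)
            if device.vendor:
                # surface vendor-specific limits (e.g. PVARP maxima) early
                _vendors.create_model(device.vendor, device.vendor_config, device)
        except (ValueError, TypeError) as exc:
            problems.append(f"device: {exc}")

    if not isinstance(heart_raw, dict):
        problems.append("'heart' section must be a mapping")
    else:
        check_keys(heart_raw, _HEART_KEYS, "heart")
        try:
            heart = HeartParams(
                **{k: v for k, v in heart_raw.items() if k in _HEART_KEYS}
            )
        except (ValueError, TypeError) as exc:
            problems.append(f"heart: {exc}")

    duration = raw.get("duration_ms", 60000)
    if not isinstance(duration, int) or duration <= 0:
        problems.append("'duration_ms' must be a positive integer")

    outputs = raw.get("outputs")
    if outputs is not None:
        if not isinstance(outputs, dict):
            problems.append("'outputs' must be a mapping")
        else:
            check_keys(outputs, _OUTPUT_KEYS, "outputs")

    if problems:
        raise ScenarioConfigError(problems)
    return ScenarioConfig(
        name=name,
        device=device,
        heart=heart,
        duration_ms=duration,
        seed=raw.get("seed"),
        outputs=outputs,
    )


def load_config(path) -> ScenarioConfig:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_config(fh.read())


def serialize_config(cfg: ScenarioConfig) -> str:
    """Serialize a config back to YAML (stable key order)."""
    device = {
        k: (v.value if isinstance(v, (Mode, TimingBase)) else v)
        for k, v in asdict(cfg.device).items()
        if v is not None
    }
    if cfg.device.vendor_config is not None:
        device["vendor_config"] = asdict(cfg.device.vendor_config)
    doc = {
        "name": cfg.name,
        "device": device,
        "heart": asdict(cfg.heart),
        "duration_ms": cfg.duration_ms,
    }
    if cfg.seed is not None:
        doc["seed"] = cfg.seed
    if cfg.outputs is not None:
        doc["outputs"] = dict(cfg.outputs)
    return yaml.safe_dump(doc, sort_keys=False)
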