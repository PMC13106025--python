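"""Manufacturer-specific algorithm models layered on the timing engine.

Each vendor model is a small state machine that consumes timing-core events
through hooks and emits detection/termination/AP-delay actions:

* anti-PMT detection and termination in DDD (counting consecutive
  qualifying VP-AS cycles, an optional AV-delay-modulation verification
  beat, then a one-cycle refractory response or a re-timing atrial pace);
* post-refractory-sense (AR) atrial-pacing delay in DDI, protecting the
  refractory atrium from a competitive stimulus;
* the MicroPort DDI quirk where every atrial sense is marked AR yet acts
  as an ordinary inhibiting sense.

Stability tolerances and the handful of intervals the manufacturers do not
publish (verification AV-delay shortening, Abbott's termination AP
coupling, the protection-window widths) are configurable with documented
defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Optional, Tuple

from .timing import (
    DeviceParams,
    EventLog,
    Marker,
    Mode,
    TimingBase,
    ppm_to_interval_ms,
)

__all__ = [
    "TrackedSenseAction",
    "VendorModel",
    "AbbottConfig",
    "BiotronikConfig",
    "BostonConfig",
    "MedtronicConfig",
    "MicroPortConfig",
    "AbbottModel",
    "BiotronikModel",
    "BostonModel",
    "MedtronicModel",
    "MicroPortModel",
    "VENDORS",
    "VENDOR_NAMES",
    "create_model",
    "default_config",
    "max_pvarp_ms",
    "default_timing_base",
]


@dataclass(frozen=True)
class TrackedSenseAction:
    """Reaction of a vendor model to a tracked atrial sense."""

    sav_delta: int = 0
    suppress_vp: bool = False
    termination_ap_offset: int = 0
    annotation: str = ""


_NO_ACTION = TrackedSenseAction()


# ---------------------------------------------------------------------------
# Vendor configurations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AbbottConfig:
    pmt_detection_rate_ppm: int = 120  # programmable, min 90, 5-bpm grid
    detection_beats: int = 8
    vpas_stability_tol_ms: int = 16
    sav_modulation_delta_ms: int = -50
    termination_ap_delay_ms: int = 330  # AP after AS; guarantees atrial capture

    def __post_init__(self) -> None:
        if self.pmt_detection_rate_ppm < 90:
            raise ValueError("pmt_detection_rate_ppm must be >= 90 bpm")


@dataclass(frozen=True)
class BiotronikConfig:
    va_criterion_ms: int = 350  # detection threshold, max 500
    detection_beats: int = 8
    deviation_tol_ms: int = 16
    sav_modulation_delta_ms: int = -50
    termination_ext_margin_ms: int = 50  # PVARP extended to criterion + margin
    post_ar_ap_delay_ms: int = 350
    min_pav_ms: int = 75

    def __post_init__(self) -> None:
        if self.va_criterion_ms > 500:
            raise ValueError("va_criterion_ms must be <= 500 ms")


@dataclass(frozen=True)
class BostonConfig:
    detection_cycles: int = 16  # consecutive VP at the upper-rate bound after AS
    stability_window_ms: int = 32  # total width, anchored at cycle 2's VP-AS
    termination_pvarp_ext_ms: int = 500
    afr_rate_ppm: int = 170  # atrial-flutter-response window = 60000 / rate
    min_pav_ms: int = 30


@dataclass(frozen=True)
class MedtronicConfig:
    vac_detection_limit_ms: int = 400  # strict upper bound on observed VP-AS
    detection_beats: int = 8
    intervention_pvarp_ext_ms: int = 400
    ncap_window_ms: int = 300  # non-competitive atrial pacing window
    min_pav_ms: int = 30


@dataclass(frozen=True)
class MicroPortConfig:
    vac_detection_limit_ms: int = 470  # inclusive bound on observed VP-AS
    detection_beats: int = 8
    stability_tol_ms: int = 16
    sav_modulation_delta_ms: int = -50
    termination_arp_ms: int = 500  # atrial refractory period after the next VP


# ---------------------------------------------------------------------------
# Vendor state machines
# ---------------------------------------------------------------------------


class VendorModel:
    """Hook interface consumed by :class:`pacesim.timing.Simulator`."""

    name = "generic"
    timing_base = TimingBase.V_V
    max_pvarp_ms = 500
    ddi_functional_ar = False

    def __init__(self, config, device: Optional[DeviceParams] = None) -> None:
        self.config = config
        self.device = device
        self.reset()

    def reset(self) -> None:
        """Return the detector to its idle state."""

    # Detection hooks -------------------------------------------------

    def on_tracked_as(
        self, t: int, vp_as: Optional[int], aa: Optional[int], log: EventLog
    ) -> TrackedSenseAction:
        return _NO_ACTION

    def on_vp(self, t: int, tracked: bool, at_mtr: bool, log: EventLog) -> None:
        pass

    def on_ar(self, t: int, vp_as: Optional[int], log: EventLog) -> None:
        self.reset()

    def on_ap(self, t: int, log: EventLog) -> None:
        self.reset()

    def consume_pvarp_extension(self) -> Optional[int]:
        return None

    # Post-AR atrial-escape adjustment --------------------------------

    def adjust_atrial_escape(
        self, ar_t: int, scheduled_ap: int, vp_target: int
    ) -> Optional[Tuple[int, int]]:
        """Return ``(new_ap_time, pav_for_that_beat)`` or ``None`` (no change)."""
        return None


class _CountVerifyModel(VendorModel):
    """Shared machinery: count qualifying beats, verify with an AV-delay
    modulation beat, then arm a one-cycle refractory intervention."""

    verification = True

    def reset(self) -> None:
        self.count = 0
        self.ref_vp_as: Optional[int] = None
        self.phase = "count"  # count | modulate | verify | intervene
        self.pending_ext: Optional[int] = None

    # predicates supplied by subclasses
    def _qualifies(self, vp_as: int, aa: Optional[int]) -> bool:
        raise NotImplementedError

    def _stability_tol(self) -> int:
        raise NotImplementedError

    def _intervention_ext(self) -> int:
        raise NotImplementedError

    def _sav_delta(self) -> int:
        return getattr(self.config, "sav_modulation_delta_ms", -50)

    def _detection_beats(self) -> int:
        return self.config.detection_beats

    def on_tracked_as(self, t, vp_as, aa, log) -> TrackedSenseAction:
        if vp_as is None:
            self.reset()
            return _NO_ACTION
        if self.phase == "intervene":
            # Refractory response was applied but the retrograde sense was
            # still tracked: the loop escaped the intervention window.
            self.reset()
        if self.phase == "verify":
            stable = abs(vp_as - self.ref_vp_as) <= self._stability_tol()
            if stable:
                log.append(
                    t,
                    Marker.PMT_DETECT,
                    f"VP-AS {vp_as} ms unchanged under AV-delay modulation",
                )
                self._on_detect(t, log)
            else:
                self.reset()
            return _NO_ACTION
        if self.phase == "modulate":
            self.phase = "verify"
            return TrackedSenseAction(
                sav_delta=self._sav_delta(),
                annotation="AV-delay modulation (verification beat)",
            )
        # counting
        qualifying = self._qualifies(vp_as, aa) and (
            self.count == 0 or abs(vp_as - self.ref_vp_as) <= self._stability_tol()
        )
        if qualifying:
            if self.count == 0:
                self.ref_vp_as = vp_as
            self.count += 1
            if self.count >= self._detection_beats():
                log.append(
                    t,
                    Marker.PMT_SUSPECT,
                    f"{self.count} consecutive qualifying VP-AS cycles",
                )
                if self.verification:
                    self.phase = "modulate"
                else:
                    log.append(
                        t, Marker.PMT_DETECT, f"VP-AS {vp_as} ms within detection limit"
                    )
                    self._on_detect(t, log)
        else:
            if self._qualifies(vp_as, aa):
                self.count = 1
                self.ref_vp_as = vp_as
            else:
                self.count = 0
                self.ref_vp_as = None
        return _NO_ACTION

    def _on_detect(self, t: int, log: EventLog) -> None:
        self.pending_ext = self._intervention_ext()
        self.phase = "intervene"
        self.count = 0

    def on_ar(self, t, vp_as, log) -> None:
        if self.phase == "intervene":
            log.append(
                t,
                Marker.PMT_TERMINATE,
                f"retrograde sense refractory (VP-AS {vp_as} ms); loop broken",
            )
        self.reset()

    def on_ap(self, t, log) -> None:
        # An atrial pace interrupts any VP-AS counting, but a pending
        # one-cycle refractory response survives until the next VP.
        pending = self.pending_ext
        phase = self.phase
        self.reset()
        if phase == "intervene":
            self.pending_ext = pending
            self.phase = "intervene"

    def consume_pvarp_extension(self) -> Optional[int]:
        ext, self.pending_ext = self.pending_ext, None
        return ext


class AbbottModel(_CountVerifyModel):
    """Detection by A-A rate + stable VP-AS; termination by a re-timing AP."""

    name = "abbott"
    timing_base = TimingBase.V_V
    max_pvarp_ms = 500

    def reset(self) -> None:
        super().reset()
        self.detection_interval_ms = ppm_to_interval_ms(
            self.config.pmt_detection_rate_ppm
        )

    def _qualifies(self, vp_as, aa) -> bool:
        return aa is not None and aa < self.detection_interval_ms

    def _stability_tol(self) -> int:
        return self.config.vpas_stability_tol_ms

    def _on_detect(self, t, log) -> None:
        # No refractory response: the next AS suppresses VP and triggers AP.
        self.phase = "terminate"
        self.count = 0

    def on_tracked_as(self, t, vp_as, aa, log) -> TrackedSenseAction:
        if self.phase == "terminate":
            self.reset()
            return TrackedSenseAction(
                suppress_vp=True,
                termination_ap_offset=self.config.termination_ap_delay_ms,
                annotation=(
                    f"VP suppressed; AP at AS + {self.config.termination_ap_delay_ms} ms"
                ),
            )
        return super().on_tracked_as(t, vp_as, aa, log)

    def on_ar(self, t, vp_as, log) -> None:
        self.reset()


class BiotronikModel(_CountVerifyModel):
    """Detection when VP-AS < VA criterion; termination by a one-cycle
    PVARP extension 50 ms beyond the criterion."""

    name = "biotronik"
    timing_base = TimingBase.V_V
    max_pvarp_ms = 600

    def _qualifies(self, vp_as, aa) -> bool:
        return vp_as < self.config.va_criterion_ms

    def _stability_tol(self) -> int:
        return self.config.deviation_tol_ms

    def _intervention_ext(self) -> int:
        return self.config.va_criterion_ms + self.config.termination_ext_margin_ms

    def adjust_atrial_escape(self, ar_t, scheduled_ap, vp_target):
        delayed = ar_t + self.config.post_ar_ap_delay_ms
        if delayed <= scheduled_ap:
            return None
        pav = max(self.config.min_pav_ms, vp_target - delayed)
        return delayed, pav


class BostonModel(VendorModel):
    """Detection by consecutive upper-rate VP cycles after AS (no
    verification phase); termination by a one-cycle PVARP extension."""

    name = "boston"
    timing_base = TimingBase.V_V
    max_pvarp_ms = 500

    def reset(self) -> None:
        self.vp_mt_vacs: list = []
        self.last_vp_as: Optional[int] = None
        self.phase = "count"
        self.pending_ext: Optional[int] = None

    def on_tracked_as(self, t, vp_as, aa, log) -> TrackedSenseAction:
        if self.phase == "intervene":
            self.phase = "count"
            self.vp_mt_vacs = []
        self.last_vp_as = vp_as
        return _NO_ACTION

    def on_vp(self, t, tracked, at_mtr, log) -> None:
        if not (tracked and at_mtr and self.last_vp_as is not None):
            self.vp_mt_vacs = []
            return
        self.vp_mt_vacs.append(self.last_vp_as)
        if len(self.vp_mt_vacs) >= 2:
            # Stability window anchored at the second upper-rate cycle's VP-AS;
            # the first flagged cycle is excluded from the comparison.
            ref = self.vp_mt_vacs[1]
            half = self.config.stability_window_ms // 2
            if abs(self.vp_mt_vacs[-1] - ref) > half:
                self.vp_mt_vacs = [self.vp_mt_vacs[-1]]
                return
        if len(self.vp_mt_vacs) >= self.config.detection_cycles:
            log.append(
                t,
                Marker.PMT_SUSPECT,
                f"{len(self.vp_mt_vacs)} consecutive VP cycles at the upper rate",
            )
            log.append(
                t,
                Marker.PMT_DETECT,
                "upper-rate persistence with stable VP-AS",
            )
            self.pending_ext = self.config.termination_pvarp_ext_ms
            self.phase = "intervene"
            self.vp_mt_vacs = []

    def on_ar(self, t, vp_as, log) -> None:
        if self.phase == "intervene":
            log.append(
                t,
                Marker.PMT_TERMINATE,
                f"retrograde sense refractory (VP-AS {vp_as} ms); loop broken",
            )
        self.reset()

    def on_ap(self, t, log) -> None:
        pending, phase = self.pending_ext, self.phase
        self.reset()
        if phase == "intervene":
            self.pending_ext = pending
            self.phase = "intervene"

    def consume_pvarp_extension(self) -> Optional[int]:
        ext, self.pending_ext = self.pending_ext, None
        return ext

    def adjust_atrial_escape(self, ar_t, scheduled_ap, vp_target):
        window = ppm_to_interval_ms(self.config.afr_rate_ppm)
        delayed = ar_t + window
        if delayed <= scheduled_ap:
            return None
        pav = max(self.config.min_pav_ms, vp_target - delayed)
        return delayed, pav


class MedtronicModel(_CountVerifyModel):
    """Detection limited to observed VP-AS strictly below 400 ms; A-A
    timing base; non-competitive atrial pacing after refractory senses.

    The bench protocols never reach the intervention (observed VP-AS is
    always above the limit); the one-cycle PVARP extension on detection is
    kept so the detector's action is testable below the limit.
    """

    name = "medtronic"
    timing_base = TimingBase.A_A
    max_pvarp_ms = 500
    verification = False

    def _qualifies(self, vp_as, aa) -> bool:
        return vp_as < self.config.vac_detection_limit_ms

    def _stability_tol(self) -> int:
        return 16

    def _intervention_ext(self) -> int:
        return self.config.intervention_pvarp_ext_ms

    def adjust_atrial_escape(self, ar_t, scheduled_ap, vp_target):
        if scheduled_ap - ar_t >= self.config.ncap_window_ms:
            return None
        delayed = ar_t + self.config.ncap_window_ms
        pav = max(self.config.min_pav_ms, vp_target - delayed)
        return delayed, pav


class MicroPortModel(_CountVerifyModel):
    """Detection when observed VP-AS <= 470 ms (inclusive); termination by
    a 500-ms atrial refractory period after the next VP.  In DDI every
    atrial sense is marked AR but acts as an inhibiting, non-tracked
    sense (the acceleration-detection window is inactive)."""

    name = "microport"
    timing_base = TimingBase.V_V
    max_pvarp_ms = 500  # PVARP not extendable in the DDI protocol
    ddi_functional_ar = True

    def _qualifies(self, vp_as, aa) -> bool:
        return vp_as <= self.config.vac_detection_limit_ms

    def _stability_tol(self) -> int:
        return self.config.stability_tol_ms

    def _intervention_ext(self) -> int:
        return self.config.termination_arp_ms


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

VENDORS = {
    "abbott": (AbbottConfig, AbbottModel),
    "biotronik": (BiotronikConfig, BiotronikModel),
    "boston": (BostonConfig, BostonModel),
    "medtronic": (MedtronicConfig, MedtronicModel),
    "microport": (MicroPortConfig, MicroPortModel),
}

VENDOR_NAMES = tuple(VENDORS)


def default_config(name: str):
    """Fresh configuration with shipped defaults for ``name``."""
    cfg_cls, _ = _lookup(name)
    return cfg_cls()


def max_pvarp_ms(name: str) -> int:
    _, model_cls = _lookup(name)
    return model_cls.max_pvarp_ms


def default_timing_base(name: str) -> TimingBase:
    _, model_cls = _lookup(name)
    return model_cls.timing_base


def _lookup(name: str):
    try:
        return VENDORS[name.lower()]
    except KeyError:
        raise ValueError(
            f"unknown vendor {name!r}; expected one of {sorted(VENDORS)}"
        ) from None


def config_from_dict(name: str, values: dict):
    """Build a vendor config from a mapping, rejecting unknown keys."""
    cfg_cls, _ = _lookup(name)
    allowed = {f.name for f in fields(cfg_cls)}
    unknown = set(values) - allowed
    if unknown:
        raise ValueError(
            f"unknown {cfg_cls.__name__} keys: {sorted(unknown)}"
        )
    return cfg_cls(**values)


def create_model(
    name: str, config=None, device: Optional[DeviceParams] = None
) -> VendorModel:
    """Instantiate the vendor state machine, validating the configuration."""
    cfg_cls, model_cls = _lookup(name)
    if config is None:
        config = cfg_cls()
    elif isinstance(config, dict):
        config = config_from_dict(name, config)
    elif not isinstance(config, cfg_cls):
        raise TypeError(
            f"vendor {name!r} expects {cfg_cls.__name__}, got {type(config).__name__}"
        )
    if device is not None and device.pvarp_ms > model_cls.max_pvarp_ms:
        raise ValueError(
            f"PVARP {device.pvarp_ms} ms exceeds {name} maximum "
            f"{model_cls.max_pvarp_ms} ms"
        )
    return model_cls(config, device)
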