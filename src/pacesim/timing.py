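"""Vendor-neutral dual-chamber pacemaker timing engine.

Implements DDD and DDI timing cycles on an integer-millisecond clock:
lower-rate and AV-interval scheduling, PVARP/PVAB classification of atrial
senses, upper-rate (MTR) limitation with Wenckebach delay of tracked
ventricular paces, and A-A versus V-V atrial-escape timing bases.  The
engine couples to the heart substrate in :mod:`pacesim.heart` and produces
a marker-channel :class:`EventLog`.

Vendor-specific behaviour (anti-PMT detection, PVARP extension, post-AR
atrial-pace delay) is injected through the hook interface defined in
:mod:`pacesim.vendors`; with ``vendor=None`` the engine is a plain
dual-chamber device.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import TYPE_CHECKING, Iterator, List, Optional

from .heart import (
    CaptureResult,
    HeartParams,
    HeartState,
    on_atrial_pace,
    on_retrograde_arrival,
    on_ventricular_activation,
)

if TYPE_CHECKING:  # pragma: no cover
    from .vendors import VendorModel

MS_PER_MIN = 60000

__all__ = [
    "MS_PER_MIN",
    "ppm_to_interval_ms",
    "pmt_cycle_closed_form",
    "Mode",
    "TimingBase",
    "Channel",
    "Marker",
    "SenseClass",
    "DeviceParams",
    "MarkerEvent",
    "EventLog",
    "classify_atrial_sense",
    "Simulator",
    "run_simulation",
]


def ppm_to_interval_ms(ppm: int) -> int:
    """Convert a rate in pulses/min to an interval in ms (round half up)."""
    if ppm <= 0:
        raise ValueError("rate must be > 0 ppm")
    return int(MS_PER_MIN / ppm + 0.5)


def pmt_cycle_closed_form(vac_ms: int, sav_ms: int, mtr_ppm: int) -> int:
    """Closed-form steady cycle length of a sustained tracking loop.

    The loop runs at the upper-rate interval when VAC + SAV is shorter
    than it, and at VAC + SAV otherwise.
    """
    return max(vac_ms + sav_ms, ppm_to_interval_ms(mtr_ppm))


class Mode(str, Enum):
    DDD = "DDD"
    DDI = "DDI"


class TimingBase(str, Enum):
    A_A = "A_A"
    V_V = "V_V"


class Channel(str, Enum):
    A = "A"
    V = "V"
    DEVICE = "DEVICE"


class Marker(str, Enum):
    AP = "AP"
    AP_NONCAPTURE = "AP_NONCAPTURE"
    AS = "AS"
    AR = "AR"
    AS_BLANKED = "AS_BLANKED"
    VP = "VP"
    PVARP_EXT = "PVARP_EXT"
    PMT_SUSPECT = "PMT_SUSPECT"
    PMT_DETECT = "PMT_DETECT"
    PMT_TERMINATE = "PMT_TERMINATE"
    AP_DELAYED = "AP_DELAYED"


_CHANNEL_OF_MARKER = {
    Marker.AP: Channel.A,
    Marker.AP_NONCAPTURE: Channel.A,
    Marker.AS: Channel.A,
    Marker.AR: Channel.A,
    Marker.AS_BLANKED: Channel.A,
    Marker.VP: Channel.V,
    Marker.PVARP_EXT: Channel.DEVICE,
    Marker.PMT_SUSPECT: Channel.DEVICE,
    Marker.PMT_DETECT: Channel.DEVICE,
    Marker.PMT_TERMINATE: Channel.DEVICE,
    Marker.AP_DELAYED: Channel.DEVICE,
}

_CHANNEL_ORDER = {Channel.A: 0, Channel.V: 1, Channel.DEVICE: 2}


class SenseClass(str, Enum):
    BLANKED = "blanked"
    REFRACTORY_SENSE = "refractory_sense"
    TRACKED_SENSE = "tracked_sense"
    NONREFRACTORY_SENSE = "nonrefractory_sense"


@dataclass(frozen=True)
class MarkerEvent:
    """One annotated marker-channel event."""

    time_ms: int
    channel: Channel
    marker: Marker
    annotation: str = ""

    def __post_init__(self) -> None:
        if self.time_ms < 0:
            raise ValueError("time_ms must be >= 0")


class EventLog:
    """Time-ordered sequence of marker events plus scenario metadata.

    Ordering is strictly non-decreasing in time; within one timestamp ties
    follow the fixed channel order A < V < DEVICE.
    """

    CSV_HEADER = ("time_ms", "channel", "marker", "annotation")

    def __init__(self, metadata: Optional[dict] = None) -> None:
        self.events: List[MarkerEvent] = []
        self.metadata: dict = dict(metadata or {})

    def append(
        self, time_ms: int, marker: Marker, annotation: str = ""
    ) -> MarkerEvent:
        ev = MarkerEvent(time_ms, _CHANNEL_OF_MARKER[marker], marker, annotation)
        if self.events:
            last = self.events[-1]
            key_last = (last.time_ms, _CHANNEL_ORDER[last.channel])
            key_new = (ev.time_ms, _CHANNEL_ORDER[ev.channel])
            if key_new < key_last:
                raise ValueError(
                    f"event log ordering violated: {ev} after {last}"
                )
        self.events.append(ev)
        return ev

    def __iter__(self) -> Iterator[MarkerEvent]:
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)

    def times(self, marker: Marker) -> List[int]:
        return [e.time_ms for e in self.events if e.marker is marker]

    def has(self, marker: Marker) -> bool:
        return any(e.marker is marker for e in self.events)

    def to_csv(self) -> str:
        buf = io.StringIO(newline="")
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(self.CSV_HEADER)
        for e in self.events:
            writer.writerow([e.time_ms, e.channel.value, e.marker.value, e.annotation])
        return buf.getvalue()

    def write_csv(self, path: str) -> None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write(self.to_csv())

    @classmethod
    def from_csv(cls, text: str) -> "EventLog":
        log = cls()
        reader = csv.reader(io.StringIO(text))
        header = next(reader)
        if tuple(header) != cls.CSV_HEADER:
            raise ValueError(f"unexpected event CSV header: {header!r}")
        for row in reader:
            if not row:
                continue
            t, channel, marker, annotation = row
            log.append(int(t), Marker(marker), annotation)
        return log


@dataclass(frozen=True)
class DeviceParams:
    """Programmed bradycardia settings plus vendor algorithm selection.

    ``timing_base=None`` defers to the vendor's default architecture
    (V-V for all shipped vendors except Medtronic's A-A).
    """

    mode: Mode = Mode.DDD
    lrl_ppm: int = 70
    mtr_ppm: int = 130
    sav_ms: int = 140
    pav_ms: int = 200
    pvarp_ms: int = 280
    pvab_ms: int = 150
    timing_base: Optional[TimingBase] = None
    vendor: Optional[str] = None
    vendor_config: Optional[object] = None

    def __post_init__(self) -> None:
        problems = []
        if self.lrl_ppm <= 0 or self.mtr_ppm <= 0:
            problems.append("rates must be > 0 ppm")
        elif self.lrl_ppm > self.mtr_ppm:
            problems.append(
                f"lrl_ppm ({self.lrl_ppm}) must not exceed mtr_ppm ({self.mtr_ppm})"
            )
        if self.sav_ms <= 0 or self.pav_ms <= 0:
            problems.append("AV delays must be > 0 ms")
        elif self.sav_ms > self.pav_ms:
            problems.append(
                f"sav_ms ({self.sav_ms}) must not exceed pav_ms ({self.pav_ms})"
            )
        if self.pvarp_ms <= 0 or self.pvab_ms <= 0:
            problems.append("refractory/blanking intervals must be > 0 ms")
        elif self.pvab_ms > self.pvarp_ms:
            problems.append(
                f"pvab_ms ({self.pvab_ms}) must not exceed pvarp_ms ({self.pvarp_ms})"
            )
        if self.lrl_ppm > 0 and self.pav_ms >= ppm_to_interval_ms(self.lrl_ppm):
            problems.append("pav_ms must be shorter than the lower-rate interval")
        if problems:
            raise ValueError("; ".join(problems))

    @property
    def lri_ms(self) -> int:
        """Lower-rate interval."""
        return ppm_to_interval_ms(self.lrl_ppm)

    @property
    def mtri_ms(self) -> int:
        """Maximum-tracking-rate (upper-rate) interval."""
        return ppm_to_interval_ms(self.mtr_ppm)

    def with_overrides(self, **kwargs) -> "DeviceParams":
        return replace(self, **kwargs)


def classify_atrial_sense(
    t: int,
    last_vp: Optional[int],
    device: DeviceParams,
    effective_pvarp_ms: Optional[int] = None,
) -> SenseClass:
    """Classify an atrial activation visible to the device at ``t``.

    ``effective_pvarp_ms`` overrides the programmed PVARP for the current
    post-ventricular window (one-shot vendor extensions).
    """
    if last_vp is not None:
        dt = t - last_vp
        if dt < device.pvab_ms:
            return SenseClass.BLANKED
        pvarp = device.pvarp_ms if effective_pvarp_ms is None else effective_pvarp_ms
        if dt < pvarp:
            return SenseClass.REFRACTORY_SENSE
    if device.mode is Mode.DDD:
        return SenseClass.TRACKED_SENSE
    return SenseClass.NONREFRACTORY_SENSE


# Event-queue priorities within one timestamp: heart activation is
# processed before device pacing; A-channel pacing before V-channel.
_PRIO_RETRO, _PRIO_AP, _PRIO_VP = 0, 1, 2


class Simulator:
    """Coupled device-heart discrete-event loop.

    The loop is fully deterministic: identical parameters give bit-for-bit
    identical event logs.
    """

    def __init__(
        self,
        device: DeviceParams,
        heart: HeartParams,
        vendor_model: "Optional[VendorModel]" = None,
    ) -> None:
        self.device = device
        self.heart = heart
        self.vendor = vendor_model
        if device.timing_base is not None:
            self.timing_base = device.timing_base
        elif vendor_model is not None:
            self.timing_base = vendor_model.timing_base
        else:
            self.timing_base = TimingBase.V_V
        self.lri = device.lri_ms
        self.mtri = device.mtri_ms

    # -- public API ---------------------------------------------------

    def run(self, duration_ms: int, induction: str = "auto") -> EventLog:
        if duration_ms < 10 * self.lri:
            raise ValueError("duration must cover at least 10 lower-rate cycles")
        if induction not in ("auto", "none"):
            raise ValueError(f"unknown induction mode: {induction!r}")

        dev = self.device
        self.log = EventLog(
            metadata={
                "mode": dev.mode.value,
                "lrl_ppm": dev.lrl_ppm,
                "mtr_ppm": dev.mtr_ppm,
                "sav_ms": dev.sav_ms,
                "pav_ms": dev.pav_ms,
                "pvarp_ms": dev.pvarp_ms,
                "pvab_ms": dev.pvab_ms,
                "timing_base": self.timing_base.value,
                "vendor": dev.vendor or "none",
                "vac_time_ms": self.heart.vac_time_ms,
                "retrograde_1to1": self.heart.retrograde_1to1,
                "atrial_myo_refractory_ms": self.heart.atrial_myo_refractory_ms,
                "duration_ms": duration_ms,
                "induction": induction,
            }
        )
        self.hs = HeartState()
        self.last_vp: Optional[int] = None
        self.last_atrial_dev: Optional[int] = None  # last device A timing event
        self.pvarp_eff = dev.pvarp_ms
        self.next_ap: Optional[int] = 0  # device wakes pacing the atrium
        self.next_ap_pav: Optional[int] = None
        self.pending_vp: Optional[int] = None
        self.vp_tracked = False
        self.vp_at_mtr = False
        self.pending_retro: Optional[int] = None
        if self.vendor is not None:
            self.vendor.reset()

        while True:
            candidates = []
            if self.pending_retro is not None:
                candidates.append((self.pending_retro, _PRIO_RETRO))
            if self.next_ap is not None:
                candidates.append((self.next_ap, _PRIO_AP))
            if self.pending_vp is not None:
                candidates.append((self.pending_vp, _PRIO_VP))
            if not candidates:  # pragma: no cover - engine always reschedules
                break
            t, prio = min(candidates)
            if t > duration_ms:
                break
            if prio == _PRIO_RETRO:
                self._handle_retro(t)
            elif prio == _PRIO_AP:
                self._handle_ap(t)
            else:
                self._handle_vp(t)

        self.log.metadata["converged"] = self._steady_state_reached()
        return self.log

    # -- event handlers -----------------------------------------------

    def _handle_retro(self, t: int) -> None:
        """Retrograde atrial activation arrives at the atrium (and device)."""
        on_retrograde_arrival(t, self.hs)
        self.pending_retro = None
        dev = self.device
        cls = classify_atrial_sense(t, self.last_vp, dev, self.pvarp_eff)
        if cls is SenseClass.BLANKED:
            self.log.append(t, Marker.AS_BLANKED, "within PVAB; invisible to timing")
            return

        vp_as = t - self.last_vp if self.last_vp is not None else None
        if (
            dev.mode is Mode.DDI
            and self.vendor is not None
            and self.vendor.ddi_functional_ar
        ):
            # MicroPort quirk: every DDI sense is marked AR but inhibits AP.
            self.log.append(
                t,
                Marker.AR,
                "functional sense (WARAD inactive in DDI); AP inhibited",
            )
            self._ddi_inhibit(t)
            return

        if cls is SenseClass.REFRACTORY_SENSE:
            self.log.append(
                t,
                Marker.AR,
                f"refractory; VP-AS {vp_as} ms < PVARP {self.pvarp_eff} ms",
            )
            if self.vendor is not None:
                self.vendor.on_ar(t, vp_as, self.log)
                self._apply_post_ar_adjust(t)
            return

        if cls is SenseClass.TRACKED_SENSE:
            self.log.append(t, Marker.AS, f"tracked; VP-AS {vp_as} ms")
            action = None
            if self.vendor is not None:
                aa = (
                    t - self.last_atrial_dev
                    if self.last_atrial_dev is not None
                    else None
                )
                action = self.vendor.on_tracked_as(t, vp_as, aa, self.log)
            self.last_atrial_dev = t
            if action is not None and action.suppress_vp:
                # Anti-PMT termination: VP suppressed, AP re-times the atrium.
                self.log.append(
                    t,
                    Marker.PMT_TERMINATE,
                    action.annotation or "VP suppressed; AP scheduled after AS",
                )
                self.next_ap = t + action.termination_ap_offset
                self.next_ap_pav = None
                self.pending_vp = None
                return
            sav = self.device.sav_ms
            if action is not None and action.sav_delta:
                sav = max(30, sav + action.sav_delta)
            due = t + sav
            bound = self.last_vp + self.mtri if self.last_vp is not None else due
            vp_t = max(due, bound)
            self.pending_vp = vp_t
            self.vp_tracked = True
            self.vp_at_mtr = vp_t == bound
            self.next_ap = None
            self.next_ap_pav = None
            return

        # Non-refractory sense in DDI: inhibits AP, never starts SAV.
        self.log.append(t, Marker.AS, "non-refractory; AP inhibited")
        self._ddi_inhibit(t)

    def _ddi_inhibit(self, t: int) -> None:
        self.last_atrial_dev = t
        self.next_ap = None
        self.next_ap_pav = None
        # VVI-like fallback: ventricular escape at the lower-rate interval.
        self.pending_vp = self.last_vp + self.lri
        self.vp_tracked = False
        self.vp_at_mtr = False

    def _apply_post_ar_adjust(self, ar_t: int) -> None:
        """Let the vendor delay a scheduled AP away from the refractory atrium."""
        if self.next_ap is None or self.vendor is None:
            return
        if self.device.mode is Mode.DDI and self.pending_vp is not None:
            vp_target = self.pending_vp
        else:
            vp_target = self.next_ap + self.device.pav_ms
        adj = self.vendor.adjust_atrial_escape(ar_t, self.next_ap, vp_target)
        if adj is None:
            return
        new_ap, new_pav = adj
        if new_ap > self.next_ap:
            self.log.append(
                ar_t,
                Marker.AP_DELAYED,
                f"AP {self.next_ap}->{new_ap} ms after AR; PAV {new_pav} ms",
            )
        self.next_ap = new_ap
        self.next_ap_pav = new_pav
        if self.pending_vp is not None and new_ap + new_pav > self.pending_vp:
            # The delayed AP pushes the ventricular escape beyond the
            # lower-rate interval (below-LRL prolongation).
            self.pending_vp = new_ap + new_pav

    def _handle_ap(self, t: int) -> None:
        result = on_atrial_pace(t, self.hs, self.heart)
        if result is CaptureResult.CAPTURED:
            self.log.append(t, Marker.AP)
        else:
            self.log.append(
                t, Marker.AP_NONCAPTURE, "stimulus in atrial refractory period"
            )
        self.last_atrial_dev = t
        if self.vendor is not None:
            self.vendor.on_ap(t, self.log)
        pav = self.next_ap_pav if self.next_ap_pav is not None else self.device.pav_ms
        self.pending_vp = t + pav
        self.vp_tracked = False
        self.vp_at_mtr = False
        self.next_ap = None
        self.next_ap_pav = None

    def _handle_vp(self, t: int) -> None:
        self.log.append(t, Marker.VP, "VP-MT (upper-rate bound)" if self.vp_at_mtr else "")
        if self.vendor is not None:
            self.vendor.on_vp(t, self.vp_tracked, self.vp_at_mtr, self.log)
        self.last_vp = t

        ext = self.vendor.consume_pvarp_extension() if self.vendor is not None else None
        if ext is not None:
            self.pvarp_eff = ext
            self.log.append(t, Marker.PVARP_EXT, f"PVARP {ext} ms this cycle")
        else:
            self.pvarp_eff = self.device.pvarp_ms

        self.pending_retro = on_ventricular_activation(t, self.hs, self.heart)

        dev = self.device
        if self.timing_base is TimingBase.A_A and self.last_atrial_dev is not None:
            ae = self.last_atrial_dev + self.lri
        else:
            ae = t + self.lri - dev.pav_ms
        ae = max(ae, t + 1)
        self.next_ap = ae
        self.next_ap_pav = None
        if dev.mode is Mode.DDD:
            self.pending_vp = None
        else:
            # DDI ventricular escape; re-timed by the AP when it is delivered.
            if self.timing_base is TimingBase.A_A:
                ve = ae + dev.pav_ms
            else:
                ve = t + self.lri
            self.pending_vp = max(ve, ae + 1)
        self.vp_tracked = False
        self.vp_at_mtr = False

    # -- diagnostics ---------------------------------------------------

    def _steady_state_reached(self) -> bool:
        """Heuristic convergence check: the tail of the V-V sequence is
        periodic with some period up to 16 beats (covers steady pacing,
        alternating AV delays, and repeated detect/terminate limit cycles)."""
        vps = self.log.times(Marker.VP)
        if len(vps) < 8:
            return False
        vv = [b - a for a, b in zip(vps, vps[1:])]
        tail = vv[-32:]
        for period in range(1, min(16, len(tail) // 2) + 1):
            if all(
                abs(tail[i] - tail[i - period]) <= 2
                for i in range(period, len(tail))
            ):
                return True
        return False


def run_simulation(
    device: DeviceParams,
    heart: HeartParams,
    duration_ms: int = 60000,
    induction: str = "auto",
) -> EventLog:
    """Simulate the coupled device-heart loop and return the event log.

    With a heart in sinus arrest the device opens with its own AP -> PAV ->
    VP sequence; when retrograde conduction is present and escapes PVARP in
    DDD the tracking loop self-initiates, so no explicit induction beat is
    injected (``induction`` is accepted for API stability).
    """
    vendor_model = None
    if device.vendor not in (None, "", "none"):
        from .vendors import create_model

        vendor_model = create_model(device.vendor, device.vendor_config, device)
    sim = Simulator(device, heart, vendor_model)
    log = sim.run(duration_ms, induction=induction)
    return log
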