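"""Patient substrate: sinus arrest, complete AV block, fixed retrograde VA conduction.

The simulated heart never generates spontaneous activity.  Every atrial
activation is the consequence of a captured atrial pacing stimulus or of
1:1 retrograde conduction from a ventricular paced beat; every ventricular
activation is paced.  Atrial myocardial refractoriness governs both capture
of atrial stimuli and retrograde block.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

__all__ = [
    "HeartParams",
    "HeartState",
    "CaptureResult",
    "on_ventricular_activation",
    "on_atrial_pace",
    "on_retrograde_arrival",
]


class CaptureResult(str, Enum):
    """Outcome of an atrial pacing stimulus."""

    CAPTURED = "captured"
    NON_CAPTURED = "non_captured"


@dataclass(frozen=True)
class HeartParams:
    """Electrophysiological parameters of the simulated patient.

    Parameters
    ----------
    vac_time_ms
        Retrograde conduction interval from ventricular activation to
        atrial activation.  Reproduction scenarios set this directly to the
        device-measured value (e.g. 468 or 570 ms).
    retrograde_1to1
        Whether retrograde VA conduction is present (constant 1:1, no
        decremental behaviour).
    atrial_myo_refractory_ms
        Tissue refractory period after any atrial activation.  Pacing into
        this window does not capture; retrograde impulses arriving inside
        it are blocked.
    sense_offset_ms
        Difference between tissue conduction time and device-measured
        conduction time.  Reserved knob for sensing-filter effects; 0 in
        all shipped scenarios.
    """

    vac_time_ms: int = 468
    retrograde_1to1: bool = True
    atrial_myo_refractory_ms: int = 250
    sense_offset_ms: int = 0

    def __post_init__(self) -> None:
        if self.vac_time_ms <= 0:
            raise ValueError("vac_time_ms must be > 0")
        if self.atrial_myo_refractory_ms < 0:
            raise ValueError("atrial_myo_refractory_ms must be >= 0")
        if self.sense_offset_ms < 0:
            raise ValueError("sense_offset_ms must be >= 0")


@dataclass
class HeartState:
    """Mutable tissue state carried across the simulation."""

    last_atrial_activation_ms: Optional[int] = None
    last_ventricular_activation_ms: Optional[int] = None
    pending_retrograde_ms: Optional[int] = None


def on_ventricular_activation(
    t: int, state: HeartState, params: HeartParams
) -> Optional[int]:
    """Register a ventricular (paced) activation at ``t``.

    Returns the time of the resulting retrograde atrial activation, or
    ``None`` if retrograde conduction is absent or blocked by atrial
    refractoriness.
    """
    state.last_ventricular_activation_ms = t
    if not params.retrograde_1to1:
        return None
    arrival = t + params.vac_time_ms
    last_a = state.last_atrial_activation_ms
    if last_a is not None and arrival - last_a < params.atrial_myo_refractory_ms:
        return None  # retrograde block: atrium still refractory on arrival
    state.pending_retrograde_ms = arrival
    return arrival


def on_atrial_pace(t: int, state: HeartState, params: HeartParams) -> CaptureResult:
    """Deliver an atrial pacing stimulus at ``t`` and report capture.

    A stimulus falling within ``atrial_myo_refractory_ms`` of the last
    atrial activation is ineffective and leaves tissue state unchanged.
    """
    last_a = state.last_atrial_activation_ms
    if last_a is not None and t - last_a < params.atrial_myo_refractory_ms:
        return CaptureResult.NON_CAPTURED
    state.last_atrial_activation_ms = t
    return CaptureResult.CAPTURED


def on_retrograde_arrival(t: int, state: HeartState) -> None:
    """Commit a previously scheduled retrograde atrial activation."""
    state.last_atrial_activation_ms = t
    state.pending_retrograde_ms = None
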