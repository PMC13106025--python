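import pytest

from pacesim import DeviceParams, HeartParams, Mode


def closed_form_cycle(vac_ms: int, sav_ms: int, mtr_ppm: int) -> int:
    """Independent interval-arithmetic oracle for the steady cycle length
    of a sustained tracking loop (kept local to the tests on purpose)."""
    upper_rate_interval = int(60000 / mtr_ppm + 0.5)
    return max(vac_ms + sav_ms, upper_rate_interval)


@pytest.fixture
def protocol_device():
    """Study-1 bradycardia settings with no vendor algorithm."""

    def _make(**overrides) -> DeviceParams:
        base = dict(
            mode=Mode.DDD,
            lrl_ppm=70,
            mtr_ppm=130,
            sav_ms=140,
            pav_ms=200,
            pvarp_ms=280,
        )
        base.update(overrides)
        return DeviceParams(**base)

    return _make


@pytest.fixture
def heart():
    def _make(vac_ms: int = 468, **overrides) -> HeartParams:
        return HeartParams(vac_time_ms=vac_ms, **overrides)

    return _make
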