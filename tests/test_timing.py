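"""Timing-core tests: rate conversion, sense classification, cycle
scheduling, the coupled simulation loop, and the event log."""

import pytest

from pacesim import (
    DeviceParams,
    EventLog,
    HeartParams,
    Marker,
    Mode,
    TimingBase,
    classify_atrial_sense,
    ppm_to_interval_ms,
    run_simulation,
)
from pacesim.timing import Channel, SenseClass

from conftest import closed_form_cycle


class TestIntervals:
    @pytest.mark.parametrize(
        "ppm,interval",
        [(70, 857), (80, 750), (90, 667), (95, 632), (130, 462), (170, 353)],
    )
    def test_rate_to_interval(self, ppm, interval):
        assert ppm_to_interval_ms(ppm) == interval

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            ppm_to_interval_ms(0)


class TestDeviceParams:
    def test_lrl_above_mtr_rejected(self):
        with pytest.raises(ValueError, match="lrl_ppm"):
            DeviceParams(lrl_ppm=140, mtr_ppm=130)

    def test_sav_above_pav_rejected(self):
        with pytest.raises(ValueError, match="sav_ms"):
            DeviceParams(sav_ms=220, pav_ms=200)

    def test_pvab_above_pvarp_rejected(self):
        with pytest.raises(ValueError, match="pvab_ms"):
            DeviceParams(pvab_ms=300, pvarp_ms=280)

    def test_interval_properties(self):
        d = DeviceParams(lrl_ppm=70, mtr_ppm=130)
        assert d.lri_ms == 857
        assert d.mtri_ms == 462


class TestClassifyAtrialSense:
    def test_refractory_sense_in_max_pvarp(self):
        d = DeviceParams(mode=Mode.DDI, pvarp_ms=500)
        assert (
            classify_atrial_sense(1468, 1000, d)
            is SenseClass.REFRACTORY_SENSE
        )

    def test_outside_pvarp_tracks_in_ddd(self):
        d = DeviceParams(mode=Mode.DDD, pvarp_ms=500)
        assert classify_atrial_sense(1570, 1000, d) is SenseClass.TRACKED_SENSE

    def test_outside_pvarp_nonrefractory_in_ddi(self):
        d = DeviceParams(mode=Mode.DDI, pvarp_ms=500)
        assert (
            classify_atrial_sense(1570, 1000, d)
            is SenseClass.NONREFRACTORY_SENSE
        )

    def test_blanked_inside_pvab(self):
        d = DeviceParams(pvab_ms=150, pvarp_ms=280)
        assert classify_atrial_sense(1100, 1000, d) is SenseClass.BLANKED

    def test_one_shot_extension_overrides_base(self):
        d = DeviceParams(pvarp_ms=280)
        assert (
            classify_atrial_sense(1468, 1000, d, effective_pvarp_ms=550)
            is SenseClass.REFRACTORY_SENSE
        )


class TestScheduling:
    def test_lower_rate_cycle_without_atrial_activity(self, protocol_device):
        log = run_simulation(
            protocol_device(),
            HeartParams(retrograde_1to1=False),
            20000,
        )
        aps = log.times(Marker.AP)
        vps = log.times(Marker.VP)
        assert not log.times(Marker.AS)
        # AP at VP + 657, VP at AP + 200, V-V = 857
        assert all(v - a == 200 for a, v in zip(aps, vps))
        assert all(b - a == 857 for a, b in zip(vps, vps[1:]))

    def test_vv_and_aa_bases_agree_at_lower_rate(self, protocol_device):
        for base in (TimingBase.V_V, TimingBase.A_A):
            log = run_simulation(
                protocol_device(timing_base=base),
                HeartParams(retrograde_1to1=False),
                20000,
            )
            vps = log.times(Marker.VP)
            assert all(b - a == 857 for a, b in zip(vps, vps[1:]))

    def test_slow_loop_cycle_is_vac_plus_sav(self, protocol_device):
        # observed conduction 570 + SAV 140 = 710 > upper-rate interval 462
        log = run_simulation(protocol_device(), HeartParams(vac_time_ms=570), 30000)
        vps = log.times(Marker.VP)
        assert vps[-1] - vps[-2] == 710

    def test_wenckebach_postpones_vp_to_upper_rate_bound(self, protocol_device):
        # VAC 468 + SAV 140 = 608 < interval at 95 ppm (632): VP held at 632
        log = run_simulation(
            protocol_device(mtr_ppm=95), HeartParams(vac_time_ms=468), 30000
        )
        vps = log.times(Marker.VP)
        assert vps[-1] - vps[-2] == 632 == closed_form_cycle(468, 140, 95)
        assert any("VP-MT" in e.annotation for e in log if e.marker is Marker.VP)


class TestRunSimulation:
    def test_tracking_loop_self_initiates(self, protocol_device):
        log = run_simulation(protocol_device(), HeartParams(vac_time_ms=468), 60000)
        tracked = [
            e for e in log
            if e.marker is Marker.AS and e.annotation.startswith("tracked")
        ]
        assert len(tracked) > 50  # sustained VP->AS loop

    def test_ddi_never_tracks(self, protocol_device):
        log = run_simulation(
            protocol_device(mode=Mode.DDI, pvarp_ms=280),
            HeartParams(vac_time_ms=570),
            30000,
        )
        vps = log.times(Marker.VP)
        # VVI-like: ventricular pacing at the lower rate, senses in between
        assert all(b - a == 857 for a, b in zip(vps[1:], vps[2:]))
        assert log.times(Marker.AS)

    def test_no_retrograde_gives_av_pacing_at_lrl_forever(self, protocol_device):
        log = run_simulation(
            protocol_device(), HeartParams(retrograde_1to1=False), 30000
        )
        assert not log.times(Marker.AS)
        assert not log.times(Marker.AR)

    def test_upper_rate_safety(self, protocol_device):
        for vac in (420, 468, 570):
            log = run_simulation(protocol_device(), HeartParams(vac_time_ms=vac), 30000)
            vps = log.times(Marker.VP)
            assert min(b - a for a, b in zip(vps, vps[1:])) >= 462

    def test_lower_rate_guarantee_without_vendor(self, protocol_device):
        for vac in (468, 570):
            for retro in (True, False):
                log = run_simulation(
                    protocol_device(),
                    HeartParams(vac_time_ms=vac, retrograde_1to1=retro),
                    30000,
                )
                vps = log.times(Marker.VP)
                assert max(b - a for a, b in zip(vps, vps[1:])) <= 857 + 1

    def test_duration_too_short_rejected(self, protocol_device):
        with pytest.raises(ValueError, match="10 lower-rate cycles"):
            run_simulation(protocol_device(), HeartParams(), 3000)

    def test_logs_reproducible_bit_for_bit(self, protocol_device):
        mk = lambda: run_simulation(
            protocol_device(), HeartParams(vac_time_ms=468), 30000
        ).to_csv()
        assert mk() == mk()


class TestEventLog:
    def test_ordering_enforced(self):
        log = EventLog()
        log.append(100, Marker.VP)
        with pytest.raises(ValueError, match="ordering"):
            log.append(50, Marker.AP)

    def test_tie_channel_order_a_before_v_before_device(self):
        log = EventLog()
        log.append(100, Marker.AS)
        log.append(100, Marker.VP)
        log.append(100, Marker.PMT_DETECT)
        with pytest.raises(ValueError, match="ordering"):
            log.append(100, Marker.AP)

    def test_csv_round_trip(self, protocol_device):
        log = run_simulation(protocol_device(), HeartParams(vac_time_ms=468), 20000)
        text = log.to_csv()
        restored = EventLog.from_csv(text)
        assert restored.to_csv() == text
        assert [e.marker for e in restored] == [e.marker for e in log]

    def test_marker_channels(self, protocol_device):
        log = run_simulation(protocol_device(), HeartParams(vac_time_ms=468), 20000)
        for e in log:
            if e.marker in (Marker.AP, Marker.AS, Marker.AR):
                assert e.channel is Channel.A
            elif e.marker is Marker.VP:
                assert e.channel is Channel.V
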