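"""Vendor algorithm tests: detection predicates, termination mechanics,
post-AR atrial-pacing delay, and the MicroPort DDI semantics."""

import pytest

from pacesim import (
    AbbottConfig,
    BiotronikConfig,
    DeviceParams,
    HeartParams,
    Marker,
    Mode,
    create_model,
    run_simulation,
)
from pacesim.studies import detect_rnrvas
from pacesim.timing import ppm_to_interval_ms

from conftest import closed_form_cycle


def ddd(vendor, vendor_config=None, **overrides):
    base = dict(
        mode=Mode.DDD, lrl_ppm=70, mtr_ppm=130, sav_ms=140,
        pav_ms=205 if vendor == "microport" else 200,
        pvarp_ms=280, vendor=vendor, vendor_config=vendor_config,
    )
    base.update(overrides)
    return DeviceParams(**base)


def ddi_max_pvarp(vendor, **overrides):
    pvarp = {"abbott": 500, "biotronik": 600, "boston": 500, "medtronic": 500,
             "microport": 280}[vendor]
    base = dict(
        mode=Mode.DDI, lrl_ppm=70, mtr_ppm=130, sav_ms=140,
        pav_ms=205 if vendor == "microport" else 200,
        pvarp_ms=pvarp, vendor=vendor,
    )
    base.update(overrides)
    return DeviceParams(**base)


def run(device, vac=468, duration=60000, **heart_kw):
    return run_simulation(device, HeartParams(vac_time_ms=vac, **heart_kw), duration)


class TestConfigValidation:
    def test_abbott_detection_rate_floor(self):
        with pytest.raises(ValueError, match=">= 90"):
            AbbottConfig(pmt_detection_rate_ppm=85)

    def test_biotronik_va_criterion_ceiling(self):
        with pytest.raises(ValueError, match="<= 500"):
            BiotronikConfig(va_criterion_ms=550)

    def test_unknown_vendor_rejected(self):
        with pytest.raises(ValueError, match="unknown vendor"):
            create_model("acme")

    def test_pvarp_above_vendor_maximum_rejected(self):
        with pytest.raises(ValueError, match="exceeds abbott maximum"):
            create_model("abbott", None, DeviceParams(pvarp_ms=510, vendor="abbott"))


class TestAbbott:
    def test_detects_and_terminates_at_rate_95(self):
        log = run(ddd("abbott", {"pmt_detection_rate_ppm": 95}), vac=468)
        assert log.has(Marker.PMT_DETECT)
        assert log.has(Marker.PMT_TERMINATE)

    def test_slow_loop_escapes_detection(self):
        # cycle 710 ms = 84.5 bpm, below the 90-bpm floor
        log = run(ddd("abbott", {"pmt_detection_rate_ppm": 90}), vac=570)
        assert not log.has(Marker.PMT_DETECT)

    def test_sav_shortening_recovers_detection(self):
        log = run(ddd("abbott", {"pmt_detection_rate_ppm": 90}, sav_ms=90), vac=570)
        assert log.has(Marker.PMT_DETECT)
        assert log.has(Marker.PMT_TERMINATE)

    def test_quiescent_without_retrograde_conduction(self):
        log = run(ddd("abbott", {"pmt_detection_rate_ppm": 90}),
                  retrograde_1to1=False)
        assert not log.has(Marker.PMT_SUSPECT)
        assert not log.has(Marker.PMT_DETECT)

    def test_termination_ap_retimes_the_atrium(self):
        log = run(ddd("abbott", {"pmt_detection_rate_ppm": 95}), vac=468)
        term = next(e.time_ms for e in log if e.marker is Marker.PMT_TERMINATE)
        ap_after = next(
            e for e in log
            if e.time_ms > term and e.marker in (Marker.AP, Marker.AP_NONCAPTURE)
        )
        assert ap_after.marker is Marker.AP  # captured: 330-ms coupling
        assert ap_after.time_ms - term == 330


class TestBiotronik:
    def test_criterion_500_detects_and_extends_pvarp(self):
        log = run(ddd("biotronik", {"va_criterion_ms": 500}), vac=468)
        assert log.has(Marker.PMT_DETECT)
        ext = next(e for e in log if e.marker is Marker.PVARP_EXT)
        assert "550" in ext.annotation  # criterion + 50
        assert log.has(Marker.PMT_TERMINATE)

    def test_conduction_beyond_criterion_escapes(self):
        log = run(ddd("biotronik", {"va_criterion_ms": 500}), vac=570)
        assert not log.has(Marker.PMT_DETECT)

    def test_default_criterion_350_misses_468(self):
        # derived from the detection predicate: 468 >= 350
        log = run(ddd("biotronik"), vac=468)
        assert not log.has(Marker.PMT_DETECT)


class TestBoston:
    def test_detects_at_mtr_95_and_terminates(self):
        log = run(ddd("boston", mtr_ppm=95), vac=468)
        assert log.has(Marker.PMT_DETECT)
        assert log.has(Marker.PMT_TERMINATE)

    def test_detection_needs_upper_rate_persistence(self):
        # at MTR 130 the 608-ms loop is slower than the MTR: no VP-MT flags
        log = run(ddd("boston"), vac=468)
        assert not log.has(Marker.PMT_DETECT)

    def test_long_conduction_detected_but_not_terminated(self):
        log = run(ddd("boston", mtr_ppm=80), vac=570)
        assert log.has(Marker.PMT_DETECT)
        assert log.has(Marker.PVARP_EXT)
        assert not log.has(Marker.PMT_TERMINATE)  # 570 > 500-ms extension

    def test_sixteen_upper_rate_cycles_before_detection(self):
        log = run(ddd("boston", mtr_ppm=95), vac=468)
        detect_t = next(e.time_ms for e in log if e.marker is Marker.PMT_DETECT)
        vp_mt = [e for e in log
                 if e.marker is Marker.VP and "VP-MT" in e.annotation
                 and e.time_ms <= detect_t]
        assert len(vp_mt) >= 16


class TestMedtronic:
    @pytest.mark.parametrize("vac", [468, 570])
    def test_never_detects_beyond_400(self, vac):
        log = run(ddd("medtronic"), vac=vac)
        assert not log.has(Marker.PMT_SUSPECT)
        assert not log.has(Marker.PMT_DETECT)

    def test_detects_below_limit(self):
        # derived: loop closed form max(380 + 140, 462) = 520; VP-AS 380 < 400
        assert closed_form_cycle(380, 140, 130) == 520
        log = run(ddd("medtronic"), vac=380)
        assert log.has(Marker.PMT_DETECT)
        assert log.has(Marker.PMT_TERMINATE)


class TestMicroPort:
    def test_detects_and_terminates_at_468(self):
        log = run(ddd("microport"), vac=468)
        assert log.has(Marker.PMT_DETECT)
        assert log.has(Marker.PMT_TERMINATE)

    def test_misses_long_conduction(self):
        log = run(ddd("microport"), vac=570)
        assert not log.has(Marker.PMT_DETECT)

    def test_boundary_is_inclusive_at_470(self):
        assert run(ddd("microport"), vac=470).has(Marker.PMT_DETECT)
        assert not run(ddd("microport"), vac=471).has(Marker.PMT_DETECT)

    def test_ddi_marks_ar_but_inhibits_like_as(self):
        log = run(ddi_max_pvarp("microport"), vac=468)
        ars = [e for e in log if e.marker is Marker.AR]
        assert ars and all("functional" in e.annotation for e in ars)
        # atrial pacing stays inhibited while retrograde conduction persists
        first_ar = ars[0].time_ms
        assert not [t for t in log.times(Marker.AP) if t > first_ar]
        vps = log.times(Marker.VP)
        assert all(b - a == 857 for a, b in zip(vps[1:], vps[2:]))  # VVI-like

    def test_ddi_ap_resumes_when_retrograde_stops(self):
        log = run(ddi_max_pvarp("microport"), retrograde_1to1=False)
        assert len(log.times(Marker.AP)) > 10


class TestPostArApDelay:
    def test_abbott_lacks_delay_and_produces_rnrvas(self):
        log = run(ddi_max_pvarp("abbott"), vac=468)
        assert not log.has(Marker.AP_DELAYED)
        assert log.has(Marker.AP_NONCAPTURE)
        assert detect_rnrvas(log)

    @pytest.mark.parametrize("vendor", ["biotronik", "boston", "medtronic"])
    def test_delaying_vendors_avoid_noncapture(self, vendor):
        log = run(ddi_max_pvarp(vendor), vac=468)
        assert log.has(Marker.AP_DELAYED)
        assert not log.has(Marker.AP_NONCAPTURE)
        assert not detect_rnrvas(log)

    def test_medtronic_every_ap_outside_ncap_window(self):
        log = run(ddi_max_pvarp("medtronic"), vac=468)
        last_ar = None
        for e in log:
            if e.marker is Marker.AR:
                last_ar = e.time_ms
            elif e.marker is Marker.AP and last_ar is not None:
                assert e.time_ms - last_ar >= 300
                last_ar = None

    def test_medtronic_pav_alternates(self):
        log = run(ddi_max_pvarp("medtronic"), vac=468)
        pavs, last_ap = [], None
        for e in log:
            if e.marker in (Marker.AP, Marker.AP_NONCAPTURE):
                last_ap = e.time_ms
            elif e.marker is Marker.VP and last_ap is not None:
                pavs.append(e.time_ms - last_ap)
                last_ap = None
        tail = pavs[-8:]
        assert sorted(set(tail)) != [200]
        assert 200 in tail  # programmed beats interleaved with shortened ones
        assert tail == [tail[i % 2] for i in range(len(tail))]

    def test_boston_holds_vv_constant(self):
        log = run(ddi_max_pvarp("boston"), vac=468)
        vps = log.times(Marker.VP)
        assert all(b - a == 857 for a, b in zip(vps[1:], vps[2:]))

    def test_biotronik_below_lrl_prolongation_arithmetic(self):
        # prolongation iff VAC + post-AR delay + shortest PAV > LRL interval
        for lrl in (60, 70):
            log = run(ddi_max_pvarp("biotronik", lrl_ppm=lrl), vac=468)
            vps = log.times(Marker.VP)
            max_vv = max(b - a for a, b in zip(vps[-10:], vps[-9:]))
            lri = ppm_to_interval_ms(lrl)
            assert (max_vv > lri) == (468 + 350 + 75 > lri)
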