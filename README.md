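# pacesim

A deterministic discrete-event simulator of dual-chamber pacemaker timing
cycles interacting with a heart model that has sinus arrest, complete AV
block, and prolonged retrograde ventriculoatrial (VA) conduction. It
includes behavioural models of five manufacturers' anti-PMT
(pacemaker-mediated tachycardia) detection/termination algorithms and
post-refractory-sense atrial-pacing-delay features, and reproduces the
device-specific outcome matrix of the underlying bench protocols: PMT
detection and termination in DDD, refractory atrial sensing (AR) in DDI,
and repetitive nonreentrant VA synchrony (RNRVAS).

## Layout

| module | role |
| --- | --- |
| `pacesim.heart` | patient substrate: retrograde conduction, atrial tissue refractoriness, capture |
| `pacesim.timing` | DDD/DDI timing engine: lower/upper-rate scheduling, PVARP/PVAB classification, Wenckebach delay, A-A vs V-V bases, marker-channel event log |
| `pacesim.vendors` | five vendor state machines (detection counting, AV-delay-modulation verification, one-cycle refractory interventions, NCAP/AFR/post-AR AP delay, MicroPort DDI quirk) |
| `pacesim.studies` | the three study protocols, outcome classification (`detect_pmt`, `detect_rnrvas`), parameter sweeps, and the summary-matrix reproduction report |
| `pacesim.config` / `pacesim.cli` / `pacesim.render` | YAML scenario files, command-line interface, ASCII ladder diagrams |
| `pacesim/scenarios/` | packaged scenario fixtures for all three studies |

Time is integer milliseconds throughout; rates convert via
`round(60000 / ppm)`. The engine has no randomness: identical inputs give
bit-for-bit identical logs.

## CLI

```sh
# simulate a packaged scenario (or any YAML file) and write the event log
pacesim run --config study1_abbott_vac450 --out-events events.csv --ladder ladder.txt

# most permissive programmable value achieving detection
pacesim sweep --vendor boston --vac 570 --param mtr          # -> 80
pacesim sweep --vendor abbott --vac 468 --param detection_rate \
    --objective detect_and_terminate                          # -> 95

# recompute the full categorical outcome matrix; exit 0 iff it matches
pacesim reproduce-table1 --out report/

# render a stored event CSV as an ASCII ladder
pacesim render --events events.csv

pacesim list-scenarios
```

Event CSVs use the schema `time_ms,channel,marker,annotation` with
channels `A`/`V`/`DEVICE` and markers `AP`, `AP_NONCAPTURE`, `AS`, `AR`,
`AS_BLANKED`, `VP`, `PVARP_EXT`, `PMT_SUSPECT`, `PMT_DETECT`,
`PMT_TERMINATE`, `AP_DELAYED`.

## Notes

* Reproduction scenarios set the heart's conduction time directly to the
  device-measured values (468 / 570 ms for the nominal 450 / 550 ms
  settings); study runners accept either label.
* A few manufacturer constants are not published (verification AV-delay
  modulation magnitude, stability tolerances, Abbott's termination AP
  coupling, NCAP/AFR/post-AR window widths). They are configurable fields
  with documented defaults chosen to reproduce the reported behaviours.
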