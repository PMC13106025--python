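name: study1_notrack_baseline
device:
  mode: DDD
  lrl_ppm: 70
  mtr_ppm: 130
  sav_ms: 140
  pav_ms: 200
  pvarp_ms: 280
heart:
  vac_time_ms: 570
  retrograde_1to1: false
  atrial_myo_refractory_ms: 250
duration_ms: 60000
seed: 0
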