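# Pig-calibrated 21-compartment model.  Derived from human_default by
# scripts/calibrate_pig.py: geometry scaled to pig size, total volume
# set so the analytic zero-flow equilibrium matches the pentobarbital
# plateau, baseline iterated to the VF-euvolemia anchors, reflex shape
# tuned against the anchor-curve reference.  Do not edit by hand.
name: pig_calibrated
total_blood_volume_ml: 3131.7
epsilon_elastance: 0.001
dt_s: 0.001
dt_post_arrest_s: 0.005
fs_hz: 200.0
heart_rate_bpm: 100.0
respiratory_rate_bpm: 12.0
intrathoracic_pressure_mmhg: 3.5
respiratory_amplitude_mmhg: 2.0
rectify_microcirculation: true
arrest_valve_r_factor: 200.0
arrest_tone_valve_gain: 300.0
compartments:
- id: 0
  name: aortic arch
  kind: arterial
  C: 0.12674
  V0: 10.92
  thoracic: true
- id: 1
  name: brachiocephalic
  kind: arterial
  C: 0.05884
  V0: 2.6
  thoracic: true
- id: 2
  name: upper-body arteries
  kind: arterial
  C: 0.19011
  V0: 104.0
  thoracic: false
- id: 3
  name: upper-body veins
  kind: venous
  C: 3.64
  V0: 312.0
  thoracic: false
- id: 4
  name: superior vena cava
  kind: venous
  C: 0.676
  V0: 8.32
  thoracic: true
- id: 5
  name: thoracic aorta
  kind: arterial
  C: 0.09505
  V0: 8.32
  thoracic: true
- id: 6
  name: abdominal aorta
  kind: arterial
  C: 0.04526
  V0: 5.2
  thoracic: false
- id: 7
  name: renal arteries
  kind: arterial
  C: 0.09505
  V0: 10.4
  thoracic: false
- id: 8
  name: renal veins
  kind: venous
  C: 2.6
  V0: 15.6
  thoracic: false
- id: 9
  name: splanchnic arteries
  kind: arterial
  C: 0.19011
  V0: 156.0
  thoracic: false
- id: 10
  name: splanchnic veins
  kind: venous
  C: 26.0
  V0: 520.0
  thoracic: false
- id: 11
  name: leg arteries
  kind: arterial
  C: 0.19011
  V0: 104.0
  thoracic: false
- id: 12
  name: leg veins
  kind: venous
  C: 9.88
  V0: 312.0
  thoracic: false
- id: 13
  name: abdominal veins
  kind: venous
  C: 13.0
  V0: 41.08
  thoracic: false
- id: 14
  name: inferior vena cava
  kind: venous
  C: 1.04
  V0: 17.16
  thoracic: true
- id: 15
  name: right atrium
  kind: cardiac
  E_min: 0.57692
  E_max: 1.42308
  V0: 7.28
  thoracic: true
- id: 16
  name: right ventricle
  kind: cardiac
  E_min: 0.13462
  E_max: 0.79018
  V0: 23.92
  thoracic: true
- id: 17
  name: pulmonary arteries
  kind: pulmonary
  C: 1.768
  V0: 83.2
  thoracic: true
- id: 18
  name: pulmonary veins
  kind: pulmonary
  C: 4.68
  V0: 197.6
  thoracic: true
- id: 19
  name: left atrium
  kind: cardiac
  E_min: 0.96154
  E_max: 1.17308
  V0: 12.48
  thoracic: true
- id: 20
  name: left ventricle
  kind: cardiac
  E_min: 0.25
  E_max: 1.33722
  V0: 28.6
  thoracic: true
connections:
- from: 20
  to: 0
  R: 0.007
  valved: true
- from: 0
  to: 1
  R: 0.014
- from: 1
  to: 2
  R: 0.014
- from: 2
  to: 3
  R: 3.86439
  microcirculation: true
- from: 3
  to: 4
  R: 0.18274
- from: 4
  to: 15
  R: 0.04651
- from: 0
  to: 5
  R: 0.011
- from: 5
  to: 6
  R: 0.01
- from: 6
  to: 7
  R: 0.1
- from: 7
  to: 8
  R: 3.23348
  microcirculation: true
- from: 8
  to: 13
  R: 0.18274
- from: 6
  to: 9
  R: 0.07
- from: 9
  to: 10
  R: 2.36596
  microcirculation: true
- from: 10
  to: 13
  R: 0.11631
- from: 6
  to: 11
  R: 0.09
- from: 11
  to: 12
  R: 3.54893
  microcirculation: true
- from: 12
  to: 13
  R: 0.16613
- from: 13
  to: 14
  R: 0.03155
- from: 14
  to: 15
  R: 0.01328
- from: 15
  to: 16
  R: 0.005
  valved: true
- from: 16
  to: 17
  R: 0.003
  valved: true
- from: 17
  to: 18
  R: 0.08
- from: 18
  to: 19
  R: 0.01
- from: 19
  to: 20
  R: 0.01
  valved: true
reflex:
  tick_hz: 200.0
  window_n: 250
  pulse_window_s: 2.0
  pulse_pressure_weight: 0.25
  setpoints:
    arterial_pressure: 53.95
    pulse_pressure: 28.25
    venous_pressure: 11.34
  saturation:
    abr: 18.0
    cpr: 5.0
  arcs:
  - name: abr_para
    afferent: arterial
    limit: abr
    kernel:
      delay: 0.2
      peak: 0.7
      end: 1.2
  - name: abr_symp
    afferent: arterial
    limit: abr
    kernel:
      delay: 2.0
      peak: 70.99
      end: 354.96
  - name: cpr_symp
    afferent: venous
    limit: cpr
    kernel:
      delay: 92.56
      peak: 555.34
      end: 1388.34
  - name: cpr_art
    afferent: venous
    limit: cpr
    kernel:
      delay: 250.0
      peak: 450.0
      end: 750.0
  gains:
    heart_rate:
      abr_para: -0.8
      abr_symp: -0.5
    contractility:
      abr_symp: -0.015
    peripheral_resistance:
      abr_para: -0.0279
      abr_symp: -0.09072
      cpr_symp: -0.15552
    unstressed_volume:
      abr_symp: 44.071
      cpr_symp: 298.915
      cpr_art: 3.033
  unstressed_volume_distribution:
    default:
      '10': 0.4789
      '3': 0.1596
      '12': 0.1596
      '8': 0.0599
      '13': 0.1397
      '2': 0.0011
      '9': 0.0011
    cpr_symp:
      '10': 0.48
      '3': 0.16
      '12': 0.16
      '8': 0.06
      '13': 0.14
    cpr_art:
      '2': 0.5
      '9': 0.5
calibration:
  tuning_vector:
  - 3.785797
  - 5.700159
  - 0.5737
  - 1.126615
  - 1.109545
  - 0.002252
  - 0.952415
  - 0.027901
  nrmse_pct: 3.79
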