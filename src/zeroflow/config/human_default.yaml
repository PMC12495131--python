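# 21-compartment closed-loop lumped-parameter model of the human circulation.
#
# Parameter values follow the CVSim-21 model family (Heldt's 21-compartment
# human model distributed through PhysioNet): two-element Windkessel
# compartments (inflow/outflow resistance + compliance), four time-varying
# elastance cardiac chambers, and an intrathoracic pressure acting on the
# thoracic compartments.  Values reconstructed from the published literature
# of that model family and adjusted so the closed loop settles at a textbook
# healthy-adult operating point (MAP ~95 mmHg, CVP ~5 mmHg, CO ~5 L/min,
# whole-circulation zero-flow equilibrium ~7 mmHg).
#
# Units: pressure mmHg, volume mL, time s, resistance mmHg.s/mL,
# compliance mL/mmHg, elastance mmHg/mL.
name: human_default
total_blood_volume_ml: 5150.0
epsilon_elastance: 1.0e-3     # floor on arrested-chamber elastance
dt_s: 0.001
dt_post_arrest_s: 0.005
fs_hz: 200.0
heart_rate_bpm: 75.0
respiratory_rate_bpm: 12.0
intrathoracic_pressure_mmhg: -4.0   # mean baseline; 0 after arrest
respiratory_amplitude_mmhg: 2.5
rectify_microcirculation: true      # arteriolar beds pass forward flow only
arrest_valve_r_factor: 200.0        # trans-cardiac resistance rise after arrest
arrest_tone_valve_gain: 300.0       # extra obstruction per unit sympathetic contractility drive

compartments:
  - {id: 0,  name: aortic arch,         kind: arterial,  C: 0.28, V0: 21.0,   thoracic: true}
  - {id: 1,  name: brachiocephalic,     kind: arterial,  C: 0.13, V0: 5.0,    thoracic: true}
  - {id: 2,  name: upper-body arteries, kind: arterial,  C: 0.42, V0: 200.0,  thoracic: false}
  - {id: 3,  name: upper-body veins,    kind: venous,    C: 7.0,  V0: 600.0,  thoracic: false}
  - {id: 4,  name: superior vena cava,  kind: venous,    C: 1.3,  V0: 16.0,   thoracic: true}
  - {id: 5,  name: thoracic aorta,      kind: arterial,  C: 0.21, V0: 16.0,   thoracic: true}
  - {id: 6,  name: abdominal aorta,     kind: arterial,  C: 0.10, V0: 10.0,   thoracic: false}
  - {id: 7,  name: renal arteries,      kind: arterial,  C: 0.21, V0: 20.0,   thoracic: false}
  - {id: 8,  name: renal veins,         kind: venous,    C: 5.0,  V0: 30.0,   thoracic: false}
  - {id: 9,  name: splanchnic arteries, kind: arterial,  C: 0.42, V0: 300.0,  thoracic: false}
  - {id: 10, name: splanchnic veins,    kind: venous,    C: 50.0, V0: 1000.0, thoracic: false}
  - {id: 11, name: leg arteries,        kind: arterial,  C: 0.42, V0: 200.0,  thoracic: false}
  - {id: 12, name: leg veins,           kind: venous,    C: 19.0, V0: 600.0,  thoracic: false}
  - {id: 13, name: abdominal veins,     kind: venous,    C: 25.0, V0: 79.0,   thoracic: false}
  - {id: 14, name: inferior vena cava,  kind: venous,    C: 2.0,  V0: 33.0,   thoracic: true}
  - {id: 15, name: right atrium,        kind: cardiac,   E_min: 0.30, E_max: 0.74, V0: 14.0, thoracic: true}
  - {id: 16, name: right ventricle,     kind: cardiac,   E_min: 0.07, E_max: 1.30, V0: 46.0, thoracic: true}
  - {id: 17, name: pulmonary arteries,  kind: pulmonary, C: 3.4,  V0: 160.0,  thoracic: true}
  - {id: 18, name: pulmonary veins,     kind: pulmonary, C: 9.0,  V0: 380.0,  thoracic: true}
  - {id: 19, name: left atrium,         kind: cardiac,   E_min: 0.50, E_max: 0.61, V0: 24.0, thoracic: true}
  - {id: 20, name: left ventricle,      kind: cardiac,   E_min: 0.13, E_max: 2.20, V0: 55.0, thoracic: true}

# Directed edges of the closed loop.  `valved: true` marks ideal diodes
# (cardiac valves); `microcirculation: true` marks the systemic arteriolar
# beds, which carry the reflex resistance effector and — when
# rectify_microcirculation is set — also behave as one-way elements
# (Starling-resistor-like arteriolar collapse under retrograde gradient).
connections:
  - {from: 20, to: 0,  R: 0.007, valved: true}    # aortic valve
  - {from: 0,  to: 1,  R: 0.014}
  - {from: 1,  to: 2,  R: 0.014}
  - {from: 2,  to: 3,  R: 4.9,  microcirculation: true}   # upper-body bed
  - {from: 3,  to: 4,  R: 0.11}
  - {from: 4,  to: 15, R: 0.028}
  - {from: 0,  to: 5,  R: 0.011}
  - {from: 5,  to: 6,  R: 0.010}
  - {from: 6,  to: 7,  R: 0.10}
  - {from: 7,  to: 8,  R: 4.1,  microcirculation: true}   # renal bed
  - {from: 8,  to: 13, R: 0.11}
  - {from: 6,  to: 9,  R: 0.07}
  - {from: 9,  to: 10, R: 3.0,  microcirculation: true}   # splanchnic bed
  - {from: 10, to: 13, R: 0.07}
  - {from: 6,  to: 11, R: 0.09}
  - {from: 11, to: 12, R: 4.5,  microcirculation: true}   # leg bed
  - {from: 12, to: 13, R: 0.10}
  - {from: 13, to: 14, R: 0.019}
  - {from: 14, to: 15, R: 0.008}
  - {from: 15, to: 16, R: 0.005, valved: true}    # tricuspid valve
  - {from: 16, to: 17, R: 0.003, valved: true}    # pulmonic valve
  - {from: 17, to: 18, R: 0.08}                   # pulmonary bed
  - {from: 18, to: 19, R: 0.01}
  - {from: 19, to: 20, R: 0.01, valved: true}     # mitral valve

# Arterial baroreflex (ABR) + cardiopulmonary reflex (CPR) controller.
# Afferent pressures are smoothed over window_n samples, offset against the
# set points, saturated through an arctan with the stated limits, convolved
# with unit-area impulse-response kernels, and mapped through static gains
# onto heart rate, contractility, arteriolar resistance, and venous
# unstressed volume.
reflex:
  tick_hz: 200.0
  window_n: 250
  pulse_window_s: 2.0
  pulse_pressure_weight: 0.25   # weight of the pulse-pressure error in the ABR afferent
  setpoints:
    arterial_pressure: 95.0
    pulse_pressure: 35.0
    venous_pressure: 3.0
  saturation:
    abr: 18.0
    cpr: 5.0
  # unit-area triangular kernels: (delay, peak, end) in seconds
  arcs:
    - {name: abr_para, afferent: arterial, limit: abr, kernel: {delay: 0.2, peak: 0.7, end: 1.2}}
    - {name: abr_symp, afferent: arterial, limit: abr, kernel: {delay: 2.0, peak: 40.0, end: 200.0}}
    - {name: cpr_symp, afferent: venous,   limit: cpr, kernel: {delay: 30.0, peak: 180.0, end: 450.0}}
  # effector = base (+ additive) or base * (1 + fractional corrections),
  # clamped at physiological floors.  Sign convention: positive scaled error
  # = pressure above set point = vagal response (HR down, dilatation,
  # unstressed volume up).
  gains:
    heart_rate:            {abr_para: -0.8, abr_symp: -0.5}       # bpm per unit
    contractility:         {abr_symp: -0.015}                     # fractional per unit
    peripheral_resistance: {abr_symp: -0.035, cpr_symp: -0.06}    # fractional per unit
    unstressed_volume:     {abr_symp: 60.0, cpr_symp: 90.0}       # mL per unit
  # distribution of the unstressed-volume effector over compartments,
  # per arc: baroreflex venoconstriction recruits the venous reservoirs with
  # a token arterial share; the slow cardiopulmonary arc carries a larger
  # arterial tone component (late arteriolar tone loss pulls the latched
  # arterial tree down)
  unstressed_volume_distribution:
    default:
      10: 0.48    # splanchnic veins
      3: 0.16     # upper-body veins
      12: 0.16    # leg veins
      8: 0.06     # renal veins
      13: 0.138   # abdominal veins
      2: 0.001    # token arterial share (slight arterial rise to the peak)
      9: 0.001
    cpr_symp:
      10: 0.46
      3: 0.16
      12: 0.16
      8: 0.05
      13: 0.15
      2: 0.008    # arterial tone share
      9: 0.008
      11: 0.004
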