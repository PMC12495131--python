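# Group mean +/- SD of the pig experiments at the four analysis time points
# (T0 = -20 s baseline, T1 = 30 s equilibration/crossing, T2 = 300 s peak,
# T3 = 600 s plateau; times relative to arrest).  Channels: MAP and CVP in
# mmHg, CO in L/min.  These anchor values constrain the synthetic-data
# generator; they are group-level summary statistics, not raw recordings.
times_s: [-20.0, 30.0, 300.0, 600.0]
groups:
  pento_eu:
    label: pentobarbital-euvolemia
    co:  {mean: [4.3, 0.0, 0.0, 0.0],     sd: [1.2, 0.0, 0.0, 0.0]}
    map: {mean: [47.0, 16.0, 14.0, 15.0], sd: [3.7, 2.5, 2.8, 2.9]}
    cvp: {mean: [12.0, 15.0, 14.0, 14.0], sd: [2.9, 3.1, 3.3, 3.5]}
  vf_eu:
    label: VF-euvolemia
    co:  {mean: [3.0, 0.0, 0.0, 0.0],     sd: [1.2, 0.0, 0.0, 0.0]}
    map: {mean: [53.0, 17.0, 17.9, 11.0], sd: [4.7, 2.2, 1.6, 0.8]}
    cvp: {mean: [11.0, 15.0, 22.9, 16.0], sd: [6.0, 4.6, 5.0, 3.7]}
  vf_hypo:
    label: VF-hypovolemia
    co:  {mean: [2.4, 0.0, 0.0, 0.0],     sd: [0.0, 0.0, 0.0, 0.0]}
    map: {mean: [45.0, 14.8, 16.2, 9.0],  sd: [5.6, 1.1, 1.1, 1.6]}
    cvp: {mean: [9.0, 13.3, 19.4, 13.0],  sd: [3.3, 2.9, 3.1, 3.1]}
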