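# Full-scale study profile: fine mesh, complete enumeration grids
# (91 partitions x 17 gamma_m x 9 gamma_r = 13923 training specifications).
domain_kind: disk
domain_params: {radius: 10.0}
n_electrodes: 10
# the rigid electrode plate covers 16 cm of the frontal boundary arc
plate_span_cm: 16.0
electrode_width: 1.0
mesh_h: 0.3
current_mA: 1.0
L: 15
d0: 0.3
gamma_f: 1.0
gamma_m_grid: [2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0, 5.5, 6.0, 6.5, 7.0, 7.5, 8.0, 8.5, 9.0, 9.5, 10.0]
gamma_r_grid: [1.5, 2.5, 3.5, 4.5, 5.5, 6.5, 7.5, 8.5, 9.5]
enforce_order: false
hidden: [512, 256, 128, 64, 32]
epochs: 800
lr_decay_every: 200
seed: 1
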