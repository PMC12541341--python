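{
  "version": 1,
  "comment": "Model radial pair potentials for the Ca-CO3 relative coordinate. Basin positions follow the qualitative landscape of the contact/solvent-shared ion pair (bidentate ~2.9 A, monodentate ~3.4 A, barrier ~4 A, solvent-shared ~5 A); depths and widths are package choices, not fits. Tail: screened Coulomb q1*q2=-4 e^2 with the model dielectric 102; 'truncated' switches the tail off smoothly between the model cutoff 6 A and twice the cutoff.",
  "presets": {
    "caco3_lr": {
      "basins": [
        [2.9, 2.2, 0.15],
        [3.15, -4.0, 0.12],
        [3.4, 1.5, 0.15],
        [4.1, -7.0, 0.35],
        [5.0, 2.5, 0.3]
      ],
      "charge_product": -4.0,
      "epsilon": 102.0,
      "tail_mode": "full",
      "cutoff": 6.0,
      "inner_wall_radius": 2.77
    },
    "caco3_sr": {
      "basins": [
        [2.9, 2.2, 0.15],
        [3.15, -4.0, 0.12],
        [3.4, 1.5, 0.15],
        [4.1, -7.0, 0.35],
        [5.0, 2.5, 0.3]
      ],
      "charge_product": -4.0,
      "epsilon": 102.0,
      "tail_mode": "truncated",
      "cutoff": 6.0,
      "inner_wall_radius": 2.77
    }
  }
}
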