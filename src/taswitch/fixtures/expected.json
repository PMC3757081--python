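{
  "reference_fixed_points": [
    [
      1.2396895996836117,
      0.12498945983644398
    ],
    [
      0.18498685751344646,
      0.9181822892230382
    ],
    [
      0.12278083271097687,
      0.9562356028847155
    ]
  ],
  "mini_state_diagram_n_bistable": 13,
  "mini_robustness_fraction": 0.36
}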