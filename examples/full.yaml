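# Full-size run: 1 incisor + 5 cheek teeth per side -> 12 bite loading
# regimes (2 incisor + 10 molar), ~53k-element phantom.
phantom:
  n_cheek_teeth: 5
sensitivity:
  multipliers: {pdl: 0.1, suture: 0.1}
  near_distance: 4.0
output_dir: runs/full
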