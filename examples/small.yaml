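# Small demonstration run: two cheek teeth per side (6 bite regimes),
# ~35k-element phantom, with the soft-tissue sensitivity variant.
phantom:
  n_cheek_teeth: 2
  height: 14.0
sensitivity:
  multipliers: {pdl: 0.1, suture: 0.1}
  near_distance: 4.0
output_dir: runs/small
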