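# Nominal deoxygenation/reoxygenation cycle: 183 µM initial O2, 50 µM heme
# stripped Hb, ~0.05 µM cytochrome c oxidase, succinate at 50 s, cell
# reopened at 1000 s; minimalist (single-affinity sequential) model.
model: minimalist
protocol:
  t_end: 1400.0
  dt: 1.0
  t_respiration_on: 50.0
  t_open: 1000.0
  o2_initial: 183.0
  o2_air: 183.0
  hb_heme_total: 50.0
  oxidase_total: 0.05
sigma: 0.5
seed: 1
outdir: hbodc_out/minimalist
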