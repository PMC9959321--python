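# Reduced-size demonstration run: same generative model and analysis
# defaults as the full study design, with fewer variants and barcodes so the
# complete pipeline finishes in a couple of minutes on one CPU.
out_dir: mpra_demo
seed: 0
simulation:
  n_variants: 300
  barcodes_per_seq_mean: 30.0
  n_pos_controls: 30
  n_neg_controls: 40
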