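# Demo: simulate a 3000-cell EMT population at a (40, 35, 25)% mixture of
# epithelial / partial-EMT / mesenchymal cells and run the full analysis.
seed: 1
simulate:
  n_cells: 3000
resolutions: [1.0]
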