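# Synthetic 4 x 10 binding-energy matrix (kBT), rows A C G T.
# Constructed fixture for tests and examples: NOT a measured TF model.
# Column minima are 0, so the consensus sequence has energy 0.
A 0.00 1.10 2.05 0.00 0.35 1.80 0.00 0.95 1.40 0.60
C 1.25 0.00 0.70 2.10 0.00 0.55 1.65 0.00 0.85 1.90
G 2.40 1.75 0.00 1.30 1.95 0.00 0.80 1.55 0.00 0.00
T 0.85 2.20 1.45 0.65 1.10 2.35 2.00 1.20 0.45 1.15
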