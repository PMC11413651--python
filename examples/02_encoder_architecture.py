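"""Shape arithmetic of the volumetric encoder.

Five conv/pool blocks halve each spatial axis (floor division), a 1x1x1
conv block mixes channels, and an average-pool/flatten tail produces the
feature vector the two heads share.  At the full brain-scan resolution of
160 x 192 x 160 the flattened vector has exactly 768 entries.
"""

import numpy as np

from harmonytm import (EncoderConfig, ScannerLabelSpace, build_bundle,
                       feature_length, forward_features, predict_disease,
                       predict_scanner)

full = EncoderConfig(input_shape=(160, 192, 160))
print(f"full resolution {full.input_shape} -> {feature_length(full)} features")

desk = EncoderConfig(input_shape=(24, 24, 24),
                     channel_widths=(4, 8, 16, 32, 32, 16))
print(f"desk scale      {desk.input_shape} -> {feature_length(desk)} features")

bundle = build_bundle(desk, ScannerLabelSpace.of_size(4), seed=0)
volumes = np.random.default_rng(0).normal(size=(5, 24, 24, 24))
feats = forward_features(bundle, volumes)
p = predict_disease(bundle, feats)
P = predict_scanner(bundle, feats)
print(f"batch of 5 -> features {feats.shape}, disease probabilities "
      f"{np.round(p, 3)}, scanner softmax row sums {P.sum(axis=1)}")
print("Row sums are exactly 1: the scanner head output is a distribution "
      "over the scanner pool for every sample.")
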