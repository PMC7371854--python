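"""Sanitize raw riboswitch sequences and extract their feature spaces.

Builds a handful of raw inputs (RNA alphabet, lowercase, ambiguity codes),
sanitizes them to ACGT, and prints the two model inputs: the 20 k-mer
frequencies used by the conventional classifiers and the integer encoding
consumed by the deep models.
"""

import numpy as np

from riboclass import encode_sequence, kmer_features, sanitize_sequence
from riboclass.featurize import FEATURE_NAMES

raw_inputs = [
    "augcaggucacgRuacg",  # RNA, lowercase, one ambiguity code
    "ACGuacguACGU",
    "ggg-ccc..AAA",  # alignment gaps are stripped
]

for raw in raw_inputs:
    clean = sanitize_sequence(raw)
    print(f"{raw!r:24s} -> {clean}")

seq = sanitize_sequence(raw_inputs[0])
features = kmer_features(seq)
print("\nk-mer features of", seq)
for name, value in zip(FEATURE_NAMES, features):
    if value > 0:
        print(f"  {name}: {value:.3f}")
print("mononucleotide block sums to", round(float(features[:4].sum()), 9))
print("dinucleotide block sums to", round(float(features[4:].sum()), 9))

codes = encode_sequence(seq, length=24)
print("\ninteger encoding (0 pads on the right):", codes.tolist())
# The frequencies feed the k-mer classifiers after standardization; the
# integer codes feed the CNN/RNN directly, so no feature engineering is
# needed for the deep models.
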