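"""Compute DNA-shape profiles and the 88-dim shape feature vector of an SNV.

MGW/ProT are per-base-pair pentamer lookups; Roll/HelT come from averaged
base-pair-step contributions of overlapping pentamers.  The feature vector
holds, for each parameter, the 11 mutated-sequence values at offsets -5..+5
around the variant followed by the 11 mutated-minus-reference differences.
"""

import numpy as np

from promshape import make_pentamer_table, shape_feature_vector, shape_profiles
from promshape.shape import shape_feature_names

table = make_pentamer_table(seed=7)

seq = "ACGTACATGCATGCA"  # 15-mer, variant at the center (position 8)
prof = shape_profiles(seq, table)
print(prof.to_frame().round(2).to_string(index=False))

mut = seq[:7] + "G" + seq[8:]  # T -> G at the center
vec = shape_feature_vector(seq, mut, table)
names = shape_feature_names()
diffs = {n: v for n, v in zip(names, vec) if "_diff_" in n and v != 0}
print(f"\n{len(diffs)} of 44 difference features are non-zero (local effect):")
for name in list(diffs)[:6]:
    print(f"  {name:22s} {diffs[name]:+.3f}")
# Diffs vanish beyond offset +-2 (MGW/ProT) and +-3 (Roll/HelT): only
# pentamers covering the substituted base can move.
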