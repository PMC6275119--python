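"""Measure what each feature group contributes via permutation ablation.

Columns of a group are jointly row-permuted in the *test* matrix (one
shared permutation, preserving within-group structure), destroying their
information without retraining; the drop in average precision quantifies
how much the trained model relies on that group.
"""

from promshape import (
    ExtractionConfig,
    FeatureMatrix,
    GTBConfig,
    SignalConfig,
    build_matrix,
    make_bundle,
    permutation_ablation,
    predict,
    stratified_split,
    train_gtb,
)

bundle = make_bundle(SignalConfig(n_pos=150, n_neg=300, n_chrom=8, seed=51))
matrix = build_matrix(
    bundle.variants,
    bundle.genome,
    bundle.pentamers,
    bundle.tracks,
    ExtractionConfig(groups=("sequence", "gc", "shape")),
)
y = matrix.y()
train_keys, _ = stratified_split(list(matrix.data.index), y, 0.2, seed=51)
mask = matrix.data.index.isin(train_keys)
subset = lambda m: FeatureMatrix(
    matrix.data[m], matrix.schema, matrix.chroms[m], matrix.labels[m]
)
m_train, m_test = subset(mask), subset(~mask)
model = train_gtb(m_train, m_train.y(), GTBConfig(n_trees=150, seed=51))

result = permutation_ablation(
    model, m_test, m_test.y(), [("gc",), ("shape",), ("gc", "shape")], seed=51
)
print(result.to_frame().round(3).to_string(index=False))
# A large AP drop after permuting a group means the model leans on it; in
# this benchmark the same allele-class signal is redundantly encoded in
# sequence, GC and shape, so single-group drops understate each group's
# information content.
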