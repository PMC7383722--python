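"""Rejection of a cell type missing from the reference.

Removes one type's profile from the reference and re-classifies: the
orphaned cluster's best correlation collapses below the 0.5 cutoff and the
cluster is left "unassigned" instead of being mislabelled.
"""

from clustercall import (
    ReferenceMatrix,
    SyntheticSpec,
    clustify,
    cor_to_call,
    generate_dataset,
    select_top_variance_genes,
)

query, meta, reference, _ = generate_dataset(SyntheticSpec(seed=1))
genes = select_top_variance_genes(query, 100)

held_out = "type2"
loo = ReferenceMatrix(reference.values.drop(columns=held_out), is_log=reference.is_log)

cor = clustify(query, meta, loo, query_genes=genes)
calls = cor_to_call(cor, threshold=0.5)
print(f"reference without {held_out!r}:")
print(calls.table, end="\n\n")

row = cor.values.loc[held_out]
print(f"{held_out} cluster's best remaining correlation: "
      f"{row.max():.3f} (vs {row.idxmax()}) < 0.5 cutoff -> unassigned.")
print("the other clusters keep their correct calls.")
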