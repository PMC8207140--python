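"""Cluster differentially expressed genes into co-expression regulons.

Filters genes with a 2-fold change in any condition, builds the signed
weighted network (beta=6), clusters 1-TOM with average linkage into four
modules, labels them by cosine match to the class expression templates,
and appends the 100 least-affected genes as "none".
"""

from sklearn.metrics import adjusted_rand_score

from ferrocre import coexpress
from ferrocre.synthgen import SynthConfig, generate_dataset

dataset = generate_dataset(SynthConfig(seed=1))
deg = coexpress.select_deg(dataset.expression, fold_threshold=2.0)
none_genes = coexpress.select_no_response(dataset.expression, n=100)
assignment = coexpress.cluster_regulons(
    dataset.expression, deg, no_response_genes=none_genes
)

print(f"DEG genes (>=2-fold): {len(deg)}")
print("module sizes:")
print(assignment.labels.value_counts().to_string())

scored = [g for g in assignment.labels.index if dataset.truth_labels[g] != "none"]
ari = adjusted_rand_score(
    [dataset.truth_labels[g] for g in scored], assignment.labels.loc[scored]
)
print(f"ARI vs planted classes: {ari:.3f}")
# An ARI near 1 means the four planted regulons were recovered almost
# perfectly; the ~1200 responsive genes pass the 2-fold filter while a
# small fraction of no-response genes leak through by chance.
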