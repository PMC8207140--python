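# ferrocre

Regulon clustering, *cis*-regulatory element (CRE) discovery and
promoter-structure modeling for iron-excess stress transcriptomes.

## The problem

Rice grown in flooded acidic soils takes up excess ferrous iron, and the
transcriptional response spans distinct gene programs — iron storage
(ferritins), iron uptake (transporters, suppressed under excess), metal
chelator synthesis, and WRKY-associated stress genes. Which short
promoter sequences (CREs) drive each program is largely unknown.
`ferrocre` implements a complete desk-scale version of the
bioinformatics route to that question: cluster stress-responsive genes
into co-expression regulons, hunt for short motifs over-represented in
each regulon's promoters, test whether motif presence/absence alone can
predict a gene's expression class, and condense the result into an
interpretable promoter-structure flowchart. A first-class synthetic-data
generator emulates the statistical structure of such a study (five gene
classes, seven log2-ratio conditions, planted TSS-proximal motifs), so
every step can be exercised and validated end to end with known ground
truth.

## The core statistics

**Regulon clustering.** On genes with a ≥2-fold change in some condition,
a signed weighted network is built from Pearson correlation,
a_ij = ((1 + r_ij)/2)^β with β = 6, converted to the topological overlap
measure

    TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij),

and 1 − TOM is clustered with average linkage into four modules, each
labeled by cosine match of its centroid to the class expression
templates. The 100 least-affected genes (below 2-fold everywhere) form
the "no response" class.

**Motif enrichment.** For a motif with k_reg occurrences in the regulon's
promoter windows (total length L_reg bp) and k_bg occurrences in a
background window set (all genes, or same-size random sequence),

    E = (k_reg / L_reg) / (k_bg / L_bg).

Significance is the upper binomial tail P(X ≥ k), X ~ Bin(n, p), with
k = regulon genes carrying the motif, n = regulon size, and p = fraction
of background genes carrying it. Discovery enumerates every exact k-mer
(default k = 8) in the regulon windows (−500..+150 relative to the TSS),
ranks by p-value, and by default applies a Bonferroni cut α/4^k over the
k-mer space so that a null regulon returns nothing.

**Classification.** Gene × motif binary presence matrices feed a
shadow-feature all-relevant selector (each iteration adds a permuted
copy of every feature; a feature scores a hit when it out-ranks the best
shadow; hits are tested against Bin(t, ½)) and a gradient-boosted tree
classifier evaluated with undersampling and stratified 5-fold CV.
Reported metrics: confusion counts, per-cell "enrichment %" (cell as a
share of its predicted-class total; 20% = chance for five balanced
classes), balanced accuracy = macro mean of (sensitivity +
specificity)/2, and one-vs-rest macro AUC-ROC.

**Promoter structure.** A shallow CART tree over motif presence is
rendered as a YES/NO flowchart with per-node five-class composition, and
branch compositions are summarized by

    pct = (p_type_in_branch × p_all_in_branch) / (p_type_overall / p_all_overall) × 100.

## Worked example

```python
from ferrocre import motifdisc
from ferrocre.seqio import WindowSpec, extract_windows
from ferrocre.synthgen import SynthConfig, generate_dataset

ds = generate_dataset(SynthConfig(seed=1))
windows = extract_windows(ds.genome, ds.genes, WindowSpec(-500, 150))
storage = {g: windows[g] for g, c in ds.truth_labels.items() if c == "storage"}
for r in motifdisc.discover_kmers(storage, windows, k=8)[:3]:
    print(r.motif.consensus, round(r.enrichment, 2),
          f"{r.genes_with_motif}/{r.n_genes}", f"{r.pvalue:.3g}")
```

prints

```
CATGCATG 4.78 215/300 1.82e-107
ATGCATGG 4.58 64/300 1.93e-24
GCATGCAT 4.29 66/300 1.04e-23
```

The top hit is the planted Fe-storage motif: it occurs 4.8× more often
per bp in storage promoters than across all genes, is present in 215 of
300 regulon genes against a ~13% background rate, and the following hits
are its shifted overlapping variants. Running
`examples/04_scan_and_classify.py` continues the analysis: selection
confirms exactly the four planted class motifs and the boosted-tree
model reaches balanced accuracy 0.848 (chance enrichment level 20%).
Each `examples/*.py` script demonstrates one capability and explains its
output.

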