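# Methods

This note documents the models and procedures implemented in
`ferrocre`, the defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the numerical conventions that
make results reproducible bit for bit.

## Synthetic data model

`synthgen.generate_dataset` draws a multi-contig genome with i.i.d.
bases (default composition A = T = 0.26, C = G = 0.24, the normalized
strand-pooled A/T vs C/G weights typical of plant promoter regions),
lays out genes on contigs of 50 genes spaced 10 kb apart with margins so
the full −3000..+2000 promoter span always fits, and draws strands
uniformly. Expression rows are class template + N(0, noise_sd) per
condition, with noise_sd = 0.5 log2 units by default.

The five classes and seven conditions mirror an iron-stress design:
five Fe-excess tissue columns (root, discrimination center, stem, old
leaf, newest leaf) plus Fe-deficient root and Zn-deficient root. The
default templates encode the qualitative sign structure of the four
response programs — storage up everywhere under excess and down under
root Fe deficiency; uptake suppressed under excess (strongest in root)
and induced under deficiency; chelator up under excess and Zn
deficiency; WRKY-type up in stem and down under root Fe deficiency —
with |log2| magnitudes up to 2.5. Magnitudes and the noise level are
package choices (no source values exist for them); they were fixed once
so that the four templates are mutually distinguishable (pairwise
template correlations ≲ 0.5), matching the premise that the four
response programs form clearly separated co-expression clusters.

Planted motifs overwrite background bases in place (no insertion), so
coordinates stay TSS-aligned; positions are drawn Normal(−150, 120) and
clipped to the span, giving the TSS-proximal bias real CREs show.
Degenerate letters are resolved uniformly per instance. Default plan:
CATGCATG → storage, CTACGTGC → uptake, GCWGCWGC → chelator,
CGACACGC → wrky, each at probability 0.7 per target gene.

Not emulated: isochore/repeat structure, dinucleotide bias,
position-specific background composition around the TSS, probe/dye
effects, correlated noise across conditions, multiple TSS per gene.
Passing tests therefore show the algorithms recover planted structure
under idealized i.i.d. backgrounds, not that they would perform
identically on real rice promoters, where background autocorrelation
inflates k-mer variance.

## Window conventions

Windows are half-open TSS-relative intervals with the TSS base at
relative 0, so "−500 to +150" spans 650 bp including the TSS base (the
inclusive/exclusive convention is fixed here to make tests bit-exact).
Minus-strand windows are taken from the opposite genomic side and
reverse-complemented, so sequences always read 5'→3' on the promoter
strand; reverse-complementing the genome and flipping strands is an
exact symmetry of all downstream results. Windows running off a contig
are clipped and flagged, never dropped, so edge density differences
between datasets cannot silently change gene sets. `N` bases match no
motif letter.

## Regulon clustering

Differential expression uses max over conditions of |log2 ratio| ≥
log2(fold) with fold = 2 (2.82, i.e. 2^1.5, is the convention for the
Fe-deficiency column when used alone). Fe-level replicate series are
merged by geometric mean — the arithmetic mean on the log2 scale —
before filtering. The network is signed: a_ij = ((1 + r_ij)/2)^β with
Pearson r and β = 6, a common signed-network default. TOM follows the
standard formula with unit diagonal; 1 − TOM distances are clustered
with average linkage.

The tree is cut to exactly k = 4 modules, but a plain maxclust cut can
waste modules on stray weakly connected genes (average linkage merges
them last — in practice the ~5% of no-response genes whose noise clears
the 2-fold filter). The cut therefore deepens until four clusters of at
least `min_module_size` (default 30) genes emerge; those are the
modules, and every remaining gene joins the module whose centroid it
best correlates with. Modules are labeled by cosine similarity of their
centroid to the responsive-class templates, with a one-to-one
(maximum-similarity assignment) fallback if two modules claim the same
label. Zero-variance genes are excluded with a warning, since Pearson
correlation is undefined for them. The 100 least-affected genes (max
|log2| < 1, ties broken by gene id) are appended as "none".

Clustering recovery is scored as adjusted Rand index against the
planted classes on genes that truly belong to one of the four
responsive regulons: no-response genes that leak through the fold filter
carry no class signal by construction, so no method can place them
"correctly", and including them would measure the filter, not the
clustering. At the default conditions the recovery ARI is ≈ 0.96–0.97
(the full assigned set, leaked genes included, sits near 0.86).

## Motif discovery and scoring

Occurrences are counted overlapping (tandem repeats such as AGCTAGCT
are themselves motifs of interest) on the promoter strand only, since
consensus CREs are written single-stranded; a both-strands option
collapses a motif with its reverse complement. Enrichment is the
per-bp occurrence rate ratio between regulon and background windows; a
zero background count yields an infinity sentinel with a flag.

The binomial null is applied per gene: k = regulon genes containing ≥1
hit, n = regulon size, p = fraction of background genes containing ≥1
hit. This matches the presence/absence representation used by the
downstream classifiers; an occurrence-based reading is available via
`score_motif`'s raw counts. The tail P(X ≥ k) is computed by
`scipy.stats.binom.sf`, verified against exact summation to 1e-12 over
the whole n ≤ 50 grid.

Discovery enumerates all exact k-mers present in the regulon (2-bit
encoded, k ≤ 12), ranks by p-value, then enrichment, then k-mer, and
applies a Bonferroni cut α/4^k by default. The uncorrected per-k-mer
cut (`correction=None`) is retained, but it cannot serve as a default:
with ~2.5·10^5 candidate 8-mers tested per regulon, a null regulon of
400 genes drawn from a 2000-gene background produces a handful of
nominal p < 10^-3 k-mers in essentially every draw, while genuinely
planted motifs score p < 10^-100 and are untouched by the correction.
Families of near-identical k-mers can be merged into IUPAC consensi by
greedy single-linkage at Hamming distance ≤ `max_mismatch`; a merged
family is kept only if its re-computed enrichment is at least the
minimum of its members', otherwise the group reverts. (Note the
GCAGCAGC/GCTGCTGC → GCWGCWGC family requires `max_mismatch=2`.)

PWM scanning scores Σ_j log2(p_j(base)/q(base)) and calls a hit at
≥ `threshold_fraction` (default 0.8) of the PWM's maximum attainable
score; no principled cutoff exists for consensus-derived PWMs, and 0.8
is a common practical choice. The scan background A = T = 0.26,
C = G = 0.24 is the normalization of strand-pooled weights
{A: 0.52, C: 0.48, G: 0.48, T: 0.52} (which sum to 2 over one strand);
normalizing preserves the A/T vs C/G asymmetry while making the vector
a probability distribution.

## Classification

Shadow selection fits a gradient-boosted ensemble (60 trees, depth 3)
each iteration on real + permuted-shadow features; a feature scores a
hit when its importance strictly exceeds the best shadow importance
(strictness guarantees constant features, importance 0, can never be
confirmed). After t iterations a two-sided binomial test of the hit
count against Bin(t, ½) at α = 0.05 confirms or rejects; iteration
stops early once every feature is decided (≤ 100 iterations).
Importances are reported as the mean over iterations scaled to max =
100. A single ensemble family (boosted trees) serves both selection and
final model for determinism; the `model` parameter swaps in any
scikit-learn-compatible classifier.

Evaluation undersamples every class to the minority size (the balanced
design the 20%-chance enrichment baseline assumes), then pools
out-of-fold predictions from stratified 5-fold CV. The confusion matrix
is oriented predictions × truth; enrichment % normalizes each cell by
its predicted-class total, which is the reading consistent with
"26 of 78 genes predicted as storage were truly storage" → 33.3%.
Balanced accuracy is the macro mean over classes of one-vs-rest
(sensitivity + specificity)/2 — note this differs from scikit-learn's
`balanced_accuracy_score` (macro recall). AUC-ROC is binary for
two-class models and macro one-vs-rest otherwise.

## Positional profiles and coverage

Profiles count genes (not occurrences) with ≥1 hit starting inside each
50 bp window over −3000..+2000, for the gene set and for all genes;
the reported curve is their ratio with 0/0 → 1 and x/0 → ∞ flagged.
Hits are assigned to windows by match start. Coverage bins use ratio-
scale fold-change edges {0.2, 0.5, 0.66, 1.5, 2, 3, 5} — reconstructed
from the induced-over-5-fold / suppressed-under-0.2 reporting levels —
and report per-bin percentages of genes whose −500..+150 window carries
the motif.

## Flowchart model

The YES/NO flowchart is a CART tree (Gini impurity, max depth 5, min
leaf 10) over binary presence features; 0/1 features make every split
read "motif present/absent". Node compositions and parent fractions
are recomputed from the genes actually routed through each node, so the
flowchart is an exact summary of the fitted tree, and the leaf mixture
reproduces the root composition to rounding. Compositions are meant to
be read on a class-balanced (undersampled) training set where every
class holds 20%. The branch composition statistic
(p_type_in_branch × p_all_in_branch)/(p_type_overall/p_all_overall)
is reported raw (it can exceed 100%).

## Determinism and problem sizes

Every stochastic step takes an explicit integer seed into
`numpy.random.default_rng`; XGBoost runs single-threaded with
`tree_method="hist"` and a fixed seed, so datasets, selections and
reports are bit-identical across runs. Default problem sizes — 1500
genes for the study conditions, 2000 genes (400-gene regulons) for
discovery experiments, 10–20 seed replicates for recovery checks — were
chosen as the smallest sizes at which the recovery statistics are
stable, keeping a full test run in a few minutes on one CPU.

## Known limitations

- The i.i.d. background understates k-mer count variance relative to
  real promoters; enrichment p-values on real data need the random-
  background option or an empirical null.
- Fixed k = 4 modules; dynamic tree cut is not implemented.
- Motif widths are limited to ≤ 12 for exact enumeration; no gapped or
  spaced motifs.
- One TSS per gene; isoform-level windows are out of scope.
- The flowchart reports training compositions; its cross-validated
  accuracy should be read from `fit_and_evaluate` on held-out folds.
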