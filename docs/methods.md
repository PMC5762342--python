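# Methods

`lncdys` implements a dysregulation-network analysis of lncRNA–protein-coding
gene (PCG) co-expression in a two-group (cancer vs normal) bulk RNA-seq
cohort, together with the downstream survival and diagnostic-panel machinery
and a synthetic cohort generator that makes every stage testable offline.
This note records the models, the defaults and why, the numerical choices,
and what the synthetic benchmarks do and do not demonstrate.

## Expression representation and gene classing

Expression is carried as RPKM (reads per kilobase of transcript per million
mapped reads): `count / (length/10^3) / (library_size/10^6)`. Gene length is
taken from the annotation table as given; collapsing multi-transcript genes
to a single length is considered upstream of this package. Genes are classed
from their annotated biotype: `protein_coding` → PCG; any other biotype is
non-coding and becomes lncRNA only when the transcript is strictly longer
than 200 nt and the biotype is not a small/housekeeping RNA class
(`rRNA, tRNA, miRNA, snoRNA, snRNA, misc_RNA` by default); everything else
is excluded. The 200 nt boundary is strict: a 200 nt transcript is excluded.

## Differential expression with a zero-ratio test switch

Low-abundance genes are often undetected (read count = 0) in many samples,
which makes a mean-difference test inappropriate. Per gene:

* if the zero fraction of read counts exceeds 30% in **either** group
  (strictly greater), the gene is tested as a binary detected/undetected
  contrast with a two-sided Fisher's exact test; significance requires
  Benjamini–Hochberg FDR < 0.01;
* otherwise a pooled-variance Student's *t* test on RPKM is used
  (df = n₁ + n₂ − 2), with FDR < 0.05.

Each gene is tested by exactly one family, and BH adjustment runs within
each family separately (the two families carry different FDR thresholds, so
pooling them would make the thresholds incoherent). Every significant call
additionally requires a ratio fold change above 2, where
FC = (max mean + ε) / (min mean + ε) with ε = 0.01 RPKM guarding zero means
(FC ≥ 1 by construction; the direction is carried separately). Degenerate
*t* inputs (zero pooled variance) use the convention p = 1 for equal means
and p = 0 otherwise.

## Per-condition co-expression and the dysregulation contrast

Within one condition, a lncRNA–PCG pair is co-expressed when the Pearson
correlation of the two RPKM profiles satisfies |r| ≥ 0.7 (inclusive) with
two-sided p < 0.001 (strict), p from t = r·√((n−2)/(1−r²)) on n−2 df. The
p threshold is applied to the raw correlation p without multiple-testing
correction — the cutoff pair is the analysis's identity, not an inference
claim. Pairs with a constant gene in a condition are skipped (not errors):
zero-inflated lncRNAs are commonly all-zero in one condition. The lncRNA
side is restricted to differentially expressed lncRNAs; the PCG side is
selectable among nested universes (all PCGs; DE PCGs; DE PCGs on a
user-supplied cancer-gene list).

Contrasting the two conditions' pair sets partitions every pair key into
Type I (present in normal only — lost), Type II (cancer only — gained),
Type III (positive → negative), Type IV (negative → positive), or retained
(same sign in both, not dysregulated). Two identities hold on any input and
are enforced by tests: |normal| = I + retained + III + IV and
|cancer| = II + retained + III + IV. Summary percentages (cancer:normal
pair ratio, dysregulated share of the pair-key union) are rounded half-up
to two decimals for parity with conventional reporting.

Scale-free structure is described, not tested: the degree histogram over
all nodes is fitted by OLS of log₁₀ count(k) on log₁₀ k and the negated
slope and R² are reported. Maximum-likelihood power-law fitting would be
the inferential alternative and is deliberately out of scope.

## Sub-module mining

Edges are ranked by the edge clustering value
ECV(u,v) = w·|N(u)∩N(v)|² / (|N(u)|·|N(v)|) with w = |r| of the defining
condition. A lncRNA–PCG network is bipartite, so the common-neighborhood
term is identically zero; the ordering then falls back to edge weight,
then to cycle support (triangles + quadrilaterals through the edge), then
to lexicographic endpoint ids. The cycle-support tie-break exists so that
bridge edges — which lie in no short cycle — sort after the block-internal
edges they connect; without it, uniform-weight graphs would be processed
in an order that lets a bridge be absorbed before either block is formed.

Clusters grow over the sorted edges with a union–find: a merge of two
endpoint clusters is accepted when the merged cluster is a λ-module
(total within-cluster degree strictly greater than λ × boundary degree,
λ = 1 by default) or when it strictly raises the in/out-degree ratio above
both components'. Two clusters that are each already λ-modules never merge;
this freeze is what keeps two dense blocks joined by a bridge apart. The
aggregate (cluster-total) form of the λ condition is a deliberate design
choice: a per-vertex form can never grow a cluster out of a single edge
inside a dense block, because early members still have most of their
neighbors outside. Modules need ≥ 3 nodes (one edge is not a module), are
node-disjoint by construction, and the whole procedure is deterministic
under edge- and node-insertion order.

## Risk stratification and survival

How a sub-module's expression defines patient risk groups is an
interpretive choice (no canonical rule exists): we z-score each member
across patients, cluster patients into two groups with Ward-linkage
hierarchical clustering on Euclidean distance, and label "high" the group
with the lower Kaplan–Meier survival at the last time point common to both
groups. Members constant across patients are dropped with a warning; a
fully degenerate matrix is an error. The pipeline feeds log2(RPKM + 1)
into the split — on the linear scale, lognormal spread lets a single
extreme sample dominate Euclidean distances. Each mined module is tested
this way and the module with the strongest log-rank separation carries
forward to the panel stage; with several candidate modules this selection
is exploratory, not a controlled test. Survival curves use the standard
product-limit estimator (deaths before censorings at tied times); group
separation uses the one-degree-of-freedom log-rank test.

## ROC machinery and the three-zone panel

AUC is the trapezoid area over all threshold steps, identical to the
normalized Mann–Whitney U statistic with ties counted one half (a property
the tests verify against a brute-force pairwise oracle). Operating cutoffs
maximize the Youden index J = sensitivity + specificity − 1 over midpoints
between adjacent distinct scores (plus outer sentinels); ties in J break
toward higher specificity, then lower cutoff — midpoints make the cutoff
deterministic and robust to which side of an observed value a future
sample falls. The AUC confidence interval is the DeLong
structural-components variance with a normal approximation, truncated to
[0, 1]; a degenerate variance (perfect separation) yields a point interval
with a warning.

A three-zone panel assigns each marker two RPKM cutoffs: the Youden cutoff
of normal vs all-cancer (`low_cutoff`) and of low-risk vs high-risk
(`high_cutoff`); the marker's direction comes from the sign of the
cancer-vs-normal mean difference. For an up-marker the zones run
normal ≤ low_cutoff < low-risk ≤ high_cutoff < high-risk; for a
down-marker the order reverses. Cutoffs that cross flag the marker
ambiguous and exclude it. A sample is zoned per marker (a value exactly at
a cutoff falls into the lower-risk zone) and the overall call is the
unweighted majority across markers, ties → indeterminate. Majority voting
with equal weights was chosen over down-weighting "accessory" markers:
with panels of ~4 markers any fractional weighting is underdetermined.

## Synthetic cohort generator

The generator emulates the cohort structure the pipeline assumes, with
defaults fixed at the study conditions: 505 cancer and 59 normal samples;
lncRNA baseline abundance at 0.1× the PCG baseline (log₂ means 5 and
5 + log₂0.1, SD 2); per-gene biological spread 0.8 log₂ units; counts
Poisson around expression × (length/10³) × (depth/10⁶) at a mean depth of
2×10⁷ with 0.15 log-normal depth spread; dropout (count forced to 0) with
probability exp(−RPKM/τ), τ = 2 RPKM, chosen so that lncRNA zero fractions
straddle the 30% switch and both test branches are exercised. Planted DE
genes (50 PCGs and 40 lncRNAs each way by default) shift the cancer mean
by a factor of 4.

Co-expression is planted through latent factors: members of a block get
z = loading·F + σ·ε on the log scale (loading 0.9, σ 0.3, expected pair
correlation loading²/(loading²+σ²) = 0.9). A block active only in normal
plants Type I pairs; only in cancer, Type II; blocks active in both with
PCG loadings negated in one condition plant Type III/IV. Because lognormal
marginals attenuate *negative* correlations on the linear RPKM scale
(at spread 0.55 nat-log units a latent −0.9 realizes ≈ −0.66), the
sign-flip blocks use a tighter spread (0.4 log₂ units) so planted |r|
stays above the 0.7 cutoff; this asymmetry is a genuine property of
lognormal expression, not an artifact. Block members are planted DE so
they survive the DE-restricted co-expression universes, and are given
dropout-safe abundance so planted correlations are not eroded by zeros.

The cancer-active ("gained") block doubles as the risk module: its factor
is bimodal (±1 + N(0, 0.35), equal mixture), the planted risk label is the
mixture component, and survival is exponential with hazard
h₀·exp(β·score), h₀ = 1/1500 days⁻¹ and β = ln2/2 (hazard ratio ≈ 2
between the planted groups). Censoring is Bernoulli at rate 0.6 per
patient, with censored times uniform on (0, T); this keeps the realized
censoring fraction controlled by construction.

What the generator does **not** emulate: batch effects, tumor purity
mixtures, library-preparation biases, overdispersed (negative-binomial)
counts, correlated null genes outside planted blocks, and non-exponential
hazards. Passing the recovery benchmarks therefore shows the pipeline's
statistics behave as designed under a clean generative model, not that the
thresholds are optimal for any particular real cohort.

## Problem sizes and determinism

The default gene universe is 1000 PCGs + 500 lncRNAs + 20 small-RNA genes —
a deliberately desk-scale stand-in for a full annotation (tens of
thousands of genes), chosen so the end-to-end suite and the acceptance
script re-run in seconds; all statistics scale to full annotations
unchanged. One integer seed determines the whole cohort and hence the
whole run; re-running an identical config is bit-reproducible
(checksummed in the run manifest).

## Known limitations

* Per-condition pair calling applies the published fixed cutoff without
  multiple-testing correction across the pair universe, faithfully to the
  method it implements; at ~10⁵–10⁶ candidate pairs the expected number of
  chance calls is nonzero (the null-pair benchmark quantifies it).
* The λ-module merge rule is a documented reconstruction of an
  edge-clustering agglomeration for the bipartite case; it is not claimed
  to replicate any particular plugin's output.
* DeLong intervals undercover near AUC = 1 (variance collapses); the
  coverage benchmark runs at a moderate effect size where the normal
  approximation holds.
* The three-zone panel's majority vote treats markers symmetrically and
  ignores inter-marker correlation.
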