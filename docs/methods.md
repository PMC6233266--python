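# Methods

## The screening model

The package classifies genes by intersecting three binary evidence layers,
each derived from its own assay type, for two transcription factors (p53,
encoded by *TP53*, and the RelA/p65 subunit of NF-κB, encoded by *RELA*):

- **Expression modulation.** Gene-level read counts over a
  {control, 4 Gy, 10 Gy} × {siCTR, siRELA, siTP53} × replicates design are
  normalized with classical median-of-ratios size factors: for sample *j*,
  `s_j = median over genes g of K_gj / geomean_j(K_gj)`, restricted to
  genes with all-positive counts. The geometric mean of the factors is not
  rescaled to 1. Low-signal genes are removed when their maximal normalized
  value is not strictly above the grand median of all gene × sample cells
  (grand median rather than per-sample medians; the alternative reading is
  noted under open choices). Differential calls use the mean-based fold
  change on the normalized scale and a classical equal-variance Student
  t-test on log2(x+1) values — the log transform stabilizes the variance of
  overdispersed counts, and the equal-variance form matches the named test.
  A gene is modulated when either dose passes FC > 1.5 or < 0.67 with raw
  p < 0.05 (no multiple-testing correction at this stage, by design of the
  screen: the thresholds are deliberately moderate because candidates are
  re-validated downstream). Doses significant in opposite directions are
  recorded as conflicts and excluded from both sets.

- **Enhanced binding.** The putative regulatory region is the symmetric
  window TSS ± 3000 bp, 0-based half-open, clipped at contig ends, and
  strand-agnostic (strand is kept only for upstream/downstream labelling).
  A peak is assigned to the gene with the nearest TSS provided the summit
  lies inside that gene's window; equidistant ties break to the smaller
  gene id. Enhancement is decided from region read counts with a one-sided
  binomial test of the treated count against n = treated + control and
  success probability equal to the treated library share — conditioning on
  the total makes the test exact and free of a rate nuisance parameter. It
  replaces read-pileup-level peak-caller statistics because this artifact
  consumes region counts, not alignments; the decision layer (BH correction
  per TF × timepoint at FDR 0.05, gene flag = OR over peaks, either-timepoint
  flag = OR over 2 h/4 h) is the part that defines the screen.

- **Silencing effect.** The ratio of mean normalized expression
  siTF / siCTR under stimulation, per dose; a gene is inhibited by the
  knockdown when the ratio is < 0.67 at either dose, stimulated when
  > 1.5. The rule is ratio-only — no p-value — with an informational
  t-test available. Ratios crossing both thresholds across doses are
  conflicts, direction none.

A gene is **TF-dependent** when modulated AND bound (either timepoint) AND
silencing-affected, for that TF; the co-regulation **mode** of a
dual-dependent, radiation-upregulated gene follows from the two silencing
directions (both inhibited → coactivated; opposite → antagonistic,
sub-labelled by the activating factor; both stimulated → corepressed).
Mode assignment is defined only for upregulated genes; downregulated genes
are classified but left unclassified for mode.

For bench validation data the package provides relative qPCR
quantification: per-replicate ΔCq = target Cq − arithmetic mean of
reference-gene Cq (equal to the geometric mean of the linear quantities),
fold change 2^(ΔCq_control − ΔCq_test), p from a two-sample t-test on the
ΔCq sets. The fold change is invariant to a constant Cq offset.

## Motif scanning

PWMs are built from aligned sites with a 0.25 pseudocount per base;
ambiguous N positions spread unit mass uniformly. Scanning scores each
window as the sum of per-position log2 odds against the background
(default: the scanned sequence's own composition). Exact p-values come
from the discretized score distribution: per-position log-odds are shifted
by their minima and scaled to at most `granularity` (default 1000) integer
bins over the full range, and the null probability mass function is built
by convolving one position at a time under the background; the tail of
that distribution gives P(score ≥ s). At the default granularity the
relative p-value discretization error is well below 1e-3 for typical
motif widths, and tests verify exact agreement with full enumeration over
all 4^w words at widths ≤ 6. Both strands are scanned; minus-strand hits
are reported at their forward-strand coordinates, and windows containing N
score the N positions at log-odds 0.

## GO-term clustering

Gene annotations are expanded to all is_a/part_of ancestors, then terms
annotated to fewer than two genes of the reference set are dropped. Wang
semantic similarity scores a term pair by its shared ancestors: within a
term's ancestor DAG, an ancestor's S-value is the maximum over descending
paths of the product of edge weights (is_a 0.8, part_of 0.6 — the
weights of the original G-SESAME formulation), and
sim(A,B) = Σ_{t∈common}(S_A(t)+S_B(t)) / (SV(A)+SV(B)). Terms are
clustered per namespace by average-linkage agglomerative clustering on
1 − similarity with the tree cut into k = 20 clusters (k capped at the
term count); average linkage is a deliberate choice where only
"hierarchical clustering" is specified, and both the linkage and the
per-namespace k are configurable. Per cluster, a subset's contribution is
the percentage of its genes annotated to at least one member term, and
subset differences are tested with the two-sided Fisher exact test on the
2 × 2 table (subset × annotated-to-cluster).

## The synthetic-data generator

The generator emulates the study design so every stage is testable
offline: a single random contig with non-overlapping gene loci spaced so
each TSS ± 3000 bp window is in-bounds; negative-binomial counts
(dispersion 0.05, base means log-uniform in [20, 5000] — values that keep
a t-test workable at 3 replicates while spanning a realistic dynamic
range) over the full design; candidate peak regions with Poisson read
counts (4× treated/control enrichment for bound genes, and background
peaks at rate 0.1 per unbound gene × TF × timepoint so the FDR layer sees
true nulls); and consensus binding sites written into bound genes'
windows.

The effect model is log-additive: each gene carries a p53 and an NF-κB
log2 component whose sum is the planted IR response; silencing an arm's TF
multiplies that TF's component by the residual activity (default 0.2,
matching knockdown to 10–30% of initial levels), and antagonistic classes
give the repressing TF a negative component. Planted magnitudes (single-TF
activation U(1.2, 2.5) log2 at 10 Gy, 4 Gy scaled by U(0.5, 0.85);
coactivated components U(1.0, 1.8) each; antagonistic repression
U(1.0, 1.4) with activation exceeding it by U(0.8, 1.5)) sit inside the
fold-change and ratio ranges observed for real candidate genes, and each
non-null class takes 2% of genes by default. Replicate count defaults to
3 per condition — a choice, since typical RNA-seq designs of this kind use
2–3 replicates — and all sampling is driven by a single integer seed, so
every output file is byte-reproducible.

Degenerate consensus positions are resolved toward a canonical word
(classical κB site GGGACTTTCC; p53 half-site GGGCATGTCC) with probability
0.7 rather than uniformly: genomic binding sites cluster around a
preferred word, which is precisely the structure a PWM scanner exploits —
maximal-entropy resolutions of GGGRNNYYCC would have exact p-values
(~1.2e-4) sitting just above the default 1e-4 scan threshold, i.e. they
would model sites no scanner is meant to find.

What the generator does *not* emulate: read-level data (no FASTQ, no
fragment-length or shift model), GC or mappability bias, correlated
replicates, batch effects, off-target siRNA effects, or TF binding without
an expression consequence beyond the background peak rate. Passing the
recovery tests therefore demonstrates internal consistency of the decision
rules under the stated noise model, not performance on real sequencing
data.

## Numerical and degenerate-input choices

- Zero reference means (fold change, silencing ratio) yield missing values
  with a warning rather than infinities; both-counts-zero binding tests
  return p = 1; zero-variance t-tests report p = 1.
- All genomic coordinates are 0-based half-open; a summit exactly 3000 bp
  from the TSS is inside the window, 3001 bp is not.
- Cluster labels are canonicalized by first appearance so permuting input
  order yields the identical partition.
- Threshold comparisons are strict (> 1.5, < 0.67, p < 0.05, signal >
  median), so boundary values never pass.

## Known limitations

- The binomial rate-ratio test ignores biological replication of ChIP
  libraries (region counts are single treated/control pairs).
- The screen's expression stage uses raw p-values by design; its type-I
  behaviour is calibrated (tests assert 0.05 ± 0.01 under the null) but
  genome-wide candidate lists will contain the corresponding false
  positives, as in any moderate-threshold screen.
- Wang similarity is quadratic in the number of terms; the implementation
  targets the few-hundred-term scale of a screen's annotation set, not a
  full ontology release.
- Hierarchical clustering of near-tied distances can be linkage-order
  sensitive; the packaged tests use well-separated structures, and k, the
  linkage and the edge weights are exposed as parameters.
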