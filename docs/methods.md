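# Methods

## The chromatin signature model

In a polyclonal cell population, a gene with clone-specific monoallelic
expression is transcribed in some cells and Polycomb-silenced in others, so
bulk ChIP-seq shows *both* H3K36me3 (deposited co-transcriptionally across
gene bodies) and H3K27me3 (the repressive mark) over the same gene body.
Expressed biallelic genes show high K36 / low K27; silent genes low K36.
The package reduces each gene to two numbers — the input-normalized
gene-body signal of each mark — and learns the boundary between the
biallelic and MAE clusters from labeled examples.

### Feature definition

For gene *g*, region *R* (gene body = full genomic span TSS→transcript
end, or the 2.5 kb proximal promoter upstream of the TSS, strand-aware and
clipped at position 0) and mark *m*:

    f(g, m, R) = log2( (Σ_R signal_m + c) / (Σ_R signal_input + c) ),  c = 1

The sums are raw per-base signal totals over the interval; no length
normalization is applied, since both numerator and denominator cover the
same interval and the log ratio cancels first-order length effects. The
pseudocount *c* = 1 keeps features finite when either track is empty over
the region; a cell is *missing* only when mark and input are both exactly
zero (no data at all), and such genes are dropped from training. The log
base is 2 by default and configurable to 10; the choice shifts features by
a constant factor and is immaterial to the tree, whose thresholds are
learned in the same scale.

When two datasets come from different labs or platforms, per-column
quantile normalization maps one feature matrix onto a reference: each value
is replaced by the reference column's empirical quantile at its
(tie-averaged) rank, linearly interpolated between reference order
statistics.

### The alternating decision tree

The classifier is a Freund–Mason ADTree: a root prediction value plus an
ordered list of rules, each rule = (precondition node, `feature >
threshold`, value-if-true, value-if-false). An instance's margin is the
root value plus every prediction value it traverses along *all* satisfied
paths; margin > 0 calls MAE. Training is boosting:

* weights start at 1, with BAE weights multiplied by the false-positive
  cost ratio (1.0 "Neutral", 8.0 "Precision");
* the root value is ½·ln(W₊/W₋), after which all weights are updated by
  w ← w·exp(−y·value);
* each of the (default 10) iterations scans every existing prediction node
  as a precondition ("expand all paths"), every feature, and every
  threshold midway between consecutive distinct observed values within the
  precondition subset, minimizing
  Z = 2[√(W₊ᵗW₋ᵗ) + √(W₊ᶠW₋ᶠ)] + W(precondition unmet);
* new prediction values are ½·ln((W₊+ε)/(W₋+ε)) with ε = 1 (smoothing
  keeps values finite on pure subsets and, because it shrinks each value
  toward zero from the unsmoothed optimum, preserves the monotone decrease
  of the boosting objective);
* ties in Z are broken toward the smaller precondition node index, smaller
  feature index, then smaller threshold, making training fully
  deterministic — the recorded seed is provenance only.

Missing feature values: instances are dropped (and counted) at training;
prediction raises by default, with optional median imputation from the
training medians stored in the model.

Evaluation is repeated stratified K-fold cross-validation (default 10
folds × 10 repeats with distinct seeded shuffles), pooling confusion counts
and reporting the F-measure of the MAE class. Feature screening uses
information gain over an equal-frequency discretization (default 10 bins)
followed by greedy forward selection on cross-validated F; this replaces a
correlation-based subset search with a simpler, testable procedure that
arrives at the same two gene-body features on synthetic data.

Genome-wide prediction covers every gene with evidence of transcription:
genes with RPKM < 0.1 are reported as silent and excluded from calls.

## Allele-specific validation statistics

Counts at heterozygous positions are Bernoulli trials with parameter p
(0 = all allele b, ½ = balance, 1 = all allele a). Per unit (gene, or SNP
when phasing is unavailable) and sample:

* **bias**: exact two-sided binomial test against p = ½, using the
  doubled-smaller-tail convention (symmetric in the two alleles; the
  minimum-likelihood convention is noted but not default), BH-adjusted
  within one analysis batch; a call additionally requires the MLE to show
  at least 2:1 skew (p̂ ∉ [⅓, ⅔]), filtering statistically significant but
  biologically weak imbalances at high coverage;
* **equivalence**: TOST with two exact one-sided binomial tests against
  the boundary values p = ⅓ and p = ⅔ at α = 0.05 per side (no FDR on
  equivalence p-values); both must reject;
* categories are mutually exclusive: below-threshold (coverage under 10
  for RNA-seq gene units, 100 for targeted SNP units), biased, unbiased,
  indeterminate. A unit with p̂ pinned at exactly ⅔ is never called
  unbiased at any coverage — the band is open at the boundary.

The 2:1 fold is configurable (e.g. 3:1); with fold ≥ 1 and a shared α the
biased and unbiased conditions are provably disjoint, which the code
asserts. gDNA controls are called with the same machinery; an assay is
retained only if its gDNA is positively unbiased in every sample where it
is testable. Clone-level status: biased in ≥ 1 clone → MAE-consistent;
unbiased in ≥ 1 clone and biased in none → unbiased; otherwise
inconclusive; opposite bias directions between clones are flagged, being
the hallmark separating clone-specific MAE from imprinted or cis-regulatory
skew (which keep one direction).

Group summaries use the 50–100 major-allele scale
(100·max(nₐ,n_b)/(nₐ+n_b)), irrespective of parental origin. Control sets
are matched to the target genes' histogram over 0.1-log₁₀-RPKM bins,
sampled without replacement, borrowing from the nearest non-empty bin on
shortfall (logged). Fisher enrichment uses the two-tailed probability-mass
rule; Kruskal–Wallis uses the tie-corrected H with a χ² (df = groups−1)
p-value; cumulative-discovery curves enumerate all cell-line orderings up
to 7 lines and sample 1000 seeded permutations beyond.

## The synthetic-data generator

`SimulationConfig` defaults define the study conditions: 10,000 genes, 13%
MAE among expressed autosomal genes, 30% silent, 2 clones, per-clone
monoallelic probability 0.85 (so MAE genes are biallelic in some clones),
50 X-linked and 20 imprinted genes, mean coverage 100× (cDNA, ChIP) and
500× (gDNA), monoallelic allele fraction 0.95.

* **Truth**: RPKM is lognormal (10^N(0.8, 0.7) expressed, silent capped
  below 0.1); each MAE gene draws an active allele per clone; X-linked
  genes share each clone's X-inactivation direction; imprinted genes keep
  one direction across clones.
* **Tracks**: 10 kb constant-step gene bodies on a synthetic assembly
  (`chrS` + `chrX`) over a uniform input of 1.0, so the recomputed log2
  feature equals the class's Gaussian draw. Cluster means (K36, K27):
  BAE (2.5, −1.0), MAE and the X-linked/imprinted controls (2.0, 1.5),
  silent (−1.5, ±1.0 bimodal), SD 0.8. These place the MAE and BAE
  clusters ≈3 SD apart in the K27 axis — clearly separated but
  overlapping, which keeps classification non-trivial and puts end-to-end
  recovery in a realistic high-70s/low-90s sensitivity band rather than at
  a degenerate 100%.
* **Counts**: coverage ~ Poisson(mean × RPKM / mean expressed RPKM); gDNA
  coverage is expression-independent. Allele splits are Binomial at 0.5
  except monoallelic states, where cDNA and H3K36me3 reads favor the
  active allele at 0.95 and H3K27me3 mirrors toward the silenced allele.
  The 0.95 (not 1.0) models partial silencing. An optional beta-binomial
  overdispersion ρ (default 0) widens allele-fraction spread.

What the generator does *not* emulate: mapping/reference bias, read-level
sequencing error, correlated coverage along genes, copy-number variation,
inter-gene signal spill-over, and realistic genome sequence. Tests passing
on this generator therefore demonstrate the correctness and calibration of
the algorithms under the stated model, not robustness to those real-data
artifacts, which the surrounding experimental pipeline must handle
upstream.

## Numerical and design choices

* Coordinates are 0-based half-open internally; wiggle and GTF converters
  live only in `genome_io`.
* Gene span from GTF is the full genomic span (min start to max end over
  records), not the exon union — the signature integrates introns too.
* AST-seq demultiplexing matches barcode pairs and flanking sequence
  exactly; reads whose SNP base is neither expected allele are discarded
  but counted, and assigned + discarded + unmatched always equals the
  input total.
* Serialized models are versioned JSON; identical data and seed give
  byte-identical files.
* Problem sizes in tests and the acceptance script (2,000-gene fixtures
  for unit tests, ten 1,500-gene datasets for the cost-tradeoff
  comparison, one 10,000-gene genome for end-to-end recovery, 10⁴ null
  genes at coverage 1000 for calibration) were chosen as the smallest
  sizes at which the binomial/Monte-Carlo error bands in the assertions
  are decisively narrower than the effects being demonstrated.

## Known limitations

* The classifier is deliberately minimal (two features by default); marks
  beyond the eight-mark vocabulary need `allow_extra_marks`.
* Cross-SNP tallying requires phased (mat/pat) counts; unphased ref/alt
  data are analyzed per SNP.
* The equivalence test is exact but conservative at the boundary; with
  2:1 boundaries, positive equivalence calls need roughly ≥ 40 reads.
* No probability calibration of margins; the decision boundary is fixed
  at 0 and cost sensitivity is exercised only through training weights.
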