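# maesig

Predicting autosomal **monoallelic expression (MAE)** from a gene-body
chromatin signature, with the allele-specific statistics needed to validate
the predictions in clonal cell lines.

## The problem

A sizable minority of autosomal genes are expressed from only one allele,
with the active allele chosen stochastically but mitotically stably per
clonal lineage. Detecting MAE directly requires allele-resolved RNA-seq in
single-cell-derived clones — expensive, and blind to genes without
transcribed heterozygous SNPs. In a *polyclonal* sample, however, an MAE
gene carries both the active-transcription mark **H3K36me3** (from cells
expressing allele A) and the Polycomb silencing mark **H3K27me3** (from
cells silencing it) across the same gene body. That co-occurrence is a
signature that ordinary ChIP-seq can see without any allele resolution.

`maesig` implements that idea end to end:

1. **Features** — for each gene, ChIP signal is summed over the gene body
   (and optionally the 2.5 kb proximal promoter) and normalized to the
   input/WCE track as `log2((mark + 1) / (input + 1))`.
2. **Classifier** — an alternating decision tree (ADTree) trained by
   boosting on the two gene-body features, with a cost-sensitive
   "Precision" mode (8:1 false-positive penalty) alongside the default
   "Neutral" (1:1) mode. The margin of a gene is the sum of the prediction
   nodes along every satisfied root-to-leaf path; margin > 0 calls MAE.
   Genes with RPKM < 0.1 are silent and never called.
3. **Validation statistics** — allelic counts at heterozygous SNPs are
   tested per clone: an FDR-corrected exact binomial test plus a ≥2:1
   skew filter calls *biased*; a TOST equivalence test with boundaries at
   the 2:1 MLE values (0.33 / 0.67) calls *unbiased*; everything else is
   *indeterminate*. gDNA controls filter out amplification-biased assays,
   and clone-level aggregation flags the direction switches that
   distinguish clone-specific MAE from imprinting.
4. **Cohort statistics** — mean allelic bias per prediction group with
   expression-matched control sets, Kruskal–Wallis tests of ChIP allelic
   bias across cDNA bias classes, Fisher enrichment, Jaccard similarity of
   MAE sets across cell types, cumulative-discovery curves, and
   bivalent-gene overlap fractions.
5. **Synthetic data** — a seeded generator that plants a known truth
   (classes, per-clone active alleles, coverage) and emits tracks, gene
   models, expression and count tables, so the whole pipeline is testable
   without external downloads.

## Worked example

```python
import numpy as np
from maesig import SimulationConfig, simulate_truth, simulate_tracks, build_feature_matrix
from maesig.adtree import TrainingSet, train_adtree, predict_genome, cross_validate

cfg = SimulationConfig(seed=1, n_genes=2000)
truth = simulate_truth(cfg)
tracks, input_track, genes = simulate_tracks(truth, cfg)
features = build_feature_matrix(tracks, input_track, genes)

labels = {g: c for g, c in truth["class"].items() if c in ("MAE", "BAE")}
data = TrainingSet.from_labels(features, labels)
report = cross_validate(data, folds=10, repeats=3, seed=1)
print(f"CV: precision={report.precision:.3f} recall={report.recall:.3f} F={report.f_measure:.3f}")

model = train_adtree(data, iterations=10, cost_ratio=1.0, seed=1)
calls = predict_genome(model, features, dict(truth["rpkm"]))
n_mae = (calls["call"] == "MAE").sum()
n_called = calls["call"].isin(["MAE", "BAE"]).sum()
print(f"predicted MAE: {n_mae}/{n_called} expressed genes")
```

prints

```
CV: precision=0.866 recall=0.797 F=0.830
predicted MAE: 298/1418 expressed genes
```

i.e. ten-fold cross-validation on the labeled genes reaches F ≈ 0.83, and
298 of the 1418 expressed genes carry the MAE chromatin signature (the
planted MAE genes, plus the X-linked and imprinted genes that genuinely
share the signature, plus classifier false positives). Validating those
calls against the simulated per-clone cDNA counts:

```python
from collections import Counter
from maesig.allelic_bias import call_bias_batch, clone_level_mae_call
from maesig.cohort_stats import enrichment_fisher
from maesig.synthetic import simulate_counts

cdna = [r for r in simulate_counts(truth, cfg) if r.source == "cDNA"]
by_gene = {}
for c in call_bias_batch(cdna, min_coverage=10):
    by_gene.setdefault(c.unit_id, {})[c.sample_id] = c
status = {g: clone_level_mae_call(v)[0] for g, v in by_gene.items()}
print(Counter(status.values()))

pred_mae = set(calls.index[calls["call"] == "MAE"])
biased = {g for g, s in status.items() if s == "MAE-consistent"}
odds, p = enrichment_fisher(biased, pred_mae, set(by_gene))
print(f"OR={odds:.1f}, p={p:.2e}")
```

```
Counter({'inconclusive': 878, 'unbiased': 413, 'MAE-consistent': 202})
OR=78.1, p=5.92e-123
```

Genes with clone-level allelic bias are overwhelmingly concentrated among
the genes the chromatin classifier predicted as MAE.

The same workflow is available from the shell:

```bash
maesig simulate --seed 7 --n-genes 2000 --outdir fixtures/
maesig features --marks H3K36me3=fixtures/H3K36me3.bedgraph \
                --marks H3K27me3=fixtures/H3K27me3.bedgraph \
                --input fixtures/input.bedgraph --genes fixtures/genes.bed \
                --track-format bedgraph -o features.tsv
maesig train --features features.tsv --labels fixtures/labels.tsv --seed 1 -o model.json
maesig predict --model model.json --features features.tsv \
               --rpkm fixtures/expression.tsv -o calls.tsv
maesig bias --counts fixtures/counts.tsv --source cDNA --min-coverage 10 -o bias.tsv
maesig clone-call --calls bias.tsv -o clone_status.tsv
```

## Layout

| module | contents |
| --- | --- |
| `maesig.genome_io` | BED/GTF gene models, wiggle/bedGraph tracks, TSV tables, AST-seq FASTQ demultiplexing |
| `maesig.chromatin_features` | signal integration, promoter intervals, log-ratio features, quantile normalization |
| `maesig.adtree` | ADTree boosting, cross-validation, info-gain ranking, forward selection, genome-wide prediction |
| `maesig.allelic_bias` | binomial bias test, BH FDR, TOST equivalence, categories, gDNA filter, clone-level calls |
| `maesig.cohort_stats` | group bias, matched controls, KW association, Fisher, Jaccard, cumulative curves |
| `maesig.synthetic` | seeded truth/track/count generator |
| `maesig.cli` | `maesig` command-line entry point |

See `docs/methods.md` for the model, parameter defaults, and limitations.
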