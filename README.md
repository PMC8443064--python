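# epm — expression prediction from enhancer and promoter histone marks

`epm` is a pipeline for quantifying how well histone-modification levels at
*enhancers*, as opposed to promoters, predict the expression of their target
genes. It covers the full analysis chain used in regulatory epigenomics for
this question:

1. **Chromatin-state post-processing** — a state-labelled segmentation (e.g.
   a 9-state ChromHMM track over H3K4me3/H3K4me1/H3K27ac/H3K27me3) is
   coalesced, its state-transition enrichment matrix is computed
   (observed / expected adjacent transitions along the linear genome), and
   runs of activation-associated states (1–4) or bivalent/poised states
   (6–7) are merged into candidate regulatory regions. Regions shorter than
   600 bp are discarded as background, and contiguous active/poised pairs
   are discarded as ambiguous.
2. **Region classification** — candidates overlapping a window of ±500 bp
   around any transcription start site become active promoters (AP) or
   bivalent promoters (BP); remaining candidates overlapping a p300 peak
   become active enhancers (AE) or poised enhancers (PE). Promoters are
   matched to genes through the same TSS-window rule.
3. **Enhancer–gene association** — an enhancer is linked to the target gene
   of a promoter *of the same chromatin category* (AE–AP, PE–BP) when the
   two regions overlap the two anchors of the same significant chromatin
   contact (optionally restricted to top contacts with FDR = 0 and
   ln p ≤ −100), or, in the distance variant, when they lie closer than
   1 Mb. A one-sided exact binomial test quantifies whether poised
   enhancers contact bivalent promoters more often than chance.
4. **Signal quantification** — per-region signal is the read count
   overlapping the region, scaled per million by library size and averaged
   per bp of region length; the same quantity is computed on genome-wide
   2-kb bins.
5. **Cyclic MA-LOESS normalization** — samples from heterogeneous sources
   are normalized by robust local regression of M = log₂(x₁/x₂) on the
   average log intensity A, cycled over all sample pairs; corrections are
   fitted on genome bins and applied to regions or gene-expression tables.
   Rows containing zeros are discarded before fitting.
6. **Expression models** — ordinary least squares of
   `y = log₂(FPKM + 0.1)` on `x_j = log₂(signal_j + 0.1)` for ten histone
   marks, with genes entering enhancer models once per associated enhancer.
   Performance is the Pearson correlation between predicted and measured
   expression on held-out genes; variable importance is the absolute
   t-statistic of each coefficient; controls shuffle expression over all
   genes; cross-context evaluation trains in one cellular context and
   scores in the others, with paired t-tests against the random models.

Because the original inputs (ChIP-seq, RNA-seq, Hi-C) are large external
datasets, the package ships a first-class **synthetic-data module** that
generates every input with known ground truth — planted region classes,
contact preferences, bias curves, and true regression coefficients — so
every stage is testable end to end on a laptop.

## Worked example

```python
from epm.simulate import SyntheticTruth, gen_signal_expression
from epm.model import (assemble_dataset, split_train_test, fit_linear_model,
                       evaluate, shuffle_expression)

truth = SyntheticTruth(seed=1)          # known beta, sigma set for r* = 0.8
sim = gen_signal_expression(truth, n_genes=2000, seed=2)["c0"]
dataset = assemble_dataset(sim.expression, sim.signal, sim.associations, truth.marks)
train, test = split_train_test(dataset, train_frac=0.8, seed=3)
model = fit_linear_model(train)
result = evaluate(model, test)
print(f"held-out r = {result.r:.3f} on {result.n} genes")
for mark, share in model.shares.sort_values(ascending=False).head(3).items():
    print(f"importance share {mark}: {share:.2f}")
```

prints

```
held-out r = 0.829 on 400 genes
importance share H3K27me3: 0.30
importance share H3K36me3: 0.13
importance share H3K27ac: 0.13
```

The held-out correlation sits at the generator's theoretical value
(r\* = 0.8 up to sampling noise), and the repressive mark H3K27me3 — planted
as the dominant coefficient — carries the largest importance share.
Refitting after shuffling expression over all genes collapses performance
(`random-control r = 0.023` for the same seed), showing the model captures
the planted mark–expression relationship rather than structure in the
predictors.

## Command line

Every stage is exposed under the `epm` command:

```
epm simulate bundle --preset small --seed 11 -o bundle/
epm bins --genome bundle/chrom.sizes --width 2000 -o bins.bed
epm states transitions bundle/segmentation.bed -o transitions.tsv
epm states merge bundle/segmentation.bed -o candidates.bed
epm classify --candidates candidates.bed --tss bundle/tss.tsv \
    --p300 bundle/p300.bed -o regions.bed --gene-map gene_map.tsv
epm link hic --interactions bundle/interactions.bedpe --regions regions.bed \
    --gene-map gene_map.tsv --mode top -o associations.tsv
epm link enrich --interactions bundle/interactions.bedpe --regions regions.bed \
    --enhancer-class PE -o enrichment.json
epm quantify --reads H3K4me3=bundle/reads/H3K4me3.bed --regions regions.bed \
    --library-sizes bundle/library_sizes.json -o signal.tsv
epm normalize fit --table signal.tsv --seed 1 -o norm_model.json
epm normalize apply --model norm_model.json --table signal.tsv -o signal_norm.tsv
epm model fit --expression bundle/expression/ESC.tsv --signal bundle/signal/ESC.tsv \
    --associations bundle/gene_enhancer_links.tsv --seed 2 -o model.json
```

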