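# chromexpr

Accessibility-augmented sequence-to-expression modelling for single-cell
multiome data.

Promoter DNA sequence alone is a weak predictor of a gene's expression in a
particular cell type, because most of the cell-type specificity lives in
chromatin state rather than in the 2 kb around the TSS. `chromexpr`
implements a simple, architecture-agnostic augmentation: supply the cell
type's pooled ATAC-seq coverage over the promoter window as a **fifth input
channel** of a 1D convolutional network, next to the four one-hot DNA
channels, and predict **GEx** — the fraction of cells of the type with a
nonzero UMI count for the gene, a probability in [0, 1].

The package is aimed at regulatory-genomics researchers who want to train,
ablate and interpret such models: it contains the full data pipeline
(promoter extraction from FASTA+GTF; fragment-file → smoothed, per-cell-type
min-max-normalized ATAC tracks; GEx from Matrix Market UMI counts), the CNN
itself with channel ablation and parameter accounting, gene-holdout
cross-validation with seed ensembles, input-scrambling controls,
fine-tuning from DNA-only weights, completeness-exact attribution against
dinucleotide-preserving shuffled backgrounds, k-mer attribution ranking
with cross-cell-type Jaccard comparison, and a ground-truth synthetic
multiome generator that makes every stage testable at desk scale.

## The model

For gene *g* and cell type *c*, the input is a C×L matrix
(C ∈ {1, 4, 5}, L = 2 kb by default, TSS centered):

```
x[0..3, :] = one-hot DNA along the coding strand      (DNA-only: 4 ch)
x[4, :]    = min-max-normalized, σ=20-smoothed ATAC    (ATAC-only: 1 ch)
                fragment coverage for cell type c      (DNA+ATAC:  5 ch)

ŷ = σ( CNN(x) )            trained with MSE against GEx ∈ [0, 1]
```

The CNN is Xpresso-like (two conv/max-pool blocks, two dense layers,
dropout, sigmoid head) and fully configurable. Useful accessibility
summaries: `auATAC` (area under the normalized track) doubles as a naïve
baseline predictor. Attribution scores satisfy the completeness identity
Σ scores = f(x) − mean f(backgrounds) exactly (a delta-propagation
backend of the DeepLIFT-rescale family); backgrounds preserve each
sequence's exact dinucleotide counts.

See `docs/methods.md` for the full model description, the synthetic
generator's generative model, and all numerical conventions.

## Worked example

`examples/03_train_ablation.py` trains the same architecture in its three
channel modes on a small synthetic dataset (1200 genes, 300 bp promoters)
and evaluates a held-out gene fold:

```
mode         channels   params  test Pearson
atac_only           1    18721         0.916
dna_only            4    19105         0.022
dna_atac            5    19233         0.932
```

Accessibility alone predicts expression well on these conditions
(expression is driven mostly by promoter openness), promoter sequence
alone barely beats chance, and the augmented model recovers the planted
motif-×-accessibility signal on top of the accessibility baseline — the
qualitative ladder the package's full desk-scale experiments confirm with
5 seed replicates and one-sided Wilcoxon tests. The other examples walk
through promoter extraction (`01`), the track/GEx pipeline from raw
fragment and MTX files (`02`), attribution with completeness checking
(`04`), k-mer ranking and cross-cell-type Jaccard (`05`) and variant-effect
scoring (`06`); each prints what it computes and what the numbers mean.

A thin CLI covers the shell-friendly steps:

```bash
chromexpr prepare-promoters --fasta genome.fa --gtf genes.gtf --flank 1000 --out prom
chromexpr prepare-gex --mtx umi.mtx --features f.txt --barcodes b.txt --annot ann.tsv --out gex.tsv
chromexpr synth-generate --n-genes 1000 --length 500 --out synth/ --render-raw-formats
chromexpr model-describe --channels 5
```

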