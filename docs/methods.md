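# Methods

## The model

`chromexpr` predicts **GEx** — the probability that a gene is expressed in
a cell type, operationalized as the fraction of that type's cells with a
nonzero UMI count — from a TSS-centered promoter window. The input to the
1D CNN is a C×L matrix: four one-hot DNA channels (rows A, C, G, T, along
the coding strand, with the TSS at index L/2) plus, for the augmented
model, a fifth channel carrying the cell type's pooled ATAC-seq coverage
over the same window. Channel ablation (ATAC-only, DNA-only, DNA+ATAC)
changes nothing but the input rows and the first convolution's input
dimension, so adding one channel adds exactly
`n_filters₁ × kernel_width₁` parameters.

The default architecture is Xpresso-like with one extra dense layer: two
convolution blocks (128 filters × width 6 → max-pool 4, then 32 × 9 →
max-pool 4), dense layers of 256 and 64 units with dropout 0.1 after each,
and a single sigmoid output. The sigmoid head is our choice (GEx is a
proportion); the published description this design follows does not state
the output nonlinearity, and its exact layer widths are not public — every
width here is configurable and we make no claim of matching its printed
parameter totals. The per-channel increment arithmetic above is the
structural invariant we do test.

### Accessibility track pipeline

Fixed order, each step testable in isolation:

1. **Coverage** — each ATAC fragment adds its count (or 1) to every base it
   overlaps within the promoter window; minus-strand windows are reversed
   so track index i matches sequence index i. A cut-sites mode (count only
   the two Tn5 insertion positions) is available but not the default.
2. **Smoothing** — Gaussian filter, σ = 20 bp, kernel truncated at 4σ,
   reflect boundaries (conserves total signal to ~1e-6).
3. **Normalization** — min-max with a single (min, max) over *all*
   positions of *all* promoter tracks of one cell type. Per-track
   normalization would erase between-gene accessibility differences, which
   are the point; a degenerate cell type (max = min) normalizes to zeros.

**auATAC** is the area under a gene's normalized track (per-base sum, unit
bin width, so 0 ≤ auATAC ≤ L). It is both the naïve baseline predictor
(scored by Spearman against GEx) and the filter used when exporting
attribution arrays for motif discovery (keep genes above the cell-type
mean).

### Training and evaluation protocol

Five-fold cross-validation over genes: the fold partition is fixed and
seed-independent; each (fold, seed) pair has its own inner train/validation
split (10% of the non-test genes — the source describes an inner split but
not its size). Five seed replicates per fold differ in weight
initialization, inner split and batch order. MSE loss; Adam with
**L2-coupled** weight decay (the decay term enters the gradient before the
moment estimates, as torch's `Adam(weight_decay=…)` does). The coupling is
deliberate: with decoupled decay, weights that receive no useful data
gradient decay at rate `lr·wd·|w|` per step and effectively never vanish,
whereas the coupled variant's normalized decay step has magnitude ≈ lr
regardless of wd — this is what lets long training actively silence an
uninformative input channel, the mechanism behind the scrambling
equivalences below. Full-scale defaults follow the published protocol
(lr 5e-5, wd 1e-3, batch 512, 500 epochs); validation MSE is computed every
4 epochs and the lowest-validation checkpoint kept; no other early
stopping. Fold-level performance is the Pearson/Spearman/MSE/R² of the
5-seed ensemble mean prediction; fold statistics are mean ± SD.

Fine-tuning initializes a 5-channel model from a trained DNA-only
checkpoint: every shared tensor is copied exactly and only the first
convolution's ATAC slice is freshly initialized, then training resumes at
lowered lr (1e-5) and weight decay (1e-4) for ≤ 200 epochs (full scale).

Scrambling experiments permute input blocks across genes in the training
split while targets stay in place: DNA blocks, ATAC rows, or both — jointly
("pairwise", preserving the DNA–ATAC pairing) or with two independent
permutations ("separate"). Permutations are drawn once per run from the run
seed; at n ≤ 2 the separate mode redraws until the two permutations differ,
otherwise breaking the pairing is only probable, not guaranteed.

### Attribution

Backgrounds for a promoter are shuffles of its own sequence preserving the
exact dinucleotide counts (Altschul–Erickson Eulerian construction, which
also fixes the first and last base); for 5-channel models each background
adds an independent position-permutation of the gene's own ATAC row.
Windows containing N are shuffled segment-wise between the N's.

Scores are computed by an own delta-propagation backend (DeepLIFT-rescale
family): multipliers are propagated from output to input such that
Σ m·(x−b) = f(x)−f(b) holds *exactly* per background — linear layers
propagate their transpose, elementwise nonlinearities use Δout/Δin with a
gradient fallback below |Δin| = 1e-9, and max-pooling distributes each
window's output delta proportionally to Δx/Σ Δx². Completeness (the
efficiency axiom) is therefore exact to float64 round-off rather than
approximate, and for a linear model the scores equal the closed-form
Shapley values. Positional aggregation is three-stage in fixed order:
seed-mean per (gene, fold) → concatenation of held-out genes across folds →
gene-mean per channel and position; per-(gene, fold, seed) arrays are kept
on disk (HDF5) so each stage is independently checkable.

### k-mer analysis

A k-mer instance's score is the mean over its k positions of the per-base
DNA attribution (the sum of the four DNA channels — for one-hot input only
the active base's channel is nonzero). All overlapping instances are
scored; windows containing N are skipped; the forward-strand k-mer is never
collapsed with its reverse complement, since orientation carries signal.
Tables average instances per k-mer (for dinucleotides: per-cell-type means
first, then an unweighted mean across cell types; whether the original
analysis weighted cell types by instance count is unstated — we chose
unweighted). The `positive_only` variant drops instances with score ≤ 0
before averaging. Rankings sort by score descending with lexicographic
tie-break, NaN (zero-instance) k-mers last; top-fraction sets use
⌈fraction·4^k⌉; cross-cell-type similarity is the Jaccard index of top-10%
sets.

## The synthetic generator

The generator emulates the *structure* of multiome data with a known
ground truth so every stage is testable without downloads:

- **Sequence**: i.i.d. background (uniform by default) with planted motif
  instances — Poisson(rate = 1.0) count per motif per promoter, uniform
  non-overlapping positions, three consensus-style 8–9 bp PWMs by default
  (CRE-like, GC-box-like, GATA-like).
- **Accessibility**: per gene, a profile of 2 Gaussian bumps near the TSS
  (width L/12, center jitter sd L/10), scaled by a per-(gene, cell type)
  latent openness ~ Beta(2, 2), plus folded-normal noise (sd 0.02). The
  observed tracks then run through the *real* smoothing/normalization
  pipeline.
- **Expression**:
  `GEx = logistic(w₀ + w_A·auATAC + Σ_m β_{m,c} Σ_i ā_i)` where ā_i is the
  mean normalized accessibility over instance i's footprint — motif effects
  are *accessibility-gated*, so sequence and accessibility interact rather
  than adding independently. Realized GEx adds N(0, 0.05) observation noise
  clipped to [0,1], or, in binomial mode, draws a Binomial(n_cells) count
  so that GEx × n_cells is an integer as for real UMI data.

Defaults were fixed once so that the logits span roughly ±3 (GEx spread
over most of [0, 1], few saturated genes) with the accessibility term
dominant and the motif term secondary: w₀ = −3, w_A = 24/L, β = 3. All
randomness flows from one master seed through named substreams (sequences,
placement, openness, tracks, noise, render). An inverse-rendering mode
emits the dataset in the real input formats (FASTA, fragments TSV sampled
so coverage approximates the raw tracks, Matrix Market UMI counts with
per-cell Bernoulli draws, annotation TSV) to exercise the I/O paths end to
end.

What the generator does **not** emulate: nucleosome positioning, Tn5
sequence bias, batch effects, doublets, mappability structure, distal
regulation, or realistic promoter base composition (CpG islands). Passing
the desk-scale experiments therefore demonstrates that the machinery
recovers the kinds of signal the method targets — not that the method
attains any particular performance on real chromatin.

## Desk-scale experiment conditions

The end-to-end experiments (`chromexpr.experiments`) run on one CPU at a
reduced scale chosen once: 3000 genes, L = 500 bp, one CV fold, 5 seed
replicates for ablation (3 for scrambling), a slimmed model (conv 16×8/pool
4 twice, dense 256+64, dropout 0.1) and a shorter, hotter schedule (lr
2e-3, wd 1e-4, batch 512, 48 epochs, validation every 4). Fine-tuning at
this scale uses lr 5e-4 for 12 epochs. These stand in for the full-scale
protocol in the same way a pilot run would; the full-scale defaults remain
the package defaults.

Two desk-scale readouts deserve explanation:

- **Scrambled-training runs are evaluated at the final epoch**, not the
  best-validation checkpoint. With scrambled training data the inner
  validation split is scrambled too, so "best validation" systematically
  selects the least-trained state — and a barely-trained CNN still reads
  the (real, informative) test accessibility amplitude through what is in
  effect a random projection, inflating its apparent performance. The
  scientifically meaningful quantity is what training on decoupled inputs
  converges to; at this scale the memorization transition that destroys
  the residual input projection completes within the 48-epoch schedule
  (both-scrambled test Pearson ≈ 0 thereafter).
- **The k-mer Jaccard comparison uses ground-truth attribution proxies**
  (per-base score = planted motif effect × local accessibility inside
  footprints, zero elsewhere) rather than trained-model attributions, so
  it isolates the k-mer machinery from training noise and runs in seconds.

## Numerical choices and edge cases

- One-hot N → all-zero column (no 0.25 smoothing); soft-masked bases are
  uppercased. Promoter windows crossing a chromosome end raise (no
  padding). Missing `Ensembl_canonical` tags fall back to the transcript
  with the 5'-most TSS, ties by transcript ID, logged.
- Correlations on constant vectors are NaN with a warning, excluded from
  fold means, never imputed. Spearman uses average ranks on ties.
- Wilcoxon signed-rank (one-sided): zero differences dropped; exact
  p-value for n ≤ 25 via dynamic programming over the (doubled, hence
  integer) signed ranks — identical to full 2ⁿ sign enumeration, which the
  tests verify up to n = 12 — and a tie-corrected normal approximation
  with continuity correction beyond.
- auROC via pairwise-concordance semantics (ties count ½), delegated to
  scikit-learn and cross-checked against the Mann–Whitney identity.
- Training is float32; attribution runs in float64. Given one seed and
  single-threaded BLAS, training is bit-reproducible; across BLAS builds
  we document a 1e-6 tolerance on losses.
- Max-pooling drops the remainder positions of a window that is not a
  multiple of the pool width; those positions receive zero gradient and
  zero attribution (they cannot influence the output).

## Known limitations

- The highly-variable-gene selector (top-n by variance-to-mean ratio of
  within-cell-type UMI counts) is a stand-in; the original selection
  procedure is not public.
- The delta-propagation max-pool rule is one valid completeness-preserving
  choice among several; attributions near ties in pooling windows are
  rule-dependent (the tests check the contract — completeness, linear-model
  exactness, symmetry — not a particular attribution brand).
- DNA-only models at desk scale sit barely above chance: with
  accessibility-gated motif effects, sequence alone explains little
  variance by construction, mirroring (in exaggerated form) the weakness
  of promoter-sequence-only prediction.
- Variant-effect scoring reuses the reference accessibility track for the
  alternative allele; regulatory variants that act by changing
  accessibility itself are out of scope.
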