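# Methods

## Problem and approach

Supervised sequence models for regulatory genomics (does a 200 b window of
DNA carry a transcription-factor binding site / accessible chromatin?) are
limited by the labeled genome: a specific TF may bind only a few thousand
loci. Regulatory sequence, however, is conserved across related species, so
every labeled locus typically has homologs in dozens of unlabeled genomes.
`seqssl` implements semi-supervised training built on that observation:

1. **Cross-species pseudo-labeling.** Peaks on the labeled genome are
   projected onto each unlabeled genome through pairwise alignment chains.
   A projected peak may split into several segments (alignment indels split
   the image). Segments on the same chromosome and strand separated by gaps
   of **less than 20 b** are merged into a single homologous peak; if the
   image stays split by **20 b or more**, maps to several chromosomes or
   strands, or does not map at all, the peak yields no homolog. Each
   homologous peak becomes one pseudo-labeled positive training sequence.
2. **SSL (pretrain → fine-tune).** A model is pretrained on the pooled
   pseudo-positives plus an equal number of labeled-genome negatives, then
   fine-tuned (all layers trainable) on the original labeled data. The
   pretraining supplies a better initialization; the fine-tune anchors the
   model to real labels.
3. **SSL-NS (noisy student).** A teacher trained on labeled data scores each
   pseudo-positive with a confidence weight `w = p_teacher ∈ [0, 1]`;
   Gaussian noise (mean 0, SD 0.1) is added once per iteration and the
   result clipped to [0, 1]; a freshly initialized student is pretrained on
   the weighted pseudo-positives (labels 1) plus weight-1 negatives
   (labels 0), fine-tuned on the labeled data, and becomes the next teacher.
   Five iterations by default; the final student is returned (all iterations
   are logged in the history).

The per-example weight enters the loss as weighted binary cross-entropy
normalized by the weight sum, so a weight-0 example contributes exactly
nothing to a training step.

## Labeling conventions

* Coordinates are 0-based half-open everywhere internally; VCF positions are
  converted on read.
* The labeled genome is tiled into non-overlapping 200 b bins; a trailing
  partial bin is dropped. A bin is positive iff the **union** of peaks
  covers **strictly more than 50%** of its bases (exactly half is negative).
  Union coverage makes labels invariant to peak fragmentation.
* Two sequence dialects: `bin_only_200` (the bin itself, L = 200) and
  `context_1kb` (a 1 kb window centered on the bin, L = 1000). Context
  windows and pseudo-label windows that overrun a chromosome end are
  N-padded, so extraction is total; windows with > 50% N are dropped.
* Training sets are balanced 1:1 by sampling negatives uniformly without
  replacement (seeded). Held-out test sets keep the genome's natural class
  imbalance, which is why average precision (AUPR) is the headline metric.
* Homologous peaks of variable length feed fixed-length models through a
  window centered on the homolog midpoint (`floor((start+end)/2)`,
  window `[mid − L/2, mid + L/2)`), reverse-complemented for minus-strand
  homologs. Centering is the minimal reconciliation between variable-length
  homologs and fixed-length model inputs; resizing or multi-window emission
  would change the example count per peak.
* When several chains cover a peak, the highest-score chain is tried first
  and others consulted only if it yields no segments (best-chain liftover
  behavior). Segments are never merged across chromosomes or strands, and
  a multi-chromosome/strand image discards the peak — a conservative
  reading of "distant loci".

## Models

Implemented in NumPy (no deep-learning framework is assumed): 1D
convolutions via an im2col GEMM, inverted dropout, Adam, early stopping on
a seeded validation split with best-weight restoration. Everything is
float32 and deterministic given (data, seeds).

| family | stack | trainable scalars |
|---|---|---|
| `shallow_cnn` | conv(64 or 256 × 24) → ReLU → global max pool → dropout .2 → dense 10 → dropout .2 → sigmoid | 6,869 (64) / 27,413 (256) |
| `deep_cnn` | + five dilated conv(kernel 3, rates 2,4,8,16,32, 'same', additive residual) after the first conv | shallow + 5·F·(3F+1) |
| `deepbind` | conv(16 × 24) → global max pool → dense 32 → dropout .5 → sigmoid | 2,129 |
| `deepsea` | conv(320×8) → pool 4/4 → .2 → conv(480×8) → pool 4/4 → .2 → conv(960×8) → .5 → flatten → dense 925 → sigmoid | ~52 M at L = 1000 |

Choices the architecture descriptions leave open, fixed here: channel order
A,C,G,T with N = all-zeros; hidden dense layers use ReLU (parameter counts
are unaffected); first convolutions use 'valid' padding (motif-scanner
semantics), dilated convolutions 'same' (residual addition needs equal
lengths); dilation rates double per layer (2…32), configurable in
`ModelSpec`. Global-max-pooled families accept any input length ≥ the
kernel span, so their parameter counts are input-length independent.

Training defaults (none prescribed by the method; all configurable):
Adam lr 1e-3, batch 64, max 50 epochs, patience 5, validation fraction 0.1.
The same settings are used for pretraining and fine-tuning; no layers are
frozen. Noise is applied to pseudo-positive weights once per student
iteration, never to negatives; students are freshly initialized each
iteration (a warm-started student would not be a "student" in the
noisy-student sense). The returned SSL-NS model is the last student.

## Evaluation

* Chromosome holdout: test chromosomes are excluded from all training;
  pseudo-labeled examples inherit their **source peak's** chromosome, and
  any example homologous to a test-chromosome peak is dropped from both
  training and test. This is stricter than a naive split — cross-species
  homologs of test loci would otherwise leak into pretraining.
* AUROC (Mann–Whitney, ties ½) and AUPR (step-wise average precision, no
  interpolation) via scikit-learn; both are cross-checked against
  brute-force oracles in the test suite. Benchmarks run 3 replicates with
  distinct seeds and report means plus percent change vs the supervised
  baseline.
* SNP effect: `(p_alt − p_ref) · max(0, p_alt, p_ref)` on a window with the
  variant at offset `floor(L/2)`; the genome base must equal the stated
  reference allele (a mismatch is an error, never silently patched). The
  score is antisymmetric under allele swap and bounded by 1.

## Synthetic world

The simulator generates the fixture the package is exercised on end to end:

* **Labeled genome**: i.i.d. uniform A/C/G/T background (default 1 Mb over
  4 chromosomes), 300 non-overlapping peaks with widths uniform in
  150–450 b (median ≈ 300 b, the realistic peak-size range), each planted
  with one instance sampled from a fixed 12-column PWM (dominant base
  probability 0.85).
* **Descendants**: a star phylogeny (default 10 species) evolved
  independently by per-base substitutions (default 0.03/base) and indels
  (default 0.002/base, geometric lengths, mean 5 b). The exact edit history
  is emitted as chain files — no aligner in the loop — and also yields the
  true homologous interval of every peak (marked lost when a deletion
  removes more than half the peak). At these rates most peaks recover,
  echoing the ~80% conservation observed between real mammalian genomes.
* **SNPs**: half placed inside planted motifs with the least likely
  alternative base (log2 PWM odds delta recorded; expected to reduce
  binding), half in background (delta 0); reference alleles always match
  the genome.

What the simulator does **not** emulate: biased mutation processes (CpG,
transition/transversion), rearrangements and inversions, selection,
GC-content structure, repeat families, and functional divergence of
conserved sequence (a surviving motif always keeps its label). A green
end-to-end test therefore establishes that the machinery behaves per
contract and that the semi-supervised gain appears when homologs are
informative — not that the same magnitude of gain transfers to any real
assay.

Test and acceptance runs scale the world down (hundreds of kilobases,
~100 peaks, capped epochs) to fit a single-CPU time budget; the statistical
structure (peak sizes, divergence rates, ≥10× pseudo-label augmentation in
the low-data regime) is unchanged.

## Numerical notes

* Validation splits are seeded permutations; if a tiny split leaves one
  class absent from training, one example of the missing class is swapped
  in from the validation side (and an error is raised if that empties it).
* Early stopping requires improvement > 1e-7 in validation loss; best
  weights are restored on stop.
* Sigmoid/BCE are computed in the numerically stable logit form; float32
  forward/backward, float64 metrics.
* Derived seeds (per noisy-student iteration, per species) come from
  `numpy.random.SeedSequence` and stay below 2^31.

## Known limitations

* Pure-NumPy training is single-threaded and desk-scale; genome-scale runs
  would need a GPU framework behind the same module surface.
* Chains are consumed one-best-first; overlapping chain stacks with
  conflicting scores are resolved by score only.
* The deepsea family is fixed to 1 kb inputs and is costly to train here;
  it is exercised for construction, shape propagation and prediction
  contracts, not benchmarked.
* The 50%-N window drop and the N-padding edge contract are this package's
  conventions; other liftover pipelines may differ at chromosome edges.
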