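# Methods

## Overview

`haplocall` casts small-variant detection as conditional sequence generation:
a transformer encoder reads a 150 bp window of aligned short reads and two
parallel transformer decoders autoregressively generate the sample's two
haplotype sequences as 4-mer tokens (vocabulary 4^4 = 256, at most 37 tokens
= 148 bases per haplotype).  Variants are never enumerated as candidates;
they fall out of aligning the generated haplotypes back to the reference.
The surrounding tool implements the full calling procedure: candidate-region
scanning, overlapping-window decoding, Smith-Waterman variant extraction,
majority-vote merging, feature annotation, and a post hoc random-forest
quality model mapped to phred-scaled QUAL scores.

## Read encoding

A window is a [g, r, 10] tensor: g = 150 reference positions, r read rows
(row 0 is the reference), 10 features per cell — one-hot base (4), base
quality, consumes-reference and consumes-read flags derived from the CIGAR
(a deletion consumes reference only, an inserted base consumes read only),
strand, clipping status, and mapping quality.  Cells without an aligned base
are all-zero; the reference row carries quality 1.0 and no flags.

Choices the on-disk formats do not dictate:

* **Quality scaling.** Base and mapping qualities are divided by 100, so the
  reference row's synthetic quality of 100 maps to 1.0 and all features lie
  in [0, 1].
* **Insertions.** The fixed grid has one slot per (position, read).  When a
  read carries an insertion immediately after a column, that column's slot
  encodes the first inserted base (consumes-reference = 0) instead of the
  aligned base; the generative decoder is responsible for reconstructing the
  full inserted sequence.  Multi-base insertions therefore enter the input
  only through their first base — a deliberate trade against widening the
  tensor.
* **Downsampling.** Windows with more than r − 1 reads are uniformly
  downsampled with an RNG keyed by (window, global seed), making encoding
  reproducible and letting one high-coverage window yield many distinct
  training examples.
* **N bases** encode as all-zero one-hot with flags set; soft-clipped bases
  occupy no columns but set the read's clipped flag; mapq-0 reads are kept.

## Model

Per cell, a linear layer embeds the 10 features in d dimensions (d = 12 for
the full-size presets).  A 2-D sinusoidal positional encoding — half the
channels indexed by genomic position, half by read row — is added, the read
axis is flattened (token size d·r), and a linear layer projects to the
encoder model dimension.  A post-norm transformer encoder (GeLU activations)
processes the g position-tokens.  Encoder output is projected to the decoder
dimension (256, the vocabulary size, by default), a standard 1-D sinusoidal
encoding is added, and the result serves as cross-attention memory for two
decoders that share no parameters.  Each decoder starts from a learned start
embedding (the vocabulary stays exactly 256), applies causally masked
self-attention plus cross-attention, and emits 256-way token logits.
Greedy decoding picks the argmax token per step (ties resolve to the lowest
token id) until 37 tokens are generated.

Named presets follow the published layer/head/width grid (30M, 50M, 100M).
The feed-forward width is set to 1x the model dimension — with the usual 4x
the presets land ~50% above their nominal parameter counts, with 1x they
land within a few percent.  Dropout is 0.1 for the large presets; the `tiny`
preset (2 encoder layers, width 64, 2 decoder layers, r = 32, decoder width
64, dropout 0) exists for CPU-scale training and testing and is not part of
the published grid.  The 100M preset requests 10 decoder heads, which does
not divide the 256-dim decoder; head counts fall back to the largest divisor
(8) at construction.

Two positional choices matter enormously at small training scales, where we
cannot brute-force the alignment problem with data:

* **Decoder positions are expressed in genomic-column units**: output token
  t receives the sinusoidal encoding of position 4t, while memory columns
  keep their integer encodings.  Queries and keys then share one positional
  scale, and each attention head can learn a fixed small offset into the
  4-mer.
* **Cross-attention query/key projections are initialized to the identity**,
  so the initial attention pattern already follows the positional diagonal
  (token t onto columns ~4t).  With random initialization, attention over
  150 columns starts uniform and the copy signal is diluted 150-fold;
  controlled experiments on a synthetic copy task showed the model then
  fails to bootstrap within a few thousand steps, while with the diagonal
  initialization it reaches near-perfect token accuracy.  Large-scale runs
  would eventually learn the same circuit; the initialization only removes
  the plateau.

## Training

Targets are built by editing each haplotype's truth alleles into the
window's reference and trimming/extending with downstream reference to
exactly 148 bases; no pad token exists.  Regions are labeled (SNV,
deletion, insertion, multi-indel, low-complexity/poor-mappability via
optional stratification BEDs, true negative) with precedence multi-indel >
low-complexity > insertion > deletion > SNV > true-negative, and sampled in
configurable proportions.  Unphased het variants are phased by enumerating
all 2^n assignments (n <= 4, variants < 100 bp apart; otherwise the region
is discarded) and scoring every read against both candidate haplotypes by
Smith-Waterman (match +2, mismatch −4, gap open −6, extend −1); the
assignment with the highest total wins, ties resolving to the
lexicographically smallest haplotype pair, and a single het variant goes to
haplotype 1 by convention.

Because the haplotype pair is unordered, the loss evaluates both pairings of
predictions with targets and keeps the cheaper one:
`min(CE(P0,T0)+CE(P1,T1), CE(P0,T1)+CE(P1,T0))`; gradients flow only
through the minimizing configuration.  The training loop optimizes the
per-token mean of this quantity — a pure rescale that keeps gradient
magnitudes independent of sequence length.  Optimization uses AdamW
(betas 0.9/0.99, weight decay 0.01 on matrix-shaped parameters), gradient
clipping at global norm 1.0, and a linear-warmup/cosine-decay schedule.
Defaults follow the full-scale recipe (peak 5e-5, floor 1e-5, batch 512;
fine-tune variant 1e-5 -> 1e-6); desk-scale runs of the tiny model use peak
2e-3, floor 2e-4, batch 32 for 1600 steps, chosen once from convergence on
the synthetic copy task.  Checkpoints store model, optimizer and RNG state,
so a resumed run reproduces the original step for step.

## Variant calling

1. Any position where at least 3 reads differ from the reference (mismatch,
   or an indel touching the position) seeds a candidate; seeds are padded by
   4 bp and seeds closer than 100 bp merge into one region.
2. Windows start 100 bp upstream of the first seed and advance by 25 bp
   until a start passes the last seed (clamped at the contig origin).
3. Each window's two greedy-decoded haplotypes are aligned to the reference
   slice (window plus 30 bp flanks) with the query end-to-end and free
   target end gaps, so terminal indels are not clipped; mismatches become
   SNVs, gaps become anchored indels, every record is left-normalized, and
   each carries the probability of the 4-mer token containing it.
   A haplotype scoring below 30% of a perfect match skips its window.
4. Calls are merged per normalized (chrom, pos, ref, alt) by majority
   genotype vote (a variant on one decoded haplotype is a het observation,
   on both a hom observation); het/hom ties break toward het.  Minority-
   window variants are retained — the quality model, not a hard filter, is
   the precision mechanism.
5. Features per call: windows containing it vs. windows covering it, cis and
   trans neighbor counts (from co-occurrence on the same or opposite decoded
   haplotype in shared windows, scoped to the candidate region), min/mean
   token probability, mean |window offset − 75|, genotype vote counts, read
   depth and alt-supporting reads.  Het calls sharing at least one window
   join a phase set (PS = 1-based position of the group's first variant).
6. A random forest (100 trees, depth 25, balanced class weights) trained on
   raw calls labeled TP/FP against truth (genotype-aware: right allele with
   wrong genotype trains as FP) yields p(true); QUAL = −10·log10(1 − p)
   capped at 100, so the default Q10 filter keeps calls with p >= 0.9.

## Simulator

The simulator generates what the caller assumes and nothing more: a random
reference (configurable GC), SNVs/insertions/deletions planted at
configurable per-bp rates (geometric indel lengths, collisions re-sampled),
each variant homozygous or assigned to one haplotype by the het fraction;
fixed-length reads drawn uniformly from both haplotypes at the target depth
with substitution (and optional read-indel) errors; and exact CIGARs from
composing the read-to-haplotype and haplotype-to-reference edit scripts.
Outputs are a FASTA, a phased truth VCF and a sorted indexed BAM.  Defaults
(150 bp reads, 50x, 0.1% base error, ~1 SNV/kb) mirror the short-read WGS
regime the method targets.  It does not model PCR duplicates, mappability
artifacts, insert-size structure or platform-specific error profiles —
passing tests on simulated data therefore demonstrate the machinery is
correct at clean, uniform coverage, not that accuracy transfers to real
instruments.

## Evaluation

Matching is exact over normalized records: TP requires identical
(chrom, pos, ref, alt) and equivalent genotype (haplotype order ignored); a
correct allele with the wrong genotype counts as a genotype mismatch and
leaves the truth record unmatched (FN) while the call counts FP.  This is a
stricter, simpler matcher than haplotype-aware tools — complex
representation differences that such tools reconcile count as errors here.
Indels are binned by |len(alt) − len(ref)| into 1–5, 6–15, >15.  Phase
precision considers adjacent pairs of het calls in one phase set (calls
below Q10 discarded), compares relative phase (cis/trans) with the truth,
and bins by POS distance: 1–24, 25–49, 50–100, >100 bp, reporting
100·correct/(correct+incorrect) per populated bin.

## Desk-scale study

The bundled study (`haplocall.workflows.run_study`, also the acceptance
script) trains the tiny preset on ~3000 regions from a 30 kb contig (50x,
0.1% base error, homozygous SNVs at 2/kb), calibrates the forest, and
evaluates on a held-out 20 kb contig through the full pipeline, sweeping
the quality threshold over {0, 10, 20, 30}.  Problem sizes were chosen so
the whole study runs in minutes on one CPU; with ~60 distinct variant
neighborhoods re-emitted under fresh read downsampling, the 30 kb contig is
small enough to learn quickly and large enough that the learned behavior
transfers to the held-out contig.

Quality calibration uses one contig at the study's own error rate — so the
forest sees true calls distributed like the evaluation sample — plus
contigs at higher error rates (0.8% and up) until the raw call set contains
false positives for the negative class; fitting still refuses single-class
input.  Calibrating only on noisy contigs systematically underrates clean
true calls and was observed to cost sensitivity at Q10.

Two further properties of the study are worth stating plainly:

* The step at which the decoder's copy circuit bootstraps varies between
  runs.  If the validation base-error rate has not fallen below 0.15 when
  the schedule ends, training continues with bounded warm-restart rounds
  (at most two, 700 steps each, peak 1.5e-3) — train-until-validation-
  converges, judged only on training-side validation windows, never on the
  held-out contig.
* Validation windows are drawn from the training contig (distinct examples,
  shared sequence), so a near-zero validation base error does not by itself
  prove sequence-level generalization; a model that partially memorized its
  contig emits noisy low-probability decodes on new sequence.  The held-out
  contig and the quality classifier are the real test: such noise arrives
  as minority-window, zero-read-support calls that calibration maps to
  q ~ 0.

## Numerical and engineering notes

* The tensor engine is a minimal reverse-mode autodiff over float32 numpy
  arrays with fused linear/layer-norm/GeLU (tanh form)/attention/
  cross-entropy kernels; every kernel's gradient is finite-difference
  checked in the test suite.
* Pairwise alignment delegates to Biopython's PairwiseAligner under one
  scoring scheme (+2/−4/−6/−1); co-optimal alignment ties resolve to its
  first enumerated alignment, which is deterministic for fixed inputs.
* Coordinates are 0-based half-open everywhere except VCF I/O.
* Argmax ties in greedy decoding take the lowest token id; merge-vote ties
  take het; het-haplotype sub-ties take haplotype 0.

## Known limitations

* The first-base insertion convention bounds what the encoder can see of
  long insertions.
* The exact matcher understates accuracy relative to haplotype-aware
  matching when representations differ legitimately.
* The tiny-scale study exercises homozygous SNVs end to end; indel and
  phasing accuracy are verified by construction-level oracles rather than
  by a trained model, since training a model to indel proficiency exceeds a
  desk-scale compute budget.
* Stratification-driven fine-tuning exists only as a configuration hook
  (the fine-tune learning-rate schedule); no stratification files ship with
  the package.
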