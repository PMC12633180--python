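# Methods

## Overview

`mycolm` implements a self-supervised masked DNA language model (LM) for
small fungal genomes, a supervised sequence-to-coverage model transferred
from it, and the interpretation stack that sits downstream: information
content logos, in-silico saturation mutagenesis (ISM), induction
time-course difference maps, cis-eQTL variant scoring with matched
negatives, and a reporter-insertion (MPRA-style) harness. Everything is
exercised on synthetic planted-motif genomes with known ground truth, so
each stage's output can be checked against the construction.

## Masked language model

**Architecture.** The model maps a one-hot window of length L (plus a
species one-hot and a mask-indicator channel) to a per-position
distribution over {A, C, G, T}. An initial width-11 convolution is
followed by residual down-sampling stages (BatchNorm → GELU → Conv →
dropout → learned residual scaling → add, then max-pool /2); channel
widths grow per stage. A stack of pre-norm transformer blocks operates at
the bottleneck resolution. The decoder mirrors the encoder with
nearest-neighbour upsampling, additive skip connections from the matching
encoder resolution (pointwise-projected so channel counts agree), and a
depthwise-separable convolution per stage; a width-1 convolution and
softmax emit base probabilities. Default geometry is a 16,384-bp window
with seven stages of widths 96→384, eight 8-head attention blocks at
128-bp resolution and a seven-stage decoder; all of this is configurable
and the desk-scale protocol uses a five-stage, one-block model (~80k
parameters) over 4,096-bp windows.

Numerical choices: the residual scaling vector is initialized at 0.1;
skip and residual paths with changing channel counts use pointwise
projections; the feed-forward inner width defaults to twice the model
width; mask tokens are encoded as a zeroed one-hot plus a dedicated
indicator channel; N bases one-hot to all-zeros and carry loss weight 0.

**Training objective.** 15% of positions per window are hidden (floor of
rate × L); of these 80% become mask tokens, 10% a random base, 10% stay
unchanged (independent per-site draws, not exact quotas). Windows are
reverse-complemented with probability 0.5. The loss is a region-weighted
cross entropy in natural log: per window, the weighted mean of
per-position CE with weights 0.1 at exonic (chewed by 2 bp per side) and
soft-masked repeat positions and 1.0 elsewhere; weights are assignments,
not products, so a position that is both exonic and repetitive still gets
0.1. Training scores masked positions only; evaluation can score all
positions (both behaviours sit behind a flag). Perplexity is exp of the
global mean loss. Validation averages several independent corruption
draws; the best-validation checkpoint (parameters *and* normalization
running statistics) is restored.

**Corpus rules.** LM mode drops contigs shorter than two windows
(32,768 bp at full scale); windows are emitted at a fixed stride and a
window is removed when its soft-masked fraction strictly exceeds 7%.
Homology leakage between training and evaluation splits is filtered from
PAF alignments with coverage = matches/query-length and identity =
matches/block-length; one alignment with coverage ≥ 5% and identity ≥ 30%
removes the window. Supervised mode splits contigs at mask intervals,
trims 1,024 bp per end, drops pieces under 16,384 bp, recursively halves
pieces over 786,432 bp, removes windows with > 50% unmappable positions,
and assigns the rest to eight folds greedily balancing nucleotide totals.
Shards are HDF5 with zlib compression and an adler32 payload checksum;
the container format is treated as interchangeable.

**Mask → predict → tile.** To reconstruct a position probability matrix
(PPM), positions are partitioned into ⌈1/rate⌉ disjoint rounds; each round
masks its positions and records the predicted distributions there, so
every position is predicted exactly once. With strand averaging the same
procedure runs on the reverse complement with the mirrored partition and
the complemented, reversed predictions are averaged in — this makes the
output exactly equivariant under reverse complementation of the input.

## Information content and motif-discovery preprocessing

A PPM row is pseudocounted (ε = 1e-4), renormalized, and converted to
Shannon entropy H in bits; information content is C = 2 − H and letter
heights are p̄·C, so heights sum to C per position. For seqlet-clustering
tools the attribution is the log-odds (p+ε)·ln((p+ε)/p̄) against the
per-position mean background. Seqlet hits are lifted to genome
coordinates by adding offsets to window starts; the nearest transcription
start site (5′ transcript end per strand) is found by binary search, ties
broken toward the upstream side, signed distance negative upstream with
respect to the TSS strand. TSS enrichment histograms use 50-bp bins over
±2.5 kb (bin width is our choice; counts are emitted, normalization is
left to plotting).

## Supervised coverage model

Per-base coverage is median-imputed, cropped (1,024 bp per end at full
scale), and summed into fixed 16-bp bins (896 per window). The coverage
model reuses the LM trunk (encoder + transformer), a shortened decoder
stopping at bin resolution, a crop of edge bins (64 at full scale), and a
dense softplus head with one channel per track. Transfer initialization
copies every trunk weight and normalization statistic from the trained
LM; the from-scratch baseline uses the same architecture with fresh
weights and the heavier-momentum optimizer settings of its own recipe.

The loss factorizes each window-track pair into total count × allocation:
a Poisson negative log-likelihood on the predicted total (N̂ − N·ln N̂) plus
five times the multinomial negative log-likelihood of the observed bin
allocation under the predicted proportions; additive constants
independent of the prediction are dropped, and the multinomial term is
computed per window. Fine-tuning applies reverse-complement augmentation
(inputs and bin targets flipped together).

Predictions ensemble over strands and small input shifts: the forward and
un-reversed reverse-complement outputs are averaged per shift, then
averaged over shifts {0, 1} bp, with output coordinates held fixed.

## Evaluation statistics

Gene-level coverage is log2(sum of a gene's exon-overlapping bins + 1),
where a bin belongs to a gene when at least half its width overlaps the
gene's exons. Per-track gene-level and bin-level agreement are reported
as Pearson r and as R² against the identity line (1 − SSE/SST of
prediction vs truth) — a calibrated-agreement convention, deliberately
not the squared correlation of a refit line. Within an assay group,
tracks can be quantile-normalized to the across-track mean quantile
profile (ties averaged, fractional ranks interpolated linearly) and
mean-centered per gene; centering makes every gene's group-row mean zero
and is idempotent. Within-gene consistency scores gene-track pairs whose
log2 vectors both have variance above 1e-6 and whose predicted variance
exceeds the per-track 80th percentile across genes (linear-interpolation
percentile convention); the per-gene score is the mean r over retained
tracks. Track-level evaluation correlates each gene's cross-track profile
between prediction and observation, raw and normalized.

## Saturation mutagenesis and time courses

ISM enumerates all three substitutions at every position of a promoter
region (−450..+50 of the TSS on the gene's strand at full scale; the
desk-scale protocol scores −250..+10 so the whole planted promoter is
covered). Each variant is scored by log2(alt + 1) − log2(ref + 1) of the
summed exon-overlapping bins; the reference base's entry is fixed at 0
before normalization. Maps average scores over a track set, subtract the
per-position four-base mean (rows then sum to zero), and project onto the
reference base — a site where every mutation hurts reads positive.
Time-course maps parse timepoints from track names (T0, T15, …), average
within timepoint, subtract the T0 map and re-normalize. Flattened maps
give pairwise Euclidean distances between timepoints, averaged
element-wise over promoter windows. Gene-level trajectories are
reads-per-million-normalized bin sums averaged over replicates per
timepoint. ISM forward passes use a single forward pass per mutant by
default (no shift ensemble) for speed; fold averaging is available by
passing several fine-tuned models.

## Variant scoring and the MPRA harness

A variant is scored in a window centred on the SNP after verifying the
reference allele against the genome (a mismatch is a hard error):
predictions for the reference and alternate windows are strand-averaged,
summed over bins overlapping the target gene's exons, and compared as
log2(Cov_alt + 1) − log2(Cov_ref + 1). A variant is cis when it lies on
the phenotype gene's chromosome within 8,000 bp (inclusive). Matched
negatives are drawn per positive from non-coding candidates with allele
frequency ≥ 0.05, same chromosome, TSS distance within ±100 bp (fallback
±200 bp), each candidate used at most once per set, four independent
sets by default; unmatched positives are recorded, not dropped.
Classification ranks variants by |log2FC| — the magnitude of the
predicted effect — and reports AUROC (rank-based, ties averaged) and
AUPRC overall and per TSS-distance bin (default edges 0/1/2/4/8 kb).

Reporter constructs wrap an 80-bp core in fixed flanks
(`TGCATTTTTTTCACATC` + core + `GGTTACGGCTGTT`, 110 bp). Insertion windows
are the half-open 110-bp span around midpoint = TSS − offset (forward) or
TSS + offset (reverse) for offsets 100..200 by 10; the half-open reading
of "midpoint ± 55" keeps the window exactly construct-sized. The score is
the log2 fold-change of the downstream gene's predicted exonic coverage
with the construct inserted versus the native sequence, averaged over
background genes; dual libraries report the alt−ref difference.

## Synthetic data: what it emulates and what it does not

The generator plants the structure the models are meant to recover:
genes on a regular grid with 600–1,200-bp bodies, optional single introns
carrying donor (GTATGT) and branch (CTAACA) signals, 250-bp promoters,
promoter-only activating motifs (E-box-like CACGTG, STRE-like AGGGGC),
neutral genome-wide copies of the same consensus sequences, a neutral
TATA-like decoy, and lowercase repeat runs. Expression is log-linear:
log expression = Σ motif activity × per-track modulation + Gaussian
noise; reads are distributed proportionally across genes, uniformly over
exons, and Poisson-sampled per base. Positive eQTLs substitute the
central base of a planted promoter motif; candidate negatives are
non-exonic, non-motif positions with allele frequencies Uniform(0.01,
0.5), so the AF ≥ 0.05 filter is exercised on both sides.

This emulates the *causal structure* of promoter-driven expression, not
its realism: no nucleosome or chromatin context, no read-level artifacts,
no alternative transcripts, uniform exon coverage, and motif effects that
are exactly additive in log space. Passing the recovery tests shows the
pipeline can extract planted regulatory signal end to end; it says
nothing about performance on real genomes at full scale.

Background copies of the promoter consensus are placed *outside*
promoters (promoter intervals are blocked for background placement).
This is deliberate: identical k-mers with and without effect inside
promoters would make the motif → expression map unidentifiable at this
genome size, which tests the wrong thing.

## Desk-scale protocol sizes

The reference protocol (module `deskscale`, also driven by
`scripts/acceptance.py`) uses: a 262,144-bp training contig plus a
16,384-bp held-out contig (~86 genes); L = 4,096 with tower widths
(16, 24, 32, 40, 48), one 2-head transformer block; LM pretraining of
14 × 40 steps at batch 6, learning rate 5e-3, clipnorm 5, 30-step warmup;
supervised fine-tuning over windows at 512-bp stride for up to 12 × 60
steps at batch 4 (transfer 6e-4 with β = (0.7, 0.9); from-scratch 1e-3
with β = (0.9, 0.999)); eight coverage tracks (four timepoints × two
replicates) of one million reads each with STRE modulation ramping
0 → 1.5; 24 planted positive eQTLs. These are the package's chosen
problem sizes for a complete run on a single CPU; the learning rates and
clipnorm are scaled up from the full-scale recipe because the model and
step budget are orders of magnitude smaller. Variant scoring and ISM can
average over several fine-tuned replicates ("folds"); the reproduction
script uses three.

## Known limitations

- The numpy autodiff engine is single-threaded and eager; it is sized for
  the desk-scale models, not for full-scale training.
- Predicted effect magnitudes are strongly compressed relative to the
  planted effects (ISM logos of ~0.02 bits where the true log2 effect is
  ~1.7); rankings and enrichments are informative, absolute magnitudes
  are not calibrated.
- The ΔISM induction signal is a second-order effect and close to the
  noise floor at this scale; it stabilizes only after fold averaging.
- Quantile normalization is implemented directly (sorted-mean target,
  averaged ties) rather than via an external package.
- The seqlet-clustering step itself is out of scope: the package prepares
  inputs for, and consumes tables from, a TF-MoDISco-compatible tool.
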