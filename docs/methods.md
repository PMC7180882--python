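# Methods

## Problem and pipeline

Atrial fibrillation (AF) shows up in a single-lead ECG as an irregular
R-R interval pattern, missing P waves, and a low-amplitude fibrillatory
baseline oscillation around 4–8 Hz. The package classifies short
single-lead recordings (300 Hz, 9–61 s) into four rhythm classes — AF,
Normal, Noisy, Other — with an end-to-end 1D convolutional network: raw
amplitude samples in, class probabilities out, no hand-crafted feature
extraction and no 2D spectrogram conversion.

The pipeline is:

1. **Length normalization** (`length_norm`) — recordings of variable
   length are converted to fixed-length segments.
2. **Classification** (`architecture` + `nn` + `training`) — a 10-block
   1D CNN with a 4-way softmax head, trained with Adam on categorical
   cross-entropy.
3. **Evaluation** (`evaluation`) — per-class F1 from one-vs-rest
   collapses of the 4×4 confusion matrix; the headline score is the
   unweighted mean of the four per-class F1 values, aggregated over
   stratified 5-fold cross-validation.
4. **Model selection** (`grid_search`) — exhaustive sweep over depth,
   kernel size, batch size and learning rate.

## Length normalization

The segment length (threshold) is chosen automatically as the modal bin
of the recording-duration histogram, binned at 1 s resolution
(`bin_width_s=1.0`); the threshold in samples is the modal bin's left
edge times the sampling rate. On a corpus whose durations cluster at
30 s this yields 9000 samples. Ties between equally populated bins break
toward the smaller duration; this situation does not arise on realistic
corpora but is pinned down and tested.

Per recording, one of three branches applies:

* **Longer than the threshold** — overlapping windows of exactly the
  threshold length are cut on a stride grid of `T − floor(T·f)` samples
  (overlap fraction `f = 0.5` by default, so adjacent grid windows share
  exactly `floor(T/2)` samples). If the last grid window stops short of
  the end, one extra window anchored at `L − T` is appended so every
  sample is covered. An 18,600-sample recording therefore yields four
  windows (starts 0, 4500, 9000, 9600). The end-anchored window is the
  only reading of the chopping rule consistent with both full coverage
  and a four-segment output at that length.
* **Exactly the threshold** — passed through unchanged.
* **Shorter** — the recording is tiled periodically (self-concatenated)
  and truncated to exactly the threshold:
  `out[i] = x[i mod len(x)]`. Self-concatenation is used rather than
  borrowing a different recording of the same class; it preserves
  per-record provenance and is the literal reading of the procedure.

Every segment inherits its source recording's label, so normalization
also augments the training set (the reference corpus grows from 8528
recordings to 10,151 segments under this rule).

## Architecture

The canonical network (`Proposed-1`) stacks 10 convolutional blocks:
valid (unpadded) convolution with stride 1 and kernel 5, ReLU, and a
size-2/stride-2 pooling layer in every block except the last. Filter
counts start at 32 and double every two blocks
(32, 32, 64, 64, 128, 128, 256, 256, 512, 512). One batch-normalization
layer sits after the ReLU of block 1 only. Dropout 0.5 follows blocks 6,
8 and 9 and the first dense layer. The head is flatten → dense 128 →
dense 32 → dense 4 → softmax. `Proposed-2` replaces every max pool with
average pooling and is otherwise identical; the ablation variants move
BN (All-BN, No-BN) or add one extra pooling layer before the flatten
(Maxpooling, Max-Average, Extra-Average).

Valid convolution and floor-halving pools are forced by the published
layer table (9000 → 8996 with kernel 5; 273 → 136 before the 132-length
convolution); the layer order conv → ReLU → BN → pool in block 1 follows
the stated placement of BN after the activation.

**Parameter accounting.** The analytic calculator
(`compute_layer_summaries`) reports, per layer: conv
`k·c_in·f + f`, BN `4c` total of which `2c` (scale and shift) are
trainable — the running mean/variance are statistics, not parameters —
and dense `in·out + out`. For the canonical stack this gives a row sum
of 3,212,804 and a trainable total of 3,212,740 (the 64 BN statistics
excluded); pooling type never changes counts, and the extra pre-flatten
pool shrinks the first dense layer's input from 4608 to 2048, giving
2,885,060. The calculator is the oracle for the built model: the
engine-reported count (a sum over actual weight-array sizes) must equal
the analytic count for every variant and grid point, and the test suite
enforces this.

**Feasibility.** Because every block but the last halves the sequence,
deep stacks can run out of samples: with input 9000, 11 conv layers are
infeasible for kernels 5 and 7 (the last convolution would receive
fewer samples than its kernel). `check_feasible` detects this, and the
grid search reports such points as N/A rather than dropping them.

**Depth variants for the grid (8, 9, 11 conv layers).** Their exact
block composition is not pinned down by the published description; this
package applies the same canonical schedule (filters doubling every two
blocks, pooling in all but the last block, dropout at relative positions
n−4, n−2, n−1). Their parameter totals are consequently *not* claimed to
match any published per-depth totals; only the 10-block stack's counts
are asserted. The "Max-Average" variant is likewise ambiguous beyond
"combines max and average pooling"; it is implemented as `Proposed-1`
plus an average pre-flatten pool, which reproduces its published
parameter count.

## The network engine

`afdetect1d.nn` is a compact NumPy CNN engine written for this package:
valid 1D convolution implemented as an im2col reshape (built from k
contiguous block copies — the strided sliding-window path in NumPy is an
order of magnitude slower) followed by one BLAS matmul; max/average
pooling with floor semantics; batch normalization over (batch, length)
per channel with momentum-0.9 running statistics; inverted dropout;
softmax cross-entropy with probabilities clipped at 1e−12; and
bias-corrected Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e−8, the standard
constants, since only the update form and the fixed learning rate are
specified by the method). All activations are float32. Correctness is
pinned by a central-difference gradient check through a stack containing
every layer kind (relative error < 2% at float32 precision).

Training defaults follow the best published configuration: learning rate
1e−4, batch size 30, dropout 0.5. The epoch budget is not part of the
published method; the default is 50, with two optional stop rules —
validation-loss patience, and a training-accuracy target used by the
desk-scale tests to stop once a separable set is memorized. Weight
initialization is He-uniform, seeded; a fixed seed makes builds,
shuffling and dropout masks — and therefore entire training runs —
bit-reproducible in single-threaded execution.

Cross-validation is stratified at segment level (each fold preserves the
class proportions of the segment set, sizes within 1 of proportionality).
Segment-level folding means sibling segments of one long recording can
straddle folds; a record-grouped split can be constructed by the caller
from the segments' `source_id` provenance, but segment-level is the
default because it matches how the reference evaluation was run.

## Metrics

Rows of the 4×4 confusion matrix are predicted classes, columns ground
truth, class order [AF, Normal, Noisy, Other]. For each target class the
one-vs-rest collapse gives TP/FP/FN/TN, then precision = TP/(TP+FP),
recall = TP/(TP+FN), accuracy = (TP+TN)/total, F1 = harmonic mean of
precision and recall, all in percent. Zero denominators yield 0 with a
logged warning (the conservative common convention; the method leaves
this case unspecified). The average F1 is the unweighted mean over the
four classes; a three-class mean excluding Noisy is also reported. Fold
aggregation reports per-class means and σ, the standard deviation of the
fold-level average F1 — population σ by default (`ddof=0`), configurable,
since the convention is not stated.

## Synthetic data

The generator emulates the corpus shape — 300 Hz, durations from a
mixture of a 30 s point mass (weight 0.7) and uniform 9–61 s, four
classes — and the class-defining waveform structure. Each beat is a sum
of Gaussian bumps (P, Q, R, S, T). Normal uses mean R-R 0.8 s with
Gaussian jitter (CV ≈ 0.025); AF draws R-R from a gamma distribution
with shape 9 (CV = 1/3, well above the 0.15 irregularity cut), zero
P-wave amplitude, and an added 0.08 mV sinusoid at a random frequency in
4–8 Hz; Other is a slower regular rhythm with widened QRS and inverted
T; Noisy is attenuated beats plus white noise at an SNR below 0 dB and a
slow drift. These parameter choices make AF vs Normal linearly separable
on two hand-crafted features (R-R coefficient of variation, 4–8 Hz band
power) by construction, which the suite verifies — this guarantees the
end-to-end network-recovery test is achievable rather than a property of
luck.

What the synthetic corpus does **not** emulate: real ECG spectral
texture, electrode artifacts, the heterogeneity of the real "Other"
class (a single morphology here), or the exact length histogram of the
reference corpus. Passing the desk-scale tests therefore demonstrates
that the pipeline's machinery is correct and that the network can learn
class structure end to end; it does not certify the published
cross-validated F1 on real data, which requires the reference corpus
and long training (see the reproduction section of the README).

## Desk-scale problem sizes

The end-to-end acceptance check trains `Proposed-2` (full size,
3.2 M parameters, input 9000) on ≈390 synthetic segments (75 recordings
per class), one stratified 80/20 split, up to 30 epochs with the
training-accuracy stop at 99.5%, and requires held-out average F1 ≥ 90.
Typical behavior: the stop triggers around epoch 25 and the held-out
average F1 is 100. Unit tests use a 2-block network on 300-sample
class-coded sinusoids, where training takes seconds. The grid-search
tests run 8-block networks on 700-sample segments, where kernel 7 is
infeasible — exercising the N/A path cheaply.

## Known limitations

* No resampling, filtering or denoising: inputs are assumed 300 Hz and
  already band-passed, as the reference corpus is.
* The engine is CPU-only and single-device by design; it is sized for
  desk-scale experiments and faithful reproduction runs, not for
  large-scale sweeps.
* Multi-lead records, streaming ingestion and per-recording vote
  aggregation are out of scope; evaluation is per segment.
* Raw ADC counts vs millivolts: both are supported at read time
  (`units=`), millivolts by default; the published method does not state
  which was fed to the network.
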