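# Methods

`ecgtl` implements a transfer-learning workflow for ECG arrhythmia
classification: an encoder is pretrained on a large corpus of
continuous single-lead ECG, then finetuned end-to-end on a small
labeled record set. Because the corpora that motivated the workflow are
large downloads, the package ships a synthetic generator that emulates
their structure with exact ground truth, so every stage is testable on
a workstation CPU.

## The synthetic corpora

The generator is deliberately not a physiological simulator. Signals
only need to carry the class-discriminative structure each task relies
on:

* a beat is a narrow Gaussian QRS bump (sigma 12 ms, amplitude 1) with
  a P bump 160 ms before (amplitude 0.15) and a T bump 250 ms after
  (amplitude 0.3);
* premature atrial contractions (PAC) arrive ~25% of an interbeat
  interval early; premature ventricular contractions (PVC) are wide
  (sigma 30 ms), 1.5x amplitude, lack a P wave and are followed by a
  1.5x compensatory pause; aberrantly conducted beats are wider and
  smaller with an inverted T wave;
* normal sinus rhythm (NSR) draws interbeat intervals (IBIs) from a
  narrow Gaussian (fractional jitter 0.04 by default); atrial
  fibrillation (AFib) draws IBIs from a Gamma distribution with
  coefficient of variation 0.30 and has no P wave — the defining
  irregularity of AF is therefore present by construction; atrial
  flutter (AFlut) is fast (mean IBI 0.35 s) and regular with a 5 Hz
  sawtooth baseline; the noise class is 0.5-40 Hz band-limited noise
  with no beats.

Upstream recordings (250 Hz, per-patient segments) tile each segment
with rhythm episodes drawn from a first-order Markov chain. Episode
dwell times are uniform in 20-60 s: continuous-monitoring arrhythmia
episodes last tens of seconds to minutes, and substantially shorter
dwells would make frame labels depend mostly on where an episode
boundary happens to fall rather than on the signal in the frame. Each
patient draws a baseline sinus IBI uniformly from 0.45-1.35 s (about
43-133 BPM), an AFib mean IBI from 0.5-0.9 s and an amplitude scale
from 0.8-1.2, giving the corpus the cross-patient heterogeneity that
both the heart-rate task and the contrastive task rely on.

Downstream profiles: `cinc2017` renders single-lead 300 Hz records of
9-60 s with exactly one label (NORMAL = clean sinus, AF = fibrillation
train, OTHER = flutter or ectopy-heavy sinus, NOISY = beat-free noise),
allocated to classes by largest-remainder rounding so integral ratios
are exact. `multilabel12` renders 10 s, 12-lead, 500 Hz records whose
leads are scaled (occasionally inverted) projections of one rendered
lead plus lead noise, labeled with the rhythm plus PVC/PAC flags.

What the generator does **not** emulate: realistic QRS morphology
across leads, baseline wander, electrode artefacts, device filtering,
or any morphology-only pathology (e.g. ST changes). Passing tests
therefore show that the pipeline's mechanics and learning dynamics are
correct on data whose classes are separable by IBI statistics and beat
morphology — they do not certify clinical-grade performance on real
ECG.

Reproducibility: one integer seed drives everything through a
splitmix-style child-seed derivation (`child_seed`), so corpora are
reproducible per patient and per segment, and every training run is
deterministic on one machine for a fixed seed.

## Frames and weak labels

A frame is a half-open window `[start, start+length)` of samples;
preset lengths are 512, 2048 and 4096 at 250 Hz (about 2, 8 and 16 s).
Frames are standardized with the mean and standard deviation of the
whole corpus, never per frame. Sampling picks a patient uniformly, then
a segment, then a start position.

* **Beat task** — the most frequent abnormal beat class in the frame,
  NORMAL if none. Count ties use the fixed priority PVC > PAC >
  ABERRATION. A frame with no annotated beats is skipped and resampled
  (the task has no noise category).
* **Rhythm task** — the class with the longest overlap with the frame,
  except that any AFib or AFlut presence wins, with the longer of the
  two chosen (exact duration ties go to AFib).
* **Heart-rate task** — the frame is extended by 1 s on each side
  (clipped at segment bounds), beats inside the window are taken from
  the annotations or from the QRS detector, and BPM = 60 / mean(IBI).
  Classes: bradycardia below 60 BPM, tachycardia above 100 BPM, normal
  in between with both boundaries inclusive, and noise when fewer than
  two beats are found (one beat yields no interval, so "failure to
  detect heartbeats" is implemented as < 2).

The QRS detector is a simple energy detector: 5-15 Hz band-pass,
squared derivative, 150 ms moving-window integration, a crest-factor
gate (maximum below 8x the median of the integrated energy means no
dominant QRS, hence no detections), peak picking with a 200 ms
refractory period, and refinement to the local band-passed amplitude
maximum. On clean synthetic sinus signals its sensitivity is 1.0 within
40 ms; on beat-free noise it returns an empty list. It is deliberately
not a production detector.

* **Future-prediction task (contrastive predictive coding)** — an
  example is K contiguous context frames, one positive frame starting
  `offset` frames after the context, and `ns` negative frames drawn
  uniformly from the whole corpus (any patient, segment or position,
  excluding windows overlapping the positive; a negative may come from
  the positive's own segment). Presets (K, ns, offset, frame):
  (8,4,2,512), (16,8,2,512), (16,8,8,512), (16,16,8,512).

## Models

The encoder is a 1D pre-activation residual network (norm - ReLU -
conv ordering) of depth 18, 34 or 50; depth 50 uses bottleneck blocks
with 4x channel expansion. Stage kernel sizes are 7, 5, 5, 3 and stage
channels 64/128/256/512 scaled by a `width_multiplier` (desk-scale
default 1/8). The stem is a kernel-7 stride-2 convolution followed by a
3-wide stride-2 max pool; stages 2-4 downsample by 2 at entry;
convolution weights use He-normal initialisation, and the output is the
globally average-pooled feature vector.

Contrastive pretraining pools the K context encodings with a
transformer encoder stack (3 layers, 8 heads, feed-forward width
2 x d_model, no dropout) prepended with a learnable context token; the
token's output is the context vector c. Candidate scores are the plain
dot products c . h_i (no temperature) through a softmax, trained with
cross-entropy on the positive's index. Because the future is
order-sensitive, learned positional embeddings are added to the pooled
sequence (token at position 0); a flag disables them, which makes the
pooling provably permutation-invariant and is exploited by a test.
With depth 50 only the first three stages are pretrained in this task
(the 4x expansion would quadruple the pooling width); at finetuning the
fourth stage starts from fresh initialisation.

Lead-count adaptation duplicates the learned single-lead stem filters
across the new input channels and multiplies the layer by the channel
ratio (1/12 for 12 leads), so a signal replicated across all leads
reproduces the single-lead output exactly — the identity
`sum_1^12 (w/12) x = w x` holds for every depth and weight draw and is
asserted to 1e-5 in float32.

## Training protocols

Pretraining holds out 5% of patients (at least one) for validation —
the split is by patient, and a provenance check asserts that no
validation patient's frames ever enter a training batch. The loss is
categorical cross-entropy, optimised with Adam at its standard
defaults (1e-3, 0.9, 0.999). Checkpoints are taken every
`checkpoint_interval_steps` (default 2000; desk-scale runs use 100) and
at the last step; the checkpoint with the highest validation accuracy
wins, earliest step on ties. For the contrastive task "validation
accuracy" is positive-identification accuracy on examples whose context
and positive come from held-out patients and whose negatives come from
the whole corpus (negatives are defined as draws from the data set).
The total sample budget is frames-per-patient (default 4096) times
training patients.

Finetuning standardizes the downstream set with statistics pooled over
the entire set — including the test records. This follows the
protocol's own preprocessing description; the (mild) leakage is a
property of the protocol being reproduced and is kept deliberately.
Records are resampled to 250 Hz by polyphase rational resampling and
zero-padded on the right to a uniform 60 s (records longer than the
target, possible only in synthetic profiles, are tail-truncated; the
relative input length is preserved when the target rate changes, e.g.
7680 samples at 128 Hz). The pretrained encoder gets a freshly
initialised fully connected head (softmax/cross-entropy for
single-label, sigmoid/binary cross-entropy for multi-label) and is
trained end-to-end with nothing frozen, for up to 200 epochs, stopping
early when training accuracy has not strictly improved for 50 epochs.
Weights revert to the epoch with the best validation macro F1
(single-label) or best validation loss (multi-label).

Evaluation fixes a stratified 20% test set once, then repeats the
finetune 10 times, drawing fresh stratified train (75%) and validation
(5%) sets from the remaining 80% pool each run, and reports the mean
and standard deviation of the test metrics. Stratification uses
largest-remainder rounding per class, borrowing one record from the
largest split when a small class would otherwise leave a non-empty
split unpopulated; a fold-based split (folds 1-8/9/10) is available for
the multi-label profile.

## Metrics

Single-label: macro F1 (unweighted mean of per-class F1; a class absent
from both truth and prediction scores 0). Multi-label: averaged
class-wise ROC-AUC (midranks for ties; classes without both a positive
and a negative are excluded), sample-centric Fmax (precision averaged
over samples with at least one predicted label, recall over all
samples, maximised over a 0-1 grid in steps of 0.01), and the
challenge-style measures with beta = 2,

    F_beta = 5 TP / (5 TP + FP + 4 FN),   G_beta = TP / (TP + FP + 2 FN),

computed per class and averaged, with degenerate denominators
contributing 0. Binary decisions for F_beta/G_beta use a threshold
searched independently per metric on the training scores (smallest
maximiser on ties). Macro F1 and AUC are computed via scikit-learn;
all four metrics are verified against exhaustive confusion-matrix and
pair-counting oracles in the tests.

## Desk-scale reference experiments

`ecgtl.experiments` fixes the problem sizes used by the test suite and
the reproduction script, as the package's own reference conditions:
encoder width 1/8, upstream corpora of 20 patients (heart-rate and
rhythm pretraining, 600 and 400 Adam steps) and 32 patients
(contrastive pretraining, 800 steps, preset K=8/ns=4/offset=2/frame
512 — more patients give the contrastive task a richer negative pool),
a 160-record single-lead downstream set with durations 9-20 s padded to
20 s, and 5 finetuning seeds per initialisation for the early-epoch
comparison. The supervised demo uses 2048-sample frames, whose 8 s span
covers most of the 10 s labeling window. Under these conditions the
heart-rate task reaches about 0.95 validation accuracy, contrastive
pretraining identifies the true future among 4 negatives about 70% of
the time (chance 20%), and a rhythm-pretrained encoder dominates random
initialisation on early-epoch downstream validation macro F1.

## Numerical notes and limitations

The network core is plain numpy with explicit backward passes
(verified against central finite differences to 1e-4 relative error);
convolution uses column-unfolding and a single matrix product. Batch
norm keeps running moments with momentum 0.9 and epsilon 1e-5;
inference uses the running moments. Weights are float32; losses and
softmax are computed in float64 for stability. There is no GPU path,
no dropout (the pooling configuration sets it to zero) and no learning
rate schedule (Adam defaults throughout). Checkpoints store full weight
copies in memory during a run and serialise as `.npz` plus a JSON
sidecar describing the architecture.

Known limitations: the generator's morphology is a stand-in (the
upstream corpus it emulates is described only at the device/lead
level); the QRS detector is tuned for the generator's clean waveforms;
desk-scale accuracies say nothing quantitative about full-scale
training; and multi-label stratification uses the records' primary
label rather than full label-set stratification.
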