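# Methods

## Problem

Musculoskeletal simulators (OpenSim and its relatives) estimate per-muscle
activation from motion and ground-reaction-force data by solving an inverse
problem over redundant muscle actuators.  The estimates differ from
EMG-derived activation envelopes in systematic, structured ways rather than
by white noise:

* a roughly constant **temporal delay** (reported around 75 ms in running
  data) between estimated and measured activity;
* **displacement of activation peaks** within the gait cycle;
* **cross-muscle leakage**: because the inverse problem is under-determined,
  activity is attributed to the wrong members of a redundant actuator group;
* gain and noise errors.

`gaitrefine` learns a per-muscle correction of these distortions with a
sequence-to-sequence LSTM encoder–decoder whose attention weights expose
*what* the correction used — input time steps (temporal attention) or input
muscles (spatial attention) — and evaluates the correction with
improvement-rate statistics under leave-one-subject-out (LOSO)
cross-validation.

## Data model

All sequences are one gait cycle (heel strike to next heel strike),
time-normalized and thinned to a 20-sample grid by linear interpolation.
Activations are unitless and clipped to [0, 1].  A dataset is a collection
of paired cycles — `simulated` (network input `xs`) and `measured`
(target `ys`) — indexed by subject × speed (four speeds per subject) ×
cycle.

Three input patterns are evaluated:

| pattern | input | steps | attention |
|---|---|---|---|
| One-Quarter | target muscle, one quarter cycle | 5 | temporal |
| One-Entire | target muscle, entire cycle | 20 | temporal |
| All-Entire | all muscles, entire cycle | 20 | spatial |

Inputs and targets are z-scored per channel with statistics from the
training fold only; held-out folds are transformed with those statistics
(the suite verifies that sentinel values in a test fold cannot perturb the
fit).  Thinning precedes standardization.  One-Quarter uses the first
quarter by default (configurable); quarter choice is not dictated by the
protocol.

## Synthetic data generator

Real paired datasets require large public downloads, so the package ships a
generator that emulates their structure.  Each channel of each subject is a
sum of 2–3 wrapped-Gaussian bursts on the periodic cycle — lower-limb
activation envelopes during gait typically show two to three bursts per
cycle.  A shared population template fixes each channel's identity; subject
random effects perturb burst centers (sd 4 % of the cycle, plus a 2 %
whole-subject timing offset) and amplitudes (sd 20 %, log-normal), the
levels of inter-subject timing/magnitude variability a gait-EMG practitioner
would recognise.  This variability is load-bearing: with near-identical
subjects, a memorised average waveform explains held-out data and no method
needs the input — exactly the shortcut the probe below is designed to
detect.  Four speed conditions scale amplitudes by 0.80/0.93/1.07/1.20.

The "simulated" member of each pair is the clean measured pattern passed
through a parametric distortion: circular temporal shift (the cycle is
periodic, so no padding choices arise and shift recovery is exact),
peak displacement (a smooth periodic warp localised at the displaced peak),
row-stochastic cross-channel mixing, gain, additive Gaussian noise, and a
final clip to [0, 1].  The default near-identity mixing matrix is symmetric
(hence doubly stochastic), so at gain 1 it conserves the per-sample total
activation before clipping — the conservation property the tests check.
The generator does not attempt physiological EMG synthesis (no motor-unit
model), and distortion magnitudes across muscles are configuration, not
claims.

## Refinement network

A single-layer LSTM encoder and a single-layer LSTM decoder (700 units each
at full scale; 64 in the desk-scale reduction) with multiplicative
attention, implemented in numpy with hand-written backpropagation through
time (the gradient of every wiring is verified against central differences
in the suite).

* **Temporal attention** (One-Quarter/One-Entire): the encoder consumes the
  target muscle's simulated sequence; attention keys are the encoder states
  at each input step.
* **Spatial attention** (All-Entire): the encoder runs once per channel
  with shared weights; keys are per-channel summary states (final hidden
  state; a per-step variant is available via `spatial_keys="per_step"`).

Scoring is multiplicative — bilinear ("general", default) or plain dot —
scaled by 1/√H to keep initial scores in the softmax's sensitive range.
The decoder is autoregressive: its input at step *t* is its own previous
output (teacher forcing is available as a training flag, default off, so
training matches inference).

Two wirings of the attention *values* are provided, and the choice matters:

* `attention_values="input"`, `output_head="context"` (**default**): the
  attention weights average the raw input samples they index, and the
  output is an affine map of that context alone.  The output must therefore
  be read *through* the attention map, which makes the map a faithful
  record of which input samples/channels produced each output sample.  On
  shift-corrupted data the learned map is the +k off-diagonal; on
  mixture-corrupted data the spatial weights approach the mixing weights.
* `attention_values="state"`, `output_head="full"` (classic): weights
  average encoder hidden states and the head also sees the decoder state.
  This wiring is maximally expressive — the final encoder state can carry
  the whole sequence, so attention maps are under-determined and tend to
  collapse onto the summary state — and it is the wiring used for the
  memorisation check below, where raw capacity is the point.

Training follows the published recipe for this architecture family:
squared-error loss, Adam (learning rate 0.001 — the optimiser is named in
the protocol, the rate is ours), batch size 1, 700 epochs at full scale.
Samples are visited in a seeded random order; per-epoch training and
validation losses are recorded (under LOSO the held-out subject serves as
the monitoring validation set only — never for selection or
standardization).  Gradients are clipped to a global norm of 5 (a
stabiliser for stochastic batch-1 training; disabled in the memorisation
check, where only step size would be capped).  Initialisation is uniform
±1/√H with forget-gate biases of 1.  Everything is deterministic given the
config seed: two runs produce bit-identical weights.

Refined outputs are de-standardized with the training-fold record and
clipped to [0, 1] — clipping happens only in activation units, never in
standardized space.

## Evaluation statistics

Per cycle, accuracy is RMSE over the N = 20 grid samples (the summation is
over N terms — the standard estimator).  Refinement quality is the
improvement rate

    Er = E_refined / E_simulator − 1,

negative when refinement beats the simulator baseline.  Each subject's
representative Er per condition is the mean of their four per-speed values
(per speed, RMSE is averaged over that speed's cycles first).  Across
subjects: one-sample two-tailed t-test of H0: Er = 0; Cohen's
d = (mean − μ0)/sd with sample sd (ddof = 1, required for internal
consistency of d with the t statistic: t = d·√n); Student-t 95 % CI
mean ± t(α/2, n−1)·sd/√n with α = 0.05.  Conditions are compared per
muscle with Tukey's studentized-range test on per-subject Er values
treated as independent groups (no repeated-measures correction is
specified by the protocol; Tukey–Kramer standard errors handle unequal
group sizes).  Report tables mark improved cells (mean Er < 0) bold and
star significance at 0.05/0.01/0.001.  Degenerate cells (identical Er for
every subject) report a zero-width CI and d = NaN rather than failing.

The published walking/running tables print an "R²" column that the
protocol never defines; it is not computed here.

## Attention analyses

* **Temporal offset**: per output step, the circular signed distance from
  the attention argmax to the output index, averaged over steps (wrapped
  to (−T/2, T/2]; the cycle is periodic, so an argmax that wraps past the
  end still reads as the injected lag).  At desk scale individual
  replicates are noisy — attention over flat waveform regions carries no
  gradient — so the headline offset is averaged over seed replicates.
* **Top-k spatial ranking**: channels ranked by attention weight at the
  decoder steps nearest 0 %, 50 % and 100 % of the cycle (nearest step on
  the 20-grid; ties in weight break toward the lower channel index).
* **Shortcut probe**: a model that merely reproduces an average waveform
  keyed to movement duration would survive timing perturbations that break
  a genuine temporal correction.  The probe feeds the model base cycles
  warped by random frequency factors (U(0.8, 1.25), resampling the
  periodic waveform) and circular phase rotations (U(0, 1) cycle) — both
  ranges are ours, the protocol gives none — applied identically to input
  and target, and t-tests the resulting Er values against zero.  A
  shift-specialised model degrades (mean Er > 0).

## Validation protocol and problem sizes

`gaitrefine.experiments` bundles the protocol the acceptance script and the
heavy tests run; sizes are chosen to complete on one CPU core in minutes:

1. **Published-table consistency** — for five cells of the walking/running
   statistics tables, the printed 95 % CI and p follow from the printed
   (mean, d, n) alone via sd = |mean/d|; recomputed and matched at table
   precision.  Cells whose printed values round inconsistently (the inputs
   are themselves rounded to 2 significant figures) are excluded.
2. **Reference agreement** — t/p/CI/d/RMSE against scipy closed forms on
   1000 random datasets, Tukey p-values against statsmodels on 100; all to
   1e-9.
3. **Temporal recovery** — +2-sample shift (75 ms on a 750 ms cycle),
   6 subjects × 4 speeds, noise sd 0.02, hidden 64, 100 epochs, LOSO,
   5 seed replicates: held-out mean Er < 0 in ≥ 4/5 seeds and seed-averaged
   attention offset within 2 ± 1 samples.
4. **Spatial recovery** — measured target = 0.6·sim(target) + 0.4·sim(donor),
   4 subjects × 4 speeds, 20 channels, hidden 64, 100 epochs, LOSO:
   held-out mean Er < 0 and the donor in the top-10 ranking at ≥ 2 of the
   3 cycle fractions with above-median weight.
5. **Shortcut probe** — 32 strong frequency/phase variants against a
   criterion-3 model: mean Er > 0.
6. **Memorisation** — one paired cycle, hidden 700, 700 epochs, batch 1,
   classic wiring with teacher forcing, no clipping (the configuration in
   which raw capacity is the only limit): free-running training RMSE
   < 0.05 standardized units.

## What passing these checks does and does not show

The generator produces smooth, burst-like, bounded envelopes with known
injected distortions.  Passing recovery checks shows the implementation
learns and localises exactly the distortion families it models.  Real
simulator errors are not exactly circular shifts or fixed mixtures; real
EMG envelopes contain measurement artifacts, within-subject cycle-to-cycle
variability and muscle-specific distortion magnitudes that the generator
does not emulate.  Results on synthetic data therefore validate the
machinery, not the clinical effect sizes; reproducing the published
improvement-rate tables requires the original public walking/running
datasets.

## Known limitations

* The interpretable default head outputs affine maps of convex input
  mixtures; targets far outside the input's value range cannot be fit
  exactly (use the classic wiring where raw capacity matters).
* Attention localisation at desk scale (hidden 64, 100 epochs) is noisy
  over flat waveform regions; offsets are meaningful as seed averages.
* Batch-1 training in numpy is matvec-bound; full-scale runs (700 units,
  700 epochs) take minutes per model on one core.
* LOSO folds train one model per held-out subject; cost grows linearly
  with subjects.
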