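# Methods

## Signal model and containers

A recording is a ``samples × channels`` float64 matrix with a sampling rate
and two per-sample annotations: movement-class label and trial index. Trials
are contiguous; every segment-aware operation (filtering, windowing,
covariance pooling) iterates over trials so that nothing straddles a
boundary. The reference acquisition conditions are 1024 Hz, ~20 movement
classes, 6 s holds repeated 6 times, 56 monopolar electrodes.

## Electrode layout and montage

The layout is a grid of ``n_around × n_along`` forearm electrodes (the
*along* axis runs proximal→distal, parallel to the muscle fibers) plus hand
chains. Channels are numbered grid-first in around-major order, then chains.
Bipolar derivation differences electrodes adjacent along the fiber direction
(anode = proximal) and consecutive electrodes within each chain, giving
``n_around·(n_along−1) + Σ(g−1)`` pairs — 45 for the 8×6 + (2,3,3) reference
layout. The fiber direction is taken as the *along* axis: it is the only
orientation consistent with 45 bipolar channels from 56 electrodes. The
differencing sign is fixed (proximal minus distal) for reproducibility; no
variance-based computation downstream depends on it.

## Preprocessing

Order-5 Butterworth high-pass at 30 Hz, then a second-order IIR notch at
50 Hz with quality factor 30 (≈1.7 Hz bandwidth; the notch design is
configurable since only its center frequency is dictated by the power line).
Both are applied zero-phase (forward–backward) per trial segment — the
natural choice for offline analysis; users who need causal filtering should
note the effective magnitude response is squared. Filtering is restarted per
trial to keep step transients from leaking across trial boundaries.

## Features

Windows of ``floor(150 ms · fs)`` samples with ``floor(100 ms · fs)`` stride
(153/102 at 1024 Hz; 59 windows per 6 s trial), never spanning trials, each
inheriting its trial's class label.

- **TD** (4/channel): MAV, zero crossings, slope-sign changes, waveform
  length. The ZC/SSC deadband defaults to 0 — no threshold is inherent to
  the definitions — but is configurable because classic implementations use
  a small one against noise-induced counts.
- **TDAR** (7/channel): order-6 autoregressive coefficients plus RMS. AR
  estimation uses the Burg method (stable on 153-sample windows, no
  windowing loss), with the prediction-form sign convention
  ``x_t = Σ a_i x_{t−i} + e_t``. A zero-variance window has undefined AR
  structure and returns zero coefficients.

Feature matrices are laid out channel-block-major so a channel subset is a
column slice; greedy selection reuses one feature pass.

## CSP / MCCSP

Per-class covariances are ``d × d`` channel covariances of the class's
mean-centered samples pooled across its trials (concatenated samples, not
trial-averaged; normalization ``n−1``; no trace normalization). CSP solves
``Σ_a w = λ (Σ_a + Σ_b) w`` via `scipy.linalg.eigh`, scaling eigenvectors so
``W(Σ_a+Σ_b)Wᵀ = I``; then ``WΣ_aWᵀ`` and ``WΣ_bWᵀ`` are diagonal with
eigenvalue pairs summing to one, patterns are ``W⁻¹``, and components are
sorted by descending target-class eigenvalue.

Numerical choices: the covariance pair is solved **unperturbed** when the
composite is well-conditioned, so the diagonalization identities hold to
solver precision (~1e-15); a diagonal ridge of ``1e-8·(trace/d)`` is added
only when the composite's smallest eigenvalue falls below ``1e-10`` of its
largest (rank-deficient montages, too few samples). An always-on ridge would
itself limit the diagonalization residual to ~1e-8.

Multi-class extension is one-versus-rest: for each class, CSP against the
element-wise **sum** of the other classes' covariances. The rest ("no
movement") class participates in the OvR problems by default — it is a class
the controller must recognize — and can be excluded by passing an explicit
class list. Channel picking takes the row of maximal absolute coefficient in
the first and last pattern columns (eigenvector sign is arbitrary, hence
absolute value; ties → lowest channel index). Occurrence ranking breaks
count ties by lowest channel index, making the whole pipeline deterministic.

## SFS and FMS baselines

SFS evaluates, at each step, the current set plus each remaining candidate
(ascending index, strict improvement required, so accuracy ties resolve to
the lowest index) and keeps the argmax. The default inner evaluation is TD
features + LDA on the half/half temporal holdout; both are configurable, and
a custom scoring callable can replace the classifier entirely. The
evaluation count for ``n`` of ``d`` channels is ``(2d+1−n)·n/2``.

FMS is implemented as the Fisher-score special case (linear-kernel
reduction) of the Fisher–Markov selector; the kernelized Markov-random-field
formulation is deliberately out of scope. Features with zero within-class
variance in every class but distinct class means receive an infinite score
and rank first; constant features score zero. Feature ranks map to channels
by integer division by the features-per-channel count, deduplicated keeping
the best-ranked occurrence.

## Classification and protocols

LDA (pooled covariance, empirical priors, SVD solver — singular pooled
covariances are handled in the data span; with one sample per class the
discriminant degenerates to nearest class mean, which is what is fitted,
with a warning). KNN uses Euclidean majority vote, k = 5 by default (no
canonical k exists for this protocol; 5 is the usual compromise between
noise sensitivity and locality), voting ties to the smallest label.

- **5-fold CV**: seeded, stratified by class (plain random folds would add
  variance; the fallback to unstratified folds when a class has < 5 windows
  is warned about). Reported accuracy is the mean over folds.
- **Half/half holdout**: within each class, the earlier ``ceil(n/2)``
  windows train and the later ones test. The split is per class because a
  purely positional split of a class-grouped matrix could leave entire
  classes unseen; per-class splitting preserves the train-early/test-late
  intent. Deterministic, no RNG.

Accuracy is ``100 · correct / total`` decisions.

## Pipeline

`run_channel_curve` ranks channels once per method (MCCSP shared across all
feature/classifier combinations; FMS per feature set; SFS per combination),
then sweeps top-*k* subsets over a channel-count range, evaluating MCCSP/FMS
subsets with CV5 and SFS subsets with the holdout (cross-validating a subset
that was itself chosen by holdout accuracy would be circular). ``k`` values
beyond a ranking's length yield NaN rows so the sweep cardinality
``|methods|·|features|·|classifiers|·|k|`` is stable. SFS dominates runtime
(its cost is quadratic in candidates); the sweep caps its depth at 8 by
default and warns, since the orderings of interest are preserved at small
depth.

## Synthetic generator

Each trial of each class is white Gaussian noise band-pass filtered to
20–350 Hz (order-4 Butterworth, zero-phase) — the standard amplitude model
for interference-pattern surface EMG — with the class's informative channels
multiplied by a gain (variance contrast = gain²). An optional AR(4) shaping
filter gives a low-frequency-weighted spectrum; off by default. Rest is a
class with no informative channels. Inter-trial rest gaps are not
synthesized. Identical seeds give bit-identical output.

What the generator does **not** emulate: motor-unit structure,
volume-conduction correlation between neighbouring electrodes, force and
fatigue drift, electrode shift, within-class nonstationarity. Passing tests
therefore demonstrate algorithmic correctness and recoverability of planted
spatial-variance structure, not clinical performance on patient recordings.

## Validation problem sizes

The test suite validates at scaled-down but structurally faithful sizes:
planted-recovery runs use 16 channels with 4–8 classes at the full 1024 Hz /
6 s × 6 trial protocol; CSP identities are checked on random SPD pairs up to
d = 20 against an independent ``inv(Σ_a+Σ_b)Σ_a`` eigendecomposition oracle;
sweep tests use 8-channel, 2 s × 2 trial recordings. These sizes are the
package's chosen validation conditions; all scale linearly to the full
56-channel protocol.

## Known limitations

- The OvR pick rule takes exactly two channels per class: the first pattern
  claims the class's single most elevated channel, and the last pattern
  claims a channel that is maximally active in the *rest* of the classes.
  When a class elevates several channels equally, only one of them can be
  picked from that class's own problem, so the ranking covers at most
  ``2·C`` channels and need not contain every informative channel — a
  property of the selection rule itself, visible in the planted-recovery
  tests. With one dominant channel per class, recovery is essentially
  perfect.
- MCCSP ranking is invariant to a uniform amplitude rescaling of the whole
  recording but **not** to per-channel rescaling, which changes the
  covariances; channel gains should be physically meaningful (no per-channel
  normalization is applied anywhere, matching the no-normalization feature
  pipeline).
- Offline analysis only: zero-phase filtering and whole-trial windowing are
  not causal; no real-time decision streaming.
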