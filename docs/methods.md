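# Methods

This note documents the models implemented in `evodecode`, the choices made
where the design was genuinely open, and what the synthetic benchmark does
and does not establish.

## Decoding model

Each decoder is a partially connected recurrent network with one hidden
layer, one tanh output neuron, and tanh hidden units.  Admissible
connections are input→hidden, input→output (skip), hidden→output, and one
self-recurrence per hidden unit; hidden↔hidden cross connections are
excluded, which also fixes the fully connected reference count used by the
connection ratio,

    R_c = N_c / N_f,    N_f = n_in·N_h + n_in + N_h + N_h,

so `R_c` is reproducible from a genome's node set alone.  The input at bin
`t` of a trial is `[N(t), N(t_pre), v_error]` — spike counts of the current
and preceding bin for all k sorted units plus the error feedback
`v_error = |v(t_pre) − v̂(t_pre)|` — giving 2k+1 inputs (2k for the
no-feedback variant).  Horizontal and vertical velocity each get their own
network.  Trials are 11 bins of 33 ms; the hidden state is reset to zero at
every trial start, since trials are separate movements.

Training is full-batch backpropagation through time on the summed
squared-error loss, unrolled over the 11 bins, with the learning rate
applied to the mean per-bin gradient so that the step size is independent of
how many trials are in the batch.  Training and validation errors are
likewise reported as mean squared error per bin, making the early-stopping
statistics scale-free across set sizes.  During training of a feedback
decoder the error input is filled at each unrolled step from the network's
own previous-bin prediction against the recorded velocity, and no gradient
is propagated through that path (the standard NARX-style teacher signal);
this makes the training-time input distribution identical to offline
test-time decoding.

Because the output is tanh-bounded, target velocities are rescaled per axis
into [−0.9, 0.9] before training and inverse-scaled on prediction.  The map
is a symmetric max-abs gain (training-set |v| maximum lands on 0.9), not a
min–max affine map: velocity is a signed quantity whose physical zero is
meaningful, and preserving it matters for the feedback loop.  When the
decoder is uncertain, a tanh output relaxes toward 0; under max-abs scaling
that means "relax toward rest", which degrades gracefully, whereas a min–max
map sends the resting velocity to an extreme of the output range, so the
same relaxation (and any learned "large error → retreat" response on the
feedback input) drives predictions toward a velocity extreme and can invert
the decoded trajectory under drift.  Spike counts are z-scored per unit with
training-set statistics; the feedback signal lives on the scaled velocity
axis.  Weights are initialized uniform on (−0.5, 0.5).

## Structure search

The population starts from minimal genomes: one hidden neuron, one random
neuronal input→hidden connection, one random neuronal input→output skip, the
error input wired to hidden or output with equal probability, and a
self-recurrence with probability 0.5.  Note that when the error input is
wired to the hidden neuron, the hidden neuron initially has no outgoing
connection; a hidden→output connection must be added by mutation before that
path influences the output.  We deliberately kept the minimal three-
connection construction rather than adding a guaranteed hidden→output edge,
so initial networks have 3 or 4 connections.

Per generation, each offspring is produced by two size-2 tournaments
(fitness `1/(1 + E_tr)`), structural crossover with probability `p_c`
(concatenate both parents' hidden layers and unite their connections; a
duplicate input→output slot keeps the fitter parent's weight), and mutation
with probability `p_m` (add one uniformly chosen absent admissible
connection).  A no-crossover offspring is a copy of the fitter parent and
retains its age; a crossed-over offspring is a new structure with age 0.
Inheritance is Lamarckian: trained weights carry over, so offspring start
from their parents' solutions.

Cluster-based pruning scores each hidden neuron by the standard deviation
over all trial-bins of its activation times the magnitude of its outgoing
weight (a neuron that never moves the output scores zero), splits the scores
into a better and a worse group with an exact 1-D two-means partition, and
removes each worse-group member with probability 0.5.  Both clusters are
nonempty by construction, so the hidden layer can never be emptied; genomes
with one hidden neuron or indistinguishable scores are left alone.  The
significance measure is pluggable.

Age-based survival selection replaces each genome with a fresh minimal
network with probability `min(1, 0.1 · max(0, age − 10))`; survivors age by
one generation.  The genome with the generation's lowest validation error is
exempt, so the best-so-far performer is never lost to replacement.

Evolution stops when `GL(τ) > P_k(τ)` (strict), with

    GL(τ)  = E_va(τ) / min_{ω≤τ} E_va(ω) − 1
    P_k(τ) = [ Σ_{ω=τ−k+1..τ} E_tr(ω) ] / [ k · min_strip E_tr ] − 1,  k = 5,

or at the generation budget.  The decoder returned is the genome with the
lowest validation error seen in any generation.  Variants: ECPNN-EFWC
disables age-based replacement, ECPNN-EFWA disables pruning, ECPNN drops the
error input, and RNN-EF skips evolution entirely, training a fully connected
recurrent network whose hidden width is matched to the evolved decoder.

Defaults not fixed by the training procedure itself — population 30 (16 in
the desk-scale benchmarks), tournament 2, crossover and mutation
probabilities 0.75, pruning removal probability 0.5, replacement onset age
10 with slope 0.1 — are exposed in `EvolutionConfig`.

## Evaluation

Daily accuracy is Pearson's r between decoded and recorded velocity series,
concatenated over all of a day's trials per axis (per-trial series of 11
points are too short for a stable correlation), then averaged over the two
axes.  Offline decoding uses the recorded previous-bin velocity in the
feedback term, exactly as in training; `zero` and `self` feedback modes are
provided for ablation.  The feedback at bin `t` uses only data through bin
`t − 1` — perturbing `v(t)` cannot change `v̂(t)` (tested).  r on integrated
positions instead of velocities is deliberately not the default.

Hyperparameter selection uses K-fold cross-validation over a `p_c × p_m`
grid (the full protocol is 5-fold over 7×7 values 0.6–0.9; the experiment
driver defaults to a reduced grid because the full surface is hours-scale on
one CPU).

## Synthetic recordings

Each trial's latent reach is a bell-shaped speed bump (Gaussian profile,
randomized amplitude, ±1-bin peak jitter, σ = 2.2 bins) along a direction
drawn per trial (N(π/4, 0.6 rad)), with small isotropic velocity noise
(sd 0.02).  Unit i fires Poisson with

    λ_i(t) = exp( b_i + m_i · |v(t)| · cos(θ_v(t) − PD_i) ) · Δ,

a log-linear cosine tuning: baseline log-rates b_i ~ N(log 40 Hz, 0.3),
modulation depths m_i ~ U(1.5, 2.5), preferred directions uniform.  The
99-ms neural lead is realized as window alignment: counts are generated from
the velocity three bins later in a longer latent trajectory and the stored
targets are the aligned velocities, mirroring how the pre-press window
convention pairs spikes with the kinematics they encode.  Poisson means are
clipped at 50 per bin as an overflow guard.  The baseline/depth ranges were
calibrated once so that a ridge readout of stationary data scores r ≈ 0.85–
0.9 — the decodability regime typical of the few-unit motor-cortex
recordings this simulator stands in for — and were not revisited afterwards.

Across-day drift is a cumulative random walk per unit: Gaussian steps on the
baseline (sd 0.12/day) and log modulation gain (sd 0.12/day), von Mises
rotation of the preferred direction (sd 0.15/day), permanent dropout with
probability 0.03/day, plus per-trial within-day gain jitter (sd 0.08).
Cumulative walks — rather than i.i.d. day effects — make late days
progressively harder, which is the property the long-term benchmark needs.
The magnitudes were calibrated so that a no-feedback decoder's daily r
declines across the ten test days while the task stays decodable; markedly
stronger drift (e.g. 0.2–0.25 rad/day rotation) pushes the feedback input
far outside its training distribution and destabilizes the feedback decoder
itself, so the calibration sits deliberately in the mild-drift regime.

What the simulator does not emulate: spike-sorting errors and unit
splitting/merging, non-Poisson count dispersion, correlated noise across
units, within-trial firing-rate adaptation, behavioral learning across days,
and any closed-loop interaction between decoding errors and the animal's
strategy.  Passing the synthetic benchmarks therefore shows the pipeline is
correct and that the feedback mechanism behaves as described under the
modeled drift; it does not certify performance on real recordings.

## Benchmark problem sizes

The packaged benchmarks run at desk scale: population 16, generation budget
25–30, 40 BPTT epochs per training call, 8 units, and 35–50 trials/day
(12 days for the drift benchmark, with days 1–2 for training/validation and
days 3–12 for testing; 5 seeds for the stationary recovery check and 10 for
the drift comparison).  These sizes keep a full run in the minutes range on
a single CPU while leaving every mechanism exercised; all of them are
ordinary config fields.

## Numerical and degenerate-input choices

* Gradient check: central differences with step 1e-6; analytic and numeric
  gradients agree to better than 1e-4 relative on random small genomes.
* `GL` and `P_k` raise on a zero running-minimum or zero strip-minimum
  (perfect fit) rather than returning infinities.
* Pearson r raises on fewer than 3 points or zero variance.
* A trial's first bin has no preceding bin: the preceding-count block is
  zero and the feedback input is 0.
* Target rescaling guards a degenerate (constant) training axis with an
  epsilon range; per-unit z-scoring floors the SD at 1e-6.
* Divergent training (non-finite loss) aborts with a diagnostic rather than
  silently returning NaN weights.

## Known limitations

* The feedback benefit under drift is regime-dependent (see calibration
  above); the implementation reports whatever the data give and the
  directional benchmark is a median over seeds, not a guarantee per seed.
* The exact pruning-significance measure, replacement schedule and
  population hyperparameters of the original method are not published in
  full; the versions here are documented defaults behind config fields, and
  numerical results should be compared across variants within this
  implementation rather than against externally reported absolute numbers.
* Only offline (open-loop) evaluation is implemented; there is no real-time
  decoding loop.
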