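# Methods

`ribofret` implements a complete desk-scale analysis chain for
single-molecule FRET recordings of translating ribosomes: synthetic trace
generation with known ground truth, trace-selection quality control,
fixed-emission hidden-Markov idealization, aa-tRNA selection kinetics with
photobleach-corrected catalytic efficiency, pre-translocation tRNA-state
occupancy, and bootstrap significance testing. This note records the models,
the tunable parameters and their defaults, the numerical choices, and what
the synthetic data do and do not establish.

## The experimental picture being modeled

A surface-immobilized 80S initiation complex carries a donor-labeled
(Cy3) initiator tRNA in the P site. In **selection** experiments, ternary
complex — eEF1A·GTP with an acceptor-labeled aa-tRNA (LD655-Phe-tRNA or
LD650-Lys-tRNA) — is stop-flow delivered at 10 nM and decoding is followed
through FRET between the two tRNAs at a 15 ms frame interval. Productive
events climb stepwise through FRET ≈ 0.2 (initial binding/codon
recognition) and ≈ 0.46 (GTPase activation) to a stable ≈ 0.72
(accommodation); non-productive events fluctuate between 0.2 and 0.46 and
end in ternary-complex dissociation (FRET 0). In **pre-translocation**
experiments the complex formed after peptide-bond formation exchanges among
classical (FRET 0.72; 0.61 for the LD650/Lys dye pair), hybrid-1 (0.42) and
hybrid-2 (0.22) tRNA configurations.

## Synthetic data generator

The generator (`ribofret.simulate`) is first-class, tested code. Its
defaults *are* the study conditions; they are not tuned per run.

**State dynamics.** Pre-translocation presets are stationary three-state
continuous-time Markov chains realized exactly (Gillespie) and discretized
by assigning each 15 ms frame the state occupied for the majority of the
frame (camera-integration analogue; ties break to the lower state index).
The generator matrix uses the construction Q_ij = k_ex·π_j (i≠j), which has
any prescribed occupancy π as its stationary law; k_ex = 2 s⁻¹ gives mean
dwells of 0.6–0.8 s, well resolved at 15 ms. `pretrans-low` encodes 15%
classical occupancy, `pretrans-high` 20%; the non-classical remainder is
split 55:45 between hybrid-1 and hybrid-2 (the split does not affect the
classical fraction).

Selection presets draw a productive accommodation time per molecule from a
two-phase hazard starting after the stop-flow dead time: a fast phase with
hazard λ = (kcat/KM)·[TC] and amplitude 0.9, and a minor slow phase
(0.05 s⁻¹, amplitude 0.1). The four presets encode kcat/KM = 50, 71, 27 and
36 µM⁻¹s⁻¹ at 10 nM ternary complex, i.e. fast hazards of 0.50, 0.71, 0.27
and 0.36 s⁻¹. Before accommodation the molecule shows transient
non-productive excursions (0.2 ↔ 0.46, attempt rate 0.25 s⁻¹, dwells of
60–80 ms) that dissociate back to zero FRET; the stepwise 0.2 → 0.46
progression is placed immediately before the accommodation time so that
reaching 0.72 happens exactly at the drawn time and the encoded hazard is
exact.

**Photophysics.** Per live frame the FRET efficiency is drawn from a
Gaussian at the state's mean/width truncated to [0,1]; acceptor = E·I and
donor = (1−E)·I with I = 1000 a.u., plus a 100 a.u. background and 40 a.u.
Gaussian noise per channel. The donor bleaches once, at an exponential time
with rate 0.1 s⁻¹, after which both channels show background only. Blinking
is a Poisson process (0.02 s⁻¹, exponential dark times of mean 60 ms). The
intensity scale and noise were chosen so that default traces clear the 8:1
and 6:1 SNR gates with margin; the blink rate is low because the
experiments this emulates include triplet-state quenchers precisely to
suppress blinking, and because a blink rate that grows trace-failure
probability with trace length would couple quality control to molecule
lifetime and distort arrival kinetics. The stop-flow dead time defaults to
0.25 s (not reported by the source experiments; chosen to be resolvable at
15 ms).

**Movie lengths.** Pre-translocation movies are 600 frames (9 s).
Selection movies are 3000 frames (45 s): with a 0.1 s⁻¹ bleach rate, 98.9%
of molecules bleach within the movie, so the QC requirement of an observed
bleach event conditions on almost nothing. At shorter movies that
conditioning measurably distorts the observed arrival curve (the exact
conditional curve acquires a negative component of amplitude
e^(−k_bleach·T_movie)).

**Reproducibility.** All randomness flows from one integer seed through
`numpy` seed sequences; trace *i* uses the substream
`SeedSequence(seed, spawn_key=(i,))`. Datasets are byte-identical across
runs for a fixed seed. A consequence of indexing substreams by trace number
alone is that two presets generated from the same seed share their
underlying uniform draws — arrival times are scaled copies — so estimates
from same-seed condition pairs have strongly correlated errors. The test
suite exploits this deliberately (paired control/knockdown comparisons,
mirroring same-session imaging) and uses different seeds where independent
errors are wanted.

**What the generator does not emulate:** acceptor photophysics beyond
uniform blinking, EMCCD gain statistics, spectral crosstalk and gamma
factors, stage drift, multi-step bleaching of aggregates (two-molecule
spots are constructed in tests by summing traces), and any dependence of
bleach rate on FRET state. Passing tests therefore demonstrate correct
recovery under idealized Gaussian photophysics, not robustness to every
camera artifact of real recordings.

## Quality control

A trace passes if it shows exactly one catastrophic bleach step, summed
signal ≥ 8× the background noise SD and ≥ 6× its own SD, fewer than four
blinks, and donor–acceptor Pearson r < 0.5. Operational definitions the
experimental description leaves open:

* "Signal" is the summed donor + acceptor intensity — total emission is
  what vanishes in one step at the donor bleach.
* The dark threshold is (2·background) + 3·√2·background-noise SD on the
  summed signal. Isolated single-frame noise pops do not interrupt a dark
  run. The bleach is the final dark run that reaches the end of the trace
  and lasts ≥ 5 frames; earlier dark runs that recover are blinks (runs
  longer than 20 frames still count but raise a warning). Additional
  sustained, never-recovering downward level steps (detected on a
  median-filtered trace at 6σ) count as extra bleach steps, so the first
  bleach of a two-molecule aggregate disqualifies the spot.
* `snr_background` = (mean pre-bleach total − post-bleach mean) /
  post-bleach SD, estimated from the post-bleach tail when ≥ 10 frames are
  available, else from metadata background values (reporting fallback).
* The correlation gate uses the signed Pearson r of raw intensities over
  pre-bleach frames (anticorrelated FRET dynamics sit near −1 and pass;
  correlated aggregates fail); the background-subtracted variant is also
  reported and is identical under a constant background.

No-bleach traces fail QC. Filtering is idempotent and each failure reason
maps to exactly one criterion.

## Idealization

States are *defined* by their Gaussian emissions — selection: 0.0 ± 0.05,
0.2 ± 0.075, 0.46 ± 0.075, 0.72 ± 0.075; pre-translocation: 0.22 / 0.42 /
0.72 ± 0.075 (0.61 ± 0.05 for the Lys dye pair) — and the "± width" is
interpreted as the emission SD. Emissions and the initial distribution
(unbound for selection, uniform for pre-translocation) stay frozen; only
the transition matrix is estimated, by expectation–maximization pooled over
all traces of a dataset (per-trace estimation is statistically unstable at
desk-scale trace counts; the pooling choice is flagged in reports). EM
starts from a sticky matrix (self-probability 0.95) and stops when the
log-likelihood improves by < 1e-6 per frame or after 500 sweeps
(non-convergence returns the best-so-far estimate with a flag). Per-trace
paths are then Viterbi decodes under the shared model; hmmlearn supplies
the numerics. FRET is computed as (A−bg)/((A−bg)+(D−bg)) over pre-bleach
frames, clamped to [−0.2, 1.2] for fitting (0–1 in reports); frames with
non-positive total are set to 0 and a trace is dropped if they exceed 10%.

## Selection kinetics

A trace is *productive* when its idealized path holds the accommodated
state for ≥ 2 consecutive frames (30 ms) before bleaching — one frame is a
noise spike, two is the smallest dwell the frame rate can vouch for — with
the arrival at the first frame of that dwell. Non-productive traces visit
the intermediate states and return to zero FRET; everything else is
no-event. The cumulative arrival curve counts, per frame, the fraction of
all QC-passed traces that have arrived, and is fit with

  N(t) = 1{t>t0} · [A1(1−e^(−k1(t−t0))) + A2(1−e^(−k2(t−t0)))].

**Fitting strategy.** The two-phase model with five free parameters is
poorly identified on a noisy cumulative curve: its errors are strongly
autocorrelated (a cumulative count is a random walk around its mean), and
near-equivalent fits exist in which a spurious extra component chases a
correlated bump, scattering the "fast rate" wildly. The fit is therefore
hierarchical. Stage one fits a single exponential + dead time (multistart
over k ∈ {0.1, 0.5, 2, 5} s⁻¹), giving a compromise rate k_s that provably
lies between the true rates for a genuine two-phase curve. Stage two refits
the full model with k1 confined to [k_s, 2.5·k_s] and the slow rate below
0.35·k_s, so the slow component can only absorb the slow tail. In the
pipeline the slow rate is additionally *pinned to the independently
measured donor bleach rate*: events feeding the slow phase are rare within
the observation window and their observed rise is dominated by competition
with bleaching (observed slow rate = λ_slow + k_bleach with λ_slow ≪
k_bleach), so a free slow rate is the least identified parameter in the
model. With k2 pinned, the total amplitude is read off the saturated
plateau and only the fast rate, the amplitude split and the dead time
remain free. Residuals are weighted by the per-frame binomial SEM (floored
at 20% of its maximum). A free slow phase that would rise by less than 10%
of its amplitude within the window is dropped — with k2→0 its amplitude
multiplies zero and is meaningless. In simulations at 400 traces this
estimator recovers the encoded kcat/KM with ≈ ±9% SD and ≲3% bias,
close to the information floor set by the number of observed arrivals.

**Photobleach correction.** The donor bleach rate is the censored
exponential MLE over the *total* dataset (observed bleach times plus movie
lengths of never-bleached traces): k̂ = events / Σ(observed times). The
apparent fast rate exceeds the true arrival hazard by the bleach rate
(independent competing exponentials), so kcat/KM = (k1 − k_bleach)/[TC].
The dead time t0 is free by default (`fix_t0` freezes it); residual
weighting defaults to the binomial SEM in the pipeline and to uniform when
no SEM is passed.

## Occupancy

Dataset-level occupancy is frame-weighted: total frames in a state divided
by total analyzed frames, summing to 1 exactly; the trace-averaged variant
is reported alongside (the two differ when trace lengths vary). SEMs come
from bootstrap over traces. The FRET histogram uses 0.02-wide bins on
[0,1] — half an emission SD, fine enough to resolve states 0.2 apart —
with each trace's histogram normalized to unit mass before averaging so
long traces do not dominate, and the across-trace SEM per bin. The
three-Gaussian fit is initialized at the model's emission means (0.61 for
the Lys classical variant) with free means, widths and amplitudes;
components are reported sorted by mean and "amplitude shares" are
area shares (amplitude × width, normalized).

## Bootstrap testing

Uncertainties are trace-level bootstrap SEMs: resample traces with
replacement, re-run the estimator (kcat/KM replicates refit the curve from
the point fit's parameters; occupancy replicates re-pool count vectors).

Two conditions are compared with a shifted-mean-null Welch test. On
*bootstrap replicate distributions*, the replicate SD already estimates the
estimator's SEM, so t = (mean_A − mean_B)/√(sd_A² + sd_B²), and each of the
n_null null t statistics is formed by drawing one value from each replicate
set after translating both to their pooled mean: the difference of one draw
per side has exactly the numerator's spread under equal means, so the test
is calibrated — which the plain Welch formula with variance/n_boot in the
denominator is not when fed n_boot replicates (its observed t grows like
√n_boot under the null). The raw-sample operations `welch_t` and
`shifted_null_pvalue` keep the classical variance/n denominator and
resample at the original sizes; they are calibrated for per-unit samples.
P-values use the add-one rule p = (1+c)/(n_null+1) and a zero count is
reported as the bound p < 1/n_null. Like any Welch-type test the procedure
is slightly anticonservative at small condition sizes (the data-level
variance fluctuation is absent from the resampled null); calibration
simulations use 100 traces per condition, where the type-I error at
α = 0.05 is within a point of nominal.

The bootstrap unit is the individual trace. The source experiments
resampled whole datasets (two to five per condition); trace-level
resampling is the finer desk-scale analogue and is flagged in reports.

## Problem sizes

Defaults used by the test suite and the acceptance script: 400 traces per
selection preset (3000 frames), 500 traces per pre-translocation preset
(600 frames), 200 bootstrap replicates, 10⁴ null t statistics for
comparisons (10⁶ reproduces the published bound and runs in seconds on the
replicate-pair null), 200 replicate pairs at 100 traces per condition for
type-I calibration. A full selection analysis takes ~10 s on one CPU; the
acceptance script completes in a few minutes.

## Known limitations

* The arrival-curve estimator's seed-to-seed spread at 400 traces (~±9%)
  is close to its information floor; single-run kcat/KM values carry
  meaningful sampling error, which the bootstrap SEM reports honestly.
* Occupancy from Viterbi paths inherits a small assignment bias when blink
  frames (FRET ≈ 0) are assigned to the lowest-FRET state of a model
  without a zero state; at the default blink rate this is < 0.5 points.
* The three-Gaussian histogram fit estimates component widths inflated by
  channel noise relative to the emission definitions; amplitude shares are
  unaffected to first order.
* Transition-rate (kinetic) analysis of classical↔hybrid exchange, state
  number selection, and emission learning are out of scope by design.
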