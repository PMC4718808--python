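# Methods

## Setting and data model

A *session* is one continuous CA1 LFP channel (default 1 kHz sampling) with
per-unit spike trains and a trial table. Behavior is a context-guided
odor–reward task: 96 trials in 24-trial blocks; within a block one odor pair
is presented, the first odor of the pair is rewarded at ports 1–2 (side 1)
and the second at ports 3–4, and the second context (session midpoint)
reverses the contingencies. An analyzed trial is a nose poke sustained for
exactly 1.5 s; the odor is released 250 ms after poke onset; a trial is
*correct* if the poked odor was the rewarded one. Correct trials in one
context half therefore cover 8 odor–position combinations, with the two
odors rewarded on the same side (A/C, B/D) value-matched. Poke windows are
half-open, [onset, onset + 1.5 s). Only sessions with accuracy ≥ 0.75 enter
population analyses; halves can be analyzed separately via
`Session.half_sessions()`.

Four bands are fixed throughout: theta 4–12 Hz, beta 15–35 Hz, low gamma
35–55 Hz, high gamma 65–90 Hz, with coherency read out at 7, 20, 45 and
75 Hz respectively.

## Signal chain

Filtering uses a 3rd-order Butterworth band-pass applied forward and
backward (`sosfiltfilt`), i.e. zero phase. Zero-phase filtering is a
deliberate choice: spike phases are assigned by sampling the filtered
trace, and a causal filter's group delay would bias every preferred phase.
The whole-session trace is filtered once and trial epochs sliced afterwards,
so trial edges carry no per-trial filter transients; the cost is that very
occasionally energy from outside a poke leaks a few tens of ms into it,
which is negligible at these bandwidths.

Amplitude and phase come from the analytic (Hilbert) signal. Phase
convention: 0 rad at the oscillation peak, ±π at the trough, increasing in
time. Constant input has undefined phase and is flagged rather than guessed.

Spectrograms are multitaper amplitude estimates: 500 ms windows stepped by
50 ms over [−0.5, 1.5] s around poke onset, time–bandwidth 3 with 5 Slepian
tapers — the conventional defaults of the Chronux family of multitaper
tools, adopted here as the package's own choice. Normalization is mean
over trials, divided by a reference mean (baseline inter-trial spectra, or
the incorrect-trial average for the correct/incorrect contrast), then log₁₀.

Binned amplitude averages the instantaneous amplitude in six consecutive
250 ms bins of the poke; session-level bin × outcome means feed the
two-factor repeated-measures ANOVA.

## Spike-phase coherence

Significance and performance category come from the Hilbert-phase Rayleigh
test; magnitude and phase for correct-vs-incorrect comparisons come from
multitaper spike–field coherency. Keeping the two estimators separate lets
each do what it is good at: the Rayleigh test is exact about nonuniformity,
the multitaper coherency is a well-behaved magnitude on [0, 1].

The Rayleigh p uses the standard small-sample-corrected approximation
p = exp(√(1 + 4n + 4(n² − (nR)²)) − (1 + 2n)). A minimum of 25 spikes per
trial type is required (configurable); the approximation is unreliable below
~20 spikes, and records below the minimum are excluded and logged rather
than silently computed. Category rule at level α: (p_c < α, p_i ≥ α) →
correct-only; reversed → incorrect-only; both → all-trials; neither → none.
An undefined p (too few spikes) is treated as non-significant and logged.

Multitaper coherency at the band center f_c uses T = 1.5 s epochs and
half-bandwidth W = min(f_c − f_lo, f_hi − f_c), giving K =
clamp(⌊2TW − 1⌋, 3, 15) tapers — 8 for theta, 14 for beta, 15 for both
gammas — the most tapers that keep spectral concentration inside the band.
Spike-train transforms subtract the mean-rate term (count/N × taper
transform) so the DC pedestal does not leak into f_c. Tapered cross- and
auto-spectra are pooled over tapers and trials; the spike side is
conjugated so the coherency phase equals the Hilbert preferred phase.

Coherency magnitude is spike-count dependent (the shot-noise floor of the
spike spectrum scales with count), so correct/incorrect comparisons are
corrected by *explicit thinning*: the higher-count condition is randomly
subsampled to the lower count and the magnitude averaged over K_thin = 100
draws. Rate corrections for coherence are often specified only as
conceptually equivalent to spike thinning; explicit thinning is the
transparent, testable implementation, and because thinning a Poisson process yields a Poisson process the thinned
magnitude is distributed as a genuine low-rate recording. A validated
caveat: spikes deleted by a refractory period are *not* Poisson, and at
high rates refractory deletion slightly weakens locking, so the calibration
experiment for the correction uses ideal (refractory-free) units.

## Task information

I = Σᵢ Pᵢ (Fᵢ/F) log₂(Fᵢ/F) bits/spike, with occupancy Pᵢ computed as time
share (equivalent to trial share under the fixed 1.5 s pokes). Terms with
Fᵢ = 0 contribute zero; F = 0 (no spikes) is undefined and the record is
skipped with a log entry. Scores use correct trials only, over the whole
poke or the *before* [−0.75, −0.25) s, *odor* [+0.25, +0.75) s and *end*
[+1.0, +1.5) s windows. Significance: whole-trial condition labels are
permuted 1000 times (preserving within-trial spike structure) and the
observed score must strictly exceed the 95th percentile of the null — the
standard one-sided reading of exceeding the shuffle distribution's 95%
bound. The shuffle stream is seeded and bit-reproducible. Interval comparisons across a
preselected population use Friedman's test (d.f. = 2) with Tukey HSD post
hocs.

## Population statistics

Chi-square tests are plain Pearson statistics without continuity
correction — recomputation of the published values (e.g. 51.5455 for the
beta interneuron counts printed as 51.54, 38.21 for its correct-vs-incorrect
post hoc) confirms no correction was used. Post hoc pairwise category tests
are judged at α/3 (three comparisons per family). Category counts reported
only as a total plus pairwise Ns are recovered by the exact linear system
c = N − N_{i,a}, i = N − N_{c,a}, a = N − N_{c,i}, with a consistency check
that the solution sums to N.

Circular–circular correlation of preferred phases is the
Jammalamadaka–SenGupta coefficient with its asymptotic normal p-value
(reported circular correlations rarely identify their variant; this one is
fixed here and cross-checked against an independent implementation in the
tests). Wilcoxon
signed-rank comparisons use the normal approximation with tie correction
and report Z plus per-condition medians; all-zero differences return
(Z = 0, p = 1).

Amplitude co-modulation correlates the concatenated correct-poke samples of
each band pair. The surrogate null circularly shifts each band's
whole-session amplitude by an independent uniform offset in
[30 s, duration − 30 s] before window extraction — this preserves each
band's amplitude marginal exactly while destroying alignment — and a pair
is flagged when the observed r leaves the central 95% of 1000 such
surrogates. Note the null is honest only for aperiodic co-modulation; a
strictly periodic shared envelope survives circular shifting by design.

Repeated-measures ANOVAs (six time bins × two outcomes across sessions;
six band-pair correlations across units) are computed directly on the
balanced complete designs the pipeline produces, each effect tested against
its own effect-by-subject interaction; 0/0 on perfectly flat data is
defined as F = 0. Both are cross-checked against pingouin in the tests.

## Unit classification

Interneuron: mean rate ≥ 5 Hz, half-max width < 150 µs, peak-to-trough
< 350 µs. Principal: rate < 3 Hz with a broad waveform. Units in the 3–5 Hz
gap or with mixed features are *unclassified* and excluded — the
conservative reading; the original workflow also used waveform clustering,
which is out of scope here, so threshold classification may unclassify some
units a human sorter would keep.

## Synthetic sessions: what they emulate, and what they do not

Each band component is a carrier cos φ(t) whose instantaneous frequency is
an Ornstein–Uhlenbeck process around the band center (τ = 0.5 s, s.d. =
bandwidth/8, clipped to the band) — not a pure sinusoid — so filters and
multitaper estimators face realistic in-band wander. Amplitude follows a
piecewise-linear epoch gain over [−0.5, 1.5] s around each poke, separately
for correct and incorrect trials; the stock "late rise" profile ramps the
gain from 1 to 1.6 over the last second of correct pokes, emulating the
correct-trial-specific low-gamma dynamic. Broadband noise is a white + 1/f
mixture (default total s.d. 0.5, half the variance pink, against unit
carrier amplitudes); no amplitude scale is claimed for real recordings —
the default SNR is a calibration choice at which a κ = 1 unit with ~200
spikes is detected essentially always, verified in the tests.

Units are inhomogeneous Poisson processes: λ(t) = base_rate ×
tuning(trial condition) × Π_b exp(κ_b cos(φ_b(t) − μ_b))/I₀(κ_b) inside
qualifying pokes (locking can apply to correct pokes, incorrect pokes, or
both), thinned from a homogeneous envelope, then pruned by deleting any
spike closer than the refractory period to its kept predecessor (default
2 ms). The von Mises factor has unit mean over uniform phase, so mean rates
are preserved (validated to within 10%). Randomness is hierarchical: one
master seed spawns child streams in a fixed order (trial table, carriers,
noise, units), so adding a unit never changes the LFP, and identical
config + seed gives a bit-identical session.

What the generator does **not** emulate — and therefore what passing tests
do not certify about real data: cross-frequency coupling (phase–amplitude
nesting), spike-sorting contamination and drift, bursting/non-Poisson
interval structure beyond the refractory period, theta asymmetry and
harmonics, behavioral timing variability (pokes are exactly 1.5 s on a
regular schedule), and electrode-level artifacts. The validation studies
show the estimators are calibrated and recover known ground truth under the
stated model, not that the biological claims hold.

## Validation studies (sizes and expectations)

The `validation` module re-derives every stochastic guarantee at sizes
chosen to keep the whole suite and the acceptance script each within tens
of seconds on one CPU: Rayleigh calibration uses 500 unlocked units spread
over 5 LFP realizations (false-positive rate must sit in the exact binomial
99% interval around 0.05, per band); phase recovery uses 50 units per
κ ∈ {0.5, 1, 2} with ≥ 500 spikes each (preferred phase within ±10°,
observed mean R ≈ I₁(κ)/I₀(κ): ~0.24/0.44/0.68, strictly increasing);
the thinning correction is audited on 50 spliced 20-vs-10 Hz replicates
(mean absolute corrected gap < 0.02); the information shuffle null on 200
replicate sessions at 200 shuffles (untuned ≈ 5% flagged, 4×-tuned > 95%);
category recovery on a 60-unit population designed 70% correct-only; and
the two-factor RM-ANOVA interaction power on 50 sets of 8 small sessions
with the late low-gamma rise (> 90% detection, in practice ~100%).

## Known limitations

* Threshold-only unit classification (no waveform clustering).
* The multitaper spike–field coherency is the Chronux-style estimator; no
  pairwise-phase-consistency or PPC-style bias-free variants.
* The jitter null assumes aperiodic envelopes (see above).
* Occupancy-from-time equals occupancy-from-trials only because analyzed
  pokes have fixed duration; variable-duration epochs would need the time
  variant the code already computes.
* Odor–position information has 8 conditions within a context half; pooling
  both halves doubles the conditions, so conjunction analyses should be run
  per half-session (the pipeline's default split).
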