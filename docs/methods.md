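# Methods

## Signal model

A voltage-clamp recording is an ordered series of equal-length sweeps
sampled at rate *f* (Hz), stored in pA (amperes are converted on import by
an exact factor of 10¹²). Indexing is zero-based; sample *j* of sweep *i*
lives at absolute time `i·T + j/f` with *T* the sweep duration. Spontaneous
PSCs appear as fast transients of one polarity (negative-going for inward
currents) riding on a slowly varying holding current contaminated by
wide-band noise.

The unitary event is a difference of exponentials,

    g(t) = (A/A′)·[−exp(−t/τ₁) + exp(−t/τ₂)]   for t > 0, else 0,
    A′ = τ₂^(τ₁/(τ₁−τ₂)) / τ₁,

with rise constant τ₁ < decay constant τ₂. Its peak sits at
t\* = τ₁τ₂/(τ₂−τ₁)·ln(τ₂/τ₁) (1.07506 ms for τ₁ = 0.5 ms, τ₂ = 3 ms); A′ as
defined does not normalise the bracket's peak to A (the peak is ≈ 0.363·A
for the nominal constants), so simulated amplitudes are set by a separate
calibration (below).

## The four-step detector

**Smoothing.** Savitzky–Golay regression of order *p* over a centred
window of 2*m*+1 samples (*m* = "side points"). Interior points use the
classic filter (scipy); within *m* samples of either sweep edge the window
shrinks asymmetrically to the available samples, dropping the degree when
fewer points than coefficients remain, so no margin is lost and events near
sweep edges stay detectable. Defaults *p* = 3, *m* = 14. Note that cubic
S–G smoothing slightly *overshoots* the asymmetric PSC valley before
attenuating it: the measured amplitude of a fixed event is unimodal in
*m* (rising ≈ 1.5% up to *m* ≈ 14, then decaying to ≈ 67% at *m* = 50),
which is why mean-amplitude-versus-smoothness curves are unimodal rather
than monotone.

**Trend.** The holding level is a centred moving median over a 0.5 s
window, reflect-padded at the edges. The median is evaluated every tenth
of a window and linearly interpolated between evaluation points — a pure
implementation economy (the trend varies on second time scales) that
leaves the estimate invariant to constant offsets and essentially blind to
individual events (a 30 pA event moves it by < 0.05 pA).

**Initial search.** Candidates are local extrema of (smoothed − trend) in
the polarity direction exceeding 3 pA (the initial threshold), with a
2 ms minimum separation (the larger extremum wins). Two additional scale
rules emulate a multiscale peak search: a *dominance* rule discards any
candidate whose baseline-to-peak segment contains a sample more extreme
than its own peak (such a candidate is a ripple on the flank of a larger
event, which carries its own candidate), and positive polarity is handled
by negating the trace and reusing the negative-going path, so mirror
symmetry holds exactly, stage by stage.

**Baseline search.** Scanning backward from each candidate peak for at
most 10 ms, the baseline is the last sample at or above the local trend —
the point where the trace left the holding level before diving into the
event. When the whole window sits below the trend (an event riding on the
decay of a predecessor), the most opposite-going local extremum in the
window is used instead, identified by a first-difference sign change
confirmed by the discrete second derivative; with no extremum at all the
window edge is taken. The *baseline level* used for the amplitude is the
trend value at the baseline point: the trace's own sample there carries
the residual smoothed noise and, being the last up-crossing, would bias
every amplitude upward by a noise-dependent bonus (≈ +1.7 pA at σ = 6 pA
with *m* = 7) — enough to multiply the false-positive count several-fold.

**Final search.** The amplitude — smoothed peak against baseline level —
must reach the minimum amplitude (default 10 pA, boundary inclusive;
strict `>` is available). Events are reported with peak/baseline indices
and values, amplitude, absolute peak time, and a 0/1 selection flag.

**Decay fit.** For each event, `y(t) = y_inf + (y_peak − y_inf)·exp(−Δt/τ)`
is least-squares fitted from the peak to min(next event's onset, peak +
50 ms). Fits with fewer than 10 samples, a flat segment, no convergence or
τ outside (0, 1000] ms are flagged as failures, never silently zeroed.

## The synthetic benchmark

250 events are placed uniformly over (0, 250 s − 50 ms) at 10 kHz; overlap
is permitted, and an event overlapped beyond recoverability counts as a
miss. Each event's time constants are multiplied by one normal factor
(mean 1, SD 0.3, redrawn while ≤ 0.1) — a *shared* factor per event, which
is a pure time rescaling of the biexponential: the kinetics vary while
every analytic peak amplitude stays identical. (Independent per-constant
factors are available via `tau_jitter="independent"`; they spread the true
amplitudes with a CV of ≈ 24%, which puts a tail of events below any
realistic detection criterion and is not what calibrated benchmark
recordings look like.) One global constant converts conductance to
current such that the mean true peak is exactly 27.85 pA; every
amplitude-ratio result is invariant to this constant. White Gaussian noise
of SD 2, 6 or 10 pA is added samplewise under its own seed.

Scoring matches detected to true peak times greedily by ascending time
difference, one-to-one, within 5 ms (exposed as a parameter); matched
pairs are TP, surplus detections FP, unmatched truth FN. On
well-separated events the greedy matching attains the optimal assignment
(property-tested against an exhaustive oracle). TN — needed only to
complete the confusion matrix — counts 1-s grid segments containing
neither a true nor a detected event and never enters precision, recall or
F1. Degenerate ratios (zero denominators) are reported as missing, with
F1 = 0 by convention.

What the generator does *not* emulate: correlated or 1/f noise, series-
resistance and dendritic filtering, amplitude–kinetics correlations,
bursting (onsets are uniform, not clustered), and baseline drift. Passing
benchmarks therefore demonstrate correctness of the pipeline under the
stated noise model, not performance on every real recording.

## Retrieval layer

Unit files are found by recursive descent from a root folder; the pattern
matches the base name without extension, `?` standing for exactly one
character, case-insensitively; excluded folder names prune the walk at any
depth, also case-insensitively. Malformed files are reported individually
while loading continues.

Per unit and per group the layer reports event counts, mean amplitude and
frequency for all events (`[t]`) and for the selected block (`[s]`), with
group mean, SD (n−1) and SEM = SD/√n over units. Frequency is defined as
n_events divided by the time of the last event, because the unit file
stores only event times, not the recording duration; a user-supplied
duration can replace it. Cumulative relative histograms use equal-width
bins on [begin, end] with out-of-range values clipped into the edge bins,
so the curve is non-decreasing and ends at exactly 1.

Hypothesis tests: the two-sample K–S test on pooled selected-event
amplitudes or inter-event intervals (intervals are formed within units,
never across), with D the supremum ECDF gap and the p value from the
asymptotic Kolmogorov distribution at (√nₑ + 0.12 + 0.11/√nₑ)·D,
nₑ = nm/(n+m); the pooled-variance (Student) independent two-sample t-test
on per-unit means, two-sided, with zero-variance inputs resolved to
(t = 0, p = 1) when the means agree; and one-way ANOVA from the
between/within sum-of-squares decomposition, which reproduces F = t² and
the t-test p exactly for two groups. No multiple-testing correction is
applied.

## Numerical choices and problem sizes

Text floats are written as the shortest round-trippable decimal; reads
accept plain or scientific notation and both line endings. The benchmark
checks in the test suite and the acceptance script run the full 250-s,
2.5-million-sample benchmark; the σ = 6 grid covers side points 7–50 and
the σ = 10 amplitude sweeps cover 2–50 at minimum amplitudes 10 and 14,
each row a complete detect-and-score pass (≈ 1.5 s per pass). The miss
rate at σ = 10 is averaged over three noise realizations. Smaller
simulations (15–25 events) back the unit and property tests.

## Known limitations

The vendor multiscale peak-detection and backward-search routines the
original instrument used are not published; the rules above are a
reconstruction validated against the aggregate benchmark metrics, and two
of the printed figures — the false-positive count (≈ 5) at σ = 10 with
minimum amplitude 15, and the ≈ 20% attenuation of the best-case mean
detected amplitude at σ = 10 with minimum amplitude 10 — require a
noise-amplitude tail that is mutually inconsistent, under white Gaussian
noise, with the low false-positive rates this detector achieves in the
σ = 6 regime at light smoothing. This implementation favours detection
quality; its best-case mean amplitude consequently sits closer to the
true mean (≈ 6–7% below it) than the printed 20% reduction, and its
false-positive count at the σ = 10 settings is ≈ 0–1 rather than ≈ 5,
while the attenuation physics itself (S–G attenuation factor 0.820 at
side points 33) matches the printed ratio. The decay-fit window and the
5 ms matching tolerance are conventions, exposed as parameters. ABF
import is an optional adapter over `pyabf` covering episodic sweep
geometry only; gap-free mode and rates above 20 kHz are refused.
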