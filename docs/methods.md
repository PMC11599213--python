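# Methods

This note records the models, parameter choices and numerical conventions
behind `mea_ephys`, and what the synthetic benchmark does and does not show.

## Signal model and containers

A recording is a channels × samples matrix in microvolts at a nominal
30 kS/s, organised as 4 recording sites × 8 electrodes (`S<site>-E<electrode>`
labels).  Time is in seconds, 0-based, and every window in the package is
half-open `[t0, t1)` — this makes window counts additive and avoids
off-by-one disagreements between segmentation and event counting.  The
on-disk container is a JSON sidecar plus raw little-endian float32
(sample-major frames), or CSV for small fixtures; the 16-bit quantisation of
the acquisition hardware is not emulated, since detection thresholds sit far
above one ADC step.  Event tables are plain CSV
(`channel_id,event_type,time_s,amplitude_uV,extra_json`).

## Spike detection

Threshold detection at `k_sigma = 6` times the baseline noise SD.  The SD is
estimated with the median absolute deviation, `MAD/0.6745`, over the whole
analysis window: the MAD is nearly unaffected by the spikes themselves,
whereas the plain SD inflates by tens of percent at realistic firing rates
(a `sigma_mode="sd"` escape hatch exists for replicating systems that
threshold on a quiescent-window SD).  Detection runs on the absolute
deviation from the channel median, since extracellular spikes may have
either polarity.  Each event claims one `cutout_ms = 5` window starting at
its first threshold crossing; crossings inside a claimed window are the same
event.  This mirrors non-overlapping cut-out selection, bounds the minimum
ISI at 5 ms (safely below the 50 ms burst criterion), and makes the detector
a simple, auditable state machine.  The event peak is the absolute-amplitude
extremum inside the claimed window; cut-outs are re-centred on the peak and
zero-padded at recording edges.  Average waveforms flip each cut-out to a
positive-peak convention before the pointwise mean, so opposite-polarity
events reinforce instead of cancelling.  No spike sorting is performed.

## Burst detection

A burst is a maximal run of at least `min_spikes = 5` spikes whose adjacent
gaps are all at most `max_isi_s = 0.050`.  A gap of exactly 50 ms is inside a
burst (inclusive comparison, with a 1 ns float slack so limit-value ISIs are
not rejected by representation noise).  Maximal runs give a unique,
order-independent decomposition; burst duration is last-spike minus
first-spike time, the only definition available from spike times alone.

## Discharge detection and filtering

The LFP chain is notch (50 Hz, Q = 30, biquad) then band-pass (Chebyshev
type-I, design order 2 — a 4-pole transfer function after the band
transform, the convention of standard design routines — 0.5 dB ripple,
4–40 Hz), both applied forward-backward (`filtfilt`, odd-reflection padding
of `3·(max(len(a),len(b))−1)` samples) so the effective magnitude is |H|²
and event timing is preserved.  The notch precedes the band-pass, matching
the usual order of line-noise removal before band isolation.  Detection runs
at the original 30 kHz on the filtered trace: threshold `4.5·SD` on the
absolute deviation from the (≈0) mean, keeping the first crossing of each
cluster and merging anything within the 50 ms refractory period into it —
one physiological discharge produces many threshold crossings, and the first
one carries the onset time.

Decimation to 100 Hz (for the time–frequency map only) is multi-stage
(factors ≤ 13, e.g. 300 = 12 × 5 × 5), each stage an 8th-order Chebyshev-I
low-pass at 0.8× the new Nyquist applied zero-phase.  Stage filters use
0.01 dB ripple and are renormalised to exact unit DC gain: the default
0.05 dB design would accumulate ≈2 % passband droop over three squared
stages, and an even-order Chebyshev-I sits at its ripple trough at DC, which
would bias constant offsets.

## Time–frequency maps

Complex Morlet CWT on 40 log-spaced frequencies in 4–40 Hz at 100 Hz.  The
wavelet has 6 cycles (σ_t = 6/(2πf)), the field-standard compromise between
temporal and spectral resolution in this band; the cycle count is exposed as
a parameter.  Power is `10·log10(|W|² + ε)` with ε = 10⁻¹² µV² purely to
guard `log(0)`.  Normalisation is per frequency row: z-score against the
mean and SD of a baseline window (default: the first 10 s of the analysed
window, configurable — nothing in the workflow fixes a canonical baseline),
then floor at z = 2 so only power that rises at least two baseline SDs
survives.  A zero baseline SD raises an error naming the frequency rather
than propagating infinities.

## Burst PSD

Welch estimate (Hann window, `min(256 ms, segment)` blocks, 50 % overlap,
no detrending) of the filtered trace over each burst padded by 100 ms,
restricted to 4–40 Hz; `band_mean_power` is the mean PSD over that band.
Segments shorter than one block degrade to a single windowed periodogram
with a warning.  Welch is the default robust estimator when no specific one
is mandated; the Hann/50 % combination keeps the estimate approximately
variance-preserving (Parseval within a few percent).

## Group statistics

Per-electrode metrics are compared without distributional assumptions:
Mann–Whitney U for two groups (exact null distribution when the smaller
group has ≤ 8 observations and there are no ties, otherwise the normal
approximation with tie and continuity corrections; identical pooled samples
short-circuit to p = 1), Kruskal–Wallis (tie-corrected, χ² reference) with
Dunn's pairwise z tests on pooled ranks and Bonferroni adjustment (the
conventional pairing) for three or more.  Percent change is
`100 × value/baseline` paired per electrode, so unchanged activity reads
100 %; zero-baseline electrodes are excluded with a warning.  Outlier
removal approximates ROUT for the one-sample location case: the full
procedure wraps robust nonlinear regression, which for scalar electrode
metrics collapses to a constant fit — median centre, robust SD from the
68.27th percentile of absolute residuals with an n/(n−1) small-sample
correction, two-sided t-tail p-values, Benjamini–Hochberg step at Q = 1 %
(the conventional default; configurable).

## Synthetic benchmark

`synthetic_data` generates ground-truthed recordings: white Gaussian noise
(σ = 10 µV), a 5 µV 50 Hz line component, lone Poisson spikes (2 Hz,
100 µV biphasic Gaussian-derivative templates with > 70 % of energy in
600–6,000 Hz), Poisson bursts (6/min, Poisson-distributed size with mean 8
floored at 5, intra-burst ISIs uniform 9–15 ms) each riding on a 10–20 Hz
Gabor LFP packet (20 µV), and 8–30 Hz Gabor discharge atoms (4/min,
100–400 ms, 35 µV — deliberately below the 60 µV spike threshold so slow
events never masquerade as fast spikes in the truth tables).

Condition effects are multiplicative and composable per factor: KCl raises
spike (×2.5) and burst (×2) rates and shrinks bursts (size ×0.6); TTX
suppresses nearly everything (rates ×0.05); GLUT1-DS halves burst rate,
doubles burst duration (via ISI ×2), triples burst LFP amplitude and doubles
discharge rate; the glucose drop to 5 mM acts only through a
`GLUT1-DS+5mM` interaction entry (spikes ×1.5, burst rate ×1.5, duration ×2).
Duration effects are deliberately split between ISI scaling and
spikes-per-burst scaling so that every injected burst still satisfies the
≥5 spikes / ≤50 ms rule exactly and scaled ISIs stay above the 5 ms spike
dead-time — a single ISI knob would break the burst definition at the
extreme arm combinations.  Magnitudes are chosen to make the programmed
directions unambiguous at n = 32 electrodes; they are simulator
configuration, not effect-size estimates.  Lone spikes keep ≥ 55 ms from
burst spikes (so they cannot extend a true burst) and ≥ 6 ms from each
other; channel RNG streams are seeded from (seed, condition, channel index),
making arms bit-reproducible and statistically independent.

Default problem sizes: 60 s per arm at 30 kS/s and 32 electrodes — enough
for ~120 spikes, ~6 bursts and ~4 discharges per baseline electrode, which
keeps every rate and duration estimate comfortably away from small-count
degeneracy while a full six-arm experiment stays around a minute of compute.

**What passing tests show and do not show.**  The simulator produces
stationary noise, stereotyped template spikes and isolated events.  It does
not model electrode drift, overlapping units and spike-waveform diversity,
1/f background (available but off by default), propagating multi-electrode
events, or amplitude non-stationarity.  Detector scores on this benchmark
therefore validate the *rules* (thresholding, dead-time, grouping,
refractory, normalisation) and the pipeline's statistical machinery — they
are upper bounds on, not estimates of, performance on tissue recordings.

## Degenerate inputs and tie-breaks

Constant channels yield σ = 0 and no events (with a warning); empty burst
lists report frequency 0 and duration as missing (NaN) rather than 0;
detection scoring with an empty detection list defines precision as 1 and
recall as 0; greedy event matching uses sorted two-pointer matching, which
is a maximum one-to-one matching for interval tolerance on sorted lists.
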