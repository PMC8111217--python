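# Methods

This note records the models, conventions and numerical choices behind
`spikelfp`, and what the synthetic-data tests do and do not establish
about real recordings.

## Signals and their model

A session couples three modalities on a common clock: an LFP sampled at
1 kHz (acquisition band-pass 0.5–200 Hz), per-unit spike timestamps in
seconds, and 40 kHz waveform snippets. Behaviour enters as reach events
(the "beam" time, t = 0 of each trial, when the animal lifts its paw)
with per-trial movement windows, plus rest intervals defined as the
complement of padded movement epochs.

## Cell classification

The trough-to-peak duration is measured on the mean waveform as
(argmax after the global trough − argmin)/fs. The post-trough maximum
must be positive; otherwise the waveform is non-canonical and the unit
stays unclassified rather than receiving an arbitrary duration. The
BS/NS boundary is fixed at 0.32 ms — the midpoint of the two class
means (0.42 and 0.22 ms) — with ties assigned to BS. A fixed boundary
is a deliberate substitute for interactive cluster-based sorting: it is
deterministic, and on class-templated waveforms with ≤10% amplitude
noise it classifies perfectly (verified over 200 synthetic units).
Firing rate is recorded but not used as a hard criterion, since no
printed rate cutoff exists. The refractory criterion accepts a unit
when fewer than 1% of ISIs fall below 2 ms.

## ISI metrics

CV uses the population standard deviation (a fixed choice; the sample
SD differs by O(1/n) and the convention matters only for
reproducibility). The ISI mode is the centre of the most populated 5 ms
bin on [0, 1] s; ties break toward the smallest bin because that is
stable under jitter. Bin indices are computed as
`floor(isi/width + 1e-9)` so values landing exactly on a bin edge go to
the upper bin regardless of floating-point grid noise. The asymmetry
index is mode/mean ISI; for a perfectly regular train it is the mode
bin centre over the ISI, ≈1 up to binning.

## PETH and modulation

Counts use 5 ms bins over a [−1.0, +1.5] s window. The smoothed rate is
the trial-mean rate convolved with a five-point Gaussian of σ = 1 bin,
normalised to unit sum; at the window edges the convolution is divided
by the kernel's local mass, which avoids edge droop at the cost of
redistributing ≲0.1% of the total mass. Baseline is the mean rate over
[−0.6, 0) s before each beam; the movement rate is the per-trial mean
over the annotated movement window. Because no named test is specified
for reach modulation, the package uses a trial-paired two-sided
Wilcoxon signed-rank of movement vs baseline rates at α = 0.05 — a
non-parametric choice consistent with the rest of the statistics; its
type-I error is verified by Monte-Carlo (≤0.06 at 500 null
simulations).

## LFP spectra

Preprocessing is a 4th-order Butterworth 0.5–200 Hz band-pass and a
Q = 30 notch at 50 Hz, both applied forward–backward for zero phase.
Short traces are even-reflection padded by up to 5 s before filtering;
without this the 0.5 Hz high-pass and the high-Q notch leave edge
transients that dominate a 10 s trace.

The PSD is a multitaper estimate: non-overlapping 0.5 s windows, the
first five DPSS tapers at NW = 3, windows demeaned, one-sided density
normalised so that ∫S df ≈ var(x) (checked against Parseval within
5%). The frequency resolution is 2 Hz and the spectral concentration
half-width NW/T = 6 Hz. Rest epochs are analysed by cutting the rest
intervals into 3 s blocks and averaging block PSDs.

Relative band power integrates the PSD over each half-open band
[low, high) and divides by the integral over the union of the bands
(0.7–200 Hz for the default set), so in-band signals have fractions
summing to one. Note two estimator properties at the fixed parameters:
power within ~6 Hz of the excluded DC bin is partially lost (a 5 Hz
tone reports ≈0.46 rather than 0.50), and power within ~6 Hz of a band
edge partially migrates to the neighbouring band. Both are properties
of the estimator, not bugs, and both also applied to the original
analyses that used the same parameters.

The spectrogram is a Hann-taper STFT (0.5 s windows, 50% overlap),
stored linear; log scaling is left to plotting.

## Spike-field coupling

For coherence the point process is embedded as 1 ms binned counts and
mean-centred; cross- and auto-spectra are averaged over the same
0.5 s/5-taper scheme, giving C(f) = |S_xy|/√(S_xx·S_yy) ∈ [0, 1] by
Cauchy–Schwarz (never clipped post hoc). A unit needs ≥40 spikes and
≥10 windows. State-resolved coherence keeps only the analysis windows
fully inside the state's intervals. Band-mean coherence is the
unweighted mean of C(f) over in-band frequencies.

Instantaneous phase comes from a 3rd-order Butterworth band-pass
(zero-phase) followed by the Hilbert transform; the analytic-signal
angle of a cosine is 0 at its maxima, so the convention peak = 0°,
trough = 180° holds by construction, mapped to [0, 360). Spikes read
the phase of the nearest LFP sample (0.5 ms worst-case error, ≈3.6° at
20 Hz). The Rayleigh test uses the refined exponential approximation
p = exp(√(1 + 4n + 4(n² − (nR̄)²)) − (1 + 2n)), validated against a
10⁵-sample simulated null. Phase-locked units are those with ≥40 spikes
and Rayleigh p < 0.05; their mean angle and vector length
R = |n⁻¹ Σe^{iθ}| feed the group comparisons.

## Group statistics

Mann–Whitney U counts pairs with x > y (ties half). For n + m ≤ 12 the
two-sided p is exact by enumerating all C(n+m, n) arrangements of the
pooled sample; larger samples use the normal approximation with tie and
continuity corrections (within 0.01 of the exact p at n = m = 20).
Two-way ANOVA (group × behaviour) is computed via ordinary least
squares with type-II sums of squares; repeated-measures ANOVA handles
the within-subject band factor. Post-hoc pairwise tests are Bonferroni
corrected: p_corr = min(1, k·p). A fully constant response returns
F = 0, p = 1 by convention rather than the 0/0 noise a regression would
produce. Significance is α = 0.05 two-sided throughout.

## Synthetic sessions

The generator's defaults are the study conditions, not tuning knobs.

**LFP.** The trace is synthesised in the frequency domain from
fixed-amplitude, random-phase spectral lines (filtered noise), so each
band's analytic power share equals its configured fraction exactly;
total power defaults to variance 1 (arbitrary units). A 1/f^α shape
(α = 1 by default) applies inside each band's support and to any
background remainder; deterministic pure tones are available for
analytic tests. Placement inside each band is estimator-aware: power
sits at least 6.5 Hz inside band edges where the band is wide enough,
and because the 0.7–12 Hz band is narrower than twice the 6 Hz taper
bandwidth, the flux it unavoidably sheds across the 12 Hz edge is
balanced by a small patch just above 12 Hz whose weight is solved at
run time from the DPSS spectral window. Injected band totals are exact
in every case; only the within-band placement adapts. With this layout
the fixed multitaper recovers the fractions within ±0.007 on 300 s
traces (tested at ±0.02).

**Spikes.** Trains are drawn by thinning a homogeneous Poisson process
at the bound λ_max = r·max(g, 1)·exp(κ)/I₀(κ) (asserted finite), with
conditional intensity λ(t) = r·g(t)·exp(κ·cos(φ(t) − μ))/I₀(κ): r the
base rate, g(t) the movement gain inside movement windows, φ(t) the
instantaneous phase of the coupling band. When the phase advances
uniformly (tone-driven), the spike-phase law is von Mises(μ, κ) and the
recovered vector length matches I₁(κ)/I₀(κ) within ±0.005 at 10⁵
spikes; for filtered-noise bands the phase occupancy is only
approximately uniform, a realism the tests exploit deliberately.

**Waveforms.** Snippets span [−0.4, +1.2] ms at 40 kHz (64 samples,
trough at sample 16). The template is a negative Gaussian trough plus a
half-amplitude positive lobe whose extrema are asserted to land on the
requested samples, so the noiseless trough-to-peak equals the nearest
sample-representable duration (0.425 ms for a 0.42 ms BS spec, 0.225 ms
for 0.22 ms NS). Noise is white with SD a configurable fraction of the
trough amplitude (default 5%).

**Events.** A renewal schedule with uniform inter-event intervals on
[4, 8] s (the sources give no trial pacing) and per-trial movement
windows of 0.96 s (control) or 1.25 s (lesioned template) with 0.1 s
Gaussian jitter, starting at the beam time. Rest intervals are the
complement of movement epochs padded by 1.5 s before and 1 s after.

**Templates.** The control template injects rest band fractions
73.51 / 15.72 / 4.26 / 3.0 / 3.51%, BS rest rate 4.76 and reaching rate
7.43 spikes/s, NS rate 7.62 spikes/s, and BS beta-band vector length
0.66 (κ inverted through I₁/I₀ ≈ 1.79); the lesioned template injects
58.65 / 24.34 / 8.09 / 4.0 / 4.92%, BS 4.15 → 6.64 spikes/s, NS
6.98 spikes/s, and vector length 0.80 (κ ≈ 2.87). The two unprinted
high-band fractions are chosen to complete the unit sum while keeping
their ordering plausible for cortical LFP. NS units are uncoupled and
unmodulated in both templates, encoding the finding that interneurons
are neither hypoactive nor synchronised. Preferred phase is 180°
(trough-locked) for all coupled units. Determinism: all randomness
derives from one SeedSequence per session, so identical configurations
give byte-identical bundles.

**Scale.** Desk-scale defaults are 300 s sessions with 2 BS + 2 NS
units; the end-to-end cohort tests use 10 sessions per condition at
240 s, which keeps the full suite within a few minutes on one CPU while
leaving every contrast far from its decision boundary.

## What the synthetic tests do not show

The generator produces stationary Gaussian-mixture LFPs, Poissonian
(apart from phase/gain modulation) spike trains without refractory
dynamics or bursts, perfectly sorted units, and artifact-free signals.
Passing tests therefore demonstrate the correctness of the estimators
and pipeline plumbing under the assumed model — not robustness to
drift, sorting errors, movement artifacts, non-stationary oscillations
or bursty discharge. The group templates encode the direction and
magnitude of the published effects, so the cohort test checks that the
pipeline can detect them, not that real recordings would reproduce
them.

## Known limitations

* Relative band power near the DC bin and near band edges carries the
  multitaper leakage bias described above.
* `restrict()` keeps a train's nominal span; rate statistics over
  masked trains must divide by the summed interval length
  (`masked_rate` does).
* The exact Mann–Whitney enumeration is O(C(n+m, n)) and is capped at
  n + m ≤ 12.
* Spike-sorting is reduced to threshold detection plus duration
  classification; no template matching or multi-channel clustering.
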