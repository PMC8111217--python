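# spikelfp

Analysis of simultaneously recorded single units and local field
potentials (LFPs) from chronic extracellular recordings — the kind of
data produced by microwire arrays in motor cortex of behaving rodents,
e.g. when comparing dopamine-intact and 6-OHDA-lesioned
(hemiparkinsonian) animals during rest and a forelimb reaching task.

The package covers the full chain from raw signals to group statistics:

* **Cell classification** (`spikelfp.units`) — trough-to-peak duration of
  the extracellular waveform separates broad-spiking (BS, putative
  pyramidal, ≈0.42 ms) from narrow-spiking (NS, putative interneuron,
  ≈0.22 ms) units, with a 2 ms refractory-period criterion.
* **Firing-pattern metrics** (`spikelfp.spiketrain_metrics`) — mean rate,
  ISI coefficient of variation (CV = σ/μ of the ISIs; 1 for Poisson,
  <1 for regular firing), ISI-histogram mode, and the asymmetry index
  (mode/mean ISI).
* **Peri-event time histograms** (`spikelfp.peth`) — 5 ms bins around the
  reach onset, five-point Gaussian smoothing, a −0.6 s baseline, and a
  trial-paired Wilcoxon test for reach-related rate modulation.
* **LFP spectra** (`spikelfp.lfp_spectral`) — zero-phase 0.5–200 Hz
  band-pass with 50 Hz notch, multitaper PSD (5 DPSS tapers, NW = 3,
  0.5 s windows at 1 kHz), relative power in the 0.7–12 / 12–35 / 35–70 /
  70–100 / 100–200 Hz bands, and an STFT spectrogram.
* **Spike-field coupling** (`spikelfp.spike_field`) — multitaper
  coherence C(f) = |S_xy| / √(S_xx·S_yy) between the binned point process
  and the LFP; band-filtered Hilbert phase (peak = 0°, trough = 180°);
  Rayleigh uniformity test; mean phase angle and vector length
  R = |n⁻¹ Σ e^{iθ}| with a ≥40-spike admissibility criterion.
* **Cohort statistics and I/O** (`spikelfp.pipeline_io`) — plain-text
  session bundles, Mann–Whitney U (exact by enumeration for small
  samples), two-way and repeated-measures ANOVA with Bonferroni post-hoc
  correction, and an end-to-end pipeline that writes CSV report tables.
* **Synthetic sessions** (`spikelfp.synthdata`) — a generator that
  injects known ground truth: band-structured 1/f LFPs, inhomogeneous
  Poisson spike trains with von Mises phase coupling
  λ(t) = r·g(t)·exp(κ·cos(φ(t) − μ))/I₀(κ), biphasic waveform snippets,
  and a renewal reach-event schedule. Every injected parameter is stored
  in a ground-truth table, so each analysis stage can be verified
  quantitatively without access to in-vivo recordings.

## Worked example

Simulate one control and one lesioned session and run the pipeline:

```sh
spikelfp simulate --template control  --seed 42 --out ctl
spikelfp simulate --template lesioned --seed 43 --out les
spikelfp analyze --session ctl --session les --out report
```

`report/classification.csv` shows every unit classified from its mean
waveform — BS units at the 0.425 ms sample-grid duration, NS at
0.225 ms:

```
       session_id unit_id  duration_ms  rate_hz class
 synth-control-42    bs00        0.425 5.016667    BS
 synth-control-42    ns00        0.225 7.416667    NS
synth-lesioned-43    bs00        0.425 4.996667    BS
synth-lesioned-43    ns00        0.225 7.150000    NS
```

`report/group_comparisons.csv` contrasts the two conditions (here with a
single session per group; p values come from the exact Mann–Whitney
enumeration and are floored by the tiny sample count):

```
                         metric  control_mean  lesioned_mean   U        p
                   BS_rest_rate      4.990829       4.340286 4.0 0.333333
            rest_fraction_12-35      0.159873       0.266925 0.0 1.000000
BS_movement_vector_length_12-35      0.660905       0.799851 0.0 0.333333
```

The direction of each effect matches the injected templates: the
lesioned template lowers the BS firing rate (4.15 vs 4.76 spikes/s at
rest), raises the 12–35 Hz (beta) share of LFP power (24.3% vs 15.7%)
and strengthens BS beta phase locking during movement (vector length
0.80 vs 0.66). With ten sessions per group all three contrasts become
significant at α = 0.05 (see `tests/test_acceptance.py`).

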