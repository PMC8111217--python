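"""Spike-LFP coupling: coherence, instantaneous phase and phase locking.

Two complementary coupling measures are provided.  Spike-field coherence
is the magnitude of the multitaper cross-spectrum between the binned,
mean-centred point process and the LFP, normalised by the auto-spectra;
it lives in [0, 1] per frequency.  Phase locking assigns each spike the
instantaneous phase of the band-filtered LFP (3rd-order Butterworth,
zero-phase, then Hilbert transform) under the convention that local
maxima of the filtered signal are 0 degrees and troughs 180 degrees.
The spike phases are summarised by the circular mean angle, the mean
resultant (vector) length R in [0, 1], and a Rayleigh uniformity test.
A unit needs at least 40 spikes in the analysed epoch before its
circular statistics are considered admissible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import AdmissibilityError, ConfigurationError
from .lfp_spectral import LfpTrace, _dpss_tapers
from .spiketrain_metrics import SpikeTrain

__all__ = [
    "CoherenceResult",
    "PhaseLockResult",
    "COUPLING_BANDS",
    "MIN_SPIKES",
    "multitaper_coherence",
    "spike_field_coherence",
    "instantaneous_phase",
    "spike_phases",
    "rayleigh_test",
    "phase_lock_summary",
]

#: Bands used for spike-LFP coupling (Hz), chosen from the LFP band set.
COUPLING_BANDS: dict[str, tuple[float, float]] = {
    "0.7-12": (0.7, 12.0),
    "12-35": (12.0, 35.0),
    "35-70": (35.0, 70.0),
}

#: Sampling criterion for circular statistics.
MIN_SPIKES = 40


@dataclass
class CoherenceResult:
    freqs: np.ndarray
    coherence: np.ndarray
    band_means: dict[str, float]
    n_spikes: int
    params: dict = field(default_factory=dict)


@dataclass
class PhaseLockResult:
    band: tuple[float, float] | None
    phases_deg: np.ndarray
    mean_angle_deg: float
    vector_length: float
    rayleigh_p: float
    n_spikes: int
    admissible: bool
    locked: bool


def instantaneous_phase(
    lfp: LfpTrace,
    band: tuple[float, float],
    order: int = 3,
) -> np.ndarray:
    """Instantaneous phase (degrees in [0, 360)) of a band-filtered LFP.

    The trace is band-passed with a 3rd-order Butterworth applied
    forward-backward (zero phase) and the analytic-signal angle of the
    result is taken.  For a cosine-like oscillation this puts local
    maxima at 0 degrees and minima at 180 degrees.
    """
    lo, hi = band
    nyq = lfp.fs / 2.0
    if not (0 < lo < hi < nyq):
        raise ConfigurationError(
            f"band ({lo}, {hi}) Hz invalid for fs={lfp.fs} Hz"
        )
    if lfp.duration_s < 3.0 / lo:
        raise ConfigurationError(
            "trace shorter than three cycles of the band's low edge"
        )
    sos = signal.butter(order, (lo, hi), btype="bandpass", fs=lfp.fs, output="sos")
    x = signal.sosfiltfilt(sos, np.asarray(lfp.samples, dtype=float))
    return np.degrees(np.angle(signal.hilbert(x))) % 360.0


def spike_phases(
    spike_times: np.ndarray,
    phases_deg: np.ndarray,
    fs: float,
    t0: float = 0.0,
) -> np.ndarray:
    """Per-spike phase by nearest-sample lookup into a phase series.

    Spikes outside the series' time support are dropped with a warning.
    """
    t = np.asarray(spike_times, dtype=float)
    idx = np.round((t - t0) * fs).astype(int)
    ok = (idx >= 0) & (idx < len(phases_deg))
    n_dropped = int(np.count_nonzero(~ok))
    if n_dropped:
        warnings.warn(
            f"{n_dropped} spike(s) outside the phase-series support dropped",
            stacklevel=2,
        )
    return np.asarray(phases_deg)[idx[ok]]


def _resultant(angles_deg: np.ndarray) -> complex:
    return np.exp(1j * np.radians(np.asarray(angles_deg, dtype=float))).sum()


def rayleigh_test(angles_deg: np.ndarray) -> float:
    """Rayleigh test of circular uniformity.

    Uses the refined exponential approximation
    ``p = exp(sqrt(1 + 4n + 4(n^2 - (n*Rbar)^2)) - (1 + 2n))``
    of the tail of Z = n * Rbar^2, clipped to (0, 1].
    """
    angles = np.asarray(angles_deg, dtype=float)
    n = len(angles)
    if n < 1:
        raise ConfigurationError("Rayleigh test needs at least one angle")
    rn = abs(_resultant(angles))  # n * Rbar
    p = np.exp(np.sqrt(1.0 + 4.0 * n + 4.0 * (n * n - rn * rn)) - (1.0 + 2.0 * n))
    return float(min(max(p, np.finfo(float).tiny), 1.0))


def phase_lock_summary(
    angles_deg: np.ndarray,
    band: tuple[float, float] | None = None,
    min_spikes: int = MIN_SPIKES,
    alpha: float = 0.05,
) -> PhaseLockResult:
    """Circular summary of spike phases.

    The mean angle is the argument and the vector length R the modulus of
    the mean resultant.  ``admissible`` requires at least `min_spikes`
    spikes; ``locked`` additionally requires Rayleigh p < alpha.
    """
    angles = np.asarray(angles_deg, dtype=float) % 360.0
    n = len(angles)
    if n == 0:
        return PhaseLockResult(
            band, angles, float("nan"), 0.0, 1.0, 0, False, False
        )
    res = _resultant(angles)
    r = abs(res) / n
    mean_angle = float(np.degrees(np.angle(res)) % 360.0) if r > 0 else float("nan")
    p = rayleigh_test(angles)
    admissible = n >= min_spikes
    return PhaseLockResult(
        band=band,
        phases_deg=angles,
        mean_angle_deg=mean_angle,
        vector_length=float(r),
        rayleigh_p=p,
        n_spikes=n,
        admissible=admissible,
        locked=bool(admissible and p < alpha),
    )


def _bin_spikes(train: SpikeTrain, lfp: LfpTrace) -> np.ndarray:
    """Embed the point process as counts on the LFP sample grid."""
    n = len(lfp.samples)
    idx = np.floor((train.times - lfp.t0) * lfp.fs).astype(int)
    idx = idx[(idx >= 0) & (idx < n)]
    return np.bincount(idx, minlength=n).astype(float)


def _window_slices(
    n_samples: int,
    win: int,
    fs: float,
    t0: float,
    intervals: list[tuple[float, float]] | None,
) -> list[slice]:
    """Non-overlapping analysis windows, optionally only those fully inside
    the given state intervals."""
    slices = []
    for start in range(0, n_samples - win + 1, win):
        if intervals is not None:
            a = t0 + start / fs
            b = t0 + (start + win) / fs
            if not any(a >= lo and b <= hi for lo, hi in intervals):
                continue
        slices.append(slice(start, start + win))
    return slices


def multitaper_coherence(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    window_s: float = 0.5,
    n_tapers: int = 5,
    time_bandwidth: float = 3.0,
    slices: list[slice] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Multitaper magnitude coherence between two equal-length series.

    ``C(f) = |Sxy| / sqrt(Sxx * Syy)`` with cross- and auto-spectra
    averaged over non-overlapping windows and DPSS tapers; in [0, 1] by
    Cauchy-Schwarz, identically 1 when the inputs coincide.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ConfigurationError("inputs must have equal length")
    win = int(round(window_s * fs))
    if slices is None:
        slices = [slice(s, s + win) for s in range(0, len(x) - win + 1, win)]
    if not slices:
        raise ConfigurationError("shorter than one analysis window")
    tapers = _dpss_tapers(win, time_bandwidth, n_tapers)
    segs_x = np.stack([x[s] for s in slices])
    segs_y = np.stack([y[s] for s in slices])
    segs_x = segs_x - segs_x.mean(axis=1, keepdims=True)
    segs_y = segs_y - segs_y.mean(axis=1, keepdims=True)
    fx = np.fft.rfft(segs_x[:, None, :] * tapers[None, :, :], axis=-1)
    fy = np.fft.rfft(segs_y[:, None, :] * tapers[None, :, :], axis=-1)
    sxy = (fx * np.conj(fy)).mean(axis=(0, 1))
    sxx = (np.abs(fx) ** 2).mean(axis=(0, 1))
    syy = (np.abs(fy) ** 2).mean(axis=(0, 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.abs(sxy) / np.sqrt(sxx * syy)
    return np.fft.rfftfreq(win, 1.0 / fs), np.nan_to_num(coh, nan=0.0)


def spike_field_coherence(
    train: SpikeTrain,
    lfp: LfpTrace,
    window_s: float = 0.5,
    n_tapers: int = 5,
    time_bandwidth: float = 3.0,
    bands: dict[str, tuple[float, float]] | None = None,
    intervals: list[tuple[float, float]] | None = None,
    min_spikes: int = MIN_SPIKES,
    min_windows: int = 10,
) -> CoherenceResult:
    """Multitaper coherence between a spike train and an LFP.

    The spikes are binned at the LFP sampling rate, the count series is
    mean-centred, and cross- and auto-spectra are averaged over
    non-overlapping `window_s` windows and DPSS tapers:
    ``C(f) = |Sxy| / sqrt(Sxx * Syy)``, which is in [0, 1] by
    construction (Cauchy-Schwarz), never clipped after the fact.

    With `intervals` given, only windows fully inside a state interval
    enter the average.  Admissibility requires `min_spikes` spikes in the
    analysed windows and `min_windows` windows.
    """
    bands = dict(COUPLING_BANDS) if bands is None else dict(bands)
    counts = _bin_spikes(train, lfp)
    x = np.asarray(lfp.samples, dtype=float)
    win = int(round(window_s * lfp.fs))
    slices = _window_slices(len(x), win, lfp.fs, lfp.t0, intervals)
    if len(slices) < min_windows:
        raise AdmissibilityError(
            f"only {len(slices)} analysis windows, need {min_windows}"
        )
    n_spk = int(sum(counts[s].sum() for s in slices))
    if n_spk < min_spikes:
        raise AdmissibilityError(
            f"only {n_spk} spikes in the analysed windows, need {min_spikes}"
        )
    freqs, coh = multitaper_coherence(
        counts, x, lfp.fs, window_s, n_tapers, time_bandwidth, slices=slices
    )
    band_means = {}
    for name, (lo, hi) in bands.items():
        m = (freqs >= lo) & (freqs < hi)
        if not m.any():
            raise ConfigurationError(f"band {name} has no frequency bin")
        band_means[name] = float(coh[m].mean())
    return CoherenceResult(
        freqs=freqs,
        coherence=coh,
        band_means=band_means,
        n_spikes=n_spk,
        params={
            "n_tapers": n_tapers,
            "time_bandwidth": time_bandwidth,
            "window_s": window_s,
            "fs": lfp.fs,
            "n_windows": len(slices),
        },
    )
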