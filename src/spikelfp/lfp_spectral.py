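"""LFP preprocessing and spectral estimation.

Local field potentials are analysed the way systems-neuroscience labs
typically do for band-limited cortical signals: zero-phase Butterworth
band-pass with a 50 Hz notch, multitaper (DPSS) power spectral density on
short non-overlapping windows, relative power over a fixed set of
physiological frequency bands, and a short-time Fourier spectrogram for
visual inspection.

The default multitaper parameters are five tapers, a time-bandwidth
product of 3 and 0.5 s analysis windows at 1 kHz, so the spectral
concentration half-width is NW/T = 6 Hz.  Band powers are reported as
fractions of the total 0.7-200 Hz power so that recordings with different
absolute gains are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.signal.windows import dpss

from .errors import ConfigurationError

__all__ = [
    "LfpTrace",
    "PsdResult",
    "BandPowerResult",
    "SpectrogramResult",
    "ANALYSIS_BANDS",
    "preprocess",
    "multitaper_psd",
    "epoch_psd",
    "relative_band_power",
    "spectrogram",
]

#: The five canonical analysis bands (Hz), half-open [low, high).
ANALYSIS_BANDS: dict[str, tuple[float, float]] = {
    "0.7-12": (0.7, 12.0),
    "12-35": (12.0, 35.0),
    "35-70": (35.0, 70.0),
    "70-100": (70.0, 100.0),
    "100-200": (100.0, 200.0),
}


@dataclass
class LfpTrace:
    """A single-channel field-potential recording.

    Parameters
    ----------
    samples : ndarray
        Voltage samples (arbitrary units).
    fs : float
        Sampling rate in Hz.
    t0 : float
        Time of the first sample in seconds.
    channel_id : str
        Channel label used in session manifests.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    channel_id: str = "lfp0"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.fs <= 0:
            raise ConfigurationError("sampling rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ConfigurationError("LFP samples must be finite")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.samples)) / self.fs


@dataclass
class PsdResult:
    """Multitaper power spectral density (one-sided, units^2/Hz)."""

    freqs: np.ndarray
    power: np.ndarray
    params: dict = field(default_factory=dict)

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    def integral(self, low: float = 0.0, high: float | None = None) -> float:
        """Integrated power over [low, high) via the rectangle rule."""
        high = self.freqs[-1] + self.df if high is None else high
        m = (self.freqs >= low) & (self.freqs < high)
        return float(self.power[m].sum() * self.df)


@dataclass
class BandPowerResult:
    """Per-band power fractions relative to the band-union total."""

    bands: dict[str, tuple[float, float]]
    fractions: dict[str, float]
    total_power: float


@dataclass
class SpectrogramResult:
    times: np.ndarray
    freqs: np.ndarray
    power: np.ndarray  # freq x time, linear scale


def preprocess(
    trace: LfpTrace,
    band: tuple[float, float] = (0.5, 200.0),
    notch_hz: float = 50.0,
    notch_q: float = 30.0,
) -> LfpTrace:
    """Zero-phase band-pass (4th-order Butterworth, forward-backward) plus a
    zero-phase notch at the line frequency.

    Length is preserved; the returned trace keeps the channel identity.
    """
    lo, hi = band
    nyq = trace.fs / 2.0
    if hi >= nyq or lo <= 0:
        raise ConfigurationError(
            f"band ({lo}, {hi}) Hz invalid for fs={trace.fs} Hz"
        )
    x = np.asarray(trace.samples, dtype=float)
    # even-reflection padding of several seconds tames the edge transients
    # of the 0.5 Hz high-pass and the high-Q notch on short traces
    padlen = int(min(len(x) - 1, 5 * trace.fs))
    sos = signal.butter(4, (lo, hi), btype="bandpass", fs=trace.fs, output="sos")
    x = signal.sosfiltfilt(sos, x, padlen=padlen, padtype="even")
    if notch_hz is not None and notch_hz < nyq:
        b, a = signal.iirnotch(notch_hz, notch_q, fs=trace.fs)
        x = signal.filtfilt(b, a, x, padlen=padlen, padtype="even")
    return LfpTrace(x, trace.fs, trace.t0, trace.channel_id)


def _dpss_tapers(n: int, time_bandwidth: float, n_tapers: int) -> np.ndarray:
    # unit-energy tapers (scipy norm=2 when Kmax is given)
    return dpss(n, time_bandwidth, n_tapers)


def multitaper_psd(
    trace: LfpTrace,
    window_s: float = 0.5,
    n_tapers: int = 5,
    time_bandwidth: float = 3.0,
) -> PsdResult:
    """Multitaper PSD averaged over non-overlapping windows and tapers.

    Each window is demeaned, multiplied by the first `n_tapers` DPSS tapers
    (time-bandwidth product NW), and the one-sided periodograms are averaged.
    The normalisation satisfies Parseval: the integral of the density over
    frequency approximates the signal variance.
    """
    x = np.asarray(trace.samples, dtype=float)
    win = int(round(window_s * trace.fs))
    n_win = len(x) // win
    if n_win < 1:
        raise ConfigurationError(
            f"trace of {len(x)} samples shorter than one {win}-sample window"
        )
    tapers = _dpss_tapers(win, time_bandwidth, n_tapers)  # (K, win)
    segs = x[: n_win * win].reshape(n_win, win)
    segs = segs - segs.mean(axis=1, keepdims=True)
    spectra = np.fft.rfft(segs[:, None, :] * tapers[None, :, :], axis=-1)
    power = (np.abs(spectra) ** 2).mean(axis=(0, 1)) / trace.fs
    power[1:] *= 2.0
    if win % 2 == 0:
        power[-1] /= 2.0  # Nyquist bin is not duplicated
    freqs = np.fft.rfftfreq(win, 1.0 / trace.fs)
    return PsdResult(
        freqs,
        power,
        params={
            "n_tapers": n_tapers,
            "time_bandwidth": time_bandwidth,
            "window_s": window_s,
            "fs": trace.fs,
            "n_windows": n_win,
        },
    )


def epoch_psd(
    trace: LfpTrace,
    intervals: list[tuple[float, float]],
    block_s: float = 3.0,
    **mt_params,
) -> PsdResult:
    """PSD of state-masked data: the given intervals are cut into `block_s`
    blocks and the block multitaper PSDs are averaged.

    Intervals shorter than one block are skipped; at least one full block is
    required.
    """
    fs = trace.fs
    nblock = int(round(block_s * fs))
    blocks = []
    for start, stop in intervals:
        i0 = max(0, int(np.ceil((start - trace.t0) * fs)))
        i1 = min(len(trace.samples), int(np.floor((stop - trace.t0) * fs)))
        for b0 in range(i0, i1 - nblock + 1, nblock):
            blocks.append(trace.samples[b0 : b0 + nblock])
    if not blocks:
        raise ConfigurationError(
            f"no interval contains a full {block_s} s block"
        )
    psds = [
        multitaper_psd(LfpTrace(b, fs, 0.0, trace.channel_id), **mt_params)
        for b in blocks
    ]
    power = np.mean([p.power for p in psds], axis=0)
    params = dict(psds[0].params)
    params["n_blocks"] = len(blocks)
    params["block_s"] = block_s
    return PsdResult(psds[0].freqs, power, params)


def relative_band_power(
    psd: PsdResult,
    bands: dict[str, tuple[float, float]] | None = None,
) -> BandPowerResult:
    """Fraction of total power in each band.

    The denominator is the integral over the union of the requested bands
    (0.7-200 Hz for the default set), so that fractions of a signal fully
    contained in the bands sum to one.  Band edges are half-open [low, high).
    """
    bands = dict(ANALYSIS_BANDS) if bands is None else dict(bands)
    union = np.zeros(len(psd.freqs), dtype=bool)
    masks = {}
    for name, (lo, hi) in bands.items():
        m = (psd.freqs >= lo) & (psd.freqs < hi)
        if not m.any():
            raise ConfigurationError(
                f"band {name} ({lo}-{hi} Hz) contains no frequency bin"
            )
        masks[name] = m
        union |= m
    total = float(psd.power[union].sum() * psd.df)
    if total <= 0:
        raise ConfigurationError("total in-band power is zero")
    fractions = {
        name: float(psd.power[m].sum() * psd.df / total)
        for name, m in masks.items()
    }
    return BandPowerResult(bands, fractions, total)


def spectrogram(
    trace: LfpTrace,
    window_s: float = 0.5,
    overlap: float = 0.5,
) -> SpectrogramResult:
    """Short-time Fourier spectrogram (Hann taper, magnitude squared).

    Values are stored linear; log scaling is a plotting concern.  Time stamps
    are at window centers, in the trace's own time base.
    """
    if not (0.0 <= overlap < 1.0):
        raise ConfigurationError("overlap must be in [0, 1)")
    nper = int(round(window_s * trace.fs))
    if len(trace.samples) < nper:
        raise ConfigurationError("trace shorter than one spectrogram window")
    nover = int(round(overlap * nper))
    freqs, times, sxx = signal.spectrogram(
        np.asarray(trace.samples, dtype=float),
        fs=trace.fs,
        window="hann",
        nperseg=nper,
        noverlap=nover,
        detrend="constant",
        mode="psd",
    )
    return SpectrogramResult(times + trace.t0, freqs, sxx)
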