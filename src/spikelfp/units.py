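"""Spike detection, waveform measurement and cell-class assignment.

Extracellular units are separated into broad-spiking (BS, putative
pyramidal) and narrow-spiking (NS, putative interneuron) classes by the
trough-to-peak duration of the mean waveform: the interval between the
first negative deflection (the global trough) and the peak of the
following positive deflection.  BS waveforms run around 0.42 ms and NS
around 0.22 ms, so the class boundary sits at their midpoint, 0.32 ms,
with ties assigned to BS.  Units whose waveform has no positive
deflection after the trough are non-canonical and stay unclassified.

A unit must also show a clean refractory period: fewer than 1% of
inter-spike intervals below 2 ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, NonCanonicalWaveformError

__all__ = [
    "WaveformSet",
    "UnitClassification",
    "CLASS_BOUNDARY_MS",
    "SNIPPET_PRE_MS",
    "SNIPPET_POST_MS",
    "detect_spikes",
    "trough_to_peak",
    "classify_unit",
    "refractory_ok",
    "classify_waveform_set",
    "waveform_pca",
]

#: BS/NS decision boundary: midpoint of the two class means (0.42, 0.22 ms).
CLASS_BOUNDARY_MS = 0.32
#: Snippet window around the threshold crossing, in ms.
SNIPPET_PRE_MS = 0.4
SNIPPET_POST_MS = 1.2


@dataclass
class WaveformSet:
    """Spike snippets of one unit (n_spikes x n_samples, 40 kHz typical)."""

    unit_id: str
    snippets: np.ndarray
    fs: float
    alignment_index: int = 0

    def __post_init__(self) -> None:
        self.snippets = np.atleast_2d(np.asarray(self.snippets))
        if self.fs <= 0:
            raise ConfigurationError("waveform sampling rate must be positive")
        if self.snippets.shape[1] < 32:
            raise ConfigurationError("snippets must have at least 32 samples")
        if not np.all(np.isfinite(self.snippets)):
            raise ConfigurationError("snippets must be finite")

    @property
    def n_spikes(self) -> int:
        return self.snippets.shape[0]

    def mean_waveform(self) -> np.ndarray:
        return self.snippets.mean(axis=0)


@dataclass
class UnitClassification:
    unit_id: str
    trough_to_peak_ms: float | None
    mean_rate_hz: float
    class_label: str  # "BS" | "NS" | "unclassified"
    refractory_ok: bool
    low_count: bool = False


def detect_spikes(
    samples: np.ndarray,
    fs: float,
    threshold: float,
    dead_time_ms: float = 1.0,
) -> tuple["WaveformSet", np.ndarray]:
    """Threshold detection of negative-going spikes on a broadband trace.

    A detection is a downward crossing of `threshold` (a negative voltage);
    a snippet spanning [-0.4, +1.2] ms around the crossing is cut out.
    Crossings within `dead_time_ms` of the previous accepted detection, or
    too close to the trace edges for a full snippet, are suppressed.

    Returns the snippet set and the crossing timestamps in seconds.
    """
    x = np.asarray(samples, dtype=float)
    if not np.isfinite(threshold):
        raise ConfigurationError("threshold must be finite")
    if dead_time_ms < 0:
        raise ConfigurationError("dead time must be non-negative")
    pre = int(round(SNIPPET_PRE_MS * fs / 1000.0))
    post = int(round(SNIPPET_POST_MS * fs / 1000.0))
    if len(x) < pre + post:
        raise ConfigurationError("trace shorter than one snippet window")
    crossings = np.flatnonzero((x[:-1] > threshold) & (x[1:] <= threshold)) + 1
    dead = dead_time_ms * fs / 1000.0
    kept: list[int] = []
    last = -np.inf
    for c in crossings:
        if c - last < dead:
            continue
        if c - pre < 0 or c + post > len(x):
            continue
        kept.append(c)
        last = c
    if kept:
        snips = np.stack([x[c - pre : c + post] for c in kept])
    else:
        snips = np.empty((0, pre + post))
    times = np.asarray(kept, dtype=float) / fs
    wf = WaveformSet("unsorted", snips, fs, alignment_index=pre)
    return wf, times


def trough_to_peak(snippet: np.ndarray, fs: float) -> float:
    """Trough-to-peak duration in ms.

    The trough is the global minimum; the peak is the maximum after the
    trough, which must be a positive deflection.  Raises
    :class:`NonCanonicalWaveformError` otherwise.
    """
    x = np.asarray(snippet, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ConfigurationError("snippet must be finite")
    trough = int(np.argmin(x))
    tail = x[trough + 1 :]
    if tail.size == 0:
        raise NonCanonicalWaveformError("trough at the last sample")
    peak = trough + 1 + int(np.argmax(tail))
    if x[peak] <= 0:
        raise NonCanonicalWaveformError(
            "no positive deflection after the trough"
        )
    return (peak - trough) / fs * 1000.0


def classify_unit(duration_ms: float, mean_rate_hz: float | None = None) -> str:
    """BS/NS call from the trough-to-peak duration.

    The boundary is 0.32 ms, inclusive on the BS side.  The firing rate is
    recorded for diagnostics but is not a hard criterion.
    """
    if duration_ms <= 0:
        raise ConfigurationError("duration must be positive")
    return "BS" if duration_ms >= CLASS_BOUNDARY_MS else "NS"


def refractory_ok(
    spike_times: np.ndarray,
    min_isi_ms: float = 2.0,
    max_violation_fraction: float = 0.01,
) -> bool:
    """True iff the fraction of ISIs below `min_isi_ms` is under the cap.

    Trains with fewer than two spikes are accepted by convention (nothing
    to violate).
    """
    t = np.asarray(spike_times, dtype=float)
    if len(t) < 2:
        return True
    isis_ms = np.diff(t) * 1000.0
    if np.any(isis_ms < 0):
        raise ConfigurationError("spike times must be ascending")
    return float(np.mean(isis_ms < min_isi_ms)) < max_violation_fraction


def classify_waveform_set(
    wf: WaveformSet,
    spike_times: np.ndarray,
    t_start: float,
    t_stop: float,
) -> UnitClassification:
    """Classify one unit from its mean waveform and spike train."""
    times = np.asarray(spike_times, dtype=float)
    duration = t_stop - t_start
    rate = len(times) / duration if duration > 0 else 0.0
    ok = refractory_ok(times)
    try:
        ttp = trough_to_peak(wf.mean_waveform(), wf.fs)
        label = classify_unit(ttp, rate)
    except NonCanonicalWaveformError:
        ttp, label = None, "unclassified"
    return UnitClassification(
        unit_id=wf.unit_id,
        trough_to_peak_ms=ttp,
        mean_rate_hz=rate,
        class_label=label,
        refractory_ok=ok,
        low_count=len(times) < 2,
    )


def waveform_pca(
    sets: list[WaveformSet], n_components: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Project all snippets on the leading principal components.

    Diagnostic only (cluster visualisation); classification never depends
    on it.  Returns (scores, unit index per row).
    """
    mats = [w.snippets for w in sets if w.n_spikes > 0]
    idx = np.concatenate(
        [np.full(w.n_spikes, i) for i, w in enumerate(sets) if w.n_spikes > 0]
    )
    x = np.concatenate(mats, axis=0)
    x = x - x.mean(axis=0, keepdims=True)
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    return x @ vt[:n_components].T, idx
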