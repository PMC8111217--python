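"""Firing-rate and inter-spike-interval pattern statistics.

Per unit and behavioural state we report the mean rate (spike count over
elapsed time), the coefficient of variation of the ISIs (population SD
over mean; one for a Poisson process, below one for regular firing), the
ISI mode (centre of the most populated 5 ms histogram bin on [0, 1] s)
and the asymmetry index (mode over mean ISI; near one for regular
trains, far below one for irregular/bursty trains).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, UndefinedMetricError

__all__ = [
    "SpikeTrain",
    "IsiStats",
    "mean_rate",
    "isi_cv",
    "isi_mode",
    "asymmetry_index",
    "isi_stats",
    "restrict",
    "masked_rate",
]


@dataclass
class SpikeTrain:
    """Spike timestamps of one unit, strictly ascending, in seconds."""

    unit_id: str
    times: np.ndarray
    t_start: float
    t_stop: float
    class_label: str | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.t_stop <= self.t_start:
            raise ConfigurationError("t_stop must exceed t_start")
        if len(self.times):
            if np.any(np.diff(self.times) <= 0):
                raise ConfigurationError(
                    f"unit {self.unit_id}: spike times must be strictly ascending"
                )
            if self.times[0] < self.t_start or self.times[-1] > self.t_stop:
                raise ConfigurationError(
                    f"unit {self.unit_id}: spikes outside [t_start, t_stop]"
                )

    def __len__(self) -> int:
        return len(self.times)

    @property
    def duration_s(self) -> float:
        return self.t_stop - self.t_start

    def isis(self) -> np.ndarray:
        return np.diff(self.times)


@dataclass
class IsiStats:
    n_spikes: int
    mean_rate: float
    cv: float
    mode_s: float
    asymmetry_index: float
    isi_histogram: tuple[np.ndarray, np.ndarray] = field(repr=False, default=None)


def mean_rate(
    train: SpikeTrain, interval: tuple[float, float] | None = None
) -> float:
    """Spike count in the interval divided by the interval length."""
    if interval is None:
        interval = (train.t_start, train.t_stop)
    a, b = interval
    if b <= a:
        raise ConfigurationError("interval must have positive length")
    n = int(np.count_nonzero((train.times >= a) & (train.times < b)))
    return n / (b - a)


def isi_cv(train: SpikeTrain) -> float:
    """Coefficient of variation of the ISIs (population SD / mean)."""
    isis = train.isis()
    if len(isis) < 2:
        raise UndefinedMetricError("CV needs at least two ISIs")
    return float(np.std(isis) / np.mean(isis))


def _isi_histogram(
    isis: np.ndarray, bin_width_s: float, range_s: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = range_s
    n_bins = int(round((hi - lo) / bin_width_s))
    edges = lo + bin_width_s * np.arange(n_bins + 1)
    # floor-based binning so values landing exactly on an edge go to the
    # upper bin despite float noise in the edge grid
    idx = np.floor((isis - lo) / bin_width_s + 1e-9).astype(int)
    idx = idx[(idx >= 0) & (idx < n_bins)]
    counts = np.bincount(idx, minlength=n_bins)
    return edges, counts


def isi_mode(
    train: SpikeTrain,
    bin_width_s: float = 0.005,
    range_s: tuple[float, float] = (0.0, 1.0),
) -> float:
    """Centre of the most populated ISI-histogram bin (ties: smallest bin)."""
    isis = train.isis()
    if len(isis) < 2:
        raise UndefinedMetricError("mode needs at least two ISIs")
    edges, counts = _isi_histogram(isis, bin_width_s, range_s)
    if counts.sum() == 0:
        raise UndefinedMetricError("all ISIs outside the histogram range")
    k = int(np.argmax(counts))  # argmax returns the first (smallest) tie
    return float(edges[k] + bin_width_s / 2.0)


def asymmetry_index(
    train: SpikeTrain,
    bin_width_s: float = 0.005,
    range_s: tuple[float, float] = (0.0, 1.0),
) -> float:
    """Ratio of the ISI mode to the mean ISI.

    Close to one for regular firing; well below one for asymmetric ISI
    histograms, i.e. irregular discharge.
    """
    mode = isi_mode(train, bin_width_s, range_s)
    return mode / float(np.mean(train.isis()))


def isi_stats(
    train: SpikeTrain,
    bin_width_s: float = 0.005,
    range_s: tuple[float, float] = (0.0, 1.0),
) -> IsiStats:
    isis = train.isis()
    edges, counts = (
        _isi_histogram(isis, bin_width_s, range_s)
        if len(isis) >= 2
        else (np.array([]), np.array([]))
    )
    try:
        cv = isi_cv(train)
        mode = isi_mode(train, bin_width_s, range_s)
        asym = asymmetry_index(train, bin_width_s, range_s)
    except UndefinedMetricError:
        cv = mode = asym = float("nan")
    return IsiStats(
        n_spikes=len(train),
        mean_rate=mean_rate(train),
        cv=cv,
        mode_s=mode,
        asymmetry_index=asym,
        isi_histogram=(edges, counts),
    )


def restrict(
    train: SpikeTrain, intervals: list[tuple[float, float]]
) -> SpikeTrain:
    """Mask a train to a set of state intervals.

    The restricted train keeps only spikes inside the intervals; its span
    runs from the first interval start to the last interval end.  Rate
    statistics over masked trains should divide by the summed interval
    length, which callers obtain from the interval list itself.
    """
    if not intervals:
        raise ConfigurationError("need at least one interval")
    ivals = sorted(intervals)
    mask = np.zeros(len(train.times), dtype=bool)
    for a, b in ivals:
        mask |= (train.times >= a) & (train.times < b)
    return SpikeTrain(
        train.unit_id,
        train.times[mask],
        min(train.t_start, ivals[0][0]),
        max(train.t_stop, ivals[-1][1]),
        train.class_label,
    )


def masked_rate(
    train: SpikeTrain, intervals: list[tuple[float, float]]
) -> float:
    """Mean rate over a union of intervals (count / summed length)."""
    total = sum(b - a for a, b in intervals)
    if total <= 0:
        raise ConfigurationError("intervals must have positive total length")
    n = 0
    for a, b in intervals:
        n += int(np.count_nonzero((train.times >= a) & (train.times < b)))
    return n / total
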