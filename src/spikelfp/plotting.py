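"""Diagnostic plots: raster/PETH, waveform classes, rose histograms.

These are quick-look figures for sanity checking synthetic sessions and
analysis output; nothing in the pipeline depends on them.
"""

from __future__ import annotations

import numpy as np

from .peth import EventSeries, PethResult
from .spike_field import PhaseLockResult
from .spiketrain_metrics import SpikeTrain
from .units import WaveformSet, waveform_pca

__all__ = ["plot_peth", "plot_waveform_classes", "plot_phase_rose"]


def plot_peth(
    peth: PethResult,
    train: SpikeTrain | None = None,
    events: EventSeries | None = None,
    ax=None,
):
    """Smoothed PETH, optionally with a spike raster above it."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    centers = peth.bin_centers
    ax.bar(centers, peth.raw_rate, width=centers[1] - centers[0],
           color="0.8", label="raw")
    ax.plot(centers, peth.rate, color="C0", label="smoothed")
    ax.axvline(0.0, color="k", ls="--", lw=0.8)
    ax.axhline(peth.baseline_rate, color="C3", ls=":", label="baseline")
    if train is not None and events is not None:
        top = ax.get_ylim()[1]
        for i, beam in enumerate(events.beam_times):
            rel = train.times[
                (train.times >= beam + centers[0])
                & (train.times < beam + centers[-1])
            ] - beam
            ax.plot(rel, np.full(len(rel), top * (1.02 + 0.01 * i)), "|",
                    color="k", ms=2)
    ax.set_xlabel("time from event (s)")
    ax.set_ylabel("rate (spikes/s)")
    ax.legend(frameon=False)
    return ax


def plot_waveform_classes(sets: list[WaveformSet], labels: list[str], ax=None):
    """Mean waveforms coloured by class plus a PC1/PC2 cluster inset."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    colors = {"BS": "C2", "NS": "C3", "unclassified": "0.5"}
    for wf, lab in zip(sets, labels):
        t = np.arange(wf.snippets.shape[1]) / wf.fs * 1000.0
        ax.plot(t, wf.mean_waveform(), color=colors.get(lab, "0.5"), alpha=0.7)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("amplitude (a.u.)")
    if len(sets) > 1:
        scores, idx = waveform_pca(sets, n_components=2)
        inset = ax.inset_axes([0.65, 0.6, 0.33, 0.35])
        for i, lab in enumerate(labels):
            pts = scores[idx == i]
            inset.plot(pts[:, 0], pts[:, 1], ".", ms=1,
                       color=colors.get(lab, "0.5"))
        inset.set_xticks([])
        inset.set_yticks([])
        inset.set_title("PCA", fontsize=7)
    return ax


def plot_phase_rose(result: PhaseLockResult, n_bins: int = 24, ax=None):
    """Circular phase histogram with the mean-resultant vector."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    theta = np.radians(result.phases_deg)
    counts, edges = np.histogram(theta, bins=n_bins, range=(0, 2 * np.pi))
    ax.bar(
        (edges[:-1] + edges[1:]) / 2,
        counts,
        width=2 * np.pi / n_bins,
        color="C0",
        alpha=0.6,
    )
    if result.vector_length > 0 and np.isfinite(result.mean_angle_deg):
        ax.annotate(
            "",
            xy=(np.radians(result.mean_angle_deg),
                result.vector_length * counts.max()),
            xytext=(0, 0),
            arrowprops={"color": "C3", "width": 1.5},
        )
    ax.set_title(
        f"R={result.vector_length:.2f}, p={result.rayleigh_p:.3g}",
        fontsize=9,
    )
    return ax
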