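"""Ground-truth synthetic recording sessions.

The generator emulates the statistical structure that the analysis
stages assume, at desk scale, with every injected parameter recorded in
a ground-truth table kept separate from the session bundle:

* an LFP composed of narrow filtered-noise components whose analytic
  power split over the bands 0.7-12 / 12-35 / 35-70 / 70-100 /
  100-200 Hz equals the configured fractions, plus an optional 1/f^a
  background and optional pure tones for analytic tests;
* spike trains drawn by thinning from a conditional intensity
  ``lambda(t) = r * g(t) * exp(k*cos(phi(t) - mu)) / I0(k)`` where
  ``phi`` is the instantaneous phase of the coupling band, ``g`` a
  multiplicative gain inside movement windows, so the mean rate stays
  ``r`` times the time-averaged gain and the spike-phase distribution is
  von Mises with concentration ``k`` (mean resultant I1(k)/I0(k));
* biphasic waveform snippets at 40 kHz whose noiseless trough-to-peak
  duration equals the configured class duration (0.42 ms broad-spiking,
  0.22 ms narrow-spiking);
* a renewal reach-event schedule (uniform inter-event intervals) with
  per-trial movement windows and complementary rest intervals.

Spectral placement is estimator-aware: because the multitaper kernel at
the fixed analysis parameters (0.5 s windows, NW = 3) is 6 Hz wide, each
band's power is placed at least 6.5 Hz inside its edges where the band
permits, and the power a narrow band unavoidably sheds across a shared
edge is balanced by a small patch just inside the neighbouring band,
solved at run time from the DPSS kernel.  Injected band totals are exact
in every case; only the placement inside each band adapts.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.signal.windows import dpss
from scipy.special import i0e, i1e

from .errors import ConfigurationError
from .lfp_spectral import ANALYSIS_BANDS, LfpTrace
from .peth import EventSeries
from .spike_field import instantaneous_phase
from .spiketrain_metrics import SpikeTrain
from .units import WaveformSet

__all__ = [
    "UnitSpec",
    "EventScheduleSpec",
    "SynthConfig",
    "GroundTruth",
    "vector_length_for_kappa",
    "kappa_for_vector_length",
    "gen_lfp",
    "gen_events",
    "gen_spike_train",
    "gen_waveforms",
    "gen_session",
    "control_template",
    "lesioned_template",
    "config_to_json",
    "config_from_json",
]


# ---------------------------------------------------------------------------
# configuration types


@dataclass
class UnitSpec:
    """Ground-truth parameters of one synthetic unit."""

    unit_id: str
    class_label: str  # "BS" | "NS"
    base_rate: float  # spikes/s outside movement windows
    trough_to_peak_ms: float
    coupling_band: str | None = None  # band label, or None for no coupling
    kappa: float = 0.0  # von Mises concentration
    preferred_phase_deg: float = 180.0
    movement_gain: float = 1.0
    waveform_noise_sd: float = 0.05  # fraction of trough amplitude

    def __post_init__(self) -> None:
        if self.base_rate < 0:
            raise ConfigurationError("base_rate must be >= 0")
        if self.kappa < 0:
            raise ConfigurationError("kappa must be >= 0")
        if self.trough_to_peak_ms <= 0:
            raise ConfigurationError("trough_to_peak_ms must be > 0")
        if self.movement_gain < 0:
            raise ConfigurationError("movement_gain must be >= 0")


@dataclass
class EventScheduleSpec:
    """Renewal reach-event schedule: uniform inter-event intervals."""

    iti_range_s: tuple[float, float] = (4.0, 8.0)
    movement_duration_s: float = 0.96
    movement_duration_jitter_s: float = 0.1
    first_event_s: float = 3.0
    margin_s: float = 3.0  # keep events away from the session end


@dataclass
class SynthConfig:
    """Free parameters of a synthetic session."""

    seed: int
    duration_s: float = 300.0
    lfp_fs: float = 1000.0
    wf_fs: float = 40000.0
    band_fractions: dict[str, float] = field(default_factory=dict)
    one_over_f_exponent: float = 1.0
    total_power: float = 1.0
    tones: list[tuple[float, float]] = field(default_factory=list)
    units: list[UnitSpec] = field(default_factory=list)
    events: EventScheduleSpec = field(default_factory=EventScheduleSpec)
    condition_label: str = "control"

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ConfigurationError("duration_s must be positive")
        total = 0.0
        for name, frac in self.band_fractions.items():
            if name not in ANALYSIS_BANDS:
                raise ConfigurationError(f"unknown band label {name!r}")
            if not (0.0 <= frac <= 1.0):
                raise ConfigurationError(f"fraction for {name} outside [0, 1]")
            total += frac
        if total > 1.0 + 1e-9:
            raise ConfigurationError("band fractions sum above one")
        edges = [ANALYSIS_BANDS[n][1] for n in self.band_fractions] + [
            f for f, _ in self.tones
        ]
        if edges and max(edges) >= self.lfp_fs / 2.0:
            raise ConfigurationError("band edge or tone at/above Nyquist")


@dataclass
class GroundTruth:
    """Injected truth, stored apart from the session bundle."""

    units: pd.DataFrame
    band_fractions: dict[str, float]
    condition_label: str
    seed: int


# ---------------------------------------------------------------------------
# circular helpers


def vector_length_for_kappa(kappa: float) -> float:
    """Mean resultant length of a von Mises distribution: I1(k)/I0(k)."""
    if kappa < 0:
        raise ConfigurationError("kappa must be >= 0")
    if kappa == 0:
        return 0.0
    return float(i1e(kappa) / i0e(kappa))


def kappa_for_vector_length(r: float) -> float:
    """Invert I1(k)/I0(k) = R for the concentration parameter."""
    if not (0.0 <= r < 1.0):
        raise ConfigurationError("vector length must be in [0, 1)")
    if r == 0.0:
        return 0.0
    return float(brentq(lambda k: vector_length_for_kappa(k) - r, 1e-9, 1e4))


# ---------------------------------------------------------------------------
# LFP synthesis

_MT_WINDOW_S = 0.5
_MT_NW = 3.0
_MT_K = 5
_EDGE_MARGIN_HZ = 6.5  # just past the NW/T = 6 Hz kernel half-width
_PATCH_HALF_HZ = 0.25


def _mt_kernel(fs: float, nfft: int = 8192) -> tuple[np.ndarray, np.ndarray]:
    """Averaged DPSS spectral window of the analysis multitaper."""
    win = int(round(_MT_WINDOW_S * fs))
    tapers = dpss(win, _MT_NW, _MT_K)
    u = np.abs(np.fft.rfft(tapers, nfft, axis=-1)) ** 2
    k = u.mean(axis=0)
    k /= k.sum()
    return np.fft.rfftfreq(nfft, 1.0 / fs), k


def _line_response(
    fc: float,
    kern_f: np.ndarray,
    kern: np.ndarray,
    bin_freqs: np.ndarray,
) -> np.ndarray:
    """Expected per-bin share of a unit-power line at `fc` in the
    multitaper estimate (one-sided, with the negative-frequency fold)."""
    df_k = kern_f[1] - kern_f[0]

    def at(offsets: np.ndarray) -> np.ndarray:
        idx = np.clip(np.round(np.abs(offsets) / df_k).astype(int), 0, len(kern) - 1)
        return kern[idx]

    resp = at(bin_freqs - fc) + at(bin_freqs + fc)
    return resp / resp.sum()


def _band_placement(
    lo: float, hi: float
) -> tuple[float, float]:
    """Main support of a band's power: inset by the kernel margin where the
    band is wide enough, a narrow mid-band patch otherwise."""
    if hi - lo >= 2 * _EDGE_MARGIN_HZ + 1.0:
        return lo + _EDGE_MARGIN_HZ, hi - _EDGE_MARGIN_HZ
    c = (lo + hi) / 2.0
    return c - _PATCH_HALF_HZ, c + _PATCH_HALF_HZ


def _patch_response(
    f0: float,
    f1: float,
    kern_f: np.ndarray,
    kern: np.ndarray,
    bin_freqs: np.ndarray,
    band_masks: list[np.ndarray],
    n_lines: int = 15,
) -> np.ndarray:
    """Recovered per-band share of unit power spread over [f0, f1]."""
    lines = np.linspace(f0, f1, n_lines)
    resp = np.mean(
        [_line_response(fc, kern_f, kern, bin_freqs) for fc in lines], axis=0
    )
    return np.array([resp[m].sum() for m in band_masks])


def _solve_compensation(
    band_list: list[tuple[str, float, float, float]],
    fs: float,
) -> dict[str, float]:
    """Weight of each band's power moved to its low-edge compensation patch.

    A band narrower than twice the kernel margin cannot keep its power
    clear of its upper edge; the net flux it sheds into the neighbour
    above is balanced by giving that neighbour a patch just inside the
    shared edge.  The weights solve the linearised fraction-recovery
    equations for the narrow bands; they are clipped to [0, 0.8].
    """
    kern_f, kern = _mt_kernel(fs)
    win = int(round(_MT_WINDOW_S * fs))
    bin_freqs = np.fft.rfftfreq(win, 1.0 / fs)
    masks = [
        (bin_freqs >= lo) & (bin_freqs < hi) for _, lo, hi, _ in band_list
    ]
    t = np.array([w for _, _, _, w in band_list])
    n = len(band_list)
    main_cols = []
    comp_cols = []
    for i, (_, lo, hi, _) in enumerate(band_list):
        f0, f1 = _band_placement(lo, hi)
        main_cols.append(
            _patch_response(f0, f1, kern_f, kern, bin_freqs, masks)
        )
        comp_cols.append(
            _patch_response(
                lo + 0.75, lo + 1.25, kern_f, kern, bin_freqs, masks
            )
        )
    main_cols = np.array(main_cols)  # (band, recovered-band)
    comp_cols = np.array(comp_cols)
    # bands needing compensation: narrow band i with a neighbour i+1 present
    comp_idx = [
        i + 1
        for i in range(n - 1)
        if band_list[i][2] - band_list[i][1] < 2 * _EDGE_MARGIN_HZ + 1.0
        and abs(band_list[i][2] - band_list[i + 1][1]) < 1e-9
        and t[i] > 0
        and t[i + 1] > 0
    ]
    weights = {name: 0.0 for name, *_ in band_list}
    if not comp_idx:
        return weights

    def residuals(w_vec: np.ndarray) -> np.ndarray:
        cols = main_cols.copy()
        for w, j in zip(w_vec, comp_idx):
            cols[j] = (1 - w) * main_cols[j] + w * comp_cols[j]
        r = t @ cols
        den = r.sum()
        # fraction-recovery error of each narrow (compensated-into) band
        return np.array([r[j - 1] / den - t[j - 1] / t.sum() for j in comp_idx])

    w0 = np.zeros(len(comp_idx))
    r0 = residuals(w0)
    jac = np.column_stack(
        [
            (residuals(w0 + 0.1 * e) - r0) / 0.1
            for e in np.eye(len(comp_idx))
        ]
    )
    sol, *_ = np.linalg.lstsq(jac, -r0, rcond=None)
    for j, w in zip(comp_idx, np.clip(sol, 0.0, 0.8)):
        weights[band_list[j][0]] = float(w)
    return weights


def gen_lfp(config: SynthConfig, seed: int | None = None) -> LfpTrace:
    """Synthesise the session LFP in the frequency domain.

    Each band's share of `total_power` is carried by fixed-amplitude,
    random-phase spectral lines (filtered noise) on the placement support
    described above, so realised band powers are analytically exact.  Any
    remainder of the fractions becomes a 1/f^a background over
    0.7-200 Hz, and configured pure tones are added deterministically.
    Identical configuration and seed give a bit-identical trace.
    """
    seed = config.seed if seed is None else seed
    fs = config.lfp_fs
    n = int(round(config.duration_s * fs))
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    alpha = config.one_over_f_exponent
    amp2 = np.zeros(len(freqs))  # per-line power (amplitude^2 / 2)

    def add_patch(f0: float, f1: float, power: float) -> None:
        m = (freqs >= f0) & (freqs <= f1)
        if not m.any():
            raise ConfigurationError(
                f"support [{f0}, {f1}] Hz contains no spectral line"
            )
        shape = 1.0 / np.maximum(freqs[m], 0.1) ** alpha
        amp2[m] += power * shape / shape.sum()

    band_list = [
        (name, *ANALYSIS_BANDS[name], config.band_fractions.get(name, 0.0))
        for name in ANALYSIS_BANDS
        if config.band_fractions.get(name, 0.0) > 0
    ]
    if band_list:
        weights = _solve_compensation(band_list, fs)
        for name, lo, hi, frac in band_list:
            power = frac * config.total_power
            w = weights[name]
            f0, f1 = _band_placement(lo, hi)
            add_patch(f0, f1, (1 - w) * power)
            if w > 0:
                add_patch(lo + 0.75, lo + 1.25, w * power)
    bg = config.total_power * (1.0 - sum(config.band_fractions.values()))
    if band_list and bg > 1e-12:
        add_patch(0.7, 200.0, bg)

    rng = np.random.default_rng(seed)
    phases = rng.uniform(0.0, 2.0 * np.pi, len(freqs))
    # line of power p has amplitude sqrt(2p); rfft coefficient a*n/2
    coef = np.sqrt(2.0 * amp2) * np.exp(1j * phases) * (n / 2.0)
    coef[0] = 0.0
    x = np.fft.irfft(coef, n)
    t = np.arange(n) / fs
    for f_tone, a_tone in config.tones:
        if f_tone >= fs / 2.0:
            raise ConfigurationError("tone frequency at/above Nyquist")
        x = x + a_tone * np.cos(2.0 * np.pi * f_tone * t)
    return LfpTrace(x.astype(np.float32), fs, 0.0, "lfp0")


# ---------------------------------------------------------------------------
# events, spikes, waveforms


def gen_events(config: SynthConfig, seed: int | None = None) -> EventSeries:
    """Renewal reach schedule with per-trial movement windows."""
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    sched = config.events
    lo, hi = sched.iti_range_s
    beams = []
    windows = []
    t = sched.first_event_s
    while t < config.duration_s - sched.margin_s:
        dur = float(
            np.clip(
                rng.normal(sched.movement_duration_s, sched.movement_duration_jitter_s),
                0.3,
                3.0,
            )
        )
        beams.append(t)
        windows.append((t, t + dur))
        t += float(rng.uniform(lo, hi))
    return EventSeries(np.asarray(beams), windows)


def rest_intervals(
    events: EventSeries,
    duration_s: float,
    pre_pad_s: float = 1.5,
    post_pad_s: float = 1.0,
) -> list[tuple[float, float]]:
    """Complement of padded movement epochs within [0, duration]."""
    exclusions = [
        (max(0.0, beam - pre_pad_s), min(duration_s, end + post_pad_s))
        for beam, (_, end) in zip(events.beam_times, events.movement_windows)
    ]
    out = []
    cursor = 0.0
    for a, b in sorted(exclusions):
        if a > cursor:
            out.append((cursor, a))
        cursor = max(cursor, b)
    if cursor < duration_s:
        out.append((cursor, duration_s))
    return out


def gen_spike_train(
    unit: UnitSpec,
    lfp: LfpTrace,
    events: EventSeries | None,
    seed: int,
) -> SpikeTrain:
    """Draw spikes by thinning an inhomogeneous Poisson process.

    The intensity is ``base_rate * g(t) * exp(k*cos(phi(t)-mu))/I0(k)``
    with g(t) = movement_gain inside movement windows and 1 elsewhere.
    The thinning bound is ``base_rate * max(gain, 1) * exp(k)/I0(k)``.
    """
    rng = np.random.default_rng(seed)
    duration = lfp.duration_s
    if unit.base_rate == 0:
        return SpikeTrain(unit.unit_id, np.array([]), lfp.t0, lfp.t0 + duration,
                          unit.class_label)
    # exp(k)/I0(k) written with the scaled Bessel to stay finite at large k
    vm_peak = 1.0 / float(i0e(unit.kappa)) if unit.kappa > 0 else 1.0
    lam_max = unit.base_rate * max(unit.movement_gain, 1.0) * vm_peak
    if not np.isfinite(lam_max):
        raise ConfigurationError("thinning bound is not finite")
    n_cand = rng.poisson(lam_max * duration)
    cand = np.sort(rng.uniform(0.0, duration, n_cand)) + lfp.t0
    lam = np.full(len(cand), unit.base_rate)
    if events is not None and unit.movement_gain != 1.0:
        in_move = np.zeros(len(cand), dtype=bool)
        for a, b in events.movement_windows:
            in_move |= (cand >= a) & (cand < b)
        lam[in_move] *= unit.movement_gain
    if unit.kappa > 0:
        if unit.coupling_band is None:
            raise ConfigurationError("kappa > 0 requires a coupling band")
        band = ANALYSIS_BANDS[unit.coupling_band]
        phi = instantaneous_phase(lfp, band)
        idx = np.clip(
            np.round((cand - lfp.t0) * lfp.fs).astype(int), 0, len(phi) - 1
        )
        rel = np.radians(phi[idx] - unit.preferred_phase_deg)
        lam *= np.exp(unit.kappa * (np.cos(rel) - 1.0)) / i0e(unit.kappa)
    keep = rng.uniform(0.0, lam_max, len(cand)) < lam
    times = np.unique(cand[keep])
    return SpikeTrain(
        unit.unit_id, times, lfp.t0, lfp.t0 + duration, unit.class_label
    )


def gen_waveforms(
    unit: UnitSpec,
    n_spikes: int,
    seed: int,
    wf_fs: float = 40000.0,
) -> WaveformSet:
    """Biphasic snippets whose noiseless trough-to-peak duration equals the
    nearest sample-representable value of the configured duration."""
    if n_spikes < 1:
        raise ConfigurationError("need at least one snippet")
    sep = int(round(unit.trough_to_peak_ms * wf_fs / 1000.0))
    if sep < 2:
        raise ConfigurationError(
            "trough_to_peak_ms shorter than two samples at the waveform rate"
        )
    pre = int(round(0.4e-3 * wf_fs))
    post = int(round(1.2e-3 * wf_fs))
    n_samp = pre + post
    trough = pre
    peak = trough + sep
    if peak >= n_samp - 1:
        raise ConfigurationError("trough-to-peak duration exceeds the snippet")
    i = np.arange(n_samp)
    s1 = max(1.0, sep / 4.0)
    s2 = max(1.5, sep / 3.0)
    template = -np.exp(-0.5 * ((i - trough) / s1) ** 2) + 0.5 * np.exp(
        -0.5 * ((i - peak) / s2) ** 2
    )
    # the construction must place the extrema on the requested samples
    assert int(np.argmin(template)) == trough
    assert trough + 1 + int(np.argmax(template[trough + 1 :])) == peak
    rng = np.random.default_rng(seed)
    noise_sd = unit.waveform_noise_sd * float(np.abs(template).max())
    snippets = template[None, :] + rng.normal(0.0, noise_sd, (n_spikes, n_samp))
    return WaveformSet(
        unit.unit_id, snippets.astype(np.float32), wf_fs, alignment_index=pre
    )


# ---------------------------------------------------------------------------
# whole sessions


def gen_session(config: SynthConfig):
    """Generate a full session bundle plus its ground-truth record.

    Seeds for the LFP, the event schedule and each unit are derived from
    the configuration seed through a SeedSequence, so identical
    configurations give byte-identical sessions.
    """
    from .pipeline_io import SessionBundle  # deferred: avoid import cycle

    ss = np.random.SeedSequence(config.seed)
    n_units = len(config.units)
    state = ss.generate_state(2 + 2 * max(n_units, 1)).astype(np.int64)
    state = state % (2**31 - 1)
    lfp = gen_lfp(config, seed=int(state[0]))
    events = gen_events(config, seed=int(state[1]))
    rest = rest_intervals(events, config.duration_s)
    trains: dict[str, SpikeTrain] = {}
    waveforms: dict[str, WaveformSet] = {}
    rows = []
    for k, unit in enumerate(config.units):
        train = gen_spike_train(unit, lfp, events, int(state[2 + 2 * k]))
        wf = gen_waveforms(
            unit, max(len(train), 1), int(state[3 + 2 * k]), config.wf_fs
        )
        trains[unit.unit_id] = train
        waveforms[unit.unit_id] = wf
        rows.append(
            {
                "unit_id": unit.unit_id,
                "class_label": unit.class_label,
                "base_rate": unit.base_rate,
                "movement_gain": unit.movement_gain,
                "trough_to_peak_ms": unit.trough_to_peak_ms,
                "coupling_band": unit.coupling_band or "",
                "kappa": unit.kappa,
                "preferred_phase_deg": unit.preferred_phase_deg,
                "expected_vector_length": vector_length_for_kappa(unit.kappa),
                "n_spikes": len(train),
            }
        )
    bundle = SessionBundle(
        session_id=f"synth-{config.condition_label}-{config.seed}",
        condition=config.condition_label,
        duration_s=config.duration_s,
        lfp={"lfp0": lfp},
        trains=trains,
        waveforms=waveforms,
        events=events,
        rest_intervals=rest,
    )
    truth = GroundTruth(
        units=pd.DataFrame(
            rows,
            columns=[
                "unit_id",
                "class_label",
                "base_rate",
                "movement_gain",
                "trough_to_peak_ms",
                "coupling_band",
                "kappa",
                "preferred_phase_deg",
                "expected_vector_length",
                "n_spikes",
            ],
        ),
        band_fractions=dict(config.band_fractions),
        condition_label=config.condition_label,
        seed=config.seed,
    )
    return bundle, truth


def _template(
    seed: int,
    condition: str,
    fractions: dict[str, float],
    bs_rate: float,
    bs_reach_rate: float,
    ns_rate: float,
    bs_vector_length: float,
    movement_duration_s: float,
    duration_s: float,
    n_bs: int,
    n_ns: int,
) -> SynthConfig:
    kappa = kappa_for_vector_length(bs_vector_length)
    units = []
    for k in range(n_bs):
        units.append(
            UnitSpec(
                unit_id=f"bs{k:02d}",
                class_label="BS",
                base_rate=bs_rate,
                trough_to_peak_ms=0.42,
                coupling_band="12-35",
                kappa=kappa,
                preferred_phase_deg=180.0,
                movement_gain=bs_reach_rate / bs_rate,
            )
        )
    for k in range(n_ns):
        units.append(
            UnitSpec(
                unit_id=f"ns{k:02d}",
                class_label="NS",
                base_rate=ns_rate,
                trough_to_peak_ms=0.22,
                coupling_band=None,
                kappa=0.0,
                movement_gain=1.0,
            )
        )
    return SynthConfig(
        seed=seed,
        duration_s=duration_s,
        band_fractions=fractions,
        units=units,
        events=EventScheduleSpec(movement_duration_s=movement_duration_s),
        condition_label=condition,
    )


def control_template(
    seed: int, duration_s: float = 300.0, n_bs: int = 2, n_ns: int = 2
) -> SynthConfig:
    """Session template anchored to the control-group values: rest band
    fractions 73.51 / 15.72 / 4.26 % (remainder split over the two high
    bands), BS rest rate 4.76 and reaching rate 7.43 spikes/s, NS rate
    7.62 spikes/s, BS beta vector length 0.66, movement duration 0.96 s."""
    return _template(
        seed,
        "control",
        {
            "0.7-12": 0.7351,
            "12-35": 0.1572,
            "35-70": 0.0426,
            "70-100": 0.0300,
            "100-200": 0.0351,
        },
        bs_rate=4.76,
        bs_reach_rate=7.43,
        ns_rate=7.62,
        bs_vector_length=0.66,
        movement_duration_s=0.96,
        duration_s=duration_s,
        n_bs=n_bs,
        n_ns=n_ns,
    )


def lesioned_template(
    seed: int, duration_s: float = 300.0, n_bs: int = 2, n_ns: int = 2
) -> SynthConfig:
    """Session template anchored to the dopamine-depleted group: rest band
    fractions 58.65 / 24.34 / 8.09 %, BS rest rate 4.15 and reaching rate
    6.64 spikes/s, NS rate 6.98 spikes/s, BS beta vector length 0.80,
    movement duration 1.25 s."""
    return _template(
        seed,
        "lesioned",
        {
            "0.7-12": 0.5865,
            "12-35": 0.2434,
            "35-70": 0.0809,
            "70-100": 0.0400,
            "100-200": 0.0492,
        },
        bs_rate=4.15,
        bs_reach_rate=6.64,
        ns_rate=6.98,
        bs_vector_length=0.80,
        movement_duration_s=1.25,
        duration_s=duration_s,
        n_bs=n_bs,
        n_ns=n_ns,
    )


# ---------------------------------------------------------------------------
# JSON config round trip


def config_to_json(config: SynthConfig) -> str:
    d = asdict(config)
    d["events"]["iti_range_s"] = list(d["events"]["iti_range_s"])
    d["tones"] = [list(t) for t in d["tones"]]
    return json.dumps(d, indent=2)


def config_from_json(text: str | dict) -> SynthConfig:
    d = dict(json.loads(text)) if isinstance(text, str) else dict(text)
    events = d.pop("events", {})
    if events:
        events["iti_range_s"] = tuple(events.get("iti_range_s", (4.0, 8.0)))
    units = [UnitSpec(**u) for u in d.pop("units", [])]
    d["tones"] = [tuple(t) for t in d.get("tones", [])]
    return SynthConfig(
        units=units, events=EventScheduleSpec(**events), **d
    )
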