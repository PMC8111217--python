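"""Session persistence, group statistics and the end-to-end pipeline.

A session bundle is stored as a plain directory: a JSON manifest,
little-endian float32 binaries for LFP channels and waveform stacks,
one ASCII timestamp file per unit, and CSV tables for events and state
intervals.  Loading validates the layout against the manifest and
reproduces every floating-point value bit-identically.

Group-level statistics follow the conventions of the source analyses:
Mann-Whitney U for non-parametric single comparisons (exact enumeration
for small samples), two-way ANOVA with group x behaviour factors,
repeated-measures ANOVA for within-subject band factors, and Bonferroni
correction for post-hoc comparisons, all at alpha = 0.05 two-sided.
"""

from __future__ import annotations

import csv
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import lfp_spectral, peth, spike_field, spiketrain_metrics, units
from .errors import ConfigurationError, SessionValidationError
from .lfp_spectral import ANALYSIS_BANDS, LfpTrace
from .peth import EventSeries
from .spiketrain_metrics import SpikeTrain
from .units import WaveformSet

__all__ = [
    "SessionBundle",
    "GroupComparison",
    "PipelineConfig",
    "save_session",
    "load_session",
    "mann_whitney_u",
    "bonferroni",
    "group_compare",
    "repeated_measures_anova",
    "run_pipeline",
]

log = logging.getLogger("spikelfp")


@dataclass
class SessionBundle:
    """One recording session: signals, trains, waveforms, behaviour."""

    session_id: str
    condition: str  # "control" | "lesioned"
    duration_s: float
    lfp: dict[str, LfpTrace]
    trains: dict[str, SpikeTrain]
    waveforms: dict[str, WaveformSet]
    events: EventSeries
    rest_intervals: list[tuple[float, float]]

    def __post_init__(self) -> None:
        if set(self.trains) != set(self.waveforms):
            raise SessionValidationError(
                "unit inventories of trains and waveforms differ"
            )
        for a, b in self.rest_intervals:
            if not (0.0 <= a < b <= self.duration_s + 1e-9):
                raise SessionValidationError(
                    f"rest interval ({a}, {b}) outside [0, {self.duration_s}]"
                )


@dataclass
class GroupComparison:
    metric: str
    groups: dict[str, dict]  # name -> {mean, sem, n}
    test: str
    statistic: float
    p: float
    corrected_p: float | None = None


# ---------------------------------------------------------------------------
# persistence


def _write_floats_ascii(path: Path, values: np.ndarray) -> None:
    with open(path, "w") as fh:
        for v in values:
            fh.write(repr(float(v)) + "\n")


def _read_floats_ascii(path: Path) -> np.ndarray:
    with open(path) as fh:
        return np.array([float(line) for line in fh if line.strip()], dtype=float)


def save_session(bundle: SessionBundle, directory: str | Path) -> Path:
    """Write a bundle to a directory; lossless under :func:`load_session`."""
    d = Path(directory)
    (d / "lfp").mkdir(parents=True, exist_ok=True)
    (d / "units").mkdir(exist_ok=True)
    (d / "waveforms").mkdir(exist_ok=True)
    manifest = {
        "session_id": bundle.session_id,
        "condition": bundle.condition,
        "duration_s": bundle.duration_s,
        "lfp": {},
        "units": sorted(bundle.trains),
        "waveforms": {},
    }
    for chan, trace in bundle.lfp.items():
        np.asarray(trace.samples, dtype="<f4").tofile(d / "lfp" / f"{chan}.f32")
        manifest["lfp"][chan] = {
            "fs": trace.fs,
            "t0": trace.t0,
            "n_samples": int(len(trace.samples)),
        }
    for unit_id in manifest["units"]:
        train = bundle.trains[unit_id]
        _write_floats_ascii(d / "units" / f"{unit_id}.txt", train.times)
        wf = bundle.waveforms[unit_id]
        np.asarray(wf.snippets, dtype="<f4").tofile(
            d / "waveforms" / f"{unit_id}.f32"
        )
        manifest["waveforms"][unit_id] = {
            "n_spikes": int(wf.n_spikes),
            "n_samples": int(wf.snippets.shape[1]),
            "fs": wf.fs,
            "alignment_index": int(wf.alignment_index),
            "t_start": train.t_start,
            "t_stop": train.t_stop,
            "class_label": train.class_label,
        }
    with open(d / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    with open(d / "events.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["trial_id", "beam_time_s", "move_start_s", "move_end_s"])
        for i, (beam, (a, b)) in enumerate(
            zip(bundle.events.beam_times, bundle.events.movement_windows)
        ):
            w.writerow([i, repr(float(beam)), repr(float(a)), repr(float(b))])
    with open(d / "intervals.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["state", "start_s", "end_s"])
        for a, b in bundle.rest_intervals:
            w.writerow(["rest", repr(float(a)), repr(float(b))])
    return d


def load_session(directory: str | Path) -> SessionBundle:
    """Load and validate a stored session bundle."""
    d = Path(directory)
    try:
        with open(d / "manifest.json") as fh:
            manifest = json.load(fh)
    except FileNotFoundError as exc:
        raise SessionValidationError(f"missing manifest in {d}") from exc
    lfp = {}
    for chan, meta in manifest["lfp"].items():
        path = d / "lfp" / f"{chan}.f32"
        if not path.exists():
            raise SessionValidationError(f"missing LFP file for channel {chan}")
        samples = np.fromfile(path, dtype="<f4")
        if len(samples) != meta["n_samples"]:
            raise SessionValidationError(
                f"channel {chan}: {len(samples)} samples, manifest says "
                f"{meta['n_samples']}"
            )
        if meta["fs"] <= 0:
            raise SessionValidationError(f"channel {chan}: non-positive fs")
        lfp[chan] = LfpTrace(samples, meta["fs"], meta["t0"], chan)
    trains, waveforms = {}, {}
    for unit_id in manifest["units"]:
        tpath = d / "units" / f"{unit_id}.txt"
        if not tpath.exists():
            raise SessionValidationError(
                f"unit {unit_id}: timestamp file missing"
            )
        times = _read_floats_ascii(tpath)
        wmeta = manifest["waveforms"][unit_id]
        try:
            trains[unit_id] = SpikeTrain(
                unit_id,
                times,
                wmeta["t_start"],
                wmeta["t_stop"],
                wmeta.get("class_label"),
            )
        except ConfigurationError as exc:
            raise SessionValidationError(str(exc)) from exc
        wpath = d / "waveforms" / f"{unit_id}.f32"
        if not wpath.exists():
            raise SessionValidationError(
                f"unit {unit_id}: waveform file missing"
            )
        flat = np.fromfile(wpath, dtype="<f4")
        shape = (wmeta["n_spikes"], wmeta["n_samples"])
        if flat.size != shape[0] * shape[1]:
            raise SessionValidationError(
                f"unit {unit_id}: waveform file size does not match manifest"
            )
        waveforms[unit_id] = WaveformSet(
            unit_id, flat.reshape(shape), wmeta["fs"], wmeta["alignment_index"]
        )
    beams, windows = [], []
    with open(d / "events.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            beams.append(float(row["beam_time_s"]))
            windows.append((float(row["move_start_s"]), float(row["move_end_s"])))
    rest = []
    with open(d / "intervals.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            if row["state"] == "rest":
                rest.append((float(row["start_s"]), float(row["end_s"])))
    return SessionBundle(
        session_id=manifest["session_id"],
        condition=manifest["condition"],
        duration_s=manifest["duration_s"],
        lfp=lfp,
        trains=trains,
        waveforms=waveforms,
        events=EventSeries(np.asarray(beams), windows),
        rest_intervals=rest,
    )


# ---------------------------------------------------------------------------
# statistics


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def mann_whitney_u(x, y, exact_limit: int = 12) -> tuple[float, float]:
    """Mann-Whitney U with a two-sided p value.

    U counts pairs where x exceeds y (ties count half).  For
    n + m <= `exact_limit` the p value is exact by enumerating all
    arrangements of the pooled sample; otherwise the normal approximation
    with tie correction and continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ConfigurationError("both samples must be non-empty")
    n, m = len(x), len(y)
    u_obs = _u_statistic(x, y)
    if n + m <= exact_limit:
        pooled = np.concatenate([x, y])
        center = n * m / 2.0
        dev = abs(u_obs - center)
        hits = total = 0
        for combo in itertools.combinations(range(n + m), n):
            mask = np.zeros(n + m, dtype=bool)
            mask[list(combo)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u - center) >= dev - 1e-12:
                hits += 1
        return u_obs, hits / total
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return u_obs, float(res.pvalue)


def bonferroni(p: float, k: int) -> float:
    """Bonferroni-corrected p value: min(1, k*p)."""
    return min(1.0, k * p)


def _summary(values: np.ndarray) -> dict:
    v = np.asarray(values, dtype=float)
    return {
        "mean": float(v.mean()),
        "sem": float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0,
        "n": int(len(v)),
    }


def group_compare(
    table: pd.DataFrame,
    value: str = "value",
    group: str = "group",
    behavior: str | None = "behavior",
    metric_name: str = "metric",
) -> list[GroupComparison]:
    """Two-way ANOVA (group x behaviour) with Bonferroni post-hoc tests.

    With `behavior` None, a single Mann-Whitney comparison between the
    two groups is returned instead.  Each cell needs at least two
    observations.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = table.copy()
    out: list[GroupComparison] = []
    if behavior is None or behavior not in df.columns:
        names = sorted(df[group].unique())
        if len(names) != 2:
            raise ConfigurationError("need exactly two groups")
        xs = df.loc[df[group] == names[0], value].to_numpy()
        ys = df.loc[df[group] == names[1], value].to_numpy()
        u, p = mann_whitney_u(xs, ys)
        return [
            GroupComparison(
                metric_name,
                {names[0]: _summary(xs), names[1]: _summary(ys)},
                "mann-whitney",
                u,
                p,
            )
        ]
    cells = df.groupby([group, behavior])[value].count()
    if (cells < 2).any():
        raise ConfigurationError("each design cell needs at least 2 values")
    df = df.rename(columns={value: "_v", group: "_g", behavior: "_b"})
    effect_rows = {
        "group": "C(_g)",
        "behavior": "C(_b)",
        "interaction": "C(_g):C(_b)",
    }
    if np.ptp(df["_v"].to_numpy()) == 0:
        # constant response: no effect of anything, by convention F=0, p=1
        anova = pd.DataFrame(
            {"F": 0.0, "PR(>F)": 1.0}, index=list(effect_rows.values())
        )
    else:
        model = ols("_v ~ C(_g) * C(_b)", data=df).fit()
        anova = sm.stats.anova_lm(model, typ=2)
    group_names = sorted(df["_g"].unique())
    summaries = {
        str(g): _summary(df.loc[df["_g"] == g, "_v"].to_numpy())
        for g in group_names
    }
    for label, row in effect_rows.items():
        out.append(
            GroupComparison(
                f"{metric_name}:{label}",
                summaries,
                "two-way-anova",
                float(anova.loc[row, "F"]),
                float(anova.loc[row, "PR(>F)"]),
            )
        )
    # post hoc: groups within each behaviour level, Bonferroni over levels
    levels = sorted(df["_b"].unique())
    k = len(levels)
    for lev in levels:
        sub = df[df["_b"] == lev]
        xs = sub.loc[sub["_g"] == group_names[0], "_v"].to_numpy()
        ys = sub.loc[sub["_g"] == group_names[1], "_v"].to_numpy()
        t, p = stats.ttest_ind(xs, ys)
        out.append(
            GroupComparison(
                f"{metric_name}:{group_names[0]}-vs-{group_names[1]}@{lev}",
                {
                    str(group_names[0]): _summary(xs),
                    str(group_names[1]): _summary(ys),
                },
                "t-test+bonferroni",
                float(t),
                float(p),
                corrected_p=bonferroni(float(p), k),
            )
        )
    return out


def repeated_measures_anova(
    table: pd.DataFrame,
    value: str = "value",
    subject: str = "subject",
    within: str = "band",
) -> tuple[float, float]:
    """Repeated-measures ANOVA with one within-subject factor.

    Returns (F, p) for the within factor.
    """
    from statsmodels.stats.anova import AnovaRM

    res = AnovaRM(
        table, depvar=value, subject=subject, within=[within]
    ).fit()
    row = res.anova_table.iloc[0]
    return float(row["F Value"]), float(row["Pr > F"])


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineConfig:
    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(ANALYSIS_BANDS)
    )
    coupling_bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(spike_field.COUPLING_BANDS)
    )
    alpha: float = 0.05
    peth_window: tuple[float, float] = (-1.0, 1.5)
    rest_block_s: float = 3.0


def _analyze_session(bundle: SessionBundle, cfg: PipelineConfig) -> dict:
    """All per-session tables: classification, metrics, PETH, band power,
    coupling."""
    sid, cond = bundle.session_id, bundle.condition
    move_windows = bundle.events.movement_windows
    classification, metrics, peths, coupling = [], [], [], []
    chan, trace = sorted(bundle.lfp.items())[0]
    clean = lfp_spectral.preprocess(trace)
    psd = lfp_spectral.epoch_psd(
        clean, bundle.rest_intervals, block_s=cfg.rest_block_s
    )
    bp = lfp_spectral.relative_band_power(psd, cfg.bands)
    bandpower = [
        {
            "session_id": sid,
            "condition": cond,
            "channel": chan,
            "state": "rest",
            "band": name,
            "fraction": frac,
        }
        for name, frac in sorted(bp.fractions.items())
    ]
    phase_by_band = {
        name: spike_field.instantaneous_phase(clean, band)
        for name, band in cfg.coupling_bands.items()
    }
    for unit_id in sorted(bundle.trains):
        train = bundle.trains[unit_id]
        cls = units.classify_waveform_set(
            bundle.waveforms[unit_id], train.times, train.t_start, train.t_stop
        )
        classification.append(
            {
                "session_id": sid,
                "condition": cond,
                "unit_id": unit_id,
                "duration_ms": cls.trough_to_peak_ms,
                "rate_hz": cls.mean_rate_hz,
                "class": cls.class_label,
                "refractory_ok": cls.refractory_ok,
            }
        )
        for state, ivals in (
            ("rest", bundle.rest_intervals),
            ("movement", move_windows),
        ):
            if not ivals:
                continue
            sub = spiketrain_metrics.restrict(train, ivals)
            rate = spiketrain_metrics.masked_rate(train, ivals)
            st = spiketrain_metrics.isi_stats(sub)
            metrics.append(
                {
                    "session_id": sid,
                    "condition": cond,
                    "unit_id": unit_id,
                    "class": cls.class_label,
                    "state": state,
                    "n_spikes": len(sub),
                    "rate": rate,
                    "cv": st.cv,
                    "mode_s": st.mode_s,
                    "asymmetry_index": st.asymmetry_index,
                }
            )
        if bundle.events.n_trials >= 10:
            pr = peth.build_peth(
                train, bundle.events, window=cfg.peth_window, alpha=cfg.alpha
            )
            peths.append(
                {
                    "session_id": sid,
                    "condition": cond,
                    "unit_id": unit_id,
                    "class": cls.class_label,
                    "baseline_rate": pr.baseline_rate,
                    "movement_rate": pr.movement_rate,
                    "modulation_p": pr.modulation_p,
                    "modulated": pr.modulated,
                }
            )
        for state, ivals in (
            ("rest", bundle.rest_intervals),
            ("movement", move_windows),
        ):
            for bname, band in cfg.coupling_bands.items():
                row = {
                    "session_id": sid,
                    "condition": cond,
                    "unit_id": unit_id,
                    "class": cls.class_label,
                    "state": state,
                    "band": bname,
                }
                sub = spiketrain_metrics.restrict(train, ivals)
                angles = spike_field.spike_phases(
                    sub.times, phase_by_band[bname], clean.fs, clean.t0
                )
                pl = spike_field.phase_lock_summary(
                    angles, band, alpha=cfg.alpha
                )
                row.update(
                    {
                        "n_spikes": pl.n_spikes,
                        "mean_angle_deg": pl.mean_angle_deg,
                        "vector_length": pl.vector_length,
                        "rayleigh_p": pl.rayleigh_p,
                        "admissible": pl.admissible,
                        "locked": pl.locked,
                    }
                )
                try:
                    coh = spike_field.spike_field_coherence(
                        train,
                        clean,
                        bands={bname: band},
                        intervals=None if state == "movement" else ivals,
                    )
                    row["band_mean_coherence"] = coh.band_means[bname]
                except Exception:
                    row["band_mean_coherence"] = float("nan")
                coupling.append(row)
    return {
        "classification": classification,
        "metrics": metrics,
        "bandpower": bandpower,
        "peth": peths,
        "coupling": coupling,
    }


def run_pipeline(
    session_dirs: list[str | Path],
    out_dir: str | Path,
    config: PipelineConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Analyse a cohort of stored sessions and write report tables.

    Emits per-unit classification, state-resolved metrics, PETH
    summaries, rest band-power fractions and coupling tables, plus
    group comparisons across conditions.  Deterministic given inputs;
    a failing session is logged and skipped.
    """
    if not session_dirs:
        raise ConfigurationError("need at least one session directory")
    cfg = config or PipelineConfig()
    tables: dict[str, list] = {
        k: [] for k in ("classification", "metrics", "bandpower", "peth", "coupling")
    }
    n_failed = 0
    for sdir in session_dirs:
        try:
            bundle = load_session(sdir)
            log.info("analysing %s (%s)", bundle.session_id, bundle.condition)
            result = _analyze_session(bundle, cfg)
        except Exception:
            log.exception("session %s failed; skipping", sdir)
            n_failed += 1
            continue
        for k, rows in result.items():
            tables[k].extend(rows)
    if n_failed == len(session_dirs):
        raise ConfigurationError("every session failed to analyse")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames = {k: pd.DataFrame(rows) for k, rows in tables.items()}
    frames["group_comparisons"] = _group_comparisons(frames, cfg)
    for name, frame in frames.items():
        frame.to_csv(out / f"{name}.csv", index=False)
    with open(out / "pipeline_config.json", "w") as fh:
        json.dump(
            {
                "alpha": cfg.alpha,
                "bands": {k: list(v) for k, v in cfg.bands.items()},
                "coupling_bands": {
                    k: list(v) for k, v in cfg.coupling_bands.items()
                },
                "peth_window": list(cfg.peth_window),
                "rest_block_s": cfg.rest_block_s,
                "n_sessions": len(session_dirs),
                "n_failed": n_failed,
            },
            fh,
            indent=2,
        )
    return frames


def _group_comparisons(
    frames: dict[str, pd.DataFrame], cfg: PipelineConfig
) -> pd.DataFrame:
    """Condition contrasts mirroring the headline analyses: per-class rest
    and reaching rates, rest band-power fractions, and movement-epoch beta
    vector length of phase-locked broad-spiking units."""
    rows = []

    def add(metric: str, ctl: np.ndarray, les: np.ndarray) -> None:
        if len(ctl) == 0 or len(les) == 0:
            return
        u, p = mann_whitney_u(ctl, les)
        sc, sl = _summary(ctl), _summary(les)
        rows.append(
            {
                "metric": metric,
                "control_mean": sc["mean"],
                "control_sem": sc["sem"],
                "control_n": sc["n"],
                "lesioned_mean": sl["mean"],
                "lesioned_sem": sl["sem"],
                "lesioned_n": sl["n"],
                "test": "mann-whitney",
                "U": u,
                "p": p,
                "significant": p < cfg.alpha,
                "direction": (
                    "lesioned>control"
                    if sl["mean"] > sc["mean"]
                    else "lesioned<control"
                ),
            }
        )

    met = frames["metrics"]
    if len(met):
        for klass in ("BS", "NS"):
            for state in ("rest", "movement"):
                sub = met[(met["class"] == klass) & (met["state"] == state)]
                add(
                    f"{klass}_{state}_rate",
                    sub.loc[sub.condition == "control", "rate"].to_numpy(),
                    sub.loc[sub.condition == "lesioned", "rate"].to_numpy(),
                )
    bp = frames["bandpower"]
    if len(bp):
        for band in sorted(bp["band"].unique()):
            sub = bp[bp["band"] == band]
            add(
                f"rest_fraction_{band}",
                sub.loc[sub.condition == "control", "fraction"].to_numpy(),
                sub.loc[sub.condition == "lesioned", "fraction"].to_numpy(),
            )
    cp = frames["coupling"]
    if len(cp):
        for klass in ("BS", "NS"):
            sub = cp[
                (cp["class"] == klass)
                & (cp["state"] == "movement")
                & (cp["band"] == "12-35")
                & cp["admissible"]
                & cp["locked"]
            ]
            add(
                f"{klass}_movement_vector_length_12-35",
                sub.loc[sub.condition == "control", "vector_length"].to_numpy(),
                sub.loc[sub.condition == "lesioned", "vector_length"].to_numpy(),
            )
            subc = cp[
                (cp["class"] == klass)
                & (cp["state"] == "movement")
                & (cp["band"] == "12-35")
            ].dropna(subset=["band_mean_coherence"])
            add(
                f"{klass}_movement_coherence_12-35",
                subc.loc[
                    subc.condition == "control", "band_mean_coherence"
                ].to_numpy(),
                subc.loc[
                    subc.condition == "lesioned", "band_mean_coherence"
                ].to_numpy(),
            )
    return pd.DataFrame(rows)
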