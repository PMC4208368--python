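"""Extraction of the 92 functional measures from raw trials.

Pre-processing chains are fixed:

* torque: trim (7 s head, 2 s tail) -> zero-phase Butterworth low-pass
  (4th order, 25 Hz) -> mean/SD/CV; MVIC = best of three peak torques.
* centre of pressure: trim (2 s head and tail) -> zero-phase Butterworth
  (2nd order, 5 Hz) -> posturography metrics.
* gait: zero-phase Butterworth (4th order, 25 Hz) on marker trajectories ->
  foot-velocity event detection -> stride parameters -> first/last stride of
  each walk removed -> mean/SD/CV across the pooled strides.

Coefficients of variation are reported dimensionless (SD/mean), never in
percent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as spstats

from .registry import MeasureID, default_registry, registry_ids
from .trial import RawTrial

__all__ = [
    "ExtractionConfig",
    "butterworth_filter",
    "trim_signal",
    "summary_stats",
    "compute_mvic",
    "preprocess_cop",
    "cop_metrics",
    "detect_gait_events",
    "stride_parameters",
    "gait_summary",
    "extract_subject",
    "assemble_feature_table",
    "GaitEvents",
    "StrideTable",
]


@dataclass
class ExtractionConfig:
    """Tunable extraction parameters (defaults are the protocol values)."""

    torque_trim: tuple[float, float] = (7.0, 2.0)  # s head, s tail
    torque_filter: tuple[int, float] = (4, 25.0)  # order, cutoff Hz
    cop_trim: tuple[float, float] = (2.0, 2.0)
    cop_filter: tuple[int, float] = (2, 5.0)
    gait_filter: tuple[int, float] = (4, 25.0)
    #: fraction of the swing used for the MinFC search window (central third)
    midswing_window: tuple[float, float] = (1 / 3, 2 / 3)
    min_strides_per_foot: int = 5
    stance_speed_fraction: float = 0.15
    min_stance_s: float = 0.12


# ---------------------------------------------------------------------------
# signal primitives


from functools import lru_cache


@lru_cache(maxsize=64)
def _butter_sos(order: int, wn: float) -> np.ndarray:
    return sps.butter(order, wn, btype="low", output="sos")


def butterworth_filter(
    x: np.ndarray, order: int, cutoff_hz: float, rate: float, zero_phase: bool = True
) -> np.ndarray:
    """Butterworth low-pass; ``zero_phase`` applies forward-backward passes
    (net zero phase lag, squared magnitude response). Output length equals
    input length."""
    nyq = rate / 2.0
    if cutoff_hz >= nyq:
        raise ValueError(f"cutoff {cutoff_hz} Hz >= Nyquist {nyq} Hz")
    sos = _butter_sos(order, cutoff_hz / nyq)
    x = np.asarray(x, dtype=float)
    if zero_phase:
        return sps.sosfiltfilt(sos, x, axis=-1)
    return sps.sosfilt(sos, x, axis=-1)


def trim_signal(trial: RawTrial, head_s: float, tail_s: float) -> RawTrial:
    """Drop the first ``head_s`` and last ``tail_s`` seconds of a trial."""
    if trial.duration <= head_s + tail_s:
        raise ValueError(
            f"trial {trial.trial_id}: duration {trial.duration:.2f}s too short "
            f"to trim {head_s}+{tail_s}s"
        )
    i0 = int(round(head_s * trial.rate))
    i1 = trial.n_samples - int(round(tail_s * trial.rate))
    return trial.copy_with({k: v[i0:i1] for k, v in trial.channels.items()})


class SummaryStats(NamedTuple):
    mean: float
    sd: float
    cv: float  # NaN when the mean is (numerically) zero


def summary_stats(series: np.ndarray, mean_tol: float = 1e-12) -> SummaryStats:
    """Mean, sample (n-1) SD and CV = SD/mean of a series."""
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("summary_stats requires at least 2 samples")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    cv = sd / mean if abs(mean) > mean_tol else float("nan")
    return SummaryStats(mean, sd, cv)


def compute_mvic(
    trials: list[RawTrial], order: int = 4, cutoff_hz: float = 25.0
) -> float:
    """Maximum voluntary isometric contraction: the largest peak torque over
    the (filtered) contraction trials."""
    if not trials:
        raise ValueError("compute_mvic requires at least one trial")
    peaks = [
        float(np.max(butterworth_filter(t.channels["torque"], order, cutoff_hz, t.rate)))
        for t in trials
    ]
    return max(peaks)


# ---------------------------------------------------------------------------
# posturography


def preprocess_cop(trial: RawTrial, config: ExtractionConfig | None = None) -> RawTrial:
    config = config or ExtractionConfig()
    t = trim_signal(trial, *config.cop_trim)
    order, cutoff = config.cop_filter
    return t.copy_with(
        {k: butterworth_filter(v, order, cutoff, t.rate) for k, v in t.channels.items()}
    )


def cop_metrics(trial: RawTrial) -> dict[str, float]:
    """Standard sway metrics of a (pre-processed) two-channel CoP trace.

    The trace is mean-centred first, so every metric is invariant to a
    constant translation of the CoP. Definitions:

    * ``DIST``: mean resultant distance from the mean CoP; per axis the mean
      absolute deviation.
    * ``RMS``: root-mean-square (resultant / per axis) distance.
    * ``VEL``: sway-path length divided by duration (per axis: the rectified
      axis path length over duration), m/s.
    * ``FREQ``: the rotational frequency of an equivalent circular sway,
      ``VEL / (2*pi*DIST)``; per axis the equivalent oscillation frequency
      ``VEL_axis / (4*DIST_axis)``, Hz.
    * ``AREA``: sway area swept per second — the sum of the triangle areas
      spanned by successive samples about the mean, divided by duration,
      m^2/s.
    * ``EA``: the 95% confidence ellipse area,
      ``2*pi*F(0.95; 2, n-2) * sqrt(s_AP^2 s_ML^2 - s_APML^2)``, m^2.

    A zero-variance trace yields zero distance/velocity/area metrics and NaN
    frequencies.
    """
    ap = np.asarray(trial.channels["AP"], dtype=float)
    ml = np.asarray(trial.channels["ML"], dtype=float)
    n = ap.size
    duration = (n - 1) / trial.rate
    ap = ap - ap.mean()
    ml = ml - ml.mean()
    rd = np.hypot(ap, ml)

    out: dict[str, float] = {}
    out["DIST"] = float(rd.mean())
    out["DIST-AP"] = float(np.abs(ap).mean())
    out["DIST-ML"] = float(np.abs(ml).mean())
    out["RMS"] = float(np.sqrt(np.mean(rd**2)))
    out["RMS-AP"] = float(np.sqrt(np.mean(ap**2)))
    out["RMS-ML"] = float(np.sqrt(np.mean(ml**2)))
    path = float(np.sum(np.hypot(np.diff(ap), np.diff(ml))))
    out["VEL"] = path / duration
    out["VEL-AP"] = float(np.sum(np.abs(np.diff(ap)))) / duration
    out["VEL-ML"] = float(np.sum(np.abs(np.diff(ml)))) / duration

    def _freq(vel: float, dist: float, directional: bool) -> float:
        if dist < 1e-12:  # numerically zero sway: frequency undefined
            return float("nan")
        return vel / (4 * dist) if directional else vel / (2 * np.pi * dist)

    out["FREQ"] = _freq(out["VEL"], out["DIST"], False)
    out["FREQ-AP"] = _freq(out["VEL-AP"], out["DIST-AP"], True)
    out["FREQ-ML"] = _freq(out["VEL-ML"], out["DIST-ML"], True)
    tri = 0.5 * np.abs(ap[:-1] * ml[1:] - ap[1:] * ml[:-1])
    out["AREA"] = float(tri.sum()) / duration
    s_ap = np.var(ap, ddof=1)
    s_ml = np.var(ml, ddof=1)
    s_apml = float(np.cov(ap, ml, ddof=1)[0, 1])
    det = max(s_ap * s_ml - s_apml**2, 0.0)
    f95 = spstats.f.ppf(0.95, 2, n - 2)
    out["EA"] = float(2 * np.pi * f95 * np.sqrt(det))
    return out


# ---------------------------------------------------------------------------
# gait events


@dataclass
class FootEvents:
    """Heel-strike and toe-off events of one foot, in time order."""

    hs_t: np.ndarray  # heel-strike times, s
    hs_x: np.ndarray  # AP position at heel strike, m
    hs_y: np.ndarray  # ML position at heel strike, m
    to_t: np.ndarray  # toe-off times, s
    stance_intervals: list[tuple[float, float]] = field(default_factory=list)


@dataclass
class GaitEvents:
    feet: dict[str, FootEvents]
    rate: float

    def __post_init__(self) -> None:
        for side, ev in self.feet.items():
            if np.any(np.diff(ev.hs_t) <= 0) or np.any(np.diff(ev.to_t) <= 0):
                raise ValueError(f"{side}: event times must be strictly increasing")


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as half-open (start, stop) index pairs."""
    idx = np.flatnonzero(np.diff(np.concatenate(([False], mask, [False])).astype(int)))
    return list(zip(idx[::2], idx[1::2]))


def detect_gait_events(
    trial: RawTrial, config: ExtractionConfig | None = None
) -> GaitEvents | None:
    """Foot-velocity gait event detection.

    The foot centre is the midpoint of the heel marker and the marker at the
    base of the second/third metatarsus. The terminal-swing minimum of the
    foot-centre vertical velocity and the early-swing maximum bracket each
    stance phase, which appears as a contiguous low-speed period of the foot
    centre (threshold relative to the trial's peak foot speed, so the
    detector is invariant to playback speed). The heel strike is fixed at
    stance onset — the first low-speed sample after the vertical-velocity
    minimum — and the toe-off at stance offset, immediately before the
    vertical-velocity maximum; on noise-free signals both land within one
    sample of the true contact times, whereas the velocity extrema
    themselves are displaced by the low-pass filtering.

    Returns ``None`` (with a warning) when fewer than two heel strikes are
    found on a foot — the walk is discarded.
    """
    config = config or ExtractionConfig()
    order, cutoff = config.gait_filter
    rate = trial.rate
    feet: dict[str, FootEvents] = {}
    for side in ("L", "R"):
        pos = np.vstack(
            [
                0.5
                * (
                    butterworth_filter(trial.channels[f"{side}_heel_{ax}"], order, cutoff, rate)
                    + butterworth_filter(trial.channels[f"{side}_met23_{ax}"], order, cutoff, rate)
                )
                for ax in ("x", "y", "z")
            ]
        )
        vel = np.gradient(pos, 1.0 / rate, axis=1)
        speed = np.linalg.norm(vel, axis=0)
        thr = config.stance_speed_fraction * np.percentile(speed, 98)
        runs = [
            (a, b)
            for a, b in _runs(speed < thr)
            if (b - a) / rate >= config.min_stance_s
        ]
        hs_idx: list[int] = []
        to_idx: list[int] = []
        for a, b in runs:
            if a > 0:  # a stance starting inside the trial -> heel strike
                hs_idx.append(a)
            if b < len(speed):  # stance ending inside the trial -> toe-off
                to_idx.append(b)
        if len(hs_idx) < 2:
            warnings.warn(
                f"trial {trial.trial_id}: <2 heel strikes on foot {side}; "
                "walk discarded"
            )
            return None
        t = trial.time
        stance = [
            (t[a] if a > 0 else 0.0, t[b - 1] if b < len(speed) else t[-1])
            for a, b in runs
        ]
        feet[side] = FootEvents(
            hs_t=t[np.array(hs_idx)],
            hs_x=pos[0, np.array(hs_idx)],
            hs_y=pos[1, np.array(hs_idx)],
            to_t=t[np.array(to_idx)],
            stance_intervals=stance,
        )
    return GaitEvents(feet=feet, rate=rate)


# ---------------------------------------------------------------------------
# stride parameters


@dataclass
class StrideTable:
    """Per-stride and per-step parameters of one walk (transient strides
    already removed)."""

    strides: pd.DataFrame  # foot, stride_time, stance_time, swing_time, dst,
    #                        stride_length, maxfc, minfc
    steps: pd.DataFrame  # step_length, step_width
    cadence: float  # steps/min for the walk


def _intersect_total(
    intervals_a: list[tuple[float, float]],
    intervals_b: list[tuple[float, float]],
    lo: float,
    hi: float,
) -> float:
    total = 0.0
    for a0, a1 in intervals_a:
        for b0, b1 in intervals_b:
            s = max(a0, b0, lo)
            e = min(a1, b1, hi)
            if e > s:
                total += e - s
    return total


def _toe_height(trial: RawTrial, side: str, config: ExtractionConfig) -> np.ndarray:
    order, cutoff = config.gait_filter
    z = 0.5 * (
        butterworth_filter(trial.channels[f"{side}_met1_z"], order, cutoff, trial.rate)
        + butterworth_filter(trial.channels[f"{side}_met5_z"], order, cutoff, trial.rate)
    )
    return z


def stride_parameters(
    events: GaitEvents,
    trial: RawTrial,
    config: ExtractionConfig | None = None,
    trim: bool = True,
) -> StrideTable:
    """Spatiotemporal stride/step parameters from detected events.

    Two consecutive ipsilateral heel strikes define a stride; toe-off within
    the stride splits it into stance and swing. Stride length is the AP
    distance between the strikes; clearance is taken from the toe-region
    (first/fifth metatarsal head) markers during swing, relative to the
    ground plane estimated from stance. Step length/width come from
    consecutive contralateral strikes. With ``trim`` the first and last
    stride of each foot (and the first and last step) are removed to avoid
    gait-initiation/termination transients. Cycles violating left/right
    alternation are dropped with a warning.
    """
    config = config or ExtractionConfig()
    rows = []
    t_axis = trial.time
    ground = {}
    toe_z = {}
    for side in ("L", "R"):
        toe_z[side] = _toe_height(trial, side, config)
        stance_mask = np.zeros(len(t_axis), dtype=bool)
        for s0, s1 in events.feet[side].stance_intervals:
            stance_mask |= (t_axis >= s0) & (t_axis <= s1)
        ground[side] = float(np.median(toe_z[side][stance_mask])) if stance_mask.any() else float(np.min(toe_z[side]))

    # merged strike sequence for alternation checks and steps
    merged = sorted(
        [(t, side, x, y) for side in ("L", "R") for t, x, y in zip(
            events.feet[side].hs_t, events.feet[side].hs_x, events.feet[side].hs_y
        )]
    )

    for side in ("L", "R"):
        other = "R" if side == "L" else "L"
        ev = events.feet[side]
        n_str = len(ev.hs_t) - 1
        for i in range(n_str):
            t0, t1 = ev.hs_t[i], ev.hs_t[i + 1]
            # alternation: exactly one contralateral strike inside the cycle
            inside = [m for m in merged if t0 < m[0] < t1 and m[1] == other]
            if len(inside) != 1:
                warnings.warn(
                    f"trial {trial.trial_id}: foot {side} cycle at {t0:.2f}s "
                    "violates alternation; cycle dropped"
                )
                continue
            tos = ev.to_t[(ev.to_t > t0) & (ev.to_t < t1)]
            if len(tos) != 1:
                warnings.warn(
                    f"trial {trial.trial_id}: foot {side} cycle at {t0:.2f}s "
                    "has no unique toe-off; cycle dropped"
                )
                continue
            to = float(tos[0])
            stride_time = t1 - t0
            stance_time = to - t0
            swing_time = stride_time - stance_time
            dst = _intersect_total(
                events.feet[side].stance_intervals,
                events.feet[other].stance_intervals,
                t0,
                t1,
            )
            stride_length = ev.hs_x[i + 1] - ev.hs_x[i]
            sw_mask = (t_axis >= to) & (t_axis <= t1)
            z_swing = toe_z[side][sw_mask] - ground[side]
            maxfc = float(np.max(z_swing)) if z_swing.size else float("nan")
            lo, hi = config.midswing_window
            mid_mask = (t_axis >= to + lo * swing_time) & (t_axis <= to + hi * swing_time)
            z_mid = toe_z[side][mid_mask] - ground[side]
            minfc = float(np.min(z_mid)) if z_mid.size else float("nan")
            rows.append(
                dict(
                    foot=side,
                    order=i,
                    n_cycles=n_str,
                    stride_time=stride_time,
                    stance_time=stance_time,
                    swing_time=swing_time,
                    dst=dst,
                    stride_length=stride_length,
                    maxfc=maxfc,
                    minfc=minfc,
                )
            )
    strides = pd.DataFrame(rows)
    if trim and not strides.empty:
        strides = strides[
            (strides["order"] > 0) & (strides["order"] < strides["n_cycles"] - 1)
        ]
    strides = strides.drop(columns=["order", "n_cycles"], errors="ignore").reset_index(
        drop=True
    )

    step_rows = []
    for a, b in zip(merged[:-1], merged[1:]):
        if a[1] == b[1]:
            continue  # alternation break; affected step skipped
        step_rows.append(dict(step_length=b[2] - a[2], step_width=abs(b[3] - a[3])))
    if trim and len(step_rows) >= 3:
        step_rows = step_rows[1:-1]
    steps = pd.DataFrame(step_rows)

    cadence = (
        120.0 / float(strides["stride_time"].mean()) if len(strides) else float("nan")
    )
    return StrideTable(strides=strides, steps=steps, cadence=cadence)


_GAIT_PARAMS = {
    "stride_time": "Str-T",
    "stance_time": "Stn-T",
    "swing_time": "Sw-T",
    "dst": "DST",
    "stride_length": "Str-Len",
    "maxfc": "MaxFC",
}


def gait_summary(
    tables: list[StrideTable], config: ExtractionConfig | None = None
) -> dict[str, float]:
    """Per-subject gait measures: mean/SD/CV over the strides pooled across
    walks (per foot), plus bilateral cadence, step width and step length.

    Returns an empty dict (with a warning) when fewer than
    ``min_strides_per_foot`` strides survive on either foot.
    """
    config = config or ExtractionConfig()
    strides = pd.concat([t.strides for t in tables], ignore_index=True)
    out: dict[str, float] = {}
    for side in ("L", "R"):
        sub = strides[strides["foot"] == side]
        if len(sub) < config.min_strides_per_foot:
            warnings.warn(
                f"only {len(sub)} retained strides on foot {side}; "
                "gait measures set missing"
            )
            return {}
    for side in ("L", "R"):
        sub = strides[strides["foot"] == side]
        for col, name in _GAIT_PARAMS.items():
            mean, sd, cv = summary_stats(sub[col].to_numpy())
            out[f"GA:Mn-{name}-{side}"] = mean
            out[f"GA:SD-{name}-{side}"] = sd
            out[f"GA:CV-{name}-{side}"] = cv
        out[f"GA:Mn-MinFC-{side}"] = float(sub["minfc"].mean())
    cad = np.array([t.cadence for t in tables if np.isfinite(t.cadence)])
    if cad.size >= 2:
        out["GA:Mn-CAD"], out["GA:SD-CAD"], _ = summary_stats(cad)
    steps = pd.concat([t.steps for t in tables], ignore_index=True)
    if len(steps) >= 2:
        out["GA:Mn-Stp-Len"], out["GA:SD-Stp-Len"], _ = summary_stats(
            steps["step_length"].to_numpy()
        )
        out["GA:Mn-SW"], out["GA:SD-SW"], _ = summary_stats(
            steps["step_width"].to_numpy()
        )
    return out


# ---------------------------------------------------------------------------
# per-subject extraction + table assembly

_JOINTS = ("KE", "PF")
_TARGETS = ("c15", "c20", "r1520")


def extract_subject(
    trials: list[RawTrial], config: ExtractionConfig | None = None
) -> dict[str, float]:
    """Compute every available measure for one subject from raw trials."""
    config = config or ExtractionConfig()
    out: dict[str, float] = {}

    # --- force control
    torque = [t for t in trials if t.modality == "torque"]
    for joint in _JOINTS:
        mvic_trials = [t for t in torque if t.condition == f"{joint}:mvic"]
        if mvic_trials:
            order, cutoff = config.torque_filter
            out[f"FC:Mn-MVIC-{joint}"] = compute_mvic(mvic_trials, order, cutoff)
        for target in _TARGETS:
            reps = [t for t in torque if t.condition == f"{joint}:{target}"]
            if not reps:
                continue
            stats = []
            for t in reps:
                trimmed = trim_signal(t, *config.torque_trim)
                order, cutoff = config.torque_filter
                x = butterworth_filter(trimmed.channels["torque"], order, cutoff, t.rate)
                stats.append(summary_stats(x))
            out[f"FC:Mn-{target}-{joint}"] = float(np.mean([s.mean for s in stats]))
            out[f"FC:SD-{target}-{joint}"] = float(np.mean([s.sd for s in stats]))
            out[f"FC:CV-{target}-{joint}"] = float(np.mean([s.cv for s in stats]))

    # --- quiet standing
    cop = [t for t in trials if t.modality == "cop"]
    for cond in ("QEO", "QEC"):
        reps = [t for t in cop if t.condition == cond]
        if not reps:
            continue
        metric_reps = [cop_metrics(preprocess_cop(t, config)) for t in reps]
        for key in metric_reps[0]:
            out[f"QS:Mn-{key}-{cond}"] = float(
                np.mean([m[key] for m in metric_reps])
            )

    # --- gait
    walks = [t for t in trials if t.modality == "gait_markers"]
    tables = []
    for w in sorted(walks, key=lambda t: t.trial_id):
        events = detect_gait_events(w, config)
        if events is None:
            continue
        tables.append(stride_parameters(events, w, config))
    if tables:
        out.update(gait_summary(tables, config))
    return out


def assemble_feature_table(
    subject_measures: dict[str, dict[str, float]],
    registry: list[MeasureID] | None = None,
) -> pd.DataFrame:
    """Stack per-subject measure dicts into a subjects x measures table.

    Rows follow insertion order of ``subject_measures``; columns are the
    registry (default: the canonical 92). Measures absent for a subject are
    missing (NaN). Duplicate subject ids raise.
    """
    ids = list(subject_measures)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject ids")
    cols = registry_ids(registry if registry is not None else default_registry())
    data = {
        sid: [vals.get(c, float("nan")) for c in cols]
        for sid, vals in subject_measures.items()
    }
    table = pd.DataFrame.from_dict(data, orient="index", columns=cols)
    table.index.name = "subject_id"
    return table
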