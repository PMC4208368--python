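"""Synthetic cohort generator.

Emulates a laboratory fall-risk study in older women: two retrospectively
classified groups (fallers / non-fallers, the latter containing a small
prospective first-time-faller subset), each subject measured in three
functional domains — isometric force control at the knee and ankle, quiet
standing on force plates (eyes open / closed), and barefoot walking over a
10 m walkway with foot markers.

The generative model is deliberately simple: each subject carries a latent
vector over the seven functional domains that the analysis is expected to
recover (static balance, temporal gait, spatial gait, temporal variability
right/left, spatial variability, dynamic balance), drawn from group-specific
multivariate normals with identity covariance (truncated at +-3 SD) and
group mean shifts given by ``effect_sizes``. Within-subject (cycle- and
trial-level) variation is i.i.d. normal on top. Strength and force-steadiness
quantities are mixtures of the same seven latents plus trial noise — the
generator plants no separate strength domain, so exactly seven common factors
underlie the 92-measure battery.

Group contrasts default to the reported directionality: fallers have shorter
strides/steps and lower foot clearance (spatial gait down) and larger
inter-cycle temporal variability on both feet; every other domain overlaps.
First-time fallers sit midway between the group means.

Two sampling paths share every random draw: :func:`generate_cohort`
synthesises full raw trials (marker trajectories with planted gait events,
CoP traces, torque traces) for the signal-level pipeline, while
:func:`sample_cohort_features` summarises the identical cycle-level draws
directly into the feature table, bypassing marker synthesis and event
detection (which the event-recovery tests show to be exact to one sample).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numpy.random import SeedSequence, default_rng
from scipy import signal as sps

from .features import (
    ExtractionConfig,
    StrideTable,
    _intersect_total,
    assemble_feature_table,
    butterworth_filter,
    compute_mvic,
    cop_metrics,
    gait_summary,
    preprocess_cop,
    summary_stats,
    trim_signal,
)
from .trial import RawTrial

__all__ = [
    "DOMAINS",
    "DEFAULT_EFFECT_SIZES",
    "CohortSpec",
    "SubjectParams",
    "draw_subject_params",
    "generate_gait_trial",
    "generate_cop_trial",
    "generate_torque_trial",
    "generate_cohort",
    "iter_cohort",
    "sample_cohort_features",
    "build_manifest",
]

DOMAINS = (
    "static_balance",
    "temporal_gait",
    "spatial_gait",
    "temporal_variability_right",
    "temporal_variability_left",
    "spatial_variability",
    "dynamic_balance",
)

#: standardized faller-minus-nonfaller latent mean differences
DEFAULT_EFFECT_SIZES = {
    "static_balance": 0.0,
    "temporal_gait": 0.0,
    "spatial_gait": -0.85,
    "temporal_variability_right": 0.45,
    "temporal_variability_left": 0.60,
    "spatial_variability": 0.0,
    "dynamic_balance": 0.0,
}

_JOINTS = ("KE", "PF")
_TARGETS = ("c15", "c20", "r1520")


@dataclass
class CohortSpec:
    """Study design of a synthetic cohort."""

    n_fallers: int = 38
    n_nonfallers: int = 42
    n_ftf: int = 6
    seed: int = 0
    effect_sizes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_SIZES)
    )
    #: per-domain multipliers on the within-subject noise scales
    noise_sd: dict[str, float] = field(default_factory=dict)
    gait_hz: float = 100.0
    cop_hz: float = 120.0
    torque_hz: float = 100.0
    n_walks: int = 6
    sway_reps: int = 3
    torque_reps: int = 3
    mvic_reps: int = 3
    walkway_m: float = 10.0
    sway_duration_s: float = 30.0
    torque_duration_s: float = 15.0
    mvic_duration_s: float = 10.0

    def __post_init__(self) -> None:
        if self.n_fallers <= 0 or self.n_nonfallers <= 0:
            raise ValueError("n_fallers and n_nonfallers must be > 0")
        if not 0 <= self.n_ftf <= self.n_nonfallers:
            raise ValueError("n_ftf must lie within the non-faller group")
        for name in ("gait_hz", "cop_hz", "torque_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_walks < 6:
            raise ValueError("at least 6 walks are required")
        if self.sway_reps < 3:
            raise ValueError("3 sway repetitions per condition are required")
        if self.torque_reps < 3 or self.mvic_reps < 3:
            raise ValueError("at least 3 torque trials per condition are required")
        unknown = set(self.effect_sizes) - set(DOMAINS)
        if unknown:
            raise ValueError(f"unknown effect-size domains: {sorted(unknown)}")
        unknown = set(self.noise_sd) - set(DOMAINS)
        if unknown:
            raise ValueError(f"unknown noise_sd domains: {sorted(unknown)}")

    @property
    def n_subjects(self) -> int:
        return self.n_fallers + self.n_nonfallers


@dataclass
class SubjectParams:
    """Subject-level generative parameters (SI units)."""

    subject_id: str
    group: str  # faller | nonfaller | ftf
    latents: dict[str, float]
    # gait, spatial
    stride_length: float  # m
    step_width: float  # m
    maxfc: dict[str, float]  # m, per foot
    minfc: dict[str, float]  # m, per foot
    # gait, temporal
    stride_time: float  # s
    stance_frac: float  # stance fraction of the cycle
    phase: float  # contralateral strike phase within the cycle
    # within-subject cycle noise
    stride_time_sd: dict[str, float]  # s, per foot
    stride_length_sd: float  # m
    step_width_sd: float  # m
    stance_frac_sd: float
    phase_sd: float
    maxfc_sd: float = 0.006
    minfc_sd: float = 0.003
    marker_noise_sd: float = 0.0003  # m, sensor noise on marker positions
    # quiet standing
    sway_amp: dict[str, float] = field(default_factory=dict)  # m per condition
    sway_theta: dict[str, float] = field(default_factory=dict)  # Hz per condition
    sway_trial_jitter: float = 0.10
    # force control
    mvic: dict[str, float] = field(default_factory=dict)  # N*m per joint
    tremor_cv: dict[str, float] = field(default_factory=dict)  # per joint
    #: optional per-"joint:target" steadiness override (falls back to the
    #: joint-level CV)
    tremor_cv_target: dict[str, float] = field(default_factory=dict)
    tremor_trial_jitter: float = 0.08
    #: attempt-to-attempt force noise scales with the subject's steadiness
    mvic_attempt_factor: float = 0.6  # log-SD of an MVIC attempt, x tremor CV
    target_bias_factor: float = 1.8  # log-SD of the held submaximal level, x CV

    def __post_init__(self) -> None:
        if self.group not in ("faller", "nonfaller", "ftf"):
            raise ValueError(f"unknown group {self.group!r}")
        positives = {
            "stride_length": self.stride_length,
            "stride_time": self.stride_time,
            "step_width": self.step_width,
            **{f"maxfc_{k}": v for k, v in self.maxfc.items()},
            **{f"mvic_{k}": v for k, v in self.mvic.items()},
            **{f"sway_amp_{k}": v for k, v in self.sway_amp.items()},
            **{f"sway_theta_{k}": v for k, v in self.sway_theta.items()},
        }
        for name, v in positives.items():
            if v <= 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        for k, v in self.stride_time_sd.items():
            if v < 0:
                raise ValueError(f"stride_time_sd[{k}] must be >= 0")
        for k, v in self.minfc.items():
            if v < 0:
                raise ValueError(f"minfc[{k}] must be >= 0")
        if not 0.4 < self.stance_frac < 0.8:
            raise ValueError("stance_frac outside the physiological 0.4-0.8 band")
        if not 0.3 < self.phase < 0.7:
            raise ValueError("phase outside the 0.3-0.7 band")
        if self.phase >= self.stance_frac:
            raise ValueError(
                "phase must precede stance fraction (double support > 0)"
            )

    @property
    def swing_frac(self) -> float:
        """Swing fraction; stance + swing = 1 per cycle."""
        return 1.0 - self.stance_frac


def _group_shift(group: str, effect_sizes: dict[str, float]) -> np.ndarray:
    sign = {"faller": +0.5, "nonfaller": -0.5, "ftf": 0.0}[group]
    return np.array([sign * effect_sizes.get(d, 0.0) for d in DOMAINS])


def draw_subject_params(
    spec: CohortSpec, subject_id: str, group: str, rng: np.random.Generator
) -> SubjectParams:
    """Draw one subject's latent vector and map it to physical parameters."""
    z = rng.standard_normal(len(DOMAINS))
    z = np.clip(z, -3.0, 3.0) + _group_shift(group, spec.effect_sizes)
    lat = dict(zip(DOMAINS, z))
    b = lat["static_balance"]
    g = lat["temporal_gait"]
    s = lat["spatial_gait"]
    vr = lat["temporal_variability_right"]
    vl = lat["temporal_variability_left"]
    sv = lat["spatial_variability"]
    d = lat["dynamic_balance"]
    ns = {dom: spec.noise_sd.get(dom, 1.0) for dom in DOMAINS}

    eta = rng.standard_normal(24)  # subject-level measure-specific jitter

    stride_length = 1.22 * np.exp(0.065 * s + 0.020 * eta[0])
    maxfc = {
        "L": 0.125 * np.exp(0.10 * s + 0.035 * eta[1]),
        "R": 0.125 * np.exp(0.10 * s + 0.035 * eta[2]),
    }
    minfc = {
        "L": 0.023 * np.exp(0.12 * s + 0.05 * eta[3]),
        "R": 0.023 * np.exp(0.12 * s + 0.05 * eta[4]),
    }
    stride_time = 1.07 * np.exp(0.045 * g + 0.012 * eta[5])
    stance_frac = float(np.clip(0.62 * (1 + 0.004 * eta[6]), 0.55, 0.68))
    phase = float(np.clip(0.50 * (1 + 0.004 * eta[7]), 0.46, 0.54))
    stride_time_sd = {
        "R": 0.021 * ns["temporal_variability_right"] * np.exp(0.45 * vr + 0.05 * eta[8]),
        "L": 0.021 * ns["temporal_variability_left"] * np.exp(0.45 * vl + 0.05 * eta[9]),
    }
    stride_length_sd = 0.018 * ns["spatial_variability"] * np.exp(0.45 * sv + 0.05 * eta[10])
    # wider steps accompany poorer standing balance
    step_width = 0.09 * np.exp(0.12 * (0.75 * b + 0.66 * eta[11]))
    step_width_sd = 0.010 * ns["spatial_variability"] * np.exp(0.45 * sv + 0.05 * eta[12])
    # contact-timing noise is kept small: double-support variability then
    # reflects both feet's stride-timing noise (a bilateral mixture)
    stance_frac_sd = 0.002 * np.exp(0.30 * d + 0.10 * eta[13])
    phase_sd = 0.003 * np.exp(0.30 * d + 0.10 * eta[14])
    maxfc_sd = 0.006 * ns["spatial_variability"] * np.exp(0.40 * sv + 0.10 * eta[23])
    minfc_sd = 0.003 * ns["spatial_variability"] * np.exp(0.40 * sv)

    amp_qec = 0.0085 * ns["static_balance"] * np.exp(0.30 * b + 0.05 * eta[15])
    sway_amp = {"QEC": amp_qec, "QEO": amp_qec / 1.5 * np.exp(0.08 * eta[16])}
    # sway bandwidth (how fast the CoP is steered about its mean) is its own
    # postural-regulation domain, independent of sway magnitude
    sway_theta = {
        "QEC": 0.90 * np.exp(0.35 * d + 0.08 * eta[17]),
        "QEO": 1.00 * np.exp(0.35 * d + 0.08 * eta[18]),
    }

    # strength/steadiness: mixtures of the seven domains + subject jitter only
    # (no separate strength domain is planted; stronger subjects walk with
    # longer strides, higher cadence and steadier stance)
    mvic = {
        "KE": 150.0 * np.exp(0.13 * (0.55 * s - 0.55 * g + 0.45 * b) + 0.015 * eta[19]),
        "PF": 60.0 * np.exp(0.13 * (0.50 * s - 0.55 * g + 0.50 * b) + 0.015 * eta[20]),
    }
    # steadiness at each force level taps a different pair of control
    # domains, so no single force-steadiness direction (and hence no eighth
    # factor) exists in the battery
    tremor_mix = {
        "KE:c15": 0.55 * b + 0.55 * vl + 0.20 * vr,
        "KE:c20": 0.20 * b + 0.55 * vl + 0.55 * vr,
        "KE:r1520": 0.55 * b + 0.20 * vl + 0.55 * vr,
        "PF:c15": 0.55 * b + 0.20 * vl + 0.55 * vr,
        "PF:c20": 0.55 * b + 0.55 * vl + 0.20 * vr,
        "PF:r1520": 0.20 * b + 0.55 * vl + 0.55 * vr,
    }
    tremor_cv_target = {
        key: 0.035 * np.exp(0.50 * mix + 0.10 * eta[21] + 0.05 * eta[22])
        for key, mix in tremor_mix.items()
    }
    tremor_cv = {
        "KE": float(np.mean([tremor_cv_target[f"KE:{t}"] for t in ("c15", "c20", "r1520")])),
        "PF": float(np.mean([tremor_cv_target[f"PF:{t}"] for t in ("c15", "c20", "r1520")])),
    }

    return SubjectParams(
        subject_id=subject_id,
        group=group,
        latents=lat,
        stride_length=float(stride_length),
        step_width=float(step_width),
        maxfc={k: float(v) for k, v in maxfc.items()},
        minfc={k: float(v) for k, v in minfc.items()},
        stride_time=float(stride_time),
        stance_frac=stance_frac,
        phase=phase,
        stride_time_sd={k: float(v) for k, v in stride_time_sd.items()},
        stride_length_sd=float(stride_length_sd),
        step_width_sd=float(step_width_sd),
        stance_frac_sd=float(stance_frac_sd),
        phase_sd=float(phase_sd),
        maxfc_sd=float(maxfc_sd),
        minfc_sd=float(minfc_sd),
        sway_amp={k: float(v) for k, v in sway_amp.items()},
        sway_theta={k: float(v) for k, v in sway_theta.items()},
        mvic={k: float(v) for k, v in mvic.items()},
        tremor_cv={k: float(v) for k, v in tremor_cv.items()},
        tremor_cv_target={k: float(v) for k, v in tremor_cv_target.items()},
    )


# ---------------------------------------------------------------------------
# walk plans: the cycle-level draws shared by both sampling paths


@dataclass
class WalkPlan:
    """Planted events of one walk (continuous times/positions)."""

    hs_t: dict[str, np.ndarray]
    hs_x: dict[str, np.ndarray]
    hs_y: dict[str, np.ndarray]
    to_t: dict[str, np.ndarray]  # one toe-off per stride (after each strike
    #                              except the last)
    maxfc: dict[str, np.ndarray]  # per stride (swing apex height)
    minfc: dict[str, np.ndarray]  # per stride (mid-swing minimum)
    duration: float


def draw_walk_plan(params: SubjectParams, rng: np.random.Generator,
                   walkway_m: float = 10.0) -> WalkPlan:
    """Draw the cycle-level randomness of one walk and lay out its events.

    Strike times follow a drift-free clock with i.i.d. per-strike timing
    jitter (per foot, SD = stride-time SD / sqrt(2), so successive stride
    times have the subject's stride-time SD); strike positions accumulate
    i.i.d. stride-length increments; the contralateral foot strikes midway
    (in space) between the surrounding ipsilateral strikes.
    """
    T = params.stride_time
    L = params.stride_length
    usable = walkway_m - 0.6
    n_strides = min(7, int(usable // L))
    if n_strides < 1:
        raise ValueError(
            f"walkway {walkway_m} m too short for one stride of {L:.2f} m"
        )
    n_l = n_strides + 1  # left strikes
    n_r = n_strides  # right strikes

    jit_l = rng.normal(0.0, params.stride_time_sd["L"] / np.sqrt(2), n_l)
    jit_r = rng.normal(0.0, params.stride_time_sd["R"] / np.sqrt(2), n_r)
    ph = params.phase + rng.normal(0.0, params.phase_sd, n_r)
    sf_l = params.stance_frac + rng.normal(0.0, params.stance_frac_sd, n_l)
    sf_r = params.stance_frac + rng.normal(0.0, params.stance_frac_sd, n_r)
    dl = rng.normal(0.0, params.stride_length_sd, n_l - 1)
    gam = rng.normal(0.0, 0.7 * params.stride_length_sd, n_r)
    wy_l = rng.normal(0.0, params.step_width_sd / np.sqrt(2), n_l)
    wy_r = rng.normal(0.0, params.step_width_sd / np.sqrt(2), n_r)
    mfc = {
        side: np.clip(
            params.maxfc[side] + rng.normal(0.0, params.maxfc_sd, n),
            0.02,
            None,
        )
        for side, n in (("L", n_l - 1), ("R", max(n_r - 1, 0)))
    }
    mnf = {
        side: np.clip(
            params.minfc[side] + rng.normal(0.0, params.minfc_sd, n),
            0.004,
            None,
        )
        for side, n in (("L", n_l - 1), ("R", max(n_r - 1, 0)))
    }
    for side in ("L", "R"):  # apex strictly above the mid-swing minimum
        mnf[side] = np.minimum(mnf[side], 0.6 * mfc[side])

    t0 = 0.6
    hs_l = t0 + np.arange(n_l) * T + jit_l
    hs_r = t0 + (np.arange(n_r) + ph) * T + jit_r
    x_l = 0.3 + np.concatenate(([0.0], np.cumsum(L + dl)))
    x_r = 0.5 * (x_l[:-1] + x_l[1:]) + gam
    y_l = +(params.step_width / 2) + wy_l
    y_r = -(params.step_width / 2) + wy_r

    def _toe_offs(hs: np.ndarray, sf: np.ndarray) -> np.ndarray:
        return hs[:-1] + sf[:-1] * np.diff(hs)

    plan = WalkPlan(
        hs_t={"L": hs_l, "R": hs_r},
        hs_x={"L": x_l, "R": x_r},
        hs_y={"L": y_l, "R": y_r},
        to_t={"L": _toe_offs(hs_l, sf_l), "R": _toe_offs(hs_r, sf_r)},
        maxfc=mfc,
        minfc=mnf,
        duration=float(max(hs_l[-1], hs_r[-1] if n_r else 0.0) + 0.7),
    )
    return plan


def _stance_intervals(plan: WalkPlan, side: str) -> list[tuple[float, float]]:
    hs, to = plan.hs_t[side], plan.to_t[side]
    ivals = [(0.0, to[0] if len(to) else plan.duration)]
    for i in range(len(hs) - 1):
        ivals.append((hs[i], to[i]))
    ivals.append((hs[-1], plan.duration))
    # first interval above duplicates strike 0's stance start at t=0 (the
    # foot begins the trial on the ground); merge overlaps conservatively
    ivals = sorted(set(ivals))
    merged: list[tuple[float, float]] = []
    for a, b in ivals:
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def stride_table_from_plan(plan: WalkPlan) -> StrideTable:
    """Exact stride parameters implied by a walk plan (the feature-level
    path; mirrors what event detection recovers from the synthesised trial)."""
    stance = {side: _stance_intervals(plan, side) for side in ("L", "R")}
    rows = []
    for side in ("L", "R"):
        other = "R" if side == "L" else "L"
        hs, to = plan.hs_t[side], plan.to_t[side]
        n_str = len(hs) - 1
        for i in range(n_str):
            if i == 0 or i == n_str - 1:  # transient strides trimmed
                continue
            t0, t1 = hs[i], hs[i + 1]
            rows.append(
                dict(
                    foot=side,
                    stride_time=t1 - t0,
                    stance_time=to[i] - t0,
                    swing_time=t1 - to[i],
                    dst=_intersect_total(stance[side], stance[other], t0, t1),
                    stride_length=plan.hs_x[side][i + 1] - plan.hs_x[side][i],
                    maxfc=plan.maxfc[side][i],
                    minfc=plan.minfc[side][i],
                )
            )
    strides = pd.DataFrame(rows)

    merged = sorted(
        (t, side, plan.hs_x[side][k], plan.hs_y[side][k])
        for side in ("L", "R")
        for k, t in enumerate(plan.hs_t[side])
    )
    step_rows = [
        dict(step_length=b[2] - a[2], step_width=abs(b[3] - a[3]))
        for a, b in zip(merged[:-1], merged[1:])
        if a[1] != b[1]
    ][1:-1]
    cadence = 120.0 / float(strides["stride_time"].mean()) if len(strides) else float("nan")
    return StrideTable(strides=strides, steps=pd.DataFrame(step_rows), cadence=cadence)


# ---------------------------------------------------------------------------
# raw-signal synthesis


def _swing_z(s: np.ndarray, apex: float, mid_min: float) -> np.ndarray:
    """Vertical toe profile over normalized swing time ``s`` in [0, 1].

    Quarter-sine rise to the apex (peak upward velocity at toe-off), cosine
    descent to the mid-swing minimum, partial recovery, then quarter-cosine
    final descent so the peak downward velocity occurs exactly at touchdown —
    the signature the foot-velocity event detector keys on.
    """
    h2 = mid_min + 0.45 * (apex - mid_min)
    z = np.empty_like(s)
    m1 = s < 0.30
    z[m1] = apex * np.sin(np.pi / 2 * s[m1] / 0.30)
    m2 = (s >= 0.30) & (s < 0.55)
    u = (s[m2] - 0.30) / 0.25
    z[m2] = mid_min + (apex - mid_min) * (1 + np.cos(np.pi * u)) / 2
    m3 = (s >= 0.55) & (s < 0.78)
    u = (s[m3] - 0.55) / 0.23
    z[m3] = mid_min + (h2 - mid_min) * (1 - np.cos(np.pi * u)) / 2
    m4 = s >= 0.78
    u = (s[m4] - 0.78) / 0.22
    z[m4] = h2 * np.cos(np.pi / 2 * u)
    return z


# fixed marker offsets (m) in the foot frame: (along AP, along ML)
_MARKER_OFFSETS = {
    "heel": (-0.10, 0.0),
    "met23": (+0.06, 0.0),
    "met1": (+0.13, +0.025),
    "met5": (+0.10, -0.035),
}


def generate_gait_trial(
    params: SubjectParams,
    walk_index: int,
    seed,
    rate: float = 100.0,
    walkway_m: float = 10.0,
    plan: WalkPlan | None = None,
) -> tuple[RawTrial, dict]:
    """Synthesize one walking trial; returns the trial plus its ground truth
    (planted event times/positions and per-stride clearances)."""
    rng = default_rng(seed)
    if plan is None:
        plan = draw_walk_plan(params, rng, walkway_m)
    n = int(round(plan.duration * rate))
    t = np.arange(n) / rate
    channels: dict[str, np.ndarray] = {}
    for side in ("L", "R"):
        hs, to = plan.hs_t[side], plan.to_t[side]
        xs, ys = plan.hs_x[side], plan.hs_y[side]
        # lead-in: the foot starts one stride behind and lands at the first
        # planted strike, so every planted strike is a real touchdown
        swing_dur = (1 - params.stance_frac) * params.stride_time
        lead_to = max(hs[0] - swing_dur, 0.15)
        lead_x = xs[0] - params.stride_length
        x = np.full(n, lead_x)
        y = np.full(n, ys[0])
        z = np.zeros(n)
        # lead-in swing
        swing = (t >= lead_to) & (t < hs[0])
        s = (t[swing] - lead_to) / (hs[0] - lead_to)
        blend = (1 - np.cos(np.pi * s)) / 2
        x[swing] = lead_x + (xs[0] - lead_x) * blend
        z[swing] = _swing_z(s, params.maxfc[side], params.minfc[side])
        after = t >= hs[0]
        x[after], y[after] = xs[0], ys[0]
        for i in range(len(hs) - 1):
            stance = (t >= hs[i]) & (t < to[i])
            x[stance], y[stance] = xs[i], ys[i]
            swing = (t >= to[i]) & (t < hs[i + 1])
            s = (t[swing] - to[i]) / (hs[i + 1] - to[i])
            blend = (1 - np.cos(np.pi * s)) / 2
            x[swing] = xs[i] + (xs[i + 1] - xs[i]) * blend
            y[swing] = ys[i] + (ys[i + 1] - ys[i]) * blend
            z[swing] = _swing_z(s, plan.maxfc[side][i], plan.minfc[side][i])
        tail = t >= hs[-1]
        x[tail], y[tail] = xs[-1], ys[-1]
        for role, (dx, dy) in _MARKER_OFFSETS.items():
            for ax, base in (("x", x + dx), ("y", y + dy), ("z", z)):
                noise = rng.normal(0.0, params.marker_noise_sd, n) if params.marker_noise_sd else 0.0
                channels[f"{side}_{role}_{ax}"] = base + noise
    trial = RawTrial(
        trial_id=f"{params.subject_id}_walk{walk_index:02d}",
        subject_id=params.subject_id,
        modality="gait_markers",
        condition=f"walk{walk_index:02d}",
        rate=rate,
        channels=channels,
        units={name: "m" for name in channels},
    )
    truth = {
        "hs_t": {k: v.tolist() for k, v in plan.hs_t.items()},
        "hs_x": {k: v.tolist() for k, v in plan.hs_x.items()},
        "hs_y": {k: v.tolist() for k, v in plan.hs_y.items()},
        "to_t": {k: v.tolist() for k, v in plan.to_t.items()},
        "maxfc": {k: v.tolist() for k, v in plan.maxfc.items()},
        "minfc": {k: v.tolist() for k, v in plan.minfc.items()},
    }
    return trial, truth


def _ar1(n: int, sd: float, rho: float, rng: np.random.Generator) -> np.ndarray:
    eps = rng.standard_normal(n)
    x = sps.lfilter([np.sqrt(1 - rho**2)], [1, -rho], eps)
    x[0] = eps[0]  # stationary start
    return sd * x


def generate_cop_trial(
    params: SubjectParams,
    condition: str,
    seed,
    rate: float = 120.0,
    duration_s: float = 30.0,
    rep: int = 0,
    amp_jitter: float | None = None,
) -> RawTrial:
    """Synthesize a 30 s two-channel CoP trace: a mean-reverting (AR(1))
    random sway with subject-specific amplitude and bandwidth; the eyes-closed
    amplitude exceeds eyes-open by the subject's QEC/QEO ratio."""
    if condition not in ("QEO", "QEC"):
        raise ValueError(f"unknown standing condition {condition!r}")
    rng = default_rng(seed)
    if amp_jitter is None:
        amp_jitter = float(np.exp(rng.normal(0.0, params.sway_trial_jitter)))
    amp = params.sway_amp[condition] * amp_jitter
    theta = params.sway_theta[condition]
    rho = float(np.exp(-2 * np.pi * theta / rate))
    n = int(round(duration_s * rate))
    ap = _ar1(n, amp, rho, rng) + rng.normal(0.0, 0.002)
    ml = _ar1(n, 0.6 * amp, rho, rng) + rng.normal(0.0, 0.002)
    return RawTrial(
        trial_id=f"{params.subject_id}_{condition}_r{rep}",
        subject_id=params.subject_id,
        modality="cop",
        condition=condition,
        rate=rate,
        channels={"AP": ap, "ML": ml},
        units={"AP": "m", "ML": "m"},
    )


def _band_noise(n: int, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-SD low-frequency (<= 4 Hz) physiological tremor carrier."""
    w = rng.standard_normal(n)
    x = butterworth_filter(w, 2, 4.0, rate)
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def generate_torque_trial(
    params: SubjectParams,
    joint: str,
    target: str,
    seed,
    rate: float = 100.0,
    duration_s: float = 15.0,
    mvic_duration_s: float = 10.0,
    rep: int = 0,
    mvic_reference: float | None = None,
) -> RawTrial:
    """Synthesize one torque trial.

    ``target='mvic'``: a rise-plateau-release contraction peaking at the
    subject's latent MVIC (times attempt noise proportional to the subject's
    force steadiness). Submaximal targets track 15%, 20% or a ramped 15-20%
    of ``mvic_reference`` (the measured MVIC; defaults to the latent value)
    with multiplicative tremor at the subject's force-steadiness CV.
    """
    if joint not in _JOINTS:
        raise ValueError(f"unknown joint {joint!r}")
    rng = default_rng(seed)
    cv = params.tremor_cv_target.get(f"{joint}:{target}", params.tremor_cv[joint])
    if target == "mvic":
        n = int(round(mvic_duration_s * rate))
        t = np.arange(n) / rate
        attempt_sd = params.mvic_attempt_factor * cv
        peak = params.mvic[joint] * float(np.exp(rng.normal(0.0, attempt_sd)))
        rise = np.clip(t / 3.0, 0, 1)
        fall = np.clip((mvic_duration_s - t) / 1.0, 0, 1)
        profile = np.minimum(3 * rise**2 - 2 * rise**3, fall)
        torque = peak * profile
    elif target in _TARGETS:
        ref = mvic_reference if mvic_reference is not None else params.mvic[joint]
        n = int(round(duration_s * rate))
        t = np.arange(n) / rate
        bias = float(np.exp(rng.normal(0.0, params.target_bias_factor * cv)))
        if target == "r1520":
            frac = 0.15 + 0.05 * t / duration_s
        else:
            frac = np.full(n, 0.15 if target == "c15" else 0.20)
        level = frac * ref * bias
        cv_trial = cv * float(np.exp(rng.normal(0.0, params.tremor_trial_jitter))) if cv > 0 else 0.0
        tremor = cv_trial * _band_noise(n, rate, rng) if cv_trial > 0 else 0.0
        ramp_in = np.clip(t / 1.5, 0, 1)
        torque = level * (1.0 + tremor) * (3 * ramp_in**2 - 2 * ramp_in**3)
    else:
        raise ValueError(f"unknown torque target {target!r}")
    return RawTrial(
        trial_id=f"{params.subject_id}_{joint}_{target}_r{rep}",
        subject_id=params.subject_id,
        modality="torque",
        condition=f"{joint}:{target}",
        rate=rate,
        channels={"torque": np.maximum(torque, 0.0)},
        units={"torque": "N*m"},
    )


# ---------------------------------------------------------------------------
# cohort assembly


@dataclass
class SubjectRecord:
    params: SubjectParams
    trials: list[RawTrial]
    ground_truth: dict[str, dict]  # per gait trial id


def _subject_groups(spec: CohortSpec) -> list[tuple[str, str]]:
    out = []
    for i in range(spec.n_fallers):
        out.append((f"S{i + 1:03d}", "faller"))
    n_plain_nf = spec.n_nonfallers - spec.n_ftf
    for i in range(spec.n_nonfallers):
        sid = f"S{spec.n_fallers + i + 1:03d}"
        out.append((sid, "nonfaller" if i < n_plain_nf else "ftf"))
    return out


def _subject_plan(spec: CohortSpec, sid: str, group: str, child: SeedSequence):
    """Everything random about one subject, in a fixed draw order shared by
    the signal-level and feature-level paths."""
    rng = default_rng(child)
    params = draw_subject_params(spec, sid, group, rng)
    anthro = dict(
        age=float(np.clip(rng.normal(69.0, 4.6), 60, 85)),
        weight_kg=float(rng.normal(69.0, 10.0)),
        height_cm=float(rng.normal(162.0, 6.5)),
    )
    walks = [draw_walk_plan(params, rng, spec.walkway_m) for _ in range(spec.n_walks)]
    trial_seeds = rng.integers(0, 2**62, size=1000)
    return params, anthro, walks, iter(trial_seeds)


def iter_cohort(spec: CohortSpec):
    """Yield one :class:`SubjectRecord` per subject (full raw trials)."""
    root = SeedSequence(spec.seed)
    children = root.spawn(spec.n_subjects)
    for (sid, group), child in zip(_subject_groups(spec), children):
        params, anthro, walks, seeds = _subject_plan(spec, sid, group, child)
        trials: list[RawTrial] = []
        truth: dict[str, dict] = {}
        for w, plan in enumerate(walks):
            trial, gt = generate_gait_trial(
                params, w, next(seeds), rate=spec.gait_hz,
                walkway_m=spec.walkway_m, plan=plan,
            )
            trials.append(trial)
            truth[trial.trial_id] = gt
        for cond in ("QEO", "QEC"):
            for rep in range(spec.sway_reps):
                trials.append(
                    generate_cop_trial(
                        params, cond, next(seeds), rate=spec.cop_hz,
                        duration_s=spec.sway_duration_s, rep=rep,
                    )
                )
        for joint in _JOINTS:
            mvic_trials = [
                generate_torque_trial(
                    params, joint, "mvic", next(seeds), rate=spec.torque_hz,
                    mvic_duration_s=spec.mvic_duration_s, rep=rep,
                )
                for rep in range(spec.mvic_reps)
            ]
            trials.extend(mvic_trials)
            measured = compute_mvic(mvic_trials)
            for target in _TARGETS:
                for rep in range(spec.torque_reps):
                    trials.append(
                        generate_torque_trial(
                            params, joint, target, next(seeds),
                            rate=spec.torque_hz,
                            duration_s=spec.torque_duration_s, rep=rep,
                            mvic_reference=measured,
                        )
                    )
        yield SubjectRecord(params=params, trials=trials, ground_truth=truth), anthro


def generate_cohort(spec: CohortSpec) -> tuple[list[SubjectRecord], pd.DataFrame]:
    """Materialize the full cohort plus its manifest."""
    records = []
    anthros = []
    for rec, anthro in iter_cohort(spec):
        records.append(rec)
        anthros.append((rec.params, anthro))
    return records, build_manifest(anthros)


def build_manifest(subjects: list[tuple[SubjectParams, dict]]) -> pd.DataFrame:
    rows = {}
    for params, anthro in subjects:
        rows[params.subject_id] = dict(
            group=params.group,
            fall_label=int(params.group == "faller"),
            follow_up_fall=int(params.group == "ftf"),
            **anthro,
        )
    m = pd.DataFrame.from_dict(rows, orient="index")
    m.index.name = "subject_id"
    return m


def sample_cohort_features(
    spec: CohortSpec, config: ExtractionConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fast feature-level path: the same per-subject draws, summarised
    directly into the subjects x 92 feature table (plus manifest)."""
    config = config or ExtractionConfig()
    root = SeedSequence(spec.seed)
    children = root.spawn(spec.n_subjects)
    measures: dict[str, dict[str, float]] = {}
    anthros = []
    for (sid, group), child in zip(_subject_groups(spec), children):
        params, anthro, walks, seeds = _subject_plan(spec, sid, group, child)
        anthros.append((params, anthro))
        out: dict[str, float] = {}
        for _ in range(spec.n_walks):  # consume the gait trial seeds
            next(seeds)
        tables = [stride_table_from_plan(p) for p in walks]
        out.update(gait_summary(tables, config))
        for cond in ("QEO", "QEC"):
            reps = [
                cop_metrics(
                    preprocess_cop(
                        generate_cop_trial(
                            params, cond, next(seeds), rate=spec.cop_hz,
                            duration_s=spec.sway_duration_s, rep=rep,
                        ),
                        config,
                    )
                )
                for rep in range(spec.sway_reps)
            ]
            for key in reps[0]:
                out[f"QS:Mn-{key}-{cond}"] = float(np.mean([r[key] for r in reps]))
        for joint in _JOINTS:
            mvic_trials = [
                generate_torque_trial(
                    params, joint, "mvic", next(seeds), rate=spec.torque_hz,
                    mvic_duration_s=spec.mvic_duration_s, rep=rep,
                )
                for rep in range(spec.mvic_reps)
            ]
            order, cutoff = config.torque_filter
            measured = compute_mvic(mvic_trials, order, cutoff)
            out[f"FC:Mn-MVIC-{joint}"] = measured
            for target in _TARGETS:
                stats = []
                for rep in range(spec.torque_reps):
                    trial = generate_torque_trial(
                        params, joint, target, next(seeds), rate=spec.torque_hz,
                        duration_s=spec.torque_duration_s, rep=rep,
                        mvic_reference=measured,
                    )
                    trimmed = trim_signal(trial, *config.torque_trim)
                    x = butterworth_filter(
                        trimmed.channels["torque"], order, cutoff, trial.rate
                    )
                    stats.append(summary_stats(x))
                out[f"FC:Mn-{target}-{joint}"] = float(np.mean([s.mean for s in stats]))
                out[f"FC:SD-{target}-{joint}"] = float(np.mean([s.sd for s in stats]))
                out[f"FC:CV-{target}-{joint}"] = float(np.mean([s.cv for s in stats]))
        measures[sid] = out
    table = assemble_feature_table(measures)
    return table, build_manifest(anthros)
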