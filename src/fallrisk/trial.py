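"""In-memory container for one recorded (or simulated) trial.

A trial is a uniformly sampled multichannel time series: marker trajectories
for walking trials, centre-of-pressure traces for standing trials, torque
traces for force-matching trials. Axis convention: x = direction of
progression (AP), y = medio-lateral, z = vertical; metres; ground at z = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MODALITIES = ("gait_markers", "cop", "torque")

#: marker roles required per foot in a gait trial
GAIT_MARKER_ROLES = ("heel", "met1", "met5", "met23")


@dataclass
class RawTrial:
    """One recorded trial.

    Parameters
    ----------
    trial_id, subject_id : str
    modality : {"gait_markers", "cop", "torque"}
    condition : str
        Condition tag, e.g. ``QEO``/``QEC``, ``KE:c15``, ``walk03``.
    rate : float
        Sampling rate in samples/s.
    channels : dict of str -> ndarray
        Named series; all the same length. CoP trials use ``AP``/``ML`` (m),
        torque trials ``torque`` (N·m), gait trials ``<side>_<role>_<axis>``
        (m) for sides L/R, roles heel/met1/met5/met23 and axes x/y/z.
    units : dict of str -> str
    """

    trial_id: str
    subject_id: str
    modality: str
    condition: str
    rate: float
    channels: dict[str, np.ndarray]
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if not np.isfinite(self.rate) or self.rate <= 0:
            raise ValueError(f"sampling rate must be > 0, got {self.rate}")
        if not self.channels:
            raise ValueError("trial has no channels")
        lengths = {name: len(np.asarray(v)) for name, v in self.channels.items()}
        if len(set(lengths.values())) != 1:
            raise ValueError(f"channels have unequal lengths: {lengths}")
        self.channels = {
            name: np.ascontiguousarray(np.asarray(v, dtype=float))
            for name, v in self.channels.items()
        }
        for name, v in self.channels.items():
            if not np.all(np.isfinite(v)):
                raise ValueError(f"channel {name!r} contains non-finite samples")
        if self.modality == "gait_markers":
            missing = [
                f"{side}_{role}_{ax}"
                for side in ("L", "R")
                for role in GAIT_MARKER_ROLES
                for ax in ("x", "y", "z")
                if f"{side}_{role}_{ax}" not in self.channels
            ]
            if missing:
                raise ValueError(f"gait trial missing marker channels: {missing}")
        if self.modality == "cop" and not {"AP", "ML"} <= set(self.channels):
            raise ValueError("cop trial requires AP and ML channels")
        if self.modality == "torque" and "torque" not in self.channels:
            raise ValueError("torque trial requires a 'torque' channel")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration(self) -> float:
        """Trial duration in seconds (n samples at a constant rate)."""
        return self.n_samples / self.rate

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate

    def copy_with(self, channels: dict[str, np.ndarray]) -> "RawTrial":
        return RawTrial(
            trial_id=self.trial_id,
            subject_id=self.subject_id,
            modality=self.modality,
            condition=self.condition,
            rate=self.rate,
            channels=channels,
            units=dict(self.units),
        )
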