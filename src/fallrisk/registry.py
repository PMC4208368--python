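"""Canonical measure identifiers for the 92-measure functional battery.

Every feature produced by the pipeline is keyed by a :class:`MeasureID` whose
string form follows the test-domain naming scheme used throughout the package:
``<domain>:<statistic>-<metric>[-<suffix>...]``, e.g. ``GA:Mn-Str-T-L`` (mean
left stride time) or ``QS:Mn-VEL-AP-QEC`` (mean anterior-posterior sway
velocity, eyes closed).

Domains
-------
``QS``
    quiet standing (posturography), 28 measures: {Mn-DIST, RMS, Mn-VEL,
    Mn-FREQ} x {total, AP, ML} plus AREA and EA, for each of the QEO / QEC
    conditions (each averaged over the three repetitions).
``FC``
    force control, 20 measures: MVIC per joint plus mean/SD/CV of the torque
    trace at three submaximal targets (constant 15%, constant 20%, ramped
    15-20% of MVIC) for knee extensors (KE) and ankle plantarflexors (PF).
``GA``
    gait analysis, 44 measures: mean/SD/CV per foot of stride, stance, swing
    and double-support time, stride length and maximum foot clearance; mean
    minimum foot clearance per foot; mean/SD of cadence, step width and step
    length.

The exact composition of the original battery's measure list is not public;
this registry is the package's documented reconstruction (see
``docs/methods.md``) and can be overridden with any subset via the pipeline
configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "MeasureID",
    "parse_measure_id",
    "default_registry",
    "registry_ids",
    "load_registry",
]

_DOMAINS = ("QS", "FC", "GA")
_STATISTICS = ("Mn", "SD", "CV")
# suffix vocabulary: side, sway axis, standing condition, joint
_SUFFIXES = ("L", "R", "AP", "ML", "QEO", "QEC", "KE", "PF")

_METRICS = {
    "QS": ("DIST", "RMS", "VEL", "FREQ", "AREA", "EA"),
    "FC": ("MVIC", "c15", "c20", "r1520"),
    "GA": (
        "Str-T",
        "Stn-T",
        "Sw-T",
        "DST",
        "Str-Len",
        "MaxFC",
        "MinFC",
        "CAD",
        "SW",
        "Stp-Len",
    ),
}


@dataclass(frozen=True, order=True)
class MeasureID:
    """One canonical measure identifier.

    Parameters
    ----------
    domain : {"QS", "FC", "GA"}
    statistic : {"Mn", "SD", "CV"}
        Summary statistic across repetitions/cycles.
    metric : str
        Metric name within the domain (may itself contain hyphens,
        e.g. ``Str-T``).
    suffix : tuple of str
        Side/axis/condition/joint qualifiers, in canonical order.
    """

    domain: str
    statistic: str
    metric: str
    suffix: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.domain not in _DOMAINS:
            raise ValueError(f"unknown domain {self.domain!r}")
        if self.statistic not in _STATISTICS:
            raise ValueError(f"unknown statistic {self.statistic!r}")
        if self.metric not in _METRICS[self.domain]:
            raise ValueError(
                f"unknown metric {self.metric!r} for domain {self.domain}"
            )
        for s in self.suffix:
            if s not in _SUFFIXES:
                raise ValueError(f"unknown suffix {s!r}")

    def __str__(self) -> str:
        parts = [self.statistic, self.metric, *self.suffix]
        return f"{self.domain}:{'-'.join(parts)}"


def parse_measure_id(text: str) -> MeasureID:
    """Parse the canonical string form back into a :class:`MeasureID`.

    Round-trip identity: ``parse_measure_id(str(m)) == m``.
    """
    try:
        domain, rest = text.split(":", 1)
    except ValueError:
        raise ValueError(f"malformed measure id {text!r}: missing ':'") from None
    tokens = rest.split("-")
    if len(tokens) < 2:
        raise ValueError(f"malformed measure id {text!r}")
    statistic, tokens = tokens[0], tokens[1:]
    # strip suffix tokens from the right, the remainder is the metric name
    suffix: list[str] = []
    while tokens and tokens[-1] in _SUFFIXES:
        suffix.insert(0, tokens.pop())
    metric = "-".join(tokens)
    if not metric and suffix:
        # metric names never collide with suffix vocabulary, so an empty
        # remainder means the id was malformed
        raise ValueError(f"malformed measure id {text!r}: empty metric")
    return MeasureID(domain, statistic, metric, tuple(suffix))


def _sway_block() -> list[MeasureID]:
    out = []
    for cond in ("QEO", "QEC"):
        for metric in ("DIST", "RMS", "VEL", "FREQ"):
            for axis in ((), ("AP",), ("ML",)):
                out.append(MeasureID("QS", "Mn", metric, (*axis, cond)))
        out.append(MeasureID("QS", "Mn", "AREA", (cond,)))
        out.append(MeasureID("QS", "Mn", "EA", (cond,)))
    return out


def _force_block() -> list[MeasureID]:
    out = []
    for joint in ("KE", "PF"):
        out.append(MeasureID("FC", "Mn", "MVIC", (joint,)))
        for target in ("c15", "c20", "r1520"):
            for stat in ("Mn", "SD", "CV"):
                out.append(MeasureID("FC", stat, target, (joint,)))
    return out


def _gait_block() -> list[MeasureID]:
    out = []
    for metric in ("Str-T", "Stn-T", "Sw-T", "DST", "Str-Len", "MaxFC"):
        for side in ("L", "R"):
            for stat in ("Mn", "SD", "CV"):
                out.append(MeasureID("GA", stat, metric, (side,)))
    for side in ("L", "R"):
        out.append(MeasureID("GA", "Mn", "MinFC", (side,)))
    for metric in ("CAD", "SW", "Stp-Len"):
        for stat in ("Mn", "SD"):
            out.append(MeasureID("GA", stat, metric))
    return out


def default_registry() -> list[MeasureID]:
    """The default 92-measure registry: 28 sway + 20 force + 44 gait."""
    reg = _sway_block() + _force_block() + _gait_block()
    assert len(reg) == 92, f"registry size {len(reg)} != 92"
    return reg


def registry_ids(registry: list[MeasureID] | None = None) -> list[str]:
    """Canonical string forms, in registry order."""
    return [str(m) for m in (registry if registry is not None else default_registry())]


def load_registry(path) -> list[MeasureID]:
    """Load a registry override: one canonical measure id per line.

    Blank lines and ``#`` comments are ignored. Unknown ids raise, listing
    every offending name.
    """
    ids: list[MeasureID] = []
    bad: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                ids.append(parse_measure_id(line))
            except ValueError:
                bad.append(line)
    if bad:
        raise ValueError(f"unknown measure ids in {path}: {bad}")
    return ids
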