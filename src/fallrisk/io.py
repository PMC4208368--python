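"""On-disk formats: trials, cohort manifests, feature tables, force-plate files.

All writers are deterministic (stable column order, fixed ``%.12g`` decimal
formatting, UTF-8, comma delimiter, SI units) so that identical inputs produce
byte-identical files. Every reader rejects exactly what its writer cannot
produce, with parse errors naming the offending line.

Trial format: ``# key=value`` header lines followed by a CSV block with a
``time_s`` column and one column per channel. Feature tables are plain CSV
with a ``subject_id`` first column and canonical measure-id columns; missing
values are empty cells (never sentinel numbers).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .registry import MeasureID, parse_measure_id, registry_ids
from .trial import RawTrial

__all__ = [
    "write_trial",
    "read_trial",
    "write_feature_table",
    "read_feature_table",
    "read_forceplate",
    "write_manifest",
    "read_manifest",
    "write_json",
    "read_json",
]

_FMT = "%.12g"


class TrialParseError(ValueError):
    """Raised when a trial file is malformed; message names the line."""


def _fmt(x: float) -> str:
    return _FMT % x


def write_trial(trial: RawTrial, path) -> None:
    """Write a trial; round-trips losslessly at %.12g precision."""
    path = Path(path)
    names = list(trial.channels)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# trial_id={trial.trial_id}\n")
        fh.write(f"# subject_id={trial.subject_id}\n")
        fh.write(f"# modality={trial.modality}\n")
        fh.write(f"# condition={trial.condition}\n")
        fh.write(f"# rate={_fmt(trial.rate)}\n")
        fh.write(f"# duration_s={_fmt(trial.duration)}\n")
        units = ";".join(f"{k}:{v}" for k, v in trial.units.items())
        fh.write(f"# units={units}\n")
        fh.write("time_s," + ",".join(names) + "\n")
        t = trial.time
        cols = [trial.channels[n] for n in names]
        for i in range(trial.n_samples):
            fh.write(_fmt(t[i]) + "," + ",".join(_fmt(c[i]) for c in cols) + "\n")


def read_trial(path) -> RawTrial:
    path = Path(path)
    header: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines) and lines[i].startswith("#"):
        body = lines[i][1:].strip()
        if "=" not in body:
            raise TrialParseError(f"{path}:{i + 1}: malformed header line {lines[i]!r}")
        key, _, val = body.partition("=")
        header[key.strip()] = val.strip()
        i += 1
    for key in ("trial_id", "subject_id", "modality", "condition", "rate"):
        if key not in header:
            raise TrialParseError(f"{path}:{i}: missing header key {key!r}")
    try:
        rate = float(header["rate"])
    except ValueError:
        raise TrialParseError(f"{path}: header rate={header['rate']!r} not a number")
    if rate <= 0:
        raise TrialParseError(f"{path}: header rate must be > 0, got {rate}")
    if i >= len(lines):
        raise TrialParseError(f"{path}:{i + 1}: missing column header row")
    cols = lines[i].rstrip("\n").split(",")
    if cols[0] != "time_s":
        raise TrialParseError(f"{path}:{i + 1}: first column must be time_s")
    names = cols[1:]
    ncol = len(cols)
    data = np.empty((len(lines) - i - 1, ncol))
    for j, line in enumerate(lines[i + 1 :], start=i + 2):
        fields = line.rstrip("\n").split(",")
        if len(fields) != ncol or any(f == "" for f in fields):
            raise TrialParseError(f"{path}:{j}: expected {ncol} values, got {line!r}")
        try:
            data[j - i - 2] = [float(f) for f in fields]
        except ValueError:
            raise TrialParseError(f"{path}:{j}: non-numeric value in {line!r}")
    if data.shape[0] == 0:
        raise TrialParseError(f"{path}: no data rows")
    t = data[:, 0]
    if np.any(np.diff(t) <= 0):
        k = int(np.argmax(np.diff(t) <= 0))
        raise TrialParseError(f"{path}:{i + 3 + k}: non-monotonic time")
    units = {}
    for item in header.get("units", "").split(";"):
        if item:
            k, _, v = item.partition(":")
            units[k] = v
    return RawTrial(
        trial_id=header["trial_id"],
        subject_id=header["subject_id"],
        modality=header["modality"],
        condition=header["condition"],
        rate=rate,
        channels={n: data[:, k + 1] for k, n in enumerate(names)},
        units=units,
    )


# ---------------------------------------------------------------------------
# feature tables


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Write a subjects x measures table (index = subject_id, columns =
    canonical measure ids); NaN -> empty cell."""
    bad = [c for c in table.columns if _invalid_measure(c)]
    if bad:
        raise ValueError(f"unknown measure id columns: {bad}")
    out = table.copy()
    out.index.name = "subject_id"
    out.to_csv(path, float_format=_FMT, na_rep="")


def _invalid_measure(name: str) -> bool:
    try:
        parse_measure_id(name)
        return False
    except ValueError:
        return True


def read_feature_table(path, registry: list[MeasureID] | None = None) -> pd.DataFrame:
    """Read a feature table; empty cells become NaN (missing).

    If ``registry`` is given, columns must be exactly that registry (any
    order accepted, output reordered canonically).
    """
    table = pd.read_csv(path, index_col="subject_id")
    bad = [c for c in table.columns if _invalid_measure(c)]
    if bad:
        raise ValueError(f"unknown measure id columns in {path}: {bad}")
    if registry is not None:
        want = registry_ids(registry)
        missing = sorted(set(want) - set(table.columns))
        extra = sorted(set(table.columns) - set(want))
        if missing or extra:
            raise ValueError(
                f"feature table columns do not match registry "
                f"(missing {missing}, extra {extra})"
            )
        table = table[want]
    table.index = table.index.astype(str)
    return table.astype(float)


# ---------------------------------------------------------------------------
# force-plate reader (convenience for real recordings)


def read_forceplate(path, min_fz: float = 10.0, bad_fraction: float = 0.05) -> RawTrial:
    """Read a two-plate forces+moments file and return a combined CoP trial.

    The file uses the trial header format with ``modality=forceplate`` and
    per-plate channels ``Fz1, Mx1, My1`` (and optionally ``Fz2, Mx2, My2``),
    plus header keys ``origin1`` / ``origin2`` giving each plate's AP,ML
    origin in metres (``x;y``). Per-plate CoP in the plate frame is
    ``(-My/Fz, Mx/Fz)``; the net CoP is the Fz-weighted average after
    translating by the plate origins.

    Samples with ``Fz <= min_fz`` on a plate are tolerated up to
    ``bad_fraction`` of the trial (the subject momentarily unloading a
    plate); beyond that the subject is considered off the plate and an error
    is raised.
    """
    path = Path(path)
    header: dict[str, str] = {}
    rows: list[list[float]] = []
    names: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                header[key.strip()] = val.strip()
            elif not names:
                names = line.split(",")
            elif line:
                fields = line.split(",")
                if len(fields) != len(names) or any(f == "" for f in fields):
                    raise TrialParseError(f"{path}:{ln}: ragged row {line!r}")
                rows.append([float(f) for f in fields])
    data = {n: np.array([r[k] for r in rows]) for k, n in enumerate(names)}
    rate = float(header.get("rate", "0"))
    if rate <= 0:
        raise TrialParseError(f"{path}: header rate must be > 0")
    plates = [p for p in ("1", "2") if f"Fz{p}" in data]
    if not plates:
        raise TrialParseError(f"{path}: no per-plate Fz channels found")
    n = len(next(iter(data.values())))
    ap = np.zeros(n)
    ml = np.zeros(n)
    fz_tot = np.zeros(n)
    for p in plates:
        fz = data[f"Fz{p}"]
        bad = fz <= min_fz
        if bad.mean() > bad_fraction:
            raise ValueError(
                f"{path}: plate {p} unloaded (Fz<={min_fz} N) in "
                f"{bad.mean():.0%} of samples — subject off plate"
            )
        ox, oy = (float(v) for v in header.get(f"origin{p}", "0;0").split(";"))
        fz_safe = np.where(bad, np.nan, fz)
        cop_x = -data[f"My{p}"] / fz_safe + ox
        cop_y = data[f"Mx{p}"] / fz_safe + oy
        w = np.where(bad, 0.0, fz)
        ap += np.nan_to_num(cop_x * w)
        ml += np.nan_to_num(cop_y * w)
        fz_tot += w
    if np.any(fz_tot <= 0):
        raise ValueError(f"{path}: zero total vertical load in some samples")
    return RawTrial(
        trial_id=header.get("trial_id", path.stem),
        subject_id=header.get("subject_id", "unknown"),
        modality="cop",
        condition=header.get("condition", "QEO"),
        rate=rate,
        channels={"AP": ap / fz_tot, "ML": ml / fz_tot},
        units={"AP": "m", "ML": "m"},
    )


# ---------------------------------------------------------------------------
# manifest + structured artifacts


def write_manifest(manifest: pd.DataFrame, path) -> None:
    """Cohort manifest: subject_id, group, follow_up_fall, anthropometrics."""
    out = manifest.copy()
    out.index.name = "subject_id"
    out.to_csv(path, float_format=_FMT)


def read_manifest(path) -> pd.DataFrame:
    m = pd.read_csv(path, index_col="subject_id")
    m.index = m.index.astype(str)
    if "group" not in m.columns:
        raise ValueError(f"manifest {path} lacks a 'group' column")
    bad = sorted(set(m["group"]) - {"faller", "nonfaller", "ftf"})
    if bad:
        raise ValueError(f"manifest {path} has unknown groups: {bad}")
    return m


def write_json(obj, path) -> None:
    """Deterministic JSON writer for structured artifacts (factor solutions,
    models, reports)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")


def read_json(path):
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)
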