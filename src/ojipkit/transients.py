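"""Containers and I/O for fluorescence and 820 nm reflection traces.

A fast-fluorescence (OJIP) measurement is a time-ordered trace of
fluorescence intensity recorded from the onset of actinic illumination,
typically from ~10 µs out to 1-2 s on a quasi-logarithmic grid.  Time zero
is always light onset; every landmark time used downstream (20 µs, 150 µs,
270 µs, 300 µs, 2 ms, 30 ms) is absolute from onset.

Traces are read from plain delimited text (comma or tab, optional header,
two numeric columns) — the format Handy-PEA-style instruments export — and
validated on construction.  No binary instrument formats are supported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "FluorescenceTransient",
    "MRTrace",
    "TransientValidationError",
    "read_transient",
    "read_mr_trace",
    "write_transient",
    "value_at",
]

#: multiplicative factors to µs for the accepted time units
_TIME_UNIT_US = {"us": 1.0, "µs": 1.0, "ms": 1e3, "s": 1e6}


class TransientValidationError(ValueError):
    """Raised when a trace violates its structural invariants."""


def _validate_time_signal(time, signal, *, min_points, name):
    time = np.asarray(time, dtype=float)
    signal = np.asarray(signal, dtype=float)
    if time.ndim != 1 or signal.ndim != 1 or time.size != signal.size:
        raise TransientValidationError(
            f"{name}: time and signal must be 1-D sequences of equal length"
        )
    if time.size < min_points:
        raise TransientValidationError(
            f"{name}: needs at least {min_points} points, got {time.size}"
        )
    if not np.all(np.isfinite(time)) or not np.all(np.isfinite(signal)):
        raise TransientValidationError(f"{name}: non-finite values present")
    diffs = np.diff(time)
    if np.any(diffs <= 0):
        row = int(np.argmax(diffs <= 0)) + 1
        raise TransientValidationError(
            f"{name}: time not strictly increasing at row {row} "
            f"(t={time[row]!r} follows t={time[row - 1]!r})"
        )
    return time, signal


@dataclass(frozen=True)
class FluorescenceTransient:
    """A validated OJIP fluorescence rise curve.

    Parameters
    ----------
    time : array-like
        Elapsed time since actinic-light onset, in µs, strictly increasing.
        The first sample must fall at or before 50 µs so the 20 µs minimal
        fluorescence point can be read.
    F : array-like
        Fluorescence intensity in instrument units, finite and non-negative.
    label, group : str
        Sample identifier and treatment group (e.g. ``"mock"``,
        ``"GT_100uM"``).
    """

    time: np.ndarray
    F: np.ndarray
    label: str = ""
    group: str = ""

    def __post_init__(self):
        time, F = _validate_time_signal(
            self.time, self.F, min_points=10, name="FluorescenceTransient"
        )
        if np.any(F < 0):
            raise TransientValidationError(
                "FluorescenceTransient: negative fluorescence values"
            )
        if time[0] > 50.0:
            raise TransientValidationError(
                f"FluorescenceTransient: first sample at {time[0]:g} µs "
                "does not bracket the 20 µs minimal-fluorescence point "
                "(must be ≤ 50 µs)"
            )
        t_peak = time[int(np.argmax(F))]
        if time[-1] < t_peak:  # pragma: no cover - unreachable by construction
            raise TransientValidationError(
                "FluorescenceTransient: trace ends before the fluorescence peak"
            )
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "F", F)

    def __len__(self):
        return self.time.size

    def with_meta(self, *, label=None, group=None):
        return replace(
            self,
            label=self.label if label is None else label,
            group=self.group if group is None else group,
        )


@dataclass(frozen=True)
class MRTrace:
    """A modulated 820 nm reflection trace (plastocyanin/P700 redox proxy).

    time is in ms from actinic onset and must begin at or before 0.7 ms,
    the first reliable reflection sample; MR is strictly positive.
    """

    time: np.ndarray
    MR: np.ndarray
    label: str = ""
    group: str = ""

    def __post_init__(self):
        time, MR = _validate_time_signal(self.time, self.MR, min_points=10, name="MRTrace")
        if np.any(MR <= 0):
            raise TransientValidationError("MRTrace: MR values must be > 0")
        if time[0] > 0.7:
            raise TransientValidationError(
                f"MRTrace: first sample at {time[0]:g} ms is after the "
                "0.7 ms reference point"
            )
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "MR", MR)

    def __len__(self):
        return self.time.size


@dataclass(frozen=True)
class Dialect:
    """Column/delimiter configuration for delimited trace files.

    delimiter None lets pandas sniff comma vs whitespace; time_unit is one
    of "us", "ms", "s" and is converted to µs on read (ms for MR traces).
    """

    delimiter: str | None = None
    time_column: int = 0
    signal_column: int = 1
    time_unit: str = "ms"
    header: bool | None = None  # None = auto-detect


def _read_two_columns(path, dialect: Dialect):
    sep = dialect.delimiter
    kwargs = dict(comment="#", skip_blank_lines=True, dtype=str)
    if sep is None:
        kwargs.update(sep=None, engine="python")
    else:
        kwargs.update(sep=sep)
    raw = pd.read_csv(path, header=None, **kwargs)
    if raw.shape[1] <= max(dialect.time_column, dialect.signal_column):
        raise TransientValidationError(
            f"{path}: cannot resolve columns {dialect.time_column} and "
            f"{dialect.signal_column} in a {raw.shape[1]}-column file"
        )
    def to_float(col):
        # Python float() is correctly rounded, so written values round-trip
        # to the last ulp (pd.to_numeric's fast path is not)
        def conv(x):
            try:
                return float(x)
            except (TypeError, ValueError):
                return float("nan")

        return col.map(conv)

    t_raw = to_float(raw.iloc[:, dialect.time_column])
    s_raw = to_float(raw.iloc[:, dialect.signal_column])
    header = dialect.header
    if header is None:
        header = bool(np.isnan(t_raw.iloc[0]) and np.isnan(s_raw.iloc[0]))
    if header:
        t_raw, s_raw = t_raw.iloc[1:], s_raw.iloc[1:]
    keep = t_raw.notna() & s_raw.notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(f"{path}: {n_dropped} rows dropped (non-numeric fields)")
    return t_raw[keep].to_numpy(float), s_raw[keep].to_numpy(float), n_dropped


def read_transient(path, dialect: Dialect | None = None, *, label="", group=""):
    """Read a delimited (time, fluorescence) file into a validated transient.

    Rows with non-numeric fields are dropped with a warning counting them;
    fewer than 10 valid rows, or non-monotone time, is a hard error naming
    the offending row.
    """
    dialect = dialect or Dialect()
    unit = _TIME_UNIT_US.get(dialect.time_unit)
    if unit is None:
        raise ValueError(f"unknown time unit {dialect.time_unit!r}")
    t, s, _ = _read_two_columns(path, dialect)
    return FluorescenceTransient(t * unit, s, label=label or str(path), group=group)


def read_mr_trace(path, dialect: Dialect | None = None, *, label="", group=""):
    """Read a delimited (time, reflection) file; time converted to ms."""
    dialect = dialect or Dialect()
    unit = _TIME_UNIT_US.get(dialect.time_unit)
    if unit is None:
        raise ValueError(f"unknown time unit {dialect.time_unit!r}")
    t, s, _ = _read_two_columns(path, dialect)
    return MRTrace(t * unit / 1e3, s, label=label or str(path), group=group)


def write_transient(transient: FluorescenceTransient, path, *, delimiter="\t"):
    """Write a transient as two-column delimited text (time in µs).

    Values are written with full repr precision so a read → write → read
    cycle round-trips exactly.
    """
    with open(path, "w") as fh:
        fh.write(f"time_us{delimiter}F\n")
        for t, f in zip(transient.time, transient.F):
            fh.write(f"{float(t)!r}{delimiter}{float(f)!r}\n")


def value_at(transient, t, *, rule="linear"):
    """Interpolated signal value at time ``t`` (µs for fluorescence traces).

    rule "linear" interpolates linearly in linear time (the default: PEA
    instruments sample densely at early times so the rule barely matters,
    but it must be fixed).  rule "log" interpolates log-signal linearly in
    log-time (geometric interpolation), useful on sparse early grids.
    Exact at sample points; error outside the sampled range.
    """
    time = transient.time
    sig = transient.F if hasattr(transient, "F") else transient.MR
    t = float(t)
    if t < time[0] or t > time[-1]:
        raise ValueError(
            f"t={t:g} outside sampled range [{time[0]:g}, {time[-1]:g}]"
        )
    if rule == "linear":
        return float(np.interp(t, time, sig))
    if rule == "log":
        i = int(np.searchsorted(time, t))
        if time[min(i, len(time) - 1)] == t:
            return float(sig[min(i, len(time) - 1)])
        if i > 0 and time[i - 1] == t:
            return float(sig[i - 1])
        t0, t1 = time[i - 1], time[i]
        s0, s1 = sig[i - 1], sig[i]
        if t0 <= 0 or s0 <= 0 or s1 <= 0:
            # log rule undefined at non-positive coordinates; fall back
            return float(np.interp(t, time, sig))
        w = np.log(t / t0) / np.log(t1 / t0)
        return float(s0 * (s1 / s0) ** w)
    raise ValueError(f"unknown interpolation rule {rule!r}")
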