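"""Domain containers and input handling.

Three tabular inputs drive the integrated population model:

* annual winter counts reported as low--high ranges,
* annual counts of new recruits, also reported as ranges,
* telemetry survival records, one per collared animal, each a triplet
  ``{a, b, delta}`` of entry time, exit time and an event indicator.

This module validates those inputs, converts count ranges into midpoints
plus a shared measurement-error SD, and expands survival triplets onto a
fine time grid in counting-process form (at-risk indicators ``Y_i(s)`` and
event increments ``dM_i(s)``) so the survival likelihood can treat the
increments as Poisson counts.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DataValidationError",
    "CountSeries",
    "RecruitSeries",
    "SurvivalRecord",
    "RiskTable",
    "PeriodMap",
    "derive_counts",
    "derive_recruits",
    "expand_records",
    "standardize_log_abundance",
    "decimal_year",
    "read_counts",
    "read_recruits",
    "read_telemetry",
    "write_telemetry",
]


class DataValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


# ---------------------------------------------------------------------------
# count and recruit series
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CountSeries:
    """Annual count ranges, their midpoints and the measurement-error SD.

    ``v`` is the standard deviation of the lognormal observation error on
    the log scale, shared across years.
    """

    year: np.ndarray
    n_low: np.ndarray
    n_high: np.ndarray
    n_mid: np.ndarray
    v: float

    def __post_init__(self) -> None:
        year = np.asarray(self.year, dtype=int)
        low = np.asarray(self.n_low, dtype=float)
        high = np.asarray(self.n_high, dtype=float)
        mid = np.asarray(self.n_mid, dtype=float)
        object.__setattr__(self, "year", year)
        object.__setattr__(self, "n_low", low)
        object.__setattr__(self, "n_high", high)
        object.__setattr__(self, "n_mid", mid)
        if year.ndim != 1 or len(year) == 0:
            raise DataValidationError("count series must be a non-empty 1-d table")
        gaps = np.flatnonzero(np.diff(year) != 1)
        if gaps.size:
            g = gaps[0]
            raise DataValidationError(
                f"count years must be contiguous: gap between {year[g]} and {year[g + 1]}"
            )
        if np.any(low < 0):
            raise DataValidationError("counts must be non-negative")
        if np.any(low > high):
            bad = year[np.argmax(low > high)]
            raise DataValidationError(f"low count exceeds high count in year {bad}")
        if not np.allclose(mid, (low + high) / 2.0):
            raise DataValidationError("n_mid must be the midpoint of (n_low, n_high)")
        if not (self.v > 0):
            raise DataValidationError("measurement-error SD v must be > 0")

    @property
    def n_years(self) -> int:
        return len(self.year)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.year, "low": self.n_low, "high": self.n_high})

    def write_csv(self, path: str | Path) -> None:
        _write_range_csv(path, self.year, self.n_low, self.n_high)

    def drop_last(self, k: int = 1) -> "CountSeries":
        """Return the series without its final ``k`` years (hold-out splits)."""
        if k >= self.n_years:
            raise DataValidationError("cannot drop every year of a count series")
        return CountSeries(
            self.year[:-k], self.n_low[:-k], self.n_high[:-k], self.n_mid[:-k], self.v
        )


@dataclass(frozen=True)
class RecruitSeries:
    """Annual recruit-count ranges and midpoints (animals)."""

    year: np.ndarray
    r_low: np.ndarray
    r_high: np.ndarray
    r_mid: np.ndarray

    def __post_init__(self) -> None:
        year = np.asarray(self.year, dtype=int)
        low = np.asarray(self.r_low, dtype=float)
        high = np.asarray(self.r_high, dtype=float)
        mid = np.asarray(self.r_mid, dtype=float)
        for name, arr in (("year", year), ("r_low", low), ("r_high", high), ("r_mid", mid)):
            object.__setattr__(self, name, arr)
        if year.ndim != 1 or len(year) == 0:
            raise DataValidationError("recruit series must be a non-empty 1-d table")
        if np.any(np.diff(year) <= 0):
            raise DataValidationError("recruit years must be strictly increasing")
        if np.any(low < 0):
            raise DataValidationError("recruit counts must be non-negative")
        if np.any(low > high):
            bad = year[np.argmax(low > high)]
            raise DataValidationError(f"low recruit count exceeds high in year {bad}")
        if not np.allclose(mid, (low + high) / 2.0):
            raise DataValidationError("r_mid must be the midpoint of (r_low, r_high)")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.year, "low": self.r_low, "high": self.r_high})

    def write_csv(self, path: str | Path) -> None:
        _write_range_csv(path, self.year, self.r_low, self.r_high)

    def restrict_to(self, years: np.ndarray) -> "RecruitSeries":
        keep = np.isin(self.year, years)
        if not keep.any():
            raise DataValidationError("no recruit years overlap the requested span")
        return RecruitSeries(
            self.year[keep], self.r_low[keep], self.r_high[keep], self.r_mid[keep]
        )


def derive_counts(
    raw_ranges: pd.DataFrame | Iterable[tuple], error_scale: str = "absolute"
) -> CountSeries:
    """Convert a (year, low, high) table into a :class:`CountSeries`.

    The midpoint of each range is the working count and the shared
    measurement-error SD is the mean over years of one quarter of the
    range width.  ``error_scale="absolute"`` keeps that quarter-range in
    count units; ``"log"`` divides each quarter-range by its midpoint,
    giving a coefficient of variation that matches the log-scale SD of the
    lognormal observation model.
    """
    year, low, high = _coerce_range_table(raw_ranges)
    order = np.argsort(year)
    year, low, high = year[order], low[order], high[order]
    if np.any(low > high):
        bad = year[np.argmax(low > high)]
        raise DataValidationError(f"low count exceeds high count in year {bad}")
    mid = (low + high) / 2.0
    quarter = (high - low) / 4.0
    if error_scale == "absolute":
        v = float(np.mean(quarter))
    elif error_scale == "log":
        if np.any(mid <= 0):
            raise DataValidationError("log-scale error requires positive midpoints")
        v = float(np.mean(quarter / mid))
    else:
        raise DataValidationError(f"unknown error_scale {error_scale!r}")
    if v <= 0:
        raise DataValidationError(
            "derived measurement-error SD is zero (all ranges degenerate); v > 0 required"
        )
    return CountSeries(year, low, high, mid, v)


def derive_recruits(raw_ranges: pd.DataFrame | Iterable[tuple]) -> RecruitSeries:
    """Convert a (year, low, high) recruit table into a :class:`RecruitSeries`."""
    year, low, high = _coerce_range_table(raw_ranges)
    order = np.argsort(year)
    year, low, high = year[order], low[order], high[order]
    return RecruitSeries(year, low, high, (low + high) / 2.0)


def _coerce_range_table(raw) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(raw, pd.DataFrame):
        cols = {c.lower(): c for c in raw.columns}
        try:
            year = raw[cols["year"]].to_numpy()
            low = raw[cols["low"]].to_numpy(dtype=float)
            high = raw[cols["high"]].to_numpy(dtype=float)
        except KeyError as exc:  # pragma: no cover - defensive
            raise DataValidationError(f"missing column {exc} in range table") from exc
    else:
        rows = list(raw)
        if not rows:
            raise DataValidationError("empty range table")
        arr = np.asarray(rows, dtype=float)
        year, low, high = arr[:, 0], arr[:, 1], arr[:, 2]
    return np.asarray(year, dtype=int), np.asarray(low, float), np.asarray(high, float)


# ---------------------------------------------------------------------------
# survival records and the counting-process expansion
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SurvivalRecord:
    """One telemetry follow-up interval: entry ``a``, exit ``b`` (decimal
    years) and ``delta`` = 1 for a death at ``b``, 0 for censoring."""

    animal_id: str
    a: float
    b: float
    delta: int

    def __post_init__(self) -> None:
        if not (self.a < self.b):
            raise DataValidationError(
                f"record {self.animal_id}: entry {self.a} must precede exit {self.b}"
            )
        if self.delta not in (0, 1):
            raise DataValidationError(
                f"record {self.animal_id}: event indicator must be 0 or 1"
            )


def decimal_year(value) -> float:
    """Convert an ISO date string (``YYYY-MM-DD``) or a number to decimal years."""
    if isinstance(value, (int, float, np.floating, np.integer)):
        return float(value)
    ts = pd.Timestamp(str(value))
    start = pd.Timestamp(year=ts.year, month=1, day=1)
    end = pd.Timestamp(year=ts.year + 1, month=1, day=1)
    return ts.year + (ts - start) / (end - start)


def _year_start_offset(year_start: str) -> float:
    """Fraction of a year at which the model year begins (e.g. '09-01')."""
    if year_start in ("01-01", None, ""):
        return 0.0
    month, day = (int(p) for p in year_start.split("-"))
    ref = pd.Timestamp(year=2001, month=month, day=day)  # non-leap reference
    return float((ref.dayofyear - 1) / 365.0)


@dataclass(frozen=True)
class RiskTable:
    """Counting-process expansion of survival records onto a uniform grid.

    ``Y[i, j]`` flags record *i* at risk in interval *j* = ``[grid[j],
    grid[j+1])``; ``dM[i, j]`` = 1 marks the death of record *i* in that
    interval.  ``year_of_interval`` gives the integer (model) year each
    interval starts in, which downstream code maps onto transition years.
    """

    grid: np.ndarray              # interval edges, length S + 1
    ds: float
    Y: np.ndarray                 # (n_records, S) uint8
    dM: np.ndarray                # (n_records, S) uint8
    year_of_interval: np.ndarray  # (S,) int
    entry: np.ndarray             # per-record a
    exit: np.ndarray              # per-record b
    delta: np.ndarray             # per-record event indicator
    animal_id: tuple = ()

    @property
    def n_records(self) -> int:
        return self.Y.shape[0]

    @property
    def n_intervals(self) -> int:
        return self.Y.shape[1]

    @property
    def at_risk_count(self) -> np.ndarray:
        """Number of records at risk in each interval (``Y_+(s)``)."""
        return self.Y.sum(axis=0).astype(float)

    @property
    def event_count(self) -> np.ndarray:
        """Number of deaths in each interval (``dM_+(s)``)."""
        return self.dM.sum(axis=0).astype(float)

    @property
    def total_events(self) -> int:
        return int(self.dM.sum())

    @property
    def total_exposure(self) -> float:
        """Total at-risk time in years (sum of Y * ds)."""
        return float(self.Y.sum()) * self.ds


def expand_records(
    records: Sequence[SurvivalRecord],
    span: tuple[int, int],
    ds: float = 1.0 / 12.0,
    year_start: str = "09-01",
) -> RiskTable:
    """Expand survival triplets into the counting-process representation.

    ``span = (first_year, last_year)`` bounds the modeled period: the grid
    covers ``[first_year + o, last_year + o)`` where ``o`` is the year-start
    offset (default 1 September, the entry criterion for young animals).  A
    record is at risk in an interval iff it overlaps the interval's
    interior, which preserves total exposure up to grid rounding; the death
    of a record with ``delta = 1`` lands in the interval containing its exit
    time ``b``.
    """
    per_year = 1.0 / ds
    if abs(per_year - round(per_year)) > 1e-9:
        raise DataValidationError(f"ds={ds} must divide the model year evenly")
    per_year = int(round(per_year))
    first, last = int(span[0]), int(span[1])
    if last <= first:
        raise DataValidationError("span must cover at least one model year")
    offset = _year_start_offset(year_start)
    t0 = first + offset
    n_years = last - first
    S = n_years * per_year
    grid = t0 + ds * np.arange(S + 1)
    grid[-1] = last + offset  # exact right edge

    n = len(records)
    if n == 0:
        raise DataValidationError("no survival records supplied")
    a = np.array([r.a for r in records], dtype=float)
    b = np.array([r.b for r in records], dtype=float)
    delta = np.array([r.delta for r in records], dtype=np.int64)
    ids = tuple(r.animal_id for r in records)
    if np.any(a < t0 - 1e-9) or np.any(b > grid[-1] + 1e-9):
        bad = np.argmax((a < t0 - 1e-9) | (b > grid[-1] + 1e-9))
        raise DataValidationError(
            f"record {ids[bad]} ({a[bad]:.3f}-{b[bad]:.3f}) lies outside the "
            f"grid span [{t0:.3f}, {grid[-1]:.3f}]"
        )

    left = grid[:-1][None, :]
    right = grid[1:][None, :]
    Y = ((a[:, None] < right) & (b[:, None] > left)).astype(np.uint8)
    dM = np.zeros_like(Y)
    j_event = np.ceil((b - t0) / ds).astype(int) - 1
    j_event = np.clip(j_event, 0, S - 1)
    rows = np.flatnonzero(delta == 1)
    dM[rows, j_event[rows]] = 1
    if np.any(dM > Y):  # pragma: no cover - defensive; impossible by construction
        raise DataValidationError("event placed outside its record's risk set")

    year_of_interval = first + (np.arange(S) // per_year)
    return RiskTable(grid, ds, Y, dM, year_of_interval, a, b, delta, ids)


# ---------------------------------------------------------------------------
# period map and covariate standardization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PeriodMap:
    """Map model years onto correction-factor periods.

    ``breakpoints`` are the years at which a new period begins; years before
    the first breakpoint fall in period 0.
    """

    breakpoints: tuple = ()

    def __post_init__(self) -> None:
        bp = tuple(int(b) for b in self.breakpoints)
        if any(b2 <= b1 for b1, b2 in zip(bp, bp[1:])):
            raise DataValidationError("period breakpoints must be strictly increasing")
        object.__setattr__(self, "breakpoints", bp)

    @property
    def n_periods(self) -> int:
        return len(self.breakpoints) + 1

    def period_of_year(self, year) -> np.ndarray:
        return np.searchsorted(np.asarray(self.breakpoints), np.asarray(year), side="right")


def standardize_log_abundance(values, ddof: int = 0) -> np.ndarray:
    """Standardize log abundances to mean 0, SD 1.

    Takes logs, subtracts the sample mean and divides by the sample SD
    (population, divide-by-n, convention by default; ``ddof=1`` for the
    n-1 variant).  Scaling the inputs by a positive constant leaves the
    result unchanged because a log-scale shift drops out.
    """
    x = np.asarray(values, dtype=float)
    if np.any(x <= 0):
        raise DataValidationError("abundances must be positive to take logs")
    if len(np.unique(x)) < 2:
        raise DataValidationError("cannot standardize a constant series (zero SD)")
    lx = np.log(x)
    sd = np.std(lx, ddof=ddof)
    return (lx - np.mean(lx)) / sd


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------


def _write_range_csv(path, year, low, high) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["year", "low", "high"])
        for y, lo, hi in zip(year, low, high):
            writer.writerow([int(y), repr(float(lo)), repr(float(hi))])


def read_counts(path: str | Path, error_scale: str = "absolute") -> CountSeries:
    """Read ``counts.csv`` (columns year, low, high)."""
    return derive_counts(pd.read_csv(path, float_precision="round_trip"), error_scale=error_scale)


def read_recruits(path: str | Path) -> RecruitSeries:
    """Read ``recruits.csv`` (columns year, low, high)."""
    return derive_recruits(pd.read_csv(path, float_precision="round_trip"))


def read_telemetry(path: str | Path) -> list[SurvivalRecord]:
    """Read ``telemetry.csv`` (animal_id, entry_time, exit_time, event).

    Times may be decimal years or ISO dates; ISO dates are converted to
    decimal years as year + elapsed-fraction-of-year.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    cols = {c.lower(): c for c in df.columns}
    records = []
    for _, row in df.iterrows():
        records.append(
            SurvivalRecord(
                str(row[cols["animal_id"]]),
                decimal_year(row[cols["entry_time"]]),
                decimal_year(row[cols["exit_time"]]),
                int(row[cols["event"]]),
            )
        )
    return records


def write_telemetry(path: str | Path, records: Sequence[SurvivalRecord]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["animal_id", "entry_time", "exit_time", "event"])
        for r in records:
            writer.writerow([r.animal_id, repr(float(r.a)), repr(float(r.b)), int(r.delta)])
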