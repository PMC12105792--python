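"""Reading, windowing and summarising RFID feeder-visit logs.

A visit log holds one row per antenna detection: a timestamp at 1-second
resolution, the PIT-tag ID of the bird, and the feeder ID.  The study design
alternates week-long *full* periods with two-week *empty* gaps.  The full
week preceding an empty gap is an **association period** (AP) whose visit
stream defines the social network; the full week that follows refilling is a
**diffusion period** (DP) whose order of first visits is the behavioural
diffusion analysed downstream.

Conventions used throughout the package:

* windows are half-open ``[start, end)``;
* timestamps are timezone-naive local time at 1-second resolution;
* visit tables are plain :class:`pandas.DataFrame` objects with columns
  ``timestamp`` (datetime64), ``individual_id`` and ``feeder_id``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VISIT_COLUMNS = ("timestamp", "individual_id", "feeder_id")

AP = "AP"
DP = "DP"


@dataclass(frozen=True)
class PeriodWindow:
    """One association or diffusion window for a single feeder."""

    period_index: int
    feeder_id: str
    role: str  # "AP" or "DP"
    start: pd.Timestamp
    end: pd.Timestamp

    def __post_init__(self) -> None:
        if self.role not in (AP, DP):
            raise ValueError(f"role must be 'AP' or 'DP', got {self.role!r}")
        if self.period_index < 1:
            raise ValueError("period_index must be >= 1")
        if not self.start < self.end:
            raise ValueError("window start must precede end")

    @property
    def duration_s(self) -> float:
        return (self.end - self.start).total_seconds()


@dataclass
class DiffusionRecord:
    """Ordered first-visit acquisition sequence for one feeder x DP.

    ``acquisition_order`` lists the individuals that visited during the DP in
    the order of their first detection; individuals in ``risk_set`` that never
    visited are censored (they stay in every likelihood denominator but never
    acquire).  ``ilv`` is the standardized feeder-use covariate aligned to
    ``risk_set``.
    """

    feeder_id: str
    dp_index: int
    acquisition_order: list[str]
    risk_set: list[str]
    ilv: np.ndarray | None = None
    tie_log: list[list[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        risk = set(self.risk_set)
        if len(self.acquisition_order) != len(set(self.acquisition_order)):
            raise ValueError("acquisition_order contains duplicates")
        if not set(self.acquisition_order) <= risk:
            raise ValueError("acquisition_order must be a subset of risk_set")
        if self.ilv is not None:
            self.ilv = np.asarray(self.ilv, dtype=float)
            if self.ilv.shape != (len(self.risk_set),):
                raise ValueError("ilv must align with risk_set")
            if not np.all(np.isfinite(self.ilv)):
                raise ValueError("ilv must be finite")

    @property
    def n_events(self) -> int:
        return len(self.acquisition_order)

    @property
    def censored(self) -> list[str]:
        acquired = set(self.acquisition_order)
        return [i for i in self.risk_set if i not in acquired]


@dataclass
class TemperatureSummary:
    """Daytime average temperature for the first day of one DP."""

    dp_index: int
    day: pd.Timestamp
    daytime_avg_temp: float
    hours_used: list[int]


# ---------------------------------------------------------------------------
# I/O


def read_visits(path) -> pd.DataFrame:
    """Read a visit CSV (timestamp, individual_id, feeder_id), sorted by time.

    Malformed timestamps raise a ``ValueError`` naming the offending data
    line(s); an empty file yields an empty table with a warning.
    """
    df = pd.read_csv(path, dtype={"individual_id": str, "feeder_id": str})
    if df.empty:
        warnings.warn(f"visit file {path} contains no rows")
        return pd.DataFrame(columns=list(VISIT_COLUMNS)).astype(
            {"timestamp": "datetime64[ns]"}
        )
    missing = [c for c in VISIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"visit file {path} lacks columns {missing}")
    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    bad = np.flatnonzero(ts.isna().to_numpy())
    if bad.size:
        # +2: one for the header line, one for 1-based numbering
        lines = ", ".join(str(i + 2) for i in bad[:10])
        raise ValueError(f"unparseable timestamp in {path} at line(s) {lines}")
    df = df.assign(timestamp=ts)
    return df.sort_values("timestamp", kind="stable").reset_index(drop=True)


def write_visits(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False, columns=list(VISIT_COLUMNS))


def read_schedule(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"feeder_id": str, "role": str})
    for col in ("start", "end"):
        df[col] = pd.to_datetime(df[col], format="ISO8601")
    return df


def schedule_windows(schedule: pd.DataFrame) -> list[PeriodWindow]:
    """Turn AP/DP rows of a schedule table into :class:`PeriodWindow` objects."""
    out = []
    for row in schedule.itertuples(index=False):
        if row.role in (AP, DP):
            out.append(
                PeriodWindow(
                    period_index=int(row.period_id),
                    feeder_id=str(row.feeder_id),
                    role=row.role,
                    start=pd.Timestamp(row.start),
                    end=pd.Timestamp(row.end),
                )
            )
    return out


def read_weather(path) -> pd.DataFrame:
    """Read an hourly weather CSV with columns ``hour`` and ``temp_C``."""
    df = pd.read_csv(path)
    df["hour"] = pd.to_datetime(df["hour"], format="ISO8601")
    return df


# ---------------------------------------------------------------------------
# Windowing and debouncing


def in_window(visits: pd.DataFrame, window: PeriodWindow) -> pd.DataFrame:
    """Visits at the window's feeder within half-open [start, end)."""
    m = (
        (visits["feeder_id"] == window.feeder_id)
        & (visits["timestamp"] >= window.start)
        & (visits["timestamp"] < window.end)
    )
    return visits.loc[m]


def debounce(visits: pd.DataFrame, gap_s: float) -> pd.DataFrame:
    """Collapse runs of repeated antenna reads into single visits.

    Consecutive reads of the same individual at the same feeder separated by
    at most ``gap_s`` seconds are collapsed to the first read of the run.
    ``gap_s=0`` is the identity (every read kept); the operation is
    idempotent because kept reads are run starts, which are separated by more
    than ``gap_s`` by construction.
    """
    if gap_s < 0:
        raise ValueError("gap_s must be >= 0")
    if gap_s == 0 or visits.empty:
        return visits
    v = visits.sort_values(
        ["individual_id", "feeder_id", "timestamp"], kind="stable"
    )
    same_group = (
        v["individual_id"].eq(v["individual_id"].shift())
        & v["feeder_id"].eq(v["feeder_id"].shift())
    ).to_numpy()
    dt = v["timestamp"].diff().dt.total_seconds().to_numpy()
    keep = ~(same_group & (dt <= gap_s))
    return (
        v.loc[keep].sort_values("timestamp", kind="stable").reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# Acquisition order, ILV, temperature


def first_visit_order(
    visits: pd.DataFrame,
    window: PeriodWindow,
    risk_set: list[str],
    seed: int = 0,
) -> DiffusionRecord:
    """Extract the order of first visits during a diffusion period.

    Individuals in ``risk_set`` never detected are censored.  Ties at the
    1-second logger resolution are broken by a seeded random permutation and
    recorded in ``tie_log``.  Individuals detected in the DP but absent from
    the risk set (no row in the preceding association network) are excluded
    with a warning.
    """
    if window.role != DP:
        raise ValueError("first_visit_order requires a DP window")
    sub = in_window(visits, window)
    risk = set(risk_set)
    outsiders = sorted(set(sub["individual_id"]) - risk)
    if outsiders:
        warnings.warn(
            f"{len(outsiders)} individual(s) visited {window.feeder_id} DP"
            f"{window.period_index} but are absent from the risk set and were"
            f" excluded: {outsiders[:5]}"
        )
        sub = sub[sub["individual_id"].isin(risk)]
    if sub.empty:
        return DiffusionRecord(
            feeder_id=window.feeder_id,
            dp_index=window.period_index,
            acquisition_order=[],
            risk_set=list(risk_set),
            tie_log=[],
        )
    firsts = (
        sub.groupby("individual_id")["timestamp"].min().reset_index()
    )
    rng = np.random.default_rng(seed)
    firsts["_tiebreak"] = rng.permutation(len(firsts))
    firsts = firsts.sort_values(["timestamp", "_tiebreak"], kind="stable")
    tie_log = [
        sorted(grp["individual_id"])
        for _, grp in firsts.groupby("timestamp")
        if len(grp) > 1
    ]
    return DiffusionRecord(
        feeder_id=window.feeder_id,
        dp_index=window.period_index,
        acquisition_order=firsts["individual_id"].tolist(),
        risk_set=list(risk_set),
        tie_log=tie_log,
    )


def feeder_use_ilv(
    visits: pd.DataFrame,
    window: PeriodWindow,
    risk_set: list[str],
    mode: str = "zscore",
) -> np.ndarray:
    """Standardized individual feeder use within one feeder x period.

    ``zscore`` (default): visit counts mean-centred and scaled (sample sd)
    within the window; a degenerate sd of 0 yields all zeros.  ``ratio``:
    counts divided by the mean count across the risk set.
    """
    if not risk_set:
        raise ValueError("risk_set must be nonempty")
    sub = in_window(visits, window)
    counts = (
        sub["individual_id"].value_counts().reindex(risk_set).fillna(0.0)
    ).to_numpy(dtype=float)
    if mode == "zscore":
        sd = counts.std(ddof=1) if len(counts) > 1 else 0.0
        if sd == 0:
            return np.zeros_like(counts)
        return (counts - counts.mean()) / sd
    if mode == "ratio":
        mean = counts.mean()
        if mean == 0:
            raise ValueError(
                "ratio ILV undefined: zero visits for every individual"
            )
        return counts / mean
    raise ValueError(f"unknown ILV mode {mode!r}")


def daytime_avg_temperature(
    weather: pd.DataFrame,
    dp_window: PeriodWindow,
    visits: pd.DataFrame,
    mode: str = "activity_span",
    fixed_hours: list[int] | None = None,
) -> TemperatureSummary:
    """Average daytime temperature for the first day of a diffusion period.

    ``activity_span`` (default) averages hourly temperatures over the clock
    hours between the first and last feeder visit (any feeder, inclusive) on
    that day; ``fixed_hours`` averages over a configured list of clock hours.
    """
    day = dp_window.start.normalize()
    if mode == "activity_span":
        day_mask = (visits["timestamp"] >= day) & (
            visits["timestamp"] < day + pd.Timedelta(days=1)
        )
        day_visits = visits.loc[day_mask, "timestamp"]
        if day_visits.empty:
            raise ValueError(
                f"no visits on {day.date()}: activity span undefined"
            )
        h0 = int(day_visits.min().hour)
        h1 = int(day_visits.max().hour)
        hours = list(range(h0, h1 + 1))
    elif mode == "fixed_hours":
        if not fixed_hours:
            raise ValueError("fixed_hours mode requires a list of clock hours")
        hours = sorted(fixed_hours)
    else:
        raise ValueError(f"unknown temperature mode {mode!r}")

    lookup = pd.Series(
        weather["temp_C"].to_numpy(), index=pd.DatetimeIndex(weather["hour"])
    )
    wanted = [day + pd.Timedelta(hours=h) for h in hours]
    missing = [t for t in wanted if t not in lookup.index]
    if missing:
        raise ValueError(
            "weather series is missing hourly values: "
            + ", ".join(str(t) for t in missing)
        )
    temps = np.array([lookup[t] for t in wanted], dtype=float)
    return TemperatureSummary(
        dp_index=dp_window.period_index,
        day=day,
        daytime_avg_temp=float(temps.mean()),
        hours_used=hours,
    )
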