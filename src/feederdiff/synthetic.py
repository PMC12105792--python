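"""Synthetic RFID visit streams and diffusions with known ground truth.

The generator emulates the structure the analysis assumes: several feeders
with strong site fidelity (disjoint memberships), week-long full periods
alternating with two-week empty gaps, temporally clustered dyadic visits
produced by a latent flock-arrival process, and diffusion orders drawn from
the additive OADA rate model with a per-period social-transmission strength
``s`` that can be tied to ambient temperature.

Flock clustering model: each latent flock generates Poisson arrival epochs
during active daylight hours; every flock member independently joins each
epoch with a fixed probability and is detected at the epoch time plus
Gaussian jitter.  Individuals additionally make independent solo visits via
a homogeneous Poisson process.  Real chickadee visit streams are not
generated by any known process; this is the minimal structure that makes
the co-detection association index informative, and recovery targets refer
to this latent structure, not to field data.

During each diffusion period a configurable fraction of members "drops out"
(is never detected), reproducing the imperfect overlap between association
and diffusion membership seen in field deployments: dropped members are
censored in that period's diffusion, and members returning after a dropout
week appear as risk-set newcomers the analysis must exclude.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .association import build_network
from .oada import DiffusionDesign, compute_pst
from .visits import AP, DP, PeriodWindow, VISIT_COLUMNS

SECONDS_PER_DAY = 86400


@dataclass
class SimConfig:
    """Study-design and rate parameters for the synthetic generator.

    Defaults mirror the emulated field design: 8 feeders, group sizes
    drawn from 8-42, four full/empty cycles of 7 full + 14 empty days, and
    per-period temperatures spanning roughly -11 to +5 °C.  Rates are in
    events per hour of active daylight (08:00-17:00 local).
    """

    n_feeders: int = 8
    group_size_range: tuple[int, int] = (8, 42)
    n_cycles: int = 4
    full_days: int = 7
    empty_days: int = 14
    flock_size: int = 6
    flock_arrival_rate: float = 1.5  # arrivals/hour per flock
    member_join_prob: float = 0.5
    arrival_jitter_sd: float = 5.0  # seconds
    solo_visit_rate: float = 0.25  # visits/hour/individual
    active_hours: tuple[int, int] = (8, 17)
    dropout_fraction: float = 0.2
    true_s_per_period: tuple[float, ...] | None = None
    s_baseline: float = 5.0
    true_beta: float = 0.0
    temp_per_period: tuple[float, ...] = (-8.0, -11.0, 5.0, -2.0)
    temp_slope_log_s: float | None = None
    start_date: str = "2021-01-04"
    rng_seed: int = 0

    def validate(self) -> None:
        lo, hi = self.group_size_range
        if not (1 <= lo <= hi):
            raise ValueError("group_size_range must satisfy 1 <= min <= max")
        for name in (
            "flock_arrival_rate", "solo_visit_rate", "arrival_jitter_sd",
            "s_baseline", "dropout_fraction",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.member_join_prob <= 1.0:
            raise ValueError("member_join_prob must lie in [0, 1]")
        if not 0.0 <= self.dropout_fraction < 1.0:
            raise ValueError("dropout_fraction must lie in [0, 1)")
        if self.full_days <= 0 or self.empty_days <= 0:
            raise ValueError("period lengths must be > 0")
        if self.n_feeders < 1 or self.n_cycles < 1:
            raise ValueError("n_feeders and n_cycles must be >= 1")
        a, b = self.active_hours
        if not (0 <= a < b <= 24):
            raise ValueError("active_hours must satisfy 0 <= start < end <= 24")
        if len(self.temp_per_period) != self.n_cycles:
            raise ValueError(
                "temp_per_period must provide one temperature per cycle"
            )
        if self.true_s_per_period is not None:
            if len(self.true_s_per_period) != self.n_cycles:
                raise ValueError(
                    "true_s_per_period must provide one s per cycle"
                )
            if any(s < 0 for s in self.true_s_per_period):
                raise ValueError("s values must be >= 0")

    def s_for_period(self, dp_index: int) -> float:
        """Generative s for DP ``dp_index`` (1-based)."""
        if self.true_s_per_period is not None:
            return float(self.true_s_per_period[dp_index - 1])
        if self.temp_slope_log_s is not None:
            t = self.temp_per_period[dp_index - 1]
            return float(
                np.exp(np.log(self.s_baseline) + self.temp_slope_log_s * t)
            )
        return float(self.s_baseline)


@dataclass
class GroundTruth:
    """Generative parameters and realized quantities, for recovery checks."""

    rng_seed: int
    memberships: dict[str, list[str]]
    flocks: dict[str, list[list[str]]]
    temp_per_period: list[float]
    true_beta: float
    per_period: list[dict] = field(default_factory=list)

    def expected_pst_by_period(self) -> pd.Series:
        df = pd.DataFrame(self.per_period)
        return df.groupby("dp_index")["realized_pst"].mean()

    def s_by_period(self) -> pd.Series:
        df = pd.DataFrame(self.per_period)
        return df.groupby("dp_index")["true_s"].first()

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=float)


def _coerce_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def simulate_visit_stream(
    cfg: SimConfig,
    members: list[str],
    flocks: list[list[str]],
    window: tuple[pd.Timestamp, pd.Timestamp],
    feeder_id: str,
    rng=0,
) -> pd.DataFrame:
    """Visit stream for one feeder over one window (half-open, whole days).

    Flock members share Poisson arrival epochs (joined independently with
    ``member_join_prob``, detected at epoch + Gaussian jitter); every member
    additionally makes independent solo visits.  Timestamps are rounded to
    the 1-second logger resolution and sorted.
    """
    rng = _coerce_rng(rng)
    start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    if not start < end:
        raise ValueError("window must have positive length")
    if not members:
        warnings.warn(f"feeder {feeder_id}: empty membership, empty stream")
        return _empty_visits()
    n_days = max(1, int(round((end - start) / pd.Timedelta(days=1))))
    a, b = cfg.active_hours
    secs_per_day = (b - a) * 3600
    total_s = n_days * secs_per_day
    hours = total_s / 3600.0

    offs: list[np.ndarray] = []
    whos: list[str] = []

    for flock in flocks:
        flock = [m for m in flock if m in set(members)]
        if not flock:
            continue
        n_ep = rng.poisson(cfg.flock_arrival_rate * hours)
        epochs = rng.uniform(0, total_s, n_ep)
        for m in flock:
            join = rng.random(n_ep) < cfg.member_join_prob
            t = epochs[join] + rng.normal(0, cfg.arrival_jitter_sd, int(join.sum()))
            t = t[(t >= 0) & (t < total_s)]
            offs.append(t)
            whos.extend([m] * t.size)
    for m in members:
        n = rng.poisson(cfg.solo_visit_rate * hours)
        t = rng.uniform(0, total_s, n)
        offs.append(t)
        whos.extend([m] * n)

    if not offs or sum(o.size for o in offs) == 0:
        return _empty_visits()
    off = np.concatenate(offs)
    day = np.floor(off / secs_per_day).astype(np.int64)
    within = np.floor(off - day * secs_per_day).astype(np.int64)
    secs = day * SECONDS_PER_DAY + a * 3600 + within
    ts = start.to_numpy() + secs.astype("timedelta64[s]")
    df = pd.DataFrame(
        {
            "timestamp": pd.DatetimeIndex(ts),
            "individual_id": whos,
            "feeder_id": feeder_id,
        }
    )
    return df.sort_values("timestamp", kind="stable").reset_index(drop=True)


def _empty_visits() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "timestamp": pd.DatetimeIndex([]),
            "individual_id": pd.Series([], dtype=str),
            "feeder_id": pd.Series([], dtype=str),
        }
    )


def simulate_diffusion(network, s: float, beta: float, ilv=None, rng=0):
    """Draw a full acquisition order from the additive OADA rate model.

    At each step a naive individual acquires with probability proportional
    to ``exp(beta*x_i) + s * sum_j a_ij z_j``.  Accepts an
    :class:`~feederdiff.association.AssociationNetwork` (returns ids) or a
    raw matrix (returns indices).
    """
    if s < 0:
        raise ValueError("s must be >= 0")
    rng = _coerce_rng(rng)
    ids = None
    A = network
    if hasattr(network, "matrix"):
        ids = network.ids
        A = network.matrix
    A = np.asarray(A, dtype=float)
    if np.isnan(A).any():
        raise ValueError("network contains NaN")
    N = A.shape[0]
    x = np.zeros(N) if ilv is None else np.asarray(ilv, dtype=float)
    if x.shape != (N,):
        raise ValueError("ilv length must match the network")
    naive = list(range(N))
    z = np.zeros(N)
    order: list[int] = []
    for _ in range(N):
        R = np.exp(beta * x[naive]) + s * (A[naive] @ z)
        p = R / R.sum()
        pick = naive[rng.choice(len(naive), p=p)]
        order.append(pick)
        naive.remove(pick)
        z[pick] = 1.0
    if ids is not None:
        return [ids[i] for i in order]
    return order


@dataclass
class SimStudy:
    """One synthetic study: CSV-shaped tables plus the generative truth."""

    visits: pd.DataFrame
    schedule: pd.DataFrame
    weather: pd.DataFrame
    truth: GroundTruth

    def write(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        v = self.visits.copy()
        v["timestamp"] = v["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
        v.to_csv(out / "visits.csv", index=False, columns=list(VISIT_COLUMNS))
        s = self.schedule.copy()
        for col in ("start", "end"):
            s[col] = pd.to_datetime(s[col]).dt.strftime("%Y-%m-%dT%H:%M:%S")
        s.to_csv(out / "schedule.csv", index=False)
        w = self.weather.copy()
        w["hour"] = pd.to_datetime(w["hour"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
        w.to_csv(out / "weather.csv", index=False)
        self.truth.to_json(out / "ground_truth.json")


def simulate_study(cfg: SimConfig) -> SimStudy:
    """End-to-end synthetic dataset: visits, schedule, weather, truth.

    Layout: full periods 0..n_cycles, each followed by an empty gap; full
    period k-1 is association period AP k and full period k is diffusion
    period DP k, so every feeder contributes ``n_cycles`` feeder-period
    combinations.  Diffusion orders are drawn from the OADA rate model on
    the modSRI network realized in the preceding full week, then embedded
    into the week's visit stream as each participant's first visit.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed)
    start0 = pd.Timestamp(cfg.start_date)
    cycle_days = cfg.full_days + cfg.empty_days
    full_starts = [
        start0 + pd.Timedelta(days=i * cycle_days) for i in range(cfg.n_cycles + 1)
    ]
    full_len = pd.Timedelta(days=cfg.full_days)

    feeders = [f"F{f + 1}" for f in range(cfg.n_feeders)]
    memberships: dict[str, list[str]] = {}
    flocks: dict[str, list[list[str]]] = {}
    lo, hi = cfg.group_size_range
    for fid in feeders:
        size = int(rng.integers(lo, hi + 1))
        ids = [f"{fid}B{j:03d}" for j in range(size)]
        perm = [ids[i] for i in rng.permutation(size)]
        flocks[fid] = [
            perm[i : i + cfg.flock_size] for i in range(0, size, cfg.flock_size)
        ]
        memberships[fid] = ids

    truth = GroundTruth(
        rng_seed=cfg.rng_seed,
        memberships=memberships,
        flocks=flocks,
        temp_per_period=list(cfg.temp_per_period),
        true_beta=cfg.true_beta,
    )

    all_visits: list[pd.DataFrame] = []
    prev_visits: dict[str, pd.DataFrame] = {}

    # full period 0: pure association week
    for fid in feeders:
        present = _sample_present(cfg, memberships[fid], rng)
        stream = simulate_visit_stream(
            cfg, present, flocks[fid], (full_starts[0], full_starts[0] + full_len),
            fid, rng,
        )
        prev_visits[fid] = stream
        all_visits.append(stream)

    for k in range(1, cfg.n_cycles + 1):
        win = (full_starts[k], full_starts[k] + full_len)
        s_k = cfg.s_for_period(k)
        for fid in feeders:
            ap_window = PeriodWindow(
                period_index=k, feeder_id=fid, role=AP,
                start=full_starts[k - 1], end=full_starts[k - 1] + full_len,
            )
            network = (
                build_network(prev_visits[fid], ap_window)
                if not prev_visits[fid].empty
                else None
            )
            present = _sample_present(cfg, memberships[fid], rng)
            stream = simulate_visit_stream(
                cfg, present, flocks[fid], win, fid, rng
            )
            if network is not None and len(network.ids) >= 2:
                participants = [i for i in network.ids if i in set(present)]
            else:
                participants = []
            if len(participants) >= 2:
                sub = network.submatrix(participants)
                np.fill_diagonal(sub, 0.0)
                counts = np.array(
                    [network.visit_counts[i] for i in participants], dtype=float
                )
                sd = counts.std(ddof=1)
                ilv = (counts - counts.mean()) / sd if sd > 0 else np.zeros_like(counts)
                order_ids = simulate_diffusion(sub, s_k, cfg.true_beta, ilv, rng)
                order_ids = [participants[i] for i in order_ids]
                stream = _embed_first_visits(
                    cfg, stream, order_ids, win[0], fid, rng
                )
                design = DiffusionDesign(
                    sub, [participants.index(i) for i in order_ids], ilv
                )
                realized_pst = compute_pst(design, s=s_k, beta=cfg.true_beta)
                truth.per_period.append(
                    {
                        "feeder_id": fid,
                        "dp_index": k,
                        "true_s": s_k,
                        "true_beta": cfg.true_beta,
                        "temp": float(cfg.temp_per_period[k - 1]),
                        "realized_pst": realized_pst,
                        "n_participants": len(participants),
                        "n_censored": len(network.ids) - len(participants),
                        "acquisition_order": order_ids,
                    }
                )
            prev_visits[fid] = stream
            all_visits.append(stream)

    visits = (
        pd.concat(all_visits, ignore_index=True)
        .sort_values("timestamp", kind="stable")
        .reset_index(drop=True)
    )

    sched_rows = []
    for fid in feeders:
        for k in range(1, cfg.n_cycles + 1):
            sched_rows.append(
                (k, fid, AP, full_starts[k - 1], full_starts[k - 1] + full_len)
            )
            sched_rows.append(
                (k, fid, "EMPTY", full_starts[k - 1] + full_len, full_starts[k])
            )
            sched_rows.append((k, fid, DP, full_starts[k], full_starts[k] + full_len))
    schedule = pd.DataFrame(
        sched_rows, columns=["period_id", "feeder_id", "role", "start", "end"]
    )

    weather = _make_weather(cfg, full_starts, full_len)
    return SimStudy(visits=visits, schedule=schedule, weather=weather, truth=truth)


def _sample_present(cfg, members, rng) -> list[str]:
    n_drop = int(round(cfg.dropout_fraction * len(members)))
    if n_drop == 0:
        return list(members)
    dropped = set(
        np.asarray(members)[rng.choice(len(members), n_drop, replace=False)]
    )
    return [m for m in members if m not in dropped]


def _embed_first_visits(cfg, stream, order_ids, day1, feeder_id, rng):
    """Overwrite participants' earliest visits so first visits realize the order.

    First visits land on day 1 at increasing times (>=30 s apart); each
    participant's earlier candidate visits are dropped, later ones kept so
    flock clustering survives for the next association week.
    """
    a = cfg.active_hours[0]
    t = day1 + pd.Timedelta(hours=a, minutes=30)
    first_times = {}
    for ind in order_ids:
        t = t + pd.Timedelta(seconds=float(30.0 + rng.exponential(90.0)))
        first_times[ind] = t.floor("s")
    keep = []
    for ind, grp in stream.groupby("individual_id"):
        if ind in first_times:
            keep.append(grp[grp["timestamp"] > first_times[ind]])
        else:
            keep.append(grp)
    firsts = pd.DataFrame(
        {
            "timestamp": [first_times[i] for i in order_ids],
            "individual_id": order_ids,
            "feeder_id": feeder_id,
        }
    )
    return (
        pd.concat(keep + [firsts], ignore_index=True)
        .sort_values("timestamp", kind="stable")
        .reset_index(drop=True)
    )


def _make_weather(cfg, full_starts, full_len) -> pd.DataFrame:
    """Hourly series, piecewise constant at each cycle's DP temperature."""
    start = full_starts[0]
    end = full_starts[-1] + full_len
    hours = pd.date_range(start, end, freq="h", inclusive="left")
    temps = np.empty(len(hours))
    bounds = [full_starts[k] for k in range(1, cfg.n_cycles + 1)]
    for i, h in enumerate(hours):
        idx = 0
        for k, b in enumerate(bounds):
            if h >= b:
                idx = k
        temps[i] = cfg.temp_per_period[idx]
    return pd.DataFrame({"hour": hours, "temp_C": temps})
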