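"""End-to-end orchestration: visits -> networks -> OADA -> pST -> meta-regression.

For every feeder x diffusion period the pipeline builds the modSRI network
from the preceding association period, extracts the first-visit acquisition
order, fits social and asocial OADA models, selects the AICc winner (with
the convention that a non-converged social winner is replaced by the asocial
model), converts the winning social fits to pST with profile-likelihood CIs,
and finally regresses logit-pST on daytime temperature and DP number with
inverse-variance weights and a feeder random intercept.

Feeder-periods with missing or degenerate data (logger failures, too few
individuals or acquisition events) are skipped and counted as attrition so a
run reports "k out of n scheduled combinations analysed".
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, meta, oada, visits as vmod


@dataclass
class PipelineConfig:
    """Tunable settings for one pipeline run."""

    tau_seconds: float = 20.0
    debounce_gap_s: float = 0.0
    ilv_mode: str = "zscore"
    temperature_mode: str = "activity_span"
    fixed_hours: tuple[int, ...] | None = None
    s_cap: float = 1e6
    n_starts: int = 5
    min_events: int = 4  # social AICc needs n_events > k+1 = 3
    ci_level: float = 0.95
    reml: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.tau_seconds <= 0:
            raise ValueError("tau_seconds must be > 0")
        if self.debounce_gap_s < 0:
            raise ValueError("debounce_gap_s must be >= 0")
        if self.min_events < 4:
            raise ValueError("min_events below 4 leaves the social AICc undefined")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


@dataclass
class RunResult:
    """Everything one pipeline run produces."""

    fits: pd.DataFrame
    pst_table: pd.DataFrame
    temperatures: pd.DataFrame
    meta_fit: meta.MetaFit | None
    meta_table: pd.DataFrame | None
    fisher_p_pre: float | None
    fisher_p_post: float | None
    best_counts_pre: pd.DataFrame | None
    best_counts_post: pd.DataFrame | None
    n_scheduled: int
    n_analyzed: int
    attrition: list[dict]
    config: PipelineConfig
    meta_failure: str | None = None

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.fits.to_csv(out / "fits.csv", index=False)
        self.pst_table.to_csv(out / "pst.csv", index=False)
        self.temperatures.to_csv(out / "temperatures.csv", index=False)
        if self.meta_table is not None:
            self.meta_table.to_csv(out / "meta_coefficients.csv", index=False)
        log = {
            "config": asdict(self.config),
            "config_hash": self.config.config_hash(),
            "n_scheduled": self.n_scheduled,
            "n_analyzed": self.n_analyzed,
            "attrition": self.attrition,
            "fisher_p_pre_replacement": self.fisher_p_pre,
            "fisher_p_post_replacement": self.fisher_p_post,
            "meta_method": None if self.meta_fit is None else self.meta_fit.method,
            "meta_df_method": None
            if self.meta_fit is None
            else self.meta_fit.df_method,
            "meta_failure": self.meta_failure,
        }
        with open(out / "run_log.json", "w") as fh:
            json.dump(log, fh, indent=1, default=float)


def _pair_windows(windows):
    """Map (feeder, period) -> {'AP': window, 'DP': window}."""
    table: dict[tuple[str, int], dict] = {}
    for w in windows:
        table.setdefault((w.feeder_id, w.period_index), {})[w.role] = w
    return table


def run_pipeline(
    visit_table: pd.DataFrame,
    schedule: pd.DataFrame,
    weather: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> RunResult:
    """Run the full analysis on in-memory tables; see module docstring."""
    config = config or PipelineConfig()
    config.validate()
    v = vmod.debounce(visit_table, config.debounce_gap_s)
    windows = vmod.schedule_windows(schedule)
    pairs = _pair_windows(windows)
    keys = sorted(pairs.keys())
    n_scheduled = sum(1 for k in keys if vmod.DP in pairs[k])
    attrition: list[dict] = []
    fit_rows: list[dict] = []
    estimates: list[oada.PstEstimate] = []
    winners_pre: list[tuple[int, str]] = []
    winners_post: list[tuple[int, str]] = []

    for key in keys:
        feeder_id, k = key
        roles = pairs[key]
        if vmod.DP not in roles:
            continue
        key_digest = int.from_bytes(
            hashlib.sha1(f"{feeder_id}|{k}".encode()).digest()[:4], "big"
        )
        sub_seed = int(
            np.random.SeedSequence([config.seed, key_digest])
            .generate_state(1)[0]
            % (2**31)
        )
        if vmod.AP not in roles:
            attrition.append(
                {"feeder_id": feeder_id, "dp_index": k, "reason": "no AP window"}
            )
            continue
        ap_w, dp_w = roles[vmod.AP], roles[vmod.DP]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            network = association.build_network(v, ap_w, tau=config.tau_seconds)
        if len(network.ids) < 2:
            attrition.append(
                {
                    "feeder_id": feeder_id,
                    "dp_index": k,
                    "reason": "fewer than 2 individuals in AP",
                }
            )
            continue
        risk_set = network.ids
        diff = vmod.first_visit_order(v, dp_w, risk_set, seed=sub_seed)
        if diff.n_events < config.min_events:
            attrition.append(
                {
                    "feeder_id": feeder_id,
                    "dp_index": k,
                    "reason": f"only {diff.n_events} acquisition events",
                }
            )
            continue
        diff.ilv = vmod.feeder_use_ilv(v, ap_w, risk_set, mode=config.ilv_mode)

        social = oada.fit_oada(
            diff,
            network,
            oada.OadaModelSpec(
                model_type="social",
                s_max=config.s_cap,
                n_starts=config.n_starts,
                seed=sub_seed,
            ),
        )
        asocial = oada.fit_oada(
            diff,
            network,
            oada.OadaModelSpec(
                model_type="asocial", n_starts=config.n_starts, seed=sub_seed
            ),
        )
        sel = oada.compare_models(social, asocial)
        pre_winner = "social" if social.aicc < asocial.aicc else "asocial"
        winners_pre.append((k, pre_winner))
        winners_post.append((k, sel.winner))

        if sel.winner == "social":
            ci = oada.profile_ci_s(
                diff, network, social, level=config.ci_level, s_cap=config.s_cap
            )
            est = oada.pst_with_ci(
                social, ci, diff, network, feeder_id=feeder_id, dp_index=k
            )
        else:
            ci = None
            est = oada.fixed_zero_pst(feeder_id=feeder_id, dp_index=k)
        estimates.append(est)

        for fit in (social, asocial):
            fit_rows.append(
                {
                    "feeder_id": feeder_id,
                    "dp_index": k,
                    "model": fit.model_type,
                    "loglik": fit.loglik,
                    "k": fit.k,
                    "n_events": fit.n_events,
                    "aicc": fit.aicc,
                    "s_hat": fit.s_hat,
                    "beta_hat": fit.beta_hat,
                    "converged": fit.converged,
                    "winner": sel.winner,
                    "replaced": sel.replaced,
                    "pst": est.pst,
                    "pst_lower": est.pst_lower,
                    "pst_upper": est.pst_upper,
                    "s_lower": None if ci is None else ci.s_lower,
                    "s_upper": None
                    if ci is None
                    else (np.inf if ci.unbounded_upper else ci.s_upper),
                    "tau": config.tau_seconds,
                }
            )

    fits = pd.DataFrame(fit_rows)
    pst_table = meta.build_pst_table(estimates)
    n_analyzed = len(estimates)

    # one daytime temperature per DP (first DP day, all feeders pooled)
    temp_rows = []
    dp_indices = sorted({k for (_, k), r in pairs.items() if vmod.DP in r})
    for k in dp_indices:
        wins = [r[vmod.DP] for (f, kk), r in pairs.items() if kk == k and vmod.DP in r]
        first = min(wins, key=lambda w: w.start)
        try:
            summ = vmod.daytime_avg_temperature(
                weather,
                first,
                v,
                mode=config.temperature_mode,
                fixed_hours=list(config.fixed_hours) if config.fixed_hours else None,
            )
        except ValueError as exc:
            warnings.warn(f"DP{k}: temperature unavailable ({exc})")
            continue
        temp_rows.append(
            {
                "dp_index": k,
                "daytime_avg_temp": summ.daytime_avg_temp,
                "day": summ.day,
                "hours_used": summ.hours_used,
            }
        )
    temperatures = pd.DataFrame(temp_rows)

    fisher_pre, counts_pre = _fisher_by_period(winners_pre)
    fisher_post, counts_post = _fisher_by_period(winners_post)

    meta_fit = meta_table = None
    meta_failure = None
    if n_analyzed:
        try:
            meta_fit, meta_table = meta.run_meta_regression(
                pst_table,
                temperatures,
                method="REML" if config.reml else "ML",
            )
        except ValueError as exc:
            meta_failure = str(exc)
            warnings.warn(f"meta-regression skipped: {exc}")

    return RunResult(
        fits=fits,
        pst_table=pst_table,
        temperatures=temperatures,
        meta_fit=meta_fit,
        meta_table=meta_table,
        fisher_p_pre=fisher_pre,
        fisher_p_post=fisher_post,
        best_counts_pre=counts_pre,
        best_counts_post=counts_post,
        n_scheduled=n_scheduled,
        n_analyzed=n_analyzed,
        attrition=attrition,
        config=config,
    )


def _fisher_by_period(winners):
    """2 x K table of social/asocial best fits per DP and its Fisher p."""
    if not winners:
        return None, None
    df = pd.DataFrame(winners, columns=["dp_index", "winner"])
    counts = (
        df.pivot_table(
            index="winner", columns="dp_index", aggfunc="size", fill_value=0
        )
        .reindex(["social", "asocial"])
        .fillna(0)
        .astype(int)
    )
    if counts.shape[1] < 2:
        return None, counts
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = oada.fisher_exact_2xk(counts.to_numpy())
    return p, counts


def run_from_paths(
    visits_path, schedule_path, weather_path, config: PipelineConfig | None = None
) -> RunResult:
    """Read the three CSV inputs and run the pipeline."""
    return run_pipeline(
        vmod.read_visits(visits_path),
        vmod.read_schedule(schedule_path),
        vmod.read_weather(weather_path),
        config,
    )
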