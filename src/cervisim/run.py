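"""Grid experiment runner and table-shaped summaries.

``run`` executes every scenario cell (cohort x frequency x modality x delay
x variant) with the deterministic cohort solver and, optionally, the
microsimulation, and writes tidy result files plus a manifest that ties every
row to parameter-file hashes and the master seed. ``summarize`` reshapes the
per-cell results into the familiar reporting layouts: excess lifetime cases
of a 5-year delay by screening frequency, within-window rate ratios for
underscreeners versus guidelines-compliant screeners, and cohort-averaged
lifetime risks with percent-of-cancers-prevented.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import outcomes
from .cohort import cohort_solve
from .kernel import simulate_cohort
from .params import Demography, NaturalHistoryParams
from .scenarios import (
    DEFAULT_COHORTS,
    DEFAULT_DELAYS,
    DEFAULT_FREQUENCIES,
    MODALITIES,
    ScenarioSpec,
    build_grid,
    build_schedule,
)
from .synthetic_params import (
    default_demography,
    default_variant,
    default_vaccination,
)

logger = logging.getLogger("cervisim")

#: Guidelines-compliant comparator frequency by primary modality.
COMPLIANT_FREQUENCY = {"CYTOLOGY": 3, "HPV_PRIMARY": 5}


@dataclass
class RunConfig:
    variants: tuple[str, ...] = ("short_dwell", "medium_dwell", "long_dwell")
    cohorts: tuple[int, ...] = DEFAULT_COHORTS
    frequencies: tuple[int, ...] = DEFAULT_FREQUENCIES
    modalities: tuple[str, ...] = MODALITIES
    delays: tuple[int, ...] = DEFAULT_DELAYS
    engine: str = "cohort"  # "cohort" | "microsim" | "both"
    n_per_cell: int = 200_000
    master_seed: int = 1
    outdir: str = "results"

    def __post_init__(self) -> None:
        if self.engine not in ("cohort", "microsim", "both"):
            raise ValueError("engine must be cohort, microsim or both")
        if self.n_per_cell < 1:
            raise ValueError("n_per_cell must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        for k in ("variants", "cohorts", "frequencies", "modalities", "delays"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def _window_months(spec: ScenarioSpec) -> tuple[int, int]:
    start = (spec.policy.disruption_start_year - spec.birth_year) * 12
    return start, start + spec.delay_years * 12


def solve_cell(
    spec: ScenarioSpec,
    params: NaturalHistoryParams,
    demography: Demography,
    engine: str = "cohort",
    n: int = 0,
    master_seed: int = 1,
) -> dict:
    """Run one scenario cell; returns a tidy result row."""
    schedule = build_schedule(spec)
    vacc = default_vaccination(spec.birth_year)
    window = _window_months(spec)
    row = {
        "variant": params.variant_name,
        "birth_year": spec.birth_year,
        "frequency": 0 if spec.is_no_screening else spec.frequency_years,
        "modality": "NONE" if spec.is_no_screening else spec.modality,
        "delay": spec.delay_years,
        "cell_id": f"{params.variant_name}/{spec.cell_id}",
        "n_screens": len(schedule.events),
    }
    if engine in ("cohort", "both"):
        sol = cohort_solve(schedule, params, demography, vacc)
        row["lifetime_risk_pct"] = sol.lifetime_risk_percent
        row["window_rate_per_100k"] = sol.window_symptomatic_rate(window)
        row["eligible_frac_at_window"] = float(sol.eligible_frac[window[0]])
    if engine in ("microsim", "both"):
        sample = simulate_cohort(
            schedule, params, demography, vacc, n=n, master_seed=master_seed
        )
        row["mc_lifetime_risk_pct"] = outcomes.lifetime_risk(sample)
        row["mc_lifetime_risk_se_pct"] = outcomes.lifetime_risk_se(sample)
        row["mc_window_rate_per_100k"] = outcomes.symptomatic_rate_in_window(sample, window)
        row["mc_n"] = n
    return row


def run(config: RunConfig) -> pd.DataFrame:
    """Execute the full grid and write result files under ``config.outdir``.

    Writes ``cells.csv`` (one row per variant x cell), the summary tables
    from :func:`summarize`, and ``manifest.json``. Idempotent for a fixed
    seed: identical configs produce identical files.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not logger.handlers:
        logging.basicConfig(stream=sys.stderr, level=logging.INFO, format="%(name)s %(message)s")
    demography = default_demography()
    rows, failures = [], []
    param_hashes = {}
    for name in config.variants:
        params = default_variant(name)
        param_hashes[name] = hashlib.sha256(params.to_yaml().encode()).hexdigest()
        specs = build_grid(config.cohorts, config.frequencies, config.modalities, config.delays)
        logger.info("variant %s: %d cells (engine=%s)", name, len(specs), config.engine)
        for spec in specs:
            try:
                rows.append(
                    solve_cell(
                        spec, params, demography,
                        engine=config.engine, n=config.n_per_cell,
                        master_seed=config.master_seed,
                    )
                )
            except Exception as err:  # pragma: no cover - defensive
                logger.error("cell %s failed: %s", spec.cell_id, err)
                failures.append((name, spec.cell_id, str(err)))
    cells = pd.DataFrame(rows)
    cells.to_csv(outdir / "cells.csv", index=False)
    for tname, table in summarize(cells).items():
        table.to_csv(outdir / f"{tname}.csv")
    manifest = {
        "master_seed": config.master_seed,
        "engine": config.engine,
        "n_per_cell": config.n_per_cell,
        "config": {
            k: list(v) if isinstance(v, tuple) else v
            for k, v in asdict(config).items()
            if k != "outdir"  # output location must not break byte-identity
        },
        "parameter_hashes": param_hashes,
        "demography_hash": hashlib.sha256(demography.to_csv().encode()).hexdigest(),
        "n_cells": int(len(cells)),
        "failures": failures,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("wrote %d result rows to %s", len(cells), outdir)
    if failures:
        raise RuntimeError(f"{len(failures)} cells failed; see manifest")
    return cells


def _cohort_mean(df: pd.DataFrame, value: str) -> pd.DataFrame:
    """Average a per-cell value over birth cohorts."""
    keys = ["variant", "modality", "frequency", "delay"]
    return df.groupby(keys, as_index=False)[value].mean()


def summarize(cells: pd.DataFrame, risk_col: str = "lifetime_risk_pct") -> dict[str, pd.DataFrame]:
    """Reshape per-cell results into reporting tables.

    Returns ``excess_cases`` (5-year-delay excess lifetime cases per 100,000
    by frequency x modality x variant, with risks rounded to 0.001%),
    ``rate_ratios`` (within-window symptomatic RR versus the same-delay
    guidelines-compliant screener; no delay-0 rows), ``lifetime_risks``
    (cohort-averaged risk and percent prevented per cell).
    """
    screening = cells[cells["frequency"] > 0].copy()
    noscreen = cells[cells["frequency"] == 0]

    lr = _cohort_mean(screening, risk_col)
    lr_ns = noscreen.groupby("variant")[risk_col].mean()

    # --- lifetime risks + percent prevented ----------------------------
    lifetime = lr.copy()
    lifetime["lifetime_risk_pct"] = lifetime[risk_col].map(outcomes.round_risk_percent)
    lifetime["percent_prevented"] = [
        outcomes.percent_prevented(r, lr_ns[v])
        for r, v in zip(lifetime[risk_col], lifetime["variant"])
    ]
    if risk_col != "lifetime_risk_pct":
        lifetime = lifetime.drop(columns=[risk_col])

    # --- excess cases of the maximal delay vs none ---------------------
    dmax = int(screening["delay"].max())
    base = lr[lr["delay"] == 0].set_index(["variant", "modality", "frequency"])[risk_col]
    delayed = lr[lr["delay"] == dmax].set_index(["variant", "modality", "frequency"])[risk_col]
    delta_pts = (delayed - base).rename("delta_risk_pct_points")
    excess = delta_pts.reset_index()
    excess["excess_cases_per_100k"] = excess["delta_risk_pct_points"] * 1000.0
    excess["delta_risk_pct_points"] = excess["delta_risk_pct_points"].map(outcomes.round_risk_percent)
    excess = excess.pivot_table(
        index=["modality", "variant"], columns="frequency",
        values="excess_cases_per_100k",
    )
    excess.columns = [f"{c}-yearly" for c in excess.columns]

    # --- within-window rate ratios --------------------------------------
    rate_col = "window_rate_per_100k" if "window_rate_per_100k" in cells else "mc_window_rate_per_100k"
    rates = _cohort_mean(screening[screening["delay"] > 0], rate_col)
    rr_rows = []
    for (variant, modality, delay), grp in rates.groupby(["variant", "modality", "delay"]):
        comp_freq = COMPLIANT_FREQUENCY[modality]
        comp = grp.loc[grp["frequency"] == comp_freq, rate_col]
        comp_rate = float(comp.iloc[0]) if len(comp) else float("nan")
        for _, r in grp.iterrows():
            rr_rows.append(
                {
                    "variant": variant, "modality": modality, "delay": delay,
                    "frequency": int(r["frequency"]),
                    "rate_per_100k": r[rate_col],
                    "rate_ratio": outcomes.short_term_rate_ratio(r[rate_col], comp_rate),
                }
            )
    rate_ratios = pd.DataFrame(rr_rows)
    if len(rate_ratios):
        rate_ratios = rate_ratios.pivot_table(
            index=["modality", "variant", "delay"], columns="frequency", values="rate_ratio"
        )
        rate_ratios.columns = [f"{c}y_since_last_screen" for c in rate_ratios.columns]

    return {
        "excess_cases": excess,
        "rate_ratios": rate_ratios,
        "lifetime_risks": lifetime.set_index(["variant", "modality", "frequency", "delay"]),
    }
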