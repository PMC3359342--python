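"""End-to-end orchestration: simulate → striae → season → growth fit → compare.

``fixture_statistics`` recomputes every cross-station statistic whose inputs
are fully tabulated in the packaged station fixtures; ``analyze_station_series``
runs the daily-growth processing chain on one cohort of raw striae series;
``run_pipeline`` ties both together from a configuration mapping and writes
CSV outputs plus a reproducibility manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .comparative import (
    arrhenius_fit,
    simple_regression,
    studentized_outlier_test,
)
from .season import SeasonSummary, growth_days_per_age, summarize_station
from .stations import load_fixture_tables
from .striae import (
    MIN_STOP_RUN_DAYS,
    STOP_THRESHOLD_UM,
    PopulationTrajectory,
    StriaeSeries,
    back_calculate_heights,
    detect_winter_breaks,
    mean_trajectory,
    synchronize_cohort,
    truncate_winters,
    write_striae_csv,
)
from .synthetic import StationScenario, simulate_cohort
from .vonbert import VBFit, VBFitError, compute_phi_prime, fit_von_bertalanffy

__all__ = [
    "fixture_statistics",
    "analyze_station_series",
    "StationAnalysis",
    "run_pipeline",
]

_CSV_HEADER = (
    "# sclerogrowth output; coordinates in signed decimal degrees;"
    " lengths um/mm as labelled; values unrounded\n"
)


def fixture_statistics() -> dict:
    """Every Results-section statistic computable from the packaged tables.

    Chlorophyll a enters its latitude regression log-transformed (its
    distribution over stations is right-skewed and the environment maps are
    drawn on a log scale); temperature enters untransformed.
    """
    stations, growth = load_fixture_tables()
    lat = np.array([s.latitude_deg for s in stations])
    temp = np.array([s.mean_temp_C for s in stations])
    chla = np.array([s.mean_chla for s in stations])
    h_inf = np.array([g.h_inf for g in growth])
    k = np.array([g.k for g in growth])
    mdg = np.array([g.mdg for g in growth])
    names = [g.name for g in growth]

    phi = np.array([compute_phi_prime(kk, hh) for kk, hh in zip(k, h_inf)])
    temp_lat = simple_regression(lat, temp)
    chla_lat = simple_regression(lat, np.log(chla))
    arrhenius = arrhenius_fit(phi, temp)
    hinf_temp = simple_regression(temp, h_inf)
    mdg_temp = simple_regression(temp, mdg)
    out_ext = studentized_outlier_test(arrhenius.report, kind="external")
    out_int = studentized_outlier_test(arrhenius.report, kind="internal")

    i_min = int(np.argmin(phi))
    i_max = int(np.argmax(phi))
    return {
        "phi_prime": {n: round(float(p), 2) for n, p in zip(names, phi)},
        "phi_prime_min": {"station": names[i_min], "value": round(float(phi[i_min]), 2)},
        "phi_prime_max": {"station": names[i_max], "value": round(float(phi[i_max]), 2)},
        "temperature_vs_latitude": temp_lat.as_dict(),
        "log_chlorophyll_vs_latitude": chla_lat.as_dict(),
        "arrhenius_phi_vs_temperature": {
            "alpha_K": arrhenius.alpha,
            "beta": arrhenius.beta,
            **arrhenius.report.as_dict(),
        },
        "h_inf_vs_temperature": hinf_temp.as_dict(),
        "mdg_vs_temperature": mdg_temp.as_dict(),
        "arrhenius_outliers": {
            "flagged_stations": [names[i] for i in out_ext.flagged],
            "statistic_external": {
                n: float(v) for n, v in zip(names, out_ext.statistics)
            },
            "statistic_internal": {
                n: float(v) for n, v in zip(names, out_int.statistics)
            },
            "critical": out_ext.critical,
            "df": out_ext.df,
        },
    }


@dataclass
class StationAnalysis:
    """Products of the daily-growth chain for one station cohort."""

    station_id: str
    trajectory: PopulationTrajectory
    summary: SeasonSummary
    heights: pd.DataFrame
    vb: VBFit | None


def analyze_station_series(
    series: Sequence[StriaeSeries],
    station_id: str,
    stop_threshold_um: float = STOP_THRESHOLD_UM,
    min_stop_run_days: int = MIN_STOP_RUN_DAYS,
    max_lag_days: int = 30,
    omega_from_mng_age: bool = False,
) -> StationAnalysis:
    """Raw striae series → synchronized trajectory, season metrics, VB fit.

    Winter breaks are (re-)detected from the increments, winters truncated,
    each age class synchronized by lag search, and the mean trajectory's
    descriptors computed.  Heights back-calculated at the winter rings of all
    individuals are pooled for the von Bertalanffy fit; the fit is skipped
    (``vb=None``) when fewer than 4 distinct ages are available.
    """
    truncated = []
    heights_rows = []
    for s in series:
        breaks = detect_winter_breaks(
            s.increments_um, stop_threshold_um, min_stop_run_days
        )
        raw = replace(s, winter_breaks=breaks)
        t = truncate_winters(raw, stop_threshold_um, min_stop_run_days)
        truncated.append(t)
        for age, h in back_calculate_heights(t):
            heights_rows.append(
                {"individual_id": s.individual_id, "age": age, "height_mm": h}
            )
    heights = pd.DataFrame(heights_rows)

    max_ages = max(len(t.segments) for t in truncated)
    by_age: dict[int, pd.DataFrame] = {}
    offsets: dict[tuple[str, int], int] = {}
    for age in range(1, max_ages + 1):
        members = [t for t in truncated if len(t.segments) >= age]
        segs = [t.segments[age - 1] for t in members]
        offs, _ = synchronize_cohort(segs, max_lag_days=max_lag_days)
        by_age[age] = mean_trajectory(segs, offs)
        for t, o in zip(members, offs):
            offsets[(t.individual_id, age)] = o
    trajectory = PopulationTrajectory(station_id, by_age, offsets)

    summary = summarize_station(
        station_id,
        {a: df["mean_um"].to_numpy() for a, df in by_age.items()},
        growth_day_counts=[growth_days_per_age(t) for t in truncated],
        omega_from_mng_age=omega_from_mng_age,
    )
    vb: VBFit | None = None
    if heights["age"].nunique() >= 4:
        try:
            vb = fit_von_bertalanffy(
                heights["age"].to_numpy(float), heights["height_mm"].to_numpy()
            )
        except VBFitError:
            vb = None
    return StationAnalysis(station_id, trajectory, summary, heights, vb)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(_CSV_HEADER)
        df.to_csv(fh, index=False)


def run_pipeline(config: Mapping | str | Path, out_dir: str | Path | None = None) -> dict:
    """Execute the configured stages and write outputs plus a manifest.

    ``config`` is a mapping (or path to a YAML file) with keys:

    * ``seed``: master seed for all scenarios (default 0),
    * ``scenarios``: list of ``StationScenario`` keyword mappings (optional),
    * ``fixtures``: recompute the fixture comparison statistics (default True),
    * ``stop_threshold_um`` / ``min_stop_run_days`` / ``max_lag_days``:
      processing conventions,
    * ``out_dir``: output directory (overridable by the argument).

    At least one of ``scenarios``/``fixtures`` must be active.  A rerun with
    the same configuration is bit-identical.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    cfg = dict(config)
    out = Path(out_dir or cfg.get("out_dir") or ".")
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    scenarios = cfg.get("scenarios") or []
    do_fixtures = bool(cfg.get("fixtures", True))
    if not scenarios and not do_fixtures:
        raise ValueError("empty configuration: no scenarios and fixtures disabled")
    stop = float(cfg.get("stop_threshold_um", STOP_THRESHOLD_UM))
    min_run = int(cfg.get("min_stop_run_days", MIN_STOP_RUN_DAYS))
    max_lag = int(cfg.get("max_lag_days", 30))

    results: dict = {"stations": {}}
    summary_rows: list[dict] = []
    vb_rows: list[dict] = []
    for spec_kwargs in scenarios:
        kw = dict(spec_kwargs)
        kw.setdefault("seed", seed)
        scenario = StationScenario(**kw)
        cohort = simulate_cohort(scenario)
        write_striae_csv(cohort.series, out / f"striae_{scenario.station_id}.csv")
        analysis = analyze_station_series(
            cohort.series,
            scenario.station_id,
            stop_threshold_um=stop,
            min_stop_run_days=min_run,
            max_lag_days=max_lag,
        )
        _write_csv(
            analysis.trajectory.to_frame(),
            out / f"trajectory_{scenario.station_id}.csv",
        )
        _write_csv(analysis.heights, out / f"heights_{scenario.station_id}.csv")
        summary_rows.extend(analysis.summary.to_rows())
        if analysis.vb is not None:
            vb_rows.append({"station_id": scenario.station_id, **analysis.vb.as_dict()})
        results["stations"][scenario.station_id] = {
            "mdg": analysis.summary.mdg_um_per_day,
            "mng": analysis.summary.mng_days,
            "omega": analysis.summary.omega_d_per_yr,
            "vb": analysis.vb.as_dict() if analysis.vb else None,
        }
    if summary_rows:
        _write_csv(pd.DataFrame(summary_rows), out / "season_summary.csv")
    if vb_rows:
        _write_csv(pd.DataFrame(vb_rows), out / "vb_fits.csv")
    if do_fixtures:
        stats = fixture_statistics()
        results["fixture_statistics"] = stats
        with open(out / "fixture_statistics.json", "w") as fh:
            json.dump(stats, fh, indent=2, sort_keys=True)

    manifest = {
        "package": "sclerogrowth",
        "version": __version__,
        "seed": seed,
        "config": _jsonable(cfg),
        "conventions": {
            "stop_threshold_um": stop,
            "min_stop_run_days": min_run,
            "max_lag_days": max_lag,
            "regression_df": "dfm=1, dfe=n-2",
            "chow_df": "F(2, n-4)",
            "outlier_df": "n-2 (configurable)",
            "age_class": "1 + winters experienced",
        },
        "scenarios": [s.get("station_id", "?") if isinstance(s, Mapping) else "?" for s in scenarios],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    results["manifest"] = manifest
    return results


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
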