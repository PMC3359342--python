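"""Seasonal growth descriptors: MDG, annual growth days, MNG and Ω.

MDG (maximum daily growth, µm d⁻¹) is the mean of the 10 widest *successive*
daily increments — the best window of length 10, not the 10 best days.  The
annual number of growth days is the stria count between two consecutive
winters; MNG is its maximum over age classes; Ω (d yr⁻¹) is the OLS slope of
annual growth days on age class, quantifying how the growing season shortens
as the animal ages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .striae import StriaeSeries

__all__ = [
    "SeasonSummary",
    "OmegaFit",
    "max_daily_growth",
    "growth_days_per_age",
    "omega_slope",
    "summarize_station",
]

MDG_WINDOW = 10


def max_daily_growth(
    increments: Sequence[float] | np.ndarray, window: int = MDG_WINDOW
) -> tuple[float, float]:
    """Maximum mean over all contiguous windows of ``window`` increments.

    Returns ``(mdg, se)`` where ``se`` is the standard error of the values
    inside the first-occurring argmax window.
    """
    x = np.asarray(increments, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if x.size < window:
        raise ValueError(
            f"series of length {x.size} shorter than MDG window {window}"
        )
    csum = np.concatenate(([0.0], np.cumsum(x)))
    means = (csum[window:] - csum[:-window]) / window
    i = int(np.argmax(means))  # argmax takes the first maximum on ties
    win = x[i : i + window]
    se = float(win.std(ddof=1) / np.sqrt(window)) if window > 1 else 0.0
    return float(means[i]), se


def growth_days_per_age(s: StriaeSeries) -> dict[int, int]:
    """Stria count strictly between consecutive winter breaks, per age class."""
    edges = [0, *s.winter_breaks]
    if not s.winter_breaks or s.winter_breaks[-1] < len(s):
        edges.append(len(s))
    counts = {}
    age = 1
    for a, b in zip(edges[:-1], edges[1:]):
        if b > a:
            counts[age] = int(b - a)
            age += 1
    return counts


@dataclass(frozen=True)
class OmegaFit:
    omega_d_per_yr: float
    se: float
    r2: float
    intercept: float
    n: int

    @property
    def ci95(self) -> tuple[float, float]:
        if self.n <= 2:
            return (-np.inf, np.inf)
        tcrit = stats.t.ppf(0.975, self.n - 2)
        return (
            self.omega_d_per_yr - tcrit * self.se,
            self.omega_d_per_yr + tcrit * self.se,
        )


def omega_slope(
    growth_days: Mapping[int, float] | Sequence[float],
    ages: Sequence[float] | None = None,
    start_age: int = 1,
) -> OmegaFit:
    """OLS slope of annual growth days on age class.

    Accepts either a mapping ``age → growth days`` (possibly pooled means) or
    parallel ``growth_days``/``ages`` sequences pooling several individuals.
    ``start_age`` drops earlier age classes, e.g. to fit from the MNG age
    onward in populations whose season peaks after the first year.
    """
    if isinstance(growth_days, Mapping):
        a = np.array(sorted(growth_days), dtype=float)
        y = np.array([growth_days[int(v)] for v in a], dtype=float)
    else:
        if ages is None:
            raise ValueError("ages required with sequence input")
        a = np.asarray(ages, dtype=float)
        y = np.asarray(growth_days, dtype=float)
    keep = a >= start_age
    a, y = a[keep], y[keep]
    if a.size < 2 or np.unique(a).size < 2:
        raise ValueError("omega_slope needs >= 2 distinct age classes")
    res = stats.linregress(a, y)
    return OmegaFit(
        omega_d_per_yr=float(res.slope),
        se=float(res.stderr),
        r2=float(res.rvalue**2),
        intercept=float(res.intercept),
        n=int(a.size),
    )


@dataclass
class SeasonSummary:
    """One station's seasonal descriptor set."""

    station_id: str
    mdg_um_per_day: float
    mdg_se: float
    growth_days_by_age: dict[int, float]
    mng_days: float
    omega_d_per_yr: float
    omega_se: float
    omega_r2: float
    omega_start_age: int = 1

    def to_rows(self) -> list[dict]:
        head = {
            "station_id": self.station_id,
            "mdg": self.mdg_um_per_day,
            "mdg_se": self.mdg_se,
            "mng": self.mng_days,
            "omega": self.omega_d_per_yr,
            "omega_se": self.omega_se,
            "omega_r2": self.omega_r2,
            "omega_start_age": self.omega_start_age,
        }
        return [
            {**head, "age_class": age, "growth_days": gd}
            for age, gd in sorted(self.growth_days_by_age.items())
        ]


def summarize_station(
    station_id: str,
    trajectory_by_age: Mapping[int, "np.ndarray | Sequence[float]"],
    growth_day_counts: Sequence[Mapping[int, int]] | None = None,
    omega_from_mng_age: bool = False,
) -> SeasonSummary:
    """Season metrics from a station's synchronized mean trajectories.

    MDG is computed on the concatenated mean trajectory (population level).
    Growth days per age come from the per-individual stria counts when
    ``growth_day_counts`` (one age→count mapping per individual) is given —
    the count of striae between two winters is an individual-level quantity,
    and the aligned-union span of the mean trajectory overstates it by the
    start-jitter spread.  Without counts the trajectory lengths are used.
    The Ω regression pools all (age, count) points; ``omega_from_mng_age``
    starts it at the age class attaining MNG instead of age 1.
    """
    if not trajectory_by_age:
        raise ValueError("no age classes")
    concat = np.concatenate(
        [np.asarray(trajectory_by_age[a], float) for a in sorted(trajectory_by_age)]
    )
    mdg, mdg_se = max_daily_growth(concat)
    if growth_day_counts:
        pooled_ages: list[float] = []
        pooled_days: list[float] = []
        per_age: dict[int, list[float]] = {}
        for counts in growth_day_counts:
            for a, d in counts.items():
                pooled_ages.append(float(a))
                pooled_days.append(float(d))
                per_age.setdefault(int(a), []).append(float(d))
        gd = {a: float(np.mean(v)) for a, v in per_age.items()}
    else:
        gd = {int(a): float(len(trajectory_by_age[a])) for a in trajectory_by_age}
        pooled_ages = [float(a) for a in gd]
        pooled_days = [gd[a] for a in gd]
    mng_age = max(gd, key=lambda a: (gd[a], -a))
    start = mng_age if omega_from_mng_age else 1
    fit = omega_slope(pooled_days, ages=pooled_ages, start_age=start)
    return SeasonSummary(
        station_id=station_id,
        mdg_um_per_day=mdg,
        mdg_se=mdg_se,
        growth_days_by_age=gd,
        mng_days=max(gd.values()),
        omega_d_per_yr=fit.omega_d_per_yr,
        omega_se=fit.se,
        omega_r2=fit.r2,
        omega_start_age=start,
    )
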