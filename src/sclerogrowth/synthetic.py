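"""Synthetic daily shell-growth generator.

Emulates the statistical structure of *Pecten maximus* daily increment data:
each growing season is a smooth unimodal daily-growth envelope (cosine-tapered
rise and fall around a plateau occupying the middle 50% of the season),
modulated by a shared day-to-day environmental forcing signal and rescaled so
the deterministic maximum 10-day running mean equals the target maximum daily
growth; winters are explicit zero-increment runs; season length declines with
age at a station-specific rate Ω; individuals differ by multiplicative
lognormal noise on daily increments and by a jittered season start that
desynchronizes the cohort.

Both the envelope and the forcing are locked to the station calendar, not to
each individual's own first stria: an individual starting ``jitter`` days
late samples a later window of the same curve.  The shared forcing mimics the
common food/temperature fluctuations that drive day-to-day covariation in
real cohorts — it is what makes synchronization (recovering the jitters by
lag search) a well-posed inference problem rather than a no-op.

Everything is deterministic given the scenario seed; each individual draws
from its own seeded substream so cohorts are reproducible element-wise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .striae import StriaeSeries

__all__ = [
    "StationScenario",
    "VBScenario",
    "CohortData",
    "simulate_daily_individual",
    "simulate_cohort",
    "simulate_annual_heights",
    "write_heights_csv",
]

#: fraction of the peak used as the slow-growth floor at season edges; keeps
#: in-season increments above the winter-stop threshold (5 µm d⁻¹) so winter
#: detection never splits a season.
FLOOR_FRACTION = 0.08
#: zero days appended after the final season so the last winter ring exists.
TRAILING_WINTER_DAYS = 15
#: hard cap on a realized season so a 365-day calendar year always retains a
#: winter gap of at least ~25 zero days.
MAX_SEASON_DAYS = 340


@dataclass(frozen=True)
class StationScenario:
    """Generative conditions for one station's daily-growth cohort.

    Parameters
    ----------
    station_id : identifier
    latitude_deg : decimal degrees (metadata only; growth is imposed, not
        temperature-driven)
    mean_temp_C : °C (metadata only)
    peak_daily_growth_um : target maximum daily growth (µm d⁻¹); the envelope
        plateau, hence the noiseless maximum 10-day running mean.
    season_length_by_age : nominal growth days per age class.
    omega_true : signed generative slope of season length on age (d yr⁻¹).
    n_individuals : cohort size.
    noise_cv : coefficient of variation of the multiplicative lognormal daily
        noise; also the CV of realized season length around its nominal value.
    start_jitter_days : maximum absolute day-offset of an individual's season
        start from the station calendar.
    seed : master seed; individual substreams derive from (seed, index).
    start_doy : day-of-year on which the station's nominal season opens.
    forcing_sd : standard deviation of the shared multiplicative day-to-day
        forcing (``None`` → twice ``noise_cv``, so a noiseless scenario has a
        perfectly smooth season).
    forcing_corr_days : correlation length (Gaussian kernel σ, days) of the
        shared forcing.
    """

    station_id: str
    peak_daily_growth_um: float
    season_length_by_age: tuple[int, ...]
    omega_true: float = 0.0
    n_individuals: int = 1
    noise_cv: float = 0.05
    start_jitter_days: int = 10
    seed: int = 0
    latitude_deg: float = 48.0
    mean_temp_C: float = 12.0
    start_doy: int = 60
    forcing_sd: float | None = None
    forcing_corr_days: float = 2.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "season_length_by_age", tuple(int(v) for v in self.season_length_by_age)
        )
        if len(self.season_length_by_age) == 0:
            raise ValueError("unusable scenario: empty season_length_by_age")
        if self.peak_daily_growth_um <= 0:
            raise ValueError("peak_daily_growth_um must be positive")
        if any(not 0 <= v <= 366 for v in self.season_length_by_age):
            raise ValueError("season lengths must lie in [0, 366]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.start_jitter_days < 0:
            raise ValueError("start_jitter_days must be >= 0")
        if self.forcing_sd is not None and self.forcing_sd < 0:
            raise ValueError("forcing_sd must be >= 0")
        if self.forcing_corr_days <= 0:
            raise ValueError("forcing_corr_days must be positive")

    @property
    def effective_forcing_sd(self) -> float:
        return 2.0 * self.noise_cv if self.forcing_sd is None else self.forcing_sd

    @classmethod
    def linear_seasons(
        cls,
        station_id: str,
        peak_daily_growth_um: float,
        first_season_days: float,
        omega: float,
        n_ages: int,
        **kwargs,
    ) -> "StationScenario":
        """Scenario whose nominal season lengths follow ``first + Ω·(age−1)``."""
        lengths = tuple(
            int(round(first_season_days + omega * a)) for a in range(n_ages)
        )
        return cls(
            station_id=station_id,
            peak_daily_growth_um=peak_daily_growth_um,
            season_length_by_age=lengths,
            omega_true=omega,
            **kwargs,
        )


@dataclass(frozen=True)
class VBScenario:
    """Height-at-age sampling conditions for von Bertalanffy round-trips."""

    H_inf_mm: float
    k_per_yr: float
    t0_yr: float
    ages: tuple[float, ...]
    noise_sd_mm: float = 0.0
    n_individuals: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "ages", tuple(float(a) for a in self.ages))
        if len(self.ages) == 0:
            raise ValueError("ages must be non-empty")
        if self.H_inf_mm <= 0 or self.k_per_yr <= 0:
            raise ValueError("H_inf_mm and k_per_yr must be positive")
        if any(b <= a for a, b in zip(self.ages, self.ages[1:])):
            raise ValueError("ages must be strictly increasing")
        if self.noise_sd_mm < 0:
            raise ValueError("noise_sd_mm must be >= 0")


def seasonal_envelope(
    x: np.ndarray,
    nominal_length: int,
    jitter_max: int,
    peak: float,
    floor_fraction: float = FLOOR_FRACTION,
) -> np.ndarray:
    """Shared calendar-locked daily-growth curve for one age class.

    Support is ``nominal_length + 2·jitter_max`` days: cosine rise over the
    first quarter, plateau at ``peak`` over the middle half, cosine fall over
    the last quarter; outside the support the curve sits at the floor so a
    late-starting individual still records slow positive growth.
    """
    S = nominal_length + 2 * jitter_max
    r = 0.25 * S
    floor = floor_fraction * peak
    x = np.asarray(x, dtype=float)
    y = np.full(x.shape, floor)
    rise = (x >= 0) & (x < r)
    y[rise] = floor + (peak - floor) * 0.5 * (1 - np.cos(np.pi * x[rise] / r))
    mid = (x >= r) & (x <= S - r)
    y[mid] = peak
    fall = (x > S - r) & (x < S)
    y[fall] = floor + (peak - floor) * 0.5 * (1 - np.cos(np.pi * (S - x[fall]) / r))
    return y


def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def _shared_forcing(
    seed: int, age_index: int, n_days: int, sd: float, corr_days: float
) -> np.ndarray:
    """Calendar-locked multiplicative forcing, common to the whole cohort.

    Gaussian-kernel-smoothed white noise with unit variance restored after
    smoothing, scaled to ``sd``; the factor ``1 + f`` is floored at 0.2 so
    growth never collapses below a fifth of the envelope.  Deterministic given
    ``(seed, age_index)`` only, hence identical across individuals.
    """
    if sd == 0 or n_days == 0:
        return np.ones(n_days)
    rng = np.random.default_rng([seed, 1_000_000 + age_index])
    half = int(np.ceil(4 * corr_days))
    z = rng.standard_normal(n_days + 2 * half)
    kernel = np.exp(-0.5 * (np.arange(-half, half + 1) / corr_days) ** 2)
    kernel /= np.sqrt(np.sum(kernel * kernel))
    f = np.convolve(z, kernel, mode="valid")[:n_days]
    return np.maximum(1.0 + sd * f, 0.2)


#: realized season length may exceed its nominal value by at most this much,
#: keeping every individual inside the shared forcing's calendar domain.
MAX_LENGTH_EXCESS_DAYS = 60


def _season_curve(
    scenario: StationScenario, age_index: int
) -> np.ndarray:
    """Deterministic daily-growth curve for one age class over the calendar.

    Envelope × shared forcing, rescaled so the maximum 10-day running mean
    over the nominal season support equals ``peak_daily_growth_um`` exactly
    (so the target MDG holds by construction even with forcing).  Indexed by
    the calendar coordinate ``x`` used by ``seasonal_envelope``; the domain
    extends past the support to cover jittered, noise-lengthened windows.
    """
    L_nom = scenario.season_length_by_age[age_index]
    J = scenario.start_jitter_days
    S = L_nom + 2 * J
    domain = S + MAX_LENGTH_EXCESS_DAYS + 1
    env = seasonal_envelope(
        np.arange(domain), L_nom, J, scenario.peak_daily_growth_um
    )
    curve = env * _shared_forcing(
        scenario.seed,
        age_index,
        domain,
        scenario.effective_forcing_sd,
        scenario.forcing_corr_days,
    )
    w = min(10, S)
    csum = np.concatenate(([0.0], np.cumsum(curve[:S])))
    max_mean = np.max((csum[w:] - csum[:-w]) / w)
    if max_mean > 0:
        curve = curve * (scenario.peak_daily_growth_um / max_mean)
    return curve


@dataclass
class IndividualTruth:
    """Generator bookkeeping for one simulated individual."""

    individual_id: str
    jitter_days: int
    season_lengths: list[int]
    season_height_gain_mm: list[float]
    winter_breaks: list[int]


def _simulate_one(
    scenario: StationScenario, individual_index: int
) -> tuple[StriaeSeries, IndividualTruth]:
    if individual_index >= scenario.n_individuals or individual_index < 0:
        raise ValueError("individual_index out of range")
    rng = np.random.default_rng([scenario.seed, individual_index])
    J = scenario.start_jitter_days
    jitter = int(rng.integers(-J, J + 1)) if J > 0 else 0

    incs: list[np.ndarray] = []
    cal: list[np.ndarray] = []
    breaks: list[int] = []
    lengths: list[int] = []
    gains: list[float] = []
    pos = 0
    for a, L_nom in enumerate(scenario.season_length_by_age):
        factor = _lognormal_factors(rng, scenario.noise_cv, 1)[0]
        L = int(round(L_nom * factor))
        L = int(np.clip(L, 1, min(MAX_SEASON_DAYS, L_nom + MAX_LENGTH_EXCESS_DAYS)))
        x = J + jitter + np.arange(L)
        daily = _season_curve(scenario, a)[x] * _lognormal_factors(
            rng, scenario.noise_cv, L
        )
        start_abs = a * 365 + scenario.start_doy + jitter
        incs.append(daily)
        cal.append(start_abs + np.arange(L))
        pos += L
        lengths.append(L)
        gains.append(float(daily.sum()) / 1000.0)
        if a + 1 < len(scenario.season_length_by_age):
            next_start = (a + 1) * 365 + scenario.start_doy + jitter
            gap = next_start - (start_abs + L)
            incs.append(np.zeros(gap))
            cal.append(start_abs + L + np.arange(gap))
            breaks.append(pos + gap)
            pos += gap
        else:
            incs.append(np.zeros(TRAILING_WINTER_DAYS))
            cal.append(start_abs + L + np.arange(TRAILING_WINTER_DAYS))
            breaks.append(pos + TRAILING_WINTER_DAYS)
            pos += TRAILING_WINTER_DAYS
    ind_id = f"{scenario.station_id}-{individual_index:03d}"
    series = StriaeSeries(
        individual_id=ind_id,
        increments_um=np.concatenate(incs),
        winter_breaks=breaks,
        calendar_days=np.concatenate(cal),
        station_id=scenario.station_id,
    )
    truth = IndividualTruth(ind_id, jitter, lengths, gains, breaks)
    return series, truth


def simulate_daily_individual(
    scenario: StationScenario, individual_index: int
) -> StriaeSeries:
    """One individual's raw striae series (winters as explicit zero runs).

    Deterministic given ``(scenario.seed, individual_index)``.  The returned
    ``winter_breaks`` are the generator's true season boundaries; downstream
    detection should reproduce them.
    """
    return _simulate_one(scenario, individual_index)[0]


@dataclass
class CohortData:
    """A simulated station cohort plus the generator's ground truth."""

    scenario: StationScenario
    series: list[StriaeSeries]
    truth: list[IndividualTruth] = field(repr=False)

    @property
    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.truth:
            for age, (L, g) in enumerate(
                zip(t.season_lengths, t.season_height_gain_mm), start=1
            ):
                rows.append(
                    {
                        "individual_id": t.individual_id,
                        "jitter_days": t.jitter_days,
                        "age_class": age,
                        "season_length_d": L,
                        "height_gain_mm": g,
                    }
                )
        return pd.DataFrame(rows)


def simulate_cohort(scenario: StationScenario) -> CohortData:
    """Simulate all individuals of a scenario with their bookkeeping."""
    pairs = [_simulate_one(scenario, i) for i in range(scenario.n_individuals)]
    return CohortData(
        scenario, [p[0] for p in pairs], [p[1] for p in pairs]
    )


def vb_height(t, H_inf: float, k: float, t0: float):
    """Specialized von Bertalanffy height-at-age curve (mm)."""
    return H_inf * (1.0 - np.exp(-k * (np.asarray(t, dtype=float) - t0)))


def simulate_annual_heights(scenario: VBScenario) -> pd.DataFrame:
    """Back-calculated height-at-age table drawn around a von Bertalanffy curve.

    Heights are the deterministic curve plus Gaussian noise of the scenario's
    standard deviation, truncated at zero.  Deterministic given the seed.
    Columns: ``individual_id, age, height_mm``.
    """
    rng = np.random.default_rng(scenario.seed)
    ages = np.asarray(scenario.ages)
    rows = []
    for i in range(scenario.n_individuals):
        h = vb_height(ages, scenario.H_inf_mm, scenario.k_per_yr, scenario.t0_yr)
        if scenario.noise_sd_mm > 0:
            h = h + rng.normal(0.0, scenario.noise_sd_mm, size=ages.size)
        h = np.clip(h, 0.0, None)
        rows.append(
            pd.DataFrame(
                {"individual_id": f"ind-{i:03d}", "age": ages, "height_mm": h}
            )
        )
    return pd.concat(rows, ignore_index=True)


def write_heights_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)
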