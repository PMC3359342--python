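"""Per-individual daily striae-width processing and cohort synchronization.

The scallop *Pecten maximus* deposits one growth stria per day; the distance
between consecutive striae is that day's shell extension in µm.  Growth stops
in winter, so a lifetime series of inter-striae distances decomposes into
annual growing seasons separated by winter gaps.  This module turns raw
per-individual series into:

* detected winter breaks (runs of no measurable growth),
* back-calculated shell heights at each winter ring,
* winter-truncated, per-age-class growth-day series,
* a synchronized population mean daily-growth trajectory with 95% CIs.

Age-class convention: the age class of a stria is 1 + the number of winters
(1st-of-January crossings) the individual has already experienced, so the
first growing season is age class 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StriaeSeries",
    "PopulationTrajectory",
    "detect_winter_breaks",
    "back_calculate_heights",
    "truncate_winters",
    "synchronize_cohort",
    "mean_trajectory",
    "read_striae_csv",
    "write_striae_csv",
]

#: default winter-stop recognition: a run of at least this many consecutive
#: days at or below STOP_THRESHOLD_UM counts as a winter gap.  Robust to
#: isolated slow days, permissive enough for real measurement floors.
STOP_THRESHOLD_UM = 5.0
MIN_STOP_RUN_DAYS = 5


@dataclass
class StriaeSeries:
    """One individual's ordered daily growth increments (µm d⁻¹).

    Parameters
    ----------
    individual_id:
        Identifier of the shell.
    increments_um:
        Inter-striae distances from the earliest detectable stria to the
        shell edge, in µm per day.  May contain explicit zero runs encoding
        winters (raw series) or not (truncated series).
    winter_breaks:
        Strictly increasing index positions; each is the index *just after*
        the last element of a winter run (raw) or the cumulative stria count
        at the end of a growth year (truncated).
    initial_height_um:
        Umbo-to-first-stria offset in µm (0 if the first stria is at the umbo).
    calendar_days:
        Optional absolute day index per stria (day 1 = 1 January of the
        settlement year), same length as ``increments_um``.
    """

    individual_id: str
    increments_um: np.ndarray
    winter_breaks: list[int] = field(default_factory=list)
    initial_height_um: float = 0.0
    calendar_days: np.ndarray | None = None
    station_id: str | None = None

    def __post_init__(self) -> None:
        self.increments_um = np.asarray(self.increments_um, dtype=float)
        if self.increments_um.ndim != 1:
            raise ValueError("increments_um must be one-dimensional")
        if not np.all(np.isfinite(self.increments_um)):
            raise ValueError("increments must be finite")
        if np.any(self.increments_um < 0):
            raise ValueError("increments must be non-negative")
        breaks = list(self.winter_breaks)
        if breaks != sorted(set(breaks)):
            raise ValueError("winter_breaks must be strictly increasing")
        if breaks and (breaks[0] <= 0 or breaks[-1] > len(self.increments_um)):
            raise ValueError("winter_breaks out of range")
        self.winter_breaks = breaks
        if self.calendar_days is not None:
            self.calendar_days = np.asarray(self.calendar_days)
            if self.calendar_days.shape != self.increments_um.shape:
                raise ValueError("calendar_days must match increments length")

    def __len__(self) -> int:
        return len(self.increments_um)

    @property
    def segments(self) -> list[np.ndarray]:
        """Increment sub-arrays delimited by the winter breaks."""
        edges = [0, *self.winter_breaks]
        if not self.winter_breaks or self.winter_breaks[-1] < len(self):
            edges.append(len(self))
        return [
            self.increments_um[a:b] for a, b in zip(edges[:-1], edges[1:]) if b > a
        ]


def detect_winter_breaks(
    increments_um: Sequence[float] | np.ndarray,
    stop_threshold_um: float = STOP_THRESHOLD_UM,
    min_stop_run_days: int = MIN_STOP_RUN_DAYS,
) -> list[int]:
    """Locate winter growth stops in a raw increment series.

    A break is declared at every maximal run of at least ``min_stop_run_days``
    consecutive values ≤ ``stop_threshold_um``; the returned index is the
    position just after the run.  Idempotent: re-running on a series whose
    flagged runs were removed finds nothing.
    """
    if stop_threshold_um < 0:
        raise ValueError("stop_threshold_um must be non-negative")
    if min_stop_run_days < 1:
        raise ValueError("min_stop_run_days must be >= 1")
    x = np.asarray(increments_um, dtype=float)
    if x.size == 0:
        raise ValueError("empty increment series")
    breaks: list[int] = []
    for start, stop in _slow_runs(x, stop_threshold_um, min_stop_run_days):
        breaks.append(stop)
    return breaks


def _slow_runs(
    x: np.ndarray, threshold: float, min_run: int
) -> list[tuple[int, int]]:
    """Maximal runs (half-open [start, stop)) of values <= threshold, length >= min_run."""
    slow = x <= threshold
    edges = np.flatnonzero(np.diff(np.concatenate(([False], slow, [False])).astype(int)))
    runs = edges.reshape(-1, 2)
    return [(int(a), int(b)) for a, b in runs if b - a >= min_run]


def back_calculate_heights(s: StriaeSeries) -> list[tuple[int, float]]:
    """Shell height (mm) at each winter ring by cumulative increment sums.

    The height at winter *i* is the umbo offset plus all daily growth up to
    that winter, divided by 1000 (µm → mm).  If the series continues past the
    last break, the shell-edge height is appended as one further age.
    """
    csum = np.concatenate(([0.0], np.cumsum(s.increments_um)))
    ages_heights = [
        (age, (s.initial_height_um + csum[b]) / 1000.0)
        for age, b in enumerate(s.winter_breaks, start=1)
    ]
    if not s.winter_breaks:
        ages_heights.append((1, (s.initial_height_um + csum[-1]) / 1000.0))
    elif s.winter_breaks[-1] < len(s):
        ages_heights.append(
            (len(s.winter_breaks) + 1, (s.initial_height_um + csum[-1]) / 1000.0)
        )
    return ages_heights


def truncate_winters(
    s: StriaeSeries,
    stop_threshold_um: float = STOP_THRESHOLD_UM,
    min_stop_run_days: int = MIN_STOP_RUN_DAYS,
) -> StriaeSeries:
    """Remove winter zero-runs, producing contiguous per-age-class growth days.

    Only runs matching the winter criterion are dropped; isolated slow days
    inside a season are kept.  The result's ``winter_breaks`` are cumulative
    growth-day counts at each season end, so ``segments`` re-indexes every age
    class from growth day 1.  The total retained stria count is conserved.
    Applying the operation to an already-truncated series is the identity.
    """
    x = s.increments_um
    runs = _slow_runs(x, stop_threshold_um, min_stop_run_days)
    keep = np.ones(len(x), dtype=bool)
    for a, b in runs:
        keep[a:b] = False
    kept_before = np.concatenate(([0], np.cumsum(keep)))
    # boundaries from removed runs, merged with pre-existing breaks mapped
    # into the truncated coordinates (keeps the operation idempotent)
    candidates = {int(kept_before[b]) for _, b in runs}
    candidates |= {int(kept_before[b]) for b in s.winter_breaks}
    new_breaks = sorted(v for v in candidates if v > 0)
    cal = s.calendar_days[keep] if s.calendar_days is not None else None
    return replace(
        s,
        increments_um=x[keep],
        winter_breaks=new_breaks,
        calendar_days=cal,
    )


def _pair_msd(a: np.ndarray, b: np.ndarray, rel: int, penalty: float) -> float:
    """Mean squared difference of a and b with b shifted by rel days."""
    lo = max(0, rel)
    hi = min(len(a), rel + len(b))
    if hi <= lo:
        return penalty
    da = a[lo:hi]
    db = b[lo - rel : hi - rel]
    d = da - db
    return float(d @ d) / (hi - lo)


def _pair_msd_table(
    a: np.ndarray, b: np.ndarray, max_rel: int, penalty: float
) -> np.ndarray:
    """``_pair_msd(a, b, rel)`` for every rel in [-max_rel, max_rel], vectorized.

    Uses the cross-correlation identity Σ(a−b)² = Σa² + Σb² − 2Σab over the
    overlap, with prefix sums for the squared terms.
    """
    la, lb = len(a), len(b)
    corr = np.correlate(a, b, mode="full")  # corr[rel + lb - 1] = Σ a[t]·b[t-rel]
    ca = np.concatenate(([0.0], np.cumsum(a * a)))
    cb = np.concatenate(([0.0], np.cumsum(b * b)))
    rels = np.arange(-max_rel, max_rel + 1)
    out = np.full(rels.size, penalty)
    for idx, rel in enumerate(rels):
        lo = max(0, rel)
        hi = min(la, rel + lb)
        if hi <= lo:
            continue
        sum_ab = corr[rel + lb - 1] if -lb < rel < la else 0.0
        sum_a2 = ca[hi] - ca[lo]
        sum_b2 = cb[hi - rel] - cb[lo - rel]
        out[idx] = (sum_a2 + sum_b2 - 2.0 * sum_ab) / (hi - lo)
    return out


def synchronize_cohort(
    segments: Sequence[np.ndarray] | Sequence[Sequence[float]],
    max_lag_days: int = 30,
    max_sweeps: int = 50,
) -> tuple[list[int], float]:
    """Align one age class of a cohort by integer day-offsets.

    Minimizes the sum over unordered pairs of the overlap-normalized mean
    squared difference between series, by exhaustive per-individual lag search
    within ``±max_lag_days`` inside coordinate descent.  The first individual
    is pinned at offset 0; ties break toward the smaller ``|offset|``.  The
    search is a heuristic — each sweep cannot increase the objective but the
    global optimum is not guaranteed.

    Returns
    -------
    offsets, objective:
        One integer offset per individual and the final objective value.
    """
    if max_lag_days < 0:
        raise ValueError("max_lag_days must be >= 0")
    series = [np.asarray(s, dtype=float) for s in segments]
    if len(series) == 0:
        raise ValueError("no individuals to synchronize")
    if any(len(s) == 0 for s in series):
        raise ValueError("empty series cannot be synchronized")
    n = len(series)
    offsets = np.zeros(n, dtype=int)
    if n == 1:
        return [0], 0.0
    # penalty for non-overlapping pairs: larger than any achievable MSD
    scale = max(float(np.max(np.abs(s))) for s in series) or 1.0
    penalty = 4.0 * scale * scale * 1e6

    # offsets live in ±max_lag, so pairwise relative lags live in ±2·max_lag
    max_rel = 2 * max_lag_days
    tables = {}
    for j in range(n):
        for i in range(j + 1, n):
            tables[(j, i)] = _pair_msd_table(series[j], series[i], max_rel, penalty)

    def pair_cost(j: int, i: int, rel: int) -> float:
        """Cost of pair (j, i) with series i shifted rel days after series j."""
        if j < i:
            return tables[(j, i)][rel + max_rel]
        return tables[(i, j)][-rel + max_rel]

    lags = np.arange(-max_lag_days, max_lag_days + 1)
    for _ in range(max_sweeps):
        changed = False
        for i in range(1, n):
            costs = np.array(
                [
                    sum(
                        pair_cost(j, i, int(lag - offsets[j]))
                        for j in range(n)
                        if j != i
                    )
                    for lag in lags
                ]
            )
            order = np.lexsort((lags, np.abs(lags), costs))
            new = int(lags[order[0]])
            if new != offsets[i]:
                offsets[i] = new
                changed = True
        if not changed:
            # rigid group-translation move: per-individual updates cannot shift
            # a mutually aligned block relative to the pinned anchor, so scan a
            # common shift of all non-anchor offsets against the anchor pairs
            lo = -max_lag_days - int(offsets[1:].min())
            hi = max_lag_days - int(offsets[1:].max())
            deltas = [d for d in range(lo, hi + 1)]
            if deltas:
                costs = np.array(
                    [
                        sum(
                            pair_cost(0, i, int(offsets[i] + d)) for i in range(1, n)
                        )
                        for d in deltas
                    ]
                )
                darr = np.array(deltas)
                order = np.lexsort((darr, np.abs(darr), costs))
                best_d = int(darr[order[0]])
                if best_d != 0:
                    offsets[1:] += best_d
                    continue
            break
    objective = sum(
        pair_cost(j, i, int(offsets[i] - offsets[j]))
        for j in range(n)
        for i in range(j + 1, n)
    )
    return offsets.tolist(), float(objective)


@dataclass
class PopulationTrajectory:
    """Synchronized mean daily growth per growth-day index, per age class.

    ``by_age`` maps an age class to a DataFrame indexed by 1-based growth day
    with columns ``mean_um``, ``ci95_um`` (half-width of the 95% CI of the
    mean, Student-t based), and ``n`` (contributing individuals).  Growth days
    with a single contributor carry the value with half-width 0 and are
    degenerate (``n == 1``).  ``offsets`` records the integer day-offset
    applied to each individual in each age class.
    """

    station_id: str
    by_age: dict[int, pd.DataFrame]
    offsets: dict[tuple[str, int], int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for age, df in sorted(self.by_age.items()):
            d = df.copy()
            d.insert(0, "age_class", age)
            d.insert(0, "station_id", self.station_id)
            rows.append(d.reset_index(names="growth_day"))
        return pd.concat(rows, ignore_index=True)


def mean_trajectory(
    aligned: Mapping[str, np.ndarray] | Sequence[np.ndarray],
    offsets: Sequence[int] | None = None,
    station_id: str = "",
    age_class: int = 1,
) -> pd.DataFrame:
    """Mean daily growth and 95% CI over aligned individual series.

    At each growth-day index with ``n >= 2`` contributors the CI half-width is
    ``t(0.975, n-1) × SE``; single-contributor days carry the lone value with
    half-width 0.  Growth days are re-indexed so the earliest aligned day is 1.
    """
    if isinstance(aligned, Mapping):
        series = [np.asarray(v, float) for v in aligned.values()]
    else:
        series = [np.asarray(v, float) for v in aligned]
    if len(series) == 0:
        raise ValueError("no series to average")
    offs = np.zeros(len(series), dtype=int) if offsets is None else np.asarray(offsets)
    start = int(offs.min())
    length = int(max(o + len(s) for o, s in zip(offs, series)) - start)
    stack = np.full((len(series), length), np.nan)
    for row, (o, s) in enumerate(zip(offs, series)):
        stack[row, o - start : o - start + len(s)] = s
    n = np.sum(~np.isnan(stack), axis=0)
    mean = np.full(length, np.nan)
    has = n > 0
    mean[has] = np.nansum(stack[:, has], axis=0) / n[has]
    ci = np.zeros(length)
    for idx in range(length):
        ni = int(n[idx])
        if ni >= 2:
            col = stack[:, idx]
            col = col[~np.isnan(col)]
            se = col.std(ddof=1) / np.sqrt(ni)
            ci[idx] = stats.t.ppf(0.975, ni - 1) * se
    df = pd.DataFrame(
        {"mean_um": mean, "ci95_um": ci, "n": n.astype(int)},
        index=pd.RangeIndex(1, length + 1, name="growth_day"),
    )
    return df[df["n"] >= 1]


def write_striae_csv(series: Sequence[StriaeSeries], path) -> None:
    """Write raw series in the long CSV dialect (one row per stria)."""
    frames = []
    for s in series:
        breaks = set(s.winter_breaks)
        age = 1 + np.array(
            [sum(1 for b in breaks if b <= i) for i in range(len(s))]
        )
        frames.append(
            pd.DataFrame(
                {
                    "individual_id": s.individual_id,
                    "station_id": s.station_id or "",
                    "stria_index": np.arange(len(s)),
                    "age_class": age,
                    "increment_um": s.increments_um,
                    "calendar_day": (
                        s.calendar_days
                        if s.calendar_days is not None
                        else np.full(len(s), -1)
                    ),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_striae_csv(path) -> list[StriaeSeries]:
    """Read the long CSV dialect back into per-individual series."""
    df = pd.read_csv(path)
    out = []
    for ind, g in df.groupby("individual_id", sort=False):
        g = g.sort_values("stria_index")
        age = g["age_class"].to_numpy()
        breaks = (np.flatnonzero(np.diff(age)) + 1).tolist()
        inc = g["increment_um"].to_numpy()
        # a final winter shows as a trailing zero run, not an age change
        trailing = np.flatnonzero(inc > 0)
        if trailing.size and len(inc) - 1 - trailing[-1] >= MIN_STOP_RUN_DAYS:
            breaks.append(len(inc))
        cal = g["calendar_day"].to_numpy()
        out.append(
            StriaeSeries(
                individual_id=str(ind),
                increments_um=g["increment_um"].to_numpy(),
                winter_breaks=breaks,
                calendar_days=None if (cal < 0).all() else cal,
                station_id=str(g["station_id"].iloc[0]) or None,
            )
        )
    return out
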