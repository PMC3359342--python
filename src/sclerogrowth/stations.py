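"""Packaged station fixtures and coordinate parsing.

The 12 Northeast-Atlantic sampling stations (Vigo, 42°N, to Traena, 66°N)
with their MODIS-climatology environment, and each station's fitted growth
summary (von Bertalanffy parameters, Φ′, MDG), shipped as small CSV fixtures.

Coordinates are decimal degrees printed with degree/prime marks: ``42°23′N``
reads as 42.23 decimal degrees (the minutes field may exceed 59, e.g.
``8°71′W`` = −8.71, which is what forces the decimal reading).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .vonbert import compute_phi_prime

__all__ = [
    "StationRecord",
    "GrowthSummaryRow",
    "parse_coordinate",
    "load_fixture_tables",
    "load_station_frame",
    "load_growth_frame",
]

_COORD_RE = re.compile(r"^\s*(\d+)°(\d+)[′']([NSEW])\s*$")


def parse_coordinate(token: str) -> float:
    """Decimal degrees from a ``D°MM′H`` token; south/west negative."""
    m = _COORD_RE.match(token)
    if not m:
        raise ValueError(f"malformed coordinate token: {token!r}")
    deg, frac, hemi = int(m.group(1)), m.group(2), m.group(3)
    value = deg + int(frac) / 100.0
    return -value if hemi in "SW" else value


@dataclass(frozen=True)
class StationRecord:
    """One sampling station's geography, environment and sample sizes."""

    station_id: int
    name: str
    latitude_deg: float
    longitude_deg: float
    mean_temp_C: float
    mean_chla: float
    n_vb: int
    age_max_vb: int
    n_dg: int
    age_max_dg: int

    def __post_init__(self) -> None:
        if not -90 <= self.latitude_deg <= 90:
            raise ValueError("latitude out of range")
        if not -180 <= self.longitude_deg <= 180:
            raise ValueError("longitude out of range")
        if not -2 < self.mean_temp_C < 40:
            raise ValueError("implausible sea-surface temperature")


@dataclass(frozen=True)
class GrowthSummaryRow:
    """One station's fitted growth summary (Table-2-shaped)."""

    station_id: int
    name: str
    h_inf: float
    h_inf_ci: tuple[float, float]
    k: float
    k_ci: tuple[float, float]
    t0: float
    t0_ci: tuple[float, float]
    r2: float
    phi_prime: float
    mdg: float
    mdg_se: float


def _read_packaged(name: str) -> pd.DataFrame:
    with resources.files("sclerogrowth.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, comment="#")


def load_station_frame() -> pd.DataFrame:
    """Station fixture as a DataFrame with parsed decimal coordinates."""
    df = _read_packaged("table1.csv")
    df["latitude_deg"] = df["latitude"].map(parse_coordinate)
    df["longitude_deg"] = df["longitude"].map(parse_coordinate)
    return df


def load_growth_frame() -> pd.DataFrame:
    return _read_packaged("table2.csv")


def load_fixture_tables() -> tuple[list[StationRecord], list[GrowthSummaryRow]]:
    """Load and validate both packaged station tables.

    Raises if either table does not hold exactly 12 self-consistent rows, or
    if any growth row's printed Φ′ disagrees at 2 decimals with the value
    recomputed from its (H∞, k) pair — a fixture-corruption checksum.
    """
    sdf = load_station_frame()
    gdf = load_growth_frame()
    if len(sdf) != 12 or len(gdf) != 12:
        raise ValueError("fixture checksum mismatch: expected 12 stations")
    stations = [
        StationRecord(
            station_id=int(r.station_id),
            name=str(r.name_),
            latitude_deg=float(r.latitude_deg),
            longitude_deg=float(r.longitude_deg),
            mean_temp_C=float(r.mean_temp_C),
            mean_chla=float(r.mean_chla),
            n_vb=int(r.n_vb),
            age_max_vb=int(r.age_max_vb),
            n_dg=int(r.n_dg),
            age_max_dg=int(r.age_max_dg),
        )
        for r in sdf.rename(columns={"name": "name_"}).itertuples()
    ]
    growth = []
    for r in gdf.itertuples():
        recomputed = compute_phi_prime(float(r.k), float(r.h_inf))
        if round(recomputed, 2) != round(float(r.phi_prime), 2):
            raise ValueError(
                f"fixture checksum mismatch: station {r.station_id} phi_prime "
                f"{r.phi_prime} vs recomputed {recomputed:.4f}"
            )
        growth.append(
            GrowthSummaryRow(
                station_id=int(r.station_id),
                name=str(r.name),
                h_inf=float(r.h_inf),
                h_inf_ci=(float(r.h_inf_lo), float(r.h_inf_hi)),
                k=float(r.k),
                k_ci=(float(r.k_lo), float(r.k_hi)),
                t0=float(r.t0),
                t0_ci=(float(r.t0_lo), float(r.t0_hi)),
                r2=float(r.r2),
                phi_prime=float(r.phi_prime),
                mdg=float(r.mdg),
                mdg_se=float(r.mdg_se),
            )
        )
    return stations, growth
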