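"""Sun position and clear-sky irradiance.

Sun position uses the standard astronomical algorithm (Spencer day-angle
series for declination and the equation of time, hour angle from local clock
time and longitude), accurate to a fraction of a degree — ample for canopy
radiation work.  Irradiance uses a simplified broadband clear-sky model:
direct-normal = solar constant x PAR fraction x exp(-tau * airmass) with
Kasten-Young airmass, and a configurable diffuse fraction.  The interface
isolates the atmosphere so a more detailed two-band parameterisation can be
dropped in.

Frame: x = north, y = east, z = up; solar azimuth degrees clockwise from
north.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class SolarGeometry:
    """Site and time for a solar-position query.

    ``hour`` is local clock time (decimal hours); solar position is derived
    from the longitude and UTC offset.
    """

    latitude: float = 35.3
    longitude: float = 113.85
    date: _dt.date = _dt.date(2022, 8, 3)
    hour: float = 12.0
    utc_offset: float = 8.0

    def __post_init__(self):
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError("latitude must be in [-90, 90]")

    def day_of_year(self) -> int:
        return self.date.timetuple().tm_yday


@dataclass(frozen=True)
class AtmosphereParams:
    """Simplified clear-sky atmosphere (PAR broadband).

    ``optical_depth`` is the broadband extinction coefficient applied to the
    airmass; ``diffuse_fraction`` is the diffuse share of total horizontal
    irradiance in ``fixed_fraction`` mode.
    """

    solar_constant: float = 1361.0
    par_fraction: float = 0.45
    optical_depth: float = 0.15
    diffuse_fraction: float = 0.15
    diffuse_mode: str = "fixed_fraction"

    def __post_init__(self):
        if not 0.0 <= self.diffuse_fraction < 1.0:
            raise ValueError("diffuse_fraction must be in [0, 1)")


@dataclass(frozen=True)
class SkyIrradiance:
    """Direct/diffuse horizontal fluxes (W/m^2) and the unit sun direction."""

    direct_horizontal: float
    diffuse_horizontal: float
    sun_direction: tuple[float, float, float]

    def __post_init__(self):
        if self.direct_horizontal < 0 or self.diffuse_horizontal < 0:
            raise ValueError("fluxes must be >= 0")


def _spencer_terms(doy: int, hour: float) -> tuple[float, float]:
    """(declination rad, equation of time minutes) via Spencer's series."""
    g = 2.0 * math.pi / 365.0 * (doy - 1 + (hour - 12.0) / 24.0)
    decl = (0.006918 - 0.399912 * math.cos(g) + 0.070257 * math.sin(g)
            - 0.006758 * math.cos(2 * g) + 0.000907 * math.sin(2 * g)
            - 0.002697 * math.cos(3 * g) + 0.00148 * math.sin(3 * g))
    eot = 229.18 * (0.000075 + 0.001868 * math.cos(g) - 0.032077 * math.sin(g)
                    - 0.014615 * math.cos(2 * g) - 0.040849 * math.sin(2 * g))
    return decl, eot


def sun_position(geom: SolarGeometry) -> tuple[float, float]:
    """Solar (zenith, azimuth) in degrees; azimuth clockwise from north."""
    decl, eot = _spencer_terms(geom.day_of_year(), geom.hour)
    tst = geom.hour + (4.0 * (geom.longitude - 15.0 * geom.utc_offset) + eot) / 60.0
    hour_angle = math.radians(15.0 * (tst - 12.0))
    lat = math.radians(geom.latitude)
    cos_z = (math.sin(lat) * math.sin(decl)
             + math.cos(lat) * math.cos(decl) * math.cos(hour_angle))
    cos_z = min(1.0, max(-1.0, cos_z))
    zenith = math.degrees(math.acos(cos_z))
    sin_z = math.sqrt(max(0.0, 1.0 - cos_z * cos_z))
    if sin_z < 1e-12:
        azimuth = 180.0
    else:
        cos_az = (math.sin(decl) - math.sin(lat) * cos_z) / (math.cos(lat) * sin_z)
        cos_az = min(1.0, max(-1.0, cos_az))
        azimuth = math.degrees(math.acos(cos_az))
        if hour_angle > 0:  # afternoon: sun in the west
            azimuth = 360.0 - azimuth
    return zenith, azimuth


def sun_direction(zenith: float, azimuth: float) -> np.ndarray:
    """Unit vector pointing towards the sun (x north, y east, z up)."""
    z = math.radians(zenith)
    a = math.radians(azimuth)
    return np.array([
        math.sin(z) * math.cos(a),
        math.sin(z) * math.sin(a),
        math.cos(z),
    ])


def airmass(zenith: float) -> float:
    """Kasten-Young relative optical airmass."""
    if zenith >= 90.0:
        return math.inf
    return 1.0 / (math.cos(math.radians(zenith))
                  + 0.50572 * (96.07995 - zenith) ** -1.6364)


def clear_sky_irradiance(geom: SolarGeometry,
                         atmosphere: AtmosphereParams | None = None) -> SkyIrradiance:
    """Clear-sky direct/diffuse horizontal PAR flux at the given time."""
    atm = atmosphere or AtmosphereParams()
    zenith, azimuth = sun_position(geom)
    s = sun_direction(zenith, azimuth)
    if zenith >= 90.0:
        return SkyIrradiance(0.0, 0.0, tuple(s))
    m = airmass(zenith)
    dni = atm.solar_constant * atm.par_fraction * math.exp(-atm.optical_depth * m)
    direct_h = dni * math.cos(math.radians(zenith))
    if atm.diffuse_mode == "fixed_fraction":
        f = atm.diffuse_fraction
        diffuse_h = direct_h * f / (1.0 - f)
    else:
        raise ValueError(f"unknown diffuse_mode '{atm.diffuse_mode}'")
    return SkyIrradiance(direct_h, diffuse_h, tuple(s))
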