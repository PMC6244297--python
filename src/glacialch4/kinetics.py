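"""Incubation and static-chamber CH4 kinetics.

Rates come from blank-corrected ordinary least-squares regression of
headspace mixing ratio against time.  Sealed sediment-slurry vials yield
mass-specific potentials (fmol CH4 per gram dry sediment per hour,
positive = production, negative = consumption); proglacial static
chambers yield areal fluxes (umol CH4 m^-2 day^-1, positive = emission).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .config import ATM_PA, R_GAS, PhysicalConstants

log = logging.getLogger(__name__)

CONDITIONS = ("methanogenic_anoxic", "methanotrophic_oxic", "control_blank")

#: Fits with R^2 below this are flagged (not rejected), mirroring common
#: chamber-flux QC practice.
R2_FLAG_THRESHOLD = 0.7


@dataclass
class RateFit:
    """OLS slope of concentration on time with diagnostics.

    ``stderr`` is NaN for two-point (finite-difference) fits, where it is
    undefined.  ``flagged`` marks poor linearity (R^2 below threshold).
    """

    slope: float
    stderr: float
    intercept: float
    r_squared: float
    n: int
    flagged: bool = False

    def per_day(self) -> float:
        """Convenience conversion of an hourly slope to per-day."""
        return self.slope * 24.0


def linear_rate(times, conc, r2_threshold: float = R2_FLAG_THRESHOLD) -> RateFit:
    """OLS slope of concentration against time (units of conc per time unit).

    With exactly two points the slope is the finite difference and the
    standard error is reported as missing (NaN).

    Raises
    ------
    ValueError
        Fewer than two points, or duplicated/non-increasing times.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    if t.size < 2:
        raise ValueError("rate estimation needs at least 2 timepoints")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing (no duplicates)")
    if t.size == 2:
        slope = (c[1] - c[0]) / (t[1] - t[0])
        return RateFit(slope=float(slope), stderr=math.nan,
                       intercept=float(c[0] - slope * t[0]),
                       r_squared=1.0, n=2)
    with warnings.catch_warnings():
        # flat series trigger a harmless divide-by-zero in the r-value
        warnings.simplefilter("ignore")
        res = stats.linregress(t, c)
    r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 1.0
    return RateFit(
        slope=float(res.slope),
        stderr=float(res.stderr),
        intercept=float(res.intercept),
        r_squared=r2,
        n=int(t.size),
        flagged=r2 < r2_threshold,
    )


def blank_correct_rate(sample_slope: float, blank_slope: float) -> float:
    """Subtract the sediment-free control slope (identical units assumed)."""
    return sample_slope - blank_slope


@dataclass
class IncubationSeries:
    """Time-resolved headspace CH4 for one sealed sediment slurry.

    Times in hours, headspace CH4 in ppm by volume; optional residual-pool
    isotope readings per timepoint (permil).
    """

    series_id: str
    condition: str
    temperature_c: float
    sediment_fresh_mass: float  # g
    sediment_dry_mass: float  # g
    slurry_water_volume: float  # ml
    headspace_volume: float  # ml
    initial_ch4: float  # ppm
    times_h: list = field(default_factory=list)
    ch4_ppm: list = field(default_factory=list)
    d13c_permil: list | None = None
    dd_permil: list | None = None

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.sediment_fresh_mass <= 0 and self.condition != "control_blank":
            raise ValueError("sediment masses must be positive")
        if self.condition != "control_blank" and (
            self.sediment_dry_mass <= 0
            or self.sediment_dry_mass > self.sediment_fresh_mass
        ):
            raise ValueError("need 0 < dry mass <= fresh mass")
        if self.slurry_water_volume < 0 or self.headspace_volume <= 0:
            raise ValueError("volumes must be positive")
        t = np.asarray(self.times_h, dtype=float)
        if t.size >= 2 and np.any(np.diff(t) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if len(self.times_h) != len(self.ch4_ppm):
            raise ValueError("times and concentrations must align")


def incubation_rate(
    series: IncubationSeries,
    blank: IncubationSeries | None = None,
    *,
    include_dissolved: bool = False,
    henry_cc: float | None = None,
    pressure_atm: float = PhysicalConstants.pressure_atm,
) -> float:
    """Mass-specific CH4 turnover potential, fmol g^-1 (dry) h^-1.

    Blank-corrects the ppm h^-1 slope, converts it to mol h^-1 through the
    ideal-gas headspace inventory at the incubation temperature
    (optionally adding the dissolved slurry phase via ``henry_cc``), and
    normalises by dry sediment mass.  Positive = production.

    A missing blank proceeds with zero correction and a logged warning.
    """
    if series.sediment_dry_mass <= 0:
        raise ValueError("dry mass required for mass-specific rate")
    slope = linear_rate(series.times_h, series.ch4_ppm).slope
    if blank is None:
        log.warning("no control blank for %s: proceeding with zero blank",
                    series.series_id)
        blank_slope = 0.0
    else:
        blank_slope = linear_rate(blank.times_h, blank.ch4_ppm).slope
    slope = blank_correct_rate(slope, blank_slope)
    t_k = series.temperature_c + 273.15
    moles_per_fraction = pressure_atm * ATM_PA * (series.headspace_volume * 1e-6) / (
        R_GAS * t_k
    )
    if include_dissolved:
        if henry_cc is None:
            raise ValueError("include_dissolved requires henry_cc")
        moles_per_fraction += (
            henry_cc
            * pressure_atm
            * ATM_PA
            * (series.slurry_water_volume * 1e-6)
            / (R_GAS * t_k)
        )
    rate_mol_h = slope * 1e-6 * moles_per_fraction
    return rate_mol_h / series.sediment_dry_mass * 1e15


@dataclass
class ChamberSeries:
    """Static-chamber headspace time series (times in minutes, CH4 in ppm)."""

    chamber_id: str
    diameter: float  # m
    height: float  # m
    temperature_c: float
    times_min: list = field(default_factory=list)
    ch4_ppm: list = field(default_factory=list)
    max_deployment_min: float = 45.0

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.height <= 0:
            raise ValueError("chamber geometry must be positive")
        t = np.asarray(self.times_min, dtype=float)
        if t.size and (t.max() - t.min()) > self.max_deployment_min:
            raise ValueError(
                f"timepoints span more than the {self.max_deployment_min}-minute "
                "deployment"
            )
        if len(self.times_min) != len(self.ch4_ppm):
            raise ValueError("times and concentrations must align")


def chamber_flux(
    series: ChamberSeries, pressure_atm: float = PhysicalConstants.pressure_atm
) -> float:
    """Areal CH4 flux from a static chamber, umol m^-2 day^-1.

    flux = slope(ppm min^-1) x (V/A = height) x molar gas density at the
    chamber temperature, converted to umol m^-2 day^-1.  Positive =
    emission to atmosphere.
    """
    slope = linear_rate(series.times_min, series.ch4_ppm).slope  # ppm/min
    molar_density = pressure_atm * ATM_PA / (R_GAS * (series.temperature_c + 273.15))
    # 1e-6 (ppm->fraction) * 1440 (min->day) * 1e6 (mol->umol)
    return slope * molar_density * series.height * 1440.0
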