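"""Catchment-scale methane export and evasion budget.

Combines stream discharge, mean aqueous CH4 concentration and catchment
geometry into the headline quantities: meltwater export (tonnes day^-1),
per-glaciated-area production capacity (mmol m^-2 day^-1), the
upstream-downstream evasion fraction, the evasive flux to the atmosphere
and its stream-area weighting (mol m^-2 day^-1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import CatchmentConfig, PhysicalConstants

log = logging.getLogger(__name__)

_SECONDS_PER_DAY = 86400.0
_MG_PER_TONNE = 1e9


@dataclass(frozen=True)
class CatchmentGeometry:
    """Glaciated area and proglacial stream reach dimensions (metres/m^2)."""

    glaciated_area: float = CatchmentConfig.glaciated_area_m2
    stream_length: float = CatchmentConfig.stream_length_m
    stream_width: float = CatchmentConfig.stream_width_m

    def __post_init__(self) -> None:
        if min(self.glaciated_area, self.stream_length, self.stream_width) <= 0:
            raise ValueError("geometry must be positive")

    @property
    def stream_area(self) -> float:
        return self.stream_length * self.stream_width


@dataclass(frozen=True)
class FluxResult:
    """A catchment mass flux with its area-weighted molar equivalent.

    The molar and mass forms are cross-checked on construction: they must
    agree under the configured molar mass to within 1e-9 relative error.
    """

    mass_flux: float  # tonnes CH4 day^-1
    molar_area_flux: float  # mol CH4 m^-2 day^-1
    basis_area: float  # m^2
    provenance: str = ""
    molar_mass: float = PhysicalConstants.ch4_molar_mass

    def __post_init__(self) -> None:
        if self.mass_flux < 0:
            raise ValueError("mass flux must be non-negative")
        expected = self.mass_flux * 1e6 / self.molar_mass / self.basis_area
        if expected > 0 and abs(self.molar_area_flux - expected) / expected > 1e-9:
            raise ValueError("mass and molar fluxes disagree under the molar mass")


def flux_result(
    mass_flux: float,
    basis_area: float,
    provenance: str = "",
    molar_mass: float = PhysicalConstants.ch4_molar_mass,
) -> FluxResult:
    """Build a :class:`FluxResult` with the molar form derived consistently."""
    return FluxResult(
        mass_flux=mass_flux,
        molar_area_flux=mass_flux * 1e6 / molar_mass / basis_area,
        basis_area=basis_area,
        provenance=provenance,
        molar_mass=molar_mass,
    )


def export_flux(discharge_m3_s: float, concentration_mg_l: float) -> float:
    """Dissolved CH4 exported by the stream, tonnes day^-1.

    ``Q (m^3 s^-1) x 1000 l m^-3 x C (mg l^-1) x 86400 s day^-1 / 1e9``.
    Bilinear in discharge and concentration.
    """
    if discharge_m3_s <= 0 or concentration_mg_l < 0:
        raise ValueError("discharge must be positive, concentration non-negative")
    return (
        discharge_m3_s * 1000.0 * concentration_mg_l * _SECONDS_PER_DAY / _MG_PER_TONNE
    )


def area_production(
    mass_flux_t_day: float,
    area_m2: float,
    molar_mass: float = PhysicalConstants.ch4_molar_mass,
) -> float:
    """Per-area production capacity, mmol CH4 m^-2 day^-1."""
    if area_m2 <= 0:
        raise ValueError("area must be positive")
    return mass_flux_t_day * 1e6 / molar_mass / area_m2 * 1000.0


def evasion_fraction(upstream_conc: float, downstream_conc: float) -> float:
    """Fraction of CH4 lost to the atmosphere along the reach.

    ``1 - downstream/upstream``.  A downstream concentration exceeding
    the upstream one returns a negative fraction and logs an
    inconsistency (gaining stream) rather than raising.
    """
    if upstream_conc <= 0 or downstream_conc < 0:
        raise ValueError("upstream must be positive, downstream non-negative")
    frac = 1.0 - downstream_conc / upstream_conc
    if frac < 0:
        log.warning(
            "downstream concentration exceeds upstream (gaining stream): "
            "evasion fraction %.3f", frac,
        )
    return frac


def evasive_flux(export_t_day: float, fraction: float) -> float:
    """Evasive flux to the atmosphere, tonnes day^-1 (export x fraction)."""
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must lie in [0, 1]")
    return export_t_day * fraction


def stream_area_flux(
    evasive_t_day: float,
    geometry: CatchmentGeometry,
    molar_mass: float = PhysicalConstants.ch4_molar_mass,
) -> float:
    """Stream-area-weighted evasion, mol CH4 m^-2 day^-1."""
    return evasive_t_day * 1e6 / molar_mass / geometry.stream_area


@dataclass(frozen=True)
class Scenario:
    """One budget scenario: discharge plus concentration/evasion inputs.

    ``concentration_mg_l`` may be given directly or aggregated from
    sample summaries; ``evasion`` likewise may be a headline input or
    computed from upstream/downstream means.
    """

    name: str
    discharge_m3_s: float
    concentration_mg_l: float | None = None
    evasion: float | None = None
    upstream_mg_l: float | None = None
    downstream_mg_l: float | None = None


def reconstruct_concentration(site_phase_means) -> float:
    """Aggregate site-phase mean concentrations into a scenario mean.

    The rule is an unweighted arithmetic mean over the per-(year, phase)
    group means — not over individual samples.
    """
    means = np.asarray(list(site_phase_means), dtype=float)
    if means.size == 0:
        raise ValueError("no group means to aggregate")
    return float(means.mean())


def budget_report(
    scenarios,
    geometry: CatchmentGeometry = CatchmentGeometry(),
    molar_mass: float = PhysicalConstants.ch4_molar_mass,
) -> pd.DataFrame:
    """Assemble the per-scenario budget table.

    One row per scenario: concentration used, export flux, per-glaciated-
    area production, evasion fraction (headline input if supplied, else
    computed from upstream/downstream means), evasive flux and
    stream-area evasion.  All values carry full precision; rounding is
    left to the display layer.  Scenarios lacking both an evasion input
    and upstream/downstream means get missing evasion fields (logged).
    An empty scenario list returns an empty table.
    """
    rows = []
    for sc in scenarios:
        conc = sc.concentration_mg_l
        if conc is None:
            raise ValueError(f"scenario {sc.name!r} has no concentration")
        export = export_flux(sc.discharge_m3_s, conc)
        prod = area_production(export, geometry.glaciated_area, molar_mass)
        frac = sc.evasion
        frac_source = "headline input"
        if frac is None:
            if sc.upstream_mg_l is not None and sc.downstream_mg_l is not None:
                frac = evasion_fraction(sc.upstream_mg_l, sc.downstream_mg_l)
                frac_source = "upstream-downstream mass balance"
            else:
                log.warning(
                    "scenario %s: no evasion input or upstream/downstream "
                    "means; evasion fields missing", sc.name,
                )
                frac_source = "missing"
        if frac is not None and frac >= 0:
            evasive = evasive_flux(export, min(frac, 1.0))
            stream = stream_area_flux(evasive, geometry, molar_mass)
        else:
            evasive = stream = np.nan
        rows.append(
            {
                "scenario": sc.name,
                "discharge_m3_s": sc.discharge_m3_s,
                "concentration_mg_l": conc,
                "export_t_day": export,
                "production_mmol_m2_day": prod,
                "evasion_fraction": np.nan if frac is None else frac,
                "evasion_source": frac_source,
                "evasive_t_day": evasive,
                "stream_flux_mol_m2_day": stream,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "scenario",
            "discharge_m3_s",
            "concentration_mg_l",
            "export_t_day",
            "production_mmol_m2_day",
            "evasion_fraction",
            "evasion_source",
            "evasive_t_day",
            "stream_flux_mol_m2_day",
        ],
    )
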