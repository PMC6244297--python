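"""Configuration and physical constants shared across the pipeline.

All tunable physical constants (Henry's-law parameters, molar mass,
pressure), isotope-space geometry (source-field polygons, standard
ratios, trajectory fractionation factors) and catchment geometry live
here so that alternative compilations or site geometries are a config
edit, not a code change.  ``load_config`` merges a YAML file over the
defaults; every module accepts the relevant sub-config explicitly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

#: Universal gas constant, J mol^-1 K^-1.
R_GAS = 8.314462618
#: Standard atmosphere, Pa.
ATM_PA = 101325.0
#: Reference temperature for Henry solubilities, K.
T_REF = 298.15


@dataclass(frozen=True)
class PhysicalConstants:
    """CH4 solubility and gas-phase constants.

    Parameters
    ----------
    henry_hcp0
        Henry solubility of CH4 at 298.15 K, mol m^-3 Pa^-1
        (standard compilation value).
    henry_b
        Van't Hoff temperature coefficient d(ln Hcp)/d(1/T), K.
    pressure_atm
        Total pressure assumed for headspace balances, atm.
    ch4_molar_mass
        Molar mass of CH4, g mol^-1.
    negative_tolerance_ppm
        Headspace depletion (c_eq below background) smaller than this is
        treated as instrument noise and clipped to zero; larger negative
        excursions raise a data-quality error.
    """

    henry_hcp0: float = 1.4e-5
    henry_b: float = 1900.0
    pressure_atm: float = 1.0
    ch4_molar_mass: float = 16.04
    negative_tolerance_ppm: float = 0.05


@dataclass(frozen=True)
class IsotopeConfig:
    """Isotope standards, source-field geometry and classifier tolerances.

    Polygons are closed vertex lists in (delta13C, deltaD) per-mil space.
    Defaults follow published literature ranges for biogenic methane
    (delta13C -110 to -50 permil, deltaD -531 to -170 permil) and for
    geogenic/geothermal methane (delta13C -50 to -20 permil, deltaD -200
    to 0 permil).
    """

    r_vpdb: float = 0.011180
    r_vsmow: float = 1.5576e-4
    microbial_polygon: tuple = (
        (-110.0, -531.0),
        (-110.0, -170.0),
        (-50.0, -170.0),
        (-50.0, -531.0),
    )
    geogenic_polygon: tuple = (
        (-50.0, -200.0),
        (-50.0, 0.0),
        (-20.0, 0.0),
        (-20.0, -200.0),
    )
    #: Default fractionation factors of methanotrophic oxidation used for
    #: trajectory construction: alpha_C for 13C/12C, alpha_D for D/H.
    trajectory_alpha_c: float = 1.019
    trajectory_alpha_d: float = 1.197
    #: Max perpendicular distance (permil, Euclidean in delta space) from
    #: the two-end-member mixing segment for a "mixed" label.
    mixing_tolerance_permil: float = 10.0
    #: Max distance (permil) from the oxidation trajectory anchored at the
    #: microbial centroid for an "oxidation_affected" label.
    oxidation_tolerance_permil: float = 30.0


@dataclass(frozen=True)
class CatchmentConfig:
    """Catchment geometry and per-phase discharge/evasion scenario inputs."""

    glaciated_area_m2: float = 78e6
    stream_length_m: float = 4000.0
    stream_width_m: float = 20.0
    #: Typical discharge per campaign phase, m^3 s^-1.
    discharge_m3_s: Mapping[str, float] = field(
        default_factory=lambda: {
            "pre_upwelling": 10.0,
            "early_post": 50.0,
            "late_post": 50.0,
        }
    )
    #: Headline evasion fractions accepted as direct inputs per phase;
    #: sample-level fractions are computed alongside when data allow.
    evasion_fraction: Mapping[str, float] = field(
        default_factory=lambda: {
            "pre_upwelling": 0.54,
            "early_post": 0.86,
            "late_post": 0.86,
        }
    )


@dataclass(frozen=True)
class PhaseBreakpoints:
    """Day-of-year breakpoints separating campaign phases.

    ``pre_upwelling`` runs up to and including ``b1``; ``early_post``
    covers days strictly between ``b1`` and ``b2``; ``late_post`` starts
    at ``b2``.  Known only for the 2014 season; other years default to
    the same values.
    """

    b1: int = 128
    b2: int = 185

    def __post_init__(self) -> None:
        if not self.b1 < self.b2:
            raise ValueError("breakpoints must satisfy b1 < b2")


@dataclass(frozen=True)
class Config:
    constants: PhysicalConstants = field(default_factory=PhysicalConstants)
    isotopes: IsotopeConfig = field(default_factory=IsotopeConfig)
    catchment: CatchmentConfig = field(default_factory=CatchmentConfig)
    breakpoints: PhaseBreakpoints = field(default_factory=PhaseBreakpoints)


def default_config() -> Config:
    return Config()


def _merge(cls, defaults, overrides: Mapping):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name in overrides:
            val = overrides[f.name]
            if dataclasses.is_dataclass(f.type) or f.name in (
                "constants",
                "isotopes",
                "catchment",
                "breakpoints",
            ):
                sub_default = getattr(defaults, f.name)
                kwargs[f.name] = _merge(type(sub_default), sub_default, val)
            elif isinstance(val, Sequence) and not isinstance(val, (str, Mapping)):
                kwargs[f.name] = tuple(
                    tuple(v) if isinstance(v, Sequence) else v for v in val
                )
            else:
                kwargs[f.name] = val
        else:
            kwargs[f.name] = getattr(defaults, f.name)
    return cls(**kwargs)


def load_config(path: str | Path | None = None) -> Config:
    """Load a YAML config file and merge it over the defaults.

    Top-level keys mirror the :class:`Config` fields (``constants``,
    ``isotopes``, ``catchment``, ``breakpoints``); unknown keys raise.
    """
    cfg = default_config()
    if path is None:
        return cfg
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(Config)}
    unknown = set(raw) - known
    if unknown:
        raise KeyError(f"unknown config sections: {sorted(unknown)}")
    return _merge(Config, cfg, raw)
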