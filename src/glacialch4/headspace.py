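"""Headspace equilibration: recover aqueous CH4 from closed-vessel headspace.

A known volume of water is sealed with a gas headspace at atmospheric
pressure and left to equilibrate.  At equilibrium the aqueous and
gas-phase concentrations are linked by the dimensionless Henry's-law
solubility constant ``H_cc = C_aq / C_g``.  The original dissolved
concentration is then the mole sum of what moved into the headspace and
what remained dissolved, divided by the water volume.

The headspace mixing ratios are ppm by volume (mole fraction x 1e6);
aqueous concentrations are reported in mg l^-1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ATM_PA, R_GAS, T_REF, PhysicalConstants
from .errors import DataQualityError, MissingBackgroundError, ValidityError

#: Validity window of the van't Hoff extrapolation, K.
T_MIN, T_MAX = 260.0, 320.0


def henry_cc_at(
    temperature_k: float,
    hcp0: float = PhysicalConstants.henry_hcp0,
    b: float = PhysicalConstants.henry_b,
) -> float:
    """Dimensionless Henry solubility ``H_cc = C_aq/C_g`` for CH4 at ``T``.

    Uses the van't Hoff extrapolation of the Henry solubility
    ``Hcp(T) = hcp0 * exp(b * (1/T - 1/298.15))`` (mol m^-3 Pa^-1) and the
    ideal-gas conversion ``H_cc = Hcp * R * T``.  Monotonically decreasing
    in temperature over the validity window: cold water holds more methane.

    Raises
    ------
    ValidityError
        If ``temperature_k`` falls outside [260, 320] K.
    """
    if not (T_MIN <= temperature_k <= T_MAX):
        raise ValidityError(
            f"temperature {temperature_k} K outside validity window "
            f"[{T_MIN}, {T_MAX}] K"
        )
    hcp = hcp0 * np.exp(b * (1.0 / temperature_k - 1.0 / T_REF))
    return float(hcp * R_GAS * temperature_k)


@dataclass
class HeadspaceEquilibration:
    """One closed-vessel equilibration record.

    Attributes
    ----------
    water_volume : float
        Volume of water in the vessel, litres.
    headspace_volume : float
        Gas volume, litres.
    temperature : float
        Equilibration temperature, kelvin.
    pressure : float
        Total pressure, atmospheres.
    c_g_background : float
        Headspace CH4 mixing ratio at t = 0, ppm by volume.
    c_g_equilibrated : float
        Headspace CH4 mixing ratio after equilibration, ppm by volume.
    henry_cc : float
        Dimensionless solubility constant at ``temperature``.
    """

    water_volume: float
    headspace_volume: float
    temperature: float
    pressure: float
    c_g_background: float
    c_g_equilibrated: float
    henry_cc: float

    def __post_init__(self) -> None:
        if self.water_volume <= 0 or self.headspace_volume <= 0:
            raise ValueError("vessel volumes must be positive")
        if self.temperature <= 0 or self.pressure <= 0:
            raise ValueError("temperature and pressure must be positive")
        if self.c_g_background < 0 or self.c_g_equilibrated < 0:
            raise ValueError("mixing ratios must be non-negative")
        if self.henry_cc < 0:
            raise ValueError("henry_cc must be non-negative")


def aqueous_from_headspace(
    record: HeadspaceEquilibration,
    molar_mass: float = PhysicalConstants.ch4_molar_mass,
    negative_tolerance_ppm: float = PhysicalConstants.negative_tolerance_ppm,
) -> float:
    """Original aqueous CH4 concentration (mg l^-1) from one record.

    Mole balance: the methane originally dissolved ends up either in the
    headspace (``n_h = dx * P/(R T) * V_h``) or still dissolved at
    equilibrium (``n_d = H_cc * dx * P/(R T) * V_w``), with ``dx`` the
    background-corrected headspace mole fraction.

    Raises
    ------
    DataQualityError
        If the equilibrated reading falls below background by more than
        ``negative_tolerance_ppm`` (flagged, never silently clipped).
    """
    d_ppm = record.c_g_equilibrated - record.c_g_background
    if d_ppm < -negative_tolerance_ppm:
        raise DataQualityError(
            f"equilibrated headspace {record.c_g_equilibrated} ppm below "
            f"background {record.c_g_background} ppm beyond tolerance "
            f"{negative_tolerance_ppm} ppm"
        )
    d_ppm = max(d_ppm, 0.0)
    dx = d_ppm * 1e-6
    molar_density = record.pressure * ATM_PA / (R_GAS * record.temperature)  # mol m^-3
    v_h = record.headspace_volume * 1e-3  # m^3
    v_w = record.water_volume * 1e-3
    n_head = dx * molar_density * v_h
    n_diss = record.henry_cc * dx * molar_density * v_w
    grams = (n_head + n_diss) * molar_mass
    return grams * 1000.0 / record.water_volume  # mg per litre


def background_correct(
    readings_ppm, t0_ppm: float | None = None, negative_tolerance_ppm: float = 0.05
) -> np.ndarray:
    """Subtract the t = 0 background from a series of headspace readings.

    The corrected t = 0 value is exactly zero.  Negative corrected values
    are retained (they signal consumption) and flagged with a warning when
    they exceed the noise tolerance.

    Raises
    ------
    MissingBackgroundError
        If no t0 reading is supplied; callers should pass the configured
        ambient default instead.
    """
    if t0_ppm is None:
        raise MissingBackgroundError(
            "no t = 0 background reading; supply the configured ambient default"
        )
    readings = np.asarray(readings_ppm, dtype=float)
    corrected = readings - t0_ppm
    if np.any(corrected < -negative_tolerance_ppm):
        warnings.warn(
            "background exceeds later readings: negative corrected values "
            "retained (consumption signal)",
            stacklevel=2,
        )
    return corrected


def process_field_samples(
    df: pd.DataFrame, constants: PhysicalConstants = PhysicalConstants()
) -> pd.DataFrame:
    """Fill ``ch4_aq_mg_l`` in a ``field_samples.csv``-schema table.

    Rows that already carry a pre-computed ``ch4_aq_mg_l`` pass through
    unchanged; rows with headspace readings are converted with
    :func:`aqueous_from_headspace` at the row's temperature.
    """
    out = df.copy()
    if "ch4_aq_mg_l" not in out.columns:
        out["ch4_aq_mg_l"] = np.nan
    needs = out["ch4_aq_mg_l"].isna()
    for idx in out.index[needs]:
        row = out.loc[idx]
        if pd.isna(row.get("cg_eq_ppm")):
            continue
        rec = HeadspaceEquilibration(
            water_volume=row["water_volume_l"],
            headspace_volume=row["headspace_volume_l"],
            temperature=row["temp_K"],
            pressure=constants.pressure_atm,
            c_g_background=row["cg_t0_ppm"],
            c_g_equilibrated=row["cg_eq_ppm"],
            henry_cc=henry_cc_at(row["temp_K"], constants.henry_hcp0, constants.henry_b),
        )
        out.loc[idx, "ch4_aq_mg_l"] = aqueous_from_headspace(
            rec, constants.ch4_molar_mass, constants.negative_tolerance_ppm
        )
    return out
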