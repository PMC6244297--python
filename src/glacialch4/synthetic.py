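"""Synthetic field-campaign, incubation and chamber data with known truth.

Each generator is the measurable inverse of its analysis stage: at zero
noise the corresponding estimator recovers the configured ground truth
exactly, and every output carries provenance metadata (seed, config
hash) plus a ground-truth key.  The generators emulate

* the site x phase concentration structure of a melt-season campaign
  (log-normal concentrations — field ranges are strongly right-skewed),
* two-end-member isotope mixing followed by closed-system Rayleigh
  enrichment of the residual pool at configurable alpha,
* linear headspace production in sealed anoxic slurries and first-order
  (exponential) consumption in methane-amended oxic slurries — the
  simplest closed-vessel kinetics consistent with the Rayleigh
  formalism,
* linear static-chamber accumulation through the V/A relation.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import ATM_PA, R_GAS
from .isotopes import EndMember, IsotopePair, mixing_curve, rayleigh_residual
from .kinetics import ChamberSeries, IncubationSeries


def config_hash(cfg) -> str:
    """Short stable hash of a generator config, for provenance metadata."""
    return hashlib.md5(repr(cfg).encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# field campaign
# ---------------------------------------------------------------------------

_PHASE_DOY = {"pre_upwelling": 100, "early_post": 150, "late_post": 200}


@dataclass(frozen=True)
class SiteSpec:
    """Ground truth for one (site_class, year, phase) sampling group.

    ``conc_gsd`` is the geometric standard deviation of the log-normal
    concentration draw (1 = no dispersion); ``fraction_microbial`` sets
    the end-member mixture and ``f_remaining`` the residual methane
    fraction after oxidation.
    """

    site_class: str
    phase: str
    conc_mean_mg_l: float
    n: int
    year: int = 2014
    conc_gsd: float = 1.3
    fraction_microbial: float = 1.0
    f_remaining: float = 1.0
    day_of_year: int | None = None

    def __post_init__(self) -> None:
        if self.conc_mean_mg_l < 0 or self.conc_gsd < 1.0:
            raise ValueError("need mean >= 0 and geometric sd >= 1")
        if not (0.0 <= self.fraction_microbial <= 1.0):
            raise ValueError("fraction_microbial must lie in [0, 1]")
        if not (0.0 < self.f_remaining <= 1.0):
            raise ValueError("f_remaining must lie in (0, 1]")
        if self.n < 1:
            raise ValueError("need n >= 1")


@dataclass(frozen=True)
class CampaignConfig:
    """Full ground truth for a synthetic field campaign."""

    sites: tuple
    end_microbial: EndMember = EndMember(IsotopePair(-80.0, -350.0), 17.0)
    end_geogenic: EndMember = EndMember(IsotopePair(-35.0, -100.0), 1.0)
    alpha_c: float = 1.019
    alpha_d: float = 1.197
    conc_noise_rel: float = 0.02
    isotope_noise_permil: float = 0.5
    seed: int = 0


def gen_field_campaign(cfg: CampaignConfig):
    """Draw a campaign sample table plus its ground-truth key.

    Returns ``(samples, truth)`` dataframes.  ``samples`` follows the
    standard field-sample schema; ``truth`` holds one row per site group
    with the configured parameters, the noiseless isotope signature and
    provenance metadata.
    """
    rng = np.random.default_rng(cfg.seed)
    h = config_hash(cfg)
    sample_rows, truth_rows = [], []
    counter = 0
    for spec in cfg.sites:
        base = mixing_curve(cfg.end_microbial, cfg.end_geogenic, spec.fraction_microbial)
        expected = IsotopePair(
            rayleigh_residual(base.delta13c, cfg.alpha_c, spec.f_remaining),
            rayleigh_residual(base.deltad, cfg.alpha_d, spec.f_remaining),
        )
        doy = spec.day_of_year if spec.day_of_year is not None else _PHASE_DOY[spec.phase]
        sdlog = np.log(spec.conc_gsd)
        for _ in range(spec.n):
            counter += 1
            if sdlog > 0 and spec.conc_mean_mg_l > 0:
                mu = np.log(spec.conc_mean_mg_l) - 0.5 * sdlog**2
                conc = float(rng.lognormal(mu, sdlog))
            else:
                conc = spec.conc_mean_mg_l
            conc = max(conc * (1.0 + cfg.conc_noise_rel * rng.standard_normal()), 0.0)
            d13c = expected.delta13c + cfg.isotope_noise_permil * rng.standard_normal()
            dd = expected.deltad + cfg.isotope_noise_permil * rng.standard_normal()
            sample_rows.append(
                {
                    "sample_id": f"syn{counter:04d}",
                    "site_class": spec.site_class,
                    "campaign_year": spec.year,
                    "day_of_year": doy,
                    "phase": spec.phase,
                    "ch4_aq_mg_l": conc,
                    "d13C_permil": d13c,
                    "dD_permil": dd,
                }
            )
        truth_rows.append(
            {
                "site_class": spec.site_class,
                "year": spec.year,
                "phase": spec.phase,
                "conc_mean_mg_l": spec.conc_mean_mg_l,
                "conc_gsd": spec.conc_gsd,
                "fraction_microbial": spec.fraction_microbial,
                "f_remaining": spec.f_remaining,
                "d13C_true": expected.delta13c,
                "dD_true": expected.deltad,
                "n": spec.n,
                "seed": cfg.seed,
                "config_hash": h,
            }
        )
    return pd.DataFrame(sample_rows), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# incubations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IncubationConfig:
    """Ground truth for one set of replicate incubations.

    ``rate_fmol_g_h`` is the signed turnover potential (negative for
    methanotrophic consumption).  Concentration noise is Gaussian with
    sigma = ``conc_noise_frac_of_range`` x the noiseless signal range;
    isotope noise is additive in permil.
    """

    condition: str
    rate_fmol_g_h: float
    times_h: tuple
    initial_ch4_ppm: float = 1.9
    alpha_c: float = 1.019
    alpha_d: float = 1.197
    initial_isotopes: IsotopePair = IsotopePair(-60.0, -320.0)
    fresh_mass_g: float = 10.0
    dry_mass_g: float = 8.0
    water_ml: float = 20.0
    headspace_ml: float = 80.0
    temperature_c: float = 15.0
    pressure_atm: float = 1.0
    conc_noise_frac_of_range: float = 0.0
    isotope_noise_permil: float = 0.0
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.condition == "methanotrophic_oxic" and self.rate_fmol_g_h >= 0:
            raise ValueError("methanotrophic series need a negative true rate")
        if len(self.times_h) < 2:
            raise ValueError("need at least 2 timepoints")


def _moles_per_fraction(cfg: IncubationConfig) -> float:
    return (
        cfg.pressure_atm
        * ATM_PA
        * (cfg.headspace_ml * 1e-6)
        / (R_GAS * (cfg.temperature_c + 273.15))
    )


def rate_to_slope_ppm_h(cfg: IncubationConfig) -> float:
    """Headspace ppm h^-1 equivalent of the configured mass-specific rate."""
    rate_mol_h = cfg.rate_fmol_g_h * 1e-15 * cfg.dry_mass_g
    return rate_mol_h / _moles_per_fraction(cfg) * 1e6


def consumption_constant(cfg: IncubationConfig) -> float:
    """First-order constant k (h^-1) whose initial slope matches the rate."""
    return -rate_to_slope_ppm_h(cfg) / cfg.initial_ch4_ppm


def times_for_fractions(cfg: IncubationConfig, f_targets) -> tuple:
    """Sampling times (h) at which the pool reaches the given fractions."""
    k = consumption_constant(cfg)
    if k <= 0:
        raise ValueError("only defined for consuming (methanotrophic) configs")
    return tuple(float(-np.log(f) / k) for f in f_targets)


def gen_incubation(cfg: IncubationConfig):
    """Replicate incubation series plus a ground-truth key.

    Anoxic (and control) series rise linearly at the configured rate;
    methanotrophic series decay exponentially with the matching initial
    slope, and their residual-pool isotopes follow the Rayleigh model at
    each timepoint's ``f = C(t)/C(0)``.

    Returns ``(series_list, truth)`` where ``truth`` maps parameter
    names to configured values plus provenance metadata.
    """
    rng = np.random.default_rng(cfg.seed)
    t = np.asarray(cfg.times_h, dtype=float)
    if cfg.condition == "methanotrophic_oxic":
        k = consumption_constant(cfg)
        clean = cfg.initial_ch4_ppm * np.exp(-k * t)
    else:
        slope = rate_to_slope_ppm_h(cfg) if cfg.condition != "control_blank" else 0.0
        clean = cfg.initial_ch4_ppm + slope * t
    sigma = cfg.conc_noise_frac_of_range * float(np.ptp(clean))
    series = []
    for rep in range(cfg.n_replicates):
        ppm = clean + sigma * rng.standard_normal(t.size)
        kwargs = dict(
            series_id=f"{cfg.condition}_{rep + 1:02d}",
            condition=cfg.condition,
            temperature_c=cfg.temperature_c,
            sediment_fresh_mass=0.0 if cfg.condition == "control_blank" else cfg.fresh_mass_g,
            sediment_dry_mass=0.0 if cfg.condition == "control_blank" else cfg.dry_mass_g,
            slurry_water_volume=cfg.water_ml,
            headspace_volume=cfg.headspace_ml,
            initial_ch4=cfg.initial_ch4_ppm,
            times_h=t.tolist(),
            ch4_ppm=ppm.tolist(),
        )
        if cfg.condition == "methanotrophic_oxic":
            f = clean / cfg.initial_ch4_ppm
            d13c = np.array(
                [rayleigh_residual(cfg.initial_isotopes.delta13c, cfg.alpha_c, fi) for fi in f]
            )
            dd = np.array(
                [rayleigh_residual(cfg.initial_isotopes.deltad, cfg.alpha_d, fi) for fi in f]
            )
            kwargs["d13c_permil"] = (
                d13c + cfg.isotope_noise_permil * rng.standard_normal(t.size)
            ).tolist()
            kwargs["dd_permil"] = (
                dd + cfg.isotope_noise_permil * rng.standard_normal(t.size)
            ).tolist()
        series.append(IncubationSeries(**kwargs))
    truth = {
        "condition": cfg.condition,
        "rate_fmol_g_h": cfg.rate_fmol_g_h,
        "alpha_c": cfg.alpha_c,
        "alpha_d": cfg.alpha_d,
        "slope_ppm_h": rate_to_slope_ppm_h(cfg),
        "seed": cfg.seed,
        "config_hash": config_hash(cfg),
    }
    return series, truth


def control_blank_for(cfg: IncubationConfig) -> IncubationSeries:
    """Sediment-free control matching a config's headspace conditions."""
    blank_cfg = replace(
        cfg,
        condition="control_blank",
        rate_fmol_g_h=0.0,
        conc_noise_frac_of_range=0.0,
        isotope_noise_permil=0.0,
        n_replicates=1,
    )
    return gen_incubation(blank_cfg)[0][0]


def methanogenic_defaults(seed: int = 0, **overrides) -> IncubationConfig:
    """Anoxic production assay: weekly sampling over a 49-day incubation."""
    kwargs = dict(
        condition="methanogenic_anoxic",
        rate_fmol_g_h=1.15e7,
        times_h=tuple(float(x) for x in np.linspace(0.0, 49 * 24.0, 8)),
        initial_ch4_ppm=1.9,
        conc_noise_frac_of_range=0.02,
        seed=seed,
    )
    kwargs.update(overrides)
    return IncubationConfig(**kwargs)


def methanotrophic_rate_defaults(seed: int = 0, **overrides) -> IncubationConfig:
    """Oxic consumption assay sampled within the near-linear initial window.

    The 150-ppm amended pool is followed over its first 4% of
    consumption so the linear estimator sees first-order decay in its
    linear regime.
    """
    base = IncubationConfig(
        condition="methanotrophic_oxic",
        rate_fmol_g_h=-9.6e9,
        times_h=(0.0, 1.0),
        initial_ch4_ppm=150.0,
        seed=seed,
    )
    f_targets = np.linspace(1.0, 0.96, 8)
    kwargs = dict(
        condition="methanotrophic_oxic",
        rate_fmol_g_h=-9.6e9,
        times_h=times_for_fractions(base, f_targets),
        initial_ch4_ppm=150.0,
        conc_noise_frac_of_range=0.02,
        seed=seed,
    )
    kwargs.update(overrides)
    return IncubationConfig(**kwargs)


def methanotrophic_isotope_defaults(seed: int = 0, **overrides) -> IncubationConfig:
    """Oxic assay sampled deep into consumption for Rayleigh alpha fitting."""
    base = IncubationConfig(
        condition="methanotrophic_oxic",
        rate_fmol_g_h=-9.6e9,
        times_h=(0.0, 1.0),
        initial_ch4_ppm=150.0,
        seed=seed,
    )
    f_targets = np.geomspace(0.9, 0.2, 8)
    kwargs = dict(
        condition="methanotrophic_oxic",
        rate_fmol_g_h=-9.6e9,
        times_h=times_for_fractions(base, f_targets),
        initial_ch4_ppm=150.0,
        isotope_noise_permil=0.5,
        seed=seed,
    )
    kwargs.update(overrides)
    return IncubationConfig(**kwargs)


# ---------------------------------------------------------------------------
# chambers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChamberConfig:
    """Ground truth for replicate static-chamber deployments."""

    flux_umol_m2_day: float
    diameter_m: float = 0.15
    height_m: float = 0.10
    temperature_c: float = 10.0
    times_min: tuple = (0.0, 15.0, 30.0, 45.0)
    initial_ppm: float = 1.9
    pressure_atm: float = 1.0
    conc_noise_frac_of_range: float = 0.0
    n_chambers: int = 3
    seed: int = 0


def gen_chamber(cfg: ChamberConfig):
    """Replicate chamber series plus a ground-truth key.

    The ppm slope follows from the true areal flux through the chamber
    V/A relation (= height) and the molar gas density at the deployment
    temperature; noise is Gaussian on the ppm readings.
    """
    rng = np.random.default_rng(cfg.seed)
    molar_density = cfg.pressure_atm * ATM_PA / (R_GAS * (cfg.temperature_c + 273.15))
    slope_ppm_min = cfg.flux_umol_m2_day / (molar_density * cfg.height_m * 1440.0)
    t = np.asarray(cfg.times_min, dtype=float)
    clean = cfg.initial_ppm + slope_ppm_min * t
    sigma = cfg.conc_noise_frac_of_range * float(np.ptp(clean))
    series = [
        ChamberSeries(
            chamber_id=f"chamber_{i + 1:02d}",
            diameter=cfg.diameter_m,
            height=cfg.height_m,
            temperature_c=cfg.temperature_c,
            times_min=t.tolist(),
            ch4_ppm=(clean + sigma * rng.standard_normal(t.size)).tolist(),
        )
        for i in range(cfg.n_chambers)
    ]
    truth = {
        "flux_umol_m2_day": cfg.flux_umol_m2_day,
        "slope_ppm_min": slope_ppm_min,
        "seed": cfg.seed,
        "config_hash": config_hash(cfg),
    }
    return series, truth
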