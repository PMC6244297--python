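"""Site x phase summaries of field water samples.

Groups samples by sampling-site class, campaign year and melt-season
phase and reports mean, range and n for aqueous CH4 and the two isotope
systems — the layout field campaigns tabulate.  Phase is assigned from
day-of-year breakpoints around the onset of subglacial upwelling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PhaseBreakpoints
from .isotopes import IsotopePair

log = logging.getLogger(__name__)

SITE_CLASSES = (
    "supraglacial",
    "subglacial_upwelling",
    "meltwater_outlet",
    "proglacial_lake_east",
    "proglacial_lake_west",
    "catchment_outlet",
    "external_control",
)
PHASES = ("pre_upwelling", "early_post", "late_post")

#: Summary variables and their sample-table columns.
_VARIABLES = {
    "ch4_aq_mg_l": "ch4_aq_mg_l",
    "d13C_permil": "d13C_permil",
    "dD_permil": "dD_permil",
}


@dataclass
class WaterSample:
    """One field water measurement."""

    sample_id: str
    site_class: str
    campaign_year: int
    day_of_year: int
    ch4_aq: float  # mg l^-1
    phase: str | None = None
    isotopes: IsotopePair | None = None

    def __post_init__(self) -> None:
        if self.site_class not in SITE_CLASSES:
            raise ValueError(f"unknown site class {self.site_class!r}")
        if not (1 <= self.day_of_year <= 366):
            raise ValueError("day_of_year must lie in 1..366")
        if self.ch4_aq < 0:
            raise ValueError("aqueous CH4 must be non-negative")
        if self.phase is not None and self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")


def assign_phase(
    day_of_year: int, breakpoints: PhaseBreakpoints = PhaseBreakpoints()
) -> str:
    """Melt-season phase from day of year.

    Up to and including the first breakpoint -> ``pre_upwelling``;
    strictly between the breakpoints -> ``early_post``; from the second
    breakpoint onwards -> ``late_post``.
    """
    if not (1 <= day_of_year <= 366):
        raise ValueError("day_of_year must lie in 1..366")
    if day_of_year <= breakpoints.b1:
        return "pre_upwelling"
    if day_of_year < breakpoints.b2:
        return "early_post"
    return "late_post"


def samples_to_frame(samples) -> pd.DataFrame:
    """Convert :class:`WaterSample` records to the standard long table."""
    rows = []
    for s in samples:
        rows.append(
            {
                "sample_id": s.sample_id,
                "site_class": s.site_class,
                "campaign_year": s.campaign_year,
                "day_of_year": s.day_of_year,
                "phase": s.phase,
                "ch4_aq_mg_l": s.ch4_aq,
                "d13C_permil": s.isotopes.delta13c if s.isotopes else np.nan,
                "dD_permil": s.isotopes.deltad if s.isotopes else np.nan,
            }
        )
    return pd.DataFrame(rows)


def summarize(
    samples: pd.DataFrame, breakpoints: PhaseBreakpoints = PhaseBreakpoints()
) -> pd.DataFrame:
    """Per (site_class, year, phase) mean / min / max / n, long format.

    ``n`` counts non-missing values per variable independently, so
    samples lacking isotope readings still contribute to the
    concentration count.  Empty groups are omitted.  Missing phases are
    derived from ``day_of_year`` via :func:`assign_phase`.
    """
    df = samples.copy()
    if df.empty:
        return pd.DataFrame(
            columns=["site_class", "year", "phase", "variable", "mean", "min", "max", "n"]
        )
    if "phase" not in df.columns:
        df["phase"] = None
    missing_phase = df["phase"].isna()
    if missing_phase.any():
        df.loc[missing_phase, "phase"] = df.loc[missing_phase, "day_of_year"].map(
            lambda d: assign_phase(int(d), breakpoints)
        )
    rows = []
    for (site, year, phase), grp in df.groupby(
        ["site_class", "campaign_year", "phase"], sort=True
    ):
        for var, col in _VARIABLES.items():
            if col not in grp.columns:
                continue
            vals = grp[col].dropna()
            if vals.empty:
                continue
            rows.append(
                {
                    "site_class": site,
                    "year": int(year),
                    "phase": phase,
                    "variable": var,
                    "mean": float(vals.mean()),
                    "min": float(vals.min()),
                    "max": float(vals.max()),
                    "n": int(vals.size),
                }
            )
    return pd.DataFrame(rows)


def group_mean(
    summary: pd.DataFrame, site_class: str, phases, variable: str = "ch4_aq_mg_l"
) -> pd.Series:
    """Per-(year, phase) means of one variable at one site class."""
    sel = summary[
        (summary["site_class"] == site_class)
        & summary["phase"].isin(list(phases))
        & (summary["variable"] == variable)
    ]
    return sel.set_index(["year", "phase"])["mean"]
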