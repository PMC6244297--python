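"""Closed-system Rayleigh fractionation, dual-isotope mixing and source
classification of methane in delta13C-deltaD space.

The central model is closed-system Rayleigh distillation of a finite
methane pool consumed by methanotrophy.  With ``f`` the fraction of
methane remaining and ``alpha`` the kinetic fractionation factor, the
residual pool evolves as

    delta_t = (delta_i + 1000) * f**(1/alpha - 1) - 1000

equivalently

    alpha = [ ln((delta_t + 1000)/(delta_i + 1000)) / ln f + 1 ]^-1

``alpha > 1`` means the consuming process prefers the light
isotopologue, so the residual pool becomes enriched (heavier) as the
reaction proceeds.  Methanotrophic consumption enriches residual CH4 in
both 13C and D, tracing a characteristic trajectory in delta13C-deltaD
space that distinguishes oxidation-affected samples from simple mixtures
of biogenic and geogenic end members.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from shapely.geometry import LineString, Point, Polygon

from .config import IsotopeConfig
from .errors import AmbiguityError, InconsistencyError

_DELTA_FLOOR = -1000.0


def _check_delta(*deltas: float) -> None:
    for d in deltas:
        if d <= _DELTA_FLOOR:
            raise ValueError(f"delta value {d} permil at or below the -1000 bound")


@dataclass(frozen=True)
class IsotopePair:
    """A (delta13C vs VPDB, deltaD vs VSMOW) pair in permil."""

    delta13c: float
    deltad: float

    def __post_init__(self) -> None:
        _check_delta(self.delta13c, self.deltad)


@dataclass(frozen=True)
class RayleighState:
    """One isotope system's (delta_i, delta_t, f, alpha) quadruple."""

    delta_initial: float
    delta_residual: float
    f: float
    alpha: float

    def __post_init__(self) -> None:
        _check_delta(self.delta_initial, self.delta_residual)
        if not (0.0 < self.f <= 1.0):
            raise ValueError("f must lie in (0, 1]")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.f == 1.0 and self.delta_residual != self.delta_initial:
            raise InconsistencyError("at f = 1 the residual equals the initial")


def delta_to_ratio(delta: float, standard_ratio: float) -> float:
    """Absolute isotope ratio from a delta value: R = (delta/1000 + 1) R_std."""
    if standard_ratio <= 0:
        raise ValueError("standard ratio must be positive")
    if delta < _DELTA_FLOOR:
        raise ValueError("delta below the -1000 permil bound")
    return (delta / 1000.0 + 1.0) * standard_ratio


def ratio_to_delta(ratio: float, standard_ratio: float) -> float:
    """Inverse of :func:`delta_to_ratio` (exact)."""
    if standard_ratio <= 0:
        raise ValueError("standard ratio must be positive")
    return (ratio / standard_ratio - 1.0) * 1000.0


def rayleigh_alpha(delta_initial: float, delta_residual: float, f: float) -> float:
    """Fractionation factor from an initial/residual pair at known ``f``.

    Raises
    ------
    ValueError
        If ``f`` is outside (0, 1); ``f = 1`` is undefined (ln 1 = 0).
    """
    _check_delta(delta_initial, delta_residual)
    if not (0.0 < f < 1.0):
        raise ValueError("f must lie strictly in (0, 1); alpha undefined at f = 1")
    num = math.log((delta_residual + 1000.0) / (delta_initial + 1000.0))
    return 1.0 / (num / math.log(f) + 1.0)


def rayleigh_residual(delta_initial: float, alpha: float, f: float) -> float:
    """Residual-pool delta after consuming to fraction ``f`` at ``alpha``."""
    _check_delta(delta_initial)
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if not (0.0 < f <= 1.0):
        raise ValueError("f must lie in (0, 1]")
    return (delta_initial + 1000.0) * f ** (1.0 / alpha - 1.0) - 1000.0


def fraction_remaining(delta_initial: float, delta_residual: float, alpha: float) -> float:
    """Fraction of methane remaining implied by the observed enrichment.

    Returns values > 1 (flagged with a warning) when the inputs are
    inconsistent with consumption at the given ``alpha``.
    """
    _check_delta(delta_initial, delta_residual)
    if alpha == 1.0:
        if delta_residual == delta_initial:
            return 1.0
        raise InconsistencyError("alpha = 1 cannot produce enrichment")
    f = math.exp(
        math.log((delta_residual + 1000.0) / (delta_initial + 1000.0))
        / (1.0 / alpha - 1.0)
    )
    if f > 1.0:
        warnings.warn(
            "computed f > 1: observations inconsistent with consumption",
            stacklevel=2,
        )
    return f


@dataclass
class AlphaFit:
    """Fitted fractionation factor with its standard error."""

    alpha: float
    stderr: float
    slope: float
    n: int


def fit_alpha_series(
    f_values, delta_residuals, delta_initial: float, method: str = "regression"
) -> AlphaFit:
    """Estimate alpha from a residual-pool series at known fractions.

    ``method="regression"`` (default) fits the slope ``m`` of
    ``ln((delta_t + 1000)/(delta_i + 1000))`` on ``ln f`` through the
    origin — the linear form the Rayleigh model implies — and returns
    ``alpha = 1/(m + 1)``.  ``method="pointwise"`` averages the
    closed-form per-point alphas instead (comparison option).  A single
    observation falls back to the closed form.

    Raises
    ------
    ValueError
        If no observation has ``f < 1`` (no information on alpha).
    """
    f = np.asarray(f_values, dtype=float)
    d = np.asarray(delta_residuals, dtype=float)
    if f.shape != d.shape:
        raise ValueError("f and delta arrays must align")
    informative = f < 1.0
    if not np.any(informative):
        raise ValueError("all f = 1: series carries no information on alpha")
    f, d = f[informative], d[informative]
    if np.any(f <= 0):
        raise ValueError("f must be positive")
    _check_delta(delta_initial, *d.tolist())
    if f.size == 1:
        return AlphaFit(
            alpha=rayleigh_alpha(delta_initial, float(d[0]), float(f[0])),
            stderr=math.nan,
            slope=math.nan,
            n=1,
        )
    x = np.log(f)
    y = np.log((d + 1000.0) / (delta_initial + 1000.0))
    if method == "pointwise":
        alphas = 1.0 / (y / x + 1.0)
        return AlphaFit(
            alpha=float(np.mean(alphas)),
            stderr=float(np.std(alphas, ddof=1) / math.sqrt(alphas.size)),
            slope=math.nan,
            n=int(f.size),
        )
    if method != "regression":
        raise ValueError(f"unknown method {method!r}")
    sxx = float(np.dot(x, x))
    m = float(np.dot(x, y)) / sxx
    resid = y - m * x
    sigma2 = float(np.dot(resid, resid)) / max(f.size - 1, 1)
    se_m = math.sqrt(sigma2 / sxx)
    alpha = 1.0 / (m + 1.0)
    return AlphaFit(
        alpha=alpha,
        stderr=se_m / (m + 1.0) ** 2,  # delta method
        slope=m,
        n=int(f.size),
    )


@dataclass(frozen=True)
class EndMember:
    """A source end member: isotopic signature plus CH4 concentration."""

    isotopes: IsotopePair
    concentration: float

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError("end-member concentration must be positive")


def mixing_curve(
    end_a: EndMember,
    end_b: EndMember,
    fraction_a: float,
    config: IsotopeConfig = IsotopeConfig(),
) -> IsotopePair:
    """Concentration-weighted two-end-member isotope mixture.

    ``fraction_a`` is the water-volume fraction contributed by end member
    ``a``; each end member's methane contribution is weighted by its
    concentration.  Deltas are converted to absolute ratios with the
    configured standard ratios, mass-weighted, and converted back.  With
    equal end-member concentrations this is linear interpolation in delta.
    """
    if not (0.0 <= fraction_a <= 1.0):
        raise ValueError("fraction_a must lie in [0, 1]")
    wa = fraction_a * end_a.concentration
    wb = (1.0 - fraction_a) * end_b.concentration
    total = wa + wb
    out = []
    for attr, r_std in (("delta13c", config.r_vpdb), ("deltad", config.r_vsmow)):
        ra = delta_to_ratio(getattr(end_a.isotopes, attr), r_std)
        rb = delta_to_ratio(getattr(end_b.isotopes, attr), r_std)
        out.append(ratio_to_delta((wa * ra + wb * rb) / total, r_std))
    return IsotopePair(delta13c=out[0], deltad=out[1])


@dataclass(frozen=True)
class SourceField:
    """A named source field: simple polygon in (delta13C, deltaD) space."""

    name: str
    polygon: tuple

    def __post_init__(self) -> None:
        if len(self.polygon) < 3:
            raise ValueError("polygon needs at least 3 vertices")
        if not self.shape.is_valid:
            raise ValueError("polygon must be simple (non-self-intersecting)")

    @property
    def shape(self) -> Polygon:
        return Polygon(self.polygon)

    def contains(self, sample: IsotopePair) -> bool:
        """Point-in-polygon; a point exactly on an edge counts as inside."""
        return self.shape.covers(Point(sample.delta13c, sample.deltad))

    def centroid(self) -> IsotopePair:
        c = self.shape.centroid
        return IsotopePair(delta13c=c.x, deltad=c.y)


def default_source_fields(config: IsotopeConfig = IsotopeConfig()):
    return (
        SourceField("microbial", tuple(map(tuple, config.microbial_polygon))),
        SourceField("geogenic", tuple(map(tuple, config.geogenic_polygon))),
    )


def trajectory(
    start: IsotopePair, alpha_c: float, alpha_d: float, f_values
) -> list[IsotopePair]:
    """Rayleigh enrichment trajectory in dual-isotope space.

    Applies :func:`rayleigh_residual` independently to each isotope
    system at each ``f``.  Near the start the slope d(deltaD)/d(delta13C)
    is ``[(deltaD+1000)(1/alpha_D - 1)] / [(delta13C+1000)(1/alpha_C - 1)]``.
    """
    f = np.asarray(f_values, dtype=float)
    if np.any((f <= 0) | (f > 1)):
        raise ValueError("f values must lie in (0, 1]")
    if f.size > 1 and np.any(np.diff(f) >= 0):
        raise ValueError("f values must be strictly decreasing")
    return [
        IsotopePair(
            delta13c=rayleigh_residual(start.delta13c, alpha_c, fi),
            deltad=rayleigh_residual(start.deltad, alpha_d, fi),
        )
        for fi in f
    ]


def classify_source(
    sample: IsotopePair,
    fields=None,
    trajectory_alphas: tuple[float, float] | None = None,
    config: IsotopeConfig = IsotopeConfig(),
) -> str:
    """Label a sample microbial / geogenic / mixed / oxidation_affected /
    indeterminate from its position in delta13C-deltaD space.

    Decision sequence:

    1. inside exactly one source polygon -> that source's label;
       inside both -> :class:`AmbiguityError`;
    2. within ``config.mixing_tolerance_permil`` (Euclidean, permil) of
       the mixing segment joining the two field centroids -> ``mixed``;
    3. enriched beyond the geogenic field's upper bounds and within
       ``config.oxidation_tolerance_permil`` of the Rayleigh trajectory
       anchored at the microbial centroid (alphas from
       ``trajectory_alphas`` or the config defaults) ->
       ``oxidation_affected``;
    4. otherwise ``indeterminate``.
    """
    if fields is None:
        fields = default_source_fields(config)
    if trajectory_alphas is None:
        trajectory_alphas = (config.trajectory_alpha_c, config.trajectory_alpha_d)
    if not (math.isfinite(sample.delta13c) and math.isfinite(sample.deltad)):
        raise ValueError("sample isotopes must be finite")
    by_name = {fld.name: fld for fld in fields}
    if set(by_name) != {"microbial", "geogenic"}:
        raise ValueError("need exactly a microbial and a geogenic field")

    inside = [fld for fld in fields if fld.contains(sample)]
    if len(inside) > 1:
        raise AmbiguityError("sample lies inside overlapping source fields")
    if len(inside) == 1:
        return inside[0].name

    pt = Point(sample.delta13c, sample.deltad)
    mic_c = by_name["microbial"].centroid()
    geo_c = by_name["geogenic"].centroid()
    segment = LineString(
        [(mic_c.delta13c, mic_c.deltad), (geo_c.delta13c, geo_c.deltad)]
    )
    if segment.distance(pt) <= config.mixing_tolerance_permil:
        return "mixed"

    alpha_c, alpha_d = trajectory_alphas
    geo_bounds = by_name["geogenic"].shape.bounds  # (minx, miny, maxx, maxy)
    beyond_geogenic = sample.delta13c > geo_bounds[2] or sample.deltad > geo_bounds[3]
    enriched = (
        sample.delta13c > mic_c.delta13c and sample.deltad > mic_c.deltad
    )
    if enriched and beyond_geogenic:
        fs = np.geomspace(1.0, 1e-4, 400)
        traj = trajectory(mic_c, alpha_c, alpha_d, fs[1:])
        line = LineString(
            [(mic_c.delta13c, mic_c.deltad)] + [(p.delta13c, p.deltad) for p in traj]
        )
        if line.distance(pt) <= config.oxidation_tolerance_permil:
            return "oxidation_affected"
    return "indeterminate"
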