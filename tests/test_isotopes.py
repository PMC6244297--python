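"""Rayleigh fractionation, mixing and dual-isotope source classification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glacialch4.config import IsotopeConfig
from glacialch4.errors import AmbiguityError, InconsistencyError
from glacialch4.isotopes import (
    EndMember,
    IsotopePair,
    RayleighState,
    SourceField,
    classify_source,
    default_source_fields,
    delta_to_ratio,
    fit_alpha_series,
    fraction_remaining,
    mixing_curve,
    ratio_to_delta,
    rayleigh_alpha,
    rayleigh_residual,
    trajectory,
)


class TestRayleighCore:
    def test_no_fractionation_alpha_is_one(self):
        assert rayleigh_alpha(-60.0, -60.0, 0.5) == pytest.approx(1.0, rel=1e-14)

    def test_residual_identity_at_f1_and_alpha1(self):
        assert rayleigh_residual(-60.0, 1.05, 1.0) == -60.0
        assert rayleigh_residual(-60.0, 1.0, 0.3) == pytest.approx(-60.0, abs=1e-12)

    def test_hand_evaluated_residual(self):
        # 940 * 0.5**(1/1.019 - 1) - 1000
        assert rayleigh_residual(-60.0, 1.019, 0.5) == pytest.approx(-47.77, abs=0.01)

    def test_alpha_roundtrip_ten_significant_figures(self):
        dt = rayleigh_residual(-60.0, 1.05, 0.5)
        assert rayleigh_alpha(-60.0, dt, 0.5) == pytest.approx(1.05, rel=1e-12)

    def test_enriched_residual_implies_alpha_above_one(self):
        assert rayleigh_alpha(-60.0, -40.0, 0.5) > 1.0

    @settings(derandomize=True, max_examples=300)
    @given(
        alpha=st.floats(1.001, 1.5),
        f=st.floats(0.01, 0.99),
        di=st.floats(-110.0, 0.0),
    )
    def test_roundtrip_property(self, alpha, f, di):
        dt = rayleigh_residual(di, alpha, f)
        assert rayleigh_alpha(di, dt, f) == pytest.approx(alpha, rel=1e-10)

    @pytest.mark.parametrize("f", [0.0, -0.5, 1.0, 1.5])
    def test_alpha_domain_errors(self, f):
        with pytest.raises(ValueError):
            rayleigh_alpha(-60.0, -50.0, f)

    def test_fraction_remaining_roundtrip(self):
        dt = rayleigh_residual(-60.0, 1.197, 0.3)
        assert fraction_remaining(-60.0, dt, 1.197) == pytest.approx(0.3, rel=1e-12)

    def test_fraction_remaining_trivial_and_monotone(self):
        assert fraction_remaining(-60.0, -60.0, 1.019) == pytest.approx(1.0)
        f_small = fraction_remaining(-60.0, -30.0, 1.019)
        f_large = fraction_remaining(-60.0, -50.0, 1.019)
        assert f_small < f_large

    def test_alpha_one_with_enrichment_inconsistent(self):
        with pytest.raises(InconsistencyError):
            fraction_remaining(-60.0, -40.0, 1.0)

    def test_f_above_one_flagged(self):
        with pytest.warns(UserWarning, match="f > 1"):
            f = fraction_remaining(-60.0, -70.0, 1.019)
        assert f > 1.0

    def test_rayleigh_state_invariants(self):
        with pytest.raises(InconsistencyError):
            RayleighState(-60.0, -50.0, 1.0, 1.019)
        with pytest.raises(ValueError):
            RayleighState(-60.0, -60.0, 0.0, 1.019)


class TestAlphaFit:
    def test_noiseless_series_exact(self):
        f = np.array([0.8, 0.6, 0.4, 0.2])
        dt = [rayleigh_residual(-60.0, 1.019, fi) for fi in f]
        fit = fit_alpha_series(f, dt, -60.0)
        assert fit.alpha == pytest.approx(1.019, rel=1e-12)

    def test_constant_deltas_give_alpha_one(self):
        fit = fit_alpha_series([0.8, 0.5, 0.2], [-60.0, -60.0, -60.0], -60.0)
        assert fit.alpha == pytest.approx(1.0, rel=1e-12)

    def test_single_observation_closed_form(self):
        dt = rayleigh_residual(-60.0, 1.1, 0.4)
        fit = fit_alpha_series([0.4], [dt], -60.0)
        assert fit.alpha == pytest.approx(1.1, rel=1e-12)
        assert fit.n == 1

    def test_noisy_recovery_within_uncertainty(self, rng):
        f = np.geomspace(0.9, 0.2, 8)
        dt = np.array([rayleigh_residual(-60.0, 1.019, fi) for fi in f])
        fit = fit_alpha_series(f, dt + rng.normal(0, 0.5, 8), -60.0)
        assert abs(fit.alpha - 1.019) < 3.0 * fit.stderr

    def test_pointwise_agrees_on_noiseless_data(self):
        f = np.array([0.7, 0.5, 0.3])
        dt = [rayleigh_residual(-50.0, 1.197, fi) for fi in f]
        fit = fit_alpha_series(f, dt, -50.0, method="pointwise")
        assert fit.alpha == pytest.approx(1.197, rel=1e-12)

    def test_all_f_one_no_information(self):
        with pytest.raises(ValueError, match="no information"):
            fit_alpha_series([1.0, 1.0], [-60.0, -60.0], -60.0)


class TestDeltaRatio:
    def test_zero_delta_is_standard(self):
        assert delta_to_ratio(0.0, 0.011180) == 0.011180

    def test_roundtrip_machine_precision(self):
        r = delta_to_ratio(-59.6, 0.011180)
        assert ratio_to_delta(r, 0.011180) == pytest.approx(-59.6, abs=1e-12)

    def test_lower_bound_maps_to_zero(self):
        assert delta_to_ratio(-1000.0, 1.5576e-4) == 0.0


class TestMixing:
    end_a = EndMember(IsotopePair(-60.0, -320.0), 10.0)
    end_b = EndMember(IsotopePair(-20.0, 100.0), 10.0)

    @pytest.mark.parametrize("frac,expect", [(1.0, "a"), (0.0, "b")])
    def test_endpoints_exact(self, frac, expect):
        out = mixing_curve(self.end_a, self.end_b, frac)
        ref = self.end_a.isotopes if expect == "a" else self.end_b.isotopes
        assert out.delta13c == pytest.approx(ref.delta13c, abs=1e-12)
        assert out.deltad == pytest.approx(ref.deltad, abs=1e-12)

    def test_equal_concentration_midpoint_matches_ratio_oracle(self):
        out = mixing_curve(self.end_a, self.end_b, 0.5)
        cfg = IsotopeConfig()
        # full ratio-space oracle, written out explicitly
        for attr, r_std, expect in (
            ("delta13c", cfg.r_vpdb, -40.0),
            ("deltad", cfg.r_vsmow, -110.0),
        ):
            ra = (getattr(self.end_a.isotopes, attr) / 1000 + 1) * r_std
            rb = (getattr(self.end_b.isotopes, attr) / 1000 + 1) * r_std
            oracle = ((ra + rb) / 2 / r_std - 1) * 1000
            assert getattr(out, attr) == pytest.approx(oracle, abs=1e-9)
            assert abs(getattr(out, attr) - expect) < 0.5

    def test_concentration_weighting_pulls_toward_richer_end(self):
        rich_a = EndMember(self.end_a.isotopes, 100.0)
        out = mixing_curve(rich_a, self.end_b, 0.5)
        assert out.delta13c < -55.0  # dominated by the concentrated end

    def test_fraction_out_of_range(self):
        with pytest.raises(ValueError):
            mixing_curve(self.end_a, self.end_b, 1.5)


class TestTrajectory:
    start = IsotopePair(-60.0, -324.0)

    def test_f1_returns_start(self):
        (pt,) = trajectory(self.start, 1.019, 1.197, [1.0])
        assert (pt.delta13c, pt.deltad) == (-60.0, -324.0)

    def test_near_start_slope_hand_value(self):
        # [(dD+1000)(1/aD-1)] / [(d13C+1000)(1/aC-1)] at the start point
        pts = trajectory(self.start, 1.019, 1.197, [1.0, 0.999])
        slope = (pts[1].deltad - pts[0].deltad) / (pts[1].delta13c - pts[0].delta13c)
        assert slope == pytest.approx(6.35, abs=0.01)

    def test_monotone_enrichment_in_both_systems(self):
        pts = trajectory(self.start, 1.019, 1.197, np.geomspace(1.0, 0.01, 20))
        d13 = [p.delta13c for p in pts]
        dd = [p.deltad for p in pts]
        assert all(np.diff(d13) > 0) and all(np.diff(dd) > 0)

    def test_collapses_to_start_as_alphas_approach_one(self):
        pts = trajectory(self.start, 1.0 + 1e-9, 1.0 + 1e-9, [0.5, 0.1])
        for p in pts:
            assert p.delta13c == pytest.approx(-60.0, abs=1e-4)
            assert p.deltad == pytest.approx(-324.0, abs=1e-4)

    def test_increasing_f_rejected(self):
        with pytest.raises(ValueError):
            trajectory(self.start, 1.019, 1.197, [0.5, 0.8])


class TestClassifySource:
    def test_subglacial_upwelling_mean_is_microbial(self, config):
        label = classify_source(IsotopePair(-59.6, -323.7), config=config.isotopes)
        assert label == "microbial"

    def test_geogenic_centroid_is_geogenic(self, config):
        fields = default_source_fields(config.isotopes)
        geo = next(f for f in fields if f.name == "geogenic").centroid()
        assert classify_source(geo, config=config.isotopes) == "geogenic"

    def test_point_on_edge_counts_inside(self, config):
        # on the microbial polygon boundary, away from the shared edge
        label = classify_source(IsotopePair(-110.0, -300.0), config=config.isotopes)
        assert label == "microbial"

    def test_point_near_mixing_segment_between_fields_is_mixed(self, config):
        # in the gap between the two fields, a few permil off the
        # centroid-to-centroid segment
        label = classify_source(IsotopePair(-52.0, -165.0), config=config.isotopes)
        assert label == "mixed"

    def test_enriched_outlet_mean_is_oxidation_affected(self, config):
        # pre-upwelling outlet mean sits on the enrichment side of both fields
        label = classify_source(IsotopePair(-22.5, 22.9), config=config.isotopes)
        assert label == "oxidation_affected"

    def test_far_off_trajectory_point_is_indeterminate(self, config):
        label = classify_source(IsotopePair(-5.0, -600.0), config=config.isotopes)
        assert label == "indeterminate"

    def test_invariant_under_vertex_rotation_and_reversal(self, config):
        base = default_source_fields(config.isotopes)
        mic = list(config.isotopes.microbial_polygon)
        geo = list(config.isotopes.geogenic_polygon)
        rotated = (
            SourceField("microbial", tuple(mic[2:] + mic[:2])),
            SourceField("geogenic", tuple(reversed(geo))),
        )
        for pair in (IsotopePair(-59.6, -323.7), IsotopePair(-22.5, 22.9),
                     IsotopePair(-35.0, -100.0)):
            assert classify_source(pair, rotated, config=config.isotopes) == \
                classify_source(pair, base, config=config.isotopes)

    def test_overlapping_fields_raise_ambiguity(self, config):
        square = ((-80.0, -300.0), (-80.0, -200.0), (-60.0, -200.0), (-60.0, -300.0))
        fields = (SourceField("microbial", square), SourceField("geogenic", square))
        with pytest.raises(AmbiguityError):
            classify_source(IsotopePair(-70.0, -250.0), fields,
                            config=config.isotopes)

    def test_delta_floor_enforced(self):
        with pytest.raises(ValueError):
            IsotopePair(-1000.0, 0.0)
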