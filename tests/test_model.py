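"""Unit and property tests for the closed-form radial-fracture model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ovfatigue import (
    CeramicMaterial,
    DomainError,
    LoadCase,
    LogBase,
    ModelConstants,
    VeneerGeometry,
    critical_load_at_cycles,
    critical_radial_load,
    crossover_thickness,
    cycles_to_failure,
    effective_modulus,
    failure_probability_before,
    foundation_interaction_exponent,
    normal_load,
    predict_lifetime,
)
from ovfatigue.model import band_parameters, required_strength
from ovfatigue.params import FoundationStack


class TestNormalLoad:
    @pytest.mark.parametrize(
        "F, theta, expected",
        [
            (49.0, 15.0, 47.33036548816435),  # the reference chewing load case
            (49.0, 0.0, 49.0),
            (100.0, 60.0, 50.0),
        ],
    )
    def test_cusp_incline_decomposition(self, F, theta, expected):
        load = LoadCase(applied_load_F=F, frequency_f=1.6)
        geo = VeneerGeometry(thickness_d=0.5, cusp_incline_theta=theta)
        assert normal_load(load, geo) == pytest.approx(expected, rel=1e-9)

    def test_never_exceeds_applied_load(self, load_case):
        for theta in np.linspace(0, 89, 20):
            geo = VeneerGeometry(thickness_d=0.5, cusp_incline_theta=float(theta))
            assert normal_load(load_case, geo) <= load_case.applied_load_F


class TestFoundationExponent:
    def test_reference_cement_layer(self, foundation, constants):
        # 40 um cement under a 0.5 mm veneer; frozen from hand evaluation
        geo = VeneerGeometry(thickness_d=0.5)
        L = foundation_interaction_exponent(foundation, geo, constants)
        assert L == pytest.approx(0.5866809128, rel=1e-8)

    def test_log_term_vanishes_when_h_equals_d(self, constants):
        fnd = FoundationStack(
            cement_modulus_Es=7.9, substrate_modulus_Ec=18.6, cement_thickness_h=0.3
        )
        geo = VeneerGeometry(thickness_d=0.3)
        L = foundation_interaction_exponent(fnd, geo, constants)
        assert L == pytest.approx(math.exp(-(1.18**3.13)), rel=1e-12)
        assert L == pytest.approx(0.1866037298, rel=1e-8)

    def test_bracket_nonpositive_is_domain_error(self, constants):
        # h/d small enough that alpha + beta*log10(h/d) <= 0
        fnd = FoundationStack(
            cement_modulus_Es=7.9, substrate_modulus_Ec=18.6, cement_thickness_h=1e-4
        )
        geo = VeneerGeometry(thickness_d=2.0)
        with pytest.raises(DomainError, match="h/d"):
            foundation_interaction_exponent(fnd, geo, constants)

    def test_within_valid_domain_L_in_unit_interval(self, foundation, constants):
        for d in np.linspace(0.1, 2.0, 50):
            L = foundation_interaction_exponent(
                foundation, VeneerGeometry(thickness_d=float(d)), constants
            )
            assert 0.0 < L < 1.0


class TestEffectiveModulus:
    @pytest.mark.parametrize(
        "L, expected",
        [(0.0, 18.6), (1.0, 7.9), (0.5866809128, 11.2547178661)],
    )
    def test_interpolates_between_substrate_and_cement(self, foundation, L, expected):
        assert effective_modulus(foundation, L) == pytest.approx(expected, rel=1e-8)

    def test_result_bounded_by_constituent_moduli(self, foundation):
        for L in np.linspace(0, 1, 21):
            E = effective_modulus(foundation, float(L))
            assert 7.9 <= E <= 18.6

    @pytest.mark.parametrize("L", [-0.1, 1.5])
    def test_exponent_outside_unit_interval_rejected(self, foundation, L):
        with pytest.raises(DomainError):
            effective_modulus(foundation, L)


class TestCriticalRadialLoad:
    ESTAR_05 = 11.254717866115262  # effective modulus under a 0.5 mm veneer

    def test_zirconia_half_millimetre(self, zirconia, constants):
        geo = VeneerGeometry(thickness_d=0.5)
        FnR = critical_radial_load(zirconia, geo, self.ESTAR_05, constants)
        assert FnR == pytest.approx(109.1464095, rel=1e-7)

    def test_lithium_disilicate_half_millimetre(self, lithium_disilicate, constants):
        geo = VeneerGeometry(thickness_d=0.5)
        FnR = critical_radial_load(lithium_disilicate, geo, self.ESTAR_05, constants)
        assert FnR == pytest.approx(168.3148237, rel=1e-7)

    def test_quadratic_thickness_scaling(self, zirconia, constants):
        f1 = critical_radial_load(
            zirconia, VeneerGeometry(thickness_d=0.5), self.ESTAR_05, constants
        )
        f2 = critical_radial_load(
            zirconia, VeneerGeometry(thickness_d=1.0), self.ESTAR_05, constants
        )
        assert f2 == pytest.approx(4.0 * f1, rel=1e-12)

    def test_strength_override_scales_linearly(self, zirconia, constants):
        geo = VeneerGeometry(thickness_d=0.5)
        base = critical_radial_load(zirconia, geo, self.ESTAR_05, constants)
        halved = critical_radial_load(
            zirconia, geo, self.ESTAR_05, constants, strength_override=411.0 / 2
        )
        assert halved == pytest.approx(base / 2, rel=1e-12)

    def test_plate_softer_than_foundation_rejected(self, constants):
        soft = CeramicMaterial(
            name="soft",
            elastic_modulus_E=10.0,
            strength_mean=400.0,
            strength_sd=30.0,
            scg_exponent_mean=20.0,
            scg_exponent_lower=18.0,
        )
        with pytest.raises(DomainError, match="stiffer"):
            critical_radial_load(
                soft, VeneerGeometry(thickness_d=0.5), self.ESTAR_05, constants
            )

    def test_units_closure_si_rederivation(self, zirconia, constants):
        """Computing with sigma in Pa and d in m gives identical newtons to
        10 significant digits (sigma*d^2 is a force in both unit systems)."""
        geo = VeneerGeometry(thickness_d=0.5)
        FnR = critical_radial_load(zirconia, geo, self.ESTAR_05, constants)
        sigma_pa = 411.0e6
        d_m = 0.5e-3
        # the stiffness ratio is dimensionless, so the log term is unchanged
        si = 1.35 * sigma_pa * d_m**2 / math.log10(1.0 * 210.0 / self.ESTAR_05)
        assert si == pytest.approx(FnR, rel=1e-10)


class TestCyclesToFailure:
    def test_unit_load_ratio_gives_one_reference_period(self, load_case):
        log10_n = cycles_to_failure(47.33, 47.33, 25.0, load_case)
        assert log10_n == pytest.approx(math.log10(1.6), abs=1e-12)

    def test_strictly_decreasing_in_applied_load(self, load_case):
        vals = [cycles_to_failure(f, 100.0, 20.0, load_case) for f in (40, 60, 80)]
        assert vals[0] > vals[1] > vals[2]

    def test_strictly_increasing_in_scg_exponent_when_ratio_above_one(self, load_case):
        vals = [cycles_to_failure(47.0, 100.0, N, load_case) for N in (15, 20, 25)]
        assert vals[0] < vals[1] < vals[2]

    def test_below_first_cycle_signals_immediate_failure_unclamped(self, load_case):
        # applied above critical: lifetime below one loading period, not clamped
        log10_n = cycles_to_failure(100.0, 50.0, 20.0, load_case)
        assert log10_n < math.log10(1.6 * 1.0)


class TestCriticalLoadAtCycles:
    def test_reference_cycle_count_returns_initial_load(self, load_case):
        assert critical_load_at_cycles(109.1, 1.6, 25.0, load_case) == pytest.approx(
            109.1, rel=1e-12
        )

    def test_degraded_load_after_one_million_cycles(self, load_case):
        # zirconia 0.5 mm mean critical load degraded to the 10^6-cycle level
        F = critical_load_at_cycles(109.1464095, 1e6, 25.0, load_case)
        assert F == pytest.approx(63.9991569, rel=1e-6)

    @pytest.mark.parametrize("n", [1e2, 1e3, 1e6, 1e9, 1e12])
    def test_inverse_consistency_with_cycles_to_failure(self, load_case, n):
        F0 = 150.0
        Fn = critical_load_at_cycles(F0, n, 22.0, load_case)
        assert cycles_to_failure(Fn, F0, 22.0, load_case) == pytest.approx(
            math.log10(n), abs=1e-9
        )

    def test_strictly_decreasing_in_cycles(self, load_case):
        ns = np.logspace(1, 12, 30)
        vals = [critical_load_at_cycles(100.0, float(n), 20.0, load_case) for n in ns]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestPredictLifetime:
    def test_zirconia_half_mm_lower_band(self, zirconia, foundation, load_case, constants):
        """The conservative lower band (sigma-1SD, N_lower) puts the 0.5 mm
        zirconia lifetime near 3.4e5 cycles, inside the observed failure
        range of the chewing simulation."""
        geo = VeneerGeometry(thickness_d=0.5, cusp_incline_theta=15.0)
        pred = predict_lifetime(
            zirconia, geo, foundation, load_case, constants, band="lower"
        )
        assert pred.log10_cycles_to_failure == pytest.approx(5.5378512, rel=1e-6)
        assert pred.strength_sigma0 == 304.0
        assert pred.scg_exponent_N == 23.0
        assert 9.5e4 < 10**pred.log10_cycles_to_failure < 8.5e5

    def test_thick_zirconia_lower_band_outlives_protocol(
        self, zirconia, foundation, load_case, constants
    ):
        geo = VeneerGeometry(thickness_d=1.0, cusp_incline_theta=15.0)
        pred = predict_lifetime(
            zirconia, geo, foundation, load_case, constants, band="lower"
        )
        assert pred.log10_cycles_to_failure > math.log10(1.2e6)

    def test_fields_consistent_with_standalone_operations(
        self, zirconia, lithium_disilicate, foundation, load_case, constants
    ):
        rng = np.random.default_rng(42)
        for _ in range(20):
            material = (zirconia, lithium_disilicate)[int(rng.integers(2))]
            geo = VeneerGeometry(
                thickness_d=float(rng.uniform(0.3, 1.5)),
                cusp_incline_theta=float(rng.uniform(0, 30)),
            )
            band = ("mean", "lower")[int(rng.integers(2))]
            pred = predict_lifetime(
                material, geo, foundation, load_case, constants, band=band
            )
            Fn = normal_load(load_case, geo)
            L = foundation_interaction_exponent(foundation, geo, constants)
            Estar = effective_modulus(foundation, L)
            sigma0, N = band_parameters(material, band)
            FnR = critical_radial_load(material, geo, Estar, constants, sigma0)
            assert pred.normal_load_Fn == pytest.approx(Fn, rel=1e-12)
            assert pred.interaction_exponent_L == pytest.approx(L, rel=1e-12)
            assert pred.effective_modulus_Estar == pytest.approx(Estar, rel=1e-12)
            assert pred.critical_load_FnR == pytest.approx(FnR, rel=1e-12)
            assert pred.log10_cycles_to_failure == pytest.approx(
                cycles_to_failure(Fn, FnR, N, load_case), rel=1e-12
            )
            # 10^log10(n) == f * t_F
            assert 10**pred.log10_cycles_to_failure == pytest.approx(
                load_case.frequency_f * pred.time_to_fracture_tF, rel=1e-9
            )

    def test_lifetime_strictly_increasing_in_thickness(
        self, zirconia, lithium_disilicate, foundation, load_case, constants
    ):
        for material in (zirconia, lithium_disilicate):
            for band in ("mean", "lower"):
                grid = np.arange(0.3, 2.0 + 1e-9, 0.01)
                vals = [
                    predict_lifetime(
                        material,
                        VeneerGeometry(thickness_d=float(d), cusp_incline_theta=15.0),
                        foundation,
                        load_case,
                        constants,
                        band=band,
                    ).log10_cycles_to_failure
                    for d in grid
                ]
                assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_natural_log_convention_differs(self, zirconia, foundation, load_case):
        geo = VeneerGeometry(thickness_d=0.5, cusp_incline_theta=15.0)
        nat = predict_lifetime(
            zirconia,
            geo,
            foundation,
            load_case,
            ModelConstants(log_base=LogBase.natural),
            band="mean",
        )
        b10 = predict_lifetime(
            zirconia, geo, foundation, load_case, ModelConstants(), band="mean"
        )
        assert nat.log10_cycles_to_failure != pytest.approx(
            b10.log10_cycles_to_failure, rel=1e-3
        )

    def test_n_only_lower_band_policy(self, zirconia, foundation, load_case, constants):
        geo = VeneerGeometry(thickness_d=0.5, cusp_incline_theta=15.0)
        n_only = predict_lifetime(
            zirconia,
            geo,
            foundation,
            load_case,
            constants,
            band="lower",
            lower_strength_policy="n_only",
        )
        assert n_only.strength_sigma0 == 411.0
        default = predict_lifetime(
            zirconia, geo, foundation, load_case, constants, band="lower"
        )
        assert n_only.log10_cycles_to_failure > default.log10_cycles_to_failure


class TestCrossoverThickness:
    def test_zirconia_overtakes_lithium_disilicate(
        self, zirconia, lithium_disilicate, foundation, load_case, constants
    ):
        d_star = crossover_thickness(
            zirconia, lithium_disilicate, foundation, load_case, constants, band="mean"
        )
        assert 0.6 < d_star < 0.8
        # grid-scan oracle: last sign change on a 0.01 mm grid brackets the root
        grid = np.arange(0.3, 1.5 + 1e-9, 0.01)
        diffs = []
        for d in grid:
            geo = VeneerGeometry(thickness_d=float(d))
            a = predict_lifetime(
                zirconia, geo, foundation, load_case, constants, band="mean"
            ).log10_cycles_to_failure
            b = predict_lifetime(
                lithium_disilicate, geo, foundation, load_case, constants, band="mean"
            ).log10_cycles_to_failure
            diffs.append(a - b)
        signs = np.sign(diffs)
        (changes,) = np.nonzero(signs[:-1] * signs[1:] < 0)
        assert len(changes) == 1
        lo, hi = grid[changes[0]], grid[changes[0] + 1]
        assert lo <= d_star <= hi

    def test_identical_materials_rejected(self, zirconia, foundation, load_case, constants):
        with pytest.raises(DomainError):
            crossover_thickness(
                zirconia, zirconia, foundation, load_case, constants, band="mean"
            )

    def test_symmetric_in_argument_order(
        self, zirconia, lithium_disilicate, foundation, load_case, constants
    ):
        a = crossover_thickness(
            zirconia, lithium_disilicate, foundation, load_case, constants, band="mean"
        )
        b = crossover_thickness(
            lithium_disilicate, zirconia, foundation, load_case, constants, band="mean"
        )
        assert a == pytest.approx(b, abs=1e-4)


class TestFailureProbability:
    def test_median_specimen_fails_at_mean_strength_threshold(
        self, zirconia, foundation, load_case, constants, geometry_05
    ):
        # n_c chosen so the threshold strength equals the mean strength
        pred = predict_lifetime(
            zirconia, geometry_05, foundation, load_case, constants, band="mean"
        )
        n_c = 10**pred.log10_cycles_to_failure
        p = failure_probability_before(
            n_c, zirconia, geometry_05, foundation, load_case, constants, 25.0
        )
        assert p == pytest.approx(0.5, abs=1e-9)

    def test_vanishing_scatter_gives_step_probability(
        self, foundation, load_case, constants, geometry_05
    ):
        sharp = CeramicMaterial(
            name="sharp",
            elastic_modulus_E=210.0,
            strength_mean=411.0,
            strength_sd=1e-6,
            scg_exponent_mean=25.0,
            scg_exponent_lower=23.0,
        )
        p = failure_probability_before(
            1.2e6, sharp, geometry_05, foundation, load_case, constants, 25.0
        )
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_reference_configuration_close_to_one_in_six(
        self, zirconia, foundation, load_case, constants, geometry_05
    ):
        p = failure_probability_before(
            1.2e6, zirconia, geometry_05, foundation, load_case, constants, 25.0
        )
        assert p == pytest.approx(0.1636319, rel=1e-5)

    def test_monotone_nondecreasing_in_horizon(
        self, zirconia, foundation, load_case, constants, geometry_05
    ):
        horizons = np.logspace(2, 9, 15)
        ps = [
            failure_probability_before(
                float(n), zirconia, geometry_05, foundation, load_case, constants, 25.0
            )
            for n in horizons
        ]
        assert all(a <= b for a, b in zip(ps, ps[1:]))

    def test_required_strength_inverts_observed_failure(
        self, zirconia, foundation, load_case, constants, geometry_05
    ):
        # earliest observed Z-0.5 failure implies ~287 MPa at N_lower = 23
        sigma = required_strength(
            95_107, zirconia, geometry_05, foundation, load_case, constants, 23.0
        )
        assert sigma == pytest.approx(287.5, rel=2e-3)


# ---------------------------------------------------------------------------
# property-based invariants

_material_st = st.builds(
    CeramicMaterial,
    name=st.just("hyp"),
    elastic_modulus_E=st.floats(60, 300),
    strength_mean=st.floats(250, 900),
    strength_sd=st.floats(5, 80),
    scg_exponent_mean=st.floats(15, 30),
    scg_exponent_lower=st.floats(10, 15),
)


@settings(max_examples=60, derandomize=True)
@given(
    material=_material_st,
    d=st.floats(0.3, 2.0),
    h=st.floats(0.02, 0.1),
)
def test_lower_band_never_outlives_mean_band(material, d, h):
    """Reducing strength by one SD and N to its lower bound can only shorten
    the predicted lifetime whenever the lower-band critical load still
    exceeds the applied load."""
    foundation = FoundationStack(
        cement_modulus_Es=7.9, substrate_modulus_Ec=18.6, cement_thickness_h=h
    )
    load = LoadCase(applied_load_F=49.0, frequency_f=1.6)
    geo = VeneerGeometry(thickness_d=d, cusp_incline_theta=15.0)
    lower = predict_lifetime(material, geo, foundation, load, band="lower")
    mean = predict_lifetime(material, geo, foundation, load, band="mean")
    if lower.critical_load_FnR > lower.normal_load_Fn:
        assert lower.log10_cycles_to_failure <= mean.log10_cycles_to_failure


@settings(max_examples=40, derandomize=True)
@given(
    sigma_pa=st.floats(2e8, 9e8),
    d_mm=st.floats(0.3, 2.0),
    ratio=st.floats(2.0, 40.0),
)
def test_units_closure_property(sigma_pa, d_mm, ratio):
    """MPa·mm² and Pa·m² paths agree to 10 significant digits for the
    critical-load formula."""
    mat = CeramicMaterial(
        name="u",
        elastic_modulus_E=ratio * 11.25,
        strength_mean=sigma_pa / 1e6,
        strength_sd=1.0,
        scg_exponent_mean=20.0,
        scg_exponent_lower=18.0,
    )
    FnR = critical_radial_load(
        mat, VeneerGeometry(thickness_d=d_mm), 11.25, ModelConstants()
    )
    si = 1.35 * sigma_pa * (d_mm * 1e-3) ** 2 / math.log10(ratio)
    assert si == pytest.approx(FnR, rel=1e-10)
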