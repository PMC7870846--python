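import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mfapkit.equilibria import (
    BinaryBindingSystem,
    CompetitionSystem,
    IsothermFit,
    TernaryAllosterySystem,
    TitrationSeries,
    bimolecular_complex,
    dynamic_range,
    fit_analyte_titration,
    fit_single_site_isotherm,
    fraction_bound_excess,
    optimal_label_concentration,
    solve_competition,
    ternary_state_fractions,
)
from mfapkit.synthetic_data import NoiseModel, gen_titration_plate

from conftest import bisect

pos_conc = st.floats(min_value=1e-3, max_value=1e4)


class TestFractionBoundExcess:
    @pytest.mark.parametrize(
        "protein, kd, expected",
        [
            (134.0, 5.8, 134.0 / 139.8),  # excess-protein bound fraction ~95.9%
            (206.0, 1.8, 206.0 / 207.8),  # ~99.1%
            (0.0, 3.0, 0.0),
        ],
    )
    def test_examples(self, protein, kd, expected):
        assert fraction_bound_excess(protein, kd) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_kd_raises(self):
        with pytest.raises(ValueError):
            fraction_bound_excess(1.0, 0.0)


class TestBimolecularComplex:
    def test_equal_totals_unit_kd(self):
        # closed form (3 - sqrt(5))/2, cross-checked by fixed-point iteration
        # on C = A0*B0 / (Kd + A0 + B0 - C) frozen at 0.3819660112501051
        c = bimolecular_complex(BinaryBindingSystem(1.0, 1.0, 1.0))
        assert c == pytest.approx((3 - math.sqrt(5)) / 2, rel=1e-12)
        assert c == pytest.approx(0.3819660112501051, rel=1e-12)

    def test_percent_bound_cross_check(self):
        c = bimolecular_complex(BinaryBindingSystem(134.0, 1.0, 5.8))
        assert c / 1.0 == pytest.approx(0.958, abs=1e-3)

    def test_stoichiometric_limit(self):
        c = bimolecular_complex(BinaryBindingSystem(3.0, 7.0, 1e-12))
        assert c == pytest.approx(3.0, rel=1e-9)

    @given(a=pos_conc, b=pos_conc, kd=pos_conc)
    @settings(max_examples=100, deadline=None)
    def test_bounds_symmetry_and_mass_action(self, a, b, kd):
        c = bimolecular_complex(BinaryBindingSystem(a, b, kd))
        assert 0.0 <= c <= min(a, b) + 1e-12
        c_swap = bimolecular_complex(BinaryBindingSystem(b, a, kd))
        assert c == pytest.approx(c_swap, rel=1e-9, abs=1e-12)
        if c > 1e-9:
            assert (a - c) * (b - c) / c == pytest.approx(kd, rel=1e-7)

    def test_trace_ligand_approaches_excess_formula(self):
        a, kd = 50.0, 3.0
        exact = bimolecular_complex(BinaryBindingSystem(a, 1e-6, kd)) / 1e-6
        assert exact == pytest.approx(fraction_bound_excess(a, kd), abs=1e-6)
        # the excess formula is an upper bound on the exact bound fraction
        for b in (0.1, 1.0, 10.0):
            frac = bimolecular_complex(BinaryBindingSystem(a, b, kd)) / b
            assert frac <= fraction_bound_excess(a, kd) + 1e-12


class TestIsothermFit:
    def test_noiseless_recovery(self):
        series = gen_titration_plate(kd=1.8, f_min=50.0, f_max=9000.0, top_conc=31.6,
                                     n_dilutions=11)
        fit = fit_single_site_isotherm(series)
        assert fit.kd == pytest.approx(1.8, rel=1e-6)
        assert not fit.is_lower_bound
        assert fit.f_max >= fit.f_min

    def test_noisy_recovery_median(self):
        errs = []
        for seed in range(100):
            series = gen_titration_plate(
                kd=0.15, f_min=20.0, f_max=5000.0, top_conc=31.6,
                noise=NoiseModel(cv=0.05), seed=seed,
            )
            fit = fit_single_site_isotherm(series)
            errs.append(abs(fit.kd - 0.15) / 0.15)
        assert np.median(errs) <= 0.15

    def test_lower_bound_flag(self):
        # Kd 100x above the top tested concentration: signal never plateaus
        series = gen_titration_plate(kd=3160.0, f_min=0.0, f_max=1000.0, top_conc=31.6)
        fit = fit_single_site_isotherm(series)
        assert fit.is_lower_bound
        assert fit.report_kd().startswith("≥")

    def test_flat_series_raises(self):
        series = TitrationSeries(
            analyte_conc=[0.0, 1.0, 2.0, 4.0, 8.0, 16.0],
            rfu=np.full((6, 3), 100.0),
        )
        with pytest.raises(RuntimeError):
            fit_single_site_isotherm(series)

    def test_too_few_points_raises(self):
        series = TitrationSeries(analyte_conc=[0.0, 1.0, 2.0, 4.0],
                                 rfu=[[0.0], [10.0], [20.0], [30.0]])
        with pytest.raises(ValueError):
            fit_single_site_isotherm(series)

    def test_blank_subtraction_used(self):
        series = gen_titration_plate(kd=2.0, f_min=0.0, f_max=1000.0, top_conc=31.6)
        offset = np.full_like(series.rfu, 77.0)
        shifted = TitrationSeries(
            analyte_conc=series.analyte_conc, rfu=series.rfu + offset, blanks=offset
        )
        fit = fit_single_site_isotherm(shifted)
        assert fit.kd == pytest.approx(2.0, rel=1e-6)


class TestAnalyteTitration:
    def test_decreasing_recovery(self):
        # EF2n-like negative allostery: fluorescence falls with Ca2+
        series = gen_titration_plate(kd=60.0, f_min=100.0, f_max=8000.0,
                                     top_conc=9000.0, n_dilutions=11,
                                     direction="decreasing")
        fit = fit_analyte_titration(series, direction="decreasing")
        assert fit.kd == pytest.approx(60.0, rel=1e-6)
        assert fit.direction == "decreasing"

    def test_weak_binder_sampled_short(self):
        # Kd far above the sampled range: documented lower-bound behavior
        series = gen_titration_plate(kd=2300.0, f_min=0.0, f_max=1000.0,
                                     top_conc=900.0, n_dilutions=11)
        fit = fit_analyte_titration(series, direction="increasing")
        assert fit.kd > 900.0 or fit.is_lower_bound

    def test_free_hill_diagnostic_near_one(self):
        series = gen_titration_plate(kd=60.0, f_min=0.0, f_max=1000.0,
                                     top_conc=9000.0, n_dilutions=11)
        fit = fit_analyte_titration(series, fix_hill=False)
        assert fit.hill == pytest.approx(1.0, abs=1e-6)


class TestTernaryAllostery:
    def test_cycle_closure_by_construction(self, negative_allostery_system):
        s = negative_allostery_system
        lhs = s.kd_chromophore_apo * s.kd_analyte_holo
        rhs = s.kd_chromophore_holo * s.kd_analyte_apo
        assert lhs == pytest.approx(rhs, rel=1e-15)

    def test_fractions_sum_to_one(self, positive_allostery_system):
        for c in (0.0, 0.1, 4.45, 100.0):
            for a in (0.0, 10.0, 1e4):
                fr = ternary_state_fractions(positive_allostery_system, c, a)
                assert min(fr) >= 0.0
                assert sum(fr) == pytest.approx(1.0, abs=1e-12)

    def test_no_coupling_means_analyte_independent_occupancy(self):
        s = TernaryAllosterySystem(5.0, 5.0, 100.0)
        assert s.coupling == 1.0
        occ = []
        for a in (0.0, 10.0, 1e3, 1e6):
            fr = ternary_state_fractions(s, 2.0, a)
            occ.append(fr[1] + fr[3])
        assert np.ptp(occ) < 1e-12

    def test_limits_reduce_to_binary_isotherms(self, positive_allostery_system):
        s = positive_allostery_system
        c = 4.45
        fr0 = ternary_state_fractions(s, c, 0.0)
        assert fr0[1] == pytest.approx(c / (c + s.kd_chromophore_apo), rel=1e-12)
        fr_inf = ternary_state_fractions(s, c, 1e12)
        assert fr_inf[3] == pytest.approx(c / (c + s.kd_chromophore_holo), rel=1e-6)

    def test_doubly_bound_increases_with_analyte(self, positive_allostery_system):
        c = optimal_label_concentration(1.8, 11.0)
        doubly = [
            ternary_state_fractions(positive_allostery_system, c, a)[3]
            for a in np.logspace(0, 5, 25)
        ]
        assert np.all(np.diff(doubly) > 0)

    def test_exact_mode_matches_excess_at_trace_sensor(self, negative_allostery_system):
        ex = ternary_state_fractions(negative_allostery_system, 30.0, 200.0)
        xa = ternary_state_fractions(
            negative_allostery_system, 30.0, 200.0, mode="exact", sensor_total=1e-4
        )
        assert np.allclose(ex, xa, atol=1e-6)

    def test_exact_mode_matches_bisection_oracle(self):
        # brute-force nested bisection on the two conservation equations
        rng = np.random.default_rng(42)
        for _ in range(100):
            kdm, kdp, kda = rng.uniform(0.1, 50, 3)
            s = TernaryAllosterySystem(kdm, kdp, kda)
            sensor, c_tot, a_tot = rng.uniform(0.1, 20, 3)

            def fracs(c, a):
                wc = c / s.kd_chromophore_apo
                wa = a / s.kd_analyte_apo
                wca = wa * c / s.kd_chromophore_holo
                z = 1 + wc + wa + wca
                return wc / z, wa / z, wca / z

            def c_resid(c):
                def a_resid(a):
                    fc, fa, fca = fracs(c, a)
                    return a + sensor * (fa + fca) - a_tot

                a = bisect(a_resid, 0.0, a_tot)
                fc, fa, fca = fracs(c, a)
                return c + sensor * (fc + fca) - c_tot

            c_free = bisect(c_resid, 0.0, c_tot)

            def a_resid(a):
                fc, fa, fca = fracs(c_free, a)
                return a + sensor * (fa + fca) - a_tot

            a_free = bisect(a_resid, 0.0, a_tot)
            wc = c_free / s.kd_chromophore_apo
            wa = a_free / s.kd_analyte_apo
            wca = wa * c_free / s.kd_chromophore_holo
            z = 1 + wc + wa + wca
            oracle = np.array([1 / z, wc / z, wa / z, wca / z])

            got = np.array(
                ternary_state_fractions(s, c_tot, a_tot, mode="exact", sensor_total=sensor)
            )
            assert np.allclose(got, oracle, atol=1e-6)

    def test_negative_concentration_raises(self, negative_allostery_system):
        with pytest.raises(ValueError):
            ternary_state_fractions(negative_allostery_system, -1.0, 0.0)


class TestOptimalLabelConcentration:
    @pytest.mark.parametrize(
        "kp, km, expected",
        [(0.3, 2.7, 0.9), (5.0, 5.0, 5.0), (1.8, 11.0, 4.449719092257398)],
    )
    def test_geometric_mean(self, kp, km, expected):
        assert optimal_label_concentration(kp, km) == pytest.approx(expected, rel=1e-12)
        assert optimal_label_concentration(km, kp) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_raises(self):
        with pytest.raises(ValueError):
            optimal_label_concentration(0.0, 1.0)


class TestCompetition:
    def test_symmetric_system(self):
        c1, c2 = solve_competition(CompetitionSystem(2.0, (5.0, 5.0), (1.0, 1.0)))
        assert c1 == pytest.approx(c2, rel=1e-9)

    def test_high_affinity_ligand_dominates(self):
        # 10 uM at Kd 0.8 nM vs 2 uM at Kd 320 nM for a 2 uM receptor
        c1, c2 = solve_competition(
            CompetitionSystem(2.0, (2.0, 10.0), (0.32, 0.0008))
        )
        assert c2 / (c1 + c2) > 0.99

    def test_single_ligand_reduces_to_bimolecular(self):
        c1, c2 = solve_competition(CompetitionSystem(2.0, (3.0, 0.0), (0.5, 1.0)))
        assert c2 == 0.0
        assert c1 == pytest.approx(
            bimolecular_complex(BinaryBindingSystem(2.0, 3.0, 0.5)), rel=1e-9
        )

    def test_matches_nested_bisection_oracle_on_random_systems(self):
        # independent oracle: bisection over free ligand concentrations
        rng = np.random.default_rng(7)
        for _ in range(100):
            r_tot = rng.uniform(0.1, 20)
            l1t, l2t = rng.uniform(0.1, 30, 2)
            k1, k2 = 10 ** rng.uniform(-3, 2, 2)
            sys = CompetitionSystem(r_tot, (l1t, l2t), (k1, k2))
            got = solve_competition(sys)

            def r_free(f1, f2):
                return r_tot / (1.0 + f1 / k1 + f2 / k2)

            def l2_resid(f1, f2):
                return f2 + r_free(f1, f2) * f2 / k2 - l2t

            def l1_resid(f1):
                f2 = bisect(lambda x: l2_resid(f1, x), 0.0, l2t)
                return f1 + r_free(f1, f2) * f1 / k1 - l1t

            f1 = bisect(l1_resid, 0.0, l1t)
            f2 = bisect(lambda x: l2_resid(f1, x), 0.0, l2t)
            r = r_free(f1, f2)
            oracle = (r * f1 / k1, r * f2 / k2)
            scale = max(r_tot, 1.0)
            assert abs(got[0] - oracle[0]) / scale < 1e-6
            assert abs(got[1] - oracle[1]) / scale < 1e-6

    def test_mass_conservation(self):
        sys = CompetitionSystem(2.0, (2.0, 10.0), (0.32, 0.0008))
        c1, c2 = solve_competition(sys)
        # receptor conservation via mass action on either complex
        r_free = c1 * sys.kds[0] / (sys.ligand_totals[0] - c1)
        assert r_free + c1 + c2 == pytest.approx(sys.receptor_total, rel=1e-9)


class TestDynamicRange:
    def test_no_coupling_gives_zero(self):
        s = TernaryAllosterySystem(5.0, 5.0, 100.0)
        assert dynamic_range(s, 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_low_chromophore_limit_is_coupling_minus_one(self, positive_allostery_system):
        s = positive_allostery_system
        dr = dynamic_range(s, 1e-6)
        assert dr == pytest.approx(s.coupling - 1.0, rel=1e-5)

    def test_saturating_chromophore_limit_is_zero(self, positive_allostery_system):
        assert abs(dynamic_range(positive_allostery_system, 1e6)) < 1e-4

    def test_sign_matches_allostery_direction(self, negative_allostery_system,
                                              positive_allostery_system):
        assert dynamic_range(positive_allostery_system, 4.45) > 0
        assert dynamic_range(negative_allostery_system, 4.45) < 0


class TestIsothermFitType:
    def test_invalid_kd_rejected(self):
        with pytest.raises(ValueError):
            IsothermFit(kd=-1.0, f_max=1.0, f_min=0.0)

    def test_titration_series_validation(self):
        with pytest.raises(ValueError):
            TitrationSeries(analyte_conc=[0.0, 2.0, 1.0], rfu=np.zeros((3, 2)))
        with pytest.raises(ValueError):
            TitrationSeries(analyte_conc=[0.0, 1.0], rfu=np.zeros((3, 2)))
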