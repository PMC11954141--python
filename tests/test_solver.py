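"""Suspension solver: worked examples, oracles, and balance invariants."""

import math
from dataclasses import replace

import numpy as np
import pytest

from puresol import (ActivityContext, CompoundSpec, SuspensionSpec,
                     closed_form_monoprotic_phw, co2_adjusted_intrinsic,
                     derive_intrinsic_from_sw, derive_intrinsic_state,
                     diprotic_phw_cubic, generate_random_compound,
                     get_fixture, grid_search_oracle, solve_suspension,
                     water_pkw)


def _ctx_off(T):
    return ActivityContext(temperature=T, corrections_enabled=False)


class TestWorkedSuspension:
    def test_saturated_acetaminophen(self, acetaminophen_worked):
        st = solve_suspension(SuspensionSpec(compound=acetaminophen_worked,
                                             total_added=0.164))
        assert st.saturated and st.solid_remaining > 0
        assert st.p_cH == pytest.approx(5.28, abs=0.06)
        assert st.ionic_strength == pytest.approx(6.6e-6, rel=0.2)

    def test_subsaturated_acetaminophen(self, acetaminophen_worked):
        st = solve_suspension(SuspensionSpec(compound=acetaminophen_worked,
                                             total_added=0.132))
        assert not st.saturated and st.solid_remaining == 0
        assert st.dissolved_total == pytest.approx(0.132, rel=1e-10)
        assert st.p_cH == pytest.approx(5.29, abs=0.06)
        assert st.ionic_strength == pytest.approx(5.7e-6, rel=0.1)

    def test_pure_water(self):
        w = CompoundSpec(name="blank", compound_class="acid", pKa_ref=(7.0,),
                         max_cation_charge=0, T=25.0, pS0_ref=0.0)
        st = solve_suspension(SuspensionSpec(compound=w, total_added=0.0),
                              _ctx_off(25.0))
        assert st.p_cH == pytest.approx(0.5 * water_pkw(25.0), abs=1e-9)

    def test_lysine_high_ionic_strength(self):
        c = get_fixture("Lysine, L- (2-fold excess)")
        ps0_i, ps0_ref, ph_w, i_w = derive_intrinsic_from_sw(c)
        assert ph_w == pytest.approx(10.01, abs=0.15)
        assert 0.4 < i_w < 0.8     # multi-molar-adjacent regime, ~0.6-0.7 M


class TestInverseProblem:
    @pytest.mark.parametrize("name,logs0_ref,phw,tol_ph", [
        ("Crocetin", -7.04, 5.56, 0.05),
        ("Glibenclamide", -4.33, 4.81, 0.06),
        ("Ketoconazole", -4.92, 7.48, 0.05),
    ])
    def test_tabulated_compounds(self, name, logs0_ref, phw, tol_ph):
        c = get_fixture(name)
        ps0_i, ps0_ref, ph_w, i_w = derive_intrinsic_from_sw(c)
        assert -ps0_ref == pytest.approx(logs0_ref, abs=0.05)
        assert ph_w == pytest.approx(phw, abs=tol_ph)

    def test_unionizable_compound_recovers_sw(self):
        # pKa far outside 0-14: S_0 = S_w, pH_w = pure-water pH
        c = CompoundSpec(name="inert", compound_class="acid", pKa_ref=(25.0,),
                         max_cation_charge=0, T=25.0, log_Sw=-3.0, k_salt=0.0)
        ps0_i, ps0_ref, ph_w, i_w = derive_intrinsic_from_sw(c, _ctx_off(25.0))
        assert ps0_i == pytest.approx(3.0, abs=1e-9)
        assert ph_w == pytest.approx(0.5 * water_pkw(25.0), abs=1e-6)

    @pytest.mark.parametrize("klass,n", [("acid", 1), ("acid", 2),
                                         ("base", 1), ("base", 2),
                                         ("ampholyte", 2), ("ampholyte", 3)])
    def test_parameter_recovery(self, klass, n):
        """pS0 round trip: forward S_w then inverse recovers pS0 <= 1e-6."""
        for seed in range(40):
            c = generate_random_compound(1000 * n + seed, n, klass)
            st = solve_suspension(SuspensionSpec(
                compound=c, total_added=2.5 * 10 ** -c.pS0_ref))
            if not st.saturated:
                continue
            c2 = replace(c, log_Sw=math.log10(st.dissolved_total),
                         pS0_ref=None)
            ps0_i, ps0_ref, ph_w, i_w = derive_intrinsic_from_sw(c2)
            assert ps0_ref == pytest.approx(c.pS0_ref, abs=1e-6), c.name


class TestCo2Impurity:
    def test_terfenadine_zero_co2(self):
        c = get_fixture("Terfenadine")
        ph_w, log_s0 = co2_adjusted_intrinsic(c, 0.0)
        assert log_s0 == pytest.approx(-5.7, abs=0.1)

    def test_zero_co2_is_plain_inverse_problem(self):
        c = get_fixture("Terfenadine")
        ps0_i, ps0_ref, ph_w, i_w = derive_intrinsic_from_sw(c)
        ph_w2, log_s0 = co2_adjusted_intrinsic(c, 0.0)
        assert ph_w2 == pytest.approx(ph_w, abs=1e-9)
        assert log_s0 == pytest.approx(-ps0_ref, abs=1e-9)

    def test_co2_lowers_phw_and_apparent_s0(self):
        c = get_fixture("Terfenadine")
        results = [co2_adjusted_intrinsic(c, co2) for co2 in
                   (0.0, 10e-6, 20e-6)]
        phs = [r[0] for r in results]
        s0s = [r[1] for r in results]
        assert phs[0] > phs[1] > phs[2]
        assert s0s[0] > s0s[1] > s0s[2]
        # CO2 = 10 uM moves log S0 from ~-5.7 toward ~-6.3
        assert s0s[1] == pytest.approx(-6.3, abs=0.15)


class TestClosedFormOracles:
    def test_acetaminophen_explicit_equation(self):
        ph = closed_form_monoprotic_phw(9.41, 0.87, water_pkw(37.0), "acid")
        # approximation anchor: 0.5 (pS0 + pKa) = 5.14 for a soluble acid
        assert ph == pytest.approx(0.5 * (9.41 + 0.87), abs=0.01)

    def test_very_soluble_acid_approaches_half_pka(self):
        ph = closed_form_monoprotic_phw(9.41, -6.0, 14.0, "acid")
        assert ph == pytest.approx(0.5 * (9.41 - 6.0), abs=1e-6)

    def test_degenerate_diprotic_reduces_to_monoprotic(self):
        mono = closed_form_monoprotic_phw(4.0, 3.0, 14.0, "acid")
        di = diprotic_phw_cubic(4.0, 30.0, 3.0, 14.0, "acid")
        assert di == pytest.approx(mono, abs=1e-6)

    @pytest.mark.parametrize("klass,kind,n", [("acid", "acid", 1),
                                              ("acid", "acid", 2),
                                              ("base", "base", 1),
                                              ("base", "base", 2)])
    def test_solver_matches_closed_forms(self, klass, kind, n):
        """Corrections off, solver pH == explicit equations to 1e-5."""
        for seed in range(60):
            c = generate_random_compound(7000 + 13 * seed + n, n, klass)
            st = solve_suspension(SuspensionSpec(
                compound=c, total_added=3.0 * 10 ** -c.pS0_ref),
                _ctx_off(c.T))
            if not st.saturated:
                continue
            pkw = water_pkw(c.T)
            if n == 1:
                cf = closed_form_monoprotic_phw(c.pKa_ref[0], c.pS0_ref,
                                                pkw, kind)
            else:
                cf = diprotic_phw_cubic(c.pKa_ref[0], c.pKa_ref[1],
                                        c.pS0_ref, pkw, kind)
            assert st.p_cH == pytest.approx(cf, abs=1e-5), c.name


class TestGridOracle:
    def test_acetaminophen_cross_check(self, acetaminophen_worked):
        spec = SuspensionSpec(compound=acetaminophen_worked,
                              total_added=0.164)
        st = solve_suspension(spec)
        g = grid_search_oracle(spec, grid_step=0.01)
        assert abs(st.p_cH - g.p_cH) < 1e-5

    def test_pure_water_grid(self):
        w = CompoundSpec(name="blank", compound_class="acid", pKa_ref=(7.0,),
                         max_cation_charge=0, T=25.0, pS0_ref=0.0)
        g = grid_search_oracle(SuspensionSpec(compound=w, total_added=0.0),
                               _ctx_off(25.0), grid_step=0.05)
        assert g.p_cH == pytest.approx(0.5 * water_pkw(25.0), abs=1e-6)

    def test_random_compound_sweep(self):
        for seed in range(25):
            for klass, n in (("acid", 1), ("base", 2), ("ampholyte", 3)):
                c = generate_random_compound(500 + seed, n, klass)
                spec = SuspensionSpec(compound=c,
                                      total_added=2.0 * 10 ** -c.pS0_ref)
                st = solve_suspension(spec)
                g = grid_search_oracle(spec, grid_step=0.05)
                assert abs(st.p_cH - g.p_cH) <= 1e-5, c.name


class TestBalances:
    @pytest.mark.parametrize("name", ["Crocetin", "Ketoconazole",
                                      "Lysine, L- (2-fold excess)",
                                      "Mellitic acid (2-fold excess)"])
    def test_charge_and_mass_balance(self, name):
        c = get_fixture(name)
        st = derive_intrinsic_state(c)
        assert abs(st.charge_residual) <= 1e-10 * max(st.ionic_strength,
                                                      1e-7)
        assert st.dissolved_total == pytest.approx(c.sw_molar, rel=1e-10)

    def test_forward_mass_balance(self, acetaminophen_worked):
        st = solve_suspension(SuspensionSpec(compound=acetaminophen_worked,
                                             total_added=0.164))
        total = st.solid_remaining + st.dissolved_total
        assert total == pytest.approx(0.164, rel=1e-10)
        assert st.solid_remaining >= 0
        assert st.saturated == (st.solid_remaining > 0)

    def test_saturation_continuity(self, acetaminophen_worked):
        """pH continuous across the saturation threshold in C_tot."""
        sat = solve_suspension(SuspensionSpec(compound=acetaminophen_worked,
                                              total_added=0.1406))
        just_below = solve_suspension(SuspensionSpec(
            compound=acetaminophen_worked, total_added=0.1404))
        assert abs(sat.p_cH - just_below.p_cH) < 5e-3

    def test_dilute_compound_insensitive_to_excess(self):
        c = get_fixture("Ketoconazole")
        c = replace(c, pS0_ref=4.92)
        ph = [solve_suspension(SuspensionSpec(compound=c, total_added=t)).p_cH
              for t in (5e-5, 5e-4, 5e-3)]
        assert max(ph) - min(ph) < 1e-6
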