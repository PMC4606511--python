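"""Tests of the two-site 5mTHF-GNMT binding subsystem: mass-action
kinetics, analytic equilibrium against independent routes, titration
invariants and the per-occupancy activity hypothesis."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from onecarbon import default_parameters
from onecarbon.binding import (
    ActivityWeights,
    BindingState,
    binding_rhs,
    equilibrium_species,
    gnmt_activity,
    integrate_binding,
    titration_experiment,
)

P = default_parameters()

species = st.floats(min_value=0.0, max_value=100.0, allow_nan=False)


def cubic_equilibrium_free_ligand(total: float, gtot: float, kd1: float, kd2: float) -> float:
    """Independent oracle: free ligand as the admissible root of the cubic
    obtained by eliminating the enzyme species from the conservation laws."""
    a, b = 1.0 / kd1, 1.0 / (kd1 * kd2)
    # (f - T)(1 + a f + b f^2) + G(a f + 2 b f^2) = 0
    coeffs = [b, a + (2.0 * gtot - total) * b, 1.0 + (gtot - total) * a, -total]
    roots = np.roots(coeffs)
    real = [r.real for r in roots if abs(r.imag) < 1e-9 and -1e-12 <= r.real <= total + 1e-9]
    assert real, "cubic produced no admissible root"
    return max(min(real), 0.0)


class TestBindingRHS:
    def test_all_zero_state_is_stationary(self):
        rhs = binding_rhs(BindingState(0, 0, 0, 0), P)
        assert np.all(rhs == 0.0)

    @given(f=species, g=species, s=species, d=species)
    def test_enzyme_and_ligand_conservation(self, f, g, s, d):
        rhs = binding_rhs(BindingState(f, g, s, d), P)
        # total enzyme g + s + d is conserved
        assert rhs[1] + rhs[2] + rhs[3] == pytest.approx(0.0, abs=1e-9)
        # total ligand f + s + 2 d is conserved
        assert rhs[0] + rhs[2] + 2.0 * rhs[3] == pytest.approx(0.0, abs=1e-9)

    def test_rhs_terms_match_mass_action_expansion(self):
        b = BindingState(2.0, 0.5, 0.3, 0.2)
        k1, k2, k3, k4 = (P[f"binding.k{i}"] for i in (1, 2, 3, 4))
        a1 = k1 * b.f_free * b.g_free - k2 * b.g_single
        a2 = k3 * b.g_single * b.f_free - k4 * b.g_double
        expect = np.array([-a1 - a2, -a1, a1 - a2, a2])
        assert np.allclose(binding_rhs(b, P), expect, rtol=0, atol=0)


class TestEquilibrium:
    def test_no_ligand(self):
        eq = equilibrium_species(0.0, 1.0, P)
        assert (eq.f_free, eq.g_free, eq.g_single, eq.g_double) == (0.0, 1.0, 0.0, 0.0)

    def test_no_enzyme(self):
        eq = equilibrium_species(5.0, 0.0, P)
        assert (eq.f_free, eq.g_free, eq.g_single, eq.g_double) == (5.0, 0.0, 0.0, 0.0)

    def test_negative_totals_rejected(self):
        with pytest.raises(ValueError):
            equilibrium_species(-1.0, 1.0, P)

    @pytest.mark.parametrize("total", [0.05, 0.3, 1.0, 2.0, 5.0, 20.0])
    def test_matches_cubic_oracle(self, total):
        eq = equilibrium_species(total, 1.0, P)
        f_oracle = cubic_equilibrium_free_ligand(total, 1.0, P.kd1, P.kd2)
        assert eq.f_free == pytest.approx(f_oracle, abs=1e-9)

    def test_matches_long_time_integration_over_grid(self):
        # dynamic route: start fully dissociated and integrate to rest
        grid = np.linspace(0.1, 10.0, 20)
        for total in grid:
            eq = equilibrium_species(total, 1.0, P)
            dyn = integrate_binding(BindingState(total, 1.0, 0.0, 0.0), P, t_end=2000.0)
            for attr in ("f_free", "g_free", "g_single", "g_double"):
                assert getattr(dyn, attr) == pytest.approx(getattr(eq, attr), abs=1e-6)

    @given(total=st.floats(0.0, 50.0), gtot=st.floats(0.0, 5.0))
    def test_equilibrium_conserves_totals(self, total, gtot):
        eq = equilibrium_species(total, gtot, P)
        assert eq.gnmt_total == pytest.approx(gtot, abs=1e-9)
        assert eq.total_5mthf == pytest.approx(total, abs=1e-8)


class TestActivity:
    def test_occupancy_weighting(self):
        w = ActivityWeights()
        assert gnmt_activity(BindingState(0, 1, 0, 0), w) == 1.0
        assert gnmt_activity(BindingState(0, 0, 1, 0), w) == 0.5
        assert gnmt_activity(BindingState(0, 0, 0, 1), w) == 0.0

    def test_zero_enzyme_undefined(self):
        with pytest.raises(ValueError):
            gnmt_activity(BindingState(1, 0, 0, 0), ActivityWeights())

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            ActivityWeights(1.0, 1.2, 0.0)

    def test_half_activity_hypothesis_fits_published_inhibition_points(self):
        # published summary of the in-vitro inhibition data: 15 % inhibition
        # at 0.1 uM total 5mTHF, 50 % at 1 uM, 90 % at 10 uM (1 uM enzyme).
        data = [(0.1, 0.85), (1.0, 0.50), (10.0, 0.10)]

        def sse(w):
            return sum(
                (gnmt_activity(equilibrium_species(t, 1.0, P), w) - a) ** 2
                for t, a in data
            )

        half = sse(ActivityWeights(1.0, 0.5, 0.0))
        dead = sse(ActivityWeights(1.0, 0.0, 0.0))
        assert half < dead
        assert half < 0.05  # the half-activity curve tracks the data closely


class TestTitration:
    def test_invariants_along_curve(self):
        grid = np.linspace(0.0, 30.0, 40)
        curve = titration_experiment(grid, 1.0, ActivityWeights(), P)
        assert np.allclose(curve.bound + curve.free, grid, atol=1e-8)
        assert np.all((curve.activity >= 0) & (curve.activity <= 1))
        assert np.all(np.diff(curve.activity) <= 1e-12)  # nonincreasing
        assert np.all(curve.bound <= 2.0 + 1e-9)
        # bound-vs-free curve is increasing and concave
        db = np.diff(curve.bound[1:]) / np.diff(curve.free[1:])
        assert np.all(db > -1e-12)
        assert np.all(np.diff(db) < 1e-6)

    def test_two_site_signature_and_asymptote(self):
        curve = titration_experiment(np.array([5.0, 50.0, 1e5]), 1.0, ActivityWeights(), P)
        # bound 5mTHF exceeds the 1 uM of enzyme: there must be two sites
        assert curve.bound[0] > 1.0
        assert curve.bound[-1] == pytest.approx(2.0, rel=1e-3)

    def test_unsorted_grid_rejected(self):
        with pytest.raises(ValueError):
            titration_experiment(np.array([1.0, 0.5]), 1.0, ActivityWeights(), P)
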