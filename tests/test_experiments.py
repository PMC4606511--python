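"""Tests of the virtual experiments: perturbation panels, sweeps,
jitter envelopes and meal simulations."""

import numpy as np
import pytest

from onecarbon import default_parameters
from onecarbon.experiments import (
    PerturbationSpec,
    folate_sweep,
    knockout_panel,
    meal_simulation,
    methionine_sweep,
    relative_amplitude,
    run_perturbation,
    vmax_envelope,
)
from onecarbon.system import InputSchedule

P = default_parameters()


@pytest.fixture(scope="module")
def panels(baseline):
    return {
        lri: knockout_panel(P, lri=lri) for lri in (True, False)
    }


@pytest.fixture(scope="module")
def met_curves():
    grid = np.linspace(10, 100, 10)
    return (
        grid,
        methionine_sweep(grid, P, lri=True),
        methionine_sweep(grid, P, lri=False),
    )


@pytest.fixture(scope="module")
def folate_curves():
    grid = np.linspace(5, 20, 6)
    return (
        grid,
        folate_sweep(grid, P, lri=True),
        folate_sweep(grid, P, lri=False),
    )


@pytest.fixture(scope="module")
def meal_traj():
    return meal_simulation(InputSchedule(mode="meal"), 2, P)


def pct(panel, target, quantity):
    row = panel[(panel["target"] == target) & (panel["quantity"] == quantity)]
    assert len(row) == 1
    return float(row["pct_change"].iloc[0])


class TestPerturbations:
    def test_identity_multiplier_changes_nothing(self, baseline):
        res = run_perturbation(PerturbationSpec("gamt", 1.0, True), P, baseline)
        assert all(abs(v) < 1e-6 for v in res.pct_flux.values())
        assert all(abs(v) < 1e-6 for v in res.pct_tracked.values())

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            PerturbationSpec("mthfr", 0.0)
        with pytest.raises(ValueError):
            PerturbationSpec("gamt", -1.0)

    def test_knockout_raises_other_fluxes_and_upregulation_lowers_them(self, panels):
        on = panels[True]
        for target in ("pemt", "gamt", "gnmt"):
            others = [m for m in ("pemt", "gamt", "dnmt", "as3mt") if m != target]
            for other in others:
                assert pct(on, target, other) > 0
        for other in ("pemt", "gamt", "as3mt", "gnmt"):
            assert pct(on, "dnmt", other) < 0

    def test_gnmt_acts_as_salvage_pathway(self, panels):
        # GNMT moves opposite to the perturbed flux, absorbing the change
        on = panels[True]
        assert pct(on, "pemt", "gnmt") > 0
        assert pct(on, "gamt", "gnmt") > 0
        assert pct(on, "dnmt", "gnmt") < 0

    def test_long_range_interactions_damp_every_response(self, panels):
        # for each non-GNMT perturbation, every unperturbed MT flux moves
        # strictly less with the interactions on than off
        for target, mult in (("pemt", 0.0), ("gamt", 0.0), ("dnmt", 20.0)):
            others = [m for m in ("gnmt", "pemt", "gamt", "as3mt") if m != target]
            for other in others:
                a = abs(pct(panels[True], target, other))
                b = abs(pct(panels[False], target, other))
                assert a < b, (target, other, a, b)

    def test_clamped_regulators_leave_folate_side_untouched(self, panels):
        # the lri-off signature: 5mTHF, bound GNMT and frac do not move for
        # any perturbation that leaves GNMT itself intact
        off = panels[False]
        for target in ("pemt", "gamt", "dnmt"):
            for q in ("m5", "gs", "frac"):
                assert abs(pct(off, target, q)) < 0.01, (target, q)

    def test_gnmt_knockout_empties_binding_subsystem(self, baseline):
        res = run_perturbation(PerturbationSpec("gnmt", 0.0, True), P, baseline)
        for name in ("g", "gs", "gd"):
            assert res.perturbed.concentration(name) == 0.0
        assert res.perturbed.fluxes["gnmt"] == 0.0


class TestSweeps:
    def test_sam_monotone_in_input_both_toggles(self, met_curves):
        _, on, off = met_curves
        assert on["sam"].is_monotonic_increasing
        assert off["sam"].is_monotonic_increasing

    def test_interactions_flatten_the_response_above_baseline(self, met_curves):
        grid, on, off = met_curves
        above = grid > 50.0
        assert np.all(off["sam"].to_numpy()[above] > on["sam"].to_numpy()[above])

    def test_substrate_switch_accelerates_at_high_input(self, met_curves):
        _, on, off = met_curves
        for df in (on, off):
            d = np.diff(df["sam"].to_numpy())
            assert d[-1] > d[0]  # accelerating growth

    def test_baseline_input_recovers_reference_sam(self, met_curves):
        grid, on, _ = met_curves
        i = int(np.argmin(np.abs(grid - 50.0)))
        assert on["sam"].iloc[i] == pytest.approx(23.97, rel=1e-6)

    def test_sam_increasing_in_folate_both_toggles(self, folate_curves):
        _, on, off = folate_curves
        assert on["sam"].is_monotonic_increasing
        assert off["sam"].is_monotonic_increasing

    def test_sam_is_nearly_linear_in_folate(self, folate_curves):
        grid, on, off = folate_curves
        for df in (on, off):
            sam = df["sam"].to_numpy()
            fit = np.polyfit(grid, sam, 1)
            resid = sam - np.polyval(fit, grid)
            assert np.max(np.abs(resid)) < 0.05 * (sam.max() - sam.min())

    def test_interactions_protect_total_methylation(self, folate_curves):
        _, on, off = folate_curves

        def rel_drop(df):
            tm = df["total_methylation"].to_numpy()
            return (tm[-1] - tm[0]) / tm[-1]

        assert rel_drop(on) < rel_drop(off)
        assert rel_drop(on) < 0.05  # nearly flat with the interactions on

    def test_baseline_total_methylation_is_sum_of_reference_mt_fluxes(self, folate_curves):
        _, on, _ = folate_curves
        # 43.97 + 2.05 + 25.42 + 27.53 + 1.28 summed from the reference fluxes
        assert on["total_methylation"].iloc[-1] == pytest.approx(100.25, rel=1e-6)


class TestEnvelope:
    GRID = np.linspace(8, 20, 3)

    def test_zero_jitter_collapses_to_base_curve(self):
        env = vmax_envelope(self.GRID, P, n_reps=2, jitter=0.0, seed=3)
        assert np.allclose(env["sam_min"], env["base_sam"], atol=1e-6)
        assert np.allclose(env["sam_max"], env["base_sam"], atol=1e-6)

    def test_base_curve_inside_envelope_and_deterministic(self):
        e1 = vmax_envelope(self.GRID, P, n_reps=3, jitter=0.1, seed=11)
        e2 = vmax_envelope(self.GRID, P, n_reps=3, jitter=0.1, seed=11)
        for key in ("sam_min", "sam_max", "total_methylation_min"):
            assert np.array_equal(e1[key], e2[key])
        assert np.all(e1["sam_min"] <= e1["base_sam"] + 1e-9)
        assert np.all(e1["base_sam"] <= e1["sam_max"] + 1e-9)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            vmax_envelope(self.GRID, P, n_reps=0)
        with pytest.raises(ValueError):
            vmax_envelope(self.GRID, P, jitter=1.5)


class TestMeals:
    def test_low_km_flux_is_flat_and_gamt_fluctuates(self, meal_traj):
        # DNMT runs far above its Km, so meals barely move it
        assert relative_amplitude(meal_traj["dnmt"]) < relative_amplitude(meal_traj["gamt"])

    def test_sah_inhibition_buffers_pemt(self, meal_traj):
        # PEMT's small Ki for SAH compensates the SAM swings
        assert relative_amplitude(meal_traj["pemt"]) < relative_amplitude(meal_traj["gamt"])

    def test_sah_and_hcy_covary_with_sam_and_5mthf_antivaries(self, meal_traj):
        assert meal_traj["sah"].corr(meal_traj["sam"]) > 0.8
        assert meal_traj["hcy"].corr(meal_traj["sam"]) > 0.8
        assert meal_traj["m5"].corr(meal_traj["sam"]) < -0.8

    def test_constant_schedule_keeps_trajectories_flat(self):
        df = meal_simulation(InputSchedule(mode="constant", rate=50.0), 2, P)
        assert relative_amplitude(df["sam"]) < 1e-6
        assert relative_amplitude(df["gamt"]) < 1e-6

    def test_too_few_days_rejected(self):
        with pytest.raises(ValueError):
            meal_simulation(InputSchedule(mode="meal"), 1, P)
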