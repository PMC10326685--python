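"""ODE engine: oracles, mass balance, turnover, NCA."""

import dataclasses
import math

import numpy as np
import pytest

import imatinib_pbpk as ip
from imatinib_pbpk.engine import _geo_sum
from imatinib_pbpk.mechanisms import (hepatic_intrinsic_clearance,
                                      renal_clearance_individual)


def closed_form_oral_auc(ind, drug, dose):
    """Analytic AUC(0-inf) for the linearized system.

    fa * Fg * Fh * D / (CLh_plasma + CL_R) with the well-stirred liver on
    the blood scale converted to plasma clearance; equivalently
    fa * Fg * D / (fu*CLint + CL_R*(1 + fub*CLint/Qh)).
    """
    clint = hepatic_intrinsic_clearance(ind, drug)["total"]
    fu = ind.fu_baseline
    x = fu / drug.blood_plasma_ratio * clint
    clr = renal_clearance_individual(ind, drug)
    kmet = (drug.clint_per_pmol["CYP3A4_gut"] * ind.enzyme_abundance["CYP3A4_gut"]
            * 1000.0 * 60.0e-6 / drug.gut_wall_volume)
    fg = drug.gut_transit / (drug.gut_transit + kmet)
    return drug.fa * fg * dose / (fu * clint + clr * (1.0 + x / ind.qh))


def test_multi_dose_superposition_sum_matches_bruteforce():
    """Closed-form geometric dose superposition equals the explicit sum."""
    rng = np.random.default_rng(3)
    for _ in range(50):
        t0, tau, n, k = rng.uniform(-48, 48), rng.uniform(4, 24), rng.integers(1, 60), rng.uniform(0.01, 2.0)
        t = t0 + rng.uniform(0, tau * n * 1.5)
        doses = [t0 + j * tau for j in range(int(n)) if t0 + j * tau <= t]
        brute = sum(math.exp(-k * (t - tj)) for tj in doses)
        assert _geo_sum(t, t0, tau, int(n), k) == pytest.approx(brute, rel=1e-10, abs=1e-12)
        assert _geo_sum(t0 - 1.0, t0, tau, int(n), k) == 0.0


class TestSingleDoseOracle:
    def test_matches_closed_form_within_one_percent(self, cfg):
        """Linearized single-dose AUC(0-inf) vs the analytic solution."""
        drug, system = cfg.drug, cfg.system
        for seed in (3, 11, 27):
            ind = ip.sample_individual(system, {}, seed, drug=drug)
            opts = ip.SolverOptions.linear()
            opts.dense_final_points = 6001
            reg = ip.DoseRegimen(dose=400.0, interval=1200.0, n_doses=1)
            res = ip.simulate(ind, drug, reg, options=opts, kdeg=system.kdeg)
            auc = np.trapezoid(res.plasma_conc, res.time)
            expected = closed_form_oral_auc(ind, drug, 400.0)
            assert auc == pytest.approx(expected, rel=0.01)

    def test_zero_dose_gives_zero_trajectories(self, cfg):
        reg = ip.DoseRegimen(dose=0.0, interval=24.0, n_doses=3)
        res = ip.simulate(ip.sample_individual(cfg.system, {}, 1, drug=cfg.drug),
                          cfg.drug, reg, kdeg=cfg.system.kdeg,
                          options=ip.SolverOptions.population())
        assert np.all(res.plasma_conc == 0.0)
        assert all(np.all(v == 0.0) for v in res.amounts.values())


class TestMassBalanceAndLinearity:
    def test_mass_balance_reference_simulation(self, ref_ss_result):
        assert ref_ss_result.mass_balance_rel_error < 1e-3

    def test_unabsorbed_fraction_accounted(self, cfg, ref_ss_result):
        assert ref_ss_result.unabsorbed == pytest.approx(
            (1.0 - cfg.drug.fa) * ref_ss_result.administered)

    def test_dose_linearity_exact_in_linear_mode(self, cfg):
        """With MBI and saturable binding off, AUC is exactly dose-proportional
        and time-invariant (day 1 == day 14)."""
        drug, system = cfg.drug, cfg.system
        ind = ip.sample_individual(system, {}, 4, drug=drug)
        m = {}
        for dose in (200.0, 400.0):
            opts = ip.SolverOptions(autoinhibition=False, saturable_binding=False,
                                    atol=1e-10 * dose / 400.0, dense_all=True)
            res = ip.simulate(ind, drug, ip.DoseRegimen(dose, 24.0, 14),
                              options=opts, kdeg=system.kdeg)
            m[dose] = res
        r = m[400.0].metrics["auc_0_24_ss"] / m[200.0].metrics["auc_0_24_ss"]
        assert r == pytest.approx(2.0, rel=1e-6)
        # time invariance at steady state: day-14 equals the superposition limit
        day1 = ip.nca(m[400.0], (0.0, 24.0))
        assert m[400.0].metrics["cl_over_f"] < day1["cl_over_f"]  # accumulation only
        # enzyme activities stay at baseline without MBI
        assert np.allclose(m[400.0].enzyme_activity["CYP3A4_hepatic"], 1.0)


class TestAutoinhibition:
    def test_day14_clearance_below_day1(self, cfg, ref_ind, regimen_ss):
        opts = ip.SolverOptions.population()
        opts.dense_all = True
        res = ip.simulate(ref_ind, cfg.drug, regimen_ss, options=opts,
                          kdeg=cfg.system.kdeg)
        day1 = ip.nca(res, (0.0, 24.0))
        assert res.metrics["cl_over_f"] < day1["cl_over_f"]

    def test_cyp3a4_activity_declines_to_positive_plateau(self, ref_ss_result):
        e = ref_ss_result.enzyme_activity["CYP3A4_hepatic"]
        t = ref_ss_result.time
        first_day = e[t <= 24.0]
        assert np.all(np.diff(first_day) <= 1e-9)     # monotone decline on day 1
        assert 0.0 < e[-1] < 1.0
        # plateau: last two dosing-interval endpoints nearly equal
        assert e[-1] == pytest.approx(e[np.searchsorted(t, t[-1] - 24.0)], rel=0.02)

    def test_trough_in_physiologic_range(self, ref_ss_result):
        """Steady-state trough near the 1.0 ug/mL clinical target band."""
        assert 0.5 < ref_ss_result.metrics["css_min"] < 2.0


class TestSolverRobustness:
    def test_tolerance_convergence(self, cfg, ref_ind, regimen_ss):
        loose = ip.simulate(ref_ind, cfg.drug, regimen_ss, kdeg=cfg.system.kdeg,
                            options=ip.SolverOptions(rtol=1e-7, atol=1e-9))
        tight = ip.simulate(ref_ind, cfg.drug, regimen_ss, kdeg=cfg.system.kdeg,
                            options=ip.SolverOptions(rtol=1e-8, atol=1e-10))
        assert loose.metrics["auc_0_24_ss"] == pytest.approx(
            tight.metrics["auc_0_24_ss"], rel=1e-3)

    def test_regimen_validation(self, cfg, ref_ind):
        with pytest.raises(ip.ValidationError):
            ip.DoseRegimen(dose=-1.0, interval=24.0, n_doses=14)
        with pytest.raises(ip.ValidationError):
            ip.DoseRegimen(dose=400.0, interval=24.0, n_doses=0)
        with pytest.raises(ip.ValidationError):
            # 12-h regimen too short for metric extraction
            ip.simulate(ref_ind, cfg.drug, ip.DoseRegimen(400.0, 12.0, 1),
                        kdeg=cfg.system.kdeg)

    def test_perpetrator_overflow_rejected(self, cfg, ref_ind, regimen_ss):
        perp = cfg.perpetrator("trimethoprim")
        bad = dataclasses.replace(
            perp, regimen=dataclasses.replace(perp.regimen, n_doses=30))
        with pytest.raises(ip.ValidationError):
            ip.simulate(ref_ind, cfg.drug, regimen_ss, perpetrator=bad,
                        kdeg=cfg.system.kdeg)


class TestNca:
    def _flat_result(self, c=2.0):
        t = np.linspace(0.0, 24.0, 241)
        return ip.SimulationResult(
            time=t, plasma_conc=np.full_like(t, c), amounts={}, eliminated={},
            enzyme_activity={}, metrics={},
            regimen=ip.DoseRegimen(100.0, 24.0, 1))

    def test_constant_concentration(self):
        m = ip.nca(self._flat_result(2.0), (0.0, 24.0))
        assert m["auc_0_24_ss"] == pytest.approx(48.0, rel=1e-12)
        assert m["css_max"] == m["css_min"] == 2.0
        assert m["cl_over_f"] == pytest.approx(100.0 / 48.0)

    def test_interval_outside_span_rejected(self):
        with pytest.raises(ip.DomainError):
            ip.nca(self._flat_result(), (0.0, 48.0))

    def test_coarse_grid_rejected(self):
        res = self._flat_result()
        res.time = res.time[::10]
        res.plasma_conc = res.plasma_conc[::10]
        with pytest.raises(ip.DomainError):
            ip.nca(res, (0.0, 24.0))

    def test_steady_state_profile_matches_superposition(self, cfg):
        """Linear-mode day-14 AUC equals the single-dose AUC(0-inf)."""
        drug, system = cfg.drug, cfg.system
        ind = ip.sample_individual(system, {}, 8, drug=drug)
        ss = ip.simulate(ind, drug, ip.DoseRegimen(400.0, 24.0, 14),
                         options=ip.SolverOptions.linear(), kdeg=system.kdeg)
        expected = closed_form_oral_auc(ind, drug, 400.0)
        assert ss.metrics["auc_0_24_ss"] == pytest.approx(expected, rel=0.005)


class TestEnzymeSteadyState:
    @pytest.mark.parametrize("e0,kdeg,inact,ind_m,expected", [
        (1.0, 0.0158, 0.0, 1.0, 1.0),
        (1.0, 0.0158, 0.0158, 1.0, 0.5),
        (0.8, 0.02, 0.0, 2.0, 1.6),
    ])
    def test_closed_form(self, e0, kdeg, inact, ind_m, expected):
        assert ip.enzyme_steady_state(e0, kdeg, inact, ind_m) == \
            pytest.approx(expected, rel=1e-12)

    def test_half_saturation_substitution(self):
        # unbound drug at KI -> inactivation at kinact/2
        kdeg, kinact = 0.0158, 0.25
        assert ip.enzyme_steady_state(1.0, kdeg, kinact / 2.0) == \
            pytest.approx(kdeg / (kdeg + kinact / 2.0), rel=1e-12)

    def test_ode_converges_to_closed_form(self):
        """Turnover trajectory reaches the analytic plateau within 1%
        after 5/kdeg hours at constant drivers."""
        from scipy.integrate import odeint
        kdeg, inact, s = 0.0158, 0.021, 1.0
        sol = odeint(lambda e, t: kdeg * s - e * (kdeg + inact),
                     [1.0], [0.0, 5.0 / kdeg])
        assert sol[-1, 0] == pytest.approx(
            ip.enzyme_steady_state(1.0, kdeg, inact, s), rel=0.01)
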