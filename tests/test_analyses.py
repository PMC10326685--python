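"""Trial machinery, summary statistics and DDI ratio studies."""

import dataclasses
import itertools
import math

import numpy as np
import pytest
from scipy import stats

import imatinib_pbpk as ip


@pytest.fixture(scope="module")
def small_design():
    return ip.TrialDesign(n_trials=2, n_subjects=5, seed=11)


@pytest.fixture(scope="module")
def short_regimen():
    # 4 once-daily doses: enough for metric extraction, cheap to integrate
    return ip.DoseRegimen(dose=400.0, interval=24.0, n_doses=4)


@pytest.fixture(scope="module")
def small_table(cfg, small_design, short_regimen, pop_opts):
    return ip.run_virtual_trials(small_design, cfg.drug, cfg.system,
                                 short_regimen, options=pop_opts)


class TestGeomeanCi:
    def test_log_symmetry(self):
        assert ip.geomean_ci([1.0, 100.0])["gm"] == pytest.approx(10.0, rel=1e-12)

    def test_degenerate_zero_width(self):
        g = ip.geomean_ci([3.0, 3.0, 3.0])
        assert g["gm"] == pytest.approx(3.0)
        assert g["ci"][0] == pytest.approx(3.0) and g["ci"][1] == pytest.approx(3.0)

    def test_hand_computed_t_interval(self):
        # {2,4,8}: GM 4; se = ln2/sqrt(3); t(.975, 2) = 4.302653;
        # CI = 4 * exp(-+ 4.302653 * 0.400187) = (0.71497, 22.3786)
        g = ip.geomean_ci([2.0, 4.0, 8.0], level=0.95)
        assert g["gm"] == pytest.approx(4.0, rel=1e-12)
        assert g["ci"][0] == pytest.approx(0.714924, rel=1e-5)
        assert g["ci"][1] == pytest.approx(22.37999, rel=1e-5)

    def test_domain_errors(self):
        with pytest.raises(ip.DomainError):
            ip.geomean_ci([1.0])
        with pytest.raises(ip.DomainError):
            ip.geomean_ci([1.0, -2.0])


def _kruskal_h(x, y):
    """Rank-formula H for two groups (hand implementation, tie-free)."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n = pooled.size
    rx, ry = ranks[:len(x)], ranks[len(x):]
    return 12.0 / (n * (n + 1)) * (
        len(x) * (rx.mean() - (n + 1) / 2) ** 2
        + len(y) * (ry.mean() - (n + 1) / 2) ** 2)


class TestKruskalWallis:
    def test_frozen_example(self):
        """{1,2,3,4} vs {10,20,30,40}: H = 16/3, p ~ 0.021 (chi-square)."""
        res = stats.kruskal([1, 2, 3, 4], [10, 20, 30, 40])
        assert res.statistic == pytest.approx(16.0 / 3.0, rel=1e-10)
        assert res.pvalue == pytest.approx(0.0209, abs=5e-4)

    @pytest.mark.parametrize("n1,n2", [(3, 3), (4, 4), (4, 6), (6, 6)])
    def test_matches_exact_permutation_oracle(self, n1, n2):
        """H equals the rank formula for every size; the chi-square p tracks
        the exact permutation distribution once groups reach n >= 4 (the
        asymptotic approximation is known to be poor at 3 per group)."""
        rng = np.random.default_rng(n1 * 10 + n2)
        x = rng.normal(0.8, 1.0, n1)
        y = rng.normal(0.0, 1.0, n2)
        res = stats.kruskal(x, y)
        assert res.statistic == pytest.approx(_kruskal_h(x, y), rel=1e-10)
        pooled = np.concatenate([x, y])
        h_obs = res.statistic
        count = total = 0
        for idx in itertools.combinations(range(n1 + n2), n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(idx)] = True
            total += 1
            if _kruskal_h(pooled[mask], pooled[~mask]) >= h_obs - 1e-12:
                count += 1
        p_exact = count / total
        if min(n1, n2) >= 4:
            assert res.pvalue == pytest.approx(p_exact, abs=0.05)


class TestCompareGroups:
    def test_identical_groups(self):
        import pandas as pd
        vals = np.array([1.0, 2.0, 3.0, 4.0] * 2)
        table = pd.DataFrame({m: vals for m in ip.METRICS})
        out = ip.compare_groups(table, [True] * 4 + [False] * 4)
        for m in ip.METRICS:
            assert out[m]["gm_ratio"] == pytest.approx(1.0)
            assert out[m]["p_kruskal_wallis"] > 0.9

    def test_separated_groups_significant(self):
        import pandas as pd
        vals = np.concatenate([[1, 2, 3, 4], [10, 20, 30, 40]]).astype(float)
        table = pd.DataFrame({m: vals for m in ip.METRICS})
        out = ip.compare_groups(table, [True] * 4 + [False] * 4)
        assert out["auc_0_24_ss"]["p_kruskal_wallis"] == pytest.approx(0.0209, abs=5e-4)
        assert out["auc_0_24_ss"]["significant"]

    def test_small_group_rejected(self, small_table):
        with pytest.raises(ip.DomainError):
            ip.compare_groups(small_table, [True] + [False] * (len(small_table) - 1))


class TestRunVirtualTrials:
    def test_shape_and_determinism(self, cfg, small_design, short_regimen, pop_opts,
                                   small_table):
        assert len(small_table) == 10
        again = ip.run_virtual_trials(small_design, cfg.drug, cfg.system,
                                      short_regimen, options=pop_opts)
        assert small_table.equals(again)

    def test_sex_mix_fixed_per_trial(self, small_design):
        sexes = [small_design.subject_sex(s) for s in range(5)]
        assert sexes.count("F") == 2  # 0.4 * 5

    def test_dose_doubling_in_linear_mode(self, cfg, small_design, short_regimen):
        opts = ip.SolverOptions(autoinhibition=False, saturable_binding=False,
                                rtol=1e-8, atol=1e-10)
        lo = ip.run_virtual_trials(small_design, cfg.drug, cfg.system,
                                   short_regimen, options=opts)
        hi_reg = ip.DoseRegimen(800.0, 24.0, 4)
        opts_hi = dataclasses.replace(opts, atol=2e-10)
        hi = ip.run_virtual_trials(small_design, cfg.drug, cfg.system,
                                   hi_reg, options=opts_hi)
        ratios = hi["auc_0_24_ss"].to_numpy() / lo["auc_0_24_ss"].to_numpy()
        assert np.allclose(ratios, 2.0, rtol=1e-6)


class TestSensitivitySweep:
    def test_single_level_fold_is_one(self, cfg, small_design, short_regimen, pop_opts):
        res = ip.sensitivity_sweep("AAG", [0.91], small_design, cfg.drug,
                                   cfg.system, short_regimen, options=pop_opts)
        assert all(f == pytest.approx(1.0) for f in res["fold_change"].values())

    def test_unknown_parameter_rejected(self, cfg, small_design, short_regimen):
        with pytest.raises(ip.ConfigurationError):
            ip.sensitivity_sweep("CYP9Z9", [1, 2], small_design, cfg.drug,
                                 cfg.system, short_regimen)

    def test_gut_cyp3a4_has_no_significant_effect(self, cfg, regimen_ss, pop_opts):
        """Enterocyte CYP3A4 across its range barely moves steady-state AUC."""
        design = ip.TrialDesign(n_trials=2, n_subjects=5, seed=21)
        res = ip.sensitivity_sweep("CYP3A4_gut", [5.0, 250.0], design, cfg.drug,
                                   cfg.system, regimen_ss, options=pop_opts)
        fold = res["fold_change"]["auc_0_24_ss"]
        assert 0.85 < fold < 1.0  # small decrease only
        assert res["p_kruskal_wallis_auc"] > 0.05

    def test_cyp2c8_sweep_monotone(self, cfg, regimen_ss, pop_opts):
        design = ip.TrialDesign(n_trials=1, n_subjects=4, seed=5)
        res = ip.sensitivity_sweep("CYP2C8_hepatic", [1e-6, 22.4, 85.0], design,
                                   cfg.drug, cfg.system, regimen_ss, options=pop_opts)
        gms = [res["summary"]["auc_0_24_ss"][str(v)]["gm"]
               for v in (1e-6, 22.4, 85.0)]
        assert gms[0] > gms[1] > gms[2]


class TestDdiStudy:
    def test_null_perpetrator_gmr_exactly_one(self, cfg, small_design,
                                              short_regimen, pop_opts):
        """Zero-dose perpetrator: paired seeds give GMR 1.0 to machine precision."""
        perp = cfg.perpetrator("diltiazem")
        null = dataclasses.replace(
            perp, regimen=dataclasses.replace(perp.regimen, dose=0.0, n_doses=16))
        res = ip.ddi_study(cfg.drug, cfg.system, short_regimen, null,
                           small_design, options=pop_opts)
        for g in res["gmr"].values():
            assert abs(g.ratio - 1.0) < 1e-12
            assert not g.clinically_significant

    def test_no_interaction_terms_gmr_exactly_one(self, cfg, small_design,
                                                  short_regimen, pop_opts):
        perp = dataclasses.replace(cfg.perpetrator("trimethoprim"),
                                   interactions=[],
                                   regimen=ip.Regimen(300.0, 24.0, 4, 0.0))
        res = ip.ddi_study(cfg.drug, cfg.system, short_regimen, perp,
                           small_design, options=pop_opts)
        assert all(abs(g.ratio - 1.0) < 1e-12 for g in res["gmr"].values())

    def test_gmr_approaches_one_as_ki_grows(self, cfg, small_design,
                                            short_regimen, pop_opts):
        """Competitive CYP2C8 inhibition washes out monotonically with Ki."""
        base = cfg.perpetrator("trimethoprim")
        gmrs = []
        for ki in (1.0, 30.0, 1000.0):
            ix = [dataclasses.replace(base.interactions[0],
                                      parameters={"ki_uM": ki})]
            perp = dataclasses.replace(base, interactions=ix,
                                       regimen=ip.Regimen(300.0, 24.0, 4, 0.0))
            res = ip.ddi_study(cfg.drug, cfg.system, short_regimen, perp,
                               small_design, options=pop_opts)
            gmrs.append(res["gmr"]["auc_0_24_ss"].ratio)
        assert gmrs[0] > gmrs[1] > gmrs[2] > 1.0
        assert gmrs[2] == pytest.approx(1.0, abs=0.01)

    def test_steady_state_gmr_below_single_dose_gmr(self, cfg, pop_opts):
        """CYP3A4 inhibitor interaction shrinks at steady state because the
        drug's own autoinhibition has already suppressed hepatic CYP3A4."""
        design = ip.TrialDesign(n_trials=1, n_subjects=4, seed=9)
        dilt = cfg.perpetrator("diltiazem")
        ss = ip.ddi_study(cfg.drug, cfg.system,
                          ip.DoseRegimen(400.0, 24.0, 14), dilt, design,
                          options=pop_opts)
        # single victim dose with the perpetrator pre-dosed for a week
        pre = dataclasses.replace(
            dilt, regimen=dataclasses.replace(dilt.regimen, start_offset=-168.0,
                                              n_doses=32))
        sd = ip.ddi_study(cfg.drug, cfg.system, ip.DoseRegimen(400.0, 24.0, 1),
                          pre, design, options=pop_opts)
        assert ss["gmr"]["auc_0_24_ss"].ratio < sd["gmr"]["auc_0_24_ss"].ratio


class TestCohortSimulation:
    def test_comedication_applied(self, cfg, pop_opts):
        from imatinib_pbpk.population import PatientRecord
        recs = [
            PatientRecord(id="A", age=55, sex="M", ancestry="European",
                          dose_mg_per_day=400.0),
            PatientRecord(id="B", age=55, sex="M", ancestry="European",
                          dose_mg_per_day=400.0, comedications=["clopidogrel"]),
        ]
        perps = {p.name: p for p in cfg.perpetrators}
        out = ip.simulate_cohort_records(recs, cfg.drug, cfg.system, seed=3,
                                         perpetrators=perps, options=pop_opts)
        assert len(out) == 2
        # the CYP2C8-inhibited subject, compared against itself without the
        # comedication (same seed substream), shows higher exposure
        ctrl = ip.simulate_cohort_records(
            [recs[0], dataclasses.replace(recs[1], comedications=[])],
            cfg.drug, cfg.system, seed=3, perpetrators=perps, options=pop_opts)
        assert out["auc_0_24_ss"][1] > 1.2 * ctrl["auc_0_24_ss"][1]
        assert out["auc_0_24_ss"][0] == ctrl["auc_0_24_ss"][0]
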