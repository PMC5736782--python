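"""Reservoir bookkeeping, first-order absorption fits, AUC and mass balance."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from pgp_lungdisp.ipml_kinetics import (
    PerfusateProfile,
    Verdict,
    auc_0_30,
    cumulative_absorbed,
    fit_first_order,
    ipml_qc,
    lung_retention,
    retention_difference,
    sampling_corrected_mass,
)
from pgp_lungdisp.synthetic_data import IpmlSimSpec, gen_ipml_arm


def _pct_curve(t, f, ka):
    return 100.0 * f * (1.0 - np.exp(-ka * np.asarray(t, dtype=float)))


class TestCumulativeAbsorbed:
    def test_hand_bookkeeping_example(self):
        profile = PerfusateProfile(
            times=[5.0, 10.0],
            reservoir_concentrations=[1.0, 1.0],
            deposited_dose=20.0,
            reservoir_volume=10.0,
            sample_volume=0.25,
        )
        series = cumulative_absorbed(profile)
        np.testing.assert_allclose(series["cumulative_nmol"], [10.0, 10.25])
        np.testing.assert_allclose(series["cumulative_pct_dose"], [50.0, 51.25])

    def test_zero_concentrations_give_zero_mass(self):
        profile = PerfusateProfile(
            times=[2.0, 5.0, 10.0],
            reservoir_concentrations=[0.0, 0.0, 0.0],
            deposited_dose=1.0,
        )
        assert (cumulative_absorbed(profile)["cumulative_nmol"] == 0).all()

    def test_recovers_simulator_ground_truth_exactly(self):
        spec = IpmlSimSpec(seed=11, cv=0.0, f=0.4, ka=0.15, n_replicates=1)
        profile = gen_ipml_arm(spec)[0]
        truth = profile.deposited_dose * spec.f * (
            1.0 - np.exp(-spec.ka * profile.times)
        )
        series = cumulative_absorbed(profile)
        np.testing.assert_allclose(series["cumulative_nmol"], truth, rtol=1e-9)

    def test_mass_conservation_at_zero_noise(self):
        # removed samples + what is left in the reservoir == everything that entered
        spec = IpmlSimSpec(seed=3, cv=0.0, f=0.7, ka=0.05, n_replicates=1)
        profile = gen_ipml_arm(spec)[0]
        c = profile.reservoir_concentrations
        removed = np.sum(c * profile.sample_volume)
        remaining = c[-1] * (profile.reservoir_volume - profile.sample_volume)
        entered = profile.deposited_dose * spec.f * (
            1.0 - np.exp(-spec.ka * profile.times[-1])
        )
        assert removed + remaining == pytest.approx(entered, rel=1e-9)

    @given(
        concs=st.lists(st.floats(0.0, 50.0), min_size=1, max_size=12),
        vs=st.floats(0.01, 0.9),
    )
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_correction_identity(self, concs, vs):
        # algebraic identity: M_n = removed(<=n) + remaining after sample n
        c = np.asarray(concs)
        mass = sampling_corrected_mass(c, 10.0, vs)
        removed = np.cumsum(c * vs)
        remaining = c * (10.0 - vs)
        np.testing.assert_allclose(mass, removed + remaining, rtol=1e-12, atol=1e-12)

    def test_invalid_profiles_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            PerfusateProfile(times=[0.0, 5.0], reservoir_concentrations=[0, 1],
                             deposited_dose=1.0)
        with pytest.raises(ValueError, match="non-negative"):
            PerfusateProfile(times=[5.0], reservoir_concentrations=[-1.0],
                             deposited_dose=1.0)
        with pytest.raises(ValueError, match="sample volume"):
            PerfusateProfile(times=[5.0], reservoir_concentrations=[1.0],
                             deposited_dose=1.0, sample_volume=11.0)


class TestFirstOrderFit:
    def test_noiseless_recovery(self):
        t = np.array([2, 5, 10, 15, 20, 30], dtype=float)
        fit = fit_first_order(t, _pct_curve(t, 0.5, 0.1))
        assert fit.f == pytest.approx(0.5, abs=1e-6)
        assert fit.ka == pytest.approx(0.1, abs=1e-6)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)

    def test_two_point_exact_solution_matches_algebraic_oracle(self):
        t1, t2 = 5.0, 15.0
        y1, y2 = _pct_curve([t1, t2], 0.4, 0.2)
        # closed-form inversion: the ratio y2/y1 pins Ka, then F follows
        ka_oracle = brentq(
            lambda k: y1 * (1 - np.exp(-k * t2)) - y2 * (1 - np.exp(-k * t1)),
            1e-6,
            5.0,
        )
        f_oracle = y1 / (100.0 * (1 - np.exp(-ka_oracle * t1)))
        fit = fit_first_order([t1, t2], [y1, y2])
        assert fit.ka == pytest.approx(ka_oracle, rel=1e-6)
        assert fit.f == pytest.approx(f_oracle, rel=1e-6)
        assert fit.f == pytest.approx(0.4, rel=1e-6)

    def test_fit_idempotence(self):
        t = np.array([2, 5, 10, 15, 20, 30], dtype=float)
        rng = np.random.default_rng(7)
        y = _pct_curve(t, 0.3, 0.08) * rng.lognormal(0, 0.05, len(t))
        first = fit_first_order(t, y)
        second = fit_first_order(t, np.asarray(first.predict(t)))
        assert second.f == pytest.approx(first.f, rel=1e-6)
        assert second.ka == pytest.approx(first.ka, rel=1e-6)

    def test_rate_constant_less_precise_than_extent_under_noise(self):
        # sparse 6-point schedules pin F well but leave Ka poorly identified
        schedule = np.array([2, 5, 10, 15, 20, 30], dtype=float)
        rng = np.random.default_rng(42)
        ka_cvs, f_cvs = [], []
        for _ in range(200):
            y = _pct_curve(schedule, 0.3, 0.1) * rng.lognormal(0, 0.05, len(schedule))
            fit = fit_first_order(schedule, np.clip(y, 0, 110))
            ka_cvs.append(fit.ka_cv_pct)
            f_cvs.append(fit.f_cv_pct)
        assert np.median(ka_cvs) > np.median(f_cvs)

    def test_all_zero_series_unidentifiable(self):
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_first_order([2, 5, 10], [0.0, 0.0, 0.0])


class TestAuc:
    def test_constant_zero(self):
        assert auc_0_30([5, 10, 30], [0, 0, 0]).auc_0_30 == 0.0

    def test_constant_hundred_from_t0_is_upper_bound(self):
        assert auc_0_30([0, 30], [100, 100]).auc_0_30 == pytest.approx(3000.0)

    def test_dense_grid_matches_analytic_integral(self):
        f, ka = 0.5, 0.1
        t = np.arange(1, 31, dtype=float)
        analytic = 100 * f * (30 - (1 - np.exp(-30 * ka)) / ka)
        assert analytic == pytest.approx(1024.9, abs=0.05)
        result = auc_0_30(t, _pct_curve(t, f, ka))
        assert result.auc_0_30 == pytest.approx(analytic, rel=0.005)

    def test_flat_carry_to_30(self):
        # last sample at 20 min: value carried flat over the last 10 min
        res = auc_0_30([10.0, 20.0], [10.0, 10.0])
        assert res.auc_0_30 == pytest.approx(0.5 * 10 * 10 + 10 * 10 + 10 * 10)

    def test_monotone_in_extent(self):
        t = np.array([2, 5, 10, 15, 20, 30], dtype=float)
        aucs = [auc_0_30(t, _pct_curve(t, f, 0.1)).auc_0_30 for f in (0.2, 0.4, 0.8)]
        assert aucs[0] < aucs[1] < aucs[2]

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            auc_0_30([], [])


class TestMassBalance:
    def test_printed_retention_difference(self):
        # inhaled archetype: retained 74.5% (WT) vs 58.3% (KO)
        diff = retention_difference(74.5, 58.3)
        assert diff == pytest.approx(16.2)
        assert round(diff) == 16

    def test_nothing_absorbed_is_fully_retained(self):
        mb = lung_retention(deposited_dose=1.0, absorbed_to_perfusate=0.0)
        assert mb.retained_pct == 100.0
        assert mb.absorbed_pct + mb.retained_pct == pytest.approx(100.0)

    def test_synthetic_fraction_round_trip(self):
        for f in (0.1, 0.37, 0.93):
            mb = lung_retention(deposited_dose=2.0, absorbed_to_perfusate=2.0 * f)
            assert mb.retained_pct == pytest.approx(100 * (1 - f), rel=1e-9)

    def test_overdraw_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            lung_retention(deposited_dose=1.0, absorbed_to_perfusate=1.5)


class TestIpmlQc:
    @pytest.mark.parametrize(
        "mannitol, verdict",
        [(66.0, Verdict.EXCLUDE), (65.0, Verdict.KEEP), (44.3, Verdict.KEEP)],
    )
    def test_mannitol_rule_boundary(self, mannitol, verdict):
        assert ipml_qc(mannitol).verdict is verdict

    def test_wet_dry_is_advisory_only(self):
        res = ipml_qc(40.0, wet_dry_ratio=9.9)
        assert res.verdict is Verdict.KEEP
        assert res.wet_dry_ratio == 9.9
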