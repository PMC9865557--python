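import io

import numpy as np
import pytest

from ilscale import (
    FreeEnergyEstimate,
    LambdaSeries,
    WorkSet,
    bootstrap_sd,
    combine_stages,
    exp_estimator,
    generate_gaussian_works,
    integrate_dhdl,
    transfer_free_energy,
)
from ilscale.constants import KB_KJ
from ilscale.errors import PairingError, ScheduleError, UnitError
from ilscale.neq import read_lambda_series, read_workset, write_workset


def naive_exp(works):
    """Independent reference: direct exponential average (moderate works only)."""
    return -np.log(np.mean(np.exp(-np.asarray(works, dtype=float))))


class TestIntegrateDhdl:
    def test_constant_integrand(self):
        s = LambdaSeries(lam=[0, 0.5, 1.0], dhdl=[3.2, 3.2, 3.2])
        assert integrate_dhdl(s) == pytest.approx(3.2)

    def test_linear_integrand_dense(self):
        lam = np.linspace(0, 1, 10001)
        s = LambdaSeries(lam=lam, dhdl=2 * lam)
        assert integrate_dhdl(s) == pytest.approx(1.0, abs=1e-6)

    def test_three_point_trapezoid(self):
        s = LambdaSeries(lam=[0, 0.5, 1.0], dhdl=[0.0, 4.0, 0.0])
        assert integrate_dhdl(s) == pytest.approx(2.0)

    def test_kj_units_convert_to_kt(self):
        t = 298.0
        s = LambdaSeries(lam=[0, 1.0], dhdl=[KB_KJ * t, KB_KJ * t],
                         units="kJ/mol", temperature=t)
        assert integrate_dhdl(s) == pytest.approx(1.0)

    def test_decreasing_lambda_rejected(self):
        with pytest.raises(ScheduleError):
            LambdaSeries(lam=[0, 0.6, 0.4, 1.0], dhdl=[0, 1, 1, 0])

    def test_endpoints_enforced(self):
        with pytest.raises(ScheduleError):
            LambdaSeries(lam=[0.1, 1.0], dhdl=[1, 1])
        with pytest.raises(ScheduleError):
            LambdaSeries(lam=[0.0, 0.9], dhdl=[1, 1])


class TestExpEstimator:
    def test_degenerate_distribution(self):
        ws = WorkSet(works=[2.5] * 10)
        assert exp_estimator(ws).value_kt == pytest.approx(2.5)

    def test_single_realization_exact(self):
        assert exp_estimator(WorkSet(works=[7.25])).value_kt == pytest.approx(7.25)

    def test_two_work_arithmetic(self):
        ws = WorkSet(works=[1.0, 2.0])
        expect = -np.log((np.exp(-1.0) + np.exp(-2.0)) / 2)
        assert exp_estimator(ws).value_kt == pytest.approx(expect, abs=1e-12)
        assert expect == pytest.approx(1.3799, abs=1e-4)

    def test_gaussian_closed_form(self):
        # for W ~ N(mu, s^2), EXP converges to mu - s^2/2
        rng = np.random.default_rng(123)
        ws = WorkSet(works=rng.normal(5.0, np.sqrt(2.0), size=10**5))
        assert exp_estimator(ws).value_kt == pytest.approx(4.0, abs=0.05)

    def test_agrees_with_naive_reference(self):
        rng = np.random.default_rng(99)
        for _ in range(20):
            n = int(rng.integers(2, 1000))
            works = rng.normal(rng.uniform(-3, 3), rng.uniform(0.1, 2), size=n)
            est = exp_estimator(WorkSet(works=works)).value_kt
            assert est == pytest.approx(naive_exp(works), abs=1e-8)

    def test_jensen_upper_bound(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            works = rng.normal(0, rng.uniform(0.1, 3), size=int(rng.integers(2, 200)))
            ws = WorkSet(works=works)
            assert exp_estimator(ws).value_kt <= np.mean(works) + 1e-12

    def test_extreme_works_do_not_overflow(self):
        ws = WorkSet(works=[-1000.0, 0.0, 1000.0])
        v = exp_estimator(ws).value_kt
        assert np.isfinite(v)
        assert v == pytest.approx(-1000.0 + np.log(3), abs=1e-9)

    def test_finite_sample_bias_is_positive(self):
        # EXP overestimates dG at finite n; sigma_w = 2 kT, n = 100
        ests = [
            exp_estimator(generate_gaussian_works(0.0, 2.0, 100, seed=s)).value_kt
            for s in range(200)
        ]
        sem = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert np.mean(ests) > 3 * sem

    def test_non_finite_work_names_realization(self):
        with pytest.raises(ValueError, match="r7"):
            WorkSet(works=[1.0, np.inf], ids=["r3", "r7"])


class TestBootstrap:
    def test_identical_works_zero_sd(self):
        ws = WorkSet(works=[1.5] * 20)
        assert bootstrap_sd(ws, 200, seed=1) == 0.0

    def test_deterministic_for_seed(self):
        ws = generate_gaussian_works(2.0, 1.0, 50, seed=3)
        assert bootstrap_sd(ws, 500, seed=9) == bootstrap_sd(ws, 500, seed=9)

    def test_matches_replication_sd(self):
        # bootstrap SD should track the SD over independent replications;
        # average over worksets since a single bootstrap SD is itself noisy
        n, b = 1000, 1000
        boot = np.mean([
            bootstrap_sd(generate_gaussian_works(0.0, 1.0, n, seed=s), b,
                         seed=s + 1)
            for s in range(10)
        ])
        reps = [
            exp_estimator(generate_gaussian_works(0.0, 1.0, n, seed=1000 + s)).value_kt
            for s in range(400)
        ]
        truth = np.std(reps, ddof=1)
        assert abs(boot - truth) <= 0.25 * truth

    def test_single_realization_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_sd(WorkSet(works=[1.0]), 200, seed=0)


class TestCombineStages:
    def test_zero_charging_stage_is_identity(self):
        vdw = WorkSet(works=[1.0, 2.0, 3.0], stage="vdw-coupling")
        chg = WorkSet(works=[0.0, 0.0, 0.0], stage="charging")
        total = combine_stages(vdw, chg)
        assert exp_estimator(total).value_kt == pytest.approx(
            exp_estimator(vdw).value_kt)

    def test_degenerate_stages_sum_under_both_modes(self):
        vdw = WorkSet(works=[1.2] * 8, stage="vdw-coupling")
        chg = WorkSet(works=[0.7] * 8, stage="charging")
        per_real = exp_estimator(combine_stages(vdw, chg)).value_kt
        per_stage = combine_stages(vdw, chg, mode="per-stage").value_kt
        assert per_real == pytest.approx(1.9)
        assert per_stage == pytest.approx(1.9)

    def test_pairing_respects_ids_not_order(self):
        vdw = WorkSet(works=[1.0, 2.0], ids=["a", "b"], stage="vdw-coupling")
        chg = WorkSet(works=[10.0, 20.0], ids=["b", "a"], stage="charging")
        total = combine_stages(vdw, chg)
        paired = dict(zip(total.ids, total.works))
        assert paired == {"b": 12.0, "a": 21.0}

    def test_mismatched_ids_raise(self):
        vdw = WorkSet(works=[1.0, 2.0], ids=["a", "b"])
        chg = WorkSet(works=[1.0, 2.0], ids=["a", "c"])
        with pytest.raises(PairingError):
            combine_stages(vdw, chg)

    def test_gaussian_stages_per_stage_closed_form(self):
        vdw = generate_gaussian_works(3.0, 1.0, 10**5, seed=10, stage="vdw-coupling")
        chg = generate_gaussian_works(-1.0, 0.5, 10**5, seed=11, stage="charging")
        est = combine_stages(vdw, chg, mode="per-stage", n_resamples=100, seed=0)
        assert est.value_kt == pytest.approx(2.0, abs=0.05)


class TestTransfer:
    def test_cancellation(self):
        a = FreeEnergyEstimate(value_kt=-3.0, sd_kt=0.2)
        d = transfer_free_energy(a, a)
        assert d.value_kt == 0.0
        assert d.sd_kt == pytest.approx(np.sqrt(2) * 0.2)

    def test_kcal_arithmetic(self):
        il = FreeEnergyEstimate.from_kcal(-5.0, 0.3)
        water = FreeEnergyEstimate.from_kcal(-3.0, 0.4)
        d = transfer_free_energy(il, water)
        assert d.value_kcal == pytest.approx(-2.0)
        assert d.sd_kcal == pytest.approx(0.5)

    def test_zero_water_reference_is_identity(self):
        il = FreeEnergyEstimate(value_kt=-4.2, sd_kt=0.1)
        d = transfer_free_energy(il, FreeEnergyEstimate(value_kt=0.0, sd_kt=0.0))
        assert d.value_kt == pytest.approx(-4.2)
        assert d.sd_kt == pytest.approx(0.1)

    def test_temperature_mismatch(self):
        a = FreeEnergyEstimate(value_kt=1.0, temperature=298.0)
        b = FreeEnergyEstimate(value_kt=1.0, temperature=310.0)
        with pytest.raises(UnitError):
            transfer_free_energy(a, b)

    def test_kcal_kt_consistency(self):
        est = FreeEnergyEstimate(value_kt=-8.0, sd_kt=0.5, temperature=298.0)
        assert est.value_kcal == pytest.approx(-8.0 * 0.0019872041 * 298.0)


class TestIO:
    def test_workset_round_trip(self):
        ws = generate_gaussian_works(1.0, 0.5, 25, seed=2)
        buf = io.StringIO()
        write_workset(ws, buf)
        buf.seek(0)
        again = read_workset(buf)
        np.testing.assert_allclose(again.works, ws.works, rtol=1e-10)

    def test_kj_per_mol_units_converted(self):
        t = 300.0
        text = f"# units: kJ/mol\nr1 {KB_KJ * t:.10f}\n"
        ws = read_workset(io.StringIO(text), temperature=t)
        assert ws.works[0] == pytest.approx(1.0)

    def test_xvg_comments_tolerated(self):
        text = ('@ title "dhdl"\n# comment\n0.0 1.0\n0.5 1.0\n1.0 1.0\n')
        s = read_lambda_series(io.StringIO(text))
        assert integrate_dhdl(s) == pytest.approx(1.0)
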