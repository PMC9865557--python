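import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ilscale import (
    PairedData,
    compute_report,
    error_metrics,
    generate_paired_dataset,
    kendall_tau,
    outlier_counts,
    pearlman_pi,
    pearson_r,
)
from ilscale.errors import UndefinedMetricError
from ilscale.metrics import read_paired_csv


def paired(calc, expt):
    return PairedData(labels=list(range(len(calc))), calc=calc, expt=expt)


def brute_tau_b(calc, expt):
    """Tie-corrected Kendall tau by explicit enumeration over pairs."""
    calc, expt = np.asarray(calc), np.asarray(expt)
    n = len(calc)
    conc = disc = ties_c = ties_e = 0
    for i in range(n):
        for j in range(i + 1, n):
            dc, de = calc[j] - calc[i], expt[j] - expt[i]
            if dc == 0 and de == 0:
                ties_c += 1
                ties_e += 1
            elif dc == 0:
                ties_c += 1
            elif de == 0:
                ties_e += 1
            elif dc * de > 0:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) // 2
    return (conc - disc) / np.sqrt((n0 - ties_c) * (n0 - ties_e))


def brute_pi(calc, expt):
    """Pearlman's predictive index by explicit enumeration over pairs."""
    calc, expt = np.asarray(calc), np.asarray(expt)
    num = den = 0.0
    n = len(calc)
    for i in range(n):
        for j in range(i + 1, n):
            w = abs(expt[j] - expt[i])
            dc = calc[j] - calc[i]
            de = expt[j] - expt[i]
            if dc == 0:
                c = 0.0
            elif de / dc > 0:
                c = 1.0
            else:
                c = -1.0
            num += w * c
            den += w
    return num / den


class TestErrorMetrics:
    def test_perfect_agreement(self):
        d = paired([1.0, 2.0], [1.0, 2.0])
        assert error_metrics(d) == (0.0, 0.0, 0.0)

    def test_symmetric_errors(self):
        d = paired([1.0, -1.0], [0.0, 0.0])
        mae, mse, rmse = error_metrics(d)
        assert (mae, mse, rmse) == (1.0, 0.0, 1.0)

    def test_arithmetic(self):
        d = paired([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        mae, mse, rmse = error_metrics(d)
        assert mae == pytest.approx(2.0)
        assert mse == pytest.approx(2.0)
        assert rmse == pytest.approx(np.sqrt(14.0 / 3.0))


class TestKendallTau:
    def test_perfect_concordance(self):
        assert kendall_tau(paired([1, 2, 3], [10, 20, 30])) == pytest.approx(1.0)

    def test_perfect_discordance(self):
        assert kendall_tau(paired([3, 2, 1], [10, 20, 30])) == pytest.approx(-1.0)

    def test_one_swap(self):
        d = paired([1, 2, 3, 4], [1, 3, 2, 4])
        assert kendall_tau(d) == pytest.approx(4.0 / 6.0)

    def test_all_tied_undefined(self):
        with pytest.raises(UndefinedMetricError):
            kendall_tau(paired([1.0, 1.0], [1.0, 2.0]))

    def test_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(3, 20))
            calc = np.round(rng.normal(size=n), 1)  # rounding induces ties
            expt = np.round(rng.normal(size=n), 1)
            if np.ptp(calc) == 0 or np.ptp(expt) == 0:
                continue
            d = paired(calc, expt)
            assert kendall_tau(d) == pytest.approx(brute_tau_b(calc, expt), abs=1e-12)


class TestPearlmanPI:
    def test_comonotonic(self):
        assert pearlman_pi(paired([1, 2, 3], [5, 7, 9])) == pytest.approx(1.0)

    def test_antimonotonic(self):
        assert pearlman_pi(paired([3, 2, 1], [5, 7, 9])) == pytest.approx(-1.0)

    def test_weighted_example(self):
        d = paired([0.0, 2.0, 1.0], [0.0, 1.0, 3.0])
        assert pearlman_pi(d) == pytest.approx(1.0 / 3.0)

    def test_all_expt_equal_undefined(self):
        with pytest.raises(UndefinedMetricError):
            pearlman_pi(paired([1.0, 2.0], [1.0, 1.0]))

    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(2, 20))
            calc = rng.normal(size=n)
            expt = rng.normal(size=n)
            if np.ptp(expt) == 0:
                continue
            d = paired(calc, expt)
            assert pearlman_pi(d) == pytest.approx(brute_pi(calc, expt), abs=1e-12)


class TestPearsonR:
    def test_exact_linearity(self):
        e = np.array([1.0, 2.0, 5.0])
        assert pearson_r(paired(2 * e + 1, e)) == pytest.approx(1.0)
        assert pearson_r(paired(-e, e)) == pytest.approx(-1.0)

    def test_arithmetic(self):
        calc, expt = np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 4.0])
        # direct product-moment formula as an independent check
        num = np.sum((calc - calc.mean()) * (expt - expt.mean()))
        den = np.sqrt(np.sum((calc - calc.mean()) ** 2)
                      * np.sum((expt - expt.mean()) ** 2))
        assert pearson_r(paired(calc, expt)) == pytest.approx(num / den)
        assert num / den == pytest.approx(0.982, abs=1e-3)

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedMetricError):
            pearson_r(paired([1.0, 1.0], [1.0, 2.0]))


class TestOutliers:
    def test_perfect_data(self):
        assert outlier_counts(paired([1.0, 2.0], [1.0, 2.0])) == {1.0: 0, 2.0: 0}

    def test_counting(self):
        d = paired([0.5, 1.5, 2.5], [0.0, 0.0, 0.0])
        assert outlier_counts(d, (1.0, 2.0)) == {1.0: 2, 2.0: 1}

    def test_large_threshold_bound(self):
        d = paired([0.5, 1.5, 2.5], [0.0, 0.0, 0.0])
        assert outlier_counts(d, (10.0,)) == {10.0: 0}


class TestInvariants:
    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.integers(2, 30), st.integers(0, 10**6))
    def test_rmse_mae_mse_ordering(self, n, seed):
        rng = np.random.default_rng(seed)
        d = paired(rng.normal(size=n), rng.normal(size=n))
        mae, mse, rmse = error_metrics(d)
        assert rmse >= mae - 1e-12
        assert mae >= abs(mse) - 1e-12

    def test_affine_invariance_and_negation_flip(self):
        rng = np.random.default_rng(2)
        calc, expt = rng.normal(size=12), rng.normal(size=12)
        d = paired(calc, expt)
        d2 = paired(3.0 * calc + 5.0, 3.0 * expt + 5.0)
        assert kendall_tau(d2) == pytest.approx(kendall_tau(d))
        assert pearlman_pi(d2) == pytest.approx(pearlman_pi(d))
        assert pearson_r(d2) == pytest.approx(pearson_r(d))
        flipped = paired(-calc, expt)
        assert kendall_tau(flipped) == pytest.approx(-kendall_tau(d))
        assert pearlman_pi(flipped) == pytest.approx(-pearlman_pi(d))

    def test_pi_and_tau_agree_in_sign(self):
        # PI reweights pairs by experimental separation, so its sign can
        # differ from tau's near zero; on clearly ranked data they agree
        rng = np.random.default_rng(3)
        for _ in range(30):
            expt = rng.normal(size=10)
            calc = expt + 0.5 * rng.normal(size=10)
            d = paired(calc, expt)
            tau, pi = kendall_tau(d), pearlman_pi(d)
            if abs(tau) > 0.4:
                assert np.sign(pi) == np.sign(tau)
            neg = paired(-calc, expt)
            if abs(tau) > 0.4:
                assert np.sign(pearlman_pi(neg)) == np.sign(kendall_tau(neg))


class TestReportAndIO:
    def test_perfect_synthetic_dataset(self):
        rep = compute_report(generate_paired_dataset(15, 0.0, seed=0))
        assert rep.mae == 0.0
        assert rep.tau == pytest.approx(1.0)
        assert rep.pi == pytest.approx(1.0)
        assert rep.pearson == pytest.approx(1.0)
        assert rep.outliers == {1.0: 0, 2.0: 0}

    def test_csv_round_trip(self):
        csv = "label,calc,expt\na,-3.2,-3.0\nb,-1.0,-2.0\nc,0.5,0.0\n"
        d = read_paired_csv(io.StringIO(csv))
        assert d.n == 3
        rep = compute_report(d)
        assert rep.to_dict()["n"] == 3
        assert "RMSE" in rep.to_json()
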