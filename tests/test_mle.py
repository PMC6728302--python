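import numpy as np
import pytest

from crgof import (
    CRParams,
    CensoredSample,
    cr_sample,
    log_likelihood,
    mle_alpha_given_beta,
    mle_fixed_beta,
    mle_joint,
    score,
    v_transform,
)
from crgof.distributions import cr_logsf, cr_pdf

from conftest import random_censored_sample


def product_form_loglik(s, alpha, beta):
    """Independent oracle: sum log f(x_i) + (n-r) log S(x_r) - r ln 2.

    The working log-likelihood drops the parameter-free constants
    ln[n!/(n-r)!] and r ln 2 relative to the exact censored log-density.
    """
    p = CRParams(alpha, beta)
    ll = float(np.sum(np.log(cr_pdf(s.observed, p))))
    ll += (s.n - s.r) * cr_logsf(s.observed[-1], p)
    return ll - s.r * np.log(2.0)


class TestCensoredSample:
    def test_sorts_internally(self):
        s = CensoredSample(np.array([3.0, 1.0, 2.0]), n=5)
        np.testing.assert_array_equal(s.observed, [1.0, 2.0, 3.0])
        assert s.r == 3 and not s.is_complete

    def test_rejects_nonpositive_values(self):
        with pytest.raises(ValueError):
            CensoredSample(np.array([0.0, 1.0]), n=2)

    def test_rejects_r_above_n(self):
        with pytest.raises(ValueError):
            CensoredSample(np.array([1.0, 2.0]), n=1)


class TestVTransform:
    def test_hand_value(self):
        s = CensoredSample.complete([1.0])
        assert v_transform(s, 1.0)[0] == pytest.approx(np.log(2), abs=1e-12)

    def test_zero_maps_to_zero(self):
        assert v_transform(np.array([0.0]), 2.0)[0] == 0.0

    def test_monotone(self, rng):
        s, p = random_censored_sample(rng)
        assert np.all(np.diff(v_transform(s, p.beta)) >= 0)

    def test_rejects_nonpositive_beta(self):
        with pytest.raises(ValueError):
            v_transform(CensoredSample.complete([1.0]), 0.0)


class TestLogLikelihood:
    def test_hand_value_single_point(self):
        # r=n=1, x=1, alpha=beta=1: ln a - ln b + ln 1 - 2 ln 2
        s = CensoredSample.complete([1.0])
        assert log_likelihood(s, 1.0, 1.0) == pytest.approx(-2 * np.log(2), abs=1e-12)

    def test_censored_item_shifts_by_alpha_vr(self):
        x = [0.5, 1.0, 1.7]
        alpha, beta = 1.3, 0.9
        base = log_likelihood(CensoredSample(np.array(x), n=3), alpha, beta)
        plus1 = log_likelihood(CensoredSample(np.array(x), n=4), alpha, beta)
        vr = float(v_transform(np.array([1.7]), beta)[0])
        assert plus1 - base == pytest.approx(-alpha * vr, abs=1e-12)

    def test_matches_product_form_oracle(self, rng):
        for _ in range(20):
            s, _ = random_censored_sample(rng)
            alpha = float(rng.uniform(0.3, 4))
            beta = float(rng.uniform(0.2, 5))
            assert log_likelihood(s, alpha, beta) == pytest.approx(
                product_form_loglik(s, alpha, beta), abs=1e-10
            )

    def test_rejects_nonpositive_params(self):
        s = CensoredSample.complete([1.0, 2.0])
        with pytest.raises(ValueError):
            log_likelihood(s, -1.0, 1.0)
        with pytest.raises(ValueError):
            log_likelihood(s, 1.0, 0.0)


class TestScore:
    def test_finite_difference_agreement(self, rng):
        h = 1e-6
        for _ in range(20):
            s, _ = random_censored_sample(rng)
            alpha = float(rng.uniform(0.5, 3))
            beta = float(rng.uniform(0.5, 3))
            s_a, s_b = score(s, alpha, beta)
            fd_a = (log_likelihood(s, alpha + h, beta) - log_likelihood(s, alpha - h, beta)) / (2 * h)
            fd_b = (log_likelihood(s, alpha, beta + h) - log_likelihood(s, alpha, beta - h)) / (2 * h)
            assert s_a == pytest.approx(fd_a, rel=1e-6, abs=1e-6)
            assert s_b == pytest.approx(fd_b, rel=1e-6, abs=1e-6)

    def test_alpha_component_zero_at_closed_form(self, rng):
        s, p = random_censored_sample(rng)
        alpha_hat = mle_alpha_given_beta(s, p.beta)
        s_a, _ = score(s, alpha_hat, p.beta)
        assert s_a == pytest.approx(0.0, abs=1e-10)


class TestAlphaGivenBeta:
    def test_hand_value_complete(self):
        s = CensoredSample.complete([1.0, 1.0])
        assert mle_alpha_given_beta(s, 1.0) == pytest.approx(2 / (2 * np.log(2)), abs=1e-12)

    def test_hand_value_censored(self):
        s = CensoredSample(np.array([1.0]), n=2)
        assert mle_alpha_given_beta(s, 1.0) == pytest.approx(1 / (2 * np.log(2)), abs=1e-12)

    def test_is_profile_argmax(self, rng):
        # closed form beats every alpha on a grid at fixed beta
        for _ in range(5):
            s, p = random_censored_sample(rng)
            a_hat = mle_alpha_given_beta(s, p.beta)
            ll_hat = log_likelihood(s, a_hat, p.beta)
            for a in np.geomspace(a_hat / 10, a_hat * 10, 101):
                assert ll_hat >= log_likelihood(s, a, p.beta) - 1e-9

    def test_scale_equivariance(self, rng):
        # x -> c x with beta -> c^2 beta leaves v_i and hence alpha_hat fixed
        s, p = random_censored_sample(rng)
        c = 3.7
        scaled = CensoredSample(s.observed * c, n=s.n)
        assert mle_alpha_given_beta(scaled, p.beta * c**2) == pytest.approx(
            mle_alpha_given_beta(s, p.beta), rel=1e-12
        )


class TestJointMLE:
    def test_stationarity_at_optimum(self, rng):
        for _ in range(10):
            s, _ = random_censored_sample(rng, n_max=40)
            res = mle_joint(s)
            if not res.converged:
                continue  # boundary profiles have no interior stationary point
            s_a, s_b = score(s, res.alpha_hat, res.beta_hat)
            assert abs(s_a) < 1e-8 * s.r
            assert abs(res.beta_hat * s_b) < 1e-8 * s.r

    def test_matches_2d_grid_search(self, rng):
        hits = 0
        for _ in range(5):
            s, _ = random_censored_sample(rng, n_max=12)
            res = mle_joint(s)
            if not res.converged:
                continue
            hits += 1
            # profile maximizer beats a coarse 2-D lattice around it
            for a in np.geomspace(res.alpha_hat / 5, res.alpha_hat * 5, 21):
                for b in np.geomspace(res.beta_hat / 5, res.beta_hat * 5, 21):
                    assert res.log_lik >= log_likelihood(s, a, b) - 1e-8
        assert hits >= 1

    def test_negative_definite_hessian_at_interior_max(self):
        x = cr_sample(200, CRParams(2.0, 1.0), 17)
        s = CensoredSample.complete(x)
        res = mle_joint(s)
        assert res.converged
        h = 1e-4
        a, b = res.alpha_hat, res.beta_hat
        f = lambda aa, bb: log_likelihood(s, aa, bb)
        faa = (f(a + h, b) - 2 * f(a, b) + f(a - h, b)) / h**2
        fbb = (f(a, b + h) - 2 * f(a, b) + f(a, b - h)) / h**2
        fab = (f(a + h, b + h) - f(a + h, b - h) - f(a - h, b + h) + f(a - h, b - h)) / (4 * h**2)
        H = np.array([[faa, fab], [fab, fbb]])
        assert np.all(np.linalg.eigvalsh(H) < 0)

    def test_ordering_invariance(self, rng):
        x = cr_sample(25, CRParams(1.5, 1.0), 23)
        a = mle_joint(CensoredSample.complete(x))
        b = mle_joint(CensoredSample.complete(x[::-1]))
        assert a.alpha_hat == b.alpha_hat and a.beta_hat == b.beta_hat

    def test_identifiability_guard(self):
        with pytest.raises(ValueError):
            mle_joint(CensoredSample.complete([2.0, 2.0, 2.0]))

    def test_fixed_beta_result_fields(self):
        s = CensoredSample.complete([0.5, 1.0, 2.0])
        res = mle_fixed_beta(s, 0.5)
        assert res.beta_fixed == 0.5 and res.converged
        assert res.alpha_hat == pytest.approx(mle_alpha_given_beta(s, 0.5))

    def test_recovery_improves_with_n(self):
        # bias/RMSE of both estimates shrink over n in {50, 200, 800}
        truth = CRParams(2.0, 1.0)
        rmse = []
        for n, seed in [(50, 100), (200, 200), (800, 300)]:
            errs = []
            for k in range(40):
                x = cr_sample(n, truth, seed + k)
                res = mle_joint(CensoredSample.complete(x))
                errs.append([(res.alpha_hat - 2.0) ** 2, (res.beta_hat - 1.0) ** 2])
            rmse.append(np.sqrt(np.mean(errs, axis=0)))
        rmse = np.array(rmse)
        assert np.all(rmse[1] < rmse[0]) and np.all(rmse[2] < rmse[1])
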