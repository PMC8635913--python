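"""Log-moment numerics, composition, and the (epsilon, delta) tail bound."""

import numpy as np
import pytest

from fedchain.accountant import (
    DEFAULT_LAMBDAS,
    MechanismSpec,
    MomentLedger,
    PrivacyBudget,
    accumulate,
    epsilon_for_delta,
    is_exhausted,
    log_moment,
    log_moments,
    sampling_probability,
)


class TestLogMoment:
    def test_q_zero_is_free(self):
        spec = MechanismSpec(q=0.0, noise_std=4.0)
        assert np.all(log_moments(spec) == 0.0)

    def test_q_one_matches_gaussian_closed_form(self):
        """At q=1 the quadrature must reproduce alpha = lam(lam+1)/(2 s^2)."""
        for s in (4.0, 12.0):
            spec = MechanismSpec(q=1.0, noise_std=s)
            a = log_moments(spec)
            lam = np.asarray(DEFAULT_LAMBDAS, dtype=float)
            closed = lam * (lam + 1) / (2 * s**2)
            np.testing.assert_allclose(a, closed, rtol=1e-6)

    def test_matches_monte_carlo_estimate(self):
        """alpha at q=0.1, s=4, lam=8 agrees with a 1e6-draw sampling oracle."""
        q, s, lam = 0.1, 4.0, 8
        rng = np.random.default_rng(123)
        n = 1_000_000
        # draws from the mixture mu
        comp = rng.random(n) < q
        x = rng.normal(0.0, s, size=n) + comp * 1.0
        log_ratio = (2 * x - 1) / (2 * s**2)  # log mu1 - log mu0
        ratio = np.log1p(q * np.expm1(log_ratio))  # log(mu/mu0)
        e2_samples = np.exp(lam * ratio)
        e2_hat, se = e2_samples.mean(), e2_samples.std() / np.sqrt(n)
        alpha = log_moment(MechanismSpec(q=q, noise_std=s), lam)
        assert np.exp(alpha) == pytest.approx(e2_hat, abs=3 * se)

    def test_alpha_nonnegative_and_monotone_in_q(self):
        lam_grid = (1, 4, 16, 64)
        prev = np.zeros(len(lam_grid))
        for q in (0.0, 0.05, 0.2, 0.5, 1.0):
            a = log_moments(MechanismSpec(q=q, noise_std=4.0), lam_grid)
            assert np.all(a >= 0.0)
            assert np.all(a >= prev - 1e-9)
            prev = a

    def test_invalid_moment_order(self):
        with pytest.raises(ValueError):
            log_moment(MechanismSpec(q=0.5, noise_std=4.0), 0)

    def test_mode_dependence_on_clipping_threshold(self):
        """absolute cost moves with C_t; normalized cost does not."""
        sigma = 4.0
        for C_t_a, C_t_b in [(3.0, 1.0)]:
            printed_a = log_moment(
                MechanismSpec(q=1.0, noise_std=C_t_a * sigma, mode="absolute"), 8
            )
            printed_b = log_moment(
                MechanismSpec(q=1.0, noise_std=C_t_b * sigma, mode="absolute"), 8
            )
            assert printed_b > printed_a  # smaller C_t, larger per-round cost
        norm_a = log_moment(MechanismSpec(q=1.0, noise_std=sigma, mode="normalized"), 8)
        norm_b = log_moment(MechanismSpec(q=1.0, noise_std=sigma, mode="normalized"), 8)
        assert norm_a == norm_b


class TestComposition:
    def test_single_round_single_device(self):
        spec = MechanismSpec(q=1.0, noise_std=12.0)
        ledger = accumulate(MomentLedger(), spec)
        np.testing.assert_allclose(ledger.totals, log_moments(spec))

    def test_two_identical_rounds_double(self):
        spec = MechanismSpec(q=1.0, noise_std=12.0)
        once = accumulate(MomentLedger(), spec)
        twice = accumulate(once, spec)
        np.testing.assert_allclose(twice.totals, 2 * once.totals)

    def test_device_multiplier_in_sum_mode(self):
        spec = MechanismSpec(q=1.0, noise_std=12.0)
        single = accumulate(MomentLedger(), spec, devices=1)
        twenty = accumulate(MomentLedger(), spec, devices=20)
        np.testing.assert_allclose(twenty.totals, 20 * single.totals)

    def test_rounds_only_mode_ignores_devices(self):
        spec = MechanismSpec(q=1.0, noise_std=12.0)
        ledger = accumulate(
            MomentLedger(composition_mode="rounds_only"), spec, devices=20
        )
        np.testing.assert_allclose(ledger.totals, log_moments(spec))

    def test_additivity_is_exact(self):
        a = MechanismSpec(q=1.0, noise_std=12.0)
        b = MechanismSpec(q=0.5, noise_std=8.0)
        split = accumulate(accumulate(MomentLedger(), a), b)
        joint = MomentLedger()
        joint.totals = log_moments(a) + log_moments(b)
        np.testing.assert_array_equal(split.totals, joint.totals)


class TestTailBound:
    def test_zero_moments_inversion(self):
        ledger = accumulate(MomentLedger(), MechanismSpec(q=0.0, noise_std=1.0))
        delta = 1e-4
        assert epsilon_for_delta(ledger, delta) == pytest.approx(
            np.log(1 / delta) / max(DEFAULT_LAMBDAS)
        )

    def test_empty_ledger_spends_nothing(self):
        assert epsilon_for_delta(MomentLedger(), 1e-4) == 0.0

    def test_matches_exhaustive_grid_search(self):
        """q=1, s=4 single round: epsilon equals the grid minimum by hand."""
        ledger = accumulate(MomentLedger(), MechanismSpec(q=1.0, noise_std=4.0))
        lam = np.asarray(DEFAULT_LAMBDAS, dtype=float)
        oracle = np.min((lam * (lam + 1) / 32 + np.log(1e4)) / lam)
        assert epsilon_for_delta(ledger, 1e-4) == pytest.approx(oracle, rel=1e-6)

    def test_doubling_moments_never_decreases_epsilon(self):
        ledger = accumulate(MomentLedger(), MechanismSpec(q=1.0, noise_std=4.0))
        doubled = ledger.copy()
        doubled.totals = 2 * ledger.totals
        assert epsilon_for_delta(doubled, 1e-4) >= epsilon_for_delta(ledger, 1e-4)


class TestExhaustion:
    def test_empty_ledger_not_exhausted(self):
        assert not is_exhausted(PrivacyBudget(3.0, 1e-4), MomentLedger())

    def test_zero_budget_exhausted_after_first_release(self):
        ledger = accumulate(MomentLedger(), MechanismSpec(q=1.0, noise_std=12.0))
        assert is_exhausted(PrivacyBudget(0.0, 1e-4), ledger)

    def test_spent_epsilon_crosses_budget_exactly_once(self):
        """Over 100 simulated rounds the spent epsilon grows monotonically."""
        spec = MechanismSpec(q=1.0, noise_std=12.0)
        budget = PrivacyBudget(3.0, 1e-4)
        ledger = MomentLedger()
        flags, spends = [], []
        for _ in range(100):
            ledger = accumulate(ledger, spec)
            spends.append(epsilon_for_delta(ledger, budget.delta))
            flags.append(is_exhausted(budget, ledger))
        assert np.all(np.diff(spends) >= -1e-12)
        switches = np.diff(np.asarray(flags).astype(int))
        assert np.all(switches >= 0) and switches.sum() <= 1


def test_sampling_probability_caps_at_one():
    assert sampling_probability(64, 27) == 1.0
    assert sampling_probability(16, 64) == 0.25
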