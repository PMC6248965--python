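"""Replicate combiners: averaging, log-averaging, Kalman filtering, priors."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from shapekf.denoise import (
    DEFAULT_PRIOR,
    GaussianPrior,
    IdealPriorSpec,
    average_profile,
    fit_prior,
    kalman_filter_nucleotide,
    kalman_profile,
    log_average_profile,
    make_ideal_prior,
    posterior_closed_form,
    sample_log_variance,
)
from shapekf.io_formats import DomainError, ReactivityProfile
from shapekf.preprocess import to_log_domain
from shapekf.simulate import ReplicateSet, generate_ground_truth, simulate_replicates


def repset(matrix):
    return ReplicateSet(measurements=np.array(matrix, dtype=float))


class TestAverageProfile:
    def test_arithmetic_mean(self):
        out = average_profile(repset([[1.0, 2.0, 3.0]]))
        assert out.reactivities[0] == 2.0

    def test_identical_replicates_identity(self):
        out = average_profile(repset([[0.4, 0.4], [1.1, 1.1]]))
        np.testing.assert_allclose(out.reactivities, [0.4, 1.1])

    def test_missing_measurements_dropped(self):
        out = average_profile(repset([[1.0, np.nan, 3.0], [np.nan, np.nan, np.nan]]))
        assert out.reactivities[0] == 2.0
        assert math.isnan(out.reactivities[1])


class TestLogAverageProfile:
    def test_geometric_mean(self):
        out = log_average_profile(repset([[math.e, math.e**3]]))
        assert out.reactivities[0] == pytest.approx(math.e**2)

    def test_single_replicate_identity(self):
        out = log_average_profile(repset([[0.7], [1.3]]))
        np.testing.assert_allclose(out.reactivities, [0.7, 1.3])

    def test_nonpositive_measurement_rejected(self):
        with pytest.raises(DomainError):
            log_average_profile(repset([[1.0, -0.5]]))

    @given(
        st.lists(
            st.lists(st.floats(0.01, 10.0), min_size=2, max_size=6),
            min_size=1,
            max_size=10,
        ).filter(lambda rows: len({len(r) for r in rows}) == 1)
    )
    def test_am_gm_inequality(self, rows):
        """The arithmetic mean dominates the geometric mean per nucleotide."""
        reps = repset(rows)
        am = average_profile(reps).reactivities
        gm = log_average_profile(reps).reactivities
        assert np.all(am >= gm - 1e-12)


class TestSampleLogVariance:
    @pytest.mark.parametrize(
        "vals,expected",
        [([2.0, 2.0, 2.0], 0.0), ([1.0, 2.0, 3.0], 1.0), ([0.3, 1.7], (0.3 - 1.7) ** 2 / 2)],
    )
    def test_hand_values(self, vals, expected):
        assert sample_log_variance(vals) == pytest.approx(expected)

    def test_single_measurement_rejected(self):
        with pytest.raises(ValueError):
            sample_log_variance([1.0])


class TestKalmanFilterNucleotide:
    def test_conjugate_example(self):
        st_ = kalman_filter_nucleotide([0.5, 1.5], GaussianPrior(0.0, 1.0))
        assert st_.measurement_variance == pytest.approx(0.5)
        assert st_.estimate == pytest.approx(0.8)
        assert st_.variance == pytest.approx(0.2)

    def test_zero_variance_prior_returns_prior_mean(self):
        st_ = kalman_filter_nucleotide([5.0, -3.0, 2.0], GaussianPrior(-1.74, 0.0))
        assert st_.estimate == -1.74
        assert st_.variance == 0.0
        assert all(g == 0.0 for g in st_.gains)

    def test_identical_measurements_return_common_value(self):
        st_ = kalman_filter_nucleotide([0.9, 0.9, 0.9], GaussianPrior(0.0, 1.0))
        assert st_.estimate == 0.9
        assert st_.variance == 0.0

    def test_single_measurement_needs_override(self):
        with pytest.raises(ValueError):
            kalman_filter_nucleotide([1.0], DEFAULT_PRIOR)
        st_ = kalman_filter_nucleotide([1.0], GaussianPrior(0.0, 1.0), measurement_sd=1.0)
        assert st_.estimate == pytest.approx(0.5)

    def test_nonfinite_measurement_rejected(self):
        with pytest.raises(DomainError):
            kalman_filter_nucleotide([1.0, np.inf], DEFAULT_PRIOR)

    @given(
        st.lists(st.floats(-4, 4), min_size=2, max_size=20).filter(
            lambda v: sample_log_variance(v) > 1e-8
        ),
        st.floats(-3, 3),
        st.floats(0.05, 5),
    )
    def test_oracle_equivalence_property(self, vals, mu0, sigma0):
        """Iterative filter equals the closed-form conjugate-normal posterior."""
        prior = GaussianPrior(mu0, sigma0)
        st_ = kalman_filter_nucleotide(vals, prior)
        mean, var = posterior_closed_form(vals, prior)
        assert st_.estimate == pytest.approx(mean, abs=1e-9)
        assert st_.variance == pytest.approx(var, abs=1e-9)

    @given(
        st.lists(st.floats(-4, 4), min_size=2, max_size=20).filter(
            lambda v: sample_log_variance(v) > 1e-8
        ),
        st.floats(0.05, 5),
    )
    def test_gains_in_unit_interval_and_variance_decreases(self, vals, sigma0):
        st_ = kalman_filter_nucleotide(vals, GaussianPrior(0.0, sigma0))
        assert all(0.0 <= g <= 1.0 for g in st_.gains)
        # gains shrink monotonically as the posterior tightens
        assert all(a >= b for a, b in zip(st_.gains, st_.gains[1:]))
        assert st_.variance < sigma0**2

    @given(
        st.lists(st.floats(-4, 4), min_size=2, max_size=20).filter(
            lambda v: sample_log_variance(v) > 1e-8
        ),
        st.floats(-3, 3),
        st.floats(0.05, 5),
    )
    def test_shrinkage_between_prior_mean_and_log_average(self, vals, mu0, sigma0):
        st_ = kalman_filter_nucleotide(vals, GaussianPrior(mu0, sigma0))
        lo, hi = sorted((mu0, float(np.mean(vals))))
        assert lo - 1e-9 <= st_.estimate <= hi + 1e-9

    def test_order_invariance(self, rng):
        vals = rng.normal(size=8)
        base = kalman_filter_nucleotide(vals, DEFAULT_PRIOR).estimate
        for _ in range(20):
            perm = rng.permutation(vals)
            assert kalman_filter_nucleotide(perm, DEFAULT_PRIOR).estimate == pytest.approx(
                base, abs=1e-10
            )


class TestKalmanProfile:
    def test_zero_noise_recovers_truth(self, rng):
        truth = generate_ground_truth(40, DEFAULT_PRIOR, rng)
        reps = simulate_replicates(truth, 3, ("low"), rng, noise_sds=np.zeros(40))
        out = kalman_profile(reps)
        np.testing.assert_allclose(out.reactivities, truth.reactivities, rtol=1e-10)

    def test_flat_prior_matches_log_average(self, rng):
        truth = generate_ground_truth(100, DEFAULT_PRIOR, rng)
        reps = simulate_replicates(truth, 5, "medium", rng)
        kf = kalman_profile(reps, prior=GaussianPrior(0.0, 1e6))
        la = log_average_profile(reps)
        np.testing.assert_allclose(kf.reactivities, la.reactivities, rtol=1e-6)

    def test_single_measurement_nucleotides_become_missing(self, rng):
        m = np.array([[1.0, 2.0], [0.5, np.nan]])
        reps = ReplicateSet(measurements=m)
        with pytest.warns(UserWarning, match="fewer than 2"):
            out = kalman_profile(reps)
        assert not math.isnan(out.reactivities[0])
        assert math.isnan(out.reactivities[1])

    def test_fixed_measurement_sd_rescues_single_measurements(self):
        m = np.array([[0.5, np.nan]])
        out = kalman_profile(ReplicateSet(measurements=m), measurement_sd=0.5)
        assert not math.isnan(out.reactivities[0])

    def test_per_nucleotide_priors(self, rng):
        truth = generate_ground_truth(30, DEFAULT_PRIOR, rng)
        reps = simulate_replicates(truth, 3, "high", rng)
        priors = make_ideal_prior(to_log_domain(truth), IdealPriorSpec(0.0, 0.0))
        out = kalman_profile(reps, prior=priors)
        np.testing.assert_allclose(out.reactivities, truth.reactivities, rtol=1e-10)


class TestPriors:
    def test_fit_prior_hand_values(self):
        prior = fit_prior([-2.0, 0.0])
        assert prior.mu == pytest.approx(-1.0)
        assert prior.sigma == pytest.approx(math.sqrt(2))

    def test_fit_prior_constant_input(self):
        prior = fit_prior([0.3, 0.3, 0.3])
        assert (prior.mu, prior.sigma) == (pytest.approx(0.3), 0.0)

    def test_fit_prior_needs_two_values(self):
        with pytest.raises(ValueError):
            fit_prior([1.0])

    def test_fit_prior_recovers_generating_parameters(self, rng):
        vals = rng.normal(-1.74, 1.52, size=50_000)
        prior = fit_prior(vals)
        assert prior.mu == pytest.approx(-1.74, abs=0.03)
        assert prior.sigma == pytest.approx(1.52, abs=0.03)

    def test_ideal_prior_offset_and_sigma(self, rng):
        truth_log = to_log_domain(generate_ground_truth(5, DEFAULT_PRIOR, rng))
        priors = make_ideal_prior(truth_log, IdealPriorSpec(mu_offset=2.0, sigma=0.5))
        for p, l in zip(priors, truth_log.reactivities):
            assert p.mu == pytest.approx(l + 2.0)
            assert p.sigma == 0.5

    def test_default_prior_constants(self):
        assert DEFAULT_PRIOR == GaussianPrior(-1.74, 1.52)
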