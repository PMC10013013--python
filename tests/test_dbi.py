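"""Dynamical Bayesian inference of directional phase coupling."""

import math
import statistics

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cardionet.dbi import (
    CouplingWindowResult,
    DBIPosterior,
    FourierBasis,
    SurrogateThresholds,
    apply_surrogate_threshold,
    build_design,
    coupling_strength,
    directionality,
    infer_window,
    propagate_prior,
    run_dbi,
    segment_windows,
    surrogate_thresholds,
)
from cardionet.synthetic import OscillatorSpec, simulate_coupled_phases


class TestSegmentWindows:
    def test_five_minute_record_gives_23_windows(self):
        assert len(segment_windows(300, 25, 0.5)) == 23

    def test_window_equal_to_duration_gives_one(self):
        assert segment_windows(25, 25, 0.5) == [(0.0, 25.0)]

    def test_zero_overlap_tiles_the_record(self):
        wins = segment_windows(100, 25, 0.0)
        assert wins == [(0, 25), (25, 50), (50, 75), (75, 100)]

    def test_window_longer_than_record_rejected(self):
        with pytest.raises(ValueError, match="segment_windows"):
            segment_windows(20, 25, 0.5)

    @given(
        duration=st.floats(30, 1000),
        window=st.floats(5, 30),
        overlap=st.floats(0, 0.9),
    )
    def test_count_formula_and_containment(self, duration, window, overlap):
        wins = segment_windows(duration, window, overlap)
        step = window * (1 - overlap)
        assert len(wins) == math.floor((duration - window) / step + 1e-9) + 1
        assert all(0 <= a < b <= duration + 1e-9 for a, b in wins)


class TestFourierBasis:
    def test_second_order_term_count_by_enumeration(self):
        """N=2: one constant + sin/cos over the 12 deduplicated index pairs."""
        basis = FourierBasis(2)
        pairs = set()
        for n1 in range(-2, 3):
            for n2 in range(-2, 3):
                if (n1, n2) != (0, 0) and (-n1, -n2) not in pairs:
                    pairs.add((n1, n2))
        assert basis.n_terms == 1 + 2 * len(pairs) == 25

    def test_no_redundant_sign_pairs(self):
        basis = FourierBasis(2)
        idx = [(n1, n2) for n1, n2, p in basis.terms if p != "const"]
        assert all((-a, -b) not in idx or (a, b) == (-a, -b) for a, b in set(idx))

    def test_cross_masks_select_other_oscillator_terms(self):
        basis = FourierBasis(1)
        m1 = basis.cross_mask(1)
        assert all(t[1] != 0 for t, keep in zip(basis.terms, m1) if keep)
        m2 = basis.cross_mask(2)
        assert all(t[0] != 0 for t, keep in zip(basis.terms, m2) if keep)


class TestBuildDesign:
    def test_pure_rotation_recovers_natural_frequency(self):
        t = np.arange(0, 50, 0.02)
        phi1, phi2 = 2 * np.pi * t, 2 * np.pi * 0.25 * t
        basis = FourierBasis(0)
        design, targets = build_design(phi1, phi2, basis, dt=0.02)
        sol, *_ = np.linalg.lstsq(design, targets[:, 0], rcond=None)
        assert abs(sol[0] - 2 * np.pi) < 1e-9

    def test_short_series_rejected(self):
        basis = FourierBasis(2)
        with pytest.raises(ValueError, match="at least"):
            build_design(np.zeros(10), np.zeros(10), basis, dt=0.02)

    def test_rowwise_construction_no_temporal_smoothing(self, rng):
        phi1 = np.cumsum(rng.uniform(0.01, 0.1, 200))
        phi2 = np.cumsum(rng.uniform(0.01, 0.1, 200))
        basis = FourierBasis(1)
        d_full, _ = build_design(phi1, phi2, basis, dt=1.0)
        # row k depends only on samples k, k+1
        d_sub, _ = build_design(phi1[50:80], phi2[50:80], basis, dt=1.0)
        assert np.allclose(d_full[50:79], d_sub)


def _simulated_window(coupling=0.3, noise=0.0, seed=0, duration=60.0, dt=0.02):
    s1 = OscillatorSpec(1.1, {(0, 1, "sin"): coupling}, noise_sd=noise)
    s2 = OscillatorSpec(0.25, noise_sd=noise)
    return simulate_coupled_phases(s1, s2, duration, dt, seed=seed)


class TestInferWindow:
    def test_noise_free_coefficient_recovery(self):
        phi1, phi2 = _simulated_window(coupling=0.3)
        basis = FourierBasis(2)
        design, targets = build_design(phi1, phi2, basis, dt=0.02)
        post = infer_window(design, targets, prior=None, dt=0.02)
        j = basis.terms.index((0, 1, "sin"))
        assert abs(post.coeff_mean[0, j] - 0.3) < 0.02
        assert post.converged

    def test_zero_targets_give_zero_posterior_mean(self):
        rngd = np.random.default_rng(0)
        design = rngd.standard_normal((100, 5))
        post = infer_window(design, np.zeros((100, 2)), prior=None, dt=0.02)
        assert np.allclose(post.coeff_mean, 0.0, atol=1e-12)

    def test_dt_rescaling_leaves_posterior_unchanged(self):
        phi1, phi2 = _simulated_window(coupling=0.2)
        basis = FourierBasis(1)
        design, targets = build_design(phi1, phi2, basis, dt=0.02)
        a = infer_window(design, targets, prior=None, dt=0.02)
        b = infer_window(design, targets, prior=None, dt=0.04)
        assert np.allclose(a.coeff_mean, b.coeff_mean, atol=1e-8)


class TestPropagatePrior:
    def _posterior(self, mean, cov):
        return DBIPosterior(
            coeff_mean=np.asarray(mean, float).reshape(1, -1),
            coeff_cov=np.asarray(cov, float),
            noise_matrix=np.eye(2),
        )

    def test_zero_pw_freezes_covariance(self):
        post = self._posterior([1.0, 2.0], np.diag([0.5, 0.7]))
        prior = propagate_prior(post, pw=0.0)
        assert np.array_equal(prior.coeff_cov, post.coeff_cov)

    def test_direct_formula_evaluation(self):
        post = self._posterior([1.0, 0.0], np.eye(2))
        prior = propagate_prior(post, pw=0.2)
        assert np.allclose(prior.coeff_cov, np.diag([1.04, 1.0]))

    def test_diffusion_grows_with_pw_for_nonzero_means(self):
        post = self._posterior([1.0, -2.0], np.eye(2))
        d1 = np.diag(propagate_prior(post, pw=0.1).coeff_cov)
        d2 = np.diag(propagate_prior(post, pw=0.3).coeff_cov)
        assert np.all(d2 > d1)


class TestCouplingStrength:
    def _posterior_from(self, coeffs):
        basis = FourierBasis(2)
        mean = np.zeros((2, basis.n_terms))
        for (eq, term), v in coeffs.items():
            mean[eq, basis.terms.index(term)] = v
        return basis, DBIPosterior(mean, np.eye(2 * basis.n_terms), np.eye(2))

    def test_no_cross_terms_no_coupling(self):
        basis, post = self._posterior_from({(0, (0, 0, "const")): 2.0})
        assert coupling_strength(post, basis) == (0.0, 0.0)

    def test_single_cross_coefficient(self):
        basis, post = self._posterior_from({(0, (0, 1, "sin")): 0.3})
        s_1to2, s_2to1 = coupling_strength(post, basis)
        assert s_2to1 == pytest.approx(0.3) and s_1to2 == 0.0

    def test_matches_flat_loop_norm_oracle(self, rng):
        basis = FourierBasis(2)
        mean = rng.standard_normal((2, basis.n_terms))
        post = DBIPosterior(mean, np.eye(2 * basis.n_terms), np.eye(2))
        s_1to2, s_2to1 = coupling_strength(post, basis)
        acc = 0.0
        for j, (n1, n2, p) in enumerate(basis.terms):
            if p != "const" and n2 != 0:
                acc += mean[0, j] ** 2
        assert abs(s_2to1 - math.sqrt(acc)) < 1e-12

    def test_squared_variant_is_square_of_norm(self, rng):
        basis = FourierBasis(2)
        mean = rng.standard_normal((2, basis.n_terms))
        post = DBIPosterior(mean, np.eye(2 * basis.n_terms), np.eye(2))
        a = coupling_strength(post, basis, squared=False)
        b = coupling_strength(post, basis, squared=True)
        assert b[0] == pytest.approx(a[0] ** 2) and b[1] == pytest.approx(a[1] ** 2)


class TestDirectionality:
    @pytest.mark.parametrize(
        "s12, s21, expect", [(0.3, 0.1, 0.5), (0.7, 0.7, 0.0), (0.3, 0.0, 1.0)]
    )
    def test_formula(self, s12, s21, expect):
        assert directionality(s12, s21) == pytest.approx(expect)

    def test_both_zero_is_missing_not_zero(self):
        assert directionality(0.0, 0.0) is None

    @given(st.floats(0, 10), st.floats(0, 10))
    def test_antisymmetry_and_algebra(self, a, b):
        d = directionality(a, b)
        if d is None:
            assert a == b == 0
        else:
            assert -1 <= d <= 1
            assert abs(d * (a + b) - (a - b)) < 1e-12 * max(a + b, 1)
            assert directionality(b, a) == pytest.approx(-d, abs=1e-15)


class TestRunDBI:
    def test_five_minute_phases_give_23_windows(self):
        phi1, phi2 = _simulated_window(duration=300.0, seed=1)
        results = run_dbi(phi2, phi1, fs=50.0)
        assert len(results) == 23

    def test_parameter_recovery_within_five_percent(self):
        """Noise-free phases generated inside the N=2 basis are recovered."""
        s1 = OscillatorSpec(1.1, {(0, 1, "sin"): 0.4, (1, -1, "cos"): 0.1})
        s2 = OscillatorSpec(0.25)
        phi1, phi2 = simulate_coupled_phases(s1, s2, 300.0, 0.02, seed=0)
        results = run_dbi(phi2, phi1, fs=50.0)  # oscillator order: (resp, cardiac)
        truth = math.sqrt(0.4**2 + 0.1**2)
        med = statistics.median(r.s_1to2 for r in results)
        assert abs(med - truth) / truth < 0.05

    def test_null_directionality_centred_on_zero(self):
        meds = []
        for seed in range(15):
            s1 = OscillatorSpec(1.18, noise_sd=0.1)
            s2 = OscillatorSpec(0.25, noise_sd=0.1)
            phi1, phi2 = simulate_coupled_phases(s1, s2, 300.0, 0.02, seed=seed)
            res = run_dbi(phi2, phi1, fs=50.0)
            meds.append(statistics.median(r.d for r in res))
        assert abs(np.median(meds)) < 0.1

    def test_directional_coupling_recovered_with_positive_sign(self):
        wins = 0
        for seed in range(10):
            phi1, phi2 = _simulated_window(coupling=0.5, noise=0.1, duration=300.0, seed=seed)
            res = run_dbi(phi2, phi1, fs=50.0)
            if statistics.median(r.d for r in res) > 0:
                wins += 1
        assert wins >= 9


class TestSurrogateThresholding:
    def _fake_results(self, strengths):
        return [
            CouplingWindowResult(i, 0.0, s12, s21, directionality(s12, s21))
            for i, (s12, s21) in enumerate(strengths)
        ]

    def test_zero_thresholds_accept_everything(self):
        res = self._fake_results([(0.5, 0.2), (0.1, 0.1)])
        th = SurrogateThresholds(0.0, 0.0, 1, 2)
        out = apply_surrogate_threshold(res, th)
        assert all(w.significant_1to2 and w.significant_2to1 for w in out)

    def test_infinite_thresholds_reject_everything(self):
        res = self._fake_results([(0.5, 0.2)])
        th = SurrogateThresholds(np.inf, np.inf, 1, 1)
        out = apply_surrogate_threshold(res, th)
        assert not any(w.significant_1to2 or w.significant_2to1 for w in out)

    def test_thresholds_are_pooled_medians(self):
        lists = [self._fake_results([(1.0, 4.0), (2.0, 5.0)]),
                 self._fake_results([(3.0, 6.0)])]
        th = surrogate_thresholds(lists)
        assert th.median_1to2 == 2.0 and th.median_2to1 == 5.0
        assert th.n_surrogates == 2 and th.n_windows_total == 3

    def test_null_coupling_rejected_at_surrogate_median(self):
        """The surrogate median is the null 50th percentile: about half of
        null windows fail per direction, and most fail in at least one."""
        null_results = []
        for seed in range(8):
            phi1, phi2 = _simulated_window(coupling=0.0, noise=0.1, duration=300.0, seed=100 + seed)
            null_results.append(run_dbi(phi2, phi1, fs=50.0))
        th = surrogate_thresholds(null_results)
        flat = [w for res in null_results for w in apply_surrogate_threshold(res, th)]
        frac_12 = np.mean([w.significant_1to2 for w in flat])
        frac_21 = np.mean([w.significant_2to1 for w in flat])
        assert frac_12 <= 0.55 and frac_21 <= 0.55
        both = np.mean([w.significant_1to2 and w.significant_2to1 for w in flat])
        assert both <= 0.5
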