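"""Profile likelihoods, CI extraction, identifiability classification, mCI."""

import math

import numpy as np
import pytest

from dcmident import (
    CIStatus,
    ProfileCurve,
    ProfileSettings,
    assess_model,
    chi2_threshold,
    extract_ci,
    fit_problem,
    mean_ci,
    profile_curve,
)


class ToyProblem:
    def __init__(self, fn, t, y, sigma, n_params):
        self.fn = fn
        self.t = np.asarray(t, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.sigma = float(sigma)
        self.n_params = n_params

    def residuals(self, theta):
        return (self.y - self.fn(self.t, theta)) / self.sigma

    def chi2(self, theta):
        r = self.residuals(np.asarray(theta, dtype=float))
        return float(r @ r)


class TestThreshold:
    def test_pointwise_95_percent_df1(self):
        assert chi2_threshold(0.05, 1) == pytest.approx(3.841, abs=1e-3)

    def test_monotone_in_df(self):
        assert chi2_threshold(0.05, 2) > chi2_threshold(0.05, 1)

    def test_one_sigma_level(self):
        assert chi2_threshold(0.32, 1) == pytest.approx(0.99, abs=0.01)

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.2])
    def test_alpha_out_of_range(self, alpha):
        with pytest.raises(ValueError):
            chi2_threshold(alpha, 1)


def _curve(grid, vals, chi2_hat, center=None):
    grid = np.asarray(grid, dtype=float)
    vals = np.asarray(vals, dtype=float)
    if center is None:
        center = int(np.argmin(vals))
    return ProfileCurve(
        param_index=0, theta_grid=grid, chi2_pl=vals, chi2_hat=chi2_hat,
        capped=np.zeros(len(grid), dtype=bool), center_index=center,
    )


class TestExtractCI:
    def test_parabola_gives_analytic_crossings(self):
        grid = np.linspace(0.0, 4.0, 81)
        curve = _curve(grid, (grid - 2.0) ** 2 + 10.0, 10.0)
        ci = extract_ci(curve, delta=1.0)
        assert ci.status == CIStatus.IDENTIFIABLE
        assert ci.lower == pytest.approx(1.0, abs=1e-6)
        assert ci.upper == pytest.approx(3.0, abs=1e-6)
        assert not ci.contains_zero

    def test_one_sided_curve_is_practically_non_identifiable(self):
        # decreases to a minimum then flattens: upper crossing never happens
        grid = np.linspace(-2.0, 8.0, 101)
        vals = np.where(grid < 0.0, 10.0 + (grid) ** 2 * 8.0, 10.0)
        curve = _curve(grid, vals, 10.0, center=20)
        ci = extract_ci(curve, delta=3.841)
        assert ci.status == CIStatus.PRACTICAL_UPPER
        assert math.isfinite(ci.lower)
        assert ci.upper == math.inf

    def test_flat_curve_is_structural(self):
        grid = np.linspace(-5.0, 5.0, 51)
        curve = _curve(grid, np.full(51, 10.0), 10.0, center=25)
        ci = extract_ci(curve, delta=3.841)
        assert ci.status == CIStatus.STRUCTURAL
        assert ci.lower == -math.inf and ci.upper == math.inf
        assert ci.contains_zero

    def test_non_flat_double_miss_is_practical_both(self):
        grid = np.linspace(-5.0, 5.0, 51)
        vals = 10.0 + 0.5 * np.abs(grid)  # rises but never reaches +3.841
        curve = _curve(grid, vals, 10.0, center=25)
        ci = extract_ci(curve, delta=3.841)
        assert ci.status == CIStatus.PRACTICAL_BOTH

    def test_empty_curve_rejected(self):
        curve = _curve(np.empty(0), np.empty(0), 0.0, center=0)
        with pytest.raises(ValueError):
            extract_ci(curve, delta=1.0)


class TestMeanCI:
    def _ci(self, lo, hi):
        from dcmident import ConfidenceInterval

        return ConfidenceInterval(lo, hi, 0.05, CIStatus.IDENTIFIABLE,
                                  lo <= 0 <= hi)

    def test_arithmetic_mean_of_widths(self):
        assert mean_ci([self._ci(0.0, 0.2), self._ci(0.0, 0.4)]) == (
            pytest.approx(0.3)
        )

    def test_single_parameter(self):
        assert mean_ci([self._ci(-0.1, 0.4)]) == pytest.approx(0.5)

    def test_any_infinite_bound_gives_infinite_mci(self):
        assert mean_ci([self._ci(0.0, 0.2), self._ci(0.0, math.inf)]) == (
            math.inf
        )

    def test_order_invariance(self):
        cis = [self._ci(0.0, w) for w in (0.1, 0.7, 0.3)]
        assert mean_ci(cis) == pytest.approx(mean_ci(cis[::-1]))

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            mean_ci([])


class TestProfileScan:
    def test_linear_model_ci_matches_asymptotic(self):
        """For y = theta * t with known sigma the profile is an exact
        parabola and the likelihood CI equals theta_hat +/- 1.96 sigma_theta."""
        rng = np.random.default_rng(1)
        t = np.linspace(0.5, 10.0, 60)
        sigma = 0.4
        y = 0.8 * t + rng.normal(0.0, sigma, size=t.shape)
        prob = ToyProblem(lambda tt, th: th[0] * tt, t, y, sigma, 1)
        res = fit_problem(prob, np.array([0.0]))
        curve = profile_curve(prob, res.theta_hat, res.chi2_min, 0)
        ci = extract_ci(curve, chi2_threshold(0.05, 1))
        se = sigma / np.sqrt(np.sum(t**2))
        half_expected = 1.959964 * se
        half = (ci.upper - ci.lower) / 2.0
        assert ci.status == CIStatus.IDENTIFIABLE
        assert abs(half - half_expected) / half_expected < 0.02

    def test_exact_compensation_yields_flat_profile(self):
        """y = (theta1 + theta2) t: only the sum is determined, so each
        addend is structurally non-identifiable."""
        rng = np.random.default_rng(2)
        t = np.linspace(0.0, 5.0, 30)
        y = 1.0 * t + rng.normal(0.0, 0.2, size=t.shape)
        prob = ToyProblem(lambda tt, th: (th[0] + th[1]) * tt, t, y, 0.2, 2)
        res = fit_problem(prob, np.array([0.4, 0.4]))
        settings = ProfileSettings(max_steps=20)
        curve = profile_curve(prob, res.theta_hat, res.chi2_min, 0, settings)
        ci = extract_ci(curve, chi2_threshold(0.05, 1))
        assert ci.status == CIStatus.STRUCTURAL
        assert np.ptp(curve.chi2_pl) < 0.01 * chi2_threshold(0.05, 1)

    def test_profile_minimum_at_the_estimate(self):
        rng = np.random.default_rng(3)
        t = np.linspace(0.0, 6.0, 40)
        y = 1.2 * (1 - np.exp(-0.8 * t)) + rng.normal(0, 0.05, size=t.shape)
        prob = ToyProblem(
            lambda tt, th: th[0] * (1 - np.exp(-th[1] * tt)), t, y, 0.05, 2
        )
        res = fit_problem(prob, np.array([1.0, 1.0]))
        curve = profile_curve(prob, res.theta_hat, res.chi2_min, 1)
        assert curve.theta_grid[curve.center_index] == pytest.approx(
            res.theta_hat[1]
        )
        assert curve.chi2_pl.min() >= curve.chi2_min() if callable(
            getattr(curve, "chi2_min", None)
        ) else curve.chi2_pl.min() >= curve.chi2_hat - 1e-6

    def test_ci_matches_brute_force_2d_grid(self):
        """Profile CI of a 2-parameter saturating-exponential model vs an
        exhaustive chi2 evaluation on a dense 2-D grid."""
        rng = np.random.default_rng(4)
        t = np.linspace(0.2, 6.0, 50)
        sigma = 0.08
        y = 1.0 * (1 - np.exp(-0.8 * t)) + rng.normal(0, sigma, size=t.shape)
        prob = ToyProblem(
            lambda tt, th: th[0] * (1 - np.exp(-th[1] * tt)), t, y, sigma, 2
        )
        res = fit_problem(prob, np.array([1.2, 1.0]))
        delta = chi2_threshold(0.05, 1)
        curve = profile_curve(prob, res.theta_hat, res.chi2_min, 1)
        ci = extract_ci(curve, delta)

        # independent oracle: dense grid, exact per-column minimization
        th1 = np.linspace(0.7, 1.4, 501)
        th2 = np.linspace(0.4, 1.6, 1201)
        basis = 1 - np.exp(-np.outer(th2, t))          # (n2, nt)
        pred = th1[:, None, None] * basis[None, :, :]  # (n1, n2, nt)
        chi2 = (((y - pred) / sigma) ** 2).sum(axis=2)
        pl = chi2.min(axis=0)                          # profile over theta2
        level = chi2.min() + delta
        inside = np.nonzero(pl <= level)[0]

        def interp(i_in, i_out):
            x0, x1 = pl[i_in], pl[i_out]
            f = (level - x0) / (x1 - x0)
            return th2[i_in] + f * (th2[i_out] - th2[i_in])

        lo = interp(inside[0], inside[0] - 1)
        hi = interp(inside[-1], inside[-1] + 1)
        width = hi - lo
        assert abs(ci.lower - lo) / width < 0.02
        assert abs(ci.upper - hi) / width < 0.02

    def test_reported_ci_contains_the_estimate(
        self, two_region_model, two_region_design
    ):
        report = assess_model(
            two_region_model, two_region_model.pack(), two_region_design,
            snr=5.0, seed=8, settings=ProfileSettings(max_steps=25),
        )
        assert report.fit.converged
        for j, ci in enumerate(report.cis):
            assert ci.lower <= report.fit.x[j] <= ci.upper


class TestAssessModel:
    def test_noise_free_cis_narrower_than_snr5(
        self, two_region_model, two_region_design
    ):
        """Shrinking the noise shrinks every confidence interval."""
        settings = ProfileSettings(max_steps=25)
        params = two_region_model.pack()
        noisy = assess_model(two_region_model, params, two_region_design,
                             snr=5.0, seed=4, settings=settings)
        clean = assess_model(two_region_model, params, two_region_design,
                             snr=np.inf, seed=4, settings=settings)
        assert noisy.fit.converged and clean.fit.converged
        assert all(c.status == CIStatus.IDENTIFIABLE for c in clean.cis)
        for c_ci, n_ci in zip(clean.cis, noisy.cis):
            assert c_ci.width < n_ci.width

    def test_reproducible_under_seed(
        self, two_region_model, two_region_design
    ):
        settings = ProfileSettings(max_steps=10)
        params = two_region_model.pack()
        a = assess_model(two_region_model, params, two_region_design,
                         snr=5.0, seed=21, settings=settings)
        b = assess_model(two_region_model, params, two_region_design,
                         snr=5.0, seed=21, settings=settings)
        assert np.array_equal(a.fit.x, b.fit.x)
        for ca, cb in zip(a.curves, b.curves):
            assert np.array_equal(ca.theta_grid, cb.theta_grid)
            assert np.array_equal(ca.chi2_pl, cb.chi2_pl)
        assert a.mci == b.mci

    def test_parallel_profiles_match_serial(
        self, two_region_model, two_region_design
    ):
        settings = ProfileSettings(max_steps=10)
        params = two_region_model.pack()
        serial = assess_model(two_region_model, params, two_region_design,
                              snr=5.0, seed=13, settings=settings, n_jobs=1)
        parallel = assess_model(two_region_model, params, two_region_design,
                                snr=5.0, seed=13, settings=settings, n_jobs=2)
        for cs, cp in zip(serial.curves, parallel.curves):
            assert np.array_equal(cs.chi2_pl, cp.chi2_pl)

    def test_profile_parameter_wrapper_matches_core(
        self, two_region_model, two_region_design
    ):
        """The model-level profiling entry point reproduces the generic scan
        and refuses unconverged fits."""
        from dcmident import DCMProblem, fit, perturb_start, profile_parameter
        from dcmident.simulate import simulate_dataset

        ds = simulate_dataset(two_region_model, two_region_design, 5.0, 6)
        fr = fit(two_region_model, ds,
                 perturb_start(ds.true_params, 0.1, 6), seed=6)
        settings = ProfileSettings(max_steps=8)
        cv = profile_parameter(1, fr, two_region_model, ds, settings)
        prob = DCMProblem.from_dataset(two_region_model, ds)
        ref = profile_curve(prob, fr.x, fr.chi2_min, 1, settings)
        assert np.array_equal(cv.theta_grid, ref.theta_grid)
        assert np.array_equal(cv.chi2_pl, ref.chi2_pl)
        fr.converged = False
        with pytest.raises(ValueError, match="converged"):
            profile_parameter(1, fr, two_region_model, ds, settings)

    def test_unconverged_fit_yields_undetermined_report(
        self, two_region_model, two_region_design
    ):
        """A fit stuck in a divergent regime with no restart budget emits a
        diagnostic report with undetermined statuses, never an exception."""
        settings = ProfileSettings(start_perturbation=10.0, fit_restarts=0,
                                   max_steps=5)
        report = assess_model(
            two_region_model, two_region_model.pack(), two_region_design,
            snr=5.0, seed=0, settings=settings,
        )
        assert not report.fit.converged
        assert report.diagnostic
        assert report.mci == math.inf
        assert all(ci.status == CIStatus.UNDETERMINED for ci in report.cis)

    def test_mci_infinite_iff_any_non_identifiable(self):
        from dcmident import ConfidenceInterval

        good = ConfidenceInterval(0.1, 0.3, 0.05, CIStatus.IDENTIFIABLE, False)
        bad = ConfidenceInterval(0.1, math.inf, 0.05,
                                 CIStatus.PRACTICAL_UPPER, False)
        assert math.isfinite(mean_ci([good, good]))
        assert mean_ci([good, bad]) == math.inf
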