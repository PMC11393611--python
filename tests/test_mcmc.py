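"""Adaptive-covariance MCMC, convergence diagnostics and posterior QC."""

import numpy as np
import pytest

from eisfit import (
    CircuitParameters,
    ParameterBounds,
    PosteriorSamples,
    electrode_amalgamation_qc,
    fit_cmaes,
    gelman_rubin,
    generate_spectrum,
    posterior_summary,
    rct_separation,
    run_mcmc,
    spectrum_from_model,
)
from eisfit.mcmc import adaptive_metropolis

MU = np.array([1.0, -2.0, 0.0, 5.0, 10.0, -1.0, 3.0])
SD = np.array([1.0, 0.5, 2.0, 1.0, 3.0, 0.2, 1.0])


def gaussian_log_target(x: np.ndarray) -> float:
    return float(-0.5 * np.sum(((x - MU) / SD) ** 2))


class TestAdaptiveMetropolis:
    def test_gaussian_target_moments(self):
        # Conjugate-density oracle: pooled mean within 3 standard errors and
        # pooled variance within 10% of the analytic values, per coordinate.
        chains = []
        for seed in range(3):
            chain, rate = adaptive_metropolis(gaussian_log_target, MU + 0.1, 10_000, seed=seed)
            assert 0.1 < rate < 0.5
            chains.append(chain[3000:])
        pooled = np.concatenate(chains)
        # Efficiency of optimal random-walk Metropolis in d = 7 is ~0.33/d,
        # giving an effective sample size of roughly n_eff = N * 0.047.
        n_eff = pooled.shape[0] * 0.33 / len(MU)
        se = SD / np.sqrt(n_eff)
        assert np.all(np.abs(pooled.mean(axis=0) - MU) < 3 * se)
        assert np.all(np.abs(pooled.var(axis=0) / SD**2 - 1) < 0.10)

    def test_cross_check_against_emcee_ensemble_sampler(self):
        # Independent sampler oracle on a correlated 2-d Gaussian.
        emcee = pytest.importorskip("emcee")
        cov = np.array([[2.0, 1.2], [1.2, 1.5]])
        prec = np.linalg.inv(cov)

        def logp(x):
            return float(-0.5 * x @ prec @ x)

        chain, _ = adaptive_metropolis(logp, np.zeros(2), 20_000, seed=0)
        mine = np.cov(chain[5000:].T)

        sampler = emcee.EnsembleSampler(16, 2, logp)
        rng = np.random.default_rng(1)
        state = sampler.run_mcmc(rng.normal(size=(16, 2)) * 0.1, 3000, progress=False)
        theirs = np.cov(sampler.get_chain(discard=1000, flat=True).T)
        assert np.allclose(mine, theirs, rtol=0.15, atol=0.1)

    def test_non_finite_start_rejected(self):
        with pytest.raises(ValueError):
            adaptive_metropolis(lambda x: -np.inf, np.zeros(2), 100, seed=0)


class TestRunMcmc:
    def test_bookkeeping_three_draws(self, noisy_spectrum, ml_fit):
        post = run_mcmc(
            noisy_spectrum, init=ml_fit.best_fit, n_chains=3, n_iter=11, burn_in=10, seed=1
        )
        assert post.pooled.shape == (3, 7)

    def test_all_retained_draws_inside_bounds(self, posterior):
        bounds = ParameterBounds.default()
        pooled = posterior.pooled
        assert np.all(pooled >= bounds.lower) and np.all(pooled <= bounds.upper)

    def test_posterior_concentrates_on_truth_at_low_noise(self, truth, grid, posterior):
        quiet_truth = truth.replace(sigma1=1e-4, sigma2=1.0)
        spectrum = generate_spectrum(quiet_truth, grid, seed=4)
        fit = fit_cmaes(spectrum, seed=40)
        post = run_mcmc(spectrum, init=fit.best_fit, n_chains=3, n_iter=2000, burn_in=600, seed=41)
        lo, hi = np.percentile(post.parameter("R_ct"), [2.5, 97.5])
        assert lo <= truth.R_ct <= hi
        noisy_lo, noisy_hi = np.percentile(posterior.parameter("R_ct"), [2.5, 97.5])
        assert (hi - lo) < (noisy_hi - noisy_lo)

    def test_init_outside_bounds_rejected(self, noisy_spectrum):
        bounds = ParameterBounds.from_mapping({"R_ct": (1.0, 10.0)})
        init = CircuitParameters(
            R_s=200.0, R_ct=100.0, Z_w=3e3, Q=5e-7, alpha=0.9, sigma1=0.01, sigma2=150.0
        )
        with pytest.raises(ValueError, match="outside"):
            run_mcmc(noisy_spectrum, bounds, init, n_iter=100, burn_in=10, seed=0)

    def test_determinism_for_fixed_seed(self, noisy_spectrum, ml_fit):
        a = run_mcmc(noisy_spectrum, init=ml_fit.best_fit, n_iter=300, burn_in=100, seed=9)
        b = run_mcmc(noisy_spectrum, init=ml_fit.best_fit, n_iter=300, burn_in=100, seed=9)
        assert np.array_equal(a.chains, b.chains)


def _make_samples(chains: np.ndarray, burn_in: int = 0) -> PosteriorSamples:
    return PosteriorSamples(chains=chains, burn_in=burn_in, seed=0,
                            param_names=tuple(f"p{i}" for i in range(chains.shape[2])))


class TestGelmanRubin:
    def test_iid_chains_near_unity(self):
        rng = np.random.default_rng(0)
        samples = _make_samples(rng.normal(size=(3, 1000, 2)))
        report = gelman_rubin(samples)
        assert np.all((report.psrf >= 0.99) & (report.psrf < 1.1))
        assert report.passed

    def test_disjoint_chains_fail(self):
        rng = np.random.default_rng(1)
        chains = rng.normal(size=(2, 500, 1))
        chains[1] += 100.0
        report = gelman_rubin(_make_samples(chains))
        assert report.psrf[0] > 1.1
        assert not report.passed

    def test_formula_oracle_two_chains(self):
        # Direct spreadsheet-style evaluation of the split between/within
        # variance formula on a tiny hand-sized example.
        rng = np.random.default_rng(2)
        chains = rng.normal(size=(2, 20, 1))
        report = gelman_rubin(_make_samples(chains))

        split = np.array([chains[0, :10, 0], chains[0, 10:, 0],
                          chains[1, :10, 0], chains[1, 10:, 0]])
        n = 10
        means = split.mean(axis=1)
        variances = split.var(axis=1, ddof=1)
        w = variances.mean()
        b_over_n = means.var(ddof=1)
        expected = np.sqrt(((n - 1) / n * w + b_over_n) / w)
        assert report.psrf[0] == pytest.approx(expected, rel=1e-12)

    def test_agrees_with_arviz_split_rhat(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(3)
        chains = np.cumsum(rng.normal(size=(4, 400, 1)), axis=1) * 0.01 + rng.normal(
            size=(4, 400, 1)
        )
        report = gelman_rubin(_make_samples(chains))
        reference = float(az.rhat(az.convert_to_dataset(chains[:, :, 0]), method="split")["x"])
        assert report.psrf[0] == pytest.approx(reference, rel=1e-6)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin(_make_samples(np.zeros((1, 100, 1)) + np.random.default_rng(0).normal(size=(1, 100, 1))))


class TestPosteriorSummary:
    def test_perfect_anticorrelation(self):
        t = np.linspace(0, 1, 50)
        chains = np.stack([t, 1 - t], axis=1)[None, :, :]
        summary = posterior_summary(_make_samples(chains))
        assert summary["correlation"][0, 1] == pytest.approx(-1.0)

    def test_histogram_counts_sum_to_pool_size(self, posterior):
        summary = posterior_summary(posterior)
        for counts, _ in summary["histograms"].values():
            assert counts.sum() == posterior.pooled.shape[0]

    def test_correlation_matrix_symmetric_unit_diagonal(self, posterior):
        corr = posterior_summary(posterior)["correlation"]
        assert np.allclose(corr, corr.T)
        assert np.allclose(np.diag(corr), 1.0)

    def test_q_alpha_correlation_dominates(self, posterior):
        # The CPE magnitude and exponent trade off against each other, so
        # |corr(Q, alpha)| should be the largest off-diagonal element.
        summary = posterior_summary(posterior)
        names = list(summary["param_names"])
        corr = np.abs(summary["correlation"].copy())
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        assert {names[i], names[j]} == {"Q", "alpha"}

    def test_single_draw_degenerate_intervals(self):
        chains = np.full((1, 1, 2), 3.5)
        summary = posterior_summary(_make_samples(chains))
        assert summary["intervals"]["p0"] == (3.5, 3.5)


class TestRctSeparation:
    def test_identical_samples_overlap_fully(self, posterior):
        overlap, distinct = rct_separation(posterior, posterior)
        assert overlap > 0.95
        assert not distinct

    def test_far_separated_posteriors_distinct(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=(2, 500, 7)) + 10.0
        far = base + 1000.0
        a = PosteriorSamples(chains=np.abs(base), burn_in=0, seed=0)
        b = PosteriorSamples(chains=np.abs(far), burn_in=0, seed=0)
        overlap, distinct = rct_separation(a, b)
        assert overlap == 0.0
        assert distinct


class TestElectrodeQc:
    def test_paper_trio_pools_together(self):
        assert electrode_amalgamation_qc([12.9e3, 7.7e3, 10.4e3]) == [0, 1, 2]

    def test_identical_values_all_selected(self):
        assert electrode_amalgamation_qc([10.0, 10.0, 10.0], tolerance=0.0) == [0, 1, 2]

    def test_extreme_spread_gives_singleton(self):
        assert len(electrode_amalgamation_qc([1.0, 100.0])) == 1

    def test_accepts_fit_results(self, ml_fit):
        indices = electrode_amalgamation_qc([ml_fit, ml_fit, ml_fit])
        assert indices == [0, 1, 2]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            electrode_amalgamation_qc([])
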