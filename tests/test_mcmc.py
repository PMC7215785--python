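import numpy as np
import pytest
from scipy.special import expit

from carlogit.data_model import CrashDataset, chain_graph
from carlogit.mcmc import (
    McmcConfig,
    batch_means_mc_error,
    fit,
    mc_error_ratio,
    summarize,
)
from conftest import make_dataset


def toy_two_segment_dataset():
    """5 records on 2 adjacent segments, intercept-only on both sides."""
    return CrashDataset(
        y=np.array([1, 2, 2, 3, 1]),
        X=np.ones((5, 1)),
        Z=np.ones((5, 1)),
        segments=np.array([1, 2, 1, 2, 2]),
        x_names=("constant",),
        z_names=("constant",),
        graph=chain_graph(2),
    )


class TestConfig:
    def test_burn_in_must_precede_end(self):
        with pytest.raises(ValueError):
            McmcConfig(n_iter=100, burn_in=100)

    def test_defaults_follow_reference_protocol(self):
        cfg = McmcConfig()
        assert (cfg.n_iter, cfg.burn_in) == (60_000, 50_000)
        assert cfg.prior_coef_variance == 1e4
        assert (cfg.prior_tau_shape, cfg.prior_tau_rate) == (0.01, 0.01)


class TestSampler:
    def test_fixed_seed_is_bit_identical(self, small_dataset):
        cfg = McmcConfig(n_iter=400, burn_in=200, seed=3)
        a = fit("spatial", small_dataset, cfg)
        b = fit("spatial", small_dataset, cfg)
        assert np.array_equal(a.beta, b.beta)
        assert np.array_equal(a.alpha, b.alpha)
        assert np.array_equal(a.phi, b.phi)
        assert np.array_equal(a.tau_phi, b.tau_phi)

    def test_draw_count_bookkeeping(self, small_dataset):
        cfg = McmcConfig(n_iter=1000, burn_in=400, thin=3, seed=0)
        chain = fit("nonspatial", small_dataset, cfg)
        assert chain.n_draws == 200
        assert chain.phi is None

    def test_prior_recovery_with_no_data(self):
        """With an empty dataset the posterior is the prior: coefficient
        draws must reproduce the Normal(0, 1e4) prior SD of 100."""
        empty = CrashDataset(
            y=np.zeros(0, dtype=int),
            X=np.zeros((0, 1)),
            Z=np.zeros((0, 1)),
            segments=np.zeros(0, dtype=int),
            x_names=("constant",),
            z_names=("constant",),
            graph=chain_graph(1),
        )
        chain = fit("nonspatial", empty, McmcConfig(n_iter=40_000, burn_in=10_000, seed=1))
        for draws in (chain.beta[:, 0], chain.alpha[:, 0]):
            assert draws.std() == pytest.approx(100.0, rel=0.10)
            assert abs(draws.mean()) < 10.0

    def test_posterior_matches_dense_grid_oracle(self):
        """On the toy dataset, sampler means for the intercepts and the
        segment contrast must match a dense-grid posterior computed with the
        spatial precision integrated out analytically."""
        ds = toy_two_segment_dataset()
        a_t = b_t = 0.01
        g = np.linspace(-6.0, 6.0, 161)
        d = np.linspace(-4.0, 4.0, 161)
        B0, A0, D = np.meshgrid(g, g, d, indexing="ij")

        def loglik(b0, a0, dd):
            total = 0.0
            for yi, s in zip(ds.y, ds.segments):
                eta = b0 + (dd if s == 1 else -dd)
                mu2 = np.exp(a0)
                p1 = expit(-eta)
                p3 = expit(eta - mu2)
                p = p1 if yi == 1 else (np.clip(1 - p1 - p3, 1e-300, 1) if yi == 2 else p3)
                total = total + np.log(np.maximum(p, 1e-300))
            return total

        # phi = (d, -d) on the sum-to-zero subspace; SS = (2d)^2, df = 1;
        # integrating the Gamma(a,b) precision gives prior ∝ (b + SS/2)^-(a+1/2)
        log_post = (
            loglik(B0, A0, D)
            - (B0**2 + A0**2) / (2e4)
            - (a_t + 0.5) * np.log(b_t + 0.5 * (2 * D) ** 2)
        )
        w = np.exp(log_post - log_post.max())
        w /= w.sum()
        oracle = {
            "b0": float((w * B0).sum()),
            "a0": float((w * A0).sum()),
            "d": float((w * D).sum()),
        }

        chain = fit("spatial", ds, McmcConfig(n_iter=40_000, burn_in=8_000, seed=7))
        checks = {
            "b0": chain.beta[:, 0],
            "a0": chain.alpha[:, 0],
            "d": chain.phi[:, 0],
        }
        for key, draws in checks.items():
            mce = batch_means_mc_error(draws)
            assert draws.mean() == pytest.approx(oracle[key], abs=3 * mce)

    def test_crash_on_island_segment_rejected(self):
        from carlogit.data_model import SegmentGraph

        ds = CrashDataset(
            y=np.array([1, 2]),
            X=np.ones((2, 1)),
            Z=np.ones((2, 1)),
            segments=np.array([1, 3]),
            x_names=("constant",),
            z_names=("constant",),
            graph=SegmentGraph(3, ((1, 2),)),
        )
        with pytest.raises(ValueError, match="island"):
            fit("spatial", ds, McmcConfig(n_iter=200, burn_in=100, seed=0))

    def test_recentred_field_sums_to_zero(self, small_dataset):
        chain = fit("spatial", small_dataset, McmcConfig(n_iter=600, burn_in=300, seed=2))
        assert np.abs(chain.phi.sum(axis=1)).max() < 1e-8


class TestAgainstMaximumLikelihood:
    def test_constant_threshold_matches_ordered_logit_mle(self):
        """With a constant-only threshold the model is an ordinary ordered
        logit (cutpoints 0 and exp(alpha0)); under diffuse priors the
        posterior means must agree with the independent maximum-likelihood
        fit of statsmodels' OrderedModel."""
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        ds = make_dataset(
            n=2500, p=2, q=0, seed=13, beta=[0.4, 0.9, -0.6], alpha=[0.8]
        )
        chain = fit("nonspatial", ds, McmcConfig(n_iter=8000, burn_in=4000, seed=2))
        post_beta = chain.beta.mean(axis=0)
        post_alpha0 = chain.alpha.mean(axis=0)[0]

        mle = OrderedModel(ds.y, ds.X[:, 1:], distr="logit").fit(
            method="bfgs", disp=False
        )
        b_mle = mle.params[:2]
        # OrderedModel: P(y<=j) = F(t_j - x'b); ours absorbs the intercept,
        # so t1 = -beta0 and t2 = exp(alpha0) - beta0
        t1, t2 = mle.model.transform_threshold_params(mle.params)[1:-1]
        se = np.sqrt(np.diag(mle.cov_params()))[:2]
        assert np.all(np.abs(post_beta[1:] - b_mle) < 3 * np.maximum(se, 0.02))
        assert -post_beta[0] == pytest.approx(t1, abs=0.15)
        assert np.exp(post_alpha0) - post_beta[0] == pytest.approx(t2, abs=0.2)


class TestMcError:
    def test_iid_draws_ratio(self, rng):
        from carlogit.mcmc import PosteriorChain

        n = 10_000
        chain = PosteriorChain(
            model="nonspatial",
            beta=rng.normal(size=(n, 1)),
            alpha=np.zeros((n, 1)),
            tau_phi=np.ones(n),
            phi=None,
            deviance=np.zeros(n),
            x_names=("constant",),
            z_names=("constant",),
            acceptance={},
        )
        ratio = mc_error_ratio(chain, "beta[constant]")
        assert ratio == pytest.approx(1 / np.sqrt(n), rel=0.35)
        assert ratio < 0.05

    def test_degenerate_constant_chain_flagged(self):
        from carlogit.mcmc import PosteriorChain

        chain = PosteriorChain(
            model="nonspatial",
            beta=np.full((500, 1), 2.0),
            alpha=np.zeros((500, 1)),
            tau_phi=np.ones(500),
            phi=None,
            deviance=np.zeros(500),
            x_names=("constant",),
            z_names=("constant",),
            acceptance={},
        )
        assert mc_error_ratio(chain, "beta[constant]") == np.inf

    def test_ar1_chain_matches_effective_sample_size_theory(self, rng):
        from carlogit.mcmc import PosteriorChain

        n, rho = 200_000, 0.9
        x = np.empty(n)
        x[0] = rng.normal()
        eps = rng.normal(size=n) * np.sqrt(1 - rho**2)
        for t in range(1, n):
            x[t] = rho * x[t - 1] + eps[t]
        chain = PosteriorChain(
            model="nonspatial",
            beta=x[:, None],
            alpha=np.zeros((n, 1)),
            tau_phi=np.ones(n),
            phi=None,
            deviance=np.zeros(n),
            x_names=("constant",),
            z_names=("constant",),
            acceptance={},
        )
        analytic = np.sqrt((1 + rho) / (1 - rho)) / np.sqrt(n)
        assert mc_error_ratio(chain, "beta[constant]") == pytest.approx(analytic, rel=0.25)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            batch_means_mc_error(np.arange(50.0))


class TestSummaries:
    def _chain_from(self, draws):
        from carlogit.mcmc import PosteriorChain

        draws = np.asarray(draws, float)
        return PosteriorChain(
            model="nonspatial",
            beta=draws[:, None],
            alpha=np.zeros((draws.size, 1)),
            tau_phi=np.ones(draws.size),
            phi=None,
            deviance=np.zeros(draws.size),
            x_names=("constant",),
            z_names=("constant",),
            acceptance={},
        )

    def test_constant_chain_degenerate_intervals(self):
        s = summarize(self._chain_from(np.full(500, 3.2)))
        row = s.loc["beta[constant]"]
        assert row["mean"] == pytest.approx(3.2)
        assert row["q2.5"] == row["q97.5"] == 3.2

    def test_symmetric_draws_not_significant(self, rng):
        s = summarize(self._chain_from(rng.normal(0, 1, 5000)))
        row = s.loc["beta[constant]"]
        assert not row["sig90"] and not row["sig95"]
        assert row["q5"] < 0 < row["q95"]

    def test_gaussian_quantile_oracle(self, rng):
        s = summarize(self._chain_from(rng.normal(2.0, 0.5, 200_000)))
        row = s.loc["beta[constant]"]
        assert row["q2.5"] == pytest.approx(2 - 1.96 * 0.5, abs=0.02)
        assert row["q97.5"] == pytest.approx(2 + 1.96 * 0.5, abs=0.02)
        assert row["sig95"]

    def test_intervals_nested(self, small_dataset):
        chain = fit("nonspatial", small_dataset, McmcConfig(n_iter=800, burn_in=400, seed=5))
        s = summarize(chain)
        assert (s["q2.5"] <= s["q5"]).all()
        assert (s["q95"] <= s["q97.5"]).all()
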