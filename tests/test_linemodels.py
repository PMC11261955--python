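import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from thyrodissect.linemodels import (
    LineModelGroup,
    LineModelMixture,
    LineModelMixtureResults,
    em_fit,
    gibbs_assign,
    group_prior_cov,
    lrt_groups,
    pair_loglik,
    prior_scale_coverage,
)
from thyrodissect.simulate import MixtureSimConfig, simulate_effect_pairs


def _pairs_df(b1, b2, se1, se2, keys=None):
    n = len(b1)
    return pd.DataFrame(
        {
            "key": keys or [f"v{i}" for i in range(n)],
            "beta1": b1, "se1": se1, "beta2": b2, "se2": se2,
        }
    )


class TestPriorCovariance:
    def test_degenerate_line_on_horizontal_axis(self):
        cov = group_prior_cov(LineModelGroup(scale=0.6, slope=0.0, cor=1.0))
        np.testing.assert_allclose(cov, np.diag([0.36, 0.0]), atol=1e-15)

    def test_unit_slope_pearson_equals_cor(self):
        # at |slope| = 1 the correlation parameter is the Pearson correlation
        for cor in (0.5, 0.9, 0.99):
            cov = group_prior_cov(LineModelGroup(scale=1.3, slope=1.0, cor=cor))
            pearson = cov[0, 1] / math.sqrt(cov[0, 0] * cov[1, 1])
            assert pearson == pytest.approx(cor)

    def test_outer_product_arithmetic(self):
        """Entries match an explicit eigen-axis outer-product evaluation."""
        s, b, cor = 0.6, 0.447, 0.99
        u = np.array([1.0, b]) / math.hypot(1.0, b)
        v = np.array([-b, 1.0]) / math.hypot(1.0, b)
        expected = s**2 * np.outer(u, u) + s**2 * (1 - cor) / (1 + cor) * np.outer(v, v)
        got = group_prior_cov(LineModelGroup(s, b, cor))
        np.testing.assert_allclose(got, expected, rtol=1e-12)
        # symmetric PSD
        assert np.linalg.eigvalsh(got).min() >= 0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            LineModelGroup(scale=0.0)
        with pytest.raises(ValueError):
            LineModelGroup(cor=1.5)


class TestPairLoglik:
    def test_closed_form_at_origin(self):
        # total covariance diag(0.37, 0.01): density 1/(2*pi*sqrt(0.0037))
        g = LineModelGroup(scale=0.6, slope=0.0, cor=1.0)
        expected = -math.log(2 * math.pi * math.sqrt(0.37 * 0.01))
        assert pair_loglik(0, 0, 0.1, 0.1, g) == pytest.approx(expected)
        assert math.exp(expected) == pytest.approx(2.616, abs=0.001)

    def test_point_reflection_symmetry(self):
        g = LineModelGroup(scale=0.6, slope=0.447, cor=0.99)
        assert pair_loglik(0.3, 0.2, 0.05, 0.04, g) == pytest.approx(
            pair_loglik(-0.3, -0.2, 0.05, 0.04, g)
        )

    def test_matches_quadrature_oracle(self):
        """The analytic Gaussian convolution equals brute-force 2-D
        integration of prior x noise on random fixtures."""
        rng = np.random.default_rng(42)
        for _ in range(5):
            g = LineModelGroup(
                scale=rng.uniform(0.3, 1.0),
                slope=rng.uniform(-1.5, 1.5),
                cor=rng.uniform(0.5, 0.995),
            )
            x1, x2 = rng.normal(0, 0.4, size=2)
            se1, se2 = rng.uniform(0.05, 0.2, size=2)
            cov = group_prior_cov(g)
            prior = stats.multivariate_normal([0, 0], cov)

            def integrand(t2, t1):
                return (
                    prior.pdf([t1, t2])
                    * stats.norm.pdf(x1, t1, se1)
                    * stats.norm.pdf(x2, t2, se2)
                )

            lim = 6.0 * g.scale
            val, _ = integrate.dblquad(
                integrand, -lim, lim, -lim, lim, epsabs=1e-12, epsrel=1e-9
            )
            assert pair_loglik(x1, x2, se1, se2, g) == pytest.approx(
                math.log(val), rel=1e-6
            )

    def test_singular_covariance_named(self):
        # cor=1 collapses the prior onto the line; a zero SE then leaves the
        # off-line direction without any variance
        g = LineModelGroup(scale=0.6, slope=0.0, cor=1.0)
        with pytest.raises(ValueError, match="singular.*beta2"):
            pair_loglik(0.1, 0.0, 0.1, 0.0, g)


class TestPriorCalibration:
    def test_two_scale_coverage_is_95_percent(self):
        cov = prior_scale_coverage(2.0)
        assert cov == pytest.approx(0.9545, abs=1e-4)
        assert round(100 * cov) == 95


class TestEMFit:
    def test_recovers_single_group_slope(self):
        cfg = MixtureSimConfig(
            n=400,
            groups=[LineModelGroup(0.6, 0.447, 0.99, slope_fixed=True)],
            proportions=(1.0,),
            seed=11,
        )
        df = simulate_effect_pairs(cfg)
        res = em_fit(
            df, [LineModelGroup(0.6, 0.2, 0.99, slope_fixed=False)], seed=11
        )
        assert res.groups[0].slope == pytest.approx(0.447, abs=0.05)
        assert res.converged

    def test_symmetric_data_gives_equal_proportions(self):
        rng = np.random.default_rng(3)
        # equally many points on the +1 and -1 lines
        amp = rng.normal(0, 0.5, size=200)
        b1 = np.concatenate([amp, amp])
        b2 = np.concatenate([amp, -amp]) + rng.normal(0, 0.02, size=400)
        df = _pairs_df(b1, b2, np.full(400, 0.02), np.full(400, 0.02))
        groups = [
            LineModelGroup(0.6, 1.0, 0.99, slope_fixed=True),
            LineModelGroup(0.6, -1.0, 0.99, slope_fixed=True),
        ]
        res = em_fit(df, groups, seed=3)
        assert res.proportions[0] == pytest.approx(0.5, abs=0.03)

    def test_loglik_trace_monotone(self):
        for seed in range(5):
            cfg = MixtureSimConfig(n=150, seed=seed)
            df = simulate_effect_pairs(cfg)
            res = em_fit(
                df,
                [
                    LineModelGroup(0.6, 0.0, 0.99, slope_fixed=True),
                    LineModelGroup(0.6, 0.8, 0.99, slope_fixed=False),
                ],
                seed=seed,
            )
            assert np.all(np.diff(res.loglik_trace) >= -1e-9)

    def test_proportions_sum_to_one(self):
        df = simulate_effect_pairs(MixtureSimConfig(n=100, seed=5))
        res = em_fit(
            df,
            [
                LineModelGroup(0.6, 0.0, 0.99, slope_fixed=True),
                LineModelGroup(0.6, 0.5, 0.99, slope_fixed=False),
            ],
            seed=5,
        )
        assert res.proportions.sum() == pytest.approx(1.0, abs=1e-12)

    def test_needs_two_points_and_one_group(self):
        df = _pairs_df([0.1], [0.1], [0.05], [0.05])
        with pytest.raises(ValueError):
            LineModelMixture(df, [LineModelGroup()])
        df2 = _pairs_df([0.1, 0.2], [0.1, 0.2], [0.05, 0.05], [0.05, 0.05])
        with pytest.raises(ValueError):
            LineModelMixture(df2, [])

    def test_parameter_recovery_over_replicates(self):
        """Over 20 seeded replicates at n=400 the free slope and the mixing
        proportion are both recovered to better than 0.05 on average."""
        slope_err, prop_err = [], []
        for seed in range(20):
            cfg = MixtureSimConfig(
                n=400,
                groups=[
                    LineModelGroup(0.6, 0.0, 0.99, slope_fixed=True),
                    LineModelGroup(0.6, 0.447, 0.99, slope_fixed=False),
                ],
                proportions=(0.66, 0.34),
                seed=seed,
            )
            df = simulate_effect_pairs(cfg)
            res = em_fit(
                df,
                [
                    LineModelGroup(0.6, 0.0, 0.99, slope_fixed=True),
                    LineModelGroup(0.6, 0.5, 0.99, slope_fixed=False),
                ],
                seed=seed,
            )
            slope_err.append(abs(res.groups[1].slope - 0.447))
            prop_err.append(abs(res.proportions[1] - 0.34))
        assert np.mean(slope_err) < 0.05
        assert np.mean(prop_err) < 0.05

    def test_classification_accuracy_at_high_posterior(self):
        """Variants assigned with posterior > 0.99 are almost always from
        the group they are assigned to."""
        correct = total = 0
        for seed in range(20):
            cfg = MixtureSimConfig(
                n=400,
                groups=[
                    LineModelGroup(0.6, 0.0, 0.99, slope_fixed=True),
                    LineModelGroup(0.6, 0.447, 0.99, slope_fixed=False),
                ],
                proportions=(0.66, 0.34),
                seed=100 + seed,
            )
            df = simulate_effect_pairs(cfg)
            res = em_fit(
                df,
                [
                    LineModelGroup(0.6, 0.0, 0.99, slope_fixed=True),
                    LineModelGroup(0.6, 0.5, 0.99, slope_fixed=False),
                ],
                seed=seed,
            )
            conf = res.posterior.max(axis=1) > 0.99
            assigned = res.posterior.argmax(axis=1)
            truth = df["true_group"].to_numpy()
            correct += int(np.sum(assigned[conf] == truth[conf]))
            total += int(conf.sum())
        assert total > 0
        assert correct / total > 0.95


class TestLRT:
    def _fits(self, seed=0):
        cfg = MixtureSimConfig(
            n=400,
            groups=[
                LineModelGroup(0.6, 0.0, 0.99, slope_fixed=True),
                LineModelGroup(0.6, 0.9, 0.99, slope_fixed=False),
            ],
            proportions=(0.5, 0.5),
            seed=seed,
        )
        df = simulate_effect_pairs(cfg)
        fit1 = em_fit(
            df, [LineModelGroup(0.6, 0.4, 0.99, slope_fixed=False)], seed=seed
        )
        fit2 = em_fit(
            df,
            [
                LineModelGroup(0.6, 0.0, 0.99, slope_fixed=True),
                LineModelGroup(0.6, 0.5, 0.99, slope_fixed=False),
            ],
            seed=seed,
        )
        return df, fit1, fit2

    def test_duplicated_group_statistic_near_zero(self):
        df = simulate_effect_pairs(MixtureSimConfig(n=200, seed=9))
        g = LineModelGroup(0.6, 0.3, 0.99, slope_fixed=True)
        fit1 = em_fit(df, [g], seed=9)
        fit2 = em_fit(df, [g, g], seed=9)
        out = lrt_groups(fit1, fit2)
        assert out["statistic"] == pytest.approx(0.0, abs=1e-6)
        assert out["p"] == pytest.approx(1.0, abs=1e-6)
        assert out["boundary_nonregular"] is True

    def test_separated_slopes_strongly_favoured(self):
        _, fit1, fit2 = self._fits(seed=0)
        out = lrt_groups(fit1, fit2)
        assert out["df"] == 1  # extra mixing proportion (second slope is fixed at 0)
        assert out["p"] < 1e-20

    def test_df_two_when_both_slopes_free(self):
        # one free-slope group vs two free-slope groups: extra slope + proportion
        df = simulate_effect_pairs(
            MixtureSimConfig(
                n=300,
                groups=[
                    LineModelGroup(0.6, 0.137, 0.99, slope_fixed=False),
                    LineModelGroup(0.6, 0.964, 0.99, slope_fixed=False),
                ],
                proportions=(0.5, 0.5),
                seed=21,
            )
        )
        fit1 = em_fit(
            df, [LineModelGroup(0.6, 0.5, 0.99, slope_fixed=False)], seed=21
        )
        fit2 = em_fit(
            df,
            [
                LineModelGroup(0.6, 0.1, 0.99, slope_fixed=False),
                LineModelGroup(0.6, 1.0, 0.99, slope_fixed=False),
            ],
            seed=21,
        )
        out = lrt_groups(fit1, fit2)
        assert out["df"] == 2
        assert out["p"] < 1e-20

    def test_statistic_invariant_to_data_order(self):
        df, fit1, fit2 = self._fits(seed=1)
        stat = lrt_groups(fit1, fit2)["statistic"]
        rev = df.iloc[::-1].reset_index(drop=True)
        fit1r = em_fit(
            rev, [LineModelGroup(0.6, 0.4, 0.99, slope_fixed=False)], seed=1
        )
        fit2r = em_fit(
            rev,
            [
                LineModelGroup(0.6, 0.0, 0.99, slope_fixed=True),
                LineModelGroup(0.6, 0.5, 0.99, slope_fixed=False),
            ],
            seed=1,
        )
        assert lrt_groups(fit1r, fit2r)["statistic"] == pytest.approx(stat, abs=1e-4)


class TestGibbs:
    def _fitted(self, df, groups, pi):
        model = LineModelMixture(df, groups)
        L = model._loglik_matrix(groups)
        ll, gamma = LineModelMixture._total_and_gamma(L, np.asarray(pi))
        return LineModelMixtureResults(
            model=model, groups=groups, proportions=np.asarray(pi, dtype=float),
            posterior=gamma, loglik=ll, loglik_trace=np.array([ll]),
            n_iter=1, converged=True,
        )

    def test_identical_groups_give_half_memberships(self):
        df = simulate_effect_pairs(MixtureSimConfig(n=60, seed=2))
        g = LineModelGroup(0.6, 0.3, 0.99, slope_fixed=True)
        res = self._fitted(df, [g, g], [0.5, 0.5])
        # with the proportions held at the symmetric point every membership
        # is exactly 0.5 up to binomial Monte-Carlo error
        member = res.gibbs(n_iter=8000, burn_in=500, seed=2, fix_proportions=True)
        np.testing.assert_allclose(member["p_group1"], 0.5, atol=0.03)
        # the full sampler also integrates over the proportions; identical
        # groups make their posterior uninformative (marginally uniform), so
        # the label chain mixes slowly and the tolerance is wider
        member_free = res.gibbs(n_iter=2000, burn_in=500, seed=2)
        np.testing.assert_allclose(member_free["p_group1"], 0.5, atol=0.1)

    def test_fixed_proportions_match_analytic_posterior(self):
        """With proportions held fixed the sweep means converge to the
        analytic responsibilities (law of large numbers)."""
        df = simulate_effect_pairs(MixtureSimConfig(n=80, seed=4))
        groups = [
            LineModelGroup(0.6, 0.0, 0.99, slope_fixed=True),
            LineModelGroup(0.6, 0.447, 0.99, slope_fixed=True),
        ]
        res = self._fitted(df, groups, [0.5, 0.5])
        member = res.gibbs(
            n_iter=2000, burn_in=500, seed=4, fix_proportions=True
        )
        err = np.abs(member["p_group2"].to_numpy() - res.posterior[:, 1])
        assert err.mean() < 0.02
        assert err.max() < 0.05

    def test_extreme_point_assigned_to_its_line(self):
        groups = [
            LineModelGroup(0.6, 0.0, 0.99, slope_fixed=True),
            LineModelGroup(0.6, 0.9, 0.99, slope_fixed=True),
        ]
        # far along the slope-0.9 line, tiny SEs; filler points on each line
        df = _pairs_df(
            [1.0, 0.5, -0.4], [0.9, 0.01, -0.01],
            [0.005, 0.01, 0.01], [0.005, 0.01, 0.01],
        )
        res = self._fitted(df, groups, [0.5, 0.5])
        assert res.posterior[0, 1] > 0.99
        member = res.gibbs(n_iter=2000, burn_in=500, seed=6)
        assert member["p_group2"].iloc[0] > 0.99

    def test_reproducible_under_seed(self):
        df = simulate_effect_pairs(MixtureSimConfig(n=50, seed=8))
        groups = [
            LineModelGroup(0.6, 0.0, 0.99, slope_fixed=True),
            LineModelGroup(0.6, 0.447, 0.99, slope_fixed=True),
        ]
        res = self._fitted(df, groups, [0.5, 0.5])
        m1 = res.gibbs(n_iter=500, burn_in=100, seed=77)
        m2 = res.gibbs(n_iter=500, burn_in=100, seed=77)
        pd.testing.assert_frame_equal(m1, m2)

    def test_seed_required(self):
        df = simulate_effect_pairs(MixtureSimConfig(n=50, seed=8))
        g = LineModelGroup(0.6, 0.0, 0.99, slope_fixed=True)
        res = self._fitted(df, [g, g], [0.5, 0.5])
        with pytest.raises(ValueError, match="seed"):
            res.gibbs(n_iter=500, burn_in=100)

    def test_functional_wrapper(self):
        df = simulate_effect_pairs(MixtureSimConfig(n=50, seed=8))
        groups = [
            LineModelGroup(0.6, 0.0, 0.99, slope_fixed=True),
            LineModelGroup(0.6, 0.447, 0.99, slope_fixed=True),
        ]
        res = self._fitted(df, groups, [0.5, 0.5])
        out = gibbs_assign(df, res, n_iter=500, burn_in=100, seed=5)
        assert set(out.columns) == {"key", "p_group1", "p_group2", "map_group"}
        sums = out["p_group1"] + out["p_group2"]
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)


class TestSummary:
    def test_summary_contains_estimates(self):
        df = simulate_effect_pairs(MixtureSimConfig(n=100, seed=1))
        res = em_fit(
            df,
            [
                LineModelGroup(0.6, 0.0, 0.99, slope_fixed=True),
                LineModelGroup(0.6, 0.5, 0.99, slope_fixed=False),
            ],
            seed=1,
        )
        text = res.summary()
        assert "log-likelihood" in text
        assert f"{res.groups[1].slope:>9.4f}".strip() in text

    def test_plot_scatter_returns_axis(self):
        import matplotlib

        matplotlib.use("Agg")
        df = simulate_effect_pairs(MixtureSimConfig(n=100, seed=1))
        res = em_fit(
            df,
            [
                LineModelGroup(0.6, 0.0, 0.99, slope_fixed=True),
                LineModelGroup(0.6, 0.5, 0.99, slope_fixed=False),
            ],
            seed=1,
        )
        ax = res.plot_scatter()
        assert ax.get_xlabel().startswith("effect in primary")
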