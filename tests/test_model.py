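"""Gibbs-sampler tests: initializer, conjugate oracle, imputation, DIC, ESS."""

import numpy as np
import pandas as pd
import pytest

import mvgrowth as mg
from mvgrowth.data import build_design
from mvgrowth.model import (
    PriorSpec,
    _Workspace,
    deviance,
    effective_sample_size,
    gibbs_step,
    initialize,
    run_chains,
)
from mvgrowth.params import OUTCOMES, Y_COLUMNS


def _single_child_frame(n_occasions=40, seed=0):
    """One school, one child, many occasions: a plain linear model in disguise."""
    rng = np.random.default_rng(seed)
    rows = []
    sigma = np.array([[1.0, 0.3, -0.2], [0.3, 0.8, 0.1], [-0.2, 0.1, 1.2]])
    chol = np.linalg.cholesky(sigma)
    beta = np.array([[0.5, -0.2, 1.0], [0.1, 0.3, -0.4]])  # intercept, t
    for occ in range(1, n_occasions + 1):
        t = occ - 1.0
        mu = beta[0] + beta[1] * t
        y = mu + chol @ rng.standard_normal(3)
        rows.append(
            {
                "school_id": 1, "child_id": 1, "arm": 0, "occasion": occ,
                "male": 0, "fsm": 0, "at_risk": 0,
                "school_size_z": 0.0, "school_fsm_z": 0.0,
                "y_concentration": y[0], "y_disruptive": y[1], "y_prosocial": y[2],
            }
        )
    return pd.DataFrame(rows), sigma


class TestInitialize:
    def test_noise_free_single_level_recovers_beta_exactly(self):
        frame, _ = _single_child_frame()
        # replace outcomes with the exact linear trend: zero residual
        t = frame["occasion"].to_numpy(float) - 1.0
        frame["y_concentration"] = 0.5 + 0.1 * t
        frame["y_disruptive"] = -0.2 + 0.3 * t
        frame["y_prosocial"] = 1.0 - 0.4 * t
        spec = mg.ModelSpec(fixed_terms=("intercept", "t"), poly_degree=1)
        state = initialize(build_design(frame, spec))
        np.testing.assert_allclose(
            state.beta, np.array([[0.5, -0.2, 1.0], [0.1, 0.3, -0.4]]), atol=1e-8
        )
        assert np.diag(state.omega_school).max() < 1e-5
        assert np.diag(state.omega_child)[:3].max() < 1e-5

    def test_intercept_only_init_is_observed_means(self, uncond_frame):
        frame, _ = uncond_frame
        state = initialize(build_design(frame, mg.ModelSpec.unconditional()))
        means = frame[list(Y_COLUMNS)].mean().to_numpy()
        np.testing.assert_allclose(state.beta.ravel(), means, atol=1e-10)

    def test_balanced_two_level_variance_split(self):
        """1:1 child/residual variance split recovered within 20% at 100 schools."""
        tp = mg.TrueParameters(
            beta=np.zeros((1, 3)),
            omega_school=np.zeros((3, 3)),
            omega_child=np.eye(3),
            omega_resid=np.eye(3),
            terms=("intercept",),
        )
        cfg = mg.SimulationConfig(
            n_schools=100, children_per_school=(20, 20), true_params=tp,
            missingness=mg.MissingnessSpec.none(), seed=31,
        )
        frame, _ = mg.simulate_trial(cfg)
        state = initialize(build_design(frame, mg.ModelSpec.unconditional()))
        np.testing.assert_allclose(np.diag(state.omega_child)[:3], 1.0, rtol=0.2)
        np.testing.assert_allclose(np.diag(state.omega_resid), 1.0, rtol=0.2)

    def test_too_few_observations_rejected(self):
        frame, _ = _single_child_frame(n_occasions=3)
        frame = frame.iloc[:2]
        with pytest.raises(ValueError, match="fewer observations"):
            initialize(build_design(frame, mg.ModelSpec.full()))


class TestGibbsStep:
    def test_beta_draws_match_conjugate_closed_form(self):
        """With covariances frozen and no higher-level effects, the coefficient
        draws must follow the closed-form multivariate-normal posterior."""
        frame, sigma = _single_child_frame()
        spec = mg.ModelSpec(fixed_terms=("intercept", "t"), poly_degree=1)
        design = build_design(frame, spec)
        work = _Workspace(design)
        state = initialize(design)
        state.omega_resid = sigma  # freeze at the true residual covariance
        priors = PriorSpec.from_state(state)
        rng = np.random.default_rng(77)

        E = np.linalg.inv(sigma)
        X, Y = design.X, design.Y
        prec = np.kron(E, X.T @ X)
        cov = np.linalg.inv(prec)
        mean = cov @ (X.T @ Y @ E).T.ravel()

        n_draws = 50_000
        draws = np.empty((n_draws, 6))
        for i in range(n_draws):
            gibbs_step(state, design, priors, rng, updates=("beta",), work=work)
            draws[i] = state.beta.T.ravel()

        mc_se = np.sqrt(np.diag(cov) / n_draws)
        np.testing.assert_allclose(draws.mean(axis=0), mean, atol=4.5 * mc_se.max())
        emp_cov = np.cov(draws.T)
        scale = np.abs(np.diag(cov)).max()
        np.testing.assert_allclose(emp_cov, cov, atol=6 * scale / np.sqrt(n_draws) + 0.02 * scale)

    def test_impute_is_noop_without_missing_cells(self, uncond_frame):
        frame, _ = uncond_frame
        design = build_design(frame, mg.ModelSpec.unconditional())
        work = _Workspace(design)
        assert work.patterns == []
        state = initialize(design)
        y_before = state.y.copy()
        gibbs_step(state, design, PriorSpec.from_state(state),
                   np.random.default_rng(0), updates=("impute",), work=work)
        np.testing.assert_array_equal(state.y, y_before)

    def test_imputation_fills_only_missing_cells(self, full_frame):
        frame, _ = full_frame
        design = build_design(frame, mg.ModelSpec.full())
        work = _Workspace(design)
        assert len(work.patterns) > 0
        state = initialize(design)
        gibbs_step(state, design, PriorSpec.from_state(state),
                   np.random.default_rng(0), updates=("impute",), work=work)
        np.testing.assert_array_equal(
            state.y[design.obs_mask], design.Y[design.obs_mask]
        )

    def test_degenerate_truth_beta_recovery(self):
        """Zero random-effect variances and identity residual: the sampler's
        beta posterior centers on truth and level-2/3 variances shrink."""
        tp = mg.TrueParameters(
            beta=np.zeros((1, 3)),
            omega_school=np.zeros((3, 3)),
            omega_child=np.zeros((3, 3)),
            omega_resid=np.eye(3),
            terms=("intercept",),
        )
        cfg = mg.SimulationConfig(
            n_schools=20, children_per_school=(10, 10), true_params=tp,
            missingness=mg.MissingnessSpec.none(), seed=32,
        )
        frame, _ = mg.simulate_trial(cfg)
        samples = mg.fit_model(
            frame, mg.ModelSpec.unconditional(), n_chains=2, n_iter=600,
            burn_in=150, seed=33,
        )
        summ = samples.summary()
        for out in OUTCOMES:
            row = summ.loc[f"beta[{out},intercept]"]
            mc_se = row["sd"] / np.sqrt(max(row["ess"], 1.0))
            # true beta = 0; allow sampling noise of the data itself (n=1000)
            assert abs(row["mean"]) < 3 * (mc_se + 1.0 / np.sqrt(1000))
        assert summ.loc["omega_school[0,0]", "mean"] < 0.05
        assert summ.loc["omega_child[0,0]", "mean"] < 0.08


class TestRunChains:
    def test_same_per_chain_seeds_give_identical_chains(self, uncond_frame):
        frame, _ = uncond_frame
        samples = mg.fit_model(
            frame, mg.ModelSpec.unconditional(), n_chains=3, n_iter=60,
            burn_in=10, seed=[5, 5, 5],
        )
        np.testing.assert_array_equal(samples.draws[0], samples.draws[1])
        np.testing.assert_array_equal(samples.draws[0], samples.draws[2])

    def test_run_is_reproducible(self, uncond_frame):
        frame, _ = uncond_frame
        a = mg.fit_model(frame, mg.ModelSpec.unconditional(), n_chains=2,
                         n_iter=60, burn_in=10, seed=6)
        b = mg.fit_model(frame, mg.ModelSpec.unconditional(), n_chains=2,
                         n_iter=60, burn_in=10, seed=6)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_burn_in_validation(self, uncond_frame):
        frame, _ = uncond_frame
        with pytest.raises(ValueError, match="n_iter > burn_in"):
            mg.fit_model(frame, mg.ModelSpec.unconditional(), n_iter=10, burn_in=10)

    def test_all_covariance_draws_psd(self, full_samples):
        for draws in (
            full_samples.omega_school_draws(),
            full_samples.omega_child_draws(),
            full_samples.omega_resid_draws(),
        ):
            eigmin = np.linalg.eigvalsh(draws).min()
            assert eigmin > -1e-8

    def test_marginal_variance_conservation_unconditional(self):
        """Posterior mean of the summed level variances matches the observed
        total variance of each outcome within 5% (at a scale where the weak
        covariance priors carry negligible weight)."""
        cfg = mg.SimulationConfig(
            n_schools=40, children_per_school=(25, 25),
            true_params=mg.TrueParameters.unconditional_reference(),
            missingness=mg.MissingnessSpec.none(), seed=40,
        )
        frame, _ = mg.simulate_trial(cfg)
        z, _ = mg.standardize_outcomes(frame)
        samples = mg.fit_model(z, mg.ModelSpec.unconditional(), n_chains=2,
                               n_iter=500, burn_in=100, seed=34)
        means = samples.posterior_mean_state()
        total = (
            np.diag(means["omega_school"])
            + np.diag(means["omega_child"])[:3]
            + np.diag(means["omega_resid"])
        )
        observed = z[list(Y_COLUMNS)].var(ddof=1).to_numpy()
        np.testing.assert_allclose(total, observed, rtol=0.05)

    def test_child_row_permutation_gives_identical_design_and_fit(self, full_frame):
        """Row order cannot matter: the design canonicalizes ordering, so the
        same seed gives bit-identical posteriors."""
        frame, _ = full_frame
        shuffled = frame.sample(frac=1.0, random_state=3).reset_index(drop=True)
        a = mg.fit_model(frame, mg.ModelSpec.full(), n_chains=1, n_iter=40,
                         burn_in=10, seed=7)
        b = mg.fit_model(shuffled, mg.ModelSpec.full(), n_chains=1, n_iter=40,
                         burn_in=10, seed=7)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_mcar_masking_leaves_beta_posterior_unchanged(self):
        """Masking 10% of outcome cells completely at random must not move the
        coefficient posterior beyond Monte-Carlo error: the augmented-data
        sampler uses all remaining information."""
        tp = mg.TrueParameters.unconditional_reference()
        cfg = mg.SimulationConfig(
            n_schools=30, children_per_school=(15, 15), true_params=tp,
            missingness=mg.MissingnessSpec.none(), seed=35,
        )
        frame, _ = mg.simulate_trial(cfg)
        masked = mg.apply_missingness(
            frame, mg.MissingnessSpec(wave_base_rates=(0.1,) * 5, cell_level=True),
            seed=36,
        )
        kw = dict(n_chains=2, n_iter=900, burn_in=200)
        full = mg.fit_model(frame, mg.ModelSpec.unconditional(), seed=37, **kw)
        part = mg.fit_model(masked, mg.ModelSpec.unconditional(), seed=38, **kw)
        s1, s2 = full.summary(), part.summary()
        for out in OUTCOMES:
            name = f"beta[{out},intercept]"
            se = np.sqrt(
                s1.loc[name, "sd"] ** 2 / max(s1.loc[name, "ess"], 1)
                + s2.loc[name, "sd"] ** 2 / max(s2.loc[name, "ess"], 1)
            )
            assert abs(s1.loc[name, "mean"] - s2.loc[name, "mean"]) < 3 * se


class TestDIC:
    def test_deviance_doubles_when_data_duplicated(self, uncond_frame):
        frame, _ = uncond_frame
        spec = mg.ModelSpec.unconditional()
        d1 = build_design(frame, spec)
        dup = frame.copy()
        dup["child_id"] = dup["child_id"] + 1_000_000
        both = pd.concat([frame, dup], ignore_index=True)
        d2 = build_design(both, spec)
        state = initialize(d1)
        u1 = np.zeros((d1.n_schools, 3))
        vw1 = np.zeros((d1.n_children, 3))
        u2 = np.zeros((d2.n_schools, 3))
        vw2 = np.zeros((d2.n_children, 3))
        dev1 = deviance(d1, state.beta, u1, vw1, state.omega_resid)
        dev2 = deviance(d2, state.beta, u2, vw2, state.omega_resid)
        assert dev2 == pytest.approx(2 * dev1, rel=1e-12)

    def test_point_mass_posterior_has_zero_pd(self, uncond_frame):
        """A single stored draw is a point-mass posterior: pD = 0 and DIC
        equals the deviance at that point."""
        frame, _ = uncond_frame
        samples = mg.fit_model(frame, mg.ModelSpec.unconditional(), n_chains=1,
                               n_iter=21, burn_in=20, seed=39)
        assert samples.n_stored == 1
        assert samples.pd_eff == pytest.approx(0.0, abs=1e-6)
        assert samples.dic == pytest.approx(samples.deviance[0, 0], rel=1e-9)

    def test_cubic_model_beats_intercept_only_when_truth_is_cubic(self):
        """DIC selects the cubic-time model over the empty model on data with
        strong cubic trends, across seeds."""
        terms = ("intercept", "t", "t2", "t3")
        beta = np.array(
            [[-0.4, -0.5, 0.35], [0.5, 0.4, -0.45],
             [-0.2, 0.15, 0.18], [0.05, -0.03, -0.04]]
        )
        cubic_spec = mg.ModelSpec(fixed_terms=terms, poly_degree=3)
        empty_spec = mg.ModelSpec.unconditional()
        wins = 0
        for seed in range(10):
            tp = mg.TrueParameters(
                beta=beta,
                omega_school=0.05 * np.eye(3),
                omega_child=0.5 * np.eye(3),
                omega_resid=0.4 * np.eye(3),
                terms=terms,
            )
            cfg = mg.SimulationConfig(
                n_schools=12, children_per_school=(8, 8), true_params=tp,
                missingness=mg.MissingnessSpec.none(), seed=100 + seed,
            )
            frame, _ = mg.simulate_trial(cfg)
            kw = dict(n_chains=1, n_iter=300, burn_in=100, seed=seed)
            dic_cubic = mg.fit_model(frame, cubic_spec, **kw).dic
            dic_empty = mg.fit_model(frame, empty_spec, **kw).dic
            wins += dic_cubic < dic_empty
        assert wins >= 9


class TestESS:
    def test_white_noise(self, rng):
        x = rng.standard_normal(10_000)
        assert effective_sample_size(x) == pytest.approx(10_000, rel=0.10)

    def test_ar1_closed_form(self, rng):
        rho, n = 0.9, 10_000
        x = np.empty(n)
        x[0] = rng.standard_normal()
        eps = rng.standard_normal(n) * np.sqrt(1 - rho**2)
        for i in range(1, n):
            x[i] = rho * x[i - 1] + eps[i]
        expected = n * (1 - rho) / (1 + rho)
        assert effective_sample_size(x) == pytest.approx(expected, rel=0.25)

    def test_constant_chain_is_zero_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert effective_sample_size(np.ones(500)) == 0.0

    def test_chains_sum(self, rng):
        x = rng.standard_normal((2, 5_000))
        total = effective_sample_size(x)
        assert total == pytest.approx(10_000, rel=0.10)


def test_save_load_round_trip(tmp_path, full_samples):
    from mvgrowth.model import load_samples, save_samples

    save_samples(full_samples, tmp_path / "s.csv", tmp_path / "s.json")
    back = load_samples(tmp_path / "s.csv", tmp_path / "s.json")
    np.testing.assert_allclose(back.draws, full_samples.draws, rtol=0, atol=1e-12)
    assert back.param_names == full_samples.param_names
    assert back.dic == pytest.approx(full_samples.dic)
    assert back.spec == full_samples.spec
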