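"""Multivariate three-level growth-curve model fit by Gibbs sampling.

The model for the 3-vector of standardized outcomes of child *i* in school
*j* at occasion *t* (time coded 0..T-1) is

    y_tij = B' x_tij + u_j + v_ij + w_ij * t + e_tij

with school intercepts u_j ~ N3(0, Omega_school), child effects
(v_ij, w_ij) ~ N6(0, Omega_child) (w = 0 for intercept-only child parts),
and occasion-level residual triples e_tij ~ N3(0, Omega_resid) independent
across occasions with a single time-invariant covariance. The fixed-part
design x is shared across the three outcomes.

Estimation is a bespoke Gibbs sampler: every full conditional is conjugate
(multivariate-normal draws for coefficients and random effects,
inverse-Wishart draws for the three covariance matrices), and missing outcome
components are imputed by data augmentation from their multivariate-normal
conditional, which makes the fit use all available information and leaves it
unbiased under missing-at-random outcome loss. No Metropolis step is needed.

Priors are diffuse: improper flat on the fixed effects, and inverse-Wishart
with degrees of freedom equal to the dimension and scale matrix set from the
(method-of-moments) initializer estimate for each covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy.stats import invwishart

from .data import DesignMatrices, ModelSpec, build_design
from .params import OUTCOMES


class NumericalError(RuntimeError):
    """A linear-algebra step failed even after diagonal regularization."""


_JITTER = 1e-8


def _chol(mat: np.ndarray, what: str) -> np.ndarray:
    """Lower Cholesky factor with a diagonal nudge; NumericalError on failure."""
    try:
        return np.linalg.cholesky(mat + _JITTER * np.eye(mat.shape[0]))
    except np.linalg.LinAlgError as exc:
        raise NumericalError(f"Cholesky failed for {what}: {exc}") from exc


def _sym_inv(mat: np.ndarray, what: str) -> np.ndarray:
    L = _chol(mat, what)
    inv = sla.cho_solve((L, True), np.eye(mat.shape[0]))
    return (inv + inv.T) / 2.0


@dataclass(frozen=True)
class PriorSpec:
    """Diffuse priors: flat on beta, inverse-Wishart on each covariance.

    Degrees of freedom default to the matrix dimension (the weakest proper
    choice) and the scale matrix to ``df * initializer estimate``, so the
    prior mode sits near the data-driven starting value while contributing
    the weight of only ``df`` pseudo-observations. ``scale_factor`` rescales
    all three scale matrices for prior-sensitivity checks.
    """

    df_school: int
    scale_school: np.ndarray
    df_child: int
    scale_child: np.ndarray
    df_resid: int
    scale_resid: np.ndarray

    def __post_init__(self) -> None:
        for df, scale, name in (
            (self.df_school, self.scale_school, "school"),
            (self.df_child, self.scale_child, "child"),
            (self.df_resid, self.scale_resid, "resid"),
        ):
            if df < scale.shape[0]:
                raise ValueError(f"{name}: df must be >= dimension")

    @classmethod
    def from_state(cls, state: "ParameterState", scale_factor: float = 1.0) -> "PriorSpec":
        def scale(mat: np.ndarray) -> np.ndarray:
            dim = mat.shape[0]
            s = mat.copy()
            # floor tiny initializer variances so the prior scale stays PD
            np.fill_diagonal(s, np.maximum(np.diag(s), 1e-3))
            return scale_factor * dim * s

        return cls(
            df_school=3,
            scale_school=scale(state.omega_school),
            df_child=state.omega_child.shape[0],
            scale_child=scale(state.omega_child),
            df_resid=3,
            scale_resid=scale(state.omega_resid),
        )


@dataclass
class ParameterState:
    """One complete parameter draw, including random effects and imputations."""

    beta: np.ndarray          # (p, 3)
    u: np.ndarray             # (n_schools, 3)
    vw: np.ndarray            # (n_children, 3 or 6)
    omega_school: np.ndarray  # (3, 3)
    omega_child: np.ndarray   # (3, 3) or (6, 6)
    omega_resid: np.ndarray   # (3, 3)
    y: np.ndarray             # (n_rows, 3) completed outcomes


ALL_UPDATES = ("impute", "beta", "school", "child", "cov_school", "cov_child", "cov_resid")


def initialize(design: DesignMatrices) -> ParameterState:
    """Starting values: per-outcome OLS plus a method-of-moments variance split.

    Fixed effects come from ordinary least squares on the observed cells of
    each outcome; the OLS residuals are then split into between-school,
    between-children and within-child variance by comparing school means,
    child means, and within-child deviations. Cross-outcome covariances start
    at zero. Starting values only affect convergence speed here; burn-in
    adequacy is judged by ESS and multi-chain agreement.
    """
    X, Y, mask = design.X, design.Y, design.obs_mask
    p = X.shape[1]
    beta = np.zeros((p, 3))
    resid = np.full_like(Y, np.nan)
    for k in range(3):
        rows = mask[:, k]
        if rows.sum() < p:
            raise ValueError(
                f"outcome {OUTCOMES[k]}: fewer observations ({rows.sum()}) than "
                f"fixed terms ({p})"
            )
        coef, *_ = np.linalg.lstsq(X[rows], Y[rows, k], rcond=None)
        beta[:, k] = coef
        resid[rows, k] = Y[rows, k] - X[rows] @ coef

    def _safe_var(values: np.ndarray) -> float:
        values = values[~np.isnan(values)]
        if values.size < 2:
            return 0.0
        return float(np.var(values, ddof=1))

    var_school = np.zeros(3)
    var_child = np.zeros(3)
    var_within = np.zeros(3)
    rdf = pd.DataFrame(resid, columns=list(OUTCOMES))
    rdf["child"] = design.child_idx
    rdf["school"] = design.school_idx
    mean_occasions = len(rdf) / design.n_children
    for k, out in enumerate(OUTCOMES):
        # unbiased within: average per-child sample variance
        per_child_var = rdf.groupby("child")[out].var(ddof=1)
        var_within[k] = max(np.nanmean(per_child_var.to_numpy()), 1e-6)
        child_means = rdf.groupby("child")[out].mean()
        school_of_child = pd.Series(design.child_school, index=np.arange(design.n_children))
        school_means = child_means.groupby(school_of_child.loc[child_means.index]).mean()
        var_school[k] = max(_safe_var(school_means.to_numpy()), 0.0)
        centered_child = child_means - school_means.loc[
            school_of_child.loc[child_means.index]
        ].to_numpy()
        # child-mean variance contains within-noise ~ sigma_w / T; remove it
        var_child[k] = max(
            _safe_var(centered_child.to_numpy()) - var_within[k] / mean_occasions, 0.0
        )

    q = design.spec.n_child_effects
    omega_child = np.zeros((q, q))
    omega_child[:3, :3] = np.diag(np.maximum(var_child, 1e-6))
    if q == 6:
        # modest starting slope variance; refined by the sampler
        omega_child[3:, 3:] = np.diag(np.maximum(0.1 * var_child, 1e-4))

    y_complete = Y.copy()
    fitted = X @ beta
    y_complete[~mask] = fitted[~mask]
    return ParameterState(
        beta=beta,
        u=np.zeros((design.n_schools, 3)),
        vw=np.zeros((design.n_children, q)),
        omega_school=np.diag(np.maximum(var_school, 1e-6)),
        omega_child=omega_child,
        omega_resid=np.diag(var_within),
        y=y_complete,
    )


class _Workspace:
    """Static per-design quantities reused at every Gibbs iteration."""

    def __init__(self, design: DesignMatrices):
        d = design
        self.XtX = d.X.T @ d.X
        self.t = d.time
        C = d.n_children
        self.child_starts = np.searchsorted(d.child_idx, np.arange(C))
        self.child_n = np.bincount(d.child_idx, minlength=C).astype(float)
        self.child_st = np.bincount(d.child_idx, weights=d.time, minlength=C)
        self.child_stt = np.bincount(d.child_idx, weights=d.time**2, minlength=C)
        self.school_n = np.bincount(d.school_idx, minlength=d.n_schools).astype(float)
        # missingness patterns among kept rows (>=1 observed outcome each)
        self.patterns: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
        self.full_rows = np.flatnonzero(d.obs_mask.all(axis=1))
        partial = np.flatnonzero(~d.obs_mask.all(axis=1))
        if partial.size:
            keys = d.obs_mask[partial] @ np.array([1, 2, 4])
            for key in np.unique(keys):
                idx = partial[keys == key]
                obs = np.flatnonzero(d.obs_mask[idx[0]])
                mis = np.flatnonzero(~d.obs_mask[idx[0]])
                self.patterns.append((obs, mis, idx))


def _batched_normal_draw(
    rng: np.random.Generator, prec: np.ndarray, lin: np.ndarray, what: str
) -> np.ndarray:
    """Draw x_b ~ N(prec_b^-1 lin_b, prec_b^-1) for a batch of small systems."""
    try:
        prec = prec + _JITTER * np.eye(prec.shape[-1])
        cov = np.linalg.inv(prec)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(f"precision inversion failed for {what}") from exc
    cov = (cov + np.swapaxes(cov, -1, -2)) / 2.0
    mean = np.einsum("...ij,...j->...i", cov, lin)
    try:
        chol = np.linalg.cholesky(cov + _JITTER * np.eye(cov.shape[-1]))
    except np.linalg.LinAlgError as exc:
        raise NumericalError(f"covariance factorization failed for {what}") from exc
    z = rng.standard_normal(mean.shape)
    return mean + np.einsum("...ij,...j->...i", chol, z)


def _child_contribution(state: ParameterState, design: DesignMatrices) -> np.ndarray:
    cv = state.vw[design.child_idx]
    out = cv[:, :3].copy()
    if state.vw.shape[1] == 6:
        out += cv[:, 3:] * design.time[:, None]
    return out


def gibbs_step(
    state: ParameterState,
    design: DesignMatrices,
    priors: PriorSpec,
    rng: np.random.Generator,
    updates: tuple[str, ...] = ALL_UPDATES,
    work: _Workspace | None = None,
) -> ParameterState:
    """One full scan of conjugate conditional updates, in fixed order.

    Order: (1) impute missing outcome components; (2) joint fixed-effect
    draw; (3) school intercepts; (4) child effects; (5) school- and
    child-level covariances (inverse-Wishart); (6) residual covariance
    (inverse-Wishart). ``updates`` can mask substeps, e.g. to freeze the
    covariances when checking the coefficient draw against its closed form.
    Mutates and returns ``state``. Random numbers are consumed strictly in
    the substep order above, so a seed reproduces the chain exactly.
    """
    if work is None:
        work = _Workspace(design)
    d = design
    E = _sym_inv(state.omega_resid, "omega_resid")
    u_rows = state.u[d.school_idx]
    child_rows = _child_contribution(state, d)
    q = state.vw.shape[1]

    if "impute" in updates and work.patterns:
        mu = d.X @ state.beta + u_rows + child_rows
        sigma = state.omega_resid
        for obs, mis, idx in work.patterns:
            s_oo_inv = _sym_inv(sigma[np.ix_(obs, obs)], "imputation block")
            gain = sigma[np.ix_(mis, obs)] @ s_oo_inv
            cond_cov = sigma[np.ix_(mis, mis)] - gain @ sigma[np.ix_(obs, mis)]
            resid_obs = d.Y[np.ix_(idx, obs)] - mu[np.ix_(idx, obs)]
            cond_mean = mu[np.ix_(idx, mis)] + resid_obs @ gain.T
            chol = _chol(cond_cov, "imputation conditional")
            z = rng.standard_normal((idx.size, mis.size))
            state.y[np.ix_(idx, mis)] = cond_mean + z @ chol.T

    if "beta" in updates:
        p = d.X.shape[1]
        ystar = state.y - u_rows - child_rows
        prec = np.kron(E, work.XtX)
        lin = (d.X.T @ (ystar @ E)).T.ravel()
        try:
            cf = sla.cho_factor(prec + _JITTER * np.eye(3 * p))
        except np.linalg.LinAlgError as exc:
            raise NumericalError("degenerate fixed-part design") from exc
        mean = sla.cho_solve(cf, lin)
        upper = np.triu(cf[0]) if not cf[1] else None
        if upper is None:  # pragma: no cover - cho_factor returns upper by default
            upper = np.linalg.cholesky(prec + _JITTER * np.eye(3 * p)).T
        z = rng.standard_normal(3 * p)
        draw = mean + sla.solve_triangular(upper, z, lower=False)
        state.beta = draw.reshape(3, p).T
        u_rows = state.u[d.school_idx]

    fixed = d.X @ state.beta

    if "school" in updates:
        resid = state.y - fixed - child_rows
        school_sums = np.zeros((d.n_schools, 3))
        np.add.at(school_sums, d.school_idx, resid)
        om_u_inv = _sym_inv(state.omega_school, "omega_school")
        prec = om_u_inv[None, :, :] + work.school_n[:, None, None] * E[None, :, :]
        lin = school_sums @ E
        state.u = _batched_normal_draw(rng, prec, lin, "school effects")
        u_rows = state.u[d.school_idx]

    if "child" in updates:
        resid = state.y - fixed - u_rows
        s0 = np.add.reduceat(resid, work.child_starts, axis=0)
        om_c_inv = _sym_inv(state.omega_child, "omega_child")
        if q == 3:
            prec = om_c_inv[None, :, :] + work.child_n[:, None, None] * E[None, :, :]
            lin = s0 @ E
        else:
            s1 = np.add.reduceat(resid * d.time[:, None], work.child_starts, axis=0)
            C = d.n_children
            prec = np.tile(om_c_inv, (C, 1, 1))
            prec[:, :3, :3] += work.child_n[:, None, None] * E
            prec[:, :3, 3:] += work.child_st[:, None, None] * E
            prec[:, 3:, :3] += work.child_st[:, None, None] * E
            prec[:, 3:, 3:] += work.child_stt[:, None, None] * E
            lin = np.concatenate([s0 @ E, s1 @ E], axis=1)
        state.vw = _batched_normal_draw(rng, prec, lin, "child effects")
        child_rows = _child_contribution(state, d)

    if "cov_school" in updates:
        scale = priors.scale_school + state.u.T @ state.u
        state.omega_school = invwishart.rvs(
            df=priors.df_school + d.n_schools, scale=scale, random_state=rng
        )
    if "cov_child" in updates:
        scale = priors.scale_child + state.vw.T @ state.vw
        state.omega_child = invwishart.rvs(
            df=priors.df_child + d.n_children, scale=scale, random_state=rng
        )
    if "cov_resid" in updates:
        resid = state.y - fixed - u_rows - child_rows
        scale = priors.scale_resid + resid.T @ resid
        state.omega_resid = invwishart.rvs(
            df=priors.df_resid + d.n_rows, scale=scale, random_state=rng
        )
    return state


def deviance(
    design: DesignMatrices,
    beta: np.ndarray,
    u: np.ndarray,
    vw: np.ndarray,
    omega_resid: np.ndarray,
    work: _Workspace | None = None,
) -> float:
    """-2 log multivariate-normal likelihood of the observed outcome cells.

    Conditional on the random effects; for partially observed triples the
    missing components are marginalized by dropping their dimensions.
    """
    if work is None:
        work = _Workspace(design)
    d = design
    mu = d.X @ beta + u[d.school_idx]
    cv = vw[d.child_idx]
    mu += cv[:, :3]
    if vw.shape[1] == 6:
        mu += cv[:, 3:] * d.time[:, None]

    total = 0.0
    groups = [(np.arange(3), work.full_rows)]
    groups += [(obs, idx) for obs, _, idx in work.patterns]
    for obs, idx in groups:
        if idx.size == 0:
            continue
        sub = omega_resid[np.ix_(obs, obs)]
        L = _chol(sub, "deviance block")
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        r = d.Y[np.ix_(idx, obs)] - mu[np.ix_(idx, obs)]
        sol = sla.solve_triangular(L, r.T, lower=True)
        quad = np.sum(sol**2)
        total += idx.size * (len(obs) * np.log(2 * np.pi) + logdet) + quad
    return float(total)


def _tri_indices(dim: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(dim) for j in range(i, dim)]


@dataclass
class PosteriorSamples:
    """Stored chains with burn-in bookkeeping, deviance, DIC, and ESS."""

    draws: np.ndarray            # (n_chains, n_stored, n_params)
    param_names: list[str]
    deviance: np.ndarray         # (n_chains, n_stored)
    burn_in: int
    seeds: list[int]
    spec: ModelSpec
    n_fixed_terms: int
    terms: tuple[str, ...]
    mean_u: np.ndarray
    mean_vw: np.ndarray
    dic: float = np.nan
    pd_eff: float = np.nan

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_stored(self) -> int:
        return self.draws.shape[1]

    def stacked(self) -> np.ndarray:
        """All chains pooled: (n_chains * n_stored, n_params)."""
        return self.draws.reshape(-1, self.draws.shape[2])

    def get(self, name: str) -> np.ndarray:
        """(n_chains, n_stored) draws of one scalar parameter."""
        return self.draws[:, :, self.param_names.index(name)]

    def beta_draws(self) -> np.ndarray:
        """(total_draws, p, 3) fixed-effect draws."""
        p = self.n_fixed_terms
        flat = self.stacked()[:, : 3 * p]
        return flat.reshape(-1, 3, p).transpose(0, 2, 1)

    def _cov_draws(self, prefix: str, dim: int) -> np.ndarray:
        n = len(self.param_names)
        cols = {name: i for i, name in enumerate(self.param_names)}
        out = np.empty((self.n_chains * self.n_stored, dim, dim))
        flat = self.stacked()
        for i, j in _tri_indices(dim):
            vals = flat[:, cols[f"{prefix}[{i},{j}]"]]
            out[:, i, j] = vals
            out[:, j, i] = vals
        return out

    def omega_school_draws(self) -> np.ndarray:
        return self._cov_draws("omega_school", 3)

    def omega_child_draws(self) -> np.ndarray:
        return self._cov_draws("omega_child", self.spec.n_child_effects)

    def omega_resid_draws(self) -> np.ndarray:
        return self._cov_draws("omega_resid", 3)

    def posterior_mean_state(self) -> dict[str, np.ndarray]:
        flat = self.stacked().mean(axis=0)
        p = self.n_fixed_terms
        beta = flat[: 3 * p].reshape(3, p).T
        return {
            "beta": beta,
            "omega_school": self.omega_school_draws().mean(axis=0),
            "omega_child": self.omega_child_draws().mean(axis=0),
            "omega_resid": self.omega_resid_draws().mean(axis=0),
        }

    def summary(self) -> pd.DataFrame:
        """Posterior mean, SD, central 95% interval and ESS per parameter."""
        flat = self.stacked()
        q = np.percentile(flat, [2.5, 97.5], axis=0)
        ess = np.array(
            [effective_sample_size(self.draws[:, :, j]) for j in range(flat.shape[1])]
        )
        return pd.DataFrame(
            {
                "mean": flat.mean(axis=0),
                "sd": flat.std(axis=0, ddof=1),
                "q2.5": q[0],
                "q97.5": q[1],
                "ess": ess,
            },
            index=self.param_names,
        )


def _param_names(terms: tuple[str, ...], q: int) -> list[str]:
    names = [f"beta[{out},{term}]" for out in OUTCOMES for term in terms]
    for prefix, dim in (("omega_school", 3), ("omega_child", q), ("omega_resid", 3)):
        names += [f"{prefix}[{i},{j}]" for i, j in _tri_indices(dim)]
    return names


def _flatten_state(state: ParameterState, q: int) -> np.ndarray:
    parts = [state.beta.T.ravel()]
    for mat, dim in (
        (state.omega_school, 3),
        (state.omega_child, q),
        (state.omega_resid, 3),
    ):
        parts.append(np.array([mat[i, j] for i, j in _tri_indices(dim)]))
    return np.concatenate(parts)


def run_chains(
    design: DesignMatrices,
    priors: PriorSpec | None = None,
    n_chains: int = 3,
    n_iter: int = 2500,
    burn_in: int = 500,
    seed: int | list[int] = 0,
    prior_scale_factor: float = 1.0,
) -> PosteriorSamples:
    """Run independent Gibbs chains and pool their stored draws.

    ``seed`` may be a single integer (per-chain streams are spawned from it)
    or an explicit list of per-chain seeds. Stored draws exclude burn-in.
    DIC is computed from the stored conditional deviances:
    DIC = mean(D) + pD with pD = mean(D) - D(posterior means).
    """
    if not n_iter > burn_in >= 0:
        raise ValueError("need n_iter > burn_in >= 0")
    work = _Workspace(design)
    init = initialize(design)
    if priors is None:
        priors = PriorSpec.from_state(init, scale_factor=prior_scale_factor)

    if isinstance(seed, (int, np.integer)):
        ss = np.random.SeedSequence(seed)
        chain_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_chains)]
    else:
        chain_seeds = [int(s) for s in seed]
        if len(chain_seeds) != n_chains:
            raise ValueError("need one seed per chain")

    q = design.spec.n_child_effects
    n_stored = n_iter - burn_in
    names = _param_names(design.terms, q)
    draws = np.empty((n_chains, n_stored, len(names)))
    dev = np.empty((n_chains, n_stored))
    sum_u = np.zeros((design.n_schools, 3))
    sum_vw = np.zeros((design.n_children, q))

    for c, s in enumerate(chain_seeds):
        rng = np.random.default_rng(s)
        state = ParameterState(
            beta=init.beta.copy(),
            u=init.u.copy(),
            vw=init.vw.copy(),
            omega_school=init.omega_school.copy(),
            omega_child=init.omega_child.copy(),
            omega_resid=init.omega_resid.copy(),
            y=init.y.copy(),
        )
        for it in range(n_iter):
            gibbs_step(state, design, priors, rng, work=work)
            if it >= burn_in:
                k = it - burn_in
                draws[c, k] = _flatten_state(state, q)
                dev[c, k] = deviance(
                    design, state.beta, state.u, state.vw, state.omega_resid, work
                )
                sum_u += state.u
                sum_vw += state.vw

    n_total = n_chains * n_stored
    samples = PosteriorSamples(
        draws=draws,
        param_names=names,
        deviance=dev,
        burn_in=burn_in,
        seeds=chain_seeds,
        spec=design.spec,
        n_fixed_terms=design.X.shape[1],
        terms=design.terms,
        mean_u=sum_u / n_total,
        mean_vw=sum_vw / n_total,
    )
    samples.dic = compute_dic(samples, design)
    mean_dev = float(dev.mean())
    samples.pd_eff = mean_dev - _deviance_at_means(samples, design, work)
    return samples


def _deviance_at_means(
    samples: PosteriorSamples, design: DesignMatrices, work: _Workspace | None = None
) -> float:
    means = samples.posterior_mean_state()
    return deviance(
        design,
        means["beta"],
        samples.mean_u,
        samples.mean_vw,
        means["omega_resid"],
        work,
    )


def compute_dic(samples: PosteriorSamples, design: DesignMatrices) -> float:
    """Deviance information criterion: mean deviance plus pD.

    pD = mean deviance - deviance at the posterior means of all parameters
    (fixed effects, residual covariance, and random effects), using the
    conditional multivariate-normal likelihood of the observed cells.
    """
    mean_dev = float(samples.deviance.mean())
    d_hat = _deviance_at_means(samples, design)
    return mean_dev + (mean_dev - d_hat)


def effective_sample_size(draws: np.ndarray) -> float:
    """ESS of an MCMC scalar via Geyer's initial-positive-sequence estimator.

    ``draws`` is (n,) for one chain or (n_chains, n); per-chain estimates are
    summed. A constant chain has ESS 0 (with a warning).
    """
    arr = np.atleast_2d(np.asarray(draws, float))
    total = 0.0
    for chain in arr:
        n = chain.size
        var = chain.var()
        if var == 0 or n < 4:
            warnings.warn("degenerate chain: ESS set to 0", stacklevel=2)
            continue
        centered = chain - chain.mean()
        nfft = int(2 ** np.ceil(np.log2(2 * n)))
        f = np.fft.rfft(centered, nfft)
        acov = np.fft.irfft(f * np.conjugate(f), nfft)[:n].real / n
        rho = acov / acov[0]
        # Geyer: sum consecutive pairs until the pair sum goes negative
        tau = -rho[0]  # = -1
        k = 0
        while 2 * k + 1 < n:
            pair = rho[2 * k] + rho[2 * k + 1]
            if pair < 0:
                break
            tau += 2 * pair
            k += 1
        tau = max(tau, 1.0 / n)
        total += n / tau
    return float(total)


def save_samples(samples: PosteriorSamples, csv_path, meta_path) -> None:
    """Persist stored draws as CSV plus a JSON summary/metadata file."""
    import json

    rows = []
    for c in range(samples.n_chains):
        block = pd.DataFrame(samples.draws[c], columns=samples.param_names)
        block.insert(0, "chain", c)
        block.insert(1, "iteration", np.arange(samples.n_stored) + samples.burn_in)
        block["deviance"] = samples.deviance[c]
        rows.append(block)
    pd.concat(rows, ignore_index=True).to_csv(csv_path, index=False)

    summ = samples.summary()
    meta = {
        "burn_in": samples.burn_in,
        "seeds": samples.seeds,
        "dic": samples.dic,
        "pd": samples.pd_eff,
        "terms": list(samples.terms),
        "n_fixed_terms": samples.n_fixed_terms,
        "spec": {
            "fixed_terms": list(samples.spec.fixed_terms),
            "poly_degree": samples.spec.poly_degree,
            "child_random": samples.spec.child_random,
            "school_random": samples.spec.school_random,
        },
        "mean_u": samples.mean_u.tolist(),
        "mean_vw": samples.mean_vw.tolist(),
        "summary": {
            name: {k: float(v) for k, v in row.items()}
            for name, row in summ.iterrows()
        },
    }
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=1)


def load_samples(csv_path, meta_path) -> PosteriorSamples:
    """Reload samples written by :func:`save_samples`."""
    import json

    with open(meta_path) as fh:
        meta = json.load(fh)
    table = pd.read_csv(csv_path)
    param_names = [c for c in table.columns if c not in ("chain", "iteration", "deviance")]
    chains = sorted(table["chain"].unique())
    draws = np.stack(
        [table.loc[table["chain"] == c, param_names].to_numpy() for c in chains]
    )
    dev = np.stack(
        [table.loc[table["chain"] == c, "deviance"].to_numpy() for c in chains]
    )
    spec = ModelSpec(
        fixed_terms=tuple(meta["spec"]["fixed_terms"]),
        poly_degree=meta["spec"]["poly_degree"],
        child_random=meta["spec"]["child_random"],
        school_random=meta["spec"]["school_random"],
    )
    return PosteriorSamples(
        draws=draws,
        param_names=param_names,
        deviance=dev,
        burn_in=meta["burn_in"],
        seeds=meta["seeds"],
        spec=spec,
        n_fixed_terms=meta["n_fixed_terms"],
        terms=tuple(meta["terms"]),
        mean_u=np.asarray(meta["mean_u"]),
        mean_vw=np.asarray(meta["mean_vw"]),
        dic=meta["dic"],
        pd_eff=meta["pd"],
    )


def fit_model(
    frame: pd.DataFrame,
    spec: ModelSpec,
    priors: PriorSpec | None = None,
    n_chains: int = 3,
    n_iter: int = 2500,
    burn_in: int = 500,
    seed: int | list[int] = 0,
) -> PosteriorSamples:
    """Convenience wrapper: build the design from a trial frame and sample."""
    design = build_design(frame, spec)
    return run_chains(
        design, priors=priors, n_chains=n_chains, n_iter=n_iter, burn_in=burn_in, seed=seed
    )
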