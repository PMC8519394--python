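"""Synthetic cluster-randomized longitudinal trial generator.

Emulates the structure of a two-arm school-based prevention trial: schools
are allocated to arms by covariate-adaptive minimization, children are nested
in schools, and three correlated standardized outcomes are observed on annual
occasions. Outcomes follow a three-level random-slopes growth model — school
intercepts, child intercepts (and optionally child linear-time slopes), and
occasion-level residual triples — with wave-dependent missing-at-random
attrition applied afterwards.

Everything is deterministic given the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import params as P
from .data import SCHEMA, Y_COLUMNS, fixed_design_columns, validate_frame


def _check_psd(mat: np.ndarray, name: str) -> None:
    m = np.asarray(mat, float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    eigmin = np.linalg.eigvalsh(m).min()
    if eigmin < -1e-10:
        raise ValueError(f"{name} is not positive semi-definite (min eig {eigmin:.3g})")


@dataclass(frozen=True)
class TrueParameters:
    """Generating truth of the simulated trial.

    ``beta`` has one row per fixed-effect term (in ``terms`` order) and one
    column per outcome. ``omega_child`` is 3x3 for intercept-only child
    effects or 6x6 for intercepts plus linear-time slopes (first three rows =
    intercepts, last three = slopes, outcome order preserved).
    """

    beta: np.ndarray
    omega_school: np.ndarray
    omega_child: np.ndarray
    omega_resid: np.ndarray
    terms: tuple[str, ...] = P.FULL_MODEL_TERMS
    covariate_prevalences: dict = field(
        default_factory=lambda: dict(P.REFERENCE_PREVALENCES)
    )
    school_covariate_moments: dict = field(
        default_factory=lambda: {
            "log_size_mean": 5.45,
            "log_size_sd": 0.45,
            "logit_fsm_mean": logit(0.25),
            "logit_fsm_sd": 0.7,
        }
    )

    def __post_init__(self) -> None:
        beta = np.asarray(self.beta, float)
        if beta.shape != (len(self.terms), 3):
            raise ValueError(
                f"beta must be {len(self.terms)} terms x 3 outcomes, got {beta.shape}"
            )
        _check_psd(self.omega_school, "omega_school")
        _check_psd(self.omega_resid, "omega_resid")
        _check_psd(self.omega_child, "omega_child")
        if self.omega_child.shape[0] not in (3, 6):
            raise ValueError("omega_child must be 3x3 or 6x6")
        for name, p in self.covariate_prevalences.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence {name} outside [0, 1]")

    @classmethod
    def reference(cls, slope_var: float = P.REFERENCE_SLOPE_VAR) -> "TrueParameters":
        """Full-model truth at the published trial-scale estimates."""
        return cls(
            beta=P.REFERENCE_BETA.copy(),
            omega_school=P.REFERENCE_OMEGA_SCHOOL.copy(),
            omega_child=P.reference_omega_child_full(slope_var),
            omega_resid=P.REFERENCE_OMEGA_RESID.copy(),
        )

    @classmethod
    def unconditional_reference(cls) -> "TrueParameters":
        """Intercepts-only truth at the published variance-decomposition scale."""
        return cls(
            beta=np.zeros((1, 3)),
            omega_school=P.REFERENCE_OMEGA_SCHOOL.copy(),
            omega_child=P.REFERENCE_OMEGA_CHILD.copy(),
            omega_resid=P.REFERENCE_OMEGA_RESID.copy(),
            terms=("intercept",),
        )


@dataclass(frozen=True)
class MissingnessSpec:
    """Wave-dependent MAR missingness for outcome triples.

    Each child-occasion's outcome triple goes missing with probability
    ``logit^-1(logit(wave rate) + sum(covariate_log_odds * covariate))``;
    a wave rate of exactly 0 or 1 is kept as such regardless of covariates.
    ``school_dropout_prob`` is the per-school, per-wave chance of whole-school
    dropout from a sampled wave onward. With ``cell_level=True`` the
    missingness coin is tossed per outcome cell instead of per triple,
    producing partially observed triples for the imputation path.
    """

    wave_base_rates: tuple[float, ...] = P.REFERENCE_WAVE_MISSING_RATES
    covariate_log_odds: dict = field(default_factory=dict)
    school_dropout_prob: float = 0.0
    cell_level: bool = False

    def __post_init__(self) -> None:
        for r in self.wave_base_rates:
            if not 0.0 <= r <= 1.0:
                raise ValueError("wave base rates must lie in [0, 1]")
        if not 0.0 <= self.school_dropout_prob <= 1.0:
            raise ValueError("school_dropout_prob must lie in [0, 1]")

    @classmethod
    def none(cls) -> "MissingnessSpec":
        return cls(wave_base_rates=(0.0,) * 5)


@dataclass(frozen=True)
class SimulationConfig:
    """Complete recipe for one synthetic trial; the seed fixes everything."""

    n_schools: int = P.REFERENCE_N_SCHOOLS
    children_per_school: tuple[int, int] = (20, 60)
    n_occasions: int = P.REFERENCE_N_OCCASIONS
    true_params: TrueParameters = field(default_factory=TrueParameters.reference)
    missingness: MissingnessSpec = field(default_factory=MissingnessSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_schools < 2:
            raise ValueError("need at least 2 schools")
        if self.n_occasions < 2:
            raise ValueError("need at least 2 occasions")
        lo, hi = self.children_per_school
        if not (0 < lo <= hi):
            raise ValueError("children_per_school must satisfy 0 < min <= max")


def simulate_school_table(
    n_schools: int, moments: dict, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw school size (log-normal) and %FSM (logit-normal), with z-scores."""
    size = np.exp(rng.normal(moments["log_size_mean"], moments["log_size_sd"], n_schools))
    size = np.maximum(np.round(size).astype(int), 10)
    pct_fsm = 100.0 * expit(rng.normal(moments["logit_fsm_mean"], moments["logit_fsm_sd"], n_schools))
    tbl = pd.DataFrame(
        {"school_id": np.arange(1, n_schools + 1), "size": size, "pct_fsm": pct_fsm}
    )
    for col, zcol in (("size", "school_size_z"), ("pct_fsm", "school_fsm_z")):
        sd = tbl[col].std(ddof=1)
        tbl[zcol] = (tbl[col] - tbl[col].mean()) / (sd if sd > 0 else 1.0)
    return tbl


def allocate_minimization(school_table: pd.DataFrame, seed: int) -> np.ndarray:
    """Allocate schools to arms by Pocock-Simon minimization.

    Balances the two arms on school size and %FSM, each dichotomized at the
    running median of the schools processed so far, plus the overall arm
    totals. Schools are processed in a seeded random order; each is assigned
    to the arm that minimizes the summed marginal imbalance, with seeded
    fair-coin tie-breaking. Returns the arm (0/1) per row of ``school_table``
    in its original order.
    """
    if len(school_table) < 2:
        raise ValueError("minimization needs at least 2 schools")
    for col in ("size", "pct_fsm"):
        if col not in school_table.columns or school_table[col].isna().any():
            raise ValueError(f"school factor {col!r} missing")

    rng = np.random.default_rng(seed)
    n = len(school_table)
    order = rng.permutation(n)
    factors = school_table[["size", "pct_fsm"]].to_numpy(float)
    arms = np.full(n, -1, dtype=int)
    seen: list[int] = []
    # counts[factor, level, arm]
    counts = np.zeros((2, 2, 2), dtype=int)

    for idx in order:
        seen.append(idx)
        values = factors[np.array(seen)]
        medians = np.median(values, axis=0)
        levels = (factors[idx] > medians).astype(int)
        if not np.any(arms >= 0):
            arm = int(rng.integers(2))
        else:
            # recompute marginal counts at current dichotomization
            assigned = np.array([i for i in seen[:-1]])
            counts[:] = 0
            lv = (factors[assigned] > medians).astype(int)
            for f in range(2):
                for a in (0, 1):
                    sel = arms[assigned] == a
                    counts[f, 0, a] = np.sum((lv[sel, f] == 0))
                    counts[f, 1, a] = np.sum((lv[sel, f] == 1))
            arm_totals = np.array(
                [np.sum(arms[assigned] == 0), np.sum(arms[assigned] == 1)]
            )
            imbalance = np.zeros(2)
            for cand in (0, 1):
                tot = 0
                for f in range(2):
                    c = counts[f, levels[f]].copy()
                    c[cand] += 1
                    tot += abs(c[0] - c[1])
                t = arm_totals.copy()
                t[cand] += 1
                tot += abs(t[0] - t[1])
                imbalance[cand] = tot
            if imbalance[0] < imbalance[1]:
                arm = 0
            elif imbalance[1] < imbalance[0]:
                arm = 1
            else:
                arm = int(rng.integers(2))
        arms[idx] = arm
    return arms


def simulate_children(config: SimulationConfig) -> pd.DataFrame:
    """Draw the child roster: school membership and baseline covariates.

    Covariates (male, FSM eligibility, conduct-problems at-risk flag) are
    independent Bernoulli draws at the configured prevalences.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    lo, hi = config.children_per_school
    sizes = rng.integers(lo, hi + 1, size=config.n_schools)
    school = np.repeat(np.arange(1, config.n_schools + 1), sizes)
    n = len(school)
    prev = config.true_params.covariate_prevalences
    roster = pd.DataFrame(
        {
            "child_id": np.arange(1, n + 1),
            "school_id": school,
            "male": (rng.random(n) < prev["male"]).astype(int),
            "fsm": (rng.random(n) < prev["fsm"]).astype(int),
            "at_risk": (rng.random(n) < prev["at_risk"]).astype(int),
        }
    )
    return roster


def simulate_outcomes(
    roster: pd.DataFrame,
    school_table: pd.DataFrame,
    arms: np.ndarray,
    true_params: TrueParameters,
    seed: int,
    n_occasions: int = 5,
) -> pd.DataFrame:
    """Generate the complete (no-missingness) long-format trial frame.

    Per child-occasion, the 3-vector of outcomes is

        y = B'x + u_school + v_child + w_child * t + e

    with u ~ N3(0, omega_school), (v, w) ~ N6(0, omega_child) (or v ~ N3 when
    the child part is intercept-only, w = 0), and e ~ N3(0, omega_resid)
    independent across occasions.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    tp = true_params
    schools = school_table.copy()
    schools["arm"] = np.asarray(arms, int)
    long = roster.merge(
        schools[["school_id", "arm", "school_size_z", "school_fsm_z"]],
        on="school_id",
        how="left",
    )
    if long["arm"].isna().any():
        raise ValueError("every child's school needs an arm assignment")
    long = long.loc[long.index.repeat(n_occasions)].reset_index(drop=True)
    long["occasion"] = np.tile(np.arange(1, n_occasions + 1), len(roster))

    X = fixed_design_columns(long, tp.terms)
    mu = X @ tp.beta  # (n, 3)

    n_schools = len(schools)
    n_children = len(roster)
    u = rng.multivariate_normal(np.zeros(3), tp.omega_school, size=n_schools,
                                method="eigh")
    q = tp.omega_child.shape[0]
    vw = rng.multivariate_normal(np.zeros(q), tp.omega_child, size=n_children,
                                 method="eigh")
    e = rng.multivariate_normal(np.zeros(3), tp.omega_resid, size=len(long),
                                method="eigh")

    school_pos = pd.Series(np.arange(n_schools), index=schools["school_id"])
    child_pos = pd.Series(np.arange(n_children), index=roster["child_id"])
    su = u[school_pos.loc[long["school_id"]].to_numpy()]
    cv = vw[child_pos.loc[long["child_id"]].to_numpy()]
    t = long["occasion"].to_numpy(float)[:, None] - 1.0
    y = mu + su + cv[:, :3] + e
    if q == 6:
        y = y + cv[:, 3:] * t

    for k, col in enumerate(Y_COLUMNS):
        long[col] = y[:, k]
    frame = long[list(SCHEMA)]
    validate_frame(frame)
    return frame


def apply_missingness(
    frame: pd.DataFrame, spec: MissingnessSpec, seed: int
) -> pd.DataFrame:
    """Mask outcome cells according to the MAR missingness specification."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    out = frame.copy()
    occ = out["occasion"].to_numpy(int)
    rates = np.asarray(spec.wave_base_rates, float)
    if rates.size < occ.max():
        rates = np.resize(rates, occ.max())
    base = rates[occ - 1]

    eta = np.where((base > 0) & (base < 1), logit(np.clip(base, 1e-12, 1 - 1e-12)), 0.0)
    shift = np.zeros(len(out))
    for cov, lo in spec.covariate_log_odds.items():
        shift += lo * out[cov].to_numpy(float)
    p = np.where((base > 0) & (base < 1), expit(eta + shift), base)

    if spec.cell_level:
        mask = rng.random((len(out), 3)) < p[:, None]
    else:
        mask = np.repeat((rng.random(len(out)) < p)[:, None], 3, axis=1)

    if spec.school_dropout_prob > 0:
        n_waves = occ.max()
        for sid in out["school_id"].unique():
            # a school can trigger dropout at any wave after baseline
            trig = rng.random(n_waves - 1) < spec.school_dropout_prob
            if trig.any():
                start = 2 + int(np.argmax(trig))
                mask[(out["school_id"] == sid).to_numpy() & (occ >= start)] = True

    y = out[list(Y_COLUMNS)].to_numpy(float)
    y[mask] = np.nan
    out[list(Y_COLUMNS)] = y
    return out


def simulate_trial(config: SimulationConfig) -> tuple[pd.DataFrame, dict]:
    """Run the full generator: schools, minimization, roster, outcomes, MAR.

    Returns the trial frame and a ground-truth dictionary (school table,
    arms, and the generating parameters) for recovery checks.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    schools = simulate_school_table(
        config.n_schools, config.true_params.school_covariate_moments, rng
    )
    arms = allocate_minimization(schools, seed=config.seed + 10007)
    roster = simulate_children(config)
    frame = simulate_outcomes(
        roster, schools, arms, config.true_params, config.seed, config.n_occasions
    )
    frame = apply_missingness(frame, config.missingness, config.seed)
    truth = {
        "school_table": schools.assign(arm=arms),
        "true_params": config.true_params,
        "config": config,
    }
    return frame, truth
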