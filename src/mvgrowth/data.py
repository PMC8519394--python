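"""Long-format trial data: schema, I/O, standardization, design matrices.

The single exchange format of the pipeline is the *trial frame*: a pandas
DataFrame with one row per child x occasion and columns

    school_id, child_id, arm, occasion, male, fsm, at_risk,
    school_size_z, school_fsm_z, y_concentration, y_disruptive, y_prosocial

Outcome cells may be missing (NaN); covariates never are. ``arm`` is the
school-level trial-arm indicator (0 = control, 1 = GBG intervention),
``occasion`` is the wave index 1..T, and the two ``school_*_z`` columns are
standardized school-level covariates (size and %FSM).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .params import FULL_MODEL_TERMS, OUTCOMES, Y_COLUMNS

ID_COLUMNS = ("school_id", "child_id", "arm", "occasion")
COVARIATE_COLUMNS = ("male", "fsm", "at_risk", "school_size_z", "school_fsm_z")
SCHEMA = ID_COLUMNS + COVARIATE_COLUMNS + Y_COLUMNS

# Factorization of every fixed-effect term into elementary covariates. ``t`` is
# occasion - 1 so the intercept is the baseline mean.
TERM_FACTORS: dict[str, tuple[str, ...]] = {
    "intercept": (),
    "t": ("t",),
    "t2": ("t", "t"),
    "t3": ("t", "t", "t"),
    "gbg": ("gbg",),
    "t_gbg": ("t", "gbg"),
    "t2_gbg": ("t", "t", "gbg"),
    "t3_gbg": ("t", "t", "t", "gbg"),
    "at_risk": ("at_risk",),
    "fsm": ("fsm",),
    "school_size_z": ("school_size_z",),
    "school_fsm_z": ("school_fsm_z",),
    "gbg_fsm": ("gbg", "fsm"),
    "gbg_at_risk": ("gbg", "at_risk"),
    "male": ("male",),
    "gbg_male": ("gbg", "male"),
    "male_at_risk": ("male", "at_risk"),
    "gbg_male_at_risk": ("gbg", "male", "at_risk"),
    "gbg_school_size_z": ("gbg", "school_size_z"),
    "gbg_school_fsm_z": ("gbg", "school_fsm_z"),
}

_BASE_COLUMNS = {
    "t": lambda df: df["occasion"].to_numpy(float) - 1.0,
    "gbg": lambda df: df["arm"].to_numpy(float),
    "at_risk": lambda df: df["at_risk"].to_numpy(float),
    "fsm": lambda df: df["fsm"].to_numpy(float),
    "male": lambda df: df["male"].to_numpy(float),
    "school_size_z": lambda df: df["school_size_z"].to_numpy(float),
    "school_fsm_z": lambda df: df["school_fsm_z"].to_numpy(float),
}


class SchemaError(ValueError):
    """The trial frame violates its schema or invariants."""


def validate_frame(frame: pd.DataFrame) -> None:
    """Check schema columns and structural invariants; raise SchemaError."""
    missing = [c for c in SCHEMA if c not in frame.columns]
    if missing:
        raise SchemaError(f"trial frame is missing columns: {missing}")
    if frame.duplicated(subset=["child_id", "occasion"]).any():
        raise SchemaError("duplicate (child_id, occasion) rows")
    per_child_schools = frame.groupby("child_id")["school_id"].nunique()
    if (per_child_schools > 1).any():
        bad = per_child_schools[per_child_schools > 1].index[:3].tolist()
        raise SchemaError(f"children mapped to more than one school: {bad}")
    per_school_arms = frame.groupby("school_id")["arm"].nunique()
    if (per_school_arms > 1).any():
        raise SchemaError("arm varies within school")
    for col in ("male", "fsm", "at_risk"):
        if (frame.groupby("child_id")[col].nunique() > 1).any():
            raise SchemaError(f"covariate {col!r} varies within child")
    if not frame["arm"].isin([0, 1]).all():
        raise SchemaError("arm must be 0 or 1")
    if (frame["occasion"] < 1).any():
        raise SchemaError("occasion indices must start at 1")


def write_long_csv(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a trial frame as long-format CSV (empty cell = missing)."""
    validate_frame(frame)
    frame.to_csv(path, index=False, columns=list(SCHEMA))


def read_long_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format trial-frame CSV."""
    frame = pd.read_csv(path)
    validate_frame(frame)
    for col in ("arm", "occasion", "male", "fsm", "at_risk"):
        frame[col] = frame[col].astype(int)
    for col in Y_COLUMNS:
        frame[col] = frame[col].astype(float)
    return frame


@dataclass(frozen=True)
class StandardizationParams:
    """Pooled mean and SD per outcome, in canonical outcome order."""

    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.sd) <= 0):
            raise ValueError("standardization SDs must be positive")


def standardize_outcomes(
    frame: pd.DataFrame, params: StandardizationParams | None = None
) -> tuple[pd.DataFrame, StandardizationParams]:
    """Z-score the three outcomes against pooled (all-occasion) moments.

    Pooling all occasions into one mean/SD per outcome preserves growth over
    time; missing cells are preserved. When ``params`` is supplied it is
    applied as-is (e.g. to score new data on the training scale).
    """
    out = frame.copy()
    if params is None:
        means, sds = [], []
        for col in Y_COLUMNS:
            observed = frame[col].dropna()
            if len(observed) < 2:
                raise ValueError(f"{col}: need >=2 observed values to standardize")
            sd = observed.std(ddof=1)
            if sd == 0:
                raise ValueError(f"{col}: zero variance, cannot standardize")
            means.append(observed.mean())
            sds.append(sd)
        params = StandardizationParams(np.array(means), np.array(sds))
    for k, col in enumerate(Y_COLUMNS):
        out[col] = (out[col] - params.mean[k]) / params.sd[k]
    return out, params


def unstandardize_outcomes(
    frame: pd.DataFrame, params: StandardizationParams
) -> pd.DataFrame:
    """Invert :func:`standardize_outcomes` on the outcome columns."""
    out = frame.copy()
    for k, col in enumerate(Y_COLUMNS):
        out[col] = out[col] * params.sd[k] + params.mean[k]
    return out


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of the growth-curve model to fit.

    ``fixed_terms`` name the columns of the shared fixed-part design matrix
    (identical across the three outcomes); ``poly_degree`` is the degree of
    the time polynomial implied by those terms (0 for the unconditional
    means model, 3 for the full model); the random part is an intercept per
    outcome at school level and either intercepts only (3x3 child covariance)
    or intercepts plus linear-time slopes (6x6) at child level.
    """

    fixed_terms: tuple[str, ...]
    poly_degree: int = 0
    child_random: str = "intercept_only"
    school_random: str = "intercept_only"

    def __post_init__(self) -> None:
        if self.poly_degree not in (0, 1, 2, 3):
            raise ValueError("poly_degree must be in 0..3")
        if self.child_random not in ("intercept_only", "intercept_plus_time"):
            raise ValueError(f"unknown child_random: {self.child_random}")
        if self.school_random != "intercept_only":
            raise ValueError("school random part must be intercept_only")
        if self.poly_degree == 0 and self.child_random != "intercept_only":
            raise ValueError(
                "unconditional (degree-0) spec requires intercept-only child part"
            )
        unknown = [t for t in self.fixed_terms if t not in TERM_FACTORS]
        if unknown:
            raise ValueError(f"unknown fixed-effect terms: {unknown}")

    @property
    def n_child_effects(self) -> int:
        return 6 if self.child_random == "intercept_plus_time" else 3

    @classmethod
    def unconditional(cls) -> "ModelSpec":
        """Intercepts-only model used to decompose variance across levels."""
        return cls(fixed_terms=("intercept",), poly_degree=0)

    @classmethod
    def full(cls) -> "ModelSpec":
        """Cubic-time growth model with arm, child and school covariates."""
        return cls(
            fixed_terms=FULL_MODEL_TERMS,
            poly_degree=3,
            child_random="intercept_plus_time",
        )


def fixed_design_columns(frame: pd.DataFrame, terms: tuple[str, ...]) -> np.ndarray:
    """Evaluate the named fixed-effect terms on a trial frame (rows x terms)."""
    n = len(frame)
    cols = np.empty((n, len(terms)))
    for j, term in enumerate(terms):
        factors = TERM_FACTORS.get(term)
        if factors is None:
            raise ValueError(f"unknown fixed-effect term: {term!r}")
        col = np.ones(n)
        for f in factors:
            col = col * _BASE_COLUMNS[f](frame)
        cols[:, j] = col
    return cols


@dataclass
class DesignMatrices:
    """Model inputs in array form, restricted to informative rows.

    Rows are child-occasions with at least one observed outcome, sorted by
    (school, child, occasion) so per-group reductions are contiguous.
    """

    X: np.ndarray                 # (n, p) shared fixed-part design
    terms: tuple[str, ...]
    Y: np.ndarray                 # (n, 3), NaN where missing
    obs_mask: np.ndarray          # (n, 3) bool
    time: np.ndarray              # (n,) occasion - 1
    child_idx: np.ndarray         # (n,) codes 0..C-1
    school_idx: np.ndarray        # (n,) codes 0..S-1
    child_school: np.ndarray      # (C,) school code of each child
    child_ids: np.ndarray
    school_ids: np.ndarray
    spec: ModelSpec
    frame_index: np.ndarray = field(repr=False, default=None)

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    @property
    def n_children(self) -> int:
        return len(self.child_ids)

    @property
    def n_schools(self) -> int:
        return len(self.school_ids)


def build_design(frame: pd.DataFrame, spec: ModelSpec) -> DesignMatrices:
    """Build design matrices for ``spec`` from a validated trial frame.

    Child-occasions with all three outcomes missing carry no information and
    are dropped from the likelihood; partially observed triples are kept and
    flagged in the observation mask.
    """
    validate_frame(frame)
    y = frame[list(Y_COLUMNS)].to_numpy(float)
    keep = ~np.all(np.isnan(y), axis=1)
    sub = frame.loc[keep].sort_values(["school_id", "child_id", "occasion"])
    sub = sub.reset_index(drop=False)

    X = fixed_design_columns(sub, spec.fixed_terms)
    child_codes, child_ids = pd.factorize(sub["child_id"], sort=True)
    school_codes, school_ids = pd.factorize(sub["school_id"], sort=True)
    # re-sort rows so each child's rows are contiguous in factorized order
    order = np.lexsort((sub["occasion"].to_numpy(), child_codes))
    sub = sub.iloc[order].reset_index(drop=True)
    X = X[order]
    child_codes = child_codes[order]
    school_codes = school_codes[order]

    yv = sub[list(Y_COLUMNS)].to_numpy(float)
    child_school = np.empty(len(child_ids), dtype=int)
    child_school[child_codes] = school_codes
    return DesignMatrices(
        X=X,
        terms=tuple(spec.fixed_terms),
        Y=yv,
        obs_mask=~np.isnan(yv),
        time=sub["occasion"].to_numpy(float) - 1.0,
        child_idx=child_codes,
        school_idx=school_codes,
        child_school=child_school,
        child_ids=np.asarray(child_ids),
        school_ids=np.asarray(school_ids),
        spec=spec,
        frame_index=sub["index"].to_numpy(),
    )


def missingness_audit(
    frame: pd.DataFrame, covariates: list[str] | tuple[str, ...] = COVARIATE_COLUMNS
) -> pd.DataFrame:
    """Logistic audit of outcome missingness against baseline covariates.

    Regresses the indicator "any outcome missing at this child-occasion" on
    the named covariates plus wave dummies, by maximum likelihood with
    standard errors clustered on school. Under MAR-compatible data collection
    the covariate coefficients should be indistinguishable from the
    generating dependence (zero in the null case).

    Returns one row per covariate with columns
    ``coef, se, ci_low, ci_high``; an empty table if no cell is missing.
    """
    import statsmodels.api as sm

    validate_frame(frame)
    if frame["occasion"].nunique() < 2:
        raise ValueError("missingness audit needs at least two waves")
    miss = frame[list(Y_COLUMNS)].isna().any(axis=1).astype(float)
    if miss.sum() == 0:
        return pd.DataFrame(columns=["coef", "se", "ci_low", "ci_high"])

    X = frame[list(covariates)].astype(float).copy()
    waves = pd.get_dummies(frame["occasion"], prefix="wave", drop_first=True)
    X = pd.concat([X, waves.astype(float)], axis=1)
    X = sm.add_constant(X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(miss.to_numpy(), X.to_numpy(), family=sm.families.Binomial())
        res = model.fit(
            cov_type="cluster", cov_kwds={"groups": frame["school_id"].to_numpy()}
        )
    names = list(X.columns)
    ci = res.conf_int()
    table = pd.DataFrame(
        {
            "coef": res.params,
            "se": res.bse,
            "ci_low": ci[:, 0],
            "ci_high": ci[:, 1],
        },
        index=names,
    )
    return table.loc[list(covariates)]
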