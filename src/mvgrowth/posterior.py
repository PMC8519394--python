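"""From posterior samples to reported quantities.

Variance partition coefficients (VPC) across the three levels of nesting,
level-specific cross-outcome correlations, predicted arm trajectories at
reference covariates, and informative-hypothesis Bayes factors with
encompassing priors.

The informative-hypothesis machinery evaluates, per outcome and occasion, the
directional hypothesis H1 that the intervention arm does better than control
against its complement H2. Under an encompassing prior that puts mass 1/2 on
each direction, BF1 = Pr(H1 | data) / (1/2) = 2p where p is the posterior
proportion of draws satisfying H1, BF2 = 2(1 - p), and the posterior model
probabilities are PMP1 = p, PMP2 = 1 - p.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .model import PosteriorSamples
from .params import OUTCOMES

#: Direction of the "intervention does better" hypothesis per outcome, as the
#: sign of (control - intervention): problems should shrink (difference > 0),
#: prosocial behaviour should grow (difference < 0).
DEFAULT_DIRECTIONS = {
    "concentration": "greater",
    "disruptive": "greater",
    "prosocial": "less",
}


def variance_partition(
    omega_school: np.ndarray,
    omega_child: np.ndarray,
    omega_resid: np.ndarray,
) -> pd.DataFrame:
    """Percentage of total variance at each level, per outcome.

    For a 6x6 child-level matrix (intercepts + slopes) only the intercept
    block enters, which keeps the partition time-invariant and comparable to
    the unconditional means model; slope variance would otherwise make the
    decomposition a function of time.
    """
    child = np.asarray(omega_child, float)[:3, :3]
    school = np.asarray(omega_school, float)
    resid = np.asarray(omega_resid, float)
    rows = []
    for k, out in enumerate(OUTCOMES):
        parts = np.array([resid[k, k], child[k, k], school[k, k]])
        total = parts.sum()
        if total <= 0:
            raise ValueError(f"zero total variance for outcome {out}")
        pct = 100.0 * parts / total
        rows.append(
            {
                "outcome": out,
                "pct_within": pct[0],
                "pct_between_children": pct[1],
                "pct_between_schools": pct[2],
            }
        )
    return pd.DataFrame(rows).set_index("outcome")


def cov_to_corr(cov: np.ndarray) -> np.ndarray:
    """Convert a covariance matrix to a correlation matrix."""
    cov = np.asarray(cov, float)
    d = np.diag(cov)
    if np.any(d <= 0):
        raise ValueError("covariance matrix has non-positive diagonal entries")
    s = np.sqrt(d)
    corr = cov / np.outer(s, s)
    np.fill_diagonal(corr, 1.0)
    return corr


def predicted_trajectory(
    beta_draws: np.ndarray,
    terms: tuple[str, ...],
    arm: int,
    occasions: np.ndarray | range = range(1, 6),
) -> tuple[pd.DataFrame, np.ndarray]:
    """Predicted outcome means over occasions for one arm, per draw.

    Reference covariates: female, non-FSM, not at-risk, school covariates at
    their standardized mean of 0 — so at occasion 1 (t = 0) the control
    prediction equals the intercept draw. ``beta_draws`` is
    (n_draws, n_terms, 3).

    Returns the posterior-mean table (occasion x outcome) and the per-draw
    trajectories of shape (n_draws, n_occasions, 3).
    """
    beta_draws = np.asarray(beta_draws, float)
    if beta_draws.ndim == 2:
        beta_draws = beta_draws[None, :, :]
    required = ["intercept"]
    if arm == 1:
        required.append("gbg")
    missing = [t for t in required if t not in terms]
    if missing:
        raise ValueError(f"beta draws lack required terms: {missing}")

    occasions = np.asarray(list(occasions))
    t = occasions.astype(float) - 1.0
    poly = {"intercept": t**0, "t": t, "t2": t**2, "t3": t**3}
    arm_poly = {"gbg": t**0, "t_gbg": t, "t2_gbg": t**2, "t3_gbg": t**3}
    weights = np.zeros((len(terms), len(t)))
    for j, name in enumerate(terms):
        if name in poly:
            weights[j] = poly[name]
        elif name in arm_poly and arm == 1:
            weights[j] = arm_poly[name]
    # (n_draws, n_terms, 3) x (n_terms, n_occ) -> (n_draws, n_occ, 3)
    traj = np.einsum("dpk,pt->dtk", beta_draws, weights)
    table = pd.DataFrame(
        traj.mean(axis=0), index=pd.Index(occasions, name="occasion"), columns=list(OUTCOMES)
    )
    return table, traj


def bf_from_proportion(p: float, n_draws: int | None = None) -> dict:
    """Encompassing-prior Bayes factors and PMPs from a posterior proportion.

    ``p`` is the posterior probability of the directional hypothesis H1.
    When ``n_draws`` is given, p is clamped to [1/(2N), 1 - 1/(2N)] before
    forming the BF1/BF2 ratio so a degenerate sample cannot produce an
    infinite ratio; the clamping is reported in the output.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("proportion must lie in [0, 1]")
    bf1 = 2.0 * p
    bf2 = 2.0 * (1.0 - p)
    clamped = False
    p_ratio = p
    if n_draws is not None:
        lo = 1.0 / (2.0 * n_draws)
        p_clamped = min(max(p, lo), 1.0 - lo)
        clamped = p_clamped != p
        p_ratio = p_clamped
    if p_ratio in (0.0, 1.0):
        raise ValueError("degenerate proportion; supply n_draws to cap the ratio")
    bf12 = p_ratio / (1.0 - p_ratio)
    return {
        "BF1": bf1,
        "BF2": bf2,
        "BF12": bf12,
        "PMP1": p,
        "PMP2": 1.0 - p,
        "label": evidence_label(bf12),
        "clamped": clamped,
    }


def evidence_label(bf12: float) -> str:
    """Broad verbal band for a directional Bayes factor (annotation only)."""
    if bf12 < 1.0:
        return "favors-complement"
    if bf12 < 3.0:
        return "weak"
    if bf12 <= 10.0:
        return "moderate"
    return "strong"


def informative_bf(differences: np.ndarray, direction: str) -> dict:
    """Evaluate H1 against its complement from per-draw arm differences.

    ``differences`` are posterior draws of (control mean - intervention
    mean); ``direction`` is "greater" if H1 predicts a positive difference,
    "less" if negative.
    """
    diffs = np.asarray(differences, float).ravel()
    if diffs.size == 0:
        raise ValueError("no posterior draws supplied")
    if diffs.size < 1000:
        warnings.warn(
            f"only {diffs.size} draws: Bayes-factor estimates will be noisy",
            stacklevel=2,
        )
    if direction == "greater":
        p = float(np.mean(diffs > 0))
    elif direction == "less":
        p = float(np.mean(diffs < 0))
    else:
        raise ValueError("direction must be 'greater' or 'less'")
    row = bf_from_proportion(p, n_draws=diffs.size)
    row["difference"] = float(diffs.mean())
    return row


def bf_report(
    samples: PosteriorSamples,
    occasions: range | np.ndarray = range(1, 6),
    directions: dict[str, str] = DEFAULT_DIRECTIONS,
) -> pd.DataFrame:
    """Full per-outcome, per-occasion Bayes-factor table.

    Combines :func:`predicted_trajectory` for both arms with
    :func:`informative_bf` per outcome x occasion, using each outcome's
    "intervention does better" direction.
    """
    beta = samples.beta_draws()
    ctrl_table, ctrl = predicted_trajectory(beta, samples.terms, arm=0, occasions=occasions)
    gbg_table, gbg = predicted_trajectory(beta, samples.terms, arm=1, occasions=occasions)
    diffs = ctrl - gbg  # (n_draws, n_occ, 3)
    rows = []
    occasions = np.asarray(list(occasions))
    for k, out in enumerate(OUTCOMES):
        for i, occ in enumerate(occasions):
            row = informative_bf(diffs[:, i, k], directions[out])
            rows.append(
                {
                    "outcome": out,
                    "occasion": int(occ),
                    "control": ctrl_table.iloc[i, k],
                    "gbg": gbg_table.iloc[i, k],
                    **row,
                }
            )
    table = pd.DataFrame(rows)
    cols = [
        "outcome", "occasion", "control", "gbg", "difference",
        "BF1", "BF2", "BF12", "PMP1", "PMP2", "label", "clamped",
    ]
    return table[cols]


def trajectory_figure(
    samples: PosteriorSamples,
    occasions: range | np.ndarray = range(1, 6),
    path: str | None = None,
):
    """Three-panel predicted-trajectory figure, both arms over occasions."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    beta = samples.beta_draws()
    ctrl, _ = predicted_trajectory(beta, samples.terms, arm=0, occasions=occasions)
    gbg, _ = predicted_trajectory(beta, samples.terms, arm=1, occasions=occasions)
    fig, axes = plt.subplots(1, 3, figsize=(10.5, 3.2), sharex=True)
    for k, (ax, out) in enumerate(zip(axes, OUTCOMES)):
        ax.plot(ctrl.index, ctrl[out], "o-", label="control")
        ax.plot(gbg.index, gbg[out], "s--", label="GBG")
        ax.set_title(out.replace("_", " "))
        ax.set_xlabel("occasion")
        if k == 0:
            ax.set_ylabel("predicted standardized score")
    axes[0].legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
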