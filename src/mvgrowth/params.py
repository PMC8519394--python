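"""Reference parameter values for the simulated trial.

These are posterior-mean estimates from a large UK cluster-randomized trial of
the Good Behavior Game (GBG): 77 primary schools, ~3,084 children followed over
five annual waves, with three standardized teacher-rated outcomes
(concentration problems, disruptive behavior, prosocial behavior). They serve
as the default generating truth of the synthetic-trial simulator, so that
parameter-recovery exercises run at a realistic scale and realistic
signal-to-noise.

Outcome order everywhere in this package is
``(concentration, disruptive, prosocial)``.
"""

from __future__ import annotations

import numpy as np

#: Outcome names in canonical order.
OUTCOMES = ("concentration", "disruptive", "prosocial")

#: Outcome columns of the long-format trial frame.
Y_COLUMNS = tuple(f"y_{o}" for o in OUTCOMES)

#: Fixed-effect design terms of the full growth-curve model, in canonical
#: order. ``t`` is time in years since baseline (occasion - 1); ``gbg`` is the
#: trial-arm indicator (1 = intervention).
FULL_MODEL_TERMS = (
    "intercept",
    "t",
    "t2",
    "t3",
    "gbg",
    "t_gbg",
    "t2_gbg",
    "t3_gbg",
    "at_risk",
    "fsm",
    "school_size_z",
    "school_fsm_z",
    "gbg_fsm",
    "gbg_at_risk",
    "male",
    "gbg_male",
    "male_at_risk",
    "gbg_male_at_risk",
    "gbg_school_size_z",
    "gbg_school_fsm_z",
)

# Posterior-mean fixed effects of the full model, one row per term in
# FULL_MODEL_TERMS order, columns (concentration, disruptive, prosocial).
# Standardized-outcome scale.
REFERENCE_BETA = np.array(
    [
        [-0.368, -0.496, 0.353],   # intercept
        [0.174, 0.016, -0.075],    # t
        [-0.128, 0.013, 0.048],    # t^2
        [0.020, -0.001, -0.010],   # t^3
        [0.011, 0.072, -0.020],    # gbg
        [-0.151, 0.109, -0.102],   # t * gbg
        [0.096, -0.073, 0.051],    # t^2 * gbg
        [-0.016, 0.010, -0.004],   # t^3 * gbg
        [1.108, 1.517, -1.336],    # at_risk
        [0.262, 0.190, -0.216],    # fsm
        [-0.041, -0.062, -0.001],  # school size (z)
        [0.029, -0.002, -0.003],   # school %FSM (z)
        [-0.022, -0.059, -0.004],  # gbg * fsm
        [-0.164, -0.205, 0.377],   # gbg * at_risk
        [0.390, 0.232, -0.184],    # male
        [0.002, 0.013, -0.036],    # gbg * male
        [-0.085, 0.176, 0.247],    # male * at_risk
        [0.114, 0.072, -0.203],    # gbg * male * at_risk
        [0.096, 0.032, -0.067],    # gbg * school size
        [-0.004, 0.046, 0.016],    # gbg * school %FSM
    ]
)

# Level-specific covariance matrices of the unconditional (intercepts-only)
# model, posterior means, outcome order (concentration, disruptive, prosocial).

#: Between-school covariance of the three outcome intercepts.
REFERENCE_OMEGA_SCHOOL = np.array(
    [
        [0.040, 0.039, -0.045],
        [0.039, 0.056, -0.047],
        [-0.045, -0.047, 0.069],
    ]
)

#: Between-children covariance of the three outcome intercepts.
REFERENCE_OMEGA_CHILD = np.array(
    [
        [0.572, 0.430, -0.389],
        [0.430, 0.574, -0.397],
        [-0.389, -0.397, 0.387],
    ]
)

#: Within-child (occasion-level) residual covariance.
REFERENCE_OMEGA_RESID = np.array(
    [
        [0.406, 0.148, -0.264],
        [0.148, 0.400, -0.239],
        [-0.264, -0.239, 0.560],
    ]
)

#: Variance of the child-specific linear-time slope, per outcome. The source
#: analysis lets the linear growth rate vary across children but does not
#: report its magnitude; 0.01 (slope SD 0.1 SD-units/year) is a realistic
#: order for teacher-rated behaviour trajectories and is the simulator default.
REFERENCE_SLOPE_VAR = 0.01


def reference_omega_child_full(
    slope_var: float = REFERENCE_SLOPE_VAR,
) -> np.ndarray:
    """6x6 child-level covariance for the full model.

    Block-diagonal: the 3x3 intercept covariance above, plus independent
    outcome-specific linear-slope variances. Intercept-slope covariances are
    set to zero in the default truth (not reported by the source analysis).
    """
    out = np.zeros((6, 6))
    out[:3, :3] = REFERENCE_OMEGA_CHILD
    out[3:, 3:] = np.eye(3) * slope_var
    return out


#: Baseline covariate prevalences: male sex, free-school-meal eligibility, and
#: the conduct-problems at-risk screen (SDQ conduct subscale >= 3 at baseline;
#: 15.7% of the trial cohort).
REFERENCE_PREVALENCES = {"male": 0.51, "fsm": 0.26, "at_risk": 0.157}

#: Trial structure: schools and cohort size.
REFERENCE_N_SCHOOLS = 77
REFERENCE_N_CHILDREN = 3084
REFERENCE_N_OCCASIONS = 5

#: Wave-specific base probabilities that a child-occasion's outcome triple is
#: not collected. Baseline (pre-randomization) is complete by design; attrition
#: then grows roughly linearly, emulating the trial's lost-to-follow-up flow.
REFERENCE_WAVE_MISSING_RATES = (0.0, 0.10, 0.15, 0.20, 0.25)
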