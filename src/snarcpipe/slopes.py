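"""Per-digit dRT profiles and individual SNARC/MARC slope estimation.

dRT_d = mean right-hand RT minus mean left-hand RT for digit d. Three slope
models are supported:

- ``pj_linear``: OLS of the 8 dRTs on digit magnitude (1,2,3,4,6,7,8,9) plus
  a parity contrast (-0.5 odd / +0.5 even). Magnitude and parity are
  orthogonal in this stimulus set, so the magnitude coefficient is unchanged
  by the parity predictor.
- ``mc_categorical``: predictor -0.5 for small digits (1-4), +0.5 for large
  (6-9); the slope equals dRT(large) - dRT(small) exactly.
- ``mc_continuous``: OLS of the 8 dRTs on magnitude, no parity term.

Standardized slopes are Fisher-z transforms of the standardized regression
weights; for these orthogonal designs each weight equals the zero-order
correlation of the dRT profile with the predictor. Weights are clamped to
+/-(1 - 1e-12) before atanh so a perfectly linear profile stays finite.
A zero-variance profile gets standardized weight 0 (no evidence of
association; the unstandardized slope is 0 as well).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from snarcpipe.simulate import DIGITS, PARITY

MAGNITUDE = np.array(DIGITS, dtype=float)
PARITY_CONTRAST = np.array([PARITY[d] for d in DIGITS])
SMALL = np.array([d < 5 for d in DIGITS])
CATEGORY_CONTRAST = np.where(SMALL, -0.5, 0.5)

_CLAMP = 1.0 - 1e-12

MODELS = ("pj_linear", "mc_categorical", "mc_continuous")


@dataclass
class DrtProfile:
    """Right-minus-left mean RT difference per digit, in presentation order of DIGITS."""

    drt: np.ndarray  # shape (8,), aligned with DIGITS

    def __post_init__(self) -> None:
        self.drt = np.asarray(self.drt, dtype=float)
        if self.drt.shape != (len(DIGITS),):
            raise ValueError(f"drt must have shape ({len(DIGITS)},)")
        if not np.all(np.isfinite(self.drt)):
            raise ValueError("drt contains non-finite values")

    @property
    def small_mean(self) -> float:
        return float(self.drt[SMALL].mean())

    @property
    def large_mean(self) -> float:
        return float(self.drt[~SMALL].mean())


@dataclass
class SlopeEstimate:
    task: str
    model: str
    b_mag: float
    intercept: float
    z_mag: float
    b_par: float | None = None
    z_par: float | None = None


def compute_drt(trials: pd.DataFrame) -> DrtProfile:
    """Per-digit dRT for one participant in one task, from retained trials."""
    if len(trials) == 0:
        raise ValueError("no retained trials")
    if trials["participant_id"].nunique() > 1 or trials["task"].nunique() > 1:
        raise ValueError("compute_drt expects one participant and one task")
    means = trials.groupby(["digit", "response_side"])["rt_ms"].mean()
    drt = np.empty(len(DIGITS))
    for k, d in enumerate(DIGITS):
        for side in ("left", "right"):
            if (d, side) not in means.index:
                raise ValueError(
                    f"empty cell: digit {d}, side {side} has no retained trials"
                )
        drt[k] = means[(d, "right")] - means[(d, "left")]
    return DrtProfile(drt)


def _corr_or_zero(y: np.ndarray, x: np.ndarray) -> float:
    sy = y.std()
    sx = x.std()
    if sy == 0.0 or sx == 0.0:
        return 0.0
    r = float(np.corrcoef(y, x)[0, 1])
    return r


def _fisher_z(weight: float) -> float:
    return math.atanh(max(-_CLAMP, min(_CLAMP, weight)))


def standardize_slope(profile: DrtProfile, model: str) -> dict[str, float]:
    """Fisher-z standardized regression weight(s) for the given model."""
    y = profile.drt
    if model == "pj_linear":
        return {
            "z_mag": _fisher_z(_corr_or_zero(y, MAGNITUDE)),
            "z_par": _fisher_z(_corr_or_zero(y, PARITY_CONTRAST)),
        }
    if model == "mc_categorical":
        return {"z_mag": _fisher_z(_corr_or_zero(y, CATEGORY_CONTRAST))}
    if model == "mc_continuous":
        return {"z_mag": _fisher_z(_corr_or_zero(y, MAGNITUDE))}
    raise ValueError(f"unknown model: {model}")


def fit_pj_model(profile: DrtProfile, task: str = "PJ") -> SlopeEstimate:
    """OLS of dRT on magnitude + parity contrast, with intercept."""
    y = profile.drt
    X = np.column_stack([np.ones(len(DIGITS)), MAGNITUDE, PARITY_CONTRAST])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    z = standardize_slope(profile, "pj_linear")
    return SlopeEstimate(
        task=task,
        model="pj_linear",
        b_mag=float(coef[1]),
        b_par=float(coef[2]),
        intercept=float(coef[0]),
        z_mag=z["z_mag"],
        z_par=z["z_par"],
    )


def fit_mc_models(
    profile: DrtProfile, task: str = "MC"
) -> tuple[SlopeEstimate, SlopeEstimate]:
    """Categorical and continuous magnitude models for the MC task."""
    y = profile.drt
    b_cat = profile.large_mean - profile.small_mean
    intercept_cat = 0.5 * (profile.large_mean + profile.small_mean)
    categorical = SlopeEstimate(
        task=task,
        model="mc_categorical",
        b_mag=float(b_cat),
        intercept=float(intercept_cat),
        z_mag=standardize_slope(profile, "mc_categorical")["z_mag"],
    )
    X = np.column_stack([np.ones(len(DIGITS)), MAGNITUDE])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    continuous = SlopeEstimate(
        task=task,
        model="mc_continuous",
        b_mag=float(coef[1]),
        intercept=float(coef[0]),
        z_mag=standardize_slope(profile, "mc_continuous")["z_mag"],
    )
    return categorical, continuous


def group_curve_fit(
    profiles: Sequence[DrtProfile], model: str
) -> tuple[np.ndarray, float]:
    """Fit a model to the group-mean dRT curve; return (mean curve, adj. R^2).

    Adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - p - 1) with n = 8 digit means
    and p the number of predictors (2 for pj_linear, 1 otherwise).
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    mean_curve = np.mean([p.drt for p in profiles], axis=0)
    if model == "pj_linear":
        X = np.column_stack([np.ones(len(DIGITS)), MAGNITUDE, PARITY_CONTRAST])
    elif model == "mc_categorical":
        X = np.column_stack([np.ones(len(DIGITS)), CATEGORY_CONTRAST])
    elif model == "mc_continuous":
        X = np.column_stack([np.ones(len(DIGITS)), MAGNITUDE])
    else:
        raise ValueError(f"unknown model: {model}")
    n, p_plus_1 = X.shape
    p = p_plus_1 - 1
    if n < p + 2:
        raise ValueError("too few points for adjusted R^2")
    coef, *_ = np.linalg.lstsq(X, mean_curve, rcond=None)
    resid = mean_curve - X @ coef
    sst = float(((mean_curve - mean_curve.mean()) ** 2).sum())
    sse = float((resid**2).sum())
    r2 = 1.0 if sst == 0.0 else 1.0 - sse / sst
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    return mean_curve, float(adj_r2)


def estimate_participant(
    pj_trials: pd.DataFrame, mc_trials: pd.DataFrame
) -> dict[str, SlopeEstimate]:
    """All three slope estimates for one participant from retained trials."""
    pj_profile = compute_drt(pj_trials)
    mc_profile = compute_drt(mc_trials)
    cat, cont = fit_mc_models(mc_profile)
    return {
        "pj_linear": fit_pj_model(pj_profile),
        "mc_categorical": cat,
        "mc_continuous": cont,
    }
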