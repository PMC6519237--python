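"""Blame-regression model of third-party moral judgment.

Blame ratings of an agent's money-versus-shocks choices are modelled as a
linear function of the trial features (dm, ds) and their interactions
with the judge's own harm-aversion parameters (kappa_self, kappa_other):

    Blame = b0 + b1*dm + b2*ds + b3*dm*ko + b4*dm*ks + b5*ds*ko
            + b6*ds*ks + b7*dm*ks*ko + b8*ds*ks*ko

With b1 < 0 and b2 > 0 the model expresses the signature pattern of blame:
extra profit partially excuses a harmful choice while extra pain aggravates
it.  The judge's kappas come from the decision-model fit and are passed in
explicitly; they are never re-estimated here.  Fitting is ordinary least
squares via statsmodels.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .types import DecisionTrial, JudgmentCoefficients, JudgmentTrial

TERM_NAMES = [
    "intercept",
    "dm",
    "ds",
    "dm:kappa_o",
    "dm:kappa_s",
    "ds:kappa_o",
    "ds:kappa_s",
    "dm:kappa_s:kappa_o",
    "ds:kappa_s:kappa_o",
]

DEFAULT_SCALE = (0.0, 100.0)


def _design_row(dm: float, ds: float, ks: float, ko: float) -> np.ndarray:
    return np.array(
        [1.0, dm, ds, dm * ko, dm * ks, ds * ko, ds * ks, dm * ks * ko, ds * ks * ko]
    )


def predict_blame(
    trial,
    kappa_self: float,
    kappa_other: float,
    coef: JudgmentCoefficients,
    *,
    clip: bool = False,
    scale: tuple[float, float] = DEFAULT_SCALE,
) -> float:
    """Predicted blame for one trial under the linear blame model.

    Clipping to the rating scale is off by default (fitting uses the raw
    linear predictor) and enabled when emitting simulated ratings.
    """
    for k in (kappa_self, kappa_other):
        if not 0.0 <= k <= 1.0:
            raise ValueError(f"kappa must lie in [0, 1], got {k}")
    val = float(_design_row(trial.dm, trial.ds, kappa_self, kappa_other) @ coef.as_array())
    if clip:
        val = float(np.clip(val, *scale))
    return val


def blame_regressor(
    coef: JudgmentCoefficients,
    trials: Sequence[DecisionTrial],
    kappa_self: float,
    kappa_other: float,
    *,
    standardize: bool = False,
) -> np.ndarray:
    """Per-trial predicted-blame series for an individual decider.

    With ``standardize=True`` the series is z-scored for downstream use as
    a parametric regressor; a constant series cannot be standardized and
    raises.
    """
    series = np.array(
        [predict_blame(t, kappa_self, kappa_other, coef) for t in trials], dtype=float
    )
    if standardize:
        sd = series.std(ddof=0)
        if sd == 0:
            raise ValueError("cannot standardize a constant blame series")
        series = (series - series.mean()) / sd
    return series


@dataclasses.dataclass
class JudgmentFit:
    coef: JudgmentCoefficients
    se: np.ndarray
    conf_int: np.ndarray  # (9, 2) 95% bounds
    r_squared: float
    n_obs: int
    term_names: list[str]

    def to_dict(self) -> dict:
        return {
            "coef": {n: c for n, c in zip(self.term_names, self.coef.as_array())},
            "se": {n: s for n, s in zip(self.term_names, self.se)},
            "r_squared": self.r_squared,
            "n_obs": self.n_obs,
        }


def fit_judgment(
    dataset: Sequence[tuple[JudgmentTrial, float, float]],
    *,
    standardize_predictors: bool = False,
    rank_tol: float = 1e-8,
) -> JudgmentFit:
    """OLS fit of the blame regression to (trial, kappa_self, kappa_other) rows.

    Identification of the kappa interaction terms requires both a
    decorrelated dm/ds design and kappa variation across judges; a
    rank-deficient design raises, naming the collinear columns.
    """
    if len(dataset) < 10:
        raise ValueError("too few judgment observations to fit 9 coefficients")
    X = np.array([_design_row(t.dm, t.ds, ks, ko) for t, ks, ko in dataset])
    y = np.array([t.blame for t, _, _ in dataset], dtype=float)

    if np.linalg.matrix_rank(X, tol=rank_tol * np.abs(X).max()) < X.shape[1]:
        # identify which non-intercept columns are linearly dependent
        bad = []
        for j in range(1, X.shape[1]):
            others = np.delete(X, j, axis=1)
            resid = X[:, j] - others @ np.linalg.lstsq(others, X[:, j], rcond=None)[0]
            if np.linalg.norm(resid) < rank_tol * max(1.0, np.linalg.norm(X[:, j])):
                bad.append(TERM_NAMES[j])
        raise ValueError(f"rank-deficient blame design; collinear columns: {bad}")

    scales = np.ones(X.shape[1])
    if standardize_predictors:
        scales[1:] = X[:, 1:].std(axis=0, ddof=0)
        X = X.copy()
        X[:, 1:] /= scales[1:]

    model = sm.OLS(y, X).fit()
    coef = model.params / scales  # back to raw-predictor scale
    se = model.bse / scales
    ci = model.conf_int(alpha=0.05) / scales[:, None]
    return JudgmentFit(
        coef=JudgmentCoefficients.from_array(coef),
        se=np.asarray(se),
        conf_int=np.asarray(ci),
        r_squared=float(model.rsquared),
        n_obs=int(model.nobs),
        term_names=list(TERM_NAMES),
    )


def simulate_judgments(
    coef: JudgmentCoefficients,
    trials: Sequence[DecisionTrial],
    judge_params: Sequence[tuple[float, float]],
    noise_sd: float,
    seed: int | np.random.Generator,
    *,
    scale: tuple[float, float] = DEFAULT_SCALE,
) -> list[tuple[JudgmentTrial, float, float]]:
    """Generate a synthetic judgment dataset: the generative twin of the fit.

    Every judge in ``judge_params`` (a list of (kappa_self, kappa_other)
    draws) rates every trial; Gaussian rating noise is added and the
    result clipped to the rating scale.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    out = []
    for ks, ko in judge_params:
        for t in trials:
            mu = predict_blame(t, ks, ko, coef)
            blame = float(np.clip(mu + rng.normal(0.0, noise_sd), *scale)) if noise_sd > 0 else float(
                np.clip(mu, *scale)
            )
            out.append((JudgmentTrial(dm=t.dm, ds=t.ds, blame=blame), ks, ko))
    return out


def blame_slopes(
    coef: JudgmentCoefficients, kappa_self: float, kappa_other: float
) -> tuple[float, float]:
    """Total derivatives of predicted blame w.r.t. dm and ds for one judge.

    Includes the judge's kappa interaction terms:
    d(blame)/d(dm) = b1 + b3*ko + b4*ks + b7*ks*ko, and analogously for ds.
    """
    ks, ko = kappa_self, kappa_other
    d_dm = coef.b1 + coef.b3 * ko + coef.b4 * ks + coef.b7 * ks * ko
    d_ds = coef.b2 + coef.b5 * ko + coef.b6 * ks + coef.b8 * ks * ko
    return d_dm, d_ds
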