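"""Metrics at the intersections of moral decision, judgment, and inference.

Three derived measures, each reduced to quantities the core models
define:

* **Hypocrisy** — the gap between the money-per-shock exchange rate a
  person's own decisions reveal (kappa_o / (1 - kappa_o)) and the
  exchange rate implied by their blame judgments (ratio of the total
  pain and profit slopes of their blame function).  A calibrated judge,
  whose blame slopes are the utility-model slopes up to a common positive
  factor, has index zero.
* **Moral influence** — after observing a role model in the inference
  task, a decider's kappa_other may shift toward the model's kappa; the
  attraction weight lambda in [0, 1] measures how far along the line
  from the pre-exposure kappa to the model's kappa the post-exposure
  kappa lies.
* **Person-centered weighting** — whether the consequence slopes (profit
  and pain) of the blame function are larger when judging a bad agent
  than a good one.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .decision import indifference_rate
from .judgment import blame_slopes
from .types import DeciderParams, JudgmentCoefficients


@dataclasses.dataclass
class HypocrisyResult:
    decision_rate: float
    judgment_rate: Optional[float]
    index: Optional[float]
    flag: Optional[str] = None


def hypocrisy_index(
    decider: DeciderParams, coef: JudgmentCoefficients
) -> HypocrisyResult:
    """Indifference-point discrepancy between one's decisions and judgments.

    decision_rate = kappa_o / (1 - kappa_o); judgment_rate =
    (d blame / d ds) / (-d blame / d dm) with both slopes evaluated at the
    judge's own kappas (interaction terms included).  The judgment rate is
    only meaningful when profit mitigates (negative dm slope) and pain
    aggravates (positive ds slope) blame; otherwise the index is flagged
    non-computable.
    """
    decision_rate = indifference_rate(decider.kappa_other)
    d_dm, d_ds = blame_slopes(coef, decider.kappa_self, decider.kappa_other)
    if d_dm == 0:
        return HypocrisyResult(decision_rate, None, None, flag="zero_dm_slope")
    if d_dm > 0 or d_ds < 0:
        return HypocrisyResult(
            decision_rate, None, None,
            flag=f"slopes_not_blame_like: d_dm={d_dm:.4g}, d_ds={d_ds:.4g}",
        )
    judgment_rate = d_ds / (-d_dm)
    return HypocrisyResult(decision_rate, judgment_rate, judgment_rate - decision_rate)


@dataclasses.dataclass
class InfluenceResult:
    kappa_pre: float
    kappa_post: float
    model_kappa: float
    lambda_hat: Optional[float]
    lambda_raw: Optional[float]
    similarity: float
    excluded: bool = False
    flag: Optional[str] = None


@dataclasses.dataclass
class InfluenceSummary:
    results: list[InfluenceResult]
    mean_lambda: Optional[float]
    n_included: int
    regression: Optional[pd.DataFrame]  # lambda ~ kappa_pre + similarity


def influence_effect(
    pre_fits: Sequence[DeciderParams],
    post_fits: Sequence[DeciderParams],
    model_kappa: float,
    *,
    min_gap: float = 0.05,
) -> InfluenceSummary:
    """Per-subject attraction toward a role model's harm aversion.

    lambda_hat = (kappa_post - kappa_pre) / (model_kappa - kappa_pre),
    clamped to [0, 1] (raw value kept for diagnostics).  Subjects whose
    pre-exposure kappa already sits within ``min_gap`` of the model's are
    excluded: the ratio is unidentified.  The cohort summary regresses
    lambda_hat on the pre kappa and the pre-model similarity, probing
    whether morally better (or more similar) people are more susceptible.
    """
    if len(pre_fits) != len(post_fits):
        raise ValueError("pre and post fits must be matched by subject")
    results = []
    for pre, post in zip(pre_fits, post_fits):
        kp, kq = pre.kappa_other, post.kappa_other
        sim = abs(kp - model_kappa)
        denom = model_kappa - kp
        if abs(denom) < min_gap:
            results.append(
                InfluenceResult(kp, kq, model_kappa, None, None, sim,
                                excluded=True, flag="pre_kappa_too_close_to_model")
            )
            continue
        raw = (kq - kp) / denom
        results.append(
            InfluenceResult(kp, kq, model_kappa, float(np.clip(raw, 0.0, 1.0)),
                            float(raw), sim)
        )
    included = [r for r in results if not r.excluded]
    mean_lambda = float(np.mean([r.lambda_hat for r in included])) if included else None

    regression = None
    if len(included) >= 5:
        X = sm.add_constant(
            np.column_stack(
                [[r.kappa_pre for r in included], [r.similarity for r in included]]
            )
        )
        y = np.array([r.lambda_hat for r in included])
        if np.linalg.matrix_rank(X) == X.shape[1]:
            fit = sm.OLS(y, X).fit()
            regression = pd.DataFrame(
                {
                    "term": ["intercept", "kappa_pre", "similarity"],
                    "coef": fit.params,
                    "se": fit.bse,
                    "pvalue": fit.pvalues,
                }
            )
    return InfluenceSummary(
        results=results,
        mean_lambda=mean_lambda,
        n_included=len(included),
        regression=regression,
    )


def character_weighting_contrast(
    fits_by_agent: dict[str, JudgmentCoefficients],
    *,
    kappa_self: float = 0.0,
    kappa_other: float = 0.0,
) -> tuple[float, float]:
    """Consequence-weighting difference when judging bad versus good agents.

    Returns (|ds slope, bad| - |ds slope, good|, |dm slope, bad| -
    |dm slope, good|): positive values mean pain and profit weigh more
    heavily in judgments of the bad agent.  Slopes are the total blame
    derivatives at the supplied judge kappas (defaults reduce them to the
    main-effect coefficients b2 and b1).  Both fits must come from
    identical trial designs.
    """
    missing = {"good", "bad"} - set(fits_by_agent)
    if missing:
        raise ValueError(f"need fits for both agents; missing {sorted(missing)}")
    slopes = {
        label: blame_slopes(fits_by_agent[label], kappa_self, kappa_other)
        for label in ("good", "bad")
    }
    ds_contrast = abs(slopes["bad"][1]) - abs(slopes["good"][1])
    dm_contrast = abs(slopes["bad"][0]) - abs(slopes["good"][0])
    return ds_contrast, dm_contrast
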