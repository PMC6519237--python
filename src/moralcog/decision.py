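"""Harm-aversion utility model of moral decision-making.

A decider facing a choice between a harmful option (more money, more
shocks) and a less harmful one assigns the harmful option the relative
value

    V(harm) = (1 - kappa) * dm - kappa * ds

and chooses it with probability ``logistic(beta * V)``.  ``kappa`` in
[0, 1] is the harm-aversion parameter — the exchange rate between money
and pain — estimated separately for shocks to self and shocks to another
person; ``beta >= 0`` is the softmax choice consistency.  This module
provides the forward model, simulation, maximum-likelihood fitting with
optional weak MAP regularization, and the derived indices (indifference
exchange rate, hyperaltruism).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .types import ChoiceRecord, DecisionTrial, DeciderParams, Target

_KAPPA_EPS = 1e-6


def harm_utility(dm: float, ds: float, kappa: float) -> float:
    """Relative value of the harmful option: ``(1 - kappa)*dm - kappa*ds``.

    Linear in both the money difference ``dm`` and shock difference
    ``ds``; zero on the indifference locus ``dm/ds = kappa/(1-kappa)``.
    """
    if not 0.0 <= kappa <= 1.0:
        raise ValueError(f"kappa must lie in [0, 1], got {kappa}")
    return (1.0 - kappa) * dm - kappa * ds


def choice_prob(utility: float, beta: float) -> float:
    """Softmax probability of choosing the harmful option.

    ``beta = 0`` yields 0.5 (random choice); for ``beta > 0`` the
    probability increases strictly with utility and equals 0.5 at
    indifference.
    """
    if beta < 0:
        raise ValueError(f"beta must be >= 0, got {beta}")
    # clamp into the open interval so downstream log-likelihoods stay finite
    return float(np.clip(expit(beta * utility), 1e-15, 1 - 1e-15))


def indifference_rate(kappa: float) -> float:
    """Money-per-shock exchange rate ``kappa / (1 - kappa)`` at indifference.

    The compensation (currency units per shock) at which the harmful and
    helpful options are equally valued.
    """
    if not 0.0 <= kappa <= 1.0:
        raise ValueError(f"kappa must lie in [0, 1], got {kappa}")
    if kappa == 1.0:
        raise ValueError("kappa = 1 implies an infinite exchange rate")
    return kappa / (1.0 - kappa)


def hyperaltruism_index(params: DeciderParams) -> float:
    """``kappa_other - kappa_self``; positive values are hyperaltruistic."""
    return params.kappa_other - params.kappa_self


def simulate_decisions(
    params: DeciderParams,
    trials: Sequence[DecisionTrial],
    seed: int | np.random.Generator,
) -> list[ChoiceRecord]:
    """Sample Bernoulli choices from the utility model, one per trial."""
    if len(trials) == 0:
        raise ValueError("trials must be non-empty")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    records = []
    for t in trials:
        p = choice_prob(harm_utility(t.dm, t.ds, params.kappa_for(t.target)), params.beta)
        records.append(ChoiceRecord(trial=t, chose_harm=bool(rng.random() < p)))
    return records


@dataclasses.dataclass
class DecisionFit:
    """Maximum-likelihood (or MAP) fit of the utility model to one subject."""

    params: DeciderParams
    loglik: float
    n_trials: int
    boundary_flags: list[str]
    converged: bool

    def to_dict(self) -> dict:
        return {
            "kappa_self": self.params.kappa_self,
            "kappa_other": self.params.kappa_other,
            "beta": self.params.beta,
            "loglik": self.loglik,
            "n_trials": self.n_trials,
            "boundary_flags": self.boundary_flags,
        }


def _design_arrays(records: Sequence[ChoiceRecord]):
    dm = np.array([r.trial.dm for r in records], dtype=float)
    ds = np.array([r.trial.ds for r in records], dtype=float)
    is_self = np.array([r.trial.target == Target.SELF for r in records], dtype=bool)
    y = np.array([r.chose_harm for r in records], dtype=float)
    return dm, ds, is_self, y


def _neg_log_post(theta, dm, ds, is_self, y, has_self, has_other, map_prior):
    """Negative log-likelihood in unconstrained coordinates.

    theta = (logit kappa_self, logit kappa_other, log beta); absent
    conditions keep their slot but contribute nothing.
    """
    ks = expit(theta[0])
    ko = expit(theta[1])
    beta = math.exp(min(theta[2], 20.0))  # cap avoids overflow on wild search steps
    kappa = np.where(is_self, ks, ko)
    v = (1.0 - kappa) * dm - kappa * ds
    z = beta * v
    # log P(y) = y*z - log(1 + e^z), numerically stable
    ll = float(np.sum(y * z - np.logaddexp(0.0, z)))
    if map_prior:
        # kappa ~ Beta(1.1, 1.1), log beta ~ Normal(1, 2^2)
        for k, present in ((ks, has_self), (ko, has_other)):
            if present:
                ll += 0.1 * (math.log(k) + math.log1p(-k))
        ll += -0.5 * ((theta[2] - 1.0) / 2.0) ** 2
    return -ll


def fit_decision(
    records: Sequence[ChoiceRecord],
    *,
    map_prior: bool = False,
    n_starts: int = 5,
    seed: int = 0,
) -> DecisionFit:
    """Fit ``(kappa_self, kappa_other, beta)`` by maximum likelihood.

    Kappas are optimized through a logit transform and beta through a log
    transform so the search is unconstrained; a multi-start local
    optimizer guards against flat likelihoods at extreme beta.  A kappa is
    estimated only for target conditions present in the data; with
    ``map_prior=True`` a weak prior (kappa ~ Beta(1.1, 1.1),
    log beta ~ N(1, 2^2)) regularizes degenerate responders.

    Subjects who never (or always) chose the harmful option within a
    condition are unidentifiable there: the estimate is clamped to the
    boundary and flagged rather than raising.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 trials to fit the decision model")
    dm, ds, is_self, y = _design_arrays(records)
    has_self = bool(is_self.any())
    has_other = bool((~is_self).any())

    flags = []
    for name, mask in (("self", is_self), ("other", ~is_self)):
        if mask.any():
            ymask = y[mask]
            if ymask.min() == ymask.max():
                flags.append(f"degenerate_{name}: all choices identical")

    rng = np.random.default_rng(seed)
    best = None
    starts = [np.array([0.0, 0.0, math.log(2.0)])]
    starts += [
        np.array([rng.normal(0, 1.2), rng.normal(0, 1.2), rng.normal(1.0, 0.8)])
        for _ in range(max(0, n_starts - 1))
    ]
    args = (dm, ds, is_self, y, has_self, has_other, map_prior)
    converged = False
    for x0 in starts:
        res = minimize(_neg_log_post, x0, args=args, method="L-BFGS-B")
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success)

    ks = float(np.clip(expit(best.x[0]), _KAPPA_EPS, 1 - _KAPPA_EPS)) if has_self else 0.5
    ko = float(np.clip(expit(best.x[1]), _KAPPA_EPS, 1 - _KAPPA_EPS)) if has_other else 0.5
    beta = float(math.exp(min(best.x[2], 20.0)))
    if not has_self:
        flags.append("no_self_trials")
    if not has_other:
        flags.append("no_other_trials")
    # report the pure data log-likelihood even under MAP fitting
    ll = -_neg_log_post(best.x, dm, ds, is_self, y, has_self, has_other, False)
    params = DeciderParams(kappa_self=ks, kappa_other=ko, beta=min(beta, 1e6))
    return DecisionFit(
        params=params,
        loglik=float(ll),
        n_trials=len(records),
        boundary_flags=flags,
        converged=converged,
    )


def decision_loglik(params: DeciderParams, records: Sequence[ChoiceRecord]) -> float:
    """Bernoulli log-likelihood of observed choices under given parameters."""
    dm, ds, is_self, y = _design_arrays(records)
    kappa = np.where(is_self, params.kappa_self, params.kappa_other)
    z = params.beta * ((1.0 - kappa) * dm - kappa * ds)
    return float(np.sum(y * z - np.logaddexp(0.0, z)))
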