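"""Bayesian moral inference: learning another agent's harm aversion.

An observer watches an agent make money-versus-shocks choices and
maintains a belief — a probability distribution over the agent's harm
aversion kappa_o — that is updated after every observed choice.  Three
learners are implemented:

``grid``
    The normative oracle: an explicit posterior density over a kappa grid,
    diffused each trial by a Gaussian random-walk kernel of variance
    ``exp(omega)`` (reflecting boundaries on [0, 1]) and multiplied by the
    Bernoulli likelihood of the observed choice under the softmax utility
    model.
``gaussian``
    A hierarchical-Gaussian-filter-style approximation carrying only
    (mu, sigma) over kappa.  The mean moves by the prediction error
    weighted by the predictive variance — large uncertainty means large
    updates — via a moment-matching (assumed-density) projection of each
    one-observation posterior back onto the Gaussian family.
``rw``
    A Rescorla-Wagner comparator tracking a single running probability of
    the harmful choice with a constant learning rate; it ignores both
    trial features and belief uncertainty.

Fitting maximizes the Bernoulli likelihood of the participant's
trial-by-trial predictions; AIC/BIC model comparison discriminates the
uncertainty-weighted learners from the fixed-rate one.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import minimize
from scipy.special import expit, logit

from .decision import choice_prob, harm_utility
from .types import BeliefState, DecisionTrial, InferenceParams, PredictionRecord, ProbeRating

DEFAULT_GRID_SIZE = 201
_P_EPS = 1e-9
VARIANTS = ("grid", "gaussian", "rw")


def predict_from_belief(mu: float, trial: DecisionTrial, beta_pred: float) -> float:
    """Probability of predicting the harmful option, given belief mean ``mu``.

    The observer passes the current belief about the agent's harm aversion
    through the same utility model that generates choices:
    ``logistic(beta_pred * ((1 - mu)*dm - mu*ds))``.
    """
    if not 0.0 <= mu <= 1.0:
        raise ValueError(f"belief mean must lie in [0, 1], got {mu}")
    return choice_prob(harm_utility(trial.dm, trial.ds, mu), beta_pred)


# ---------------------------------------------------------------------------
# grid filter (oracle)
# ---------------------------------------------------------------------------

def initial_grid_belief(
    params: InferenceParams, grid_size: int = DEFAULT_GRID_SIZE
) -> BeliefState:
    """Prior belief as a discretized Normal(mu0, sigma0) on a kappa grid."""
    grid = np.linspace(0.0, 1.0, grid_size)
    density = np.exp(-0.5 * (grid - params.mu0) ** 2 / params.sigma0)
    density /= density.sum()
    return _belief_from_grid(grid, density, trial_index=0)


def _belief_from_grid(grid: np.ndarray, density: np.ndarray, trial_index: int) -> BeliefState:
    mu = float(np.sum(grid * density))
    var = float(np.sum((grid - mu) ** 2 * density))
    return BeliefState(
        mu=min(max(mu, 0.0), 1.0),
        sigma=max(var, 1e-12),
        trial_index=trial_index,
        grid=tuple(grid),
        grid_density=tuple(density / density.sum()),
    )


def grid_filter_update(
    belief: BeliefState,
    trial: DecisionTrial,
    agent_choice: bool,
    params: InferenceParams,
    *,
    diffuse: bool = True,
) -> BeliefState:
    """Exact sequential Bayes on the kappa grid.

    Two steps: (1) volatility diffusion — convolve the density with a
    Gaussian kernel of variance ``exp(omega)`` under reflecting boundaries
    and renormalize; (2) Bayes — multiply by the Bernoulli likelihood of
    the observed choice at each grid kappa and renormalize.  Belief mean
    and variance are recomputed as grid moments.
    """
    if belief.grid_density is None:
        raise ValueError("grid_filter_update requires a belief with grid_density")
    grid = np.asarray(belief.grid)
    density = np.asarray(belief.grid_density, dtype=float)

    if diffuse:
        dx = grid[1] - grid[0]
        sd_cells = math.sqrt(math.exp(params.omega)) / dx
        if sd_cells > 1e-6:
            density = gaussian_filter1d(density, sigma=sd_cells, mode="reflect")
            density = np.clip(density, 0.0, None)
            density /= density.sum()

    v = (1.0 - grid) * trial.dm - grid * trial.ds
    p = expit(params.agent_consistency * v)
    lik = p if agent_choice else 1.0 - p
    post = density * lik
    total = post.sum()
    if total <= 0.0 or not np.isfinite(total):
        raise FloatingPointError(
            f"grid posterior mass underflow at trial {belief.trial_index + 1} "
            f"(dm={trial.dm}, ds={trial.ds}, choice={agent_choice})"
        )
    return _belief_from_grid(grid, post / total, belief.trial_index + 1)


def batch_grid_posterior(
    trials: Sequence[DecisionTrial],
    choices: Sequence[bool],
    params: InferenceParams,
    grid_size: int = DEFAULT_GRID_SIZE,
) -> BeliefState:
    """All-at-once Bayes posterior (no diffusion) — the static reference.

    Equals the sequential grid filter with diffusion disabled; used to
    verify the sequential implementation.
    """
    grid = np.linspace(0.0, 1.0, grid_size)
    log_post = -0.5 * (grid - params.mu0) ** 2 / params.sigma0
    for t, y in zip(trials, choices):
        z = params.agent_consistency * ((1.0 - grid) * t.dm - grid * t.ds)
        log_post += (z if y else 0.0) - np.logaddexp(0.0, z)
    log_post -= log_post.max()
    density = np.exp(log_post)
    return _belief_from_grid(grid, density / density.sum(), len(trials))


# ---------------------------------------------------------------------------
# Gaussian (HGF-style) learner
# ---------------------------------------------------------------------------

_GL_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _gauss_legendre01(n: int = 81) -> tuple[np.ndarray, np.ndarray]:
    """Cached Gauss-Legendre nodes and weights mapped onto [0, 1]."""
    if n not in _GL_CACHE:
        x, w = np.polynomial.legendre.leggauss(n)
        _GL_CACHE[n] = ((x + 1.0) / 2.0, w / 2.0)
    return _GL_CACHE[n]

def initial_gaussian_belief(params: InferenceParams) -> BeliefState:
    """Prior for the Gaussian learner: N(mu0, sigma0) on the kappa scale."""
    return BeliefState(mu=params.mu0, sigma=params.sigma0, trial_index=0)


def gaussian_update(
    belief: BeliefState,
    trial: DecisionTrial,
    agent_choice: bool,
    params: InferenceParams,
) -> BeliefState:
    """Uncertainty-weighted Gaussian belief update (moment matching).

    The belief is a truncated Gaussian over kappa on [0, 1].  Predictive
    variance inflates by the volatility term, then the belief is
    projected back onto the Gaussian family by matching the first two
    moments of the exact one-observation posterior (assumed-density
    filtering):

        sigma_hat = sigma + exp(omega)
        posterior ~ N(kappa; mu, sigma_hat) * Bernoulli(choice | kappa)
                    restricted to [0, 1]
        mu_new, sigma_new = mean, variance of that posterior

    The moments are computed by Gauss-Legendre quadrature on [0, 1].
    The moment-matched mean obeys the canonical Gaussian-filter identity
    mu_new = mu + sigma_hat * d(log Z)/d(mu): the belief moves by the
    prediction error weighted by the predictive uncertainty, which is
    the defining difference from a fixed-rate learner.  The volatility
    exp(omega) is on the kappa scale, commensurate with the grid filter.
    """
    mu, var = belief.mu, belief.sigma
    var_hat = var + math.exp(params.omega)
    beta_a = params.agent_consistency

    k, w = _gauss_legendre01()
    # reflected Gaussian prior: mirrors the grid filter's reflecting
    # boundaries so mass never leaks outside [0, 1]
    prior = (
        np.exp(-0.5 * (k - mu) ** 2 / var_hat)
        + np.exp(-0.5 * (k + mu) ** 2 / var_hat)
        + np.exp(-0.5 * (2.0 - k - mu) ** 2 / var_hat)
    )
    z = beta_a * ((1.0 - k) * trial.dm - k * trial.ds)
    p_nodes = expit(z if agent_choice else -z)
    wl = w * prior * np.clip(p_nodes, _P_EPS, None)
    zmass = wl.sum()
    if zmass <= 0.0 or not np.isfinite(zmass):
        raise FloatingPointError(
            f"vanishing posterior mass at trial {belief.trial_index + 1}: "
            f"mu={mu}, sigma={var}, dm={trial.dm}, ds={trial.ds}, "
            f"choice={agent_choice}"
        )
    wl /= zmass
    mu_new = float(np.sum(wl * k))
    var_new = max(float(np.sum(wl * (k - mu_new) ** 2)), 1e-12)
    if not (np.isfinite(mu_new) and 0.0 <= mu_new <= 1.0):
        raise FloatingPointError(
            f"non-finite Gaussian update at trial {belief.trial_index + 1}: "
            f"mu={mu}, sigma={var}"
        )
    return BeliefState(
        mu=mu_new, sigma=var_new, trial_index=belief.trial_index + 1
    )


# ---------------------------------------------------------------------------
# Rescorla-Wagner comparator
# ---------------------------------------------------------------------------

def rw_update(p_hat: float, agent_choice: bool, alpha: float) -> float:
    """Fixed-rate update of the running harmful-choice probability."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    y = 1.0 if agent_choice else 0.0
    return p_hat + alpha * (y - p_hat)


# ---------------------------------------------------------------------------
# trajectories and fitting
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Trajectories:
    """Per-trial learner output.

    ``y_hat[i]`` is the prediction probability before observing choice i;
    ``mu[i]``/``sigma[i]`` the belief after incorporating it.  ``sigma``
    is None for the rw variant, which carries no uncertainty.
    """

    variant: str
    mu: np.ndarray
    sigma: Optional[np.ndarray]
    y_hat: np.ndarray
    mu0: float
    sigma0: Optional[float]
    beliefs: Optional[list[BeliefState]] = None


def run_learner(
    session: Sequence[PredictionRecord],
    params: InferenceParams,
    variant: str = "gaussian",
    *,
    grid_size: int = DEFAULT_GRID_SIZE,
    keep_beliefs: bool = False,
) -> Trajectories:
    """Run one learner over a session of observed agent choices.

    Deterministic given inputs.  An empty session returns prior state
    only (length-0 trajectories).
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")

    n = len(session)
    mu = np.empty(n)
    y_hat = np.empty(n)
    beliefs: list[BeliefState] = []

    if variant == "rw":
        p_hat = 0.5  # prior harm probability before any observation
        for i, rec in enumerate(session):
            y_hat[i] = min(max(p_hat, _P_EPS), 1 - _P_EPS)
            p_hat = rw_update(p_hat, rec.agent_choice, params.alpha)
            mu[i] = p_hat
        return Trajectories("rw", mu, None, y_hat, mu0=0.5, sigma0=None)

    sigma = np.empty(n)
    if variant == "grid":
        belief = initial_grid_belief(params, grid_size)
        step = grid_filter_update
    else:
        belief = initial_gaussian_belief(params)
        step = gaussian_update
    for i, rec in enumerate(session):
        y_hat[i] = predict_from_belief(belief.mu, rec.trial, params.beta_pred)
        belief = step(belief, rec.trial, rec.agent_choice, params)
        mu[i] = belief.mu
        sigma[i] = belief.sigma
        if keep_beliefs:
            beliefs.append(belief)
    return Trajectories(
        variant, mu, sigma, y_hat, mu0=params.mu0, sigma0=params.sigma0,
        beliefs=beliefs if keep_beliefs else None,
    )


@dataclasses.dataclass
class InferenceFit:
    """Fitted learner for one participant (possibly several agents)."""

    variant: str
    params: InferenceParams
    omega_by_agent: Optional[dict[str, float]]
    loglik: float
    n_obs: int
    n_params: int
    aic: float
    bic: float
    flags: list[str]

    def to_dict(self) -> dict:
        d = {
            "variant": self.variant,
            "omega": self.params.omega if self.omega_by_agent is None else None,
            "omega_by_agent": self.omega_by_agent,
            "beta_pred": self.params.beta_pred,
            "alpha": self.params.alpha if self.variant == "rw" else None,
            "mu0": self.params.mu0,
            "sigma0": self.params.sigma0,
            "loglik": self.loglik,
            "aic": self.aic,
            "bic": self.bic,
            "flags": self.flags,
        }
        return d


def _sessions_loglik(
    sessions: dict[str, Sequence[PredictionRecord]],
    params_by_agent: dict[str, InferenceParams],
    variant: str,
    grid_size: int,
) -> float:
    ll = 0.0
    for agent_id, session in sessions.items():
        traj = run_learner(session, params_by_agent[agent_id], variant, grid_size=grid_size)
        y = np.array(
            [r.participant_prediction for r in session], dtype=float
        )
        p = np.clip(traj.y_hat, _P_EPS, 1 - _P_EPS)
        ll += float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
    return ll


def fit_inference(
    sessions: dict[str, Sequence[PredictionRecord]] | Sequence[PredictionRecord],
    *,
    variant: str = "gaussian",
    per_agent_omega: bool = False,
    base_params: Optional[InferenceParams] = None,
    grid_size: int = 101,
    n_starts: int = 3,
    seed: int = 0,
) -> InferenceFit:
    """Fit a learner to a participant's trial-by-trial predictions.

    Maximizes the Bernoulli likelihood of ``participant_prediction`` under
    the learner's prediction probabilities.  Free parameters: ``omega``
    (shared, or one per agent with ``per_agent_omega=True``) and
    ``beta_pred`` for the Bayesian variants; the learning rate ``alpha``
    for rw.  Prior ``mu0``/``sigma0`` are fixed by ``base_params``.
    Constant predictions across all trials are flagged as boundary cases.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    if not isinstance(sessions, dict):
        sessions = {"agent": list(sessions)}
    sessions = {a: list(s) for a, s in sessions.items()}
    n_obs = sum(len(s) for s in sessions.values())
    if n_obs == 0:
        raise ValueError("no prediction trials to fit")
    for a, s in sessions.items():
        for r in s:
            if r.participant_prediction is None:
                raise ValueError(f"session {a!r} contains trials without predictions")
    base = base_params or InferenceParams()
    agent_ids = sorted(sessions)

    flags = []
    all_preds = [r.participant_prediction for s in sessions.values() for r in s]
    if len(set(all_preds)) == 1:
        flags.append("constant_predictions")

    rng = np.random.default_rng(seed)

    if variant == "rw":
        def nll(theta):
            p = base.model_copy(update={"alpha": float(expit(theta[0]))})
            return -_sessions_loglik(sessions, {a: p for a in agent_ids}, variant, grid_size)

        best = None
        for x0 in [np.array([logit(0.2)])] + [rng.normal(0, 1, 1) for _ in range(n_starts - 1)]:
            res = minimize(nll, x0, method="Nelder-Mead")
            if best is None or res.fun < best.fun:
                best = res
        params = base.model_copy(update={"alpha": float(expit(best.x[0]))})
        k = 1
        omega_by_agent = None
    else:
        n_omega = len(agent_ids) if per_agent_omega else 1

        def unpack(theta):
            omegas = theta[:n_omega]
            beta = float(math.exp(min(theta[n_omega], 8.0)))
            by_agent = {}
            for j, a in enumerate(agent_ids):
                w = float(omegas[j if per_agent_omega else 0])
                by_agent[a] = base.model_copy(update={"omega": w, "beta_pred": beta})
            return by_agent

        def nll(theta):
            try:
                return -_sessions_loglik(sessions, unpack(theta), variant, grid_size)
            except FloatingPointError:
                return 1e12

        x0s = [np.concatenate([np.full(n_omega, -4.0), [math.log(3.0)]])]
        for _ in range(n_starts - 1):
            x0s.append(np.concatenate([rng.normal(-4, 2, n_omega), [rng.normal(1.0, 0.7)]]))
        best = None
        for x0 in x0s:
            res = minimize(nll, x0, method="Nelder-Mead",
                           options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 600})
            if best is None or res.fun < best.fun:
                best = res
        by_agent = unpack(best.x)
        params = by_agent[agent_ids[0]]
        omega_by_agent = (
            {a: by_agent[a].omega for a in agent_ids} if per_agent_omega else None
        )
        k = n_omega + 1
        if params.beta_pred < 1e-3:
            flags.append("flat_likelihood: beta_pred near 0")

    ll = -float(best.fun)
    aic = 2 * k - 2 * ll
    bic = k * math.log(n_obs) - 2 * ll
    return InferenceFit(
        variant=variant,
        params=params,
        omega_by_agent=omega_by_agent,
        loglik=ll,
        n_obs=n_obs,
        n_params=k,
        aic=aic,
        bic=bic,
        flags=flags,
    )


def compare_models(fits: dict[str, InferenceFit]) -> pd.DataFrame:
    """AIC/BIC comparison table across learner variants fit to the same data.

    Ties (equal AIC within 1e-9) are broken toward the variant with fewer
    parameters.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fitted variants to compare")
    ns = {f.n_obs for f in fits.values()}
    if len(ns) > 1:
        raise ValueError(f"variants were fit to different trial counts: {ns}")
    rows = []
    for name, f in fits.items():
        rows.append(
            {"variant": name, "loglik": f.loglik, "k": f.n_params, "aic": f.aic, "bic": f.bic}
        )
    df = pd.DataFrame(rows).sort_values(["aic", "k"], kind="stable").reset_index(drop=True)
    best_aic = df["aic"].min()
    contenders = df[df["aic"] <= best_aic + 1e-9]
    best_variant = contenders.sort_values("k", kind="stable").iloc[0]["variant"]
    df["best"] = df["variant"] == best_variant
    df["tie"] = len(contenders) > 1
    return df


# ---------------------------------------------------------------------------
# probe ratings
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class RatingMap:
    """Affine read-out from belief state to 0-100 probe ratings.

    Character maps the belief mean (higher kappa_o reads as 'nicer');
    uncertainty maps the belief variance.  The default uncertainty slope
    spans the scale at the variance of a uniform belief (1/12).
    """

    char_intercept: float = 0.0
    char_slope: float = 100.0
    unc_intercept: float = 0.0
    unc_slope: float = 1200.0


def probe_prediction(
    belief: BeliefState, rating_map: RatingMap = RatingMap()
) -> ProbeRating:
    """Expected probe ratings from the current belief, clipped to scale."""
    for s in (rating_map.char_slope, rating_map.unc_slope):
        if not np.isfinite(s):
            raise ValueError("rating map slopes must be finite")
    character = float(
        np.clip(rating_map.char_intercept + rating_map.char_slope * belief.mu, 0, 100)
    )
    uncertainty = float(
        np.clip(rating_map.unc_intercept + rating_map.unc_slope * belief.sigma, 0, 100)
    )
    return ProbeRating(
        character=character, uncertainty=uncertainty, trial_index=belief.trial_index
    )


def fit_rating_map(
    probes: Sequence[ProbeRating], mus: Sequence[float], sigmas: Sequence[float]
) -> RatingMap:
    """Recover the affine rating map from probes by least squares."""
    char = np.polyfit(np.asarray(mus), [p.character for p in probes], 1)
    unc = np.polyfit(np.asarray(sigmas), [p.uncertainty for p in probes], 1)
    return RatingMap(
        char_intercept=float(char[1]),
        char_slope=float(char[0]),
        unc_intercept=float(unc[1]),
        unc_slope=float(unc[0]),
    )
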