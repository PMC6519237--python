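"""Domain types shared across the moral-cognition models.

All three tasks (decision, judgment, inference) are built on the same
money-versus-shocks tradeoff: each trial offers a harmful option yielding
``dm`` extra currency units at the cost of ``ds`` extra electric shocks,
relative to a less harmful option.  The types here are thin validated
records; the behavioural models live in :mod:`moralcog.decision`,
:mod:`moralcog.judgment` and :mod:`moralcog.inference`.
"""

from __future__ import annotations

import enum
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator


class Target(str, enum.Enum):
    """Who receives the shocks in a decision trial."""

    SELF = "self"
    OTHER = "other"


class AgentLabel(str, enum.Enum):
    GOOD = "good"
    BAD = "bad"
    UNKNOWN = "unknown"
    CUSTOM = "custom"


class Causation(str, enum.Enum):
    ACTIVE = "active"
    PASSIVE = "passive"


class DecisionTrial(BaseModel):
    """One money-versus-shocks tradeoff.

    ``dm`` and ``ds`` are the money and shock differences of the harmful
    option minus the less harmful option; both are non-negative and at
    least one must be positive, so the tradeoff is real.
    """

    model_config = ConfigDict(frozen=True)

    dm: float = Field(ge=0)
    ds: float = Field(ge=0)
    target: Target = Target.OTHER

    @model_validator(mode="after")
    def _not_degenerate(self) -> "DecisionTrial":
        if self.dm == 0 and self.ds == 0:
            raise ValueError("trial must have dm > 0 or ds > 0")
        return self


class DeciderParams(BaseModel):
    """Subject-level parameters of the harm-aversion utility model.

    ``kappa_self`` / ``kappa_other`` weigh shocks against money for trials
    where the decider or another person receives the shocks; ``beta`` is
    the softmax inverse temperature (choice consistency).
    """

    model_config = ConfigDict(frozen=True)

    kappa_self: float = Field(ge=0.0, le=1.0)
    kappa_other: float = Field(ge=0.0, le=1.0)
    beta: float = Field(ge=0.0)

    @model_validator(mode="after")
    def _finite_beta(self) -> "DeciderParams":
        if not np.isfinite(self.beta):
            raise ValueError("beta must be finite")
        return self

    def kappa_for(self, target: Target) -> float:
        return self.kappa_self if target == Target.SELF else self.kappa_other


class ChoiceRecord(BaseModel):
    """Observed behaviour on one decision trial."""

    model_config = ConfigDict(frozen=True)

    trial: DecisionTrial
    chose_harm: bool


class JudgmentTrial(BaseModel):
    """A third-party blame rating of an agent's choice on one tradeoff."""

    model_config = ConfigDict(frozen=True)

    dm: float = Field(ge=0)
    ds: float = Field(ge=0)
    blame: float
    agent_label: AgentLabel = AgentLabel.UNKNOWN
    causation: Optional[Causation] = None


class JudgmentCoefficients(BaseModel):
    """Weights of the blame regression.

    Blame = b0 + b1*dm + b2*ds + b3*dm*ko + b4*dm*ks + b5*ds*ko
            + b6*ds*ks + b7*dm*ks*ko + b8*ds*ks*ko
    where ks/ko are the judge's own harm-aversion parameters.
    """

    model_config = ConfigDict(frozen=True)

    b0: float = 0.0
    b1: float = 0.0
    b2: float = 0.0
    b3: float = 0.0
    b4: float = 0.0
    b5: float = 0.0
    b6: float = 0.0
    b7: float = 0.0
    b8: float = 0.0

    @model_validator(mode="after")
    def _finite(self) -> "JudgmentCoefficients":
        if not all(np.isfinite(v) for v in self.as_array()):
            raise ValueError("all coefficients must be finite")
        return self

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f"b{i}") for i in range(9)], dtype=float)

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "JudgmentCoefficients":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (9,):
            raise ValueError("expected 9 coefficients")
        return cls(**{f"b{i}": float(arr[i]) for i in range(9)})


class BeliefState(BaseModel):
    """Posterior belief over an agent's harm aversion.

    ``mu``/``sigma`` are the posterior mean and variance on the kappa
    scale; ``mu_logit``/``sigma_logit`` carry the Gaussian learner's
    internal state on the logit scale; ``grid_density`` carries the grid
    filter's full normalized density.
    """

    model_config = ConfigDict(frozen=True, arbitrary_types_allowed=True)

    mu: float = Field(ge=0.0, le=1.0)
    sigma: float = Field(gt=0.0)
    trial_index: int = 0
    grid: Optional[tuple[float, ...]] = None
    grid_density: Optional[tuple[float, ...]] = None
    mu_logit: Optional[float] = None
    sigma_logit: Optional[float] = None

    @model_validator(mode="after")
    def _density_normalized(self) -> "BeliefState":
        if self.grid_density is not None:
            if self.grid is None or len(self.grid) != len(self.grid_density):
                raise ValueError("grid and grid_density must align")
            total = float(np.sum(self.grid_density))
            if abs(total - 1.0) > 1e-10:
                raise ValueError(f"grid density sums to {total}, not 1")
        return self


class InferenceParams(BaseModel):
    """Learner-level parameters of the belief-updating models.

    ``omega`` is log belief volatility: the belief random walk gains
    variance exp(omega) per trial.  ``beta_pred`` is the softmax
    consistency of predictions; ``mu0``/``sigma0`` the prior mean and
    variance over the agent's kappa; ``alpha`` the Rescorla-Wagner
    learning rate (used by the rw variant only).
    """

    model_config = ConfigDict(frozen=True)

    omega: float = -4.0
    beta_pred: float = Field(default=3.0, ge=0.0)
    mu0: float = Field(default=0.5, ge=0.0, le=1.0)
    sigma0: float = Field(default=1.0 / 12.0, gt=0.0)
    alpha: float = Field(default=0.2, ge=0.0, le=1.0)
    beta_agent: Optional[float] = None

    @property
    def agent_consistency(self) -> float:
        """Consistency assumed for the observed agent (defaults to beta_pred)."""
        return self.beta_pred if self.beta_agent is None else self.beta_agent


class PredictionRecord(BaseModel):
    """One trial of the moral-inference task."""

    model_config = ConfigDict(frozen=True)

    trial: DecisionTrial
    agent_choice: bool
    participant_prediction: Optional[bool] = None
    feedback_correct: Optional[bool] = None

    @model_validator(mode="after")
    def _feedback_consistent(self) -> "PredictionRecord":
        if self.feedback_correct is not None and self.participant_prediction is not None:
            if self.feedback_correct != (self.agent_choice == self.participant_prediction):
                raise ValueError("feedback_correct inconsistent with prediction and choice")
        return self


class ProbeRating(BaseModel):
    """Periodic character ('nasty'-'nice') and uncertainty probe."""

    model_config = ConfigDict(frozen=True)

    character: float = Field(ge=0.0, le=100.0)
    uncertainty: float = Field(ge=0.0, le=100.0)
    trial_index: int


class AgentSpec(BaseModel):
    """An agent whose choices are observed in the inference task."""

    model_config = ConfigDict(frozen=True)

    kappa_o: float = Field(ge=0.0, le=1.0)
    beta_agent: float = Field(default=5.0, ge=0.0)
    label: AgentLabel = AgentLabel.CUSTOM


class CohortSpec(BaseModel):
    """Distributional spec for a synthetic cohort of deciders.

    Defaults produce a hyperaltruistic cohort: mean harm aversion for
    others exceeds mean harm aversion for self.
    """

    n_subjects: int = Field(default=20, ge=0)
    kappa_self_mean: float = 0.45
    kappa_self_sd: float = 0.15
    kappa_other_mean: float = 0.55
    kappa_other_sd: float = 0.15
    log_beta_mean: float = 1.6
    log_beta_sd: float = 0.3
    kappa_trunc: tuple[float, float] = (0.02, 0.98)
    seed: int = 0

    @model_validator(mode="after")
    def _valid_trunc(self) -> "CohortSpec":
        lo, hi = self.kappa_trunc
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("kappa truncation must satisfy 0 <= lo < hi <= 1")
        return self
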