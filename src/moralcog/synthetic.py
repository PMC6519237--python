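"""Synthetic task designs and full study datasets.

Generates the three task datasets with the statistical structure the
models assume: decision trials with decorrelated money and shock
differences, judgment designs rated by judges with heterogeneous harm
aversion, and inference sessions in which a synthetic participant
predicts the choices of a 'good' or 'bad' agent.  The default good/bad
pair (kappa_o = 0.7 vs 0.3) differs more than five-fold in its
money-per-shock exchange rate.  Every dataset is accompanied by a
ground-truth manifest so recovery tests can score estimates without
peeking during fitting.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from . import decision, inference, judgment
from .types import (
    AgentLabel,
    AgentSpec,
    ChoiceRecord,
    CohortSpec,
    DecisionTrial,
    DeciderParams,
    InferenceParams,
    JudgmentCoefficients,
    PredictionRecord,
    Target,
)

DEFAULT_DM_RANGE = (1, 20)
DEFAULT_DS_RANGE = (1, 10)
DEFAULT_SESSION_LENGTH = 60
DEFAULT_PROBE_EVERY = 8
DECORRELATION_TOL = 0.05
_MAX_RETRIES = 200

#: Cohort-level blame-regression weights used by the default generator:
#: profit mitigates blame, pain aggravates it, and judges with higher
#: harm aversion for others weigh both consequences more strongly.
DEFAULT_JUDGMENT_COEF = JudgmentCoefficients(
    b0=40.0, b1=-1.0, b2=3.0, b3=-1.0, b4=-0.2, b5=2.0, b6=0.5, b7=0.0, b8=0.0
)


def generate_decision_trials(
    n: int,
    dm_range: tuple[float, float] = DEFAULT_DM_RANGE,
    ds_range: tuple[float, float] = DEFAULT_DS_RANGE,
    decorrelate: bool = True,
    seed: int | np.random.Generator = 0,
    *,
    target: Target | str = Target.OTHER,
    alternate_targets: bool = False,
) -> list[DecisionTrial]:
    """Sample n tradeoff trials with integer dm and ds in the given ranges.

    With ``decorrelate=True`` the set is resampled (bounded retries) until
    |Pearson r(dm, ds)| < 0.05, the design property that lets the blame
    regression separate profit and pain effects.
    """
    if dm_range[0] >= dm_range[1] or ds_range[0] >= ds_range[1]:
        raise ValueError("dm_range and ds_range must be non-degenerate")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    target = Target(target)

    for _ in range(_MAX_RETRIES):
        dm = rng.integers(dm_range[0], dm_range[1] + 1, size=n).astype(float)
        ds = rng.integers(ds_range[0], ds_range[1] + 1, size=n).astype(float)
        if not decorrelate or n < 3:
            break
        with np.errstate(invalid="ignore"):
            r = np.corrcoef(dm, ds)[0, 1]
        if np.isnan(r) or abs(r) < DECORRELATION_TOL:
            break
    else:
        raise RuntimeError(
            f"could not decorrelate dm/ds to |r| < {DECORRELATION_TOL} "
            f"in {_MAX_RETRIES} attempts"
        )
    targets = (
        [Target.SELF if i % 2 == 0 else Target.OTHER for i in range(n)]
        if alternate_targets
        else [target] * n
    )
    return [
        DecisionTrial(dm=float(m), ds=float(s), target=t)
        for m, s, t in zip(dm, ds, targets)
    ]


def make_agent(
    label: AgentLabel | str | None = None,
    *,
    kappa_o: Optional[float] = None,
    beta_agent: float = 5.0,
) -> AgentSpec:
    """Construct an agent by label or explicit harm aversion.

    The default 'good' agent has kappa_o = 0.7 and the 'bad' agent 0.3,
    so their indifference exchange rates (7/3 vs 3/7 currency units per
    shock) differ by a factor of 49/9 > 5.
    """
    if label is not None and kappa_o is not None:
        raise ValueError("give either a label or an explicit kappa_o, not both")
    if label is not None:
        label = AgentLabel(label)
        if label == AgentLabel.GOOD:
            return AgentSpec(kappa_o=0.7, beta_agent=beta_agent, label=label)
        if label == AgentLabel.BAD:
            return AgentSpec(kappa_o=0.3, beta_agent=beta_agent, label=label)
        raise ValueError("label must be 'good' or 'bad'; use kappa_o= for custom agents")
    if kappa_o is None:
        raise ValueError("need a label or kappa_o")
    return AgentSpec(kappa_o=kappa_o, beta_agent=beta_agent, label=AgentLabel.CUSTOM)


@dataclasses.dataclass
class InferenceSession:
    """One synthetic observer-agent session with ground truth attached."""

    agent: AgentSpec
    records: list[PredictionRecord]
    probes: pd.DataFrame  # trial_index, character, uncertainty
    learner_mu: np.ndarray
    learner_sigma: Optional[np.ndarray]


def generate_inference_session(
    agent: AgentSpec,
    trials: Sequence[DecisionTrial],
    probe_every: int = DEFAULT_PROBE_EVERY,
    learner: InferenceParams | str = "ideal",
    seed: int | np.random.Generator = 0,
    *,
    variant: str = "gaussian",
    probe_noise_sd: float = 0.0,
    rating_map: inference.RatingMap = inference.RatingMap(),
) -> InferenceSession:
    """Simulate a full inference session.

    Agent choices are sampled from the utility model at the agent's
    kappa_o; the synthetic participant's predictions are sampled from the
    specified learner's trial-by-trial prediction probabilities ('ideal'
    uses a grid filter with near-zero volatility and high consistency).
    Probes are emitted every ``probe_every`` trials from the learner's
    belief via the rating map, plus optional Gaussian noise.
    """
    if probe_every < 1:
        raise ValueError("probe_every must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    if learner == "ideal":
        params = InferenceParams(
            omega=-30.0, beta_pred=agent.beta_agent, beta_agent=agent.beta_agent
        )
        variant = "grid"
    else:
        params = learner

    # agent choices
    agent_choices = []
    for t in trials:
        p = decision.choice_prob(
            decision.harm_utility(t.dm, t.ds, agent.kappa_o), agent.beta_agent
        )
        agent_choices.append(bool(rng.random() < p))

    # learner trajectory over observed choices (deterministic)
    bare = [
        PredictionRecord(trial=t, agent_choice=c) for t, c in zip(trials, agent_choices)
    ]
    traj = inference.run_learner(bare, params, variant, keep_beliefs=True)

    records = []
    for rec, y_hat in zip(bare, traj.y_hat):
        pred = bool(rng.random() < y_hat)
        records.append(
            PredictionRecord(
                trial=rec.trial,
                agent_choice=rec.agent_choice,
                participant_prediction=pred,
                feedback_correct=(pred == rec.agent_choice),
            )
        )

    probe_rows = []
    if traj.beliefs:
        for i, belief in enumerate(traj.beliefs, start=1):
            if i % probe_every == 0:
                probe = inference.probe_prediction(belief, rating_map)
                probe_rows.append(
                    {
                        "trial_index": i,
                        "character": float(
                            np.clip(probe.character + rng.normal(0, probe_noise_sd), 0, 100)
                        ),
                        "uncertainty": float(
                            np.clip(probe.uncertainty + rng.normal(0, probe_noise_sd), 0, 100)
                        ),
                    }
                )
    probes = pd.DataFrame(probe_rows, columns=["trial_index", "character", "uncertainty"])
    return InferenceSession(
        agent=agent,
        records=records,
        probes=probes,
        learner_mu=traj.mu,
        learner_sigma=traj.sigma,
    )


def sample_cohort_params(spec: CohortSpec) -> list[DeciderParams]:
    """Draw decider parameters from the cohort's truncated distributions."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.kappa_trunc

    def draw_kappa(mean, sd, size):
        a, b = (lo - mean) / sd, (hi - mean) / sd
        return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)

    ks = draw_kappa(spec.kappa_self_mean, spec.kappa_self_sd, spec.n_subjects)
    ko = draw_kappa(spec.kappa_other_mean, spec.kappa_other_sd, spec.n_subjects)
    beta = np.exp(rng.normal(spec.log_beta_mean, spec.log_beta_sd, spec.n_subjects))
    return [
        DeciderParams(kappa_self=float(a), kappa_other=float(b), beta=float(c))
        for a, b, c in zip(ks, ko, beta)
    ]


def generate_cohort(
    spec: CohortSpec,
    out_dir: str | Path,
    *,
    n_decision_trials: int = 100,
    n_judgment_trials: int = 40,
    session_length: int = DEFAULT_SESSION_LENGTH,
    judgment_coef: JudgmentCoefficients = DEFAULT_JUDGMENT_COEF,
    judgment_noise_sd: float = 5.0,
    learner_params: Optional[InferenceParams] = None,
) -> dict[str, Path]:
    """Write a complete synthetic study to ``out_dir``.

    Emits ``decision.csv``, ``judgment.csv``, ``inference.csv`` in the
    documented schemas plus ``truth_manifest.json`` holding every
    generating parameter, for recovery scoring only.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    cohort = sample_cohort_params(spec)
    learner_params = learner_params or InferenceParams(omega=-4.0, beta_pred=3.0)

    decision_rows, judgment_rows, inference_rows = [], [], []
    manifest_subjects = []
    agents = {"good": make_agent("good"), "bad": make_agent("bad")}

    for si, params in enumerate(cohort):
        sid = f"S{si:03d}"
        # decision task: alternating self/other targets, decorrelated design
        trials = generate_decision_trials(
            n_decision_trials, seed=rng, alternate_targets=True
        )
        for ti, rec in enumerate(decision.simulate_decisions(params, trials, rng)):
            decision_rows.append(
                {
                    "subject_id": sid,
                    "trial_index": ti,
                    "dm": rec.trial.dm,
                    "ds": rec.trial.ds,
                    "target": rec.trial.target.value,
                    "chose_harm": int(rec.chose_harm),
                }
            )
        # judgment task: this subject judges a shared decorrelated design
        jtrials = generate_decision_trials(n_judgment_trials, seed=rng)
        jdata = judgment.simulate_judgments(
            judgment_coef,
            jtrials,
            [(params.kappa_self, params.kappa_other)],
            judgment_noise_sd,
            rng,
        )
        for ti, (jt, _, _) in enumerate(jdata):
            judgment_rows.append(
                {
                    "subject_id": sid,
                    "trial_index": ti,
                    "dm": jt.dm,
                    "ds": jt.ds,
                    "agent_label": jt.agent_label.value,
                    "causation": "",
                    "blame": jt.blame,
                }
            )
        # inference task: one session per agent
        for agent_name, agent in agents.items():
            itrials = generate_decision_trials(session_length, seed=rng)
            sess = generate_inference_session(
                agent, itrials, learner=learner_params, seed=rng
            )
            probe_by_idx = {
                int(r.trial_index): r for r in sess.probes.itertuples(index=False)
            }
            for ti, rec in enumerate(sess.records):
                probe = probe_by_idx.get(ti + 1)
                inference_rows.append(
                    {
                        "subject_id": sid,
                        "agent_id": agent_name,
                        "trial_index": ti,
                        "dm": rec.trial.dm,
                        "ds": rec.trial.ds,
                        "agent_choice": int(rec.agent_choice),
                        "prediction": int(rec.participant_prediction),
                        "feedback_correct": int(rec.feedback_correct),
                        "probe_character": "" if probe is None else probe.character,
                        "probe_uncertainty": "" if probe is None else probe.uncertainty,
                    }
                )
        manifest_subjects.append(
            {
                "subject_id": sid,
                "kappa_self": params.kappa_self,
                "kappa_other": params.kappa_other,
                "beta": params.beta,
            }
        )

    dec_cols = ["subject_id", "trial_index", "dm", "ds", "target", "chose_harm"]
    jud_cols = ["subject_id", "trial_index", "dm", "ds", "agent_label", "causation", "blame"]
    inf_cols = [
        "subject_id", "agent_id", "trial_index", "dm", "ds", "agent_choice",
        "prediction", "feedback_correct", "probe_character", "probe_uncertainty",
    ]
    paths = {
        "decision": out_dir / "decision.csv",
        "judgment": out_dir / "judgment.csv",
        "inference": out_dir / "inference.csv",
        "manifest": out_dir / "truth_manifest.json",
    }
    pd.DataFrame(decision_rows, columns=dec_cols).to_csv(paths["decision"], index=False)
    pd.DataFrame(judgment_rows, columns=jud_cols).to_csv(paths["judgment"], index=False)
    pd.DataFrame(inference_rows, columns=inf_cols).to_csv(paths["inference"], index=False)
    manifest = {
        "seed": spec.seed,
        "spec": spec.model_dump(),
        "subjects": manifest_subjects,
        "judgment_coef": {f"b{i}": v for i, v in enumerate(judgment_coef.as_array())},
        "judgment_noise_sd": judgment_noise_sd,
        "agents": {n: a.model_dump() for n, a in agents.items()},
        "learner": learner_params.model_dump(),
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2))
    return paths
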