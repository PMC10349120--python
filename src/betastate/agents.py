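"""Synthetic rating-producing agents with a trait-anxiety covariate.

Cohorts mix two strategies: *gradual* agents rate according to the 1-state
beta learner, *switching* agents according to the n-state hidden-state
model.  Each agent carries a trait-anxiety (TA) score drawn from a truncated
normal emulating STAI-trait scores (median ~39, observed range 20-71), and a
configurable effect map can tie TA to the probability of being a switching
agent, which downstream analyses then try to recover.

Ratings are the model's predicted shock probability perturbed by
mode-parameterized beta noise: for prediction m and concentration kappa the
rating is drawn from Beta(1 + m*kappa, 1 + (1-m)*kappa), whose mode is m.
This respects the [0, 1] bounds and matches the beta likelihood used in
fitting.  Real raters are not characterized this precisely; the noise model
is a documented assumption of the generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .models import EPS_PROB, ModelTrace, ParamSet, crp_difficulty_table, simulate
from .schedule import CUE_REVERSAL, CUES, Schedule, SessionSpec, assemble_schedule

STRATEGY_GRADUAL = "gradual"
STRATEGY_SWITCHING = "switching"

#: Default generative parameters.  The shock step size exceeds the no-shock
#: step size (faster learning from aversive outcomes), decay is mild, the
#: prior is weak and symmetric, and the switching agents' threshold eta sits
#: in the regime where a session typically yields two to three states with
#: switches back to established states at most reversals (rather than a
#: fresh state per reversal).
GRADUAL_DEFAULTS = ParamSet(tau_plus=1.1, tau_minus=0.7, lam=0.95, a0=2.0, b0=2.0)
SWITCHING_DEFAULTS = replace(GRADUAL_DEFAULTS, eta=2.5)

#: Trait-anxiety distribution defaults (STAI-trait-like).
TA_MEAN = 39.0
TA_SD = 10.0
TA_BOUNDS = (20.0, 71.0)

DEFAULT_NOISE_KAPPA = 200.0


@dataclass(frozen=True)
class AgentSpec:
    agent_id: str
    strategy: str = STRATEGY_GRADUAL
    params: ParamSet = GRADUAL_DEFAULTS
    ta_score: float = TA_MEAN
    noise_kappa: float = DEFAULT_NOISE_KAPPA
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in (STRATEGY_GRADUAL, STRATEGY_SWITCHING):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if not 20.0 <= self.ta_score <= 80.0:
            raise ValueError(f"ta_score out of [20, 80]: {self.ta_score}")
        if self.noise_kappa <= 0:
            raise ValueError("noise_kappa must be positive")
        if self.strategy == STRATEGY_SWITCHING and self.params.eta is None:
            raise ValueError("switching agents need eta in params")

    @property
    def model(self) -> str:
        return "1state" if self.strategy == STRATEGY_GRADUAL else "nstate"


@dataclass(frozen=True)
class EffectMap:
    """Links trait anxiety to the chance of being a switching agent.

    P(switching) = logistic(intercept + slope * (TA - center)); with all
    weights zero the strategies are assigned 50/50 independent of TA.
    ``sessions`` optionally restricts the TA effect to named sessions (the
    effect is replaced by the intercept-only probability elsewhere), which
    lets a cohort carry a session-specific TA association.
    """

    intercept: float = 0.0
    slope: float = 0.0
    center: float = TA_MEAN
    sessions: tuple[str, ...] | None = None

    def p_switching(self, ta: float) -> float:
        z = self.intercept + self.slope * (ta - self.center)
        return 1.0 / (1.0 + np.exp(-z))


@dataclass(frozen=True)
class CohortSpec:
    n_agents: int = 40
    sessions: tuple[SessionSpec, ...] = ()
    ta_mean: float = TA_MEAN
    ta_sd: float = TA_SD
    ta_bounds: tuple[float, float] = TA_BOUNDS
    effect_map: EffectMap = field(default_factory=EffectMap)
    noise_kappa: float = DEFAULT_NOISE_KAPPA
    gradual_params: ParamSet = GRADUAL_DEFAULTS
    switching_params: ParamSet = SWITCHING_DEFAULTS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_agents < 2:
            raise ValueError("n_agents must be >= 2")


def mode_beta_rating(p_hat: np.ndarray, kappa: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Noisy ratings: Beta(1 + m*kappa, 1 + (1-m)*kappa) draws around each
    predicted probability m, clipped away from the bounds."""
    a = 1.0 + p_hat * kappa
    b = 1.0 + (1.0 - p_hat) * kappa
    r = rng.beta(a, b)
    return np.clip(r, EPS_PROB, 1.0 - EPS_PROB)


def simulate_agent(agent: AgentSpec, sched: Schedule,
                   rng: np.random.Generator | None = None,
                   rate_stable_cues: bool = False,
                   round_to_grid: bool = False) -> pd.DataFrame:
    """Run an agent through a schedule and return its trial table.

    Ratings (on [0, 1]) are produced for every reversal-cue trial and, when
    ``rate_stable_cues`` is set, for stable cues as well; other trials carry
    NaN.  ``round_to_grid`` snaps ratings to the task's 1% slider grid.
    Deterministic under the agent's seed.
    """
    if rng is None:
        rng = np.random.default_rng(agent.seed)
    df = sched.to_frame()
    df["rating"] = np.nan

    q_table = crp_difficulty_table() if agent.model == "nstate" else None
    cues = CUES if rate_stable_cues else (CUE_REVERSAL,)
    for cue in cues:
        mask = df["cue"] == cue
        outcomes = df.loc[mask, "outcome"].to_numpy()
        trace: ModelTrace = simulate(agent.model, agent.params, outcomes,
                                     q_table=q_table)
        df.loc[mask, "rating"] = mode_beta_rating(trace.p_hat,
                                                  agent.noise_kappa, rng)
    if round_to_grid:
        df["rating"] = np.round(df["rating"] * 100.0) / 100.0
    return df


def draw_ta_scores(n: int, rng: np.random.Generator, mean: float = TA_MEAN,
                   sd: float = TA_SD,
                   bounds: tuple[float, float] = TA_BOUNDS) -> np.ndarray:
    lo, hi = (bounds[0] - mean) / sd, (bounds[1] - mean) / sd
    return truncnorm.rvs(lo, hi, loc=mean, scale=sd, size=n, random_state=rng)


def simulate_cohort(c: CohortSpec,
                    rate_stable_cues: bool = False) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort across sessions.

    Returns ``(cohort, truth)``: the trial-level table (one row per
    agent x session x trial, with NaN ratings on unrated trials) and the
    ground-truth table holding each agent's strategy, parameters, TA score
    and seed so that recovery analyses can be scored and the simulation can
    be reproduced.
    """
    if not c.sessions:
        raise ValueError("CohortSpec.sessions is empty")
    root = np.random.SeedSequence(c.seed)
    agent_seeds = root.spawn(c.n_agents)
    rng = np.random.default_rng(root.spawn(1)[0])

    ta = draw_ta_scores(c.n_agents, rng, c.ta_mean, c.ta_sd, c.ta_bounds)

    cohort_rows = []
    truth_rows = []
    for i in range(c.n_agents):
        agent_id = f"agent{i:03d}"
        aseed = agent_seeds[i]
        arng = np.random.default_rng(aseed)
        for j, sess in enumerate(c.sessions):
            session_specific = (c.effect_map.sessions is None
                                or sess.label in c.effect_map.sessions)
            em = c.effect_map if session_specific else \
                replace(c.effect_map, slope=0.0)
            strategy = (STRATEGY_SWITCHING
                        if arng.random() < em.p_switching(ta[i])
                        else STRATEGY_GRADUAL)
            params = (c.switching_params if strategy == STRATEGY_SWITCHING
                      else c.gradual_params)
            sched_seed = int(arng.integers(2**31))
            sched = assemble_schedule(replace(sess, seed=sched_seed))
            agent = AgentSpec(agent_id=agent_id, strategy=strategy,
                              params=params, ta_score=float(np.clip(ta[i], 20, 80)),
                              noise_kappa=c.noise_kappa,
                              seed=int(arng.integers(2**31)))
            df = simulate_agent(agent, sched, rate_stable_cues=rate_stable_cues)
            df.insert(0, "agent_id", agent_id)
            df.insert(1, "session", sess.label)
            df["ta_score"] = agent.ta_score
            cohort_rows.append(df)
            truth_rows.append(dict(
                agent_id=agent_id, session=sess.label, strategy=strategy,
                ta_score=agent.ta_score, tau_plus=params.tau_plus,
                tau_minus=params.tau_minus, lam=params.lam, a0=params.a0,
                b0=params.b0,
                eta=params.eta if params.eta is not None else np.nan,
                schedule_seed=sched_seed, agent_seed=agent.seed))
    cohort = pd.concat(cohort_rows, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    return cohort, truth


def cohort_to_csv(cohort: pd.DataFrame, path) -> None:
    """Serialize a cohort table with ratings on the task's 0-100 scale."""
    out = cohort.copy()
    out["rating"] = out["rating"] * 100.0
    out.to_csv(path, index=False, float_format="%.6g")


def cohort_from_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["rating"] = df["rating"] / 100.0
    return df
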