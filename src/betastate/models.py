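"""Beta-distribution learning models: a 1-state gradual learner and an
n-state hidden-state-inference extension.

Both models represent the current belief about shock probability as a beta
distribution Beta(a, b).  The reported probability estimate is the mode
P_hat = (a-1)/(a+b-2) and the state's uncertainty is the beta standard
deviation sigma.  After a shock the shape parameter ``a`` grows by a step
size tau_plus; after an omission ``b`` grows by tau_minus; every trial both
parameters decay by lambda, the model's forgetting rate.  Shapes are floored
at 1 (keeping the density unimodal) and their sum is capped at 30 (the
evidence cap), which bounds how certain a state can become.

The n-state model additionally tracks a per-state running surprise

    S_t = (1 - pi) * S_{t-1} + pi * |O_t - P_hat_t|,

an exponentially smoothed absolute prediction error bounded in [0, 1].
When S exceeds the basic threshold sigma * eta the model polls existing
states near the expected value E = P_hat +/- S and switches to the most
likely candidate; when S exceeds the compound threshold sigma * eta * q(K)
and no candidate exists, a new state is created at E.  The difficulty
multiplier q(K) grows with the number of existing states K following a
Chinese-restaurant-process construction, so each additional state is
progressively harder to create.  With eta pushed to infinity neither
threshold is ever crossed and the n-state model reduces exactly to the
1-state model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import brentq

# ---------------------------------------------------------------------------
# Fixed model constants
# ---------------------------------------------------------------------------

#: Surprise smoothing weight pi (fixed, not fitted; mid-range smoothing
#: keeps the free-parameter count at 5 for the 1-state and 6 for the
#: n-state model).
PI_SURPRISE = 0.3
#: Chinese-restaurant-process parameters controlling state-creation difficulty.
CRP_THETA = 0.25
CRP_ALPHA = 1.0
#: Number of Monte-Carlo seating sequences used to build the q table.
CRP_N_MC = 10_000
#: Horizon (customers per seating sequence) for the q table; on the order of
#: one session's trial count.
CRP_HORIZON = 200
#: Internal seed for the cached default q table, so that every model run
#: shares one deterministic table.
_CRP_TABLE_SEED = 202_310
#: Cap on a + b: bounds state certainty and keeps the updates numerically
#: stable.
EVIDENCE_CAP = 30.0
#: Probability clipping constant shared with the fitting likelihood.
EPS_PROB = 0.005

EVENT_UPDATE = "update"
EVENT_SWITCH = "switch"
EVENT_CREATE = "create"


@dataclass(frozen=True)
class ParamSet:
    """Free parameters of the beta learners.

    ``eta`` is the n-state surprise threshold; ``eta=None`` denotes the
    1-state model (thresholds disabled).  The remaining attributes are fixed
    constants shared by both models.
    """

    tau_plus: float = 1.0
    tau_minus: float = 1.0
    lam: float = 0.95
    a0: float = 2.0
    b0: float = 2.0
    eta: float | None = None
    pi_s: float = PI_SURPRISE
    crp_theta: float = CRP_THETA
    crp_alpha: float = CRP_ALPHA
    evidence_cap: float = EVIDENCE_CAP

    def validate(self) -> None:
        if not 0.0 <= self.tau_plus <= 2.0:
            raise ValueError(f"tau_plus out of [0, 2]: {self.tau_plus}")
        if not 0.0 <= self.tau_minus <= 2.0:
            raise ValueError(f"tau_minus out of [0, 2]: {self.tau_minus}")
        if not 0.0 < self.lam <= 1.0:
            raise ValueError(f"lam out of (0, 1]: {self.lam}")
        if not 1.0 <= self.a0 <= 10.0 or not 1.0 <= self.b0 <= 10.0:
            raise ValueError(f"a0/b0 out of [1, 10]: {self.a0}, {self.b0}")
        if self.eta is not None and self.eta <= 0:
            raise ValueError(f"eta must be positive: {self.eta}")

    @property
    def n_free(self) -> int:
        """Number of free parameters: 5 (1-state) or 6 (n-state)."""
        return 5 if self.eta is None else 6

    def to_dict(self) -> dict:
        """Plain-dict form (YAML/JSON-friendly), free parameters plus the
        fixed constants."""
        return {
            "tau_plus": self.tau_plus, "tau_minus": self.tau_minus,
            "lam": self.lam, "a0": self.a0, "b0": self.b0, "eta": self.eta,
            "pi_s": self.pi_s, "crp_theta": self.crp_theta,
            "crp_alpha": self.crp_alpha, "evidence_cap": self.evidence_cap,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParamSet":
        known = {k: v for k, v in d.items()
                 if k in cls.__dataclass_fields__}
        return cls(**known)


@dataclass(slots=True)
class BetaState:
    """One latent state's belief: beta shapes plus bookkeeping."""

    a: float
    b: float
    created_t: int = 0
    last_active_t: int = 0
    surprise: float = 0.0

    @property
    def mode(self) -> float:
        return beta_mode(self.a, self.b)

    @property
    def sd(self) -> float:
        return beta_sd(self.a, self.b)


def beta_mode(a: float, b: float) -> float:
    """Mode of Beta(a, b) for a, b >= 1; 0.5 by convention when a = b
    (including the flat a = b = 1 case)."""
    if a == b:
        return 0.5
    return (a - 1.0) / (a + b - 2.0)


def beta_sd(a: float, b: float) -> float:
    """Standard deviation of Beta(a, b)."""
    s = a + b
    return math.sqrt(a * b / (s * s * (s + 1.0)))


def update_state(a: float, b: float, outcome: int, p: ParamSet,
                 active: bool) -> tuple[float, float]:
    """One trial's shape update: step-size increment for the active state,
    decay for everyone, then floor at 1 and cap a+b at the evidence cap."""
    lam = p.lam
    if active:
        if outcome == 1:
            a, b = lam * (a + p.tau_plus), lam * b
        else:
            a, b = lam * a, lam * (b + p.tau_minus)
    else:
        a, b = lam * a, lam * b
    return _clamp_shapes(a, b, p.evidence_cap)


def _clamp_shapes(a: float, b: float, cap: float) -> tuple[float, float]:
    if a < 1.0:
        a = 1.0
    if b < 1.0:
        b = 1.0
    s = a + b
    if s > cap:
        a, b = a * cap / s, b * cap / s
        # proportional rescale can push the smaller shape below 1; restore
        # both invariants at the cap boundary
        if a < 1.0:
            a, b = 1.0, cap - 1.0
        elif b < 1.0:
            a, b = cap - 1.0, 1.0
    return a, b


def update_surprise(s_prev: float, outcome: int, p_hat: float,
                    pi_s: float = PI_SURPRISE) -> float:
    """Exponentially smoothed absolute prediction error, bounded in [0, 1]."""
    return (1.0 - pi_s) * s_prev + pi_s * abs(outcome - p_hat)


# ---------------------------------------------------------------------------
# Chinese-restaurant-process difficulty of creating new states
# ---------------------------------------------------------------------------

def _crp_new_state_prob(t: int, k: int, theta: float, alpha: float) -> float:
    """Probability that customer t+1 opens a new table given k tables.

    Generalized CRP rule (theta + (alpha - 1) * k) / (t + theta), which at
    the default alpha = 1 reduces to the standard single-parameter CRP
    theta / (t + theta).  (The two-parameter Pitman-Yor reading with
    discount alpha = 1 is degenerate: every customer would open a new
    table.)
    """
    return min(1.0, max(0.0, (theta + (alpha - 1.0) * k) / (t + theta)))


@lru_cache(maxsize=8)
def crp_difficulty_table(k_max: int = 10, theta: float = CRP_THETA,
                         alpha: float = CRP_ALPHA, horizon: int = CRP_HORIZON,
                         n_mc: int = CRP_N_MC,
                         seed: int = _CRP_TABLE_SEED) -> tuple[float, ...]:
    """Monte-Carlo table of difficulty multipliers q(1..k_max).

    Seating sequences of ``horizon`` customers are simulated; the per-step
    new-table probability is averaged conditional on the current number of
    tables K, and q(K) = Pbar_new(1) / Pbar_new(K), clipped below at 1 and
    made non-decreasing; table counts never visited in the simulation
    inherit the running maximum.
    """
    rng = np.random.default_rng(seed)
    sum_p = np.zeros(k_max + 2)
    cnt = np.zeros(k_max + 2)
    k = np.ones(n_mc, dtype=np.int64)
    for t in range(1, horizon + 1):
        p_new = np.minimum(1.0, np.maximum(
            0.0, (theta + (alpha - 1.0) * k) / (t + theta)))
        kk = np.minimum(k, k_max)
        np.add.at(sum_p, kk, p_new)
        np.add.at(cnt, kk, 1.0)
        k = k + (rng.random(n_mc) < p_new)
    with np.errstate(invalid="ignore", divide="ignore"):
        pbar = sum_p / cnt
    q = np.empty(k_max + 1)
    q[0] = np.nan
    last = 1.0
    for kk in range(1, k_max + 1):
        if cnt[kk] > 0 and pbar[kk] > 0:
            val = max(1.0, pbar[1] / pbar[kk])
        else:
            val = last  # beyond visited range: keep the last estimate
        last = max(last, val)
        q[kk] = last
    return tuple(q[1:])


def crp_difficulty(k: int, horizon: int = CRP_HORIZON, n_mc: int = CRP_N_MC,
                   rng: np.random.Generator | None = None,
                   theta: float = CRP_THETA, alpha: float = CRP_ALPHA) -> float:
    """Difficulty multiplier q(K) >= 1 for creating a state when K exist."""
    if k < 1:
        raise ValueError(f"K must be >= 1, got {k}")
    seed = _CRP_TABLE_SEED if rng is None else int(rng.integers(2**31))
    table = crp_difficulty_table(max(10, k), theta, alpha, horizon, n_mc, seed)
    return table[k - 1]


# ---------------------------------------------------------------------------
# State initialization at a target mode
# ---------------------------------------------------------------------------

def shapes_from_mode_sd(mode: float, sd: float,
                        cap: float = EVIDENCE_CAP) -> tuple[float, float]:
    """Solve for beta shapes with the given mode and (approximately) the
    given standard deviation.

    Parameterized as a = 1 + m*c, b = 1 + (1-m)*c with concentration
    c = a + b - 2 >= 0, which pins the mode exactly for any c > 0; c is then
    solved by bisection so the SD matches.  SD is decreasing in c, so when
    the target is outside the attainable range c is clipped to its bounds
    (the flat-prior end or the evidence cap).
    """
    m = min(max(mode, EPS_PROB), 1.0 - EPS_PROB)

    def sd_at(c: float) -> float:
        return beta_sd(1.0 + m * c, 1.0 + (1.0 - m) * c)

    lo, hi = 1e-9, cap - 2.0
    if sd >= sd_at(lo):
        c = lo
    elif sd <= sd_at(hi):
        c = hi
    else:
        c = brentq(lambda x: sd_at(x) - sd, lo, hi, xtol=1e-10)
    return 1.0 + m * c, 1.0 + (1.0 - m) * c


# ---------------------------------------------------------------------------
# Forward simulation
# ---------------------------------------------------------------------------

@dataclass
class ModelTrace:
    """Per-trial record of a forward model run.

    ``p_hat``, ``sigma`` and the beta shapes ``a_pre``/``b_pre`` are the
    active state's belief *before* the trial's outcome; ``surprise`` is the
    active state's running surprise after seeing it.
    """

    p_hat: np.ndarray
    sigma: np.ndarray
    a_pre: np.ndarray
    b_pre: np.ndarray
    surprise: np.ndarray
    active_state: np.ndarray
    n_states: np.ndarray
    events: list[str]
    states: list[BetaState] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.p_hat)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(len(self.p_hat)),
                "p_hat": self.p_hat,
                "sigma": self.sigma,
                "active_state": self.active_state,
                "n_states": self.n_states,
                "surprise": self.surprise,
                "event": self.events,
            }
        )


def step_nstate(states: list[BetaState], active: int, outcome: int,
                p: ParamSet, t: int,
                q_table: tuple[float, ...] | None = None,
                thresholds_enabled: bool = True) -> tuple[list[BetaState], int, str]:
    """Advance the n-state model by one trial, in place.

    Returns ``(states, new_active_id, event)`` with event one of
    ``update`` (belief update only), ``switch`` (re-activated an existing
    state) or ``create`` (added a new state).  The active state's belief and
    surprise absorb the outcome first; threshold crossings then decide
    whether the *next* trial starts from a different state.
    """
    cur = states[active]
    a, b = cur.a, cur.b
    # floored shapes (a or b exactly 1) put the raw mode on the boundary;
    # clip so predictions and surprise stay strictly inside (0, 1)
    m = 0.5 if a == b else (a - 1.0) / (a + b - 2.0)
    p_hat = min(max(m, EPS_PROB), 1.0 - EPS_PROB)
    s = a + b
    sigma = math.sqrt(a * b / (s * s * (s + 1.0)))

    cur.surprise = (1.0 - p.pi_s) * cur.surprise \
        + p.pi_s * abs(outcome - p_hat)
    s_val = cur.surprise
    lam, cap = p.lam, p.evidence_cap
    for i, st in enumerate(states):
        if i == active:
            if outcome == 1:
                sa, sb = lam * (st.a + p.tau_plus), lam * st.b
            else:
                sa, sb = lam * st.a, lam * (st.b + p.tau_minus)
        else:
            sa, sb = lam * st.a, lam * st.b
        st.a, st.b = _clamp_shapes(sa, sb, cap)
    cur.last_active_t = t

    event = EVENT_UPDATE
    if thresholds_enabled and p.eta is not None:
        basic = sigma * p.eta
        if s_val > basic:
            if q_table is None:
                q_table = crp_difficulty_table()
            k = len(states)
            q = q_table[min(k, len(q_table)) - 1]
            e_val = p_hat + math.copysign(s_val, outcome - p_hat)
            e_val = min(max(e_val, EPS_PROB), 1.0 - EPS_PROB)
            cand = _poll_states(states, e_val, basic)
            if cand is not None and cand != active:
                active = cand
                event = EVENT_SWITCH
            elif cand is None and s_val > basic * q:
                sd0 = beta_sd(p.a0, p.b0)
                a_new, b_new = shapes_from_mode_sd(e_val, sd0, p.evidence_cap)
                states.append(BetaState(a=a_new, b=b_new, created_t=t,
                                        last_active_t=t, surprise=0.0))
                active = len(states) - 1
                event = EVENT_CREATE
    return states, active, event


def _poll_states(states: list[BetaState], e_val: float,
                 window: float) -> int | None:
    """Most likely existing state for expected value ``e_val``: among states
    whose mode lies within ``e_val +/- window``, the one with maximal beta
    density at ``e_val`` (ties broken toward the most recently active)."""
    best: int | None = None
    best_key: tuple[float, int] | None = None
    for i, st in enumerate(states):
        if abs(st.mode - e_val) <= window:
            logpdf = ((st.a - 1.0) * math.log(e_val)
                      + (st.b - 1.0) * math.log1p(-e_val)
                      - _betaln(st.a, st.b))
            key = (logpdf, st.last_active_t)
            if best_key is None or key > best_key:
                best, best_key = i, key
    return best


def _betaln(a: float, b: float) -> float:
    return math.lgamma(a) + math.lgamma(b) - math.lgamma(a + b)


def simulate(model: str, p: ParamSet, outcomes,
             q_table: tuple[float, ...] | None = None) -> ModelTrace:
    """Forward-simulate a model over a binary outcome sequence.

    ``model`` is ``"1state"`` or ``"nstate"``.  The trace's ``p_hat`` at
    trial t is the prediction made before outcome t is observed.
    """
    if model not in ("1state", "nstate"):
        raise ValueError(f"unknown model {model!r}")
    nstate = model == "nstate"
    if nstate and p.eta is None:
        raise ValueError("n-state model requires eta")
    if nstate and q_table is None:
        q_table = crp_difficulty_table()

    outcomes = np.asarray(outcomes, dtype=int)
    n = outcomes.size

    p_hat = np.empty(n)
    sigma = np.empty(n)
    a_pre = np.empty(n)
    b_pre = np.empty(n)
    surprise = np.empty(n)
    active_arr = np.empty(n, dtype=int)
    n_states_arr = np.empty(n, dtype=int)
    events: list[str] = []

    if not nstate:
        # single-state fast path: same arithmetic as step_nstate with
        # thresholds disabled, without per-trial object overhead
        a, b = float(p.a0), float(p.b0)
        s_val = 0.0
        lam, tp, tm, pi_s, cap = p.lam, p.tau_plus, p.tau_minus, p.pi_s, \
            p.evidence_cap
        lo_clip, hi_clip = EPS_PROB, 1.0 - EPS_PROB
        out_list = outcomes.tolist()
        for t in range(n):
            a_pre[t] = a
            b_pre[t] = b
            m = 0.5 if a == b else (a - 1.0) / (a + b - 2.0)
            m = lo_clip if m < lo_clip else (hi_clip if m > hi_clip else m)
            p_hat[t] = m
            s = a + b
            sigma[t] = math.sqrt(a * b / (s * s * (s + 1.0)))
            o = out_list[t]
            s_val = (1.0 - pi_s) * s_val + pi_s * abs(o - m)
            surprise[t] = s_val
            if o == 1:
                a, b = lam * (a + tp), lam * b
            else:
                a, b = lam * a, lam * (b + tm)
            a, b = _clamp_shapes(a, b, cap)
        active_arr[:] = 0
        n_states_arr[:] = 1
        events = [EVENT_UPDATE] * n
        return ModelTrace(p_hat=p_hat, sigma=sigma, a_pre=a_pre, b_pre=b_pre,
                          surprise=surprise, active_state=active_arr,
                          n_states=n_states_arr, events=events,
                          states=[BetaState(a=a, b=b, last_active_t=n - 1,
                                            surprise=s_val)])

    states = [BetaState(a=float(p.a0), b=float(p.b0))]
    active = 0
    for t in range(n):
        cur = states[active]
        a_pre[t] = cur.a
        b_pre[t] = cur.b
        p_hat[t] = min(max(cur.mode, EPS_PROB), 1.0 - EPS_PROB)
        sigma[t] = cur.sd
        active_arr[t] = active
        states, active, event = step_nstate(
            states, active, int(outcomes[t]), p, t, q_table,
            thresholds_enabled=nstate)
        surprise[t] = states[active_arr[t]].surprise
        n_states_arr[t] = len(states)
        events.append(event)

    return ModelTrace(p_hat=p_hat, sigma=sigma, a_pre=a_pre, b_pre=b_pre,
                      surprise=surprise, active_state=active_arr,
                      n_states=n_states_arr, events=events, states=states)
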