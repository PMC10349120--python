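"""Pseudo-randomized trial schedules for a three-cue probabilistic aversive
reversal-learning task.

A session presents three visual cues: a stable low-probability cue, a stable
high-probability cue, and a reversal cue whose shock probability flips between
the session's low and high contingency at phase boundaries.  Schedules are
generated phase by phase ("mini-blocks") under the task's ordering and
contingency constraints and then assembled, with a second whole-session
contingency check:

* realized per-cue shock rate within +/-5 percentage points of target, both
  per phase and across the whole session;
* no cue shown on more than three consecutive trials;
* on the first five reversal-cue trials of a phase, at least three outcomes
  point in the phase's contingency direction (>=3 shocks in a high phase,
  >=3 omissions in a low phase);
* 6-10 phases per session.

Constraints are satisfied by rejection sampling (generate-and-check) with a
retry budget, which reproduces how such schedules are built in practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

CUE_STABLE_LOW = "stable_low"
CUE_STABLE_HIGH = "stable_high"
CUE_REVERSAL = "reversal"
CUES = (CUE_STABLE_LOW, CUE_STABLE_HIGH, CUE_REVERSAL)

#: Session labels mapped to the high-contingency shock probability.
SESSION_CONTINGENCIES = {"60/40": 0.6, "75/25": 0.75, "90/10": 0.9}

#: Per-experiment task-structure parameters: mean phase length in trials
#: (all cues), +/- jitter, cue proportions (stable_low, stable_high,
#: reversal), and the probability that a phase boundary flips the reversal
#: cue's contingency.
EXPERIMENT_STYLES = {
    "I": dict(phase_len_mean=30, phase_len_jitter=2, cue_props=(0.30, 0.30, 0.40), switch_prob=0.75),
    "II": dict(phase_len_mean=30, phase_len_jitter=5, cue_props=(0.25, 0.25, 0.50), switch_prob=0.75),
    "III": dict(phase_len_mean=35, phase_len_jitter=10, cue_props=(0.20, 0.20, 0.60), switch_prob=1.0),
}

RATE_TOLERANCE = 0.05  # +/- tolerance on realized shock fraction, in absolute probability
MAX_CUE_RUN = 3
FIRST_FIVE_WINDOW = 5
FIRST_FIVE_MIN_NEW_DIRECTION = 3
DEFAULT_RETRY_BUDGET = 10_000


class ScheduleError(RuntimeError):
    """Raised when a schedule constraint cannot be satisfied within budget."""


@dataclass(frozen=True)
class SessionSpec:
    """Parameters of one task session.

    ``p_high`` is the shock probability of the stable-high cue and of the
    reversal cue during high phases; the low probability is ``1 - p_high``.
    ``phase_len_mean`` counts trials across all three cues.
    """

    label: str
    p_high: float
    phase_len_mean: int = 35
    phase_len_jitter: int = 10
    cue_props: tuple[float, float, float] = (0.20, 0.20, 0.60)
    switch_prob: float = 1.0
    n_phases: int = 7
    start_high: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.5 < self.p_high <= 1.0:
            raise ValueError(f"p_high must be in (0.5, 1], got {self.p_high}")
        if abs(sum(self.cue_props) - 1.0) > 1e-9:
            raise ValueError(f"cue_props must sum to 1, got {self.cue_props}")
        if not 6 <= self.n_phases <= 10:
            raise ValueError(f"n_phases must be in [6, 10], got {self.n_phases}")

    @property
    def p_low(self) -> float:
        return 1.0 - self.p_high

    @classmethod
    def from_style(cls, session: str, experiment_style: str = "III",
                   n_phases: int = 7, start_high: bool = False,
                   seed: int = 0) -> "SessionSpec":
        """Build a spec for one of the named contingency sessions
        (``60/40``, ``75/25``, ``90/10``) under an experiment style
        (``I``, ``II`` or ``III``)."""
        style = EXPERIMENT_STYLES[experiment_style]
        return cls(label=session, p_high=SESSION_CONTINGENCIES[session],
                   n_phases=n_phases, start_high=start_high, seed=seed, **style)

    def cue_target(self, cue: str, phase_type: str) -> float:
        """Target shock probability of ``cue`` during a ``low``/``high`` phase."""
        if cue == CUE_STABLE_LOW:
            return self.p_low
        if cue == CUE_STABLE_HIGH:
            return self.p_high
        return self.p_high if phase_type == "high" else self.p_low


@dataclass(frozen=True)
class TrialRecord:
    t: int
    cue: str
    phase_idx: int
    phase_type: str  # reversal cue's current contingency: "low" | "high"
    p_true: float
    outcome: int  # 1 = shock
    rating: float | None = None


@dataclass
class Schedule:
    spec: SessionSpec
    trials: list[TrialRecord]
    phase_boundaries: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.trials)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": [tr.t for tr in self.trials],
                "cue": [tr.cue for tr in self.trials],
                "phase_idx": [tr.phase_idx for tr in self.trials],
                "phase_type": [tr.phase_type for tr in self.trials],
                "p_true": [tr.p_true for tr in self.trials],
                "outcome": [tr.outcome for tr in self.trials],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, spec: SessionSpec) -> "Schedule":
        trials = [
            TrialRecord(int(r.trial), r.cue, int(r.phase_idx), r.phase_type,
                        float(r.p_true), int(r.outcome))
            for r in df.itertuples()
        ]
        bounds = [tr.t for prev, tr in zip(trials, trials[1:])
                  if tr.phase_idx != prev.phase_idx]
        return cls(spec=spec, trials=trials, phase_boundaries=bounds)

    def cue_outcomes(self, cue: str) -> np.ndarray:
        return np.array([tr.outcome for tr in self.trials if tr.cue == cue], dtype=int)


def largest_remainder_counts(n: int, props: Sequence[float]) -> list[int]:
    """Apportion ``n`` items by ``props`` with largest-remainder rounding."""
    raw = np.asarray(props, dtype=float) * n
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(raw - counts))
    for i in range(short):
        counts[order[i]] += 1
    return counts.tolist()


def _rate_ok(outcomes: np.ndarray, target: float) -> bool:
    if outcomes.size == 0:
        return True
    return abs(outcomes.mean() - target) <= RATE_TOLERANCE + 1e-12


def _max_run(seq: Sequence[str]) -> int:
    best = run = 0
    prev = None
    for x in seq:
        run = run + 1 if x == prev else 1
        prev = x
        best = max(best, run)
    return best


def _first_five_ok(rev_outcomes: np.ndarray, phase_type: str) -> bool:
    window = rev_outcomes[:FIRST_FIVE_WINDOW]
    new_dir = window.sum() if phase_type == "high" else (window.size - window.sum())
    return new_dir >= min(FIRST_FIVE_MIN_NEW_DIRECTION, window.size)


def generate_phase(spec: SessionSpec, phase_type: str, phase_idx: int,
                   rng: np.random.Generator,
                   retry_budget: int = DEFAULT_RETRY_BUDGET) -> list[TrialRecord]:
    """Generate one phase (mini-block) of trials by rejection sampling.

    Each attempt draws the phase length as ``phase_len_mean`` +/- a uniform
    integer jitter, with cue counts following ``cue_props`` under
    largest-remainder rounding; the cue order is resampled until no cue runs
    longer than three trials, and each cue's outcomes are resampled until the
    realized shock rate is within +/-5 points of target, with the reversal
    cue additionally satisfying the first-five rule on phases after the
    first.  Some drawn lengths admit no integer shock count within the rate
    tolerance for a low-frequency cue (e.g. 5 stable-cue trials at p = 0.1);
    such lengths are rejected and redrawn like any other failed sample.
    """
    inner_budget = max(200, retry_budget // 20)
    last_reason = "no attempt made"
    for _ in range(max(1, retry_budget // 100)):
        length = spec.phase_len_mean + int(
            rng.integers(-spec.phase_len_jitter, spec.phase_len_jitter + 1))
        counts = largest_remainder_counts(length, spec.cue_props)

        # a length is only viable if every cue has an integer shock count
        # inside the rate tolerance
        viable = all(
            any(abs(c / n - spec.cue_target(cue, phase_type)) <= RATE_TOLERANCE + 1e-12
                for c in range(n + 1)) if n else True
            for n, cue in zip(counts, CUES))
        if not viable:
            last_reason = (f"+/-5% contingency has no attainable count for "
                           f"length {length} (counts {counts})")
            continue

        cue_seq = np.repeat(np.arange(3), counts)
        # the run-length rule presumes interleaving cues; with a single cue
        # present it is vacuous
        single_cue = sum(1 for c in counts if c > 0) <= 1
        order = None
        for _ in range(inner_budget):
            cand = rng.permutation(cue_seq)
            if single_cue or _max_run(cand.tolist()) <= MAX_CUE_RUN:
                order = cand
                break
        if order is None:
            last_reason = f"max-run-length <= {MAX_CUE_RUN} (length {length})"
            continue

        outcomes_by_cue: dict[int, np.ndarray] = {}
        for ci, cue in enumerate(CUES):
            n_cue = counts[ci]
            target = spec.cue_target(cue, phase_type)
            check_first_five = cue == CUE_REVERSAL and phase_idx > 0
            for _ in range(inner_budget):
                draws = (rng.random(n_cue) < target).astype(int)
                if not _rate_ok(draws, target):
                    continue
                if check_first_five and not _first_five_ok(draws, phase_type):
                    continue
                outcomes_by_cue[ci] = draws
                break
            else:
                last_reason = (f"+/-5% contingency{' and first-five' if check_first_five else ''} "
                               f"for cue {cue} (n={n_cue}, target={target})")
                break
        if len(outcomes_by_cue) < 3:
            continue

        trials = []
        positions = [0, 0, 0]
        for t, ci in enumerate(order):
            cue = CUES[ci]
            trials.append(TrialRecord(
                t=t, cue=cue, phase_idx=phase_idx, phase_type=phase_type,
                p_true=spec.cue_target(cue, phase_type),
                outcome=int(outcomes_by_cue[ci][positions[ci]])))
            positions[ci] += 1
        return trials
    raise ScheduleError(
        f"phase {phase_idx} constraint unsatisfiable within retry budget; "
        f"last violation: {last_reason}")


def assemble_schedule(spec: SessionSpec,
                      rng: np.random.Generator | None = None,
                      retry_budget: int = DEFAULT_RETRY_BUDGET) -> Schedule:
    """Assemble ``n_phases`` mini-blocks into a full session schedule.

    The reversal cue's contingency flips at each boundary with probability
    ``switch_prob`` (otherwise the next phase repeats the same contingency).
    After assembly a second +/-5-point contingency check is applied across
    the whole session separately for each cue; the schedule is redrawn on
    failure.  Deterministic for a fixed ``(spec, seed)``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)

    for _ in range(max(1, retry_budget // 100)):
        phase_type = "high" if spec.start_high else "low"
        trials: list[TrialRecord] = []
        boundaries: list[int] = []
        for phase_idx in range(spec.n_phases):
            if phase_idx > 0:
                boundaries.append(len(trials))
                if rng.random() < spec.switch_prob:
                    phase_type = "low" if phase_type == "high" else "high"
            phase = generate_phase(spec, phase_type, phase_idx, rng, retry_budget)
            offset = len(trials)
            trials.extend(replace(tr, t=tr.t + offset) for tr in phase)
        sched = Schedule(spec=spec, trials=trials, phase_boundaries=boundaries)
        if all(_session_rates_ok(sched).values()):
            return sched
    raise ScheduleError("whole-session +/-5% contingency check failed repeatedly")


def _session_rates_ok(s: Schedule) -> dict[str, bool]:
    """Whole-session realized-vs-target rate check, per cue.

    For the reversal cue the session target is the phase-composition-weighted
    mixture of the high and low contingencies.
    """
    out = {}
    for cue in CUES:
        sub = [tr for tr in s.trials if tr.cue == cue]
        if not sub:
            out[cue] = True
            continue
        realized = float(np.mean([tr.outcome for tr in sub]))
        target = float(np.mean([tr.p_true for tr in sub]))
        out[cue] = abs(realized - target) <= RATE_TOLERANCE + 1e-12
    return out


@dataclass
class ScheduleReport:
    """Named pass/fail results from :func:`validate_schedule`."""

    checks: dict[str, bool]
    details: dict[str, object] = field(default_factory=dict)

    @property
    def all_pass(self) -> bool:
        return all(self.checks.values())

    def failed(self) -> list[str]:
        return [k for k, ok in self.checks.items() if not ok]


def validate_schedule(s: Schedule) -> ScheduleReport:
    """Check every schedule constraint; reports per-constraint booleans,
    never raises."""
    checks: dict[str, bool] = {}
    details: dict[str, object] = {}

    phase_ids = sorted({tr.phase_idx for tr in s.trials})
    checks["n_phases_in_range"] = 6 <= len(phase_ids) <= 10

    per_phase_ok = True
    first_five_ok = True
    run_ok = True
    for pid in phase_ids:
        phase = [tr for tr in s.trials if tr.phase_idx == pid]
        if len({tr.cue for tr in phase}) > 1:
            run_ok &= _max_run([tr.cue for tr in phase]) <= MAX_CUE_RUN
        ptype = phase[0].phase_type
        for cue in CUES:
            outs = np.array([tr.outcome for tr in phase if tr.cue == cue])
            per_phase_ok &= _rate_ok(outs, s.spec.cue_target(cue, ptype))
        if pid > 0:
            rev = np.array([tr.outcome for tr in phase if tr.cue == CUE_REVERSAL])
            first_five_ok &= _first_five_ok(rev, ptype)
    checks["per_phase_rate_within_5pt"] = bool(per_phase_ok)
    checks["max_cue_run_le_3"] = bool(run_ok)
    checks["first_five_new_direction"] = bool(first_five_ok)

    session_rates = _session_rates_ok(s)
    checks["session_rate_within_5pt"] = all(session_rates.values())
    details["session_rates"] = session_rates
    return ScheduleReport(checks=checks, details=details)
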