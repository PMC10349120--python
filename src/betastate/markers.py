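"""Model-free behavioral markers of reversal learning.

All markers work on the reversal cue's trial stream, indexed by the trial's
position among that cue's presentations within its phase (1-based).

* Trial-wise learning rates invert the delta rule:
  alpha_t = (P_{t+1} - P_t) / (O_t - P_t).  Values outside [0, 1] (e.g. a
  rating lowered after a shock) are excluded, as are zero-denominator cases
  where the rating already equals the outcome.
* Meaningful vs oddball: reversal-cue trials within the first ``cutoff``
  (default 5) positions of a phase are *meaningful* (updating there tracks a
  genuine change); later trials are *oddballs* (surprising outcomes there
  should be discounted).  The first phase is unlabeled, having no preceding
  reversal.  Cutoffs 7, 10 and 13 support sensitivity analyses.
* Post-reversal slope: OLS slope of ratings on positions 1..10, per phase
  and switch direction, in percentage points per trial.
* Stable-window mean: mean rating from position 10 until the next reversal,
  split by phase type.
* Reinforcement error: rating minus the running mean of delivered outcomes
  within a (cue, phase-type) group; positive values are overestimation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schedule import CUE_REVERSAL, Schedule

MEANINGFUL = "meaningful"
ODDBALL = "oddball"
UNLABELED = "unlabeled"

DEFAULT_CUTOFF = 5
SLOPE_WINDOW = 10
STABLE_FROM = 10
LR_LOG_FLOOR = 1e-3
CUTOFF_GRID = (5, 7, 10, 13)


def trialwise_learning_rate(p_t: float, p_next: float, o_t: int) -> float:
    """Learning rate implied by consecutive ratings; NaN when excluded
    (outside [0, 1], zero denominator, or missing input)."""
    if not (np.isfinite(p_t) and np.isfinite(p_next)):
        return math.nan
    denom = o_t - p_t
    if denom == 0.0:
        return math.nan
    alpha = (p_next - p_t) / denom
    return alpha if 0.0 <= alpha <= 1.0 else math.nan


def learning_rate_series(ratings, outcomes) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized learning rates for a contiguous cue stream.

    Returns ``(alpha, flag)`` of length n-1 (the last trial has no follow-up
    rating); flags are ``ok``, ``out_of_range``, ``zero_denom`` or
    ``missing``.
    """
    r = np.asarray(ratings, dtype=float)
    o = np.asarray(outcomes, dtype=float)
    p_t, p_next, o_t = r[:-1], r[1:], o[:-1]
    denom = o_t - p_t
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha = (p_next - p_t) / denom
    flag = np.full(alpha.shape, "ok", dtype=object)
    missing = ~np.isfinite(p_t) | ~np.isfinite(p_next)
    zero = (denom == 0.0) & ~missing
    oor = ~missing & ~zero & ((alpha < 0.0) | (alpha > 1.0))
    flag[missing] = "missing"
    flag[zero] = "zero_denom"
    flag[oor] = "out_of_range"
    alpha[missing | zero | oor] = np.nan
    return alpha, flag


def _reversal_frame(source) -> pd.DataFrame:
    """Reversal-cue trials with a 1-based within-phase position column."""
    if isinstance(source, Schedule):
        df = source.to_frame()
        if "rating" not in df.columns:
            df["rating"] = np.nan
    else:
        df = source
    rev = df[df["cue"] == CUE_REVERSAL].copy()
    rev["position"] = rev.groupby("phase_idx").cumcount() + 1
    return rev


def classify_trials(sched, cutoff: int = DEFAULT_CUTOFF) -> np.ndarray:
    """Label each reversal-cue trial (in presentation order) as meaningful,
    oddball, or unlabeled (first phase)."""
    rev = _reversal_frame(sched)
    first_phase = rev["phase_idx"].min()
    labels = np.where(rev["position"] <= cutoff, MEANINGFUL, ODDBALL)
    labels = np.where(rev["phase_idx"] == first_phase, UNLABELED, labels)
    return labels


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    if x.size < 3:
        return math.nan
    return float(np.polyfit(x, y, 1)[0])


def post_reversal_slope(ratings, sched: Schedule,
                        window: int = SLOPE_WINDOW) -> pd.DataFrame:
    """Per-phase OLS slopes of ratings over reversal positions 1..window.

    ``ratings`` are on [0, 1], aligned to the schedule's reversal-cue trials
    in presentation order; slopes are reported in percentage points per
    trial.  ``direction`` is ``lh``/``hl`` for genuine flips and ``ll``/
    ``hh`` when a boundary repeated the contingency; the first phase has no
    direction and is skipped.  Phases with fewer than 3 rated trials in the
    window get NaN.
    """
    rev = _reversal_frame(sched)
    rev = rev.assign(rating=np.asarray(ratings, dtype=float))
    phase_types = rev.groupby("phase_idx")["phase_type"].first()
    rows = []
    for phase_idx, grp in rev.groupby("phase_idx"):
        if phase_idx == phase_types.index.min():
            continue
        prev_type = phase_types.loc[phase_idx - 1]
        cur_type = phase_types.loc[phase_idx]
        direction = prev_type[0] + cur_type[0]  # "lh", "hl", "ll", "hh"
        win = grp[grp["position"] <= window].dropna(subset=["rating"])
        slope = _ols_slope(win["position"].to_numpy(dtype=float),
                           win["rating"].to_numpy() * 100.0)
        rows.append(dict(phase_idx=phase_idx, direction=direction,
                         slope=slope, n=len(win)))
    return pd.DataFrame(rows, columns=["phase_idx", "direction", "slope", "n"])


def stable_window_mean(ratings, sched: Schedule,
                       from_trial: int = STABLE_FROM) -> dict[str, float]:
    """Mean rating over reversal-cue trials at positions >= ``from_trial``,
    split by phase type; NaN when no trial qualifies.  The first phase is
    excluded (no preceding reversal)."""
    rev = _reversal_frame(sched)
    rev = rev.assign(rating=np.asarray(ratings, dtype=float))
    rev = rev[rev["phase_idx"] > rev["phase_idx"].min()]
    out = {}
    for ptype in ("high", "low"):
        vals = rev.loc[(rev["phase_type"] == ptype)
                       & (rev["position"] >= from_trial), "rating"].dropna()
        out[ptype] = float(vals.mean()) if len(vals) else math.nan
    return out


def reinforcement_error(ratings, outcomes, groups) -> np.ndarray:
    """Per-trial deviation of ratings from the running reinforcement rate.

    The running mean of outcomes (up to and including the current trial) is
    tracked separately within each group label (state condition) and
    subtracted from the rating; positive errors are overestimation.
    """
    r = np.asarray(ratings, dtype=float)
    o = np.asarray(outcomes, dtype=float)
    g = np.asarray(groups)
    err = np.full(r.shape, np.nan)
    for label in pd.unique(g):
        idx = np.flatnonzero(g == label)
        cummean = np.cumsum(o[idx]) / np.arange(1, idx.size + 1)
        err[idx] = r[idx] - cummean
    return err


@dataclass(frozen=True)
class MarkerConfig:
    cutoff: int = DEFAULT_CUTOFF
    slope_window: int = SLOPE_WINDOW
    stable_from: int = STABLE_FROM


def session_markers(session_df: pd.DataFrame,
                    config: MarkerConfig = MarkerConfig()) -> dict[str, float]:
    """Markers for one agent x session trial table (reversal cue)."""
    rev = _reversal_frame(session_df)
    ratings = rev["rating"].to_numpy()
    outcomes = rev["outcome"].to_numpy()

    alpha, _ = learning_rate_series(ratings, outcomes)
    labels = classify_trials(session_df, cutoff=config.cutoff)[:-1]
    lr_meaningful = float(np.nanmean(alpha[labels == MEANINGFUL])) \
        if np.isfinite(alpha[labels == MEANINGFUL]).any() else math.nan
    lr_oddball = float(np.nanmean(alpha[labels == ODDBALL])) \
        if np.isfinite(alpha[labels == ODDBALL]).any() else math.nan

    slopes = post_reversal_slope(ratings, session_df, window=config.slope_window)
    slope_lh = float(slopes.loc[slopes["direction"] == "lh", "slope"].mean())
    slope_hl = float(slopes.loc[slopes["direction"] == "hl", "slope"].mean())
    flips = slopes[slopes["direction"].isin(["lh", "hl"])]
    abs_slope = float(flips["slope"].abs().mean())

    stable = stable_window_mean(ratings, session_df,
                                from_trial=config.stable_from)

    err = reinforcement_error(ratings, outcomes,
                              rev["phase_type"].to_numpy())
    err_by_type = {
        f"reinf_err_{p}": float(np.nanmean(err[rev["phase_type"] == p]))
        if np.isfinite(err[rev["phase_type"] == p]).any() else math.nan
        for p in ("high", "low")
    }

    def _log(x: float) -> float:
        return math.log(max(x, LR_LOG_FLOOR)) if np.isfinite(x) else math.nan

    return dict(
        slope_lh=slope_lh, slope_hl=slope_hl, abs_slope=abs_slope,
        lr_meaningful=lr_meaningful, lr_oddball=lr_oddball,
        lr_diff=(lr_meaningful - lr_oddball
                 if np.isfinite(lr_meaningful) and np.isfinite(lr_oddball)
                 else math.nan),
        log_lr_meaningful=_log(lr_meaningful), log_lr_oddball=_log(lr_oddball),
        stable_mean_high=stable["high"], stable_mean_low=stable["low"],
        **err_by_type,
    )


def compute_markers(cohort: pd.DataFrame,
                    config: MarkerConfig = MarkerConfig()) -> pd.DataFrame:
    """Marker table: one row per agent x session (columns as
    :func:`session_markers`, plus the agent's trait-anxiety score when
    present)."""
    rows = []
    for (agent_id, session), grp in cohort.groupby(["agent_id", "session"],
                                                   sort=True):
        row = dict(agent_id=agent_id, session=session)
        row.update(session_markers(grp, config))
        if "ta_score" in grp.columns:
            row["ta_score"] = float(grp["ta_score"].iloc[0])
        rows.append(row)
    return pd.DataFrame(rows)
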