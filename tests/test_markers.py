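"""Tests for the model-free behavioral markers."""

import math

import numpy as np
import pandas as pd
import pytest

import betastate as bs
from betastate import markers as mk


# ---------------------------------------------------------------------------
# Trial-wise learning rates
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("p_t,p_next,o,expected", [
    (0.3, 0.5, 1, 0.2 / 0.7),           # direct formula
    (0.3, 0.2, 1, math.nan),            # lowered after shock: excluded
    (0.4, 1.0, 1, 1.0),                 # full update to the outcome
    (0.4, 0.4, 1, 0.0),                 # no update
    (1.0, 0.8, 1, math.nan),            # zero denominator
])
def test_trialwise_learning_rate_cases(p_t, p_next, o, expected):
    got = bs.trialwise_learning_rate(p_t, p_next, o)
    if math.isnan(expected):
        assert math.isnan(got)
    else:
        assert got == pytest.approx(expected)


def test_learning_rate_series_matches_scalar_oracle():
    rng = np.random.default_rng(8)
    for _ in range(100):
        n = rng.integers(5, 40)
        ratings = rng.random(n)
        ratings[rng.random(n) < 0.1] = np.nan
        outcomes = (rng.random(n) < 0.5).astype(int)
        alpha, flags = bs.learning_rate_series(ratings, outcomes)
        for t in range(n - 1):
            oracle = bs.trialwise_learning_rate(ratings[t], ratings[t + 1],
                                                outcomes[t])
            if math.isnan(oracle):
                assert math.isnan(alpha[t])
                assert flags[t] != "ok"
            else:
                assert alpha[t] == pytest.approx(oracle)
                assert flags[t] == "ok"


def test_learning_rate_exclusion_never_drops_valid_values():
    rng = np.random.default_rng(9)
    ratings = rng.random(200)
    outcomes = (rng.random(200) < 0.5).astype(int)
    alpha, flags = bs.learning_rate_series(ratings, outcomes)
    ok = np.isfinite(alpha)
    assert np.all((alpha[ok] >= 0) & (alpha[ok] <= 1))
    assert np.all(flags[ok] == "ok")


# ---------------------------------------------------------------------------
# Meaningful / oddball classification
# ---------------------------------------------------------------------------

def test_classification_counts(sched_7525):
    labels = bs.classify_trials(sched_7525, cutoff=5)
    df = sched_7525.to_frame()
    rev = df[df.cue == "reversal"].copy()
    rev["label"] = labels
    first = rev.phase_idx.min()
    for pid, grp in rev.groupby("phase_idx"):
        if pid == first:
            assert (grp.label == "unlabeled").all()
        else:
            n = len(grp)
            assert (grp.label == "meaningful").sum() == min(5, n)
            assert (grp.label == "oddball").sum() == max(0, n - 5)


def test_classification_partitions_after_first_phase(sched_9010):
    for cutoff in mk.CUTOFF_GRID:
        labels = bs.classify_trials(sched_9010, cutoff=cutoff)
        assert set(labels) <= {"meaningful", "oddball", "unlabeled"}
        rev = sched_9010.to_frame().query("cue == 'reversal'")
        after_first = (rev.phase_idx > rev.phase_idx.min()).to_numpy()
        assert np.all(np.isin(labels[after_first], ["meaningful", "oddball"]))


def test_cutoff_equal_to_phase_length_leaves_no_oddballs():
    labels = None
    spec = bs.SessionSpec.from_style("75/25", "III", seed=5)
    s = bs.assemble_schedule(spec)
    rev = s.to_frame().query("cue == 'reversal'")
    max_len = rev.groupby("phase_idx").size().max()
    labels = bs.classify_trials(s, cutoff=int(max_len))
    assert "oddball" not in labels


def test_classification_matches_bruteforce_loop():
    rng = np.random.default_rng(31)
    for seed in range(20):
        s = bs.assemble_schedule(
            bs.SessionSpec.from_style("60/40", "II", seed=seed))
        cutoff = int(rng.choice(mk.CUTOFF_GRID))
        labels = bs.classify_trials(s, cutoff=cutoff)
        # brute force: walk trials, count reversal positions per phase
        expected = []
        pos = {}
        first = min(tr.phase_idx for tr in s.trials)
        for tr in s.trials:
            if tr.cue != "reversal":
                continue
            pos[tr.phase_idx] = pos.get(tr.phase_idx, 0) + 1
            if tr.phase_idx == first:
                expected.append("unlabeled")
            elif pos[tr.phase_idx] <= cutoff:
                expected.append("meaningful")
            else:
                expected.append("oddball")
        assert list(labels) == expected


# ---------------------------------------------------------------------------
# Post-reversal slope
# ---------------------------------------------------------------------------

def _two_phase_frame(ratings_p1):
    """Schedule-like frame: phase 0 low (10 reversal trials), phase 1 high."""
    rows = []
    t = 0
    for _ in range(10):
        rows.append(dict(trial=t, cue="reversal", phase_idx=0,
                         phase_type="low", p_true=0.25, outcome=0,
                         rating=0.2))
        t += 1
    for r in ratings_p1:
        rows.append(dict(trial=t, cue="reversal", phase_idx=1,
                         phase_type="high", p_true=0.75, outcome=1,
                         rating=r))
        t += 1
    return pd.DataFrame(rows)


def test_slope_exact_line():
    df = _two_phase_frame([i / 10 for i in range(1, 11)])
    rev = df[df.cue == "reversal"]
    slopes = bs.post_reversal_slope(rev["rating"].to_numpy(), df)
    assert len(slopes) == 1
    assert slopes.slope.iloc[0] == pytest.approx(10.0)
    assert slopes.direction.iloc[0] == "lh"


def test_slope_constant_ratings_is_zero():
    df = _two_phase_frame([0.6] * 10)
    slopes = bs.post_reversal_slope(df["rating"].to_numpy()[df.cue == "reversal"],
                                    df)
    assert slopes.slope.iloc[0] == pytest.approx(0.0)


def test_slope_requires_three_rated_trials():
    df = _two_phase_frame([0.5, 0.6] + [np.nan] * 8)
    slopes = bs.post_reversal_slope(df["rating"].to_numpy()[df.cue == "reversal"],
                                    df)
    assert math.isnan(slopes.slope.iloc[0])


def test_noiseless_slopes_steeper_in_9010_than_6040():
    """A switching agent's post-reversal updating is steeper when the
    contingency gap is wide (90/10) than when it is narrow (60/40)."""
    mean_abs = {}
    for session in ("90/10", "60/40"):
        vals = []
        for seed in range(6):
            s = bs.assemble_schedule(
                bs.SessionSpec.from_style(session, "III", seed=seed))
            o = s.cue_outcomes("reversal")
            tr = bs.simulate("nstate", bs.SWITCHING_DEFAULTS, o)
            slopes = bs.post_reversal_slope(tr.p_hat, s)
            flips = slopes[slopes.direction.isin(["lh", "hl"])]
            vals.append(flips.slope.abs().mean())
        mean_abs[session] = np.mean(vals)
    assert mean_abs["90/10"] > mean_abs["60/40"]


# ---------------------------------------------------------------------------
# Stable-window mean
# ---------------------------------------------------------------------------

def test_stable_window_constant_ratings(sched_7525):
    n_rev = (sched_7525.to_frame().cue == "reversal").sum()
    out = bs.stable_window_mean(np.full(n_rev, 0.7), sched_7525)
    assert out["high"] == pytest.approx(0.7)
    assert out["low"] == pytest.approx(0.7)


def test_stable_window_ignores_first_nine_positions(sched_7525):
    df = sched_7525.to_frame()
    rev = df[df.cue == "reversal"].copy()
    rev["position"] = rev.groupby("phase_idx").cumcount() + 1
    base = np.full(len(rev), 0.5)
    altered = base.copy()
    altered[(rev.position <= 9).to_numpy()] = 0.99
    assert bs.stable_window_mean(base, sched_7525) == \
        bs.stable_window_mean(altered, sched_7525)


def test_stable_window_matches_bruteforce(sched_9010):
    rng = np.random.default_rng(17)
    df = sched_9010.to_frame()
    rev = df[df.cue == "reversal"].copy()
    ratings = rng.random(len(rev))
    got = bs.stable_window_mean(ratings, sched_9010)
    # brute force per trial
    sums = {"high": [], "low": []}
    pos = {}
    first = rev.phase_idx.min()
    for r, (_, tr) in zip(ratings, rev.iterrows()):
        pos[tr.phase_idx] = pos.get(tr.phase_idx, 0) + 1
        if tr.phase_idx != first and pos[tr.phase_idx] >= 10:
            sums[tr.phase_type].append(r)
    for k in ("high", "low"):
        assert got[k] == pytest.approx(np.mean(sums[k]))


# ---------------------------------------------------------------------------
# Reinforcement error
# ---------------------------------------------------------------------------

def test_reinforcement_error_example():
    err = bs.reinforcement_error([1.0, 1.0, 1.0], [1, 1, 0], ["a", "a", "a"])
    np.testing.assert_allclose(err, [0.0, 0.0, 1.0 / 3.0])


def test_reinforcement_error_zero_when_rating_tracks_rate():
    o = np.array([1, 0, 1, 1, 0])
    cummean = np.cumsum(o) / np.arange(1, 6)
    err = bs.reinforcement_error(cummean, o, ["g"] * 5)
    np.testing.assert_allclose(err, 0.0, atol=1e-12)


def test_reinforcement_error_matches_bruteforce_groups():
    rng = np.random.default_rng(23)
    for _ in range(100):
        n = int(rng.integers(5, 50))
        r = rng.random(n)
        o = (rng.random(n) < 0.5).astype(int)
        g = rng.choice(["high", "low"], n)
        err = bs.reinforcement_error(r, o, g)
        for label in ("high", "low"):
            seen = []
            for t in range(n):
                if g[t] != label:
                    continue
                seen.append(o[t])
                assert err[t] == pytest.approx(r[t] - np.mean(seen))


# ---------------------------------------------------------------------------
# Cross-module consistency and the marker table
# ---------------------------------------------------------------------------

def test_learning_rate_recovers_model_update_fraction():
    """On noiseless 1-state ratings the inverted delta rule returns the
    model's own implied per-trial update fraction."""
    p = bs.ParamSet(tau_plus=1.0, tau_minus=1.0, lam=1.0, a0=2.0, b0=2.0)
    rng = np.random.default_rng(4)
    outcomes = (rng.random(30) < 0.7).astype(int)
    tr = bs.simulate("1state", p, outcomes)
    alpha, _ = bs.learning_rate_series(tr.p_hat, outcomes)
    implied = (tr.p_hat[1:] - tr.p_hat[:-1]) / (outcomes[:-1] - tr.p_hat[:-1])
    ok = np.isfinite(alpha)
    assert ok.sum() > 10
    np.testing.assert_allclose(alpha[ok], implied[ok], atol=1e-12)


def test_marker_table_schema_and_cutoff_smoothness(sched_9010):
    agent = bs.AgentSpec("a1", "switching", bs.SWITCHING_DEFAULTS, seed=3)
    df = bs.simulate_agent(agent, sched_9010)
    df.insert(0, "agent_id", "a1")
    df.insert(1, "session", "90/10")
    prev = None
    means = []
    for cutoff in mk.CUTOFF_GRID:
        table = bs.compute_markers(df, mk.MarkerConfig(cutoff=cutoff))
        assert {"slope_lh", "slope_hl", "abs_slope", "lr_meaningful",
                "lr_oddball", "lr_diff", "stable_mean_high",
                "stable_mean_low"} <= set(table.columns)
        means.append((table.lr_meaningful.iloc[0], table.lr_oddball.iloc[0]))
    # estimates shift smoothly across cutoffs: no jump larger than the
    # overall meaningful-oddball separation scale
    m = np.array(means)
    assert np.all(np.isfinite(m))
    assert np.max(np.abs(np.diff(m[:, 0]))) < 0.25
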