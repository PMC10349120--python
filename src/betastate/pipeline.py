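"""End-to-end orchestration: recovery studies, cohort correlations,
split-half out-of-sample checks, and the correlation power calculation.

The recovery analyses close the loop on the synthetic cohorts: simulate
agents from known models/parameters, fit both models, and verify that BIC
picks the generating model (model recovery) and that fitted step sizes
track the generating ones (parameter recovery).  Cohort analyses mirror the
headline tests of the empirical design at the level of simple per-subject
summaries: correlations (Pearson/Spearman, bootstrap CIs, optional
permutation p-values) between trait anxiety and relative model fit
(delta BIC) or the model-free markers.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import agents as ag
from . import fitting as ft
from . import markers as mk
from .models import ParamSet, simulate
from .schedule import CUE_REVERSAL, SessionSpec, assemble_schedule

BONFERRONI_SESSIONS = 3
DEFAULT_N_BOOT = 2000
DEFAULT_N_PERM = 5000


# ---------------------------------------------------------------------------
# Correlation utilities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrResult:
    method: str
    r: float
    ci_low: float
    ci_high: float
    n: int
    p_value: float | None = None
    p_permutation: float | None = None
    note: str = ""

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("method", "r", "ci_low", "ci_high", "n", "p_value",
                 "p_permutation", "note")}


def _corr(x: np.ndarray, y: np.ndarray, method: str) -> tuple[float, float]:
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)


def correlate(x, y, method: str = "pearson", n_boot: int = DEFAULT_N_BOOT,
              rng: np.random.Generator | None = None,
              n_perm: int = 0) -> CorrResult:
    """Correlation with a percentile bootstrap CI over case resampling and
    an optional permutation p-value.

    Pairs with non-finite entries are dropped; fewer than 4 complete pairs
    or zero variance yield a NaN result flagged in ``note``.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 4:
        return CorrResult(method, math.nan, math.nan, math.nan, n,
                          note="fewer than 4 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrResult(method, math.nan, math.nan, math.nan, n,
                          note="zero variance")

    r, p = _corr(x, y, method)
    boot = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        xb, yb = x[idx], y[idx]
        if np.ptp(xb) == 0 or np.ptp(yb) == 0:
            boot[i] = np.nan
            continue
        boot[i] = _corr(xb, yb, method)[0]
    lo, hi = np.nanpercentile(boot, [2.5, 97.5])

    p_perm = None
    if n_perm > 0:
        count = 0
        for _ in range(n_perm):
            rp = _corr(x, rng.permutation(y), method)[0]
            if abs(rp) >= abs(r):
                count += 1
        p_perm = (count + 1) / (n_perm + 1)
    return CorrResult(method, r, float(lo), float(hi), n, p_value=p,
                      p_permutation=p_perm)


def required_n_correlation(r: float, power: float = 0.8,
                           alpha_two_tailed: float = 0.05) -> int:
    """Smallest sample size detecting a correlation of magnitude ``r`` at
    the given power, under the Fisher z approximation:
    n = ceil(((z_{1-alpha/2} + z_power) / atanh(r))^2 + 3).
    """
    if not 0 < r < 1:
        raise ValueError("effect size r must be in (0, 1)")
    if not 0 < power < 1 or not 0 < alpha_two_tailed < 1:
        raise ValueError("power and alpha must be in (0, 1)")
    z_a = stats.norm.ppf(1.0 - alpha_two_tailed / 2.0)
    z_b = stats.norm.ppf(power)
    return int(math.ceil(((z_a + z_b) / math.atanh(r)) ** 2 + 3.0))


# ---------------------------------------------------------------------------
# Model and parameter recovery
# ---------------------------------------------------------------------------

#: Default generator summaries (mean, sd) per parameter, per model, used to
#: draw ground-truth parameters for recovery runs; means are the cohort
#: defaults with moderate between-agent spread.
DEFAULT_PARAM_SUMMARY = {
    "1state": {"tau_plus": (1.1, 0.25), "tau_minus": (0.7, 0.2),
               "lam": (0.95, 0.02), "a0": (2.0, 0.8), "b0": (2.0, 0.8)},
    "nstate": {"tau_plus": (1.1, 0.25), "tau_minus": (0.7, 0.2),
               "lam": (0.95, 0.02), "a0": (2.0, 0.8), "b0": (2.0, 0.8),
               "eta": (2.5, 0.6)},
}

_PARAM_RANGES = {"tau_plus": (0.05, 2.0), "tau_minus": (0.05, 2.0),
                 "lam": (0.8, 0.999), "a0": (1.0, 10.0), "b0": (1.0, 10.0),
                 "eta": (0.3, 8.0)}


def draw_params(model: str, rng: np.random.Generator,
                summary: dict | None = None) -> ParamSet:
    """Draw a ground-truth parameter set from per-parameter normal
    summaries, truncated to sensible ranges."""
    if summary is None:
        summary = DEFAULT_PARAM_SUMMARY[model]
    values = {}
    for name, (mean, sd) in summary.items():
        lo, hi = _PARAM_RANGES[name]
        values[name] = float(np.clip(rng.normal(mean, sd), lo, hi))
    if model == "1state":
        values.pop("eta", None)
    return ParamSet(**values)


@dataclass
class RecoveryReport:
    confusion: pd.DataFrame  # rows: generator, cols: winner, counts
    param_corr: dict[str, float]
    n_agents: int
    details: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def accuracy(self) -> dict[str, float]:
        acc = {}
        for gen in self.confusion.index:
            row = self.confusion.loc[gen]
            acc[gen] = float(row.get(gen, 0)) / float(row.sum())
        return acc


def model_recovery(param_summary: dict | None = None,
                   session: str = "90/10", experiment_style: str = "III",
                   n_agents: int = 30, noise_kappa: float = 200.0,
                   n_restarts: int = 15,
                   rng: np.random.Generator | None = None) -> RecoveryReport:
    """Simulate agents from each generator model, fit both candidates to
    every dataset, and tabulate which model BIC selects.

    Also reports truth-vs-estimate Pearson correlations for parameters of
    the matched fit (fit of the generating model).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    rows = []
    for gen_model, strategy in (("1state", ag.STRATEGY_GRADUAL),
                                ("nstate", ag.STRATEGY_SWITCHING)):
        summary = None if param_summary is None else param_summary[gen_model]
        for i in range(n_agents):
            truth = draw_params(gen_model, rng, summary)
            spec = SessionSpec.from_style(session, experiment_style,
                                          seed=int(rng.integers(2**31)))
            sched = assemble_schedule(spec)
            agent = ag.AgentSpec(agent_id=f"{gen_model}-{i:03d}",
                                 strategy=strategy, params=truth,
                                 noise_kappa=noise_kappa,
                                 seed=int(rng.integers(2**31)))
            data = ag.simulate_agent(agent, sched)
            rev = data[data["cue"] == CUE_REVERSAL]
            outcomes = rev["outcome"].to_numpy()
            ratings = rev["rating"].to_numpy()
            fit1 = ft.fit_model("1state", outcomes, ratings,
                                n_restarts=n_restarts, rng=rng,
                                keep_trace=False)
            fitn = ft.fit_model("nstate", outcomes, ratings,
                                n_restarts=n_restarts, rng=rng,
                                keep_trace=False)
            comp = ft.compare_models(fit1, fitn)
            matched = fit1 if gen_model == "1state" else fitn
            row = dict(generator=gen_model, agent=agent.agent_id,
                       winner=comp.winner, delta_bic=comp.delta_bic)
            for name in ("tau_plus", "tau_minus", "lam", "a0", "b0", "eta"):
                tv = getattr(truth, name)
                fv = getattr(matched.params, name)
                row[f"true_{name}"] = np.nan if tv is None else tv
                row[f"fit_{name}"] = np.nan if fv is None else fv
            rows.append(row)
    details = pd.DataFrame(rows)
    confusion = (details.groupby("generator")["winner"].value_counts()
                 .unstack(fill_value=0)
                 .reindex(index=["1state", "nstate"],
                          columns=["1state", "nstate"], fill_value=0))
    param_corr = {}
    for name in ("tau_plus", "tau_minus", "lam"):
        t = details[f"true_{name}"].to_numpy(dtype=float)
        e = details[f"fit_{name}"].to_numpy(dtype=float)
        keep = np.isfinite(t) & np.isfinite(e)
        if keep.sum() >= 4 and np.ptp(t[keep]) > 0:
            param_corr[name] = float(stats.pearsonr(t[keep], e[keep]).statistic)
        else:
            param_corr[name] = math.nan
    return RecoveryReport(confusion=confusion, param_corr=param_corr,
                          n_agents=n_agents, details=details)


def block_outcome_stream(n_trials: int, p_high: float = 0.9,
                         block_len: int = 20, start_high: bool = False,
                         rng: np.random.Generator | None = None) -> np.ndarray:
    """A single-cue outcome stream alternating high/low Bernoulli blocks;
    convenient for long parameter-recovery runs where only the reversal
    cue's stream matters."""
    if rng is None:
        rng = np.random.default_rng(0)
    out = np.empty(n_trials, dtype=int)
    high = start_high
    for start in range(0, n_trials, block_len):
        p = p_high if high else 1.0 - p_high
        stop = min(start + block_len, n_trials)
        out[start:stop] = (rng.random(stop - start) < p).astype(int)
        high = not high
    return out


def parameter_recovery(n_agents: int = 40, n_trials: int = 300,
                       noise_kappa: float = 200.0, n_restarts: int = 15,
                       rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate 1-state agents on long block-reversal streams, refit, and
    return truth/estimate pairs per agent for the free parameters."""
    if rng is None:
        rng = np.random.default_rng(0)
    rows = []
    for i in range(n_agents):
        truth = draw_params("1state", rng)
        outcomes = block_outcome_stream(n_trials, rng=rng)
        trace = simulate("1state", truth, outcomes)
        ratings = ag.mode_beta_rating(trace.p_hat, noise_kappa, rng)
        fit = ft.fit_model("1state", outcomes, ratings,
                           n_restarts=n_restarts, rng=rng, keep_trace=False)
        row = {"agent": i}
        for name in ("tau_plus", "tau_minus", "lam", "a0", "b0"):
            row[f"true_{name}"] = getattr(truth, name)
            row[f"fit_{name}"] = getattr(fit.params, name)
        rows.append(row)
    return pd.DataFrame(rows)


def recovery_correlations(pairs: pd.DataFrame) -> dict[str, float]:
    """Truth-vs-estimate Pearson correlations per parameter, plus the log
    step-size ratio log(tau+/tau-).

    The ratio is reported because it is the cleanly identified quantity
    under low-noise ratings: the beta likelihood rewards beliefs as tight
    as the evidence cap allows, which slides the raw step-size *scale*
    toward its bound while preserving the shock/no-shock asymmetry.
    """
    out = {}
    for name in ("tau_plus", "tau_minus", "lam", "a0", "b0"):
        if f"true_{name}" in pairs:
            out[name] = float(stats.pearsonr(pairs[f"true_{name}"],
                                             pairs[f"fit_{name}"]).statistic)
    if "true_tau_plus" in pairs:
        lt = np.log(pairs["true_tau_plus"].clip(lower=1e-3)
                    / pairs["true_tau_minus"].clip(lower=1e-3))
        lf = np.log(pairs["fit_tau_plus"].clip(lower=1e-3)
                    / pairs["fit_tau_minus"].clip(lower=1e-3))
        out["log_tau_ratio"] = float(stats.pearsonr(lt, lf).statistic)
    return out


# ---------------------------------------------------------------------------
# Split-half out-of-sample check
# ---------------------------------------------------------------------------

def split_half_check(cohort: pd.DataFrame, n_restarts: int = 15,
                     rng: np.random.Generator | None = None,
                     config: mk.MarkerConfig = mk.MarkerConfig()) -> dict:
    """Fit models on the first half of each session and relate the
    resulting relative fit (delta BIC) to markers computed on the held-out
    second half.

    Sessions are split at the phase boundary nearest the midpoint; sessions
    without at least two phases per half are flagged and skipped.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    rows = []
    skipped = []
    for (agent_id, session), grp in cohort.groupby(["agent_id", "session"],
                                                   sort=True):
        phases = sorted(grp["phase_idx"].unique())
        if len(phases) < 4:
            skipped.append((agent_id, session, "fewer than 4 phases"))
            continue
        mid_trial = grp["trial"].median()
        bounds = grp.groupby("phase_idx")["trial"].min()
        candidates = [p for p in phases[2:-1]]
        if not candidates:
            skipped.append((agent_id, session, "no admissible split"))
            continue
        split_phase = min(candidates, key=lambda p: abs(bounds[p] - mid_trial))
        first = grp[grp["phase_idx"] < split_phase]
        second = grp[grp["phase_idx"] >= split_phase]

        rev = first[first["cue"] == CUE_REVERSAL]
        fit1 = ft.fit_model("1state", rev["outcome"].to_numpy(),
                            rev["rating"].to_numpy(), n_restarts=n_restarts,
                            rng=rng, keep_trace=False)
        fitn = ft.fit_model("nstate", rev["outcome"].to_numpy(),
                            rev["rating"].to_numpy(), n_restarts=n_restarts,
                            rng=rng, keep_trace=False)
        comp = ft.compare_models(fit1, fitn)
        m = mk.session_markers(second, config)
        rows.append(dict(agent_id=agent_id, session=session,
                         delta_bic_first=comp.delta_bic,
                         abs_slope_second=m["abs_slope"],
                         lr_diff_second=m["lr_diff"]))
    table = pd.DataFrame(rows)
    result = {"table": table, "skipped": skipped}
    if len(table) >= 4:
        result["corr_abs_slope"] = correlate(
            table["delta_bic_first"], table["abs_slope_second"],
            method="spearman", rng=rng)
        result["corr_lr_diff"] = correlate(
            table["delta_bic_first"], table["lr_diff_second"],
            method="spearman", rng=rng)
    return result


def classification_consistency_chance(winner_frac: pd.DataFrame) -> float:
    """Chance level for one agent being assigned the same winning model in
    every session, from the empirical per-session winner fractions:
    sum over models of the product across sessions of that model's share."""
    chance = 0.0
    for model in winner_frac.columns:
        chance += float(np.prod(winner_frac[model].to_numpy()))
    return chance


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

DEFAULT_CONFIG = {
    "seed": 0,
    "cohort": {
        "n_agents": 12,
        "sessions": [{"label": "75/25", "experiment_style": "III",
                      "n_phases": 7}],
        "ta_mean": 39.0,
        "ta_sd": 10.0,
        "effect_map": {"intercept": 0.0, "slope": 0.0},
        "noise_kappa": 200.0,
    },
    "fitting": {"n_restarts": 15},
    "markers": {"cutoff": 5},
    "analysis": {"n_boot": 500, "n_perm": 0},
    "recovery": {"enabled": False, "n_agents": 8},
    "figures": True,
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and \
            isinstance(base.get(k), dict) else v
    return out


def load_config(source) -> dict:
    """Accept a dict, a YAML path, or None (defaults)."""
    if source is None:
        return dict(DEFAULT_CONFIG)
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            source = yaml.safe_load(fh)
    return _merge(DEFAULT_CONFIG, source)


def _cohort_spec_from_config(cfg: dict) -> ag.CohortSpec:
    c = cfg["cohort"]
    sessions = tuple(
        SessionSpec.from_style(s["label"], s.get("experiment_style", "III"),
                               n_phases=s.get("n_phases", 7),
                               start_high=s.get("start_high", False))
        for s in c["sessions"])
    em = ag.EffectMap(
        intercept=c["effect_map"].get("intercept", 0.0),
        slope=c["effect_map"].get("slope", 0.0),
        sessions=(tuple(c["effect_map"]["sessions"])
                  if c["effect_map"].get("sessions") else None))
    return ag.CohortSpec(n_agents=c["n_agents"], sessions=sessions,
                         ta_mean=c.get("ta_mean", 39.0),
                         ta_sd=c.get("ta_sd", 10.0),
                         effect_map=em,
                         noise_kappa=c.get("noise_kappa", 200.0),
                         seed=cfg["seed"])


def run_full_analysis(config=None, out_dir=None) -> dict:
    """Generate a synthetic cohort, fit both models, compute markers,
    correlate trait anxiety with relative fit and markers, and (optionally)
    run a model-recovery study.  Writes cohort.csv, truth.csv, fits.csv,
    markers.csv, cohort_results.json and diagnostic figures to ``out_dir``;
    byte-identical outputs under a fixed config.
    """
    cfg = load_config(config)
    seed = int(cfg["seed"])
    cohort_spec = _cohort_spec_from_config(cfg)
    cohort, truth = ag.simulate_cohort(cohort_spec)

    fit_rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    fits = ft.fit_cohort(cohort, n_restarts=cfg["fitting"]["n_restarts"],
                         rng=fit_rng)
    markers = mk.compute_markers(
        cohort, mk.MarkerConfig(cutoff=cfg["markers"]["cutoff"]))

    per_agent = (fits[fits["model"] == "1state"]
                 [["agent_id", "session", "delta_bic", "winner"]]
                 .merge(markers, on=["agent_id", "session"]))

    ana_rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    n_boot = cfg["analysis"]["n_boot"]
    n_perm = cfg["analysis"]["n_perm"]
    results: dict = {"seed": seed, "n_agents": cohort_spec.n_agents,
                     "sessions": [s.label for s in cohort_spec.sessions],
                     "correlations": {}, "winner_fractions": {}}
    for session, grp in per_agent.groupby("session"):
        sess_res = {}
        for var in ("delta_bic", "abs_slope", "lr_diff"):
            for method in ("pearson", "spearman"):
                cr = correlate(grp["ta_score"], grp[var], method=method,
                               n_boot=n_boot, rng=ana_rng, n_perm=n_perm)
                d = cr.to_dict()
                if d.get("p_value") is not None:
                    d["p_bonferroni"] = min(1.0, d["p_value"]
                                            * BONFERRONI_SESSIONS)
                sess_res[f"ta_vs_{var}_{method}"] = d
        results["correlations"][session] = sess_res
        frac = grp["winner"].value_counts(normalize=True)
        results["winner_fractions"][session] = {
            m: float(frac.get(m, 0.0)) for m in ("1state", "nstate")}

    if len(results["winner_fractions"]) > 1:
        wf = pd.DataFrame(results["winner_fractions"]).T
        results["classification_consistency_chance"] = \
            classification_consistency_chance(wf)

    if cfg["recovery"]["enabled"]:
        rec = model_recovery(n_agents=cfg["recovery"]["n_agents"],
                             n_restarts=cfg["fitting"]["n_restarts"],
                             rng=np.random.default_rng(
                                 np.random.SeedSequence([seed, 3])))
        results["recovery"] = {
            "accuracy": rec.accuracy,
            "confusion": rec.confusion.to_dict(),
            "param_corr": rec.param_corr,
        }

    bundle = {"cohort": cohort, "truth": truth, "fits": fits,
              "markers": markers, "per_agent": per_agent, "results": results}

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        ag.cohort_to_csv(cohort, out / "cohort.csv")
        truth.to_csv(out / "truth.csv", index=False, float_format="%.6g")
        fits.to_csv(out / "fits.csv", index=False, float_format="%.6g")
        markers.to_csv(out / "markers.csv", index=False, float_format="%.6g")
        with open(out / "cohort_results.json", "w") as fh:
            json.dump(results, fh, indent=2, sort_keys=True, default=float)
        if cfg.get("figures", True):
            _diagnostic_figures(cohort, per_agent, out)
    return bundle


def _diagnostic_figures(cohort: pd.DataFrame, per_agent: pd.DataFrame,
                        out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    one = cohort[(cohort["agent_id"] == cohort["agent_id"].iloc[0])
                 & (cohort["session"] == cohort["session"].iloc[0])]
    rev = one[one["cue"] == CUE_REVERSAL]
    ax.plot(rev["trial"], rev["rating"], ".-", label="rating", alpha=0.7)
    ax.step(rev["trial"], rev["p_true"], where="post", label="p(shock)",
            color="k", lw=1)
    ax.set(xlabel="trial", ylabel="p(shock)", title="example reversal-cue run")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "rating_timecourse.png", dpi=100)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(per_agent["ta_score"], per_agent["delta_bic"], alpha=0.7)
    ax.set(xlabel="trait anxiety", ylabel="BIC(1-state) - BIC(n-state)")
    fig.tight_layout()
    fig.savefig(out / "delta_bic_vs_ta.png", dpi=100)
    plt.close(fig)
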