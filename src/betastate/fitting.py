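"""Maximum-likelihood fitting of the beta learners to rating sequences.

The models' predictions are full beta distributions, so ratings are scored
directly with a beta likelihood: at trial t the contribution is
log BetaPDF(rating_t; a_t, b_t) where (a_t, b_t) is the active state's
belief before outcome t.  Fitting minimizes the negative log likelihood
with a bounded derivative-free local search (Nelder-Mead) restarted from
many random initializations; the restart with the lowest NLL wins.  Model
comparison uses BIC = k * ln(n) + 2 * NLL, so the n-state model's extra
threshold parameter must buy a genuine likelihood gain to win.

Decay lambda and threshold eta are optimized in log space; ratings are
clipped to [0.005, 0.995] before scoring (slider responses of exactly 0%
or 100% otherwise have unbounded density).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import betaln

from .models import EPS_PROB, ModelTrace, ParamSet, crp_difficulty_table, simulate

DEFAULT_N_RESTARTS = 45
_NM_OPTIONS = dict(xatol=1e-3, fatol=1e-3, maxfev=300)


@dataclass(frozen=True)
class Bounds:
    """Per-parameter (lower, upper, transform) boxes for the optimizer.

    ``log``-transformed parameters are searched log-uniformly.  The decay
    bound stays away from 0 (a lambda below ~0.2 erases all evidence within
    a couple of trials) and eta spans never-switch to hair-trigger regimes.
    """

    spec: dict[str, tuple[float, float, str]] = field(default_factory=lambda: {
        "tau_plus": (0.0, 2.0, "identity"),
        "tau_minus": (0.0, 2.0, "identity"),
        "lam": (0.2, 1.0 - 1e-6, "log"),
        "a0": (1.0, 10.0, "identity"),
        "b0": (1.0, 10.0, "identity"),
        "eta": (0.05, 20.0, "log"),
    })

    def names(self, model: str) -> list[str]:
        base = ["tau_plus", "tau_minus", "lam", "a0", "b0"]
        return base + ["eta"] if model == "nstate" else base

    def to_opt(self, name: str, value: float) -> float:
        lo, hi, tr = self.spec[name]
        value = min(max(value, lo), hi)
        return math.log(value) if tr == "log" else value

    def from_opt(self, name: str, z: float) -> float:
        lo, hi, tr = self.spec[name]
        value = math.exp(z) if tr == "log" else z
        return min(max(value, lo), hi)

    def opt_box(self, model: str) -> list[tuple[float, float]]:
        return [(self.to_opt(n, self.spec[n][0]), self.to_opt(n, self.spec[n][1]))
                for n in self.names(model)]


@dataclass
class FitResult:
    model: str
    params: ParamSet
    nll: float
    bic: float
    n_trials: int
    n_params: int
    n_restarts: int
    best_restart_idx: int
    restart_nlls: np.ndarray
    trace: ModelTrace | None = None

    def as_row(self) -> dict:
        p = self.params
        return dict(model=self.model, nll=self.nll, bic=self.bic,
                    n_trials=self.n_trials, n_restarts=self.n_restarts,
                    tau_plus=p.tau_plus, tau_minus=p.tau_minus, lam=p.lam,
                    a0=p.a0, b0=p.b0,
                    eta=p.eta if p.eta is not None else np.nan)


def clip_ratings(ratings: np.ndarray) -> np.ndarray:
    return np.clip(ratings, EPS_PROB, 1.0 - EPS_PROB)


def negloglik(model: str, p: ParamSet, outcomes, ratings,
              q_table: tuple[float, ...] | None = None) -> float:
    """Negative log beta likelihood of the ratings under a model's forward
    trace; missing (NaN) ratings are skipped, an empty rating vector scores
    0."""
    ratings = np.asarray(ratings, dtype=float)
    mask = np.isfinite(ratings)
    if not mask.any():
        return 0.0
    trace = simulate(model, p, outcomes, q_table=q_table)
    r = clip_ratings(ratings[mask])
    a = trace.a_pre[mask]
    b = trace.b_pre[mask]
    ll = (a - 1.0) * np.log(r) + (b - 1.0) * np.log1p(-r) - betaln(a, b)
    return float(-ll.sum())


def bic(nll: float, n_params: int, n_trials: int) -> float:
    """Bayesian information criterion: k * ln(n) + 2 * NLL."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    return n_params * math.log(n_trials) + 2.0 * nll


def _params_from_vector(model: str, names: list[str], z: np.ndarray,
                        bounds: Bounds) -> ParamSet:
    values = {n: bounds.from_opt(n, float(v)) for n, v in zip(names, z)}
    if model == "1state":
        values["eta"] = None
    return ParamSet(**values)


def fit_model(model: str, outcomes, ratings, bounds: Bounds | None = None,
              n_restarts: int = DEFAULT_N_RESTARTS,
              rng: np.random.Generator | None = None,
              keep_trace: bool = True) -> FitResult:
    """Multi-start maximum-likelihood fit of one model to one rating
    sequence.

    Restart initializations are uniform (log-uniform for transformed
    parameters) within bounds; the returned fit is the restart with minimal
    NLL and all restart NLLs are kept as convergence diagnostics.
    Deterministic under a seeded ``rng``.
    """
    if bounds is None:
        bounds = Bounds()
    if rng is None:
        rng = np.random.default_rng(0)
    outcomes = np.asarray(outcomes, dtype=int)
    ratings = np.asarray(ratings, dtype=float)
    n_rated = int(np.isfinite(ratings).sum())
    q_table = crp_difficulty_table() if model == "nstate" else None

    names = bounds.names(model)
    box = bounds.opt_box(model)
    lo = np.array([b[0] for b in box])
    hi = np.array([b[1] for b in box])

    def objective(z: np.ndarray) -> float:
        p = _params_from_vector(model, names, z, bounds)
        return negloglik(model, p, outcomes, ratings, q_table)

    restart_nlls = np.full(n_restarts, np.inf)
    best_z = None
    failures = []
    for i in range(n_restarts):
        z0 = lo + rng.random(len(names)) * (hi - lo)
        try:
            res = minimize(objective, z0, method="Nelder-Mead",
                           bounds=box, options=_NM_OPTIONS)
        except Exception as exc:  # pragma: no cover - diagnostic path
            failures.append((i, repr(exc)))
            continue
        restart_nlls[i] = res.fun
        if best_z is None or res.fun <= restart_nlls[:i].min(initial=np.inf):
            best_z = res.x
    if best_z is None:
        raise RuntimeError(f"all {n_restarts} restarts failed: {failures}")

    best_idx = int(np.argmin(restart_nlls))
    best_params = _params_from_vector(model, names, best_z, bounds)
    best_nll = float(restart_nlls[best_idx])
    trace = simulate(model, best_params, outcomes, q_table=q_table) \
        if keep_trace else None
    return FitResult(model=model, params=best_params, nll=best_nll,
                     bic=bic(best_nll, len(names), max(n_rated, 1)),
                     n_trials=n_rated, n_params=len(names),
                     n_restarts=n_restarts, best_restart_idx=best_idx,
                     restart_nlls=restart_nlls, trace=trace)


@dataclass(frozen=True)
class ModelComparison:
    delta_bic: float  # BIC(1-state) - BIC(n-state); positive favors n-state
    winner: str


def compare_models(fit1: FitResult, fitn: FitResult) -> ModelComparison:
    """BIC comparison; ties go to the simpler 1-state model (parsimony)."""
    if fit1.n_trials != fitn.n_trials:
        raise ValueError(
            f"fits cover different data: {fit1.n_trials} vs {fitn.n_trials} trials")
    delta = fit1.bic - fitn.bic
    return ModelComparison(delta_bic=delta,
                           winner="nstate" if delta > 0 else "1state")


def fit_cohort(cohort: pd.DataFrame, models: tuple[str, ...] = ("1state", "nstate"),
               cue: str = "reversal", n_restarts: int = DEFAULT_N_RESTARTS,
               rng: np.random.Generator | None = None,
               bounds: Bounds | None = None) -> pd.DataFrame:
    """Fit each model per agent x session on one cue's rated trials.

    Returns one row per agent x session x model (columns as
    ``FitResult.as_row``) plus, when both models are fitted, ``delta_bic``
    and ``winner`` columns repeated on both rows.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    rows = []
    for (agent_id, session), grp in cohort.groupby(["agent_id", "session"],
                                                   sort=True):
        sub = grp[grp["cue"] == cue]
        outcomes = sub["outcome"].to_numpy()
        ratings = sub["rating"].to_numpy()
        fits = {}
        for model in models:
            fit = fit_model(model, outcomes, ratings, bounds=bounds,
                            n_restarts=n_restarts, rng=rng, keep_trace=False)
            fits[model] = fit
        comp = (compare_models(fits["1state"], fits["nstate"])
                if {"1state", "nstate"} <= set(fits) else None)
        for model, fit in fits.items():
            row = dict(agent_id=agent_id, session=session, **fit.as_row())
            if comp is not None:
                row["delta_bic"] = comp.delta_bic
                row["winner"] = comp.winner
            rows.append(row)
    return pd.DataFrame(rows)
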