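"""Competitive fitness: selection coefficients and power-law trajectories.

A pairwise competition between an evolved (E) and ancestral (A) strain over
T generations yields the selection coefficient s from the change in the
log-odds of the evolved allele:

    ln(1 + s) = ln[ (f_E,t / f_A,t) / (f_E,0 / f_A,0) ] / T,    w_E = 1 + s

with T = log2(dilution factor) generations per growth cycle (log2 100 ≈ 6.64
for a 100-fold dilution).  Natural logarithms are used throughout; the
definition depends only on odds ratios, so counts and frequencies give the
same answer.

Mean fitness along an asexual adaptation trajectory in a constant
environment is modeled as an offset power law

    w̄(t) = (a·t + 1)^b

(w̄(0) = 1 by construction), fitted by Levenberg–Marquardt nonlinear least
squares.  Inverting the fitness definition predicts the post-competition
frequency expected for any initial frequency:

    f_E,t = r / (1 + r),   r = ŵ^T · f_E,0 / (1 − f_E,0).

At b = 0 (or a = 0) the model is flat and the other parameter is
unidentifiable; fits flag this rather than resolving it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "CompetitionSample",
    "PowerLawFit",
    "selection_coefficient",
    "generations_elapsed",
    "power_law_fitness",
    "fit_power_law",
    "predict_post_frequency",
    "fitness_trajectory",
]


@dataclass(frozen=True)
class CompetitionSample:
    """Pre/post frequencies of the evolved strain in one competition."""

    f_E_0: float
    f_E_t: float
    T: float
    time_generations: float | None = None
    replicate: int | None = None

    @property
    def f_A_0(self) -> float:
        return 1.0 - self.f_E_0

    @property
    def f_A_t(self) -> float:
        return 1.0 - self.f_E_t


def _check_open_unit(value: float, name: str) -> None:
    if not 0.0 < value < 1.0:
        raise ValueError(f"{name} = {value} is outside (0, 1); fitness undefined")


def selection_coefficient(f_E_0: float, f_E_t: float, T: float) -> tuple[float, float]:
    """Selection coefficient s and relative fitness w_E = 1 + s.

    Defined through the per-generation change in log-odds of the evolved
    allele (natural log).  Frequencies must lie strictly inside (0, 1).
    """
    _check_open_unit(f_E_0, "f_E_0")
    _check_open_unit(f_E_t, "f_E_t")
    if T <= 0:
        raise ValueError(f"T = {T} must be positive")
    log_w = (math.log((f_E_t / (1.0 - f_E_t)) / (f_E_0 / (1.0 - f_E_0)))) / T
    w = math.exp(log_w)
    return w - 1.0, w


def generations_elapsed(dilution_factor: float) -> float:
    """Generations per competition cycle: log2 of the dilution factor."""
    if dilution_factor <= 1:
        raise ValueError(f"dilution factor {dilution_factor} must exceed 1")
    return math.log2(dilution_factor)


def power_law_fitness(t, a: float, b: float):
    """Offset power law w̄(t) = (a·t + 1)^b."""
    return np.power(a * np.asarray(t, dtype=float) + 1.0, b)


@dataclass(frozen=True)
class PowerLawFit:
    """Fitted (a, b) with residual sum of squares and standard errors."""

    a: float
    b: float
    rss: float
    converged: bool
    se_a: float
    se_b: float
    n: int

    @property
    def identifiable(self) -> bool:
        """False near the flat ridge a = 0 / b = 0 where (a, b) trade off."""
        return not (math.isclose(self.a, 0.0, abs_tol=1e-12)
                    or math.isclose(self.b, 0.0, abs_tol=1e-12)
                    or not np.isfinite(self.se_a) or not np.isfinite(self.se_b))


_RESTART_GRID = [(a0, b0)
                 for a0 in (1e-4, 1e-3, 1e-2, 1e-1)
                 for b0 in (0.05, 0.1, 0.3, 0.5, 1.0)]


def fit_power_law(times, fitnesses, initial_guess: tuple[float, float] = (0.01, 0.1),
                  xtol: float = 1e-12, ftol: float = 1e-12,
                  gtol: float = 1e-12) -> PowerLawFit:
    """Levenberg–Marquardt fit of w̄ = (a·t + 1)^b.

    Minimizes Σ (w̄ᵢ − (a·tᵢ + 1)^b)².  Falls back to a small grid of
    restarts when the default start fails to converge; non-convergence is
    flagged but parameters and residuals are still reported.
    """
    t = np.asarray(times, dtype=float)
    w = np.asarray(fitnesses, dtype=float)
    if t.shape != w.shape or t.ndim != 1:
        raise ValueError("times and fitnesses must be 1-D and equal length")
    if np.unique(t).size < 2:
        raise ValueError("need at least two distinct time points")
    if np.any(w <= 0):
        raise ValueError("fitness values must be positive")

    tmax = t.max() if t.max() > 0 else 1.0

    def residuals(params):
        a, b = params
        base = a * t + 1.0
        if np.any(base <= 0):
            # outside the model domain: steer back with a large smooth penalty
            return 1e6 * (1.0 + np.abs(base.min())) * np.ones_like(w)
        return np.power(base, b) - w

    best = None
    for guess in [tuple(initial_guess)] + _RESTART_GRID:
        # keep a*t+1 > 0 at the start
        if guess[0] * tmax <= -1:
            continue
        sol = least_squares(residuals, x0=guess, method="lm",
                            xtol=xtol, ftol=ftol, gtol=gtol, max_nfev=10000)
        if best is None or sol.cost < best.cost:
            best = sol
        if sol.success:
            break
    res = best.fun
    rss = float(res @ res)
    n, p = t.size, 2
    se_a = se_b = float("nan")
    if n > p:
        try:
            jtj = best.jac.T @ best.jac
            cov = np.linalg.inv(jtj) * rss / (n - p)
            se_a, se_b = (float(x) for x in np.sqrt(np.maximum(np.diag(cov), 0.0)))
        except np.linalg.LinAlgError:
            pass
    return PowerLawFit(a=float(best.x[0]), b=float(best.x[1]), rss=rss,
                       converged=bool(best.success), se_a=se_a, se_b=se_b, n=n)


def predict_post_frequency(w: float, f_E_0: float, T: float) -> float:
    """Expected post-competition frequency under relative fitness ``w``.

    Exact inverse of :func:`selection_coefficient`: neutrality (w = 1) is a
    fixed point, and the result is strictly increasing in both ``w`` and
    ``f_E_0``.
    """
    if w <= 0:
        raise ValueError(f"w = {w} must be positive")
    _check_open_unit(f_E_0, "f_E_0")
    if T <= 0:
        raise ValueError(f"T = {T} must be positive")
    r = (w ** T) * f_E_0 / (1.0 - f_E_0)
    return r / (1.0 + r)


def fitness_trajectory(competitions: pd.DataFrame,
                       fit: bool = True) -> dict:
    """Full trajectory analysis of a competition table.

    ``competitions`` needs columns ``time``, ``replicate``, ``f_E_0``,
    ``f_E_t``, ``T``.  Returns per-sample s and w_E, per-time mean fitness
    with its standard error (the basis for confidence bands), and optionally
    the power-law fit to the per-time means.
    """
    required = {"time", "replicate", "f_E_0", "f_E_t", "T"}
    missing = required - set(competitions.columns)
    if missing:
        raise ValueError(f"competition table lacks column(s) {sorted(missing)}")
    rows = []
    for _, rec in competitions.iterrows():
        s, w = selection_coefficient(rec["f_E_0"], rec["f_E_t"], rec["T"])
        rows.append((rec["time"], rec["replicate"], rec["f_E_0"], rec["f_E_t"],
                     rec["T"], s, w))
    per_sample = pd.DataFrame(rows, columns=["time", "replicate", "f_E_0",
                                             "f_E_t", "T", "s", "w_E"])
    grouped = per_sample.groupby("time")["w_E"]
    per_time = grouped.agg(mean_w="mean", sd_w="std", n="count").reset_index()
    per_time["sem_w"] = per_time["sd_w"] / np.sqrt(per_time["n"])
    result = {"per_sample": per_sample, "per_time": per_time, "fit": None}
    if fit and per_time["time"].nunique() >= 2:
        result["fit"] = fit_power_law(per_time["time"].to_numpy(),
                                      per_time["mean_w"].to_numpy())
    return result


def read_competitions_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
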