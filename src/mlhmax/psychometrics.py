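"""Psychometric analysis: cumulative-Gaussian fits, PSE, JND, flat-line F-test.

Per-trial long/short decisions are aggregated into one point per signed
length difference (delta = top - bottom, pixels): the proportion classified
"long".  A cumulative Gaussian

    p(delta) = Phi((delta - mu) / sigma)

is fitted to the proportions by unweighted least squares.  The mean ``mu``
is the point of subjective equality (PSE): the length difference at which
the classifier responds "long" half the time, whose displacement from zero
measures illusory bias.  The just-noticeable difference (JND), the
precision measure, is the semi-interquartile range of the fitted Gaussian,
0.6745 x sigma.  Fits that do not beat a horizontal line at 50 % (chance)
in an extra-sum-of-squares F-test at alpha = 0.05 are discarded.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["JND_FACTOR", "aggregate", "CumulativeGaussianModel",
           "PsychometricResults", "fit_cumulative_gaussian", "flat_line_f_test",
           "summarize_condition", "ConditionSummary", "plot_fit"]

#: semi-interquartile range of a Gaussian per unit standard deviation
JND_FACTOR = 0.6745

#: multi-start initialization grid; ties broken by smallest sigma
MU_STARTS = (-40.0, -20.0, 0.0, 20.0, 40.0)
SIGMA_STARTS = (5.0, 15.0, 30.0)

ALPHA = 0.05


def aggregate(predictions: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-trial decisions into one psychometric point per delta.

    ``predictions`` needs columns ``delta`` (signed pixels) and
    ``predicted`` ("long"/"short").  Returns a frame with columns
    delta, n_trials, n_long, p_long, sorted by delta; counts are conserved.
    """
    if len(predictions) == 0:
        raise ValueError("no predictions to aggregate")
    df = predictions.copy()
    df["is_long"] = (df["predicted"] == "long").astype(int)
    g = df.groupby("delta", sort=True)["is_long"].agg(n_trials="count", n_long="sum")
    g = g.reset_index()
    g["p_long"] = g["n_long"] / g["n_trials"]
    return g


@dataclass
class PsychometricResults:
    """Fitted cumulative Gaussian and its diagnostics.

    ``pse`` is ``mu``; ``jnd`` equals ``JND_FACTOR * sigma``; ``accepted``
    is True iff the F-test rejects the flat 50 % line at alpha = 0.05.
    """

    mu: float
    sigma: float
    sse_full: float
    sse_flat: float
    n_points: int
    converged: bool
    model: "CumulativeGaussianModel" = field(repr=False, default=None)

    def __post_init__(self):
        self.f_stat, self.p_value, self.accepted = flat_line_f_test(
            self.sse_flat, self.sse_full, self.n_points)
        if not self.converged:
            self.accepted = False

    @property
    def pse(self) -> float:
        return self.mu

    @property
    def jnd(self) -> float:
        return JND_FACTOR * self.sigma

    def predict(self, delta) -> np.ndarray:
        return stats.norm.cdf((np.asarray(delta, float) - self.mu) / self.sigma)

    def summary(self) -> str:
        rows = [
            ("points (deltas)", f"{self.n_points:d}"),
            ("PSE (mu) [px]", f"{self.mu:.3f}"),
            ("sigma [px]", f"{self.sigma:.3f}"),
            (f"JND = {JND_FACTOR}*sigma [px]", f"{self.jnd:.3f}"),
            ("SSE full / flat", f"{self.sse_full:.5f} / {self.sse_flat:.5f}"),
            ("F vs flat 50% line", f"{self.f_stat:.3f} (p = {self.p_value:.4g})"),
            (f"accepted (p < {ALPHA})", str(self.accepted)),
        ]
        width = max(len(k) for k, _ in rows)
        lines = ["Cumulative Gaussian psychometric fit",
                 "------------------------------------"]
        lines += [f"{k:<{width}}  {v}" for k, v in rows]
        return "\n".join(lines)


class CumulativeGaussianModel:
    """Least-squares cumulative-Gaussian model of proportion-"long" data.

    Parameters
    ----------
    delta : array of signed length differences (pixels), one per point.
    p_long : proportions classified "long" at each delta.
    n_trials : optional trial counts (metadata only; the fit is unweighted,
        matching a plain least-squares procedure on proportions).
    """

    def __init__(self, delta, p_long, n_trials=None):
        self.delta = np.asarray(delta, dtype=float)
        self.p_long = np.asarray(p_long, dtype=float)
        if self.delta.ndim != 1 or self.delta.shape != self.p_long.shape:
            raise ValueError("delta and p_long must be equal-length 1-D arrays")
        if len(np.unique(self.delta)) < 3:
            raise ValueError("need at least 3 distinct deltas to fit 2 parameters")
        if np.any((self.p_long < 0) | (self.p_long > 1)):
            raise ValueError("proportions must lie in [0, 1]")
        self.n_trials = None if n_trials is None else np.asarray(n_trials, int)

    @classmethod
    def from_points(cls, points: pd.DataFrame) -> "CumulativeGaussianModel":
        return cls(points["delta"], points["p_long"],
                   points["n_trials"] if "n_trials" in points else None)

    @classmethod
    def from_predictions(cls, predictions: pd.DataFrame) -> "CumulativeGaussianModel":
        return cls.from_points(aggregate(predictions))

    def _residuals(self, params):
        mu, sigma = params
        return stats.norm.cdf((self.delta - mu) / sigma) - self.p_long

    def _jacobian(self, params):
        mu, sigma = params
        z = (self.delta - mu) / sigma
        phi = stats.norm.pdf(z)
        return np.column_stack([-phi / sigma, -phi * z / sigma])

    N_REFINED_STARTS = 5  # grid points actually refined, ranked by initial SSE

    def fit(self) -> PsychometricResults:
        """Multi-start least squares over (mu, sigma > 0); best SSE wins,
        ties broken by the smallest sigma.

        All grid starts are scored by their initial SSE; the most promising
        few are refined with a bounded trust-region solver.
        """
        grid = list(itertools.product(MU_STARTS, SIGMA_STARTS))
        initial = [(float(np.sum(self._residuals((m, s)) ** 2)), s, m) for m, s in grid]
        initial.sort()
        best = None
        for _, s0, mu0 in initial[:self.N_REFINED_STARTS]:
            try:
                sol = optimize.least_squares(
                    self._residuals, x0=[mu0, s0], jac=self._jacobian,
                    bounds=([-np.inf, 1e-6], [np.inf, np.inf]), max_nfev=200)
            except Exception:
                continue
            if not sol.success:
                continue
            sse = float(np.sum(sol.fun ** 2))
            cand = (sse, float(sol.x[1]), float(sol.x[0]))  # (sse, sigma, mu)
            if (best is None or cand[0] < best[0] - 1e-12
                    or (abs(cand[0] - best[0]) <= 1e-12 and cand[1] < best[1])):
                best = cand
        sse_flat = float(np.sum((self.p_long - 0.5) ** 2))
        if best is None:
            return PsychometricResults(np.nan, np.nan, np.inf, sse_flat,
                                       len(self.delta), converged=False, model=self)
        sse, sigma, mu = best
        return PsychometricResults(mu, sigma, sse, sse_flat, len(self.delta),
                                   converged=True, model=self)


def fit_cumulative_gaussian(points: pd.DataFrame) -> PsychometricResults:
    """Convenience wrapper: aggregate points frame -> fitted results."""
    return CumulativeGaussianModel.from_points(points).fit()


def flat_line_f_test(sse_flat: float, sse_full: float, n_points: int,
                     alpha: float = ALPHA):
    """Extra-sum-of-squares F-test of the 2-parameter fit against the fixed
    flat 50 % line (zero free parameters, so 2 extra df).

    Returns (f_stat, p_value, accepted); a perfect full fit (SSE = 0) is
    accepted by convention with an infinite F.
    """
    df_extra = 2
    df_full = n_points - 2
    if df_full <= 0:
        raise ValueError("need more points than full-model parameters")
    if sse_full == 0.0:
        return np.inf, 0.0, True
    f = ((sse_flat - sse_full) / df_extra) / (sse_full / df_full)
    p = float(stats.f.sf(f, df_extra, df_full)) if f >= 0 else 1.0
    return float(f), p, p < alpha


@dataclass
class ConditionSummary:
    """Per-condition PSE/JND over runs: mean +/- s.e.m. across accepted fits."""

    condition: dict
    pses: list
    jnds: list
    n_discarded: int

    @property
    def n_accepted(self) -> int:
        return len(self.pses)

    @property
    def pse_mean(self) -> float:
        return float(np.mean(self.pses)) if self.pses else np.nan

    @property
    def jnd_mean(self) -> float:
        return float(np.mean(self.jnds)) if self.jnds else np.nan

    @property
    def pse_sem(self) -> float:
        return (float(np.std(self.pses, ddof=1) / np.sqrt(len(self.pses)))
                if len(self.pses) > 1 else np.nan)

    @property
    def jnd_sem(self) -> float:
        return (float(np.std(self.jnds, ddof=1) / np.sqrt(len(self.jnds)))
                if len(self.jnds) > 1 else np.nan)

    @property
    def available(self) -> bool:
        return self.n_accepted > 0

    def as_row(self) -> dict:
        return {**self.condition, "pse_mean": self.pse_mean, "pse_sem": self.pse_sem,
                "jnd_mean": self.jnd_mean, "jnd_sem": self.jnd_sem,
                "n_accepted": self.n_accepted, "n_discarded": self.n_discarded}


def summarize_condition(fits, condition: dict | None = None) -> ConditionSummary:
    """Mean and s.e.m. of PSE and JND over the accepted per-run fits."""
    fits = list(fits)
    accepted = [f for f in fits if f.accepted]
    return ConditionSummary(condition or {},
                            [f.pse for f in accepted], [f.jnd for f in accepted],
                            n_discarded=len(fits) - len(accepted))


def plot_fit(res: PsychometricResults, ax=None):
    """Plot the data points, fitted curve, and PSE marker."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    m = res.model
    ax.plot(m.delta, m.p_long, "ko", label="data")
    xs = np.linspace(m.delta.min(), m.delta.max(), 200)
    ax.plot(xs, res.predict(xs), "b-", label="cumulative Gaussian")
    ax.axhline(0.5, color="gray", lw=0.5)
    ax.axvline(res.pse, color="r", ls="--", label=f"PSE = {res.pse:.1f} px")
    ax.set_xlabel("length difference top - bottom (px)")
    ax.set_ylabel('proportion classified "long"')
    ax.legend()
    return ax
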