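"""Model/Results interface for divergence-rate correction.

`DivergenceModel` wraps the binomial double-infection model around a set of
observed counts, in the style of a statistical modelling package: build the
model from counts or from a labelled-cell table, call :meth:`fit` to obtain
a :class:`DivergenceResults` carrying the corrected rate, its bootstrap
confidence interval, diagnostics and a text ``summary()``.  Forward
simulation and the observed-vs-true sensitivity curve hang off the model;
plotting hangs off both.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import inference, quantify
from .errors import InfeasibleRateError
from .inference import EfficiencyModel, MonteCarloRate


class DivergenceModel:
    """Binomial double-infection model for one group of counts.

    Parameters
    ----------
    n_double, n_total : int
        Double-labelled and total labelled premotor cells.
    efficiency : float
        Assumed per-jump transfer efficiency e (default 0.25, the upper
        bound suggested for the SAD-B19 strain; always an assumption, and
        echoed in every output).
    interference : float
        Interference rho; forward simulation only — the inversion has no
        closed form with interference, so it is excluded there.
    """

    def __init__(self, n_double: int, n_total: int,
                 efficiency: float = 0.25, interference: float = 0.0):
        if n_total <= 0:
            raise ValueError("n_total must be positive")
        if not (0 <= n_double <= n_total):
            raise ValueError("need 0 <= n_double <= n_total")
        self.n_double = int(n_double)
        self.n_total = int(n_total)
        self.efficiency_model = EfficiencyModel(e=efficiency, rho=interference)

    # -- constructors ----------------------------------------------------

    @classmethod
    def from_counts(cls, n_double: int, n_total: int,
                    efficiency: float = 0.25) -> "DivergenceModel":
        return cls(n_double, n_total, efficiency=efficiency)

    @classmethod
    def from_dataframe(cls, cells: pd.DataFrame,
                       colours: Sequence[str] = quantify.DEFAULT_COLOURS,
                       efficiency: float = 0.25,
                       sampling=None) -> "DivergenceModel":
        """Build from a labelled-cell table (pooled over all groups),
        applying the standard section subsampling and motoneuron
        exclusion."""
        summary = quantify.divergence_summary(
            cells.assign(_all="all"), group_by=["_all"],
            sampling=sampling, colours=colours)
        if summary.empty:
            raise ValueError("no labelled premotor cells in table")
        row = summary.iloc[0]
        return cls(int(row["n_double"]), int(row["n_total"]),
                   efficiency=efficiency)

    @classmethod
    def from_summary_row(cls, row, efficiency: float = 0.25
                         ) -> "DivergenceModel":
        """Build from one row of a :func:`divtrace.quantify.divergence_summary`."""
        return cls(int(row["n_double"]), int(row["n_total"]),
                   efficiency=efficiency)

    # -- properties ------------------------------------------------------

    @property
    def observed_rate(self) -> float:
        return self.n_double / self.n_total

    @property
    def feasibility_bound(self) -> float:
        """Largest observable rate under the assumed efficiency, e/(2-e)."""
        return self.efficiency_model.r_max

    def implied_min_efficiency(self) -> float:
        """Smallest efficiency consistent with the observed rate."""
        return inference.implied_min_efficiency(self.observed_rate)

    # -- fitting ---------------------------------------------------------

    def fit(self, n_boot: int = 10_000, seed: int = 0,
            ci_level: float = 0.95) -> "DivergenceResults":
        """Invert the model and bootstrap a CI for the true rate.

        Raises
        ------
        InfeasibleRateError
            If the observed rate is at/above e/(2-e); the error carries
            ``implied_min_efficiency``.
        """
        est = inference.correct_estimate(
            self.n_double, self.n_total, self.efficiency_model,
            n_boot=n_boot, seed=seed, ci_level=ci_level)
        return DivergenceResults(self, est, ci_level=ci_level)

    # -- simulation and curve -------------------------------------------

    def simulate(self, d: float, n: int = 1_000_000, reps: int = 100,
                 seed: int = 0) -> MonteCarloRate:
        """Forward Monte Carlo of the observed rate at true divergence d."""
        return inference.mc_observed_rate(
            d, self.efficiency_model.e, n=n, reps=reps, seed=seed)

    def curve(self, d_grid: Optional[Sequence[float]] = None) -> pd.DataFrame:
        """Observed-vs-true sensitivity curve at this model's efficiency."""
        if d_grid is None:
            d_grid = np.linspace(0.0, 1.0, 101)
        return inference.divergence_curve(self.efficiency_model.e, d_grid)

    def plot_curve(self, ax=None, d_grid=None, mark_observed: bool = True):
        """Plot r(d); optionally mark the observed rate and its inverse."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        cv = self.curve(d_grid)
        ax.plot(cv["d"] * 100, cv["r"] * 100,
                label=f"e = {self.efficiency_model.e:g}")
        if mark_observed:
            r = self.observed_rate
            try:
                d = inference.true_rate(r, self.efficiency_model.e)
                ax.plot([d * 100], [r * 100], "o")
                ax.annotate(f"({d * 100:.0f}%, {r * 100:.0f}%)",
                            (d * 100, r * 100), textcoords="offset points",
                            xytext=(6, -10))
            except InfeasibleRateError:
                ax.axhline(r * 100, linestyle="--", color="grey")
        ax.set_xlabel("true rate of divergence (%)")
        ax.set_ylabel("observed rate of divergence (%)")
        ax.legend()
        return ax


class DivergenceResults:
    """Fitted correction: estimates, uncertainty, diagnostics."""

    def __init__(self, model: DivergenceModel,
                 estimate: inference.DivergenceEstimate, ci_level: float):
        self.model = model
        self.estimate = estimate
        self.ci_level = ci_level

    # convenience attribute access
    @property
    def observed_rate(self) -> float:
        return self.estimate.observed_rate

    @property
    def corrected_rate(self) -> float:
        return self.estimate.corrected_rate

    @property
    def conf_int(self) -> tuple[float, float]:
        return (self.estimate.ci_low, self.estimate.ci_high)

    @property
    def n_infeasible_resamples(self) -> int:
        return self.estimate.n_infeasible_resamples

    def to_frame(self) -> pd.DataFrame:
        e = self.estimate
        return pd.DataFrame([{
            "n_double": e.n_double, "n_total": e.n_total,
            "observed_rate": e.observed_rate,
            "corrected_rate": e.corrected_rate,
            "ci_low": e.ci_low, "ci_high": e.ci_high,
            "e": e.e, "method": e.method, "n_boot": e.n_boot,
            "n_infeasible_resamples": e.n_infeasible_resamples,
        }])

    def summary(self) -> str:
        e = self.estimate
        pct = quantify.format_percent
        lines = [
            "Divergence-rate correction (binomial double-infection model)",
            "=" * 60,
            f"counts:              {e.n_double} double / {e.n_total} labelled",
            f"observed rate r:     {e.observed_rate:.6f}  ({pct(e.observed_rate)}%)",
            f"assumed efficiency:  e = {e.e:g}  (assumption, not estimated)",
            f"corrected rate d:    {e.corrected_rate:.6f}  ({pct(e.corrected_rate)}%)",
            f"{int(self.ci_level * 100)}% bootstrap CI:    "
            f"[{e.ci_low:.4f}, {e.ci_high:.4f}]  (n_boot = {e.n_boot})",
        ]
        if e.n_infeasible_resamples:
            lines.append(f"infeasible resamples: {e.n_infeasible_resamples} "
                         f"(mapped to d = 1; upper bound capped)")
        return "\n".join(lines)

    def __repr__(self):
        return (f"<DivergenceResults r={self.observed_rate:.4f} "
                f"d={self.corrected_rate:.4f} "
                f"CI=[{self.estimate.ci_low:.4f}, {self.estimate.ci_high:.4f}]>")
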