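"""Power simulation for the stepped-wedge ALRI trial and closed-form
sample-size calculators for the birthweight outcomes.

The simulation study regenerates the trial from its generative model
(Poisson-35 cohorts in 12 groups x 4 sectors, monthly binary ALRI responses
with stated seasonality, trend, and random-effect variances), fits the
logistic mixed model with a chosen spline df, and reports the Wald rejection
rate of theta = 0 over replicates, with its binomial Monte-Carlo standard
error.  Scaled-down runs (fewer sectors, children, or replicates) are
first-class; the scale is recorded in the output.

The closed-form calculators expose every assumption (SD, ICC, cluster size,
design effect) of the minimum-detectable-difference and low-birthweight
power computations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import StepWedgeDesign, randomize_wedge_order
from .glmm import SteppedWedgeLogit
from .simulate import SimulationParams, generate_cohort, simulate_panel

__all__ = [
    "PowerScenario",
    "PowerResult",
    "run_power_cell",
    "run_power_grid",
    "mdd_continuous",
    "power_proportion",
]


@dataclass(frozen=True)
class PowerScenario:
    """One cell of the power grid."""

    theta: float = -0.2
    trend: str = "none"
    v_fit: int = 8
    n_sims: int = 100
    alpha: float = 0.05
    design: StepWedgeDesign | None = None
    params: SimulationParams | None = None

    def __post_init__(self) -> None:
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")

    def resolved(self) -> tuple[StepWedgeDesign, SimulationParams]:
        design = self.design
        params = self.params if self.params is not None else SimulationParams()
        params = params.with_(theta=self.theta, trend_scenario=self.trend)
        return design, params


@dataclass
class PowerResult:
    """Rejection rate (percent) for one scenario, with Monte-Carlo error."""

    scenario: PowerScenario
    rejection_rate: float
    mc_se: float
    mean_theta_hat: float
    n_converged: int
    n_sims: int
    scale_note: str = "full design"

    def as_row(self) -> dict:
        return {
            "theta": self.scenario.theta,
            "trend": self.scenario.trend,
            "v": self.scenario.v_fit,
            "rejection_pct": self.rejection_rate,
            "mc_se_pct": self.mc_se,
            "mean_theta_hat": self.mean_theta_hat,
            "n_converged": self.n_converged,
            "n_sims": self.n_sims,
            "scale": self.scale_note,
        }


def _scenario_seed_seq(scenario: PowerScenario, seed: int) -> np.random.SeedSequence:
    """Seed stream keyed by the scenario content, not its grid position."""
    key = (
        int(abs(round(scenario.theta * 1000))),
        0 if scenario.trend == "none" else 1,
        int(scenario.v_fit),
    )
    return np.random.SeedSequence(entropy=int(seed) % (2**31), spawn_key=key)


def run_power_cell(
    scenario: PowerScenario, seed: int, scale_note: str | None = None
) -> PowerResult:
    """Estimate rejection probability of the Wald test for one scenario.

    Each replicate draws a fresh wedge order, cohort, and panel from the
    generative model, fits the logistic mixed model with ``v_fit`` spline
    df, and tests theta = 0 at ``alpha`` (two-sided, model-based SE).
    Non-converged fits are excluded from the denominator and counted.
    """
    design, params = scenario.resolved()
    ss = _scenario_seed_seq(scenario, seed)
    child_seeds = ss.spawn(scenario.n_sims)
    rejections = 0
    thetas = []
    n_converged = 0
    for rep_ss in child_seeds:
        rng = np.random.default_rng(rep_ss)
        rep_design = design
        if rep_design is None:
            order = randomize_wedge_order(12, rng.integers(2**31))
            rep_design = StepWedgeDesign.from_wedge_order(order)
        cohort = generate_cohort(rep_design, params, rng=rng)
        if len(cohort) == 0:
            continue
        panel = simulate_panel(rep_design, cohort, params, rng=rng)
        try:
            fit = SteppedWedgeLogit(
                panel, v=scenario.v_fit, alpha=scenario.alpha
            ).fit()
        except (ValueError, np.linalg.LinAlgError):
            continue
        if not fit.converged:
            continue
        n_converged += 1
        thetas.append(fit.theta_hat)
        if fit.p_value < scenario.alpha:
            rejections += 1
    if n_converged == 0:
        raise RuntimeError("all replicates failed to converge")
    p = rejections / n_converged
    return PowerResult(
        scenario=scenario,
        rejection_rate=100.0 * p,
        mc_se=100.0 * float(np.sqrt(p * (1 - p) / n_converged)),
        mean_theta_hat=float(np.mean(thetas)),
        n_converged=n_converged,
        n_sims=scenario.n_sims,
        scale_note=scale_note or ("full design" if design is None else "custom design"),
    )


def run_power_grid(
    thetas: Sequence[float] = (-0.1, -0.2, -0.3),
    trends: Sequence[str] = ("none", "large"),
    vs: Sequence[int] = (0, 2, 8),
    n_sims: int = 100,
    seed: int = 0,
    design: StepWedgeDesign | None = None,
    params: SimulationParams | None = None,
    scale_note: str | None = None,
) -> pd.DataFrame:
    """Run the full power grid and return one row per cell.

    Cells use independent seed streams keyed by scenario content, so results
    do not depend on the evaluation order of the grid.
    """
    if not (len(thetas) and len(trends) and len(vs)):
        raise ValueError("grids must be non-empty")
    rows = []
    for trend in trends:
        for theta in thetas:
            for v in vs:
                scenario = PowerScenario(
                    theta=theta,
                    trend=trend,
                    v_fit=v,
                    n_sims=n_sims,
                    design=design,
                    params=params,
                )
                rows.append(run_power_cell(scenario, seed, scale_note).as_row())
    return pd.DataFrame(rows)


def power_table(grid: pd.DataFrame) -> pd.DataFrame:
    """Pivot a power grid into the trend x (theta, v) presentation table."""
    return grid.pivot_table(
        index="trend", columns=["theta", "v"], values="rejection_pct"
    )


def mdd_continuous(
    n_per_group: int,
    sd: float,
    icc: float = 0.0,
    cluster_size: int = 1,
    power: float = 0.80,
    alpha: float = 0.05,
) -> float:
    """Minimum detectable mean difference for a continuous outcome (grams).

    Two-sample comparison with ``n_per_group`` subjects per arm, inflated by
    the design effect DE = 1 + (cluster_size - 1) * icc:

        delta = (z_{1-alpha/2} + z_power) * sd * sqrt(2 * DE / n_per_group)
    """
    if n_per_group <= 0 or sd <= 0:
        raise ValueError("n_per_group and sd must be positive")
    if not 0 <= icc < 1:
        raise ValueError("icc must lie in [0, 1)")
    if not 0 < power < 1 or not 0 < alpha < 1:
        raise ValueError("power and alpha must lie in (0, 1)")
    deff = 1.0 + (cluster_size - 1) * icc
    z_a = stats.norm.ppf(1 - alpha / 2)
    z_b = stats.norm.ppf(power)
    return float((z_a + z_b) * sd * np.sqrt(2.0 * deff / n_per_group))


def power_proportion(
    p_control: float,
    relative_reduction: float,
    n_per_group: int,
    deff: float = 1.0,
    alpha: float = 0.05,
) -> float:
    """Power of the two-sample proportion test under a relative reduction.

    Normal approximation with pooled variance under the null (matching the
    standard two-proportion z-test), effective per-arm size
    ``n_per_group / deff``, and ``p_intervention = p_control * (1 -
    relative_reduction)``.  Two-sided.
    """
    if not 0 < p_control < 1:
        raise ValueError("p_control must lie in (0, 1)")
    if deff < 1:
        raise ValueError("design effect must be >= 1")
    if n_per_group <= 0:
        raise ValueError("n_per_group must be positive")
    p1 = p_control * (1.0 - relative_reduction)
    if not 0 <= p1 < 1:
        raise ValueError("implied intervention proportion outside [0, 1)")
    n_eff = n_per_group / deff
    delta = p_control - p1
    p_bar = (p_control + p1) / 2.0
    se0 = np.sqrt(2.0 * p_bar * (1.0 - p_bar) / n_eff)
    se1 = np.sqrt(
        p_control * (1 - p_control) / n_eff + p1 * (1 - p1) / n_eff
    )
    z_a = stats.norm.ppf(1 - alpha / 2)
    upper = stats.norm.cdf((delta - z_a * se0) / se1)
    lower = stats.norm.cdf((-delta - z_a * se0) / se1)
    return float(upper + lower)
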