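"""Synthetic data generators for every input the analysis pipeline consumes.

These generators encode the study conditions of the trial's power analysis:
Poisson(35) children per sector, an acute-lower-respiratory-infection (ALRI)
rate of about 1.0 episodes per child-year, sinusoidal seasonality of relative
amplitude 1.05, an optional large secular trend (odds +50% at month 1 decaying
to zero over 10 months), village and child random-intercept variances 0.025
and 0.10 on the log-odds scale, and clustered birthweights with mean 2700 g,
SD 437 g, and intra-sector correlation 0.03357.

Every generator is reproducible for a fixed seed and returns ground truth
alongside the data wherever a downstream detector or estimator will be judged
against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .design import StepWedgeDesign, intervention_indicator

__all__ = [
    "SimulationParams",
    "generate_cohort",
    "seasonal_multiplier",
    "trend_log_odds",
    "calibrate_alpha0",
    "simulate_panel",
    "simulate_diaries",
    "simulate_logger_trace",
    "simulate_birthweights",
]


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of the generative trial model.

    ``theta`` is the intervention effect on the log-odds scale (negative =
    protective); ``baseline_rate`` is episodes per child-year under the null;
    the two variances are random-intercept variances on the log-odds scale
    for the village (sector) and child levels.  Seasonality multiplies the
    ALRI rate by ``season_amplitude**sin(2*pi*(t - season_phase)/season_period)``
    so peaks/troughs are ``season_amplitude`` times higher/lower than the
    long-term average; with the defaults the peak falls in month 3.  The
    "large" trend scenario raises the odds by ``trend_start_odds_increase``
    at month 1, decaying linearly to zero over ``trend_decay_months``.
    """

    theta: float = 0.0
    baseline_rate: float = 1.0
    var_village: float = 0.025
    var_child: float = 0.10
    season_amplitude: float = 1.05
    season_period: float = 12.0
    season_phase: float = 0.0
    trend_scenario: Literal["none", "large"] = "none"
    trend_start_odds_increase: float = 0.5
    trend_decay_months: int = 10
    mean_children_per_sector: float = 35.0
    periods_per_year: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.var_village < 0 or self.var_child < 0:
            raise ValueError("random-effect variances must be >= 0")
        if self.season_amplitude < 1:
            raise ValueError("season_amplitude must be >= 1")
        if self.season_period <= 0:
            raise ValueError("season_period must be positive")
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        if self.trend_scenario not in ("none", "large"):
            raise ValueError(f"unknown trend scenario {self.trend_scenario!r}")

    def with_(self, **kwargs: object) -> "SimulationParams":
        return replace(self, **kwargs)


def seasonal_multiplier(t: float | np.ndarray, params: SimulationParams) -> np.ndarray:
    """Multiplicative seasonal factor on the ALRI rate at period ``t``.

    ``amplitude**sin(...)`` is log-symmetric: its geometric mean over a full
    period is 1, so seasonality preserves the long-term average rate.
    """
    phase = 2.0 * np.pi * (np.asarray(t, dtype=float) - params.season_phase)
    return params.season_amplitude ** np.sin(phase / params.season_period)


def trend_log_odds(t: float | np.ndarray, params: SimulationParams) -> np.ndarray:
    """Additive secular-trend term on the log-odds scale at period ``t``."""
    t = np.asarray(t, dtype=float)
    if params.trend_scenario == "none":
        return np.zeros_like(t)
    start = np.log1p(params.trend_start_odds_increase)
    return start * np.maximum(0.0, 1.0 - (t - 1.0) / params.trend_decay_months)


def calibrate_alpha0(params: SimulationParams, n_quad: int = 31) -> float:
    """Baseline log-odds intercept matching the target annual episode rate.

    Solves for alpha0 such that, under the null scenario (theta irrelevant,
    no secular trend), the population-averaged per-period probability —
    integrating the Normal(0, var_village + var_child) random effects by
    Gauss-Hermite quadrature and averaging over one full season cycle —
    equals ``baseline_rate / periods_per_year``.
    """
    p0 = params.baseline_rate / params.periods_per_year
    if not 0 < p0 < 1:
        raise ValueError("baseline_rate / periods_per_year must lie in (0, 1)")
    sigma = np.sqrt(params.var_village + params.var_child)
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_quad)
    weights = weights / weights.sum()
    t = np.arange(1, int(round(params.season_period)) + 1)
    season = np.log(seasonal_multiplier(t, params))

    def marginal(a0: float) -> float:
        eta = a0 + season[:, None] + sigma * nodes[None, :]
        return float(np.mean(expit(eta) @ weights)) - p0

    center = float(logit(p0))
    return brentq(marginal, center - 3.0, center + 3.0, xtol=1e-12)


def generate_cohort(
    design: StepWedgeDesign,
    params: SimulationParams,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw the child cohort: Poisson sector sizes plus random intercepts.

    Returns one row per child with columns ``child_id``, ``sector_id``,
    ``group_id``, ``b_village`` (the child's sector-level random effect) and
    ``c_child``.  Empty sectors produce no rows but still count toward the
    sector-size distribution (see ``sector_sizes``).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    sectors = np.asarray(design.sector_table()["sector_id"])
    groups = np.asarray(design.sector_table()["group_id"])
    sizes = rng.poisson(params.mean_children_per_sector, size=len(sectors))
    b = rng.normal(0.0, np.sqrt(params.var_village), size=len(sectors))
    n_total = int(sizes.sum())
    sector_of_child = np.repeat(sectors, sizes)
    group_of_child = np.repeat(groups, sizes)
    c = rng.normal(0.0, np.sqrt(params.var_child), size=n_total)
    cohort = pd.DataFrame(
        {
            "child_id": np.arange(1, n_total + 1),
            "sector_id": sector_of_child,
            "group_id": group_of_child,
            "b_village": np.repeat(b, sizes),
            "c_child": c,
        }
    )
    cohort.attrs["sector_sizes"] = pd.Series(sizes, index=sectors, name="n_children")
    return cohort


def simulate_panel(
    design: StepWedgeDesign,
    cohort: pd.DataFrame,
    params: SimulationParams,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Generate the child-period binary ALRI panel under the trial model.

    For child j in sector i at period t,
    ``logit p = alpha0 + b_i + c_ij + log season(t) + trend(t) + theta * x``
    with x the stepped-wedge exposure indicator of the child's group.
    Seasonality enters the linear predictor as the log of the rate
    multiplier (rate and odds multipliers are interchangeable at the small
    per-period probabilities involved).  Periods dropped by the transition
    rule are omitted from the output.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed + 1)
    if not {"child_id", "sector_id", "group_id", "b_village", "c_child"} <= set(
        cohort.columns
    ):
        raise ValueError("cohort does not match the generator schema")
    if len(cohort) and not set(cohort["group_id"]).issubset(set(design.groups)):
        raise ValueError("cohort groups do not match the design")
    alpha0 = calibrate_alpha0(params)
    periods = np.arange(1, design.n_periods + 1)
    x_by_group = {
        g: np.array(
            [intervention_indicator(design, g, int(t)) for t in periods], dtype=object
        )
        for g in design.groups
    }

    n = len(cohort)
    T = len(periods)
    child = np.repeat(np.asarray(cohort["child_id"]), T)
    sector = np.repeat(np.asarray(cohort["sector_id"]), T)
    group = np.repeat(np.asarray(cohort["group_id"]), T)
    b = np.repeat(np.asarray(cohort["b_village"], dtype=float), T)
    c = np.repeat(np.asarray(cohort["c_child"], dtype=float), T)
    t = np.tile(periods, n)
    x_obj = np.concatenate([x_by_group[g][periods - 1] for g in cohort["group_id"]]) if n else np.array([], dtype=object)

    keep = np.array([xv is not None for xv in x_obj], dtype=bool)
    x = np.where(keep, x_obj, 0).astype(float)

    s_t = np.log(seasonal_multiplier(t, params)) + trend_log_odds(t, params)
    eta = alpha0 + b + c + s_t + params.theta * x
    y = (rng.random(n * T) < expit(eta)).astype(np.int8)

    panel = pd.DataFrame(
        {
            "child_id": child,
            "sector_id": sector,
            "group_id": group,
            "period": t,
            "x": x.astype(np.int8),
            "y": y,
        }
    )[keep]
    panel.attrs["alpha0"] = alpha0
    return panel.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Daily symptom diaries


SYMPTOM_COLUMNS = [
    "fever",
    "fast_difficult_breathing",
    "persistent_cough",
    "wheezing",
    "watery_stool",
    "ear_discharge",
]


def simulate_diaries(
    cohort: pd.DataFrame,
    episode_rate: float = 1.0,
    n_days: int = 365,
    noise_rate: float = 0.0,
    start_date: str = "2011-01-01",
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Daily symptom diaries with planted ALRI episodes and ground truth.

    Episodes satisfy the diary case definition by construction: length >= 2
    days, every episode day has fever or fast/difficult breathing, at least
    one day has both, and planted episodes (and noise days) are separated by
    at least 7 symptom-free days so a correct detector recovers the ground
    truth exactly.  ``noise_rate`` plants isolated single-core-symptom days
    (per child-year) that can never qualify as episodes.  Ancillary symptoms
    (cough, wheeze, watery stool, ear discharge) are decorated at random and
    play no role in episode detection.

    Returns ``(diary, truth)``: one diary row per child-day and one truth row
    per planted episode (child_id, start_date, end_date, n_days).
    """
    if episode_rate <= 0:
        raise ValueError("episode_rate must be positive")
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    base = pd.Timestamp(start_date)
    diary_rows: list[pd.DataFrame] = []
    truth_rows: list[dict] = []
    for child_id in cohort["child_id"]:
        flags = np.zeros((n_days, 2), dtype=bool)  # fever, fast/difficult breathing
        blocked = np.zeros(n_days, dtype=bool)  # days unusable for new events
        n_episodes = rng.poisson(episode_rate * n_days / 365.0)
        for _ in range(n_episodes):
            length = 2 + int(rng.poisson(1.5))
            placed = _place_window(rng, blocked, length, gap=7)
            if placed is None:
                continue
            s, e = placed
            fever = rng.random(length) < 0.7
            fdb = rng.random(length) < 0.7
            neither = ~(fever | fdb)
            fever[neither] = True  # every episode day has >=1 core symptom
            both = fever & fdb
            if not both.any():
                k = int(rng.integers(length))
                fever[k] = fdb[k] = True
            flags[s : e + 1, 0] = fever
            flags[s : e + 1, 1] = fdb
            blocked[max(0, s - 7) : min(n_days, e + 8)] = True
            truth_rows.append(
                {
                    "child_id": child_id,
                    "start_date": base + pd.Timedelta(days=s),
                    "end_date": base + pd.Timedelta(days=e),
                    "n_days": length,
                }
            )
        n_noise = rng.poisson(noise_rate * n_days / 365.0)
        for _ in range(n_noise):
            placed = _place_window(rng, blocked, 1, gap=7)
            if placed is None:
                continue
            s, _ = placed
            flags[s, int(rng.integers(2))] = True  # single core symptom only
            blocked[max(0, s - 7) : min(n_days, s + 8)] = True
        frame = pd.DataFrame(
            {
                "child_id": child_id,
                "date": base + pd.to_timedelta(np.arange(n_days), unit="D"),
                "fever": flags[:, 0],
                "fast_difficult_breathing": flags[:, 1],
            }
        )
        for col in SYMPTOM_COLUMNS[2:]:
            frame[col] = rng.random(n_days) < 0.01
        diary_rows.append(frame)
    diary = pd.concat(diary_rows, ignore_index=True)
    truth = pd.DataFrame(
        truth_rows, columns=["child_id", "start_date", "end_date", "n_days"]
    )
    return diary, truth


def _place_window(
    rng: np.random.Generator, blocked: np.ndarray, length: int, gap: int
) -> tuple[int, int] | None:
    """Find a random start so [start, start+length-1] plus a ``gap``-day margin
    is free of existing events; None if no slot is found after 50 tries."""
    n = len(blocked)
    if length > n:
        return None
    for _ in range(50):
        s = int(rng.integers(0, n - length + 1))
        lo, hi = max(0, s - gap), min(n, s + length + gap)
        if not blocked[lo:hi].any():
            return s, s + length - 1
    return None


# ---------------------------------------------------------------------------
# 10-second logger traces


def simulate_logger_trace(
    n_cooking_events: int = 2,
    baseline_level: float = 50.0,
    event_magnitude: float = 500.0,
    duration_h: float = 24.0,
    event_minutes: float = 90.0,
    noise_sd: float = 0.0,
    spike_rate_per_h: float = 0.0,
    spike_magnitude: float = 5000.0,
    baseline_drift: float = 0.0,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A 10-second PM2.5/CO logger trace with known cooking-event windows.

    The trace is ``baseline * drift(t) + events(t)`` times multiplicative
    log-normal noise, plus optional isolated 1-2-sample spikes emulating
    large-particle contamination.  Cooking events are near-rectangular
    excursions of ``event_magnitude`` above baseline lasting
    ``event_minutes`` with 2-minute cosine ramps; their exact windows are
    returned as ground truth for round-trip tests of the stove-influenced-
    time detector.

    Returns ``(trace, events)``; ``trace`` has columns ``timestamp``(s),
    ``value``, ``relative_humidity``, ``temperature``; ``events`` has
    ``start_s``/``end_s``.
    """
    if baseline_level < 0 or event_magnitude < 0:
        raise ValueError("levels must be >= 0")
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    n = int(round(duration_h * 360))  # 10-s cadence
    t = np.arange(n) * 10.0
    drift = 1.0 + baseline_drift * np.sin(2 * np.pi * t / t[-1]) if n > 1 else np.ones(n)
    value = baseline_level * drift

    ev_len = int(round(event_minutes * 6))
    ramp = max(1, int(2 * 6))  # 2-minute ramps
    blocked = np.zeros(n, dtype=bool)
    events: list[dict] = []
    for _ in range(n_cooking_events):
        placed = _place_window(rng, blocked, ev_len, gap=6 * 30)
        if placed is None:
            continue
        s, e = placed
        shape = np.ones(ev_len)
        shape[:ramp] = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
        shape[-ramp:] = shape[:ramp][::-1]
        value[s : e + 1] += event_magnitude * shape
        blocked[max(0, s - 180) : min(n, e + 181)] = True
        events.append({"start_s": t[s], "end_s": t[e]})

    if noise_sd > 0:
        value = value * np.exp(rng.normal(0.0, noise_sd, size=n))
    n_spikes = rng.poisson(spike_rate_per_h * duration_h)
    for _ in range(n_spikes):
        i = int(rng.integers(n))
        width = int(rng.integers(1, 3))
        value[i : i + width] += spike_magnitude
    trace = pd.DataFrame(
        {
            "timestamp": t,
            "value": value,
            "relative_humidity": 60.0 + 10.0 * np.sin(2 * np.pi * t / 86400.0),
            "temperature": 25.0 + 5.0 * np.sin(2 * np.pi * (t - 21600.0) / 86400.0),
        }
    )
    events_df = pd.DataFrame(events, columns=["start_s", "end_s"])
    return trace, events_df


# ---------------------------------------------------------------------------
# Clustered birthweights


def simulate_birthweights(
    n_clusters: int = 48,
    cluster_sizes: int | Sequence[int] = 25,
    mean_g: float = 2700.0,
    sd_g: float = 437.0,
    icc: float = 0.03357,
    effect_g: float = 0.0,
    treated: Sequence[bool] | None = None,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Clustered birthweights: Normal cluster effects plus child noise.

    Cluster effects have variance ``icc * sd_g**2`` and child-level noise
    ``(1 - icc) * sd_g**2`` so the marginal mean and SD equal ``mean_g`` and
    ``sd_g``.  Clusters flagged in ``treated`` are shifted by ``effect_g``.
    """
    if not 0 <= icc < 1:
        raise ValueError("icc must lie in [0, 1)")
    if sd_g <= 0:
        raise ValueError("sd_g must be positive")
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    sizes = (
        np.full(n_clusters, int(cluster_sizes))
        if np.isscalar(cluster_sizes)
        else np.asarray(cluster_sizes, dtype=int)
    )
    if len(sizes) != n_clusters:
        raise ValueError("cluster_sizes length must equal n_clusters")
    if treated is None:
        treated_arr = np.zeros(n_clusters, dtype=bool)
    else:
        treated_arr = np.asarray(treated, dtype=bool)
    u = rng.normal(0.0, sd_g * np.sqrt(icc), size=n_clusters)
    total = int(sizes.sum())
    e = rng.normal(0.0, sd_g * np.sqrt(1.0 - icc), size=total)
    cluster = np.repeat(np.arange(1, n_clusters + 1), sizes)
    weight = mean_g + np.repeat(u, sizes) + e
    weight = weight + effect_g * np.repeat(treated_arr, sizes)
    return pd.DataFrame(
        {
            "cluster_id": cluster,
            "arm": np.where(np.repeat(treated_arr, sizes), "intervention", "control"),
            "weight_g": weight,
        }
    )
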