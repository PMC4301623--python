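"""Indoor-air exposure metrics from 10-second PM2.5 / CO logger traces.

Processing chain for one monitored day (a deployment window of >= 18 h):

1. optional nephelometer correction (pluggable, applied to raw samples);
2. 10-minute averages of the 10-second samples using 3%-per-tail trimmed
   means (robust to isolated large-particle spikes);
3. running median of length 5 over the 10-minute averages (removes
   short-term excursions), shrinking windows at the ends;
4. daily baseline = 10th percentile (linear-interpolation quantile) of the
   filtered values;
5. Stove Influenced Time (SIT): 10-minute intervals whose filtered value
   strictly exceeds 1.2x the baseline;
6. Stove Influenced Particulate / CO (SIP / SIC): the sum of
   (10-minute average - baseline) over the SIT intervals.

The before/after stove contrast compares household-day summaries around
installation with household random intercepts and harmonic season plus
secular-trend adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import trim_mean

import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "ExposureSummary",
    "trimmed_mean_10min",
    "running_median5",
    "daily_baseline",
    "stove_influenced_time",
    "integrate_sip",
    "humidity_correct",
    "summarize_day",
    "stove_contrast",
]

SAMPLES_PER_INTERVAL = 60  # 10-s cadence -> 60 samples per 10-minute interval


@dataclass
class ExposureSummary:
    """Derived exposure metrics for one monitored day."""

    date: object
    baseline: float
    sit_intervals: list[int]  # 1-based 10-minute interval indices
    sit_minutes: float
    sip_or_sic: float  # concentration x 10-min units
    n_valid_intervals: int
    n_intervals: int

    @property
    def sip_concentration_hours(self) -> float:
        return self.sip_or_sic * 10.0 / 60.0

    @property
    def sip_per_24h(self) -> float:
        """SIP rescaled from the deployment window to a nominal 24 h day."""
        if self.n_intervals == 0:
            return 0.0
        return self.sip_or_sic * (144.0 / self.n_intervals)


def trimmed_mean_10min(
    values: Sequence[float],
    trim: float = 0.03,
    per_tail: bool = True,
    samples_per_interval: int = SAMPLES_PER_INTERVAL,
    min_valid_fraction: float = 0.75,
) -> tuple[np.ndarray, np.ndarray]:
    """10-minute trimmed-mean averages of a 10-second series.

    Windows are consecutive blocks of ``samples_per_interval`` samples
    aligned to the trace start; the final partial window is kept if it meets
    the validity threshold.  Trimming removes ``floor(n * trim)`` samples
    from each tail (``per_tail=True``, the default symmetric reading of
    "3% trimmed"; ``per_tail=False`` splits the fraction across both tails),
    always retaining at least one sample.  Intervals with fewer than
    ``min_valid_fraction`` of their nominal samples valid (finite) are
    flagged invalid and set to NaN.

    Returns ``(means, valid)`` arrays, one entry per interval.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty trace")
    cut = trim if per_tail else trim / 2.0
    n_int = int(np.ceil(x.size / samples_per_interval))
    means = np.full(n_int, np.nan)
    valid = np.zeros(n_int, dtype=bool)
    for k in range(n_int):
        window = x[k * samples_per_interval : (k + 1) * samples_per_interval]
        finite = window[np.isfinite(window)]
        if finite.size < min_valid_fraction * samples_per_interval:
            continue
        k_cut = int(np.floor(finite.size * cut))
        if finite.size - 2 * k_cut < 1:
            k_cut = (finite.size - 1) // 2
        means[k] = trim_mean(finite, k_cut / finite.size) if k_cut else finite.mean()
        valid[k] = True
    return means, valid


def running_median5(values: Sequence[float]) -> np.ndarray:
    """Centered running median of length 5 with shrinking end windows.

    Output length equals input length: interior points use a 5-point window,
    the second/penultimate points a 3-point window, and the end points pass
    through unchanged (window of 1).  NaNs (invalid intervals) propagate as
    NaN at their own position and are excluded from neighbours' windows.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n == 0:
        return x.copy()
    out = np.empty(n)
    for i in range(n):
        half = min(2, i, n - 1 - i)
        window = x[i - half : i + half + 1]
        if np.isnan(x[i]):
            out[i] = np.nan
        else:
            out[i] = np.nanmedian(window)
    return out


def daily_baseline(filtered: Sequence[float], q: float = 10.0) -> float:
    """Daily baseline: the ``q``-th percentile of the day's filtered values.

    Uses the linear-interpolation quantile (numpy's default), pinned for
    reproducibility.
    """
    x = np.asarray(filtered, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("no valid intervals in day")
    return float(np.percentile(x, q))


def stove_influenced_time(
    filtered: Sequence[float], baseline: float, multiplier: float = 1.2
) -> list[int]:
    """SIT: 1-based indices of intervals with filtered value > multiplier x baseline.

    The threshold is strict; with a degenerate zero baseline every interval
    with a positive filtered value is stove-influenced.
    """
    if multiplier < 0:
        raise ValueError("multiplier must be >= 0")
    if baseline < 0:
        raise ValueError("baseline must be >= 0")
    x = np.asarray(filtered, dtype=float)
    with np.errstate(invalid="ignore"):
        mask = x > multiplier * baseline
    return [int(i) + 1 for i in np.flatnonzero(mask)]


def integrate_sip(
    averages_10min: Sequence[float],
    baseline: float,
    sit: Sequence[int],
    valid: Sequence[bool] | None = None,
    use_filtered: bool = False,
    filtered: Sequence[float] | None = None,
    date: object = None,
) -> ExposureSummary:
    """SIP/SIC: summed excess over baseline across the SIT intervals.

    By default the sum uses the unfiltered 10-minute averages (the filtered
    series only defines which intervals are stove-influenced);
    ``use_filtered=True`` integrates the filtered values instead.  Units are
    concentration x 10-minute intervals.
    """
    avg = np.asarray(averages_10min, dtype=float)
    series = np.asarray(filtered, dtype=float) if use_filtered else avg
    if use_filtered and filtered is None:
        raise ValueError("use_filtered=True requires the filtered series")
    valid_mask = (
        np.isfinite(avg) if valid is None else np.asarray(valid, dtype=bool)
    )
    sit = [int(k) for k in sit]
    for k in sit:
        if not 1 <= k <= avg.size or not valid_mask[k - 1]:
            raise ValueError(f"SIT interval {k} is not a valid interval")
    idx = np.array(sit, dtype=int) - 1
    sip = float(np.sum(series[idx] - baseline)) if idx.size else 0.0
    return ExposureSummary(
        date=date,
        baseline=float(baseline),
        sit_intervals=sorted(sit),
        sit_minutes=10.0 * len(sit),
        sip_or_sic=sip,
        n_valid_intervals=int(valid_mask.sum()),
        n_intervals=int(avg.size),
    )


def humidity_correct(
    trace: pd.DataFrame,
    correction: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
) -> pd.DataFrame:
    """Apply a pluggable nephelometer correction to the raw samples.

    ``correction(value, relative_humidity)`` is applied pointwise before any
    averaging; the identity is the default.  Negative corrected values are
    clipped to zero with a warning.
    """
    out = trace.copy()
    if correction is None:
        return out
    corrected = np.asarray(
        correction(
            out["value"].to_numpy(dtype=float),
            out.get("relative_humidity", pd.Series(np.nan, index=out.index)).to_numpy(
                dtype=float
            ),
        ),
        dtype=float,
    )
    if (corrected < 0).any():
        warnings.warn("correction produced negative concentrations; clipped to 0")
        corrected = np.clip(corrected, 0.0, None)
    out["value"] = corrected
    return out


def summarize_day(
    trace: pd.DataFrame,
    correction: Callable | None = None,
    multiplier: float = 1.2,
    trim: float = 0.03,
    per_tail: bool = True,
    use_filtered: bool = False,
    date: object = None,
    min_duration_h: float = 18.0,
) -> ExposureSummary:
    """Run the full chain raw trace -> ExposureSummary for one day.

    Warns (but proceeds) if the deployment window is shorter than
    ``min_duration_h``, the minimum for a valid daily assessment.
    """
    duration_h = len(trace) / 360.0
    if duration_h < min_duration_h:
        warnings.warn(
            f"trace covers {duration_h:.1f} h < {min_duration_h} h; "
            "daily summary may not be representative"
        )
    corrected = humidity_correct(trace, correction)
    averages, valid = trimmed_mean_10min(
        corrected["value"].to_numpy(), trim=trim, per_tail=per_tail
    )
    filtered = running_median5(averages)
    baseline = daily_baseline(filtered)
    sit = stove_influenced_time(filtered, baseline, multiplier)
    return integrate_sip(
        averages,
        baseline,
        sit,
        valid=valid,
        use_filtered=use_filtered,
        filtered=filtered,
        date=date,
    )


def stove_contrast(
    summaries: pd.DataFrame,
    immediate_window_months: int = 2,
    season_period: float = 12.0,
) -> pd.DataFrame:
    """Before/after stove-installation exposure contrasts.

    ``summaries`` needs columns ``household_id``, ``month`` (calendar month
    index, 1-based), ``install_month`` (the household's installation month),
    and ``value`` (a daily exposure summary such as SIP or the daily mean).

    Two contrasts are estimated, each from a linear mixed model with a
    household random intercept, harmonic season terms (sin/cos of the annual
    cycle), and a linear secular-trend term:

    - ``annual``: mean after-installation difference using all observations;
    - ``immediate``: the same comparison restricted to observations within
      ``immediate_window_months`` months either side of installation
      (households observed on only one side of the window are excluded and
      reported).

    Returns one row per contrast with the point estimate, standard error
    from the mixed model, and the number of households used.
    """
    required = {"household_id", "month", "install_month", "value"}
    if not required <= set(summaries.columns):
        raise ValueError(f"summaries missing columns: {sorted(required - set(summaries.columns))}")
    df = summaries.copy()
    df["after"] = (df["month"] > df["install_month"]).astype(float)
    df["season_sin"] = np.sin(2 * np.pi * df["month"] / season_period)
    df["season_cos"] = np.cos(2 * np.pi * df["month"] / season_period)
    df["trend"] = df["month"].astype(float)

    per_hh = df.groupby("household_id")["after"].agg(["min", "max"])
    paired = per_hh[(per_hh["min"] == 0) & (per_hh["max"] == 1)].index
    unpaired = sorted(set(per_hh.index) - set(paired))
    if unpaired:
        warnings.warn(
            f"{len(unpaired)} household(s) observed on one side only; "
            "excluded from contrasts"
        )
    df = df[df["household_id"].isin(paired)]
    if df.empty:
        raise ValueError("no household has summaries on both sides of installation")

    rows = []
    for name, sub in (
        ("annual", df),
        (
            "immediate",
            df[
                (df["month"] - df["install_month"]).abs()
                <= immediate_window_months
            ],
        ),
    ):
        ok = sub.groupby("household_id")["after"].agg(["min", "max"])
        keep = ok[(ok["min"] == 0) & (ok["max"] == 1)].index
        sub = sub[sub["household_id"].isin(keep)]
        if sub.empty or sub["after"].nunique() < 2:
            rows.append(
                {"contrast": name, "estimate": np.nan, "se": np.nan, "n_households": 0}
            )
            continue
        exog_cols = ["after", "season_sin", "season_cos", "trend"]
        exog = sm.add_constant(sub[exog_cols])
        # drop adjustment columns with no variation (degenerate subsets)
        keep_cols = (exog.std() > 0).to_numpy() | (exog.columns == "const")
        exog = exog.loc[:, keep_cols]
        if sub["value"].std() == 0:
            rows.append(
                {
                    "contrast": name,
                    "estimate": 0.0,
                    "se": 0.0,
                    "n_households": int(sub["household_id"].nunique()),
                }
            )
            continue
        model = sm.MixedLM(
            sub["value"].astype(float), exog, groups=sub["household_id"]
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = model.fit(reml=True)
        rows.append(
            {
                "contrast": name,
                "estimate": float(fit.params["after"]),
                "se": float(fit.bse["after"]),
                "n_households": int(sub["household_id"].nunique()),
            }
        )
    return pd.DataFrame(rows)
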