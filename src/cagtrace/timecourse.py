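"""Time-course statistics: per-condition expansion rates and contrasts.

Estimates how fast an instability metric (modal repeat or instability
index) changes over time in replicate cultures of each condition, and how
much each knockdown condition is slowed relative to the non-targeting
control.

The primary estimator is a two-stage procedure: metrics are first expressed
as deltas from each replicate culture's own baseline timepoint, then a
per-replicate ordinary-least-squares slope through the origin is fitted,
and the condition rate is the mean of its replicate slopes with a
t-interval on the replicate scatter.  For balanced designs this gives the
same condition means as a linear mixed-effects model with a random slope
per culture; that mixed model is available as an alternative backend
(``method="mixed"``, via statsmodels MixedLM).

Pairwise condition differences in replicate slopes are compared by Tukey's
honestly-significant-difference test (studentized-range critical values).
Percent slowing is ``100 * (1 - rate / control_rate)`` with a
delta-method t-interval on the ratio of replicate-slope means; it is
undefined (NaN) when the control rate is not positive.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .metrics import InstabilityResult

__all__ = [
    "SHEET_COLUMNS",
    "RateEstimate",
    "load_sample_sheet",
    "results_frame",
    "baseline_relative",
    "replicate_slopes",
    "fit_condition_rates",
    "compare_conditions",
    "rates_frame",
]

logger = logging.getLogger(__name__)

#: Required sample-sheet columns.
SHEET_COLUMNS = [
    "sample_id",
    "condition",
    "replicate",
    "time",
    "time_unit",
    "is_control",
    "is_baseline",
]

METRICS = ("modal_repeat", "instability_index")


@dataclass(frozen=True)
class RateEstimate:
    """Per-condition slope of a metric versus time.

    ``slope`` is in metric units per sample-sheet time unit; ``ci95`` is a
    t-interval over replicate slopes; ``percent_slowing`` compares the
    condition rate with the pooled control rate (NaN when undefined).
    """

    condition: str
    metric: str
    slope: float
    se: float
    ci95: tuple[float, float]
    n_replicates: int
    percent_slowing: float
    percent_slowing_ci95: tuple[float, float]
    is_control: bool
    time_unit: str
    replicate_slopes: np.ndarray = field(repr=False, default=None)


def load_sample_sheet(path) -> pd.DataFrame:
    """Read and validate a sample-sheet CSV."""
    sheet = pd.read_csv(path)
    return validate_sheet(sheet)


def validate_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    if sheet is None or len(sheet) == 0:
        raise InputError("sample sheet is empty")
    missing = [c for c in SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise InputError(f"sample sheet is missing columns: {missing}")
    sheet = sheet.copy()
    for col in ("is_control", "is_baseline"):
        sheet[col] = sheet[col].astype(bool)
    if not sheet["is_control"].any():
        raise InputError("sample sheet flags no control condition")
    mixed = sheet.groupby("condition")["is_control"].nunique()
    if (mixed > 1).any():
        raise InputError("is_control must be consistent within each condition")
    return sheet


def results_frame(results) -> pd.DataFrame:
    """Coerce a list of :class:`InstabilityResult` (or a frame) to a frame."""
    if isinstance(results, pd.DataFrame):
        return results
    return pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "modal_repeat": r.modal_repeat,
                "instability_index": r.instability_index,
                "n_peaks_retained": r.n_peaks_retained,
                "reference_repeat": r.reference_repeat,
            }
            for r in results
        ]
    )


def baseline_relative(results, sheet: pd.DataFrame) -> pd.DataFrame:
    """Express metrics as deltas from each replicate's baseline timepoint.

    Returns the results joined to the sheet with ``delta_<metric>`` columns
    and ``t_rel`` (time since the replicate's baseline).  Baseline rows
    become exactly zero.  A replicate without a designated baseline raises
    :class:`InputError` naming it.
    """
    sheet = validate_sheet(sheet)
    df = results_frame(results).merge(sheet, on="sample_id", how="inner")
    if len(df) < len(sheet):
        missing = set(sheet["sample_id"]) - set(df["sample_id"])
        raise InputError(f"samples in sheet without results: {sorted(missing)[:5]}")
    out = []
    for (cond, rep), group in df.groupby(["condition", "replicate"], sort=False):
        base = group[group["is_baseline"]]
        if len(base) == 0:
            raise InputError(f"replicate {cond}/{rep} has no baseline sample")
        if len(base) > 1:
            raise InputError(f"replicate {cond}/{rep} has multiple baseline samples")
        base = base.iloc[0]
        g = group.copy()
        g["t_rel"] = g["time"] - base["time"]
        for metric in METRICS:
            g[f"delta_{metric}"] = g[metric] - base[metric]
        out.append(g)
    return pd.concat(out, ignore_index=True)


def replicate_slopes(
    deltas: pd.DataFrame, metric: str = "instability_index"
) -> pd.DataFrame:
    """Per-replicate OLS slope of the baseline-delta metric through the origin.

    Replicates with fewer than 3 distinct timepoints are excluded with a
    logged warning.  Returns a frame with one row per retained replicate.
    """
    if metric not in METRICS:
        raise InputError(f"metric must be one of {METRICS}, got {metric!r}")
    col = f"delta_{metric}"
    rows = []
    for (cond, rep), g in deltas.groupby(["condition", "replicate"], sort=False):
        t = g["t_rel"].to_numpy(dtype=float)
        y = g[col].to_numpy(dtype=float)
        n_times = np.unique(t).size
        if n_times < 3:
            logger.warning(
                "excluding replicate %s/%s: only %d timepoints", cond, rep, n_times
            )
            continue
        denom = float(t @ t)
        rows.append(
            {
                "condition": cond,
                "replicate": rep,
                "slope": float(t @ y) / denom,
                "n_timepoints": int(n_times),
                "is_control": bool(g["is_control"].iloc[0]),
            }
        )
    frame = pd.DataFrame(
        rows, columns=["condition", "replicate", "slope", "n_timepoints", "is_control"]
    )
    return frame.sort_values(["condition", "replicate"], ignore_index=True)


def _mean_se(x: np.ndarray) -> tuple[float, float]:
    mean = float(np.mean(x))
    se = float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else float("nan")
    return mean, se


def _t_ci(mean: float, se: float, n: int) -> tuple[float, float]:
    if n < 2 or not np.isfinite(se):
        return (float("nan"), float("nan"))
    half = stats.t.ppf(0.975, n - 1) * se
    return (mean - half, mean + half)


def _slowing_with_ci(m_t, se_t, n_t, m_c, se_c, n_c):
    """Percent slowing 100*(1 - m_t/m_c) with a delta-method t-interval."""
    if not m_c > 0:
        return float("nan"), (float("nan"), float("nan"))
    ratio = m_t / m_c
    slowing = 100.0 * (1.0 - ratio)
    if n_t < 2 or n_c < 2 or not (np.isfinite(se_t) and np.isfinite(se_c)):
        return slowing, (float("nan"), float("nan"))
    a = se_t**2 / m_c**2
    b = ratio**2 * se_c**2 / m_c**2
    se = 100.0 * np.sqrt(a + b)
    if a + b == 0:
        return slowing, (slowing, slowing)
    df = (a + b) ** 2 / (a**2 / (n_t - 1) + b**2 / (n_c - 1))
    half = stats.t.ppf(0.975, df) * se
    return slowing, (slowing - half, slowing + half)


def _mixed_model_slopes(deltas: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Condition slopes from a random-slope linear mixed-effects model."""
    import statsmodels.formula.api as smf

    df = deltas.copy()
    df["y"] = df[f"delta_{metric}"]
    df["group"] = df["condition"].astype(str) + "/" + df["replicate"].astype(str)
    model = smf.mixedlm(
        "y ~ 0 + C(condition):t_rel", data=df, groups=df["group"], re_formula="0 + t_rel"
    )
    fit = model.fit(reml=True)
    rows = []
    for name, value in fit.fe_params.items():
        cond = name.split("[")[1].split("]")[0].removeprefix("T.")
        rows.append({"condition": cond, "slope": float(value),
                     "se": float(fit.bse[name])})
    return pd.DataFrame(rows)


def fit_condition_rates(
    results,
    sheet: pd.DataFrame,
    metric: str = "instability_index",
    method: str = "two_stage",
) -> list[RateEstimate]:
    """Estimate per-condition rates of change and percent slowing vs control.

    ``method`` is ``"two_stage"`` (default; replicate-slope means) or
    ``"mixed"`` (random-slope mixed model for the condition slopes and
    standard errors; slowing intervals still use the replicate slopes).
    Conditions are reported in sorted name order.  Raises
    :class:`InputError` if every replicate of some condition is excluded.
    """
    if method not in ("two_stage", "mixed"):
        raise InputError(f"unknown method {method!r}")
    deltas = baseline_relative(results, sheet)
    slopes = replicate_slopes(deltas, metric)
    all_conditions = sorted(pd.unique(deltas["condition"]))
    present = set(slopes["condition"]) if len(slopes) else set()
    dropped = [c for c in all_conditions if c not in present]
    if dropped:
        raise InputError(
            f"all replicates excluded for condition(s) {dropped}; "
            "rate fitting requires >= 3 timepoints per replicate"
        )
    time_unit = str(deltas["time_unit"].iloc[0])

    control_slopes = slopes.loc[slopes["is_control"], "slope"].to_numpy()
    m_c, se_c = _mean_se(control_slopes)
    n_c = control_slopes.size

    mixed = _mixed_model_slopes(deltas, metric) if method == "mixed" else None

    estimates = []
    for cond in all_conditions:
        sub = slopes[slopes["condition"] == cond]
        rep = sub["slope"].to_numpy()
        mean, se = _mean_se(rep)
        n = rep.size
        if method == "mixed":
            row = mixed[mixed["condition"] == cond].iloc[0]
            mean, se = float(row["slope"]), float(row["se"])
        slowing, slowing_ci = _slowing_with_ci(
            float(np.mean(rep)), _mean_se(rep)[1], n, m_c, se_c, n_c
        )
        estimates.append(
            RateEstimate(
                condition=cond,
                metric=metric,
                slope=mean,
                se=se,
                ci95=_t_ci(mean, se, n),
                n_replicates=n,
                percent_slowing=slowing,
                percent_slowing_ci95=slowing_ci,
                is_control=bool(sub["is_control"].iloc[0]),
                time_unit=time_unit,
                replicate_slopes=rep,
            )
        )
    return estimates


def compare_conditions(slopes: pd.DataFrame) -> pd.DataFrame:
    """Tukey HSD on replicate slopes across conditions.

    ``slopes`` is the output of :func:`replicate_slopes`.  Returns one row
    per unordered condition pair with the slope-mean difference, the
    Tukey-adjusted p value, and a 0.05-level significance flag.
    """
    conditions = sorted(pd.unique(slopes["condition"]))
    if len(conditions) < 2:
        raise InputError("pairwise comparison requires at least 2 conditions")
    groups = []
    for cond in conditions:
        x = slopes.loc[slopes["condition"] == cond, "slope"].to_numpy()
        if x.size < 2:
            raise InputError(
                f"condition {cond!r} has {x.size} replicate slope(s); "
                "Tukey HSD requires >= 2"
            )
        groups.append(x)
    res = stats.tukey_hsd(*groups)
    rows = []
    for i, j in itertools.combinations(range(len(conditions)), 2):
        p = float(res.pvalue[i, j])
        rows.append(
            {
                "condition_a": conditions[i],
                "condition_b": conditions[j],
                "difference": float(np.mean(groups[i]) - np.mean(groups[j])),
                "p_adj": p,
                "significant": p < 0.05,
            }
        )
    return pd.DataFrame(rows)


def rates_frame(estimates: list[RateEstimate]) -> pd.DataFrame:
    """Tidy frame of rate estimates (one row per condition and metric)."""
    return pd.DataFrame(
        [
            {
                "condition": e.condition,
                "metric": e.metric,
                "slope": e.slope,
                "se": e.se,
                "ci95_low": e.ci95[0],
                "ci95_high": e.ci95[1],
                "n_replicates": e.n_replicates,
                "percent_slowing": e.percent_slowing,
                "percent_slowing_ci95_low": e.percent_slowing_ci95[0],
                "percent_slowing_ci95_high": e.percent_slowing_ci95[1],
                "is_control": e.is_control,
                "time_unit": e.time_unit,
            }
            for e in estimates
        ]
    )
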