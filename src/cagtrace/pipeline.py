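"""End-to-end orchestration: simulate study designs, analyze peak tables.

A *design* describes a knockdown time-course study: one or more conditions
(each a gain-rate multiplier, with the non-targeting control at 1.0),
replicate cultures drawn from independent pools, and a shared timepoint
grid.  :func:`simulate_design` renders the design into GeneMapper-style
peak tables plus a sample sheet and a ground-truth table;
:func:`analyze_study` runs the full measurement chain (calibration,
per-sample instability summaries, baseline deltas, condition rates,
Tukey contrasts) on any peak tables and sheet, simulated or real.

All randomness is funnelled through a single seeded generator, so a run is
reproducible byte-for-byte given its seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import metrics, simulate, timecourse, traceio
from .errors import InputError

__all__ = [
    "Condition",
    "Design",
    "SimulatedStudy",
    "AnalysisOutputs",
    "ipsc_design",
    "msn_design",
    "simulate_design",
    "write_study",
    "analyze_study",
    "write_analysis",
    "load_run_config",
]

logger = logging.getLogger(__name__)

#: Per-replicate lognormal coefficient of variation on the gain rate,
#: emulating biological culture-to-culture variability in expansion rate.
DEFAULT_REPLICATE_RATE_CV = 0.10


@dataclass(frozen=True)
class Condition:
    """One experimental arm: a guide/target label and its rate multiplier."""

    name: str
    rate_multiplier: float = 1.0
    is_control: bool = False


@dataclass(frozen=True)
class Design:
    """Study layout: conditions x pools x replicate cultures x timepoints.

    ``times`` are in ``time_unit`` ("day" or "week"); simulation always
    advances in days internally.
    """

    conditions: tuple
    times: tuple
    time_unit: str = "day"
    n_replicates: int = 4
    n_pools: int = 2
    replicate_rate_cv: float = DEFAULT_REPLICATE_RATE_CV

    def __post_init__(self) -> None:
        if len(self.conditions) == 0:
            raise InputError("design requires at least one condition")
        if self.time_unit not in ("day", "week"):
            raise InputError(f"time_unit must be 'day' or 'week', got {self.time_unit!r}")
        if self.n_replicates < 1 or self.n_pools < 1:
            raise InputError("n_replicates and n_pools must be >= 1")
        if self.replicate_rate_cv < 0:
            raise InputError("replicate_rate_cv must be >= 0")
        object.__setattr__(self, "conditions", tuple(self.conditions))
        object.__setattr__(self, "times", tuple(float(t) for t in self.times))

    def times_days(self) -> np.ndarray:
        scale = 7.0 if self.time_unit == "week" else 1.0
        return np.asarray(self.times, dtype=float) * scale


def ipsc_design(conditions=None, **overrides) -> Design:
    """80-day dividing-culture design: 20-day sampling, 4 cultures x 2 pools."""
    if conditions is None:
        conditions = (Condition("NTC", 1.0, is_control=True),)
    defaults = dict(times=(0, 20, 40, 60, 80), time_unit="day")
    defaults.update(overrides)
    return Design(conditions=tuple(conditions), **defaults)


def msn_design(conditions=None, **overrides) -> Design:
    """9-week striatal-neuron design: 3-week sampling from the day-36 baseline."""
    if conditions is None:
        conditions = (Condition("NTC", 1.0, is_control=True),)
    defaults = dict(times=(0, 3, 6, 9), time_unit="week")
    defaults.update(overrides)
    return Design(conditions=tuple(conditions), **defaults)


def mutl_knockdown_conditions() -> tuple:
    """NTC plus the four calibrated MutL knockdown arms."""
    conds = [Condition("NTC", 1.0, is_control=True)]
    conds += [
        Condition(name, mult)
        for name, mult in simulate.KNOCKDOWN_MULTIPLIERS.items()
    ]
    return tuple(conds)


@dataclass
class SimulatedStudy:
    """In-memory result of rendering a design."""

    peak_tables: list
    sheet: pd.DataFrame
    truth: pd.DataFrame
    size_map: metrics.SizeToRepeatMap
    seed: int


def _effective_multiplier(base: float, cv: float, rng: np.random.Generator) -> float:
    if cv <= 0:
        return base
    sigma = float(np.sqrt(np.log1p(cv**2)))
    return base * float(rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma))


def simulate_design(
    design: Design,
    sim_config: simulate.SimConfig,
    seed: int,
) -> SimulatedStudy:
    """Render a design into peak tables, a sample sheet, and ground truth.

    Each culture gets an independent allele population whose gain rate is
    the condition multiplier times a per-replicate lognormal factor (mean
    1, CV ``design.replicate_rate_cv``).  Peak heights are the stuttered
    proportional masses on the fluorescence scale; bp positions come from
    the default linear repeat map.
    """
    rng = np.random.default_rng(seed)
    smap = metrics.SizeToRepeatMap(intercept_bp=0.0)
    times_days = design.times_days()
    peak_tables, sheet_rows, truth_rows = [], [], []
    for cond in design.conditions:
        for pool in range(1, design.n_pools + 1):
            for rep in range(1, design.n_replicates + 1):
                replicate = f"p{pool}r{rep}"
                eff = _effective_multiplier(
                    cond.rate_multiplier, design.replicate_rate_cv, rng
                )
                cfg = replace(sim_config, rate_multiplier=eff, seed=None)
                pops = simulate.simulate_population(cfg, times_days, rng=rng)
                for t_sheet, pop in zip(design.times, pops):
                    dist = simulate.apply_stutter(
                        pop, cfg.stutter_ratio, cfg.stutter_orders
                    )
                    sample_id = f"{cond.name}_{replicate}_t{t_sheet:g}"
                    peak_tables.append(
                        traceio.PeakTable(
                            sample_id,
                            np.asarray(smap.repeat_to_bp(dist.repeats)),
                            dist.masses * simulate.TRACE_PEAK_SCALE,
                        )
                    )
                    sheet_rows.append(
                        {
                            "sample_id": sample_id,
                            "condition": cond.name,
                            "replicate": replicate,
                            "time": t_sheet,
                            "time_unit": design.time_unit,
                            "is_control": cond.is_control,
                            "is_baseline": t_sheet == design.times[0],
                        }
                    )
                    truth_rows.append(
                        {
                            "condition": cond.name,
                            "replicate": replicate,
                            "time": t_sheet,
                            "effective_multiplier": eff,
                            "true_modal_repeat": pop.modal_length(),
                            "true_mean_repeat": float(pop.repeat_lengths.mean()),
                        }
                    )
    return SimulatedStudy(
        peak_tables=peak_tables,
        sheet=pd.DataFrame(sheet_rows),
        truth=pd.DataFrame(truth_rows),
        size_map=smap,
        seed=seed,
    )


def write_study(study: SimulatedStudy, outdir) -> dict[str, Path]:
    """Write peaks.csv, sheet.csv and truth.csv under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "peaks": outdir / "peaks.csv",
        "sheet": outdir / "sheet.csv",
        "truth": outdir / "truth.csv",
    }
    traceio.write_peak_table(study.peak_tables, paths["peaks"])
    study.sheet.to_csv(paths["sheet"], index=False)
    study.truth.to_csv(paths["truth"], index=False, float_format="%.6f")
    logger.info("wrote simulated study (seed %d) to %s", study.seed, outdir)
    return paths


@dataclass
class AnalysisOutputs:
    """Results of a full analysis run."""

    results: pd.DataFrame
    rates: pd.DataFrame
    contrasts: pd.DataFrame
    size_map: metrics.SizeToRepeatMap
    estimates: dict = field(default_factory=dict, repr=False)


def _pick_calibration_table(tables: dict, sheet: pd.DataFrame) -> str:
    """Default calibration sample: first control baseline by sorted id."""
    mask = sheet["is_control"] & sheet["is_baseline"]
    if not mask.any():
        raise InputError("no control baseline sample available for calibration")
    return sorted(sheet.loc[mask, "sample_id"])[0]


def analyze_study(
    peak_tables,
    sheet: pd.DataFrame,
    config: metrics.AnalysisConfig = metrics.AnalysisConfig(),
    size_map: metrics.SizeToRepeatMap | None = None,
    known_modal_repeat: int = 125,
    calibration_sample: str | None = None,
    bp_per_repeat: float = metrics.DEFAULT_BP_PER_REPEAT,
    method: str = "two_stage",
) -> AnalysisOutputs:
    """Full measurement chain on peak tables plus a sample sheet.

    If no ``size_map`` is given, the intercept is calibrated from
    ``calibration_sample`` (default: the first control baseline sample)
    assuming its modal allele carries ``known_modal_repeat`` CAG units.
    The instability index of every sample is referenced to its replicate's
    baseline modal repeat (``config.reference_mode == "baseline"``), to the
    sample's own modal repeat (``"self"``), or to a fixed integer.
    """
    sheet = timecourse.validate_sheet(sheet)
    tables = {t.sample_id: t for t in peak_tables}
    missing = [s for s in sheet["sample_id"] if s not in tables]
    if missing:
        raise InputError(f"sheet samples without peak tables: {missing[:5]}")

    if size_map is None:
        cal_id = calibration_sample or _pick_calibration_table(tables, sheet)
        if cal_id not in tables:
            raise InputError(f"calibration sample {cal_id!r} not found")
        size_map = metrics.calibrate_intercept(
            tables[cal_id], known_modal_repeat, bp_per_repeat
        )
        logger.info(
            "calibrated intercept %.4f bp from sample %s (modal repeat %d)",
            size_map.intercept_bp, cal_id, known_modal_repeat,
        )

    # first pass: per-replicate baseline modal repeats (the index reference)
    references: dict[tuple, int] = {}
    if config.reference_mode == "baseline":
        for (cond, rep), g in sheet.groupby(["condition", "replicate"], sort=False):
            base = g[g["is_baseline"]]
            if len(base) != 1:
                raise InputError(
                    f"replicate {cond}/{rep} must have exactly one baseline sample"
                )
            base_id = base["sample_id"].iloc[0]
            references[(cond, rep)] = metrics.summarize_sample(
                tables[base_id], size_map, config
            ).modal_repeat

    results = []
    for row in sheet.itertuples(index=False):
        if config.reference_mode == "baseline":
            ref = references[(row.condition, row.replicate)]
        elif config.reference_mode == "self":
            ref = None
        else:
            ref = int(config.reference_mode)
        results.append(
            metrics.summarize_sample(tables[row.sample_id], size_map, config, ref)
        )
    results_df = timecourse.results_frame(results)

    rates_frames, contrasts_frames, estimates = [], [], {}
    for metric in timecourse.METRICS:
        ests = timecourse.fit_condition_rates(results_df, sheet, metric, method)
        estimates[metric] = ests
        rates_frames.append(timecourse.rates_frame(ests))
        deltas = timecourse.baseline_relative(results_df, sheet)
        slopes = timecourse.replicate_slopes(deltas, metric)
        if slopes["condition"].nunique() >= 2:
            contrasts = timecourse.compare_conditions(slopes)
            contrasts.insert(0, "metric", metric)
            contrasts_frames.append(contrasts)
    rates = pd.concat(rates_frames, ignore_index=True)
    contrasts = (
        pd.concat(contrasts_frames, ignore_index=True)
        if contrasts_frames
        else pd.DataFrame()
    )
    logger.info(
        "analyzed %d samples, %d conditions", len(results_df), sheet["condition"].nunique()
    )
    return AnalysisOutputs(
        results=results_df, rates=rates, contrasts=contrasts,
        size_map=size_map, estimates=estimates,
    )


def write_analysis(outputs: AnalysisOutputs, outdir) -> dict[str, Path]:
    """Write results.csv, rates.csv and contrasts.csv under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "results": outdir / "results.csv",
        "rates": outdir / "rates.csv",
        "contrasts": outdir / "contrasts.csv",
    }
    outputs.results.to_csv(paths["results"], index=False, float_format="%.6f")
    outputs.rates.to_csv(paths["rates"], index=False, float_format="%.6f")
    outputs.contrasts.to_csv(paths["contrasts"], index=False, float_format="%.6f")
    return paths


# ---------------------------------------------------------------------------
# Structured run configuration (YAML)
# ---------------------------------------------------------------------------

def load_run_config(path) -> dict:
    """Load a YAML run configuration.

    Recognised keys: ``seed`` (int), ``preset`` (simulator preset name),
    ``sim`` (SimConfig field overrides), ``design`` (Design fields with a
    ``conditions`` list of ``{name, rate_multiplier, is_control}``),
    ``analysis`` (AnalysisConfig fields).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise InputError(f"run config {path} must be a mapping")
    return raw


def build_sim_config(raw: dict) -> simulate.SimConfig:
    base = (
        simulate.preset(raw["preset"]) if raw.get("preset") else simulate.SimConfig()
    )
    overrides = raw.get("sim") or {}
    return replace(base, **overrides)


def build_design(raw: dict) -> Design:
    fields = dict(raw.get("design") or {})
    cond_rows = fields.pop("conditions", None)
    if not cond_rows:
        raise InputError("run config design must list at least one condition")
    conditions = tuple(
        Condition(
            name=str(c["name"]),
            rate_multiplier=float(c.get("rate_multiplier", 1.0)),
            is_control=bool(c.get("is_control", False)),
        )
        for c in cond_rows
    )
    return Design(conditions=conditions, **fields)
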