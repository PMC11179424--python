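"""Repeat-count metrics for CAG-repeat fragment analysis.

This module turns sized capillary-electrophoresis peaks (base pairs,
fluorescence heights) into integer CAG repeat counts and summary statistics
of somatic instability:

* a linear size-to-repeat map whose slope is the apparent electrophoretic
  mobility per CAG unit (default 2.724117 bp/repeat) and whose intercept is
  calibrated against a sample of known modal genotype;
* the modal-height threshold filter that discards peaks below a fixed
  fraction (default 20%) of the tallest peak;
* the modal repeat length and the *modified instability index* — the
  height-weighted mean deviation of retained repeat lengths from a reference
  repeat (typically the control or baseline sample's modal repeat).

Peak heights are treated as proportional abundances after renormalisation
over the retained peaks, so the index is invariant to overall signal
intensity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CalibrationError, InputError

__all__ = [
    "DEFAULT_BP_PER_REPEAT",
    "DEFAULT_THRESHOLD_FRAC",
    "SizeToRepeatMap",
    "AnalysisConfig",
    "RepeatDistribution",
    "InstabilityResult",
    "size_to_repeat",
    "calibrate_intercept",
    "filter_peaks",
    "modal_repeat",
    "instability_index",
    "summarize_sample",
]

#: Apparent base pairs of mobility per CAG unit on the capillary.
DEFAULT_BP_PER_REPEAT = 2.724117

#: Fraction of the modal peak height below which peaks are discarded.
DEFAULT_THRESHOLD_FRAC = 0.20

_MASS_TOL = 1e-9


@dataclass(frozen=True)
class SizeToRepeatMap:
    """Linear map between fragment size (bp) and CAG repeat count.

    ``size_bp = intercept_bp + repeat * bp_per_repeat``.  The intercept
    absorbs primer flanks and sizing-algorithm offsets and is normally set by
    :func:`calibrate_intercept` from a sample of known modal repeat.
    """

    bp_per_repeat: float = DEFAULT_BP_PER_REPEAT
    intercept_bp: float = 0.0

    def __post_init__(self) -> None:
        if not self.bp_per_repeat > 0:
            raise InputError(f"bp_per_repeat must be > 0, got {self.bp_per_repeat}")

    def repeat_to_bp(self, repeat):
        """Apparent fragment size of an allele with ``repeat`` CAG units."""
        return self.intercept_bp + np.asarray(repeat, dtype=float) * self.bp_per_repeat

    def fractional_repeat(self, size_bp):
        """Un-rounded repeat coordinate of a fragment size."""
        return (np.asarray(size_bp, dtype=float) - self.intercept_bp) / self.bp_per_repeat


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters of the per-sample instability summary.

    ``reference_mode`` selects the reference repeat for the index:
    ``"baseline"`` (each replicate's baseline-sample modal repeat — the
    default used by the pipeline), ``"self"`` (the sample's own modal
    repeat), or a fixed integer repeat count.
    """

    threshold_frac: float = DEFAULT_THRESHOLD_FRAC
    rounding_rule: str = "half_up"
    reference_mode: str | int = "baseline"

    def __post_init__(self) -> None:
        if not 0 <= self.threshold_frac < 1:
            raise InputError(
                f"threshold_frac must be in [0, 1), got {self.threshold_frac}"
            )
        if self.rounding_rule not in ("half_up", "half_even"):
            raise InputError(f"unknown rounding_rule {self.rounding_rule!r}")


@dataclass(frozen=True)
class RepeatDistribution:
    """Filtered peaks on the repeat-count axis with proportional heights.

    ``repeats`` are strictly increasing integer CAG counts and ``masses``
    are non-negative proportional heights summing to one.
    """

    repeats: np.ndarray
    masses: np.ndarray

    def __post_init__(self) -> None:
        repeats = np.asarray(self.repeats, dtype=np.int64)
        masses = np.asarray(self.masses, dtype=float)
        object.__setattr__(self, "repeats", repeats)
        object.__setattr__(self, "masses", masses)
        if repeats.ndim != 1 or masses.shape != repeats.shape:
            raise InputError("repeats and masses must be 1-d arrays of equal length")
        if repeats.size == 0:
            raise InputError("empty repeat distribution")
        if np.any(np.diff(repeats) <= 0):
            raise InputError("repeats must be strictly increasing")
        if np.any(masses < 0):
            raise InputError("masses must be non-negative")
        if abs(masses.sum() - 1.0) > _MASS_TOL:
            raise InputError(f"masses must sum to 1, got {masses.sum()!r}")

    @classmethod
    def from_heights(cls, repeats, heights) -> "RepeatDistribution":
        """Normalise raw peak heights into proportional masses."""
        heights = np.asarray(heights, dtype=float)
        total = heights.sum()
        if not total > 0:
            raise InputError("total peak height must be positive")
        return cls(np.asarray(repeats, dtype=np.int64), heights / total)


@dataclass(frozen=True)
class InstabilityResult:
    """Per-sample instability summary."""

    sample_id: str
    modal_repeat: int
    instability_index: float
    n_peaks_retained: int
    reference_repeat: int


def _round_repeat(x: float, rule: str = "half_up") -> int:
    if rule == "half_even":
        return int(np.rint(x))
    # half-up: deterministic nearest-integer with ties away from the origin
    return int(np.floor(x + 0.5))


def size_to_repeat(size_bp: float, smap: SizeToRepeatMap, rule: str = "half_up") -> int:
    """Nearest-integer CAG repeat count of a sized fragment.

    Raises :class:`CalibrationError` if the computed repeat is negative,
    which indicates the map's intercept does not match the assay.
    """
    repeat = _round_repeat(float(smap.fractional_repeat(size_bp)), rule)
    if repeat < 0:
        raise CalibrationError(
            f"size {size_bp} bp maps to negative repeat {repeat}; "
            "check the size-to-repeat calibration"
        )
    return repeat


def calibrate_intercept(
    peak_table,
    known_modal_repeat: int,
    bp_per_repeat: float = DEFAULT_BP_PER_REPEAT,
) -> SizeToRepeatMap:
    """Anchor the size-to-repeat map to a sample of known modal genotype.

    The tallest peak of ``peak_table`` is taken to be the known modal allele
    and the intercept is set so that it maps exactly to
    ``known_modal_repeat``.  A height tie between peaks more than one repeat
    unit apart is ambiguous and raises :class:`CalibrationError`.
    """
    sizes = np.asarray(peak_table.sizes_bp, dtype=float)
    heights = np.asarray(peak_table.heights, dtype=float)
    if sizes.size == 0:
        raise CalibrationError("cannot calibrate from an empty peak table")
    top = heights == heights.max()
    tied_sizes = sizes[top]
    if tied_sizes.max() - tied_sizes.min() > bp_per_repeat:
        raise CalibrationError(
            "modal peak is ambiguous: height tie spans more than one repeat unit"
        )
    modal_size = float(tied_sizes.min())
    intercept = modal_size - known_modal_repeat * bp_per_repeat
    return SizeToRepeatMap(bp_per_repeat=bp_per_repeat, intercept_bp=intercept)


def filter_peaks(repeats, heights, threshold_frac: float = DEFAULT_THRESHOLD_FRAC):
    """Retain peaks whose height is >= ``threshold_frac`` x modal height.

    The comparison is inclusive, so a peak exactly at the threshold is kept;
    the modal peak itself is always retained.  Returns the retained
    ``(repeats, heights)`` arrays.
    """
    if not 0 <= threshold_frac < 1:
        raise InputError(f"threshold_frac must be in [0, 1), got {threshold_frac}")
    repeats = np.asarray(repeats)
    heights = np.asarray(heights, dtype=float)
    if heights.size == 0:
        raise InputError("filter_peaks requires at least one peak")
    keep = heights >= threshold_frac * heights.max()
    return repeats[keep], heights[keep]


def modal_repeat(dist: RepeatDistribution) -> int:
    """Repeat length of the tallest peak; exact ties go to the smaller repeat."""
    return int(dist.repeats[int(np.argmax(dist.masses))])


def instability_index(dist: RepeatDistribution, reference_repeat: int) -> float:
    """Height-weighted mean deviation from the reference repeat.

    ``sum_i mass_i * (repeat_i - reference_repeat)`` over the retained,
    renormalised peaks.  Positive values indicate net expansion beyond the
    reference length.
    """
    return float(np.sum(dist.masses * (dist.repeats - int(reference_repeat))))


def _merge_repeats(repeats, heights):
    """Sum heights of peaks that round to the same repeat count."""
    repeats = np.asarray(repeats, dtype=np.int64)
    heights = np.asarray(heights, dtype=float)
    uniq, inv = np.unique(repeats, return_inverse=True)
    summed = np.zeros(uniq.size)
    np.add.at(summed, inv, heights)
    return uniq, summed


def summarize_sample(
    peak_table,
    smap: SizeToRepeatMap,
    config: AnalysisConfig = AnalysisConfig(),
    reference_repeat: int | None = None,
) -> InstabilityResult:
    """Full per-sample chain: size->repeat, merge, threshold, modal, index.

    Peaks rounding to the same repeat are merged by summing heights before
    the threshold filter.  If ``reference_repeat`` is None the sample's own
    modal repeat is used (yielding the sample-internal index).
    """
    sizes = np.asarray(peak_table.sizes_bp, dtype=float)
    heights = np.asarray(peak_table.heights, dtype=float)
    if sizes.size == 0:
        raise InputError(f"peak table {peak_table.sample_id!r} is empty")
    repeats = np.array(
        [size_to_repeat(s, smap, config.rounding_rule) for s in sizes], dtype=np.int64
    )
    repeats, merged = _merge_repeats(repeats, heights)
    kept_r, kept_h = filter_peaks(repeats, merged, config.threshold_frac)
    dist = RepeatDistribution.from_heights(kept_r, kept_h)
    modal = modal_repeat(dist)
    ref = modal if reference_repeat is None else int(reference_repeat)
    return InstabilityResult(
        sample_id=peak_table.sample_id,
        modal_repeat=modal,
        instability_index=instability_index(dist, ref),
        n_peaks_retained=int(kept_r.size),
        reference_repeat=ref,
    )
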