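"""Generative model of somatic CAG-repeat expansion and its measurement.

The biological process is modelled as a length-dependent birth-death walk on
integer repeat counts: over an interval of ``dt`` days each allele gains
``Poisson(gain_rate * rate_multiplier * dt * f(L))`` repeats and loses
``Poisson(loss_rate * dt * f(L))``, where ``f(L) = max(0, 1 +
length_dependence * (L - initial_repeat))``.  This reproduces the unimodal,
upward-drifting repeat-length distributions seen in proliferating and
post-mitotic HD-model cultures while keeping the mean and variance of the
net gain in closed form (``(gain - loss) * t`` each, for the
length-independent case).

Measurement artefacts are layered on top:

* PCR stutter — each allele of length L contributes geometrically decaying
  mass ``stutter_ratio**k`` at L-k for k = 0..stutter_orders (downward-only,
  the dominant direction for long CAG tracts);
* capillary traces — Gaussian peaks on the bp axis at the positions given by
  the linear size-to-repeat map, plus optional Gaussian baseline noise, with
  a size-standard ladder channel.

Presets encode the two control conditions the generator is calibrated to:
``"ipsc-control"`` (expected modal gain of 5 CAG over 80 days of passaging)
and ``"msn-control"`` (expected fitted instability-index slope of 0.20
units/week over a 9-week striatal-neuron time course).  The calibration is
analytic (infinite-allele limit of the full stutter + threshold measurement
chain) and documented in docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import InputError
from .metrics import DEFAULT_BP_PER_REPEAT, RepeatDistribution, SizeToRepeatMap
from .traceio import Electropherogram

__all__ = [
    "SimConfig",
    "AllelePopulation",
    "simulate_population",
    "apply_stutter",
    "synthesize_trace",
    "expected_mean_gain",
    "preset",
    "PRESETS",
    "KNOCKDOWN_MULTIPLIERS",
    "LADDER_SIZES_BP",
    "SCANS_PER_BP",
    "TRACE_PEAK_SCALE",
]

#: Synthetic size-standard ladder (bp).  Stands in for the ROX-series
#: 50-1000 bp ladders used on ABI capillary sequencers; the exact fragment
#: sizes of the commercial standard are not reproduced here.
LADDER_SIZES_BP = np.array(
    [50, 100, 150, 200, 250, 300, 350, 400, 450, 500, 600, 700, 800, 900, 1000],
    dtype=float,
)

#: Scan-axis resolution of synthesised traces (scans per bp of mobility).
SCANS_PER_BP = 20

#: Fluorescence scale: a peak carrying all mass has this apex height.
TRACE_PEAK_SCALE = 10000.0


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the expansion process and its measurement.

    Rates are per allele per day.  ``rate_multiplier`` scales the gain rate
    only and is the knob used to emulate per-condition knockdown effects.
    """

    initial_repeat: int = 125
    n_alleles: int = 1000
    gain_rate: float = 0.05
    loss_rate: float = 0.0
    length_dependence: float = 0.0
    rate_multiplier: float = 1.0
    stutter_ratio: float = 0.3
    stutter_orders: int = 5
    trace_sigma_bp: float = 0.8
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.initial_repeat < 1:
            raise InputError("initial_repeat must be >= 1")
        if self.n_alleles < 1:
            raise InputError("n_alleles must be >= 1")
        if self.gain_rate < 0 or self.loss_rate < 0:
            raise InputError("gain_rate and loss_rate must be >= 0")
        if not 0 <= self.stutter_ratio < 1:
            raise InputError(
                f"stutter_ratio must be in [0, 1), got {self.stutter_ratio}"
            )
        if self.stutter_orders < 0:
            raise InputError("stutter_orders must be >= 0")
        if self.rate_multiplier < 0:
            raise InputError("rate_multiplier must be >= 0")
        if self.noise_sd < 0:
            raise InputError("noise_sd must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class AllelePopulation:
    """Multiset of integer CAG repeat lengths at one timepoint."""

    repeat_lengths: np.ndarray
    time_days: float

    def __post_init__(self) -> None:
        lengths = np.asarray(self.repeat_lengths, dtype=np.int64)
        object.__setattr__(self, "repeat_lengths", lengths)
        if lengths.size == 0:
            raise InputError("population must contain at least one allele")
        if np.any(lengths < 1):
            raise InputError("repeat lengths must be >= 1")

    @property
    def n_alleles(self) -> int:
        return int(self.repeat_lengths.size)

    def modal_length(self) -> int:
        """True modal repeat length (ties go to the smaller length)."""
        uniq, counts = np.unique(self.repeat_lengths, return_counts=True)
        return int(uniq[int(np.argmax(counts))])


def simulate_population(
    config: SimConfig,
    times,
    rng: np.random.Generator | None = None,
) -> list[AllelePopulation]:
    """Evolve an allele population through the requested timepoints (days).

    ``times`` must be sorted, non-negative, and start at 0; the population
    at time 0 is ``n_alleles`` copies of ``initial_repeat``.  Gains and
    losses are drawn per interval as described in the module docstring and
    lengths are floored at 1.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise InputError("times must be non-empty")
    if np.any(times < 0):
        raise InputError("times must be non-negative")
    if np.any(np.diff(times) < 0):
        raise InputError("times must be sorted ascending")
    if times[0] != 0:
        raise InputError("times must start at 0 (the baseline)")
    if rng is None:
        rng = config.rng()

    lengths = np.full(config.n_alleles, config.initial_repeat, dtype=np.int64)
    pops = [AllelePopulation(lengths.copy(), 0.0)]
    for prev_t, t in zip(times[:-1], times[1:]):
        dt = t - prev_t
        factor = np.maximum(
            0.0, 1.0 + config.length_dependence * (lengths - config.initial_repeat)
        )
        gains = rng.poisson(config.gain_rate * config.rate_multiplier * dt * factor)
        losses = rng.poisson(config.loss_rate * dt * factor)
        lengths = np.maximum(1, lengths + gains - losses)
        pops.append(AllelePopulation(lengths.copy(), float(t)))
    return pops


def apply_stutter(
    population: AllelePopulation,
    stutter_ratio: float,
    stutter_orders: int,
) -> RepeatDistribution:
    """Render a population into a stuttered, normalised repeat distribution.

    Each allele of length L contributes relative mass ``stutter_ratio**k``
    at L-k for k = 0..stutter_orders (products shorter than one repeat are
    dropped); masses are summed per length and normalised to 1.  With
    ``stutter_ratio = 0`` this is the empirical length-frequency
    distribution.
    """
    if not 0 <= stutter_ratio < 1:
        raise InputError(f"stutter_ratio must be in [0, 1), got {stutter_ratio}")
    if stutter_orders < 0:
        raise InputError("stutter_orders must be >= 0")
    uniq, counts = np.unique(population.repeat_lengths, return_counts=True)
    lo = max(1, int(uniq.min()) - stutter_orders)
    acc = np.zeros(int(uniq.max()) - lo + 1)
    for k in range(stutter_orders + 1):
        pos = uniq - k
        valid = pos >= 1
        if not valid.any():
            break
        np.add.at(acc, pos[valid] - lo, counts[valid] * stutter_ratio**k)
    support = np.nonzero(acc > 0)[0]
    return RepeatDistribution.from_heights(support + lo, acc[support])


def synthesize_trace(
    dist: RepeatDistribution,
    size_map: SizeToRepeatMap,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    ladder_sizes=None,
) -> Electropherogram:
    """Render a repeat distribution as a noisy capillary trace.

    Peaks are Gaussian kernels of width ``trace_sigma_bp`` centred at each
    repeat's apparent bp position with apex heights proportional to mass,
    plus optional N(0, noise_sd) baseline noise (clipped at zero signal).
    The scan axis runs at :data:`SCANS_PER_BP` scans per bp over the ladder
    span, and the ladder channel is returned as its peak calls.
    """
    if config.trace_sigma_bp <= 0:
        raise InputError("trace_sigma_bp must be > 0")
    ladder_sizes = np.asarray(
        LADDER_SIZES_BP if ladder_sizes is None else ladder_sizes, dtype=float
    )
    positions_bp = np.asarray(size_map.repeat_to_bp(dist.repeats), dtype=float)
    n_scans = int(np.ceil(ladder_sizes.max() * SCANS_PER_BP)) + 1
    scans = np.arange(n_scans, dtype=np.int64)
    grid_bp = scans / SCANS_PER_BP
    kernels = np.exp(
        -0.5 * ((grid_bp[None, :] - positions_bp[:, None]) / config.trace_sigma_bp) ** 2
    )
    signal = TRACE_PEAK_SCALE * (dist.masses @ kernels)
    if config.noise_sd > 0:
        if rng is None:
            rng = config.rng()
        signal = signal + rng.normal(0.0, config.noise_sd, size=signal.shape)
    signal = np.clip(signal, 0.0, None)
    ladder_scans = np.round(ladder_sizes * SCANS_PER_BP).astype(np.int64)
    return Electropherogram(scans, signal, ladder_scans, ladder_sizes)


def expected_mean_gain(config: SimConfig, time_days: float) -> float:
    """Closed-form expected net repeat gain for the length-independent model."""
    if config.length_dependence != 0:
        raise InputError("closed form requires length_dependence == 0")
    return (
        config.gain_rate * config.rate_multiplier - config.loss_rate
    ) * float(time_days)


# ---------------------------------------------------------------------------
# Calibrated presets.  Gain rates were fixed by an analytic computation of
# the expected measurement readout (Poisson gains, geometric stutter, 20%
# modal-height threshold, infinite-allele limit); see docs/methods.md.
# ---------------------------------------------------------------------------

PRESETS: dict[str, SimConfig] = {
    # dividing iPSC control cultures: expected modal gain of 5 CAG at day 80
    "ipsc-control": SimConfig(gain_rate=0.07, n_alleles=10000),
    # post-mitotic striatal-neuron control cultures: expected fitted
    # instability-index slope of 0.20 units/week on a 0/3/6/9-week design
    "msn-control": SimConfig(gain_rate=0.03220567, n_alleles=10000),
}

#: Gain-rate multipliers emulating CRISPRi knockdown of each MutL factor in
#: striatal-neuron cultures, calibrated (by Monte-Carlo inversion of the
#: full measurement chain on the 9-week design) so the expected measured
#: instability-index slowing matches the knockdown effects the generator
#: emulates (~75/46/41/38% for MLH1/PMS1/PMS2/MLH3).
KNOCKDOWN_MULTIPLIERS: dict[str, float] = {
    "MLH1": 0.3162,
    "PMS1": 0.5804,
    "PMS2": 0.6304,
    "MLH3": 0.6652,
}


def preset(name: str, **overrides) -> SimConfig:
    """Return a named calibrated preset, optionally with field overrides."""
    try:
        base = PRESETS[name]
    except KeyError:
        raise InputError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
    return replace(base, **overrides) if overrides else base


_DEFAULT_SIZE_MAP = SizeToRepeatMap(bp_per_repeat=DEFAULT_BP_PER_REPEAT, intercept_bp=0.0)
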