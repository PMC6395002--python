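"""Competitive-fitness assay arithmetic and replicate aggregation.

Fitness is measured by competing a test strain against a fluorescently
labelled reference, reading the ratio of reference to test cells at two
timepoints ``t`` generations apart, and converting the log change in that
ratio to a per-generation selection coefficient.  The public interface works
in percent per generation throughout; natural log is used internally, as is
standard for Malthusian selection coefficients.

Sign convention
---------------
With ``r`` defined as reference/test, a fitter test strain makes ``r`` shrink,
so the raw quantity (1/t)·ln(r_f/r_i) is *negative* for a fitter test strain.
The default orientation ``"test"`` therefore returns the fitness of the test
strain relative to the reference, i.e. the negated raw quantity; pass
``orientation="reference"`` for the literal formula.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "RatioPair",
    "FounderRecord",
    "FitnessMeasurement",
    "RevertantTriplet",
    "competitive_fitness",
    "aggregate_measurements",
    "fitness_gain",
    "median_revertant",
]


@dataclass(frozen=True)
class RatioPair:
    """Reference/test cell-count ratios at two timepoints ``t`` generations apart."""

    r_initial: float
    r_final: float
    t: float = 20.0

    def __post_init__(self) -> None:
        if not (self.r_initial > 0 and self.r_final > 0):
            raise ValueError("cell-count ratios must be positive")
        if not self.t > 0:
            raise ValueError("elapsed generations t must be positive")


@dataclass(frozen=True)
class FounderRecord:
    """One deletion founder: gene, functional module, and initial fitness.

    ``initial_fitness`` (and its standard error) are in percent per
    generation relative to the wild-type ancestor.
    """

    gene: str
    module: str
    initial_fitness: float
    se: float = 0.0


@dataclass(frozen=True)
class FitnessMeasurement:
    """One replicate fitness measurement of one evolved population.

    Indices follow the nesting module ``i`` > founder gene ``j`` >
    population ``k`` > replicate ``l``; ``value`` is in percent per
    generation.  ``is_gain`` flags whether the value is a fitness gain
    relative to the founder (rather than raw fitness relative to wild type).
    """

    module: str
    gene: str
    population: int
    replicate: int
    value: float
    is_gain: bool = True

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError("fitness value must be finite")


@dataclass(frozen=True)
class RevertantTriplet:
    """Median-summarised fitnesses of three revertant clones from one population."""

    population: int | str
    clone_fitnesses: tuple[float, float, float]
    median: float
    outlier_flag: bool


def competitive_fitness(pair: RatioPair, orientation: str = "test") -> float:
    """Per-generation competitive fitness from a pair of ratio measurements.

    Returns s = (1/t)·ln(r_f/r_i) in percent per generation, with the sign
    oriented so that a fitter *test* strain is positive (default); see the
    module docstring for the convention.
    """
    raw = math.log(pair.r_final / pair.r_initial) / pair.t
    if orientation == "test":
        raw = -raw
    elif orientation != "reference":
        raise ValueError(f"unknown orientation {orientation!r}")
    return 100.0 * raw


def aggregate_measurements(values: Iterable[float]) -> tuple[float, float, float]:
    """Sample mean, sd (n-1 denominator) and standard error of measurements.

    A single value returns ``(value, nan, nan)`` — the sd of one measurement
    is undefined and flagged as NaN rather than zero.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one measurement")
    mean = float(arr.mean())
    if arr.size == 1:
        return mean, float("nan"), float("nan")
    sd = float(arr.std(ddof=1))
    return mean, sd, sd / math.sqrt(arr.size)


def fitness_gain(evolved_fitness: float, founder_fitness: float) -> float:
    """Fitness gain of an evolved population relative to its founder (%/gen)."""
    if not (math.isfinite(evolved_fitness) and math.isfinite(founder_fitness)):
        raise ValueError("fitnesses must be finite")
    return evolved_fitness - founder_fitness


def median_revertant(
    clone_fitnesses: Sequence[float],
    population: int | str = 0,
    outlier_sd_threshold: float = 0.5,
) -> RevertantTriplet:
    """Summarise three revertant-clone fitnesses by their median.

    Transformation occasionally introduces a de-novo mutation into one of the
    three independent transformants, which shows up as exactly one clone
    deviating from the other two.  The triplet is flagged as containing an
    outlier when the within-triplet sd exceeds ``outlier_sd_threshold``
    (default 0.5 %/gen) *and* the deviation is concentrated in a single
    clone (the two nearest clones agree to within the threshold).  The median
    is robust to that failure mode, which is why it is the summary used.
    """
    vals = tuple(float(v) for v in clone_fitnesses)
    if len(vals) != 3:
        raise ValueError("exactly three clone fitnesses are required")
    if not all(math.isfinite(v) for v in vals):
        raise ValueError("clone fitnesses must be finite")
    srt = sorted(vals)
    median = srt[1]
    sd = float(np.std(vals, ddof=1))
    one_deviant = min(srt[1] - srt[0], srt[2] - srt[1]) <= outlier_sd_threshold
    outlier = sd > outlier_sd_threshold and one_deviant
    return RevertantTriplet(population, vals, median, outlier)
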