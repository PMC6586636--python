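"""Callable genome, mutation frequencies, per-offspring rates and the
sperm-assay detection-fraction extrapolation.

The mutation-frequency denominator is *diploid* callable nucleotides: a
heterozygous de novo mutation is one event on one of two surveyed
chromosomes, so a count of 37 over 5 offspring each with 2.4 Gb diploid
callable sequence gives 37 / (5 x 2.4e9) = 3.1e-9 per nucleotide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .intervals import IntervalSet
from .stats import modified_wald_ci, poisson_rate_ci

__all__ = [
    "CallableRegions",
    "RateComparison",
    "callable_genome",
    "mutation_frequency",
    "rate_and_ratio",
    "expected_genome_mutations",
    "detection_fraction",
]


@dataclass
class CallableRegions:
    """Autosomal regions where mutations are detectable.

    ``total_bp`` is the haploid interval length; ``diploid_bp`` doubles it
    when ``diploid`` is set, matching a denominator expressed in diploid
    nucleotides.
    """

    intervals: IntervalSet
    diploid: bool = True

    @property
    def total_bp(self) -> int:
        return self.intervals.total_bp

    @property
    def diploid_bp(self) -> int:
        return self.total_bp * (2 if self.diploid else 1)


def callable_genome(
    coverage: IntervalSet,
    repeat_mask: Optional[IntervalSet] = None,
    autosomes_only: bool = True,
    diploid: bool = True,
) -> CallableRegions:
    """Coverage (>=10x) minus repeat-masked sequence, restricted to autosomes.

    Both inputs must share the package's 1-based inclusive convention (BED
    files are converted on read). The operation is a per-base set difference;
    it is idempotent and invariant to how the inputs split their intervals.
    """
    regions = coverage
    if autosomes_only:
        regions = regions.restrict_autosomes()
    if repeat_mask is not None:
        mask = repeat_mask.restrict_autosomes() if autosomes_only else repeat_mask
        regions = regions.difference(mask)
    return CallableRegions(intervals=regions, diploid=diploid)


def mutation_frequency(count: int, callable_diploid_bp: float, n_animals: int) -> float:
    """Per-nucleotide de novo mutation frequency.

    ``count`` is the number of de novo mutations (VAF > 0.39) across
    ``n_animals`` offspring, each surveyed over ``callable_diploid_bp``
    diploid callable nucleotides.
    """
    if callable_diploid_bp <= 0:
        raise ValueError("callable genome size must be positive")
    if n_animals <= 0:
        raise ValueError("need at least one animal")
    if count < 0:
        raise ValueError("count must be non-negative")
    return count / (callable_diploid_bp * n_animals)


@dataclass
class RateComparison:
    """Per-group mutation burden with its contrast to the control group."""

    group: str
    n_offspring: int
    count: int
    rate: float
    ci_low: float
    ci_high: float
    ratio_to_control: Optional[float] = None
    p_value: Optional[float] = None
    p_adjusted: Optional[float] = None
    notes: List[str] = field(default_factory=list)


def rate_and_ratio(
    groups: Dict[str, Tuple[int, int]],
    control: str,
    ci_method: str = "poisson",
) -> List[RateComparison]:
    """Per-offspring rates with 95% CIs and ratios to the control group.

    Parameters
    ----------
    groups : mapping group label -> (mutation count, number of offspring);
        insertion order is preserved in the output.
    control : label of the control group (must be present).
    ci_method : "poisson" (exact, for SNV/indel counts) or "wald"
        (modified-Wald binomial, for CNV frequencies).

    When the control rate is zero the ratio is computed against the upper
    bound of the control group's 95% CI (flagged in ``notes``), mirroring the
    convention used for frequency tables with empty control cells.
    """
    if control not in groups:
        raise ValueError(f"control group {control!r} missing")
    out: List[RateComparison] = []
    ctrl_count, ctrl_n = groups[control]
    if ctrl_n <= 0:
        raise ValueError("control group size must be positive")

    def _ci(count: int, n: int) -> Tuple[float, float]:
        if ci_method == "poisson":
            return poisson_rate_ci(count, n)
        if ci_method == "wald":
            return modified_wald_ci(count, n)
        raise ValueError(f"unknown ci_method {ci_method!r}")

    ctrl_rate = ctrl_count / ctrl_n
    ctrl_ci = _ci(ctrl_count, ctrl_n)
    for label, (count, n) in groups.items():
        if n <= 0:
            raise ValueError(f"group {label!r} has no offspring")
        rate = count / n
        lo, hi = _ci(count, n)
        rc = RateComparison(label, n, count, rate, lo, hi)
        if label != control:
            if ctrl_rate > 0:
                rc.ratio_to_control = rate / ctrl_rate
            else:
                rc.ratio_to_control = rate / ctrl_ci[1]
                rc.notes.append("control rate 0; ratio uses control 95% CI upper bound")
        out.append(rc)
    return out


def expected_genome_mutations(assay_count: float, assay_surveyed_bp: float, genome_bp: float) -> float:
    """Extrapolate a targeted-assay mutation count to a whole genome.

    ``assay_count`` mutations observed over ``assay_surveyed_bp`` total
    surveyed nucleotides imply ``assay_count / assay_surveyed_bp * genome_bp``
    mutations for a genome of ``genome_bp`` nucleotides, assuming mutations
    are uniformly distributed. ``genome_bp`` is an explicit parameter (diploid
    genome size), not a constant.
    """
    if assay_surveyed_bp <= 0:
        raise ValueError("surveyed bp must be positive")
    if genome_bp <= 0:
        raise ValueError("genome bp must be positive")
    return assay_count / assay_surveyed_bp * genome_bp


def detection_fraction(observed_per_offspring: float, expected_per_genome: float) -> float:
    """Percent of extrapolated per-genome mutations actually detected."""
    if expected_per_genome <= 0:
        raise ValueError("expected mutations per genome must be positive (undefined fraction)")
    return observed_per_offspring / expected_per_genome * 100.0
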