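"""Demographic side computations for founder-variant dating.

Holds the demography configuration shared by both age estimators, the
carrier-prevalence projection, generation/year conversion, the
Luria-Delbruck growing-population clock correction, and the
sampled-proportion bookkeeping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .datamodel import ValidationError, cM_to_recombination_fraction

#: The growing-population clock correction reported by the original
#: founder-dating study of MYOC p.Cys433Arg (kept for regression
#: reporting only; no standard Luria-Delbruck formula reproduces it from
#: the stated growth rate and flanking recombination fraction, so it is
#: never asserted as the output of the methods below).
REPORTED_G0_REFERENCE = 4.25


@dataclass(frozen=True)
class DemographyConfig:
    """Population history inputs shared by the age estimators.

    ``growth_rate`` is the per-generation proportional growth of the
    mutant-allele class (the study used the long-run Brazilian population
    growth rate 0.095); ``sampled_proportion`` is the fraction of all
    mutant chromosomes in the population present in the sample;
    ``generation_years`` converts generations to calendar years for
    reporting; ``max_age`` bounds the uniform age prior.
    """

    growth_rate: float = 0.095
    sampled_proportion: float = 0.0294
    generation_years: float = 20.0
    max_age: int = 500

    def __post_init__(self) -> None:
        if self.growth_rate <= -1:
            raise ValidationError("growth_rate must exceed -1")
        if not (0 < self.sampled_proportion <= 1):
            raise ValidationError("sampled_proportion must be in (0, 1]")
        if self.generation_years <= 0:
            raise ValidationError("generation_years must be positive")
        if self.max_age < 2:
            raise ValidationError("max_age must be at least 2")


@dataclass(frozen=True)
class PrevalenceInputs:
    """Inputs of the regional carrier-count projection."""

    world_affected: float
    world_pop: float
    region_pop: float
    variant_freq_in_affected: float

    def __post_init__(self) -> None:
        for name in ("world_affected", "world_pop", "region_pop"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not (0 <= self.variant_freq_in_affected <= 1):
            raise ValidationError("variant_freq_in_affected must be in [0, 1]")
        if self.world_affected > self.world_pop:
            raise ValidationError("world_affected cannot exceed world_pop")


#: The study's printed projection inputs: JOAG cases worldwide (WHO),
#: world population, Southeast-Brazil population (IBGE), and the share of
#: MYOC-variant JOAG patients carrying p.Cys433Arg.
STUDY_PREVALENCE_INPUTS = PrevalenceInputs(
    world_affected=150_000,
    world_pop=7_465_000_000,
    region_pop=80_350_000,
    variant_freq_in_affected=0.30,
)


def estimate_regional_carriers(inputs: PrevalenceInputs) -> int:
    """Projected number of variant chromosomes in the region.

    Scales the worldwide disease prevalence to the regional population
    and multiplies by the variant's share among affected individuals;
    rounded half-up to whole chromosomes (carriers are heterozygous, so
    this is also the projected number of carrier persons).
    """
    value = (
        inputs.region_pop
        * (inputs.world_affected / inputs.world_pop)
        * inputs.variant_freq_in_affected
    )
    return int(math.floor(value + 0.5))


def generations_to_years(g: float, generation_years: float) -> float:
    """Exact product; the study reports ages at 20 years per generation."""
    if g < 0:
        raise ValidationError("generations must be non-negative")
    if generation_years <= 0:
        raise ValidationError("generation_years must be positive")
    return g * generation_years


def sampled_proportion(n_sampled_chromosomes: int, estimated_total: int) -> float:
    """Fraction of the population's mutant chromosomes present in the sample.

    Note: for the study's own counts (51 sampled, 484 projected) this is
    0.1054, which does not reproduce the 0.0294 the study entered into
    its dating software; the proportion is therefore always an explicit
    config input rather than derived.
    """
    if n_sampled_chromosomes <= 0:
        raise ValidationError("n_sampled_chromosomes must be positive")
    if estimated_total < n_sampled_chromosomes:
        raise ValidationError("estimated_total must be at least n_sampled_chromosomes")
    return n_sampled_chromosomes / estimated_total


# ---------------------------------------------------------------------------
# Luria-Delbruck clock correction


@dataclass(frozen=True)
class ClockCorrection:
    """Extra "silent" generations of an LD clock in a growing allele class.

    While the mutant class is small, recombination events are rarer than
    the equilibrium clock assumes, so LD-based ages underestimate the
    true age; ``g0`` is the expected number of generations elapsed before
    the class experiences its first recombination within the flanking
    interval.
    """

    growth_rate: float
    flank_rec_frac: float
    g0: float
    method: str  # simulation | closed_form_variant
    mc_se: Optional[float] = None
    seed: Optional[int] = None


def luria_delbruck_g0(
    d: float,
    c: float,
    method: str = "simulation",
    n_reps: int = 100_000,
    seed: int = 0,
    max_generations: int = 100_000,
) -> ClockCorrection:
    """Expected generations before the first recombination in a growing class.

    ``d`` is the per-generation growth rate and ``c`` the per-meiosis
    recombination probability across the flanking interval (convert a cM
    distance with :func:`founderage.datamodel.cM_to_recombination_fraction`
    first).  The default simulation draws, per replicate, the generation
    of the first recombination when the class grows deterministically as
    ``(1+d)**g`` from one copy and each copy recombines independently
    with probability ``c`` per generation; ``g0`` is the mean with a
    Monte-Carlo standard error.  ``closed_form_variant`` evaluates
    ``ln(1 + d/c) / ln(1 + d)`` — the deterministic-growth first-event
    time — as one published reading of the correction.
    """
    if d <= 0:
        raise ValidationError("growth rate d must be positive")
    if not (0 < c < 0.5):
        raise ValidationError("flank recombination fraction c must be in (0, 0.5)")
    if method == "closed_form_variant":
        g0 = math.log(1.0 + d / c) / math.log(1.0 + d)
        return ClockCorrection(d, c, g0, method)
    if method != "simulation":
        raise ValidationError(f"unknown method {method!r}")
    # survival function S(g) = P(no recombination in generations 1..g)
    # with hazard 1-(1-c)^{N_g}, N_g = (1+d)^{g-1} copies during generation g
    log1mc = math.log1p(-c)
    surv = [1.0]
    s = 1.0
    g = 0
    while s > 1e-12 and g < max_generations:
        g += 1
        n_copies = (1.0 + d) ** (g - 1)
        s *= math.exp(log1mc * n_copies)
        surv.append(s)
    surv_arr = np.array(surv)
    rng = np.random.default_rng(seed)
    u = rng.random(n_reps)
    # first generation g with S(g) < u  (inverse-CDF sampling of the
    # discrete first-event distribution)
    draws = np.searchsorted(-surv_arr, -u, side="right")
    g0 = float(draws.mean())
    se = float(draws.std(ddof=1) / math.sqrt(n_reps))
    return ClockCorrection(d, c, g0, "simulation", mc_se=se, seed=seed)


def flank_correction_from_cM(
    d: float,
    flank_cM: float = 0.0076,
    map_function: str = "haldane",
    method: str = "simulation",
    n_reps: int = 100_000,
    seed: int = 0,
) -> ClockCorrection:
    """Convenience wrapper: convert the flanking interval from cM first."""
    c = cM_to_recombination_fraction(flank_cM, map_function)
    return luria_delbruck_g0(d, c, method=method, n_reps=n_reps, seed=seed)


def corrected_age(estimate, correction: ClockCorrection):
    """Shift an age estimate by the clock correction (CI width preserved)."""
    from .coalescent import AgeEstimate  # local import to avoid a cycle

    if not isinstance(estimate, AgeEstimate):
        raise ValidationError("corrected_age expects an AgeEstimate")
    g0 = correction.g0
    return replace(
        estimate,
        samples=estimate.samples + g0 if estimate.samples is not None else None,
        mode=estimate.mode + g0,
        ci95=(estimate.ci95[0] + g0, estimate.ci95[1] + g0),
        note=(
            estimate.note
            + f" | Luria-Delbruck corrected: +{g0:g} generations ({correction.method})"
        ).strip(" |"),
    )
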