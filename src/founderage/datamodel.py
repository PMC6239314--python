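"""Core domain types for founder-haplotype dating.

A study panel is a small set of ordered STR/SNP markers flanking a focal
disease variant, together with a genetic map.  Carrier and control
chromosomes typed at those markers are represented as :class:`Haplotype`
objects collected in a :class:`HaplotypeSet`, which also carries the
per-marker population allele frequencies estimated from control
chromosomes.  Ages are expressed in generations throughout; years are a
reporting conversion only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

#: Reserved symbol for a missing/unknown allele (also used for an
#: undetermined phase after pedigree analysis).
MISSING = "."

STR = "STR"
SNP = "SNP"

_SNP_LETTERS = frozenset("ACGT")


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


# ---------------------------------------------------------------------------
# map functions


def haldane_cM_to_theta(distance_cM: float) -> float:
    """Haldane map function: theta = (1 - exp(-2 d)) / 2 with d in Morgans."""
    if distance_cM < 0:
        raise ValidationError(f"negative genetic distance: {distance_cM} cM")
    return 0.5 * (1.0 - math.exp(-2.0 * distance_cM / 100.0))


def morgan_cM_to_theta(distance_cM: float) -> float:
    """Morgan (linear) map function: theta = d in Morgans, capped at 0.5."""
    if distance_cM < 0:
        raise ValidationError(f"negative genetic distance: {distance_cM} cM")
    return min(distance_cM / 100.0, 0.5)


_MAP_FUNCTIONS = {"haldane": haldane_cM_to_theta, "morgan": morgan_cM_to_theta}


def cM_to_recombination_fraction(distance_cM: float, map_function: str = "haldane") -> float:
    """Convert a genetic distance in centimorgans to a recombination fraction.

    ``map_function`` is ``"haldane"`` (default) or ``"morgan"``.  At the
    sub-centimorgan distances relevant to a conserved founder core the two
    agree to well under a part in a thousand.
    """
    try:
        fn = _MAP_FUNCTIONS[map_function]
    except KeyError:
        raise ValidationError(
            f"unknown map function {map_function!r}; choose from {sorted(_MAP_FUNCTIONS)}"
        ) from None
    return fn(distance_cM)


# ---------------------------------------------------------------------------
# markers and panels


@dataclass(frozen=True)
class Marker:
    """A single typed locus: an STR (integer-coded alleles) or a SNP."""

    name: str
    kind: str  # STR or SNP
    chrom: str
    position_bp: int
    genetic_pos_cM: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in (STR, SNP):
            raise ValidationError(f"marker {self.name}: kind must be STR or SNP, got {self.kind!r}")
        if self.position_bp <= 0:
            raise ValidationError(f"marker {self.name}: position_bp must be positive (1-based)")

    def validate_allele(self, allele: str) -> None:
        """Check one allele symbol against this marker's alphabet.

        STR alleles are integer codes assigned in ascending size order;
        SNP alleles are single nucleotide letters.  ``MISSING`` always
        passes.
        """
        if allele == MISSING:
            return
        if self.kind == STR:
            try:
                val = int(allele)
            except ValueError:
                raise ValidationError(
                    f"marker {self.name}: STR allele {allele!r} is not an integer code"
                ) from None
            if val < 1:
                raise ValidationError(f"marker {self.name}: STR allele codes start at 1, got {val}")
        else:
            if allele not in _SNP_LETTERS:
                raise ValidationError(
                    f"marker {self.name}: SNP allele {allele!r} is not one of A/C/G/T"
                )


@dataclass(frozen=True)
class MarkerPanel:
    """Ordered flanking markers plus the focal variant they bracket.

    The focal variant is represented as a marker-like locus (its two
    "alleles" are the wild-type and mutant nucleotides) whose physical
    position must fall inside the panel span.  Markers upstream of the
    variant (smaller bp) are labelled ``proximal``, downstream ``distal``.
    """

    markers: tuple[Marker, ...]
    focal_variant: Marker
    window_bp: int = 5_000_000

    def __post_init__(self) -> None:
        object.__setattr__(self, "markers", tuple(self.markers))
        if not self.markers:
            raise ValidationError("panel needs at least one marker")
        pos = [m.position_bp for m in self.markers]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValidationError("panel markers must be strictly ordered by position_bp")
        v = self.focal_variant.position_bp
        if v in pos:
            raise ValidationError("focal variant cannot share a position with a marker")
        if len(pos) >= 2 and not (pos[0] < v < pos[-1]):
            raise ValidationError(
                "focal variant position must lie strictly within the panel's physical span"
            )
        if pos[-1] - pos[0] > self.window_bp:
            raise ValidationError(
                f"panel span {pos[-1] - pos[0]} bp exceeds the configured window of {self.window_bp} bp"
            )
        names = [m.name for m in self.markers] + [self.focal_variant.name]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate marker names in panel")

    def __len__(self) -> int:
        return len(self.markers)

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.markers]

    def side(self, marker: Marker) -> str:
        """'proximal' for markers upstream of the variant, 'distal' downstream."""
        return "proximal" if marker.position_bp < self.focal_variant.position_bp else "distal"

    def index(self, name: str) -> int:
        for i, m in enumerate(self.markers):
            if m.name == name:
                return i
        raise KeyError(name)

    @property
    def variant_insert_index(self) -> int:
        """Number of markers proximal to the variant (the variant slots in here)."""
        return sum(1 for m in self.markers if m.position_bp < self.focal_variant.position_bp)


# ---------------------------------------------------------------------------
# genetic map


@dataclass(frozen=True)
class GeneticMap:
    """Piecewise-linear physical-to-genetic map from (bp, cM) anchor pairs.

    The study-style default — used when no interpolated map is available —
    is a uniform 1 cM/Mb map over the panel window, which at these scales
    is the conventional sex-averaged human genome-wide average.
    """

    anchors: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "anchors", tuple((int(b), float(c)) for b, c in self.anchors))
        if len(self.anchors) < 2:
            raise ValidationError("a genetic map needs at least two anchors")
        bps = [a[0] for a in self.anchors]
        cms = [a[1] for a in self.anchors]
        if any(b2 <= b1 for b1, b2 in zip(bps, bps[1:])):
            raise ValidationError("map anchors must be strictly increasing in bp")
        if any(c2 <= c1 for c1, c2 in zip(cms, cms[1:])):
            raise ValidationError("map anchors must be strictly increasing in cM")

    @classmethod
    def uniform(cls, start_bp: int, end_bp: int, rate_cM_per_Mb: float = 1.0) -> "GeneticMap":
        """A constant-rate map covering [start_bp, end_bp]."""
        span_cM = (end_bp - start_bp) * rate_cM_per_Mb / 1e6
        return cls(anchors=((start_bp, 0.0), (end_bp, span_cM)))

    def interpolate(self, position_bp: int, extrapolate: bool = False) -> float:
        """Genetic position (cM) of ``position_bp`` by linear interpolation.

        Exact at anchors.  Outside the anchor span the boundary segment's
        rate is extended only when ``extrapolate`` is True.
        """
        bps = [a[0] for a in self.anchors]
        cms = [a[1] for a in self.anchors]
        if not extrapolate and not (bps[0] <= position_bp <= bps[-1]):
            raise ValidationError(
                f"position {position_bp} outside map anchor span [{bps[0]}, {bps[-1]}] "
                "(pass extrapolate=True to extend the boundary segments)"
            )
        if position_bp <= bps[0]:
            i = 0
        elif position_bp >= bps[-1]:
            i = len(bps) - 2
        else:
            i = int(np.searchsorted(bps, position_bp, side="right")) - 1
        b0, c0 = bps[i], cms[i]
        b1, c1 = bps[i + 1], cms[i + 1]
        return c0 + (c1 - c0) * (position_bp - b0) / (b1 - b0)

    def distance_cM(self, pos_a: int, pos_b: int, extrapolate: bool = False) -> float:
        return abs(self.interpolate(pos_a, extrapolate) - self.interpolate(pos_b, extrapolate))

    def rec_fracs_to_variant(
        self,
        panel: MarkerPanel,
        map_function: str = "haldane",
        extrapolate: bool = False,
    ) -> np.ndarray:
        """Per-marker recombination fraction to the focal variant (theta_i)."""
        v = panel.focal_variant.position_bp
        theta = np.array(
            [
                cM_to_recombination_fraction(
                    self.distance_cM(m.position_bp, v, extrapolate), map_function
                )
                for m in panel.markers
            ]
        )
        return theta


# ---------------------------------------------------------------------------
# genotypes and haplotypes

CARRIER = "carrier"
CONTROL = "control"
_STATUSES = (CARRIER, CONTROL)
_VARIANT_GENOTYPES = ("het", "hom", "absent")


@dataclass
class GenotypeRecord:
    """Unphased genotypes of one individual across the panel markers."""

    sample_id: str
    status: str
    genotypes: dict[str, tuple[str, str]]  # marker name -> unordered allele pair
    variant_genotype: str = "absent"
    family_id: Optional[str] = None

    def validate(self, panel: MarkerPanel) -> None:
        if self.status not in _STATUSES:
            raise ValidationError(
                f"sample {self.sample_id}: status {self.status!r} not in {set(_STATUSES)}"
            )
        if self.variant_genotype not in _VARIANT_GENOTYPES:
            raise ValidationError(
                f"sample {self.sample_id}: variant_genotype {self.variant_genotype!r} "
                f"not in {set(_VARIANT_GENOTYPES)}"
            )
        if self.status == CARRIER and self.variant_genotype == "absent":
            raise ValidationError(
                f"sample {self.sample_id}: carriers must have variant_genotype het or hom"
            )
        for m in panel.markers:
            if m.name not in self.genotypes:
                raise ValidationError(f"sample {self.sample_id}: missing genotype for {m.name}")
            for allele in self.genotypes[m.name]:
                try:
                    m.validate_allele(allele)
                except ValidationError as exc:
                    raise ValidationError(f"sample {self.sample_id}: {exc}") from None
        for name in self.genotypes:
            if name not in panel.names:
                raise ValidationError(
                    f"sample {self.sample_id}: genotype for unknown marker {name!r}"
                )


@dataclass(frozen=True)
class Haplotype:
    """One phased chromosome across the panel markers.

    ``alleles`` is aligned to panel order; ``MISSING`` marks either an
    untyped allele or a site whose phase could not be determined.
    ``source`` records how the phase was obtained.
    """

    alleles: tuple[str, ...]
    carries_variant: bool
    source: str = "simulated"  # pedigree | EM | simulated
    sample_id: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "alleles", tuple(self.alleles))

    def validate(self, panel: MarkerPanel) -> None:
        if len(self.alleles) != len(panel):
            raise ValidationError(
                f"haplotype length {len(self.alleles)} does not match panel size {len(panel)}"
            )
        for m, a in zip(panel.markers, self.alleles):
            m.validate_allele(a)


def allele_frequencies(
    chromosomes: Sequence[Sequence[str]], panel: MarkerPanel
) -> list[dict[str, float]]:
    """Per-marker allele relative frequencies from a set of chromosomes.

    Missing alleles are excluded marker-wise from the denominator.
    """
    freqs: list[dict[str, float]] = []
    for i, m in enumerate(panel.markers):
        counts: dict[str, int] = {}
        for chrom in chromosomes:
            a = chrom[i]
            if a != MISSING:
                counts[a] = counts.get(a, 0) + 1
        total = sum(counts.values())
        if total == 0:
            freqs.append({})
        else:
            freqs.append({a: c / total for a, c in sorted(counts.items())})
    return freqs


@dataclass
class HaplotypeSet:
    """Carrier and control chromosomes plus control allele frequencies."""

    haplotypes: list[Haplotype]
    panel: MarkerPanel
    population_allele_freqs: Optional[list[dict[str, float]]] = None

    def __post_init__(self) -> None:
        for h in self.haplotypes:
            h.validate(self.panel)
        if self.population_allele_freqs is not None:
            for i, table in enumerate(self.population_allele_freqs):
                if table and abs(sum(table.values()) - 1.0) > 1e-9:
                    raise ValidationError(
                        f"allele frequencies at marker {self.panel.markers[i].name} "
                        f"sum to {sum(table.values())}, not 1"
                    )

    @property
    def carriers(self) -> list[Haplotype]:
        return [h for h in self.haplotypes if h.carries_variant]

    @property
    def controls(self) -> list[Haplotype]:
        return [h for h in self.haplotypes if not h.carries_variant]

    def with_control_frequencies(self) -> "HaplotypeSet":
        """Recompute population allele frequencies from the control chromosomes."""
        freqs = allele_frequencies([h.alleles for h in self.controls], self.panel)
        return HaplotypeSet(self.haplotypes, self.panel, freqs)


# ---------------------------------------------------------------------------
# integer encodings shared by the numerical modules


@dataclass(frozen=True)
class EncodedPanel:
    """Carrier haplotypes and frequencies encoded as integer/real arrays.

    Per marker, alleles are mapped to consecutive integer codes covering
    every allele seen on a carrier chromosome or with positive control
    frequency; code -1 is missing.  ``freq[i, k]`` holds the population
    frequency of allele code ``k`` at marker ``i``; alleles observed on
    carriers but absent from controls receive the documented frequency
    floor (renormalisation keeps each row a probability vector).
    """

    X: np.ndarray  # (n_chrom, n_markers) int16 allele codes, -1 = missing
    freq: np.ndarray  # (n_markers, max_alleles) float, rows sum to 1 over valid codes
    n_alleles: np.ndarray  # (n_markers,) number of valid codes per marker
    alphabets: tuple[tuple[str, ...], ...]  # code -> allele symbol per marker
    theta: np.ndarray  # (n_markers,) recombination fraction to the variant

    FREQ_FLOOR = 1e-12

    def decode(self, codes: Sequence[int]) -> tuple[str, ...]:
        return tuple(
            MISSING if c < 0 else self.alphabets[i][int(c)] for i, c in enumerate(codes)
        )

    def encode_haplotype(self, alleles: Sequence[str]) -> np.ndarray:
        out = np.full(len(alleles), -1, dtype=np.int16)
        for i, a in enumerate(alleles):
            if a == MISSING:
                continue
            try:
                out[i] = self.alphabets[i].index(a)
            except ValueError:
                raise ValidationError(
                    f"allele {a!r} at marker index {i} is outside the encoded alphabet"
                ) from None
        return out


def encode_carriers(
    carriers: Sequence[Haplotype] | Sequence[Sequence[str]],
    freqs: Sequence[Mapping[str, float]],
    theta: np.ndarray,
) -> EncodedPanel:
    """Build the dense encoding used by the age estimators.

    ``carriers`` may be Haplotype objects or plain allele sequences; the
    marker count must match ``freqs`` and ``theta``.
    """
    rows = [h.alleles if isinstance(h, Haplotype) else tuple(h) for h in carriers]
    m = len(theta)
    if any(len(r) != m for r in rows):
        raise ValidationError("carrier haplotype length does not match the marker count")
    alphabets: list[tuple[str, ...]] = []
    for i in range(m):
        seen = set(a for a, f in freqs[i].items() if f > 0)
        seen.update(r[i] for r in rows if r[i] != MISSING)
        alphabets.append(tuple(sorted(seen)))
    max_k = max((len(a) for a in alphabets), default=1)
    freq = np.zeros((m, max(max_k, 1)))
    n_alleles = np.zeros(m, dtype=np.int64)
    for i, alpha in enumerate(alphabets):
        n_alleles[i] = len(alpha)
        for k, a in enumerate(alpha):
            freq[i, k] = max(freqs[i].get(a, 0.0), EncodedPanel.FREQ_FLOOR)
        if len(alpha):
            freq[i, : len(alpha)] /= freq[i, : len(alpha)].sum()
    X = np.full((len(rows), m), -1, dtype=np.int16)
    for j, r in enumerate(rows):
        for i, a in enumerate(r):
            if a != MISSING:
                X[j, i] = alphabets[i].index(a)
    return EncodedPanel(
        X=X,
        freq=freq,
        n_alleles=n_alleles,
        alphabets=tuple(alphabets),
        theta=np.asarray(theta, dtype=float),
    )
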