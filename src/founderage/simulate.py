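"""Synthetic founder-mutation panels with known truth.

The generator emulates the data shape of a founder-variant dating study:
a 5 Mb panel of STR/SNP markers around a dominant disease variant, a set
of carrier chromosomes descending from a single founding mutation, and
unrelated population controls.  The mutant class grows by a forward
linear birth-death process; carrier chromosomes are leaves of the
extracted genealogy; recombination is laid down per branch with
proximal-crossover-censors-distal semantics (the first crossover on a
flank replaces every marker beyond it with population material); and
carriers are diploidised against control chromosomes, matching dominant
inheritance with heterozygous carriers.  The true age, ancestral
haplotype, genealogy and realised copy number are recorded for scoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .birthdeath import BirthDeathParams, _extract_genealogy
from .datamodel import (
    CARRIER,
    CONTROL,
    MISSING,
    SNP,
    STR,
    GenotypeRecord,
    GeneticMap,
    Haplotype,
    HaplotypeSet,
    Marker,
    MarkerPanel,
    ValidationError,
    allele_frequencies,
)
from .demography import DemographyConfig
from .phasing import Pedigree, PedigreeMember
from .trees import Genealogy


@dataclass(frozen=True)
class SimulationConfig:
    true_age: float
    panel: MarkerPanel
    gmap: GeneticMap
    control_allele_freqs: tuple[dict[str, float], ...]
    demography: DemographyConfig = DemographyConfig()
    n_carriers: int = 51
    n_control_individuals: int = 32
    family_sizes: tuple[int, ...] = ()
    str_mutation_rate: float = 0.0
    background_pool_size: Optional[int] = None  # draw controls from a small
    # haplotype pool to inject background LD; None = linkage equilibrium
    condition_copies: Optional[tuple[int, int]] = None  # accept only
    # realisations whose surviving copy number falls in this band (used to
    # pin the realised class size to an externally implied value, e.g.
    # n / sampled_proportion)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_age < 1:
            raise ValidationError("true_age must be at least 1 generation")
        if self.n_carriers < 1 or self.n_control_individuals < 0:
            raise ValidationError("sample sizes must be positive")
        if sum(self.family_sizes) > self.n_carriers:
            raise ValidationError("family sizes cannot exceed the carrier count")
        if any(k < 1 for k in self.family_sizes):
            raise ValidationError("each family needs at least one affected member")
        if len(self.control_allele_freqs) != len(self.panel):
            raise ValidationError("control_allele_freqs must cover every panel marker")
        for i, table in enumerate(self.control_allele_freqs):
            if not table or abs(sum(table.values()) - 1.0) > 1e-9:
                raise ValidationError(
                    f"control frequencies at marker {self.panel.markers[i].name} "
                    "must be a valid simplex"
                )

    @property
    def n_founder_lineages(self) -> int:
        """Independent mutant lineages sampled from the genealogy: one per
        family plus every unrelated carrier."""
        return self.n_carriers - sum(self.family_sizes) + len(self.family_sizes)


@dataclass
class FounderSimResult:
    haplotype_set: HaplotypeSet
    records: list[GenotypeRecord]
    pedigree: Pedigree
    pedigree_rows: list[tuple]
    truth: dict
    config: SimulationConfig

    @property
    def carrier_haplotypes(self) -> list[Haplotype]:
        return self.haplotype_set.carriers


def _draw_control_chromosome(
    freqs: Sequence[dict[str, float]], rng: np.random.Generator
) -> list[str]:
    return [
        str(rng.choice(list(t.keys()), p=list(t.values())))
        for t in freqs
    ]


def _control_source(
    config: SimulationConfig, rng: np.random.Generator
) -> Callable[[], list[str]]:
    freqs = config.control_allele_freqs
    if config.background_pool_size is None:
        return lambda: _draw_control_chromosome(freqs, rng)
    pool = [_draw_control_chromosome(freqs, rng) for _ in range(config.background_pool_size)]
    return lambda: list(pool[rng.integers(len(pool))])


def _genetic_distances(panel: MarkerPanel, gmap: GeneticMap) -> np.ndarray:
    """Per-marker distance to the variant in Morgans (crossovers are laid
    down on the genetic scale, so the Morgan distance is the Poisson rate)."""
    v = panel.focal_variant.position_bp
    return np.array(
        [gmap.distance_cM(m.position_bp, v, extrapolate=True) / 100.0 for m in panel.markers]
    )


def _recombine(
    alleles: list[str],
    n_meioses: float,
    dist: np.ndarray,
    is_left: np.ndarray,
    fresh: Callable[[], list[str]],
    rng: np.random.Generator,
) -> list[str]:
    """Apply ``n_meioses`` generations of recombination to one chromosome.

    Per flank, the genetic position of the first crossover is
    exponential with rate ``n_meioses`` per Morgan; markers beyond it are
    replaced from a fresh population chromosome (later crossovers only
    reshuffle population material, which is neutral at linkage
    equilibrium).
    """
    out = list(alleles)
    if n_meioses <= 0:
        return out
    for side_mask in (is_left, ~is_left):
        g = rng.exponential(1.0 / n_meioses)
        hit = side_mask & (dist > g)
        if np.any(hit):
            repl = fresh()
            for i in np.nonzero(hit)[0]:
                out[i] = repl[i]
    return out


def _mutate_strs(
    alleles: list[str],
    n_meioses: float,
    rate: float,
    is_str: np.ndarray,
    rng: np.random.Generator,
) -> list[str]:
    if rate <= 0 or n_meioses <= 0:
        return alleles
    out = list(alleles)
    for i in np.nonzero(is_str)[0]:
        k = rng.poisson(rate * n_meioses)
        if k:
            steps = int(rng.choice([-1, 1], size=k).sum())
            out[i] = str(max(1, int(out[i]) + steps))
    return out


def _drop_down_genealogy(
    ancestral: list[str],
    tree: Genealogy,
    dist: np.ndarray,
    is_left: np.ndarray,
    is_str: np.ndarray,
    str_rate: float,
    fresh: Callable[[], list[str]],
    rng: np.random.Generator,
) -> list[list[str]]:
    """Transmit the ancestral haplotype to every leaf along the genealogy."""
    kids = tree.children()
    haps: dict[int, list[str]] = {}
    stack = [(tree.root, ancestral)]
    while stack:
        node, parent_hap = stack.pop()
        L = tree.branch_length(node)
        h = _recombine(parent_hap, L, dist, is_left, fresh, rng)
        h = _mutate_strs(h, L, str_rate, is_str, rng)
        if node < tree.n_leaves:
            haps[node] = h
        for c in kids[node]:
            stack.append((c, h))
    return [haps[i] for i in range(tree.n_leaves)]


def _simulate_genealogy_with_size(
    n_leaves: int, t: float, params: BirthDeathParams, rng: np.random.Generator,
    max_retries: int = 10_000,
    copies_band: Optional[tuple[int, int]] = None,
) -> tuple[Genealogy, int]:
    from ._kernels import bd_forward

    cap = int(1000 + 40 * math.exp(params.growth * t))
    if copies_band is not None:
        cap = max(cap, 10 * copies_band[1])
    for _ in range(max_retries):
        kseed = int(rng.integers(2**31 - 1))
        status, _count, parent_rec, tbirth, alive, n_alive = bd_forward(
            float(t), params.birth_rate, params.death_rate, kseed, cap
        )
        if status == 1:
            cap *= 2
            continue
        if n_alive < n_leaves:
            continue
        if copies_band is not None and not (
            copies_band[0] <= n_alive <= copies_band[1]
        ):
            continue
        sample = rng.choice(alive[:n_alive], size=n_leaves, replace=False)
        tree = _extract_genealogy(parent_rec, tbirth, list(map(int, sample)), float(t))
        return tree, int(n_alive)
    raise ValidationError(
        f"mutant class kept going extinct or staying below {n_leaves} copies at "
        f"age {t}; retries exhausted"
    )


def simulate_founder_panel(config: SimulationConfig) -> FounderSimResult:
    """Generate a case/control panel descending from one founding mutation.

    Families are expanded from one founder lineage each: the family
    founder carries a genealogy leaf chromosome, spouses are population
    controls, and affected children inherit the variant chromosome
    through an explicitly simulated meiosis, so the emitted pedigree and
    genotypes are Mendelian-consistent by construction.
    """
    rng = np.random.default_rng(config.seed)
    panel = config.panel
    dist = _genetic_distances(panel, config.gmap)
    v = panel.focal_variant.position_bp
    is_left = np.array([m.position_bp < v for m in panel.markers])
    is_str = np.array([m.kind == STR for m in panel.markers])
    fresh = _control_source(config, rng)

    ancestral = _draw_control_chromosome(config.control_allele_freqs, rng)
    params = BirthDeathParams.from_growth(config.demography.growth_rate)
    n_lineages = config.n_founder_lineages
    if n_lineages == 1:
        tree = Genealogy(1, np.array([-1]), np.array([0.0]), float(config.true_age))
        n_alive = 1
    else:
        tree, n_alive = _simulate_genealogy_with_size(
            n_lineages,
            config.true_age,
            params,
            rng,
            copies_band=config.condition_copies,
        )
    leaf_haps = _drop_down_genealogy(
        ancestral,
        tree,
        dist,
        is_left,
        is_str,
        config.str_mutation_rate,
        fresh,
        rng,
    )

    haplotypes: list[Haplotype] = []
    records: list[GenotypeRecord] = []
    ped_rows: list[tuple] = []
    members: dict[str, PedigreeMember] = {}

    def add_individual(
        sid: str,
        chrom_a: list[str],
        chrom_b: list[str],
        carries_a: bool,
        carries_b: bool,
        status: str,
        family_id: Optional[str],
    ) -> None:
        for alleles, carries in ((chrom_a, carries_a), (chrom_b, carries_b)):
            haplotypes.append(
                Haplotype(
                    alleles=tuple(alleles),
                    carries_variant=carries,
                    source="simulated",
                    sample_id=sid,
                )
            )
        genotypes = {
            name: tuple(sorted((chrom_a[i], chrom_b[i])))
            for i, name in enumerate(panel.names)
        }
        n_var = int(carries_a) + int(carries_b)
        records.append(
            GenotypeRecord(
                sample_id=sid,
                status=status,
                genotypes=genotypes,
                variant_genotype={0: "absent", 1: "het", 2: "hom"}[n_var],
                family_id=family_id,
            )
        )

    def add_ped(fid: str, sid: str, father: str, mother: str, sex: str, status: str) -> None:
        ped_rows.append((fid, sid, father, mother, sex, status))
        members[sid] = PedigreeMember(
            sample_id=sid,
            family_id=fid,
            father=None if father == "0" else father,
            mother=None if mother == "0" else mother,
            sex=sex,
            status=status,
        )

    def meiosis(h_keep: list[str], h_other: list[str]) -> list[str]:
        """One meiosis conditioned on transmitting the ``h_keep`` chromosome
        at the variant position; flanks may cross over onto ``h_other``."""
        out = list(h_keep)
        for side_mask in (is_left, ~is_left):
            g = rng.exponential(1.0)
            hit = side_mask & (dist > g)
            for i in np.nonzero(hit)[0]:
                out[i] = h_other[i]
        return out

    leaf_iter = iter(range(tree.n_leaves))
    # families first: one founder lineage each
    for fi, fam_size in enumerate(config.family_sizes):
        fid = f"FAM{fi + 1}"
        founder = f"{fid}_A1"
        leaf = next(leaf_iter)
        founder_carrier = leaf_haps[leaf]
        founder_other = fresh()
        add_individual(founder, founder_carrier, founder_other, True, False, CARRIER, fid)
        add_ped(fid, founder, "0", "0", "1", "affected")
        remaining = fam_size - 1
        parent_id = founder
        parent_carrier, parent_other = founder_carrier, founder_other
        gen = 0
        child_counter = 0
        while remaining > 0:
            gen += 1
            spouse = f"{fid}_S{gen}"
            spouse_a, spouse_b = fresh(), fresh()
            add_individual(spouse, spouse_a, spouse_b, False, False, CONTROL, fid)
            add_ped(fid, spouse, "0", "0", "2" if gen % 2 == 1 else "1", "unaffected")
            father, mother = (parent_id, spouse) if gen % 2 == 1 else (spouse, parent_id)
            n_children = min(remaining, 5)
            next_parent = None
            for _c in range(n_children):
                child_counter += 1
                child = f"{fid}_A{child_counter + 1}"
                child_carrier = meiosis(parent_carrier, parent_other)
                if rng.random() < 0.5:
                    child_other = meiosis(spouse_a, spouse_b)
                else:
                    child_other = meiosis(spouse_b, spouse_a)
                add_individual(child, child_carrier, child_other, True, False, CARRIER, fid)
                add_ped(fid, child, father, mother, "1" if rng.random() < 0.5 else "2", "affected")
                if next_parent is None:
                    next_parent = (child, child_carrier, child_other)
                remaining -= 1
            parent_id, parent_carrier, parent_other = next_parent

    # unrelated carriers
    n_unrelated = config.n_carriers - sum(config.family_sizes)
    for u in range(n_unrelated):
        sid = f"P{u + 1}"
        leaf = next(leaf_iter)
        add_individual(sid, leaf_haps[leaf], fresh(), True, False, CARRIER, None)

    # unrelated controls
    for c in range(config.n_control_individuals):
        sid = f"C{c + 1}"
        add_individual(sid, fresh(), fresh(), False, False, CONTROL, None)

    # population frequencies from the unrelated control group only (not the
    # carriers' partner chromosomes or family spouses)
    control_ids = {f"C{c + 1}" for c in range(config.n_control_individuals)}
    control_chroms = [h.alleles for h in haplotypes if h.sample_id in control_ids]
    hapset = HaplotypeSet(
        haplotypes=haplotypes,
        panel=panel,
        population_allele_freqs=allele_frequencies(control_chroms, panel)
        if control_chroms
        else None,
    )
    truth = {
        "true_age": config.true_age,
        "ancestral": tuple(ancestral),
        "n_founder_lineages": n_lineages,
        "population_copies": n_alive,
        "sampled_proportion_true": n_lineages / n_alive,
        "seed": config.seed,
    }
    return FounderSimResult(
        haplotype_set=hapset,
        records=records,
        pedigree=Pedigree(members=members),
        pedigree_rows=ped_rows,
        truth=truth,
        config=config,
    )


def two_locus_dprime(n11: int, n10: int, n01: int, n00: int) -> float:
    """Standardised LD coefficient D' from phased two-locus chromosome counts.

    ``n11`` counts chromosomes carrying allele 1 at both loci, and so on.
    Returns NaN when either locus is monomorphic (D' undefined).
    """
    tot = n11 + n10 + n01 + n00
    if tot == 0:
        return float("nan")
    pA = (n11 + n10) / tot
    pB = (n11 + n01) / tot
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        return float("nan")
    D = n11 / tot - pA * pB
    if D >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    return float("nan") if dmax == 0 else D / dmax


def panel_summary_stats(result: FounderSimResult) -> pd.DataFrame:
    """Per-marker ancestral-allele retention and variant-marker D'.

    Retention is the fraction of carrier chromosomes still carrying the
    true ancestral allele.  D' binarises each marker as
    ancestral/non-ancestral and uses the standard two-locus formula over
    all chromosomes (carriers and controls); it is undefined (NaN) at
    monomorphic markers.
    """
    panel = result.config.panel
    ancestral = result.truth["ancestral"]
    carriers = [h.alleles for h in result.haplotype_set.carriers]
    everyone = [(h.alleles, h.carries_variant) for h in result.haplotype_set.haplotypes]
    rows = []
    for i, m in enumerate(panel.markers):
        obs = [c[i] for c in carriers if c[i] != MISSING]
        retention = (
            sum(1 for a in obs if a == ancestral[i]) / len(obs) if obs else float("nan")
        )
        # D' between variant presence and the ancestral allele
        n11 = n10 = n01 = n00 = 0
        distinct = set()
        for alleles, carries in everyone:
            a = alleles[i]
            if a == MISSING:
                continue
            distinct.add(a)
            b = a == ancestral[i]
            if carries and b:
                n11 += 1
            elif carries:
                n10 += 1
            elif b:
                n01 += 1
            else:
                n00 += 1
        dprime = (
            float("nan") if len(distinct) < 2 else two_locus_dprime(n11, n10, n01, n00)
        )
        rows.append(
            {
                "marker": m.name,
                "kind": m.kind,
                "position_bp": m.position_bp,
                "distance_to_variant_bp": abs(
                    m.position_bp - panel.focal_variant.position_bp
                ),
                "ancestral_allele": ancestral[i],
                "retention": retention,
                "dprime": dprime,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# study-shaped defaults
#
# The marker names are those of the original MYOC p.Cys433Arg panel; the
# physical positions are synthetic (the study's interpolated map was not
# published) but reproduce its structure: a 5 Mb window on 1q24.3, a
# tight 4-marker core (rs3219828, rs2266782, rs2266780, rs2234708)
# spanning 0.0076 cM around the variant at the default 1 cM/Mb map, and
# the remaining markers spread across the flanks.

_VARIANT_BP = 171_636_338


def study_panel() -> tuple[MarkerPanel, GeneticMap]:
    chrom = "1"
    defs = [
        ("D1S1165", STR, 169_400_000),
        ("rs3220994", STR, 170_100_000),
        ("rs3220452", STR, 170_800_000),
        ("rs6133", SNP, 171_300_000),
        ("rs3219828", STR, 171_632_400),
        ("rs2266782", SNP, 171_635_900),
        ("rs2266780", SNP, 171_638_200),
        ("rs2234708", STR, 171_640_000),
        ("D1S2815", STR, 172_200_000),
        ("rs3219958", STR, 172_900_000),
        ("rs3221612", STR, 173_600_000),
        ("rs3223566", STR, 174_300_000),
    ]
    markers = tuple(Marker(name=n, kind=k, chrom=chrom, position_bp=p) for n, k, p in defs)
    variant = Marker(name="rs74315338", kind=SNP, chrom=chrom, position_bp=_VARIANT_BP)
    panel = MarkerPanel(markers=markers, focal_variant=variant, window_bp=5_000_000)
    gmap = GeneticMap.uniform(169_000_000, 175_000_000, rate_cM_per_Mb=1.0)
    return panel, gmap


_STR_FREQS = {
    "D1S1165": {"1": 0.06, "2": 0.22, "3": 0.34, "4": 0.21, "5": 0.12, "6": 0.05},
    "rs3220994": {"1": 0.10, "2": 0.28, "3": 0.32, "4": 0.18, "5": 0.12},
    "rs3220452": {"1": 0.08, "2": 0.30, "3": 0.36, "4": 0.16, "5": 0.10},
    "rs3219828": {"1": 0.12, "2": 0.30, "3": 0.28, "4": 0.18, "5": 0.12},
    "rs2234708": {"1": 0.15, "2": 0.35, "3": 0.30, "4": 0.20},
    "D1S2815": {"1": 0.07, "2": 0.23, "3": 0.33, "4": 0.22, "5": 0.15},
    "rs3219958": {"1": 0.10, "2": 0.26, "3": 0.30, "4": 0.22, "5": 0.12},
    "rs3221612": {"1": 0.05, "2": 0.18, "3": 0.27, "4": 0.25, "5": 0.15, "6": 0.10},
    "rs3223566": {"1": 0.20, "2": 0.35, "3": 0.30, "4": 0.15},
}
_SNP_FREQS = {
    "rs6133": {"C": 1.0},  # monomorphic in the study's population sample
    "rs2266782": {"G": 0.78, "A": 0.22},
    "rs2266780": {"A": 0.80, "G": 0.20},
}


def study_control_frequencies(panel: MarkerPanel) -> tuple[dict[str, float], ...]:
    out = []
    for m in panel.markers:
        table = _STR_FREQS.get(m.name) if m.kind == STR else _SNP_FREQS.get(m.name)
        if table is None:
            raise ValidationError(f"no study frequencies defined for marker {m.name}")
        out.append(dict(table))
    return tuple(out)


def study_simulation_config(
    true_age: float = 43.0,
    seed: int = 0,
    with_families: bool = True,
    demography: Optional[DemographyConfig] = None,
    condition_on_implied_copies: bool = False,
) -> SimulationConfig:
    """The study-shaped conditions: 51 carriers (35 in three families plus
    16 unrelated), 32 unrelated controls, 12 markers in 5 Mb, growth
    0.095.  ``true_age`` defaults to the study's primary LD-decay point
    estimate of 43 generations.

    ``condition_on_implied_copies`` accepts only realisations whose
    surviving mutant-class size is within 20% of the copy number implied
    by the configured sampled proportion (n / f); this makes the
    synthetic stand-in internally consistent with the demography the
    estimators are run with.
    """
    panel, gmap = study_panel()
    dem = demography or DemographyConfig()
    band = None
    if condition_on_implied_copies:
        implied = 51 / dem.sampled_proportion
        band = (int(0.8 * implied), int(1.2 * implied))
    return SimulationConfig(
        true_age=true_age,
        panel=panel,
        gmap=gmap,
        control_allele_freqs=study_control_frequencies(panel),
        demography=dem,
        n_carriers=51,
        n_control_individuals=32,
        family_sizes=(12, 12, 11) if with_families else (),
        condition_copies=band,
        seed=seed,
    )


def write_dataset(result: FounderSimResult, outdir: str, metadata: Optional[dict] = None) -> dict:
    """Emit the genotype TSV, pedigree TSV, phased VCF, marker map and
    truth JSON consumed by the rest of the pipeline; returns the paths."""
    import os

    from . import io as fio

    os.makedirs(outdir, exist_ok=True)
    panel = result.config.panel
    paths = {
        "genotypes": os.path.join(outdir, "genotypes.tsv"),
        "pedigree": os.path.join(outdir, "pedigree.tsv"),
        "markers": os.path.join(outdir, "markers.tsv"),
        "haplotypes_vcf": os.path.join(outdir, "haplotypes.vcf"),
        "truth": os.path.join(outdir, "truth.json"),
        "summary": os.path.join(outdir, "marker_summary.tsv"),
    }
    fio.write_genotype_table(result.records, panel, paths["genotypes"], metadata)
    fio.write_pedigree(result.pedigree_rows, paths["pedigree"], metadata)
    fio.write_marker_map(panel, paths["markers"], metadata)
    fio.write_phased_vcf(result.haplotype_set, paths["haplotypes_vcf"], metadata=metadata)
    truth = dict(result.truth)
    truth["ancestral"] = list(truth["ancestral"])
    fio.write_json(truth, paths["truth"])
    with open(paths["summary"], "w") as fh:
        if metadata:
            fh.write("".join(f"# {k}={v}\n" for k, v in metadata.items()))
        panel_summary_stats(result).to_csv(fh, sep="\t", index=False)
    return paths
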