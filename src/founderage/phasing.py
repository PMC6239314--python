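"""Haplotype determination around the focal variant.

Family samples are phased by Mendelian pedigree analysis: a site's phase
is assigned only where transmission logically forces it, so the output
never asserts more than the genotype data imply.  Unrelated samples are
phased by standard gene-counting EM over multilocus haplotype
frequencies.  The focal variant participates as an extra binary locus, so
that the variant-bearing chromosome of each carrier falls out of the same
machinery.  Finally, the conserved founder core — the contiguous marker
window around the variant on which carrier chromosomes agree — is located
by direct allele counting.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    MISSING,
    GenotypeRecord,
    Haplotype,
    HaplotypeSet,
    MarkerPanel,
    ValidationError,
)

#: Internal binary alleles for the focal-variant pseudo-locus.
VARIANT_WT = "0"
VARIANT_MUT = "1"

_VARIANT_PAIRS = {
    "absent": (VARIANT_WT, VARIANT_WT),
    "het": (VARIANT_WT, VARIANT_MUT),
    "hom": (VARIANT_MUT, VARIANT_MUT),
}


class MendelianError(ValidationError):
    """A child/parent genotype combination impossible under Mendelian transmission."""


@dataclass(frozen=True)
class PedigreeMember:
    sample_id: str
    family_id: str
    father: Optional[str] = None
    mother: Optional[str] = None
    sex: str = "0"
    status: str = "0"


@dataclass
class Pedigree:
    members: dict[str, PedigreeMember]

    def __post_init__(self) -> None:
        for m in self.members.values():
            for parent in (m.father, m.mother):
                if parent is not None and parent not in self.members:
                    raise ValidationError(
                        f"pedigree member {m.sample_id}: parent {parent} not in pedigree"
                    )
        # acyclicity: walk each ancestry chain with a visited set
        for start in self.members:
            seen = set()
            stack = [start]
            while stack:
                cur = stack.pop()
                if cur in seen:
                    raise ValidationError(f"pedigree contains a cycle through {cur}")
                seen.add(cur)
                mem = self.members[cur]
                stack.extend(p for p in (mem.father, mem.mother) if p is not None)


@dataclass
class PedigreePhasingResult:
    """Phased family haplotypes plus bookkeeping of what stayed unforced."""

    haplotype_set: HaplotypeSet
    unphased_sites: dict[str, list[str]]  # sample -> locus names left unphased
    variant_resolved: dict[str, bool]  # sample -> variant chromosome identified


def _loci_names(panel: MarkerPanel) -> list[str]:
    return panel.names + [panel.focal_variant.name]


def _genotype_rows(records: Sequence[GenotypeRecord], panel: MarkerPanel) -> dict[str, list]:
    """Per sample, per locus (markers then variant), the unordered allele pair."""
    rows = {}
    for r in records:
        r.validate(panel)
        pairs = [tuple(r.genotypes[name]) for name in panel.names]
        pairs.append(_VARIANT_PAIRS[r.variant_genotype])
        rows[r.sample_id] = pairs
    return rows


def _parent_allows(allele: str, parent_pair: Optional[tuple[str, str]]) -> bool:
    """Can ``parent_pair`` have transmitted ``allele``?  Untyped/missing allows all."""
    if parent_pair is None or MISSING in parent_pair:
        return True
    return allele in parent_pair


def phase_pedigree(
    records: Sequence[GenotypeRecord], ped: Pedigree, panel: MarkerPanel
) -> PedigreePhasingResult:
    """Assign paternal/maternal phase wherever transmission forces it.

    For each individual and locus, the two possible orientations of a
    heterozygous genotype are checked against the parents' genotypes; if
    exactly one orientation is transmissible the phase is forced, if both
    are the site is left unphased (``MISSING`` on both output
    haplotypes), and if neither is a :class:`MendelianError` is raised
    naming the trio and locus.  This per-site membership rule equals the
    intersection of all Mendelian-consistent full phase assignments,
    because single-locus transmission constrains only which parental
    genotype each child allele belongs to.
    """
    genos = _genotype_rows(records, panel)
    for sid in genos:
        if sid not in ped.members:
            raise ValidationError(f"genotype record for unknown pedigree sample {sid!r}")
    names = _loci_names(panel)
    m = len(panel)
    haplotypes: list[Haplotype] = []
    unphased: dict[str, list[str]] = {}
    variant_resolved: dict[str, bool] = {}
    for sid, pairs in genos.items():
        member = ped.members[sid]
        fpairs = genos.get(member.father) if member.father else None
        mpairs = genos.get(member.mother) if member.mother else None
        pat: list[str] = []
        mat: list[str] = []
        left_unphased: list[str] = []
        for l, (a, b) in enumerate(pairs):
            f_pair = fpairs[l] if fpairs is not None else None
            m_pair = mpairs[l] if mpairs is not None else None
            if MISSING in (a, b):
                pat.append(MISSING)
                mat.append(MISSING)
                continue
            if a == b:
                if not (_parent_allows(a, f_pair) and _parent_allows(a, m_pair)):
                    raise MendelianError(
                        f"locus {names[l]}: child {sid} homozygous {a}/{a} is inconsistent "
                        f"with parents {member.father}/{member.mother}"
                    )
                pat.append(a)
                mat.append(a)
                continue
            ab_ok = _parent_allows(a, f_pair) and _parent_allows(b, m_pair)
            ba_ok = _parent_allows(b, f_pair) and _parent_allows(a, m_pair)
            if not ab_ok and not ba_ok:
                raise MendelianError(
                    f"locus {names[l]}: child {sid} genotype {a}/{b} is inconsistent "
                    f"with parents {member.father}/{member.mother}"
                )
            if ab_ok and ba_ok:
                pat.append(MISSING)
                mat.append(MISSING)
                left_unphased.append(names[l])
            elif ab_ok:
                pat.append(a)
                mat.append(b)
            else:
                pat.append(b)
                mat.append(a)
        unphased[sid] = left_unphased
        v_pat, v_mat = pat[m], mat[m]
        resolved = MISSING not in (v_pat, v_mat)
        variant_resolved[sid] = resolved or pairs[m][0] == pairs[m][1]
        for chrom_alleles, v_allele in ((pat[:m], v_pat), (mat[:m], v_mat)):
            haplotypes.append(
                Haplotype(
                    alleles=tuple(chrom_alleles),
                    carries_variant=(v_allele == VARIANT_MUT),
                    source="pedigree",
                    sample_id=sid,
                )
            )
    return PedigreePhasingResult(
        haplotype_set=HaplotypeSet(haplotypes=haplotypes, panel=panel),
        unphased_sites=unphased,
        variant_resolved=variant_resolved,
    )


# ---------------------------------------------------------------------------
# EM haplotype-frequency inference (gene counting)


@dataclass
class HaplotypeFrequencyModel:
    """Multilocus haplotype frequencies fitted by EM, plus fit diagnostics."""

    haplotypes: list[tuple[str, ...]]  # over panel markers + variant pseudo-locus
    frequencies: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    panel: MarkerPanel
    include_variant: bool = True

    FREQ_FLOOR = 1e-12

    def frequency_of(self, hap: tuple[str, ...]) -> float:
        try:
            return float(self.frequencies[self.haplotypes.index(hap)])
        except ValueError:
            return 0.0


def _site_alphabets(
    rows: dict[str, list], n_loci: int
) -> list[tuple[str, ...]]:
    alphabets = []
    for l in range(n_loci):
        seen = set()
        for pairs in rows.values():
            for a in pairs[l]:
                if a != MISSING:
                    seen.add(a)
        alphabets.append(tuple(sorted(seen)) or (MISSING,))
    return alphabets


_MAX_CONFIGS = 1 << 16


def _compatible_pairs(
    pairs: list[tuple[str, str]], alphabets: list[tuple[str, ...]]
) -> list[tuple[tuple[str, ...], tuple[str, ...]]]:
    """All unordered haplotype pairs consistent with one individual's genotypes.

    Heterozygous sites contribute an orientation choice; missing alleles
    are marginalised over the alleles observed in the sample at that
    locus.
    """
    site_options: list[list[tuple[str, str]]] = []
    n_configs = 1
    for l, (a, b) in enumerate(pairs):
        if a == MISSING and b == MISSING:
            opts = [
                (x, y) for x in alphabets[l] for y in alphabets[l]
            ]
        elif MISSING in (a, b):
            known = b if a == MISSING else a
            opts = [(x, known) for x in alphabets[l]] + [
                (known, y) for y in alphabets[l] if y != known
            ]
        elif a == b:
            opts = [(a, a)]
        else:
            opts = [(a, b), (b, a)]
        site_options.append(opts)
        n_configs *= len(opts)
        if n_configs > _MAX_CONFIGS:
            raise ValidationError(
                "too many phase configurations to enumerate for one individual "
                f"(> {_MAX_CONFIGS}); reduce missingness or marker count"
            )
    out = set()
    for combo in itertools.product(*site_options):
        h1 = tuple(c[0] for c in combo)
        h2 = tuple(c[1] for c in combo)
        out.add((h1, h2) if h1 <= h2 else (h2, h1))
    return sorted(out)


def em_haplotype_inference(
    records: Sequence[GenotypeRecord],
    panel: MarkerPanel,
    max_iter: int = 1000,
    tol: float = 1e-8,
    n_restarts: int = 3,
    seed: int = 0,
    include_variant: bool = True,
) -> HaplotypeFrequencyModel:
    """Gene-counting EM for multilocus haplotype frequencies.

    The E-step weights each phase configuration consistent with an
    individual's genotypes by the current haplotype frequencies; the
    M-step re-estimates frequencies from the expected counts.  The run
    stops when the log-likelihood gain drops below ``tol`` and the best
    of ``n_restarts`` starts (uniform, then random simplex draws) is
    returned.  Individuals missing every genotype are excluded with a
    warning.
    """
    if len(panel) == 0:
        raise ValidationError("EM needs at least one marker")
    rows = _genotype_rows(records, panel)
    n_loci = len(panel) + 1 if include_variant else len(panel)
    if not include_variant:
        rows = {sid: pairs[: len(panel)] for sid, pairs in rows.items()}
    kept = {}
    for sid, pairs in rows.items():
        if all(MISSING in p and p[0] == p[1] for p in pairs):
            warnings.warn(f"sample {sid}: all genotypes missing; excluded from EM")
            continue
        kept[sid] = pairs
    if not kept:
        raise ValidationError("no individuals left after excluding all-missing samples")
    alphabets = _site_alphabets(kept, n_loci)
    pair_lists = {sid: _compatible_pairs(pairs, alphabets) for sid, pairs in kept.items()}

    universe = sorted({h for plist in pair_lists.values() for pair in plist for h in pair})
    index = {h: i for i, h in enumerate(universe)}
    H = len(universe)
    # per individual: arrays of pair indices and multiplicity (2 for het pair)
    ind_pairs = []
    for sid, plist in pair_lists.items():
        i1 = np.array([index[p[0]] for p in plist])
        i2 = np.array([index[p[1]] for p in plist])
        mult = np.where(i1 == i2, 1.0, 2.0)
        ind_pairs.append((i1, i2, mult))

    rng = np.random.default_rng(seed)
    floor = HaplotypeFrequencyModel.FREQ_FLOOR
    best = None
    for restart in range(max(n_restarts, 1)):
        if restart == 0:
            f = np.full(H, 1.0 / H)
        else:
            f = rng.dirichlet(np.ones(H))
        prev_ll = -np.inf
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            counts = np.zeros(H)
            ll = 0.0
            for i1, i2, mult in ind_pairs:
                w = mult * np.maximum(f[i1], floor) * np.maximum(f[i2], floor)
                tot = w.sum()
                ll += np.log(tot)
                w /= tot
                np.add.at(counts, i1, w)
                np.add.at(counts, i2, w)
            if ll + 1e-9 < prev_ll:
                raise AssertionError(
                    f"EM log-likelihood decreased ({prev_ll} -> {ll}); this is a bug"
                )
            f = counts / counts.sum()
            if ll - prev_ll < tol and it > 1:
                converged = True
                prev_ll = ll
                break
            prev_ll = ll
        if best is None or prev_ll > best[0]:
            best = (prev_ll, f, it, converged)
    ll, f, it, converged = best
    return HaplotypeFrequencyModel(
        haplotypes=universe,
        frequencies=f,
        loglik=float(ll),
        n_iter=it,
        converged=converged,
        panel=panel,
        include_variant=include_variant,
    )


def assign_most_probable_phase(
    model: HaplotypeFrequencyModel, record: GenotypeRecord
) -> tuple[Haplotype, Haplotype, float]:
    """Most probable phase of one individual under a fitted frequency model.

    Returns the two haplotypes (panel markers only, variant status set
    from the variant pseudo-locus) and the posterior weight of the chosen
    configuration among all consistent ones.  Ties are broken by
    panel-order lexicographic rank of the haplotype pair.
    """
    panel = model.panel
    pairs = _genotype_rows([record], panel)[record.sample_id]
    if not model.include_variant:
        pairs = pairs[: len(panel)]
    n_loci = len(panel) + 1 if model.include_variant else len(panel)
    alphabets = []
    model_sites = list(zip(*model.haplotypes)) if model.haplotypes else []
    for l in range(n_loci):
        seen = set(model_sites[l]) if model_sites else set()
        for a in pairs[l]:
            if a != MISSING:
                seen.add(a)
        seen.discard(MISSING)
        alphabets.append(tuple(sorted(seen)) or (MISSING,))
    candidates = _compatible_pairs(pairs, alphabets)
    weights = []
    for h1, h2 in candidates:
        f1, f2 = model.frequency_of(h1), model.frequency_of(h2)
        mult = 1.0 if h1 == h2 else 2.0
        weights.append(mult * f1 * f2)
    total = float(np.sum(weights))
    if total <= 0.0:
        raise ValidationError(
            f"sample {record.sample_id}: genotypes inconsistent with every haplotype "
            "pair in the fitted model (all configurations below the frequency floor)"
        )
    order = np.argsort([-w for w in weights], kind="stable")
    best_i = int(order[0])
    h1, h2 = candidates[best_i]
    posterior = weights[best_i] / total
    m = len(panel)

    def to_hap(h: tuple[str, ...]) -> Haplotype:
        carries = model.include_variant and h[m] == VARIANT_MUT
        return Haplotype(
            alleles=h[:m], carries_variant=carries, source="EM", sample_id=record.sample_id
        )

    return to_hap(h1), to_hap(h2), float(posterior)


def phase_unrelated_by_anchor(
    records: Sequence[GenotypeRecord],
    panel: MarkerPanel,
    min_posterior: float = 0.95,
    seed: int = 0,
    em_kwargs: Optional[dict] = None,
) -> HaplotypeSet:
    """Phase unrelated individuals marker-by-marker against the variant.

    Joint EM over a dozen multiallelic loci is unidentifiable in a small
    sample — nearly every full haplotype is a singleton, so any phase
    assignment fits equally well.  The information that does exist is
    the pairwise LD between each marker and the focal variant, so each
    marker is phased by a two-locus EM anchored at the variant: the
    marker allele assigned to the variant-bearing chromosome is the most
    probable configuration, accepted only when its posterior reaches
    ``min_posterior``; uncertain sites stay unphased (``MISSING``).
    Homozygous sites are always phased, and non-carriers get an
    arbitrary but frequency-neutral split.
    """
    if not records:
        raise ValidationError("no records to phase")
    m = len(panel)
    out_alleles: dict[str, list[list[str]]] = {
        r.sample_id: [[MISSING] * m, [MISSING] * m] for r in records
    }
    kwargs = dict(max_iter=1000, tol=1e-10, n_restarts=2)
    if em_kwargs:
        kwargs.update(em_kwargs)
    for i, marker in enumerate(panel.markers):
        sub_markers = (marker,)
        sub_panel = MarkerPanel(
            markers=sub_markers,
            focal_variant=panel.focal_variant,
            window_bp=panel.window_bp,
        )
        sub_records = [
            GenotypeRecord(
                sample_id=r.sample_id,
                status=r.status,
                genotypes={marker.name: r.genotypes[marker.name]},
                variant_genotype=r.variant_genotype,
                family_id=r.family_id,
            )
            for r in records
        ]
        model = em_haplotype_inference(
            sub_records, sub_panel, seed=seed + i, include_variant=True, **kwargs
        )
        for rec in sub_records:
            a, b = rec.genotypes[marker.name]
            h1, h2, post = assign_most_probable_phase(model, rec)
            if h2.carries_variant and not h1.carries_variant:
                h1, h2 = h2, h1  # variant-bearing chromosome first
            sid = rec.sample_id
            if a == b or rec.variant_genotype != "het" or post >= min_posterior:
                out_alleles[sid][0][i] = h1.alleles[0]
                out_alleles[sid][1][i] = h2.alleles[0]
            # else: leave both chromosomes unphased at this marker
    haps = []
    for r in records:
        carries = (
            (True, False)
            if r.variant_genotype == "het"
            else (True, True)
            if r.variant_genotype == "hom"
            else (False, False)
        )
        for k in range(2):
            haps.append(
                Haplotype(
                    alleles=tuple(out_alleles[r.sample_id][k]),
                    carries_variant=carries[k],
                    source="EM",
                    sample_id=r.sample_id,
                )
            )
    return HaplotypeSet(haplotypes=haps, panel=panel)


# ---------------------------------------------------------------------------
# shared founder core


@dataclass
class SharedCore:
    """The contiguous marker window around the variant conserved on carriers."""

    marker_names: list[str]
    alleles: list[str]
    match_fractions: list[float]
    threshold: float

    @property
    def size(self) -> int:
        return len(self.marker_names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker": self.marker_names,
                "core_allele": self.alleles,
                "match_fraction": self.match_fractions,
            }
        )


def find_shared_core(
    carriers: HaplotypeSet | Sequence[Haplotype],
    panel: MarkerPanel,
    match_threshold: float = 1.0,
) -> SharedCore:
    """Largest contiguous marker window around the variant with a conserved allele.

    Per marker the modal allele among carrier chromosomes is counted
    (missing alleles excluded from the denominator; ties broken by symbol
    order); the window grows outwards from the variant on each side while
    the modal-allele fraction stays at or above ``match_threshold``.  An
    empty core (warning) means even the variant-adjacent markers fail the
    threshold.

    When ``carriers`` is a :class:`HaplotypeSet` with population allele
    frequencies, markers monomorphic in the population are treated as
    transparent: agreement there is no evidence of shared ancestry, so
    they neither stop the window from growing nor appear in the reported
    core.
    """
    if isinstance(carriers, HaplotypeSet):
        haps = carriers.carriers
        pop_freqs = carriers.population_allele_freqs
    else:
        haps = [h for h in carriers if h.carries_variant]
        pop_freqs = None
    if len(haps) < 2:
        raise ValidationError("shared-core detection needs at least 2 carrier haplotypes")
    m = len(panel)
    modal: list[str] = []
    frac: list[float] = []
    for i in range(m):
        counts: dict[str, int] = {}
        for h in haps:
            a = h.alleles[i]
            if a != MISSING:
                counts[a] = counts.get(a, 0) + 1
        if not counts:
            modal.append(MISSING)
            frac.append(0.0)
            continue
        best = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0]
        modal.append(best[0])
        frac.append(best[1] / sum(counts.values()))
    informative = [True] * m
    if pop_freqs is not None:
        for i in range(m):
            table = pop_freqs[i]
            if table and sum(1 for f in table.values() if f > 0) < 2:
                informative[i] = False
    v = panel.variant_insert_index
    left = []
    for i in range(v - 1, -1, -1):
        if not informative[i]:
            continue
        if frac[i] >= match_threshold:
            left.append(i)
        else:
            break
    right = []
    for i in range(v, m):
        if not informative[i]:
            continue
        if frac[i] >= match_threshold:
            right.append(i)
        else:
            break
    idx = sorted(left) + right
    if not idx:
        warnings.warn(
            "no marker adjacent to the variant reaches the match threshold; empty core"
        )
    return SharedCore(
        marker_names=[panel.markers[i].name for i in idx],
        alleles=[modal[i] for i in idx],
        match_fractions=[frac[i] for i in idx],
        threshold=match_threshold,
    )
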