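"""Readers and writers for the panel's tabular and VCF interchange formats.

All tabular formats are plain TSV.  Phased haplotypes travel as VCF 4.2
with pipe-separated GT fields; STR alleles, which are integer size-rank
codes internally, are encoded in REF/ALT as runs of ``A`` whose length is
the code (code 3 -> ``AAA``), keeping the file a valid nucleotide VCF
while remaining bijective.
"""

from __future__ import annotations

import json
from typing import Iterable, Optional, Sequence

import pandas as pd
import pysam

from .datamodel import (
    MISSING,
    SNP,
    STR,
    GenotypeRecord,
    Haplotype,
    HaplotypeSet,
    Marker,
    MarkerPanel,
    ValidationError,
)

_META_PREFIX = "#"


def _comment_lines(metadata: Optional[dict]) -> str:
    if not metadata:
        return ""
    return "".join(f"# {k}={v}\n" for k, v in metadata.items())


# ---------------------------------------------------------------------------
# marker map


def write_marker_map(panel: MarkerPanel, path: str, metadata: Optional[dict] = None) -> None:
    rows = []
    for m in panel.markers:
        rows.append((m.name, m.kind, m.chrom, m.position_bp, m.genetic_pos_cM, "marker"))
    v = panel.focal_variant
    rows.append((v.name, v.kind, v.chrom, v.position_bp, v.genetic_pos_cM, "focal_variant"))
    rows.sort(key=lambda r: r[3])
    df = pd.DataFrame(
        rows, columns=["name", "kind", "chrom", "position_bp", "genetic_pos_cM", "role"]
    )
    with open(path, "w") as fh:
        fh.write(_comment_lines(metadata))
        df.to_csv(fh, sep="\t", index=False)


def read_marker_map(path: str, window_bp: int = 5_000_000) -> MarkerPanel:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"name": str, "chrom": str})
    required = {"name", "kind", "chrom", "position_bp", "role"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"marker map {path}: missing columns {sorted(missing)}")
    markers, variant = [], None
    for _, row in df.iterrows():
        cm = row.get("genetic_pos_cM")
        marker = Marker(
            name=row["name"],
            kind=row["kind"],
            chrom=row["chrom"],
            position_bp=int(row["position_bp"]),
            genetic_pos_cM=None if pd.isna(cm) else float(cm),
        )
        if row["role"] == "focal_variant":
            if variant is not None:
                raise ValidationError(f"marker map {path}: more than one focal_variant row")
            variant = marker
        else:
            markers.append(marker)
    if variant is None:
        raise ValidationError(f"marker map {path}: no focal_variant row")
    markers.sort(key=lambda m: m.position_bp)
    return MarkerPanel(markers=tuple(markers), focal_variant=variant, window_bp=window_bp)


# ---------------------------------------------------------------------------
# genotype table


def write_genotype_table(
    records: Sequence[GenotypeRecord],
    panel: MarkerPanel,
    path: str,
    metadata: Optional[dict] = None,
) -> None:
    cols = ["sample_id", "status", "family_id", "variant_genotype"]
    for name in panel.names:
        cols += [f"{name}.1", f"{name}.2"]
    rows = []
    for r in records:
        row = [r.sample_id, r.status, r.family_id if r.family_id else ".", r.variant_genotype]
        for name in panel.names:
            a, b = r.genotypes[name]
            row += [a, b]
        rows.append(row)
    df = pd.DataFrame(rows, columns=cols)
    with open(path, "w") as fh:
        fh.write(_comment_lines(metadata))
        df.to_csv(fh, sep="\t", index=False)


def read_genotype_table(path: str, panel: MarkerPanel) -> list[GenotypeRecord]:
    """Read a per-individual genotype TSV (two allele columns per marker).

    Unknown marker columns and alleles outside a marker's alphabet are hard
    errors naming the offending sample/marker; missing alleles must use the
    reserved ``.`` code and are preserved.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    fixed = {"sample_id", "status", "family_id", "variant_genotype"}
    missing_fixed = fixed - set(df.columns)
    if missing_fixed:
        raise ValidationError(f"genotype table {path}: missing columns {sorted(missing_fixed)}")
    marker_cols = [c for c in df.columns if c not in fixed]
    expected = [f"{n}.{i}" for n in panel.names for i in (1, 2)]
    unknown = [c for c in marker_cols if c not in expected]
    if unknown:
        raise ValidationError(
            f"genotype table {path}: columns {unknown} do not match any panel marker"
        )
    absent = [c for c in expected if c not in marker_cols]
    if absent:
        raise ValidationError(f"genotype table {path}: missing marker columns {absent}")
    records = []
    for _, row in df.iterrows():
        genotypes = {
            name: (row[f"{name}.1"], row[f"{name}.2"]) for name in panel.names
        }
        rec = GenotypeRecord(
            sample_id=row["sample_id"],
            status=row["status"],
            genotypes=genotypes,
            variant_genotype=row["variant_genotype"],
            family_id=None if row["family_id"] in (".", "") else row["family_id"],
        )
        rec.validate(panel)
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# phased VCF


def _allele_to_vcf(marker: Marker, allele: str) -> str:
    if marker.kind == STR:
        return "A" * int(allele)
    return allele


def _allele_from_vcf(marker: Marker, seq: str) -> str:
    if marker.kind == STR:
        if set(seq) != {"A"}:
            raise ValidationError(
                f"marker {marker.name}: cannot decode STR allele from sequence {seq!r}"
            )
        return str(len(seq))
    return seq


def write_phased_vcf(
    hapset: HaplotypeSet,
    path: str,
    variant_alleles: tuple[str, str] = ("T", "C"),
    metadata: Optional[dict] = None,
) -> None:
    """Write diploid samples with phased GT; haplotypes are paired by sample_id.

    ``variant_alleles`` gives (wild-type REF, mutant ALT) for the focal
    variant record.
    """
    panel = hapset.panel
    by_sample: dict[str, list[Haplotype]] = {}
    for h in hapset.haplotypes:
        if h.sample_id is None:
            raise ValidationError("VCF output requires every haplotype to carry a sample_id")
        by_sample.setdefault(h.sample_id, []).append(h)
    for sid, haps in by_sample.items():
        if len(haps) != 2:
            raise ValidationError(f"sample {sid}: expected exactly 2 haplotypes, got {len(haps)}")

    header = pysam.VariantHeader()
    header.add_line("##source=founderage")
    if metadata:
        for k, v in metadata.items():
            header.add_line(f"##founderage_{k}={v}")
    chrom = panel.focal_variant.chrom
    max_pos = max(m.position_bp for m in panel.markers + (panel.focal_variant,))
    header.contigs.add(chrom, length=max_pos + 1)
    header.formats.add("GT", 1, "String", "Genotype")
    samples = sorted(by_sample)
    for sid in samples:
        header.add_sample(sid)

    loci: list[tuple[Marker, Optional[int]]] = [(m, i) for i, m in enumerate(panel.markers)]
    loci.append((panel.focal_variant, None))
    loci.sort(key=lambda t: t[0].position_bp)

    with pysam.VariantFile(path, "w", header=header) as vcf:
        for marker, idx in loci:
            if idx is None:
                alleles = list(variant_alleles)
            else:
                seen = sorted(
                    {h.alleles[idx] for h in hapset.haplotypes if h.alleles[idx] != MISSING},
                    key=(lambda a: int(a)) if marker.kind == STR else str,
                )
                if not seen:
                    seen = ["A"] if marker.kind == SNP else ["1"]
                alleles = [_allele_to_vcf(marker, a) for a in seen]
                if len(alleles) == 1:  # VCF needs an ALT even at monomorphic sites
                    if marker.kind == SNP:
                        alleles.append("A" if alleles[0] != "A" else "G")
                    else:
                        alleles.append(alleles[0] + "A")
            rec = vcf.new_record(
                contig=chrom, start=marker.position_bp - 1, alleles=tuple(alleles), id=marker.name
            )
            for sid in samples:
                h1, h2 = by_sample[sid]
                gt = []
                for h in (h1, h2):
                    if idx is None:
                        gt.append(1 if h.carries_variant else 0)
                    else:
                        a = h.alleles[idx]
                        if a == MISSING:
                            gt.append(None)
                        else:
                            gt.append(alleles.index(_allele_to_vcf(marker, a)))
                rec.samples[sid]["GT"] = tuple(gt)
                rec.samples[sid].phased = True
            vcf.write(rec)


def read_phased_vcf(path: str, panel: MarkerPanel) -> HaplotypeSet:
    """Read phased diploid genotypes back into two haplotypes per sample.

    Every GT must be phased (``|``); an unphased separator is an error
    suggesting the phasing module.  The focal variant must be present as a
    record so that carrier chromosomes can be identified.
    """
    by_pos = {m.position_bp: (m, i) for i, m in enumerate(panel.markers)}
    vpos = panel.focal_variant.position_bp
    with pysam.VariantFile(path) as vcf:
        samples = list(vcf.header.samples)
        alleles: dict[str, list[list[str]]] = {
            s: [[MISSING] * len(panel), [MISSING] * len(panel)] for s in samples
        }
        carries: dict[str, list[Optional[bool]]] = {s: [None, None] for s in samples}
        seen_variant = False
        for rec in vcf:
            pos = rec.pos
            is_variant = pos == vpos
            if not is_variant and pos not in by_pos:
                continue
            for s in samples:
                call = rec.samples[s]
                gt = call["GT"]
                if gt is None or len(gt) != 2:
                    raise ValidationError(f"sample {s} at {rec.id}: expected a diploid GT")
                if not call.phased and not all(g is None for g in gt):
                    raise ValidationError(
                        f"sample {s} at {rec.id}: GT is unphased; phase the data first "
                        "(see the phasing module: pedigree analysis or EM inference)"
                    )
                for k, g in enumerate(gt):
                    if is_variant:
                        carries[s][k] = bool(g) if g is not None else None
                    else:
                        marker, idx = by_pos[pos]
                        if g is not None:
                            alleles[s][k][idx] = _allele_from_vcf(marker, rec.alleles[g])
            if is_variant:
                seen_variant = True
    if not seen_variant:
        raise ValidationError(
            f"VCF {path}: no record at the focal variant position {vpos}; "
            "carrier chromosomes cannot be identified"
        )
    haps = []
    for s in samples:
        for k in (0, 1):
            haps.append(
                Haplotype(
                    alleles=tuple(alleles[s][k]),
                    carries_variant=bool(carries[s][k]),
                    source="simulated",
                    sample_id=s,
                )
            )
    return HaplotypeSet(haplotypes=haps, panel=panel).with_control_frequencies()


# ---------------------------------------------------------------------------
# phased haplotype table (one chromosome per row)


def write_haplotype_table(
    hapset: HaplotypeSet, path: str, metadata: Optional[dict] = None
) -> None:
    panel = hapset.panel
    cols = ["sample_id", "chromosome", "carries_variant", "source"] + panel.names
    rows = []
    seen: dict[str, int] = {}
    for h in hapset.haplotypes:
        sid = h.sample_id or "?"
        seen[sid] = seen.get(sid, 0) + 1
        rows.append([sid, seen[sid], int(h.carries_variant), h.source] + list(h.alleles))
    df = pd.DataFrame(rows, columns=cols)
    with open(path, "w") as fh:
        fh.write(_comment_lines(metadata))
        df.to_csv(fh, sep="\t", index=False)


def read_haplotype_table(path: str, panel: MarkerPanel) -> HaplotypeSet:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    required = {"sample_id", "carries_variant", "source"} | set(panel.names)
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"haplotype table {path}: missing columns {sorted(missing)}")
    haps = []
    for _, row in df.iterrows():
        haps.append(
            Haplotype(
                alleles=tuple(row[name] for name in panel.names),
                carries_variant=bool(int(row["carries_variant"])),
                source=row["source"],
                sample_id=row["sample_id"],
            )
        )
    return HaplotypeSet(haplotypes=haps, panel=panel).with_control_frequencies()


# ---------------------------------------------------------------------------
# pedigree (PED-style TSV)


def write_pedigree(rows: Iterable[tuple], path: str, metadata: Optional[dict] = None) -> None:
    """Rows are (family_id, sample_id, father, mother, sex, status); 0 = unknown."""
    df = pd.DataFrame(
        list(rows), columns=["family_id", "sample_id", "father", "mother", "sex", "status"]
    )
    with open(path, "w") as fh:
        fh.write(_comment_lines(metadata))
        df.to_csv(fh, sep="\t", index=False)


def read_pedigree(path: str):
    """Parse a PED-style TSV into a phasing.Pedigree."""
    from .phasing import Pedigree, PedigreeMember

    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    required = {"family_id", "sample_id", "father", "mother", "sex", "status"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"pedigree {path}: missing columns {sorted(missing)}")
    members = {}
    for _, row in df.iterrows():
        members[row["sample_id"]] = PedigreeMember(
            sample_id=row["sample_id"],
            family_id=row["family_id"],
            father=None if row["father"] in ("0", "", ".") else row["father"],
            mother=None if row["mother"] in ("0", "", ".") else row["mother"],
            sex=row["sex"],
            status=row["status"],
        )
    return Pedigree(members=members)


# ---------------------------------------------------------------------------
# JSON helpers


def write_json(obj: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str) -> dict:
    with open(path) as fh:
        return json.load(fh)
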