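"""Genotype input/output: files -> functional-allele dosages.

Scoring operates on *dosages*: the number of functional-allele copies a
patient carries at each panel site (0, 1, 2, or missing).  This module maps
per-sample genotype calls from VCF (via :mod:`cyvcf2`) or from a delimited
genotype matrix onto dosages against a :class:`~htnpgx.panel.Panel`.

Calls are treated as unphased; allele order within a call never matters.
The ACE insertion/deletion is carried symbolically: the deletion allele is
``"D"`` and the insertion ``"I"``, and in VCF the shorter of REF/ALT is
taken as ``D``.  Missing stays missing — no imputation is performed; the
scoring layer renormalizes over observed sites instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .panel import Panel, VariantSite

__all__ = [
    "GenotypeCall",
    "PatientGenotype",
    "GenotypeParseError",
    "read_genotypes_vcf",
    "read_genotypes_table",
    "write_genotypes_vcf",
    "write_genotypes_table",
]


class GenotypeParseError(ValueError):
    """Malformed genotype input."""


@dataclass(frozen=True)
class GenotypeCall:
    """One unphased diploid call at one site."""

    rsid: str
    alleles: tuple[str, ...]  # () when missing
    missing: bool = False

    def __post_init__(self) -> None:
        if self.missing != (len(self.alleles) == 0):
            raise GenotypeParseError(
                f"{self.rsid}: alleles must be empty iff the call is missing"
            )


@dataclass
class PatientGenotype:
    """Per-patient functional-allele dosages keyed by rsID.

    ``dosages[rsid]`` is 2 for homozygous functional, 1 for heterozygous,
    0 for homozygous non-functional and ``None`` for missing.
    """

    patient_id: str
    dosages: dict[str, Optional[int]] = field(default_factory=dict)

    def dosage(self, rsid: str) -> Optional[int]:
        return self.dosages.get(rsid)


def _dosage_from_alleles(site: VariantSite, alleles: Sequence[str]) -> int:
    """Count functional-allele copies; reject alleles foreign to the site."""
    known = {site.functional_allele}
    if site.other_allele:
        known.add(site.other_allele)
    dosage = 0
    for a in alleles:
        if a == site.functional_allele:
            dosage += 1
        elif site.other_allele is not None and a not in known:
            raise GenotypeParseError(
                f"{site.rsid}: unexpected allele {a!r} "
                f"(expected {sorted(known)})"
            )
    return dosage


def _indel_symbol(allele: str, ref: str, alt: str) -> str:
    """Map a concrete indel allele to the symbolic D (shorter) / I (longer)."""
    return "D" if len(allele) == min(len(ref), len(alt)) else "I"


def read_genotypes_vcf(path: str | Path, panel: Panel) -> list[PatientGenotype]:
    """Read per-sample dosages from a VCF (GT subfield only).

    Sites are matched to the panel by ID first, with chrom/pos fallback for
    panel entries that carry coordinates.  Panel sites absent from the file
    are recorded as missing.  Phase separators are ignored.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise GenotypeParseError(f"{path}: VCF has no sample columns")

    by_rsid = {s.rsid: s for s in panel.sites}
    by_pos = {
        (s.chrom, s.pos): s for s in panel.sites if s.chrom is not None and s.pos
    }
    patients = [PatientGenotype(pid, {s.rsid: None for s in panel.sites}) for pid in samples]

    for variant in vcf:
        site = by_rsid.get(variant.ID) or by_pos.get((variant.CHROM, variant.POS))
        if site is None:
            continue
        ref = variant.REF
        alts = list(variant.ALT)
        symbolic_indel = site.functional_allele in ("D", "I") and alts
        for i, gt in enumerate(variant.genotypes):
            # cyvcf2 genotype row: [allele_idx, allele_idx, phased_flag]
            idxs = [g for g in gt[:-1] if g is not None and g >= 0]
            if len(idxs) != 2:
                continue  # stays missing
            alleles = []
            for idx in idxs:
                raw = ref if idx == 0 else alts[idx - 1]
                if symbolic_indel:
                    raw = _indel_symbol(raw, ref, alts[0])
                alleles.append(raw)
            patients[i].dosages[site.rsid] = _dosage_from_alleles(site, alleles)
    return patients


_PAIR_SEPS = ("/", "|")


def _parse_cell(cell: object, site: VariantSite, row: str, col: str) -> Optional[int]:
    """One matrix cell -> dosage.  Accepts allele pairs ('A/G') or integers."""
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return None
    text = str(cell).strip()
    if text == "" or text.lower() in ("na", "nan", "."):
        return None
    for sep in _PAIR_SEPS:
        if sep in text:
            alleles = [a.strip() for a in text.split(sep)]
            if len(alleles) != 2 or not all(alleles):
                raise GenotypeParseError(
                    f"malformed genotype cell {text!r} at row {row}, column {col}"
                )
            try:
                return _dosage_from_alleles(site, alleles)
            except GenotypeParseError as exc:
                raise GenotypeParseError(f"row {row}, column {col}: {exc}") from None
    try:
        dosage = int(text)
    except ValueError:
        raise GenotypeParseError(
            f"malformed genotype cell {text!r} at row {row}, column {col}"
        ) from None
    if dosage not in (0, 1, 2):
        raise GenotypeParseError(
            f"dosage out of range ({dosage}) at row {row}, column {col}"
        )
    return dosage


def read_genotypes_table(path: str | Path, panel: Panel) -> list[PatientGenotype]:
    """Read a patients-by-rsID genotype matrix (TSV or CSV).

    The first column holds patient identifiers; remaining columns are rsIDs.
    Cells may be allele pairs (``A/G``, ``D/I``) or dosage integers 0/1/2;
    empty cells are missing.  Columns not in the panel are warned about and
    ignored.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2:
        raise GenotypeParseError(f"{path}: expected an ID column plus rsID columns")
    id_col = df.columns[0]
    by_rsid = {s.rsid: s for s in panel.sites}

    unknown = [c for c in df.columns[1:] if c not in by_rsid]
    if unknown:
        warnings.warn(
            f"{path.name}: ignoring {len(unknown)} non-panel column(s): "
            + ", ".join(unknown),
            stacklevel=2,
        )

    patients = []
    for _, record in df.iterrows():
        pid = str(record[id_col])
        dosages: dict[str, Optional[int]] = {s.rsid: None for s in panel.sites}
        for col in df.columns[1:]:
            site = by_rsid.get(col)
            if site is None:
                continue
            dosages[col] = _parse_cell(record[col], site, row=pid, col=col)
        patients.append(PatientGenotype(pid, dosages))
    return patients


def write_genotypes_table(
    patients: Sequence[PatientGenotype], panel: Panel, path: str | Path
) -> None:
    """Write dosages as a patients-by-rsID integer matrix (blank = missing)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    rows = {
        p.patient_id: {
            rsid: ("" if p.dosage(rsid) is None else p.dosage(rsid))
            for rsid in panel.rsids
        }
        for p in patients
    }
    df = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=list(panel.rsids))
    df.index.name = "patient_id"
    df.to_csv(path, sep=sep)


# Synthetic contigs/coordinates used when writing panel sites to VCF; one
# panel site per megabase on a single artificial contig.
_VCF_CONTIG = "chr1"
_ACE_INS_SEQ = "TACAGTCACTT"  # stand-in insertion sequence for the ACE indel


def _vcf_ref_alt(site: VariantSite) -> tuple[str, str]:
    if site.functional_allele in ("D", "I"):
        # REF = insertion haplotype, ALT = deletion (shorter) haplotype
        return "A" + _ACE_INS_SEQ, "A"
    return site.other_allele or "N", site.functional_allele


def write_genotypes_vcf(
    patients: Sequence[PatientGenotype], panel: Panel, path: str | Path
) -> None:
    """Write dosages as a minimal VCFv4.2 with GT-only sample columns.

    SNP sites use REF = non-functional allele, ALT = functional allele; the
    ACE indel is written as a length-polymorphic REF/ALT pair whose shorter
    allele is the deletion.  Reading the file back with
    :func:`read_genotypes_vcf` reproduces the dosages exactly.
    """
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={_VCF_CONTIG}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(p.patient_id for p in patients),
    ]
    for k, site in enumerate(panel.sites):
        ref, alt = _vcf_ref_alt(site)
        pos = site.pos or (k + 1) * 1_000_000
        chrom = site.chrom or _VCF_CONTIG
        gts = []
        for p in patients:
            d = p.dosage(site.rsid)
            if d is None:
                gts.append("./.")
            else:
                # ALT carries the functional allele (count = dosage)
                gts.append("/".join(["1"] * d + ["0"] * (2 - d)))
        lines.append(
            f"{chrom}\t{pos}\t{site.rsid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
            + "\t".join(gts)
        )
    Path(path).write_text("\n".join(lines) + "\n")
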