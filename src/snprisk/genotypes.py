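"""Subject genotypes: reading (TSV / VCF) and encoding into model x-vectors.

Genotype classes are defined by the count of the marker's risk allele in
the diploid call: 0 -> non-carrier, 1 -> heterozygous, 2 -> homozygous
risk. Encoding maps these to the model's x-values: 0, 1 and x_hom
(ln(OR_hom)/ln(OR_het) when a homozygous OR exists, else the configured
carrier value). Missing calls encode as 0 by default and are counted.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Literal, Mapping, Optional

from .markers import MarkerCatalog, hwe_genotype_freqs
from .model import LogisticRiskModel

__all__ = [
    "GenotypeClass",
    "GenotypeProfile",
    "EncodedProfile",
    "GenotypeError",
    "read_genotype_tsv",
    "write_genotype_tsv",
    "read_stratum_map",
    "read_vcf",
    "encode",
]

MISSING_CALL = "./."

#: Strand-ambiguous SNP alleles (complement equals the other common allele).
_AMBIGUOUS_PAIRS = {frozenset("AT"), frozenset("CG")}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class GenotypeError(ValueError):
    """Raised for malformed or incompatible genotype calls in strict mode."""


class GenotypeClass(str, Enum):
    NON_CARRIER = "non_carrier"
    HETEROZYGOUS = "heterozygous"
    HOMOZYGOUS_RISK = "homozygous_risk"
    MISSING = "missing"


_BY_COUNT = (
    GenotypeClass.NON_CARRIER,
    GenotypeClass.HETEROZYGOUS,
    GenotypeClass.HOMOZYGOUS_RISK,
)


@dataclass(frozen=True)
class GenotypeProfile:
    """One subject's genotype classes at the catalog's SNPs."""

    subject_id: str
    stratum: str
    calls: Mapping[str, GenotypeClass]


@dataclass(frozen=True)
class EncodedProfile:
    """A subject's numeric x-vector aligned to a model's coefficients."""

    subject_id: str
    stratum: str
    x: tuple[float, ...]
    n_missing: int


def _classify_call(
    call: str, snp_id: str, risk_allele: str, subject_id: str, strict: bool
) -> GenotypeClass:
    call = call.strip().upper()
    if call in {MISSING_CALL, "..", "", "NA"}:
        return GenotypeClass.MISSING
    if len(call) != 2 or any(a not in "ACGT" for a in call):
        raise GenotypeError(
            f"subject {subject_id!r}, {snp_id}: malformed genotype call {call!r}"
        )
    count = call.count(risk_allele)
    if count == 0:
        # A call like "AG" for a C/T marker means the wrong locus or strand.
        alleles = set(call)
        complemented = {a.translate(_COMPLEMENT) for a in alleles}
        if risk_allele in complemented:
            msg = (
                f"subject {subject_id!r}, {snp_id}: call {call!r} matches the risk "
                f"allele {risk_allele} only on the opposite strand; strand flips are "
                "not auto-resolved"
            )
            if strict:
                raise GenotypeError(msg)
            warnings.warn(msg)
            return GenotypeClass.MISSING
    return _BY_COUNT[count]


def read_genotype_tsv(
    path: str | Path, catalog: MarkerCatalog, strict: bool = False
) -> list[GenotypeProfile]:
    """Read a subject-by-SNP genotype TSV.

    Header: ``subject_id<TAB>stratum<TAB><snp_id>...``; cells are unordered
    two-letter diploid calls ("AG" == "GA") or ``./.`` for missing. SNP
    columns not present in ``catalog`` raise; catalog SNPs absent from the
    file become missing calls.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or header[:2] != ["subject_id", "stratum"]:
            raise GenotypeError(
                f"{path}: header must start with 'subject_id\\tstratum'"
            )
        snp_cols = header[2:]
        unknown = [s for s in snp_cols if s not in catalog.snp_ids]
        if unknown:
            raise GenotypeError(f"{path}: SNP columns not in catalog: {unknown}")
        profiles: list[GenotypeProfile] = []
        for row in reader:
            if not row:
                continue
            subject_id, stratum = row[0], row[1]
            calls: dict[str, GenotypeClass] = {}
            for snp_id, cell in zip(snp_cols, row[2:]):
                calls[snp_id] = _classify_call(
                    cell, snp_id, catalog[snp_id].risk_allele, subject_id, strict
                )
            for snp_id in catalog.snp_ids:
                calls.setdefault(snp_id, GenotypeClass.MISSING)
            profiles.append(GenotypeProfile(subject_id, stratum, calls))
    return profiles


def write_genotype_tsv(
    profiles: list[GenotypeProfile], catalog: MarkerCatalog, path: str | Path
) -> None:
    """Write profiles in the dialect :func:`read_genotype_tsv` reads.

    Genotype classes are rendered as two-letter calls using the marker's
    risk allele and a placeholder non-risk allele (the first base in
    A/C/G/T order that is neither the risk allele nor its strand
    complement, so the written call is never strand-ambiguous).
    """
    def other(allele: str) -> str:
        comp = allele.translate(_COMPLEMENT)
        return next(a for a in "ACGT" if a not in (allele, comp))

    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["subject_id", "stratum", *catalog.snp_ids])
        for p in profiles:
            row = [p.subject_id, p.stratum]
            for snp_id in catalog.snp_ids:
                risk = catalog[snp_id].risk_allele
                alt = other(risk)
                cls = p.calls.get(snp_id, GenotypeClass.MISSING)
                row.append(
                    {
                        GenotypeClass.NON_CARRIER: alt + alt,
                        GenotypeClass.HETEROZYGOUS: alt + risk,
                        GenotypeClass.HOMOZYGOUS_RISK: risk + risk,
                        GenotypeClass.MISSING: MISSING_CALL,
                    }[cls]
                )
            writer.writerow(row)


def read_stratum_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV ``subject_id<TAB>stratum`` (header optional)."""
    mapping: dict[str, str] = {}
    with Path(path).open(newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0] == "subject_id":
                continue
            mapping[row[0]] = row[1]
    return mapping


def read_vcf(
    path: str | Path,
    catalog: MarkerCatalog,
    stratum_map: Mapping[str, str],
    strict: bool = False,
) -> list[GenotypeProfile]:
    """Read genotypes from a VCF (v4.x), matching markers by rsID.

    The risk-allele count per sample is derived from the GT field against
    REF/ALT. A risk allele matching neither REF nor any ALT is warned
    about and treated as missing (``strict=True`` raises instead); strand
    flips are never auto-resolved. Catalog sites absent from the VCF are
    missing for every subject.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    unknown = [s for s in samples if s not in stratum_map]
    if unknown:
        raise GenotypeError(f"samples without a stratum assignment: {unknown}")

    calls: dict[str, dict[str, GenotypeClass]] = {
        s: {snp: GenotypeClass.MISSING for snp in catalog.snp_ids} for s in samples
    }
    wanted = set(catalog.snp_ids)
    for variant in vcf:
        rsid = variant.ID
        if rsid not in wanted:
            continue
        marker = catalog[rsid]
        alleles = [variant.REF, *variant.ALT]
        if marker.risk_allele not in alleles:
            msg = (
                f"{rsid}: risk allele {marker.risk_allele} matches neither REF "
                f"{variant.REF} nor ALT {variant.ALT}"
            )
            if strict:
                raise GenotypeError(msg)
            warnings.warn(msg)
            continue
        risk_idx = alleles.index(marker.risk_allele)
        if frozenset((variant.REF, *variant.ALT[:1])) in _AMBIGUOUS_PAIRS:
            warnings.warn(
                f"{rsid}: strand-ambiguous {variant.REF}/{variant.ALT[0]} site; "
                "verify the reporting strand matches the catalog"
            )
        for sample, gt in zip(samples, variant.genotypes):
            gt_alleles = [a for a in gt[:-1] if a is not None and a >= 0]
            if len(gt_alleles) < 2:
                calls[sample][rsid] = GenotypeClass.MISSING
                continue
            count = sum(1 for a in gt_alleles if a == risk_idx)
            calls[sample][rsid] = _BY_COUNT[min(count, 2)]
    return [
        GenotypeProfile(subject_id=s, stratum=stratum_map[s], calls=calls[s])
        for s in samples
    ]


def encode(
    profile: GenotypeProfile,
    model: LogisticRiskModel,
    missing: Literal["zero", "hwe"] = "zero",
) -> EncodedProfile:
    """Encode a genotype profile into the model's x-vector.

    non_carrier -> 0, heterozygous -> 1, homozygous_risk -> the marker's
    x_hom. Missing calls encode as 0 ("zero", default, counted in
    ``n_missing``) or as the Hardy-Weinberg expectation of x ("hwe").
    """
    if profile.stratum not in model.intercepts:
        raise KeyError(
            f"subject {profile.subject_id!r}: unknown stratum {profile.stratum!r}; "
            f"model has {sorted(model.intercepts)}"
        )
    x: list[float] = []
    n_missing = 0
    for entry in model.coefficients:
        cls = profile.calls.get(entry.snp_id, GenotypeClass.MISSING)
        if cls is GenotypeClass.NON_CARRIER:
            x.append(0.0)
        elif cls is GenotypeClass.HETEROZYGOUS:
            x.append(1.0)
        elif cls is GenotypeClass.HOMOZYGOUS_RISK:
            x.append(entry.x_hom)
        else:
            n_missing += 1
            if missing == "zero":
                x.append(0.0)
            elif missing == "hwe":
                het_f, hom_f = hwe_genotype_freqs(model.catalog[entry.snp_id].freq)
                x.append(het_f * 1.0 + hom_f * entry.x_hom)
            else:
                raise ValueError(f"unknown missing policy {missing!r}")
    return EncodedProfile(
        subject_id=profile.subject_id,
        stratum=profile.stratum,
        x=tuple(x),
        n_missing=n_missing,
    )
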