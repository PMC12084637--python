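"""Variant filtering and polarization against an ancestral genome.

Biallelic SNVs passing call-rate and minor-allele-count filters are
oriented by matching their alleles to the inferred ancestral base: the
allele equal to the ancestral base is the ancestral allele, the other is
the derived allele.  Sites where neither allele matches (or the ancestral
base is undefined) are rejected, as are sites whose derived allele has
nearly fixed (DAF >= 0.98 by default), following the convention that a
near-fixed "derived" allele more likely reflects ancestral misassignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import pysam

from ._seq import VALID_BASES
from .ancestral import AncestralGenome

__all__ = [
    "SiteRecord",
    "PolarizedVariant",
    "filter_site",
    "polarize_site",
    "daf_filter",
    "polarize_sites",
    "read_vcf_sites",
    "write_polarized_vcf",
    "read_polarized_vcf",
]

#: machine-readable rejection reason codes
REASONS = (
    "not_snv",
    "multiallelic",
    "call_rate",
    "mac",
    "ancestral_undefined",
    "ancestral_mismatch",
    "daf",
)


@dataclass
class SiteRecord:
    """A parsed biallelic VCF site, format-agnostic.

    ``genotypes`` holds one ``(allele_a, allele_b)`` tuple per sample with
    allele indices 0 (REF) / 1 (ALT) and ``None`` for missing; ``phased``
    holds the per-sample phase flag (allele order within a phased tuple is
    the haplotype order).
    """

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alts: tuple[str, ...]
    genotypes: list[tuple[Optional[int], Optional[int]]]
    phased: list[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.phased:
            self.phased = [False] * len(self.genotypes)

    @property
    def alt(self) -> str:
        return self.alts[0]

    def allele_counts(self) -> tuple[int, int, int]:
        """(ref copies, alt copies, missing allele slots)."""
        n_ref = n_alt = n_missing = 0
        for a, b in self.genotypes:
            for allele in (a, b):
                if allele is None:
                    n_missing += 1
                elif allele == 0:
                    n_ref += 1
                else:
                    n_alt += 1
        return n_ref, n_alt, n_missing


@dataclass
class PolarizedVariant:
    """A biallelic SNV with ancestral/derived alleles resolved."""

    chrom: str
    pos: int  # 1-based
    ancestral: str
    derived: str
    derived_is_alt: bool
    daf: float
    genotypes: list[tuple[Optional[int], Optional[int]]]
    phased: list[bool]

    def derived_copies(self, sample_index: int) -> int:
        """Number of derived-allele copies carried by one sample."""
        target = 1 if self.derived_is_alt else 0
        return sum(
            1 for a in self.genotypes[sample_index] if a is not None and a == target
        )

    def haplotype_carriers(self) -> set[tuple[int, int]]:
        """Set of (sample index, haplotype index) carrying the derived allele.

        Meaningful only when genotypes are phased.
        """
        target = 1 if self.derived_is_alt else 0
        carriers = set()
        for s, (a, b) in enumerate(self.genotypes):
            if a == target:
                carriers.add((s, 0))
            if b == target:
                carriers.add((s, 1))
        return carriers


def filter_site(
    record: SiteRecord, call_rate_min: float = 0.9, mac_min: int = 3
) -> Optional[str]:
    """Return ``None`` to keep a site, or a rejection reason code.

    Keeps only biallelic SNVs (single-base REF and ALT in {A,C,G,T}) with
    allele call rate >= ``call_rate_min`` and minor allele count >=
    ``mac_min`` (the default reproduces the conventional MAC > 2 filter).
    """
    if len(record.alts) != 1:
        return "multiallelic"
    if (
        len(record.ref) != 1
        or len(record.alt) != 1
        or record.ref.upper() not in VALID_BASES
        or record.alt.upper() not in VALID_BASES
    ):
        return "not_snv"
    n_ref, n_alt, n_missing = record.allele_counts()
    total = n_ref + n_alt + n_missing
    if total == 0:
        return "call_rate"
    if (n_ref + n_alt) / total < call_rate_min:
        return "call_rate"
    if min(n_ref, n_alt) < mac_min:
        return "mac"
    return None


def polarize_site(
    record: SiteRecord, ancestral: AncestralGenome
) -> PolarizedVariant | str:
    """Polarize a filtered site; returns a variant or a rejection code."""
    anc_base = ancestral.base(record.chrom, record.pos - 1)
    ref, alt = record.ref.upper(), record.alt.upper()
    if anc_base == "N":
        return "ancestral_undefined"
    if anc_base == ref:
        derived, derived_is_alt = alt, True
    elif anc_base == alt:
        derived, derived_is_alt = ref, False
    else:
        return "ancestral_mismatch"
    n_ref, n_alt, _ = record.allele_counts()
    called = n_ref + n_alt
    derived_copies = n_alt if derived_is_alt else n_ref
    daf = derived_copies / called if called else 0.0
    return PolarizedVariant(
        chrom=record.chrom,
        pos=record.pos,
        ancestral=anc_base,
        derived=derived,
        derived_is_alt=derived_is_alt,
        daf=daf,
        genotypes=record.genotypes,
        phased=record.phased,
    )


def daf_filter(variant: PolarizedVariant, daf_max: float = 0.98) -> bool:
    """Keep iff the derived allele frequency is strictly below ``daf_max``."""
    return variant.daf < daf_max


def polarize_sites(
    records: Iterable[SiteRecord],
    ancestral: AncestralGenome,
    call_rate_min: float = 0.9,
    mac_min: int = 3,
    daf_max: float = 0.98,
    rejections: dict | None = None,
) -> Iterator[PolarizedVariant]:
    """Filter + polarize + DAF-filter a stream of sites.

    Every input site ends up either yielded or counted once in
    ``rejections`` (reason code -> count) when a dict is supplied.
    """
    for record in records:
        reason = filter_site(record, call_rate_min=call_rate_min, mac_min=mac_min)
        if reason is None:
            result = polarize_site(record, ancestral)
            if isinstance(result, str):
                reason = result
            elif not daf_filter(result, daf_max=daf_max):
                reason = "daf"
            else:
                yield result
                continue
        if rejections is not None:
            rejections[reason] = rejections.get(reason, 0) + 1


# ---------------------------------------------------------------------------
# VCF I/O


def _site_from_pysam(rec) -> SiteRecord:
    genotypes = []
    phased = []
    for sample in rec.samples.values():
        gt = sample.get("GT", (None, None))
        if gt is None:
            gt = (None, None)
        if len(gt) == 1:  # haploid call: treat second slot as missing
            gt = (gt[0], None)
        genotypes.append((gt[0], gt[1]))
        phased.append(bool(sample.phased))
    return SiteRecord(
        chrom=rec.chrom,
        pos=rec.pos,
        ref=rec.ref or "",
        alts=tuple(rec.alts or ()),
        genotypes=genotypes,
        phased=phased,
    )


def read_vcf_sites(path: str) -> tuple[list[str], Iterator[SiteRecord]]:
    """Open a VCF and return (sample names, site iterator)."""
    vcf = pysam.VariantFile(path)
    samples = list(vcf.header.samples)

    def _iter():
        with vcf:
            for rec in vcf:
                yield _site_from_pysam(rec)

    return samples, _iter()


def write_polarized_vcf(
    path: str,
    variants: Sequence[PolarizedVariant],
    samples: Sequence[str],
    contig_lengths: dict[str, int],
) -> None:
    """Write polarized variants with AA and DAF INFO fields."""
    header = pysam.VariantHeader()
    for chrom, length in contig_lengths.items():
        header.contigs.add(chrom, length=length)
    header.info.add("AA", 1, "String", "Ancestral allele")
    header.info.add("DAF", 1, "Float", "Derived allele frequency")
    header.formats.add("GT", 1, "String", "Genotype")
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(path, "w", header=header) as out:
        for v in variants:
            ref = v.ancestral if v.derived_is_alt else v.derived
            alt = v.derived if v.derived_is_alt else v.ancestral
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, alleles=(ref, alt)
            )
            rec.info["AA"] = v.ancestral
            rec.info["DAF"] = v.daf
            for i, s in enumerate(samples):
                rec.samples[s]["GT"] = v.genotypes[i]
                rec.samples[s].phased = v.phased[i]
            out.write(rec)


def read_polarized_vcf(path: str) -> tuple[list[str], list[PolarizedVariant]]:
    """Load a VCF carrying AA INFO back into polarized variants."""
    vcf = pysam.VariantFile(path)
    samples = list(vcf.header.samples)
    variants = []
    with vcf:
        for rec in vcf:
            site = _site_from_pysam(rec)
            aa = rec.info.get("AA")
            if aa is None:
                raise ValueError(
                    f"record {rec.chrom}:{rec.pos} lacks the AA INFO field; "
                    "run polarization first"
                )
            ref, alt = site.ref.upper(), site.alt.upper()
            if aa == ref:
                derived, derived_is_alt = alt, True
            elif aa == alt:
                derived, derived_is_alt = ref, False
            else:
                raise ValueError(
                    f"AA={aa} matches neither allele at {rec.chrom}:{rec.pos}"
                )
            n_ref, n_alt, _ = site.allele_counts()
            called = n_ref + n_alt
            derived_copies = n_alt if derived_is_alt else n_ref
            variants.append(
                PolarizedVariant(
                    chrom=site.chrom,
                    pos=site.pos,
                    ancestral=aa,
                    derived=derived,
                    derived_is_alt=derived_is_alt,
                    daf=derived_copies / called if called else 0.0,
                    genotypes=site.genotypes,
                    phased=site.phased,
                )
            )
    return samples, variants
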