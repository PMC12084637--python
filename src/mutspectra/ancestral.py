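"""Ancestral genome reconstruction from MAF alignment blocks.

A whole-genome alignment between the reference assembly and an inferred
ancestor sequence (e.g. a CACTUS internal node exported with ``hal2maf``)
is distilled into a per-chromosome ancestral base string in reference
coordinates.  Every reference position covered by exactly one ungapped,
unambiguous ancestor base receives that base; everything else — uncovered
positions, ancestor gaps, ambiguous bases, and multiply-covered positions
without a strict majority — is set to ``N``.  The resulting sequence is the
substrate for variant polarization and K-mer target counting.
"""

from __future__ import annotations

import io
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

import pandas as pd
from Bio import AlignIO
from pyfaidx import Fasta

from ._seq import VALID_BASES, revcomp

__all__ = [
    "AlignmentBlock",
    "AncestralGenome",
    "MafParseError",
    "parse_maf",
    "build_ancestral",
    "coverage_report",
    "read_ancestral_fasta",
    "write_fasta",
]


class MafParseError(ValueError):
    """Raised for a structurally invalid MAF block."""


@dataclass
class AlignmentBlock:
    """One pairwise slice of a MAF block: reference row vs. ancestor row.

    Coordinates are normalized to the reference forward strand, 0-based.
    ``ref_text`` and ``anc_text`` are equal-length aligned strings over
    ``{A,C,G,T,N,-}`` (case preserved from the MAF).
    """

    ref_chrom: str
    ref_start: int
    ref_text: str
    anc_text: str
    anc_name: str

    def __post_init__(self) -> None:
        if len(self.ref_text) != len(self.anc_text):
            raise MafParseError(
                f"aligned rows differ in length for block at "
                f"{self.ref_chrom}:{self.ref_start}"
            )

    @property
    def ref_span(self) -> int:
        """Ungapped reference length of the block."""
        return len(self.ref_text) - self.ref_text.count("-")


@dataclass
class AncestralGenome:
    """Per-chromosome ancestral base strings in reference coordinates.

    ``sequences`` maps chromosome name to an uppercase string over
    ``{A,C,G,T,N}`` whose length equals the reference chromosome length.
    """

    sequences: dict[str, str] = field(default_factory=dict)

    def base(self, chrom: str, pos0: int) -> str:
        """Ancestral base at a 0-based position."""
        seq = self.sequences[chrom]
        if pos0 < 0 or pos0 >= len(seq):
            raise IndexError(f"position {pos0} outside {chrom} (len {len(seq)})")
        return seq[pos0]

    def coverage(self) -> dict[str, float]:
        """Fraction of non-N bases per chromosome."""
        return {
            name: (len(s) - s.count("N")) / len(s) if s else 0.0
            for name, s in self.sequences.items()
        }


def _src_genome_and_chrom(src: str) -> tuple[str, str]:
    # hal2maf writes rows as "genome.chrom"; a bare name is its own genome.
    if "." in src:
        genome, chrom = src.split(".", 1)
        return genome, chrom
    return src, src


def parse_maf(
    maf: str | IO[str],
    ancestor_name: str,
    reference_name: str,
    stats: dict | None = None,
) -> Iterator[AlignmentBlock]:
    """Yield reference/ancestor :class:`AlignmentBlock` pairs from a MAF.

    Blocks lacking either the reference or the ancestor row are skipped
    (counted in ``stats['skipped_missing_row']`` when a dict is supplied).
    Reference rows on the '-' strand are flipped to forward orientation,
    reverse-complementing both aligned texts.
    """
    if stats is not None:
        stats.setdefault("blocks", 0)
        stats.setdefault("skipped_missing_row", 0)
    handle: IO[str]
    close = False
    if isinstance(maf, str):
        handle = open(maf)
        close = True
    else:
        handle = maf
    try:
        for i, aln in enumerate(AlignIO.parse(handle, "maf")):
            if stats is not None:
                stats["blocks"] += 1
            ref_rec = anc_rec = None
            for rec in aln:
                genome, chrom = _src_genome_and_chrom(rec.id)
                if genome == reference_name and ref_rec is None:
                    ref_rec = (rec, chrom)
                elif genome == ancestor_name and anc_rec is None:
                    anc_rec = rec
            if ref_rec is None or anc_rec is None:
                if stats is not None:
                    stats["skipped_missing_row"] += 1
                continue
            rec, chrom = ref_rec
            ref_text = str(rec.seq)
            anc_text = str(anc_rec.seq)
            if len(ref_text) != len(anc_text):
                raise MafParseError(f"row length mismatch in MAF block {i}")
            start = int(rec.annotations["start"])
            size = int(rec.annotations["size"])
            strand = rec.annotations.get("strand", 1)
            if strand in (-1, "-"):
                src_size = int(rec.annotations["srcSize"])
                start = src_size - start - size
                ref_text = revcomp(ref_text)
                anc_text = revcomp(anc_text)
            block = AlignmentBlock(
                ref_chrom=chrom,
                ref_start=start,
                ref_text=ref_text,
                anc_text=anc_text,
                anc_name=ancestor_name,
            )
            if block.ref_span != size:
                raise MafParseError(
                    f"MAF block {i}: reference row claims {size} bases but "
                    f"aligned text has {block.ref_span}"
                )
            yield block
    finally:
        if close:
            handle.close()


def build_ancestral(
    blocks: Iterable[AlignmentBlock],
    reference_lengths: dict[str, int],
) -> AncestralGenome:
    """Assemble the ancestral genome from alignment blocks.

    Each covered reference position collects one vote per covering block:
    the aligned ancestor base (uppercased; bases outside {A,C,G,T} and
    ancestor gaps vote 'N').  A position is assigned a base only when that
    base holds a strict majority of its votes; otherwise it stays 'N'.
    Uncovered positions are 'N'.
    """
    votes: dict[str, dict[int, Counter]] = defaultdict(lambda: defaultdict(Counter))
    for block in blocks:
        if block.ref_chrom not in reference_lengths:
            raise KeyError(f"unknown chromosome {block.ref_chrom!r} in MAF block")
        length = reference_lengths[block.ref_chrom]
        if block.ref_start + block.ref_span > length:
            raise ValueError(
                f"block at {block.ref_chrom}:{block.ref_start} extends past "
                f"chromosome end ({length})"
            )
        chrom_votes = votes[block.ref_chrom]
        pos = block.ref_start
        for ref_ch, anc_ch in zip(block.ref_text, block.anc_text):
            if ref_ch == "-":
                continue  # insertion in ancestor: no reference coordinate
            base = anc_ch.upper()
            if base not in VALID_BASES:
                base = "N"
            chrom_votes[pos][base] += 1
            pos += 1

    sequences: dict[str, str] = {}
    for chrom, length in reference_lengths.items():
        seq = bytearray(b"N" * length)
        for pos, counter in votes.get(chrom, {}).items():
            total = sum(counter.values())
            base, count = counter.most_common(1)[0]
            if base != "N" and 2 * count > total:
                seq[pos] = ord(base)
        sequences[chrom] = seq.decode()
    return AncestralGenome(sequences=sequences)


def coverage_report(ancestral: AncestralGenome) -> pd.DataFrame:
    """Per-chromosome and total coverage (fraction of non-N bases)."""
    rows = []
    for chrom, seq in ancestral.sequences.items():
        covered = len(seq) - seq.count("N")
        rows.append(
            {
                "chrom": chrom,
                "length": len(seq),
                "covered": covered,
                "fraction": covered / len(seq) if seq else 0.0,
            }
        )
    total_len = sum(r["length"] for r in rows)
    total_cov = sum(r["covered"] for r in rows)
    rows.append(
        {
            "chrom": "TOTAL",
            "length": total_len,
            "covered": total_cov,
            "fraction": total_cov / total_len if total_len else 0.0,
        }
    )
    return pd.DataFrame(rows, columns=["chrom", "length", "covered", "fraction"])


def write_fasta(sequences: dict[str, str], path: str, width: int = 60) -> None:
    """Write sequences as FASTA with fixed line width."""
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_ancestral_fasta(path: str) -> AncestralGenome:
    """Load an ancestral genome from FASTA (bases uppercased)."""
    fa = Fasta(path, as_raw=True, sequence_always_upper=True, rebuild=True)
    sequences = {name: str(fa[name][:]) for name in fa.keys()}
    fa.close()
    return AncestralGenome(sequences=sequences)
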