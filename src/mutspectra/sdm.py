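"""Sequential dinucleotide mutation (SDM) detection and spectra.

Directly adjacent polarized SNVs are paired and classified from phased
haplotypes: pairs whose derived alleles ride on identical haplotype sets
are multi-nucleotide polymorphisms (MNPs, one mutational event), while
pairs with differing carriage arose from two events at different times —
SDMs.  The temporal order of an SDM's two changes is inferred from
derived allele frequencies (the older change is the more frequent one),
giving a three-step path ancestral dinucleotide -> intermediate ->
derived dinucleotide, strand-canonicalized into a channel label such as
``CA>TA>TG``.  Per-sample spectra count haplotypes carrying both derived
alleles; ancestral dinucleotide occurrence counts serve as the
normalization targets, analogously to the K-mer targets for SNVs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from ._seq import VALID_BASES, revcomp
from .ancestral import AncestralGenome
from .polarize import PolarizedVariant

__all__ = [
    "SDMType",
    "AdjacentPair",
    "UnphasedGenotypesError",
    "find_adjacent_pairs",
    "classify_pair",
    "sdm_type",
    "count_sdm_spectra",
    "dinuc_targets",
    "canonical_dinuc",
]

UNRESOLVED_PREFIX = "unresolved:"


class UnphasedGenotypesError(ValueError):
    """Raised when SDM analysis meets unphased genotypes.

    Phase the VCF upstream, or pass ``unphased='drop'`` to discard pairs
    with unphased carriers.
    """


@dataclass(frozen=True)
class SDMType:
    """A canonical SDM channel: ancestral -> intermediate -> derived path."""

    anc_dinuc: str
    intermediate_dinuc: str
    derived_dinuc: str

    @property
    def label(self) -> str:
        return f"{self.anc_dinuc}>{self.intermediate_dinuc}>{self.derived_dinuc}"

    def __str__(self) -> str:  # pragma: no cover
        return self.label


@dataclass
class AdjacentPair:
    """Two polarized SNVs at consecutive positions on one chromosome."""

    left: PolarizedVariant
    right: PolarizedVariant
    classification: str = ""  # "SDM" | "MNP"
    order: str = ""  # "left_first" | "right_first" | "unresolved" | "" (MNP)
    left_carriers: set = field(default_factory=set)
    right_carriers: set = field(default_factory=set)

    @property
    def both_carriers(self) -> set:
        """Haplotypes carrying both derived alleles."""
        return self.left_carriers & self.right_carriers


def _check_phasing(variant: PolarizedVariant, unphased: str) -> bool:
    """True when the variant is usable; raises or drops on unphased hets."""
    for (a, b), ph in zip(variant.genotypes, variant.phased):
        if a is None or b is None:
            continue
        if a != b and not ph:
            if unphased == "drop":
                return False
            raise UnphasedGenotypesError(
                f"unphased heterozygote at {variant.chrom}:{variant.pos}; "
                "phase the VCF or pass unphased='drop'"
            )
    return True


def find_adjacent_pairs(
    variants: Iterable[PolarizedVariant], unphased: str = "error"
) -> Iterator[AdjacentPair]:
    """Yield every consecutive same-chromosome pair at distance 1.

    ``variants`` must be position-sorted within each chromosome.  Each
    pair is classified (see :func:`classify_pair`) before being yielded.
    """
    prev: PolarizedVariant | None = None
    prev_ok = False
    for v in variants:
        ok = _check_phasing(v, unphased)
        if (
            prev is not None
            and prev.chrom == v.chrom
            and v.pos == prev.pos + 1
            and prev_ok
            and ok
        ):
            pair = AdjacentPair(
                left=prev,
                right=v,
                left_carriers=prev.haplotype_carriers(),
                right_carriers=v.haplotype_carriers(),
            )
            classify_pair(pair)
            yield pair
        prev, prev_ok = v, ok


def classify_pair(pair: AdjacentPair) -> AdjacentPair:
    """Classify an adjacent pair as MNP or SDM and set the event order.

    MNP iff both derived alleles occur on identical haplotype sets (the
    single-event signature); otherwise SDM with the higher-DAF site as
    the first (older) event, or ``unresolved`` on an exact DAF tie.
    """
    if pair.left_carriers == pair.right_carriers:
        pair.classification = "MNP"
        pair.order = ""
    else:
        pair.classification = "SDM"
        if pair.left.daf > pair.right.daf:
            pair.order = "left_first"
        elif pair.right.daf > pair.left.daf:
            pair.order = "right_first"
        else:
            pair.order = "unresolved"
    return pair


def canonical_dinuc(dinuc: str) -> str:
    """Lexicographically smaller of a dinucleotide and its reverse complement."""
    return min(dinuc, revcomp(dinuc))


def sdm_type(pair: AdjacentPair, ancestral: AncestralGenome) -> SDMType | str:
    """Build the canonical SDM channel for a classified SDM pair.

    The path applies the first (older) change to the ancestral
    dinucleotide, then the second.  Between the path and its reverse
    complement (both dinucleotides complemented and their positions
    swapped), the label whose ancestral dinucleotide — then full label —
    is lexicographically smaller is kept, so each physical event maps to
    exactly one channel.  Pairs with unresolved order return an
    ``"unresolved:AN>DN"`` channel over the canonical ancestral/derived
    dinucleotides.
    """
    if pair.classification != "SDM":
        raise ValueError("sdm_type requires an SDM-classified pair")
    anc = pair.left.ancestral + pair.right.ancestral
    der = pair.left.derived + pair.right.derived
    if any(b not in VALID_BASES for b in anc + der):
        raise ValueError(f"non-ACGT base in SDM pair at {pair.left.chrom}:{pair.left.pos}")
    if pair.order == "unresolved":
        a, d = anc, der
        if (revcomp(a), revcomp(d)) < (a, d):
            a, d = revcomp(a), revcomp(d)
        return f"{UNRESOLVED_PREFIX}{a}>{d}"
    if pair.order == "left_first":
        inter = pair.left.derived + pair.right.ancestral
    else:
        inter = pair.left.ancestral + pair.right.derived
    fwd = (anc, inter, der)
    rev = (revcomp(anc), revcomp(inter), revcomp(der))
    chosen = min(fwd, rev)
    return SDMType(*chosen)


def count_sdm_spectra(
    pairs: Iterable[AdjacentPair],
    samples: Sequence[str],
    ancestral: AncestralGenome,
) -> pd.DataFrame:
    """Per-sample SDM spectra (samples x SDM channels).

    A sample's cell for a channel grows by the number of its haplotypes
    carrying both derived alleles of each SDM pair of that channel.  MNP
    pairs are excluded; unresolved-order SDMs accumulate under their
    ``unresolved:`` channel.
    """
    cells: dict[str, np.ndarray] = {}
    n = len(samples)
    for pair in pairs:
        if pair.classification != "SDM":
            continue
        t = sdm_type(pair, ancestral)
        label = t if isinstance(t, str) else t.label
        col = cells.setdefault(label, np.zeros(n, dtype=np.int64))
        for sample_idx, _hap in pair.both_carriers:
            col[sample_idx] += 1
    if not cells:
        return pd.DataFrame(
            np.zeros((n, 0), dtype=np.int64), index=list(samples)
        )
    df = pd.DataFrame(cells, index=list(samples))
    return df[sorted(df.columns)]


def dinuc_targets(ancestral: AncestralGenome) -> pd.Series:
    """Canonical ancestral dinucleotide occurrence counts.

    Every window of two consecutive ACGT bases adds 1 to the
    lexicographically canonical orientation of its dinucleotide — the
    opportunity denominator for SDM rate normalization.
    """
    dinucs = sorted({canonical_dinuc(a + b) for a in "ACGT" for b in "ACGT"})
    counts = dict.fromkeys(dinucs, 0)
    for seq in ancestral.sequences.values():
        for i in range(len(seq) - 1):
            d = seq[i : i + 2]
            if d[0] in VALID_BASES and d[1] in VALID_BASES:
                counts[canonical_dinuc(d)] += 1
    return pd.Series(counts, name="count")


def sdm_channel_target(label: str) -> str:
    """Map an SDM channel label to its ancestral-dinucleotide target key."""
    if label.startswith(UNRESOLVED_PREFIX):
        anc = label[len(UNRESOLVED_PREFIX) :].split(">")[0]
    else:
        anc = label.split(">")[0]
    return canonical_dinuc(anc)
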