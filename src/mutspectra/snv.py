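"""K-mer SNV mutation typing and per-sample spectrum counting.

Each polarized SNV is annotated with its ancestral K-mer context (read
from the ancestral genome, i.e. the pre-mutation state) and strand-
collapsed so that the central ancestral base is A or C, yielding the
standard channel set: 6 channels for K=1, 96 for K=3 (the SBS layout),
1536 for K=5.  Spectra are accumulated per sample by derived-allele copy
(het = 1, hom-derived = 2); an optional random-allocation mode assigns
each variant to a single random carrier instead.  Ancestral K-mer target
counts provide the opportunity denominator for rate normalization.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from ._seq import VALID_BASES, complement, revcomp
from .ancestral import AncestralGenome
from .polarize import PolarizedVariant

__all__ = [
    "MutationType",
    "mutation_type",
    "channel_labels",
    "count_spectra",
    "kmer_targets",
    "collapse_cpg",
    "collapse_kmer",
    "parse_label",
]

_LABEL_RE = re.compile(r"^([ACGT]*)\[([ACGT])>([ACGT])\]([ACGT]*)$")


@dataclass(frozen=True)
class MutationType:
    """A strand-collapsed K-mer mutation channel.

    ``anc_kmer`` is the K-length ancestral context with central base A or
    C; ``derived_base`` is the post-mutation central base.
    """

    anc_kmer: str
    derived_base: str

    @property
    def k(self) -> int:
        return len(self.anc_kmer)

    @property
    def central(self) -> str:
        return self.anc_kmer[self.k // 2]

    @property
    def label(self) -> str:
        h = self.k // 2
        return (
            f"{self.anc_kmer[:h]}[{self.central}>{self.derived_base}]"
            f"{self.anc_kmer[h + 1:]}"
        )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def parse_label(label: str) -> MutationType:
    """Parse a channel label like ``A[C>T]G`` back into a MutationType."""
    m = _LABEL_RE.match(label)
    if not m:
        raise ValueError(f"not a K-mer mutation channel label: {label!r}")
    left, anc, der, right = m.groups()
    if len(left) != len(right):
        raise ValueError(f"asymmetric context in label {label!r}")
    return MutationType(anc_kmer=left + anc + right, derived_base=der)


def collapse_kmer(kmer: str) -> str:
    """Strand-collapse a K-mer so its central base is A or C."""
    k = len(kmer)
    if k % 2 == 0:
        raise ValueError("K must be odd")
    return kmer if kmer[k // 2] in "AC" else revcomp(kmer)


def channel_labels(k: int = 3) -> list[str]:
    """All channel labels for window size ``k``, in catalogue order.

    Channels carry a central ancestral base of A or C (the strand
    collapse used throughout this package); labels are sorted by base
    change (A>C ... C>T) then context.  For K=3 this yields the 96
    channels of the SBS layout up to reverse complementation of the
    T-central entries.
    """
    if k % 2 == 0 or k < 1:
        raise ValueError("K must be odd and >= 1")
    h = k // 2
    channels = []
    for central in "AC":
        for derived in "ACGT":
            if derived == central:
                continue
            for flanks in itertools.product("ACGT", repeat=2 * h):
                kmer = "".join(flanks[:h]) + central + "".join(flanks[h:])
                channels.append(MutationType(kmer, derived))
    return sorted(
        (c.label for c in channels),
        key=lambda lab: (lab[_label_change_slice(k)], lab),
    )


def _label_change_slice(k: int) -> slice:
    h = k // 2
    return slice(h + 1, h + 4)  # the "C>T" part inside the brackets


def mutation_type(
    variant: PolarizedVariant, ancestral: AncestralGenome, k: int = 3
) -> Optional[MutationType]:
    """Type a polarized SNV by its ancestral K-mer context.

    Returns ``None`` (context rejection) when the window runs off the
    chromosome end or contains a non-ACGT base.
    """
    if k % 2 == 0 or k < 1:
        raise ValueError("K must be odd and >= 1")
    h = k // 2
    seq = ancestral.sequences[variant.chrom]
    start = variant.pos - 1 - h
    end = variant.pos - 1 + h + 1
    if start < 0 or end > len(seq):
        return None
    window = seq[start:end]
    if any(b not in VALID_BASES for b in window):
        return None
    if window[h] != variant.ancestral:
        raise ValueError(
            f"ancestral genome base {window[h]} at {variant.chrom}:{variant.pos} "
            f"disagrees with variant ancestral allele {variant.ancestral}"
        )
    derived = variant.derived
    if window[h] in "GT":
        window = revcomp(window)
        derived = complement(derived)
    return MutationType(anc_kmer=window, derived_base=derived)


def count_spectra(
    variants: Iterable[PolarizedVariant],
    samples: Sequence[str],
    ancestral: AncestralGenome,
    k: int = 3,
    mode: str = "carrier-copies",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-sample K-mer mutation spectra (samples x channels).

    In ``carrier-copies`` mode (default) each sample's cell for a channel
    grows by the number of derived-allele copies it carries at each
    variant of that channel.  In ``random-allocation`` mode each variant
    contributes 1 to a single carrier drawn uniformly among its derived
    copies (requires ``rng``).
    """
    if mode not in ("carrier-copies", "random-allocation"):
        raise ValueError(f"unknown counting mode {mode!r}")
    if mode == "random-allocation" and rng is None:
        raise ValueError("random-allocation mode needs an rng")
    labels = channel_labels(k)
    col_index = {lab: j for j, lab in enumerate(labels)}
    mat = np.zeros((len(samples), len(labels)), dtype=np.int64)
    for v in variants:
        mt = mutation_type(v, ancestral, k=k)
        if mt is None:
            continue
        j = col_index[mt.label]
        copies = [(i, v.derived_copies(i)) for i in range(len(samples))]
        if mode == "carrier-copies":
            for i, c in copies:
                if c:
                    mat[i, j] += c
        else:
            pool = [i for i, c in copies for _ in range(c)]
            if pool:
                mat[pool[int(rng.integers(len(pool)))], j] += 1
    return pd.DataFrame(mat, index=list(samples), columns=labels)


def kmer_targets(ancestral: AncestralGenome, k: int = 3) -> pd.Series:
    """Collapsed K-mer occurrence counts across the ancestral genome.

    Slides a K-window over every chromosome; windows containing non-ACGT
    bases are skipped; each valid window adds 1 to its strand-collapsed
    K-mer (central base A/C).
    """
    if k % 2 == 0 or k < 1:
        raise ValueError("K must be odd and >= 1")
    kmers = [
        "".join(p[: k // 2]) + c + "".join(p[k // 2 :])
        for c in "AC"
        for p in itertools.product("ACGT", repeat=k - 1)
    ]
    counts = dict.fromkeys(sorted(kmers), 0)
    base_code = {b: i for i, b in enumerate("ACGT")}
    for seq in ancestral.sequences.values():
        if len(seq) < k:
            continue
        codes = np.frombuffer(seq.encode(), dtype=np.uint8)
        lut = np.full(256, -1, dtype=np.int64)
        for b, i in base_code.items():
            lut[ord(b)] = i
        coded = lut[codes]
        valid = coded >= 0
        # rolling validity and base-4 encoding of each window
        n = len(seq)
        window_valid = np.ones(n - k + 1, dtype=bool)
        window_code = np.zeros(n - k + 1, dtype=np.int64)
        for off in range(k):
            window_valid &= valid[off : off + n - k + 1]
            window_code = window_code * 4 + np.where(
                valid[off : off + n - k + 1], coded[off : off + n - k + 1], 0
            )
        codes_valid, freq = np.unique(window_code[window_valid], return_counts=True)
        bases = "ACGT"
        for code, f in zip(codes_valid, freq):
            kmer = "".join(
                bases[(code >> (2 * (k - 1 - i))) & 3] for i in range(k)
            )
            counts[collapse_kmer(kmer)] += int(f)
    return pd.Series(counts, name="count")


# CpG>TpG channels and the strand-collapsed labels of their reverse changes
# (TpG>CpG read on the same strand, i.e. X[T>C]G -> C[A>G]revcomp(X)).
_CPG_PAIRS = {
    f"{x}[C>T]G": "C[A>G]" + complement(x) for x in "ACGT"
}


def collapse_cpg(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pool CpG>TpG channels with their reverse-direction counterparts.

    For each 5' context X, counts of the reverse change X[T>C]G (which
    strand-collapses to C[A>G]X') are added into X[C>T]G and the reverse
    channel is dropped.  This guards the CpG deamination signal against
    ancestral-allele misassignment flipping the direction of change.
    Requires a K=3 matrix.
    """
    if not all(lab in matrix.columns for lab in _CPG_PAIRS):
        raise ValueError("collapse_cpg requires a K=3 channel matrix")
    out = matrix.copy()
    for fwd, rev in _CPG_PAIRS.items():
        out[fwd] = out[fwd] + out[rev]
    return out.drop(columns=list(_CPG_PAIRS.values()))
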