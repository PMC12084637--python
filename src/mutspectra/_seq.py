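"""Small shared sequence utilities."""

from __future__ import annotations

_COMP = str.maketrans("ACGTNacgtn-", "TGCANtgcan-")

VALID_BASES = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement; preserves gaps ('-') and N."""
    return seq.translate(_COMP)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMP)
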