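"""Spectrum normalization: ancestral targets, zero offset, median of ratios.

Raw channel counts are first divided by the occurrence count of the
channel's ancestral K-mer (or dinucleotide) in the ancestral genome,
turning counts into per-opportunity rates that are comparable across
genomes with different base compositions.  A second, sample-wise
normalization borrowed from RNA-seq analysis then removes differences in
total mutation number: each sample j receives the size factor

    s_hat_j = median_i  k_ij / ( prod_v k_iv )^(1/m)

— the median over channels i of the sample's rate divided by the
channel's geometric mean across all m samples — and its rates are
divided by s_hat_j.  Sparse matrices (many zero cells) would make the
median degenerate, so when zeros are present a small offset
1 x 10^floor(log10(smallest positive entry)) is added to every cell
beforehand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import snv

__all__ = [
    "NormalizationFactors",
    "target_normalize",
    "zero_offset",
    "median_of_ratios",
    "combine_datasets",
    "snv_channel_target",
]


@dataclass
class NormalizationFactors:
    """Per-sample median-of-ratios size factors."""

    s_hat: pd.Series
    pseudo_offset: float = 0.0

    @property
    def m(self) -> int:
        return len(self.s_hat)


def snv_channel_target(label: str) -> str:
    """Map an SNV channel label (e.g. ``A[C>T]G``) to its ancestral K-mer."""
    return snv.parse_label(label).anc_kmer


def target_normalize(
    counts: pd.DataFrame,
    targets: pd.Series,
    channel_to_target: Callable[[str], str] = snv_channel_target,
) -> pd.DataFrame:
    """Divide each channel's counts by its ancestral target count.

    ``channel_to_target`` maps a column label to a key of ``targets``;
    the default handles SNV K-mer labels, pass
    :func:`mutspectra.sdm.sdm_channel_target` for SDM matrices.
    """
    missing = []
    divisors = {}
    for col in counts.columns:
        key = channel_to_target(col)
        t = targets.get(key, 0)
        if t is None or t <= 0:
            missing.append(col)
        else:
            divisors[col] = float(t)
    if missing:
        raise ValueError(
            "channels with zero or missing ancestral target count: "
            + ", ".join(missing)
        )
    return counts.astype(float).div(pd.Series(divisors), axis=1)


def zero_offset(matrix: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Add the decade-of-smallest-positive-entry offset when zeros exist.

    If any cell is 0, every cell receives 10^floor(log10(min positive))
    (e.g. smallest positive entry 3.5e-9 -> offset 1e-9); a matrix
    without zeros is returned unchanged with offset 0.
    """
    values = matrix.to_numpy(dtype=float)
    if values.size == 0 or not (values > 0).any():
        raise ValueError("zero_offset needs at least one positive entry")
    if (values < 0).any():
        raise ValueError("negative entries are not valid spectrum rates")
    if not (values == 0).any():
        return matrix, 0.0
    smallest = values[values > 0].min()
    offset = 10.0 ** math.floor(math.log10(smallest))
    return matrix + offset, offset


def median_of_ratios(
    matrix: pd.DataFrame,
    stabilize: bool = False,
) -> tuple[pd.DataFrame, NormalizationFactors]:
    """Sample-wise median-of-ratios normalization (samples x channels).

    Channels whose geometric mean across samples is zero are excluded
    from the median; apply :func:`zero_offset` first for sparse data.

    The formula pins size factors only up to one global constant
    (scaling every factor by c and the normalized matrix by 1/c changes
    no comparison the method supports).  ``stabilize=True`` fixes that
    free constant by rescaling factors to geometric mean 1, which makes
    the operation exactly idempotent; the default leaves the factors as
    the formula prints them.
    """
    if len(matrix) < 1:
        raise ValueError("median_of_ratios needs at least one sample")
    values = matrix.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("negative entries are not valid spectrum rates")
    with np.errstate(divide="ignore"):
        logs = np.log(values)  # -inf where zero
    finite = np.isfinite(logs).all(axis=0)  # channels positive in all samples
    if not finite.any():
        raise ValueError("no channel is positive in every sample; apply zero_offset")
    log_gmean = logs[:, finite].mean(axis=0)
    ratios = values[:, finite] / np.exp(log_gmean)[None, :]
    s_hat = np.median(ratios, axis=1)
    if not (np.isfinite(s_hat).all() and (s_hat > 0).all()):
        raise ValueError("non-positive size factor; matrix too sparse")
    if stabilize:
        s_hat = s_hat / np.exp(np.mean(np.log(s_hat)))
    factors = NormalizationFactors(
        s_hat=pd.Series(s_hat, index=matrix.index, name="s_hat")
    )
    normalized = matrix.astype(float).div(factors.s_hat, axis=0)
    return normalized, factors


def combine_datasets(
    matrices: Sequence[pd.DataFrame],
) -> tuple[pd.DataFrame, NormalizationFactors, float]:
    """Row-concatenate target-normalized matrices and jointly normalize.

    All inputs must share an identical channel set and order; the joint
    matrix goes through :func:`zero_offset` then :func:`median_of_ratios`,
    placing all samples (e.g. from different species) on one scale.
    """
    if not matrices:
        raise ValueError("no matrices to combine")
    ref_cols = list(matrices[0].columns)
    for m in matrices[1:]:
        if list(m.columns) != ref_cols:
            extra = set(m.columns) ^ set(ref_cols)
            raise ValueError(
                "channel sets differ between datasets: " + ", ".join(sorted(extra))
            )
    joint = pd.concat(matrices, axis=0)
    offset_matrix, offset = zero_offset(joint)
    normalized, factors = median_of_ratios(offset_matrix)
    factors.pseudo_offset = offset
    return normalized, factors, offset
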