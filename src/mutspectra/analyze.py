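"""Downstream spectrum analyses.

PCA of normalized spectra, derived-allele-frequency-binned mutation-type
fractions (to localize "pulses" of a mutation type in a narrow frequency
range), per-channel chi-square enrichment tests between populations, and
rank-1 nonnegative matrix factorization of a pooled spectrum with cosine
matching against a signature catalogue (COSMIC SBS layout).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from ._seq import revcomp
from .polarize import PolarizedVariant
from .snv import MutationType, collapse_kmer, parse_label

__all__ = [
    "PCAResult",
    "pca",
    "default_daf_bins",
    "daf_fractions",
    "EnrichmentResult",
    "enrichment_test",
    "enrichment_scan",
    "rank1_signature",
    "MatchResult",
    "cosine_match",
    "read_signature_catalog",
    "canonicalize_channel",
]


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # channels x components
    variance_fractions: np.ndarray


def pca(
    matrix: pd.DataFrame,
    n_components: int | None = None,
    standardize: bool = True,
) -> PCAResult:
    """PCA of a normalized spectrum matrix (samples x channels).

    Columns are centered, and unit-scaled when ``standardize`` is true
    (constant columns are dropped — they carry no information and would
    divide by zero).  Uses an exact full SVD, so results are
    deterministic up to component sign.
    """
    if len(matrix) < 2:
        raise ValueError("PCA needs at least two samples")
    X = matrix.to_numpy(dtype=float)
    std = X.std(axis=0, ddof=0)
    keep = std > 0
    if not keep.any():
        raise ValueError("matrix is constant across samples; no variance for PCA")
    cols = matrix.columns[keep]
    X = X[:, keep]
    X = X - X.mean(axis=0)
    if standardize:
        X = X / std[keep]
    max_comp = min(X.shape[0] - 1, X.shape[1])
    k = max_comp if n_components is None else min(n_components, max_comp)
    model = PCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(X)
    comp_names = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.index, columns=comp_names),
        loadings=pd.DataFrame(model.components_.T, index=cols, columns=comp_names),
        variance_fractions=model.explained_variance_ratio_,
    )


# ---------------------------------------------------------------------------
# DAF-binned fractions (pulse analysis)


def default_daf_bins(
    n_haplotypes: int, daf_max: float = 0.98, n_bins: int = 8
) -> np.ndarray:
    """Logarithmically spaced DAF bin edges over (1/n_haplotypes, daf_max].

    Log spacing resolves the low-frequency range where mutation pulses
    (e.g. the TCC>TTC pulse around 1% frequency) live.
    """
    lo = 1.0 / max(n_haplotypes, 2)
    return np.geomspace(lo, daf_max, n_bins + 1)


def _population_daf(variant: PolarizedVariant, sample_idx: Sequence[int]) -> float:
    called = derived = 0
    target = 1 if variant.derived_is_alt else 0
    for i in sample_idx:
        for a in variant.genotypes[i]:
            if a is not None:
                called += 1
                if a == target:
                    derived += 1
    return derived / called if called else 0.0


def daf_fractions(
    typed_variants: Iterable[tuple[PolarizedVariant, MutationType]],
    samples: Sequence[str],
    populations: Mapping[str, str],
    bin_edges: Sequence[float],
) -> dict[str, pd.DataFrame]:
    """Per-population, per-DAF-bin fractions of each mutation type.

    DAF is recomputed within each population; variants not segregating in
    a population (population DAF 0, or 1 after recomputation) are not
    counted for it.  Bins are half-open ``(edge[i], edge[i+1]]``.
    Returns population -> DataFrame (bins x channels) of fractions, with
    the per-bin variant count in an extra ``n_variants`` column.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if len(edges) < 2 or not (np.diff(edges) > 0).all():
        raise ValueError("bin edges must be strictly increasing")
    pop_samples: dict[str, list[int]] = {}
    for i, s in enumerate(samples):
        pop = populations.get(s)
        if pop is not None:
            pop_samples.setdefault(pop, []).append(i)
    counts: dict[str, dict[int, dict[str, int]]] = {
        p: {b: {} for b in range(len(edges) - 1)} for p in pop_samples
    }
    for variant, mtype in typed_variants:
        label = mtype.label
        for pop, idx in pop_samples.items():
            daf = _population_daf(variant, idx)
            if daf <= 0 or daf >= 1:
                continue
            b = int(np.searchsorted(edges, daf, side="left")) - 1
            if b < 0 or b >= len(edges) - 1:
                continue
            bin_counts = counts[pop][b]
            bin_counts[label] = bin_counts.get(label, 0) + 1
    out = {}
    labels = sorted({lab for p in counts.values() for b in p.values() for lab in b})
    bin_names = [f"({edges[i]:.6g},{edges[i + 1]:.6g}]" for i in range(len(edges) - 1)]
    for pop, bins in counts.items():
        mat = pd.DataFrame(0.0, index=bin_names, columns=labels)
        n_col = []
        for b, bin_counts in bins.items():
            total = sum(bin_counts.values())
            n_col.append(total)
            if total:
                for lab, c in bin_counts.items():
                    mat.iloc[b, mat.columns.get_loc(lab)] = c / total
        mat["n_variants"] = n_col
        out[pop] = mat
    return out


# ---------------------------------------------------------------------------
# Enrichment testing


@dataclass
class EnrichmentResult:
    mutation_type: str
    table: np.ndarray  # 2x2: [type, other] x [pop A, pop B]
    statistic: float
    p_value: float
    low_count: bool = False
    p_adjusted: float | None = None


def enrichment_test(
    counts_a: Mapping[str, int] | pd.Series,
    counts_b: Mapping[str, int] | pd.Series,
    mutation_type: str,
) -> EnrichmentResult:
    """Chi-square (1 df) test of one channel's share between populations.

    Builds the 2x2 table [count of the type, count of all other types]
    x [population A, population B] and applies Pearson's chi-square
    without continuity correction.  Tables with any expected cell < 5
    are flagged ``low_count`` (the statistic is still computed).
    """
    a = pd.Series(counts_a, dtype=float)
    b = pd.Series(counts_b, dtype=float)
    ta, tb = a.sum(), b.sum()
    if ta <= 0 or tb <= 0:
        raise ValueError("both populations need positive total counts")
    xa = float(a.get(mutation_type, 0.0))
    xb = float(b.get(mutation_type, 0.0))
    table = np.array([[xa, ta - xa], [xb, tb - xb]]).T  # [type, other] x [A, B]
    if (table == 0).all(axis=1).any():
        statistic, p = 0.0, 1.0
        expected = table.astype(float)
    else:
        statistic, p, _, expected = stats.chi2_contingency(table, correction=False)
    return EnrichmentResult(
        mutation_type=mutation_type,
        table=table,
        statistic=float(statistic),
        p_value=float(p),
        low_count=bool((expected < 5).any()),
    )


def enrichment_scan(
    counts_a: Mapping[str, int] | pd.Series,
    counts_b: Mapping[str, int] | pd.Series,
    adjust: str = "bonferroni",
) -> pd.DataFrame:
    """Test every channel present in either population; adjust p-values.

    ``adjust`` is one of ``bonferroni`` (default), ``bh`` or ``none``.
    Returns a DataFrame sorted by p-value.
    """
    if adjust not in ("bonferroni", "bh", "none"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    a = pd.Series(counts_a, dtype=float)
    b = pd.Series(counts_b, dtype=float)
    labels = sorted(set(a.index) | set(b.index))
    results = [enrichment_test(a, b, lab) for lab in labels]
    p = np.array([r.p_value for r in results])
    m = len(p)
    if adjust == "bonferroni":
        p_adj = np.minimum(p * m, 1.0)
    elif adjust == "bh":
        order = np.argsort(p)
        ranked = p[order] * m / (np.arange(m) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        p_adj = np.empty(m)
        p_adj[order] = np.minimum(ranked, 1.0)
    else:
        p_adj = p
    rows = []
    for r, adj in zip(results, p_adj):
        r.p_adjusted = float(adj)
        rows.append(
            {
                "mutation_type": r.mutation_type,
                "count_a": r.table[0, 0],
                "other_a": r.table[1, 0],
                "count_b": r.table[0, 1],
                "other_b": r.table[1, 1],
                "statistic": r.statistic,
                "p_value": r.p_value,
                "p_adjusted": r.p_adjusted,
                "low_count": r.low_count,
            }
        )
    df = pd.DataFrame(rows).sort_values("p_value", kind="stable")
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Rank-1 signature extraction and catalogue matching


def rank1_signature(
    matrix: pd.DataFrame,
    max_iter: int = 1000,
    tol: float = 1e-9,
) -> tuple[pd.Series, pd.Series]:
    """Rank-1 NMF of a nonnegative spectrum matrix (samples x channels).

    Initialized from the leading singular pair (whose nonnegative
    rectification is the rank-1 global optimum up to scaling), then
    refined by multiplicative updates until the relative reconstruction
    error changes by less than ``tol``.  Returns (signature summing to 1
    over channels, per-sample exposures).
    """
    V = matrix.to_numpy(dtype=float)
    if (V < 0).any():
        raise ValueError("NMF input must be nonnegative")
    if not (V > 0).any():
        raise ValueError("NMF input is all zero")
    U, S, Vt = np.linalg.svd(V, full_matrices=False)
    w = np.abs(U[:, 0]) * np.sqrt(S[0])  # exposures
    h = np.abs(Vt[0, :]) * np.sqrt(S[0])  # signature
    w = np.maximum(w, 1e-12)
    h = np.maximum(h, 1e-12)
    norm_v = np.linalg.norm(V)
    prev_err = np.inf
    for _ in range(max_iter):
        # multiplicative updates for Frobenius-norm rank-1 NMF
        h *= (w @ V) / (w @ w * h + 1e-300)
        w *= (V @ h) / (h @ h * w + 1e-300)
        err = np.linalg.norm(V - np.outer(w, h)) / norm_v
        if abs(prev_err - err) < tol:
            break
        prev_err = err
    total = h.sum()
    signature = pd.Series(h / total, index=matrix.columns, name="signature")
    exposures = pd.Series(w * total, index=matrix.index, name="exposure")
    return signature, exposures


def canonicalize_channel(label: str) -> str:
    """Rewrite a 3-mer channel label so the central ancestral base is A/C.

    COSMIC catalogues use a central pyrimidine (C/T); this package uses
    central A/C.  Both conventions meet on this canonical form, allowing
    signatures from either to be compared channel-by-channel.
    """
    mt = parse_label(label)
    h = mt.k // 2
    if mt.anc_kmer[h] in "AC":
        return mt.label
    kmer = revcomp(mt.anc_kmer)
    derived = revcomp(mt.derived_base)
    return MutationType(anc_kmer=kmer, derived_base=derived).label


@dataclass
class MatchResult:
    matched: bool
    name: str | None
    similarity: float
    best_name: str
    best_similarity: float


def read_signature_catalog(path: str) -> pd.DataFrame:
    """Read a channels x signatures table (COSMIC SBS layout TSV).

    First column holds channel labels like ``A[C>A]A``; remaining columns
    are signatures.  Labels are canonicalized to this package's central
    A/C convention.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 1:
        raise ValueError("catalogue has no signature columns")
    if (df.to_numpy() < 0).any():
        raise ValueError("catalogue entries must be nonnegative")
    df.index = [canonicalize_channel(lab) for lab in df.index]
    return df


def cosine_match(
    signature: pd.Series,
    catalog: pd.DataFrame,
    cutoff: float = 0.8,
) -> MatchResult:
    """Best cosine match of a signature against a catalogue.

    Channel labels are canonicalized and must coincide as sets; the best
    catalogue signature is reported, flagged unmatched when its cosine
    similarity falls below ``cutoff``.
    """
    sig = signature.copy()
    sig.index = [canonicalize_channel(lab) for lab in sig.index]
    if set(sig.index) != set(catalog.index):
        missing = set(sig.index) ^ set(catalog.index)
        raise ValueError(
            "channel labels differ between signature and catalogue: "
            + ", ".join(sorted(missing)[:5])
        )
    cat = catalog.loc[sig.index]
    v = sig.to_numpy(dtype=float)
    M = cat.to_numpy(dtype=float)
    nv = np.linalg.norm(v)
    nM = np.linalg.norm(M, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sims = (v @ M) / (nv * nM)
    sims = np.nan_to_num(sims)
    best = int(np.argmax(sims))
    best_name = str(cat.columns[best])
    best_sim = float(sims[best])
    matched = best_sim >= cutoff
    return MatchResult(
        matched=matched,
        name=best_name if matched else None,
        similarity=best_sim if matched else 0.0,
        best_name=best_name,
        best_similarity=best_sim,
    )
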