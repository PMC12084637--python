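"""Independent brute-force reference implementations used as oracles.

Deliberately naive: plain loops, local complement tables, direct
transcription of formulas.  Nothing here imports the code paths it
checks.
"""

import math
import statistics

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq):
    return "".join(_COMP[b] for b in reversed(seq))


def brute_mutation_label(kmer, derived):
    """Strand-collapsed channel label from an ancestral K-mer + derived base."""
    h = len(kmer) // 2
    if kmer[h] in "GT":
        kmer = rc(kmer)
        derived = _COMP[derived]
    return f"{kmer[:h]}[{kmer[h]}>{derived}]{kmer[h + 1:]}"


def brute_snv_matrix(variants, samples, ancestral_sequences, k):
    """Per-sample channel counts by exhaustive (sample, variant) enumeration."""
    h = k // 2
    counts = {s: {} for s in samples}
    for v in variants:
        seq = ancestral_sequences[v.chrom]
        start, end = v.pos - 1 - h, v.pos - 1 + h + 1
        if start < 0 or end > len(seq):
            continue
        window = seq[start:end]
        if any(b not in "ACGT" for b in window):
            continue
        label = brute_mutation_label(window, v.derived)
        derived_code = 1 if v.derived_is_alt else 0
        for i, s in enumerate(samples):
            c = sum(1 for a in v.genotypes[i] if a is not None and a == derived_code)
            if c:
                counts[s][label] = counts[s].get(label, 0) + c
    return counts


def brute_kmer_targets(ancestral_sequences, k):
    """Collapsed K-mer counts by direct window enumeration."""
    h = k // 2
    counts = {}
    for seq in ancestral_sequences.values():
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if any(b not in "ACGT" for b in w):
                continue
            if w[h] in "GT":
                w = rc(w)
            counts[w] = counts.get(w, 0) + 1
    return counts


def brute_median_of_ratios(matrix_dict):
    """Direct transcription of the size-factor formula.

    ``matrix_dict``: sample -> {channel: value}.  Returns (normalized
    dict, factors dict).
    """
    samples = list(matrix_dict)
    channels = list(next(iter(matrix_dict.values())))
    m = len(samples)
    gmean = {}
    for ch in channels:
        prod = 1.0
        ok = True
        for s in samples:
            v = matrix_dict[s][ch]
            if v <= 0:
                ok = False
                break
            prod *= v ** (1.0 / m)
        gmean[ch] = prod if ok else 0.0
    factors = {}
    for s in samples:
        ratios = [
            matrix_dict[s][ch] / gmean[ch] for ch in channels if gmean[ch] > 0
        ]
        factors[s] = statistics.median(ratios)
    normalized = {
        s: {ch: matrix_dict[s][ch] / factors[s] for ch in channels} for s in samples
    }
    return normalized, factors


def brute_sdm_path(anc_l, anc_r, der_l, der_r, order):
    """Canonical SDM label by explicit path construction."""
    anc = anc_l + anc_r
    der = der_l + der_r
    inter = (der_l + anc_r) if order == "left_first" else (anc_l + der_r)
    fwd = (anc, inter, der)
    rev = (rc(anc), rc(inter), rc(der))
    a, i_, d = min(fwd, rev)
    return f"{a}>{i_}>{d}"


def brute_sdm_matrix(pairs, samples):
    """sample -> {sdm label: count} by haplotype enumeration.

    ``pairs``: iterables of (label, left_variant, right_variant).
    """
    counts = {s: {} for s in samples}
    for label, vl, vr in pairs:
        code_l = 1 if vl.derived_is_alt else 0
        code_r = 1 if vr.derived_is_alt else 0
        for i, s in enumerate(samples):
            for hap in (0, 1):
                if (
                    vl.genotypes[i][hap] == code_l
                    and vr.genotypes[i][hap] == code_r
                ):
                    counts[s][label] = counts[s].get(label, 0) + 1
    return counts


def brute_chi2(table):
    """Pearson chi-square for a 2x2 table [[a, b], [c, d]] by the textbook formula."""
    (a, b), (c, d) = table
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
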