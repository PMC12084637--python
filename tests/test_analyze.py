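import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oracles import brute_chi2
from mutspectra.analyze import (
    canonicalize_channel,
    cosine_match,
    daf_fractions,
    default_daf_bins,
    enrichment_scan,
    enrichment_test,
    pca,
    rank1_signature,
    read_signature_catalog,
)
from mutspectra.polarize import PolarizedVariant
from mutspectra.snv import MutationType, channel_labels


def _matrix(seed=0, n=12, c=20):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.gamma(4.0, 1.0, size=(n, c)),
        index=[f"s{i}" for i in range(n)],
        columns=channel_labels(3)[:c],
    )


class TestPca:
    def test_single_differing_channel_drives_pc1(self):
        mat = _matrix(seed=1)
        mat.iloc[:6, 3] += 50.0  # group structure in one channel
        res = pca(mat, n_components=2, standardize=False)
        g1 = res.scores.iloc[:6, 0]
        g2 = res.scores.iloc[6:, 0]
        assert (g1.max() < g2.min()) or (g2.max() < g1.min())
        loading = res.loadings["PC1"].abs()
        assert loading.idxmax() == mat.columns[3]

    def test_variance_fractions_nonincreasing_and_bounded(self):
        res = pca(_matrix(seed=2))
        vf = res.variance_fractions
        assert (np.diff(vf) <= 1e-12).all()
        assert vf.sum() <= 1 + 1e-9

    def test_scores_match_eigendecomposition_oracle(self):
        mat = _matrix(seed=3)
        res = pca(mat, n_components=4, standardize=False)
        X = mat.to_numpy() - mat.to_numpy().mean(axis=0)
        w, v = np.linalg.eigh(X.T @ X)
        order = np.argsort(w)[::-1]
        for j in range(4):
            oracle = X @ v[:, order[j]]
            got = res.scores.iloc[:, j].to_numpy()
            assert np.allclose(got, oracle, atol=1e-8) or np.allclose(
                got, -oracle, atol=1e-8
            )

    def test_sample_reordering_leaves_scores_invariant_up_to_sign(self):
        mat = _matrix(seed=4)
        res = pca(mat, n_components=3)
        rng = np.random.default_rng(0)
        perm = rng.permutation(mat.index)
        res2 = pca(mat.loc[perm], n_components=3)
        for j in range(3):
            a = res.scores.iloc[:, j].loc[perm].to_numpy()
            b = res2.scores.iloc[:, j].to_numpy()
            assert np.allclose(a, b, atol=1e-9) or np.allclose(a, -b, atol=1e-9)

    def test_constant_matrix_is_error(self):
        mat = pd.DataFrame(np.ones((4, 5)))
        with pytest.raises(ValueError, match="constant"):
            pca(mat)


def _daf_variant(pos, daf_copies, n_samples, mtype_central="C", derived="T"):
    """A variant with the given number of derived copies spread over haplotypes."""
    gts = [[0, 0] for _ in range(n_samples)]
    for h in range(daf_copies):
        gts[h // 2][h % 2] = 1
    called = 2 * n_samples
    return PolarizedVariant(
        "chr1", pos, mtype_central, derived, True, daf_copies / called,
        [tuple(g) for g in gts], [True] * n_samples,
    )


class TestDafFractions:
    def _typed(self, variants, labels):
        out = []
        for v, lab in zip(variants, labels):
            h = lab.index("[")
            mt = MutationType(
                anc_kmer=lab[:h] + lab[h + 1] + lab[-1], derived_base=lab[h + 3]
            )
            out.append((v, mt))
        return out

    def test_single_bin_fraction(self):
        n = 10
        variants = [_daf_variant(p, 4, n) for p in (10, 20, 30)]
        typed = self._typed(variants, ["A[C>T]G", "A[C>T]G", "T[C>A]T"])
        pops = {f"s{i}": "P" for i in range(n)}
        samples = [f"s{i}" for i in range(n)]
        out = daf_fractions(typed, samples, pops, [0.0, 1.0])
        frac = out["P"]
        assert frac.loc[frac.index[0], "A[C>T]G"] == pytest.approx(2 / 3)
        assert frac.loc[frac.index[0], "n_variants"] == 3

    def test_fractions_sum_to_one_per_nonempty_bin(self):
        n = 20
        rng = np.random.default_rng(8)
        variants = []
        labels = []
        for i in range(60):
            variants.append(_daf_variant(10 + i * 3, int(rng.integers(1, 2 * n)), n))
            labels.append(rng.choice(["A[C>T]G", "T[C>A]T", "C[A>G]C"]))
        typed = self._typed(variants, labels)
        samples = [f"s{i}" for i in range(n)]
        pops = {s: "P" for s in samples}
        edges = default_daf_bins(2 * n)
        out = daf_fractions(typed, samples, pops, edges)["P"]
        for _, row in out.iterrows():
            if row["n_variants"] > 0:
                assert row.drop("n_variants").sum() == pytest.approx(1.0, abs=1e-9)

    def test_count_conservation_across_bins(self):
        n = 20
        variants = [_daf_variant(10 + i * 3, 2 + i, n) for i in range(20)]
        typed = self._typed(variants, ["A[C>T]G"] * 20)
        samples = [f"s{i}" for i in range(n)]
        pops = {s: "P" for s in samples}
        out = daf_fractions(typed, samples, pops, default_daf_bins(2 * n))["P"]
        total = (
            out.drop(columns="n_variants")
            .mul(out["n_variants"], axis=0)
            .to_numpy()
            .sum()
        )
        assert total == pytest.approx(out["n_variants"].sum())

    def test_low_frequency_excess_peaks_in_lowest_bins(self):
        n = 30
        variants, labels = [], []
        rng = np.random.default_rng(9)
        for i in range(80):  # background: broad frequency range, other type
            variants.append(_daf_variant(10 + i * 3, int(rng.integers(2, 2 * n)), n))
            labels.append("T[C>A]T")
        for i in range(40):  # excess type confined to 2-4 copies
            variants.append(
                _daf_variant(400 + i * 3, int(rng.integers(2, 5)), n)
            )
            labels.append("A[C>T]G")
        typed = self._typed(variants, labels)
        samples = [f"s{i}" for i in range(n)]
        pops = {s: "P" for s in samples}
        out = daf_fractions(typed, samples, pops, default_daf_bins(2 * n))["P"]
        frac = out["A[C>T]G"].to_numpy()
        assert frac.argmax() < len(frac) // 2

    def test_unsorted_bin_edges_rejected(self):
        with pytest.raises(ValueError):
            daf_fractions([], [], {}, [0.5, 0.1])


class TestEnrichment:
    def test_identical_proportions_give_null_result(self):
        counts = {"x": 30, "y": 70}
        res = enrichment_test(counts, counts, "x")
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_statistic_matches_textbook_formula(self):
        a = {"x": 30, "y": 70}
        b = {"x": 10, "y": 90}
        res = enrichment_test(a, b, "x")
        oracle = brute_chi2([[30, 70], [10, 90]])
        assert res.statistic == pytest.approx(oracle, rel=1e-12)
        assert res.statistic == pytest.approx(12.5)
        assert res.p_value == pytest.approx(stats.chi2.sf(12.5, 1), rel=1e-12)

    def test_symmetric_in_populations(self):
        a = {"x": 13, "y": 55, "z": 8}
        b = {"x": 40, "y": 22, "z": 19}
        assert enrichment_test(a, b, "y").statistic == pytest.approx(
            enrichment_test(b, a, "y").statistic, rel=1e-12
        )

    def test_low_expected_count_flagged_not_suppressed(self):
        res = enrichment_test({"x": 2, "y": 400}, {"x": 3, "y": 398}, "x")
        assert res.low_count
        assert np.isfinite(res.statistic)

    def test_scan_orders_by_p_and_bonferroni_adjusts(self):
        rng = np.random.default_rng(11)
        labels = channel_labels(3)[:10]
        a = pd.Series(rng.integers(50, 100, size=10), index=labels)
        b = a.copy()
        b.iloc[0] = a.iloc[0] * 4  # strong enrichment in one channel
        scan = enrichment_scan(a, b, adjust="bonferroni")
        assert scan.iloc[0]["mutation_type"] == labels[0]
        row = scan.iloc[0]
        assert row["p_adjusted"] == pytest.approx(min(1.0, row["p_value"] * 10))

    def test_null_calibration_quick(self):
        """Type-I error of the test at alpha=0.05 under equal rates."""
        rng = np.random.default_rng(12)
        p = np.ones(20) / 20
        rejections = 0
        reps = 400
        for _ in range(reps):
            a = rng.multinomial(2000, p)
            b = rng.multinomial(2000, p)
            res = enrichment_test(
                dict(zip(range(20), a)), dict(zip(range(20), b)), 0
            )
            rejections += res.p_value < 0.05
        assert 0.02 <= rejections / reps <= 0.08


class TestRank1Signature:
    def test_recovers_exact_rank1_structure(self):
        rng = np.random.default_rng(13)
        sig = rng.dirichlet(np.ones(30))
        expo = rng.gamma(5, 10, size=8)
        mat = pd.DataFrame(
            np.outer(expo, sig),
            index=[f"s{i}" for i in range(8)],
            columns=channel_labels(3)[:30],
        )
        signature, exposures = rank1_signature(mat)
        cos = signature @ sig / np.linalg.norm(signature) / np.linalg.norm(sig)
        assert cos >= 0.999
        assert signature.sum() == pytest.approx(1.0, abs=1e-12)
        assert (signature >= 0).all() and (exposures >= 0).all()

    def test_reconstruction_error_near_spectral_optimum(self):
        rng = np.random.default_rng(14)
        mat = pd.DataFrame(rng.gamma(2, 1, size=(10, 25)))
        signature, exposures = rank1_signature(mat)
        V = mat.to_numpy()
        recon = np.outer(exposures.to_numpy(), signature.to_numpy())
        err = np.linalg.norm(V - recon)
        s = np.linalg.svd(V, compute_uv=False)
        spectral_optimum = np.sqrt((s[1:] ** 2).sum())
        assert err <= spectral_optimum + 1e-6

    def test_all_zero_matrix_is_error(self):
        with pytest.raises(ValueError):
            rank1_signature(pd.DataFrame(np.zeros((3, 4))))


class TestCosineMatch:
    def test_exact_catalogue_entry_matches_at_one(self, toy_catalog):
        sig = toy_catalog["SIG3"].copy()
        res = cosine_match(sig, toy_catalog)
        assert res.matched and res.name == "SIG3"
        assert res.similarity == pytest.approx(1.0)

    def test_orthogonal_vector_is_no_match(self):
        labels = channel_labels(3)
        catalog = pd.DataFrame({"S1": [1.0] + [0.0] * 95}, index=labels)
        sig = pd.Series([0.0, 1.0] + [0.0] * 94, index=labels)
        res = cosine_match(sig, catalog)
        assert not res.matched
        assert res.best_similarity == pytest.approx(0.0)

    @pytest.mark.parametrize("cos,expect_match", [(0.79, False), (0.81, True)])
    def test_cutoff_applied_strictly(self, cos, expect_match):
        labels = channel_labels(3)
        e1 = np.zeros(96)
        e1[0] = 1.0
        e2 = np.zeros(96)
        e2[1] = 1.0
        catalog = pd.DataFrame(
            {"S1": cos * e1 + np.sqrt(1 - cos**2) * e2}, index=labels
        )
        sig = pd.Series(e1, index=labels)
        res = cosine_match(sig, catalog, cutoff=0.8)
        assert res.matched is expect_match
        assert res.best_similarity == pytest.approx(cos, abs=1e-12)

    def test_channel_label_mismatch_is_error(self, toy_catalog):
        sig = pd.Series(
            np.ones(95) / 95, index=toy_catalog.index[:95]
        )
        with pytest.raises(ValueError, match="channel"):
            cosine_match(sig, toy_catalog)

    def test_cosmic_style_pyrimidine_labels_canonicalized(self, tmp_path):
        # write a catalogue with central-pyrimidine labels (COSMIC layout)
        labels = channel_labels(3)
        from mutspectra.analyze import canonicalize_channel
        from mutspectra._seq import revcomp

        def to_pyrimidine(lab):
            # central A channels become their T-central reverse complement
            if lab[1] == "[" and lab[2] == "A":
                kmer = lab[0] + lab[2] + lab[6]
                der = lab[4]
                rk, rd = revcomp(kmer), revcomp(der)
                return f"{rk[0]}[{rk[1]}>{rd}]{rk[2]}"
            return lab

        pyr = [to_pyrimidine(lab) for lab in labels]
        rng = np.random.default_rng(15)
        df = pd.DataFrame({"Type": pyr, "SBSX": rng.dirichlet(np.ones(96))})
        path = tmp_path / "catalog.tsv"
        df.to_csv(path, sep="\t", index=False)
        catalog = read_signature_catalog(str(path))
        assert set(catalog.index) == set(labels)
        sig = catalog["SBSX"].copy()
        res = cosine_match(sig, catalog)
        assert res.matched and res.similarity == pytest.approx(1.0)

    def test_canonicalize_roundtrip(self):
        assert canonicalize_channel("A[T>C]A") == "T[A>G]T"
        assert canonicalize_channel("A[C>T]G") == "A[C>T]G"
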