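import math

import numpy as np
import pandas as pd
import pytest

from glycomicrobe import glycotraits as gt
from glycomicrobe.compositional import centered_pca, impute_min_fraction

LN2 = math.log(2.0)


class TestImputation:
    def test_zero_replaced_by_min_positive_fraction(self):
        rel = pd.DataFrame({"t1": [0.2, 0.0, 0.1], "t2": [0.8, 1.0, 0.9]},
                           index=list("abc"))
        out = impute_min_fraction(rel)
        # pre-renormalization value is min(0.2, 0.1) = 0.1 -> row (0.1, 1.0)
        np.testing.assert_allclose(out.loc["b"], [0.1 / 1.1, 1.0 / 1.1])

    def test_no_zeros_identity_up_to_closure(self, rng):
        rel = pd.DataFrame(rng.dirichlet(np.ones(4), size=5))
        np.testing.assert_allclose(impute_min_fraction(rel), rel, atol=1e-12)

    def test_all_zero_part_rejected(self):
        rel = pd.DataFrame({"t1": [0.0, 0.0], "t2": [1.0, 1.0]})
        with pytest.raises(ValueError, match="t1"):
            impute_min_fraction(rel)


class TestHarmonize:
    def test_identity_map(self, toy_peaks):
        hmap = gt.HarmonizationMap({c: c.upper() for c in toy_peaks.columns})
        out = gt.harmonize(toy_peaks, hmap)
        np.testing.assert_allclose(out.to_numpy(), toy_peaks.to_numpy())

    def test_merging_toy_hand_computed(self, toy_peaks):
        hmap = gt.HarmonizationMap({"a": "X", "b": "X", "c": "Y", "d": "Z"})
        out = gt.harmonize(toy_peaks, hmap)
        np.testing.assert_allclose(out.loc["s1"], [0.3, 0.3, 0.4])
        np.testing.assert_allclose(out.loc["s2"], [0.5, 0.25, 0.25])

    def test_shipped_map_conserves_row_sums(self, rng):
        hmap = gt.default_harmonization_map()
        raw = pd.DataFrame(rng.dirichlet(np.ones(39), size=8),
                           columns=hmap.original_peaks)
        out = gt.harmonize(raw, hmap)
        assert out.shape[1] == 36
        np.testing.assert_allclose(out.sum(axis=1), raw.sum(axis=1), atol=1e-12)

    def test_unmapped_peak_rejected(self, toy_peaks):
        hmap = gt.HarmonizationMap({"a": "X", "b": "X", "c": "Y"})
        with pytest.raises(ValueError, match="unmapped"):
            gt.harmonize(toy_peaks, hmap)


class TestNormalize:
    def test_simple_row(self):
        out = gt.total_area_normalize(pd.DataFrame([[2.0, 2.0, 4.0]]))
        np.testing.assert_allclose(out.to_numpy(), [[0.25, 0.25, 0.5]])

    def test_idempotent(self, toy_peaks):
        once = gt.total_area_normalize(toy_peaks)
        np.testing.assert_allclose(gt.total_area_normalize(once), once,
                                   atol=1e-12)

    def test_zero_row_sum_names_sample(self):
        bad = pd.DataFrame([[0.0, 0.0]], index=["s9"])
        with pytest.raises(ValueError, match="s9"):
            gt.total_area_normalize(bad)


class TestDeriveTrait:
    def test_ratio_ilr_symmetric_is_zero(self):
        tdef = gt.DerivedTraitDef("t", "RATIO_ILR", frozenset({"a"}),
                                  denominator=frozenset({"b"}))
        peaks = pd.DataFrame({"a": [0.3, 0.1], "b": [0.3, 0.1],
                              "c": [0.4, 0.8]})
        np.testing.assert_allclose(gt.derive_trait(peaks, tdef), 0.0, atol=1e-12)

    def test_ratio_ilr_closed_form(self):
        tdef = gt.DerivedTraitDef("t", "RATIO_ILR", frozenset({"a"}),
                                  denominator=frozenset({"b"}))
        peaks = pd.DataFrame({"a": [0.5], "b": [0.25], "c": [0.25]})
        assert gt.derive_trait(peaks, tdef)[0] == pytest.approx(
            LN2 / math.sqrt(2.0), rel=1e-12)

    def test_merge_clr_uniform_closed_form(self):
        # uniform 4-part, numerator of 2 -> merged (0.5, 0.25, 0.25):
        # ln 0.5 - (ln 0.5 + 2 ln 0.25)/3 = (2/3) ln 2
        tdef = gt.DerivedTraitDef("t", "MERGE_CLR", frozenset({"a", "b"}))
        peaks = pd.DataFrame({c: [0.25] for c in "abcd"})
        assert gt.derive_trait(peaks, tdef)[0] == pytest.approx(2 * LN2 / 3,
                                                               rel=1e-12)

    def test_subcomp_clr_scale_invariant(self, rng):
        tdef = gt.DerivedTraitDef("t", "SUBCOMP_CLR", frozenset({"a"}),
                                  repertoire=frozenset({"a", "b", "c"}))
        peaks = pd.DataFrame(rng.dirichlet(np.ones(4), size=6),
                             columns=list("abcd"))
        base = gt.derive_trait(peaks, tdef)
        scaled = peaks.copy()
        scaled[["a", "b", "c"]] *= 7.0  # common factor on the repertoire
        np.testing.assert_allclose(gt.derive_trait(scaled, tdef), base,
                                   atol=1e-12)

    def test_degenerate_definitions_rejected(self):
        with pytest.raises(ValueError, match="empty numerator"):
            gt.DerivedTraitDef("t", "MERGE_CLR", frozenset())
        with pytest.raises(ValueError, match="overlap"):
            gt.DerivedTraitDef("t", "RATIO_ILR", frozenset({"a"}),
                               denominator=frozenset({"a", "b"}))
        tdef = gt.DerivedTraitDef("t", "MERGE_CLR", frozenset({"a", "b"}))
        with pytest.raises(ValueError, match="whole composition"):
            gt.derive_trait(pd.DataFrame({"a": [0.5], "b": [0.5]}), tdef)


class TestRegistryAndTraitMatrix:
    def test_shipped_registry_valid(self):
        reg = gt.default_registry()
        assert len(reg) == 81
        names = [t.name for t in reg]
        assert len(set(names)) == 81

    def test_trait_matrix_shape_and_scale_invariance(self, rng):
        hmap = gt.default_harmonization_map()
        raw = pd.DataFrame(rng.dirichlet(np.ones(39) * 5, size=6) * 100,
                           columns=hmap.original_peaks)
        tm = gt.build_trait_matrix(raw)
        assert tm.shape == (6, 117)
        scaled = raw * 3.5  # per-sample total area is arbitrary
        np.testing.assert_allclose(gt.build_trait_matrix(scaled), tm, atol=1e-9)

    def test_original_clr_rows_sum_to_zero(self, rng):
        gp = pd.DataFrame(rng.dirichlet(np.ones(36), size=5))
        out = gt.original_trait_clr(gp)
        np.testing.assert_allclose(out.sum(axis=1), 0.0, atol=1e-12)
        uniform = pd.DataFrame([np.full(36, 1 / 36)])
        np.testing.assert_allclose(gt.original_trait_clr(uniform), 0.0,
                                   atol=1e-12)


class TestPca:
    def test_rank_one_variance_fraction(self):
        v = np.arange(6, dtype=float)
        mat = pd.DataFrame(np.outer(v, [1.0, -2.0, 0.5]))
        scores, _, frac = gt.glycan_pca(mat, k=1)
        assert frac[0] == pytest.approx(1.0, abs=1e-9)

    def test_variance_fractions_sum_to_one(self, rng):
        mat = pd.DataFrame(rng.standard_normal((12, 4)))
        _, _, frac = gt.glycan_pca(mat, k=4)
        assert frac.sum() == pytest.approx(1.0, abs=1e-9)

    def test_scores_match_covariance_eigendecomposition(self, rng):
        mat = pd.DataFrame(rng.standard_normal((5, 4)))
        scores, loadings, frac = gt.glycan_pca(mat, k=3)
        Xc = mat.to_numpy() - mat.to_numpy().mean(axis=0)
        lam, vec = np.linalg.eigh(np.cov(Xc, rowvar=False))
        lam, vec = lam[::-1], vec[:, ::-1]
        for i in range(3):
            v = vec[:, i]
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            np.testing.assert_allclose(scores.iloc[:, i], Xc @ v, atol=1e-9)
            np.testing.assert_allclose(frac[i], lam[i] / lam.sum(), atol=1e-9)

    def test_k_beyond_rank_rejected(self):
        mat = pd.DataFrame(np.outer(np.arange(4.0), [1.0, 2.0, 3.0]))
        with pytest.raises(ValueError, match="rank"):
            centered_pca(mat, k=3)
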