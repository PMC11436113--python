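"""Correlation, KMO/Bartlett diagnostics and correlation-matrix PCA."""

import numpy as np
import pandas as pd
import pytest

from soilpte import multivariate as mva
from soilpte.synthetic import SourceScenario, generate_survey


def frame(arr, cols=None):
    cols = cols or [f"v{i}" for i in range(arr.shape[1])]
    return pd.DataFrame(arr, columns=cols)


class TestPearson:
    def test_self_correlation_unit_diagonal(self, survey304):
        table, _ = survey304
        R, p = mva.pearson_matrix(table)
        np.testing.assert_allclose(np.diag(R), 1.0)
        np.testing.assert_allclose(R, R.T)
        np.testing.assert_allclose(np.diag(p), 0.0)

    def test_proportional_columns(self):
        x = np.arange(1.0, 21.0)
        R, p = mva.pearson_matrix(frame(np.column_stack([x, 3 * x])))
        assert R.iloc[0, 1] == pytest.approx(1.0)
        assert p.iloc[0, 1] < 1e-12

    def test_zero_variance_column_rejected(self):
        arr = np.column_stack([np.arange(5.0), np.ones(5)])
        with pytest.raises(ValueError, match="v1"):
            mva.pearson_matrix(frame(arr))

    def test_null_distribution(self):
        # independent columns: correlations small, p-values roughly uniform
        rng = np.random.default_rng(0)
        X = rng.standard_normal((1000, 6))
        R, p = mva.pearson_matrix(frame(X))
        off = ~np.eye(6, dtype=bool)
        assert np.abs(R.to_numpy()[off]).max() < 0.12
        pv = p.to_numpy()[np.triu_indices(6, 1)]
        assert 0.2 < np.mean(pv < 0.5) < 0.8


class TestBartlett:
    def test_identity_gives_zero_chi2(self):
        chi2, df, p = mva.bartlett_sphericity(np.eye(5), n=100)
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert df == 10
        assert p == pytest.approx(1.0)

    def test_bivariate_closed_form(self):
        R = np.array([[1.0, 0.5], [0.5, 1.0]])
        chi2, df, _ = mva.bartlett_sphericity(R, n=100)
        assert df == 1
        assert chi2 == pytest.approx(-(99 - 9 / 6) * np.log(0.75))

    def test_chi2_increases_with_correlation(self):
        vals = [mva.bartlett_sphericity(
            np.array([[1.0, r], [r, 1.0]]), n=50)[0] for r in (0.1, 0.4, 0.7)]
        assert vals == sorted(vals)

    def test_singular_matrix_rejected(self):
        R = np.ones((3, 3))
        with pytest.raises(np.linalg.LinAlgError):
            mva.bartlett_sphericity(R, n=10)


class TestKMO:
    @pytest.mark.parametrize("r", [0.2, 0.5, -0.7])
    def test_bivariate_is_half(self, r):
        # partial correlation equals simple correlation for two variables
        overall, msa = mva.kmo(np.array([[1.0, r], [r, 1.0]]))
        assert overall == pytest.approx(0.5)
        np.testing.assert_allclose(msa, 0.5)

    def test_block_structure_symmetry(self):
        R = np.eye(4)
        R[0, 1] = R[1, 0] = 0.9
        R[2, 3] = R[3, 2] = 0.9
        _, msa = mva.kmo(R)
        assert msa[0] == pytest.approx(msa[1])
        assert msa[2] == pytest.approx(msa[3])

    def test_identity_degenerate_case(self):
        with pytest.warns(UserWarning, match="identity"):
            overall, msa = mva.kmo(np.eye(6))
        assert overall == 0.0

    def test_reorder_invariant(self, survey304):
        table, _ = survey304
        R, _ = mva.pearson_matrix(table)
        k1, _ = mva.kmo(R)
        perm = np.random.default_rng(0).permutation(8)
        k2, _ = mva.kmo(R.to_numpy()[np.ix_(perm, perm)])
        assert k1 == pytest.approx(k2)


class TestPCA:
    def test_independent_columns_flat_spectrum(self):
        rng = np.random.default_rng(1)
        res = mva.pca(frame(rng.standard_normal((5000, 5))))
        np.testing.assert_allclose(res.eigenvalues, 1.0, atol=0.1)

    def test_bivariate_closed_form(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(20000)
        y = 0.6 * x + 0.8 * rng.standard_normal(20000)
        res = mva.pca(frame(np.column_stack([x, y])))
        r = np.corrcoef(x, y)[0, 1]
        np.testing.assert_allclose(res.eigenvalues, [1 + r, 1 - r], atol=1e-9)

    def test_trace_conservation(self, survey304):
        table, _ = survey304
        res = mva.pca(table)
        assert res.eigenvalues.sum() == pytest.approx(8.0, abs=1e-8)
        assert res.variance_pct.sum() == pytest.approx(100.0)
        assert res.cumulative_pct[-1] == pytest.approx(100.0)

    def test_loadings_reconstruct_correlation(self, survey304):
        table, _ = survey304
        res = mva.pca(table)
        R, _ = mva.pearson_matrix(table)
        L = res.loadings.to_numpy()
        np.testing.assert_allclose(L @ L.T, R.to_numpy(), atol=1e-6)

    def test_component_column_norm_is_eigenvalue(self, survey304):
        table, _ = survey304
        res = mva.pca(table)
        np.testing.assert_allclose((res.loadings**2).sum(axis=0),
                                   res.eigenvalues, atol=1e-10)

    def test_sign_convention(self, survey304):
        table, _ = survey304
        L = mva.pca(table).loadings.to_numpy()
        for k in range(L.shape[1]):
            assert L[np.argmax(np.abs(L[:, k])), k] > 0

    def test_n_must_exceed_p(self):
        with pytest.raises(ValueError):
            mva.pca(frame(np.random.default_rng(0).standard_normal((4, 5))))

    def test_co_generated_elements_load_together(self):
        # recovery oracle: four sources with disjoint element blocks; the
        # max-|loading| grouping must reproduce the generator blocks
        blocks = [("As", "Cd"), ("Cr", "Cu"), ("Hg", "Ni"), ("Pb", "Zn")]
        elements = [e for b in blocks for e in b]
        profiles = pd.DataFrame(0.0, index=[f"s{k}" for k in range(4)],
                                columns=elements)
        for k, block in enumerate(blocks):
            for el in block:
                profiles.loc[f"s{k}", el] = 10.0
        # distinct noise per block gives distinct within-block correlations,
        # breaking the eigenvalue degeneracy of four equal pairs
        block_ef = {"As": 0.02, "Cd": 0.02, "Cr": 0.15, "Cu": 0.15,
                    "Hg": 0.30, "Ni": 0.30, "Pb": 0.50, "Zn": 0.50}
        sc = SourceScenario(
            profiles=profiles,
            contribution_mean=(1.0,) * 4,
            contribution_cv=(0.5,) * 4,
            error_fraction=block_ef,
            mdl={e: 1e-3 for e in elements},
        )
        table, _ = generate_survey(sc, 2000, seed=21)
        res = mva.pca(table)
        top = res.loadings.abs().idxmax(axis=1)
        for block in blocks:
            assert len({top[el] for el in block}) == 1, (block, dict(top))
        assert top.nunique() == 4


class TestVarimax:
    def test_rotation_preserves_communalities(self, survey304):
        table, _ = survey304
        plain = mva.pca(table)
        rotated = mva.pca(table, rotate=True)
        k = plain.retained
        # orthogonal rotation preserves each variable's explained variance
        np.testing.assert_allclose(
            (plain.loadings.iloc[:, :k] ** 2).sum(axis=1),
            (rotated.loadings.iloc[:, :k] ** 2).sum(axis=1), atol=1e-8)

    def test_rotation_increases_loading_variance(self, survey304):
        table, _ = survey304
        plain = mva.pca(table)
        rotated = mva.pca(table, rotate=True)
        k = plain.retained

        def simplicity(L):
            L2 = L**2
            return (L2**2).sum() - (L2.sum(axis=0) ** 2).sum() / L.shape[0]

        assert simplicity(rotated.loadings.to_numpy()[:, :k]) >= \
            simplicity(plain.loadings.to_numpy()[:, :k]) - 1e-10
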