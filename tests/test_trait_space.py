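"""Standardization and PCA fitting: arithmetic oracles, brute-force
eigendecomposition equivalence, closed forms, and the space invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from traitspace import fit_space, standardize, trait_component_correlations
from traitspace.trait_space import _fix_signs

from conftest import random_trait_table


def exact_correlated_z(n: int, r: float, seed: int) -> np.ndarray:
    """Two mean-0, SD-1 (n-1 divisor) columns with sample correlation exactly r."""
    rng = np.random.default_rng(seed)
    u = rng.standard_normal(n)
    v = rng.standard_normal(n)
    z1 = (u - u.mean()) / u.std(ddof=1)
    w = v - v.mean()
    w -= (z1 @ w) / (z1 @ z1) * z1
    w /= w.std(ddof=1)
    return np.column_stack([z1, r * z1 + np.sqrt(1 - r * r) * w])


def z_table(z: np.ndarray, traits=("H", "LMA")) -> pd.DataFrame:
    table = pd.DataFrame(10.0**z, columns=list(traits))
    table.insert(0, "entity_id", [f"e{i}" for i in range(len(z))])
    return table


class TestStandardize:
    def test_hand_computed_toy_oracle(self):
        """3x2 table with power-of-ten values: z-scores known by hand."""
        table = pd.DataFrame(
            {"entity_id": ["a", "b", "c"], "H": [10.0, 100.0, 1000.0], "LMA": [10.0, 1000.0, 100.0]}
        )
        z, stats = standardize(table, ["H", "LMA"])
        expected = np.array([[-1.0, -1.0], [0.0, 1.0], [1.0, 0.0]])
        np.testing.assert_allclose(z.to_numpy(), expected, atol=1e-12)
        np.testing.assert_allclose(stats.mean, [2.0, 2.0], atol=1e-12)
        np.testing.assert_allclose(stats.sd, [1.0, 1.0], atol=1e-12)
        assert stats.n_used == 3

    def test_zero_variance_trait_errors(self):
        table = pd.DataFrame(
            {"entity_id": list("abcd"), "H": [5.0] * 4, "LMA": [1.0, 2.0, 3.0, 4.0]}
        )
        with pytest.raises(ValueError, match="zero variance"):
            standardize(table, ["H", "LMA"])

    def test_reference_geometric_means_standardize_to_zero(self, small_table):
        z, stats = standardize(small_table, ["H", "LMA", "SM"])
        gm = pd.DataFrame(
            {"entity_id": ["gm"], **{t: [10.0 ** stats.mean[i]] for i, t in enumerate(stats.traits)}}
        )
        z_gm, _ = standardize(gm, stats.traits, stats=stats)
        np.testing.assert_allclose(z_gm.to_numpy(), 0.0, atol=1e-12)

    def test_log_base_invariance(self, small_table):
        """z-scoring absorbs the log base: natural-log z equals log10 z."""
        traits = ["H", "LA", "Nmass"]
        z, _ = standardize(small_table, traits)
        ln = np.log(small_table[traits].to_numpy(dtype=float))
        z_ln = (ln - ln.mean(axis=0)) / ln.std(axis=0, ddof=1)
        np.testing.assert_allclose(z.to_numpy(), z_ln, atol=1e-12)

    def test_incomplete_rows_dropped(self):
        table = pd.DataFrame(
            {"entity_id": list("abcd"), "H": [1.0, np.nan, 3.0, 9.0], "LMA": [10.0, 20.0, 30.0, 40.0]}
        )
        z, stats = standardize(table, ["H", "LMA"])
        assert len(z) == 3 and stats.n_used == 3
        assert list(z.index) == [0, 2, 3]

    def test_too_few_complete_rows_errors(self):
        table = pd.DataFrame(
            {"entity_id": list("abc"), "H": [1.0, np.nan, 3.0], "LMA": [10.0, 20.0, 30.0]}
        )
        with pytest.raises(ValueError, match="at least 3"):
            standardize(table, ["H", "LMA"])


class TestFitSpace:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_eigendecomposition(self, seed):
        """Loadings, eigenvalues and scores agree with a direct
        eigendecomposition of the standardized covariance matrix."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 200))
        p = int(rng.integers(2, 7))
        table = random_trait_table(rng, n, p)
        space = fit_space(table)

        z, _ = standardize(table, space.traits)
        cov = np.cov(z.to_numpy(), rowvar=False, ddof=1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], _fix_signs(evecs[:, order])

        np.testing.assert_allclose(space.eigenvalues, evals, atol=1e-8)
        np.testing.assert_allclose(space.loadings, evecs, atol=1e-8)
        np.testing.assert_allclose(space.scores, z.to_numpy() @ evecs, atol=1e-8)

    def test_two_identical_standardized_columns(self):
        """Perfectly correlated traits: eigenvalues [2, 0]."""
        rng = np.random.default_rng(3)
        h = 10.0 ** rng.normal(0, 0.5, 40)
        table = pd.DataFrame(
            {"entity_id": [f"e{i}" for i in range(40)], "H": h, "LA": h**2}
        )
        space = fit_space(table)
        np.testing.assert_allclose(space.eigenvalues, [2.0, 0.0], atol=1e-10)

    @pytest.mark.parametrize("r", [0.5, -0.3, 0.9])
    def test_two_trait_closed_form_eigenvalues(self, r):
        """For p = 2 standardized traits the eigenvalues are 1 +/- |r|."""
        space = fit_space(z_table(exact_correlated_z(60, r, seed=11)))
        np.testing.assert_allclose(
            np.sort(space.eigenvalues), np.sort([1 + abs(r), 1 - abs(r)]), atol=1e-10
        )

    def test_space_invariants(self, default_space):
        p = default_space.n_components
        gram = default_space.loadings.T @ default_space.loadings
        np.testing.assert_allclose(gram, np.eye(p), atol=1e-8)
        assert default_space.eigenvalues.sum() == pytest.approx(p, abs=1e-8)
        assert np.all(np.diff(default_space.eigenvalues) <= 1e-12)
        np.testing.assert_allclose(default_space.scores.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(
            default_space.scores.var(axis=0, ddof=1), default_space.eigenvalues, atol=1e-8
        )
        assert default_space.explained.sum() == pytest.approx(1.0, abs=1e-10)

    def test_sign_convention(self, default_space):
        """Each component's largest-|loading| trait loads positively."""
        for k in range(default_space.n_components):
            col = default_space.loadings[:, k]
            assert col[np.argmax(np.abs(col))] > 0

    def test_growth_form_and_trait_subsetting(self, default_table):
        """A four-trait, herbs-only request fits a 4-component space on herb
        rows only."""
        space = fit_space(default_table, traits=["H", "LA", "LMA", "SM"], growth_forms=["herb"])
        assert space.traits == ("H", "LA", "LMA", "SM")
        assert space.n_components == 4
        n_herbs = int((default_table["growth_form"] == "herb").sum())
        assert space.stats.n_used == n_herbs
        assert set(space.entity_growth_forms) == {"herb"}

    def test_single_trait_rejected(self, small_table):
        with pytest.raises(ValueError, match="two traits"):
            fit_space(small_table, traits=["H"])

    def test_warns_when_rows_not_exceed_traits(self):
        rng = np.random.default_rng(8)
        table = random_trait_table(rng, 4, 5)
        with pytest.warns(UserWarning, match="unstable"):
            fit_space(table)

    def test_archive_roundtrip(self, tmp_path, small_space):
        path = tmp_path / "space.json"
        small_space.save(path)
        from traitspace import TraitSpace

        loaded = TraitSpace.load(path)
        assert loaded.traits == small_space.traits
        np.testing.assert_allclose(loaded.loadings, small_space.loadings)
        np.testing.assert_allclose(loaded.scores, small_space.scores)
        np.testing.assert_allclose(loaded.stats.mean, small_space.stats.mean)
        assert loaded.stats.n_used == small_space.stats.n_used
        assert loaded.entity_ids == small_space.entity_ids

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(10, 80), p=st.integers(2, 6))
    def test_spectrum_conservation_property(self, seed, n, p):
        """For any table: eigenvalue sum = p, explained sums to 1, loadings
        orthonormal."""
        table = random_trait_table(np.random.default_rng(seed), n, p)
        space = fit_space(table)
        assert space.eigenvalues.sum() == pytest.approx(p, abs=1e-8)
        assert space.explained.sum() == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(
            space.loadings.T @ space.loadings, np.eye(p), atol=1e-8
        )


class TestTraitComponentCorrelations:
    def test_closed_form_at_half_correlation(self):
        """r = 0.5: each trait's |correlation| with PC1 is sqrt(1.5/2)."""
        space = fit_space(z_table(exact_correlated_z(50, 0.5, seed=21)))
        corr = trait_component_correlations(space)
        np.testing.assert_allclose(
            np.abs(corr["PC1"].to_numpy()), np.sqrt(1.5 / 2.0), atol=1e-10
        )

    def test_matches_empirical_correlation(self, small_table):
        """Entries equal the empirical correlation between each standardized
        trait column and each score column."""
        space = fit_space(small_table)
        z, _ = standardize(small_table, space.traits)
        corr = trait_component_correlations(space)
        for i, t in enumerate(space.traits):
            for k in range(space.n_components):
                emp = np.corrcoef(z.to_numpy()[:, i], space.scores[:, k])[0, 1]
                assert corr.iloc[i, k] == pytest.approx(emp, abs=1e-6)

    def test_bounded_and_unit_communality(self, default_space):
        corr = trait_component_correlations(default_space).to_numpy()
        assert np.all(np.abs(corr) <= 1.0 + 1e-12)
        np.testing.assert_allclose((corr**2).sum(axis=1), 1.0, atol=1e-8)
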