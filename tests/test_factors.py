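"""Standardization, sampling adequacy, VARIMAX and the iterative reduction."""

import numpy as np
import pandas as pd
import pytest

from fallrisk.factors import (
    FactorSolution,
    ZTable,
    complex_structure,
    component_scores,
    extract_rotate,
    iterative_reduce,
    msa_kmo,
    standardize,
    varimax,
    varimax_criterion,
)


def _ztable(x: np.ndarray, cols=None) -> ZTable:
    cols = cols or [f"GA:Mn-Str-T-L"] and [f"v{i}" for i in range(x.shape[1])]
    df = pd.DataFrame(x, columns=cols)
    return ZTable(values=df, mask=df.isna())


def _sample_from_corr(r: np.ndarray, n: int, rng) -> np.ndarray:
    chol = np.linalg.cholesky(r)
    return rng.standard_normal((n, r.shape[0])) @ chol.T


class TestStandardize:
    def test_simple_column(self):
        table = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        z = standardize(table)
        np.testing.assert_allclose(z.values["a"], [-1.0, 0.0, 1.0])

    def test_missing_imputed_to_zero_after_scoring(self):
        table = pd.DataFrame({"a": [1.0, np.nan, 3.0]})
        z = standardize(table)
        # observed mean 2, sample SD sqrt(2)
        np.testing.assert_allclose(
            z.values["a"], [-1 / np.sqrt(2), 0.0, 1 / np.sqrt(2)]
        )
        assert z.mask["a"].tolist() == [False, True, False]

    def test_constant_column_rejected_by_name(self):
        table = pd.DataFrame({"a": [1.0, 2.0], "bad": [5.0, 5.0]})
        with pytest.raises(ValueError, match="bad"):
            standardize(table)


class TestMsaKmo:
    def test_equicorrelated_closed_form(self, rng):
        # 3 variables, rho = 0.5: each partial correlation is 1/3;
        # KMO = (6*0.25)/(6*0.25 + 6/9)
        r = np.full((3, 3), 0.5)
        np.fill_diagonal(r, 1.0)
        msa, kmo = msa_kmo(r)
        expected = (6 * 0.25) / (6 * 0.25 + 6 * (1 / 9))
        assert kmo == pytest.approx(expected, abs=1e-12)
        np.testing.assert_allclose(msa, expected, atol=1e-12)

    def test_matches_brute_force_anti_image_oracle(self, rng):
        # oracle: partial correlation of (i, j) from the residuals of
        # regressing each on all remaining variables
        for _ in range(5):
            p = 6
            a = rng.standard_normal((p, p))
            r = a @ a.T
            d = np.sqrt(np.diag(r))
            r = r / np.outer(d, d)
            msa, kmo = msa_kmo(r)
            x = _sample_from_corr(r, 200000, rng)
            # direct partial-correlation oracle via matrix regression
            q = np.zeros((p, p))
            for i in range(p):
                for j in range(i + 1, p):
                    rest = [k for k in range(p) if k not in (i, j)]
                    bi = np.linalg.lstsq(x[:, rest], x[:, i], rcond=None)[0]
                    bj = np.linalg.lstsq(x[:, rest], x[:, j], rcond=None)[0]
                    resid_i = x[:, i] - x[:, rest] @ bi
                    resid_j = x[:, j] - x[:, rest] @ bj
                    q[i, j] = q[j, i] = np.corrcoef(resid_i, resid_j)[0, 1]
            r_emp = np.corrcoef(x, rowvar=False)
            r2 = (r_emp - np.eye(p)) ** 2
            q2 = q**2
            kmo_oracle = r2.sum() / (r2.sum() + q2.sum())
            msa_emp, kmo_emp = msa_kmo(r_emp)
            assert kmo_emp == pytest.approx(kmo_oracle, abs=1e-3)

    def test_exact_anti_image_identity_small_matrix(self):
        # exact check at machine precision: partials from the inverse equal
        # the population partial correlations for a 3-variable system
        r = np.array([[1.0, 0.6, 0.3], [0.6, 1.0, 0.2], [0.3, 0.2, 1.0]])
        msa, kmo = msa_kmo(r)
        # population partial correlation formula for 3 variables
        def partial(ij, k, r):
            i, j = ij
            return (r[i, j] - r[i, k] * r[j, k]) / np.sqrt(
                (1 - r[i, k] ** 2) * (1 - r[j, k] ** 2)
            )
        q01 = partial((0, 1), 2, r)
        q02 = partial((0, 2), 1, r)
        q12 = partial((1, 2), 0, r)
        num = r[0, 1] ** 2 + r[0, 2] ** 2 + r[1, 2] ** 2
        den = num + q01**2 + q02**2 + q12**2
        assert kmo == pytest.approx(num / den, abs=1e-12)

    def test_independent_noise_gives_low_kmo(self, rng):
        x = rng.standard_normal((400, 8))
        z = standardize(pd.DataFrame(x, columns=[f"v{i}" for i in range(8)]))
        _, kmo = msa_kmo(z)
        assert kmo < 0.55  # no common variance: "unacceptable" adequacy


class TestVarimax:
    def _two_block_corr(self):
        r = np.eye(6)
        for i in range(3):
            for j in range(3):
                if i != j:
                    r[i, j] = r[i + 3, j + 3] = 0.8
        return r

    def test_two_block_structure_recovered(self, rng):
        x = _sample_from_corr(self._two_block_corr(), 5000, rng)
        z = standardize(pd.DataFrame(x, columns=[f"v{i}" for i in range(6)]))
        sol = extract_rotate(z)
        assert sol.n_components == 2
        load = sol.loadings.abs()
        for i in range(3):
            assert load.iloc[i, 0] > 0.4 or load.iloc[i, 1] > 0.4
        # each measure loads on exactly its own block
        own = load.to_numpy().argmax(axis=1)
        assert len(set(own[:3])) == 1 and len(set(own[3:])) == 1
        assert own[0] != own[3]

    def test_simple_structure_is_a_fixed_point(self, rng):
        lam = np.array(
            [[0.9, 0.0], [0.85, 0.0], [0.8, 0.0], [0.0, 0.9], [0.0, 0.85], [0.0, 0.8]]
        )
        rotated, rot = varimax(lam)
        # unchanged up to column sign/permutation
        perm = np.abs(rot).argmax(axis=0)
        recovered = np.abs(rotated[:, np.argsort(perm)]) if False else np.abs(rotated)
        assert np.allclose(np.sort(np.abs(rot).ravel())[::-1][:2], 1.0, atol=1e-6)
        np.testing.assert_allclose(np.sort(recovered.ravel()), np.sort(np.abs(lam).ravel()), atol=1e-6)

    def test_rotation_preserves_communalities(self, rng):
        lam = rng.standard_normal((12, 4)) * 0.4
        rotated, rot = varimax(lam)
        np.testing.assert_allclose(
            (rotated**2).sum(axis=1), (lam**2).sum(axis=1), atol=1e-10
        )
        np.testing.assert_allclose(rot @ rot.T, np.eye(4), atol=1e-10)

    def test_criterion_nondecreasing_under_rotation(self, rng):
        for _ in range(5):
            lam = rng.standard_normal((10, 3)) * 0.5
            rotated, _ = varimax(lam, normalize=False)
            assert varimax_criterion(rotated) >= varimax_criterion(lam) - 1e-12

    def test_matches_statsmodels_rotation_oracle(self, rng):
        from statsmodels.multivariate.factor_rotation import rotate_factors

        lam = rng.standard_normal((15, 3)) * 0.5
        ours, _ = varimax(lam, normalize=False)
        theirs, _ = rotate_factors(lam, "varimax")
        assert varimax_criterion(ours) == pytest.approx(
            varimax_criterion(np.asarray(theirs)), abs=1e-8
        )


class TestComplexStructure:
    def _sol(self, rows):
        lam = pd.DataFrame(rows, columns=["C1", "C2", "C3"][: len(rows[0])])
        lam.index = [f"m{i}" for i in range(len(rows))]
        return FactorSolution(
            measures=list(lam.index),
            eigenvalues=np.ones(lam.shape[1]) * 2,
            loadings=lam,
            communalities=(lam**2).sum(axis=1),
            variance_explained=np.ones(lam.shape[1]),
        )

    def test_threshold_semantics(self):
        sol = self._sol([[0.9, 0.1, 0.0], [0.5, -0.45, 0.0], [0.41, 0.41, 0.02]])
        flagged = complex_structure(sol)
        assert list(flagged.index) == ["m1", "m2"]

    def test_boundary_is_strictly_greater(self):
        sol = self._sol([[0.4, 0.4, 0.4]])
        assert complex_structure(sol).empty


class TestIterativeReduce:
    def test_clean_structure_converges_without_drops(self, rng):
        r = np.eye(6)
        for i in range(3):
            for j in range(3):
                if i != j:
                    r[i, j] = r[i + 3, j + 3] = 0.8
        x = _sample_from_corr(r, 3000, rng)
        z = standardize(pd.DataFrame(x, columns=[f"v{i}" for i in range(6)]))
        sol = iterative_reduce(z)
        assert len(sol.iteration_log) == 1
        assert sol.measures == list(z.measures)
        assert sol.n_components == 2

    def test_pure_noise_measure_removed_via_msa(self):
        # two tight 5-measure blocks plus one independent noise column: the
        # noise column shares no common variance and fails sampling adequacy
        rng = np.random.default_rng(0)
        bs, rho = 5, 0.85
        r = np.eye(2 * bs + 1)
        for i in range(bs):
            for j in range(bs):
                if i != j:
                    r[i, j] = r[i + bs, j + bs] = rho
        x = _sample_from_corr(r, 200, rng)  # last column is independent noise
        z = standardize(pd.DataFrame(x, columns=[f"v{i}" for i in range(11)]))
        sol = iterative_reduce(z)
        assert "v10" not in sol.measures
        dropped_by_msa = [m for e in sol.iteration_log for m in e["dropped_msa"]]
        assert "v10" in dropped_by_msa
        assert set(sol.measures) == {f"v{i}" for i in range(10)}
        assert sol.n_components == 2

    def test_pruning_monotone_and_logged(self, rng):
        r = np.eye(8)
        for i in range(4):
            for j in range(4):
                if i != j:
                    r[i, j] = r[i + 4, j + 4] = 0.75
        # a measure straddling both blocks -> complex structure
        r[0, 4:] = r[4:, 0] = 0.5
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        # nearest PD projection
        w, v = np.linalg.eigh(r)
        r = v @ np.diag(np.clip(w, 1e-3, None)) @ v.T
        d = np.sqrt(np.diag(r))
        r = r / np.outer(d, d)
        x = _sample_from_corr(r, 2000, rng)
        z = standardize(pd.DataFrame(x, columns=[f"v{i}" for i in range(8)]))
        sol = iterative_reduce(z)
        sizes = [e["n_measures"] for e in sol.iteration_log]
        assert sizes == sorted(sizes, reverse=True)

    def test_conservation_of_variance(self, rng):
        r = np.eye(6)
        for i in range(3):
            for j in range(3):
                if i != j:
                    r[i, j] = r[i + 3, j + 3] = 0.8
        x = _sample_from_corr(r, 3000, rng)
        z = standardize(pd.DataFrame(x, columns=[f"v{i}" for i in range(6)]))
        sol = iterative_reduce(z)
        p = len(sol.measures)
        # sum of retained eigenvalues == sum of variance-explained * p / 100
        assert np.sum(sol.eigenvalues) == pytest.approx(
            np.sum(sol.variance_explained) * p / 100, abs=1e-8
        )
        # communality identity
        np.testing.assert_allclose(
            sol.communalities, (sol.loadings**2).sum(axis=1), atol=1e-12
        )
        assert (sol.communalities <= 1 + 1e-8).all()
        assert (sol.eigenvalues > 1).all()

    def test_no_retainable_components_is_an_error(self):
        # exactly orthogonal columns: both eigenvalues are exactly 1, and the
        # Kaiser rule is strictly greater-than
        x = np.array([[1.0, 1.0], [1.0, -1.0], [-1.0, 1.0], [-1.0, -1.0]])
        z = standardize(pd.DataFrame(x, columns=["a", "b"]))
        with pytest.raises(ValueError, match="retainable"):
            extract_rotate(z)


class TestComponentScores:
    def test_duplicate_measures_give_shared_score(self, rng):
        f = rng.standard_normal(1000)
        x = np.column_stack([f + 0.05 * rng.standard_normal(1000) for _ in range(3)])
        z = standardize(pd.DataFrame(x, columns=["a", "b", "c"]))
        sol = iterative_reduce(z)
        scores = component_scores(sol, z)
        assert sol.n_components == 1
        r = np.corrcoef(scores.iloc[:, 0], f)[0, 1]
        assert abs(r) > 0.99

    def test_score_columns_centred(self, rng):
        f = rng.standard_normal((500, 2))
        lam = np.zeros((6, 2))
        lam[:3, 0] = 0.85
        lam[3:, 1] = 0.85
        x = f @ lam.T + 0.5 * rng.standard_normal((500, 6))
        z = standardize(pd.DataFrame(x, columns=[f"v{i}" for i in range(6)]))
        sol = iterative_reduce(z)
        scores = component_scores(sol, z)
        assert np.abs(scores.mean(axis=0)).max() < 1e-8

    def test_planted_two_factor_recovery(self, rng):
        n = 500
        f = rng.standard_normal((n, 2))
        lam = np.zeros((10, 2))
        lam[:5, 0] = 0.85
        lam[5:, 1] = 0.85
        x = f @ lam.T + 0.4 * rng.standard_normal((n, 10))
        z = standardize(pd.DataFrame(x, columns=[f"v{i}" for i in range(10)]))
        sol = iterative_reduce(z)
        scores = component_scores(sol, z)
        assert sol.n_components == 2
        # each true factor correlates > 0.9 with exactly one recovered score
        c = np.abs(np.corrcoef(np.hstack([f, scores.to_numpy()]).T)[:2, 2:])
        assert c.max(axis=1).min() > 0.9
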