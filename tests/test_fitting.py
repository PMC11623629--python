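"""Spearman fits, joint rank-regression, variance partitioning, noise ceiling."""

import itertools

import numpy as np
import pytest
from scipy import stats

import repgeom as rg
from repgeom.errors import InvalidArgumentError, RankDeficiencyError

from conftest import random_rdm


def rdm_from_vector(vec, n, labels=None):
    """Place a pair vector into a symmetric zero-diagonal matrix."""
    m = np.zeros((n, n))
    m[np.tril_indices(n, k=-1)] = vec
    m = m + m.T
    return rg.RDM(m, labels or tuple(f"c{i}" for i in range(n)))


class TestSpearmanFit:
    def test_self_fit_is_one(self, rng):
        r = random_rdm(rng, 6)
        assert rg.spearman_fit(r, r) == pytest.approx(1.0)

    def test_monotone_transform_invariance(self, rng):
        r = random_rdm(rng, 6)
        increasing = rdm_from_vector(np.exp(r.vector()), 6)
        decreasing = rdm_from_vector(-r.vector() + 100, 6)
        assert rg.spearman_fit(r, increasing) == pytest.approx(1.0)
        assert rg.spearman_fit(r, decreasing) == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self, rng):
        a, b = random_rdm(rng, 8), random_rdm(rng, 8)
        expected = np.corrcoef(
            stats.rankdata(a.vector()), stats.rankdata(b.vector())
        )[0, 1]
        assert rg.spearman_fit(a, b) == pytest.approx(expected, abs=1e-12)


class TestJointFit:
    def test_single_identical_model_r2_one(self, rng):
        r = random_rdm(rng, 6)
        assert rg.joint_fit(r, [r]) == pytest.approx(1.0)

    def test_rank_orthogonal_model_r2_zero(self):
        """Construct a model whose ranked vector is exactly orthogonal (after
        centering) to the ranked neural vector.  Uses 6 conditions (15 pairs):
        for 6 or 10 pairs no rank permutation can be orthogonal (the required
        rank cross-product n(n+1)^2/4 is non-integer)."""
        n_pairs = 15  # 6 conditions
        y_ranks = np.arange(1, n_pairs + 1, dtype=float)
        yc = y_ranks - y_ranks.mean()
        search = np.random.default_rng(0)
        for _ in range(20_000):
            s = search.permutation(y_ranks)
            if abs((s - s.mean()) @ yc) < 1e-9:
                break
        else:  # pragma: no cover
            pytest.fail("no orthogonal rank permutation found")
        neural = rdm_from_vector(y_ranks, 6)
        model = rdm_from_vector(s, 6)
        assert rg.joint_fit(neural, [model]) == pytest.approx(0.0, abs=1e-12)

    def test_single_model_r2_equals_squared_spearman(self, rng):
        neural, model = random_rdm(rng, 7), random_rdm(rng, 7)
        rho = rg.spearman_fit(neural, model)
        assert rg.joint_fit(neural, [model]) == pytest.approx(rho**2, abs=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        neural = random_rdm(rng, 20)
        models = [random_rdm(rng, 20) for _ in range(3)]
        r2 = rg.joint_fit(neural, models)
        yr = stats.rankdata(neural.vector())
        yr = (yr - yr.mean()) / yr.std(ddof=1)
        cols = []
        for m in models:
            xr = stats.rankdata(m.vector())
            cols.append((xr - xr.mean()) / xr.std(ddof=1))
        x = np.column_stack([np.ones(len(yr)), *cols])
        beta = np.linalg.solve(x.T @ x, x.T @ yr)
        resid = yr - x @ beta
        expected = 1 - resid @ resid / ((yr - yr.mean()) @ (yr - yr.mean()))
        assert r2 == pytest.approx(expected, abs=1e-10)

    def test_collinear_models_rejected(self, rng):
        neural = random_rdm(rng, 6)
        m = random_rdm(rng, 6)
        with pytest.raises(RankDeficiencyError):
            rg.joint_fit(neural, [m, m])

    def test_adding_models_never_decreases_r2(self, rng):
        neural = random_rdm(rng, 10)
        models = [random_rdm(rng, 10) for _ in range(4)]
        r2s = [rg.joint_fit(neural, models[:k]) for k in range(1, 5)]
        assert all(b >= a - 1e-12 for a, b in zip(r2s, r2s[1:]))


class TestVariancePartition:
    def test_duplicated_model_has_zero_unique_r2(self, rng):
        neural = random_rdm(rng, 8)
        m1, m2 = random_rdm(rng, 8), random_rdm(rng, 8)
        copy = rg.RDM(m1.matrix.copy(), m1.labels)
        table = rg.variance_partition(
            neural, {"a": m1, "a_copy": copy, "b": m2}, [["a"]]
        )
        assert table.unique_r2["a"] == pytest.approx(0.0, abs=1e-10)

    def test_orthogonal_models_decompose_additively(self):
        """Mutually rank-orthogonal predictors: sum of unique R2 = full R2."""
        n_pairs = 15  # 6 conditions
        ranks = np.arange(1.0, n_pairs + 1)
        search = np.random.default_rng(1)
        p1 = p2 = None
        for _ in range(50_000):
            a, b = search.permutation(ranks), search.permutation(ranks)
            if abs((a - a.mean()) @ (b - b.mean())) < 1e-9:
                p1, p2 = a, b
                break
        assert p1 is not None, "no mutually orthogonal rank pair found"
        neural = rdm_from_vector(search.permutation(ranks), 6)
        models = {"m0": rdm_from_vector(p1, 6), "m1": rdm_from_vector(p2, 6)}
        table = rg.variance_partition(neural, models, [["m0"], ["m1"]])
        assert sum(table.unique_r2.values()) == pytest.approx(table.full_r2, abs=1e-10)

    def test_matches_full_nested_regression_oracle(self, rng):
        neural = random_rdm(rng, 12)
        models = {f"m{i}": random_rdm(rng, 12) for i in range(3)}
        table = rg.variance_partition(neural, models, [["m0"], ["m1", "m2"]])
        full = rg.joint_fit(neural, list(models.values()))
        nested_m0 = rg.joint_fit(neural, [models["m1"], models["m2"]])
        nested_m12 = rg.joint_fit(neural, [models["m0"]])
        assert table.full_r2 == pytest.approx(full, abs=1e-12)
        assert table.unique_r2["m0"] == pytest.approx(full - nested_m0, abs=1e-10)
        assert table.unique_r2["m1+m2"] == pytest.approx(full - nested_m12, abs=1e-10)
        assert all(u >= -1e-12 for u in table.unique_r2.values())

    def test_unknown_label_rejected(self, rng):
        neural = random_rdm(rng, 5)
        with pytest.raises(InvalidArgumentError, match="unknown"):
            rg.variance_partition(neural, {"a": random_rdm(rng, 5)}, [["zzz"]])


class TestNoiseCeiling:
    def test_shared_rdm_gives_isc_one(self, rng):
        r = random_rdm(rng, 6)
        res = rg.isc_noise_ceiling([r, r, r])
        np.testing.assert_allclose(res.values, 1.0)
        assert res.group_mean == pytest.approx(1.0)

    def test_two_rank_reversed_subjects(self, rng):
        r = random_rdm(rng, 6)
        flipped = rdm_from_vector(100.0 - r.vector(), 6)
        res = rg.isc_noise_ceiling([r, flipped])
        np.testing.assert_allclose(res.values, -1.0, atol=1e-12)

    def test_matches_leave_one_out_loop_oracle(self, rng):
        rdms = [random_rdm(rng, 7) for _ in range(5)]
        res = rg.isc_noise_ceiling(rdms)
        for i in range(5):
            others = np.mean([r.matrix for j, r in enumerate(rdms) if j != i], axis=0)
            expected = stats.spearmanr(
                rdms[i].vector(), rg.RDM(others, rdms[i].labels).vector()
            ).statistic
            assert res.values[i] == pytest.approx(expected, abs=1e-12)
        z = np.arctanh(res.values)
        assert res.group_mean == pytest.approx(np.tanh(z.mean()))

    def test_needs_two_subjects(self, rng):
        with pytest.raises(InvalidArgumentError):
            rg.isc_noise_ceiling([random_rdm(rng, 5)])


class TestCeilingFraction:
    def test_printed_ingredients(self):
        assert rg.ceiling_fraction(0.22, 0.75) == pytest.approx(39.11, abs=0.01)

    def test_zero_model(self):
        assert rg.ceiling_fraction(0.0, 0.5) == 0.0

    def test_unit_ceiling(self, rng):
        x = float(rng.uniform(0, 1))
        assert rg.ceiling_fraction(x, 1.0) == pytest.approx(100 * x)

    def test_invalid_ceiling_rejected(self):
        with pytest.raises(InvalidArgumentError):
            rg.ceiling_fraction(0.2, 0.0)
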