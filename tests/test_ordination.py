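"""Bray-Curtis, PCoA, and dbRDA behaviour, checked against closed forms,
distance-reconstruction oracles, and scikit-bio's independent PCoA."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix
from skbio.stats.ordination import pcoa as skbio_pcoa

from riversem.ordination import (
    AliasedPredictorsError,
    bray_curtis,
    build_design,
    dbrda,
    pcoa,
    residual_pattern_check,
    sqrt_transform,
)


def euclidean_dm(points: np.ndarray) -> DistanceMatrix:
    ids = [f"s{i}" for i in range(len(points))]
    return DistanceMatrix(squareform(pdist(points)), ids=ids)


class TestTransformAndBrayCurtis:
    def test_sqrt_examples(self):
        df = pd.DataFrame([[4.0, 9.0], [0.0, 2.0]])
        out = sqrt_transform(df)
        assert out.iloc[0].tolist() == [2.0, 3.0]
        assert out.iloc[1, 0] == 0.0
        assert out.iloc[1, 1] == pytest.approx(np.sqrt(2))

    def test_sqrt_rejects_negative(self):
        with pytest.raises(ValueError):
            sqrt_transform(pd.DataFrame([[-1.0]]))

    def test_identical_rows_zero(self):
        d = bray_curtis(pd.DataFrame([[1, 2, 3], [1, 2, 3]]))
        assert d.data[0, 1] == 0.0

    def test_disjoint_rows_one(self):
        d = bray_curtis(pd.DataFrame([[1, 0], [0, 1]]))
        assert d.data[0, 1] == 1.0

    def test_hand_computed_value(self):
        # (|2-1| + |2-3|) / (3 + 5) = 0.25
        d = bray_curtis(pd.DataFrame([[2, 2], [1, 3]]))
        assert d.data[0, 1] == pytest.approx(0.25)

    def test_double_zero_pair_warns_and_is_zero(self):
        with pytest.warns(UserWarning, match="double-zero"):
            d = bray_curtis(pd.DataFrame([[0, 0], [0, 0], [1, 2]]))
        assert d.data[0, 1] == 0.0

    def test_bounded_symmetric(self, rng):
        counts = rng.poisson(3.0, size=(12, 6))
        d = bray_curtis(pd.DataFrame(counts)).data
        assert (d >= 0).all() and (d <= 1).all()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)


class TestPCoA:
    def test_two_points_closed_form(self):
        d = DistanceMatrix([[0, 0.6], [0.6, 0]], ids=["a", "b"])
        res = pcoa(d)
        lam = res.eigenvalues[res.eigenvalues > 1e-12]
        assert lam.size == 1
        assert lam[0] == pytest.approx(0.6**2 / 2)

    def test_collinear_points_rank_one(self):
        pts = np.array([[0.0], [1.0], [3.0]])
        res = pcoa(euclidean_dm(pts))
        lam = np.abs(res.eigenvalues)
        assert (lam[1:] < 1e-10).all()

    def test_distance_reconstruction(self, rng):
        pts = rng.normal(size=(15, 4))
        dm = euclidean_dm(pts)
        res = pcoa(dm)
        rec = squareform(pdist(res.scores.to_numpy()))
        assert np.abs(rec - dm.data).max() < 1e-8

    def test_eigenvalue_sum_equals_gower_trace(self, rng):
        counts = rng.poisson(4.0, size=(10, 8))
        d = bray_curtis(pd.DataFrame(counts))
        res = pcoa(d)
        a = -0.5 * d.data**2
        b = a - a.mean(1, keepdims=True) - a.mean(0, keepdims=True) + a.mean()
        assert res.eigenvalues.sum() == pytest.approx(np.trace(b), abs=1e-8)

    def test_matches_skbio(self, rng):
        counts = rng.poisson(4.0, size=(12, 9))
        d = bray_curtis(pd.DataFrame(counts))
        ours = pcoa(d)
        theirs = skbio_pcoa(d, number_of_dimensions=0)
        k = ours.scores.shape[1]
        assert np.allclose(
            ours.eigenvalues[:k], theirs.eigvals.to_numpy()[:k], atol=1e-8
        )
        # scores agree up to axis sign (ties in eigenvalues absent here)
        ref = theirs.samples.to_numpy()[:, :k]
        for j in range(k):
            col = ours.scores.to_numpy()[:, j]
            assert np.allclose(col, ref[:, j], atol=1e-6) or np.allclose(
                col, -ref[:, j], atol=1e-6
            )

    def test_axis_signs_deterministic(self, rng):
        counts = rng.poisson(4.0, size=(10, 6))
        d = bray_curtis(pd.DataFrame(counts))
        s1 = pcoa(d).scores.to_numpy()
        s2 = pcoa(d).scores.to_numpy()
        assert (s1 == s2).all()
        for j in range(s1.shape[1]):
            assert s1[np.argmax(np.abs(s1[:, j])), j] > 0

    def test_lingoes_removes_negative_eigenvalues(self, rng):
        counts = rng.poisson(2.0, size=(10, 5))
        d = bray_curtis(pd.DataFrame(counts))
        res = pcoa(d, lingoes=True)
        assert res.eigenvalues.min() > -1e-8


@pytest.fixture
def linear_response(rng):
    """Euclidean distances generated exactly as a linear map of predictors."""
    n = 30
    x = pd.DataFrame(
        {"a": rng.normal(size=n), "b": rng.normal(size=n)},
        index=[f"s{i}" for i in range(n)],
    )
    y = x.to_numpy() @ np.array([[1.0, 0.3, -0.5], [0.2, -1.0, 0.4]])
    return euclidean_dm(y), x


class TestDbRDA:
    def test_conditioning_on_predictors_removes_everything(self, linear_response):
        dm, x = linear_response
        res = dbrda(dm, predictors=x, condition=x.copy(), n_permutations=99, seed=1)
        assert res.constrained_inertia == pytest.approx(0.0, abs=1e-16)

    def test_noiseless_linear_model(self, linear_response):
        dm, x = linear_response
        res = dbrda(dm, predictors=x, n_permutations=199, seed=1)
        assert res.residual_inertia < 1e-8 * res.total_inertia
        assert res.permutation_p == pytest.approx(1 / 200)

    def test_inertia_decomposition(self, rng):
        counts = rng.poisson(4.0, size=(20, 8))
        d = bray_curtis(pd.DataFrame(counts, index=[f"s{i}" for i in range(20)]))
        x = pd.DataFrame(
            {"u": rng.normal(size=20)}, index=[f"s{i}" for i in range(20)]
        )
        z = pd.DataFrame(
            {"w": rng.normal(size=20)}, index=[f"s{i}" for i in range(20)]
        )
        res = dbrda(d, predictors=x, condition=z, n_permutations=99, seed=0)
        total = res.conditional_inertia + res.constrained_inertia + res.residual_inertia
        assert total == pytest.approx(res.total_inertia, rel=1e-6)

    def test_p_invariant_to_scaling_and_relabeling(self, rng):
        n = 25
        ids = [f"s{i}" for i in range(n)]
        counts = rng.poisson(4.0, size=(n, 8))
        x = pd.DataFrame({"u": rng.normal(size=n)}, index=ids)
        d = bray_curtis(pd.DataFrame(counts, index=ids))
        p1 = dbrda(d, x, n_permutations=199, seed=7).permutation_p
        p2 = dbrda(d, x * 13.7, n_permutations=199, seed=7).permutation_p
        assert p1 == p2
        relabel = {f"s{i}": f"q{i}" for i in range(n)}
        d2 = DistanceMatrix(d.data, ids=[relabel[i] for i in d.ids])
        x2 = x.rename(index=relabel)
        assert dbrda(d2, x2, n_permutations=199, seed=7).permutation_p == p1

    def test_null_p_roughly_uniform(self, rng):
        # predictor independent of the community: p should not pile up low
        n = 20
        ids = [f"s{i}" for i in range(n)]
        counts = rng.poisson(4.0, size=(n, 8))
        d = bray_curtis(pd.DataFrame(counts, index=ids))
        ps = []
        for rep in range(60):
            x = pd.DataFrame({"u": rng.normal(size=n)}, index=ids)
            ps.append(dbrda(d, x, n_permutations=99, seed=rep).permutation_p)
        from scipy import stats

        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_aliased_predictors_named(self, rng):
        n = 15
        ids = [f"s{i}" for i in range(n)]
        counts = rng.poisson(4.0, size=(n, 6))
        d = bray_curtis(pd.DataFrame(counts, index=ids))
        u = rng.normal(size=n)
        x = pd.DataFrame({"u": u, "v": 2 * u}, index=ids)
        with pytest.raises(AliasedPredictorsError) as exc:
            dbrda(d, x, n_permutations=99, seed=0)
        assert set(exc.value.aliased) <= {"u", "v"}

    def test_too_few_rows(self, rng):
        ids = ["a", "b", "c"]
        d = bray_curtis(pd.DataFrame(rng.poisson(3.0, size=(3, 4)), index=ids))
        x = pd.DataFrame({"u": [1.0, 2.0, 3.0], "v": [0.0, 1.0, 0.0]}, index=ids)
        with pytest.raises(ValueError, match="too few"):
            dbrda(d, x, n_permutations=9, seed=0)


class TestResidualPatternCheck:
    def test_wellspecified_residuals_unpatterned(self, rng):
        n = 40
        ids = [f"s{i}" for i in range(n)]
        dist = np.linspace(0, 10, n)
        t = np.tile(np.arange(4), 10).astype(float)
        y = np.column_stack([dist * 0.5 + rng.normal(0, 1, n), rng.normal(0, 1, n)])
        dm = euclidean_dm(y)
        site = pd.DataFrame({"distance": dist, "time": t}, index=ids)
        x = pd.DataFrame({"distance": dist, "time": t}, index=ids)
        res = dbrda(dm, x, n_permutations=49, seed=0)
        table = residual_pattern_check(res, site)
        assert set(["distance_p", "time_p"]) <= set(table.columns)
        assert (table["distance_p"] > 0.001).all()

    def test_omitted_distance_effect_detected(self, rng):
        n = 60
        ids = [f"s{i}" for i in range(n)]
        dist = np.linspace(0, 10, n)
        t = np.tile(np.arange(6), 10).astype(float)
        y = np.column_stack([3.0 * dist + rng.normal(0, 0.5, n), rng.normal(0, 0.5, n)])
        dm = euclidean_dm(y)
        site = pd.DataFrame({"distance": dist, "time": t}, index=ids)
        x = pd.DataFrame({"time": t}, index=ids)
        res = dbrda(dm, x, n_permutations=49, seed=0)
        table = residual_pattern_check(res, site)
        assert table["distance_p"].min() < 0.05

    def test_constant_residuals_warn(self, linear_response):
        dm, x = linear_response
        res = dbrda(dm, predictors=x, n_permutations=49, seed=0)
        site = pd.DataFrame(
            {"distance": np.arange(30.0), "time": np.arange(30.0)},
            index=x.index,
        )
        with pytest.warns(UserWarning, match="constant"):
            table = residual_pattern_check(res, site)
        assert (table["distance_p"] == 1.0).all()


def test_build_design_interactions():
    t = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]})
    d = build_design(t, ["a", "a:b"])
    assert d["a:b"].tolist() == [3.0, 8.0]
    with pytest.raises(KeyError):
        build_design(t, ["c"])
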