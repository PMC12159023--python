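import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from pikathresh import (
    bartlett_sphericity,
    build_ghi,
    classify_disturbance,
    ghi_score,
    kmo,
    kmo_from_correlation,
    min_max_standardize,
    pca_weights,
)
from pikathresh.ghi import IndicatorMatrix
from pikathresh.errors import InvalidParameterError


class TestMinMax:
    def test_positive_and_reversed(self):
        raw = pd.DataFrame({"a": [0.0, 5.0, 10.0], "b": [0.0, 5.0, 10.0]})
        std = min_max_standardize(raw, {"a": +1, "b": -1})
        assert list(std.values["a"]) == pytest.approx([0.0, 0.5, 1.0])
        assert list(std.values["b"]) == pytest.approx([1.0, 0.5, 0.0])

    def test_zero_variance_column_dropped_with_warning(self):
        raw = pd.DataFrame({"a": [1.0, 2.0, 3.0], "c": [2.0, 2.0, 2.0]})
        with pytest.warns(UserWarning, match="zero variance"):
            std = min_max_standardize(raw)
        assert std.dropped == ["c"] and std.columns == ["a"]

    def test_needs_two_rows(self):
        with pytest.raises(InvalidParameterError):
            min_max_standardize(pd.DataFrame({"a": [1.0]}))

    def test_all_entries_in_unit_interval(self, indicators):
        std = min_max_standardize(indicators[["VC", "AB", "EH", "CH", "SR", "HB", "SW"]])
        v = std.values.to_numpy()
        assert (v >= 0).all() and (v <= 1).all()


def _partial_corr_residual_oracle(x: np.ndarray, i: int, j: int) -> float:
    """Partial correlation of columns i, j given all others, via regression
    residuals — an independent route to the anti-image values."""
    others = [k for k in range(x.shape[1]) if k not in (i, j)]
    xi, xj = x[:, i], x[:, j]
    if others:
        z = np.column_stack([x[:, others], np.ones(len(x))])
        ri = xi - z @ np.linalg.lstsq(z, xi, rcond=None)[0]
        rj = xj - z @ np.linalg.lstsq(z, xj, rcond=None)[0]
    else:
        ri, rj = xi - xi.mean(), xj - xj.mean()
    return float(np.corrcoef(ri, rj)[0, 1])


class TestKMO:
    def test_two_variables_is_exactly_half(self, rng):
        # with two variables the partial equals the simple correlation
        x = rng.normal(size=(40, 2))
        x[:, 1] += 0.5 * x[:, 0]
        assert kmo(x) == pytest.approx(0.5, abs=1e-12)

    def test_equicorrelated_population_matrix(self):
        # 3 variables, rho = 0.5: q = (rho - rho^2)/(1 - rho^2) = 1/3,
        # KMO = 3·0.25/(3·0.25 + 3·(1/9)) = 9/13
        r = np.full((3, 3), 0.5)
        np.fill_diagonal(r, 1.0)
        assert kmo_from_correlation(r) == pytest.approx(9 / 13, abs=1e-12)
        assert kmo_from_correlation(r) == pytest.approx(0.6923, abs=1e-4)

    def test_matches_residual_regression_oracle(self, rng):
        x = rng.normal(size=(60, 4)) @ rng.normal(size=(4, 4))
        r = np.corrcoef(x, rowvar=False)
        s = np.linalg.inv(r)
        d = np.sqrt(np.outer(np.diag(s), np.diag(s)))
        q = -s / d
        r2 = q2 = 0.0
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                q_oracle = _partial_corr_residual_oracle(x, i, j)
                assert q[i, j] == pytest.approx(q_oracle, abs=1e-8)
                r2 += r[i, j] ** 2
                q2 += q_oracle**2
        assert kmo(x) == pytest.approx(r2 / (r2 + q2), abs=1e-8)

    def test_rejects_collinear(self, rng):
        x = rng.normal(size=(30, 1))
        with pytest.raises(Exception):
            kmo(np.column_stack([x, x]))


class TestBartlett:
    def test_uncorrelated_columns_give_zero_chi2(self):
        # exactly orthogonal contrast patterns -> sample correlation = I
        x = np.array([[1.0, 1.0], [-1.0, 1.0], [1.0, -1.0], [-1.0, -1.0]])
        chi2, p = bartlett_sphericity(x)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_closed_form_two_columns(self, rng):
        n, r_target = 50, 0.9
        z = rng.normal(size=n)
        x = np.column_stack([z, r_target * z + np.sqrt(1 - r_target**2) * rng.normal(size=n)])
        chi2, p = bartlett_sphericity(x)
        r = np.corrcoef(x, rowvar=False)[0, 1]
        expected = -(n - 1 - (2 * 2 + 5) / 6) * np.log(1 - r**2)
        assert chi2 == pytest.approx(expected, rel=1e-10)
        assert 0 < p < 1e-6

    def test_chi2_increases_with_correlation(self, rng):
        n = 40
        z = rng.normal(size=n)
        prev = -1.0
        for rho in (0.2, 0.5, 0.8):
            x = np.column_stack([z, rho * z + np.sqrt(1 - rho**2) * rng.normal(size=n)])
            chi2, _ = bartlett_sphericity(x)
            assert chi2 > prev
            prev = chi2

    def test_needs_more_rows_than_columns(self, rng):
        with pytest.raises(InvalidParameterError):
            bartlett_sphericity(rng.normal(size=(3, 3)))


def _power_iteration_eigh(r: np.ndarray, iters: int = 5000):
    """Deflation + power iteration: an independent eigensolver for tiny matrices."""
    m = r.copy()
    vals, vecs = [], []
    for _ in range(r.shape[0]):
        v = np.ones(r.shape[0]) / np.sqrt(r.shape[0])
        for _ in range(iters):
            w = m @ v
            nrm = np.linalg.norm(w)
            if nrm == 0:
                break
            v = w / nrm
        lam = float(v @ m @ v)
        vals.append(lam)
        vecs.append(v.copy())
        m = m - lam * np.outer(v, v)
    return np.array(vals), np.column_stack(vecs)


class TestPCAWeights:
    def test_two_perfectly_correlated_indicators(self):
        x = pd.DataFrame({"a": [0.0, 0.5, 1.0], "b": [0.0, 0.5, 1.0]})
        w = pca_weights(IndicatorMatrix(values=x, orientations={}))
        assert w.to_numpy() == pytest.approx([0.5, 0.5], abs=1e-10)

    def test_matches_power_iteration_oracle(self, rng):
        x = rng.normal(size=(30, 3)) @ rng.normal(size=(3, 3))
        df = pd.DataFrame(x, columns=["a", "b", "c"])
        r = np.corrcoef(x, rowvar=False)
        vals, vecs = _power_iteration_eigh(r)
        evals = np.linalg.eigvalsh(r)[::-1]
        assert vals == pytest.approx(evals, abs=1e-8)
        retained = vals > 1.0
        if not retained.any():
            retained[0] = True
        load = np.abs(vecs[:, retained]) * np.sqrt(vals[retained])
        w_expected = (load * (vals[retained] / vals.sum())).sum(axis=1)
        w_expected /= w_expected.sum()
        w = pca_weights(df)
        assert w.to_numpy() == pytest.approx(w_expected, abs=1e-8)

    @settings(deadline=None, max_examples=50)
    @given(arrays(np.float64, (8, 4), elements=st.floats(-10, 10)))
    def test_weights_nonnegative_and_sum_to_one(self, x):
        df = pd.DataFrame(x, columns=list("abcd"))
        if (df.std() < 1e-8).any() or not np.isfinite(np.corrcoef(x, rowvar=False)).all():
            return
        w = pca_weights(df)
        assert (w >= 0).all()
        assert w.sum() == pytest.approx(1.0, abs=1e-10)


class TestGHIScore:
    def test_endpoints_and_hand_value(self):
        v = pd.DataFrame({"a": [1.0, 0.0, 0.2], "b": [1.0, 0.0, 0.8]})
        w = pd.Series([0.5, 0.5], index=["a", "b"])
        s = ghi_score(v, w)
        assert list(s) == pytest.approx([1.0, 0.0, 0.5])

    def test_misaligned_weights_rejected(self):
        v = pd.DataFrame({"a": [1.0, 0.0]})
        w = pd.Series([1.0], index=["zzz"])
        with pytest.raises(InvalidParameterError):
            ghi_score(v, w)


def _ward_oracle_partition(scores: np.ndarray, k: int) -> list:
    """Greedy Ward agglomeration by direct minimization of the within-cluster
    variance increase Δ = |A||B|/(|A|+|B|)·(mean_A − mean_B)²."""
    clusters = [[i] for i in range(len(scores))]
    while len(clusters) > k:
        best, best_pair = None, None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                na, nb = len(clusters[a]), len(clusters[b])
                ma = scores[clusters[a]].mean()
                mb = scores[clusters[b]].mean()
                delta = na * nb / (na + nb) * (ma - mb) ** 2
                if best is None or delta < best:
                    best, best_pair = delta, (a, b)
        a, b = best_pair
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return clusters


class TestClassify:
    def test_well_separated_pairs(self):
        scores = pd.Series([0.92, 0.90, 0.61, 0.59, 0.34, 0.32, 0.10, 0.08],
                           index=[f"p{i}" for i in range(8)])
        levels, _ = classify_disturbance(scores, k=4)
        assert list(levels) == ["I", "I", "II", "II", "III", "III", "IV", "IV"]

    def test_four_distinct_scores_each_own_level(self):
        scores = pd.Series([0.9, 0.6, 0.3, 0.1], index=list("abcd"))
        levels, _ = classify_disturbance(scores, k=4)
        assert list(levels) == ["I", "II", "III", "IV"]

    def test_matches_ward_oracle_on_five_points(self, rng):
        for _ in range(20):
            s = np.sort(rng.uniform(0, 1, 5))[::-1]
            scores = pd.Series(s, index=[f"p{i}" for i in range(5)])
            levels, _ = classify_disturbance(scores, k=3)
            oracle = _ward_oracle_partition(s, 3)
            got = {frozenset(scores.index[levels == lab]) for lab in levels.unique()}
            expect = {frozenset(f"p{i}" for i in c) for c in oracle}
            assert got == expect

    def test_too_few_distinct_scores(self):
        scores = pd.Series([0.5, 0.5, 0.5, 0.5])
        with pytest.raises(InvalidParameterError, match="k"):
            classify_disturbance(scores, k=4)

    def test_level_means_strictly_decrease(self, indicators):
        res = build_ghi(indicators[indicators["type"] == "AM"])
        means = res.scores.groupby(res.levels).mean()
        assert (means["I"] > means["II"] > means["III"] > means["IV"])

    def test_permutation_equivariance(self, indicators):
        am = indicators[indicators["type"] == "AM"].reset_index(drop=True)
        res1 = build_ghi(am)
        shuffled = am.sample(frac=1.0, random_state=1).reset_index(drop=True)
        res2 = build_ghi(shuffled)
        assert res1.levels.sort_index().equals(res2.levels.sort_index())
        assert res1.scores.sort_index().round(12).equals(res2.scores.sort_index().round(12))


def test_build_ghi_scores_in_unit_interval_and_levels_anticorrelate(indicators):
    res = build_ghi(indicators[indicators["type"] == "AS"])
    assert ((res.scores >= -1e-12) & (res.scores <= 1 + 1e-12)).all()
    assert res.weights.sum() == pytest.approx(1.0)
    assert 0 < res.kmo < 1
    # heavier disturbance levels sit at higher burrow densities
    sub = indicators[indicators["type"] == "AS"].set_index("plot_id")
    rank = res.levels.map({"I": 1, "II": 2, "III": 3, "IV": 4})
    rho = np.corrcoef(rank.loc[sub.index], sub["EH"])[0, 1]
    assert rho > 0
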