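import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ansbr.data_model import DistanceMatrix
from ansbr.correlation import (
    classify_correlation,
    correlation_table,
    pearson,
    permanova,
    permanova_table,
)
from ansbr.errors import (
    DomainError,
    InsufficientDataError,
    UndefinedCorrelationError,
    ValidationError,
)


def pearson_oracle(x, y):
    """Direct textbook formula: covariance over the product of SDs, p from t."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    xm, ym = x - x.mean(), y - y.mean()
    r = (xm * ym).sum() / math.sqrt((xm**2).sum() * (ym**2).sum())
    t = r * math.sqrt((n - 2) / (1 - r**2)) if abs(r) < 1 else math.inf
    p = 2 * stats.t.sf(abs(t), n - 2)
    return r, p


def permanova_oracle_groups(D, labels):
    """Anderson's group-sum pseudo-F, independent of the hat-matrix route."""
    labels = np.asarray(labels)
    n = len(labels)
    d2 = D**2
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    groups = np.unique(labels)
    for g in groups:
        idx = np.flatnonzero(labels == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    a = len(groups)
    ss_between = ss_total - ss_within
    return (ss_between / (a - 1)) / (ss_within / (n - a))


class TestPearson:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        r, p, n = pearson(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert n == 10

    def test_orthogonal_series_have_zero_correlation(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        r, p, _ = pearson(x, y)
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_matches_textbook_formula_on_small_vectors(self):
        x = [1, 2, 3, 4, 5]
        y = [2, 1, 4, 3, 7]
        r, p, n = pearson(x, y)
        r0, p0 = pearson_oracle(x, y)
        assert r == pytest.approx(r0, abs=1e-12)
        assert p == pytest.approx(p0, abs=1e-12)

    def test_pairwise_deletion_of_missing_values(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [1.1, 2.2, 3.0, np.nan, 5.1]
        r, p, n = pearson(x, y)
        assert n == 3

    def test_fewer_than_three_pairs_is_insufficient(self):
        with pytest.raises(InsufficientDataError):
            pearson([1.0, 2.0], [3.0, 4.0])

    def test_zero_variance_is_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @given(
        a=st.floats(-5, 5), b=st.floats(0.1, 5), flip=st.booleans(),
        seed=st.integers(0, 100),
    )
    @settings(derandomize=True, max_examples=30)
    def test_affine_invariance_and_antisymmetry(self, a, b, flip, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        r, _, _ = pearson(x, y)
        r2, _, _ = pearson(a + b * x, y)
        assert abs(r2) == pytest.approx(abs(r), abs=1e-9)
        r3, _, _ = pearson(-x, y) if flip else pearson(x, -y)
        assert r3 == pytest.approx(-r, abs=1e-9)


class TestClassification:
    @pytest.mark.parametrize(
        "r,p,expected",
        [
            (0.56, 0.00, "moderate"),   # TCOD removal vs reactor ammonification
            (-0.81, 0.03, "high"),      # ZSV vs carbohydrate concentration
            (0.10, 0.64, "none"),       # TCOD removal vs protein concentration
            (0.30, 0.01, "low"),
            (0.60, 0.01, "moderate"),
            (0.61, 0.01, "high"),
            (-0.25, 0.049, "low"),
        ],
    )
    def test_band_assignment(self, r, p, expected):
        assert classify_correlation(r, p) == expected

    def test_out_of_range_coefficient_rejected(self):
        with pytest.raises(DomainError):
            classify_correlation(1.2, 0.01)

    @given(r=st.floats(-1, 1), p=st.floats(0, 1))
    @settings(derandomize=True, max_examples=200)
    def test_exhaustive_and_mutually_exclusive(self, r, p):
        assert classify_correlation(r, p) in {"none", "low", "moderate", "high"}


class TestPermanova:
    def _dm(self, D, ids=None):
        n = D.shape[0]
        return DistanceMatrix(tuple(ids or (f"s{i}" for i in range(n))), D)

    def test_binary_grouping_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(4, 2))
        D = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        labels = np.array(["a", "a", "b", "b"])
        res = permanova(self._dm(D), labels, n_permutations=10_000, seed=0)
        f_obs = permanova_oracle_groups(D, labels)
        assert res.pseudo_F == pytest.approx(f_obs, rel=1e-9)
        perms = [
            permanova_oracle_groups(D, labels[list(p)])
            for p in itertools.permutations(range(4))
        ]
        p_exact = np.mean([f >= f_obs - 1e-12 for f in perms])
        assert res.p == pytest.approx(p_exact, abs=1e-12)

    def test_five_sample_enumeration_also_exact(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(5, 2))
        D = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        labels = np.array(["a", "a", "a", "b", "b"])
        res = permanova(self._dm(D), labels, n_permutations=10_000, seed=0)
        f_obs = permanova_oracle_groups(D, labels)
        perms = [
            permanova_oracle_groups(D, labels[list(p)])
            for p in itertools.permutations(range(5))
        ]
        assert res.p == pytest.approx(np.mean([f >= f_obs - 1e-12 for f in perms]), abs=1e-12)

    def test_well_separated_groups_give_high_r2_and_minimal_p(self):
        rng = np.random.default_rng(4)
        pts = np.vstack([rng.normal(0, 0.05, (6, 2)), rng.normal(10, 0.05, (6, 2))])
        D = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        labels = np.array(["a"] * 6 + ["b"] * 6)
        res = permanova(self._dm(D), labels, n_permutations=999, seed=0)
        assert res.R2 > 0.9
        # permutations that merely swap the two group labels reproduce the
        # observed F, so the attainable minimum is a handful of counts / 1000
        assert res.p <= 5 / (1 + 999)

    def test_continuous_covariate_r2_bounds_and_determinism(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(10, 3))
        D = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        z = rng.normal(size=10)
        a = permanova(self._dm(D), z, n_permutations=499, seed=11)
        b = permanova(self._dm(D), z, n_permutations=499, seed=11)
        assert 0.0 <= a.R2 <= 1.0
        assert 0.0 < a.p <= 1.0
        assert a.p == b.p and a.pseudo_F == b.pseudo_F

    def test_constant_variable_rejected(self):
        D = 1.0 - np.eye(4)
        with pytest.raises(DomainError):
            permanova(self._dm(D), np.ones(4))

    def test_length_mismatch_rejected(self):
        D = 1.0 - np.eye(4)
        with pytest.raises(ValidationError):
            permanova(self._dm(D), np.arange(3))

    def test_permanova_table_runs_one_test_per_covariate(self):
        rng = np.random.default_rng(12)
        pts = rng.normal(size=(8, 2))
        D = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        dm = self._dm(D)
        cov = pd.DataFrame(
            {"olr": rng.uniform(2, 6, 8), "hrt": rng.uniform(1, 3, 8)},
            index=list(dm.ids),
        )
        out = permanova_table(dm, cov, n_permutations=99, seed=1)
        assert list(out["factor"]) == ["olr", "hrt"]
        assert ((out["R2"] >= 0) & (out["R2"] <= 1)).all()


class TestCorrelationTable:
    def test_planted_linear_dependence_recovered_as_high(self):
        rng = np.random.default_rng(13)
        days = np.arange(0, 60, 2.0)
        x = rng.normal(size=len(days))
        y = 0.8 * x + np.sqrt(1 - 0.8**2) * rng.normal(size=len(days))
        series = {
            "olr": pd.Series(x, index=days),
            "tcod_removal": pd.Series(y, index=days),
        }
        results = correlation_table(series, outputs=["tcod_removal"])
        assert len(results) == 1
        res = results[0]
        assert res.r == pytest.approx(0.8, abs=0.15)
        assert res.category == "high"

    def test_nearest_day_join_within_window(self):
        days_a = np.array([0.0, 10.0, 20.0, 30.0])
        days_b = days_a + 1.0  # offset sampling grid, within the +/-2 d window
        x = np.array([1.0, 2.0, 3.0, 4.0])
        series = {
            "out": pd.Series(2 * x, index=days_a),
            "pred": pd.Series(x, index=days_b),
        }
        results = correlation_table(series, outputs=["out"])
        assert results[0].n == 4
        assert results[0].r == pytest.approx(1.0)

    def test_disjoint_day_ranges_skipped_with_warning(self, caplog):
        series = {
            "out": pd.Series([1.0, 2.0, 3.0], index=[0.0, 1.0, 2.0]),
            "pred": pd.Series([1.0, 2.0, 3.0], index=[100.0, 101.0, 102.0]),
        }
        with caplog.at_level("WARNING"):
            results = correlation_table(series, outputs=["out"])
        assert results == []
        assert any("overlap" in m for m in caplog.messages)
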