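"""Correlation screening: Pearson oracle, exhaustive pair search, combinations."""

import numpy as np
import pandas as pd
import pytest

from specfrac import (
    DerivativeSet,
    TwoBandCorrelationSelector,
    build_combinations,
    pearson_r,
    rank_features,
    two_band_correlation,
)
from specfrac.indices import SAVI_L
from specfrac.selection import SelectionError, two_band_correlation_multi


def _deriv(values, order=0.5, wl_start=700.0):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    wl = wl_start + np.arange(values.shape[1])
    return DerivativeSet(order, [f"S{i}" for i in range(values.shape[0])], wl, values)


def brute_force_matrix(X, y, kind):
    """Naive double loop over ordered pairs, one pearson_r call per cell."""
    n_bands = X.shape[1]
    r = np.full((n_bands, n_bands), np.nan)
    for i in range(n_bands):
        for j in range(n_bands):
            if kind == "DI":
                v = X[:, i] - X[:, j]
            else:
                with np.errstate(divide="ignore", invalid="ignore"):
                    v = (1 + SAVI_L) * (X[:, i] - X[:, j]) / (
                        X[:, i] + X[:, j] + SAVI_L
                    )
            if not np.all(np.isfinite(v)):
                continue
            r[i, j] = pearson_r(v, y)
    return r


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        assert pearson_r([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_zero_variance_flagged(self):
        assert np.isnan(pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            pearson_r([1, 2, 3], [1, 2])


class TestTwoBandSearch:
    @pytest.mark.parametrize("kind", ["DI", "SAVI"])
    @pytest.mark.parametrize("block_size", [1, 2, 64])
    def test_matches_brute_force_toy(self, kind, block_size, rng):
        X = rng.uniform(0, 1, (8, 5))
        y = rng.uniform(0, 1, 8)
        res = two_band_correlation(_deriv(X), kind, y, block_size=block_size)
        expected = brute_force_matrix(X, y, kind)
        finite = np.isfinite(expected)
        np.testing.assert_allclose(
            res.r_matrix[finite], expected[finite], atol=1e-10
        )
        assert np.array_equal(np.isnan(res.r_matrix), ~finite)

    def test_di_matches_covariance_identity(self, rng):
        """corr(Ri - Rj, y) from the covariance shortcut, independently."""
        X = rng.uniform(0, 1, (30, 100))
        y = rng.uniform(0, 1, 30)
        res = two_band_correlation(_deriv(X), "DI", y)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        cov_xy = Xc.T @ yc
        gram = Xc.T @ Xc
        ssq = np.diag(gram)
        num = cov_xy[:, None] - cov_xy[None, :]
        den = np.sqrt(
            (ssq[:, None] + ssq[None, :] - 2 * gram) * (yc @ yc)
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            expected = num / den
        finite = np.isfinite(expected)
        np.testing.assert_allclose(res.r_matrix[finite], expected[finite], atol=1e-10)

    def test_self_correlation_argmax(self, rng):
        X = rng.uniform(0, 1, (12, 6))
        target = X[:, 3] - X[:, 1]  # DI(band3, band1) itself
        res = two_band_correlation(_deriv(X, wl_start=700), "DI", target)
        assert abs(res.r_max) == pytest.approx(1.0, abs=1e-12)
        # the |r| argmax is the pair or its antisymmetric twin; the row-major
        # tie rule picks the smaller i first
        assert (res.i_max, res.j_max) == (701.0, 703.0)

    def test_antisymmetry_of_di_matrix(self, rng):
        X = rng.uniform(0, 1, (10, 7))
        y = rng.uniform(0, 1, 10)
        res = two_band_correlation(_deriv(X), "DI", y)
        r = res.r_matrix
        off = ~np.eye(7, dtype=bool)
        np.testing.assert_allclose(r[off], -r.T[off], atol=1e-12)

    def test_constant_derivative_selection_error(self):
        X = np.full((8, 5), 0.3)
        with pytest.raises(SelectionError):
            two_band_correlation(_deriv(X), "DI", np.arange(8.0))

    def test_multi_target_matches_single(self, rng):
        X = rng.uniform(0, 1, (15, 20))
        y1, y2 = rng.uniform(0, 1, (2, 15))
        multi = two_band_correlation_multi(
            _deriv(X), "DI", {"a": y1, "b": y2}
        )
        for name, y in (("a", y1), ("b", y2)):
            single = two_band_correlation(_deriv(X), "DI", y)
            assert multi[name].r_max == pytest.approx(single.r_max, abs=1e-12)
            assert multi[name].i_max == single.i_max
            assert multi[name].j_max == single.j_max

    def test_triangular_mode_restricts_pairs(self, rng):
        X = rng.uniform(0, 1, (9, 6))
        y = rng.uniform(0, 1, 9)
        res = two_band_correlation(_deriv(X), "DI", y, triangular=True)
        assert np.all(np.isnan(res.r_matrix[np.tril_indices(6)]))
        assert res.i_max < res.j_max

    def test_selector_transform_returns_selected_index(self, rng):
        X = rng.uniform(0, 1, (12, 5))
        y = rng.uniform(0, 1, 12)
        sel = TwoBandCorrelationSelector(kind="DI").fit(X, y)
        col = sel.transform(X)
        np.testing.assert_allclose(
            col[:, 0], X[:, sel.i_max_] - X[:, sel.j_max_]
        )


class TestRanking:
    def test_signed_feature_and_negation_tie(self, rng):
        f = rng.uniform(0, 1, 20)
        feats = pd.DataFrame(
            {"f": f, "neg": -f, "noise": rng.uniform(0, 1, 20)}
        )
        top = rank_features(feats, f, k=1)
        assert top["feature"].iloc[0] in ("f", "neg")
        assert abs(top["r"].iloc[0]) == pytest.approx(1.0)

    def test_matches_brute_force_sort(self, small_dataset, small_smoothed):
        from specfrac import compute_empirical_indices

        feats = compute_empirical_indices(small_smoothed)
        y = small_dataset.trait("lcc_area")
        ranked = rank_features(feats, y)
        expected = sorted(
            (
                (name, pearson_r(feats[name], y))
                for name in feats.columns
                if np.isfinite(pearson_r(feats[name], y))
            ),
            key=lambda t: -abs(t[1]),
        )
        assert list(ranked["feature"]) == [n for n, _ in expected]

    def test_k_equals_all_returns_all(self, rng):
        feats = pd.DataFrame(rng.uniform(0, 1, (15, 4)), columns=list("abcd"))
        y = rng.uniform(0, 1, 15)
        assert len(rank_features(feats, y, k=4)) == 4

    def test_empty_table_rejected(self):
        with pytest.raises(SelectionError):
            rank_features(pd.DataFrame(), np.arange(5.0))


class TestCombinations:
    def _ranked(self, names, rs):
        df = pd.DataFrame({"feature": names, "r": rs})
        return df.reindex(
            df["r"].abs().sort_values(ascending=False).index
        ).reset_index(drop=True)

    def test_disjoint_families_partition_combination4(self):
        emp = self._ranked([f"e{i}" for i in range(8)], np.linspace(0.9, 0.2, 8))
        tri = self._ranked([f"t{i}" for i in range(8)], np.linspace(0.85, 0.15, 8))
        two = self._ranked([f"w{i}" for i in range(8)], np.linspace(0.8, 0.1, 8))
        combos = build_combinations(emp, tri, two, k=7)
        members4 = set(combos["combination 4"].feature_names)
        union = (
            set(combos["combination 1"].feature_names)
            | set(combos["combination 2"].feature_names)
            | set(combos["combination 3"].feature_names)
        )
        assert members4 <= union
        for name in members4:
            count = sum(
                name in combos[f"combination {i}"].feature_names for i in (1, 2, 3)
            )
            assert count == 1

    def test_dominant_family_fills_combination4(self):
        emp = self._ranked([f"e{i}" for i in range(7)], np.linspace(0.5, 0.2, 7))
        tri = self._ranked([f"t{i}" for i in range(7)], np.linspace(0.55, 0.25, 7))
        two = self._ranked([f"w{i}" for i in range(7)], np.linspace(0.99, 0.9, 7))
        combos = build_combinations(emp, tri, two, k=7)
        assert combos["combination 4"].feature_names == combos[
            "combination 3"
        ].feature_names

    def test_each_combination_has_exactly_k(self):
        emp = self._ranked([f"e{i}" for i in range(10)], np.linspace(0.9, 0.1, 10))
        tri = self._ranked([f"t{i}" for i in range(10)], np.linspace(0.9, 0.1, 10))
        two = self._ranked([f"w{i}" for i in range(10)], np.linspace(0.9, 0.1, 10))
        combos = build_combinations(emp, tri, two, k=7)
        assert all(len(c.members) == 7 for c in combos.values())

    def test_short_family_names_the_culprit(self):
        emp = self._ranked(["e0", "e1"], [0.9, 0.8])
        tri = self._ranked([f"t{i}" for i in range(8)], np.linspace(0.9, 0.2, 8))
        with pytest.raises(SelectionError, match="combination 1"):
            build_combinations(emp, tri, tri, k=7)
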