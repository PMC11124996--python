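"""Empirical index formulas, trilateral parameters, and two-band indices."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from specfrac import (
    SpectraSet,
    TwoBandIndexSpec,
    compute_empirical_indices,
    compute_trilateral,
    fractional_derivative,
    two_band_values,
)
from specfrac.indices import CoverageError


def _flat(value=0.3, n=1, lo=350, hi=900):
    wl = np.arange(float(lo), float(hi) + 1)
    return SpectraSet([f"S{i}" for i in range(n)], wl, np.full((n, wl.size), value))


def _from_rows(rows, lo=350, hi=900):
    rows = np.atleast_2d(rows)
    wl = np.arange(float(lo), float(hi) + 1)
    return SpectraSet([f"S{i}" for i in range(rows.shape[0])], wl, rows)


class TestEmpiricalIndices:
    def test_cari_direct_substitution(self):
        # R700 = R670 = 0.1 -> CARI = -0.04
        idx = compute_empirical_indices(_flat(0.1))
        assert idx["CARI"].iloc[0] == pytest.approx(-0.04, abs=1e-12)

    def test_sr1_ratio_identity(self):
        idx = compute_empirical_indices(_flat(0.42))
        assert idx["SR1"].iloc[0] == pytest.approx(1.0)

    def test_flat_spectrum_values(self):
        """Hand evaluation of each formula on a constant 0.3 spectrum.

        SIPI is 0/0 on a constant spectrum and is flagged non-finite.
        """
        idx = compute_empirical_indices(_flat(0.3)).iloc[0]
        assert idx["PRI"] == pytest.approx(0.0)
        assert idx["PRI1"] == pytest.approx(0.0)
        assert idx["GRVI"] == pytest.approx(1.0)
        assert idx["IPVI"] == pytest.approx(0.5)
        assert idx["SR705"] == pytest.approx(1.0)
        assert np.isnan(idx["SIPI"])

    def test_ipvi_printed_form(self):
        idx = compute_empirical_indices(_flat(0.3), ipvi_as_printed=True)
        assert idx["IPVI"].iloc[0] == pytest.approx(0.3 * 0.6, abs=1e-12)

    def test_missing_band_coverage_error(self):
        with pytest.raises(CoverageError):
            compute_empirical_indices(_flat(0.3, lo=500, hi=700))

    def test_sample_order_invariance(self, small_smoothed):
        idx = compute_empirical_indices(small_smoothed)
        rev = SpectraSet(
            small_smoothed.sample_ids[::-1],
            small_smoothed.wavelengths,
            small_smoothed.reflectance[::-1],
        )
        idx_rev = compute_empirical_indices(rev)
        np.testing.assert_allclose(
            idx.loc[idx.index[::-1]].to_numpy(), idx_rev.to_numpy()
        )


class TestTrilateral:
    def test_linear_spectrum_constant_derivative(self):
        wl = np.arange(350.0, 901.0)
        c = 2.5e-4
        s = _from_rows(0.05 + c * (wl - 350.0))
        d1 = fractional_derivative(s, 1.0)
        tri = compute_trilateral(s, d1).iloc[0]
        assert tri["Db"] == pytest.approx(c, abs=1e-12)
        assert tri["Dy"] == pytest.approx(c, abs=1e-12)
        assert tri["Dr"] == pytest.approx(c, abs=1e-12)
        n_red = int(760 - 670 + 1)
        assert tri["SDr"] == pytest.approx(c * n_red, abs=1e-10)

    def test_constant_spectrum_zero_derivative_params(self):
        s = _flat(0.3)
        d1 = fractional_derivative(s, 1.0)
        tri = compute_trilateral(s, d1).iloc[0]
        for name in ("Db", "Dy", "Dr", "SDb", "SDy", "SDr", "SDr-SDb"):
            assert tri[name] == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(tri["SDr/SDy"])
        assert tri["Rg"] == pytest.approx(0.3)
        assert tri["Rr"] == pytest.approx(0.3)

    def test_dr_matches_brute_force_argmax(self, small_dataset, small_smoothed):
        d1 = fractional_derivative(small_smoothed, 1.0)
        tri = compute_trilateral(small_smoothed, d1)
        wl = small_smoothed.wavelengths
        mask = (wl >= 670) & (wl <= 760)
        for i in range(small_smoothed.n_samples):
            best = max(d1.values[i, mask])
            assert tri["Dr"].iloc[i] == pytest.approx(best, abs=1e-12)
            peak_wl = wl[mask][np.argmax(d1.values[i, mask])]
            assert 670 <= peak_wl <= 760

    def test_requires_first_order_derivative(self, small_smoothed):
        d05 = fractional_derivative(small_smoothed, 0.5)
        with pytest.raises(ValueError, match="order-1"):
            compute_trilateral(small_smoothed, d05)


class TestTwoBand:
    def _deriv(self, r700, r800, order=0.5):
        wl = np.arange(650.0, 851.0)
        refl = np.full((len(r700), wl.size), 0.1)
        refl[:, wl == 700] = np.asarray(r700)[:, None]
        refl[:, wl == 800] = np.asarray(r800)[:, None]
        from specfrac import DerivativeSet

        return DerivativeSet(order, [f"S{i}" for i in range(len(r700))], wl, refl)

    def test_di_direct_subtraction(self):
        d = self._deriv([0.5], [0.3])
        v = two_band_values(d, TwoBandIndexSpec("DI", 0.5, 700, 800))
        assert v[0] == pytest.approx(0.2, abs=1e-12)

    def test_savi_hand_arithmetic(self):
        d = self._deriv([0.5], [0.3])
        v = two_band_values(d, TwoBandIndexSpec("SAVI", 0.5, 700, 800))
        assert v[0] == pytest.approx(1.16 * 0.2 / 0.96, abs=1e-12)

    def test_equal_bands_give_zero(self):
        d = self._deriv([0.4], [0.4])
        assert two_band_values(d, TwoBandIndexSpec("DI", 0.5, 700, 800))[0] == 0.0
        assert two_band_values(d, TwoBandIndexSpec("SAVI", 0.5, 700, 800))[0] == 0.0

    def test_savi_zero_denominator_flagged(self):
        d = self._deriv([0.0], [-0.16])
        v = two_band_values(d, TwoBandIndexSpec("SAVI", 0.5, 700, 800))
        assert np.isnan(v[0])

    @settings(deadline=None, max_examples=30)
    @given(
        ri=st.floats(-1, 1, allow_nan=False),
        rj=st.floats(-1, 1, allow_nan=False),
    )
    def test_antisymmetry(self, ri, rj):
        d = self._deriv([ri], [rj])
        for kind in ("DI", "SAVI"):
            fwd = two_band_values(d, TwoBandIndexSpec(kind, 0.5, 700, 800))[0]
            rev = two_band_values(d, TwoBandIndexSpec(kind, 0.5, 800, 700))[0]
            if np.isfinite(fwd):
                assert fwd == pytest.approx(-rev, abs=1e-12)

    def test_order_mismatch_rejected(self):
        d = self._deriv([0.5], [0.3], order=1.0)
        with pytest.raises(ValueError, match="order"):
            two_band_values(d, TwoBandIndexSpec("DI", 0.5, 700, 800))

    def test_invalid_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            TwoBandIndexSpec("NDVI", 0.5, 700, 800)
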