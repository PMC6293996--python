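"""Spectrum I/O, resampling, and cropping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from carbphase import (
    DomainError,
    FormatError,
    InsufficientDataError,
    SpectralWindow,
    Spectrum,
    crop,
    read_two_column,
    resample,
    write_csv,
)


def _write(tmp_path, text, name="spec.txt"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadTwoColumn:
    def test_identity_readback(self, tmp_path):
        rows = "\n".join(f"{100 + i},{float(i % 2)}" for i in range(8))
        s = read_two_column(_write(tmp_path, rows))
        assert len(s) == 8
        np.testing.assert_allclose(s.shift, np.arange(100, 108))

    def test_descending_input_is_sorted(self, tmp_path):
        asc = "\n".join(f"{100 + i} {i * 0.5}" for i in range(10))
        desc = "\n".join(f"{109 - i} {(9 - i) * 0.5}" for i in range(10))
        a = read_two_column(_write(tmp_path, asc, "a.txt"))
        b = read_two_column(_write(tmp_path, desc, "b.txt"))
        np.testing.assert_array_equal(a.shift, b.shift)
        np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_duplicate_shifts_collapse_to_mean(self, tmp_path):
        rows = "\n".join(f"{100 + i},1.0" for i in range(8))
        rows += "\n200,1.0\n200,3.0"
        s = read_two_column(_write(tmp_path, rows))
        assert np.count_nonzero(s.shift == 200) == 1
        assert s.intensity[s.shift == 200][0] == pytest.approx(2.0)

    def test_comments_and_header_skipped(self, tmp_path):
        rows = "##NAME test\n# comment\nshift,intensity\n" + "\n".join(
            f"{i},{i}" for i in range(10)
        )
        s = read_two_column(_write(tmp_path, rows))
        assert len(s) == 10

    def test_bad_line_names_line_number(self, tmp_path):
        rows = "\n".join(f"{i},{i}" for i in range(10)) + "\nnot numbers here"
        with pytest.raises(FormatError, match="line 11"):
            read_two_column(_write(tmp_path, rows))

    def test_too_few_rows(self, tmp_path):
        with pytest.raises(InsufficientDataError):
            read_two_column(_write(tmp_path, "1,1\n2,2\n3,3"))

    def test_roundtrip_preserves_six_significant_digits(self, tmp_path):
        rng = np.random.default_rng(3)
        s = Spectrum(np.linspace(100, 400, 50), rng.uniform(0.1, 2.0, 50))
        path = tmp_path / "out.csv"
        write_csv(s, path)
        back = read_two_column(path)
        np.testing.assert_allclose(back.shift, s.shift, rtol=1e-5)
        np.testing.assert_allclose(back.intensity, s.intensity, rtol=1e-5)


class TestResample:
    def test_exact_on_a_line(self):
        s = Spectrum([0.0, 5.0, 10.0], [0.0, 10.0, 20.0])
        r = resample(s, 1.0, 0.0, 10.0)
        np.testing.assert_allclose(r.intensity, 2.0 * np.arange(11))

    def test_idempotent_on_same_grid(self):
        rng = np.random.default_rng(0)
        s = Spectrum(np.linspace(100, 400, 61), rng.uniform(0, 1, 61))
        once = resample(s, 1.0, 100, 400)
        twice = resample(once, 1.0, 100, 400)
        np.testing.assert_array_equal(once.shift, twice.shift)
        np.testing.assert_allclose(once.intensity, twice.intensity, rtol=1e-12)

    def test_digitized_gaussian_recovered(self):
        # 37 irregular knots emulating manual figure digitization: clicks
        # are quasi-regular but denser where the curve bends, with jitter
        truth = lambda x: np.exp(-0.5 * ((x - 280.0) / 10.0) ** 2)
        xx = np.linspace(230, 330, 2001)
        curv = np.abs(np.gradient(np.gradient(truth(xx), xx), xx))
        weight = 0.15 * curv.max() + curv
        cdf = np.cumsum(weight)
        cdf /= cdf[-1]
        rng = np.random.default_rng(42)
        u = (np.arange(37) + 0.5 + rng.uniform(-0.35, 0.35, 37)) / 37
        knots = np.unique(np.interp(np.sort(u), cdf, xx))
        s = Spectrum(knots, truth(knots))
        r = resample(s, 1.0, 230, 330)
        assert np.max(np.abs(r.intensity - truth(r.shift))) < 0.01

    def test_never_extrapolates(self):
        s = Spectrum(np.linspace(200, 300, 21), np.ones(21))
        r = resample(s, 1.0, 100, 400)
        assert r.span[0] >= 200 and r.span[1] <= 300

    def test_empty_overlap_raises(self):
        s = Spectrum(np.linspace(200, 300, 21), np.ones(21))
        with pytest.raises(DomainError):
            resample(s, 1.0, 500, 600)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(
        step=st.floats(0.25, 5.0),
        lo=st.floats(100.0, 150.0),
    )
    def test_grid_spacing_is_exactly_step(self, step, lo):
        rng = np.random.default_rng(1)
        x = np.sort(rng.uniform(90, 500, 40))
        x += np.arange(40) * 1e-6  # guarantee strictly increasing
        s = Spectrum(x, rng.uniform(0, 1, 40))
        r = resample(s, step, lo, lo + 60 * step)
        np.testing.assert_allclose(np.diff(r.shift), step, rtol=1e-12)


class TestCrop:
    def test_bounds_respected(self):
        s = Spectrum(np.linspace(0, 1300, 261), np.ones(261))
        c = crop(s, SpectralWindow(100, 400))
        assert c.shift.min() >= 100 and c.shift.max() <= 400

    def test_full_span_is_identity(self):
        rng = np.random.default_rng(5)
        s = Spectrum(np.linspace(100, 400, 31), rng.uniform(0, 1, 31))
        c = crop(s, SpectralWindow(100, 400))
        np.testing.assert_array_equal(c.shift, s.shift)
        np.testing.assert_array_equal(c.intensity, s.intensity)

    def test_boundaries_are_closed(self):
        s = Spectrum([99.5, 100.0, 400.0, 400.5], [1.0, 2.0, 3.0, 4.0])
        c = crop(s, SpectralWindow(100, 400))
        assert len(c) == 2
        np.testing.assert_array_equal(c.shift, [100.0, 400.0])

    def test_intensities_unaltered(self):
        rng = np.random.default_rng(6)
        s = Spectrum(np.linspace(50, 500, 91), rng.uniform(0, 1, 91))
        c = crop(s, SpectralWindow(100, 400))
        mask = (s.shift >= 100) & (s.shift <= 400)
        np.testing.assert_array_equal(c.intensity, s.intensity[mask])

    def test_no_overlap_raises(self):
        s = Spectrum(np.linspace(500, 600, 21), np.ones(21))
        with pytest.raises(DomainError):
            crop(s, SpectralWindow(100, 400))


class TestSpectrumInvariants:
    def test_rejects_nonmonotonic_shift(self):
        with pytest.raises(ValueError):
            Spectrum([1.0, 3.0, 2.0, 4.0, 5.0, 6.0, 7.0, 8.0], np.zeros(8))

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            Spectrum(np.arange(8.0), [0, 1, np.nan, 3, 4, 5, 6, 7])

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError):
            Spectrum(np.arange(8.0), np.zeros(9))
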