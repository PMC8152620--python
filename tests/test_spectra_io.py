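import numpy as np
import pytest

from autonmr.spectra_io import (
    InputError,
    RawFID,
    Spectrum,
    UnsupportedFormatError,
    read_bruker,
    read_jcamp,
    transform,
    write_bruker,
    write_jcamp,
)


def _damped_sinusoid(n=1024, sfo=400.0, sw=4800.0, f_hz=200.0, decay=1.5):
    t = np.arange(n) / sw
    points = np.exp(2j * np.pi * f_hz * t - np.pi * decay * t)
    return RawFID(points, spectrometer_frequency=sfo, sweep_width=sw,
                  frequency_offset=6.0 * sfo)


class TestBrukerRoundTrip:
    def test_metadata_and_points_survive(self, tmp_path):
        fid = _damped_sinusoid()
        write_bruker(fid, tmp_path / "acq")
        back = read_bruker(tmp_path / "acq")
        assert back.spectrometer_frequency == fid.spectrometer_frequency
        assert back.sweep_width == fid.sweep_width
        assert back.frequency_offset == fid.frequency_offset
        assert back.nucleus == "H1"
        np.testing.assert_allclose(back.points, fid.points, rtol=1e-12)

    @pytest.mark.parametrize("byte_order", ["<", ">"])
    @pytest.mark.parametrize("dtype", ["f8", "i4"])
    def test_encodings_agree(self, tmp_path, byte_order, dtype):
        fid = _damped_sinusoid()
        if dtype == "i4":  # integer storage needs integer-scale data
            fid = RawFID(np.round(fid.points * 1e6),
                         fid.spectrometer_frequency, fid.sweep_width,
                         fid.frequency_offset)
        d = tmp_path / f"acq_{byte_order == '<'}_{dtype}"
        write_bruker(fid, d, byte_order=byte_order, dtype=dtype)
        back = read_bruker(d)
        np.testing.assert_allclose(back.points, fid.points, rtol=1e-9)

    def test_missing_fid_file(self, tmp_path):
        d = tmp_path / "broken"
        write_bruker(_damped_sinusoid(), d)
        (d / "fid").unlink()
        with pytest.raises(InputError, match="FID"):
            read_bruker(d)

    def test_missing_required_key(self, tmp_path):
        d = tmp_path / "broken2"
        write_bruker(_damped_sinusoid(), d)
        acqus = (d / "acqus").read_text().replace("##$SW_h", "##$XX")
        (d / "acqus").write_text(acqus)
        with pytest.raises(InputError, match="SW_h"):
            read_bruker(d)

    def test_truncated_binary(self, tmp_path):
        d = tmp_path / "trunc"
        write_bruker(_damped_sinusoid(), d)
        raw = (d / "fid").read_bytes()
        (d / "fid").write_bytes(raw[: len(raw) // 2])
        with pytest.raises(InputError, match="truncated"):
            read_bruker(d)


class TestJcamp:
    def test_fid_round_trip(self, tmp_path):
        fid = _damped_sinusoid()
        path = write_jcamp(fid, tmp_path / "fid.jdx")
        back = read_jcamp(path)
        assert isinstance(back, RawFID)
        np.testing.assert_allclose(back.points, fid.points, rtol=1e-9)
        assert back.sweep_width == fid.sweep_width

    def test_spectrum_round_trip_and_axis(self, tmp_path):
        spec = transform(_damped_sinusoid())
        path = write_jcamp(spec, tmp_path / "spec.jdx")
        back = read_jcamp(path)
        assert isinstance(back, Spectrum)
        assert back.ppm_axis[0] == pytest.approx(spec.ppm_axis[0])
        assert back.ppm_axis[-1] == pytest.approx(spec.ppm_axis[-1])
        np.testing.assert_allclose(back.real, spec.real, rtol=1e-9, atol=1e-9)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.jdx"
        p.write_text("")
        with pytest.raises(InputError):
            read_jcamp(p)

    def test_asdf_compression_rejected(self, tmp_path):
        p = tmp_path / "asdf.jdx"
        p.write_text(
            "##TITLE= t\n##DATA TYPE= NMR SPECTRUM\n##FIRSTX= 10\n##LASTX= 0\n"
            "##NPOINTS= 6\n##XUNITS= PPM\n##XYDATA= (X++(Y..Y))\n"
            "10 A123J45K21\n##END=\n"
        )
        with pytest.raises(UnsupportedFormatError):
            read_jcamp(p)


class TestTransform:
    def test_single_sinusoid_lands_at_expected_ppm(self):
        fid = _damped_sinusoid(f_hz=200.0)
        spec = transform(fid, line_broadening=0.0)
        peak_ppm = spec.ppm_axis[np.argmax(spec.real)]
        expected = 6.0 + 200.0 / 400.0  # carrier + offset
        assert abs(peak_ppm - expected) <= spec.ppm_per_point

    def test_zero_fid_gives_zero_spectrum(self):
        fid = RawFID(np.zeros(256, complex) + 0j, 400.0, 4800.0)
        # zero FID is allowed (non-empty array of zeros)
        spec = transform(fid)
        assert np.allclose(spec.intensity, 0)

    def test_zero_fill_consistency(self):
        fid = _damped_sinusoid(f_hz=137.0)
        p2 = transform(fid, zero_fill_factor=2)
        p4 = transform(fid, zero_fill_factor=4)
        ppm2 = p2.ppm_axis[np.argmax(p2.real)]
        ppm4 = p4.ppm_axis[np.argmax(p4.real)]
        assert abs(ppm2 - ppm4) <= 0.5 * p2.ppm_per_point

    def test_parseval_without_apodization(self):
        fid = _damped_sinusoid()
        spec = transform(fid, line_broadening=0.0, zero_fill_factor=1)
        # zero filling to the next power of two only; input is already 2^k
        power_t = np.sum(np.abs(fid.points) ** 2)
        power_f = np.sum(np.abs(spec.intensity) ** 2) / spec.n_points
        assert power_f == pytest.approx(power_t, rel=1e-10)

    def test_group_delay_removed(self):
        fid = _damped_sinusoid()
        shifted = RawFID(np.roll(fid.points, 7), fid.spectrometer_frequency,
                         fid.sweep_width, fid.frequency_offset, group_delay=7)
        a = transform(fid, line_broadening=0.0)
        b = transform(shifted, line_broadening=0.0)
        np.testing.assert_allclose(a.real, b.real, rtol=1e-9, atol=1e-9)

    def test_invariants_rejected(self):
        with pytest.raises(InputError):
            RawFID(np.array([]), 400.0, 4800.0)
        with pytest.raises(InputError):
            RawFID(np.ones(4), -1.0, 4800.0)
        with pytest.raises(InputError):
            Spectrum(np.ones(4), np.array([1.0, 2.0, 1.5, 0.5]))
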