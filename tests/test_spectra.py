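"""Spectrum I/O, validity filtering, loss features and tokenization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fluorospec import spectra
from fluorospec.spectra import Peak, SpectrumRecord


def make_record(precursor=499.0, ion_mode="negative", adduct="[M-H]-",
                ce=35.0, peaks=((100.0, 50.0), (200.0, 100.0)), **kw):
    return SpectrumRecord(
        precursor_mz=precursor, adduct=adduct, ion_mode=ion_mode,
        collision_energy=ce,
        peaks=tuple(Peak(mz=m, intensity=i) for m, i in peaks),
        source_id=kw.pop("source_id", "s1"), **kw)


class TestReadWrite:
    def test_mgf_round_trip(self, tmp_path):
        recs = [make_record(source_id="a"), make_record(precursor=321.4321,
                                                        source_id="b")]
        path = tmp_path / "x.mgf"
        spectra.write_spectra(recs, path)
        back = spectra.read_spectra(path)
        assert len(back) == 2
        for orig, rt in zip(recs, back):
            assert rt.precursor_mz == pytest.approx(orig.precursor_mz, abs=1e-4)
            assert rt.source_id == orig.source_id
            assert len(rt.peaks) == len(orig.peaks)
            for p, q in zip(orig.peaks, rt.peaks):
                assert q.mz == pytest.approx(p.mz, abs=1e-4)

    def test_msp_round_trip(self, tmp_path):
        recs = [make_record(source_id="a")]
        path = tmp_path / "x.msp"
        spectra.write_spectra(recs, path)
        back = spectra.read_spectra(path)
        assert len(back) == 1
        assert back[0].precursor_mz == pytest.approx(499.0, abs=1e-4)
        assert spectra.filter_spectrum(back[0]) is None

    def test_entry_without_precursor_skipped(self, tmp_path):
        path = tmp_path / "x.msp"
        path.write_text(
            "Name: good\nPrecursorMZ: 400.1\nNum Peaks: 1\n100.0 1.0\n\n"
            "Name: bad\nNum Peaks: 1\n100.0 1.0\n\n")
        back = spectra.read_spectra(path)
        assert len(back) == 1
        assert back[0].source_id == "good"

    def test_missing_file_and_empty_input(self, tmp_path):
        with pytest.raises(spectra.SpectraIOError):
            spectra.read_spectra(tmp_path / "nope.mgf")
        empty = tmp_path / "empty.mgf"
        empty.write_text("")
        with pytest.raises(spectra.EmptyInputError):
            spectra.read_spectra(empty)


class TestValidityFilter:
    def test_accept(self):
        assert spectra.filter_spectrum(make_record()) is None

    @pytest.mark.parametrize("kwargs,reason", [
        (dict(ce=60.0), "collision-energy"),
        (dict(ce=5.0), "collision-energy"),
        (dict(precursor=1200.0), "precursor-range"),
        (dict(ion_mode="positive"), "ion-mode"),
        (dict(adduct="[M+H]+"), "adduct"),
        (dict(ce=None), "missing-metadata"),
    ])
    def test_rejections(self, kwargs, reason):
        assert spectra.filter_spectrum(make_record(**kwargs)) == reason

    @pytest.mark.parametrize("ce", [10.0, 50.0])
    def test_collision_energy_bounds_inclusive(self, ce):
        assert spectra.filter_spectrum(make_record(ce=ce)) is None

    @pytest.mark.parametrize("adduct", ["[M-H]-", "[M-H]1-", "M-H", " [m-h]- "])
    def test_adduct_aliases(self, adduct):
        assert spectra.filter_spectrum(make_record(adduct=adduct)) is None

    def test_filter_is_order_independent(self):
        records = [make_record(ce=c, source_id=str(c))
                   for c in (5.0, 35.0, 60.0, 20.0)]
        accepted = {r.source_id for r in records
                    if spectra.filter_spectrum(r) is None}
        accepted_rev = {r.source_id for r in reversed(records)
                        if spectra.filter_spectrum(r) is None}
        assert accepted == accepted_rev == {"35.0", "20.0"}


class TestNormalize:
    def test_scaling(self):
        out = spectra.normalize_intensities(
            [Peak(100, 50.0), Peak(200, 100.0)])
        assert [p.intensity for p in out] == [0.5, 1.0]

    def test_single_and_tied_peaks(self):
        assert spectra.normalize_intensities([Peak(10, 7.0)])[0].intensity == 1.0
        out = spectra.normalize_intensities([Peak(100, 2.0), Peak(150, 2.0)])
        assert [p.intensity for p in out] == [1.0, 1.0]

    def test_errors(self):
        with pytest.raises(spectra.EmptyInputError):
            spectra.normalize_intensities([])
        with pytest.raises(spectra.DegenerateSpectrumError):
            spectra.normalize_intensities([Peak(100, 0.0)])


class TestLossFeatures:
    def test_losses_appended(self):
        rec = make_record(precursor=200.0,
                          peaks=((50.0, 0.5), (120.0, 1.0)))
        out = spectra.add_loss_features(rec)
        assert [(p.mz, p.intensity) for p in out.loss_peaks] \
            == [(80.0, 1.0), (150.0, 0.5)]
        assert out.fragment_peaks == rec.peaks

    def test_zero_mz_loss_dropped(self):
        rec = make_record(precursor=200.0, peaks=((200.0, 1.0), (50.0, 0.2)))
        out = spectra.add_loss_features(rec)
        assert len(out.loss_peaks) == 1
        assert out.loss_peaks[0].mz == pytest.approx(150.0)

    def test_conservation_and_count_bound(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 20))
            precursor = float(rng.uniform(100, 999))
            mzs = rng.uniform(10, precursor - 1, size=n)
            rec = make_record(precursor=precursor,
                              peaks=[(float(m), float(rng.uniform(0.01, 1)))
                                     for m in mzs])
            out = spectra.add_loss_features(rec)
            assert len(out.loss_peaks) <= len(out.fragment_peaks)
            frag_mzs = sorted(p.mz for p in out.fragment_peaks)
            for lp in out.loss_peaks:
                assert any(abs(lp.mz + f - precursor) < 0.005 for f in frag_mzs)


class TestTokenization:
    @pytest.mark.parametrize("mz,token", [
        (118.9925, 11899),
        (50.005, 5001),   # half away from zero
        (1000.0, 100000),
    ])
    def test_token_examples(self, mz, token):
        assert spectra.mz_to_token(mz) == token

    def test_out_of_range(self):
        with pytest.raises(spectra.MzRangeError):
            spectra.mz_to_token(1000.01)

    @settings(derandomize=True, max_examples=300)
    @given(st.floats(min_value=1e-3, max_value=999.99, allow_nan=False))
    def test_bijectivity_property(self, mz):
        token = spectra.mz_to_token(mz)
        assert spectra.token_to_mz(token) == pytest.approx(round(mz, 2), abs=5e-3)

    def test_ordering_fragments_then_losses(self):
        rec = make_record(precursor=300.0,
                          peaks=((120.0, 1.0), (50.0, 0.4), (220.0, 0.2)))
        rec = spectra.add_loss_features(rec)
        ts = spectra.tokenize_spectrum(rec)
        frags = [t for t, f in zip(ts.tokens, ts.segment_flags) if f == "fragment"]
        losses = [t for t, f in zip(ts.tokens, ts.segment_flags) if f == "loss"]
        assert frags == sorted(frags) == [5000, 12000, 22000]
        assert losses == sorted(losses) == [8000, 18000, 25000]

    def test_peak_cap_keeps_most_intense(self):
        rec = make_record(precursor=600.0,
                          peaks=[(float(10 + i), 1.0 / (i + 1)) for i in range(30)])
        rec = spectra.add_loss_features(rec)
        ts = spectra.tokenize_spectrum(rec, max_peaks=5)
        frags = [t for t, f in zip(ts.tokens, ts.segment_flags) if f == "fragment"]
        assert frags == [1000, 1100, 1200, 1300, 1400]
        # losses correspond only to surviving fragments
        assert sum(f == "loss" for f in ts.segment_flags) == 5

    def test_deterministic(self):
        rec = spectra.add_loss_features(
            make_record(precursor=300.0, peaks=((120.0, 1.0), (50.0, 0.4))))
        assert spectra.tokenize_spectrum(rec) == spectra.tokenize_spectrum(rec)


class TestPpmMatching:
    @pytest.mark.parametrize("observed,theoretical,expected", [
        (500.0000, 500.0020, True),    # 4.0 ppm
        (500.0000, 500.0100, False),   # 20 ppm
        (500.0025, 500.0000, True),    # exactly 5.0 ppm, inclusive
    ])
    def test_examples(self, observed, theoretical, expected):
        assert spectra.match_precursor_ppm(observed, theoretical, 5) is expected

    def test_divides_by_theoretical(self):
        # asymmetric by construction: the tolerance window scales with the
        # theoretical mass passed second
        assert spectra.match_precursor_ppm(100.0004, 100.0, 5)
        with pytest.raises(ValueError):
            spectra.match_precursor_ppm(-1.0, 100.0)
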