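"""mzML/MSP/manifest/feature-table I/O round trips and error contracts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gcnts.msdata import (
    EI,
    LibrarySpectrum,
    MSPError,
    MzMLError,
    Run,
    SampleMeta,
    Spectrum,
    load_library,
    load_run,
    meta_from_row,
    read_feature_table,
    read_manifest,
    save_library,
    write_feature_table,
    write_manifest,
    write_run,
)
from gcnts.simulate import default_foodweb_spec, generate_run

from conftest import make_run


class TestSpectrumAndRun:
    def test_spectrum_invariants_enforced(self):
        with pytest.raises(ValueError, match="ascending"):
            Spectrum(rt=1.0, mz=[100.0, 99.0], intensity=[1.0, 1.0])
        with pytest.raises(ValueError, match=">= 0"):
            Spectrum(rt=1.0, mz=[100.0, 101.0], intensity=[1.0, -1.0])
        with pytest.raises(ValueError, match="rt"):
            Spectrum(rt=-0.5, mz=[100.0], intensity=[1.0])
        with pytest.raises(ValueError, match="equal length"):
            Spectrum(rt=1.0, mz=[100.0, 101.0], intensity=[1.0])

    def test_empty_run_rejected(self):
        meta = SampleMeta("T", "x", "x", "benthic_fish", 1, 1, 1.0)
        with pytest.raises(ValueError, match="no spectra"):
            Run([], meta)

    def test_sample_meta_validation(self):
        with pytest.raises(ValueError, match="fraction_id"):
            SampleMeta("T", "x", "x", "benthic_fish", 1, 4, 1.0)
        with pytest.raises(ValueError, match="lipid"):
            SampleMeta("T", "x", "x", "benthic_fish", 1, 1, 0.0)
        with pytest.raises(ValueError, match="trophic role"):
            SampleMeta("T", "x", "x", "apex_shark", 1, 1, 1.0)


class TestMzML:
    def test_round_trip_bit_identical(self, tmp_path):
        """write_run → load_run reproduces every m/z and intensity array exactly."""
        rng = np.random.default_rng(7)
        spectra = []
        for i in range(20):
            mz = np.sort(rng.uniform(50, 450, rng.integers(3, 30)))
            inten = rng.exponential(500, mz.size).astype(np.float32)
            spectra.append((i / 60.0, mz.tolist(), inten.tolist()))
        run = make_run(spectra)
        path = tmp_path / "run.mzML"
        write_run(run, path)
        back = load_run(path, run.sample_meta, mode=EI)
        assert len(back) == len(run)
        for a, b in zip(run.spectra, back.spectra):
            np.testing.assert_array_equal(a.mz, b.mz)
            np.testing.assert_array_equal(a.intensity, b.intensity)
            assert a.rt == pytest.approx(b.rt, abs=1e-9)

    def test_default_ei_run_has_expected_scan_count(self):
        """A 48-min run at 1 spectrum/s (2-min hold + 44-min ramp + 2-min hold)
        holds 2880 ± 1 spectra."""
        spec = default_foodweb_spec(1)
        template = next(s for s in spec.samples if s.code == "BM")
        run, _ = generate_run(spec, template, 1, 1, EI)
        assert abs(len(run) - 2880) <= 1

    def test_profile_mode_rejected(self, tmp_path):
        path = tmp_path / "profile.mzML"
        text = path.read_text if False else None  # noqa: F841
        run = make_run([(0.0, [100.0], [10.0])])
        write_run(run, path)
        patched = path.read_text().replace(
            'accession="MS:1000127" name="centroid spectrum"',
            'accession="MS:1000128" name="profile spectrum"',
        )
        path.write_text(patched)
        with pytest.raises(MzMLError, match="profile"):
            load_run(path, run.sample_meta)

    def test_malformed_mzml_names_spectrum(self, tmp_path):
        path = tmp_path / "bad.mzML"
        run = make_run([(0.0, [100.0], [10.0]), (1 / 60, [100.0], [12.0])])
        write_run(run, path)
        text = path.read_text()
        # corrupt the second spectrum's binary payload
        idx = text.rindex("<binary>")
        path.write_text(text[:idx] + "<binary>!!notbase64!!" + text[idx + 20 :])
        with pytest.raises(MzMLError, match="spectrum"):
            load_run(path, run.sample_meta)


class TestMSP:
    def test_round_trip(self, tmp_path, toy_library):
        path = tmp_path / "lib.msp"
        save_library(toy_library, path)
        back = load_library(path)
        assert [e.name for e in back] == [e.name for e in toy_library]
        for a, b in zip(toy_library, back):
            np.testing.assert_allclose(a.mz, b.mz, atol=1e-5)
            np.testing.assert_allclose(a.intensities, b.intensities, rtol=1e-4)
            assert a.rt == pytest.approx(b.rt, abs=1e-4)

    def test_base_peak_rescaled_to_999(self, tmp_path):
        path = tmp_path / "t.msp"
        path.write_text("Name: X\nNum Peaks: 2\n50.0 100\n77.0 40\n\n")
        (entry,) = load_library(path)
        assert max(i for _, i in entry.peaks) == pytest.approx(999.0)
        assert dict(entry.peaks)[77.0] == pytest.approx(999.0 * 0.4)

    def test_duplicate_names_preserved(self, tmp_path):
        path = tmp_path / "t.msp"
        path.write_text(
            "Name: A\nNum Peaks: 1\n50.0 100\n\nName: A\nNum Peaks: 1\n60.0 100\n\n"
        )
        entries = load_library(path)
        assert [e.name for e in entries] == ["A", "A"]

    def test_num_peaks_mismatch_names_entry(self, tmp_path):
        path = tmp_path / "t.msp"
        path.write_text("Name: Broken\nNum Peaks: 3\n50.0 100\n60.0 50\n\n")
        with pytest.raises(MSPError, match="Broken"):
            load_library(path)

    def test_entry_without_peaks_rejected(self):
        with pytest.raises(ValueError, match="no peaks"):
            LibrarySpectrum(name="X", peaks=[])


class TestFeatureTable:
    def test_empty_table_header_only(self, tmp_path):
        path = tmp_path / "f.csv"
        write_feature_table(pd.DataFrame(), path)
        df = read_feature_table(path)
        assert len(df) == 0
        assert "area_per_g_lipid" in df.columns

    def test_round_trip_numeric(self, tmp_path):
        table = pd.DataFrame(
            {
                "name": ["A", "B"],
                "rt_min": [1.234567891, 2.0],
                "lri": [1100.0, 1200.0],
                "sample_code": ["EM", "EM"],
                "replicate_id": [1, 1],
                "fraction_id": [1, 1],
                "area": [12345.6789, 0.000123456],
                "area_per_g_lipid": [1.0, 2.0],
                "ar": [0.5, 0.25],
                "qc_flags": ["", ""],
            }
        )
        path = tmp_path / "f.csv"
        write_feature_table(table, path)
        back = read_feature_table(path)
        np.testing.assert_allclose(back["area"], table["area"], rtol=1e-9)

    def test_equal_rt_ordered_by_name(self, tmp_path):
        table = pd.DataFrame(
            {
                "name": ["Zeta", "Alpha"],
                "rt_min": [1.0, 1.0],
                "sample_code": ["EM", "EM"],
                "replicate_id": [1, 1],
                "fraction_id": [1, 1],
                "area": [1.0, 2.0],
                "area_per_g_lipid": [1.0, 2.0],
            }
        )
        path = tmp_path / "f.csv"
        write_feature_table(table, path)
        back = read_feature_table(path)
        assert back["name"].tolist() == ["Alpha", "Zeta"]


class TestManifest:
    def test_round_trip_and_meta(self, tmp_path):
        rows = [
            {
                "run_file": "runs/EM_r1_f1_EI.mzML",
                "sample_code": "EM",
                "species": "eelpout",
                "tissue": "muscle",
                "trophic_role": "benthic_fish",
                "replicate_id": 1,
                "fraction_id": 1,
                "mode": "EI",
                "lipid_mass_g": 0.25,
                "is_blank": False,
            }
        ]
        path = tmp_path / "manifest.csv"
        write_manifest(rows, path)
        df = read_manifest(path)
        meta = meta_from_row(df.iloc[0])
        assert meta.sample_code == "EM"
        assert meta.lipid_mass_g == pytest.approx(0.25)
        assert not meta.is_blank

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"run_file": ["x"]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="missing columns"):
            read_manifest(path)
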