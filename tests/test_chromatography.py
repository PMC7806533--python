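"""EIC extraction, peak detection/integration, alignment and LRI."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gcnts.chromatography import (
    EIC,
    AlkaneLadder,
    ChromPeak,
    align_features,
    compute_lri,
    detect_peaks,
    extract_eic,
)
from gcnts.msdata import Run
from gcnts.simulate import generate_run

from conftest import gaussian_trace, make_run


class TestExtractEIC:
    def test_single_centroid_at_target(self):
        run = make_run([(0.0, [100.0], [100.0])])
        eic = extract_eic(run, 100.0, tol=0.005)
        np.testing.assert_array_equal(eic.intensity, [100.0])

    def test_centroid_outside_window(self):
        run = make_run([(0.0, [100.01], [100.0])])
        eic = extract_eic(run, 100.0, tol=0.005)
        np.testing.assert_array_equal(eic.intensity, [0.0])

    def test_tolerance_must_be_positive(self):
        run = make_run([(0.0, [100.0], [100.0])])
        with pytest.raises(ValueError):
            extract_eic(run, 100.0, tol=0.0)

    def test_conservation_against_brute_force(self):
        """EIC totals equal a direct per-spectrum sum of in-window centroids."""
        rng = np.random.default_rng(3)
        spectra = []
        for i in range(30):
            mz = np.sort(rng.uniform(50, 110, 15))
            inten = rng.exponential(100, 15)
            spectra.append((i / 60.0, mz.tolist(), inten.tolist()))
        run = make_run(spectra)
        for target in (60.0, 75.5, 99.9):
            for tol in (0.005, 0.5, 5.0):
                eic = extract_eic(run, target, tol=tol)
                brute = np.array(
                    [
                        float(
                            s.intensity[np.abs(s.mz - target) <= tol]
                            .astype(np.float64)
                            .sum()
                        )
                        for s in run.spectra
                    ]
                )
                np.testing.assert_allclose(eic.intensity, brute, rtol=1e-12)

    def test_channel_fast_path_equals_generic(self, mini_spec):
        """Synthetic runs carry a channel cache; it must agree with the
        per-spectrum representation exactly."""
        template = next(s for s in mini_spec.samples if s.code == "EM")
        run, _ = generate_run(mini_spec, template, 1, 1, "EI")
        generic = Run(run.spectra, run.sample_meta, mode=run.mode)
        centers = run.channels[0]
        for target in list(centers[:3]) + [centers[0] + 0.004, 77.7]:
            fast = extract_eic(run, float(target), tol=0.005).intensity
            slow = extract_eic(generic, float(target), tol=0.005).intensity
            np.testing.assert_allclose(fast, slow, rtol=0, atol=1e-9)


class TestDetectPeaks:
    def test_all_zero_trace_empty(self):
        eic = EIC(100.0, 0.005, np.arange(10) / 60.0, np.zeros(10))
        assert detect_peaks(eic) == []

    def test_too_short_trace_rejected(self):
        eic = EIC(100.0, 0.005, np.arange(3) / 60.0, np.ones(3))
        with pytest.raises(ValueError, match="5 points"):
            detect_peaks(eic)

    def test_noiseless_gaussian_single_peak(self):
        rt, y = gaussian_trace(area=5.0e4)
        peaks = detect_peaks(EIC(100.0, 0.005, rt, y))
        assert len(peaks) == 1
        p = peaks[0]
        assert p.rt_apex == pytest.approx(300.0 / 60.0, abs=1.01 / 60.0)
        assert p.snr == np.inf

    def test_gaussian_area_within_half_percent(self):
        """Trapezoidal area of a 1 Hz-sampled σ = 2 s Gaussian is within 0.5%
        of the analytic area, across sampling phases."""
        for shift in (0.0, 0.3, 0.5, 0.77):
            rt, y = gaussian_trace(center_s=300.0 + shift, area=5.0e4)
            (p,) = detect_peaks(EIC(100.0, 0.005, rt, y))
            assert p.area == pytest.approx(5.0e4, rel=5e-3)

    def test_two_resolved_gaussians(self):
        rt1, y1 = gaussian_trace(center_s=200.0, area=2.0e4)
        _, y2 = gaussian_trace(center_s=400.0, area=4.0e4)
        peaks = detect_peaks(EIC(100.0, 0.005, rt1, y1 + y2))
        assert len(peaks) == 2
        assert peaks[0].rt_apex < peaks[1].rt_apex
        assert peaks[0].area == pytest.approx(2.0e4, rel=5e-3)
        assert peaks[1].area == pytest.approx(4.0e4, rel=5e-3)

    def test_snr_gate_separates_weak_from_clear_peaks(self):
        """A peak built at S/N 2 is rejected and the same peak at S/N 5 is
        detected, consistently (≥ 90% of 50 noise seeds each)."""
        noise_sd, floor = 20.0, 60.0
        outcomes = {2: 0, 5: 0}
        for snr_level in outcomes:
            height = snr_level * noise_sd
            area = height * 2.0 * np.sqrt(2 * np.pi)
            for seed in range(50):
                rt, y = gaussian_trace(
                    area=area, noise_sd=noise_sd, noise_floor=floor, seed=seed
                )
                peaks = [
                    p
                    for p in detect_peaks(EIC(100.0, 0.005, rt, y), snr_min=3.0)
                    if abs(p.rt_apex - 5.0) < 0.1
                ]
                detected = len(peaks) > 0
                if (snr_level == 5 and detected) or (snr_level == 2 and not detected):
                    outcomes[snr_level] += 1
        assert outcomes[5] >= 45  # ≥ 90% detected
        assert outcomes[2] >= 45  # ≥ 90% rejected

    def test_pure_noise_trace_yields_nothing(self):
        rng = np.random.default_rng(11)
        for seed in range(10):
            rt = np.arange(1200) / 60.0
            y = np.clip(np.random.default_rng(seed).normal(60, 20, 1200), 0, None)
            assert detect_peaks(EIC(100.0, 0.005, rt, y), snr_min=3.0) == []
        del rng


def _peak(rt: float, area: float = 1.0) -> ChromPeak:
    return ChromPeak(rt_apex=rt, rt_start=rt - 0.01, rt_end=rt + 0.01,
                     area=area, height=area, snr=10.0)


class TestAlignFeatures:
    def test_identical_rt_lists_one_feature_per_rt(self):
        lists = {s: [_peak(1.0), _peak(2.0)] for s in ("a", "b", "c")}
        feats = align_features(lists, rt_tol=0.05)
        assert len(feats) == 2
        for f in feats:
            assert all(f["areas"][s] > 0 for s in ("a", "b", "c"))

    def test_shift_of_half_tolerance_still_one_feature(self):
        lists = {"a": [_peak(1.0)], "b": [_peak(1.025)]}
        assert len(align_features(lists, rt_tol=0.05)) == 1

    def test_two_tolerances_apart_two_features(self):
        lists = {"a": [_peak(1.0)], "b": [_peak(1.1)]}
        feats = align_features(lists, rt_tol=0.05)
        assert len(feats) == 2
        # absent sample recorded with zero area
        assert feats[0]["areas"]["b"] == 0.0
        assert feats[1]["areas"]["a"] == 0.0

    def test_partition_every_peak_in_exactly_one_feature(self):
        rng = np.random.default_rng(5)
        lists = {
            s: sorted([_peak(float(rt)) for rt in rng.uniform(0, 30, 40)],
                      key=lambda p: p.rt_apex)
            for s in ("a", "b", "c")
        }
        feats = align_features(lists, rt_tol=0.05)
        n_in = sum(len(v) for v in lists.values())
        n_grouped = 0
        for f in feats:
            for sample, peak in f["peaks"].items():
                assert peak in lists[sample]
                n_grouped += 1
        # every peak lands in exactly one group (same-sample collisions keep
        # the larger peak as representative but still consume the group slot)
        assert n_grouped <= n_in
        all_assigned = {
            (s, p.rt_apex) for f in feats for s, p in f["peaks"].items()
        }
        assert len(all_assigned) == len(set(all_assigned))


LADDER = AlkaneLadder([(n, 4.0 + 1.75 * (n - 6)) for n in range(6, 31)])


class TestComputeLRI:
    def test_exact_on_ladder_point(self):
        rt_c12 = dict(LADDER.entries)[12]
        assert compute_lri(rt_c12, LADDER) == pytest.approx(1200.0)

    def test_midpoint_is_1250(self):
        rt = (dict(LADDER.entries)[12] + dict(LADDER.entries)[13]) / 2
        assert compute_lri(rt, LADDER) == pytest.approx(1250.0)

    def test_worked_two_alkane_example(self):
        ladder = AlkaneLadder([(11, 10.0), (12, 12.0)])
        assert compute_lri(11.5, ladder) == pytest.approx(1175.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside ladder"):
            compute_lri(0.5, LADDER)

    @given(st.floats(min_value=4.0, max_value=46.0))
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing_in_rt(self, rt):
        eps = 0.01
        if rt + eps <= 46.0:
            assert compute_lri(rt + eps, LADDER) > compute_lri(rt, LADDER)

    def test_ladder_validation(self):
        with pytest.raises(ValueError):
            AlkaneLadder([(12, 10.0)])
        with pytest.raises(ValueError):
            AlkaneLadder([(11, 10.0), (12, 9.0)])
        with pytest.raises(ValueError, match=">= 5"):
            AlkaneLadder([(3, 1.0), (4, 2.0)])

    def test_csv_round_trip(self, tmp_path):
        path = tmp_path / "ladder.csv"
        LADDER.to_csv(path)
        back = AlkaneLadder.from_csv(path)
        assert back.entries == LADDER.entries
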