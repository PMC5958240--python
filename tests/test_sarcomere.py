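"""Line-scan segmentation, aligned averaging and peak metrics."""

import numpy as np
import pandas as pd
import pytest

from myotail import sarcomere as sc
from myotail import synthetic as syn


def symmetric_profile(peak=2.0, minimum=1.0, sep=0.70, half=0.925, dx=0.065):
    """Toy aligned profile: two Gaussian peaks of known height at ±sep/2."""
    x = np.arange(-half, half + dx / 2, dx)
    y = np.full_like(x, minimum)
    for s in (-1, 1):
        y += (peak - minimum) * np.exp(-(((x - s * sep / 2) / 0.10) ** 2) / 2)
    return sc.SarcomereProfile(x, y, n_sarcomeres=1, n_myofibrils=1)


class TestSegmentation:
    def test_five_sarcomere_scan_yields_expected_windows(self):
        scans, truth = syn.gen_linescans(n_myofibrils=1, n_sarcomeres=5, seed=0)
        windows = sc.segment_sarcomeres(scans[0])
        assert 4 <= len(windows) <= 6
        # each window spans roughly one sarcomere
        for w in windows:
            extent = w.offsets_um[-1] - w.offsets_um[0]
            assert extent == pytest.approx(truth["sarcomere_length_um"], rel=0.1)

    def test_flat_profile_errors(self):
        scan = sc.LineScan(np.arange(100) * 0.065, np.ones(100))
        with pytest.raises(sc.SegmentationError):
            sc.segment_sarcomeres(scan)

    def test_start_shift_changes_window_count_by_at_most_one(self):
        scans, _ = syn.gen_linescans(n_myofibrils=1, n_sarcomeres=5, noise_sd=0.0, seed=1)
        scan = scans[0]
        n_full = len(sc.segment_sarcomeres(scan))
        shifted = sc.LineScan(scan.positions_um[:-9], scan.intensity[9:], "mf")
        n_shift = len(sc.segment_sarcomeres(shifted))
        assert abs(n_full - n_shift) <= 1

    def test_nonuniform_sampling_rejected(self):
        x = np.array([0.0, 0.1, 0.3])
        with pytest.raises(ValueError, match="uniform"):
            sc.LineScan(x, np.zeros(3))


class TestAlignAverage:
    def test_identical_windows_average_to_one_window(self):
        scans, _ = syn.gen_linescans(n_myofibrils=1, n_sarcomeres=5, noise_sd=0.0, seed=2)
        windows = sc.segment_sarcomeres(scans[0])
        profile = sc.align_average([windows[1], windows[1]])
        aligned = sc._align_to_grid(windows[1], profile.offsets_um)
        assert np.allclose(profile.mean_intensity, aligned)

    def test_offset_windows_align_minimum_to_zero(self):
        scans, _ = syn.gen_linescans(n_myofibrils=2, n_sarcomeres=5, noise_sd=0.0, seed=3)
        windows = [w for s in scans for w in sc.segment_sarcomeres(s)]
        # shift one window's offsets by one sample: alignment must undo it
        w = windows[0]
        shifted = sc.SarcomereWindow(w.offsets_um + w.offsets_um[1] - w.offsets_um[0],
                                     w.intensity, w.myofibril_id)
        profile = sc.align_average([w, shifted])
        x, y = profile.offsets_um, profile.mean_intensity
        central = np.abs(x) <= 0.3
        assert abs(x[central][np.argmin(y[central])]) < 1e-9

    def test_recovered_profile_within_noise_envelope(self):
        scans, truth = syn.gen_linescans(n_myofibrils=6, n_sarcomeres=5, seed=4)
        windows = [w for s in scans for w in sc.segment_sarcomeres(s)]
        profile = sc.align_average(windows)
        x = profile.offsets_um
        m = truth["m_line_amplitude"]
        expected = truth["baseline"] + m * np.exp(-((x / 0.20) ** 2) / 2)
        for s in (-1, 1):
            expected += truth["peak_amplitude"] * np.exp(
                -(((x - s * truth["peak_separation_um"] / 2) / 0.13) ** 2) / 2
            )
        inner = np.abs(x) < 0.8
        tol = 5 * truth["noise_sd"] / np.sqrt(profile.n_sarcomeres) + 0.05
        assert np.max(np.abs(profile.mean_intensity[inner] - expected[inner])) < 0.12

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            sc.align_average([])

    def test_pooled_level_available_but_distinct(self):
        scans, _ = syn.gen_linescans(n_myofibrils=3, n_sarcomeres=4, seed=5)
        windows = [w for s in scans for w in sc.segment_sarcomeres(s)]
        hierarchical = sc.align_average(windows, level="myofibril")
        pooled = sc.align_average(windows, level="pooled")
        assert hierarchical.metadata["level"] == "myofibril"
        assert pooled.metadata["level"] == "pooled"


class TestProfileMetrics:
    def test_symmetric_toy_profile(self):
        metrics = sc.profile_metrics(symmetric_profile())
        assert metrics["peak_to_min_ratio"] == pytest.approx(2.0, abs=0.02)
        assert metrics["peak_peak_distance_um"] == pytest.approx(0.70, abs=0.07)
        assert metrics["mean_peak_value"] == pytest.approx(2.0, abs=0.02)

    def test_constant_offset_changes_ratio_predictably(self):
        base = sc.profile_metrics(symmetric_profile())
        shifted_profile = symmetric_profile()
        shifted_profile.mean_intensity = shifted_profile.mean_intensity + 1.0
        shifted = sc.profile_metrics(shifted_profile)
        p, m = base["mean_peak_value"], base["min_value"]
        assert shifted["peak_to_min_ratio"] == pytest.approx((p + 1) / (m + 1), abs=0.02)

    def test_intensity_scaling_leaves_ratio(self):
        prof = symmetric_profile()
        scaled = sc.SarcomereProfile(prof.offsets_um, 7.5 * prof.mean_intensity, 1, 1)
        assert sc.profile_metrics(scaled)["peak_to_min_ratio"] == pytest.approx(
            sc.profile_metrics(prof)["peak_to_min_ratio"]
        )

    def test_near_zero_minimum_capped(self):
        prof = symmetric_profile(minimum=0.0)
        prof.mean_intensity[np.argmin(np.abs(prof.offsets_um))] = 0.0
        metrics = sc.profile_metrics(prof)
        assert metrics["capped"]

    def test_peak_separation_recovery_within_one_pixel(self):
        """Closed loop with the generator at high SNR (weak M-line term)."""
        scans, truth = syn.gen_linescans(
            n_myofibrils=4, n_sarcomeres=5, m_line_amplitude=0.0, noise_sd=0.01, seed=6
        )
        windows = [w for s in scans for w in sc.segment_sarcomeres(s)]
        metrics = sc.profile_metrics(sc.align_average(windows))
        assert abs(
            metrics["peak_peak_distance_um"] - truth["peak_separation_um"]
        ) <= truth["pixel_size_um"]


class TestGroupComparison:
    @staticmethod
    def _group_metrics(scenario, seed):
        scans, _ = syn.gen_linescans_for_scenario(scenario, seed=seed)
        rows = []
        for scan in scans:
            prof = sc.align_average(sc.segment_sarcomeres(scan))
            m = sc.profile_metrics(prof)
            rows.append({"group": scenario, "peak_to_min_ratio": m["peak_to_min_ratio"]})
        return pd.DataFrame(rows)

    def test_mutant_ratio_significantly_lower(self):
        df = pd.concat([self._group_metrics("WT", 7), self._group_metrics("K1617del", 7)])
        out = sc.compare_profile_groups(df)
        row = out[(out["group"] == "K1617del") & (out["metric"] == "peak_to_min_ratio")].iloc[0]
        assert row["mean"] < row["ref_mean"]
        assert row["p_vs_ref"] < 0.05

    def test_identical_groups_not_significant(self):
        a = self._group_metrics("WT", 8)
        b = a.copy()
        b["group"] = "MUT"
        out = sc.compare_profile_groups(pd.concat([a, b]))
        assert out.iloc[0]["p_vs_ref"] > 0.9

    def test_single_myofibril_group_rejected(self):
        df = pd.DataFrame(
            {"group": ["WT", "WT", "MUT"], "peak_to_min_ratio": [1.5, 1.6, 1.2]}
        )
        with pytest.raises(ValueError, match="myofibril"):
            sc.compare_profile_groups(df)
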