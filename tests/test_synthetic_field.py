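"""Trial generation, scene rendering, yield streams, and GeoTIFF round-trip."""

import numpy as np
import pandas as pd
import pytest

from aonrvi.config import SimConfig, TrialSpec, default_study_design
from aonrvi.io import read_scene_geotiff, write_scene_geotiff
from aonrvi.synthetic_field import (
    canopy_fraction,
    generate_trial,
    generate_yield_points,
    mixture_reflectance,
    plateau_response,
    render_scene,
    transect_yield_table,
)
from aonrvi.vi_core import compute_vi, rescale_reflectance, zonal_vi_table


def zero_noise(cfg: SimConfig) -> SimConfig:
    return cfg.with_(
        noise_sd_reflectance=0.0, noise_sd_yield=0.0, artifact_fraction=0.0
    )


class TestGenerateTrial:
    def test_subplot_count_is_transects_times_treatments(self, mini_config):
        design, _ = generate_trial(mini_config, 0)
        assert len(design.subplots) == 3 * 5
        design.validate()  # every transect holds every treatment exactly once

    def test_paper_design_has_forty_subplots_per_trial(self):
        cfg = default_study_design(seed=0)
        for i in range(3):
            design, _ = generate_trial(cfg, i)
            assert len(design.subplots) == 8 * 5
            assert len(design.transect_ids) == 8

    def test_deterministic_under_seed(self, mini_config):
        d1, t1 = generate_trial(mini_config, 0)
        d2, t2 = generate_trial(mini_config, 0)
        assert d1 == d2
        assert t1.aonr == t2.aonr
        assert t1.expected_yield == t2.expected_yield
        s1 = render_scene(d1, t1, 1, mini_config)
        s2 = render_scene(d2, t2, 1, mini_config)
        assert np.array_equal(s1.nir, s2.nir)
        p1 = generate_yield_points(d1, t1, mini_config)
        p2 = generate_yield_points(d2, t2, mini_config)
        pd.testing.assert_frame_equal(p1, p2)

    def test_different_seeds_differ(self, mini_config):
        _, t1 = generate_trial(mini_config, 0)
        _, t2 = generate_trial(mini_config.with_(seed=43), 0)
        assert t1.aonr != t2.aonr

    def test_true_aonr_truncated_to_tested_range(self):
        cfg = default_study_design(seed=9, aonr_mean=300.0, aonr_sd=80.0)
        _, truth = generate_trial(cfg, 0)
        max_rate = cfg.trials[0].max_n_rate
        assert all(0 < a <= max_rate for a in truth.aonr.values())

    def test_plateau_yield_structure(self, mini_config):
        """Expected yield rises with N up to the transect AONR, flat beyond."""
        design, truth = generate_trial(zero_noise(mini_config), 0)
        for tid in design.transect_ids:
            subs = sorted(
                (s for s in design.subplots if s.transect_id == tid),
                key=lambda s: s.n_rate,
            )
            ys = [truth.expected_yield[s.subplot_id] for s in subs]
            assert all(b >= a - 1e-12 for a, b in zip(ys, ys[1:]))
            top = [
                truth.expected_yield[s.subplot_id]
                for s in subs
                if s.n_rate >= truth.aonr[tid]
            ]
            assert all(t == pytest.approx(truth.plateau_yield[tid]) for t in top)

    def test_refitting_zero_noise_yield_recovers_aonr(self, mini_config):
        from aonrvi.response_models import fit_and_screen

        cfg = zero_noise(mini_config)
        design, truth = generate_trial(cfg, 0)
        for tid in design.transect_ids:
            subs = [s for s in design.subplots if s.transect_id == tid]
            x = np.array([s.n_rate for s in subs])
            y = np.array([truth.expected_yield[s.subplot_id] for s in subs])
            d = fit_and_screen(x, y, design.max_n_rate)
            assert d.aonr == pytest.approx(truth.aonr[tid], abs=0.5)

    def test_too_few_distinct_rates_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            TrialSpec(
                "bad", 100.0, (("a", 50.0), ("b", 50.0), ("c", 100.0))
            ).validate()

    def test_out_of_range_trial_index(self, mini_config):
        with pytest.raises(IndexError):
            generate_trial(mini_config, 99)

    def test_canopy_fraction_nondecreasing_in_timing(self, mini_config):
        for n in (40.0, 140.0, 260.0):
            fs = [
                canopy_fraction(mini_config, n, 180.0, t) for t in (1, 2, 3, 4)
            ]
            assert all(b >= a for a, b in zip(fs, fs[1:]))
            assert all(0.0 <= f <= 1.0 for f in fs)


class TestPlateauResponse:
    def test_families_hit_anchor_points(self):
        for fam in ("quadratic_plateau", "linear_plateau"):
            assert plateau_response(0.0, fam, 5.0, 12.0, 150.0) == pytest.approx(5.0)
            assert plateau_response(150.0, fam, 5.0, 12.0, 150.0) == pytest.approx(12.0)
            assert plateau_response(280.0, fam, 5.0, 12.0, 150.0) == pytest.approx(12.0)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            plateau_response(10.0, "cubic", 5.0, 12.0, 150.0)


class TestRenderScene:
    def test_full_canopy_zero_noise_gives_canopy_endmember(self, mini_config):
        cfg = zero_noise(mini_config).with_(
            canopy_logistic_rate=100.0, canopy_logistic_midpoint=-10.0,
            canopy_gamma=0.0,
        )  # forces f = 1 in every subplot
        design, truth = generate_trial(cfg, 0)
        assert all(
            f == pytest.approx(1.0)
            for (sid, t), f in truth.canopy_fraction.items()
            if t == 1
        )
        scene = render_scene(design, truth, 1, cfg)
        rows, cols = truth.zone_pixels[design.subplots[0].subplot_id]
        assert np.all(
            scene.nir[rows, cols]
            == round(cfg.endmembers["canopy"]["nir"] * 10000)
        )

    def test_background_is_pure_residue_when_residue_fraction_one(self):
        trials = (
            TrialSpec(
                "R", 200.0,
                (("a", 50.0), ("b", 100.0), ("c", 150.0), ("d", 200.0)),
                residue_fraction=1.0, subplot_length_m=9.0, plot_width_m=6.0,
            ),
        )
        cfg = SimConfig(trials=trials, transects_per_trial=2, seed=1,
                        noise_sd_reflectance=0.0)
        design, truth = generate_trial(cfg, 0)
        scene = render_scene(design, truth, 1, cfg)
        # corner pixel is outside every subplot -> f = 0 background
        assert scene.red[0, 0] == round(cfg.endmembers["residue"]["red"] * 10000)

    def test_unknown_timing_rejected(self, mini_trial, mini_config):
        design, truth = mini_trial
        with pytest.raises(ValueError):
            render_scene(design, truth, 99, mini_config)

    def test_ndvi_strictly_increasing_in_canopy_fraction(self, mini_config):
        """Brute-force over f in {0, 0.1, ..., 1}: with canopy NIR above and
        canopy red below the background, mixture NDVI rises with f."""
        trial = mini_config.trials[0]
        fs = np.linspace(0.0, 1.0, 11)
        nir = np.array([mixture_reflectance(mini_config, trial, f, "nir") for f in fs])
        red = np.array([mixture_reflectance(mini_config, trial, f, "red") for f in fs])
        ndvi = (nir - red) / (nir + red)
        assert np.all(np.diff(ndvi) > 0)

    def test_mean_subplot_ndvi_nondecreasing_in_n(self, mini_config):
        cfg = zero_noise(mini_config)
        design, truth = generate_trial(cfg, 0)
        zones = truth.zone_table(design)
        for timing in (1, 2, 3):
            zt = zonal_vi_table(
                render_scene(design, truth, timing, cfg), zones, vis=("NDVI",)
            )
            for tid in design.transect_ids:
                sub = zt[zt.transect_id == tid].sort_values("n_rate")
                vals = sub["mean_value"].to_numpy()
                assert np.all(np.diff(vals) >= -1e-12)

    def test_quantization_toggle(self, mini_trial, mini_config):
        design, truth = mini_trial
        q = render_scene(design, truth, 1, mini_config)
        assert q.nir.dtype == np.uint16
        fcfg = mini_config.with_(quantize_scenes=False)
        d2, t2 = generate_trial(fcfg, 0)
        f = render_scene(d2, t2, 1, fcfg)
        assert f.nir.dtype == np.float64
        assert np.allclose(q.nir, f.nir, atol=0.5 + 1e-9)


class TestGeoTiffRoundTrip:
    def test_pixel_values_and_georeferencing_survive(self, tmp_path, mini_trial,
                                                     mini_config):
        design, truth = mini_trial
        scene = render_scene(design, truth, 2, mini_config)
        path = tmp_path / "scene.tif"
        write_scene_geotiff(scene, path)
        back = read_scene_geotiff(path)
        for band in ("blue", "green", "red", "nir"):
            assert np.array_equal(scene.band(band), back.band(band))
        assert back.timing == 2
        assert back.stage == scene.stage
        assert back.pixel_size_m == mini_config.pixel_size_m
        assert back.trial_id == design.trial_id

    def test_rescaled_scene_rejected_by_writer(self, tmp_path, mini_trial,
                                               mini_config):
        design, truth = mini_trial
        scene = rescale_reflectance(render_scene(design, truth, 1, mini_config))
        with pytest.raises(ValueError):
            write_scene_geotiff(scene, tmp_path / "x.tif")


class TestYieldPoints:
    def test_zero_noise_mean_equals_expected(self, mini_config):
        cfg = zero_noise(mini_config)
        design, truth = generate_trial(cfg, 0)
        pts = generate_yield_points(design, truth, cfg)
        tab = transect_yield_table(pts, design)
        for rec in tab.itertuples():
            assert rec.adjusted_yield == pytest.approx(
                truth.expected_yield[rec.subplot_id], abs=1e-9
            )

    def test_injected_moisture_label_matches_value(self, mini_config):
        design, truth = generate_trial(mini_config, 0)
        pts = generate_yield_points(design, truth, mini_config)
        low = pts[pts.artifact == "moisture_low"]
        high = pts[pts.artifact == "moisture_high"]
        assert (low.moisture_pct < 10).all()
        assert (high.moisture_pct > 33).all()

    def test_artifact_fraction_zero_injects_nothing(self, mini_config):
        cfg = mini_config.with_(artifact_fraction=0.0)
        design, truth = generate_trial(cfg, 0)
        pts = generate_yield_points(design, truth, cfg)
        assert (pts.artifact == "").all()

    def test_points_sorted_within_pass(self, mini_config):
        design, truth = generate_trial(mini_config, 0)
        pts = generate_yield_points(design, truth, mini_config)
        for _, g in pts.groupby("pass_id"):
            assert g["seq"].is_monotonic_increasing

    def test_clean_speed_steps_below_jump_threshold(self, mini_config):
        cfg = mini_config.with_(artifact_fraction=0.0)
        design, truth = generate_trial(cfg, 0)
        pts = generate_yield_points(design, truth, cfg)
        for _, g in pts.groupby("pass_id"):
            v = g["speed_mph"].to_numpy()
            rel = np.abs(np.diff(v)) / v[:-1]
            assert np.all(rel <= 0.15)


class TestConfigValidation:
    def test_bad_endmember_rejected(self, mini_config):
        import copy

        cfg = copy.deepcopy(mini_config)
        cfg.endmembers["canopy"]["nir"] = 1.5
        with pytest.raises(ValueError, match="outside"):
            cfg.validate()

    def test_missing_band_rejected(self, mini_config):
        import copy

        cfg = copy.deepcopy(mini_config)
        del cfg.endmembers["soil"]["red"]
        with pytest.raises(ValueError, match="missing band"):
            cfg.validate()

    def test_negative_buffer_rejected(self, mini_config):
        with pytest.raises(ValueError, match="buffer"):
            mini_config.with_(buffer_adjacent_m=-1.0).validate()
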