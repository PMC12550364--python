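import numpy as np
import pandas as pd
import pytest

from coloct import phantom as ph
from coloct import quantification as qn
from coloct import reconstruction as rc
from coloct import segmentation as sg


class TestThicknessMap:
    def test_boundary_separation_in_physical_units(self):
        from dataclasses import replace

        g = replace(ph.default_phantom_geometry(n_bscans=2), refractive_index=1.0)
        wall = sg.WallMask(None, np.full((2, 5), 10), np.full((2, 5), 110))
        tmap = qn.thickness_map(wall, g)
        assert np.allclose(tmap, 100 * g.axial_pixel_pitch)

    def test_missing_alines_are_nan(self, geom):
        top = np.full((1, 4), 10)
        bottom = np.full((1, 4), 60)
        top[0, 2] = sg.SENTINEL
        tmap = qn.thickness_map(sg.WallMask(None, top, bottom), geom)
        assert np.isnan(tmap[0, 2]) and np.isfinite(tmap[0, 0])

    def test_phantom_recovery_within_two_samples(
        self, segmented_wall, volume_truth, geom
    ):
        _, truth = volume_truth
        tmap = qn.thickness_map(segmented_wall, geom)
        prof = qn.sample_thickness(tmap, geom, 10)
        mae = np.nanmean(np.abs(prof.thickness_um - truth.true_thickness_um[0, 0]))
        assert mae <= 2 * geom.axial_pixel_pitch / geom.refractive_index

    def test_invariant_to_flattening(self, segmented_wall, geom):
        """Thickness comes from boundaries, so flattening cannot change it."""
        tmap = qn.thickness_map(segmented_wall, geom)
        shifted = sg.WallMask(
            None,
            segmented_wall.top_boundary - segmented_wall.top_boundary,
            segmented_wall.bottom_boundary - segmented_wall.top_boundary,
        )
        assert np.allclose(
            qn.thickness_map(shifted, geom)[segmented_wall.valid],
            tmap[segmented_wall.valid],
            equal_nan=True,
        )


class TestSampleThickness:
    def test_uniform_map_gives_constant_profile(self, geom):
        tmap = np.full((20, 36), 380.0)
        prof = qn.sample_thickness(tmap, geom, 10)
        assert np.allclose(prof.thickness_um, 380.0)
        assert len(prof.positions_mm) == 10
        assert prof.positions_mm[0] == pytest.approx(0.6)  # first bin center, mm

    def test_single_location_is_global_median(self, geom, rng):
        tmap = rng.random((20, 36)) * 100
        prof = qn.sample_thickness(tmap, geom, 1)
        assert prof.thickness_um[0] == pytest.approx(np.median(tmap))

    def test_gradient_gives_monotone_profile(self, geom):
        tmap = np.linspace(100, 500, 20)[:, None] * np.ones((1, 36))
        prof = qn.sample_thickness(tmap, geom, 10)
        assert np.all(np.diff(prof.thickness_um) > 0)

    def test_empty_bin_warns_and_is_nan(self, geom):
        tmap = np.full((20, 36), np.nan)
        tmap[10:] = 300.0
        with pytest.warns(UserWarning, match="bin"):
            prof = qn.sample_thickness(tmap, geom, 10)
        assert np.isnan(prof.thickness_um[0]) and prof.thickness_um[-1] == 300.0


class TestFitAttenuation:
    @pytest.mark.parametrize("mu", [0.5, 1.0, 2.0, 4.0])
    def test_noiseless_exact(self, geom, mu):
        prof = ph.simulate_ascan([10, 200], [mu], geom)
        fit = qn.fit_attenuation(prof, 10, 200, geom)
        assert abs(fit.mu_A_mm - mu) / mu < 1e-9
        assert fit.r_squared > 1.0 - 1e-12

    def test_constant_profile_zero_attenuation(self, geom):
        fit = qn.fit_attenuation(np.full(100, 0.5), 10, 90, geom)
        assert fit.mu_A_mm == pytest.approx(0.0, abs=1e-12)

    def test_short_window_rejected(self, geom):
        with pytest.raises(ValueError, match="4 samples"):
            qn.fit_attenuation(np.ones(100), 10, 13, geom)

    def test_speckled_averaged_recovery(self, geom, rng):
        """500 averaged A-lines recover muA to within 5%."""
        errs = []
        for mu in (0.5, 1.0, 2.0, 4.0):
            acc = np.zeros(geom.n_depth_samples)
            for _ in range(500):
                acc += ph.simulate_ascan([10, 200], [mu], geom, rng=rng)
            fit = qn.fit_attenuation(acc / 500, 13, 200, geom)
            errs.append(abs(fit.mu_A_mm - mu) / mu)
        assert np.median(errs) <= 0.05

    def test_nonlinear_matches_loglinear_on_clean_data(self, geom):
        prof = ph.simulate_ascan([10, 200], [1.7], geom)
        lin = qn.fit_attenuation(prof, 10, 200, geom)
        nl = qn.fit_attenuation(prof, 10, 200, geom, nonlinear=True)
        assert nl.mu_A_mm == pytest.approx(lin.mu_A_mm, rel=1e-6)

    def test_estimator_consistency_with_averaging(self, geom):
        """Recovery error shrinks as more A-lines are averaged."""
        mu = 2.0
        med = {}
        for n in (10, 100, 1000):
            errs = []
            for rep in range(8):
                r = np.random.default_rng(1000 * n + rep)
                acc = np.zeros(geom.n_depth_samples)
                for _ in range(n):
                    acc += ph.simulate_ascan([10, 150], [mu], geom, rng=r)
                fit = qn.fit_attenuation(acc / n, 13, 150, geom)
                errs.append(abs(fit.mu_A_mm - mu))
            med[n] = np.median(errs)
        assert med[1000] < med[100] < med[10]


class TestLayerAttenuation:
    @pytest.fixture(scope="class")
    def thick_layer_study(self):
        """Phantom with 150 um layers so every fit window is well-posed."""
        layers = tuple(
            ph.LayerSpec(name, 150.0, mu, refl)
            for name, mu, refl in zip(
                ph.LAYER_NAMES, (3.0, 1.0, 2.0, 1.5), (1.0, 0.8, 0.9, 0.7)
            )
        )
        spec = ph.PhantomSpec(layers=layers)
        geom = ph.default_phantom_geometry(n_bscans=20, n_depth_samples=360)
        vol, truth = ph.simulate_volume(spec, geom)
        return spec, geom, vol, truth

    def test_per_layer_recovery_within_ten_percent(self, thick_layer_study):
        spec, geom, vol, truth = thick_layer_study
        wall = sg.WallMask(None, truth.top_boundary, truth.bottom_boundary)
        flat, _ = sg.flatten_volume(vol, wall, int(truth.layer_offsets[-1]) + 1)
        attn = qn.layer_attenuation(
            flat, truth.layer_offsets, geom,
            layer_names=tuple(truth.true_attenuation_mm), n_locations=10,
        )
        est = attn.groupby("layer")["mu_A_mm"].mean()
        for name, mu in truth.true_attenuation_mm.items():
            assert abs(est[name] - mu) / mu <= 0.10

    def test_identical_layers_give_identical_estimates(self, geom):
        layers = tuple(ph.LayerSpec(n, 120.0, 2.0, 1.0) for n in ph.LAYER_NAMES)
        spec = ph.PhantomSpec(
            layers=layers, speckle_model="none", noise_floor=0.0,
            detachment=ph.DetachmentSpec(0, 0, 0),
            motion_jitter=ph.MotionJitterSpec(0, 0),
            crypt_modulation=ph.CryptModulationSpec(0, 12),
            surface_waviness_um=0.0,
        )
        g = ph.default_phantom_geometry(n_bscans=4, n_depth_samples=360)
        vol, truth = ph.simulate_volume(spec, g)
        wall = sg.WallMask(None, truth.top_boundary, truth.bottom_boundary)
        flat, _ = sg.flatten_volume(vol, wall, int(truth.layer_offsets[-1]) + 1)
        attn = qn.layer_attenuation(
            flat, truth.layer_offsets, g,
            layer_names=tuple(truth.true_attenuation_mm), n_locations=2,
        )
        assert np.allclose(attn["mu_A_mm"], 2.0, rtol=1e-6)

    def test_inflamed_attenuation_ratio(self, geom):
        """A 0.7 attenuation multiplier shows up as a 0.7 fitted ratio."""
        ratios = []
        for seed in (3, 4):
            spec0 = ph.PhantomSpec(seed=seed)
            mult_layers = tuple(
                ph.LayerSpec(l.name, l.thickness_um, 0.7 * l.attenuation_mm,
                             l.surface_reflectivity)
                for l in spec0.layers
            )
            spec9 = ph.PhantomSpec(layers=mult_layers, seed=seed + 100)
            est = {}
            for label, spec in (("d0", spec0), ("d9", spec9)):
                vol, truth = ph.simulate_volume(spec, geom)
                params = ph.default_segmentation_params(spec, geom)
                wall = sg.segment_volume(rc.log_compress(vol, floor=1e-4), params)
                flat, _ = sg.flatten_volume(
                    vol, wall, int(truth.layer_offsets[-1]) + 1
                )
                attn = qn.layer_attenuation(
                    flat, truth.layer_offsets, geom,
                    layer_names=tuple(truth.true_attenuation_mm),
                    valid=wall.top_boundary != sg.SENTINEL,
                )
                est[label] = attn[attn["layer"] == "colonic_mucosa"]["mu_A_mm"].mean()
            ratios.append(est["d9"] / est["d0"])
        assert np.mean(ratios) == pytest.approx(0.7, abs=0.05)


class TestNormalizeToBaseline:
    def make_table(self):
        return pd.DataFrame(
            {
                "mouse": ["m1"] * 3 + ["m2"] * 3,
                "layer": ["wall"] * 6,
                "day": [0, 9, 24] * 2,
                "value": [100.0, 150.0, 100.0, 200.0, 140.0, 260.0],
            }
        )

    def test_reference_percentages(self):
        out = qn.normalize_to_baseline(self.make_table(), "value")
        m1 = out[out["mouse"] == "m1"].set_index("day")["pct_change"]
        assert m1[0] == pytest.approx(0.0)
        assert m1[9] == pytest.approx(50.0)
        m2 = out[out["mouse"] == "m2"].set_index("day")["pct_change"]
        assert m2[9] == pytest.approx(-30.0)
        assert m2[24] == pytest.approx(30.0)

    def test_missing_baseline_excluded_with_warning(self):
        table = self.make_table()
        table = table[~((table["mouse"] == "m2") & (table["day"] == 0))]
        with pytest.warns(UserWarning, match="m2"):
            out = qn.normalize_to_baseline(table, "value")
        assert set(out["mouse"]) == {"m1"}


class TestStudyQuantification:
    def test_thickness_multiplier_increases_measurement(self, quiet_geom):
        means = []
        for mult in (1.0, 1.2, 1.5):
            layers = tuple(
                ph.LayerSpec(l.name, l.thickness_um * mult, l.attenuation_mm,
                             l.surface_reflectivity)
                for l in ph.murine_colon_layers()
            )
            spec = ph.PhantomSpec(layers=layers)
            _, truth = ph.simulate_volume(spec, quiet_geom, render=False)
            wall = sg.WallMask(None, truth.top_boundary, truth.bottom_boundary)
            tmap = qn.thickness_map(wall, quiet_geom)
            means.append(np.nanmean(tmap))
        assert means[0] < means[1] < means[2]

    def test_quant_table_shape(self, quiet_spec, quiet_geom):
        recs = ph.simulate_study(
            ph.StudyDesign(seed=6), quiet_spec, None, quiet_geom, render=False
        )
        q = qn.quantify_study(recs, quiet_geom, n_locations=4, use_truth_boundaries=True)
        # 2 groups x 3 mice x 3 days x 4 bins x 4 layers
        assert len(q) == 2 * 3 * 3 * 4 * 4
        assert set(q["layer"]) == set(ph.LAYER_NAMES)
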