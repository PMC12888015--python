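import dataclasses

import numpy as np
import pytest

from morphomsi import fixtures, spectra
from morphomsi.fixtures import (CorePhantom, FixturePhantom, Follicle,
                                SpectrumModel, render_he_image, render_msi_cube)


class TestPhantomValidation:
    def test_core_outside_bounds_rejected(self):
        core = CorePhantom((10.0, 10.0), 50.0, "PTC")
        with pytest.raises(ValueError, match="bounds"):
            FixturePhantom(cores=[core], image_size_um=(100.0, 100.0))

    def test_pitch_must_be_coarser_than_pixels(self):
        with pytest.raises(ValueError, match="coarser"):
            FixturePhantom(cores=[], image_px_size_um=25.0, msi_pitch_um=20.0)

    def test_oversized_image_refused(self):
        core = CorePhantom((3000.0, 3000.0), 100.0, "FA")
        ph = FixturePhantom(cores=[core], max_image_px=2000)
        with pytest.raises(ValueError, match="cap"):
            render_he_image(ph)


class TestRenderHE:
    def test_empty_phantom_gives_blank_background(self):
        ph = FixturePhantom(cores=[], image_size_um=(50.0, 50.0))
        scene = render_he_image(ph)
        assert not scene.masks["tissue"].any()
        assert len(scene.training) == 0 and len(scene.pathologist) == 0
        # background stays near-white
        assert scene.image.mean() > 240

    def test_single_follicle_rim_area_matches_annulus(self):
        """Rendered rim pixel count ~ analytic annulus area / px area."""
        lumen, rim = 20.0, 10.0
        core = CorePhantom((60.0, 60.0), 50.0, "PTC", [Follicle((0, 0), lumen, rim)])
        ph = FixturePhantom(cores=[core], image_size_um=(120.0, 120.0), seed=1)
        scene = render_he_image(ph)
        analytic = np.pi * ((lumen + rim) ** 2 - lumen ** 2) / ph.image_px_size_um ** 2
        rendered = scene.masks["cell_rich"].sum()
        assert abs(rendered - analytic) / analytic < 0.02  # anti-aliasing tolerance

    def test_same_seed_is_bit_identical(self, tiny_phantom):
        a = render_he_image(tiny_phantom)
        b = render_he_image(tiny_phantom)
        assert np.array_equal(a.image, b.image)
        assert all(np.array_equal(a.masks[k], b.masks[k]) for k in a.masks)

    def test_lumen_and_rim_disjoint(self, tiny_scene):
        assert not (tiny_scene.masks["cell_rich"] & tiny_scene.masks["colloid"]).any()

    def test_pathologist_polygons_engulf_lumens(self, tiny_phantom, tiny_scene):
        """Coarse annotations include colloid, as manual subcore outlines do."""
        from skimage.draw import polygon as draw_polygon
        h, w = tiny_scene.masks["colloid"].shape
        inside = np.zeros((h, w), dtype=bool)
        for ann in tiny_scene.pathologist:
            for geom in getattr(ann.geometry, "geoms", [ann.geometry]):
                col, row = np.asarray(geom.exterior.coords).T
                rr, cc = draw_polygon(row, col, shape=(h, w))
                inside[rr, cc] = True
        colloid = tiny_scene.masks["colloid"]
        assert (inside & colloid).sum() / colloid.sum() > 0.9


class TestRenderCube:
    def test_colloid_spot_interferent_amplitude(self):
        """Fully-colloid spot: amplitude = base * (1 + enrichment)."""
        # large lumen so some 20 um grid cells lie fully in colloid
        core = CorePhantom((80.0, 80.0), 60.0, "PTC", [Follicle((0, 0), 40.0, 10.0)])
        ph = FixturePhantom(cores=[core], mz_range=(700.0, 760.0), seed=2)
        scene = render_he_image(ph)
        model = SpectrumModel(interferent_peaks=[(712.20, 8.0, 2.0)],
                              trypsin_peaks=[], noise_sd=0.0)
        ds, gt = render_msi_cube(ph, model, scene)
        full = np.nonzero(gt["colloid_fraction"] >= 0.999)[0]
        assert full.size > 0
        k = np.argmin(np.abs(ds.mz_axis - 712.20))
        apex = ds.intensities[full, k] - model.baseline_level
        assert np.allclose(apex, 3 * 8.0, rtol=1e-3)
        # and the per-spot enrichment law holds everywhere (noiseless)
        expect = 8.0 * (1.0 + 2.0 * gt["colloid_fraction"])
        assert np.allclose(ds.intensities[:, k] - model.baseline_level, expect, rtol=2e-2)

    def test_spots_outside_tissue_absent(self, tiny_phantom, tiny_scene, tiny_cube):
        ds, _ = tiny_cube
        t = tiny_phantom.planted_transform
        tissue = tiny_scene.masks["tissue"]
        h, w = tissue.shape
        for x, y in ds.coordinates:
            # spot cell must contain at least one tissue pixel
            corners_um = np.array([[x * 20.0, y * 20.0], [(x + 1) * 20.0, (y + 1) * 20.0]])
            px = t.inverse().apply(corners_um)
            x0, x1 = int(np.floor(px[0, 0])), int(np.ceil(px[1, 0]))
            y0, y1 = int(np.floor(px[0, 1])), int(np.ceil(px[1, 1]))
            assert tissue[max(0, y0):y1, max(0, x0):x1].any()

    def test_noiseless_peak_height_is_amplitude_plus_baseline(self, tiny_phantom, tiny_scene):
        model = SpectrumModel(shared_peptide_peaks=[(745.60, 17.0)],
                              interferent_peaks=[], trypsin_peaks=[], noise_sd=0.0)
        ds, gt = render_msi_cube(tiny_phantom, model, tiny_scene)
        window = np.abs(ds.mz_axis - 745.60) <= 0.1
        full_cell = np.nonzero(gt["cell_fraction"] >= 0.999)[0]
        if full_cell.size == 0:
            full_cell = np.array([np.argmax(gt["cell_fraction"])])
        amp = 17.0 * gt["cell_fraction"][full_cell[0]]
        got = ds.intensities[full_cell[0], window].max()
        assert got == pytest.approx(amp + model.baseline_level, rel=1e-6)

    def test_enrichment_monotonicity(self, tiny_phantom, tiny_scene):
        means = []
        for enrich in (1.0, 2.0, 4.0):
            model = SpectrumModel(interferent_peaks=[(712.20, 8.0, enrich)],
                                  trypsin_peaks=[], noise_sd=0.0)
            ds, gt = render_msi_cube(tiny_phantom, model, tiny_scene)
            colloid = gt["colloid_fraction"] > 0.5
            k = np.argmin(np.abs(ds.mz_axis - 712.20))
            means.append(ds.intensities[colloid, k].mean())
        assert means[0] < means[1] < means[2]

    def test_peak_outside_range_rejected(self, tiny_phantom, tiny_scene):
        model = SpectrumModel(shared_peptide_peaks=[(500.0, 5.0)])
        with pytest.raises(ValueError, match="mz_range"):
            render_msi_cube(tiny_phantom, model, tiny_scene)

    def test_no_tissue_under_grid_reports_footprint_mismatch(self, tiny_model):
        ph = FixturePhantom(cores=[], image_size_um=(50.0, 50.0),
                            mz_range=(700.0, 760.0))
        scene = render_he_image(ph)
        with pytest.raises(ValueError, match="grid|footprint"):
            render_msi_cube(ph, tiny_model, scene)

    def test_determinism(self, tiny_phantom, tiny_scene, tiny_model, tiny_cube):
        ds, _ = tiny_cube
        ds2, _ = render_msi_cube(tiny_phantom, tiny_model, tiny_scene)
        assert np.array_equal(ds.intensities, ds2.intensities)
        assert np.array_equal(ds.coordinates, ds2.coordinates)


class TestImzmlRoundtrip:
    def test_bit_exact_roundtrip(self, tiny_cube, tmp_path):
        ds, _ = tiny_cube
        path = tmp_path / "cube.imzML"
        spectra.write_imzml(ds, path)
        back = spectra.read_imzml(path, pitch_um=ds.pitch_um)
        assert np.array_equal(back.mz_axis, ds.mz_axis)
        assert np.array_equal(back.intensities, ds.intensities)
        assert np.array_equal(back.coordinates, ds.coordinates)
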