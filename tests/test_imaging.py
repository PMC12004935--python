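"""Annulus measurement: pixel-centre band membership and batch routing."""

import numpy as np
import pandas as pd
import pytest

from vescharge.imaging import (
    AnnulusAnnotation,
    measure_annulus,
    measure_batch,
)
from vescharge.synthetic import SyntheticImageSpec, render_images


def _ann(**kw):
    base = dict(vesicle_id="v0", cx_px=31.5, cy_px=31.5, inner_radius_um=5.0,
                pixel_size_um=0.25, band_width_um=1.0)
    base.update(kw)
    return AnnulusAnnotation(**base)


def _ring_image(i_mem=250.0, i_bg=50.0, spec=None):
    spec = spec or SyntheticImageSpec()
    rec = pd.DataFrame([{"vesicle_id": "v0", "I_mem": i_mem, "I_bg": i_bg}])
    imgs, ann = render_images(rec, spec)
    return imgs[0], ann.iloc[0], spec


class TestMeasureAnnulus:
    def test_constant_field(self):
        img = np.full((64, 64), 7.25)
        m = measure_annulus(img, _ann())
        assert m.i_mem == 7.25
        assert m.i_bg == 7.25
        assert m.i_net == 0.0
        assert m.n_pixels_band > 0

    def test_recovers_rendered_ring_amplitude(self):
        img, ann, spec = _ring_image(i_mem=250.0, i_bg=50.0)
        m = measure_annulus(img, _ann(cx_px=ann.cx_px, cy_px=ann.cy_px))
        # within 2 % of the ring amplitude: ring-profile discretisation plus
        # the faint Gaussian tail the local-background annulus picks up
        assert m.i_net == pytest.approx(200.0, rel=0.02)
        assert m.i_bg == pytest.approx(50.0, abs=0.02 * 200.0)

    def test_amplitude_linearity(self):
        img1, ann, _ = _ring_image(i_mem=150.0, i_bg=50.0)
        img2, _, _ = _ring_image(i_mem=250.0, i_bg=50.0)
        a = _ann(cx_px=ann.cx_px, cy_px=ann.cy_px)
        net1 = measure_annulus(img1, a).i_net
        net2 = measure_annulus(img2, a).i_net
        assert net2 == pytest.approx(2 * net1, rel=1e-9)

    def test_zero_amplitude_zero_net(self):
        img, ann, _ = _ring_image(i_mem=50.0, i_bg=50.0)
        m = measure_annulus(img, _ann(cx_px=ann.cx_px, cy_px=ann.cy_px))
        assert m.i_net == pytest.approx(0.0, abs=1e-9)

    def test_matches_bruteforce_pixel_loop(self, rng):
        # independent double-loop oracle with explicit membership test
        img = rng.uniform(0, 100, size=(64, 64))
        ann = _ann(cx_px=30.0, cy_px=33.0, inner_radius_um=4.0)
        m = measure_annulus(img, ann)
        r_in, r_out = ann.inner_radius_px, ann.outer_radius_px
        band_vals, bg_vals = [], []
        for y in range(64):
            for x in range(64):
                r = np.sqrt((x - 30.0) ** 2 + (y - 33.0) ** 2)
                if r_in <= r < r_out:
                    band_vals.append(img[y, x])
                elif r_out + 2.0 <= r < r_out + 6.0:
                    bg_vals.append(img[y, x])
        assert m.i_mem == pytest.approx(np.mean(band_vals), abs=1e-12)
        assert m.i_bg == pytest.approx(np.mean(bg_vals), abs=1e-12)
        assert m.n_pixels_band == len(band_vals)

    def test_rotation_invariance(self):
        img, ann, _ = _ring_image()
        a = _ann(cx_px=ann.cx_px, cy_px=ann.cy_px)
        m0 = measure_annulus(img, a)
        m90 = measure_annulus(np.rot90(img), a)
        assert m90.i_mem == pytest.approx(m0.i_mem, abs=1e-9)

    def test_band_is_half_open(self):
        # pixel exactly at the outer radius is excluded; at the inner, included
        img = np.zeros((41, 41))
        ann = AnnulusAnnotation(vesicle_id="v0", cx_px=20, cy_px=20,
                                inner_radius_um=3.0, pixel_size_um=1.0,
                                band_width_um=2.0)
        img[20, 25] = 999.0  # r = 5 = outer radius -> excluded
        assert measure_annulus(img, ann).i_mem == 0.0
        img[20, 23] = 999.0  # r = 3 = inner radius -> included
        assert measure_annulus(img, ann).i_mem > 0.0

    def test_out_of_bounds_names_vesicle(self):
        img = np.zeros((32, 32))
        with pytest.raises(ValueError, match="v7"):
            measure_annulus(img, _ann(vesicle_id="v7", cx_px=4, cy_px=4,
                                      inner_radius_um=3.0, pixel_size_um=1.0))


class TestMeasureBatch:
    def test_empty_annotations(self):
        meas, skip = measure_batch(pd.DataFrame(columns=["image", "vesicle_id",
                                                         "cx_px", "cy_px", "radius_px"]))
        assert meas.empty and skip.empty

    def test_routes_bad_rows_to_skip_table(self):
        img = np.full((64, 64), 10.0)
        ann = pd.DataFrame(
            [
                {"image": "a", "vesicle_id": f"v{i}", "cx_px": 31.5, "cy_px": 31.5,
                 "radius_px": 10.0}
                for i in range(3)
            ]
            + [{"image": "a", "vesicle_id": "bad", "cx_px": 2.0, "cy_px": 2.0,
                "radius_px": 10.0}]
        )
        meas, skip = measure_batch(ann, images={"a": img})
        assert len(meas) == 3
        assert len(skip) == 1 and skip.iloc[0]["vesicle_id"] == "bad"

    def test_missing_image_recorded(self):
        ann = pd.DataFrame([{"image": "ghost.tif", "vesicle_id": "v0",
                             "cx_px": 31.5, "cy_px": 31.5, "radius_px": 10.0}])
        meas, skip = measure_batch(ann, images={})
        assert meas.empty
        assert "not provided" in skip.iloc[0]["reason"]

    def test_batch_equals_per_call(self, rng):
        img = rng.uniform(0, 50, size=(64, 64))
        rows = [{"image": "a", "vesicle_id": f"v{i}", "cx_px": 31.5, "cy_px": 31.5,
                 "radius_px": 8.0 + i} for i in range(3)]
        meas, _ = measure_batch(pd.DataFrame(rows), images={"a": img})
        for row, (_, got) in zip(rows, meas.iterrows()):
            single = measure_annulus(
                img,
                AnnulusAnnotation(vesicle_id=row["vesicle_id"], cx_px=31.5,
                                  cy_px=31.5, inner_radius_um=row["radius_px"],
                                  pixel_size_um=1.0),
            )
            assert got["I_mem"] == pytest.approx(single.i_mem, abs=1e-12)
            assert got["I_bg"] == pytest.approx(single.i_bg, abs=1e-12)


def test_tiff_roundtrip(tmp_path, rng):
    """Rendered tiles written to disk re-measure like the in-memory arrays."""
    rec = pd.DataFrame([{"vesicle_id": "v0", "I_mem": 250.0, "I_bg": 50.0}])
    spec = SyntheticImageSpec()
    imgs, ann = render_images(rec, spec, out_dir=tmp_path)
    meas, skip = measure_batch(
        pd.read_csv(tmp_path / "annotations.csv"), image_dir=tmp_path,
        pixel_size_um=spec.pixel_size_um, band_width_um=spec.band_width_um,
    )
    assert skip.empty
    assert meas.iloc[0]["I_net"] == pytest.approx(200.0, rel=0.02)
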