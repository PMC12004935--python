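"""Annulus-based single-vesicle intensity measurement.

Replicates the standard FIJI workflow for quantifying vesicle membrane
fluorescence: a circle is drawn along the inside perimeter of the membrane,
expanded into a band (annulus) of fixed physical thickness (default 1 µm),
and the mean pixel intensity inside the band taken as the membrane signal
I_mem.  A nearby offset annulus provides the local background I_bg, and the
net signal is I_net = I_mem - I_bg.

Band membership uses the pixel-centre distance criterion with a half-open
interval: a pixel belongs to the band when

    inner_radius <= r < inner_radius + band_width

with r the distance from its centre (integer coordinates, x right / y down)
to the annotation centre.  This matches ImageJ's "Make band" behaviour and
makes membership exactly testable; no sub-pixel area weighting is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AnnulusAnnotation",
    "IntensityMeasurement",
    "measure_annulus",
    "measure_batch",
    "read_image",
]

#: background annulus offsets (px) beyond the outer band radius
BG_INNER_OFFSET_PX = 2.0
BG_OUTER_OFFSET_PX = 6.0


@dataclass(frozen=True)
class AnnulusAnnotation:
    """One vesicle's measurement geometry.

    Coordinates are 0-based pixel indices (x right, y down) with pixel
    centres at integers.  Radii and the band width are physical (µm) and are
    converted through ``pixel_size_um``; ``inner_radius_um`` is the circle
    along the inside of the membrane.
    """

    vesicle_id: str
    cx_px: float
    cy_px: float
    inner_radius_um: float
    pixel_size_um: float = 1.0
    band_width_um: float = 1.0
    image: str = ""

    def __post_init__(self):
        if self.inner_radius_um <= 0:
            raise ValueError(f"vesicle {self.vesicle_id}: inner radius must be positive")
        if self.band_width_um <= 0 or self.pixel_size_um <= 0:
            raise ValueError(f"vesicle {self.vesicle_id}: band width and pixel size must be positive")

    @property
    def inner_radius_px(self) -> float:
        return self.inner_radius_um / self.pixel_size_um

    @property
    def outer_radius_px(self) -> float:
        return (self.inner_radius_um + self.band_width_um) / self.pixel_size_um


@dataclass(frozen=True)
class IntensityMeasurement:
    """Mean band and background intensities for one vesicle."""

    vesicle_id: str
    i_mem: float
    i_bg: float
    n_pixels_band: int
    n_pixels_bg: int
    low_signal_flag: bool = False  # I_net < -3 * background SD

    @property
    def i_net(self) -> float:
        return self.i_mem - self.i_bg


def read_image(path: str | Path) -> np.ndarray:
    """Load a single-channel TIFF or PNG as a float array."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        return tifffile.imread(path).astype(float)
    import imageio.v3 as iio

    return iio.imread(path).astype(float)


def _radius_map(shape: tuple[int, int], cx: float, cy: float) -> np.ndarray:
    yy, xx = np.indices(shape)
    return np.hypot(xx - cx, yy - cy)


def measure_annulus(image: np.ndarray, ann: AnnulusAnnotation) -> IntensityMeasurement:
    """Mean membrane and local-background intensity for one annotation.

    The background region is an offset annulus 2-6 px outside the band's
    outer radius.  Raises if the background annulus extends past the image
    bounds or if either region contains no pixel centres.
    """
    h, w = image.shape
    r_in = ann.inner_radius_px
    r_out = ann.outer_radius_px
    bg_in = r_out + BG_INNER_OFFSET_PX
    bg_out = r_out + BG_OUTER_OFFSET_PX
    if (
        ann.cx_px - bg_out < -0.5
        or ann.cy_px - bg_out < -0.5
        or ann.cx_px + bg_out > w - 0.5
        or ann.cy_px + bg_out > h - 0.5
    ):
        raise ValueError(
            f"vesicle {ann.vesicle_id}: annulus (outer {bg_out:.1f} px) exceeds "
            f"image bounds {w}x{h}"
        )

    r = _radius_map(image.shape, ann.cx_px, ann.cy_px)
    band = (r >= r_in) & (r < r_out)
    bg = (r >= bg_in) & (r < bg_out)
    if not band.any():
        raise ValueError(f"vesicle {ann.vesicle_id}: membrane band contains no pixels")
    if not bg.any():
        raise ValueError(f"vesicle {ann.vesicle_id}: background region contains no pixels")

    i_mem = float(image[band].mean())
    i_bg = float(image[bg].mean())
    bg_sd = float(image[bg].std())
    return IntensityMeasurement(
        vesicle_id=ann.vesicle_id,
        i_mem=i_mem,
        i_bg=i_bg,
        n_pixels_band=int(band.sum()),
        n_pixels_bg=int(bg.sum()),
        low_signal_flag=bool(i_mem - i_bg < -3.0 * bg_sd),
    )


def measure_batch(
    annotations: pd.DataFrame,
    images: dict[str, np.ndarray] | None = None,
    image_dir: str | Path | None = None,
    pixel_size_um: float = 1.0,
    band_width_um: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply :func:`measure_annulus` to every annotation row.

    ``annotations`` columns: image, vesicle_id, cx_px, cy_px, radius_px
    (converted to µm with ``pixel_size_um``).  Images come either from the
    in-memory mapping or are loaded from ``image_dir``.  Failing rows
    (missing image, out-of-bounds annulus) are routed to a skip table with
    the reason instead of aborting the batch; row order is preserved.

    Returns (measurements, skipped) DataFrames.
    """
    rows, skipped = [], []
    cache: dict[str, np.ndarray] = {}
    for _, row in annotations.iterrows():
        name = str(row["image"])
        try:
            if images is not None and name in images:
                img = images[name]
            elif name in cache:
                img = cache[name]
            elif image_dir is not None:
                p = Path(image_dir) / name
                if not p.exists():
                    raise FileNotFoundError(f"image file not found: {p}")
                img = read_image(p)
                cache[name] = img
            else:
                raise FileNotFoundError(f"image {name!r} not provided")
            ann = AnnulusAnnotation(
                vesicle_id=str(row["vesicle_id"]),
                cx_px=float(row["cx_px"]),
                cy_px=float(row["cy_px"]),
                inner_radius_um=float(row["radius_px"]) * pixel_size_um,
                pixel_size_um=pixel_size_um,
                band_width_um=band_width_um,
                image=name,
            )
            m = measure_annulus(img, ann)
        except (ValueError, FileNotFoundError) as exc:
            skipped.append({"vesicle_id": row.get("vesicle_id"), "image": name,
                            "reason": str(exc)})
            continue
        rows.append(
            {
                "vesicle_id": m.vesicle_id,
                "image": name,
                "I_mem": m.i_mem,
                "I_bg": m.i_bg,
                "I_net": m.i_net,
                "n_pixels_band": m.n_pixels_band,
                "low_signal_flag": m.low_signal_flag,
            }
        )
    meas = pd.DataFrame(rows, columns=["vesicle_id", "image", "I_mem", "I_bg",
                                       "I_net", "n_pixels_band", "low_signal_flag"])
    skip = pd.DataFrame(skipped, columns=["vesicle_id", "image", "reason"])
    return meas, skip
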