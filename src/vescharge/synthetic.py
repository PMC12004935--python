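"""Synthetic single-vesicle data with the statistical structure the
analysis assumes.

Every input the pipeline consumes can be generated here: vesicle
populations whose probe binding follows the Langmuir-Boltzmann model with
broad vesicle-to-vesicle spread, rendered ring images with pixel-accurate
annotations, linear fluorescence calibrations, Grahame-type zeta-potential
curves, and two-phase flow-rate mixing runs.

Vesicle heterogeneity is placed on the binding constant: each vesicle draws
K_B from a log-normal distribution with median equal to the population truth
and a chosen coefficient of variation.  This encodes the view that
vesicle-to-vesicle spread reflects per-vesicle surface differences (e.g.
residual solvent altering surface charge) acting through K_B rather than
through the saturation capacity.  The free-DNA concentration is treated as
externally fixed per incubation level — the incubation volume vastly
exceeds the membranes' binding capacity, so depletion is negligible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import erf

from .calibration import CalibrationCurve
from .binding import langmuir_bound
from .constants import IONIC_STRENGTH_MM, T_REF
from .electrostatics import grahame_potential, sigma_from_n_pg

__all__ = [
    "GroundTruth",
    "SyntheticImageSpec",
    "default_membrane_calibration",
    "default_solution_calibration",
    "generate_population",
    "generate_calibration_points",
    "render_images",
    "generate_zeta_table",
    "generate_mixing_run",
    "mean_intensity_ratio",
]

_MAX_RESAMPLE_ROUNDS = 50


@dataclass(frozen=True)
class GroundTruth:
    """Ground-truth parameters of one synthetic vesicle population."""

    n_pg: float = 0.0                # anionic lipid mole fraction, [0, 1]
    k_b_true: float = 4.7            # median effective binding constant, per µM
    dna_max_true: float = 0.37       # saturation bound fraction, mol %
    cv_vesicle: float = 0.3          # CV of per-vesicle K_B (log-normal)
    seed: int | None = None

    def __post_init__(self):
        if not 0.0 <= self.n_pg <= 1.0:
            raise ValueError("n_pg must be in [0, 1]")
        if self.k_b_true <= 0:
            raise ValueError("k_b_true must be positive")
        if not 0.0 < self.dna_max_true < 100.0:
            raise ValueError("dna_max_true must be in (0, 100) mol %")
        if self.cv_vesicle < 0:
            raise ValueError("cv_vesicle must be non-negative")


def default_membrane_calibration() -> CalibrationCurve:
    """Membrane-dye channel: counts per mol % bound DNA (net signal, zero offset)."""
    return CalibrationCurve(channel="mem", gain=1000.0, offset=0.0,
                            r_squared=1.0, valid_range=(0.0, 1.0))


def default_solution_calibration() -> CalibrationCurve:
    """Solution-dye channel: counts per µM free DNA over a dark offset."""
    return CalibrationCurve(channel="sol", gain=100.0, offset=50.0,
                            r_squared=1.0, valid_range=(0.0, 10.0))


def generate_population(
    truth: GroundTruth,
    dna_added_levels,
    n_vesicles_per_level: int,
    *,
    cal_mem: CalibrationCurve | None = None,
    cal_sol: CalibrationCurve | None = None,
    intensity_noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate a single-vesicle binding titration.

    For each incubation level the free-DNA concentration is the added
    concentration (no depletion); each vesicle draws its own K_B from a
    log-normal with median ``truth.k_b_true`` and CV ``truth.cv_vesicle``,
    and its bound fraction from the Langmuir isotherm.  Intensities are the
    forward calibrations plus Gaussian noise; measured concentrations are
    recovered back through the same calibrations, so zero noise and zero CV
    reproduce the noise-free Langmuir curve exactly and population means
    converge to it as n grows.

    Returns a table with one row per vesicle: identifiers, ground truth
    (``k_b_i``, ``dna_mem_true_molpct``), intensities (``I_mem``, ``I_bg``)
    and measured concentrations (``dna_mem_molpct``, ``dna_free_uM``).

    Draws whose bound fraction would reach ``dna_max_true`` are resampled;
    exceeding the resampling bound raises (signals an absurd CV).
    """
    levels = np.asarray(dna_added_levels, dtype=float)
    if np.any(levels <= 0):
        raise ValueError("all dna_added_levels must be positive")
    if n_vesicles_per_level < 1:
        raise ValueError("n_vesicles_per_level must be >= 1")
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    cal_mem = cal_mem or default_membrane_calibration()
    cal_sol = cal_sol or default_solution_calibration()

    sigma_ln = float(np.sqrt(np.log1p(truth.cv_vesicle**2)))
    rows = []
    vid = 0
    for dna_added in levels:
        dna_free = dna_added  # depletion negligible
        for _ in range(n_vesicles_per_level):
            for attempt in range(_MAX_RESAMPLE_ROUNDS):
                k_i = truth.k_b_true * float(np.exp(rng.normal(0.0, sigma_ln)))
                dna_mem = float(langmuir_bound(dna_free, k_i, truth.dna_max_true))
                if dna_mem < truth.dna_max_true:
                    break
            else:
                raise RuntimeError(
                    "resampling bound exceeded: per-vesicle binding keeps "
                    f"saturating (cv_vesicle={truth.cv_vesicle} is implausible)"
                )
            i_bg_true = float(cal_sol.forward(dna_free))
            i_mem_true = i_bg_true + cal_mem.gain * dna_mem
            noise = rng.normal(0.0, intensity_noise_sd, size=2) if intensity_noise_sd > 0 else (0.0, 0.0)
            i_mem = i_mem_true + float(noise[0])
            i_bg = i_bg_true + float(noise[1])
            rows.append(
                {
                    "vesicle_id": f"v{vid:05d}",
                    "n_PG": truth.n_pg,
                    "dna_added_uM": dna_added,
                    "channel": cal_mem.channel,
                    "k_b_i": k_i,
                    "dna_mem_true_molpct": dna_mem,
                    "I_mem": i_mem,
                    "I_bg": i_bg,
                    "dna_mem_molpct": max((i_mem - i_bg) / cal_mem.gain, 0.0),
                    "dna_free_uM": max((i_bg - cal_sol.offset) / cal_sol.gain, 0.0),
                }
            )
            vid += 1
    return pd.DataFrame(rows)


def generate_calibration_points(
    cal: CalibrationCurve,
    concentrations,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Forward-evaluate a calibration line at given concentrations (+ noise)."""
    rng = rng or np.random.default_rng()
    conc = np.asarray(concentrations, dtype=float)
    inten = cal.forward(conc)
    if noise_sd > 0:
        inten = inten + rng.normal(0.0, noise_sd, size=conc.shape)
    return pd.DataFrame({"channel": cal.channel, "concentration": conc,
                         "intensity": inten})


@dataclass(frozen=True)
class SyntheticImageSpec:
    """Geometry and noise of rendered vesicle tiles (one vesicle per tile)."""

    image_size_px: int = 64
    pixel_size_um: float = 0.25
    ring_radius_um: float = 5.0      # inner membrane radius
    ring_sigma_um: float = 0.4       # radial Gaussian width of the membrane
    band_width_um: float = 1.0
    background_level: float = 50.0
    photon_noise_scale: float = 0.0  # additive Gaussian SD, intensity units
    bit_depth: int = 16

    def __post_init__(self):
        span = self.image_size_px * self.pixel_size_um
        # tile must hold the ring plus the background annulus (6 px margin)
        needed = 2 * (self.ring_radius_um + self.band_width_um + 6 * self.pixel_size_um)
        if needed >= span:
            raise ValueError(
                f"ring (needs {needed:.1f} µm incl. background annulus) does not "
                f"fit the {span:.1f} µm tile"
            )
        if self.photon_noise_scale < 0 or self.ring_sigma_um <= 0:
            raise ValueError("noise scales must be >= 0 and ring_sigma positive")


def _band_mean_factor(spec: SyntheticImageSpec) -> float:
    # mean over the band [R, R+w) of a unit Gaussian centred at R + w/2:
    # (1/w) * integral exp(-u^2 / 2 sigma^2) du over [-w/2, w/2]
    s, w = spec.ring_sigma_um, spec.band_width_um
    return float(s * np.sqrt(2.0 * np.pi) / w * erf(w / (2.0 * np.sqrt(2.0) * s)))


def render_images(
    records: pd.DataFrame,
    spec: SyntheticImageSpec,
    out_dir: str | Path | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Render one tile per vesicle: a radially Gaussian ring over flat background.

    The ring's peak amplitude is scaled so that the *mean* intensity over
    the measurement band [R, R + band_width) equals the record's net signal
    I_mem - I_bg; the annulus measurement thus recovers the record's
    intensities up to ring-profile discretisation (~2 %).  Returns the float
    images and a pixel-accurate annotation table (image, vesicle_id, cx_px,
    cy_px, radius_px); with ``out_dir`` the tiles are also written as 16-bit
    single-channel TIFFs.
    """
    rng = rng or np.random.default_rng()
    n = spec.image_size_px
    c = (n - 1) / 2.0
    yy, xx = np.indices((n, n))
    r_um = np.hypot(xx - c, yy - c) * spec.pixel_size_um
    r_mid = spec.ring_radius_um + spec.band_width_um / 2.0
    profile = np.exp(-((r_um - r_mid) ** 2) / (2.0 * spec.ring_sigma_um**2))
    factor = _band_mean_factor(spec)

    images, ann = [], []
    for _, row in records.iterrows():
        amp = (float(row["I_mem"]) - float(row["I_bg"])) / factor
        img = float(row["I_bg"]) + amp * profile
        if spec.photon_noise_scale > 0:
            img = img + rng.normal(0.0, spec.photon_noise_scale, size=img.shape)
        images.append(img)
        ann.append(
            {
                "image": f"{row['vesicle_id']}.tif",
                "vesicle_id": row["vesicle_id"],
                "cx_px": c,
                "cy_px": c,
                "radius_px": spec.ring_radius_um / spec.pixel_size_um,
            }
        )
    annotations = pd.DataFrame(ann, columns=["image", "vesicle_id", "cx_px", "cy_px", "radius_px"])

    if out_dir is not None:
        import tifffile

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        peak = float(2**spec.bit_depth - 1)
        for img, name in zip(images, annotations["image"]):
            tifffile.imwrite(out / name, np.clip(img, 0, peak).astype(np.uint16))
        annotations.to_csv(out / "annotations.csv", index=False)
    return images, annotations


def generate_zeta_table(
    n_pg_levels,
    ionic_strength_mM: float = IONIC_STRENGTH_MM,
    noise_sd_mV: float = 0.0,
    seed: int | None = None,
    T: float = T_REF,
) -> pd.DataFrame:
    """Zeta potentials of vesicle preparations of varying anionic fraction.

    The noise-free curve is the Grahame surface potential of the bilayer's
    charge density (one -1e per PG headgroup over the area per lipid):
    proportional to n_PG at small fractions and sublinear (deviating beneath
    the linear trend) at high surface charge.  Gaussian noise emulates
    measurement error of electrophoretic-mobility instruments.
    """
    levels = np.asarray(n_pg_levels, dtype=float)
    if np.any((levels < 0) | (levels > 1)):
        raise ValueError("n_PG levels must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    phi = grahame_potential(sigma_from_n_pg(levels), ionic_strength_mM, T)
    if noise_sd_mV > 0:
        phi = phi + rng.normal(0.0, noise_sd_mV, size=levels.shape)
    return pd.DataFrame({"n_PG": levels, "phi_z_mV": phi})


def generate_mixing_run(
    q_a: float,
    q_b: float,
    *,
    gain_nbd: float = 1.0,
    gain_rhod: float = 1.0,
    n_vesicles: int = 1000,
    ratio_cv: float = 0.2,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-vesicle dye intensities for one two-phase flow-rate condition.

    Phase fractions follow the relative flow rates (x_A = Q_A/Q); the
    NBD-labelled phase A and Rhod-labelled phase B contribute intensities
    proportional to their fractions, a shared per-vesicle brightness factor
    (size/illumination, log-normal), and mean-one log-normal channel scatter
    — so the population mean of I_NBD / I_Rhod is proportional to Q_A/Q_B.
    """
    if q_a < 0 or q_b < 0 or q_a + q_b == 0:
        raise ValueError("flow rates must be non-negative and not both zero")
    rng = np.random.default_rng(seed)
    q = q_a + q_b
    x_a, x_b = q_a / q, q_b / q
    size = np.exp(rng.normal(0.0, 0.3, size=n_vesicles))  # shared brightness
    sigma = float(np.sqrt(np.log1p(ratio_cv**2)))
    # mean-one multiplicative scatter on the NBD channel keeps E[ratio] exact
    scatter = np.exp(rng.normal(-sigma**2 / 2.0, sigma, size=n_vesicles))
    i_rhod = gain_rhod * x_b * size
    i_nbd = gain_nbd * x_a * size * scatter
    return pd.DataFrame(
        {"vesicle_id": [f"m{i:05d}" for i in range(n_vesicles)],
         "I_NBD": i_nbd, "I_Rhod": i_rhod}
    )


def mean_intensity_ratio(run: pd.DataFrame) -> tuple[float, bool]:
    """Population mean of I_NBD / I_Rhod with a division guard.

    Returns (ratio, defined): when the Rhod channel is dark (phase B absent)
    the ratio is reported as inf with ``defined = False`` rather than raising.
    """
    i_rhod = run["I_Rhod"].to_numpy(dtype=float)
    if np.all(i_rhod == 0):
        return float("inf"), False
    return float(np.mean(run["I_NBD"].to_numpy(dtype=float) / i_rhod)), True
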