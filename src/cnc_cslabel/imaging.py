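"""Incoherent Z-contrast rendering of atomistic scenes.

High-angle annular dark-field contrast is, to a good approximation,
incoherent: each atom contributes independently an intensity proportional
to Z^1.7, blurred by the finite probe.  A micrograph is therefore rendered
as the sum of normalized Gaussian point-spread functions centered on the
projected (x, y) atom positions, weighted by Z^z_exponent; the beam runs
along -z and the projection discards depth (top and bottom surfaces of a
specimen are indistinguishable).  Shot noise follows from the per-pixel
electron budget set by probe current and dwell time.

This is a deliberate stand-in for full multislice wave-optics: dynamical
diffraction, channeling and detector response are ignored, but relative
peak positions and intensity ordering — the quantities compared against
measured spacings — are preserved.  Scenes can be exported (XYZ/CIF) for
external multislice codes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as _io

__all__ = ["ProbeParams", "Micrograph", "render", "add_noise", "export_scene", "ATOMIC_NUMBER"]

ATOMIC_NUMBER = {"H": 1, "C": 6, "N": 7, "O": 8, "Na": 11, "S": 16, "Cl": 17, "Cs": 55}

_E_CHARGE = 1.602176634e-19  # C


@dataclass(frozen=True)
class ProbeParams:
    """STEM probe and detector settings.

    Collection angles and beam energy are recorded as metadata; the render
    itself is controlled by the probe size (``psf_fwhm_pm``), the pixel
    sampling (``pixel_size_pm``) and the contrast exponent.
    """

    energy_kev: float = 300.0
    convergence_mrad: float = 19.6
    haadf_range_mrad: tuple[float, float] = (62.2, 214.0)
    adf_range_mrad: tuple[float, float] = (19.5, 59.0)
    current_pa: float = 10.0
    dwell_us: float = 3.0
    psf_fwhm_pm: float = 100.0
    pixel_size_pm: float = 20.0
    z_exponent: float = 1.7

    def __post_init__(self):
        if self.psf_fwhm_pm <= 0 or self.pixel_size_pm <= 0:
            raise ValueError("psf_fwhm_pm and pixel_size_pm must be positive")
        if not (1.0 <= self.z_exponent <= 2.0):
            raise ValueError("z_exponent must lie in [1, 2]")

    @property
    def electrons_per_pixel(self) -> float:
        """Electron budget n_e = I * t_dwell / e (~187 at 10 pA, 3 µs)."""
        return self.current_pa * 1e-12 * self.dwell_us * 1e-6 / _E_CHARGE


@dataclass
class Micrograph:
    """2D intensity grid with pixel calibration.

    ``origin`` is the scene coordinate (Å) of the top-left pixel center;
    row index increases toward smaller y (image convention).
    """

    intensity: np.ndarray
    pixel_size_pm: float
    origin: tuple[float, float] = (0.0, 0.0)
    provenance: dict = field(default_factory=dict)

    @property
    def pixel_size_A(self) -> float:
        return self.pixel_size_pm / 100.0

    def pixel_to_xy(self, rows, cols) -> tuple[np.ndarray, np.ndarray]:
        p = self.pixel_size_A
        return self.origin[0] + np.asarray(cols) * p, self.origin[1] - np.asarray(rows) * p

    def xy_to_pixel(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        p = self.pixel_size_A
        return (self.origin[1] - np.asarray(y)) / p, (np.asarray(x) - self.origin[0]) / p


def render(
    scene: pd.DataFrame,
    probe: ProbeParams,
    extent: tuple[float, float, float, float] | None = None,
) -> Micrograph:
    """Render a scene (atom table) to a noise-free micrograph.

    ``extent = (x_min, x_max, y_min, y_max)`` in Å; defaults to the scene
    bounding box plus a 5 Å margin.  Intensity units: Z^z_exponent per
    unit PSF (the PSF integrates to 1 over pixels).
    """
    if len(scene) == 0:
        raise ValueError("cannot render an empty scene")
    xs = scene["x"].to_numpy(float)
    ys = scene["y"].to_numpy(float)
    z_num = scene["element"].map(ATOMIC_NUMBER)
    if z_num.isna().any():
        bad = sorted(set(scene["element"][z_num.isna()]))
        raise ValueError(f"unknown element(s) {bad}")
    amp = z_num.to_numpy(float) ** probe.z_exponent

    px = probe.pixel_size_pm / 100.0
    if extent is None:
        extent = (xs.min() - 5.0, xs.max() + 5.0, ys.min() - 5.0, ys.max() + 5.0)
    x0, x1, y0, y1 = extent
    n_cols = max(int(round((x1 - x0) / px)) + 1, 1)
    n_rows = max(int(round((y1 - y0) / px)) + 1, 1)
    origin = (x0, y1)

    sigma = probe.psf_fwhm_pm / 100.0 / (2.0 * np.sqrt(2.0 * np.log(2.0))) / px  # px
    half = max(int(np.ceil(4.0 * sigma)), 2)
    cols = (xs - x0) / px
    rows = (y1 - ys) / px
    img = np.zeros((n_rows, n_cols))
    base_c = np.floor(cols).astype(int)
    base_r = np.floor(rows).astype(int)
    norm = 1.0 / (2.0 * np.pi * sigma * sigma)
    for dr in range(-half, half + 2):
        rr = base_r + dr
        okr = (rr >= 0) & (rr < n_rows)
        gy = np.exp(-((rr - rows) ** 2) / (2 * sigma * sigma))
        for dc in range(-half, half + 2):
            cc = base_c + dc
            ok = okr & (cc >= 0) & (cc < n_cols)
            if not ok.any():
                continue
            w = amp[ok] * norm * gy[ok] * np.exp(-((cc[ok] - cols[ok]) ** 2) / (2 * sigma * sigma))
            np.add.at(img, (rr[ok], cc[ok]), w)
    return Micrograph(
        intensity=img,
        pixel_size_pm=probe.pixel_size_pm,
        origin=origin,
        provenance={"scene_hash": _io.scene_hash(scene), "noise": False},
    )


def add_noise(img: Micrograph, probe: ProbeParams, dose_scale: float = 1.0, seed: int = 0) -> Micrograph:
    """Apply Poisson shot noise at the probe's per-pixel electron budget.

    The noise-free intensity is scaled so its mean equals
    ``n_e * dose_scale`` expected counts, then counts are drawn pixel-wise
    from a Poisson law and rescaled back to the input intensity units.
    Zero-intensity pixels always yield zero counts.
    """
    if dose_scale < 0:
        raise ValueError("dose_scale must be non-negative")
    if (img.intensity < 0).any():
        raise ValueError("input intensity must be non-negative")
    mean_i = float(img.intensity.mean())
    if mean_i == 0 or dose_scale == 0:
        out = np.zeros_like(img.intensity)
    else:
        n_e = probe.electrons_per_pixel * dose_scale
        lam = img.intensity * (n_e / mean_i)
        rng = np.random.default_rng(seed)
        out = rng.poisson(lam).astype(float) * (mean_i / n_e)
    prov = dict(img.provenance)
    prov.update({"noise": True, "dose_scale": dose_scale, "seed": int(seed)})
    return Micrograph(out, img.pixel_size_pm, img.origin, prov)


def export_scene(scene: pd.DataFrame, path, fmt: str | None = None) -> None:
    """Write a scene as XYZ or CIF (for external multislice codes)."""
    if len(scene) == 0:
        raise ValueError("cannot export an empty scene")
    _io.write_structure(scene, path, fmt)
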