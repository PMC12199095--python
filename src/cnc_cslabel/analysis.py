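"""Interatomic statistics: RDF, line-profile spacings, Cs-row geometry.

These are the measurements that connect images (or detected atom
positions) back to candidate crystal models: a 2D radial distribution
function over detected positions, Gaussian-fitted peak spacings along
intensity profiles, grouping of detections into lines parallel to the
crystal long axis, and the analytic "twin" of those measurements computed
directly from a decorated model's Cs coordinates in projection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import find_peaks
from scipy.spatial.distance import pdist

from .imaging import Micrograph
from .lattice import CNCModel

__all__ = [
    "RDFResult",
    "SpacingReport",
    "rdf",
    "line_profile_spacings",
    "group_rows",
    "model_projected_spacings",
    "compare_models",
    "distinct_spacings",
]

# Gap threshold (Å) for clustering projected positions into lines: half
# the smallest expected inter-row distance (5.2 Å) so that distinct
# crystallographic rows never merge while top/bottom-surface combs of the
# same row do.
ROW_GAP_A = 2.6

# Spacings below this (Å) are treated as the same projected site
# (top/bottom coincidences), not a physical repeat.
_COINCIDENCE_A = 0.5


@dataclass
class RDFResult:
    """2D radial distribution function of a point set."""

    bin_centers: np.ndarray  # nm
    g: np.ndarray
    n_positions: int
    bin_width: float
    r_max: float


@dataclass
class SpacingReport:
    """Measured or predicted repeat distances, in Å, with uncertainties."""

    along_axis_spacings: np.ndarray = field(default_factory=lambda: np.empty(0))
    along_axis_errors: np.ndarray = field(default_factory=lambda: np.empty(0))
    inter_line_spacings: np.ndarray = field(default_factory=lambda: np.empty(0))
    inter_line_errors: np.ndarray = field(default_factory=lambda: np.empty(0))
    axis_direction: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0]))
    method: str = "rows"


def rdf(positions_nm: np.ndarray, bin_width: float = 0.02, r_max: float = 3.0) -> RDFResult:
    """Radial distribution function of 2D positions (nm).

    g(r) = pair_count(r) / (N * rho * 2 pi r dr) with rho the density over
    the bounding box of the positions and ordered pair counting, so g -> 1
    for a Poisson point set.  No edge correction is applied, which biases
    g downward at r comparable to the box size; short distances are also
    depressed whenever nearby points were merged upstream by segmentation.
    """
    pos = np.asarray(positions_nm, dtype=float).reshape(-1, 2)
    n = len(pos)
    if n < 2:
        raise ValueError("need at least 2 positions for an RDF")
    span = pos.max(axis=0) - pos.min(axis=0)
    area = float(np.prod(np.maximum(span, bin_width)))
    rho = n / area
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    counts, _ = np.histogram(pdist(pos), bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    shell = 2.0 * np.pi * centers * bin_width
    g = 2.0 * counts / (n * rho * shell)
    return RDFResult(bin_centers=centers, g=g, n_positions=n, bin_width=bin_width, r_max=r_max)


def _gaussian(x, amp, mu, sigma, base):
    return base + amp * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def _fit_peaks(profile: np.ndarray, step_A: float, min_prominence_frac: float = 0.1):
    """Gaussian-refined peak centers (Å along the profile) and 1-sigma errors."""
    rng = float(profile.max() - profile.min())
    if rng == 0:
        return np.empty(0), np.empty(0)
    idx, _ = find_peaks(profile, prominence=min_prominence_frac * rng)
    centers, errors = [], []
    if len(idx) >= 2:
        typical = int(round(np.median(np.diff(idx))))
    else:
        typical = max(len(profile) // 4, 3)
    half = max(int(round(0.75 * typical)), 2)
    x = np.arange(len(profile), dtype=float)
    for i in idx:
        lo, hi = max(i - half, 0), min(i + half + 1, len(profile))
        xs, ys = x[lo:hi], profile[lo:hi]
        p0 = [profile[i] - ys.min(), float(i), max(typical / 3.0, 1.0), float(ys.min())]
        try:
            popt, pcov = curve_fit(_gaussian, xs, ys, p0=p0, maxfev=4000)
            mu, mu_err = popt[1], math.sqrt(max(pcov[1, 1], 0.0))
        except RuntimeError:
            mu, mu_err = float(i), float("nan")
        if lo <= mu <= hi:
            centers.append(mu * step_A)
            errors.append(mu_err * step_A)
    return np.asarray(centers), np.asarray(errors)


def line_profile_spacings(
    img: Micrograph,
    line: tuple[tuple[float, float], tuple[float, float]],
    width_px: int = 5,
) -> SpacingReport:
    """Peak spacings along an intensity profile between two scene points (Å).

    Intensity is averaged across ``width_px`` perpendicular to the line;
    peaks are refined by least-squares Gaussian fits and spacings are
    differences of adjacent fitted centers, with uncertainties propagated
    from the fit covariances.
    """
    from skimage.measure import profile_line

    (x1, y1), (x2, y2) = line
    r1, c1 = img.xy_to_pixel(x1, y1)
    r2, c2 = img.xy_to_pixel(x2, y2)
    shape = img.intensity.shape
    for r, c in ((r1, c1), (r2, c2)):
        if not (0 <= r <= shape[0] - 1 and 0 <= c <= shape[1] - 1):
            raise ValueError("profile line endpoints must lie inside the image")
    prof = profile_line(
        img.intensity, (float(r1), float(c1)), (float(r2), float(c2)),
        linewidth=width_px, order=1, mode="reflect", reduce_func=np.mean,
    )
    length_A = math.hypot(x2 - x1, y2 - y1)
    step_A = length_A / max(len(prof) - 1, 1)
    centers, errors = _fit_peaks(np.asarray(prof, float), step_A)
    if len(centers) < 2:
        raise ValueError(
            f"fewer than 2 peaks found along the profile (profile={list(np.round(prof, 3))})"
        )
    spac = np.diff(centers)
    errs = np.sqrt(errors[:-1] ** 2 + errors[1:] ** 2)
    d = np.array([x2 - x1, y2 - y1]) / length_A
    return SpacingReport(
        along_axis_spacings=spac, along_axis_errors=errs,
        axis_direction=d, method="profile",
    )


def _principal_axis(pos: np.ndarray) -> np.ndarray:
    centered = pos - pos.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    v = vt[0]
    return v / np.linalg.norm(v)


def group_rows(
    positions: np.ndarray,
    axis_direction: np.ndarray | None = None,
    gap_A: float = ROW_GAP_A,
    units_per_A: float = 1.0,
) -> list[np.ndarray]:
    """Partition positions into lines parallel to the long axis.

    Positions are projected perpendicular to ``axis_direction`` (PCA
    principal axis if not given) and split 1D wherever the sorted
    perpendicular gap exceeds ``gap_A``.  Returns index arrays, each
    ordered along the axis.  ``units_per_A`` converts the position units
    to Å (e.g. 0.1 for nm input).
    """
    pos = np.asarray(positions, dtype=float).reshape(-1, 2)
    if len(pos) < 2:
        raise ValueError("need at least 2 positions to group rows")
    axis = _principal_axis(pos) if axis_direction is None else np.asarray(axis_direction, float)
    axis = axis / np.linalg.norm(axis)
    perp = np.array([-axis[1], axis[0]])
    u = pos @ perp / units_per_A  # Å
    t = pos @ axis
    order = np.argsort(u, kind="mergesort")
    gaps = np.diff(u[order])
    breaks = np.flatnonzero(gaps > gap_A)
    rows = []
    start = 0
    for b in list(breaks) + [len(order) - 1]:
        idx = order[start : b + 1]
        rows.append(idx[np.argsort(t[idx], kind="mergesort")])
        start = b + 1
    return rows


def model_projected_spacings(
    model: CNCModel, rotation_about_001: float = 0.0, gap_A: float = ROW_GAP_A
) -> SpacingReport:
    """Analytic spacings of projected Cs positions (no imaging).

    The model is rotated by ``rotation_about_001`` degrees about its chain
    axis and projected along the +y direction (the beam).  Cs positions
    are grouped into lines parallel to [001]; reported are the adjacent
    line-center distances (perpendicular to the axis) and the
    nearest-neighbor distances along the axis within each line
    (coincident projections closer than 0.5 Å are not repeats and are
    dropped).  This is the analytic twin of measuring a rendered image.
    """
    cs = model.atoms[model.atoms.role.isin(["Cs", "Na"])]
    cs = cs[cs.element == "Cs"]
    if len(cs) == 0:
        raise ValueError("model contains no Cs atoms; decorate it first")
    th = math.radians(rotation_about_001)
    x = cs["x"].to_numpy() * math.cos(th) - cs["y"].to_numpy() * math.sin(th)
    z = cs["z"].to_numpy()
    pos = np.stack([z, x], axis=1)  # axis first -> axis_direction (1, 0)
    rows = group_rows(pos, axis_direction=np.array([1.0, 0.0]), gap_A=gap_A)
    centers = sorted(float(np.mean(pos[r][:, 1])) for r in rows)
    inter = np.diff(centers)
    along = []
    for r in rows:
        t = np.sort(pos[r][:, 0])
        d = np.diff(t)
        along.extend(d[d > _COINCIDENCE_A])
    along = np.asarray(along)
    return SpacingReport(
        along_axis_spacings=along,
        along_axis_errors=np.zeros_like(along),
        inter_line_spacings=inter,
        inter_line_errors=np.zeros(len(inter)),
        axis_direction=np.array([0.0, 0.0, 1.0])[:2],
        method="rows",
    )


def distinct_spacings(values: np.ndarray, tol: float = 0.3) -> list[tuple[float, int]]:
    """Cluster a spacing list into distinct values with multiplicities.

    Returns (mean value, count) sorted by descending count — the "most
    important distance values" of a projection.
    """
    v = np.sort(np.asarray(values, dtype=float))
    if len(v) == 0:
        return []
    groups = []
    start = 0
    for i in range(1, len(v) + 1):
        if i == len(v) or v[i] - v[i - 1] > tol:
            groups.append((float(v[start:i].mean()), i - start))
            start = i
    return sorted(groups, key=lambda t: (-t[1], t[0]))


def compare_models(
    measured: SpacingReport,
    candidates: list[tuple[str, CNCModel, float]],
    tol_distinct: float = 0.3,
) -> pd.DataFrame:
    """Rank candidate models by mean absolute spacing mismatch.

    Each measured spacing (along-axis and inter-line pooled per category)
    is greedily matched to the nearest distinct predicted value of the
    candidate's projection at the given rotation; the score is the mean
    |measured - predicted| in Å, ascending (best first).
    """
    if len(candidates) == 0:
        raise ValueError("no candidate models given")
    m_along = np.asarray(measured.along_axis_spacings, float)
    m_inter = np.asarray(measured.inter_line_spacings, float)
    if len(m_along) + len(m_inter) == 0:
        raise ValueError("measured report contains no spacings")
    rows = []
    for name, model, rot in candidates:
        pred = model_projected_spacings(model, rot)
        devs = []
        for meas, vals in (
            (m_along, pred.along_axis_spacings),
            (m_inter, pred.inter_line_spacings),
        ):
            if len(meas) == 0:
                continue
            if len(vals) == 0:
                devs.extend([np.inf] * len(meas))
                continue
            distinct = np.array([v for v, _ in distinct_spacings(vals, tol_distinct)])
            for mv in meas:
                devs.append(float(np.min(np.abs(distinct - mv))))
        rows.append({"model": name, "rotation_deg": rot, "score_A": float(np.mean(devs))})
    return pd.DataFrame(rows).sort_values("score_A", kind="mergesort").reset_index(drop=True)
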