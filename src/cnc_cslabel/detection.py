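"""Single-atom detection in micrographs.

Pipeline: 3x3 mean smoothing -> per-pixel two-class labeling (heavy atom
vs background, either a robust threshold above the local background or a
supervised random-forest classifier) -> 8-connected segmentation with a
minimum-area filter -> intensity-weighted centroid per segment.  Centroid
positions are reported in scene coordinates (nm); nearby atoms whose
segments merge are, as in experiment, returned as a single detection.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .imaging import Micrograph

__all__ = [
    "AtomDetections",
    "smooth",
    "classify_pixels",
    "segment_and_centroid",
    "match_to_truth",
    "PixelClassifier",
    "MatchResult",
]


@dataclass
class AtomDetections:
    """Detected atom centroids with segment statistics."""

    table: pd.DataFrame  # columns: x_nm, y_nm, area_px, peak, truth_id
    pixel_size_pm: float

    def __len__(self) -> int:
        return len(self.table)

    @property
    def positions_nm(self) -> np.ndarray:
        return self.table[["x_nm", "y_nm"]].to_numpy()


def smooth(img: Micrograph) -> Micrograph:
    """3x3 mean filter (reflection padding at the edges)."""
    if min(img.intensity.shape) < 3:
        raise ValueError("image must be at least 3x3 to smooth")
    out = ndimage.uniform_filter(img.intensity, size=3, mode="reflect")
    prov = dict(img.provenance)
    prov["smoothed"] = True
    return Micrograph(out, img.pixel_size_pm, img.origin, prov)


class PixelClassifier:
    """Supervised per-pixel two-class labeling (heavy atom vs background).

    A random-forest on intensity, multi-scale Gaussian intensity, gradient
    magnitude and Laplacian features — the same contract as interactive
    pixel-classification tools, trained on synthetic frames with known
    label masks.
    """

    SCALES = (1.0, 2.0, 4.0)

    def __init__(self, n_estimators: int = 50, seed: int = 0):
        from sklearn.ensemble import RandomForestClassifier

        self.model = RandomForestClassifier(
            n_estimators=n_estimators, random_state=seed, n_jobs=1
        )
        self.fitted = False

    @staticmethod
    def features(intensity: np.ndarray) -> np.ndarray:
        feats = [intensity]
        for s in PixelClassifier.SCALES:
            g = ndimage.gaussian_filter(intensity, s)
            feats.append(g)
            feats.append(ndimage.gaussian_gradient_magnitude(intensity, s))
            feats.append(ndimage.gaussian_laplace(intensity, s))
        return np.stack([f.ravel() for f in feats], axis=1)

    def fit(self, images: list[np.ndarray], masks: list[np.ndarray]) -> "PixelClassifier":
        X = np.concatenate([self.features(im) for im in images])
        y = np.concatenate([m.ravel().astype(int) for m in masks])
        self.model.fit(X, y)
        self.fitted = True
        return self

    def predict(self, intensity: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise ValueError("classifier has not been trained")
        return self.model.predict(self.features(intensity)).reshape(intensity.shape).astype(bool)

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path) -> "PixelClassifier":
        with open(path, "rb") as fh:
            return pickle.load(fh)


def classify_pixels(
    img: Micrograph,
    mode: str = "threshold",
    k_sigma: float = 3.0,
    background_window: int = 31,
    classifier: PixelClassifier | None = None,
) -> np.ndarray:
    """Binary mask of pixels belonging to heavy-atom spots.

    Threshold mode: pixel > local background (large-window median) plus
    ``k_sigma`` robust standard deviations of the residual.  Learned mode
    requires a trained :class:`PixelClassifier`.
    """
    arr = img.intensity
    if mode == "threshold":
        bg = ndimage.median_filter(arr, size=background_window, mode="reflect")
        resid = arr - bg
        sigma = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
        if sigma == 0:
            # noiseless flat background: anything clearly above it is signal
            peak = float(resid.max())
            return resid > 0.2 * peak if peak > 0 else np.zeros_like(arr, dtype=bool)
        return resid > k_sigma * sigma
    if mode == "learned":
        if classifier is None:
            raise ValueError("learned mode requires a trained PixelClassifier")
        return classifier.predict(arr)
    raise ValueError(f"unknown mode {mode!r} (use 'threshold' or 'learned')")


def segment_and_centroid(
    mask: np.ndarray, img: Micrograph, min_area: int = 4
) -> AtomDetections:
    """8-connected components -> intensity-weighted centroids.

    Components smaller than ``min_area`` pixels are discarded.  Centroids
    use background-subtracted intensity weights for sub-pixel accuracy.
    """
    if mask.shape != img.intensity.shape:
        raise ValueError("mask and image shapes differ")
    lab = cc_label(mask, connectivity=2)
    floor = float(np.median(img.intensity))
    weights = np.clip(img.intensity - floor, 0, None)
    rows = []
    for rp in regionprops(lab, intensity_image=weights):
        if rp.area < min_area:
            continue
        r, c = rp.centroid_weighted
        if not np.isfinite(r):  # zero-weight segment; fall back to geometry
            r, c = rp.centroid
        x, y = img.pixel_to_xy(r, c)
        peak = float(img.intensity[rp.slice][rp.image].max())
        rows.append((float(x) / 10.0, float(y) / 10.0, int(rp.area), peak, -1))
    table = pd.DataFrame(rows, columns=["x_nm", "y_nm", "area_px", "peak", "truth_id"])
    return AtomDetections(table=table, pixel_size_pm=img.pixel_size_pm)


@dataclass
class MatchResult:
    """Greedy one-to-one detection/ground-truth matching and its metrics."""

    pairs: list[tuple[int, int]]  # (detection index, truth index)
    recall: float
    precision: float
    rmse_pm: float
    n_truth: int = 0
    unmatched_truth: list[int] = field(default_factory=list)


def match_to_truth(
    det: AtomDetections, truth_nm: np.ndarray, radius_nm: float = 0.1
) -> MatchResult:
    """Greedy nearest-pair matching within a radius; metrics over matches.

    Ties are broken by ascending distance, then detection index.  RMSE is
    the localization error of matched detections, in pm.
    """
    if radius_nm <= 0:
        raise ValueError("radius must be positive")
    truth_nm = np.asarray(truth_nm, dtype=float).reshape(-1, 2)
    pos = det.positions_nm
    if len(pos) == 0 or len(truth_nm) == 0:
        return MatchResult(
            pairs=[], recall=0.0, precision=0.0 if len(pos) else 1.0,
            rmse_pm=float("nan"), n_truth=len(truth_nm),
            unmatched_truth=list(range(len(truth_nm))),
        )
    d = np.linalg.norm(pos[:, None, :] - truth_nm[None, :, :], axis=2)
    cand = np.argwhere(d <= radius_nm)
    order = np.lexsort((cand[:, 0], d[cand[:, 0], cand[:, 1]]))
    used_det, used_tru, pairs, errs = set(), set(), [], []
    for i in order:
        di, ti = int(cand[i, 0]), int(cand[i, 1])
        if di in used_det or ti in used_tru:
            continue
        used_det.add(di)
        used_tru.add(ti)
        pairs.append((di, ti))
        errs.append(d[di, ti])
    recall = len(pairs) / len(truth_nm)
    precision = len(pairs) / len(pos)
    rmse_pm = float(np.sqrt(np.mean(np.square(errs))) * 1000.0) if errs else float("nan")
    return MatchResult(
        pairs=pairs, recall=recall, precision=precision, rmse_pm=rmse_pm,
        n_truth=len(truth_nm),
        unmatched_truth=[t for t in range(len(truth_nm)) if t not in used_tru],
    )
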