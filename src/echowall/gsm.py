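"""Gray-scale median (GSM) quantification from wall images.

GSM is the 50th percentile of the pixel gray levels (0-255) inside a region
of interest of a B-mode far-wall image: low values mark echolucent
(lipid-rich, rupture-prone) tissue, high values echogenic (fibrous or
calcified) tissue.  Because absolute gray levels depend on acquisition
settings, every image carries a calibration pair -- the darkest lumen
section ("reference black", 0-37) and the brightest adventitia section
("reference white", 104-255) -- and measurements are rescaled per image.

This module also applies the subject-level selection rules (the darkest of
the two thickest plaques across sides; left/right averaging of the
plaque-free common-carotid intima-media GSM), the cohort-level a-priori
adjustment of GSM for the calibration references, and scan-rescan
reproducibility statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ROI",
    "CalibrationPair",
    "GsmMeasurement",
    "ImGsm",
    "pixel_median",
    "calibrate",
    "select_plaque_gsm",
    "compute_im_gsm",
    "adjust_for_calibration",
    "reproducibility_stats",
    "W_TARGET",
]

#: gray level the reference white is mapped to (blood-0 / adventitia-190
#: normalization convention); the reference black maps to 0
W_TARGET = 190.0

PLAQUE_IMT_THRESHOLD_MM = 1.5


@dataclass(frozen=True)
class ROI:
    """A region of interest in pixel coordinates (0-based, row/column).

    Either a half-open rectangle ``(row0, col0, row1, col1)`` or a polygon
    given by its vertices; ``label`` names the anatomical target.
    """

    label: str = "im_complex"
    rect: Optional[tuple[int, int, int, int]] = None
    polygon: Optional[Sequence[tuple[float, float]]] = None

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean pixel mask of the ROI on an image of ``shape``."""
        h, w = shape
        m = np.zeros((h, w), dtype=bool)
        if self.rect is not None:
            r0, c0, r1, c1 = self.rect
            if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
                raise ValueError(f"rectangle {self.rect} outside image bounds {shape}")
            m[r0:r1, c0:c1] = True
        elif self.polygon is not None:
            from skimage.draw import polygon as sk_polygon

            rows = [p[0] for p in self.polygon]
            cols = [p[1] for p in self.polygon]
            rr, cc = sk_polygon(rows, cols, shape=(h, w))
            m[rr, cc] = True
        else:
            raise ValueError("ROI needs either a rect or a polygon")
        if not m.any():
            raise ValueError("ROI covers no pixels")
        return m


@dataclass(frozen=True)
class CalibrationPair:
    """Per-image calibration anchors: reference black and reference white."""

    black: float
    white: float

    def __post_init__(self):
        if not (0 <= self.black <= 37):
            raise ValueError(f"reference black {self.black} outside [0, 37]")
        if not (104 <= self.white <= 255):
            raise ValueError(f"reference white {self.white} outside [104, 255]")
        if self.black >= self.white:
            raise ValueError("reference black must be below reference white")


@dataclass(frozen=True)
class GsmMeasurement:
    """A single GSM measurement with its calibration and location."""

    raw_gsm: float
    calibrated_gsm: float
    calibration: CalibrationPair
    side: str = "left"  # {left, right}
    segment: str = "CC"  # {CC, Bif, ICA}
    imt_of_lesion: Optional[float] = None  # mm, plaque measurements only


@dataclass(frozen=True)
class ImGsm:
    """Left/right-averaged intima-media GSM, flagged if one side missing."""

    value: float
    single_side: bool


def pixel_median(image, roi: ROI) -> float:
    """GSM of an ROI: the 50th percentile of its pixel gray levels.

    For an even pixel count the midpoint of the two central order
    statistics is returned.  ``image`` may be a 2-D array or a
    :class:`~echowall.synth.WallImage`.
    """
    arr = np.asarray(getattr(image, "image", image))
    mask = roi.mask(arr.shape)
    return float(np.median(arr[mask].astype(float)))


def calibrate(raw: float, cal: CalibrationPair, w_target: float = W_TARGET) -> float:
    """Linearly rescale a raw gray level using the image's calibration pair.

    The reference black maps to 0 and the reference white to ``w_target``
    (default 190, the conventional blood/adventitia normalization); the
    result is clipped below at 0.
    """
    value = w_target * (raw - cal.black) / (cal.white - cal.black)
    return float(max(value, 0.0))


def select_plaque_gsm(candidates: Sequence[GsmMeasurement]) -> GsmMeasurement:
    """Pick the subject's plaque-GSM: the darkest of the two thickest plaques.

    Per side (left/right), the lesion with the largest IMT wins, regardless
    of segment; a thickness tie goes to the lower calibrated GSM.  Across
    the (up to two) side winners the lower calibrated GSM is returned, a GSM
    tie going to the left side.  Only lesions with IMT >= 1.5 mm are
    eligible; with none, ``LookupError`` signals "no plaque".
    """
    eligible = [
        m
        for m in candidates
        if m.imt_of_lesion is not None and m.imt_of_lesion >= PLAQUE_IMT_THRESHOLD_MM
    ]
    if not eligible:
        raise LookupError("no eligible lesion (IMT_max >= 1.5 mm) on either side")
    winners = []
    for side in ("left", "right"):
        side_ms = [m for m in eligible if m.side == side]
        if side_ms:
            winners.append(
                min(side_ms, key=lambda m: (-m.imt_of_lesion, m.calibrated_gsm))
            )
    side_order = {"left": 0, "right": 1}
    return min(winners, key=lambda m: (m.calibrated_gsm, side_order[m.side]))


def compute_im_gsm(
    left: Optional[GsmMeasurement], right: Optional[GsmMeasurement]
) -> ImGsm:
    """Average the left and right plaque-free common-carotid GSM.

    With one side missing the other side's value is returned with a
    single-side flag; with both missing an error is raised.
    """
    if left is None and right is None:
        raise ValueError("both sides missing: IM-GSM undefined")
    if left is None or right is None:
        present = left if left is not None else right
        return ImGsm(value=present.calibrated_gsm, single_side=True)
    return ImGsm(
        value=0.5 * (left.calibrated_gsm + right.calibrated_gsm), single_side=False
    )


def adjust_for_calibration(
    gsm: np.ndarray, black: np.ndarray, white: np.ndarray
) -> np.ndarray:
    """A-priori adjustment of GSM for the calibration references.

    Returns the residuals of the least-squares regression of GSM on the
    black and white references (with intercept), re-centered to the
    original grand mean, so the output is uncorrelated with both
    references.  Missing values propagate.  A degenerate design (both
    references constant) returns the input unchanged with a warning.
    """
    gsm = np.asarray(gsm, dtype=float)
    black = np.asarray(black, dtype=float)
    white = np.asarray(white, dtype=float)
    if not (len(gsm) == len(black) == len(white)):
        raise ValueError("gsm, black and white must have equal length")
    if len(gsm) < 3:
        raise ValueError("need at least 3 observations to adjust")
    mask = np.isfinite(gsm) & np.isfinite(black) & np.isfinite(white)
    cols = [np.ones(int(mask.sum()))]
    for ref in (black[mask], white[mask]):
        if ref.std() > 0:
            cols.append(ref)
    if len(cols) == 1:
        warnings.warn(
            "calibration references are constant; GSM returned unadjusted",
            stacklevel=2,
        )
        return gsm.copy()
    D = np.column_stack(cols)
    y = gsm[mask]
    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    out = np.full(gsm.shape, np.nan)
    out[mask] = y - D @ beta + y.mean()
    return out


def reproducibility_stats(pairs: pd.DataFrame) -> dict[str, float]:
    """Scan-rescan agreement: mean/SD of absolute differences and ICC.

    ``pairs`` needs ``scan1`` and ``scan2`` columns (one row per subject).
    The ICC is the one-way random-effects, single-measure estimate
    (between-subject vs within-subject mean squares).
    """
    sub = pairs[["scan1", "scan2"]].dropna()
    if len(sub) < 2:
        raise ValueError("need at least 2 complete pairs")
    a = sub["scan1"].to_numpy(dtype=float)
    b = sub["scan2"].to_numpy(dtype=float)
    d = np.abs(a - b)
    n, k = len(a), 2
    grand = (a.mean() + b.mean()) / 2.0
    means = (a + b) / 2.0
    msb = k * float(((means - grand) ** 2).sum()) / (n - 1)
    msw = float(((a - means) ** 2 + (b - means) ** 2).sum()) / (n * (k - 1))
    icc = (msb - msw) / (msb + (k - 1) * msw) if (msb + msw) > 0 else np.nan
    return {
        "mean_abs_diff": float(d.mean()),
        "sd_abs_diff": float(d.std(ddof=1)),
        "icc": float(icc),
        "n_pairs": n,
    }
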