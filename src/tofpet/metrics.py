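"""Image-quality figures of merit for reconstructed 2-D activity images.

Contrast recovery coefficient (CRC) for hot regions over a pooled
background, peak-to-valley ratio for resolution-rod sections, and the
centre-of-gravity-to-ROI-mean ratio that flags edge (ringing) artefacts at
sharp activity transitions.  A voxel belongs to a disc ROI iff its centre
lies inside the disc; all three metrics are invariant under global image
scaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from tofpet.recon import ImageGrid2D

__all__ = ["ROISpec", "roi_mask", "roi_mean", "crc", "ptv_ratio", "cog_ratio", "nema_background_rois"]


@dataclass(frozen=True)
class ROISpec:
    """Disc region of interest."""

    centre: tuple[float, float]
    diameter: float
    role: str = "hot"

    def __post_init__(self):
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")


def roi_mask(image: ImageGrid2D, roi: ROISpec) -> np.ndarray:
    """Boolean flat mask of voxels whose centres fall inside the ROI disc."""
    xs, ys = image.voxel_centres()
    gx, gy = np.meshgrid(xs, ys)  # shape (ny, nx)
    r2 = (gx - roi.centre[0]) ** 2 + (gy - roi.centre[1]) ** 2
    mask = (r2 <= (roi.diameter / 2.0) ** 2).ravel()
    half = roi.diameter / 2.0
    if (
        abs(roi.centre[0]) + half > -image.x_min
        or abs(roi.centre[1]) + half > -image.y_min
    ):
        raise ValueError("ROI extends beyond the image bounds")
    if not mask.any():
        raise ValueError("ROI contains no voxel centres")
    return mask


def roi_mean(image: ImageGrid2D, roi: ROISpec) -> float:
    return float(image.values[roi_mask(image, roi)].mean())


def crc(image: ImageGrid2D, hot: ROISpec, bkg: Sequence[ROISpec], alpha: float = 4.5) -> float:
    """Contrast recovery coefficient ``((mu_H / mu_B) - 1) / (alpha - 1)``.

    ``mu_B`` pools the voxels of all background ROIs; ``alpha`` is the true
    hot-to-background activity ratio, so perfect recovery gives 1.
    """
    if not alpha > 1:
        raise ValueError("alpha must exceed 1")
    mu_h = roi_mean(image, hot)
    bkg_vox = np.concatenate([image.values[roi_mask(image, r)] for r in bkg])
    mu_b = float(bkg_vox.mean())
    if mu_b <= 0:
        raise ValueError("background mean is zero; CRC undefined")
    return (mu_h / mu_b - 1.0) / (alpha - 1.0)


def ptv_ratio(
    image: ImageGrid2D,
    rod_centres: Sequence[tuple[float, float]],
    valley_points: Sequence[tuple[float, float]] | None = None,
) -> float:
    """Peak-to-valley ratio of a rod section.

    Peaks are the image values at the voxels nearest the rod centres;
    valleys default to the midpoints of nearest-neighbour rod pairs (within
    5% of the minimum centre separation).  Returns ``+inf`` when the valley
    mean is zero.
    """
    if len(rod_centres) < 2:
        raise ValueError("need at least two rods")
    if valley_points is None:
        centres = np.asarray(rod_centres, dtype=float)
        d2 = np.sum((centres[:, None, :] - centres[None, :, :]) ** 2, axis=-1)
        np.fill_diagonal(d2, np.inf)
        dmin = math.sqrt(d2.min())
        ii, jj = np.nonzero((d2 <= (1.05 * dmin) ** 2) & np.triu(np.ones_like(d2, dtype=bool)))
        valley_points = [tuple(0.5 * (centres[i] + centres[j])) for i, j in zip(ii, jj)]
    if not valley_points:
        raise ValueError("no valley points found")
    peak = float(np.mean([image.value_at(*c) for c in rod_centres]))
    valley = float(np.mean([image.value_at(*v) for v in valley_points]))
    if valley == 0:
        return math.inf
    return peak / valley


def cog_ratio(image: ImageGrid2D, roi: ROISpec) -> float:
    """Value at the ROI's intensity centre of gravity over the ROI mean.

    Rises above 1 for centrally peaked sources; dips below 1 when a ring-
    shaped (centre-dipped) edge artefact hollows the source out.
    """
    mask = roi_mask(image, roi)
    vals = image.values[mask]
    total = vals.sum()
    if total <= 0:
        raise ValueError("ROI has zero total intensity")
    xs, ys = image.voxel_centres()
    gx, gy = np.meshgrid(xs, ys)
    cx = float((gx.ravel()[mask] * vals).sum() / total)
    cy = float((gy.ravel()[mask] * vals).sum() / total)
    mean = float(vals.mean())
    return image.value_at(cx, cy) / mean


def nema_background_rois(
    diameter: float,
    placement_radius: float = 34.0,
    n: int = 4,
    angle_offset: float = math.pi / 4.0,
) -> list[ROISpec]:
    """Background ROIs for the 2-D NEMA-IQ section.

    ``n`` discs of the sphere's diameter on the 45-degree diagonals at
    ``placement_radius`` — far enough out that even the largest (22 mm)
    background disc clears every hot disc, yet well inside the background.
    """
    out = []
    for k in range(n):
        a = angle_offset + 2.0 * math.pi * k / n
        out.append(
            ROISpec(
                centre=(placement_radius * math.cos(a), placement_radius * math.sin(a)),
                diameter=diameter,
                role="background",
            )
        )
    return out
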