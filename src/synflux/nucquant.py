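"""Nuclear pCREB immunofluorescence quantification.

Nuclei are segmented from the nuclear-stain channel (Otsu threshold +
connected components); a nucleus counts as neuronal when its centroid
falls inside the (dilated) MAP2-positive somatodendritic mask.  A
fixed-radius circular ROI at each neuronal centroid is transposed to the
pCREB channel, where the per-nucleus mean minus the per-image background
(mean outside all dilated nuclei) is measured.  Visual-field means are
normalized to the control-group mean of the same experiment (CTRL
mean = 100 %), which removes day-to-day staining and illumination
differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import disk

__all__ = [
    "NuclearROI",
    "nuclear_rois",
    "nuclear_intensity",
    "normalize_to_ctrl",
    "quantify_field",
]

logger = logging.getLogger(__name__)

EXPECTED_NUCLEI = (10, 15)


@dataclass
class NuclearROI:
    """Circular ROI over one neuronal nucleus."""

    center: tuple[float, float]      # row, col
    radius: float


def nuclear_rois(
    nuclei_channel: np.ndarray,
    map2_channel: np.ndarray,
    roi_radius: float = 6.0,
    min_area: int = 40,
    map2_dilation_px: int = 5,
) -> list[NuclearROI]:
    """Segment nuclei and keep those belonging to MAP2-positive cells.

    Nuclei: Otsu threshold + connected components (tiny specks below
    ``min_area`` pixels are ignored).  A component is neuronal when its
    centroid lies inside the Otsu-thresholded, ``map2_dilation_px``-dilated
    MAP2 mask.  Returns fixed-radius circular ROIs at the centroids.
    """
    nuclei_channel = np.asarray(nuclei_channel, dtype=float)
    map2_channel = np.asarray(map2_channel, dtype=float)
    if nuclei_channel.shape != map2_channel.shape:
        raise ValueError("nuclei and MAP2 channels must have the same shape")
    if np.ptp(map2_channel) == 0:
        raise ValueError("MAP2 channel is empty; cannot identify neuronal "
                         "nuclei")
    nuc_mask = nuclei_channel > threshold_otsu(nuclei_channel)
    map2_mask = map2_channel > threshold_otsu(map2_channel)
    map2_mask = binary_dilation(map2_mask, structure=disk(map2_dilation_px))

    rois = []
    for region in regionprops(label(nuc_mask)):
        if region.area < min_area:
            continue
        r, c = region.centroid
        if map2_mask[int(round(r)), int(round(c))]:
            rois.append(NuclearROI(center=(r, c), radius=roi_radius))
    if not rois:
        raise ValueError("no neuronal (MAP2-positive) nuclei found")
    n = len(rois)
    if not (EXPECTED_NUCLEI[0] <= n <= EXPECTED_NUCLEI[1]):
        logger.warning("%d neuronal nuclei in field (expected %d-%d)",
                       n, *EXPECTED_NUCLEI)
    return rois


def nuclear_intensity(
    pcreb_channel: np.ndarray,
    rois: list[NuclearROI],
    nuclei_channel: np.ndarray | None = None,
    background_dilation_px: int = 8,
) -> np.ndarray:
    """Background-subtracted mean pCREB intensity per nucleus.

    The per-image background is the mean outside all (dilated) nuclei —
    segmented from ``nuclei_channel`` when given, otherwise approximated
    by excluding dilated ROI disks.
    """
    pcreb_channel = np.asarray(pcreb_channel, dtype=float)
    H, W = pcreb_channel.shape
    yy, xx = np.mgrid[0:H, 0:W]

    if nuclei_channel is not None:
        nuc_mask = np.asarray(nuclei_channel) > threshold_otsu(
            np.asarray(nuclei_channel, dtype=float))
    else:
        nuc_mask = np.zeros((H, W), dtype=bool)
        for roi in rois:
            r, c = roi.center
            nuc_mask |= (yy - r) ** 2 + (xx - c) ** 2 <= roi.radius**2
    bg_mask = ~binary_dilation(nuc_mask, structure=disk(background_dilation_px))
    if not bg_mask.any():
        raise ValueError("background region is empty after excluding nuclei")
    background = float(pcreb_channel[bg_mask].mean())

    values = np.empty(len(rois))
    for i, roi in enumerate(rois):
        r, c = roi.center
        m = (yy - r) ** 2 + (xx - c) ** 2 <= roi.radius**2
        if not m.any():
            raise ValueError(f"ROI {i} at {roi.center} covers no pixels")
        values[i] = pcreb_channel[m].mean() - background
    return values


def normalize_to_ctrl(
    table: pd.DataFrame,
    control: str = "CTRL",
    value_col: str = "mean_if",
) -> pd.DataFrame:
    """Express visual-field means as percent of the same-experiment
    control mean.

    ``table`` is long-format with columns ``experiment``, ``condition``,
    and ``value_col`` (one row per visual field).  Every experiment must
    contain the control condition.  Adds ``normalized_pct``.
    """
    table = table.copy()
    out = []
    for exp, grp in table.groupby("experiment", sort=True):
        ctrl_vals = grp.loc[grp["condition"] == control, value_col]
        if ctrl_vals.empty:
            raise ValueError(f"experiment {exp!r} has no {control!r} group")
        ctrl_mean = ctrl_vals.mean()
        if ctrl_mean <= 0:
            raise ValueError(f"experiment {exp!r}: control mean is not positive")
        g = grp.copy()
        g["normalized_pct"] = 100.0 * g[value_col] / ctrl_mean
        out.append(g)
    return pd.concat(out, ignore_index=True)


def quantify_field(
    pcreb_channel: np.ndarray,
    nuclei_channel: np.ndarray,
    map2_channel: np.ndarray,
    roi_radius: float = 6.0,
) -> tuple[float, np.ndarray]:
    """Convenience: segment, measure, and return (field mean, per-nucleus
    values) for one three-channel image."""
    rois = nuclear_rois(nuclei_channel, map2_channel, roi_radius=roi_radius)
    values = nuclear_intensity(pcreb_channel, rois, nuclei_channel=nuclei_channel)
    return float(values.mean()), values
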