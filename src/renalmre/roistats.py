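"""Per-ROI summaries of the biomechanical parameter maps.

ROIs are the gross anatomical renal compartments (cortex, medulla, sinus,
vessel), the composite "vessel_sinus" (sinus plus vessels) and "kidneys"
(everything).  Statistics (mean, median, sample SD, RMS) are computed over
valid voxels only; invalid voxels are excluded rather than zero-filled.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from .fields import LabelMap, ParameterMaps

#: ROI name -> compartment labels it unites.
DEFAULT_ROIS = {
    "cortex": ("cortex",),
    "medulla": ("medulla",),
    "sinus": ("sinus",),
    "vessel": ("vessel",),
    "vessel_sinus": ("sinus", "vessel"),
    "kidneys": ("cortex", "medulla", "sinus", "vessel"),
}

#: ROI pairs whose differences are reported (first minus second).
DEFAULT_PAIRS = (
    ("cortex", "medulla"),
    ("cortex", "sinus"),
    ("medulla", "sinus"),
    ("cortex", "vessel_sinus"),
    ("medulla", "vessel_sinus"),
    ("cortex", "vessel"),
    ("medulla", "vessel"),
    ("sinus", "vessel"),
)


def present_rois(labels: LabelMap, rois=None) -> dict:
    """Filter an ROI table down to compartments present in the label map."""
    rois = rois or DEFAULT_ROIS
    out = {}
    for roi, names in rois.items():
        kept = tuple(n for n in names if labels.mask(n).any())
        if kept:
            out[roi] = kept
    return out


def erode_mask(mask: np.ndarray, n: int = 2) -> np.ndarray:
    """Binary erosion by ``n`` voxels (6-connected structuring element)."""
    if n <= 0:
        return np.asarray(mask, dtype=bool)
    return ndimage.binary_erosion(mask, iterations=n, border_value=0)


def roi_mask(labels: LabelMap, roi: str, rois=None) -> np.ndarray:
    rois = rois or DEFAULT_ROIS
    if roi not in rois:
        raise ValueError(f"unknown ROI '{roi}'")
    m = np.zeros(labels.shape, dtype=bool)
    for name in rois[roi]:
        m |= labels.mask(name)
    return m


def innermost_slice_mask(shape, n_slices: int) -> np.ndarray:
    """Mask selecting the ``n_slices`` central slices along the slab axis."""
    nz = shape[2]
    lo = (nz - n_slices) // 2
    m = np.zeros(shape, dtype=bool)
    m[:, :, lo : lo + n_slices] = True
    return m


def summarize_roi(
    maps: ParameterMaps,
    labels: LabelMap,
    rois=None,
    innermost_slices: int | None = None,
    erode: int = 0,
) -> pd.DataFrame:
    """Mean / median / sample SD / RMS of each parameter per ROI.

    ``innermost_slices`` optionally restricts the statistics to the central
    slices of the slab (the slices with the most reliable inversion);
    ``erode`` shrinks every ROI by that many voxels first, excluding
    partial-volume boundary voxels.  Raises naming any ROI left without
    valid voxels.
    """
    rois = rois or DEFAULT_ROIS
    if maps.valid.shape != labels.shape:
        raise ValueError("maps and labels must share one grid")
    restrict = np.ones(labels.shape, dtype=bool)
    if innermost_slices is not None:
        restrict &= innermost_slice_mask(labels.shape, innermost_slices)
    rows = []
    for roi in rois:
        m = erode_mask(roi_mask(labels, roi, rois), erode) & restrict & maps.valid
        if not m.any():
            raise ValueError(f"ROI '{roi}' has no valid voxels")
        for param, arr in maps.as_dict().items():
            v = arr[m]
            v = v[np.isfinite(v)]
            if v.size == 0:
                raise ValueError(f"ROI '{roi}' has no valid voxels for {param}")
            rows.append(
                {
                    "roi": roi,
                    "parameter": param,
                    "n_voxels": int(v.size),
                    "mean": float(np.mean(v)),
                    "median": float(np.median(v)),
                    "sd": float(np.std(v, ddof=1)) if v.size > 1 else 0.0,
                    "rms": float(np.sqrt(np.mean(v**2))),
                }
            )
    return pd.DataFrame(rows)


def roi_differences(summary: pd.DataFrame, pairs=DEFAULT_PAIRS) -> pd.DataFrame:
    """Differences of ROI medians, first-minus-second, per parameter."""
    known = set(summary["roi"])
    rows = []
    for a, b in pairs:
        if a not in known or b not in known:
            raise ValueError(f"unknown ROI pair ({a}, {b})")
        for param in summary["parameter"].unique():
            med = summary.set_index(["roi", "parameter"])["median"]
            rows.append(
                {
                    "pair": f"{a}-{b}",
                    "parameter": param,
                    "difference": float(med[(a, param)] - med[(b, param)]),
                }
            )
    return pd.DataFrame(rows)


def voxels_per_wavelength(c_s: float, f: float, voxel_mm: float) -> float:
    """Shear wavelength over voxel size, to one decimal.

    ``(c_s / f)`` is the wavelength in metres; dividing by the voxel edge
    gives the sampling density of the wave.  Around 8 voxels per wavelength
    is the recommended operating point for direct inversion.
    """
    if c_s <= 0 or f <= 0 or voxel_mm <= 0:
        raise ValueError("all inputs must be positive")
    return round((c_s / f) * 1000.0 / voxel_mm, 1)


def tidy_summary(
    summary: pd.DataFrame,
    subject: str = "phantom",
    side: str = "left",
    hydration: str = "fasting",
) -> pd.DataFrame:
    """Long-format (subject, side, hydration_state, roi, parameter,
    statistic, value) table consumed by the cohort statistics stage."""
    rows = []
    for _, r in summary.iterrows():
        for stat in ("mean", "median", "sd", "rms"):
            rows.append(
                {
                    "subject": subject,
                    "side": side,
                    "hydration_state": hydration,
                    "roi": r["roi"],
                    "parameter": r["parameter"],
                    "statistic": stat,
                    "value": r[stat],
                }
            )
    return pd.DataFrame(rows)
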