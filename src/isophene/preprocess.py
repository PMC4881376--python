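"""From raw ion images to per-ROI accumulated counts.

Pipeline order: dead-time correction (per plane, rate-based) → plane
alignment (integer shifts against the biomass channel) → plane accumulation
over the common overlap → ROI extraction (supplied mask or automatic
thresholding of the 14N12C image) → per-ROI count tabulation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .io import CHANNEL_COLUMNS, IonImageStack
from .isotope import COUNT_COLUMNS, KEY_COLUMNS

DEFAULT_DEAD_TIME = 44e-9  # seconds; typical electron-multiplier dead time
REFERENCE_CHANNEL = "14N12C"  # biomass proxy, richest in structure


@dataclass(frozen=True)
class InstrumentParams:
    """Detector timing constants for the dead-time correction."""

    dead_time: float = DEFAULT_DEAD_TIME
    dwell_time: float = 0.015

    def __post_init__(self):
        if self.dwell_time <= 0:
            raise ValueError("dwell_time must be > 0")
        if self.dead_time < 0:
            raise ValueError("dead_time must be >= 0")


class SaturationError(ValueError):
    """A pixel's count rate saturates the detector (r·τ ≥ 1)."""


def dead_time_correct(stack: IonImageStack, params: InstrumentParams | None = None
                      ) -> IonImageStack:
    """Correct pulse-counting dead-time losses per pixel, plane and channel.

    corrected = measured / (1 − (measured/dwell)·τ).  Strictly increasing in
    the measured counts; the identity when τ = 0.
    """
    if params is None:
        params = InstrumentParams(dwell_time=stack.dwell_time)
    tau = params.dead_time
    counts = stack.counts.astype(float)
    loss = (counts / params.dwell_time) * tau
    if (loss >= 1.0).any():
        ch, pl, row, col = np.unravel_index(int(np.argmax(loss)), loss.shape)
        raise SaturationError(
            f"saturated pixel: channel {stack.channels[ch].label}, plane {pl}, "
            f"pixel ({row}, {col})")
    corrected = counts / (1.0 - loss)
    return replace(stack, counts=corrected)


class AlignmentError(ValueError):
    pass


def align_planes(stack: IonImageStack, reference_channel: str = REFERENCE_CHANNEL,
                 max_shift: int = 10) -> np.ndarray:
    """Integer (dy, dx) shift per plane maximizing cross-correlation.

    Each plane of the reference channel is correlated against plane 0;
    the search is restricted to ±``max_shift`` pixels.  Plane 0 has shift
    (0, 0) by construction.
    """
    ref = stack.counts[stack.channel_index(reference_channel)].astype(float)
    n_planes = ref.shape[0]
    base = ref[0] - ref[0].mean()
    if not base.any():
        raise AlignmentError("flat (zero-variance) reference plane")
    F0 = np.fft.rfft2(base)
    shifts = np.zeros((n_planes, 2), dtype=int)
    for p in range(1, n_planes):
        img = ref[p] - ref[p].mean()
        if not img.any():
            raise AlignmentError(f"flat reference plane {p}")
        # circular cross-correlation of plane p against plane 0
        corr = np.fft.irfft2(F0 * np.conj(np.fft.rfft2(img)), s=base.shape)
        h, w = corr.shape
        dys = np.r_[0:max_shift + 1, -max_shift:0]
        dxs = np.r_[0:max_shift + 1, -max_shift:0]
        window = corr[np.ix_(dys % h, dxs % w)]
        i, j = np.unravel_index(int(np.argmax(window)), window.shape)
        shifts[p] = (dys[i], dxs[j])
    return shifts


def accumulate_planes(stack: IonImageStack, shifts: np.ndarray | None = None
                      ) -> np.ndarray:
    """Sum aligned planes per channel over the common overlap region.

    Each plane is translated by its (dy, dx) shift; pixels not covered by
    every plane are set to zero (excluded).  With zero shifts the sum is
    exact and conserves total counts.
    Returns an array (channel, row, col).
    """
    c, n_planes, h, w = stack.counts.shape
    if shifts is None:
        shifts = np.zeros((n_planes, 2), dtype=int)
    shifts = np.asarray(shifts, dtype=int)
    if shifts.shape[0] != n_planes:
        raise ValueError("shifts must cover every plane")
    acc = np.zeros((c, h, w), dtype=float)
    covered = np.zeros((h, w), dtype=int)
    for p in range(n_planes):
        dy, dx = shifts[p]
        src_y = slice(max(0, -dy), min(h, h - dy))
        src_x = slice(max(0, -dx), min(w, w - dx))
        dst_y = slice(max(0, dy), min(h, h + dy))
        dst_x = slice(max(0, dx), min(w, w + dx))
        acc[:, dst_y, dst_x] += stack.counts[:, p, src_y, src_x]
        covered[dst_y, dst_x] += 1
    overlap = covered == n_planes
    acc[:, ~overlap] = 0.0
    return acc


def extract_rois_auto(image: np.ndarray, threshold: float | None = None,
                      min_area_px: int = 20) -> np.ndarray:
    """Automatic ROI extraction from an accumulated biomass (14N12C) image.

    Pixels above the threshold (Otsu if not given) are grouped by
    8-connectivity; components smaller than ``min_area_px`` are discarded;
    the survivors are labeled 1..n in raster-scan order of their first
    pixel.  An empty foreground yields an all-background mask.
    """
    image = np.asarray(image, dtype=float)
    if (image < 0).any():
        raise ValueError("image must be nonnegative")
    if threshold is None:
        if image.max() == image.min():
            return np.zeros(image.shape, dtype=np.int64)
        threshold = threshold_otsu(image)
    fg = image > threshold
    if not fg.any():
        return np.zeros(image.shape, dtype=np.int64)
    lab = cc_label(fg, connectivity=2)
    out = np.zeros_like(lab, dtype=np.int64)
    next_id = 1
    # skimage labels components in raster order of first pixel already;
    # renumber after the size filter to keep ids contiguous.
    for comp_id in range(1, lab.max() + 1):
        member = lab == comp_id
        if member.sum() >= min_area_px:
            out[member] = next_id
            next_id += 1
    return out


def tabulate_roi_counts(accumulated: np.ndarray, mask: np.ndarray,
                        stack: IonImageStack | None = None,
                        session: str = "session", region: str = "region",
                        n_planes: int | None = None) -> pd.DataFrame:
    """Accumulated counts, centroid and area per ROI.

    Per channel, the ROI count is the sum of accumulated counts over member
    pixels.  Poisson counting uncertainties (sqrt of counts) are reported as
    ``sigma_<col>`` annotation columns.  Centroids are unweighted pixel
    means, 0-based, x = column.
    """
    accumulated = np.asarray(accumulated, dtype=float)
    mask = np.asarray(mask)
    if accumulated.shape[1:] != mask.shape:
        raise ValueError("mask and accumulated images must share dimensions")
    if stack is not None:
        labels = [c.label for c in stack.channels]
        meta = stack.session_meta
        session = meta.get("session", session)
        region = meta.get("region", region)
        if n_planes is None:
            n_planes = stack.n_planes
    else:
        labels = list(CHANNEL_COLUMNS)
    if n_planes is None:
        n_planes = 1
    roi_ids = np.unique(mask)
    roi_ids = roi_ids[roi_ids > 0]
    rows = []
    for rid in roi_ids:
        member = mask == rid
        ys, xs = np.nonzero(member)
        row = {"session": session, "region": region, "roi_id": int(rid)}
        for i, lab in enumerate(labels):
            col = CHANNEL_COLUMNS[lab]
            total = float(accumulated[i][member].sum())
            row[col] = total
            row[f"sigma_{col}"] = float(np.sqrt(total))
        row["centroid_x"] = float(xs.mean())
        row["centroid_y"] = float(ys.mean())
        row["area_px"] = int(member.sum())
        row["n_planes"] = int(n_planes)
        rows.append(row)
    cols = (KEY_COLUMNS + COUNT_COLUMNS + ["centroid_x", "centroid_y", "area_px", "n_planes"]
            + [f"sigma_{c}" for c in COUNT_COLUMNS])
    return pd.DataFrame(rows, columns=cols)


def stack_to_roi_table(stack: IonImageStack, mask: np.ndarray | None = None,
                       params: InstrumentParams | None = None,
                       align: bool = True, min_area_px: int = 20) -> pd.DataFrame:
    """Convenience pipeline: dead-time correct, align, accumulate, tabulate."""
    corrected = dead_time_correct(stack, params)
    shifts = align_planes(corrected) if align and stack.n_planes > 1 else None
    acc = accumulate_planes(corrected, shifts)
    if mask is None:
        mask = extract_rois_auto(acc[stack.channel_index(REFERENCE_CHANNEL)],
                                 min_area_px=min_area_px)
    return tabulate_roi_counts(acc, mask, stack=stack)
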