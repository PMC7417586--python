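"""Sub-pixel bead tracking, needle-contour extraction and force-feedback
replay on image sequences.

The measurement chain mirrors the live instrument software: the region of
interest is binarized by automatic (Otsu) thresholding, beads are found by
blob detection with a size filter, a template of the chosen bead drives
normalized cross-correlation tracking with parabolic sub-pixel refinement,
the needle contour is the largest border-touching dark component, and the
bead–needle distance (shortest Euclidean distance from bead centre to the
contour) feeds the calibration inverse to replay the constant-force
feedback loop offline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import feature, filters, measure

from .calibration import (CalibrationModel, CalibrationRangeWarning,
                          ForceOutOfRangeError, required_current)
from .images import ImageStack

__all__ = [
    "Blob", "BeadDetection", "TrackResult", "NeedleNotFoundError",
    "binarize", "detect_beads", "track_template", "needle_distance",
    "feedback_replay", "track_stack",
]


class NeedleNotFoundError(RuntimeError):
    """No border-touching foreground component in the mask."""


def binarize(frame: np.ndarray, roi=None, dark_foreground: bool = True) -> np.ndarray:
    """Binarize a frame (or its ROI) by Otsu thresholding.

    Foreground means the dark objects (bead, needle) on the bright
    background; set ``dark_foreground=False`` for inverted-contrast input.
    A constant image yields an empty mask with a warning.
    """
    img = np.asarray(frame)
    if roi is not None:
        r0, c0, h, w = roi
        if r0 < 0 or c0 < 0 or r0 + h > img.shape[0] or c0 + w > img.shape[1]:
            raise ValueError("roi must lie within the frame")
        img = img[r0:r0 + h, c0:c0 + w]
    if np.ptp(img) == 0:
        warnings.warn("constant image: empty mask", stacklevel=2)
        return np.zeros(img.shape, dtype=bool)
    thr = filters.threshold_otsu(img)
    # skimage's convention puts the threshold value itself in the lower
    # class, so dark foreground uses <=
    return (img <= thr) if dark_foreground else (img > thr)


@dataclass(frozen=True)
class Blob:
    centroid_px: tuple[float, float]  # (row, col)
    area_px: int
    equivalent_diameter_px: float


@dataclass(frozen=True)
class BeadDetection:
    beads: tuple[Blob, ...]
    fused: tuple[Blob, ...]          # bead-sized bulges merged into the needle
    needle_present: bool
    rejected: tuple[tuple[Blob, str], ...] = ()


def _needle_label(labels: np.ndarray) -> int:
    """Label of the largest component touching the image border (0 if none)."""
    border = np.concatenate([labels[0], labels[-1], labels[:, 0], labels[:, -1]])
    cands = np.unique(border[border > 0])
    if cands.size == 0:
        return 0
    areas = [(labels == lab).sum() for lab in cands]
    return int(cands[int(np.argmax(areas))])


def detect_beads(mask: np.ndarray, expected_diameter_px: float,
                 tolerance: float = 0.3) -> BeadDetection:
    """Blob detection with a size filter.

    Connected components whose equivalent diameter lies within
    ``tolerance`` (fractional) of the expected bead diameter are kept.  The
    largest border-touching component is taken to be the needle and
    excluded; bead-sized bulges of the needle component (detected as local
    maxima of its distance transform near the expected radius) are reported
    as "fused" — a bead overlapping the needle contour cannot be tracked.
    """
    if not expected_diameter_px > 1:
        raise ValueError("expected diameter must exceed 1 px")
    labels = measure.label(mask)
    needle_lab = _needle_label(labels)
    beads, rejected = [], []
    for rp in measure.regionprops(labels):
        blob = Blob(centroid_px=tuple(rp.centroid), area_px=int(rp.area),
                    equivalent_diameter_px=float(rp.equivalent_diameter_area))
        if rp.label == needle_lab:
            continue
        rel = abs(blob.equivalent_diameter_px - expected_diameter_px) / expected_diameter_px
        if rel <= tolerance:
            beads.append(blob)
        else:
            reason = "too_small" if blob.equivalent_diameter_px < expected_diameter_px else "too_large"
            rejected.append((blob, reason))
    fused = []
    if needle_lab:
        from scipy import ndimage
        comp = labels == needle_lab
        edt = ndimage.distance_transform_edt(comp)
        r_exp = expected_diameter_px / 2.0
        peaks = feature.peak_local_max(edt, min_distance=max(int(r_exp), 1),
                                       exclude_border=True)
        for rr, cc in peaks:
            val = edt[rr, cc]
            if abs(val - r_exp) / r_exp <= tolerance:
                fused.append(Blob(centroid_px=(float(rr), float(cc)),
                                  area_px=int(np.pi * val ** 2),
                                  equivalent_diameter_px=float(2 * val)))
    return BeadDetection(beads=tuple(beads), fused=tuple(fused),
                         needle_present=bool(needle_lab),
                         rejected=tuple(rejected))


def _parabolic_offset(cm1: float, c0: float, cp1: float) -> float:
    denom = cm1 - 2.0 * c0 + cp1
    if denom >= -1e-12:   # not a proper maximum
        return 0.0
    return float(np.clip(0.5 * (cm1 - cp1) / denom, -0.5, 0.5))


@dataclass
class TrackResult:
    """Per-frame sub-pixel bead positions and tracking quality.

    ``positions_um`` holds (x, y) = (col, row) * pixel_size.  Optional
    needle outputs are attached by :func:`track_stack`.
    """

    positions_um: np.ndarray
    positions_px: np.ndarray
    quality: np.ndarray
    time_s: np.ndarray
    terminated_at: int | None = None
    termination_reason: str | None = None
    needle_contour_px: np.ndarray | None = None
    bead_needle_distance_um: np.ndarray | None = None

    def to_frame(self):
        import pandas as pd
        df = pd.DataFrame({
            "frame": np.arange(len(self.time_s)),
            "t_s": self.time_s,
            "x_um": self.positions_um[:, 0],
            "y_um": self.positions_um[:, 1],
            "peak_corr": self.quality,
        })
        if self.bead_needle_distance_um is not None:
            df["distance_um"] = self.bead_needle_distance_um
        return df


def track_template(stack: ImageStack, template: np.ndarray,
                   start_px: tuple[float, float],
                   search_radius_px: int = 12,
                   min_correlation: float = 0.5) -> TrackResult:
    """Track a bead by normalized cross-correlation against a fixed template.

    ``start_px`` is the (row, col) template-centre position in the first
    frame.  Each frame is searched in a window of ``search_radius_px``
    around the previous position; the correlation peak is refined by
    parabolic interpolation of its 3x3 neighbourhood.  Tracking stops when
    the peak correlation falls below ``min_correlation``.
    """
    template = np.asarray(template, dtype=float)
    th, tw = template.shape
    H, W = stack.shape
    r0 = int(round(start_px[0])) - th // 2
    c0 = int(round(start_px[1])) - tw // 2
    if r0 < 0 or c0 < 0 or r0 + th > H or c0 + tw > W:
        raise ValueError("template must fit inside the first frame around start")
    n = len(stack)
    pos = np.full((n, 2), np.nan)          # (row, col)
    quality = np.full(n, np.nan)
    prev = np.asarray(start_px, dtype=float)
    terminated_at = None
    reason = None
    for i in range(n):
        pr, pc = int(round(prev[0])), int(round(prev[1]))
        rlo = max(pr - th // 2 - search_radius_px, 0)
        rhi = min(pr + th // 2 + search_radius_px + 1, H)
        clo = max(pc - tw // 2 - search_radius_px, 0)
        chi = min(pc + tw // 2 + search_radius_px + 1, W)
        window = stack.frames[i, rlo:rhi, clo:chi].astype(float)
        if window.shape[0] < th or window.shape[1] < tw:
            terminated_at, reason = i, "search window left the frame"
            break
        resp = feature.match_template(window, template, pad_input=True)
        peak = np.unravel_index(np.argmax(resp), resp.shape)
        q = float(resp[peak])
        if q < min_correlation:
            terminated_at, reason = i, f"correlation {q:.3f} below threshold"
            break
        dr = dc = 0.0
        if 0 < peak[0] < resp.shape[0] - 1:
            dr = _parabolic_offset(resp[peak[0] - 1, peak[1]], q, resp[peak[0] + 1, peak[1]])
        if 0 < peak[1] < resp.shape[1] - 1:
            dc = _parabolic_offset(resp[peak[0], peak[1] - 1], q, resp[peak[0], peak[1] + 1])
        row = rlo + peak[0] + dr
        col = clo + peak[1] + dc
        pos[i] = (row, col)
        quality[i] = q
        prev = pos[i]
    valid = ~np.isnan(pos[:, 0])
    pos = pos[valid]
    quality = quality[valid]
    time_s = stack.timestamps[valid]
    positions_um = pos[:, ::-1] * stack.pixel_size_um  # (x, y) = (col, row)
    return TrackResult(positions_um=positions_um, positions_px=pos,
                       quality=quality, time_s=time_s,
                       terminated_at=terminated_at, termination_reason=reason)


def needle_distance(mask: np.ndarray, bead_position_px: tuple[float, float],
                    pixel_size_um: float = 1.0):
    """Needle contour and shortest Euclidean bead–needle distance.

    The needle is the largest foreground component touching the image
    border.  Returns ``(contour_px, distance_um)`` where ``contour_px`` is
    an (n, 2) array of sub-pixel (row, col) contour points.  A bead centre
    inside the needle component gives distance 0.
    """
    labels = measure.label(mask)
    lab = _needle_label(labels)
    if lab == 0:
        raise NeedleNotFoundError("no border-touching foreground component")
    comp = labels == lab
    contours = measure.find_contours(comp.astype(float), 0.5)
    contour = np.vstack(contours)
    br, bc = float(bead_position_px[0]), float(bead_position_px[1])
    ir, ic = int(round(br)), int(round(bc))
    if 0 <= ir < comp.shape[0] and 0 <= ic < comp.shape[1] and comp[ir, ic]:
        return contour, 0.0
    d = np.min(np.hypot(contour[:, 0] - br, contour[:, 1] - bc))
    return contour, float(d * pixel_size_um)


@dataclass(frozen=True)
class FeedbackReplay:
    currents_A: np.ndarray
    errors: tuple[tuple[int, str], ...]
    n_clamped: int


def feedback_replay(cal: CalibrationModel, target_force_nN: float,
                    distances_um) -> FeedbackReplay:
    """Replay the constant-force feedback loop: per-frame coil current from
    the calibration inverse.

    Frames where the force is unattainable get NaN current and an error
    record; the schedule is still returned.
    """
    distances_um = np.asarray(distances_um, dtype=float)
    currents = np.full(distances_um.shape, np.nan)
    errors = []
    n_clamped = 0
    hi = min(cal.saturation_current, cal.current_range[1])
    lo = cal.current_range[0]
    for i, d in enumerate(distances_um):
        try:
            I = required_current(cal, target_force_nN, d)
        except ForceOutOfRangeError as exc:
            errors.append((i, str(exc)))
            continue
        if I > hi:
            warnings.warn(f"frame {i}: required current {I:.3g} A clamped to "
                          f"{hi} A (saturation)", CalibrationRangeWarning,
                          stacklevel=2)
            errors.append((i, f"required current {I:.4g} A above saturation"))
            currents[i] = hi
            n_clamped += 1
        elif I < lo:
            errors.append((i, f"required current {I:.4g} A below the "
                              "calibrated range"))
        else:
            currents[i] = I
    return FeedbackReplay(currents_A=currents, errors=tuple(errors),
                          n_clamped=n_clamped)


def track_stack(stack: ImageStack, expected_diameter_um: float | None = None,
                min_correlation: float = 0.5,
                template_scale: float = 1.6) -> TrackResult:
    """High-level pipeline on a stack: binarize, detect the bead, build a
    template, track it, and attach the per-frame needle distance.

    Uses the first frame for detection and needle-contour extraction (the
    needle is static during a measurement).
    """
    first = stack.crop_roi(0)
    off_r = off_c = 0
    if stack.roi is not None:
        off_r, off_c, _, _ = stack.roi
    mask = binarize(first)
    if expected_diameter_um is None:
        expected_diameter_um = 4.5
    exp_px = expected_diameter_um / stack.pixel_size_um
    det = detect_beads(mask, exp_px)
    if not det.beads:
        raise RuntimeError("no bead of the expected size found")
    blob = max(det.beads, key=lambda b: b.area_px)
    tsize = int(round(exp_px * template_scale)) | 1
    br = int(round(blob.centroid_px[0])) + off_r
    bc = int(round(blob.centroid_px[1])) + off_c
    half = tsize // 2
    H, W = stack.shape
    br = int(np.clip(br, half, H - half - 1))
    bc = int(np.clip(bc, half, W - half - 1))
    template = stack.frames[0, br - half:br + half + 1,
                            bc - half:bc + half + 1].astype(float)
    result = track_template(stack, template, (br, bc),
                            min_correlation=min_correlation)
    # correlation localizes the template grid, not the bead: shift all
    # positions by the sub-pixel offset of the bead (dark-mass centroid)
    # within the template itself
    border = np.concatenate([template[0], template[-1],
                             template[:, 0], template[:, -1]])
    weights = np.clip(float(np.median(border)) - template, 0.0, None)
    if weights.sum() > 0:
        rr, cc = np.mgrid[0:template.shape[0], 0:template.shape[1]]
        d_row = float((weights * rr).sum() / weights.sum()) - half
        d_col = float((weights * cc).sum() / weights.sum()) - half
        result.positions_px = result.positions_px + np.array([d_row, d_col])
        result.positions_um = result.positions_px[:, ::-1] * stack.pixel_size_um
    try:
        contour, _ = needle_distance(mask, blob.centroid_px, stack.pixel_size_um)
        contour = contour + np.array([off_r, off_c])
        dists = np.empty(len(result.time_s))
        for i, (row, col) in enumerate(result.positions_px):
            dists[i] = np.min(np.hypot(contour[:, 0] - row,
                                       contour[:, 1] - col)) * stack.pixel_size_um
        result.needle_contour_px = contour
        result.bead_needle_distance_um = dists
    except NeedleNotFoundError:
        pass
    return result
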