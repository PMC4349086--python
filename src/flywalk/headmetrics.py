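"""Interocular distance from ocelli landmarks and eye-edge contrast.

The IOD is measured on the brightest red frame: the head ROI comes from
the body model, the ocelli triangle is found by normalised
cross-correlation against a three-dot template, and the luminance along
the line through the two posterior ocelli is scanned outward; the
outermost derivative peaks above threshold on each side mark the inner
eye edges, whose separation is the interocular distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import match_template, peak_local_max

from .config import HeadConfig
from .templates import ocelli_template_image


class HeadMeasurementError(RuntimeError):
    pass


@dataclass
class HeadMeasurement:
    ocelli_posterior: np.ndarray  # (2, 2) sub-pixel (row, col)
    scan_point: np.ndarray
    scan_direction: np.ndarray
    eye_edges: np.ndarray  # (2, 2) points
    iod_px: float
    iod_mm: float


def select_brightest_red_frame(red_frames: np.ndarray, fg_masks=None) -> int:
    """Index of the frame with the highest mean red luminance on the fly.

    Ties resolve to the earliest frame.
    """
    means = []
    for i, frame in enumerate(red_frames):
        if fg_masks is not None:
            m = fg_masks[i]
            means.append(frame[m].mean() if m.any() else 0.0)
        else:
            means.append(float(np.asarray(frame, dtype=float).mean()))
    return int(np.argmax(means))


def locate_head(body_model, margin: int = 5) -> tuple[slice, slice]:
    """Head ROI: the head segment's bounding box dilated by ``margin``."""
    head = body_model.segment_mask("head")
    if not head.any():
        raise HeadMeasurementError("body model has no head segment")
    rows = np.flatnonzero(head.any(axis=1))
    cols = np.flatnonzero(head.any(axis=0))
    h, w = head.shape
    return (
        slice(max(rows[0] - margin, 0), min(rows[-1] + margin + 1, h)),
        slice(max(cols[0] - margin, 0), min(cols[-1] + margin + 1, w)),
    )


def _subpixel_peak(img: np.ndarray, r: int, c: int) -> np.ndarray:
    """Quadratic interpolation of a local maximum (3x3 neighbourhood)."""
    out = np.array([float(r), float(c)])
    for axis, idx in ((0, r), (1, c)):
        if idx <= 0 or idx >= img.shape[axis] - 1:
            continue
        if axis == 0:
            y0, y1, y2 = img[r - 1, c], img[r, c], img[r + 1, c]
        else:
            y0, y1, y2 = img[r, c - 1], img[r, c], img[r, c + 1]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            out[axis] += 0.5 * (y0 - y2) / denom * -1.0
    return out


def match_ocelli(
    head_roi: np.ndarray, cfg: HeadConfig | None = None
) -> tuple[np.ndarray, float]:
    """Posterior ocelli pair via template matching plus local refinement.

    The template encodes the triangle at a nominal separation; after the
    correlation peak localises it, each posterior dot is re-centred on
    the nearest luminance maximum with sub-pixel quadratic
    interpolation, which absorbs the fly-to-fly scale difference.
    Raises when the best correlation is below ``ocelli_min_corr``.
    """
    cfg = cfg or HeadConfig()
    roi = np.asarray(head_roi, dtype=float)
    tpl = ocelli_template_image(cfg.template_separation_px)
    if roi.shape[0] <= tpl.shape[0] or roi.shape[1] <= tpl.shape[1]:
        raise HeadMeasurementError("head ROI smaller than the ocelli template")
    corr = match_template(roi, tpl, pad_input=True)
    peak = np.unravel_index(np.argmax(corr), corr.shape)
    score = float(corr[peak])
    if score < cfg.ocelli_min_corr:
        raise HeadMeasurementError(f"ocelli not found (corr={score:.2f})")
    centre = np.array(peak, dtype=float)
    half = cfg.template_separation_px / 2.0
    # triangle pose: posterior pair sits below the anterior dot in the
    # aligned frame; template centre offsets are purely lateral
    offs = ocelli_offsets_guess = np.array([[0.0, -half], [0.0, half]])
    dots = []
    smoothed = ndimage.gaussian_filter(roi, 1.0)
    for off in offs:
        guess = centre + off
        r0 = int(round(guess[0]))
        c0 = int(round(guess[1]))
        win = smoothed[
            max(r0 - 4, 0) : r0 + 5,
            max(c0 - 4, 0) : c0 + 5,
        ]
        if win.size == 0:
            raise HeadMeasurementError("ocellus window outside ROI")
        rr, cc = np.unravel_index(np.argmax(win), win.shape)
        rr += max(r0 - 4, 0)
        cc += max(c0 - 4, 0)
        dots.append(_subpixel_peak(smoothed, rr, cc))
    dots = np.array(dots)
    if np.linalg.norm(dots[0] - dots[1]) < 2.0:
        raise HeadMeasurementError("posterior ocelli collapsed to one dot")
    return dots, score


def eye_edges_and_iod(
    frame: np.ndarray,
    ocelli_pair: np.ndarray,
    cfg: HeadConfig | None = None,
    mm_per_px: float = 0.0087,
    half_length: float | None = None,
) -> HeadMeasurement:
    """Scan the posterior-ocelli line for the eye edges and measure IOD.

    The luminance is sampled along the line through both posterior
    ocelli, Gaussian-smoothed, differentiated; on each side of the
    midpoint the *outermost* derivative-magnitude peak above threshold
    is taken as the eye edge (a global maximum could instead lock onto
    cuticle texture closer in).
    """
    cfg = cfg or HeadConfig()
    frame = np.asarray(frame, dtype=float)
    p1, p2 = np.asarray(ocelli_pair, dtype=float)
    mid = (p1 + p2) / 2.0
    d = p2 - p1
    norm = np.linalg.norm(d)
    if norm == 0:
        raise HeadMeasurementError("degenerate ocelli pair")
    d = d / norm
    if half_length is None:
        half_length = 6.0 * norm
    step = cfg.scan_step
    ts = np.arange(-half_length, half_length + step, step)
    pts = mid[None, :] + ts[:, None] * d[None, :]
    lum = ndimage.map_coordinates(frame, pts.T, order=1, mode="nearest")
    lum = ndimage.gaussian_filter1d(lum, cfg.smooth_sigma_px / step)
    deriv = np.gradient(lum, step)
    mag = np.abs(deriv)
    thr = cfg.edge_threshold
    peaks = [
        i
        for i in range(1, len(mag) - 1)
        if mag[i] >= thr and mag[i] >= mag[i - 1] and mag[i] >= mag[i + 1]
    ]
    left = [i for i in peaks if ts[i] < 0]
    right = [i for i in peaks if ts[i] > 0]
    if not left or not right:
        raise HeadMeasurementError("eye edges not found")
    edges_idx = [left[0], right[-1]]  # outermost on each side
    edge_ts = []
    for i in edges_idx:
        # sub-sample refinement of the derivative-magnitude peak
        if 0 < i < len(mag) - 1:
            y0, y1, y2 = mag[i - 1], mag[i], mag[i + 1]
            denom = y0 - 2 * y1 + y2
            dt = 0.5 * (y0 - y2) / denom * -1.0 * step if denom != 0 else 0.0
        else:
            dt = 0.0
        edge_ts.append(ts[i] + dt)
    edges = mid[None, :] + np.array(edge_ts)[:, None] * d[None, :]
    iod_px = float(abs(edge_ts[1] - edge_ts[0]))
    return HeadMeasurement(
        ocelli_posterior=np.array([p1, p2]),
        scan_point=mid,
        scan_direction=d,
        eye_edges=edges,
        iod_px=iod_px,
        iod_mm=iod_px * mm_per_px,
    )


def measure_iod(
    red_aligned: np.ndarray,
    body_model,
    cfg: HeadConfig | None = None,
    mm_per_px: float = 0.0087,
) -> HeadMeasurement:
    """Head ROI -> ocelli -> eye edges on one aligned red frame."""
    cfg = cfg or HeadConfig()
    rows, cols = locate_head(body_model, cfg.roi_margin)
    roi = red_aligned[rows, cols]
    dots, _ = match_ocelli(roi, cfg)
    dots_frame = dots + np.array([rows.start, cols.start], dtype=float)
    # scan stays inside the head: beyond its silhouette the background
    # and crossing legs would offer spurious "outermost" contrast edges
    head_fit = body_model.fits.get("head")
    half = max(head_fit.semi_minor - 3.0, 10.0) if head_fit else None
    return eye_edges_and_iod(
        red_aligned, dots_frame, cfg, mm_per_px, half_length=half
    )
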