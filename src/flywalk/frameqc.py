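"""Per-frame validity checks and the sequence accept/reject decision.

A frame is usable for morphometry only if the fly is sharp, fully inside
the image, free of specular reflections on the wings, walking with both
wings exposed to the camera, roughly aligned with the tunnel axis, and
bilaterally symmetric about that axis (no folded wing, no strong roll).
A fly is accepted when at least ``min_valid_frames`` (default 3) frames
pass all six checks; otherwise it would be sent back for re-measurement.

The six criteria are operationalised as:

* focus        - variance of the Laplacian inside the fly bounding box;
* border       - no foreground pixel within ``border_margin`` px of any edge;
* reflections  - fraction of saturated red pixels in the wing region;
* orientation  - wing-silhouette area / body area (a dorsal view exposes
                 both wings, so the ratio collapses when the fly rolls);
* alignment    - angle between the silhouette's principal axis and the
                 tunnel (row) axis;
* symmetry     - IoU of the silhouette with its reflection across its
                 own principal axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .config import QCConfig
from .geometry import align_image, mass_moments

_rr, _cc = np.mgrid[-3:4, -3:4]
_DISK3 = (_rr**2 + _cc**2) <= 9


@dataclass
class FrameQCResult:
    focus_ok: bool
    border_ok: bool
    reflection_ok: bool
    orientation_ok: bool
    alignment_ok: bool
    symmetry_ok: bool
    metrics: dict = field(default_factory=dict)

    @property
    def valid(self) -> bool:
        return (
            self.focus_ok
            and self.border_ok
            and self.reflection_ok
            and self.orientation_ok
            and self.alignment_ok
            and self.symmetry_ok
        )

    def failing(self) -> list[str]:
        return [
            name
            for name, ok in [
                ("focus", self.focus_ok),
                ("border", self.border_ok),
                ("reflection", self.reflection_ok),
                ("orientation", self.orientation_ok),
                ("alignment", self.alignment_ok),
                ("symmetry", self.symmetry_ok),
            ]
            if not ok
        ]


@dataclass
class SequenceDecision:
    n_valid: int
    accepted: bool
    valid_frame_indices: list[int]


def foreground_mask(blue: np.ndarray, background_blue: np.ndarray, cfg: QCConfig):
    """Fly pixels: where the backlit frame departs from the background."""
    diff = np.abs(blue.astype(np.int16) - background_blue.astype(np.int16))
    return diff > cfg.fg_diff_threshold


def check_focus(frame: np.ndarray, threshold: float, fg: np.ndarray | None = None):
    """(ok, metric): variance of the Laplacian within the fly bounding box."""
    img = np.asarray(frame, dtype=float)
    if fg is not None:
        rows = np.flatnonzero(fg.any(axis=1))
        cols = np.flatnonzero(fg.any(axis=0))
        if rows.size == 0:
            return False, 0.0
        img = img[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
    lap = ndimage.laplace(img)
    metric = float(lap.var())
    return metric >= threshold, metric


def check_border_clearance(fg: np.ndarray, margin: int = 2) -> bool:
    """True iff no foreground pixel lies within ``margin`` px of the border."""
    if not fg.any():
        return False  # no fly detected at all
    m = int(margin)
    band = np.zeros_like(fg)
    band[: m + 1, :] = True
    band[-(m + 1) :, :] = True
    band[:, : m + 1] = True
    band[:, -(m + 1) :] = True
    return not bool((fg & band).any())


def wing_region(blue: np.ndarray, fg: np.ndarray, cfg: QCConfig) -> np.ndarray:
    """Semi-transparent silhouette pixels: the wing blades off the body."""
    lo, hi = cfg.wing_level_range
    return fg & (blue > lo) & (blue < hi)


def check_reflections(red: np.ndarray, wing_mask: np.ndarray, cfg: QCConfig):
    """(ok, metric): saturated-pixel fraction within the wing region."""
    n = int(wing_mask.sum())
    if n == 0:
        return True, 0.0
    frac = float((red[wing_mask] >= cfg.saturation_level).sum() / n)
    return frac < cfg.reflection_max_frac, frac


def check_orientation_and_alignment(
    blue: np.ndarray, fg: np.ndarray, cfg: QCConfig
) -> tuple[bool, bool, dict]:
    """Wing-exposure ratio and principal-axis angle of the silhouette."""
    area = int(fg.sum())
    if area < cfg.min_mask_area:
        return False, False, {"wing_ratio": 0.0, "angle_deg": float("nan")}
    body = fg & (blue < cfg.body_level_max)
    wings = wing_region(blue, fg, cfg)
    n_body = max(int(body.sum()), 1)
    ratio = float(wings.sum() / n_body)
    # the longitudinal axis is measured on the dark body core: the wings
    # are translucent and their posture must not masquerade as body yaw
    axis_src = body if body.sum() >= cfg.min_mask_area else fg
    _, _, angle = mass_moments(axis_src.astype(float))
    angle_deg = float(np.degrees(angle))
    return (
        ratio >= cfg.min_wing_body_ratio,
        abs(angle_deg) <= cfg.max_axis_angle_deg,
        {"wing_ratio": ratio, "angle_deg": angle_deg},
    )


def check_symmetry(fg: np.ndarray, cfg: QCConfig) -> tuple[bool, float]:
    """IoU of the silhouette with its mirror across its own major axis.

    Thin structures (legs, bristles) are stripped by a morphological
    opening first: leg placement is asymmetric in any single walking
    frame and carries no information about wing/body symmetry.
    """
    if not fg.any():
        return False, 0.0
    fg = ndimage.binary_opening(fg, structure=_DISK3)
    if not fg.any():
        return False, 0.0
    # crop to a window that contains the mask under any rotation (speed)
    rr, cc = np.nonzero(fg)
    r0, c0 = rr.mean(), cc.mean()
    radius = int(np.sqrt(((rr - r0) ** 2 + (cc - c0) ** 2).max())) + 3
    rlo, clo = int(r0) - radius, int(c0) - radius
    win = np.zeros((2 * radius + 1, 2 * radius + 1))
    rs = slice(max(rlo, 0), min(int(r0) + radius + 1, fg.shape[0]))
    cs = slice(max(clo, 0), min(int(c0) + radius + 1, fg.shape[1]))
    win[rs.start - rlo : rs.stop - rlo, cs.start - clo : cs.stop - clo] = fg[rs, cs]
    r0w, c0w, angle = mass_moments(win)
    upright = align_image(win, (r0w, c0w), angle, cval=0.0, order=0) > 0.5
    mirrored = upright[:, ::-1]
    # the centroid lands on the exact image centre only for odd widths;
    # flipping about the centre column keeps sub-pixel error < 1 px
    inter = int((upright & mirrored).sum())
    union = int((upright | mirrored).sum())
    iou = inter / union if union else 0.0
    return iou >= cfg.symmetry_min_iou, float(iou)


def validate_frame(
    blue: np.ndarray,
    red: np.ndarray,
    background_blue: np.ndarray,
    cfg: QCConfig | None = None,
) -> FrameQCResult:
    """Run all six checks on one registered blue/red frame pair."""
    cfg = cfg or QCConfig()
    if blue.shape != red.shape or blue.shape != background_blue.shape:
        raise ValueError("blue, red and background frames must share one shape")
    fg = foreground_mask(blue, background_blue, cfg)
    focus_ok, focus_var = check_focus(blue, cfg.focus_threshold, fg)
    border_ok = check_border_clearance(fg, cfg.border_margin)
    wings = wing_region(blue, fg, cfg)
    reflection_ok, refl_frac = check_reflections(red, wings, cfg)
    orientation_ok, alignment_ok, oa_metrics = check_orientation_and_alignment(
        blue, fg, cfg
    )
    symmetry_ok, sym_iou = check_symmetry(fg, cfg)
    return FrameQCResult(
        focus_ok=focus_ok,
        border_ok=border_ok,
        reflection_ok=reflection_ok,
        orientation_ok=orientation_ok,
        alignment_ok=alignment_ok,
        symmetry_ok=symmetry_ok,
        metrics={
            "focus_var": focus_var,
            "reflection_frac": refl_frac,
            "symmetry_iou": sym_iou,
            **oa_metrics,
        },
    )


def validate_sequence(seq, cfg: QCConfig | None = None) -> list[FrameQCResult]:
    cfg = cfg or QCConfig()
    return [
        validate_frame(seq.blue[i], seq.red[i], seq.background_blue, cfg)
        for i in range(seq.n_frames)
    ]


def accept_sequence(
    results: list[FrameQCResult], min_valid_frames: int = 3
) -> SequenceDecision:
    """Accept when at least ``min_valid_frames`` frames passed every check."""
    valid_idx = [i for i, r in enumerate(results) if r.valid]
    return SequenceDecision(
        n_valid=len(valid_idx),
        accepted=len(valid_idx) >= min_valid_frames,
        valid_frame_indices=valid_idx,
    )


def qc_table(fly_id: str, results: list[FrameQCResult]):
    """Flat per-frame QC rows for the report CSV."""
    rows = []
    for i, r in enumerate(results):
        rows.append(
            {
                "fly_id": fly_id,
                "frame": i,
                "focus_ok": r.focus_ok,
                "border_ok": r.border_ok,
                "reflection_ok": r.reflection_ok,
                "orientation_ok": r.orientation_ok,
                "alignment_ok": r.alignment_ok,
                "symmetry_ok": r.symmetry_ok,
                "valid": r.valid,
                **{k: round(v, 6) for k, v in r.metrics.items()},
            }
        )
    return rows
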