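"""Body segmentation: aligned silhouette stack, leg removal by temporal
percentile projection, watershed split into head/thorax/abdomen, and
ellipse-template fits of the segment dimensions.

The processing chain for one fly is:

1. subtract each valid blue frame from the background and invert, giving
   the complement image (dark fly on a bright field);
2. align every complement frame with its central image moments so the
   centroid sits at the image centre and the major axis runs vertically,
   head up (the 180-degree ambiguity is resolved by putting the heavier
   mass half - abdomen plus wings - at the bottom);
3. project the stack with a per-pixel high percentile (default the 95th):
   a walking leg darkens any given pixel in at most a frame or two, so
   the high order statistic restores the background beneath it;
4. threshold the projection and apply a grayscale closing that erases
   structures thinner than the structuring element (wing veins,
   bristles), keeping the solid body silhouette;
5. split the silhouette with a marker-based watershed on the negated
   distance transform (markers = the three strongest distance maxima,
   axially separated) and fit an ellipse to each segment's contour.

Shoulder width is read off the thorax template scale rather than from
humeral landmarks: ``sw = reference_width x fitted scale``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure, morphology, segmentation
from skimage.feature import peak_local_max
from skimage.filters import threshold_multiotsu

from .config import BodyConfig
from .geometry import align_image, mass_moments


class SegmentationError(RuntimeError):
    pass


@dataclass
class FrameTransform:
    centroid: tuple[float, float]
    angle: float  # rad, major axis vs the row (tunnel) axis
    flip: bool

    def apply(self, image: np.ndarray, cval: float, order: int = 1) -> np.ndarray:
        return align_image(
            image, self.centroid, self.angle, cval=cval, flip=self.flip, order=order
        )

    def to_raw(self, points: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
        """Map (n, 2) aligned-frame (row, col) points back to raw coords."""
        theta = self.angle + (np.pi if self.flip else 0.0)
        cos, sin = np.cos(theta), np.sin(theta)
        rot = np.array([[cos, -sin], [sin, cos]])
        centre = np.array([(shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0])
        return (np.atleast_2d(points) - centre) @ rot.T + np.asarray(self.centroid)


@dataclass
class AlignedStack:
    frames: np.ndarray  # (n, rows, cols) float, aligned complement images
    transforms: list[FrameTransform]


@dataclass
class SegmentFit:
    name: str
    center: tuple[float, float]  # (row, col)
    semi_major: float
    semi_minor: float
    angle: float  # major-axis angle from the column axis (x convention)
    area: float

    # frames are axis-aligned, so a segment's length is its extent along
    # the body (row) axis and its width the lateral (column) extent --
    # robust even when a near-circular fit swaps major and minor axis
    @property
    def length(self) -> float:
        a, b, th = self.semi_major, self.semi_minor, self.angle
        return 2.0 * float(np.hypot(a * np.sin(th), b * np.cos(th)))

    @property
    def width(self) -> float:
        a, b, th = self.semi_major, self.semi_minor, self.angle
        return 2.0 * float(np.hypot(a * np.cos(th), b * np.sin(th)))


@dataclass
class BodyModel:
    mask: np.ndarray  # body silhouette (legs and wings removed)
    labels: np.ndarray  # 0 background, 1 head, 2 thorax, 3 abdomen
    fits: dict[str, SegmentFit] = field(default_factory=dict)
    sw_px: float = float("nan")

    SEGMENTS = ("head", "thorax", "abdomen")

    @property
    def axis_col(self) -> float:
        return float(np.flatnonzero(self.mask.any(axis=0)).mean())

    def segment_mask(self, name: str) -> np.ndarray:
        return self.labels == (self.SEGMENTS.index(name) + 1)


# ---------------------------------------------------------------------------
# Stage operations
# ---------------------------------------------------------------------------

def subtract_and_complement(frame_blue: np.ndarray, background: np.ndarray):
    """Background-subtract and invert: dark fly on a bright (255) field."""
    if frame_blue.shape != background.shape:
        raise ValueError("frame and background shapes differ")
    diff = np.clip(
        background.astype(np.int16) - frame_blue.astype(np.int16), 0, 255
    )
    return (255 - diff).astype(np.uint8)


def frame_transform(complement: np.ndarray, mass_floor: float = 20.0):
    """Centroid/orientation of one complement frame, with the head-up flip.

    Returns None for a frame with no appreciable mass.
    """
    mass = 255.0 - np.asarray(complement, dtype=float)
    mass[mass < mass_floor] = 0.0
    if mass.sum() <= 0:
        return None
    r0, c0, angle = mass_moments(mass)
    rr, cc = np.nonzero(mass)
    axial = (rr - r0) * np.cos(angle) + (cc - c0) * np.sin(angle)
    w = mass[rr, cc]
    heavier_ahead = float(w[axial < 0].sum()) > float(w[axial > 0].sum())
    return FrameTransform(centroid=(r0, c0), angle=angle, flip=heavier_ahead)


def moments_align(complements: list[np.ndarray]) -> AlignedStack:
    """Centre and de-rotate every frame so the body axis is vertical."""
    frames, transforms = [], []
    for img in complements:
        tf = frame_transform(img)
        if tf is None:
            continue  # zero-mass frame: skip (caller may warn)
        frames.append(tf.apply(img, cval=255.0))
        transforms.append(tf)
    if not frames:
        raise SegmentationError("no frame with foreground mass to align")
    return AlignedStack(frames=np.stack(frames), transforms=transforms)


def percentile_projection(stack: np.ndarray, q: float = 95.0) -> np.ndarray:
    """Per-pixel q-th percentile over frames (linear interpolation).

    On complement images the moving legs are dark transients, so a high
    percentile recovers the bright background underneath them.
    """
    if not 0.0 <= q <= 100.0:
        raise ValueError("q must be in [0, 100]")
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("need a (n_frames, rows, cols) stack")
    return np.percentile(stack, q, axis=0, method="linear")


def binarize_and_close(
    image: np.ndarray,
    threshold: float | None = None,
    selem_radius: int = 2,
    min_area: int = 500,
) -> np.ndarray:
    """Silhouette mask from the projected complement image.

    A grayscale closing removes dark structures thinner than the disk
    (veins, bristles, leg remnants) before thresholding.  Without an
    explicit threshold a three-class multi-Otsu is used and the lower
    threshold taken, separating the opaque body from both the bright
    background and the semi-transparent wing blades.
    """
    img = np.asarray(image, dtype=float)
    closed = morphology.closing(img, morphology.disk(selem_radius))
    if threshold is None:
        # three classes: opaque body, translucent wing blades, background;
        # the lower threshold isolates the body.  Degenerate (two-level)
        # images fall back to plain Otsu.
        try:
            levels = threshold_multiotsu(closed.astype(np.uint8), classes=3)
            threshold = float(levels[0])
        except ValueError:
            from skimage.filters import threshold_otsu

            threshold = float(threshold_otsu(closed.astype(np.uint8)))
    mask = closed <= threshold
    if not mask.any():
        raise SegmentationError("no fly found after thresholding")
    lab, n = ndimage.label(mask)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    if sizes.max() < min_area:
        raise SegmentationError("no fly found after thresholding")
    mask = lab == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(mask)


def watershed_segments(
    mask: np.ndarray, min_marker_separation: int = 45
) -> np.ndarray:
    """Split the silhouette into 3 axially ordered segments.

    Markers are the three strongest maxima of the distance transform with
    pairwise axial separation >= ``min_marker_separation``; the watershed
    runs on the negated distance transform within the mask.  Label 1 is
    the head (the smaller terminal segment), then thorax, then abdomen.
    """
    mask = np.asarray(mask, dtype=bool)
    dist = ndimage.distance_transform_edt(mask)
    peaks = peak_local_max(dist, min_distance=10, exclude_border=False)
    if len(peaks) == 0:
        raise SegmentationError("empty mask")
    order = np.argsort(-dist[peaks[:, 0], peaks[:, 1]])
    chosen: list[np.ndarray] = []
    for idx in order:
        p = peaks[idx]
        if all(abs(int(p[0]) - int(qq[0])) >= min_marker_separation for qq in chosen):
            chosen.append(p)
        if len(chosen) == 3:
            break
    if len(chosen) < 3:
        raise SegmentationError(
            "segmentation failed: fewer than 3 separated distance maxima"
        )
    chosen.sort(key=lambda p: p[0])  # anterior -> posterior
    markers = np.zeros(mask.shape, dtype=np.int32)
    for lab, p in enumerate(chosen, start=1):
        markers[p[0], p[1]] = lab
    labels = segmentation.watershed(-dist, markers, mask=mask, watershed_line=True)
    # head = smaller terminal segment; relabel so 1 is always the head
    areas = {lab: int((labels == lab).sum()) for lab in (1, 2, 3)}
    if areas[1] > areas[3]:
        labels = np.where(labels > 0, 4 - labels, 0)
    return labels


def _lsq_ellipse(xy: np.ndarray):
    """(xc, yc, a, b, theta) least-squares ellipse, or None on failure.

    Wraps the two scikit-image EllipseModel APIs (from_estimate vs the
    older estimate method).
    """
    if hasattr(measure.EllipseModel, "from_estimate"):
        model = measure.EllipseModel.from_estimate(xy)
        if not model:
            return None
        xc, yc = model.center
        a, b = model.axis_lengths
        return float(xc), float(yc), float(a), float(b), float(model.theta)
    model = measure.EllipseModel()
    if not model.estimate(xy):
        return None
    return tuple(float(v) for v in model.params)


def fit_segment_templates(labels: np.ndarray) -> dict[str, SegmentFit]:
    """Least-squares ellipse fit of each segment's contour."""
    fits: dict[str, SegmentFit] = {}
    for lab, name in enumerate(BodyModel.SEGMENTS, start=1):
        region = labels == lab
        if not region.any():
            raise SegmentationError(f"segment {name} missing")
        contours = measure.find_contours(region.astype(float), 0.5)
        contour = max(contours, key=len)
        if len(contour) < 5:
            raise SegmentationError(f"contour of {name} too short to fit")
        params = _lsq_ellipse(contour[:, ::-1])  # (x=col, y=row)
        if params is not None:
            xc, yc, a, b, theta = params
            if b > a:
                a, b = b, a
                theta += np.pi / 2
            fit = SegmentFit(
                name=name,
                center=(float(yc), float(xc)),
                semi_major=float(a),
                semi_minor=float(b),
                angle=float(theta),
                area=float(region.sum()),
            )
        else:  # nearly degenerate contour: fall back to the inertia ellipse
            props = measure.regionprops(region.astype(np.uint8))[0]
            fit = SegmentFit(
                name=name,
                center=tuple(map(float, props.centroid)),
                semi_major=props.axis_major_length / 2.0,
                semi_minor=props.axis_minor_length / 2.0,
                # regionprops measures from the row axis; convert to the
                # column-axis convention used above
                angle=float(np.pi / 2 - props.orientation),
                area=float(region.sum()),
            )
        fits[name] = fit
    return fits


def shoulder_width(thorax_width_px: float, reference_width: float) -> float:
    """Thorax-template scale times the template's reference width.

    With an isotropic template scale the product reduces to the fitted
    thorax width itself; the indirection keeps the measurement defined
    even if a non-unit template reference is configured.
    """
    if reference_width <= 0:
        raise ValueError("reference_width must be positive")
    scale = thorax_width_px / reference_width
    return reference_width * scale


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def build_body_model(
    seq, valid_indices: list[int], cfg: BodyConfig | None = None
) -> tuple[BodyModel, AlignedStack]:
    """Full body pipeline on the valid frames of one sequence."""
    cfg = cfg or BodyConfig()
    if not valid_indices:
        raise SegmentationError("no valid frames")
    complements = [
        subtract_and_complement(seq.blue[i], seq.background_blue) for i in valid_indices
    ]
    stack = moments_align(complements)
    projection = percentile_projection(stack.frames, cfg.projection_percentile)
    mask = binarize_and_close(
        projection, selem_radius=cfg.closing_radius, min_area=cfg.min_body_area
    )
    labels = watershed_segments(mask, cfg.min_marker_separation)
    fits = fit_segment_templates(labels)
    sw = shoulder_width(fits["thorax"].width, cfg.thorax_reference_width_px)
    return BodyModel(mask=mask, labels=labels, fits=fits, sw_px=sw), stack


def align_channel(seq, channel: str, stack: AlignedStack, valid_indices: list[int]):
    """Apply the per-frame body transforms to the other imaging channel."""
    frames = getattr(seq, channel)
    cval = float(np.median(frames[valid_indices[0]][:5, :5]))
    out = [
        tf.apply(frames[i].astype(float), cval=cval)
        for i, tf in zip(valid_indices, stack.transforms)
    ]
    return np.stack(out)
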