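"""Parametric synthetic fly renderer with exact ground-truth morphometrics.

A fly is modelled as three overlapping ellipses (head, thorax, abdomen)
on a vertical body axis, two wings built from the canonical spline
template in :mod:`flywalk.templates`, six moving legs, and the
red-channel features the analysis relies on: ocelli, compound-eye edges,
a sex-dependent abdominal luminance gradient, and male sex combs on the
forelegs.  Every trait the pipeline measures (IOD, SW, WL, WW, WA,
segment dimensions) is known exactly from the generating geometry, so
each downstream stage has an oracle.

The renderer is deliberately non-photorealistic: flat luminance levels
with additive Gaussian noise and hard edges.  Configurable per-frame
nuisances (defocus, border contact, wing reflections, body tilt,
asymmetric wing posture) emulate the failure modes the frame validation
stage must catch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import draw

from .geometry import shoelace_area
from .sequence import FrameSequence
from .templates import VEIN_NAMES, ocelli_offsets, abdominal_luminance, wing_template, wing_unit_measurements

# 8-bit luminance levels of the scene elements
BLUE_BG, BLUE_BODY, BLUE_MEMBRANE, BLUE_WING_LINE, BLUE_LEG = 235, 40, 150, 95, 70
RED_BG, RED_HEAD, RED_EYE, RED_OCELLI, RED_THORAX = 18, 150, 55, 250, 170
RED_WING_LINE, RED_LEG, RED_COMB = 38, 110, 40


class RenderError(RuntimeError):
    """Fly geometry does not fit the frame (outside a border-touch frame)."""


# ---------------------------------------------------------------------------
# Trait model
# ---------------------------------------------------------------------------

@dataclass
class SexTraitModel:
    """Normal trait distributions for one sex (px units)."""

    head_a: tuple[float, float]
    head_b: tuple[float, float]
    thorax_a: tuple[float, float]
    thorax_b: tuple[float, float]
    abd_a: tuple[float, float]
    abd_b: tuple[float, float]
    wl: tuple[float, float]  # wing scale = hinge-to-tip length
    iod_frac: tuple[float, float]  # IOD as fraction of head width
    wing_angle_deg: tuple[float, float]
    size_sd: float = 0.04  # latent common size factor (correlates traits)


def default_trait_model() -> dict[str, SexTraitModel]:
    female = SexTraitModel(
        head_a=(32.0, 1.3),
        head_b=(30.0, 1.2),
        thorax_a=(55.0, 2.2),
        thorax_b=(45.0, 1.8),
        abd_a=(95.0, 4.0),
        abd_b=(58.0, 2.4),
        wl=(230.0, 9.0),
        iod_frac=(0.62, 0.02),
        wing_angle_deg=(20.0, 1.5),
    )
    male = SexTraitModel(
        head_a=(28.0, 1.1),
        head_b=(26.5, 1.1),
        thorax_a=(48.0, 2.0),
        thorax_b=(40.0, 1.6),
        abd_a=(82.0, 3.5),
        abd_b=(50.0, 2.0),
        wl=(200.0, 8.0),
        iod_frac=(0.62, 0.02),
        wing_angle_deg=(20.0, 1.5),
    )
    return {"female": female, "male": male}


@dataclass
class FlyGroundTruth:
    """Generating geometry of one fly, body frame (u axial, v lateral)."""

    sex: str
    head: tuple[float, float, float]  # (centre u, semi-major a, semi-minor b)
    thorax: tuple[float, float, float]
    abdomen: tuple[float, float, float]
    iod_true: float
    sw_true: float
    wing_scale: float
    wing_angles_deg: tuple[float, float]  # (left, right)
    hinge: tuple[float, float]  # right-side hinge (u, v); left mirrored
    wl_true: float
    ww_true: float
    wa_true: float
    abdomen_luminance: dict
    sexcomb_present: bool
    leg_phase: int
    ocelli_sep: float
    ocelli_u: float

    # -- geometry helpers --------------------------------------------------
    def body_ellipses(self) -> dict[str, tuple[float, float, float]]:
        return {"head": self.head, "thorax": self.thorax, "abdomen": self.abdomen}

    def wing_curves(self, side: str, angle_deg: float | None = None):
        """Template curves mapped into the body frame for one wing.

        Returns a dict name -> (n, 2) array of (u, v) points.  ``side`` is
        'left' or 'right'; the left wing mirrors the lateral coordinate.
        """
        if angle_deg is None:
            angle_deg = self.wing_angles_deg[1 if side == "right" else 0]
        phi = math.radians(angle_deg)
        xhat = np.array([math.cos(phi), math.sin(phi)])
        yhat = np.array([-math.sin(phi), math.cos(phi)])
        hinge = np.asarray(self.hinge)
        tpl = wing_template()
        out = {}
        for name, pts in tpl.items():
            body = hinge + self.wing_scale * (
                pts[:, :1] * xhat + pts[:, 1:] * yhat
            )
            if side == "left":
                body = body * np.array([1.0, -1.0])
            out[name] = body
        return out

    def eye_polygons(self) -> list[np.ndarray]:
        """Compound eyes: head-ellipse sectors with |v| >= iod/2.

        The inner eye edge is therefore an axial chord exactly iod apart,
        which is the edge pair the interocular scan must find.
        """
        cu, a, b = self.head
        t = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        ell = np.column_stack([cu + a * np.cos(t), b * np.sin(t)])
        polys = []
        for sign in (1.0, -1.0):
            sel = sign * ell[:, 1] >= self.iod_true / 2.0
            # the selected parameter range is contiguous, so the arc closes
            # with a straight chord at |v| = iod/2 (the inner eye edge)
            polys.append(ell[sel])
        return polys

    def ocelli_points(self) -> np.ndarray:
        """(3, 2) ocelli centres (u, v); rows 0-1 are the posterior pair."""
        offs = ocelli_offsets(self.ocelli_sep)
        return offs + np.array([self.ocelli_u, 0.0])


def sample_fly(
    seed: int,
    sex: str | None = None,
    traits: dict[str, SexTraitModel] | None = None,
) -> FlyGroundTruth:
    """Draw one geometrically valid fly from the trait model.

    The same seed always yields the same fly.  Females are larger on
    average.  A latent size factor correlates all linear traits, as body
    parts scale together in real animals.
    """
    rng = np.random.default_rng(seed)
    if sex is None:
        sex = "male" if rng.random() < 0.5 else "female"
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be male/female, got {sex!r}")
    model = (traits or default_trait_model())[sex]

    def _draw(pair, g):
        return g * pair[0] + rng.normal(0.0, pair[1])

    for _ in range(50):
        g = 1.0 + rng.normal(0.0, model.size_sd)
        head_a = _draw(model.head_a, g)
        head_b = _draw(model.head_b, g)
        thorax_a = _draw(model.thorax_a, g)
        thorax_b = _draw(model.thorax_b, g)
        abd_a = _draw(model.abd_a, g)
        abd_b = _draw(model.abd_b, g)
        wl = _draw(model.wl, g)
        if min(head_a, head_b, thorax_a, thorax_b, abd_a, abd_b, wl) <= 5:
            continue
        areas = (head_a * head_b, thorax_a * thorax_b, abd_a * abd_b)
        if not (areas[0] < areas[1] < areas[2]):
            continue
        break
    else:  # pragma: no cover - the defaults essentially never get here
        raise RuntimeError("could not sample a valid fly geometry")

    iod = float(np.clip(rng.normal(*model.iod_frac), 0.45, 0.8)) * 2.0 * head_b
    angle = rng.normal(*model.wing_angle_deg)
    dl, dr = rng.normal(0.0, 0.4, size=2)

    head_u = -(thorax_a + head_a - 0.40 * head_a)
    abd_u = thorax_a + abd_a - 0.25 * abd_a
    unit = wing_unit_measurements()

    lum: dict[str, float] = {}
    if sex == "male":
        lum = {
            "base": float(165.0 + rng.normal(0, 4)),
            "depth": float(95.0 + rng.normal(0, 5)),
            "edge": float(0.58 + rng.normal(0, 0.02)),
            "width": 0.07,
        }
    else:
        lum = {
            "base": float(150.0 + rng.normal(0, 4)),
            "band_amp": float(22.0 + rng.normal(0, 2)),
            "band_freq": 3.0,
            "slope": float(-15.0 + rng.normal(0, 2)),
        }

    return FlyGroundTruth(
        sex=sex,
        head=(float(head_u), float(head_a), float(head_b)),
        thorax=(0.0, float(thorax_a), float(thorax_b)),
        abdomen=(float(abd_u), float(abd_a), float(abd_b)),
        iod_true=float(iod),
        sw_true=float(2.0 * thorax_b),
        wing_scale=float(wl),
        wing_angles_deg=(float(angle + dl), float(angle + dr)),
        hinge=(float(0.75 * thorax_a), float(0.55 * thorax_b)),
        wl_true=float(wl * unit["wl"]),
        ww_true=float(wl * unit["ww"]),
        wa_true=float(wl**2 * unit["wa"]),
        abdomen_luminance=lum,
        sexcomb_present=sex == "male",
        leg_phase=int(rng.integers(0, 2**31 - 1)),
        ocelli_sep=float(0.35 * iod),
        ocelli_u=float(head_u + 0.35 * head_a),
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

@dataclass
class RenderConfig:
    shape: tuple[int, int] = (1800, 600)  # (rows, cols), portrait tunnel
    n_frames: int = 6
    mm_per_px: float = 0.0087
    noise_sd: float = 2.0
    jitter_px: float = 4.0
    rotation_per_frame: float = 2.0  # sd of the per-frame axis wobble, deg
    defocus_frames: tuple[int, ...] = ()
    defocus_sigma: float = 4.0
    border_touch_frames: tuple[int, ...] = ()
    reflection_frames: tuple[int, ...] = ()
    reflection_radius: int = 8
    tilt_frames: tuple[int, ...] = ()  # body axis far off the tunnel axis
    tilt_angle_deg: float = 25.0
    fold_frames: tuple[int, ...] = ()  # asymmetric wing posture
    fold_angles_deg: tuple[float, float] = (8.0, 36.0)
    comb_frame_frac: float = 0.6
    seed: int = 0

    def validate(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.mm_per_px <= 0:
            raise ValueError("mm_per_px must be positive")


_LEGS = (  # base (u, v-frac of thorax_b), direction (du, dv), length
    ("fore", (-30.0, 0.80), (-0.90, 0.45), 120.0),
    ("mid", (-5.0, 0.95), (-0.15, 1.00), 100.0),
    ("hind", (25.0, 0.90), (0.45, 0.90), 110.0),
)


def _paint_polygon(canvas, poly_rc, value, mask=None, step=1):
    # decimating the polygon speeds up rasterisation (fill is O(n_vertices
    # * bbox)) with negligible area change for smooth outlines
    if step > 1:
        poly_rc = poly_rc[::step]
    rr, cc = draw.polygon(poly_rc[:, 0], poly_rc[:, 1], shape=canvas.shape)
    if mask is not None:
        keep = mask[rr, cc]
        rr, cc = rr[keep], cc[keep]
    canvas[rr, cc] = value
    return rr, cc


def _curve_mask(shape, pts_rc, thick=2):
    m = np.zeros(shape, dtype=bool)
    p = np.round(pts_rc).astype(int)
    rs, cs = [], []
    for (r0, c0), (r1, c1) in zip(p[:-1], p[1:]):
        rr, cc = draw.line(r0, c0, r1, c1)
        rs.append(rr)
        cs.append(cc)
    rr = np.concatenate(rs)
    cc = np.concatenate(cs)
    ok = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
    rr, cc = rr[ok], cc[ok]
    if rr.size == 0:
        return m
    m[rr, cc] = True
    if thick > 1:
        # dilate only within the curve's bounding box (speed)
        r0, r1 = rr.min(), min(rr.max() + thick, shape[0])
        c0, c1 = cc.min(), min(cc.max() + thick, shape[1])
        m[r0:r1, c0:c1] = ndimage.binary_dilation(
            m[r0:r1, c0:c1], structure=np.ones((thick, thick), bool)
        )
    return m


def _ellipse_poly(cu, a, b, n=72):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([cu + a * np.cos(t), b * np.sin(t)])


class _Pose:
    """Body-frame (u, v) -> image (row, col) map for one frame."""

    def __init__(self, centre_rc, theta_rad):
        self.centre = np.asarray(centre_rc, dtype=float)
        self.theta = theta_rad
        c, s = math.cos(theta_rad), math.sin(theta_rad)
        self.mat = np.array([[c, -s], [s, c]])

    def __call__(self, uv: np.ndarray) -> np.ndarray:
        return np.atleast_2d(uv) @ self.mat.T + self.centre


def _frame_pose(truth, cfg, rng, idx):
    h, w = cfg.shape
    centre = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    centre += np.clip(rng.normal(0.0, cfg.jitter_px, 2), -10, 10)
    if idx in cfg.tilt_frames:
        theta = math.radians(cfg.tilt_angle_deg)
    else:
        theta = math.radians(
            float(np.clip(rng.normal(0.0, cfg.rotation_per_frame), -6.0, 6.0))
        )
    return centre, theta


def _leg_segments(truth, rng, male_comb: bool):
    """Per-frame leg polylines (body frame) and the comb centre if any."""
    _, _, thorax_b = truth.thorax
    segs = []
    comb = None
    for name, (bu, bvf), (du, dv), length in _LEGS:
        for side in (1.0, -1.0):
            base = np.array([bu, side * bvf * thorax_b])
            d = np.array([du, side * dv])
            d = d / np.linalg.norm(d)
            ang = math.radians(rng.uniform(-8.0, 8.0))
            c, s = math.cos(ang), math.sin(ang)
            d = np.array([c * d[0] - s * d[1], s * d[0] + c * d[1]])
            ln = length + rng.uniform(-10.0, 10.0)
            knee_dir = np.array(
                [0.97 * d[0] - 0.26 * d[1], 0.26 * d[0] + 0.97 * d[1]]
            )
            knee = base + 0.5 * ln * knee_dir
            tip = base + ln * d
            segs.append(np.array([base, knee, tip]))
            if name == "fore" and side > 0 and male_comb:
                # sex comb sits on the distal tarsus: 85% along the
                # actual (bent) leg polyline so it stays on the leg
                arc1 = float(np.linalg.norm(knee - base))
                arc2 = float(np.linalg.norm(tip - knee))
                s = 0.85 * (arc1 + arc2)
                comb = knee + (s - arc1) * (tip - knee) / arc2
    return segs, comb


def render_frame(truth: FlyGroundTruth, cfg: RenderConfig, rng, idx: int):
    """Render one (blue, red) frame pair; internal helper of render_sequence."""
    h, w = cfg.shape
    blue = np.full((h, w), BLUE_BG, dtype=np.float32)
    red = np.full((h, w), RED_BG, dtype=np.float32)
    body_mask = np.zeros((h, w), dtype=bool)

    centre, theta = _frame_pose(truth, cfg, rng, idx)
    if idx in cfg.fold_frames:
        angles = cfg.fold_angles_deg
    else:
        angles = truth.wing_angles_deg
    wings = {
        "left": truth.wing_curves("left", angles[0]),
        "right": truth.wing_curves("right", angles[1]),
    }

    # lateral shift for border-touch frames: push a wing tip into the margin
    pose = _Pose(centre, theta)
    if idx in cfg.border_touch_frames:
        cols = np.concatenate([pose(wings[s]["outline"])[:, 1] for s in wings])
        shift = (w - 2) - cols.max()
        pose = _Pose(centre + np.array([0.0, shift]), theta)

    # bounds check on the outermost geometry
    pts = np.concatenate(
        [pose(wings[s]["outline"]) for s in wings]
        + [pose(_ellipse_poly(*truth.body_ellipses()[n])) for n in ("head", "thorax", "abdomen")]
    )
    if idx not in cfg.border_touch_frames:
        if (
            pts[:, 0].min() < 5
            or pts[:, 0].max() > h - 6
            or pts[:, 1].min() < 5
            or pts[:, 1].max() > w - 6
        ):
            raise RenderError(
                f"fly geometry exceeds image bounds in frame {idx}; "
                "enlarge the image or shrink the fly"
            )

    # legs first (wings and body occlude them)
    comb_on = (
        truth.sexcomb_present
        and (idx in _comb_frames(truth, cfg))
    )
    legs, comb = _leg_segments(truth, rng, comb_on)
    for seg in legs:
        m = _curve_mask((h, w), pose(seg), thick=2)
        blue[m] = BLUE_LEG
        red[m] = RED_LEG

    # wings: membrane fill, then outline and veins as darker lines
    for side in ("left", "right"):
        _paint_polygon(blue, pose(wings[side]["outline"]), BLUE_MEMBRANE, step=3)
    wing_lines = np.zeros((h, w), dtype=bool)
    for side in ("left", "right"):
        for name in ("outline",) + tuple(VEIN_NAMES):
            wing_lines |= _curve_mask((h, w), pose(wings[side][name]), thick=2)
    blue[wing_lines] = BLUE_WING_LINE

    # body: thorax, abdomen (with axial luminance), head + eyes + ocelli
    for name, value in (("thorax", RED_THORAX), ("head", RED_HEAD)):
        cu, a, b = truth.body_ellipses()[name]
        rr, cc = _paint_polygon(red, pose(_ellipse_poly(cu, a, b)), value)
        body_mask[rr, cc] = True
        _paint_polygon(blue, pose(_ellipse_poly(cu, a, b)), BLUE_BODY)

    cu, a, b = truth.abdomen
    rr, cc = _paint_polygon(red, pose(_ellipse_poly(cu, a, b)), 0.0)
    body_mask[rr, cc] = True
    _paint_polygon(blue, pose(_ellipse_poly(cu, a, b)), BLUE_BODY)
    # axial position of each abdomen pixel -> luminance profile
    du = (rr - pose.centre[0]) * math.cos(theta) + (cc - pose.centre[1]) * math.sin(theta)
    s = np.clip((du - (cu - a)) / (2 * a), 0.0, 1.0)
    red[rr, cc] = abdominal_luminance(s, truth.sex, truth.abdomen_luminance)

    for poly in truth.eye_polygons():
        _paint_polygon(red, pose(poly), RED_EYE)
    for pt in pose(truth.ocelli_points()):
        rr, cc = draw.disk(tuple(pt), 2.3, shape=(h, w))
        red[rr, cc] = RED_OCELLI

    # wing veins/outline over the body, seen in the red channel only
    red[wing_lines & body_mask] = RED_WING_LINE

    if comb is not None:
        crc = pose(comb)[0]
        rr, cc = draw.ellipse(crc[0], crc[1], 2.2, 1.4, shape=(h, w), rotation=0.6)
        red[rr, cc] = RED_COMB

    gain = float(np.clip(1.0 + rng.normal(0.0, 0.02), 0.95, 1.05))
    red = red * gain
    if idx in cfg.reflection_frames:
        # saturated specular blob on the distal wing blade (right side);
        # painted after the flash-gain so it stays at full saturation
        mid = truth.hinge + 0.7 * truth.wing_scale * np.array(
            [math.cos(math.radians(angles[1])), math.sin(math.radians(angles[1]))]
        )
        rr, cc = draw.disk(tuple(pose(mid)[0]), cfg.reflection_radius, shape=(h, w))
        red[rr, cc] = 255.0
    blue += cfg.noise_sd * rng.standard_normal(blue.shape, dtype=np.float32)
    red += cfg.noise_sd * rng.standard_normal(red.shape, dtype=np.float32)
    if idx in cfg.defocus_frames:
        blue = ndimage.gaussian_filter(blue, cfg.defocus_sigma)
        red = ndimage.gaussian_filter(red, cfg.defocus_sigma)
    return (
        np.clip(blue, 0, 255).astype(np.uint8),
        np.clip(red, 0, 255).astype(np.uint8),
    )


def _comb_frames(truth: FlyGroundTruth, cfg: RenderConfig) -> set[int]:
    """Deterministic subset of frames carrying the sex comb (>= half)."""
    if not truth.sexcomb_present or cfg.comb_frame_frac <= 0:
        return set()
    k = max(1, math.ceil(cfg.comb_frame_frac * cfg.n_frames))
    order = np.random.default_rng(truth.leg_phase).permutation(cfg.n_frames)
    return set(int(i) for i in order[:k])


def render_sequence(
    truth: FlyGroundTruth, cfg: RenderConfig, fly_id: str = "fly_0"
) -> FrameSequence:
    """Render the full two-channel sequence plus fly-free background frames."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    blues, reds = [], []
    for i in range(cfg.n_frames):
        b, r = render_frame(truth, cfg, rng, i)
        blues.append(b)
        reds.append(r)
    h, w = cfg.shape
    bg_blue = np.clip(
        BLUE_BG + cfg.noise_sd * rng.standard_normal((h, w), dtype=np.float32), 0, 255
    ).astype(np.uint8)
    bg_red = np.clip(
        RED_BG + cfg.noise_sd * rng.standard_normal((h, w), dtype=np.float32), 0, 255
    ).astype(np.uint8)
    return FrameSequence(
        fly_id=fly_id,
        blue=np.stack(blues),
        red=np.stack(reds),
        background_blue=bg_blue,
        background_red=bg_red,
        mm_per_px=cfg.mm_per_px,
        meta={"seed": cfg.seed},
    )


# ---------------------------------------------------------------------------
# Populations
# ---------------------------------------------------------------------------

TRUTH_COLUMNS = [
    "fly_id",
    "sex",
    "iod_px",
    "sw_px",
    "wl_px",
    "ww_px",
    "wa_px2",
    "head_len_px",
    "head_wid_px",
    "thorax_len_px",
    "thorax_wid_px",
    "abd_len_px",
    "abd_wid_px",
    "sexcomb_present",
]


def truth_row(fly_id: str, t: FlyGroundTruth) -> dict:
    return {
        "fly_id": fly_id,
        "sex": t.sex,
        "iod_px": t.iod_true,
        "sw_px": t.sw_true,
        "wl_px": t.wl_true,
        "ww_px": t.ww_true,
        "wa_px2": t.wa_true,
        "head_len_px": 2 * t.head[1],
        "head_wid_px": 2 * t.head[2],
        "thorax_len_px": 2 * t.thorax[1],
        "thorax_wid_px": 2 * t.thorax[2],
        "abd_len_px": 2 * t.abdomen[1],
        "abd_wid_px": 2 * t.abdomen[2],
        "sexcomb_present": t.sexcomb_present,
    }


def render_population(
    n: int,
    seed: int,
    cfg: RenderConfig | None = None,
    sex: str | None = None,
    out_dir: str | Path | None = None,
    fmt: str = "tiff",
) -> tuple[list[tuple[FrameSequence, FlyGroundTruth]], pd.DataFrame]:
    """Render ``n`` independent flies (mixed sex unless ``sex`` given).

    With ``out_dir`` set, sequences are written to disk (multi-page TIFF
    or PNG directories) together with ``truth.csv``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    cfg = cfg or RenderConfig()
    master = np.random.default_rng(seed)
    pairs = []
    rows = []
    for i in range(n):
        fly_seed = int(master.integers(0, 2**31 - 1))
        render_seed = int(master.integers(0, 2**31 - 1))
        truth = sample_fly(fly_seed, sex=sex)
        fly_id = f"fly_{i:04d}"
        seq = render_sequence(truth, replace(cfg, seed=render_seed), fly_id=fly_id)
        pairs.append((seq, truth))
        rows.append(truth_row(fly_id, truth))
    table = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for seq, _ in pairs:
            if fmt == "tiff":
                seq.save_tiff(out_dir / f"{seq.fly_id}.tif")
            else:
                seq.save_png_dir(out_dir / seq.fly_id)
        table.to_csv(out_dir / "truth.csv", index=False, float_format="%.4f")
    return pairs, table
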