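"""Wing outline and vein extraction with B-spline template fitting.

The wing is observed through two channels on the brightest red frame:
where the blades do not overlap the body, the blue backlight shows the
outline and veins as dark curves through the translucent membrane;
where they do overlap, the bright body acts as the diffuser and the red
channel shows the veins as dark lines instead.  The union of both is
thinned to a one-pixel topological skeleton and a template of the
outline plus longitudinal veins L2-L5 is fitted to it: a similarity
transform first (trimmed iterative closest point), then an active
snap-and-smooth loop that moves every template sample to the local
centroid of its assigned skeleton points and refits a cubic B-spline
per curve.

Measurements follow the landmark definitions: wing length from the
hinge to the intersection of the outline with vein L3, wing width
between the outline intersections of veins L2 and L5, wing area as the
area enclosed by the outline spline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import splev, splprep
from scipy.spatial import cKDTree
from skimage import exposure, morphology

from .config import WingConfig
from .geometry import shoelace_area, umeyama_similarity
from .templates import VEIN_NAMES, wing_template

_OUTLINE_SAMPLES = 160
_VEIN_SAMPLES = 48


class WingExtractionError(RuntimeError):
    pass


@dataclass
class WingModel:
    side: str
    outline: np.ndarray  # (n, 2) refined outline samples (row, col), closed
    veins: dict[str, np.ndarray]  # vein name -> (m, 2) samples
    outline_tck: tuple
    vein_tcks: dict[str, tuple]
    hinge: np.ndarray
    landmarks: dict[str, np.ndarray]  # 'L2','L3','L5' -> outline point
    vein_fitted: dict[str, bool]
    wl_px: float
    ww_px: float
    wa_px2: float
    converged: bool
    residual_px: float  # median skeleton-to-model distance

    def measurements(self, mm_per_px: float) -> dict[str, float]:
        return {
            "wl_px": self.wl_px,
            "ww_px": self.ww_px,
            "wa_px2": self.wa_px2,
            "wl_mm": self.wl_px * mm_per_px,
            "ww_mm": self.ww_px * mm_per_px,
            "wa_mm2": self.wa_px2 * mm_per_px**2,
        }


# ---------------------------------------------------------------------------
# Image operations
# ---------------------------------------------------------------------------

def enhance_contrast(
    image: np.ndarray, clip_limit: float = 2.0, tiles: int = 8
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalisation (8-bit in/out).

    The clip limit is expressed in the conventional multiples-of-uniform
    parameterisation and mapped to scikit-image's [0, 1] fraction.
    """
    img = np.asarray(image)
    if img.max() == img.min():
        return img.copy()
    eq = exposure.equalize_adapthist(
        img.astype(np.uint8),
        kernel_size=tuple(max(s // tiles, 8) for s in img.shape),
        clip_limit=clip_limit / 100.0,
    )
    return (eq * 255).astype(np.uint8)


def _membrane_mask(blue_al, body_mask, cfg: WingConfig):
    from skimage.measure import label, regionprops

    lo, hi = 110.0, 205.0
    band = (blue_al > lo) & (blue_al < hi) & ~body_mask
    # alignment interpolation grades leg edges through the membrane band,
    # leaving thin halo rings around every leg; an opening removes those
    # while the solid wing blades survive, and the size filter drops any
    # remaining clutter
    band = ndimage.binary_opening(band, structure=np.ones((3, 3), bool))
    lab = label(band)
    keep = np.zeros_like(band)
    for reg in regionprops(lab):
        if reg.area >= cfg.min_membrane_area:
            keep[lab == reg.label] = True
    return keep


def wing_mask_two_channel(
    blue_al: np.ndarray,
    red_al: np.ndarray,
    body_mask: np.ndarray,
    cfg: WingConfig | None = None,
) -> np.ndarray:
    """Filled wing silhouette from both channels.

    Off the body the translucent membrane band of the blue channel gives
    the blades directly; over the body the dark red-channel vein/outline
    curves are closed and filled to recover the overlap region.
    """
    cfg = cfg or WingConfig()
    membrane = _membrane_mask(blue_al, body_mask, cfg)
    red_structs = (red_al < cfg.red_structure_max) & body_mask
    if not membrane.any() and not red_structs.any():
        raise WingExtractionError("wing not found in either channel")
    combined = membrane | red_structs
    closed = morphology.closing(combined, morphology.disk(7))
    filled = ndimage.binary_fill_holes(closed)
    return morphology.opening(filled, morphology.disk(2))


def wing_structures(
    blue_al: np.ndarray,
    red_al: np.ndarray,
    body_mask: np.ndarray,
    cfg: WingConfig | None = None,
) -> np.ndarray:
    """Binary outline+vein curves feeding the skeleton.

    Blue-channel curves are taken inside the (filled, slightly dilated)
    membrane region only, which excludes legs and stray clutter; red
    curves only within the body.  A band around the body boundary is
    dropped because alignment interpolation grades the strong body edge
    through every threshold band.
    """
    cfg = cfg or WingConfig()
    lo, hi = cfg.blue_structure_range
    membrane = _membrane_mask(blue_al, body_mask, cfg)
    wingreg = ndimage.binary_dilation(
        ndimage.binary_fill_holes(membrane), iterations=3
    )
    sb = (blue_al > lo) & (blue_al < hi) & wingreg & ~body_mask
    sr = (red_al < cfg.red_structure_max) & body_mask
    boundary = body_mask ^ ndimage.binary_erosion(body_mask)
    near_boundary = ndimage.binary_dilation(
        boundary, iterations=cfg.boundary_exclude_px
    )
    return (sb | sr) & ~near_boundary


def skeletonize_wing(mask: np.ndarray) -> np.ndarray:
    """One-pixel-wide topological skeleton (connectivity preserving)."""
    return morphology.skeletonize(np.asarray(mask, dtype=bool))


# ---------------------------------------------------------------------------
# Template fitting
# ---------------------------------------------------------------------------

def _template_samples():
    tpl = wing_template()
    curves = {}
    for name, n in [("outline", _OUTLINE_SAMPLES)] + [
        (v, _VEIN_SAMPLES) for v in VEIN_NAMES
    ]:
        pts = tpl[name]
        idx = np.linspace(0, len(pts) - 1, n).round().astype(int)
        curves[name] = pts[idx]
    return curves


def _transform(pts, scale, rot, trans):
    return scale * pts @ rot.T + trans


def _curve_normals(samples: np.ndarray, closed: bool) -> np.ndarray:
    """Unit normals per sample from central-difference tangents."""
    if closed:
        tang = np.roll(samples, -1, axis=0) - np.roll(samples, 1, axis=0)
    else:
        tang = np.gradient(samples, axis=0)
    norms = np.linalg.norm(tang, axis=1, keepdims=True)
    tang = tang / np.where(norms > 0, norms, 1.0)
    return np.column_stack([-tang[:, 1], tang[:, 0]])


def _smooth_curve(
    samples: np.ndarray,
    closed: bool,
    smooth: float,
    weights: np.ndarray | None = None,
):
    """Cubic smoothing B-spline through ordered samples; returns tck and
    the re-evaluated samples.  ``weights`` down-weights low-confidence
    samples so the spline interpolates them from their neighbours."""
    pts = samples
    kwargs = {"s": smooth * len(pts), "k": 3}
    if weights is not None:
        kwargs["w"] = weights
    if closed:
        tck, _ = splprep([pts[:, 0], pts[:, 1]], per=True, **kwargs)
        u = np.linspace(0, 1, len(pts), endpoint=False)
    else:
        tck, _ = splprep([pts[:, 0], pts[:, 1]], **kwargs)
        u = np.linspace(0, 1, len(pts))
    x, y = splev(u, tck)
    return tck, np.column_stack([x, y])


def fit_wing_splines(
    skeleton: np.ndarray,
    side: str,
    init: tuple[np.ndarray, float, float],
    cfg: WingConfig | None = None,
) -> WingModel:
    """Fit the outline+vein template to a one-wing skeleton image.

    ``init`` is (hinge_guess (row, col), angle_deg, scale_guess) taken
    from the body model: the hinge sits at the posterior dorsal thorax
    and the wing axis points posterior-laterally.  The template is
    mirrored for the left side so a proper rotation suffices.
    """
    cfg = cfg or WingConfig()
    pts = np.column_stack(np.nonzero(skeleton)).astype(float)
    if len(pts) < 80:
        raise WingExtractionError(f"too few skeleton points ({len(pts)})")
    mirror = -1.0 if side == "left" else 1.0
    curves = {
        name: c * np.array([1.0, mirror]) for name, c in _template_samples().items()
    }
    tpl_all = np.concatenate(list(curves.values()))
    labels = np.concatenate(
        [np.full(len(c), i) for i, c in enumerate(curves.values())]
    )
    sample_idx = np.concatenate([np.arange(len(c)) for c in curves.values()])
    names = list(curves.keys())

    hinge0, angle_deg, scale0 = init
    phi = np.radians(angle_deg) * mirror
    rot = np.array(
        [[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]]
    )
    scale, trans = float(scale0), np.asarray(hinge0, dtype=float)

    # stage 1: trimmed ICP for the similarity transform
    for _ in range(8):
        placed = _transform(tpl_all, scale, rot, trans)
        dist, j = cKDTree(placed).query(pts)
        keep = dist < max(cfg.trim_distance_px, np.median(dist) * 2)
        if keep.sum() < 50:
            raise WingExtractionError("similarity initialisation found no overlap")
        scale, rot, trans = umeyama_similarity(tpl_all[j[keep]], pts[keep])

    # stage 2: deformable refinement on top of the similarity backbone.
    # Every template sample may move only along its local curve normal,
    # by a clipped displacement smoothed along the curve (normalised
    # convolution over the supported samples).  Tangential motion and
    # free drift are structurally impossible, so the outline can neither
    # fold into a self-intersecting polygon nor balloon across stretches
    # that the skeleton does not cover (body-boundary cuts, junction
    # dropouts): those decay back to the backbone placement.

    def _refine_pass(max_shift: float = 4.0, sigma: float = 2.0):
        placed = {
            name: _transform(c, scale, rot, trans) for name, c in curves.items()
        }
        refined = {name: p.copy() for name, p in placed.items()}
        support = {name: np.zeros(len(c), dtype=bool) for name, c in curves.items()}
        moved = np.inf
        for _ in range(max(2, cfg.fit_iterations)):
            previous = {name: c.copy() for name, c in refined.items()}
            # per-curve distances; points ambiguous between two curves
            # (junction blobs where veins meet the outline, closely
            # parallel proximal curves) are discarded
            percurve = np.stack(
                [cKDTree(refined[name]).query(pts)[0] for name in names], axis=1
            )
            order = np.argsort(percurve, axis=1)
            d_best = percurve[np.arange(len(pts)), order[:, 0]]
            d_second = percurve[np.arange(len(pts)), order[:, 1]]
            keep = (d_best < cfg.trim_distance_px) & (d_second - d_best >= 3.0)
            flat = np.concatenate(list(refined.values()))
            _, j = cKDTree(flat).query(pts)
            for ci, name in enumerate(names):
                base = placed[name]
                normals = _curve_normals(base, name == "outline")
                disp = np.zeros(len(base))
                sup = np.zeros(len(base), dtype=bool)
                sel = keep & (labels[j] == ci)
                tgt = sample_idx[j[sel]]
                pp = pts[sel]
                for k in np.unique(tgt):
                    off = (pp[tgt == k] - refined[name][k]) @ normals[k]
                    prev = (refined[name][k] - base[k]) @ normals[k]
                    disp[k] = np.clip(prev + off.mean(), -max_shift, max_shift)
                    sup[k] = True
                mode = "wrap" if name == "outline" else "nearest"
                num = ndimage.gaussian_filter1d(disp * sup, sigma, mode=mode)
                den = ndimage.gaussian_filter1d(sup.astype(float), sigma, mode=mode)
                smooth_disp = np.where(den > 1e-6, num / np.maximum(den, 1e-6), 0.0)
                refined[name] = base + normals * smooth_disp[:, None]
                support[name] = sup
            moved = float(
                np.mean(
                    [np.abs(refined[n] - previous[n]).mean() for n in names]
                )
            )
            if moved < cfg.fit_tol_px:
                break
        return refined, support, moved

    def _placement_cost(s, r, t):
        placed = _transform(tpl_all, s, r, t)
        d, _ = cKDTree(pts).query(placed)
        return float(np.clip(d, None, cfg.trim_distance_px).mean())

    refined, support, moved = _refine_pass()

    # corrective backbone pass: re-estimate the similarity from the
    # supported samples (the trimmed ICP can settle a few px off when
    # parts of the wing are hidden) and refine again from the better
    # placement, keeping it only if it fits the skeleton better
    sup_all = np.concatenate([support[n] for n in names])
    if sup_all.sum() >= 100:
        ref_all = np.concatenate([refined[n] for n in names])
        s2, r2, t2 = umeyama_similarity(tpl_all[sup_all], ref_all[sup_all])
        if 0.5 < s2 / scale < 2.0 and _placement_cost(s2, r2, t2) <= _placement_cost(
            scale, rot, trans
        ):
            scale, rot, trans = s2, r2, t2
            refined, support, moved = _refine_pass()
    converged = moved < cfg.fit_tol_px

    # final splines and landmarks
    outline_tck, outline = _smooth_curve(refined["outline"], True, 0.05)
    vein_tcks, veins, fitted = {}, {}, {}
    for v in VEIN_NAMES:
        vein_tcks[v], veins[v] = _smooth_curve(refined[v], False, 0.05)
        # a vein counts as fitted when its distal half has skeleton support
        half = len(support[v]) // 2
        fitted[v] = bool(support[v][half:].mean() > 0.5)

    dense_u = np.linspace(0, 1, 512, endpoint=False)
    ox, oy = splev(dense_u, outline_tck)
    outline_dense = np.column_stack([ox, oy])

    hinge = _transform(np.zeros((1, 2)), scale, rot, trans)[0]
    landmarks = {}
    for v in ("L2", "L3", "L5"):
        landmarks[v] = _vein_outline_intersection(veins[v], outline_dense)

    wl = float(np.linalg.norm(hinge - landmarks["L3"])) if fitted["L3"] else float("nan")
    ww = (
        float(np.linalg.norm(landmarks["L2"] - landmarks["L5"]))
        if fitted["L2"] and fitted["L5"]
        else float("nan")
    )
    wa = shoelace_area(outline_dense)

    dist, _ = cKDTree(np.concatenate([outline] + list(veins.values()))).query(pts)
    residual = float(np.median(dist))
    return WingModel(
        side=side,
        outline=outline,
        veins=veins,
        outline_tck=outline_tck,
        vein_tcks=vein_tcks,
        hinge=hinge,
        landmarks=landmarks,
        vein_fitted=fitted,
        wl_px=wl,
        ww_px=ww,
        wa_px2=wa,
        converged=converged,
        residual_px=residual,
    )


def _vein_outline_intersection(
    vein: np.ndarray, outline_dense: np.ndarray
) -> np.ndarray:
    """Crossing point of the distal vein with the outline spline.

    The distal vein is extended a little along its end tangent and
    properly intersected with the closed outline; taking the nearest
    outline *point* instead would slide along the rim wherever a vein
    meets it at a shallow angle.  Falls back to the nearest outline
    point if the curves do not quite touch.
    """
    from shapely.geometry import LineString

    tip = vein[-1]
    tangent = vein[-1] - vein[-5]
    n = np.linalg.norm(tangent)
    tangent = tangent / n if n > 0 else np.array([1.0, 0.0])
    distal = np.vstack([vein[-12:], tip + 20.0 * tangent])
    ring = LineString(np.vstack([outline_dense, outline_dense[:1]]))
    inter = LineString(distal).intersection(ring)
    if not inter.is_empty:
        geoms = inter.geoms if hasattr(inter, "geoms") else [inter]
        cand = []
        for g in geoms:
            p = g if g.geom_type == "Point" else g.centroid
            cand.append(np.array([p.x, p.y]))
        return min(cand, key=lambda p: np.linalg.norm(p - tip))
    return outline_dense[np.argmin(((outline_dense - tip) ** 2).sum(axis=1))]


def wing_measurements(model: WingModel, mm_per_px: float) -> dict[str, float]:
    """WL/WW/WA in px and mm; missing landmarks yield NaN, never zero."""
    return model.measurements(mm_per_px)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def measure_wings(
    blue_al: np.ndarray,
    red_al: np.ndarray,
    body_model,
    cfg: WingConfig | None = None,
) -> WingModel:
    """Extract structures, skeletonize per side, fit, keep the better wing."""
    cfg = cfg or WingConfig()
    structures = wing_structures(blue_al, red_al, body_model.mask, cfg)
    axis_col = body_model.axis_col
    thorax = body_model.fits["thorax"]
    row_min = int(thorax.center[0] - 10)
    window = np.zeros_like(structures)
    window[row_min:] = True
    skel_full = skeletonize_wing(structures & window)
    # assign each connected curve fragment to a wing by which side of the
    # body axis its centroid falls on: with the wings held close to the
    # body their posterior rims run within a few pixels of the midline,
    # and a hard column split would slice those rims away
    lab, n_comp = ndimage.label(skel_full, structure=np.ones((3, 3)))
    side_of = {}
    for comp in range(1, n_comp + 1):
        cols = np.nonzero(lab == comp)[1]
        side_of[comp] = "right" if cols.mean() >= axis_col else "left"
    scale0 = None
    models = []
    for side in ("left", "right"):
        keep_labels = [c for c, s in side_of.items() if s == side]
        skel = np.isin(lab, keep_labels)
        npts = int(skel.sum())
        if npts < 80:
            continue
        sign = 1.0 if side == "right" else -1.0
        hinge0 = np.array(
            [
                thorax.center[0] + 0.75 * thorax.semi_major,
                axis_col + sign * 0.55 * thorax.semi_minor,
            ]
        )
        if scale0 is None:
            rr, cc = np.nonzero(skel)
            d = np.sqrt((rr - hinge0[0]) ** 2 + (cc - hinge0[1]) ** 2)
            scale0 = float(np.percentile(d, 99))
        try:
            models.append(fit_wing_splines(skel, side, (hinge0, 20.0, scale0), cfg))
        except WingExtractionError:
            continue
    if not models:
        raise WingExtractionError("no wing could be fitted on either side")
    return min(models, key=lambda m: m.residual_px)
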