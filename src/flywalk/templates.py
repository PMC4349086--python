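"""Canonical templates shared by the synthetic renderer and the fitters.

The wing template is a unit-length right wing: a closed outline through
fixed control points plus the four longitudinal veins L2-L5 drawn from
the hinge region to anchor points on the outline.  The same template is
(a) scaled and placed by the synthetic generator, which makes its
geometry the ground truth, and (b) used by the wing fitter as the
initial shape that is deformed onto the observed skeleton.  Users
working with real images can substitute their own template control
points; nothing downstream assumes the default shape.

Luminance templates for sex calling are likewise built from the
generator's abdominal luminance model (mean of many sampled flies per
sex), mirroring how the original templates were averaged from sorted
specimens.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.interpolate import splev, splprep

from .geometry import resample_polyline, shoelace_area

# Closed outline control polygon of a unit-length right wing,
# (x along the wing axis from the hinge, y across). Hinge at the origin.
WING_OUTLINE_CONTROL = np.array(
    [
        [0.00, 0.000],
        [0.08, 0.085],
        [0.25, 0.150],
        [0.50, 0.185],
        [0.75, 0.170],
        [0.92, 0.105],
        [1.00, 0.000],
        [0.93, -0.090],
        [0.75, -0.160],
        [0.50, -0.200],
        [0.25, -0.160],
        [0.07, -0.070],
    ]
)

# Vein start points (near the hinge), mid control points, and nominal
# distal anchors; the distal anchor is snapped onto the sampled outline.
_VEIN_SPECS = {
    "L2": ([0.06, 0.030], [0.45, 0.105], [0.90, 0.130]),
    "L3": ([0.05, 0.010], [0.50, 0.020], [1.00, 0.000]),
    "L4": ([0.05, -0.015], [0.50, -0.050], [0.93, -0.090]),
    "L5": ([0.06, -0.050], [0.40, -0.120], [0.72, -0.175]),
}

VEIN_NAMES = ("L2", "L3", "L4", "L5")


@lru_cache(maxsize=None)
def wing_template(n_outline: int = 360, n_vein: int = 60):
    """Sampled unit wing: dict with 'outline' (closed, (n,2)) and each vein.

    The outline is a periodic cubic B-spline through the control polygon;
    veins are quadratic Beziers whose distal ends are snapped to the
    nearest sampled outline point so that, by construction, every vein
    terminates on the outline.
    """
    ctrl = WING_OUTLINE_CONTROL
    tck, _ = splprep([ctrl[:, 0], ctrl[:, 1]], s=0, per=True, k=3)
    t = np.linspace(0.0, 1.0, n_outline, endpoint=False)
    ox, oy = splev(t, tck)
    outline = np.column_stack([ox, oy])

    curves = {"outline": outline}
    for name, (p0, p1, p2) in _VEIN_SPECS.items():
        p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
        anchor = np.asarray(p2, float)
        idx = int(np.argmin(((outline - anchor) ** 2).sum(axis=1)))
        p2 = outline[idx]
        s = np.linspace(0.0, 1.0, n_vein)[:, None]
        bez = (1 - s) ** 2 * p0 + 2 * s * (1 - s) * p1 + s**2 * p2
        curves[name] = resample_polyline(bez, n_vein)
    return curves


def wing_unit_measurements() -> dict[str, float]:
    """WL/WW/WA of the unit template (hinge at origin, length ~= 1)."""
    tpl = wing_template()
    hinge = np.zeros(2)
    l3 = tpl["L3"][-1]
    l2 = tpl["L2"][-1]
    l5 = tpl["L5"][-1]
    return {
        "wl": float(np.linalg.norm(l3 - hinge)),
        "ww": float(np.linalg.norm(l2 - l5)),
        "wa": shoelace_area(tpl["outline"]),
    }


def ocelli_offsets(separation: float, anterior_drop: float | None = None) -> np.ndarray:
    """Body-frame offsets (u, v) of the three ocelli around their centre.

    The posterior pair sits symmetric about the midline, ``separation``
    apart; the anterior ocellus sits ``anterior_drop`` ahead (default
    0.6 * separation), forming the characteristic triangle.
    """
    if anterior_drop is None:
        anterior_drop = 0.6 * separation
    half = separation / 2.0
    return np.array([[0.0, -half], [0.0, half], [-anterior_drop, 0.0]])


def ocelli_template_image(
    separation: float = 12.0, dot_sigma: float = 1.3, pad: int = 6
) -> np.ndarray:
    """Small float image of three bright Gaussian dots for template matching."""
    offs = ocelli_offsets(separation)
    u0, v0 = offs[:, 0].min() - pad, offs[:, 1].min() - pad
    h = int(np.ceil(offs[:, 0].max() - u0 + pad + 1))
    w = int(np.ceil(offs[:, 1].max() - v0 + pad + 1))
    rr, cc = np.mgrid[0:h, 0:w]
    img = np.zeros((h, w))
    for du, dv in offs:
        img += np.exp(
            -(((rr - (du - u0)) ** 2 + (cc - (dv - v0)) ** 2) / (2 * dot_sigma**2))
        )
    return img


# ---------------------------------------------------------------------------
# Abdominal luminance model
# ---------------------------------------------------------------------------

def abdominal_luminance(s: np.ndarray, sex: str, params: dict | None = None):
    """Red-channel luminance along the abdomen, ``s`` in [0, 1] (anterior ->
    posterior), in 8-bit levels.

    Males carry a conspicuous darkening of the posterior tergites (here a
    smooth posterior drop); females stay light overall with tergite
    banding.  The parameters are stored per fly so that templates can be
    rebuilt from sampled populations.
    """
    s = np.asarray(s, dtype=float)
    p = params or {}
    if sex == "male":
        base = p.get("base", 165.0)
        depth = p.get("depth", 95.0)
        edge = p.get("edge", 0.58)
        width = p.get("width", 0.07)
        return base - depth / (1.0 + np.exp(-(s - edge) / width))
    base = p.get("base", 150.0)
    band_amp = p.get("band_amp", 22.0)
    band_freq = p.get("band_freq", 3.0)
    slope = p.get("slope", -15.0)
    return base + slope * s + band_amp * np.sin(2 * np.pi * band_freq * s + 0.8)


def build_luminance_templates(
    n_flies: int = 50, n_samples: int = 100, seed: int = 777
) -> dict[str, np.ndarray]:
    """Mean normalised luminance curve per sex over ``n_flies`` sampled flies.

    Imported lazily from :mod:`flywalk.synthio` to avoid a module cycle.
    """
    from .synthio import sample_fly

    rng = np.random.default_rng(seed)
    s = np.linspace(0.0, 1.0, n_samples)
    out = {}
    for sex in ("male", "female"):
        curves = []
        for _ in range(n_flies):
            fly = sample_fly(int(rng.integers(0, 2**31 - 1)), sex=sex)
            lum = abdominal_luminance(s, sex, fly.abdomen_luminance)
            curves.append(lum / lum.mean())
        out[sex] = np.mean(curves, axis=0)
    return out
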