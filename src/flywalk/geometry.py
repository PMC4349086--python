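"""Shared low-level geometry: image moments, similarity transforms, polygon area.

Conventions used throughout the package:

* images are ``(rows, cols)`` arrays; the tunnel axis is the row axis,
  anterior (head) pointing toward row 0;
* "body frame" coordinates are ``(u, v)`` with ``u`` axial (positive
  posterior, i.e. increasing row when the fly is upright) and ``v``
  lateral (positive toward increasing column);
* angles are measured from the row axis, counter-clockwise positive,
  in radians unless a name says degrees.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage


def mass_moments(weight: np.ndarray) -> tuple[float, float, float]:
    """Centroid ``(r, c)`` and major-axis angle of a non-negative weight image.

    The angle is derived from the second central moments and is the
    angle between the principal (major) axis and the row axis, wrapped
    to ``(-pi/2, pi/2]``.
    """
    w = np.asarray(weight, dtype=float)
    total = w.sum()
    if total <= 0:
        raise ValueError("weight image has zero mass")
    rr, cc = np.mgrid[0 : w.shape[0], 0 : w.shape[1]]
    r0 = float((rr * w).sum() / total)
    c0 = float((cc * w).sum() / total)
    dr = rr - r0
    dc = cc - c0
    mu20 = float((dr * dr * w).sum() / total)  # variance along rows
    mu02 = float((dc * dc * w).sum() / total)
    mu11 = float((dr * dc * w).sum() / total)
    # principal axis relative to the row axis
    angle = 0.5 * np.arctan2(2.0 * mu11, mu20 - mu02)
    # ensure the returned axis is the major one
    var_along = (
        mu20 * np.cos(angle) ** 2
        + mu02 * np.sin(angle) ** 2
        + 2 * mu11 * np.sin(angle) * np.cos(angle)
    )
    var_across = mu20 + mu02 - var_along
    if var_across > var_along:
        angle += np.pi / 2
    if angle > np.pi / 2:
        angle -= np.pi
    elif angle <= -np.pi / 2:
        angle += np.pi
    return r0, c0, float(angle)


def align_image(
    image: np.ndarray,
    centroid: tuple[float, float],
    angle: float,
    *,
    cval: float,
    flip: bool = False,
    order: int = 1,
) -> np.ndarray:
    """Rotate by ``-angle`` about ``centroid`` and translate centroid to the
    image centre (so the major axis becomes vertical). ``flip`` adds 180 deg.

    Uses an inverse-map affine transform; output has the input shape.
    """
    img = np.asarray(image, dtype=float)
    h, wdt = img.shape
    centre = np.array([(h - 1) / 2.0, (wdt - 1) / 2.0])
    theta = angle + (np.pi if flip else 0.0)
    # output coords -> input coords: rotate by +theta about centre then shift
    cos, sin = np.cos(theta), np.sin(theta)
    rot = np.array([[cos, -sin], [sin, cos]])
    offset = np.asarray(centroid) - rot @ centre
    return ndimage.affine_transform(
        img, rot, offset=offset, order=order, cval=cval, mode="constant"
    )


def rotate_points(points: np.ndarray, angle: float) -> np.ndarray:
    """Rotate ``(n, 2)`` row/col points about the origin by ``angle``."""
    cos, sin = np.cos(angle), np.sin(angle)
    rot = np.array([[cos, -sin], [sin, cos]])
    return np.asarray(points, dtype=float) @ rot.T


def shoelace_area(polygon: np.ndarray) -> float:
    """Absolute area of a closed polygon given as ``(n, 2)`` vertices."""
    p = np.asarray(polygon, dtype=float)
    x = p[:, 0]
    y = p[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def umeyama_similarity(
    src: np.ndarray, dst: np.ndarray, weights: np.ndarray | None = None
) -> tuple[float, np.ndarray, np.ndarray]:
    """Least-squares similarity transform (scale, rotation, translation)
    mapping ``src`` points onto ``dst``: ``dst ~= s * R @ src + t``.

    Reflections are not produced; mirror the source beforehand if needed.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if weights is None:
        weights = np.ones(len(src))
    w = weights / weights.sum()
    mu_s = (src * w[:, None]).sum(axis=0)
    mu_d = (dst * w[:, None]).sum(axis=0)
    ds = src - mu_s
    dd = dst - mu_d
    cov = (dd * w[:, None]).T @ ds
    u, svals, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(u @ vt))
    diag = np.diag([1.0, d])
    rot = u @ diag @ vt
    var_s = float(((ds**2).sum(axis=1) * w).sum())
    scale = float(np.trace(np.diag(svals) @ diag) / var_s)
    trans = mu_d - scale * rot @ mu_s
    return scale, rot, trans


def resample_polyline(points: np.ndarray, n: int) -> np.ndarray:
    """Resample an open polyline to ``n`` points equally spaced in arc length."""
    p = np.asarray(points, dtype=float)
    seg = np.sqrt(((np.diff(p, axis=0)) ** 2).sum(axis=1))
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] <= 0:
        return np.repeat(p[:1], n, axis=0)
    t = np.linspace(0.0, s[-1], n)
    out = np.empty((n, 2))
    for k in range(2):
        out[:, k] = np.interp(t, s, p[:, k])
    return out
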