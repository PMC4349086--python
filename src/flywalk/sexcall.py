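"""Sex determination from abdominal luminance and sex-comb detection.

Two independent lines of evidence are fused:

* the normalised red-channel luminance profile along the abdomen's
  anterior-posterior axis, correlated against average male and female
  template curves (males darken sharply over the posterior tergites);
* detection of sex combs - compact dark spots on the forelegs, scanned
  for in the region anterior to the head; elongated dark objects (a leg
  crossing the antennae) are rejected by their eccentricity.

Combs exist only in males, so confident comb evidence forces a male
call; otherwise the luminance correlations decide, and when neither
method is confident the fly is labelled ``unknown`` for the user to
resolve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from .config import SexConfig
from .geometry import resample_polyline


@dataclass
class LuminanceProfile:
    positions: np.ndarray  # normalised arc length in [0, 1], increasing
    values: np.ndarray  # luminance / mean luminance

    def __post_init__(self):
        if not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")


@dataclass
class CombResult:
    detected: bool
    confidence: float
    detections: list[dict] = field(default_factory=list)


@dataclass
class SexCall:
    sex: str  # male / female / unknown
    r_male: float
    r_female: float
    lum_confidence: float
    comb_detected: bool
    comb_confidence: float


def abdominal_profile(
    red_aligned: np.ndarray,
    abdomen_mask: np.ndarray,
    n_samples: int = 100,
    min_area: int = 500,
) -> LuminanceProfile:
    """Luminance along the abdomen axis, resampled and mean-normalised.

    Operates on an axis-aligned frame, so the abdomen's major axis is
    vertical and the profile is the per-row mean over the segment mask.
    """
    area = int(abdomen_mask.sum())
    if area < min_area:
        raise ValueError(f"abdomen segment too small ({area} px)")
    rows = np.flatnonzero(abdomen_mask.any(axis=1))
    r0, r1 = rows[0], rows[-1]
    sums = np.where(abdomen_mask[r0 : r1 + 1], red_aligned[r0 : r1 + 1], 0.0).sum(axis=1)
    counts = abdomen_mask[r0 : r1 + 1].sum(axis=1)
    profile = sums / np.maximum(counts, 1)
    pos = np.linspace(0.0, 1.0, n_samples)
    values = np.interp(pos, np.linspace(0.0, 1.0, len(profile)), profile)
    mean = values.mean()
    if mean <= 0:
        raise ValueError("abdomen luminance is zero")
    return LuminanceProfile(positions=pos, values=values / mean)


def correlate_templates(
    profile: LuminanceProfile, tpl_male: np.ndarray, tpl_female: np.ndarray
) -> tuple[float, float]:
    """Zero-lag Pearson correlation against each sex template.

    Profiles are already arc-length normalised to a common number of
    samples, so no lag search is needed.  A constant profile has no
    defined correlation and scores 0 against both templates.
    """
    v = profile.values
    if len(tpl_male) != len(v) or len(tpl_female) != len(v):
        raise ValueError("templates must match the profile sampling")
    out = []
    for tpl in (tpl_male, tpl_female):
        if v.std() == 0 or np.std(tpl) == 0:
            out.append(0.0)
        else:
            out.append(float(np.corrcoef(v, tpl)[0, 1]))
    return out[0], out[1]


@lru_cache(maxsize=4)
def default_templates(n_samples: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Packaged (male, female) templates, averaged from sampled flies."""
    from .templates import build_luminance_templates

    tpls = build_luminance_templates(n_flies=50, n_samples=n_samples)
    return tpls["male"], tpls["female"]


def load_templates(path) -> np.ndarray:
    """Two-column CSV (position, luminance) -> luminance resampled as stored."""
    table = pd.read_csv(path)
    return table.iloc[:, 1].to_numpy(dtype=float)


def detect_sex_combs(
    red_frames: np.ndarray,
    head_apex_rc: np.ndarray,
    anterior_up: np.ndarray,
    cfg: SexConfig | None = None,
) -> CombResult:
    """Scan the region anterior to the head for compact dark leg spots.

    Works on the *raw* red frames (interpolation during alignment smears
    luminance edges through the comb band and fakes spots).
    ``head_apex_rc`` gives the head apex per frame in raw coordinates and
    ``anterior_up`` whether anterior points toward row 0 in that frame.
    The strip beyond the apex is searched: pixels at leg luminance form
    the leg image; connected regions whose luminance falls in the comb
    band, whose area is plausible and whose eccentricity is below the
    cutoff count as detections.  Confidence combines the mean detected
    area with the fraction of frames showing a detection.
    """
    cfg = cfg or SexConfig()
    lo, hi = cfg.comb_level_range
    amin, amax = cfg.comb_area_range
    n_frames = len(red_frames)
    detections = []
    frames_with = 0
    for idx in range(n_frames):
        frame = red_frames[idx]
        r_apex = int(head_apex_rc[idx][0])
        c0 = int(head_apex_rc[idx][1])
        if anterior_up[idx]:
            rows = slice(0, max(r_apex - 2, 1))
        else:
            rows = slice(min(r_apex + 2, frame.shape[0] - 1), frame.shape[0])
        strip = frame[rows, max(c0 - 150, 0) : c0 + 150]
        legs = strip > cfg.leg_level_min
        if not legs.any():
            continue
        near_legs = ndimage.binary_dilation(legs, iterations=3)
        candidates = (strip > lo) & (strip < hi) & near_legs
        if not candidates.any():
            continue
        found = False
        for region in measure.regionprops(measure.label(candidates)):
            if not amin <= region.area <= amax:
                continue
            if region.eccentricity > cfg.eccentricity_max:
                continue  # elongated: leg over antenna, not a comb
            detections.append(
                {"frame": idx, "area": float(region.area), "centroid": region.centroid}
            )
            found = True
        frames_with += bool(found)
    if not detections:
        return CombResult(detected=False, confidence=0.0)
    mean_area = float(np.mean([d["area"] for d in detections]))
    conf = (frames_with / n_frames) * min(1.0, mean_area / cfg.comb_area_ref)
    return CombResult(detected=True, confidence=float(conf), detections=detections)


def combine_evidence(
    r_male: float,
    r_female: float,
    comb: CombResult,
    cfg: SexConfig | None = None,
) -> SexCall:
    """Fuse the two methods into male / female / unknown.

    Combs occur only in males, so confident comb evidence wins outright.
    Otherwise the template correlations decide when their difference is
    large enough; absence of a comb is itself weak evidence for female,
    so a female-leaning correlation needs only half the margin.
    """
    cfg = cfg or SexConfig()
    lum_conf = float(np.clip(abs(r_male - r_female), 0.0, 1.0))
    lum_sex = "male" if r_male >= r_female else "female"
    if comb.detected and comb.confidence >= cfg.tau_comb:
        sex = "male"
    elif lum_conf >= cfg.tau_lum:
        sex = lum_sex
    elif not comb.detected and lum_sex == "female" and lum_conf >= cfg.tau_lum / 2:
        sex = "female"
    else:
        sex = "unknown"
    return SexCall(
        sex=sex,
        r_male=float(r_male),
        r_female=float(r_female),
        lum_confidence=lum_conf,
        comb_detected=comb.detected,
        comb_confidence=comb.confidence,
    )


def call_sex(
    red_aligned_frames: np.ndarray,
    raw_red_frames: np.ndarray,
    transforms,
    body_model,
    cfg: SexConfig | None = None,
    templates: tuple[np.ndarray, np.ndarray] | None = None,
    brightest_index: int = 0,
) -> SexCall:
    """Run both methods for one fly and fuse the evidence.

    ``red_aligned_frames`` feed the luminance method (the abdomen mask
    lives in aligned coordinates); ``raw_red_frames`` with the matching
    per-frame ``transforms`` feed the comb scan.
    """
    cfg = cfg or SexConfig()
    tpl_male, tpl_female = templates or default_templates(cfg.n_samples)
    profile = abdominal_profile(
        red_aligned_frames[brightest_index],
        body_model.segment_mask("abdomen"),
        n_samples=cfg.n_samples,
        min_area=cfg.min_abdomen_area,
    )
    r_male, r_female = correlate_templates(profile, tpl_male, tpl_female)
    head_rows = np.flatnonzero(body_model.segment_mask("head").any(axis=1))
    head_top = int(head_rows[0]) if head_rows.size else 0
    shape = body_model.mask.shape
    apex_aligned = np.array([head_top, body_model.axis_col])
    apices, ups = [], []
    for tf in transforms:
        apices.append(tf.to_raw(apex_aligned, shape)[0])
        # anterior direction in raw coords: where the aligned "up" maps
        up_vec = tf.to_raw(apex_aligned - np.array([10.0, 0.0]), shape)[0] - apices[-1]
        ups.append(up_vec[0] < 0)
    comb = detect_sex_combs(raw_red_frames, np.array(apices), np.array(ups), cfg)
    return combine_evidence(r_male, r_female, comb, cfg)
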