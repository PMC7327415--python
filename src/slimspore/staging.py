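"""Automated sporulation-stage categorization.

A cell image is segmented with a "sausage" model (rectangle capped by two
hemicircles), rotated to the horizontal, and searched for a spore feature
-- a septum or forespore -- by a double-threshold (3-class) Otsu on a
5-frame average.  Candidate connected components are accepted if their
centroid lies within 40% of either cell end, within +-40% of the cell-width
midline, and their area exceeds 10 pixels; among survivors the one with the
highest summed intensity wins, with one retry against the lower Otsu
threshold.  Accepted features are ellipse-fitted and classed 'septa'
(aspect ratio > 1.2) or 'filled'; 'septa' features are skeletonized and a
dimensionless linear curvature computed.  Stages are assigned from the
combination of mYPet and FM4-64 feature classes:

* I (pre-sporulation): no mYPet spore feature;
* II_i: both 'septa', mYPet curvature < 1 (flat septum);
* II_ii: FM 'septa' with mYPet 'filled' (released SpoIIE);
* II_iii: both 'septa', mYPet curvature > 1 (engulfing dome);
* III: both 'filled' (engulfed forespore);
* anything else: indeterminate.

The module also provides the normalized 0-1 forespore coordinate and the
eigenimage (Hotelling-deflation PCA) basis used to validate the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure, morphology, transform
from skimage.filters import threshold_multiotsu, threshold_otsu

from slimspore.config import Config, DEFAULT_CONFIG
from slimspore.simulate import ImageStack

STAGE_LABELS = ("I_pre", "II_i", "II_ii", "II_iii", "III", "indeterminate")


class NoCellError(ValueError):
    """Raised when a frame has no above-threshold pixels to segment."""


@dataclass
class CellSegmentation:
    """Sausage-model segmentation of one cell, in (row, col) pixel
    coordinates of the *rotated* (horizontal) image."""

    mask: np.ndarray                 # boolean, rotated frame
    center: tuple[float, float]      # (row, col)
    orientation_deg: float           # original-image angle, [-90, 90)
    body_length_px: float            # rectangle part of the sausage
    width_px: float
    bounding_box: tuple[int, int, int, int]

    @property
    def total_length_px(self) -> float:
        """Full pole-to-pole sausage length (body + two hemicircle caps)."""
        return self.body_length_px + self.width_px

    @property
    def x_start(self) -> float:
        return self.center[1] - self.total_length_px / 2.0

    @property
    def x_end(self) -> float:
        return self.center[1] + self.total_length_px / 2.0


@dataclass
class SporeFeature:
    """Segmented septum/forespore feature with ellipse descriptors."""

    mask: np.ndarray
    centroid: tuple[float, float]    # (row, col)
    area: int
    major_axis: float
    minor_axis: float
    orientation: float               # radians, skimage convention
    summed_intensity: float
    channel: str = "mYPet"
    shape_class: str | None = None   # 'septa' | 'filled'
    curvature: float | None = None
    # full feature support: the lower-Otsu-threshold component containing
    # the feature, used for curvature (the upper threshold keeps only the
    # brightest arc segment of a curved septum)
    support_mask: np.ndarray | None = None
    intensity_image: np.ndarray | None = None


@dataclass
class StageResult:
    stage: str
    segmentation: CellSegmentation | None = None
    mypet_feature: SporeFeature | None = None
    fm_feature: SporeFeature | None = None


# ---------------------------------------------------------------------------
# segmentation


def _sausage_mask(shape, center, body_length, width):
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    cy, cx = center
    half = body_length / 2.0
    dx = np.clip(np.abs(cc - cx) - half, 0, None)
    return dx ** 2 + (rr - cy) ** 2 <= (width / 2.0) ** 2


def _halfmax_extent(image: np.ndarray, mask: np.ndarray, axis: int,
                    sigma_px: float) -> tuple[float, float]:
    """Outer cell boundary along ``axis`` (0: columns, 1: rows) from the
    half-maximum crossings of the membrane-ridge profile, pulled in by the
    PSF half-width.  The plateau level is the median ridge brightness over
    the central half of the coarse mask, which makes the estimate robust to
    locally brighter (double-membrane) septal features."""
    # restrict the transverse direction to the central half of the cell so
    # the profile tracks the plain membrane ridge: the row profile then
    # ignores polar septal features, while the column profile still sees
    # the cap apex (which lies on the central rows)
    other = np.where(mask.any(axis=1 if axis == 0 else 0))[0]
    o_span = other[-1] - other[0]
    o_lo, o_hi = other[0] + o_span // 4, other[-1] - o_span // 4 + 1
    sub = image[o_lo:o_hi, :] if axis == 0 else image[:, o_lo:o_hi]
    prof = sub.max(axis=0) if axis == 0 else sub.max(axis=1)
    idx = np.where(mask.any(axis=0 if axis == 0 else 1))[0]
    span = idx[-1] - idx[0]
    core = prof[idx[0] + span // 4: idx[-1] - span // 4 + 1]
    plateau = np.median(core) if core.size else prof.max()
    above = np.where(prof >= 0.5 * plateau)[0]
    if above.size == 0:
        above = idx
    shrink = 1.1774 * sigma_px  # half-max radius of a Gaussian ridge
    return above[0] + shrink, above[-1] + 1 - shrink


def segment_cell(frame: np.ndarray, fluor_avg: np.ndarray | None = None,
                 config: Config = DEFAULT_CONFIG) -> CellSegmentation:
    """Coarse threshold segmentation followed by a sausage fit.

    ``frame`` is the reference channel used for the coarse threshold
    (brightfield or a fluorescence average); ``fluor_avg`` is the
    fluorescence average whose above-background signal the sausage must
    enclose (defaults to ``frame``).  The returned segmentation is expressed
    in the rotated-to-horizontal frame; use :func:`rotate_to_horizontal`
    to bring image data into the same frame.
    """
    frame = np.asarray(frame, dtype=float)
    if fluor_avg is None:
        fluor_avg = frame
    if frame.max() <= 0 or np.allclose(frame, frame.flat[0]):
        raise NoCellError("no cell: frame is empty or constant")
    thr = threshold_otsu(frame)
    coarse = frame > thr
    if not coarse.any():
        raise NoCellError("no cell: no above-threshold pixels")
    lbl, _ = ndimage.label(coarse)
    sizes = np.bincount(lbl.ravel())
    sizes[0] = 0
    coarse = lbl == sizes.argmax()
    coarse = ndimage.binary_fill_holes(
        morphology.closing(coarse, morphology.disk(2)))

    props = measure.regionprops(coarse.astype(int))[0]
    # skimage orientation: angle between major axis and the row (vertical)
    # axis; convert to angle from the image x-axis in degrees
    angle = 90.0 - np.degrees(props.orientation)
    if angle >= 90.0:
        angle -= 180.0

    rot = transform.rotate(fluor_avg, angle, center=props.centroid[::-1],
                           preserve_range=True, order=1)
    rot_mask = transform.rotate(coarse.astype(float), angle,
                                center=props.centroid[::-1],
                                preserve_range=True, order=0) > 0.5
    if not rot_mask.any():
        raise NoCellError("no cell: segmentation lost during rotation")

    # cell boundary from half-maximum crossings of the membrane ridge,
    # corrected for the known PSF blur (a Gaussian-blurred thin rim crosses
    # half its peak ~1.18 sigma outside the rim)
    sigma_px = config.psf_fwhm_nm / 2.355 / config.pixel_size_nm
    lo_c, hi_c = _halfmax_extent(rot, rot_mask, axis=0, sigma_px=sigma_px)
    lo_r, hi_r = _halfmax_extent(rot, rot_mask, axis=1, sigma_px=sigma_px)
    cy = (lo_r + hi_r) / 2.0
    cx = (lo_c + hi_c) / 2.0
    total_len = hi_c - lo_c
    width = float(hi_r - lo_r)
    body = max(total_len - width, 1.0)
    rows = np.where(rot_mask.any(axis=1))[0]
    cols = np.where(rot_mask.any(axis=0))[0]
    mask = _sausage_mask(rot.shape, (cy, cx), body, width)
    return CellSegmentation(
        mask=mask, center=(float(cy), float(cx)), orientation_deg=float(angle),
        body_length_px=float(body), width_px=width,
        bounding_box=(int(rows[0]), int(cols[0]), int(rows[-1]) + 1,
                      int(cols[-1]) + 1),
    )


def rotate_to_horizontal(image: np.ndarray, seg: CellSegmentation,
                         original_centroid: tuple[float, float] | None = None
                         ) -> np.ndarray:
    """Rotate a frame by the segmentation angle (about the cell centroid)."""
    if abs(seg.orientation_deg) < 1e-9:
        return np.asarray(image, dtype=float)
    return transform.rotate(np.asarray(image, dtype=float), seg.orientation_deg,
                            center=seg.center[::-1], preserve_range=True,
                            order=1)


# ---------------------------------------------------------------------------
# spore-feature detection


def _frame_average(stack: ImageStack | np.ndarray, n: int = 5) -> np.ndarray:
    frames = stack.frames if isinstance(stack, ImageStack) else np.asarray(stack)
    if frames.ndim == 2:
        return frames.astype(float)
    k = min(n, frames.shape[0])
    return frames[:k].mean(axis=0)


def _candidate_features(mask: np.ndarray, image: np.ndarray, channel: str
                        ) -> list[SporeFeature]:
    lbl = measure.label(mask)
    feats = []
    for p in measure.regionprops(lbl, intensity_image=image):
        feats.append(SporeFeature(
            mask=lbl == p.label,
            centroid=tuple(p.centroid),
            area=int(p.area),
            major_axis=float(p.axis_major_length),
            minor_axis=float(p.axis_minor_length),
            orientation=float(p.orientation),
            summed_intensity=float(p.image_intensity.sum()),
            channel=channel,
            intensity_image=image,
        ))
    return feats


def _passes_rules(f: SporeFeature, seg: CellSegmentation, config: Config,
                  x_range: tuple[float, float] | None,
                  cell_median: float = 0.0) -> bool:
    cy, cx = f.centroid
    # contrast gate: reject noise speckle in a channel with no real feature
    if f.area > 0:
        mean_I = f.summed_intensity / f.area
        if mean_I < config.feature_contrast_min * cell_median:
            return False
    L = seg.total_length_px
    # 5.1 centroid within 40% of either end of the cell (along the axis)
    u = (cx - seg.x_start) / L
    if not (u <= config.end_fraction or u >= 1.0 - config.end_fraction):
        return False
    # 5.2 centroid within +-40% of the middle of the cell width
    if abs(cy - seg.center[0]) > config.width_fraction * seg.width_px / 2.0:
        return False
    # 5.3 area strictly greater than 10 px, no upper threshold
    if f.area <= config.feature_min_area_px:
        return False
    if x_range is not None and not (x_range[0] <= cx <= x_range[1]):
        return False
    return True


def detect_spore_feature(
    fluor_stack: ImageStack | np.ndarray,
    seg: CellSegmentation,
    channel: str = "mYPet",
    config: Config = DEFAULT_CONFIG,
    x_range: tuple[float, float] | None = None,
) -> SporeFeature | None:
    """Find the spore feature in a (rotated) fluorescence stack, or None.

    The 5-frame average is double-threshold (3-class) Otsu'd; connected
    components above the upper threshold inside the cell mask face the
    acceptance rules (position, area, brightest-wins).  If nothing is
    accepted the rules are retried once on the lower-threshold components
    with the first-pass candidates excluded.  ``x_range`` optionally
    restricts candidate centroids to a column interval (used to confine the
    FM4-64 search to the forespore end of the cell).  Absence is a valid
    result and means pre-sporulation for the mYPet channel.
    """
    avg = _frame_average(fluor_stack)
    avg = rotate_to_horizontal(avg, seg) if avg.shape == seg.mask.shape else avg
    inside = avg[seg.mask]
    if inside.size == 0 or avg.max() <= 0:
        return None
    vals = avg[seg.mask]
    if np.unique(vals).size < 3:
        return None
    try:
        lo, hi = threshold_multiotsu(vals, classes=config.otsu_classes)
    except ValueError:
        return None

    cell_median = float(np.median(vals))
    upper_mask = (avg > hi) & seg.mask
    first_pass = _candidate_features(upper_mask, avg, channel)
    accepted = [f for f in first_pass
                if _passes_rules(f, seg, config, x_range, cell_median)]
    if not accepted:
        # one retry: lower-threshold components, first-pass regions excluded
        lower_mask = (avg > lo) & seg.mask & ~upper_mask
        second = _candidate_features(lower_mask, avg, channel)
        accepted = [f for f in second
                    if _passes_rules(f, seg, config, x_range, cell_median)]
    if not accepted:
        return None
    # 5.4: highest summed pixel intensity wins
    best = max(accepted, key=lambda f: f.summed_intensity)
    # attach the lower-threshold component containing the feature
    low_lbl = measure.label((avg > lo) & seg.mask)
    r0, c0 = (int(round(v)) for v in best.centroid)
    lab = low_lbl[np.clip(r0, 0, avg.shape[0] - 1),
                  np.clip(c0, 0, avg.shape[1] - 1)]
    if lab == 0:
        overlap = np.bincount(low_lbl[best.mask].ravel())
        overlap[0] = 0
        lab = overlap.argmax() if overlap.any() else 0
    best.support_mask = low_lbl == lab if lab else best.mask
    return best


def classify_feature_shape(feature: SporeFeature,
                           config: Config = DEFAULT_CONFIG) -> str:
    """'septa' iff the ellipse aspect ratio (major/minor) exceeds 1.2,
    otherwise 'filled'; a degenerate (zero-minor-axis) fit is 'septa'."""
    if feature.minor_axis <= 0:
        feature.shape_class = "septa"
        return "septa"
    ratio = feature.major_axis / feature.minor_axis
    feature.shape_class = "septa" if ratio > config.aspect_threshold else "filled"
    return feature.shape_class


def septum_curvature(feature: SporeFeature,
                     seg: CellSegmentation | None = None) -> float:
    """Dimensionless linear curvature of a septum feature.

    The mask is thinned to a centerline: its pixels are projected onto the
    principal (chord) axis, binned at 1 px, and the mean transverse
    coordinate per bin traces the midline with sub-pixel precision.  With
    the chord drawn between the centerline endpoints and the sagitta the
    maximum perpendicular deviation of the centerline from that chord,
    curvature = sagitta / (chord / 4).  A flat septum scores ~0, a
    hemispherical dome (semicircular midline: sagitta r, chord 2r)
    scores 2; the stage decision threshold sits at 1.  The metric is
    invariant under rotation and translation of the mask.
    """
    # centerline from the bright (upper-threshold) arc, whose ridge is least
    # contaminated by out-of-focus glow; chord span from the full feature
    # support so the bend is normalized to the whole septum extent
    mask = feature.mask
    support = (feature.support_mask if feature.support_mask is not None
               else feature.mask)
    pts = np.column_stack(np.nonzero(mask)).astype(float)
    if len(pts) < 3:
        feature.curvature = 0.0
        return 0.0
    if feature.intensity_image is not None and \
            feature.intensity_image.shape == mask.shape:
        w = feature.intensity_image[mask].astype(float)
        w = np.clip(w - w.min(), 0, None) + 1e-12
    else:
        w = np.ones(len(pts))
    mean = (pts * w[:, None]).sum(axis=0) / w.sum()
    centred = pts - mean
    # weighted principal axis of the mask = chord direction
    cov = (centred * w[:, None]).T @ centred / w.sum()
    _, vecs = np.linalg.eigh(cov)
    u_axis, v_axis = vecs[:, 1], vecs[:, 0]
    u = centred @ u_axis
    v = centred @ v_axis
    bins = np.round(u).astype(int)
    order = np.argsort(bins)
    uniq, starts = np.unique(bins[order], return_index=True)
    if len(uniq) < 3:
        feature.curvature = 0.0
        return 0.0
    bounds = list(starts[1:]) + [len(order)]
    u_mid = np.array([np.average(u[order[s:e]], weights=w[order[s:e]])
                      for s, e in zip(starts, bounds)])
    v_mid = np.array([np.average(v[order[s:e]], weights=w[order[s:e]])
                      for s, e in zip(starts, bounds)])
    sup_pts = np.column_stack(np.nonzero(support)).astype(float) - mean
    sup_u = sup_pts @ u_axis
    chord = float(sup_u.max() - sup_u.min())
    if chord < 1e-9:
        feature.curvature = 0.0
        return 0.0
    # The steep ends of a curved midline are biased straight by transverse
    # PSF mixing, so the bend is estimated from the central portion of the
    # centerline (circle fit) and the sagitta evaluated from the fitted
    # circle across the full chord.
    # a genuinely flat septum shows no bend along its own centerline; only
    # a real bend justifies extrapolating the circle fit to the full chord
    span = u_mid[-1] - u_mid[0]
    if abs(span) > 1e-9:
        t = (u_mid - u_mid[0]) / span
        line = v_mid[0] + t * (v_mid[-1] - v_mid[0])
        direct_sag = float(np.max(np.abs(v_mid - line)))
    else:
        direct_sag = 0.0
    if direct_sag < 0.5:
        kappa = float(min(direct_sag / (chord / 4.0), 2.0))
        feature.curvature = kappa
        return kappa
    centre_u = (u_mid[0] + u_mid[-1]) / 2.0
    sel = np.abs(u_mid - centre_u) <= 0.35 * (u_mid[-1] - u_mid[0])
    if sel.sum() < 3:
        sel = np.ones_like(u_mid, dtype=bool)
    uu, vv = u_mid[sel], v_mid[sel]
    # Kasa algebraic circle fit: u^2 + v^2 + A u + B v + C = 0
    M = np.column_stack([uu, vv, np.ones_like(uu)])
    rhs = -(uu ** 2 + vv ** 2)
    try:
        (A, B, Cc), *_ = np.linalg.lstsq(M, rhs, rcond=None)
        R = float(np.sqrt(max(A ** 2 / 4 + B ** 2 / 4 - Cc, 0.0)))
    except np.linalg.LinAlgError:
        R = np.inf
    half = chord / 2.0
    if not np.isfinite(R) or R <= 0:
        sagitta = 0.0
    elif R <= half:
        sagitta = R
    else:
        sagitta = R - np.sqrt(R ** 2 - half ** 2)
    kappa = float(min(sagitta / (chord / 4.0), 2.0))
    feature.curvature = kappa
    return kappa


def assign_stage(mypet: SporeFeature | None, fm: SporeFeature | None,
                 config: Config = DEFAULT_CONFIG) -> str:
    """Combine mYPet and FM4-64 feature classes into a stage label.

    Pure function of the feature shape classes and the mYPet curvature;
    see the module docstring for the decision table.
    """
    if mypet is None:
        return "I_pre"
    if mypet.shape_class is None:
        classify_feature_shape(mypet, config)
    if fm is not None and fm.shape_class is None:
        classify_feature_shape(fm, config)
    if fm is None:
        return "indeterminate"
    if fm.shape_class == "septa" and mypet.shape_class == "filled":
        return "II_ii"
    if fm.shape_class == "septa" and mypet.shape_class == "septa":
        kappa = mypet.curvature
        if kappa is None:
            kappa = septum_curvature(mypet)
        if kappa < config.curvature_threshold:
            return "II_i"
        if kappa > config.curvature_threshold:
            return "II_iii"
        return "indeterminate"
    if fm.shape_class == "filled" and mypet.shape_class == "filled":
        return "III"
    return "indeterminate"


def classify_cell(
    mypet_stack: ImageStack | np.ndarray,
    fm_stack: ImageStack | np.ndarray,
    config: Config = DEFAULT_CONFIG,
) -> StageResult:
    """Run the full categorization on one two-channel cell image.

    Segmentation uses the FM4-64 average (membrane stain, always present);
    the FM feature search is confined to the cell end holding the mYPet
    feature, implementing the restriction of the FM segmentation to the
    forespore region.
    """
    fm_avg = _frame_average(fm_stack)
    mypet_avg = _frame_average(mypet_stack)
    seg = segment_cell(fm_avg, fm_avg, config)
    fm_rot = rotate_to_horizontal(fm_avg, seg)
    mypet_rot = rotate_to_horizontal(mypet_avg, seg)

    mypet_feat = detect_spore_feature(mypet_rot, seg, "mYPet", config)
    if mypet_feat is None:
        return StageResult("I_pre", seg, None, None)
    classify_feature_shape(mypet_feat, config)
    if mypet_feat.shape_class == "septa":
        septum_curvature(mypet_feat, seg)

    # confine the FM search to the forespore end of the cell
    L = seg.total_length_px
    if mypet_feat.centroid[1] >= seg.center[1]:
        x_range = (seg.center[1], seg.x_end + 1)
    else:
        x_range = (seg.x_start - 1, seg.center[1])
    fm_feat = detect_spore_feature(fm_rot, seg, "FM", config, x_range=x_range)
    if fm_feat is not None:
        classify_feature_shape(fm_feat, config)
    stage = assign_stage(mypet_feat, fm_feat, config)
    return StageResult(stage, seg, mypet_feat, fm_feat)


# ---------------------------------------------------------------------------
# normalized forespore coordinate


def normalized_spore_coordinate(position: tuple[float, float],
                                forespore_mask: np.ndarray,
                                pole_side: str = "right") -> float:
    """Project a (row, col) position onto the cell long axis and normalize
    it 0-1 between the two most extreme points of the forespore mask:
    0 at the mother-cell-side extreme, 1 at the pole-side extreme
    (``pole_side`` is 'left' or 'right' in the rotated frame).  Clamped
    to [0, 1]."""
    forespore_mask = np.asarray(forespore_mask, dtype=bool)
    if not forespore_mask.any():
        raise ValueError("empty forespore mask")
    cols = np.where(forespore_mask.any(axis=0))[0]
    lo, hi = float(cols[0]), float(cols[-1])
    if hi == lo:
        return 0.5
    x = float(position[1])
    if pole_side == "right":
        u = (x - lo) / (hi - lo)
    else:
        u = (hi - x) / (hi - lo)
    return float(np.clip(u, 0.0, 1.0))


# ---------------------------------------------------------------------------
# eigenimage (PCA) validation


@dataclass
class EigenBasis:
    """Orthonormal eigenimages with descending eigenvalues."""

    eigenimages: np.ndarray   # (k, 16, 16)
    eigenvalues: np.ndarray   # (k,), descending, nonnegative

    def eigenvalue_fractions(self) -> np.ndarray:
        tot = self.eigenvalues.sum()
        return self.eigenvalues / tot if tot > 0 else self.eigenvalues


def crop_and_align(image: np.ndarray, feature: SporeFeature,
                   size: int = 16) -> np.ndarray:
    """Rotate the feature's major axis to horizontal, crop ``size``x``size``
    about the centroid and L2-normalize the intensity."""
    angle = 90.0 - np.degrees(feature.orientation)
    rot = transform.rotate(np.asarray(image, float), angle,
                           center=feature.centroid[::-1], preserve_range=True)
    r0 = int(round(feature.centroid[0])) - size // 2
    c0 = int(round(feature.centroid[1])) - size // 2
    padded = np.pad(rot, size, mode="constant")
    crop = padded[r0 + size:r0 + 2 * size, c0 + size:c0 + 2 * size]
    norm = np.linalg.norm(crop)
    return crop / norm if norm > 0 else crop


def eigenimage_basis(crops: np.ndarray, n_components: int = 8,
                     max_iter: int = 5000, tol: float = 1e-14) -> EigenBasis:
    """Principal eigenimages of a crop set by Hotelling's deflation.

    Power iteration finds the leading eigenvector of the raw crop
    second-moment matrix (crops are intensity-normalized upstream, not
    mean-centred, so a set of identical crops is exactly rank one); its
    projection is subtracted and the loop repeats.  The result matches a
    dense eigendecomposition and the eigenimages are mutually orthonormal
    with descending eigenvalues.
    """
    crops = np.asarray(crops, dtype=float)
    if crops.ndim != 3 or len(crops) < 2:
        raise ValueError("need >= 2 image crops")
    k, h, w = crops.shape
    d = h * w
    if n_components > d:
        raise ValueError(f"n_components exceeds pixel dimension {d}")
    X = crops.reshape(k, d)
    C = X.T @ X / (k - 1)
    eigenimages = np.empty((n_components, h, w))
    eigenvalues = np.empty(n_components)
    rng = np.random.default_rng(0)
    for comp in range(n_components):
        v = rng.normal(size=d)
        v /= np.linalg.norm(v)
        for _ in range(max_iter):
            nv = C @ v
            nrm = np.linalg.norm(nv)
            if nrm < 1e-300:
                break
            nv /= nrm
            converged = 1.0 - np.abs(np.dot(nv, v)) < tol
            v = nv
            if converged:
                break
        lam = float(v @ C @ v)
        eigenvalues[comp] = max(lam, 0.0)
        eigenimages[comp] = v.reshape(h, w)
        C -= lam * np.outer(v, v)
    return EigenBasis(eigenimages=eigenimages, eigenvalues=eigenvalues)
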