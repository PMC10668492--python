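"""Three-view extraction, 2-D registration with spine fallback, image
subtraction and SSIM scoring.

For each scan, the largest tumor cross-section along each body axis is
cropped as the smallest enclosing square (plus a margin).  The baseline
view is registered onto the follow-up view with one of three method
classes — keypoint (ORB + RANSAC), monomodal intensity (mean squares) or
multimodal (mutual information) — over a rigid + isotropic-scale transform
family.  When direct registration fails or scores poorly, the transform is
estimated on the rigid spine landmark instead and applied to the nodule
view.  The warped baseline is subtracted from the follow-up view and the
difference is normalized for CNN input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import optimize
from skimage.feature import ORB, match_descriptors
from skimage.measure import ransac
from skimage.transform import SimilarityTransform, resize, warp

__all__ = [
    "ViewSet",
    "RegistrationResult",
    "DeltaImageSet",
    "extract_views",
    "register",
    "spine_fallback_register",
    "subtract",
    "ssim",
    "register_pair",
]

AXES = ("x", "y", "z")  # body axes; arrays are (z, y, x) so x-view fixes axis 2


@dataclass
class ViewSet:
    """Per-axis maximal-cross-section square crops for one timepoint."""

    views: dict[str, np.ndarray]
    crop_boxes: dict[str, tuple[int, slice, slice]]  # (slice index, rows, cols)

    def __getitem__(self, axis: str) -> np.ndarray:
        return self.views[axis]


@dataclass
class RegistrationResult:
    """An estimated 2-D transform with its quality score."""

    method: str
    transform: SimilarityTransform
    warped_image: np.ndarray
    ssim: float
    fallback_used: bool = False

    @property
    def translation(self) -> tuple[float, float]:
        return tuple(self.transform.translation)

    @property
    def rotation_deg(self) -> float:
        return float(np.rad2deg(self.transform.rotation))

    @property
    def scale(self) -> float:
        return float(self.transform.scale)


@dataclass
class DeltaImageSet:
    """Per-axis normalized difference images (follow-up − warped baseline)."""

    images: dict[str, np.ndarray]
    subject_id: str = ""
    registration: dict[str, RegistrationResult] = field(default_factory=dict)

    def stacked(self) -> np.ndarray:
        return np.stack([self.images[a] for a in AXES])


# ---------------------------------------------------------------------------
# view extraction

_VIEW_AXIS = {"x": 2, "y": 1, "z": 0}


def extract_views(volume: np.ndarray, mask: np.ndarray, margin: int = 4) -> ViewSet:
    """Crop the largest tumor cross-section along each body axis.

    The slice maximizing the in-plane mask area is chosen (lowest index on
    ties); the crop is the tight bounding square of the mask in that slice
    expanded by ``margin`` pixels, zero-padded where it leaves the grid.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("mask is empty")
    volume = np.asarray(volume, dtype=float)
    views, boxes = {}, {}
    for axis_name, axis in _VIEW_AXIS.items():
        areas = mask.sum(axis=tuple(a for a in range(3) if a != axis))
        idx = int(np.argmax(areas))  # argmax takes the lowest index on ties
        plane = np.take(volume, idx, axis=axis)
        pmask = np.take(mask, idx, axis=axis)
        rows = np.where(pmask.any(axis=1))[0]
        cols = np.where(pmask.any(axis=0))[0]
        r0, r1 = rows[0], rows[-1] + 1
        c0, c1 = cols[0], cols[-1] + 1
        side = max(r1 - r0, c1 - c0) + 2 * margin
        rc, cc = (r0 + r1) // 2, (c0 + c1) // 2
        r0s, c0s = rc - side // 2, cc - side // 2
        crop = np.zeros((side, side), dtype=float)
        rr0, rr1 = max(0, r0s), min(plane.shape[0], r0s + side)
        cc0, cc1 = max(0, c0s), min(plane.shape[1], c0s + side)
        crop[rr0 - r0s:rr1 - r0s, cc0 - c0s:cc1 - c0s] = plane[rr0:rr1, cc0:cc1]
        views[axis_name] = crop
        boxes[axis_name] = (idx, slice(r0s, r0s + side), slice(c0s, c0s + side))
    return ViewSet(views=views, crop_boxes=boxes)


def extract_spine_views(volume: np.ndarray, nodule_views: ViewSet,
                        threshold_hu: float = 150.0, side: int = 48,
                        centers: dict | None = None):
    """Square crops of the spine landmark from the nodule-view slices.

    Returns ``(crops, centers)``.  Pass the fixed scan's ``centers`` when
    cropping the moving scan so both timepoints use the same window —
    otherwise re-centering on each scan's own landmark would absorb the
    very motion the spine registration is meant to recover.  When the
    nodule's slice does not intersect the spine (e.g. a coronal view
    anterior to it), the slice with the strongest landmark along the same
    axis is used instead; the estimated transform is in-plane either way.
    """
    out, used_centers = {}, {}
    volume = np.asarray(volume, dtype=float)
    for axis_name, (idx, _, _) in nodule_views.crop_boxes.items():
        axis = _VIEW_AXIS[axis_name]
        if centers is not None:
            idx, rc, cc = centers[axis_name]
            plane = np.take(volume, idx, axis=axis)
        else:
            plane = np.take(volume, idx, axis=axis)
            bright = plane >= threshold_hu
            if not bright.any():
                counts = (volume >= threshold_hu).sum(
                    axis=tuple(a for a in range(3) if a != axis))
                if counts.max() == 0:
                    raise ValueError(
                        f"no spine landmark above {threshold_hu} HU anywhere "
                        f"along the {axis_name} axis")
                idx = int(np.argmax(counts))
                plane = np.take(volume, idx, axis=axis)
                bright = plane >= threshold_hu
            rows = np.where(bright.any(axis=1))[0]
            cols = np.where(bright.any(axis=0))[0]
            rc = int((rows[0] + rows[-1]) // 2)
            cc = int((cols[0] + cols[-1]) // 2)
        used_centers[axis_name] = (idx, rc, cc)
        half = side // 2
        crop = np.full((side, side), plane.min(), dtype=float)
        rr0, rr1 = max(0, rc - half), min(plane.shape[0], rc + half)
        cc0, cc1 = max(0, cc - half), min(plane.shape[1], cc + half)
        crop[rr0 - (rc - half):rr1 - (rc - half),
             cc0 - (cc - half):cc1 - (cc - half)] = plane[rr0:rr1, cc0:cc1]
        out[axis_name] = crop
    return out, used_centers


# ---------------------------------------------------------------------------
# SSIM

def _gaussian_kernel(size: int, sigma: float) -> np.ndarray:
    ax = np.arange(size) - (size - 1) / 2.0
    g = np.exp(-(ax**2) / (2.0 * sigma**2))
    k = np.outer(g, g)
    return k / k.sum()


def ssim(a: np.ndarray, b: np.ndarray, window: int = 11, sigma: float = 1.5,
         k1: float = 0.01, k2: float = 0.03, data_range: float | None = None) -> float:
    """Structural similarity with a Gaussian window, averaged over all
    fully-inside (valid) window positions.

    A constant pair of images scores 1.0 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    if data_range is None:
        lo = min(a.min(), b.min())
        hi = max(a.max(), b.max())
        data_range = hi - lo
    if data_range == 0:
        return 1.0
    win = min(window, *a.shape)
    kern = _gaussian_kernel(win, sigma)

    def local(img):
        return np.tensordot(sliding_window_view(img, (win, win)), kern, axes=([2, 3], [0, 1]))

    mu_a, mu_b = local(a), local(b)
    e_aa, e_bb, e_ab = local(a * a), local(b * b), local(a * b)
    var_a = e_aa - mu_a**2
    var_b = e_bb - mu_b**2
    cov = e_ab - mu_a * mu_b
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    num = (2 * mu_a * mu_b + c1) * (2 * cov + c2)
    den = (mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2)
    return float(np.mean(num / den))


# ---------------------------------------------------------------------------
# registration

def _apply_transform(moving: np.ndarray, tf: SimilarityTransform) -> np.ndarray:
    # tf maps moving -> fixed coordinates; warp wants the inverse map
    return warp(moving, tf.inverse, output_shape=moving.shape,
                order=1, mode="constant", cval=float(moving.min()), preserve_range=True)


def _params_to_tf(params, shape, rigid_only=False) -> SimilarityTransform:
    ty, tx, theta_deg = params[:3]
    scale = 1.0 if rigid_only else float(params[3])
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    centre = SimilarityTransform(translation=(-cx, -cy))
    core = SimilarityTransform(rotation=np.deg2rad(theta_deg), scale=scale)
    back = SimilarityTransform(translation=(cx + tx, cy + ty))
    return SimilarityTransform(matrix=back.params @ core.params @ centre.params)


def _mse_metric(fixed, warped):
    return float(np.mean((fixed - warped) ** 2))


def _mi_metric(fixed, warped, bins: int = 32):
    hist, _, _ = np.histogram2d(fixed.ravel(), warped.ravel(), bins=bins)
    p = hist / hist.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))


def _phase_translation(fixed, moving):
    from skimage.registration import phase_cross_correlation

    try:
        shift, _, _ = phase_cross_correlation(fixed, moving, upsample_factor=10)
        return float(shift[0]), float(shift[1])
    except Exception:
        return 0.0, 0.0


def _intensity_register(fixed, moving, metric, rigid_only=False):
    ty0, tx0 = _phase_translation(fixed, moving)
    maximize = metric is _mi_metric

    big = 1e12

    def cost(params):
        if not rigid_only and not 0.3 <= params[3] <= 3.0:
            return big  # keep the scale in a sane, invertible range
        if abs(params[0]) > fixed.shape[0] or abs(params[1]) > fixed.shape[1]:
            return big
        tf = _params_to_tf(params, fixed.shape, rigid_only)
        w = _apply_transform(moving, tf)
        v = metric(fixed, w)
        return -v if maximize else v

    # clamp the phase-correlation init: wrap-around estimates can strand the
    # optimizer in a no-overlap plateau
    lim = max(fixed.shape) / 3.0
    ty0 = float(np.clip(ty0, -lim, lim))
    tx0 = float(np.clip(tx0, -lim, lim))
    tail = [] if rigid_only else [1.0]
    starts = [[ty0, tx0, th] + tail for th in (0.0, -8.0, 8.0)]
    starts.append([0.0, 0.0, 0.0] + tail)
    # refine only the two most promising starts
    starts.sort(key=cost)
    best_x, best_f = starts[0], cost(starts[0])
    for start in starts[:2]:
        res = optimize.minimize(cost, start, method="Powell",
                                options={"xtol": 1e-3, "ftol": 1e-6, "maxiter": 300})
        if res.fun < best_f:
            best_x, best_f = res.x, res.fun
    return _params_to_tf(best_x, fixed.shape, rigid_only)


def _keypoint_register(fixed, moving):
    def norm(img):
        rng = img.max() - img.min()
        return (img - img.min()) / rng if rng > 0 else img * 0.0

    orb = ORB(n_keypoints=200, fast_threshold=0.05)
    try:
        orb.detect_and_extract(norm(fixed))
        kf, df = orb.keypoints, orb.descriptors
        orb.detect_and_extract(norm(moving))
        km, dm = orb.keypoints, orb.descriptors
    except RuntimeError as exc:
        raise RuntimeError("keypoint detection failed") from exc
    matches = match_descriptors(dm, df, cross_check=True)
    if len(matches) < 3:
        raise RuntimeError("fewer than 3 matched keypoints; fallback needed")
    src = km[matches[:, 0]][:, ::-1]  # (row, col) -> (x, y)
    dst = kf[matches[:, 1]][:, ::-1]
    model, inliers = ransac((src, dst), SimilarityTransform, min_samples=3,
                            residual_threshold=2.0, max_trials=500, rng=0)
    if model is None or inliers is None or inliers.sum() < 3:
        raise RuntimeError("RANSAC found fewer than 3 inliers; fallback needed")
    return SimilarityTransform(matrix=model.params)


def register(fixed: np.ndarray, moving: np.ndarray, method: str = "multimodal_mi",
             safeguard_tol: float = 0.02) -> RegistrationResult:
    """Estimate a rigid+scale transform aligning ``moving`` onto ``fixed``.

    Methods: ``keypoint`` (ORB features + RANSAC similarity fit),
    ``monomodal_intensity`` (mean-squares minimization) and
    ``multimodal_mi`` (mutual-information maximization).  If the warped
    result scores worse in SSIM than the untransformed pair by more than
    ``safeguard_tol``, the identity transform is returned instead.
    """
    fixed = np.asarray(fixed, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if fixed.ndim != moving.ndim:
        raise ValueError("images must share dimensionality")
    if moving.shape != fixed.shape:
        moving = resize(moving, fixed.shape, order=1, preserve_range=True, anti_aliasing=True)
    if method == "keypoint":
        tf = _keypoint_register(fixed, moving)
    elif method == "monomodal_intensity":
        tf = _intensity_register(fixed, moving, _mse_metric)
    elif method == "multimodal_mi":
        tf = _intensity_register(fixed, moving, _mi_metric)
    else:
        raise ValueError(f"unknown registration method {method!r}")
    warped = _apply_transform(moving, tf)
    score = ssim(fixed, warped)
    baseline_score = ssim(fixed, moving)
    if score < baseline_score - safeguard_tol:
        tf = SimilarityTransform()
        warped = moving
        score = baseline_score
    return RegistrationResult(method=method, transform=tf, warped_image=warped, ssim=score)


def spine_fallback_register(fixed_spine: np.ndarray, moving_spine: np.ndarray,
                            moving_nodule_view: np.ndarray,
                            fixed_nodule_view: np.ndarray | None = None) -> RegistrationResult:
    """Estimate a rigid transform on the spine crops, apply it to the nodule view.

    The spine is treated as absolutely rigid, so only translation+rotation
    are fit (scale fixed at 1).  ``fixed_nodule_view`` is used for the SSIM
    report when given.
    """
    fixed_spine = np.asarray(fixed_spine, dtype=float)
    moving_spine = np.asarray(moving_spine, dtype=float)
    if moving_spine.shape != fixed_spine.shape:
        raise ValueError("spine crops must come from matching grids")
    tf = _intensity_register(fixed_spine, moving_spine, _mse_metric, rigid_only=True)
    spine_score = ssim(fixed_spine, _apply_transform(moving_spine, tf))
    if spine_score < 0.2:
        raise RuntimeError(
            f"spine registration failed (SSIM {spine_score:.3f}); "
            "the landmark crops may not correspond"
        )
    view = np.asarray(moving_nodule_view, dtype=float)
    warped = _apply_transform(view, tf)
    score = (
        ssim(np.asarray(fixed_nodule_view, dtype=float), warped)
        if fixed_nodule_view is not None else spine_score
    )
    return RegistrationResult(method="spine_fallback", transform=tf,
                              warped_image=warped, ssim=score, fallback_used=True)


# ---------------------------------------------------------------------------
# subtraction

def subtract(warped_baseline: np.ndarray, followup_view: np.ndarray,
             clip_hu: float = 200.0, out_size: int | None = 64,
             normalize: bool = True) -> np.ndarray:
    """Delta-image: follow-up minus warped baseline, normalized for the CNN.

    The raw difference is clipped symmetrically at ±``clip_hu`` and mapped
    linearly to [0, 1] (0.5 = no change), then resized to
    ``out_size`` × ``out_size``.  With ``normalize=False`` the raw
    difference is returned.
    """
    a = np.asarray(warped_baseline, dtype=float)
    b = np.asarray(followup_view, dtype=float)
    if a.shape != b.shape:
        raise ValueError("views must share a grid")
    diff = b - a
    if not normalize:
        return diff
    out = (np.clip(diff, -clip_hu, clip_hu) + clip_hu) / (2.0 * clip_hu)
    if out_size is not None and out.shape != (out_size, out_size):
        out = resize(out, (out_size, out_size), order=1,
                     preserve_range=True, anti_aliasing=True)
    return out


def register_pair(pair, method: str = "multimodal_mi", fallback_threshold: float = 0.5,
                  out_size: int = 64, clip_hu: float = 200.0, margin: int = 4) -> DeltaImageSet:
    """Full per-subject path: views → registration (spine fallback) → delta-images."""
    fixed_views = extract_views(pair.followup_volume, pair.followup_mask, margin=margin)
    moving_views = extract_views(pair.baseline_volume, pair.baseline_mask, margin=margin)
    images, regs = {}, {}
    spine_fixed = spine_moving = None
    for axis in AXES:
        fixed = fixed_views[axis]
        moving = moving_views[axis]
        try:
            res = register(fixed, moving, method=method)
        except RuntimeError:
            res = None
        if res is None or res.ssim < fallback_threshold:
            if spine_fixed is None:
                spine_fixed, centers = extract_spine_views(
                    pair.followup_volume, fixed_views)
                spine_moving, _ = extract_spine_views(
                    pair.baseline_volume, fixed_views, centers=centers)
            moving_rs = resize(moving, fixed.shape, order=1, preserve_range=True,
                               anti_aliasing=True)
            res = spine_fallback_register(spine_fixed[axis], spine_moving[axis],
                                          moving_rs, fixed_nodule_view=fixed)
        regs[axis] = res
        images[axis] = subtract(res.warped_image, fixed, clip_hu=clip_hu, out_size=out_size)
    return DeltaImageSet(images=images, subject_id=getattr(pair, "subject_id", ""),
                         registration=regs)
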