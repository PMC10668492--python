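"""Synthetic longitudinal CT nodule phantoms.

Generates paired baseline/follow-up volumes of an ellipsoidal, textured
nodule embedded in a low-attenuation lung background, optionally with a
high-attenuation spine landmark.  Between the two scans the nodule grows
(exponentially per axis by default), its internal heterogeneity may drift,
and the whole scene undergoes a rigid inter-scan motion, so that every
downstream stage — mask refinement, radiomics, time-slope deltas,
registration, subtraction and CNN training — can be exercised with a known
ground truth.

Conventions: arrays are indexed (z, y, x); spacing is given per axis in mm
in the same order; intensities are Hounsfield units.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

__all__ = [
    "PhantomSpec",
    "PhantomPair",
    "ClassRecipe",
    "generate_volume",
    "generate_pair",
    "generate_cohort",
    "default_recipes",
    "growth_signal_recipes",
]

# chest-CT-like attenuation levels (HU); configurable per spec
LUNG_HU = -800.0
NODULE_HU = -50.0
SPINE_HU = 300.0


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterization of one synthetic scan pair.

    Parameters
    ----------
    grid_shape : (nz, ny, nx) voxels.
    spacing_mm : per-axis voxel size (z, y, x) in mm.
    nodule_center_mm : nodule centre in world mm (z, y, x).
    radii_mm : baseline ellipsoid semi-axes (z, y, x) in mm.
    growth_rates_per_day : per-axis relative growth rate (1/day);
        radii follow r_i(t) = r_i0 * exp(g_i * (t - t_b)) by default,
        or r_i0 * (1 + g_i * (t - t_b)) when ``linear_growth``.
    texture_sd_hu : SD of the intra-nodule heterogeneity field at baseline.
    heterogeneity_drift_per_day : change of texture SD per day.
    motion_translation_mm / motion_rotation_deg : rigid scene motion applied
        to the follow-up scan (rotation about the z axis through the grid
        centre, in-plane, plus a 3-D translation).
    noise_sd_hu : SD of additive Gaussian noise, drawn fresh per scan.
    interval_days : follow-up minus baseline acquisition time (> 0).
    include_spine : render a rigid high-attenuation spine block.
    seed : RNG seed; generation is deterministic given the spec.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    nodule_center_mm: tuple[float, float, float] | None = None
    radii_mm: tuple[float, float, float] = (6.0, 6.0, 6.0)
    growth_rates_per_day: tuple[float, float, float] = (0.0, 0.0, 0.0)
    texture_sd_hu: float = 0.0
    heterogeneity_drift_per_day: float = 0.0
    motion_translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    motion_rotation_deg: float = 0.0
    noise_sd_hu: float = 0.0
    interval_days: float = 90.0
    include_spine: bool = True
    linear_growth: bool = False
    seed: int = 0

    def __post_init__(self):
        if any(r <= 0 for r in self.radii_mm):
            raise ValueError("radii_mm must be positive")
        if self.interval_days <= 0:
            raise ValueError("interval_days must be positive")
        if self.nodule_center_mm is None:
            centre = tuple(
                0.5 * (n - 1) * s for n, s in zip(self.grid_shape, self.spacing_mm)
            )
            object.__setattr__(self, "nodule_center_mm", centre)
        # grid must contain the nodule at both timepoints
        for t in (0.0, self.interval_days):
            radii = self.radii_at(t)
            for c, r, n, s in zip(
                self.nodule_center_mm, radii, self.grid_shape, self.spacing_mm
            ):
                if c - r < 0 or c + r > (n - 1) * s:
                    raise ValueError(
                        f"nodule (radius {r:.1f} mm at t={t:.0f} d) exceeds grid"
                    )

    def radii_at(self, t_days: float) -> tuple[float, float, float]:
        """Ellipsoid semi-axes at time ``t_days`` after baseline."""
        if self.linear_growth:
            return tuple(
                r * (1.0 + g * t_days)
                for r, g in zip(self.radii_mm, self.growth_rates_per_day)
            )
        return tuple(
            r * float(np.exp(g * t_days))
            for r, g in zip(self.radii_mm, self.growth_rates_per_day)
        )

    def texture_sd_at(self, t_days: float) -> float:
        return max(0.0, self.texture_sd_hu + self.heterogeneity_drift_per_day * t_days)


@dataclass
class PhantomPair:
    """One subject's baseline + follow-up scan with truth masks and label."""

    baseline_volume: np.ndarray
    followup_volume: np.ndarray
    baseline_mask: np.ndarray
    followup_mask: np.ndarray
    times_days: tuple[float, float]
    label: int
    truth: PhantomSpec
    subject_id: str = "s000"

    def __post_init__(self):
        if not self.baseline_mask.any() or not self.followup_mask.any():
            raise ValueError("phantom masks must be nonempty")
        if self.baseline_volume.shape != self.followup_volume.shape:
            raise ValueError("pair volumes must share one grid")
        if self.times_days[1] <= self.times_days[0]:
            raise ValueError("follow-up time must exceed baseline time")

    @property
    def spacing_mm(self) -> tuple[float, float, float]:
        return self.truth.spacing_mm

    @property
    def interval_days(self) -> float:
        return self.times_days[1] - self.times_days[0]


def _world_coords(spec: PhantomSpec):
    axes = [
        np.arange(n, dtype=float) * s
        for n, s in zip(spec.grid_shape, spec.spacing_mm)
    ]
    return np.meshgrid(*axes, indexing="ij")


def _rigid_inverse(spec: PhantomSpec, coords):
    """Map follow-up grid coordinates back into the baseline scene frame.

    The follow-up scene is the baseline scene moved by (R, t); to render it
    we evaluate scene functions at R^-1 (x - t), rotating in-plane about the
    grid centre.
    """
    z, y, x = coords
    tz, ty, tx = spec.motion_translation_mm
    theta = np.deg2rad(spec.motion_rotation_deg)
    cz = 0.5 * (spec.grid_shape[0] - 1) * spec.spacing_mm[0]
    cy = 0.5 * (spec.grid_shape[1] - 1) * spec.spacing_mm[1]
    cx = 0.5 * (spec.grid_shape[2] - 1) * spec.spacing_mm[2]
    zs = z - tz
    ys = y - ty - cy
    xs = x - tx - cx
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    # inverse of an in-plane (y,x) rotation by theta
    yr = cos_t * ys + sin_t * xs
    xr = -sin_t * ys + cos_t * xs
    return zs, yr + cy, xr + cx


_TEXTURE_LATTICE = 33  # canonical texture field resolution (per axis)


def _texture_field(rng: np.random.Generator) -> np.ndarray:
    """Smooth zero-mean unit-variance heterogeneity field on [-1, 1]^3."""
    raw = rng.standard_normal((_TEXTURE_LATTICE,) * 3)
    smooth = gaussian_filter(raw, sigma=1.5, mode="wrap")
    smooth -= smooth.mean()
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def generate_volume(
    spec: PhantomSpec, time_days: float = 0.0, _moved: bool | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Render the scene at ``time_days`` after baseline.

    Returns ``(volume_hu, mask)`` where the mask is the analytic ellipsoid
    of the grown radii (never derived from the rendered intensities).  The
    rigid inter-scan motion is applied whenever ``time_days > 0`` (or when
    ``_moved`` explicitly says so), so a follow-up call sees the moved,
    grown nodule and the moved spine.
    """
    moved = (time_days > 0) if _moved is None else _moved
    rng = np.random.default_rng(
        np.random.SeedSequence([int(spec.seed), 1 if moved else 0])
    )
    texture_rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 7]))

    coords = _world_coords(spec)
    scene = _rigid_inverse(spec, coords) if moved else coords

    radii = spec.radii_at(time_days)
    centre = spec.nodule_center_mm
    # local normalized nodule frame: the texture rides along with the nodule
    u = [(c - c0) / r for c, c0, r in zip(scene, centre, radii)]
    rho2 = u[0] ** 2 + u[1] ** 2 + u[2] ** 2
    inside = rho2 <= 1.0

    volume = np.full(spec.grid_shape, LUNG_HU, dtype=float)
    volume[inside] = NODULE_HU

    sd_t = spec.texture_sd_at(time_days)
    if sd_t > 0:
        fld = _texture_field(texture_rng)
        half = (_TEXTURE_LATTICE - 1) / 2.0
        # map local nodule coords in [-1, 1] onto the canonical lattice
        idx = [np.clip((ui[inside] + 1.0) * half, 0, _TEXTURE_LATTICE - 1) for ui in u]
        vals = map_coordinates(fld, np.vstack(idx), order=1, mode="nearest")
        volume[inside] += sd_t * vals

    if spec.include_spine:
        # rigid posterior block, ~15 mm wide, spanning the full z extent
        _, ys, xs = scene
        ny_mm = (spec.grid_shape[1] - 1) * spec.spacing_mm[1]
        nx_mm = (spec.grid_shape[2] - 1) * spec.spacing_mm[2]
        spine = (
            (ys >= ny_mm - 12.0)
            & (ys <= ny_mm - 2.0)
            & (np.abs(xs - nx_mm / 2.0) <= 8.0)
        )
        volume[spine] = SPINE_HU

    if spec.noise_sd_hu > 0:
        volume = volume + rng.normal(0.0, spec.noise_sd_hu, size=spec.grid_shape)

    # analytic mask on the same (possibly moved) scene frame
    mask = inside.copy()
    if not mask.any():
        raise ValueError("nodule mask empty on this grid")
    return volume, mask


def generate_pair(spec: PhantomSpec, label: int = 0, subject_id: str = "s000") -> PhantomPair:
    """Generate the baseline/follow-up pair described by ``spec``."""
    base_vol, base_mask = generate_volume(spec, 0.0, _moved=False)
    fu_vol, fu_mask = generate_volume(spec, spec.interval_days, _moved=True)
    return PhantomPair(
        baseline_volume=base_vol,
        followup_volume=fu_vol,
        baseline_mask=base_mask,
        followup_mask=fu_mask,
        times_days=(0.0, spec.interval_days),
        label=int(label),
        truth=spec,
        subject_id=subject_id,
    )


@dataclass(frozen=True)
class ClassRecipe:
    """Sampling distribution of PhantomSpec fields for one STAS class.

    Each draw perturbs the template: baseline radii U(radius_range) per
    axis scaled by per-axis anisotropy factors, growth rate
    U(growth_range) with per-axis anisotropy, and so on.  ``followup_radius_match``
    instead samples the *follow-up* mean radius from radius_range and
    back-computes baseline radii, which makes the classes'
    follow-up marginals coincide while growth dynamics differ.
    """

    template: PhantomSpec = field(default_factory=PhantomSpec)
    radius_range_mm: tuple[float, float] = (5.0, 8.0)
    growth_range_per_day: tuple[float, float] = (0.0, 0.002)
    growth_anisotropy: tuple[float, float, float] = (1.0, 1.0, 1.0)
    texture_sd_hu: float = 20.0
    heterogeneity_drift_per_day: float = 0.0
    motion_translation_sd_mm: float = 2.0
    motion_rotation_sd_deg: float = 2.0
    noise_sd_hu: float = 5.0
    interval_range_days: tuple[float, float] = (30.0, 180.0)
    followup_radius_match: bool = False

    def draw(self, rng: np.random.Generator, seed: int) -> PhantomSpec:
        interval = float(rng.uniform(*self.interval_range_days))
        g = float(rng.uniform(*self.growth_range_per_day))
        growth = tuple(g * a for a in self.growth_anisotropy)
        r = float(rng.uniform(*self.radius_range_mm))
        jitter = rng.uniform(0.9, 1.1, size=3)
        radii = np.array([r, r, r]) * jitter
        if self.followup_radius_match:
            radii = radii * np.exp(-np.array(growth) * interval)
        motion_t = tuple(rng.normal(0.0, self.motion_translation_sd_mm, size=3))
        motion_r = float(rng.normal(0.0, self.motion_rotation_sd_deg))
        return dataclasses.replace(
            self.template,
            radii_mm=tuple(float(x) for x in radii),
            growth_rates_per_day=growth,
            texture_sd_hu=self.texture_sd_hu,
            heterogeneity_drift_per_day=self.heterogeneity_drift_per_day,
            motion_translation_mm=tuple(float(x) for x in motion_t),
            motion_rotation_deg=motion_r,
            noise_sd_hu=self.noise_sd_hu,
            interval_days=interval,
            seed=int(seed),
        )


def default_recipes() -> dict[int, ClassRecipe]:
    """Default class recipes: positives grow faster, anisotropically, with
    heterogeneity drift; negatives grow slowly and isotropically.

    Growth rates correspond to volume doubling times of roughly 300+ days
    (negatives) vs 50–120 days (positives), typical of indolent vs
    aggressive lung nodules; both stay inside the default grid over the
    longest sampled interval.
    """
    return {
        0: ClassRecipe(
            growth_range_per_day=(0.0, 0.001),
            growth_anisotropy=(1.0, 1.0, 1.0),
            heterogeneity_drift_per_day=0.0,
            interval_range_days=(30.0, 120.0),
        ),
        1: ClassRecipe(
            growth_range_per_day=(0.002, 0.005),
            growth_anisotropy=(1.4, 1.0, 0.7),
            heterogeneity_drift_per_day=0.15,
            interval_range_days=(30.0, 120.0),
        ),
    }


def growth_signal_recipes(interval_days: float = 90.0) -> dict[int, ClassRecipe]:
    """Recipes whose *follow-up* size marginals coincide across classes.

    Both classes grow isotropically and end at the same follow-up radius
    distribution; only the growth *rate* (hence the baseline size and the
    size trajectory) separates them.  Classic follow-up-only features then
    carry no class signal while time-slope deltas and delta-images do.
    """
    common = dict(
        radius_range_mm=(6.0, 9.0),
        interval_range_days=(interval_days, interval_days),
        followup_radius_match=True,
        texture_sd_hu=20.0,
        noise_sd_hu=5.0,
    )
    return {
        0: ClassRecipe(growth_range_per_day=(0.0005, 0.0015), **common),
        1: ClassRecipe(growth_range_per_day=(0.008, 0.012), **common),
    }


def generate_cohort(
    n: int,
    class_recipes: dict[int, ClassRecipe] | None = None,
    prevalence: float = 0.244,
    seed: int = 0,
) -> list[PhantomPair]:
    """Generate ``n`` subjects with exactly ``round(n * prevalence)`` positives.

    Per-subject seeds are spawned reproducibly from the master seed, so two
    calls with the same arguments yield identical cohorts.
    """
    if n < 2:
        raise ValueError("cohort size must be at least 2")
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must lie strictly in (0, 1)")
    recipes = class_recipes if class_recipes is not None else default_recipes()
    n_pos = int(round(n * prevalence))
    labels = np.array([1] * n_pos + [0] * (n - n_pos))
    master = np.random.default_rng(np.random.SeedSequence(int(seed)))
    order = master.permutation(n)
    labels = labels[order]
    pairs = []
    for i, lab in enumerate(labels):
        sub_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11, i]))
        sub_seed = int(sub_rng.integers(0, 2**31 - 1))
        spec = recipes[int(lab)].draw(sub_rng, sub_seed)
        pairs.append(generate_pair(spec, label=int(lab), subject_id=f"s{i:03d}"))
    return pairs
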