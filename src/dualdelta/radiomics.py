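"""Radiomics feature extraction.

Implements the standard 851-feature inventory used for CT nodules:

* 14 shape features (mesh- and PCA-based, computed once on the 3-D mask),
* 93 intensity/texture features on the original image — 18 first-order,
  24 GLCM, 14 GLDM, 16 GLRLM, 16 GLSZM and 5 NGTDM — and
* the same 93 recomputed on each of the 8 sub-band images of a one-level
  3-D discrete wavelet decomposition (LLL ... HHH), i.e. 744 wavelet
  features.

Naming follows the common ``<filter>_<family>_<Name>`` convention
(e.g. ``original_glcm_Contrast``, ``wavelet-LLH_firstorder_Mean``).

Gray levels are discretized with a fixed bin width (default 25 HU).
Texture matrices (GLCM, GLRLM) aggregate over the 13 unique 3-D direction
offsets; GLSZM zones use 26-connectivity.  All computations are plain
NumPy/SciPy and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import ndimage
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from skimage import measure

from .roi import RegionMask

__all__ = [
    "RadiomicsConfig",
    "FeatureVector",
    "FeatureTable",
    "extract_features",
    "minmax_normalize",
    "feature_names",
    "FAMILY_COUNTS",
    "WAVELET_BANDS",
]

_EPS = np.spacing(1.0)

FAMILY_COUNTS = {
    "shape": 14,
    "firstorder": 18,
    "glcm": 24,
    "gldm": 14,
    "glrlm": 16,
    "glszm": 16,
    "ngtdm": 5,
}

WAVELET_BANDS = ("LLL", "LLH", "LHL", "HLL", "LHH", "HLH", "HHL", "HHH")

SHAPE_NAMES = (
    "MeshVolume", "VoxelVolume", "SurfaceArea", "SurfaceVolumeRatio",
    "Sphericity", "Maximum3DDiameter", "Maximum2DDiameterSlice",
    "Maximum2DDiameterColumn", "Maximum2DDiameterRow", "MajorAxisLength",
    "MinorAxisLength", "LeastAxisLength", "Elongation", "Flatness",
)
FIRSTORDER_NAMES = (
    "Energy", "TotalEnergy", "Entropy", "Minimum", "10Percentile",
    "90Percentile", "Maximum", "Mean", "Median", "InterquartileRange",
    "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity",
)
GLCM_NAMES = (
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "JointEnergy", "JointEntropy",
    "Imc1", "Imc2", "Idm", "Idmn", "Id", "Idn", "InverseVariance",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares", "MCC",
)
GLDM_NAMES = (
    "SmallDependenceEmphasis", "LargeDependenceEmphasis",
    "GrayLevelNonUniformity", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "GrayLevelVariance",
    "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)
GLRLM_NAMES = (
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
    "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)
GLSZM_NAMES = (
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage", "GrayLevelVariance",
    "ZoneVariance", "ZoneEntropy", "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)
NGTDM_NAMES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")

_TEXTURE_FAMILIES = (
    ("firstorder", FIRSTORDER_NAMES),
    ("glcm", GLCM_NAMES),
    ("gldm", GLDM_NAMES),
    ("glrlm", GLRLM_NAMES),
    ("glszm", GLSZM_NAMES),
    ("ngtdm", NGTDM_NAMES),
)

# the 13 unique 3-D direction offsets (half of the 26-neighborhood)
_OFFSETS_13 = [
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1),
    (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]
_OFFSETS_26 = _OFFSETS_13 + [tuple(-o for o in d) for d in _OFFSETS_13]


@dataclass(frozen=True)
class RadiomicsConfig:
    """Extraction settings.

    bin_width_hu : fixed gray-level bin width for discretization (HU).
    resample_spacing_mm : isotropic spacing to resample to before texture
        extraction; None keeps the native grid.
    wavelet : include the 744 wavelet sub-band features.
    wavelet_family : PyWavelets wavelet name for the 3-D decomposition.
    """

    bin_width_hu: float = 25.0
    resample_spacing_mm: float | None = 1.0
    wavelet: bool = True
    wavelet_family: str = "coif1"


@dataclass
class FeatureVector:
    """Named feature values for one (subject, region, timepoint)."""

    values: dict[str, float]
    region_tag: str = "intratumoral"
    timepoint_tag: str = "baseline"
    subject_id: str = ""
    rater_id: str = "r1"

    def __post_init__(self):
        bad = [k for k, v in self.values.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite feature values: {bad[:5]}")

    def __len__(self):
        return len(self.values)

    @property
    def names(self) -> list[str]:
        return list(self.values)

    def as_array(self) -> np.ndarray:
        return np.array(list(self.values.values()), dtype=float)


@dataclass
class FeatureTable:
    """Samples x features with normalization bookkeeping.

    Wraps a pandas DataFrame (rows = subjects, columns = named features);
    ``normalization_state`` is "raw" or "minmax", and ``fitted_ranges``
    stores the per-feature (min, max) learned on the fitting rows.
    """

    data: "pd.DataFrame"
    normalization_state: str = "raw"
    fitted_ranges: "pd.DataFrame | None" = None

    @classmethod
    def from_vectors(cls, vectors: list[FeatureVector], prefix: str = "") -> "FeatureTable":
        import pandas as pd

        rows = {v.subject_id: v.values for v in vectors}
        df = pd.DataFrame.from_dict(rows, orient="index")
        if prefix:
            df.columns = [f"{prefix}{c}" for c in df.columns]
        return cls(df)

    @property
    def n_features(self) -> int:
        return self.data.shape[1]


def feature_names(config: RadiomicsConfig | None = None) -> list[str]:
    """The full ordered inventory for a given configuration."""
    config = config or RadiomicsConfig()
    names = [f"original_shape_{n}" for n in SHAPE_NAMES]
    for fam, fam_names in _TEXTURE_FAMILIES:
        names += [f"original_{fam}_{n}" for n in fam_names]
    if config.wavelet:
        for band in WAVELET_BANDS:
            for fam, fam_names in _TEXTURE_FAMILIES:
                names += [f"wavelet-{band}_{fam}_{n}" for n in fam_names]
    return names


# ---------------------------------------------------------------------------
# helpers

def _shifted(a: np.ndarray, off, fill=0) -> np.ndarray:
    """out[x] = a[x - off], with out-of-range positions set to ``fill``."""
    out = np.full_like(a, fill)
    src, dst = [], []
    for n, o in zip(a.shape, off):
        if o >= 0:
            src.append(slice(0, n - o))
            dst.append(slice(o, n))
        else:
            src.append(slice(-o, n))
            dst.append(slice(0, n + o))
    out[tuple(dst)] = a[tuple(src)]
    return out


def _discretize(values: np.ndarray, bin_width: float) -> np.ndarray:
    """Fixed-bin-width gray levels, 1-based."""
    lo = np.min(values)
    return (np.floor(values / bin_width) - np.floor(lo / bin_width)).astype(np.int64) + 1


def _crop(volume, mask, pad=1):
    sl = ndimage.find_objects(mask.astype(np.int8))[0]
    sl = tuple(
        slice(max(0, s.start - pad), min(n, s.stop + pad))
        for s, n in zip(sl, mask.shape)
    )
    return volume[sl], mask[sl]


def _entropy2(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


# ---------------------------------------------------------------------------
# shape

def _shape_features(mask: np.ndarray, spacing) -> dict[str, float]:
    spacing = np.asarray(spacing, dtype=float)
    nvox = int(mask.sum())
    voxvol = float(np.prod(spacing))
    out = {}
    out["VoxelVolume"] = nvox * voxvol

    padded = np.pad(mask.astype(float), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=tuple(spacing))
    # signed tetrahedron volumes against the origin
    v0, v1, v2 = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    mesh_volume = float(abs(np.einsum("ij,ij->i", v0, np.cross(v1, v2)).sum()) / 6.0)
    surf = float(measure.mesh_surface_area(verts, faces))
    out["MeshVolume"] = mesh_volume
    out["SurfaceArea"] = surf
    out["SurfaceVolumeRatio"] = surf / mesh_volume
    out["Sphericity"] = (36.0 * np.pi * mesh_volume**2) ** (1.0 / 3.0) / surf

    # boundary voxels in physical coordinates for diameter features
    eroded = ndimage.binary_erosion(mask)
    boundary = mask & ~eroded
    pts = np.argwhere(boundary if boundary.any() else mask) * spacing

    def _max_pairwise(p):
        if len(p) < 2:
            return 0.0
        if len(p) > 400 and p.shape[1] == 3:
            try:
                p = p[ConvexHull(p).vertices]
            except Exception:
                pass
        return float(pdist(p).max())

    out["Maximum3DDiameter"] = _max_pairwise(pts)

    def _max_plane(fixed_axis):
        best = 0.0
        other = [a for a in range(3) if a != fixed_axis]
        coords = np.argwhere(mask)
        vals = np.unique(coords[:, fixed_axis])
        for v in vals:
            q = coords[coords[:, fixed_axis] == v][:, other] * spacing[other]
            if len(q) >= 2:
                if len(q) > 200:
                    try:
                        q = q[ConvexHull(q).vertices]
                    except Exception:
                        pass
                best = max(best, float(pdist(q).max()))
        return best

    # slice = axial (fixed z), column / row = the two orthogonal planes
    out["Maximum2DDiameterSlice"] = _max_plane(0)
    out["Maximum2DDiameterColumn"] = _max_plane(1)
    out["Maximum2DDiameterRow"] = _max_plane(2)

    coords = np.argwhere(mask) * spacing
    centered = coords - coords.mean(axis=0)
    if len(coords) > 1:
        cov = np.cov(centered.T)
        eig = np.sort(np.clip(np.linalg.eigvalsh(np.atleast_2d(cov)), 0, None))[::-1]
    else:
        eig = np.zeros(3)
    major, minor, least = (4.0 * np.sqrt(eig)).tolist()
    out["MajorAxisLength"] = major
    out["MinorAxisLength"] = minor
    out["LeastAxisLength"] = least
    out["Elongation"] = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 1.0
    out["Flatness"] = float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 1.0
    return {k: out[k] for k in SHAPE_NAMES}


# ---------------------------------------------------------------------------
# first order

def _firstorder_features(x: np.ndarray, voxvol: float, bin_width: float) -> dict:
    n = x.size
    mean = float(x.mean())
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    var = float(x.var())
    sd = np.sqrt(var)
    levels = _discretize(x, bin_width)
    p = np.bincount(levels)[1:].astype(float)
    p = p[p > 0] / n
    robust = x[(x >= p10) & (x <= p90)]
    out = {
        "Energy": float(np.sum(x**2)),
        "TotalEnergy": float(voxvol * np.sum(x**2)),
        "Entropy": _entropy2(p),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": float(np.abs(robust - robust.mean()).mean())
        if robust.size else 0.0,
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "Skewness": float(np.mean((x - mean) ** 3) / sd**3) if sd > 0 else 0.0,
        "Kurtosis": float(np.mean((x - mean) ** 4) / var**2) if var > 0 else 0.0,
        "Variance": var,
        "Uniformity": float(np.sum(p**2)),
    }
    return {k: out[k] for k in FIRSTORDER_NAMES}


# ---------------------------------------------------------------------------
# GLCM

def glcm_matrix(levels: np.ndarray, mask: np.ndarray, offset) -> np.ndarray:
    """Symmetric co-occurrence counts for one direction offset (unnormalized)."""
    ng = int(levels[mask].max())
    a_mask = mask & _shifted(mask, tuple(-o for o in offset), False)
    la = levels[a_mask]
    lb = _shifted(levels, tuple(-o for o in offset))[a_mask]
    counts = np.bincount((la - 1) * ng + (lb - 1), minlength=ng * ng).reshape(ng, ng)
    return counts + counts.T


def _glcm_features(levels, mask) -> dict:
    ng = int(levels[mask].max())
    i_idx = np.arange(1, ng + 1, dtype=float)
    ii, jj = np.meshgrid(i_idx, i_idx, indexing="ij")
    acc = {k: [] for k in GLCM_NAMES}
    for off in _OFFSETS_13:
        C = glcm_matrix(levels, mask, off).astype(float)
        s = C.sum()
        if s == 0:
            continue
        P = C / s
        px = P.sum(axis=1)
        mu_x = float((i_idx * px).sum())
        sig_x = float(np.sqrt(((i_idx - mu_x) ** 2 * px).sum()))
        # diagonal / cross-diagonal distributions
        k_diff = np.arange(ng, dtype=float)
        p_diff = np.array([P[np.abs(ii - jj) == k].sum() for k in range(ng)])
        k_sum = np.arange(2, 2 * ng + 1, dtype=float)
        p_sum = np.array([P[(ii + jj) == k].sum() for k in range(2, 2 * ng + 1)])
        da = float((k_diff * p_diff).sum())
        hxy = _entropy2(P.ravel())
        px_py = np.outer(px, px)
        nz = (P > 0) | (px_py > 0)
        hxy1 = float(-np.sum(P[px_py > 0] * np.log2(px_py[px_py > 0] + _EPS)))
        hxy2 = _entropy2(px_py.ravel())
        hx = _entropy2(px)
        corr = (
            float(((ii - mu_x) * (jj - mu_x) * P).sum() / (sig_x**2))
            if sig_x > 0 else 1.0
        )
        # MCC via the Q matrix's second-largest eigenvalue
        if ng > 1:
            with np.errstate(divide="ignore", invalid="ignore"):
                Q = (P[:, None, :] * P[None, :, :] /
                     (px[:, None, None] * px[None, None, :] + _EPS)).sum(axis=2)
            ev = np.sort(np.real(np.linalg.eigvals(Q)))
            mcc = float(np.sqrt(max(ev[-2], 0.0)))
        else:
            mcc = 1.0
        vals = {
            "Autocorrelation": float((ii * jj * P).sum()),
            "JointAverage": mu_x,
            "ClusterProminence": float(((ii + jj - 2 * mu_x) ** 4 * P).sum()),
            "ClusterShade": float(((ii + jj - 2 * mu_x) ** 3 * P).sum()),
            "ClusterTendency": float(((ii + jj - 2 * mu_x) ** 2 * P).sum()),
            "Contrast": float(((ii - jj) ** 2 * P).sum()),
            "Correlation": corr,
            "DifferenceAverage": da,
            "DifferenceEntropy": _entropy2(p_diff),
            "DifferenceVariance": float(((k_diff - da) ** 2 * p_diff).sum()),
            "JointEnergy": float((P**2).sum()),
            "JointEntropy": hxy,
            "Imc1": (hxy - hxy1) / hx if hx > 0 else 0.0,
            "Imc2": float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
            if hxy2 >= hxy else 0.0,
            "Idm": float((P / (1.0 + (ii - jj) ** 2)).sum()),
            "Idmn": float((P / (1.0 + (ii - jj) ** 2 / ng**2)).sum()),
            "Id": float((P / (1.0 + np.abs(ii - jj))).sum()),
            "Idn": float((P / (1.0 + np.abs(ii - jj) / ng)).sum()),
            "InverseVariance": float(
                (P[ii != jj] / (ii - jj)[ii != jj] ** 2).sum()
            ),
            "MaximumProbability": float(P.max()),
            "SumAverage": float((k_sum * p_sum).sum()),
            "SumEntropy": _entropy2(p_sum),
            "SumSquares": float(((ii - mu_x) ** 2 * P).sum()),
            "MCC": mcc,
        }
        for k, v in vals.items():
            acc[k].append(v)
    return {k: float(np.mean(v)) if v else 0.0 for k, v in acc.items()}


# ---------------------------------------------------------------------------
# GLRLM

def glrlm_matrix(levels: np.ndarray, mask: np.ndarray, offset) -> np.ndarray:
    """Run-length counts R[level-1, length-1] along one direction."""
    ng = int(levels[mask].max())
    nmax = max(levels.shape)
    R = np.zeros((ng, nmax), dtype=np.int64)
    lv = np.where(mask, levels, 0)
    prev = _shifted(lv, offset)
    cont = mask & (prev == lv) & _shifted(mask, offset, False)
    start = mask & ~cont
    active = start
    length = 1
    cont_next = _shifted(cont, tuple(-o for o in offset), False)  # cont at x+off
    while active.any():
        ended = active & ~cont_next
        if ended.any():
            R[:, length - 1] += np.bincount(lv[ended] - 1, minlength=ng)
        active = _shifted(active, offset, False) & cont
        length += 1
        if length > nmax:
            break
    return R


def _glrlm_features(levels, mask) -> dict:
    ng = int(levels[mask].max())
    n_p = int(mask.sum())
    acc = {k: [] for k in GLRLM_NAMES}
    for off in _OFFSETS_13:
        R = glrlm_matrix(levels, mask, off).astype(float)
        nr = R.sum()
        i = np.arange(1, R.shape[0] + 1, dtype=float)[:, None]
        j = np.arange(1, R.shape[1] + 1, dtype=float)[None, :]
        P = R / nr
        ri = R.sum(axis=1)
        rj = R.sum(axis=0)
        mu_i = float((np.arange(1, ng + 1) * ri / nr).sum())
        mu_j = float((np.arange(1, R.shape[1] + 1) * rj / nr).sum())
        vals = {
            "ShortRunEmphasis": float((R / j**2).sum() / nr),
            "LongRunEmphasis": float((R * j**2).sum() / nr),
            "GrayLevelNonUniformity": float((ri**2).sum() / nr),
            "GrayLevelNonUniformityNormalized": float((ri**2).sum() / nr**2),
            "RunLengthNonUniformity": float((rj**2).sum() / nr),
            "RunLengthNonUniformityNormalized": float((rj**2).sum() / nr**2),
            "RunPercentage": float(nr / n_p),
            "GrayLevelVariance": float((((i - mu_i) ** 2) * P).sum()),
            "RunVariance": float((((j - mu_j) ** 2) * P).sum()),
            "RunEntropy": _entropy2(P.ravel()),
            "LowGrayLevelRunEmphasis": float((R / i**2).sum() / nr),
            "HighGrayLevelRunEmphasis": float((R * i**2).sum() / nr),
            "ShortRunLowGrayLevelEmphasis": float((R / (i**2 * j**2)).sum() / nr),
            "ShortRunHighGrayLevelEmphasis": float((R * i**2 / j**2).sum() / nr),
            "LongRunLowGrayLevelEmphasis": float((R * j**2 / i**2).sum() / nr),
            "LongRunHighGrayLevelEmphasis": float((R * i**2 * j**2).sum() / nr),
        }
        for k, v in vals.items():
            acc[k].append(v)
    return {k: float(np.mean(v)) for k, v in acc.items()}


# ---------------------------------------------------------------------------
# GLSZM

def glszm_zones(levels: np.ndarray, mask: np.ndarray):
    """(zone gray level, zone size) arrays under 26-connectivity."""
    ng = int(levels[mask].max())
    structure = np.ones((3,) * levels.ndim, dtype=bool)
    zl, zs = [], []
    lv = np.where(mask, levels, 0)
    for g in range(1, ng + 1):
        lab, n = ndimage.label(lv == g, structure=structure)
        if n:
            sizes = np.bincount(lab.ravel())[1:]
            zl += [g] * n
            zs += sizes.tolist()
    return np.array(zl, dtype=float), np.array(zs, dtype=float)


def _glszm_features(levels, mask) -> dict:
    zi, zs = glszm_zones(levels, mask)
    nz = len(zi)
    n_p = int(mask.sum())
    ni = np.bincount(zi.astype(int))[1:].astype(float)
    ms = np.bincount(zs.astype(int))[1:].astype(float)
    mu_i, mu_s = zi.mean(), zs.mean()
    pair_counts = {}
    for a, b in zip(zi, zs):
        pair_counts[(a, b)] = pair_counts.get((a, b), 0) + 1
    p_pair = np.array(list(pair_counts.values()), dtype=float) / nz
    out = {
        "SmallAreaEmphasis": float(np.mean(1.0 / zs**2)),
        "LargeAreaEmphasis": float(np.mean(zs**2)),
        "GrayLevelNonUniformity": float((ni**2).sum() / nz),
        "GrayLevelNonUniformityNormalized": float((ni**2).sum() / nz**2),
        "SizeZoneNonUniformity": float((ms**2).sum() / nz),
        "SizeZoneNonUniformityNormalized": float((ms**2).sum() / nz**2),
        "ZonePercentage": float(nz / n_p),
        "GrayLevelVariance": float(np.mean((zi - mu_i) ** 2)),
        "ZoneVariance": float(np.mean((zs - mu_s) ** 2)),
        "ZoneEntropy": _entropy2(p_pair),
        "LowGrayLevelZoneEmphasis": float(np.mean(1.0 / zi**2)),
        "HighGrayLevelZoneEmphasis": float(np.mean(zi**2)),
        "SmallAreaLowGrayLevelEmphasis": float(np.mean(1.0 / (zi**2 * zs**2))),
        "SmallAreaHighGrayLevelEmphasis": float(np.mean(zi**2 / zs**2)),
        "LargeAreaLowGrayLevelEmphasis": float(np.mean(zs**2 / zi**2)),
        "LargeAreaHighGrayLevelEmphasis": float(np.mean(zi**2 * zs**2)),
    }
    return {k: out[k] for k in GLSZM_NAMES}


# ---------------------------------------------------------------------------
# GLDM

def _gldm_features(levels, mask) -> dict:
    lv = np.where(mask, levels, 0)
    dep = np.zeros(levels.shape, dtype=np.int64)
    for off in _OFFSETS_26:
        nb = _shifted(lv, off)
        dep += mask & (nb == lv) & (nb > 0)
    i_vox = lv[mask].astype(float)
    j_vox = dep[mask].astype(float) + 1.0  # dependence size includes the center
    n = i_vox.size
    ni = np.bincount(i_vox.astype(int))[1:].astype(float)
    mj = np.bincount(j_vox.astype(int))[1:].astype(float)
    joint = np.bincount(
        (i_vox.astype(int) - 1) * int(j_vox.max()) + (j_vox.astype(int) - 1)
    ).astype(float)
    p_joint = joint[joint > 0] / n
    out = {
        "SmallDependenceEmphasis": float(np.mean(1.0 / j_vox**2)),
        "LargeDependenceEmphasis": float(np.mean(j_vox**2)),
        "GrayLevelNonUniformity": float((ni**2).sum() / n),
        "DependenceNonUniformity": float((mj**2).sum() / n),
        "DependenceNonUniformityNormalized": float((mj**2).sum() / n**2),
        "GrayLevelVariance": float(np.var(i_vox)),
        "DependenceVariance": float(np.var(j_vox)),
        "DependenceEntropy": _entropy2(p_joint),
        "LowGrayLevelEmphasis": float(np.mean(1.0 / i_vox**2)),
        "HighGrayLevelEmphasis": float(np.mean(i_vox**2)),
        "SmallDependenceLowGrayLevelEmphasis": float(np.mean(1.0 / (i_vox**2 * j_vox**2))),
        "SmallDependenceHighGrayLevelEmphasis": float(np.mean(i_vox**2 / j_vox**2)),
        "LargeDependenceLowGrayLevelEmphasis": float(np.mean(j_vox**2 / i_vox**2)),
        "LargeDependenceHighGrayLevelEmphasis": float(np.mean(i_vox**2 * j_vox**2)),
    }
    return {k: out[k] for k in GLDM_NAMES}


# ---------------------------------------------------------------------------
# NGTDM

def _ngtdm_features(levels, mask) -> dict:
    lv = np.where(mask, levels, 0).astype(float)
    nb_sum = np.zeros(levels.shape, dtype=float)
    nb_cnt = np.zeros(levels.shape, dtype=float)
    for off in _OFFSETS_26:
        nb_sum += _shifted(lv, off)
        nb_cnt += _shifted(mask.astype(float), off)
    valid = mask & (nb_cnt > 0)
    abar = np.zeros_like(lv)
    abar[valid] = nb_sum[valid] / nb_cnt[valid]
    iv = lv[valid].astype(int)
    diff = np.abs(lv[valid] - abar[valid])
    ng = int(levels[mask].max())
    n_vp = int(valid.sum())
    ncount = np.bincount(iv, minlength=ng + 1)[1:].astype(float)
    s = np.bincount(iv, weights=diff, minlength=ng + 1)[1:]
    p = ncount / n_vp
    grays = np.arange(1, ng + 1, dtype=float)
    present = p > 0
    ngp = int(present.sum())
    pi, pj = np.meshgrid(p[present], p[present], indexing="ij")
    gi, gj = np.meshgrid(grays[present], grays[present], indexing="ij")
    si, sj = np.meshgrid(s[present], s[present], indexing="ij")
    ps = float((p * s).sum())
    out = {}
    out["Coarseness"] = float(1.0 / ps) if ps > 0 else 1e6
    out["Contrast"] = (
        float((pi * pj * (gi - gj) ** 2).sum() / (ngp * (ngp - 1)) * s.sum() / n_vp)
        if ngp > 1 else 0.0
    )
    denom_b = float(np.abs(gi * pi - gj * pj).sum())
    out["Busyness"] = ps / denom_b if denom_b > 0 else 0.0
    out["Complexity"] = float(
        (np.abs(gi - gj) * (pi * si + pj * sj) / (pi + pj)).sum() / n_vp
    )
    out["Strength"] = float(((pi + pj) * (gi - gj) ** 2).sum() / s.sum()) if s.sum() > 0 else 0.0
    return {k: out[k] for k in NGTDM_NAMES}


# ---------------------------------------------------------------------------
# wavelet

def wavelet_bands(volume: np.ndarray, family: str = "coif1") -> dict[str, np.ndarray]:
    """Eight same-size sub-band images of a one-level 3-D DWT.

    Each band is reconstructed back to the original grid with all other
    bands zeroed, so the original mask applies unchanged.  Key letters are
    ordered (z, y, x); 'L' = approximation, 'H' = detail.
    """
    coeffs = pywt.dwtn(volume, family)
    out = {}
    for key, arr in coeffs.items():
        single = {k: (arr if k == key else np.zeros_like(v)) for k, v in coeffs.items()}
        rec = pywt.idwtn(single, family)
        rec = rec[tuple(slice(0, n) for n in volume.shape)]
        label = key.replace("a", "L").replace("d", "H")
        out[label] = rec
    return {band: out[band] for band in WAVELET_BANDS}


# ---------------------------------------------------------------------------
# top level

def _texture_block(volume, mask, voxvol, bin_width) -> dict[str, float]:
    x = volume[mask].astype(float)
    levels = _discretize(volume, bin_width)
    levels = np.where(mask, levels - int(levels[mask].min()) + 1, 0)
    out = {}
    for name, val in _firstorder_features(x, voxvol, bin_width).items():
        out[f"firstorder_{name}"] = val
    for fam, fn in (
        ("glcm", _glcm_features),
        ("gldm", _gldm_features),
        ("glrlm", _glrlm_features),
        ("glszm", _glszm_features),
        ("ngtdm", _ngtdm_features),
    ):
        for name, val in fn(levels, mask).items():
            out[f"{fam}_{name}"] = val
    return out


def resample_isotropic(volume, mask, spacing_mm, target_mm=1.0):
    """Cubic-resample the image (nearest for the mask) to isotropic spacing."""
    zoom = np.asarray(spacing_mm, dtype=float) / float(target_mm)
    if np.allclose(zoom, 1.0):
        return volume, mask, tuple(spacing_mm)
    vol = ndimage.zoom(volume, zoom, order=3)
    msk = ndimage.zoom(mask.astype(float), zoom, order=0) > 0.5
    return vol, msk, (target_mm,) * len(spacing_mm)


def extract_features(
    volume: np.ndarray,
    mask,
    config: RadiomicsConfig | None = None,
    spacing_mm=None,
    **tags,
) -> FeatureVector:
    """Extract the full configured feature inventory for one VOI.

    With the default configuration this yields exactly 851 named features
    (14 shape + 93 original intensity/texture + 744 wavelet).  Disabling
    the wavelet stage yields 107.
    """
    config = config or RadiomicsConfig()
    if isinstance(mask, RegionMask):
        spacing = mask.spacing_mm
        tags.setdefault("region_tag", mask.region_tag)
        tags.setdefault("rater_id", mask.rater_id)
        mask_arr = mask.array
    else:
        mask_arr = np.asarray(mask).astype(bool)
        spacing = tuple(spacing_mm) if spacing_mm is not None else (1.0,) * volume.ndim
    if not mask_arr.any():
        raise ValueError("mask is empty")
    if mask_arr.sum() <= 1:
        raise ValueError("mask too small for texture matrices (<= 1 voxel)")
    if config.resample_spacing_mm is not None:
        volume, mask_arr, spacing = resample_isotropic(
            volume, mask_arr, spacing, config.resample_spacing_mm
        )
    voxvol = float(np.prod(spacing))

    values: dict[str, float] = {}
    for name, val in _shape_features(mask_arr, spacing).items():
        values[f"original_shape_{name}"] = val

    cvol, cmask = _crop(np.asarray(volume, dtype=float), mask_arr, pad=2)
    for name, val in _texture_block(cvol, cmask, voxvol, config.bin_width_hu).items():
        values[f"original_{name}"] = val

    if config.wavelet:
        for band, img in wavelet_bands(cvol, config.wavelet_family).items():
            block = _texture_block(img, cmask, voxvol, config.bin_width_hu)
            for name, val in block.items():
                values[f"wavelet-{band}_{name}"] = val
    return FeatureVector(values=values, **tags)


def minmax_normalize(table: FeatureTable, fit_rows=None) -> FeatureTable:
    """Min–max normalize, fitting ranges on ``fit_rows`` only.

    x' = (x - min) / (max - min) with the ranges learned on the fitting
    split; held-out rows transformed with the same ranges may legitimately
    fall outside [0, 1].  Constant features map to 0.
    """
    import pandas as pd
    import warnings

    df = table.data
    fit = df if fit_rows is None else df.loc[fit_rows]
    if len(fit) == 0:
        raise ValueError("fit_rows must be nonempty")
    lo, hi = fit.min(axis=0), fit.max(axis=0)
    span = hi - lo
    constant = span <= 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant feature(s) set to 0 under min-max "
            "normalization", stacklevel=2,
        )
    safe = span.where(~constant, 1.0)
    out = (df - lo) / safe
    out.loc[:, constant] = 0.0
    ranges = pd.DataFrame({"min": lo, "max": hi})
    return FeatureTable(out, normalization_state="minmax", fitted_ranges=ranges)
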