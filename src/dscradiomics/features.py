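"""Radiomic feature extraction on parametric maps within a tumor ROI.

Implements a defined, configurable subset of the classical radiomics
catalogue: first-order statistics, gray-level co-occurrence (GLCM),
run-length (GLRLM), size-zone (GLSZM) and dependence (GLDM) texture
matrices, 3D shape descriptors, and filtered variants (separable 2-tap
wavelet bands, Laplacian of Gaussian, gradient magnitude, logarithmic and
exponential intensity transforms, slice-wise LBP-2D).

Conventions (fixed here because parametric maps carry heterogeneous
physical units, which makes absolute bin widths meaningless):

- discretization: fixed bin count (default 32) over the in-ROI range;
- GLCM: the 13 unique 3D offsets at Chebyshev distance 1, symmetric,
  features averaged over offsets;
- GLRLM: runs along the same 13 directions, features averaged;
- GLSZM: 26-connected zones; GLDM: 26-neighbourhood, dependence
  threshold alpha = 0 (equal levels only);
- 2D features (LBP) are computed slice-wise along the last (axial) axis.

Feature names encode provenance as ``map__filter__class__feature`` and are
stable across runs, which downstream selection relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.feature import local_binary_pattern

__all__ = [
    "DiscretizationSpec",
    "FeatureConfig",
    "discretize",
    "first_order_features",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "gldm_features",
    "shape_features",
    "apply_filter",
    "extract_all",
    "extract_cohort_table",
]

# 13 unique 3D displacement vectors at Chebyshev distance 1 (half of the
# 26-neighbourhood; the other half are their negatives)
OFFSETS_3D = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)


@dataclass(frozen=True)
class DiscretizationSpec:
    mode: str = "fixed-count"     # or "fixed-width"
    n_bins: int = 32
    bin_width: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("fixed-count", "fixed-width"):
            raise ValueError(f"unknown discretization mode {self.mode!r}")
        if self.mode == "fixed-count" and self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.mode == "fixed-width" and not (self.bin_width and self.bin_width > 0):
            raise ValueError("fixed-width mode needs a positive bin_width")


def discretize(
    image: np.ndarray, mask: np.ndarray, spec: DiscretizationSpec | None = None
) -> np.ndarray:
    """Map in-mask intensities to integer levels 1..L; 0 outside the mask."""
    spec = spec or DiscretizationSpec()
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask")
    vals = np.asarray(image, float)[mask]
    out = np.zeros(np.shape(image), dtype=np.int64)
    lo, hi = float(vals.min()), float(vals.max())
    if spec.mode == "fixed-count":
        if hi == lo:
            out[mask] = 1
            return out
        edges = np.linspace(lo, hi, spec.n_bins + 1)
        levels = np.clip(np.digitize(vals, edges[1:-1], right=False) + 1, 1, spec.n_bins)
    else:
        levels = np.floor((vals - lo) / spec.bin_width).astype(np.int64) + 1
    out[mask] = levels
    return out


def _masked_values(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    vals = np.asarray(image, float)[np.asarray(mask, bool)]
    return vals[np.isfinite(vals)]


def first_order_features(
    image: np.ndarray, mask: np.ndarray, n_bins: int = 32
) -> dict[str, float]:
    """First-order intensity statistics over the ROI.

    Variance, skewness and kurtosis are population moments (kurtosis in
    Pearson convention, i.e. 3 for a Gaussian); entropy is Shannon entropy
    in bits of the discretized in-ROI histogram.  Degenerate (constant)
    regions report zero skewness/kurtosis rather than NaN.
    """
    x = _masked_values(image, mask)
    if len(x) < 2:
        raise ValueError("first-order features need at least 2 finite voxels")
    var = float(np.var(x))
    levels = discretize(x, np.ones_like(x, bool), DiscretizationSpec(n_bins=n_bins))
    p = np.bincount(levels)[1:].astype(float)
    p = p[p > 0] / p.sum()
    return {
        "Mean": float(np.mean(x)),
        "Variance": var,
        "Skewness": float(stats.skew(x)) if var > 0 else 0.0,
        "Kurtosis": float(stats.kurtosis(x, fisher=False)) if var > 0 else 0.0,
        "Energy": float(np.sum(x**2)),
        "Entropy": float(-np.sum(p * np.log2(p))),
        "Minimum": float(np.min(x)),
        "Maximum": float(np.max(x)),
        "Range": float(np.ptp(x)),
        "P10": float(np.percentile(x, 10)),
        "Median": float(np.percentile(x, 50)),
        "P90": float(np.percentile(x, 90)),
        "MAD": float(np.mean(np.abs(x - np.mean(x)))),
    }


def _glcm_matrix(
    levels: np.ndarray, mask: np.ndarray, offset: tuple[int, int, int],
    n_levels: int, symmetric: bool,
) -> np.ndarray:
    """Co-occurrence counts for one displacement vector."""
    mask = np.asarray(mask, bool)
    src = []
    dst = []
    sl_from = tuple(
        slice(max(0, -o), levels.shape[i] - max(0, o)) for i, o in enumerate(offset)
    )
    sl_to = tuple(
        slice(max(0, o), levels.shape[i] + min(0, o)) for i, o in enumerate(offset)
    )
    both = mask[sl_from] & mask[sl_to]
    src = levels[sl_from][both] - 1
    dst = levels[sl_to][both] - 1
    mat = np.zeros((n_levels, n_levels))
    np.add.at(mat, (src, dst), 1.0)
    if symmetric:
        mat = mat + mat.T
    return mat


def glcm_features(
    levels: np.ndarray, mask: np.ndarray,
    offsets: tuple[tuple[int, int, int], ...] = OFFSETS_3D,
    symmetric: bool = True,
) -> dict[str, float]:
    """GLCM features averaged over offsets: contrast, correlation, joint
    energy, joint entropy and homogeneity (inverse difference moment).

    Correlation of a degenerate (single-level) matrix is reported as 0.
    """
    n_levels = int(levels[np.asarray(mask, bool)].max())
    feats = {k: [] for k in ("Contrast", "Correlation", "JointEnergy",
                             "JointEntropy", "Homogeneity")}
    i = np.arange(1, n_levels + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    any_pairs = False
    for off in offsets:
        mat = _glcm_matrix(levels, mask, off, n_levels, symmetric)
        total = mat.sum()
        if total == 0:
            continue
        any_pairs = True
        p = mat / total
        px = p.sum(axis=1)
        mu_x = float(np.sum(i * px))
        sd_x = float(np.sqrt(np.sum((i - mu_x) ** 2 * px)))
        py = p.sum(axis=0)
        mu_y = float(np.sum(i * py))
        sd_y = float(np.sqrt(np.sum((i - mu_y) ** 2 * py)))
        nz = p > 0
        feats["Contrast"].append(float(np.sum(p * (ii - jj) ** 2)))
        if sd_x > 0 and sd_y > 0:
            feats["Correlation"].append(
                float(np.sum(p * (ii - mu_x) * (jj - mu_y)) / (sd_x * sd_y))
            )
        else:
            feats["Correlation"].append(0.0)
        feats["JointEnergy"].append(float(np.sum(p**2)))
        feats["JointEntropy"].append(float(-np.sum(p[nz] * np.log2(p[nz]))))
        feats["Homogeneity"].append(float(np.sum(p / (1.0 + (ii - jj) ** 2))))
    if not any_pairs:
        raise ValueError("no co-occurring voxel pairs in mask")
    return {k: float(np.mean(v)) for k, v in feats.items()}


def _runs_along(
    levels: np.ndarray, mask: np.ndarray, direction: tuple[int, int, int]
) -> list[tuple[int, int]]:
    """Enumerate (gray level, run length) for maximal runs along one
    direction; a run starts at any voxel whose predecessor is outside the
    mask or has a different level."""
    mask = np.asarray(mask, bool)
    sx, sy, sz = levels.shape
    dx, dy, dz = direction
    runs = []
    for x, y, z in zip(*(a.tolist() for a in np.nonzero(mask))):
        px, py, pz = x - dx, y - dy, z - dz
        lvl = levels[x, y, z]
        if (
            0 <= px < sx and 0 <= py < sy and 0 <= pz < sz
            and mask[px, py, pz] and levels[px, py, pz] == lvl
        ):
            continue  # interior of a run
        length = 1
        cx, cy, cz = x + dx, y + dy, z + dz
        while (
            0 <= cx < sx and 0 <= cy < sy and 0 <= cz < sz
            and mask[cx, cy, cz] and levels[cx, cy, cz] == lvl
        ):
            length += 1
            cx, cy, cz = cx + dx, cy + dy, cz + dz
        runs.append((int(lvl), length))
    return runs


def glrlm_features(
    levels: np.ndarray, mask: np.ndarray,
    directions: tuple[tuple[int, int, int], ...] = OFFSETS_3D,
) -> dict[str, float]:
    """Run-length features averaged over directions: short/long-run
    emphasis, gray-level and run-length non-uniformity, run percentage."""
    mask = np.asarray(mask, bool)
    n_p = int(mask.sum())
    if n_p == 0:
        raise ValueError("empty mask")
    acc = {k: [] for k in ("ShortRunEmphasis", "LongRunEmphasis",
                           "GrayLevelNonUniformity", "RunLengthNonUniformity",
                           "RunPercentage")}
    for d in directions:
        runs = _runs_along(levels, mask, d)
        lengths = np.array([r[1] for r in runs], dtype=float)
        glv = np.array([r[0] for r in runs])
        n_r = len(runs)
        acc["ShortRunEmphasis"].append(float(np.sum(1.0 / lengths**2)) / n_r)
        acc["LongRunEmphasis"].append(float(np.sum(lengths**2)) / n_r)
        gl_counts = np.bincount(glv)
        acc["GrayLevelNonUniformity"].append(float(np.sum(gl_counts**2)) / n_r)
        ln_counts = np.bincount(lengths.astype(int))
        acc["RunLengthNonUniformity"].append(float(np.sum(ln_counts**2)) / n_r)
        acc["RunPercentage"].append(n_r / n_p)
    return {k: float(np.mean(v)) for k, v in acc.items()}


def glszm_features(levels: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """Size-zone features over 26-connected equal-level zones."""
    mask = np.asarray(mask, bool)
    n_p = int(mask.sum())
    if n_p == 0:
        raise ValueError("empty mask")
    structure = np.ones((3,) * levels.ndim, dtype=bool)
    sizes = []
    for lvl in np.unique(levels[mask]):
        lab, n_zones = ndimage.label((levels == lvl) & mask, structure=structure)
        if n_zones:
            sizes.extend(np.bincount(lab.ravel())[1:].tolist())
    sizes = np.array(sizes, dtype=float)
    n_z = len(sizes)
    size_counts = np.bincount(sizes.astype(int))
    return {
        "SmallAreaEmphasis": float(np.sum(1.0 / sizes**2)) / n_z,
        "LargeAreaEmphasis": float(np.sum(sizes**2)) / n_z,
        "SizeZoneNonUniformity": float(np.sum(size_counts**2)) / n_z,
        "ZonePercentage": n_z / n_p,
    }


def gldm_features(
    levels: np.ndarray, mask: np.ndarray, alpha: int = 0
) -> dict[str, float]:
    """Dependence features: for each voxel, the dependence is the number
    of 26-neighbours inside the mask whose level differs by at most
    ``alpha`` (default 0: equal levels)."""
    mask = np.asarray(mask, bool)
    n_p = int(mask.sum())
    if n_p == 0:
        raise ValueError("empty mask")
    offsets = list(OFFSETS_3D) + [tuple(-x for x in o) for o in OFFSETS_3D]
    dep_map = np.zeros(levels.shape, dtype=np.int64)
    for off in offsets:
        sl_c = tuple(
            slice(max(0, -o), levels.shape[i] - max(0, o)) for i, o in enumerate(off)
        )
        sl_n = tuple(
            slice(max(0, o), levels.shape[i] + min(0, o)) for i, o in enumerate(off)
        )
        hit = (
            mask[sl_c] & mask[sl_n]
            & (np.abs(levels[sl_c] - levels[sl_n]) <= alpha)
        )
        dep_map[sl_c] += hit
    deps = dep_map[mask].astype(float) + 1.0  # count the voxel itself
    dep_counts = np.bincount(deps.astype(int))
    return {
        "SmallDependenceEmphasis": float(np.mean(1.0 / deps**2)),
        "LargeDependenceEmphasis": float(np.mean(deps**2)),
        "DependenceNonUniformity": float(np.sum(dep_counts**2)) / n_p,
    }


def shape_features(
    mask: np.ndarray, spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
) -> dict[str, float]:
    """3D shape descriptors of the ROI mask.

    Surface area counts exposed voxel faces (no meshing); sphericity is
    pi^(1/3) (6V)^(2/3) / A; elongation and flatness come from the
    principal moments of the voxel-centre point cloud.
    """
    mask = np.asarray(mask, bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty mask")
    spacing = tuple(float(s) for s in spacing)
    voxel_volume = spacing[0] * spacing[1] * spacing[2]
    volume = n * voxel_volume

    padded = np.pad(mask, 1)
    area = 0.0
    for ax in range(3):
        face = voxel_volume / spacing[ax]
        diff = np.diff(padded.astype(np.int8), axis=ax)
        area += float(np.sum(np.abs(diff))) * face

    sphericity = float(np.pi ** (1 / 3) * (6 * volume) ** (2 / 3) / area)

    coords = np.column_stack(np.nonzero(mask)).astype(float) * np.array(spacing)
    if n > 2000:  # diameter only needs the boundary voxels
        eroded = ndimage.binary_erosion(mask)
        coords_d = np.column_stack(np.nonzero(mask & ~eroded)).astype(float) * np.array(
            spacing
        )
    else:
        coords_d = coords
    diffs = coords_d[:, None, :] - coords_d[None, :, :]
    max_diam = float(np.sqrt((diffs**2).sum(-1).max()))

    if n > 1:
        cov = np.cov(coords.T)
        eig = np.sort(np.linalg.eigvalsh(np.atleast_2d(cov)))[::-1]
        eig = np.clip(eig, 0, None)
        elongation = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 1.0
        flatness = float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 1.0
    else:
        elongation = flatness = 1.0
    return {
        "VoxelVolume": volume,
        "SurfaceArea": area,
        "Sphericity": sphericity,
        "Maximum3DDiameter": max_diam,
        "Elongation": elongation,
        "Flatness": flatness,
    }


# ---------------------------------------------------------------------------
# image filters

_WAVELET_LOW = np.array([0.5, 0.5])
_WAVELET_HIGH = np.array([0.5, -0.5])


def _separable_wavelet_bands(image: np.ndarray) -> dict[str, np.ndarray]:
    """One-level undecimated separable decomposition with averaging (L)
    and differencing (H) 2-tap kernels along each axis: 8 bands in 3D.
    The LLL band of a constant image is that constant; all bands
    containing an H factor vanish on constants."""
    bands = {"": image.astype(float)}
    for ax in range(image.ndim):
        new = {}
        for name, img in bands.items():
            new[name + "L"] = ndimage.correlate1d(img, _WAVELET_LOW, axis=ax, mode="nearest")
            new[name + "H"] = ndimage.correlate1d(img, _WAVELET_HIGH, axis=ax, mode="nearest")
        bands = new
    return bands


def logarithmic_transform(image: np.ndarray, shift: float | None = None) -> np.ndarray:
    """``log(x + shift)``; by default shifted so the minimum maps to log(1)=0.
    With ``shift=0`` this is the exact inverse of
    :func:`exponential_transform` at ``scale=1``."""
    x = np.asarray(image, float)
    if shift is None:
        shift = 1.0 - float(np.nanmin(x))
    return np.log(x + shift)


def exponential_transform(image: np.ndarray, scale: float | None = None) -> np.ndarray:
    """``exp(scale * x)``; the default scale compresses the image range so
    the largest magnitude maps to 1e6, keeping downstream statistics
    finite for maps in arbitrary physical units."""
    x = np.asarray(image, float)
    if scale is None:
        m = float(np.nanmax(np.abs(x)))
        scale = np.log(1e6) / m if m > 0 else 1.0
    return np.exp(scale * x)


def _lbp_2d(image: np.ndarray) -> np.ndarray:
    """Slice-wise local binary patterns (8 neighbours, radius 1) along the
    last (axial) axis."""
    out = np.zeros_like(image, dtype=float)
    for k in range(image.shape[2]):
        out[:, :, k] = local_binary_pattern(image[:, :, k], P=8, R=1, method="uniform")
    return out


def apply_filter(
    image: np.ndarray,
    name: str,
    *,
    log_sigmas: tuple[float, ...] = (1.0,),
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> dict[str, np.ndarray]:
    """Apply a named filter; returns ``{band_name: filtered image}``.

    Known filters: original, wavelet (8 bands), log (Laplacian of
    Gaussian, one band per sigma), gradient, logarithm, exponential,
    lbp2d.
    """
    img = np.asarray(image, float)
    if name == "original":
        return {"original": img}
    if name == "wavelet":
        return {f"wavelet-{b}": v for b, v in _separable_wavelet_bands(img).items()}
    if name == "log":
        return {
            f"log-sigma-{s:g}": ndimage.gaussian_laplace(img, sigma=s)
            for s in log_sigmas
        }
    if name == "gradient":
        grads = np.gradient(img, *spacing)
        return {"gradient": np.sqrt(sum(g**2 for g in grads))}
    if name == "logarithm":
        return {"logarithm": logarithmic_transform(img)}
    if name == "exponential":
        return {"exponential": exponential_transform(img)}
    if name == "lbp2d":
        return {"lbp2d": _lbp_2d(img)}
    raise ValueError(f"unknown filter {name!r}")


# ---------------------------------------------------------------------------
# orchestration

@dataclass(frozen=True)
class FeatureConfig:
    filters: tuple[str, ...] = ("original", "wavelet")
    feature_classes: tuple[str, ...] = (
        "firstorder", "glcm", "glrlm", "glszm", "gldm", "shape"
    )
    n_bins: int = 32
    log_sigmas: tuple[float, ...] = (1.0,)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    glcm_symmetric: bool = True

    def discretization(self) -> DiscretizationSpec:
        return DiscretizationSpec(n_bins=self.n_bins)


_TEXTURE_DISPATCH = {
    "glcm": lambda lv, m, cfg: glcm_features(lv, m, symmetric=cfg.glcm_symmetric),
    "glrlm": lambda lv, m, cfg: glrlm_features(lv, m),
    "glszm": lambda lv, m, cfg: glszm_features(lv, m),
    "gldm": lambda lv, m, cfg: gldm_features(lv, m),
}


def extract_all(
    maps: dict[str, np.ndarray],
    mask: np.ndarray,
    config: FeatureConfig | None = None,
) -> pd.Series:
    """Extract the configured feature set for one subject.

    Returns a Series indexed by ``map__filter__class__feature``.  Shape
    features depend only on the mask and appear once under
    ``mask__original__shape__*``.  Maps whose in-ROI values are not finite
    enough for a feature class yield NaN for those features (flagged, not
    raised), so one failed voxel fit cannot sink the whole subject.
    """
    config = config or FeatureConfig()
    mask = np.asarray(mask, bool)
    out: dict[str, float] = {}

    if "shape" in config.feature_classes:
        for feat, val in shape_features(mask, config.spacing).items():
            out[f"mask__original__shape__{feat}"] = val

    texture_classes = [c for c in config.feature_classes if c in _TEXTURE_DISPATCH]
    for map_name, image in maps.items():
        finite_mask = mask & np.isfinite(np.asarray(image, float))
        for filter_name in config.filters:
            bands = apply_filter(
                np.nan_to_num(np.asarray(image, float)),
                filter_name,
                log_sigmas=config.log_sigmas,
                spacing=config.spacing,
            )
            for band, filtered in bands.items():
                band_mask = finite_mask & np.isfinite(filtered)
                prefix = f"{map_name}__{band}"
                if "firstorder" in config.feature_classes:
                    try:
                        fo = first_order_features(filtered, band_mask, config.n_bins)
                    except ValueError:
                        fo = {}
                    for feat in ("Mean", "Variance", "Skewness", "Kurtosis",
                                 "Energy", "Entropy", "Minimum", "Maximum",
                                 "Range", "P10", "Median", "P90", "MAD"):
                        out[f"{prefix}__firstorder__{feat}"] = fo.get(feat, np.nan)
                if texture_classes:
                    try:
                        levels = discretize(filtered, band_mask, config.discretization())
                    except ValueError:
                        levels = None
                    for cls in texture_classes:
                        try:
                            if levels is None:
                                raise ValueError
                            vals = _TEXTURE_DISPATCH[cls](levels, band_mask, config)
                        except ValueError:
                            vals = {}
                        names = _TEXTURE_FEATURE_NAMES[cls]
                        for feat in names:
                            out[f"{prefix}__{cls}__{feat}"] = vals.get(feat, np.nan)
    return pd.Series(out)


_TEXTURE_FEATURE_NAMES = {
    "glcm": ("Contrast", "Correlation", "JointEnergy", "JointEntropy", "Homogeneity"),
    "glrlm": ("ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
              "RunLengthNonUniformity", "RunPercentage"),
    "glszm": ("SmallAreaEmphasis", "LargeAreaEmphasis", "SizeZoneNonUniformity",
              "ZonePercentage"),
    "gldm": ("SmallDependenceEmphasis", "LargeDependenceEmphasis",
             "DependenceNonUniformity"),
}


def extract_cohort_table(
    subjects: list[tuple[dict[str, np.ndarray], np.ndarray]],
    labels: list[int] | np.ndarray,
    config: FeatureConfig | None = None,
) -> pd.DataFrame:
    """Feature table for a cohort: one row per subject plus a ``label``
    column; column order is identical across rows by construction."""
    rows = [extract_all(maps, mask, config) for maps, mask in subjects]
    table = pd.DataFrame(rows).reset_index(drop=True)
    table["label"] = np.asarray(labels, dtype=int)
    return table
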