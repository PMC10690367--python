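"""Readers, writers and run configuration.

Volumes, parametric maps and masks travel as NIfTI-1 (masks as unsigned
8-bit, nonzero = inside); curves and tables as single-header CSV; the run
configuration as YAML with unknown keys rejected.  Tabular artifacts carry
the hash of the configuration that produced them as a ``config_hash``
column, so re-runs are verifiably reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "read_dsc_series",
    "write_nifti",
    "read_nifti",
    "read_mask",
    "write_mask",
    "read_aif",
    "write_aif",
    "RunConfig",
]


def read_dsc_series(path, dt: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Load a 4D DSC series.

    Returns (data as (x, y, z, t) float array, affine, time grid built
    from ``dt``).  A 3D file is rejected with a clear message; ``dt`` must
    be supplied because NIfTI headers rarely carry a trustworthy TR.
    """
    if dt is None or dt <= 0:
        raise ValueError("temporal resolution dt (seconds) is required and must be > 0")
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 4:
        raise ValueError(
            f"expected a 4D series with a trailing time axis, got {data.ndim}D"
        )
    time_grid = np.arange(data.shape[3]) * float(dt)
    return data, img.affine, time_grid


def write_nifti(path, data: np.ndarray, affine: np.ndarray | None = None) -> None:
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine), str(path))


def read_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=float), img.affine


def write_mask(path, mask: np.ndarray, affine: np.ndarray | None = None) -> None:
    affine = np.eye(4) if affine is None else affine
    nib.save(
        nib.Nifti1Image(np.asarray(mask).astype(np.uint8), affine), str(path)
    )


def read_mask(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata()) > 0


def read_aif(path) -> tuple[np.ndarray, np.ndarray]:
    """Two-column CSV (time_s, value) -> (time grid, curve)."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("AIF file needs two columns: time_s, value")
    return df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float)


def write_aif(path, time_grid: np.ndarray, values: np.ndarray) -> None:
    pd.DataFrame({"time_s": time_grid, "value": values}).to_csv(path, index=False)


@dataclass
class RunConfig:
    """Validated configuration for a pipeline run."""

    te: float = 0.040                 # echo time, s
    dt: float = 1.87                  # temporal resolution, s
    n_baseline: int = 5               # pre-bolus frames
    gamma: bool = True                # fit the gamma transport model
    unidirectional: bool = True
    bidirectional: bool = True
    variance_threshold: float = 0.5
    anova_alpha: float = 0.05
    l1_C: float = 0.3
    svm_C: float = 1.0
    k_folds: int = 5
    smote_k_neighbors: int = 5
    n_bins: int = 32
    filters: tuple[str, ...] = ("original", "wavelet")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.te <= 0 or self.dt <= 0:
            raise ValueError("te and dt must be positive")
        if self.n_baseline < 2:
            raise ValueError("n_baseline must be >= 2")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        self.filters = tuple(self.filters)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["filters"] = list(d["filters"])
        return d

    def hash(self) -> str:
        """Stable hash identifying this configuration."""
        canon = json.dumps(self.as_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
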