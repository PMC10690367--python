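"""Synthetic DSC phantom cohort with known kinetic ground truth.

No public DSC-MRI cohort with IDH labels accompanies this package, so every
downstream stage (curve fitting, leakage correction, radiomics, selection,
classification) is exercised on simulated 4D phantoms whose voxelwise
kinetic parameters are known exactly.

A phantom is a concentric-block geometry: a brain box containing a tumor
box split into enhancement / oedema / necrosis slabs, mirroring the usual
whole-tumor ROI (union of the three).  Each tissue class carries a gamma
transport-function truth (Ft, t1, sigma1, a1) and a leakage truth
(K1, K2, Kep).  Voxel concentration curves are built with the forward
models of :mod:`dscradiomics.kinetics` and :mod:`dscradiomics.leakage`,
converted to MR signal (S = s0 exp(-TE C)), and corrupted with additive
Gaussian noise on the signal — where scanner thermal noise actually enters.

The default cohort reproduces the class imbalance of a 160-patient glioma
study: 41 IDH-mutant vs 119 IDH-wildtype phantoms, with class-shifted
tumor blood-flow (Ft) and permeability (K2) distributions.  The default
acquisition grid is 60 frames at dt = 1.87 s with TE = 40 ms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import kinetics, leakage

logger = logging.getLogger(__name__)

__all__ = [
    "GammaBolusParams",
    "KineticTruth",
    "LeakageTruth",
    "TissueClass",
    "PhantomSpec",
    "GroundTruth",
    "Phantom",
    "ClassEffect",
    "CohortEffect",
    "make_aif",
    "build_phantom",
    "make_cohort",
]


@dataclass(frozen=True)
class GammaBolusParams:
    """Peak-normalized gamma-variate bolus: value ``amplitude`` at its
    maximum ``t = t1 + a1*sigma1``, zero before the arrival delay ``t1``."""

    amplitude: float = 10.0   # peak Delta-R2*, 1/s
    t1: float = 10.0          # arrival delay, s
    sigma1: float = 1.5       # dispersion, s
    a1: float = 3.0           # shape, dimensionless

    def __post_init__(self) -> None:
        if self.sigma1 <= 0 or self.a1 <= 0:
            raise ValueError("sigma1 and a1 must be positive")


@dataclass(frozen=True)
class KineticTruth:
    """Ground-truth gamma transport parameters of a tissue class."""

    ft: float
    t1: float = 2.0
    sigma1: float = 1.5
    a1: float = 3.0


@dataclass(frozen=True)
class LeakageTruth:
    k1: float = 1.0
    k2: float = 0.0
    kep: float = 0.0


@dataclass(frozen=True)
class TissueClass:
    name: str
    kinetic: KineticTruth
    leak: LeakageTruth = field(default_factory=LeakageTruth)


@dataclass(frozen=True)
class PhantomSpec:
    """Full recipe for one phantom; identical spec + seed => identical data."""

    grid_shape: tuple[int, int, int] = (16, 16, 7)
    n_timepoints: int = 60
    dt: float = 1.87          # s, temporal resolution
    te: float = 0.040         # s, echo time
    n_baseline: int = 5       # frames before bolus arrival
    aif_params: GammaBolusParams = field(default_factory=GammaBolusParams)
    normal_tissue: KineticTruth = field(default_factory=lambda: KineticTruth(ft=0.05))
    tissue_classes: tuple[TissueClass, ...] = ()
    noise_sd: float = 2.0     # signal units
    s0: float = 100.0         # baseline signal
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(s < 4 for s in self.grid_shape):
            raise ValueError("grid_shape must be 3 dimensions of at least 4 voxels")
        if self.n_timepoints <= self.n_baseline or self.n_baseline < 2:
            raise ValueError("need 2 <= n_baseline < n_timepoints")
        if self.dt <= 0 or self.te <= 0 or self.s0 <= 0 or self.noise_sd < 0:
            raise ValueError("dt, te, s0 must be positive and noise_sd >= 0")

    @property
    def time_grid(self) -> np.ndarray:
        return np.arange(self.n_timepoints) * self.dt


@dataclass
class GroundTruth:
    """Per-voxel truth maps (keys: ft, t1, sigma1, a1, k1, k2, kep)."""

    param_maps: dict[str, np.ndarray]
    label: int = 0


@dataclass
class Phantom:
    series: np.ndarray                 # (x, y, z, t) signal
    time_grid: np.ndarray
    masks: dict[str, np.ndarray]       # brain, tumor, enhancement, oedema, necrosis
    truth: GroundTruth
    spec: PhantomSpec
    label: int = 0


def make_aif(params: GammaBolusParams, time_grid: np.ndarray) -> np.ndarray:
    """Arterial input function: peak-normalized gamma-variate bolus."""
    t = np.asarray(time_grid, dtype=float)
    if t.ndim != 1 or len(t) < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("time_grid must be strictly increasing")
    x = t - params.t1
    out = np.zeros_like(t)
    pos = x > 0
    peak = params.a1 * params.sigma1
    out[pos] = params.amplitude * np.exp(
        params.a1 * (np.log(x[pos] / peak) + 1.0) - x[pos] / params.sigma1
    )
    return out


def _tumor_geometry(shape: tuple[int, int, int]) -> dict[str, np.ndarray]:
    """Concentric blocks: brain box inside a 1-voxel border, tumor box at
    the centre split into three slabs along x."""
    nx, ny, nz = shape
    brain = np.zeros(shape, dtype=bool)
    brain[1 : nx - 1, 1 : ny - 1, 1 : nz - 1] = True

    # central tumor box; roughly a third of each in-plane extent
    hx, hy = max(2, nx // 5), max(2, ny // 5)
    tx0, tx1 = nx // 2 - hx, nx // 2 + hx
    ty0, ty1 = ny // 2 - hy, ny // 2 + hy
    tz0, tz1 = max(1, nz // 2 - 1), min(nz - 1, nz // 2 + 2)
    tumor = np.zeros(shape, dtype=bool)
    tumor[tx0:tx1, ty0:ty1, tz0:tz1] = True

    thirds = np.array_split(np.arange(tx0, tx1), 3)
    names = ("enhancement", "oedema", "necrosis")
    masks: dict[str, np.ndarray] = {"brain": brain, "tumor": tumor}
    for name, rows in zip(names, thirds):
        sub = np.zeros(shape, dtype=bool)
        sub[rows[0] : rows[-1] + 1, ty0:ty1, tz0:tz1] = True
        masks[name] = sub
    return masks


#: within-tumor modulation of the phantom-level (Ft, K2) draw per sub-region
_SUBCLASS_SCALES = {
    "enhancement": (1.3, 1.5),
    "oedema": (0.8, 0.5),
    "necrosis": (0.3, 0.2),
}


def default_tissue_classes(
    ft_tumor: float, k2_tumor: float, kep_tumor: float, ft_normal: float
) -> tuple[TissueClass, ...]:
    """Enhancement/oedema/necrosis classes from one phantom-level draw.

    K1 is the ratio of tumor to normal flow because the tumor curve is
    constructed as a scaled copy of the normal-tissue response minus the
    leakage term — exactly the form the exchange models fit.
    """
    classes = []
    for name, (ft_scale, k2_scale) in _SUBCLASS_SCALES.items():
        ft = ft_tumor * ft_scale
        classes.append(
            TissueClass(
                name,
                KineticTruth(ft=ft),
                LeakageTruth(k1=ft / ft_normal, k2=k2_tumor * k2_scale, kep=kep_tumor),
            )
        )
    return tuple(classes)


def build_phantom(spec: PhantomSpec, label: int = 0) -> Phantom:
    """Assemble a 4D signal series, masks and ground truth from a spec."""
    t = spec.time_grid
    aif = make_aif(spec.aif_params, t)
    masks = _tumor_geometry(spec.grid_shape)

    normal = spec.normal_tissue
    ref_clean = kinetics.simulate_tissue_curve(
        aif, t, normal.ft, normal.t1, normal.sigma1, normal.a1
    )

    shape4 = spec.grid_shape + (spec.n_timepoints,)
    conc = np.zeros(shape4)
    conc[masks["brain"]] = ref_clean

    maps = {
        k: np.zeros(spec.grid_shape)
        for k in ("ft", "t1", "sigma1", "a1", "k1", "k2", "kep")
    }
    brain = masks["brain"]
    maps["ft"][brain] = normal.ft
    maps["t1"][brain] = normal.t1
    maps["sigma1"][brain] = normal.sigma1
    maps["a1"][brain] = normal.a1
    maps["k1"][brain] = 1.0

    for tc in spec.tissue_classes:
        m = masks.get(tc.name)
        if m is None:
            raise ValueError(f"unknown tissue class {tc.name!r}")
        kin, lk = tc.kinetic, tc.leak
        if (kin.t1, kin.sigma1, kin.a1) == (normal.t1, normal.sigma1, normal.a1):
            clean = (kin.ft / normal.ft) * ref_clean
        else:
            clean = kinetics.simulate_tissue_curve(
                aif, t, kin.ft, kin.t1, kin.sigma1, kin.a1
            )
        curve = clean - lk.k2 * leakage.exp_kernel_convolution(
            ref_clean, lk.kep, spec.dt
        )
        conc[m] = curve
        for key, val in (
            ("ft", kin.ft), ("t1", kin.t1), ("sigma1", kin.sigma1),
            ("a1", kin.a1), ("k1", lk.k1), ("k2", lk.k2), ("kep", lk.kep),
        ):
            maps[key][m] = val

    signal = kinetics.concentration_to_signal(conc, spec.s0, spec.te)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        signal = signal + rng.normal(0.0, spec.noise_sd, size=signal.shape)

    return Phantom(
        series=signal,
        time_grid=t,
        masks=masks,
        truth=GroundTruth(param_maps=maps, label=label),
        spec=spec,
        label=label,
    )


@dataclass(frozen=True)
class ClassEffect:
    """Sampling distribution of phantom-level tumor kinetics for one class."""

    ft_mean: float
    ft_sd: float
    k2_mean: float
    k2_sd: float
    kep_mean: float = 0.06
    kep_sd: float = 0.012


# Default class effects: IDH-wildtype gliomas are the more aggressive,
# hyperperfused and leakier phenotype; the mutant class sits lower on both
# axes.  Chosen once as a clearly separable but overlapping benchmark.
IDH_MUTANT_EFFECT = ClassEffect(ft_mean=0.06, ft_sd=0.012, k2_mean=0.008, k2_sd=0.003)
IDH_WILDTYPE_EFFECT = ClassEffect(ft_mean=0.11, ft_sd=0.022, k2_mean=0.020, k2_sd=0.006)


@dataclass(frozen=True)
class CohortEffect:
    class0: ClassEffect = IDH_MUTANT_EFFECT    # minority, label 0
    class1: ClassEffect = IDH_WILDTYPE_EFFECT  # majority, label 1

    @staticmethod
    def null() -> "CohortEffect":
        """No class difference: both classes sample the same distribution."""
        return CohortEffect(class0=IDH_MUTANT_EFFECT, class1=IDH_MUTANT_EFFECT)


def make_cohort(
    n_class0: int = 41,
    n_class1: int = 119,
    effect: CohortEffect | None = None,
    seed: int = 0,
    *,
    base_spec: PhantomSpec | None = None,
) -> list[Phantom]:
    """Generate a labeled phantom cohort (default 41 + 119 = 160).

    Each phantom draws its tumor-level (Ft, K2, Kep) from the class
    distribution in ``effect`` and receives its own noise stream derived
    from ``seed``; the whole cohort is deterministic given ``seed``.
    """
    if n_class0 < 1 or n_class1 < 1:
        raise ValueError("both class counts must be >= 1")
    effect = effect or CohortEffect()
    if effect.class0 == effect.class1:
        logger.warning("cohort effect is null: class distributions are identical")
    base = base_spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    # independent per-phantom noise seeds, bounded below 2**31
    noise_seeds = rng.integers(0, 2**31 - 1, size=n_class0 + n_class1)

    phantoms: list[Phantom] = []
    labels = [0] * n_class0 + [1] * n_class1
    for i, label in enumerate(labels):
        eff = effect.class0 if label == 0 else effect.class1
        ft = max(0.005, rng.normal(eff.ft_mean, eff.ft_sd))
        k2 = rng.normal(eff.k2_mean, eff.k2_sd)
        kep = max(1e-3, rng.normal(eff.kep_mean, eff.kep_sd))
        spec = replace(
            base,
            tissue_classes=default_tissue_classes(
                ft, k2, kep, base.normal_tissue.ft
            ),
            seed=int(noise_seeds[i]),
        )
        phantoms.append(build_phantom(spec, label=label))
    return phantoms
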