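"""Leakage-corrected blood-volume estimation for DSC-MRI.

A disrupted blood-brain barrier lets contrast agent extravasate from the
intravascular space (IVS) into the extravascular-extracellular space (EES),
biasing the directly integrated blood volume nrCBV.  Two exchange models
express the measured voxel curve through the whole-brain average
concentration of non-enhancing tissue, ``ref(t)``:

unidirectional (IVS -> EES only)::

    Ct(t) = K1 * ref(t) - K2 * int_0^t ref(tau) dtau

bidirectional (return flow EES -> IVS at rate Kep)::

    Ct(t) = K1 * ref(t) - K2 * (ref ** exp(-Kep t))(t)

``K1`` is a susceptibility scaling factor, ``K2`` the intra-to-extravascular
permeability term and ``Kep`` the extra-to-intravascular transfer constant.
All three are fitted over the reals without sign constraints: with an
unconstrained K2 both T1- and T2*-dominant leakage regimes are
representable.  The corrected curve adds the leakage term back
(``Ct + K2 * ...``), and nrCBV is the trapezoidal integral of the curve
between bolus arrival and replenish time points.

Discretisation: all cumulative integrals and the exponential-kernel
convolution use trapezoid weights on the native dt, so the Kep -> 0 limit
of the bidirectional kernel reproduces the unidirectional running integral
exactly (not merely to O(dt)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, ndimage, optimize

__all__ = [
    "UnidirParams",
    "BidirParams",
    "cumulative_trapezoid_curve",
    "exp_kernel_convolution",
    "contaminate_with_leakage",
    "compute_reference_curve",
    "replenish_index",
    "integrate_nrcbv",
    "fit_unidirectional",
    "correct_unidirectional",
    "fit_bidirectional",
    "correct_bidirectional",
]


@dataclass
class UnidirParams:
    k1: float
    k2: float
    residual_norm: float = 0.0


@dataclass
class BidirParams:
    k1: float
    k2: float
    kep: float
    residual_norm: float = 0.0
    converged: bool = True
    #: K2 ~ 0 makes Kep unidentifiable (the leakage term vanishes)
    kep_identifiable: bool = True


def cumulative_trapezoid_curve(curve: np.ndarray, dt: float) -> np.ndarray:
    """Running trapezoid integral of a uniformly sampled curve, from t=0."""
    return integrate.cumulative_trapezoid(np.asarray(curve, float), dx=dt, initial=0.0)


def exp_kernel_convolution(curve: np.ndarray, kep: float, dt: float) -> np.ndarray:
    """Trapezoid-weighted causal convolution ``(curve ** exp(-kep t)) * dt``.

    Evaluated by the exact recurrence

        K[n] = e^(-kep dt) K[n-1] + dt/2 (curve[n] + e^(-kep dt) curve[n-1])

    which reduces to the running trapezoid integral at kep = 0.
    """
    c = np.asarray(curve, dtype=float)
    out = np.zeros_like(c)
    decay = float(np.exp(-kep * dt))
    for n in range(1, len(c)):
        out[n] = decay * out[n - 1] + 0.5 * dt * (c[n] + decay * c[n - 1])
    return out


def contaminate_with_leakage(
    reference: np.ndarray, k1: float, k2: float, kep: float, dt: float
) -> np.ndarray:
    """Forward bidirectional-exchange model: build a leaky voxel curve
    ``K1*ref - K2*(ref ** exp(-Kep t))`` from the reference curve.

    With kep = 0 the kernel degenerates to the running integral and the
    expression becomes the unidirectional forward model.
    """
    reference = np.asarray(reference, dtype=float)
    return k1 * reference - k2 * exp_kernel_convolution(reference, kep, dt)


def compute_reference_curve(
    conc_series: np.ndarray,
    brain_mask: np.ndarray,
    tumor_mask: np.ndarray,
    *,
    dilation_voxels: int = 2,
) -> tuple[np.ndarray, int]:
    """Whole-brain average concentration over non-enhancing voxels.

    The tumor mask is dilated by ``dilation_voxels`` to exclude the
    partial-volume rim, then subtracted from the brain mask; the reference
    is the mean curve over the remaining voxels.

    Parameters
    ----------
    conc_series : (x, y, z, t) concentration array.
    brain_mask, tumor_mask : boolean (x, y, z) arrays.

    Returns
    -------
    (reference curve of length t, number of voxels averaged)
    """
    brain = np.asarray(brain_mask, bool)
    tumor = np.asarray(tumor_mask, bool)
    if brain.shape != conc_series.shape[:3] or tumor.shape != brain.shape:
        raise ValueError("masks must match the spatial grid of the series")
    if dilation_voxels > 0:
        tumor = ndimage.binary_dilation(tumor, iterations=dilation_voxels)
    ref_mask = brain & ~tumor
    n = int(np.sum(ref_mask))
    if n == 0:
        raise ValueError("empty reference region: brain minus dilated tumor")
    return conc_series[ref_mask].mean(axis=0), n


def replenish_index(reference: np.ndarray) -> int:
    """Replenish time point: first local minimum of the reference curve
    after its global peak; falls back to the last sample if the tail is
    monotone."""
    ref = np.asarray(reference, dtype=float)
    peak = int(np.argmax(ref))
    for i in range(peak + 1, len(ref) - 1):
        if ref[i] <= ref[i - 1] and ref[i] <= ref[i + 1]:
            return i
    return len(ref) - 1


def integrate_nrcbv(conc: np.ndarray, t0_index: int, t1_index: int, dt: float) -> float:
    """nrCBV: trapezoidal integral of the concentration curve between the
    bolus-arrival and replenish indices (both endpoints included in the
    quadrature)."""
    conc = np.asarray(conc, dtype=float)
    if not (0 <= t0_index < t1_index < len(conc)):
        raise ValueError("invalid integration window")
    return float(np.trapezoid(conc[t0_index : t1_index + 1], dx=dt))


def _unidir_design(reference: np.ndarray, dt: float) -> np.ndarray:
    return np.column_stack(
        [reference, -cumulative_trapezoid_curve(reference, dt)]
    )


def fit_unidirectional(conc: np.ndarray, reference: np.ndarray, dt: float) -> UnidirParams:
    """Linear least-squares fit of ``Ct = K1*ref - K2*int(ref)``.

    The problem is linear in (K1, K2); the solution matches the
    normal-equations closed form to numerical precision.
    """
    conc = np.asarray(conc, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if conc.shape != reference.shape:
        raise ValueError("curve and reference must share the time grid")
    design = _unidir_design(reference, dt)
    coef, _, rank, _ = np.linalg.lstsq(design, conc)
    if rank < 2:
        raise ValueError("rank-deficient design: reference curve degenerate")
    resid = conc - design @ coef
    return UnidirParams(float(coef[0]), float(coef[1]), float(np.linalg.norm(resid)))


def correct_unidirectional(
    conc: np.ndarray, reference: np.ndarray, k2: float, dt: float
) -> np.ndarray:
    """Add the fitted unidirectional leakage term back:
    ``Ct_corr = Ct + K2 * int_0^t ref``."""
    return np.asarray(conc, float) + k2 * cumulative_trapezoid_curve(reference, dt)


def fit_bidirectional(
    conc: np.ndarray,
    reference: np.ndarray,
    dt: float,
    *,
    init: tuple[float, float, float] = (1.0, 0.0, 0.01),
    kep_search_max: float = 2.0,
    k2_identifiability_tol: float = 1e-8,
) -> BidirParams:
    """Fit ``Ct = K1*ref - K2*(ref ** exp(-Kep t))``.

    Primary solver: unconstrained Levenberg-Marquardt on (K1, K2, Kep)
    starting at the near-unidirectional regime ``init = (1, 0, 0.01)``.
    For fixed Kep the model is linear in (K1, K2), which provides a
    profiled fallback (inner linear solve, outer bounded 1-D search on
    Kep) whenever LM fails or is beaten by the profile.  No sign
    constraint is imposed on any parameter.
    """
    conc = np.asarray(conc, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if conc.shape != reference.shape:
        raise ValueError("curve and reference must share the time grid")
    scale = float(np.max(np.abs(conc))) or 1.0

    def residuals(p: np.ndarray) -> np.ndarray:
        r = (
            p[0] * reference
            - p[1] * exp_kernel_convolution(reference, p[2], dt)
            - conc
        )
        # strongly negative Kep trials overflow the growing kernel
        return np.nan_to_num(r, nan=1e3 * scale, posinf=1e3 * scale, neginf=-1e3 * scale)

    sol = optimize.least_squares(
        residuals, np.asarray(init, dtype=float), method="lm",
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )

    def linear_fit(kep: float) -> tuple[np.ndarray, float]:
        design = np.column_stack(
            [reference, -exp_kernel_convolution(reference, kep, dt)]
        )
        coef, _, _, _ = np.linalg.lstsq(design, conc)
        resid = conc - design @ coef
        return coef, float(resid @ resid)

    if sol.success:
        k1, k2, kep = (float(v) for v in sol.x)
        rnorm = float(np.sqrt(2 * sol.cost))
        converged = True
    else:
        res = optimize.minimize_scalar(
            lambda kep: linear_fit(kep)[1],
            bounds=(0.0, kep_search_max), method="bounded",
            options={"xatol": 1e-10},
        )
        kep = min([float(res.x), float(init[2]), 0.0],
                  key=lambda v: linear_fit(v)[1])
        (k1, k2), cost = linear_fit(kep)
        k1, k2 = float(k1), float(k2)
        rnorm = float(np.sqrt(cost))
        converged = bool(res.success)
    ref_scale = float(np.max(np.abs(reference))) or 1.0
    identifiable = abs(k2) > k2_identifiability_tol * ref_scale
    return BidirParams(k1, k2, kep, rnorm, converged, identifiable)


def correct_bidirectional(
    conc: np.ndarray, reference: np.ndarray, k2: float, kep: float, dt: float
) -> np.ndarray:
    """Add the fitted bidirectional leakage term back:
    ``Ct_corr = Ct + K2 * (ref ** exp(-Kep t)) * dt``; reduces to the
    unidirectional correction at kep = 0."""
    return np.asarray(conc, float) + k2 * exp_kernel_convolution(reference, kep, dt)
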