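"""Voxelwise parametric-map computation.

Chains signal-to-concentration conversion, gamma transport-function
fitting and leakage-model fitting over a masked 4D series to produce the
named 3D maps used for radiomics: rCBF, rMTT, rCBV, TMAX, MSI from the
gamma model; nrCBV, K1/K2 (unidirectional) and K1/K2/Kep (bidirectional)
with their corrected blood volumes from the exchange models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import kinetics, leakage

logger = logging.getLogger(__name__)

__all__ = [
    "ParametricMapSet",
    "series_to_concentration",
    "compute_gamma_maps",
    "compute_leakage_maps",
    "compute_all_maps",
    "GAMMA_MAP_NAMES",
    "LEAKAGE_MAP_NAMES",
]

GAMMA_MAP_NAMES = ("rCBF", "rMTT", "rCBV", "TMAX", "MSI")
LEAKAGE_MAP_NAMES = (
    "nrCBV", "K1_unidir", "K2_unidir", "nrCBV_unidir",
    "K1_bidir", "K2_bidir", "Kep_bidir", "nrCBV_bidir",
)


@dataclass
class ParametricMapSet:
    """Named 3D maps on a shared grid with a joint validity mask."""

    maps: dict[str, np.ndarray]
    validity: np.ndarray
    diagnostics: dict[str, float] = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.maps[name]

    def names(self) -> list[str]:
        return list(self.maps)


def series_to_concentration(
    series: np.ndarray, te: float, n_baseline: int
) -> tuple[np.ndarray, np.ndarray, int]:
    """Convert a 4D signal series to concentration voxelwise.

    Returns (concentration series, validity mask, clamped-sample count).
    Voxels with nonpositive baseline mean are marked invalid and zeroed.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 4:
        raise ValueError("expected a 4D (x, y, z, t) series")
    if not (1 <= n_baseline < series.shape[3]):
        raise ValueError("n_baseline must be in [1, n_timepoints)")
    s0 = series[..., :n_baseline].mean(axis=3)
    valid = s0 > 0
    floor = kinetics.SIGNAL_CLAMP_FRACTION * np.where(valid, s0, 1.0)
    n_clamped = int(np.sum((series <= 0) & valid[..., None]))
    clamped = np.maximum(series, floor[..., None])
    conc = np.zeros_like(series)
    conc[valid] = -np.log(clamped[valid] / s0[valid, None]) / te
    if n_clamped:
        logger.warning("clamped %d nonpositive signal samples", n_clamped)
    return conc, valid, n_clamped


def compute_gamma_maps(
    conc: np.ndarray,
    aif: np.ndarray,
    time_grid: np.ndarray,
    mask: np.ndarray,
    n_baseline: int,
    *,
    fit_flow: bool = True,
    multistart: bool = False,
) -> ParametricMapSet:
    """Gamma-model maps in every masked voxel.

    rCBF = Ft, rMTT = t1 + sigma1(1 + a1), rCBV = rCBF * rMTT (central
    volume principle, exact by construction).  TMAX and MSI are computed
    on the measured concentration curve, with t0 the last baseline frame;
    they need no model fit, so ``fit_flow=False`` skips the (expensive)
    voxelwise least squares and emits only the curve-derived maps.
    Non-converged voxels and voxels whose maximum precedes t0 are invalid.
    """
    mask = np.asarray(mask, bool)
    names = GAMMA_MAP_NAMES if fit_flow else ("TMAX", "MSI")
    out = {name: np.full(mask.shape, np.nan) for name in names}
    validity = np.zeros(mask.shape, dtype=bool)
    n_failed = 0
    t0 = n_baseline - 1
    for idx in zip(*np.nonzero(mask)):
        curve = conc[idx]
        try:
            msi, i_max = kinetics.mean_slope_of_increase(curve, t0)
        except ValueError:
            n_failed += 1
            continue
        if fit_flow:
            fit = kinetics.fit_gamma_model(curve, aif, time_grid, multistart=multistart)
            if not fit.converged:
                n_failed += 1
                continue
            out["rCBF"][idx] = fit.ft
            out["rMTT"][idx] = fit.rmtt
            out["rCBV"][idx] = fit.rcbv
        out["TMAX"][idx] = time_grid[i_max]
        out["MSI"][idx] = msi
        validity[idx] = True
    if n_failed:
        logger.warning("gamma fit failed or MSI undefined in %d voxels", n_failed)
    return ParametricMapSet(out, validity, {"n_failed": float(n_failed)})


def compute_leakage_maps(
    conc: np.ndarray,
    brain_mask: np.ndarray,
    tumor_mask: np.ndarray,
    dt: float,
    *,
    fit_bidirectional: bool = True,
    arrival_fraction: float = 0.05,
) -> ParametricMapSet:
    """Fit the exchange models in every tumor voxel against the
    non-enhancing whole-brain reference curve.

    The integration window for all nrCBV variants runs from the reference
    bolus arrival (first sample above ``arrival_fraction`` of the peak) to
    its replenish point (first local minimum after the peak).
    """
    ref, n_ref = leakage.compute_reference_curve(conc, brain_mask, tumor_mask)
    peak = float(np.max(ref))
    t0 = int(np.argmax(ref > arrival_fraction * peak)) if peak > 0 else 0
    t1 = leakage.replenish_index(ref)
    if t1 <= t0:
        raise ValueError("degenerate reference curve: no integration window")

    tumor = np.asarray(tumor_mask, bool)
    names = list(LEAKAGE_MAP_NAMES) if fit_bidirectional else list(LEAKAGE_MAP_NAMES[:4])
    out = {name: np.full(tumor.shape, np.nan) for name in names}
    validity = np.zeros(tumor.shape, dtype=bool)
    n_failed = 0
    for idx in zip(*np.nonzero(tumor)):
        curve = conc[idx]
        out["nrCBV"][idx] = leakage.integrate_nrcbv(curve, t0, t1, dt)
        uni = leakage.fit_unidirectional(curve, ref, dt)
        out["K1_unidir"][idx] = uni.k1
        out["K2_unidir"][idx] = uni.k2
        corr = leakage.correct_unidirectional(curve, ref, uni.k2, dt)
        out["nrCBV_unidir"][idx] = leakage.integrate_nrcbv(corr, t0, t1, dt)
        ok = True
        if fit_bidirectional:
            bid = leakage.fit_bidirectional(curve, ref, dt)
            if bid.converged:
                out["K1_bidir"][idx] = bid.k1
                out["K2_bidir"][idx] = bid.k2
                out["Kep_bidir"][idx] = bid.kep
                corr2 = leakage.correct_bidirectional(curve, ref, bid.k2, bid.kep, dt)
                out["nrCBV_bidir"][idx] = leakage.integrate_nrcbv(corr2, t0, t1, dt)
            else:
                ok = False
                n_failed += 1
        validity[idx] = ok
    if n_failed:
        logger.warning("bidirectional fit failed in %d voxels", n_failed)
    diag = {
        "n_reference_voxels": float(n_ref),
        "window_t0": float(t0),
        "window_t1": float(t1),
        "n_failed": float(n_failed),
    }
    return ParametricMapSet(out, validity, diag)


def compute_all_maps(
    series: np.ndarray,
    aif: np.ndarray,
    time_grid: np.ndarray,
    brain_mask: np.ndarray,
    tumor_mask: np.ndarray,
    te: float,
    n_baseline: int,
    *,
    gamma: bool = True,
    unidirectional: bool = True,
    bidirectional: bool = True,
) -> ParametricMapSet:
    """Full map computation for one subject/phantom.

    Gamma-model maps are fitted inside the tumor mask only (the radiomics
    ROI); leakage maps additionally use the brain mask to form the
    non-enhancing reference curve.  The curve-derived TMAX/MSI maps are
    always produced; ``gamma=False`` skips only the voxelwise flow fit.
    """
    dt = float(time_grid[1] - time_grid[0])
    conc, valid_conc, _ = series_to_concentration(series, te, n_baseline)
    maps: dict[str, np.ndarray] = {}
    validity = np.asarray(tumor_mask, bool) & valid_conc
    diagnostics: dict[str, float] = {}
    gset = compute_gamma_maps(
        conc, aif, time_grid, validity, n_baseline, fit_flow=gamma
    )
    maps.update(gset.maps)
    validity = validity & gset.validity
    diagnostics.update({f"gamma_{k}": v for k, v in gset.diagnostics.items()})
    if unidirectional or bidirectional:
        lset = compute_leakage_maps(
            conc, brain_mask, tumor_mask, dt, fit_bidirectional=bidirectional
        )
        maps.update(lset.maps)
        validity = validity & (lset.validity | ~np.asarray(tumor_mask, bool))
        diagnostics.update({f"leak_{k}": v for k, v in lset.diagnostics.items()})
    return ParametricMapSet(maps, validity, diagnostics)
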