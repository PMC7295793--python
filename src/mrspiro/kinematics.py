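"""Finite-strain kinematics of the breathing lung.

Given the Lagrangian displacement u(R, t_n) of every voxel relative to the
end-expiration reference, this module computes, per voxel and per motion bin:

* the deformation gradient F = I + du/dR (spacing-aware finite differences),
* the Jacobian J = det F, the local volume ratio dV/dV0,
* the Green-Lagrange strain tensor eps = (F^T F - I)/2 (rotation-invariant),
* its principal strains eps_I >= eps_II >= eps_III, principal stretch ratios
  lambda_i = sqrt(1 + 2 eps_i) (the singular values of F), and
* the fractional anisotropy FA of the stretch triple,

plus a periodic temporal smoother for the displacement fields and the
small-strain consistency diagnostic J ~ 1 + tr(eps).

Derivatives are central differences in world units (mm), falling back to
one-sided differences where a neighbour leaves the lung mask; voxels whose
full central stencil leaves the mask are flagged and excluded from the
``interior`` set used for statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .grid_io import DisplacementField4D, ImageGrid, LungMask

_EYE3 = np.eye(3)


@dataclass
class DeformationGradientField:
    """F per voxel per bin; identity outside the mask and at the reference bin."""

    grid: ImageGrid
    F: np.ndarray               # (n_bins, nx, ny, nz, 3, 3)
    mask: LungMask
    interior: np.ndarray        # voxels whose full central stencil is in-mask
    partial_stencil: np.ndarray  # in-mask voxels differentiated one-sided

    @property
    def n_bins(self) -> int:
        return self.F.shape[0]


@dataclass
class JacobianField:
    grid: ImageGrid
    J: np.ndarray               # (n_bins, nx, ny, nz)
    folding_mask: np.ndarray    # J <= 0 inside the lung mask

    @property
    def n_bins(self) -> int:
        return self.J.shape[0]


@dataclass
class StrainField:
    grid: ImageGrid
    eps: np.ndarray             # (n_bins, nx, ny, nz, 3, 3), exactly symmetric


@dataclass
class PrincipalStrainField:
    grid: ImageGrid
    eps_principal: np.ndarray   # (n_bins, nx, ny, nz, 3), descending
    eigvec: np.ndarray          # (n_bins, nx, ny, nz, 3, 3), columns = axes
    lam: np.ndarray             # stretch ratios sqrt(1+2 eps_i); NaN if invalid
    nonphysical: np.ndarray     # (n_bins, nx, ny, nz) where 1+2 eps_III <= 0

    def nonphysical_report(self, max_locations: int = 20) -> dict:
        locs = np.argwhere(self.nonphysical)
        return {
            "count": int(self.nonphysical.sum()),
            "locations": locs[:max_locations].tolist(),
        }


@dataclass
class FAField:
    grid: ImageGrid
    FA: np.ndarray              # (n_bins, nx, ny, nz) in [0, 1]


# ---------------------------------------------------------------------------
# temporal smoothing
# ---------------------------------------------------------------------------

def smooth_fields_temporally(
    u: DisplacementField4D, smoothing: float | str = 0.0
) -> DisplacementField4D:
    """Penalized least-squares smoothing along the bin axis, periodic in time.

    Minimizes ||y - x||^2 + s ||D2 x||^2 per voxel/component, with D2 the
    periodic second difference along the respiratory cycle (bin N adjacent to
    bin 1), solved exactly in Fourier space: the filter gain at angular
    frequency w is 1 / (1 + s (2 - 2 cos w)^2). ``smoothing`` is the penalty
    s >= 0 (0 returns the input unchanged) or ``"gcv"`` to pick s by
    generalized cross-validation pooled over all voxels. The zero displacement
    of the reference bin is re-imposed afterwards by subtracting the residual
    reference-bin field from every bin.
    """
    n = u.n_bins
    if n < 4:
        raise ValueError("temporal smoothing needs at least 4 bins")
    if isinstance(smoothing, str):
        if smoothing != "gcv":
            raise ValueError(f"unknown smoothing setting {smoothing!r}")
        s = _gcv_smoothing(u.u)
    else:
        s = float(smoothing)
        if s < 0:
            raise ValueError("smoothing penalty must be >= 0")
    if s == 0:
        return DisplacementField4D(
            grid=u.grid, u=u.u.copy(), reference_bin=u.reference_bin
        )
    smoothed = _periodic_smooth(u.u, s)
    smoothed -= smoothed[u.reference_bin]
    return DisplacementField4D(grid=u.grid, u=smoothed, reference_bin=u.reference_bin)


def _filter_gain(n: int, s: float) -> np.ndarray:
    w = 2 * np.pi * np.fft.rfftfreq(n)
    return 1.0 / (1.0 + s * (2 - 2 * np.cos(w)) ** 2)


def _periodic_smooth(y: np.ndarray, s: float) -> np.ndarray:
    n = y.shape[0]
    gain = _filter_gain(n, s)
    Y = np.fft.rfft(y, axis=0)
    Y *= gain.reshape((-1,) + (1,) * (y.ndim - 1))
    return np.fft.irfft(Y, n=n, axis=0)


def _gcv_smoothing(y: np.ndarray) -> float:
    """GCV choice of the penalty, pooled over every voxel/component series."""
    n = y.shape[0]
    Y = np.fft.rfft(y, axis=0)
    # per-frequency power pooled over series; rfft duplicity weights
    mult = np.full(Y.shape[0], 2.0)
    mult[0] = 1.0
    if n % 2 == 0:
        mult[-1] = 1.0
    P = mult * np.sum(np.abs(Y) ** 2, axis=tuple(range(1, Y.ndim))) / n
    lam = (2 - 2 * np.cos(2 * np.pi * np.fft.rfftfreq(n))) ** 2

    def gcv(log10_s: float) -> float:
        g = 1.0 / (1.0 + 10.0**log10_s * lam)
        rss = float(np.sum(P * (1 - g) ** 2))
        tr_h = float(np.sum(mult * g))
        denom = max(n - tr_h / (np.sum(mult) / n), 1e-9)  # effective per-series
        return n * rss / denom**2

    res = minimize_scalar(gcv, bounds=(-6, 6), method="bounded")
    return float(10.0 ** res.x)


# ---------------------------------------------------------------------------
# differentiation
# ---------------------------------------------------------------------------

def _masked_derivative(vol: np.ndarray, mask: np.ndarray, axis: int, h: float):
    """d(vol)/d(axis) inside mask: central, one-sided at the mask boundary.

    Returns (derivative, central_ok) where central_ok marks voxels with both
    neighbours in-mask along this axis.
    """
    def shifted(arr, d, fill=0.0):
        out = np.full_like(arr, fill)
        src = [slice(None)] * arr.ndim
        dst = [slice(None)] * arr.ndim
        if d > 0:
            src[axis], dst[axis] = slice(d, None), slice(None, -d)
        else:
            src[axis], dst[axis] = slice(None, d), slice(-d, None)
        out[tuple(dst)] = arr[tuple(src)]
        return out

    vp, vm = shifted(vol, +1), shifted(vol, -1)
    mp = shifted(mask.astype(bool), +1, fill=False)
    mm = shifted(mask.astype(bool), -1, fill=False)
    both = mask & mp & mm
    only_p = mask & mp & ~mm
    only_m = mask & mm & ~mp
    deriv = np.zeros_like(vol)
    deriv[both] = (vp[both] - vm[both]) / (2 * h)
    deriv[only_p] = (vp[only_p] - vol[only_p]) / h
    deriv[only_m] = (vol[only_m] - vm[only_m]) / h
    return deriv, both


def deformation_gradient(
    u: DisplacementField4D, mask: LungMask
) -> DeformationGradientField:
    """F = I + du/dR by spacing-aware finite differences inside the mask."""
    if not u.grid.matches(mask.grid):
        raise ValueError("displacement field and mask are on different grids")
    m = mask.membership
    for ax in range(3):
        occupied = int(m.any(axis=tuple(i for i in range(3) if i != ax)).sum())
        if occupied < 2:
            raise ValueError(
                f"lung mask thinner than 2 voxels along axis {ax}"
            )
    n = u.n_bins
    F = np.zeros((n,) + u.grid.shape + (3, 3))
    F[..., :, :] = _EYE3
    interior = m.copy()
    for k in range(n):
        for i in range(3):
            for j in range(3):
                d, central = _masked_derivative(
                    u.u[k, ..., i], m, axis=j, h=u.grid.spacing[j]
                )
                F[k, ..., i, j] += d
                if k == 0 and i == 0:
                    interior &= central
    partial = m & ~interior
    return DeformationGradientField(
        grid=u.grid, F=F, mask=mask, interior=interior, partial_stencil=partial
    )


def jacobian(F: DeformationGradientField) -> JacobianField:
    """J = det(F); folding_mask marks in-mask voxels with J <= 0."""
    J = np.linalg.det(F.F)
    folding = (J <= 0) & F.mask.membership[None]
    return JacobianField(grid=F.grid, J=J, folding_mask=folding)


def green_lagrange(F: DeformationGradientField) -> StrainField:
    """eps = (F^T F - I)/2, symmetrized exactly."""
    C = np.einsum("...ji,...jk->...ik", F.F, F.F)
    C = 0.5 * (C + np.swapaxes(C, -1, -2))
    eps = 0.5 * (C - _EYE3)
    return StrainField(grid=F.grid, eps=eps)


def principal_strains(strain: StrainField) -> PrincipalStrainField:
    """Diagonalize the strain tensor; eigenvalues sorted descending.

    Stretch ratios lambda_i = sqrt(1 + 2 eps_i). Voxels with
    1 + 2 eps_III <= 0 are physically impossible (they indicate registration
    failure); their lambdas are NaN and they are flagged, never clamped.
    Eigenvector signs are fixed by making each vector's largest-magnitude
    component positive, for reproducible maps.
    """
    vals, vecs = np.linalg.eigh(strain.eps)          # ascending
    vals = vals[..., ::-1]
    vecs = vecs[..., ::-1]
    # sign convention per eigenvector (columns of vecs)
    comp = np.argmax(np.abs(vecs), axis=-2, keepdims=True)
    signs = np.sign(np.take_along_axis(vecs, comp, axis=-2))
    signs[signs == 0] = 1.0
    vecs = vecs * signs
    arg = 1 + 2 * vals
    nonphysical = arg[..., 2] <= 0
    lam = np.sqrt(np.where(arg > 0, arg, np.nan))
    return PrincipalStrainField(
        grid=strain.grid,
        eps_principal=vals,
        eigvec=vecs,
        lam=lam,
        nonphysical=nonphysical,
    )


def fractional_anisotropy(p: PrincipalStrainField, tol: float = 1e-30) -> FAField:
    """FA of the stretch triple; 0 where all stretches are (numerically) equal.

    FA = sqrt( ((l1-l2)^2 + (l2-l3)^2 + (l1-l3)^2) / (2 (l1^2+l2^2+l3^2)) ),
    ranging 0 (isotropic deformation) to 1.
    """
    l1, l2, l3 = p.lam[..., 0], p.lam[..., 1], p.lam[..., 2]
    num = (l1 - l2) ** 2 + (l2 - l3) ** 2 + (l1 - l3) ** 2
    den = 2 * (l1**2 + l2**2 + l3**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.where(den > tol, np.sqrt(num / np.maximum(den, tol)), 0.0)
    return FAField(grid=p.grid, FA=fa)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

@dataclass
class SmallStrainReport:
    """Residual of the small-strain identity J ~ 1 + tr(eps)."""

    residual: np.ndarray        # (n_bins, nx, ny, nz)
    quantiles: pd.DataFrame     # per-bin residual quantiles over the region


def check_small_strain(
    J: JacobianField,
    strain: StrainField,
    region: np.ndarray | None = None,
) -> SmallStrainReport:
    """Per-voxel |J - (1 + eps_xx + eps_yy + eps_zz)| with summary quantiles.

    A sanity diagnostic: the residual is second order in strain, so it must
    shrink quadratically as the deformation amplitude shrinks. Never used to
    compute J.
    """
    tr = np.trace(strain.eps, axis1=-2, axis2=-1)
    residual = np.abs(J.J - (1 + tr))
    if region is None:
        region = np.ones(J.J.shape[1:], dtype=bool)
    rows = []
    for k in range(J.n_bins):
        r = residual[k][region]
        rows.append(
            {
                "bin": k,
                "median": float(np.median(r)),
                "q90": float(np.quantile(r, 0.9)),
                "q99": float(np.quantile(r, 0.99)),
                "max": float(r.max()),
            }
        )
    return SmallStrainReport(residual=residual, quantiles=pd.DataFrame(rows))


def fa_summary(fa: FAField, mask: LungMask) -> pd.DataFrame:
    """Mean +/- sd of FA over the lung mask, per bin and pooled.

    Mirrors the reporting form "FA = (mean +/- sd)" over the entire lung
    volume; the pooled row aggregates all bins.
    """
    m = mask.membership
    rows = [
        {
            "bin": k,
            "fa_mean": float(np.nanmean(fa.FA[k][m])),
            "fa_sd": float(np.nanstd(fa.FA[k][m])),
        }
        for k in range(fa.FA.shape[0])
    ]
    pooled = fa.FA[:, m]
    rows.append(
        {
            "bin": -1,
            "fa_mean": float(np.nanmean(pooled)),
            "fa_sd": float(np.nanstd(pooled)),
        }
    )
    return pd.DataFrame(rows)
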