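"""Regional spirometry: gas flow, flow-volume loops, trajectories, LTV/LEV1.

The Jacobian J_n at bin time t_n is a dimensionless regional volume ratio;
its time derivative Q_n = dJ/dt (units 1/s) is the instantaneous regional
gas flow per unit reference volume. Multiplying by the reference voxel
volume dV0 gives volumetric flow in mm^3/s. Q is computed with a weighted
finite-difference scheme on the (generally nonuniform) bin time-stamps,

    Q_n = 1/(t_{n+1} - t_{n-1}) * [ (t_{n+1}-t_n)/(t_n-t_{n-1}) (J_n - J_{n-1})
                                  + (t_n-t_{n-1})/(t_{n+1}-t_n) (J_{n+1} - J_n) ],

exact for quadratics and reducing to the central difference for uniform
spacing. Periodic boundary conditions close the respiratory cycle: the
neighbours of the first and last bins wrap with the period added/subtracted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid_io import BinTiming, DisplacementField4D, ImageGrid, LungMask
from .kinematics import JacobianField


@dataclass
class FlowField:
    """Per-voxel rate of volume change dJ/dt per bin (1/s)."""

    grid: ImageGrid
    Q: np.ndarray               # (n_bins, nx, ny, nz)
    timing: BinTiming

    def volumetric(self) -> np.ndarray:
        """Flow in mm^3/s: Q scaled by the reference voxel volume dV0."""
        return self.Q * self.grid.voxel_volume_mm3


@dataclass
class FlowVolumeLoop:
    """Closed (J_n, Q_n) cycle for one voxel, region or the whole lung.

    ``volume`` is J (dimensionless) for voxel/region scope and V(t) in mm^3
    for the whole lung; ``flow`` is its weighted-finite-difference derivative.
    """

    volume: np.ndarray          # (n_bins,)
    flow: np.ndarray            # (n_bins,)
    phase: np.ndarray
    scope: str                  # "voxel" | "region" | "whole"
    label: object = None

    def display_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Points in the standard spirometry rendering convention.

        Expiration on top (expiratory flow plotted positive) and deflation to
        the right (volume axis reversed): returns (-volume, -flow), closed by
        repeating the first point.
        """
        x = np.append(-self.volume, -self.volume[0])
        y = np.append(-self.flow, -self.flow[0])
        return x, y


@dataclass
class Trajectory:
    """Closed path r(R, t_n) of one reference voxel over the cycle."""

    index: tuple[int, int, int]
    positions: np.ndarray       # (n_bins, 3) world mm
    phase: np.ndarray
    areas: dict = field(default_factory=dict)        # projection -> area >= 0
    orientations: dict = field(default_factory=dict)  # -> "ccw"/"cw"/None

    def extent(self, axis: int) -> float:
        return float(np.ptp(self.positions[:, axis]))


@dataclass
class SpiroMetrics:
    """Per-voxel tidal volume and first-second expiratory volume (mm^3)."""

    LTV: np.ndarray
    LEV1: np.ndarray
    lev1_defined: bool


PROJECTIONS = {"sagittal": (0, 2), "coronal": (0, 1), "axial": (1, 2)}


# ---------------------------------------------------------------------------
# flow
# ---------------------------------------------------------------------------

def _wrapped_times(timing: BinTiming) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    t = timing.times
    if np.any(np.diff(t) <= 0):
        dup = np.flatnonzero(np.diff(t) <= 0)
        raise ValueError(
            f"bin time-stamps must be strictly increasing within the cycle; "
            f"violation after bin(s) {dup.tolist()}"
        )
    t_prev = np.roll(t, 1)
    t_prev[0] -= timing.period_s
    t_next = np.roll(t, -1)
    t_next[-1] += timing.period_s
    return t_prev, t, t_next


def weighted_finite_difference(y: np.ndarray, timing: BinTiming) -> np.ndarray:
    """dy/dt on nonuniform periodic samples (bin axis first)."""
    t_prev, t, t_next = _wrapped_times(timing)
    dt1 = t - t_prev
    dt2 = t_next - t
    y_prev = np.roll(y, 1, axis=0)
    y_next = np.roll(y, -1, axis=0)
    shape = (-1,) + (1,) * (y.ndim - 1)
    dt1 = dt1.reshape(shape)
    dt2 = dt2.reshape(shape)
    return ((dt2 / dt1) * (y - y_prev) + (dt1 / dt2) * (y_next - y)) / (dt1 + dt2)


def regional_flow(J: JacobianField, timing: BinTiming) -> FlowField:
    """Q_n = dJ/dt at every voxel, periodic over the respiratory cycle."""
    if timing.n_bins != J.n_bins:
        raise ValueError("timing and Jacobian disagree on the number of bins")
    if timing.n_bins < 3:
        raise ValueError("need at least 3 bins for the flow stencil")
    Q = weighted_finite_difference(J.J, timing)
    return FlowField(grid=J.grid, Q=Q, timing=timing)


def cycle_closure(flow: FlowField, region: np.ndarray | None = None
                  ) -> tuple[float, float]:
    """Residual of the closed-cycle integral of Q with trapezoidal weights.

    Returns (|sum Q_n w_n|, sum |Q_n| w_n) aggregated over the region; the
    ratio is the relative closure error of the flow-volume loop.
    """
    t_prev, _, t_next = _wrapped_times(flow.timing)
    w = 0.5 * (t_next - t_prev)
    Q = flow.Q if region is None else flow.Q[:, region]
    w = w.reshape((-1,) + (1,) * (Q.ndim - 1))
    signed = np.abs(np.sum(Q * w, axis=0))
    mass = np.sum(np.abs(Q) * w, axis=0)
    return float(np.sum(signed)), float(np.sum(mass))


# ---------------------------------------------------------------------------
# loops
# ---------------------------------------------------------------------------

def build_loops(
    J: JacobianField,
    flow: FlowField,
    mask: LungMask,
    scope: str = "whole",
    voxels: list[tuple[int, int, int]] | None = None,
) -> list[FlowVolumeLoop]:
    """Flow-volume loops at voxel, region (mask label) or whole-lung scope.

    Whole-lung: V(t_n) = sum over mask of dV0 * J_n (mm^3) with its own
    weighted-finite-difference derivative (mm^3/s). Regions aggregate J by
    dV0-weighted mean (uniform grid: plain mean) before differentiation.
    """
    timing = flow.timing
    phase = timing.phase
    if scope == "whole":
        m = mask.membership
        V = J.J[:, m].sum(axis=1) * J.grid.voxel_volume_mm3
        Q = weighted_finite_difference(V, timing)
        return [FlowVolumeLoop(volume=V, flow=Q, phase=phase, scope="whole")]
    if scope == "region":
        if mask.labels is None:
            raise ValueError("region scope requires a labelled mask")
        loops = []
        for lab in np.unique(mask.labels[mask.labels > 0]):
            sel = mask.labels == lab
            if not sel.any():
                raise ValueError(f"empty region {lab}")
            Jbar = J.J[:, sel].mean(axis=1)
            loops.append(
                FlowVolumeLoop(
                    volume=Jbar,
                    flow=weighted_finite_difference(Jbar, timing),
                    phase=phase,
                    scope="region",
                    label=int(lab),
                )
            )
        if not loops:
            raise ValueError("mask has no labelled regions")
        return loops
    if scope == "voxel":
        if not voxels:
            raise ValueError("voxel scope requires explicit voxel indices")
        return [
            FlowVolumeLoop(
                volume=J.J[(slice(None),) + tuple(v)],
                flow=flow.Q[(slice(None),) + tuple(v)],
                phase=phase,
                scope="voxel",
                label=tuple(v),
            )
            for v in voxels
        ]
    raise ValueError(f"unknown scope {scope!r}")


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def _shoelace(x: np.ndarray, y: np.ndarray) -> float:
    """Signed area of the closed polygon (positive = counterclockwise)."""
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def voxel_trajectories(
    u: DisplacementField4D,
    sample: list[tuple[int, int, int]],
    timing: BinTiming | None = None,
    area_tol_mm2: float = 1e-9,
) -> list[Trajectory]:
    """Closed material trajectories r = R + u(R, t_n) at sampled voxels.

    Enclosed areas per anatomical projection are computed with the shoelace
    formula on the ordered (closed) polygon; orientation (counterclockwise /
    clockwise in the projection's (first, second)-axis frame) is defined only
    when the area exceeds ``area_tol_mm2``.
    """
    phase = (
        timing.phase
        if timing is not None
        else np.array(["?"] * u.n_bins, dtype=object)
    )
    spacing = np.asarray(u.grid.spacing)
    origin = np.asarray(u.grid.origin)
    out = []
    for idx in sample:
        idx = tuple(int(i) for i in idx)
        R = origin + spacing * np.asarray(idx)
        pos = R[None, :] + u.u[(slice(None),) + idx]
        areas, orientations = {}, {}
        for name, (a, b) in PROJECTIONS.items():
            s = _shoelace(pos[:, a], pos[:, b])
            areas[name] = abs(s)
            orientations[name] = (
                None if abs(s) <= area_tol_mm2 else ("ccw" if s > 0 else "cw")
            )
        out.append(
            Trajectory(
                index=idx,
                positions=pos,
                phase=phase,
                areas=areas,
                orientations=orientations,
            )
        )
    return out


# ---------------------------------------------------------------------------
# LTV / LEV1
# ---------------------------------------------------------------------------

def spiro_metrics(
    J: JacobianField,
    timing: BinTiming,
    mask: LungMask | None = None,
) -> SpiroMetrics:
    """Local tidal volume and first-second expiratory volume maps.

    LTV = dV0 * (max_n J_n - min_n J_n). LEV1 = dV0 * (J(t_pk) - J(t_pk + 1 s))
    with J(t) linearly interpolated on the wrapped time axis and t_pk the bin
    time of the per-voxel J maximum — the start of local expiration. For
    cycles shorter than 1 s LEV1 is undefined (NaN, ``lev1_defined=False``).
    """
    dv0 = J.grid.voxel_volume_mm3
    ltv = dv0 * (J.J.max(axis=0) - J.J.min(axis=0))

    if timing.period_s < 1.0:
        lev1 = np.full(J.J.shape[1:], np.nan)
        return SpiroMetrics(LTV=ltv, LEV1=lev1, lev1_defined=False)

    t = timing.times
    n = timing.n_bins
    k_peak = np.argmax(J.J, axis=0)
    t_peak = t[k_peak]
    t_query = t_peak + 1.0

    # wrapped linear interpolation: extend one period each way
    t_ext = np.concatenate([t, t + timing.period_s])
    flat_J = J.J.reshape(n, -1)
    J_ext = np.concatenate([flat_J, flat_J], axis=0)
    tq = np.mod(t_query, timing.period_s).ravel()
    # shift queries into the covered span [t_0, t_0 + period)
    tq = np.where(tq < t_ext[0], tq + timing.period_s, tq)
    pos = np.searchsorted(t_ext, tq, side="right") - 1
    pos = np.clip(pos, 0, 2 * n - 2)
    cols = np.arange(flat_J.shape[1])
    t0, t1 = t_ext[pos], t_ext[pos + 1]
    J0 = J_ext[pos, cols]
    J1 = J_ext[pos + 1, cols]
    frac = np.where(t1 > t0, (tq - t0) / np.where(t1 > t0, t1 - t0, 1.0), 0.0)
    J_at = (J0 + frac * (J1 - J0)).reshape(J.J.shape[1:])
    J_pk = np.take_along_axis(J.J, k_peak[None], axis=0)[0]
    lev1 = dv0 * (J_pk - J_at)
    return SpiroMetrics(LTV=ltv, LEV1=lev1, lev1_defined=True)
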