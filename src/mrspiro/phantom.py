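"""Synthetic 4D breathing-thorax phantom with analytically known kinematics.

The phantom deforms a simple thorax (torso shell, two ellipsoidal lungs with
bright vessel-like landmarks) with a smooth, periodic, hysteretic displacement
field built from two spatial modes:

* a **diaphragm mode** along the superior-inferior (SI, x) axis whose
  amplitude grows toward the lung base,
* a **chest mode** along the anterior-posterior (AP, z) axis, split into a
  volumetric part (AP stretching, in phase with the diaphragm drive) and a
  chest-wall translation part that *lags* the diaphragm drive by
  ``hysteresis_phase``.

The lag makes every tissue trajectory a closed loop with nonzero enclosed
area (respiratory hysteresis), while the local volume change remains driven
by a single temporal phase so that the Jacobian rises monotonically through
inspiration and falls through expiration at every voxel — the behaviour
reported for free-breathing human lungs. Because the lagged chest-wall mode
depends only on x and displaces along z, it contributes no volume change:
``J`` stays in closed form.

All truth quantities (F, J, Green-Lagrange strain, principal stretches, FA,
per-bin lung volume) are evaluated from the closed-form deformation gradient,
independent of the finite-difference pipeline under test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .grid_io import BinTiming, DisplacementField4D, ImageGrid, LungMask, VolumeSeries
from .selfgating import SpokeStream

BREATHING_MODES = ("normal", "thoracic", "diaphragmatic")

#: default (SI, AP) displacement amplitudes in mm for each breathing pattern;
#: quiet-breathing basal diaphragm excursion is O(10-15 mm), chest-wall AP
#: excursion a few mm, with the ratio flipped for thoracic breathing
MODE_AMPLITUDES_MM = {
    "normal": (13.0, 5.0),
    "thoracic": (3.0, 12.0),
    "diaphragmatic": (18.0, 2.0),
}

# fraction of the AP mode carried by the lagged chest-wall translation
WALL_FRACTION = 0.5
# residual SI motion at the lung apex relative to the base (whole-lung descent)
APEX_FLOOR = 0.2

# lung ellipsoids, as fractions of the grid extent
_LUNG_CENTERS = ((0.5, 0.30, 0.5), (0.5, 0.70, 0.5))
_LUNG_SEMIAXES = (0.33, 0.155, 0.27)
_TORSO_SEMIAXES = (0.49, 0.44, 0.42)

INTENSITY = {"background": 0.0, "torso": 0.8, "lung": 0.15, "vessel": 1.0}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic breathing thorax.

    ``hysteresis_phase`` is the lag (radians, stored in [0, 2pi)) of the
    chest-wall drive behind the diaphragm drive; ``gradient_si`` is the
    dimensionless linear increase of SI amplitude toward the lung base.
    """

    grid: ImageGrid = field(
        default_factory=lambda: ImageGrid((48, 48, 48), (4.0, 4.0, 4.0))
    )
    n_bins: int = 32
    breathing_mode: str = "normal"
    amplitude_si: float = 13.0
    amplitude_ap: float = 5.0
    hysteresis_phase: float = 0.15
    period_s: float = 4.0
    gradient_si: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.breathing_mode not in BREATHING_MODES:
            raise ValueError(f"unknown breathing_mode {self.breathing_mode!r}")
        if self.amplitude_si < 0 or self.amplitude_ap < 0:
            raise ValueError("amplitudes must be non-negative")
        object.__setattr__(
            self, "hysteresis_phase", float(np.mod(self.hysteresis_phase, 2 * np.pi))
        )
        if self.n_bins < 4 or self.n_bins % 2:
            raise ValueError("n_bins must be even and >= 4")
        if self.period_s <= 0:
            raise ValueError("period must be positive")
        if min(self.grid.shape) < 12:
            raise ValueError(
                f"grid {self.grid.shape} too small to contain the lung ellipsoids "
                "(need >= 12 voxels per axis)"
            )

    @classmethod
    def preset(cls, breathing_mode: str, **overrides) -> "PhantomSpec":
        """Spec with the amplitude ratio fixed by the breathing pattern."""
        if breathing_mode not in MODE_AMPLITUDES_MM:
            raise ValueError(f"unknown breathing_mode {breathing_mode!r}")
        a_si, a_ap = MODE_AMPLITUDES_MM[breathing_mode]
        params = dict(
            breathing_mode=breathing_mode, amplitude_si=a_si, amplitude_ap=a_ap
        )
        params.update(overrides)
        return cls(**params)


@dataclass
class PhantomTruth:
    """Analytic ground truth attached to one phantom realization."""

    u_true: DisplacementField4D
    J_true: np.ndarray          # (n_bins, nx, ny, nz)
    strain_true: np.ndarray     # (n_bins, nx, ny, nz, 3, 3)
    FA_true: np.ndarray         # (n_bins, nx, ny, nz)
    lambda_true: np.ndarray     # (n_bins, nx, ny, nz, 3), descending
    V_true: np.ndarray          # (n_bins,) lung volume in mm^3
    mask: LungMask
    timing: BinTiming


# ---------------------------------------------------------------------------
# analytic building blocks
# ---------------------------------------------------------------------------

def _normalized_coords(grid: ImageGrid):
    X, Y, Z = grid.coordinates()
    Lx, Ly, Lz = grid.extent_mm
    ox, oy, oz = grid.origin
    return (X - ox) / Lx, (Y - oy) / Ly, (Z - oz) / Lz, (Lx, Ly, Lz)


def _g_si(xh: np.ndarray, gamma: float) -> np.ndarray:
    """SI diaphragm-mode profile: apex floor + smooth growth toward the base."""
    base = APEX_FLOOR + (1 - APEX_FLOOR) * np.sin(np.pi * xh / 2) ** 2
    return base * (1 + gamma * xh) / (1 + gamma)


def _g_si_prime(xh: np.ndarray, gamma: float) -> np.ndarray:
    """d/d(xh) of :func:`_g_si`."""
    s2 = np.sin(np.pi * xh / 2) ** 2
    base = APEX_FLOOR + (1 - APEX_FLOOR) * s2
    dbase = (1 - APEX_FLOOR) * (np.pi / 2) * np.sin(np.pi * xh)
    return (dbase * (1 + gamma * xh) + gamma * base) / (1 + gamma)


def _h_ap(zh: np.ndarray) -> np.ndarray:
    """AP volumetric chest-mode profile (stretch toward the posterior wall)."""
    return np.sin(np.pi * zh / 2) ** 2


def _h_ap_prime(zh: np.ndarray) -> np.ndarray:
    return (np.pi / 2) * np.sin(np.pi * zh)


def _c_wall(xh: np.ndarray) -> np.ndarray:
    """Chest-wall translation profile along SI (volume preserving)."""
    return np.sin(np.pi * xh)


def _c_wall_prime(xh: np.ndarray) -> np.ndarray:
    return np.pi * np.cos(np.pi * xh)


def _drives(spec: PhantomSpec, t) -> tuple[np.ndarray, np.ndarray]:
    """In-phase drive s(t) in [0,1] and the re-based lagged drive.

    s = 0 at t = 0 (end-expiration, minimal volume); the lagged drive is
    shifted so that it also vanishes at t = 0, which pins u == 0 at the
    reference bin without affecting any other property.
    """
    theta = 2 * np.pi * np.asarray(t, dtype=float) / spec.period_s
    s = 0.5 * (1 - np.cos(theta))
    phi = spec.hysteresis_phase
    s_lag = 0.5 * (np.cos(phi) - np.cos(theta - phi))
    return s, s_lag


def evaluate_displacement(
    spec: PhantomSpec, X: np.ndarray, Y: np.ndarray, Z: np.ndarray, t: float
) -> np.ndarray:
    """Closed-form u(R, t) (mm) at arbitrary world points; shape (..., 3)."""
    Lx, Ly, Lz = spec.grid.extent_mm
    ox, oy, oz = spec.grid.origin
    xh = (np.asarray(X, float) - ox) / Lx
    zh = (np.asarray(Z, float) - oz) / Lz
    s, s_lag = _drives(spec, t)
    u = np.zeros(np.broadcast(X, Y, Z).shape + (3,))
    u[..., 0] = spec.amplitude_si * s * _g_si(xh, spec.gradient_si)
    u[..., 2] = spec.amplitude_ap * (
        (1 - WALL_FRACTION) * s * _h_ap(zh) + WALL_FRACTION * s_lag * _c_wall(xh)
    )
    return u


def _gradient_entries(spec: PhantomSpec, t: float):
    """Nonzero entries (F00, F20, F22) of the closed-form deformation gradient."""
    xh, yh, zh, (Lx, Ly, Lz) = _normalized_coords(spec.grid)
    s, s_lag = _drives(spec, t)
    F00 = 1 + spec.amplitude_si * s * _g_si_prime(xh, spec.gradient_si) / Lx
    F22 = 1 + spec.amplitude_ap * (1 - WALL_FRACTION) * s * _h_ap_prime(zh) / Lz
    F20 = spec.amplitude_ap * WALL_FRACTION * s_lag * _c_wall_prime(xh) / Lx
    return F00, F20, F22


def bin_times(spec: PhantomSpec) -> BinTiming:
    """Equally spaced bin time-stamps with bin 0 at end-expiration (t = 0)."""
    n = spec.n_bins
    times = np.arange(n) * spec.period_s / n
    phase = np.array(
        ["exp"] + ["insp"] * (n // 2) + ["exp"] * (n // 2 - 1), dtype=object
    )
    return BinTiming(times=times, phase=phase, period_s=spec.period_s)


def lung_mask(spec: PhantomSpec) -> LungMask:
    """Reference-frame (end-expiration) lung membership, left/right labelled."""
    xh, yh, zh, _ = _normalized_coords(spec.grid)
    labels = np.zeros(spec.grid.shape, dtype=np.int8)
    for lab, (cx, cy, cz) in enumerate(_LUNG_CENTERS, start=1):
        ax, ay, az = _LUNG_SEMIAXES
        inside = (
            ((xh - cx) / ax) ** 2 + ((yh - cy) / ay) ** 2 + ((zh - cz) / az) ** 2
        ) <= 1.0
        labels[inside] = lab
    return LungMask(grid=spec.grid, membership=labels > 0, labels=labels)


# ---------------------------------------------------------------------------
# main generators
# ---------------------------------------------------------------------------

def make_displacement(spec: PhantomSpec) -> tuple[DisplacementField4D, PhantomTruth]:
    """Generate the analytic displacement field and its exact ground truth.

    The reference bin (index 0) is the minimum-volume, zero-displacement
    state; all truth fields derive from the closed-form deformation gradient.
    Principal stretches are obtained in closed form from the 2x2 sagittal
    block of F^T F (the left-right direction is an exact unit eigendirection).
    """
    timing = bin_times(spec)
    mask = lung_mask(spec)
    shape = spec.grid.shape
    n = spec.n_bins
    X, Y, Z = spec.grid.coordinates()

    u = np.empty((n,) + shape + (3,))
    J = np.empty((n,) + shape)
    strain = np.zeros((n,) + shape + (3, 3))
    lam = np.empty((n,) + shape + (3,))
    for k, t in enumerate(timing.times):
        u[k] = evaluate_displacement(spec, X, Y, Z, t)
        F00, F20, F22 = _gradient_entries(spec, t)
        J[k] = F00 * F22
        # C = F^T F for F = [[F00,0,0],[0,1,0],[F20,0,F22]]
        Cxx = F00**2 + F20**2
        Czz = F22**2
        Cxz = F20 * F22
        strain[k, ..., 0, 0] = 0.5 * (Cxx - 1)
        strain[k, ..., 2, 2] = 0.5 * (Czz - 1)
        strain[k, ..., 0, 2] = 0.5 * Cxz
        strain[k, ..., 2, 0] = 0.5 * Cxz
        # eigenvalues of C: {1} and the 2x2 block in the (x, z) plane
        tr2 = Cxx + Czz
        disc = np.sqrt(np.maximum((Cxx - Czz) ** 2 + 4 * Cxz**2, 0.0))
        lam2_hi = 0.5 * (tr2 + disc)
        lam2_lo = 0.5 * (tr2 - disc)
        lam[k] = np.sort(
            np.sqrt(np.stack([lam2_hi, np.ones_like(tr2), lam2_lo], axis=-1)),
            axis=-1,
        )[..., ::-1]
    u[0] = 0.0  # exact zero at the reference bin

    num = (
        (lam[..., 0] - lam[..., 1]) ** 2
        + (lam[..., 1] - lam[..., 2]) ** 2
        + (lam[..., 0] - lam[..., 2]) ** 2
    )
    den = 2 * np.sum(lam**2, axis=-1)
    FA = np.sqrt(num / den)

    m = mask.membership
    V_true = J[:, m].mean(axis=1) * mask.n_voxels * spec.grid.voxel_volume_mm3

    field4d = DisplacementField4D(grid=spec.grid, u=u, reference_bin=0)
    truth = PhantomTruth(
        u_true=field4d,
        J_true=J,
        strain_true=strain,
        FA_true=FA,
        lambda_true=lam,
        V_true=V_true,
        mask=mask,
        timing=timing,
    )
    return field4d, truth


def _reference_intensity(spec: PhantomSpec, X, Y, Z, landmarks) -> np.ndarray:
    """Intensity of the undeformed anatomy at arbitrary world points."""
    Lx, Ly, Lz = spec.grid.extent_mm
    ox, oy, oz = spec.grid.origin
    xh, yh, zh = (X - ox) / Lx, (Y - oy) / Ly, (Z - oz) / Lz
    img = np.full(np.broadcast(X, Y, Z).shape, INTENSITY["background"])
    tx, ty, tz = _TORSO_SEMIAXES
    torso = (
        ((xh - 0.5) / tx) ** 2 + ((yh - 0.5) / ty) ** 2 + ((zh - 0.5) / tz) ** 2
    ) <= 1.0
    img[torso] = INTENSITY["torso"]
    for cx, cy, cz in _LUNG_CENTERS:
        ax, ay, az = _LUNG_SEMIAXES
        inside = (
            ((xh - cx) / ax) ** 2 + ((yh - cy) / ay) ** 2 + ((zh - cz) / az) ** 2
        ) <= 1.0
        img[inside] = INTENSITY["lung"]
    for (px, py, pz), r in landmarks:
        d2 = (X - px) ** 2 + (Y - py) ** 2 + (Z - pz) ** 2
        img[d2 <= r**2] = INTENSITY["vessel"]
    return img


def vessel_landmarks(
    spec: PhantomSpec, n_landmarks: int = 24, radius_mm: float = 6.0
) -> list[tuple[tuple[float, float, float], float]]:
    """Seeded vessel-like bright spheres inside the lungs (world coords, mm)."""
    rng = np.random.default_rng(spec.seed)
    Lx, Ly, Lz = spec.grid.extent_mm
    ox, oy, oz = spec.grid.origin
    marks = []
    while len(marks) < n_landmarks:
        cx, cy, cz = _LUNG_CENTERS[rng.integers(len(_LUNG_CENTERS))]
        ax, ay, az = _LUNG_SEMIAXES
        p = rng.uniform(-0.75, 0.75, size=3)  # stay inside the ellipsoid
        if np.sum(p**2) > 1:
            continue
        world = (
            ox + (cx + p[0] * ax) * Lx,
            oy + (cy + p[1] * ay) * Ly,
            oz + (cz + p[2] * az) * Lz,
        )
        marks.append((world, radius_mm))
    return marks


def render_volumes(
    spec: PhantomSpec,
    field: DisplacementField4D,
    n_landmarks: int = 24,
    landmark_radius_mm: float = 6.0,
) -> VolumeSeries:
    """Render intensity volumes warped per bin by the phantom deformation.

    Each bin image is sampled exactly: for every deformed grid point x the
    material (reference) point R with x = R + u(R, t) is found by fixed-point
    iteration on the closed-form displacement, and the reference anatomy is
    evaluated at R. Deterministic given ``spec.seed`` (landmark placement).
    """
    timing = bin_times(spec)
    landmarks = vessel_landmarks(spec, n_landmarks, landmark_radius_mm)
    X, Y, Z = spec.grid.coordinates()
    vols = np.empty((spec.n_bins,) + spec.grid.shape)
    for k, t in enumerate(timing.times):
        Rx, Ry, Rz = X.copy(), Y.copy(), Z.copy()
        for _ in range(30):
            u = evaluate_displacement(spec, Rx, Ry, Rz, t)
            Rx_new, Ry_new, Rz_new = X - u[..., 0], Y - u[..., 1], Z - u[..., 2]
            delta = max(
                np.max(np.abs(Rx_new - Rx)),
                np.max(np.abs(Ry_new - Ry)),
                np.max(np.abs(Rz_new - Rz)),
            )
            Rx, Ry, Rz = Rx_new, Ry_new, Rz_new
            if delta < 1e-3:
                break
        vols[k] = _reference_intensity(spec, Rx, Ry, Rz, landmarks)
    return VolumeSeries(grid=spec.grid, data=vols, reference_bin=field.reference_bin)


# ---------------------------------------------------------------------------
# synthetic self-gating spoke stream
# ---------------------------------------------------------------------------

def make_spoke_stream(
    spec: PhantomSpec,
    n_channels: int = 30,
    spokes_per_period: int = 2000,
    n_periods: int = 20,
    noise_sd: float = 0.0,
    outlier_periods: tuple[int, ...] = (),
    outlier_amplitude_factor: float = 3.0,
    outlier_duration_factor: float = 1.0,
) -> tuple[SpokeStream, dict]:
    """Complex per-spoke DC samples embedding the phantom's volume waveform.

    Each receive channel sees a complex gain and offset applied to one shared
    respiratory waveform (the lung-volume drive ``s(t)``), plus white complex
    Gaussian noise of standard deviation ``noise_sd`` times the per-channel
    signal range — a rank-1 mixture, as for the DC (k-space centre) sample of
    every spoke across a coil array. ``outlier_periods`` get their amplitude
    and/or duration scaled, emulating sighs or irregular breaths.

    Returns the stream and a ground-truth dict with the waveform, per-period
    trough times/durations/amplitudes and outlier flags. The default spoke
    spacing is ``period_s / spokes_per_period`` (2 ms for the default 4 s
    period), matching a short-TR radial acquisition.
    """
    if n_channels < 2:
        raise ValueError("need at least 2 channels")
    rng = np.random.default_rng(spec.seed)
    tr = spec.period_s / spokes_per_period

    amp = np.ones(n_periods)
    dur = np.full(n_periods, spec.period_s)
    for p in outlier_periods:
        amp[p] *= outlier_amplitude_factor
        dur[p] *= outlier_duration_factor

    times, wave, trough_times, spans = [], [], [], []
    t0 = 0.0
    for p in range(n_periods):
        n_sp = max(int(round(dur[p] / tr)), 8)
        tau = np.arange(n_sp) * tr
        times.append(t0 + tau)
        wave.append(amp[p] * 0.5 * (1 - np.cos(2 * np.pi * tau / dur[p])))
        trough_times.append(t0)
        spans.append((t0, t0 + n_sp * tr))
        t0 += n_sp * tr
    times = np.concatenate(times)
    wave = np.concatenate(wave)

    gains = rng.uniform(0.5, 1.5, n_channels) * np.exp(
        1j * rng.uniform(0, 2 * np.pi, n_channels)
    )
    offsets = rng.normal(0, 1, n_channels) + 1j * rng.normal(0, 1, n_channels)
    dc = offsets[None, :] + gains[None, :] * wave[:, None]
    if noise_sd > 0:
        scale = noise_sd * np.abs(gains) * (wave.max() - wave.min())
        noise = rng.normal(0, 1, dc.shape) + 1j * rng.normal(0, 1, dc.shape)
        dc = dc + scale[None, :] * noise / np.sqrt(2)

    stream = SpokeStream(times=times, dc=dc)
    truth = {
        "waveform": wave,
        "trough_times": np.array(trough_times),
        "period_spans": np.array(spans),
        "durations": dur,
        "amplitudes": amp,
        "outlier_periods": np.array(sorted(outlier_periods), dtype=int),
        "tr": tr,
    }
    return stream, truth
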