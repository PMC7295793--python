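"""Respiratory self-gating from per-spoke k-space centre (DC) samples.

A radial UTE acquisition samples the k-space centre at the start of every
spoke on every receive channel. Across channels these complex DC samples are,
to first order, a fixed mixture of one respiratory waveform plus noise, so the
first principal component of the (real, imaginary) channel time series is a
respiratory surrogate ("self-navigator"). This module extracts that
navigator, segments it into respiratory periods, discards outlying periods,
slices each period into amplitude-defined motion bins (split into inspiration
and expiration branches), computes view-sharing membership and soft-gating
weights, and time-stamps every bin relative to end-expiration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy import signal as sps

from .grid_io import BinTiming


@dataclass
class SpokeStream:
    """Per-spoke acquisition times (s) and complex DC samples per channel."""

    times: np.ndarray           # (n_spokes,), strictly increasing
    dc: np.ndarray              # (n_spokes, n_channels), complex

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.dc = np.asarray(self.dc, dtype=complex)
        if self.times.ndim != 1 or self.dc.ndim != 2:
            raise ValueError("times must be 1D and dc 2D (spokes x channels)")
        if self.dc.shape[0] != self.times.size:
            raise ValueError("times and dc disagree on the number of spokes")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("spoke times must be strictly increasing")

    @property
    def n_spokes(self) -> int:
        return self.times.size

    @property
    def n_channels(self) -> int:
        return self.dc.shape[1]

    @property
    def sampling_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.times)))


@dataclass
class NavigatorSignal:
    """Scalar respiratory surrogate, one sample per spoke.

    ``sign_convention`` documents the intended orientation (larger value =
    larger inflation); for symmetric waveforms the PCA sign is intrinsically
    ambiguous and is left as extracted.
    """

    times: np.ndarray
    value: np.ndarray
    sign_convention: str = "inflation-positive"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.value = np.asarray(self.value, float)
        if self.times.shape != self.value.shape:
            raise ValueError("times and value must have equal length")

    @property
    def sampling_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.times)))


@dataclass
class RespiratoryPeriod:
    """One trough-to-trough breath of the navigator."""

    start_idx: int
    peak_idx: int
    end_idx: int
    trough_time: float
    peak_time: float
    amplitude: float
    duration: float


@dataclass
class PeriodSet:
    periods: list[RespiratoryPeriod]
    spoke_period: np.ndarray    # per-spoke period index, -1 = unassigned

    def __len__(self) -> int:
        return len(self.periods)


@dataclass
class BinAssignment:
    """Spoke-to-bin membership with soft-gating weights.

    ``primary_bin`` is -1 for discarded spokes (weight 0). ``members`` lists,
    per bin, the spoke indices and weights including view-shared spokes.
    ``phase`` holds "insp" for the first n_bins/2 bins and "exp" for the rest;
    inspiration bins run trough -> peak in rising navigator amplitude,
    expiration bins peak -> trough in falling amplitude (cycle order).
    """

    n_bins: int
    primary_bin: np.ndarray
    weight: np.ndarray
    members: list[tuple[np.ndarray, np.ndarray]]
    phase: np.ndarray
    empty_bins: list[int] = field(default_factory=list)


# ---------------------------------------------------------------------------
# navigator extraction
# ---------------------------------------------------------------------------

def extract_navigator(
    stream: SpokeStream, lowpass_hz: float = 0.8
) -> NavigatorSignal:
    """First principal component of the detrended, standardized DC series.

    Real and imaginary parts of every channel enter as separate columns, so
    the result is invariant to per-channel complex gains (scaling and global
    phase rotation) up to sign. The component is low-pass filtered to the
    respiratory band (zero-phase Butterworth, cutoff ``lowpass_hz``). The sign
    is oriented by the waveform's skewness when decisive (inflation peaks are
    brief relative to the expiratory plateau in real breathing); symmetric
    waveforms keep the extracted sign.
    """
    X = np.concatenate([stream.dc.real, stream.dc.imag], axis=1)
    X = sps.detrend(X, axis=0, type="linear")
    std = X.std(axis=0)
    scale_floor = 1e-12 * max(std.max(), 1.0)
    keep = std > scale_floor
    if not keep.any():
        raise ValueError("no respiratory component: DC stream is constant")
    X = X[:, keep] / std[keep]

    # first left singular vector = PC1 scores
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    if s[0] <= scale_floor:
        raise ValueError("no respiratory component: DC stream is degenerate")
    nav = u[:, 0] * s[0]

    fs = stream.sampling_rate
    if 0 < lowpass_hz < 0.5 * fs:
        b, a = sps.butter(4, lowpass_hz / (0.5 * fs), btype="low")
        padlen = min(3 * max(len(a), len(b)), nav.size - 1)
        nav = sps.filtfilt(b, a, nav, padlen=padlen)

    centred = nav - np.median(nav)
    skew = np.mean(centred**3) / max(np.mean(centred**2) ** 1.5, 1e-30)
    if abs(skew) > 0.05:
        nav = nav * np.sign(skew)
    return NavigatorSignal(times=stream.times.copy(), value=nav)


# ---------------------------------------------------------------------------
# period detection and outlier rejection
# ---------------------------------------------------------------------------

def detect_periods(
    nav: NavigatorSignal,
    min_period_s: float = 1.5,
    prominence_frac: float = 0.5,
    apnea_min_s: float = 1.0,
    apnea_level_frac: float = 0.05,
) -> PeriodSet:
    """Segment the navigator into trough-to-trough respiratory periods.

    Peaks are detected with a robust prominence threshold
    (``prominence_frac`` of the navigator's 10-90 percentile range); each
    period spans the amplitude minima between consecutive peaks, carrying its
    end-expiration trough time, peak time, amplitude and duration. Flat
    (apneic) stretches — samples lingering within ``apnea_level_frac`` of the
    period amplitude above the trough for longer than ``apnea_min_s`` — are
    assigned to no period.
    """
    v = nav.value
    fs = nav.sampling_rate
    q10, q90 = np.percentile(v, [10, 90])
    prom = prominence_frac * max(q90 - q10, 1e-30)
    distance = max(int(min_period_s * fs), 1)
    peaks, _ = sps.find_peaks(v, prominence=prom, distance=distance)
    if peaks.size < 4:
        raise ValueError(
            f"navigator spans fewer than 3 respiratory periods "
            f"({max(peaks.size - 1, 0)} detected)"
        )

    spoke_period = np.full(v.size, -1, dtype=int)
    periods: list[RespiratoryPeriod] = []
    # troughs between consecutive peaks bound full periods
    troughs = [
        int(peaks[i] + np.argmin(v[peaks[i]: peaks[i + 1] + 1]))
        for i in range(peaks.size - 1)
    ]
    for k in range(len(troughs) - 1):
        i0, i1 = troughs[k], troughs[k + 1]
        seg = v[i0: i1 + 1]
        pk = i0 + int(np.argmax(seg))
        amp = float(v[pk] - seg.min())
        periods.append(
            RespiratoryPeriod(
                start_idx=i0,
                peak_idx=pk,
                end_idx=i1,
                trough_time=float(nav.times[i0]),
                peak_time=float(nav.times[pk]),
                amplitude=amp,
                duration=float(nav.times[i1] - nav.times[i0]),
            )
        )
        member = np.arange(i0, i1)
        low = v[member] <= seg.min() + apnea_level_frac * amp
        member_keep = member[_trim_long_runs(low, int(apnea_min_s * fs))]
        spoke_period[member_keep] = len(periods) - 1
    if len(periods) < 3:
        raise ValueError("fewer than 3 respiratory periods detected")
    return PeriodSet(periods=periods, spoke_period=spoke_period)


def _trim_long_runs(flag: np.ndarray, max_run: int) -> np.ndarray:
    """Boolean keep-mask that drops runs of True in ``flag`` longer than max_run."""
    keep = np.ones(flag.size, dtype=bool)
    if max_run <= 0:
        return keep
    i = 0
    while i < flag.size:
        if flag[i]:
            j = i
            while j < flag.size and flag[j]:
                j += 1
            if j - i > max_run:
                keep[i:j] = False
            i = j
        else:
            i += 1
    return keep


def reject_outlier_periods(
    periodset: PeriodSet, k_mad: float = 3.0, scale_floor_frac: float = 0.02
) -> tuple[PeriodSet, pd.DataFrame]:
    """Discard periods whose amplitude or duration is a robust outlier.

    A period is rejected when either quantity deviates from the median by more
    than ``k_mad`` robust standard deviations (1.4826 x MAD). The robust scale
    is floored at ``scale_floor_frac`` of the median: breath-to-breath
    variation of a few percent is physiological, and an almost-degenerate MAD
    (as on very regular breathing) must not flag sub-percent deviations.
    Returns the kept set (spoke membership of rejected periods cleared) and a
    per-period log.
    """
    if len(periodset) < 3:
        raise ValueError("need at least 3 periods for outlier statistics")
    amp = np.array([p.amplitude for p in periodset.periods])
    dur = np.array([p.duration for p in periodset.periods])

    def _is_outlier(x: np.ndarray) -> np.ndarray:
        med = np.median(x)
        sigma = max(1.4826 * np.median(np.abs(x - med)),
                    scale_floor_frac * abs(med))
        with np.errstate(invalid="ignore"):
            return np.abs(x - med) > k_mad * sigma

    rej = _is_outlier(amp) | _is_outlier(dur)
    log = pd.DataFrame(
        {
            "period": np.arange(len(periodset)),
            "amplitude": amp,
            "duration_s": dur,
            "rejected": rej,
        }
    )
    if rej.all():
        raise ValueError(
            "all respiratory periods rejected as outliers; increase k_mad"
        )
    kept_ids = np.flatnonzero(~rej)
    remap = {old: new for new, old in enumerate(kept_ids)}
    spoke_period = periodset.spoke_period.copy()
    spoke_period = np.array(
        [remap.get(p, -1) for p in spoke_period], dtype=int
    )
    kept = PeriodSet(
        periods=[periodset.periods[i] for i in kept_ids],
        spoke_period=spoke_period,
    )
    return kept, log


# ---------------------------------------------------------------------------
# binning, soft-gating, time-stamping
# ---------------------------------------------------------------------------

def assign_bins(
    nav: NavigatorSignal,
    periodset: PeriodSet,
    n_bins: int = 32,
    sharing_fraction: float = 0.5,
    softgate_sigma: float | None = None,
) -> BinAssignment:
    """Slice each period into amplitude-defined inspiration/expiration bins.

    Within each kept period, the navigator amplitude is normalized to [0, 1]
    between that period's trough and peak. Rising-branch spokes fill the
    n_bins/2 inspiration bins, falling-branch spokes the n_bins/2 expiration
    bins, by equal-amplitude slicing (bin widths 2/n_bins in normalized
    amplitude). View sharing additionally admits a spoke into an adjacent bin
    of the same branch when its amplitude lies within ``sharing_fraction``
    bin widths of that bin's slice. Soft-gating weights are
    ``exp(-d^2 / (2 sigma^2))`` with ``d`` the normalized-amplitude distance
    to the bin centre; ``softgate_sigma`` defaults to half a bin width, and
    ``0`` means hard unit weights.
    """
    if n_bins % 2 or n_bins < 4:
        raise ValueError("n_bins must be even and >= 4")
    half = n_bins // 2
    width = 1.0 / half
    if softgate_sigma is None:
        softgate_sigma = width / 2

    v = nav.value
    n_spokes = v.size
    primary = np.full(n_spokes, -1, dtype=int)
    primary_w = np.zeros(n_spokes)
    member_idx: list[list[int]] = [[] for _ in range(n_bins)]
    member_w: list[list[float]] = [[] for _ in range(n_bins)]

    def _weight(a: np.ndarray, b: int) -> np.ndarray:
        if softgate_sigma == 0:
            return np.ones_like(a)
        center = _bin_center(b, half)
        d = a - center
        return np.exp(-(d**2) / (2 * softgate_sigma**2))

    for p_idx, period in enumerate(periodset.periods):
        spokes = np.flatnonzero(periodset.spoke_period == p_idx)
        if spokes.size == 0:
            continue
        rising = spokes[spokes <= period.peak_idx]
        falling = spokes[spokes > period.peak_idx]
        for branch, idxs in (("insp", rising), ("exp", falling)):
            if idxs.size == 0:
                continue
            trough_val = v[period.start_idx if branch == "insp" else period.end_idx]
            span = v[period.peak_idx] - trough_val
            if span <= 0:
                continue
            a = np.clip((v[idxs] - trough_val) / span, 0.0, 1.0)
            slot = np.minimum((a / width).astype(int), half - 1)
            bins = slot if branch == "insp" else n_bins - 1 - slot
            primary[idxs] = bins
            for b in range(n_bins):
                if (branch == "insp") != (b < half):
                    continue
                s_lo, s_hi = _bin_slice(b, half)
                lo = s_lo - sharing_fraction * width
                hi = s_hi + sharing_fraction * width
                in_b = (a >= lo) & (a < hi) if b not in (half - 1, half) else (
                    (a >= lo) & (a <= hi)
                )
                if not in_b.any():
                    continue
                w = _weight(a[in_b], b)
                member_idx[b].extend(idxs[in_b].tolist())
                member_w[b].extend(w.tolist())

    # primary weight = the spoke's soft-gating weight in its own bin
    for b in range(n_bins):
        idxs = np.asarray(member_idx[b], dtype=int)
        ws = np.asarray(member_w[b], dtype=float)
        own = primary[idxs] == b
        primary_w[idxs[own]] = ws[own]

    phase = np.array(["insp"] * half + ["exp"] * half, dtype=object)
    members = [
        (np.asarray(member_idx[b], dtype=int), np.asarray(member_w[b], dtype=float))
        for b in range(n_bins)
    ]
    empty = [b for b in range(n_bins) if members[b][0].size == 0]
    return BinAssignment(
        n_bins=n_bins,
        primary_bin=primary,
        weight=primary_w,
        members=members,
        phase=phase,
        empty_bins=empty,
    )


def _bin_slice(b: int, half: int) -> tuple[float, float]:
    """Normalized-amplitude slice [lo, hi) of bin b in cycle order."""
    width = 1.0 / half
    if b < half:  # inspiration, rising amplitude
        return b * width, (b + 1) * width
    j = b - half  # expiration, falling amplitude
    return (half - 1 - j) * width, (half - j) * width


def _bin_center(b: int, half: int) -> float:
    lo, hi = _bin_slice(b, half)
    return 0.5 * (lo + hi)


def timestamp_bins(
    assignment: BinAssignment,
    periodset: PeriodSet,
    stream: SpokeStream,
) -> BinTiming:
    """Time-stamp each bin relative to end-expiration.

    Every spoke's offset is its acquisition time minus its own period's
    end-expiration trough time; a bin's time-stamp is the unweighted mean of
    the offsets of its primary member spokes over the whole acquisition, so
    t = 0 corresponds to the end-expiration reference phase. Empty bins get a
    timestamp interpolated linearly from their neighbours and are flagged.
    """
    if len(periodset) < 1 or (periodset.spoke_period >= 0).sum() == 0:
        raise ValueError("assignment covers no kept period")
    trough = np.array([p.trough_time for p in periodset.periods])
    period_s = float(np.mean([p.duration for p in periodset.periods]))

    n = assignment.n_bins
    times = np.full(n, np.nan)
    for b in range(n):
        sel = assignment.primary_bin == b
        if not sel.any():
            continue
        offs = stream.times[sel] - trough[periodset.spoke_period[sel]]
        times[b] = float(np.mean(offs))

    missing = np.isnan(times)
    if missing.any():
        good = np.flatnonzero(~missing)
        if good.size < 2:
            raise ValueError("too few populated bins to interpolate timestamps")
        times[missing] = np.interp(np.flatnonzero(missing), good, times[good])
    times = np.clip(times, 0.0, np.nextafter(period_s, 0.0))
    return BinTiming(times=times, phase=assignment.phase.copy(), period_s=period_s)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_spoke_stream(stream: SpokeStream, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=stream.times)
        f.create_dataset("dc", data=stream.dc)


def read_spoke_stream(path: str | Path) -> SpokeStream:
    with h5py.File(path, "r") as f:
        return SpokeStream(times=f["times"][()], dc=f["dc"][()])


def write_assignment(assignment: BinAssignment, path: str | Path) -> None:
    pd.DataFrame(
        {
            "spoke": np.arange(assignment.primary_bin.size),
            "bin": assignment.primary_bin,
            "weight": assignment.weight,
        }
    ).to_csv(path, index=False)
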