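# Methods

## Scope and data model

`mrspiro` covers the analysis chain of free-breathing, motion-resolved lung
MRI *after* image reconstruction and deformable registration: it consumes
either per-bin Lagrangian displacement fields or generates them from its own
phantom, and produces regional ventilation (Jacobian), finite-strain and
anisotropy maps, regional gas flow and flow-volume loops, and LTV/LEV₁
metrics. Reconstruction (parallel imaging / compressed sensing) and the
registration algorithm itself are deliberately out of scope; the adapter in
`grid_io` defines the contract with external registration tools.

All grids are axis-aligned with anatomical axes fixed as
x = superior-inferior, y = left-right, z = anterior-posterior; world
coordinates in mm, indices 0-based, `world = origin + index · spacing`.
Displacement fields are stored in the **Lagrangian forward** convention —
`u(R, t_n)` displaces the tissue element whose end-expiration position is
`R` — because the deformation gradient differentiates the deformed position
with respect to reference coordinates. Registration packages that produce
backward maps are converted at import by fixed-point inversion
(`u(R) = −w(R + u(R))`, trilinear interpolation, tolerance 0.01 mm, ≤ 50
iterations); the convention must be tagged explicitly because tool output
conventions vary and cannot be inferred from the data.

## Kinematics

The deformation gradient is computed by central differences in world units,
falling back to one-sided differences where a neighbour leaves the lung
mask. Voxels whose full central stencil lies in-mask form the `interior`
set used for statistics and validation; boundary voxels are flagged, not
silently mixed in, since one-sided differences are only first-order
accurate. A mask thinner than two voxels along any axis is rejected.

Derived fields follow the standard finite-strain definitions: `J = det F`
(with voxels where J ≤ 0 collected in a folding mask — they indicate
registration failure), `ε = ½(FᵀF − I)` symmetrized exactly, eigenvalues by
a symmetric solver sorted descending with eigenvector signs fixed
(largest-magnitude component positive) for reproducible maps, stretches
`λ_i = √(1+2ε_i)`. Strains with `1 + 2ε_III ≤ 0` are physically impossible;
they are flagged and reported with NaN stretches, never clamped. FA is set
to 0 where the stretch norm underflows. The small-strain identity
`J ≈ 1 + tr ε` is exposed as a diagnostic (`check_small_strain`): its
residual is second order in strain, so it should shrink ~4× when the
breathing amplitude halves; it is never used to compute J.

Temporal smoothing of displacement fields (applied before differentiation,
not to the derived maps) is penalized least squares along the bin axis with
a **periodic** second-difference penalty, solved exactly in Fourier space —
the periodic analogue of DCT-based penalized smoothing, appropriate because
bin N is adjacent to bin 1 on the averaged cycle. The penalty is either
fixed or chosen by generalized cross-validation pooled over all voxel
series; smoothing preserves constants, and the reference bin's zero
displacement is re-imposed afterwards. Default is no smoothing: the phantom
fields are noise-free, and smoothing is a user decision for registration
output.

## Flow and spirometry metrics

Bin time-stamps are generally nonuniform, so `Q_n = dJ/dt` uses the
weighted finite difference

    Q_n = [ (Δt₊/Δt₋)(J_n − J_{n−1}) + (Δt₋/Δt₊)(J_{n+1} − J_n) ] / (Δt₋ + Δt₊)

which is exact for quadratics, reduces to the central difference for
uniform spacing, and wraps periodically (neighbour times shifted by ± one
period) at the cycle ends. Q is dimensionless per second (dJ/dt);
volumetric flow is obtained by scaling with the reference voxel volume δV₀.
Whole-lung loops use `V(t_n) = Σ_mask δV₀ J_n` (a sum, not a mean) and the
same stencil; regional loops aggregate J by δV₀-weighted mean. Loop exports
follow standard spirometry rendering: expiratory flow positive upward,
deflation to the right (`display_coords` returns (−V, −Q)).

LTV is `δV₀ (max_n J_n − min_n J_n)`. LEV₁ starts at the per-voxel J
maximum (local end-inspiration) rather than a global bin — regional
expiration onset varies — and evaluates `J(t_pk + 1 s)` by linear
interpolation on the wrapped time axis; both the start convention and the
interpolation are exposed, and cycles shorter than 1 s flag LEV₁ undefined.
Trajectory hysteresis is quantified per anatomical projection by the
shoelace signed area of the closed bin-ordered polygon; orientation is
reported only when the area exceeds a tolerance.

## Self-gating

The navigator is the first principal component of the per-channel real and
imaginary DC time series, linearly detrended and standardized per column —
this makes extraction invariant to channel ordering, gains and global phase
rotations (up to sign). It is low-pass filtered to the respiratory band
(zero-phase Butterworth, default cutoff 0.8 Hz, well above resting
respiratory rates of 0.2–0.3 Hz). The PCA sign is intrinsically arbitrary;
it is oriented by waveform skewness when decisive (real expiratory plateaus
make inflation-positive signals right-skewed) and left unchanged for
symmetric waveforms.

Breaths are segmented trough-to-trough via robust peak detection
(prominence = 0.5 × the 10–90 percentile range, minimum period 1.5 s);
each period carries its end-expiration trough time, peak time, amplitude
and duration. Flat stretches lingering within 5% of the period amplitude
above the trough for more than 1 s (apnea) belong to no period. Outlier
periods are rejected when amplitude or duration deviates from the median by
more than k (default 3) robust standard deviations (1.4826 × MAD), with the
robust scale floored at 2% of the median: a degenerate MAD on very regular
breathing must not reject physiological sub-percent variation.

Binning is **amplitude-based within each breath**: the navigator is
normalized to [0, 1] between that period's trough and peak, the rising
branch fills the N/2 inspiration bins and the falling branch the N/2
expiration bins by equal-amplitude slicing. Bins therefore correspond to
inflation states across irregular breaths, at the cost of unequal spoke
counts per bin (for a sinusoidal navigator the counts follow the arcsine
law — extreme bins are fuller). View sharing admits spokes within a
configurable fraction (default 0.5) of a bin width beyond the slice edges;
soft-gating weights are Gaussian in normalized-amplitude distance from the
bin centre with σ defaulting to half a bin width (σ = 0 means hard unit
weights). Bin time-stamps are unweighted means of the member spokes'
offsets from their own breath's end-expiration trough, so t = 0 is the
end-expiration reference phase; empty bins get interpolated time-stamps and
are flagged. On a pure sinusoid these time-stamps agree with the
closed-form (arccosine) slice-midpoint times to within half a spoke
spacing.

## The phantom

The phantom exists so that every downstream stage can be validated against
exact truth. A simple thorax (torso shell, two ellipsoidal lungs, bright
vessel-like landmarks — included because registration is hardest where
landmarks are sparse) is deformed by two smooth spatial modes driven by a
raised-cosine respiratory cycle `s(t) = (1 − cos 2πt/T)/2`:

- a **diaphragm mode** along SI: `u_x = A_si · s(t) · g(x̂)` with
  `g(x̂) = [0.2 + 0.8 sin²(πx̂/2)] (1 + γx̂)/(1+γ)` — a smooth profile with a
  20% apex floor (the whole lung descends with diaphragm pull) and a linear
  gain γ (`gradient_si`) toward the base;
- a **chest mode** along AP, split into a volumetric part
  `(1−η) A_ap s(t) sin²(πẑ/2)` and a chest-wall translation part
  `η A_ap s(t − φT/2π) sin(πx̂)` that lags the diaphragm drive by the
  hysteresis phase φ (wall fraction η = 0.5).

This split encodes a physiological observation: measured per-voxel J rises
monotonically through inspiration and falls through expiration even though
trajectories show hysteresis — i.e. respiratory hysteresis in healthy lungs
is predominantly *positional*, not a phase dispersion of local volume
change. The lagged wall mode depends only on x and displaces along z, so it
contributes exactly zero volume change: F is lower-triangular in the
sagittal plane, `J = F_xx · F_zz` stays driven by the single phase s(t)
(hence exactly monotone per half-cycle and minimal at t = 0, which pins the
zero-displacement reference bin), while trajectories become closed loops
whose orientation flips with the sign of φ. All truth quantities are closed
form; principal stretches come from the 2×2 sagittal block of FᵀF (the
left-right axis is an exact unit eigendirection), evaluated independently
of the finite-difference path under test. The spatial profiles are
deliberately non-polynomial so that central differences have genuine O(h²)
truncation error and grid-refinement convergence is testable.

Defaults are chosen as a realistic quiet-breathing study: period 4 s
(15 breaths/min), 32 bins (16 inspiration + 16 expiration), SI/AP
amplitudes (13, 5) mm for normal, (3, 12) mm for thoracic and (18, 2) mm
for diaphragmatic breathing (basal diaphragm excursion of order 10–15 mm in
quiet breathing, chest-wall AP motion a few mm, ratio flipped by pattern),
amplitude gain γ = 1 toward the base, hysteresis phase 0.15 rad. With a
nonzero lag, per-voxel volume phases would disperse by up to φ if the lag
were applied to the volumetric terms; keeping the volumetric drive
single-phase is what preserves exact monotonicity at 32-bin sampling.
Phantom bin times are equally spaced with bin 0 (t = 0) at end-expiration.
The default grid is 48³ at 4 mm — coarser than clinical 1.5 mm lung
protocols but resolving the same dimensionless strain field; validation
sizes (16³–32³, 4–32 bins) are chosen so the full suite and the acceptance
script run in seconds while leaving truncation error (≪ 1%) comfortably
measurable.

The synthetic spoke stream models the k-space-centre (DC) sample of each
spoke across a receive array as a rank-1 complex mixture of the lung-volume
waveform plus white complex noise (per-channel random gains, phases and
offsets), with 2 ms spoke spacing; designated outlier periods get scaled
amplitude and/or duration. It reproduces exactly the property self-gating
relies on (a dominant shared respiratory component) and none of the
confounds of real data: no bulk motion, cardiac contamination, drift, or
trajectory-dependent DC modulation. Self-gating tests therefore demonstrate
correctness of the extraction/binning machinery, not robustness to real
acquisitions.

What the phantom does *not* emulate: real parenchyma texture and MR
contrast, registration error (fields are exact), lobar sliding, gravity
dependence beyond the imposed SI gain, cardiac-induced motion. Passing the
suite shows the numerics are correct and second-order convergent against
exact truth; accuracy on real data is bounded by registration quality,
which this package reports on (folding voxels, non-physical strains,
small-strain residual) but cannot fix.

## Pipeline and reproducibility

`RunConfig` fully serializes into the output directory, and identical
configs and seeds give bit-identical outputs (summaries, NIfTI maps, CSVs);
stage timings go to a separate log excluded from that guarantee. Stage
caching was considered and dropped — runs are seconds long at validation
sizes, and a cache keyed by config hash adds an invalidation surface with
no real benefit here. A `volumes` input mode (binned magnitude images
without fields) is rejected with an explicit pointer to the fields adapter,
since deformable registration is out of scope; rendered phantom volumes
exist precisely so external registration tools can be exercised end-to-end.

## Known limitations

- One-sided boundary differences are first-order; statistics are therefore
  reported over the full-stencil interior, and near-pleura values should be
  read with that caveat.
- LEV₁'s definition (local-peak start, linear interpolation) is one
  reasonable convention among several; comparisons across tools must match
  conventions.
- The navigator sign heuristic (skewness) can leave symmetric waveforms
  with an arbitrary orientation; downstream phase labels are consistent
  either way, but "inspiration" and "expiration" names may swap on
  perfectly symmetric synthetic input.
- Equal-amplitude binning yields unequal per-bin spoke counts (arcsine
  weighting); reconstruction SNR per bin varies accordingly.
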