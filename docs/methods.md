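# Methods

This note documents the models, numerical choices, and design decisions
behind `ventstrain`, and what the synthetic validation does and does not
demonstrate about real data.

## Coordinate and transformation conventions

Arrays are indexed `(x, y, z)` = (right-left, ventral-to-dorsal,
caudal-rostral); world coordinate = 0-based voxel index × spacing (mm).
Transformations are dense displacement fields `u_n` on the reference grid,
`phi_n(X) = X + u_n(X)`, periodic in the phase index (mod N). Registration
itself is out of scope: transformations are inputs (or phantom ground truth).
B-spline parameterisations can be rasterised to dense fields on import.

Field inversion uses the fixed-point iteration
`v_{i+1}(x) = -u(x + v_i(x))` from `v_0 = 0`, stopping when the largest
update falls below 0.01 voxels or after 50 iterations; the round-trip
residual `|phi(phi^{-1}(x)) - x|` is reported per voxel and the operation
fails if it exceeds 0.5 voxels inside the mask. This converges whenever the
displacement is a contraction (spectral norm of the displacement gradient
below 1), which holds for all phantom settings that keep `det J > 0`.

Pullback mappings `T_{n->m}(x_m) = phi_n(phi_m^{-1}(x_m))` and image warps
use trilinear interpolation; points leaving the image domain are flagged
invalid and excluded from every downstream summary. Jacobians use central
finite differences on the interior and one-sided differences at grid
boundaries; this is second-order accurate, and its truncation error — not
interpolation — dominates the analytic-recovery error measured on the
phantom (≤ ~3e-4 on the interior of baseline phantoms at 0.6 mm).

## Per-voxel metrics

Aeration change is the per-voxel max-min intensity range over aligned
phases. Volume is `V_n = deltaV * det J_{n->ref}`; strain is referenced to
the per-voxel minimum over the cycle, so `min_n eps_n = 0` and
`d_eps = max_n eps_n` exactly. Strain rate uses periodic forward differences
with `dt = 1/(f0 N)`; the rates telescope to zero over a cycle by
construction. Voxels whose pullback leaves the domain at any phase, or whose
numeric determinant is non-positive, are removed from the analysis mask,
alongside a 6.0 mm trim at both axial (caudal-rostral) boundaries where
through-plane motion corrupts registration.

Spatial gradients are three independent univariate OLS slopes of metric
value against world coordinate (one observation per mask voxel), reported
signed and absolute, raw and mean-normalized; the coefficient of variation
uses the population standard deviation. Units are per mm. Multivariate
regression would differ only when mask geometry correlates the axes; the
per-axis form matches how the gradients are interpreted and reported.

## Harmonic analysis

For each voxel series, one-sided DFT amplitudes
`A_k = (2/N)|sum_n x_n e^{-j 2 pi k n / N}|` and phases are computed for
harmonics k = 1..K of the fundamental (K = 4 by default, matching the
5/10/15/20 Hz analysis band; K < N/2 enforced). Phase maps are reported
relative to the per-harmonic median phase over lung voxels, which removes
the arbitrary time origin while preserving voxel-to-voxel phase differences.
The harmonic distortion index is the power fraction above the fundamental,
`HDI = sum_{k>=2} A_k^2 / sum_{k>=1} A_k^2` in [0, 1]; the root-power THD
variant (`sqrt(sum_{k>=2} A_k^2)/A_1`) is available behind a flag. Either
the strain or the strain-rate series can feed the harmonic comparison
against the airway-opening volume waveform; amplitude ratios are identical
for the two (differentiation scales every harmonic by `2 pi k f0` but the
comparison is done per-harmonic), so no default is asserted.

## Heterogeneity decomposition

Both decompositions start from one ROI covering the whole mask and
recursively subdivide any ROI whose masked standard deviation of
mean-normalized `d_eps` is >= 0.3 while the ROI holds >= 0.2% of the mask.
Octree subdivision bisects each axis of the ROI's own bounding box (floor
split for odd extents, empty octants discarded) — box-adaptive rather than
image-fixed planes, which keeps the split scale tied to the region being
examined. Supervoxel subdivision is a deterministic 2-means over features
`[z-scored value, w_p * position / L]` with `L` the ROI bounding-box
diagonal and `w_p = 1` by default (equal balance); initial centres are the
farthest pair found by the standard two-pass approximation, iterations are
capped at 50, and a degenerate ROI (identical features) is treated as below
threshold. The proximity weight is a documented sensitivity knob: smaller
values favour intensity coherence and larger, more irregular clusters.
Patchiness is the mean ROI voxel count as a fraction of the mask.

## Ventilation, gas exchange, impedance

OI is reported on the conventional clinical scale (FiO2 entered as a
fraction, scaled by 100); the convention is switchable and stamped in the
output. The RMS volume integral is discretised as the mean of squares over
samples (at 200 Hz the scheme choice is negligible). The analysis window is
one breath for CMV and exactly 1 s (five 5 Hz cycles) for oscillatory
modalities. Dynamic elastance is defined only for CMV; oscillatory pressure
swings include resistive/inertial loads and are reported as driving pressure
only.

Impedance is estimated with the Welch method: 25.6 s rectangular segments,
80% overlap, H1 transfer estimate `Z = S_qp/S_qq`, coherence
`|S_qp|^2/(S_qq S_pp)`, evaluated only at the nine driving tones (harmonics
{2, 5, 11, 23, 47, 79, 121, 171, 228} of 1/25.6 Hz, spanning 0.078-8.9 Hz —
a non-sum/non-difference set; only the band endpoints are externally
prescribed). On noiseless multi-sine records the estimate is exact because
segments span integer periods of every tone. The constant-phase fit
minimises the unweighted complex residual under non-negativity bounds, from
18 deterministic data-scaled starts followed by L-BFGS-B; the resonant
frequency comes from a cubic spline through the nine reactance samples
(undefined and flagged when the reactance does not cross zero in-band, which
mirrors how stiff lungs push resonance above the measured range). The spline
root agrees with the closed-form root `(2 pi f)^(1+alpha) = H/I_aw` to
within the spline's interpolation error over the sparse tone spacing
(~0.06 Hz near 6.4 Hz).

## Statistics

Kruskal-Wallis (tie-corrected, chi-square p with k-1 df) tests the lung
condition effect across all rows and the modality effect separately within
each condition. Dunn's pairwise z statistics use the tie-corrected variance
`S = N(N+1)/12 - sum(t^3 - t)/(12(N-1))`; comparisons are two-sided
(sidedness is not externally prescribed) and BH-adjusted within each
outcome's family of three modality pairs. An all-constant outcome is
reported as H = 0, p = 1.

## The synthetic phantom

Two ellipsoidal lungs sit in a soft-tissue cylinder; each lung deforms
radially about its centre by `phi_n(X) = c + (1 + a_n A(X))^(1/3) (X - c)`.
The cube-root form makes the determinant exactly linear in the ventilatory
modulation: `det J_n = 1 + a_n (A + (X - c)·grad A / 3)`. The amplitude
field `A` is analytic: a dorsal-ventral linear modulation (default ±30%,
dependent lung ventilating more), a smooth tanh consolidation ramp in the
injured condition, and a low-order random cosine texture (six components,
wavelengths 0.5-0.9 of the grid extent, ~15% RMS). Smoothness parameters
were fixed so the field is resolvable by the documented central-difference
scheme at 0.6 mm; sharper textures would measure discretisation error, not
implementation error. Intensities follow the gas/tissue mixture model
`I = -1000(1 - F) + 40 F` HU with `F_n = F_0 / det J_n` (reference tissue
fraction 0.35), so tissue volume `F_n V_n` is conserved per voxel by
construction; phase images are rendered in their own frames through numeric
field inversion, and the consolidated region's CT density is an exposed
parameter (default 30 HU). Phase 0 is placed at the waveform minimum, so the
reference frame coincides with the phase-0 frame; reference-phase invariance
is verified at a second reference phase.

Ventilatory modulations: CMV is the periodic first-order response to a
square pressure wave (I:E = 1:2, rate 20/min, time constant 0.4 s — a small
pig with a narrow tracheal tube, R ≈ 40 cmH2O L^-1 s, C ≈ 0.01 L cmH2O^-1);
HFOV is a raised 5 Hz cosine; MFOV superimposes four sinusoids with volume
amplitudes ∝ 1/k (uniform flow amplitudes), component phases zero by default
and configurable. Per-modality default strain amplitudes (CMV 0.25, HFOV
0.10, MFOV 0.075 peak fractional volume excursion) emulate eucapnic
titration: oscillatory gas exchange needs far smaller delivered volumes, and
the defaults scale with the reported RMS-volume contrasts between
modalities. The injured condition consolidates the dorsal 30% of each lung
(near-zero deformation, tissue-density HU) and redistributes strain into the
aerated lung by a factor 1.25, reproducing the "baby lung" concentration of
strain. Cardiogenic artifact is not emulated.

Impedance records are multi-sine flows with seeded random tone phases;
pressure is the exact frequency-domain constant-phase response plus optional
Gaussian noise, 90 s at 40 Hz.

## What the phantom does and does not show

Passing tests demonstrate that every operator recovers its analytic target
on smooth, periodic, noise-controlled data: Jacobians to < 1e-3, strain to
< 2% relative on the interior, harmonic ratios to < 3%, impedance exactly on
noiseless records, decompositions equal to brute-force references. Real
4DCT adds registration error, cardiogenic motion, reconstruction artifact,
non-smooth deformation at tissue interfaces, and recruitment-driven
intensity changes that violate tissue conservation — none of which the
phantom emulates. Results on the phantom therefore validate the analysis
chain, not the registration, and the injured-phantom contrasts are
directional reproductions (signs and orderings), not quantitative
predictions of animal data. Near the consolidation interface the
central-difference truncation error grows to ~2e-3 at conventional strain
amplitudes; the analytic-recovery bound is asserted on baseline phantoms.

## Problem sizes

Validation runs use 48³ grids (0.6 mm isotropic, ~16,000 analysed lung
voxels) with 21 phases per cycle, 100-seed Monte-Carlo replicates for the
impedance study, 10^5 permutations for the rank-test oracle, and 1000
permuted-label runs for type-I error calibration; these sizes were chosen so
the full suite completes in a few minutes while every contract is measured
with comfortable statistical margin.
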