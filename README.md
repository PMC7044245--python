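# ventstrain

Registration-based analysis of regional lung deformation under conventional
and oscillatory mechanical ventilation.

Ventilator-induced lung injury is driven by heterogeneous regional stress and
strain. Time-resolved (4D) CT plus deformable image registration makes the
regional deformation field observable: given a periodic sequence of `N`
phase-binned volumes `I_n(x_n)` and transformations `phi_n(X)` from a common
reference frame, every phase can be aligned to a single reference phase
through the pullback `T_{n->0}(x_0) = phi_n(phi_0^{-1}(x_0))`. This package
implements the complete post-registration analysis for comparing conventional
pressure-controlled ventilation (CMV), single-frequency high-frequency
oscillatory ventilation (HFOV, 5 Hz), and multi-frequency oscillatory
ventilation (MFOV, superimposed 5/10/15/20 Hz sinusoids with uniform flow
amplitudes), for researchers in respiratory mechanics and functional lung
imaging.

## What it computes

**Per-voxel intratidal metrics** (in the reference frame, `det J > 1` =
expansion):

- aeration change `dI(x_0) = max_n I_{n->0} - min_n I_{n->0}` (HU)
- regional volume `V_n(x_0) = deltaV |J_{n->0}(x_0)|` from the Jacobian of the
  pullback mapping (central finite differences)
- volumetric strain `eps_n = (V_n - min_n V_n) / min_n V_n` with range
  `d_eps = max_n eps_n`, and strain rate by periodic forward differences with
  `dt = 1/(f0 N)`
- spatial summaries: mask mean, coefficient of variation, and per-axis OLS
  gradients (signed/absolute, raw/mean-normalized), with a 6 mm axial
  boundary trim

**Heterogeneity**: recursive octree and supervoxel (weighted 2-means)
decomposition of mean-normalized `d_eps`, subdividing while the ROI standard
deviation is >= 0.3 and the ROI holds >= 0.2% of the lung mask; patchiness is
summarised by the mean ROI volume fraction `V_ROI`.

**Harmonics**: per-voxel DFT amplitude/phase maps at harmonics of the
ventilatory fundamental, phase referenced to the median lung voxel, and a
harmonic distortion index `HDI = sum_{k>=2} A_k^2 / sum_k A_k^2`.

**Ventilation and gas exchange**: oxygenation index
`OI = Paw_mean * FiO2 / PaO2`, ventilatory cost `V_C = V_rms^2 * PaCO2 / Wt`,
`V_rms`, `V_pp`, driving pressure `dP_aw`, and dynamic elastance
`E_rs = dP_aw / V_pp` (CMV only).

**Respiratory impedance**: Welch cross-spectral estimation (rectangular
windows, 80% overlap, 25.6 s segments) of `Z_rs = S_qp/S_qq` with coherence at
the nine multi-sine driving tones (0.078-8.9 Hz), spline-interpolated
resonant frequency, and a constrained fit of the constant-phase model
`Z(f) = R + j 2 pi f I_aw + (eta - j) H / (2 pi f)^alpha`,
`alpha = (2/pi) atan(1/eta)`.

**Statistics**: Kruskal-Wallis rank tests for condition and (within-condition)
modality effects, Dunn's tie-corrected post hoc comparisons with
Benjamini-Hochberg adjustment, and a Table-style significance grid.

Because no imaging data ship with the method, a first-class synthetic phantom
(`ventstrain.phantom`) generates periodically deforming two-lobed lungs with
analytic transformations and Jacobians, tissue-conserving HU intensities,
dorsal-ventral ventilation gradients, an optional consolidated "injured"
region, CMV/HFOV/MFOV waveforms, and constant-phase impedance records — so
every stage of the analysis is validated against closed-form ground truth.

## Worked example

```python
import numpy as np
from ventstrain import PhantomConfig, make_phantom
from ventstrain.regional import compute_metric_maps, summarize_maps
from ventstrain.harmonics import dft_maps, harmonic_distortion

cfg = PhantomConfig(modality="MFOV", condition="baseline", noise_sd_hu=0.0, seed=0)
seq, truth = make_phantom(cfg)
maps = compute_metric_maps(seq, truth.transforms, trim_mm=6.0)
s = summarize_maps(maps, seq.spacing)["delta_eps"]
print(f"analysis mask: {maps.mask.sum()} voxels, dt = {maps.dt*1e3:.2f} ms")
print(f"delta-eps mean = {s.mean:.4f}, CoV = {s.cov:.3f}, "
      f"dorsal-ventral slope = {s.slope[1]:.5f} per mm")
hm = dft_maps(maps.eps, maps.mask, f0=seq.f0, K=4)
amps = np.array([np.median(hm.amplitude[k][maps.mask]) for k in range(4)])
print("median strain harmonic amplitudes:",
      " ".join(f"{a:.4f}" for a in amps),
      f"-> HDI = {harmonic_distortion(amps):.3f}")
```

prints

```
analysis mask: 16120 voxels, dt = 9.52 ms
delta-eps mean = 0.0717, CoV = 0.304, dorsal-ventral slope = 0.00367 per mm
median strain harmonic amplitudes: 0.0231 0.0116 0.0077 0.0058 -> HDI = 0.298
```

The strain range averages ~7% across the lung under the MFOV settings, with a
positive dorsal-ventral gradient (dependent lung ventilates more). The four
strain harmonics fall off as 1/k — the uniform-flow multisine's volume
amplitude ratios — putting ~30% of the oscillatory spectral power above the
5 Hz fundamental, which matches the closed-form distortion of that waveform,
(1/4 + 1/9 + 1/16) / (1 + 1/4 + 1/9 + 1/16) ≈ 0.2976.

The same pipeline is scriptable from a shell:

```bash
ventstrain simulate --modality MFOV --condition injured --seed 7 --out run/sim
ventstrain strain --in run/sim --out run/strain
ventstrain decompose --strain-dir run/strain --out run/decomp
ventstrain harmonics --in run/sim --strain-dir run/strain --out run/harm
ventstrain report --in run/strain --in run/decomp --out run/report
```

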