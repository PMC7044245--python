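"""Synthetic 4D deforming-lung phantom with analytic ground truth.

The phantom places two ellipsoidal lungs inside a soft-tissue body cylinder
and deforms each lung by a radial map about its hilum,

    phi_n(X) = c + (1 + a_n A(X))^(1/3) (X - c),

where ``a_n`` is the ventilatory modulation sampled from the modality
waveform (CMV / HFOV / MFOV) and ``A(X)`` is a smooth analytic amplitude
field combining a dorsal-ventral gradient, an optional "injured"
consolidation ramp, and a low-order cosine texture.  The cube-root form makes
the Jacobian determinant exactly linear in the waveform,

    det J_n(X) = 1 + a_n (A(X) + (X - c) . grad A(X) / 3),

so volumetric strain, harmonic amplitude ratios, and conservation identities
all have closed-form ground truth.  Voxel intensities follow the
gas/tissue-fraction model I = hu_gas (1 - F) + hu_tissue F with
F_n = F_0 / det J_n, so the tissue volume F_n V_n contained in each material
element is conserved over the cycle by construction.

Axis convention: (x, y, z) = (right-left, ventral-to-dorsal, caudal-rostral);
world coordinate = voxel index times spacing (mm).  Phase 0 is placed at the
waveform minimum, so phi_0 is the identity and the reference frame coincides
with the phase-0 frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import PeriodicImageSequence
from .impedance import DEFAULT_TONES, ConstantPhaseParams
from .transforms import TransformSet, invert_transform, reference_grid_mm
from .ventgas import WaveformRecord

HU_GAS = -1000.0
HU_TISSUE = 40.0

MODALITIES = ("CMV", "HFOV", "MFOV")
#: Eucapnic study conditions: fundamental frequency (Hz) and peak fractional
#: volume excursion per modality.  Oscillatory amplitudes are much smaller
#: than conventional tidal excursions because gas exchange at 5-20 Hz
#: requires far less delivered volume.
DEFAULT_F0 = {"CMV": 1.0 / 3.0, "HFOV": 5.0, "MFOV": 5.0}
DEFAULT_STRAIN_AMPLITUDE = {"CMV": 0.25, "HFOV": 0.10, "MFOV": 0.075}

# lung geometry as fractions of the grid extent
_LUNG_X_OFFSET = 0.21
_LUNG_SEMIAXES = (0.17, 0.30, 0.36)
_ENVELOPE_OUTER = 1.2  # displacement tapers to zero by this ellipsoidal radius
_BODY_RADIUS = 0.46


# ---------------------------------------------------------------------------
# ventilator waveforms
# ---------------------------------------------------------------------------


def _cmv_modulation(t, period, duty=1.0 / 3.0, tau=0.4):
    """Normalized periodic first-order volume response to a square pressure
    wave with inspiratory duty cycle ``duty``; 0 at end-expiration, 1 at
    end-inspiration."""
    ti = duty * period
    te = period - ti
    a, b = np.exp(-ti / tau), np.exp(-te / tau)
    v0 = (1 - a) * b / (1 - a * b)  # start-inspiration volume (steady state)
    v1 = 1 - (1 - v0) * a  # end-inspiration volume
    tt = np.asarray(t, dtype=float) % period
    v = np.where(
        tt < ti,
        1 - (1 - v0) * np.exp(-tt / tau),
        v1 * np.exp(-(tt - ti) / tau),
    )
    return (v - v0) / (v1 - v0)


def _mfov_volume(t, f0, phases, n_tones=4):
    """Uniform-flow multisine volume waveform (volume amplitudes 1/k)."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    for k in range(1, n_tones + 1):
        out += np.sin(2 * np.pi * k * f0 * t + phases[k - 1]) / k
    return out


def phase_modulation(
    modality: str,
    n_phases: int,
    f0: float,
    mfov_phases=None,
    cmv_tau: float = 0.4,
    cmv_duty: float = 1.0 / 3.0,
) -> np.ndarray:
    """Normalized volume modulation ``w_n`` in [0, 1] at the N phase times.

    The cycle is shifted so that phase 0 sits at the waveform minimum
    (``w_0 = 0``); the continuous maximum is normalized to 1.
    """
    modality = modality.upper()
    if modality not in MODALITIES:
        raise ValueError(f"unknown modality {modality!r}")
    period = 1.0 / f0
    t_n = np.arange(n_phases) / (f0 * n_phases)
    if modality == "CMV":
        return _cmv_modulation(t_n, period, duty=cmv_duty, tau=cmv_tau)
    if modality == "HFOV":
        return 0.5 * (1.0 - np.cos(2 * np.pi * f0 * t_n))
    phases = np.zeros(4) if mfov_phases is None else np.asarray(mfov_phases, float)
    t_fine = np.linspace(0, period, 8192, endpoint=False)
    m_fine = _mfov_volume(t_fine, f0, phases)
    t0 = t_fine[np.argmin(m_fine)]
    lo, hi = m_fine.min(), m_fine.max()
    return (_mfov_volume(t_n + t0, f0, phases) - lo) / (hi - lo)


def make_waveform(
    modality: str,
    f0: float | None = None,
    amplitude: float | None = None,
    duration: float | None = None,
    fs: float = 200.0,
    *,
    paw_mean: float = 12.0,
    delta_p: float = 13.0,
    cmv_tau: float = 0.4,
    cmv_duty: float = 1.0 / 3.0,
    r_rs: float = 20.0,
    e_rs: float = 150.0,
    mfov_phases=None,
    n_tones: int = 4,
) -> WaveformRecord:
    """Synthesize an airway-opening pressure/flow/volume record.

    CMV: square pressure wave (I:E from ``cmv_duty``) with the volume as the
    first-order single-compartment response; ``amplitude`` is the tidal
    volume in L (default 0.1).  HFOV: single sinusoidal flow at ``f0``
    (default 5 Hz); ``amplitude`` is the flow amplitude in L/s (default 0.3),
    so the volume amplitude is Q/(2 pi f0).  MFOV: superimposed sinusoidal
    flows at f0..n_tones*f0 with uniform flow amplitudes (volume amplitudes
    proportional to 1/k).  Oscillatory airway pressure is synthesized from a
    single-compartment load P = Pbar + E V + R Q.
    """
    modality = modality.upper()
    if modality not in MODALITIES:
        raise ValueError(f"unknown modality {modality!r}")
    if f0 is None:
        f0 = DEFAULT_F0[modality]
    if f0 <= 0:
        raise ValueError("f0 must be positive")
    if amplitude is None:
        amplitude = 0.1 if modality == "CMV" else 0.3
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    f_max = f0 * (n_tones if modality == "MFOV" else 1)
    if fs <= 2 * f_max:
        raise ValueError("sampling rate must exceed twice the highest tone")
    if duration is None:
        # at least three cycles, and long enough for the 1-s oscillatory
        # analysis window
        duration = max(3.0 / f0, 2.0) if modality != "CMV" else 3.0 / f0
    t = np.arange(int(round(duration * fs))) / fs
    period = 1.0 / f0

    if modality == "CMV":
        vol = amplitude * _cmv_modulation(t, period, duty=cmv_duty, tau=cmv_tau)
        # analytic derivative of the piecewise-exponential response
        ti = cmv_duty * period
        a, b = np.exp(-ti / cmv_tau), np.exp(-(period - ti) / cmv_tau)
        v0 = (1 - a) * b / (1 - a * b)
        v1 = 1 - (1 - v0) * a
        tt = t % period
        scale = amplitude / (v1 - v0)
        flow = np.where(
            tt < ti,
            scale * (1 - v0) / cmv_tau * np.exp(-tt / cmv_tau),
            -scale * v1 / cmv_tau * np.exp(-(tt - ti) / cmv_tau),
        )
        peep = paw_mean - delta_p * cmv_duty
        paw = peep + delta_p * (tt < ti)
    elif modality == "HFOV":
        w = 2 * np.pi * f0
        vol = amplitude / w * np.sin(w * t)
        flow = amplitude * np.cos(w * t)
        paw = paw_mean + e_rs * vol + r_rs * flow
    else:  # MFOV
        phases = np.zeros(n_tones) if mfov_phases is None else np.asarray(mfov_phases)
        vol = np.zeros_like(t)
        flow = np.zeros_like(t)
        for k in range(1, n_tones + 1):
            wk = 2 * np.pi * k * f0
            vol += amplitude / wk * np.sin(wk * t + phases[k - 1])
            flow += amplitude * np.cos(wk * t + phases[k - 1])
        paw = paw_mean + e_rs * vol + r_rs * flow

    return WaveformRecord(
        time=t, paw=paw, flow=flow, volume=vol, modality=modality, f0=f0, fs=fs
    )


def make_impedance_record(
    params: ConstantPhaseParams,
    freqs=None,
    fs: float = 40.0,
    duration: float = 90.0,
    amplitude: float = 0.1,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Multi-sine forced-oscillation record from a constant-phase model.

    Flow is a sum of sinusoids at ``freqs`` (default 9-tone set, all on the
    25.6-s frequency grid) with seeded random phases; pressure is the exact
    frequency-domain response of the model plus additive Gaussian noise.
    Returns ``(pressure, flow)`` sampled at ``fs``.
    """
    freqs = DEFAULT_TONES if freqs is None else np.asarray(freqs, dtype=float)
    grid = 1.0 / 25.6
    if np.any(np.abs(freqs / grid - np.rint(freqs / grid)) > 1e-9):
        raise ValueError("frequencies must be integer multiples of 1/25.6 Hz")
    if duration < 3 * 25.6:
        raise ValueError("duration must cover at least three 25.6-s periods")
    rng = np.random.default_rng(seed)
    t = np.arange(int(round(duration * fs))) / fs
    phases = rng.uniform(0, 2 * np.pi, size=freqs.size)
    Z = params.impedance(freqs)
    flow = np.zeros_like(t)
    pressure = np.zeros_like(t)
    for fk, ph, zk in zip(freqs, phases, Z):
        arg = 2 * np.pi * fk * t + ph
        flow += amplitude * np.cos(arg)
        pressure += amplitude * np.abs(zk) * np.cos(arg + np.angle(zk))
    if noise_sd > 0:
        pressure = pressure + rng.normal(0.0, noise_sd, size=t.size)
    return pressure, flow


# ---------------------------------------------------------------------------
# phantom configuration and geometry
# ---------------------------------------------------------------------------


@dataclass
class PhantomConfig:
    """Study conditions for one synthetic 4DCT acquisition.

    Defaults emulate the experimental protocol: 21 ventilatory phases,
    isotropic 0.6 mm voxels, eucapnic per-modality amplitude settings, and a
    dorsal-dependent ventilation gradient.  The injured condition adds a
    non-deforming dorsal consolidation and a modest redistribution of strain
    into the remaining aerated lung.
    """

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    spacing: float = 0.6  # mm, isotropic
    n_phases: int = 21
    f0: float | None = None  # Hz; modality default when None
    modality: str = "CMV"
    condition: str = "baseline"
    strain_amplitude: float | None = None  # peak fractional volume excursion
    dv_gradient: float = 0.3  # fractional dorsal-ventral amplitude modulation
    consolidation_fraction: float | None = None  # dorsal lung fraction (injured)
    noise_sd_hu: float = 20.0
    texture_amplitude: float = 0.15  # fractional low-order amplitude texture
    tissue_fraction: float = 0.35  # reference-phase aerated tissue fraction
    consolidation_hu: float = 30.0  # CT intensity of consolidated tissue
    injury_redistribution: float = 1.25  # aerated-region strain gain (injured)
    mfov_phases: tuple | None = None
    cmv_tau: float = 0.4  # s, first-order time constant of the CMV response
    seed: int = 0

    def __post_init__(self) -> None:
        self.modality = self.modality.upper()
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.condition not in ("baseline", "injured"):
            raise ValueError("condition must be 'baseline' or 'injured'")
        if self.f0 is None:
            self.f0 = DEFAULT_F0[self.modality]
        if self.strain_amplitude is None:
            self.strain_amplitude = DEFAULT_STRAIN_AMPLITUDE[self.modality]
        if self.consolidation_fraction is None:
            self.consolidation_fraction = 0.3 if self.condition == "injured" else 0.0
        if self.condition == "baseline" and self.consolidation_fraction > 0:
            raise ValueError("consolidation requires the injured condition")
        if not 0 <= self.consolidation_fraction < 1:
            raise ValueError("consolidation_fraction must lie in [0, 1)")
        if self.n_phases < 3:
            raise ValueError("need at least 3 phases per cycle")
        if self.f0 <= 0 or self.spacing <= 0:
            raise ValueError("f0 and spacing must be positive")
        if self.strain_amplitude < 0:
            raise ValueError("strain_amplitude must be non-negative")

    @property
    def spacing_vec(self) -> np.ndarray:
        return np.full(3, float(self.spacing))

    @property
    def extent_mm(self) -> np.ndarray:
        return np.asarray(self.grid_shape, float) * self.spacing


class _Lung:
    """One ellipsoidal lung with its analytic amplitude field."""

    def __init__(self, center, semiaxes, cfg: PhantomConfig, texture):
        self.center = np.asarray(center, float)
        self.semiaxes = np.asarray(semiaxes, float)
        self.cfg = cfg
        self.texture = texture  # (coeffs, kvecs, psis)
        # dorsal consolidation boundary: the dorsal `consolidation_fraction`
        # of the lung's ventral-dorsal diameter is consolidated
        self.y_boundary = self.center[1] + self.semiaxes[1] * (
            1.0 - 2.0 * cfg.consolidation_fraction
        )
        self.sigmoid_width = 3.6  # mm; smooth consolidation transition

    def rho(self, pts: np.ndarray) -> np.ndarray:
        """Ellipsoidal radius (1 on the lung surface)."""
        d = (pts - self.center) / self.semiaxes
        return np.sqrt(np.sum(d * d, axis=-1))

    def _texture(self, pts):
        coeffs, kvecs, psis = self.texture
        T = np.ones(pts.shape[:-1])
        gradT = np.zeros(pts.shape[:-1] + (3,))
        for b, k, psi in zip(coeffs, kvecs, psis):
            arg = pts @ k + psi
            T += b * np.cos(arg)
            gradT -= (b * np.sin(arg))[..., None] * k
        return T, gradT

    def _gravity(self, pts):
        """Dorsal-ventral modulation g(y) and its derivative dg/dy."""
        cfg = self.cfg
        y = pts[..., 1]
        y_norm = (y - self.center[1]) / self.semiaxes[1]
        g1 = 1.0 + cfg.dv_gradient * y_norm
        dg1 = np.full_like(y, cfg.dv_gradient / self.semiaxes[1])
        if cfg.condition == "baseline":
            return g1, dg1
        th = np.tanh((self.y_boundary - y) / self.sigmoid_width)
        s = 0.5 * (1.0 + th)
        ds = -0.5 * (1.0 - th * th) / self.sigmoid_width
        r = cfg.injury_redistribution
        return r * g1 * s, r * (dg1 * s + g1 * ds)

    def amplitude_field(self, pts: np.ndarray):
        """Analytic amplitude A(X) and gradient, at arbitrary points (mm)."""
        g, dg = self._gravity(pts)
        T, gradT = self._texture(pts)
        A = g * T
        gradA = g[..., None] * gradT
        gradA[..., 1] += dg * T
        return A, gradA

    def det_jacobian_factor(self, pts: np.ndarray) -> np.ndarray:
        """G(X) such that det J_n = 1 + a_n G(X)."""
        A, gradA = self.amplitude_field(pts)
        radial = np.sum((pts - self.center) * gradA, axis=-1)
        return A + radial / 3.0

    def envelope(self, rho: np.ndarray) -> np.ndarray:
        """1 inside the lung, smoothstep to 0 by rho = _ENVELOPE_OUTER."""
        t = np.clip((_ENVELOPE_OUTER - rho) / (_ENVELOPE_OUTER - 1.0), 0.0, 1.0)
        return t * t * (3.0 - 2.0 * t)

    def displacement(self, pts: np.ndarray, a_n: float) -> np.ndarray:
        """u(X) = env * ((1 + a A)^(1/3) - 1) (X - c)."""
        rho = self.rho(pts)
        region = rho < _ENVELOPE_OUTER
        u = np.zeros_like(pts)
        if a_n == 0 or not np.any(region):
            return u
        sub = pts[region]
        A, _ = self.amplitude_field(sub)
        base = 1.0 + a_n * A
        if np.min(base) <= 0:
            raise ValueError(
                "deformation would collapse the Jacobian (1 + a A <= 0); "
                "reduce strain_amplitude, dv_gradient or texture_amplitude"
            )
        scale = self.envelope(rho[region]) * (np.cbrt(base) - 1.0)
        u[region] = scale[..., None] * (sub - self.center)
        return u

    def tissue_fraction(self, pts: np.ndarray) -> np.ndarray:
        """Reference-phase tissue fraction F_0(X)."""
        cfg = self.cfg
        f0 = np.full(pts.shape[:-1], cfg.tissue_fraction)
        if cfg.condition == "injured":
            th = np.tanh((self.y_boundary - pts[..., 1]) / self.sigmoid_width)
            s = 0.5 * (1.0 + th)
            f_cons = (cfg.consolidation_hu - HU_GAS) / (HU_TISSUE - HU_GAS)
            f0 = f0 * s + f_cons * (1.0 - s)
        return f0


def _build_lungs(cfg: PhantomConfig) -> list[_Lung]:
    ext = cfg.extent_mm
    semi = np.array(_LUNG_SEMIAXES) * ext
    rng = np.random.default_rng(cfg.seed + 1)
    lungs = []
    for sign in (-1.0, 1.0):
        center = np.array(
            [ext[0] * (0.5 + sign * _LUNG_X_OFFSET), ext[1] * 0.5, ext[2] * 0.5]
        )
        n_comp = 6
        raw = rng.normal(size=n_comp)
        if cfg.texture_amplitude > 0:
            coeffs = raw * cfg.texture_amplitude / np.sqrt(np.sum(raw**2) / 2.0)
        else:
            coeffs = np.zeros(n_comp)
        dirs = rng.normal(size=(n_comp, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        wavelengths = rng.uniform(0.5, 0.9, size=n_comp) * np.min(ext)
        kvecs = dirs * (2 * np.pi / wavelengths)[:, None]
        psis = rng.uniform(0, 2 * np.pi, size=n_comp)
        lungs.append(_Lung(center, semi, cfg, (coeffs, kvecs, psis)))
    return lungs


# ---------------------------------------------------------------------------
# ground truth container and phantom assembly
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Analytic ground truth accompanying a phantom image sequence."""

    transforms: TransformSet
    det_series: np.ndarray  # (N, nx, ny, nz) analytic det J_{n->0}
    strain_field: np.ndarray  # G(X): det J_n = 1 + a_n G
    tissue_fraction: np.ndarray  # F_0(X) at the reference phase
    mask: np.ndarray  # reference-phase lung mask
    amplitudes: np.ndarray  # a_n, peak-normalized waveform times amplitude
    config: PhantomConfig

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.transforms.spacing))

    @property
    def volume_series(self) -> np.ndarray:
        """Per-voxel V_n = deltaV * det J_{n->0} (mm^3), reference frame."""
        return self.voxel_volume * self.det_series

    def delta_strain(self) -> np.ndarray:
        """Ground-truth strain range: max_n a_n * G(X) (phase 0 at minimum)."""
        return np.max(self.amplitudes) * self.strain_field

    def tissue_volume_series(self) -> np.ndarray:
        """F_n V_n per phase; constant over n by construction (noiseless)."""
        f_n = self.tissue_fraction[None] / self.det_series
        return f_n * self.volume_series


def make_phantom(config: PhantomConfig):
    """Generate a phantom image sequence with exact transformations.

    Returns ``(PeriodicImageSequence, GroundTruth)``.  Raises ValueError if
    the requested deformation would produce a non-positive Jacobian
    determinant anywhere inside the lung mask.
    """
    cfg = config
    shape = tuple(cfg.grid_shape)
    spacing = cfg.spacing_vec
    ext = cfg.extent_mm
    grid = reference_grid_mm(shape, spacing)
    lungs = _build_lungs(cfg)

    w_n = phase_modulation(
        cfg.modality,
        cfg.n_phases,
        cfg.f0,
        mfov_phases=cfg.mfov_phases,
        cmv_tau=cfg.cmv_tau,
    )
    a_n = cfg.strain_amplitude * w_n

    rho = [lung.rho(grid) for lung in lungs]
    in_lung = [r <= 1.0 for r in rho]
    mask_ref = in_lung[0] | in_lung[1]
    if not np.any(mask_ref):
        raise ValueError("phantom grid too small: empty lung mask")

    # analytic det-J factor G(X) and tissue fraction on the reference grid
    strain_field = np.zeros(shape)
    f0_field = np.zeros(shape)
    for lung, inside in zip(lungs, in_lung):
        pts = grid[inside]
        strain_field[inside] = lung.det_jacobian_factor(pts)
        f0_field[inside] = lung.tissue_fraction(pts)

    det_series = 1.0 + a_n[:, None, None, None] * strain_field[None]
    if np.any(det_series[:, mask_ref] <= 0):
        worst = float(np.min(det_series[:, mask_ref]))
        raise ValueError(
            f"deformation yields non-positive det J (min {worst:.3f}) inside "
            "the lung mask; reduce strain_amplitude or amplitude modulation"
        )

    # forward displacement fields on the reference grid
    disp = np.zeros((cfg.n_phases,) + shape + (3,))
    for n in range(cfg.n_phases):
        if a_n[n] == 0:
            continue
        for lung in lungs:
            disp[n] += lung.displacement(grid, a_n[n])
    transforms = TransformSet(displacements=disp, spacing=spacing, f0=cfg.f0)

    # render each phase image in its own frame via numeric inversion
    body = (
        (grid[..., 0] - ext[0] / 2) ** 2 + (grid[..., 1] - ext[1] / 2) ** 2
    ) <= (_BODY_RADIUS * min(ext[0], ext[1])) ** 2
    rng = np.random.default_rng(cfg.seed)
    images = np.empty((cfg.n_phases,) + shape)
    masks = np.empty((cfg.n_phases,) + shape, dtype=bool)
    for n in range(cfg.n_phases):
        if a_n[n] == 0:
            material_pts = grid
        else:
            v_inv, _ = invert_transform(disp[n], spacing, mask=mask_ref)
            material_pts = grid + v_inv
        hu = np.where(body, HU_TISSUE, HU_GAS)
        mask_n = np.zeros(shape, dtype=bool)
        for lung in lungs:
            inside = lung.rho(material_pts) <= 1.0
            pts = material_pts[inside]
            det = 1.0 + a_n[n] * lung.det_jacobian_factor(pts)
            frac = np.clip(lung.tissue_fraction(pts) / det, 0.0, 1.0)
            hu[inside] = HU_GAS * (1.0 - frac) + HU_TISSUE * frac
            mask_n |= inside
        if cfg.noise_sd_hu > 0:
            hu = hu + rng.normal(0.0, cfg.noise_sd_hu, size=shape)
        images[n] = hu
        masks[n] = mask_n

    sequence = PeriodicImageSequence(
        images=images, masks=masks, spacing=spacing, f0=cfg.f0
    )
    truth = GroundTruth(
        transforms=transforms,
        det_series=det_series,
        strain_field=strain_field,
        tissue_fraction=f0_field,
        mask=mask_ref,
        amplitudes=a_n,
        config=cfg,
    )
    return sequence, truth
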