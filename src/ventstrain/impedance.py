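"""Respiratory input impedance: Welch estimation and constant-phase modelling.

The respiratory system is probed with a multi-sine forced-oscillation signal;
the input impedance ``Z_rs(f) = P(f)/Q(f)`` (cmH2O L^-1 s) is estimated from
airway pressure and flow records by the Welch cross-spectral method and
evaluated only at the driving tones.  Each spectrum is characterised by the
four-parameter constant-phase model

    Z(f) = R + j 2 pi f I_aw + (eta - j) H / (2 pi f)^alpha,

with Newtonian resistance ``R``, airway inertance ``I_aw``, tissue
hysteresivity ``eta``, tissue elastance ``H`` (cmH2O L^-1 at 1 rad/s), and
``alpha = (2/pi) atan(1/eta)``.  The resonant frequency is the zero crossing
of the reactance ``X_rs = Im Z``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq, minimize

#: Default 9-tone forcing frequencies (Hz): harmonics {2,5,11,23,47,79,121,
#: 171,228} of the 25.6-s record period, a non-sum/non-difference set spanning
#: 0.078-8.9 Hz.
DEFAULT_TONES = np.array([2, 5, 11, 23, 47, 79, 121, 171, 228]) / 25.6


def constant_phase_alpha(eta: float) -> float:
    """Tissue-phase exponent ``alpha = (2/pi) atan(1/eta)``."""
    if eta < 0:
        raise ValueError("eta must be non-negative")
    return (2.0 / np.pi) * np.arctan(1.0 / eta) if eta > 0 else 1.0


@dataclass
class ConstantPhaseParams:
    """Constant-phase model parameters (all non-negative)."""

    R: float
    I_aw: float
    eta: float
    H: float
    residual_norm: float = 0.0
    converged: bool = True

    def __post_init__(self) -> None:
        if min(self.R, self.I_aw, self.eta, self.H) < 0:
            raise ValueError("constant-phase parameters must be non-negative")

    @property
    def alpha(self) -> float:
        return constant_phase_alpha(self.eta)

    @property
    def f_res_model(self) -> float:
        """Closed-form reactance zero: ``(2 pi f)^(1+alpha) = H / I_aw``."""
        if self.I_aw <= 0 or self.H <= 0:
            return np.nan
        return (self.H / self.I_aw) ** (1.0 / (1.0 + self.alpha)) / (2.0 * np.pi)

    def impedance(self, freqs) -> np.ndarray:
        return constant_phase_impedance(freqs, self.R, self.I_aw, self.eta, self.H)


def constant_phase_impedance(freqs, R, I_aw, eta, H) -> np.ndarray:
    """Model impedance at ``freqs`` (Hz), complex, cmH2O L^-1 s."""
    f = np.asarray(freqs, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequencies must be positive")
    w = 2.0 * np.pi * f
    alpha = constant_phase_alpha(eta)
    return R + 1j * w * I_aw + (eta - 1j) * H / w**alpha


@dataclass
class ImpedanceSpectrum:
    """Impedance and coherence at the driving tones."""

    frequencies: np.ndarray
    Z: np.ndarray
    coherence: np.ndarray

    @property
    def R_rs(self) -> np.ndarray:
        return self.Z.real

    @property
    def X_rs(self) -> np.ndarray:
        return self.Z.imag


def estimate_impedance(
    pressure: np.ndarray,
    flow: np.ndarray,
    fs: float,
    freqs=None,
    segment_s: float = 25.6,
    overlap: float = 0.8,
) -> ImpedanceSpectrum:
    """Welch-periodogram impedance estimate with rectangular windows.

    Auto- and cross-spectra are averaged over segments of ``segment_s``
    seconds with fractional ``overlap``; the H1 transfer estimate
    ``Z = S_qp / S_qq`` and coherence ``gamma^2 = |S_qp|^2/(S_qq S_pp)`` are
    evaluated only at the driving ``freqs`` (default 9-tone set), which must
    lie on the segment frequency grid.
    """
    pressure = np.asarray(pressure, dtype=float)
    flow = np.asarray(flow, dtype=float)
    if pressure.shape != flow.shape:
        raise ValueError("pressure and flow must have equal length")
    nperseg = int(round(segment_s * fs))
    if pressure.size < nperseg:
        raise ValueError("record shorter than one Welch segment")
    noverlap = int(round(overlap * nperseg))
    freqs = DEFAULT_TONES if freqs is None else np.asarray(freqs, dtype=float)

    kw = dict(fs=fs, window="boxcar", nperseg=nperseg, noverlap=noverlap, detrend=False)
    f_grid, s_qp = signal.csd(flow, pressure, **kw)
    _, s_qq = signal.welch(flow, **kw)
    _, s_pp = signal.welch(pressure, **kw)

    df = f_grid[1] - f_grid[0]
    idx = np.rint(freqs / df).astype(int)
    off_grid = np.abs(freqs - idx * df) > 1e-9 * max(df, 1.0)
    if np.any(off_grid) or np.any(idx >= f_grid.size) or np.any(idx < 1):
        raise ValueError(
            f"driving frequencies must lie on the {segment_s}-s segment grid "
            f"(multiples of {df:.6g} Hz)"
        )
    Z = s_qp[idx] / s_qq[idx]
    coh = np.abs(s_qp[idx]) ** 2 / (s_qq[idx] * s_pp[idx]).real
    return ImpedanceSpectrum(frequencies=freqs, Z=Z, coherence=np.clip(coh.real, 0, 1))


def resonant_frequency(spectrum: ImpedanceSpectrum) -> float:
    """Reactance zero crossing by cubic-spline interpolation of ``X_rs(f)``.

    Returns NaN when the reactance does not change sign within the measured
    band (resonance above the measurement range).
    """
    f = np.asarray(spectrum.frequencies, dtype=float)
    x = np.asarray(spectrum.X_rs, dtype=float)
    order = np.argsort(f)
    f, x = f[order], x[order]
    if np.all(x < 0) or np.all(x > 0):
        return np.nan
    spline = CubicSpline(f, x)
    roots = spline.roots(extrapolate=False)
    roots = roots[(roots >= f[0]) & (roots <= f[-1])]
    return float(roots.min()) if roots.size else np.nan


def _fit_residual(theta, w, Z) -> float:
    R, I_aw, eta, H = theta
    alpha = constant_phase_alpha(max(eta, 0.0))
    model = R + 1j * w * I_aw + (eta - 1j) * H / w**alpha
    return float(np.sum(np.abs(Z - model) ** 2))


def fit_constant_phase(spectrum: ImpedanceSpectrum) -> ConstantPhaseParams:
    """Least-squares constant-phase fit with non-negativity constraints.

    Minimises the unweighted complex residual ``sum_f |Z - Zhat|^2`` over a
    deterministic multi-start grid (data-scaled initial guesses) followed by
    bounded local optimisation.
    """
    f = np.asarray(spectrum.frequencies, dtype=float)
    Z = np.asarray(spectrum.Z)
    ok = np.isfinite(Z)
    f, Z = f[ok], Z[ok]
    if f.size < 4:
        raise ValueError("need at least 4 valid frequencies to fit 4 parameters")
    w = 2.0 * np.pi * f

    # data-driven scales: R ~ high-f resistance, H ~ low-f elastic reactance
    r_scale = max(float(np.median(Z.real)), 1e-3)
    h_scale = max(float(-Z.imag[np.argmin(f)] * w[np.argmin(f)] ** 0.9), 1e-2)
    starts = []
    for r_mul in (0.5, 1.0, 2.0):
        for h_mul in (0.3, 1.0, 3.0):
            for eta0 in (0.1, 0.3):
                starts.append([r_scale * r_mul, 1e-2, eta0, h_scale * h_mul])

    best = None
    bounds = [(0, None)] * 4
    for x0 in starts:
        res = minimize(
            _fit_residual,
            x0,
            args=(w, Z),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-12},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError("constant-phase fit failed from every start")
    R, I_aw, eta, H = (float(v) for v in best.x)
    return ConstantPhaseParams(
        R=R,
        I_aw=I_aw,
        eta=eta,
        H=H,
        residual_norm=float(best.fun),
        converged=bool(best.success),
    )
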