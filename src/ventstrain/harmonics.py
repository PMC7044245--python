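"""Per-voxel harmonic decomposition of periodic metric series.

For a periodic series ``x_n`` sampled at N phases over one ventilatory cycle,
the one-sided DFT amplitude at harmonic k of the fundamental f0 is
``A_k = (2/N) |sum_n x_n exp(-j 2 pi k n / N)|`` with phase from the
argument.  Phase maps are reported relative to the per-harmonic median phase
over lung voxels (a leading/lagging convention that is invariant to the
arbitrary choice of time origin).  The harmonic distortion index is the
fraction of oscillatory spectral power above the fundamental.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .ventgas import WaveformRecord


def _wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    out = (phi + np.pi) % (2 * np.pi) - np.pi
    return np.where(out == -np.pi, np.pi, out)


@dataclass
class HarmonicMaps:
    """Amplitude and (median-referenced) phase maps for harmonics 1..K."""

    amplitude: np.ndarray  # (K, ...) one-sided amplitudes A_k >= 0
    phase: np.ndarray  # (K, ...) relative to the median lung-voxel phase
    median_phase: np.ndarray  # (K,) reference phase per harmonic
    f0: float
    mask: np.ndarray

    @property
    def frequencies(self) -> np.ndarray:
        return self.f0 * np.arange(1, self.amplitude.shape[0] + 1)


def dft_maps(series: np.ndarray, mask: np.ndarray, f0: float, K: int = 4) -> HarmonicMaps:
    """Harmonic amplitude/phase maps of a per-voxel periodic series.

    ``series`` has shape (N, nx, ny, nz).  Requires N > 2K (harmonics up to K
    must be below the Nyquist order).
    """
    series = np.asarray(series, dtype=float)
    N = series.shape[0]
    if K < 1:
        raise ValueError("K must be at least 1")
    if 2 * K >= N:
        raise ValueError(f"K={K} aliases with N={N} phases (need N > 2K)")
    spec = np.fft.fft(series, axis=0)
    amp = (2.0 / N) * np.abs(spec[1 : K + 1])
    phase = np.angle(spec[1 : K + 1])
    median = np.array([np.median(phase[k][mask]) for k in range(K)])
    rel = _wrap_phase(phase - median[(slice(None),) + (None,) * (series.ndim - 1)])
    return HarmonicMaps(
        amplitude=amp, phase=rel, median_phase=median, f0=f0, mask=mask
    )


def harmonic_distortion(amplitudes: np.ndarray, formula: str = "power") -> np.ndarray:
    """Harmonic distortion from amplitudes ``A_1..A_K`` (first axis).

    ``formula='power'`` (default): fraction of oscillatory spectral power
    above the fundamental, ``sum_{k>=2} A_k^2 / sum_{k>=1} A_k^2`` in [0, 1].
    ``formula='root'``: the root-power THD, ``sqrt(sum_{k>=2} A_k^2) / A_1``.
    All-zero amplitude stacks yield NaN.
    """
    A = np.asarray(amplitudes, dtype=float)
    if A.shape[0] < 2:
        raise ValueError("need at least 2 harmonics")
    power_high = np.sum(A[1:] ** 2, axis=0)
    power_all = np.sum(A**2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        if formula == "power":
            out = power_high / power_all
            out = np.where(power_all > 0, out, np.nan)
        elif formula == "root":
            out = np.sqrt(power_high) / A[0]
            out = np.where(A[0] > 0, out, np.nan)
        else:
            raise ValueError("formula must be 'power' or 'root'")
    return out


def waveform_harmonics(record: WaveformRecord, f0: float | None = None, K: int = 4):
    """Volume-waveform amplitudes at harmonics k*f0 of the airway record.

    The record is trimmed to an integer number of fundamental cycles (with a
    warning if trimming was needed); amplitudes come from the DFT bins at
    k * f0.  Used to correlate regional harmonic content against what the
    ventilator delivered at the airway opening.
    """
    if f0 is None:
        f0 = record.f0
    v = np.asarray(record.volume, dtype=float)
    samples_per_cycle = record.fs / f0
    n_cycles = int(np.floor(len(v) / samples_per_cycle))
    if n_cycles < 1:
        raise ValueError("record shorter than one fundamental period")
    n_keep = int(round(n_cycles * samples_per_cycle))
    if n_keep != len(v):
        warnings.warn(
            "record trimmed to an integer number of fundamental cycles",
            stacklevel=2,
        )
        v = v[:n_keep]
    spec = np.fft.fft(v)
    bins = np.arange(1, K + 1) * n_cycles
    if np.any(bins >= len(v) // 2 + 1):
        raise ValueError("harmonic above the record Nyquist frequency")
    return (2.0 / len(v)) * np.abs(spec[bins])
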