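"""Scalar ventilation and gas-exchange indices from ventilator waveforms.

Implements the oxygenation index OI = P_aw_mean * FiO2 / PaO2, the
ventilatory cost function V_C = V_rms^2 * PaCO2 / Wt, RMS and peak-to-peak
volume statistics, driving pressure, and dynamic elastance
E_rs = dP_aw / V_pp.  The analysis window is one breath for conventional
ventilation and one second (five fundamental cycles at 5 Hz) for oscillatory
modalities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

OSCILLATORY_WINDOW_S = 1.0


@dataclass
class WaveformRecord:
    """Uniformly sampled airway pressure/flow/volume record.

    Units: time s, pressure cmH2O, flow L/s, volume L.
    """

    time: np.ndarray
    paw: np.ndarray
    flow: np.ndarray
    volume: np.ndarray
    modality: str
    f0: float
    fs: float

    def __post_init__(self) -> None:
        n = len(self.time)
        if not (len(self.paw) == len(self.flow) == len(self.volume) == n):
            raise ValueError("waveform channels must share a length")
        dt = np.diff(self.time)
        if dt.size and not np.allclose(dt, 1.0 / self.fs, rtol=1e-6, atol=1e-9):
            raise ValueError("record must be uniformly sampled at fs")

    @property
    def period(self) -> float:
        """Fundamental ventilatory period T (s)."""
        return 1.0 / self.f0

    @property
    def paw_mean(self) -> float:
        return float(np.mean(self.paw))

    def default_window(self) -> float:
        """One breath for CMV; one second for HFOV/MFOV."""
        return self.period if self.modality.upper() == "CMV" else OSCILLATORY_WINDOW_S


@dataclass
class GasPanel:
    """Arterial blood-gas panel plus body weight."""

    pao2: float  # mmHg
    paco2: float  # mmHg
    fio2: float  # fraction of inspired oxygen, (0, 1]
    spo2: float = np.nan  # %
    weight_kg: float = np.nan

    def __post_init__(self) -> None:
        if not 0 < self.fio2 <= 1:
            raise ValueError("FiO2 must be a fraction in (0, 1]")
        if self.pao2 <= 0 or self.paco2 <= 0:
            raise ValueError("blood-gas tensions must be positive")


def oxygenation_index(panel: GasPanel, paw_mean: float, percent: bool = True) -> float:
    """OI = P_aw_mean * FiO2 / PaO2.

    With ``percent=True`` (default) FiO2 enters as a percentage, giving the
    conventional clinical OI scale (e.g. 12 cmH2O, 40%, 100 mmHg -> 4.8).
    """
    fio2 = panel.fio2 * 100.0 if percent else panel.fio2
    return paw_mean * fio2 / panel.pao2


def _window_slice(record: WaveformRecord, window_s: float | None) -> slice:
    if window_s is None:
        window_s = record.default_window()
    n = int(round(window_s * record.fs))
    if n < 2 or n > len(record.time):
        raise ValueError("analysis window must fit within the record")
    return slice(0, n)


def volume_stats(record: WaveformRecord, window_s: float | None = None):
    """Mean, RMS (mean-removed) and peak-to-peak volume over the window.

    Returns ``(v_mean, v_rms, v_pp)`` in litres; the RMS integral is
    approximated by the mean of squares over samples.
    """
    v = np.asarray(record.volume, dtype=float)[_window_slice(record, window_s)]
    v_mean = float(np.mean(v))
    v_rms = float(np.sqrt(np.mean((v - v_mean) ** 2)))
    v_pp = float(np.max(v) - np.min(v))
    return v_mean, v_rms, v_pp


def ventilatory_cost(v_rms: float, paco2: float, weight_kg: float) -> float:
    """V_C = V_rms^2 * PaCO2 / Wt  (L^2 mmHg kg^-1)."""
    if weight_kg <= 0:
        raise ValueError("weight must be positive")
    return v_rms**2 * paco2 / weight_kg


def driving_pressure_elastance(record: WaveformRecord, window_s: float | None = None):
    """Driving pressure dP_aw = max-min of P_aw, and E_rs = dP_aw / V_pp.

    Dynamic elastance is defined only for CMV records; for oscillatory
    modalities it is returned as NaN (pressure swings there include resistive
    and inertial loads, not alveolar distension).
    """
    sl = _window_slice(record, window_s)
    p = np.asarray(record.paw, dtype=float)[sl]
    dp_aw = float(np.max(p) - np.min(p))
    if record.modality.upper() != "CMV":
        return dp_aw, np.nan
    _, _, v_pp = volume_stats(record, window_s)
    if v_pp == 0:
        return dp_aw, np.nan
    return dp_aw, dp_aw / v_pp


@dataclass
class VentOutcomes:
    """Bundle of per-record ventilation/gas-exchange outcomes."""

    oi: float
    v_rms: float
    v_pp: float
    dp_aw: float
    e_rs: float
    v_c: float
    v_pp_per_kg: float
    v_rms_per_kg: float
    oi_convention: str = "FiO2 in percent"


def evaluate_record(record: WaveformRecord, panel: GasPanel) -> VentOutcomes:
    """All scalar outcomes for one waveform record and its gas panel."""
    _, v_rms, v_pp = volume_stats(record)
    dp_aw, e_rs = driving_pressure_elastance(record)
    oi = oxygenation_index(panel, record.paw_mean)
    v_c = ventilatory_cost(v_rms, panel.paco2, panel.weight_kg)
    return VentOutcomes(
        oi=oi,
        v_rms=v_rms,
        v_pp=v_pp,
        dp_aw=dp_aw,
        e_rs=e_rs,
        v_c=v_c,
        v_pp_per_kg=v_pp / panel.weight_kg,
        v_rms_per_kg=v_rms / panel.weight_kg,
    )
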