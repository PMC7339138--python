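"""Capnograph traces and end-tidal CO2 (PetCO2) extraction.

Expired-gas CO2 partial pressure oscillates at the breathing frequency:
during exhalation it plateaus near the alveolar (end-tidal) value, during
inspiration it drops toward the inspired level (~0 mmHg on room air).  The
per-breath end-tidal values track arterial CO2 and serve as the
scan-specific vascular stimulus once interpolated onto the volume grid and
convolved with the HRF.

End-tidal extraction is operationalized as per-breath local maxima separated
by a refractory interval (default 2 s), linearly interpolated onto the
requested grid with constant extrapolation outside the detected breaths.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import find_peaks

from .paradigm import HRFKernel, Regressor, ValidationError, convolve_to_regressor

__all__ = [
    "RawGasTrace",
    "PetCO2Trace",
    "simulate_capnograph",
    "extract_end_tidal",
    "baseline_normalize",
    "vascular_regressor",
    "save_raw_trace",
    "load_raw_trace",
]


@dataclass(frozen=True)
class RawGasTrace:
    """Continuously sampled CO2 partial pressure (mmHg) on a uniform grid."""

    t_s: np.ndarray = field(repr=False)
    pco2_mmHg: np.ndarray = field(repr=False)

    def __post_init__(self):
        t = np.asarray(self.t_s, dtype=float)
        p = np.asarray(self.pco2_mmHg, dtype=float)
        if t.size != p.size:
            raise ValidationError("time and pressure arrays differ in length")
        if t.size >= 2 and np.any(np.diff(t) <= 0):
            raise ValidationError("time must be strictly increasing")
        if np.any(p < 0):
            raise ValidationError("pco2 must be non-negative")

    @property
    def rate_hz(self) -> float:
        return 1.0 / float(np.median(np.diff(self.t_s)))

    @property
    def duration_s(self) -> float:
        return float(self.t_s[-1] - self.t_s[0])


@dataclass(frozen=True)
class PetCO2Trace:
    """Per-breath end-tidal CO2 values and their uniform-grid interpolation."""

    breath_t_s: np.ndarray = field(repr=False)
    petco2_mmHg: np.ndarray = field(repr=False)
    grid_t_s: np.ndarray = field(repr=False)
    grid_values: np.ndarray = field(repr=False)
    baseline_mmHg: float | None = None

    @property
    def n_breaths(self) -> int:
        return self.breath_t_s.size


def simulate_capnograph(
    envelope,
    breath_period_s: float = 4.0,
    total_s: float = 660.0,
    rate_hz: float = 25.0,
    seed: int = 0,
    plateau_jitter_mmHg: float = 0.2,
    period_jitter_frac: float = 0.05,
    inspired_mmHg: float = 1.0,
) -> RawGasTrace:
    """Simulate a raw capnograph trace under a PetCO2 envelope.

    ``envelope`` maps time (s) to the end-tidal value (mmHg); it may be a
    callable or an array sampled at ``rate_hz``.  Each breath rises to a
    plateau at the envelope value (plus per-breath jitter) then drops toward
    the inspired level.  Deterministic per seed.
    """
    if not (2.0 <= breath_period_s <= 10.0):
        raise ValidationError(f"breath_period_s must be in [2, 10], got {breath_period_s}")
    rng = np.random.default_rng(seed)
    n = int(round(total_s * rate_hz))
    t = np.arange(n) / rate_hz
    if callable(envelope):
        env = np.asarray([envelope(ti) for ti in t], dtype=float)
    else:
        env = np.asarray(envelope, dtype=float)
        if env.size != n:
            raise ValidationError(
                f"envelope array length {env.size} != expected {n} samples"
            )
    if np.any(env <= 0):
        raise ValidationError("envelope must be positive")

    pco2 = np.full(n, inspired_mmHg)
    t0 = 0.0
    while t0 < total_s:
        period = breath_period_s * (1 + period_jitter_frac * rng.standard_normal())
        period = float(np.clip(period, 2.0, 10.0))
        i0 = int(round(t0 * rate_hz))
        i1 = min(int(round((t0 + period) * rate_hz)), n)
        if i1 <= i0:
            break
        mid = t0 + 0.5 * period
        et = float(env[min(int(round(mid * rate_hz)), n - 1)])
        et += plateau_jitter_mmHg * rng.standard_normal()
        phase = (t[i0:i1] - t0) / period
        seg = np.empty(i1 - i0)
        rise = phase < 0.15
        plateau = (phase >= 0.15) & (phase < 0.65)
        fall = phase >= 0.65
        seg[rise] = inspired_mmHg + (et - inspired_mmHg) * (phase[rise] / 0.15)
        seg[plateau] = et
        seg[fall] = inspired_mmHg + (et - inspired_mmHg) * np.exp(
            -(phase[fall] - 0.65) / 0.08
        )
        pco2[i0:i1] = seg
        t0 += period
    pco2 = np.clip(pco2, 0.0, None)
    return RawGasTrace(t_s=t, pco2_mmHg=pco2)


def extract_end_tidal(
    raw: RawGasTrace,
    min_breath_interval_s: float = 2.0,
    grid_t_s: np.ndarray | None = None,
) -> PetCO2Trace:
    """Extract per-breath end-tidal CO2 values as refractory local maxima.

    Peaks must be separated by at least ``min_breath_interval_s`` and have a
    prominence of a quarter of the robust trace range (rejects within-plateau
    ripple).  Values are linearly interpolated onto ``grid_t_s`` (default:
    1-s grid over the trace) with constant extrapolation at the ends.
    """
    p = np.asarray(raw.pco2_mmHg, dtype=float)
    rate = raw.rate_hz
    lo, hi = np.percentile(p, [5, 95])
    prominence = max(0.25 * (hi - lo), 1.0)
    distance = max(int(round(min_breath_interval_s * rate)), 1)
    peaks, _ = find_peaks(p, distance=distance, prominence=prominence)
    if peaks.size < 2:
        raise ValidationError(
            f"only {peaks.size} breath(s) detected; need at least 2"
        )
    breath_t = raw.t_s[peaks]
    petco2 = p[peaks]
    if grid_t_s is None:
        grid_t_s = np.arange(0.0, raw.t_s[-1] + 0.5, 1.0)
    grid_t_s = np.asarray(grid_t_s, dtype=float)
    grid_values = np.interp(grid_t_s, breath_t, petco2)  # constant beyond ends
    return PetCO2Trace(
        breath_t_s=breath_t,
        petco2_mmHg=petco2,
        grid_t_s=grid_t_s,
        grid_values=grid_values,
    )


def baseline_normalize(trace: PetCO2Trace, window_s: float = 100.0) -> PetCO2Trace:
    """Subtract the mean end-tidal level over the first ``window_s`` seconds.

    Mirrors the convention of expressing PetCO2 relative to the baseline
    level (mean value in the first 100 s of the scan).
    """
    t = trace.grid_t_s
    if t[-1] < window_s:
        raise ValidationError(
            f"trace covers {t[-1]:.1f}s, shorter than the {window_s}s window"
        )
    sel = t < window_s
    baseline = float(trace.grid_values[sel].mean())
    return replace(
        trace,
        grid_values=trace.grid_values - baseline,
        petco2_mmHg=trace.petco2_mmHg - baseline,
        baseline_mmHg=baseline,
    )


def vascular_regressor(
    trace: PetCO2Trace,
    hrf: HRFKernel,
    tr_s: float,
    n_vols: int,
    name: str = "co2",
) -> Regressor:
    """Baseline-normalized PetCO2, HRF-convolved, on the volume grid.

    The scan-specific vascular stimulus model: resample the (normalized)
    end-tidal grid trace to the HRF's dt, convolve, sample at the TR grid.
    """
    if trace.baseline_mmHg is None:
        trace = baseline_normalize(trace)
    dt = hrf.dt_s
    t_fine = np.arange(0.0, n_vols * tr_s, dt)
    fine = np.interp(t_fine, trace.grid_t_s, trace.grid_values)
    return convolve_to_regressor(fine, hrf, tr_s, n_vols, name=name)


def save_raw_trace(raw: RawGasTrace, path) -> None:
    """2-column delimited text (time_s, pco2_mmHg) with a one-line header."""
    np.savetxt(
        path,
        np.column_stack([raw.t_s, raw.pco2_mmHg]),
        fmt="%.6g",
        header="time_s\tpco2_mmHg",
        delimiter="\t",
    )


def load_raw_trace(path) -> RawGasTrace:
    arr = np.loadtxt(path, skiprows=1, ndmin=2)
    return RawGasTrace(t_s=arr[:, 0], pco2_mmHg=arr[:, 1])
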