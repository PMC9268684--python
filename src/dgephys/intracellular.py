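"""Current-clamp sweep analysis: F–I curves and first-AP properties.

Mirrors the slice protocol: square current steps (100 pA increments) from a
−70 mV holding potential; firing frequency per step gives the F–I curve, and
single-AP properties (voltage threshold, amplitude, fast AHP, half-amplitude
width) are measured on the first action potential a step evokes.

Conventions (the original protocol leaves these open; all are configurable):
spike onset is where dV/dt first crosses 20 mV/ms with the voltage
subsequently exceeding −20 mV; the AHP is threshold minus the minimum within
10 ms after the peak; half-width is measured at threshold + amplitude/2
(threshold-referenced, not baseline-referenced), with linear interpolation
between samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import NoAPError, ParameterError

__all__ = [
    "CurrentClampSweep",
    "APProperties",
    "detect_spikes_intracellular",
    "fi_curve",
    "ap_properties",
]


@dataclass(frozen=True)
class CurrentClampSweep:
    """One current-clamp sweep: sampled voltage plus the injected step.

    ``step_start_s``/``step_duration_s`` annotate the current-step window;
    when absent the step is assumed to span the whole sweep.
    """

    voltage_mv: np.ndarray
    sampling_rate_hz: float
    injected_current_pa: float
    baseline_mv: float = -70.0
    step_start_s: float | None = None
    step_duration_s: float | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.voltage_mv, dtype=float)
        object.__setattr__(self, "voltage_mv", arr)
        if arr.ndim != 1 or arr.size < 8:
            raise ParameterError("sweep needs a 1-D voltage trace with >= 8 samples")
        if not np.all(np.isfinite(arr)):
            raise ParameterError("sweep contains non-finite samples")
        if not self.sampling_rate_hz > 0:
            raise ParameterError("sampling_rate_hz must be positive")

    @property
    def dt_s(self) -> float:
        return 1.0 / self.sampling_rate_hz

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sampling_rate_hz

    def step_window(self) -> tuple[float, float]:
        """(start_s, end_s) of the current step; whole sweep if unannotated."""
        if self.step_start_s is None or self.step_duration_s is None:
            return 0.0, self.voltage_mv.size * self.dt_s
        return self.step_start_s, self.step_start_s + self.step_duration_s


@dataclass(frozen=True)
class APProperties:
    """First-action-potential properties.

    amplitude = peak − threshold; ahp = threshold − post-peak minimum;
    half_width is the duration at threshold + amplitude/2.
    """

    threshold_mv: float
    amplitude_mv: float
    ahp_mv: float
    half_width_ms: float
    peak_mv: float
    threshold_time_s: float

    def __post_init__(self) -> None:
        if not self.amplitude_mv > 0:
            raise ParameterError("amplitude_mv must be positive for a valid AP")
        if not self.half_width_ms > 0:
            raise ParameterError("half_width_ms must be positive")


def _smoothed_dvdt(sweep: CurrentClampSweep, smooth_ms: float) -> np.ndarray:
    """Central-difference dV/dt (mV/ms), boxcar-smoothed over ``smooth_ms``."""
    dvdt = np.gradient(sweep.voltage_mv, sweep.dt_ms)
    k = int(round(smooth_ms / sweep.dt_ms))
    if k >= 2:
        if k % 2 == 0:
            k += 1
        kernel = np.ones(k) / k
        dvdt = np.convolve(dvdt, kernel, mode="same")
    return dvdt


def detect_spikes_intracellular(
    sweep: CurrentClampSweep,
    dvdt_threshold_mv_per_ms: float = 20.0,
    min_peak_mv: float = -20.0,
    lockout_ms: float = 1.0,
    smooth_ms: float = 0.1,
    confirm_window_ms: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Detect spike onsets in a current-clamp sweep.

    Onset is the first sample where the (optionally smoothed) dV/dt crosses
    the slope criterion from below; a candidate is accepted only when the
    voltage exceeds ``min_peak_mv`` within the confirmation window, and
    detections within the refractory lockout of the previous one are
    discarded.  Returns (onset times in s, onset sample indices); no-spike
    sweeps return empty arrays.
    """
    if dvdt_threshold_mv_per_ms <= 0:
        raise ParameterError("dvdt_threshold_mv_per_ms must be positive")
    v = sweep.voltage_mv
    dvdt = _smoothed_dvdt(sweep, smooth_ms)
    above = dvdt >= dvdt_threshold_mv_per_ms
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    confirm_n = max(1, int(round(confirm_window_ms / sweep.dt_ms)))
    lockout_n = int(round(lockout_ms / sweep.dt_ms))
    accepted: list[int] = []
    for idx in crossings:
        if accepted and idx - accepted[-1] < lockout_n:
            continue
        if v[idx : idx + confirm_n].max(initial=-np.inf) > min_peak_mv:
            accepted.append(int(idx))
    indices = np.asarray(accepted, dtype=int)
    return indices * sweep.dt_s, indices


def fi_curve(sweeps, step_window: tuple[float, float] | None = None, **detect_kwargs) -> pd.DataFrame:
    """Firing frequency versus injected current.

    Frequency is the spike count in the step window divided by the window
    duration, one row per current, ordered by current.  Sweeps must share a
    sampling rate; duplicate currents are aggregated by mean with a warning.
    """
    sweeps = list(sweeps)
    if not sweeps:
        raise ParameterError("no sweeps given")
    rates = {s.sampling_rate_hz for s in sweeps}
    if len(rates) > 1:
        raise ParameterError("sweeps must share a sampling rate")
    rows = []
    for sweep in sweeps:
        lo, hi = step_window if step_window is not None else sweep.step_window()
        if not hi > lo:
            raise ParameterError("step window must have positive duration")
        times, _ = detect_spikes_intracellular(sweep, **detect_kwargs)
        n = int(np.count_nonzero((times >= lo) & (times < hi)))
        rows.append({"current_pa": sweep.injected_current_pa, "frequency_hz": n / (hi - lo)})
    df = pd.DataFrame(rows)
    if df["current_pa"].duplicated().any():
        warnings.warn("duplicate injected currents; aggregating by mean", stacklevel=2)
        df = df.groupby("current_pa", as_index=False)["frequency_hz"].mean()
    return df.sort_values("current_pa", ignore_index=True)


def ap_properties(
    sweep: CurrentClampSweep,
    dvdt_threshold_mv_per_ms: float = 20.0,
    ahp_window_ms: float = 10.0,
    peak_search_ms: float = 5.0,
    smooth_ms: float = 0.1,
) -> APProperties:
    """Measure the four single-AP properties on a sweep's *first* spike.

    Raises :class:`NoAPError` when no spike is detected.
    """
    times, indices = detect_spikes_intracellular(
        sweep, dvdt_threshold_mv_per_ms=dvdt_threshold_mv_per_ms, smooth_ms=smooth_ms
    )
    if indices.size == 0:
        raise NoAPError("no action potential detected in sweep")
    v = sweep.voltage_mv
    i0 = int(indices[0])
    threshold = float(v[i0])
    peak_n = max(2, int(round(peak_search_ms / sweep.dt_ms)))
    seg = v[i0 : i0 + peak_n]
    i_peak = i0 + int(np.argmax(seg))
    peak = float(v[i_peak])
    amplitude = peak - threshold
    if amplitude <= 0:
        raise NoAPError("no positive-going peak after detected onset")
    ahp_n = max(2, int(round(ahp_window_ms / sweep.dt_ms)))
    post_min = float(v[i_peak : i_peak + ahp_n].min())
    ahp = threshold - post_min
    half = threshold + amplitude / 2.0
    t_rise = _cross_time(v, i0, i_peak, half, sweep.dt_s, rising=True)
    t_fall = _cross_time(v, i_peak, min(i_peak + ahp_n, v.size - 1), half, sweep.dt_s, rising=False)
    if t_rise is None or t_fall is None:
        raise NoAPError("could not bracket the half-amplitude crossings")
    return APProperties(
        threshold_mv=threshold,
        amplitude_mv=amplitude,
        ahp_mv=ahp,
        half_width_ms=(t_fall - t_rise) * 1000.0,
        peak_mv=peak,
        threshold_time_s=float(times[0]),
    )


def _cross_time(v: np.ndarray, lo: int, hi: int, level: float, dt: float, rising: bool):
    """Linearly interpolated time where v crosses ``level`` between lo and hi."""
    for i in range(lo, hi):
        a, b = v[i], v[i + 1]
        hit = (a < level <= b) if rising else (a >= level > b)
        if hit:
            frac = 0.0 if b == a else (level - a) / (b - a)
            return (i + frac) * dt
    return None
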