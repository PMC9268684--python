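"""Per-unit discriminative features for extracellular units.

Four features drive the downstream putative cell-type assignment:

* **trough-to-peak latency** (ms) — time from the waveform's negative trough
  (extracellular convention) to the first positive-going local maximum after
  it; narrow (≤ 0.4 ms) waveforms mark putative fast-spiking PV interneurons.
* **burst index** (dimensionless) — ratio of the per-ms inter-spike-interval
  frequency in the 0–10 ms window to that in the 200–300 ms window; values
  above 1.8 mark bursting (putative excitatory) units.
* **AHP derivative metric** (μV/ms) — maximum |dV/dt| of the mean waveform
  after the positive peak.  Working on the first derivative removes the
  amplitude attenuation caused by variable electrode-to-soma distance;
  mossy cells sit low (< 70 μV/ms) and granule cells high (> 70 μV/ms).
* **mean firing rate** (Hz) — spike count over recording duration.

All waveform amplitudes are in μV, waveform-internal times in ms, spike
times in seconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateWaveformError, ParameterError

__all__ = [
    "WaveformTemplate",
    "SpikeTrain",
    "ISIHistogram",
    "UnitFeatures",
    "trough_to_peak_latency",
    "isi_histogram",
    "burst_index",
    "first_derivative",
    "ahp_derivative_metric",
    "mean_firing_rate",
    "extract_features",
]

# quality flags attached to UnitFeatures
FLAG_FEW_SPIKES = "few_spikes"
FLAG_INFINITE_BI = "infinite_burst_index"
FLAG_DEGENERATE_WAVEFORM = "degenerate_waveform"
FLAG_INVERTED_POLARITY = "inverted_polarity"


@dataclass(frozen=True)
class WaveformTemplate:
    """A unit's mean extracellular spike waveform.

    Parameters
    ----------
    samples : array of float
        Amplitudes in μV; at least 16 finite samples.
    sampling_rate_hz : float
        Sampling rate, default 20 kHz (one sample = 0.05 ms).
    """

    samples: np.ndarray
    sampling_rate_hz: float = 20_000.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", arr)
        if arr.ndim != 1 or arr.size < 16:
            raise ParameterError(
                f"waveform needs >= 16 samples in one dimension, got shape {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise ParameterError("waveform contains non-finite samples")
        if not self.sampling_rate_hz > 0:
            raise ParameterError("sampling_rate_hz must be positive")

    @property
    def dt_ms(self) -> float:
        """Sample period in milliseconds."""
        return 1000.0 / self.sampling_rate_hz

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times (seconds) for one unit over a recording span."""

    times_s: np.ndarray
    duration_s: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.times_s, dtype=float)
        object.__setattr__(self, "times_s", arr)
        if not self.duration_s > 0:
            raise ParameterError("duration_s must be positive")
        if arr.size:
            if not np.all(np.isfinite(arr)):
                raise ParameterError("spike times contain non-finite values")
            if arr.min() < 0 or arr.max() > self.duration_s:
                raise ParameterError("spike times must lie in [0, duration_s]")
            if arr.size > 1 and not np.all(np.diff(arr) > 0):
                raise ParameterError("spike times must be strictly increasing")

    @property
    def n_spikes(self) -> int:
        return int(self.times_s.size)

    def isis_ms(self) -> np.ndarray:
        """Successive inter-spike intervals in milliseconds."""
        return np.diff(self.times_s) * 1000.0


@dataclass(frozen=True)
class ISIHistogram:
    """Inter-spike-interval histogram over at least 0–300 ms.

    Intervals at or beyond the covered range are excluded, not clipped, so
    ``counts.sum() <= number of ISIs``.
    """

    bin_width_ms: float
    counts: np.ndarray
    bin_edges_ms: np.ndarray

    def window_count(self, lo_ms: float, hi_ms: float) -> int:
        """Total ISIs in the half-open window [lo_ms, hi_ms).

        The window must align with bin edges.
        """
        edges = self.bin_edges_ms
        lo = int(round(lo_ms / self.bin_width_ms))
        hi = int(round(hi_ms / self.bin_width_ms))
        if not (np.isclose(edges[lo], lo_ms) and np.isclose(edges[hi], hi_ms)):
            raise ParameterError("window does not align with histogram bin edges")
        return int(self.counts[lo:hi].sum())


@dataclass(frozen=True)
class UnitFeatures:
    """Bundle of the four discriminative features plus quality flags."""

    trough_to_peak_ms: float
    burst_index: float
    ahp_uv_per_ms: float
    firing_rate_hz: float
    flags: frozenset = field(default_factory=frozenset)


# ---------------------------------------------------------------------------
# waveform features
# ---------------------------------------------------------------------------


def _parabolic_offset(y_prev: float, y_mid: float, y_next: float) -> float:
    """Sub-sample vertex offset of a parabola through three equidistant points.

    Returns the offset in sample units, clamped to [-0.5, 0.5].
    """
    denom = y_prev - 2.0 * y_mid + y_next
    if denom == 0:
        return 0.0
    delta = 0.5 * (y_prev - y_next) / denom
    return float(np.clip(delta, -0.5, 0.5))


def _locate_trough_peak(
    waveform: WaveformTemplate,
    flip_inverted: bool = True,
    min_peak_fraction: float = 0.5,
) -> tuple[np.ndarray, int, int, bool]:
    """Find trough (global minimum) and the first substantial post-trough local max.

    Returns (possibly flipped samples, trough index, peak index, flipped?).

    ``min_peak_fraction`` guards the "first local maximum" rule against tiny
    noise bumps: only post-trough local maxima rising at least that fraction
    of the largest post-trough excursion above the trough are considered.
    """
    v = waveform.samples
    flipped = False
    if flip_inverted and int(np.argmax(v)) < int(np.argmin(v)):
        warnings.warn(
            "waveform polarity appears inverted (max precedes min); flipping",
            stacklevel=3,
        )
        v = -v
        flipped = True
    trough = int(np.argmin(v))
    if trough == 0 or trough == v.size - 1:
        raise DegenerateWaveformError("global minimum at waveform boundary")
    post = v[trough:]
    best = trough + int(np.argmax(post[1:])) + 1
    if best == v.size - 1:
        raise DegenerateWaveformError("no local maximum after the trough")
    height = v[best] - v[trough]
    if height <= 0:
        raise DegenerateWaveformError("no positive-going peak after the trough")
    peak = None
    for i in range(trough + 1, v.size - 1):
        if v[i] >= v[i + 1] and v[i] > v[i - 1] and (v[i] - v[trough]) >= min_peak_fraction * height:
            peak = i
            break
    if peak is None:
        raise DegenerateWaveformError("no local maximum after the trough")
    return v, trough, peak, flipped


def trough_to_peak_latency(
    waveform: WaveformTemplate,
    interpolate: bool = True,
    flip_inverted: bool = True,
) -> float:
    """Trough-to-peak latency in milliseconds.

    Latency runs from the global minimum (the extracellular trough) to the
    first local maximum after it.  With ``interpolate`` on, both extrema are
    refined to sub-sample precision with a 3-point parabolic fit.

    Raises
    ------
    DegenerateWaveformError
        If the trough sits at a boundary or no positive-going local maximum
        follows it.
    """
    v, trough, peak, _ = _locate_trough_peak(waveform, flip_inverted)
    t_pos = float(trough)
    p_pos = float(peak)
    if interpolate:
        t_pos += _parabolic_offset(v[trough - 1], v[trough], v[trough + 1])
        p_pos += _parabolic_offset(v[peak - 1], v[peak], v[peak + 1])
    return (p_pos - t_pos) * waveform.dt_ms


def first_derivative(waveform: WaveformTemplate) -> np.ndarray:
    """First derivative of the waveform in μV/ms.

    Central differences in the interior, one-sided at the boundaries; the
    output has the same length as the input.
    """
    return np.gradient(waveform.samples, waveform.dt_ms)


_AHP_MODES = ("post_peak_max_abs", "post_peak_max_neg", "tail_max_abs")


def ahp_derivative_metric(
    waveform: WaveformTemplate,
    mode: str = "post_peak_max_abs",
    flip_inverted: bool = True,
) -> float:
    """Afterhyperpolarization metric from the waveform's first derivative, μV/ms.

    Default is the maximum |dV/dt| in the window strictly after the
    post-trough peak.  The exact window/extremum convention is configurable:

    * ``post_peak_max_abs`` — max |dV/dt| after the peak (default)
    * ``post_peak_max_neg`` — magnitude of the most negative dV/dt after the peak
    * ``tail_max_abs`` — max |dV/dt| from the trough onward

    Raises
    ------
    DegenerateWaveformError
        If the post-peak window holds fewer than 3 samples.
    """
    if mode not in _AHP_MODES:
        raise ParameterError(f"mode must be one of {_AHP_MODES}")
    v, trough, peak, _ = _locate_trough_peak(waveform, flip_inverted)
    flipped_wf = WaveformTemplate(v, waveform.sampling_rate_hz)
    deriv = first_derivative(flipped_wf)
    start = trough + 1 if mode == "tail_max_abs" else peak + 1
    window = deriv[start:]
    if window.size < 3:
        raise DegenerateWaveformError("AHP window holds fewer than 3 samples")
    if mode == "post_peak_max_neg":
        return float(max(0.0, -window.min()))
    return float(np.abs(window).max())


# ---------------------------------------------------------------------------
# spike-train features
# ---------------------------------------------------------------------------


def isi_histogram(
    train: SpikeTrain,
    bin_width_ms: float = 1.0,
    range_ms: float = 300.0,
) -> ISIHistogram:
    """Histogram of successive inter-spike intervals over [0, range_ms).

    Intervals at or beyond ``range_ms`` are excluded.  Trains with fewer than
    two spikes yield an all-zero histogram (not an error).
    """
    if not bin_width_ms > 0:
        raise ParameterError("bin_width_ms must be positive")
    if range_ms < 300.0:
        raise ParameterError("histogram must cover at least 0-300 ms")
    n_bins = int(np.ceil(range_ms / bin_width_ms))
    edges = np.arange(n_bins + 1) * bin_width_ms
    isis = train.isis_ms()
    if isis.size == 0:
        counts = np.zeros(n_bins, dtype=int)
    else:
        counts, _ = np.histogram(isis[isis < edges[-1]], bins=edges)
    return ISIHistogram(bin_width_ms=bin_width_ms, counts=counts, bin_edges_ms=edges)


def burst_index(
    train: SpikeTrain,
    normalize_by_width: bool = True,
    early_window_ms: tuple[float, float] = (0.0, 10.0),
    late_window_ms: tuple[float, float] = (200.0, 300.0),
) -> float:
    """Burst index: ISI-frequency ratio of the 0–10 ms to the 200–300 ms window.

    With ``normalize_by_width`` (default) each window count is divided by its
    width in ms, making the index the ratio of mean per-ms ISI frequencies and
    directly comparable to the 1.8 bursting threshold.  The raw-count ratio is
    available with ``normalize_by_width=False``.

    Zero-window rules: an empty early window gives 0 regardless of the late
    window; an empty late window with a populated early window gives +inf.
    Trains with fewer than 2 spikes give 0.
    """
    isis = train.isis_ms()
    e_lo, e_hi = early_window_ms
    l_lo, l_hi = late_window_ms
    n_early = int(np.count_nonzero((isis >= e_lo) & (isis < e_hi)))
    n_late = int(np.count_nonzero((isis >= l_lo) & (isis < l_hi)))
    if normalize_by_width:
        num = n_early / (e_hi - e_lo)
        den = n_late / (l_hi - l_lo)
    else:
        num, den = float(n_early), float(n_late)
    if num == 0:
        return 0.0
    if den == 0:
        return float("inf")
    return num / den


def mean_firing_rate(train: SpikeTrain) -> float:
    """Mean firing rate in Hz: spike count over recording duration."""
    return train.n_spikes / train.duration_s


# ---------------------------------------------------------------------------
# feature bundling
# ---------------------------------------------------------------------------


def extract_features(
    waveform: WaveformTemplate | None,
    train: SpikeTrain,
    interpolate: bool = True,
    ahp_mode: str = "post_peak_max_abs",
    normalize_bi_by_width: bool = True,
) -> UnitFeatures:
    """Compute the full feature bundle for one unit.

    A degenerate waveform does not abort the pipeline: the waveform features
    come back NaN with a ``degenerate_waveform`` flag and the unit is later
    reported unclassifiable.  Trains with < 2 spikes carry a ``few_spikes``
    flag; an infinite burst index is flagged explicitly.
    """
    flags: set[str] = set()
    ttp = float("nan")
    ahp = float("nan")
    if waveform is None:
        flags.add(FLAG_DEGENERATE_WAVEFORM)
    else:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                ttp = trough_to_peak_latency(waveform, interpolate=interpolate)
                ahp = ahp_derivative_metric(waveform, mode=ahp_mode)
            except DegenerateWaveformError:
                flags.add(FLAG_DEGENERATE_WAVEFORM)
        if any("inverted" in str(w.message) for w in caught):
            flags.add(FLAG_INVERTED_POLARITY)
    bi = burst_index(train, normalize_by_width=normalize_bi_by_width)
    if train.n_spikes < 2:
        flags.add(FLAG_FEW_SPIKES)
    if np.isinf(bi):
        flags.add(FLAG_INFINITE_BI)
    rate = mean_firing_rate(train)
    return UnitFeatures(
        trough_to_peak_ms=ttp,
        burst_index=bi,
        ahp_uv_per_ms=ahp,
        firing_rate_hz=rate,
        flags=frozenset(flags),
    )
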