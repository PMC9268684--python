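"""Ground-truthed synthetic data for every stage of the pipeline.

The generators emulate the statistical structure the analysis assumes:

* mean extracellular waveforms whose trough-to-peak latency and post-peak
  derivative metric are closed-form parameters, so feature recovery can be
  checked against analytic ground truth;
* spike trains (Poisson with refractory dead time, bursty, jittered-regular)
  whose inter-spike-interval structure places the burst index on either side
  of the 1.8 threshold by construction;
* cohorts of four unit classes (putative PV, wide interneuron, mossy,
  granule) across the four experimental groups (ND, Res, Sus, Sus+Ket) with
  group-wise firing-rate multipliers encoding the reported effect
  directions — PV rate elevated only in susceptible animals, granule rate
  reduced in susceptible animals, mossy and wide rates flat across
  ND/Res/Sus;
* behavioral tables (social-interaction phase times, sucrose/water volumes)
  that produce both susceptible (SI ratio < 1) and resilient (≥ 1) animals;
* current-clamp sweep sets with triangular-kinetics action potentials and a
  linear frequency–current relation above rheobase.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import ParameterError
from .features import SpikeTrain, WaveformTemplate

__all__ = [
    "WaveformParams",
    "TrainParams",
    "ClassParams",
    "CohortSpec",
    "CohortData",
    "BehaviorGroupEffect",
    "APShape",
    "generate_waveform",
    "generate_spike_train",
    "generate_cohort",
    "generate_behavior",
    "generate_intracellular_sweeps",
    "default_class_params",
    "default_rate_multipliers",
    "default_behavior_effects",
]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# waveforms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WaveformParams:
    """Closed-form template parameters for a mean extracellular waveform.

    ``ahp_slope_uv_per_ms`` is the analytic maximum |dV/dt| after the
    positive peak, i.e. the ground truth for the AHP derivative metric.
    The peak amplitude is tied to the trough (40% of its magnitude).
    """

    trough_to_peak_ms: float
    trough_amplitude_uv: float = -150.0
    ahp_slope_uv_per_ms: float = 80.0
    total_duration_ms: float = 3.0
    sampling_rate_hz: float = 20_000.0
    noise_sd_uv: float = 0.0
    peak_fraction: float = 0.4

    def __post_init__(self) -> None:
        if not self.trough_to_peak_ms > 0:
            raise ParameterError("trough_to_peak_ms must be positive")
        if not self.trough_to_peak_ms < self.total_duration_ms:
            raise ParameterError("trough_to_peak_ms must be below total_duration_ms")
        if not self.trough_amplitude_uv < 0:
            raise ParameterError("trough_amplitude_uv must be negative (extracellular trough)")
        if self.ahp_slope_uv_per_ms < 0:
            raise ParameterError("ahp_slope_uv_per_ms must be nonnegative")
        if not self.sampling_rate_hz > 0:
            raise ParameterError("sampling_rate_hz must be positive")
        if self.noise_sd_uv < 0:
            raise ParameterError("noise_sd_uv must be nonnegative")
        if not 0 < self.peak_fraction <= 1:
            raise ParameterError("peak_fraction must be in (0, 1]")


def _hermite(t: np.ndarray, t0: float, t1: float, y0: float, y1: float, s0: float, s1: float) -> np.ndarray:
    """Cubic Hermite segment on [t0, t1] with endpoint values/slopes."""
    h = t1 - t0
    u = (t - t0) / h
    h00 = 2 * u**3 - 3 * u**2 + 1
    h10 = u**3 - 2 * u**2 + u
    h01 = -2 * u**3 + 3 * u**2
    h11 = u**3 - u**2
    return h00 * y0 + h10 * s0 * h + h01 * y1 + h11 * s1 * h


def generate_waveform(params: WaveformParams, seed=0) -> WaveformTemplate:
    """Synthesize a mean extracellular waveform with analytic ground truth.

    Shape, left to right: flat baseline, cubic-Hermite descent into a
    quadratic trough cap, cubic-Hermite rise, and a Gaussian peak-decay lobe.
    The trough and peak are placed exactly on the sample grid whenever the
    latency is a multiple of the sample period, and both extrema have
    mirror-symmetric ±1-sample neighborhoods, so parabolic sub-sample
    refinement recovers them exactly at zero noise.  The Gaussian decay's
    maximum |dV/dt| equals ``ahp_slope_uv_per_ms`` in closed form.
    """
    h = 1000.0 / params.sampling_rate_hz  # sample period, ms
    ttp = params.trough_to_peak_ms
    if ttp < 3 * h - 1e-9:
        raise ParameterError("trough_to_peak_ms must span at least 3 sample periods")
    n = int(round(params.total_duration_ms / h))
    if n < 16:
        raise ParameterError("waveform would hold fewer than 16 samples")
    a = params.trough_amplitude_uv
    p_amp = params.peak_fraction * abs(a)
    # trough on the sample grid, leaving room for the descent
    t_tr = round(max(0.5, 0.2 * params.total_duration_ms) / h) * h
    t_pk = t_tr + ttp
    if t_pk > (n - 5) * h:
        raise ParameterError("peak too close to the end of the waveform")
    u0 = h  # half-width of the symmetric caps
    s = params.ahp_slope_uv_per_ms
    if s > 0:
        # Gaussian decay p_amp*exp(-u^2/(2 sigma^2)); max |V'| = p_amp e^-.5 / sigma
        sigma = p_amp * math.exp(-0.5) / s
        v_edge = p_amp * math.exp(-(u0**2) / (2 * sigma**2))
        m_edge = p_amp * u0 / sigma**2 * math.exp(-(u0**2) / (2 * sigma**2))
    else:
        sigma = math.inf
        v_edge = p_amp
        m_edge = 0.0
    d0 = min(0.5, t_tr - 2 * h)  # descent duration
    if d0 <= u0:
        raise ParameterError("waveform too short for the descent segment")
    # trough-cap curvature: edge slope = rise secant, capped to keep descent monotone
    sec_rise = (v_edge - a) / max(ttp - 2 * u0, h)
    gamma = min(sec_rise, 2.0 * abs(a) / (d0 - u0)) / u0
    y_cap = a + gamma * u0**2 / 2.0

    t = np.arange(n) * h
    v = np.zeros(n)
    seg = (t >= t_tr - d0) & (t < t_tr - u0)
    v[seg] = _hermite(t[seg], t_tr - d0, t_tr - u0, 0.0, y_cap, 0.0, -gamma * u0)
    seg = np.abs(t - t_tr) <= u0 + 1e-12
    v[seg] = a + gamma * (t[seg] - t_tr) ** 2 / 2.0
    seg = (t > t_tr + u0) & (t < t_pk - u0)
    if np.any(seg):
        v[seg] = _hermite(t[seg], t_tr + u0, t_pk - u0, y_cap, v_edge, gamma * u0, m_edge)
    seg = t >= t_pk - u0 - 1e-12
    if math.isinf(sigma):
        v[seg] = p_amp
    else:
        v[seg] = p_amp * np.exp(-((t[seg] - t_pk) ** 2) / (2 * sigma**2))
    if params.noise_sd_uv > 0:
        v = v + _as_rng(seed).normal(0.0, params.noise_sd_uv, size=n)
    return WaveformTemplate(samples=v, sampling_rate_hz=params.sampling_rate_hz)


# ---------------------------------------------------------------------------
# spike trains
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrainParams:
    """Parameters of a synthetic spike train.

    Modes
    -----
    poisson
        Homogeneous Poisson process with refractory dead time (spikes closer
        than ``refractory_ms`` to the last kept spike are deleted); the kept
        process is renewal with mean ISI = refractory + 1/rate.
    bursty
        Poisson burst onsets (rate ``burst_onset_rate_hz``, default
        rate/spikes_per_burst_mean), geometric within-burst spike counts with
        the stated mean, and intra-burst ISIs jittered around
        ``intra_burst_isi_ms`` — concentrating ISI mass in the 0–10 ms window.
    regular
        Jittered lattice at 1/rate; jitter SD is ``jitter_fraction`` of the
        lattice period.
    """

    mode: str = "poisson"
    rate_hz: float = 10.0
    duration_s: float = 300.0
    burst_onset_rate_hz: float | None = None
    intra_burst_isi_ms: float = 4.0
    spikes_per_burst_mean: float = 3.0
    refractory_ms: float = 1.0
    jitter_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("poisson", "bursty", "regular"):
            raise ParameterError("mode must be poisson, bursty or regular")
        if not self.rate_hz > 0 or not self.duration_s > 0:
            raise ParameterError("rate_hz and duration_s must be positive")
        if self.burst_onset_rate_hz is not None and not self.burst_onset_rate_hz > 0:
            raise ParameterError("burst_onset_rate_hz must be positive")
        if not self.intra_burst_isi_ms > 0 or not self.spikes_per_burst_mean >= 1:
            raise ParameterError("invalid burst parameters")
        if not self.refractory_ms > 0:
            raise ParameterError("refractory_ms must be positive")
        if self.jitter_fraction < 0:
            raise ParameterError("jitter_fraction must be nonnegative")


def _thin_refractory(times: np.ndarray, refractory_s: float) -> np.ndarray:
    """Delete spikes closer than the refractory period to the last kept spike."""
    if times.size == 0:
        return times
    kept = [times[0]]
    for x in times[1:]:
        if x - kept[-1] >= refractory_s:
            kept.append(x)
    return np.asarray(kept)


def generate_spike_train(params: TrainParams, seed=None) -> SpikeTrain:
    """Generate one spike train; see :class:`TrainParams` for the modes.

    ``seed`` overrides ``params.seed`` and may be a Generator (used by the
    cohort generator to draw many trains from one stream).
    """
    rng = _as_rng(params.seed if seed is None else seed)
    dur = params.duration_s
    refr_s = params.refractory_ms / 1000.0
    if params.mode == "poisson":
        n_draw = int(params.rate_hz * dur + 4 * math.sqrt(params.rate_hz * dur) + 16)
        isis = rng.exponential(1.0 / params.rate_hz, size=n_draw)
        times = np.cumsum(isis)
        while times.size and times[-1] < dur:  # pragma: no cover - rare top-up
            extra = rng.exponential(1.0 / params.rate_hz, size=n_draw)
            times = np.concatenate([times, times[-1] + np.cumsum(extra)])
        times = times[times < dur]
    elif params.mode == "regular":
        period = 1.0 / params.rate_hz
        n = int(math.floor(dur * params.rate_hz))
        base = (np.arange(n) + 0.5) * period
        times = base + rng.normal(0.0, params.jitter_fraction * period, size=n)
        times = np.sort(times)
        times = times[(times >= 0) & (times < dur)]
    else:  # bursty
        onset_rate = params.burst_onset_rate_hz or params.rate_hz / params.spikes_per_burst_mean
        n_onsets = rng.poisson(onset_rate * dur)
        onsets = np.sort(rng.uniform(0.0, dur, size=n_onsets))
        p_geom = min(1.0, 1.0 / params.spikes_per_burst_mean)
        chunks = []
        for onset in onsets:
            k = int(rng.geometric(p_geom))
            isis_ms = params.intra_burst_isi_ms * (1.0 + 0.1 * rng.standard_normal(k - 1))
            isis_ms = np.clip(isis_ms, params.refractory_ms, None)
            chunks.append(onset + np.concatenate([[0.0], np.cumsum(isis_ms) / 1000.0]))
        times = np.sort(np.concatenate(chunks)) if chunks else np.empty(0)
        times = times[times < dur]
    times = _thin_refractory(times, refr_s)
    times = times[(times >= 0) & (times <= dur)]
    return SpikeTrain(times_s=times, duration_s=dur)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassParams:
    """Per-class generator distributions: waveform template plus train mode/rate."""

    waveform: WaveformParams
    train_mode: str
    base_rate_hz: float


def default_class_params() -> dict:
    """Default per-class parameters.

    Latencies straddle the 0.4 ms boundary (PV narrow at 0.25 ms, the rest
    wide), mossy/granule AHP slopes straddle 70 μV/ms (45 vs 105), and train
    modes place the burst index on the intended side of 1.8: bursty for the
    excitatory classes, jittered-regular for wide interneurons (burst index
    0), Poisson for PV (fast, irregular — genuinely narrow *and* bursting).
    Base rates follow the fast-spiking-PV > mossy > granule ordering typical
    of dentate recordings.
    """
    return {
        "putative_PV": ClassParams(
            WaveformParams(trough_to_peak_ms=0.25, trough_amplitude_uv=-150.0,
                           ahp_slope_uv_per_ms=90.0, noise_sd_uv=0.25),
            train_mode="poisson", base_rate_hz=25.0,
        ),
        "wide_interneuron": ClassParams(
            WaveformParams(trough_to_peak_ms=0.65, trough_amplitude_uv=-120.0,
                           ahp_slope_uv_per_ms=60.0, noise_sd_uv=0.25),
            train_mode="regular", base_rate_hz=8.0,
        ),
        "putative_mossy": ClassParams(
            WaveformParams(trough_to_peak_ms=0.70, trough_amplitude_uv=-140.0,
                           ahp_slope_uv_per_ms=45.0, noise_sd_uv=0.25),
            train_mode="bursty", base_rate_hz=6.0,
        ),
        "putative_granule": ClassParams(
            WaveformParams(trough_to_peak_ms=0.75, trough_amplitude_uv=-130.0,
                           ahp_slope_uv_per_ms=105.0, noise_sd_uv=0.25),
            train_mode="bursty", base_rate_hz=2.0,
        ),
    }


def default_rate_multipliers() -> dict:
    """Group-wise firing-rate multipliers encoding the reported effect directions.

    PV rate is elevated only in the susceptible group (reversed by ketamine);
    granule rate is reduced in the susceptible group (reversed by ketamine);
    mossy rate rises under ketamine; wide-interneuron rates are flat.
    Unlisted (class, group) pairs default to 1.
    """
    return {
        ("putative_PV", "Sus"): 1.5,
        ("putative_granule", "Sus"): 0.6,
        ("putative_mossy", "Sus+Ket"): 1.5,
    }


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a simulated multi-animal cohort.

    Defaults give 4 classes × 10 units × 4 groups = 160 units (5 animals per
    group, 2 units per class per animal) recorded for 300 s, with unit-to-unit
    log-normal rate scatter (``rate_sigma``) and mild jitter on the waveform
    ground-truth parameters.
    """

    groups: tuple = ("ND", "Res", "Sus", "Sus+Ket")
    animals_per_group: int = 5
    units_per_class_per_animal: int = 2
    duration_s: float = 300.0
    class_params: dict | None = None
    group_rate_multipliers: dict | None = None
    rate_sigma: float = 0.35
    ttp_jitter_ms: float = 0.015
    ahp_sigma: float = 0.08
    amp_jitter: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.groups) == 0:
            raise ParameterError("groups must be nonempty")
        if self.animals_per_group < 1 or self.units_per_class_per_animal < 1:
            raise ParameterError("animals_per_group and units_per_class_per_animal must be >= 1")
        if not self.duration_s > 0:
            raise ParameterError("duration_s must be positive")

    def resolved_class_params(self) -> dict:
        return self.class_params if self.class_params is not None else default_class_params()

    def resolved_multipliers(self) -> dict:
        if self.group_rate_multipliers is not None:
            return self.group_rate_multipliers
        return default_rate_multipliers()


@dataclass
class CohortData:
    """Generated cohort tables in the same dialects the pipeline reads.

    ``waveforms`` is wide (unit_id, sampling_rate_hz, s0..sN), ``spikes`` is
    long (unit_id, time_s), ``metadata`` carries animal/group/duration, and
    ``truth`` records per-unit generator ground truth.
    """

    waveforms: pd.DataFrame
    spikes: pd.DataFrame
    metadata: pd.DataFrame
    truth: pd.DataFrame


def generate_cohort(spec: CohortSpec) -> CohortData:
    """Generate a ground-truthed cohort of units across groups and animals."""
    rng = np.random.default_rng(spec.seed)
    class_params = spec.resolved_class_params()
    multipliers = spec.resolved_multipliers()
    if not class_params:
        raise ParameterError("class_params must be nonempty")
    wf_rows, spike_frames, meta_rows, truth_rows = [], [], [], []
    uid = 0
    for group in spec.groups:
        for a in range(spec.animals_per_group):
            animal_id = f"{group}_m{a:02d}"
            for cls, cp in class_params.items():
                mult = multipliers.get((cls, group), 1.0)
                for _ in range(spec.units_per_class_per_animal):
                    unit_id = f"u{uid:04d}"
                    uid += 1
                    ttp = cp.waveform.trough_to_peak_ms + rng.normal(0.0, spec.ttp_jitter_ms)
                    ttp = max(ttp, 3000.0 / cp.waveform.sampling_rate_hz)
                    ahp = cp.waveform.ahp_slope_uv_per_ms * math.exp(rng.normal(0.0, spec.ahp_sigma))
                    amp = cp.waveform.trough_amplitude_uv * (1.0 + spec.amp_jitter * rng.standard_normal())
                    wp = replace(cp.waveform, trough_to_peak_ms=ttp,
                                 ahp_slope_uv_per_ms=ahp,
                                 trough_amplitude_uv=min(amp, -10.0))
                    wf = generate_waveform(wp, rng)
                    rate = cp.base_rate_hz * mult * math.exp(rng.normal(0.0, spec.rate_sigma))
                    tp = TrainParams(mode=cp.train_mode, rate_hz=rate, duration_s=spec.duration_s)
                    train = generate_spike_train(tp, seed=rng)
                    wf_rows.append(
                        {"unit_id": unit_id, "sampling_rate_hz": wp.sampling_rate_hz,
                         **{f"s{i}": v for i, v in enumerate(wf.samples)}}
                    )
                    spike_frames.append(
                        pd.DataFrame({"unit_id": unit_id, "time_s": train.times_s})
                    )
                    meta_rows.append(
                        {"unit_id": unit_id, "animal_id": animal_id, "group": group,
                         "duration_s": spec.duration_s}
                    )
                    truth_rows.append(
                        {"unit_id": unit_id, "true_class": cls, "true_ttp_ms": ttp,
                         "true_rate_hz": rate, "true_ahp_slope_uv_per_ms": ahp,
                         "animal_id": animal_id, "group": group}
                    )
    return CohortData(
        waveforms=pd.DataFrame(wf_rows),
        spikes=pd.concat(spike_frames, ignore_index=True),
        metadata=pd.DataFrame(meta_rows),
        truth=pd.DataFrame(truth_rows),
    )


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BehaviorGroupEffect:
    """Per-group behavioral generator parameters.

    ``si_scale`` is the median ratio of phase-2 to phase-1 interaction time;
    ``sucrose_scale`` scales median sucrose intake relative to the 3:1
    sucrose:water baseline.
    """

    defeated: bool
    si_scale: float = 1.0
    sucrose_scale: float = 1.0


def default_behavior_effects() -> dict:
    """Group effects emulating the selected experimental populations.

    The Res/Sus labels are post hoc in the real paradigm (animals are split
    on the measured SI ratio); here they name populations drawn with median
    SI ratios above/below 1 so that both phenotypes occur in defeated groups.
    """
    return {
        "ND": BehaviorGroupEffect(defeated=False, si_scale=1.0, sucrose_scale=1.0),
        "Res": BehaviorGroupEffect(defeated=True, si_scale=1.3, sucrose_scale=0.9),
        "Sus": BehaviorGroupEffect(defeated=True, si_scale=0.55, sucrose_scale=0.4),
        "Sus+Ket": BehaviorGroupEffect(defeated=True, si_scale=1.0, sucrose_scale=0.8),
    }


_SI_PHASE_S = 150.0  # each SI phase lasts 150 s
_PHASE1_MEDIAN_S = 60.0
_PHASE_SIGMA = 0.25
_RATIO_SIGMA = 0.35
_SUCROSE_MEDIAN_ML = 3.0
_WATER_MEDIAN_ML = 1.0
_VOLUME_SIGMA = 0.3


def generate_behavior(
    n_per_group: int,
    group_effects: dict | None = None,
    seed=0,
) -> pd.DataFrame:
    """Generate a per-animal behavioral table.

    Phase-1 interaction-zone time is log-normal (median 60 s of the 150 s
    phase); phase-2 time is phase-1 times a log-normal ratio with the group's
    ``si_scale`` median, both clipped to the phase duration.  Sucrose and
    water volumes are log-normal.  Columns: animal_id, group, defeated,
    phase1_s, phase2_s, sucrose_ml, water_ml.
    """
    if n_per_group < 1:
        raise ParameterError("n_per_group must be >= 1")
    rng = _as_rng(seed)
    effects = group_effects if group_effects is not None else default_behavior_effects()
    rows = []
    for group, eff in effects.items():
        for i in range(n_per_group):
            p1 = float(np.clip(_PHASE1_MEDIAN_S * math.exp(rng.normal(0, _PHASE_SIGMA)),
                               1.0, _SI_PHASE_S))
            ratio = eff.si_scale * math.exp(rng.normal(0, _RATIO_SIGMA))
            p2 = float(np.clip(p1 * ratio, 0.5, _SI_PHASE_S))
            suc = _SUCROSE_MEDIAN_ML * eff.sucrose_scale * math.exp(rng.normal(0, _VOLUME_SIGMA))
            wat = _WATER_MEDIAN_ML * math.exp(rng.normal(0, _VOLUME_SIGMA))
            rows.append(
                {"animal_id": f"{group}_b{i:03d}", "group": group,
                 "defeated": bool(eff.defeated), "phase1_s": p1, "phase2_s": p2,
                 "sucrose_ml": float(suc), "water_ml": float(wat)}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# intracellular sweeps
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class APShape:
    """Piecewise-linear action-potential kinetics for synthetic sweeps.

    The spike runs: slow lead ramp from the inter-spike level to
    ``threshold_mv``, fast rise to ``peak_mv``, fall to
    ``threshold_mv - ahp_depth_mv``, then linear recovery.
    """

    threshold_mv: float = -45.0
    peak_mv: float = 35.0
    ahp_depth_mv: float = 15.0
    rise_ms: float = 0.4
    fall_ms: float = 0.6
    lead_ms: float = 2.0
    recover_ms: float = 3.0

    @property
    def amplitude_mv(self) -> float:
        return self.peak_mv - self.threshold_mv

    @property
    def span_ms(self) -> float:
        return self.lead_ms + self.rise_ms + self.fall_ms + self.recover_ms


def generate_intracellular_sweeps(
    step_pa_list=None,
    f_i_slope_hz_per_pa: float = 0.3,
    rheobase_pa: float = 150.0,
    ap_shape: APShape | None = None,
    step_duration_s: float = 0.5,
    sampling_rate_hz: float = 50_000.0,
    pre_s: float = 0.1,
    post_s: float = 0.1,
    baseline_mv: float = -70.0,
    inter_spike_mv: float = -60.0,
    noise_sd_mv: float = 0.1,
    seed=0,
):
    """Generate a current-clamp sweep set with a linear F–I relation.

    Per sweep, the spike count is ``round(max(0, slope × (I − rheobase)) ×
    step_duration)``, with spikes evenly spaced in the step window; AP
    vertices are snapped to the sample grid so recovered properties match the
    shape parameters.  Returns a list of
    :class:`dgephys.intracellular.CurrentClampSweep`.
    """
    from .intracellular import CurrentClampSweep  # local import avoids a cycle

    if step_pa_list is None:
        step_pa_list = [0.0, 100.0, 200.0, 300.0, 400.0, 500.0]
    if any(i < 0 for i in step_pa_list):
        raise ParameterError("injected currents must be nonnegative")
    if f_i_slope_hz_per_pa < 0 or step_duration_s <= 0 or sampling_rate_hz <= 0:
        raise ParameterError("invalid sweep parameters")
    shape = ap_shape or APShape()
    rng = _as_rng(seed)
    dt = 1.0 / sampling_rate_hz
    n_total = int(round((pre_s + step_duration_s + post_s) * sampling_rate_hz))
    step_start = pre_s
    sweeps = []
    for current in step_pa_list:
        v = np.full(n_total, baseline_mv)
        t = np.arange(n_total) * dt
        in_step = (t >= step_start) & (t < step_start + step_duration_s)
        n_spikes = int(round(max(0.0, f_i_slope_hz_per_pa * (current - rheobase_pa)) * step_duration_s))
        capacity = int(step_duration_s * 1000.0 / shape.span_ms)
        n_spikes = min(n_spikes, capacity)
        if current > 0:
            v[in_step] = inter_spike_mv
        for k in range(n_spikes):
            onset = step_start + (k + 0.5) * step_duration_s / n_spikes
            onset = round(onset / dt) * dt
            _insert_ap(v, onset, shape, inter_spike_mv, dt)
        if noise_sd_mv > 0:
            v = v + rng.normal(0.0, noise_sd_mv, size=n_total)
        sweeps.append(
            CurrentClampSweep(
                voltage_mv=v, sampling_rate_hz=sampling_rate_hz,
                injected_current_pa=float(current), baseline_mv=baseline_mv,
                step_start_s=step_start, step_duration_s=step_duration_s,
            )
        )
    return sweeps


def _insert_ap(v: np.ndarray, onset_s: float, shape: APShape, level_mv: float, dt: float) -> None:
    """Overwrite ``v`` in place with one piecewise-linear AP starting at onset."""
    ms = 1e-3
    knots_t = np.array([
        0.0,
        shape.lead_ms,
        shape.lead_ms + shape.rise_ms,
        shape.lead_ms + shape.rise_ms + shape.fall_ms,
        shape.span_ms,
    ]) * ms + onset_s
    # snap knots to the sample grid so vertices are exactly representable
    knots_t = np.round(knots_t / dt) * dt
    knots_v = np.array([
        level_mv,
        shape.threshold_mv,
        shape.peak_mv,
        shape.threshold_mv - shape.ahp_depth_mv,
        level_mv,
    ])
    i0 = int(round(knots_t[0] / dt))
    i1 = int(round(knots_t[-1] / dt))
    i1 = min(i1, v.size - 1)
    if i0 >= v.size or i1 <= i0:
        return
    tt = np.arange(i0, i1 + 1) * dt
    v[i0 : i1 + 1] = np.interp(tt, knots_t, knots_v)
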