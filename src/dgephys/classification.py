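"""Putative cell-type assignment for dentate gyrus units.

Three thresholds drive a staged rule:

1. trough-to-peak latency ≤ 0.4 ms → narrow waveform, putative PV basket cell;
2. otherwise burst index > 1.8 → putative excitatory, further split by the
   AHP derivative metric at 70 μV/ms into putative mossy (< 70) and putative
   granule (≥ 70) cells;
3. otherwise → wide-waveform putative interneuron.

The AHP split point can alternatively be recovered from the data: the AHP
metric of excitatory units is bimodal, and the valley of a kernel density
estimate between the two main modes is used as the threshold.

Units that both satisfy the narrow-latency and bursting criteria are resolved
by a configurable precedence (latency first by default); both orders are
supported because the original rule set does not disambiguate them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .errors import NoBimodalityError, ParameterError
from .features import FLAG_DEGENERATE_WAVEFORM, UnitFeatures

__all__ = [
    "CellClass",
    "ClassifierConfig",
    "classify_unit",
    "detect_bimodal_threshold",
    "classify_cohort",
]


class CellClass(str, Enum):
    """Putative cell-type labels; `unclassifiable` is a first-class outcome."""

    PUTATIVE_PV = "putative_PV"
    WIDE_INTERNEURON = "wide_interneuron"
    PUTATIVE_MOSSY = "putative_mossy"
    PUTATIVE_GRANULE = "putative_granule"
    UNCLASSIFIABLE = "unclassifiable"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds and rule options for the staged classifier.

    ``ahp_tie`` fixes the label at AHP exactly equal to the threshold; the
    source captions ("AHP < 70" / "AHP > 70") leave the boundary open, and
    granule is the documented default.
    """

    ttp_threshold_ms: float = 0.4
    bi_threshold: float = 1.8
    ahp_threshold_uv_per_ms: float = 70.0
    precedence: str = "latency_first"  # or "bi_first"
    ahp_threshold_mode: str = "fixed"  # or "data_driven"
    ahp_tie: str = "granule"  # or "mossy"

    def __post_init__(self) -> None:
        if self.ttp_threshold_ms <= 0 or self.bi_threshold <= 0 or self.ahp_threshold_uv_per_ms <= 0:
            raise ParameterError("classifier thresholds must be strictly positive")
        if self.precedence not in ("latency_first", "bi_first"):
            raise ParameterError("precedence must be 'latency_first' or 'bi_first'")
        if self.ahp_threshold_mode not in ("fixed", "data_driven"):
            raise ParameterError("ahp_threshold_mode must be 'fixed' or 'data_driven'")
        if self.ahp_tie not in ("granule", "mossy"):
            raise ParameterError("ahp_tie must be 'granule' or 'mossy'")


def _split_excitatory(ahp: float, config: ClassifierConfig) -> CellClass:
    if not np.isfinite(ahp):
        return CellClass.UNCLASSIFIABLE
    thr = config.ahp_threshold_uv_per_ms
    if ahp < thr:
        return CellClass.PUTATIVE_MOSSY
    if ahp > thr:
        return CellClass.PUTATIVE_GRANULE
    return CellClass.PUTATIVE_GRANULE if config.ahp_tie == "granule" else CellClass.PUTATIVE_MOSSY


def classify_unit(features: UnitFeatures, config: ClassifierConfig | None = None) -> CellClass:
    """Assign one putative cell-type label to a unit.

    Boundary conventions: latency exactly at 0.4 ms counts as narrow
    (the "latency ≤ 0.4 ms" convention); burst index exactly 1.8 is *not*
    bursting ("higher than 1.8"); AHP exactly at threshold follows
    ``config.ahp_tie``.  Units flagged with a degenerate waveform, or with a
    NaN value in a feature the rule needs, are unclassifiable.
    """
    config = config or ClassifierConfig()
    if FLAG_DEGENERATE_WAVEFORM in features.flags or not np.isfinite(features.trough_to_peak_ms):
        return CellClass.UNCLASSIFIABLE
    if np.isnan(features.burst_index):
        raise ParameterError("burst index missing without a quality flag")
    narrow = features.trough_to_peak_ms <= config.ttp_threshold_ms
    bursting = features.burst_index > config.bi_threshold  # +inf counts as bursting
    if config.precedence == "latency_first":
        if narrow:
            return CellClass.PUTATIVE_PV
        if bursting:
            return _split_excitatory(features.ahp_uv_per_ms, config)
        return CellClass.WIDE_INTERNEURON
    # bi_first
    if bursting:
        return _split_excitatory(features.ahp_uv_per_ms, config)
    if narrow:
        return CellClass.PUTATIVE_PV
    return CellClass.WIDE_INTERNEURON


def detect_bimodal_threshold(
    values,
    bw_method=None,
    grid_size: int = 512,
    valley_ratio: float = 0.9,
) -> float:
    """Recover the split point of a bimodal distribution of AHP metrics.

    A Gaussian kernel density estimate (Scott's plug-in bandwidth by default)
    is evaluated on a regular grid; the two highest local maxima are taken as
    the modes, and the threshold is the midpoint of the minimal-density
    plateau between them (the plateau rule makes the valley well-defined even
    when the inter-mode density underflows to a flat near-zero stretch).

    Bimodality is asserted before returning: the valley density must be at
    most ``valley_ratio`` of the lower mode's density, otherwise
    :class:`NoBimodalityError` is raised and the caller should fall back to
    the fixed 70 μV/ms threshold.

    Requires at least 20 values.
    """
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 20:
        raise ParameterError("need >= 20 finite values for bimodality detection")
    if np.ptp(vals) == 0:
        raise NoBimodalityError("all values identical")
    kde = gaussian_kde(vals, bw_method=bw_method)
    bw = float(kde.factor * vals.std(ddof=1))
    grid = np.linspace(vals.min() - 3 * bw, vals.max() + 3 * bw, grid_size)
    dens = kde(grid)
    interior = dens[1:-1]
    is_max = (interior >= dens[2:]) & (interior > dens[:-2])
    peaks = np.flatnonzero(is_max) + 1
    if peaks.size < 2:
        raise NoBimodalityError("density estimate has fewer than two modes")
    top_two = peaks[np.argsort(dens[peaks])][-2:]
    lo, hi = int(top_two.min()), int(top_two.max())
    between = dens[lo : hi + 1]
    d_min = between.min()
    if d_min > valley_ratio * min(dens[lo], dens[hi]):
        raise NoBimodalityError("no sufficiently deep valley between the two modes")
    plateau = np.flatnonzero(between <= d_min + 1e-3 * dens.max())
    # contiguous plateau containing the argmin
    argmin = int(np.argmin(between))
    run = [argmin]
    for step in (-1, 1):
        i = argmin + step
        while 0 <= i < between.size and between[i] <= d_min + 1e-3 * dens.max():
            run.append(i)
            i += step
    mid = int(round((min(run) + max(run)) / 2))
    del plateau
    return float(grid[lo + mid])


def classify_cohort(
    features_df: pd.DataFrame,
    config: ClassifierConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Label every unit in a feature table and tally class counts.

    Parameters
    ----------
    features_df : DataFrame
        Columns ``unit_id, ttp_ms, burst_index, ahp_uv_per_ms, rate_hz`` and
        optionally ``flags`` (semicolon-joined flag names).
    config : ClassifierConfig
        With ``ahp_threshold_mode='data_driven'`` the AHP split is recovered
        from the AHP values of units reaching the excitatory stage, falling
        back to the fixed threshold when no bimodality is found.

    Returns
    -------
    (labeled DataFrame, summary dict)
        The summary holds per-class counts (always summing to the input
        size), the AHP threshold actually used, and any warnings.
    """
    config = config or ClassifierConfig()
    if features_df is None or len(features_df) == 0:
        raise ParameterError("feature table is empty")
    df = features_df.copy()
    if "flags" not in df.columns:
        df["flags"] = ""
    run_warnings: list[str] = []
    threshold_used = config.ahp_threshold_uv_per_ms
    if config.ahp_threshold_mode == "data_driven":
        stage = []
        for row in df.itertuples(index=False):
            flags = str(row.flags) if isinstance(row.flags, str) else ""
            if FLAG_DEGENERATE_WAVEFORM in flags or not np.isfinite(row.ttp_ms):
                continue
            narrow = row.ttp_ms <= config.ttp_threshold_ms
            bursting = row.burst_index > config.bi_threshold
            reaches_split = (
                bursting if config.precedence == "bi_first" else (not narrow and bursting)
            )
            if reaches_split and np.isfinite(row.ahp_uv_per_ms):
                stage.append(row.ahp_uv_per_ms)
        try:
            threshold_used = detect_bimodal_threshold(stage)
        except (NoBimodalityError, ParameterError) as exc:
            msg = f"data-driven AHP threshold failed ({exc}); using fixed {config.ahp_threshold_uv_per_ms}"
            run_warnings.append(msg)
            warnings.warn(msg, stacklevel=2)
    effective = replace(config, ahp_threshold_uv_per_ms=threshold_used)

    labels = []
    for row in df.itertuples(index=False):
        flag_str = str(row.flags) if isinstance(row.flags, str) else ""
        flags = frozenset(f for f in flag_str.split(";") if f)
        feats = UnitFeatures(
            trough_to_peak_ms=float(row.ttp_ms),
            burst_index=float(row.burst_index),
            ahp_uv_per_ms=float(row.ahp_uv_per_ms),
            firing_rate_hz=float(row.rate_hz),
            flags=flags,
        )
        labels.append(classify_unit(feats, effective).value)
    out = df.copy()
    out["cell_class"] = labels
    out["ahp_threshold_used"] = threshold_used
    counts = {c.value: int(sum(1 for x in labels if x == c.value)) for c in CellClass}
    summary = {
        "n_units": int(len(out)),
        "counts": counts,
        "ahp_threshold_used": float(threshold_used),
        "warnings": run_warnings,
    }
    assert sum(counts.values()) == len(out)
    return out, summary
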