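"""Behavioral scoring for the chronic social defeat paradigm.

Social interaction (SI): two 150 s phases in an open field with a wire-mesh
enclosure — empty in phase 1, holding a novel aggressor in phase 2.  The SI
ratio is phase-2 over phase-1 interaction-zone time; defeated animals with a
ratio below 1 are susceptible, those at or above 1 resilient (the ratio-of-1
boundary is assigned to resilient).

Sucrose preference: sucrose consumed over total fluid consumed, as a
percentage; reduced preference indexes anhedonia-like behavior.

Marker correlations: Pearson product-moment correlation between a per-animal
molecular readout and the SI ratio, with listwise deletion of missing pairs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DGEphysError,
    ParameterError,
    UndefinedCorrelationError,
    UndefinedPreferenceError,
    UndefinedRatioError,
)

__all__ = [
    "SI_PHASE_DURATION_S",
    "si_ratio",
    "assign_phenotype",
    "sucrose_preference",
    "marker_behavior_correlation",
    "score_behavior_table",
]

SI_PHASE_DURATION_S = 150.0

PHENOTYPE_SUSCEPTIBLE = "susceptible"
PHENOTYPE_RESILIENT = "resilient"
PHENOTYPE_NA = "not_applicable"
PHENOTYPE_EXCLUDED = "excluded"


def si_ratio(phase1_zone_time_s: float, phase2_zone_time_s: float) -> float:
    """SI ratio = phase-2 / phase-1 interaction-zone time.

    Raises :class:`UndefinedRatioError` when phase-1 time is zero (such
    records are excluded from phenotype counts rather than mapped to +inf).
    """
    if phase1_zone_time_s < 0 or phase2_zone_time_s < 0:
        raise ParameterError("zone times must be nonnegative")
    if phase1_zone_time_s > SI_PHASE_DURATION_S or phase2_zone_time_s > SI_PHASE_DURATION_S:
        raise ParameterError(f"zone times cannot exceed the {SI_PHASE_DURATION_S:.0f} s phase")
    if phase1_zone_time_s == 0:
        raise UndefinedRatioError("phase-1 interaction time is zero; SI ratio undefined")
    return phase2_zone_time_s / phase1_zone_time_s


def assign_phenotype(si_ratio_value: float, defeated: bool) -> str:
    """Susceptible/resilient split at SI ratio 1 for defeated animals.

    Defeated: ratio < 1 → susceptible, ratio ≥ 1 → resilient (the boundary
    counts as resilient).  Non-defeated animals are ``not_applicable``.
    """
    if not np.isfinite(si_ratio_value) or si_ratio_value < 0:
        raise ParameterError("si_ratio must be a nonnegative finite number")
    if not defeated:
        return PHENOTYPE_NA
    return PHENOTYPE_SUSCEPTIBLE if si_ratio_value < 1.0 else PHENOTYPE_RESILIENT


def sucrose_preference(sucrose_ml: float, water_ml: float) -> float:
    """Sucrose preference percentage: sucrose / (sucrose + water) × 100."""
    if sucrose_ml < 0 or water_ml < 0:
        raise ParameterError("volumes must be nonnegative")
    total = sucrose_ml + water_ml
    if total == 0:
        raise UndefinedPreferenceError("no fluid consumed; preference undefined")
    return 100.0 * (sucrose_ml / total)


def marker_behavior_correlation(marker_values, si_ratios) -> tuple[float, float, int]:
    """Pearson correlation between a molecular marker and the SI ratio.

    Pairs with a missing value in either series are dropped listwise; the
    returned ``n`` is the number of complete pairs actually correlated.
    Returns (r, two-sided p, n).
    """
    x = np.asarray(marker_values, dtype=float)
    y = np.asarray(si_ratios, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("marker and SI series must be 1-D and the same length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = int(x.size)
    if n < 3:
        raise ParameterError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in one series")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue), n


def score_behavior_table(table: pd.DataFrame) -> pd.DataFrame:
    """Score a behavior table in place of the raw phase times and volumes.

    Input columns: ``animal_id, group, defeated, phase1_s, phase2_s`` and
    optionally ``sucrose_ml, water_ml``.  Adds ``si_ratio``, ``phenotype``
    and ``sucrose_pref_pct``.  Records with zero phase-1 time get a NaN ratio
    and the ``excluded`` phenotype; missing or all-zero fluid volumes give a
    NaN preference.  No record is silently dropped.
    """
    required = {"animal_id", "group", "defeated", "phase1_s", "phase2_s"}
    missing = required - set(table.columns)
    if missing:
        raise ParameterError(f"behavior table missing columns: {sorted(missing)}")
    out = table.copy()
    ratios, phenotypes, prefs = [], [], []
    has_fluid = {"sucrose_ml", "water_ml"} <= set(out.columns)
    for row in out.itertuples(index=False):
        try:
            r = si_ratio(float(row.phase1_s), float(row.phase2_s))
            ratios.append(r)
            phenotypes.append(assign_phenotype(r, bool(row.defeated)))
        except UndefinedRatioError:
            ratios.append(float("nan"))
            phenotypes.append(PHENOTYPE_EXCLUDED)
        if has_fluid and np.isfinite(row.sucrose_ml) and np.isfinite(row.water_ml):
            try:
                prefs.append(sucrose_preference(float(row.sucrose_ml), float(row.water_ml)))
            except DGEphysError:
                prefs.append(float("nan"))
        else:
            prefs.append(float("nan"))
    out["si_ratio"] = ratios
    out["phenotype"] = phenotypes
    out["sucrose_pref_pct"] = prefs
    return out
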