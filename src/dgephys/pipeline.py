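"""File formats, run configuration, and the end-to-end pipeline.

All tables are plain CSV/TSV with mandatory headers (see docs/formats.md):
spike times in seconds, waveforms in μV as wide rows (``s0..sN``) with the
sampling rate in a column, metadata joining units to animals/groups.  A run
produces a features TSV, labels TSV, stats TSV, scored behavior CSV, and a
manifest JSON recording the tool version, config hash, seed, per-stage
record counts, and every warning — no record is dropped silently.

Runs are deterministic: identical config + seed give byte-identical outputs
(floats serialized at 12 significant digits).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import score_behavior_table
from .classification import ClassifierConfig, classify_cohort
from .errors import ConfigError, ParameterError, ParseError
from .features import SpikeTrain, WaveformTemplate, extract_features
from .group_stats import compare_firing_by_group
from .synthetic import CohortData, CohortSpec, generate_behavior, generate_cohort

__all__ = [
    "RunConfig",
    "UnitDataset",
    "dataset_from_cohort",
    "read_units",
    "write_cohort",
    "features_table",
    "run_pipeline",
    "load_config",
]

log = logging.getLogger("dgephys")

_FLOAT_FMT = "%.12g"


@dataclass
class UnitDataset:
    """Joined sorted-unit dataset: waveforms + spike trains + metadata.

    ``flags`` maps unit_id to the list of missing components; flagged units
    stay in the dataset and surface in the manifest rather than vanishing.
    """

    waveforms: dict  # unit_id -> WaveformTemplate
    trains: dict  # unit_id -> SpikeTrain
    metadata: pd.DataFrame  # unit_id, animal_id, group, duration_s
    flags: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    @property
    def unit_ids(self) -> list:
        return list(self.metadata["unit_id"])


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = set(cols) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")


def read_units(spike_csv, waveform_csv, metadata_csv, default_duration_s: float | None = None) -> UnitDataset:
    """Read and join the three sorted-unit CSVs.

    Units missing a waveform, spikes, or metadata are flagged (and the run
    continues); a unit_id mismatch across files raises no error but is
    reported in ``warnings`` with counts.  Malformed waveform rows (wrong
    sample count / non-numeric) raise :class:`ParseError` naming the row.
    """
    spikes = pd.read_csv(spike_csv)
    _require_columns(spikes, ["unit_id", "time_s"], spike_csv)
    wf = pd.read_csv(waveform_csv)
    _require_columns(wf, ["unit_id", "sampling_rate_hz"], waveform_csv)
    meta = pd.read_csv(metadata_csv)
    _require_columns(meta, ["unit_id", "animal_id", "group"], metadata_csv)

    sample_cols = [c for c in wf.columns if c.startswith("s") and c[1:].isdigit()]
    sample_cols.sort(key=lambda c: int(c[1:]))
    if len(sample_cols) < 16:
        raise ParseError(f"{waveform_csv}: fewer than 16 waveform sample columns")
    waveforms = {}
    for i, row in wf.iterrows():
        vals = row[sample_cols].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ParseError(f"{waveform_csv}: row {i} (unit {row['unit_id']}) has non-numeric samples")
        waveforms[row["unit_id"]] = WaveformTemplate(vals, float(row["sampling_rate_hz"]))

    if "duration_s" in meta.columns:
        durations = dict(zip(meta["unit_id"], meta["duration_s"]))
    else:
        durations = {}
    fallback = default_duration_s or (float(spikes["time_s"].max()) if len(spikes) else 1.0)
    trains = {}
    for unit_id, g in spikes.groupby("unit_id"):
        dur = float(durations.get(unit_id, fallback))
        times = np.sort(g["time_s"].to_numpy(dtype=float))
        trains[unit_id] = SpikeTrain(times_s=times, duration_s=dur)

    all_ids = sorted(set(waveforms) | set(trains) | set(meta["unit_id"]), key=str)
    warnings_: list[str] = []
    flags: dict = {}
    for uid in all_ids:
        missing = [name for name, has in
                   (("waveform", uid in waveforms), ("spikes", uid in trains),
                    ("metadata", uid in set(meta["unit_id"])))
                   if not has]
        if missing:
            flags[uid] = missing
    if flags:
        warnings_.append(f"{len(flags)} unit(s) missing components: "
                         + "; ".join(f"{u}:{','.join(m)}" for u, m in sorted(flags.items())))
    meta_full = meta.set_index("unit_id").reindex(all_ids).reset_index()
    meta_full["duration_s"] = [durations.get(u, fallback) for u in all_ids]
    return UnitDataset(waveforms=waveforms, trains=trains, metadata=meta_full,
                       flags=flags, warnings=warnings_)


def dataset_from_cohort(cohort: CohortData) -> UnitDataset:
    """Wrap an in-memory synthetic cohort as a joined UnitDataset."""
    sample_cols = [c for c in cohort.waveforms.columns if c.startswith("s") and c[1:].isdigit()]
    sample_cols.sort(key=lambda c: int(c[1:]))
    waveforms = {
        row["unit_id"]: WaveformTemplate(
            row[sample_cols].to_numpy(dtype=float), float(row["sampling_rate_hz"])
        )
        for _, row in cohort.waveforms.iterrows()
    }
    durations = dict(zip(cohort.metadata["unit_id"], cohort.metadata["duration_s"]))
    grouped = {k: np.sort(v["time_s"].to_numpy(dtype=float)) for k, v in cohort.spikes.groupby("unit_id")}
    trains = {
        uid: SpikeTrain(times_s=grouped.get(uid, np.empty(0)), duration_s=float(dur))
        for uid, dur in durations.items()
    }
    return UnitDataset(waveforms=waveforms, trains=trains, metadata=cohort.metadata.copy())


def write_cohort(cohort: CohortData, out_dir, behavior: pd.DataFrame | None = None) -> dict:
    """Write a synthetic cohort to the CSV dialects :func:`read_units` reads.

    Returns the paths written.  Ground truth goes to its own CSV.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "spikes": out / "spikes.csv",
        "waveforms": out / "waveforms.csv",
        "metadata": out / "metadata.csv",
        "truth": out / "truth.csv",
    }
    cohort.spikes.to_csv(paths["spikes"], index=False, float_format=_FLOAT_FMT)
    cohort.waveforms.to_csv(paths["waveforms"], index=False, float_format=_FLOAT_FMT)
    cohort.metadata.to_csv(paths["metadata"], index=False, float_format=_FLOAT_FMT)
    cohort.truth.to_csv(paths["truth"], index=False, float_format=_FLOAT_FMT)
    if behavior is not None:
        paths["behavior"] = out / "behavior.csv"
        behavior.to_csv(paths["behavior"], index=False, float_format=_FLOAT_FMT)
    return {k: str(v) for k, v in paths.items()}


def features_table(dataset: UnitDataset, interpolate: bool = True, **feature_kwargs) -> pd.DataFrame:
    """Extract the per-unit feature table from a joined dataset.

    Units missing a waveform still get spike-train features with a
    ``degenerate_waveform`` flag; units missing spikes are skipped here and
    stay visible through ``dataset.flags``.
    """
    rows = []
    for uid in dataset.unit_ids:
        train = dataset.trains.get(uid)
        if train is None:
            continue
        feats = extract_features(dataset.waveforms.get(uid), train,
                                 interpolate=interpolate, **feature_kwargs)
        rows.append(
            {"unit_id": uid, "ttp_ms": feats.trough_to_peak_ms,
             "burst_index": feats.burst_index, "ahp_uv_per_ms": feats.ahp_uv_per_ms,
             "rate_hz": feats.firing_rate_hz, "flags": ";".join(sorted(feats.flags))}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """End-to-end run configuration.

    Exactly one of ``synthetic`` (CohortSpec field overrides, plus optional
    ``behavior_n_per_group``) or ``inputs`` (paths: spikes, waveforms,
    metadata, optional behavior) must be given.
    """

    synthetic: dict | None = None
    inputs: dict | None = None
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    alpha: float = 0.05
    seed: int | None = None
    out_dir: str = "dgephys_run"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.inputs is None):
            raise ConfigError("exactly one of 'synthetic' or 'inputs' must be set")

    def to_dict(self) -> dict:
        d = {"synthetic": self.synthetic, "inputs": self.inputs,
             "classifier": asdict(self.classifier), "alpha": self.alpha,
             "seed": self.seed, "out_dir": str(self.out_dir), "log_level": self.log_level}
        return d


def load_config(path) -> RunConfig:
    """Load a RunConfig from a JSON or YAML file mirroring the field names."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)  # YAML is a JSON superset
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    cls_cfg = ClassifierConfig(**data.pop("classifier", {}))
    return RunConfig(classifier=cls_cfg, **data)


def _config_hash(config_dict: dict) -> str:
    # hash the scientific configuration only; where outputs land (and how
    # chattily) must not change the recorded identity of a run
    payload = {k: v for k, v in config_dict.items() if k not in ("out_dir", "log_level")}
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def run_pipeline(config: RunConfig) -> Path:
    """Run generation/ingest → features → classification → stats → behavior.

    Returns the output directory.  Deterministic for a fixed config + seed;
    the manifest records counts at every stage and all warnings.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO),
                        format="[dgephys:%(levelname)s] %(message)s")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    if seed is None:
        seed = int(np.random.SeedSequence().entropy % (2**31))
        log.info("no seed given; generated %d", seed)
    manifest: dict = {"tool": "dgephys", "version": __version__, "seed": seed,
                      "counts": {}, "warnings": []}
    cfg_dict = config.to_dict()
    cfg_dict["seed"] = seed
    manifest["config_hash"] = _config_hash(cfg_dict)
    (out / "config.json").write_text(json.dumps(cfg_dict, indent=2, sort_keys=True, default=str) + "\n")

    behavior_df = None
    if config.synthetic is not None:
        log.info("stage simulate: generating synthetic cohort")
        syn = dict(config.synthetic)
        n_behavior = syn.pop("behavior_n_per_group", 10)
        spec = CohortSpec(**{**syn, "seed": seed})
        cohort = generate_cohort(spec)
        behavior_df = generate_behavior(n_behavior, seed=seed + 1)
        paths = write_cohort(cohort, out / "inputs", behavior=behavior_df)
        dataset = read_units(paths["spikes"], paths["waveforms"], paths["metadata"])
    else:
        log.info("stage ingest: reading unit tables")
        inp = config.inputs
        dataset = read_units(inp["spikes"], inp["waveforms"], inp["metadata"])
        if "behavior" in inp:
            behavior_df = pd.read_csv(inp["behavior"])
    manifest["warnings"].extend(dataset.warnings)
    manifest["counts"]["units_in"] = len(dataset.metadata)
    manifest["counts"]["units_flagged_missing"] = len(dataset.flags)

    log.info("stage features: %d units", len(dataset.metadata))
    feats = features_table(dataset)
    _write_tsv(feats, out / "features.tsv")
    manifest["counts"]["units_with_features"] = len(feats)

    log.info("stage classify")
    labeled, summary = classify_cohort(feats, config.classifier)
    labeled = labeled.merge(dataset.metadata[["unit_id", "animal_id", "group"]], on="unit_id", how="left")
    _write_tsv(labeled, out / "labels.tsv")
    (out / "class_counts.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    manifest["counts"]["labeled"] = summary["n_units"] - summary["counts"]["unclassifiable"]
    manifest["counts"]["unclassifiable"] = summary["counts"]["unclassifiable"]
    manifest["warnings"].extend(summary["warnings"])
    if manifest["counts"]["labeled"] + manifest["counts"]["unclassifiable"] != manifest["counts"]["units_with_features"]:
        raise ParameterError("unit bookkeeping violated: labeled + unclassifiable != units in")

    log.info("stage stats")
    import warnings as _w
    with _w.catch_warnings(record=True) as caught:
        _w.simplefilter("always")
        _, tidy = compare_firing_by_group(labeled, alpha=config.alpha)
    manifest["warnings"].extend(str(w.message) for w in caught)
    _write_tsv(tidy, out / "stats.tsv")
    manifest["counts"]["stat_comparisons"] = len(tidy)

    if behavior_df is not None:
        log.info("stage behavior: %d animals", len(behavior_df))
        scored = score_behavior_table(behavior_df)
        scored.to_csv(out / "behavior_scored.csv", index=False, float_format=_FLOAT_FMT)
        manifest["counts"]["behavior_animals"] = len(scored)
        manifest["counts"]["behavior_excluded"] = int((scored["phenotype"] == "excluded").sum())

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    log.info("run complete: %s", out)
    return out
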