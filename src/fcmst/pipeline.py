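"""End-to-end orchestration: simulate -> preprocess -> FC -> MST -> statistics.

A run is driven by a flat config document (YAML-friendly dict).  Outputs are
long-format CSV tables plus a JSON run summary; identical config + seed
reproduces identical numeric content.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bands import DEFAULT_BANDS, BandDefinition
from .connectivity import (
    DEFAULT_EDGE_FRACTION,
    MEASURES,
    connectivity_matrix,
    instantaneous_phase,
)
from .errors import FCMSTError, InvalidSpecError
from .model import MSTComparison
from .mst import METRIC_NAMES, kruskal_max_spanning_tree, mst_metrics
from .preprocessing import (
    average_reference,
    band_decompose,
    broadband_filter,
    extract_epochs,
)
from .recording import Recording, read_recording
from .synthetic import (
    CohortSpec,
    SubjectRecording,
    default_coupling_spec,
    generate_cohort,
)

__all__ = [
    "RunConfig",
    "RunRecord",
    "PipelineStageError",
    "validate_config",
    "run_pipeline",
    "subject_metrics",
    "cohort_metric_table",
]

log = logging.getLogger("fcmst")


class PipelineStageError(FCMSTError, RuntimeError):
    """A pipeline stage failed; carries the stage name and subject id."""

    def __init__(self, stage: str, subject_id: str, cause: Exception):
        self.stage = stage
        self.subject_id = subject_id
        super().__init__(f"stage {stage!r} failed for subject {subject_id!r}: {cause}")


@dataclass
class RunConfig:
    """Flat configuration of one pipeline run.

    Either ``manifest`` points at a cohort on disk (CSV recordings listed in
    a manifest file) or ``simulate`` is true and a synthetic cohort is
    generated from the simulation fields.
    """

    # input
    manifest: str | None = None
    simulate: bool = False
    channels: list | None = None
    fs: float = 512.0
    # simulation design
    n_per_group: int = 20
    n_epochs: int = 75
    epoch_len_s: float = 8.0
    group_effect: dict | None = None
    jitter_sd: float = 0.8
    noise_sd: float = 0.5
    common_source_gain: float = 0.0
    n_channels: int = 19
    carrier_band: tuple = (8.0, 12.0)
    # preprocessing
    broadband: tuple | None = (0.5, 45.0)
    average_reference: bool = True
    reject_uV: float | None = None
    bands: list | None = None  # None -> the six defaults
    # connectivity / MST
    measures: tuple = ("PLI", "PLV")
    mst_per: str = "epoch"
    edge_fraction: float = DEFAULT_EDGE_FRACTION
    # statistics
    fdr_family: str = "all"
    zscore_metrics: bool = True
    alpha: float = 0.05
    # bookkeeping
    seed: int | None = None
    out_dir: str = "fcmst_out"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise InvalidSpecError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc)

    def band_definitions(self) -> tuple[BandDefinition, ...]:
        if self.bands is None:
            return DEFAULT_BANDS
        return tuple(
            BandDefinition(b["name"], float(b["low"]), float(b["high"]))
            for b in self.bands
        )

    def cohort_spec(self) -> CohortSpec:
        base = default_coupling_spec(
            n_channels=self.n_channels,
            band=BandDefinition("carrier", *self.carrier_band),
            jitter_sd=self.jitter_sd,
            common_source_gain=self.common_source_gain,
            noise_sd=self.noise_sd,
        )
        return CohortSpec(
            base=base,
            n_per_group=self.n_per_group,
            group_effect=self.group_effect,
            fs=self.fs,
            epoch_len_s=self.epoch_len_s,
            n_epochs=self.n_epochs,
            seed=0 if self.seed is None else self.seed,
        )


def validate_config(config: RunConfig) -> list[str]:
    """Collect invariant violations as 'path: message' strings (no side effects)."""
    errors = []
    bad_measures = set(config.measures) - set(MEASURES)
    if bad_measures:
        errors.append(
            f"measures: unknown {sorted(bad_measures)}; allowed: {list(MEASURES)}"
        )
    if not config.measures:
        errors.append("measures: at least one measure is required")
    if config.mst_per not in ("epoch", "subject"):
        errors.append(f"mst_per: must be 'epoch' or 'subject', got {config.mst_per!r}")
    if config.fdr_family not in ("all", "per_band"):
        errors.append(
            f"fdr_family: must be 'all' or 'per_band', got {config.fdr_family!r}"
        )
    if config.fs <= 0:
        errors.append(f"fs: must be positive, got {config.fs}")
    else:
        try:
            names = [b.name for b in config.band_definitions()]
            if len(names) != len(set(names)):
                errors.append("bands: duplicate band names")
            for b in config.band_definitions():
                if b.high_hz >= config.fs / 2:
                    errors.append(
                        f"bands.{b.name}: upper edge {b.high_hz} Hz >= fs/2"
                    )
        except Exception as err:
            errors.append(f"bands: {err}")
    if not 0 <= config.edge_fraction < 0.5:
        errors.append(f"edge_fraction: must be in [0, 0.5), got {config.edge_fraction}")
    if config.simulate and config.seed is None:
        errors.append("seed: required when simulation is requested")
    if config.simulate and config.manifest:
        errors.append("manifest: give either a manifest or simulate, not both")
    if not config.simulate and not config.manifest:
        errors.append("manifest: required unless simulate is true")
    if config.n_epochs < 1:
        errors.append(f"n_epochs: must be >= 1, got {config.n_epochs}")
    if config.epoch_len_s <= 0:
        errors.append(f"epoch_len_s: must be positive, got {config.epoch_len_s}")
    return errors


def _tree_metric_values(weights: np.ndarray) -> dict:
    tree = kruskal_max_spanning_tree(weights)
    return mst_metrics(tree).as_dict()


def subject_metrics(
    rec: Recording,
    subject_id: str,
    group: str,
    config: RunConfig,
) -> list[dict]:
    """Run one subject through preprocessing, FC and MST; return metric rows."""
    stage = "preprocess"
    try:
        if config.broadband is not None:
            rec = broadband_filter(rec, *config.broadband)
        if config.average_reference:
            rec = average_reference(rec)
        epochs = extract_epochs(
            rec,
            epoch_len_s=config.epoch_len_s,
            n_epochs=config.n_epochs,
            reject_amplitude=config.reject_uV,
        )
        band_sets = band_decompose(
            epochs,
            bands=config.band_definitions(),
            fs=rec.fs,
            subject_id=subject_id,
            group_label=group,
            channel_labels=rec.channel_labels,
        )
        rows = []
        for band_name, bset in band_sets.items():
            stage = f"connectivity/{band_name}"
            phase_epochs = [
                instantaneous_phase(
                    bset.tensor[e],
                    fs=bset.fs,
                    band=bset.band,
                    edge_fraction=config.edge_fraction,
                )
                for e in range(bset.n_epochs)
            ]
            for measure in config.measures:
                stage = f"mst/{band_name}/{measure}"
                if config.mst_per == "epoch":
                    per_epoch = [
                        _tree_metric_values(
                            connectivity_matrix(ph, measure).weights
                        )
                        for ph in phase_epochs
                    ]
                    values = {
                        name: float(
                            np.nanmean([m[name] for m in per_epoch])
                        ) if not all(
                            np.isnan(m[name]) for m in per_epoch
                        ) else float("nan")
                        for name in METRIC_NAMES
                    }
                else:
                    conn = connectivity_matrix(phase_epochs, measure)
                    values = _tree_metric_values(conn.weights)
                rows.extend(
                    {
                        "subject_id": subject_id,
                        "group": group,
                        "band": band_name,
                        "measure": measure,
                        "metric": name,
                        "value": values[name],
                    }
                    for name in METRIC_NAMES
                )
        return rows
    except FCMSTError:
        raise
    except Exception as err:
        raise PipelineStageError(stage, subject_id, err) from err


def cohort_metric_table(
    cohort: list[SubjectRecording], config: RunConfig
) -> pd.DataFrame:
    """Metric rows for every subject of an in-memory cohort."""
    rows = []
    for subj in cohort:
        rows.extend(
            subject_metrics(subj.recording, subj.subject_id, subj.group, config)
        )
    return pd.DataFrame(rows)


def _load_cohort(config: RunConfig) -> list[SubjectRecording]:
    manifest = Path(config.manifest)
    table = pd.read_csv(manifest)
    cohort = []
    for _, row in table.iterrows():
        fs = float(row["fs"]) if "fs" in table.columns else config.fs
        rec = read_recording(
            manifest.parent / row["file"], fs=fs, channels=config.channels
        )
        cohort.append(
            SubjectRecording(
                str(row["subject_id"]),
                str(row["group"]),
                int(row.get("seed", -1)),
                rec,
            )
        )
    return cohort


@dataclass
class RunRecord:
    """Provenance of one pipeline run."""

    config: dict
    version: str
    row_counts: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    timings_s: dict = field(default_factory=dict)
    significance_counts: dict = field(default_factory=dict)


def run_pipeline(config: RunConfig) -> RunRecord:
    """Execute the configured run and write metrics + statistics tables.

    Writes ``metrics.csv``, ``between_group.csv``, ``within_group.csv`` and
    ``summary.json`` into ``config.out_dir``.  Any stage failure removes
    partial outputs and re-raises with the stage and subject named.
    """
    errors = validate_config(config)
    if errors:
        raise InvalidSpecError("invalid config: " + "; ".join(errors))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs = [
        out_dir / "metrics.csv",
        out_dir / "between_group.csv",
        out_dir / "within_group.csv",
        out_dir / "summary.json",
    ]
    record = RunRecord(config=asdict(config), version=__version__)
    t0 = time.perf_counter()
    try:
        if config.simulate:
            cohort = generate_cohort(config.cohort_spec())
        else:
            cohort = _load_cohort(config)
        record.timings_s["load"] = round(time.perf_counter() - t0, 3)
        log.info("cohort loaded: %d subjects", len(cohort))

        t1 = time.perf_counter()
        metrics = cohort_metric_table(cohort, config)
        record.timings_s["metrics"] = round(time.perf_counter() - t1, 3)
        metrics.to_csv(out_dir / "metrics.csv", index=False, float_format="%.10g")
        record.row_counts["metrics.csv"] = len(metrics)
        log.info("metrics computed: %d rows", len(metrics))

        t2 = time.perf_counter()
        results = MSTComparison(metrics).fit(
            fdr_family=config.fdr_family,
            zscore_metrics=config.zscore_metrics,
            alpha=config.alpha,
        )
        if len(config.measures) < 2:
            record.warnings.append(
                "single measure configured: within-group measure ANOVA skipped"
            )
            log.info("within-group measure ANOVA skipped (one measure)")
        results.between.to_csv(
            out_dir / "between_group.csv", index=False, float_format="%.10g"
        )
        record.row_counts["between_group.csv"] = len(results.between)

        wf = results.within_frame()
        ph = results.posthoc_frame()
        if not wf.empty:
            wf.insert(0, "row_type", "anova")
        if not ph.empty:
            ph.insert(0, "row_type", "posthoc")
        within = pd.concat([wf, ph], ignore_index=True)
        if within.empty:  # keep the file self-describing even with no rows
            within = pd.DataFrame(
                columns=[
                    "row_type", "group", "band", "effect", "F", "df1", "df2",
                    "p", "partial_eta_sq", "metric", "contrast", "t",
                    "p_bonferroni",
                ]
            )
        within.to_csv(
            out_dir / "within_group.csv", index=False, float_format="%.10g"
        )
        record.row_counts["within_group.csv"] = len(within)
        record.timings_s["stats"] = round(time.perf_counter() - t2, 3)
        record.significance_counts = results.significance_counts()
        for cell in results.dropped_cells:
            record.warnings.append(f"non-finite values dropped in cell {cell}")

        # timings are process noise, not results: keep summary.json
        # byte-identical across reruns with the same config + seed
        payload = asdict(record)
        payload.pop("timings_s", None)
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(payload, fh, indent=2, default=str, sort_keys=True)
        return record
    except Exception:
        for path in outputs:
            path.unlink(missing_ok=True)
        raise
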