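"""Dataset I/O and the end-to-end pipeline drivers.

TIFF is the only image dialect (8/16-bit grayscale, one file per channel
per field).  A dataset directory holds the per-field TIFFs, a
``manifest.json`` describing conditions/wells/fields, and — for simulated
data — ``ground_truth.csv`` and the generating config.

``run_simulate`` writes such a directory from a :class:`SimExperiment`;
``run_quantify`` reads one (simulated or real) and produces particle
tables, per-field metrics, replicate summaries, the resolved config and a
log.  Reruns with the same config and inputs are byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import tifffile
from pydantic import BaseModel, ConfigDict, Field

from . import metrics as mx
from .aggregate import AggregateResult, Condition, ExperimentManifest, WellSpec, aggregate
from .field import ImageField
from .preprocess import preprocess
from .segment import (
    binarize,
    class_separation,
    label_components,
    measure_particles,
    otsu_threshold,
    watershed_split,
)
from .simulate import (
    SimConfig,
    simulate_mitochondria,
    simulate_monolayer_field,
    simulate_neurite_field,
)

__all__ = [
    "RunConfig",
    "ConditionSpec",
    "SimExperiment",
    "save_field",
    "load_field",
    "segment_field",
    "run_simulate",
    "run_quantify",
]

logger = logging.getLogger("neuritequant")

#: channel used as the structural ("neurite covered area") reference
STRUCTURE_CHANNEL = "calcein"


class RunConfig(BaseModel):
    """Resolved analysis parameters; serialized beside every run's outputs."""

    model_config = ConfigDict(extra="forbid")

    pixel_size_um: float = Field(default=0.65, gt=0)
    bit_depth: Literal[8, 16] = 16
    # preprocessing
    background_radius_px: int | None = 50
    unsharp_strength: float | None = 0.6
    unsharp_radius_px: float = 2.0
    median_radius_px: int | None = 1
    footprint_decomposition: str | None = "sequence"
    preprocess_structure_channel: bool = True
    # segmentation
    n_bins: int = 256
    min_area_um2: float = 1.0
    min_class_separation: float = 4.0
    manual_threshold: float | None = None
    watershed_channels: list[str] = ["tmre", "cytc", "hoechst"]
    # metrics
    expand_um: float = 3.2
    viable_soma_fraction: float = 0.3
    min_nucleus_area_um2: float = 20.0
    coloc_thresholds: tuple[float, float] | None = None  # None → per-channel Otsu
    # aggregation
    min_fields_per_tech: int = 3
    # misc
    seed: int = 0
    log_level: str = "INFO"

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate_json(Path(path).read_text())


class ConditionSpec(BaseModel):
    """One simulated condition: identity, role, and SimConfig overrides."""

    model_config = ConfigDict(extra="forbid")

    id: str
    role: Literal["sample", "intact_control", "degenerated_control", "untreated_control"] = (
        "sample"
    )
    treatment: str = ""
    dose: float | None = None
    timepoint_h: float | None = None
    overrides: dict = Field(default_factory=dict)


class SimExperiment(BaseModel):
    """A full synthetic experiment: conditions × replicates × fields."""

    model_config = ConfigDict(extra="forbid")

    base: SimConfig = Field(default_factory=SimConfig)
    mode: Literal["neurite", "monolayer"] = "neurite"
    include_mitochondria: bool = False
    conditions: list[ConditionSpec]
    n_biological: int = 3
    n_technical: int = 5
    n_fields: int = 10

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimExperiment":
        return cls.model_validate_json(Path(path).read_text())


def save_field(img: ImageField, path: str | Path) -> None:
    """Write one channel as an 8/16-bit grayscale TIFF."""
    dtype = np.uint8 if img.bit_depth == 8 else np.uint16
    tifffile.imwrite(str(path), np.asarray(img.pixels).astype(dtype))


def load_field(
    path: str | Path,
    pixel_size: float,
    bit_depth: int,
    channel: str = "",
    field_id: str = "",
    well_id: str = "",
    condition_id: str = "",
) -> ImageField:
    pixels = tifffile.imread(str(path))
    return ImageField(
        pixels=pixels,
        pixel_size=pixel_size,
        bit_depth=bit_depth,
        channel=channel,
        field_id=field_id,
        well_id=well_id,
        condition_id=condition_id,
    )


def _tiff_name(condition_id: str, well_id: str, field_id: str, channel: str) -> str:
    return f"{condition_id}__{well_id}__{field_id}__{channel}.tif"


def _field_seed(base_seed: int, *indices: int) -> int:
    """Stable per-field seed derived from the experiment seed."""
    ss = np.random.SeedSequence([int(base_seed), *[int(i) for i in indices]])
    return int(ss.generate_state(1)[0] % (2**31))


def run_simulate(experiment: SimExperiment, outdir: str | Path) -> Path:
    """Write a complete simulated dataset directory.

    Per field and channel one TIFF, plus ``ground_truth.csv`` (one row per
    field, and ``mito_records.csv`` when mitochondria are simulated),
    ``manifest.json`` and the generating ``sim_experiment.json``.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    gt_rows: list[dict] = []
    mito_tables: list[pd.DataFrame] = []
    wells: list[WellSpec] = []
    conditions: list[Condition] = []

    for ci, spec in enumerate(experiment.conditions):
        conditions.append(
            Condition(
                id=spec.id,
                treatment=spec.treatment,
                dose=spec.dose,
                timepoint_h=spec.timepoint_h,
                role=spec.role,
            )
        )
        cfg_dict = experiment.base.model_dump()
        cfg_dict.update(spec.overrides)
        for b in range(1, experiment.n_biological + 1):
            for t in range(1, experiment.n_technical + 1):
                well_id = f"{spec.id}_b{b}_t{t}"
                field_ids = [f"f{f}" for f in range(1, experiment.n_fields + 1)]
                wells.append(
                    WellSpec(
                        well_id=well_id,
                        condition_id=spec.id,
                        biological_replicate=b,
                        technical_replicate=t,
                        fields=field_ids,
                    )
                )
                for f, field_id in enumerate(field_ids, start=1):
                    cfg = SimConfig(
                        **{**cfg_dict, "seed": _field_seed(experiment.base.seed, ci, b, t, f)}
                    )
                    if experiment.mode == "monolayer":
                        channels, gt = simulate_monolayer_field(
                            cfg, field_id=field_id, well_id=well_id, condition_id=spec.id
                        )
                    else:
                        channels, gt = simulate_neurite_field(
                            cfg, field_id=field_id, well_id=well_id, condition_id=spec.id
                        )
                        if experiment.include_mitochondria:
                            mito_channels, records = simulate_mitochondria(
                                cfg,
                                gt.skeletons,
                                field_id=field_id,
                                well_id=well_id,
                                condition_id=spec.id,
                            )
                            channels.update(mito_channels)
                            records.insert(0, "condition_id", spec.id)
                            records.insert(1, "well_id", well_id)
                            records.insert(2, "field_id", field_id)
                            mito_tables.append(records)
                    for channel, img in channels.items():
                        # an annexin channel with nothing in it carries no
                        # information; don't write (or later quantify) it
                        if channel == "annexin" and cfg.annexin_positive_fraction == 0:
                            continue
                        save_field(img, out / _tiff_name(spec.id, well_id, field_id, channel))
                    gt_rows.append(
                        {
                            "condition_id": spec.id,
                            "well_id": well_id,
                            "field_id": field_id,
                            "biological_replicate": b,
                            "technical_replicate": t,
                            **gt.summary_row(),
                        }
                    )

    manifest = ExperimentManifest(conditions=conditions, wells=wells)
    manifest.to_json(out / "manifest.json")
    pd.DataFrame(gt_rows).to_csv(out / "ground_truth.csv", index=False)
    if mito_tables:
        pd.concat(mito_tables, ignore_index=True).to_csv(
            out / "mito_records.csv", index=False
        )
    experiment.to_json(out / "sim_experiment.json")
    return out


# ---------------------------------------------------------------------------
# quantification


def _preprocess_for(img: ImageField, channel: str, cfg: RunConfig) -> ImageField:
    if channel == STRUCTURE_CHANNEL and not cfg.preprocess_structure_channel:
        return img
    return preprocess(
        img,
        background_radius_px=cfg.background_radius_px,
        unsharp_strength=cfg.unsharp_strength,
        unsharp_radius_px=cfg.unsharp_radius_px,
        median_radius_px=cfg.median_radius_px,
        decomposition=cfg.footprint_decomposition,
    )


def segment_field(
    img: ImageField, channel: str | None = None, cfg: RunConfig | None = None
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Preprocess and segment one channel with the standard per-field route.

    Convenience wrapper over the pipeline internals: preprocessing chain →
    Otsu (with the signal-free-channel guard) → watershed or plain
    components depending on the channel → particle measurement.  Returns
    (mask, labels, particle table).
    """
    return _segment_channel(img, channel or img.channel, cfg or RunConfig())


def _segment_channel(
    img: ImageField, channel: str, cfg: RunConfig
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """(mask, labels, particle table) for one channel; empty on constant image."""
    pre = _preprocess_for(img, channel, cfg)
    empty = np.zeros(img.shape, dtype=bool)
    try:
        threshold = (
            cfg.manual_threshold
            if cfg.manual_threshold is not None
            else otsu_threshold(pre, cfg.n_bins)
        )
    except ValueError:
        return empty, empty.astype(np.int32), measure_particles(empty.astype(np.int32), img)
    if (
        cfg.manual_threshold is None
        and class_separation(pre, threshold) < cfg.min_class_separation
    ):
        # signal-free channel: Otsu merely bisected the noise distribution
        return empty, empty.astype(np.int32), measure_particles(empty.astype(np.int32), img)
    mask = binarize(pre, threshold)
    if channel in cfg.watershed_channels:
        labels = watershed_split(mask)
    else:
        labels = label_components(mask)
    table = measure_particles(labels, img, min_area_um2=cfg.min_area_um2)
    return mask, labels, table


def _annexin_background(annexin_mask: np.ndarray) -> np.ndarray:
    """Single unspecific-background region: pixels away from any signal."""
    from skimage import morphology

    return ~morphology.dilation(annexin_mask, morphology.disk(5))


def run_quantify(
    config: RunConfig,
    manifest: ExperimentManifest,
    images_dir: str | Path,
    outdir: str | Path,
) -> Path:
    """Quantify a dataset directory end to end.

    Per field: preprocessing → segmentation → metrics.  The calcein
    (structure) channel yields object count/mean area and the neurite-area
    denominator; TMRE/cytochrome-c channels yield mitochondrial counts,
    densities and shape fractions; the annexin channel yields
    background-corrected integrated intensity and Manders coefficients
    against calcein; hoechst+calcein fields yield monolayer viability and
    neurite area.  Degeneration indices are anchored per biological
    replicate to the designated intact / fully-degenerated controls, and
    per-field rows are collapsed to technical-, biological- and
    condition-level tables.

    Unreadable images are flagged in ``qc.csv`` and the run continues; a
    malformed manifest aborts.
    """
    images = Path(images_dir)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    log_path = out / "quantify.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(config.log_level)

    particle_tables: list[pd.DataFrame] = []
    metric_rows: list[dict] = []
    qc_rows: list[dict] = []

    try:
        for well in sorted(manifest.wells, key=lambda w: w.well_id):
            for field_id in well.fields:
                key = {
                    "condition_id": well.condition_id,
                    "well_id": well.well_id,
                    "field_id": field_id,
                    "biological_replicate": well.biological_replicate,
                    "technical_replicate": well.technical_replicate,
                }
                channels: dict[str, ImageField] = {}
                flagged = False
                for channel in ("calcein", "annexin", "tmre", "cytc", "hoechst"):
                    path = images / _tiff_name(
                        well.condition_id, well.well_id, field_id, channel
                    )
                    if not path.exists():
                        continue
                    try:
                        channels[channel] = load_field(
                            path,
                            pixel_size=config.pixel_size_um,
                            bit_depth=config.bit_depth,
                            channel=channel,
                            **{
                                "field_id": field_id,
                                "well_id": well.well_id,
                                "condition_id": well.condition_id,
                            },
                        )
                    except Exception as exc:  # unreadable image: flag, continue
                        logger.error("unreadable image %s: %s", path.name, exc)
                        qc_rows.append({**key, "channel": channel, "problem": str(exc)})
                        flagged = True
                if not channels or flagged:
                    if not channels:
                        qc_rows.append({**key, "channel": "", "problem": "no images found"})
                    continue

                rows = _quantify_field(channels, key, config, particle_tables)
                metric_rows.extend(rows)
    finally:
        logger.removeHandler(handler)
        handler.close()

    field_metrics = pd.DataFrame(
        metric_rows,
        columns=[
            "condition_id", "well_id", "field_id",
            "biological_replicate", "technical_replicate", "metric", "value",
        ],
    )
    field_metrics = _normalize_metrics(field_metrics, manifest)
    field_metrics = field_metrics.sort_values(
        ["metric", "condition_id", "biological_replicate", "technical_replicate", "field_id"]
    ).reset_index(drop=True)

    summary: AggregateResult | None = None
    if not field_metrics.empty:
        summary = aggregate(
            manifest, field_metrics, min_fields_per_tech=config.min_fields_per_tech
        )

    if particle_tables:
        pd.concat(particle_tables, ignore_index=True).to_csv(
            out / "particles.csv", index=False
        )
    field_metrics.to_csv(out / "field_metrics.csv", index=False)
    if summary is not None:
        summary.technical.to_csv(out / "technical.csv", index=False)
        summary.biological.to_csv(out / "biological.csv", index=False)
        summary.condition.to_csv(out / "condition_summary.csv", index=False)
        summary.excluded.to_csv(out / "excluded.csv", index=False)
    pd.DataFrame(qc_rows, columns=[
        "condition_id", "well_id", "field_id", "biological_replicate",
        "technical_replicate", "channel", "problem",
    ]).to_csv(out / "qc.csv", index=False)
    config.to_json(out / "resolved_config.json")
    return out


def _quantify_field(
    channels: dict[str, ImageField],
    key: dict,
    config: RunConfig,
    particle_tables: list[pd.DataFrame],
) -> list[dict]:
    rows: list[dict] = []

    def add(metric: str, value: float) -> None:
        rows.append({**key, "metric": metric, "value": value})

    structure_mask = None
    if "calcein" in channels and "hoechst" not in channels:
        mask, _, table = _segment_channel(channels["calcein"], "calcein", config)
        structure_mask = mask
        table = table.copy()
        for col, val in key.items():
            table[col] = val
        particle_tables.append(table)
        add("raw_object_count", float(len(table)))
        add(
            "raw_mean_object_area_um2",
            float(table["area_um2"].mean()) if len(table) else np.nan,
        )

    for mito_channel in ("tmre", "cytc"):
        if mito_channel not in channels:
            continue
        _, _, table = _segment_channel(channels[mito_channel], mito_channel, config)
        add(f"{mito_channel}_count", float(len(table)))
        if structure_mask is not None and structure_mask.any():
            add(
                f"{mito_channel}_density_per_um2",
                mx.mito_density(table, structure_mask, config.pixel_size_um),
            )
        if mito_channel == "cytc" and len(table):
            stats = mx.classify_shapes(table)
            add("fraction_round", stats.fraction_round)
            add("fraction_intermediate", stats.fraction_intermediate)
            add("fraction_elongated", stats.fraction_elongated)

    if "annexin" in channels and "calcein" in channels:
        annexin = channels["annexin"]
        mask, _, _ = _segment_channel(annexin, "annexin", config)
        # a signal-free annexin channel yields an empty mask above; skip the
        # colocalization metrics rather than correlating noise
        if mask.any():
            background = _annexin_background(mask)
            if background.any():
                add(
                    "annexin_integrated_intensity",
                    mx.integrated_intensity(annexin, mask, background),
                )
            try:
                coloc = mx.manders(annexin, channels["calcein"], config.coloc_thresholds)
                add("manders_m1", coloc.m1)
                add("manders_m2", coloc.m2)
            except ValueError as exc:
                logger.warning("manders skipped for %s: %s", key["field_id"], exc)

    if "hoechst" in channels and "calcein" in channels:
        try:
            scores = mx.monolayer_scores(
                channels["calcein"],
                channels["hoechst"],
                expand_um=config.expand_um,
                viable_soma_fraction=config.viable_soma_fraction,
                min_nucleus_area_um2=config.min_nucleus_area_um2,
            )
            add("raw_viability", scores.raw_viability)
            add("neurite_area_um2", scores.neurite_area_um2)
        except ValueError as exc:
            logger.warning("monolayer scoring failed for %s: %s", key["field_id"], exc)
    return rows


def _normalize_metrics(
    field_metrics: pd.DataFrame, manifest: ExperimentManifest
) -> pd.DataFrame:
    """Add control-anchored metric rows, per biological replicate.

    * integrity_pct / fragmentation_pct from the intact / degenerated
      controls (structure channel);
    * viability_pct_of_control, neurite_area_pct_of_control and
      tmre_density_pct_of_control from the untreated/intact control.
    """
    if field_metrics.empty:
        return field_metrics
    out = [field_metrics]
    roles = {c.id: c.role for c in manifest.conditions}
    fm = field_metrics

    def control_mean(metric: str, role: str, bio: int) -> float:
        ids = [cid for cid, r in roles.items() if r == role]
        sel = fm[
            (fm["metric"] == metric)
            & (fm["biological_replicate"] == bio)
            & (fm["condition_id"].isin(ids))
        ]["value"]
        return float(sel.mean()) if len(sel) else np.nan

    norm_specs = [
        ("raw_mean_object_area_um2", "intact_control", "integrity_pct"),
        ("raw_object_count", "degenerated_control", "fragmentation_pct"),
        ("raw_viability", "untreated_control", "viability_pct_of_control"),
        ("neurite_area_um2", "untreated_control", "neurite_area_pct_of_control"),
        ("tmre_density_per_um2", "intact_control", "tmre_density_pct_of_control"),
    ]
    for raw_metric, role, name in norm_specs:
        sub = fm[fm["metric"] == raw_metric]
        if sub.empty or not any(r == role for r in roles.values()):
            continue
        anchors = {
            bio: control_mean(raw_metric, role, bio)
            for bio in sub["biological_replicate"].unique()
        }
        normalized = sub.copy()
        normalized["metric"] = name
        normalized["value"] = [
            100.0 * v / anchors[b] if anchors.get(b) and anchors[b] > 0 else np.nan
            for v, b in zip(sub["value"], sub["biological_replicate"])
        ]
        out.append(normalized)
    return pd.concat(out, ignore_index=True)
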