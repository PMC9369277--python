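"""File-based orchestration: simulate -> segment -> quantify -> score -> compare.

Artifacts per run: per-field density records, per-specimen aggregates, IHS
records, comparison reports (CSV + JSON), the resolved configuration (YAML)
and a log file. Reruns with the same configuration and seed are
byte-identical for every tabular artifact.
"""
from __future__ import annotations

import filecmp
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import ihs as ihs_mod
from . import stats as stats_mod
from .config import PipelineConfig, SegmentationParams, QuantParams, IHSParams, TissueType
from .io import CHANNELS, ChannelError, ChannelStack, read_field
from .quantify import (
    DensityRecord,
    VesselObject,
    classify_maturity,
    compute_densities,
    extract_vessels,
)
from .segmentation import (
    BinaryMask,
    CompartmentMasks,
    binarize_channel,
    build_compartment_masks,
    clean_mask,
    label_objects,
)
from .synthetic import generate_cohort, paper_like_cohort

log = logging.getLogger(__name__)

MARKER_CHANNELS = ("CD31", "aSMA", "PDPN", "CD10", "DAPI")


class PipelineError(RuntimeError):
    """Pipeline failure; the message names the failing stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"{stage}: {message}")
        self.stage = stage


def _binarize(stack: ChannelStack, channel: str, seg: SegmentationParams, aliases) -> BinaryMask:
    """Binary layer for one channel; a constant plane means no signal."""
    fixed = seg.fixed_thresholds.get(channel)
    if seg.method == "fixed" or fixed is not None:
        if fixed is None:
            raise PipelineError("segmentation", f"fixed threshold for {channel} not configured")
        return binarize_channel(stack, channel, "fixed", fixed, aliases)
    try:
        return binarize_channel(
            stack, channel, "otsu", aliases=aliases,
            min_class_separation=seg.min_class_separation,
        )
    except ValueError:
        # constant plane: no contrast to threshold; a bright constant plane is
        # a uniformly stained marker, a dark one is marker-free
        plane = np.asarray(stack.plane(channel, aliases), float)
        log.warning("%s: channel %s has constant intensity %g; using mid-range threshold",
                    stack.field_id, channel, plane.flat[0])
        return BinaryMask(plane >= 128.0, channel, "otsu", 128.0)


@dataclass
class SegmentedField:
    layers: Dict[str, BinaryMask]  # cleaned binary layer per marker
    compartments: CompartmentMasks
    thresholds: Dict[str, float]


def segment_field(stack: ChannelStack, seg: SegmentationParams, aliases=None) -> SegmentedField:
    """Binarize and clean all marker layers and build the compartment masks."""
    px = stack.pixel_um
    min_px = seg.min_object_px(px)
    close_px = seg.closing_radius_px(px)
    raw = {ch: _binarize(stack, ch, seg, aliases) for ch in MARKER_CHANNELS}
    layers = {ch: clean_mask(m, min_px, close_px) for ch, m in raw.items()}
    compartments = build_compartment_masks(
        raw["CD10"], raw["aSMA"], layers["DAPI"],
        vessel_masks=(layers["CD31"], layers["PDPN"]),
        min_object_px=min_px,
        closing_radius_px=close_px,
        gland_min_dapi_fraction=seg.gland_min_dapi_fraction,
        small_hole_max_px=seg.small_hole_max_px(px),
    )
    return SegmentedField(
        layers=layers,
        compartments=compartments,
        thresholds={ch: m.threshold_used for ch, m in raw.items()},
    )


def quantify_field(
    stack: ChannelStack,
    seg: SegmentedField,
    quant: QuantParams,
    connectivity: int = 8,
) -> Tuple[List[DensityRecord], List[VesselObject]]:
    """Vessel objects, maturity calls and density records for one field."""
    px = stack.pixel_um
    cd31_objects = label_objects(seg.layers["CD31"], connectivity)
    vessels = extract_vessels(
        cd31_objects, seg.layers["PDPN"], seg.compartments, px,
        min_area_um2=quant.min_area_um2, lymph_overlap_cut=quant.lymph_overlap_cut,
    )
    dil_px = quant.maturity_dilation_px(px)
    vessels = [
        classify_maturity(v, seg.layers["aSMA"], dil_px, quant.maturity_overlap_cut)
        if v.vessel_class == "blood" else v
        for v in vessels
    ]
    records = compute_densities(
        vessels, seg.compartments, seg.layers["CD31"], seg.layers["PDPN"], px,
        specimen_id=stack.specimen_id, field_id=stack.field_id,
    )
    return records, vessels


def score_field(stack: ChannelStack, seg: SegmentedField, params: IHSParams, aliases=None):
    return ihs_mod.score_field(
        stack, seg.compartments,
        vegf_threshold=params.vegf_threshold,
        cell_radius_px=params.cell_radius_px(stack.pixel_um),
        dapi_threshold=params.dapi_threshold,
        calibration=params.calibration,
        aliases=aliases,
    )


def analyze_stack(stack: ChannelStack, cfg: PipelineConfig):
    """Segment, quantify and score one field; returns (densities, ihs records)."""
    seg = segment_field(stack, cfg.segmentation, cfg.channel_aliases or None)
    densities, _ = quantify_field(stack, seg, cfg.quantification, cfg.segmentation.connectivity)
    scores = score_field(stack, seg, cfg.ihs, cfg.channel_aliases or None)
    return densities, scores


PRIMARY_COMPARTMENT = {
    "eutopic_endometrium": "stroma",
    "ectopic_endometrium": "stroma",
    "control_endometrium": "stroma",
    "myometrium": "myometrium",
}


def build_outcome_table(
    field_df: pd.DataFrame, metadata: pd.DataFrame, ihs_df: Optional[pd.DataFrame] = None
) -> pd.DataFrame:
    """Specimen-level outcome table: pooled primary-compartment outcomes + IHS.

    Pooling is total count over total area across fields (percent areas
    pool area-weighted, the mature ratio as total mature / total blood).
    The ``ihs_score`` column carries the primary compartment's IHS
    (stroma for endometrial samples, myometrium for myometrium samples);
    gland IHS is kept in ``ihs_glands_score``.
    """
    grp = field_df.groupby(["specimen_id", "compartment"], sort=True)
    agg = grp.agg(
        n_fields=("field_id", "nunique"),
        compartment_area_mm2=("compartment_area_mm2", "sum"),
        blood_count=("blood_count", "sum"),
        lymph_count=("lymph_count", "sum"),
        mature_count=("mature_count", "sum"),
        _cd31_wt=("_cd31_weighted", "sum"),
        _pdpn_wt=("_pdpn_weighted", "sum"),
    ).reset_index()
    agg["bvd_vessels_per_mm2"] = agg["blood_count"] / agg["compartment_area_mm2"]
    agg["lvd_vessels_per_mm2"] = agg["lymph_count"] / agg["compartment_area_mm2"]
    agg["pct_cd31_area_pct"] = agg["_cd31_wt"] / agg["compartment_area_mm2"]
    agg["pct_pdpn_area_pct"] = agg["_pdpn_wt"] / agg["compartment_area_mm2"]
    agg["mature_ratio_fraction"] = np.where(
        (agg["compartment"] == "stroma") & (agg["blood_count"] > 0),
        agg["mature_count"] / agg["blood_count"],
        np.nan,
    )
    agg = agg.drop(columns=["_cd31_wt", "_pdpn_wt"])

    meta = metadata.set_index("specimen_id")
    agg["tissue_type"] = agg["specimen_id"].map(meta["tissue_type"])
    agg["_primary"] = agg["tissue_type"].map(PRIMARY_COMPARTMENT)
    table = agg[agg["compartment"] == agg["_primary"]].drop(columns=["_primary"]).copy()
    for col in ("group", "cycle_phase", "medication"):
        table[col] = table["specimen_id"].map(meta[col])

    if ihs_df is not None and not ihs_df.empty:
        pivot = ihs_df.pivot_table(index="specimen_id", columns="compartment",
                                   values="ihs", aggfunc="first")
        primary_ihs = []
        for sid, comp in zip(table["specimen_id"], table["compartment"]):
            col = "stroma" if comp == "stroma" else "myometrium"
            primary_ihs.append(pivot.at[sid, col] if (sid in pivot.index and col in pivot) else np.nan)
        table["ihs_score"] = primary_ihs
        table["ihs_glands_score"] = table["specimen_id"].map(
            pivot["glands"] if "glands" in pivot else pd.Series(dtype=float))
    else:
        table["ihs_score"] = np.nan
        table["ihs_glands_score"] = np.nan
    cols = ["specimen_id", "group", "tissue_type", "cycle_phase", "medication",
            "compartment", "n_fields", "compartment_area_mm2", "blood_count",
            "lymph_count", "mature_count", "bvd_vessels_per_mm2", "lvd_vessels_per_mm2",
            "pct_cd31_area_pct", "pct_pdpn_area_pct", "mature_ratio_fraction",
            "ihs_score", "ihs_glands_score"]
    return table[cols].sort_values("specimen_id").reset_index(drop=True)


@dataclass
class PipelineResult:
    out_dir: Path
    paths: Dict[str, Path]
    field_densities: pd.DataFrame
    specimen_outcomes: pd.DataFrame
    ihs_records: pd.DataFrame
    reports: List[stats_mod.ComparisonReport]


def _round_for_csv(df: pd.DataFrame) -> pd.DataFrame:
    """Densities and percentages to 2 decimals, areas to 4, for the CSV view."""
    out = df.copy()
    two = [c for c in out.columns
           if c.endswith(("_per_mm2", "_pct", "_fraction")) or c == "ihs_score"]
    four = [c for c in out.columns if c.endswith("_mm2")]
    for c in two:
        out[c] = out[c].astype(float).round(2)
    for c in four:
        out[c] = out[c].astype(float).round(4)
    return out


def _collect_inputs(cfg: PipelineConfig, out_dir: Path):
    """Resolve the image list and metadata, simulating a cohort if requested."""
    if cfg.preset is not None:
        specs = paper_like_cohort(cfg.seed, cfg.preset_overrides)
        sim_dir = out_dir / "simulated"
        log.info("ingestion: simulating paper-like cohort (%d specimens) into %s",
                 len(specs), sim_dir)
        cohort = generate_cohort(specs, cfg.seed, out_dir=sim_dir)
        return sorted(cohort.image_paths), cohort.metadata
    if cfg.input_dir is None:
        raise PipelineError("ingestion", "neither input_dir nor a preset configured")
    in_dir = Path(cfg.input_dir)
    images = sorted(p for p in in_dir.glob("**/*.tif*") if p.is_file())
    if not images:
        raise PipelineError("ingestion", f"no TIFF images found under {in_dir}")
    meta_path = in_dir / "metadata.csv"
    if not meta_path.exists():
        raise PipelineError("ingestion", f"missing metadata table {meta_path}")
    return images, pd.read_csv(meta_path)


def _analysis_pass(images, cfg: PipelineConfig):
    field_rows, ihs_records = [], []
    aliases = cfg.channel_aliases or None
    for path in images:
        try:
            stack = read_field(path, aliases=aliases, pixel_um=cfg.pixel_um_override)
        except (ChannelError, ValueError) as exc:
            raise PipelineError("ingestion", str(exc)) from exc
        densities, scores = analyze_stack(stack, cfg)
        for r in densities:
            d = asdict(r)
            d["_cd31_weighted"] = r.pct_cd31_area_pct * r.compartment_area_mm2
            d["_pdpn_weighted"] = r.pct_pdpn_area_pct * r.compartment_area_mm2
            field_rows.append(d)
        ihs_records.extend(scores)
    if not field_rows:
        raise PipelineError("quantification", "no fields produced density records")
    return pd.DataFrame(field_rows), ihs_records


def run_pipeline(cfg: PipelineConfig, replicate: bool = False) -> PipelineResult:
    """Run the full pipeline; see module docstring for the artifact list."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("adenoquant")
    root.addHandler(handler)
    root.setLevel(getattr(logging, cfg.log_level.upper(), logging.INFO))
    try:
        images, metadata = _collect_inputs(cfg, out_dir)
        if metadata.empty:
            raise PipelineError("ingestion", "empty cohort metadata")
        log.info("quantification: %d fields", len(images))
        field_df, ihs_records = _analysis_pass(images, cfg)

        ihs_agg = pd.DataFrame([asdict(r) for r in ihs_mod.aggregate_ihs(
            ihs_records, cfg.ihs.calibration)])
        outcomes = build_outcome_table(field_df, metadata, ihs_agg)

        log.info("statistics: comparing tissue groups (alpha=%g)", cfg.stats.alpha)
        reports = stats_mod.compare_tissues(
            outcomes, alpha=cfg.stats.alpha, stratify_by=cfg.stats.stratify_by,
            include_pooled=cfg.stats.include_pooled, holm=cfg.stats.holm,
            mwu_method=cfg.stats.mwu_method,
        )
        reports += stats_mod.medication_subgroup(outcomes, alpha=cfg.stats.alpha,
                                                 mwu_method=cfg.stats.mwu_method)

        paths: Dict[str, Path] = {}
        field_csv = field_df.drop(columns=["_cd31_weighted", "_pdpn_weighted"])
        paths["field_densities"] = out_dir / "field_densities.csv"
        _round_for_csv(field_csv).to_csv(paths["field_densities"], index=False)
        paths["specimen_outcomes"] = out_dir / "specimen_outcomes.csv"
        _round_for_csv(outcomes).to_csv(paths["specimen_outcomes"], index=False)
        paths["ihs_records"] = out_dir / "ihs_records.csv"
        _round_for_csv(ihs_agg).to_csv(paths["ihs_records"], index=False)

        report_rows = [row for r in reports for row in stats_mod.report_to_rows(r)]
        paths["comparison_report_csv"] = out_dir / "comparison_report.csv"
        pd.DataFrame(report_rows).round(6).to_csv(paths["comparison_report_csv"], index=False)
        paths["comparison_report_json"] = out_dir / "comparison_report.json"
        with open(paths["comparison_report_json"], "w") as fh:
            json.dump([stats_mod.report_to_dict(r) for r in reports], fh, indent=1, sort_keys=True)

        paths["resolved_config"] = out_dir / "resolved_config.yaml"
        with open(paths["resolved_config"], "w") as fh:
            yaml.safe_dump(cfg.model_dump(mode="json"), fh, sort_keys=True)

        if replicate:
            log.info("replicate: re-running quantification for the blinded duplicate check")
            field2, _ = _analysis_pass(images, cfg)
            rep_dir = out_dir / "replicate"
            rep_dir.mkdir(exist_ok=True)
            rep_csv = rep_dir / "field_densities.csv"
            _round_for_csv(field2.drop(columns=["_cd31_weighted", "_pdpn_weighted"])
                           ).to_csv(rep_csv, index=False)
            identical = filecmp.cmp(paths["field_densities"], rep_csv, shallow=False)
            (rep_dir / "replicate_check.txt").write_text(
                "identical\n" if identical else "DIFFERENT\n")
            paths["replicate_check"] = rep_dir / "replicate_check.txt"
            log.info("replicate: outputs %s", "identical" if identical else "DIFFERENT")

        return PipelineResult(out_dir, paths, field_csv, outcomes, ihs_agg, reports)
    finally:
        root.removeHandler(handler)
        handler.close()
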