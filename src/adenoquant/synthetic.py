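"""Synthetic multiplex-IHC tissue fields with fully known ground truth.

Emulates the study design this package quantifies: per tissue sample, five
multispectral fields of 0.9 x 0.7 mm imaged at x200, with six marker
channels (DAPI, CD31, aSMA, PDPN, CD10, VEGF). Endometrial fields are
CD10-positive stroma perforated by elliptical glands; myometrial fields are
solid aSMA tissue; ectopic-endometrium fields embed CD10-positive islands in
an aSMA background. Blood vessels are CD31 annuli (mature ones with a
concentric aSMA mural ring), lymphatics are podoplanin annuli, and VEGF is
painted on a planted fraction of nuclei at a planted intensity level.

The generator has two layers:

1. a specimen-level sampler (:func:`paper_like_cohort`,
   :func:`planted_outcome_table`) that draws per-specimen planted densities
   around group medians — used for cohort construction and for statistical
   simulations that need no pixels; and
2. the field renderer (:func:`generate_field`) that turns one specimen's
   planted parameters into pixel data plus an exact ground-truth record.

Everything is deterministic in (seed, specimen_id, field_index).
"""
from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import ellipse as _draw_ellipse

from .config import (
    INVASION_THRESHOLD_MM,
    CyclePhase,
    Group,
    Medication,
    NoiseConfig,
    PresetOverrides,
    SpecimenConfig,
    TissueType,
    VEGFPlan,
)
from .io import CHANNELS, ChannelStack, mask_area_mm2, write_field

FOREGROUND = 200.0
VEGF_LEVEL_STEP = 50.0  # intensity units per planted VEGF level (levels 0..4)
NUCLEUS_RADIUS_UM = 2.5
NUCLEUS_SPACING_UM = 12.0
GLAND_RIM_SPACING_UM = 7.0
GLAND_RIM_UM = 5.0
VEGF_DISK_UM = 4.0
VESSEL_R_OUT_UM = (4.0, 15.0)
VESSEL_WALL_UM = (2.0, 3.0)
MURAL_GAP_UM = 1.0
MURAL_WALL_UM = 2.0
CENTER_CLEARANCE_UM = 2.0
MAX_PLACEMENT_TRIES = 500


class VesselPlacementError(RuntimeError):
    """Raised when the requested vessel count cannot be placed without overlap."""


def classify_adenomyosis(lesion_depth_mm: float, threshold_mm: float = INVASION_THRESHOLD_MM) -> bool:
    """Adenomyosis ground-truth call: myometrial invasion strictly deeper than threshold."""
    if not np.isfinite(lesion_depth_mm) or not np.isfinite(threshold_mm):
        raise ValueError("depth and threshold must be finite")
    if lesion_depth_mm < 0:
        raise ValueError("lesion depth cannot be negative")
    if threshold_mm <= 0:
        raise ValueError("threshold must be positive")
    return lesion_depth_mm > threshold_mm


@dataclass
class PlantedVessel:
    vessel_class: str  # "blood" | "lymph"
    row: int
    col: int
    r_outer_um: float
    wall_um: float
    has_asma_ring: bool
    compartment: str  # "stroma" | "myometrium"


@dataclass
class FieldGroundTruth:
    """Exact record of everything planted in one rendered field."""

    specimen_id: str
    field_id: str
    pixel_um: float
    vessels: List[PlantedVessel]
    compartment_area_mm2: Dict[str, float]
    vegf: Dict[str, Tuple[float, int]]  # compartment -> (achieved fraction, level)
    lesion_depth_mm: float
    is_adenomyosis: bool

    def count(self, vessel_class: str, compartment: str) -> int:
        return sum(
            1 for v in self.vessels
            if v.vessel_class == vessel_class and v.compartment == compartment
        )

    def true_bvd(self, compartment: str = "stroma") -> float:
        area = self.compartment_area_mm2.get(compartment, 0.0)
        return self.count("blood", compartment) / area if area > 0 else float("nan")

    def true_lvd(self, compartment: str = "stroma") -> float:
        area = self.compartment_area_mm2.get(compartment, 0.0)
        return self.count("lymph", compartment) / area if area > 0 else float("nan")

    def true_mature_fraction(self) -> float:
        blood = [v for v in self.vessels if v.vessel_class == "blood" and v.compartment == "stroma"]
        if not blood:
            return float("nan")
        return sum(v.has_asma_ring for v in blood) / len(blood)


# ---------------------------------------------------------------------------
# low-level stamping helpers

def _disk(radius: int) -> np.ndarray:
    r = int(radius)
    yy, xx = np.ogrid[-r:r + 1, -r:r + 1]
    return yy * yy + xx * xx <= r * r


def _window(shape, row, col, half):
    r0 = max(0, int(row) - half)
    r1 = min(shape[0], int(row) + half + 1)
    c0 = max(0, int(col) - half)
    c1 = min(shape[1], int(col) + half + 1)
    return r0, r1, c0, c1


def _dist_grid(row, col, r0, r1, c0, c1):
    yy = np.arange(r0, r1)[:, None] - row
    xx = np.arange(c0, c1)[None, :] - col
    return np.hypot(yy, xx)


def _stamp_disk(plane, row, col, radius_px, value):
    half = int(np.ceil(radius_px)) + 1
    r0, r1, c0, c1 = _window(plane.shape, row, col, half)
    d = _dist_grid(row, col, r0, r1, c0, c1)
    sub = plane[r0:r1, c0:c1]
    np.maximum(sub, np.where(d <= radius_px, value, 0.0), out=sub)


def _stamp_annulus(plane, row, col, r_out_px, r_in_px, value):
    half = int(np.ceil(r_out_px)) + 1
    r0, r1, c0, c1 = _window(plane.shape, row, col, half)
    d = _dist_grid(row, col, r0, r1, c0, c1)
    ring = (d <= r_out_px) & (d > r_in_px)
    sub = plane[r0:r1, c0:c1]
    np.maximum(sub, np.where(ring, value, 0.0), out=sub)


def _nucleus_kernel(radius_px: float) -> np.ndarray:
    """Peaked nucleus profile: bright centre, soft fall-off, zero past the rim."""
    k = max(1, int(round(radius_px)))
    yy, xx = np.ogrid[-k:k + 1, -k:k + 1]
    d = np.hypot(yy, xx)
    kern = FOREGROUND * np.exp(-1.2 * (d / max(radius_px, 1.0)) ** 2)
    kern[d > radius_px + 0.5] = 0.0
    return kern.astype(np.float32)


def _stamp_nuclei(plane, points, kernel):
    kh = kernel.shape[0] // 2
    H, W = plane.shape
    for row, col in points:
        r0, r1, c0, c1 = _window(plane.shape, row, col, kh)
        kr0 = r0 - (row - kh)
        kc0 = c0 - (col - kh)
        sub = plane[r0:r1, c0:c1]
        np.maximum(sub, kernel[kr0:kr0 + (r1 - r0), kc0:kc0 + (c1 - c0)], out=sub)


def _grid_points(mask: np.ndarray, spacing_px: float, rng: np.random.Generator) -> np.ndarray:
    """Jittered-grid point process restricted to a mask; returns (N, 2) ints."""
    H, W = mask.shape
    sp = max(2.0, float(spacing_px))
    rows = np.arange(sp / 2.0, H, sp)
    cols = np.arange(sp / 2.0, W, sp)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    rr = rr.ravel()
    cc = cc.ravel()
    rr = rr + rng.uniform(-0.2, 0.2, rr.size) * sp
    cc = cc + rng.uniform(-0.2, 0.2, cc.size) * sp
    r = np.clip(np.rint(rr), 0, H - 1).astype(int)
    c = np.clip(np.rint(cc), 0, W - 1).astype(int)
    keep = mask[r, c]
    return np.stack([r[keep], c[keep]], axis=1)


# ---------------------------------------------------------------------------
# geometry

def _sample_ellipse(rng, shape, ax_lo_px, ax_hi_px):
    """One ellipse fully inside the field; returns its boolean mask and params."""
    H, W = shape
    a = rng.uniform(ax_lo_px, ax_hi_px)
    b = rng.uniform(ax_lo_px, ax_hi_px)
    rot = rng.uniform(0, np.pi)
    bound = max(a, b) + 2
    if 2 * bound >= min(H, W):
        a = b = bound = min(H, W) / 4.0
        rot = 0.0
    r0 = rng.uniform(bound, H - bound)
    c0 = rng.uniform(bound, W - bound)
    mask = np.zeros(shape, bool)
    rr, cc = _draw_ellipse(r0, c0, a, b, shape=shape, rotation=rot)
    mask[rr, cc] = True
    return mask


def _make_geometry(config: SpecimenConfig, rng: np.random.Generator, shape):
    """Return (stroma, glands, myometrium) boolean masks for one field."""
    px = config.pixel_um
    H, W = shape
    zeros = np.zeros(shape, bool)
    tt = config.tissue_type
    field_area_mm2 = H * W * px * px / 1e6
    if tt in (TissueType.control_endometrium, TissueType.eutopic_endometrium):
        glands = np.zeros(shape, bool)
        # ~16 glands/mm^2 keeps gland coverage near 10% at any field size
        n_glands = max(2, int(round(16.0 * field_area_mm2))) + int(rng.integers(0, 3))
        for _ in range(n_glands):
            glands |= _sample_ellipse(rng, shape, 25.0 / px, 70.0 / px)
        stroma = ~glands
        return stroma, glands, zeros.copy()
    if tt is TissueType.myometrium:
        return zeros.copy(), zeros.copy(), np.ones(shape, bool)
    # ectopic endometrium: CD10 islands inside a myometrial background
    field_min_um = min(H, W) * px
    islands = np.zeros(shape, bool)
    for _ in range(int(rng.integers(2, 5))):
        islands |= _sample_ellipse(
            rng, shape, 0.10 * field_min_um / px, 0.22 * field_min_um / px
        )
    glands = np.zeros(shape, bool)
    dt = ndi.distance_transform_edt(islands)
    for _ in range(int(rng.integers(2, 6))):
        g_px = rng.uniform(15.0 / px, 40.0 / px)
        allowed = np.flatnonzero(dt.ravel() > g_px + 2)
        if allowed.size == 0:
            continue
        pos = allowed[rng.integers(allowed.size)]
        r0, c0 = divmod(int(pos), W)
        gm = np.zeros(shape, bool)
        rr, cc = _draw_ellipse(
            r0, c0, g_px, g_px * rng.uniform(0.6, 1.0), shape=shape, rotation=rng.uniform(0, np.pi)
        )
        gm[rr, cc] = True
        glands |= gm & islands
    stroma = islands & ~glands
    myo = ~(islands | glands)
    return stroma, glands, myo


# ---------------------------------------------------------------------------
# vessels

def _plant_vessels(
    rng: np.random.Generator,
    mask: np.ndarray,
    compartment: str,
    bvd: float,
    lvd: float,
    mature_fraction: float,
    pixel_um: float,
    field_label: str,
    existing: List[PlantedVessel],
) -> List[PlantedVessel]:
    H, W = mask.shape
    area_mm2 = mask_area_mm2(mask, pixel_um)
    n_blood = int(round(bvd * area_mm2))
    n_lymph = int(round(lvd * area_mm2))
    if n_blood + n_lymph == 0:
        return []
    dt = ndi.distance_transform_edt(mask)
    rr = np.arange(H, dtype=float)
    cc = np.arange(W, dtype=float)
    edge = np.minimum(
        np.minimum(rr, H - 1 - rr)[:, None], np.minimum(cc, W - 1 - cc)[None, :]
    )
    limit = np.minimum(dt, edge + 1.0).ravel()

    n_mature = int(round(mature_fraction * n_blood))
    mature_flags = np.zeros(n_blood, bool)
    mature_flags[rng.permutation(n_blood)[:n_mature]] = True

    specs = []
    for i in range(n_blood):
        specs.append(("blood", bool(mature_flags[i])))
    for _ in range(n_lymph):
        specs.append(("lymph", False))

    placed: List[PlantedVessel] = []
    for vessel_class, has_ring in specs:
        r_out = rng.uniform(*VESSEL_R_OUT_UM)
        wall = rng.uniform(*VESSEL_WALL_UM)
        extent = r_out + (MURAL_GAP_UM + MURAL_WALL_UM if has_ring else 0.0)
        margin_px = extent / pixel_um + 2.0
        cand = np.flatnonzero(limit > margin_px)
        if cand.size == 0:
            raise VesselPlacementError(
                f"{field_label}: no room for a vessel of extent {extent:.1f} um in {compartment}"
            )
        others = placed + existing
        for _ in range(MAX_PLACEMENT_TRIES):
            pos = int(cand[rng.integers(cand.size)])
            row, col = divmod(pos, W)
            ok = True
            for o in others:
                o_ext = o.r_outer_um + (MURAL_GAP_UM + MURAL_WALL_UM if o.has_asma_ring else 0.0)
                d_um = np.hypot(row - o.row, col - o.col) * pixel_um
                if d_um < extent + o_ext + CENTER_CLEARANCE_UM:
                    ok = False
                    break
            if ok:
                placed.append(
                    PlantedVessel(vessel_class, row, col, r_out, wall, has_ring, compartment)
                )
                break
        else:
            raise VesselPlacementError(
                f"{field_label}: could not place vessel {len(placed) + 1} of "
                f"{len(specs)} in {compartment} after {MAX_PLACEMENT_TRIES} tries"
            )
    return placed


# ---------------------------------------------------------------------------
# field rendering

def generate_field(config: SpecimenConfig, field_index: int) -> Tuple[ChannelStack, FieldGroundTruth]:
    """Render one field of a specimen; deterministic in (config.seed, field_index)."""
    if not (0 <= field_index < config.n_fields):
        raise ValueError(f"field_index {field_index} out of range (n_fields={config.n_fields})")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7, field_index]))
    shape = config.field_px
    px = config.pixel_um
    field_id = f"{config.specimen_id}_f{field_index}"

    stroma, glands, myo = _make_geometry(config, rng, shape)
    planes = {ch: np.zeros(shape, np.float32) for ch in CHANNELS}
    planes["CD10"][stroma] = FOREGROUND
    planes["aSMA"][myo] = FOREGROUND

    # nuclei (jittered grid per compartment; gland epithelium lines the rim)
    kernel = _nucleus_kernel(NUCLEUS_RADIUS_UM / px)
    stroma_n = _grid_points(stroma, NUCLEUS_SPACING_UM / px, rng)
    myo_n = _grid_points(myo, NUCLEUS_SPACING_UM / px, rng)
    rim_px = max(1, int(round(GLAND_RIM_UM / px)))
    gland_rim = glands & ~ndi.binary_erosion(glands, _disk(rim_px))
    gland_n = _grid_points(gland_rim, GLAND_RIM_SPACING_UM / px, rng)
    for pts in (stroma_n, myo_n, gland_n):
        _stamp_nuclei(planes["DAPI"], pts, kernel)

    # VEGF on a planted fraction of each compartment's nuclei
    vegf_truth: Dict[str, Tuple[float, int]] = {}
    for comp, pts in (("stroma", stroma_n), ("glands", gland_n), ("myometrium", myo_n)):
        plan = config.planted_vegf.get(comp)
        if plan is None or len(pts) == 0:
            vegf_truth[comp] = (0.0, 0)
            continue
        n_pos = int(round(plan.fraction * len(pts)))
        if n_pos > 0 and plan.intensity_level > 0:
            sel = rng.choice(len(pts), size=n_pos, replace=False)
            val = plan.intensity_level * VEGF_LEVEL_STEP
            for row, col in pts[sel]:
                _stamp_disk(planes["VEGF"], row, col, VEGF_DISK_UM / px, val)
        vegf_truth[comp] = (n_pos / len(pts), plan.intensity_level)

    # vessels
    vessels: List[PlantedVessel] = []
    primary = config.primary_compartment
    primary_mask = myo if primary == "myometrium" else stroma
    # every myometrial vessel is wrapped in smooth muscle, so mature by construction
    primary_mature = 1.0 if primary == "myometrium" else config.planted_mature_fraction
    vessels += _plant_vessels(
        rng, primary_mask, primary, config.planted_bvd, config.planted_lvd,
        primary_mature, px, field_id, vessels,
    )
    if config.tissue_type is TissueType.ectopic_endometrium:
        vessels += _plant_vessels(
            rng, myo, "myometrium", config.myo_bvd, config.myo_lvd, 1.0, px, field_id, vessels,
        )

    for v in vessels:
        r_out_px = v.r_outer_um / px
        r_in_px = max(r_out_px - max(v.wall_um / px, 1.0), 0.0)
        chan = "CD31" if v.vessel_class == "blood" else "PDPN"
        _stamp_annulus(planes[chan], v.row, v.col, r_out_px, r_in_px, FOREGROUND)
        if v.has_asma_ring:
            m_out_px = (v.r_outer_um + MURAL_GAP_UM + MURAL_WALL_UM) / px
            m_in_px = max((v.r_outer_um + MURAL_GAP_UM) / px, r_out_px)
            m_in_px = min(m_in_px, m_out_px - 1.0)
            _stamp_annulus(planes["aSMA"], v.row, v.col, m_out_px, m_in_px, FOREGROUND)

    # spectral bleed-through, then additive acquisition noise, then 8-bit
    noise = config.noise
    if noise.bleedthrough > 0:
        raw = {ch: planes[ch].copy() for ch in CHANNELS}
        for a, b in zip(CHANNELS, CHANNELS[1:]):
            planes[b] += noise.bleedthrough * raw[a]
    out: Dict[str, np.ndarray] = {}
    for ch in CHANNELS:
        arr = planes[ch] + noise.background
        if noise.sigma > 0:
            arr = arr + rng.normal(0.0, noise.sigma, arr.shape)
        out[ch] = np.clip(np.rint(arr), 0, 255).astype(np.uint8)

    gt = FieldGroundTruth(
        specimen_id=config.specimen_id,
        field_id=field_id,
        pixel_um=px,
        vessels=vessels,
        compartment_area_mm2={
            "stroma": mask_area_mm2(stroma, px),
            "glands": mask_area_mm2(glands, px),
            "myometrium": mask_area_mm2(myo, px),
            "background": 0.0,
        },
        vegf=vegf_truth,
        lesion_depth_mm=config.lesion_depth_mm,
        is_adenomyosis=classify_adenomyosis(config.lesion_depth_mm)
        if config.lesion_depth_mm >= 0 else False,
    )
    stack = ChannelStack(out, px, field_id=field_id, specimen_id=config.specimen_id)
    return stack, gt


# ---------------------------------------------------------------------------
# cohorts

def specimen_seed(master_seed: int, specimen_id: str) -> int:
    """Reproducible per-specimen seed from (master seed, specimen id)."""
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, zlib.crc32(specimen_id.encode())])
    return int(ss.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)


@dataclass
class CohortResult:
    specimens: List[SpecimenConfig]
    metadata: pd.DataFrame
    ground_truth: pd.DataFrame
    field_truths: Dict[str, List[FieldGroundTruth]]
    image_paths: List[Path] = field(default_factory=list)
    stacks: Optional[Dict[str, List[ChannelStack]]] = None


def _truth_rows(sid: str, cfg: SpecimenConfig, truths: List[FieldGroundTruth]):
    rows = []
    for comp in ("stroma", "myometrium"):
        blood = sum(t.count("blood", comp) for t in truths)
        lymph = sum(t.count("lymph", comp) for t in truths)
        area = sum(t.compartment_area_mm2[comp] for t in truths)
        if area <= 0:
            continue
        mature = sum(
            sum(1 for v in t.vessels if v.vessel_class == "blood"
                and v.compartment == comp and v.has_asma_ring)
            for t in truths
        )
        rows.append({
            "specimen_id": sid,
            "compartment": comp,
            "true_area_mm2": area,
            "true_blood_count": blood,
            "true_lymph_count": lymph,
            "true_bvd_vessels_per_mm2": blood / area,
            "true_lvd_vessels_per_mm2": lymph / area,
            "true_mature_fraction": (mature / blood) if (blood and comp == "stroma") else np.nan,
            "lesion_depth_mm": cfg.lesion_depth_mm,
            "is_adenomyosis": classify_adenomyosis(cfg.lesion_depth_mm),
        })
    return rows


def generate_cohort(
    specimens: Sequence[SpecimenConfig],
    seed: int,
    out_dir=None,
    keep_images: bool = False,
) -> CohortResult:
    """Render a cohort; per-specimen seeds derive from the master seed.

    Writes one OME-TIFF per field plus ``metadata.csv`` and
    ``ground_truth.json`` when ``out_dir`` is given.
    """
    if not specimens:
        raise ValueError("empty study configuration")
    ids = [s.specimen_id for s in specimens]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate specimen identifiers: {dupes}")

    out_dir = Path(out_dir) if out_dir is not None else None
    meta_rows = []
    truth_rows = []
    field_truths: Dict[str, List[FieldGroundTruth]] = {}
    image_paths: List[Path] = []
    stacks: Dict[str, List[ChannelStack]] = {} if keep_images else None
    truth_json: Dict[str, dict] = {}

    for cfg in specimens:
        cfg = cfg.model_copy(update={"seed": specimen_seed(seed, cfg.specimen_id)})
        sid = cfg.specimen_id
        truths = []
        per_spec_stacks = []
        for i in range(cfg.n_fields):
            stack, gt = generate_field(cfg, i)
            truths.append(gt)
            if out_dir is not None:
                image_paths.append(write_field(stack, out_dir / "images" / f"{gt.field_id}.ome.tif"))
            if keep_images:
                per_spec_stacks.append(stack)
        field_truths[sid] = truths
        if keep_images:
            stacks[sid] = per_spec_stacks
        meta_rows.append({
            "specimen_id": sid,
            "group": cfg.group.value,
            "tissue_type": cfg.tissue_type.value,
            "cycle_phase": cfg.cycle_phase.value,
            "medication": cfg.medication.value,
            "n_fields": cfg.n_fields,
            "pixel_um": cfg.pixel_um,
        })
        truth_rows.extend(_truth_rows(sid, cfg, truths))
        truth_json[sid] = {
            "lesion_depth_mm": cfg.lesion_depth_mm,
            "is_adenomyosis": classify_adenomyosis(cfg.lesion_depth_mm),
            "fields": [
                {
                    "field_id": t.field_id,
                    "compartment_area_mm2": t.compartment_area_mm2,
                    "vegf": {k: list(v) for k, v in t.vegf.items()},
                    "vessels": [asdict(v) for v in t.vessels],
                }
                for t in truths
            ],
        }

    metadata = pd.DataFrame(meta_rows)
    ground_truth = pd.DataFrame(truth_rows)
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        metadata.to_csv(out_dir / "metadata.csv", index=False)
        with open(out_dir / "ground_truth.json", "w") as fh:
            json.dump(truth_json, fh, indent=1, sort_keys=True)
        ground_truth.to_csv(out_dir / "ground_truth.csv", index=False, float_format="%.6f")
    return CohortResult(list(specimens), metadata, ground_truth, field_truths, image_paths, stacks)


# ---------------------------------------------------------------------------
# paper-like cohort preset

#: Group-median planted values per (tissue key, phase): BVD, LVD (vessels/mm^2)
#: and mature fraction. Directions mirror the study's findings: ectopic BVD
#: elevated, eutopic LVD elevated in the proliferative phase, maturity ratio
#: depressed in eutopic and ectopic endometrium, secretory BVD higher overall.
GROUP_MEDIANS: Dict[Tuple[str, str], Dict[str, float]] = {
    ("control_endometrium", "proliferative"): {"bvd": 22.0, "lvd": 8.0, "mature": 0.60},
    ("control_endometrium", "secretory"): {"bvd": 29.0, "lvd": 8.0, "mature": 0.60},
    ("eutopic_endometrium", "proliferative"): {"bvd": 22.0, "lvd": 16.0, "mature": 0.35},
    ("eutopic_endometrium", "secretory"): {"bvd": 29.0, "lvd": 9.0, "mature": 0.35},
    ("ectopic_endometrium", "proliferative"): {"bvd": 44.0, "lvd": 8.0, "mature": 0.35},
    ("ectopic_endometrium", "secretory"): {"bvd": 58.0, "lvd": 8.0, "mature": 0.35},
    ("myometrium", "proliferative"): {"bvd": 14.0, "lvd": 3.0, "mature": 1.0},
    ("myometrium", "secretory"): {"bvd": 14.0, "lvd": 3.0, "mature": 1.0},
}

#: Between-specimen variability: densities are lognormal around the group
#: median with this log-sigma (CV ~= 20%); the maturity fraction is Gaussian
#: with sd 0.06, clipped to (0.02, 0.98); VEGF immunoreactive fractions vary
#: proportionally with CV 0.2.
SPECIMEN_LOG_SIGMA = 0.2
MATURE_SD = 0.06
VEGF_FRACTION_CV = 0.2

# Table 1 structure: phase split and antiangiogenic-medication counts.
PHASE_SPLIT = {"adenomyosis": (7, 12), "control": (6, 13)}  # (proliferative, secretory)
ANTIANGIOGENIC_N = {"adenomyosis": 4, "control": 5}


def draw_specimen(
    rng: np.random.Generator,
    specimen_id: str,
    group: Group,
    tissue: TissueType,
    phase: CyclePhase,
    medication: Medication = Medication.none_other,
    base: Optional[PresetOverrides] = None,
) -> SpecimenConfig:
    """Draw one specimen's planted parameters around its group medians."""
    base = base or PresetOverrides()
    med = GROUP_MEDIANS[(tissue.value, phase.value)]
    bvd = med["bvd"] * float(np.exp(rng.normal(0.0, SPECIMEN_LOG_SIGMA)))
    lvd = med["lvd"] * float(np.exp(rng.normal(0.0, SPECIMEN_LOG_SIGMA)))
    mature = float(np.clip(rng.normal(med["mature"], MATURE_SD), 0.02, 0.98))
    vegf = {}
    for comp, plan in _default_vegf_levels().items():
        frac = float(np.clip(rng.normal(plan[0], VEGF_FRACTION_CV * plan[0]), 0.0, 1.0))
        vegf[comp] = VEGFPlan(fraction=frac, intensity_level=plan[1])
    lesion = float(rng.uniform(3.0, 8.0)) if group is Group.adenomyosis else 0.0
    return SpecimenConfig(
        specimen_id=specimen_id,
        group=group,
        tissue_type=tissue,
        cycle_phase=phase,
        medication=medication,
        n_fields=base.n_fields,
        field_mm=base.field_mm,
        pixel_um=base.pixel_um,
        planted_bvd=bvd,
        planted_lvd=lvd,
        planted_mature_fraction=mature,
        planted_vegf=vegf,
        lesion_depth_mm=lesion,
        noise=base.noise,
    )


def _default_vegf_levels() -> Dict[str, Tuple[float, int]]:
    # medians: stroma IHS 1 (=1x1), glands IHS 3 (=3x1), myometrium IHS 4 (=2x2)
    return {"stroma": (0.05, 1), "glands": (0.60, 1), "myometrium": (0.30, 2)}


def paper_like_cohort(seed: int, overrides: Optional[PresetOverrides] = None) -> List[SpecimenConfig]:
    """Specimen configurations emulating the study cohort.

    19 adenomyosis patients (eutopic endometrium, ectopic endometrium and
    myometrium samples each) and 19 controls (endometrium and myometrium),
    with the study's phase split and antiangiogenic-medication counts.
    Per-specimen planted densities are drawn around the group medians.
    """
    base = overrides or PresetOverrides()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 1311]))
    specimens: List[SpecimenConfig] = []
    for group, n_pat, prefix in (
        (Group.adenomyosis, base.n_adenomyosis, "A"),
        (Group.control, base.n_control, "C"),
    ):
        n_prolif, n_secr = PHASE_SPLIT[group.value]
        phases = [CyclePhase.proliferative] * n_prolif + [CyclePhase.secretory] * n_secr
        if len(phases) < n_pat:  # scale split proportionally if cohort resized
            reps = int(np.ceil(n_pat / len(phases)))
            phases = (phases * reps)[:n_pat]
        phases = phases[:n_pat]
        n_anti = min(ANTIANGIOGENIC_N[group.value], n_pat)
        meds = [Medication.antiangiogenic] * n_anti + [Medication.none_other] * (n_pat - n_anti)
        med_order = rng.permutation(n_pat)
        tissues = (
            (TissueType.eutopic_endometrium, TissueType.ectopic_endometrium, TissueType.myometrium)
            if group is Group.adenomyosis
            else (TissueType.control_endometrium, TissueType.myometrium)
        )
        for i in range(n_pat):
            pid = f"{prefix}{i + 1:02d}"
            phase = phases[i]
            medication = meds[med_order[i]]
            for tissue in tissues:
                short = {
                    TissueType.eutopic_endometrium: "eut",
                    TissueType.ectopic_endometrium: "ect",
                    TissueType.myometrium: "myo",
                    TissueType.control_endometrium: "endo",
                }[tissue]
                specimens.append(
                    draw_specimen(rng, f"{pid}-{short}", group, tissue, phase, medication, base)
                )
    return specimens


def planted_outcome_table(specimens: Sequence[SpecimenConfig]) -> pd.DataFrame:
    """Specimen-level table of planted outcome values (no rendering).

    Columns mirror the measured outcome table so the statistics stage can be
    exercised directly on ground truth, e.g. for power or type-I simulations.
    """
    rows = []
    for cfg in specimens:
        vegf = cfg.planted_vegf
        # IHS from planted (fraction, level) via the printed formula
        from .ihs import compute_ihs  # local import to avoid a cycle at module load

        comp = cfg.primary_compartment
        plan = vegf.get(comp)
        ihs_val = compute_ihs(100.0 * plan.fraction, plan.intensity_level).ihs if plan else np.nan
        rows.append({
            "specimen_id": cfg.specimen_id,
            "group": cfg.group.value,
            "tissue_type": cfg.tissue_type.value,
            "cycle_phase": cfg.cycle_phase.value,
            "medication": cfg.medication.value,
            "bvd_vessels_per_mm2": cfg.planted_bvd,
            "lvd_vessels_per_mm2": cfg.planted_lvd,
            "pct_cd31_area_pct": np.nan,
            "pct_pdpn_area_pct": np.nan,
            "mature_ratio_fraction": (
                cfg.planted_mature_fraction if comp == "stroma" else np.nan
            ),
            "ihs_score": ihs_val,
        })
    return pd.DataFrame(rows)
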