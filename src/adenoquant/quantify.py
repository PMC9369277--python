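"""Vessel extraction and the four vascular outcomes per field and compartment.

Outcomes follow the study definitions: blood/lymph vessel density as vessel
count per mm^2 of the relevant compartment (CD10-stained stroma or
aSMA-stained myometrium), percent marker-positive area as a consistency
metric, and the mature:total ratio — the fraction of CD31 vessels whose
outer boundary is double-stained with aSMA — computed in the stroma only,
because every myometrial vessel is surrounded by smooth muscle.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import dilation as sk_dilation
from skimage.morphology import disk

from .segmentation import BinaryMask, CompartmentMasks, LabeledObjects, label_objects

log = logging.getLogger(__name__)


@dataclass
class VesselObject:
    """One detected endothelial (blood) or lymphatic cluster."""

    label: int
    vessel_class: str  # "blood" | "lymph"
    area_um2: float
    centroid: Tuple[float, float]
    compartment: str  # "stroma" | "myometrium"
    bbox: Tuple[int, int, int, int]
    footprint: np.ndarray  # local bool mask within bbox
    pdpn_overlap: float
    is_mature: Optional[bool] = None  # blood vessels only
    asma_boundary_overlap: Optional[float] = None


@dataclass
class DensityRecord:
    """Per field x compartment vascular outcomes (units in field names)."""

    specimen_id: str
    field_id: str
    compartment: str
    compartment_area_mm2: float
    blood_count: int
    lymph_count: int
    mature_count: Optional[int]
    bvd_vessels_per_mm2: float
    lvd_vessels_per_mm2: float
    pct_cd31_area_pct: float
    pct_pdpn_area_pct: float
    mature_ratio_fraction: Optional[float]


def _majority_compartment(
    labels: np.ndarray, compartments: CompartmentMasks, n_labels: int
) -> List[str]:
    """Per label: compartment holding the majority of its pixels."""
    names = ["stroma", "glands", "myometrium", "background"]
    counts = np.zeros((n_labels, len(names)))
    flat = labels.ravel()
    for j, name in enumerate(names):
        sel = compartments.get(name).pixels.ravel()
        counts[:, j] = np.bincount(flat[sel], minlength=n_labels + 1)[1:]
    return [names[j] for j in counts.argmax(axis=1)]


def _objects_from_labels(
    objects: LabeledObjects,
    pdpn_mask: BinaryMask,
    compartments: CompartmentMasks,
    pixel_um: float,
    min_area_um2: float,
    lymph_overlap_cut: float,
    classify_lymph: bool,
) -> List[VesselObject]:
    labels = objects.labels
    n = objects.count
    if n == 0:
        return []
    flat = labels.ravel()
    pdpn_px = np.bincount(flat[pdpn_mask.pixels.ravel()], minlength=n + 1)[1:]
    overlap = pdpn_px / objects.areas_px
    comp = _majority_compartment(labels, compartments, n)
    slices = ndi.find_objects(labels)
    out: List[VesselObject] = []
    for i in range(n):
        area_um2 = float(objects.areas_px[i]) * pixel_um**2
        if area_um2 < min_area_um2:
            continue
        if comp[i] not in ("stroma", "myometrium"):
            continue  # majority in background or glands: dropped
        sl = slices[i]
        if classify_lymph:
            vessel_class = "lymph" if overlap[i] >= lymph_overlap_cut else "blood"
        else:
            vessel_class = "lymph"
        out.append(
            VesselObject(
                label=i + 1,
                vessel_class=vessel_class,
                area_um2=area_um2,
                centroid=tuple(objects.centroids[i]),
                compartment=comp[i],
                bbox=(sl[0].start, sl[1].start, sl[0].stop, sl[1].stop),
                footprint=labels[sl] == i + 1,
                pdpn_overlap=float(overlap[i]),
            )
        )
    return out


def extract_vessels(
    cd31_objects: LabeledObjects,
    pdpn_mask: BinaryMask,
    compartments: CompartmentMasks,
    pixel_um: float,
    min_area_um2: float = 5.0,
    lymph_overlap_cut: float = 0.5,
) -> List[VesselObject]:
    """Turn labeled CD31 clusters plus the podoplanin layer into vessel objects.

    Every CD31 cluster of at least ``min_area_um2`` becomes a vessel: lymph
    when its podoplanin overlap reaches ``lymph_overlap_cut``, blood
    otherwise. Podoplanin clusters without CD31 become additional lymph
    vessels. Objects whose pixel majority lies outside stroma/myometrium are
    dropped.
    """
    if cd31_objects.labels.shape != pdpn_mask.shape:
        raise ValueError("inputs differ in shape")
    vessels = _objects_from_labels(
        cd31_objects, pdpn_mask, compartments, pixel_um,
        min_area_um2, lymph_overlap_cut, classify_lymph=True,
    )
    # podoplanin-only clusters
    cd31_fg = cd31_objects.labels > 0
    pdpn_objects = label_objects(pdpn_mask, connectivity=8)
    if pdpn_objects.count:
        flat = pdpn_objects.labels.ravel()
        cd31_px = np.bincount(flat[cd31_fg.ravel()], minlength=pdpn_objects.count + 1)[1:]
        cd31_frac = cd31_px / pdpn_objects.areas_px
        keep = cd31_frac < lymph_overlap_cut
        extra = _objects_from_labels(
            pdpn_objects, pdpn_mask, compartments, pixel_um,
            min_area_um2, lymph_overlap_cut, classify_lymph=False,
        )
        offset = max((v.label for v in vessels), default=0)
        for v in extra:
            if keep[v.label - 1]:
                vessels.append(replace(v, label=v.label + offset))
    return vessels


def classify_maturity(
    vessel: VesselObject,
    asma_mask: BinaryMask,
    dilation_radius_px: int = 2,
    overlap_cut: float = 0.1,
) -> VesselObject:
    """Mark a blood vessel mature when its dilated outer boundary is aSMA-positive.

    The boundary is the ring of pixels gained by dilating the vessel
    footprint by ``dilation_radius_px``; the vessel is mature when at least
    ``overlap_cut`` of those pixels carry aSMA signal (double immunostaining
    of CD31 and aSMA read as colocalization on the mural side).
    """
    if vessel.vessel_class != "blood":
        raise ValueError("maturity is defined for blood vessels only")
    r = int(dilation_radius_px)
    r0, c0, r1, c1 = vessel.bbox
    H, W = asma_mask.shape
    pr0, pc0 = max(0, r0 - r - 1), max(0, c0 - r - 1)
    pr1, pc1 = min(H, r1 + r + 1), min(W, c1 + r + 1)
    local = np.zeros((pr1 - pr0, pc1 - pc0), bool)
    local[r0 - pr0:r1 - pr0, c0 - pc0:c1 - pc0] = vessel.footprint
    boundary = sk_dilation(local, disk(r)).astype(bool) & ~local
    n_boundary = int(boundary.sum())
    if n_boundary == 0:
        overlap = 0.0
    else:
        asma_local = asma_mask.pixels[pr0:pr1, pc0:pc1]
        overlap = float(asma_local[boundary].sum()) / n_boundary
    return replace(vessel, asma_boundary_overlap=overlap, is_mature=bool(overlap >= overlap_cut))


def compute_densities(
    vessels: Sequence[VesselObject],
    masks: CompartmentMasks,
    cd31_mask: BinaryMask,
    pdpn_mask: BinaryMask,
    pixel_um: float,
    specimen_id: str = "",
    field_id: str = "",
) -> List[DensityRecord]:
    """One record per compartment with counts, densities and percent areas.

    BVD/LVD are exact count-over-area ratios; the mature ratio is reported
    for the stroma only and is undefined when no blood vessel was detected.
    Compartments with zero area are suppressed with a logged warning.
    """
    records: List[DensityRecord] = []
    for comp in ("stroma", "myometrium"):
        cmask = masks.get(comp).pixels
        n_px = int(cmask.sum())
        area = n_px * pixel_um**2 / 1e6
        if area <= 0:
            log.warning("%s/%s: compartment %s has zero area; record suppressed",
                        specimen_id, field_id, comp)
            continue
        blood = [v for v in vessels if v.compartment == comp and v.vessel_class == "blood"]
        lymph = [v for v in vessels if v.compartment == comp and v.vessel_class == "lymph"]
        pct_cd31 = 100.0 * int((cd31_mask.pixels & cmask).sum()) / n_px
        pct_pdpn = 100.0 * int((pdpn_mask.pixels & cmask).sum()) / n_px
        classified = [v for v in blood if v.is_mature is not None]
        if comp == "stroma" and classified:
            mature_count: Optional[int] = sum(bool(v.is_mature) for v in classified)
            ratio: Optional[float] = mature_count / len(blood)
        else:
            mature_count, ratio = None, None
        records.append(
            DensityRecord(
                specimen_id=specimen_id,
                field_id=field_id,
                compartment=comp,
                compartment_area_mm2=area,
                blood_count=len(blood),
                lymph_count=len(lymph),
                mature_count=mature_count,
                bvd_vessels_per_mm2=len(blood) / area,
                lvd_vessels_per_mm2=len(lymph) / area,
                pct_cd31_area_pct=pct_cd31,
                pct_pdpn_area_pct=pct_pdpn,
                mature_ratio_fraction=ratio,
            )
        )
    return records


def aggregate_specimen(records: Sequence[DensityRecord]) -> List[Dict]:
    """Pool a specimen's field records per compartment (total count / total area).

    Area-weighted pooling is robust to unequal compartment areas across the
    five fields; percent areas pool as pixel-weighted means and the mature
    ratio as total mature over total blood.
    """
    if not records:
        raise ValueError("no field records to aggregate")
    out: List[Dict] = []
    by_comp: Dict[str, List[DensityRecord]] = {}
    for r in records:
        by_comp.setdefault(r.compartment, []).append(r)
    sid = records[0].specimen_id
    for comp, recs in by_comp.items():
        area = sum(r.compartment_area_mm2 for r in recs)
        blood = sum(r.blood_count for r in recs)
        lymph = sum(r.lymph_count for r in recs)
        pct_cd31 = sum(r.pct_cd31_area_pct * r.compartment_area_mm2 for r in recs) / area
        pct_pdpn = sum(r.pct_pdpn_area_pct * r.compartment_area_mm2 for r in recs) / area
        matures = [r.mature_count for r in recs if r.mature_count is not None]
        if comp == "stroma" and blood > 0 and matures:
            ratio: Optional[float] = sum(matures) / blood
        else:
            ratio = None
        out.append({
            "specimen_id": sid,
            "compartment": comp,
            "n_fields": len(recs),
            "compartment_area_mm2": area,
            "blood_count": blood,
            "lymph_count": lymph,
            "bvd_vessels_per_mm2": blood / area,
            "lvd_vessels_per_mm2": lymph / area,
            "pct_cd31_area_pct": pct_cd31,
            "pct_pdpn_area_pct": pct_pdpn,
            "mature_ratio_fraction": ratio,
        })
    return out
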