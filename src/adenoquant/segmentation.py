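"""Binary-layer segmentation of marker channels and tissue compartments.

Mirrors the binary-layer stage of automated multiplex-IHC analysis: each
marker channel is thresholded into a binary layer, cleaned morphologically,
and connected clusters are labeled. The CD10 and aSMA layers delineate the
endometrial-stroma and myometrium compartments; glands are the DAPI-lined
CD10-negative regions enclosed by stroma.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.morphology import closing as sk_closing
from skimage.morphology import disk

from .io import ChannelStack, mask_area_mm2

log = logging.getLogger(__name__)


@dataclass
class BinaryMask:
    """A thresholded marker layer; the threshold used is kept for audit."""

    pixels: np.ndarray  # 2-D bool
    channel: str
    method: str  # "otsu" | "fixed" | "derived"
    threshold_used: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape

    def area_mm2(self, pixel_um: float) -> float:
        return mask_area_mm2(self.pixels, pixel_um)


@dataclass
class LabeledObjects:
    """Connected components of a binary layer (labels 1..K, 0 = background)."""

    labels: np.ndarray  # 2-D int
    areas_px: np.ndarray  # (K,)
    centroids: np.ndarray  # (K, 2) row, col
    bboxes: List[Tuple[int, int, int, int]]
    connectivity: int

    @property
    def count(self) -> int:
        return int(self.areas_px.size)


@dataclass
class CompartmentMasks:
    """Mutually exclusive masks that partition a field."""

    stroma: BinaryMask
    glands: BinaryMask
    myometrium: BinaryMask
    background: BinaryMask

    def __iter__(self):
        yield from (("stroma", self.stroma), ("glands", self.glands),
                    ("myometrium", self.myometrium), ("background", self.background))

    def get(self, name: str) -> BinaryMask:
        return getattr(self, name)

    def is_partition(self) -> bool:
        total = np.zeros(self.stroma.shape, np.uint8)
        for _, m in self:
            total += m.pixels.astype(np.uint8)
        return bool((total == 1).all())


def binarize_channel(
    stack: ChannelStack,
    channel: str,
    method: str = "otsu",
    fixed_threshold: Optional[float] = None,
    aliases: Optional[Dict[str, str]] = None,
    min_class_separation: float = 32.0,
) -> BinaryMask:
    """Threshold one channel into a binary layer (pixel true iff intensity >= t).

    With ``method="otsu"`` the threshold is data-driven per channel per field;
    a constant plane raises (use a fixed threshold instead). When the two
    Otsu classes are closer than ``min_class_separation`` intensity units the
    plane has no real contrast — Otsu would split pure noise in half and
    flood the field with false foreground, or split a uniformly stained
    plane into arbitrary halves — so the layer falls back to a fixed
    mid-range threshold (128 of 255): a dark contrast-free plane reads as
    marker-free, a bright one as uniformly stained.
    """
    plane = np.asarray(stack.plane(channel, aliases), float)
    if method == "fixed":
        if fixed_threshold is None:
            raise ValueError("method='fixed' requires fixed_threshold")
        thr = float(fixed_threshold)
        return BinaryMask(plane >= thr, channel, "fixed", thr)
    if method != "otsu":
        raise ValueError(f"unknown binarization method {method!r}")
    if plane.min() == plane.max():
        raise ValueError(
            f"channel {channel!r} has constant intensity {plane.flat[0]:g}; "
            "Otsu is undefined — use method='fixed' with an explicit threshold"
        )
    thr = float(threshold_otsu(plane))
    fg = plane >= thr
    lo = plane[~fg]
    sep = float(plane[fg].mean() - (lo.mean() if lo.size else 0.0))
    if sep < min_class_separation:
        log.debug("channel %s: class separation %.1f < %.1f, falling back to mid-range threshold",
                  channel, sep, min_class_separation)
        return BinaryMask(plane >= 128.0, channel, "otsu", 128.0)
    return BinaryMask(fg, channel, "otsu", thr)


def clean_mask(mask: BinaryMask, min_object_px: int = 20, closing_radius_px: int = 2) -> BinaryMask:
    """Morphological closing followed by small-object removal (idempotent)."""
    if min_object_px < 0 or closing_radius_px < 0:
        raise ValueError("cleaning parameters must be nonnegative")
    px = mask.pixels
    if closing_radius_px > 0:
        px = sk_closing(px, disk(closing_radius_px)).astype(bool)
    if min_object_px > 1:
        # drop components strictly smaller than min_object_px (8-connectivity)
        lab, _ = ndi.label(px, structure=np.ones((3, 3), bool))
        sizes = np.bincount(lab.ravel())
        keep = np.flatnonzero(sizes >= min_object_px)
        keep = keep[keep != 0]
        px = np.isin(lab, keep)
    return replace(mask, pixels=px)


def label_objects(mask: BinaryMask, connectivity: int = 8) -> LabeledObjects:
    """Connected-component labeling (4- or 8-connectivity)."""
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    labels = sk_label(mask.pixels, connectivity=1 if connectivity == 4 else 2)
    props = regionprops(labels)
    areas = np.array([p.area for p in props], dtype=np.int64)
    cents = (
        np.array([p.centroid for p in props], dtype=float)
        if props else np.empty((0, 2))
    )
    bboxes = [tuple(p.bbox) for p in props]
    return LabeledObjects(labels, areas, cents, bboxes, connectivity)


def build_compartment_masks(
    cd10: BinaryMask,
    asma: BinaryMask,
    dapi: BinaryMask,
    vessel_masks: Sequence[BinaryMask] = (),
    min_object_px: int = 20,
    closing_radius_px: int = 2,
    gland_min_dapi_fraction: float = 0.01,
    small_hole_max_px: int = 2000,
) -> CompartmentMasks:
    """Partition a field into stroma, glands, myometrium and background.

    Stroma is the cleaned CD10 layer; regions enclosed by stroma are glands
    when DAPI-lined, merged back into stroma when small (vessel lumina,
    staining dropouts — ``vessel_masks`` pixels always count as such), and
    background otherwise. Myometrium is the cleaned aSMA layer outside
    endometrial tissue (stroma precedence on overlap), so vascular aSMA
    rings inside the stroma never count as myometrium.
    """
    shape = cd10.shape
    for m in (asma, dapi, *vessel_masks):
        if m.shape != shape:
            raise ValueError("compartment input masks differ in shape")

    stroma0 = clean_mask(cd10, min_object_px, closing_radius_px).pixels
    asma_c = clean_mask(asma, min_object_px, closing_radius_px).pixels
    filled = ndi.binary_fill_holes(stroma0)
    holes = filled & ~stroma0

    vessel_union = np.zeros(shape, bool)
    for m in vessel_masks:
        vessel_union |= m.pixels

    glands = np.zeros(shape, bool)
    stroma = stroma0.copy()
    if holes.any():
        lab, n = ndi.label(holes, structure=np.ones((3, 3), bool))
        sizes = np.bincount(lab.ravel())[1:]
        dapi_px = np.bincount(lab.ravel(), weights=dapi.pixels.ravel().astype(float))[1:]
        vess_px = np.bincount(lab.ravel(), weights=vessel_union.ravel().astype(float))[1:]
        gland_ids, merge_ids = [], []
        for i in range(n):
            if dapi_px[i] / sizes[i] >= gland_min_dapi_fraction:
                gland_ids.append(i + 1)
            elif sizes[i] <= small_hole_max_px or vess_px[i] > 0:
                merge_ids.append(i + 1)
            # else: large hole with no nuclei -> background
        if gland_ids:
            glands = np.isin(lab, gland_ids)
        if merge_ids:
            stroma |= np.isin(lab, merge_ids)

    endometrial = stroma | glands
    myometrium = asma_c & ~filled & ~endometrial
    background = ~(endometrial | myometrium)

    def _bm(px: np.ndarray, name: str) -> BinaryMask:
        return BinaryMask(px, name, "derived", float("nan"))

    masks = CompartmentMasks(
        stroma=_bm(stroma, "stroma"),
        glands=_bm(glands, "glands"),
        myometrium=_bm(myometrium, "myometrium"),
        background=_bm(background, "background"),
    )
    assert masks.is_partition(), "compartment masks must partition the field"
    return masks
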