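"""Multichannel field container and OME-TIFF round-trip.

One field = one multipage TIFF with named channels and physical pixel size
in the OME metadata. Planes are stored as 8-bit intensities so that a
write/read round trip is bit-exact.
"""
from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Mapping, Optional, Sequence

import numpy as np
import tifffile

#: Canonical channel order of the marker panel.
CHANNELS = ("DAPI", "CD31", "aSMA", "PDPN", "CD10", "VEGF")


class ChannelError(KeyError):
    """A required channel is missing from a field."""


@dataclass
class ChannelStack:
    """A registered multichannel image of one field.

    planes map channel name -> 2-D intensity array; all planes share the
    same shape. ``pixel_um`` is the physical pixel size in micrometres.
    """

    planes: Dict[str, np.ndarray]
    pixel_um: float
    field_id: str = ""
    specimen_id: str = ""

    def __post_init__(self) -> None:
        if not self.planes:
            raise ValueError("ChannelStack needs at least one plane")
        if self.pixel_um <= 0:
            raise ValueError("pixel_um must be positive")
        shapes = {p.shape for p in self.planes.values()}
        if len(shapes) != 1:
            raise ValueError(f"planes differ in shape: {shapes}")
        for name, p in self.planes.items():
            if p.ndim != 2:
                raise ValueError(f"plane {name!r} is not 2-D")
            if np.issubdtype(p.dtype, np.floating) and (p < 0).any():
                raise ValueError(f"plane {name!r} has negative intensities")

    @property
    def shape(self) -> tuple:
        return next(iter(self.planes.values())).shape

    def plane(self, name: str, aliases: Optional[Mapping[str, str]] = None) -> np.ndarray:
        """Return the plane for canonical channel ``name``, via optional aliases.

        ``aliases`` maps canonical name -> name used in the file
        (e.g. ``{"PDPN": "D2-40"}``).
        """
        wanted = (aliases or {}).get(name, name)
        lower = {k.lower(): k for k in self.planes}
        key = lower.get(wanted.lower())
        if key is None:
            raise ChannelError(
                f"channel {name!r} (looked for {wanted!r}) not in {sorted(self.planes)}"
            )
        return self.planes[key]

    def require(self, names: Iterable[str], aliases: Optional[Mapping[str, str]] = None) -> None:
        missing = []
        for n in names:
            try:
                self.plane(n, aliases)
            except ChannelError:
                missing.append(n)
        if missing:
            raise ChannelError(f"field {self.field_id!r} is missing channels {missing}")


def write_field(stack: ChannelStack, path) -> Path:
    """Write a field as OME-TIFF with channel names and pixel size metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    names = list(stack.planes)
    data = np.stack([np.asarray(stack.planes[n]) for n in names])
    tifffile.imwrite(
        path,
        data,
        ome=True,
        photometric="minisblack",
        compression="zlib",
        metadata={
            "axes": "CYX",
            "Channel": {"Name": names},
            "PhysicalSizeX": stack.pixel_um,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": stack.pixel_um,
            "PhysicalSizeYUnit": "µm",
        },
    )
    return path


def _parse_ome(xml_text: str):
    """Return (channel names, pixel size µm or None) from OME-XML."""
    root = ET.fromstring(xml_text)

    def local(tag: str) -> str:
        return tag.rsplit("}", 1)[-1]

    names: list = []
    pixel_um = None
    for el in root.iter():
        if local(el.tag) == "Pixels":
            if pixel_um is None and "PhysicalSizeX" in el.attrib:
                pixel_um = float(el.attrib["PhysicalSizeX"])
            for ch in el:
                if local(ch.tag) == "Channel":
                    names.append(ch.attrib.get("Name", f"C{len(names)}"))
    return names, pixel_um


def read_field(
    path,
    aliases: Optional[Mapping[str, str]] = None,
    pixel_um: Optional[float] = None,
    required: Sequence[str] = CHANNELS,
) -> ChannelStack:
    """Read a multichannel TIFF field back into a :class:`ChannelStack`.

    Channel names and pixel size come from the OME metadata; ``pixel_um``
    overrides (and is required when the file has no size metadata, because
    densities per mm^2 would otherwise be meaningless).
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        names: Sequence[str] = ()
        meta_px = None
        if tf.ome_metadata:
            names, meta_px = _parse_ome(tf.ome_metadata)
    arr = np.atleast_3d(arr)
    if arr.ndim != 3:
        arr = arr.reshape((-1,) + arr.shape[-2:])
    if not names or len(names) != arr.shape[0]:
        names = [f"C{i}" for i in range(arr.shape[0])]
    px = pixel_um if pixel_um is not None else meta_px
    if px is None:
        raise ValueError(
            f"{path.name}: no physical pixel size in metadata and no override given"
        )
    stem = path.stem
    if stem.endswith(".ome"):
        stem = stem[:-4]
    specimen_id = stem.rsplit("_f", 1)[0] if "_f" in stem else stem
    stack = ChannelStack(
        planes={n: arr[i] for i, n in enumerate(names)},
        pixel_um=float(px),
        field_id=stem,
        specimen_id=specimen_id,
    )
    if required:
        stack.require(required, aliases)
    return stack


def mask_area_mm2(mask: np.ndarray, pixel_um: float) -> float:
    """Area of a boolean mask in mm^2."""
    return float(np.count_nonzero(mask)) * pixel_um**2 / 1e6
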