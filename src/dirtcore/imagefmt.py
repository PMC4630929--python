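"""Readers and writers for every external format the pipeline touches.

Raster photographs (PNG/JPEG/TIFF) are loaded into :class:`RootImage`, a
grayscale intensity grid normalized to [0, 1].  Computed traits are written as
Excel-compatible CSV (RFC 4180, UTF-8, literal ``NA`` for missing values) and
root-tip-path geometry as RSML 1.0 XML.  Per-image experiment metadata is read
from a pre-formatted CSV keyed by image identifier.
"""
from __future__ import annotations

import csv
import logging
import numbers
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
from lxml import etree
from PIL import Image

from .errors import ConsistencyError, FormatError, InvalidInputError

logger = logging.getLogger(__name__)

#: Rec. 601 luminance weights used for color-to-grayscale conversion.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

SUPPORTED_SUFFIXES = {".png", ".jpg", ".jpeg", ".tif", ".tiff"}


@dataclass(frozen=True)
class RootImage:
    """A grayscale photograph of an excavated root crown scene.

    Intensities are normalized to [0, 1]; row index increases downward
    (image convention), so larger row means deeper in the scene.
    """

    pixels: np.ndarray
    source_id: str
    path: Optional[Path] = None

    def __post_init__(self) -> None:
        px = self.pixels
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise InvalidInputError("image must be a non-empty 2D intensity grid")
        if float(px.min()) < 0.0 or float(px.max()) > 1.0:
            raise InvalidInputError("intensities must lie in [0, 1]")

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


@dataclass
class MetadataTable:
    """Per-image metadata rows keyed by image identifier.

    ``columns`` preserves the non-identifier header order of the source CSV;
    each row is a flat key -> string map (genotype, dry biomass, ...).
    """

    rows: dict[str, dict[str, str]] = field(default_factory=dict)
    columns: list[str] = field(default_factory=list)

    def get(self, image_id: str) -> dict[str, str]:
        return self.rows.get(image_id, {})


def _integer_scale(arr: np.ndarray, pil_mode: str) -> float:
    if arr.dtype == np.uint8:
        return 255.0
    if arr.dtype == np.uint16:
        return 65535.0
    # PIL decodes 16-bit grayscale TIFFs to mode "I" (int32); the dynamic
    # range is still 16 bit.
    if pil_mode.startswith("I"):
        return 65535.0
    return float(np.iinfo(arr.dtype).max)


def load_image(path) -> RootImage:
    """Load a PNG/JPEG/TIFF photograph as a normalized grayscale image.

    Color images are converted by fixed luminance weighting
    (0.299 R + 0.587 G + 0.114 B); 8- and 16-bit integer data are rescaled
    to [0, 1].  The ``source_id`` is the file name without its extension.
    """
    p = Path(path)
    try:
        with Image.open(p) as img:
            img.load()
            mode = img.mode
            arr = np.asarray(img)
    except FileNotFoundError:
        raise
    except Exception as exc:  # truncated / undecodable file
        raise FormatError(f"cannot read image file {p}: {exc}") from exc
    if arr.size == 0:
        raise InvalidInputError(f"image {p} has zero size")
    if np.issubdtype(arr.dtype, np.floating):
        gray_channels = arr.astype(np.float64)
    else:
        gray_channels = arr.astype(np.float64) / _integer_scale(arr, mode)
    if gray_channels.ndim == 3:
        rgb = gray_channels[..., :3]  # drop alpha if present
        gray = rgb @ np.asarray(LUMA_WEIGHTS)
    else:
        gray = gray_channels
    gray = np.clip(gray, 0.0, 1.0)
    return RootImage(pixels=gray, source_id=p.stem, path=p)


def _format_cell(value) -> str:
    if isinstance(value, numbers.Real) and not isinstance(value, bool):
        v = float(value)
        if np.isfinite(v):
            if v == int(v) and abs(v) < 1e15:
                return str(int(v))
            return format(v, ".10g")
    return "NA"


def write_traits_csv(records, registry, metadata: Optional[MetadataTable], path) -> Path:
    """Write one CSV row per image with all registry traits in stable order.

    Header: ``image_id``, then trait ids in registry order, then metadata
    columns when a table is supplied.  Missing or failed traits are written
    as the literal ``NA``.  Dialect is RFC 4180 (comma, minimal quoting,
    CRLF) encoded as UTF-8, which Excel opens directly.
    """
    path = Path(path)
    trait_ids = [d.id for d in registry]
    known = set(trait_ids)
    for rec in records:
        unknown = set(rec.values) - known
        if unknown:
            raise ConsistencyError(
                f"record {rec.image_id!r} references unknown trait ids: {sorted(unknown)}"
            )
    meta_cols = list(metadata.columns) if metadata is not None else []
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)  # csv default lineterminator is CRLF
        writer.writerow(["image_id"] + trait_ids + meta_cols)
        for rec in records:
            row = [rec.image_id]
            row += [_format_cell(rec.values.get(tid)) for tid in trait_ids]
            if metadata is not None:
                meta_row = metadata.get(rec.image_id)
                row += [meta_row.get(col, "") for col in meta_cols]
            writer.writerow(row)
    return path


def write_rsml(paths: Sequence, scale, image_meta: Mapping[str, str], path) -> Path:
    """Write root-tip-path polylines as an RSML 1.0 document.

    Coordinates are kept in pixels (``x`` = column, ``y`` = row) with the
    pixel-per-mm resolution recorded in the metadata block, preserving the
    raw measurement.  One ``<root>`` element is emitted per path, with a
    per-point ``diameter`` function when medial radii are available.  An
    empty path list yields a valid scene with a plant and zero roots.
    """
    out = Path(path)
    for rtp in paths:
        if len(rtp.points) < 2:
            raise InvalidInputError("every RSML path needs at least 2 points")
    rsml = etree.Element("rsml")
    meta = etree.SubElement(rsml, "metadata")
    etree.SubElement(meta, "version").text = "1"
    etree.SubElement(meta, "unit").text = "pixel"
    resolution = float(scale.pixels_per_mm) if scale is not None else 1.0
    etree.SubElement(meta, "resolution").text = format(resolution, "g")
    etree.SubElement(meta, "software").text = "dirtcore"
    if image_meta:
        img_el = etree.SubElement(meta, "image")
        for key, value in image_meta.items():
            prop = etree.SubElement(img_el, "property")
            prop.set("name", str(key))
            prop.set("value", str(value))
    scene = etree.SubElement(rsml, "scene")
    plant = etree.SubElement(scene, "plant")
    plant.set("ID", "1")
    for i, rtp in enumerate(paths, start=1):
        root_el = etree.SubElement(plant, "root")
        root_el.set("ID", str(i))
        geom = etree.SubElement(root_el, "geometry")
        poly = etree.SubElement(geom, "polyline")
        for r, c in np.asarray(rtp.points, dtype=float):
            pt = etree.SubElement(poly, "point")
            pt.set("x", format(c, "g"))
            pt.set("y", format(r, "g"))
        radii = getattr(rtp, "radii", None)
        if radii is not None and len(radii) == len(rtp.points):
            funcs = etree.SubElement(root_el, "functions")
            fn = etree.SubElement(funcs, "function")
            fn.set("name", "diameter")
            fn.set("domain", "polyline")
            for r in np.asarray(radii, dtype=float):
                sample = etree.SubElement(fn, "sample")
                sample.set("value", format(2.0 * r, "g"))
    tree = etree.ElementTree(rsml)
    tree.write(str(out), xml_declaration=True, encoding="UTF-8", pretty_print=True)
    return out


def read_metadata_csv(path) -> MetadataTable:
    """Read a pre-formatted metadata CSV whose first column is the image id.

    Duplicate image ids keep the last row (a warning is logged); all values
    are kept as strings.
    """
    p = Path(path)
    with open(p, "r", newline="", encoding="utf-8-sig") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"metadata CSV {p} is empty (missing header row)")
        if not header or not any(h.strip() for h in header):
            raise FormatError(f"metadata CSV {p} has a blank header row")
        columns = [h.strip() for h in header[1:]]
        table = MetadataTable(columns=columns)
        for row in reader:
            if not row or not any(cell.strip() for cell in row):
                continue
            image_id = row[0].strip()
            if image_id in table.rows:
                logger.warning("duplicate metadata row for image id %r; keeping the last", image_id)
            values = row[1:]
            table.rows[image_id] = {
                col: (values[i] if i < len(values) else "") for i, col in enumerate(columns)
            }
    return table
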