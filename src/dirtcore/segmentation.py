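"""Scene segmentation and pixel-to-millimetre calibration.

A protocol-compliant photograph shows a bright root crown on a dark diffuse
background together with a light circular scale marker of known physical
diameter and (optionally) a rectangular identification tag above the root.
This module thresholds the image, labels connected components, classifies
them into root / marker / tag, and derives the pixel size from the marker.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .errors import InvalidInputError, NoRootError
from .imagefmt import RootImage

#: 3x3 cross structuring element used for the single speckle-removal opening.
_CROSS = ndimage.generate_binary_structure(2, 1)
#: 8-connectivity structure for component labeling.
_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass
class BinaryMask:
    """Foreground mask (putative root/marker/tag material) at one threshold."""

    mask: np.ndarray
    threshold_used: float

    @property
    def foreground_fraction(self) -> float:
        return float(self.mask.mean())


@dataclass
class SceneComponent:
    """One labeled connected component with the shape summaries used for
    classification.  Bounding boxes are 0-based, half-open (row0, col0, row1, col1)."""

    label: int
    pixels: np.ndarray  # (N, 2) array of (row, col)
    area: int
    perimeter: int
    bbox: tuple[int, int, int, int]
    centroid: tuple[float, float]
    circularity: float

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.pixels[:, 0], self.pixels[:, 1]] = True
        return m

    @property
    def bbox_fill_ratio(self) -> float:
        r0, c0, r1, c1 = self.bbox
        return self.area / float((r1 - r0) * (c1 - c0))


@dataclass
class RootScene:
    """Classified scene: the root crown, the scale marker and the tag (either
    may be absent), plus residual noise components."""

    root: SceneComponent
    marker: Optional[SceneComponent] = None
    tag: Optional[SceneComponent] = None
    residual: list[SceneComponent] = field(default_factory=list)
    image_shape: tuple[int, int] = (0, 0)

    def root_mask(self) -> np.ndarray:
        return self.root.mask(self.image_shape)


@dataclass(frozen=True)
class ScaleInfo:
    """Pixel-size calibration derived from the circular scale marker."""

    pixels_per_mm: float
    marker_known_diameter_mm: float
    marker_equivalent_diameter_px: float
    circularity: float


def binary_mask(image: RootImage, threshold: float) -> BinaryMask:
    """Threshold the image (foreground iff intensity > threshold) and apply a
    single 3x3-cross binary opening to remove speckle.

    The opening clips sharp convex corners by construction; its purpose is
    removing isolated noise pixels, not preserving exact silhouettes.
    """
    if not 0.0 <= threshold <= 1.0:
        raise InvalidInputError(f"threshold must be in [0, 1], got {threshold}")
    fg = image.pixels > threshold
    opened = ndimage.binary_opening(fg, structure=_CROSS)
    return BinaryMask(mask=opened, threshold_used=float(threshold))


def calibration_sweep(image: RootImage, thresholds: Sequence[float]):
    """Compute one mask per candidate threshold with a small summary
    (foreground fraction, component count) supporting visual selection of the
    best segmentation threshold."""
    thresholds = list(thresholds)
    if not thresholds:
        raise InvalidInputError("threshold list must be non-empty")
    results = []
    for t in thresholds:
        bm = binary_mask(image, t)
        _, n = ndimage.label(bm.mask, structure=_EIGHT)
        summary = {
            "threshold": float(t),
            "foreground_fraction": bm.foreground_fraction,
            "component_count": int(n),
        }
        results.append((float(t), bm, summary))
    return results


def label_components(mask: BinaryMask) -> list[SceneComponent]:
    """Label 8-connected components, sorted by area descending.

    Perimeter is the count of foreground pixels 4-adjacent to background
    (image border counts as background); circularity is the isoperimetric
    quotient 4*pi*A/P^2 clipped to [0, 1.2].
    """
    m = mask.mask
    labels, n = ndimage.label(m, structure=_EIGHT)
    if n == 0:
        return []
    pad = np.pad(m, 1, constant_values=False)
    has_bg_neighbor = (
        ~pad[:-2, 1:-1] | ~pad[2:, 1:-1] | ~pad[1:-1, :-2] | ~pad[1:-1, 2:]
    )
    boundary = m & has_bg_neighbor
    areas = np.bincount(labels.ravel(), minlength=n + 1)
    perims = np.bincount(labels[boundary], minlength=n + 1)
    slices = ndimage.find_objects(labels)
    components = []
    for lab in range(1, n + 1):
        sl = slices[lab - 1]
        pix = np.argwhere(labels == lab)
        area = int(areas[lab])
        perim = int(perims[lab])
        circ = 4.0 * np.pi * area / (perim * perim) if perim > 0 else 1.2
        components.append(
            SceneComponent(
                label=lab,
                pixels=pix,
                area=area,
                perimeter=perim,
                bbox=(sl[0].start, sl[1].start, sl[0].stop, sl[1].stop),
                centroid=(float(pix[:, 0].mean()), float(pix[:, 1].mean())),
                circularity=float(min(max(circ, 0.0), 1.2)),
            )
        )
    components.sort(key=lambda c: (-c.area, c.centroid[0], c.centroid[1]))
    return components


def classify_components(components: Sequence[SceneComponent], image: RootImage, config) -> RootScene:
    """Assign scene roles.

    1. Marker: the most circular component with circularity >= ``c_min`` and
       area >= ``a_min``.
    2. Tag: the largest remaining component with bounding-box fill ratio
       >= 0.75 whose centroid lies above the top edge of the largest
       remaining component.
    3. Root: the largest component not claimed as marker or tag; everything
       else is residual noise.
    """
    comps = sorted(components, key=lambda c: (-c.area, c.centroid[0], c.centroid[1]))
    if not comps:
        raise NoRootError("no root found: the mask contains no components")
    c_min = getattr(config, "c_min", 0.7)
    a_min = getattr(config, "a_min", 200)

    marker = None
    candidates = [c for c in comps if c.circularity >= c_min and c.area >= a_min]
    if candidates:
        marker = max(candidates, key=lambda c: c.circularity)
    remaining = [c for c in comps if c is not marker]
    if not remaining:
        raise NoRootError("no root found: only the scale marker is present")

    largest = remaining[0]
    tag = None
    tag_candidates = [
        c
        for c in remaining[1:]
        if c.bbox_fill_ratio >= 0.75 and c.centroid[0] < largest.bbox[0]
    ]
    if tag_candidates:
        tag = max(tag_candidates, key=lambda c: c.area)

    root = next(c for c in remaining if c is not tag)
    residual = [c for c in comps if c not in (root, marker, tag)]
    return RootScene(
        root=root, marker=marker, tag=tag, residual=residual, image_shape=image.pixels.shape
    )


def scale_from_marker(marker: SceneComponent, known_diameter_mm: float) -> ScaleInfo:
    """Derive pixels-per-mm from the marker's equivalent diameter
    d_px = 2*sqrt(area/pi)."""
    if known_diameter_mm <= 0:
        raise InvalidInputError("marker known diameter must be positive")
    if marker.area < 1:
        raise InvalidInputError("marker component is empty")
    d_px = 2.0 * np.sqrt(marker.area / np.pi)
    return ScaleInfo(
        pixels_per_mm=d_px / known_diameter_mm,
        marker_known_diameter_mm=float(known_diameter_mm),
        marker_equivalent_diameter_px=float(d_px),
        circularity=marker.circularity,
    )


def crop_tag(scene: RootScene, image: RootImage, pad: int = 5) -> Optional[np.ndarray]:
    """Return the tag bounding-box crop (padded, clipped to the image) for
    external barcode/QR decoding, or ``None`` when no tag was found."""
    if scene.tag is None:
        return None
    r0, c0, r1, c1 = scene.tag.bbox
    r0 = max(0, r0 - pad)
    c0 = max(0, c0 - pad)
    r1 = min(image.height, r1 + pad)
    c1 = min(image.width, c1 + pad)
    return image.pixels[r0:r1, c0:c1]
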