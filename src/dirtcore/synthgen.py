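"""Synthetic protocol-compliant scenes with analytically known traits.

Each generated image emulates the field imaging protocol: a dark, noisy
background; one bright near-circular scale marker of known physical diameter;
one rectangular identification tag above the root; and a root drawn as
constant-width strokes.  Strokes are binary-valued (plus optional Gaussian
noise) rather than photorealistic so that the ground truth stays analytic:
widths come from the per-row extent formula of the stroke geometry, angles
from the stroke directions, the pixel size from the marker specification.

Presets
-------
``monocot_fan``
    A vertical stem of known width from the collar down to a branch point,
    then straight strokes fanning out to a common depth.
``dicot_taproot``
    A vertical taproot with straight laterals emerging at known depths and
    angles, alternating sides.
``excised_segments``
    Disjoint horizontal segments of known lengths and widths.

Rasterization: a stroke of width w covers the pixel centers strictly within
w/2 of its centerline segment; even widths therefore measure exactly w under
the medial-diameter convention (2 * Euclidean distance to background).
"""
from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from PIL import Image

from .errors import InvalidInputError
from .imagefmt import RootImage
from .traits import fit_line_angle

PRESETS = ("monocot_fan", "dicot_taproot", "excised_segments")

_DEFAULTS = {
    "monocot_fan": dict(
        depth=450, branch_frac=0.1, stem_width=16, n_strokes=9,
        theta_left=25.0, theta_right=25.0, stroke_width=6,
    ),
    "dicot_taproot": dict(
        depth=420, tap_width=14, n_laterals=8, lat_width=6, lat_len=90,
        lat_angle=55.0, z_first=0.25, z_last=0.85,
    ),
    "excised_segments": dict(segment_lengths=(180, 260, 340), segment_width=10),
}


@dataclass(frozen=True)
class SyntheticRootSpec:
    """Generative parameters for one protocol-compliant scene."""

    preset: str
    params: dict = field(default_factory=dict)
    seed: int = 0
    background_level: float = 0.08
    noise_sd: float = 0.03
    root_intensity: float = 0.9
    marker_diameter_px: float = 60.0
    marker_diameter_mm: float = 12.0
    marker_intensity: float = 0.95
    with_marker: bool = True
    with_tag: bool = True
    tag_intensity: float = 0.85
    collar_row: int = 90

    def resolved_params(self) -> dict:
        if self.preset not in PRESETS:
            raise InvalidInputError(f"unknown preset {self.preset!r}")
        p = dict(_DEFAULTS[self.preset])
        p.update(self.params)
        return p


@dataclass
class GroundTruth:
    """Expected trait values (same units as the pipeline reports, i.e. mm
    where a scale is defined) with per-trait tolerances."""

    traits: dict  # trait id -> (expected value, tolerance)
    pixels_per_mm: float

    def value(self, tid: str) -> float:
        return self.traits[tid][0]

    def tol(self, tid: str) -> float:
        return self.traits[tid][1]


def _stamp_segment(mask: np.ndarray, p0, p1, width: float,
                   row_lo: Optional[int] = None, row_hi: Optional[int] = None) -> None:
    """Set pixels whose centers lie strictly within width/2 of the segment
    p0-p1 (rows optionally clipped to [row_lo, row_hi])."""
    half = width / 2.0
    r0f, c0f = float(p0[0]), float(p0[1])
    r1f, c1f = float(p1[0]), float(p1[1])
    rmin = int(math.floor(min(r0f, r1f) - half)) - 1
    rmax = int(math.ceil(max(r0f, r1f) + half)) + 1
    cmin = int(math.floor(min(c0f, c1f) - half)) - 1
    cmax = int(math.ceil(max(c0f, c1f) + half)) + 1
    if row_lo is not None:
        rmin = max(rmin, row_lo)
    if row_hi is not None:
        rmax = min(rmax, row_hi)
    rmin = max(rmin, 0)
    cmin = max(cmin, 0)
    rmax = min(rmax, mask.shape[0] - 1)
    cmax = min(cmax, mask.shape[1] - 1)
    if rmax < rmin or cmax < cmin:
        return
    rr, cc = np.mgrid[rmin : rmax + 1, cmin : cmax + 1]
    dr, dc = r1f - r0f, c1f - c0f
    seg_len2 = dr * dr + dc * dc
    if seg_len2 == 0:
        dist = np.hypot(rr - r0f, cc - c0f)
    else:
        t = np.clip(((rr - r0f) * dr + (cc - c0f) * dc) / seg_len2, 0.0, 1.0)
        dist = np.hypot(rr - (r0f + t * dr), cc - (c0f + t * dc))
    mask[rmin : rmax + 1, cmin : cmax + 1] |= dist < half


# ---------------------------------------------------------------------------
# preset geometry + analytic ground truth
# ---------------------------------------------------------------------------

def _fan_geometry(spec: SyntheticRootSpec, ppmm: float):
    p = spec.resolved_params()
    H = int(p["depth"])
    Hb = int(round(p["branch_frac"] * H))
    ws = int(p["stem_width"])
    wf = int(p["stroke_width"])
    thetas = np.linspace(-float(p["theta_left"]), float(p["theta_right"]), int(p["n_strokes"]))
    tl = math.radians(float(p["theta_left"]))
    tr = math.radians(float(p["theta_right"]))
    spread = (H - Hb) * max(math.tan(tl), math.tan(tr)) + wf
    width = 2 * int(math.ceil(spread)) + 160
    width = max(width, 420)
    row0 = spec.collar_row
    shape = (row0 + H + 40, width)
    col0 = width // 2

    mask = np.zeros(shape, dtype=bool)
    _stamp_segment(mask, (row0, col0), (row0 + Hb, col0), ws, row_lo=row0, row_hi=row0 + Hb)
    for th in thetas:
        rad = math.radians(float(th))
        end = (row0 + H, col0 + math.tan(rad) * (H - Hb))
        _stamp_segment(mask, (row0 + Hb, col0), end, wf, row_lo=row0 + Hb, row_hi=row0 + H)

    # analytic per-row extent: stem rows, then the fan envelope
    d = np.arange(0, H + 1, dtype=float)
    cos_l, cos_r = math.cos(tl), math.cos(tr)
    fan_extent = (d - Hb) * (math.tan(tl) + math.tan(tr)) + (wf / 2.0) * (1 / cos_l + 1 / cos_r)
    extent = np.where(d <= Hb, float(ws - 1), fan_extent)

    gt: dict = {}
    gt["WIDTH_MAX"] = (float(extent.max()) / ppmm, max(2.0 / ppmm, 0.02 * extent.max() / ppmm))
    gt["WIDTH_MED"] = (float(np.median(extent)) / ppmm, max(2.0 / ppmm, 0.04 * np.median(extent) / ppmm))
    gt["DIA_STM"] = (ws / ppmm, max(2.0, 0.1 * ws) / ppmm)
    gt["DIA_STM_SIMPLE"] = ((ws - 1) / ppmm, 2.0 / ppmm)
    gt["ANG_BTM"] = (90.0 - 0.5 * (math.degrees(tl) + math.degrees(tr)), 3.0)

    # top band boundary: vertical stem edge then the outermost stroke edge
    n_top = int(round(0.3 * H))
    sides = []
    for t_side, cos_side in ((tl, cos_l), (tr, cos_r)):
        rows = np.arange(0, n_top + 1, dtype=float)
        offs = np.where(
            rows <= Hb,
            (ws - 1) / 2.0,
            (rows - Hb) * math.tan(t_side) + (wf / 2.0) / cos_side,
        )
        sides.append(fit_line_angle(np.stack([rows, offs], axis=1)))
    gt["ANG_TOP"] = (float(np.mean(sides)), 3.0)

    # tip count is only guaranteed when adjacent strokes separate well before
    # the bottom of the fan
    if len(thetas) > 1:
        gaps = np.radians(np.diff(thetas))
        l_sep = (wf + 2) / max(gaps.min(), 1e-9)
        if l_sep < 0.45 * (H - Hb):
            gt["RTP_COUNT"] = (float(len(thetas)), 0.0)
    else:
        gt["RTP_COUNT"] = (1.0, 0.0)
    return mask, gt


def _dicot_geometry(spec: SyntheticRootSpec, ppmm: float):
    p = spec.resolved_params()
    H = int(p["depth"])
    wt = int(p["tap_width"])
    wl = int(p["lat_width"])
    ll = float(p["lat_len"])
    phi = float(p["lat_angle"])
    n = int(p["n_laterals"])
    zs = np.linspace(float(p["z_first"]), float(p["z_last"]), n)
    row0 = spec.collar_row
    width = max(int(2 * (ll + 60)), 420)
    col0 = width // 2
    shape = (row0 + H + 40, width)
    mask = np.zeros(shape, dtype=bool)
    _stamp_segment(mask, (row0, col0), (row0 + H, col0), wt, row_lo=row0, row_hi=row0 + H)
    rad = math.radians(phi)
    for i, z in enumerate(zs):
        side = 1 if i % 2 == 0 else -1
        start = (row0 + z * H, col0)
        end = (start[0] + ll * math.cos(rad), col0 + side * ll * math.sin(rad))
        _stamp_segment(mask, start, end, wl)

    advt = int(np.sum(zs <= 0.05))
    basal = int(np.sum((zs > 0.05) & (zs <= 0.15)))
    lats = int(np.sum(zs > 0.15))
    gt: dict = {
        "ADVT_COUNT": (float(advt), 0.0),
        "BASAL_COUNT": (float(basal), 0.0),
        "TAP_DIA": (wt / ppmm, max(2.0, 0.15 * wt) / ppmm),
        "HYP_DIA": (wt / ppmm, max(2.0, 0.15 * wt) / ppmm),
        "LT_AVG_ANG": (phi, 5.0),
        "LT_MED_DIA": (wl / ppmm, 2.0 / ppmm),
    }
    if lats:
        gt["LT_BRA_FRQ"] = (lats / (H / ppmm), 0.15 * lats / (H / ppmm))
        gt["LT_DIST_FIRST"] = (
            float(zs[zs > 0.15][0]) * H / ppmm,
            max(8.0, 0.1 * zs[zs > 0.15][0] * H) / ppmm,
        )
        gt["LT_AVG_LEN"] = ((ll - wl) / ppmm, max(8.0, 0.15 * ll) / ppmm)
    return mask, gt


def _excised_geometry(spec: SyntheticRootSpec, ppmm: float):
    p = spec.resolved_params()
    lengths = [int(v) for v in p["segment_lengths"]]
    w = int(p["segment_width"])
    row0 = spec.collar_row
    gap = 50
    width = max(max(lengths) + 160, 420)
    shape = (row0 + len(lengths) * gap + 40, width)
    mask = np.zeros(shape, dtype=bool)
    for i, L in enumerate(lengths):
        r = row0 + 20 + i * gap
        c0 = (width - L) // 2
        _stamp_segment(mask, (r, c0), (r, c0 + L - 1), w)
    lens_mm = np.asarray([(L - w) / ppmm for L in lengths])
    gt = {
        "EXC_SEG_COUNT": (float(len(lengths)), 0.0),
        "EXC_TOT_LEN": (float(lens_mm.sum()), max(4.0 * len(lengths), 0.08 * lens_mm.sum() * ppmm) / ppmm),
        "EXC_AVG_LEN": (float(lens_mm.mean()), max(4.0, 0.08 * lens_mm.mean() * ppmm) / ppmm),
        "EXC_MED_LEN": (float(np.median(lens_mm)), max(4.0, 0.08 * float(np.median(lens_mm)) * ppmm) / ppmm),
        "EXC_MAX_LEN": (float(lens_mm.max()), max(4.0, 0.08 * lens_mm.max() * ppmm) / ppmm),
        "EXC_MED_DIA": (w / ppmm, 2.0 / ppmm),
        "EXC_AVG_DIA": (w / ppmm, 2.0 / ppmm),
        "EXC_TIP_COUNT": (2.0 * len(lengths), 0.0),
        "EXC_BRA_FRQ": (0.0, 1e-9),
        "EXC_AREA": (sum(L * (w - 1) for L in lengths) / ppmm**2,
                     0.15 * sum(L * (w - 1) for L in lengths) / ppmm**2),
    }
    return mask, gt


_GEOMETRY = {
    "monocot_fan": _fan_geometry,
    "dicot_taproot": _dicot_geometry,
    "excised_segments": _excised_geometry,
}


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_scene(spec: SyntheticRootSpec) -> tuple[RootImage, GroundTruth]:
    """Render one scene deterministically from its spec.

    Raises an invalid-input error if the marker, tag and root regions would
    overlap.
    """
    ppmm = spec.marker_diameter_px / spec.marker_diameter_mm
    root_mask, gt_traits = _GEOMETRY[spec.preset](spec, ppmm)
    shape = root_mask.shape

    marker_mask = np.zeros(shape, dtype=bool)
    if spec.with_marker:
        r = spec.marker_diameter_px / 2.0
        center = (45.0, 45.0)
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
        marker_mask = np.hypot(rr - center[0], cc - center[1]) <= r
    tag_mask = np.zeros(shape, dtype=bool)
    if spec.with_tag:
        col0 = shape[1] // 2
        tag_mask[20:44, col0 - 55 : col0 + 55] = True

    if (root_mask & marker_mask).any() or (root_mask & tag_mask).any() or (
        marker_mask & tag_mask
    ).any():
        raise InvalidInputError("marker, tag and root regions must be pairwise disjoint")

    base = np.full(shape, spec.background_level)
    base[tag_mask] = spec.tag_intensity
    base[marker_mask] = spec.marker_intensity
    base[root_mask] = spec.root_intensity
    rng = np.random.default_rng(spec.seed)
    img = np.clip(base + spec.noise_sd * rng.standard_normal(shape), 0.0, 1.0)

    gt = GroundTruth(traits=dict(gt_traits), pixels_per_mm=ppmm if spec.with_marker else 1.0)
    image = RootImage(pixels=img, source_id=f"{spec.preset}_{spec.seed:05d}")
    return image, gt


# ---------------------------------------------------------------------------
# suites
# ---------------------------------------------------------------------------

def sample_spec(preset: str, parameter_ranges: dict, seed: int,
                scene_overrides: Optional[dict] = None) -> SyntheticRootSpec:
    """Sample one spec with parameters drawn uniformly from the given ranges
    ((lo, hi) tuples for continuous values, sequences for discrete choices)."""
    if preset not in PRESETS:
        raise InvalidInputError(f"unknown preset {preset!r}")
    rng = np.random.default_rng(seed)
    params = {}
    scene_kwargs = dict(scene_overrides or {})
    for name in sorted(parameter_ranges):
        spec_range = parameter_ranges[name]
        if isinstance(spec_range, tuple) and len(spec_range) == 2 and all(
            isinstance(v, (int, float)) for v in spec_range
        ):
            lo, hi = spec_range
            if lo > hi:
                raise InvalidInputError(f"empty range for parameter {name!r}")
            value = float(rng.uniform(lo, hi))
        else:
            choices = list(spec_range)
            if not choices:
                raise InvalidInputError(f"empty choice list for parameter {name!r}")
            value = choices[int(rng.integers(len(choices)))]
        if name in ("noise_sd", "background_level"):
            scene_kwargs[name] = value
        else:
            params[name] = value
    return SyntheticRootSpec(preset=preset, params=params, seed=seed, **scene_kwargs)


def make_suite(n: int, preset: str, parameter_ranges: dict, seed: int,
               scene_overrides: Optional[dict] = None):
    """Render ``n`` scenes with per-item seeds ``seed + i`` (reproducible
    end-to-end).  Returns a list of (spec, image, ground truth) triples."""
    if n < 1:
        raise InvalidInputError("suite size must be >= 1")
    items = []
    for i in range(n):
        spec = sample_spec(preset, parameter_ranges, seed + i, scene_overrides)
        image, gt = render_scene(spec)
        items.append((spec, image, gt))
    return items


#: Parameter ranges for the monocot validation suite: opening angle
#: 20-80 degrees total, stem widths 8-40 px, 5-25 strokes, noise sd <= 0.05.
MONOCOT_VALIDATION_RANGES = {
    "theta_left": (10.0, 40.0),
    "theta_right": (10.0, 40.0),
    "stem_width": list(range(8, 42, 2)),
    "n_strokes": list(range(5, 26)),
    "stroke_width": [6, 8],
    "noise_sd": (0.01, 0.05),
}


def monocot_validation_suite(n: int = 50, seed: int = 1):
    """The seeded fan suite used to validate stem diameter, widths and
    top/bottom angles against analytic ground truth."""
    return make_suite(n, "monocot_fan", MONOCOT_VALIDATION_RANGES, seed)


def write_suite(items, outdir) -> Path:
    """Write PNG renderings plus a ground-truth CSV for offline inspection."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    trait_ids = sorted({tid for _, _, gt in items for tid in gt.traits})
    with open(out / "ground_truth.csv", "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_id", "pixels_per_mm"] + trait_ids)
        for spec, image, gt in items:
            png = out / f"{image.source_id}.png"
            Image.fromarray((image.pixels * 255).astype(np.uint8)).save(png)
            row = [image.source_id, format(gt.pixels_per_mm, "g")]
            row += [
                format(gt.value(t), ".6g") if t in gt.traits else ""
                for t in trait_ids
            ]
            writer.writerow(row)
    return out
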