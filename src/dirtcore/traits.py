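"""The 78-trait registry and its measurement operations.

Traits fall into four families: common traits defined for every root system
architecture (shape, width profile, stem diameter, top/bottom angle, spatial
distribution), monocot traits (root-tissue-angle statistics of fibrous
crowns), dicot traits (taproot, hypocotyl and lateral measurements) and
traits for excised root samples (per-segment lengths, diameters, branching).

All lengths are reported in mm (or px with a unit flag when no scale marker
was found), areas in mm^2, angles in absolute degrees from horizontal in
[0, 90] (steeper = larger).  Depth is measured along image rows, as a
fraction of the root bounding-box height.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .errors import InvalidInputError
from .segmentation import RootScene, ScaleInfo
from .structure import (
    RootTipPath,
    Skeleton,
    SkeletonGraph,
    build_skeleton_graph,
    distance_transform,
    find_collar,
    prune_spurs,
    root_tip_paths,
    skeletonize,
)

CATEGORIES = ("common", "monocot", "dicot", "excised")


class FailureCode(enum.Enum):
    NOT_APPLICABLE = "not-applicable"
    NO_SCALE = "no-scale"
    COMPUTATION_FAILED = "computation-failed"


@dataclass(frozen=True)
class TraitDefinition:
    id: str
    category: str
    units: str
    description: str = ""
    parameters: dict = field(default_factory=dict)


@dataclass
class TraitRecord:
    """Per-image trait values; failed traits carry a :class:`FailureCode`."""

    image_id: str
    values: dict = field(default_factory=dict)
    units: str = "mm"  # "px" when no scale marker was found
    provenance: dict = field(default_factory=dict)

    def numeric(self, trait_id: str) -> Optional[float]:
        v = self.values.get(trait_id)
        return float(v) if isinstance(v, (int, float)) else None


def _defs() -> list[TraitDefinition]:
    d: list[TraitDefinition] = []

    def add(tid, cat, units, desc, **params):
        d.append(TraitDefinition(tid, cat, units, desc, dict(params)))

    # -- common (31) ------------------------------------------------------
    add("AREA", "common", "mm^2", "projected root area (foreground pixel count)")
    add("AVG_DENSITY", "common", "1", "root pixel count over bounding-box area")
    add("WIDTH_MED", "common", "mm", "median horizontal extent over non-empty rows")
    add("WIDTH_MAX", "common", "mm", "maximum horizontal extent")
    add("DIA_STM", "common", "mm", "stem diameter from medial radii near the collar", f_stem=0.05)
    add("DIA_STM_SIMPLE", "common", "mm", "stem diameter from top-band row extents", f_stem=0.05)
    add("ANG_TOP", "common", "deg", "root top angle from side-boundary line fits", f_top=0.3)
    add("ANG_BTM", "common", "deg", "root bottom angle from side-boundary line fits", f_btm=0.3)
    add("SKL_DEPTH", "common", "mm", "skeleton bounding-box height")
    add("SKL_WIDTH", "common", "mm", "skeleton bounding-box width")
    add("RTP_COUNT", "common", "count", "number of collar-to-tip paths")
    add("RDISTR_X", "common", "1", "horizontal centroid position within the root bbox")
    add("RDISTR_Y", "common", "1", "vertical centroid position within the root bbox")
    for x in range(10, 100, 10):
        add(f"D{x}", "common", "1", f"depth fraction accumulating {x}% of total row width")
    for x in range(10, 100, 10):
        add(f"DS{x}", "common", "1", f"slope of the cumulative width curve at D{x}")

    # -- monocot (22) -----------------------------------------------------
    add("STA_RANGE", "monocot", "deg", "range of soil-tissue angles sampled at fixed depths")
    add("STA_DOM_I", "monocot", "deg", "dominant soil-tissue angle (most populated 10-deg bin)")
    add("STA_DOM_II", "monocot", "deg", "second dominant soil-tissue angle bin")
    for x in (25, 50, 75, 90):
        add(f"STA_{x}_I", "monocot", "deg", f"median tissue angle at {x}% depth, major side")
        add(f"STA_{x}_II", "monocot", "deg", f"median tissue angle at {x}% depth, minor side")
    add("RTA_RANGE", "monocot", "deg", "range of root-tip angles (tangent at 90% arclength)")
    add("RTA_DOM_I", "monocot", "deg", "dominant root-tip angle bin")
    add("RTA_DOM_II", "monocot", "deg", "second dominant root-tip angle bin")
    add("NR_RTP_SEG_I", "monocot", "count", "paths whose tip angle falls in the dominant bin")
    add("NR_RTP_SEG_II", "monocot", "count", "paths whose tip angle falls in the second bin")
    for x in (25, 50, 75, 90):
        add(f"CP_DIA{x}", "monocot", "mm", f"central-path diameter at {x}% depth")
    add("MAX_DIA_90", "monocot", "mm", "max central-path diameter within 90% of its arclength")
    add("DROP_50", "monocot", "1", "depth fraction where width first drops below half its max")

    # -- dicot (15) -------------------------------------------------------
    add("ADVT_COUNT", "dicot", "count", "adventitious roots (branching at <= 5% depth)", z_max=0.05)
    add("BASAL_COUNT", "dicot", "count", "basal roots (branching at 5-15% depth)", z_max=0.15)
    add("ADVT_ANG", "dicot", "deg", "mean emergence angle of adventitious roots")
    add("BASAL_ANG", "dicot", "deg", "mean emergence angle of basal roots")
    add("HYP_DIA", "dicot", "mm", "hypocotyl diameter (taproot diameter at 2.5% depth)")
    add("TAP_DIA", "dicot", "mm", "taproot diameter at 50% depth")
    add("LT_BRA_FRQ", "dicot", "1/mm", "lateral branching frequency along the taproot")
    add("LT_AVG_LEN", "dicot", "mm", "mean lateral subtree length")
    add("LT_DIST_FIRST", "dicot", "mm", "taproot arclength from collar to the first lateral")
    add("LT_MED_DIA", "dicot", "mm", "median lateral diameter")
    add("LT_AVG_DIA", "dicot", "mm", "mean lateral diameter")
    add("LT_AVG_ANG", "dicot", "deg", "mean lateral emergence angle")
    add("LT_ANG_RANGE", "dicot", "deg", "range of lateral emergence angles")
    add("LT_MIN_ANG", "dicot", "deg", "minimum lateral emergence angle")
    add("LT_MAX_ANG", "dicot", "deg", "maximum lateral emergence angle")

    # -- excised (10) -----------------------------------------------------
    add("EXC_SEG_COUNT", "excised", "count", "number of excised root segments")
    add("EXC_TOT_LEN", "excised", "mm", "total skeleton length over all segments")
    add("EXC_AVG_LEN", "excised", "mm", "mean segment skeleton length")
    add("EXC_MED_LEN", "excised", "mm", "median segment skeleton length")
    add("EXC_MAX_LEN", "excised", "mm", "maximum segment skeleton length")
    add("EXC_AVG_DIA", "excised", "mm", "mean skeleton diameter over all segments")
    add("EXC_MED_DIA", "excised", "mm", "median skeleton diameter over all segments")
    add("EXC_BRA_FRQ", "excised", "1/mm", "branch tips per unit skeleton length")
    add("EXC_TIP_COUNT", "excised", "count", "total skeleton tips over all segments")
    add("EXC_AREA", "excised", "mm^2", "total segment area")
    return d


_REGISTRY = _defs()


def trait_registry() -> list[TraitDefinition]:
    """The full 78-entry trait registry in stable output order."""
    return list(_REGISTRY)


def registry_ids(category: Optional[str] = None) -> list[str]:
    return [t.id for t in _REGISTRY if category is None or t.category == category]


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def fit_line_angle(points: np.ndarray) -> float:
    """Absolute angle from horizontal (degrees, [0, 90]) of the total
    least-squares line through ``points`` (rows, cols), via the principal
    direction of the centered point cloud."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        raise InvalidInputError("need at least 2 points to fit a line")
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    dr, dc = vt[0]
    return math.degrees(math.atan2(abs(dr), abs(dc)))


def _angle_between_lines(u: np.ndarray, v: np.ndarray) -> float:
    """Absolute angle between two undirected directions, degrees in [0, 90]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise InvalidInputError("zero-length direction vector")
    c = abs(float(np.dot(u, v))) / (nu * nv)
    return math.degrees(math.acos(min(1.0, max(-1.0, c))))


def _scale_factor(scale: Optional[ScaleInfo]) -> float:
    return float(scale.pixels_per_mm) if scale is not None else 1.0


# ---------------------------------------------------------------------------
# width profile
# ---------------------------------------------------------------------------

@dataclass
class WidthProfile:
    """Per-row horizontal extent and pixel count of the root component,
    from its top bounding-box row to its bottom row."""

    extents: np.ndarray  # (H,) rightmost - leftmost + 1 per row, 0 on empty rows
    counts: np.ndarray  # (H,) foreground pixels per row
    top_row: int

    @property
    def height(self) -> int:
        return len(self.extents)

    def depth_fracs(self) -> np.ndarray:
        h = self.height
        return np.arange(h) / max(h - 1, 1)


def width_profile(scene: RootScene) -> WidthProfile:
    pix = scene.root.pixels
    r0, _, r1, _ = scene.root.bbox
    h = r1 - r0
    extents = np.zeros(h, dtype=int)
    counts = np.zeros(h, dtype=int)
    rows = pix[:, 0] - r0
    cols = pix[:, 1]
    order = np.argsort(rows, kind="stable")
    rows, cols = rows[order], cols[order]
    uniq, starts = np.unique(rows, return_index=True)
    ends = np.append(starts[1:], len(rows))
    for u, a, b in zip(uniq, starts, ends):
        extents[u] = cols[a:b].max() - cols[a:b].min() + 1
        counts[u] = b - a
    return WidthProfile(extents=extents, counts=counts, top_row=r0)


# ---------------------------------------------------------------------------
# common traits
# ---------------------------------------------------------------------------

def compute_shape_traits(
    profile: WidthProfile,
    scene: RootScene,
    skeleton: Optional[Skeleton],
    scale: Optional[ScaleInfo],
) -> dict:
    """Width, area, density, spatial-distribution and depth-profile traits."""
    out: dict = {}
    s = _scale_factor(scale)
    ext = profile.extents
    nonzero = ext[ext > 0]
    if nonzero.size == 0:
        return {
            tid: FailureCode.COMPUTATION_FAILED
            for tid in registry_ids("common")
            if not tid.startswith(("ANG", "DIA", "RTP"))
        }
    out["WIDTH_MED"] = float(np.median(nonzero)) / s
    out["WIDTH_MAX"] = float(ext.max()) / s
    root = scene.root
    out["AREA"] = root.area / (s * s)
    r0, c0, r1, c1 = root.bbox
    out["AVG_DENSITY"] = root.area / float((r1 - r0) * (c1 - c0))
    cr, cc = root.centroid
    out["RDISTR_X"] = (cc - c0) / max(c1 - c0 - 1, 1)
    out["RDISTR_Y"] = (cr - r0) / max(r1 - r0 - 1, 1)
    if skeleton is not None and skeleton.mask.any():
        sp = np.argwhere(skeleton.mask)
        out["SKL_DEPTH"] = float(sp[:, 0].max() - sp[:, 0].min() + 1) / s
        out["SKL_WIDTH"] = float(sp[:, 1].max() - sp[:, 1].min() + 1) / s
    else:
        out["SKL_DEPTH"] = FailureCode.COMPUTATION_FAILED
        out["SKL_WIDTH"] = FailureCode.COMPUTATION_FAILED
    cum = np.cumsum(ext, dtype=float)
    total = cum[-1]
    fracs = profile.depth_fracs()
    norm = cum / total
    for x in range(10, 100, 10):
        i = int(np.searchsorted(cum, x / 100.0 * total))
        i = min(i, len(cum) - 1)
        out[f"D{x}"] = float(fracs[i])
        a, b = max(0, i - 1), min(len(cum) - 1, i + 1)
        df = fracs[b] - fracs[a]
        out[f"DS{x}"] = float((norm[b] - norm[a]) / df) if df > 0 else FailureCode.COMPUTATION_FAILED
    return out


def _depth_frac_of_rows(rows: np.ndarray, top: int, height: int) -> np.ndarray:
    return (np.asarray(rows) - top) / max(height - 1, 1)


def compute_stem_traits(
    paths: Sequence[RootTipPath],
    profile: WidthProfile,
    scale: Optional[ScaleInfo],
    config=None,
) -> dict:
    """Stem diameter near the collar, from medial radii along the central
    (longest) root-tip path and, independently, from top-band row extents."""
    if not paths:
        raise InvalidInputError("stem traits need at least one root-tip path")
    s = _scale_factor(scale)
    f_stem = getattr(config, "f_stem", 0.05)
    out: dict = {}
    central = max(paths, key=lambda p: p.arclength_px)
    fracs = _depth_frac_of_rows(central.points[:, 0], profile.top_row, profile.height)
    band = central.radii[fracs <= f_stem]
    if band.size == 0:  # widen to the top 10 rows
        band = central.radii[central.points[:, 0] <= profile.top_row + 10]
    out["DIA_STM"] = (
        2.0 * float(np.median(band)) / s if band.size else FailureCode.COMPUTATION_FAILED
    )
    n_rows = max(1, round(f_stem * profile.height))
    top_ext = profile.extents[:n_rows]
    top_ext = top_ext[top_ext > 0]
    out["DIA_STM_SIMPLE"] = (
        float(np.median(top_ext)) / s if top_ext.size else FailureCode.COMPUTATION_FAILED
    )
    return out


def _side_boundaries(scene: RootScene) -> tuple[np.ndarray, np.ndarray]:
    """Outermost root pixel per row: (left boundary, right boundary), each an
    (H, 2) array of (row, col) over non-empty rows."""
    pix = scene.root.pixels
    rows = pix[:, 0]
    cols = pix[:, 1]
    order = np.lexsort((cols, rows))
    rows, cols = rows[order], cols[order]
    uniq, starts = np.unique(rows, return_index=True)
    ends = np.append(starts[1:], len(rows))
    left = np.stack([uniq, cols[starts]], axis=1)
    right = np.stack([uniq, cols[ends - 1]], axis=1)
    return left, right


def compute_angle_traits(scene: RootScene, paths=None, config=None) -> dict:
    """Root top and bottom angle: per side, the absolute angle from horizontal
    of a total-least-squares line through that side's outermost boundary
    pixels within the top (resp. bottom) depth band; the trait is the mean
    over the two sides."""
    f_top = getattr(config, "f_top", 0.3)
    f_btm = getattr(config, "f_btm", 0.3)
    left, right = _side_boundaries(scene)
    r0, _, r1, _ = scene.root.bbox
    h = r1 - r0
    out: dict = {}
    for tid, lo, hi in (("ANG_TOP", 0.0, f_top), ("ANG_BTM", 1.0 - f_btm, 1.0)):
        side_angles = []
        for boundary in (left, right):
            fr = _depth_frac_of_rows(boundary[:, 0], r0, h)
            pts = boundary[(fr >= lo) & (fr <= hi)]
            if len(pts) >= 5:
                side_angles.append(fit_line_angle(pts))
        out[tid] = float(np.mean(side_angles)) if side_angles else FailureCode.COMPUTATION_FAILED
    return out


# ---------------------------------------------------------------------------
# monocot traits
# ---------------------------------------------------------------------------

_STA_DEPTHS = (0.25, 0.5, 0.75, 0.9)


def _first_index_at_frac(path: RootTipPath, frac: float, top: int, height: int) -> Optional[int]:
    fr = _depth_frac_of_rows(path.points[:, 0], top, height)
    idx = np.nonzero(fr >= frac)[0]
    return int(idx[0]) if idx.size else None


def _dominant_bins(samples: np.ndarray, bin_width: float) -> list[tuple[float, int]]:
    """(bin center, count) ordered by population, ties broken toward the
    steeper bin."""
    edges = np.arange(0.0, 90.0 + bin_width, bin_width)
    idx = np.clip(np.digitize(samples, edges) - 1, 0, len(edges) - 2)
    counts = np.bincount(idx, minlength=len(edges) - 1)
    order = sorted(range(len(counts)), key=lambda i: (-counts[i], -i))
    return [(float(edges[i] + bin_width / 2.0), int(counts[i])) for i in order]


def compute_monocot_traits(
    paths: Sequence[RootTipPath],
    skeleton: Optional[Skeleton],
    profile: WidthProfile,
    scale: Optional[ScaleInfo],
    config=None,
) -> dict:
    """Soil-tissue-angle (STA) and root-tip-angle (RTA) statistics, dominant
    angle bins, central-path diameters and the width drop-off depth."""
    if not paths:
        raise InvalidInputError("monocot traits need at least one root-tip path")
    s = _scale_factor(scale)
    bin_width = getattr(config, "bin_width", 10.0)
    top, h = profile.top_row, profile.height
    out: dict = {}

    # STA: tangent where each path first reaches depth fraction d
    sta_samples: list[float] = []
    collar_col = paths[0].collar_col
    for d in _STA_DEPTHS:
        lefts, rights = [], []
        for p in paths:
            i = _first_index_at_frac(p, d, top, h)
            if i is None:
                continue
            ang = float(p.tangents[i])
            sta_samples.append(ang)
            (lefts if p.points[i, 1] < collar_col else rights).append(ang)
        major, minor = (lefts, rights) if len(lefts) > len(rights) else (rights, lefts)
        if len(lefts) == len(rights):
            med_l = np.median(lefts) if lefts else -1.0
            med_r = np.median(rights) if rights else -1.0
            major, minor = (lefts, rights) if med_l >= med_r else (rights, lefts)
        key = f"STA_{int(d * 100)}"
        out[f"{key}_I"] = float(np.median(major)) if major else FailureCode.COMPUTATION_FAILED
        out[f"{key}_II"] = float(np.median(minor)) if minor else FailureCode.NOT_APPLICABLE
    if sta_samples:
        arr = np.asarray(sta_samples)
        out["STA_RANGE"] = float(arr.max() - arr.min())
        bins = _dominant_bins(arr, bin_width)
        out["STA_DOM_I"] = bins[0][0]
        out["STA_DOM_II"] = bins[1][0] if len(bins) > 1 and bins[1][1] > 0 else (
            FailureCode.NOT_APPLICABLE if len(paths) < 2 else bins[0][0]
        )
    else:
        out["STA_RANGE"] = out["STA_DOM_I"] = out["STA_DOM_II"] = FailureCode.COMPUTATION_FAILED

    # RTA: tangent at 90% of each path's own arclength
    rta_samples = []
    for p in paths:
        cum = p.cumlength()
        i = int(np.searchsorted(cum, 0.9 * cum[-1]))
        rta_samples.append(float(p.tangents[min(i, len(cum) - 1)]))
    arr = np.asarray(rta_samples)
    out["RTA_RANGE"] = float(arr.max() - arr.min())
    bins = _dominant_bins(arr, bin_width)
    dom_i, dom_ii = bins[0], (bins[1] if len(bins) > 1 else None)
    out["RTA_DOM_I"] = dom_i[0]
    in_bin_i = int(np.sum(np.abs(arr - dom_i[0]) <= bin_width / 2.0))
    out["NR_RTP_SEG_I"] = in_bin_i
    if len(paths) < 2 or dom_ii is None or dom_ii[1] == 0:
        out["RTA_DOM_II"] = FailureCode.NOT_APPLICABLE
        out["NR_RTP_SEG_II"] = FailureCode.NOT_APPLICABLE
    else:
        out["RTA_DOM_II"] = dom_ii[0]
        out["NR_RTP_SEG_II"] = int(np.sum(np.abs(arr - dom_ii[0]) <= bin_width / 2.0))

    # central-path diameters
    central = max(paths, key=lambda p: p.arclength_px)
    for x in (25, 50, 75, 90):
        i = _first_index_at_frac(central, x / 100.0, top, h)
        out[f"CP_DIA{x}"] = (
            2.0 * float(central.radii[i]) / s if i is not None else FailureCode.COMPUTATION_FAILED
        )
    cum = central.cumlength()
    within = central.radii[cum <= 0.9 * cum[-1]]
    out["MAX_DIA_90"] = (
        2.0 * float(within.max()) / s if within.size else FailureCode.COMPUTATION_FAILED
    )

    # width drop-off
    ext = profile.extents
    imax = int(np.argmax(ext))
    half = 0.5 * ext[imax]
    below = np.nonzero(ext[imax + 1 :] < half)[0]
    fracs = profile.depth_fracs()
    out["DROP_50"] = float(fracs[imax + 1 + below[0]]) if below.size else 1.0
    return out


# ---------------------------------------------------------------------------
# dicot traits
# ---------------------------------------------------------------------------

def _path_edge_keys(graph: SkeletonGraph, path: RootTipPath) -> set:
    g = graph.graph
    used = set()
    for a, b in zip(path.node_seq[:-1], path.node_seq[1:]):
        key, _ = min(g[a][b].items(), key=lambda kv: kv[1]["length"])
        used.add((min(a, b), max(a, b), key))
    return used


def _direction_at(path: RootTipPath, idx: int, half: int = 4) -> np.ndarray:
    a = max(0, idx - half)
    b = min(len(path.points) - 1, idx + half)
    return path.points[b].astype(float) - path.points[a].astype(float)


def compute_dicot_traits(
    paths: Sequence[RootTipPath],
    graph: SkeletonGraph,
    scale: Optional[ScaleInfo],
    config=None,
    scene: Optional[RootScene] = None,
) -> dict:
    """Taproot, hypocotyl and lateral traits.

    The taproot is the central (longest) root-tip path.  Branches leaving it
    are classified by junction depth fraction z: adventitious (z <= 0.05),
    basal (0.05 < z <= 0.15), lateral otherwise.  Emergence angle is the
    absolute angle between a branch's initial secant and the taproot tangent
    at the junction.
    """
    if not paths:
        raise InvalidInputError("dicot traits need at least one root-tip path")
    s = _scale_factor(scale)
    advt_z = getattr(config, "advt_z", 0.05)
    basal_z = getattr(config, "basal_z", 0.15)
    window = getattr(config, "tangent_window", 9)
    out: dict = {}
    central = max(paths, key=lambda p: p.arclength_px)
    g = graph.graph
    if scene is not None:
        r0, _, r1, _ = scene.root.bbox
        top, h = r0, r1 - r0
    else:
        top = int(central.points[:, 0].min())
        h = int(central.points[:, 0].max()) - top + 1
    used = _path_edge_keys(graph, central)
    taproot_nodes = set(central.node_seq)
    cum = central.cumlength()

    g_sub = g.copy()
    g_sub.remove_nodes_from(taproot_nodes)

    branches = []  # (z, cum_arclen, emergence_angle, subtree_len_px, subtree_radii)
    for seq_i, node in enumerate(central.node_seq[1:-1], start=1):
        jrow, _ = graph.node_pos(node)
        z = (jrow - top) / max(h - 1, 1)
        j_idx = central.node_point_idx[seq_i]
        tap_dir = _direction_at(central, j_idx, half=window // 2)
        for u, v, key, data in g.edges(node, keys=True, data=True):
            if (min(u, v), max(u, v), key) in used:
                continue
            poly = data["polyline"]
            node_pixels = set(map(tuple, g.nodes[node]["pixels"]))
            if tuple(poly[0]) not in node_pixels:
                poly = poly[::-1]
            # the medial axis bends toward the parent within roughly one
            # medial radius of the junction; start the branch secant beyond
            # that exclusion zone
            steps = np.diff(poly.astype(float), axis=0)
            cumd = np.concatenate([[0.0], np.cumsum(np.hypot(steps[:, 0], steps[:, 1]))])
            jr_, jc_ = graph.node_pos(node)
            excl = 1.5 * float(graph.skeleton.radii[jr_, jc_])
            i0 = int(np.searchsorted(cumd, excl))
            if i0 >= len(poly) - 1:
                i0 = 0  # branch too short to skip the zone: use the whole edge
            k = min(i0 + window - 1, len(poly) - 1)
            branch_dir = poly[k].astype(float) - poly[i0].astype(float)
            try:
                ang = _angle_between_lines(tap_dir, branch_dir)
            except InvalidInputError:
                continue
            far = v if u == node else u
            subtree_len = float(data["length"])
            subtree_radii = [np.asarray(data["radii"], dtype=float)]
            if far not in taproot_nodes and far in g_sub:
                comp = nx.node_connected_component(g_sub, far)
                for a, b, d2 in g_sub.edges(comp, data=True):
                    subtree_len += float(d2["length"])
                    subtree_radii.append(np.asarray(d2["radii"], dtype=float))
            branches.append((z, float(cum[j_idx]), ang, subtree_len, np.concatenate(subtree_radii)))

    advt = [b for b in branches if b[0] <= advt_z]
    basal = [b for b in branches if advt_z < b[0] <= basal_z]
    lats = [b for b in branches if b[0] > basal_z]
    out["ADVT_COUNT"] = len(advt)
    out["BASAL_COUNT"] = len(basal)
    out["ADVT_ANG"] = float(np.mean([b[2] for b in advt])) if advt else FailureCode.NOT_APPLICABLE
    out["BASAL_ANG"] = float(np.mean([b[2] for b in basal])) if basal else FailureCode.NOT_APPLICABLE

    for tid, frac in (("HYP_DIA", 0.025), ("TAP_DIA", 0.5)):
        i = _first_index_at_frac(central, frac, top, h)
        out[tid] = 2.0 * float(central.radii[i]) / s if i is not None else FailureCode.COMPUTATION_FAILED

    tap_len_mm = central.arclength_px / s
    out["LT_BRA_FRQ"] = len(lats) / tap_len_mm if tap_len_mm > 0 else FailureCode.COMPUTATION_FAILED
    if lats:
        out["LT_AVG_LEN"] = float(np.mean([b[3] for b in lats])) / s
        out["LT_DIST_FIRST"] = float(min(b[1] for b in lats)) / s
        all_radii = np.concatenate([b[4] for b in lats])
        out["LT_MED_DIA"] = 2.0 * float(np.median(all_radii)) / s
        out["LT_AVG_DIA"] = 2.0 * float(np.mean(all_radii)) / s
        angs = np.asarray([b[2] for b in lats])
        out["LT_AVG_ANG"] = float(angs.mean())
        out["LT_ANG_RANGE"] = float(angs.max() - angs.min())
        out["LT_MIN_ANG"] = float(angs.min())
        out["LT_MAX_ANG"] = float(angs.max())
    else:
        out["LT_AVG_LEN"] = 0.0
        out["LT_DIST_FIRST"] = FailureCode.NOT_APPLICABLE
        for tid in ("LT_MED_DIA", "LT_AVG_DIA", "LT_AVG_ANG", "LT_ANG_RANGE", "LT_MIN_ANG", "LT_MAX_ANG"):
            out[tid] = FailureCode.NOT_APPLICABLE
    return out


# ---------------------------------------------------------------------------
# excised traits
# ---------------------------------------------------------------------------

def compute_excised_traits(scene: RootScene, scale: Optional[ScaleInfo], config=None) -> dict:
    """Per-segment length/diameter/branching traits for excised samples.

    Every large component (area >= ``a_root``) counts as a segment: the one
    classified as root plus any residual components above the debris cutoff.
    """
    s = _scale_factor(scale)
    a_root = getattr(config, "a_root", 200)
    min_spur = getattr(config, "min_spur_len", 10.0)
    segments = [scene.root] + [c for c in scene.residual if c.area >= a_root]
    seg_lengths = []
    tip_total = 0
    all_radii = []
    total_area = 0
    shape = scene.image_shape
    for comp in segments:
        total_area += comp.area
        mask = comp.mask(shape)
        try:
            skel = skeletonize(mask, distance_transform(mask))
            sg = prune_spurs(build_skeleton_graph(skel), min_spur)
        except InvalidInputError:
            continue
        seg_lengths.append(sg.total_length())
        tip_total += len(sg.tips())
        rad = sg.skeleton.radii[sg.skeleton.mask]
        if rad.size:
            all_radii.append(rad)
    out: dict = {"EXC_SEG_COUNT": len(segments), "EXC_TIP_COUNT": tip_total}
    if seg_lengths:
        lens = np.asarray(seg_lengths) / s
        out["EXC_TOT_LEN"] = float(lens.sum())
        out["EXC_AVG_LEN"] = float(lens.mean())
        out["EXC_MED_LEN"] = float(np.median(lens))
        out["EXC_MAX_LEN"] = float(lens.max())
        tot = float(lens.sum())
        out["EXC_BRA_FRQ"] = max(0, tip_total - 2 * len(seg_lengths)) / tot if tot > 0 else 0.0
    else:
        for tid in ("EXC_TOT_LEN", "EXC_AVG_LEN", "EXC_MED_LEN", "EXC_MAX_LEN", "EXC_BRA_FRQ"):
            out[tid] = FailureCode.COMPUTATION_FAILED
    if all_radii:
        rad = np.concatenate(all_radii)
        out["EXC_AVG_DIA"] = 2.0 * float(rad.mean()) / s
        out["EXC_MED_DIA"] = 2.0 * float(np.median(rad)) / s
    else:
        out["EXC_AVG_DIA"] = out["EXC_MED_DIA"] = FailureCode.COMPUTATION_FAILED
    out["EXC_AREA"] = total_area / (s * s)
    return out


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclass
class SceneAnalysis:
    """Intermediate products shared by the trait families."""

    profile: WidthProfile
    field: np.ndarray
    skeleton: Skeleton
    graph: SkeletonGraph
    collar: int
    paths: list[RootTipPath]


def analyze_scene(scene: RootScene, config=None) -> SceneAnalysis:
    """Run the structural stages (distance field, skeleton, graph, spur
    pruning, collar, root-tip paths) once for reuse by all trait families."""
    min_spur = getattr(config, "min_spur_len", 10.0)
    window = getattr(config, "tangent_window", 9)
    profile = width_profile(scene)
    mask = scene.root_mask()
    field_ = distance_transform(mask)
    skel = skeletonize(mask, field_)
    graph = prune_spurs(build_skeleton_graph(skel), min_spur)
    collar = find_collar(graph, scene)
    paths = root_tip_paths(graph, collar, tangent_window=window)
    return SceneAnalysis(
        profile=profile, field=field_, skeleton=graph.skeleton, graph=graph,
        collar=collar, paths=paths,
    )


_CLASS_FAMILIES = {
    "monocot": {"common", "monocot"},
    "dicot": {"common", "dicot"},
    "excised": {"common", "excised"},
    "all": set(CATEGORIES),
}


def compute_all(
    scene: RootScene,
    config=None,
    scale: Optional[ScaleInfo] = None,
    analysis: Optional[SceneAnalysis] = None,
) -> TraitRecord:
    """Compute the full registry for one scene.

    Families outside ``config.root_class`` (and ids outside
    ``config.trait_selection``) are marked not-applicable; a failing family
    marks only its own traits as failed and never aborts the image.
    """
    root_class = getattr(config, "root_class", "all")
    selection = getattr(config, "trait_selection", "all")
    families = _CLASS_FAMILIES[root_class]
    record = TraitRecord(
        image_id=getattr(scene, "source_id", "") or "",
        units="mm" if scale is not None else "px",
        provenance={
            "threshold": getattr(config, "threshold", None),
            "pixels_per_mm": scale.pixels_per_mm if scale is not None else None,
            "min_spur_len": getattr(config, "min_spur_len", 10.0),
            "root_class": root_class,
        },
    )
    values = {t.id: FailureCode.NOT_APPLICABLE for t in _REGISTRY}

    if analysis is None:
        try:
            analysis = analyze_scene(scene, config)
        except Exception:
            analysis = None

    def run(category, fail_ids, fn):
        if category not in families:
            return
        try:
            values.update(fn())
        except Exception:
            for tid in fail_ids:
                values[tid] = FailureCode.COMPUTATION_FAILED

    _shape_ids = [t for t in registry_ids("common") if t not in (
        "DIA_STM", "DIA_STM_SIMPLE", "ANG_TOP", "ANG_BTM", "RTP_COUNT")]
    if analysis is not None:
        a = analysis
        run("common", _shape_ids,
            lambda: compute_shape_traits(a.profile, scene, a.skeleton, scale))
        run("common", ["DIA_STM", "DIA_STM_SIMPLE"],
            lambda: compute_stem_traits(a.paths, a.profile, scale, config))
        run("common", ["ANG_TOP", "ANG_BTM"],
            lambda: compute_angle_traits(scene, a.paths, config))
        if "common" in families:
            values["RTP_COUNT"] = len(a.paths)
        run("monocot", registry_ids("monocot"),
            lambda: compute_monocot_traits(a.paths, a.skeleton, a.profile, scale, config))
        run("dicot", registry_ids("dicot"),
            lambda: compute_dicot_traits(a.paths, a.graph, scale, config, scene))
    else:
        for cat in ("common", "monocot", "dicot"):
            if cat in families:
                for tid in registry_ids(cat):
                    values[tid] = FailureCode.COMPUTATION_FAILED
    run("excised", registry_ids("excised"), lambda: compute_excised_traits(scene, scale, config))

    if selection != "all":
        selected = set(selection)
        for tid in values:
            if tid not in selected:
                values[tid] = FailureCode.NOT_APPLICABLE
    record.values = values
    return record
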