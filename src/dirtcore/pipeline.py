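"""Per-image processing and parallel batch orchestration.

Each image runs through load -> mask -> components -> classify -> scale ->
skeleton -> graph -> root-tip paths -> traits.  Stage failures are contained
per image (the manifest records the failing stage); a batch never aborts
because of a single bad photograph.  Batch output order is the sorted input
file names regardless of worker count or completion order, so trait CSVs are
byte-identical for any parallelism level.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from PIL import Image

from . import traits as traits_mod
from .errors import ConfigError, InvalidInputError, NoRootError
from .imagefmt import (
    SUPPORTED_SUFFIXES,
    MetadataTable,
    load_image,
    write_rsml,
    write_traits_csv,
)
from .segmentation import binary_mask, classify_components, label_components, scale_from_marker
from .traits import FailureCode, TraitRecord, compute_all, trait_registry

logger = logging.getLogger(__name__)

PIPELINE_VERSION = "1.0.0"

_ROOT_CLASSES = ("dicot", "monocot", "excised", "all")


@dataclass
class PipelineConfig:
    """Resolved computation parameters (defaults < config file < CLI flags)."""

    threshold: float = 0.5
    marker_diameter_mm: float = 25.4
    root_class: str = "all"
    trait_selection: object = "all"  # "all" or a list of trait ids
    f_top: float = 0.3
    f_btm: float = 0.3
    f_stem: float = 0.05
    c_min: float = 0.7
    a_min: int = 200
    a_root: int = 200
    min_spur_len: float = 10.0
    tangent_window: int = 9
    bin_width: float = 10.0
    advt_z: float = 0.05
    basal_z: float = 0.15
    output_dir: Optional[str] = None
    workers: int = 1
    debug_artifacts: bool = False

    def validate(self) -> "PipelineConfig":
        bad = []
        if not 0.0 <= self.threshold <= 1.0:
            bad.append("threshold")
        if self.marker_diameter_mm <= 0:
            bad.append("marker_diameter_mm")
        if self.root_class not in _ROOT_CLASSES:
            bad.append("root_class")
        for name in ("f_top", "f_btm", "f_stem", "advt_z", "basal_z"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                bad.append(name)
        if not 0.0 <= self.c_min <= 1.2:
            bad.append("c_min")
        if self.a_min < 1:
            bad.append("a_min")
        if self.a_root < 1:
            bad.append("a_root")
        if self.min_spur_len < 0:
            bad.append("min_spur_len")
        if self.tangent_window < 3:
            bad.append("tangent_window")
        if self.bin_width <= 0 or self.bin_width > 90:
            bad.append("bin_width")
        if self.workers < 1:
            bad.append("workers")
        if self.trait_selection != "all" and not isinstance(self.trait_selection, (list, tuple, set)):
            bad.append("trait_selection")
        if bad:
            raise ConfigError(f"configuration values out of range: {', '.join(sorted(set(bad)))}")
        return self


def load_config(path=None, **flags) -> PipelineConfig:
    """Layered configuration: package defaults, overridden by a config file
    (YAML or flat ``key=value`` lines), overridden by explicit flags."""
    values: dict = {}
    if path is not None:
        text = Path(path).read_text(encoding="utf-8")
        parsed = None
        try:
            parsed = yaml.safe_load(text)
        except yaml.YAMLError:
            parsed = None
        if not isinstance(parsed, dict):
            parsed = {}
            for line in text.splitlines():
                line = line.strip()
                if not line or line.startswith("#") or "=" not in line:
                    continue
                key, _, val = line.partition("=")
                parsed[key.strip()] = yaml.safe_load(val.strip())
        values.update(parsed)
    values.update({k: v for k, v in flags.items() if v is not None})
    known = {f.name: f for f in dataclasses.fields(PipelineConfig)}
    unknown = set(values) - set(known)
    if unknown:
        raise ConfigError(f"unknown configuration keys: {', '.join(sorted(unknown))}")
    return PipelineConfig(**values).validate()


@dataclass
class ImageResult:
    image_id: str
    status: str  # ok | no-root | no-marker(px-units) | failed:<stage>
    record: TraitRecord
    artifacts: dict = field(default_factory=dict)


def _empty_record(image_id: str) -> TraitRecord:
    return TraitRecord(image_id=image_id, values={}, units="px")


def process_image(path, config: PipelineConfig) -> ImageResult:
    """Run the full per-image pipeline with stage-level fault containment."""
    p = Path(path)
    image_id = p.stem
    stage = "load"
    try:
        image = load_image(p)
        stage = "mask"
        mask = binary_mask(image, config.threshold)
        stage = "classify"
        try:
            scene = classify_components(label_components(mask), image, config)
        except NoRootError:
            return ImageResult(image_id, "no-root", _empty_record(image_id))
        stage = "scale"
        scale = None
        status = "ok"
        if scene.marker is not None:
            scale = scale_from_marker(scene.marker, config.marker_diameter_mm)
        else:
            status = "no-marker(px-units)"
        stage = "traits"
        record = compute_all(scene, config, scale)
        record.image_id = image_id
        stage = "artifacts"
        artifacts = _write_artifacts(image, mask, scene, scale, record, config)
        return ImageResult(image_id, status, record, artifacts)
    except Exception as exc:
        logger.warning("image %s failed at stage %s: %s", image_id, stage, exc)
        return ImageResult(image_id, f"failed:{stage}", _empty_record(image_id))


def _write_artifacts(image, mask, scene, scale, record, config) -> dict:
    if not config.output_dir:
        return {}
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts = {}
    mask_png = outdir / f"{record.image_id}_mask.png"
    Image.fromarray((mask.mask * 255).astype(np.uint8)).save(mask_png)
    artifacts["mask"] = str(mask_png)
    try:
        analysis = traits_mod.analyze_scene(scene, config)
        rsml = outdir / f"{record.image_id}.rsml"
        write_rsml(analysis.paths, scale, {"label": record.image_id}, rsml)
        artifacts["rsml"] = str(rsml)
        if config.debug_artifacts:
            skel_png = outdir / f"{record.image_id}_skeleton.png"
            Image.fromarray((analysis.skeleton.mask * 255).astype(np.uint8)).save(skel_png)
            artifacts["skeleton"] = str(skel_png)
    except Exception:
        pass  # structural artifacts are best-effort
    return artifacts


def _process_one(args) -> ImageResult:
    path, config = args
    return process_image(path, config)


def process_batch(
    input_dir,
    config: PipelineConfig,
    workers: Optional[int] = None,
    metadata: Optional[MetadataTable] = None,
):
    """Process every image in a directory, in parallel across worker
    processes, and write the trait CSV plus a computation manifest.

    Returns ``(csv_path, manifest_dict)``.
    """
    indir = Path(input_dir)
    files = sorted(
        p for p in indir.iterdir() if p.suffix.lower() in SUPPORTED_SUFFIXES and p.is_file()
    )
    if not files:
        raise InvalidInputError(f"no image files found in {indir}")
    workers = workers if workers is not None else config.workers
    started = datetime.now(timezone.utc).isoformat()
    if workers > 1:
        with ProcessPoolExecutor(max_workers=workers) as pool:
            results = list(pool.map(_process_one, [(str(p), config) for p in files]))
    else:
        results = [process_image(p, config) for p in files]
    finished = datetime.now(timezone.utc).isoformat()

    outdir = Path(config.output_dir) if config.output_dir else indir
    outdir.mkdir(parents=True, exist_ok=True)
    csv_path = outdir / "traits.csv"
    write_traits_csv([r.record for r in results], trait_registry(), metadata, csv_path)
    manifest = {
        "pipeline_version": PIPELINE_VERSION,
        "config": {
            k: (list(v) if isinstance(v, (tuple, set)) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "started": started,
        "finished": finished,
        "images": {r.image_id: r.status for r in results},
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8")
    return csv_path, manifest
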