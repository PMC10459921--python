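"""File plumbing: acquisition-stack TIFF + manifest JSON, COCO annotation
round trips, scene JSON, and image output."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import tifffile
from PIL import Image

from .boxes import BBox, coco_to_cxcywh_norm
from .optics import AcquisitionStack, Frame
from .phantom import Annotation, AnnotationSet, Cell, PhantomScene

__all__ = [
    "write_stack",
    "read_stack",
    "write_coco",
    "read_coco",
    "write_scene_json",
    "read_scene_json",
    "save_png",
    "load_png",
    "SchemaError",
]


class SchemaError(ValueError):
    """Malformed annotation/scene JSON, with the offending field path."""


def write_stack(stack: AcquisitionStack, out_dir: Path) -> Path:
    """Write frames as a multi-frame 16-bit TIFF plus a manifest JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    peak = max(float(f.intensity.max()) for f in stack.frames) or 1.0
    pages = np.stack(
        [np.round(f.intensity / peak * 65535).astype(np.uint16) for f in stack.frames]
    )
    tifffile.imwrite(out_dir / "stack.tif", pages)
    manifest = {
        "lowres_side": stack.lowres_side,
        "downsample_ratio": stack.downsample_ratio,
        "pixel_pitch_highres_um": stack.pixel_pitch_highres,
        "na": stack.na,
        "intensity_scale": peak / 65535.0,
        "frames": [
            {
                "led_row": f.led_row,
                "led_col": f.led_col,
                "led_index": f.led_index,
                "channel": f.channel,
                "wavelength_um": f.wavelength,
                "kx": f.kx,
                "ky": f.ky,
            }
            for f in stack.frames
        ],
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out_dir


def read_stack(stack_dir: Path) -> AcquisitionStack:
    stack_dir = Path(stack_dir)
    manifest = json.loads((stack_dir / "manifest.json").read_text())
    pages = tifffile.imread(stack_dir / "stack.tif")
    if pages.ndim == 2:
        pages = pages[None]
    scale = manifest["intensity_scale"]
    frames = [
        Frame(
            intensity=page.astype(float) * scale,
            led_row=meta["led_row"],
            led_col=meta["led_col"],
            led_index=meta["led_index"],
            channel=meta["channel"],
            wavelength=meta["wavelength_um"],
            kx=meta["kx"],
            ky=meta["ky"],
        )
        for page, meta in zip(pages, manifest["frames"])
    ]
    return AcquisitionStack(
        frames=frames,
        lowres_side=manifest["lowres_side"],
        downsample_ratio=manifest["downsample_ratio"],
        pixel_pitch_highres=manifest["pixel_pitch_highres_um"],
        na=manifest["na"],
    )


def write_coco(annotation_sets: Sequence[AnnotationSet], path: Path) -> Path:
    """COCO detection JSON: [x, y, w, h] pixel floats, top-left origin."""
    path = Path(path)
    images = []
    annotations = []
    ann_id = 1
    for aset in annotation_sets:
        images.append(
            {
                "id": aset.image_id,
                "width": aset.image_side,
                "height": aset.image_side,
                "file_name": f"image_{aset.image_id:05d}.png",
            }
        )
        for ann, coco_box in zip(aset.annotations, aset.coco_boxes()):
            annotations.append(
                {
                    "id": ann_id,
                    "image_id": aset.image_id,
                    "category_id": 1,
                    "bbox": [round(float(v), 4) for v in coco_box],
                    "area": round(float(coco_box[2] * coco_box[3]), 4),
                    "iscrowd": 0,
                }
            )
            ann_id += 1
    doc = {
        "categories": [{"id": 1, "name": "wbc"}],
        "images": images,
        "annotations": annotations,
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(doc, indent=1, sort_keys=True))
    return path


def read_coco(path: Path) -> List[AnnotationSet]:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise SchemaError(f"invalid JSON: {e}") from e
    for key in ("images", "annotations", "categories"):
        if key not in doc:
            raise SchemaError(f"missing top-level field '{key}'")
    cats = {c["id"]: c["name"] for c in doc["categories"]}
    sets: Dict[int, AnnotationSet] = {}
    for im in doc["images"]:
        for f in ("id", "width", "height"):
            if f not in im:
                raise SchemaError(f"images[].{f} missing")
        sets[im["id"]] = AnnotationSet(
            annotations=[], image_id=im["id"], image_side=im["width"]
        )
    for i, ann in enumerate(doc["annotations"]):
        for f in ("image_id", "bbox", "category_id"):
            if f not in ann:
                raise SchemaError(f"annotations[{i}].{f} missing")
        if ann["image_id"] not in sets:
            raise SchemaError(f"annotations[{i}].image_id unknown")
        side = sets[ann["image_id"]].image_side
        box = coco_to_cxcywh_norm(np.asarray(ann["bbox"], dtype=float), side)
        sets[ann["image_id"]].annotations.append(
            Annotation(
                box=BBox(cx=float(box[0]), cy=float(box[1]), w=float(box[2]), h=float(box[3])),
                label=cats.get(ann["category_id"], "wbc"),
            )
        )
    return [sets[k] for k in sorted(sets)]


def write_scene_json(scene: PhantomScene, path: Path) -> Path:
    path = Path(path)
    doc = {
        "field_of_view_um": scene.field_of_view,
        "seed": scene.seed,
        "background_absorption": scene.background_absorption,
        "cells": [
            {
                "kind": c.kind,
                "center_um": list(c.center),
                "radius_um": c.radius,
                "absorption": c.absorption,
                "phase_delay": c.phase_delay,
                "nucleus_fraction": c.nucleus_fraction,
            }
            for c in scene.cells
        ],
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(doc, indent=1))
    return path


def read_scene_json(path: Path) -> PhantomScene:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise SchemaError(f"invalid JSON: {e}") from e
    try:
        cells = [
            Cell(
                kind=c["kind"],
                center=tuple(c["center_um"]),
                radius=c["radius_um"],
                absorption=c["absorption"],
                phase_delay=c["phase_delay"],
                nucleus_fraction=c.get("nucleus_fraction", 0.0),
            )
            for c in doc["cells"]
        ]
        return PhantomScene(
            field_of_view=doc["field_of_view_um"],
            cells=cells,
            seed=doc["seed"],
            background_absorption=doc.get("background_absorption", 0.05),
        )
    except KeyError as e:
        raise SchemaError(f"missing field {e}") from e


def save_png(image: np.ndarray, path: Path) -> Path:
    """Save an H×W or H×W×3 float image in [0, 1] as 8-bit PNG."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.round(np.clip(image, 0, 1) * 255).astype(np.uint8)
    Image.fromarray(arr).save(path)
    return path


def load_png(path: Path) -> np.ndarray:
    return np.asarray(Image.open(path), dtype=float) / 255.0
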