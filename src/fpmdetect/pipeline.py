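"""End-to-end orchestration: phantom generation → acquisition simulation →
reconstruction → crop extraction → GAN augmentation → detector training →
evaluation, with a run manifest tying artifacts to checksums and one seed."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml
from PIL import Image

from . import io as fio
from .boxes import LossWeights
from .detector import (
    DETRDetector,
    DetectorConfig,
    evaluate_map,
    forward_detect,
    train_detector,
)
from .gan import GanConfig, augment_dataset, train_dcgan
from .optics import (
    CHANNELS,
    CoherentTransferFunction,
    LEDArray,
    NoiseSpec,
    simulate_stack,
)
from .phantom import (
    PhantomConfig,
    generate_scene,
    render_highres,
    render_rgb,
    scene_to_annotations,
)
from .recon import reconstruct_rgb

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "load_config", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: Dict = {
    # NOTE: optics geometry (na, pitch, distance) is not specified by any
    # reference; these are plausible FPM-scale defaults.
    "leds": {"rows": 7, "cols": 7, "pitch_mm": 4.0, "distance_mm": 90.0},
    "optics": {
        "na": 0.1,
        "wavelengths_um": {"red": 0.632, "green": 0.532, "blue": 0.470},
        "highres_side": 128,
        "pixel_pitch_um": 0.4,
    },
    "sensor": {"ratio": 4, "noise": {"gaussian_sigma": 0.0, "poisson_photons": 0.0}},
    "phantom": {
        "n_images": 8,
        "field_of_view_um": 64.0,
        "n_wbc_max": 3,
        "n_rbc": 18,
        "overlap_prob": 0.2,
    },
    "recon": {"iters": 5},
    "dataset": {"train_size": 128, "split": 0.8, "optical": True},
    "gan": {"epochs": 5, "base_channels": 64, "batch_size": 8},
    "detector": {
        "epochs": 5,
        "batch_size": 4,
        "lr": 1e-3,
        "num_queries": 10,
        "hidden_dim": 32,
        "encoder_layers": 1,
        "decoder_layers": 1,
        "heads": 4,
        "backbone": "mini",
        "improved_blocks": True,
        "box_loss": "ciou",
    },
}


def load_config(path: Optional[Path] = None) -> Dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        _merge(cfg, user)
    return cfg


def _merge(base: Dict, upd: Dict) -> None:
    for k, v in upd.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _merge(base[k], v)
        else:
            base[k] = v


@dataclass
class RunManifest:
    seed: int
    config: Dict
    stages: Dict[str, Dict] = dc_field(default_factory=dict)
    started: float = dc_field(default_factory=time.time)

    def record(self, stage: str, **info) -> None:
        self.stages[stage] = {**info, "timestamp": time.time()}

    def to_json(self) -> str:
        return json.dumps(
            {"seed": self.seed, "config": self.config, "stages": self.stages},
            indent=1,
            sort_keys=True,
            default=str,
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _resize(image: np.ndarray, side: int) -> np.ndarray:
    if image.shape[0] == side:
        return image
    im = Image.fromarray(np.round(np.clip(image, 0, 1) * 255).astype(np.uint8))
    return np.asarray(im.resize((side, side), Image.BILINEAR), dtype=float) / 255.0


def _phantom_config(cfg: Dict, n_wbc: int) -> PhantomConfig:
    p = cfg["phantom"]
    return PhantomConfig(
        field_of_view=p["field_of_view_um"],
        n_wbc=n_wbc,
        n_rbc=p["n_rbc"],
        overlap_prob=p["overlap_prob"],
    )


def make_detection_image(
    scene, cfg: Dict, train_size: int, optical: bool
) -> np.ndarray:
    """Render one detector input image, either through the full FPM forward +
    reconstruction path or by direct rasterization."""
    if not optical:
        return _resize(render_rgb(scene, train_size), train_size)
    o = cfg["optics"]
    side = o["highres_side"]
    leds = cfg["leds"]
    array = LEDArray(
        rows=leds["rows"],
        cols=leds["cols"],
        pitch=leds["pitch_mm"],
        distance_to_sample=leds["distance_mm"],
        wavelengths=o["wavelengths_um"],
    )
    fields = {ch: render_highres(scene, side, ch) for ch in CHANNELS}
    ctfs = {
        ch: CoherentTransferFunction(
            na=o["na"],
            wavelength=o["wavelengths_um"][ch],
            grid_side=side,
            pixel_pitch_highres=fields[ch].pixel_pitch,
        )
        for ch in CHANNELS
    }
    noise = cfg["sensor"]["noise"]
    stack = simulate_stack(
        fields,
        array,
        ctfs,
        ratio=cfg["sensor"]["ratio"],
        noise=NoiseSpec(noise["gaussian_sigma"], noise["poisson_photons"]),
        seed=scene.seed,
    )
    rgb = reconstruct_rgb(stack, n_iters=cfg["recon"]["iters"])
    return _resize(rgb, train_size)


def build_detection_dataset(
    cfg: Dict, seed: int, n_images: Optional[int] = None, optical: Optional[bool] = None
) -> List[Tuple[np.ndarray, np.ndarray, object]]:
    """(image HWC, target boxes (T,4) normalized cxcywh, AnnotationSet) per
    phantom; wbc count per image is uniform on [1, n_wbc_max]."""
    rng = np.random.default_rng(seed)
    n = cfg["phantom"]["n_images"] if n_images is None else n_images
    train_size = cfg["dataset"]["train_size"]
    optical = cfg["dataset"]["optical"] if optical is None else optical
    out = []
    for i in range(n):
        n_wbc = int(rng.integers(1, cfg["phantom"]["n_wbc_max"] + 1))
        scene = generate_scene(_phantom_config(cfg, n_wbc), seed=int(rng.integers(2**31)))
        image = make_detection_image(scene, cfg, train_size, optical)
        aset = scene_to_annotations(scene, train_size, image_id=i)
        boxes = (
            np.stack([a.box.as_array() for a in aset.annotations])
            if aset.annotations
            else np.zeros((0, 4))
        )
        out.append((image, boxes, aset))
    return out


def extract_wbc_crops(
    dataset: Sequence[Tuple[np.ndarray, np.ndarray, object]], crop_side: int = 64
) -> List[np.ndarray]:
    """Square crops centered on each ground-truth box, edge-clamped."""
    crops = []
    for image, boxes, _ in dataset:
        side = image.shape[0]
        for b in boxes:
            cx, cy = int(b[0] * side), int(b[1] * side)
            half = crop_side // 2
            x0 = min(max(cx - half, 0), side - crop_side)
            y0 = min(max(cy - half, 0), side - crop_side)
            crops.append(image[y0 : y0 + crop_side, x0 : x0 + crop_side].copy())
    return crops


def composite_synthetic_images(
    synthetic_crops: Sequence[np.ndarray],
    cfg: Dict,
    seed: int,
    box_frac: float = 0.6,
) -> List[Tuple[np.ndarray, np.ndarray, object]]:
    """Paste generated wbc crops into rbc-only backgrounds, deriving boxes
    from the pasted region (central ``box_frac`` of the crop)."""
    rng = np.random.default_rng(seed)
    train_size = cfg["dataset"]["train_size"]
    out = []
    for i, crop in enumerate(synthetic_crops):
        scene = generate_scene(
            _phantom_config(cfg, n_wbc=0), seed=int(rng.integers(2**31))
        )
        image = _resize(render_rgb(scene, train_size), train_size)
        cs = crop.shape[0]
        x0 = int(rng.integers(0, train_size - cs + 1))
        y0 = int(rng.integers(0, train_size - cs + 1))
        # soft-blend the crop so paste borders do not dominate training
        yy, xx = np.mgrid[0:cs, 0:cs]
        r = np.hypot(yy - cs / 2, xx - cs / 2) / (cs / 2)
        alpha = np.clip(1.2 - r * 1.4, 0, 1)[..., None]
        region = image[y0 : y0 + cs, x0 : x0 + cs]
        image[y0 : y0 + cs, x0 : x0 + cs] = alpha * crop[..., :3] + (1 - alpha) * region
        box = np.array(
            [
                (x0 + cs / 2) / train_size,
                (y0 + cs / 2) / train_size,
                box_frac * cs / train_size,
                box_frac * cs / train_size,
            ]
        )
        out.append((image, box[None, :], None))
    return out


def _detector_config(cfg: Dict, train_size: int) -> DetectorConfig:
    d = cfg["detector"]
    return DetectorConfig(
        num_queries=d["num_queries"],
        hidden_dim=d["hidden_dim"],
        encoder_layers=d["encoder_layers"],
        decoder_layers=d["decoder_layers"],
        heads=d["heads"],
        backbone=d["backbone"],
        improved_blocks=d["improved_blocks"],
        image_side=train_size,
        box_loss_kind=d["box_loss"],
    )


def run_pipeline(config_path: Optional[Path], seed: int, out_dir: Path) -> RunManifest:
    """Execute all stages in order, writing artifacts and a manifest."""
    cfg = load_config(config_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=seed, config=cfg)
    train_size = cfg["dataset"]["train_size"]

    # 1. phantoms -> images + annotations
    dataset = build_detection_dataset(cfg, seed)
    img_dir = out_dir / "images"
    asets = []
    for i, (image, _, aset) in enumerate(dataset):
        fio.save_png(image, img_dir / f"image_{i:05d}.png")
        asets.append(aset)
    coco_path = fio.write_coco(asets, out_dir / "annotations.json")
    manifest.record(
        "phantom",
        n_images=len(dataset),
        annotations=str(coco_path),
        checksum=_sha256(coco_path),
    )

    # 2. split
    split = cfg["dataset"]["split"]
    n_train = int(round(split * len(dataset)))
    train_set = dataset[:n_train]
    test_set = dataset[n_train:]
    manifest.record("split", ratio=split, n_train=n_train, n_test=len(test_set))

    # 3. wbc crops + DCGAN + 1:1 augmentation
    crops = extract_wbc_crops(train_set)
    gan_cfg = GanConfig(
        base_channels=cfg["gan"]["base_channels"],
        batch_size=cfg["gan"]["batch_size"],
        seed=seed,
    )
    gan_result = train_dcgan(crops, gan_cfg, epochs=cfg["gan"]["epochs"])
    expanded = augment_dataset(crops, gan_result.generator, seed=seed)
    synthetic = [item.image for item in expanded if item.provenance == "generated"]
    synth_images = composite_synthetic_images(synthetic, cfg, seed + 1)
    manifest.record(
        "augment",
        n_real_crops=len(crops),
        n_expanded=len(expanded),
        g_loss_final=gan_result.g_losses[-1] if gan_result.g_losses else None,
    )

    # 4. detector training on real + composited synthetic images
    train_pairs = [(im, b) for im, b, _ in train_set] + [
        (im, b) for im, b, _ in synth_images
    ]
    det_cfg = _detector_config(cfg, train_size)
    model, history = train_detector(
        train_pairs,
        det_cfg,
        seed=seed,
        epochs=cfg["detector"]["epochs"],
        batch_size=cfg["detector"]["batch_size"],
        lr=cfg["detector"]["lr"],
    )
    manifest.record(
        "train_detector",
        epochs=cfg["detector"]["epochs"],
        final_loss=history.epoch_loss[-1],
        n_parameters=model.n_parameters(),
    )

    # 5. evaluation on the held-out split (falls back to train when empty)
    eval_set = test_set if test_set else train_set
    preds = {i: forward_detect(im, model) for i, (im, _, _) in enumerate(eval_set)}
    gts = {i: b for i, (_, b, _) in enumerate(eval_set)}
    ap = evaluate_map(preds, gts, iou_threshold=0.5)
    manifest.record("evaluate", map50=ap, n_images=len(eval_set))

    (out_dir / "manifest.json").write_text(manifest.to_json())
    return manifest
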