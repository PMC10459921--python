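"""Synthetic blood-smear scenes: complex optical fields with known detection
ground truth, and two-bar resolution targets.

Scenes emulate stained-smear imagery: a cluttered background of many small
round cells (rbc), sparser larger nucleated cells (wbc) as the detection
class, optional overlapping/adherent cells, and low target–background
contrast.  Coordinates are µm with the origin at the top-left of the field of
view, x right / y down, so they map directly onto the image raster.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .boxes import BBox
from .optics import ComplexField

__all__ = [
    "Cell",
    "PhantomScene",
    "PhantomConfig",
    "Annotation",
    "AnnotationSet",
    "generate_scene",
    "render_highres",
    "render_rgb",
    "scene_to_annotations",
    "make_resolution_target",
    "resolution_target_bar_centers",
    "GenerationError",
]

# Per-channel stain absorption multipliers (Romanowsky-like: red cells pass
# red light, nuclei stain dark across the band, strongest in green).
RBC_STAIN = {"red": 0.35, "green": 1.0, "blue": 0.8, None: 1.0}
WBC_STAIN = {"red": 0.75, "green": 1.0, "blue": 0.85, None: 1.0}


class GenerationError(RuntimeError):
    """Raised when a feasible cell layout cannot be found."""


@dataclass(frozen=True)
class Cell:
    kind: str  # {"rbc", "wbc"}
    center: Tuple[float, float]  # µm
    radius: float  # µm
    absorption: float
    phase_delay: float
    nucleus_fraction: float = 0.0  # radius fraction, wbc only

    def __post_init__(self) -> None:
        if self.kind not in ("rbc", "wbc"):
            raise ValueError(f"unknown cell kind {self.kind!r}")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.kind == "wbc" and not (0 < self.nucleus_fraction <= 1):
            raise ValueError("wbc nucleus_fraction must be in (0, 1]")


@dataclass
class PhantomScene:
    field_of_view: float  # µm
    cells: List[Cell]
    seed: int
    background_absorption: float = 0.05

    @property
    def wbc(self) -> List[Cell]:
        return [c for c in self.cells if c.kind == "wbc"]

    @property
    def rbc(self) -> List[Cell]:
        return [c for c in self.cells if c.kind == "rbc"]


@dataclass(frozen=True)
class PhantomConfig:
    """Scene statistics.  Defaults mirror peripheral-blood class imbalance
    (≈1 wbc per ``rbc_per_wbc`` rbc); detection-scale configs override the
    counts and field of view."""

    field_of_view: float = 400.0  # µm
    n_wbc: int = 1
    n_rbc: Optional[int] = None  # default: n_wbc * rbc_per_wbc
    rbc_per_wbc: int = 800
    overlap_prob: float = 0.2
    rbc_radius: Tuple[float, float] = (3.5, 0.4)  # mean, std (µm)
    wbc_radius: Tuple[float, float] = (5.8, 0.6)
    rbc_absorption: Tuple[float, float] = (0.22, 0.04)
    wbc_absorption: Tuple[float, float] = (0.18, 0.03)
    nucleus_extra_absorption: float = 0.35
    nucleus_fraction: Tuple[float, float] = (0.55, 0.08)
    rbc_phase: Tuple[float, float] = (0.4, 0.1)
    wbc_phase: Tuple[float, float] = (0.9, 0.15)
    background_absorption: float = 0.05
    margin: float = 0.0  # keep-out border, µm; cells may straddle the edge
    max_retries: int = 200


def _intersects(c: Cell, others: Sequence[Cell]) -> bool:
    return any(
        np.hypot(c.center[0] - o.center[0], c.center[1] - o.center[1])
        < c.radius + o.radius
        for o in others
    )


def _sample_cell(cfg: PhantomConfig, kind: str, rng: np.random.Generator) -> Cell:
    if kind == "rbc":
        radius = max(0.5, rng.normal(*cfg.rbc_radius))
        return Cell(
            kind="rbc",
            center=(0.0, 0.0),
            radius=radius,
            absorption=float(np.clip(rng.normal(*cfg.rbc_absorption), 0.02, 0.9)),
            phase_delay=float(rng.normal(*cfg.rbc_phase)),
        )
    radius = max(1.0, rng.normal(*cfg.wbc_radius))
    return Cell(
        kind="wbc",
        center=(0.0, 0.0),
        radius=radius,
        absorption=float(np.clip(rng.normal(*cfg.wbc_absorption), 0.02, 0.9)),
        phase_delay=float(rng.normal(*cfg.wbc_phase)),
        nucleus_fraction=float(np.clip(rng.normal(*cfg.nucleus_fraction), 0.2, 1.0)),
    )


def _place_free(
    cell: Cell, placed: List[Cell], cfg: PhantomConfig, rng: np.random.Generator
) -> Cell:
    fov = cfg.field_of_view
    for _ in range(cfg.max_retries):
        xy = rng.uniform(cfg.margin, fov - cfg.margin, size=2)
        cand = replace(cell, center=(float(xy[0]), float(xy[1])))
        if not _intersects(cand, placed):
            return cand
    raise GenerationError(
        f"could not place a {cell.kind} without overlap after "
        f"{cfg.max_retries} retries (density too high for FOV {fov} µm)"
    )


def _place_touching(
    cell: Cell, partner: Cell, placed: List[Cell], cfg: PhantomConfig,
    rng: np.random.Generator,
) -> Cell:
    """Place ``cell`` intersecting ``partner`` but (best-effort) no one else."""
    fallback = None
    for _ in range(cfg.max_retries):
        theta = rng.uniform(0, 2 * np.pi)
        dist = rng.uniform(0.55, 0.95) * (cell.radius + partner.radius)
        xy = (
            partner.center[0] + dist * np.cos(theta),
            partner.center[1] + dist * np.sin(theta),
        )
        if not (0 <= xy[0] <= cfg.field_of_view and 0 <= xy[1] <= cfg.field_of_view):
            continue
        cand = replace(cell, center=(float(xy[0]), float(xy[1])))
        others = [c for c in placed if c is not partner]
        if not _intersects(cand, others):
            return cand
        fallback = cand
    if fallback is not None:
        return fallback
    raise GenerationError("could not place an adherent cell inside the FOV")


def generate_scene(config: PhantomConfig, seed: int) -> PhantomScene:
    """Place rbc/wbc disks with a configurable contact fraction.

    Approximately ``overlap_prob`` of all cells intersect at least one
    neighbor; contacts are created as adherent pairs so isolated cells stay
    isolated.  Deterministic for a fixed (config, seed).
    """
    rng = np.random.default_rng(seed)
    n_rbc = config.n_rbc if config.n_rbc is not None else config.n_wbc * config.rbc_per_wbc
    if n_rbc < 0 or config.n_wbc < 0:
        raise ValueError("cell counts must be nonnegative")
    n_total = n_rbc + config.n_wbc
    if n_total == 0:
        return PhantomScene(
            field_of_view=config.field_of_view,
            cells=[],
            seed=seed,
            background_absorption=config.background_absorption,
        )

    kinds = ["wbc"] * config.n_wbc + ["rbc"] * n_rbc
    rng.shuffle(kinds)
    n_touch = int(round(config.overlap_prob * n_total))
    n_pairs, odd = divmod(n_touch, 2)

    placed: List[Cell] = []
    pair_members: List[Cell] = []
    i = 0
    for _ in range(n_pairs):
        first = _place_free(_sample_cell(config, kinds[i], rng), placed, config, rng)
        placed.append(first)
        second = _place_touching(
            _sample_cell(config, kinds[i + 1], rng), first, placed, config, rng
        )
        placed.append(second)
        pair_members.extend([first, second])
        i += 2
    if odd and pair_members:
        extra = _place_touching(
            _sample_cell(config, kinds[i], rng), pair_members[0], placed, config, rng
        )
        placed.append(extra)
        i += 1
    while i < n_total:
        placed.append(_place_free(_sample_cell(config, kinds[i], rng), placed, config, rng))
        i += 1

    return PhantomScene(
        field_of_view=config.field_of_view,
        cells=placed,
        seed=seed,
        background_absorption=config.background_absorption,
    )


def _soft_disk(
    side: int, pitch: float, center: Tuple[float, float], radius: float,
    taper: float = 0.6,
) -> np.ndarray:
    """Cosine-tapered disk mask in [0, 1]; taper width in µm."""
    lo_i = max(0, int((center[1] - radius - taper) / pitch) - 1)
    hi_i = min(side, int((center[1] + radius + taper) / pitch) + 2)
    lo_j = max(0, int((center[0] - radius - taper) / pitch) - 1)
    hi_j = min(side, int((center[0] + radius + taper) / pitch) + 2)
    out = np.zeros((side, side))
    if lo_i >= hi_i or lo_j >= hi_j:
        return out
    ii = (np.arange(lo_i, hi_i) + 0.5) * pitch
    jj = (np.arange(lo_j, hi_j) + 0.5) * pitch
    yy, xx = np.meshgrid(ii, jj, indexing="ij")
    r = np.hypot(xx - center[0], yy - center[1])
    patch = np.clip((radius + taper / 2 - r) / taper, 0.0, 1.0)
    patch = 0.5 - 0.5 * np.cos(np.pi * patch)
    out[lo_i:hi_i, lo_j:hi_j] = patch
    return out


def render_highres(
    scene: PhantomScene, side: int, channel: Optional[str] = None
) -> ComplexField:
    """Rasterize the scene to a complex transmittance field.

    amplitude = 1 − Σ absorption masks (clipped to [0, 1]); phase = Σ phase
    delays; wbc nuclei are darker than cytoplasm; absorption is scaled per
    channel to mimic staining color.
    """
    if side % 2 != 0:
        raise ValueError("side must be even")
    pitch = scene.field_of_view / side
    absorption = np.full((side, side), scene.background_absorption)
    phase = np.zeros((side, side))
    for cell in scene.cells:
        stain = (RBC_STAIN if cell.kind == "rbc" else WBC_STAIN).get(channel, 1.0)
        mask = _soft_disk(side, pitch, cell.center, cell.radius)
        absorption += stain * cell.absorption * mask
        phase += cell.phase_delay * mask
        if cell.kind == "wbc":
            nucleus = _soft_disk(
                side, pitch, cell.center, cell.nucleus_fraction * cell.radius,
                taper=0.4,
            )
            absorption += stain * scene_nucleus_extra(scene, cell) * nucleus
            phase += 0.5 * cell.phase_delay * nucleus
    amplitude = np.clip(1.0 - absorption, 0.0, 1.0)
    return ComplexField(amplitude * np.exp(1j * phase), pitch, channel)


def scene_nucleus_extra(scene: PhantomScene, cell: Cell) -> float:
    # Nucleus contrast rides on the cell's own absorption scale.
    return 0.35 + 0.5 * cell.absorption


def render_rgb(scene: PhantomScene, side: int) -> np.ndarray:
    """Direct RGB rendering (H×W×3 amplitude image in [0, 1]) without the
    optical round trip; used for detector-scale datasets."""
    planes = [
        np.abs(render_highres(scene, side, ch).values) for ch in ("red", "green", "blue")
    ]
    return np.clip(np.stack(planes, axis=-1), 0.0, 1.0)


@dataclass(frozen=True)
class Annotation:
    box: BBox  # normalized center format
    label: str = "wbc"


@dataclass
class AnnotationSet:
    annotations: List[Annotation]
    image_id: int
    image_side: int

    def coco_boxes(self) -> np.ndarray:
        """COCO [x, y, w, h] pixel boxes, top-left origin, 0-based."""
        if not self.annotations:
            return np.zeros((0, 4))
        from .boxes import cxcywh_norm_to_coco

        arr = np.stack([a.box.as_array() for a in self.annotations])
        return cxcywh_norm_to_coco(arr, self.image_side)


def scene_to_annotations(
    scene: PhantomScene, side: int, image_id: int = 0
) -> AnnotationSet:
    """One tight box per wbc: the cell disk's bounding square, clipped to the
    image; rbc are background and get no boxes."""
    pitch = scene.field_of_view / side
    annotations: List[Annotation] = []
    for cell in scene.wbc:
        x0 = (cell.center[0] - cell.radius) / pitch
        y0 = (cell.center[1] - cell.radius) / pitch
        x1 = (cell.center[0] + cell.radius) / pitch
        y1 = (cell.center[1] + cell.radius) / pitch
        x0, y0 = max(0.0, x0), max(0.0, y0)
        x1, y1 = min(float(side), x1), min(float(side), y1)
        if x1 - x0 <= 0 or y1 - y0 <= 0:
            continue  # entirely outside the image
        annotations.append(
            Annotation(
                box=BBox(
                    cx=(x0 + x1) / 2 / side,
                    cy=(y0 + y1) / 2 / side,
                    w=(x1 - x0) / side,
                    h=(y1 - y0) / side,
                )
            )
        )
    return AnnotationSet(annotations=annotations, image_id=image_id, image_side=side)


def resolution_target_bar_centers(
    side: int, pixel_pitch: float, bar_separations: Sequence[float]
) -> List[Tuple[float, float, float]]:
    """(x_left, x_right, y) bar-pair centers in µm for each separation."""
    fov = side * pixel_pitch
    n = len(bar_separations)
    out = []
    for i, sep in enumerate(bar_separations):
        y = fov * (i + 1) / (n + 1)
        out.append((fov / 2 - sep / 2, fov / 2 + sep / 2, y))
    return out


def make_resolution_target(
    side: int, bar_separations: Sequence[float], pixel_pitch: float = 0.4
) -> ComplexField:
    """Binary-amplitude target ({0.2, 1.0}) with one vertical bar pair per
    requested separation, stacked down the field of view."""
    if side % 2 != 0:
        raise ValueError("side must be even")
    for sep in bar_separations:
        if sep <= pixel_pitch:
            raise ValueError(
                f"separation {sep} µm is below the pixel pitch {pixel_pitch} µm"
            )
    fov = side * pixel_pitch
    amplitude = np.ones((side, side))
    coords = (np.arange(side) + 0.5) * pixel_pitch
    for (x_left, x_right, y), sep in zip(
        resolution_target_bar_centers(side, pixel_pitch, bar_separations),
        bar_separations,
    ):
        bar_w = max(pixel_pitch, sep / 3)
        bar_h = min(fov / (2 * len(bar_separations) + 2), 10 * sep)
        row_mask = np.abs(coords - y) <= bar_h / 2
        for xc in (x_left, x_right):
            col_mask = np.abs(coords - xc) <= bar_w / 2
            amplitude[np.ix_(row_mask, col_mask)] = 0.2
    return ComplexField(amplitude.astype(complex), pixel_pitch)
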