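"""DCGAN generator/discriminator and the 1:1 dataset-expansion policy.

Generator: latent vector → fully connected stem to a 4×4×1024 feature map →
four stride-2 transposed-convolution stages halving channels
(1024→512→256→128→3) → tanh, emitting 64×64×3 images in [−1, 1].
Discriminator: stride-2 convolution stack down to a scalar realness score.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "GanConfig",
    "GanSample",
    "Generator",
    "Discriminator",
    "build_generator",
    "build_discriminator",
    "shape_trace",
    "train_dcgan",
    "GanTrainResult",
    "augment_dataset",
    "AugmentedItem",
]


@dataclass(frozen=True)
class GanConfig:
    latent_dim: int = 100
    base_channels: int = 1024  # channels of the 4×4 stem feature map
    image_side: int = 64
    lr: float = 2e-4
    beta1: float = 0.5
    epochs: int = 300
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        n_up = self.n_upsample_layers
        if 4 * 2**n_up != self.image_side:
            raise ValueError("image_side must be 4 × 2^n for integer n ≥ 1")
        if self.base_channels % 2 ** (n_up - 1):
            raise ValueError("base_channels must halve cleanly at every stage")

    @property
    def n_upsample_layers(self) -> int:
        n = int(round(np.log2(self.image_side / 4)))
        return max(n, 1)


@dataclass(frozen=True)
class GanSample:
    image: np.ndarray  # H×W×3 in [−1, 1]
    latent: np.ndarray


class Generator(nn.Module):
    def __init__(self, cfg: GanConfig, rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng(cfg.seed)
        self.cfg = cfg
        c = cfg.base_channels
        self.fc = nn.Linear(cfg.latent_dim, 4 * 4 * c, rng)
        self.stem_bn = nn.BatchNorm2d(c)
        stages: List[nn.Module] = []
        for i in range(cfg.n_upsample_layers):
            out_c = 3 if i == cfg.n_upsample_layers - 1 else c // 2
            stages.append(nn.ConvTranspose2d(c, out_c, 4, rng, stride=2, padding=1, bias=False))
            if out_c != 3:
                stages.append(nn.BatchNorm2d(out_c))
                stages.append(nn.ReLU())
            c = out_c
        self.stages = nn.Sequential(*stages)

    def stem(self, z: Tensor) -> Tensor:
        c = self.cfg.base_channels
        y = self.fc(z).reshape(z.shape[0], c, 4, 4)
        return self.stem_bn(y).relu()

    def forward(self, z: Tensor) -> Tensor:
        return self.stages(self.stem(z)).tanh()

    def sample(self, n: int, rng: np.random.Generator) -> List[GanSample]:
        z = rng.normal(size=(n, self.cfg.latent_dim))
        self.eval()
        imgs = self(Tensor(z)).data
        self.train()
        return [
            GanSample(image=np.transpose(im, (1, 2, 0)), latent=zi)
            for im, zi in zip(imgs, z)
        ]


class Discriminator(nn.Module):
    def __init__(self, cfg: GanConfig, rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng(cfg.seed + 1)
        self.cfg = cfg
        # mirror the generator's channel schedule on the way down
        chans = [3]
        c = cfg.base_channels // 2 ** (cfg.n_upsample_layers - 1)
        for _ in range(cfg.n_upsample_layers):
            chans.append(c)
            c *= 2
        layers: List[nn.Module] = []
        for i in range(cfg.n_upsample_layers):
            layers.append(nn.Conv2d(chans[i], chans[i + 1], 4, rng, stride=2, padding=1, bias=False))
            if i > 0:
                layers.append(nn.BatchNorm2d(chans[i + 1]))
            layers.append(nn.LeakyReLU(0.2))
        self.features = nn.Sequential(*layers)
        self.classifier = nn.Linear(chans[-1] * 4 * 4, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        """x (B, 3, side, side) -> realness scores (B,) in (0, 1)."""
        if x.shape[2] != self.cfg.image_side:
            raise ValueError(f"expected input side {self.cfg.image_side}")
        y = self.features(x)
        b = y.shape[0]
        return self.classifier(y.reshape(b, -1)).sigmoid().reshape(b)


def build_generator(cfg: GanConfig, rng: Optional[np.random.Generator] = None) -> Generator:
    return Generator(cfg, rng)


def build_discriminator(cfg: GanConfig, rng: Optional[np.random.Generator] = None) -> Discriminator:
    return Discriminator(cfg, rng)


def shape_trace(gen: Generator, latent: Optional[np.ndarray] = None) -> List[Tuple[int, ...]]:
    """Per-stage output shapes (C, H, W) for one latent vector, stem first."""
    if latent is None:
        latent = np.zeros(gen.cfg.latent_dim)
    z = Tensor(latent[None])
    gen.eval()
    shapes = []
    y = gen.stem(z)
    shapes.append(tuple(int(s) for s in y.shape[1:]))
    for m in gen.stages:
        y = m(y)
        if isinstance(m, nn.ConvTranspose2d):
            shapes.append(tuple(int(s) for s in y.shape[1:]))
    gen.train()
    return shapes


@dataclass
class GanTrainResult:
    generator: Generator
    discriminator: Discriminator
    g_losses: List[float] = dc_field(default_factory=list)
    d_losses: List[float] = dc_field(default_factory=list)
    trained_epochs: int = 0


def _bce(scores: Tensor, target: float) -> Tensor:
    eps = 1e-7
    p = scores.maximum(eps).minimum(1 - eps)
    if target == 1.0:
        return -(p.log()).mean()
    return -((1.0 - p).log()).mean()


def sample_grid(gen: Generator, n: int = 16, seed: int = 0) -> np.ndarray:
    """Tile n generated samples into one [0, 1] image (√n × √n grid)."""
    g = int(np.ceil(np.sqrt(n)))
    samples = gen.sample(n, np.random.default_rng(seed))
    side = gen.cfg.image_side
    grid = np.ones((g * side, g * side, 3))
    for i, s in enumerate(samples):
        r, c = divmod(i, g)
        grid[r * side : (r + 1) * side, c * side : (c + 1) * side] = (s.image + 1) / 2
    return np.clip(grid, 0, 1)


def train_dcgan(
    crops: Sequence[np.ndarray],
    cfg: GanConfig,
    epochs: Optional[int] = None,
    sample_every: Optional[int] = None,
    sample_dir=None,
) -> GanTrainResult:
    """Alternating adversarial training on H×W×3 crops in [0, 1] or [−1, 1].

    Crops are mapped to [−1, 1] to match the generator's tanh output.  Fully
    seeded: the same (crops, cfg) reproduces identical losses.
    """
    if len(crops) == 0:
        raise ValueError("training requires at least one crop")
    epochs = cfg.epochs if epochs is None else epochs
    rng = np.random.default_rng(cfg.seed)
    data = np.stack([np.transpose(c, (2, 0, 1)) for c in crops]).astype(float)
    if data.min() >= 0:
        data = data * 2.0 - 1.0
    gen = Generator(cfg, np.random.default_rng(cfg.seed + 10))
    disc = Discriminator(cfg, np.random.default_rng(cfg.seed + 11))
    g_opt = nn.AdamW(gen.parameters(), lr=cfg.lr, betas=(cfg.beta1, 0.999))
    d_opt = nn.AdamW(disc.parameters(), lr=cfg.lr, betas=(cfg.beta1, 0.999))
    result = GanTrainResult(generator=gen, discriminator=disc)
    n = len(data)
    bs = min(cfg.batch_size, n)
    for _ in range(epochs):
        order = rng.permutation(n)
        g_epoch, d_epoch = [], []
        for start in range(0, n, bs):
            real = Tensor(data[order[start : start + bs]])
            m = real.shape[0]
            z = Tensor(rng.normal(size=(m, cfg.latent_dim)))
            # discriminator update
            fake = gen(z)
            d_loss = _bce(disc(real), 1.0) + _bce(disc(fake.detach()), 0.0)
            d_opt.zero_grad()
            d_loss.backward()
            d_opt.step()
            # generator update (non-saturating objective)
            z2 = Tensor(rng.normal(size=(m, cfg.latent_dim)))
            g_loss = _bce(disc(gen(z2)), 1.0)
            g_opt.zero_grad()
            gen.zero_grad()
            disc.zero_grad()
            g_loss.backward()
            for p in disc.parameters():
                p.grad = None  # generator step must not move the critic
            g_opt.step()
            g_epoch.append(float(g_loss.data))
            d_epoch.append(float(d_loss.data))
        result.g_losses.append(float(np.mean(g_epoch)))
        result.d_losses.append(float(np.mean(d_epoch)))
        result.trained_epochs += 1
        if sample_every and sample_dir is not None and result.trained_epochs % sample_every == 0:
            from .io import save_png
            from pathlib import Path

            save_png(
                sample_grid(gen, seed=cfg.seed),
                Path(sample_dir) / f"samples_epoch{result.trained_epochs:04d}.png",
            )
    return result


@dataclass(frozen=True)
class AugmentedItem:
    image: np.ndarray  # H×W×3 in [0, 1]
    provenance: str  # {"real", "generated"}
    checksum: str


def _checksum(img: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(img).tobytes()).hexdigest()


def augment_dataset(
    real_crops: Sequence[np.ndarray],
    generator: Generator,
    trained: bool = True,
    seed: int = 0,
) -> List[AugmentedItem]:
    """Expand a crop set 1:1 with generated samples.

    Emits one synthetic crop per real crop; the expanded set has exactly
    twice the original size, real items first and bit-identical to their
    inputs, every synthetic item flagged ``provenance="generated"``.
    """
    if not trained:
        raise ValueError("refusing to augment with an untrained generator")
    items = [
        AugmentedItem(image=np.asarray(c, dtype=float), provenance="real", checksum=_checksum(np.asarray(c, dtype=float)))
        for c in real_crops
    ]
    if not real_crops:
        return items
    rng = np.random.default_rng(seed)
    for s in generator.sample(len(real_crops), rng):
        img = (s.image + 1.0) / 2.0
        items.append(
            AugmentedItem(image=img, provenance="generated", checksum=_checksum(img))
        )
    return items
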