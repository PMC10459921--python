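# fpmdetect

A self-contained toolkit that

1. **simulates** Fourier ptychographic microscopy (FPM) acquisition of
   synthetic blood-smear scenes — angled LED illumination, pupil filtering,
   and low-resolution intensity capture,
2. **reconstructs** high-resolution, wide-field complex images by iterative
   frequency-domain sub-aperture replacement, per color channel, with RGB
   synthesis,
3. **detects** white-blood-cell-like targets with a set-prediction
   (DETR-style) detector built on an improved residual Conv Block (average-
   pool shortcut, stride on the 3×3 kernel) and a CIOU + L1 border loss, and
4. **augments** training data with a DCGAN (4×4×1024 stem → four transposed-
   convolution stages → 64×64×3) using a 1:1 expansion policy.

No external data is required: phantoms, stacks, annotations, and crops are all
generated internally. The neural-network components run on a small
numpy-based autodiff engine (`fpmdetect.nn`) — no GPU or deep-learning
framework needed.

## CLI

```bash
fpmdetect phantom --n 8 --seed 7 --out data/            # scenes + images + COCO JSON
fpmdetect simulate --phantom scene.json --config optics.yaml --out stack/
fpmdetect reconstruct --stack stack/ --iters 15 --out recon/
fpmdetect train-gan --data data/ --out gan/
fpmdetect train-detector --data data/ --seed 7 --out det/
fpmdetect evaluate --ckpt det/detector.npz --data data/
fpmdetect run-all --seed 7 --out run/                   # full pipeline + manifest
```

All verbs accept `--config <yaml>`; see `fpmdetect.pipeline.DEFAULT_CONFIG`
for the schema (LED grid, optics, sensor ratio/noise, phantom statistics,
reconstruction iterations, GAN and detector hyperparameters). One seed
governs every stochastic stage; `run-all` writes a manifest with per-stage
artifacts and checksums.

## Layout

| module | contents |
|---|---|
| `fpmdetect.optics` | LED array geometry, wave vectors, pupil (CTF), forward capture model |
| `fpmdetect.recon` | sub-aperture alternating-projection reconstruction, RGB synthesis |
| `fpmdetect.phantom` | blood-smear scene generator, rasterizer, annotations, resolution targets |
| `fpmdetect.boxes` | IoU / GIoU / CIoU losses, combined border loss, Hungarian matching |
| `fpmdetect.nn` | numpy autodiff engine: conv/pool/norm/attention layers, AdamW |
| `fpmdetect.detector` | ResNet-style backbones with improved Conv Blocks, transformer encoder–decoder, training, mAP |
| `fpmdetect.gan` | DCGAN generator/discriminator, training, 1:1 augmentation |
| `fpmdetect.pipeline` / `fpmdetect.cli` | orchestration, config, manifests, CLI |
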