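# plantdet

A lightweight two-stage plant detection toolkit, exercisable entirely on
synthetic fixtures. It implements:

- **Unsharp-mask enhancement** (`plantdet.enhance`) — `sharp = I + k·(I − B)`
  with a Gaussian blur `B`, default `k = 1.5`, plus Laplacian / Sobel /
  high-boost / HSV-value comparison enhancers.
- **Split SAM** (`plantdet.split_sam`) — grouped spatial attention: channels
  are split into `G` contiguous groups (default `G = 1`), each gated by a
  sigmoid map from its channel-wise max/avg pool passed through a shared
  7×7 convolution.
- **Light backbone** (`plantdet.light_backbone`) — a ResNet-50-layout
  feature extractor whose bottleneck 3×3 convolution is depthwise
  (one filter per channel), with optional Split SAM after each block.
  The first three stages produce stride-16 features (600 → 38); the
  fourth stage serves as the RoI head.
- **Two-stage detector** (`plantdet.detector`) — anchors
  (ratios [0.5, 1, 2] × scales [8, 16, 32] at stride 16), RPN with
  NMS IoU 0.7, RoI max pooling, classification + class-agnostic box
  regression, Adam training (lr 1e-4, batch 4, weight decay 5e-4 by
  default) and letterboxed 600×600 inference.
- **VOC I/O** (`plantdet.voc_io`) — Pascal VOC XML read/write (1-based
  inclusive boxes converted to 0-based half-open internally), stratified
  train/val/test splitting (8:1:1, ±1 per class), brightness and
  resolution statistics.
- **Synthetic fixtures** (`plantdet.synthetic_fixtures`) — deterministic
  plant-like scenes: 5 classes with distinctive color/shape signatures,
  cluttered backgrounds, optional occlusion bars, mean grayscale pulled
  into [100, 120].
- **Evaluation** (`plantdet.eval_metrics`) — greedy IoU matching at 0.5,
  precision/recall/F1, all-point interpolated AP, unweighted mean
  summaries (mAP etc.) and ablation deltas.
- **Profiler** (`plantdet.profiler`) — exact parameter census, traced MAC
  counts (FLOPs = 2×MACs, convention recorded), and the edge-performance
  scaling chain `speed_up1 = fps_device/fps_base`,
  `speed_up2 = speed_up1/r`, `fps_simulated = fps_base·speed_up2`.

The neural-network layers run on a small NumPy reverse-mode autodiff
engine (`plantdet.nn`) — no deep-learning framework is required.

## CLI

```bash
plantdet synth --n 50 --out data/ --seed 42       # synthetic VOC dataset
plantdet stats --data-dir data/                   # brightness/resolution stats
plantdet split --data-dir data/ --seed 0          # stratified 8:1:1 split
plantdet enhance --method um --k 1.5 --in a.png --out b.png
plantdet train --config cfg.yaml --data-dir data/ --out run/
plantdet predict --weights run/model.pkl --image img.png --score-thr 0.5
plantdet eval --dets dets.csv --gt data/ --iou 0.5
plantdet profile --input-size 600 --proposals 300
plantdet edge-sim --fps-base 0.08 --fps-device 0.5 --r 0.35
```

Configuration is YAML with validated keys (unknown keys are rejected);
every training run writes its resolved config next to its outputs.

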