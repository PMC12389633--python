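"""Deterministic synthetic plant-scene generator.

Produces cluttered RGB scenes containing class-distinctive shapes (one
color/geometry signature per class) with tight bounding boxes, a global
mean-grayscale brightness pulled into a target band, and VOC-format
output that :mod:`plantdet.voc_io` reads back losslessly.  Object
appearance is parameterized, not photorealistic: the point is that a
detector can learn the classes quickly, not that the scenes look real.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw

from .voc_io import VOCAnnotation, VOCObject, grayscale_mean, write_voc_xml

__all__ = ["SceneSpec", "DEFAULT_CLASSES", "CLASS_SIGNATURES", "make_scene",
           "make_dataset"]

DEFAULT_CLASSES = (
    "Acanthus mollis",
    "Cirsium eriophorum",
    "Gentiana lutea",
    "Hyacinthoides non-scripta",
    "Urospermum dalechampii",
)

# (fill RGB, shape tag) per class -- widely separated hues so that a
# nearest-centroid color classifier separates crops trivially.
CLASS_SIGNATURES = {
    "Acanthus mollis": ((205, 35, 35), "star"),
    "Cirsium eriophorum": ((35, 190, 190), "ellipse"),
    "Gentiana lutea": ((225, 205, 35), "diamond"),
    "Hyacinthoides non-scripta": ((45, 60, 215), "disc"),
    "Urospermum dalechampii": ((205, 45, 205), "ring"),
}


@dataclass(frozen=True)
class SceneSpec:
    width: int = 320
    height: int = 240
    n_objects: int = 3
    class_names: tuple = DEFAULT_CLASSES
    brightness_target: tuple = (100.0, 120.0)
    clutter_level: float = 0.3
    occlusion_prob: float = 0.0
    min_object_frac: float = 0.25
    max_object_frac: float = 0.45
    seed: int = 0

    def __post_init__(self):
        if self.n_objects < 0:
            raise ValueError("n_objects must be >= 0")
        lo, hi = self.brightness_target
        if not (0 <= lo <= hi <= 255):
            raise ValueError(f"brightness_target out of range: {self.brightness_target}")


def _background(rng: np.random.Generator, w: int, h: int,
                clutter_level: float) -> Image.Image:
    # low-frequency mottled backdrop: coarse noise grid upsampled by repetition
    gh, gw = 6, 8
    base = rng.uniform(40, 110, size=(gh, gw, 3))
    tile = np.repeat(np.repeat(base, -(-h // gh), axis=0), -(-w // gw), axis=1)
    arr = tile[:h, :w].astype(np.uint8)
    img = Image.fromarray(arr, "RGB")
    draw = ImageDraw.Draw(img)
    n_clutter = int(clutter_level * 25)
    for _ in range(n_clutter):
        cx, cy = rng.uniform(0, w), rng.uniform(0, h)
        r = rng.uniform(0.02, 0.08) * min(w, h)
        shade = tuple(int(v) for v in rng.uniform(30, 120, size=3))
        draw.ellipse([cx - r, cy - r, cx + r, cy + r], fill=shade)
    return img


def _draw_object(rng: np.random.Generator, size: int, cls: str) -> Image.Image:
    """Render one object on a transparent square canvas of side `size`."""
    color, shape = CLASS_SIGNATURES.get(cls, ((160, 160, 160), "disc"))
    layer = Image.new("RGBA", (size, size), (0, 0, 0, 0))
    draw = ImageDraw.Draw(layer)
    c = size / 2.0
    r = size * 0.48
    jitter = rng.uniform(0.9, 1.0)
    r *= jitter
    if shape == "star":
        pts = []
        n_spikes = 7
        for i in range(2 * n_spikes):
            ang = np.pi * i / n_spikes
            rad = r if i % 2 == 0 else 0.45 * r
            pts.append((c + rad * np.cos(ang), c + rad * np.sin(ang)))
        draw.polygon(pts, fill=color + (255,))
    elif shape == "ellipse":
        ry = r * rng.uniform(0.6, 0.8)
        draw.ellipse([c - r, c - ry, c + r, c + ry], fill=color + (255,))
    elif shape == "diamond":
        draw.polygon([(c, c - r), (c + r, c), (c, c + r), (c - r, c)],
                     fill=color + (255,))
    elif shape == "ring":
        wdt = max(2, int(r * 0.35))
        draw.ellipse([c - r, c - r, c + r, c + r], outline=color + (255,),
                     width=wdt)
    else:  # disc
        draw.ellipse([c - r, c - r, c + r, c + r], fill=color + (255,))
        draw.ellipse([c - 0.4 * r, c - 0.4 * r, c + 0.4 * r, c + 0.4 * r],
                     fill=tuple(min(255, int(v * 1.3)) for v in color) + (255,))
    return layer


def _adjust_brightness(arr: np.ndarray, target: tuple) -> np.ndarray:
    """Gain/offset loop pushing mean grayscale into [target[0], target[1]]."""
    lo, hi = target
    mid = 0.5 * (lo + hi)
    out = arr.astype(np.float64)
    for _ in range(25):
        g = grayscale_mean(out)
        if lo <= g <= hi:
            break
        if g > 1e-6:
            out = np.clip(out * (mid / g), 0, 255)
        else:
            out = np.clip(out + mid, 0, 255)
    return np.rint(out).astype(np.uint8)


def make_scene(spec: SceneSpec) -> tuple[np.ndarray, VOCAnnotation]:
    """Generate one scene and its annotation; bit-identical under a seed."""
    rng = np.random.default_rng(spec.seed)
    w, h = spec.width, spec.height
    img = _background(rng, w, h, spec.clutter_level)
    objects: list[VOCObject] = []
    for _ in range(spec.n_objects):
        cls = spec.class_names[rng.integers(len(spec.class_names))]
        frac = rng.uniform(spec.min_object_frac, spec.max_object_frac)
        size = max(12, int(frac * min(w, h)))
        layer = _draw_object(rng, size, cls)
        bbox = layer.getbbox()  # tight alpha bounds within the canvas
        x0 = int(rng.integers(0, max(1, w - size)))
        y0 = int(rng.integers(0, max(1, h - size)))
        img.paste(layer, (x0, y0), layer)
        bx1, by1, bx2, by2 = bbox
        x1, y1 = x0 + bx1, y0 + by1
        x2, y2 = min(x0 + bx2, w), min(y0 + by2, h)
        if spec.occlusion_prob > 0 and rng.random() < spec.occlusion_prob:
            draw = ImageDraw.Draw(img)
            bar_h = max(2, int(0.2 * (y2 - y1)))
            by = int(rng.uniform(y1, max(y1, y2 - bar_h)))
            draw.rectangle([x1, by, x2 - 1, by + bar_h], fill=(70, 70, 70))
        objects.append(VOCObject.from_xyxy(cls, x1, y1, x2, y2))
    arr = _adjust_brightness(np.asarray(img), spec.brightness_target)
    ann = VOCAnnotation(filename="scene.png", width=w, height=h, depth=3,
                        objects=objects)
    return arr, ann


def make_dataset(n_images: int, out_dir, seed: int = 0, class_mix=None,
                 size_pool=((320, 240), (480, 360), (256, 256)),
                 n_objects_range=(1, 4), occlusion_prob=0.0,
                 clutter_level=0.3, img_format="png"):
    """Write a VOC-layout folder of synthetic scenes; returns the manifest.

    Each image gets a dominant class (drawn from class_mix) so that the
    stratified splitter has a meaningful per-image label.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    classes = list(class_mix) if class_mix else list(DEFAULT_CLASSES)
    rng = np.random.default_rng(seed)
    manifest = []
    for i in range(n_images):
        dominant = classes[i % len(classes)]
        w, h = size_pool[int(rng.integers(len(size_pool)))]
        n_obj = int(rng.integers(n_objects_range[0], n_objects_range[1] + 1))
        scene_seed = int(rng.integers(2 ** 31))
        spec = SceneSpec(width=w, height=h, n_objects=n_obj,
                         class_names=(dominant,) * 3 + tuple(classes),
                         occlusion_prob=occlusion_prob,
                         clutter_level=clutter_level, seed=scene_seed)
        arr, ann = make_scene(spec)
        stem = f"scene_{i:04d}"
        ann.filename = f"{stem}.{img_format}"
        Image.fromarray(arr).save(out_dir / ann.filename)
        write_voc_xml(ann, out_dir / f"{stem}.xml")
        manifest.append({
            "image": ann.filename,
            "xml": f"{stem}.xml",
            "width": w, "height": h,
            "classes": ann.class_names(),
            "dominant": dominant,
        })
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
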