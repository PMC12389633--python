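"""Pascal VOC XML annotation I/O, stratified splitting and dataset stats.

VOC boxes are stored 1-based inclusive, as written by common labeling
tools; :meth:`VOCObject.xyxy` converts to the 0-based half-open pixel
convention used internally, and that conversion happens only here.
"""
from __future__ import annotations

import xml.etree.ElementTree as ET
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "VOCObject", "VOCAnnotation", "SplitSpec", "read_voc_xml",
    "write_voc_xml", "stratified_split", "brightness_stats",
    "resolution_table", "load_dataset", "LUMA_WEIGHTS",
]

LUMA_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass
class VOCObject:
    name: str
    xmin: int  # 1-based inclusive corners (VOC convention)
    ymin: int
    xmax: int
    ymax: int

    def __post_init__(self):
        if self.xmin > self.xmax or self.ymin > self.ymax:
            raise ValueError(f"degenerate box {self}")
        if min(self.xmin, self.ymin) < 1:
            raise ValueError(f"VOC coordinates are 1-based, got {self}")

    def xyxy(self) -> tuple[float, float, float, float]:
        """0-based half-open (x1, y1, x2, y2)."""
        return (self.xmin - 1.0, self.ymin - 1.0, float(self.xmax), float(self.ymax))

    @classmethod
    def from_xyxy(cls, name, x1, y1, x2, y2):
        return cls(name, int(round(x1)) + 1, int(round(y1)) + 1,
                   int(round(x2)), int(round(y2)))


@dataclass
class VOCAnnotation:
    filename: str
    width: int
    height: int
    depth: int = 3
    objects: list[VOCObject] = field(default_factory=list)

    def class_names(self) -> list[str]:
        return [o.name for o in self.objects]

    def majority_class(self) -> str | None:
        """Most frequent object class; the stratification label."""
        if not self.objects:
            return None
        counts = Counter(self.class_names())
        return max(sorted(counts), key=counts.get)


class VOCParseError(ValueError):
    pass


def _req(node, tag, path):
    child = node.find(tag)
    if child is None:
        raise VOCParseError(f"{path}: missing required element <{tag}>")
    return child


def read_voc_xml(path) -> VOCAnnotation:
    path = Path(path)
    root = ET.parse(path).getroot()
    size = _req(root, "size", path)
    width = int(_req(size, "width", path).text)
    height = int(_req(size, "height", path).text)
    depth_node = size.find("depth")
    depth = int(depth_node.text) if depth_node is not None else 3
    fname_node = root.find("filename")
    filename = fname_node.text if fname_node is not None else path.stem
    objects = []
    for obj in root.findall("object"):
        name = _req(obj, "name", path).text
        bb = _req(obj, "bndbox", path)
        coords = {t: int(round(float(_req(bb, t, path).text)))
                  for t in ("xmin", "ymin", "xmax", "ymax")}
        objects.append(VOCObject(name, **coords))
    return VOCAnnotation(filename, width, height, depth, objects)


def write_voc_xml(ann: VOCAnnotation, path) -> None:
    root = ET.Element("annotation")
    ET.SubElement(root, "folder").text = "images"
    ET.SubElement(root, "filename").text = ann.filename
    size = ET.SubElement(root, "size")
    ET.SubElement(size, "width").text = str(ann.width)
    ET.SubElement(size, "height").text = str(ann.height)
    ET.SubElement(size, "depth").text = str(ann.depth)
    for obj in ann.objects:
        o = ET.SubElement(root, "object")
        ET.SubElement(o, "name").text = obj.name
        ET.SubElement(o, "difficult").text = "0"
        bb = ET.SubElement(o, "bndbox")
        ET.SubElement(bb, "xmin").text = str(obj.xmin)
        ET.SubElement(bb, "ymin").text = str(obj.ymin)
        ET.SubElement(bb, "xmax").text = str(obj.xmax)
        ET.SubElement(bb, "ymax").text = str(obj.ymax)
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="unicode")


@dataclass(frozen=True)
class SplitSpec:
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError(f"split ratios must sum to 1, got {self.ratios}")


def _allocate(n: int, ratios) -> list[int]:
    """Largest-remainder allocation of n items over the ratios."""
    ideal = [n * r for r in ratios]
    base = [int(np.floor(v)) for v in ideal]
    rem = n - sum(base)
    order = sorted(range(len(ratios)), key=lambda i: ideal[i] - base[i], reverse=True)
    for i in order[:rem]:
        base[i] += 1
    return base


def stratified_split(records, spec: SplitSpec = SplitSpec(), label_fn=None):
    """Partition records into (train, val, test) preserving class mix.

    Per class, subset sizes follow largest-remainder rounding of the
    ratios, so every class count is within +-1 of the exact proportion.
    Classes with fewer records than split parts go entirely to train.
    """
    import warnings

    if label_fn is None:
        label_fn = lambda r: r.majority_class() if isinstance(r, VOCAnnotation) else r[1]
    by_class: dict[str, list] = {}
    for rec in records:
        by_class.setdefault(str(label_fn(rec)), []).append(rec)
    rng = np.random.default_rng(spec.seed)
    parts = ([], [], [])
    for cls in sorted(by_class):
        group = by_class[cls]
        if len(group) < sum(1 for r in spec.ratios if r > 0):
            warnings.warn(
                f"class {cls!r} has only {len(group)} record(s); assigning all to train")
            parts[0].extend(group)
            continue
        idx = rng.permutation(len(group))
        counts = _allocate(len(group), spec.ratios)
        start = 0
        for part, cnt in zip(parts, counts):
            part.extend(group[i] for i in idx[start:start + cnt])
            start += cnt
    return parts


def grayscale_mean(image: np.ndarray) -> float:
    """Mean luminance (0.299 R + 0.587 G + 0.114 B) of an RGB image."""
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim == 2:
        return float(arr.mean())
    gray = arr[..., 0] * LUMA_WEIGHTS[0] + arr[..., 1] * LUMA_WEIGHTS[1] \
        + arr[..., 2] * LUMA_WEIGHTS[2]
    return float(gray.mean())


def brightness_stats(images, bins: int = 16):
    """Per-image mean grayscale values plus a histogram over [0, 255]."""
    images = list(images)
    if not images:
        raise ValueError("brightness_stats requires at least one image")
    means = np.array([grayscale_mean(im) for im in images])
    hist, edges = np.histogram(means, bins=bins, range=(0.0, 255.0))
    return means, hist, edges


def resolution_table(annotations) -> list[tuple[int, int, int]]:
    """Multiset count of (width, height) pairs, sorted by count desc."""
    counts = Counter((a.width, a.height) for a in annotations)
    return sorted(((w, h, n) for (w, h), n in counts.items()),
                  key=lambda r: (-r[2], r[0], r[1]))


def load_dataset(data_dir):
    """Read every XML under data_dir; returns list of (annotation, image path)."""
    data_dir = Path(data_dir)
    out = []
    for xml_path in sorted(data_dir.glob("**/*.xml")):
        ann = read_voc_xml(xml_path)
        img_path = None
        for ext in (".png", ".jpg", ".jpeg"):
            cand = xml_path.with_suffix(ext)
            if cand.exists():
                img_path = cand
                break
            cand = xml_path.parent / (Path(ann.filename).stem + ext)
            if cand.exists():
                img_path = cand
                break
        out.append((ann, img_path))
    return out


def load_image(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))
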