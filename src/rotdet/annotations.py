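"""Annotation I/O for rotated and horizontal field-survey datasets.

Two XML dialects are supported:

* **roLabelImg** — rotated boxes stored as
  ``annotation/object/robndbox/{cx,cy,w,h,angle}``. The stored angle is in
  radians, clockwise from the image x-axis for the *stored* ``w`` edge, in
  ``[0, pi)``. On read every box is canonicalized into the package's
  long-edge convention (``w >= h``, ``theta in [-pi/4, 3pi/4)``); on write
  the angle is mapped back into ``[0, pi)``. Round trips are lossless to
  well below 1e-6.
* **labelImg / PASCAL-VOC** — horizontal boxes stored as
  ``annotation/object/bndbox/{xmin,ymin,xmax,ymax}``.

A rotated dataset can be derived into its horizontal counterpart by
replacing every instance with its circumscribed axis-aligned box, which is
exactly how horizontal-baseline annotation sets are produced from rotated
ones. Boxes extending past the image border are kept unclipped by default
(truncated symptoms are legitimate instances); pass ``clip=True`` to clip.
"""

from __future__ import annotations

import json
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .geometry import (
    HorizontalBox,
    RotatedBox,
    canonicalize,
    circumscribed_hbb,
    rbox_to_corners,
)

__all__ = [
    "AnnotationRecord",
    "DatasetSummary",
    "read_rolabelimg",
    "write_rolabelimg",
    "read_labelimg",
    "write_labelimg",
    "convert_to_horizontal",
    "dataset_summary",
    "split_subsets",
    "load_dataset",
    "ASPECT_BINS",
    "N_ANGLE_BINS",
]

DEFAULT_CLASS = "damage"

# aspect-ratio bin edges (w/h, always >= 1); last bin is [8, inf)
ASPECT_BINS: tuple[float, ...] = (1.0, 2.0, 3.0, 5.0, 8.0)
# equal-width angle bins over the long-edge range [-pi/4, 3pi/4)
N_ANGLE_BINS = 8

_SPARSE_MAX = 9
_MEDIUM_MAX = 19


@dataclass
class AnnotationRecord:
    """One image's ground-truth instances with provenance.

    ``instances`` holds :class:`RotatedBox` objects for rotated records or
    :class:`HorizontalBox` objects for horizontal ones.
    """

    image_id: str
    image_size: tuple[int, int]  # (width, height) in pixels
    instances: list = field(default_factory=list)
    source_path: str = ""

    @property
    def n_instances(self) -> int:
        return len(self.instances)

    @property
    def is_rotated(self) -> bool:
        return all(isinstance(b, RotatedBox) for b in self.instances)


@dataclass
class DatasetSummary:
    n_images: int
    n_instances: int
    mean_instances_per_image: float  # reported to 2 decimals
    aspect_ratio_histogram: list[int]
    angle_histogram: list[int]
    subset_labels: dict[str, str]

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_images": self.n_images,
                "n_instances": self.n_instances,
                "mean_instances_per_image": self.mean_instances_per_image,
                "aspect_ratio_histogram": self.aspect_ratio_histogram,
                "aspect_ratio_bin_edges": list(ASPECT_BINS),
                "angle_histogram": self.angle_histogram,
                "subset_labels": self.subset_labels,
            },
            indent=2,
        )


def _req(node: ET.Element, tag: str) -> str:
    child = node.find(tag)
    if child is None or child.text is None:
        raise ValueError(f"malformed annotation: missing <{tag}> under <{node.tag}>")
    return child.text.strip()


def _clip_rotated(box: RotatedBox, size: tuple[int, int]) -> RotatedBox | None:
    """Clip a rotated box's corners to image bounds, refitting the smallest
    enclosing rotated box at the original angle. Returns None if nothing
    remains inside."""
    w_img, h_img = size
    q = rbox_to_corners(box)
    q[:, 0] = np.clip(q[:, 0], 0, w_img)
    q[:, 1] = np.clip(q[:, 1], 0, h_img)
    # refit in the box's local frame
    c, s = math.cos(box.theta), math.sin(box.theta)
    lx = c * (q[:, 0] - box.x) + s * (q[:, 1] - box.y)
    ly = -s * (q[:, 0] - box.x) + c * (q[:, 1] - box.y)
    w = float(lx.max() - lx.min())
    h = float(ly.max() - ly.min())
    if w <= 1e-6 or h <= 1e-6:
        return None
    mx = float((lx.max() + lx.min()) / 2)
    my = float((ly.max() + ly.min()) / 2)
    return canonicalize(
        box.x + c * mx - s * my, box.y + s * mx + c * my, w, h, box.theta
    )


def read_rolabelimg(xml_path: str | Path, clip: bool = False) -> AnnotationRecord:
    """Parse a roLabelImg XML file into a rotated :class:`AnnotationRecord`.

    Every ``robndbox`` is canonicalized into the long-edge convention;
    instance order is preserved. A file with no objects yields a valid
    empty record.
    """
    xml_path = Path(xml_path)
    root = ET.parse(xml_path).getroot()
    size_node = root.find("size")
    if size_node is None:
        raise ValueError(f"{xml_path}: missing <size>")
    width = int(_req(size_node, "width"))
    height = int(_req(size_node, "height"))
    filename = root.findtext("filename", default=xml_path.stem)
    instances: list[RotatedBox] = []
    for obj in root.iter("object"):
        rb = obj.find("robndbox")
        if rb is None:
            raise ValueError(
                f"{xml_path}: <object> without <robndbox> (horizontal dialect? "
                "use read_labelimg)"
            )
        box = canonicalize(
            float(_req(rb, "cx")),
            float(_req(rb, "cy")),
            float(_req(rb, "w")),
            float(_req(rb, "h")),
            float(_req(rb, "angle")),
        )
        if clip:
            clipped = _clip_rotated(box, (width, height))
            if clipped is None:
                continue
            box = clipped
        instances.append(box)
    return AnnotationRecord(
        image_id=Path(filename).stem,
        image_size=(width, height),
        instances=instances,
        source_path=str(xml_path),
    )


def _xml_header(
    root: ET.Element, record: AnnotationRecord, filename: str
) -> None:
    ET.SubElement(root, "folder").text = "images"
    ET.SubElement(root, "filename").text = filename
    src = ET.SubElement(root, "source")
    ET.SubElement(src, "database").text = "Unknown"
    size = ET.SubElement(root, "size")
    ET.SubElement(size, "width").text = str(record.image_size[0])
    ET.SubElement(size, "height").text = str(record.image_size[1])
    ET.SubElement(size, "depth").text = "3"
    ET.SubElement(root, "segmented").text = "0"


def write_rolabelimg(
    record: AnnotationRecord, xml_path: str | Path, class_name: str = DEFAULT_CLASS
) -> None:
    """Serialise a rotated record as roLabelImg XML (lossless round trip).

    The stored angle is the long-edge angle mapped into ``[0, pi)``.
    """
    root = ET.Element("annotation")
    _xml_header(root, record, f"{record.image_id}.png")
    for box in record.instances:
        if not isinstance(box, RotatedBox):
            raise TypeError("write_rolabelimg expects RotatedBox instances")
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "type").text = "robndbox"
        ET.SubElement(obj, "name").text = class_name
        ET.SubElement(obj, "pose").text = "Unspecified"
        ET.SubElement(obj, "truncated").text = "0"
        ET.SubElement(obj, "difficult").text = "0"
        rb = ET.SubElement(obj, "robndbox")
        ET.SubElement(rb, "cx").text = repr(box.x)
        ET.SubElement(rb, "cy").text = repr(box.y)
        ET.SubElement(rb, "w").text = repr(box.w)
        ET.SubElement(rb, "h").text = repr(box.h)
        ET.SubElement(rb, "angle").text = repr(box.theta % math.pi)
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(xml_path, encoding="unicode")


def read_labelimg(xml_path: str | Path) -> AnnotationRecord:
    """Parse a labelImg / PASCAL-VOC XML file into a horizontal record."""
    xml_path = Path(xml_path)
    root = ET.parse(xml_path).getroot()
    size_node = root.find("size")
    if size_node is None:
        raise ValueError(f"{xml_path}: missing <size>")
    width = int(_req(size_node, "width"))
    height = int(_req(size_node, "height"))
    filename = root.findtext("filename", default=xml_path.stem)
    instances: list[HorizontalBox] = []
    for obj in root.iter("object"):
        bb = obj.find("bndbox")
        if bb is None:
            raise ValueError(f"{xml_path}: <object> without <bndbox>")
        instances.append(
            HorizontalBox(
                float(_req(bb, "xmin")),
                float(_req(bb, "ymin")),
                float(_req(bb, "xmax")),
                float(_req(bb, "ymax")),
            )
        )
    return AnnotationRecord(
        image_id=Path(filename).stem,
        image_size=(width, height),
        instances=instances,
        source_path=str(xml_path),
    )


def write_labelimg(
    record: AnnotationRecord, xml_path: str | Path, class_name: str = DEFAULT_CLASS
) -> None:
    """Serialise a horizontal record as labelImg / PASCAL-VOC XML."""
    root = ET.Element("annotation")
    _xml_header(root, record, f"{record.image_id}.png")
    for box in record.instances:
        if not isinstance(box, HorizontalBox):
            raise TypeError("write_labelimg expects HorizontalBox instances")
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = class_name
        ET.SubElement(obj, "pose").text = "Unspecified"
        ET.SubElement(obj, "truncated").text = "0"
        ET.SubElement(obj, "difficult").text = "0"
        bb = ET.SubElement(obj, "bndbox")
        ET.SubElement(bb, "xmin").text = repr(box.x1)
        ET.SubElement(bb, "ymin").text = repr(box.y1)
        ET.SubElement(bb, "xmax").text = repr(box.x2)
        ET.SubElement(bb, "ymax").text = repr(box.y2)
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(xml_path, encoding="unicode")


def convert_to_horizontal(record: AnnotationRecord) -> AnnotationRecord:
    """Replace every rotated instance by its circumscribed horizontal box.

    Instance count is preserved; instance area never decreases.
    """
    instances = []
    for box in record.instances:
        if isinstance(box, HorizontalBox):
            instances.append(box)
        else:
            instances.append(circumscribed_hbb(box))
    return AnnotationRecord(
        image_id=record.image_id,
        image_size=record.image_size,
        instances=instances,
        source_path=record.source_path,
    )


def split_subsets(records: Iterable[AnnotationRecord]) -> dict[str, str]:
    """Label each image by instance density: 1-9 sparse, 10-19 medium,
    >=20 dense; images with no instances are left unlabeled."""
    labels: dict[str, str] = {}
    for rec in records:
        n = rec.n_instances
        if n == 0:
            continue
        if n <= _SPARSE_MAX:
            labels[rec.image_id] = "sparse"
        elif n <= _MEDIUM_MAX:
            labels[rec.image_id] = "medium"
        else:
            labels[rec.image_id] = "dense"
    return labels


def dataset_summary(records: Sequence[AnnotationRecord]) -> DatasetSummary:
    """Dataset-level statistics: totals, per-image mean (2 decimals),
    aspect-ratio and angle histograms, density subset labels.

    Histograms are filled only from rotated instances (horizontal boxes
    carry no orientation); both histograms sum to the number of instances
    they cover.
    """
    records = list(records)
    if not records:
        raise ValueError("dataset_summary requires at least one record")
    n_images = len(records)
    n_instances = sum(r.n_instances for r in records)
    mean = round(n_instances / n_images, 2)

    aspect_hist = [0] * len(ASPECT_BINS)
    angle_hist = [0] * N_ANGLE_BINS
    angle_lo, angle_width = -math.pi / 4, math.pi / N_ANGLE_BINS
    for rec in records:
        for box in rec.instances:
            if isinstance(box, RotatedBox):
                ratio = box.aspect_ratio
                idx = 0
                for i, edge in enumerate(ASPECT_BINS):
                    if ratio >= edge:
                        idx = i
                aspect_hist[idx] += 1
                a_idx = int((box.theta - angle_lo) / angle_width)
                angle_hist[min(a_idx, N_ANGLE_BINS - 1)] += 1
            else:
                hb: HorizontalBox = box
                ratio = max(hb.width, hb.height) / min(hb.width, hb.height)
                idx = 0
                for i, edge in enumerate(ASPECT_BINS):
                    if ratio >= edge:
                        idx = i
                aspect_hist[idx] += 1

    return DatasetSummary(
        n_images=n_images,
        n_instances=n_instances,
        mean_instances_per_image=mean,
        aspect_ratio_histogram=aspect_hist,
        angle_histogram=angle_hist,
        subset_labels=split_subsets(records),
    )


def load_dataset(directory: str | Path, clip: bool = False) -> list[AnnotationRecord]:
    """Read every ``*.xml`` in a directory as roLabelImg annotations,
    sorted by filename for determinism."""
    directory = Path(directory)
    paths = sorted(directory.glob("*.xml"))
    if not paths:
        raise FileNotFoundError(f"no XML annotations found in {directory}")
    return [read_rolabelimg(p, clip=clip) for p in paths]
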