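"""Reading and writing box annotations.

Two on-disk dialects are supported: the LabelImg flavour of PASCAL-VOC XML
(one file per image, 1-based inclusive integer pixel coordinates) and COCO
detection JSON (one file per dataset, [x, y, w, h] boxes). In memory
everything uses the package's 0-based half-open continuous convention: a VOC
``xmin`` becomes ``x_min = xmin - 1`` while ``xmax`` is already the correct
exclusive bound.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

from lxml import etree

from .boxes import Box

__all__ = [
    "ImageAnnotation",
    "DatasetIndex",
    "read_voc_xml",
    "write_voc_xml",
    "read_coco_json",
    "write_coco_json",
    "count_of",
]

log = logging.getLogger(__name__)

PathLike = Union[str, Path]

# boxes whose area after conversion/clipping falls at or below this many
# square pixels are treated as annotation noise and dropped with a warning
MIN_BOX_AREA = 1.0


@dataclass
class ImageAnnotation:
    """An image reference plus its ground-truth boxes.

    The number of boxes doubles as the ground-truth count for the
    count-prediction task.
    """

    image_id: str
    width: int
    height: int
    boxes: list[Box] = field(default_factory=list)

    def count(self) -> int:
        return len(self.boxes)

    def validate(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError(f"{self.image_id}: non-positive image size")
        for b in self.boxes:
            if not (0 <= b.x_min < b.x_max <= self.width):
                raise ValueError(f"{self.image_id}: box x-range {b} outside image")
            if not (0 <= b.y_min < b.y_max <= self.height):
                raise ValueError(f"{self.image_id}: box y-range {b} outside image")


@dataclass
class DatasetIndex:
    """A collection of annotated images with a fixed class vocabulary."""

    items: list[ImageAnnotation] = field(default_factory=list)
    class_names: list[str] = field(default_factory=lambda: ["pod"])

    def validate(self) -> None:
        ids = [it.image_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate image_ids in dataset")
        for it in self.items:
            it.validate()

    def total_boxes(self) -> int:
        return sum(it.count() for it in self.items)

    def mean_count(self) -> float:
        return self.total_boxes() / len(self.items) if self.items else 0.0


def count_of(annotation: ImageAnnotation) -> int:
    """Ground-truth object count of an image: the number of its boxes."""
    return annotation.count()


def _int_text(node: etree._Element, tag: str, path: PathLike) -> int:
    child = node.find(tag)
    if child is None or child.text is None:
        raise ValueError(f"{path}: missing <{tag}> element")
    return int(round(float(child.text)))


def read_voc_xml(path: PathLike, label: str = "pod") -> ImageAnnotation:
    """Parse one LabelImg/PASCAL-VOC XML file.

    VOC stores 1-based inclusive integer corners; they are converted to the
    internal 0-based half-open convention (``xmin - 1``; ``xmax`` kept as the
    exclusive bound). Objects with non-positive area after conversion are
    dropped with a warning.
    """
    path = Path(path)
    try:
        root = etree.parse(str(path)).getroot()
    except (etree.XMLSyntaxError, OSError) as exc:
        raise ValueError(f"cannot parse VOC XML {path}: {exc}") from exc
    size = root.find("size")
    if size is None:
        raise ValueError(f"{path}: missing <size> element")
    width = _int_text(size, "width", path)
    height = _int_text(size, "height", path)
    filename = root.findtext("filename") or path.stem

    boxes: list[Box] = []
    for obj in root.findall("object"):
        name = obj.findtext("name") or label
        bnd = obj.find("bndbox")
        if bnd is None:
            raise ValueError(f"{path}: <object> without <bndbox>")
        x0 = _int_text(bnd, "xmin", path) - 1
        y0 = _int_text(bnd, "ymin", path) - 1
        x1 = _int_text(bnd, "xmax", path)
        y1 = _int_text(bnd, "ymax", path)
        x0, y0 = max(x0, 0), max(y0, 0)
        x1, y1 = min(x1, width), min(y1, height)
        if x1 - x0 <= 0 or y1 - y0 <= 0 or (x1 - x0) * (y1 - y0) <= MIN_BOX_AREA:
            warnings.warn(
                f"{path}: dropping degenerate object "
                f"({x0}, {y0}, {x1}, {y1})",
                stacklevel=2,
            )
            continue
        boxes.append(Box(float(x0), float(y0), float(x1), float(y1), label=name))

    ann = ImageAnnotation(Path(filename).stem, width, height, boxes)
    ann.validate()
    return ann


def write_voc_xml(ann: ImageAnnotation, path: PathLike, image_filename: str | None = None) -> None:
    """Write one annotation back to LabelImg-style VOC XML (inverse of read)."""
    root = etree.Element("annotation")
    etree.SubElement(root, "folder").text = "images"
    etree.SubElement(root, "filename").text = image_filename or f"{ann.image_id}.png"
    size = etree.SubElement(root, "size")
    etree.SubElement(size, "width").text = str(ann.width)
    etree.SubElement(size, "height").text = str(ann.height)
    etree.SubElement(size, "depth").text = "3"
    etree.SubElement(root, "segmented").text = "0"
    for b in ann.boxes:
        obj = etree.SubElement(root, "object")
        etree.SubElement(obj, "name").text = b.label
        etree.SubElement(obj, "pose").text = "Unspecified"
        etree.SubElement(obj, "truncated").text = "0"
        etree.SubElement(obj, "difficult").text = "0"
        bnd = etree.SubElement(obj, "bndbox")
        etree.SubElement(bnd, "xmin").text = str(int(round(b.x_min)) + 1)
        etree.SubElement(bnd, "ymin").text = str(int(round(b.y_min)) + 1)
        etree.SubElement(bnd, "xmax").text = str(int(round(b.x_max)))
        etree.SubElement(bnd, "ymax").text = str(int(round(b.y_max)))
    tree = etree.ElementTree(root)
    tree.write(str(path), pretty_print=True, encoding="utf-8")


def write_coco_json(dataset: DatasetIndex, path: PathLike) -> None:
    """Write a dataset as COCO detection-format JSON ([x, y, w, h] boxes)."""
    dataset.validate()
    categories = [
        {"id": i + 1, "name": name} for i, name in enumerate(dataset.class_names)
    ]
    cat_id = {c["name"]: c["id"] for c in categories}
    images, annotations = [], []
    ann_id = 1
    for img_idx, item in enumerate(dataset.items, start=1):
        images.append(
            {
                "id": img_idx,
                "file_name": f"{item.image_id}.png",
                "width": item.width,
                "height": item.height,
            }
        )
        for b in item.boxes:
            annotations.append(
                {
                    "id": ann_id,
                    "image_id": img_idx,
                    "category_id": cat_id.get(b.label, 1),
                    "bbox": [b.x_min, b.y_min, b.width, b.height],
                    "area": b.area,
                    "iscrowd": 0,
                }
            )
            ann_id += 1
    payload = {"images": images, "annotations": annotations, "categories": categories}
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_coco_json(path: PathLike) -> DatasetIndex:
    """Read a COCO detection-format JSON file back into a DatasetIndex."""
    with open(path) as fh:
        payload = json.load(fh)
    cat_name = {c["id"]: c["name"] for c in payload.get("categories", [])}
    items: dict[int, ImageAnnotation] = {}
    for img in payload["images"]:
        items[img["id"]] = ImageAnnotation(
            Path(img["file_name"]).stem, img["width"], img["height"]
        )
    for ann in payload.get("annotations", []):
        x, y, w, h = ann["bbox"]
        items[ann["image_id"]].boxes.append(
            Box(x, y, x + w, y + h, label=cat_name.get(ann.get("category_id"), "pod"))
        )
    ds = DatasetIndex(
        items=list(items.values()),
        class_names=list(cat_name.values()) or ["pod"],
    )
    ds.validate()
    return ds


def read_voc_dir(annotations_dir: PathLike, label: str = "pod") -> DatasetIndex:
    """Read every ``*.xml`` in a directory into one DatasetIndex."""
    files = sorted(Path(annotations_dir).glob("*.xml"))
    if not files:
        raise FileNotFoundError(f"no .xml files in {annotations_dir}")
    ds = DatasetIndex(items=[read_voc_xml(p, label=label) for p in files])
    ds.validate()
    return ds
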