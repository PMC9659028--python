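"""Polygon lesion annotations in slide micrometer coordinates.

Annotations follow the ASAP dialect (the open Automated Slide Analysis
Platform XML format) for interchange: one ``Annotation`` element of type
Polygon per lesion, coordinates in slide micrometers, origin top-left,
x right, y down.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lxml import etree
from skimage.draw import polygon as draw_polygon


@dataclass
class Lesion:
    """One annotated tumor deposit: a closed polygon plus metadata."""

    polygon_um: np.ndarray  # (N, 2) array of (x, y) vertices, micrometers
    name: str = ""
    diameter_mm: float | None = None  # long-axis size where known (planted truth)

    def __post_init__(self) -> None:
        self.polygon_um = np.asarray(self.polygon_um, dtype=np.float64)
        if self.polygon_um.ndim != 2 or self.polygon_um.shape[1] != 2:
            raise ValueError("polygon must be an (N, 2) array of (x, y)")


@dataclass
class AnnotationSet:
    """All lesion annotations of one slide."""

    lesions: list[Lesion] = field(default_factory=list)
    group: str = "metastases"

    def __len__(self) -> int:
        return len(self.lesions)

    def __iter__(self):
        return iter(self.lesions)

    def diameters_mm(self) -> list[float]:
        return [l.diameter_mm for l in self.lesions if l.diameter_mm is not None]

    def rasterize(self, shape: tuple[int, int], spacing_um: float,
                  offset_um: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
        """Label image: pixel value i+1 inside lesion i, 0 elsewhere.

        The same rasterization is used when planting lesions and when
        matching detection points to lesions, so pixel membership is
        consistent across the pipeline.  Later lesions overwrite earlier
        ones where polygons overlap (planted lesions never overlap).
        """
        label = np.zeros(shape, dtype=np.int32)
        for i, lesion in enumerate(self.lesions):
            cols = (lesion.polygon_um[:, 0] - offset_um[0]) / spacing_um
            rows = (lesion.polygon_um[:, 1] - offset_um[1]) / spacing_um
            rr, cc = draw_polygon(rows, cols, shape=shape)
            label[rr, cc] = i + 1
        return label

    # ----- ASAP-dialect XML ------------------------------------------------

    def to_asap_xml(self, path) -> None:
        root = etree.Element("ASAP_Annotations")
        anns = etree.SubElement(root, "Annotations")
        for i, lesion in enumerate(self.lesions):
            ann = etree.SubElement(
                anns,
                "Annotation",
                Name=lesion.name or f"Annotation {i}",
                Type="Polygon",
                PartOfGroup=self.group,
                Color="#F4FA58",
            )
            coords = etree.SubElement(ann, "Coordinates")
            for order, (x, y) in enumerate(lesion.polygon_um):
                etree.SubElement(
                    coords,
                    "Coordinate",
                    Order=str(order),
                    X=f"{x:.4f}",
                    Y=f"{y:.4f}",
                )
        groups = etree.SubElement(root, "AnnotationGroups")
        etree.SubElement(
            groups, "Group", Name=self.group, PartOfGroup="None", Color="#64FE2E"
        ).append(etree.Element("Attributes"))
        etree.ElementTree(root).write(
            str(path), pretty_print=True, xml_declaration=True, encoding="utf-8"
        )

    @classmethod
    def from_asap_xml(cls, path) -> "AnnotationSet":
        tree = etree.parse(str(path))
        lesions: list[Lesion] = []
        group = "metastases"
        for ann in tree.findall(".//Annotation"):
            if ann.get("Type") != "Polygon":
                continue
            group = ann.get("PartOfGroup", group)
            pts = sorted(
                ann.findall(".//Coordinate"), key=lambda c: int(c.get("Order", "0"))
            )
            poly = np.array(
                [[float(c.get("X")), float(c.get("Y"))] for c in pts], dtype=np.float64
            )
            lesions.append(Lesion(polygon_um=poly, name=ann.get("Name", "")))
        return cls(lesions=lesions, group=group)
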