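"""Annotation JSON reading and writing.

One JSON file per disector pair:

.. code-block:: json

    {
      "units": "um",
      "thickness_um": 0.055,
      "animal_id": "SE01",
      "pair_id": "SE01-p00",
      "alignment": {"angle": 0.0, "dx": 0.0, "dy": 0.0},
      "sections": [
        {"id": "s1", "role": "reference",
         "field_bounds": [[0,0],[11,0],[11,11],[0,11]],
         "transects": [
            {"id": "t1", "type": "dcv", "circle": {"cx": 1.0, "cy": 2.0, "r": 0.05}},
            {"id": "t2", "type": "synapse", "polygon": [[3,3],[3.4,3],[3.2,3.3]]}
         ]},
        {"id": "s2", "role": "lookup", "...": "..."}
      ],
      "synapse_profiles": [
        {"id": "syn1", "pre_membrane": [[x,y], "..."], "psd": [[x,y], "..."],
         "cleft_polygon": null, "central_line": null,
         "vesicles": [{"cx": 0.1, "cy": 0.2, "r": 0.02}]}
      ]
    }

Coordinates may be given in pixels instead (``"units": "px"`` plus a
``"pixel_size_um"`` field); the reader converts to μm exactly once, so
all downstream geometry is unit-consistent.
"""

from __future__ import annotations

import json
from pathlib import Path

from .disector import (
    CircleFootprint,
    DisectorPair,
    ParticleTransect,
    SectionAnnotation,
)
from .geometry import Polygon2D, Polyline2D, RigidTransform2D
from .morphometry import SynapseProfile, VesicleCircle

__all__ = ["AnnotationError", "load_pair", "save_pair", "load_roi", "save_roi"]


class AnnotationError(ValueError):
    """Raised for malformed annotation files."""


def _scale_of(doc: dict, path) -> float:
    units = doc.get("units", "um")
    if units == "um":
        return 1.0
    if units == "px":
        try:
            return float(doc["pixel_size_um"])
        except KeyError:
            raise AnnotationError(f"{path}: units 'px' require 'pixel_size_um'") from None
    raise AnnotationError(f"{path}: unknown units {units!r}")


def _coords(obj, scale: float):
    return [[float(x) * scale, float(y) * scale] for x, y in obj]


def _parse_transect(t: dict, scale: float, path) -> ParticleTransect:
    try:
        tid = t["id"]
        ptype = t["type"]
    except KeyError as e:
        raise AnnotationError(f"{path}: transect missing field {e}") from None
    if "circle" in t:
        c = t["circle"]
        fp = CircleFootprint(float(c["cx"]) * scale, float(c["cy"]) * scale,
                             float(c["r"]) * scale)
    elif "polygon" in t:
        fp = Polygon2D(_coords(t["polygon"], scale))
    else:
        raise AnnotationError(f"{path}: transect {tid!r} needs a 'circle' or 'polygon'")
    return ParticleTransect(tid, ptype, fp)


def _parse_profile(p: dict, scale: float, path) -> SynapseProfile:
    if "id" not in p:
        raise AnnotationError(f"{path}: synapse profile missing 'id'")

    def line(key):
        return Polyline2D(_coords(p[key], scale)) if p.get(key) else None

    poly = Polygon2D(_coords(p["cleft_polygon"], scale)) if p.get("cleft_polygon") else None
    vesicles = [
        VesicleCircle(float(v["cx"]) * scale, float(v["cy"]) * scale, float(v["r"]) * scale)
        for v in p.get("vesicles", [])
    ]
    return SynapseProfile(
        id=p["id"],
        pre_membrane=line("pre_membrane"),
        psd=line("psd"),
        cleft_polygon=poly,
        central_line=line("central_line"),
        vesicles=vesicles,
    )


def load_pair(path) -> tuple[DisectorPair, list[SynapseProfile], dict]:
    """Read one annotation pair file.

    Returns (pair, synapse profiles, metadata) where metadata carries
    ``animal_id`` and ``pair_id`` when present.
    """
    path = Path(path)
    doc = json.loads(path.read_text())
    scale = _scale_of(doc, path)
    al = doc.get("alignment", {})
    alignment = RigidTransform2D(
        angle=float(al.get("angle", 0.0)),
        dx=float(al.get("dx", 0.0)) * scale,
        dy=float(al.get("dy", 0.0)) * scale,
    )
    sections = {}
    for s in doc.get("sections", []):
        try:
            role = s["role"]
        except KeyError:
            raise AnnotationError(f"{path}: section missing 'role'") from None
        if role in sections:
            raise AnnotationError(f"{path}: duplicate {role!r} section")
        sections[role] = SectionAnnotation(
            section_id=s.get("id", role),
            role=role,
            transects=[_parse_transect(t, scale, path) for t in s.get("transects", [])],
            field_bounds=Polygon2D(_coords(s["field_bounds"], scale)),
        )
    if set(sections) != {"reference", "lookup"}:
        raise AnnotationError(f"{path}: need exactly one reference and one lookup section")
    pair = DisectorPair(
        reference=sections["reference"],
        lookup=sections["lookup"],
        alignment=alignment,
        thickness=float(doc.get("thickness_um", 0.055)) * scale if doc.get("units") == "px"
        else float(doc.get("thickness_um", 0.055)),
    )
    profiles = [_parse_profile(p, scale, path) for p in doc.get("synapse_profiles", [])]
    meta = {k: doc[k] for k in ("animal_id", "pair_id") if k in doc}
    return pair, profiles, meta


def _dump_transect(t: ParticleTransect) -> dict:
    fp = t.footprint
    if isinstance(fp, CircleFootprint):
        return {"id": t.id, "type": t.particle_type,
                "circle": {"cx": fp.cx, "cy": fp.cy, "r": fp.radius}}
    return {"id": t.id, "type": t.particle_type,
            "polygon": [[float(x), float(y)] for x, y in fp.vertices]}


def _dump_profile(p: SynapseProfile) -> dict:
    def pts(line):
        return None if line is None else [[float(x), float(y)] for x, y in line.points]

    return {
        "id": p.id,
        "pre_membrane": pts(p.pre_membrane),
        "psd": pts(p.psd),
        "cleft_polygon": None if p.cleft_polygon is None
        else [[float(x), float(y)] for x, y in p.cleft_polygon.vertices],
        "central_line": pts(p.central_line),
        "vesicles": [{"cx": v.cx, "cy": v.cy, "r": v.radius} for v in p.vesicles],
    }


def save_pair(
    pair: DisectorPair,
    path,
    profiles: list[SynapseProfile] | None = None,
    animal_id: str | None = None,
    pair_id: str | None = None,
) -> None:
    """Write one annotation pair (always in μm)."""
    doc: dict = {
        "units": "um",
        "thickness_um": pair.thickness,
        "alignment": {
            "angle": pair.alignment.angle,
            "dx": pair.alignment.dx,
            "dy": pair.alignment.dy,
        },
        "sections": [
            {
                "id": sec.section_id,
                "role": sec.role,
                "field_bounds": [[float(x), float(y)] for x, y in sec.field_bounds.vertices],
                "transects": [_dump_transect(t) for t in sec.transects],
            }
            for sec in (pair.reference, pair.lookup)
        ],
        "synapse_profiles": [_dump_profile(p) for p in (profiles or [])],
    }
    if animal_id is not None:
        doc["animal_id"] = animal_id
    if pair_id is not None:
        doc["pair_id"] = pair_id
    Path(path).write_text(json.dumps(doc, sort_keys=True) + "\n")


def load_roi(path) -> Polygon2D:
    """Read an ROI outline: ``{"units": "um", "vertices": [[x, y], ...]}``."""
    path = Path(path)
    doc = json.loads(path.read_text())
    scale = _scale_of(doc, path)
    try:
        verts = doc["vertices"]
    except KeyError:
        raise AnnotationError(f"{path}: ROI file missing 'vertices'") from None
    return Polygon2D(_coords(verts, scale))


def save_roi(roi: Polygon2D, path) -> None:
    doc = {"units": "um", "vertices": [[float(x), float(y)] for x, y in roi.vertices]}
    Path(path).write_text(json.dumps(doc, sort_keys=True) + "\n")
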