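"""Project persistence, CSV export and annotated-image rendering.

A project file is a versioned JSON document holding everything needed to
resume an analysis: the image reference and checksum, the enhancement
provenance, lane/band geometry with densitometry, the ladder calibration,
the presence/absence matrix, merge state, marker calls, the tree in Newick
form, population-genetics results and the seeds used.  Serialization is
canonical (sorted keys), so save -> load -> save is byte-identical, and
unknown keys survive a round-trip for forward compatibility.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from PIL import Image, ImageDraw

from .detection import Band, Lane, LaneSet
from .image import GelImage
from .quantify import BandClass, Calibration, PresenceMatrix

PROJECT_VERSION = 1

_KNOWN_KEYS = {
    "version", "image_path", "image_checksum", "provenance", "lanes",
    "calibration", "presence_matrix", "merge_state", "marker_calls",
    "tree_newick", "popgen_state", "seeds",
}


@dataclass
class Project:
    """Resumable analysis state; `extra` preserves unknown future fields."""

    image_path: str | None = None
    image_checksum: str | None = None
    provenance: list = field(default_factory=list)
    lanes: list = field(default_factory=list)  # serialized lane dicts
    calibration: list | None = None  # knots
    presence_matrix: dict | None = None
    merge_state: dict | None = None
    marker_calls: list = field(default_factory=list)
    tree_newick: str | None = None
    popgen_state: dict | None = None
    seeds: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)


def image_checksum(img: GelImage) -> str:
    return hashlib.sha256(np.ascontiguousarray(img.pixels).tobytes()).hexdigest()


def lane_to_dict(lane: Lane) -> dict:
    return {
        "id": lane.id, "x_top": list(lane.x_top), "x_bottom": list(lane.x_bottom),
        "y_range": list(lane.y_range) if lane.y_range else None,
        "sample_name": lane.sample_name,
        "bands": [
            {"id": b.id, "y_top": b.y_top, "y_center": b.y_center,
             "y_bottom": b.y_bottom, "density": b.density, "rf": b.rf,
             "mw": b.mw, "quantity": b.quantity}
            for b in lane.bands
        ],
    }


def lane_from_dict(d: dict) -> Lane:
    lane = Lane(x_top=tuple(d["x_top"]), x_bottom=tuple(d["x_bottom"]),
                y_range=tuple(d["y_range"]) if d.get("y_range") else None,
                sample_name=d.get("sample_name", ""), id=d["id"])
    lane.bands = [
        Band(y_top=b["y_top"], y_center=b["y_center"], y_bottom=b["y_bottom"],
             lane_id=lane.id, id=b["id"], density=b.get("density"),
             rf=b.get("rf"), mw=b.get("mw"), quantity=b.get("quantity"))
        for b in d["bands"]
    ]
    return lane


def presence_to_dict(m: PresenceMatrix) -> dict:
    return {
        "basis": m.basis,
        "samples": list(m.samples),
        "classes": [{"value": c.value, "members": [list(t) for t in c.members]}
                    for c in m.band_classes],
        "entries": np.asarray(m.entries).tolist(),
    }


def presence_from_dict(d: dict) -> PresenceMatrix:
    return PresenceMatrix(
        band_classes=[BandClass(value=c["value"],
                                members=[tuple(t) for t in c["members"]])
                      for c in d["classes"]],
        samples=list(d["samples"]),
        entries=np.asarray(d["entries"], dtype=int),
        basis=d.get("basis", "mw"),
    )


def _project_to_doc(p: Project) -> dict:
    doc = {
        "version": PROJECT_VERSION,
        "image_path": p.image_path,
        "image_checksum": p.image_checksum,
        "provenance": p.provenance,
        "lanes": p.lanes,
        "calibration": p.calibration,
        "presence_matrix": p.presence_matrix,
        "merge_state": p.merge_state,
        "marker_calls": p.marker_calls,
        "tree_newick": p.tree_newick,
        "popgen_state": p.popgen_state,
        "seeds": p.seeds,
    }
    doc.update(p.extra)
    return doc


def save_project(p: Project, path) -> None:
    """Write the project as canonical JSON (sorted keys, stable bytes)."""
    doc = _project_to_doc(p)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(doc, fh, sort_keys=True, indent=2, ensure_ascii=False)
        fh.write("\n")


def load_project(path) -> Project:
    """Read a project file; unknown keys are preserved in ``extra``."""
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)  # raises JSONDecodeError with location if corrupt
    version = doc.get("version")
    if version != PROJECT_VERSION:
        raise ValueError(
            f"project version {version!r} not supported (expected "
            f"{PROJECT_VERSION}); no migration path available")
    extra = {k: v for k, v in doc.items() if k not in _KNOWN_KEYS}
    return Project(
        image_path=doc.get("image_path"),
        image_checksum=doc.get("image_checksum"),
        provenance=doc.get("provenance", []),
        lanes=doc.get("lanes", []),
        calibration=doc.get("calibration"),
        presence_matrix=doc.get("presence_matrix"),
        merge_state=doc.get("merge_state"),
        marker_calls=doc.get("marker_calls", []),
        tree_newick=doc.get("tree_newick"),
        popgen_state=doc.get("popgen_state"),
        seeds=doc.get("seeds", {}),
        extra=extra,
    )


def calibration_from_knots(knots) -> Calibration:
    return Calibration(knots=[tuple(k) for k in knots])


# ---------------------------------------------------------------------------
# CSV export
# ---------------------------------------------------------------------------

def export_csv(table, path, line_terminator: str = "\n") -> None:
    """Write a DataFrame (or rows) as RFC-4180-style CSV, UTF-8, header row."""
    import pandas as pd

    df = table if isinstance(table, pd.DataFrame) else pd.DataFrame(table)
    if df.empty:
        raise ValueError("refusing to export an empty table")
    # shortest-round-trip float formatting so a re-read restores exact values
    df.to_csv(path, index=False, lineterminator=line_terminator,
              encoding="utf-8", float_format=lambda v: repr(float(v)))


# ---------------------------------------------------------------------------
# annotated image
# ---------------------------------------------------------------------------

def render_annotated_image(img: GelImage, lanes, marker_calls=None,
                           out_path=None, overlay: bool = True) -> dict:
    """Draw lane boxes, band lines, sample names and marker values on the gel.

    Writes a PNG plus a sidecar JSON (``<out_path>.labels.json``) listing
    every drawn label, so downstream checks need no OCR.  With
    ``overlay=False`` the PNG is a pixel-identical copy of the input.
    Returns the sidecar document.
    """
    marker_calls = marker_calls or []
    if overlay:
        rgb = img.pixels if img.pixels.ndim == 3 else np.stack([img.pixels] * 3,
                                                               axis=-1)
        pil = Image.fromarray(rgb.astype(np.uint8))
    else:
        pil = Image.fromarray(img.pixels)
    labels = []
    if overlay:
        draw = ImageDraw.Draw(pil)
        marker_values = {round(c.class_value, 6) for c in marker_calls}
        for lane in lanes:
            lo, hi = lane.x_top
            y0, y1 = lane.y_range if lane.y_range else (0, img.height)
            draw.rectangle([lo, y0, hi - 1, y1 - 1], outline=(255, 0, 0))
            name = lane.sample_name
            if not name:
                warnings.warn(f"lane {lane.id} has no sample name; blank label",
                              UserWarning, stacklevel=2)
            draw.text((lo + 2, max(y0 - 12, 0)), name, fill=(255, 255, 0))
            labels.append({"kind": "sample", "text": name, "x": lo, "y": y0})
            for band in lane.bands:
                yc = int(round(band.y_center))
                draw.line([(lo, yc), (hi - 1, yc)], fill=(0, 255, 0))
                if band.mw is not None and round(band.mw, 6) in marker_values:
                    text = f"{band.mw:g}"
                    draw.text((hi + 2, yc - 5), text, fill=(255, 0, 255))
                    labels.append({"kind": "marker", "text": text,
                                   "x": hi, "y": yc})
    sidecar = {"overlay": overlay, "labels": labels}
    if out_path is not None:
        pil.save(out_path, format="PNG")
        with open(f"{out_path}.labels.json", "w", encoding="utf-8") as fh:
            json.dump(sidecar, fh, sort_keys=True, indent=2)
    return sidecar
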