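"""Reading and writing quilts, and the packaged survey of 16 museum quilts.

Two interchange formats are supported:

* JSON — one self-contained document::

      {"name": ..., "class": "regular"|"crazy", "units": "cm"|"px",
       "scale_cm_per_px": ...,           # required when units == "px"
       "window": {"w": ..., "h": ...},
       "patches": [{"id": ..., "category": ..., "vertices": [[x, y], ...]}, ...]}

* CSV — one vertex per row (``quilt, patch_id, category, vertex_index, x, y``)
  with a JSON sidecar (``<stem>.meta.json``) holding name/class/units/window.

Pixel-unit files are converted to cm at ingest (lengths scale by
``scale_cm_per_px``, areas by its square).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .geometry import InvalidGeometryError, Patch, Quilt, QuiltClass

__all__ = [
    "QuiltRecord",
    "QuiltParseError",
    "read_quilt",
    "write_quilt",
    "quilt_survey",
]


class QuiltParseError(ValueError):
    """Raised for malformed quilt files; the message names the offending patch."""


@dataclass(frozen=True)
class QuiltRecord:
    """Summary row for one surveyed quilt (no patch geometry)."""

    name: str
    quilt_class: QuiltClass
    year: str
    n_patches: int
    height_cm: float
    width_cm: float
    overall_area_cm2: float
    patched_area_cm2: float

    def __post_init__(self) -> None:
        if self.n_patches < 1:
            raise ValueError(f"{self.name}: n_patches must be >= 1")
        if self.patched_area_cm2 > self.overall_area_cm2:
            raise ValueError(f"{self.name}: patched area exceeds overall area")


def quilt_survey() -> list[QuiltRecord]:
    """The 16 surveyed quilts (R1–R8 regular, C1–C8 crazy), as published.

    Heights/widths are in cm, areas in cm^2; years are the exact or
    approximate production years.  The records carry no polygon geometry:
    the original tracings were never deposited, which is why the synthetic
    generator exists.
    """
    text = resources.files("patchstat.data").joinpath("quilt_summary.csv").read_text()
    out = []
    for row in csv.DictReader(text.splitlines()):
        out.append(
            QuiltRecord(
                name=row["name"],
                quilt_class=QuiltClass(row["quilt_class"]),
                year=row["year"],
                n_patches=int(row["n_patches"]),
                height_cm=float(row["height_cm"]),
                width_cm=float(row["width_cm"]),
                overall_area_cm2=float(row["overall_area_cm2"]),
                patched_area_cm2=float(row["patched_area_cm2"]),
            )
        )
    return out


def _build_quilt(
    name: str,
    quilt_class: str,
    units: str,
    scale: float | None,
    window: tuple[float, float],
    raw_patches: list[tuple[str, str | None, list[list[float]]]],
) -> Quilt:
    if units not in ("cm", "px"):
        raise QuiltParseError(f"unknown units {units!r} (expected 'cm' or 'px')")
    if units == "px":
        if scale is None or scale <= 0:
            raise QuiltParseError("pixel-unit file needs a positive scale_cm_per_px")
        s = float(scale)
    else:
        s = 1.0
    patches = []
    for pid, category, vertices in raw_patches:
        try:
            patch = Patch(
                vertices=tuple((x * s, y * s) for x, y in vertices),
                category=category,
            )
        except (InvalidGeometryError, ValueError) as exc:
            raise QuiltParseError(f"patch {pid!r}: {exc}") from exc
        patches.append(patch)
    return Quilt(
        window=(window[0] * s, window[1] * s),
        patches=tuple(patches),
        quilt_class=QuiltClass(quilt_class),
        name=name,
        scale=s,
    )


def read_quilt(path: str | Path, format: str | None = None) -> Quilt:
    """Read a quilt from JSON or CSV (format inferred from the suffix)."""
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "json")
    if fmt == "json":
        doc = json.loads(path.read_text())
        try:
            raw = [
                (str(p.get("id", i)), p.get("category"), p["vertices"])
                for i, p in enumerate(doc["patches"])
            ]
            return _build_quilt(
                name=doc.get("name", path.stem),
                quilt_class=doc["class"],
                units=doc.get("units", "cm"),
                scale=doc.get("scale_cm_per_px"),
                window=(float(doc["window"]["w"]), float(doc["window"]["h"])),
                raw_patches=raw,
            )
        except (KeyError, TypeError) as exc:
            raise QuiltParseError(f"malformed quilt JSON {path}: {exc}") from exc
    if fmt == "csv":
        meta_path = path.with_suffix(".meta.json")
        if not meta_path.exists():
            raise QuiltParseError(f"missing sidecar metadata file {meta_path}")
        meta = json.loads(meta_path.read_text())
        rows: dict[str, tuple[str | None, list[tuple[int, float, float]]]] = {}
        with path.open(newline="") as fh:
            for row in csv.DictReader(fh):
                pid = row["patch_id"]
                cat = row.get("category") or None
                rows.setdefault(pid, (cat, []))[1].append(
                    (int(row["vertex_index"]), float(row["x"]), float(row["y"]))
                )
        raw = []
        for pid, (cat, verts) in rows.items():
            verts.sort()
            raw.append((pid, cat, [[x, y] for _, x, y in verts]))
        try:
            return _build_quilt(
                name=meta.get("name", path.stem),
                quilt_class=meta["class"],
                units=meta.get("units", "cm"),
                scale=meta.get("scale_cm_per_px"),
                window=(float(meta["window"]["w"]), float(meta["window"]["h"])),
                raw_patches=raw,
            )
        except KeyError as exc:
            raise QuiltParseError(f"malformed sidecar {meta_path}: {exc}") from exc
    raise ValueError(f"unknown format {fmt!r}")


def write_quilt(quilt: Quilt, path: str | Path, format: str | None = None) -> None:
    """Write a quilt to JSON or CSV (+ sidecar); inverse of :func:`read_quilt`."""
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "json")
    if fmt == "json":
        doc = {
            "name": quilt.name,
            "class": quilt.quilt_class.value,
            "units": "cm",
            "window": {"w": quilt.window[0], "h": quilt.window[1]},
            "patches": [
                {
                    "id": str(i),
                    "category": p.category,
                    "vertices": [[x, y] for x, y in p.vertices],
                }
                for i, p in enumerate(quilt.patches)
            ],
        }
        path.write_text(json.dumps(doc, indent=1))
        return
    if fmt == "csv":
        with path.open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["quilt", "patch_id", "category", "vertex_index", "x", "y"])
            for i, p in enumerate(quilt.patches):
                for j, (x, y) in enumerate(p.vertices):
                    w.writerow([quilt.name, i, p.category or "", j, repr(x), repr(y)])
        meta = {
            "name": quilt.name,
            "class": quilt.quilt_class.value,
            "units": "cm",
            "window": {"w": quilt.window[0], "h": quilt.window[1]},
        }
        path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1))
        return
    raise ValueError(f"unknown format {fmt!r}")
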