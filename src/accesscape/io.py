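"""Readers/writers for the pipeline's file formats.

Rasters travel as ESRI ASCII grids (``.asc`` — plain text, readable by GDAL
and QGIS) with an explicit nodata tag and a ``.prj`` sidecar carrying the
CRS label; class rasters hold integer codes, elevation/time/birth rasters
floats at full double precision so round-trips are exact.  Vector layers and
councils are GeoJSON with a ``class`` (or ``name``) property; facilities are
CSV ``id,x,y,care_level``.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
from shapely.geometry import mapping, shape

from accesscape.cost import TravelTimeSurface
from accesscape.coverage import AdminUnits, BirthRaster
from accesscape.grid import (
    ClassRaster,
    Dem,
    Facility,
    Feature,
    GridSpec,
    LandClass,
    VectorLayer,
)

NODATA_FLOAT = -9999.0


# ---------------------------------------------------------------------------
# ASCII grids


def write_ascii_grid(
    path: str | Path,
    grid: GridSpec,
    values: np.ndarray,
    nodata,
    integer: bool,
) -> None:
    path = Path(path)
    xll = grid.origin_x
    yll = grid.origin_y - grid.height_m
    lines = [
        f"ncols {grid.n_cols}",
        f"nrows {grid.n_rows}",
        f"xllcorner {xll!r}",
        f"yllcorner {yll!r}",
        f"cellsize {grid.cell_size!r}",
        f"NODATA_value {nodata}",
    ]
    fmt = "%d" if integer else "%.17g"
    body = "\n".join(
        " ".join(fmt % v for v in row) for row in np.asarray(values)
    )
    path.write_text("\n".join(lines) + "\n" + body + "\n")
    path.with_suffix(".prj").write_text(grid.crs_label + "\n")


def read_ascii_grid(path: str | Path) -> tuple[GridSpec, np.ndarray, float]:
    path = Path(path)
    text = path.read_text().splitlines()
    hdr: dict[str, str] = {}
    i = 0
    while i < len(text) and text[i].split()[0].lower() in (
        "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
    ):
        k, v = text[i].split(maxsplit=1)
        hdr[k.lower()] = v
        i += 1
    n_cols = int(hdr["ncols"])
    n_rows = int(hdr["nrows"])
    cell = float(hdr["cellsize"])
    xll = float(hdr["xllcorner"])
    yll = float(hdr["yllcorner"])
    nodata = float(hdr.get("nodata_value", NODATA_FLOAT))
    crs = "local-projected-meters"
    prj = path.with_suffix(".prj")
    if prj.exists():
        crs = prj.read_text().strip()
    grid = GridSpec(n_rows, n_cols, cell, xll, yll + n_rows * cell, crs)
    vals = np.loadtxt(text[i:], dtype=float)
    vals = vals.reshape(n_rows, n_cols)
    return grid, vals, nodata


def write_raster(
    obj: ClassRaster | Dem | BirthRaster | TravelTimeSurface,
    path: str | Path,
) -> None:
    """Serialize any raster object; unreachable travel times become nodata."""
    if isinstance(obj, ClassRaster):
        write_ascii_grid(path, obj.grid, obj.values, obj.nodata_code, True)
    elif isinstance(obj, Dem):
        write_ascii_grid(path, obj.grid, obj.elevation, NODATA_FLOAT, False)
    elif isinstance(obj, BirthRaster):
        write_ascii_grid(path, obj.grid, obj.births, NODATA_FLOAT, False)
    elif isinstance(obj, TravelTimeSurface):
        vals = np.where(obj.unreachable, NODATA_FLOAT, obj.minutes)
        write_ascii_grid(path, obj.grid, vals, NODATA_FLOAT, False)
    else:
        raise TypeError(f"cannot serialize {type(obj).__name__}")


def read_raster(path: str | Path, kind: str):
    """Read a raster back as the requested kind.

    kind: "class" | "dem" | "births" | "travel_time" | "zones".
    Unknown class codes raise with the offending codes listed.
    """
    grid, vals, nodata = read_ascii_grid(path)
    if kind == "class":
        ivals = vals.astype(np.int16)
        if not np.array_equal(ivals, vals):
            raise ValueError("class raster contains non-integer values")
        return ClassRaster(grid, ivals, int(nodata))
    if kind == "dem":
        return Dem(grid, vals)
    if kind == "births":
        return BirthRaster(grid, vals)
    if kind == "travel_time":
        minutes = np.where(vals == nodata, np.inf, vals)
        return TravelTimeSurface(grid, minutes)
    if kind == "zones":
        from accesscape.catchments import ZoneRaster

        return ZoneRaster(grid, vals.astype(np.int8))
    raise ValueError(f"unknown raster kind {kind!r}")


# ---------------------------------------------------------------------------
# vectors / facilities / councils


def write_vector_layer(layer: VectorLayer, path: str | Path) -> None:
    feats = []
    for f in layer.features:
        tag = f.tag
        if isinstance(tag, LandClass):
            tag = tag.name.lower()
        feats.append(
            {
                "type": "Feature",
                "geometry": mapping(f.geometry),
                "properties": {"class": tag},
            }
        )
    doc = {
        "type": "FeatureCollection",
        "crs_label": layer.crs_label,
        "geometry_kind": layer.geometry_kind,
        "features": feats,
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True))


def read_vector_layer(path: str | Path) -> VectorLayer:
    doc = json.loads(Path(path).read_text())
    kind = doc.get("geometry_kind")
    feats = []
    for f in doc["features"]:
        geom = shape(f["geometry"])
        tag = f.get("properties", {}).get("class")
        try:
            tag = LandClass[tag.upper()] if isinstance(tag, str) else tag
        except KeyError:
            pass  # keep non-class tags (e.g. zone names) as strings
        feats.append(Feature(geom, tag))
    if kind is None:
        kind = {
            "LineString": "polyline", "MultiLineString": "polyline",
            "Polygon": "polygon", "MultiPolygon": "polygon",
            "Point": "point", "MultiPoint": "point",
        }[feats[0].geometry.geom_type] if feats else "polyline"
    return VectorLayer(kind, feats,
                       crs_label=doc.get("crs_label", "local-projected-meters"))


def write_facilities_csv(facilities: list[Facility], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "x", "y", "care_level"])
        for f in facilities:
            w.writerow([f.id, repr(f.x), repr(f.y), f.care_level])


def read_facilities_csv(path: str | Path) -> list[Facility]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                Facility(row["id"], float(row["x"]), float(row["y"]),
                         row["care_level"])
            )
    return out


def write_admin_units(units: AdminUnits, path: str | Path) -> None:
    feats = [
        {
            "type": "Feature",
            "geometry": mapping(poly),
            "properties": {"name": name},
        }
        for name, poly in zip(units.names, units.polygons)
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": feats},
                   sort_keys=True)
    )


def read_admin_units(path: str | Path) -> AdminUnits:
    doc = json.loads(Path(path).read_text())
    names, polys = [], []
    for f in doc["features"]:
        names.append(f["properties"]["name"])
        polys.append(shape(f["geometry"]))
    return AdminUnits(names, polys)
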