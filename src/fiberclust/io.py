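"""Readers and writers for fiber tables and region geometry.

Fiber tables are delimited text (one header row, UTF-8); the column names
and delimiter are configurable through :class:`TableDialect` because
segmentation exports (Fiji, Neurolucida, ...) are heterogeneous.  Region
geometry is GeoJSON (``Polygon`` with exterior + interior rings, possibly
wrapped in a Feature or FeatureCollection) or a CSV vertex list with a
ring-index column (ring 0 = outer contour, rings 1.. = holes).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .exceptions import FormatError, GeometryError
from .geometry import Fascicle, FiberClass, FiberRecord, Region

__all__ = [
    "TableDialect",
    "read_fiber_table",
    "write_fiber_table",
    "read_region",
    "write_region",
    "fascicle_from_files",
]

_OPTIONAL = ("area", "perimeter", "diameter")


@dataclass
class TableDialect:
    """Column mapping and delimiter for fiber tables.

    ``columns`` maps canonical names (id, x, y, area, perimeter, diameter,
    fiber_class) to the header names actually present in the file.
    """

    delimiter: str = ","
    columns: dict[str, str] = field(
        default_factory=lambda: {
            "id": "id",
            "x": "x",
            "y": "y",
            "area": "area",
            "perimeter": "perimeter",
            "diameter": "diameter",
            "fiber_class": "fiber_class",
        }
    )


def read_fiber_table(path: str | Path, dialect: TableDialect | None = None) -> list[FiberRecord]:
    """Read one fiber per row from a delimited text file.

    Mandatory columns: id, x, y.  Optional: area, perimeter, diameter,
    fiber_class.  Row order is preserved.

    Raises
    ------
    FormatError
        If a mandatory column is missing (naming it) or a coordinate is
        non-numeric (naming the 1-based data line).
    """
    dialect = dialect or TableDialect()
    path = Path(path)
    df = pd.read_csv(path, sep=dialect.delimiter, dtype=str, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]

    cols = dialect.columns
    for canon in ("id", "x", "y"):
        if cols.get(canon, canon) not in df.columns:
            raise FormatError(
                f"{path.name}: missing mandatory column {cols.get(canon, canon)!r} ({canon})"
            )

    def numeric(canon: str, required: bool) -> np.ndarray | None:
        name = cols.get(canon, canon)
        if name not in df.columns:
            return None
        raw = df[name]
        vals = np.empty(len(raw))
        for i, v in enumerate(raw):
            if v is None or (isinstance(v, float) and np.isnan(v)) or str(v).strip() == "":
                if required:
                    raise FormatError(
                        f"{path.name}: empty value in column {name!r} at data line {i + 1}"
                    )
                vals[i] = np.nan
                continue
            try:
                # python float(): exact round-trip parsing (pandas' fast
                # parser can lose the last ulp)
                vals[i] = float(v)
            except ValueError:
                raise FormatError(
                    f"{path.name}: non-numeric value {v!r} in column "
                    f"{name!r} at data line {i + 1}"
                ) from None
        return vals

    x = numeric("x", required=True)
    y = numeric("y", required=True)
    opt = {canon: numeric(canon, required=False) for canon in _OPTIONAL}
    ids = df[cols.get("id", "id")].astype(str).to_numpy()
    klass_col = cols.get("fiber_class", "fiber_class")
    classes = (
        df[klass_col].fillna("UNASSIGNED").to_numpy()
        if klass_col in df.columns
        else np.full(len(df), "UNASSIGNED")
    )

    records = []
    for i in range(len(df)):
        def pick(canon: str) -> float | None:
            arr = opt[canon]
            if arr is None or np.isnan(arr[i]):
                return None
            return float(arr[i])

        records.append(
            FiberRecord(
                fiber_id=ids[i],
                x=float(x[i]),
                y=float(y[i]),
                area=pick("area"),
                perimeter=pick("perimeter"),
                diameter=pick("diameter"),
                fiber_class=FiberClass(classes[i]),
            )
        )
    return records


def write_fiber_table(
    records: list[FiberRecord], path: str | Path, dialect: TableDialect | None = None
) -> None:
    """Write fibers as delimited text; numeric fields keep full precision
    (shortest round-trip repr), so read → write → read is lossless."""
    dialect = dialect or TableDialect()
    cols = dialect.columns
    rows = [
        {
            cols.get("id", "id"): f.fiber_id,
            cols.get("x", "x"): f.x,
            cols.get("y", "y"): f.y,
            cols.get("area", "area"): f.area,
            cols.get("perimeter", "perimeter"): f.perimeter,
            cols.get("diameter", "diameter"): f.diameter,
            cols.get("fiber_class", "fiber_class"): f.fiber_class.value,
        }
        for f in records
    ]
    header = [
        cols.get(c, c) for c in ("id", "x", "y", "area", "perimeter", "diameter", "fiber_class")
    ]
    pd.DataFrame(rows, columns=header).to_csv(path, sep=dialect.delimiter, index=False)


# -- region geometry --------------------------------------------------------


def _region_from_geojson(obj: dict, name: str) -> Region:
    if obj.get("type") == "FeatureCollection":
        feats = obj.get("features", [])
        if not feats:
            raise GeometryError(f"{name}: empty FeatureCollection")
        obj = feats[0]
    props = {}
    if obj.get("type") == "Feature":
        props = obj.get("properties") or {}
        obj = obj["geometry"]
    geom = shape(obj)
    if geom.geom_type != "Polygon":
        raise GeometryError(f"{name}: expected a Polygon geometry, got {geom.geom_type}")
    return Region(
        outer=np.asarray(geom.exterior.coords),
        holes=tuple(np.asarray(r.coords) for r in geom.interiors),
        name=str(props.get("name", name)),
    )


def read_region(path: str | Path) -> Region:
    """Read a region from GeoJSON or a ring-indexed CSV vertex list.

    CSV files need columns ``ring, x, y``; ring 0 is the outer contour and
    every other ring index is a hole.

    Raises
    ------
    GeometryError
        For self-intersecting outer rings, holes outside the outer ring,
        or unsupported geometry types.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    stripped = text.lstrip()
    if stripped.startswith("{"):
        return _region_from_geojson(json.loads(text), path.stem)
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("ring", "x", "y"):
        if col not in df.columns:
            raise FormatError(f"{path.name}: vertex list needs columns ring,x,y")
    rings = {int(r): g[["x", "y"]].to_numpy(dtype=float) for r, g in df.groupby("ring", sort=True)}
    if 0 not in rings:
        raise GeometryError(f"{path.name}: no ring 0 (outer contour)")
    holes = tuple(rings[r] for r in sorted(rings) if r != 0)
    return Region(outer=rings[0], holes=holes, name=path.stem)


def write_region(region: Region, path: str | Path) -> None:
    """Write a region as a GeoJSON Feature with a ``name`` property."""
    feature = {
        "type": "Feature",
        "properties": {"name": region.name},
        "geometry": mapping(region.polygon),
    }
    Path(path).write_text(json.dumps(feature), encoding="utf-8")


def fascicle_from_files(
    fiber_path: str | Path,
    region_path: str | Path,
    fascicle_id: str | None = None,
    dialect: TableDialect | None = None,
) -> Fascicle:
    """Convenience loader: fiber table + region geometry → Fascicle."""
    region = read_region(region_path)
    fibers = read_fiber_table(fiber_path, dialect=dialect)
    return Fascicle(region=region, fibers=fibers, fascicle_id=fascicle_id or region.name)
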