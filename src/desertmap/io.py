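"""Readers and writers for the pipeline's tabular and GeoJSON formats.

CSV schemas (header names are fixed and documented here):

* blocks:     ``block_id, tract_id, latitude, longitude, population``
* tracts:     ``tract_id, state, land_area_sqmi, population, median_income,
  prop_below_fpl, car_owner_count`` plus any number of ``demo_<name>``
  proportion columns
* pharmacies: ``pharmacy_id, latitude, longitude, ownership`` plus
  ``svc_<flag>`` boolean columns and an optional ``tract_id``
* metros:     ``metro_id, latitude, longitude, median_income``

Missing values are encoded as empty strings (CSV) or ``null`` (GeoJSON)
and round-trip as missing — never as zero.  GeoJSON files follow the
standard (lon, lat) axis order; the internal representation is
(lat, lon) and conversion is the reader's/writer's job.

Loading never silently drops records: every reader returns a
:class:`LoadResult` reporting accepted and rejected counts, and raises by
default when any record is invalid.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .models import (
    SERVICE_FLAGS,
    Block,
    MetroArea,
    Ownership,
    Pharmacy,
    SchemaError,
    Tract,
    ValidationError,
)

_TRACT_BASE_COLS = [
    "tract_id",
    "state",
    "land_area_sqmi",
    "population",
    "median_income",
    "prop_below_fpl",
    "car_owner_count",
]


@dataclass
class LoadResult:
    """Outcome of a load: accepted records plus per-record rejections.

    ``n_input == len(records) + len(rejected)`` always holds.
    """

    records: list
    rejected: list[tuple[str, str]] = field(default_factory=list)  # (row id, reason)

    @property
    def n_input(self) -> int:
        return len(self.records) + len(self.rejected)


def _opt_float(value) -> Optional[float]:
    if value is None or value == "":
        return None
    f = float(value)
    if math.isnan(f):
        return None
    return f


def _opt_int(value) -> Optional[int]:
    f = _opt_float(value)
    return None if f is None else int(round(f))


_BOOL_STRINGS = {
    "true": True, "t": True, "yes": True, "y": True, "1": True,
    "false": False, "f": False, "no": False, "n": False, "0": False,
}


def _opt_bool(value) -> Optional[bool]:
    if value is None or value == "":
        return None
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in _BOOL_STRINGS:
        return _BOOL_STRINGS[s]
    raise ValidationError(f"cannot interpret {value!r} as a boolean flag")


def _check_header(present: Sequence[str], required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in present]
    if missing:
        raise SchemaError(f"{what}: missing required column(s) {missing}")


def _finish(result: LoadResult, strict: bool, what: str) -> LoadResult:
    if strict and result.rejected:
        lines = "; ".join(f"{rid}: {reason}" for rid, reason in result.rejected[:5])
        raise ValidationError(
            f"{what}: {len(result.rejected)} invalid record(s) — {lines}"
        )
    return result


def _check_unique(ids: list[str], what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"{what}: duplicate id {i!r}")
        seen.add(i)


# ---------------------------------------------------------------- blocks

def _block_from_props(bid, tid, lat, lon, pop) -> Block:
    return Block(
        block_id=str(bid),
        tract_id=str(tid),
        latitude=float(lat),
        longitude=float(lon),
        population=int(pop),
    )


def read_blocks(path, format: str = "csv", strict: bool = True) -> LoadResult:
    path = Path(path)
    result = LoadResult(records=[])
    if format == "csv":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            _check_header(
                reader.fieldnames or [],
                ["block_id", "tract_id", "latitude", "longitude", "population"],
                f"blocks file {path.name}",
            )
            for row in reader:
                try:
                    result.records.append(
                        _block_from_props(
                            row["block_id"], row["tract_id"],
                            row["latitude"], row["longitude"], row["population"],
                        )
                    )
                except (ValidationError, ValueError) as exc:
                    result.rejected.append((str(row.get("block_id")), str(exc)))
    elif format == "geojson":
        fc = json.loads(path.read_text())
        for feat in fc["features"]:
            props = feat["properties"]
            lon, lat = feat["geometry"]["coordinates"]
            try:
                result.records.append(
                    _block_from_props(
                        props["block_id"], props["tract_id"], lat, lon,
                        props["population"],
                    )
                )
            except (ValidationError, ValueError, KeyError) as exc:
                result.rejected.append((str(props.get("block_id")), str(exc)))
    else:
        raise SchemaError(f"unknown blocks format {format!r}")
    _check_unique([b.block_id for b in result.records], "blocks")
    return _finish(result, strict, "blocks")


def write_blocks(blocks: Sequence[Block], path, format: str = "csv") -> None:
    path = Path(path)
    if format == "csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["block_id", "tract_id", "latitude", "longitude", "population"])
            for b in blocks:
                w.writerow(
                    [b.block_id, b.tract_id, repr(b.latitude), repr(b.longitude),
                     b.population]
                )
    elif format == "geojson":
        feats = [
            {
                "type": "Feature",
                "geometry": {
                    "type": "Point",
                    "coordinates": [b.longitude, b.latitude],
                },
                "properties": {
                    "block_id": b.block_id,
                    "tract_id": b.tract_id,
                    "population": b.population,
                },
            }
            for b in blocks
        ]
        path.write_text(
            json.dumps({"type": "FeatureCollection", "features": feats})
        )
    else:
        raise SchemaError(f"unknown blocks format {format!r}")


# ---------------------------------------------------------------- tracts

def _tract_from_row(row: dict, demo_cols: Sequence[str]) -> Tract:
    demographics = {}
    for col in demo_cols:
        val = _opt_float(row.get(col))
        if val is not None:
            demographics[col[len("demo_"):]] = val
    return Tract(
        tract_id=str(row["tract_id"]),
        state=str(row["state"]),
        land_area=float(row["land_area_sqmi"]),
        population=int(row["population"]),
        median_income=_opt_float(row["median_income"]),
        prop_below_fpl=_opt_float(row["prop_below_fpl"]),
        car_owner_count=_opt_int(row["car_owner_count"]),
        demographics=demographics,
    )


def read_tracts(path, format: str = "csv", strict: bool = True) -> LoadResult:
    path = Path(path)
    result = LoadResult(records=[])
    if format == "csv":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            cols = reader.fieldnames or []
            _check_header(cols, _TRACT_BASE_COLS, f"tracts file {path.name}")
            demo_cols = [c for c in cols if c.startswith("demo_")]
            for row in reader:
                try:
                    result.records.append(_tract_from_row(row, demo_cols))
                except (ValidationError, ValueError) as exc:
                    result.rejected.append((str(row.get("tract_id")), str(exc)))
    elif format == "geojson":
        fc = json.loads(path.read_text())
        for feat in fc["features"]:
            props = dict(feat["properties"])
            demo_cols = [c for c in props if c.startswith("demo_")]
            try:
                result.records.append(_tract_from_row(props, demo_cols))
            except (ValidationError, ValueError, KeyError) as exc:
                result.rejected.append((str(props.get("tract_id")), str(exc)))
    else:
        raise SchemaError(f"unknown tracts format {format!r}")
    _check_unique([t.tract_id for t in result.records], "tracts")
    return _finish(result, strict, "tracts")


def write_tracts(tracts: Sequence[Tract], path, format: str = "csv") -> None:
    path = Path(path)
    demo_names = sorted({name for t in tracts for name in t.demographics})
    if format != "csv":
        raise SchemaError(f"unknown tracts format {format!r}")
    cols = _TRACT_BASE_COLS + [f"demo_{n}" for n in demo_names]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(cols)
        for t in tracts:
            row = [
                t.tract_id, t.state, repr(t.land_area), t.population,
                "" if t.median_income is None else repr(t.median_income),
                "" if t.prop_below_fpl is None else repr(t.prop_below_fpl),
                "" if t.car_owner_count is None else t.car_owner_count,
            ]
            for n in demo_names:
                v = t.demographics.get(n)
                row.append("" if v is None else repr(v))
            w.writerow(row)


def validate_tract_populations(
    tracts: Sequence[Tract], blocks: Sequence[Block]
) -> list[str]:
    """Consistency check: each tract's population must equal the sum of
    its blocks'.  Returns human-readable warnings (empty when
    consistent); tracts with population > 0 but no blocks on file are
    flagged explicitly rather than guessed at."""
    by_tract: dict[str, int] = {}
    counts: dict[str, int] = {}
    for b in blocks:
        by_tract[b.tract_id] = by_tract.get(b.tract_id, 0) + b.population
        counts[b.tract_id] = counts.get(b.tract_id, 0) + 1
    warnings = []
    for t in tracts:
        if counts.get(t.tract_id, 0) == 0 and t.population > 0:
            warnings.append(
                f"tract {t.tract_id}: population {t.population} but no blocks on file"
            )
        elif by_tract.get(t.tract_id, 0) != t.population:
            warnings.append(
                f"tract {t.tract_id}: population {t.population} != block sum "
                f"{by_tract.get(t.tract_id, 0)}"
            )
    return warnings


# ------------------------------------------------------------ pharmacies

def _pharmacy_from_row(row: dict) -> Pharmacy:
    raw = str(row["ownership"]).strip().lower()
    try:
        ownership = Ownership(raw)
    except ValueError:
        raise ValidationError(
            f"pharmacy {row.get('pharmacy_id')}: unknown ownership {row['ownership']!r}"
        )
    services = {}
    for flag in SERVICE_FLAGS:
        services[flag] = _opt_bool(row.get(f"svc_{flag}"))
    tid = row.get("tract_id")
    return Pharmacy(
        pharmacy_id=str(row["pharmacy_id"]),
        latitude=float(row["latitude"]),
        longitude=float(row["longitude"]),
        ownership=ownership,
        services=services,
        tract_id=None if tid in (None, "") else str(tid),
    )


def read_pharmacies(path, format: str = "csv", strict: bool = True) -> LoadResult:
    path = Path(path)
    result = LoadResult(records=[])
    if format == "csv":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            _check_header(
                reader.fieldnames or [],
                ["pharmacy_id", "latitude", "longitude", "ownership"],
                f"pharmacies file {path.name}",
            )
            for row in reader:
                try:
                    result.records.append(_pharmacy_from_row(row))
                except (ValidationError, ValueError) as exc:
                    result.rejected.append((str(row.get("pharmacy_id")), str(exc)))
    elif format == "geojson":
        fc = json.loads(path.read_text())
        for feat in fc["features"]:
            props = dict(feat["properties"])
            lon, lat = feat["geometry"]["coordinates"]
            props["latitude"], props["longitude"] = lat, lon
            try:
                result.records.append(_pharmacy_from_row(props))
            except (ValidationError, ValueError, KeyError) as exc:
                result.rejected.append((str(props.get("pharmacy_id")), str(exc)))
    else:
        raise SchemaError(f"unknown pharmacies format {format!r}")
    _check_unique([p.pharmacy_id for p in result.records], "pharmacies")
    return _finish(result, strict, "pharmacies")


def write_pharmacies(pharmacies: Sequence[Pharmacy], path, format: str = "csv") -> None:
    path = Path(path)
    if format != "csv":
        raise SchemaError(f"unknown pharmacies format {format!r}")
    cols = ["pharmacy_id", "latitude", "longitude", "ownership", "tract_id"] + [
        f"svc_{f}" for f in SERVICE_FLAGS
    ]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(cols)
        for p in pharmacies:
            row = [
                p.pharmacy_id, repr(p.latitude), repr(p.longitude),
                p.ownership.value, p.tract_id or "",
            ]
            for f in SERVICE_FLAGS:
                v = p.services.get(f)
                row.append("" if v is None else ("true" if v else "false"))
            w.writerow(row)


# ---------------------------------------------------------------- metros

def read_metros(path, strict: bool = True) -> LoadResult:
    path = Path(path)
    result = LoadResult(records=[])
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        _check_header(
            reader.fieldnames or [],
            ["metro_id", "latitude", "longitude", "median_income"],
            f"metros file {path.name}",
        )
        for row in reader:
            try:
                result.records.append(
                    MetroArea(
                        metro_id=str(row["metro_id"]),
                        latitude=float(row["latitude"]),
                        longitude=float(row["longitude"]),
                        median_income=float(row["median_income"]),
                    )
                )
            except (ValidationError, ValueError) as exc:
                result.rejected.append((str(row.get("metro_id")), str(exc)))
    _check_unique([m.metro_id for m in result.records], "metros")
    return _finish(result, strict, "metros")


def write_metros(metros: Sequence[MetroArea], path) -> None:
    with open(Path(path), "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["metro_id", "latitude", "longitude", "median_income"])
        for m in metros:
            w.writerow([m.metro_id, repr(m.latitude), repr(m.longitude),
                        repr(m.median_income)])


# ------------------------------------------------------------- choropleth

def write_classification_geojson(
    classifications,
    tracts: Sequence[Tract],
    path,
    blocks: Optional[Sequence[Block]] = None,
    geometries: Optional[dict] = None,
) -> None:
    """Map-ready FeatureCollection: one feature per classified tract.

    Geometry comes from ``geometries`` (tract_id -> GeoJSON geometry,
    e.g. polygons loaded from a boundary file) when provided; otherwise a
    Point at the tract's population-weighted block centroid; otherwise
    null geometry.  Properties carry the verdict and the intermediate
    indicators behind it.
    """
    from .classify import tract_reference_point  # local import avoids a cycle

    known = {t.tract_id: t for t in tracts}
    blocks_by_tract: dict[str, list[Block]] = {}
    for b in blocks or []:
        blocks_by_tract.setdefault(b.tract_id, []).append(b)

    features = []
    for c in classifications:
        if c.tract_id not in known:
            raise ValidationError(
                f"classification references unknown tract {c.tract_id!r}"
            )
        geometry = None
        if geometries and c.tract_id in geometries:
            geometry = geometries[c.tract_id]
        elif blocks_by_tract.get(c.tract_id):
            lat, lon = tract_reference_point(
                known[c.tract_id], blocks_by_tract[c.tract_id]
            )
            geometry = {"type": "Point", "coordinates": [lon, lat]}
        features.append(
            {
                "type": "Feature",
                "geometry": geometry,
                "properties": {
                    "tract_id": c.tract_id,
                    "verdict": c.verdict.value,
                    "urbanicity": c.urbanicity.value if c.urbanicity else None,
                    "prop_outside_radius": c.prop_outside,
                    "low_income": c.low_income,
                    "low_access": c.low_access,
                },
            }
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
    )
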