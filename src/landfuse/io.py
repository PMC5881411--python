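"""File formats: GeoTIFF rasters, point CSVs, conditional-table dumps.

Rasters are single-band GeoTIFFs in geographic WGS84 with the standard
GeoTIFF tags (ModelPixelScale, ModelTiepoint, a GeoKeyDirectory declaring
EPSG:4326 and the GDAL nodata tag), written and parsed with ``tifffile``.
Categorical rasters are integer-typed, continuous ones floating; whether a
file is categorical is declared by the caller (config), never guessed from
the pixel type.

Point tables use the published validation-CSV dialect: comma-separated,
UTF-8, header ``Id,Lat,Lon,Class_id,Class_name``.
"""
from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .fusion import ConditionalTable, ConditionalTableSet, NOT_SURE, ReferencePoint
from .grid import ARCSEC_PER_DEGREE, GridSpec
from .raster import CategoricalRaster, ContinuousRaster
from .validation import CLASS_ID_NAMES, VALID_CLASS_IDS, ValidationRecord

TAG_MODEL_PIXEL_SCALE = 33550
TAG_MODEL_TIEPOINT = 33922
TAG_GEO_KEY_DIRECTORY = 34735
TAG_GDAL_NODATA = 42113

# GeoKeyDirectory: v1.1.0, 3 keys: geographic model, PixelIsArea, EPSG:4326
_GEOKEYS = (1, 1, 0, 3, 1024, 0, 1, 2, 1025, 0, 1, 1, 2048, 0, 1, 4326)


class RasterFormatError(ValueError):
    """A raster file violates the single-band GeoTIFF contract."""


def write_raster(path, raster) -> None:
    """Write a raster as a single-band WGS84 GeoTIFF with declared nodata."""
    grid = raster.grid
    step = grid.step
    if isinstance(raster, CategoricalRaster):
        data = raster.codes.astype(np.int32)
        nodata = raster.nodata_code
    else:
        data = raster.values.astype(np.float64)
        nodata = raster.nodata_value
    extratags = [
        (TAG_MODEL_PIXEL_SCALE, 12, 3, (step, step, 0.0)),
        (TAG_MODEL_TIEPOINT, 12, 6, (0.0, 0.0, 0.0, grid.origin_lon, grid.origin_lat, 0.0)),
        (TAG_GEO_KEY_DIRECTORY, 3, len(_GEOKEYS), _GEOKEYS),
        (TAG_GDAL_NODATA, 2, None, str(nodata).encode() + b"\x00"),
    ]
    tifffile.imwrite(str(path), data, extratags=extratags)


def _read_geotiff(path):
    with tifffile.TiffFile(str(path)) as tf:
        if len(tf.pages) != 1:
            raise RasterFormatError(f"{path}: expected a single-band GeoTIFF")
        page = tf.pages[0]
        data = page.asarray()
        if data.ndim != 2:
            raise RasterFormatError(f"{path}: expected a single 2-D band")
        tags = page.tags
        if TAG_MODEL_PIXEL_SCALE not in tags or TAG_MODEL_TIEPOINT not in tags:
            raise RasterFormatError(f"{path}: missing GeoTIFF georeferencing tags")
        sx, sy = tags[TAG_MODEL_PIXEL_SCALE].value[:2]
        tp = tags[TAG_MODEL_TIEPOINT].value
        origin_lon = tp[3] - tp[0] * sx
        origin_lat = tp[4] + tp[1] * sy
        if abs(sx - sy) > 1e-12:
            raise RasterFormatError(f"{path}: anisotropic cells are not supported")
        nodata = None
        if TAG_GDAL_NODATA in tags:
            nodata = tags[TAG_GDAL_NODATA].value
            if isinstance(nodata, bytes):
                nodata = nodata.decode()
            nodata = float(str(nodata).rstrip("\x00"))
    grid = GridSpec(sx * ARCSEC_PER_DEGREE, origin_lon, origin_lat, *data.shape)
    return grid, data, nodata


def read_categorical(path, alphabet, legend_id="", nodata_code=None) -> CategoricalRaster:
    """Read a categorical GeoTIFF; the alphabet comes from config, and codes
    outside it raise a legend error."""
    grid, data, nodata = _read_geotiff(path)
    if nodata is None and nodata_code is None:
        raise RasterFormatError(
            f"{path}: no nodata declared in the file; set nodata_code in the config"
        )
    nodata_code = int(nodata) if nodata_code is None else int(nodata_code)
    return CategoricalRaster(
        grid, data.astype(np.int64), nodata_code, tuple(alphabet), legend_id
    )


def read_continuous(path, nodata_value=None) -> ContinuousRaster:
    """Read a continuous (percentage) GeoTIFF."""
    grid, data, nodata = _read_geotiff(path)
    if nodata is None and nodata_value is None:
        raise RasterFormatError(
            f"{path}: no nodata declared in the file; set nodata_value in the config"
        )
    nodata_value = float(nodata) if nodata_value is None else float(nodata_value)
    return ContinuousRaster(grid, data.astype(float), nodata_value)


def write_posterior(path_probs, path_flags, posterior) -> None:
    """Posterior as a 3-band float GeoTIFF plus a 1-band flag mask."""
    grid = posterior.grid
    step = grid.step
    extratags = [
        (TAG_MODEL_PIXEL_SCALE, 12, 3, (step, step, 0.0)),
        (TAG_MODEL_TIEPOINT, 12, 6, (0.0, 0.0, 0.0, grid.origin_lon, grid.origin_lat, 0.0)),
        (TAG_GEO_KEY_DIRECTORY, 3, len(_GEOKEYS), _GEOKEYS),
    ]
    tifffile.imwrite(
        str(path_probs),
        posterior.probs.astype(np.float64),
        photometric="minisblack",
        extratags=extratags,
    )
    flags = (posterior.degenerate.astype(np.uint8) + 2 * (~posterior.valid)).astype(np.uint8)
    tifffile.imwrite(str(path_flags), flags, extratags=extratags)


# -- point CSVs -------------------------------------------------------------

_HEADER = ["Id", "Lat", "Lon", "Class_id", "Class_name"]


def read_validation_csv(path) -> list[ValidationRecord]:
    """Parse a validation CSV (``Id,Lat,Lon,Class_id,Class_name``).

    Unknown Class_id values raise with the offending line number.
    """
    df = pd.read_csv(path)
    missing = [c for c in _HEADER[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}; expected {_HEADER}")
    records = []
    for pos, row in enumerate(df.itertuples(index=False), start=2):
        cid = int(row.Class_id)
        if cid not in VALID_CLASS_IDS:
            raise ValueError(
                f"{path}:{pos}: Class_id {cid} not in {VALID_CLASS_IDS}"
            )
        records.append(
            ValidationRecord(
                id=int(row.Id),
                lat=float(row.Lat),
                lon=float(row.Lon),
                class_id=cid,
                class_name=str(getattr(row, "Class_name", CLASS_ID_NAMES[cid])),
            )
        )
    return records


def write_validation_csv(path, records) -> None:
    pd.DataFrame(
        {
            "Id": [r.id for r in records],
            "Lat": [r.lat for r in records],
            "Lon": [r.lon for r in records],
            "Class_id": [r.class_id for r in records],
            "Class_name": [r.class_name or CLASS_ID_NAMES[r.class_id] for r in records],
        }
    ).to_csv(path, index=False)


def read_reference_csv(path, not_sure_sentinel: int = NOT_SURE) -> list[ReferencePoint]:
    """Reference (training) points; same dialect, Class_id in {1,2,3} or the
    not-sure sentinel (default 0)."""
    df = pd.read_csv(path)
    missing = [c for c in _HEADER[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}; expected {_HEADER}")
    points = []
    for pos, row in enumerate(df.itertuples(index=False), start=2):
        cid = int(row.Class_id)
        if cid not in (1, 2, 3, not_sure_sentinel):
            raise ValueError(
                f"{path}:{pos}: Class_id {cid} not in (1, 2, 3, {not_sure_sentinel})"
            )
        label = NOT_SURE if cid == not_sure_sentinel else cid
        points.append(
            ReferencePoint(id=int(row.Id), lon=float(row.Lon), lat=float(row.Lat), label=label)
        )
    return points


def write_reference_csv(path, points) -> None:
    names = {1: "arable land", 2: "abandoned land", 3: "other land", NOT_SURE: "not sure"}
    pd.DataFrame(
        {
            "Id": [p.id for p in points],
            "Lat": [p.lat for p in points],
            "Lon": [p.lon for p in points],
            "Class_id": [p.label for p in points],
            "Class_name": [names[p.label] for p in points],
        }
    ).to_csv(path, index=False)


# -- conditional tables ------------------------------------------------------

def write_conditional_tables(path, tables: ConditionalTableSet) -> None:
    """Human-readable YAML dump of all conditional tables with support counts."""
    doc = {
        "sources": list(tables.source_names),
        "alphabets": [list(a) for a in tables.alphabets],
        "strata": {},
        "pooled": [],
    }
    for e in tables.strata:
        doc["strata"][int(e)] = [
            {
                "source": tables.source_names[k],
                "pooled_fallback": bool(t.pooled_fallback),
                "probabilities": [[float(x) for x in row] for row in t.probs],
                "support": [[float(x) for x in row] for row in t.support],
            }
            for k, t in enumerate(tables.for_stratum(e))
        ]
    for k, t in enumerate(tables.pooled):
        doc["pooled"].append(
            {
                "source": tables.source_names[k],
                "probabilities": [[float(x) for x in row] for row in t.probs],
                "support": [[float(x) for x in row] for row in t.support],
            }
        )
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_conditional_tables(path) -> ConditionalTableSet:
    doc = yaml.safe_load(Path(path).read_text())
    alphabets = [tuple(a) for a in doc["alphabets"]]
    tables = {}
    for e, entries in doc["strata"].items():
        tables[int(e)] = [
            ConditionalTable(
                alphabets[k],
                np.array(entry["probabilities"]),
                np.array(entry["support"]),
                pooled_fallback=entry.get("pooled_fallback", False),
            )
            for k, entry in enumerate(entries)
        ]
    pooled = [
        ConditionalTable(
            alphabets[k], np.array(entry["probabilities"]), np.array(entry["support"])
        )
        for k, entry in enumerate(doc.get("pooled", []))
    ]
    return ConditionalTableSet(list(doc["sources"]), alphabets, tables, pooled)
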