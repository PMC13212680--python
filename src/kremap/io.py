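"""File formats: ESRI ASCII grids, GeoJSON block groups, patient CSV.

All interchange formats are plain text: ESRI ASCII grid (.asc) for rasters,
GeoJSON for polygons, CSV for tables.  Rasters written and read here always
share one GridSpec per run; a mismatch on read is a hard error upstream.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping, shape

from .grid import GridSpec

__all__ = [
    "write_asc",
    "read_asc",
    "write_block_groups_geojson",
    "read_block_groups_geojson",
    "PATIENT_CSV_COLUMNS",
    "write_patients_csv",
    "read_patients_csv",
]

PathLike = Union[str, Path]

#: Column order of the patient CSV contract.
PATIENT_CSV_COLUMNS = [
    "patient_id",
    "site",
    "age_group",
    "block_group_id",
    "path_stage",
    "clin_stage",
    "sex",
    "race_eth",
    "payer",
    "ruca",
    "comorbidity_count",
]


def write_asc(spec: GridSpec, values: np.ndarray, path: PathLike, nodata: float = -1.0) -> None:
    """Write a raster as an ESRI ASCII grid; NaN cells become ``nodata``."""
    values = np.asarray(values, dtype=float)
    if values.shape != spec.shape:
        raise ValueError(f"values shape {values.shape} != grid shape {spec.shape}")
    out = np.where(np.isnan(values), nodata, values)
    header = (
        f"ncols {spec.n_cols}\n"
        f"nrows {spec.n_rows}\n"
        f"xllcorner {spec.origin_x!r}\n"
        f"yllcorner {spec.origin_y!r}\n"
        f"cellsize {spec.cell_size!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for row in out:
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


def read_asc(path: PathLike, crs_label: str = "local-projected") -> tuple[GridSpec, np.ndarray]:
    """Read an ESRI ASCII grid; nodata cells come back as NaN."""
    with open(path) as fh:
        lines = fh.read().split("\n")
    header: dict[str, float] = {}
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
        }:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"malformed ASCII grid {path}: missing {key}")
    body = " ".join(lines[i:])
    values = np.array(body.split(), dtype=float) if body.strip() else np.array([])
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    if values.size != n_rows * n_cols:
        raise ValueError(
            f"malformed ASCII grid {path}: expected {n_rows * n_cols} values, got {values.size}"
        )
    values = values.reshape(n_rows, n_cols)
    nodata = header.get("nodata_value")
    if nodata is not None:
        values = np.where(values == nodata, np.nan, values)
    spec = GridSpec(
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"],
        cell_size=header["cellsize"],
        n_rows=n_rows,
        n_cols=n_cols,
        crs_label=crs_label,
    )
    return spec, values


def write_block_groups_geojson(groups, path: PathLike) -> None:
    """Write a BlockGroupSet as a GeoJSON FeatureCollection.

    Each feature carries ``id`` and ``age_fractions`` properties.
    """
    features = []
    for i, gid in enumerate(groups.ids):
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(groups.polygons[i]),
                "properties": {
                    "id": gid,
                    "age_fractions": [float(f) for f in groups.age_fractions[i]],
                },
            }
        )
    collection = {
        "type": "FeatureCollection",
        "features": features,
        "properties": {"age_group_names": list(groups.age_group_names)},
    }
    with open(path, "w") as fh:
        json.dump(collection, fh)


def read_block_groups_geojson(path: PathLike):
    """Read a BlockGroupSet written by :func:`write_block_groups_geojson`."""
    from .synthetic import BlockGroupSet

    with open(path) as fh:
        collection = json.load(fh)
    ids, polygons, fractions = [], [], []
    for feat in collection["features"]:
        ids.append(feat["properties"]["id"])
        polygons.append(shape(feat["geometry"]))
        fractions.append(feat["properties"]["age_fractions"])
    names = collection.get("properties", {}).get("age_group_names")
    if names is None:
        names = [f"age{k}" for k in range(len(fractions[0]))]
    return BlockGroupSet(
        ids=ids,
        polygons=polygons,
        age_fractions=np.asarray(fractions, dtype=float),
        age_group_names=tuple(names),
    )


def write_patients_csv(table: pd.DataFrame, path: PathLike) -> None:
    cols = [c for c in PATIENT_CSV_COLUMNS if c in table.columns]
    extra = [c for c in table.columns if c not in cols]
    table[cols + extra].to_csv(path, index=False)


def read_patients_csv(path: PathLike) -> pd.DataFrame:
    """Read a patient CSV; empty stage/location fields become 'missing'/NA."""
    df = pd.read_csv(path, dtype={"block_group_id": "string", "patient_id": "string"})
    for col in ("path_stage", "clin_stage"):
        if col in df.columns:
            df[col] = df[col].fillna("missing").astype(str)
    return df
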