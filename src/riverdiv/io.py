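"""Readers and writers for the pipeline's on-disk formats.

Tabular data are plain CSV; geometries are GeoJSON FeatureCollections
(rivers as LineStrings, reserves and grid cells as Polygons); trees are
Newick.  All writers produce deterministic output (sorted rows, fixed float
formatting) so that identical inputs yield byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from shapely.geometry import LineString, mapping, shape

from .assessment import EffectivenessReport, ReserveLayer
from .correlation import CorrelationMatrix
from .errors import InvalidInputError
from .grid import CellSet, GridSpec, RiverNetwork, make_catalog, make_occurrence_table
from .hotspots import HotspotSet
from .metrics import CellValueTable

__all__ = [
    "write_occurrences", "read_occurrences",
    "write_catalog", "read_catalog",
    "write_rivers_geojson", "read_rivers_geojson",
    "write_reserves_geojson", "read_reserves_geojson",
    "write_cells_geojson",
    "write_presence_matrix", "read_presence_matrix",
    "write_indicator", "read_indicator", "write_indicators_wide",
    "write_cleaning_log", "write_hotspots_geojson",
    "write_effectiveness_report", "write_correlation",
]


def write_occurrences(df: pd.DataFrame, path: str | Path) -> None:
    df = make_occurrence_table(df)
    cols = ["species", "x", "y", "locality_ok", "river_id"]
    df[cols].to_csv(path, index=False, float_format="%.6f")


def read_occurrences(path: str | Path) -> pd.DataFrame:
    return make_occurrence_table(pd.read_csv(path))


def write_catalog(catalog: pd.DataFrame, path: str | Path) -> None:
    out = catalog.copy()
    out.index.name = "species"
    out.sort_index().to_csv(path)


def read_catalog(path: str | Path) -> pd.DataFrame:
    return make_catalog(pd.read_csv(path))


def _feature_collection(features: list[dict]) -> dict:
    return {"type": "FeatureCollection", "features": features}


def _dump_geojson(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def write_rivers_geojson(rivers: RiverNetwork, path: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"river_id": rid},
            "geometry": mapping(line),
        }
        for rid, line in rivers.rivers
    ]
    _dump_geojson(_feature_collection(features), path)


def read_rivers_geojson(path: str | Path) -> RiverNetwork:
    data = json.loads(Path(path).read_text())
    rivers = []
    for i, feat in enumerate(data.get("features", [])):
        geom = shape(feat["geometry"])
        if not isinstance(geom, LineString):
            raise InvalidInputError("river features must be LineStrings")
        rid = feat.get("properties", {}).get("river_id", f"river_{i + 1}")
        rivers.append((rid, geom))
    return RiverNetwork(rivers=tuple(rivers))


def write_reserves_geojson(reserves: ReserveLayer, path: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"id": rid, "tier": tier},
            "geometry": mapping(geom),
        }
        for rid, tier, geom in reserves.polygons
    ]
    _dump_geojson(_feature_collection(features), path)


def read_reserves_geojson(path: str | Path) -> ReserveLayer:
    data = json.loads(Path(path).read_text())
    polys = []
    for i, feat in enumerate(data.get("features", [])):
        props = feat.get("properties", {})
        polys.append(
            (
                props.get("id", f"res_{i + 1:03d}"),
                props.get("tier", "provincial"),
                shape(feat["geometry"]),
            )
        )
    return ReserveLayer(polygons=tuple(polys))


def write_cells_geojson(cells: CellSet, path: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"cell_id": int(cid)},
            "geometry": mapping(cells.grid.cell_polygon(cid)),
        }
        for cid in cells.cell_ids
    ]
    _dump_geojson(_feature_collection(features), path)


def write_presence_matrix(matrix, path: str | Path) -> None:
    """Sparse triplet CSV: cell_id, species, 1 (one row per presence)."""
    rows = []
    for i, cid in enumerate(matrix.cell_ids):
        for j, sp in enumerate(matrix.species):
            if matrix.incidence[i, j]:
                rows.append((int(cid), sp, 1))
    pd.DataFrame(rows, columns=["cell_id", "species", "presence"]).to_csv(
        path, index=False
    )


def read_presence_matrix(path: str | Path, grid: GridSpec):
    """Rebuild a PresenceMatrix from a sparse triplet CSV and its grid."""
    from .grid import PresenceMatrix  # deferred: avoid cycle at import time

    df = pd.read_csv(path)
    cell_ids = sorted(df["cell_id"].unique())
    species = sorted(df["species"].unique())
    cells = CellSet(grid, tuple(int(c) for c in cell_ids))
    ci = {c: i for i, c in enumerate(cells.cell_ids)}
    sj = {s: j for j, s in enumerate(species)}
    import numpy as np

    inc = np.zeros((len(cells), len(species)), dtype=bool)
    for cid, sp in zip(df["cell_id"], df["species"]):
        inc[ci[int(cid)], sj[sp]] = True
    return PresenceMatrix(cells=cells, species=species, incidence=inc)


def write_indicator(table: CellValueTable, path: str | Path) -> None:
    s = table.as_series()
    s.index.name = "cell_id"
    s.rename("value").to_csv(path, float_format="%.9g")


def read_indicator(path: str | Path, name: str | None = None) -> CellValueTable:
    df = pd.read_csv(path)
    return CellValueTable(
        name=name or Path(path).stem,
        values={int(c): float(v) for c, v in zip(df["cell_id"], df["value"])},
    )


def write_indicators_wide(
    tables: Iterable[CellValueTable], path: str | Path
) -> None:
    """Merged wide CSV: one row per cell, one column per indicator."""
    frame = pd.DataFrame(
        {t.name: t.as_series() for t in tables}
    ).fillna(0.0)
    frame.index.name = "cell_id"
    frame.sort_index().to_csv(path, float_format="%.9g")


def write_cleaning_log(log: Mapping[str, int], path: str | Path) -> None:
    pd.Series(dict(log), name="dropped").rename_axis("rule").to_csv(path)


def write_hotspots_geojson(
    hotspots: HotspotSet, cells: CellSet, path: str | Path
) -> None:
    """Hotspot cells with combined score and per-indicator membership flags."""
    features = []
    for cid in sorted(hotspots.combined):
        props = {
            "cell_id": int(cid),
            "combined_score": round(hotspots.combined_scores.get(cid, 0.0), 9),
        }
        for name, sel in sorted(hotspots.per_indicator.items()):
            props[f"in_{name}"] = cid in sel
        features.append(
            {
                "type": "Feature",
                "properties": props,
                "geometry": mapping(cells.grid.cell_polygon(cid)),
            }
        )
    _dump_geojson(_feature_collection(features), path)


def write_effectiveness_report(
    report: EffectivenessReport, path: str | Path, digits: int = 1
) -> None:
    """Long-format CSV: stratum, class, count, percentage."""
    pct = report.percentages(digits=digits)
    rows = []
    for stratum in report.table.index:
        for cls in report.table.columns:
            rows.append(
                (
                    stratum,
                    cls,
                    int(report.table.at[stratum, cls]),
                    pct.at[stratum, cls] if stratum in pct.index else "",
                )
            )
    pd.DataFrame(
        rows, columns=["stratum", "class", "count", "percent_of_denominator"]
    ).to_csv(path, index=False)


def write_correlation(corr: CorrelationMatrix, out_dir: str | Path) -> None:
    out = Path(out_dir)
    corr.r.rename_axis("indicator").to_csv(out / "correlation_r.csv", float_format="%.9g")
    corr.to_long().to_csv(out / "correlation_pairs.csv", index=False, float_format="%.9g")
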