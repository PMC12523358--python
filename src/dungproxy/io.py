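"""Readers and writers for the pipeline's file formats.

Everything is plain text: vector geometry as GeoJSON (coordinates in
metres of the declared local CRS), tables as UTF-8 comma-separated CSV
with a header row and '.' decimals, and rasters as ESRI ASCII grid
(nodata -1) with a JSON sidecar recording period, bandwidth, adjustment
factor and cell size.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import mapping, shape

from .geometry import PastureGeometry
from .kde import GridSpec, GrazingIntensityRaster, HerdSnapshot

NODATA = -1.0


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


# ---------------------------------------------------------------- rasters

def write_ascii_grid(raster: GrazingIntensityRaster, path) -> None:
    """ESRI ASCII grid (rows north to south) plus a JSON metadata sidecar."""
    path = Path(path)
    g = raster.grid
    header = (f"ncols {g.n_cols}\nnrows {g.n_rows}\n"
              f"xllcorner {g.x0!r}\nyllcorner {g.y0!r}\n"
              f"cellsize {g.cell_size_m!r}\nNODATA_value {NODATA}\n")
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, raster.values[::-1], fmt="%.10g")
    meta = {"period": raster.period, **raster.metadata}
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta))


def read_ascii_grid(path) -> GrazingIntensityRaster:
    path = Path(path)
    with open(path) as fh:
        header = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    values = np.atleast_2d(values)[::-1]
    grid = GridSpec(x0=header["xllcorner"], y0=header["yllcorner"],
                    cell_size_m=header["cellsize"],
                    n_rows=int(header["nrows"]), n_cols=int(header["ncols"]))
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    period = meta.pop("period", "")
    return GrazingIntensityRaster(grid=grid, values=np.clip(values, 0, None),
                                  period=period, metadata=meta)


# ----------------------------------------------------------------- tables

SNAPSHOT_COLUMNS = ["month", "day", "hour", "yak_id", "x_m", "y_m"]


def snapshots_to_frame(snapshots: list[HerdSnapshot]) -> pd.DataFrame:
    rows = []
    for s in snapshots:
        for yak_id, (x, y) in enumerate(s.positions):
            rows.append((s.month, s.day, s.hour, yak_id, x, y))
    return pd.DataFrame(rows, columns=SNAPSHOT_COLUMNS)


def frame_to_snapshots(df: pd.DataFrame) -> list[HerdSnapshot]:
    out = []
    for (month, day, hour), grp in df.groupby(["month", "day", "hour"], sort=True):
        pos = grp.sort_values("yak_id")[["x_m", "y_m"]].to_numpy()
        out.append(HerdSnapshot(month=int(month), day=int(day),
                                hour=int(hour), positions=pos))
    return out


def write_snapshots_csv(snapshots: list[HerdSnapshot], path) -> None:
    snapshots_to_frame(snapshots).to_csv(path, index=False)


def read_snapshots_csv(path) -> list[HerdSnapshot]:
    return frame_to_snapshots(pd.read_csv(path))


# --------------------------------------------------------------- GeoJSON

def write_pasture_geojson(pasture: PastureGeometry, path) -> None:
    features = [
        {"type": "Feature", "geometry": mapping(pasture.boundary),
         "properties": {"role": "boundary",
                        "fence_buffer_m": pasture.fence_buffer_m}},
        {"type": "Feature", "geometry": mapping(pasture.campsite),
         "properties": {"role": "campsite",
                        "campsite_buffer_m": pasture.campsite_buffer_m}},
    ]
    if pasture.riverbed is not None:
        features.append({"type": "Feature", "geometry": mapping(pasture.riverbed),
                         "properties": {"role": "riverbed"}})
    doc = {"type": "FeatureCollection",
           "crs_note": "local planar metres, origin at pasture bbox SW corner",
           "features": features}
    Path(path).write_text(json.dumps(doc))


def read_pasture_geojson(path) -> PastureGeometry:
    doc = json.loads(Path(path).read_text())
    boundary = campsite = riverbed = None
    fence, camp_buf = 50.0, 150.0
    for feat in doc["features"]:
        role = feat["properties"].get("role")
        geom = shape(feat["geometry"])
        if role == "boundary":
            boundary = geom
            fence = feat["properties"].get("fence_buffer_m", fence)
        elif role == "campsite":
            campsite = geom
            camp_buf = feat["properties"].get("campsite_buffer_m", camp_buf)
        elif role == "riverbed":
            riverbed = geom
    if boundary is None or campsite is None:
        raise ValueError("GeoJSON must contain boundary and campsite features")
    return PastureGeometry(boundary=boundary, campsite=campsite,
                           riverbed=riverbed, fence_buffer_m=fence,
                           campsite_buffer_m=camp_buf)


# ----------------------------------------------------------- study bundle

def save_study_dataset(dataset, outdir) -> list[str]:
    """Serialise a StudyDataset as a directory of text files.

    Writes one dung-count table per month, the pooled snapshot and pat
    tables, waypoint table, monthly estimate and truth rasters, pasture
    GeoJSON, a config echo, and an append-only run log with file digests.
    """
    from .kde import month_label

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    def _note(p):
        written.append(str(p))

    for month in sorted(dataset.monthly_estimate):
        name = month_label(month)
        sub = dataset.counts[dataset.counts.month == month]
        p = outdir / f"counts_{name}.csv"
        sub.to_csv(p, index=False)
        _note(p)
        for tag, store in (("estimate", dataset.monthly_estimate),
                           ("truth", dataset.monthly_truth)):
            p = outdir / f"intensity_{tag}_{name}.asc"
            write_ascii_grid(store[month], p)
            _note(p)

    all_snaps = [s for month in sorted(dataset.snapshots)
                 for s in dataset.snapshots[month]]
    p = outdir / "snapshots.csv"
    write_snapshots_csv(all_snaps, p)
    _note(p)

    p = outdir / "pats.csv"
    dataset.pats.to_csv(p, index=False)
    _note(p)

    p = outdir / "waypoints.csv"
    dataset.waypoints.to_csv(p, index=False)
    _note(p)

    p = outdir / "pasture.geojson"
    write_pasture_geojson(dataset.pasture, p)
    _note(p)

    p = outdir / "config.yaml"
    p.write_text(yaml.safe_dump(dataset.config.model_dump(mode="json")))
    _note(p)

    from datetime import datetime, timezone
    stamp = datetime.now(timezone.utc).isoformat()
    log = list(dataset.log) + [{"event": "saved", "file": f,
                                "sha256": file_digest(f)} for f in written]
    logp = outdir / "run_log.jsonl"
    with open(logp, "w") as fh:
        for entry in log:
            fh.write(json.dumps({"time": stamp, **entry}) + "\n")
    written.append(str(logp))
    return written
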