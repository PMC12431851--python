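"""File I/O for all pipeline artefacts.

Schemas (units fixed across the package: µm, seconds, pascals, degrees):

* tracks: CSV ``track_id,t_s,x_um,y_um``;
* force curves: two-column CSV ``indentation_m,force_N`` per grid point,
  named ``r<row>_c<col>.csv`` in a batch directory with one ``probe.json``
  sidecar (tip radius, Poisson ratio, spring constant, grid pitch);
* stiffness maps: float32 TIFF in Pa plus a JSON sidecar (pitch, origin,
  provenance), or a plain TSV matrix with the same sidecar;
* flux tables: CSV ``animal_id,site,photon_flux``;
* fibres: CSV ``fiber_id,point_index,x_um,y_um[,width_um]``;
* patterns: JSON documents (moduli in Pa, widths in µm).

Readers validate and report violations with row/field context; every writer
round-trips exactly through its reader.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from . import tumor
from .afm import ForceCurve, StiffnessMap
from .exceptions import SchemaError
from .migration import Track
from .substrates import SubstratePattern
from .tumor import FiberPolyline

# --------------------------------------------------------------- tracks CSV

TRACK_COLUMNS = ["track_id", "t_s", "x_um", "y_um"]


def write_tracks(tracks, path):
    rows = []
    for tr in tracks:
        for t, x, y in zip(tr.t, tr.x, tr.y):
            rows.append({"track_id": tr.track_id, "t_s": t, "x_um": x, "y_um": y})
    pd.DataFrame(rows, columns=TRACK_COLUMNS).to_csv(path, index=False)


def read_tracks(path):
    df = pd.read_csv(path)
    missing = set(TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    tracks = []
    for tid, sub in df.groupby("track_id", sort=False):
        sub = sub.reset_index()
        t = sub["t_s"].to_numpy(dtype=float)
        dup = np.flatnonzero(np.diff(t) == 0)
        if dup.size:
            raise SchemaError(f"{path}: track {tid!r} row {int(sub['index'][dup[0] + 1]) + 2}: "
                              "duplicated timestamp")
        if np.any(np.diff(t) < 0):
            row = int(sub["index"][int(np.flatnonzero(np.diff(t) < 0)[0]) + 1]) + 2
            raise SchemaError(f"{path}: track {tid!r} row {row}: time not increasing")
        if len(t) < 2:
            raise SchemaError(f"{path}: track {tid!r}: fewer than 2 points")
        tracks.append(Track(str(tid), t, sub["x_um"].to_numpy(dtype=float),
                            sub["y_um"].to_numpy(dtype=float)))
    return tracks


# -------------------------------------------------------------- force curves

def write_force_curves(curves, directory, pitch_um=None):
    """One ``r<row>_c<col>.csv`` per curve plus a ``probe.json`` sidecar.

    Curves without positions are written as ``curve<i>.csv``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    first = curves[0]
    sidecar = {"tip_radius_m": first.tip_radius, "poisson": first.poisson,
               "spring_constant_N_per_m": first.spring_constant}
    if pitch_um is not None:
        sidecar["pitch_um"] = pitch_um
    (directory / "probe.json").write_text(json.dumps(sidecar, indent=1))
    for i, c in enumerate(curves):
        if c.position is not None and pitch_um:
            col = int(round(c.position[0] / pitch_um))
            row = int(round(c.position[1] / pitch_um))
            name = f"r{row:03d}_c{col:03d}.csv"
        else:
            name = f"curve{i:04d}.csv"
        pd.DataFrame({"indentation_m": c.indentation,
                      "force_N": c.force}).to_csv(directory / name, index=False)


def read_force_curves(directory):
    directory = Path(directory)
    sidecar_path = directory / "probe.json"
    if not sidecar_path.exists():
        raise SchemaError(f"{directory}: missing probe.json sidecar")
    side = json.loads(sidecar_path.read_text())
    pitch = side.get("pitch_um")
    curves = []
    for f in sorted(directory.glob("*.csv")):
        df = pd.read_csv(f)
        missing = {"indentation_m", "force_N"} - set(df.columns)
        if missing:
            raise SchemaError(f"{f}: missing columns {sorted(missing)}")
        pos = None
        m = re.match(r"r(\d+)_c(\d+)\.csv$", f.name)
        if m and pitch:
            pos = (int(m.group(2)) * pitch, int(m.group(1)) * pitch)
        try:
            curves.append(ForceCurve(df["indentation_m"].to_numpy(dtype=float),
                                     df["force_N"].to_numpy(dtype=float),
                                     tip_radius=side["tip_radius_m"],
                                     poisson=side["poisson"],
                                     spring_constant=side.get(
                                         "spring_constant_N_per_m", 0.06),
                                     position=pos))
        except ValueError as exc:
            raise SchemaError(f"{f}: {exc}") from exc
    if not curves:
        raise SchemaError(f"{directory}: no curve CSV files found")
    return curves


# --------------------------------------------------------------------- maps

def _map_sidecar_path(path):
    return Path(path).with_suffix(Path(path).suffix + ".json")


def write_map(smap: StiffnessMap, path):
    """Write a stiffness map as float32 TIFF (.tif) or TSV matrix (.tsv)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, smap.grid.astype(np.float32))
    elif path.suffix.lower() == ".tsv":
        np.savetxt(path, smap.grid, delimiter="\t")
    else:
        raise SchemaError(f"{path}: unsupported map format (use .tif or .tsv)")
    side = {"pitch_um": smap.pitch, "origin_um": list(smap.origin),
            "provenance": _jsonable(smap.provenance)}
    _map_sidecar_path(path).write_text(json.dumps(side, indent=1))


def read_map(path) -> StiffnessMap:
    path = Path(path)
    sidecar = _map_sidecar_path(path)
    if not sidecar.exists():
        raise SchemaError(f"{path}: missing sidecar {sidecar.name}")
    side = json.loads(sidecar.read_text())
    if "pitch_um" not in side:
        raise SchemaError(f"{sidecar}: missing field pitch_um")
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        grid = tifffile.imread(path).astype(float)
    else:
        grid = np.loadtxt(path, delimiter="\t", ndmin=2)
    return StiffnessMap(grid, float(side["pitch_um"]),
                        tuple(side.get("origin_um", (0.0, 0.0))),
                        side.get("provenance", {}))


# --------------------------------------------------------------- flux tables

def write_flux(table: pd.DataFrame, path):
    tumor.validate_flux_table(table)
    table.to_csv(path, index=False)


def read_flux(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    try:
        return tumor.validate_flux_table(df)
    except SchemaError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


# -------------------------------------------------------------------- fibres

def write_fibers(fibers, path):
    rows = []
    for f in fibers:
        for i, (x, y) in enumerate(f.points):
            row = {"fiber_id": f.fiber_id, "point_index": i, "x_um": x, "y_um": y}
            if f.width is not None:
                row["width_um"] = f.width
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_fibers(path):
    df = pd.read_csv(path)
    missing = {"fiber_id", "point_index", "x_um", "y_um"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    fibers = []
    for fid, sub in df.groupby("fiber_id", sort=False):
        sub = sub.sort_values("point_index")
        width = float(sub["width_um"].iloc[0]) if "width_um" in sub.columns else None
        try:
            fibers.append(FiberPolyline(sub[["x_um", "y_um"]].to_numpy(dtype=float),
                                        width, fiber_id=str(fid)))
        except ValueError as exc:
            raise SchemaError(f"{path}: fibre {fid!r}: {exc}") from exc
    return fibers


# ------------------------------------------------------------------ patterns

def write_pattern(pattern: SubstratePattern, path):
    Path(path).write_text(json.dumps(pattern.to_dict(), indent=1))


def read_pattern(path) -> SubstratePattern:
    d = json.loads(Path(path).read_text())
    try:
        return SubstratePattern.from_dict(d)
    except (KeyError, ValueError) as exc:
        raise SchemaError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------- summaries

def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_json(obj, path):
    Path(path).write_text(json.dumps(_jsonable(obj), indent=1))
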