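"""CSV dialects, configuration loading and run metadata.

All files are plain text. Coordinates are km in a local planar frame; an
optional ``origin`` metadata field documents the projected (UTM) origin of
that frame — no geodesy is performed.

Formats
-------
traps.csv      trap_id, x_km, y_km, kind, K [, bait]
captures.csv   individual_id, trap_id, count [, occasion]
occ.csv        camera_id, detections
telemetry.csv  individual_id, day, x_km, y_km
draws file     columnar CSV, one row per retained iteration (chain, iteration,
               then one column per parameter)
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .inference import FitConfig, PriorConfig
from .synthetic import ScenarioConfig, thin_telemetry
from .types import CAMERA, LIVE_TRAP, DataBundle, OccData, SCRData, TelemetryData, TrapArray

logger = logging.getLogger(__name__)

__all__ = [
    "read_traps",
    "read_captures",
    "read_occ",
    "read_telemetry",
    "write_bundle",
    "read_bundle",
    "load_config",
    "write_run_metadata",
]

PathLike = Union[str, Path]


def _read_csv(path: PathLike, required: set) -> pd.DataFrame:
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty input file")
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_traps(path: PathLike) -> TrapArray:
    """Read a detector array (one kind per file)."""
    df = _read_csv(path, {"trap_id", "x_km", "y_km", "kind", "K"})
    if df["trap_id"].duplicated().any():
        dupes = df.loc[df["trap_id"].duplicated(), "trap_id"].tolist()
        raise ValueError(f"{path}: duplicate trap ids {dupes}")
    kinds = set(df["kind"].unique())
    if not kinds <= {LIVE_TRAP, CAMERA}:
        raise ValueError(f"{path}: unknown detector kind(s) {kinds - {LIVE_TRAP, CAMERA}}")
    if len(kinds) != 1:
        raise ValueError(f"{path}: mixed detector kinds in one file")
    coords = df[["x_km", "y_km"]].to_numpy(dtype=float)
    if not np.isfinite(coords).all():
        raise ValueError(f"{path}: non-numeric or non-finite coordinates")
    K = df["K"].to_numpy()
    if (K < 0).any():
        raise ValueError(f"{path}: negative effort K")
    bait = None
    if "bait" in df.columns:
        b = df["bait"].to_numpy()
        if not np.isin(b, (0, 1)).all():
            raise ValueError(f"{path}: bait values must be 0 or 1")
        bait = b
    return TrapArray(
        coords=coords,
        kind=kinds.pop(),
        effort=K.astype(np.int64),
        bait=bait,
        ids=df["trap_id"].astype(str).tolist(),
    )


def read_captures(path: PathLike, traps: TrapArray) -> SCRData:
    """Read long-format captures and pivot to an n x J count matrix.

    Individuals are ordered by first appearance. An optional ``occasion``
    column is aggregated on load (the model is occasion-aggregated).
    """
    df = _read_csv(path, {"individual_id", "trap_id", "count"})
    if "occasion" in df.columns:
        logger.info("%s: aggregating per-occasion capture rows over occasions", path)
        df = df.groupby(["individual_id", "trap_id"], sort=False, as_index=False)["count"].sum()
    trap_index = {t: j for j, t in enumerate(traps.ids)}
    inds = list(dict.fromkeys(df["individual_id"].tolist()))
    ind_index = {i: k for k, i in enumerate(inds)}
    y = np.zeros((len(inds), traps.n_traps), dtype=np.int64)
    for row in df.itertuples(index=False):
        tid = str(row.trap_id)
        if tid not in trap_index:
            raise ValueError(f"{path}: unknown trap_id {row.trap_id!r}")
        j = trap_index[tid]
        if row.count > traps.effort[j]:
            raise ValueError(
                f"{path}: count {row.count} exceeds effort K={traps.effort[j]} "
                f"(individual {row.individual_id!r}, trap {row.trap_id!r})"
            )
        y[ind_index[row.individual_id], j] += int(row.count)
    if np.any(y > traps.effort[None, :]):
        bad = np.argwhere(y > traps.effort[None, :])[0]
        raise ValueError(
            f"{path}: aggregated count exceeds effort for individual "
            f"{inds[bad[0]]!r} at trap {traps.ids[bad[1]]!r}"
        )
    return SCRData(y=y, individual_ids=[str(i) for i in inds])


def read_occ(path: PathLike, cameras: TrapArray) -> OccData:
    """Read per-camera detection counts (already quantized and aggregated)."""
    df = _read_csv(path, {"camera_id", "detections"})
    cam_index = {t: j for j, t in enumerate(cameras.ids)}
    y = np.zeros(cameras.n_traps, dtype=np.int64)
    for row in df.itertuples(index=False):
        cid = str(row.camera_id)
        if cid not in cam_index:
            raise ValueError(f"{path}: unknown camera_id {row.camera_id!r}")
        y[cam_index[cid]] = int(row.detections)
    data = OccData(y=y)
    data.validate_against(cameras)
    return data


def read_telemetry(
    path: PathLike,
    scr: Optional[SCRData] = None,
    thin: bool = False,
    seed: Optional[int] = None,
) -> TelemetryData:
    """Read telemetry fixes; optionally thin to one fix per individual-day.

    When ``scr`` is given, individual ids are linked to capture rows (and
    unknown ids rejected); otherwise links follow file order. Duplicate
    individual-days are rejected unless ``thin=True``.
    """
    df = _read_csv(path, {"individual_id", "day", "x_km", "y_km"})
    if thin:
        df = thin_telemetry(df, seed=seed)
    elif df.duplicated(["individual_id", "day"]).any():
        raise ValueError(
            f"{path}: multiple fixes per individual-day; pass thin=True to subsample"
        )
    ids = list(dict.fromkeys(df["individual_id"].tolist()))
    fixes = [
        df.loc[df["individual_id"] == i, ["x_km", "y_km"]].to_numpy(dtype=float) for i in ids
    ]
    if scr is not None:
        index = {i: k for k, i in enumerate(scr.individual_ids)}
        links = []
        for i in ids:
            if str(i) not in index:
                raise ValueError(f"{path}: telemetry individual {i!r} not in capture file")
            links.append(index[str(i)])
        links = np.array(links)
    else:
        links = np.arange(len(ids))
    return TelemetryData(fixes=fixes, links=links)


# ---------------------------------------------------------------------------
# bundle round-trip


def write_bundle(bundle: DataBundle, outdir: PathLike) -> dict:
    """Write a bundle as the CSV dialects above; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    def traps_frame(arr: TrapArray) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "trap_id": arr.ids,
                "x_km": arr.coords[:, 0],
                "y_km": arr.coords[:, 1],
                "kind": arr.kind,
                "K": arr.effort,
            }
        )
        if arr.bait is not None:
            df["bait"] = arr.bait
        return df

    paths["traps"] = outdir / "traps.csv"
    traps_frame(bundle.traps).to_csv(paths["traps"], index=False)

    rows = []
    for i, ind in enumerate(bundle.scr.individual_ids):
        for j in np.flatnonzero(bundle.scr.y[i]):
            rows.append(
                {"individual_id": ind, "trap_id": bundle.traps.ids[j],
                 "count": int(bundle.scr.y[i, j])}
            )
    paths["captures"] = outdir / "captures.csv"
    pd.DataFrame(rows).to_csv(paths["captures"], index=False)

    if bundle.cameras is not None:
        paths["cameras"] = outdir / "cameras.csv"
        traps_frame(bundle.cameras).to_csv(paths["cameras"], index=False)
        paths["occ"] = outdir / "occ.csv"
        pd.DataFrame(
            {"camera_id": bundle.cameras.ids, "detections": bundle.occ.y}
        ).to_csv(paths["occ"], index=False)

    if bundle.telemetry is not None:
        rows = []
        for k, fixes in enumerate(bundle.telemetry.fixes):
            ind = bundle.scr.individual_ids[bundle.telemetry.links[k]]
            for day, (x, y) in enumerate(fixes, start=1):
                rows.append({"individual_id": ind, "day": day, "x_km": x, "y_km": y})
        paths["telemetry"] = outdir / "telemetry.csv"
        pd.DataFrame(rows).to_csv(paths["telemetry"], index=False)

    paths["space"] = outdir / "space.json"
    with open(paths["space"], "w") as fh:
        json.dump(
            {"xmin": bundle.space.xmin, "xmax": bundle.space.xmax,
             "ymin": bundle.space.ymin, "ymax": bundle.space.ymax},
            fh,
        )
    return {k: str(v) for k, v in paths.items()}


def read_bundle(
    traps: PathLike,
    captures: PathLike,
    space: PathLike,
    cameras: Optional[PathLike] = None,
    occ: Optional[PathLike] = None,
    telemetry: Optional[PathLike] = None,
    thin: bool = False,
    seed: Optional[int] = None,
) -> DataBundle:
    """Assemble a DataBundle from CSV paths (inverse of :func:`write_bundle`)."""
    from .types import StateSpace

    trap_arr = read_traps(traps)
    scr = read_captures(captures, trap_arr)
    with open(space) as fh:
        sp = json.load(fh)
    space_obj = StateSpace(sp["xmin"], sp["xmax"], sp["ymin"], sp["ymax"])
    cam_arr = read_traps(cameras) if cameras else None
    occ_data = read_occ(occ, cam_arr) if occ else None
    tel = read_telemetry(telemetry, scr, thin=thin, seed=seed) if telemetry else None
    return DataBundle(
        traps=trap_arr, scr=scr, space=space_obj, cameras=cam_arr, occ=occ_data, telemetry=tel
    )


# ---------------------------------------------------------------------------
# configuration


def _from_mapping(cls, data: dict, path):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(
            f"{path}: unknown config keys {sorted(unknown)}; valid keys: {sorted(names)}"
        )
    return cls(**data)


def load_config(path: PathLike, kind: str = "fit"):
    """Load a YAML/JSON config into a FitConfig (``kind='fit'``) or
    ScenarioConfig (``kind='scenario'``); unknown keys are rejected."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    if kind == "fit":
        priors = data.pop("priors", None)
        cfg = _from_mapping(FitConfig, data, path)
        if priors is not None:
            cfg.priors = _from_mapping(PriorConfig, priors, path)
        return cfg
    if kind == "scenario":
        if "camera_effort_range" in data:
            data["camera_effort_range"] = tuple(data["camera_effort_range"])
        return _from_mapping(ScenarioConfig, data, path)
    raise ValueError("kind must be 'fit' or 'scenario'")


def write_run_metadata(path: PathLike, config, extra: Optional[dict] = None) -> None:
    """Echo the full configuration (including seeds) next to any output."""
    meta = dataclasses.asdict(config) if dataclasses.is_dataclass(config) else dict(config)
    if extra:
        meta.update(extra)
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
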