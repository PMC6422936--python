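"""Config files, track CSV round-trips and provenance headers.

Track tables are written as CSV with commented provenance headers
(``# key: value``) so a file is self-describing; geometry and attractant
specs live in one YAML document.
"""

from __future__ import annotations

import json
from dataclasses import asdict

import pandas as pd
import yaml

from .geometry import ChemoattractantSpec, DeviceGeometry
from .simulate import TRACK_COLUMNS


def geometry_to_dict(geometry: DeviceGeometry) -> dict:
    d = asdict(geometry)
    d["rung_offsets"] = list(d["rung_offsets"])
    return d


def load_config(path) -> dict:
    """Load a device/assay YAML config.

    Recognised top-level keys: ``geometry`` (DeviceGeometry fields),
    ``attractants`` (mapping side -> ChemoattractantSpec fields) and
    ``boundary_model``. Missing keys fall back to package defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    geom_kwargs = raw.get("geometry", {}) or {}
    if "rung_offsets" in geom_kwargs:
        geom_kwargs["rung_offsets"] = tuple(geom_kwargs["rung_offsets"])
    geometry = DeviceGeometry(**geom_kwargs)
    attractants = {}
    for side, spec in (raw.get("attractants") or {}).items():
        attractants[side] = ChemoattractantSpec(**spec)
    return {
        "geometry": geometry,
        "attractants": attractants,
        "boundary_model": raw.get("boundary_model", "sink"),
    }


def save_config(path, geometry: DeviceGeometry, attractants: dict, boundary_model="sink"):
    doc = {
        "geometry": geometry_to_dict(geometry),
        "attractants": {k: asdict(v) for k, v in attractants.items()},
        "boundary_model": boundary_model,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def write_tracks_csv(tracks: pd.DataFrame, path, provenance: dict | None = None):
    with open(path, "w") as fh:
        for key, value in (provenance or {}).items():
            fh.write(f"# {key}: {json.dumps(value, default=str)}\n")
        tracks.to_csv(fh, index=False)


def read_tracks_csv(path) -> tuple[pd.DataFrame, dict]:
    provenance = {}
    with open(path) as fh:
        pos = 0
        for line in fh:
            if not line.startswith("#"):
                break
            pos += len(line)
            key, _, value = line[1:].strip().partition(":")
            try:
                provenance[key.strip()] = json.loads(value.strip())
            except json.JSONDecodeError:
                provenance[key.strip()] = value.strip()
        fh.seek(pos)
        tracks = pd.read_csv(fh)
    missing = [c for c in TRACK_COLUMNS if c not in tracks.columns and c != "region"]
    if missing:
        raise ValueError(f"track CSV missing columns: {missing}")
    return tracks, provenance
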