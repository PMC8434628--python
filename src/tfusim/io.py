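"""Result persistence: HDF5 fields, CSV profiles/tables, JSON metrics, and
run manifests."""

from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .scene import SceneConfig, build_medium_maps, build_source
from .solver import AmplitudeField


def write_field_h5(fld: AmplitudeField, path) -> None:
    """Amplitude field plus grid coordinates and provenance attributes."""
    grid = fld.grid
    with h5py.File(path, "w") as h5:
        ds = h5.create_dataset("amplitude_pa", data=fld.data)
        ds.attrs["mode"] = grid.mode
        h5.create_dataset("z_m", data=grid.z)
        if grid.mode == "axisymmetric":
            h5.create_dataset("r_m", data=grid.r)
        elif grid.mode == "3d":
            h5.create_dataset("y_m", data=grid.y)
            h5.create_dataset("x_m", data=grid.x)
        for key, val in fld.meta.items():
            if isinstance(val, (str, int, float, bool)):
                ds.attrs[key] = val
        ds.attrs["meta_json"] = json.dumps(fld.meta, default=str,
                                           sort_keys=True)


def read_field_h5(path) -> dict:
    with h5py.File(path, "r") as h5:
        out = {k: h5[k][...] for k in h5}
        out["meta"] = json.loads(h5["amplitude_pa"].attrs["meta_json"])
    return out


def write_masks_h5(scene: SceneConfig, path) -> None:
    """Plate and source occupancy masks for geometry inspection."""
    media = build_medium_maps(scene)
    src = build_source(scene.transducer, scene.grid)
    src_mask = np.zeros(scene.grid.shape, dtype=bool)
    src_mask[src.indices] = True
    with h5py.File(path, "w") as h5:
        h5.create_dataset("plate_mask", data=media.plate_mask)
        h5.create_dataset("source_mask", data=src_mask)
        h5.create_dataset("sound_speed_m_s", data=media.c)
        h5.create_dataset("density_kg_m3", data=media.rho)
        h5.attrs["scene_hash"] = scene.hash()


def write_axial_csv(fld: AmplitudeField, path) -> None:
    z, amp = fld.on_axis()
    pd.DataFrame({"z_mm": z * 1e3, "amplitude_pa": amp}).to_csv(path,
                                                                index=False)


def write_json(payload: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")


@dataclass
class RunManifest:
    """Reproducibility record of one CLI run: the scene hash and settings
    fully determine every output (the solve path has no randomness)."""

    scene_hash: str
    settings: dict
    outputs: list = field(default_factory=list)
    software_version: str = __version__
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.timestamp:
            self.timestamp = datetime.datetime.now(
                datetime.timezone.utc).isoformat()

    def content_hash(self) -> str:
        """Hash of the manifest excluding the timestamp (stable under key
        reordering)."""
        payload = {"scene_hash": self.scene_hash, "settings": self.settings,
                   "outputs": sorted(self.outputs),
                   "software_version": self.software_version}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]

    def write(self, path) -> None:
        d = {"scene_hash": self.scene_hash, "settings": self.settings,
             "outputs": sorted(self.outputs),
             "software_version": self.software_version,
             "timestamp": self.timestamp,
             "content_hash": self.content_hash()}
        write_json(d, path)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
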