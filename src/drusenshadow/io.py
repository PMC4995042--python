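"""TIFF + JSON-sidecar I/O for volumes and en face images.

Every array product is written as 32-bit float multi-page TIFF (pages are
depth slices for volumes) next to a ``.json`` sidecar carrying the
acquisition metadata needed to reinterpret it.  Round-trips are lossless for
float32 data.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import tifffile

from .oct_simulator import OCTVolume, DevicePreset
from .octa_engine import NoiseStats, OCTAVolume
from .slab_projection import EnFacePair, SlabSpec

__all__ = [
    "write_volume",
    "read_volume",
    "write_octa",
    "read_octa",
    "write_enface_pair",
    "read_enface_pair",
]


def _write_sidecar(path: Path, meta: dict) -> None:
    path.write_text(json.dumps(meta, indent=2, sort_keys=True, default=str))


def _preset_meta(preset: DevicePreset) -> dict:
    d = dataclasses.asdict(preset)
    if np.isinf(d["rolloff_6db_depth_um"]):
        d["rolloff_6db_depth_um"] = "inf"
    return d


def _preset_from_meta(meta: dict) -> DevicePreset:
    d = dict(meta)
    if d.get("rolloff_6db_depth_um") == "inf":
        d["rolloff_6db_depth_um"] = np.inf
    return DevicePreset(**d)


def write_volume(prefix: str | Path, volume: OCTVolume) -> list[Path]:
    """One multi-page TIFF per repeat (pages = depth slices) + JSON sidecar."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = []
    for n in range(volume.repeats):
        p = prefix.with_name(f"{prefix.name}_rep{n}.tif")
        # (nz, ny, nx): depth slices as pages
        tifffile.imwrite(p, np.moveaxis(volume.amplitudes[n], -1, 0))
        paths.append(p)
    sidecar = prefix.with_name(f"{prefix.name}.json")
    _write_sidecar(
        sidecar,
        {
            "kind": "oct_volume",
            "repeats": volume.repeats,
            "axial_pitch_um": volume.axial_pitch_um,
            "preset": _preset_meta(volume.preset),
            "provenance": volume.provenance,
        },
    )
    return paths + [sidecar]


def read_volume(prefix: str | Path) -> OCTVolume:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_name(f"{prefix.name}.json").read_text())
    reps = []
    for n in range(int(meta["repeats"])):
        arr = tifffile.imread(prefix.with_name(f"{prefix.name}_rep{n}.tif"))
        reps.append(np.moveaxis(arr, 0, -1))
    return OCTVolume(
        amplitudes=np.stack(reps),
        preset=_preset_from_meta(meta["preset"]),
        axial_pitch_um=float(meta["axial_pitch_um"]),
        provenance=meta.get("provenance", {}),
    )


def write_octa(prefix: str | Path, octa: OCTAVolume) -> list[Path]:
    """Decorrelation as float32 TIFF, mask as uint8 TIFF, stats in the sidecar."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    d_path = prefix.with_name(f"{prefix.name}_decorr.tif")
    m_path = prefix.with_name(f"{prefix.name}_mask.tif")
    o_path = prefix.with_name(f"{prefix.name}_meanoct.tif")
    tifffile.imwrite(d_path, np.moveaxis(octa.decorrelation.astype(np.float32), -1, 0))
    tifffile.imwrite(m_path, np.moveaxis(octa.mask_below_threshold.astype(np.uint8), -1, 0))
    tifffile.imwrite(o_path, np.moveaxis(octa.mean_oct.astype(np.float32), -1, 0))
    sidecar = prefix.with_name(f"{prefix.name}.json")
    _write_sidecar(
        sidecar,
        {
            "kind": "octa_volume",
            "preset_name": octa.preset_name,
            "axial_pitch_um": octa.axial_pitch_um,
            "noise": dataclasses.asdict(octa.noise),
            "provenance": octa.provenance,
        },
    )
    return [d_path, m_path, o_path, sidecar]


def read_octa(prefix: str | Path) -> OCTAVolume:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_name(f"{prefix.name}.json").read_text())
    d = np.moveaxis(tifffile.imread(prefix.with_name(f"{prefix.name}_decorr.tif")), 0, -1)
    m = np.moveaxis(tifffile.imread(prefix.with_name(f"{prefix.name}_mask.tif")), 0, -1)
    o = np.moveaxis(tifffile.imread(prefix.with_name(f"{prefix.name}_meanoct.tif")), 0, -1)
    n = meta["noise"]
    return OCTAVolume(
        decorrelation=d,
        mask_below_threshold=m.astype(bool),
        noise=NoiseStats(n["mean"], n["sd"], n["threshold"], n.get("region", "")),
        mean_oct=o,
        preset_name=meta.get("preset_name", ""),
        axial_pitch_um=float(meta["axial_pitch_um"]),
        provenance=meta.get("provenance", {}),
    )


def write_enface_pair(prefix: str | Path, pair: EnFacePair) -> list[Path]:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, img in (
        ("oct", pair.oct_slab),
        ("octa", pair.octa_slab),
        ("maskfrac", pair.masked_fraction),
    ):
        p = prefix.with_name(f"{prefix.name}_{name}.tif")
        tifffile.imwrite(p, img.astype(np.float32))
        paths.append(p)
    sidecar = prefix.with_name(f"{prefix.name}.json")
    _write_sidecar(
        sidecar,
        {
            "kind": "enface_pair",
            "device": pair.device,
            "spec": dataclasses.asdict(pair.spec),
            "provenance": pair.provenance,
        },
    )
    return paths + [sidecar]


def read_enface_pair(prefix: str | Path) -> EnFacePair:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_name(f"{prefix.name}.json").read_text())
    imgs = {
        name: tifffile.imread(prefix.with_name(f"{prefix.name}_{name}.tif"))
        for name in ("oct", "octa", "maskfrac")
    }
    return EnFacePair(
        oct_slab=imgs["oct"],
        octa_slab=imgs["octa"],
        masked_fraction=imgs["maskfrac"],
        spec=SlabSpec(**meta["spec"]),
        device=meta["device"],
        provenance=meta.get("provenance", {}),
    )
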