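"""File I/O: TIFF + JSON sidecars, HDF5 scan stacks, CSV tables."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .geometry import OpticalGeometry
from .holography import Hologram, PhaseMap
from .phantom import CellPhantom, FilamentTruth, NucleusParams
from .saxs import QCalibration, ScanGrid, ScanStack


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def save_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=_json_default))


def load_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def save_image(path: str | Path, image: np.ndarray, sidecar: dict | None = None):
    """32-bit float TIFF with an optional JSON metadata sidecar."""
    tifffile.imwrite(str(path), np.asarray(image, dtype=np.float32))
    if sidecar is not None:
        save_json(Path(path).with_suffix(".json"), sidecar)


def load_image(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path))


def save_phantom(path: str | Path, phantom: CellPhantom) -> None:
    """Multi-page TIFF (density, phase, label map) + JSON ground truth."""
    stack = np.stack([phantom.density, phantom.phase, phantom.label_map])
    tifffile.imwrite(str(path), stack.astype(np.float32), photometric="minisblack")
    save_json(
        Path(path).with_suffix(".json"),
        {
            "pixel_size_nm": phantom.pixel_size,
            "phase_scale": phantom.phase_scale,
            "seed": phantom.seed,
            "nucleus": dataclasses.asdict(phantom.nucleus),
            "pages": ["density", "phase", "label_map"],
            "filaments": [dataclasses.asdict(f) for f in phantom.true_filaments],
        },
    )


def load_phantom(path: str | Path) -> CellPhantom:
    stack = tifffile.imread(str(path))
    meta = load_json(Path(path).with_suffix(".json"))
    nuc = meta["nucleus"]
    return CellPhantom(
        density=stack[0].astype(float),
        phase=stack[1].astype(float),
        label_map=stack[2].astype(float),
        true_filaments=[
            FilamentTruth(
                p1=tuple(f["p1"]), p2=tuple(f["p2"]),
                orientation=f["orientation"], width=f["width"],
                labeled=f["labeled"],
            )
            for f in meta["filaments"]
        ],
        nucleus=NucleusParams(
            center=tuple(nuc["center"]),
            semi_axes=tuple(nuc["semi_axes"]),
            scale=nuc["scale"],
        ),
        pixel_size=meta["pixel_size_nm"],
        phase_scale=meta["phase_scale"],
        seed=meta["seed"],
    )


def save_hologram(path: str | Path, holo: Hologram) -> None:
    save_image(path, holo.intensity, sidecar=holo.geometry.to_dict())


def load_hologram(path: str | Path) -> Hologram:
    geom = OpticalGeometry.from_dict(load_json(Path(path).with_suffix(".json")))
    return Hologram(intensity=load_image(path), geometry=geom)


def save_phase_map(path: str | Path, pm: PhaseMap) -> None:
    save_image(path, pm.phase, sidecar={"pixel_size_nm": pm.pixel_size})


def load_phase_map(path: str | Path) -> PhaseMap:
    meta = load_json(Path(path).with_suffix(".json"))
    return PhaseMap(phase=load_image(path), pixel_size=meta["pixel_size_nm"])


def save_scan_stack(path: str | Path, stack: ScanStack) -> None:
    """HDF5: frames, mask, scan positions, q-calibration attributes."""
    with h5py.File(str(path), "w") as f:
        f.create_dataset("frames", data=stack.counts, compression="gzip")
        f.create_dataset("mask", data=stack.mask)
        f.create_dataset("empty", data=stack.empty)
        f.create_dataset("positions_um", data=stack.grid.positions())
        f.attrs["grid_shape"] = stack.grid.shape
        f.attrs["step_um"] = stack.grid.step_um
        f.attrs["origin_um"] = stack.grid.origin_um
        f.attrs["exposure_s"] = stack.exposure
        cal = stack.calibration
        f.attrs["beam_center"] = cal.beam_center
        f.attrs["distance_mm"] = cal.distance_mm
        f.attrs["det_pixel_um"] = cal.pixel_size_um
        f.attrs["wavelength_nm"] = cal.wavelength_nm


def load_scan_stack(path: str | Path) -> ScanStack:
    with h5py.File(str(path), "r") as f:
        grid = ScanGrid(
            shape=tuple(int(x) for x in f.attrs["grid_shape"]),
            step_um=float(f.attrs["step_um"]),
            origin_um=tuple(float(x) for x in f.attrs["origin_um"]),
        )
        cal = QCalibration(
            beam_center=tuple(float(x) for x in f.attrs["beam_center"]),
            distance_mm=float(f.attrs["distance_mm"]),
            pixel_size_um=float(f.attrs["det_pixel_um"]),
            wavelength_nm=float(f.attrs["wavelength_nm"]),
        )
        return ScanStack(
            counts=f["frames"][...],
            mask=f["mask"][...].astype(bool),
            grid=grid,
            calibration=cal,
            exposure=float(f.attrs["exposure_s"]),
            empty=f["empty"][...].astype(bool),
        )
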