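"""Stack manifests and image IO.

A hologram stack on disk is a set of single-frame grayscale images
(8/16-bit integer or 32-bit float TIFF, or 8/16-bit PNG) plus a JSON or
YAML manifest:

.. code-block:: json

    {
      "pixel_pitch_m": 2e-06,
      "multiplex_mode": "distance",
      "camera": {"bit_depth": 8},
      "frames": [
        {"path": "frame0.tif", "distance_m": 0.002, "wavelength_m": 5e-07},
        {"path": "frame1.tif", "distance_m": 0.003, "wavelength_m": 5e-07}
      ]
    }

Images are read into float gray-level units *without rescaling*, so M and
ΔM keep their camera-unit meaning.  Field names carry SI units to prevent
unit bugs; pixel coordinates in configs are 0-based and half-open.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .optics import ComplexField, GridSpec
from .simulate import CameraModel, Hologram, HologramStack

__all__ = [
    "SchemaError",
    "read_image",
    "write_image",
    "read_stack",
    "write_stack",
    "write_field",
    "split_rgb",
    "file_sha256",
]

RGB_WAVELENGTHS_M = (450e-9, 532e-9, 635e-9)


class SchemaError(ValueError):
    """A manifest is missing or mistypes a required field."""


def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def read_image(path) -> np.ndarray:
    """Decode an image to float64 gray levels, no rescaling."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    return np.asarray(arr, dtype=np.float64)


def write_image(path, array: np.ndarray) -> None:
    """Write a 2-D array: float32 TIFF for float data, native integer
    TIFF/PNG for integer data."""
    path = Path(path)
    array = np.asarray(array)
    if path.suffix.lower() in (".tif", ".tiff"):
        if np.issubdtype(array.dtype, np.integer):
            tifffile.imwrite(path, array)
        else:
            tifffile.imwrite(path, array.astype(np.float32))
    else:
        import imageio.v3 as iio

        iio.imwrite(path, array)


def _load_manifest(path: Path) -> dict:
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if not isinstance(data, dict):
        raise SchemaError("manifest must be a mapping")
    return data


def _require(mapping: dict, field: str, where: str):
    if field not in mapping:
        raise SchemaError(f"{where}: missing required field {field!r}")
    return mapping[field]


def read_stack(manifest_path) -> HologramStack:
    """Load a :class:`HologramStack` from a JSON/YAML manifest.

    Frame paths are resolved relative to the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    data = _load_manifest(manifest_path)
    pitch = float(_require(data, "pixel_pitch_m", "manifest"))
    mode = _require(data, "multiplex_mode", "manifest")
    frame_entries = _require(data, "frames", "manifest")
    if not frame_entries:
        raise SchemaError("manifest: frames list is empty")
    camera = None
    if "camera" in data and data["camera"] is not None:
        cam = data["camera"]
        camera = CameraModel(
            bit_depth=int(_require(cam, "bit_depth", "camera")),
            gain=float(cam.get("gain", 1.0)),
            exposure_scale=float(cam.get("exposure_scale", 1.0)),
        )
    frames = []
    shape = None
    for i, entry in enumerate(frame_entries):
        where = f"frames[{i}]"
        rel = _require(entry, "path", where)
        img_path = manifest_path.parent / rel
        img = read_image(img_path)
        if img.ndim != 2:
            raise ValueError(f"{img_path}: expected a 2-D grayscale image, got {img.shape}")
        if shape is None:
            shape = img.shape
        elif img.shape != shape:
            raise ValueError(f"{img_path}: frame shape {img.shape} != {shape}")
        frames.append(
            Hologram(
                img,
                distance=float(_require(entry, "distance_m", where)),
                wavelength=float(_require(entry, "wavelength_m", where)),
                grid=GridSpec(img.shape[0], img.shape[1], pitch),
                acquisition=camera,
                provenance=str(img_path),
            )
        )
    return HologramStack(frames, multiplex_mode=mode)


def write_stack(stack: HologramStack, outdir, prefix: str = "frame") -> Path:
    """Write one TIFF per frame plus ``manifest.json``; returns the
    manifest path.  Float intensities go out as 32-bit float TIFF,
    quantized (integer-valued, with camera metadata) ones as integers."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, h in enumerate(stack):
        name = f"{prefix}{i}.tif"
        data = h.intensity
        if h.acquisition is not None and np.all(data == np.round(data)):
            dtype = np.uint8 if h.acquisition.bit_depth <= 8 else np.uint16
            data = data.astype(dtype)
        write_image(outdir / name, data)
        entries.append(
            {"path": name, "distance_m": h.distance, "wavelength_m": h.wavelength}
        )
    manifest = {
        "pixel_pitch_m": stack.grid.pitch,
        "multiplex_mode": stack.multiplex_mode,
        "frames": entries,
    }
    cam = stack.frames[0].acquisition
    if cam is not None:
        manifest["camera"] = {
            "bit_depth": cam.bit_depth,
            "gain": cam.gain,
            "exposure_scale": cam.exposure_scale,
        }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def write_field(field: ComplexField, outdir, basename: str = "reconstruction") -> dict:
    """Write a complex field as ``<basename>_phase.tif`` and
    ``<basename>_amplitude.tif`` (32-bit float); returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "phase": outdir / f"{basename}_phase.tif",
        "amplitude": outdir / f"{basename}_amplitude.tif",
    }
    write_image(paths["phase"], field.phase.astype(np.float32))
    write_image(paths["amplitude"], field.amplitude.astype(np.float32))
    return paths


def split_rgb(
    image,
    distance_m: float,
    pixel_pitch_m: float,
    wavelengths_m=RGB_WAVELENGTHS_M,
) -> HologramStack:
    """Treat the three channels of an RGB image as wavelength-multiplexed
    holograms sharing one defocus distance.

    ``image`` may be a path or an HxWx3 array; default wavelengths are
    the 450/532/635 nm RGB laser lines.
    """
    arr = read_image(image) if isinstance(image, (str, Path)) else np.asarray(
        image, dtype=np.float64
    )
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 RGB image, got shape {arr.shape}")
    if len(wavelengths_m) != 3:
        raise ValueError("need exactly three wavelengths")
    grid = GridSpec(arr.shape[0], arr.shape[1], pixel_pitch_m)
    frames = [
        Hologram(arr[:, :, c], distance_m, float(wavelengths_m[c]), grid)
        for c in range(3)
    ]
    return HologramStack(frames, multiplex_mode="wavelength")
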