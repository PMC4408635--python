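"""Float-raster and bundle I/O.

Depth, gradient and irradiance maps are stored as grayscale little-endian
PFM (portable float map), a minimal uncompressed format: a three-line ASCII
header (``Pf``, ``<width> <height>``, negative scale for little-endian)
followed by rows of float32, bottom row first.  Previews are written as
16-bit PNG with the linear scale recorded in a JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .camera import CameraModel
from .render import GroundTruthBundle, RadianceImage
from .surfaces import surface_from_dict

__all__ = [
    "write_pfm",
    "read_pfm",
    "write_preview_png",
    "write_bundle",
    "read_bundle",
    "load_camera_json",
]


def write_pfm(path, data: np.ndarray) -> None:
    data = np.asarray(data, dtype=np.float32)
    if data.ndim != 2:
        raise ValueError("only grayscale 2-D rasters are supported")
    with open(path, "wb") as fh:
        fh.write(b"Pf\n")
        fh.write(f"{data.shape[1]} {data.shape[0]}\n".encode())
        fh.write(b"-1.0\n")  # negative scale => little-endian
        fh.write(np.flipud(data).astype("<f4").tobytes())


def read_pfm(path) -> np.ndarray:
    with open(path, "rb") as fh:
        header = fh.readline().strip()
        if header != b"Pf":
            raise ValueError(f"not a grayscale PFM file: header {header!r}")
        dims = fh.readline().split()
        w, h = int(dims[0]), int(dims[1])
        scale = float(fh.readline())
        dtype = "<f4" if scale < 0 else ">f4"
        data = np.frombuffer(fh.read(w * h * 4), dtype=dtype).reshape(h, w)
    return np.flipud(data).astype(float)


def write_preview_png(path, data: np.ndarray) -> None:
    """Scaled 16-bit preview with the scale in a ``.json`` sidecar."""
    data = np.asarray(data, dtype=float)
    finite = np.isfinite(data)
    lo = float(data[finite].min()) if finite.any() else 0.0
    hi = float(data[finite].max()) if finite.any() else 1.0
    span = hi - lo if hi > lo else 1.0
    scaled = np.zeros(data.shape, dtype=np.uint16)
    scaled[finite] = np.round((data[finite] - lo) / span * 65535).astype(np.uint16)
    iio.imwrite(path, scaled)
    Path(str(path) + ".json").write_text(json.dumps({"offset": lo, "scale": span / 65535.0}))


def write_bundle(dirpath, bundle: GroundTruthBundle) -> None:
    """GroundTruthBundle as a directory of PFM rasters plus scene JSON."""
    d = Path(dirpath)
    d.mkdir(parents=True, exist_ok=True)
    write_pfm(d / "radiance.pfm", np.where(bundle.mask, bundle.radiance.E, 0.0))
    write_pfm(d / "depth.pfm", bundle.depth)
    write_pfm(d / "p.pfm", bundle.p)
    write_pfm(d / "q.pfm", bundle.q)
    iio.imwrite(d / "mask.png", (bundle.mask * 255).astype(np.uint8))
    iio.imwrite(d / "limb_mask.png", (bundle.limb_mask * 255).astype(np.uint8))
    (d / "scene.json").write_text(
        json.dumps(
            {
                "surface": bundle.surface.to_dict(),
                "camera": bundle.camera.to_dict(),
                "reflectance_C": bundle.radiance.C,
            },
            indent=2,
        )
    )


def read_bundle(dirpath) -> GroundTruthBundle:
    d = Path(dirpath)
    meta = json.loads((d / "scene.json").read_text())
    camera = CameraModel.from_dict(meta["camera"])
    surface = surface_from_dict(meta["surface"])
    mask = np.asarray(iio.imread(d / "mask.png")) > 0
    limb = np.asarray(iio.imread(d / "limb_mask.png")) > 0
    E = read_pfm(d / "radiance.pfm")
    depth = read_pfm(d / "depth.pfm")
    p = read_pfm(d / "p.pfm")
    q = read_pfm(d / "q.pfm")
    return GroundTruthBundle(
        radiance=RadianceImage(E, meta["reflectance_C"], mask),
        depth=np.where(mask, depth, np.nan),
        p=np.where(mask, p, np.nan),
        q=np.where(mask, q, np.nan),
        mask=mask,
        limb_mask=limb,
        surface=surface,
        camera=camera,
    )


def load_camera_json(path) -> CameraModel:
    d = json.loads(Path(path).read_text())
    if "camera" in d:
        d = d["camera"]
    return CameraModel.from_dict(d)
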