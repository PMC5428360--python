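"""File formats and run configuration.

Interferograms travel as 8/16-bit grayscale TIFF or PNG with a YAML sidecar
holding the acquisition geometry; phase maps as 32-bit float TIFF; bundles of
frames plus ground truth as NumPy ``.npz`` archives.  :class:`RunConfig`
gathers every knob of the retrieval pipeline and round-trips losslessly
through YAML.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .geometry import AcquisitionConfig
from .phantoms import PhaseMap
from .simulate import Interferogram

__all__ = [
    "RunConfig",
    "write_image",
    "read_image",
    "write_interferogram",
    "read_interferogram",
    "write_phasemap",
    "read_phasemap",
    "write_bundle",
    "read_bundle",
]


@dataclass
class RunConfig:
    """Every pipeline option in one serializable bag of parameters."""

    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    distance_a_mm: float = 2.2617
    distance_b_mm: float = 1.8888
    window_radius: float | None = None
    taper: bool = True
    flat_frac: float = 0.8
    eps_rel: float = 1e-6
    weights: tuple[float, float] = (1.0, 1.0)
    subtract_background: bool = False
    out_dir: str = "."
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["weights"] = list(self.weights)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "acquisition" in d and isinstance(d["acquisition"], dict):
            d["acquisition"] = AcquisitionConfig.from_dict(d["acquisition"])
        if "weights" in d:
            d["weights"] = tuple(d["weights"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ---- images ----------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def write_image(path: str | Path, image: np.ndarray, *, bit_depth: int = 16) -> None:
    """Write a grayscale image as TIFF or PNG at the requested bit depth."""
    path = Path(path)
    dtype = np.uint8 if bit_depth <= 8 else np.uint16
    arr = np.clip(np.rint(image), 0, 2**bit_depth - 1).astype(dtype)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    elif path.suffix.lower() == ".png":
        iio.imwrite(path, arr)
    else:
        raise ValueError(f"unsupported image format: {path.suffix}")


def read_image(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a grayscale image plus its sidecar metadata (if present).

    Colour images are rejected; a missing sidecar yields empty metadata.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    elif path.suffix.lower() == ".png":
        arr = iio.imread(path)
    elif path.suffix.lower() == ".npz":
        with np.load(path) as z:
            arr = z[z.files[0]]
    else:
        raise ValueError(f"unsupported image format: {path.suffix}")
    if arr.ndim != 2:
        raise ValueError("expected a single-channel grayscale image")
    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text()) or {}
    return np.asarray(arr), meta


def write_interferogram(path: str | Path, frame: Interferogram) -> None:
    """Image file plus YAML sidecar with the acquisition geometry."""
    write_image(path, frame.intensity, bit_depth=frame.config.bit_depth)
    meta = {
        "acquisition": frame.config.to_dict(),
        "distance_mm": frame.distance_mm,
        "shear_mm": frame.shear_mm,
    }
    _sidecar_path(Path(path)).write_text(yaml.safe_dump(meta, sort_keys=True))


def read_interferogram(path: str | Path) -> Interferogram:
    arr, meta = read_image(path)
    if "acquisition" not in meta:
        raise ValueError(f"missing sidecar config for {path}")
    cfg = AcquisitionConfig.from_dict(meta["acquisition"])
    return Interferogram(arr.astype(np.float64), cfg, float(meta["distance_mm"]))


def write_phasemap(path: str | Path, pm: PhaseMap) -> None:
    """32-bit float TIFF with unit/extent metadata in the TIFF description."""
    tifffile.imwrite(
        Path(path),
        pm.values.astype(np.float32),
        description=json.dumps({"unit": pm.unit, "extent_mm": pm.extent_mm}),
    )


def read_phasemap(path: str | Path) -> PhaseMap:
    with tifffile.TiffFile(Path(path)) as tf:
        arr = tf.asarray()
        desc = tf.pages[0].tags.get("ImageDescription")
        meta = json.loads(desc.value) if desc is not None else {}
    return PhaseMap(
        arr.astype(np.float64),
        float(meta.get("extent_mm", 1.0)),
        meta.get("unit", "opd_nm"),
    )


# ---- bundled array archives ------------------------------------------------


def write_bundle(path: str | Path, **arrays: np.ndarray) -> None:
    """Compressed archive of frames / phases / ground truth for tests."""
    np.savez_compressed(Path(path), **arrays)


def read_bundle(path: str | Path) -> dict[str, np.ndarray]:
    with np.load(Path(path)) as z:
        return {k: z[k] for k in z.files}
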