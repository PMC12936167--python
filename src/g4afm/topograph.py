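"""Container and file I/O for AFM height maps.

A :class:`Topograph` is a 2-D raster of surface heights in nanometres with a
known, isotropic pixel size.  The raster convention used throughout the
package is row-major with the origin at the top-left corner; pixel centres sit
at integer indices, so the physical position of pixel ``(row, col)`` is
``(x, y) = (col * pixel_size_nm, row * pixel_size_nm)``.

Topographs are stored on disk either as plain-text numeric matrices (one scan
line per row, values in nm) or as 32-bit float grayscale TIFFs, always with a
YAML sidecar carrying the pixel size and provenance metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import tifffile
import yaml

MIN_GRID = 16


@dataclass
class Topograph:
    """A 2-D AFM height map.

    Parameters
    ----------
    heights
        Surface heights in nm, shape ``(rows, cols)``; must be finite and at
        least 16x16.
    pixel_size_nm
        Physical size of one pixel (nm/px), identical along both axes.
    origin
        Raster convention tag; only ``"upper"`` (row 0 at the top) is used.
    meta
        Free-form provenance record (generator parameters, seed, source file).
    """

    heights: np.ndarray
    pixel_size_nm: float
    origin: str = "upper"
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise ValueError("heights must be a 2-D array")
        if min(self.heights.shape) < MIN_GRID:
            raise ValueError(
                f"height grid must be at least {MIN_GRID}x{MIN_GRID}, "
                f"got {self.heights.shape}"
            )
        if not np.all(np.isfinite(self.heights)):
            raise ValueError("heights must all be finite")
        if not self.pixel_size_nm > 0:
            raise ValueError("pixel_size_nm must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape

    @property
    def extent_nm(self) -> tuple[float, float]:
        """Physical size ``(width, height)`` of the image in nm."""
        rows, cols = self.heights.shape
        return ((cols - 1) * self.pixel_size_nm, (rows - 1) * self.pixel_size_nm)

    def copy(self) -> "Topograph":
        return Topograph(
            self.heights.copy(), self.pixel_size_nm, self.origin, dict(self.meta)
        )

    def with_heights(self, heights: np.ndarray, **extra_meta: Any) -> "Topograph":
        """Return a new topograph sharing this one's geometry and metadata."""
        meta = dict(self.meta)
        meta.update(extra_meta)
        return Topograph(heights, self.pixel_size_nm, self.origin, meta)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def _write_sidecar(topo: Topograph, path: Path) -> None:
    record = {
        "pixel_size_nm": float(topo.pixel_size_nm),
        "origin": topo.origin,
        "meta": _plain(topo.meta),
    }
    _sidecar_path(path).write_text(yaml.safe_dump(record, sort_keys=False))


def _plain(obj: Any) -> Any:
    """Recursively convert numpy scalars/arrays so YAML can serialise them."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def _read_sidecar(path: Path) -> dict[str, Any]:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"missing sidecar {sidecar.name}: topographs need a YAML sidecar "
            "with at least pixel_size_nm"
        )
    return yaml.safe_load(sidecar.read_text())


def save_txt(topo: Topograph, path: str | Path) -> Path:
    """Write as a plain-text matrix (nm values) plus YAML sidecar."""
    path = Path(path)
    np.savetxt(path, topo.heights, fmt="%.6g")
    _write_sidecar(topo, path)
    return path


def load_txt(path: str | Path) -> Topograph:
    path = Path(path)
    record = _read_sidecar(path)
    heights = np.loadtxt(path)
    return Topograph(
        heights,
        float(record["pixel_size_nm"]),
        record.get("origin", "upper"),
        record.get("meta") or {},
    )


def save_tiff(topo: Topograph, path: str | Path) -> Path:
    """Write as a 32-bit float grayscale TIFF plus YAML sidecar."""
    path = Path(path)
    tifffile.imwrite(path, topo.heights.astype(np.float32))
    _write_sidecar(topo, path)
    return path


def load_tiff(path: str | Path) -> Topograph:
    path = Path(path)
    record = _read_sidecar(path)
    heights = tifffile.imread(path).astype(float)
    return Topograph(
        heights,
        float(record["pixel_size_nm"]),
        record.get("origin", "upper"),
        record.get("meta") or {},
    )


def load(path: str | Path) -> Topograph:
    """Load a topograph, dispatching on file extension (.txt/.dat vs .tif)."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        return load_tiff(path)
    return load_txt(path)
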