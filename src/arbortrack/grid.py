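"""Voxel grids: 3D image volumes with physical voxel spacing.

Axis convention throughout the package: arrays are indexed ``[z, y, x]``
(page, row, column, matching multi-page TIFF), while physical coordinates
and spacing tuples are ordered ``(x, y, z)`` in μm with the origin at the
stack corner. ``kind`` distinguishes raw intensity volumes, binary masks
and connected-component label maps.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
import yaml

__all__ = ["VoxelGrid", "read_stack", "write_stack"]


@dataclass
class VoxelGrid:
    values: np.ndarray  # 3D, indexed [z, y, x]
    spacing: tuple[float, float, float]  # (dx, dy, dz) in μm
    kind: str = "intensity"  # intensity | binary | labels

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or self.values.size == 0:
            raise ValueError("values must be a non-empty 3D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive lengths, got {self.spacing}")
        if self.kind not in ("intensity", "binary", "labels"):
            raise ValueError(f"unknown grid kind {self.kind!r}")
        if self.kind == "binary":
            uniq = np.unique(self.values)
            if not np.all(np.isin(uniq, [0, 1])):
                raise ValueError("binary grids may contain only {0, 1}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def spacing_zyx(self) -> tuple[float, float, float]:
        dx, dy, dz = self.spacing
        return (dz, dy, dx)

    def voxel_volume(self) -> float:
        """Volume of one voxel in μm³."""
        dx, dy, dz = self.spacing
        return dx * dy * dz

    def index_to_um(self, indices: np.ndarray) -> np.ndarray:
        """Map (n, 3) ``[z, y, x]`` voxel indices to (n, 3) (x, y, z) μm coordinates
        of voxel centers."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        dz, dy, dx = self.spacing_zyx
        return np.column_stack(
            [(idx[:, 2] + 0.5) * dx, (idx[:, 1] + 0.5) * dy, (idx[:, 0] + 0.5) * dz]
        )

    def um_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map (n, 3) (x, y, z) μm coordinates to fractional ``[z, y, x]`` indices."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        dx, dy, dz = self.spacing
        return np.column_stack(
            [pts[:, 2] / dz - 0.5, pts[:, 1] / dy - 0.5, pts[:, 0] / dx - 0.5]
        )


def write_stack(grid: VoxelGrid, path: str | Path) -> None:
    """Write a grid as multi-page TIFF plus a YAML sidecar recording spacing/kind."""
    path = Path(path)
    values = grid.values
    if grid.kind in ("binary", "labels"):
        values = values.astype(np.uint16)
    else:
        values = values.astype(np.float32)
    tifffile.imwrite(path, values)
    sidecar = path.with_suffix(path.suffix + ".yaml")
    with open(sidecar, "w") as fh:
        yaml.safe_dump({"spacing_um_xyz": list(grid.spacing), "kind": grid.kind}, fh)


def read_stack(path: str | Path, spacing: tuple[float, float, float] | None = None) -> VoxelGrid:
    """Read a multi-page TIFF; spacing from the YAML sidecar unless given explicitly."""
    path = Path(path)
    values = tifffile.imread(path)
    kind = "intensity"
    sidecar = path.with_suffix(path.suffix + ".yaml")
    if spacing is None:
        if not sidecar.exists():
            raise FileNotFoundError(
                f"no spacing given and no sidecar {sidecar.name}; cannot scale voxels"
            )
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh)
        spacing = tuple(meta["spacing_um_xyz"])
        kind = meta.get("kind", "intensity")
    return VoxelGrid(values, spacing, kind=kind)
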