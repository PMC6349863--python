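"""Desk-scale analysis geometry: a grid-graph cortical surface and a voxel skeleton.

Real analyses run on ~41k-vertex hemisphere meshes and a tract skeleton inside
a registered volume. For simulation and testing we use a small structured
stand-in: surface vertices on a 2-D grid graph (optionally periodic, i.e. a
torus, which makes every vertex degree equal) and a skeleton defined as an
explicit list of voxel coordinates inside a small 3-D grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError


@dataclass(frozen=True)
class Geometry:
    """Shared location index for surface and skeleton analyses.

    Parameters
    ----------
    surface_shape:
        (rows, cols) of the surface grid graph; vertex ids are row-major.
    grid_shape:
        Voxel counts per axis of the 3-D volume grid.
    skeleton_index:
        (K, 3) integer voxel coordinates of skeleton voxels, unique, in-grid.
    voxel_size_mm:
        Isotropic voxel edge length.
    vertex_spacing_mm:
        Edge length between adjacent surface vertices (used to translate a
        smoothing FWHM in mm into iterations of neighbour averaging).
    periodic_surface:
        If True the surface grid wraps around (torus): a regular closed graph
        on which neighbour averaging exactly preserves the map mean.
    """

    surface_shape: tuple[int, int] = (50, 40)
    grid_shape: tuple[int, int, int] = (20, 20, 20)
    skeleton_index: np.ndarray = field(default=None)  # type: ignore[assignment]
    voxel_size_mm: float = 2.0
    vertex_spacing_mm: float = 3.0
    periodic_surface: bool = False

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.surface_shape):
            raise ConfigurationError("surface_shape entries must be >= 1")
        if any(s < 1 for s in self.grid_shape):
            raise ConfigurationError("grid_shape entries must be >= 1")
        if self.skeleton_index is None:
            object.__setattr__(
                self, "skeleton_index", _default_skeleton(self.grid_shape)
            )
        idx = np.asarray(self.skeleton_index, dtype=np.intp)
        if idx.ndim != 2 or idx.shape[1] != 3 or idx.shape[0] < 1:
            raise ConfigurationError("skeleton_index must be a non-empty (K, 3) array")
        if (idx < 0).any() or (idx >= np.asarray(self.grid_shape)).any():
            raise ConfigurationError("skeleton_index contains out-of-grid voxels")
        if len(np.unique(np.ravel_multi_index(idx.T, self.grid_shape))) != len(idx):
            raise ConfigurationError("skeleton_index contains duplicate voxels")
        object.__setattr__(self, "skeleton_index", idx)

    @property
    def n_vertices(self) -> int:
        return self.surface_shape[0] * self.surface_shape[1]

    @property
    def n_skeleton_voxels(self) -> int:
        return int(self.skeleton_index.shape[0])

    def n_locations(self, space: str) -> int:
        if space == "surface":
            return self.n_vertices
        if space == "skeleton":
            return self.n_skeleton_voxels
        raise ConfigurationError(f"unknown space {space!r}")

    def surface_adjacency(self) -> list[np.ndarray]:
        """Neighbour lists of the surface grid graph (4-neighbourhood).

        Symmetric by construction; on a periodic surface every vertex has
        exactly 4 neighbours.
        """
        rows, cols = self.surface_shape
        adj: list[np.ndarray] = []
        for r in range(rows):
            for c in range(cols):
                nbrs = []
                for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                    rr, cc = r + dr, c + dc
                    if self.periodic_surface:
                        rr, cc = rr % rows, cc % cols
                    elif not (0 <= rr < rows and 0 <= cc < cols):
                        continue
                    nbrs.append(rr * cols + cc)
                adj.append(np.array(sorted(set(nbrs)), dtype=np.intp))
        return adj

    def skeleton_mask_volume(self) -> np.ndarray:
        """Binary 3-D volume with 1 at skeleton voxels."""
        vol = np.zeros(self.grid_shape, dtype=np.uint8)
        vol[tuple(self.skeleton_index.T)] = 1
        return vol

    def embed_skeleton_values(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter per-skeleton-voxel values into a full 3-D volume."""
        values = np.asarray(values, dtype=float)
        if values.shape[-1] != self.n_skeleton_voxels:
            raise ConfigurationError(
                f"expected {self.n_skeleton_voxels} skeleton values, got {values.shape[-1]}"
            )
        vol = np.full(self.grid_shape, fill, dtype=float)
        vol[tuple(self.skeleton_index.T)] = values
        return vol

    def extract_skeleton_values(self, volume: np.ndarray) -> np.ndarray:
        volume = np.asarray(volume)
        if volume.shape != self.grid_shape:
            raise ConfigurationError(
                f"volume shape {volume.shape} does not match grid {self.grid_shape}"
            )
        return volume[tuple(self.skeleton_index.T)].astype(float)

    def to_dict(self) -> dict:
        return {
            "surface_shape": list(self.surface_shape),
            "grid_shape": list(self.grid_shape),
            "skeleton_index": self.skeleton_index.tolist(),
            "voxel_size_mm": self.voxel_size_mm,
            "vertex_spacing_mm": self.vertex_spacing_mm,
            "periodic_surface": self.periodic_surface,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Geometry":
        return cls(
            surface_shape=tuple(d["surface_shape"]),
            grid_shape=tuple(d["grid_shape"]),
            skeleton_index=np.asarray(d["skeleton_index"], dtype=np.intp),
            voxel_size_mm=float(d["voxel_size_mm"]),
            vertex_spacing_mm=float(d["vertex_spacing_mm"]),
            periodic_surface=bool(d.get("periodic_surface", False)),
        )

    @classmethod
    def toy(cls, periodic_surface: bool = False) -> "Geometry":
        """Default desk-scale geometry: 2000 surface vertices, ~1.2k skeleton voxels."""
        return cls(periodic_surface=periodic_surface)


def _default_skeleton(grid_shape: tuple[int, int, int]) -> np.ndarray:
    """A deterministic tract-like skeleton: an axial sheet crossed by a sagittal sheet.

    On the default 20^3 grid this yields 1184 voxels, a desk-scale stand-in
    for a white-matter tract skeleton.
    """
    nx, ny, nz = grid_shape
    vox = set()
    x0, x1 = max(0, nx // 10), min(nx, nx - nx // 10)
    y0, y1 = max(0, ny // 10), min(ny, ny - ny // 10)
    z0, z1 = max(0, nz // 10), min(nz, nz - nz // 10)
    zc = nz // 2
    for x in range(x0, x1):
        for y in range(y0, y1):
            for z in range(max(0, zc - 1), min(nz, zc + 2)):
                vox.add((x, y, z))
    yc = ny // 2
    for x in range(x0, x1):
        for y in (yc - 1, yc):
            for z in range(z0, z1):
                if 0 <= y < ny:
                    vox.add((x, y, z))
    return np.array(sorted(vox), dtype=np.intp)
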