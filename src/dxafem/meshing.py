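"""Structured planar meshing of a binary femur silhouette.

The mesh is a pixel-aligned grid of square 4-node quadrilaterals clipped to
the mask: one element per foreground cell of the (possibly resampled) mask.
Node coordinates are physical millimetres in a y-up frame (row 0 of the image
is the top of the femur, so y = (n_rows - i) * h for node-grid row i).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

# orthogonal (4-) connectivity: diagonal-only contact would produce elements
# coupled through a single node, i.e. a mechanism
_CROSS = ndimage.generate_binary_structure(2, 1)


@dataclass
class PlanarMesh:
    """Constant-thickness 2D plate mesh of square bilinear quadrilaterals."""

    nodes: np.ndarray      # (n_nodes, 2) xy in mm, y-up
    elements: np.ndarray   # (n_elem, 4) node indices, counter-clockwise
    thickness_t: float     # mm, uniform
    elem_size_mm: float
    #: (row, col) of the mask cell each element was cut from
    elem_cells: np.ndarray = field(repr=False, default=None)
    grid_shape: tuple[int, int] = (0, 0)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)

    def area(self) -> float:
        """Total mesh area in mm^2 (elements are squares of the target size)."""
        return self.n_elements * self.elem_size_mm**2

    def boundary_nodes(self) -> np.ndarray:
        """Indices of nodes on the mesh boundary (on an edge used by 1 element)."""
        edges = np.concatenate(
            [self.elements[:, [k, (k + 1) % 4]] for k in range(4)]
        )
        edges_sorted = np.sort(edges, axis=1)
        _, inverse, counts = np.unique(
            edges_sorted, axis=0, return_inverse=True, return_counts=True
        )
        free = edges[counts[inverse] == 1]
        return np.unique(free)


def resample_mask(mask: np.ndarray, spacing_mm: float, target_mm: float) -> np.ndarray:
    """Nearest-neighbour resampling of the mask onto the element grid."""
    if abs(spacing_mm - target_mm) < 1e-12:
        return np.asarray(mask, dtype=bool)
    zoom = spacing_mm / target_mm
    return ndimage.zoom(np.asarray(mask, dtype=bool), zoom, order=0)


def build_mesh(
    femur_mask: np.ndarray,
    spacing_mm: float,
    target_elem_size_mm: float = 0.5,
    thickness_t: float = 1.0,
) -> PlanarMesh:
    """Mesh the femur mask with square plane-stress quadrilaterals.

    Raises ``ValueError`` when the mask splits into several orthogonally
    connected components (the message names their number).
    """
    if thickness_t <= 0:
        raise ValueError("plate thickness must be > 0")
    cells = resample_mask(femur_mask, spacing_mm, target_elem_size_mm)
    if not cells.any():
        raise ValueError("empty femur mask")
    _, n_comp = ndimage.label(cells, structure=_CROSS)
    if n_comp != 1:
        raise ValueError(
            f"femur mask has {n_comp} connected components; expected 1"
        )
    h = target_elem_size_mm
    n_rows, n_cols = cells.shape
    rows, cols = np.nonzero(cells)

    # node grid: (n_rows+1) x (n_cols+1) cell corners, only used ones kept
    corner_ids = -np.ones((n_rows + 1, n_cols + 1), dtype=np.int64)
    # CCW in the y-up frame: BL, BR, TR, TL of each cell
    corner_offsets = ((1, 0), (1, 1), (0, 1), (0, 0))
    corners_ij = np.stack(
        [np.stack([rows + di, cols + dj], axis=1) for di, dj in corner_offsets],
        axis=1,
    )  # (n_elem, 4, 2)
    flat = corners_ij.reshape(-1, 2)
    used = np.zeros((n_rows + 1, n_cols + 1), dtype=bool)
    used[flat[:, 0], flat[:, 1]] = True
    ui, uj = np.nonzero(used)
    corner_ids[ui, uj] = np.arange(len(ui))
    nodes = np.stack([uj * h, (n_rows - ui) * h], axis=1).astype(float)
    elements = corner_ids[corners_ij[..., 0], corners_ij[..., 1]]

    return PlanarMesh(
        nodes=nodes,
        elements=elements,
        thickness_t=float(thickness_t),
        elem_size_mm=h,
        elem_cells=np.stack([rows, cols], axis=1),
        grid_shape=(n_rows, n_cols),
    )


def elements_in_mask(mesh: PlanarMesh, region_mask: np.ndarray, spacing_mm: float) -> np.ndarray:
    """Boolean selector of elements whose source pixel lies in ``region_mask``.

    The region mask is given at the original image spacing; it is resampled to
    the element grid first.
    """
    cells = resample_mask(region_mask, spacing_mm, mesh.elem_size_mm)
    cells = _pad_to(cells, mesh.grid_shape)
    return cells[mesh.elem_cells[:, 0], mesh.elem_cells[:, 1]]


def _pad_to(arr: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Pad/crop a resampled mask to the mesh grid shape (rounding artefacts)."""
    out = np.zeros(shape, dtype=bool)
    r = min(shape[0], arr.shape[0])
    c = min(shape[1], arr.shape[1])
    out[:r, :c] = arr[:r, :c]
    return out


def nearest_pixel(
    centroids_mm: np.ndarray, spacing_mm: float, image_shape: tuple[int, int]
) -> np.ndarray:
    """Map element centroids (y-up mm) to their closest image pixel (row, col)."""
    n_rows, _ = image_shape
    col = np.clip((centroids_mm[:, 0] / spacing_mm).astype(int), 0, image_shape[1] - 1)
    row = np.clip(
        (n_rows - centroids_mm[:, 1] / spacing_mm).astype(int), 0, n_rows - 1
    )
    return np.stack([row, col], axis=1)
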