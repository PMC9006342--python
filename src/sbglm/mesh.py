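"""Triangulated surface meshes.

The spatial unit of analysis is a vertex of a triangulated cortical
surface (e.g. a midthickness surface).  A mesh may carry more vertices
than there are data locations: medial-wall or boundary "padding"
vertices participate in the spatial model (they stabilise estimation
along the data boundary) but carry no BOLD data.  The ``data_mask``
distinguishes the two.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp


class MeshError(ValueError):
    """Raised when a mesh violates its structural invariants."""


@dataclass
class TriangularMesh:
    """A triangulated surface with a data-location mask.

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex coordinates in millimetres.
    faces : (m, 3) int array
        Triples of vertex indices, counter-clockwise winding.
    data_mask : (n,) bool array, optional
        True where BOLD data live; False for padding vertices
        (medial wall, boundary ring).  Defaults to all-True.
    """

    vertices: np.ndarray
    faces: np.ndarray
    data_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshError("faces must be an (m, 3) array")
        n = self.n_vertices
        if self.data_mask is None:
            self.data_mask = np.ones(n, dtype=bool)
        self.data_mask = np.asarray(self.data_mask, dtype=bool)
        if self.data_mask.shape != (n,):
            raise MeshError("data_mask length must equal the vertex count")
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= n):
            raise MeshError("face indices out of range")
        areas = self.triangle_areas()
        bad = np.flatnonzero(areas <= 0)
        if bad.size:
            raise MeshError(f"degenerate (zero-area) triangle at face {bad[0]}")
        # each undirected edge may be shared by at most two triangles
        edges = np.sort(
            np.concatenate(
                [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
            ),
            axis=1,
        )
        _, counts = np.unique(edges, axis=0, return_counts=True)
        if counts.size and counts.max() > 2:
            raise MeshError("non-manifold edge: shared by more than two faces")
        if not self.data_mask.any():
            raise MeshError("mesh has no data locations")

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]

    @property
    def n_data(self) -> int:
        return int(self.data_mask.sum())

    @property
    def data_indices(self) -> np.ndarray:
        return np.flatnonzero(self.data_mask)

    def triangle_areas(self) -> np.ndarray:
        p = self.vertices
        f = self.faces
        cross = np.cross(p[f[:, 1]] - p[f[:, 0]], p[f[:, 2]] - p[f[:, 0]])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def edge_length_graph(self) -> sp.csr_matrix:
        """Sparse symmetric graph of mesh edges weighted by Euclidean length.

        Used for graph-geodesic distances (kernel smoothing and
        diagnostics); edge lengths on a well-resolved surface are a good
        proxy for geodesic distance along the surface.
        """
        i = np.concatenate([self.faces[:, 0], self.faces[:, 1], self.faces[:, 2]])
        j = np.concatenate([self.faces[:, 1], self.faces[:, 2], self.faces[:, 0]])
        w = np.linalg.norm(self.vertices[i] - self.vertices[j], axis=1)
        n = self.n_vertices
        g = sp.coo_matrix((w, (i, j)), shape=(n, n)).tocsr()
        g = g.maximum(g.T)
        return g

    def with_data_mask(self, mask: np.ndarray) -> "TriangularMesh":
        return TriangularMesh(self.vertices.copy(), self.faces.copy(), np.asarray(mask, bool))
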