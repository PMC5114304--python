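"""ROI atlases on surface meshes.

The default layout mimics a myeloarchitectonic parcellation: a set of
heavily myelinated sensory/motor analogs (somatosensory and motor strips,
early visual areas, MT, auditory gyrus/sulcus), moderately myelinated
premotor/frontal analogs, one lightly myelinated retrosplenial analog, and
a lightly myelinated background filling the rest of the cortex.  Each named
region is grown as a contiguous patch from a seed vertex; the background is
everything left over, which guarantees every patch borders lightly
myelinated cortex — the neighbor region used as the contrast reference in
CNR computations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError, LayoutError
from .mesh import SurfaceMesh

__all__ = ["RegionInfo", "ROIAtlas", "build_atlas", "DEFAULT_LAYOUT"]

BACKGROUND_LABEL = 0

#: Default region layout: name, myelination class, fraction of vertices.
DEFAULT_LAYOUT = {
    "regions": [
        {"name": "BA1", "class": "heavy", "fraction": 0.03},
        {"name": "BA2", "class": "heavy", "fraction": 0.03},
        {"name": "BA3", "class": "heavy", "fraction": 0.03},
        {"name": "BA4", "class": "heavy", "fraction": 0.03},
        {"name": "V1", "class": "heavy", "fraction": 0.04},
        {"name": "V2", "class": "heavy", "fraction": 0.04},
        {"name": "MT", "class": "heavy", "fraction": 0.02},
        {"name": "gTT", "class": "heavy", "fraction": 0.02},
        {"name": "sTT", "class": "heavy", "fraction": 0.02},
        {"name": "BA6", "class": "moderate", "fraction": 0.04},
        {"name": "BA44", "class": "moderate", "fraction": 0.03},
        {"name": "BA45", "class": "moderate", "fraction": 0.03},
        {"name": "RSC", "class": "light", "fraction": 0.02},
    ],
    "background_name": "BG",
}

_CLASSES = ("heavy", "moderate", "light")


@dataclass(frozen=True)
class RegionInfo:
    name: str
    myelin_class: str
    neighbor_label: int | None  # lightly myelinated contrast reference


@dataclass
class ROIAtlas:
    """Per-vertex integer labels plus a region table."""

    labels: np.ndarray
    table: dict  # label -> RegionInfo

    def vertices_of(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.labels == label)

    @property
    def region_labels(self) -> list:
        """Named (non-background) region labels in table order."""
        return [lb for lb in self.table if lb != BACKGROUND_LABEL]

    def label_by_name(self, name: str) -> int:
        for lb, info in self.table.items():
            if info.name == name:
                return lb
        raise KeyError(name)

    def validate(self, mesh: SurfaceMesh):
        if len(self.labels) != mesh.n_vertices:
            raise LayoutError("label map does not cover the vertex set")
        for lb, info in self.table.items():
            if not np.any(self.labels == lb):
                raise LayoutError(f"region {info.name!r} is empty on the mesh")
        for lb, info in self.table.items():
            if info.neighbor_label is None:
                continue
            nb_info = self.table[info.neighbor_label]
            if nb_info.myelin_class != "light":
                raise LayoutError(
                    f"neighbor of {info.name!r} is not lightly myelinated")
            if not self._shares_edge(mesh, lb, info.neighbor_label):
                raise LayoutError(
                    f"region {info.name!r} does not touch its neighbor region")

    def _shares_edge(self, mesh: SurfaceMesh, a: int, b: int) -> bool:
        e = mesh.edges()
        la, lbb = self.labels[e[:, 0]], self.labels[e[:, 1]]
        return bool(np.any(((la == a) & (lbb == b)) | ((la == b) & (lbb == a))))


def _bfs_hops(mesh: SurfaceMesh, sources: list) -> np.ndarray:
    dist = np.full(mesh.n_vertices, np.iinfo(np.int64).max, dtype=np.int64)
    frontier = list(sources)
    for s in sources:
        dist[s] = 0
    d = 0
    while frontier:
        d += 1
        nxt = []
        for v in frontier:
            for w in mesh.neighbors[v]:
                if dist[w] > d:
                    dist[w] = d
                    nxt.append(int(w))
        frontier = nxt
    return dist


def build_atlas(mesh: SurfaceMesh, layout: dict | None = None) -> ROIAtlas:
    """Grow a contiguous ROI atlas on ``mesh``.

    Seeds are placed by greedy farthest-point sampling in graph distance and
    regions grown ring-by-ring in round-robin order until each reaches its
    vertex budget.  Unclaimed vertices become lightly myelinated background.
    """
    layout = DEFAULT_LAYOUT if layout is None else layout
    regions = layout["regions"]
    if len(regions) < 2:
        raise InvalidArgumentError("layout must name at least 2 regions")
    classes = {r["class"] for r in regions}
    for c in classes:
        if c not in _CLASSES:
            raise InvalidArgumentError(f"unknown myelination class {c!r}")
    if "heavy" not in classes:
        raise InvalidArgumentError("layout needs at least one heavy region")

    n = mesh.n_vertices
    budgets = [max(1, int(round(r.get("fraction", 0.03) * n))) for r in regions]
    if sum(budgets) + 1 > n or len(regions) + 1 > n:
        raise LayoutError("mesh too small to host the requested regions contiguously")

    # farthest-point seeds
    seeds = [0]
    for _ in range(len(regions) - 1):
        d = _bfs_hops(mesh, seeds)
        cand = int(np.argmax(d))
        if d[cand] == 0:
            raise LayoutError("cannot separate region seeds on this mesh")
        seeds.append(cand)

    labels = np.full(n, BACKGROUND_LABEL, dtype=np.int64)
    frontiers = []
    for k, s in enumerate(seeds):
        labels[s] = k + 1
        frontiers.append([s])
    sizes = [1] * len(regions)

    grown = True
    while grown:
        grown = False
        for k in range(len(regions)):
            if sizes[k] >= budgets[k] or not frontiers[k]:
                continue
            ring = []
            for v in frontiers[k]:
                for w in mesh.neighbors[v]:
                    if labels[w] == BACKGROUND_LABEL and sizes[k] < budgets[k]:
                        labels[w] = k + 1
                        sizes[k] += 1
                        ring.append(int(w))
            frontiers[k] = ring
            if ring:
                grown = True

    if not np.any(labels == BACKGROUND_LABEL):
        raise LayoutError("layout leaves no background; reduce region fractions")

    table = {BACKGROUND_LABEL: RegionInfo(layout.get("background_name", "BG"),
                                          "light", None)}
    for k, r in enumerate(regions):
        table[k + 1] = RegionInfo(r["name"], r["class"], BACKGROUND_LABEL)

    atlas = ROIAtlas(labels, table)
    atlas.validate(mesh)
    return atlas
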