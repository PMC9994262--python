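"""Pore bottleneck estimation through an atomic wall.

A scene of van-der-Waals spheres is discretized onto a regular grid of
clearance values (distance to the nearest sphere surface).  The widest
passage between two points is found as the max-min ("bottleneck") path over
26-connected grid moves: a priority-first search that greedily expands the
node with the largest attainable minimum clearance.  The reported bottleneck
diameter is twice the smallest clearance along that path — the diameter of
the largest sphere that can traverse the route, a grid stand-in for
Voronoi-based tunnel tools.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .structure_io import VDW_RADIUS

__all__ = ["PoreScene", "TunnelResult", "clearance_field", "widest_path",
           "slit_survey", "scene_from_table"]


@dataclass(frozen=True)
class PoreScene:
    """Atom spheres plus the start/end probe points of a tunnel search."""

    centers: np.ndarray
    radii: np.ndarray
    start: np.ndarray
    end: np.ndarray
    box_min: np.ndarray = field(default=None)
    box_max: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        centers = np.atleast_2d(np.asarray(self.centers, float))
        radii = np.atleast_1d(np.asarray(self.radii, float))
        if len(radii) != len(centers):
            raise ValueError("centers and radii length mismatch")
        if np.any(radii <= 0):
            raise ValueError("van der Waals radii must be positive")
        start = np.asarray(self.start, float)
        end = np.asarray(self.end, float)
        for name, point in (("start", start), ("end", end)):
            if len(centers) and np.any(np.linalg.norm(centers - point, axis=1) < radii):
                raise ValueError(f"{name} point lies inside an atom sphere")
        box_min = self.box_min
        box_max = self.box_max
        if box_min is None or box_max is None:
            pts = np.vstack([centers, start[None], end[None]]) if len(centers) \
                else np.vstack([start[None], end[None]])
            pad = radii.max() + 2.0 if len(centers) else 2.0
            box_min = pts.min(axis=0) - pad
            box_max = pts.max(axis=0) + pad
        object.__setattr__(self, "centers", centers)
        object.__setattr__(self, "radii", radii)
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "end", end)
        object.__setattr__(self, "box_min", np.asarray(box_min, float))
        object.__setattr__(self, "box_max", np.asarray(box_max, float))


@dataclass(frozen=True)
class TunnelResult:
    path: np.ndarray
    clearance: np.ndarray
    bottleneck: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "path", np.asarray(self.path, float))
        object.__setattr__(self, "clearance", np.asarray(self.clearance, float))


def _grid_axes(scene: PoreScene, spacing: float):
    axes = []
    for lo, hi in zip(scene.box_min, scene.box_max):
        n = max(int(np.ceil((hi - lo) / spacing)) + 1, 2)
        axes.append(lo + np.arange(n) * spacing)
    return axes


def clearance_field(scene: PoreScene, spacing: float = 0.25
                    ) -> tuple[np.ndarray, list[np.ndarray]]:
    """Clearance (min over atoms of distance-to-surface) on a regular grid.

    Returns ``(field, axes)``; values are negative inside atoms.  Empty
    scenes get a large positive clearance bounded by the box diagonal.
    """
    if spacing <= 0:
        raise ValueError("grid spacing must be positive")
    axes = _grid_axes(scene, spacing)
    shape = tuple(len(a) for a in axes)
    if len(scene.centers) == 0:
        diag = float(np.linalg.norm(scene.box_max - scene.box_min))
        return np.full(shape, diag), axes
    xs, ys, zs = np.meshgrid(*axes, indexing="ij")
    nodes = np.column_stack([xs.ravel(), ys.ravel(), zs.ravel()])
    # exact minimum over atoms: one nearest-neighbor query per distinct radius
    from scipy.spatial import cKDTree

    field = np.full(len(nodes), np.inf)
    for radius in np.unique(scene.radii):
        tree = cKDTree(scene.centers[scene.radii == radius])
        d, _ = tree.query(nodes, k=1)
        np.minimum(field, d - radius, out=field)
    return field.reshape(shape), axes


def _nearest_node(axes, point) -> tuple[int, int, int]:
    return tuple(int(np.clip(np.rint((p - a[0]) / (a[1] - a[0])), 0, len(a) - 1))
                 for a, p in zip(axes, point))


_NEIGHBORS = np.array([d for d in itertools.product((-1, 0, 1), repeat=3)
                       if d != (0, 0, 0)])


_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def widest_path(scene: PoreScene, spacing: float = 0.25) -> TunnelResult:
    """Max-min clearance path from scene.start to scene.end on the grid.

    The bottleneck clearance c* is the largest threshold at which start and
    end stay 26-connected within {clearance >= threshold}; it is found by
    bisection over the sorted node clearances using connected-component
    labelling.  A breadth-first wavefront on that super-level set then
    recovers one shortest realizing path, deterministically (backtracking
    ties broken by lexicographic node order).  Equivalent to a priority-
    first maximin search, but vectorized.
    """
    from scipy import ndimage

    field, axes = clearance_field(scene, spacing)
    start = _nearest_node(axes, scene.start)
    end = _nearest_node(axes, scene.end)
    for name, node in (("start", start), ("end", end)):
        if field[node] <= 0:
            raise ValueError(f"{name} point has non-positive clearance on the grid; "
                             "refine the grid spacing or move the point")

    def connected(threshold: float) -> bool:
        mask = field >= threshold
        labels, _ = ndimage.label(mask, structure=_STRUCT26)
        return labels[start] != 0 and labels[start] == labels[end]

    cap = min(field[start], field[end])
    candidates = np.unique(field[(field > 0) & (field <= cap)])
    if len(candidates) == 0 or not connected(candidates[0]):
        raise ValueError("start and end are disconnected at this grid spacing")
    lo, hi = 0, len(candidates) - 1  # connected(candidates[lo]) is True
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if connected(candidates[mid]):
            lo = mid
        else:
            hi = mid - 1
    c_star = float(candidates[lo])

    # shortest path within the super-level set by vectorized BFS
    mask = field >= c_star
    dist = np.full(field.shape, -1, dtype=np.int32)
    frontier = np.zeros(field.shape, dtype=bool)
    frontier[start] = True
    dist[start] = 0
    step = 0
    while dist[end] < 0:
        step += 1
        reached = dist >= 0
        frontier = ndimage.binary_dilation(frontier, structure=_STRUCT26) \
            & mask & ~reached
        if not frontier.any():  # pragma: no cover - guarded by connectivity
            raise ValueError("path reconstruction failed")
        dist[frontier] = step
    nodes = [end]
    shape = field.shape
    while nodes[-1] != start:
        node = nodes[-1]
        target = dist[node] - 1
        best_nb = None
        for delta in _NEIGHBORS:
            nb = (node[0] + delta[0], node[1] + delta[1], node[2] + delta[2])
            if not all(0 <= nb[d] < shape[d] for d in range(3)):
                continue
            if dist[nb] == target and (best_nb is None or nb < best_nb):
                best_nb = nb
        nodes.append(best_nb)
    nodes.reverse()
    path = np.array([[axes[d][idx[d]] for d in range(3)] for idx in nodes])
    clearance = np.array([field[idx] for idx in nodes])
    return TunnelResult(path=path, clearance=clearance,
                        bottleneck=float(2.0 * clearance.min()))


def slit_survey(scene: PoreScene, pairs: list[tuple[np.ndarray, np.ndarray]],
                spacing: float = 0.25) -> list[TunnelResult]:
    """Independent widest-path searches for several start/end pairs."""
    if len(pairs) < 1:
        raise ValueError("need at least one start/end pair")
    results = []
    for start, end in pairs:
        sub = PoreScene(scene.centers, scene.radii, start, end,
                        box_min=scene.box_min, box_max=scene.box_max)
        results.append(widest_path(sub, spacing))
    return results


def scene_from_table(path, start, end, sep=None) -> PoreScene:
    """Build a scene from a delimited atom table (x, y, z, element[, radius])."""
    import pandas as pd

    df = pd.read_csv(path, sep=sep, engine="python")
    cols = {c.lower(): c for c in df.columns}
    coords = df[[cols["x"], cols["y"], cols["z"]]].to_numpy(float)
    if "radius" in cols:
        radii = df[cols["radius"]].to_numpy(float)
    elif "element" in cols:
        radii = np.array([VDW_RADIUS.get(str(e).upper(), 1.7)
                          for e in df[cols["element"]]])
    else:
        raise ValueError("atom table needs a 'radius' or 'element' column")
    return PoreScene(coords, radii, np.asarray(start, float), np.asarray(end, float))
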