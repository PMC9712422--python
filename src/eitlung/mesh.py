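"""Thorax cross-section meshing for 16-electrode belt EIT.

The belt plane is modelled as a 2D convex domain (circle or ellipse) scaled to
normalized units: the major diameter is 2, so distances are in units of the
thorax half-width.  Sixteen electrode arcs are placed equally spaced along the
boundary arc length.  Orientation convention (caudal view, used everywhere in
the package): anterior is +y, the subject's left is +x (the viewer's right).
Electrode 1 is centered on the anterior midline and numbering proceeds toward
the subject's left.

Mesh generation is fully deterministic: boundary nodes are sampled at equal
arc-length intervals, interior nodes on concentric scaled rings, and the
triangulation is a Delaunay triangulation of that fixed point set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from scipy.spatial import Delaunay

from .errors import InvalidGeometryError

N_ELECTRODES = 16

__all__ = ["Mesh", "build_thorax_mesh", "N_ELECTRODES"]


@dataclass(frozen=True)
class Mesh:
    """Triangulated thorax cross-section with boundary electrode arcs.

    Attributes
    ----------
    nodes : (N, 2) float array
        Node coordinates in normalized units (domain diameter 2).
    elements : (E, 3) int array
        Triangles as node-index triples, counterclockwise orientation.
    electrode_arcs : tuple of int arrays
        For each of the 16 electrodes, the ordered boundary node indices the
        electrode covers.  Arcs are pairwise disjoint.
    boundary_nodes : int array
        All boundary node indices ordered along the boundary starting at
        electrode 1 and proceeding toward the subject's left.
    shape : str
        ``"circle"`` or ``"ellipse"``.
    axis_ratio : float
        Minor/major axis ratio (1 for a circle).  The major axis is
        left-right (x), as in a thorax cross-section.
    """

    nodes: np.ndarray
    elements: np.ndarray
    electrode_arcs: tuple
    boundary_nodes: np.ndarray
    shape: str = "circle"
    axis_ratio: float = 1.0

    @cached_property
    def element_areas(self) -> np.ndarray:
        p = self.nodes[self.elements]
        return 0.5 * np.abs(
            (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
            - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
        )

    @cached_property
    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    def inside(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the boundary curve."""
        pts = np.atleast_2d(points)
        return (pts[:, 0] ** 2 + (pts[:, 1] / self.axis_ratio) ** 2) <= 1.0 + 1e-12


def _boundary_curve(axis_ratio: float, n_param: int = 20000):
    """Equal-arclength sampler of the boundary.

    Returns a function mapping arc length s in [0, P) to (x, y), measured from
    the anterior midline (top of the ellipse) toward the subject's left (+x),
    together with the perimeter P.
    """
    # parameter t runs clockwise (in math convention) from the top: x = sin(t'),
    # y = ratio*cos(t') with t' in [0, 2*pi)
    t = np.linspace(0.0, 2 * np.pi, n_param, endpoint=False)
    x = np.sin(t)
    y = axis_ratio * np.cos(t)
    dx = np.diff(np.concatenate([x, x[:1]]))
    dy = np.diff(np.concatenate([y, y[:1]]))
    seg = np.hypot(dx, dy)
    s_cum = np.concatenate([[0.0], np.cumsum(seg)])
    perimeter = s_cum[-1]

    def at(s: np.ndarray) -> np.ndarray:
        s = np.asarray(s, dtype=float) % perimeter
        tt = np.interp(s, s_cum, np.concatenate([t, [2 * np.pi]]))
        return np.column_stack([np.sin(tt), axis_ratio * np.cos(tt)])

    return at, perimeter


def build_thorax_mesh(
    boundary_shape: str = "circle",
    target_element_count: int = 800,
    electrode_coverage: float = 0.5,
    axis_ratio: float = 1.0,
) -> Mesh:
    """Build a conforming triangulated thorax mesh with 16 electrode arcs.

    Parameters
    ----------
    boundary_shape : {"circle", "ellipse"}
    target_element_count : int
        Requested number of triangles (>= 64); the result is within 30%.
    electrode_coverage : float in (0, 0.5]
        Fraction of the circumference covered by electrodes in total.
    axis_ratio : float
        Minor/major axis ratio for ``"ellipse"`` (must be > 0); ignored for
        ``"circle"``.
    """
    if boundary_shape not in ("circle", "ellipse"):
        raise InvalidGeometryError(f"unknown boundary shape {boundary_shape!r}")
    if boundary_shape == "circle":
        axis_ratio = 1.0
    if axis_ratio <= 0:
        raise InvalidGeometryError(f"axis ratio must be positive, got {axis_ratio}")
    if target_element_count < 64:
        raise InvalidGeometryError(
            f"target_element_count must be >= 64, got {target_element_count}"
        )
    if not 0 < electrode_coverage <= 0.5:
        raise InvalidGeometryError(
            f"electrode_coverage must be in (0, 0.5], got {electrode_coverage}"
        )

    # boundary node count: multiple of 16 so electrode arcs tile exactly;
    # for a uniform equilateral-ish mesh E ~ 0.184 * n_b^2 on the unit disk,
    # oversampled 1.5x to resolve the electrode contact-impedance layer
    m = max(2, round(1.5 * np.sqrt(target_element_count / 0.184) / N_ELECTRODES))
    n_b = N_ELECTRODES * m

    curve, perimeter = _boundary_curve(axis_ratio)
    s_nodes = np.arange(n_b) * (perimeter / n_b)
    boundary_pts = curve(s_nodes)

    # interior node budget from Euler's relation: E = 2*N_int + n_b - 2
    n_int = max(1, (target_element_count - n_b + 2) // 2)
    interior_pts = _interior_rings(curve, perimeter, axis_ratio, n_b, n_int)

    points = np.vstack([boundary_pts, interior_pts])
    tri = Delaunay(points)
    elements = np.array(tri.simplices, dtype=np.int64)
    elements = _orient_ccw(points, elements)

    # electrode arcs: electrode i centered at boundary node i*m, spanning
    # `span` boundary segments (>= 1)
    span = max(1, round(electrode_coverage * n_b / N_ELECTRODES))
    if span + 1 > m:
        raise InvalidGeometryError(
            "electrode arcs overlap: increase target_element_count or "
            "decrease electrode_coverage"
        )
    arcs = []
    for i in range(N_ELECTRODES):
        start = i * m - span // 2
        arcs.append(np.array([(start + k) % n_b for k in range(span + 1)]))

    return Mesh(
        nodes=points,
        elements=elements,
        electrode_arcs=tuple(arcs),
        boundary_nodes=np.arange(n_b),
        shape=boundary_shape,
        axis_ratio=axis_ratio,
    )


def _interior_rings(curve, perimeter, axis_ratio, n_b, n_int):
    """Place n_int interior nodes on concentric scaled copies of the boundary."""
    n_rings = max(1, round(2 * n_int / n_b))
    weights = np.arange(1, n_rings + 1, dtype=float)
    raw = n_int * weights / weights.sum()
    counts = np.floor(raw).astype(int)
    # largest-remainder allocation to hit n_int exactly
    rem = raw - counts
    for idx in np.argsort(-rem)[: n_int - counts.sum()]:
        counts[idx] += 1
    pts = []
    budget = n_int
    for j in range(n_rings, 0, -1):
        c = min(counts[j - 1], budget)
        if c <= 0:
            continue
        scale = j / (n_rings + 1)
        # stagger alternate rings by half a spacing to avoid slivers
        offset = 0.5 * (perimeter / c) * (j % 2)
        s = offset + np.arange(c) * (perimeter / c)
        pts.append(scale * curve(s))
        budget -= c
    return np.vstack(pts) if pts else np.zeros((0, 2))


def _orient_ccw(points, elements):
    p = points[elements]
    signed = (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1]) - (
        p[:, 2, 0] - p[:, 0, 0]
    ) * (p[:, 1, 1] - p[:, 0, 1])
    flip = signed < 0
    elements = elements.copy()
    elements[flip] = elements[flip][:, [0, 2, 1]]
    return elements
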