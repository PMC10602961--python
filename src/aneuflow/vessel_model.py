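"""Geometric data model for vessel trees and luminal cross-sections.

A vessel tree is a rooted directed tree with a single inlet, internal
branch junctions and two or more outlets.  Each segment (edge) carries a
length and either a circular radius or a full :class:`CrossSection` — a
planar polyline tracing the luminal border, from which the "real"
cross-sectional area is recovered by casting rays from the centerline
anchor to the border and fan-triangulating the hit points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np

__all__ = [
    "CrossSection",
    "VesselTree",
    "SplitResult",
    "polygon_area_raytrace",
    "equivalent_diameter",
    "validate_tree",
    "circular_section",
]

#: Methods recognised by :class:`SplitResult`.
METHODS = ("bc1", "bc2", "bc3", "bc4", "bc5")


@dataclass(frozen=True)
class CrossSection:
    """A planar luminal cross-section.

    Parameters
    ----------
    anchor
        3D point on the vessel centerline, in mm.
    normal
        Unit normal of the section plane.
    boundary
        Ordered (closed) polyline of >= 3 coplanar 3D points, in mm,
        tracing the luminal border around the anchor.
    planarity_tol
        Maximum out-of-plane distance tolerated for boundary points, mm.
    """

    anchor: np.ndarray
    normal: np.ndarray
    boundary: np.ndarray
    planarity_tol: float = 1e-6

    def __post_init__(self) -> None:
        anchor = np.asarray(self.anchor, dtype=float).reshape(3)
        normal = np.asarray(self.normal, dtype=float).reshape(3)
        boundary = np.asarray(self.boundary, dtype=float).reshape(-1, 3)
        nrm = np.linalg.norm(normal)
        if nrm == 0:
            raise ValueError("section normal must be non-zero")
        object.__setattr__(self, "anchor", anchor)
        object.__setattr__(self, "normal", normal / nrm)
        object.__setattr__(self, "boundary", boundary)
        if len(boundary) < 3:
            raise ValueError("boundary polyline needs at least 3 points")

    # -- plane frame -------------------------------------------------
    def plane_basis(self) -> tuple[np.ndarray, np.ndarray]:
        """In-plane orthonormal basis (e1, e2).

        e1 is the projection of the global +x axis onto the plane; if that
        projection is degenerate (normal ~ +x), +y is projected instead.
        This fixes the phase of the ray fan so results are reproducible.
        """
        for trial in (np.array([1.0, 0, 0]), np.array([0, 1.0, 0])):
            e1 = trial - np.dot(trial, self.normal) * self.normal
            n1 = np.linalg.norm(e1)
            if n1 > 1e-8:
                e1 = e1 / n1
                e2 = np.cross(self.normal, e1)
                return e1, e2
        raise RuntimeError("unreachable: +x and +y cannot both align with the normal")

    def to_plane(self, points: np.ndarray) -> np.ndarray:
        """Project 3D points to 2D plane coordinates centred on the anchor."""
        e1, e2 = self.plane_basis()
        rel = np.asarray(points, dtype=float) - self.anchor
        return np.column_stack([rel @ e1, rel @ e2])

    def out_of_plane_error(self) -> float:
        rel = self.boundary - self.anchor
        return float(np.max(np.abs(rel @ self.normal))) if len(rel) else 0.0


@dataclass(frozen=True)
class SplitResult:
    """Per-outlet flow fractions produced by one splitting strategy."""

    method: str
    fractions: dict[str, float]

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {total!r}, not 1")
        if any(f < 0 for f in self.fractions.values()):
            raise ValueError("fractions must be non-negative")

    def as_array(self, order: list[str]) -> np.ndarray:
        return np.array([self.fractions[o] for o in order])


class VesselTree:
    """Rooted directed tree of vessel segments.

    Nodes are string identifiers; exactly one node has kind ``"inlet"``,
    leaves have kind ``"outlet"`` and internal nodes kind ``"junction"``.
    Each directed edge parent->child carries ``length`` (mm) and either
    ``radius`` (mm, circular section) or ``section`` (:class:`CrossSection`).
    """

    def __init__(self) -> None:
        self.graph = nx.DiGraph()

    # -- construction ------------------------------------------------
    def add_node(self, node_id: str, kind: str) -> None:
        if kind not in ("inlet", "junction", "outlet"):
            raise ValueError(f"unknown node kind {kind!r}")
        self.graph.add_node(node_id, kind=kind)

    def add_segment(
        self,
        parent: str,
        child: str,
        *,
        length: float,
        radius: float | None = None,
        section: CrossSection | None = None,
    ) -> None:
        if radius is None and section is None:
            raise ValueError(f"segment {parent}->{child} needs a radius or a section")
        self.graph.add_edge(parent, child, length=float(length), radius=radius, section=section)

    # -- queries -----------------------------------------------------
    @property
    def inlet(self) -> str:
        inlets = [n for n, d in self.graph.nodes(data=True) if d.get("kind") == "inlet"]
        if len(inlets) != 1:
            raise ValueError(f"tree has {len(inlets)} inlets, expected exactly 1")
        return inlets[0]

    @property
    def outlets(self) -> list[str]:
        """Outlets in stable (insertion) order — matches reported outlet numbering."""
        return [n for n, d in self.graph.nodes(data=True) if d.get("kind") == "outlet"]

    def children(self, node: str) -> list[str]:
        return list(self.graph.successors(node))

    def segment(self, parent: str, child: str) -> dict:
        return self.graph.edges[parent, child]

    def segment_diameter(self, parent: str, child: str, n_rays: int = 64) -> float:
        """Equivalent diameter of a segment, mm.

        Circular segments return 2*radius; sectioned segments return the
        diameter of the circle matching the raytraced area.
        """
        data = self.segment(parent, child)
        if data.get("radius") is not None:
            return 2.0 * float(data["radius"])
        sec = data.get("section")
        if sec is None:
            raise ValueError(f"segment {parent}->{child} has neither radius nor section")
        return equivalent_diameter(polygon_area_raytrace(sec, n_rays))

    def segment_area(self, parent: str, child: str, n_rays: int = 64) -> float:
        """Luminal area of a segment, mm^2 (raytraced if a section is present)."""
        data = self.segment(parent, child)
        sec = data.get("section")
        if sec is not None:
            return polygon_area_raytrace(sec, n_rays)
        if data.get("radius") is not None:
            return float(np.pi * data["radius"] ** 2)
        raise ValueError(f"segment {parent}->{child} has neither radius nor section")


def circular_section(
    anchor, normal, radius: float, n_points: int = 128
) -> CrossSection:
    """A perfectly circular :class:`CrossSection` of the given radius (mm)."""
    sec_frame = CrossSection(
        anchor=np.asarray(anchor, float),
        normal=np.asarray(normal, float),
        boundary=np.zeros((3, 3)),  # placeholder to obtain the basis
    )
    e1, e2 = sec_frame.plane_basis()
    theta = np.linspace(0.0, 2 * np.pi, n_points, endpoint=False)
    pts = (
        np.asarray(anchor, float)
        + radius * np.outer(np.cos(theta), e1)
        + radius * np.outer(np.sin(theta), e2)
    )
    return CrossSection(anchor=anchor, normal=normal, boundary=pts)


# ---------------------------------------------------------------------------
# raytraced polygonal area
# ---------------------------------------------------------------------------

def polygon_area_raytrace(section: CrossSection, n_rays: int = 64) -> float:
    """Approximate the luminal area by raytracing, in mm^2.

    ``n_rays`` rays are cast from the centerline anchor, uniformly spaced
    in angle within the section plane (phase fixed by
    :meth:`CrossSection.plane_basis`).  Each ray's nearest intersection
    with the boundary polyline becomes a vertex of a star-shaped polygon
    whose (fan-triangulated) area is returned.  Non-convex borders are
    permitted; taking the nearest hit makes the polygon star-shaped
    around the anchor.
    """
    if n_rays < 3:
        raise ValueError(f"n_rays must be >= 3, got {n_rays}")
    err = section.out_of_plane_error()
    if err > section.planarity_tol:
        raise ValueError(
            f"boundary is non-planar: max out-of-plane distance {err:.3g} mm "
            f"exceeds tolerance {section.planarity_tol:.3g} mm"
        )
    poly = section.to_plane(section.boundary)  # (M, 2), anchor at origin
    if not _point_in_polygon(np.zeros(2), poly):
        raise ValueError("anchor lies outside the boundary polygon; rays may miss the border")

    theta = 2 * np.pi * np.arange(n_rays) / n_rays
    radii = _ray_polyline_distances(poly, theta)
    # shoelace for a fan of rays at known angles and radii
    r_next = np.roll(radii, -1)
    dtheta = 2 * np.pi / n_rays
    return float(0.5 * np.sum(radii * r_next) * np.sin(dtheta))


def _ray_polyline_distances(poly: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Distance from origin to the nearest polyline hit along each ray angle.

    Vectorised over all (ray, segment) pairs.  A ray passing exactly
    through a vertex yields two coincident candidate hits; the minimum
    positive distance is taken, which is the deterministic/continuous
    choice.
    """
    a = poly
    b = np.roll(poly, -1, axis=0)
    d = np.column_stack([np.cos(theta), np.sin(theta)])  # (R, 2)
    e = b - a  # (S, 2) segment vectors

    # solve  t*d_r = a_s + s*e_s  for t (ray param) and s in [0, 1]
    # cross products:  t = cross(a, e) / cross(d, e),  s = cross(a, d) / cross(d, e)
    cross_de = d[:, 0, None] * e[None, :, 1] - d[:, 1, None] * e[None, :, 0]  # (R, S)
    cross_ae = a[None, :, 0] * e[None, :, 1] - a[None, :, 1] * e[None, :, 0]  # (1, S)
    cross_ad = a[None, :, 0] * d[:, 1, None] - a[None, :, 1] * d[:, 0, None]  # (R, S)

    # t*d = a + s*e  =>  t = (a x e)/(d x e),  s = (a x d)/(d x e)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = cross_ae / cross_de
        s = cross_ad / cross_de
    valid = (np.abs(cross_de) > 1e-300) & (s >= -1e-12) & (s <= 1 + 1e-12) & (t > 1e-12)
    t = np.where(valid, t, np.inf)
    hits = t.min(axis=1)
    if not np.all(np.isfinite(hits)):
        missed = int(np.argmax(~np.isfinite(hits)))
        raise ValueError(f"ray {missed} (angle {theta[missed]:.4f} rad) misses the boundary")
    return hits


def _point_in_polygon(pt: np.ndarray, poly: np.ndarray) -> bool:
    """Even-odd rule point-in-polygon test in 2D."""
    x, y = pt
    x0, y0 = poly[:, 0], poly[:, 1]
    x1, y1 = np.roll(x0, -1), np.roll(y0, -1)
    cond = (y0 > y) != (y1 > y)
    with np.errstate(divide="ignore", invalid="ignore"):
        x_int = x0 + (y - y0) / (y1 - y0) * (x1 - x0)
    crossings = cond & (x < x_int)
    return bool(np.sum(crossings) % 2 == 1)


def equivalent_diameter(area: float) -> float:
    """Diameter (mm) of the circle with the given area (mm^2): D = 2 sqrt(A/pi)."""
    if area <= 0:
        raise ValueError(f"area must be positive, got {area}")
    return 2.0 * float(np.sqrt(area / np.pi))


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_tree(tree: VesselTree) -> list[str]:
    """Diagnostic check of the tree invariants; returns a list of violations."""
    g = tree.graph
    violations: list[str] = []
    if not nx.is_directed_acyclic_graph(g) or not nx.is_tree(g.to_undirected(as_view=True)):
        violations.append("graph is not a tree (cycle or disconnected component present)")
        return violations

    inlets = [n for n, d in g.nodes(data=True) if d.get("kind") == "inlet"]
    if len(inlets) != 1:
        violations.append(f"expected exactly 1 inlet, found {len(inlets)}")
    for node, data in g.nodes(data=True):
        kind = data.get("kind")
        n_out = g.out_degree(node)
        n_in = g.in_degree(node)
        if kind == "inlet" and n_in != 0:
            violations.append(f"inlet {node!r} has incoming segments")
        if kind == "junction" and n_out < 2:
            violations.append(f"junction {node!r} has {n_out} children (needs >= 2)")
        if kind == "outlet" and n_out != 0:
            violations.append(f"outlet {node!r} has outgoing segments (must be a leaf)")
        if n_out == 0 and kind != "outlet":
            violations.append(f"leaf {node!r} is marked {kind!r}, not outlet")
    for u, v, data in g.edges(data=True):
        if data.get("radius") is None and data.get("section") is None:
            violations.append(f"segment {u}->{v} carries neither radius nor section")
        elif data.get("radius") is not None and data["radius"] <= 0:
            violations.append(f"segment {u}->{v} has non-positive radius")
    return violations
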