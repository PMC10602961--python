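"""Per-outlet flow fractions under the five outlet boundary-condition strategies.

The five strategies compared are:

* **BC1** — zero-pressure at every outlet.  In a 3D solver the resulting
  split is only known after the simulation; here it is emulated by a 0D
  Poiseuille resistance network (an explicitly labeled surrogate).
* **BC2 / BC3** — Murray's law over the outlet cross-sections with
  exponent n = 2 / n = 3: fraction_i = D_i^n / sum_j D_j^n.  The power
  law is written as a proportionality; the normalised form is the one
  that conserves mass.
* **BC4** — Murray n = 2 applied locally at every branch junction
  (Q1/Q2 = (D1/D2)^2), with an outlet's global fraction the product of
  local fractions along the root->outlet path.
* **BC5** — like BC4 but with the squared diameter replaced by the real
  luminal cross-sectional area from raytracing (Q1/Q2 = A1/A2).  Being
  the most anatomically informed, it is the usual reference strategy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .vessel_model import (
    SplitResult,
    VesselTree,
    polygon_area_raytrace,
    validate_tree,
)

__all__ = [
    "NetworkProperties",
    "murray_split",
    "bifurcation_split",
    "area_split",
    "zero_pressure_network_split",
    "compute_all_splits",
]


@dataclass(frozen=True)
class NetworkProperties:
    """Physical properties for the 0D Poiseuille network surrogate.

    viscosity is in Pa*s (blood default 0.004); segment lengths and radii
    are taken from the tree itself (mm).
    """

    viscosity: float = 0.004

    def __post_init__(self) -> None:
        if self.viscosity <= 0:
            raise ValueError("viscosity must be positive")


def murray_split(diameters: Mapping[str, float], n: float, method: str = "bc2") -> SplitResult:
    """Murray-law split over outlet diameters: fraction_i = D_i^n / sum D_j^n."""
    if not diameters:
        raise ValueError("empty diameter set")
    if any(d <= 0 for d in diameters.values()):
        bad = [k for k, d in diameters.items() if d <= 0]
        raise ValueError(f"non-positive diameter for outlet(s) {bad}")
    if n <= 0:
        raise ValueError(f"exponent must be positive, got {n}")
    keys = list(diameters)
    powered = np.array([diameters[k] for k in keys], dtype=float) ** n
    fractions = powered / powered.sum()
    return SplitResult(method=method, fractions=dict(zip(keys, fractions)))


def _hierarchical_split(
    tree: VesselTree, local_weight, method: str
) -> SplitResult:
    """Root->leaf product of local child weights; shared by BC4 and BC5."""
    violations = validate_tree(tree)
    if violations:
        raise ValueError("invalid tree: " + "; ".join(violations))
    fractions: dict[str, float] = {}

    def descend(node: str, fraction: float) -> None:
        children = tree.children(node)
        if not children:
            fractions[node] = fraction
            return
        if len(children) == 1:
            # pass-through: a segment chain, not a branch junction
            descend(children[0], fraction)
            return
        weights = np.array([local_weight(node, c) for c in children], dtype=float)
        if np.any(weights <= 0):
            bad = children[int(np.argmax(weights <= 0))]
            raise ValueError(f"non-positive weight on segment {node}->{bad}")
        local = weights / weights.sum()
        for child, f in zip(children, local):
            descend(child, fraction * f)

    descend(tree.inlet, 1.0)
    ordered = {o: fractions[o] for o in tree.outlets}
    # guard against float drift in deep trees
    total = sum(ordered.values())
    ordered = {k: v / total for k, v in ordered.items()}
    return SplitResult(method=method, fractions=ordered)


def bifurcation_split(tree: VesselTree, exponent: float = 2.0, n_rays: int = 64) -> SplitResult:
    """Local (per-junction) Murray split with child weights D^exponent (BC4)."""

    def weight(parent: str, child: str) -> float:
        return tree.segment_diameter(parent, child, n_rays=n_rays) ** exponent

    return _hierarchical_split(tree, weight, method="bc4")


def area_split(tree: VesselTree, n_rays: int = 64) -> SplitResult:
    """Local split with child weights equal to the raytraced luminal area (BC5)."""

    def weight(parent: str, child: str) -> float:
        try:
            return tree.segment_area(parent, child, n_rays=n_rays)
        except ValueError as exc:
            raise ValueError(f"segment {parent}->{child}: {exc}") from exc

    return _hierarchical_split(tree, weight, method="bc5")


def zero_pressure_network_split(
    tree: VesselTree, props: NetworkProperties | None = None
) -> SplitResult:
    """0D Poiseuille-network surrogate for the zero-pressure outlet condition (BC1).

    Each segment is a resistor with conductance G = pi R^4 / (8 mu L);
    a unit flow enters the inlet and every outlet is held at pressure 0.
    The returned fractions are the outlet flows.  This is a surrogate:
    the reference study derives its zero-pressure splits from the full
    transient 3D solution, which a lumped network cannot reproduce.
    """
    props = props or NetworkProperties()
    violations = validate_tree(tree)
    if violations:
        raise ValueError("invalid tree: " + "; ".join(violations))

    g = tree.graph
    nodes = list(g.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    outlets = set(tree.outlets)
    mu = props.viscosity

    conduct = {}
    for u, v, data in g.edges(data=True):
        radius = data.get("radius")
        if radius is None:
            sec = data.get("section")
            if sec is None:
                raise ValueError(f"segment {u}->{v} lacks a radius")
            from .vessel_model import equivalent_diameter

            radius = equivalent_diameter(polygon_area_raytrace(sec)) / 2.0
        if radius <= 0:
            raise ValueError(f"segment {u}->{v} has zero radius; network is singular")
        length = data["length"]
        if length <= 0:
            raise ValueError(f"segment {u}->{v} has non-positive length")
        # mm -> m; fractions are scale-free but SI keeps magnitudes sane
        r_m, l_m = radius * 1e-3, length * 1e-3
        conduct[(u, v)] = np.pi * r_m**4 / (8.0 * mu * l_m)

    # nodal analysis: unknown pressures at non-outlet nodes, outlets grounded
    unknown = [n for n in nodes if n not in outlets]
    uidx = {n: i for i, n in enumerate(unknown)}
    a_mat = np.zeros((len(unknown), len(unknown)))
    rhs = np.zeros(len(unknown))
    rhs[uidx[tree.inlet]] = 1.0  # unit inflow
    for (u, v), g_uv in conduct.items():
        for a, b in ((u, v), (v, u)):
            if a in uidx:
                a_mat[uidx[a], uidx[a]] += g_uv
                if b in uidx:
                    a_mat[uidx[a], uidx[b]] -= g_uv
    try:
        pressures = np.linalg.solve(a_mat, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular 0D network: {exc}") from exc

    p = {n: (pressures[uidx[n]] if n in uidx else 0.0) for n in nodes}
    flows = {}
    for o in tree.outlets:
        (parent,) = g.predecessors(o)
        flows[o] = conduct[(parent, o)] * (p[parent] - p[o])
    total = sum(flows.values())
    fractions = {o: flows[o] / total for o in tree.outlets}
    return SplitResult(method="bc1", fractions=fractions)


def compute_all_splits(
    tree: VesselTree,
    props: NetworkProperties | None = None,
    n_rays: int = 64,
) -> dict[str, SplitResult]:
    """All five strategies on one tree, keyed ``bc1``..``bc5``.

    BC2/BC3 use the equivalent diameters of the *outlet* sections (global
    Murray law); BC4/BC5 traverse the junctions locally.  BC1 is the 0D
    network surrogate.
    """
    outlet_d = {}
    for o in tree.outlets:
        (parent,) = tree.graph.predecessors(o)
        outlet_d[o] = tree.segment_diameter(parent, o, n_rays=n_rays)
    return {
        "bc1": zero_pressure_network_split(tree, props),
        "bc2": murray_split(outlet_d, n=2, method="bc2"),
        "bc3": murray_split(outlet_d, n=3, method="bc3"),
        "bc4": bifurcation_split(tree, exponent=2, n_rays=n_rays),
        "bc5": area_split(tree, n_rays=n_rays),
    }
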