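"""Synthetic vessel trees, segmentation ensembles and analytic flow phantoms.

Everything the pipeline consumes can be generated here, deterministically
from a seed:

* bifurcating vessel trees with circular outlet sections and Murray-type
  internal radii (parent^3 = sum child^3);
* "segmentation ensembles" — copies of a base tree whose luminal borders
  are perturbed by smooth low-order radial noise, a per-member global
  over/under-segmentation scale factor, and per-section radius noise,
  emulating the scatter between human operators reconstructing the same
  lumen (statistical structure only; no claim of matching any real
  reconstruction);
* analytic pulsatile flow phantoms on tetrahedral tube/sphere meshes
  whose metric values are known in closed form, returned alongside the
  fields as a prescription record.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import ConvexHull, Delaunay

from .hemodynamics import FieldSeries, RegionSet
from .vessel_model import CrossSection, VesselTree, circular_section

__all__ = [
    "EnsembleSpec",
    "PhantomSpec",
    "make_tree",
    "make_ensemble",
    "make_phantom",
]


# ---------------------------------------------------------------------------
# vessel trees
# ---------------------------------------------------------------------------

def make_tree(
    outlet_radii: Sequence[float],
    depth: str = "balanced",
    segment_length: float = 10.0,
    section_points: int = 128,
) -> VesselTree:
    """Deterministic bifurcating tree with the given outlet radii (mm).

    Leaves carry perfectly circular cross-sections; internal segment
    radii follow the Murray closure parent^3 = sum(child^3).  ``depth``
    selects the branching pattern: ``"balanced"`` splits the outlet list
    in half recursively, ``"caterpillar"`` peels one outlet per level.
    Outlet ids ``o1..ok`` follow the input order.
    """
    radii = [float(r) for r in outlet_radii]
    if len(radii) < 2:
        raise ValueError("need at least 2 outlet radii")
    if any(r <= 0 for r in radii):
        raise ValueError("outlet radii must be positive")
    if depth not in ("balanced", "caterpillar"):
        raise ValueError(f"unknown branching pattern {depth!r}")

    tree = VesselTree()
    tree.add_node("inlet", kind="inlet")
    counter = {"j": 0}
    # outlets registered in input order so tree.outlets is stable
    for i in range(len(radii)):
        tree.add_node(f"o{i + 1}", kind="outlet")

    def murray_radius(child_radii: list[float]) -> float:
        return float(np.cbrt(sum(r**3 for r in child_radii)))

    def build(indices: list[int], parent: str, z: float) -> float:
        """Attach the subtree for ``indices`` under ``parent``; return its radius."""
        if len(indices) == 1:
            i = indices[0]
            r = radii[i]
            anchor = np.array([0.0, float(i), z + segment_length])
            tree.add_segment(
                parent,
                f"o{i + 1}",
                length=segment_length,
                radius=r,
                section=circular_section(anchor, [0, 0, 1.0], r, n_points=section_points),
            )
            return r
        counter["j"] += 1
        junction = f"j{counter['j']}"
        tree.add_node(junction, kind="junction")
        if depth == "balanced":
            half = len(indices) // 2
            groups = [indices[:half], indices[half:]]
        else:
            groups = [indices[:1], indices[1:]]
        child_r = [build(g, junction, z + segment_length) for g in groups]
        r = murray_radius(child_r)
        # connect after the subtree exists so the junction segment radius is known
        tree.graph.add_edge(parent, junction, length=segment_length, radius=r, section=None)
        return r

    # the inlet feeds the root junction through one trunk segment
    build(list(range(len(radii))), "inlet", 0.0)
    return tree


@dataclass(frozen=True)
class EnsembleSpec:
    """Parameters of a synthetic segmentation ensemble.

    radius_noise_sd : relative SD of per-section radius jitter.
    scale_range : (lo, hi) multiplicative over/under-segmentation factor
        drawn once per member.
    roughness : relative amplitude of the low-order (modes 2-6) Fourier
        radial perturbation of each boundary.
    """

    base: VesselTree
    n_members: int = 10
    radius_noise_sd: float = 0.03
    scale_range: tuple[float, float] = (0.95, 1.05)
    roughness: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")
        if self.radius_noise_sd < 0 or self.roughness < 0:
            raise ValueError("noise parameters must be >= 0")
        lo, hi = self.scale_range
        if lo <= 0 or hi < lo:
            raise ValueError("scale_range must satisfy 0 < lo <= hi")


def _perturb_tree(tree: VesselTree, scale: float, rng: np.random.Generator,
                  radius_sd: float, roughness: float) -> VesselTree:
    out = VesselTree()
    for node, data in tree.graph.nodes(data=True):
        out.add_node(node, kind=data["kind"])
    for u, v, data in tree.graph.edges(data=True):
        radius = data.get("radius")
        section = data.get("section")
        jitter = scale * (1.0 + radius_sd * rng.standard_normal()) if radius_sd > 0 else scale
        new_radius = radius * jitter if radius is not None else None
        new_section = None
        if section is not None:
            new_section = _perturb_section(section, jitter, rng, roughness)
        out.graph.add_edge(u, v, length=data["length"], radius=new_radius, section=new_section)
    return out


def _perturb_section(sec: CrossSection, scale: float, rng: np.random.Generator,
                     roughness: float) -> CrossSection:
    """Radial Fourier perturbation (modes 2-6) plus a global scale factor."""
    xy = sec.to_plane(sec.boundary)
    r = np.linalg.norm(xy, axis=1)
    theta = np.arctan2(xy[:, 1], xy[:, 0])
    factor = np.full_like(r, scale)
    if roughness > 0:
        for mode in range(2, 7):
            amp = roughness * rng.standard_normal() / np.sqrt(5)
            phase = rng.uniform(0, 2 * np.pi)
            factor *= 1.0 + amp * np.cos(mode * theta + phase)
    r_new = r * factor
    e1, e2 = sec.plane_basis()
    pts = (
        sec.anchor
        + np.outer(r_new * np.cos(theta), e1)
        + np.outer(r_new * np.sin(theta), e2)
    )
    return CrossSection(anchor=sec.anchor, normal=sec.normal, boundary=pts)


def make_ensemble(spec: EnsembleSpec) -> list[VesselTree]:
    """Reproducible segmentation ensemble; member 0 is the unperturbed base."""
    rng = np.random.default_rng(spec.seed)
    members = [_perturb_tree(spec.base, 1.0, np.random.default_rng(0), 0.0, 0.0)]
    for _ in range(spec.n_members - 1):
        scale = rng.uniform(*spec.scale_range)
        members.append(
            _perturb_tree(spec.base, scale, rng, spec.radius_noise_sd, spec.roughness)
        )
    return members


# ---------------------------------------------------------------------------
# analytic flow phantoms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of an analytic flow phantom.

    kind : poiseuille | rigid_rotation | pulsatile_poiseuille | sac_on_pipe.
    radius, length : pipe geometry in m (length also spaces the sac).
    sac_radius : sphere radius in m (sac_on_pipe only).
    mean_speed : bulk (cross-section mean) speed in m/s.
    omega : rotation rate in rad/s (rigid_rotation).
    pulse_amplitude : sinusoidal modulation of the bulk speed, same units
        as mean_speed.  mean_speed 0 with amplitude > 0 gives perfectly
        reversing flow.
    speed_ratio : sac / parent mean-speed ratio (sac_on_pipe).
    wss_ratio : sac / parent WSS magnitude ratio (sac_on_pipe).
    resolution : (n_radial, n_angular, n_axial) mesh density.
    n_times : time samples over one period (>= 8 for pulsatile kinds).
    """

    kind: str
    radius: float = 0.002
    length: float = 0.008
    sac_radius: float = 0.003
    mean_speed: float = 0.25
    omega: float = 5.0
    pulse_amplitude: float = 0.0
    speed_ratio: float = 0.5
    wss_ratio: float = 1.0
    #: axial grading of the sac WSS magnitude, relative amplitude in [0, 1):
    #: |WSS|(z) = wss_ratio * tau_parent * (1 + g * z/sac_radius); makes the
    #: low-shear area a continuous spherical-cap fraction instead of {0, 1}
    wss_gradient: float = 0.0
    #: twist wavenumber of the sac velocity direction, in units of
    #: 1/sac_radius; the field s*(cos kz, sin kz, 0) keeps |V| uniform while
    #: giving a uniform vorticity magnitude s*k
    sac_twist: float = 1.0
    period: float = 1.0
    # isotropic spacing: length/n_axial ~ radius/n_radial keeps the
    # least-squares gradient neighbourhoods well conditioned
    resolution: tuple[int, int, int] = (8, 20, 32)
    n_times: int = 33
    rho: float = 1055.0
    mu: float = 0.004

    def __post_init__(self) -> None:
        if self.kind not in ("poiseuille", "rigid_rotation", "pulsatile_poiseuille", "sac_on_pipe"):
            raise ValueError(f"unsupported phantom kind {self.kind!r}")
        if min(self.radius, self.length, self.sac_radius, self.period) <= 0:
            raise ValueError("dimensions and period must be positive")
        pulsatile = self.kind == "pulsatile_poiseuille"
        if pulsatile and self.n_times < 8:
            raise ValueError("pulsatile phantoms need >= 8 time samples")
        if self.n_times < 2:
            raise ValueError("need >= 2 time samples")


#: relative slip of the pipe-phantom axial profile at the wall (see make_phantom)
_WALL_SLIP = 0.02


def _cylinder_mesh(R: float, L: float, nr: int, ntheta: int, nz: int):
    """Structured cylinder point cloud, its Delaunay tets and wall triangles."""
    zs = np.linspace(0.0, L, nz + 1)
    pts = []
    wall_rows = []  # wall point index per (z, theta)
    for z in zs:
        pts.append([0.0, 0.0, z])
        row = None
        for j in range(1, nr + 1):
            r = R * j / nr
            theta = 2 * np.pi * np.arange(ntheta) / ntheta
            ring_start = len(pts)
            for th in theta:
                pts.append([r * np.cos(th), r * np.sin(th), z])
            if j == nr:
                row = list(range(ring_start, ring_start + ntheta))
        wall_rows.append(row)
    points = np.array(pts)
    tets = Delaunay(points).simplices
    tris = []
    for iz in range(nz):
        a, b = wall_rows[iz], wall_rows[iz + 1]
        for k in range(ntheta):
            k2 = (k + 1) % ntheta
            tris.append([a[k], a[k2], b[k]])
            tris.append([a[k2], b[k2], b[k]])
    tris = np.array(tris)
    centroids = points[tris].mean(axis=1)
    normals = centroids.copy()
    normals[:, 2] = 0.0
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return points, tets, tris, normals


def _sphere_mesh(center: np.ndarray, R: float, n_shell: int, n_surf: int):
    """Fibonacci-shell sphere cloud, Delaunay tets, hull surface triangles."""
    def fib_points(n: int, r: float) -> np.ndarray:
        i = np.arange(n) + 0.5
        phi = np.arccos(1 - 2 * i / n)
        theta = np.pi * (1 + 5**0.5) * i
        return r * np.column_stack(
            [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
        )

    pts = [np.zeros((1, 3))]
    for j in range(1, n_shell):
        r = R * j / n_shell
        pts.append(fib_points(max(8, int(n_surf * (j / n_shell) ** 2)), r))
    surf_start = sum(len(p) for p in pts)
    pts.append(fib_points(n_surf, R))
    points = np.vstack(pts) + center
    tets = Delaunay(points - center).simplices
    hull = ConvexHull(points[surf_start:] - center)
    tris = hull.simplices + surf_start
    centroids = points[tris].mean(axis=1) - center
    normals = centroids / np.linalg.norm(centroids, axis=1, keepdims=True)
    # orient triangles consistently outward
    p = points[tris]
    face_n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    flip = np.einsum("ij,ij->i", face_n, centroids) < 0
    tris[flip] = tris[flip][:, ::-1]
    return points, tets, tris, normals


def make_phantom(spec: PhantomSpec) -> tuple[FieldSeries, RegionSet, dict]:
    """Build the phantom mesh, fields, regions and its closed-form prescription.

    The prescription dict records the analytically known metric values
    (computed here from closed forms or dense quadrature, independently
    of the metric implementations) so round-trip tests and pipelines can
    compare against ground truth.
    """
    if spec.kind == "sac_on_pipe":
        return _sac_on_pipe(spec)
    nr, ntheta, nz = spec.resolution
    R, L = spec.radius, spec.length
    points, tets, tris, normals = _cylinder_mesh(R, L, nr, ntheta, nz)
    times = np.linspace(0.0, spec.period, spec.n_times)
    n_pt, n_tri = len(points), len(tris)

    r2 = points[:, 0] ** 2 + points[:, 1] ** 2
    prescription: dict[str, float] = {}
    if spec.kind == "rigid_rotation":
        base = np.column_stack([-spec.omega * points[:, 1], spec.omega * points[:, 0],
                                np.zeros(n_pt)])
        velocity = np.broadcast_to(base, (spec.n_times, n_pt, 3)).copy()
        wss = None
        prescription.update(vorticity=2.0 * spec.omega, ovi=0.0)
    else:
        # near-parabolic axial profile with a small analytic slip term eps:
        # u_z(r, t) = V(t) * (2 (1 - r^2/R^2) + eps).  The slip keeps the
        # cycle-velocity non-zero at the wall nodes, so the oscillatory
        # index of a perfectly reversing field is 0.5 at *every* node and
        # the spatial mean hits the closed form exactly; it shifts the
        # profile moments by closed-form amounts and leaves the wall
        # gradient (hence WSS) untouched.
        eps = _WALL_SLIP
        shape = 2.0 * (1.0 - r2 / R**2) + eps
        if spec.kind == "pulsatile_poiseuille":
            # bulk speed V(t) = mean_speed + amplitude * sin(2 pi t / T);
            # the spatial profile is quasi-steady
            v_t = spec.mean_speed + spec.pulse_amplitude * np.sin(2 * np.pi * times / spec.period)
        else:
            v_t = np.full(spec.n_times, spec.mean_speed)
        base = np.column_stack([np.zeros(n_pt), np.zeros(n_pt), shape])
        velocity = v_t[:, None, None] * base[None, :, :]
        # analytic WSS: quasi-steady Poiseuille, 4 mu V(t) / R, opposing the flow
        tau_mag = 4.0 * spec.mu * v_t / R
        wss = tau_mag[:, None, None] * np.array([0.0, 0.0, -1.0])[None, None, :]
        wss = np.broadcast_to(wss, (spec.n_times, n_tri, 3)).copy()
        # prescriptions by closed form / dense quadrature (independent of
        # the trapezoid-on-samples path the metrics take)
        t_dense = np.linspace(0.0, spec.period, 20001)
        if spec.kind == "pulsatile_poiseuille":
            v_dense = spec.mean_speed + spec.pulse_amplitude * np.sin(2 * np.pi * t_dense / spec.period)
        else:
            v_dense = np.full_like(t_dense, spec.mean_speed)
        mean_abs = np.trapezoid(np.abs(v_dense), t_dense) / spec.period
        mean_signed = abs(np.trapezoid(v_dense, t_dense)) / spec.period
        # spatial moments of the profile shape over the cross-section:
        # <shape> = 1 + eps,  <shape^2> = 4/3 + 2 eps + eps^2
        prescription.update(
            mean_V=(1.0 + eps) * mean_abs,
            ke=0.5 * spec.rho * (4.0 / 3.0 + 2.0 * eps + eps**2)
            * np.trapezoid(v_dense**2, t_dense) / spec.period,
            tawss=4.0 * spec.mu * mean_abs / R,
            ovi=0.5 * (1.0 - mean_signed / mean_abs) if mean_abs > 0 else 0.0,
            ker=1.0,
            ntawss=1.0,
        )

    series = FieldSeries(
        points=points, tets=tets, surface_tris=tris, surface_normals=normals,
        times=times, velocity=np.asarray(velocity, float), wss=wss,
        rho=spec.rho, mu=spec.mu,
    )
    # sac = distal half of the pipe, parent = proximal half (mirror regions)
    cell_z = points[tets].mean(axis=1)[:, 2]
    tri_z = points[tris].mean(axis=1)[:, 2]
    regions = RegionSet(
        sac_cells=np.where(cell_z >= L / 2)[0],
        parent_cells=np.where(cell_z < L / 2)[0],
        sac_surface=np.where(tri_z >= L / 2)[0],
        parent_surface=np.where(tri_z < L / 2)[0],
        ostium_point=np.array([0.0, 0.0, L / 2]),
        ostium_normal=np.array([0.0, 0.0, 1.0]),
    )
    return series, regions, prescription


def _sac_on_pipe(spec: PhantomSpec) -> tuple[FieldSeries, RegionSet, dict]:
    """Plug-flow parent pipe with a uniform-speed swirling spherical sac.

    The parent carries uniform axial speed V (exact KE = rho V^2 / 2);
    the sac carries a divergence-of-nothing azimuthal field of uniform
    speed ``speed_ratio * V``, so KER = speed_ratio^2 exactly.  Wall
    shear magnitudes are prescribed directly: parent 4 mu V / R, sac
    ``wss_ratio`` times that, so nTAWSS = wss_ratio.
    """
    nr, ntheta, nz = spec.resolution
    R, L, V = spec.radius, spec.length, spec.mean_speed
    p_pts, p_tets, p_tris, p_nrm = _cylinder_mesh(R, L, nr, ntheta, nz)
    center = np.array([0.0, 0.0, L + 2.0 * spec.sac_radius])
    s_pts, s_tets, s_tris, s_nrm = _sphere_mesh(center, spec.sac_radius,
                                                n_shell=max(3, nr // 2), n_surf=16 * ntheta)
    off_p, off_t = len(p_pts), len(p_tets)
    points = np.vstack([p_pts, s_pts])
    tets = np.vstack([p_tets, s_tets + off_p])
    tris = np.vstack([p_tris, s_tris + off_p])
    normals = np.vstack([p_nrm, s_nrm])

    v_parent = np.zeros((len(p_pts), 3))
    v_parent[:, 2] = V
    # twisted uniform-speed sac field s*(cos kz, sin kz, 0): |V| is exactly
    # speed_ratio * V at every node (KER = speed_ratio^2) and the vorticity
    # magnitude is the uniform s*k; the gentle default twist keeps the
    # direction change per cell small so vertex-to-cell averaging stays
    # within the KER tolerance
    s = spec.speed_ratio * V
    k_twist = spec.sac_twist / spec.sac_radius
    kz = k_twist * (s_pts[:, 2] - center[2])
    v_sac = s * np.column_stack([np.cos(kz), np.sin(kz), np.zeros(len(s_pts))])
    base = np.vstack([v_parent, v_sac])

    times = np.linspace(0.0, spec.period, spec.n_times)
    velocity = np.broadcast_to(base, (spec.n_times, len(points), 3)).copy()
    tau_parent = 4.0 * spec.mu * V / R
    # sac WSS graded along z: magnitude wss_ratio*tau_p*(1 + g*z_hat),
    # z_hat in [-1, 1]; the sphere-cap geometry makes the low-shear area
    # fraction a closed form in (wss_ratio, g)
    c = points[tris[len(p_tris):]].mean(axis=1) - center
    z_hat = np.clip(c[:, 2] / spec.sac_radius, -1.0, 1.0)
    g = spec.wss_gradient
    sac_mag = spec.wss_ratio * tau_parent * (1.0 + g * z_hat)
    wss_mag = np.concatenate([np.full(len(p_tris), tau_parent), sac_mag])
    wss_dir = np.zeros((len(tris), 3))
    wss_dir[: len(p_tris)] = [0.0, 0.0, -1.0]
    t_dir = np.cross(np.array([0.0, 0.0, 1.0]), c)  # azimuthal on the sphere
    t_dir /= np.maximum(np.linalg.norm(t_dir, axis=1, keepdims=True), 1e-300)
    wss_dir[len(p_tris):] = t_dir
    wss = np.broadcast_to(wss_mag[:, None] * wss_dir, (spec.n_times, len(tris), 3)).copy()

    series = FieldSeries(
        points=points, tets=tets, surface_tris=tris, surface_normals=normals,
        times=times, velocity=velocity, wss=wss, rho=spec.rho, mu=spec.mu,
    )
    regions = RegionSet(
        sac_cells=np.arange(off_t, len(tets)),
        parent_cells=np.arange(off_t),
        sac_surface=np.arange(len(p_tris), len(tris)),
        parent_surface=np.arange(len(p_tris)),
        ostium_point=np.array([0.0, 0.0, L + spec.sac_radius]),
        ostium_normal=np.array([0.0, 0.0, 1.0]),
    )
    # low-shear area: cells with wss_ratio*(1 + g*z_hat) < 1 form a
    # spherical cap, whose area fraction is (1 + z*)/2 with
    # z* = (1/wss_ratio - 1)/g
    if g > 0:
        z_star = (1.0 / spec.wss_ratio - 1.0) / g
        lsa_presc = float(np.clip((1.0 + z_star) / 2.0, 0.0, 1.0))
    else:
        lsa_presc = 1.0 if spec.wss_ratio < 1.0 else 0.0
    prescription = {
        "ker": spec.speed_ratio**2,
        "ntawss": spec.wss_ratio,
        "ovi": 0.0,
        "mean_V": spec.speed_ratio * V,
        "tawss": spec.wss_ratio * tau_parent,
        "lsa": lsa_presc,
        "sac_vorticity": spec.speed_ratio * V * spec.sac_twist / spec.sac_radius,
    }
    return series, regions, prescription
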