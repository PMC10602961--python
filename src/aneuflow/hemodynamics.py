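"""Flow and shear metrics for aneurysm fields on labeled unstructured meshes.

Works on a :class:`FieldSeries` — a tetrahedral volume mesh plus a
triangulated wall surface carrying a time-resolved velocity field (and
optionally wall shear stress) over exactly one cardiac cycle — and a
:class:`RegionSet` labeling the aneurysm sac and the proximal parent
vessel.  The metric suite follows the conventions of aneurysm CFD
post-processing:

========  ==================================================================
metric    definition
========  ==================================================================
omega     curl of velocity (weighted-least-squares gradient reconstruction)
KE        (1/2) rho |V|^2, volume-averaged over a region
KER       time-mean sac KE / time-mean parent KE
OVI       (1/2)(1 - |cycle-mean velocity vector| / cycle-mean speed),
          per point, volume-weighted over the sac; 0 = steady,
          0.5 = perfectly reversing
TAWSS     (1/T) integral of |WSS| dt, per wall cell; area-weighted mean
nTAWSS    sac mean TAWSS / parent mean TAWSS
LSA       sac area fraction with TAWSS below (parent mean - parent SD)
========  ==================================================================

Temporal integrals use the trapezoidal rule on the supplied samples;
spatial means are volume-weighted (volume metrics) or area-weighted
(wall metrics), so results are insensitive to local mesh refinement.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import NamedTuple

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "FieldSeries",
    "RegionSet",
    "MetricsReport",
    "vorticity",
    "kinetic_energy",
    "ker",
    "ovi",
    "tawss",
    "lsa",
    "ntawss",
    "wss_from_velocity",
    "metrics_report",
]


@dataclass
class FieldSeries:
    """Time-resolved velocity / WSS samples on an unstructured mesh (SI units).

    points : (N, 3) coordinates in m.
    tets : (M, 4) tetrahedral connectivity (volume cells).
    surface_tris : (S, 3) wall triangle connectivity.
    surface_normals : (S, 3) outward unit normals of the wall triangles.
    times : (T,) strictly increasing sample times in s spanning one cycle.
    velocity : (T, N, 3) point velocities in m/s.
    wss : (T, S, 3) wall-shear-stress vectors in Pa, or None.
    rho, mu : blood density (kg/m^3) and dynamic viscosity (Pa s).
    """

    points: np.ndarray
    tets: np.ndarray
    surface_tris: np.ndarray
    surface_normals: np.ndarray
    times: np.ndarray
    velocity: np.ndarray
    wss: np.ndarray | None = None
    rho: float = 1055.0
    mu: float = 0.004
    cell_volumes: np.ndarray = dc_field(default=None, repr=False)  # type: ignore[assignment]
    surface_areas: np.ndarray = dc_field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, float).reshape(-1, 3)
        self.tets = np.asarray(self.tets, int).reshape(-1, 4)
        self.surface_tris = np.asarray(self.surface_tris, int).reshape(-1, 3)
        self.surface_normals = np.asarray(self.surface_normals, float).reshape(-1, 3)
        self.times = np.asarray(self.times, float).ravel()
        self.velocity = np.asarray(self.velocity, float)
        if self.times.size < 2:
            raise ValueError("need at least 2 time samples")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.velocity.shape != (self.times.size, len(self.points), 3):
            raise ValueError(
                f"velocity shape {self.velocity.shape} does not match "
                f"(T={self.times.size}, N={len(self.points)}, 3)"
            )
        if not np.all(np.isfinite(self.velocity)):
            raise ValueError("velocity contains non-finite values")
        if self.cell_volumes is None:
            self.cell_volumes = tet_volumes(self.points, self.tets)
        if self.surface_areas is None:
            self.surface_areas = tri_areas(self.points, self.surface_tris)
        if np.any(self.cell_volumes < 0) or np.any(self.surface_areas < 0):
            raise ValueError("negative cell volume or surface area")
        if self.wss is not None:
            self.wss = np.asarray(self.wss, float)
            if self.wss.shape != (self.times.size, len(self.surface_tris), 3):
                raise ValueError(f"wss shape {self.wss.shape} inconsistent with mesh/times")

    @property
    def period(self) -> float:
        return float(self.times[-1] - self.times[0])

    def cell_velocity(self, t_index: int) -> np.ndarray:
        """Per-tet velocity, averaged from the vertices."""
        return self.velocity[t_index][self.tets].mean(axis=1)

    def point_weights(self, region: np.ndarray) -> np.ndarray:
        """Lumped volume weights: each tet spreads 1/4 of its volume to its vertices."""
        w = np.zeros(len(self.points))
        cells = np.asarray(region, int)
        np.add.at(w, self.tets[cells].ravel(), np.repeat(self.cell_volumes[cells] / 4.0, 4))
        return w


@dataclass
class RegionSet:
    """Cell labels splitting the mesh into aneurysm sac and parent vessel.

    Volume regions index into ``tets``, surface regions into
    ``surface_tris``.  The ostium plane (point, unit normal) marks the
    aneurysm neck.
    """

    sac_cells: np.ndarray
    parent_cells: np.ndarray
    sac_surface: np.ndarray
    parent_surface: np.ndarray
    ostium_point: np.ndarray | None = None
    ostium_normal: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("sac_cells", "parent_cells", "sac_surface", "parent_surface"):
            setattr(self, name, np.asarray(getattr(self, name), int).ravel())
        if np.intersect1d(self.sac_cells, self.parent_cells).size:
            raise ValueError("sac and parent volume cell sets overlap")

    def validate_against(self, series: FieldSeries) -> None:
        m, s = len(series.tets), len(series.surface_tris)
        for name, arr, limit in (
            ("sac_cells", self.sac_cells, m),
            ("parent_cells", self.parent_cells, m),
            ("sac_surface", self.sac_surface, s),
            ("parent_surface", self.parent_surface, s),
        ):
            if arr.size and (arr.min() < 0 or arr.max() >= limit):
                raise ValueError(f"{name} references cells outside the mesh (limit {limit})")


class SurfaceField(NamedTuple):
    per_cell: np.ndarray
    mean: float


@dataclass(frozen=True)
class MetricsReport:
    """Per-aneurysm scalar summary (cycle means, sac-averaged)."""

    mean_V: float          # m/s
    mean_vorticity: float  # 1/s, mean vorticity magnitude
    KE: float              # J/m^3
    KER: float
    OVI: float
    TAWSS: float           # Pa
    nTAWSS: float
    LSA: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.OVI <= 0.5 + 1e-12):
            raise ValueError(f"OVI {self.OVI} outside [0, 0.5]")
        if not (0.0 <= self.LSA <= 1.0):
            raise ValueError(f"LSA {self.LSA} outside [0, 1]")


# ---------------------------------------------------------------------------
# mesh helpers
# ---------------------------------------------------------------------------

def tet_volumes(points: np.ndarray, tets: np.ndarray) -> np.ndarray:
    p = points[tets]
    return np.abs(np.einsum("ij,ij->i", np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), p[:, 3] - p[:, 0])) / 6.0


def tri_areas(points: np.ndarray, tris: np.ndarray) -> np.ndarray:
    p = points[tris]
    return 0.5 * np.linalg.norm(np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1)


def _trapz(values: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Trapezoid integral along axis 0."""
    return np.trapezoid(values, times, axis=0)


# ---------------------------------------------------------------------------
# gradient reconstruction
# ---------------------------------------------------------------------------

class GradientOperator:
    """Weighted-least-squares gradient reconstruction on a point cloud.

    For each evaluation point the gradient tensor G (G[a, b] = d u_b / d x_a)
    minimises sum_j w_j |u_j - u_i - G^T dx_j|^2 over the k nearest
    neighbours, with inverse-distance weights.  Exact for affine fields;
    second-order on smooth ones.  Geometry factors are assembled once so
    repeated evaluation over time steps is a single batched solve.
    """

    def __init__(self, points: np.ndarray, k: int = 24, eval_idx: np.ndarray | None = None):
        points = np.asarray(points, float)
        self.eval_idx = np.arange(len(points)) if eval_idx is None else np.asarray(eval_idx, int)
        k = min(k, len(points) - 1)
        if k < 4:
            raise ValueError("need at least 4 neighbours for a 3D gradient")
        tree = cKDTree(points)
        dist, nbr = tree.query(points[self.eval_idx], k=k + 1)
        # first column is the point itself (distance 0)
        self.nbr = nbr[:, 1:]
        dx = points[self.nbr] - points[self.eval_idx, None, :]  # (P, k, 3)
        w = 1.0 / np.maximum(dist[:, 1:], 1e-300)
        a = np.einsum("pk,pka,pkb->pab", w, dx, dx)  # (P, 3, 3)
        bad = np.flatnonzero(np.linalg.matrix_rank(a) < 3)
        if bad.size:
            # coplanar k-neighbourhood (structured meshes with tied
            # distances can produce one); widen it before giving up
            k2 = min(2 * k + 1, len(points) - 1)
            d2, n2 = tree.query(points[self.eval_idx[bad]], k=k2 + 1)
            pad = k2 - self.nbr.shape[1]
            if pad > 0:
                self.nbr = np.pad(self.nbr, ((0, 0), (0, pad)), mode="edge")
                dx = points[self.nbr] - points[self.eval_idx, None, :]
                w = np.pad(w, ((0, 0), (0, pad)))  # zero weight on padding
            self.nbr[bad] = n2[:, 1:]
            dx[bad] = points[n2[:, 1:]] - points[self.eval_idx[bad], None, :]
            w[bad] = 1.0 / np.maximum(d2[:, 1:], 1e-300)
            a = np.einsum("pk,pka,pkb->pab", w, dx, dx)
            still = np.flatnonzero(np.linalg.matrix_rank(a) < 3)
            if still.size:
                worst = int(self.eval_idx[still[0]])
                raise ValueError(
                    f"degenerate neighbourhood at point {worst}: neighbours are coplanar"
                )
        self.w = w
        self.dx = dx
        self.a = a

    def __call__(self, values: np.ndarray) -> np.ndarray:
        """Gradient tensors (P, 3, 3) of a per-point field ``values`` (N, 3)."""
        du = values[self.nbr] - values[self.eval_idx, None, :]  # (P, k, 3)
        b = np.einsum("pk,pka,pkb->pab", self.w, self.dx, du)
        return np.linalg.solve(self.a, b)


def vorticity(
    series: FieldSeries,
    t_index: int,
    grad_op: GradientOperator | None = None,
    k: int = 24,
) -> np.ndarray:
    """Per-point vorticity vectors (zeta_x, zeta_y, zeta_z) in 1/s.

    zeta = curl u, with the velocity gradient reconstructed by weighted
    least squares over point neighbourhoods.
    """
    op = grad_op or GradientOperator(series.points, k=k)
    g = op(series.velocity[t_index])
    curl = np.empty((g.shape[0], 3))
    curl[:, 0] = g[:, 1, 2] - g[:, 2, 1]  # dw/dy - dv/dz
    curl[:, 1] = g[:, 2, 0] - g[:, 0, 2]  # du/dz - dw/dx
    curl[:, 2] = g[:, 0, 1] - g[:, 1, 0]  # dv/dx - du/dy
    return curl


# ---------------------------------------------------------------------------
# volume (flow) metrics
# ---------------------------------------------------------------------------

def kinetic_energy(series: FieldSeries, t_index: int, region: np.ndarray) -> float:
    """Volume-averaged kinetic energy density (1/2) rho |V|^2 over ``region`` cells."""
    region = np.asarray(region, int)
    if region.size == 0:
        raise ValueError("empty region")
    v = series.cell_velocity(t_index)[region]
    vol = series.cell_volumes[region]
    ke = 0.5 * series.rho * np.einsum("ij,ij->i", v, v)
    return float(np.average(ke, weights=vol))


def ker(series: FieldSeries, regions: RegionSet) -> float:
    """Kinetic-energy ratio: time-mean sac KE / time-mean parent KE."""
    regions.validate_against(series)
    t = series.times
    sac = _trapz(np.array([kinetic_energy(series, i, regions.sac_cells) for i in range(t.size)]), t)
    par = _trapz(np.array([kinetic_energy(series, i, regions.parent_cells) for i in range(t.size)]), t)
    if par == 0:
        raise ValueError("parent-vessel kinetic energy is zero; KER undefined")
    return float(sac / par)


def ovi(series: FieldSeries, region: np.ndarray) -> float:
    """Oscillatory velocity index, volume-weighted over ``region``.

    Per point: (1/2)(1 - |int V dt| / int |V| dt) over the cycle.  Points
    with identically zero velocity contribute 0 (trivially steady).  The
    result lies in [0, 0.5] by the triangle inequality — no clamping.
    """
    region = np.asarray(region, int)
    if region.size == 0:
        raise ValueError("empty region")
    t = series.times
    vec_int = _trapz(series.velocity, t)                          # (N, 3)
    mag_int = _trapz(np.linalg.norm(series.velocity, axis=2), t)  # (N,)
    num = np.linalg.norm(vec_int, axis=1)
    point_ovi = np.zeros(len(series.points))
    nz = mag_int > 0
    point_ovi[nz] = 0.5 * (1.0 - num[nz] / mag_int[nz])
    w = series.point_weights(region)
    return float(np.average(point_ovi, weights=w))


def mean_speed(series: FieldSeries, region: np.ndarray) -> float:
    """Cycle-mean, volume-weighted mean velocity magnitude over ``region``."""
    region = np.asarray(region, int)
    t = series.times
    speeds = np.array(
        [np.average(np.linalg.norm(series.cell_velocity(i)[region], axis=1),
                    weights=series.cell_volumes[region]) for i in range(t.size)]
    )
    return float(_trapz(speeds, t) / series.period)


def mean_vorticity_magnitude(
    series: FieldSeries, region: np.ndarray, k: int = 24
) -> float:
    """Cycle-mean, volume-weighted mean |curl u| over ``region`` cells."""
    region = np.asarray(region, int)
    pts = np.unique(series.tets[region].ravel())
    op = GradientOperator(series.points, k=k, eval_idx=pts)
    w_full = series.point_weights(region)
    w = w_full[pts]
    t = series.times
    means = np.empty(t.size)
    for i in range(t.size):
        curl = vorticity(series, i, grad_op=op)
        means[i] = np.average(np.linalg.norm(curl, axis=1), weights=w)
    return float(_trapz(means, t) / series.period)


# ---------------------------------------------------------------------------
# wall (shear) metrics
# ---------------------------------------------------------------------------

def _require_wss(series: FieldSeries) -> np.ndarray:
    if series.wss is None:
        raise ValueError("FieldSeries has no WSS samples; compute them with wss_from_velocity")
    return series.wss


def tawss(series: FieldSeries, surface_region: np.ndarray) -> SurfaceField:
    """Time-averaged WSS magnitude per wall cell and its area-weighted mean (Pa)."""
    wss = _require_wss(series)
    surface_region = np.asarray(surface_region, int)
    if surface_region.size == 0:
        raise ValueError("empty surface region")
    mag = np.linalg.norm(wss[:, surface_region, :], axis=2)  # (T, S_r)
    per_cell = _trapz(mag, series.times) / series.period
    mean = float(np.average(per_cell, weights=series.surface_areas[surface_region]))
    return SurfaceField(per_cell=per_cell, mean=mean)


def lsa(series: FieldSeries, regions: RegionSet) -> float:
    """Low-shear area fraction of the sac wall.

    Threshold = area-weighted parent mean TAWSS minus its area-weighted
    standard deviation; LSA is the sac area fraction strictly below it.
    """
    regions.validate_against(series)
    parent = tawss(series, regions.parent_surface)
    w = series.surface_areas[regions.parent_surface]
    sd = float(np.sqrt(np.average((parent.per_cell - parent.mean) ** 2, weights=w)))
    boundary = parent.mean - sd
    sac = tawss(series, regions.sac_surface)
    sac_w = series.surface_areas[regions.sac_surface]
    return float(sac_w[sac.per_cell < boundary].sum() / sac_w.sum())


def ntawss(series: FieldSeries, regions: RegionSet) -> float:
    """Sac mean TAWSS normalised by parent-vessel mean TAWSS."""
    regions.validate_against(series)
    parent = tawss(series, regions.parent_surface)
    if parent.mean == 0:
        raise ValueError("parent-vessel TAWSS is zero; normalisation undefined")
    return tawss(series, regions.sac_surface).mean / parent.mean


class QuadraticGradientOperator:
    """Gradient from a weighted quadratic least-squares fit.

    Fits du = G^T dx + (quadratic terms) over the k nearest neighbours.
    Exact for any quadratic field, which makes one-sided wall
    neighbourhoods unbiased on parabolic (Poiseuille-like) profiles where
    an affine fit systematically under-predicts the wall gradient.
    """

    N_BASIS = 9  # 3 linear + 6 quadratic monomials

    def __init__(self, points: np.ndarray, k: int = 24, eval_idx: np.ndarray | None = None):
        points = np.asarray(points, float)
        self.eval_idx = np.arange(len(points)) if eval_idx is None else np.asarray(eval_idx, int)
        k = min(k, len(points) - 1)
        if k < self.N_BASIS + 1:
            raise ValueError(f"need at least {self.N_BASIS + 1} neighbours for a quadratic fit")
        tree = cKDTree(points)
        dist, nbr = tree.query(points[self.eval_idx], k=k + 1)
        self.nbr = nbr[:, 1:]
        dx = points[self.nbr] - points[self.eval_idx, None, :]  # (P, k, 3)
        self.scale = dist[:, 1:].mean(axis=1)  # local length scale, conditioning
        xi = dx / self.scale[:, None, None]
        basis = np.concatenate(
            [
                xi,
                xi**2,
                xi[..., [0]] * xi[..., [1]],
                xi[..., [0]] * xi[..., [2]],
                xi[..., [1]] * xi[..., [2]],
            ],
            axis=2,
        )  # (P, k, 9)
        w = 1.0 / np.maximum(dist[:, 1:], 1e-300)
        self.w = w
        self.basis = basis
        self.a = np.einsum("pk,pki,pkj->pij", w, basis, basis)
        if np.any(np.linalg.matrix_rank(self.a) < self.N_BASIS):
            bad = int(self.eval_idx[np.argmax(np.linalg.matrix_rank(self.a) < self.N_BASIS)])
            raise ValueError(f"degenerate neighbourhood at point {bad} for quadratic fit")

    def __call__(self, values: np.ndarray) -> np.ndarray:
        """Gradient tensors (P, 3, 3), G[a, b] = d values_b / d x_a."""
        du = values[self.nbr] - values[self.eval_idx, None, :]  # (P, k, C)
        b = np.einsum("pk,pki,pkc->pic", self.w, self.basis, du)
        coef = np.linalg.solve(self.a, b)  # (P, 9, C)
        return coef[:, :3, :] / self.scale[:, None, None]


def wss_from_velocity(
    series: FieldSeries, surface_region: np.ndarray, k: int = 24
) -> np.ndarray:
    """Wall shear stress from the velocity field: tau = mu * d(u_t)/dn.

    The velocity gradient is reconstructed at each wall vertex by a
    weighted quadratic least-squares fit over its (one-sided, interior)
    neighbourhood — exact for linear shear and for parabolic pipe
    profiles — averaged per triangle, and the tangential part of the
    inward-normal directional derivative is scaled by the viscosity.
    Returns (T, S_r, 3) WSS vectors.
    """
    surface_region = np.asarray(surface_region, int)
    tris = series.surface_tris[surface_region]
    verts = np.unique(tris.ravel())
    op = QuadraticGradientOperator(series.points, k=k, eval_idx=verts)
    pos = {p: i for i, p in enumerate(verts)}
    tri_local = np.vectorize(pos.get)(tris)
    inward = -series.surface_normals[surface_region]  # into the fluid
    out = np.empty((series.times.size, len(tris), 3))
    for it in range(series.times.size):
        g = op(series.velocity[it])            # (P, 3, 3), g[a,b] = d u_b / d x_a
        g_tri = g[tri_local].mean(axis=1)      # (S_r, 3, 3)
        dudn = np.einsum("sa,sab->sb", inward, g_tri)
        normal_part = np.einsum("sb,sb->s", dudn, inward)[:, None] * inward
        out[it] = series.mu * (dudn - normal_part)
    return out


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def metrics_report(series: FieldSeries, regions: RegionSet, k: int = 24) -> MetricsReport:
    """All flow and shear metrics for one aneurysm over one cycle.

    Temporal means are over the supplied cycle; spatial means are over
    the sac volume (flow metrics) or sac surface (wall metrics).  If the
    series carries no WSS samples they are first derived from the
    velocity field.
    """
    regions.validate_against(series)
    if series.wss is None:
        full = np.arange(len(series.surface_tris))
        series.wss = wss_from_velocity(series, full, k=k)
    t = series.times
    ke_t = np.array([kinetic_energy(series, i, regions.sac_cells) for i in range(t.size)])
    return MetricsReport(
        mean_V=mean_speed(series, regions.sac_cells),
        mean_vorticity=mean_vorticity_magnitude(series, regions.sac_cells, k=k),
        KE=float(_trapz(ke_t, t) / series.period),
        KER=ker(series, regions),
        OVI=ovi(series, regions.sac_cells),
        TAWSS=tawss(series, regions.sac_surface).mean,
        nTAWSS=ntawss(series, regions),
        LSA=lsa(series, regions),
    )
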