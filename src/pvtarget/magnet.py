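"""Disc-magnet magnetostatics and magnetophoretic forces.

The targeting magnet is an axially magnetized neodymium (N40) disc
(remanence ``Br`` = 1.3 T, radius ``R`` = 2.0 mm, thickness ``D`` = 2.4 mm)
glued into the lid of the perfusion chamber directly above the vessel
bifurcation, with a 0.4 mm gap between the magnet face and the top lumen
surface.

On the symmetry axis the flux density at a distance ``z`` from the near
face has the closed form

    Bz(z) = (Br/2) * [ (D+z)/sqrt(R^2+(D+z)^2) - z/sqrt(R^2+z^2) ]

Off axis, the uniformly magnetized cylinder is equivalent to an azimuthal
surface-current sheet; the field is computed by superposing circular
current loops distributed over the thickness (Biot-Savart via complete
elliptic integrals).  Loop positions use Gauss-Legendre nodes so the
on-axis values reduce to the closed form to near machine precision.

Forces on superparamagnetic particles use the standard magnetophoretic
form F = V * M(B) (B_hat . grad) B with a linear-susceptibility
magnetization capped at saturation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy.special import ellipe, ellipk

MU_0 = 4.0e-7 * np.pi  # vacuum permeability, T m / A


class MagnetDomainError(ValueError):
    """Field evaluation requested inside the magnet body (model invalid there)."""


@dataclass(frozen=True)
class DiscMagnet:
    """Axially magnetized cylindrical permanent magnet.

    Parameters
    ----------
    Br : float
        Remanence, tesla.
    R : float
        Magnet radius, m.
    D : float
        Magnet thickness, m.
    face_center : tuple
        Coordinates of the center of the near (sample-facing) face.  Length
        2 or 3; must match the dimensionality of evaluation points.
    axis : tuple
        Unit vector along the magnet axis, pointing *away from the magnet
        body into the sample region* (``z`` in the axial formula is measured
        along this direction from the near face).
    """

    Br: float = 1.3
    R: float = 2.0e-3
    D: float = 2.4e-3
    face_center: tuple = (0.0, 0.0)
    axis: tuple = (0.0, -1.0)

    def __post_init__(self):
        if self.Br <= 0:
            raise ValueError(f"Br must be > 0, got {self.Br}")
        if self.R <= 0:
            raise ValueError(f"R must be > 0, got {self.R}")
        if self.D <= 0:
            raise ValueError(f"D must be > 0, got {self.D}")
        ax = np.asarray(self.axis, dtype=float)
        if len(ax) != len(self.face_center):
            raise ValueError("axis and face_center must have the same dimension")
        n = float(np.linalg.norm(ax))
        if abs(n - 1.0) > 1e-9:
            raise ValueError(f"|axis| must be 1, got {n:.6g}")


def axial_Bz(magnet: DiscMagnet, z: ArrayLike) -> NDArray | float:
    """On-axis flux density at axial distance ``z`` (m) from the near face.

    Strictly decreasing in z; bounded by (0, Br); z < 0 is rejected (the
    model is valid outside the magnet only).
    """
    z_arr = np.asarray(z, dtype=float)
    if np.any(z_arr < 0):
        raise MagnetDomainError("axial_Bz requires z >= 0 (outside the magnet)")
    R, D = magnet.R, magnet.D
    val = 0.5 * magnet.Br * (
        (D + z_arr) / np.hypot(R, D + z_arr) - z_arr / np.hypot(R, z_arr)
    )
    return val if val.ndim else float(val)


def axial_dBz_dz(magnet: DiscMagnet, z: ArrayLike) -> NDArray | float:
    """Closed-form on-axis derivative dBz/dz (T/m); negative for all z > 0."""
    z_arr = np.asarray(z, dtype=float)
    if np.any(z_arr < 0):
        raise MagnetDomainError("axial_dBz_dz requires z >= 0")
    R, D = magnet.R, magnet.D
    val = 0.5 * magnet.Br * R**2 * (
        (R**2 + (D + z_arr) ** 2) ** -1.5 - (R**2 + z_arr**2) ** -1.5
    )
    return val if val.ndim else float(val)


def _loop_field(a: float, I: float, r: NDArray, dz: NDArray):
    """Field (B_r, B_z) of a circular current loop, radius ``a``, current ``I``.

    ``r`` is the cylindrical radius of the evaluation points, ``dz`` the
    axial offset from the loop plane.  Standard Biot-Savart result in terms
    of complete elliptic integrals K(m), E(m) with m = k^2.
    """
    r = np.abs(r)
    denom_sq = (a + r) ** 2 + dz**2
    denom = np.sqrt(denom_sq)
    m = 4.0 * a * r / denom_sq
    m = np.clip(m, 0.0, 1.0 - 1e-15)
    K = ellipk(m)
    E = ellipe(m)
    near_sq = (a - r) ** 2 + dz**2
    pref = MU_0 * I / (2.0 * np.pi * denom)
    Bz = pref * (K + (a**2 - r**2 - dz**2) / near_sq * E)
    with np.errstate(divide="ignore", invalid="ignore"):
        Brad = pref * dz / r * (-K + (a**2 + r**2 + dz**2) / near_sq * E)
    Brad = np.where(r < 1e-12 * a, 0.0, Brad)
    return Brad, Bz


def _to_magnet_frame(magnet: DiscMagnet, points: NDArray):
    """Return (r, z, radial unit vectors) of points in the magnet frame."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    ax = np.asarray(magnet.axis, dtype=float)
    rel = pts - np.asarray(magnet.face_center, dtype=float)
    z = rel @ ax
    perp = rel - np.outer(z, ax)
    r = np.linalg.norm(perp, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.where(r[:, None] > 0, perp / np.where(r[:, None] == 0, 1, r[:, None]), 0.0)
    return pts, r, z, rhat, ax


def _cyl_field(magnet: DiscMagnet, r: NDArray, z: NDArray, n_loops: int = 64):
    """(B_r, B_z) of the magnetized cylinder at cylindrical coords (r, z).

    Loops at Gauss-Legendre nodes over the thickness; surface current per
    unit length Br/mu0.
    """
    nodes, weights = np.polynomial.legendre.leggauss(n_loops)
    # map [-1, 1] -> depth zeta in [0, D] behind the near face
    zeta = 0.5 * magnet.D * (nodes + 1.0)
    w = 0.5 * magnet.D * weights
    M = magnet.Br / MU_0  # magnetization = sheet current density, A/m
    Brad = np.zeros_like(r, dtype=float)
    Bz = np.zeros_like(r, dtype=float)
    for zk, wk in zip(zeta, w):
        br_k, bz_k = _loop_field(magnet.R, M * wk, r, z + zk)
        Brad += br_k
        Bz += bz_k
    return Brad, Bz


def _check_outside(magnet: DiscMagnet, r: NDArray, z: NDArray):
    inside = (r <= magnet.R) & (z <= 0) & (z >= -magnet.D)
    if np.any(inside):
        raise MagnetDomainError(
            "field requested inside the magnet body; the loop-superposition "
            "model is valid outside only"
        )


def field_at(magnet: DiscMagnet, points: ArrayLike, n_loops: int = 64) -> NDArray:
    """Flux-density vector(s) at Cartesian point(s) outside the magnet.

    Accepts a single point or an (n, dim) array; returns the same shape.
    Axisymmetric about the magnet axis; reduces to :func:`axial_Bz` on axis.
    """
    single = np.asarray(points, dtype=float).ndim == 1
    pts, r, z, rhat, ax = _to_magnet_frame(magnet, points)
    _check_outside(magnet, r, z)
    Brad, Bz = _cyl_field(magnet, r, z, n_loops=n_loops)
    B = Bz[:, None] * ax[None, :] + Brad[:, None] * rhat
    return B[0] if single else B


def gradient_at(magnet: DiscMagnet, points: ArrayLike, step: float | None = None,
                n_loops: int = 64) -> NDArray:
    """Gradient tensor dB_i/dx_j (T/m) by central differences.

    ``step`` defaults to R/100; on the axis the zz component matches the
    closed-form derivative of the axial formula.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    single = np.asarray(points, dtype=float).ndim == 1
    dim = pts.shape[1]
    h = step if step is not None else magnet.R / 100.0
    grad = np.empty((pts.shape[0], dim, dim))
    for j in range(dim):
        e = np.zeros(dim)
        e[j] = h
        Bp = np.atleast_2d(field_at(magnet, pts + e, n_loops=n_loops))
        Bm = np.atleast_2d(field_at(magnet, pts - e, n_loops=n_loops))
        grad[:, :, j] = (Bp - Bm) / (2.0 * h)
    return grad[0] if single else grad


@dataclass(frozen=True)
class ParticleMagnetics:
    """Magnetic properties of a superparamagnetic particle.

    ``magnetic_volume`` is the magnetite-equivalent core volume (m^3); the
    hydrodynamic envelope is larger and irrelevant to the force.
    ``chi`` is the effective (demagnetization-corrected) volume
    susceptibility of the core material; ``Msat`` its saturation
    magnetization (A/m).
    """

    magnetic_volume: float
    chi: float = 20.0
    Msat: float = 4.8e5

    def __post_init__(self):
        if self.magnetic_volume <= 0:
            raise ValueError("magnetic_volume must be > 0")
        if self.chi < 0:
            raise ValueError("chi must be >= 0")
        if self.Msat <= 0:
            raise ValueError("Msat must be > 0")


def magnetophoretic_force(B: ArrayLike, gradB: ArrayLike,
                          particle: ParticleMagnetics) -> NDArray:
    """Force (N) on a magnetizable particle in field ``B`` with gradient ``gradB``.

    F = V * (M . grad) B with M = chi * B / mu0 capped at |M| <= Msat.
    Below saturation this is the familiar (V chi / mu0) (B . grad) B, linear
    in the magnetic volume.  Broadcasts over leading axes: B may be (..., d)
    and gradB (..., d, d).
    """
    B = np.asarray(B, dtype=float)
    G = np.asarray(gradB, dtype=float)
    Bmag = np.linalg.norm(B, axis=-1, keepdims=True)
    M_lin = particle.chi * Bmag / MU_0
    Mmag = np.minimum(M_lin, particle.Msat)
    with np.errstate(divide="ignore", invalid="ignore"):
        Mvec = np.where(Bmag > 0, Mmag * B / np.where(Bmag == 0, 1, Bmag), 0.0)
    # F_i = V * M_j dB_i/dx_j
    return particle.magnetic_volume * np.einsum("...ij,...j->...i", G, Mvec)


@dataclass
class FieldMap:
    """Flux density and gradient sampled on a lattice of points."""

    points: NDArray          # (n, dim) sampling locations, m
    B: NDArray               # (n, dim) flux density, T
    gradB: NDArray           # (n, dim, dim) gradient tensor, T/m
    shape: tuple = field(default=())  # optional grid shape for reshaping

    @property
    def magnitude(self) -> NDArray:
        return np.linalg.norm(self.B, axis=-1)


def sample_field(magnet: DiscMagnet, points: ArrayLike, shape: tuple = (),
                 n_loops: int = 64, grad_step: float | None = None) -> FieldMap:
    """Sample B and grad B at the given points (e.g. fluid-cell centers)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    B = field_at(magnet, pts, n_loops=n_loops)
    G = gradient_at(magnet, pts, step=grad_step, n_loops=n_loops)
    return FieldMap(points=pts, B=B, gradB=G, shape=tuple(shape))


def overhead_force_interp(magnet: DiscMagnet, magnetics: "ParticleMagnetics",
                          apex_xy: tuple, z_plane: float, r_max: float,
                          nr: int = 241):
    """In-plane magnetophoretic force of a magnet held above the plane.

    The magnet axis is perpendicular to the 2D plane, its near face a
    height ``z_plane`` above it, centered over ``apex_xy``.  The returned
    callable maps (n, 2) in-plane points to the in-plane force components
    (N): the radial component of F = V M(B) (B_hat . grad) B at height
    ``z_plane``, directed along the line to ``apex_xy`` (inward for a
    gradient pulling toward the axis).  The out-of-plane pull is not
    representable in 2D and is dropped.
    """
    from scipy.interpolate import interp1d

    r = np.linspace(0.0, r_max, nr)
    dr = r[1] - r[0]
    dz = z_plane * 1e-3
    Brad0, Bz0 = _cyl_field(magnet, r, np.full_like(r, z_plane))
    Brad_p, Bz_p = _cyl_field(magnet, r + dr, np.full_like(r, z_plane))
    Brad_m, Bz_m = _cyl_field(magnet, np.maximum(r - dr, 0.0),
                              np.full_like(r, z_plane))
    Brad_zp, Bz_zp = _cyl_field(magnet, r, np.full_like(r, z_plane + dz))
    Brad_zm, Bz_zm = _cyl_field(magnet, r, np.full_like(r, z_plane - dz))
    dBr_dr = (Brad_p - Brad_m) / (2 * dr)
    dBr_dz = (Brad_zp - Brad_zm) / (2 * dz)
    Bmag = np.hypot(Brad0, Bz0)
    Mmag = np.minimum(magnetics.chi * Bmag / MU_0, magnetics.Msat)
    with np.errstate(divide="ignore", invalid="ignore"):
        bhat_r = np.where(Bmag > 0, Brad0 / np.where(Bmag == 0, 1, Bmag), 0.0)
        bhat_z = np.where(Bmag > 0, Bz0 / np.where(Bmag == 0, 1, Bmag), 0.0)
    Fr = magnetics.magnetic_volume * Mmag * (bhat_r * dBr_dr + bhat_z * dBr_dz)
    fr_of_r = interp1d(r, Fr, bounds_error=False, fill_value=0.0)
    ax = np.asarray(apex_xy, dtype=float)

    def force(pts):
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        rel = pts - ax
        rr = np.linalg.norm(rel, axis=1)
        fr = fr_of_r(rr)
        with np.errstate(divide="ignore", invalid="ignore"):
            unit = np.where(rr[:, None] > 0,
                            rel / np.where(rr[:, None] == 0, 1, rr[:, None]),
                            0.0)
        return fr[:, None] * unit

    return force


def overhead_body_force(mask, magnet: DiscMagnet, magnetics,
                        number_density: float, apex_xy: tuple,
                        z_plane: float) -> tuple:
    """Cell-centered body-force density (fx, fy), N/m^3, overhead magnet."""
    x, y = mask.cell_centers()
    X, Y = np.meshgrid(x, y, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel()])
    r_max = float(np.max(np.linalg.norm(pts - np.asarray(apex_xy), axis=1))) * 1.05
    force = overhead_force_interp(magnet, magnetics, apex_xy, z_plane, r_max)
    F = force(pts) * number_density
    fx = F[:, 0].reshape(X.shape)
    fy = F[:, 1].reshape(X.shape)
    m = mask.fluid_mask()
    fx[~m] = 0.0
    fy[~m] = 0.0
    return fx, fy


def sample_field_on_mask(magnet: DiscMagnet, mask, n_loops: int = 64) -> FieldMap:
    """Sample the field on the fluid cells of a rasterized domain.

    Raises a configuration error if the magnet body overlaps the fluid
    domain.  Returns a FieldMap whose points are the fluid-cell centers in
    mask order (see ``DomainMask.fluid_points``).
    """
    pts = mask.fluid_points()
    _, r, z, _, _ = _to_magnet_frame(magnet, pts)
    inside = (r <= magnet.R) & (z <= 0) & (z >= -magnet.D)
    if np.any(inside):
        raise MagnetDomainError("magnet body overlaps the fluid domain")
    return sample_field(magnet, pts, shape=mask.occupancy.shape,
                        n_loops=n_loops, grad_step=mask.spacing / 10.0)
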