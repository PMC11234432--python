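"""Parametric bifurcated vessel geometry, rasterization, and printing fidelity.

The bioprinted construct carries a Y-shaped pulmonary-vein-like channel:
a trunk that splits into two symmetric branches (one inlet, two outlets),
2 mm lumen diameter inside a 4 mm outer wall, printed within a
14 mm x 25 mm footprint.  The channel mid-plane is modelled in 2D with x
along the trunk axis and y the magnet-ward transverse axis; the magnet sits
above the bifurcation apex.

Printing fidelity is quantified as the ratio of measured (printed) to CAD
dimensions for construct length/width/height, channel diameter, and
circularity; a ratio of 1 is ideal.  Circularity uses the isoperimetric
quotient 4*pi*A/P^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from numpy.typing import NDArray
from scipy import ndimage
from shapely.geometry import LineString, Point, Polygon
from shapely.ops import unary_union

FLUID, WALL, INLET, OUTLET1, OUTLET2 = 1, 0, 2, 3, 4


class GeometryValidationError(ValueError):
    pass


class ResolutionError(ValueError):
    pass


@dataclass(frozen=True)
class BifurcationSpec:
    """Parametric description of the bifurcated channel.

    Lengths in meters; ``branch_half_angle_deg`` is the angle of each branch
    from the trunk axis.  ``branch_length = 0`` degenerates to a straight
    trunk-only channel (used for solver validation).  The trunk runs from
    x = 0 to x = trunk_length, branches continue to +x.
    """

    lumen_diameter: float = 2.0e-3
    wall_outer_diameter: float = 4.0e-3
    construct_width: float = 14.0e-3
    construct_height: float = 25.0e-3
    trunk_length: float = 10.0e-3
    branch_length: float = 8.0e-3
    branch_half_angle_deg: float = 30.0

    def __post_init__(self):
        for name in ("lumen_diameter", "wall_outer_diameter", "construct_width",
                     "construct_height", "trunk_length"):
            if getattr(self, name) <= 0:
                raise GeometryValidationError(f"{name} must be > 0")
        if self.branch_length < 0:
            raise GeometryValidationError("branch_length must be >= 0")
        if self.lumen_diameter >= self.wall_outer_diameter:
            raise GeometryValidationError(
                "lumen_diameter must be smaller than wall_outer_diameter")
        if self.branch_length > 0 and not (0 < self.branch_half_angle_deg < 90):
            raise GeometryValidationError(
                "branch_half_angle_deg must lie in (0, 90)")
        # generated channel must fit the printed footprint
        bb = self._bbox()
        if bb[2] - bb[0] > self.construct_height or bb[3] - bb[1] > self.construct_width:
            raise GeometryValidationError(
                "channel bounding box exceeds construct_width x construct_height")

    @property
    def apex(self) -> tuple:
        return (self.trunk_length, 0.0)

    def _bbox(self):
        r = self.lumen_diameter / 2.0
        th = np.deg2rad(self.branch_half_angle_deg)
        x_max = self.trunk_length + self.branch_length * np.cos(th)
        y_max = self.branch_length * np.sin(th) + r
        return (0.0, -y_max, x_max, y_max)  # xmin, ymin, xmax, ymax


def build_bifurcation(spec: BifurcationSpec, branch_extension: float = 0.0):
    """Centerline polylines and the channel wall polygon.

    Returns ``(centerlines, polygon)`` where ``centerlines`` is a list of
    (2, 2) arrays [trunk, branch_up, branch_down] (trunk only when
    branch_length = 0) all meeting at the apex, and ``polygon`` is the
    shapely lumen footprint (centerlines buffered by the lumen radius, flat
    caps at the three open ends, a disc patching the junction wedge).
    """
    r = spec.lumen_diameter / 2.0
    trunk = np.array([[0.0, 0.0], list(spec.apex)])
    lines = [trunk]
    if spec.branch_length > 0:
        th = np.deg2rad(spec.branch_half_angle_deg)
        d = (spec.branch_length + branch_extension) * np.array(
            [np.cos(th), np.sin(th)])
        ax, ay = spec.apex
        lines.append(np.array([[ax, ay], [ax + d[0], ay + d[1]]]))
        lines.append(np.array([[ax, ay], [ax + d[0], ay - d[1]]]))
    parts = [LineString(li).buffer(r, cap_style="flat") for li in lines]
    if spec.branch_length > 0:
        parts.append(Point(spec.apex).buffer(r, quad_segs=32))
    poly = unary_union(parts)
    if not isinstance(poly, Polygon):
        raise GeometryValidationError("channel footprint is not a single polygon")
    return lines, poly


@dataclass
class DomainMask:
    """Cell-centered rasterization of the fluid domain.

    ``occupancy[i, j]`` labels the cell with center
    ``origin + spacing * (i, j)`` (x index first).  Labels: 0 wall,
    1 fluid, 2 inlet, 3 outlet1, 4 outlet2 (inlet/outlet cells are fluid
    cells on the domain boundary).  ``roi_centers`` maps ROI names to
    (center_xy, radius) discs used by capture statistics and the
    magnet-perturbation report.
    """

    occupancy: NDArray
    spacing: float
    origin: tuple
    roi_centers: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple:
        return self.occupancy.shape

    def cell_centers(self) -> tuple:
        nx, ny = self.occupancy.shape
        x = self.origin[0] + self.spacing * np.arange(nx)
        y = self.origin[1] + self.spacing * np.arange(ny)
        return x, y

    def fluid_mask(self) -> NDArray:
        return self.occupancy != WALL

    def fluid_points(self) -> NDArray:
        x, y = self.cell_centers()
        X, Y = np.meshgrid(x, y, indexing="ij")
        m = self.fluid_mask()
        return np.column_stack([X[m], Y[m]])

    def fluid_area(self) -> float:
        return float(np.count_nonzero(self.fluid_mask())) * self.spacing**2

    def in_roi(self, name: str, points: NDArray) -> NDArray:
        c, rad = self.roi_centers[name]
        d = np.linalg.norm(np.atleast_2d(points) - np.asarray(c), axis=1)
        return d <= rad

    def to_csv(self, path):
        """Plain-text export: header lines then the integer label grid."""
        with open(path, "w") as fh:
            fh.write(f"# spacing_m {self.spacing!r}\n")
            fh.write(f"# origin_m {self.origin[0]!r} {self.origin[1]!r}\n")
            fh.write("# labels 0=wall 1=fluid 2=inlet 3=outlet1 4=outlet2\n")
            np.savetxt(fh, self.occupancy.T[::-1], fmt="%d", delimiter=",")


def rasterize(spec: BifurcationSpec, spacing: float,
              target_roi_radius: float = 2.0e-3,
              offtarget_upstream: float = 2.0e-3) -> DomainMask:
    """Rasterize the channel footprint onto a cell-centered grid.

    The grid covers the polygon bounding box exactly, so the open channel
    ends intersect the domain boundary; boundary-adjacent fluid cells there
    are labelled inlet (x = 0 end) and outlet1/outlet2 (downstream ends,
    upper/lower branch).  Default ROIs: ``target`` = disc at the apex
    (radius matching the 4 mm magnet footprint), ``off_target`` = disc
    centered 2 mm upstream of the outlet boundary on each branch axis.
    """
    if spacing > spec.lumen_diameter / 8.0:
        raise ResolutionError(
            f"spacing {spacing:g} m too coarse; need <= lumen_diameter/8 "
            f"= {spec.lumen_diameter / 8.0:g} m")
    # extend the branches past the outlet plane, then crop there, so the
    # outlet openings are full-lumen cuts of the grid boundary (the oblique
    # flat caps would otherwise truncate them to a corner)
    th = np.deg2rad(spec.branch_half_angle_deg)
    r = spec.lumen_diameter / 2.0
    ext = r * np.tan(th) if spec.branch_length > 0 else 0.0
    _, poly = build_bifurcation(spec, branch_extension=ext)
    x_cut = spec.trunk_length + spec.branch_length * np.cos(th)
    from shapely.geometry import box as shapely_box

    ymin0 = poly.bounds[1] - spacing
    ymax0 = poly.bounds[3] + spacing
    poly = poly.intersection(shapely_box(0.0, ymin0, x_cut, ymax0))
    xmin, ymin, xmax, ymax = 0.0, poly.bounds[1], x_cut, poly.bounds[3]
    nx = max(int(np.round((xmax - xmin) / spacing)), 1)
    ny = max(int(np.ceil((ymax - ymin) / spacing)), 1)
    origin = (xmin + spacing / 2.0, ymin + spacing / 2.0)
    x = origin[0] + spacing * np.arange(nx)
    y = origin[1] + spacing * np.arange(ny)
    X, Y = np.meshgrid(x, y, indexing="ij")
    fluid = shapely.contains_xy(poly, X.ravel(), Y.ravel()).reshape(X.shape)
    occ = np.where(fluid, FLUID, WALL).astype(np.int8)

    # keep the largest connected fluid component (guards stray corner cells)
    lab, nlab = ndimage.label(occ != WALL)
    if nlab > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, nlab + 1))
        keep = 1 + int(np.argmax(sizes))
        occ[(lab != keep)] = WALL

    # boundary labels: inlet on the x-min column, outlets on the x-max column
    inlet_col = occ[0, :] != WALL
    occ[0, inlet_col] = INLET
    out_col = occ[-1, :] != WALL
    if spec.branch_length > 0:
        upper = y >= spec.apex[1]
        occ[-1, out_col & upper] = OUTLET1
        occ[-1, out_col & ~upper] = OUTLET2
    else:
        occ[-1, out_col] = OUTLET1

    th = np.deg2rad(spec.branch_half_angle_deg)
    rois: dict = {"target": (spec.apex, target_roi_radius)}
    if spec.branch_length > 0:
        L = spec.branch_length - offtarget_upstream
        ax, ay = spec.apex
        rois["off_target_1"] = ((ax + L * np.cos(th), ay + L * np.sin(th)),
                                target_roi_radius)
        rois["off_target_2"] = ((ax + L * np.cos(th), ay - L * np.sin(th)),
                                target_roi_radius)
    mask = DomainMask(occupancy=occ, spacing=spacing, origin=origin,
                      roi_centers=rois)
    return mask


def export_stl(spec: BifurcationSpec, path, spacing: float | None = None):
    """Write the channel solid as a watertight binary STL.

    The lumen footprint is voxelized at ``spacing`` (default lumen/16),
    extruded through the lumen diameter (the out-of-plane channel depth),
    and surfaced with marching cubes, giving a closed triangulated solid
    re-readable by standard mesh tools; the mesh bounding box matches the
    footprint within one voxel spacing.  Returns the trimesh mesh.
    """
    import trimesh
    from skimage.measure import marching_cubes

    h = spacing if spacing is not None else spec.lumen_diameter / 16.0
    mask = rasterize(spec, h)
    nz = max(int(np.round(spec.lumen_diameter / h)), 1)
    vol = np.zeros((mask.shape[0] + 2, mask.shape[1] + 2, nz + 2), dtype=float)
    vol[1:-1, 1:-1, 1:-1] = mask.fluid_mask()[:, :, None].astype(float)
    verts, faces, _, _ = marching_cubes(vol, level=0.5, spacing=(h, h, h))
    # voxel (1,1,1) center maps to the first cell center (origin)
    offset = np.array([mask.origin[0] - h, mask.origin[1] - h, -h + h / 2.0])
    mesh = trimesh.Trimesh(vertices=verts + offset, faces=faces, process=True)
    if not mesh.is_watertight:  # pragma: no cover - closed padded volume
        raise RuntimeError("channel surface mesh is not watertight")
    mesh.export(path, file_type="stl")
    return mesh


@dataclass(frozen=True)
class FidelityReport:
    """Printed/CAD dimension ratios; 1.0 is ideal structural fidelity."""

    ratio_l: float
    ratio_w: float
    ratio_h: float
    ratio_d: float
    ratio_c: float
    tolerance: float = 0.1

    def as_dict(self) -> dict:
        return {k: getattr(self, f"ratio_{k}") for k in "lwhdc"}

    @property
    def out_of_tolerance(self) -> list:
        """Parameters whose ratio falls outside (1-tol, 1+tol)."""
        return [k for k, v in self.as_dict().items()
                if not (1.0 - self.tolerance < v < 1.0 + self.tolerance)]


def fidelity_ratios(measured: dict, cad: dict, tolerance: float = 0.1) -> FidelityReport:
    """Element-wise measured/CAD ratios for the l, w, h, d, c indices."""
    vals = {}
    for k in "lwhdc":
        if k not in measured or k not in cad:
            raise GeometryValidationError(f"missing fidelity parameter '{k}'")
        if cad[k] <= 0:
            raise GeometryValidationError(f"CAD value for '{k}' must be > 0")
        vals[k] = measured[k] / cad[k]
    return FidelityReport(*(vals[k] for k in "lwhdc"), tolerance=tolerance)


def circularity(area: float, perimeter: float) -> float:
    """Isoperimetric quotient 4*pi*A/P^2; 1 for a perfect circle."""
    if area <= 0 or perimeter <= 0:
        raise GeometryValidationError("area and perimeter must be > 0")
    return 4.0 * np.pi * area / perimeter**2
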