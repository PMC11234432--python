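"""Canonical study scenarios wiring geometry, magnet, flow and transport.

These encode the desk-scale study conditions used throughout the analysis
scripts, tests and acceptance checks:

* ``straight_channel_mask`` - a trunk-only channel with mirrored top/bottom
  wall ROIs; the geometrically symmetric configuration for zero-field null
  checks.
* ``channel_capture`` - the bifurcation perfused at a slow post-perfusion
  flow with the disc magnet held over the apex; capture is scored in the
  target (apex) versus off-target (outlet-adjacent) ROI discs.  One-way
  coupling: the frozen flow snapshot is not perturbed by the particles.
* ``dish_targeting`` - the 12-well monolayer experiment: magnet taped
  under the well bottom, no flow, deposition on the bottom surface.

Magnet representation in the 2D planform: the physical magnet sits above
the plane over the apex, so the in-plane drift/body force uses the radial
component of the overhead magnet's force at the mid-plane height
(:func:`pvtarget.magnet.overhead_force_interp`); it decays with in-plane
distance from the apex, localizing the pull at the bifurcation as in the
experiment.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .config import RunConfig
from .geometry import BifurcationSpec, DomainMask, rasterize
from .hemodynamics import FlowConfig, solve_steady
from .magnet import DiscMagnet, overhead_body_force, overhead_force_interp
from .transport import (CaptureStats, capture_stats, sample_population,
                        simulate, well_mode)


def straight_channel_mask(length: float = 16.0e-3, lumen: float = 2.0e-3,
                          spacing: float = 0.125e-3,
                          roi_radius: float = 2.0e-3) -> DomainMask:
    """Trunk-only channel with mirrored mid-length wall ROIs."""
    spec = BifurcationSpec(lumen_diameter=lumen, trunk_length=length,
                           branch_length=0.0)
    mask = rasterize(spec, spacing)
    mid = length / 2.0
    mask.roi_centers = {
        "target": ((mid, lumen / 2.0), roi_radius),
        "off_target_1": ((mid, -lumen / 2.0), roi_radius),
    }
    return mask


def overhead_plane_height(spec: BifurcationSpec, gap: float = 0.4e-3) -> float:
    """Height of the magnet near face above the channel mid-plane:
    the configured gap plus the lumen radius (top lumen surface)."""
    return gap + spec.lumen_diameter / 2.0


def _scenario_population(cfg: RunConfig, seed: int, n: int | None = None):
    return sample_population(
        n=n or cfg.particles.n, mean_d=cfg.particles.mean_d_nm * 1e-9,
        sd_d=cfg.particles.sd_d_nm * 1e-9, seed=seed,
        cores_per_particle=cfg.particles.cores_per_particle,
        core_diameter=cfg.particles.core_diameter_nm * 1e-9,
        chi=cfg.particles.chi, Msat=cfg.particles.Msat_A_m,
        temperature=cfg.particles.temperature_K)


def apex_force(cfg: RunConfig, Br: float | None = None,
               gap_mm: float | None = None, magnetics=None):
    """Overhead-magnet in-plane force callable for the bifurcation (or None
    when the remanence is zero)."""
    br = cfg.magnet.Br_T if Br is None else Br
    if br <= 0:
        return None
    spec = cfg.geometry.spec()
    magnet = replace(cfg.magnet.magnet(), Br=br)
    gap = (cfg.magnet.gap_mm if gap_mm is None else gap_mm) * 1e-3
    if magnetics is None:
        magnetics = _scenario_population(cfg, 0, n=1).magnetics
    z_plane = overhead_plane_height(spec, gap)
    return overhead_force_interp(magnet, magnetics, apex_xy=spec.apex,
                                 z_plane=z_plane, r_max=0.03)


def place_magnet_over_apex(spec: BifurcationSpec, magnet: DiscMagnet,
                           gap: float = 0.4e-3) -> DiscMagnet:
    """In-plane magnet: face ``gap`` above the highest lumen surface within
    its footprint, centered over the apex, axis pointing down (-y)."""
    from shapely.geometry import LineString

    from .geometry import build_bifurcation

    _, poly = build_bifurcation(spec)
    ax = spec.apex[0]
    xs = np.linspace(ax - magnet.R, ax + magnet.R, 41)
    ys = []
    for xi in xs:
        cut = poly.intersection(LineString([(xi, poly.bounds[1] - 1e-3),
                                            (xi, poly.bounds[3] + 1e-3)]))
        if not cut.is_empty:
            ys.append(cut.bounds[3])
    y_top = max(ys) if ys else poly.bounds[3]
    return replace(magnet, face_center=(ax, y_top + gap), axis=(0.0, -1.0))


def inplane_capture_force(cfg: RunConfig, mask: DomainMask,
                          Br: float | None = None,
                          gap_mm: float | None = None, magnetics=None):
    """Force callable of the raised in-plane magnet (capture mechanism).

    In the planform the wall nearest the magnet is the upper-branch
    shoulder; this force pulls suspended particles onto it, the 2D analog
    of pinning against the top lumen wall.  Returns None for zero
    remanence.
    """
    br = cfg.magnet.Br_T if Br is None else Br
    if br <= 0:
        return None
    gap = (cfg.magnet.gap_mm if gap_mm is None else gap_mm) * 1e-3
    magnet = replace(
        place_magnet_over_apex(cfg.geometry.spec(), cfg.magnet.magnet(),
                               gap=gap), Br=br)
    if magnetics is None:
        magnetics = _scenario_population(cfg, 0, n=1).magnetics
    from .transport import _force_interp_2d

    return _force_interp_2d(magnet, mask, magnetics)


def bifurcation_setup(cfg: RunConfig | None = None):
    """(mask, steady slow-flow field) for the capture scenario."""
    cfg = cfg or RunConfig()
    spec = cfg.geometry.spec()
    mask = rasterize(spec, cfg.geometry.spacing_mm * 1e-3,
                     target_roi_radius=cfg.particles.target_roi_radius_mm * 1e-3)
    fc = FlowConfig(density=cfg.flow.density_kg_m3,
                    viscosity=cfg.flow.viscosity_pa_s)
    flow = solve_steady(mask, fc, Q_ml_min=cfg.particles.capture_flow_ml_min,
                        initialize="profile")
    return mask, flow


def _release_uniform(mask: DomainMask, n: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    pts = mask.fluid_points()
    idx = rng.integers(0, len(pts), n)
    jitter = rng.uniform(-mask.spacing / 2, mask.spacing / 2, (n, 2))
    return pts[idx] + jitter


def null_capture(n: int = 10_000, duration: float = 120.0, dt: float = 0.05,
                 seed: int = 0) -> tuple:
    """Zero-field, zero-flow deposition in the symmetric straight channel.

    Returns (CaptureStats, TrajectoryResult); by symmetry the target and
    mirrored ROI capture fractions agree within binomial error.
    """
    mask = straight_channel_mask()
    pop = sample_population(n=n, seed=seed)
    start = _release_uniform(mask, n, seed + 1)
    traj = simulate(pop, None, mask, None, duration=duration, dt=dt,
                    seed=seed + 2, start=start)
    return capture_stats(traj, mask), traj


def channel_capture(cfg: RunConfig | None = None, Br: float | None = None,
                    seed: int = 0, flow=None, mask=None,
                    force=None, gap_mm: float | None = None) -> CaptureStats:
    """Bifurcation capture run; returns target/off-target statistics.

    ``flow``/``mask``/``force`` may be passed to reuse a solved setup
    across remanence levels and seeds.
    """
    cfg = cfg or RunConfig()
    if mask is None or flow is None:
        mask, flow = bifurcation_setup(cfg)
    pop = _scenario_population(cfg, seed)
    if force is None:
        force = inplane_capture_force(cfg, mask, Br=Br, gap_mm=gap_mm,
                                      magnetics=pop.magnetics)
    start = _release_uniform(mask, pop.n, seed + 1)
    traj = simulate(pop, flow, mask, force,
                    duration=cfg.particles.duration_s, dt=cfg.particles.dt_s,
                    seed=seed + 2, start=start,
                    viscosity=cfg.flow.viscosity_pa_s)
    return capture_stats(traj, mask)


def capture_sweep(br_levels=(0.0, 0.65, 1.3), seeds=(0, 1, 2),
                  cfg: RunConfig | None = None) -> dict:
    """Mean target-capture fraction per remanence level (fixed flow/mask)."""
    cfg = cfg or RunConfig()
    mask, flow = bifurcation_setup(cfg)
    out = {}
    for br in br_levels:
        force = inplane_capture_force(cfg, mask, Br=br)
        fr = [channel_capture(cfg, Br=br, seed=s, flow=flow, mask=mask,
                              force=force).f_target for s in seeds]
        out[br] = float(np.mean(fr))
    return out


def gap_sweep(gaps_mm=(0.4, 2.0, 5.0), seeds=(0, 1), Br: float = 1.3,
              cfg: RunConfig | None = None) -> dict:
    """Mean target-capture fraction per magnet gap (mm above the lumen)."""
    cfg = cfg or RunConfig()
    mask, flow = bifurcation_setup(cfg)
    out = {}
    for g in gaps_mm:
        force = inplane_capture_force(cfg, mask, Br=Br, gap_mm=g)
        fr = [channel_capture(cfg, seed=s, flow=flow, mask=mask,
                              force=force).f_target for s in seeds]
        out[g] = float(np.mean(fr))
    return out


def capture_body_force(cfg: RunConfig, mask: DomainMask,
                       number_density: float = 1.0e15) -> tuple:
    """Uniform-concentration overhead-magnet body force (fx, fy), N/m^3.

    Note: with a spatially uniform particle concentration this force is
    (the in-plane restriction of) a potential gradient, which an
    incompressible flow absorbs entirely into pressure — it changes p but
    not velocity or WSS.  Use :func:`particle_body_force` for the
    concentration-weighted force that does perturb the flow.
    """
    spec = cfg.geometry.spec()
    magnetics = _scenario_population(cfg, 0, n=1).magnetics
    return overhead_body_force(
        mask, cfg.magnet.magnet(), magnetics, number_density,
        apex_xy=spec.apex,
        z_plane=overhead_plane_height(spec, cfg.magnet.gap_mm * 1e-3))


def particle_body_force(cfg: RunConfig, mask: DomainMask, flow,
                        bulk_density: float = 1.0e15, seed: int = 0,
                        n_tracers: int = 2000, duration: float = 60.0,
                        sample_every: int = 10) -> tuple:
    """Concentration-weighted magnetophoretic body force (fx, fy), N/m^3.

    The drag reaction of the particle phase on the fluid is n(x) F(x): the
    magnet enriches the suspended-particle concentration near the apex, so
    the force density is non-uniform (and non-conservative), which is what
    actually perturbs an incompressible flow.  n(x) is estimated from a
    tracer transport run (time-averaged occupancy of suspended particles),
    scaled so the domain-average concentration equals ``bulk_density``
    (1/m^3).
    """
    pop = _scenario_population(cfg, seed, n=n_tracers)
    force = apex_force(cfg, magnetics=pop.magnetics)
    start = _release_uniform(mask, pop.n, seed + 1)
    dt = cfg.particles.dt_s
    counts = np.zeros(mask.shape)
    # accumulate occupancy by stepping in chunks and histogramming positions
    from .transport import TrajectoryResult  # noqa: F401  (doc pointer)

    traj_pos = start.copy()
    n_steps = int(np.ceil(duration / dt))
    h = mask.spacing
    ox, oy = mask.origin
    n_samples = 0
    chunk = sample_every
    t_done = 0.0
    while t_done < duration - 1e-12:
        t_chunk = min(chunk * dt, duration - t_done)
        res = simulate(pop, flow, mask, force, duration=t_chunk, dt=dt,
                       seed=seed + 2 + int(t_done / dt), start=traj_pos,
                       viscosity=cfg.flow.viscosity_pa_s)
        live = res.suspended
        if not np.any(live):
            break
        p = res.positions[live]
        i = np.clip(np.round((p[:, 0] - ox) / h).astype(int), 0, mask.shape[0] - 1)
        j = np.clip(np.round((p[:, 1] - oy) / h).astype(int), 0, mask.shape[1] - 1)
        np.add.at(counts, (i, j), 1.0)
        n_samples += 1
        # continue only the still-suspended tracers
        pop = ParticleSubset(pop, live)
        traj_pos = p
        t_done += t_chunk
    fluid = mask.fluid_mask()
    counts[~fluid] = 0.0
    if counts.sum() == 0:
        return np.zeros(mask.shape), np.zeros(mask.shape)
    mean_occ = counts[fluid].mean()
    conc = np.where(fluid, counts / mean_occ * bulk_density, 0.0)
    x, y = mask.cell_centers()
    X, Y = np.meshgrid(x, y, indexing="ij")
    F = force(np.column_stack([X.ravel(), Y.ravel()]))
    fx = (F[:, 0].reshape(mask.shape)) * conc
    fy = (F[:, 1].reshape(mask.shape)) * conc
    return fx, fy


class ParticleSubset:
    """View of a population restricted to a boolean index (same magnetics)."""

    def __init__(self, pop, keep):
        self.diameters = pop.diameters[keep]
        self.magnetics = pop.magnetics
        self.temperature = pop.temperature
        self.seed = pop.seed

    @property
    def n(self):
        return len(self.diameters)


def dish_targeting(cfg: RunConfig | None = None, field_on: bool = True,
                   seed: int = 0, n: int | None = None,
                   duration: float = 180.0, dt: float = 0.05):
    """Well-plate targeting run (flow-free)."""
    cfg = cfg or RunConfig()
    pop = _scenario_population(cfg, seed, n=n)
    magnet = cfg.magnet.magnet() if field_on else None
    return well_mode(pop, magnet, duration=duration, dt=dt, seed=seed + 1,
                     viscosity=cfg.flow.viscosity_pa_s)
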