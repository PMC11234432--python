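"""Seeded synthetic-data generators with recorded ground truth.

Every generator returns ``(artifact, GeneratorRecord)``: the record stores
the generator name, parameters, seed and ground-truth values, and re-running
``regenerate(record)`` reproduces the artifact exactly.  Recovery tests
consume truth from records, never from hard-coded values.

Default parameters emulate the study conditions: Hertzian indentation of
56-88 kPa gels under a 500 µm (diameter) spherical tip; the 0.48 s
perfusion waveform with 2 mL/min mean and reversal at 0.24 s; lognormal
SPION size populations (25.1 +/- 4.4 nm plain, 78.9 +/- 21.2 nm
drug-loaded); Live/Dead images around the measured ~97% viability; pore
masks near 37.86% porosity with ~125 µm^2 mean pore area; and DNA-content
histograms with prescribed phase fractions.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from numpy.typing import NDArray

from .cellcycle import DNAHistogram
from .hemodynamics import Waveform, make_waveform
from .indentation import NU_SAMPLE, E_INDENTER, IndentationCurve, NU_INDENTER
from .quant import FluorImage
from .transport import ParticlePopulation, sample_population


class GenerationError(RuntimeError):
    pass


@dataclass
class GeneratorRecord:
    generator: str
    parameters: dict
    seed: int | None
    ground_truth: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "GeneratorRecord":
        return cls(**json.loads(s))


_REGISTRY: dict = {}


def regenerate(record: GeneratorRecord):
    """Re-run a generator from its record; identical numeric outputs."""
    fn = _REGISTRY[record.generator]
    params = dict(record.parameters)
    if record.seed is not None:
        params["seed"] = record.seed
    return fn(**params)


def _register(fn):
    _REGISTRY[fn.__name__] = fn
    return fn


# ---------------------------------------------------------------------------


@_register
def gen_indentation_curve(E_true: float = 87.6e3, R: float = 250e-6,
                          hmax: float = 100e-6, noise_frac: float = 0.0,
                          n_per_phase: int = 300, seed: int = 0):
    """Hertzian sphere-on-flat force-displacement curve.

    Forward model P = (4/3) Er sqrt(R) h^1.5 with Er combining the sample
    (E_true, nu = 0.5) and tip (2 GPa) compliances; loading ramp followed
    by a mirrored elastic unloading.  ``noise_frac`` applies multiplicative
    Gaussian force noise.
    """
    if E_true <= 0 or R <= 0 or hmax <= 0:
        raise GenerationError("E_true, R, hmax must be > 0")
    if not (0 <= noise_frac < 0.2):
        raise GenerationError("noise_frac must lie in [0, 0.2)")
    if n_per_phase < 200:
        raise GenerationError("need >= 200 samples per phase")
    rng = np.random.default_rng(seed)
    inv_er = (1.0 - NU_SAMPLE**2) / E_true + (1.0 - NU_INDENTER**2) / E_INDENTER
    Er = 1.0 / inv_er
    h_load = np.linspace(0.0, hmax, n_per_phase)
    h_unload = np.linspace(hmax, 0.0, n_per_phase, endpoint=False)
    h = np.concatenate([h_load, h_unload])
    P = (4.0 / 3.0) * Er * np.sqrt(R) * h**1.5
    if noise_frac > 0:
        P = P * (1.0 + noise_frac * rng.standard_normal(len(P)))
    phase = np.array(["load"] * n_per_phase + ["unload"] * n_per_phase,
                     dtype=object)
    curve = IndentationCurve(h, P, phase, indenter_radius=R, indent_depth=hmax)
    rec = GeneratorRecord(
        "gen_indentation_curve",
        dict(E_true=E_true, R=R, hmax=hmax, noise_frac=noise_frac,
             n_per_phase=n_per_phase),
        seed, ground_truth=dict(E_true=E_true, Er_true=Er,
                                Pmax=float(P[n_per_phase - 1])))
    return curve, rec


@_register
def gen_livedead_image(n_cells: int = 1000, viability_pct: float = 96.0,
                       size: int = 1024, pixel_size: float = 1.0,
                       cell_radius_px: int = 6, min_separation_px: int = 16,
                       seed: int = 0, max_attempts: int = 200_000):
    """Two-channel Live/Dead image: disks assigned green/red by Bernoulli draw.

    Cells are placed by dart throwing with a minimum center separation so
    counts are exactly recoverable by segmentation; ground truth records
    the realized live/dead counts.
    """
    if not (0 <= viability_pct <= 100):
        raise GenerationError("viability_pct must be in [0, 100]")
    rng = np.random.default_rng(seed)
    centers = []
    attempts = 0
    margin = cell_radius_px + 2
    while len(centers) < n_cells:
        attempts += 1
        if attempts > max_attempts:
            raise GenerationError(
                f"placed only {len(centers)}/{n_cells} cells after "
                f"{max_attempts} attempts; density too high")
        c = rng.uniform(margin, size - margin, 2)
        if not centers or not _any_close(centers, c, min_separation_px):
            centers.append(c)
    centers = np.array(centers)
    alive = rng.random(n_cells) < viability_pct / 100.0
    green = np.zeros((size, size))
    red = np.zeros((size, size))
    from skimage.draw import disk

    for (r, c), a in zip(centers, alive):
        rr, cc = disk((r, c), cell_radius_px, shape=(size, size))
        (green if a else red)[rr, cc] = 255.0
    img = FluorImage({"live": green, "dead": red}, pixel_size=pixel_size)
    area_mm2 = (size * pixel_size) ** 2 / 1e6
    rec = GeneratorRecord(
        "gen_livedead_image",
        dict(n_cells=n_cells, viability_pct=viability_pct, size=size,
             pixel_size=pixel_size, cell_radius_px=cell_radius_px,
             min_separation_px=min_separation_px),
        seed, ground_truth=dict(n_live=int(alive.sum()),
                                n_dead=int(n_cells - alive.sum()),
                                viability=100.0 * float(alive.mean()),
                                density_per_mm2=n_cells / area_mm2))
    return img, rec


def _any_close(centers, c, dmin):
    arr = np.asarray(centers)
    d2 = (arr[:, 0] - c[0]) ** 2 + (arr[:, 1] - c[1]) ** 2
    return bool(np.any(d2 < dmin**2))


@_register
def gen_pore_mask(porosity_pct: float = 37.86, mean_area_um2: float = 124.9,
                  sd_area_um2: float = 80.0, size: int = 512,
                  pixel_size: float = 1.0, seed: int = 0,
                  max_attempts: int = 400_000):
    """Binary pore mask: non-overlapping discs with lognormal areas.

    Discs are added until the porosity reaches the target within 0.5
    percentage points (the last disc is radius-trimmed on overshoot); the
    achieved porosity and per-pore areas are recorded as ground truth.
    """
    if not (0 <= porosity_pct < 60):
        raise GenerationError("porosity_pct must be in [0, 60)")
    rng = np.random.default_rng(seed)
    from skimage.draw import disk

    if porosity_pct == 0:
        rec = GeneratorRecord(
            "gen_pore_mask",
            dict(porosity_pct=0.0, mean_area_um2=mean_area_um2,
                 sd_area_um2=sd_area_um2, size=size, pixel_size=pixel_size),
            seed, ground_truth=dict(porosity=0.0, n_pores=0, mean_area=0.0,
                                    areas_um2=[]))
        return np.zeros((size, size), dtype=bool), rec

    sigma2 = np.log1p((sd_area_um2 / mean_area_um2) ** 2)
    mu_ln = np.log(mean_area_um2) - sigma2 / 2.0
    mask = np.zeros((size, size), dtype=bool)
    blocked = np.zeros((size, size), dtype=bool)  # pores + 1 px separation
    total_px = size * size
    target = porosity_pct / 100.0
    # draw sizes until their areas sum to the target, then place that exact
    # set largest-first: placing in draw order rejects large discs
    # preferentially and biases the realized mean area low
    target_area = target * total_px * pixel_size**2
    drawn: list = []
    while sum(drawn) < target_area:
        drawn.extend(rng.lognormal(mu_ln, np.sqrt(sigma2), 64).tolist())
    cum = np.cumsum(drawn)
    n_keep = int(np.searchsorted(cum, target_area)) + 1
    queue = np.sort(np.asarray(drawn[:n_keep]))[::-1]
    areas = []
    attempts = 0
    qi = 0
    while mask.sum() / total_px < target - 0.001:
        if qi >= len(queue) or attempts > max_attempts:
            raise GenerationError(
                f"porosity stalled at {100 * mask.sum() / total_px:.2f}% "
                f"after {attempts} attempts")
        area = float(queue[qi])
        qi += 1
        r_px = max(np.sqrt(area / np.pi) / pixel_size, 1.0)
        # trim the final disc so porosity lands inside the band
        deficit_px = (target - mask.sum() / total_px) * total_px
        if np.pi * r_px**2 > deficit_px + 0.001 * total_px:
            r_px = max(np.sqrt((deficit_px + 0.0005 * total_px) / np.pi), 1.0)
        for _try in range(400):
            attempts += 1
            c = rng.uniform(r_px + 1, size - r_px - 1, 2)
            rr, cc = disk((c[0], c[1]), r_px, shape=(size, size))
            if np.any(blocked[rr, cc]):
                continue
            mask[rr, cc] = True
            rrb, ccb = disk((c[0], c[1]), r_px + 1.5, shape=(size, size))
            blocked[rrb, ccb] = True
            areas.append(len(rr) * pixel_size**2)
            break
    achieved = 100.0 * mask.sum() / total_px
    rec = GeneratorRecord(
        "gen_pore_mask",
        dict(porosity_pct=porosity_pct, mean_area_um2=mean_area_um2,
             sd_area_um2=sd_area_um2, size=size, pixel_size=pixel_size),
        seed, ground_truth=dict(porosity=achieved, n_pores=len(areas),
                                mean_area=float(np.mean(areas)) if areas else 0.0,
                                areas_um2=[float(a) for a in areas]))
    return mask, rec


@_register
def gen_dna_histogram(f_g1: float = 60.0, f_s: float = 25.0,
                      f_g2m: float = 15.0, mu_g1: float = 100.0,
                      cv: float = 0.05, n: int = 10_000, n_bins: int = 256,
                      seed: int = 0, ratio_g2: float = 2.0):
    """DNA-content histogram: G1/G2 Gaussians, uniform S plateau, CV spread.

    Each event draws a phase by the requested fractions; S-phase events get
    a true content uniform on (mu, ratio*mu); all events then acquire the
    multiplicative Gaussian measurement spread ``cv``.
    """
    fr = np.array([f_g1, f_s, f_g2m], dtype=float)
    if np.any(fr < 0) or abs(fr.sum() - 100.0) > 1e-9:
        raise GenerationError("fractions must be >= 0 and sum to 100")
    rng = np.random.default_rng(seed)
    phase = rng.choice(3, size=n, p=fr / 100.0)
    content = np.empty(n)
    content[phase == 0] = mu_g1
    content[phase == 2] = ratio_g2 * mu_g1
    ns = int(np.count_nonzero(phase == 1))
    content[phase == 1] = rng.uniform(mu_g1, ratio_g2 * mu_g1, ns)
    measured = content * (1.0 + cv * rng.standard_normal(n))
    lo, hi = 0.0, ratio_g2 * mu_g1 * 1.5
    counts, edges = np.histogram(measured, bins=n_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    hist = DNAHistogram(centers, counts)
    rec = GeneratorRecord(
        "gen_dna_histogram",
        dict(f_g1=f_g1, f_s=f_s, f_g2m=f_g2m, mu_g1=mu_g1, cv=cv, n=n,
             n_bins=n_bins, ratio_g2=ratio_g2),
        seed, ground_truth=dict(
            f_g1=100.0 * float(np.mean(phase == 0)),
            f_s=100.0 * float(np.mean(phase == 1)),
            f_g2m=100.0 * float(np.mean(phase == 2))))
    return hist, rec


@_register
def gen_waveform(mean: float = 2.0, period: float = 0.48,
                 q_forward: float = 6.5, q_reverse: float = -2.0,
                 t_peak_forward: float = 0.07, t_peak_reverse: float = 0.24):
    """Record-keeping wrapper over :func:`hemodynamics.make_waveform`."""
    wf = make_waveform(mean=mean, period=period, q_forward=q_forward,
                       q_reverse=q_reverse, t_peak_forward=t_peak_forward,
                       t_peak_reverse=t_peak_reverse)
    rec = GeneratorRecord(
        "gen_waveform",
        dict(mean=mean, period=period, q_forward=q_forward,
             q_reverse=q_reverse, t_peak_forward=t_peak_forward,
             t_peak_reverse=t_peak_reverse),
        None, ground_truth=dict(mean=mean, t_min=t_peak_reverse))
    return wf, rec


@_register
def gen_population(n: int = 10_000, mean_d: float = 78.9e-9,
                   sd_d: float = 21.2e-9, seed: int = 0,
                   cores_per_particle: float = 1.0):
    """Record-keeping wrapper over :func:`transport.sample_population`."""
    pop = sample_population(n=n, mean_d=mean_d, sd_d=sd_d, seed=seed,
                            cores_per_particle=cores_per_particle)
    rec = GeneratorRecord(
        "gen_population",
        dict(n=n, mean_d=mean_d, sd_d=sd_d,
             cores_per_particle=cores_per_particle),
        seed, ground_truth=dict(mean_d=mean_d, sd_d=sd_d))
    return pop, rec
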