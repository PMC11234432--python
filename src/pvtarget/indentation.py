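"""Spherical micro-indentation analysis of soft hydrogel constructs.

Implements the linear-contact-mechanics chain used to extract the Young's
modulus of bioprinted GelMA constructs from force-displacement records of
a 500 µm (diameter) spherical tip driven 100 µm into the sample:

1. unloading stiffness S: ordinary-least-squares slope of the initial
   5-20% of the unloading segment,
2. contact depth hc = hmax - eps * Pmax / S with eps = 0.75 (sphere),
3. projected contact area A(hc) = 2*pi*R*hc - pi*hc^2,
4. reduced modulus Er = (sqrt(pi) / (2*beta)) * S / sqrt(A), beta = 1,
5. sample modulus from 1/Er = (1 - nu^2)/E + (1 - nu_i^2)/E_i with
   E_i = 2 GPa, nu = nu_i = 0.5.

The tip is named by diameter in the instrument convention; the contact
formulas need the radius, so the default ``indenter_radius`` is 250 µm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.typing import NDArray

EPS_SPHERE = 0.75
BETA = 1.0
E_INDENTER = 2.0e9     # Pa, tip material modulus
NU_SAMPLE = 0.5        # hydrogel Poisson ratio (incompressible limit, used verbatim)
NU_INDENTER = 0.5


class IndentationError(ValueError):
    """Raised for physically or structurally invalid indentation inputs."""


@dataclass
class IndentationCurve:
    """A force-displacement record with per-sample phase labels.

    displacement (m) and force (N) are equal-length sequences; ``phase``
    labels each sample 'load', 'hold' or 'unload'.  Within the unload
    phase displacement must be non-increasing.
    """

    displacement: NDArray
    force: NDArray
    phase: NDArray
    indenter_radius: float = 250e-6
    indent_depth: float = 100e-6
    rate: float = 2e-6

    def __post_init__(self):
        self.displacement = np.asarray(self.displacement, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        self.phase = np.asarray(self.phase, dtype=object)
        n = len(self.displacement)
        if not (len(self.force) == len(self.phase) == n):
            raise IndentationError("displacement, force, phase must be equal length")
        if n < 10:
            raise IndentationError("curve must have at least 10 samples")
        if not np.all(np.isfinite(self.force)) or not np.all(np.isfinite(self.displacement)):
            raise IndentationError("forces and displacements must be finite")
        if not np.any(self.phase == "unload"):
            raise IndentationError("curve has no 'unload' phase")
        h_un = self.displacement[self.phase == "unload"]
        if np.any(np.diff(h_un) > 1e-15):
            raise IndentationError("displacement must be non-increasing during unload")

    @classmethod
    def from_csv(cls, path, indenter_radius: float = 250e-6) -> "IndentationCurve":
        """Read ``displacement_m, force_N[, phase]`` columns.

        Without a phase column, phases are inferred from the displacement
        extremum: everything up to the maximum is 'load', the rest 'unload'.
        """
        df = pd.read_csv(path)
        need = {"displacement_m", "force_N"}
        if not need.issubset(df.columns):
            raise IndentationError(f"CSV must contain columns {sorted(need)}")
        h = df["displacement_m"].to_numpy(float)
        if "phase" in df.columns:
            phase = df["phase"].to_numpy()
        else:
            imax = int(np.argmax(h))
            phase = np.array(["load"] * (imax + 1) + ["unload"] * (len(h) - imax - 1),
                             dtype=object)
        return cls(h, df["force_N"].to_numpy(float), phase,
                   indenter_radius=indenter_radius)

    def unload(self) -> tuple:
        m = self.phase == "unload"
        return self.displacement[m], self.force[m]


@dataclass(frozen=True)
class StiffnessFit:
    """OLS unloading-stiffness fit over an index-fraction window."""

    S: float
    window: tuple = (0.05, 0.20)
    fit_r2: float = float("nan")
    n_points: int = 0
    flagged: bool = False  # non-positive slope


@dataclass(frozen=True)
class ModulusResult:
    Pmax: float
    hmax: float
    S: float
    hc: float
    A: float
    Er: float
    E: float
    constants: dict = field(default_factory=lambda: dict(
        eps=EPS_SPHERE, beta=BETA, Ei=E_INDENTER, nu=NU_SAMPLE, nui=NU_INDENTER))

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in ("Pmax", "hmax", "S", "hc", "A", "Er", "E")}
        d.update(self.constants)
        return d


def fit_stiffness(curve: IndentationCurve, window: tuple = (0.05, 0.20)) -> StiffnessFit:
    """Slope of the force-displacement line over the initial part of unloading.

    The window is an index-fraction interval of the unloading segment
    (default the first 5-20% of samples after the force peak).
    """
    lo, hi = window
    if not (0 <= lo < hi <= 1):
        raise IndentationError(f"invalid window {window}; need 0 <= lo < hi <= 1")
    h, F = curve.unload()
    n = len(h)
    i0, i1 = int(np.floor(lo * n)), int(np.ceil(hi * n))
    if i1 - i0 < 3:
        raise IndentationError(
            f"unloading window [{lo}, {hi}] contains {i1 - i0} samples; need >= 3")
    hs, Fs = h[i0:i1], F[i0:i1]
    A = np.column_stack([hs, np.ones_like(hs)])
    coef, *_ = np.linalg.lstsq(A, Fs, rcond=None)
    S = float(coef[0])
    resid = Fs - A @ coef
    ss_tot = float(np.sum((Fs - Fs.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return StiffnessFit(S=S, window=(lo, hi), fit_r2=r2, n_points=i1 - i0,
                        flagged=S <= 0)


def contact_depth(hmax: float, Pmax: float, S: float, eps: float = EPS_SPHERE) -> float:
    """hc = hmax - eps * Pmax / S; errors if the result is non-physical."""
    if S <= 0:
        raise IndentationError("stiffness S must be > 0")
    if Pmax < 0 or hmax <= 0:
        raise IndentationError("need Pmax >= 0 and hmax > 0")
    hc = hmax - eps * Pmax / S
    if hc <= 0:
        raise IndentationError(
            f"contact depth {hc:.3g} m <= 0: stiffness too low for the given load")
    return hc


def projected_area(R: float, hc: float) -> float:
    """Spherical-cap projected contact area A = 2*pi*R*hc - pi*hc^2."""
    if hc <= 0:
        raise IndentationError("hc must be > 0")
    if hc > R:
        raise IndentationError(
            f"hc = {hc:.3g} m exceeds tip radius {R:.3g} m; the cap formula "
            "is invalid beyond the hemisphere")
    return 2.0 * np.pi * R * hc - np.pi * hc**2


def reduced_modulus(S: float, A: float, beta: float = BETA) -> float:
    """Er = (sqrt(pi) / (2*beta)) * S / sqrt(A)."""
    if S <= 0 or A <= 0:
        raise IndentationError("S and A must be > 0")
    return np.sqrt(np.pi) / (2.0 * beta) * S / np.sqrt(A)


def sample_modulus(Er: float, Ei: float = E_INDENTER, nu: float = NU_SAMPLE,
                   nui: float = NU_INDENTER) -> float:
    """Invert 1/Er = (1-nu^2)/E + (1-nui^2)/Ei for the sample modulus E."""
    if Er <= 0:
        raise IndentationError("Er must be > 0")
    budget = 1.0 / Er - (1.0 - nui**2) / Ei
    if budget <= 0:
        raise IndentationError(
            "sample compliance budget exhausted: 1/Er <= (1-nui^2)/Ei")
    return (1.0 - nu**2) / budget


def analyze(curve: IndentationCurve, window: tuple = (0.05, 0.20),
            eps: float = EPS_SPHERE, beta: float = BETA,
            Ei: float = E_INDENTER, nu: float = NU_SAMPLE,
            nui: float = NU_INDENTER) -> ModulusResult:
    """Full stiffness -> hc -> A -> Er -> E chain for one curve."""
    h_un, F_un = curve.unload()
    hmax = float(h_un[0])
    Pmax = float(F_un[0])
    try:
        fit = fit_stiffness(curve, window)
        if fit.flagged:
            raise IndentationError(f"non-positive unloading stiffness {fit.S:.3g}")
        hc = contact_depth(hmax, Pmax, fit.S, eps)
        A = projected_area(curve.indenter_radius, hc)
        Er = reduced_modulus(fit.S, A, beta)
        E = sample_modulus(Er, Ei, nu, nui)
    except IndentationError as err:
        raise IndentationError(f"indentation analysis failed: {err}") from err
    return ModulusResult(Pmax=Pmax, hmax=hmax, S=fit.S, hc=hc, A=A, Er=Er, E=E,
                         constants=dict(eps=eps, beta=beta, Ei=Ei, nu=nu, nui=nui))
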