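"""Dean-Jett-Fox deconvolution of propidium-iodide DNA-content histograms.

A PI histogram of a cycling population is modelled as

* a Gaussian G0/G1 peak at mean ``mu_g1`` with coefficient of variation
  ``cv_g1`` (instrument spread),
* a Gaussian G2/M peak at ``ratio_g2 * mu_g1`` (DNA doubling; the ratio is
  fitted inside [1.8, 2.1] to absorb cytometer linearity drift),
* an S-phase continuum: cells with true DNA content u between the two
  peaks, weighted by a quadratic polynomial in u, each broadened by the
  local Gaussian spread (the classic "broadened quadratic"),

fitted to binned counts by nonlinear least squares.  Phase fractions are
the areas of the three components and sum to 100%.

Debris/doublet modelling is omitted (the synthetic generator produces
clean histograms); real cytometry exports would need those terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.typing import NDArray
from scipy.optimize import least_squares


class CellCycleError(ValueError):
    pass


@dataclass
class DNAHistogram:
    """Binned DNA-content (PI intensity) histogram."""

    bin_centers: NDArray
    counts: NDArray

    def __post_init__(self):
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.bin_centers) != len(self.counts):
            raise CellCycleError("bin_centers and counts must be equal length")
        if np.any(np.diff(self.bin_centers) <= 0):
            raise CellCycleError("bins must be strictly increasing")
        if np.any(self.counts < 0):
            raise CellCycleError("counts must be non-negative")

    @property
    def n_events(self) -> int:
        return int(round(float(self.counts.sum())))

    @classmethod
    def from_csv(cls, path) -> "DNAHistogram":
        df = pd.read_csv(path)
        need = {"bin_center", "count"}
        if not need.issubset(df.columns):
            raise CellCycleError(f"CSV must contain columns {sorted(need)}")
        return cls(df["bin_center"].to_numpy(float), df["count"].to_numpy(float))


@dataclass
class DJFModel:
    """Fitted model parameters and phase fractions (percent)."""

    mu_g1: float
    cv_g1: float
    cv_g2: float
    ratio_g2: float
    s_poly: tuple              # quadratic weight coefficients (c1, c2); c0 = 1
    f_g1: float
    f_s: float
    f_g2m: float
    residual_rms: float = float("nan")
    converged: bool = True

    def fractions(self) -> tuple:
        return (self.f_g1, self.f_s, self.f_g2m)


def _gauss(x, mu, sd):
    return np.exp(-0.5 * ((x - mu) / sd) ** 2) / (sd * np.sqrt(2.0 * np.pi))


def _model_counts(x, bin_width, theta, n_s_nodes=60):
    """Per-bin expected counts for parameter vector theta.

    theta = (mu, cv1, cv2, ratio, A1, A2, As, c1, c2); the S weight is
    q(t) = 1 + c1 t + c2 t^2 on t in [0, 1] (clipped at 0), normalized so
    As is the S-phase area.
    """
    mu, cv1, cv2, ratio, A1, A2, As, c1, c2 = theta
    g1 = A1 * _gauss(x, mu, cv1 * mu)
    g2 = A2 * _gauss(x, ratio * mu, cv2 * ratio * mu)
    t_nodes = (np.arange(n_s_nodes) + 0.5) / n_s_nodes
    u = mu + t_nodes * (ratio - 1.0) * mu
    q = np.clip(1.0 + c1 * t_nodes + c2 * t_nodes**2, 0.0, None)
    qsum = q.sum()
    if qsum <= 0:
        s = np.zeros_like(x)
    else:
        sd_u = (cv1 + (cv2 - cv1) * t_nodes) * u
        s = As * (q[None, :] * _gauss(x[:, None], u[None, :], sd_u[None, :])
                  ).sum(axis=1) / qsum
    return (g1 + g2 + s) * bin_width, (A1, A2, As)


def fit_djf(hist: DNAHistogram, fix_ratio: float | None = None,
            n_s_nodes: int = 60, s_shape_ridge: float = 25.0) -> DJFModel:
    """Fit the three-component model to a histogram by least squares.

    Initialization: ``mu_g1`` from the dominant peak in the lower half of
    the intensity range; starting fractions from naive gating around the
    two peak windows.  ``fix_ratio`` pins the G2/G1 ratio (e.g. 2.0).
    """
    x = hist.bin_centers
    y = hist.counts
    n = float(y.sum())
    if n < 1000:
        raise CellCycleError(f"need >= 1000 events, got {n:.0f}")
    if np.count_nonzero(y) < 3:
        raise CellCycleError("degenerate histogram: fewer than 3 occupied bins")
    bw = float(np.median(np.diff(x)))

    # --- initialization ---------------------------------------------------
    smooth = np.convolve(y, np.ones(5) / 5.0, mode="same")
    lower = x <= x.min() + 0.6 * (x.max() - x.min())
    if not np.any(smooth[lower] > 0):
        raise CellCycleError("no detectable G1 peak")
    mu0 = float(x[lower][np.argmax(smooth[lower])])
    r0 = fix_ratio if fix_ratio is not None else 2.0
    g1_win = np.abs(x - mu0) < 0.15 * mu0
    g2_win = np.abs(x - r0 * mu0) < 0.15 * r0 * mu0
    a1_0 = max(float(y[g1_win].sum()), 1.0)
    a2_0 = max(float(y[g2_win].sum()), 1.0)
    as_0 = max(n - a1_0 - a2_0, 1.0)

    lo_r, hi_r = (1.8, 2.1)
    if fix_ratio is not None:
        if not (lo_r <= fix_ratio <= hi_r):
            raise CellCycleError(f"fix_ratio must lie in [{lo_r}, {hi_r}]")
        lo_r, hi_r = fix_ratio - 1e-9, fix_ratio + 1e-9
    theta0 = np.array([mu0, 0.05, 0.05, r0, a1_0, a2_0, as_0, 0.0, 0.0])
    lo = np.array([0.5 * mu0, 0.005, 0.005, lo_r, 0.0, 0.0, 0.0, -3.0, -3.0])
    hi = np.array([1.5 * mu0, 0.30, 0.30, hi_r, 2 * n, 2 * n, 2 * n, 3.0, 3.0])
    theta0 = np.clip(theta0, lo, hi)

    # mild ridge on the S-shape coefficients: the broadened-quadratic
    # deconvolution is ill-posed near the peaks (a tilted S weight can trade
    # area with the Gaussian tails almost silently), so the S shape is
    # shrunk toward flat unless the data demand otherwise
    ridge = np.sqrt(s_shape_ridge)

    def resid(theta):
        model, _ = _model_counts(x, bw, theta, n_s_nodes)
        r = (model - y) / np.sqrt(np.maximum(y, 1.0))
        return np.concatenate([r, ridge * theta[7:]])

    sol = least_squares(resid, theta0, bounds=(lo, hi), max_nfev=4000)
    if not sol.success:
        raise CellCycleError(f"DJF fit did not converge: {sol.message}")
    mu, cv1, cv2, ratio, A1, A2, As = sol.x[:7]
    c1, c2 = sol.x[7:]
    total = A1 + A2 + As
    if total <= 0:
        raise CellCycleError("degenerate fit: zero total area")
    f = 100.0 * np.array([A1, As, A2]) / total
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    return DJFModel(mu_g1=float(mu), cv_g1=float(cv1), cv_g2=float(cv2),
                    ratio_g2=float(ratio), s_poly=(float(c1), float(c2)),
                    f_g1=float(f[0]), f_s=float(f[1]), f_g2m=float(f[2]),
                    residual_rms=rms, converged=bool(sol.success))


def fractions(model: DJFModel) -> tuple:
    """(G0/G1, S, G2/M) percentages; sums to 100 by construction."""
    return model.fractions()
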