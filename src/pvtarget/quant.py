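"""Image and plate-reader quantification: viability, coverage, pores, AlamarBlue.

Mirrors the readouts used to characterize the endothelialized constructs:
Live/Dead viability from green/red cell counts, nuclei density per mm^2,
fluorescent-signal coverage of a lumen ROI, resazurin (AlamarBlue)
reduction from two-wavelength absorbances, and SEM pore metrics
(porosity %, pore areas, circular-equivalent diameters).

Segmentation is deliberately simple and fully reproducible: global
threshold (Otsu by default) -> connected components -> area filter, with
optional watershed splitting of touching objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.segmentation import watershed


class QuantError(ValueError):
    pass


@dataclass
class FluorImage:
    """Named single-plane fluorescence channels sharing one pixel grid."""

    channels: dict              # name -> 2D float array, intensities >= 0
    pixel_size: float = 1.0     # µm per pixel

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise QuantError("pixel_size must be > 0")
        shapes = {np.asarray(ch).shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise QuantError("all channels must share one shape")
        for name, ch in self.channels.items():
            if np.any(np.asarray(ch) < 0):
                raise QuantError(f"channel {name!r} has negative intensities")

    @classmethod
    def from_tiff(cls, path, channel_names: tuple, pixel_size: float = 1.0):
        import tifffile

        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[None]
        if len(channel_names) != arr.shape[0]:
            raise QuantError(
                f"{len(channel_names)} names for {arr.shape[0]} planes")
        return cls({n: arr[i].astype(float) for i, n in enumerate(channel_names)},
                   pixel_size=pixel_size)


@dataclass
class SegmentationResult:
    label_map: NDArray
    count: int
    centroids: NDArray          # (n, 2) row/col
    areas: NDArray              # µm^2


def segment_blobs(channel: NDArray, threshold: str | float = "otsu",
                  min_area_px: int = 5, pixel_size: float = 1.0,
                  split_touching: bool = False,
                  min_distance_px: int = 5) -> SegmentationResult:
    """Threshold -> connected components -> area filter (optional watershed).

    ``threshold``: 'otsu' or an absolute intensity.  A blank (constant)
    image yields zero objects.  With ``split_touching`` a distance-transform
    watershed separates merged blobs.
    """
    img = np.asarray(channel, dtype=float)
    if img.size == 0:
        raise QuantError("empty channel")
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise QuantError(f"unknown threshold method {threshold!r}")
        if np.ptp(img) == 0:
            mask = np.zeros_like(img, dtype=bool)
        else:
            mask = img > threshold_otsu(img)
    else:
        mask = img > float(threshold)
    if split_touching and mask.any():
        dist = ndimage.distance_transform_edt(mask)
        from skimage.feature import peak_local_max

        coords = peak_local_max(dist, min_distance=min_distance_px, labels=mask)
        seeds = np.zeros(mask.shape, dtype=int)
        seeds[tuple(coords.T)] = np.arange(1, len(coords) + 1)
        lab = watershed(-dist, seeds, mask=mask)
    else:
        lab = label(mask)
    props = regionprops(lab)
    keep = [p for p in props if p.area >= min_area_px]
    out = np.zeros_like(lab)
    cents, areas = [], []
    for new_id, p in enumerate(keep, start=1):
        out[lab == p.label] = new_id
        cents.append(p.centroid)
        areas.append(p.area * pixel_size**2)
    return SegmentationResult(label_map=out, count=len(keep),
                              centroids=np.array(cents).reshape(-1, 2),
                              areas=np.array(areas))


def viability_percent(n_live: int, n_dead: int) -> float:
    """Live/Dead viability: 100 * live / (live + dead)."""
    if n_live < 0 or n_dead < 0:
        raise QuantError("counts must be non-negative")
    if n_live + n_dead == 0:
        raise QuantError("no cells: viability undefined")
    return 100.0 * n_live / (n_live + n_dead)


def density_per_mm2(count: int, roi_area_um2: float) -> float:
    """Object density normalized by ROI surface area (objects per mm^2)."""
    if roi_area_um2 <= 0:
        raise QuantError("ROI area must be > 0")
    return count / roi_area_um2 * 1.0e6


def coverage_percent(channel: NDArray, roi: NDArray | None = None,
                     threshold: str | float = "otsu") -> float:
    """Percent of ROI pixels with above-threshold signal."""
    img = np.asarray(channel, dtype=float)
    if roi is None:
        roi = np.ones_like(img, dtype=bool)
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise QuantError("empty ROI")
    if isinstance(threshold, str):
        vals = img[roi]
        if np.ptp(vals) == 0:
            return 100.0 if vals.flat[0] > 0 else 0.0
        thr = threshold_otsu(vals)
    else:
        thr = float(threshold)
    return 100.0 * float(np.count_nonzero(img[roi] > thr)) / float(roi.sum())


# molar extinction coefficients of resazurin (oxidized) and resorufin
# (reduced), L mol^-1 cm^-1 x 10^-3, by wavelength (nm); the editable table
# follows the published reagent datasheet values.
ALAMAR_EXTINCTION = {
    540: {"ox": 47.619, "red": 104.395},
    570: {"ox": 80.586, "red": 155.677},
    600: {"ox": 117.216, "red": 14.652},
    630: {"ox": 34.798, "red": 5.494},
}


def _nearest_wavelength(wl: float) -> int:
    return min(ALAMAR_EXTINCTION, key=lambda k: abs(k - wl))


def alamar_reduction(A_sample: tuple, A_control: tuple,
                     wavelengths: tuple = (550, 600),
                     table: dict | None = None) -> float:
    """AlamarBlue reduction %, two-wavelength molar-extinction formula.

    ``A_sample``/``A_control`` are absorbances at ``wavelengths`` (low, high)
    for the sample and the unreduced media-only control.  Coefficients come
    from the nearest tabulated wavelengths (the 550/600 nm reader pair maps
    to the published 540/600 values).  0% for the unreduced control,
    100% for fully reduced dye; values outside [0, 100] are returned as-is
    for the caller to flag.
    """
    tab = table or ALAMAR_EXTINCTION
    a1, a2 = A_sample
    c1, c2 = A_control
    if min(a1, a2, c1, c2) <= 0:
        raise QuantError("absorbances must be positive")
    w1 = tab[_nearest_wavelength(wavelengths[0])]
    w2 = tab[_nearest_wavelength(wavelengths[1])]
    num = w2["ox"] * a1 - w1["ox"] * a2
    den = w1["red"] * c2 - w2["red"] * c1
    if den == 0:
        raise QuantError("degenerate control absorbances")
    return 100.0 * num / den


@dataclass
class PoreReport:
    """SEM pore metrics of the printed hydrogel surface."""

    pore_areas: NDArray            # µm^2, one entry per pore
    mean_area: float               # µm^2
    porosity_percent: float
    equivalent_diameters: NDArray  # µm, 2*sqrt(A/pi)
    histogram: tuple = field(default=(np.array([]), np.array([])))

    def fraction_below(self, area_um2: float) -> float:
        if len(self.pore_areas) == 0:
            return 0.0
        return float(np.mean(self.pore_areas < area_um2))


def equivalent_diameter(area: float | NDArray):
    """Circular-equivalent diameter 2*sqrt(A/pi) (same units as sqrt(A))."""
    a = np.asarray(area, dtype=float)
    out = 2.0 * np.sqrt(a / np.pi)
    return out if out.ndim else float(out)


def pore_metrics(binary_mask: NDArray, pixel_size: float = 1.0,
                 bins: int | NDArray = 20) -> PoreReport:
    """Porosity, per-pore areas and equivalent diameters from a binary mask.

    Porosity = pore pixels / total pixels * 100 (exact on the input mask);
    pores are 8-connected components of the True phase.
    """
    m = np.asarray(binary_mask)
    if m.dtype != bool:
        uniq = np.unique(m)
        if not np.all(np.isin(uniq, (0, 1))):
            raise QuantError("mask must be binary")
        m = m.astype(bool)
    if pixel_size <= 0:
        raise QuantError("pixel_size must be > 0")
    porosity = 100.0 * float(np.count_nonzero(m)) / m.size
    lab = label(m, connectivity=2)
    areas = np.array([p.area for p in regionprops(lab)], dtype=float) * pixel_size**2
    mean_area = float(areas.mean()) if len(areas) else 0.0
    eq_d = equivalent_diameter(areas) if len(areas) else np.array([])
    hist = np.histogram(areas, bins=bins) if len(areas) else \
        (np.array([]), np.array([]))
    return PoreReport(pore_areas=areas, mean_area=mean_area,
                      porosity_percent=porosity,
                      equivalent_diameters=np.asarray(eq_d),
                      histogram=hist)
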