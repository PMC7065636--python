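"""Watershed speckle binning and the deviation-from-mean (DFM) statistic.

A Mie-regime scatterer (an RPE melanin granule) backscatters with a strong,
oscillatory wavelength dependence; a large flat interface or bulk tissue
does not.  Per-pixel spectra cannot show this cleanly because the speckle
pattern itself changes with wavelength, so pixels are first binned into
single-speckle catchment basins by a watershed transform of the maximum
intensity projection (MIP) across all 27 bands.  For each basin the mean
linear intensity per band gives a 27-sample spectrum I(λ_j); its
across-band mean is subtracted to give the deviation spectrum I_dev, and

    DFM = ∫_{λ1}^{λ27} |I_dev(λ)| dλ        (trapezoidal rule, units intensity·nm)

is mapped back onto the basin's pixels.  Basins of wavelength-flat
scatterers land near zero; Mie scatterers stand out.  Thresholding the DFM
map against the noise level and counting the pixels above threshold in a
fixed depth window below the sample surface yields the concentration
metric.

All statistics operate on linear intensities.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.segmentation import watershed

from .recon import HyperStack

logger = logging.getLogger(__name__)

__all__ = [
    "BasinSegmentation",
    "BasinSpectrum",
    "DFMMap",
    "mip_across_bands",
    "watershed_basins",
    "basin_spectra",
    "deviation_spectrum",
    "dfm",
    "dfm_map",
    "estimate_noise_stats",
    "estimate_noise_sd",
    "detect_surface",
    "fraction_above_threshold",
    "rgb_encode",
    "average_repeats",
    "analyze_stack",
]


@dataclass(frozen=True)
class BasinSegmentation:
    """Watershed speckle segmentation of a B-scan.

    ``labels`` assigns every pixel a basin id in 1..n_basins;
    ``areas_um2`` is indexed by basin id − 1.
    """

    labels: np.ndarray
    n_basins: int
    areas_um2: np.ndarray
    pixel_area_um2: float
    mip: np.ndarray = field(repr=False, default=None)


@dataclass(frozen=True)
class BasinSpectrum:
    """Per-basin band means, deviation spectrum and DFM value."""

    basin_id: int
    mean_intensity: np.ndarray
    deviation: np.ndarray
    dfm: float


@dataclass(frozen=True)
class DFMMap:
    """DFM values mapped back to image space, with its thresholded version.

    The binary map marks pixels whose DFM exceeds
    ``noise_mean + k · noise_sd`` (noise statistics measured on the DFM map
    itself over a signal-free region).
    """

    dfm_image: np.ndarray
    binary: np.ndarray
    noise_sd: float
    noise_mean: float
    k: float
    threshold: float
    surface_px: np.ndarray


# ---------------------------------------------------------------------------
# Segmentation

def mip_across_bands(stack: HyperStack) -> np.ndarray:
    """Per-pixel maximum intensity over all bands: (depth, lateral)."""
    return stack.intensity.max(axis=0)


def _adjacency_counts(labels: np.ndarray) -> dict[tuple[int, int], int]:
    """Shared-boundary pixel counts between 4-adjacent distinct labels."""
    pairs = []
    for a, b in (
        (labels[:, :-1], labels[:, 1:]),
        (labels[:-1, :], labels[1:, :]),
    ):
        a, b = a.ravel(), b.ravel()
        m = a != b
        pairs.append(np.stack([a[m], b[m]]))
    ab = np.concatenate(pairs, axis=1)
    ab = np.concatenate([ab, ab[::-1]], axis=1)      # symmetric
    keys = ab[0].astype(np.int64) * (labels.max() + 1) + ab[1]
    uk, counts = np.unique(keys, return_counts=True)
    base = labels.max() + 1
    return {(int(k // base), int(k % base)): int(c) for k, c in zip(uk, counts)}


def _merge_small_basins(labels: np.ndarray, min_px: int) -> np.ndarray:
    """Merge every basin smaller than ``min_px`` into the neighbor sharing
    the longest boundary; iterate until no small basin remains."""
    labels = labels.copy()
    for _ in range(64):
        areas = np.bincount(labels.ravel())
        small = np.flatnonzero((areas > 0) & (areas < min_px))
        small = small[small > 0]
        if small.size == 0 or areas[areas > 0].size <= 1:
            break
        adj = _adjacency_counts(labels)
        neighbors: dict[int, dict[int, int]] = {}
        for (a, b), c in adj.items():
            neighbors.setdefault(a, {})[b] = c
        # union-find: robust to mutually-merging small basins
        parent = np.arange(areas.size)

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return int(i)

        for lab in sorted(small, key=lambda l: areas[l]):
            nb = neighbors.get(int(lab))
            if not nb:
                continue
            target = max(nb.items(), key=lambda kv: kv[1])[0]
            ra, rb = find(int(lab)), find(int(target))
            if ra != rb:
                parent[ra] = rb
        mapping = np.array([find(i) for i in range(areas.size)])
        labels = mapping[labels]
    # compress to contiguous ids 1..K
    uniq = np.unique(labels)
    remap = np.zeros(uniq.max() + 1, dtype=np.int32)
    remap[uniq] = np.arange(1, uniq.size + 1)
    return remap[labels]


def watershed_basins(
    mip: np.ndarray,
    pixel_area_um2: float,
    min_area_um2: float = 8.0,
) -> BasinSegmentation:
    """Watershed of the inverted MIP into single-speckle catchment basins.

    Basins form around local intensity maxima; basins smaller than
    ``min_area_um2`` (just below the image resolution, to avoid
    oversegmentation) are merged into the neighbor with the longest shared
    boundary.  Every pixel ends up labeled.
    """
    mip = np.asarray(mip, dtype=float)
    if np.any(mip < 0):
        raise ValueError("MIP must be non-negative (linear intensity)")
    if mip.max() == mip.min():
        warnings.warn("degenerate constant image: single basin", stacklevel=2)
        labels = np.ones(mip.shape, dtype=np.int32)
    else:
        labels = watershed(-mip).astype(np.int32)
        min_px = max(1, int(np.ceil(min_area_um2 / pixel_area_um2)))
        labels = _merge_small_basins(labels, min_px)
    n_basins = int(labels.max())
    areas_px = np.bincount(labels.ravel(), minlength=n_basins + 1)[1:]
    return BasinSegmentation(
        labels=labels,
        n_basins=n_basins,
        areas_um2=areas_px * pixel_area_um2,
        pixel_area_um2=pixel_area_um2,
        mip=mip,
    )


# ---------------------------------------------------------------------------
# Spectra and the DFM statistic

def basin_spectra(stack: HyperStack, seg: BasinSegmentation) -> np.ndarray:
    """Mean linear intensity per basin per band: (n_basins, n_bands)."""
    if seg.labels.shape != stack.intensity.shape[1:]:
        raise ValueError("segmentation does not match stack geometry")
    ids = np.arange(1, seg.n_basins + 1)
    means = np.empty((seg.n_basins, stack.n_bands))
    for j in range(stack.n_bands):
        means[:, j] = ndimage.mean(stack.intensity[j], seg.labels, ids)
    return means


def deviation_spectrum(spectrum: np.ndarray) -> np.ndarray:
    """I_dev(λ_j) = I(λ_j) − mean_j I; works on (..., n_bands) arrays."""
    s = np.asarray(spectrum, dtype=float)
    return s - s.mean(axis=-1, keepdims=True)


def dfm(i_dev: np.ndarray, band_centers_nm: np.ndarray) -> np.ndarray:
    """DFM = ∫|I_dev| dλ over the band centres (trapezoidal), intensity·nm."""
    lam = np.asarray(band_centers_nm, dtype=float)
    if np.any(np.diff(lam) <= 0):
        raise ValueError("band centres must be strictly increasing")
    return np.trapezoid(np.abs(np.asarray(i_dev, dtype=float)), lam, axis=-1)


def basin_spectrum_records(
    means: np.ndarray, band_centers_nm: np.ndarray
) -> list[BasinSpectrum]:
    """Wrap a basin-means matrix into per-basin records."""
    dev = deviation_spectrum(means)
    vals = dfm(dev, band_centers_nm)
    return [
        BasinSpectrum(i + 1, means[i], dev[i], float(vals[i]))
        for i in range(means.shape[0])
    ]


def dfm_map(seg: BasinSegmentation, dfm_values: np.ndarray) -> np.ndarray:
    """Paint every pixel with its basin's DFM value."""
    vals = np.asarray(dfm_values, dtype=float)
    if vals.size != seg.n_basins:
        raise ValueError("need exactly one DFM value per basin")
    lut = np.concatenate([[0.0], vals])
    return lut[seg.labels]


# ---------------------------------------------------------------------------
# Noise, surface, thresholding

def estimate_noise_stats(
    image: np.ndarray, roi_mask: np.ndarray
) -> tuple[float, float]:
    """(mean, SD) of map values over a signal-free region of interest."""
    roi = np.asarray(roi_mask, dtype=bool)
    vals = np.asarray(image, dtype=float)[roi]
    if vals.size < 100:
        raise ValueError("noise ROI must contain at least 100 pixels")
    mean, sd = float(vals.mean()), float(vals.std())
    # OCT intensity noise is heavy-tailed (speckle statistics), so only an
    # extreme outlier indicates the ROI caught real structure.
    if sd > 0 and vals.max() > mean + 30 * sd:
        warnings.warn("noise ROI appears to overlap structure", stacklevel=2)
    return mean, sd


def estimate_noise_sd(image: np.ndarray, roi_mask: np.ndarray) -> float:
    """Sample SD of map values over a signal-free ROI."""
    return estimate_noise_stats(image, roi_mask)[1]


def detect_surface(mip: np.ndarray, median_width: int = 5) -> np.ndarray:
    """Per-A-scan surface row: first depth above 50% of the column maximum,
    median-filtered across columns.  Columns with no crossing are filled
    from their neighbors."""
    mip = np.asarray(mip, dtype=float)
    n_z, n_x = mip.shape
    surface = np.full(n_x, -1, dtype=float)
    col_max = mip.max(axis=0)
    ok = col_max > 0
    above = mip >= 0.5 * col_max[None, :]
    first = above.argmax(axis=0)
    surface[ok] = first[ok]
    if not np.all(ok):
        if not np.any(ok):
            raise ValueError("image has no dominant interface")
        idx = np.flatnonzero(ok)
        surface[~ok] = np.interp(np.flatnonzero(~ok), idx, surface[idx])
        logger.info("detect_surface: filled %d empty columns", int(np.sum(~ok)))
    from scipy.signal import medfilt

    return medfilt(surface, kernel_size=median_width)


def fraction_above_threshold(
    image: np.ndarray,
    surface_px: np.ndarray,
    pitch_z_um: float,
    noise_mean: float,
    noise_sd: float,
    k: float = 3.0,
    window_um: float = 50.0,
    margin_um: float = 6.0,
) -> float:
    """Percentage of pixels above ``noise_mean + k·noise_sd`` in a depth
    window below the surface.

    The window starts one exclusion margin (default one axial resolution)
    below the detected surface line and extends ``window_um`` in physical
    depth; ``pitch_z_um`` is the physical depth pixel pitch.  Truncated
    with a warning if it reaches past the image bottom.
    """
    img = np.asarray(image, dtype=float)
    n_z, n_x = img.shape
    margin_px = int(round(margin_um / pitch_z_um))
    window_px = max(1, int(round(window_um / pitch_z_um)))
    threshold = noise_mean + k * noise_sd
    count = 0
    total = 0
    truncated = False
    for ix in range(n_x):
        z0 = int(surface_px[ix]) + margin_px
        z1 = z0 + window_px
        if z1 > n_z:
            truncated = True
            z1 = n_z
        col = img[z0:z1, ix]
        count += int(np.sum(col > threshold))
        total += col.size
    if truncated:
        warnings.warn("depth window truncated at image bottom", stacklevel=2)
    if total == 0:
        raise ValueError("empty depth window")
    return 100.0 * count / total


def rgb_encode(
    stack: HyperStack,
    bands_nm: tuple[float, float, float] = (540.0, 550.0, 560.0),
    percentiles: tuple[float, float] = (0.1, 99.9),
) -> np.ndarray:
    """Encode three band images as (B, G, R) channels of an RGB image.

    Default encoding: 540 nm in blue, 550 nm in green, 560 nm in red; each
    channel is percentile-normalized to [0, 1].  Returns (depth, lateral, 3)
    in RGB channel order.
    """
    centers = np.asarray(stack.band_centers_nm, dtype=float)
    chans = []
    for lam in bands_nm:
        idx = np.flatnonzero(np.isclose(centers, lam))
        if idx.size == 0:
            raise ValueError(f"band {lam:g} nm not present in the stack")
        img = stack.intensity[int(idx[0])]
        lo, hi = np.percentile(img, percentiles)
        chans.append(np.clip((img - lo) / max(hi - lo, 1e-30), 0.0, 1.0))
    blue, green, red = chans
    return np.stack([red, green, blue], axis=-1)


def average_repeats(stacks) -> HyperStack:
    """Pixelwise mean of linear intensities across repeated B-scans.

    Accepts a sequence of registered :class:`HyperStack` objects of equal
    geometry (the simulator is motion-free, so repeats are co-registered by
    construction).  Averaging precedes the MIP in the analysis pipeline.
    """
    stacks = list(stacks)
    first = stacks[0]
    mean = np.mean([s.intensity for s in stacks], axis=0)
    return HyperStack(
        intensity=mean,
        band_centers_nm=first.band_centers_nm,
        pitch_z_um=first.pitch_z_um,
        pitch_x_um=first.pitch_x_um,
        shifts_px=first.shifts_px,
        n_group=first.n_group,
        meta={**first.meta, "n_averaged": len(stacks)},
    )


# ---------------------------------------------------------------------------
# Full analysis

def analyze_stack(
    stack: HyperStack,
    min_area_um2: float = 8.0,
    k: float = 3.0,
    window_um: float = 50.0,
    margin_um: float = 6.0,
    noise_roi_start_px: int = 8,
) -> dict:
    """Run the full DFM analysis of one registered hyperspectral stack.

    Returns a dict with the segmentation, per-basin table, DFM map
    (:class:`DFMMap`), the intensity-thresholded MIP, and the
    fraction-above-threshold summary for both the intensity and the DFM
    images.  The noise region of interest is the area anterior to the
    detected surface (excluding the first ``noise_roi_start_px`` rows,
    which hold the suppressed DC line).
    """
    pitch_z_phys = stack.pitch_z_um / stack.n_group
    pixel_area = pitch_z_phys * stack.pitch_x_um

    mip = mip_across_bands(stack)
    surface = detect_surface(mip)

    margin_px = int(round(margin_um / pitch_z_phys))
    n_z, n_x = mip.shape
    rows = np.arange(n_z)[:, None]
    # The noise ROI is the signal-free region anterior to the shallowest
    # detected structure: sparse scatterers (e.g. RPE granules) can sit above
    # the per-column surface line in some columns, so the global minimum is
    # the safe bound.
    noise_roi = (rows >= noise_roi_start_px) & (
        rows < (float(surface.min()) - margin_px)
    ) & np.ones((1, n_x), dtype=bool)
    if noise_roi.sum() < 100:
        raise ValueError("signal-free region above the surface is too small")

    seg = watershed_basins(mip, pixel_area, min_area_um2)
    means = basin_spectra(stack, seg)
    dev = deviation_spectrum(means)
    dfm_values = dfm(dev, stack.band_centers_nm)
    dmap = dfm_map(seg, dfm_values)

    int_mean, int_sd = estimate_noise_stats(mip, noise_roi)
    # For the basin-painted DFM map, restrict the noise statistics to basins
    # fully contained in the ROI: basins straddling the ROI boundary carry
    # DFM values driven by the bright structure below it.
    in_roi = np.bincount(seg.labels[noise_roi].ravel(),
                         minlength=seg.n_basins + 1)
    tot = np.bincount(seg.labels.ravel(), minlength=seg.n_basins + 1)
    contained = (in_roi == tot) & (tot > 0)
    dfm_noise_roi = noise_roi & contained[seg.labels]
    if dfm_noise_roi.sum() >= 100:
        dfm_mean, dfm_sd = estimate_noise_stats(dmap, dfm_noise_roi)
    else:
        warnings.warn("few basins fully inside the noise ROI; DFM noise "
                      "statistics may be biased by structure", stacklevel=2)
        dfm_mean, dfm_sd = estimate_noise_stats(dmap, noise_roi)

    frac_int = fraction_above_threshold(
        mip, surface, pitch_z_phys, int_mean, int_sd, k, window_um, margin_um
    )
    frac_dfm = fraction_above_threshold(
        dmap, surface, pitch_z_phys, dfm_mean, dfm_sd, k, window_um, margin_um
    )

    dfm_result = DFMMap(
        dfm_image=dmap,
        binary=dmap > dfm_mean + k * dfm_sd,
        noise_sd=dfm_sd,
        noise_mean=dfm_mean,
        k=k,
        threshold=dfm_mean + k * dfm_sd,
        surface_px=surface,
    )

    table = pd.DataFrame(
        means, columns=[f"I_{int(c)}nm" for c in stack.band_centers_nm]
    )
    table.insert(0, "basin_id", np.arange(1, seg.n_basins + 1))
    table.insert(1, "area_um2", seg.areas_um2)
    table["dfm"] = dfm_values

    return {
        "mip": mip,
        "surface_px": surface,
        "noise_roi": noise_roi,
        "segmentation": seg,
        "basin_table": table,
        "dfm_map": dfm_result,
        "intensity_binary": mip > int_mean + k * int_sd,
        "noise": {
            "intensity_mean": int_mean,
            "intensity_sd": int_sd,
            "dfm_mean": dfm_mean,
            "dfm_sd": dfm_sd,
        },
        "fraction_above_threshold": {
            "intensity_pct": frac_int,
            "dfm_pct": frac_dfm,
        },
    }
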