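"""Explanatory diagnostics of reference patterns.

Two empirical quantities explain most of the mask-topology ranking: the
distribution of intensity-gradient values/orientations of the reference
images (refraction is encoded through grad I_r, so a broad, isotropic
gradient distribution means artifact-free displacement retrieval), and the
modulation packing density (locally missing modulations mean locally missing
information).  This module measures both on single reference images or on
the pixelwise sum of a shifted reference stack.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max

__all__ = [
    "GradientStats",
    "DensityMap",
    "gradient_stats",
    "orientation_entropy",
    "isotropy_chi2",
    "packing_density",
    "detect_modulations",
]


@dataclass
class GradientStats:
    """Gradient-magnitude and (magnitude-weighted) orientation histograms."""

    magnitude_bins: np.ndarray       # bin edges
    magnitude_histogram: np.ndarray  # normalized to sum 1
    orientation_bins: np.ndarray     # edges over [-pi, pi)
    orientation_histogram: np.ndarray
    mean_magnitude: float
    std_magnitude: float
    entropy: float                   # orientation entropy, nats
    scope: str                       # 'single_reference' | 'sum_of_K'
    degenerate: bool                 # True: no gradient anywhere


def gradient_stats(
    images: np.ndarray,
    magnitude_bins: int = 64,
    orientation_bins: int = 36,
    weighted: bool = True,
) -> GradientStats:
    """Gradient statistics of one reference image or of a summed stack.

    A (K, H, W) stack is summed pixelwise first (scope ``sum_of_K``); the
    orientation histogram is weighted by gradient magnitude (convention
    frozen here) so flat regions do not dilute the anisotropy signal.
    """
    images = np.asarray(images, dtype=np.float64)
    if images.ndim == 3:
        img = images.sum(axis=0)
        scope = "sum_of_K"
    elif images.ndim == 2:
        img = images
        scope = "single_reference"
    else:
        raise ValueError("expected a 2-D image or a (K, H, W) stack")
    gy, gx = np.gradient(img)
    mag = np.hypot(gx, gy).ravel()
    ang = np.arctan2(gy, gx).ravel()
    degenerate = not np.any(mag > 0)
    m_hist, m_edges = np.histogram(mag, bins=magnitude_bins)
    o_edges = np.linspace(-math.pi, math.pi, orientation_bins + 1)
    w = mag if weighted else None
    o_hist, _ = np.histogram(ang, bins=o_edges, weights=w)
    m_hist = m_hist / max(m_hist.sum(), 1)
    o_sum = o_hist.sum()
    o_hist = o_hist / o_sum if o_sum > 0 else o_hist
    ent = orientation_entropy(o_hist) if not degenerate else 0.0
    return GradientStats(
        magnitude_bins=m_edges,
        magnitude_histogram=m_hist,
        orientation_bins=o_edges,
        orientation_histogram=o_hist,
        mean_magnitude=float(mag.mean()),
        std_magnitude=float(mag.std()),
        entropy=ent,
        scope=scope,
        degenerate=degenerate,
    )


def orientation_entropy(p: np.ndarray) -> float:
    """Shannon entropy (nats) of a normalized orientation histogram."""
    p = np.asarray(p, dtype=np.float64)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def isotropy_chi2(
    stats: GradientStats, n_effective: int
) -> tuple[float, float]:
    """Chi-square test of the orientation histogram against uniformity.

    Gradients of neighbouring raster cells are strongly correlated within one
    modulation, so the histogram's pixel count wildly overstates the number
    of independent orientation samples; ``n_effective`` (normally the number
    of modulations in the field) sets the multinomial sample size used for
    the test.  Returns (chi2, p_value).
    """
    from scipy.stats import chi2 as chi2_dist

    p = stats.orientation_histogram
    m = len(p)
    expected = n_effective / m
    observed = p * n_effective
    stat = float(((observed - expected) ** 2 / expected).sum())
    return stat, float(chi2_dist.sf(stat, df=m - 1))


@dataclass
class DensityMap:
    """Modulation packing density on a sliding-window grid."""

    density: np.ndarray    # modulations / pixel^2, per window position
    window: int
    stride: int
    centers: np.ndarray    # detected modulation centers, (n, 2) row/col
    mean: float
    std: float


def detect_modulations(
    I_r: np.ndarray,
    spacing_px: float,
    prominence_fraction: float = 0.1,
) -> np.ndarray:
    """Detect modulation centers as band-passed regional extrema.

    A difference-of-Gaussians band-pass tuned to the design peak-to-peak
    spacing isolates the modulations; local maxima of its absolute value
    with prominence above ``prominence_fraction`` of the band-passed
    amplitude are taken as centers.
    """
    img = np.asarray(I_r, dtype=np.float64)
    s1 = max(spacing_px / 6.0, 0.5)
    band = (ndimage.gaussian_filter(img, s1)
            - ndimage.gaussian_filter(img, 1.6 * s1))
    amp = np.abs(band)
    thr = prominence_fraction * amp.max()
    min_dist = max(1, int(round(spacing_px / 2.5)))
    peaks = peak_local_max(amp, min_distance=min_dist, threshold_abs=thr,
                           exclude_border=False)
    return peaks


def packing_density(
    I_r: np.ndarray,
    window: int = 32,
    stride: int = 8,
    spacing_px: float = 4.0,
    prominence_fraction: float = 0.1,
) -> DensityMap:
    """Sliding-window modulation density (modulations / pixel^2)."""
    if window < spacing_px:
        raise ValueError(
            f"window ({window} px) must be at least the modulation spacing "
            f"({spacing_px} px)"
        )
    centers = detect_modulations(I_r, spacing_px, prominence_fraction)
    H, W = I_r.shape
    counts = np.zeros((H, W))
    if len(centers):
        counts[centers[:, 0], centers[:, 1]] = 1.0
    ys = range(0, H - window + 1, stride)
    xs = range(0, W - window + 1, stride)
    csum = counts.cumsum(axis=0).cumsum(axis=1)
    padded = np.zeros((H + 1, W + 1))
    padded[1:, 1:] = csum
    dens = np.empty((len(list(ys)), len(list(xs))))
    for i, y0 in enumerate(range(0, H - window + 1, stride)):
        for j, x0 in enumerate(range(0, W - window + 1, stride)):
            c = (padded[y0 + window, x0 + window] - padded[y0, x0 + window]
                 - padded[y0 + window, x0] + padded[y0, x0])
            dens[i, j] = c / window**2
    return DensityMap(
        density=dens,
        window=window,
        stride=stride,
        centers=centers,
        mean=float(dens.mean()),
        std=float(dens.std()),
    )
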