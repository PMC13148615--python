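"""Image-quality assessment of retrieved displacement maps.

All indices are computed on displacement maps (``D_y`` by convention, or
``D_x``), never on integrated phase: the displacement is what the retrieval
estimates directly and phase integration would smear local errors across the
field.  Reference-based indices (NRMSE, SSIM family) compare a retrieved map
against the theoretical displacement ``D0`` computed from the phantom's
thickness map; the Fourier ring correlation compares two independent
retrievals of the same scene and yields a spatial-resolution estimate at the
1/7 threshold.

Conventions frozen here (the source protocols do not pin them down): SSIM
uses a uniform 7x7 window with k1 = 0.01, k2 = 0.03 and L equal to the
dynamic range of the stacked pair; MS-SSIM uses the standard 5 dyadic scales
and weights; SR-SIM and VSI use a spectral-residual visual-saliency map
(see docs/methods.md) with the constants of their reference descriptions;
FRC uses 1-bin rings, no apodization, linear interpolation at the crossing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .synthetic_data import (
    AcquisitionGeometry,
    ThicknessMap,
    refraction_displacement,
)

__all__ = [
    "TheoreticalDisplacement",
    "SsimParams",
    "FrcCurve",
    "theoretical_displacement",
    "nrmse",
    "ssim",
    "ms_ssim",
    "sr_sim",
    "vsi",
    "frc",
    "frc_resolution",
    "angular_sensitivity",
    "place_windows",
    "snr",
    "METRICS",
]


@dataclass
class TheoreticalDisplacement:
    """Ideal displacement maps (pixels) for a phantom under a geometry."""

    D0_x: np.ndarray
    D0_y: np.ndarray

    def component(self, which: str) -> np.ndarray:
        return {"x": self.D0_x, "y": self.D0_y}[which]


def theoretical_displacement(
    sample: ThicknessMap, geometry: AcquisitionGeometry,
    detector_shape: Optional[tuple[int, int]] = None,
) -> TheoreticalDisplacement:
    """Ideal (D0_x, D0_y) on the detector grid.

    If the phantom is rasterized on an oversampled detector-conjugate grid,
    pass ``detector_shape`` to block-average down to detector pixels.
    """
    d0x, d0y = refraction_displacement(sample, geometry)
    if detector_shape is not None and d0x.shape != tuple(detector_shape):
        os_ = d0x.shape[0] // detector_shape[0]
        if (d0x.shape[0] != os_ * detector_shape[0]
                or d0x.shape[1] != os_ * detector_shape[1]):
            raise ValueError("phantom grid is not an integer multiple of detector_shape")
        h, w = detector_shape
        d0x = d0x.reshape(h, os_, w, os_).mean(axis=(1, 3))
        d0y = d0y.reshape(h, os_, w, os_).mean(axis=(1, 3))
    return TheoreticalDisplacement(D0_x=d0x, D0_y=d0y)


# ---------------------------------------------------------------------------
# reference-based indices
# ---------------------------------------------------------------------------

def nrmse(D: np.ndarray, D0: np.ndarray) -> float:
    """RMSE normalized by the Euclidean norm of the reference: ||D-D0||/||D0||."""
    D = np.asarray(D, dtype=np.float64)
    D0 = np.asarray(D0, dtype=np.float64)
    if D.shape != D0.shape:
        raise ValueError("shape mismatch")
    ref = np.linalg.norm(D0)
    if ref == 0:
        raise ValueError("reference image has zero norm; NRMSE undefined")
    return float(np.linalg.norm(D - D0) / ref)


@dataclass(frozen=True)
class SsimParams:
    k1: float = 0.01
    k2: float = 0.03
    window: int = 7
    L: Optional[float] = None  # dynamic range; None = from the stacked pair

    def dynamic_range(self, x: np.ndarray, y: np.ndarray) -> float:
        if self.L is not None:
            return self.L
        both = np.stack([x, y])
        L = float(both.max() - both.min())
        return L if L > 0 else 1.0


def _ssim_cs(x: np.ndarray, y: np.ndarray, params: SsimParams
             ) -> tuple[np.ndarray, np.ndarray]:
    """Per-window luminance*contrast-structure and contrast-structure maps."""
    w = params.window
    if min(x.shape) < w:
        raise ValueError(f"image smaller than the {w}x{w} SSIM window")
    L = params.dynamic_range(x, y)
    c1, c2 = (params.k1 * L) ** 2, (params.k2 * L) ** 2
    f = lambda a: ndimage.uniform_filter(a.astype(np.float64), size=w)
    mx, my = f(x), f(y)
    # unbiased moments as in the reference implementation
    n = w * w
    cov_norm = n / (n - 1)
    vx = cov_norm * (f(x * x) - mx * mx)
    vy = cov_norm * (f(y * y) - my * my)
    cxy = cov_norm * (f(x * y) - mx * my)
    lum = (2 * mx * my + c1) / (mx**2 + my**2 + c1)
    cs = (2 * cxy + c2) / (vx + vy + c2)
    pad = (w - 1) // 2
    sl = (slice(pad, -pad), slice(pad, -pad))
    return (lum * cs)[sl], cs[sl]


def ssim(x: np.ndarray, y: np.ndarray, params: SsimParams = SsimParams()) -> float:
    """Mean structural similarity over uniform 7x7 windows."""
    return float(_ssim_cs(x, y, params)[0].mean())


MS_SSIM_WEIGHTS = (0.0448, 0.2856, 0.3001, 0.2363, 0.1333)


def ms_ssim(x: np.ndarray, y: np.ndarray, params: SsimParams = SsimParams(),
            weights: Sequence[float] = MS_SSIM_WEIGHTS) -> float:
    """Multi-scale SSIM over a dyadic low-pass pyramid.

    Contrast-structure terms at every scale, luminance at the coarsest; if
    the image cannot support all scales the pyramid is truncated and the
    weights renormalized.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    # L frozen at the finest scale so all scales share the stabilizers
    params = SsimParams(params.k1, params.k2, params.window,
                        params.dynamic_range(x, y))
    levels = len(weights)
    while levels > 1 and min(x.shape) // 2 ** (levels - 1) < params.window:
        levels -= 1
    w = np.asarray(weights[:levels]) / np.sum(weights[:levels])
    vals = []
    for lev in range(levels):
        lcs, cs = _ssim_cs(x, y, params)
        vals.append(lcs.mean() if lev == levels - 1 else cs.mean())
        if lev < levels - 1:
            x = ndimage.uniform_filter(x, size=2)[::2, ::2]
            y = ndimage.uniform_filter(y, size=2)[::2, ::2]
    vals = np.clip(np.asarray(vals), 1e-6, None)
    return float(np.prod(vals ** w))


def _to_uint8_range(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    both = np.stack([x, y]).astype(np.float64)
    lo, hi = both.min(), both.max()
    scale = 255.0 / (hi - lo) if hi > lo else 1.0
    return (x - lo) * scale, (y - lo) * scale


def _spectral_residual_saliency(img: np.ndarray, smooth_sigma: float = 2.5
                                ) -> np.ndarray:
    """Spectral-residual visual-saliency map (log-spectrum residual model)."""
    F = np.fft.fft2(img)
    log_amp = np.log(np.abs(F) + 1e-12)
    residual = log_amp - ndimage.uniform_filter(log_amp, size=3)
    sal = np.abs(np.fft.ifft2(np.exp(residual + 1j * np.angle(F)))) ** 2
    return ndimage.gaussian_filter(sal, smooth_sigma)


def _scharr_magnitude(img: np.ndarray) -> np.ndarray:
    gx = ndimage.correlate1d(ndimage.correlate1d(img, [3, 10, 3], axis=0),
                             [-1, 0, 1], axis=1) / 16.0
    gy = ndimage.correlate1d(ndimage.correlate1d(img, [3, 10, 3], axis=1),
                             [-1, 0, 1], axis=0) / 16.0
    return np.hypot(gx, gy)


def sr_sim(x: np.ndarray, y: np.ndarray, c1: float = 0.40, c2: float = 225.0,
           alpha: float = 0.50) -> float:
    """Spectral-residual similarity: saliency term times gradient term,
    pooled with the pointwise maximum saliency as weight."""
    x8, y8 = _to_uint8_range(x, y)
    v1, v2 = _spectral_residual_saliency(x8), _spectral_residual_saliency(y8)
    g1, g2 = _scharr_magnitude(x8), _scharr_magnitude(y8)
    s_v = (2 * v1 * v2 + c1) / (v1**2 + v2**2 + c1)
    s_g = (2 * g1 * g2 + c2) / (g1**2 + g2**2 + c2)
    s = s_v * s_g**alpha
    w = np.maximum(v1, v2)
    return float((s * w).sum() / w.sum())


def vsi(x: np.ndarray, y: np.ndarray, c1: float = 1.27, c2: float = 386.0,
        alpha: float = 0.40) -> float:
    """Visual-saliency-induced index for single-channel maps.

    The visual-saliency map is the spectral-residual model (the chrominance
    term of the colour formulation does not apply to displacement maps).
    """
    x8, y8 = _to_uint8_range(x, y)
    v1 = _spectral_residual_saliency(x8)
    v2 = _spectral_residual_saliency(y8)
    # VS maps conventionally normalized to [0, 255]
    v1 *= 255.0 / max(v1.max(), 1e-12)
    v2 *= 255.0 / max(v2.max(), 1e-12)
    g1, g2 = _scharr_magnitude(x8), _scharr_magnitude(y8)
    s_vs = (2 * v1 * v2 + c1) / (v1**2 + v2**2 + c1)
    s_g = (2 * g1 * g2 + c2) / (g1**2 + g2**2 + c2)
    s = s_vs * s_g**alpha
    w = np.maximum(v1, v2)
    return float((s * w).sum() / w.sum())


METRICS = {
    "nrmse": nrmse,
    "ssim": lambda d, d0: ssim(d, d0),
    "ms_ssim": lambda d, d0: ms_ssim(d, d0),
    "sr_sim": lambda d, d0: sr_sim(d, d0),
    "vsi": lambda d, d0: vsi(d, d0),
}


# ---------------------------------------------------------------------------
# Fourier ring correlation
# ---------------------------------------------------------------------------

@dataclass
class FrcCurve:
    """Per-ring correlation of two realizations plus the 1/7 resolution."""

    frequencies: np.ndarray       # cycles/pixel (ring centers)
    correlation: np.ndarray
    threshold: float
    resolution: float             # pixels at the first threshold crossing
    crossed: bool                 # False: never fell below threshold

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"frequency": self.frequencies, "correlation": self.correlation}
        ).to_csv(path, index=False)


def frc(D_a: np.ndarray, D_b: np.ndarray, ring_width: int = 1,
        threshold: float = 1.0 / 7.0, apodize: bool = False) -> FrcCurve:
    """Fourier ring correlation between two independent retrievals.

    Per ring: Re<F_a F_b*> / sqrt(<|F_a|^2><|F_b|^2>).  The resolution is
    1/f at the first downward crossing of the threshold (linear interpolation
    between ring centers); if the curve never crosses, the Nyquist limit of
    2 pixels is reported with ``crossed=False``.
    """
    a = np.asarray(D_a, dtype=np.float64)
    b = np.asarray(D_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    n = min(a.shape)
    if a.shape[0] != a.shape[1]:  # central square crop
        oy, ox = (a.shape[0] - n) // 2, (a.shape[1] - n) // 2
        a = a[oy:oy + n, ox:ox + n]
        b = b[oy:oy + n, ox:ox + n]
    if apodize:
        win = np.hanning(n)
        w2 = win[:, None] * win[None, :]
        a, b = a * w2, b * w2
    Fa = np.fft.fftshift(np.fft.fft2(a - a.mean()))
    Fb = np.fft.fftshift(np.fft.fft2(b - b.mean()))
    yy, xx = np.indices((n, n))
    r = np.hypot(yy - n // 2, xx - n // 2)
    ring = (r / ring_width).astype(int)
    nr = n // 2 // ring_width
    idx = ring.ravel()
    num = np.bincount(idx, weights=np.real(Fa * np.conj(Fb)).ravel())[:nr]
    da = np.bincount(idx, weights=(np.abs(Fa) ** 2).ravel())[:nr]
    db = np.bincount(idx, weights=(np.abs(Fb) ** 2).ravel())[:nr]
    corr = num / np.sqrt(np.clip(da * db, 1e-300, None))
    freqs = (np.arange(nr) + 0.5) * ring_width / n
    res, crossed = frc_resolution(freqs[1:], corr[1:], threshold)
    return FrcCurve(frequencies=freqs, correlation=corr, threshold=threshold,
                    resolution=res, crossed=crossed)


def frc_resolution(freqs: np.ndarray, corr: np.ndarray, threshold: float
                   ) -> tuple[float, bool]:
    below = corr < threshold
    if not below.any():
        return 2.0, False
    i = int(np.argmax(below))
    if i == 0:
        return float(1.0 / freqs[0]), True
    f0, f1 = freqs[i - 1], freqs[i]
    c0, c1 = corr[i - 1], corr[i]
    f_cross = f0 + (c0 - threshold) * (f1 - f0) / max(c0 - c1, 1e-12)
    return float(1.0 / f_cross), True


# ---------------------------------------------------------------------------
# angular sensitivity and SNR
# ---------------------------------------------------------------------------

def place_windows(
    support: Optional[np.ndarray],
    frame_shape: tuple[int, int],
    n_windows: int = 8,
    window_shape: tuple[int, int] = (5, 40),
    margin: int = 8,
    exclusion: int = 10,
) -> list[tuple[slice, slice]]:
    """Deterministically place sample-free analysis windows.

    Candidate positions are scanned on a window-sized grid inside the frame
    (``margin`` px off the borders); windows intersecting the phantom support
    dilated by ``exclusion`` px are rejected; the accepted candidates are
    thinned evenly to ``n_windows``.
    """
    H, W = frame_shape
    wh, ww = window_shape
    if support is not None:
        forbid = ndimage.binary_dilation(support, iterations=exclusion)
    else:
        forbid = np.zeros(frame_shape, dtype=bool)
    cands = []
    for y0 in range(margin, H - margin - wh + 1, wh):
        for x0 in range(margin, W - margin - ww + 1, ww):
            win = (slice(y0, y0 + wh), slice(x0, x0 + ww))
            if not forbid[win].any():
                cands.append(win)
    if len(cands) < n_windows:
        raise ValueError(
            f"could only place {len(cands)}/{n_windows} sample-free windows"
        )
    pick = np.linspace(0, len(cands) - 1, n_windows).round().astype(int)
    return [cands[i] for i in pick]


def angular_sensitivity(
    D_y: np.ndarray,
    geometry: AcquisitionGeometry,
    windows: Optional[list[tuple[slice, slice]]] = None,
    support: Optional[np.ndarray] = None,
    n_windows: int = 8,
    window_shape: tuple[int, int] = (5, 40),
) -> tuple[float, float]:
    """Angular sensitivity in nanoradians: per-window std of the vertical
    refraction angle, mean +- standard error over the windows.

    Windows must lie in a sample-free zone; pass either explicit windows or
    the phantom support for automatic placement.
    """
    if windows is None:
        windows = place_windows(support, D_y.shape, n_windows, window_shape)
    if support is not None:
        forbid = ndimage.binary_dilation(support, iterations=3)
        for win in windows:
            if forbid[win].any():
                raise ValueError(f"window {win} overlaps the sample support")
    to_nrad = geometry.pixel_size * 1e-6 / geometry.d_sample_detector * 1e9
    stds = np.array([float(D_y[win].std()) * to_nrad for win in windows])
    mean = float(stds.mean())
    se = float(stds.std(ddof=1) / math.sqrt(len(stds))) if len(stds) > 1 else 0.0
    return mean, se


def snr(
    img: np.ndarray,
    roi_signal: tuple[slice, slice],
    roi_background: tuple[slice, slice],
) -> float:
    """(mean(signal) - mean(background)) / std(background)."""
    sig = np.asarray(img[roi_signal], dtype=np.float64)
    bg = np.asarray(img[roi_background], dtype=np.float64)
    if sig.size < 2 or bg.size < 2:
        raise ValueError("degenerate ROI")
    s = bg.std()
    if s == 0:
        raise ValueError("background has zero variance")
    return float((sig.mean() - bg.mean()) / s)
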