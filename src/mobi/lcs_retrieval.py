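"""Implicit LCS retrieval of absorption, refraction and (directional) dark-field.

The low-coherence-system (LCS) retrieval links each reference/sample pair to
the sample's optical action through a per-pixel linear model derived from the
transport-of-intensity equation and optical-flow conservation.  With the
convention fixed here (documented prominently because the coefficient
placement is a convention, not unique), pair ``k`` contributes the row

    I_r,k - I_s,k = I_obj * I_r,k + D_x * dI_r,k/dx + D_y * dI_r,k/dy
                    + D_f * (-lap I_r,k)

so that a pure attenuation yields ``I_obj > 0``, a pattern shift of ``D``
pixels is recovered in detector pixels, and a blur of std ``sigma`` yields
``D_f ~ sigma^2 / 2 >= 0`` (negative-Laplacian coupling).  The system needs
at least K = 4 pairs for the scalar dark-field and K = 6 for the symmetric
2x2 dark-field tensor, whose rows replace ``-lap`` by
``(-dxx, -2 dxy, -dyy)``.

The retrieval is exposed statsmodels-style: build :class:`LcsModel` from an
:class:`~mobi.synthetic_data.ImagePairSet`, call :meth:`LcsModel.fit` and
work with the returned :class:`LcsResults` (maps, residuals, diagnostics,
``summary()``, phase integration, HSV encoding of the tensor).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import ndimage

from .synthetic_data import AcquisitionGeometry, ImagePairSet

__all__ = [
    "LcsSystem",
    "LcsModel",
    "LcsResults",
    "build_lcs_system",
    "solve_lcs",
    "integrate_phase",
    "directional_darkfield",
    "hsv_encode",
]

SCALAR_UNKNOWNS = ("I_obj", "D_x", "D_y", "D_f")
TENSOR_UNKNOWNS = ("I_obj", "D_x", "D_y", "T_xx", "T_xy", "T_yy")


@dataclass
class LcsSystem:
    """Per-pixel linear system: ``coeffs[k] . x = rhs[k]`` for each pixel.

    coeffs : (K, P, H, W) coefficient images (P = 4 scalar, 6 tensor)
    rhs : (K, H, W) right-hand sides I_r - I_s
    border : boolean map flagging pixels whose stencils used one-sided
        differences (1-px frame)
    """

    coeffs: np.ndarray
    rhs: np.ndarray
    unknowns: tuple[str, ...]
    geometry: AcquisitionGeometry
    border: np.ndarray

    @property
    def K(self) -> int:
        return self.coeffs.shape[0]


def build_lcs_system(pairs: ImagePairSet, tensor: bool = False) -> LcsSystem:
    """Assemble the LCS coefficient images from a pair series.

    Derivatives use 2nd-order central differences (one-sided at borders,
    flagged) and the 5-point Laplacian.
    """
    need = 6 if tensor else 4
    if pairs.K < need:
        raise ValueError(
            f"LCS needs at least {need} membrane positions for the "
            f"{'tensor' if tensor else 'scalar'} dark-field "
            f"({need} unknowns); got K={pairs.K}"
        )
    K = pairs.K
    H, W = pairs.frame_shape
    P = 6 if tensor else 4
    coeffs = np.empty((K, P, H, W), dtype=np.float32)
    rhs = np.empty((K, H, W), dtype=np.float32)
    for k in range(K):
        ir = pairs.I_r[k].astype(np.float64)
        gy, gx = np.gradient(ir)
        coeffs[k, 0] = ir
        coeffs[k, 1] = gx
        coeffs[k, 2] = gy
        if tensor:
            gyy, _ = np.gradient(gy)
            gxy, gxx = np.gradient(gx)
            coeffs[k, 3] = -gxx
            coeffs[k, 4] = -2.0 * gxy
            coeffs[k, 5] = -gyy
        else:
            coeffs[k, 3] = -ndimage.laplace(ir)
        rhs[k] = ir - pairs.I_s[k].astype(np.float64)
    border = np.zeros((H, W), dtype=bool)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True
    unknowns = TENSOR_UNKNOWNS if tensor else SCALAR_UNKNOWNS
    return LcsSystem(coeffs=coeffs, rhs=rhs, unknowns=unknowns,
                     geometry=pairs.geometry, border=border)


def _normalized_gaussian_fill(chan: np.ndarray, bad: np.ndarray, sigma: float = 2.0
                              ) -> np.ndarray:
    """Replace ``bad`` pixels by a normalized-convolution estimate from
    their neighbours."""
    good = (~bad).astype(np.float64)
    num = ndimage.gaussian_filter(np.where(bad, 0.0, chan), sigma)
    den = ndimage.gaussian_filter(good, sigma)
    fill = np.divide(num, den, out=np.zeros_like(num), where=den > 1e-12)
    out = chan.copy()
    out[bad] = fill[bad]
    return out


def solve_lcs(
    system: LcsSystem,
    regularization: float = 1e-3,
    window: int = 1,
) -> "LcsResults":
    """Per-pixel damped least squares of the LCS system.

    ``regularization`` is a relative Tikhonov factor: each diagonal entry of
    the per-pixel normal matrix is inflated by that fraction of itself (plus
    a tiny absolute floor), which damps all unknowns uniformly regardless of
    their scale.  Rank-deficient pixels (condition of the undamped normal
    matrix above 1e8) are solved by the damped system, then masked and
    inpainted from their neighbours; their count is reported.

    ``window`` > 1 pools the normal equations over a window x window
    neighbourhood (robustness knob; 1 reproduces the pure per-pixel method).
    """
    A = system.coeffs.astype(np.float64)
    b = system.rhs.astype(np.float64)
    G = np.einsum("kihw,kjhw->hwij", A, A, optimize=True)
    c = np.einsum("kihw,khw->hwi", A, b, optimize=True)
    if window > 1:
        size = (window, window)
        for i in range(G.shape[2]):
            c[..., i] = ndimage.uniform_filter(c[..., i], size=size)
            for j in range(G.shape[3]):
                G[..., i, j] = ndimage.uniform_filter(G[..., i, j], size=size)
    P = G.shape[-1]
    diag = np.einsum("hwii->hwi", G)
    floor = 1e-12 * float(diag.mean() + 1.0)
    ev = np.linalg.eigvalsh(G)
    rank_deficient = ev[..., 0] < 1e-8 * np.maximum(ev[..., -1], floor)
    Greg = G.copy()
    idx = np.arange(P)
    Greg[..., idx, idx] += regularization * diag + floor
    x = np.linalg.solve(Greg, c[..., None])[..., 0]
    resid = np.einsum("kihw,hwi->khw", A, x) - b
    residual = np.sqrt(np.mean(resid**2, axis=0))
    bad = rank_deficient
    n_masked = int(bad.sum())
    if n_masked and n_masked < bad.size:
        for i in range(P):
            x[..., i] = _normalized_gaussian_fill(x[..., i], bad)
    tensor = len(system.unknowns) == 6
    maps = {name: x[..., i].astype(np.float64)
            for i, name in enumerate(system.unknowns)}
    return LcsResults(
        geometry=system.geometry,
        unknowns=system.unknowns,
        residual=residual,
        rank_deficient=bad,
        n_masked=n_masked,
        border=system.border,
        regularization=regularization,
        window=window,
        K=system.K,
        tensor=tensor,
        **maps,
    )


@dataclass
class LcsResults:
    """Maps retrieved by the LCS fit, plus diagnostics.

    All maps share the detector shape.  ``I_obj`` is dimensionless
    (positive = attenuation), ``D_x``/``D_y`` are pattern displacements in
    detector pixels, ``D_f`` the scalar dark-field (pixel^2-scaled diffusion;
    small negative excursions are noise unless ``clipped_darkfield`` is
    used).  For a tensor fit the symmetric scattering tensor components
    ``T_xx, T_xy, T_yy`` replace ``D_f``.
    """

    geometry: AcquisitionGeometry
    unknowns: tuple[str, ...]
    I_obj: np.ndarray
    D_x: np.ndarray
    D_y: np.ndarray
    residual: np.ndarray
    rank_deficient: np.ndarray
    n_masked: int
    border: np.ndarray
    regularization: float
    window: int
    K: int
    tensor: bool
    D_f: Optional[np.ndarray] = None
    T_xx: Optional[np.ndarray] = None
    T_xy: Optional[np.ndarray] = None
    T_yy: Optional[np.ndarray] = None
    n_clipped: int = 0

    # -- derived quantities -------------------------------------------------
    def clipped_darkfield(self) -> np.ndarray:
        """Scalar dark-field clipped to >= 0."""
        if self.D_f is None:
            raise ValueError("scalar dark-field not fitted (tensor model)")
        return np.clip(self.D_f, 0.0, None)

    def refraction_angles(self) -> tuple[np.ndarray, np.ndarray]:
        """(alpha_x, alpha_y) in radians: D * pixel_size / z2."""
        g = self.geometry
        s = g.pixel_size * 1e-6 / g.d_sample_detector
        return self.D_x * s, self.D_y * s

    @property
    def phase(self) -> np.ndarray:
        """Integrated, zero-mean phase map (radians)."""
        return integrate_phase(self.D_x, self.D_y, self.geometry)

    def tensor_eigen(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Eigen-decomposition of the dark-field tensor.

        Returns semi-axis lengths ``a >= b >= 0`` (pixels, sqrt of the
        PSD-clipped eigenvalues) and orientation ``psi`` of the major axis in
        [0, pi).  The number of non-PSD pixels clipped is stored in
        ``n_clipped``.
        """
        if not self.tensor:
            raise ValueError("not a tensor fit; use directional_darkfield")
        txx, txy, tyy = self.T_xx, self.T_xy, self.T_yy
        m = 0.5 * (txx + tyy)
        d = np.sqrt(np.clip((0.5 * (txx - tyy)) ** 2 + txy**2, 0.0, None))
        l1, l2 = m + d, m - d
        self.n_clipped = int(np.sum((l1 < 0) | (l2 < 0)))
        a = np.sqrt(np.clip(l1, 0.0, None))
        b = np.sqrt(np.clip(l2, 0.0, None))
        psi = np.mod(0.5 * np.arctan2(2.0 * txy, txx - tyy), math.pi)
        return a, b, psi

    def darkfield_hsv(self) -> np.ndarray:
        """HSV encoding of the directional dark-field (float, HxWx3)."""
        a, b, psi = self.tensor_eigen()
        return hsv_encode(a, b, psi)

    def darkfield_rgb(self) -> np.ndarray:
        """8-bit RGB rendering of the directional dark-field."""
        from matplotlib.colors import hsv_to_rgb

        rgb = hsv_to_rgb(self.darkfield_hsv())
        return (255.0 * np.clip(rgb, 0, 1)).astype(np.uint8)

    # -- reporting ----------------------------------------------------------
    def summary(self) -> str:
        lines = [
            "LCS retrieval results",
            "=" * 58,
            f"pairs (K): {self.K:>6d}    unknowns: {', '.join(self.unknowns)}",
            f"frame: {self.I_obj.shape}    regularization: {self.regularization:g}"
            f"    window: {self.window}",
            f"rank-deficient pixels masked/inpainted: {self.n_masked}"
            f" ({100.0 * self.n_masked / self.I_obj.size:.2f} %)",
            "-" * 58,
            f"{'map':>8s} {'mean':>11s} {'std':>11s} {'min':>11s} {'max':>11s}",
        ]
        for name in self.unknowns:
            m = getattr(self, name)
            lines.append(
                f"{name:>8s} {m.mean():>11.4g} {m.std():>11.4g} "
                f"{m.min():>11.4g} {m.max():>11.4g}"
            )
        lines.append(
            f"{'resid':>8s} {self.residual.mean():>11.4g} "
            f"{self.residual.std():>11.4g} {self.residual.min():>11.4g} "
            f"{self.residual.max():>11.4g}"
        )
        return "\n".join(lines)

    # -- persistence ---------------------------------------------------------
    def to_hdf5(self, path: str | Path) -> None:
        import h5py, json

        with h5py.File(path, "w") as f:
            for name in self.unknowns:
                f.create_dataset(name, data=getattr(self, name), compression="gzip")
            f.create_dataset("residual", data=self.residual, compression="gzip")
            f.create_dataset("phase", data=self.phase, compression="gzip")
            f.attrs["geometry"] = json.dumps(self.geometry.to_dict())
            f.attrs["n_masked"] = self.n_masked
            f.attrs["K"] = self.K

    def to_tiff_dir(self, path: str | Path) -> None:
        import tifffile

        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for name in self.unknowns:
            tifffile.imwrite(path / f"{name}.tif",
                             getattr(self, name).astype(np.float32))
        tifffile.imwrite(path / "residual.tif", self.residual.astype(np.float32))
        tifffile.imwrite(path / "phase.tif", self.phase.astype(np.float32))
        if self.tensor:
            tifffile.imwrite(path / "directional_darkfield_rgb.tif",
                             self.darkfield_rgb())


class LcsModel:
    """Per-pixel LCS retrieval model for a reference/sample pair series.

    Parameters
    ----------
    pairs : ImagePairSet
        K aligned (I_r, I_s) frames; K >= 4 (scalar) or >= 6 (tensor).
    tensor : bool
        Fit the symmetric 2x2 dark-field tensor instead of the scalar D_f.
    regularization : float
        Relative Tikhonov damping of the per-pixel normal matrix.
    window : int
        Local pooling window for the normal equations (1 = per-pixel).
    """

    def __init__(
        self,
        pairs: ImagePairSet,
        tensor: bool = False,
        regularization: float = 1e-3,
        window: int = 1,
    ):
        self.pairs = pairs
        self.tensor = tensor
        self.regularization = regularization
        self.window = window
        self.system = build_lcs_system(pairs, tensor=tensor)

    def fit(self) -> LcsResults:
        return solve_lcs(self.system, self.regularization, self.window)


def integrate_phase(
    D_x: np.ndarray, D_y: np.ndarray, geometry: AcquisitionGeometry
) -> np.ndarray:
    """Least-squares (Fourier) integration of the displacement field.

    Displacements (pixels) are converted to refraction angles
    ``alpha = D * pixel_size / z2``, then to per-cell phase increments
    ``(2 pi / lambda) * alpha * pitch_sample`` and integrated with the
    Frankot-Chellappa solver.  Output is zero-mean; NaNs propagate as zeros
    in the gradient (masked).
    """
    g = geometry
    to_angle = g.pixel_size * 1e-6 / g.d_sample_detector
    step = g.pixel_size * 1e-6 / g.m_sample  # sample-plane m per det pixel
    k = 2.0 * math.pi / g.wavelength
    gx = np.nan_to_num(D_x * to_angle * k * step)
    gy = np.nan_to_num(D_y * to_angle * k * step)
    H, W = gx.shape
    fy = np.fft.fftfreq(H)[:, None]
    fx = np.fft.fftfreq(W)[None, :]
    denom = (2.0 * math.pi) * (fx**2 + fy**2)
    num = -1j * (fx * np.fft.fft2(gx) + fy * np.fft.fft2(gy))
    with np.errstate(divide="ignore", invalid="ignore"):
        phat = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    phi = np.real(np.fft.ifft2(phat))
    return phi - phi.mean()


def directional_darkfield(
    pairs: ImagePairSet,
    regularization: float = 1e-3,
    window: int = 1,
) -> LcsResults:
    """Fit the 6-unknown tensor dark-field variant (needs K >= 6)."""
    return LcsModel(pairs, tensor=True, regularization=regularization,
                    window=window).fit()


def hsv_encode(a: np.ndarray, b: np.ndarray, psi: np.ndarray) -> np.ndarray:
    """HSV encoding of a tensor field with semi-axes a >= b, orientation psi.

    hue = major-axis angle (mod pi), saturation = principal-axis length a,
    value = tensor norm sqrt(a^2 + b^2); saturation and value are scaled by
    their robust (99.5 %) maxima for display.
    """
    hue = np.mod(psi, math.pi) / math.pi
    norm = np.sqrt(a**2 + b**2)
    smax = np.percentile(a, 99.5)
    vmax = np.percentile(norm, 99.5)
    sat = np.clip(a / max(smax, 1e-12), 0.0, 1.0)
    val = np.clip(norm / max(vmax, 1e-12), 0.0, 1.0)
    return np.stack([hue, sat, val], axis=-1)
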