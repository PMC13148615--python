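"""Phantoms and cone-beam image-pair simulation.

This module is the stand-in for the measured data of a Xeuss-like
modulation-based imaging (MoBI) setup: it builds projected-thickness maps of
parametric nylon phantoms, turns them (and membrane masks) into transmission
and phase screens, and simulates series of reference/sample detector image
pairs ``(I_r, I_s)`` with random membrane shifts and Poisson counting noise.

Two forward models are available:

``warp``
    The default geometric model.  The reference pattern is resampled by the
    sample's refraction displacement field ``D = z2 * alpha / pixel`` (the
    detector-plane pattern shift, in pixels), multiplied by the sample
    transmission, and optionally diffused by a local (possibly anisotropic)
    dark-field kernel declared by the phantom.  This is the generative
    counterpart of the LCS retrieval and serves as its parameter-recovery
    oracle.

``fresnel``
    Free-space Fresnel propagation of the masked and sample-modulated
    wavefront over the cone-beam effective distance ``z_eff = z2/M_sample``
    in the demagnified (detector-conjugate) frame, followed by source-blur
    convolution.  Both screens are collapsed onto a single effective plane;
    the 0.22 m membrane-to-sample gap is not propagated separately, which is
    adequate at the negligible Fresnel numbers of this geometry.

All simulation grids are detector-conjugate: one detector pixel corresponds
to ``oversample`` raster cells at each plane, with each plane's physical
pitch set by its magnification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .constants import optical_constants, wavelength_m
from .mask_patterns import MaskModel

__all__ = [
    "AcquisitionGeometry",
    "XEUSS",
    "ThicknessMap",
    "DarkfieldComponent",
    "ImagePairSet",
    "phantom_thickness",
    "refraction_displacement",
    "screen_from_thickness",
    "forward_image",
    "acquire_series",
    "PHANTOM_KINDS",
]

PHANTOM_KINDS = ("wire", "sphere", "cube", "torus", "shepp_logan", "julia")


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Cone-beam geometry and exposure of the MoBI bench.

    Distances in metres, pixel size and source spot in micrometres, energy
    in keV, mean counts in photons/pixel.  Defaults are the Xeuss-like
    bench: membrane at 0.33 m, sample at 0.55 m, detector 0.80 m behind the
    sample (1.35 m from the source), 75 um pixels, 8.6 keV, 50 um spot,
    75000 counts/pixel.
    """

    d_source_membrane: float = 0.33
    d_source_sample: float = 0.55
    d_sample_detector: float = 0.80  # z2
    pixel_size: float = 75.0
    detector_shape: tuple[int, int] = (514, 1030)
    energy: float = 8.6
    source_fwhm: float = 50.0
    mean_counts: float = 75000.0

    def __post_init__(self) -> None:
        if not (0 < self.d_source_membrane < self.d_source_sample):
            raise ValueError("need 0 < d_source_membrane < d_source_sample")
        if self.d_sample_detector <= 0:
            raise ValueError("z2 must be positive")
        if self.pixel_size <= 0 or self.energy <= 0 or self.mean_counts <= 0:
            raise ValueError("pixel_size, energy and mean_counts must be positive")

    # -- derived quantities -------------------------------------------------
    @property
    def d_source_detector(self) -> float:
        return self.d_source_sample + self.d_sample_detector

    def magnification(self, d_source_plane: float) -> float:
        """Geometric magnification of a plane at ``d_source_plane`` metres."""
        return self.d_source_detector / d_source_plane

    @property
    def m_sample(self) -> float:
        return self.magnification(self.d_source_sample)

    @property
    def m_membrane(self) -> float:
        return self.magnification(self.d_source_membrane)

    @property
    def z_eff(self) -> float:
        """Defocus-equivalent propagation distance z2 / M_sample (m)."""
        return self.d_sample_detector / self.m_sample

    @property
    def wavelength(self) -> float:
        return wavelength_m(self.energy)

    def sample_pitch(self, oversample: int = 1) -> float:
        """Sample-plane um per raster cell of a detector-conjugate grid."""
        return self.pixel_size / self.m_sample / oversample

    def source_sigma_px(self, d_source_plane: float) -> float:
        """Detector-plane penumbra sigma (pixels) for a screen at that plane."""
        m = self.magnification(d_source_plane)
        return self.source_fwhm * (m - 1.0) / 2.3548200450309493 / self.pixel_size

    def to_dict(self) -> dict:
        return {
            "d_source_membrane": self.d_source_membrane,
            "d_source_sample": self.d_source_sample,
            "d_sample_detector": self.d_sample_detector,
            "pixel_size": self.pixel_size,
            "detector_shape": list(self.detector_shape),
            "energy": self.energy,
            "source_fwhm": self.source_fwhm,
            "mean_counts": self.mean_counts,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionGeometry":
        d = dict(d)
        d["detector_shape"] = tuple(d["detector_shape"])
        return cls(**d)


#: The Table-1 bench.
XEUSS = AcquisitionGeometry()


@dataclass
class DarkfieldComponent:
    """Local small-angle-scattering kernel declared by a phantom.

    The component diffuses the reference pattern inside ``region`` with an
    oriented Gaussian of std ``sigma_par`` along ``theta`` and ``sigma_perp``
    across it (both in detector pixels).  ``region=None`` means the phantom
    support.
    """

    sigma_par: float
    sigma_perp: float
    theta: float = 0.0
    region: Optional[np.ndarray] = None


@dataclass
class ThicknessMap:
    """Projected material thickness along the beam, in mm.

    ``pitch`` is the sample-plane grid pitch in um per cell.
    """

    thickness: np.ndarray
    material: str = "nylon"
    pitch: float = 30.5
    darkfield: list[DarkfieldComponent] = field(default_factory=list)

    def __post_init__(self) -> None:
        t = np.asarray(self.thickness, dtype=np.float32)
        if not np.all(np.isfinite(t)) or np.any(t < 0):
            raise ValueError("thickness must be finite and non-negative")
        self.thickness = t

    @property
    def shape(self) -> tuple[int, int]:
        return self.thickness.shape

    @property
    def support(self) -> np.ndarray:
        return self.thickness > 1e-6


# ---------------------------------------------------------------------------
# phantoms
# ---------------------------------------------------------------------------

def _grid_mm(grid_shape: tuple[int, int], pitch: float):
    h, w = grid_shape
    y = (np.arange(h) + 0.5 - h / 2.0) * pitch * 1e-3
    x = (np.arange(w) + 0.5 - w / 2.0) * pitch * 1e-3
    return y[:, None], x[None, :]


def _shepp_logan(h_px: int, w_px: int) -> np.ndarray:
    from skimage.data import shepp_logan_phantom
    from skimage.transform import resize

    img = shepp_logan_phantom().T  # landscape: long axis along x
    return resize(img, (h_px, w_px), order=1, anti_aliasing=True)


def _julia(h_px: int, w_px: int, c: complex, n_iter: int) -> np.ndarray:
    # smooth escape-time map; normalized to [0, 1] with max exactly 1
    half_w = 1.55
    half_h = half_w * h_px / w_px
    y, x = np.meshgrid(
        np.linspace(-half_h, half_h, h_px), np.linspace(-half_w, half_w, w_px),
        indexing="ij",
    )
    z = x + 1j * y
    n = np.full(z.shape, float(n_iter))
    alive = np.ones(z.shape, dtype=bool)
    for i in range(n_iter):
        z[alive] = z[alive] ** 2 + c
        escaped = alive & (np.abs(z) > 2.0)
        if escaped.any():
            az = np.abs(z[escaped])
            n[escaped] = i + 1.0 - np.log2(np.log(az))
        alive &= ~escaped
    n = np.clip(n, 0.0, n_iter)
    return n / n.max()


def phantom_thickness(
    kind: str,
    grid_shape: tuple[int, int],
    pitch: float,
    scale: float = 1.0,
    **dims,
) -> ThicknessMap:
    """Projected thickness map of a parametric nylon phantom.

    Supported kinds and their default dimensions (mm):

    - ``wire``: cylinder along x, diameter 1.5
    - ``sphere``: diameter 12
    - ``cube``: side 7
    - ``torus``: outer diameter 13, inner diameter 3, max thickness 3
      (elliptical tube cross-section, as implied by the three figures)
    - ``shepp_logan``: 18 x 13 field, thickness mapped linearly to 1..5
    - ``julia``: escape-time fractal over an 18 x 10 window, max thickness 5

    ``scale`` shrinks the lateral footprint (and, for solids of revolution,
    the thickness) to fit reduced desk-scale fields; thickness ranges of the
    Shepp-Logan and fractal phantoms are kept at their physical values.
    """
    y, x = _grid_mm(grid_shape, pitch)
    if kind == "wire":
        d = dims.pop("diameter", 1.5) * scale
        r = d / 2.0
        t = 2.0 * np.sqrt(np.clip(r**2 - y**2, 0.0, None)) * np.ones_like(x)
    elif kind == "sphere":
        d = dims.pop("diameter", 12.0) * scale
        r = d / 2.0
        rho2 = x**2 + y**2
        t = 2.0 * np.sqrt(np.clip(r**2 - rho2, 0.0, None))
    elif kind == "cube":
        side = dims.pop("side", 7.0) * scale
        t = np.where((np.abs(x) <= side / 2) & (np.abs(y) <= side / 2), side, 0.0)
    elif kind == "torus":
        outer = dims.pop("outer_diameter", 13.0) * scale
        inner = dims.pop("inner_diameter", 3.0) * scale
        tmax = dims.pop("max_thickness", 3.0) * scale
        a = (outer - inner) / 4.0          # tube half-width, in-plane
        rc = (outer + inner) / 4.0         # center-line radius
        b = tmax / 2.0                     # tube half-height, along beam
        rho = np.sqrt(x**2 + y**2)
        u = (rho - rc) / a
        t = 2.0 * b * np.sqrt(np.clip(1.0 - u**2, 0.0, None))
    elif kind == "shepp_logan":
        width = dims.pop("width", 18.0) * scale
        height = dims.pop("height", 13.0) * scale
        tmin = dims.pop("t_min", 1.0)
        tmax = dims.pop("t_max", 5.0)
        h_px = max(2, int(round(height / (pitch * 1e-3))))
        w_px = max(2, int(round(width / (pitch * 1e-3))))
        img = _shepp_logan(h_px, w_px)
        support = img > 0.02
        t_small = np.zeros_like(img)
        if support.any():
            v = img[support]
            lo, hi = v.min(), v.max()
            t_small[support] = tmin + (tmax - tmin) * (v - lo) / max(hi - lo, 1e-12)
        t = _embed(t_small, grid_shape)
    elif kind == "julia":
        width = dims.pop("width", 18.0) * scale
        height = dims.pop("height", 10.0) * scale
        tmax = dims.pop("max_thickness", 5.0)
        c = dims.pop("c", -0.4 + 0.6j)
        n_iter = dims.pop("n_iter", 80)
        h_px = max(2, int(round(height / (pitch * 1e-3))))
        w_px = max(2, int(round(width / (pitch * 1e-3))))
        frac = _julia(h_px, w_px, c, n_iter)
        # drop the smooth far field so the phantom has compact support
        frac = np.clip(frac - 0.15, 0.0, None) / 0.85
        t = _embed(tmax * frac, grid_shape)
    else:
        raise ValueError(f"unknown phantom kind {kind!r}; known: {PHANTOM_KINDS}")
    if dims:
        raise TypeError(f"unknown dimensions for {kind!r}: {sorted(dims)}")
    return ThicknessMap(thickness=t.astype(np.float32), pitch=pitch)


def _embed(small: np.ndarray, grid_shape: tuple[int, int]) -> np.ndarray:
    """Center ``small`` in a zero field of ``grid_shape`` (crop if larger)."""
    h, w = grid_shape
    sh, sw = small.shape
    if sh > h:
        o = (sh - h) // 2
        small = small[o:o + h]
        sh = h
    if sw > w:
        o = (sw - w) // 2
        small = small[:, o:o + w]
        sw = w
    out = np.zeros((h, w), dtype=small.dtype)
    oy, ox = (h - sh) // 2, (w - sw) // 2
    out[oy:oy + sh, ox:ox + sw] = small
    return out


# ---------------------------------------------------------------------------
# optics
# ---------------------------------------------------------------------------

def refraction_displacement(
    sample: ThicknessMap, geometry: AcquisitionGeometry
) -> tuple[np.ndarray, np.ndarray]:
    """Ideal detector-plane pattern displacement (D0_x, D0_y), in pixels.

    A ray crossing projected thickness ``t`` is deflected by
    ``alpha = -delta * grad(t)`` (toward thinner material) and lands
    ``z2 * alpha`` away from its unperturbed position, i.e.
    ``D0 = z2 * alpha / pixel_size`` detector pixels, with the gradient taken
    in physical sample-plane coordinates.
    """
    oc = optical_constants(sample.material, geometry.energy)
    t_um = sample.thickness.astype(np.float64) * 1e3
    gy, gx = np.gradient(t_um, sample.pitch)  # dimensionless slope
    scale = -geometry.d_sample_detector * 1e6 * oc.delta / geometry.pixel_size
    return scale * gx, scale * gy


def screen_from_thickness(
    obj: "ThicknessMap | MaskModel",
    energy: float,
    absorption: bool = True,
) -> np.ndarray:
    """Complex transmission screen under the projection approximation.

    amplitude = exp(-mu t / 2), phase = -(2 pi / lambda) * delta * t.
    ``absorption=False`` yields a phase-only screen (useful for checking
    energy conservation of the wave-optical model).
    """
    if isinstance(obj, MaskModel):
        t_um = obj.thickness.astype(np.float64)
        material = obj.material
    else:
        t_um = obj.thickness.astype(np.float64) * 1e3
        material = obj.material
    oc = optical_constants(material, energy)
    lam_um = wavelength_m(energy) * 1e6
    phase = -(2.0 * math.pi / lam_um) * oc.delta * t_um
    amp = np.exp(-oc.mu * t_um / 2.0) if absorption else np.ones_like(t_um)
    return amp * np.exp(1j * phase)


# ---------------------------------------------------------------------------
# image pair container
# ---------------------------------------------------------------------------

@dataclass
class ImagePairSet:
    """K aligned reference/sample detector images plus the shifts applied.

    ``shifts[k] = (dx, dy)`` is the membrane displacement of pair ``k`` in
    detector pixels.
    """

    I_r: np.ndarray
    I_s: np.ndarray
    shifts: np.ndarray
    geometry: AcquisitionGeometry
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.I_r = np.asarray(self.I_r, dtype=np.float32)
        self.I_s = np.asarray(self.I_s, dtype=np.float32)
        self.shifts = np.asarray(self.shifts)
        if self.I_r.ndim != 3 or self.I_r.shape != self.I_s.shape:
            raise ValueError("I_r and I_s must be (K, H, W) with equal shapes")
        if self.K < 1 or self.shifts.shape != (self.K, 2):
            raise ValueError("shifts must be (K, 2) with K >= 1")

    @property
    def K(self) -> int:
        return self.I_r.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.I_r.shape[1:]

    def to_hdf5(self, path: str | Path) -> None:
        import h5py, json

        with h5py.File(path, "w") as f:
            f.create_dataset("I_r", data=self.I_r, compression="gzip")
            f.create_dataset("I_s", data=self.I_s, compression="gzip")
            f.create_dataset("shifts", data=self.shifts)
            f.attrs["geometry"] = json.dumps(self.geometry.to_dict())
            if self.seed is not None:
                f.attrs["seed"] = self.seed

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "ImagePairSet":
        import h5py, json

        with h5py.File(path, "r") as f:
            return cls(
                I_r=f["I_r"][...],
                I_s=f["I_s"][...],
                shifts=f["shifts"][...],
                geometry=AcquisitionGeometry.from_dict(json.loads(f.attrs["geometry"])),
                seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
            )

    def to_tiff_dir(self, path: str | Path) -> None:
        import tifffile, json

        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for k in range(self.K):
            tifffile.imwrite(path / f"ref_{k:03d}.tif", self.I_r[k])
            tifffile.imwrite(path / f"sample_{k:03d}.tif", self.I_s[k])
        manifest = {
            "K": self.K,
            "shifts": self.shifts.tolist(),
            "geometry": self.geometry.to_dict(),
            "seed": self.seed,
        }
        (path / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def from_tiff_dir(cls, path: str | Path) -> "ImagePairSet":
        import tifffile, json

        path = Path(path)
        manifest = json.loads((path / "manifest.json").read_text())
        K = manifest["K"]
        I_r = np.stack([tifffile.imread(path / f"ref_{k:03d}.tif") for k in range(K)])
        I_s = np.stack([tifffile.imread(path / f"sample_{k:03d}.tif") for k in range(K)])
        return cls(
            I_r=I_r, I_s=I_s, shifts=np.asarray(manifest["shifts"]),
            geometry=AcquisitionGeometry.from_dict(manifest["geometry"]),
            seed=manifest.get("seed"),
        )


# ---------------------------------------------------------------------------
# forward simulation
# ---------------------------------------------------------------------------

def _block_mean(a: np.ndarray, os: int) -> np.ndarray:
    if os == 1:
        return a
    h, w = a.shape
    return a.reshape(h // os, os, w // os, os).mean(axis=(1, 3))


def _oriented_gaussian_kernel(sig_par: float, sig_perp: float, theta: float,
                              os: int) -> np.ndarray:
    """Oriented Gaussian kernel on the oversampled grid (sigmas in det px)."""
    sp, sq = max(sig_par, 1e-3) * os, max(sig_perp, 1e-3) * os
    m = int(math.ceil(3.0 * max(sp, sq))) + 1
    ax = np.arange(-m, m + 1, dtype=float)
    yy, xx = np.meshgrid(ax, ax, indexing="ij")
    u = xx * math.cos(theta) + yy * math.sin(theta)
    v = -xx * math.sin(theta) + yy * math.cos(theta)
    k = np.exp(-0.5 * ((u / sp) ** 2 + (v / sq) ** 2))
    return k / k.sum()


class _Scene:
    """Precomputed state for simulating one mask/sample/geometry combination."""

    def __init__(
        self,
        mask: Optional[MaskModel],
        sample: Optional[ThicknessMap],
        geometry: AcquisitionGeometry,
        field_shape: Optional[tuple[int, int]] = None,
        model: str = "warp",
        source_blur: bool = True,
        oversample: int = 2,
    ):
        if model not in ("warp", "fresnel"):
            raise ValueError("model must be 'warp' or 'fresnel'")
        self.model = model
        self.geometry = geometry
        if mask is None:
            os_ = oversample
            if field_shape is None:
                field_shape = geometry.detector_shape
            self.os = os_
            self.H, self.W = field_shape
            self.margin = 0
            shape = (os_ * self.H, os_ * self.W)
            self.pattern_full = (np.ones(shape)
                                 if model == "warp"
                                 else np.ones(shape, dtype=np.complex128))
        else:
            os_ = int(mask.meta.get("oversample", 0))
            if not os_:
                raise ValueError(
                    "mask raster is not detector-conjugate; build it with "
                    "make_design_mask (meta['oversample'] missing)"
                )
            self.os = os_
            if field_shape is None:
                field_shape = tuple(
                    mask.meta.get("field_shape", geometry.detector_shape))
            self.H, self.W = field_shape
            self.margin = int(mask.meta.get("margin_px", 0))
            need = (os_ * (self.H + 2 * self.margin),
                    os_ * (self.W + 2 * self.margin))
            if mask.thickness.shape != need:
                raise ValueError(
                    f"mask raster {mask.thickness.shape} does not cover field "
                    f"{field_shape} with margin {self.margin} at oversample {os_}"
                )
            # aliasing guard: smallest modulation must span >= 4 raster cells
            spacing = mask.meta.get("spacing_px")
            if spacing is not None and spacing * os_ < 2.0:
                raise ValueError(
                    f"raster too coarse for modulation spacing {spacing} px "
                    f"at oversample {os_}"
                )
            if model == "warp":
                self.pattern_full = self._mask_pattern(mask, geometry)
            else:
                self.pattern_full = screen_from_thickness(mask, geometry.energy)
        self.mask = mask
        self.blur_sigma_cells = (
            geometry.source_sigma_px(geometry.d_source_membrane) * self.os
            if source_blur else 0.0
        )
        self.sample_blur_cells = (
            geometry.source_sigma_px(geometry.d_source_sample) * os_
            if source_blur else 0.0
        )
        # sample fields on the oversampled detector-conjugate grid
        self.sample = sample
        if sample is not None:
            want_pitch = geometry.sample_pitch(os_)
            t = sample
            if abs(sample.pitch - want_pitch) > 1e-6 * want_pitch:
                zoom = sample.pitch / want_pitch
                thick = ndimage.zoom(sample.thickness, zoom, order=1)
                t = replace(sample, thickness=np.clip(thick, 0, None), pitch=want_pitch)
            t = replace(t, thickness=_embed(t.thickness, (os_ * self.H, os_ * self.W)))
            self.sample_os = t
            oc = optical_constants(t.material, geometry.energy)
            self.T_s = np.exp(-oc.mu * t.thickness.astype(np.float64) * 1e3)
            d0x, d0y = refraction_displacement(t, geometry)
            self.d0x_cells = os_ * d0x
            self.d0y_cells = os_ * d0y
            div_s = (np.gradient(self.d0y_cells, axis=0)
                     + np.gradient(self.d0x_cells, axis=1))
            # first-order ray-crowding (propagation) contrast of the sample
            self.sample_jacobian = 1.0 / np.clip(1.0 + div_s, 0.2, 5.0)
            if model == "fresnel":
                self.sample_screen = screen_from_thickness(t, geometry.energy)
            self.df_components = []
            for comp in (sample.darkfield or []):
                region = comp.region
                if region is None:
                    region = self.sample_os.support
                else:
                    region = np.asarray(region, bool)
                    if region.shape != (os_ * self.H, os_ * self.W):
                        region = ndimage.zoom(
                            region.astype(np.float32),
                            (os_ * self.H / region.shape[0],
                             os_ * self.W / region.shape[1]),
                            order=0,
                        ) > 0.5
                kern = _oriented_gaussian_kernel(
                    comp.sigma_par, comp.sigma_perp, comp.theta, os_
                )
                self.df_components.append((region, kern))
        else:
            self.sample_os = None

    def _mask_pattern(self, mask: MaskModel, geometry: AcquisitionGeometry
                      ) -> np.ndarray:
        """Geometric-optics reference pattern of the membrane.

        Rays crossing the membrane are attenuated (Beer-Lambert) and
        deflected by ``alpha = -delta * grad t``; over the membrane-detector
        distance the deflection both displaces the pattern and locally
        crowds or dilutes the rays (first-order intensity-transport
        Jacobian), which is what turns a weak phase relief into visible
        bright/dark rims.  Valid at the large Fresnel numbers (>> 1) of
        this bench, where diffraction is negligible against ray optics.
        """
        from .constants import optical_constants

        oc = optical_constants(mask.material, geometry.energy)
        t = mask.thickness.astype(np.float64)
        trans = np.exp(-oc.mu * t)
        d_md = (geometry.d_source_detector - geometry.d_source_membrane) * 1e6
        # displacement in raster cells at the membrane-conjugate grid
        scale = -d_md * oc.delta / (mask.grid_pitch * geometry.m_membrane)
        gy, gx = np.gradient(t, mask.grid_pitch)
        dy_c, dx_c = scale * gy, scale * gx
        yy = np.arange(t.shape[0], dtype=np.float64)[:, None] - dy_c
        xx = np.arange(t.shape[1], dtype=np.float64)[None, :] - dx_c
        pattern = ndimage.map_coordinates(trans, [yy, xx], order=1,
                                          mode="nearest")
        div = np.gradient(dy_c, axis=0) + np.gradient(dx_c, axis=1)
        jac = 1.0 / np.clip(1.0 + div, 0.2, 5.0)
        return pattern * jac

    # -- pattern at the detector-conjugate oversampled grid -----------------
    def _window(self, shift: tuple[int, int]) -> np.ndarray:
        dx, dy = int(shift[0]), int(shift[1])
        if max(abs(dx), abs(dy)) > self.margin:
            raise ValueError(
                f"shift {shift} exceeds the mask margin of {self.margin} px; "
                "generate the mask with a larger margin"
            )
        os_ = self.os
        oy = os_ * (self.margin + dy)
        ox = os_ * (self.margin + dx)
        return self.pattern_full[oy:oy + os_ * self.H, ox:ox + os_ * self.W]

    def reference(self, shift: tuple[int, int]) -> np.ndarray:
        """Noise-free reference intensity (counts) for a membrane shift."""
        g = self.geometry
        if self.model == "warp":
            p = self._window(shift)
            if self.blur_sigma_cells > 0:
                p = ndimage.gaussian_filter(p, self.blur_sigma_cells, mode="nearest")
            return g.mean_counts * _block_mean(p, self.os)
        return self._fresnel_intensity(self._window(shift), with_sample=False)

    def sample_image(self, shift: tuple[int, int]) -> np.ndarray:
        """Noise-free sample intensity (counts) for a membrane shift."""
        g = self.geometry
        if self.sample_os is None:
            return self.reference(shift)
        if self.model == "fresnel":
            return self._fresnel_intensity(self._window(shift), with_sample=True)
        p = self._window(shift)
        if self.blur_sigma_cells > 0:
            p = ndimage.gaussian_filter(p, self.blur_sigma_cells, mode="nearest")
        os_ = self.os
        if getattr(self, "_warp_coords", None) is None:
            yy, xx = np.meshgrid(
                np.arange(os_ * self.H, dtype=np.float64),
                np.arange(os_ * self.W, dtype=np.float64),
                indexing="ij",
            )
            self._warp_coords = [yy - self.d0y_cells, xx - self.d0x_cells]
        pw = ndimage.map_coordinates(
            p, self._warp_coords, order=1, mode="nearest"
        ) * self.sample_jacobian
        for region, kern in self.df_components:
            from scipy.signal import fftconvolve

            pb = fftconvolve(pw, kern, mode="same")
            pw = np.where(region, pb, pw)
        return g.mean_counts * _block_mean(self.T_s * pw, self.os)

    def _fresnel_intensity(self, mask_screen: np.ndarray, with_sample: bool) -> np.ndarray:
        from scipy import fft as sfft

        g = self.geometry
        u = mask_screen.astype(np.complex64)
        if with_sample:
            u = u * self.sample_screen.astype(np.complex64)
        if getattr(self, "_tf", None) is None or self._tf.shape != u.shape:
            cell_m = g.sample_pitch(self.os) * 1e-6
            fy = np.fft.fftfreq(u.shape[0], d=cell_m)
            fx = np.fft.fftfreq(u.shape[1], d=cell_m)
            self._tf = np.exp(
                -1j * math.pi * g.wavelength * g.z_eff
                * (fy[:, None] ** 2 + fx[None, :] ** 2)
            ).astype(np.complex64)
        out = sfft.ifft2(sfft.fft2(u) * self._tf)
        inten = (out.real**2 + out.imag**2).astype(np.float64)
        if self.blur_sigma_cells > 0:
            inten = ndimage.gaussian_filter(
                inten, self.sample_blur_cells or self.blur_sigma_cells, mode="nearest"
            )
        return g.mean_counts * _block_mean(inten, self.os)


def forward_image(
    mask: MaskModel,
    sample: Optional[ThicknessMap],
    geometry: AcquisitionGeometry,
    model: str = "warp",
    shift: tuple[int, int] = (0, 0),
    seed: Optional[int] = None,
    noise: bool = True,
    source_blur: bool = True,
    field_shape: Optional[tuple[int, int]] = None,
    kind: str = "sample",
) -> np.ndarray:
    """Simulate a single detector image (counts).

    ``kind`` selects the reference ('reference') or sample ('sample') arm.
    For series use :func:`acquire_series`, which amortizes scene setup.
    """
    scene = _Scene(mask, sample, geometry, field_shape, model, source_blur)
    img = scene.sample_image(shift) if kind == "sample" else scene.reference(shift)
    if noise:
        rng = np.random.default_rng(seed)
        img = rng.poisson(np.clip(img, 0, None)).astype(np.float64)
    return img


def draw_shifts(
    K: int,
    shift_axes: str,
    shift_range: tuple[int, int],
    rng: np.random.Generator,
) -> np.ndarray:
    """K membrane shifts: per active axis a random sign and a magnitude
    drawn uniformly in ``shift_range`` (detector pixels)."""
    if shift_axes not in ("x", "xy"):
        raise ValueError("shift_axes must be 'x' or 'xy'")
    lo, hi = shift_range
    shifts = np.zeros((K, 2), dtype=int)
    for k in range(K):
        for ax in range(2 if shift_axes == "xy" else 1):
            mag = int(rng.integers(lo, hi + 1))
            sign = 1 if rng.random() < 0.5 else -1
            shifts[k, ax] = sign * mag
    return shifts


def acquire_series(
    mask: MaskModel,
    sample: Optional[ThicknessMap],
    geometry: AcquisitionGeometry,
    K: int = 10,
    shift_axes: str = "x",
    shift_range: tuple[int, int] = (50, 150),
    seed: int = 0,
    model: str = "warp",
    noise: bool = True,
    source_blur: bool = True,
    field_shape: Optional[tuple[int, int]] = None,
) -> ImagePairSet:
    """Simulate K reference/sample pairs with random membrane shifts.

    One independent shift is drawn per pair ([50, 150] px by default, random
    sign, along x or along both axes); reference and sample noise
    realizations are independent, split from ``seed`` with a counter-based
    scheme so the series is reproducible bit-for-bit.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    ss = np.random.SeedSequence(seed)
    shift_rng = np.random.default_rng(ss.spawn(1)[0])
    shifts = draw_shifts(K, shift_axes, shift_range, shift_rng)
    scene = _Scene(mask, sample, geometry, field_shape, model, source_blur)
    I_r = np.empty((K, scene.H, scene.W), dtype=np.float32)
    I_s = np.empty_like(I_r)
    child = np.random.SeedSequence(seed).spawn(2 * K + 1)[1:]
    for k in range(K):
        ref = scene.reference(tuple(shifts[k]))
        sam = scene.sample_image(tuple(shifts[k]))
        if noise:
            rng_r = np.random.default_rng(child[2 * k])
            rng_s = np.random.default_rng(child[2 * k + 1])
            ref = rng_r.poisson(np.clip(ref, 0, None))
            sam = rng_s.poisson(np.clip(sam, 0, None))
        I_r[k] = ref
        I_s[k] = sam
    return ImagePairSet(I_r=I_r, I_s=I_s, shifts=shifts, geometry=geometry, seed=seed)
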