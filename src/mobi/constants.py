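"""Physical constants and the versioned optical-constants table.

The X-ray optical properties (refractive-index decrement ``delta`` and linear
attenuation coefficient ``mu``) are shipped as a small static table evaluated
at the working energy of the Xeuss-like setup (8.6 keV, Cu anode mean energy).
Values were derived from the standard Henke atomic scattering factor / NIST
XCOM tabulations for the bulk densities quoted below; they are not fetched at
runtime.  For other energies a smooth far-from-edge scaling
(delta ~ E^-2, mu ~ E^-3) is applied, which is adequate for the light
materials; nickel sits just above its K edge (8.333 keV) where that scaling is
invalid, so scaling away from 8.6 keV is refused for it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: Golden angle (radians): 2*pi*(1 - 1/phi), the Vogel-spiral divergence angle.
GOLDEN_ANGLE = 2.0 * math.pi * (1.0 - 2.0 / (1.0 + math.sqrt(5.0)))

#: Energy (keV) at which the table below is tabulated.
REFERENCE_ENERGY_KEV = 8.6

#: h*c in eV*m, for wavelength conversion.
HC_EV_M = 1.239841984e-6

TABLE_VERSION = "2026-09-1"


@dataclass(frozen=True)
class OpticalConstants:
    """delta (refractive-index decrement) and mu (1/um) at 8.6 keV."""

    delta: float
    mu: float          # linear attenuation, 1/um
    density: float     # g/cm^3, provenance only
    near_edge: bool = False


# delta computed as r_e * lambda^2 * n_e / (2 pi); mu from mass-attenuation
# coefficients at 8.6 keV times the quoted density.
MATERIALS: dict[str, OpticalConstants] = {
    # polyamide-6 (nylon), C6H11NO, rho = 1.14
    "nylon": OpticalConstants(delta=3.51e-6, mu=4.0e-4, density=1.14),
    # fused silica, rho = 2.20
    "sio2": OpticalConstants(delta=6.17e-6, mu=6.4e-3, density=2.20),
    # nickel, rho = 8.908; 8.6 keV is just above the Ni K edge
    "ni": OpticalConstants(delta=2.38e-5, mu=0.25, density=8.908, near_edge=True),
}


def wavelength_m(energy_kev: float) -> float:
    """Photon wavelength in metres."""
    if energy_kev <= 0:
        raise ValueError("energy must be positive")
    return HC_EV_M / (energy_kev * 1e3)


def optical_constants(material: str, energy_kev: float = REFERENCE_ENERGY_KEV) -> OpticalConstants:
    """Look up (delta, mu) for ``material`` at ``energy_kev``.

    Far-from-edge power-law scaling is applied away from the tabulated
    8.6 keV point; refused for near-edge materials (Ni).
    """
    try:
        base = MATERIALS[material]
    except KeyError:
        raise KeyError(
            f"no optical constants for material {material!r}; "
            f"known: {sorted(MATERIALS)}"
        ) from None
    if abs(energy_kev - REFERENCE_ENERGY_KEV) < 1e-9:
        return base
    if base.near_edge:
        raise ValueError(
            f"{material!r} is tabulated near an absorption edge; "
            "cannot scale away from 8.6 keV"
        )
    s = REFERENCE_ENERGY_KEV / energy_kev
    return OpticalConstants(
        delta=base.delta * s**2, mu=base.mu * s**3, density=base.density
    )
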