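"""Coherent SHG and incoherent TPEF signal formation at a single focus.

SHG is generated by the squared focal field and summed coherently in the
far field: for emission direction ``s`` (unit vector),

    A(s) = sum_n chi_n * E(r_n; focus)^2 * exp(-i k2 s . (r_n - focus))

with ``k2 = 2 k n`` the second-harmonic wavenumber in a dispersionless
medium.  The squared drive field carries twice the Gouy phase, which is the
mechanism that can restore constructive interference between emitters of
opposite filament polarity placed before and after the focus.  The detected
SHG intensity integrates ``|A|^2`` over the condenser collection cone with a
Gauss-Legendre x uniform-azimuth product quadrature.

TPEF is incoherent: ``I = sum_n f_n |E(r_n; focus)|^4`` (two-photon excited
fluorescence with uniform emission collection).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .beam import BeamParameters, focal_field

__all__ = [
    "CollectionCone",
    "cone_quadrature",
    "shg_far_field",
    "shg_intensity",
    "tpef_intensity",
]


@dataclass(frozen=True)
class CollectionCone:
    """Forward collection cone of the SHG (transmitted-light) detector.

    ``na`` is the condenser numerical aperture; the half-angle in the medium
    is ``arcsin(na / n)``.  ``n_theta``/``n_phi`` set the product quadrature
    resolution (Gauss-Legendre in cos(theta), uniform in phi).
    """

    na: float
    n_theta: int = 16
    n_phi: int = 32
    direction: tuple = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if self.n_theta < 4 or self.n_phi < 8:
            raise ValueError(
                f"cone quadrature too coarse: need n_theta >= 4 and "
                f"n_phi >= 8, got ({self.n_theta}, {self.n_phi})"
            )

    def half_angle(self, refractive_index: float) -> float:
        s = self.na / refractive_index
        if not (0.0 < s < 1.0):
            raise ValueError(
                f"collection NA {self.na} invalid for medium index "
                f"{refractive_index}"
            )
        return float(np.arcsin(s))


def _orthonormal_frame(direction: np.ndarray):
    """Two unit vectors completing ``direction`` to a right-handed frame."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(d @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    return d, e1, e2


def cone_quadrature(cone: CollectionCone, refractive_index: float):
    """Quadrature nodes and weights for integrating over the cone.

    Returns ``(directions, weights)`` with directions of shape (M, 3) and
    weights summing to the cone solid angle ``2 pi (1 - cos(theta_max))``.
    """
    theta_max = cone.half_angle(refractive_index)
    # Gauss-Legendre in mu = cos(theta) over [cos(theta_max), 1]
    mu_nodes, mu_weights = np.polynomial.legendre.leggauss(cone.n_theta)
    lo = np.cos(theta_max)
    mu = 0.5 * (mu_nodes + 1.0) * (1.0 - lo) + lo
    w_mu = mu_weights * 0.5 * (1.0 - lo)

    phi = 2.0 * np.pi * (np.arange(cone.n_phi) + 0.5) / cone.n_phi
    w_phi = 2.0 * np.pi / cone.n_phi

    d, e1, e2 = _orthonormal_frame(np.asarray(cone.direction, dtype=float))
    sin_t = np.sqrt(np.clip(1.0 - mu**2, 0.0, None))

    # outer products: (n_theta, n_phi)
    dirs = (
        mu[:, None, None] * d[None, None, :]
        + (sin_t[:, None] * np.cos(phi)[None, :])[:, :, None] * e1[None, None, :]
        + (sin_t[:, None] * np.sin(phi)[None, :])[:, :, None] * e2[None, None, :]
    )
    weights = np.broadcast_to((w_mu * w_phi)[:, None], (cone.n_theta, cone.n_phi))
    return dirs.reshape(-1, 3), weights.reshape(-1).copy()


def _drive_amplitudes(scatterers, focus_um, beam, include_gouy=True):
    """chi_n * E(r_n)^2 for every scatterer (the coherent source strengths)."""
    e = focal_field(scatterers.positions_um, focus_um, beam, include_gouy=include_gouy)
    return scatterers.chi_signed * e * e


def shg_far_field(
    scatterers,
    focus_um,
    beam: BeamParameters,
    direction_unit,
    include_gouy: bool = True,
):
    """Coherent far-field SHG amplitude in one or many emission directions.

    ``direction_unit`` may be a single unit 3-vector or an (M, 3) array.
    An empty scatterer set yields zero amplitude.
    """
    dirs = np.asarray(direction_unit, dtype=float)
    scalar_input = dirs.ndim == 1
    dirs = np.atleast_2d(dirs)
    if len(scatterers) == 0:
        out = np.zeros(len(dirs), dtype=complex)
        return out[0] if scalar_input else out

    k2 = 2.0 * beam.wavenumber_medium
    c = _drive_amplitudes(scatterers, focus_um, beam, include_gouy=include_gouy)
    rel = scatterers.positions_um - np.asarray(focus_um, dtype=float)
    phase = -1j * k2 * (dirs @ rel.T)  # (M, N)
    amp = np.exp(phase) @ c
    return amp[0] if scalar_input else amp


def shg_intensity(
    scatterers,
    focus_um,
    beam: BeamParameters,
    cone: CollectionCone,
    include_gouy: bool = True,
) -> float:
    """Cone-integrated SHG intensity (arbitrary units) at one focus.

    ``I = sum_m w_m |A(s_m)|^2``; doubling every chi quadruples I
    (coherent scaling).
    """
    dirs, weights = cone_quadrature(cone, beam.refractive_index)
    amp = shg_far_field(scatterers, focus_um, beam, dirs, include_gouy=include_gouy)
    return float(weights @ (amp.real**2 + amp.imag**2))


def tpef_intensity(scatterers, focus_um, beam: BeamParameters) -> float:
    """Incoherent two-photon fluorescence intensity at one focus."""
    if len(scatterers) == 0:
        return 0.0
    e = focal_field(scatterers.positions_um, focus_um, beam)
    i2 = e.real**2 + e.imag**2
    return float(scatterers.fluor_density @ (i2 * i2))
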