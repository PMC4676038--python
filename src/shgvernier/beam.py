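"""Focused Gaussian illumination: waist, Rayleigh range and the Gouy phase.

The illumination model is a scalar paraxial Gaussian beam.  Its complex
amplitude at a point ``(rho, z)`` (cylindrical coordinates about the
propagation axis, origin at the focus) is

    E(rho, z) = (w0 / w(z)) * exp(-rho^2 / w(z)^2)
                * exp(i * [k n z - psi(z) + k n rho^2 / (2 R(z))])

with waist ``w0``, beam radius ``w(z) = w0 sqrt(1 + (z/zR)^2)``, wavefront
curvature radius ``R(z)``, Gouy phase ``psi(z) = arctan(z / zR)`` and vacuum
wavenumber ``k = 2 pi / lambda``.  The amplitude is normalized to 1 at the
focus.  The Gouy term makes the phase slip by a total of pi as the focus is
traversed; squared into the two-photon drive it is the ingredient that lets
emitters placed symmetrically before and after the focus interfere
constructively even when their geometric phases alone would cancel.

All lengths are micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BeamParameters",
    "derive_beam",
    "gouy_phase",
    "focal_field",
    "waist_from_na",
]

#: Waist convention used throughout: w0 = lambda / (pi * NA).  This is the
#: standard paraxial 1/e^2 relation; swap this single function to experiment
#: with alternatives such as 0.61 * lambda / NA.
def waist_from_na(wavelength_um: float, na: float) -> float:
    return wavelength_um / (np.pi * na)


@dataclass(frozen=True)
class BeamParameters:
    """Illumination beam description with derived focal quantities.

    Attributes
    ----------
    wavelength_um : float
        Vacuum wavelength of the fundamental (e.g. 0.850 um).
    na_objective : float
        Numerical aperture of the focusing objective; sets the waist.
    na_condenser : float
        Numerical aperture of the forward-collection condenser; used by the
        SHG collection cone, carried here because it is a beam-path property.
    refractive_index : float
        Refractive index of the (homogeneous, dispersionless) medium.
    waist_um, rayleigh_range_um : float
        Derived 1/e^2 waist and Rayleigh range, zR = pi n w0^2 / lambda.
    propagation_axis : ndarray, shape (3,)
        Unit vector along which the beam propagates.
    """

    wavelength_um: float
    na_objective: float
    na_condenser: float
    refractive_index: float
    waist_um: float
    rayleigh_range_um: float
    propagation_axis: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 1.0])
    )

    def __post_init__(self) -> None:
        axis = np.asarray(self.propagation_axis, dtype=float)
        if axis.shape != (3,):
            raise ValueError("propagation_axis must be a 3-vector")
        if abs(np.linalg.norm(axis) - 1.0) > 1e-9:
            raise ValueError("propagation_axis must have unit norm")
        object.__setattr__(self, "propagation_axis", axis)
        expected_zr = (
            np.pi * self.refractive_index * self.waist_um**2 / self.wavelength_um
        )
        if abs(expected_zr - self.rayleigh_range_um) > 1e-9 * max(expected_zr, 1.0):
            raise ValueError(
                "rayleigh_range_um inconsistent with waist_um: expected "
                f"{expected_zr:g}, got {self.rayleigh_range_um:g}"
            )

    @property
    def wavenumber_medium(self) -> float:
        """k n = 2 pi n / lambda, the fundamental wavenumber in the medium."""
        return 2.0 * np.pi * self.refractive_index / self.wavelength_um


def derive_beam(
    wavelength_um: float,
    na_objective: float,
    na_condenser: float = 0.55,
    refractive_index: float = 1.33,
    propagation_axis=(0.0, 0.0, 1.0),
) -> BeamParameters:
    """Build :class:`BeamParameters`, deriving waist and Rayleigh range.

    Raises ``ValueError`` naming the offending field for a non-positive
    wavelength or an NA outside ``(0, refractive_index)``.
    """
    if wavelength_um <= 0:
        raise ValueError(f"wavelength_um must be positive, got {wavelength_um}")
    if refractive_index <= 0:
        raise ValueError(f"refractive_index must be positive, got {refractive_index}")
    for name, na in (("na_objective", na_objective), ("na_condenser", na_condenser)):
        if not (0.0 < na < refractive_index):
            raise ValueError(
                f"{name} must lie in (0, refractive_index={refractive_index}), "
                f"got {na}"
            )
    axis = np.asarray(propagation_axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("propagation_axis must be non-zero")
    axis = axis / norm
    w0 = waist_from_na(wavelength_um, na_objective)
    zr = np.pi * refractive_index * w0**2 / wavelength_um
    return BeamParameters(
        wavelength_um=wavelength_um,
        na_objective=na_objective,
        na_condenser=na_condenser,
        refractive_index=refractive_index,
        waist_um=w0,
        rayleigh_range_um=zr,
        propagation_axis=axis,
    )


def gouy_phase(z_um, beam: BeamParameters):
    """Gouy phase psi(z) = arctan(z / zR), in radians.

    Odd in ``z``; its total excursion across the focus is pi.  Accepts
    scalars or arrays of axial positions measured from the focus along the
    propagation axis.
    """
    return np.arctan(np.asarray(z_um, dtype=float) / beam.rayleigh_range_um)


def focal_field(
    points_um,
    focus_um,
    beam: BeamParameters,
    include_gouy: bool = True,
):
    """Complex focal field at one or many points, normalized to 1 at focus.

    Parameters
    ----------
    points_um : array-like, shape (3,) or (N, 3)
        Evaluation points.
    focus_um : array-like, shape (3,)
        Focus position.
    include_gouy : bool
        When False the Gouy term is dropped (phase bookkeeping diagnostics
        and the "mechanism" tests); everything else is unchanged.

    Returns a complex scalar for a single point, else a complex ndarray.
    """
    pts = np.asarray(points_um, dtype=float)
    scalar_input = pts.ndim == 1
    pts = np.atleast_2d(pts)
    focus = np.asarray(focus_um, dtype=float)
    rel = pts - focus

    axis = beam.propagation_axis
    z = rel @ axis
    transverse = rel - np.outer(z, axis)
    rho2 = np.einsum("ij,ij->i", transverse, transverse)

    w0 = beam.waist_um
    zr = beam.rayleigh_range_um
    kn = beam.wavenumber_medium

    u2 = (z / zr) ** 2
    w2 = w0**2 * (1.0 + u2)
    envelope = (w0 / np.sqrt(w2)) * np.exp(-rho2 / w2)

    # 1/R(z) = z / (z^2 + zR^2) is finite everywhere, including z = 0.
    inv_r = z / (z**2 + zr**2)
    phase = kn * z + 0.5 * kn * rho2 * inv_r
    if include_gouy:
        phase = phase - np.arctan(z / zr)

    out = envelope * np.exp(1j * phase)
    return out[0] if scalar_input else out
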