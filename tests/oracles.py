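"""Independent brute-force reference implementations used only by tests.

Deliberately naive: explicit Python loops, scalar ``cmath``, simple
midpoint quadrature over the collection cone at elevated resolution.  No
code is shared with the package's vectorized implementations beyond the
model definition itself.
"""

import cmath
import math


def naive_field(point, focus, wavelength_um, na_objective, n_medium,
                axis=(0.0, 0.0, 1.0), include_gouy=True):
    """Scalar paraxial Gaussian focal field, one point at a time."""
    w0 = wavelength_um / (math.pi * na_objective)
    zr = math.pi * n_medium * w0 * w0 / wavelength_um
    kn = 2.0 * math.pi * n_medium / wavelength_um
    rel = [point[i] - focus[i] for i in range(3)]
    z = sum(rel[i] * axis[i] for i in range(3))
    rho2 = sum(rel[i] * rel[i] for i in range(3)) - z * z
    rho2 = max(rho2, 0.0)
    w2 = w0 * w0 * (1.0 + (z / zr) ** 2)
    envelope = (w0 / math.sqrt(w2)) * math.exp(-rho2 / w2)
    phase = kn * z + 0.5 * kn * rho2 * z / (z * z + zr * zr)
    if include_gouy:
        phase -= math.atan2(z, zr)
    return envelope * cmath.exp(1j * phase)


def naive_shg_intensity(positions, chis, focus, wavelength_um, na_objective,
                        n_medium, na_condenser, n_theta=64, n_phi=128):
    """Cone-integrated SHG intensity by direct summation.

    Midpoint-rule quadrature in (theta, phi) at 4x the production
    resolution; explicit double loop over directions and scatterers.
    """
    kn = 2.0 * math.pi * n_medium / wavelength_um
    k2 = 2.0 * kn
    theta_max = math.asin(na_condenser / n_medium)
    total = 0.0
    for it in range(n_theta):
        theta = (it + 0.5) * theta_max / n_theta
        w_theta = math.sin(theta) * (theta_max / n_theta)
        for ip in range(n_phi):
            phi = (ip + 0.5) * 2.0 * math.pi / n_phi
            w_phi = 2.0 * math.pi / n_phi
            s = (
                math.sin(theta) * math.cos(phi),
                math.sin(theta) * math.sin(phi),
                math.cos(theta),
            )
            amp = 0.0 + 0.0j
            for p, chi in zip(positions, chis):
                e = naive_field(p, focus, wavelength_um, na_objective, n_medium)
                path = sum(s[i] * (p[i] - focus[i]) for i in range(3))
                amp += chi * e * e * cmath.exp(-1j * k2 * path)
            total += w_theta * w_phi * abs(amp) ** 2
    return total


def naive_tpef_intensity(positions, densities, focus, wavelength_um,
                         na_objective, n_medium):
    total = 0.0
    for p, d in zip(positions, densities):
        e = naive_field(p, focus, wavelength_um, na_objective, n_medium)
        total += d * abs(e) ** 4
    return total


def naive_connected_components_26(mask):
    """Connected-component count of a 3D boolean array, 26-connectivity.

    Flood fill with an explicit stack; used as the oracle for mask
    centroid extraction.
    """
    import numpy as np

    mask = np.asarray(mask).astype(bool)
    seen = np.zeros_like(mask, dtype=bool)
    shape = mask.shape
    components = []
    neighbors = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        voxels = []
        while stack:
            v = stack.pop()
            voxels.append(v)
            for d in neighbors:
                n = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
                if all(0 <= n[i] < shape[i] for i in range(3)):
                    if mask[n] and not seen[n]:
                        seen[n] = True
                        stack.append(n)
        components.append(voxels)
    return components
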