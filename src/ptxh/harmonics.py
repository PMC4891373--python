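"""Real solid spherical harmonics for shim-field modelling.

The shim basis consists of real solid harmonics ``r^l * Y_lm`` (tesseral form)
through order 4.  Each term is normalised to unit peak value on a reference
sphere of radius 100 mm, so that a coefficient reads directly as "Hz at the
reference radius per unit current".
"""

from __future__ import annotations

import numpy as np
from scipy.special import sph_harm_y

from .constants import SH_REFERENCE_RADIUS_MM

#: Conventional scanner shim-coil names mapped to (l, m) of the real basis.
COIL_NAME_TO_LM = {
    "X": (1, 1),
    "Y": (1, -1),
    "Z": (1, 0),
    "Z2": (2, 0),
    "ZX": (2, 1),
    "ZY": (2, -1),
    "X2Y2": (2, 2),
    "XY": (2, -2),
    "Z3": (3, 0),
    "Z2X": (3, 1),
    "Z2Y": (3, -1),
    "ZX2Y2": (3, 2),
}

#: Default scanner coil set: full 1st + 2nd order plus four 3rd-order coils.
DEFAULT_COIL_NAMES = (
    "X", "Y", "Z", "Z2", "ZX", "ZY", "X2Y2", "XY", "Z3", "Z2X", "Z2Y", "ZX2Y2",
)


def lm_terms(order_max: int) -> list[tuple[int, int]]:
    """All (l, m) pairs through ``order_max``, l-major, m ascending."""
    return [(l, m) for l in range(order_max + 1) for m in range(-l, l + 1)]


def _real_sph_harm(l: int, m: int, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Real (tesseral) spherical harmonic on the unit sphere."""
    if m == 0:
        return sph_harm_y(l, 0, theta, phi).real
    y = sph_harm_y(l, abs(m), theta, phi)
    if m > 0:
        return np.sqrt(2.0) * (-1) ** m * y.real
    return np.sqrt(2.0) * (-1) ** m * y.imag


def _fibonacci_sphere(n: int = 4096) -> tuple[np.ndarray, np.ndarray]:
    """Near-uniform deterministic sampling of the unit sphere (theta, phi)."""
    i = np.arange(n, dtype=float) + 0.5
    theta = np.arccos(1.0 - 2.0 * i / n)
    phi = (np.pi * (1.0 + np.sqrt(5.0)) * i) % (2.0 * np.pi)
    return theta, phi


_PEAK_CACHE: dict[tuple[int, int], float] = {}


def _unit_sphere_peak(l: int, m: int) -> float:
    """Max |Y_lm^real| on the unit sphere; sets the per-term normalisation."""
    key = (l, m)
    if key not in _PEAK_CACHE:
        theta, phi = _fibonacci_sphere()
        # refine around the sampled maximum with the polar axis included
        vals = np.abs(_real_sph_harm(l, m, theta, phi))
        pole = abs(float(_real_sph_harm(l, m, np.array(0.0), np.array(0.0))))
        _PEAK_CACHE[key] = max(float(vals.max()), pole)
    return _PEAK_CACHE[key]


def real_sh_basis(
    coords_mm: np.ndarray,
    order_max: int = 4,
    reference_radius_mm: float = SH_REFERENCE_RADIUS_MM,
) -> np.ndarray:
    """Evaluate the real solid-harmonic basis at physical points.

    Parameters
    ----------
    coords_mm : (N, 3) array
        Cartesian sample positions in mm.
    order_max : int
        Highest harmonic order (0..4 supported; higher orders work but are
        untested against the scanner coil set).
    reference_radius_mm : float
        Radius at which every term has unit peak value.

    Returns
    -------
    (N, n_terms) array, columns ordered as :func:`lm_terms`.
    """
    if order_max < 0:
        raise ValueError("order_max must be >= 0")
    coords = np.atleast_2d(np.asarray(coords_mm, dtype=float))
    x, y, z = coords[:, 0], coords[:, 1], coords[:, 2]
    r = np.sqrt(x * x + y * y + z * z)
    # angles are undefined at the origin; solid harmonics vanish there (l>0)
    safe_r = np.where(r > 0, r, 1.0)
    theta = np.arccos(np.clip(z / safe_r, -1.0, 1.0))
    phi = np.arctan2(y, x)

    cols = []
    for l, m in lm_terms(order_max):
        ang = _real_sph_harm(l, m, theta, phi)
        radial = (r / reference_radius_mm) ** l
        col = radial * ang / _unit_sphere_peak(l, m)
        if l > 0:
            col = np.where(r > 0, col, 0.0)
        cols.append(col)
    return np.stack(cols, axis=1)


def coil_basis(coords_mm: np.ndarray, coil_names=DEFAULT_COIL_NAMES) -> np.ndarray:
    """Basis restricted to named scanner coils (columns in the given order)."""
    order_max = max(COIL_NAME_TO_LM[n][0] for n in coil_names)
    full = real_sh_basis(coords_mm, order_max)
    terms = lm_terms(order_max)
    idx = [terms.index(COIL_NAME_TO_LM[n]) for n in coil_names]
    return full[:, idx]
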