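"""Spherical-harmonic B0 shimming with hardware current limits.

Fits solid-harmonic basis fields (through order 4) to a measured field map,
computes box-constrained least-squares shim currents for a calibrated coil
set, and predicts the residual field after shimming.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import lsq_linear

from .b0map import field_statistics
from .core import FieldMap, FieldStats, Mask
from .harmonics import DEFAULT_COIL_NAMES, lm_terms, real_sh_basis

# re-exported: the basis evaluation is shared with the phantom generator
__all__ = [
    "ShimCoil",
    "ShimCalibration",
    "ShimSetting",
    "real_sh_basis",
    "decompose_coil_field",
    "optimize_shim_currents",
    "predict_shimmed_field",
]


@dataclass
class ShimCoil:
    """One shim coil: solid-harmonic coefficients per unit current + limit."""

    name: str
    coeffs: np.ndarray  # Hz per unit current, ordered as lm_terms(order_max)
    limit: float  # |current| bound, unit current

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if not np.all(np.isfinite(self.coeffs)):
            raise ValueError(f"coil {self.name}: non-finite coefficients")
        if not self.limit > 0:
            raise ValueError(f"coil {self.name}: current limit must be positive")


@dataclass
class ShimCalibration:
    """Calibrated coil set sharing one harmonic order."""

    coils: list[ShimCoil]
    order_max: int = 4

    def __post_init__(self):
        names = [c.name for c in self.coils]
        if len(set(names)) != len(names):
            raise ValueError("coil names must be unique")
        n_terms = len(lm_terms(self.order_max))
        for c in self.coils:
            if c.coeffs.shape != (n_terms,):
                raise ValueError(f"coil {c.name}: expected {n_terms} coefficients")

    def coil(self, name: str) -> ShimCoil:
        for c in self.coils:
            if c.name == name:
                return c
        raise KeyError(name)

    def names(self) -> list[str]:
        return [c.name for c in self.coils]

    def unit_fields(self, coords_mm: np.ndarray, coil_names=None) -> np.ndarray:
        """(N, n_coils) Hz-per-unit-current fields at the given positions."""
        basis = real_sh_basis(coords_mm, self.order_max)
        names = coil_names if coil_names is not None else self.names()
        return np.stack([basis @ self.coil(n).coeffs for n in names], axis=1)

    def save_json(self, path) -> None:
        terms = lm_terms(self.order_max)
        payload = {
            "order_max": self.order_max,
            "terms": [list(t) for t in terms],
            "coils": [
                {"name": c.name, "coeffs": c.coeffs.tolist(), "limit": c.limit}
                for c in self.coils
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def load_json(cls, path) -> "ShimCalibration":
        payload = json.loads(Path(path).read_text())
        coils = [
            ShimCoil(c["name"], np.asarray(c["coeffs"]), c["limit"])
            for c in payload["coils"]
        ]
        return cls(coils=coils, order_max=payload["order_max"])

    def save_csv(self, path) -> None:
        terms = lm_terms(self.order_max)
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["coil", "l", "m", "hz_per_unit", "limit"])
            for c in self.coils:
                for (l, m), v in zip(terms, c.coeffs):
                    if v != 0.0:
                        w.writerow([c.name, l, m, repr(v), repr(c.limit)])


@dataclass
class ShimSetting:
    """Optimised per-coil currents and the predicted residual statistics."""

    currents: dict[str, float]
    predicted_stats: FieldStats
    objective: float

    def as_dict(self) -> dict:
        return {
            "currents": self.currents,
            "objective": self.objective,
            "predicted_stats": self.predicted_stats.as_dict(),
        }


def decompose_coil_field(
    fieldmap: FieldMap,
    mask: Mask,
    order_max: int = 4,
    current: float = 1.0,
) -> tuple[np.ndarray, float]:
    """Least-squares solid-harmonic coefficients of a measured coil field.

    Returns the per-unit-current coefficient vector (ordered as
    :func:`~ptxh.harmonics.lm_terms`) and the RMS residual in Hz.
    """
    if mask.n_voxels == 0:
        raise ValueError("mask is empty")
    coords = mask.coords_mm()
    basis = real_sh_basis(coords, order_max)
    if coords.shape[0] < basis.shape[1]:
        raise ValueError("fewer in-mask voxels than basis terms")
    y = fieldmap.values[mask.data] / current
    coeffs, *_ = np.linalg.lstsq(basis, y, rcond=None)
    resid = float(np.sqrt(np.mean((basis @ coeffs - y) ** 2)))
    return coeffs, resid


def optimize_shim_currents(
    b0: FieldMap,
    cal: ShimCalibration,
    mask: Mask,
    coil_subset=None,
    tol: float = 1e-12,
) -> ShimSetting:
    """Current-limited least-squares shim setting for a measured field.

    Minimises ``sum_mask (b0 + sum_i c_i field_i)^2`` subject to
    ``|c_i| <= limit_i`` — a convex box-constrained quadratic programme,
    solved to optimality with a bounded linear least-squares routine.
    """
    names = list(coil_subset) if coil_subset is not None else cal.names()
    unknown = set(names) - set(cal.names())
    if unknown:
        raise KeyError(f"coils not in calibration: {sorted(unknown)}")
    limits = np.array([cal.coil(n).limit for n in names])
    if np.any(limits <= 0):
        raise ValueError("current limits must be positive")
    coords = mask.coords_mm()
    F = cal.unit_fields(coords, names)
    y = -b0.values[mask.data]
    res = lsq_linear(F, y, bounds=(-limits, limits), tol=tol)
    currents = dict(zip(names, res.x))
    setting = ShimSetting(currents, _predicted_stats(b0, cal, currents, mask), float(res.cost * 2))
    return setting


def _predicted_stats(b0, cal, currents, mask) -> FieldStats:
    predicted = predict_shimmed_field(b0, cal, currents, mask)
    return field_statistics(predicted, mask)


def predict_shimmed_field(
    b0: FieldMap,
    cal: ShimCalibration,
    setting: "ShimSetting | dict[str, float]",
    mask: Mask | None = None,
) -> FieldMap:
    """Voxelwise predicted field after applying shim currents."""
    currents = setting.currents if isinstance(setting, ShimSetting) else dict(setting)
    if mask is None:
        mask = b0.mask
    if mask is not None and mask.data.shape != b0.values.shape:
        raise ValueError("mask grid does not match the field map")
    from .core import voxel_coords_mm

    coords = voxel_coords_mm(b0.values.shape, b0.affine).reshape(-1, 3)
    names = list(currents)
    F = cal.unit_fields(coords, names)
    c = np.array([currents[n] for n in names])
    values = b0.values + (F @ c).reshape(b0.values.shape)
    return FieldMap(values, b0.affine, mask, b0.f0)
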