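"""Core volumetric containers: masks, field maps, B1+ map sets, flip-angle maps.

All volumes live on a regular voxel grid with a 4x4 RAS affine mapping voxel
indices to physical millimetre coordinates.  Complex volumes are written to
disk as paired real/imaginary NIfTI files so that every artifact stays a
standard, tool-readable format.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .constants import F0_9T4_HZ


def voxel_coords_mm(shape: tuple[int, ...], affine: np.ndarray) -> np.ndarray:
    """Physical coordinates (mm) of every voxel centre, shaped ``shape + (3,)``."""
    idx = np.indices(shape, dtype=float)
    ijk = np.stack([idx[0], idx[1], idx[2], np.ones(shape)], axis=-1)
    return ijk @ affine.T[:, :3]


def centered_affine(shape, voxel_size_mm) -> np.ndarray:
    """RAS affine with isotropic-or-not voxels and the grid centre at the origin."""
    shape = np.asarray(shape, dtype=float)
    vox = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
    affine = np.diag([vox[0], vox[1], vox[2], 1.0])
    affine[:3, 3] = -(shape - 1) / 2.0 * vox
    return affine


@dataclass
class Mask:
    """Boolean region-of-interest volume with a physical affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("mask must be a 3D volume")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def coords_mm(self) -> np.ndarray:
        """(N, 3) mm coordinates of the in-mask voxel centres."""
        return voxel_coords_mm(self.data.shape, self.affine)[self.data]

    def centroid_mm(self) -> np.ndarray:
        return self.coords_mm().mean(axis=0)

    def save(self, path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.uint8), self.affine), str(path))

    @classmethod
    def load(cls, path) -> "Mask":
        img = nib.load(str(path))
        return cls(np.asarray(img.dataobj) > 0, img.affine)


@dataclass
class FieldMap:
    """Scalar off-resonance volume in Hz.

    ``f0`` is the Larmor frequency used to express the same field in ppm.
    """

    values: np.ndarray
    affine: np.ndarray
    mask: Mask | None = None
    f0: float = F0_9T4_HZ

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def ppm(self) -> np.ndarray:
        return self.values / self.f0 * 1e6

    def in_mask(self) -> np.ndarray:
        if self.mask is None:
            return self.values.ravel()
        return self.values[self.mask.data]

    def save(self, path) -> None:
        nib.save(nib.Nifti1Image(self.values.astype(np.float32), self.affine), str(path))

    @classmethod
    def load(cls, path, mask: Mask | None = None, f0: float = F0_9T4_HZ) -> "FieldMap":
        img = nib.load(str(path))
        return cls(np.asarray(img.dataobj, dtype=float), img.affine, mask, f0)


@dataclass
class FieldStats:
    """Summary statistics of a field distribution inside a mask."""

    mean_hz: float
    std_hz: float
    hist_fwhm_hz: float
    p90_range_hz: float
    f0: float = F0_9T4_HZ

    @property
    def mean_ppm(self) -> float:
        return self.mean_hz / self.f0 * 1e6

    @property
    def std_ppm(self) -> float:
        return self.std_hz / self.f0 * 1e6

    @property
    def hist_fwhm_ppm(self) -> float:
        return self.hist_fwhm_hz / self.f0 * 1e6

    @property
    def p90_range_ppm(self) -> float:
        return self.p90_range_hz / self.f0 * 1e6

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.update(
            mean_ppm=self.mean_ppm,
            std_ppm=self.std_ppm,
            hist_fwhm_ppm=self.hist_fwhm_ppm,
            p90_range_ppm=self.p90_range_ppm,
        )
        return d


@dataclass
class B1MapSet:
    """Per-channel complex transmit sensitivities in uT per volt of drive."""

    maps: np.ndarray  # (n_channels, nx, ny, nz), complex
    affine: np.ndarray
    mask: Mask | None = None
    reference_voltage: float = 1.0

    def __post_init__(self):
        self.maps = np.asarray(self.maps, dtype=complex)
        if self.maps.ndim != 4:
            raise ValueError("B1 maps must be (n_channels, nx, ny, nz)")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def n_channels(self) -> int:
        return self.maps.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.maps.shape[1:]

    def cp_phases(self, at_mm: np.ndarray | None = None) -> np.ndarray:
        """Per-channel drive phases aligning all channels at a reference point.

        Defaults to the mask centroid (grid centre without a mask); this is the
        circularly-polarised-like baseline mode of the array.
        """
        if at_mm is None:
            if self.mask is not None:
                at_mm = self.mask.centroid_mm()
            else:
                at_mm = voxel_coords_mm(self.shape, self.affine).reshape(-1, 3).mean(axis=0)
        # nearest voxel to the reference point
        coords = voxel_coords_mm(self.shape, self.affine).reshape(-1, 3)
        i = int(np.argmin(((coords - at_mm) ** 2).sum(axis=1)))
        vox = np.unravel_index(i, self.shape)
        return -np.angle(self.maps[(slice(None),) + vox])

    def cp_combined(self, drive_v: float = 1.0) -> np.ndarray:
        """Complex CP-mode combined field (uT) for a common drive of ``drive_v``."""
        w = drive_v * np.exp(1j * self.cp_phases())
        return np.tensordot(w, self.maps, axes=(0, 0))

    def combined(self, weights: np.ndarray) -> np.ndarray:
        """Combined field (uT) for per-channel complex drives ``weights`` (V)."""
        return np.tensordot(np.asarray(weights, dtype=complex), self.maps, axes=(0, 0))

    def save(self, prefix) -> None:
        prefix = str(prefix)
        nib.save(nib.Nifti1Image(self.maps.real.astype(np.float32).transpose(1, 2, 3, 0), self.affine), prefix + "_real.nii")
        nib.save(nib.Nifti1Image(self.maps.imag.astype(np.float32).transpose(1, 2, 3, 0), self.affine), prefix + "_imag.nii")

    @classmethod
    def load(cls, prefix, mask: Mask | None = None) -> "B1MapSet":
        prefix = str(prefix)
        re = nib.load(prefix + "_real.nii")
        im = nib.load(prefix + "_imag.nii")
        maps = (np.asarray(re.dataobj, dtype=float) + 1j * np.asarray(im.dataobj, dtype=float)).transpose(3, 0, 1, 2)
        return cls(maps, re.affine, mask)


@dataclass
class FlipAngleMap:
    """Achieved or mapped flip angle in degrees."""

    values: np.ndarray
    affine: np.ndarray
    nominal_deg: float | None = None
    mask: Mask | None = None
    invalid: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)

    def in_mask(self) -> np.ndarray:
        if self.mask is None:
            return self.values.ravel()
        return self.values[self.mask.data]

    def save(self, path) -> None:
        nib.save(nib.Nifti1Image(self.values.astype(np.float32), self.affine), str(path))


def save_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
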