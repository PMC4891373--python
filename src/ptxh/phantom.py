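"""Synthetic head-phantom generator.

Produces every calibration input the homogenisation workflow consumes — a
head-shaped mask, a smooth-plus-local B0 inhomogeneity field, interfering
multi-channel complex B1+ sensitivities, and raw dual-echo GRE / DREAM
calibration signals — with the statistical and physical structure the
downstream algorithms assume.

The B1+ model is deliberately phenomenological: each channel is a loop-like
element on a ring around the head whose magnitude decays with distance from
the element and whose phase advances as a travelling wave ``exp(-i 2 pi d /
lambda)`` with the ~16 cm RF wavelength of 400 MHz in tissue.  The
circularly-polarised (CP) combination of such channels exhibits the
characteristic ultra-high-field pattern: a bright centre and peripheral
destructive-interference voids.  No electromagnetic simulation is attempted.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .constants import CP_MODE_UT_PER_V
from .core import B1MapSet, FieldMap, Mask, centered_affine, save_json, voxel_coords_mm
from .harmonics import COIL_NAME_TO_LM, lm_terms, real_sh_basis


@dataclass
class PhantomSpec:
    """Parameters of the synthetic head phantom.

    Defaults mirror a 9.4 T whole-head calibration protocol: a 50x50x44 grid
    of 4 mm voxels for the B0 map, a 16-channel dual-row transmit array, and a
    B0 field whose in-mask spread sits in the 40-80 Hz regime seen before
    higher-order shimming.
    """

    grid_shape: tuple[int, int, int] = (50, 50, 44)
    voxel_size_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    ellipsoid_semi_axes_mm: tuple[float, float, float] = (70.0, 85.0, 62.0)
    n_channels: int = 16
    #: smooth field component: Hz per normalised solid-harmonic term
    b0_sh_coeffs: dict = field(
        default_factory=lambda: {
            "Z": -55.0,
            "X": 26.0,
            "Z2": 130.0,
            "ZY": 62.0,
            "X2Y2": 44.0,
            (4, 0): 46.0,
        }
    )
    #: local perturbations: (centre mm, width mm, amplitude Hz)
    b0_local_perturbations: tuple = (
        ((0.0, 62.0, -28.0), 22.0, -235.0),
        ((34.0, -48.0, 26.0), 28.0, 145.0),
    )
    rf_wavelength_m: float = 0.158
    noise_snr: float = 50.0
    seed: int = 0

    def __post_init__(self):
        if any(int(s) <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape entries must be positive")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if not self.noise_snr > 0:
            raise ValueError("noise_snr must be > 0")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")

    @property
    def affine(self) -> np.ndarray:
        return centered_affine(self.grid_shape, self.voxel_size_mm)

    def fov_mm(self) -> np.ndarray:
        return np.asarray(self.grid_shape, float) * np.asarray(self.voxel_size_mm, float)

    def spec_hash(self) -> str:
        blob = json.dumps(
            {k: str(v) for k, v in self.__dict__.items()}, sort_keys=True
        ).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def make_head_mask(spec: PhantomSpec) -> Mask:
    """Ellipsoidal head-shaped mask centred in the grid."""
    a, b, c = spec.ellipsoid_semi_axes_mm
    if min(a, b, c) <= 0:
        raise ValueError("ellipsoid semi-axes must be positive (empty mask)")
    half_fov = spec.fov_mm() / 2.0
    if a > half_fov[0] or b > half_fov[1] or c > half_fov[2]:
        raise ValueError("ellipsoid semi-axes exceed the field of view")
    coords = voxel_coords_mm(spec.grid_shape, spec.affine)
    q = (
        (coords[..., 0] / a) ** 2
        + (coords[..., 1] / b) ** 2
        + (coords[..., 2] / c) ** 2
    )
    return Mask(q <= 1.0, spec.affine)


def _coeff_items(coeffs: dict):
    for key, hz in coeffs.items():
        lm = COIL_NAME_TO_LM[key] if isinstance(key, str) else tuple(key)
        yield lm, float(hz)


def make_b0_map(spec: PhantomSpec, mask: Mask) -> FieldMap:
    """Smooth solid-harmonic field plus local Gaussian perturbations (Hz)."""
    if mask.data.shape != tuple(spec.grid_shape):
        raise ValueError("mask grid does not match the phantom spec")
    coords = voxel_coords_mm(spec.grid_shape, spec.affine).reshape(-1, 3)
    order_max = max((lm[0] for lm, _ in _coeff_items(spec.b0_sh_coeffs)), default=0)
    basis = real_sh_basis(coords, order_max)
    terms = lm_terms(order_max)
    f = np.zeros(coords.shape[0])
    for lm, hz in _coeff_items(spec.b0_sh_coeffs):
        f += hz * basis[:, terms.index(lm)]
    for centre, width, amp in spec.b0_local_perturbations:
        d2 = ((coords - np.asarray(centre, float)) ** 2).sum(axis=1)
        f += amp * np.exp(-d2 / (2.0 * width**2))
    values = f.reshape(spec.grid_shape)
    return FieldMap(values, spec.affine, mask)


def _channel_positions(spec: PhantomSpec, ring_radius_mm: float, row_offset_mm: float):
    n = spec.n_channels
    if n >= 8 and n % 2 == 0:
        rows = (-row_offset_mm, row_offset_mm)
        per_row = n // 2
    else:
        rows = (0.0,)
        per_row = n
    pos = []
    for r_i, z in enumerate(rows):
        for k in range(per_row):
            ang = 2 * np.pi * k / per_row + (np.pi / per_row) * r_i
            pos.append([ring_radius_mm * np.cos(ang), ring_radius_mm * np.sin(ang), z])
    return np.asarray(pos[:n])


def make_b1_maps(
    spec: PhantomSpec,
    mask: Mask,
    uniform: bool = False,
    ring_radius_mm: float = 110.0,
    row_offset_mm: float = 35.0,
    element_reach_mm: float = 75.0,
) -> B1MapSet:
    """Per-channel complex transmit sensitivities (uT/V) on the phantom grid.

    Loop-like magnitude decay from each element position times a travelling
    wave phase; the overall scale is set so the CP-mode combination reaches
    the nominal CP transmit efficiency at the mask centroid.  ``uniform``
    replaces every channel with a constant unit sensitivity (useful for
    single-channel closed-form checks).
    """
    shape = tuple(spec.grid_shape)
    if uniform:
        maps = np.ones((spec.n_channels,) + shape, dtype=complex)
        return B1MapSet(maps, spec.affine, mask)

    rng = np.random.default_rng(spec.seed)
    coords = voxel_coords_mm(shape, spec.affine)
    lam_mm = spec.rf_wavelength_m * 1e3
    positions = _channel_positions(spec, ring_radius_mm, row_offset_mm)
    maps = np.empty((spec.n_channels,) + shape, dtype=complex)
    for c, p in enumerate(positions):
        d = np.sqrt(((coords - p) ** 2).sum(axis=-1))
        mag = 1.0 / (1.0 + (d / element_reach_mm) ** 2)
        phase = -2.0 * np.pi * d / lam_mm
        # small smooth seeded perturbation breaks the exact ring symmetry
        pert = gaussian_filter(rng.standard_normal(shape), sigma=4.0)
        pert = 0.05 * pert / max(np.abs(pert).max(), 1e-12)
        maps[c] = mag * (1.0 + pert) * np.exp(1j * phase)

    b1 = B1MapSet(maps, spec.affine, mask)
    cp = np.abs(b1.cp_combined())
    centroid_val = _value_at(cp, spec, mask.centroid_mm())
    b1.maps *= CP_MODE_UT_PER_V / centroid_val
    return b1


def _value_at(volume: np.ndarray, spec: PhantomSpec, point_mm) -> float:
    coords = voxel_coords_mm(spec.grid_shape, spec.affine).reshape(-1, 3)
    i = int(np.argmin(((coords - np.asarray(point_mm)) ** 2).sum(axis=1)))
    return float(volume.reshape(-1)[i])


def simulate_dual_echo_gre(
    b0: FieldMap,
    mask: Mask,
    te1: float = 1.00e-3,
    te2: float = 3.21e-3,
    snr: float | None = None,
    receiver_phase: float = 0.3,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Complex dual-echo GRE volumes for a known off-resonance field.

    Echo k carries phase ``2 pi f TE_k`` plus a common receiver phase; the
    magnitude is the mask with optional complex Gaussian noise at the given
    SNR (defined on the in-mask mean magnitude).
    """
    if te1 <= 0 or te2 <= 0:
        raise ValueError("echo times must be positive")
    if te2 <= te1:
        raise ValueError("te2 must exceed te1")
    rng = np.random.default_rng(seed)
    mag = mask.data.astype(float)
    echoes = []
    for te in (te1, te2):
        vol = mag * np.exp(1j * (2 * np.pi * b0.values * te + receiver_phase))
        if snr is not None and np.isfinite(snr):
            sigma = mag[mask.data].mean() / snr
            vol = vol + sigma * (
                rng.standard_normal(vol.shape) + 1j * rng.standard_normal(vol.shape)
            ) / np.sqrt(2.0)
        echoes.append(vol)
    return echoes[0], echoes[1]


@dataclass
class DreamSignals:
    """Raw transmit-encoded DREAM signal volumes, one pair per encode step."""

    ste: np.ndarray  # (n_steps, nx, ny, nz), complex (phase carries transmit phase)
    fid: np.ndarray  # (n_steps, nx, ny, nz), real magnitude
    encoding: np.ndarray  # (n_steps, n_channels)
    prep_scale_deg_per_ut: float
    provenance: dict


def simulate_dream_signals(
    b1: B1MapSet,
    encoding: np.ndarray,
    prep_scale_deg_per_ut: float,
    snr: float | None = None,
    seed: int = 0,
) -> DreamSignals:
    """Simulate stimulated-echo / FID pairs for transmit phase-encoded DREAM.

    Per encode step the channels are driven with one row of ``encoding``; the
    local preparation flip angle is proportional to the combined |B1+| and the
    STE/FID magnitude ratio follows ``tan^2(alpha)/2``.  The STE phase carries
    the relative transmit phase of the combined field.
    """
    encoding = np.atleast_2d(np.asarray(encoding, dtype=complex))
    if encoding.shape[1] != b1.n_channels:
        raise ValueError("encoding columns must match the number of channels")
    if encoding.shape[0] < b1.n_channels:
        raise ValueError("need at least as many encode steps as channels")
    provenance: dict = {"encoding_rank": int(np.linalg.matrix_rank(encoding))}
    if provenance["encoding_rank"] < b1.n_channels:
        provenance["warning"] = "encoding matrix is rank deficient"

    rng = np.random.default_rng(seed)
    shape = b1.shape
    n_steps = encoding.shape[0]
    ste = np.empty((n_steps,) + shape, dtype=complex)
    fid = np.empty((n_steps,) + shape, dtype=float)
    support = b1.mask.data.astype(float) if b1.mask is not None else 1.0
    for s in range(n_steps):
        combined = np.tensordot(encoding[s], b1.maps, axes=(0, 0))  # uT
        alpha = np.deg2rad(prep_scale_deg_per_ut * np.abs(combined))
        ste[s] = support * 0.5 * np.sin(alpha) ** 2 * np.exp(1j * np.angle(combined))
        fid[s] = support * np.cos(alpha) ** 2
    if snr is not None and np.isfinite(snr):
        ref = np.abs(ste).mean()
        sig = ref / snr
        ste = ste + sig * (rng.standard_normal(ste.shape) + 1j * rng.standard_normal(ste.shape)) / np.sqrt(2)
        fid = np.abs(fid + sig * rng.standard_normal(fid.shape))
    return DreamSignals(ste, fid, encoding, prep_scale_deg_per_ut, provenance)


def make_shim_calibration(
    coil_names=None,
    main_hz_per_unit: dict | None = None,
    limits: dict | None = None,
    imperfection: float = 0.02,
    order_max: int = 4,
    seed: int = 0,
):
    """Synthetic shim-coil calibration table.

    Each coil produces (predominantly) its namesake solid-harmonic field with
    a small seeded admixture of other terms, emulating the deviation of
    physical shim coils from ideal spherical harmonics.
    """
    from .shim import ShimCalibration, ShimCoil  # local import avoids a cycle

    if coil_names is None:
        from .harmonics import DEFAULT_COIL_NAMES

        coil_names = DEFAULT_COIL_NAMES
    default_main = {1: 400.0, 2: 250.0, 3: 120.0}
    default_limit = {1: 2.0, 2: 2.0, 3: 1.0}
    rng = np.random.default_rng(seed)
    terms = lm_terms(order_max)
    coils = []
    for name in coil_names:
        lm = COIL_NAME_TO_LM[name]
        order = lm[0]
        main = (main_hz_per_unit or {}).get(name, default_main[order])
        coeffs = np.zeros(len(terms))
        coeffs[terms.index(lm)] = main
        if imperfection > 0:
            # contaminate a couple of nearby terms
            others = [i for i, t in enumerate(terms) if t != lm and t[0] >= order]
            picks = rng.choice(others, size=min(2, len(others)), replace=False)
            coeffs[picks] += imperfection * main * rng.standard_normal(len(picks))
        limit = (limits or {}).get(name, default_limit[order])
        coils.append(ShimCoil(name=name, coeffs=coeffs, limit=float(limit)))
    return ShimCalibration(coils=coils, order_max=order_max)


def write_phantom(spec: PhantomSpec, outdir) -> dict:
    """Write mask, B0 and B1 fixtures as NIfTI plus a seed/hash manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mask = make_head_mask(spec)
    b0 = make_b0_map(spec, mask)
    b1 = make_b1_maps(spec, mask)
    mask.save(outdir / "mask.nii")
    b0.save(outdir / "b0_hz.nii")
    b1.save(outdir / "b1")
    manifest = {"seed": spec.seed, "spec_hash": spec.spec_hash(), "n_channels": spec.n_channels}
    save_json(manifest, outdir / "manifest.json")
    return manifest
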