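"""Transmit-field (B1+) mapping: DREAM decoding and PreSat-TFL flip angles.

The multi-channel maps come from a transmit phase-encoded DREAM acquisition:
each encode step drives the channels with one row of an encoding matrix, the
STE/FID magnitude ratio encodes the local preparation flip angle, and a
per-voxel least-squares solve against the encoding matrix separates the
channels.  PreSat-TFL provides a single-map flip-angle validation via the
saturated/unsaturated signal ratio.
"""

from __future__ import annotations

import numpy as np

from .core import B1MapSet, FlipAngleMap, Mask


def dream_flip_angle(
    ste: np.ndarray,
    fid: np.ndarray,
    affine: np.ndarray | None = None,
    nominal_deg: float | None = None,
) -> FlipAngleMap:
    """Preparation flip angle (degrees) from STE and FID magnitudes.

    ``alpha = arctan(sqrt(2 STE / FID))``; voxels with zero FID are marked
    invalid (the ratio is undefined there).
    """
    ste = np.abs(np.asarray(ste, dtype=complex)).astype(float) if np.iscomplexobj(ste) else np.asarray(ste, dtype=float)
    fid = np.asarray(fid, dtype=float)
    if ste.shape != fid.shape:
        raise ValueError("STE and FID volumes must share a shape")
    if np.any(ste < 0) or np.any(fid < 0):
        raise ValueError("STE and FID magnitudes must be non-negative")
    invalid = fid == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.degrees(np.arctan(np.sqrt(2.0 * ste / np.where(invalid, np.nan, fid))))
    alpha = np.where(invalid, 0.0, alpha)
    if affine is None:
        affine = np.eye(4)
    return FlipAngleMap(alpha, affine, nominal_deg=nominal_deg, invalid=invalid)


def decode_transmit_encoding(
    step_fields: np.ndarray,
    encoding: np.ndarray,
    affine: np.ndarray | None = None,
    mask: Mask | None = None,
) -> tuple[B1MapSet, float]:
    """Per-channel complex maps from per-step combined transmit fields.

    Solves ``encoding @ s = measurements`` voxelwise by least squares (for a
    unitary DFT encoding this is the inverse DFT; with more steps than
    channels it is the overdetermined pseudo-inverse solve).  Returns the map
    set and the condition number of the encoding matrix.
    """
    encoding = np.atleast_2d(np.asarray(encoding, dtype=complex))
    step_fields = np.asarray(step_fields, dtype=complex)
    n_steps, n_channels = encoding.shape
    if step_fields.shape[0] != n_steps:
        raise ValueError("first axis of step_fields must match encode steps")
    if n_steps < n_channels:
        raise ValueError("need at least as many encode steps as channels")
    if np.linalg.matrix_rank(encoding) < n_channels:
        raise ValueError("encoding matrix is rank deficient")
    cond = float(np.linalg.cond(encoding))
    vol_shape = step_fields.shape[1:]
    y = step_fields.reshape(n_steps, -1)
    s = np.linalg.pinv(encoding) @ y
    maps = s.reshape((n_channels,) + vol_shape)
    if affine is None:
        affine = np.eye(4)
    return B1MapSet(maps, affine, mask), cond


def decode_dream(
    signals,
    affine: np.ndarray | None = None,
    mask: Mask | None = None,
) -> tuple[B1MapSet, float]:
    """Full DREAM reconstruction: signals -> per-step fields -> channel maps.

    Inverts the STE/FID ratio to the preparation angle, converts it to a
    combined |B1+| through the preparation scale, attaches the STE transmit
    phase, and separates channels with :func:`decode_transmit_encoding`.
    """
    fa = dream_flip_angle(np.abs(signals.ste), signals.fid)
    combined_mag_ut = fa.values / signals.prep_scale_deg_per_ut
    fields = combined_mag_ut * np.exp(1j * np.angle(signals.ste))
    return decode_transmit_encoding(fields, signals.encoding, affine, mask)


def reference_phases(b1: B1MapSet, channel: int = 0) -> B1MapSet:
    """Reference all channel phases to one channel at the mask centroid.

    Only relative transmit phases matter to pulse design; this fixes the
    arbitrary global phase per acquisition.
    """
    if b1.mask is not None:
        at = b1.mask.centroid_mm()
    else:
        at = None
    phases = b1.cp_phases(at) if at is not None else b1.cp_phases()
    ref = -phases[channel]
    maps = b1.maps * np.exp(-1j * ref)
    return B1MapSet(maps, b1.affine, b1.mask, b1.reference_voltage)


def presat_tfl_flip_angle(
    sat: np.ndarray,
    unsat: np.ndarray,
    affine: np.ndarray | None = None,
    nominal_deg: float | None = None,
) -> FlipAngleMap:
    """Saturation flip angle from PreSat-TFL: ``alpha = arccos(sat/unsat)``."""
    sat = np.asarray(sat, dtype=float)
    unsat = np.asarray(unsat, dtype=float)
    if sat.shape != unsat.shape:
        raise ValueError("volumes must share a shape")
    invalid = unsat <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(invalid, 1.0, sat / np.where(invalid, 1.0, unsat))
    alpha = np.degrees(np.arccos(np.clip(ratio, -1.0, 1.0)))
    if affine is None:
        affine = np.eye(4)
    return FlipAngleMap(alpha, affine, nominal_deg=nominal_deg, invalid=invalid)


def dft_encoding(n_channels: int, n_steps: int | None = None) -> np.ndarray:
    """Fourier transmit-encoding matrix (n_steps x n_channels), unit modulus."""
    if n_steps is None:
        n_steps = n_channels
    m = np.arange(n_steps)[:, None]
    c = np.arange(n_channels)[None, :]
    return np.exp(2j * np.pi * m * c / n_steps)
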