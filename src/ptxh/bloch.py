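"""Multi-channel Bloch simulation and adiabatic inversion pulses.

The simulator integrates the Bloch equations without relaxation as a
sequence of exact hard-pulse rotations (Rodrigues formula), so the
magnetisation norm is conserved to machine precision.  Frequency modulation
is realised as accumulated RF phase, which is exact in the Larmor rotating
frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

from .constants import GAMMA_BAR_HZ_PER_T
from .core import B1MapSet, FieldMap, FlipAngleMap, Mask, voxel_coords_mm


@dataclass
class Waveform:
    """Sampled RF and gradient waveforms on one uniform raster.

    ``rf`` holds per-channel complex envelopes in volts; ``gradients`` the
    three gradient channels in T/m; ``fm`` an optional RF frequency
    modulation in Hz (converted to phase internally).
    """

    rf: np.ndarray  # (n_channels, n_t) complex, volts
    gradients: np.ndarray  # (3, n_t), T/m
    dt: float  # s
    fm: np.ndarray | None = None  # (n_t,), Hz

    def __post_init__(self):
        self.rf = np.atleast_2d(np.asarray(self.rf, dtype=complex))
        self.gradients = np.asarray(self.gradients, dtype=float)
        if self.dt <= 0:
            raise ValueError("raster time must be positive")
        if self.gradients.shape != (3, self.rf.shape[1]):
            raise ValueError("gradients must be (3, n_t) on the RF raster")
        if self.fm is not None:
            self.fm = np.asarray(self.fm, dtype=float)
            if self.fm.shape != (self.rf.shape[1],):
                raise ValueError("fm must share the RF raster")

    @property
    def n_channels(self) -> int:
        return self.rf.shape[0]

    @property
    def n_samples(self) -> int:
        return self.rf.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples * self.dt

    def rf_with_fm(self) -> np.ndarray:
        """RF with the frequency modulation folded into the phase."""
        if self.fm is None:
            return self.rf
        phase = 2.0 * np.pi * np.cumsum(self.fm) * self.dt
        return self.rf * np.exp(1j * phase)[None, :]

    def save_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("rf_volts", data=self.rf)
            f.create_dataset("gradients_t_per_m", data=self.gradients)
            f.attrs["dt_s"] = self.dt
            if self.fm is not None:
                f.create_dataset("fm_hz", data=self.fm)

    @classmethod
    def load_hdf5(cls, path) -> "Waveform":
        with h5py.File(path, "r") as f:
            fm = np.asarray(f["fm_hz"]) if "fm_hz" in f else None
            return cls(np.asarray(f["rf_volts"]), np.asarray(f["gradients_t_per_m"]), float(f.attrs["dt_s"]), fm)

    def save_txt(self, path) -> None:
        """Plain-text table: time, per-channel re/im volts, Gx, Gy, Gz."""
        t = np.arange(self.n_samples) * self.dt
        cols = [t]
        for c in range(self.n_channels):
            cols += [self.rf[c].real, self.rf[c].imag]
        cols += [self.gradients[0], self.gradients[1], self.gradients[2]]
        header = "t_s " + " ".join(
            f"ch{c}_re_V ch{c}_im_V" for c in range(self.n_channels)
        ) + " gx_T_per_m gy_T_per_m gz_T_per_m"
        np.savetxt(path, np.stack(cols, axis=1), header=header)


@dataclass
class Magnetization:
    """Bloch-simulated magnetisation for the in-mask voxels (unit M0)."""

    m: np.ndarray  # (n_voxels, 3): Mx, My, Mz
    mask: Mask
    affine: np.ndarray

    @property
    def flip_deg(self) -> np.ndarray:
        mxy = np.hypot(self.m[:, 0], self.m[:, 1])
        return np.degrees(np.arctan2(mxy, self.m[:, 2]))

    def flip_angle_map(self, nominal_deg: float | None = None) -> FlipAngleMap:
        vol = np.zeros(self.mask.data.shape)
        vol[self.mask.data] = self.flip_deg
        return FlipAngleMap(vol, self.affine, nominal_deg=nominal_deg, mask=self.mask)

    def mz_volume(self) -> np.ndarray:
        vol = np.ones(self.mask.data.shape)
        vol[self.mask.data] = self.m[:, 2]
        return vol


def bloch_simulate(
    wave: Waveform,
    b1: B1MapSet,
    b0: FieldMap | None,
    mask: Mask,
    warn_raster: float = 10e-6,
) -> Magnetization:
    """Hard-pulse Bloch integration of a multi-channel pulse.

    The per-step effective field (Hz) at voxel r is
    ``(gb Re(B1eff), gb Im(B1eff), df(r) + gb G.r)`` with
    ``B1eff = sum_c s_c(r) V_c(t)`` and gb the reduced gyromagnetic ratio;
    frequency modulation enters through the RF phase.  No relaxation.
    """
    if wave.n_channels != b1.n_channels:
        raise ValueError("waveform channels do not match the B1 map set")
    if mask.data.shape != b1.shape:
        raise ValueError("mask grid does not match the B1 maps")
    if wave.dt > warn_raster:
        raise ValueError("raster time exceeds the supported hard-pulse raster")
    if wave.fm is not None and wave.n_samples > 1:
        sweep_rate = np.max(np.abs(np.diff(wave.fm))) / wave.dt
        if sweep_rate * wave.dt**2 > 0.05:
            import warnings

            warnings.warn("raster too coarse for the FM sweep rate", stacklevel=2)

    rf = wave.rf_with_fm()
    if not (np.all(np.isfinite(rf)) and np.all(np.isfinite(wave.gradients))):
        raise ValueError("waveform contains non-finite samples")

    sel = mask.data
    sens = b1.maps[:, sel] * 1e-6  # uT/V -> T/V
    if not np.all(np.isfinite(sens)):
        raise ValueError("B1 maps contain non-finite values")
    coords_m = mask.coords_mm() * 1e-3
    df = b0.values[sel] if b0 is not None else np.zeros(sel.sum())
    if not np.all(np.isfinite(df)):
        raise ValueError("B0 map contains non-finite values")
    gb = GAMMA_BAR_HZ_PER_T

    n_vox = sens.shape[1]
    M = np.zeros((n_vox, 3))
    M[:, 2] = 1.0
    two_pi_dt = 2.0 * np.pi * wave.dt
    grad_hz_per_m = gb * wave.gradients  # (3, n_t)
    for t in range(wave.n_samples):
        b1eff = sens.T @ rf[:, t]  # (n_vox,), tesla
        bx = gb * b1eff.real
        by = gb * b1eff.imag
        bz = df + coords_m @ grad_hz_per_m[:, t]
        M = _rodrigues_step(M, bx, by, bz, two_pi_dt)
    return Magnetization(M, mask, b1.affine)


def _rodrigues_step(M, bx, by, bz, two_pi_dt):
    """Exact rotation of M about the effective field for one raster step."""
    norm = np.sqrt(bx * bx + by * by + bz * bz)
    active = norm > 0
    if not np.any(active):
        return M
    # rotation angle is negative: M precesses clockwise about B for gamma > 0
    theta = -two_pi_dt * norm
    with np.errstate(invalid="ignore", divide="ignore"):
        nx = np.where(active, bx / norm, 0.0)
        ny = np.where(active, by / norm, 0.0)
        nz = np.where(active, bz / norm, 1.0)
    c = np.cos(theta)
    s = np.sin(theta)
    n = np.stack([nx, ny, nz], axis=1)
    ndotm = (n * M).sum(axis=1, keepdims=True)
    cross = np.cross(n, M)
    return M * c[:, None] + cross * s[:, None] + n * ndotm * (1.0 - c[:, None])


def hs_pulse(
    duration: float = 5.12e-3,
    beta: float = 2070.0,
    mu: float = 4.9,
    peak_v: float = 166.0,
    dt: float = 5e-6,
) -> Waveform:
    """Hyperbolic-secant adiabatic inversion pulse (single channel).

    AM: ``peak * sech(beta (t - T/2))``; FM: ``-(mu beta / 2 pi) * tanh(beta
    (t - T/2))`` Hz.  The default ``beta`` (rad/s) truncates the sech
    envelope at ~1 % of peak over the 5.12 ms duration; ``mu`` sets the
    frequency-sweep width.  Representative full-passage values, configurable.
    """
    if beta <= 0 or mu <= 0:
        raise ValueError("beta and mu must be positive")
    n = int(round(duration / dt))
    t = (np.arange(n) + 0.5) * dt - duration / 2.0
    am = peak_v / np.cosh(beta * t)
    fm = -(mu * beta / (2.0 * np.pi)) * np.tanh(beta * t)
    return Waveform(am[None, :].astype(complex), np.zeros((3, n)), dt, fm)


def foci_pulse(
    duration: float = 13e-3,
    beta: float = 815.0,
    mu: float = 4.9,
    a_max: float = 5.0,
    peak_v: float = 79.8,
    dt: float = 5e-6,
) -> Waveform:
    """FOCI-style adiabatic inversion pulse (single channel).

    A hyperbolic-secant pulse whose AM and FM are both multiplied by the
    shape factor ``A(t) = min(a_max, cosh(beta (t - T/2)))``.  The AM is
    therefore flat at peak amplitude over the central portion while the FM
    sweep steepens at the edges; at matched peak B1 this lowers the adiabatic
    threshold relative to the plain hyperbolic secant.  This is a documented
    representative parameterisation, not any vendor's proprietary waveform.
    """
    if beta <= 0 or mu <= 0 or a_max < 1:
        raise ValueError("invalid FOCI parameters")
    n = int(round(duration / dt))
    t = (np.arange(n) + 0.5) * dt - duration / 2.0
    shape = np.minimum(a_max, np.cosh(beta * t))
    am = peak_v * shape / np.cosh(beta * t)
    fm = -(mu * beta / (2.0 * np.pi)) * shape * np.tanh(beta * t)
    return Waveform(am[None, :].astype(complex), np.zeros((3, n)), dt, fm)


def load_amfm_pulse(path, peak_v: float, dt: float = 5e-6) -> Waveform:
    """Load a sampled AM/FM pulse from a plain-text table (t_s, am, fm_hz).

    The waveform is resampled onto the requested raster by linear
    interpolation and the AM rescaled so its peak equals ``peak_v`` volts.
    """
    data = np.loadtxt(path)
    t, am, fm = data[:, 0], data[:, 1], data[:, 2]
    steps = np.diff(t)
    if steps.size and not np.allclose(steps, steps[0], rtol=1e-6):
        raise ValueError("input raster is not uniform")
    duration = t[-1] - t[0] + (steps[0] if steps.size else dt)
    n = int(round(duration / dt))
    tq = t[0] + (np.arange(n) + 0.5) * dt
    amq = np.interp(tq, t, am)
    fmq = np.interp(tq, t, fm)
    peak = np.abs(amq).max()
    if peak > 0:
        amq = amq * (peak_v / peak)
    return Waveform(amq[None, :].astype(complex), np.zeros((3, n)), dt, fmq)


def inversion_nrmse(m: Magnetization, mask: Mask | None = None) -> float:
    """Percent RMS deviation of the achieved flip from a perfect 180 degrees."""
    flip = m.flip_deg
    if mask is not None:
        if mask.data.shape != m.mask.data.shape:
            raise ValueError("mask shape mismatch")
        sub = mask.data[m.mask.data]
        if not sub.any():
            raise ValueError("mask is empty")
        flip = flip[sub]
    if flip.size == 0:
        raise ValueError("mask is empty")
    return float(100.0 * np.sqrt(np.mean((flip - 180.0) ** 2)) / 180.0)


def adiabatic_threshold(
    pulse_factory,
    peak_grid_v: np.ndarray,
    scale_ut_per_v: float,
    mz_target: float = -0.95,
) -> float:
    """Smallest peak voltage on a grid achieving on-resonance Mz <= target.

    The pulse is simulated for a single uniform channel of ``scale_ut_per_v``
    sensitivity at zero off-resonance.
    """
    mask = Mask(np.ones((1, 1, 1), bool), np.eye(4))
    b1 = B1MapSet(np.full((1, 1, 1, 1), scale_ut_per_v, dtype=complex), np.eye(4), mask)
    for v in np.sort(np.asarray(peak_grid_v, float)):
        mag = bloch_simulate(pulse_factory(v), b1, None, mask)
        if mag.m[0, 2] <= mz_target:
            return float(v)
    raise ValueError("no grid amplitude reached the target inversion")
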