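"""kT-points trajectory construction and small-tip-angle pulse design.

The design follows the spatial-domain small-tip-angle (STA) formalism: the
achieved flip-angle map is a linear operator applied to the per-channel,
per-kT-point complex drive amplitudes.  A magnitude least squares (MLS)
problem is solved by variable exchange (phase adoption) around a
conjugate-gradient inner solve, with optional global-power and VOP local-SAR
regularisation, and a region-growing schedule that suppresses localised
flip-angle drop-outs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .bloch import Waveform
from .constants import (
    G_MAX_T_PER_M,
    GAMMA_BAR_HZ_PER_T,
    PEAK_VOLTAGE_V,
    SLEW_MAX_T_PER_M_PER_S,
)
from .core import B1MapSet, FieldMap, FlipAngleMap, Mask


# --------------------------------------------------------------------------
# trajectory
# --------------------------------------------------------------------------


@dataclass
class TrapezoidBlip:
    """Per-axis symmetric trapezoid gradient lobe of fixed duration."""

    amplitude: np.ndarray  # (3,), signed T/m
    ramp: np.ndarray  # (3,), s
    duration: float  # s

    @property
    def area(self) -> np.ndarray:
        """Signed gradient area per axis, T s / m."""
        return self.amplitude * (self.duration - self.ramp)

    def sample(self, dt: float) -> np.ndarray:
        """(3, n) samples whose discrete area matches the analytic area."""
        n = int(round(self.duration / dt))
        t = (np.arange(n) + 0.5) * dt
        out = np.zeros((3, n))
        for ax in range(3):
            g, tr = self.amplitude[ax], self.ramp[ax]
            if g == 0.0:
                continue
            up = np.clip(t / tr, 0.0, 1.0) if tr > 0 else 1.0
            down = np.clip((self.duration - t) / tr, 0.0, 1.0) if tr > 0 else 1.0
            w = np.minimum(up, down)
            samples = g * w
            target = self.area[ax]
            total = samples.sum() * dt
            if total != 0.0:
                samples = samples * (target / total)
            out[ax] = samples
        return out


def _design_trapezoid(area: np.ndarray, duration: float, g_max: float, slew_max: float,
                      label: str) -> TrapezoidBlip:
    amplitude = np.zeros(3)
    ramp = np.zeros(3)
    for ax in range(3):
        a = float(area[ax])
        if a == 0.0:
            continue
        disc = duration**2 - 4.0 * abs(a) / slew_max
        if disc < 0:
            raise ValueError(
                f"blip {label}: area {a:.3e} T s/m unreachable in {duration*1e6:.0f} us "
                f"at slew {slew_max} T/m/s"
            )
        g = (duration - np.sqrt(disc)) * slew_max / 2.0
        if g > g_max * (1 + 1e-12):
            raise ValueError(
                f"blip {label}: required amplitude {g*1e3:.2f} mT/m exceeds "
                f"{g_max*1e3:.1f} mT/m"
            )
        amplitude[ax] = np.sign(a) * g
        ramp[ax] = g / slew_max
    return TrapezoidBlip(amplitude, ramp, duration)


@dataclass
class KTTrajectory:
    """Sparse excitation k-space trajectory with sub-pulse/blip timing.

    ``k_points`` uses the cycles convention (phase = 2 pi k . r); each point
    is played as one rectangular sub-pulse, followed by a gradient blip slot
    that moves to the next point (the final slot refocuses to the k-space
    centre, zero-area if the trajectory already ends there).
    """

    k_points: np.ndarray  # (n, 3), cycles/m
    subpulse_dur: float = 210e-6
    blip_dur: float = 70e-6
    blips: list = field(default_factory=list)
    g_max: float = G_MAX_T_PER_M
    slew_max: float = SLEW_MAX_T_PER_M_PER_S

    @property
    def n_points(self) -> int:
        return self.k_points.shape[0]

    @property
    def duration(self) -> float:
        return self.n_points * (self.subpulse_dur + self.blip_dur)

    def subpulse_centres(self) -> np.ndarray:
        j = np.arange(self.n_points)
        return j * (self.subpulse_dur + self.blip_dur) + self.subpulse_dur / 2.0

    def total_blip_area(self) -> np.ndarray:
        return np.sum([b.area for b in self.blips], axis=0)


def make_ktpoints_trajectory(
    k_radius: float = 6.33,
    n_axis_points: int = 6,
    subpulse_dur: float = 210e-6,
    blip_dur: float = 70e-6,
    g_max: float = G_MAX_T_PER_M,
    slew_max: float = SLEW_MAX_T_PER_M_PER_S,
) -> KTTrajectory:
    """Standard kT-points trajectory: centre, +-axis points, centre.

    With the defaults this yields eight 210 us rectangular sub-pulses with
    six axis points at +-6.33 1/m (roughly the inverse RF wavelength at
    9.4 T) interleaved with 70 us gradient blip slots, for a 2.24 ms total.
    """
    if subpulse_dur <= 0 or blip_dur <= 0:
        raise ValueError("durations must be positive")
    if n_axis_points < 0:
        raise ValueError("n_axis_points must be >= 0")
    axes = np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
        dtype=float,
    )
    pts = [np.zeros(3)]
    for i in range(n_axis_points):
        pts.append(k_radius * axes[i % 6])
    if n_axis_points > 0:
        pts.append(np.zeros(3))
    k_points = np.asarray(pts)

    gb = GAMMA_BAR_HZ_PER_T
    n = k_points.shape[0]
    blips = []
    for j in range(n):
        if j < n - 1:
            area = (k_points[j + 1] - k_points[j]) / gb
        else:
            area = -k_points[j] / gb  # refocus to centre
        blips.append(
            _design_trapezoid(area, blip_dur, g_max, slew_max, f"{j}->{(j + 1) % n}")
        )
    return KTTrajectory(k_points, subpulse_dur, blip_dur, blips, g_max, slew_max)


# --------------------------------------------------------------------------
# STA system
# --------------------------------------------------------------------------


@dataclass
class STASystem:
    """Linear small-tip operator: per-voxel flip (degrees) = |A @ b| (b in V).

    Column ordering is point-major: column ``j * n_channels + c`` holds
    sub-pulse j of channel c.  Off-resonance phase is referenced to the pulse
    end.
    """

    A: np.ndarray  # (n_voxels, n_channels * n_points), complex, deg/V
    positions_mm: np.ndarray
    df_hz: np.ndarray
    t_centres: np.ndarray
    T: float
    mask: Mask
    n_channels: int
    n_points: int
    affine: np.ndarray
    sens_abs: np.ndarray  # (n_voxels, n_channels), |s_c| in uT/V

    def flip(self, b: np.ndarray) -> np.ndarray:
        return np.abs(self.A @ np.asarray(b, complex).reshape(-1))


def build_sta_system(
    b1: B1MapSet,
    b0: FieldMap | None,
    traj: KTTrajectory,
    mask: Mask,
) -> STASystem:
    """Assemble the spatial-domain STA matrix for a kT-points trajectory."""
    if mask.n_voxels == 0:
        raise ValueError("mask is empty")
    if mask.data.shape != b1.shape:
        raise ValueError("mask grid does not match the B1 maps")
    if b0 is not None and b0.values.shape != b1.shape:
        raise ValueError("B0 grid does not match the B1 maps")
    sel = mask.data
    sens = b1.maps[:, sel].T  # (n_vox, n_ch), uT/V
    pos_m = mask.coords_mm() * 1e-3
    df = b0.values[sel] if b0 is not None else np.zeros(sel.sum())
    gb = GAMMA_BAR_HZ_PER_T
    tau = traj.subpulse_dur
    tj = traj.subpulse_centres()
    T = traj.duration
    nv, nc = sens.shape
    npts = traj.n_points
    A = np.empty((nv, npts * nc), dtype=complex)
    scale = 360.0 * gb * 1e-6 * tau  # deg per (uT/V * V)
    for j in range(npts):
        spatial = np.exp(
            2j * np.pi * (pos_m @ traj.k_points[j] + df * (tj[j] - T))
        )
        A[:, j * nc : (j + 1) * nc] = scale * sens * spatial[:, None]
    return STASystem(
        A, pos_m * 1e3, df, tj, T, mask, nc, npts, b1.affine, np.abs(sens)
    )


# --------------------------------------------------------------------------
# MLS solver
# --------------------------------------------------------------------------


@dataclass
class RFWeights:
    """Designed complex drive amplitudes (volts), channels x kT-points."""

    weights: np.ndarray  # (n_channels, n_points)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=complex)

    @property
    def flat(self) -> np.ndarray:
        # point-major flattening, matching the STA column ordering
        return self.weights.T.reshape(-1)

    def peak_violations(self, peak_v: float = PEAK_VOLTAGE_V):
        ch, pt = np.where(np.abs(self.weights) > peak_v)
        return list(zip(ch.tolist(), pt.tolist()))

    def save_json(self, path) -> None:
        payload = {
            "weights_real": self.weights.real.tolist(),
            "weights_imag": self.weights.imag.tolist(),
            "metadata": {k: v for k, v in self.metadata.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=str))


def _hermitian_cg(H, rhs, x0, iters, tol):
    """Conjugate gradients for a Hermitian positive-definite dense system."""
    x = x0.copy()
    r = rhs - H @ x
    p = r.copy()
    rs = np.real(np.vdot(r, r))
    ref = max(np.real(np.vdot(rhs, rhs)), 1e-300)
    for _ in range(iters):
        if rs <= tol**2 * ref:
            break
        Hp = H @ p
        alpha = rs / np.real(np.vdot(p, Hp))
        x = x + alpha * p
        r = r - alpha * Hp
        rs_new = np.real(np.vdot(r, r))
        p = r + (rs_new / rs) * p
        rs = rs_new
    return x


def _objective(A, b, target, lambda_global, lambda_local, vops, nc):
    resid = np.abs(A @ b) - target
    obj = float(resid @ resid) + lambda_global * float(np.real(np.vdot(b, b)))
    if vops is not None and lambda_local > 0:
        bm = b.reshape(-1, nc)
        sar = np.real(np.einsum("pi,vij,pj->v", bm.conj(), vops, bm))
        obj += lambda_local * float(np.max(sar))
    return obj


def solve_mls(
    system: STASystem,
    target_fa: float,
    lambda_global: float = 1e-3,
    lambda_local: float = 0.0,
    vops=None,
    cg_iters: int = 200,
    tol: float = 1e-6,
    seed: int = 0,
    max_outer: int = 50,
    init: np.ndarray | None = None,
    phase_target: np.ndarray | None = None,
    row_subset: np.ndarray | None = None,
) -> RFWeights:
    """Magnitude least squares design by variable exchange.

    Approximately minimises ``|| |A b| - theta_t ||^2 + lambda_g ||b||^2 +
    lambda_l b^H S_active b`` where ``S_active`` is the currently maximal VOP,
    re-selected each outer iteration.  The phase of the target is repeatedly
    replaced by the phase of the current excitation profile; each inner
    problem is an ordinary regularised least squares solved with conjugate
    gradients.  The total objective is kept non-increasing by damping the
    update whenever a full exchange step would increase it.
    """
    if target_fa <= 0:
        raise ValueError("target flip angle must be positive")
    if lambda_global < 0 or lambda_local < 0:
        raise ValueError("regularisation weights must be non-negative")
    A = system.A if row_subset is None else system.A[row_subset]
    if not np.all(np.isfinite(A)):
        raise ValueError("STA system contains non-finite entries")
    nv, ncol = A.shape
    nc = system.n_channels
    vmats = None
    if vops is not None:
        vmats = np.asarray(getattr(vops, "matrices", vops), dtype=complex)
        if vmats.shape[1] != nc:
            raise ValueError("VOP dimension does not match the channel count")

    target = np.full(nv, float(target_fa))
    AhA = A.conj().T @ A
    reg = lambda_global * np.eye(ncol)

    if init is not None:
        b = np.asarray(init, complex).reshape(-1).copy()
    else:
        b = _cp_init(system, A, target_fa)
    if phase_target is not None:
        phase = np.asarray(phase_target, float)
    else:
        phase = np.angle(A @ b)

    obj = _objective(A, b, target, lambda_global, lambda_local, vmats, nc)
    n_outer = 0
    converged = False
    for n_outer in range(1, max_outer + 1):
        H = AhA + reg
        if vmats is not None and lambda_local > 0:
            iv, _ = _active_vop_blocked(b, vmats, nc)
            H = H + lambda_local * np.kron(np.eye(system.n_points), vmats[iv])
        rhs = A.conj().T @ (target * np.exp(1j * phase))
        b_new = _hermitian_cg(H, rhs, b, cg_iters, 1e-12)
        # damp the step if the exchanged objective would increase
        step = b_new - b
        scale = 1.0
        for _ in range(12):
            cand = b + scale * step
            obj_new = _objective(A, cand, target, lambda_global, lambda_local, vmats, nc)
            if obj_new <= obj + 1e-12 * max(obj, 1.0):
                break
            scale *= 0.5
        else:
            break  # no improving step: converged at a fixed point
        b = b + scale * step
        phase = np.angle(A @ b)
        if obj - obj_new < tol * max(obj, 1e-30):
            obj = obj_new
            converged = True
            break
        obj = obj_new

    flips = np.abs(A @ b)
    achieved_nrmse = float(100.0 * np.sqrt(np.mean((flips - target_fa) ** 2)) / target_fa)
    meta = {
        "lambda_global": lambda_global,
        "lambda_local": lambda_local,
        "iterations": n_outer,
        "achieved_nrmse_percent": achieved_nrmse,
        "objective": obj,
        "converged": converged,
    }
    if not converged:
        meta["warning"] = "variable exchange stopped at the iteration budget"
    return RFWeights(b.reshape(system.n_points, nc).T, meta)


def _active_vop_blocked(b, vmats, nc):
    bm = b.reshape(-1, nc)
    sar = np.real(np.einsum("pi,vij,pj->v", bm.conj(), vmats, bm))
    return int(np.argmax(sar)), float(np.max(sar))


def _cp_init(system: STASystem, A: np.ndarray, target_fa: float) -> np.ndarray:
    """CP-mode drive on the centre kT-point, least-squares scaled to target."""
    nc, npts = system.n_channels, system.n_points
    j0 = 0  # trajectory starts at the k-space centre
    b = np.zeros(nc * npts, dtype=complex)
    # align channel phases at the strongest-sensitivity voxel of this subproblem
    v0 = int(np.argmax(np.abs(A[:, j0 * nc : (j0 + 1) * nc]).sum(axis=1)))
    cols = A[v0, j0 * nc : (j0 + 1) * nc]
    w = np.exp(-1j * np.angle(cols))
    b[j0 * nc : (j0 + 1) * nc] = w
    prof = A @ b
    scale = float(target_fa * np.sum(np.abs(prof)) / np.sum(np.abs(prof) ** 2))
    return scale * b


def region_growing_solve(
    system: STASystem,
    target_fa: float,
    seed_fraction: float = 0.1,
    dilate_vox: int = 2,
    min_flip_fraction: float = 0.5,
    seed: int = 0,
    **solve_kwargs,
) -> RFWeights:
    """MLS design with a region-growing target schedule.

    The design starts on a seed subregion (the highest combined-|B1+|
    fraction of the mask), then the target region is repeatedly enlarged by
    morphological dilation inside the mask; each enlarged problem adopts the
    previous solution's achieved phase as its phase target.  This prevents
    the magnitude-least-squares phase freedom from settling into solutions
    with localised flip-angle drop-outs.
    """
    if not 0 < seed_fraction <= 1:
        raise ValueError("seed_fraction must lie in (0, 1]")
    mask_vol = system.mask.data
    quality = np.zeros(mask_vol.shape)
    quality[mask_vol] = system.sens_abs.sum(axis=1)
    thresh = np.quantile(quality[mask_vol], 1.0 - seed_fraction)
    region = (quality >= thresh) & mask_vol
    if not region.any():
        region = mask_vol.copy()

    in_mask_index = np.full(mask_vol.shape, -1, dtype=int)
    in_mask_index[mask_vol] = np.arange(mask_vol.sum())

    weights = None
    phase = None
    while True:
        rows = in_mask_index[region & mask_vol]
        res = solve_mls(
            system,
            target_fa,
            seed=seed,
            init=None if weights is None else weights.flat,
            phase_target=phase,
            row_subset=rows,
            **solve_kwargs,
        )
        weights = res
        if np.array_equal(region, mask_vol):
            break
        grown = ndimage.binary_dilation(region, iterations=dilate_vox) & mask_vol
        if np.array_equal(grown, region):
            grown = mask_vol.copy()
        region = grown
        rows_next = in_mask_index[region]
        phase = np.angle(system.A[rows_next] @ weights.flat)

    flips = system.flip(weights.flat)
    min_frac = float(flips.min() / target_fa)
    weights.metadata["min_flip_fraction"] = min_frac
    weights.metadata["achieved_nrmse_percent"] = float(
        100.0 * np.sqrt(np.mean((flips - target_fa) ** 2)) / target_fa
    )
    if min_frac < min_flip_fraction:
        weights.metadata["warning"] = (
            f"minimum in-mask flip is {min_frac:.2f} of target"
        )
    return weights


# --------------------------------------------------------------------------
# prediction, metrics, waveform assembly
# --------------------------------------------------------------------------


def predict_flip_angle(system: STASystem, weights: RFWeights) -> FlipAngleMap:
    """STA-predicted flip-angle map |A b| on the mask grid."""
    b = weights.flat
    if b.shape[0] != system.A.shape[1]:
        raise ValueError("weights do not match the STA system dimensions")
    vol = np.zeros(system.mask.data.shape)
    vol[system.mask.data] = system.flip(b)
    return FlipAngleMap(vol, system.affine, mask=system.mask)


def nrmse(achieved: FlipAngleMap, target_fa: float, mask: Mask | None = None) -> float:
    """Percent normalised RMSE of a flip-angle map against a uniform target."""
    if target_fa <= 0:
        raise ValueError("target flip angle must be positive")
    if mask is None:
        mask = achieved.mask
    if mask is None or mask.n_voxels == 0:
        raise ValueError("mask is empty")
    v = achieved.values[mask.data]
    return float(100.0 * np.sqrt(np.mean((v - target_fa) ** 2)) / target_fa)


def assemble_waveforms(
    weights: RFWeights,
    traj: KTTrajectory,
    dt: float = 5e-6,
    peak_v: float = PEAK_VOLTAGE_V,
) -> Waveform:
    """Sampled per-channel RF and gradient waveforms for a kT-points pulse.

    Piecewise-constant RF during sub-pulses, zero during blips; gradients
    zero during sub-pulses and trapezoidal during blip slots.  The raster
    must divide both durations exactly.
    """
    ns = traj.subpulse_dur / dt
    nb = traj.blip_dur / dt
    if abs(ns - round(ns)) > 1e-9 or abs(nb - round(nb)) > 1e-9:
        raise ValueError("raster time must divide sub-pulse and blip durations")
    ns, nb = int(round(ns)), int(round(nb))
    viol = weights.peak_violations(peak_v)
    if viol:
        ch, pt = viol[0]
        raise ValueError(
            f"peak voltage exceeded on channel {ch}, sub-pulse {pt} "
            f"(|b| = {np.abs(weights.weights[ch, pt]):.1f} V > {peak_v} V)"
        )
    nc, npts = weights.weights.shape
    if npts != traj.n_points:
        raise ValueError("weights do not match the trajectory point count")
    n_t = npts * (ns + nb)
    rf = np.zeros((nc, n_t), dtype=complex)
    grad = np.zeros((3, n_t))
    for j in range(npts):
        start = j * (ns + nb)
        rf[:, start : start + ns] = weights.weights[:, j][:, None]
        grad[:, start + ns : start + ns + nb] = traj.blips[j].sample(dt)
    return Waveform(rf, grad, dt)


def export_pulse(weights: RFWeights, traj: KTTrajectory, outdir, dt: float = 5e-6) -> None:
    """Write HDF5 + plain-text waveforms and a JSON design report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    wave = assemble_waveforms(weights, traj, dt)
    wave.save_hdf5(outdir / "pulse.h5")
    wave.save_txt(outdir / "pulse.txt")
    weights.save_json(outdir / "design.json")
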