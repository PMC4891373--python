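"""Local/global SAR evaluation from virtual-observation-point (VOP) matrices.

VOPs are a small set of Hermitian PSD channel-covariance-to-SAR matrices that
conservatively upper-bound the 10 g local SAR of every tissue voxel for any
drive.  This module evaluates per-pulse and per-sequence SAR against the
IEC 60601-2-33 short- and long-term limits, provides a greedy VOP
compression with an explicit overestimation guarantee, and generates
synthetic PSD SAR-matrix fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np

# IEC 60601-2-33 local 10 g SAR limits (first-level controlled mode, head)
LIMIT_10S_W_PER_KG = 20.0
LIMIT_6MIN_W_PER_KG = 10.0


@dataclass
class VOPSet:
    """Stack of Hermitian PSD matrices, W/kg per V^2 at 100 % duty."""

    matrices: np.ndarray  # (n_vops, n_channels, n_channels), complex
    safety_factor: float = 2.0
    provenance: str = "synthetic"

    def __post_init__(self):
        self.matrices = np.asarray(self.matrices, dtype=complex)
        if self.matrices.ndim == 2:
            self.matrices = self.matrices[None]
        herm_err = np.abs(self.matrices - self.matrices.conj().transpose(0, 2, 1)).max()
        scale = max(np.abs(self.matrices).max(), 1.0)
        if herm_err > 1e-12 * scale:
            raise ValueError("VOP matrices must be Hermitian")
        eigs = np.linalg.eigvalsh(self.matrices)
        if eigs.min() < -1e-12 * scale:
            raise ValueError("VOP matrices must be positive semidefinite")

    @property
    def n_vops(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_channels(self) -> int:
        return self.matrices.shape[1]

    def sar_per_vop(self, drives: np.ndarray) -> np.ndarray:
        """Instantaneous SAR (W/kg at 100 % duty) per VOP for drive vector(s).

        ``drives`` is (n_channels,) or (n_samples, n_channels) volts; for the
        latter the result is averaged over samples (equal weights).
        """
        d = np.atleast_2d(np.asarray(drives, dtype=complex))
        sar = np.real(np.einsum("ti,vij,tj->v", d.conj(), self.matrices, d))
        return sar / d.shape[0]

    def save_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("matrices", data=self.matrices)
            f.attrs["safety_factor"] = self.safety_factor
            f.attrs["provenance"] = self.provenance

    @classmethod
    def load_hdf5(cls, path) -> "VOPSet":
        with h5py.File(path, "r") as f:
            return cls(
                np.asarray(f["matrices"]),
                float(f.attrs["safety_factor"]),
                str(f.attrs["provenance"]),
            )


@dataclass
class SARReport:
    """Per-pulse and windowed local-SAR summary."""

    max_sar_per_tr: float  # W/kg, before the safety factor
    max_sar_with_safety: float
    per_vop: np.ndarray
    tr: float
    sar_10s: float | None = None
    sar_6min: float | None = None
    within_10s_limit: bool | None = None
    within_6min_limit: bool | None = None

    def as_dict(self) -> dict:
        return {
            "max_sar_per_tr_w_per_kg": self.max_sar_per_tr,
            "max_sar_with_safety_w_per_kg": self.max_sar_with_safety,
            "tr_s": self.tr,
            "sar_10s_w_per_kg": self.sar_10s,
            "sar_6min_w_per_kg": self.sar_6min,
            "within_10s_limit": self.within_10s_limit,
            "within_6min_limit": self.within_6min_limit,
        }


def _drive_energy(weights_or_waveform, subpulse_dur: float | None):
    """(drives, durations): per-sample drive vectors and their durations."""
    from .bloch import Waveform
    from .ktpulse import RFWeights

    if isinstance(weights_or_waveform, Waveform):
        w = weights_or_waveform
        return w.rf.T, np.full(w.n_samples, w.dt)
    if isinstance(weights_or_waveform, RFWeights):
        if subpulse_dur is None:
            raise ValueError("subpulse duration required with RFWeights input")
        return weights_or_waveform.weights.T, np.full(
            weights_or_waveform.weights.shape[1], subpulse_dur
        )
    arr = np.asarray(weights_or_waveform, dtype=complex)
    if subpulse_dur is None:
        raise ValueError("subpulse duration required with array input")
    return np.atleast_2d(arr), np.full(np.atleast_2d(arr).shape[0], subpulse_dur)


def pulse_sar(
    weights_or_waveform,
    vops: VOPSet,
    tr: float,
    subpulse_dur: float | None = None,
) -> SARReport:
    """Maximum 10 g local SAR per TR of a pulse played every ``tr`` seconds.

    Per VOP: ``SAR_v = (1/TR) sum_samples dt * b^H S_v b``; the report carries
    both the raw maximum over VOPs and the value after the safety factor.
    """
    if tr <= 0:
        raise ValueError("TR must be positive")
    drives, durs = _drive_energy(weights_or_waveform, subpulse_dur)
    if drives.shape[1] != vops.n_channels:
        raise ValueError("drive dimension does not match the VOP channel count")
    quad = np.real(np.einsum("ti,vij,tj->vt", drives.conj(), vops.matrices, drives))
    per_vop = (quad * durs[None, :]).sum(axis=1) / tr
    mx = float(per_vop.max())
    return SARReport(
        max_sar_per_tr=mx,
        max_sar_with_safety=mx * vops.safety_factor,
        per_vop=per_vop,
        tr=tr,
    )


def sequence_lookahead(
    events: list[tuple],
    vops: VOPSet,
    tr: float,
    duty: float = 1.0,
) -> SARReport:
    """Windowed SAR projection for a steadily repeating sequence.

    ``events`` is a list of ``(weights_or_waveform, subpulse_dur_or_None)``
    pairs played once per TR; ``duty`` scales for duty-cycled sequences
    (e.g. 0.5 when pulsing every other TR).  The 10 s and 6 min windowed
    averages equal the per-TR average under steady repetition and are checked
    against the 20 and 10 W/kg IEC 60601-2-33 local limits (after the safety
    factor).
    """
    if not 0 <= duty <= 1:
        raise ValueError("duty must lie in [0, 1]")
    per_vop = np.zeros(vops.n_vops)
    for item, sub in events:
        per_vop = per_vop + pulse_sar(item, vops, tr, sub).per_vop
    per_vop = per_vop * duty
    mx = float(per_vop.max())
    with_safety = mx * vops.safety_factor
    return SARReport(
        max_sar_per_tr=mx,
        max_sar_with_safety=with_safety,
        per_vop=per_vop,
        tr=tr,
        sar_10s=with_safety,
        sar_6min=with_safety,
        within_10s_limit=bool(with_safety <= LIMIT_10S_W_PER_KG),
        within_6min_limit=bool(with_safety <= LIMIT_6MIN_W_PER_KG),
    )


def vop_compress(matrices: np.ndarray, epsilon: float, safety_factor: float = 2.0) -> VOPSet:
    """Greedy dominance compression of a stack of SAR matrices.

    A matrix Q is dropped when a retained matrix P (plus the overestimation
    term ``epsilon * lambda_max * I``) dominates it in the PSD order.  Each
    retained matrix is emitted with the overestimation term added, so the
    compressed set upper-bounds the SAR of every original matrix for every
    drive.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    mats = np.asarray(matrices, dtype=complex)
    if mats.ndim == 2:
        mats = mats[None]
    scale = max(np.abs(mats).max(), 1.0)
    if np.abs(mats - mats.conj().transpose(0, 2, 1)).max() > 1e-10 * scale:
        raise ValueError("input matrices must be Hermitian")
    eigs = np.linalg.eigvalsh(mats)
    if eigs.min() < -1e-10 * scale:
        raise ValueError("input matrices must be positive semidefinite")

    lam = float(eigs.max())
    n_ch = mats.shape[1]
    pad = epsilon * lam * np.eye(n_ch)
    order = np.argsort(-eigs.max(axis=1))  # strongest first
    retained: list[int] = []
    for i in order:
        dominated = False
        for j in retained:
            diff = mats[j] + pad - mats[i]
            if np.linalg.eigvalsh(diff)[0] >= -1e-12 * lam:
                dominated = True
                break
        if not dominated:
            retained.append(int(i))
    vop_mats = mats[retained] + pad[None]
    return VOPSet(vop_mats, safety_factor=safety_factor, provenance="compressed")


def random_psd_matrices(
    n_matrices: int,
    n_channels: int,
    seed: int = 0,
    eig_decay: float = 1.0,
    scale: float = 1.0,
    worst_pair: bool = True,
) -> np.ndarray:
    """Synthetic SAR-matrix fixtures: random PSD with controlled spectra.

    Optionally injects a "worst-case channel pair" structure (one matrix
    dominated by strong coupling between two adjacent channels) so that
    local-SAR regularisation has a distinct target to suppress.
    """
    rng = np.random.default_rng(seed)
    mats = np.empty((n_matrices, n_channels, n_channels), dtype=complex)
    for i in range(n_matrices):
        q, _ = np.linalg.qr(
            rng.standard_normal((n_channels, n_channels))
            + 1j * rng.standard_normal((n_channels, n_channels))
        )
        eigs = scale * np.exp(-eig_decay * np.arange(n_channels)) * rng.uniform(
            0.5, 1.5, n_channels
        )
        m = (q * eigs) @ q.conj().T
        mats[i] = (m + m.conj().T) / 2.0
    if worst_pair and n_matrices > 0 and n_channels >= 2:
        a, b = 0, 1
        e = np.zeros(n_channels, dtype=complex)
        e[a] = 1.0
        e[b] = 1j
        m = 2.0 * scale * np.outer(e, e.conj())
        mats[0] = (m + m.conj().T) / 2.0
    return mats
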