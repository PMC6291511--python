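"""Phase lag index (PLI) connectivity estimation.

The PLI between two signals is the absolute mean of the sign of the sine of
their instantaneous phase difference::

    PLI = | < sign( sin(dPhi(t_k)) ) > |

where the phases come from the analytic (Hilbert) representation of
band-limited signals, and < > averages over time samples.  PLI is 0 when the
phase difference has no consistent sign (including exactly zero lag — which
makes the metric blind to volume conduction / field spread) and 1 when one
signal consistently leads the other.

One symmetric zero-diagonal matrix is computed per epoch; the subject-level
matrix is the arithmetic mean over epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from .spectral import BandDefinition, EpochSet

#: |sin(dPhi)| below this is treated as an exact zero lag (contributes 0 to
#: the sign average) so floating-point rounding cannot inject sign noise.
SIN_ZERO_TOL = 1e-12


@dataclass
class ConnectivityMatrix:
    """Symmetric ROI x ROI PLI matrix in [0, 1] with zero diagonal."""

    values: np.ndarray
    band: BandDefinition | None = None
    subject_id: str = ""
    n_epochs_averaged: int = 1
    roi_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"connectivity matrix must be square, got {v.shape}")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        if np.any(np.abs(np.diag(v)) > 1e-12):
            raise ValueError("connectivity matrix diagonal must be zero")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("PLI values must lie in [0, 1]")
        if not self.roi_labels:
            self.roi_labels = [f"ROI{i:02d}" for i in range(v.shape[0])]

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


def instantaneous_phase(epoch: np.ndarray) -> np.ndarray:
    """Instantaneous phase of each ROI via the analytic signal.

    Parameters
    ----------
    epoch : (n_rois, epoch_samples) array of band-limited signals.

    Returns
    -------
    (n_rois, epoch_samples) array of phases in (-pi, pi].
    """
    epoch = np.asarray(epoch, dtype=float)
    if epoch.ndim == 1:
        epoch = epoch[None, :]
    if np.any(np.all(epoch == 0, axis=1)):
        bad = np.where(np.all(epoch == 0, axis=1))[0]
        raise ValueError(f"phase undefined for all-zero channel(s) {bad.tolist()}")
    analytic = hilbert(epoch, axis=1)
    return np.angle(analytic)


def pli_pair(phase_i: np.ndarray, phase_j: np.ndarray) -> float:
    """PLI of a single pair of phase sequences.

    ``sign(0)`` is the mathematical signum (0), so exact-zero phase
    differences dilute the average rather than biasing it.
    """
    phase_i = np.asarray(phase_i, dtype=float)
    phase_j = np.asarray(phase_j, dtype=float)
    if phase_i.shape != phase_j.shape:
        raise ValueError(f"length mismatch: {phase_i.shape} vs {phase_j.shape}")
    if phase_i.size < 1:
        raise ValueError("need at least one sample")
    s = np.sin(phase_i - phase_j)
    s[np.abs(s) < SIN_ZERO_TOL] = 0.0
    return float(abs(np.mean(np.sign(s))))


try:  # fast pairwise kernel; pure-numpy fallback below
    from numba import njit

    @njit(cache=True)
    def _pli_kernel(c: np.ndarray, s: np.ndarray, tol: float) -> np.ndarray:
        n, t = c.shape
        out = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                acc = 0.0
                for k in range(t):
                    # sin(phi_i - phi_j) via the angle-difference identity
                    v = s[i, k] * c[j, k] - c[i, k] * s[j, k]
                    if v > tol:
                        acc += 1.0
                    elif v < -tol:
                        acc -= 1.0
                p = abs(acc) / t
                out[i, j] = p
                out[j, i] = p
        return out

except ImportError:  # pragma: no cover

    def _pli_kernel(c: np.ndarray, s: np.ndarray, tol: float) -> np.ndarray:
        v = s[:, None, :] * c[None, :, :] - c[:, None, :] * s[None, :, :]
        v[np.abs(v) < tol] = 0.0
        out = np.abs(np.mean(np.sign(v), axis=2))
        np.fill_diagonal(out, 0.0)
        return (out + out.T) / 2


def pli_from_phases(phases: np.ndarray) -> np.ndarray:
    """Symmetric zero-diagonal PLI matrix from an (n_rois, t) phase array."""
    phases = np.ascontiguousarray(phases)
    return _pli_kernel(np.cos(phases), np.sin(phases), SIN_ZERO_TOL)


def pli_matrix(epochs: EpochSet) -> list[ConnectivityMatrix]:
    """One symmetric zero-diagonal PLI matrix per epoch."""
    out: list[ConnectivityMatrix] = []
    for e in range(epochs.n_epochs):
        phases = instantaneous_phase(epochs.epochs[e])
        mat = pli_from_phases(phases)
        out.append(
            ConnectivityMatrix(
                mat,
                band=epochs.band,
                subject_id=epochs.subject_id,
                n_epochs_averaged=1,
                roi_labels=list(epochs.roi_labels),
            )
        )
    return out


def average_epochs(per_epoch: list[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Merge per-epoch matrices by elementwise arithmetic average."""
    if not per_epoch:
        raise ValueError("need at least one matrix")
    first = per_epoch[0]
    for m in per_epoch[1:]:
        if m.values.shape != first.values.shape:
            raise ValueError("cannot average matrices of different shapes")
        if (m.band is None) != (first.band is None) or (
            m.band is not None and first.band is not None and m.band.name != first.band.name
        ):
            raise ValueError("cannot average matrices from different bands")
    mean = np.mean([m.values for m in per_epoch], axis=0)
    return ConnectivityMatrix(
        mean,
        band=first.band,
        subject_id=first.subject_id,
        n_epochs_averaged=len(per_epoch),
        roi_labels=list(first.roi_labels),
    )


def subject_pli(epochs: EpochSet) -> ConnectivityMatrix:
    """Convenience: per-epoch PLI matrices merged into one subject matrix."""
    return average_epochs(pli_matrix(epochs))
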