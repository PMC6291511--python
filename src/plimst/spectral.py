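"""Band-pass filtering, downsampling and epoching of ROI time series.

The entry point of the pipeline is a :class:`RoiTimeSeries` — a real-valued
``(n_rois, n_samples)`` matrix of source-reconstructed signals with a known
sampling rate.  This module decomposes it into the five canonical frequency
bands (delta through gamma), decimates it to a working rate, and cuts it into
fixed-length contiguous epochs.

All filtering is zero-phase (forward-backward Butterworth), which matters
because everything downstream is a *phase* metric: a filter with group delay
would corrupt the very quantity being estimated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band with -3 dB corner frequencies in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi):
            raise ValueError(f"band {self.name!r}: need 0 < lo < hi, got ({self.lo}, {self.hi})")

    def validate_for_fs(self, fs: float) -> None:
        if self.hi >= fs / 2:
            raise ValueError(
                f"band {self.name!r} upper edge {self.hi} Hz >= Nyquist {fs / 2} Hz at fs={fs}"
            )


#: The five canonical resting-state bands.
CANONICAL_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 30.0, 48.0),
)

BAND_BY_NAME: dict[str, BandDefinition] = {b.name: b for b in CANONICAL_BANDS}


@dataclass
class RoiTimeSeries:
    """Multichannel ROI signal: rows are ROIs, columns are time samples."""

    data: np.ndarray
    fs: float
    roi_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"data must be 2-D (n_rois, n_samples), got shape {self.data.shape}")
        n_rois, n_samples = self.data.shape
        if n_rois < 2 or n_samples < 2:
            raise ValueError(f"need >= 2 ROIs and >= 2 samples, got {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time series contains non-finite values")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not self.roi_labels:
            self.roi_labels = [f"ROI{i:02d}" for i in range(n_rois)]
        if len(self.roi_labels) != n_rois:
            raise ValueError("roi_labels length does not match number of ROIs")
        if len(set(self.roi_labels)) != n_rois:
            raise ValueError("roi_labels must be unique")

    @property
    def n_rois(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class EpochSet:
    """Contiguous non-overlapping epochs: ``(n_epochs, n_rois, epoch_samples)``."""

    epochs: np.ndarray
    fs: float
    band: BandDefinition | None
    subject_id: str = ""
    roi_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D (n_epochs, n_rois, epoch_samples)")
        if not self.roi_labels:
            self.roi_labels = [f"ROI{i:02d}" for i in range(self.epochs.shape[1])]

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_rois(self) -> int:
        return self.epochs.shape[1]

    @property
    def epoch_samples(self) -> int:
        return self.epochs.shape[2]


def downsample(ts: RoiTimeSeries, target_fs: float) -> RoiTimeSeries:
    """Decimate to ``target_fs`` after anti-alias low-pass filtering.

    The decimation factor ``fs / target_fs`` must be an integer.  ``target_fs``
    must exceed twice the highest canonical band edge (48 Hz), i.e. 96 Hz, so
    that every band survives the decimation.
    """
    factor_f = ts.fs / target_fs
    factor = int(round(factor_f))
    if abs(factor_f - factor) > 1e-9 or factor < 1:
        raise ValueError(
            f"target_fs={target_fs} does not evenly divide fs={ts.fs} (factor {factor_f:.4f})"
        )
    max_edge = max(b.hi for b in CANONICAL_BANDS)
    if target_fs <= 2 * max_edge:
        raise ValueError(
            f"target_fs={target_fs} Hz must exceed {2 * max_edge} Hz to retain the gamma band"
        )
    if factor == 1:
        return RoiTimeSeries(ts.data.copy(), ts.fs, list(ts.roi_labels))
    # scipy.signal.decimate: order-8 Chebyshev-I anti-alias filter, zero-phase.
    out = signal.decimate(ts.data, factor, axis=1, ftype="iir", zero_phase=True)
    return RoiTimeSeries(out, target_fs, list(ts.roi_labels))


def _butter_sos(band: BandDefinition, fs: float, order: int = 4):
    lo, hi = band.lo, band.hi
    nyq = fs / 2
    if hi >= nyq:
        raise ValueError(f"band {band.name!r} exceeds Nyquist ({nyq} Hz) at fs={fs}")
    try:
        sos = signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    except ValueError as exc:  # pragma: no cover - scipy diagnostics vary
        raise ValueError(f"cannot design band-pass for {band.name!r} at fs={fs}: {exc}") from exc
    if not np.all(np.isfinite(sos)):
        raise ValueError(f"band {band.name!r} too narrow for a stable filter at fs={fs}")
    return sos


def bandpass(ts: RoiTimeSeries, band: BandDefinition, order: int = 4) -> RoiTimeSeries:
    """Zero-phase Butterworth band-pass (order per pass; applied forward-backward).

    Zero net group delay preserves instantaneous phase, the quantity the
    phase lag index is built from.
    """
    band.validate_for_fs(ts.fs)
    sos = _butter_sos(band, ts.fs, order=order)
    out = signal.sosfiltfilt(sos, ts.data, axis=1)
    return RoiTimeSeries(out, ts.fs, list(ts.roi_labels))


def segment_epochs(
    ts: RoiTimeSeries,
    epoch_len: float = 8.0,
    n_epochs: int = 10,
    band: BandDefinition | None = None,
    subject_id: str = "",
) -> EpochSet:
    """Cut the first ``n_epochs`` contiguous windows of ``epoch_len`` seconds.

    Surplus samples at the end are discarded; too few samples is an error that
    names the shortfall.
    """
    epoch_samples = int(round(ts.fs * epoch_len))
    needed = n_epochs * epoch_samples
    if ts.n_samples < needed:
        raise ValueError(
            f"insufficient samples: need {needed} ({n_epochs} x {epoch_samples}), "
            f"have {ts.n_samples} (short by {needed - ts.n_samples})"
        )
    trimmed = ts.data[:, :needed]
    epochs = trimmed.reshape(ts.n_rois, n_epochs, epoch_samples).transpose(1, 0, 2)
    return EpochSet(epochs.copy(), ts.fs, band, subject_id, list(ts.roi_labels))
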