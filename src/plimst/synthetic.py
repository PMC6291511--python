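"""Synthetic cohorts of phase-coupled ROI time series with known ground truth.

Real resting-state source-space recordings for this kind of study are rarely
deposited, so every downstream stage is exercised on simulated cohorts whose
coupling structure is known exactly.

Generative model
----------------
For every coupled ROI pair a *shared* narrow-band stochastic carrier is drawn
(white noise band-passed to ``carrier_band``, normalized to unit variance).
The first ROI receives the carrier scaled by the coupling strength; the second
receives the carrier's analytic signal rotated by the requested phase lag
(a frequency-flat rotation, so the imposed lag is constant across the band),
also scaled by the strength.  Independent band-limited noise of standard
deviation ``noise_sd`` is added to every ROI; ROIs in no coupled pair carry
noise only.  A lag of exactly 0 or pi is legal and, by construction of the
phase lag index, invisible to it.

Everything is a pure function of (spec, seed): identical inputs give
bit-identical signals.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .spectral import RoiTimeSeries

TWO_PI = 2 * math.pi
_SEED_MOD = 2**31


def wrap_phase(lag: float) -> float:
    """Wrap a phase lag to (-pi, pi]."""
    w = (lag + math.pi) % TWO_PI - math.pi
    return math.pi if w == -math.pi else w


@dataclass(frozen=True)
class CouplingEdge:
    roi_i: int
    roi_j: int
    phase_lag: float  # radians, wrapped to (-pi, pi]; j lags i by this much
    strength: float  # in [0, 1]


@dataclass(frozen=True)
class CouplingSpec:
    """Full description of one group's generative process."""

    n_rois: int = 90
    fs: float = 512.0
    epoch_len: float = 8.0
    n_epochs: int = 10
    #: carriers sit in the interior of the target analysis band: the -3 dB
    #: corners of the analysis filters are at the band edges, so an
    #: edge-to-edge carrier would bleed into the neighbouring bands
    carrier_band: tuple[float, float] = (5.0, 7.0)
    edges: tuple[CouplingEdge, ...] = ()
    noise_sd: float = 0.3
    #: spectral support of the independent additive noise; by default the
    #: noise carries equal power in each canonical analysis band, so every
    #: band has an independent phase floor of its own
    noise_bands: tuple[tuple[float, float], ...] = (
        (0.5, 4.0), (4.0, 8.0), (8.0, 13.0), (13.0, 30.0), (30.0, 48.0)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.carrier_band
        if not (0 < lo < hi):
            raise ValueError(f"need 0 < lo < hi in carrier_band, got {self.carrier_band}")
        if hi >= self.fs / 2:
            raise ValueError(
                f"fs={self.fs} too low for carrier band {self.carrier_band} (need hi < fs/2)"
            )
        for nlo, nhi in self.noise_bands:
            if not (0 < nlo < nhi < self.fs / 2):
                raise ValueError(f"invalid noise band ({nlo}, {nhi}) for fs={self.fs}")
        wrapped = []
        for e in self.edges:
            if e.roi_i == e.roi_j:
                raise ValueError(f"self-coupling not allowed (ROI {e.roi_i})")
            if not (0 <= e.roi_i < self.n_rois and 0 <= e.roi_j < self.n_rois):
                raise ValueError(f"edge ({e.roi_i}, {e.roi_j}) out of range for {self.n_rois} ROIs")
            if not (0 <= e.strength <= 1):
                raise ValueError(f"coupling strength must be in [0, 1], got {e.strength}")
            wrapped.append(
                CouplingEdge(e.roi_i, e.roi_j, wrap_phase(e.phase_lag), e.strength)
            )
        object.__setattr__(self, "edges", tuple(wrapped))

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.epoch_len)) * self.n_epochs

    def with_edges(self, edges: tuple[CouplingEdge, ...]) -> "CouplingSpec":
        return CouplingSpec(
            self.n_rois, self.fs, self.epoch_len, self.n_epochs,
            self.carrier_band, edges, self.noise_sd, self.noise_bands, self.seed,
        )


@dataclass(frozen=True)
class PlantedEffect:
    """A nodal-centrality manipulation: extra strong edges incident on one ROI
    in group B, raising that ROI's expected MST degree and betweenness."""

    target_roi: int
    n_edges: int = 6
    strength: float = 0.9
    phase_lag: float = math.pi / 4

    def incident_edges(self, n_rois: int) -> tuple[CouplingEdge, ...]:
        if not (0 <= self.target_roi < n_rois):
            raise ValueError(f"planted ROI {self.target_roi} out of range for {n_rois} ROIs")
        partners = [(self.target_roi + 1 + k) % n_rois for k in range(self.n_edges)]
        return tuple(
            CouplingEdge(self.target_roi, p, self.phase_lag, self.strength) for p in partners
        )


@dataclass
class SyntheticCohort:
    group_a: list[RoiTimeSeries]
    group_b: list[RoiTimeSeries]
    spec_a: CouplingSpec
    spec_b: CouplingSpec
    planted_effect: PlantedEffect | None
    subject_ids: dict[str, list[str]] = field(default_factory=dict)
    clinical_scores: pd.DataFrame | None = None

    @property
    def n_rois(self) -> int:
        return self.spec_a.n_rois


def _bandlimited_noise(
    rng: np.random.Generator, n_ch: int, n_samples: int, band: tuple[float, float], fs: float
) -> np.ndarray:
    """Unit-variance white noise band-passed to ``band``, per channel.

    Order-8 zero-phase Butterworth: steep enough that a narrow-band carrier's
    spectral shoulders fall well below the broadband noise floor in the
    neighbouring canonical bands, keeping planted coupling band-specific.
    """
    sos = butter(8, list(band), btype="bandpass", fs=fs, output="sos")
    x = rng.standard_normal((n_ch, n_samples))
    y = sosfiltfilt(sos, x, axis=1)
    return y / y.std(axis=1, keepdims=True)


def _multiband_noise(
    rng: np.random.Generator,
    n_ch: int,
    n_samples: int,
    bands: tuple[tuple[float, float], ...],
    fs: float,
) -> np.ndarray:
    """Unit-variance noise with equal power in each listed band."""
    parts = [_bandlimited_noise(rng, n_ch, n_samples, b, fs) for b in bands]
    y = np.sum(parts, axis=0)
    return y / y.std(axis=1, keepdims=True)


def generate_coupled_timeseries(spec: CouplingSpec, subject_seed: int) -> RoiTimeSeries:
    """One subject's ROI x time signal under ``spec``'s coupling structure.

    Each ROI's summed coupled component is renormalized so its standard
    deviation equals the strongest incident coupling strength: a hub with many
    incident carriers keeps the same signal-to-noise ratio per link as a
    singly-coupled ROI instead of becoming proportionally louder.
    """
    rng = np.random.default_rng(int(subject_seed) % _SEED_MOD)
    n = spec.n_samples
    data = np.zeros((spec.n_rois, n))
    max_strength = np.zeros(spec.n_rois)
    for e in spec.edges:
        carrier = _bandlimited_noise(rng, 1, n, spec.carrier_band, spec.fs)[0]
        analytic = _analytic(carrier)
        rotated = np.real(analytic * np.exp(-1j * e.phase_lag))
        rotated /= rotated.std() or 1.0
        data[e.roi_i] += e.strength * carrier
        data[e.roi_j] += e.strength * rotated
        max_strength[e.roi_i] = max(max_strength[e.roi_i], e.strength)
        max_strength[e.roi_j] = max(max_strength[e.roi_j], e.strength)
    for r in np.where(max_strength > 0)[0]:
        sd = data[r].std()
        if sd > 0:
            data[r] *= max_strength[r] / sd
    if spec.noise_sd > 0:
        data += spec.noise_sd * _multiband_noise(
            rng, spec.n_rois, n, spec.noise_bands, spec.fs
        )
    else:
        # keep fully silent channels representable downstream
        quiet = np.all(data == 0, axis=1)
        if quiet.any():
            data[quiet] += 1e-6 * _multiband_noise(
                rng, int(quiet.sum()), n, spec.noise_bands, spec.fs
            )
    return RoiTimeSeries(data, spec.fs)


def _analytic(x: np.ndarray) -> np.ndarray:
    from scipy.signal import hilbert

    return hilbert(x)


def subject_seed(master_seed: int, group: str, index: int) -> int:
    """Deterministic per-subject seed: master seed offset by subject index,
    with group membership encoded in the offset."""
    offset = {"A": 0, "B": 100_000}[group]
    return (int(master_seed) + offset + index) % _SEED_MOD


def generate_cohort(
    null_spec: CouplingSpec,
    n_per_group: int = 16,
    planted_effect: PlantedEffect | None = None,
    master_seed: int = 0,
) -> SyntheticCohort:
    """Two groups of subjects; group B optionally carries a planted hub.

    Without a planted effect both groups are draws from the identical
    generative process (differing only in their per-subject seeds).
    """
    if n_per_group < 2:
        raise ValueError("need at least 2 subjects per group")
    spec_b = null_spec
    if planted_effect is not None:
        extra = planted_effect.incident_edges(null_spec.n_rois)
        spec_b = null_spec.with_edges(null_spec.edges + extra)
    group_a = [
        generate_coupled_timeseries(null_spec, subject_seed(master_seed, "A", i))
        for i in range(n_per_group)
    ]
    group_b = [
        generate_coupled_timeseries(spec_b, subject_seed(master_seed, "B", i))
        for i in range(n_per_group)
    ]
    ids = {
        "A": [f"A{i:03d}" for i in range(n_per_group)],
        "B": [f"B{i:03d}" for i in range(n_per_group)],
    }
    return SyntheticCohort(group_a, group_b, null_spec, spec_b, planted_effect, ids)


def generate_clinical_scores(
    target_metric_values: np.ndarray, r_target: float, noise_seed: int = 0
) -> np.ndarray:
    """Scores with expected Pearson correlation ``r_target`` to a metric.

    scores = r * z + sqrt(1 - r^2) * eps with z the standardized metric and
    eps standard Gaussian, so the population correlation is exactly r_target.
    """
    if not (-1 < r_target < 1):
        raise ValueError(f"|r_target| must be < 1, got {r_target}")
    vals = np.asarray(target_metric_values, dtype=float)
    if vals.size < 3:
        raise ValueError("need at least 3 subjects for a downstream correlation")
    sd = vals.std()
    if sd == 0:
        raise ValueError("metric values are constant; correlation target unachievable")
    z = (vals - vals.mean()) / sd
    rng = np.random.default_rng(int(noise_seed) % _SEED_MOD)
    eps = rng.standard_normal(vals.size)
    return r_target * z + math.sqrt(1 - r_target**2) * eps


# ---------------------------------------------------------------------------
# disk output: one TSV per subject + manifest + ground truth
# ---------------------------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> Path:
    """Write per-subject TSV matrices, a JSON manifest and the ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    for group, subjects in (("A", cohort.group_a), ("B", cohort.group_b)):
        for sid, ts in zip(cohort.subject_ids[group], subjects):
            path = out / f"{sid}.tsv"
            df = pd.DataFrame(ts.data.T, columns=ts.roi_labels)
            df.to_csv(path, sep="\t", index=False, float_format="%.10g")
            manifest.append({"subject": sid, "group": group, "path": path.name, "fs": ts.fs})
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    truth = {
        "planted_effect": asdict(cohort.planted_effect) if cohort.planted_effect else None,
        "spec_a": _spec_dict(cohort.spec_a),
        "spec_b": _spec_dict(cohort.spec_b),
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    return out / "manifest.json"


def _spec_dict(spec: CouplingSpec) -> dict:
    d = asdict(spec)
    d["edges"] = [asdict(e) for e in spec.edges]
    return d
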