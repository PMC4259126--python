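"""Phase-locking functional networks from multichannel signals.

Functional connectivity between two band-limited channels is the
phase-locking factor (PLF, also called phase-locking value or mean phase
coherence):

    c_ij = | (1/Ns) * sum_k exp(i * dphi_ij(t_k)) |

where ``dphi_ij`` is the instantaneous phase difference obtained from the
analytic (Hilbert-transformed) signals.  PLF is 1 for a constant phase lag
and tends to 0 for unrelated phases.  The network construction mirrors a
resting-state EEG workflow: broadband band-pass, mains notch, narrow-band
filter (e.g. the 6-9 Hz low-alpha band), Hilbert phases, pairwise PLF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt

__all__ = [
    "SignalSet",
    "PhaseSeries",
    "FunctionalNetwork",
    "bandpass",
    "notch",
    "instantaneous_phase",
    "plf",
    "build_functional_network",
]

#: seconds trimmed from each end of the phase series before PLF, to suppress
#: Hilbert end-transients
EDGE_TRIM_SECONDS = 0.5

_FILTER_ORDER = 4  # Butterworth, applied forward-backward (zero phase)


@dataclass
class SignalSet:
    """Multichannel real-valued recording (channels x samples)."""

    data: np.ndarray
    fs: float
    labels: list[str] | None = None

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if not np.all(np.isfinite(self.data)):
            raise ValueError("signals contain non-finite samples")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.labels is None:
            self.labels = [f"ch{i}" for i in range(self.data.shape[0])]
        elif len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length does not match channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class PhaseSeries:
    """Instantaneous phases (radians, wrapped to (-pi, pi])."""

    phases: np.ndarray  # (channels, samples)
    fs: float
    labels: list[str] | None = None

    def __post_init__(self):
        self.phases = np.atleast_2d(np.asarray(self.phases, dtype=float))
        if np.any(self.phases > np.pi) or np.any(self.phases <= -np.pi):
            raise ValueError("phases must be wrapped to (-pi, pi]")
        if self.labels is None:
            self.labels = [f"ch{i}" for i in range(self.phases.shape[0])]

    @property
    def n_samples(self) -> int:
        return self.phases.shape[1]


@dataclass
class FunctionalNetwork:
    """Weighted undirected network of pairwise coupling values in [0, 1].

    The diagonal is zero by convention (self-coupling excluded), so node
    degrees count only true edges.
    """

    adjacency: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self):
        w = np.asarray(self.adjacency, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.allclose(w, w.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if np.any(w < 0):
            raise ValueError("adjacency weights must be non-negative")
        self.adjacency = w
        if self.labels is None:
            self.labels = [f"n{i}" for i in range(w.shape[0])]
        elif len(self.labels) != w.shape[0]:
            raise ValueError("labels length does not match matrix size")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


def _check_band(low: float, high: float, fs: float):
    if not 0 < low < high < fs / 2:
        raise ValueError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < fs/2 = {fs / 2}"
        )


def bandpass(signals: SignalSet, low: float, high: float) -> SignalSet:
    """Zero-phase Butterworth band-pass (order 4, forward-backward)."""
    _check_band(low, high, signals.fs)
    sos = butter(_FILTER_ORDER, [low, high], btype="bandpass", fs=signals.fs, output="sos")
    return SignalSet(sosfiltfilt(sos, signals.data, axis=1), signals.fs, list(signals.labels))


def notch(signals: SignalSet, low: float, high: float) -> SignalSet:
    """Zero-phase Butterworth band-stop, e.g. 48-52 Hz for mains removal."""
    _check_band(low, high, signals.fs)
    sos = butter(_FILTER_ORDER, [low, high], btype="bandstop", fs=signals.fs, output="sos")
    return SignalSet(sosfiltfilt(sos, signals.data, axis=1), signals.fs, list(signals.labels))


def instantaneous_phase(signals: SignalSet) -> PhaseSeries:
    """Phase of the analytic signal of each (band-limited) channel.

    The caller is responsible for band-limiting the input first; phase is
    only physically meaningful for narrow-band signals.
    """
    variances = signals.data.var(axis=1)
    if np.any(variances == 0):
        bad = signals.labels[int(np.argmax(variances == 0))]
        raise ValueError(f"channel {bad!r} is constant: instantaneous phase undefined")
    analytic = hilbert(signals.data, axis=1)
    return PhaseSeries(np.angle(analytic), signals.fs, list(signals.labels))


def plf(phases: PhaseSeries, i: int, j: int) -> float:
    """Phase-locking factor between channels ``i`` and ``j``."""
    if phases.n_samples < 1:
        raise ValueError("empty phase series")
    dphi = phases.phases[i] - phases.phases[j]
    return float(np.abs(np.mean(np.exp(1j * dphi))))


def plf_matrix(phases: PhaseSeries) -> np.ndarray:
    """All pairwise PLF values, with the diagonal zeroed."""
    e = np.exp(1j * phases.phases)
    c = np.abs(e @ e.conj().T) / phases.n_samples
    np.fill_diagonal(c, 0.0)
    # numerical guard: |mean phasor| can exceed 1 by rounding only
    return np.clip((c + c.T) / 2.0, 0.0, 1.0)


def build_functional_network(
    signals: SignalSet,
    band: tuple[float, float] = (6.0, 9.0),
    preproc_band: tuple[float, float] | None = None,
    notch_band: tuple[float, float] | None = None,
    edge_trim: float = EDGE_TRIM_SECONDS,
) -> FunctionalNetwork:
    """Band-pass -> Hilbert phase -> pairwise PLF adjacency.

    ``preproc_band`` (e.g. (1, 70)) and ``notch_band`` (e.g. (48, 52)) are
    applied before the analysis band when given.  ``edge_trim`` seconds are
    dropped from each end of the phase series before averaging.
    """
    if signals.n_channels < 2:
        raise ValueError("need at least 2 channels to build a network")
    x = signals
    if preproc_band is not None:
        x = bandpass(x, *preproc_band)
    if notch_band is not None:
        x = notch(x, *notch_band)
    x = bandpass(x, *band)
    phases = instantaneous_phase(x)
    k = int(round(edge_trim * signals.fs))
    if phases.n_samples <= 2 * k:
        raise ValueError("record too short for the requested edge trim")
    trimmed = PhaseSeries(
        phases.phases[:, k : phases.n_samples - k or None], signals.fs, list(signals.labels)
    )
    return FunctionalNetwork(plf_matrix(trimmed), list(signals.labels))
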