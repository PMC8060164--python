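"""Regional time-series handling: filtering, embeddings, window and frequency estimation.

A :class:`TimeSeriesPanel` holds one subject/condition's regional signals as a
``regions x timepoints`` array sampled every ``tr`` seconds (the repetition
time of the scan, or any fixed sampling interval).  Directed-flow estimation
works on *embedded pairs*: for a source series ``x`` and target series ``y``,
the past window of length ``T`` of each series is paired with the target's
next sample, giving the three blocks (past of source, past of target, future
of target) that all covariance-based information quantities are built from.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import warnings

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps


class InvalidBandError(ValueError):
    """Band-pass edges outside (0, Nyquist) or inverted."""


class TooShortError(ValueError):
    """Series too short for the requested operation."""


class UndefinedPeakError(ValueError):
    """Spectrum carries no power; peak frequency is undefined."""


@dataclass(frozen=True)
class EmbeddingSpec:
    """Past-window specification: ``T`` past samples predict one step ahead."""

    T: int = 10
    horizon: int = 1

    def __post_init__(self) -> None:
        if self.T < 1:
            raise ValueError(f"T must be >= 1, got {self.T}")
        if self.horizon != 1:
            raise ValueError("only a one-step prediction horizon is supported")


@dataclass
class TimeSeriesPanel:
    """Regional signals for one subject and condition.

    Parameters
    ----------
    data
        Array of shape ``(n_regions, n_timepoints)``; no missing values.
    tr
        Sampling interval in seconds (must be positive).
    subject_id, condition
        Opaque labels carried through the pipeline.
    region_labels
        Ordered region names; defaults to ``R000, R001, ...``.
    """

    data: np.ndarray
    tr: float
    subject_id: str = "subject"
    condition: str = "rest"
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("panel data must be 2-D (regions x timepoints)")
        if self.data.shape[0] < 2:
            raise ValueError("a panel needs at least 2 regions")
        if not np.isfinite(self.data).all():
            raise ValueError("panel data contains non-finite values")
        if self.tr <= 0:
            raise ValueError("sampling interval must be positive")
        if not self.region_labels:
            self.region_labels = [f"R{i:03d}" for i in range(self.data.shape[0])]
        if len(self.region_labels) != self.data.shape[0]:
            raise ValueError("region_labels length does not match data rows")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    @property
    def fs(self) -> float:
        """Sampling frequency in Hz."""
        return 1.0 / self.tr

    def standardized(self) -> "TimeSeriesPanel":
        """Return a copy with each region z-scored (zero mean, unit sd)."""
        mu = self.data.mean(axis=1, keepdims=True)
        sd = self.data.std(axis=1, keepdims=True)
        if np.any(sd == 0):
            raise ValueError("cannot standardize a constant region series")
        return replace(self, data=(self.data - mu) / sd)


@dataclass(frozen=True)
class EmbeddedPair:
    """Aligned past/future blocks for one ordered region pair.

    ``past_source`` and ``past_target`` have shape ``(n - T, T)`` with column 0
    the most recent lag; ``future_target`` is the target one step beyond the
    most recent past sample.
    """

    past_source: np.ndarray
    past_target: np.ndarray
    future_target: np.ndarray


def embed_lags(series: np.ndarray, T: int) -> np.ndarray:
    """Lag matrix of shape ``(n - T, T)``; column 0 = most recent lag.

    Row ``r`` holds ``series[T-1+r], series[T-2+r], ..., series[r]`` so the
    future paired with row ``r`` is ``series[T + r]``.
    """
    series = np.asarray(series, dtype=float)
    windows = sliding_window_view(series, T)[:-1]  # rows 0..n-T-1
    return windows[:, ::-1]


def embed_pair(x: np.ndarray, y: np.ndarray, spec: EmbeddingSpec) -> EmbeddedPair:
    """Build the (past of x, past of y, future of y) blocks for NDTE.

    Raises
    ------
    TooShortError
        If the series have no room for ``T`` past samples plus one future.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n <= spec.T + 1:
        raise TooShortError(f"need more than T+1={spec.T + 1} samples, got {n}")
    return EmbeddedPair(
        past_source=embed_lags(x, spec.T),
        past_target=embed_lags(y, spec.T),
        future_target=y[spec.T:],
    )


def bandpass_filter(
    panel: TimeSeriesPanel,
    low_hz: float = 0.008,
    high_hz: float = 0.08,
    order: int = 2,
) -> TimeSeriesPanel:
    """Zero-phase Butterworth band-pass of every region series.

    The default band (0.008-0.08 Hz) is the standard narrowband for
    haemodynamic signals.  Filtering is forward-and-backward (``filtfilt``)
    so the pass band sees no phase shift and embeddings stay aligned; the
    effective amplitude response is the squared Butterworth magnitude.
    """
    nyq = panel.fs / 2.0
    if not (0.0 < low_hz < high_hz < nyq):
        raise InvalidBandError(
            f"band ({low_hz}, {high_hz}) Hz must satisfy 0 < low < high < Nyquist={nyq:.4g}"
        )
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=panel.fs, output="sos")
    # filtfilt padlen for sos: 3 * (2 * n_sections + 1) by scipy default
    padlen = 3 * (2 * sos.shape[0] + 1)
    if panel.n_timepoints <= padlen:
        raise TooShortError(
            f"series of length {panel.n_timepoints} shorter than filter padding {padlen}"
        )
    filtered = sps.sosfiltfilt(sos, panel.data, axis=1)
    return replace(panel, data=np.ascontiguousarray(filtered))


def _first_acf_minimum(series: np.ndarray, max_lag: int) -> int:
    """Lag of the first local minimum of the autocorrelation function.

    Falls back to the first 1/e crossing (with a warning) when no local
    minimum exists within ``max_lag``.
    """
    x = np.asarray(series, dtype=float)
    x = x - x.mean()
    n = x.size
    denom = float(x @ x)
    if denom == 0:
        raise ValueError("constant series has no autocorrelation structure")
    acf = np.array([1.0] + [float(x[:-k] @ x[k:]) / denom for k in range(1, max_lag + 1)])
    interior = np.nonzero((acf[1:-1] < acf[:-2]) & (acf[1:-1] <= acf[2:]))[0]
    if interior.size:
        return int(interior[0]) + 1
    below = np.nonzero(acf < 1.0 / np.e)[0]
    if below.size:
        warnings.warn(
            "no ACF local minimum within search range; using first 1/e crossing",
            stacklevel=3,
        )
        return int(below[0])
    warnings.warn("ACF neither attains a minimum nor decays below 1/e; using max lag", stacklevel=3)
    return max_lag


def estimate_window(panels: list[TimeSeriesPanel], max_lag: int = 50) -> int:
    """Average first-ACF-minimum lag over all regions and subjects.

    This is the standard delay-embedding heuristic: the past-window length is
    the lag where the autocorrelation first stops decaying.  Minima are found
    per region per subject and then averaged (rounded, floored at 1).
    """
    if not panels:
        raise ValueError("need at least one panel")
    lags: list[int] = []
    for panel in panels:
        if panel.n_timepoints < max_lag + 2:
            raise TooShortError(f"panel too short to estimate ACF to lag {max_lag}")
        for row in panel.data:
            lags.append(_first_acf_minimum(row, max_lag))
    return max(1, int(round(float(np.mean(lags)))))


def peak_frequency(panel: TimeSeriesPanel, band: tuple[float, float] | None = (0.008, 0.08)) -> np.ndarray:
    """Per-region dominant frequency (Hz) of a smoothed periodogram.

    Uses Welch averaging (segments of 128 samples, 50% overlap) and returns
    the frequency of the spectral maximum inside ``band`` (or over the whole
    axis when ``band`` is None).  This is the per-region intrinsic frequency
    fed to the oscillator model.
    """
    if panel.n_timepoints < 128:
        raise TooShortError("need at least 128 timepoints for spectral estimation")
    nperseg = min(128, panel.n_timepoints)
    freqs, pxx = sps.welch(panel.data, fs=panel.fs, nperseg=nperseg, axis=1)
    if band is not None:
        keep = (freqs >= band[0]) & (freqs <= band[1])
        if not keep.any():
            raise InvalidBandError("band contains no spectral bins")
        freqs = freqs[keep]
        pxx = pxx[:, keep]
    if np.any(pxx.max(axis=1) <= 0):
        raise UndefinedPeakError("flat (all-zero) spectrum for at least one region")
    return freqs[np.argmax(pxx, axis=1)]
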