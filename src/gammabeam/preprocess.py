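"""Epoch conditioning: DC removal, band filtering, artifact rejection.

The :class:`EpochSet` is the unit of all signal processing — a stack of
stimulus-locked trials (epochs x channels x samples) with its time axis in
milliseconds relative to stimulus onset and one condition label per epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import ConfigurationError, GammabeamError

#: Analysis windows used throughout: a pre-stimulus baseline and three
#: 200 ms post-stimulus viewing windows.
DEFAULT_PASSIVE = (-300.0, -100.0)
DEFAULT_ACTIVES = ((50.0, 250.0), (250.0, 450.0), (450.0, 650.0))
#: Frequency bands: a broad control band and the gamma band (Hz).
DEFAULT_BANDS = {"lower": (3.0, 30.0), "gamma": (30.0, 80.0)}


@dataclass
class EpochSet:
    """Stimulus-locked MEG trials with geometry-free signal content.

    data is (n_epochs, n_channels, n_samples) in tesla; time_ms is the
    shared per-epoch time axis relative to stimulus onset.
    """

    data: np.ndarray
    sampling_rate: float
    time_ms: np.ndarray
    condition_labels: np.ndarray
    rejected_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.condition_labels = np.asarray(self.condition_labels)
        if self.data.ndim != 3:
            raise ConfigurationError("data must be epochs x channels x samples")
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        if self.time_ms.shape[0] != self.data.shape[2]:
            raise ConfigurationError("time axis length mismatch")
        if np.any(np.diff(self.time_ms) <= 0):
            raise ConfigurationError("time axis must be strictly increasing")
        if self.condition_labels.shape[0] != self.data.shape[0]:
            raise ConfigurationError("one condition label per epoch required")
        if self.rejected_mask is None:
            self.rejected_mask = np.zeros(self.data.shape[0], dtype=bool)
        self.rejected_mask = np.asarray(self.rejected_mask, dtype=bool)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def surviving(self) -> np.ndarray:
        """Data restricted to epochs that passed artifact rejection."""
        return self.data[~self.rejected_mask]

    def sample_slice(self, window_ms: tuple[float, float]) -> slice:
        """Index slice of samples falling inside [t0, t1) milliseconds."""
        t0, t1 = window_ms
        idx = np.nonzero((self.time_ms >= t0) & (self.time_ms < t1))[0]
        if idx.size == 0:
            raise ConfigurationError(f"window {window_ms} outside epoch")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def select_conditions(self, labels) -> "EpochSet":
        """Sub-EpochSet containing only epochs with the given labels."""
        keep = np.isin(self.condition_labels, np.asarray(labels))
        if not keep.any():
            raise ConfigurationError(f"no epochs with labels {labels!r}")
        return replace(
            self,
            data=self.data[keep],
            condition_labels=self.condition_labels[keep],
            rejected_mask=self.rejected_mask[keep],
        )


@dataclass(frozen=True)
class AnalysisWindows:
    """Baseline and active windows (ms) plus band definitions (Hz)."""

    passive: tuple[float, float] = DEFAULT_PASSIVE
    actives: tuple[tuple[float, float], ...] = DEFAULT_ACTIVES
    bands: dict = field(default_factory=lambda: dict(DEFAULT_BANDS))

    def __post_init__(self) -> None:
        if not self.passive[0] < self.passive[1] <= 0:
            raise ConfigurationError("passive window must be pre-stimulus")
        for lo, hi in self.actives:
            if abs((hi - lo) - 200.0) > 1e-6:
                raise ConfigurationError("active windows must be 200 ms long")
        for name, (lo, hi) in self.bands.items():
            if not 0 < lo < hi:
                raise ConfigurationError(f"invalid band {name}: {(lo, hi)}")


def remove_dc(epochs: EpochSet) -> EpochSet:
    """Subtract the per-epoch, per-channel mean (zero-mean on all sensors)."""
    if epochs.n_epochs == 0:
        raise ConfigurationError("empty epoch set")
    data = epochs.data - epochs.data.mean(axis=2, keepdims=True)
    return replace(epochs, data=data)


def bandpass(epochs: EpochSet, band: tuple[float, float]) -> EpochSet:
    """Zero-phase band-pass filter (4th-order Butterworth, forward-backward).

    Filtering is applied per epoch and channel with reflection padding, so
    the group delay is zero by construction and edge transients are
    suppressed on the short epochs used here.
    """
    lo, hi = band
    nyq = epochs.sampling_rate / 2.0
    if not 0 < lo < hi:
        raise ConfigurationError(f"invalid band {band}")
    if hi >= nyq:
        raise ConfigurationError(
            f"band edge {hi} Hz at or above Nyquist ({nyq:.1f} Hz)"
        )
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=epochs.sampling_rate,
                     output="sos")
    padlen = min(3 * 2 * 4 * 10, epochs.n_samples - 1)
    data = sps.sosfiltfilt(sos, epochs.data, axis=2, padtype="even",
                           padlen=padlen)
    return replace(epochs, data=data)


def reject_artifacts(
    epochs: EpochSet,
    peak_to_peak_threshold: float | None = None,
    threshold_factor: float = 6.0,
) -> tuple[EpochSet, pd.DataFrame]:
    """Flag epochs whose worst-channel peak-to-peak amplitude is excessive.

    An automated surrogate for manual artifact inspection: an epoch is
    rejected when ``max over channels of (max - min)`` exceeds the
    threshold.  When no absolute threshold is given, it defaults to
    ``threshold_factor`` times the median per-epoch peak-to-peak amplitude.
    Surviving epochs are untouched and keep their order.

    Returns the masked EpochSet and a per-epoch report
    (epoch_index, max_ptp, rejected).
    """
    ptp = (epochs.data.max(axis=2) - epochs.data.min(axis=2)).max(axis=1)
    if peak_to_peak_threshold is None:
        peak_to_peak_threshold = threshold_factor * float(np.median(ptp))
    if not peak_to_peak_threshold > 0:
        raise ConfigurationError("peak-to-peak threshold must be positive")
    rejected = ptp > peak_to_peak_threshold
    if rejected.all():
        raise GammabeamError(
            f"all {epochs.n_epochs} epochs rejected at threshold "
            f"{peak_to_peak_threshold:.3e} T"
        )
    report = pd.DataFrame(
        {
            "epoch_index": np.arange(epochs.n_epochs),
            "max_ptp": ptp,
            "rejected": rejected,
        }
    )
    report.attrs["threshold"] = peak_to_peak_threshold
    report.attrs["rejection_fraction"] = float(rejected.mean())
    out = replace(epochs, rejected_mask=epochs.rejected_mask | rejected)
    return out, report
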