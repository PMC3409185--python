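"""Virtual electrodes and Stockwell time-frequency analysis.

A virtual electrode (VE) is the beamformer-reconstructed source time series
at one location: the same minimum-variance spatial filter as the volumetric
scan, but keeping the whole trace instead of reducing it to a power number.
Per-epoch VE traces feed a Stockwell (S-) transform; averaging traces
*before* the transform isolates phase-locked (evoked) activity, averaging
per-epoch power *after* the transform keeps non-phase-locked (induced)
activity as well.  First-level active-vs-baseline t-maps per subject are
combined across subjects with sign-flip maximum-statistic permutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .beamform import StatMap, compute_weights, find_peaks, paired_power_t
from .errors import ConfigurationError
from .forward import HeadModel, SensorArray, apply_affine, point_lead_field
from .preprocess import DEFAULT_PASSIVE, EpochSet
from .stats import PermutationResult, sign_flip_engine

#: The three canonical VE sites (MNI mm): right lateral occipital cortex,
#: left occipital pole, right fusiform gyrus.
DEFAULT_VE_SITES = (
    ((36.0, -86.0, 2.0), "R-LOC"),
    ((-20.0, -92.0, 16.0), "L-OP"),
    ((32.0, -57.0, -3.0), "R-FG"),
)


@dataclass(frozen=True)
class VESite:
    mni_coord: tuple[float, float, float]
    selection_mode: str  # between_group_peak | within_group_mean_peak | theory_driven
    label: str = ""


@dataclass
class VETrace:
    """Per-epoch reconstructed source time series at one site."""

    traces: np.ndarray  # (n_epochs, n_samples), source units
    time_ms: np.ndarray
    sampling_rate: float
    site: VESite | None = None
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.traces = np.atleast_2d(np.asarray(self.traces, dtype=float))
        if self.traces.shape[1] != len(self.time_ms):
            raise ConfigurationError("trace/time axis mismatch")

    @property
    def n_epochs(self) -> int:
        return self.traces.shape[0]

    def sample_slice(self, window_ms: tuple[float, float]) -> slice:
        t0, t1 = window_ms
        idx = np.nonzero((self.time_ms >= t0) & (self.time_ms < t1))[0]
        if idx.size == 0:
            raise ConfigurationError(f"window {window_ms} outside trace")
        return slice(int(idx[0]), int(idx[-1]) + 1)


@dataclass
class TFMap:
    """Time x frequency matrix of power or t values."""

    values: np.ndarray  # (n_freqs, n_times)
    freqs_hz: np.ndarray
    times_ms: np.ndarray
    kind: str  # evoked | induced | first_level_t | group_t
    mask: np.ndarray | None = None
    threshold: float | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.freqs_hz), len(self.times_ms)):
            raise ConfigurationError("TF values must be freqs x times")
        if self.mask is not None and not self.kind.endswith("t"):
            raise ConfigurationError("masks only apply to t-kind maps")


def select_ve_sites(
    between_map: StatMap | None = None,
    within_maps: list[StatMap] | None = None,
    theory_sites: list[tuple[tuple[float, float, float], str]] | None = None,
    k_peaks: int = 5,
) -> list[VESite]:
    """VE placement by the three supported modes.

    1. peak |t| voxel of the between-groups difference map;
    2. coordinate-wise mean of the significant maxima of each within-group
       map, snapped to the nearest grid point;
    3. theory-driven MNI coordinates passed through unchanged.
    """
    sites: list[VESite] = []
    if between_map is not None:
        idx = int(np.argmax(np.abs(between_map.values)))
        sites.append(VESite(tuple(between_map.grid.points[idx]),
                            "between_group_peak", "between-groups peak"))
    if within_maps:
        for m in within_maps:
            peaks = find_peaks(m, k=k_peaks)
            peaks = peaks[peaks.polarity == "max"]
            if peaks.empty:
                raise ConfigurationError(
                    "no significant maxima to average for VE placement"
                )
            mean_xyz = peaks[["x", "y", "z"]].mean().to_numpy()
            snap = m.grid.points[
                int(np.argmin(np.linalg.norm(m.grid.points - mean_xyz,
                                             axis=1)))
            ]
            sites.append(VESite(tuple(snap), "within_group_mean_peak",
                                "mean of significant maxima"))
    for coord, label in theory_sites or ():
        sites.append(VESite(tuple(coord), "theory_driven", label))
    return sites


def place_ve(
    site: VESite,
    affine: np.ndarray,
    sensors: SensorArray,
    head: HeadModel,
    cov,
) -> np.ndarray:
    """Beamformer weights for a VE site in one subject.

    The MNI coordinate is mapped into subject space by the subject's
    affine, the lead field is evaluated analytically at the mapped point
    (not snapped to a grid), and weights follow the usual minimum-variance
    construction with the unit-gain constraint.
    """
    subject_point = apply_affine(np.asarray(site.mni_coord), affine)
    rel = np.linalg.norm(subject_point - head.center_mm)
    if rel >= head.radius_mm:
        raise ConfigurationError(
            f"VE site maps outside the head ({rel:.1f} mm from center)"
        )
    L, _ = point_lead_field(subject_point, sensors, head)
    bw = compute_weights(L, cov)
    if bw.degenerate[0]:
        raise ConfigurationError("degenerate lead field at VE site")
    return bw.weights[0]


def reconstruct_trace(
    weights: np.ndarray, epochs: EpochSet, site: VESite | None = None
) -> VETrace:
    """Apply VE weights to the sensor data: trace = w . data per epoch."""
    w = np.asarray(weights, dtype=float)
    if not np.all(np.isfinite(w)):
        raise ConfigurationError("weights must be finite")
    traces = np.einsum("k,ekt->et", w, epochs.surviving())
    return VETrace(
        traces=traces,
        time_ms=epochs.time_ms,
        sampling_rate=epochs.sampling_rate,
        site=site,
        weights=w,
    )


def stockwell(
    x: np.ndarray,
    sampling_rate: float,
    fmin: float,
    fmax: float,
    freq_step: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Stockwell (S-) transform of one signal, frequency-domain form.

    For each analysis frequency (nearest DFT bin k) the voice is the
    inverse DFT of the spectrum shifted by k and windowed with the
    frequency-domain Gaussian exp(-2 pi^2 m^2 / k^2).  Requested
    frequencies are mapped to DFT bins of the trace; f = 0 is handled as
    the DC mean per the standard definition.

    Returns ``(freqs_hz, S)`` with S complex of shape (n_freqs, n_samples).
    The transform satisfies the time-marginal identity
    ``mean_t S[t, k] = X[k]`` where X is the (1/N-normalized) DFT of x.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 16:
        raise ConfigurationError("signal too short for an S-transform")
    if fmax >= sampling_rate / 2.0:
        raise ConfigurationError("fmax must be below Nyquist")
    if fmin < 0 or fmin > fmax:
        raise ConfigurationError("need 0 <= fmin <= fmax")
    df = sampling_rate / n
    ks = np.unique(np.round(np.arange(fmin, fmax + freq_step / 2.0,
                                      freq_step) / df).astype(int))
    spectrum = np.fft.fft(x) / n
    m = np.fft.fftfreq(n, d=1.0 / n)  # signed bin offsets
    S = np.empty((ks.size, n), dtype=complex)
    for i, k in enumerate(ks):
        if k == 0:
            S[i] = np.full(n, x.mean())  # DC voice: the signal mean
            continue
        voice_window = np.exp(-2.0 * np.pi**2 * m**2 / k**2)
        S[i] = np.fft.ifft(np.roll(spectrum, -k) * voice_window) * n
    return ks * df, S


def _tf_power_stack(
    trace: VETrace,
    fmin: float,
    fmax: float,
    freq_step: float = 1.0,
    time_decim: int = 4,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-epoch S-transform power, time-decimated: (E, F, T'), freqs, times."""
    powers = []
    freqs = None
    for e in range(trace.n_epochs):
        freqs, S = stockwell(trace.traces[e], trace.sampling_rate, fmin, fmax,
                             freq_step)
        powers.append(np.abs(S[:, ::time_decim]) ** 2)
    times = trace.time_ms[::time_decim]
    return np.stack(powers), freqs, times


def evoked_tf(
    trace: VETrace,
    fband: tuple[float, float],
    freq_step: float = 1.0,
    time_decim: int = 4,
) -> TFMap:
    """Phase-locked (evoked) power: average traces in time, then transform."""
    if trace.n_epochs < 2:
        raise ConfigurationError("evoked decomposition needs >= 2 epochs")
    avg = trace.traces.mean(axis=0)
    freqs, S = stockwell(avg, trace.sampling_rate, fband[0], fband[1],
                         freq_step)
    return TFMap(
        values=np.abs(S[:, ::time_decim]) ** 2,
        freqs_hz=freqs,
        times_ms=trace.time_ms[::time_decim],
        kind="evoked",
        provenance={"site": trace.site, "n_epochs": trace.n_epochs},
    )


def induced_tf(
    trace: VETrace,
    fband: tuple[float, float],
    freq_step: float = 1.0,
    time_decim: int = 4,
    subtract_evoked: bool = False,
) -> TFMap:
    """Induced power: transform each epoch, then average the power.

    This is total (phase-locked plus non-phase-locked) power — the
    operational definition used throughout this package.  With
    ``subtract_evoked`` the epoch-average trace is removed from every epoch
    first, leaving strictly non-phase-locked power.
    """
    if trace.n_epochs < 2:
        raise ConfigurationError("induced decomposition needs >= 2 epochs")
    work = trace
    if subtract_evoked:
        work = VETrace(
            traces=trace.traces - trace.traces.mean(axis=0, keepdims=True),
            time_ms=trace.time_ms,
            sampling_rate=trace.sampling_rate,
            site=trace.site,
        )
    stack, freqs, times = _tf_power_stack(work, fband[0], fband[1], freq_step,
                                          time_decim)
    return TFMap(
        values=stack.mean(axis=0),
        freqs_hz=freqs,
        times_ms=times,
        kind="induced",
        provenance={"site": trace.site, "n_epochs": trace.n_epochs,
                    "subtract_evoked": subtract_evoked},
    )


def tf_first_level(
    trace: VETrace,
    fband: tuple[float, float],
    passive_window: tuple[float, float] = DEFAULT_PASSIVE,
    freq_step: float = 1.0,
    time_decim: int = 4,
) -> TFMap:
    """First-level t-map: per-epoch TF power vs per-frequency baseline.

    For each (time, frequency) bin, a paired t across epochs between that
    bin's power and the same epoch's mean power over the passive window at
    the same frequency.  Degenerate (zero-variance) bins get t = 0.
    """
    stack, freqs, times = _tf_power_stack(trace, fband[0], fband[1],
                                          freq_step, time_decim)
    keep = (times >= passive_window[0]) & (times < passive_window[1])
    if not keep.any():
        raise ConfigurationError("passive window outside the trace")
    baseline = stack[:, :, keep].mean(axis=2)  # (E, F)
    t, degenerate = paired_power_t(
        stack.transpose(1, 2, 0), baseline.T[:, None, :]
    )
    return TFMap(
        values=t,
        freqs_hz=freqs,
        times_ms=times,
        kind="first_level_t",
        provenance={
            "site": trace.site,
            "df": trace.n_epochs - 1,
            "passive_window": passive_window,
            "degenerate_bins": int(degenerate.sum()),
        },
    )


def tf_group_permutation(
    first_level: list[TFMap],
    n_permutations: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> tuple[TFMap, PermutationResult]:
    """Group one-sample t over subject TF t-maps with sign-flip nulls.

    Subjects' first-level maps are polarity-inverted at random, max |t|
    over all bins is recorded per permutation, and the (1 - alpha)
    quantile thresholds the observed map two-sided.
    """
    if len(first_level) < 2:
        raise ConfigurationError("need >= 2 subjects")
    shape = first_level[0].values.shape
    for m in first_level[1:]:
        if m.values.shape != shape:
            raise ConfigurationError("incongruent TF grids across subjects")
    stack = np.stack([m.values for m in first_level])
    perm = sign_flip_engine(stack, n_permutations=n_permutations, alpha=alpha,
                            seed=seed)
    observed = perm.observed
    out = TFMap(
        values=observed,
        freqs_hz=first_level[0].freqs_hz,
        times_ms=first_level[0].times_ms,
        kind="group_t",
        mask=perm.mask,
        threshold=perm.threshold,
        provenance={"n_subjects": len(first_level), "alpha": alpha,
                    "seed": seed, "n_permutations": perm.n_permutations},
    )
    return out, perm
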