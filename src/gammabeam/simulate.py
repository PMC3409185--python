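"""Synthetic two-cohort MEG data with planted evoked/induced structure.

The generator emulates the statistical structure a face-viewing gamma study
assumes: a phase-locked evoked transient near 100 ms in occipital cortex,
sustained non-phase-locked gamma (30-80 Hz) bursts whose post-stimulus gain
differs between a TD-like cohort (gain > 1, induced power increase) and an
ASD-like cohort (gain < 1, decreasing induced power), beta-band (12-30 Hz)
desynchronization in both cohorts, 1/f background dipole noise, and white
sensor noise.  Per-subject AQ-like covariates are drawn with a configurable
negative correlation to the subject's induced-gamma gain via a Gaussian
copula, and every planted quantity is recorded as ground truth so recovery
can be tested downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .forward import HeadModel, SensorArray, apply_affine, point_lead_field
from .preprocess import EpochSet

#: Canonical MNI sites (mm) used by the default source layout.
R_LOC = (36.0, -86.0, 2.0)  # right lateral occipital cortex
L_OP = (-20.0, -92.0, 16.0)  # left occipital pole
R_FUSIFORM = (32.0, -57.0, -3.0)  # right fusiform gyrus

CONDITIONS = ("surprise", "happiness", "sadness", "fear", "anger", "disgust")


@dataclass(frozen=True)
class SourceComponent:
    """One spectral-temporal component of a simulated source."""

    kind: str  # evoked | induced | desync | background
    center_freq: float = 60.0  # Hz
    bandwidth: float = 0.0  # Hz, carrier drawn uniformly per epoch
    onset_ms: float = 150.0
    offset_ms: float = 650.0
    amplitude: float = 1.0  # dipole moment, A*m
    phase_locked: bool = False
    phase_jitter: float = np.pi  # rad; pi = uniform phase per epoch
    modulation: float = 1.0  # post-stimulus amplitude factor (desync < 1)

    def __post_init__(self) -> None:
        if self.kind not in {"evoked", "induced", "desync", "background"}:
            raise ConfigurationError(f"unknown component kind {self.kind!r}")
        if self.onset_ms >= self.offset_ms:
            raise ConfigurationError("component onset must precede offset")
        if self.kind == "evoked" and not self.phase_locked:
            raise ConfigurationError("evoked components must be phase-locked")
        if self.kind == "induced" and self.phase_locked:
            raise ConfigurationError("induced components are not phase-locked")


@dataclass(frozen=True)
class SourceSpec:
    """A dipolar source: MNI location, tangential orientation, components."""

    location: tuple[float, float, float]
    orientation: float = 0.0  # radians in the local tangential basis
    components: tuple[SourceComponent, ...] = ()


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for a two-cohort simulation.

    Defaults follow the full-scale design: 13 TD-like / 12 ASD-like
    subjects, 600 epochs over 6 emotion conditions, 2000 ms epochs sampled
    at 678.17 Hz, AQ-like covariates with group means 12.33 (6.47) and
    38.62 (6.16), and corr(AQ, induced-gamma gain) = -0.5 within group.
    """

    n_per_group: dict = field(
        default_factory=lambda: {"TD": 13, "ASD": 12}
    )
    group_gamma_gain: dict = field(
        default_factory=lambda: {"TD": 2.5, "ASD": 0.6}
    )
    aq_model: dict = field(
        default_factory=lambda: {
            "mean": {"TD": 12.33, "ASD": 38.62},
            "sd": {"TD": 6.47, "ASD": 6.16},
            "r": -0.5,
        }
    )
    gain_log_sd: float = 0.15  # subject-level lognormal gain spread
    n_epochs: int = 600
    n_conditions: int = 6
    sampling_rate: float = 678.17
    epoch_window: tuple[float, float] = (-1000.0, 1000.0)
    sensor_noise_sd: float = 1.0e-13  # tesla per sample
    sources: tuple[SourceSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_epochs % self.n_conditions != 0:
            raise ConfigurationError(
                "n_epochs must be divisible by n_conditions"
            )
        if not self.sources:
            object.__setattr__(self, "sources", default_sources())
        fmax = max(
            (c.center_freq + c.bandwidth / 2.0
             for s in self.sources for c in s.components),
            default=0.0,
        )
        if self.sampling_rate <= 2.0 * fmax:
            raise ConfigurationError(
                f"sampling rate {self.sampling_rate} Hz under twice the "
                f"highest simulated frequency ({fmax} Hz)"
            )


@dataclass
class SubjectRecord:
    """One participant: epochs, MNI affine, covariates, ground truth."""

    subject_id: str
    group: str
    epochs: EpochSet | None
    affine: np.ndarray
    covariates: dict  # AQ, age_months, FSIQ
    true_params: dict

    def __post_init__(self) -> None:
        self.affine = np.asarray(self.affine, dtype=float)
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ConfigurationError("subject affine is singular")
        if not all(np.isfinite(v) for v in self.covariates.values()):
            raise ConfigurationError("covariates must be finite")


def default_sources(
    evoked_amp: float = 4.0e-8,
    gamma_amp: float = 2.0e-8,
    beta_amp: float = 3.0e-8,
    background_amp: float = 2.0e-8,
) -> tuple[SourceSpec, ...]:
    """Default source layout: occipital evoked + induced gamma + beta
    desynchronization, plus 1/f background dipoles away from visual cortex."""
    gamma = SourceComponent(
        kind="induced", center_freq=60.0, bandwidth=20.0,
        onset_ms=150.0, offset_ms=650.0, amplitude=gamma_amp,
    )
    beta_desync = SourceComponent(
        kind="desync", center_freq=20.0, bandwidth=10.0,
        onset_ms=150.0, offset_ms=1000.0, amplitude=beta_amp,
        modulation=0.5,
    )
    evoked = SourceComponent(
        kind="evoked", center_freq=10.0, onset_ms=50.0, offset_ms=150.0,
        amplitude=evoked_amp, phase_locked=True, phase_jitter=0.0,
    )
    background = SourceComponent(
        kind="background", center_freq=0.0, bandwidth=0.0,
        onset_ms=-1000.0, offset_ms=1000.0, amplitude=background_amp,
    )
    return (
        SourceSpec(R_LOC, 0.3, (evoked, gamma, beta_desync)),
        SourceSpec(L_OP, -0.4, (gamma, beta_desync)),
        SourceSpec(R_FUSIFORM, 1.1, (gamma,)),
        SourceSpec((0.0, 42.0, 28.0), 0.7, (background,)),
        SourceSpec((-42.0, 8.0, 36.0), -1.2, (background,)),
        SourceSpec((44.0, 6.0, 34.0), 2.0, (background,)),
    )


def _envelope(t_ms: np.ndarray, onset: float, offset: float,
              ramp_ms: float = 50.0) -> np.ndarray:
    """Raised-cosine plateau envelope over [onset, offset] ms."""
    env = np.zeros_like(t_ms)
    inside = (t_ms >= onset) & (t_ms <= offset)
    env[inside] = 1.0
    up = inside & (t_ms < onset + ramp_ms)
    env[up] = 0.5 * (1 - np.cos(np.pi * (t_ms[up] - onset) / ramp_ms))
    down = inside & (t_ms > offset - ramp_ms)
    env[down] = 0.5 * (1 - np.cos(np.pi * (offset - t_ms[down]) / ramp_ms))
    return env


def _component_timecourses(
    comp: SourceComponent,
    gain: float,
    t_ms: np.ndarray,
    n_epochs: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Source time course (n_epochs, n_samples) in A*m for one component."""
    t_s = t_ms / 1000.0
    if comp.kind == "evoked":
        center = 0.5 * (comp.onset_ms + comp.offset_ms)
        sigma_ms = (comp.offset_ms - comp.onset_ms) / 4.0
        gabor_env = np.exp(-0.5 * ((t_ms - center) / sigma_ms) ** 2)
        if comp.phase_jitter > 0:
            phases = rng.uniform(-comp.phase_jitter, comp.phase_jitter,
                                 n_epochs)
        else:
            phases = np.zeros(n_epochs)
        carrier = np.cos(
            2 * np.pi * comp.center_freq * (t_s - center / 1000.0)[None, :]
            + phases[:, None]
        )
        return comp.amplitude * gabor_env[None, :] * carrier

    if comp.kind in {"induced", "desync"}:
        factor = gain if comp.kind == "induced" else comp.modulation
        env = _envelope(t_ms, comp.onset_ms, comp.offset_ms)
        ampl = 1.0 + (factor - 1.0) * env  # baseline 1, modulated window
        if comp.bandwidth > 0:
            freqs = rng.uniform(comp.center_freq - comp.bandwidth / 2.0,
                                comp.center_freq + comp.bandwidth / 2.0,
                                n_epochs)
        else:
            freqs = np.full(n_epochs, comp.center_freq)
        if comp.phase_jitter > 0:
            phases = rng.uniform(-comp.phase_jitter, comp.phase_jitter,
                                 n_epochs)
        else:
            phases = np.zeros(n_epochs)
        carrier = np.cos(2 * np.pi * freqs[:, None] * t_s[None, :]
                         + phases[:, None])
        return comp.amplitude * ampl[None, :] * carrier

    # background: per-epoch 1/f-shaped dipole noise, unit rms then scaled
    n = t_ms.size
    white = rng.standard_normal((n_epochs, n))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n, d=t_s[1] - t_s[0])
    shaping = np.zeros_like(f)
    shaping[1:] = 1.0 / np.sqrt(f[1:])
    colored = np.fft.irfft(spec * shaping[None, :], n=n, axis=1)
    rms = colored.std(axis=1, keepdims=True)
    return comp.amplitude * colored / np.where(rms > 0, rms, 1.0)


def epoch_time_axis(spec: CohortSpec) -> np.ndarray:
    """Per-epoch time axis (ms) implied by the epoch window and rate."""
    t0, t1 = spec.epoch_window
    n = int(round((t1 - t0) / 1000.0 * spec.sampling_rate))
    return t0 + np.arange(n) / spec.sampling_rate * 1000.0


def simulate_epoch_set(
    sources: tuple[SourceSpec, ...],
    subject_gain: float,
    sensors: SensorArray,
    head: HeadModel,
    spec: CohortSpec,
    seed: int,
    affine: np.ndarray | None = None,
) -> EpochSet:
    """Simulate one subject's epochs (n_epochs x n_ch x n_samples, tesla).

    Source locations are interpreted in MNI mm and mapped into the
    subject's own space by the affine (identity when omitted); each
    source's signal is projected through its analytic lead field.  Evoked
    components keep an identical phase across epochs, induced components
    draw a fresh uniform phase per epoch, and ``subject_gain`` scales the
    post-stimulus amplitude of every induced component.
    """
    rng = np.random.default_rng(seed)
    t_ms = epoch_time_axis(spec)
    n_samples = t_ms.size
    data = np.zeros((spec.n_epochs, sensors.n_channels, n_samples))

    for src in sources:
        loc = np.asarray(src.location, dtype=float)
        if affine is not None:
            loc = apply_affine(loc, affine)
        L, _basis = point_lead_field(loc, sensors, head)
        # topography of a unit dipole along the source orientation
        topo = L[0] @ np.array([np.cos(src.orientation),
                                np.sin(src.orientation)])
        for comp in src.components:
            s = _component_timecourses(comp, subject_gain, t_ms,
                                       spec.n_epochs, rng)
            data += s[:, None, :] * topo[None, :, None]

    if spec.sensor_noise_sd > 0:
        data += spec.sensor_noise_sd * rng.standard_normal(data.shape)

    labels = np.tile(
        np.asarray(CONDITIONS[: spec.n_conditions]),
        spec.n_epochs // spec.n_conditions,
    )
    return EpochSet(
        data=data,
        sampling_rate=spec.sampling_rate,
        time_ms=t_ms,
        condition_labels=labels,
    )


def _rigid_affine(rng: np.random.Generator, rot_sd_deg: float = 2.0,
                  trans_sd_mm: float = 2.0) -> np.ndarray:
    """Identity plus a small random rigid perturbation (always invertible)."""
    angles = np.deg2rad(rng.normal(0.0, rot_sd_deg, 3))
    cx, cy, cz = np.cos(angles)
    sx, sy, sz = np.sin(angles)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    aff = np.eye(4)
    aff[:3, :3] = rz @ ry @ rx
    aff[:3, 3] = rng.normal(0.0, trans_sd_mm, 3)
    return aff


_AGE_MODEL = {"TD": (188.58, 24.83), "ASD": (181.77, 33.92)}  # months
_FSIQ_MODEL = {"TD": (114.83, 12.27), "ASD": (109.23, 15.15)}


def simulate_cohort(
    spec: CohortSpec,
    sensors: SensorArray | None = None,
    head: HeadModel | None = None,
    seed: int | None = None,
    simulate_meg: bool = True,
) -> list[SubjectRecord]:
    """Generate both cohorts with covariates, affines and ground truth.

    Per subject the induced-gamma gain is the group gain times a lognormal
    deviation; AQ is a truncated Gaussian correlated with the gain
    deviation through a Gaussian copula (aq_model["r"], negative by
    default).  With ``simulate_meg=False`` only covariates, gains and
    affines are produced (cheap cohorts for covariate-level analyses).
    """
    for g, n in spec.n_per_group.items():
        if n < 2:
            raise ConfigurationError(f"group {g} needs >= 2 subjects")
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    r = spec.aq_model["r"]
    cov = np.array([[1.0, r], [r, 1.0]])
    chol = np.linalg.cholesky(cov)

    records = []
    for group in spec.n_per_group:
        n = spec.n_per_group[group]
        z = rng.standard_normal((n, 2)) @ chol.T  # (z_aq, z_gain), corr r
        aq = np.clip(
            spec.aq_model["mean"][group] + spec.aq_model["sd"][group] * z[:, 0],
            0.0, 50.0,
        )
        gains = spec.group_gamma_gain[group] * np.exp(
            spec.gain_log_sd * z[:, 1]
        )
        age = rng.normal(*_AGE_MODEL[group], n)
        fsiq = rng.normal(*_FSIQ_MODEL[group], n)
        for i in range(n):
            affine = _rigid_affine(rng)
            sid = f"{group}{i + 1:02d}"
            epoch_seed = int(rng.integers(0, 2**31 - 1))
            epochs = None
            if simulate_meg:
                if sensors is None or head is None:
                    raise ConfigurationError(
                        "sensors and head required to simulate MEG"
                    )
                epochs = simulate_epoch_set(
                    spec.sources, float(gains[i]), sensors, head, spec,
                    epoch_seed, affine=affine,
                )
            records.append(
                SubjectRecord(
                    subject_id=sid,
                    group=group,
                    epochs=epochs,
                    affine=affine,
                    covariates={
                        "AQ": float(aq[i]),
                        "age_months": float(age[i]),
                        "FSIQ": float(fsiq[i]),
                    },
                    true_params={
                        "gamma_gain": float(gains[i]),
                        "epoch_seed": epoch_seed,
                        "source_locations": [
                            tuple(s.location) for s in spec.sources
                        ],
                        "evoked_amplitude": max(
                            (c.amplitude for s in spec.sources
                             for c in s.components if c.kind == "evoked"),
                            default=0.0,
                        ),
                        "induced_amplitude": max(
                            (c.amplitude for s in spec.sources
                             for c in s.components if c.kind == "induced"),
                            default=0.0,
                        ),
                    },
                )
            )
    return records


DEFAULT_RT_MODEL = {
    "group_mean_ms": {"TD": 1400.0, "ASD": 1650.0},
    "between_subject_sd_ms": 150.0,
    "within_sigma": 0.08,  # lognormal shape per condition
    "condition_offsets_ms": {c: o for c, o in zip(
        CONDITIONS, (0.0, -120.0, 60.0, 140.0, 40.0, 100.0))},
    "accuracy_mean": {"TD": 0.88, "ASD": 0.82},
    "accuracy_sd": 0.06,
    "outlier_rate": 0.0,
}


def simulate_behavioral(
    cohort: list[SubjectRecord],
    rt_model: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per subject x condition response times (ms) and accuracy.

    RTs are right-skewed lognormal around a subject mean (group mean plus a
    condition offset plus between-subject spread); a configurable fraction
    of cells is replaced by planted >2 SD outliers.
    """
    model = {**DEFAULT_RT_MODEL, **(rt_model or {})}
    if any(v <= 0 for v in model["group_mean_ms"].values()):
        raise ConfigurationError("RT means must be positive")
    if model["between_subject_sd_ms"] < 0 or model["within_sigma"] <= 0:
        raise ConfigurationError("RT spread parameters must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for rec in cohort:
        subj_shift = rng.normal(0.0, model["between_subject_sd_ms"])
        for cond in CONDITIONS:
            mu = (model["group_mean_ms"][rec.group] + subj_shift
                  + model["condition_offsets_ms"].get(cond, 0.0))
            rt = float(np.exp(np.log(max(mu, 1.0))
                              + rng.normal(0.0, model["within_sigma"])))
            if rng.uniform() < model["outlier_rate"]:
                rt *= 3.0  # far beyond 2 group SDs
            acc = float(np.clip(
                rng.normal(model["accuracy_mean"][rec.group],
                           model["accuracy_sd"]), 0.0, 1.0))
            rows.append({
                "subject": rec.subject_id,
                "group": rec.group,
                "condition": cond,
                "rt_ms": rt,
                "accuracy": acc,
            })
    return pd.DataFrame(rows)


def fast_preset(
    seed: int = 0,
    n_per_group: dict | None = None,
    n_epochs: int = 60,
    **overrides,
) -> CohortSpec:
    """Scaled-down study conditions (8+8 subjects, 60 epochs) for fast runs."""
    return CohortSpec(
        n_per_group=n_per_group or {"TD": 8, "ASD": 8},
        n_epochs=n_epochs,
        seed=seed,
        **overrides,
    )


def null_cohort_spec(seed: int = 0, **overrides) -> CohortSpec:
    """A cohort with no planted group effect (equal gains, r = 0)."""
    base = fast_preset(seed=seed, **overrides)
    return replace(
        base,
        group_gamma_gain={"TD": 1.0, "ASD": 1.0},
        aq_model={**base.aq_model, "r": 0.0},
    )
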