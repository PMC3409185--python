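"""Volumetric minimum-variance (LCMV) beamforming and group inference.

For each grid point the scalar beamformer passes the point's tangential
lead field with unit gain while minimizing output variance:

    w = C^-1 l_theta / (l_theta' C^-1 l_theta)

with the source orientation theta chosen to maximize output power (the
eigenvector of L' C^-1 L with the smallest eigenvalue).  Stimulus-related
power changes are quantified per voxel by a paired t between active and
passive window power across epochs, z-converted per subject, and taken to
the group level with sign-flip maximum-statistic permutation.  Group
differences use the contrast-of-contrasts: a two-sample t-map for the
active windows minus the one for the passive windows, thresholded at the
higher of the two label-exchange cutoffs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sst

from .errors import ConfigurationError
from .forward import LeadField, SourceGrid
from .preprocess import (DEFAULT_ACTIVES, DEFAULT_PASSIVE, EpochSet, bandpass)
from .stats import (PermutationResult, label_exchange_engine, one_sample_t_map,
                    sign_flip_engine)

#: Condition number above which a point's 2x2 source-space matrix is
#: considered degenerate and the voxel is masked rather than zeroed.
DEGENERATE_CONDITION = 1e8

#: z-scores are clamped at this magnitude when the t CDF saturates.
Z_CLAMP = 8.0


@dataclass(frozen=True)
class CovarianceMatrix:
    matrix: np.ndarray  # (n_ch, n_ch) tesla^2
    regularization: float  # diagonal loading fraction applied
    band: tuple[float, float]
    windows: tuple  # ms spans pooled

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if not np.allclose(m, m.T, atol=1e-30 + 1e-10 * np.abs(m).max()):
            raise ConfigurationError("covariance must be symmetric")
        object.__setattr__(self, "matrix", 0.5 * (m + m.T))


@dataclass(frozen=True)
class BeamformerWeights:
    """Weight vectors (n_points, n_ch) with per-point orientation angles."""

    weights: np.ndarray
    orientation: np.ndarray  # (n_points,) radians in the tangential basis
    degenerate: np.ndarray  # (n_points,) bool


@dataclass
class StatMap:
    """Per-grid-point statistic values in MNI space."""

    values: np.ndarray
    grid: SourceGrid
    kind: str  # "t" | "z" | "diff"
    df: float | None = None
    band: tuple[float, float] | None = None
    window: tuple | None = None
    threshold: float | None = None
    mask: np.ndarray | None = None
    degenerate: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != self.grid.n_points:
            raise ConfigurationError("one value per grid point required")
        if self.degenerate is None:
            self.degenerate = np.zeros(self.grid.n_points, dtype=bool)
        if self.mask is not None and self.threshold is not None:
            if np.any(self.mask & (np.abs(self.values) < self.threshold)):
                raise ConfigurationError("mask inconsistent with threshold")


def covariance(
    epochs: EpochSet,
    band: tuple[float, float],
    windows,
    regularization: float = 0.05,
    prefiltered: bool = False,
) -> CovarianceMatrix:
    """Band-limited sample covariance pooled over windows, plus loading.

    Data are band-filtered (unless ``prefiltered``), the samples of every
    listed window are concatenated across surviving epochs, and the sample
    covariance gets diagonal loading ``regularization * mean(diagonal)``.
    """
    if np.ndim(windows[0]) == 0:
        windows = (tuple(windows),)
    filtered = epochs if prefiltered else bandpass(epochs, band)
    data = filtered.surviving()
    if data.shape[0] < 2:
        raise ConfigurationError("need >= 2 surviving epochs")
    segs = [data[:, :, filtered.sample_slice(w)] for w in windows]
    pooled = np.concatenate(
        [s.transpose(1, 0, 2).reshape(data.shape[1], -1) for s in segs], axis=1
    )
    pooled = pooled - pooled.mean(axis=1, keepdims=True)
    c = pooled @ pooled.T / (pooled.shape[1] - 1)
    if regularization < 0:
        raise ConfigurationError("regularization must be >= 0")
    if regularization == 0.0:
        if np.linalg.matrix_rank(c) < c.shape[0]:
            raise ConfigurationError(
                "rank-deficient covariance with zero regularization"
            )
    else:
        c = c + regularization * np.mean(np.diag(c)) * np.eye(c.shape[0])
    return CovarianceMatrix(c, regularization, tuple(band), tuple(windows))


def _orientation_2x2(m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Smallest-eigenvalue eigenvectors of stacked symmetric 2x2 matrices.

    Returns (unit eigenvectors (P, 2), condition numbers (P,)).
    """
    a, b, c = m[:, 0, 0], m[:, 0, 1], m[:, 1, 1]
    half_tr = 0.5 * (a + c)
    disc = np.sqrt(np.maximum(0.25 * (a - c) ** 2 + b**2, 0.0))
    lam_min = half_tr - disc
    lam_max = half_tr + disc
    with np.errstate(divide="ignore", invalid="ignore"):
        cond = np.where(lam_min > 0, lam_max / lam_min, np.inf)
    # eigenvector for lam_min: (b, lam_min - a), with axis fallback
    v = np.stack([b, lam_min - a], axis=1)
    small = np.linalg.norm(v, axis=1) < 1e-30 * np.maximum(lam_max, 1.0)
    v[small] = np.where(
        (a <= c)[small, None], np.array([[1.0, 0.0]]), np.array([[0.0, 1.0]])
    )
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v, cond


def compute_weights(
    leadfield: LeadField | np.ndarray, cov: CovarianceMatrix
) -> BeamformerWeights:
    """Minimum-variance weights and optimal orientation per grid point.

    The orientation maximizes beamformer output power, i.e. the smallest
    eigenvalue eigenvector of L' C^-1 L; the weight vector satisfies the
    unit-gain constraint w' l_theta = 1.  Points whose 2x2 matrix is
    ill-conditioned are flagged degenerate and excluded from maps.
    """
    L = leadfield.matrix if isinstance(leadfield, LeadField) else leadfield
    if L.ndim == 2:
        L = L[None]
    n_pts, n_ch, _ = L.shape
    cinv_l = np.linalg.solve(
        cov.matrix, L.transpose(1, 0, 2).reshape(n_ch, -1)
    ).reshape(n_ch, n_pts, 2).transpose(1, 0, 2)  # (P, n_ch, 2)
    m = np.einsum("pki,pkj->pij", L, cinv_l)  # L' C^-1 L
    v, cond = _orientation_2x2(m)
    degenerate = ~np.isfinite(cond) | (cond > DEGENERATE_CONDITION)
    l_theta = np.einsum("pki,pi->pk", L, v)
    cinv_ltheta = np.einsum("pki,pi->pk", cinv_l, v)
    denom = np.einsum("pk,pk->p", l_theta, cinv_ltheta)
    degenerate |= ~(denom > 0)
    safe = np.where(degenerate, 1.0, denom)
    w = cinv_ltheta / safe[:, None]
    w[degenerate] = 0.0
    return BeamformerWeights(
        weights=w,
        orientation=np.arctan2(v[:, 1], v[:, 0]),
        degenerate=degenerate,
    )


def _window_power(
    traces: np.ndarray, epochs: EpochSet, window: tuple[float, float]
) -> np.ndarray:
    """Mean squared amplitude over window samples; traces (..., E, T)."""
    sl = epochs.sample_slice(window)
    return np.mean(traces[..., sl] ** 2, axis=-1)


def paired_power_t(active: np.ndarray, passive: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Paired t across epochs of active minus passive power, vectorized.

    Returns (t, degenerate) over the leading axes; zero-variance
    differences give t = 0 with the degenerate flag set.
    """
    d = active - passive
    n = d.shape[-1]
    if n < 2:
        raise ConfigurationError("need >= 2 epochs for a paired t")
    sd = d.std(axis=-1, ddof=1)
    degenerate = sd == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(~degenerate, d.mean(axis=-1) / (sd / math.sqrt(n)), 0.0)
    return t, degenerate


def voxel_power_contrast(
    weights: np.ndarray,
    epochs: EpochSet,
    band: tuple[float, float],
    window_pair: tuple[tuple[float, float], tuple[float, float]],
    prefiltered: bool = False,
) -> dict:
    """Per-epoch active/passive power at one voxel plus the paired t.

    Positive t means a stimulus-related power increase.
    """
    filtered = epochs if prefiltered else bandpass(epochs, band)
    data = filtered.surviving()
    traces = np.einsum("k,ekt->et", np.asarray(weights, float), data)
    active_w, passive_w = window_pair
    p_act = _window_power(traces, filtered, active_w)
    p_pas = _window_power(traces, filtered, passive_w)
    t, degenerate = paired_power_t(p_act, p_pas)
    return {
        "t": float(t),
        "df": p_act.shape[0] - 1,
        "active_power": p_act,
        "passive_power": p_pas,
        "degenerate": bool(degenerate),
    }


def scan_volume(
    epochs: EpochSet,
    leadfield: LeadField,
    band: tuple[float, float],
    window_pair: tuple[tuple[float, float], tuple[float, float]] | None = None,
    regularization: float = 0.05,
    cov_windows=None,
) -> StatMap:
    """Active-vs-passive paired t at every grid point.

    The covariance pools the passive and all active windows of the
    band-filtered data (configurable through ``cov_windows``).  The
    resulting map records per-voxel subject-level mean active and passive
    power in ``extras`` for downstream between-group contrasts.
    """
    if window_pair is None:
        window_pair = (DEFAULT_ACTIVES[1], DEFAULT_PASSIVE)
    active_w, passive_w = window_pair
    if cov_windows is None:
        cov_windows = (DEFAULT_PASSIVE,) + tuple(DEFAULT_ACTIVES)
    filtered = bandpass(epochs, band)
    cov = covariance(filtered, band, cov_windows, regularization,
                     prefiltered=True)
    bw = compute_weights(leadfield, cov)
    data = filtered.surviving()  # (E, N, T)
    sl_a = filtered.sample_slice(active_w)
    sl_p = filtered.sample_slice(passive_w)
    n_epochs = data.shape[0]
    p_act = np.empty((bw.weights.shape[0], n_epochs))
    p_pas = np.empty_like(p_act)
    # per-epoch matmuls keep peak memory at one (n_points, n_samples) block
    for e in range(n_epochs):
        p_act[:, e] = np.mean((bw.weights @ data[e, :, sl_a]) ** 2, axis=1)
        p_pas[:, e] = np.mean((bw.weights @ data[e, :, sl_p]) ** 2, axis=1)
    t, degen_t = paired_power_t(p_act, p_pas)
    degenerate = bw.degenerate | degen_t
    t = np.where(bw.degenerate, 0.0, t)
    return StatMap(
        values=t,
        grid=leadfield.grid,
        kind="t",
        df=data.shape[0] - 1,
        band=tuple(band),
        window=window_pair,
        degenerate=degenerate,
        extras={
            "mean_active_power": p_act.mean(axis=1),
            "mean_passive_power": p_pas.mean(axis=1),
            "regularization": regularization,
        },
    )


def t_to_z(stat_map: StatMap) -> StatMap:
    """Convert a t map to z-scores via the probit of the t CDF.

    Sign-preserving and monotone; values past CDF saturation are clamped at
    |z| = 8 and flagged in ``extras['z_clamped']``.
    """
    if stat_map.kind != "t":
        raise ConfigurationError("t_to_z expects a t map")
    if stat_map.df is None or stat_map.df < 1:
        raise ConfigurationError("df >= 1 required")
    t = stat_map.values
    # symmetric tail formulation keeps precision for large |t|
    z = -sst.norm.ppf(sst.t.sf(np.abs(t), stat_map.df))
    clamped = ~np.isfinite(z) | (z > Z_CLAMP)
    z = np.where(clamped, Z_CLAMP, z) * np.sign(t)
    out = StatMap(
        values=z,
        grid=stat_map.grid,
        kind="z",
        df=stat_map.df,
        band=stat_map.band,
        window=stat_map.window,
        degenerate=stat_map.degenerate.copy(),
        extras=dict(stat_map.extras),
    )
    out.extras["z_clamped"] = clamped
    return out


def group_onesample(
    maps: list[StatMap],
    n_permutations: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> tuple[StatMap, PermutationResult]:
    """Group one-sample t over subject z maps with sign-flip thresholding.

    The null is built by inverting the polarity of whole subject maps; the
    (1 - alpha) quantile of the permutation max |t| is the two-sided
    significance threshold.
    """
    if len(maps) < 2:
        raise ConfigurationError("need >= 2 subjects")
    grid = maps[0].grid
    for m in maps[1:]:
        if m.grid.n_points != grid.n_points:
            raise ConfigurationError("subject maps must share the grid")
    stack = np.stack([m.values for m in maps])
    degenerate = np.any([m.degenerate for m in maps], axis=0)
    stack = np.where(degenerate[None, :], 0.0, stack)
    perm = sign_flip_engine(
        stack, statistic=one_sample_t_map, n_permutations=n_permutations,
        alpha=alpha, seed=seed,
    )
    observed = perm.observed
    result = StatMap(
        values=observed,
        grid=grid,
        kind="t",
        df=len(maps) - 1,
        band=maps[0].band,
        window=maps[0].window,
        threshold=perm.threshold,
        mask=perm.mask & ~degenerate,
        degenerate=degenerate,
    )
    return result, perm


def between_groups_contrast(
    powers_a: dict,
    powers_b: dict,
    grid: SourceGrid,
    n_permutations: int = 300,
    alpha: float = 0.001,
    seed: int | None = None,
    band=None,
    window=None,
) -> StatMap:
    """Contrast-of-contrasts between two cohorts.

    ``powers_a`` / ``powers_b`` carry per-subject mean band power per voxel
    under keys "active" and "passive" (shape n_subjects x n_points).  Two
    unpaired t-maps are computed (active A vs B, passive A vs B), each with
    its own label-exchange maximum-statistic cutoff; the output map is
    t_active - t_passive, thresholded at whichever of the two cutoffs is
    higher.
    """
    for d in (powers_a, powers_b):
        if d["active"].shape[0] < 2:
            raise ConfigurationError("each group needs >= 2 subjects")
    perm_act = label_exchange_engine(
        powers_a["active"], powers_b["active"],
        n_permutations=n_permutations, alpha=alpha, seed=seed,
    )
    perm_pas = label_exchange_engine(
        powers_a["passive"], powers_b["passive"],
        n_permutations=n_permutations, alpha=alpha,
        seed=None if seed is None else seed + 1,
    )
    diff = perm_act.observed - perm_pas.observed
    cutoff = max(perm_act.threshold, perm_pas.threshold)
    return StatMap(
        values=diff,
        grid=grid,
        kind="diff",
        band=band,
        window=window,
        threshold=cutoff,
        mask=(np.abs(diff) >= cutoff) & (np.abs(diff) > 0),
        extras={
            "t_active": perm_act.observed,
            "t_passive": perm_pas.observed,
            "cutoff_active": perm_act.threshold,
            "cutoff_passive": perm_pas.threshold,
            "n_permutations": n_permutations,
            "alpha": alpha,
            "seed": seed,
        },
    )


def find_peaks(stat_map: StatMap, k: int = 5) -> pd.DataFrame:
    """Top-k significant maxima and minima with MNI mm coordinates.

    Only voxels in the significance mask are candidates.  Within each
    polarity, voxels are ranked by |value| (descending) with lexicographic
    coordinate tie-breaks.  Returns columns (x, y, z, value, polarity);
    empty when nothing is significant.
    """
    if stat_map.mask is None:
        raise ConfigurationError("find_peaks requires a thresholded map")
    rows = []
    for polarity, sel in (
        ("max", stat_map.mask & (stat_map.values > 0)),
        ("min", stat_map.mask & (stat_map.values < 0)),
    ):
        idx = np.nonzero(sel)[0]
        if idx.size == 0:
            continue
        pts = stat_map.grid.points[idx]
        vals = stat_map.values[idx]
        order = np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0], -np.abs(vals)))
        for j in order[:k]:
            rows.append(
                {"x": pts[j, 0], "y": pts[j, 1], "z": pts[j, 2],
                 "value": vals[j], "polarity": polarity}
            )
    return pd.DataFrame(rows, columns=["x", "y", "z", "value", "polarity"])
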