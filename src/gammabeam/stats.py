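"""Shared statistical machinery.

t-tests (pooled / Welch / paired / one-sample), Bonferroni adjustment,
response-time trimming and log transform, the sign-flip and label-exchange
maximum-statistic permutation engines used by the volumetric and
time-frequency group analyses, and backward-elimination regression.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sst

from .errors import ConfigurationError, DegenerateStatisticError


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    df: float
    p: float  # two-sided
    variant: str  # pooled | welch | paired | one_sample
    group_summaries: tuple = ()  # ((n, mean, sd), ...)
    degenerate: bool = False


@dataclass(frozen=True)
class RegressionResult:
    retained: tuple[str, ...]
    coefficients: dict  # standardized betas for retained predictors
    r_squared: float
    f_statistic: float
    df_model: int
    df_resid: int
    removal_trail: tuple = ()  # ((name, p_at_removal), ...)
    coefficient_t: dict = field(default_factory=dict)
    coefficient_p: dict = field(default_factory=dict)


@dataclass(frozen=True)
class PermutationResult:
    """Observed statistic map plus the permutation null of its maximum."""

    observed: np.ndarray
    null_max: np.ndarray
    alpha: float
    threshold: float
    n_permutations: int
    seed: int | None
    exhaustive: bool = False

    @property
    def mask(self) -> np.ndarray:
        """Two-sided significance mask at the max-statistic threshold.

        A zero statistic is never significant, even under a degenerate
        all-zero null whose threshold collapses to 0.
        """
        a = np.abs(self.observed)
        return (a >= self.threshold) & (a > 0)


def _two_sided_p(t: float, df: float) -> float:
    return float(2.0 * sst.t.sf(abs(t), df))


def pooled_t(
    samples1=None,
    samples2=None,
    *,
    n1: int | None = None,
    mean1: float | None = None,
    sd1: float | None = None,
    n2: int | None = None,
    mean2: float | None = None,
    sd2: float | None = None,
) -> TTestResult:
    """Classic pooled-variance two-sample t-test, df = n1 + n2 - 2.

    Accepts either raw samples or printed summary statistics (n, mean, SD),
    so group comparisons reported only as summaries can be recomputed.
    """
    if samples1 is not None:
        x = np.asarray(samples1, dtype=float)
        y = np.asarray(samples2, dtype=float)
        n1, mean1, sd1 = len(x), float(x.mean()), float(x.std(ddof=1))
        n2, mean2, sd2 = len(y), float(y.mean()), float(y.std(ddof=1))
    if None in (n1, mean1, sd1, n2, mean2, sd2):
        raise ConfigurationError("provide raw samples or full summaries")
    if n1 < 2 or n2 < 2:
        raise ConfigurationError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ConfigurationError("standard deviations must be non-negative")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    degenerate = se == 0.0
    t = 0.0 if degenerate else (mean1 - mean2) / se
    return TTestResult(
        statistic=t,
        df=df,
        p=1.0 if degenerate else _two_sided_p(t, df),
        variant="pooled",
        group_summaries=((n1, mean1, sd1), (n2, mean2, sd2)),
        degenerate=degenerate,
    )


def welch_t(samples1, samples2) -> TTestResult:
    """Welch two-sample t-test with Satterthwaite degrees of freedom."""
    x = np.asarray(samples1, dtype=float)
    y = np.asarray(samples2, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ConfigurationError("each group needs n >= 2")
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    n1, n2 = len(x), len(y)
    se2 = v1 / n1 + v2 / n2
    if se2 == 0.0:
        return TTestResult(0.0, n1 + n2 - 2, 1.0, "welch",
                           ((n1, x.mean(), 0.0), (n2, y.mean(), 0.0)),
                           degenerate=True)
    t = float((x.mean() - y.mean()) / math.sqrt(se2))
    df = float(se2**2 / (v1**2 / (n1**2 * (n1 - 1)) + v2**2 / (n2**2 * (n2 - 1))))
    return TTestResult(
        statistic=t, df=df, p=_two_sided_p(t, df), variant="welch",
        group_summaries=((n1, float(x.mean()), float(x.std(ddof=1))),
                         (n2, float(y.mean()), float(y.std(ddof=1)))),
    )


def paired_t(x, y) -> TTestResult:
    """Paired t across matched observations; zero-variance -> t = 0 flagged."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    if d.size < 2:
        raise ConfigurationError("paired t needs n >= 2")
    return one_sample_t(d, variant="paired")


def one_sample_t(values, popmean: float = 0.0, variant: str = "one_sample") -> TTestResult:
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ConfigurationError("one-sample t needs n >= 2")
    sd = v.std(ddof=1)
    df = v.size - 1
    if sd == 0.0:
        return TTestResult(0.0, df, 1.0, variant,
                           ((v.size, float(v.mean()), 0.0),), degenerate=True)
    t = float((v.mean() - popmean) / (sd / math.sqrt(v.size)))
    return TTestResult(t, df, _two_sided_p(t, df), variant,
                       ((v.size, float(v.mean()), float(sd)),))


def bonferroni_adjust(alpha: float, m: int) -> float:
    """Per-test alpha under Bonferroni correction: alpha / m."""
    if m < 1:
        raise ConfigurationError("m must be >= 1")
    return alpha / m


def trim_outliers(table: pd.DataFrame, value_col: str, by: list[str],
                  k: float = 2.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove values more than k cell SDs from their cell mean (single pass).

    ``by`` names the grouping columns defining a cell (e.g. group x emotion).
    Returns the surviving rows and a log of removed rows with the cell
    statistics that condemned them.
    """
    if k <= 0:
        raise ConfigurationError("k must be positive")
    removed_parts = []
    keep_mask = np.ones(len(table), dtype=bool)
    for _, idx in table.groupby(by, sort=False).groups.items():
        cell = table.loc[idx, value_col].astype(float)
        if len(cell) < 3:
            raise ConfigurationError("each cell needs n >= 3 for trimming")
        mu, sd = cell.mean(), cell.std(ddof=1)
        out = (cell - mu).abs() > k * sd
        if out.any():
            log = table.loc[idx[out.to_numpy()]].copy()
            log["cell_mean"] = mu
            log["cell_sd"] = sd
            removed_parts.append(log)
            keep_mask[table.index.get_indexer(idx[out.to_numpy()])] = False
    if not keep_mask.any():
        raise DegenerateStatisticError("trimming removed every value")
    removed = (pd.concat(removed_parts) if removed_parts
               else table.iloc[0:0].copy())
    return table[keep_mask].copy(), removed


def log10_transform(values) -> np.ndarray:
    """Elementwise log10; rejects non-positive values by index."""
    v = np.asarray(values, dtype=float)
    bad = np.nonzero(~(v > 0))[0]
    if bad.size:
        raise ConfigurationError(
            f"log10 transform requires positive values; offending index "
            f"{int(bad[0])} (value {v[bad[0]]!r})"
        )
    return np.log10(v)


#: Saturation value standing in for an infinite t when every subject agrees
#: exactly (zero variance, nonzero mean).  Permutation inference only needs
#: the statistic's ordering, so any value larger than all finite ts works.
T_SATURATION = 1e12


def one_sample_t_map(maps: np.ndarray) -> np.ndarray:
    """Vectorized one-sample t across subjects for each map element.

    Zero-variance elements with a nonzero mean saturate at
    ``sign(mean) * T_SATURATION``; zero-variance zero-mean elements get 0.
    """
    n = maps.shape[0]
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / math.sqrt(n)),
                     np.sign(mean) * T_SATURATION)
    return t


def two_sample_t_map(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized pooled two-sample t (group a minus group b) per element."""
    n1, n2 = a.shape[0], b.shape[0]
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * a.var(axis=0, ddof=1)
           + (n2 - 1) * b.var(axis=0, ddof=1)) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (a.mean(axis=0) - b.mean(axis=0)) / se, 0.0)
    return t


def _perm_threshold(null_max: np.ndarray, alpha: float) -> float:
    """(1 - alpha) quantile of the null maxima, linear interpolation."""
    return float(np.quantile(null_max, 1.0 - alpha))


def sign_flip_engine(
    subject_maps: np.ndarray,
    statistic=None,
    n_permutations: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> PermutationResult:
    """One-sample maximum-statistic permutation by whole-subject sign flips.

    ``subject_maps`` is (n_subjects, ...) — one first-level map per subject;
    ``statistic`` maps the stack to a statistic array (default: one-sample
    t per element).  Each permutation flips the polarity of a random subset
    of subjects and records max |statistic|.  When every sign pattern fits
    in the permutation budget (2**n <= n_permutations) the null is built by
    exhaustive enumeration instead of sampling.
    """
    maps = np.asarray(subject_maps, dtype=float)
    n = maps.shape[0]
    if n < 2:
        raise ConfigurationError("need at least 2 subjects")
    if n_permutations < 10:
        raise ConfigurationError("fewer than 10 permutations is meaningless")
    if n_permutations < 100:
        warnings.warn("n_permutations < 100: threshold will be coarse",
                      stacklevel=2)
    statistic = statistic or one_sample_t_map
    flat = maps.reshape(n, -1)
    observed = np.asarray(statistic(flat), dtype=float)

    exhaustive = 2**n <= n_permutations
    if exhaustive:
        patterns = ((np.arange(2**n)[:, None] >> np.arange(n)) & 1) * 2 - 1
    else:
        rng = np.random.default_rng(seed)
        patterns = rng.choice([-1.0, 1.0], size=(n_permutations, n))
    null_max = np.empty(len(patterns))
    for i, signs in enumerate(patterns):
        null_max[i] = np.abs(statistic(flat * signs[:, None])).max()
    threshold = _perm_threshold(null_max, alpha)
    return PermutationResult(
        observed=observed.reshape(maps.shape[1:]),
        null_max=null_max,
        alpha=alpha,
        threshold=threshold,
        n_permutations=len(patterns),
        seed=seed,
        exhaustive=exhaustive,
    )


def label_exchange_engine(
    group_a: np.ndarray,
    group_b: np.ndarray,
    statistic=None,
    n_permutations: int = 300,
    alpha: float = 0.001,
    seed: int | None = None,
) -> PermutationResult:
    """Two-sample maximum-statistic permutation by group-label exchange.

    Pools both groups, redraws the group-A membership per permutation, and
    records max |statistic|.  When the number of distinct label assignments
    C(n, nA) is within the permutation budget, all assignments are
    enumerated (with a warning that fewer distinct permutations exist than
    requested); otherwise assignments are sampled uniformly.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise ConfigurationError("each group needs >= 2 subjects")
    statistic = statistic or two_sample_t_map
    flat_a, flat_b = a.reshape(na, -1), b.reshape(nb, -1)
    pooled = np.concatenate([flat_a, flat_b], axis=0)
    observed = np.asarray(statistic(flat_a, flat_b), dtype=float)

    n_total = na + nb
    n_distinct = math.comb(n_total, na)
    exhaustive = n_distinct <= n_permutations
    if exhaustive:
        if n_distinct < n_permutations:
            warnings.warn(
                f"only {n_distinct} distinct label assignments exist "
                f"(requested {n_permutations}); enumerating all of them",
                stacklevel=2,
            )
        assignments = [np.array(c) for c in combinations(range(n_total), na)]
    else:
        rng = np.random.default_rng(seed)
        assignments = [rng.permutation(n_total)[:na]
                       for _ in range(n_permutations)]
    null_max = np.empty(len(assignments))
    all_idx = np.arange(n_total)
    for i, idx_a in enumerate(assignments):
        mask = np.zeros(n_total, dtype=bool)
        mask[idx_a] = True
        null_max[i] = np.abs(
            statistic(pooled[mask], pooled[all_idx[~mask]])
        ).max()
    threshold = _perm_threshold(null_max, alpha)
    return PermutationResult(
        observed=observed.reshape(a.shape[1:]),
        null_max=null_max,
        alpha=alpha,
        threshold=threshold,
        n_permutations=len(assignments),
        seed=seed,
        exhaustive=exhaustive,
    )


def backward_regression(
    y,
    predictors: pd.DataFrame,
    removal_alpha: float = 0.10,
) -> RegressionResult:
    """Backward-elimination OLS on standardized response and predictors.

    Starts from the full model and repeatedly drops the predictor with the
    largest p-value above ``removal_alpha`` until every retained predictor
    is at or below it.  Coefficients are standardized betas (response and
    predictors z-scored), so they are comparable across predictors.
    """
    y = np.asarray(y, dtype=float)
    X = predictors.astype(float)
    names = list(X.columns)
    n = len(y)
    if n != len(X):
        raise ConfigurationError("response/predictor length mismatch")
    if n <= len(names) + 2:
        raise ConfigurationError("too few observations for the model")

    yz = (y - y.mean()) / y.std(ddof=1)
    Xz = (X - X.mean()) / X.std(ddof=1)
    if np.linalg.cond(Xz.to_numpy()) > 1e10:
        raise ConfigurationError("predictors are (near-)collinear")

    import statsmodels.api as sm

    def _fit(cols):
        return sm.OLS(yz, sm.add_constant(Xz[cols].to_numpy())).fit()

    trail: list[tuple[str, float]] = []
    current = list(names)
    while current:
        fit = _fit(current)
        pvals = fit.pvalues[1:]
        worst = int(np.argmax(pvals))
        if pvals[worst] > removal_alpha:
            trail.append((current[worst], float(pvals[worst])))
            current.pop(worst)
        else:
            break

    if current:
        fit = _fit(current)
        df_model = len(current)
        df_resid = n - df_model - 1
        r2 = float(fit.rsquared)
        f = float(fit.fvalue)
        coef = dict(zip(current, fit.params[1:]))
        coef_t = dict(zip(current, fit.tvalues[1:]))
        coef_p = dict(zip(current, fit.pvalues[1:]))
    else:
        df_model, df_resid, r2, f = 0, n - 1, 0.0, 0.0
        coef, coef_t, coef_p = {}, {}, {}

    return RegressionResult(
        retained=tuple(current),
        coefficients=coef,
        r_squared=float(r2),
        f_statistic=float(f),
        df_model=df_model,
        df_resid=df_resid,
        removal_trail=tuple(trail),
        coefficient_t=coef_t,
        coefficient_p=coef_p,
    )
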