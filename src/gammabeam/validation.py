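"""End-to-end validation experiments on synthetic cohorts.

Each function runs one self-contained recovery or calibration experiment
through the public pipeline — planting a known effect with the simulator,
estimating it back with the beamformer / time-frequency / statistics
stages, and reporting the recovery quality.  The acceptance script and the
acceptance test suite both call these, so the numbers they report are
always produced by the same code path as a real analysis.

Problem sizes are scaled to desk hardware (tens of sensors, tens of
epochs); the planted effect sizes and noise levels are the generator
defaults.
"""

from __future__ import annotations


import numpy as np

from . import beamform as bf
from . import pipeline as pl
from . import stats as gstats
from . import virtual_electrode as ve
from .forward import (HeadModel, build_sensor_array, build_source_grid,
                      lead_field_matrix)
from .simulate import (CohortSpec, SourceComponent, SourceSpec, fast_preset,
                       simulate_cohort, simulate_epoch_set)

GAMMA = (30.0, 80.0)
WINDOW_PAIR = ((250.0, 450.0), (-300.0, -100.0))

#: Planted occipital sites used when checking spatial recovery.
_OCCIPITAL = (np.array([36.0, -86.0, 2.0]), np.array([-20.0, -92.0, 16.0]))


def _sub_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def aq_group_separation() -> gstats.TTestResult:
    """Pooled two-sample t on the AQ questionnaire group summaries.

    Uses the printed summaries the generator's AQ model is built from:
    n=13, mean 38.62, SD 6.16 versus n=12, mean 12.33, SD 6.47.
    """
    return gstats.pooled_t(n1=13, mean1=38.62, sd1=6.16,
                           n2=12, mean2=12.33, sd2=6.47)


def localization_recovery(
    n_repeats: int = 50,
    seed: int = 0,
    n_sensors: int = 32,
    n_epochs: int = 30,
    grid_spacing: float = 5.0,
) -> dict:
    """Single-source localization: fraction of repeats in which the peak
    |t| voxel lands within one grid spacing of the planted source.

    Each repeat plants one induced 60 Hz source (default amplitude and
    sensor noise) at a random grid point, scans the whole 5 mm grid in the
    gamma band, and measures the argmax-to-truth distance.
    """
    rng = np.random.default_rng(seed)
    head = HeadModel()
    sensors = build_sensor_array(n_sensors, head=head)
    grid = build_source_grid(grid_spacing, head)
    lf = lead_field_matrix(grid, sensors, head)
    # avoid planting within a spacing of the masked rim
    d = np.linalg.norm(grid.points - head.center_mm, axis=1)
    candidates = np.nonzero(
        (d > 20.0 + grid_spacing) & (d < head.radius_mm - 5.0 - grid_spacing)
    )[0]
    hits = 0
    errors = []
    for _ in range(n_repeats):
        truth = grid.points[rng.choice(candidates)]
        comp = SourceComponent(kind="induced", center_freq=60.0,
                               bandwidth=20.0, onset_ms=150.0,
                               offset_ms=650.0, amplitude=2e-8)
        src = SourceSpec(tuple(truth), rng.uniform(-np.pi, np.pi), (comp,))
        spec = CohortSpec(n_per_group={"TD": 2, "ASD": 2},
                          n_epochs=n_epochs, sources=(src,))
        ep = simulate_epoch_set(spec.sources, 2.5, sensors, head, spec,
                                _sub_seed(rng))
        tmap = bf.scan_volume(ep, lf, GAMMA, WINDOW_PAIR)
        peak = grid.points[np.argmax(np.abs(tmap.values))]
        err = float(np.linalg.norm(peak - truth))
        errors.append(err)
        hits += err <= grid_spacing
    return {"hit_rate": hits / n_repeats, "n_repeats": n_repeats,
            "mean_error_mm": float(np.mean(errors))}


def evoked_induced_dissociation(seed: int = 0, n_epochs: int = 300,
                                n_sensors: int = 32) -> dict:
    """Evoked/induced power ratio at the source frequency for a VE trace.

    With uniform random per-epoch phase the phase-locked (evoked) estimate
    must collapse while per-epoch (induced) power is unaffected; with zero
    phase jitter the two coincide.
    """
    rng = np.random.default_rng(seed)
    head = HeadModel()
    sensors = build_sensor_array(n_sensors, head=head)
    out = {}
    for label, jitter in (("random_phase", np.pi), ("locked", 0.0)):
        comp = SourceComponent(kind="induced", center_freq=60.0,
                               bandwidth=0.0, onset_ms=150.0,
                               offset_ms=650.0, amplitude=2e-8,
                               phase_jitter=jitter)
        src = SourceSpec((36.0, -86.0, 2.0), 0.3, (comp,))
        spec = CohortSpec(n_per_group={"TD": 2, "ASD": 2},
                          n_epochs=n_epochs, sources=(src,),
                          sensor_noise_sd=1e-14)
        ep = simulate_epoch_set(spec.sources, 2.0, sensors, head, spec,
                                _sub_seed(rng))
        cov = bf.covariance(ep, GAMMA, ((-300.0, -100.0), (50.0, 650.0)),
                            0.05)
        site = ve.VESite(src.location, "theory_driven", "src")
        w = ve.place_ve(site, np.eye(4), sensors, head, cov)
        trace = ve.reconstruct_trace(w, ep, site)
        evoked = ve.evoked_tf(trace, (50.0, 70.0), freq_step=5.0)
        induced = ve.induced_tf(trace, (50.0, 70.0), freq_step=5.0)
        row = np.argmin(np.abs(evoked.freqs_hz - 60.0))
        sel = (evoked.times_ms >= 200.0) & (evoked.times_ms < 600.0)
        out[label] = float(evoked.values[row, sel].mean()
                           / induced.values[row, sel].mean())
    return {"ratio_random_phase": out["random_phase"],
            "ratio_locked": out["locked"], "n_epochs": n_epochs}


def permutation_calibration(
    n_runs: int = 200,
    seed: int = 0,
    n_subjects: int = 10,
    n_voxels: int = 50,
    n_permutations: int = 200,
    alpha: float = 0.05,
) -> dict:
    """Family-wise error of the sign-flip engine on null subject maps,
    plus exact equivalence of both engines with exhaustive enumeration.

    Null cohorts carry no effect (zero-mean subject maps), so any
    significant voxel is a family-wise false positive.
    """
    rng = np.random.default_rng(seed)
    false_positives = 0
    for r in range(n_runs):
        maps = rng.standard_normal((n_subjects, n_voxels))
        res = gstats.sign_flip_engine(maps, n_permutations=n_permutations,
                                      alpha=alpha, seed=_sub_seed(rng))
        false_positives += bool(res.mask.any())
    fwer = false_positives / n_runs

    # exhaustive equivalence, sign-flip at n=8
    import itertools
    maps8 = rng.standard_normal((8, 12))
    engine = gstats.sign_flip_engine(maps8, n_permutations=256, alpha=alpha)
    maxima = [
        np.abs(gstats.one_sample_t_map(
            maps8 * np.array(sg)[:, None])).max()
        for sg in itertools.product([-1.0, 1.0], repeat=8)
    ]
    sf_match = abs(engine.threshold
                   - float(np.quantile(maxima, 1 - alpha))) < 1e-12

    # exhaustive equivalence, label exchange at 4+4
    a = rng.standard_normal((4, 6))
    b = rng.standard_normal((4, 6))
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lex = gstats.label_exchange_engine(a, b, n_permutations=300,
                                           alpha=alpha)
    pooled = np.concatenate([a, b])
    maxima = []
    for combo in itertools.combinations(range(8), 4):
        mask = np.zeros(8, dtype=bool)
        mask[list(combo)] = True
        maxima.append(np.abs(gstats.two_sample_t_map(
            pooled[mask], pooled[~mask])).max())
    le_match = abs(lex.threshold
                   - float(np.quantile(maxima, 1 - alpha))) < 1e-12

    return {"fwer": fwer, "n_runs": n_runs,
            "signflip_exhaustive_match": bool(sf_match),
            "label_exchange_exhaustive_match": bool(le_match)}


def group_effect_recovery(seed: int = 0, n_sensors: int = 64,
                          n_epochs: int = 60) -> dict:
    """Two-cohort gamma-effect recovery at scaled-down size (8+8, 60 epochs).

    Simulates the default TD-like > ASD-like induced-gamma cohort, runs the
    full within-group and between-group volumetric analyses in the gamma
    band (250-450 ms window), and reports whether (a) the TD-like map has
    significant positive occipital voxels while the ASD-like map has no
    significant positives anywhere, and (b) the between-groups
    contrast-of-contrasts marks the planted occipital region at the
    dual-cutoff rule.
    """
    head = HeadModel()
    sensors = build_sensor_array(n_sensors, head=head)
    grid = build_source_grid(5.0, head)
    spec = fast_preset(seed=seed, n_epochs=n_epochs)
    records = simulate_cohort(spec, sensors, head, seed=seed)
    for rec in records:
        pl.preprocess_subject(rec)
    res = pl.group_band_analysis(records, sensors, head, grid, GAMMA,
                                 WINDOW_PAIR, seed=seed)
    occip = np.zeros(grid.n_points, dtype=bool)
    for site in _OCCIPITAL:
        occip |= np.linalg.norm(grid.points - site, axis=1) <= 12.0

    td = res["within"]["TD"]
    asd = res["within"]["ASD"]
    between = res["between"]
    td_occ = int((td.mask & (td.values > 0) & occip).sum())
    asd_pos = int((asd.mask & (asd.values > 0)).sum())
    between_occ = int((between.mask & (between.values > 0) & occip).sum())
    return {
        "td_occipital_sig_positive": td_occ,
        "asd_sig_positive_anywhere": asd_pos,
        "between_sig_at_planted": between_occ,
        "between_cutoff": float(between.threshold),
        "n_per_group": dict(spec.n_per_group),
    }


def regression_recovery(n_cohorts: int = 100, seed: int = 0) -> dict:
    """Backward-elimination recovery of the planted AQ-gain relation.

    Each cohort draws the default 13+12 covariate set with
    corr(AQ, induced-gamma gain) = -0.5 within group; the subject's
    planted gain (the simulator's ground truth for the induced response)
    is regressed on AQ, age and FSIQ.  Success = AQ retained with a
    negative standardized beta and both nuisance predictors dropped.
    """
    rng = np.random.default_rng(seed)
    successes = 0
    betas = []
    for _ in range(n_cohorts):
        spec = CohortSpec()
        records = simulate_cohort(spec, seed=_sub_seed(rng),
                                  simulate_meg=False)
        y = np.array([r.true_params["gamma_gain"] for r in records])
        import pandas as pd
        X = pd.DataFrame([r.covariates for r in records])[
            ["AQ", "age_months", "FSIQ"]]
        res = gstats.backward_regression(y, X)
        ok = (res.retained == ("AQ",)
              and res.coefficients["AQ"] < 0)
        successes += ok
        if "AQ" in res.coefficients:
            betas.append(res.coefficients["AQ"])
    return {"retention_rate": successes / n_cohorts,
            "n_cohorts": n_cohorts,
            "mean_aq_beta": float(np.mean(betas)) if betas else float("nan")}


def stockwell_identity(n_signals: int = 100, seed: int = 0) -> dict:
    """Max deviation of the S-transform time-marginal from the DFT."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_signals):
        n = int(rng.integers(64, 1400))
        x = rng.standard_normal(n)
        freqs, S = ve.stockwell(x, 678.17, 3.0, 100.0, 13.0)
        X = np.fft.fft(x) / n
        for i, f in enumerate(freqs):
            k = int(round(f * n / 678.17))
            worst = max(worst, abs(S[i].mean() - X[k]))
    return {"max_error": worst, "n_signals": n_signals}
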