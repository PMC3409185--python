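"""Virtual electrodes, Stockwell transform, evoked/induced decomposition."""

import numpy as np
import pytest

from gammabeam import beamform as bf
from gammabeam.errors import ConfigurationError
from gammabeam.forward import point_lead_field
from gammabeam.simulate import (CohortSpec, SourceComponent, SourceSpec,
                                simulate_epoch_set)
from gammabeam.virtual_electrode import (DEFAULT_VE_SITES, TFMap, VESite,
                                         VETrace, evoked_tf, induced_tf,
                                         place_ve, reconstruct_trace,
                                         select_ve_sites, stockwell,
                                         tf_first_level, tf_group_permutation)

FS = 678.17


def make_trace(traces, fs=FS):
    traces = np.atleast_2d(np.asarray(traces, float))
    n = traces.shape[1]
    t = -1000.0 + np.arange(n) / fs * 1000.0
    return VETrace(traces=traces, time_ms=t, sampling_rate=fs)


def planted_epochs(sensors, head, *, phase_jitter=np.pi, n_epochs=36,
                   noise=1e-14, freq=60.0, seed=0, amplitude=2e-8):
    comp = SourceComponent(kind="induced", center_freq=freq, bandwidth=0.0,
                           onset_ms=150.0, offset_ms=650.0,
                           amplitude=amplitude, phase_jitter=phase_jitter)
    src = SourceSpec((36.0, -86.0, 2.0), 0.3, (comp,))
    spec = CohortSpec(n_per_group={"TD": 2, "ASD": 2}, n_epochs=n_epochs,
                      sensor_noise_sd=noise, sources=(src,))
    return simulate_epoch_set(spec.sources, 2.0, sensors, head, spec,
                              seed), src


class TestSiteSelection:
    def test_theory_site_passthrough(self, coarse_grid):
        sites = select_ve_sites(theory_sites=[((32.0, -57.0, -3.0), "R-FG")])
        assert sites == [VESite((32.0, -57.0, -3.0), "theory_driven", "R-FG")]

    def test_single_voxel_modes_coincide(self, coarse_grid):
        vals = np.zeros(coarse_grid.n_points)
        vals[7] = 5.0
        m = bf.StatMap(values=vals, grid=coarse_grid, kind="t", df=10,
                       threshold=3.0, mask=np.abs(vals) >= 3.0)
        sites = select_ve_sites(between_map=m, within_maps=[m])
        assert sites[0].mni_coord == sites[1].mni_coord
        assert sites[0].selection_mode == "between_group_peak"
        assert sites[1].selection_mode == "within_group_mean_peak"

    def test_mean_of_maxima_matches_peak_table(self, coarse_grid, rng):
        """Oracle: arithmetic mean recomputed from the peak table."""
        vals = np.zeros(coarse_grid.n_points)
        idx = rng.choice(coarse_grid.n_points, 4, replace=False)
        vals[idx] = [5.0, 6.0, 7.0, 8.0]
        m = bf.StatMap(values=vals, grid=coarse_grid, kind="t", df=10,
                       threshold=3.0, mask=np.abs(vals) >= 3.0)
        site = select_ve_sites(within_maps=[m])[0]
        expected_mean = bf.find_peaks(m, k=5)
        expected_mean = expected_mean[expected_mean.polarity == "max"][
            ["x", "y", "z"]].mean().to_numpy()
        snapped = coarse_grid.points[np.argmin(np.linalg.norm(
            coarse_grid.points - expected_mean, axis=1))]
        np.testing.assert_array_equal(site.mni_coord, snapped)

    def test_no_maxima_is_an_error(self, coarse_grid):
        vals = np.zeros(coarse_grid.n_points)
        m = bf.StatMap(values=vals, grid=coarse_grid, kind="t", df=10,
                       threshold=3.0, mask=vals > 3.0)
        with pytest.raises(ConfigurationError):
            select_ve_sites(within_maps=[m])


class TestPlaceVE:
    def _cov(self, sensors, rng):
        c = np.eye(sensors.n_channels)
        return bf.CovarianceMatrix(c, 0.0, (30.0, 80.0), ((-500.0, 500.0),))

    def test_identity_affine_equals_direct(self, sensors, head, rng):
        site = VESite((36.0, -86.0, 2.0), "theory_driven", "R-LOC")
        cov = self._cov(sensors, rng)
        w = place_ve(site, np.eye(4), sensors, head, cov)
        L, _ = point_lead_field(np.array(site.mni_coord), sensors, head)
        direct = bf.compute_weights(L, cov).weights[0]
        np.testing.assert_allclose(w, direct, rtol=1e-12)

    def test_translated_subject_keeps_unit_gain(self, sensors, head, rng):
        site = VESite((36.0, -86.0, 2.0), "theory_driven", "R-LOC")
        aff = np.eye(4)
        aff[:3, 3] = [3.0, -2.0, 4.0]
        cov = self._cov(sensors, rng)
        w = place_ve(site, aff, sensors, head, cov)
        from gammabeam.forward import apply_affine
        pt = apply_affine(np.array(site.mni_coord), aff)
        L, _ = point_lead_field(pt, sensors, head)
        bw = bf.compute_weights(L, cov)
        v = np.array([np.cos(bw.orientation[0]), np.sin(bw.orientation[0])])
        assert abs(w @ (L[0] @ v) - 1.0) < 1e-9

    def test_outside_head_rejected(self, sensors, head, rng):
        site = VESite((36.0, -86.0, 2.0), "theory_driven", "R-LOC")
        aff = np.eye(4)
        aff[:3, 3] = [200.0, 0.0, 0.0]
        with pytest.raises(ConfigurationError, match="outside"):
            place_ve(site, aff, sensors, head, self._cov(sensors, rng))

    def test_cross_subject_ground_truth_recovery(self, sensors, head):
        """Two subjects with different affines but the same source in their
        own coordinates yield VE traces matching the planted time course."""
        rng = np.random.default_rng(3)
        for seed in (0, 1):
            aff = np.eye(4)
            aff[:3, 3] = rng.normal(0, 2.0, 3)
            ep, src = planted_epochs(sensors, head, noise=1e-16, seed=seed)
            # source planted at affine-mapped location
            spec = CohortSpec(n_per_group={"TD": 2, "ASD": 2}, n_epochs=12,
                              sensor_noise_sd=1e-16, sources=(src,))
            ep = simulate_epoch_set(spec.sources, 2.0, sensors, head, spec,
                                    seed, affine=aff)
            cov = bf.covariance(ep, (30.0, 80.0), (-900.0, 900.0), 0.05)
            site = VESite(src.location, "theory_driven", "src")
            w = place_ve(site, aff, sensors, head, cov)
            trace = reconstruct_trace(w, ep, site)
            ref = ep.data[0, np.argmax(np.abs(ep.data[0]).max(axis=1))]
            assert abs(np.corrcoef(trace.traces[0], ref)[0, 1]) >= 0.99


class TestReconstructTrace:
    def test_zero_data_zero_trace(self, sensors, head):
        n = 200
        t = np.arange(n) / FS * 1000.0 - 100.0
        from gammabeam.preprocess import EpochSet
        ep = EpochSet(data=np.zeros((3, sensors.n_channels, n)),
                      sampling_rate=FS, time_ms=t,
                      condition_labels=np.array(["c"] * 3))
        trace = reconstruct_trace(np.ones(sensors.n_channels), ep)
        assert np.abs(trace.traces).max() == 0.0

    def test_unit_gain_on_pure_leadfield_signal(self, sensors, head):
        """data = l_theta * s(t) exactly -> trace = s(t)."""
        L, _ = point_lead_field(np.array([30.0, -60.0, 20.0]), sensors, head)
        cov = bf.CovarianceMatrix(np.eye(sensors.n_channels), 0.0,
                                  (30.0, 80.0), ((-500.0, 500.0),))
        bw = bf.compute_weights(L, cov)
        v = np.array([np.cos(bw.orientation[0]), np.sin(bw.orientation[0])])
        l_theta = L[0] @ v
        n = 300
        s = np.sin(2 * np.pi * 40.0 * np.arange(n) / FS)
        from gammabeam.preprocess import EpochSet
        ep = EpochSet(
            data=(l_theta[None, :, None] * s[None, None, :]),
            sampling_rate=FS,
            time_ms=np.arange(n) / FS * 1000.0,
            condition_labels=np.array(["c"]),
        )
        trace = reconstruct_trace(bw.weights[0], ep)
        np.testing.assert_allclose(trace.traces[0], s, atol=1e-9)

    def test_matches_naive_loop(self, sensors, head, rng):
        """Oracle: explicit per-sample dot product."""
        from gammabeam.preprocess import EpochSet
        n = 64
        data = rng.standard_normal((2, sensors.n_channels, n))
        ep = EpochSet(data=data, sampling_rate=FS,
                      time_ms=np.arange(n) / FS * 1000.0,
                      condition_labels=np.array(["a", "b"]))
        w = rng.standard_normal(sensors.n_channels)
        trace = reconstruct_trace(w, ep)
        for e in range(2):
            for s in range(n):
                expected = sum(w[k] * data[e, k, s]
                               for k in range(sensors.n_channels))
                assert abs(trace.traces[e, s] - expected) < 1e-12 * max(
                    1.0, abs(expected))


class TestStockwell:
    def test_tone_concentrated_at_its_frequency(self):
        t = np.arange(1024) / FS
        x = np.sin(2 * np.pi * 40.0 * t)
        freqs, S = stockwell(x, FS, 10.0, 90.0, 2.0)
        profile = np.abs(S).mean(axis=1)
        assert abs(freqs[np.argmax(profile)] - 40.0) < 2.0

    def test_time_marginal_equals_dft(self, rng):
        """Oracle: DFT identity — the time mean of every voice equals the
        (1/N-normalized) DFT coefficient at that frequency."""
        for _ in range(20):
            x = rng.standard_normal(rng.integers(128, 1024))
            freqs, S = stockwell(x, FS, 5.0, 100.0, 7.0)
            X = np.fft.fft(x) / len(x)
            for i, f in enumerate(freqs):
                k = int(round(f * len(x) / FS))
                assert abs(S[i].mean() - X[k]) < 1e-10

    def test_impulse_time_localized(self):
        x = np.zeros(512)
        x[200] = 1.0
        freqs, S = stockwell(x, FS, 20.0, 80.0, 10.0)
        power = np.abs(S) ** 2
        for i, f in enumerate(freqs):
            assert abs(np.argmax(power[i]) - 200) < 512 / f * FS / 512 * 3
        # width shrinks with frequency
        widths = [(power[i] > power[i].max() / 2).sum()
                  for i in range(len(freqs))]
        assert widths[-1] < widths[0]

    def test_dc_row_is_mean(self, rng):
        x = rng.standard_normal(256) + 5.0
        freqs, S = stockwell(x, FS, 0.0, 40.0, 20.0)
        assert freqs[0] == 0.0
        np.testing.assert_allclose(S[0].real, x.mean(), atol=1e-12)

    def test_nyquist_violation_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            stockwell(rng.standard_normal(256), FS, 10.0, FS, 1.0)


class TestDecomposition:
    def test_identical_epochs_evoked_equals_single(self):
        t = np.arange(800) / FS
        x = np.sin(2 * np.pi * 50.0 * t) * np.exp(-((t - 0.5) ** 2) / 0.01)
        trace = make_trace(np.tile(x, (5, 1)))
        ev = evoked_tf(trace, (30.0, 80.0), freq_step=5.0)
        freqs, S = stockwell(x, FS, 30.0, 80.0, 5.0)
        expected = np.abs(S[:, ::4]) ** 2
        np.testing.assert_allclose(ev.values, expected, rtol=1e-6,
                                   atol=1e-10 * expected.max())

    def test_single_epoch_induced_equals_evoked(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(600)
        tr2 = make_trace(np.stack([x, x]))
        ev = evoked_tf(tr2, (30.0, 80.0), freq_step=5.0)
        ind = induced_tf(tr2, (30.0, 80.0), freq_step=5.0)
        np.testing.assert_allclose(ind.values, ev.values, rtol=1e-10)

    def test_random_phase_dissociation(self, rng):
        """Oracle: phase averaging — with uniform phases the trace average
        carries ~1/n of single-epoch power; per-epoch power is unchanged."""
        n, n_epochs = 1356, 200
        t = np.arange(n) / FS
        phases = rng.uniform(-np.pi, np.pi, n_epochs)
        traces = np.cos(2 * np.pi * 60.0 * t[None, :] + phases[:, None])
        trace = make_trace(traces)
        ev = evoked_tf(trace, (40.0, 80.0), freq_step=4.0)
        ind = induced_tf(trace, (40.0, 80.0), freq_step=4.0)
        row = np.argmin(np.abs(ev.freqs_hz - 60.0))
        mid = slice(ev.values.shape[1] // 4, 3 * ev.values.shape[1] // 4)
        assert ev.values[row, mid].mean() <= 0.05 * ind.values[row, mid].mean()

    def test_evoked_bounded_by_induced(self, rng):
        traces = rng.standard_normal((8, 512))
        trace = make_trace(traces)
        ev = evoked_tf(trace, (10.0, 90.0), freq_step=10.0)
        ind = induced_tf(trace, (10.0, 90.0), freq_step=10.0)
        assert np.all(ev.values <= ind.values * (1 + 1e-10))

    def test_phase_jitter_dial_monotone(self, sensors, head):
        """Evoked/induced ratio at the source frequency decreases as the
        per-epoch phase jitter grows from locked to uniform."""
        ratios = []
        for jitter in (0.0, np.pi / 8, np.pi / 4, np.pi / 2, np.pi):
            ep, src = planted_epochs(sensors, head, phase_jitter=jitter,
                                     n_epochs=30, noise=1e-15, seed=11)
            cov = bf.covariance(ep, (30.0, 80.0), (-900.0, 900.0), 0.05)
            site = VESite(src.location, "theory_driven", "src")
            w = place_ve(site, np.eye(4), sensors, head, cov)
            trace = reconstruct_trace(w, ep, site)
            ev = evoked_tf(trace, (50.0, 70.0), freq_step=5.0)
            ind = induced_tf(trace, (50.0, 70.0), freq_step=5.0)
            row = np.argmin(np.abs(ev.freqs_hz - 60.0))
            sel = (ev.times_ms >= 200) & (ev.times_ms < 600)
            ratios.append(ev.values[row, sel].mean()
                          / ind.values[row, sel].mean())
        assert all(np.diff(ratios) < 0)
        assert ratios[0] > 0.9 and ratios[-1] < 0.05


def test_ve_amplitude_recovered_within_ten_percent(sensors, head):
    """Unit gain in practice: the VE trace RMS in the burst window matches
    the planted source RMS at default SNR."""
    ep, src = planted_epochs(sensors, head, n_epochs=36, noise=1e-14,
                             seed=21, amplitude=2e-8)
    cov = bf.covariance(ep, (30.0, 80.0), ((-300.0, -100.0), (50.0, 650.0)),
                        0.05)
    site = VESite(src.location, "theory_driven", "src")
    w = place_ve(site, np.eye(4), sensors, head, cov)
    trace = reconstruct_trace(w, ep, site)
    sl = trace.sample_slice((250.0, 450.0))
    measured_rms = trace.traces[:, sl].std()
    # planted: amplitude * gain 2.0 sinusoid -> rms = amp * gain / sqrt(2)
    expected_rms = 2e-8 * 2.0 / np.sqrt(2.0)
    assert abs(measured_rms / expected_rms - 1.0) < 0.10


class TestFirstLevel:
    def test_stationary_noise_centered_t(self, rng):
        traces = rng.standard_normal((40, 1356))
        tmap = tf_first_level(make_trace(traces), (30.0, 80.0), freq_step=10.0)
        assert abs(np.mean(tmap.values)) < 0.5

    def test_planted_burst_cluster(self, rng):
        n = 1356
        t = -1000.0 + np.arange(n) / FS * 1000.0
        env = ((t >= 250) & (t < 450)).astype(float)
        traces = 0.1 * rng.standard_normal((30, n))
        phases = rng.uniform(-np.pi, np.pi, 30)
        traces += 2.0 * env[None, :] * np.cos(
            2 * np.pi * 60.0 * (t / 1000.0)[None, :] + phases[:, None])
        tmap = tf_first_level(make_trace(traces), (30.0, 80.0), freq_step=5.0)
        peak = np.unravel_index(np.argmax(tmap.values), tmap.values.shape)
        assert 50.0 <= tmap.freqs_hz[peak[0]] <= 70.0
        assert 200.0 <= tmap.times_ms[peak[1]] <= 500.0

    def test_bin_matches_scalar_recomputation(self, rng):
        """Oracle: scalar paired t from the stored per-epoch values."""
        traces = rng.standard_normal((12, 700))
        trace = make_trace(traces)
        tmap = tf_first_level(trace, (30.0, 80.0), freq_step=10.0,
                              time_decim=4)
        from gammabeam.virtual_electrode import _tf_power_stack
        stack, freqs, times = _tf_power_stack(trace, 30.0, 80.0, 10.0, 4)
        keep = (times >= -300.0) & (times < -100.0)
        f_i, t_i = 2, 50
        base = stack[:, f_i, keep].mean(axis=1)
        d = stack[:, f_i, t_i] - base
        expected = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert abs(tmap.values[f_i, t_i] - expected) < 1e-10


class TestGroupTF:
    def _tf(self, values):
        f = np.arange(values.shape[0], dtype=float) + 30.0
        t = np.linspace(-900, 900, values.shape[1])
        return TFMap(values=values, freqs_hz=f, times_ms=t,
                     kind="first_level_t")

    def test_all_zero_maps_empty_mask(self):
        maps = [self._tf(np.zeros((4, 10))) for _ in range(6)]
        out, _ = tf_group_permutation(maps, n_permutations=128, alpha=0.05)
        assert not out.mask.any()

    def test_exhaustive_threshold_small_n(self, rng):
        maps = [self._tf(rng.standard_normal((3, 8))) for _ in range(8)]
        out, perm = tf_group_permutation(maps, n_permutations=256, alpha=0.05,
                                         seed=0)
        assert perm.exhaustive
        from gammabeam.stats import one_sample_t_map
        import itertools
        stack = np.stack([m.values.ravel() for m in maps])
        maxima = [np.abs(one_sample_t_map(
            stack * np.array(sg)[:, None])).max()
            for sg in itertools.product([-1.0, 1.0], repeat=8)]
        assert abs(perm.threshold - np.quantile(maxima, 0.95)) < 1e-10

    def test_incongruent_grids_rejected(self, rng):
        maps = [self._tf(rng.standard_normal((3, 8))),
                self._tf(rng.standard_normal((3, 9)))]
        with pytest.raises(ConfigurationError):
            tf_group_permutation(maps)


def test_default_sites_are_the_canonical_three():
    coords = [c for c, _ in DEFAULT_VE_SITES]
    assert coords == [(36.0, -86.0, 2.0), (-20.0, -92.0, 16.0),
                      (32.0, -57.0, -3.0)]
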