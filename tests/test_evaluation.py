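"""Blocked statistics, quantization study, probing, power and protocols."""

import numpy as np
import pytest

from spikeskin.evaluation import (
    PowerModelParams,
    activity_metrics,
    blocked_bootstrap_median,
    effect_size_r,
    fit_quantization_curve,
    kfold_split,
    n_effective,
    power_model,
    probe_connectivity,
    quantize_weights,
    radial_profile,
    select_block_size,
    wilcoxon_blocked,
)
from spikeskin.geometry import OutputGrid
from spikeskin.neurons import (
    BackgroundInputParams,
    ConnectionBlock,
    NetworkSpec,
    NeuronParams,
    SpikeEvents,
    build_architecture,
)


def _positions(geometry, n, seed=0):
    return geometry.sample_positions(n, np.random.default_rng(seed))


class TestBlockedBootstrap:
    def test_constant_errors_zero_std(self, geometry):
        pos = _positions(geometry, 200)
        med, std = blocked_bootstrap_median(np.full(200, 4.2), pos, geometry, 30.0)
        assert med == pytest.approx(4.2)
        assert std == pytest.approx(0.0, abs=1e-9)

    def test_single_block_degenerate(self, geometry):
        pos = _positions(geometry, 50)
        with pytest.raises(ValueError):
            blocked_bootstrap_median(np.ones(50), pos, geometry, 1e6)

    def test_too_few_resamples_rejected(self, geometry):
        pos = _positions(geometry, 50)
        with pytest.raises(ValueError):
            blocked_bootstrap_median(np.ones(50), pos, geometry, 30.0, n_boot=10)

    def test_iid_errors_match_naive_bootstrap_within_20pct(self, geometry):
        rng = np.random.default_rng(0)
        n = 600
        pos = _positions(geometry, n)
        errs = rng.gamma(2.0, 2.0, n)  # spatially independent
        _, blocked = blocked_bootstrap_median(errs, pos, geometry, 12.0, n_boot=1500, seed=1)
        # naive oracle: resample trials directly
        meds = np.array([
            np.median(errs[rng.integers(0, n, n)]) for _ in range(1500)
        ])
        naive = meds.std(ddof=1)
        assert blocked == pytest.approx(naive, rel=0.20)


class TestSelectBlockSize:
    def test_single_candidate_returned(self, geometry):
        pos = _positions(geometry, 100)
        assert select_block_size(np.ones(100), pos, geometry, [20.0]) == 20.0

    def test_white_field_picks_smallest(self, geometry):
        rng = np.random.default_rng(2)
        n = 500
        pos = _positions(geometry, n)
        errs = rng.normal(5.0, 1.0, n)
        chosen = select_block_size(
            errs, pos, geometry, [12.0, 25.0, 50.0], tolerance=0.08, n_boot=800, seed=3
        )
        assert chosen == 12.0

    def test_correlated_field_picks_at_least_correlation_length(self, geometry):
        rng = np.random.default_rng(3)
        n = 800
        pos = _positions(geometry, n, seed=5)
        uv = geometry.unroll(pos[:, 0], pos[:, 1])
        # smooth field with ~30 mm correlation length
        centers = geometry.unroll(*_positions(geometry, 40, seed=6).T)
        amp = rng.normal(0, 1, 40)
        field = sum(
            a * np.exp(-np.linalg.norm(uv - c, axis=1) ** 2 / (2 * 30.0**2))
            for a, c in zip(amp, centers)
        )
        errs = 5.0 + field + rng.normal(0, 0.05, n)
        chosen = select_block_size(errs, pos, geometry, [5.0, 10.0, 30.0, 60.0], seed=7)
        assert chosen >= 30.0


class TestWilcoxon:
    def test_identical_samples_null(self, geometry):
        pos = _positions(geometry, 100)
        from spikeskin.evaluation import assign_blocks
        blocks = assign_blocks(pos, geometry, 30.0)
        errs = np.random.default_rng(0).gamma(2, 2, 100)
        stat, p, r = wilcoxon_blocked(errs, errs, blocks)
        assert p == pytest.approx(0.5)
        assert r == pytest.approx(0.0)

    def test_uniform_dominance_significant(self, geometry):
        pos = _positions(geometry, 200)
        from spikeskin.evaluation import assign_blocks
        blocks = assign_blocks(pos, geometry, 25.0)
        rng = np.random.default_rng(1)
        b = rng.gamma(2, 2, 200) + 1.0
        a = b - 0.8  # uniformly smaller
        stat, p, r = wilcoxon_blocked(a, b, blocks)
        assert p < 0.01
        assert r > 0.8

    def test_effect_size_formula(self):
        assert effect_size_r(2.0, 100) == pytest.approx(0.2)


class TestQuantization:
    def test_idempotent(self):
        spec = build_architecture("SF_DIR", (6, 8), seed=0, w_init=3.0)
        q1 = quantize_weights(spec, 3)
        q2 = quantize_weights(q1, 3)
        assert np.allclose(q1.blocks[0].weights, q2.blocks[0].weights)

    def test_max_deviation_bounded_by_half_step(self):
        spec = build_architecture("SF_DIR", (6, 8), seed=1, w_init=5.0)
        n = 6
        q = quantize_weights(spec, n)
        wmax = np.abs(spec.blocks[0].weights).max()
        step = wmax / (2 ** (n - 1) - 1)
        assert np.abs(q.blocks[0].weights - spec.blocks[0].weights).max() <= step / 2 + 1e-12

    def test_one_bit_levels(self):
        spec = build_architecture("SF_DIR", (4, 4), seed=2, w_init=2.0)
        q = quantize_weights(spec, 1)
        wmax = np.abs(spec.blocks[0].weights).max()
        assert set(np.round(np.unique(np.abs(q.blocks[0].weights)), 9)) <= {round(wmax, 9)}

    def test_masks_preserved(self):
        spec = build_architecture("SC_BIO", (6, 4, 8), seed=3, w_init=2.0)
        q = quantize_weights(spec, 2)
        assert q.check_masks()

    def test_invalid_bits_rejected(self):
        spec = build_architecture("SF_DIR", (3, 3), seed=0)
        with pytest.raises(ValueError):
            quantize_weights(spec, 0)


class TestQuantizationCurve:
    def test_n_effective_limits(self):
        assert n_effective(100, 0.0) == 100
        assert n_effective(100, 1e-9) == pytest.approx(100, rel=1e-6)
        assert n_effective(100, 1.0) == pytest.approx(46.21, rel=1e-3)

    def test_exact_exponential_recovered(self):
        bits = np.arange(1, 11, dtype=float)
        a, tau, c = 5.0, 1.8, 3.0
        y = a * np.exp(-bits / tau) + c
        af, tf, cf, chi2, p = fit_quantization_curve(bits, y, np.full_like(y, 0.1))
        assert af == pytest.approx(a, rel=1e-4)
        assert tf == pytest.approx(tau, rel=1e-4)
        assert cf == pytest.approx(c, rel=1e-4)
        assert chi2 == pytest.approx(0.0, abs=1e-6)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_autocorrelation_correction_reduces_chi2(self):
        bits = np.arange(1, 11, dtype=float)
        rng = np.random.default_rng(0)
        y = 5.0 * np.exp(-bits / 1.5) + 3.0 + rng.normal(0, 0.3, 10)
        *_, chi_raw, _ = fit_quantization_curve(bits, y, np.full(10, 0.1), tau_acf=0.0)
        *_, chi_adj, _ = fit_quantization_curve(bits, y, np.full(10, 0.1), tau_acf=2.0)
        assert chi_adj < chi_raw


def _identity_probe_spec():
    """Two inputs wired one-to-one onto two outputs with strong weights."""
    return NetworkSpec(
        "SF_DIR",
        ["input", "output"],
        {"input": 2, "output": 2},
        [ConnectionBlock("input", "output", "free", np.array([[150.0, 0.0], [0.0, 150.0]]))],
        {"input": np.zeros(2), "output": np.zeros(2)},
        NeuronParams(),
        BackgroundInputParams(0.0, 0.0),
    )


class TestProbeConnectivity:
    def test_identity_wiring_activates_paired_output(self):
        maps = probe_connectivity(_identity_probe_spec(), probe_rate=60.0,
                                  duration=1500.0, seed=0, baseline_subtract=False)
        assert maps[0, 0] > 10.0 and maps[1, 1] > 10.0
        assert maps[0, 1] == 0.0 and maps[1, 0] == 0.0

    def test_zero_weights_flat_zero_map(self):
        spec = _identity_probe_spec()
        spec.blocks[0].weights[:] = 0.0
        maps = probe_connectivity(spec, probe_rate=60.0, duration=800.0, seed=0,
                                  baseline_subtract=False)
        assert np.all(maps == 0.0)

    def test_mexican_hat_weights_show_center_surround_profile(self, geometry):
        grid = OutputGrid(geometry, 10, 8)
        sens = geometry.sensor_positions()
        out = grid.positions()
        from spikeskin.geometry import cone_distance
        d = cone_distance(out[:, None, :], sens[None, :, :], geometry)
        W = np.zeros((grid.n_neurons, 42))
        W[:, :21] = 60.0 * np.exp(-d**2 / (2 * 8.0**2)) - 25.0 * np.exp(-d**2 / (2 * 20.0**2))
        spec = NetworkSpec(
            "SF_DIR", ["input", "output"], {"input": 42, "output": grid.n_neurons},
            [ConnectionBlock("input", "output", "free", W)],
            {"input": np.zeros(42), "output": np.full(grid.n_neurons, 45.0)},
            NeuronParams(), BackgroundInputParams(0.0, 0.0),
        )
        maps = probe_connectivity(spec, probe_rate=60.0, duration=1500.0, seed=0,
                                  input_ids=np.arange(21))
        centers, med, q25, q75 = radial_profile(maps, sens, grid, n_bins=16)
        near = np.nanmean(med[:3])
        mid = np.nanmin(med[3:9])
        assert near > 0.5          # central excitation
        assert mid < -0.1          # surround suppression


class TestActivityAndPower:
    def test_activity_metrics(self):
        ev = SpikeEvents(np.array([]), np.array([]), 4, 1000.0)
        assert activity_metrics(ev) == 0.0
        ev = SpikeEvents(np.arange(1, 11, dtype=float) * 10, np.array([0] * 5 + [1] * 5), 4, 1000.0)
        assert activity_metrics(ev) == pytest.approx(10.0)  # 10 spikes over 1 s
        assert activity_metrics(ev, 0.0, 500.0) == pytest.approx(20.0)
        assert activity_metrics(ev, 500.0, 1000.0) == 0.0

    def test_power_model_arithmetic(self):
        p = PowerModelParams(E_spike=1.0, E_enc=1.0, E_br=1.0, E_rt=1.0, E_pulse=1.0, N_cores=1)
        assert power_model(np.zeros(3), np.zeros(3), p) == 0.0
        assert power_model(np.array([100.0]), np.array([2.0]), p) == pytest.approx(600.0)

    def test_power_model_linearity_and_permutation_invariance(self):
        p = PowerModelParams()
        rng = np.random.default_rng(0)
        r = rng.uniform(0, 50, 8)
        npost = rng.integers(1, 20, 8)
        total = power_model(r, npost, p)
        assert power_model(2 * r, npost, p) == pytest.approx(2 * total)
        perm = rng.permutation(8)
        assert power_model(r[perm], npost[perm], p) == pytest.approx(total)

    def test_negative_energy_rejected(self):
        with pytest.raises(ValueError):
            PowerModelParams(E_spike=-1.0)


class TestKFold:
    def test_k1_rejected(self):
        with pytest.raises(ValueError):
            kfold_split(10, k=1)

    def test_folds_partition_dataset(self):
        folds = kfold_split(53, k=5, seed=0)
        all_test = np.sort(np.concatenate([te for _, te in folds]))
        assert np.array_equal(all_test, np.arange(53))
        for tr, te in folds:
            assert len(np.intersect1d(tr, te)) == 0

    def test_same_seed_same_folds(self):
        a = kfold_split(40, 5, seed=3)
        b = kfold_split(40, 5, seed=3)
        for (tra, tea), (trb, teb) in zip(a, b):
            assert np.array_equal(tea, teb)
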