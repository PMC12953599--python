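"""Learning rule: targets, schedules, gradient fidelity, toy training."""

import numpy as np
import pytest
from dataclasses import replace

import spikeskin as sk
from spikeskin.neurons import build_architecture, rheobase
from spikeskin.training import (
    TrainerParams,
    activity_modulated_decay,
    apply_energy_level,
    backprop_error,
    bias_update,
    interneuron_count,
    leaky_heaviside,
    lr_schedule,
    rate_forward,
    target_activity,
    train,
    weight_update,
    window_counts,
)


class TestTargetActivity:
    def test_peak_and_width(self, grid):
        p = TrainerParams()
        pos = grid.positions()[40]
        y = target_activity(pos[None, :], grid, p.sigma, p.y_peak, p.W)
        peak_counts = p.y_peak * p.W / 1000.0
        assert y[40] == pytest.approx(peak_counts)
        assert y.max() == pytest.approx(peak_counts)
        # a neuron at distance ~sigma sits near peak*exp(-1/2)
        from spikeskin.geometry import cone_distance
        d = cone_distance(grid.positions(), pos[None, :], grid.geometry)
        j = int(np.argmin(np.abs(d - p.sigma)))
        expected = peak_counts * np.exp(-d[j] ** 2 / (2 * p.sigma**2))
        assert y[j] == pytest.approx(expected)

    def test_far_targets_vanish(self, grid):
        pos = grid.positions()[0]
        y = target_activity(pos[None, :], grid, 5.0, 50.0, 500.0)
        far = np.argmax(
            np.linalg.norm(grid.unrolled() - grid.geometry.unroll(*pos), axis=1)
        )
        assert y[far] < 1e-6

    def test_multi_contact_pointwise_max(self, grid):
        pos = grid.positions()
        a, b = pos[5], pos[90]
        ya = target_activity(a[None, :], grid, 10.0, 50.0, 500.0)
        yb = target_activity(b[None, :], grid, 10.0, 50.0, 500.0)
        yab = target_activity(np.stack([a, b]), grid, 10.0, 50.0, 500.0)
        assert np.allclose(yab, np.maximum(ya, yb))


class TestWindowCounts:
    def test_empty_train(self):
        c = window_counts(np.array([]), np.array([]), 3, np.array([500.0]), 500.0)
        assert np.all(c == 0)

    def test_five_spikes_inside_window(self):
        t = np.array([300.0, 350.0, 500.0, 700.0, 749.0])
        c = window_counts(t, np.zeros(5, int), 1, np.array([500.0]), 500.0)
        assert c[0, 0] == 5

    def test_left_boundary_closed_right_open(self):
        t = np.array([250.0, 750.0])  # exactly t - W/2 and t + W/2
        c = window_counts(t, np.zeros(2, int), 1, np.array([500.0]), 500.0)
        assert c[0, 0] == 1  # left edge counted, right edge excluded


class TestSchedules:
    def test_lr_schedule_limits_and_midpoint(self):
        p = TrainerParams(lambda_m=1e-3, lambda_M=1e-2, dE_m=10.0, dE_M=100.0)
        assert lr_schedule(-5.0, p) == pytest.approx(1e-3)     # small improvement
        assert lr_schedule(-200.0, p) == pytest.approx(1e-2)   # large improvement
        assert lr_schedule(-55.0, p) == pytest.approx((1e-3 + 1e-2) / 2)

    def test_lr_schedule_requires_ordered_knees(self):
        p = TrainerParams(dE_m=10.0, dE_M=10.0)
        with pytest.raises(ValueError):
            lr_schedule(0.0, p)

    def test_leaky_heaviside(self):
        assert leaky_heaviside(1.0, 0.2) == 1.0
        assert leaky_heaviside(-0.5, 0.2) == 0.2
        assert leaky_heaviside(-0.5, 0.0) == 0.0

    def test_activity_modulated_decay(self):
        p = TrainerParams(kappa_decay0=1e-3, M_decay=2.0, s_decay=5.0)
        assert activity_modulated_decay(0.0, p) == pytest.approx(1e-3 * 2.0)
        assert activity_modulated_decay(1e9, p) == pytest.approx(1e-3 * 3.0)
        ys = np.linspace(0, 50, 20)
        ks = [activity_modulated_decay(y, p) for y in ys]
        assert np.all(np.diff(ks) >= 0)

    def test_energy_level_tightens_caps(self):
        p = TrainerParams()
        q = apply_energy_level(p, 1.0)
        assert q.i_max == pytest.approx(p.i_max_min)
        assert q.kappa_decay0 > p.kappa_decay0
        with pytest.raises(ValueError):
            apply_energy_level(p, 1.5)

    def test_interneuron_schedule_linear_to_quarter(self):
        assert interneuron_count(40, 0.0) == 40
        assert interneuron_count(40, 1.0) == 10
        assert interneuron_count(40, 0.5) == 25


def _toy_sc_bio():
    """2 inputs, 1 interneuron, 2 outputs; currents well above rheobase."""
    spec = build_architecture("SC_BIO", (2, 1, 2), seed=0, w_init=0.0, i0_init=0.0,
                              background=sk.BackgroundInputParams(0.0, 0.0))
    for b in spec.blocks:
        if b.pre == "input" and b.post == "output":
            b.weights[:] = [[6.0, 2.0], [1.5, 5.0]]
        elif b.pre == "input" and b.post == "inter":
            b.weights[:] = [[3.0, 3.0]]
        elif b.pre == "inter" and b.post == "output":
            b.weights[:] = [[-2.0], [-1.5]]
    spec.i0["input"][:] = [70.0, 85.0]
    spec.i0["inter"][:] = 75.0
    spec.i0["output"][:] = 72.0
    return spec


class TestGradientFidelity:
    """Analytic updates vs finite differences of the windowed loss.

    The loss is the squared error of mean-field window counts; with the
    strict gate (h_leak = 0, all units active) and currents away from
    rheobase, the update rule is its exact gradient.
    """

    def setup_method(self):
        self.spec = _toy_sc_bio()
        self.params = replace(TrainerParams(), h_leak=0.0, m_smooth=0.0)
        self.ext = np.array([10.0, 5.0])
        y, _ = rate_forward(self.spec, self.ext, self.params, include_background=False)
        self.y_star = 0.8 * y["output"]

    def loss(self, spec):
        y, _ = rate_forward(spec, self.ext, self.params, include_background=False)
        return 0.5 * float(((y["output"] - self.y_star) ** 2).sum())

    def analytic_updates(self):
        spec = self.spec
        y, I = rate_forward(spec, self.ext, self.params, include_background=False)
        acts = {k: v[None, :] for k, v in y.items()}
        curs = {k: v[None, :] for k, v in I.items()}
        errs = backprop_error(acts, self.y_star[None, :], spec, curs, self.params)
        grads_w = []
        for b in spec.blocks:
            dw = weight_update(b.weights, spec, acts[b.pre], acts[b.post],
                               errs[b.post], curs[b.post], self.params)
            grads_w.append(-dw)  # update is -gradient
        grads_i = {
            name: -bias_update(acts[name], errs[name], curs[name], spec, self.params)
            for name in spec.layer_names
        }
        return grads_w, grads_i

    def test_output_errors_zero_when_target_met(self):
        y, I = rate_forward(self.spec, self.ext, self.params, include_background=False)
        acts = {k: v[None, :] for k, v in y.items()}
        curs = {k: v[None, :] for k, v in I.items()}
        errs = backprop_error(acts, y["output"][None, :], self.spec, curs, self.params)
        for e in errs.values():
            assert np.allclose(e, 0.0)

    def test_hidden_error_matches_hand_chain_rule(self):
        spec = self.spec
        y, I = rate_forward(spec, self.ext, self.params, include_background=False)
        acts = {k: v[None, :] for k, v in y.items()}
        curs = {k: v[None, :] for k, v in I.items()}
        errs = backprop_error(acts, self.y_star[None, :], spec, curs, self.params)
        from spikeskin.training import fi_slope
        p = spec.neuron_params
        w_io = next(b for b in spec.blocks if b.pre == "inter" and b.post == "output")
        m_out = fi_slope(I["output"], spec, 0.0)
        e_out = y["output"] - self.y_star
        # inhibitory weights decay with tau_in
        expected = (w_io.weights * p.tau_in * m_out[:, None] * e_out[:, None]).sum(axis=0)
        assert np.allclose(errs["inter"][0], expected)

    def test_weight_gradients_match_finite_differences(self):
        grads_w, _ = self.analytic_updates()
        h = 1e-5
        for bi, b in enumerate(self.spec.blocks):
            for j in range(b.weights.shape[0]):
                for i in range(b.weights.shape[1]):
                    sp = self.spec.copy()
                    sp.blocks[bi].weights[j, i] += h
                    up = self.loss(sp)
                    sp.blocks[bi].weights[j, i] -= 2 * h
                    dn = self.loss(sp)
                    fd = (up - dn) / (2 * h)
                    assert grads_w[bi][j, i] == pytest.approx(fd, rel=2e-3, abs=1e-8)

    def test_bias_gradients_match_finite_differences(self):
        _, grads_i = self.analytic_updates()
        h = 1e-5
        for name in self.spec.layer_names:
            for j in range(self.spec.layer_sizes[name]):
                sp = self.spec.copy()
                sp.i0[name][j] += h
                up = self.loss(sp)
                sp.i0[name][j] -= 2 * h
                dn = self.loss(sp)
                fd = (up - dn) / (2 * h)
                assert grads_i[name][j] == pytest.approx(fd, rel=2e-3, abs=1e-8)


class TestUpdateMechanics:
    def test_zero_error_update_is_pure_decay(self):
        spec = _toy_sc_bio()
        p = TrainerParams()
        y = {n: np.ones((1, spec.layer_sizes[n])) for n in spec.layer_names}
        I = {n: np.full((1, spec.layer_sizes[n]), 70.0) for n in spec.layer_names}
        e = {n: np.zeros((1, spec.layer_sizes[n])) for n in spec.layer_names}
        for b in spec.blocks:
            dw = weight_update(b.weights, spec, y[b.pre], y[b.post], e[b.post], I[b.post], p)
            assert np.allclose(dw, 0.0)  # Eq-16 decay applied separately at batch end

    def test_sign_projection_clips_at_zero(self):
        spec = build_architecture("SC_BIO", (3, 2, 3), seed=1, w_init=1.0)
        b = next(bl for bl in spec.blocks if bl.sign == "exc")
        b.weights -= 10.0
        b.project_sign()
        assert np.all(b.weights >= 0.0)


@pytest.fixture(scope="module")
def toy_dataset():
    proto = sk.IndentationProtocol(n_trials=50, seed=5, position_grid=3)
    return sk.generate_dataset(proto)


class TestTrain:
    def test_epoch_error_decreases_on_toy_task(self, toy_dataset, grid):
        spec = build_architecture("SF_DIR", (42, grid.n_neurons), seed=1)
        p = replace(TrainerParams(), epochs=4)
        trained, hist = train(toy_dataset, spec, grid, p, seed=0)
        assert hist["error"].iloc[-1] < hist["error"].iloc[0]

    def test_near_zero_learning_rate_leaves_only_shrinkage(self, toy_dataset, grid):
        spec = build_architecture("SF_DIR", (42, grid.n_neurons), seed=1)
        w0 = spec.blocks[0].weights.copy()
        p = replace(TrainerParams(), epochs=1, lambda_m=1e-15, lambda_M=1e-15,
                    kappa_decay0=0.0)
        trained, _ = train(toy_dataset[:10], spec, grid, p, seed=0)
        assert np.allclose(trained.blocks[0].weights, w0, atol=1e-8)

    def test_sc_bio_sign_masks_hold_after_training(self, toy_dataset, grid):
        spec = build_architecture("SC_BIO", (42, 10, grid.n_neurons), seed=1)
        p = replace(TrainerParams(), epochs=2)
        trained, _ = train(toy_dataset[:20], spec, grid, p, seed=0)
        for b in trained.blocks:
            if b.sign == "exc":
                assert np.all(b.weights >= 0.0)
            elif b.sign == "inh":
                assert np.all(b.weights <= 0.0)

    def test_empty_dataset_rejected(self, grid):
        spec = build_architecture("SF_DIR", (42, grid.n_neurons), seed=0)
        with pytest.raises(ValueError):
            train([], spec, grid)
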