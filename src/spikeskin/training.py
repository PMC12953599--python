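"""Windowed-activity gradient learning with energy regularization.

The rule trains weights and per-neuron baseline currents so that each
output neuron's windowed spike count tracks a Gaussian somatotopic target
centred on the true contact position.  Instead of backpropagation through
time, activities are summarized as spike counts in a sliding window W
evaluated on a coarse stride t_s; updates factorize as

    dw_ji = -lambda * m(I_j) * H(y_j) * tau_ji * y_i * E~_j
    dI_j  = -lambda * m(I_j) * H(y_j) * W * E~_j

where ``m`` is the slope of the closed-form LIF FI curve at the neuron's
mean input current (expressed per ms, i.e. kHz/pA, which makes the rule
the exact gradient of the window-count mean-field loss), ``H`` a leaky
gate on postsynaptic activity, ``tau_ji`` the synaptic time constant of
the connection and ``E~`` the generalized error, chained through layers as
``E~_i = sum_j w_ji m_j H_j tau_ji E~_j``.  Updates are batched over
indentations, followed by activity-modulated L2 decay, sign-mask
projection and a baseline-current cap; the learning rate follows a
piecewise-linear schedule on the epoch-error improvement.  Energy
constraints jointly tighten the current cap, boost the decay modulation
and shrink the interneuron pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .encoding import EncoderParams, encode
from .geometry import OutputGrid, cone_distance
from .neurons import NetworkSpec, lif_rate, lif_rate_derivative, simulate
from .skin import IndentationRecord

__all__ = [
    "TrainerParams",
    "TrainingDivergence",
    "target_activity",
    "window_counts",
    "fi_slope",
    "leaky_heaviside",
    "backprop_error",
    "weight_update",
    "bias_update",
    "lr_schedule",
    "activity_modulated_decay",
    "apply_energy_level",
    "rate_forward",
    "train",
]


class TrainingDivergence(RuntimeError):
    """Raised when the epoch error exceeds 10x its initial value."""


@dataclass(frozen=True)
class TrainerParams:
    sigma: float = 10.0          # target-kernel width (mm)
    y_peak: float = 50.0         # target peak rate (Hz)
    W: float = 500.0             # activity window (ms)
    t_s: float = 100.0           # evaluation stride (ms)
    batch: int = 10              # indentations per update
    lambda_m: float = 2e-3       # learning-rate floor
    lambda_M: float = 2e-2       # learning-rate ceiling
    dE_m: float = 0.0            # schedule knee (error improvement units)
    dE_M: float = 1.0
    kappa_decay0: float = 2e-4   # base L2 decay per batch
    M_decay: float = 1.0         # activity modulation amplitude of the decay
    s_decay: float = 10.0        # activity scale of the modulation (window counts)
    h_leak: float = 0.3          # leaky-gate value for silent neurons
    i_max: float = 25.0          # baseline-current cap (pA), all layers
    m_smooth: float = 2.0        # FI-slope smoothing width at rheobase (pA)
    epochs: int = 15
    # energy-constraint endpoints (level in [0, 1] interpolates linearly)
    i_max_min: float = 5.0       # cap at full constraint (pA)
    kappa_energy_gain: float = 4.0
    inter_min_frac: float = 0.25

    def __post_init__(self):
        if not (0.0 < self.lambda_m <= self.lambda_M):
            raise ValueError("need 0 < lambda_m <= lambda_M")
        if not (self.W > self.t_s > 0.0):
            raise ValueError("need W > t_s > 0")
        if not (0.0 <= self.h_leak < 1.0):
            raise ValueError("h_leak must be in [0, 1)")


def apply_energy_level(params: TrainerParams, level: float) -> TrainerParams:
    """Tighten the energy regularizers for a constraint level in [0, 1]."""
    if not (0.0 <= level <= 1.0):
        raise ValueError("energy level must be in [0, 1]")
    return replace(
        params,
        i_max=params.i_max + level * (params.i_max_min - params.i_max),
        kappa_decay0=params.kappa_decay0 * (1.0 + params.kappa_energy_gain * level),
    )


def interneuron_count(base: int, level: float, min_frac: float = 0.25) -> int:
    """Linear interneuron-count schedule: base -> min_frac*base at level 1."""
    return max(int(round(base * (1.0 - (1.0 - min_frac) * level))), 1)


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def target_activity(
    true_positions: np.ndarray,
    grid: OutputGrid,
    sigma: float,
    y_peak: float,
    W: float,
) -> np.ndarray:
    """Somatotopic Gaussian target in window counts.

    ``y*_i = y_peak*(W/1000) * exp(-d(i, truth)^2 / (2 sigma^2))`` with the
    geodesic distance on the cone; multi-contact targets take the
    pointwise maximum over contacts.
    """
    pos = grid.positions()
    tp = np.atleast_2d(true_positions)
    d = cone_distance(pos[:, None, :], tp[None, :, :], grid.geometry)
    k = np.exp(-(d**2) / (2.0 * sigma**2)).max(axis=1)
    return y_peak * (W / 1000.0) * k


def window_counts(
    times: np.ndarray,
    ids: np.ndarray,
    n_neurons: int,
    centers: np.ndarray,
    W: float,
    dt: float = 1.0,
    n_steps: int | None = None,
) -> np.ndarray:
    """Spike counts per neuron in [t - W/2, t + W/2) for each centre.

    Closed-left convention: a spike exactly at ``t - W/2`` is counted.
    Returns (n_centers, n_neurons).
    """
    if W <= 0:
        raise ValueError("W must be > 0")
    if n_steps is None:
        n_steps = int(np.ceil((centers.max() + W / 2.0) / dt)) + 1
    per_step = np.zeros((n_steps + 1, n_neurons))
    if len(times):
        s = np.clip(np.round(times / dt).astype(int), 0, n_steps)
        np.add.at(per_step, (s, ids), 1.0)
    cum = np.cumsum(per_step, axis=0)  # cum[k] = spikes with time <= k*dt
    lo = np.clip(np.ceil((centers - W / 2.0) / dt).astype(int) - 1, -1, n_steps)
    hi = np.clip(np.ceil((centers + W / 2.0) / dt).astype(int) - 1, -1, n_steps)
    cpad = np.vstack([np.zeros(n_neurons), cum])
    return cpad[hi + 1] - cpad[lo + 1]


def fi_slope(I, spec: NetworkSpec, smooth: float = 2.0) -> np.ndarray:
    """m(x): slope of the LIF FI curve in kHz/pA (per-ms rate slope)."""
    return lif_rate_derivative(I, spec.neuron_params, smooth=smooth) / 1000.0


def leaky_heaviside(x, h_leak: float) -> np.ndarray:
    """Gate: 1 where x > 0, else ``h_leak``."""
    return np.where(np.asarray(x) > 0, 1.0, h_leak)


def _block_tau(weights: np.ndarray, spec: NetworkSpec) -> np.ndarray:
    """tau_ji per connection: tau_ex where w > 0 else tau_in."""
    p = spec.neuron_params
    return np.where(weights > 0, p.tau_ex, p.tau_in)


def backprop_error(
    activities: dict[str, np.ndarray],
    targets: np.ndarray,
    spec: NetworkSpec,
    mean_currents: dict[str, np.ndarray],
    params: TrainerParams,
) -> dict[str, np.ndarray]:
    """Generalized instantaneous errors per layer, (n_pts, n) each.

    Output layer: ``E~ = y - y*``.  Hidden/input layers chain the error
    through every feedforward block leaving them:
    ``E~_i = sum_j w_ji m(I_j) H(y_j) tau_ji E~_j``.
    """
    out_name = spec.layer_names[-1]
    errors = {out_name: activities[out_name] - targets}
    # walk layers from output towards input, summing over outgoing blocks
    for name in reversed(spec.layer_names[:-1]):
        acc = np.zeros_like(activities[name])
        for b in spec.blocks:
            if b.pre != name or b.post not in errors:
                continue
            m = fi_slope(mean_currents[b.post], spec, params.m_smooth)
            H = leaky_heaviside(activities[b.post], params.h_leak)
            tau = _block_tau(b.weights, spec)
            acc += (errors[b.post] * m * H) @ (b.weights * tau)
        errors[name] = acc
    return errors


def weight_update(
    block_weights: np.ndarray,
    spec: NetworkSpec,
    y_pre: np.ndarray,
    y_post: np.ndarray,
    e_post: np.ndarray,
    i_post: np.ndarray,
    params: TrainerParams,
) -> np.ndarray:
    """Accumulated -grad contribution for one block over the t_s grid.

    Arrays are (n_pts, n) per layer; returns (n_post, n_pre).
    """
    m = fi_slope(i_post, spec, params.m_smooth)
    H = leaky_heaviside(y_post, params.h_leak)
    tau = _block_tau(block_weights, spec)
    return -((m * H * e_post).T @ y_pre) * tau


def bias_update(
    y_post: np.ndarray,
    e_post: np.ndarray,
    i_post: np.ndarray,
    spec: NetworkSpec,
    params: TrainerParams,
) -> np.ndarray:
    """Accumulated -grad contribution for one layer's baseline currents."""
    m = fi_slope(i_post, spec, params.m_smooth)
    H = leaky_heaviside(y_post, params.h_leak)
    return -(m * H * e_post).sum(axis=0) * params.W


def lr_schedule(delta_E_epoch: float, params: TrainerParams) -> float:
    """Piecewise-linear learning rate on the epoch-error improvement.

    The improvement is ``-delta_E``: below ``dE_m`` the rate floors at
    ``lambda_m``, above ``dE_M`` it saturates at ``lambda_M``, linear in
    between.
    """
    if params.dE_m >= params.dE_M:
        raise ValueError("need dE_m < dE_M")
    imp = -delta_E_epoch
    if imp < params.dE_m:
        return params.lambda_m
    if imp > params.dE_M:
        return params.lambda_M
    frac = (imp - params.dE_m) / (params.dE_M - params.dE_m)
    return params.lambda_m + frac * (params.lambda_M - params.lambda_m)


def activity_modulated_decay(y_layer_mean: float, params: TrainerParams) -> float:
    """kappa_decay0 * (1 + M / (1 + exp(-y/s))): stronger decay when busy."""
    return params.kappa_decay0 * (
        1.0 + params.M_decay / (1.0 + np.exp(-y_layer_mean / params.s_decay))
    )


# ---------------------------------------------------------------------------
# Mean-field forward pass (rate model)
# ---------------------------------------------------------------------------

def rate_forward(
    spec: NetworkSpec,
    ext_currents: np.ndarray,
    params: TrainerParams,
    include_background: bool = True,
    n_iter: int = 1,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Deterministic window-count prediction of the network activities.

    Layer-by-layer mean-field pass: each neuron's mean input current is
    ``I0 + sum_i w_ji tau_ji y_i / W + I_ext (+ background mean)`` and its
    window count ``y_j = R(I_j) * W`` with the closed-form LIF rate ``R``
    (in kHz).  ``ext_currents`` is (n_input,) in pA.  Recurrent (feedback)
    blocks are resolved by ``n_iter`` damped sweeps.  Returns
    ``(activities, currents)`` keyed by layer.
    """
    p = spec.neuron_params
    bg = spec.background.stationary_mean(p.tau_ex) if include_background else 0.0
    y = {n: np.zeros(spec.layer_sizes[n]) for n in spec.layer_names}
    I = {n: np.zeros(spec.layer_sizes[n]) for n in spec.layer_names}
    for _ in range(max(n_iter, 1)):
        for name in spec.layer_names:
            cur = spec.i0[name].astype(float).copy() + bg
            if name == spec.layer_names[0]:
                cur += ext_currents
            for b in spec.blocks:
                if b.post != name:
                    continue
                tau = _block_tau(b.weights, spec)
                cur += (b.weights * tau) @ y[b.pre] / params.W
            I[name] = cur
            y[name] = lif_rate(cur, p) / 1000.0 * params.W
    return y, I


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

def _eval_centers(duration: float, params: TrainerParams) -> np.ndarray:
    half = params.W / 2.0
    n0 = int(np.ceil(half / params.t_s))
    n1 = int(np.floor((duration - half) / params.t_s))
    return np.arange(n0, n1 + 1) * params.t_s


def _trial_force_at(record: IndentationRecord, t: float) -> float:
    idx = np.clip(np.searchsorted(record.t_ms, t, side="right") - 1, 0, len(record.t_ms) - 1)
    return float(np.sum([c.force[idx] for c in record.contacts]))


@dataclass
class TrainingHistory:
    frame: pd.DataFrame

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def train(
    records: list[IndentationRecord],
    spec: NetworkSpec,
    grid: OutputGrid,
    params: TrainerParams | None = None,
    encoder: EncoderParams | None = None,
    seed: int = 0,
    dt: float = 1.0,
    rest_probe_ms: float = 2000.0,
    progress: bool = False,
) -> tuple[NetworkSpec, pd.DataFrame]:
    """Train a network on indentation records; returns (spec, history).

    Runs ``params.epochs`` epochs of simulate -> window activities ->
    generalized errors -> batched weight/bias updates with sign projection,
    activity-modulated L2 decay and the baseline-current cap.  History
    rows: epoch, error, lambda, total_rate_active, total_rate_rest.
    """
    if not records:
        raise ValueError("dataset is empty")
    params = params or TrainerParams()
    encoder = encoder or EncoderParams()
    rng = np.random.default_rng(seed)
    spec = spec.copy()
    n = spec.n_neurons
    out_name = spec.layer_names[-1]
    out_sl = spec.layer_slice(out_name)

    duration = float(records[0].t_ms[-1] + (records[0].t_ms[1] - records[0].t_ms[0]))
    centers = _eval_centers(duration, params)
    n_steps = int(round(duration / dt))
    enc_cache = [encode(r.t_ms, r.delta_lambda, encoder, dt=dt, duration=duration) for r in records]
    targets_cache = [
        target_activity(r.contact_positions(), grid, params.sigma, params.y_peak, params.W)
        for r in records
    ]
    force_on = [
        np.array([_trial_force_at(r, c) > 0.0 for c in centers]) for r in records
    ]

    lam = params.lambda_M
    history = []
    err_prev = None
    err_first = None

    for epoch in range(params.epochs):
        order = rng.permutation(len(records))
        epoch_err = 0.0
        active_rate = 0.0
        # batch accumulators
        d_w = [np.zeros_like(b.weights) for b in spec.blocks]
        d_i0 = {name: np.zeros(spec.layer_sizes[name]) for name in spec.layer_names}
        y_batch = {name: 0.0 for name in spec.layer_names}
        n_in_batch = 0

        for k, ti in enumerate(order):
            rec = records[ti]
            sim = simulate(
                spec, enc_cache[ti], duration, dt=dt,
                seed=rng.integers(2**31), record_currents=True,
            )
            counts = window_counts(
                sim.spikes.times, sim.spikes.ids, n, centers, params.W, dt, n_steps
            )
            cur = np.empty((len(centers), n))
            for ci, c in enumerate(centers):
                a = max(int((c - params.W / 2.0) / dt), 0)
                b = min(int((c + params.W / 2.0) / dt), n_steps)
                cur[ci] = sim.currents[a:b].mean(axis=0)

            y = {name: counts[:, spec.layer_slice(name)] for name in spec.layer_names}
            I = {name: cur[:, spec.layer_slice(name)] for name in spec.layer_names}
            y_star = np.where(force_on[ti][:, None], targets_cache[ti][None, :], 0.0)

            errs = backprop_error(y, y_star, spec, I, params)
            epoch_err += float(((y[out_name] - y_star) ** 2).sum()) / 2.0
            active_rate += len(sim.spikes) / (duration / 1000.0)

            for bi, b in enumerate(spec.blocks):
                d_w[bi] += weight_update(
                    b.weights, spec, y[b.pre], y[b.post], errs[b.post], I[b.post], params
                )
            for name in spec.layer_names:
                d_i0[name] += bias_update(y[name], errs[name], I[name], spec, params)
                y_batch[name] += float(y[name].mean())
            n_in_batch += 1

            if n_in_batch == params.batch or k == len(order) - 1:
                for bi, b in enumerate(spec.blocks):
                    kappa = activity_modulated_decay(y_batch[b.post] / n_in_batch, params)
                    b.weights += lam * d_w[bi] - kappa * b.weights
                    b.project_sign()
                for name in spec.layer_names:
                    spec.i0[name] = np.clip(
                        spec.i0[name] + lam * d_i0[name], 0.0, params.i_max
                    )
                d_w = [np.zeros_like(b.weights) for b in spec.blocks]
                d_i0 = {name: np.zeros(spec.layer_sizes[name]) for name in spec.layer_names}
                y_batch = {name: 0.0 for name in spec.layer_names}
                n_in_batch = 0

        epoch_err /= len(records)
        active_rate /= len(records)
        rest = simulate(spec, None, rest_probe_ms, dt=dt, seed=rng.integers(2**31))
        rest_rate = len(rest.spikes) / (rest_probe_ms / 1000.0)
        history.append(
            {"epoch": epoch, "error": epoch_err, "lambda": lam,
             "total_rate_active": active_rate, "total_rate_rest": rest_rate}
        )
        if progress:
            print(f"epoch {epoch}: error={epoch_err:.1f} lambda={lam:.2e} "
                  f"active={active_rate:.0f}Hz rest={rest_rate:.0f}Hz")
        if err_first is None:
            err_first = epoch_err
        elif epoch_err > 10.0 * err_first:
            raise TrainingDivergence(
                f"epoch error {epoch_err:.3g} exceeds 10x initial {err_first:.3g}"
            )
        if err_prev is not None:
            lam = lr_schedule(epoch_err - err_prev, params)
        err_prev = epoch_err

    return spec, pd.DataFrame(history)
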