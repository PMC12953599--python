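"""Software emulation of mixed-signal neuromorphic deployment constraints.

Analog multi-core spiking processors of the DYNAP-SE family expose four
synapse circuits per neuron (two excitatory, two inhibitory) whose
efficacies are shared across each core — effectively a 2-bit weight
resolution — and their subthreshold analog neurons show substantial
device-to-device mismatch.  This module maps a trained network onto that
constraint set: snapping weights to the shared efficacies, injecting
log-normal parameter mismatch, matching software neurons to the hardware
pool by FI-curve similarity, and the local output spatial filter used to
suppress spurious spikes before barycentre decoding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .neurons import NetworkSpec, NeuronParams, lif_rate

__all__ = [
    "HardwareConstraints",
    "constrain_to_shared_weights",
    "inject_mismatch",
    "match_neurons",
    "spatial_filter",
]


@dataclass(frozen=True)
class HardwareConstraints:
    """Shared synaptic efficacies and device statistics of the chip."""

    exc_levels: tuple[float, float] = (4.0, 12.0)    # pA, >= 0
    inh_levels: tuple[float, float] = (-4.0, -12.0)  # pA, <= 0
    neurons_per_core: int = 256
    n_cores: int = 16
    mismatch_cv: float = 0.20
    tau_syn_cv: float = 0.05  # residual spread of the shared-bias synapse circuits

    def __post_init__(self):
        if min(self.exc_levels) < 0 or max(self.inh_levels) > 0:
            raise ValueError("excitatory efficacies must be >= 0, inhibitory <= 0")
        if self.mismatch_cv < 0:
            raise ValueError("mismatch CV must be >= 0")


def _snap(w: np.ndarray, levels: np.ndarray) -> np.ndarray:
    """Nearest allowed level per weight; ties go to the smaller magnitude."""
    order = np.argsort(np.abs(levels), kind="stable")
    lv = levels[order]  # smallest magnitude first -> wins ties via argmin
    d = np.abs(w[..., None] - lv[None, :])
    return lv[np.argmin(d, axis=-1)]


def constrain_to_shared_weights(spec: NetworkSpec, constraints: HardwareConstraints) -> NetworkSpec:
    """Map every connection to the nearest shared efficacy of its sign.

    Excitatory blocks use {0} + exc_levels, inhibitory {0} + inh_levels
    (zero prunes the synapse); free-sign blocks may take any level.
    Idempotent, sign masks preserved.
    """
    out = spec.copy()
    exc = np.array([0.0, *constraints.exc_levels])
    inh = np.array([0.0, *constraints.inh_levels])
    both = np.unique(np.concatenate([exc, inh]))
    for b in out.blocks:
        if b.sign == "exc":
            b.weights = _snap(b.weights, exc)
        elif b.sign == "inh":
            b.weights = _snap(b.weights, inh)
        else:
            b.weights = _snap(b.weights, both)
        b.project_sign()
    return out


def inject_mismatch(
    spec: NetworkSpec,
    cv: float,
    seed: int = 0,
    layers: tuple[str, ...] | None = None,
    cv_overrides: dict[str, float] | None = None,
) -> NetworkSpec:
    """Per-neuron multiplicative log-normal jitter on analog parameters.

    Applies independent log-normal factors with coefficient of variation
    ``cv`` (and unit mean) to each neuron's membrane and synaptic time
    constants, its effective postsynaptic weight gain, and its baseline
    current.  ``cv = 0`` returns an identical copy; fixed seeds are
    reproducible.

    ``layers`` restricts the jitter to the named layers (neurons kept in
    software — typically the input conversion stage — stay nominal).
    ``cv_overrides`` sets a different CV per parameter name; on multi-core
    chips the synaptic time constants come from shared per-core biases, so
    their spread is typically much smaller than the per-neuron circuits'.
    """
    out = spec.copy()
    if cv == 0.0 and not cv_overrides:
        return out
    rng = np.random.default_rng(seed)
    n = spec.n_neurons
    mask = np.ones(n, dtype=bool)
    if layers is not None:
        mask[:] = False
        for name in layers:
            mask[spec.layer_slice(name)] = True

    def draw(param_cv):
        if param_cv == 0.0:
            return np.ones(n)
        sigma2 = np.log1p(param_cv**2)
        f = rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2), n)  # unit mean
        return np.where(mask, f, 1.0)

    ov = cv_overrides or {}
    out.jitter = {
        name: draw(ov.get(name, cv))
        for name in ("tau_m", "tau_ex", "tau_in", "w_gain", "i0")
    }
    return out


def fi_responses(
    params: NeuronParams,
    probe_currents: np.ndarray,
    jitter_tau_m: np.ndarray | None = None,
) -> np.ndarray:
    """FI-curve responses (Hz) over a probe-current grid, per neuron.

    A per-neuron ``tau_m`` factor emulates the device's gain spread (leak
    conductance scaled by 1/factor).  Returns (n_neurons, n_probes).
    """
    if jitter_tau_m is None:
        return lif_rate(probe_currents, params)[None, :]
    out = np.empty((len(jitter_tau_m), len(probe_currents)))
    for i, f in enumerate(jitter_tau_m):
        p = NeuronParams(
            Cm=params.Cm, gL=params.gL / f, EL=params.EL, Vth=params.Vth,
            Vres=params.Vres, tau_ex=params.tau_ex, tau_in=params.tau_in,
            t_r=params.t_r, t_ref=params.t_ref,
        )
        out[i] = lif_rate(probe_currents, p)
    return out


def match_neurons(software: np.ndarray, hardware_pool: np.ndarray) -> tuple[np.ndarray, float]:
    """Optimal software-to-hardware neuron assignment by FI similarity.

    ``software`` is (n_soft, n_probes) and ``hardware_pool`` (n_hard,
    n_probes) of firing rates over the same probe-current grid; the
    returned assignment minimizes the total sum of squared rate
    differences (solved as an optimal assignment problem).  Returns
    ``(hardware index per software neuron, total cost)``.
    """
    software = np.atleast_2d(software)
    hardware_pool = np.atleast_2d(hardware_pool)
    if hardware_pool.shape[0] < software.shape[0]:
        raise ValueError("hardware pool smaller than the number of software neurons")
    cost = ((software[:, None, :] - hardware_pool[None, :, :]) ** 2).sum(axis=2)
    rows, cols = linear_sum_assignment(cost)
    return cols, float(cost[rows, cols].sum())


def deploy(
    spec: NetworkSpec,
    constraints: HardwareConstraints,
    seed: int = 0,
    pool_factor: int = 6,
    probe_currents: np.ndarray | None = None,
) -> NetworkSpec:
    """Full software-to-hardware mapping of a trained network.

    Composes the deployment steps the physical setup requires: snap the
    weights to the shared 2-bit efficacies, draw an analog neuron pool
    ``pool_factor`` times larger than the on-chip layers, assign each
    simulated neuron the pool unit whose FI curve best mimics it (which
    cancels most of the membrane-gain mismatch), and apply the residual
    per-neuron jitter — full ``mismatch_cv`` on weight gain and baseline
    current, ``tau_syn_cv`` on the shared-bias synaptic time constants.
    The input (sensor conversion) layer stays in software and is nominal.
    """
    out = constrain_to_shared_weights(spec, constraints)
    chip_layers = tuple(out.layer_names[1:])
    out = inject_mismatch(
        out,
        constraints.mismatch_cv,
        seed=seed,
        layers=chip_layers,
        cv_overrides={"tau_ex": constraints.tau_syn_cv, "tau_in": constraints.tau_syn_cv},
    )
    # replace the raw tau_m jitter of on-chip neurons by matched pool units
    if probe_currents is None:
        probe_currents = np.linspace(30.0, 120.0, 10)
    rng = np.random.default_rng(seed + 1)
    n = out.n_neurons
    mask = np.zeros(n, dtype=bool)
    for name in chip_layers:
        mask[out.layer_slice(name)] = True
    n_chip = int(mask.sum())
    sigma2 = np.log1p(constraints.mismatch_cv**2)
    pool = rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2), pool_factor * n_chip)
    nominal = fi_responses(out.neuron_params, probe_currents)
    hardware = fi_responses(out.neuron_params, probe_currents, pool)
    assign, _ = match_neurons(np.repeat(nominal, n_chip, axis=0), hardware)
    tau_m = np.ones(n)
    tau_m[mask] = pool[assign]
    out.jitter["tau_m"] = tau_m
    return out


def spatial_filter(activity: np.ndarray, neighbors: np.ndarray) -> np.ndarray:
    """Local online spatial filter: y_i -> y_i * mean of 4 nearest y_j.

    An isolated active neuron with silent neighbours is zeroed, while a
    compact bump is preserved up to boundary scaling — which is what
    suppresses spurious single-neuron spikes before barycentre decoding.
    ``activity`` is (..., n_neurons); ``neighbors`` (n_neurons, 4) from
    ``OutputGrid.nearest_neighbors``.
    """
    a = np.asarray(activity, dtype=float)
    return a * a[..., neighbors].mean(axis=-1)
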