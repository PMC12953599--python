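"""Shared fixtures: geometry, grids, and constructed networks.

The ``designed_map_spec`` builder produces a network with a *known*
somatotopic map (ridge-designed linear readout of the sensor code onto
Gaussian output targets) so decoder- and hardware-level tests do not have
to pay for gradient training.
"""

from __future__ import annotations

import numpy as np
import pytest

import spikeskin as sk
from spikeskin.encoding import EncoderParams, log_transform
from spikeskin.geometry import OutputGrid, SkinGeometry, cone_distance
from spikeskin.neurons import NeuronParams, build_architecture, lif_rate
from spikeskin.skin import ReceptiveFieldModel, sensor_response


@pytest.fixture(scope="session")
def geometry() -> SkinGeometry:
    return SkinGeometry()


@pytest.fixture(scope="session")
def grid(geometry) -> OutputGrid:
    return OutputGrid(geometry)


@pytest.fixture(scope="session")
def dense_grid(geometry) -> OutputGrid:
    """Output grid at the saturated density (~4 neurons/cm^2)."""
    return OutputGrid(geometry, 27, 20)


def design_somatotopic_spec(
    grid: OutputGrid,
    seed: int = 0,
    n_fit: int = 250,
    i_peak: float = 75.0,
    sigma_mm: float = 8.0,
    i0_input: float = 20.0,
    i0_output: float = 18.0,
    ridge: float = 0.002,
):
    """Ridge-designed linear map from the 42-channel code to output bumps.

    Solves for effective synaptic drives v = w * tau(w) such that the
    mean-field output current reproduces a Gaussian kernel (peak
    ``i_peak`` pA, width ``sigma_mm``) around each sampled contact, then
    converts drives back to weights with the sign-dependent time constant.
    """
    g = grid.geometry
    rng = np.random.default_rng(seed)
    enc = EncoderParams()
    rf = ReceptiveFieldModel()
    npar = NeuronParams()
    contacts = g.sample_positions(n_fit, rng)
    X = np.empty((n_fit, 42))
    bg = 16.0
    for k, c in enumerate(contacts):
        dl = sensor_response(c[None, :], g, rf, np.array([2.0]))
        cur = np.concatenate(
            [log_transform(np.maximum(dl, 0), enc), log_transform(np.maximum(-dl, 0), enc)]
        )
        X[k] = lif_rate(cur + i0_input + bg, npar) / 1000.0  # rate in kHz
    D = cone_distance(grid.positions()[:, None, :], contacts[None, :, :], g)
    Y = i_peak * np.exp(-D.T**2 / (2.0 * sigma_mm**2))  # (fit, out) target currents
    V = np.linalg.solve(X.T @ X + ridge * np.eye(42), X.T @ Y).T  # v = w*tau
    W = np.where(V > 0, V / npar.tau_ex, V / npar.tau_in)
    spec = build_architecture("SF_DIR", (42, grid.n_neurons), seed=seed, w_init=0.0, i0_init=0.0)
    spec.blocks[0].weights[:] = W
    spec.i0["input"][:] = i0_input
    spec.i0["output"][:] = i0_output
    return spec


@pytest.fixture(scope="session")
def designed_spec(dense_grid):
    return design_somatotopic_spec(dense_grid)


def gaussian_bump_spikes(
    grid: OutputGrid,
    center_uv: np.ndarray,
    seed: int,
    peak_hz: float = 60.0,
    sigma_mm: float = 8.0,
    duration: float = 1500.0,
    hot_neurons: int = 0,
    hot_hz: float = 35.0,
):
    """Poisson spike trains of a Gaussian activity bump (plus optional
    isolated spurious neurons), on the decoder's neuron indexing."""
    r = np.random.default_rng(seed)
    up = grid.unrolled()
    rates = peak_hz * np.exp(-((up - center_uv) ** 2).sum(1) / (2.0 * sigma_mm**2))
    ts, ii = [], []
    for i, rt in enumerate(rates):
        n = r.poisson(rt * duration / 1000.0)
        ts.append(r.uniform(1.0, duration, n))
        ii.append(np.full(n, i))
    if hot_neurons:
        for h in r.choice(grid.n_neurons, hot_neurons, replace=False):
            n = r.poisson(hot_hz * duration / 1000.0)
            ts.append(r.uniform(1.0, duration, n))
            ii.append(np.full(n, h))
    t_all = np.concatenate(ts)
    i_all = np.concatenate(ii).astype(np.int64)
    order = np.argsort(t_all, kind="stable")
    return sk.SpikeEvents(np.round(t_all[order]), i_all[order], grid.n_neurons, duration)


def sample_separated_contacts(geometry, rng, k, min_dist, max_tries=400):
    """k ROI positions with pairwise unrolled distance >= min_dist."""
    for _ in range(max_tries):
        c = geometry.sample_positions(k, rng)
        uv = geometry.unroll(c[:, 0], c[:, 1])
        d = np.linalg.norm(uv[:, None] - uv[None], axis=-1) + np.eye(k) * 1e9
        if d.min() >= min_dist:
            return c
    raise RuntimeError("could not sample separated contacts")
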