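"""Event-driven position decoding from output-layer spike trains.

Single-touch pipeline: each output neuron's spike train is filtered with a
causal exponential kernel (leaky rate), the top decile of active neurons
defines the instantaneous barycentre of the somatotopic map, and a
bias-corrected exponential moving average smooths the trajectory.
Detection triggers when the mean output-layer leaky rate steadily exceeds
a threshold.  Multi-touch contacts are extracted iteratively: register the
most active neuron if above threshold, suppress a Gaussian neighbourhood
around it, repeat — no prior knowledge of the contact count is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import OutputGrid, SkinGeometry, cone_distance
from .neurons import SpikeEvents

__all__ = [
    "DecoderParams",
    "DecodeResult",
    "leaky_rate",
    "leaky_rate_map",
    "instantaneous_barycenter",
    "ema_debiased",
    "detect",
    "decode_single",
    "decode_multi",
]


@dataclass(frozen=True)
class DecoderParams:
    tau_out: float = 100.0          # leaky-rate time constant (ms)
    delta_t: float = 1.0            # decoding grid step (ms)
    alpha_out: float = 0.9975       # EMA coefficient
    quantile: float = 0.9           # activity quantile defining J(t)
    detect_threshold: float = 0.02  # mean output rate threshold (Hz)
    debounce: float = 50.0          # detection debounce window (ms)
    multi_threshold: float = 3.0    # per-neuron rate threshold (Hz)
    sigma_supp: float = 15.0        # suppression kernel width (mm)
    use_spatial_filter: bool = False
    error_metric: str = "geodesic"  # or "euclidean3d"

    def __post_init__(self):
        if not (0.0 < self.alpha_out < 1.0):
            raise ValueError("alpha_out must be in (0, 1)")
        if min(self.detect_threshold, self.multi_threshold, self.debounce) < 0:
            raise ValueError("thresholds must be >= 0")


@dataclass
class DecodeResult:
    """Decoded trajectory and per-trial summary for one record."""

    t_ms: np.ndarray
    theta: np.ndarray             # estimated theta(t); NaN while undetected
    z: np.ndarray
    detected: np.ndarray          # boolean detection flag trace
    contacts: np.ndarray          # (n_c, 2) final contact estimates
    error_mm: float | None = None
    latency_ms: float | None = None

    def final_estimate(self) -> tuple[float, float]:
        idx = np.flatnonzero(self.detected)
        if len(idx) == 0:
            raise ValueError("no detection in this trial")
        j = idx[-1]
        return float(self.theta[j]), float(self.z[j])


def leaky_rate(spike_times: np.ndarray, t_grid: np.ndarray, tau_out: float = 100.0) -> np.ndarray:
    """Causal exponential filter of one spike train, in Hz.

    ``L(t) = (1/tau) * sum_i exp(-(t - t_i)/tau)`` for ``t >= t_i`` (times
    in ms, kernel normalized to unit area so L is a rate in kHz; returned
    scaled to Hz).
    """
    if tau_out <= 0:
        raise ValueError("tau_out must be > 0")
    t_grid = np.asarray(t_grid, dtype=float)
    out = np.zeros_like(t_grid)
    for ts in np.atleast_1d(spike_times):
        m = t_grid >= ts
        out[m] += np.exp(-(t_grid[m] - ts) / tau_out)
    return 1000.0 * out / tau_out


def leaky_rate_map(spikes: SpikeEvents, n_steps: int, dt: float, tau_out: float) -> np.ndarray:
    """(n_steps, n_neurons) leaky rates of all neurons on the grid (Hz).

    Recursive evaluation: exact exponential decay between grid points with
    spikes binned at their grid times.
    """
    n = spikes.n_neurons
    counts = np.zeros((n_steps, n))
    if len(spikes):
        bins = np.clip((spikes.times / dt).astype(int) - 1, 0, n_steps - 1)
        np.add.at(counts, (bins, spikes.ids), 1.0)
    dec = np.exp(-dt / tau_out)
    L = np.zeros((n_steps, n))
    acc = np.zeros(n)
    for s in range(n_steps):
        acc = acc * dec + counts[s]
        L[s] = acc
    return 1000.0 * L / tau_out


def instantaneous_barycenter(
    L: np.ndarray, positions_unrolled: np.ndarray, quantile: float = 0.9
) -> np.ndarray:
    """Weighted mean of positions of neurons in the top activity decile.

    ``J = {j : L_j > quantile(positive L values, q)}`` with linear-
    interpolation quantiles over strictly positive values and strict
    inequality for membership.  Raises on all-zero activity (callers fall
    back to the previous estimate).  Positions are unrolled planar
    coordinates, so the plain weighted mean is the on-surface barycentre.
    """
    L = np.asarray(L, dtype=float)
    pos_vals = L[L > 0]
    if len(pos_vals) == 0:
        raise ValueError("all-zero activity: barycentre undefined")
    thr = np.quantile(pos_vals, quantile)
    J = L > thr
    if not J.any():  # all positive values equal -> strict inequality empty
        J = L >= thr
    w = L[J]
    return (w[:, None] * positions_unrolled[J]).sum(axis=0) / w.sum()


def ema_debiased(x: np.ndarray, alpha_out: float) -> np.ndarray:
    """Bias-corrected exponential moving average along axis 0.

    ``xhat_n = a*xhat_{n-1} + (1-a)*x_n`` with ``xhat_{-1}=0``, reported as
    ``xhat_n / (1 - a^(n+1))`` so a constant input is reproduced exactly at
    every step.
    """
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    acc = np.zeros(x.shape[1:]) if x.ndim > 1 else 0.0
    for n in range(len(x)):
        acc = alpha_out * acc + (1.0 - alpha_out) * x[n]
        out[n] = acc / (1.0 - alpha_out ** (n + 1))
    return out


def detect(mean_rate: np.ndarray, dt: float, params: DecoderParams) -> np.ndarray:
    """Detection flag trace from the mean output-layer leaky rate (Hz).

    True from the moment the rate has exceeded the threshold continuously
    for the debounce window, until it drops back below threshold.
    """
    above = np.asarray(mean_rate) > params.detect_threshold
    need = max(int(round(params.debounce / dt)), 1)
    flag = np.zeros(len(above), dtype=bool)
    run = 0
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        flag[i] = run >= need
    return flag


def _spatial_filter(L: np.ndarray, neighbors: np.ndarray) -> np.ndarray:
    """y_i -> y_i * mean of its 4 nearest neighbours (per row)."""
    return L * L[..., neighbors].mean(axis=-1)


def decode_single(
    spikes: SpikeEvents,
    grid: OutputGrid,
    params: DecoderParams | None = None,
    truth: np.ndarray | None = None,
    t_on: float | None = None,
) -> DecodeResult:
    """Full single-touch decoding of an output-layer spike train.

    ``spikes`` must be indexed over output neurons only (use
    ``SpikeEvents.select`` upstream).  If ``truth`` (theta, z) is given the
    localization error of the final estimate is reported; with ``t_on``
    (force onset, ms) the detection latency is reported too.
    """
    p = params or DecoderParams()
    g = grid.geometry
    n_steps = int(round(spikes.duration / p.delta_t))
    L = leaky_rate_map(spikes, n_steps, p.delta_t, p.tau_out)
    # detection always uses the raw mean rate; the spatial filter only
    # reshapes the activity map fed to the barycentre
    flag = detect(L.mean(axis=1), p.delta_t, p)
    if p.use_spatial_filter:
        L = _spatial_filter(L, grid.nearest_neighbors(4))
    upos = grid.unrolled()

    raw = np.full((n_steps, 2), np.nan)
    prev = None
    for s in range(n_steps):
        try:
            prev = instantaneous_barycenter(L[s], upos, p.quantile)
        except ValueError:
            pass  # keep previous estimate
        if prev is not None:
            raw[s] = prev
    sm = ema_debiased(np.nan_to_num(raw, nan=0.0), p.alpha_out)
    # invalidate estimates before any activity was seen
    sm[np.isnan(raw[:, 0])] = np.nan

    theta_z = _planar_to_surface(sm, g)
    theta = np.where(flag, theta_z[:, 0], np.nan)
    zz = np.where(flag, theta_z[:, 1], np.nan)
    t_grid = (np.arange(n_steps) + 1) * p.delta_t

    contacts = np.empty((0, 2))
    err = None
    lat = None
    if flag.any():
        j = np.flatnonzero(flag)[-1]
        contacts = np.array([[theta_z[j, 0], theta_z[j, 1]]])
    if truth is not None:
        truth = np.asarray(truth, dtype=float)
        if contacts.shape[0]:
            err = float(_error(contacts[0], truth, g, p.error_metric))
        else:
            err = float(_error(np.asarray(g.center), truth, g, p.error_metric))
    if t_on is not None and flag.any():
        # first detection at or after force onset; in regimes where
        # spontaneous activity already exceeds the detection threshold the
        # flag may be up at onset and the latency reads ~0
        after = np.flatnonzero(flag & (t_grid >= t_on))
        if len(after):
            lat = float(t_grid[after[0]] - t_on)
    return DecodeResult(t_grid, theta, zz, flag, contacts, err, lat)


def _planar_to_surface(uv: np.ndarray, g: SkinGeometry) -> np.ndarray:
    """Invert the unrolling map: planar (x, y) -> (theta, z)."""
    s = np.linalg.norm(uv, axis=-1)
    phi = np.arctan2(uv[..., 0], uv[..., 1])
    theta = phi / g.sin_alpha
    return np.stack([theta, np.asarray(g.z_of_slant(s))], axis=-1)


def _error(est_tz, true_tz, g: SkinGeometry, metric: str) -> float:
    if metric == "euclidean3d":
        return float(np.linalg.norm(g.embed3d(*est_tz) - g.embed3d(*true_tz)))
    return float(cone_distance(np.asarray(est_tz), np.asarray(true_tz), g))


def decode_multi(
    activity: np.ndarray,
    grid: OutputGrid,
    params: DecoderParams | None = None,
) -> np.ndarray:
    """Iterative peak extraction from an output activity map (Hz).

    Repeatedly takes the most active neuron; if its rate exceeds the
    threshold its position is registered as a contact and the activity is
    multiplied by ``1 - exp(-d^2 / (2 sigma_supp^2))`` around it; stops
    when no neuron exceeds the threshold.  Terminates in at most
    ``n_neurons`` iterations.  Returns (n_contacts, 2) positions (theta, z).
    """
    p = params or DecoderParams()
    act = np.asarray(activity, dtype=float).copy()
    pos = grid.positions()
    upos = grid.unrolled()
    found = []
    for _ in range(len(act)):
        j = int(np.argmax(act))
        if act[j] <= p.multi_threshold:
            break
        found.append(pos[j])
        d2 = ((upos - upos[j]) ** 2).sum(axis=1)
        act *= 1.0 - np.exp(-d2 / (2.0 * p.sigma_supp**2))
    return np.array(found) if found else np.empty((0, 2))


def multi_touch_errors(
    estimated: np.ndarray,
    truth: np.ndarray,
    geometry: SkinGeometry,
    metric: str = "geodesic",
) -> np.ndarray:
    """Per-true-contact localization errors with the miss penalty.

    True contacts are greedily matched to the nearest estimate (each
    estimate used once); unmatched true contacts are scored against the
    skin centre.
    """
    truth = np.atleast_2d(truth)
    estimated = np.atleast_2d(estimated) if len(estimated) else np.empty((0, 2))
    center = np.asarray(geometry.center)
    errs = np.full(len(truth), np.nan)
    free = list(range(len(estimated)))
    order = np.arange(len(truth))
    for i in order:
        if not free:
            errs[i] = _error(center, truth[i], geometry, metric)
            continue
        d = [_error(estimated[j], truth[i], geometry, metric) for j in free]
        k = int(np.argmin(d))
        errs[i] = d[k]
        free.pop(k)
    return errs
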