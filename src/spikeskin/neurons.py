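"""Current-based LIF network simulator with exponential synapses.

Model
-----
Every neuron follows

    Cm dV/dt = -gL (V - EL) + I_ex + I_in + I0 + I_ext

with exponentially decaying synaptic currents: a presynaptic spike emitted
at time ``t`` increments the matching synaptic current of its targets by
the connection weight (pA) at ``t + t_r``.  When ``V`` reaches ``Vth`` a
spike is emitted, ``V`` is reset to ``Vres`` and pinned there for ``t_ref``
while the synaptic currents keep integrating.  On top of deterministic
inputs, each neuron receives independent Poisson background spikes of
weight ``omega_ext`` at rate ``nu_ext`` into its excitatory synapse, which
by Campbell's theorem yields a stationary noise current with mean
``omega_ext*nu_ext*tau_ex`` and std ``omega_ext*sqrt(nu_ext*tau_ex/2)``.

Numerics: the membrane is integrated with forward Euler on a fixed grid
(default 1 ms); synaptic currents decay exactly (exponential Euler) and
background events carry uniform within-step jitter so that the sampled
noise current reproduces the filtered-Poisson statistics without
discretization bias.  Units are pA / pF / nS / mV / ms throughout, so
``tau_m = Cm/gL`` is in ms with no conversion factors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NeuronParams",
    "BackgroundInputParams",
    "ConnectionBlock",
    "NetworkSpec",
    "NetworkState",
    "SpikeEvents",
    "ARCHITECTURES",
    "build_architecture",
    "step",
    "simulate",
    "rheobase",
    "lif_rate",
    "lif_rate_derivative",
]

ARCHITECTURES = ("SF_DIR", "SC_BIO", "SC_BIO_NOINH", "SC_BIO_FB", "SC_BIO_COMBINED")


@dataclass(frozen=True)
class NeuronParams:
    """LIF parameters (pA/pF/nS/mV/ms unit system)."""

    Cm: float = 40.0      # membrane capacitance (pF)
    gL: float = 2.0       # leak conductance (nS)
    EL: float = -70.0     # leak reversal (mV)
    Vth: float = -50.0    # spike threshold (mV)
    Vres: float = -70.0   # reset potential (mV)
    tau_ex: float = 8.0   # excitatory synaptic time constant (ms)
    tau_in: float = 4.0   # inhibitory synaptic time constant (ms)
    t_r: float = 2.0      # spike transmission delay (ms)
    t_ref: float = 2.0    # refractory period (ms)

    def __post_init__(self):
        if not (self.Vres <= self.EL < self.Vth):
            raise ValueError("require Vres <= EL < Vth")
        if min(self.tau_ex, self.tau_in, self.t_ref) <= 0 or self.t_r < 0:
            raise ValueError("tau_ex, tau_in, t_ref must be > 0 and t_r >= 0")

    @property
    def tau_m(self) -> float:
        return self.Cm / self.gL


@dataclass(frozen=True)
class BackgroundInputParams:
    """Poisson background drive into the excitatory synapse."""

    omega_ext: float = 2.0    # per-spike current increment (pA)
    nu_ext: float = 1000.0    # Poisson rate (Hz)

    def __post_init__(self):
        if self.omega_ext < 0 or self.nu_ext < 0:
            raise ValueError("omega_ext and nu_ext must be >= 0")

    def stationary_mean(self, tau_ex: float) -> float:
        """Campbell mean of the filtered Poisson current: omega*nu*tau_ex (pA)."""
        return self.omega_ext * (self.nu_ext / 1000.0) * tau_ex

    def stationary_std(self, tau_ex: float) -> float:
        return self.omega_ext * np.sqrt((self.nu_ext / 1000.0) * tau_ex / 2.0)


@dataclass
class ConnectionBlock:
    """Dense weight block between two layers.

    ``sign`` is one of ``free`` (weights may cross zero during learning),
    ``exc`` (>= 0 always) or ``inh`` (<= 0 always).  ``weights`` has shape
    (n_post, n_pre) in pA per presynaptic spike.
    """

    pre: str
    post: str
    sign: str
    weights: np.ndarray

    def project_sign(self) -> None:
        """Clip weights onto the sign mask (no-op for free blocks)."""
        if self.sign == "exc":
            np.clip(self.weights, 0.0, None, out=self.weights)
        elif self.sign == "inh":
            np.clip(self.weights, None, 0.0, out=self.weights)

    def mask_ok(self) -> bool:
        if self.sign == "exc":
            return bool(np.all(self.weights >= 0))
        if self.sign == "inh":
            return bool(np.all(self.weights <= 0))
        return True


@dataclass
class NetworkSpec:
    """Architecture + parameters of one network.

    Layers are ordered; global neuron ids concatenate layers in order.
    ``jitter`` optionally carries per-neuron multiplicative factors (used
    by the hardware-mismatch emulation) for ``tau_m``, ``tau_ex``,
    ``tau_in`` and ``w_gain`` (postsynaptic weight scaling), plus an
    additive-free multiplicative factor ``i0`` on baseline currents.
    """

    tag: str
    layer_names: list[str]
    layer_sizes: dict[str, int]
    blocks: list[ConnectionBlock]
    i0: dict[str, np.ndarray]
    neuron_params: NeuronParams = field(default_factory=NeuronParams)
    background: BackgroundInputParams = field(default_factory=BackgroundInputParams)
    background_layers: tuple[str, ...] | None = None  # None -> all layers
    jitter: dict[str, np.ndarray] | None = None

    # --- indexing ---------------------------------------------------------
    @property
    def n_neurons(self) -> int:
        return sum(self.layer_sizes[n] for n in self.layer_names)

    def layer_slice(self, name: str) -> slice:
        off = 0
        for n in self.layer_names:
            size = self.layer_sizes[n]
            if n == name:
                return slice(off, off + size)
            off += size
        raise KeyError(name)

    @property
    def input_size(self) -> int:
        return self.layer_sizes[self.layer_names[0]]

    def i0_vector(self) -> np.ndarray:
        out = np.zeros(self.n_neurons)
        for name in self.layer_names:
            out[self.layer_slice(name)] = self.i0[name]
        return out

    def global_weight_matrix(self) -> np.ndarray:
        """Dense (n, n) matrix W[post, pre] summed over blocks."""
        n = self.n_neurons
        W = np.zeros((n, n))
        for b in self.blocks:
            W[self.layer_slice(b.post), self.layer_slice(b.pre)] += b.weights
        return W

    def check_masks(self) -> bool:
        return all(b.mask_ok() for b in self.blocks)

    def copy(self) -> "NetworkSpec":
        return NetworkSpec(
            tag=self.tag,
            layer_names=list(self.layer_names),
            layer_sizes=dict(self.layer_sizes),
            blocks=[ConnectionBlock(b.pre, b.post, b.sign, b.weights.copy()) for b in self.blocks],
            i0={k: v.copy() for k, v in self.i0.items()},
            neuron_params=self.neuron_params,
            background=self.background,
            background_layers=self.background_layers,
            jitter=None if self.jitter is None else {k: v.copy() for k, v in self.jitter.items()},
        )

    # --- serialization ----------------------------------------------------
    def to_json(self) -> str:
        d = {
            "tag": self.tag,
            "layer_names": self.layer_names,
            "layer_sizes": self.layer_sizes,
            "blocks": [
                {"pre": b.pre, "post": b.post, "sign": b.sign, "weights": b.weights.tolist()}
                for b in self.blocks
            ],
            "i0": {k: v.tolist() for k, v in self.i0.items()},
            "neuron_params": vars(self.neuron_params).copy(),
            "background": vars(self.background).copy(),
            "background_layers": None if self.background_layers is None else list(self.background_layers),
            "jitter": None if self.jitter is None else {k: v.tolist() for k, v in self.jitter.items()},
        }
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "NetworkSpec":
        d = json.loads(s)
        return cls(
            tag=d["tag"],
            layer_names=d["layer_names"],
            layer_sizes={k: int(v) for k, v in d["layer_sizes"].items()},
            blocks=[
                ConnectionBlock(b["pre"], b["post"], b["sign"], np.asarray(b["weights"], dtype=float))
                for b in d["blocks"]
            ],
            i0={k: np.asarray(v, dtype=float) for k, v in d["i0"].items()},
            neuron_params=NeuronParams(**d["neuron_params"]),
            background=BackgroundInputParams(**d["background"]),
            background_layers=None if d["background_layers"] is None else tuple(d["background_layers"]),
            jitter=None
            if d.get("jitter") is None
            else {k: np.asarray(v, dtype=float) for k, v in d["jitter"].items()},
        )


@dataclass
class SpikeEvents:
    """Time-sorted spike list: parallel arrays of times (ms) and neuron ids."""

    times: np.ndarray
    ids: np.ndarray
    n_neurons: int
    duration: float

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.ids = np.asarray(self.ids, dtype=np.int64)
        if np.any(np.diff(self.times) < 0):
            raise ValueError("spike times must be nondecreasing")
        if len(self.ids) and (self.ids.min() < 0 or self.ids.max() >= self.n_neurons):
            raise ValueError("neuron id out of range")

    def __len__(self) -> int:
        return len(self.times)

    def for_neuron(self, i: int) -> np.ndarray:
        return self.times[self.ids == i]

    def select(self, sl: slice) -> "SpikeEvents":
        """Events of a contiguous id range, re-indexed from zero."""
        lo, hi = sl.start or 0, sl.stop
        m = (self.ids >= lo) & (self.ids < hi)
        return SpikeEvents(self.times[m], self.ids[m] - lo, hi - lo, self.duration)

    def rates(self, t0: float = 0.0, t1: float | None = None) -> np.ndarray:
        """Per-neuron mean firing rate (Hz) over [t0, t1)."""
        t1 = self.duration if t1 is None else t1
        m = (self.times >= t0) & (self.times < t1)
        counts = np.bincount(self.ids[m], minlength=self.n_neurons)
        return counts / ((t1 - t0) / 1000.0)


# ---------------------------------------------------------------------------
# Architecture constructors
# ---------------------------------------------------------------------------

def build_architecture(
    tag: str,
    layer_sizes: tuple[int, ...],
    seed: int | np.random.Generator = 0,
    w_init: float = 1.0,
    i0_init: float = 20.0,
    neuron_params: NeuronParams | None = None,
    background: BackgroundInputParams | None = None,
) -> NetworkSpec:
    """Construct one of the five network architectures.

    ``SF_DIR`` is a two-layer net (input -> output) whose single connection
    block carries no sign constraint.  The ``SC_BIO`` family is
    sign-constrained: input neurons are excitatory (projecting to both the
    output layer and a pool of inhibitory interneurons), interneurons are
    inhibitory onto the output layer.  ``SC_BIO_NOINH`` drops the
    interneurons; ``SC_BIO_FB`` replaces the feedforward drive of the
    interneurons with inhibitory feedback from the output layer;
    ``SC_BIO_COMBINED`` keeps both pathways.

    Initial weights are drawn uniformly with magnitude < ``w_init`` (pA),
    respecting each block's sign mask; baseline currents start at
    ``i0_init`` (pA) for every neuron.
    """
    if tag not in ARCHITECTURES:
        raise ValueError(f"unknown architecture tag {tag!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    np_ = neuron_params or NeuronParams()
    bg = background or BackgroundInputParams()

    three_layer = tag in ("SC_BIO", "SC_BIO_FB", "SC_BIO_COMBINED")
    if three_layer:
        if len(layer_sizes) != 3:
            raise ValueError(f"{tag} needs (input, interneuron, output) sizes")
        n_in, n_int, n_out = layer_sizes
        if n_int <= 0:
            raise ValueError(f"{tag} requires a nonempty interneuron layer")
        names = ["input", "inter", "output"]
        sizes = {"input": n_in, "inter": n_int, "output": n_out}
    else:
        if len(layer_sizes) != 2:
            raise ValueError(f"{tag} needs (input, output) sizes")
        n_in, n_out = layer_sizes
        names = ["input", "output"]
        sizes = {"input": n_in, "output": n_out}
    if min(layer_sizes) <= 0:
        raise ValueError("layer sizes must be positive")

    def draw(n_post, n_pre, sign):
        if sign == "free":
            return rng.uniform(-w_init, w_init, (n_post, n_pre))
        w = rng.uniform(0.0, w_init, (n_post, n_pre))
        return w if sign == "exc" else -w

    blocks: list[ConnectionBlock] = []
    if tag == "SF_DIR":
        blocks.append(ConnectionBlock("input", "output", "free", draw(n_out, n_in, "free")))
    elif tag == "SC_BIO_NOINH":
        blocks.append(ConnectionBlock("input", "output", "exc", draw(n_out, n_in, "exc")))
    else:
        n_int = sizes["inter"]
        blocks.append(ConnectionBlock("input", "output", "exc", draw(n_out, n_in, "exc")))
        if tag in ("SC_BIO", "SC_BIO_COMBINED"):
            blocks.append(ConnectionBlock("input", "inter", "exc", draw(n_int, n_in, "exc")))
        blocks.append(ConnectionBlock("inter", "output", "inh", draw(n_out, n_int, "inh")))
        if tag in ("SC_BIO_FB", "SC_BIO_COMBINED"):
            blocks.append(ConnectionBlock("output", "inter", "inh", draw(n_int, n_out, "inh")))

    i0 = {name: np.full(sizes[name], float(i0_init)) for name in names}
    return NetworkSpec(tag, names, sizes, blocks, i0, np_, bg)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

@dataclass
class NetworkState:
    """Mutable simulation state (per-neuron arrays + delay ring buffer)."""

    V: np.ndarray
    I_ex: np.ndarray
    I_in: np.ndarray
    ref: np.ndarray              # remaining refractory steps (int)
    queue: list[np.ndarray]      # ring buffer of spiking-id arrays
    q_head: int
    t: float                     # current time (ms)

    @classmethod
    def initial(cls, spec: NetworkSpec, dt: float) -> "NetworkState":
        n = spec.n_neurons
        delay_steps = max(int(round(spec.neuron_params.t_r / dt)), 0)
        return cls(
            V=np.full(n, spec.neuron_params.EL),
            I_ex=np.zeros(n),
            I_in=np.zeros(n),
            ref=np.zeros(n, dtype=np.int64),
            queue=[np.empty(0, dtype=np.int64) for _ in range(delay_steps + 1)],
            q_head=0,
            t=0.0,
        )


class _SimKernel:
    """Precomputed per-neuron arrays for the hot loop."""

    def __init__(self, spec: NetworkSpec, dt: float):
        p = spec.neuron_params
        n = spec.n_neurons
        jit = spec.jitter or {}
        ones = np.ones(n)
        tau_m = p.tau_m * jit.get("tau_m", ones)
        self.tau_ex = p.tau_ex * jit.get("tau_ex", ones)
        self.tau_in = p.tau_in * jit.get("tau_in", ones)
        self.w_gain = jit.get("w_gain", ones)
        self.gL_over_Cm = dt / tau_m
        self.dt_over_Cm = dt / p.Cm
        self.dec_ex = np.exp(-dt / self.tau_ex)
        self.dec_in = np.exp(-dt / self.tau_in)
        W = spec.global_weight_matrix() * self.w_gain[:, None]
        self.W_pos = np.clip(W, 0.0, None)
        self.W_neg = np.clip(W, None, 0.0)
        self.has_conn = bool(np.any(W != 0.0))
        self.i0 = spec.i0_vector() * jit.get("i0", ones)
        # background mask
        if spec.background_layers is None:
            self.bg_mask = np.ones(n, dtype=bool)
        else:
            self.bg_mask = np.zeros(n, dtype=bool)
            for name in spec.background_layers:
                self.bg_mask[spec.layer_slice(name)] = True
        self.bg_idx = np.flatnonzero(self.bg_mask)
        self.p = p
        self.bg = spec.background
        self.dt = dt
        self.n = n
        self.ref_steps = max(int(round(p.t_ref / dt)), 1)
        self.input_slice = spec.layer_slice(spec.layer_names[0])


def _background_increments_all(
    k: _SimKernel, n_steps: int, rng: np.random.Generator
) -> np.ndarray | None:
    """(n_steps, n) background increments for a whole run, drawn at once."""
    bg = k.bg
    nb = len(k.bg_idx)
    if bg.omega_ext == 0.0 or bg.nu_ext == 0.0 or nb == 0:
        return None
    lam = (bg.nu_ext / 1000.0) * k.dt
    # one homogeneous Poisson draw over all (step, neuron) cells, events
    # scattered uniformly -- distributionally identical to per-cell draws
    n_cells = n_steps * nb
    tot = int(rng.poisson(lam * n_cells))
    cells = rng.integers(0, n_cells, tot)
    u = rng.random(tot)
    tau_bg = k.tau_ex[k.bg_idx]
    if np.ptp(tau_bg) == 0.0:
        tau_c = tau_bg[0]
    else:
        tau_c = tau_bg[cells % nb]
    contrib = bg.omega_ext * np.exp(-(k.dt * (1.0 - u)) / tau_c)
    inc_small = np.bincount(cells, weights=contrib, minlength=n_cells).reshape(n_steps, nb)
    if nb == k.n:
        return inc_small
    inc = np.zeros((n_steps, k.n))
    inc[:, k.bg_idx] = inc_small
    return inc


def _background_increment(k: _SimKernel, rng: np.random.Generator) -> np.ndarray | None:
    """Jittered Poisson increments to I_ex for one step.

    Each background spike lands uniformly inside the step and decays for
    the residual sub-step interval, so grid samples of I_ex follow the
    exact filtered-Poisson (Campbell) statistics.
    """
    bg = k.bg
    if bg.omega_ext == 0.0 or bg.nu_ext == 0.0 or len(k.bg_idx) == 0:
        return None
    lam = (bg.nu_ext / 1000.0) * k.dt
    counts = rng.poisson(lam, len(k.bg_idx))
    tot = int(counts.sum())
    if tot == 0:
        return None
    idx = np.repeat(k.bg_idx, counts)
    u = rng.random(tot)
    contrib = bg.omega_ext * np.exp(-(k.dt * (1.0 - u)) / k.tau_ex[idx])
    return np.bincount(idx, weights=contrib, minlength=k.n)


def step(
    state: NetworkState,
    spec: NetworkSpec,
    external_currents: np.ndarray | None,
    dt: float,
    rng: np.random.Generator,
    _kernel: _SimKernel | None = None,
) -> tuple[NetworkState, np.ndarray]:
    """Advance the network by one Euler step; returns (state, spiking ids).

    ``external_currents`` is indexed by input-layer neuron (pA).  The
    threshold test runs after the update; spike times are recorded on the
    end-of-step grid point.  Aborts on non-finite state.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    k = _kernel or _SimKernel(spec, dt)

    # exact synaptic decay, then deliveries due this step (delay t_r)
    state.I_ex *= k.dec_ex
    state.I_in *= k.dec_in
    delivered = state.queue[state.q_head]
    if len(delivered) and k.has_conn:
        state.I_ex += k.W_pos[:, delivered].sum(axis=1)
        state.I_in += k.W_neg[:, delivered].sum(axis=1)
    inc = _background_increment(k, rng)
    if inc is not None:
        state.I_ex += inc

    I_tot = state.I_ex + state.I_in + k.i0
    if external_currents is not None:
        I_tot = I_tot.copy()
        I_tot[k.input_slice] += external_currents

    p = k.p
    dV = -k.gL_over_Cm * (state.V - p.EL) + k.dt_over_Cm * I_tot
    in_ref = state.ref > 0
    state.V = np.where(in_ref, p.Vres, state.V + dV)
    state.ref[in_ref] -= 1

    spiking = np.flatnonzero((state.V >= p.Vth) & ~in_ref)
    if len(spiking):
        state.V[spiking] = p.Vres
        state.ref[spiking] = k.ref_steps
    if not np.all(np.isfinite(state.V)):
        raise FloatingPointError(f"non-finite membrane potential at t={state.t + dt} ms")

    # a spike emitted at the end of this step is delivered during the step
    # whose end time is t_r later (slot q_head + delay, ring length delay+1)
    L = len(state.queue)
    state.queue[(state.q_head + L - 1) % L] = spiking
    state.q_head = (state.q_head + 1) % L
    state.t += dt
    return state, spiking


@dataclass
class SimulationResult:
    spikes: "SpikeEvents"
    currents: np.ndarray | None = None   # (T, n) total input current per step
    i_ex: np.ndarray | None = None       # (T, n) excitatory synaptic current


def simulate(
    spec: NetworkSpec,
    external_current_traces: np.ndarray | None,
    duration: float,
    dt: float = 1.0,
    seed: int | np.random.Generator = 0,
    record_currents: bool = False,
    record_i_ex: bool = False,
) -> SimulationResult:
    """Run the network for ``duration`` ms and collect spike events.

    ``external_current_traces`` has shape (n_steps, n_input) in pA (or is
    None for no external drive).  Reproducible for a fixed seed.
    """
    n_steps = int(round(duration / dt))
    if external_current_traces is not None:
        external_current_traces = np.asarray(external_current_traces, dtype=float)
        if external_current_traces.shape[0] < n_steps:
            raise ValueError("external current traces shorter than duration")
        if external_current_traces.shape[1] != spec.input_size:
            raise ValueError("external current traces do not match input-layer size")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = _SimKernel(spec, dt)
    n = spec.n_neurons
    p = k.p

    inc_bg = _background_increments_all(k, n_steps, rng)
    delay_steps = max(int(round(p.t_r / dt)), 0)
    ext_all = external_current_traces
    in_lo = k.input_slice.start or 0

    W = k.W_pos + k.W_neg
    dummy2 = np.zeros((1, 1))
    spk = np.zeros((n_steps, n), dtype=np.bool_)
    currents = np.empty((n_steps, n)) if record_currents else None
    i_ex_rec = np.empty((n_steps, n)) if record_i_ex else None
    ok = _sim_loop(
        n_steps,
        W if k.has_conn else dummy2,
        k.has_conn,
        inc_bg if inc_bg is not None else dummy2,
        inc_bg is not None,
        k.i0,
        np.ascontiguousarray(ext_all[:n_steps]) if ext_all is not None else dummy2,
        ext_all is not None,
        in_lo,
        k.dec_ex,
        k.dec_in,
        k.gL_over_Cm,
        k.dt_over_Cm,
        p.EL,
        p.Vth,
        p.Vres,
        k.ref_steps,
        delay_steps,
        spk,
        currents if record_currents else dummy2,
        record_currents,
        i_ex_rec if record_i_ex else dummy2,
        record_i_ex,
    )
    if not ok:
        raise FloatingPointError("non-finite membrane potential during simulation")
    steps_idx, ids_arr = np.nonzero(spk)
    events = SpikeEvents(
        (steps_idx + 1) * dt, ids_arr, spec.n_neurons, float(n_steps * dt)
    )
    return SimulationResult(events, currents, i_ex_rec)


def _sim_loop_py(
    n_steps, W, has_conn, inc_bg, use_bg, i0, ext, use_ext, in_lo,
    dec_ex, dec_in, g_over, dt_over_cm, EL, Vth, Vres, ref_steps, delay_steps,
    spk, cur_out, rec_cur, iex_out, rec_iex,
):
    """Pure-numpy reference loop (used when numba is unavailable)."""
    n = len(i0)
    V = np.full(n, EL)
    I_ex = np.zeros(n)
    I_in = np.zeros(n)
    ref = np.zeros(n, dtype=np.int64)
    L = delay_steps + 1
    ring = np.zeros((L, n), dtype=np.bool_)
    W_pos = np.clip(W, 0.0, None)
    W_neg = np.clip(W, None, 0.0)
    for s in range(n_steps):
        I_ex *= dec_ex
        I_in *= dec_in
        head = s % L
        delivered = np.flatnonzero(ring[head])
        if delivered.size and has_conn:
            I_ex += W_pos[:, delivered].sum(axis=1)
            I_in += W_neg[:, delivered].sum(axis=1)
        if use_bg:
            I_ex += inc_bg[s]
        I = I_ex + I_in + i0
        if use_ext:
            I = I.copy()
            I[in_lo : in_lo + ext.shape[1]] += ext[s]
        V += -g_over * (V - EL) + dt_over_cm * I
        pinned = ref > 0
        V[pinned] = Vres
        ref[pinned] -= 1
        spiking = (V >= Vth) & ~pinned
        V[spiking] = Vres
        ref[spiking] = ref_steps
        spk[s] = spiking
        ring[(head + L - 1) % L] = spiking
        if rec_cur:
            cur_out[s] = I
        if rec_iex:
            iex_out[s] = I_ex
        if s % 256 == 0 and not np.all(np.isfinite(V)):
            return False
    return bool(np.all(np.isfinite(V)))


def _make_sim_loop():
    try:
        from numba import njit
    except ImportError:  # pragma: no cover - numba is a declared dependency
        return _sim_loop_py

    @njit(cache=True)
    def _loop(
        n_steps, W, has_conn, inc_bg, use_bg, i0, ext, use_ext, in_lo,
        dec_ex, dec_in, g_over, dt_over_cm, EL, Vth, Vres, ref_steps, delay_steps,
        spk, cur_out, rec_cur, iex_out, rec_iex,
    ):
        n = i0.shape[0]
        V = np.full(n, EL)
        I_ex = np.zeros(n)
        I_in = np.zeros(n)
        ref = np.zeros(n, dtype=np.int64)
        L = delay_steps + 1
        ring = np.zeros((L, n), dtype=np.bool_)
        n_ext = ext.shape[1] if use_ext else 0
        for s in range(n_steps):
            head = s % L
            for i in range(n):
                I_ex[i] *= dec_ex[i]
                I_in[i] *= dec_in[i]
            if use_bg:
                for i in range(n):
                    I_ex[i] += inc_bg[s, i]
            if has_conn:
                for j in range(n):
                    if ring[head, j]:
                        for i in range(n):
                            w = W[i, j]
                            if w > 0.0:
                                I_ex[i] += w
                            elif w < 0.0:
                                I_in[i] += w
            write = (head + L - 1) % L
            for i in range(n):
                I = I_ex[i] + I_in[i] + i0[i]
                if use_ext and in_lo <= i < in_lo + n_ext:
                    I += ext[s, i - in_lo]
                V[i] += -g_over[i] * (V[i] - EL) + dt_over_cm * I
                spiked = False
                if ref[i] > 0:
                    V[i] = Vres
                    ref[i] -= 1
                elif V[i] >= Vth:
                    V[i] = Vres
                    ref[i] = ref_steps
                    spiked = True
                spk[s, i] = spiked
                ring[write, i] = spiked
                if rec_cur:
                    cur_out[s, i] = I
                if rec_iex:
                    iex_out[s, i] = I_ex[i]
            if s % 256 == 0:
                for i in range(n):
                    if not np.isfinite(V[i]):
                        return False
        for i in range(n):
            if not np.isfinite(V[i]):
                return False
        return True

    return _loop


_sim_loop = _make_sim_loop()


# ---------------------------------------------------------------------------
# Closed-form LIF rate (FI curve)
# ---------------------------------------------------------------------------

def rheobase(params: NeuronParams | None = None) -> float:
    """Minimum constant current for sustained firing: gL*(Vth-EL) (pA)."""
    p = params or NeuronParams()
    return p.gL * (p.Vth - p.EL)


def lif_rate(I, params: NeuronParams | None = None) -> np.ndarray:
    """Closed-form constant-current LIF firing rate (Hz).

    ``0`` below rheobase, else ``1/(t_ref + tau_m*ln((Vinf-Vres)/(Vinf-Vth)))``
    with ``Vinf = EL + I/gL``.
    """
    p = params or NeuronParams()
    I = np.asarray(I, dtype=float)
    scalar = I.ndim == 0
    I = np.atleast_1d(I)
    rate = np.zeros_like(I)
    above = I > rheobase(p)
    if np.any(above):
        vinf = p.EL + I[above] / p.gL
        isi = p.t_ref + p.tau_m * np.log((vinf - p.Vres) / (vinf - p.Vth))
        rate[above] = 1000.0 / isi
    return rate[0] if scalar else rate


def lif_rate_derivative(I, params: NeuronParams | None = None, smooth: float = 0.0) -> np.ndarray:
    """Analytic slope dR/dI of the LIF FI curve (Hz/pA).

    With ``smooth = 0`` the exact derivative is returned (0 below
    rheobase, unbounded just above it).  With ``smooth > 0`` (pA) the
    slope is evaluated no closer to rheobase than ``smooth``, for every
    input: below-rheobase currents get the small positive surrogate slope
    at ``rheobase + smooth``, which keeps silent neurons trainable.
    """
    p = params or NeuronParams()
    I = np.asarray(I, dtype=float)
    scalar = I.ndim == 0
    I = np.atleast_1d(I).copy()
    rb = rheobase(p)
    out = np.zeros_like(I)
    if smooth > 0.0:
        I = np.maximum(I, rb + smooth)
    above = I > rb
    if np.any(above):
        Ia = I[above]
        vinf = p.EL + Ia / p.gL
        a = vinf - p.Vres
        b = vinf - p.Vth
        isi = p.t_ref + p.tau_m * np.log(a / b)
        # d(isi)/dI = tau_m/gL * (1/a - 1/b);  dR/dI = -1000 * isi' / isi^2
        d_isi = (p.tau_m / p.gL) * (1.0 / a - 1.0 / b)
        out[above] = -1000.0 * d_isi / isi**2
    return out[0] if scalar else out
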