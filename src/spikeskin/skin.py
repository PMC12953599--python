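"""Synthetic e-skin: receptive-field model, indentation protocol, analyses.

The generator emulates the statistical structure of the FBG-based skin:
each sensor responds to an indentation with a positive component that
decays sharply with geodesic distance (characteristic radius ~6.1 mm,
SA1-like) and a broad, irregular negative component (~25.6 mm, SA2-like)
attributed to transversal deformation of the silicone.  Receptive fields
overlap, responses superpose across simultaneous contacts, and forces
follow quasi-static ramp-hold-release profiles with optional within-hold
fluctuations mimicking manually delivered stimuli.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .geometry import SkinGeometry, cone_distance

__all__ = [
    "ReceptiveFieldModel",
    "IndentationProtocol",
    "Contact",
    "IndentationRecord",
    "sensor_response",
    "force_profile",
    "generate_record",
    "generate_dataset",
    "fit_receptive_field",
    "rate_relative_change",
]


@dataclass(frozen=True)
class ReceptiveFieldModel:
    """Exponential receptive fields of the two signal components.

    Mean response to a unit force at geodesic distance ``d`` (mm):

        R(d) = R0_pos * exp(-d/d0_pos) - R0_neg * exp(-d/d0_neg) * (1 + g_i(theta))

    with per-sensor angular gain fields ``g_i`` modelling the irregularity
    of the negative component (zero for the positive one by default).
    """

    R0_pos: float = 1.2        # peak positive response (nm per N)
    R0_neg: float = 0.06       # peak negative response (nm per N)
    d0_pos: float = 6.1        # positive characteristic radius (mm)
    d0_neg: float = 25.6       # negative characteristic radius (mm)
    irregularity: float = 2.5  # amplitude of the angular modulation of R_neg
    noise_std: float = 0.002   # additive sensor noise (nm)
    n_harmonics: int = 3       # harmonics of the angular gain field

    def __post_init__(self):
        if self.d0_pos <= 0 or self.d0_neg <= 0:
            raise ValueError("characteristic radii must be > 0")

    def angular_gain(self, sensor_index: np.ndarray, bearing: np.ndarray) -> np.ndarray:
        """Smooth per-sensor gain field g_i(bearing) with E[g]=0.

        Deterministic in the sensor index, so the same sensor always has
        the same (irregular) field shape across trials.
        """
        if self.irregularity == 0.0:
            return np.zeros(np.broadcast(sensor_index, bearing).shape)
        g = np.zeros(np.broadcast(sensor_index, bearing).shape)
        amp = self.irregularity / np.sqrt(self.n_harmonics)
        for h in range(1, self.n_harmonics + 1):
            # fixed pseudo-random phases per (sensor, harmonic)
            phase = 2.0 * np.pi * np.modf(np.sin(12.9898 * sensor_index + 78.233 * h) * 43758.5453)[0]
            g = g + amp * np.cos(h * bearing + phase)
        return g


@dataclass(frozen=True)
class IndentationProtocol:
    """Sampling protocol for a synthetic indentation dataset.

    Quasi-static trials: zero force for ``t_pre``, linear ramp over
    ``t_ramp`` to a per-trial amplitude, hold for ``t_hold`` (with
    fluctuations scaled by ``manual_variability``), release over
    ``t_release``.  Times in ms, forces in N, sampling at ``fs`` Hz.
    """

    n_trials: int = 100
    contact_counts: tuple[int, ...] = (1,)
    position_grid: int | None = None   # side of a fixed (theta, z) grid, or None for uniform
    t_pre: float = 200.0
    t_ramp: float = 200.0
    t_hold: float = 600.0
    t_release: float = 200.0
    force_range: tuple[float, float] = (1.0, 4.0)
    manual_variability: float = 0.0
    fs: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if min(self.t_ramp, self.t_hold, self.t_release) <= 0:
            raise ValueError("profile durations must be > 0")
        if min(self.force_range) <= 0:
            raise ValueError("force amplitudes must be > 0")

    @property
    def duration(self) -> float:
        return self.t_pre + self.t_ramp + self.t_hold + self.t_release


@dataclass
class Contact:
    theta: float
    z: float
    force: np.ndarray  # force trace (N) on the record's time grid


@dataclass
class IndentationRecord:
    """One stimulus trial: time grid, 21-channel traces and ground truth."""

    t_ms: np.ndarray
    delta_lambda: np.ndarray         # (T, 21) in nm
    contacts: list[Contact]
    trial_id: int = 0
    seed: int = 0

    @property
    def n_channels(self) -> int:
        return self.delta_lambda.shape[1]

    def contact_positions(self) -> np.ndarray:
        return np.array([[c.theta, c.z] for c in self.contacts])

    def stimulation_window(self) -> tuple[float, float]:
        """(t_on, t_off) in ms where any contact force is nonzero."""
        f = np.sum([c.force for c in self.contacts], axis=0)
        nz = np.flatnonzero(f > 0)
        if len(nz) == 0:
            return 0.0, 0.0
        return float(self.t_ms[nz[0]]), float(self.t_ms[nz[-1]])


def force_profile(protocol: IndentationProtocol, amplitude: float, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Ramp-hold-release force trace (N) on the protocol's time grid."""
    dt = 1000.0 / protocol.fs
    t = np.arange(0.0, protocol.duration, dt)
    f = np.zeros_like(t)
    t0, t1 = protocol.t_pre, protocol.t_pre + protocol.t_ramp
    t2 = t1 + protocol.t_hold
    t3 = t2 + protocol.t_release
    ramp = (t >= t0) & (t < t1)
    hold = (t >= t1) & (t < t2)
    rel = (t >= t2) & (t < t3)
    f[ramp] = amplitude * (t[ramp] - t0) / protocol.t_ramp
    f[hold] = amplitude
    f[rel] = amplitude * (1.0 - (t[rel] - t2) / protocol.t_release)
    if protocol.manual_variability > 0.0:
        # smooth multiplicative fluctuation during the hold (random walk,
        # low-pass filtered), scaled by the manual-variability factor
        n = int(hold.sum())
        w = np.cumsum(rng.normal(0.0, 1.0, n))
        k = max(int(protocol.fs * 0.05), 1)
        kernel = np.ones(k) / k
        w = np.convolve(w, kernel, mode="same")
        w = w - w.mean()
        w = w / (np.abs(w).max() + 1e-12)
        f[hold] *= np.clip(1.0 + 0.5 * protocol.manual_variability * w, 0.05, None)
    return t, f


def sensor_response(
    contacts: np.ndarray,
    geometry: SkinGeometry,
    model: ReceptiveFieldModel,
    force: np.ndarray,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Wavelength shifts (nm) of all sensors for simultaneous contacts.

    ``contacts`` is (n_c, 2) of (theta, z); ``force`` is scalar-per-contact
    (n_c,) or a (T, n_c) trace.  Responses superpose linearly across
    contacts (quasi-static assumption); optional additive Gaussian noise.
    Returns (n_sensors,) or (T, n_sensors).
    """
    contacts = np.atleast_2d(np.asarray(contacts, dtype=float))
    force = np.asarray(force, dtype=float)
    sens = geometry.sensor_positions()
    d = cone_distance(sens[:, None, :], contacts[None, :, :], geometry)  # (S, C)
    # bearing of each contact as seen from each sensor, in unrolled plane
    u_s = geometry.unroll(sens[:, 0], sens[:, 1])
    u_c = geometry.unroll(contacts[:, 0], contacts[:, 1])
    dvec = u_c[None, :, :] - u_s[:, None, :]
    bearing = np.arctan2(dvec[..., 1], dvec[..., 0])
    gains = model.angular_gain(np.arange(len(sens))[:, None], bearing)
    resp = model.R0_pos * np.exp(-d / model.d0_pos) - model.R0_neg * np.exp(-d / model.d0_neg) * (1.0 + gains)
    if force.ndim <= 1:
        out = resp @ np.atleast_1d(force)          # (S,)
    else:
        out = force @ resp.T                        # (T, S)
    if rng is not None and model.noise_std > 0.0:
        out = out + rng.normal(0.0, model.noise_std, out.shape)
    return out


def _grid_sites(geometry: SkinGeometry, side: int) -> np.ndarray:
    half = geometry.theta_span / 2.0
    th = np.linspace(-0.9 * half, 0.9 * half, side)
    s = np.linspace(
        geometry.s_min + 0.05 * (geometry.s_max - geometry.s_min),
        geometry.s_max - 0.05 * (geometry.s_max - geometry.s_min),
        side,
    )
    tt, ss = np.meshgrid(th, s)
    return np.stack([tt.ravel(), np.asarray(geometry.z_of_slant(ss.ravel()))], axis=-1)


def generate_record(
    protocol: IndentationProtocol,
    geometry: SkinGeometry,
    model: ReceptiveFieldModel,
    positions: np.ndarray,
    rng: np.random.Generator,
    trial_id: int = 0,
) -> IndentationRecord:
    """Generate one trial with the given contact positions."""
    positions = np.atleast_2d(positions)
    contacts = []
    forces = []
    t = None
    for p in positions:
        amp = rng.uniform(*protocol.force_range)
        t, f = force_profile(protocol, amp, rng)
        contacts.append(Contact(float(p[0]), float(p[1]), f))
        forces.append(f)
    F = np.stack(forces, axis=1)  # (T, C)
    dlam = sensor_response(positions, geometry, model, F, rng)
    return IndentationRecord(t, dlam, contacts, trial_id=trial_id, seed=protocol.seed)


def generate_dataset(
    protocol: IndentationProtocol,
    geometry: SkinGeometry | None = None,
    model: ReceptiveFieldModel | None = None,
) -> list[IndentationRecord]:
    """Generate a seeded, reproducible set of indentation records.

    Contact counts cycle deterministically through ``contact_counts`` so a
    request for 300 trials with counts (1, 2, 3, 4) yields exactly 75 per
    condition.  With ``position_grid`` set, multi-touch configurations are
    sampled from the grid without replacement within a trial; otherwise
    positions are uniform over the ROI.
    """
    geometry = geometry or SkinGeometry()
    model = model or ReceptiveFieldModel()
    rng = np.random.default_rng(protocol.seed)
    counts = np.tile(protocol.contact_counts, int(np.ceil(protocol.n_trials / len(protocol.contact_counts))))
    counts = counts[: protocol.n_trials]
    sites = _grid_sites(geometry, protocol.position_grid) if protocol.position_grid else None
    records = []
    for i, c in enumerate(counts):
        if sites is not None:
            idx = rng.choice(len(sites), size=c, replace=False)
            pos = sites[idx]
        else:
            pos = geometry.sample_positions(c, rng)
        records.append(generate_record(protocol, geometry, model, pos, rng, trial_id=i))
    return records


# ---------------------------------------------------------------------------
# Analyses
# ---------------------------------------------------------------------------

def fit_receptive_field(
    records: list[IndentationRecord],
    geometry: SkinGeometry | None = None,
    component: str = "pos",
    n_bins: int = 24,
    d_max: float | None = None,
):
    """Fit the exponential receptive-field model to a record set.

    Peak per-trial responses (normalized by peak force) are pooled by
    sensor-contact geodesic distance; a least-squares fit of
    ``R0*exp(-d/d0)`` to the binned mean profile recovers the component's
    peak response and characteristic radius.  Also returns the mean
    coefficient of variation over ``d in [0, 3*d0]`` (relative spread of
    responses at fixed distance; 0 for a noiseless rotationally symmetric
    field).

    Returns ``(R0, d0, mean_cv)``.
    """
    geometry = geometry or SkinGeometry()
    dists, resps = [], []
    for rec in records:
        if len(rec.contacts) != 1:
            continue  # the radial profile is defined for single contacts
        pos = rec.contact_positions()[0]
        d = cone_distance(geometry.sensor_positions(), pos[None, :], geometry)
        peak_f = max(float(np.max(rec.contacts[0].force)), 1e-12)
        sig = rec.delta_lambda
        r = np.max(sig, axis=0) if component == "pos" else np.max(-sig, axis=0)
        dists.append(d)
        resps.append(r / peak_f)
    if not dists:
        raise ValueError("no single-contact records to fit")
    d = np.concatenate(dists)
    r = np.concatenate(resps)
    if len(np.unique(np.round(d, 6))) < 2:
        raise ValueError("degenerate distance support: need >= 2 distinct distances")
    if d_max is not None:
        keep = d <= d_max
        d, r = d[keep], r[keep]

    def expo(x, R0, d0):
        return R0 * np.exp(-x / d0)

    # least-squares fit of the exponential mean-profile on the raw pairs
    p0 = (max(r.max(), 1e-6), max(float(d.max()) / 4.0, 1.0))
    (R0, d0), _ = curve_fit(expo, d, r, p0=p0, maxfev=20000)
    d0 = abs(float(d0))

    # CV(d) averaged over d in [0, 3*d0] of the fitted component
    hi = min(3.0 * d0, float(d.max()))
    edges = np.linspace(0.0, hi + 1e-9, n_bins + 1)
    which = np.digitize(d, edges) - 1
    cvs = []
    for b in range(n_bins):
        m = which == b
        if m.sum() < 2:
            continue
        mu = r[m].mean()
        if mu > 0:
            cvs.append(r[m].std(ddof=1) / mu)
    mean_cv = float(np.mean(cvs)) if cvs else 0.0
    return float(R0), d0, mean_cv


def rate_relative_change(record: IndentationRecord, eps_frac: float = 0.01) -> float:
    """Mean rate of relative change of the sensor signals (%/s).

    Averages ``|ds/dt| / |s|`` over time and channels during the
    stimulation window; the denominator is floored at ``eps_frac`` of the
    per-channel absolute maximum to keep near-zero samples from dominating.
    """
    t_on, t_off = record.stimulation_window()
    t = record.t_ms
    m = (t >= t_on) & (t <= t_off)
    if m.sum() < 2:
        raise ValueError("record has no stimulation support")
    s = record.delta_lambda[m]
    if np.allclose(s, 0.0):
        raise ValueError("all-zero record")
    dt_s = (t[1] - t[0]) / 1000.0
    ds = np.gradient(s, dt_s, axis=0)
    floor = eps_frac * np.max(np.abs(s), axis=0, keepdims=True)
    floor = np.maximum(floor, 1e-15)
    ratio = np.abs(ds) / np.maximum(np.abs(s), floor)
    return float(np.mean(ratio.mean(axis=0)) * 100.0)
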