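"""Evaluation statistics and study procedures.

Localization errors on the skin are spatially correlated, so uncertainty
on median errors is estimated with a blocked bootstrap: trials are grouped
into spatial blocks (tiles of the unrolled surface) and blocks, not
trials, are resampled.  Paired architecture comparisons use a Wilcoxon
signed-rank test on block medians with the r = z/sqrt(n) effect size.  The
module also houses the weight-quantization study with its exponential
error-vs-bits fit (chi-square corrected for the effective number of
independent samples), functional-connectivity probing, activity and power
metrics, the shared k-fold protocol and the energy-constraint sweep.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit
from sklearn.model_selection import KFold

from .geometry import OutputGrid, SkinGeometry, cone_distance
from .neurons import NetworkSpec, lif_rate, simulate

__all__ = [
    "PowerModelParams",
    "assign_blocks",
    "blocked_bootstrap_median",
    "select_block_size",
    "wilcoxon_blocked",
    "quantize_weights",
    "n_effective",
    "fit_quantization_curve",
    "probe_connectivity",
    "radial_profile",
    "activity_metrics",
    "power_model",
    "kfold_split",
    "energy_sweep",
]


# ---------------------------------------------------------------------------
# Blocked resampling
# ---------------------------------------------------------------------------

def assign_blocks(positions: np.ndarray, geometry: SkinGeometry, block_size: float) -> np.ndarray:
    """Tile the unrolled surface into square blocks of side ``block_size`` mm."""
    u = geometry.unroll(positions[:, 0], positions[:, 1])
    ij = np.floor((u - u.min(axis=0)) / block_size).astype(int)
    _, labels = np.unique(ij, axis=0, return_inverse=True)
    return labels


def blocked_bootstrap_median(
    errors: np.ndarray,
    positions: np.ndarray,
    geometry: SkinGeometry,
    block_size: float,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Median error and its std estimated by resampling spatial blocks.

    Blocks are drawn with replacement until each bootstrap replicate
    reaches the original sample size (blocks are unequal, so drawing a
    fixed number of them would inflate the spread); the std of the
    bootstrap distribution of medians is returned.  With single-trial
    blocks this reduces to the naive trial bootstrap.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    errors = np.asarray(errors, dtype=float)
    n = len(errors)
    labels = assign_blocks(np.asarray(positions, dtype=float), geometry, block_size)
    n_blocks = labels.max() + 1
    if n_blocks < 2:
        raise ValueError("fewer than 2 spatial blocks: blocked bootstrap degenerate")
    rng = np.random.default_rng(seed)
    members = [np.flatnonzero(labels == b) for b in range(n_blocks)]
    meds = np.empty(n_boot)
    for i in range(n_boot):
        idx = []
        total = 0
        while total < n:
            b = int(rng.integers(0, n_blocks))
            idx.append(members[b])
            total += len(members[b])
        meds[i] = np.median(errors[np.concatenate(idx)])
    return float(np.median(errors)), float(meds.std(ddof=1))


def select_block_size(
    errors: np.ndarray,
    positions: np.ndarray,
    geometry: SkinGeometry,
    candidates: list[float],
    tolerance: float = 0.05,
    n_boot: int = 300,
    seed: int = 0,
) -> float:
    """Smallest candidate block size at the bootstrap-std plateau.

    Returns the smallest candidate whose bootstrap std changes by less
    than ``tolerance`` (relative) versus the next larger candidate; falls
    back to the largest candidate if no plateau is reached.
    """
    candidates = sorted(candidates)
    if len(candidates) == 1:
        return candidates[0]
    stds = []
    for c in candidates:
        try:
            _, s = blocked_bootstrap_median(errors, positions, geometry, c, n_boot, seed)
        except ValueError:
            s = np.nan
        stds.append(s)
    for i in range(len(candidates) - 1):
        a, b = stds[i], stds[i + 1]
        if np.isfinite(a) and np.isfinite(b) and abs(b - a) < tolerance * max(a, 1e-12):
            return candidates[i]
    return candidates[-1]


def wilcoxon_blocked(
    errors_a: np.ndarray,
    errors_b: np.ndarray,
    blocks: np.ndarray,
) -> tuple[float, float, float]:
    """One-sided Wilcoxon signed-rank test on block-median paired errors.

    Tests whether A's block medians are smaller than B's.  Returns
    ``(statistic, one-sided p, effect size r = z/sqrt(n))`` with ties
    dropped (zero differences excluded).
    """
    blocks = np.asarray(blocks)
    uniq = np.unique(blocks)
    med_a = np.array([np.median(np.asarray(errors_a)[blocks == b]) for b in uniq])
    med_b = np.array([np.median(np.asarray(errors_b)[blocks == b]) for b in uniq])
    diff = med_a - med_b
    nz = diff != 0
    n = int(nz.sum())
    if n == 0:
        return 0.0, 0.5, 0.0
    res = stats.wilcoxon(med_a[nz], med_b[nz], alternative="less", method="approx")
    z = stats.norm.ppf(res.pvalue)  # one-sided: p = Phi(z)
    r = abs(z) / np.sqrt(n)
    return float(res.statistic), float(res.pvalue), float(r)


def effect_size_r(z: float, n: int) -> float:
    """Standardized effect size r = z/sqrt(n)."""
    return z / np.sqrt(n)


# ---------------------------------------------------------------------------
# Weight quantization study
# ---------------------------------------------------------------------------

def quantize_weights(spec: NetworkSpec, n_bits: int) -> NetworkSpec:
    """Uniform symmetric quantization of every connection block.

    Per block, weights map to the nearest of ``2^n - 1`` mid-tread levels
    ``k * wmax/(2^(n-1) - 1)`` spanning [-max|w|, +max|w|] and including 0
    (for ``n >= 2``); 1-bit quantization keeps only {-wmax, +wmax}.  Sign
    masks are preserved and the mapping is idempotent.
    """
    if n_bits < 1:
        raise ValueError("n_bits must be >= 1")
    out = spec.copy()
    for b in out.blocks:
        wmax = np.abs(b.weights).max()
        if wmax == 0:
            continue
        if n_bits == 1:
            q = np.where(b.weights >= 0, wmax, -wmax)
        else:
            m = 2 ** (n_bits - 1) - 1
            step = wmax / m
            q = np.clip(np.round(b.weights / step), -m, m) * step
        b.weights = q
        b.project_sign()
    return out


def n_effective(n_samples: int, tau_acf: float) -> float:
    """Effective number of independent samples under AR-like correlation.

    ``N_eff = N (1 - e^(-1/tau)) / (1 + e^(-1/tau))``; tends to N as
    ``tau -> 0`` and shrinks with increasing correlation length.
    """
    if tau_acf <= 0:
        return float(n_samples)
    rho = np.exp(-1.0 / tau_acf)
    return n_samples * (1.0 - rho) / (1.0 + rho)


def fit_quantization_curve(
    n_bits: np.ndarray,
    median_errors: np.ndarray,
    errors_std: np.ndarray | None = None,
    tau_acf: float = 0.0,
):
    """Fit ``a*exp(-n/tau_bit) + c`` to median error vs quantization bits.

    Returns ``(a, tau_bit, c, chi2, p)``.  The chi-square on the residuals
    is evaluated against ``N_eff - 3`` degrees of freedom, with the
    statistic scaled by ``N_eff/N`` to discount autocorrelated samples
    (the correction can only reduce apparent significance).
    """
    n_bits = np.asarray(n_bits, dtype=float)
    y = np.asarray(median_errors, dtype=float)
    sig = np.ones_like(y) if errors_std is None else np.asarray(errors_std, dtype=float)

    def model(n, a, tau, c):
        return a * np.exp(-n / tau) + c

    a0 = max(y.max() - y.min(), 1e-9)
    p0 = (a0, 1.5, y.min())
    (a, tau_bit, c), _ = curve_fit(model, n_bits, y, p0=p0, maxfev=20000)
    resid = (y - model(n_bits, a, tau_bit, c)) / np.maximum(sig, 1e-12)
    chi2_raw = float((resid**2).sum())
    neff = n_effective(len(y), tau_acf)
    chi2_eff = chi2_raw * neff / len(y)
    dof = max(neff - 3.0, 1.0)
    p = float(stats.chi2.sf(chi2_eff, dof))
    return float(a), float(tau_bit), float(c), chi2_eff, p


# ---------------------------------------------------------------------------
# Functional connectivity probing
# ---------------------------------------------------------------------------

def probe_connectivity(
    spec: NetworkSpec,
    probe_rate: float = 50.0,
    duration: float = 2000.0,
    seed: int = 0,
    baseline_subtract: bool = True,
    input_ids: np.ndarray | None = None,
) -> np.ndarray:
    """Input -> output response map by stimulating one input at a time.

    Each probed input neuron is driven with the constant current that
    makes an isolated LIF fire at ``probe_rate`` Hz; the output-layer
    rates (baseline-subtracted by default) are recorded.  Returns
    (n_probed, n_output) in Hz.
    """
    out_sl = spec.layer_slice(spec.layer_names[-1])
    n_in = spec.input_size
    ids = np.arange(n_in) if input_ids is None else np.asarray(input_ids)
    # invert the FI curve on a grid for the probe current
    I_grid = np.linspace(0.0, 400.0, 2001)
    rates = lif_rate(I_grid, spec.neuron_params)
    I_probe = float(np.interp(probe_rate, rates, I_grid))
    n_steps = int(round(duration))
    base = np.zeros(out_sl.stop - out_sl.start)
    if baseline_subtract:
        sim0 = simulate(spec, None, duration, seed=seed)
        base = sim0.spikes.rates()[out_sl]
    maps = np.empty((len(ids), out_sl.stop - out_sl.start))
    for k, i in enumerate(ids):
        ext = np.zeros((n_steps, n_in))
        ext[:, i] = I_probe
        sim = simulate(spec, ext, duration, seed=seed + 1 + int(i))
        maps[k] = sim.spikes.rates()[out_sl] - base
    return maps


def radial_profile(
    maps: np.ndarray,
    input_positions: np.ndarray,
    grid: OutputGrid,
    n_bins: int = 16,
):
    """Median and interquartile response vs input-output geodesic distance.

    Pools all (probed input, output) pairs into ``n_bins`` equal-width
    distance bins.  Returns (bin_centers, median, q25, q75).
    """
    out_pos = grid.positions()
    d = cone_distance(
        np.asarray(input_positions)[:, None, :], out_pos[None, :, :], grid.geometry
    ).ravel()
    r = np.asarray(maps, dtype=float).ravel()
    edges = np.linspace(0.0, d.max() + 1e-9, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    med = np.full(n_bins, np.nan)
    q25 = np.full(n_bins, np.nan)
    q75 = np.full(n_bins, np.nan)
    which = np.digitize(d, edges) - 1
    for b in range(n_bins):
        m = which == b
        if m.any():
            med[b] = np.median(r[m])
            q25[b], q75[b] = np.percentile(r[m], [25, 75])
    return centers, med, q25, q75


# ---------------------------------------------------------------------------
# Activity and power
# ---------------------------------------------------------------------------

def activity_metrics(spikes, t0: float = 0.0, t1: float | None = None) -> float:
    """Total network spiking activity (Hz): sum of per-neuron rates."""
    return float(spikes.rates(t0, t1).sum())


@dataclass(frozen=True)
class PowerModelParams:
    """Per-event energy budget of the neuromorphic processor (J).

    Defaults are placeholders on the right order for sub-threshold analog
    arrays; absolute wattage requires the device's measured values, but
    relative comparisons only need the linear structure.
    """

    E_spike: float = 1.0e-9
    E_enc: float = 0.5e-9
    E_br: float = 2.0e-9
    E_rt: float = 2.0e-9
    E_pulse: float = 0.2e-9
    N_cores: int = 1

    def __post_init__(self):
        if min(self.E_spike, self.E_enc, self.E_br, self.E_rt, self.E_pulse) < 0:
            raise ValueError("energies must be >= 0")


def power_model(rates: np.ndarray, n_post: np.ndarray, params: PowerModelParams) -> float:
    """Total power (W): per-neuron rate times its per-spike energy cost.

    ``P = sum_i r_i (E_spike + E_enc + N_cores (E_br + E_rt) + N_post,i E_pulse)``.
    """
    rates = np.asarray(rates, dtype=float)
    n_post = np.broadcast_to(np.asarray(n_post, dtype=float), rates.shape)
    per_spike = (
        params.E_spike + params.E_enc
        + params.N_cores * (params.E_br + params.E_rt)
        + n_post * params.E_pulse
    )
    return float((rates * per_spike).sum())


# ---------------------------------------------------------------------------
# Protocols
# ---------------------------------------------------------------------------

def kfold_split(n_trials: int, k: int = 5, seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Shuffled k-fold (train, test) index splits, reusable across models."""
    if k < 2:
        raise ValueError("k must be >= 2")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr.copy(), te.copy()) for tr, te in kf.split(np.arange(n_trials))]


def energy_sweep(
    records,
    architectures: list[str],
    levels: list[float],
    train_fn,
    seeds: list[int] | None = None,
) -> pd.DataFrame:
    """Error-vs-activity curves across energy-constraint levels.

    ``train_fn(arch, level, seed) -> dict`` must run one training and
    return at least ``median_error``, ``error_std``, ``rate_active`` and
    ``rate_rest``.  Output schema: architecture, level, seed + those keys.
    """
    seeds = seeds or [0]
    rows = []
    for arch in architectures:
        for level in levels:
            for seed in seeds:
                out = train_fn(arch, level, seed)
                rows.append({"architecture": arch, "level": level, "seed": seed, **out})
    return pd.DataFrame(rows)
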