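"""Model/Results facade over the encode -> simulate -> train -> decode stack.

``TactileSNN`` is constructed from a set of indentation records plus an
architecture choice, and ``fit()`` returns a ``TactileSNNResults`` object
carrying the trained network, the training history, and evaluation
helpers (decoding, localization errors with blocked-bootstrap
uncertainties, activity metrics, a text ``summary()``), in the style of
statsmodels model objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import decoding, evaluation, training
from .encoding import EncoderParams, encode
from .geometry import OutputGrid, SkinGeometry
from .neurons import BackgroundInputParams, NetworkSpec, NeuronParams, build_architecture, simulate
from .skin import IndentationRecord
from .training import TrainerParams

__all__ = ["TactileSNN", "TactileSNNResults"]


class TactileSNN:
    """Spiking tactile-localization model.

    Parameters
    ----------
    records : list of IndentationRecord
        Training stimuli (synthetic or imported).
    architecture : str
        One of SF_DIR, SC_BIO, SC_BIO_NOINH, SC_BIO_FB, SC_BIO_COMBINED.
    grid : OutputGrid, optional
        Somatotopic output lattice (default 12 x 9 over the default skin).
    n_interneurons : int
        Interneuron pool size for the SC_BIO family (before the
        energy-level schedule is applied).
    energy_level : float
        Energy-constraint level in [0, 1]; 0 is unconstrained.
    """

    def __init__(
        self,
        records: list[IndentationRecord],
        architecture: str = "SF_DIR",
        grid: OutputGrid | None = None,
        encoder: EncoderParams | None = None,
        neuron_params: NeuronParams | None = None,
        background: BackgroundInputParams | None = None,
        trainer: TrainerParams | None = None,
        decoder: decoding.DecoderParams | None = None,
        n_interneurons: int = 40,
        energy_level: float = 0.0,
    ):
        if not records:
            raise ValueError("records must be nonempty")
        self.records = records
        self.architecture = architecture
        self.grid = grid or OutputGrid()
        self.geometry = self.grid.geometry
        self.encoder = encoder or EncoderParams()
        self.neuron_params = neuron_params or NeuronParams()
        self.background = background or BackgroundInputParams()
        self.trainer = training.apply_energy_level(trainer or TrainerParams(), energy_level)
        self.decoder = decoder or decoding.DecoderParams()
        self.energy_level = energy_level
        n_sensors = records[0].n_channels
        n_in = 2 * n_sensors
        n_out = self.grid.n_neurons
        if architecture in ("SC_BIO", "SC_BIO_FB", "SC_BIO_COMBINED"):
            n_int = training.interneuron_count(
                n_interneurons, energy_level, self.trainer.inter_min_frac
            )
            self.layer_sizes: tuple[int, ...] = (n_in, n_int, n_out)
        else:
            self.layer_sizes = (n_in, n_out)

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, contacts: list[np.ndarray], **kwargs
    ) -> "TactileSNN":
        """Build from a long-format table (trial, t_ms, ch01..ch21).

        ``contacts[i]`` is the (n_c, 2) array of true (theta, z) for trial
        i; forces are reconstructed as on during the trace support.
        """
        from .skin import Contact

        records = []
        for tid, g in frame.groupby("trial"):
            t = g["t_ms"].to_numpy(dtype=float)
            chans = [c for c in g.columns if c.startswith("ch")]
            dl = g[chans].to_numpy(dtype=float)
            on = (np.abs(dl).sum(axis=1) > 0).astype(float)
            cs = [Contact(float(p[0]), float(p[1]), on) for p in np.atleast_2d(contacts[int(tid)])]
            records.append(IndentationRecord(t, dl, cs, trial_id=int(tid)))
        return cls(records, **kwargs)

    def build_spec(self, seed: int = 0) -> NetworkSpec:
        return build_architecture(
            self.architecture,
            self.layer_sizes,
            seed=seed,
            neuron_params=self.neuron_params,
            background=self.background,
        )

    def fit(
        self,
        seed: int = 0,
        epochs: int | None = None,
        progress: bool = False,
        initial_spec: NetworkSpec | None = None,
    ) -> "TactileSNNResults":
        """Train the network; returns a results object."""
        params = self.trainer if epochs is None else training.TrainerParams(
            **{**vars(self.trainer), "epochs": epochs}
        )
        spec = initial_spec or self.build_spec(seed)
        trained, history = training.train(
            self.records, spec, self.grid, params, self.encoder,
            seed=seed, progress=progress,
        )
        return TactileSNNResults(self, trained, history, seed)


@dataclass
class TactileSNNResults:
    """Trained network plus evaluation and reporting helpers."""

    model: TactileSNN
    spec: NetworkSpec
    history: pd.DataFrame
    seed: int = 0
    _err_cache: dict = field(default_factory=dict, repr=False)

    # --- inference --------------------------------------------------------
    def simulate_record(self, record: IndentationRecord, seed: int | None = None):
        m = self.model
        duration = float(record.t_ms[-1] + (record.t_ms[1] - record.t_ms[0]))
        ext = encode(record.t_ms, record.delta_lambda, m.encoder, duration=duration)
        return simulate(self.spec, ext, duration, seed=self.seed if seed is None else seed)

    def decode_record(
        self, record: IndentationRecord, seed: int | None = None
    ) -> decoding.DecodeResult:
        """Encode, simulate and decode one record (single-touch pipeline)."""
        m = self.model
        sim = self.simulate_record(record, seed)
        out = sim.spikes.select(self.spec.layer_slice(self.spec.layer_names[-1]))
        truth = record.contact_positions()[0]
        t_on, _ = record.stimulation_window()
        return decoding.decode_single(out, m.grid, m.decoder, truth=truth, t_on=t_on)

    def decode_multi_record(self, record: IndentationRecord, seed: int | None = None) -> np.ndarray:
        """Multi-touch contact extraction from the hold-window activity."""
        m = self.model
        sim = self.simulate_record(record, seed)
        out = sim.spikes.select(self.spec.layer_slice(self.spec.layer_names[-1]))
        t_on, t_off = record.stimulation_window()
        act = out.rates(t_on, t_off)
        return decoding.decode_multi(act, m.grid, m.decoder)

    def localization_errors(self, records: list[IndentationRecord]) -> pd.DataFrame:
        """Per-trial localization errors and latencies on held-out records."""
        key = id(records)
        if key in self._err_cache:
            return self._err_cache[key]
        rows = []
        for i, rec in enumerate(records):
            res = self.decode_record(rec, seed=self.seed + 7919 * (i + 1))
            tp = rec.contact_positions()[0]
            rows.append(
                {"trial": rec.trial_id, "theta": tp[0], "z": tp[1],
                 "error_mm": res.error_mm, "latency_ms": res.latency_ms}
            )
        frame = pd.DataFrame(rows)
        self._err_cache[key] = frame
        return frame

    def median_error(
        self, records: list[IndentationRecord], block_size: float = 30.0, n_boot: int = 500
    ) -> tuple[float, float]:
        """Median localization error (mm) with blocked-bootstrap std."""
        frame = self.localization_errors(records)
        pos = frame[["theta", "z"]].to_numpy()
        return evaluation.blocked_bootstrap_median(
            frame["error_mm"].to_numpy(), pos, self.model.geometry,
            block_size, n_boot=n_boot, seed=self.seed,
        )

    def resting_activity(self, duration: float = 5000.0) -> float:
        """Total network rate (Hz) with no stimulus (background only)."""
        sim = simulate(self.spec, None, duration, seed=self.seed)
        return evaluation.activity_metrics(sim.spikes)

    # --- reporting --------------------------------------------------------
    def summary(self, test_records: list[IndentationRecord] | None = None) -> str:
        m = self.model
        lines = [
            "Spiking tactile localization results",
            "=" * 52,
            f"architecture:        {self.spec.tag}",
            f"layers:              {dict(self.spec.layer_sizes)}",
            f"output grid:         {m.grid.n_theta} x {m.grid.n_z}"
            f" ({m.grid.density:.2f} neurons/cm^2)",
            f"energy level:        {m.energy_level:.2f}",
            f"epochs:              {len(self.history)}",
            f"final epoch error:   {self.history['error'].iloc[-1]:.1f}",
            f"active rate:         {self.history['total_rate_active'].iloc[-1]:.0f} Hz",
            f"resting rate:        {self.history['total_rate_rest'].iloc[-1]:.0f} Hz",
        ]
        if test_records is not None:
            med, std = self.median_error(test_records)
            frame = self.localization_errors(test_records)
            lat = frame["latency_ms"].dropna()
            lines += [
                f"median error (test): {med:.2f} +/- {std:.2f} mm"
                f"  (n={len(test_records)}, blocked bootstrap)",
                f"sensor spacing:      {m.geometry.sensor_spacing():.1f} mm"
                f"  -> super-resolution x{m.geometry.sensor_spacing() / max(med, 1e-9):.1f}",
            ]
            if len(lat):
                lines.append(f"median latency:      {lat.median():.0f} ms")
        return "\n".join(lines)
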