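"""Run orchestration: full adaptive/static replica-exchange simulations.

A run alternates dynamics segments with neighbor swap attempts of alternating
parity, updates walker labels and visit histograms after every round, and (in
adaptive mode) periodically re-places the temperature ladder from the
accumulated fraction-cold profile.  All randomness flows from the single
configured seed, so runs are bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dynamics import DynamicsParams, ReplicaState, run_segment
from .errors import InvalidArgumentError, InvalidComparisonError
from .exchange import (
    ReplicaSet,
    SwapStats,
    WalkerLabel,
    attempt_swaps,
    exchange_rate_profile,
    record_visits,
    update_walker_labels,
)
from .ladder import (
    TemperatureLadder,
    VisitHistogram,
    adapt_temperatures,
    geometric_ladder,
)
from .models import (
    BeadStructure,
    double_well_model,
    go_bead_model,
    harmonic_model,
    ideal_helix,
)

__all__ = ["RunConfig", "RunResult", "ComparisonReport", "run_simulation",
           "compare_modes", "build_model"]

_LADDER_MODES = ("static", "adaptive")


def build_model(spec: dict):
    """Instantiate an energy model from a config mapping."""
    spec = dict(spec)
    kind = spec.pop("kind", None)
    if kind == "harmonic":
        return harmonic_model(k=spec.get("k", 1.0), dim=spec.get("dim", 1))
    if kind == "double_well":
        return double_well_model(
            barrier=spec.get("barrier", 5.0), x0=spec.get("x0", 1.0)
        )
    if kind == "go_bead":
        if "native_pdb" in spec:
            native = BeadStructure.from_pdb(spec["native_pdb"])
        elif "native_xyz" in spec:
            native = BeadStructure.from_xyz(spec["native_xyz"])
        else:
            native = ideal_helix(spec.get("helix_n_res", 20))
        return go_bead_model(
            native,
            contact_cutoff=spec.get("contact_cutoff", 6.5),
            eps=spec.get("eps", 1.0),
            bond_k=spec.get("bond_k", 100.0),
            repulsion_sigma=spec.get("repulsion_sigma", 4.0),
        )
    raise InvalidArgumentError(f"unknown model kind {kind!r}")


@dataclass
class RunConfig:
    """Full parameterization of one replica-exchange run."""

    model: dict
    t_min: float
    t_max: float
    n_replicas: int
    seed: int
    total_rounds: int
    ladder_mode: str = "static"
    steps_per_swap: int = 500
    dt: float = 0.002
    gamma: float = 1.0
    lam: float = 1.0
    t_l: float = 1.0
    masses: float = 1.0
    kb: float = 1.0
    adapt_interval: int = 100
    min_extreme_visits: int = 10
    reset_hist_on_adapt: bool = False
    rescale_momenta: bool = True
    trace_stride: int = 1
    record_exchange_log: bool = False
    outdir: str | None = None

    def __post_init__(self):
        if self.ladder_mode not in _LADDER_MODES:
            raise InvalidArgumentError(f"ladder_mode must be one of {_LADDER_MODES}")
        if self.seed is None:
            raise InvalidArgumentError("seed is mandatory")
        if self.total_rounds < 1 or self.steps_per_swap < 1:
            raise InvalidArgumentError("total_rounds and steps_per_swap must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("outdir")
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()
        ).hexdigest()[:16]

    def dynamics_params(self) -> DynamicsParams:
        return DynamicsParams(
            dt=self.dt, gamma=self.gamma, lam=self.lam, t_l=self.t_l,
            masses=self.masses, kb=self.kb,
        )


@dataclass
class RunResult:
    """In-memory artifacts of one run; `write` mirrors them to disk as CSV/JSON."""

    config: RunConfig
    ladder: TemperatureLadder
    ladder_history: list
    stats: SwapStats
    hist: VisitHistogram
    state: ReplicaState
    energy_cold: np.ndarray
    occupancy_steps: np.ndarray
    occupancy: np.ndarray
    label_trace: np.ndarray
    exchange_log: pd.DataFrame | None = None

    @property
    def round_trips(self) -> np.ndarray:
        return self.stats.round_trips

    @property
    def exchange_rates(self) -> np.ndarray:
        return exchange_rate_profile(self.stats)

    def occupancy_frame(self) -> pd.DataFrame:
        steps = np.repeat(self.occupancy_steps, self.config.n_replicas)
        reps = np.tile(np.arange(self.config.n_replicas), self.occupancy_steps.size)
        return pd.DataFrame(
            {
                "step": steps,
                "replica_id": reps,
                "window_index": self.occupancy.reshape(-1),
                "label": self.label_trace.reshape(-1),
            }
        )

    def summary(self) -> dict:
        return {
            "seed": self.config.seed,
            "config_hash": self.config.config_hash(),
            "ladder_mode": self.config.ladder_mode,
            "total_rounds": self.config.total_rounds,
            "round_trips": self.stats.round_trips.tolist(),
            "mean_round_trips": float(self.stats.round_trips.mean()),
            "exchange_rates": [None if np.isnan(v) else float(v)
                               for v in self.exchange_rates],
            "final_ladder": self.ladder.temps.tolist(),
            "n_ladder_updates": len(self.ladder_history) - 1,
        }

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(self.config.to_dict(), fh)
        self.ladder.to_csv(out / "ladder.csv")
        hist_rows = []
        for rnd, temps in self.ladder_history:
            for i, t in enumerate(temps):
                hist_rows.append((rnd, i, t))
        pd.DataFrame(
            hist_rows, columns=["round", "index", "temperature_K"]
        ).to_csv(out / "ladder_history.csv", index=False)
        self.hist.to_csv(out / "histogram.csv")
        pd.DataFrame(
            {
                "pair_low_index": np.arange(self.config.n_replicas - 1),
                "attempts": self.stats.attempts,
                "accepts": self.stats.accepts,
                "rate": self.exchange_rates,
            }
        ).to_csv(out / "exchange_stats.csv", index=False)
        pd.DataFrame(
            {"round": np.arange(self.energy_cold.size),
             "cold_window_energy": self.energy_cold}
        ).to_csv(out / "energy.csv", index=False)
        if self.occupancy_steps.size:
            self.occupancy_frame().to_csv(out / "occupancy.csv", index=False)
        if self.exchange_log is not None:
            self.exchange_log.to_csv(out / "exchange_log.csv", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(self.summary(), fh, indent=2)
        with open(out / "run.log", "a") as fh:
            fh.write(
                f"{time.strftime('%Y-%m-%dT%H:%M:%S')} run complete "
                f"seed={self.config.seed} hash={self.config.config_hash()}\n"
            )


def _initial_coords(model, config: RunConfig) -> np.ndarray:
    kind = config.model.get("kind")
    if kind == "double_well":
        x0 = config.model.get("x0", 1.0)
        return np.full((config.n_replicas, 1), -x0)
    if kind == "go_bead":
        return np.tile(model.native.coords.reshape(-1), (config.n_replicas, 1))
    return np.zeros((config.n_replicas, model.dim))


def run_simulation(config: RunConfig) -> RunResult:
    """Execute one full static or adaptive replica-exchange run."""
    rng = np.random.default_rng(config.seed)
    model = build_model(config.model)
    ladder = geometric_ladder(config.t_min, config.t_max, config.n_replicas)
    params = config.dynamics_params()
    n = config.n_replicas

    rep = ReplicaSet(ladder=ladder, kb=config.kb)
    stats = SwapStats.zeros(n)
    hist = VisitHistogram(temps=ladder.temps.copy())
    state = ReplicaState(x=_initial_coords(model, config),
                         p=np.zeros((n, model.dim)))

    ladder_history = [(0, ladder.temps.copy())]
    energy_cold = np.empty(config.total_rounds)
    occ_steps, occ_rows, lab_rows = [], [], []
    log_rows = [] if config.record_exchange_log else None
    label_codes = {WalkerLabel.UNLABELED: "u", WalkerLabel.COLD: "c",
                   WalkerLabel.HOT: "h"}

    adaptation_started = False
    for rnd in range(config.total_rounds):
        temps_of_replica = rep.ladder.temps[rep.window_of]
        state, seg = run_segment(
            state, model, temps_of_replica, params, config.steps_per_swap, rng
        )
        e_window = np.empty(n)
        e_window[rep.window_of] = seg.final_energy

        old_temps = temps_of_replica
        rep, round_log = attempt_swaps(rep, e_window, rnd % 2, rng, stats)
        if config.rescale_momenta:
            new_temps = rep.ladder.temps[rep.window_of]
            changed = new_temps != old_temps
            if changed.any():
                state.p[changed] *= np.sqrt(
                    new_temps[changed] / old_temps[changed]
                )[:, None]
        if log_rows is not None:
            for w, pr, acc in zip(round_log.pairs, round_log.probs,
                                  round_log.accepted):
                log_rows.append((rnd, int(w), int(acc), float(pr)))

        update_walker_labels(rep, stats)
        record_visits(rep, hist)
        energy_cold[rnd] = seg.final_energy[rep.replica_in[0]]

        if config.trace_stride and (rnd % config.trace_stride == 0):
            occ_steps.append(rnd)
            occ_rows.append(rep.window_of.copy())
            lab_rows.append([label_codes[l] for l in rep.labels])

        if (
            config.ladder_mode == "adaptive"
            and (rnd + 1) % config.adapt_interval == 0
        ):
            if not adaptation_started:
                adaptation_started = (
                    hist.total[0] >= config.min_extreme_visits
                    and hist.total[-1] >= config.min_extreme_visits
                )
            if adaptation_started:
                new_ladder = adapt_temperatures(rep.ladder, hist)
                rep.ladder = new_ladder
                hist.temps = new_ladder.temps.copy()
                if config.reset_hist_on_adapt:
                    hist.n_cold[:] = 0
                    hist.n_hot[:] = 0
                ladder_history.append((rnd + 1, new_ladder.temps.copy()))

    result = RunResult(
        config=config,
        ladder=rep.ladder,
        ladder_history=ladder_history,
        stats=stats,
        hist=hist,
        state=state,
        energy_cold=energy_cold,
        occupancy_steps=np.asarray(occ_steps, dtype=np.int64),
        occupancy=(np.asarray(occ_rows, dtype=np.int64)
                   if occ_rows else np.empty((0, n), dtype=np.int64)),
        label_trace=(np.asarray(lab_rows, dtype=object)
                     if lab_rows else np.empty((0, n), dtype=object)),
        exchange_log=(
            pd.DataFrame(log_rows,
                         columns=["step", "pair_low_index", "accepted_flag", "prob"])
            if log_rows is not None else None
        ),
    )
    if config.outdir is not None:
        result.write(config.outdir)
    return result


_COMPARE_IGNORED = {"ladder_mode", "seed", "outdir", "trace_stride",
                    "record_exchange_log"}


@dataclass(frozen=True)
class ComparisonReport:
    """Paired adaptive-vs-static comparison over a common set of seeds."""

    seeds: tuple
    round_trips_adaptive: np.ndarray   # (n_seeds,) mean per replica
    round_trips_static: np.ndarray
    rates_adaptive: np.ndarray         # (n_seeds, n-1)
    rates_static: np.ndarray
    final_ladders_adaptive: list
    ladder_static: np.ndarray
    cold_energy_adaptive: np.ndarray = None  # (n_seeds,) mean cold-window E
    cold_energy_static: np.ndarray = None

    def to_frame(self) -> pd.DataFrame:
        def mean_se(v):
            v = np.asarray(v, dtype=float)
            se = v.std(ddof=1) / np.sqrt(v.size) if v.size > 1 else np.nan
            return float(v.mean()), float(se)

        ma, sa = mean_se(self.round_trips_adaptive)
        ms, ss = mean_se(self.round_trips_static)
        return pd.DataFrame(
            {
                "mode": ["adaptive", "static"],
                "mean_round_trips_per_replica": [ma, ms],
                "se_round_trips": [sa, ss],
                "mean_exchange_rate": [
                    float(np.nanmean(self.rates_adaptive)),
                    float(np.nanmean(self.rates_static)),
                ],
                "mean_cold_window_energy": [
                    float(np.mean(self.cold_energy_adaptive))
                    if self.cold_energy_adaptive is not None else np.nan,
                    float(np.mean(self.cold_energy_static))
                    if self.cold_energy_static is not None else np.nan,
                ],
                "n_seeds": [len(self.seeds)] * 2,
            }
        )


def compare_modes(
    config_adaptive: RunConfig, config_static: RunConfig, seeds
) -> ComparisonReport:
    """Run both ladder modes over shared seeds and summarize round-trip flow."""
    if config_adaptive.ladder_mode != "adaptive" or config_static.ladder_mode != "static":
        raise InvalidComparisonError("configs must be one adaptive, one static")
    da = {k: v for k, v in config_adaptive.to_dict().items()
          if k not in _COMPARE_IGNORED}
    ds = {k: v for k, v in config_static.to_dict().items()
          if k not in _COMPARE_IGNORED}
    if da != ds:
        diff = {k for k in da if da[k] != ds[k]}
        raise InvalidComparisonError(f"configs differ beyond mode/seed: {diff}")

    rt_a, rt_s, rates_a, rates_s, ladders_a = [], [], [], [], []
    ce_a, ce_s = [], []
    ladder_s = None
    for seed in seeds:
        ra = run_simulation(_with(config_adaptive, seed))
        rs = run_simulation(_with(config_static, seed))
        rt_a.append(ra.stats.round_trips.mean())
        rt_s.append(rs.stats.round_trips.mean())
        rates_a.append(ra.exchange_rates)
        rates_s.append(rs.exchange_rates)
        ce_a.append(ra.energy_cold.mean())
        ce_s.append(rs.energy_cold.mean())
        ladders_a.append(ra.ladder.temps)
        ladder_s = rs.ladder.temps
    return ComparisonReport(
        seeds=tuple(seeds),
        round_trips_adaptive=np.asarray(rt_a),
        round_trips_static=np.asarray(rt_s),
        rates_adaptive=np.asarray(rates_a),
        rates_static=np.asarray(rates_s),
        final_ladders_adaptive=ladders_a,
        ladder_static=ladder_s,
        cold_energy_adaptive=np.asarray(ce_a),
        cold_energy_static=np.asarray(ce_s),
    )


def _with(config: RunConfig, seed: int) -> RunConfig:
    d = config.to_dict()
    d["seed"] = int(seed)
    d["outdir"] = None
    d["trace_stride"] = 0
    return RunConfig.from_dict(d)
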