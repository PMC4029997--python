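"""Rank-ordering, landscape analytics and score-table aggregation.

Includes the packaged benchmark score grid (top-scoring and top-16-mean
fraction-of-native-contacts values per target x sampling method x scoring
function) and the marginal averages computed over it.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import IncompleteTableError, InvalidArgumentError
from .ladder import TemperatureLadder

__all__ = [
    "METHODS",
    "FUNCTIONS",
    "ScoreTable",
    "AggregateResult",
    "LandscapeGrid",
    "load_benchmark_scores",
    "aggregate_score_table",
    "rank_and_select",
    "population_density",
    "extract_cold_ensemble",
    "temperature_profile_snapshots",
    "running_average",
]

METHODS = ("adaptive", "static")
FUNCTIONS = ("FF", "GOAP", "dDFIRE", "RWplus")

_COLUMNS = ("target", "method", "function", "top_fn", "mean16_fn")


@dataclass(frozen=True)
class ScoreTable:
    """Grid of f_N scores over (target, sampling method, scoring function)."""

    frame: pd.DataFrame

    def __post_init__(self):
        missing_cols = set(_COLUMNS) - set(self.frame.columns)
        if missing_cols:
            raise InvalidArgumentError(f"score table missing columns {missing_cols}")
        for col in ("top_fn", "mean16_fn"):
            vals = self.frame[col].to_numpy(dtype=float)
            if np.any((vals < 0.0) | (vals > 1.0)):
                raise InvalidArgumentError(f"{col} values must lie in [0, 1]")

    @property
    def targets(self) -> tuple:
        return tuple(pd.unique(self.frame["target"]))

    @classmethod
    def from_csv(cls, path) -> "ScoreTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def load_benchmark_scores() -> ScoreTable:
    """Packaged fixture: the published per-target score grid (64 cells)."""
    ref = importlib.resources.files("adaptrex.data") / "benchmark_scores.csv"
    with importlib.resources.as_file(ref) as path:
        return ScoreTable.from_csv(path)


@dataclass(frozen=True)
class AggregateResult:
    mean_raw: float
    mean_rounded: float
    n_cells: int


def aggregate_score_table(
    table: ScoreTable,
    method: str | None = None,
    function: str | None = None,
    column: str = "top_fn",
) -> AggregateResult:
    """Marginal mean of a score column over the selected method/function cells.

    With ``method`` only, averages that method's cells over all functions and
    targets; with ``function`` only, pools both methods; with both, a single
    within-method function margin.  The rounded mean uses 2 decimals, the
    table's printed precision; the raw mean is reported alongside.
    """
    if column not in ("top_fn", "mean16_fn"):
        raise InvalidArgumentError(f"unknown score column {column!r}")
    df = table.frame
    methods = [method] if method is not None else list(METHODS)
    functions = [function] if function is not None else list(FUNCTIONS)

    sel = df[df["method"].isin(methods) & df["function"].isin(functions)]
    expected = {
        (t, m, f) for t in table.targets for m in methods for f in functions
    }
    present = set(zip(sel["target"], sel["method"], sel["function"]))
    missing = expected - present
    if missing:
        raise IncompleteTableError(sorted(missing))

    values = sel[column].to_numpy(dtype=float)
    mean = float(values.mean())
    return AggregateResult(
        mean_raw=mean, mean_rounded=round(mean, 2), n_cells=int(values.size)
    )


def rank_and_select(
    scores, fn_values, k: int, ids=None
) -> tuple[list, float]:
    """Stable top-k selection by score (lower = better; ties broken by id).

    Returns the selected conformer ids and the mean f_N over the selection.
    """
    scores = np.asarray(scores, dtype=float)
    fn_values = np.asarray(fn_values, dtype=float)
    n = scores.size
    if fn_values.size != n:
        raise InvalidArgumentError("scores and f_N values must align")
    if not 1 <= k <= n:
        raise InvalidArgumentError(f"k={k} out of range for {n} conformers")
    ids = list(range(n)) if ids is None else list(ids)
    order = sorted(range(n), key=lambda i: (scores[i], ids[i]))
    top = order[:k]
    return [ids[i] for i in top], float(fn_values[top].mean())


@dataclass(frozen=True)
class LandscapeGrid:
    """2D population-density histogram over (dE from minimum, f_N)."""

    log_density: np.ndarray
    counts: np.ndarray
    e_edges: np.ndarray
    fn_edges: np.ndarray

    @property
    def total_count(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: one row per bin with edges, count, log-density."""
        ei, fi = np.meshgrid(
            np.arange(self.counts.shape[0]), np.arange(self.counts.shape[1]),
            indexing="ij",
        )
        return pd.DataFrame(
            {
                "de_low": self.e_edges[ei.ravel()],
                "de_high": self.e_edges[ei.ravel() + 1],
                "fn_low": self.fn_edges[fi.ravel()],
                "fn_high": self.fn_edges[fi.ravel() + 1],
                "count": self.counts.ravel(),
                "log_density": self.log_density.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def population_density(energies, fn_values, bins=50) -> LandscapeGrid:
    """Histogram conformers over (E - min E, f_N) with log(count + 1) density."""
    energies = np.asarray(energies, dtype=float)
    fn_values = np.asarray(fn_values, dtype=float)
    if energies.size == 0 or fn_values.size != energies.size:
        raise InvalidArgumentError("need equal-length, non-empty inputs")
    de = energies - energies.min()
    e_hi = max(float(de.max()), 1e-12)
    fn_lo, fn_hi = float(fn_values.min()), float(fn_values.max())
    if fn_hi <= fn_lo:
        fn_lo, fn_hi = fn_lo - 0.5, fn_lo + 0.5
    counts, e_edges, fn_edges = np.histogram2d(
        de, fn_values, bins=bins, range=[[0.0, e_hi], [fn_lo, fn_hi]]
    )
    return LandscapeGrid(
        log_density=np.log(counts + 1.0),
        counts=counts,
        e_edges=e_edges,
        fn_edges=fn_edges,
    )


def extract_cold_ensemble(trace: pd.DataFrame, frames) -> pd.DataFrame:
    """Replica occupying the coldest window at each requested frame.

    ``trace`` has columns (step, replica_id, window_index); exactly one
    replica holds window 0 per step.
    """
    frames = list(frames)
    cold = trace[trace["window_index"] == 0]
    by_step = cold.set_index("step")["replica_id"]
    missing = [f for f in frames if f not in by_step.index]
    if missing:
        raise InvalidArgumentError(f"frames not covered by trace: {missing[:5]}")
    picked = by_step.loc[frames]
    if isinstance(picked, pd.Series) and picked.index.has_duplicates:
        dup = picked.index[picked.index.duplicated()][:5]
        raise InvalidArgumentError(f"multiple cold replicas at steps {list(dup)}")
    return pd.DataFrame({"frame": frames, "replica_id": np.asarray(picked)})


def temperature_profile_snapshots(history, times) -> list:
    """Ladder in effect at each requested time (last record at time <= t)."""
    if not history:
        raise InvalidArgumentError("empty ladder history")
    records = sorted(history, key=lambda rec: rec[0])
    rec_times = np.array([rec[0] for rec in records], dtype=float)
    out = []
    for t in times:
        k = int(np.searchsorted(rec_times, t, side="right")) - 1
        if k < 0:
            raise InvalidArgumentError(f"time {t} precedes first record {rec_times[0]}")
        ladder = records[k][1]
        out.append(ladder if isinstance(ladder, TemperatureLadder)
                   else TemperatureLadder(ladder))
    return out


def running_average(values, window: int = 150) -> np.ndarray:
    """Trailing running mean for time-series plots (default 150-frame window)."""
    values = np.asarray(values, dtype=float)
    if window < 1:
        raise InvalidArgumentError("window must be >= 1")
    out = np.empty_like(values)
    c = np.concatenate([[0.0], np.cumsum(values)])
    for i in range(values.size):
        lo = max(0, i - window + 1)
        out[i] = (c[i + 1] - c[lo]) / (i + 1 - lo)
    return out
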