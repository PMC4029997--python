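"""Metropolis temperature swaps, walker labeling and round-trip accounting.

Replicas keep their configurations; an accepted swap exchanges the
temperature-window assignments of a neighboring pair.  Each replica is
labeled cold or hot by the last temperature extreme it visited, and a full
round trip is one excursion T_min -> T_max -> T_min.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError
from .ladder import TemperatureLadder, VisitHistogram

__all__ = [
    "WalkerLabel",
    "SwapStats",
    "SwapRound",
    "ReplicaSet",
    "swap_probability",
    "attempt_swaps",
    "update_walker_labels",
    "record_visits",
    "exchange_rate_profile",
]


class WalkerLabel(enum.Enum):
    UNLABELED = 0
    COLD = 1
    HOT = 2


@dataclass
class SwapStats:
    """Per-pair attempt/accept counters and per-replica round-trip counts."""

    attempts: np.ndarray
    accepts: np.ndarray
    round_trips: np.ndarray

    @classmethod
    def zeros(cls, n: int) -> "SwapStats":
        return cls(
            attempts=np.zeros(n - 1, dtype=np.int64),
            accepts=np.zeros(n - 1, dtype=np.int64),
            round_trips=np.zeros(n, dtype=np.int64),
        )

    def validate(self) -> None:
        if (self.accepts > self.attempts).any():
            raise InvalidArgumentError("accepts cannot exceed attempts")
        if (self.attempts < 0).any() or (self.round_trips < 0).any():
            raise InvalidArgumentError("counts must be nonnegative")


@dataclass(frozen=True)
class SwapRound:
    """Log of a single swap round: which pairs were tried and what happened."""

    pairs: np.ndarray      # low window index of each attempted pair
    probs: np.ndarray
    accepted: np.ndarray   # bool


@dataclass
class ReplicaSet:
    """Assignment of replicas to temperature windows.

    ``window_of[r]`` is the window occupied by replica ``r``; it is a
    permutation of 0..n-1 at all times.  ``labels`` travel with replicas.
    ``replicas`` (dynamic states) are optional: the exchange machinery only
    needs the permutation.
    """

    ladder: TemperatureLadder
    window_of: np.ndarray = None
    labels: list = None
    kb: float = 1.0
    replicas: list = None

    def __post_init__(self):
        n = self.ladder.n
        if self.window_of is None:
            self.window_of = np.arange(n, dtype=np.int64)
        self.window_of = np.asarray(self.window_of, dtype=np.int64)
        if self.labels is None:
            self.labels = [WalkerLabel.UNLABELED] * n
        self.check_bijection()

    @property
    def n(self) -> int:
        return self.ladder.n

    @property
    def replica_in(self) -> np.ndarray:
        """Inverse permutation: replica occupying each window."""
        inv = np.empty(self.n, dtype=np.int64)
        inv[self.window_of] = np.arange(self.n)
        return inv

    def check_bijection(self) -> None:
        if not np.array_equal(np.sort(self.window_of), np.arange(self.n)):
            raise InvalidArgumentError("window assignment is not a bijection")


def swap_probability(beta_a: float, beta_b: float, e_a: float, e_b: float) -> float:
    """Metropolis acceptance min(1, exp[(beta_a - beta_b)(E_a - E_b)])."""
    if beta_a <= 0.0 or beta_b <= 0.0:
        raise InvalidArgumentError("inverse temperatures must be positive")
    arg = (beta_a - beta_b) * (e_a - e_b)
    if arg >= 0.0:
        return 1.0
    return float(np.exp(arg))


def attempt_swaps(
    rep: ReplicaSet,
    energies: np.ndarray,
    parity: int,
    rng: np.random.Generator,
    stats: SwapStats | None = None,
) -> tuple[ReplicaSet, SwapRound]:
    """Attempt Metropolis swaps on disjoint neighbor pairs of one parity.

    ``energies[w]`` is the instantaneous potential energy of the configuration
    currently in window ``w``.  Even parity tries pairs (0,1), (2,3), ...;
    odd parity tries (1,2), (3,4), ...  Accepted swaps exchange the two
    replicas' window assignments in place.  If ``stats`` is given, its
    attempt/accept counters are updated.
    """
    if parity not in (0, 1):
        raise InvalidArgumentError("parity must be 0 (even) or 1 (odd)")
    n = rep.n
    temps = rep.ladder.temps
    inv_kb = 1.0 / rep.kb
    replica_in = rep.replica_in
    pairs = []
    probs = []
    accepted = []
    for w in range(parity, n - 1, 2):
        beta_a = inv_kb / temps[w]
        beta_b = inv_kb / temps[w + 1]
        p = swap_probability(beta_a, beta_b, float(energies[w]), float(energies[w + 1]))
        acc = rng.random() < p
        pairs.append(w)
        probs.append(p)
        accepted.append(acc)
        if stats is not None:
            stats.attempts[w] += 1
            if acc:
                stats.accepts[w] += 1
        if acc:
            ra, rb = replica_in[w], replica_in[w + 1]
            rep.window_of[ra] = w + 1
            rep.window_of[rb] = w
            replica_in[w], replica_in[w + 1] = rb, ra
    return rep, SwapRound(
        pairs=np.asarray(pairs, dtype=np.int64),
        probs=np.asarray(probs, dtype=float),
        accepted=np.asarray(accepted, dtype=bool),
    )


def update_walker_labels(rep: ReplicaSet, stats: SwapStats) -> tuple[list, SwapStats]:
    """Refresh cold/hot labels from window extremes; count completed round trips.

    A replica reaching window 0 while labeled hot has completed one full
    round trip T_min -> T_max -> T_min; its counter is incremented and it is
    relabeled cold.  Reaching window n-1 labels it hot.  Labels never revert
    to unlabeled.
    """
    n = rep.n
    for r in range(n):
        w = rep.window_of[r]
        if w == 0:
            if rep.labels[r] is WalkerLabel.HOT:
                stats.round_trips[r] += 1
            rep.labels[r] = WalkerLabel.COLD
        elif w == n - 1:
            rep.labels[r] = WalkerLabel.HOT
    return rep.labels, stats


def record_visits(rep: ReplicaSet, hist: VisitHistogram) -> VisitHistogram:
    """Accumulate one visit per labeled replica into its current window."""
    for r in range(rep.n):
        label = rep.labels[r]
        if label is WalkerLabel.COLD:
            hist.n_cold[rep.window_of[r]] += 1
        elif label is WalkerLabel.HOT:
            hist.n_hot[rep.window_of[r]] += 1
    return hist


def exchange_rate_profile(stats: SwapStats) -> np.ndarray:
    """Acceptance fraction per neighbor pair; NaN where nothing was attempted."""
    attempts = stats.attempts.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = np.where(attempts > 0, stats.accepts / np.where(attempts > 0, attempts, 1.0), np.nan)
    return rates
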