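"""Temperature ladders and feedback-driven re-placement of replica temperatures.

A ladder is the ordered set of temperatures occupied by the replica clients.
Static ladders are geometric.  Adaptive ladders are periodically re-placed so
that the fraction of cold-labeled walkers visiting each window becomes linear
in the window index, which concentrates temperatures near sharp energetic
transitions while a spacing constraint prevents full collapse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    InfeasibleConstraintError,
    InsufficientDataError,
    InvalidArgumentError,
)

__all__ = [
    "TemperatureLadder",
    "VisitHistogram",
    "FractionProfile",
    "geometric_ladder",
    "spacing_ratio",
    "fraction_cold",
    "target_fraction",
    "interpolate_inverse",
    "enforce_spacing_constraint",
    "adapt_temperatures",
]

# Minimum log-spacing between adapted neighbors; keeps ladders strictly
# increasing when the inverted profile produces ties (e.g. step profiles).
_MIN_LOG_GAP = 1e-9


@dataclass(frozen=True)
class TemperatureLadder:
    """Ordered, strictly increasing client temperatures.

    Parameters
    ----------
    temps
        Strictly increasing temperatures.  ``temps[0]`` and ``temps[-1]`` are
        the ladder bounds; units are kelvin or reduced (k_B = 1) units.
    """

    temps: np.ndarray

    def __post_init__(self):
        temps = np.asarray(self.temps, dtype=float)
        object.__setattr__(self, "temps", temps)
        if temps.ndim != 1 or temps.size < 2:
            raise InvalidArgumentError("ladder needs at least 2 temperatures")
        if temps[0] <= 0.0:
            raise InvalidArgumentError("temperatures must be positive")
        if not np.all(np.diff(temps) > 0.0):
            raise InvalidArgumentError("temperatures must be strictly increasing")

    @property
    def n(self) -> int:
        return int(self.temps.size)

    @property
    def t_min(self) -> float:
        return float(self.temps[0])

    @property
    def t_max(self) -> float:
        return float(self.temps[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"index": np.arange(self.n), "temperature_K": self.temps}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TemperatureLadder":
        df = pd.read_csv(path)
        return cls(df["temperature_K"].to_numpy(dtype=float))


@dataclass
class VisitHistogram:
    """Per-window cold/hot visit accumulators.

    ``temps`` carries the window temperatures current at accumulation time;
    counts are indexed by window, so temps may be refreshed after the ladder
    is re-placed while the counts persist.
    """

    temps: np.ndarray
    n_cold: np.ndarray = None
    n_hot: np.ndarray = None

    def __post_init__(self):
        self.temps = np.asarray(self.temps, dtype=float)
        n = self.temps.size
        if self.n_cold is None:
            self.n_cold = np.zeros(n, dtype=np.int64)
        if self.n_hot is None:
            self.n_hot = np.zeros(n, dtype=np.int64)
        self.n_cold = np.asarray(self.n_cold, dtype=np.int64)
        self.n_hot = np.asarray(self.n_hot, dtype=np.int64)
        if self.n_cold.size != n or self.n_hot.size != n:
            raise InvalidArgumentError("histogram lengths must match window count")
        if (self.n_cold < 0).any() or (self.n_hot < 0).any():
            raise InvalidArgumentError("visit counts must be nonnegative")

    @property
    def n(self) -> int:
        return int(self.temps.size)

    @property
    def total(self) -> np.ndarray:
        return self.n_cold + self.n_hot

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": np.arange(self.n),
                "temperature_K": self.temps,
                "n_cold": self.n_cold,
                "n_hot": self.n_hot,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "VisitHistogram":
        df = pd.read_csv(path)
        return cls(
            temps=df["temperature_K"].to_numpy(dtype=float),
            n_cold=df["n_cold"].to_numpy(dtype=np.int64),
            n_hot=df["n_hot"].to_numpy(dtype=np.int64),
        )


@dataclass(frozen=True)
class FractionProfile:
    """Fraction-cold values per window; NaN marks windows with no visits."""

    temps: np.ndarray
    f: np.ndarray

    def __post_init__(self):
        temps = np.asarray(self.temps, dtype=float)
        f = np.asarray(self.f, dtype=float)
        object.__setattr__(self, "temps", temps)
        object.__setattr__(self, "f", f)
        if temps.shape != f.shape:
            raise InvalidArgumentError("profile temps/f shape mismatch")
        defined = f[np.isfinite(f)]
        if ((defined < 0.0) | (defined > 1.0)).any():
            raise InvalidArgumentError("defined fractions must lie in [0, 1]")

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.f)

    @property
    def n_defined(self) -> int:
        return int(self.defined.sum())


def geometric_ladder(t_min: float, t_max: float, n: int) -> TemperatureLadder:
    """Build a geometric ladder of ``n`` temperatures spanning [t_min, t_max].

    ``temps[i] = t_min * (t_max / t_min) ** (i / (n - 1))``; the endpoints are
    set exactly to the requested bounds.
    """
    if n < 2:
        raise InvalidArgumentError(f"need at least 2 clients, got {n}")
    if t_min <= 0.0 or t_max <= t_min:
        raise InvalidArgumentError(
            f"require t_max > t_min > 0, got t_min={t_min}, t_max={t_max}"
        )
    i = np.arange(n, dtype=float)
    temps = t_min * (t_max / t_min) ** (i / (n - 1))
    temps[0] = t_min
    temps[-1] = t_max
    return TemperatureLadder(temps)


def spacing_ratio(ladder: TemperatureLadder) -> float:
    """Geometric spacing unit r = (t_max / t_min) ** (1 / (n - 1))."""
    return float((ladder.t_max / ladder.t_min) ** (1.0 / (ladder.n - 1)))


def fraction_cold(hist: VisitHistogram) -> FractionProfile:
    """f[i] = n_cold[i] / (n_cold[i] + n_hot[i]); empty windows become NaN."""
    total = hist.total.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(total > 0, hist.n_cold / np.where(total > 0, total, 1.0), np.nan)
    return FractionProfile(temps=hist.temps.copy(), f=f)


def target_fraction(i: int, n: int) -> float:
    """Index-linear target fraction: 1 at the cold end, 0 at the hot end."""
    if not 0 <= i <= n - 1:
        raise InvalidArgumentError(f"window index {i} out of range for n={n}")
    return 1.0 - i / (n - 1)


def _pava_nonincreasing(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators fit of a nonincreasing sequence (unit weights)."""
    vals: list[float] = []
    wts: list[float] = []
    sizes: list[int] = []
    for v in y:
        vals.append(float(v))
        wts.append(1.0)
        sizes.append(1)
        # merge while the tail violates monotone decrease
        while len(vals) > 1 and vals[-2] < vals[-1]:
            w = wts[-1] + wts[-2]
            merged = (vals[-1] * wts[-1] + vals[-2] * wts[-2]) / w
            vals.pop()
            wts.pop()
            s = sizes.pop()
            vals[-1] = merged
            wts[-1] = w
            sizes[-1] += s
    return np.repeat(vals, sizes)


def interpolate_inverse(profile: FractionProfile, target: float) -> float:
    """Temperature at which the regressed fraction-cold profile equals target.

    The defined profile entries are first made nonincreasing in temperature by
    isotonic (decreasing) regression, then inverted by piecewise-linear
    interpolation.  On flat segments the smallest matching temperature is
    returned; targets outside the regressed range clamp to the profile bounds.
    """
    if not 0.0 <= target <= 1.0:
        raise InvalidArgumentError(f"target fraction {target} outside [0, 1]")
    mask = profile.defined
    if mask.sum() < 2:
        raise InsufficientDataError(
            f"need >= 2 defined profile entries, have {int(mask.sum())}"
        )
    temps = profile.temps[mask]
    g = _pava_nonincreasing(profile.f[mask])
    if target >= g[0]:
        return float(temps[0])
    if target < g[-1]:
        return float(temps[-1])
    for k in range(len(g) - 1):
        if g[k] > target >= g[k + 1]:
            frac = (g[k] - target) / (g[k] - g[k + 1])
            return float(temps[k] + frac * (temps[k + 1] - temps[k]))
    return float(temps[-1])  # pragma: no cover - unreachable for valid g


def enforce_spacing_constraint(
    temps, r: float, t_min: float, t_max: float
) -> np.ndarray:
    """Project temperatures onto the max-spacing constraint T[i+1]/T[i] <= r**2.

    Performed in log space: a forward sweep lowers any temperature more than
    two geometric spacing units above its predecessor, then (after pinning the
    hot endpoint) a backward sweep raises any temperature more than two units
    below its successor.  A tiny minimum log-gap keeps the output strictly
    increasing.  Endpoints come out exactly t_min and t_max.
    """
    temps = np.asarray(temps, dtype=float)
    n = temps.size
    if n < 2:
        raise InvalidArgumentError("need at least 2 temperatures")
    if r <= 1.0:
        raise InvalidArgumentError(f"spacing ratio must exceed 1, got {r}")
    a = np.log(t_min)
    b = np.log(t_max)
    c = 2.0 * np.log(r)
    if b - a > (n - 1) * c * (1.0 + 1e-12):
        raise InfeasibleConstraintError(
            f"span {t_max / t_min:.6g} exceeds r^(2(n-1)) = {r ** (2 * (n - 1)):.6g}"
        )
    gap = min(_MIN_LOG_GAP, (b - a) / (n - 1) * 1e-3)

    u = np.log(np.clip(temps, t_min, t_max))
    u[0] = a
    for i in range(1, n):
        u[i] = min(max(u[i], u[i - 1] + gap), u[i - 1] + c)
    u[-1] = b
    for i in range(n - 2, 0, -1):
        u[i] = min(max(u[i], u[i + 1] - c), u[i + 1] - gap)
    out = np.exp(u)
    out[0] = t_min
    out[-1] = t_max
    return out


def adapt_temperatures(
    ladder: TemperatureLadder, hist: VisitHistogram
) -> TemperatureLadder:
    """Re-place ladder temperatures from the fraction-cold feedback profile.

    New interior temperatures are the inversions of the regressed profile at
    the index-linear targets; the endpoints stay at the ladder bounds and the
    result is projected onto the two-geometric-units spacing constraint.
    """
    n = ladder.n
    if hist.n != n:
        raise InvalidArgumentError("histogram window count must match ladder")
    profile = FractionProfile(temps=ladder.temps, f=fraction_cold(hist).f)
    if hist.total[0] == 0 or hist.total[-1] == 0:
        raise InsufficientDataError("both endpoint windows must have visits")
    if profile.n_defined < 2:
        raise InsufficientDataError("need >= 2 visited windows")

    new = np.empty(n)
    new[0] = ladder.t_min
    new[-1] = ladder.t_max
    for i in range(1, n - 1):
        new[i] = interpolate_inverse(profile, target_fraction(i, n))
    r = spacing_ratio(ladder)  # depends only on the fixed bounds and n
    projected = enforce_spacing_constraint(new, r, ladder.t_min, ladder.t_max)
    return TemperatureLadder(projected)
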