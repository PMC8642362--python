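"""Non-uniform sampling (NUS) schedule generators and gap statistics.

A schedule is a subset of the Nyquist grid ``{0, 1, ..., n-1}`` of evolution
times of an indirect NMR dimension (0-based grid indices; one per line in the
plain-text schedule file).  The generators implemented here are

* unweighted random sampling (uniform without replacement),
* weighted random sampling (density proportional to user weights, e.g. the
  reciprocal quarter-sine density that matches the sensitivity of
  sine-modulated Poisson-gap sampling),
* Poisson-gap (PG) sampling, where the number of *skipped* grid points
  between consecutive samples is Poisson distributed with a rate that may be
  modulated along the grid (quarter-sine, half-sine or exponential), in 1D
  and — via an anti-diagonal "add" walk — on 2D grids.

Every generated schedule contains grid index 0 (or the pair ``(0, 0)``),
because the first increment of an NMR experiment is always measured, and
never repeats a point.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Grid",
    "GapModulation",
    "Schedule",
    "GapHistogram",
    "EnsembleStats",
    "draw_poisson",
    "generate_poisson_gap",
    "generate_poisson_gap_2d",
    "generate_random",
    "reciprocal_quarter_sine_weights",
    "gap_sizes",
    "ensemble_stats",
    "write_schedule",
    "read_schedule",
    "make_schedule",
    "SCHEMES",
]

_MODULATION_KINDS = ("none", "quarter_sine", "half_sine", "exponential")

# Rates are clamped below this so a modulation zero (e.g. quarter-sine at
# t = 0) never stalls the Poisson-gap walk.
_MIN_RATE_FACTOR = 1e-6


class ScheduleError(ValueError):
    """Invalid schedule parameters or malformed schedule text."""


@dataclass(frozen=True)
class Grid:
    """Nyquist grid of an indirect dimension: ``shape=(n,)`` or ``(n1, n2)``."""

    shape: tuple[int, ...]

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        object.__setattr__(self, "shape", shape)
        if len(shape) not in (1, 2):
            raise ScheduleError(f"grid must be 1D or 2D, got shape {shape}")
        if any(s < 2 for s in shape):
            raise ScheduleError(f"grid needs >= 2 points per dimension, got {shape}")

    @property
    def dims(self) -> int:
        return len(self.shape)

    @property
    def size(self) -> int:
        """Total number of grid points."""
        return int(np.prod(self.shape))

    @property
    def t_max(self) -> tuple[int, ...]:
        """Largest grid index per dimension (n - 1)."""
        return tuple(s - 1 for s in self.shape)


@dataclass(frozen=True)
class GapModulation:
    """Gap-size modulation f(t) in (0, 1] applied to the Poisson rate.

    ``quarter_sine`` is sin(pi/2 * t/t_max) (dense sampling of the early
    signal), ``half_sine`` is sin(pi * t/t_max) (dense at both ends, suited
    to amplitude-modulated clustered signals), ``exponential`` is
    exp((t - t_max)/tau) with ``tau`` in grid-index units (default t_max/2):
    the gap grows exponentially along the grid, producing the classical
    exponentially decaying sampling density, normalized so f(t_max) = 1.
    """

    kind: str = "none"
    tau: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in _MODULATION_KINDS:
            raise ScheduleError(
                f"unknown modulation {self.kind!r}; expected one of {_MODULATION_KINDS}"
            )
        if self.tau is not None and self.tau <= 0:
            raise ScheduleError("exponential modulation tau must be positive")

    def profile(self, t_max: int) -> np.ndarray:
        """Evaluate f on t = 0..t_max, clamped below to avoid zero rates."""
        t = np.arange(t_max + 1, dtype=float)
        if self.kind == "none":
            f = np.ones_like(t)
        elif self.kind == "quarter_sine":
            f = np.sin(0.5 * np.pi * t / t_max)
        elif self.kind == "half_sine":
            f = np.sin(np.pi * t / t_max)
        else:  # exponential
            tau = self.tau if self.tau is not None else t_max / 2.0
            f = np.exp((t - t_max) / tau)
        return np.maximum(f, _MIN_RATE_FACTOR)


@dataclass(frozen=True)
class Schedule:
    """A sorted, duplicate-free set of sampled grid indices.

    1D indices are ints; 2D indices are ``(t1, t2)`` pairs.  ``seed``,
    ``generator_tag`` and ``modulation_tag`` record provenance.
    """

    grid: Grid
    indices: tuple
    seed: int | None = None
    generator_tag: str = ""
    modulation_tag: str = ""

    def __post_init__(self) -> None:
        idx = tuple(
            tuple(int(v) for v in i) if isinstance(i, (tuple, list, np.ndarray)) else int(i)
            for i in self.indices
        )
        idx = tuple(sorted(idx))
        object.__setattr__(self, "indices", idx)
        if len(idx) == 0:
            raise ScheduleError("schedule must contain at least one point")
        if len(set(idx)) != len(idx):
            raise ScheduleError("schedule contains repeated sampling points")
        if self.grid.dims == 1:
            if any(isinstance(i, tuple) for i in idx):
                raise ScheduleError("1D grid but 2D indices supplied")
            n = self.grid.shape[0]
            if idx[0] < 0 or idx[-1] >= n:
                raise ScheduleError(f"indices out of range [0, {n})")
        else:
            n1, n2 = self.grid.shape
            for pair in idx:
                if not isinstance(pair, tuple) or len(pair) != 2:
                    raise ScheduleError("2D grid requires (t1, t2) index pairs")
                if not (0 <= pair[0] < n1 and 0 <= pair[1] < n2):
                    raise ScheduleError(f"index pair {pair} out of range {self.grid.shape}")

    @property
    def m(self) -> int:
        """Number of sampled points."""
        return len(self.indices)

    @property
    def n(self) -> int:
        return self.grid.size

    def indicator(self) -> np.ndarray:
        """0/1 indicator of sampled points on the (flattened) grid."""
        ind = np.zeros(self.grid.shape, dtype=float)
        if self.grid.dims == 1:
            ind[list(self.indices)] = 1.0
        else:
            for t1, t2 in self.indices:
                ind[t1, t2] = 1.0
        return ind

    def index_array(self) -> np.ndarray:
        return np.asarray(self.indices, dtype=int)


@dataclass
class GapHistogram:
    """Pooled histogram of gap sizes g = skipped points between samples."""

    counts: np.ndarray
    n_schedules: int
    sampling_level: float

    @property
    def frequencies(self) -> np.ndarray:
        total = self.counts.sum()
        return self.counts / total if total else self.counts.astype(float)


@dataclass
class EnsembleStats:
    """Pooled gap histogram plus per-index selection counts of an ensemble."""

    histogram: GapHistogram
    selection_counts: np.ndarray


def draw_poisson(lam: float, rng: np.random.Generator) -> int:
    """Draw from Pois(lam) by Knuth's multiplicative algorithm.

    Multiplies uniforms until the product drops below exp(-lam); the number
    of factors minus one is the draw.  Exact for any lam >= 0 (O(lam) time).
    """
    if lam < 0:
        raise ScheduleError(f"Poisson rate must be nonnegative, got {lam}")
    if lam == 0:
        return 0
    limit = math.exp(-lam)
    k = 0
    p = rng.random()
    while p > limit:
        p *= rng.random()
        k += 1
    return k


class _UniformStream:
    """Buffered uniforms from one Generator (amortizes scalar-draw overhead)."""

    __slots__ = ("_rng", "_buf", "_pos", "_size")

    def __init__(self, rng: np.random.Generator, size: int = 8192) -> None:
        self._rng = rng
        self._size = size
        self._buf = rng.random(size).tolist()
        self._pos = 0

    def next(self) -> float:
        if self._pos >= len(self._buf):
            self._buf = self._rng.random(self._size).tolist()
            self._pos = 0
        u = self._buf[self._pos]
        self._pos += 1
        return u


def _poisson_stream(limit: float, stream: _UniformStream) -> int:
    # Knuth's algorithm on the buffered stream; `limit` is exp(-lam).
    if limit >= 1.0:
        return 0
    k = 0
    p = stream.next()
    while p > limit:
        p *= stream.next()
        k += 1
    return k


def _pg_walk(limits: Sequence[float], n: int, stream: _UniformStream) -> list[int]:
    """One PG walk: record t, jump by 1 + Pois(c*f(t)), until the grid ends."""
    pts: list[int] = []
    t = 0
    while t < n:
        pts.append(t)
        t += 1 + _poisson_stream(limits[t], stream)
    return pts


def generate_poisson_gap(
    grid: Grid,
    m: int,
    modulation: GapModulation | str = "none",
    seed: int = 0,
    max_attempts: int = 200,
) -> Schedule:
    """Generate a 1D Poisson-gap schedule with exactly ``m`` points.

    The walk starts at t = 0, records the point, then skips
    g ~ Pois(c * f(t)) grid points, repeating until the grid is exhausted.
    The rate scale c starts at (n-m)/m / mean(f) and after each walk is
    multiplied by achieved/m, redrawing from the seeded stream, until a walk
    yields exactly m points (at most ``max_attempts`` walks).
    """
    if isinstance(modulation, str):
        modulation = GapModulation(kind=modulation)
    if grid.dims != 1:
        raise ScheduleError("use generate_poisson_gap_2d for 2D grids")
    n = grid.shape[0]
    if not 1 <= m <= n:
        raise ScheduleError(f"m={m} must satisfy 1 <= m <= n={n}")

    f = modulation.profile(n - 1)
    mean_f = float(f.mean())
    c = (n - m) / m / mean_f

    rng = np.random.default_rng(seed)
    stream = _UniformStream(rng)
    for _ in range(max_attempts):
        limits = np.exp(-c * f).tolist()
        pts = _pg_walk(limits, n, stream)
        achieved = len(pts)
        if achieved == m:
            return Schedule(
                grid=grid,
                indices=tuple(pts),
                seed=seed,
                generator_tag="poisson_gap",
                modulation_tag=modulation.kind,
            )
        c = max(c * achieved / m, 1e-12) if achieved else c * 0.5
    raise ScheduleError(
        f"Poisson-gap calibration failed after {max_attempts} attempts "
        f"(n={n}, m={m}, modulation={modulation.kind}, seed={seed})"
    )


def _antidiagonal_cells(n1: int, n2: int) -> tuple[np.ndarray, np.ndarray]:
    """All 2D cells ordered along anti-diagonals s = t1 + t2; returns (cells, s)."""
    cells = []
    for s in range(n1 + n2 - 1):
        for t1 in range(max(0, s - n2 + 1), min(n1 - 1, s) + 1):
            cells.append((t1, s - t1))
    arr = np.asarray(cells, dtype=int)
    return arr, arr.sum(axis=1)


def generate_poisson_gap_2d(
    grid: Grid,
    m: int,
    modulation: GapModulation | str = "none",
    seed: int = 0,
    max_attempts: int = 200,
) -> Schedule:
    """Poisson-gap schedule on a 2D grid via an anti-diagonal walk.

    The grid is traversed along successive anti-diagonals s = t1 + t2 and a
    1D PG walk is performed over that ordering with the rate modulated by
    f(s / (t1_max + t2_max)), so the sampling density decays with s for
    decaying modulations.  This approximates the "add" strategy used for 3D
    NMR schedule generation; only the density-versus-s behaviour is part of
    the contract.  ``(0, 0)`` is always included.
    """
    if isinstance(modulation, str):
        modulation = GapModulation(kind=modulation)
    if grid.dims != 2:
        raise ScheduleError("generate_poisson_gap_2d requires a 2D grid")
    n1, n2 = grid.shape
    total = n1 * n2
    if not 1 <= m <= total:
        raise ScheduleError(f"m={m} must satisfy 1 <= m <= n1*n2={total}")

    cells, s_of_cell = _antidiagonal_cells(n1, n2)
    s_max = (n1 - 1) + (n2 - 1)
    f_of_s = modulation.profile(s_max)
    f = f_of_s[s_of_cell]
    mean_f = float(f.mean())
    c = (total - m) / m / mean_f

    rng = np.random.default_rng(seed)
    stream = _UniformStream(rng)
    for _ in range(max_attempts):
        limits = np.exp(-c * f).tolist()
        pts = _pg_walk(limits, total, stream)
        if len(pts) == m:
            chosen = cells[pts]
            return Schedule(
                grid=grid,
                indices=tuple(map(tuple, chosen)),
                seed=seed,
                generator_tag="poisson_gap_2d",
                modulation_tag=modulation.kind,
            )
        c = max(c * len(pts) / m, 1e-12) if pts else c * 0.5
    raise ScheduleError(
        f"2D Poisson-gap calibration failed after {max_attempts} attempts "
        f"(grid={grid.shape}, m={m}, modulation={modulation.kind}, seed={seed})"
    )


def reciprocal_quarter_sine_weights(n: int) -> np.ndarray:
    """Density weights 1/sin(pi/2 * t/t_max) for t >= 1 (entry 0 unused).

    Weighted random sampling with these weights matches the sampling density
    of quarter-sine-modulated Poisson-gap schedules, hence the time-domain
    sensitivity, without the inter-point distance restriction.
    """
    t = np.arange(n, dtype=float)
    w = np.zeros(n)
    w[1:] = 1.0 / np.sin(0.5 * np.pi * t[1:] / (n - 1))
    return w


def generate_random(
    grid: Grid,
    m: int,
    weights: np.ndarray | None = None,
    seed: int = 0,
) -> Schedule:
    """Random schedule: index 0 plus m-1 draws without replacement.

    ``weights`` (length n; entry 0 is ignored because index 0 is always
    included) sets the selection probability of indices 1..n-1; uniform if
    omitted.
    """
    if grid.dims != 1:
        raise ScheduleError("generate_random supports 1D grids")
    n = grid.shape[0]
    if not 1 <= m <= n:
        raise ScheduleError(f"m={m} must satisfy 1 <= m <= n={n}")
    rng = np.random.default_rng(seed)
    if m == 1:
        chosen: list[int] = []
    elif weights is None:
        chosen = list(rng.choice(np.arange(1, n), size=m - 1, replace=False))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,):
            raise ScheduleError(f"weights must have length n={n}")
        w = w.copy()
        w[0] = 0.0
        if np.any(w < 0) or not np.all(np.isfinite(w)):
            raise ScheduleError("weights must be finite and nonnegative")
        if np.count_nonzero(w > 0) < m - 1:
            raise ScheduleError(f"need at least {m - 1} strictly positive weights")
        chosen = list(rng.choice(np.arange(n), size=m - 1, replace=False, p=w / w.sum()))
    return Schedule(
        grid=grid,
        indices=(0, *chosen),
        seed=seed,
        generator_tag="random" if weights is None else "random_weighted",
    )


def gap_sizes(schedule: Schedule) -> np.ndarray:
    """Number of skipped grid points between consecutive samples (1D)."""
    if schedule.grid.dims != 1:
        raise ScheduleError("gap sizes are defined for 1D schedules")
    if schedule.m < 2:
        raise ScheduleError("need at least two points to form gaps")
    return np.diff(schedule.index_array()) - 1


def ensemble_stats(schedules: Iterable[Schedule]) -> EnsembleStats:
    """Pool gap histograms and per-index selection counts over an ensemble."""
    schedules = list(schedules)
    if not schedules:
        raise ScheduleError("empty schedule ensemble")
    grid = schedules[0].grid
    m = schedules[0].m
    for s in schedules[1:]:
        if s.grid != grid or s.m != m:
            raise ScheduleError("ensemble schedules must share grid and m")
    if grid.dims != 1:
        raise ScheduleError("ensemble_stats supports 1D schedules")
    n = grid.shape[0]
    counts = np.zeros(n, dtype=int)
    gap_counts = np.zeros(n, dtype=int)  # gap can be at most n-2
    for s in schedules:
        counts[s.index_array()] += 1
        if s.m >= 2:
            np.add.at(gap_counts, gap_sizes(s), 1)
    last = int(np.max(np.nonzero(gap_counts)[0])) if gap_counts.any() else 0
    hist = GapHistogram(
        counts=gap_counts[: last + 1],
        n_schedules=len(schedules),
        sampling_level=m / n,
    )
    return EnsembleStats(histogram=hist, selection_counts=counts)


def write_schedule(schedule: Schedule) -> str:
    """Serialize to plain text: one index per line (two columns for 2D)."""
    if schedule.grid.dims == 1:
        return "".join(f"{i}\n" for i in schedule.indices)
    return "".join(f"{t1} {t2}\n" for t1, t2 in schedule.indices)


def read_schedule(text: str, grid: Grid) -> Schedule:
    """Parse schedule text; indices are normalized to sorted order.

    Raises on duplicates, out-of-range indices or malformed lines, naming
    the offending line number.
    """
    indices: list = []
    seen = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != grid.dims:
            raise ScheduleError(
                f"line {lineno}: expected {grid.dims} column(s), got {len(parts)}"
            )
        try:
            vals = tuple(int(p) for p in parts)
        except ValueError as exc:
            raise ScheduleError(f"line {lineno}: non-integer index") from exc
        key = vals if grid.dims == 2 else vals[0]
        if key in seen:
            raise ScheduleError(f"line {lineno}: duplicate index {key}")
        for dim, v in enumerate(vals):
            if not 0 <= v < grid.shape[dim]:
                raise ScheduleError(f"line {lineno}: index {v} out of range")
        seen.add(key)
        indices.append(key)
    if not indices:
        raise ScheduleError("schedule text contains no indices")
    return Schedule(grid=grid, indices=tuple(indices), generator_tag="file")


#: Scheme tags covering the six generators compared throughout the package.
SCHEMES = (
    "pg-none",
    "pg-quarter-sine",
    "pg-half-sine",
    "pg-exponential",
    "random-uniform",
    "random-weighted",
)

_BLUE_NOISE_SCHEMES = ("pg-none", "pg-quarter-sine", "pg-half-sine", "pg-exponential")


def is_blue_noise(scheme: str) -> bool:
    return scheme in _BLUE_NOISE_SCHEMES


def make_schedule(scheme: str, grid: Grid, m: int, seed: int = 0) -> Schedule:
    """Generate a schedule by scheme tag (see ``SCHEMES``)."""
    if scheme == "pg-none":
        return generate_poisson_gap(grid, m, "none", seed)
    if scheme == "pg-quarter-sine":
        return generate_poisson_gap(grid, m, "quarter_sine", seed)
    if scheme == "pg-half-sine":
        return generate_poisson_gap(grid, m, "half_sine", seed)
    if scheme == "pg-exponential":
        return generate_poisson_gap(grid, m, "exponential", seed)
    if scheme == "random-uniform":
        return generate_random(grid, m, seed=seed)
    if scheme == "random-weighted":
        n = grid.shape[0]
        return generate_random(grid, m, weights=reciprocal_quarter_sine_weights(n), seed=seed)
    raise ScheduleError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
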