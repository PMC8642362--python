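"""Synthetic FIDs, benchmark scenarios, and synthetic peak-table fixtures.

The benchmark signals are sums of complex exponentials

    s(t) = sum_c A_c * exp(2*pi*i * f_c * t / n) * exp(-R_c * t),  t = 0..n-1

with optional circular complex Gaussian noise.  The standard benchmark
scenario has five components with amplitudes 1:2:3:4:5 that are either
spread evenly across the band or packed into a narrow cluster, and either
non-decaying (strictly sparse, single-bin peaks — the constant-time case) or
decaying (Lorentzian peaks).  Clustered spectra produce amplitude-modulated
("beating") time signals: two peaks separated by d bins modulate |s(t)| as
|cos(pi*d*t/n)|, and a dense cluster of q adjacent peaks gives the Dirichlet
envelope |sin(q*delta*t/2)/sin(delta*t/2)|, delta = 2*pi/n, with maxima at
the start and end of the record — the reason gap-restricted sampling helps.

Peak tables emulate protein chemical-shift datasets: entries with peaks
grouped into direct-dimension columns whose indirect shifts scatter with a
controllable standard deviation, feeding the clustering statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schedules import Schedule

__all__ = [
    "SpectralComponent",
    "SyntheticSignal",
    "ClusterSpec",
    "synth_fid",
    "spectrum",
    "sample_signal",
    "make_scenario",
    "SCENARIOS",
    "synth_peak_table",
]


@dataclass(frozen=True)
class SpectralComponent:
    """One resonance: grid frequency in [0, n), amplitude, per-sample decay."""

    freq_index: float
    amplitude: float
    decay: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be nonnegative")
        if self.decay < 0:
            raise ValueError("decay rate must be nonnegative")


@dataclass
class SyntheticSignal:
    """Complex FID with its ground-truth components and noise level."""

    samples: np.ndarray
    components: tuple[SpectralComponent, ...]
    n: int
    noise_sigma: float = 0.0
    seed: int | None = None

    def spectrum(self) -> np.ndarray:
        return spectrum(self.samples)


@dataclass(frozen=True)
class ClusterSpec:
    """Cluster geometry: window width (grid bins), center index, layout."""

    width: int = 16
    center: int | None = None
    layout: str = "clustered"

    def __post_init__(self) -> None:
        if self.layout not in ("clustered", "spread"):
            raise ValueError("layout must be 'clustered' or 'spread'")


def spectrum(samples: np.ndarray) -> np.ndarray:
    """Unitary discrete FT (1/sqrt(n) normalization, e^{-2 pi i} kernel).

    A noiseless non-decaying component at integer frequency f appears as a
    single bin of height amplitude * sqrt(n); the convention matches the
    measurement matrix in :mod:`nusclust.psf`.
    """
    samples = np.asarray(samples)
    return np.fft.fft(samples, axis=-1) / np.sqrt(samples.shape[-1])


def synth_fid(
    components: tuple[SpectralComponent, ...] | list[SpectralComponent],
    n: int,
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> SyntheticSignal:
    """Synthesize a complex FID from spectral components plus optional noise.

    Noise is circular complex Gaussian with standard deviation
    ``noise_sigma`` per real/imaginary part (mean noise power 2*sigma^2 per
    sample).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    components = tuple(components)
    if not components:
        raise ValueError("at least one component required")
    t = np.arange(n, dtype=float)
    s = np.zeros(n, dtype=complex)
    for c in components:
        s += c.amplitude * np.exp(2j * np.pi * c.freq_index * t / n - c.decay * t)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        s = s + noise_sigma * (rng.standard_normal(n) + 1j * rng.standard_normal(n))
    return SyntheticSignal(
        samples=s, components=components, n=n, noise_sigma=noise_sigma, seed=seed
    )


def sample_signal(signal: SyntheticSignal, schedule: Schedule) -> np.ndarray:
    """Measured values y: the FID at the schedule's grid indices."""
    if schedule.grid.dims != 1:
        raise ValueError("sample_signal expects a 1D schedule")
    if schedule.grid.shape[0] != signal.n:
        raise ValueError("schedule grid does not match the signal length")
    return signal.samples[schedule.index_array()]


#: Benchmark scenario tags: {spread, clustered} x {sparse, lorentzian}.
SCENARIOS = (
    "spread_sparse",
    "clustered_sparse",
    "clustered_lorentzian",
    "spread_lorentzian",
)

#: Amplitude ladder shared by all benchmark scenarios.
_AMPLITUDES = (1.0, 2.0, 3.0, 4.0, 5.0)


def make_scenario(
    kind: str,
    n: int = 256,
    cluster: ClusterSpec | None = None,
    decay_at_tmax: float = 2.0,
) -> tuple[SpectralComponent, ...]:
    """Five-component benchmark scenarios with amplitudes 1:2:3:4:5.

    Spread layouts place the components at bins floor(n/10)*(1,3,5,7,9);
    clustered layouts space them evenly inside a ``cluster.width``-bin
    window around ``cluster.center`` (default n/2).  Lorentzian variants add
    a decay such that the envelope falls to exp(-decay_at_tmax) at the last
    sample; sparse variants do not decay.
    """
    if kind not in SCENARIOS:
        raise ValueError(f"unknown scenario {kind!r}; expected one of {SCENARIOS}")
    if n < 16:
        raise ValueError("n must be >= 16")
    cluster = cluster or ClusterSpec()
    n_comp = len(_AMPLITUDES)
    if kind.startswith("spread"):
        freqs = [(n // 10) * j for j in (1, 3, 5, 7, 9)]
    else:
        width = cluster.width
        if width < n_comp:
            raise ValueError(f"cluster width {width} cannot hold {n_comp} components")
        center = cluster.center if cluster.center is not None else n // 2
        start = center - width // 2
        freqs = [start + round(j * (width - 1) / (n_comp - 1)) for j in range(n_comp)]
    decay = decay_at_tmax / (n - 1) if kind.endswith("lorentzian") else 0.0
    return tuple(
        SpectralComponent(freq_index=float(f), amplitude=a, decay=decay)
        for f, a in zip(freqs, _AMPLITUDES)
    )


def synth_peak_table(
    n_entries: int,
    m_indirect: int,
    clustering_sigma_ppm: float | tuple[float, ...],
    ranges: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    columns_per_entry: int = 30,
    peaks_per_column: int = 5,
    direct_bin_ppm: float = 0.02,
) -> pd.DataFrame:
    """Synthetic peak table emulating per-protein chemical-shift datasets.

    Each entry gets ``columns_per_entry`` direct-dimension positions placed
    at the centers of distinct ``direct_bin_ppm``-wide bins (each
    cross-section is a separate column, so downstream binning never merges
    two generated columns); each column holds ``peaks_per_column`` peaks
    whose indirect shifts are Normal(column center, clustering_sigma_ppm)
    per indirect dimension.  Only the statistical structure consumed by the
    clustering statistic is emulated, not chemical-shift chemistry.

    Returns a DataFrame with columns
    ``entry_id, direct_ppm, indirect1_ppm[, indirect2_ppm]``.
    """
    if m_indirect not in (1, 2):
        raise ValueError("number of indirect dimensions must be 1 or 2")
    if ranges is None:
        ranges = {"direct": (6.0, 10.0), "indirect": (100.0, 135.0)}
    lo_d, hi_d = ranges["direct"]
    lo_i, hi_i = ranges["indirect"]
    if not (hi_d > lo_d and hi_i > lo_i):
        raise ValueError("ranges must be nonempty intervals")
    sigmas = (
        tuple(clustering_sigma_ppm)
        if isinstance(clustering_sigma_ppm, (tuple, list))
        else (float(clustering_sigma_ppm),) * m_indirect
    )
    if len(sigmas) != m_indirect or any(s < 0 for s in sigmas):
        raise ValueError("need one nonnegative sigma per indirect dimension")

    n_direct_bins = int((hi_d - lo_d) / direct_bin_ppm)
    if columns_per_entry > n_direct_bins:
        raise ValueError(
            f"direct range holds only {n_direct_bins} bins of {direct_bin_ppm} ppm"
        )
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    for e in range(n_entries):
        entry = f"synthetic_{e:05d}"
        bins = rng.choice(n_direct_bins, size=columns_per_entry, replace=False)
        direct = lo_d + (bins + 0.5) * direct_bin_ppm
        for j in range(columns_per_entry):
            centers = rng.uniform(lo_i, hi_i, size=m_indirect)
            for _ in range(peaks_per_column):
                row = {"entry_id": entry, "direct_ppm": float(direct[j])}
                for dim in range(m_indirect):
                    shift = rng.normal(centers[dim], sigmas[dim]) if sigmas[dim] else centers[dim]
                    row[f"indirect{dim + 1}_ppm"] = float(shift)
                rows.append(row)
    return pd.DataFrame(rows)
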