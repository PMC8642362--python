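"""Measurement-matrix diagnostics: point spread function, coherence, RIP.

The measurement matrix of a 1D NUS experiment is the partial inverse-Fourier
matrix ``A[j, k] = exp(2*pi*i * t_j * k / n) / sqrt(n)`` obtained by keeping
the rows of the full (unitary) FT matrix that correspond to the sampled
grid indices ``t_j`` (0-based).  Its rows are orthonormal, every column has
squared norm m/n, and all pairwise column correlations are encoded in the
point spread function (PSF) — the FT of the schedule's 0/1 indicator:

    PSF[k] = sum_j exp(-2*pi*i * t_j * k / n) / sqrt(n)
    a_k^H a_k' = PSF[(k - k') mod n] / sqrt(n)

so the coherence mu(A) = max_{k != k'} |a_k^H a_k'| is the largest PSF
sidelobe divided by sqrt(n).  Blue-noise schedules push PSF artifacts away
from the peak at k = 0 toward high frequencies, which is what makes them
effective for spectra whose peaks form clusters.
"""

from __future__ import annotations

from itertools import combinations
from collections.abc import Iterable

import numpy as np

from .schedules import Schedule

__all__ = [
    "measurement_matrix",
    "point_spread_function",
    "coherence",
    "coherence_bruteforce",
    "rip_constant",
    "rip_constant_sampled",
    "averaged_abs_psf",
]

# Brute-force RIP enumeration guard: C(24, 4) subsets is the practical limit.
_RIP_MAX_N = 24
_RIP_MAX_K = 4


def _indices_1d(schedule: Schedule) -> np.ndarray:
    if schedule.grid.dims != 1:
        raise ValueError("PSF/coherence diagnostics operate on 1D schedules")
    return schedule.index_array()


def measurement_matrix(schedule: Schedule) -> np.ndarray:
    """Materialize the m x n partial inverse-FT matrix (test/oracle path)."""
    idx = _indices_1d(schedule)
    n = schedule.grid.shape[0]
    k = np.arange(n)
    return np.exp(2j * np.pi * np.outer(idx, k) / n) / np.sqrt(n)


def point_spread_function(schedule: Schedule, n: int | None = None) -> np.ndarray:
    """PSF of a schedule: conjugate FT of its indicator, scaled by 1/sqrt(n).

    Computed via FFT in O(n log n); PSF[0] = m/sqrt(n) and, by Parseval of
    the 0/1 indicator, sum(|PSF|^2) = m.
    """
    idx = _indices_1d(schedule)
    if n is None:
        n = schedule.grid.shape[0]
    elif n != schedule.grid.shape[0]:
        raise ValueError("n must match the schedule grid")
    indicator = np.zeros(n)
    indicator[idx] = 1.0
    return np.fft.fft(indicator) / np.sqrt(n)


def coherence(schedule: Schedule, n: int | None = None) -> float:
    """Coherence mu(A) = max over distinct column pairs of |a_k^H a_k'|.

    Uses the PSF identity: mu(A) = max_{k >= 1} |PSF[k]| / sqrt(n).
    """
    psf = point_spread_function(schedule, n)
    n_ = psf.size
    return float(np.abs(psf[1:]).max() / np.sqrt(n_))


def coherence_bruteforce(schedule: Schedule) -> float:
    """Coherence from explicit pairwise column products (O(n^2 m) oracle)."""
    a = measurement_matrix(schedule)
    gram = a.conj().T @ a
    np.fill_diagonal(gram, 0.0)
    return float(np.abs(gram).max())


def rip_constant(schedule: Schedule, k_sparse: int) -> float:
    """Restricted isometry constant delta_K by exhaustive enumeration.

    delta_K = max over all K-column submatrices A_S of
    max(sigma_max(A_S)^2 - 1, 1 - sigma_min(A_S)^2).  Exact but exponential:
    guarded to n <= 24 and K <= 4; use :func:`rip_constant_sampled` (a lower
    bound) beyond that.
    """
    n = schedule.grid.shape[0]
    if k_sparse < 1:
        raise ValueError("sparsity level K must be >= 1")
    if n > _RIP_MAX_N or k_sparse > _RIP_MAX_K:
        raise ValueError(
            f"exhaustive RIP is limited to n <= {_RIP_MAX_N}, K <= {_RIP_MAX_K}; "
            "use rip_constant_sampled for a Monte-Carlo lower bound"
        )
    a = measurement_matrix(schedule)
    delta = 0.0
    for cols in combinations(range(n), k_sparse):
        s = np.linalg.svd(a[:, cols], compute_uv=False)
        delta = max(delta, s[0] ** 2 - 1.0, 1.0 - s[-1] ** 2)
    return float(delta)


def rip_constant_sampled(
    schedule: Schedule,
    k_sparse: int,
    n_subsets: int = 1000,
    seed: int = 0,
) -> float:
    """Monte-Carlo *lower bound* on delta_K from random column subsets."""
    n = schedule.grid.shape[0]
    a = measurement_matrix(schedule)
    rng = np.random.default_rng(seed)
    delta = 0.0
    for _ in range(n_subsets):
        cols = rng.choice(n, size=k_sparse, replace=False)
        s = np.linalg.svd(a[:, cols], compute_uv=False)
        delta = max(delta, s[0] ** 2 - 1.0, 1.0 - s[-1] ** 2)
    return float(delta)


def averaged_abs_psf(schedules: Iterable[Schedule], n: int | None = None) -> np.ndarray:
    """Elementwise mean of |PSF| over a schedule ensemble."""
    total = None
    count = 0
    for s in schedules:
        p = np.abs(point_spread_function(s, n))
        total = p if total is None else total + p
        count += 1
    if count == 0:
        raise ValueError("empty schedule ensemble")
    return total / count
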