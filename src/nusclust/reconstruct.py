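"""Spectrum reconstruction from NUS data: IST-D, an exact l1 oracle, residuals.

Reconstruction solves the compressed-sensing problem of recovering a sparse
spectrum x from m < n time-domain samples y taken at schedule indices.  The
workhorse is iterative soft thresholding with a decreasing threshold
(IST-D): each iteration Fourier-transforms the zero-filled residual of the
measured data, soft-thresholds it (shrinking complex moduli, preserving
phase) and *accumulates* the extracted portion into the spectrum estimate —
a CLEAN-like peeling scheme.  The threshold decays geometrically from a
fraction ``threshold_start`` of the initial zero-filled-spectrum maximum
down to ``threshold_end`` of it.  The decreasing threshold plays the role
of the sparsity-balancing constant of the penalized formulation; no
explicit penalty weight is used.

``basis_pursuit`` is the exact l1-minimization oracle
min ||z||_1 subject to A z = y, solved by Douglas-Rachford splitting.  The
affine projection is exact and cheap because the rows of the partial
inverse-FT matrix are orthonormal (A A^H = I), so each iteration costs two
FFTs.  A ``virtual_echo`` option reconstructs on the conjugate-symmetric
doubled grid, which makes the target spectrum real and sparser.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .schedules import Grid, Schedule

__all__ = [
    "NUSData",
    "ReconstructionConfig",
    "ReconstructionResult",
    "virtual_echo",
    "virtual_echo_data",
    "ist",
    "basis_pursuit",
    "residual",
]

_BP_GRID_LIMIT = 512
_IST_2D_LIMIT = 16384


@dataclass
class NUSData:
    """Measured NUS samples aligned with the schedule's indices."""

    schedule: Schedule
    y: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=complex)
        if self.y.shape != (self.schedule.m,):
            raise ValueError(
                f"y must have one value per schedule point ({self.schedule.m}), "
                f"got shape {self.y.shape}"
            )

    def zero_fill(self) -> np.ndarray:
        """Embed y on the full grid with zeros at unsampled points."""
        zf = np.zeros(self.schedule.grid.shape, dtype=complex)
        zf[_fancy(self.schedule)] = self.y
        return zf


@dataclass(frozen=True)
class ReconstructionConfig:
    """IST-D settings.

    ``iterations``: number of thresholding passes (default 200).
    ``threshold_start``/``threshold_end``: first and last threshold as
    fractions of max|FT(zero-filled data)|, interpolated geometrically.
    ``virtual_echo``: reconstruct on the conjugate-symmetric 2n grid.
    ``final_consistency``: after the last iteration, replace the estimate's
    time-domain values at sampled indices by the measured data.
    """

    iterations: int = 200
    threshold_start: float = 0.99
    threshold_end: float = 1e-6
    virtual_echo: bool = False
    final_consistency: bool = True

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not 0 < self.threshold_end <= self.threshold_start <= 1:
            raise ValueError("need 0 < threshold_end <= threshold_start <= 1")


@dataclass
class ReconstructionResult:
    """IST output: spectrum estimate plus the threshold trace."""

    spectrum: np.ndarray
    thresholds: np.ndarray
    grid_shape: tuple[int, ...]
    virtual_echo: bool = False


def _fancy(schedule: Schedule):
    """Index object selecting the schedule's points from a grid-shaped array."""
    idx = schedule.index_array()
    if schedule.grid.dims == 1:
        return idx
    return tuple(idx.T)


def _ft(signal: np.ndarray) -> np.ndarray:
    """Unitary forward FT (any dimensionality)."""
    return np.fft.fftn(signal) / np.sqrt(signal.size)


def _ift(spec: np.ndarray) -> np.ndarray:
    return np.fft.ifftn(spec) * np.sqrt(spec.size)


def _soft(z: np.ndarray, tau: float) -> np.ndarray:
    """Complex soft threshold: shrink moduli by tau, preserving phase."""
    mag = np.abs(z)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(mag > tau, 1.0 - tau / np.where(mag > 0, mag, 1.0), 0.0)
    return z * scale


def virtual_echo(samples: np.ndarray) -> np.ndarray:
    """Conjugate-symmetric extension of a length-n FID to length 2n.

    ve[t] = s(t) for t = 1..n-1, ve[2n-t] = conj(s(t)), and the first point
    is halved into its Hermitian average ve[0] = Re(s(0)) (ve[n] = 0).  The
    FT of the result is real, so the virtual-echo spectrum of a phased
    signal is sparser (pure absorption, no dispersive tails).
    """
    s = np.asarray(samples, dtype=complex)
    n = s.size
    ve = np.zeros(2 * n, dtype=complex)
    ve[0] = s[0].real
    ve[1:n] = s[1:]
    ve[2 * n - 1 : n : -1] = np.conj(s[1:])
    return ve


def virtual_echo_data(data: NUSData) -> NUSData:
    """Virtual-echo embedding of NUS data onto the doubled (2n) grid.

    A sampled index t > 0 contributes the pair {t, 2n - t} with values
    {s(t), conj(s(t))}; index 0 (always sampled) contributes Re(s(0)).
    """
    sched = data.schedule
    if sched.grid.dims != 1:
        raise ValueError("virtual echo is defined for 1D schedules")
    n = sched.grid.shape[0]
    idx = sched.index_array()
    ve_indices: list[int] = []
    ve_values: list[complex] = []
    for t, v in zip(idx, data.y):
        if t == 0:
            ve_indices.append(0)
            ve_values.append(v.real)
        else:
            ve_indices.extend([int(t), 2 * n - int(t)])
            ve_values.extend([v, np.conj(v)])
    ve_sched = Schedule(
        grid=Grid((2 * n,)),
        indices=tuple(ve_indices),
        seed=sched.seed,
        generator_tag=sched.generator_tag + "+ve",
        modulation_tag=sched.modulation_tag,
    )
    order = np.argsort(ve_indices)
    return NUSData(schedule=ve_sched, y=np.asarray(ve_values)[order])


def ist(data: NUSData, config: ReconstructionConfig | None = None) -> ReconstructionResult:
    """Reconstruct a spectrum from NUS data by IST with decreasing threshold.

    Iterates X <- X + SoftThreshold(FT(zero_fill(y - Sample(IFT(X)))), tau_i)
    with tau_i on a geometric grid: each pass extracts the above-threshold
    part of the residual spectrum and adds it to the accumulated estimate.
    Works on 1D schedules and (for small grids) 2D schedules with a 2D FT.
    """
    config = config or ReconstructionConfig()
    if config.virtual_echo:
        data = virtual_echo_data(data)
    sched = data.schedule
    if sched.grid.dims == 2 and sched.grid.size > _IST_2D_LIMIT:
        raise ValueError(f"2D IST is guarded to grids of <= {_IST_2D_LIMIT} points")

    sel = _fancy(sched)
    zf_spectrum = _ft(data.zero_fill())
    peak = float(np.abs(zf_spectrum).max())
    if peak == 0.0:
        return ReconstructionResult(
            spectrum=np.zeros_like(zf_spectrum),
            thresholds=np.zeros(config.iterations),
            grid_shape=sched.grid.shape,
            virtual_echo=config.virtual_echo,
        )
    if config.iterations == 1:
        taus = np.array([config.threshold_end * peak])
    else:
        taus = np.geomspace(
            config.threshold_start * peak, config.threshold_end * peak, config.iterations
        )

    x = np.zeros(sched.grid.shape, dtype=complex)
    resid_grid = np.zeros(sched.grid.shape, dtype=complex)
    for tau in taus:
        s_hat = _ift(x)
        resid_grid[sel] = data.y - s_hat[sel]
        x = x + _soft(_ft(resid_grid), tau)
    if config.final_consistency:
        s_hat = _ift(x)
        s_hat[sel] = data.y
        x = _ft(s_hat)
    return ReconstructionResult(
        spectrum=x,
        thresholds=taus,
        grid_shape=sched.grid.shape,
        virtual_echo=config.virtual_echo,
    )


def basis_pursuit(
    schedule: Schedule,
    y: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 6000,
    gamma: float | None = None,
) -> np.ndarray:
    """Exact l1 oracle: argmin ||z||_1 subject to A z = y.

    Solved by Douglas-Rachford splitting between the l1 prox (complex soft
    threshold) and the projection onto the affine constraint set, which is
    z - A^H(Az - y) and exact because A's rows are orthonormal.  Iterates
    until the fixed-point gap falls below ``tol`` (relative).  Guarded to
    grids of at most 512 points (the oracle is meant for small instances).
    """
    if schedule.grid.dims != 1:
        raise ValueError("basis_pursuit supports 1D schedules")
    n = schedule.grid.shape[0]
    if n > _BP_GRID_LIMIT:
        raise ValueError(f"basis_pursuit is guarded to n <= {_BP_GRID_LIMIT}")
    y = np.asarray(y, dtype=complex)
    if y.shape != (schedule.m,):
        raise ValueError("y must align with the schedule")
    idx = schedule.index_array()
    sqrt_n = np.sqrt(n)

    def project(z: np.ndarray) -> np.ndarray:
        # z - A^H (A z - y): exact affine projection via two FFTs
        s = np.fft.ifft(z) * sqrt_n
        corr = np.zeros(n, dtype=complex)
        corr[idx] = s[idx] - y
        return z - np.fft.fft(corr) / sqrt_n

    z0 = np.zeros(n, dtype=complex)
    z0[idx] = y  # zero-filled data
    x0 = np.fft.fft(z0) / sqrt_n  # A^H y
    scale = float(np.abs(x0).max())
    if scale == 0.0:
        return np.zeros(n, dtype=complex)
    if gamma is None:
        gamma = 0.1 * scale

    u = x0.copy()
    p = project(u)
    for _ in range(max_iter):
        v = _soft(2.0 * p - u, gamma)
        u += v - p
        p_new = project(u)
        gap = np.linalg.norm(p_new - p)
        p = p_new
        if gap <= tol * max(np.linalg.norm(p), 1e-30):
            break
    return p


def residual(
    recon: np.ndarray,
    reference: np.ndarray,
    mode: str = "global",
    peaks=None,
    window: int = 3,
):
    """Reconstruction residual in percent of the reference norm.

    ``global``: 100 * ||recon - ref||_2 / ||ref||_2 over the whole grid.
    ``local``: per peak, the same ratio restricted to the +/-``window`` box
    around the peak position (an interval in 1D, a square in 2D); returns
    one value per peak.  Boxes extending beyond the grid are clipped with a
    warning.
    """
    recon = np.asarray(recon)
    reference = np.asarray(reference)
    if recon.shape != reference.shape:
        raise ValueError("recon and reference must be on the same grid")
    if mode == "global":
        ref_norm = np.linalg.norm(reference)
        if ref_norm == 0:
            raise ValueError("reference norm is zero; residual undefined")
        return float(100.0 * np.linalg.norm(recon - reference) / ref_norm)
    if mode != "local":
        raise ValueError("mode must be 'global' or 'local'")
    if peaks is None:
        raise ValueError("local residual requires peak positions")
    out = []
    for peak in np.atleast_1d(np.asarray(peaks, dtype=object)):
        pos = tuple(np.atleast_1d(peak).astype(int))
        if len(pos) != reference.ndim:
            raise ValueError(f"peak {peak} does not match grid dimensionality")
        slices = []
        for p, size in zip(pos, reference.shape):
            lo, hi = p - window, p + window + 1
            if lo < 0 or hi > size:
                warnings.warn(
                    f"local residual window around {pos} clipped to the grid",
                    stacklevel=2,
                )
            slices.append(slice(max(lo, 0), min(hi, size)))
        box = tuple(slices)
        ref_norm = np.linalg.norm(reference[box])
        if ref_norm == 0:
            raise ValueError(f"reference norm in the window around {pos} is zero")
        out.append(float(100.0 * np.linalg.norm(recon[box] - reference[box]) / ref_norm))
    return np.asarray(out)
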