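"""Empirical probes of the clustered null space property (NSP).

A measurement matrix A has the (Lambda, K)-NSP if every nonzero null-space
vector x puts strictly less l1 mass on any K-sparse support S contained in a
window of Lambda consecutive (cyclically wrapped — the FT is cyclic) grid
indices than on its complement: ||x_S||_1 < ||x_complement||_1.  The
property is equivalent to every Lambda-clustered K-sparse vector being the
unique l1-minimizing solution consistent with its measurements, so a
null-space vector violating the inequality is a concrete certificate that
some clustered vector cannot be recovered.

Certifying the NSP is NP-hard in general, so this module offers

* :func:`nsp_search_violation` — a heuristic multi-restart projected
  subgradient ascent over the null space.  Its contract is one-sided: a
  returned witness is a genuine (boundary or strict) violation, while
  ``None`` is only evidence of absence, not a certificate.
* :func:`certify_nsp_real` — exact certification by sign-pattern LP
  enumeration, practical only for small real-valued matrices; used as the
  oracle for the heuristic in tests.
* :func:`recovery_rate` — direct Monte-Carlo recovery probability of random
  clustered sparse vectors through the exact l1 oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product

import numpy as np
from scipy.linalg import null_space
from scipy.optimize import linprog

from .psf import measurement_matrix
from .reconstruct import basis_pursuit
from .schedules import Schedule

__all__ = [
    "ClusteredSupport",
    "NSPWitness",
    "cyclic_extent",
    "nullspace_basis",
    "nsp_search_violation",
    "certify_nsp_real",
    "recovery_rate",
]

_NULLSPACE_GRID_LIMIT = 1024
_BOUNDARY_TOL = 1e-8


def cyclic_extent(support, n: int) -> int:
    """Smallest number of consecutive (cyclic) indices covering the support."""
    s = np.unique(np.asarray(support, dtype=int) % n)
    if s.size == 0:
        return 0
    gaps = np.diff(np.concatenate([s, [s[0] + n]]))
    return int(n - gaps.max() + 1)


@dataclass(frozen=True)
class ClusteredSupport:
    """A support of <= K indices inside a cyclic window of Lambda indices."""

    indices: tuple[int, ...]
    lam: int
    k: int
    n: int

    def __post_init__(self) -> None:
        idx = tuple(sorted(int(i) % self.n for i in self.indices))
        object.__setattr__(self, "indices", idx)
        if len(set(idx)) != len(idx):
            raise ValueError("support has repeated indices")
        if len(idx) > self.k:
            raise ValueError(f"support of size {len(idx)} exceeds K={self.k}")
        if cyclic_extent(idx, self.n) > self.lam:
            raise ValueError(f"support extent exceeds the Lambda={self.lam} window")


@dataclass
class NSPWitness:
    """Null-space vector with margin ||x_S||_1 - ||x_complement||_1.

    ``boundary`` marks |margin| within tolerance of zero: the strict NSP
    inequality fails but no strict violation is exhibited.
    """

    vector: np.ndarray
    support: ClusteredSupport
    margin: float
    boundary: bool
    constraint_residual: float  # ||A x|| / ||x||


def _matrix_of(a) -> np.ndarray:
    if isinstance(a, Schedule):
        if a.grid.size > _NULLSPACE_GRID_LIMIT:
            raise ValueError(f"null-space probes are guarded to n <= {_NULLSPACE_GRID_LIMIT}")
        return measurement_matrix(a)
    return np.asarray(a)


def nullspace_basis(a) -> np.ndarray:
    """Orthonormal basis (n x (n-m) columns) of null(A); empty if m = n.

    ``a`` is a Schedule (partial Fourier matrix) or an explicit matrix.
    """
    mat = _matrix_of(a)
    basis = null_space(mat)
    return basis


def _margin(x: np.ndarray, support: np.ndarray) -> float:
    mask = np.zeros(x.size, dtype=bool)
    mask[support] = True
    mag = np.abs(x)
    return float(mag[mask].sum() - mag[~mask].sum())


def _polish_support(
    basis: np.ndarray,
    support: np.ndarray,
    sigma: np.ndarray,
    iters: int = 600,
) -> np.ndarray | None:
    """Best null-space vector for a fixed support and phase pattern.

    Solves the convex program min ||x_complement||_1 subject to
    x in range(basis) and sigma^H x_S = 1 by Douglas-Rachford splitting
    (the affine projection uses the orthonormality of the basis).  Returns
    the solution in x-space, or None if the constraint is infeasible.
    """
    n, d = basis.shape
    g = np.zeros(n, dtype=basis.dtype)
    g[support] = sigma
    h = basis.conj().T @ g  # constraint: h^H c = 1 in null-space coordinates
    h_norm2 = float(np.vdot(h, h).real)
    if h_norm2 < 1e-24:
        return None
    off = np.ones(n, dtype=bool)
    off[support] = False

    def project(x: np.ndarray) -> np.ndarray:
        c = basis.conj().T @ x
        c = c - h * ((np.vdot(h, c) - 1.0) / h_norm2)
        return basis @ c

    gamma = 0.25
    u = project(np.zeros(n, dtype=basis.dtype))
    p = u.copy()
    for _ in range(iters):
        r = 2.0 * p - u
        v = r.copy()
        mag = np.abs(r[off])
        with np.errstate(invalid="ignore", divide="ignore"):
            v[off] = r[off] * np.where(mag > gamma, 1.0 - gamma / np.where(mag > 0, mag, 1.0), 0.0)
        u = u + v - p
        p_new = project(u)
        if np.linalg.norm(p_new - p) <= 1e-13 * max(1.0, np.linalg.norm(p)):
            p = p_new
            break
        p = p_new
    return p


def nsp_search_violation(
    a,
    lam: int,
    k: int,
    restarts: int = 100,
    seed: int = 0,
    iters: int = 80,
):
    """Search for a null-space vector concentrated on a clustered support.

    Maximizes ||x_S||_1 - ||x_complement||_1 over unit vectors x in null(A),
    with S the best K-subset of a cyclic Lambda window.  Each restart runs a
    projected subgradient ascent from a random window/coefficient start to
    pick a candidate support and phase pattern, which is then polished by an
    exact convex solve (:func:`_polish_support`).  Returns an
    :class:`NSPWitness` when the best margin is positive (strict violation)
    or within tolerance of zero (boundary case); returns None when the best
    margin found is clearly negative.  One-sided: None certifies nothing.
    """
    mat = _matrix_of(a)
    m, n = mat.shape
    basis = null_space(mat)
    if basis.shape[1] == 0:
        return None
    complex_basis = np.iscomplexobj(basis)
    rng = np.random.default_rng(seed)
    d = basis.shape[1]

    best_margin = -np.inf
    best_x = None
    best_support = None
    for r in range(restarts):
        w = r % n if restarts >= n else int(rng.integers(n))
        win = (w + np.arange(lam)) % n
        # init: null-space projection of a vector concentrated on the window,
        # randomized so restarts explore different directions
        target = np.zeros(n, dtype=complex if complex_basis else float)
        if complex_basis:
            target[win] = rng.standard_normal(lam) + 1j * rng.standard_normal(lam)
        else:
            target[win] = rng.standard_normal(lam)
        c = basis.conj().T @ target
        if np.linalg.norm(c) == 0:
            c = rng.standard_normal(d).astype(basis.dtype)
        c = c / np.linalg.norm(c)
        for it in range(iters):
            x = basis @ c
            mag = np.abs(x)
            top = win[np.argsort(mag[win])[-k:]]
            phases = np.where(mag > 1e-15, x / np.where(mag > 0, mag, 1.0), 0.0)
            weights = -np.ones(n)
            weights[top] = 1.0
            c = c + 0.5 / (1.0 + it / 20.0) * (basis.conj().T @ (weights * phases))
            nc = np.linalg.norm(c)
            if nc == 0:
                break
            c = c / nc
        x = basis @ c
        mag = np.abs(x)
        top = np.sort(win[np.argsort(mag[win])[-k:]])
        sigma = x[top] / np.maximum(np.abs(x[top]), 1e-30)
        if not complex_basis:
            sigma = np.sign(np.where(sigma == 0, 1.0, sigma.real))
        polished = _polish_support(basis, top, sigma)
        candidates = [(x, top)]
        if polished is not None and np.linalg.norm(polished) > 0:
            candidates.append((polished / np.linalg.norm(polished), top))
        for cand, supp in candidates:
            margin = _margin(cand, supp)
            if margin > best_margin:
                best_margin = margin
                best_x = cand
                best_support = supp

    if best_x is None or best_margin < -_BOUNDARY_TOL:
        return None
    support = ClusteredSupport(indices=tuple(best_support), lam=lam, k=k, n=n)
    resid = float(np.linalg.norm(mat @ best_x) / np.linalg.norm(best_x))
    return NSPWitness(
        vector=best_x,
        support=support,
        margin=best_margin,
        boundary=abs(best_margin) <= _BOUNDARY_TOL,
        constraint_residual=resid,
    )


def certify_nsp_real(
    mat: np.ndarray,
    lam: int,
    k: int,
    tol: float = 1e-9,
):
    """Exact (Lambda, K)-NSP certification for small real matrices.

    Enumerates every K-subset S of every cyclic Lambda window and every sign
    pattern sigma on S, solving the LP

        min ||x_complement||_1  s.t.  A x = 0,  sigma . x_S = 1.

    An optimum <= 1 exhibits a violating null-space vector (== 1 within
    ``tol`` is a boundary case).  Returns (holds, worst_value, witness):
    ``holds`` is True iff no LP attains a value <= 1 + tol.  Exponential in
    K — intended for n <= 10 test oracles only.
    """
    mat = np.asarray(mat, dtype=float)
    m, n = mat.shape
    basis = null_space(mat)
    d = basis.shape[1]
    if d == 0:
        return True, np.inf, None

    worst = np.inf
    witness = None
    seen: set[tuple[int, ...]] = set()
    for w in range(n):
        win = tuple((w + j) % n for j in range(lam))
        for s_size in range(1, k + 1):
            for s in combinations(win, s_size):
                s = tuple(sorted(s))
                if s in seen:
                    continue
                seen.add(s)
                comp = [i for i in range(n) if i not in s]
                n_comp = len(comp)
                # variables: c (d, free), u (n_comp, >= 0); min 1'u
                cost = np.concatenate([np.zeros(d), np.ones(n_comp)])
                # |(Nc)_i| <= u_i  for i in complement
                rows_comp = basis[comp, :]
                a_ub = np.block(
                    [
                        [rows_comp, -np.eye(n_comp)],
                        [-rows_comp, -np.eye(n_comp)],
                    ]
                )
                b_ub = np.zeros(2 * n_comp)
                bounds = [(None, None)] * d + [(0, None)] * n_comp
                for sigma in product((-1.0, 1.0), repeat=s_size):
                    a_eq = np.concatenate(
                        [np.asarray(sigma) @ basis[list(s), :], np.zeros(n_comp)]
                    )[None, :]
                    res = linprog(
                        cost,
                        A_ub=a_ub,
                        b_ub=b_ub,
                        A_eq=a_eq,
                        b_eq=[1.0],
                        bounds=bounds,
                        method="highs",
                    )
                    if res.status != 0:
                        continue  # infeasible: no null vector with sigma.x_S = 1
                    if res.fun < worst:
                        worst = res.fun
                        witness = basis @ res.x[:d]
    holds = worst > 1.0 + tol
    return holds, float(worst), witness


def recovery_rate(
    schedule: Schedule,
    lam: int,
    k: int,
    trials: int = 100,
    seed: int = 0,
    tol: float = 1e-6,
) -> float:
    """Fraction of random clustered K-sparse vectors recovered exactly by l1.

    Each trial draws a support of ``k`` distinct indices inside a random
    cyclic Lambda window with circular complex Gaussian amplitudes, measures
    it through the schedule and solves basis pursuit; success means relative
    l2 error below ``tol``.  ``lam = n`` reproduces the arbitrary-support
    (unclustered) baseline.
    """
    if schedule.grid.dims != 1:
        raise ValueError("recovery_rate supports 1D schedules")
    n = schedule.grid.shape[0]
    if not 1 <= k <= lam <= n:
        raise ValueError("need 1 <= K <= Lambda <= n")
    idx = schedule.index_array()
    rng = np.random.default_rng(seed)
    sqrt_n = np.sqrt(n)
    hits = 0
    for _ in range(trials):
        w = int(rng.integers(n))
        offsets = rng.choice(lam, size=k, replace=False)
        support = (w + offsets) % n
        x = np.zeros(n, dtype=complex)
        x[support] = rng.standard_normal(k) + 1j * rng.standard_normal(k)
        y = (np.fft.ifft(x) * sqrt_n)[idx]
        z = basis_pursuit(schedule, y)
        if np.linalg.norm(z - x) <= tol * np.linalg.norm(x):
            hits += 1
    return hits / trials
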