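# Methods

`nusclust` studies a question from multidimensional NMR data acquisition: when
does Poisson-gap ("blue-noise") non-uniform sampling (NUS) of an indirect
dimension beat plain random sampling for compressed-sensing (CS)
reconstruction?  The working hypothesis is that the advantage appears when the
spectrum is not merely sparse but *clustered* — its significant points form a
closely spaced group of width Λ — and the package provides the machinery to
generate the schedules, quantify their measurement matrices, reconstruct
synthetic spectra, probe the clustered null space property, and measure peak
clustering in chemical-shift tables.

## Measurement model and conventions

A 1D NUS experiment on an n-point Nyquist grid measures the complex FID
s(t) at m grid indices t_1 < … < t_m (0-based; index 0 is always sampled).
The measurement matrix is the partial inverse Fourier matrix

    A[j, k] = exp(2πi · t_j · k / n) / √n,

i.e. the rows of the unitary FT matrix kept by the schedule.  Throughout the
package the forward FT is `fft(·)/√n` and its inverse `ifft(·)·√n`, so a
non-decaying unit-amplitude component at integer frequency f appears as a
single spectral bin of height √n, and the rows of A are orthonormal
(A·Aᴴ = I) — a fact exploited by both reconstruction solvers.

Indexing is 0-based half-open `[0, n)` everywhere; literature that writes the
schedule 1-based maps onto ours by ι_j = t_j + 1.

## Schedule generators

**Poisson-gap (PG).**  The walk starts at t = 0, records the point, skips
g ~ Pois(c·f(t)) grid points and repeats until the grid is exhausted; g is
drawn with Knuth's multiplicative algorithm (product of uniforms against
e^(−λ)).  f is the gap-size modulation evaluated at the *current* position
(clamped below at 10⁻⁶ so a modulation zero cannot stall the walk):

| kind          | f(t)                        | density effect                  |
|---------------|-----------------------------|---------------------------------|
| none          | 1                           | flat, mean gap (n−m)/m          |
| quarter_sine  | sin(π/2 · t/t_max)          | dense early FID                 |
| half_sine     | sin(π · t/t_max)            | dense at both ends              |
| exponential   | exp((t − t_max)/τ), τ=t_max/2 | exponentially decaying density |

The exponential kind realizes the classical exponentially *decaying* sampling
density: the gap grows exponentially along the grid, with the function
normalized into (0, 1] so the calibrated rate scale is comparable with the
sine modulations.  τ is configurable; t_max/2 (decay to e⁻² across the
record) mirrors the Lorentzian benchmark signals below.

The rate scale c is calibrated to hit exactly m points: starting from
c₀ = (n−m)/m / mean(f), each full walk multiplies c by (achieved points)/m
and redraws from the same seeded stream until a walk achieves exactly m
(at most 200 attempts; in practice ~10).  Renewal theory gives the resulting
density 1/(1 + c·f(t)); the accepted c solves ∫ dt/(1+c·f) = m and sits a
few percent above c₀ for the sine modulations.

Two finite-grid effects of exact-m generation matter for ensemble statistics:
conditioning on the achieved count under-disperses the pooled gap
distribution by a factor ≈ 1 − 1/(m−1) relative to a true Poisson, and the
grid edge censors the largest gaps of modulations that are large near t_max
(quarter-sine) but not of those that are small there (half-sine).  Both
effects are below 1% per histogram bin — invisible at plotting scale, but
statistically detectable once ~10⁵ pooled gaps are compared, which is why the
package's own equivalence test of the two sine modulations reports z-scores
of ~10 at 10,000 schedules: the two histograms are identical as continuum
distributions, not as finite-grid ones.  For the same reason the
Poisson-shape goodness-of-fit test is run at 500 schedules, where the
conditioning bias is far below the test's detection power.

**Random.**  Index 0 plus m−1 indices drawn without replacement, uniformly or
with probability proportional to per-index weights.  The weighted variant
with weights 1/sin(π/2 · t/t_max) ("reciprocal quarter-sine") reproduces the
sampling density — hence the time-domain sensitivity — of quarter-sine PG
without its inter-point distance restriction.  Equivalence is measured as the
RMS difference of per-index inclusion probabilities on the absolute scale
(full inclusion = 1) over the interior window t ∈ [10, 245], where it is
~3%; measured pointwise-relatively the two density *shapes* (1/(1+c·sin)
against ∝1/sin capped at 1) differ by up to ~15% at both record ends.

**2D PG ("add"-style).**  The 2D grid is traversed along anti-diagonals
s = t1 + t2 and a 1D PG walk runs over that ordering with rate modulated by
f(s/(t1_max + t2_max)).  Only the density-versus-s behaviour (monotone decay
for decaying modulations, (0,0) always present, no repetitions) is part of
the contract; the ordering within an anti-diagonal is an implementation
detail of this approximation.

**Determinism.**  One `numpy` Generator per schedule, seeded by the user;
Poisson draws and calibration retries consume the stream in walk order, so a
(parameters, seed) pair reproduces a schedule bit-for-bit across platforms.

## Measurement diagnostics

The point spread function, PSF_k = Σ_j exp(−2πi·t_j·k/n)/√n, is the FT of
the schedule's indicator, computed by FFT (the explicit matrix-product path
is retained as a test oracle).  It encodes every column correlation of A:
a_kᴴa_k' = PSF[(k−k') mod n]/√n, so the coherence μ(A) — the largest
modulus among distinct-column scalar products — is max_{k≥1} |PSF_k|/√n.
Useful identities asserted in tests: PSF_0 = m/√n, Σ_k |PSF_k|² = m
(Parseval of a 0/1 indicator), μ = 0 for full sampling, μ = 1/n for m = 1.

Restricted-isometry constants δ_K (the worst relative distortion of ‖Ax‖²
over K-sparse x) are computed exactly by enumerating all K-column
submatrices and taking σ²_max/σ²_min excursions; exact evaluation is
exponential, so it is guarded to n ≤ 24, K ≤ 4, with a Monte-Carlo subset
mode clearly reported as a lower bound beyond that.  δ_1 = 1 − m/n follows
analytically from the column norms and is used as an exact cross-check.

## Synthetic signals

Benchmark FIDs are sums of complex exponentials A·e^(2πi·f·t/n)·e^(−R·t)
with optional circular complex Gaussian noise (σ per quadrature, mean noise
power 2σ² per sample).  The standard scenarios hold five components with
amplitudes 1:2:3:4:5:

* *spread*: bins ⌊n/10⌋·(1,3,5,7,9) — evenly spaced, minimal separation
  2⌊n/10⌋ (50 bins at n=256);
* *clustered*: five bins evenly placed inside a Λ-bin window (default Λ=16)
  centred at n/2;
* *sparse* variants do not decay (constant-time dimensions; strictly sparse
  single-bin spectra); *Lorentzian* variants decay with R = 2/t_max so the
  envelope falls to e⁻² at the last sample.

The positions and decay are package choices (exposed as configuration): only
the qualitative design — same sparsity, different clustering/lineshape — is
inherited.  Clustered spectra produce amplitude-modulated FIDs: two peaks d
bins apart modulate |s(t)| as 2|cos(π·d·t/n)| and a dense cluster of q
adjacent peaks gives the Dirichlet envelope |sin(q·δt/2)/sin(δt/2)|,
δ = 2π/n, with maxima at the start *and end* of the record — the mechanism
that favours gap-restricted and end-dense (half-sine) sampling.

Peak-table fixtures emulate the statistical structure that the clustering
statistic consumes: per entry, columns at distinct 0.02-ppm direct-dimension
bins (distinct by construction, so downstream binning never merges two
generated columns), each holding peaks whose indirect shifts scatter
Normal(centre, σ) per dimension.  They are not chemically realistic —
passing tests say nothing about real shift distributions, only about the
statistic's arithmetic and its linearity in dispersion.

## Reconstruction

**IST-D.**  Iterative soft thresholding with a decreasing threshold, in the
accumulating (CLEAN-like) form: each of L iterations Fourier-transforms the
zero-filled residual of the measured points, shrinks complex moduli by τ_i
(phase preserved) and adds the extracted part to the running spectrum
estimate.  τ_i decays geometrically from `threshold_start`·M₀ to
`threshold_end`·M₀, where M₀ is the maximum modulus of the zero-filled data
spectrum.  Defaults: L = 200 iterations, start 0.99, end 10⁻⁶; with the
final data-consistency step (on by default) the estimate's inverse FT equals
the measured data exactly at sampled points, so full sampling reconstructs
exactly and noiseless recoverable instances reach ~10⁻⁶ relative error.  The
threshold law of the original hmsIST implementation is not published; these
defaults are documented, not claimed identical.  An explicit sparsity-weight
parameter is not used — the decreasing threshold plays its role.  A
virtual-echo mode (off by default in the simulation benchmark, matching how
the benchmark is defined; on in experimental-methodology replays) first
extends the data onto the conjugate-symmetric 2n grid — ve[t] = s(t),
ve[2n−t] = s̄(t), first point halved to Re s(0) — making the target spectrum
real and sparser.  2D data are reconstructed with a 2D FT on small grids
(≤ 16384 points) with the same thresholding.

**Exact ℓ1 oracle.**  `basis_pursuit` solves min ‖z‖₁ s.t. Az = y by
Douglas–Rachford splitting between the complex soft-threshold prox and the
affine projection z − Aᴴ(Az − y), which is exact (two FFTs) because A's
rows are orthonormal.  Step γ defaults to 0.1·max|Aᴴy|; iterations stop when
the fixed-point gap falls below 10⁻¹⁰ relative (≤ 6000 iterations).  It is
guarded to n ≤ 512 and serves as the recovery/NSP ground truth; tests verify
its output against KKT optimality certificates (a dual vector ν with
(Aᴴν) matching the solution's phases on the support and bounded by 1 off
it) and against LP solutions on small real instances, keeping the oracle
independent of IST.

**Residuals.**  Global: 100·‖x̂ − x_ref‖₂/‖x_ref‖₂.  Local: the same ratio
restricted to a ±w window around each peak (interval in 1D, square in 2D;
default w = 3, clipped at grid edges with a warning), reported per peak in
percent of that peak's reference norm.

## Null-space property probes

A schedule's matrix has the (Λ, K) clustered null space property when every
nonzero null-space vector x satisfies ‖x_S‖₁ < ‖x_S̄‖₁ for every support S
of at most K indices inside a window of Λ consecutive indices — windows are
*cyclic*, because the FT is cyclic (a design choice; "Λ-clustered" admits
window or diameter readings).  The property is equivalent to unique ℓ1
recovery of all Λ-clustered K-sparse vectors, which makes violations
actionable: a witness x with ‖x_S‖₁ ≥ ‖x_S̄‖₁ yields a clustered vector
x_S whose measurements are explained at no larger ℓ1 cost by −x_S̄.

Exact certification is NP-hard, so the package provides three levels:

* a heuristic search (`nsp_search_violation`): multi-restart projected
  subgradient ascent of ‖x_S‖₁ − ‖x_S̄‖₁ over the unit sphere of the null
  space (orthonormal basis from SVD), followed by an exact convex polish for
  the chosen support/phase pattern — minimizing ‖x_S̄‖₁ subject to
  x ∈ null(A), σᴴx_S = 1 by Douglas–Rachford with an exact affine
  projection.  The contract is one-sided: a returned witness is genuine
  (margins within 10⁻⁸ of zero are flagged "boundary", e.g. the alias pair
  e_k − e_{k+n/2} of uniform sub-Nyquist sampling); `None` certifies nothing.
* exact sign-pattern LP enumeration (`certify_nsp_real`) for small real
  matrices (the 2^K·n·C(Λ,K) LPs are practical only for n ≲ 10), used as the
  oracle for the heuristic in tests.
* direct Monte-Carlo `recovery_rate`: random Λ-clustered K-sparse complex
  Gaussian vectors measured and recovered through `basis_pursuit`; success
  is relative ℓ2 error < 10⁻⁶.  Λ = n reproduces the arbitrary-support
  baseline.

## Experiment runners and problem sizes

`run_gap_stats`, `run_reconstruction_benchmark` and `run_clustering_hist` are
config-driven, deterministic (explicit seed lists) and emit tidy CSV plus a
manifest (config hash, seeds, package version).  Default problem sizes are
chosen for desk-scale runs: gap/density/PSF ensembles of 2,000 seeds
(10,000 in the equivalence analyses), the reconstruction benchmark at
n = 256 with m ∈ {16, 32, 48, 64, 96, 128} and 50 seeds per level
(~75 s on one CPU), clustering fixtures of 10³ columns.  Larger ensembles
are config switches, not code changes.

Benchmark findings worth recording (they are recomputed by the acceptance
script, not asserted as constants): unweighted random attains the lowest
mean residual for the spread strictly-sparse signal at half sampling;
half-sine PG dominates for clustered non-decaying signals; quarter-sine PG
and its density-matched weighted random are statistically indistinguishable
on spread Lorentzian signals; and unmodulated PG overtakes unweighted random
on the clustered Lorentzian signal only above ≈43% sampling in these
conditions — below that, its flat density loses to the decaying schemes, a
crossing consistent with the requirement that the PSF's low-artifact zone
exceed about twice the cluster width.  Notably, the exact ℓ1 oracle recovers
the noiseless strictly-sparse scenarios for *all* schemes at m ≥ 24, so the
scheme ordering in the sparse panels reflects IST-D's convergence behaviour
within a fixed iteration budget rather than information-theoretic
recoverability.

## Numerical choices and degenerate inputs

* Complex soft threshold shrinks moduli and preserves phase; exact zeros stay
  zero.
* Zero measured data short-circuit IST and basis pursuit to the zero
  spectrum (no threshold schedule can be formed from M₀ = 0).
* m = n makes every generator return the full grid (all gaps 0) and empties
  the null space; m = 1 yields the forced-origin schedule.
* Population (n-divisor) standard deviation in the clustering statistic, so a
  single peak gives exactly 0 and two extreme peaks exactly 1; spectral
  widths default to the per-entry span of observed shifts ("per protein"),
  with an explicit override for the per-spectrum variant.  Entries with zero
  span are skipped and reported.  Direct-dimension grouping uses fixed
  0.02-ppm binning rather than tolerance clustering — deterministic, at the
  cost of possible splits exactly at bin edges.
* Histogram upper edges extend beyond 1 when an explicit SW override makes
  H > 1 possible, so counts always conserve the number of scored columns.

## Known limitations

* The NSP violation search is heuristic; absence of a witness is evidence,
  not proof, and its restart budget matters for small margins.
* The 2D "add"-style generator is an approximation pinned only by its
  density contract; it is not claimed to match any particular spectrometer
  implementation point-for-point.
* Exact-m schedule generation makes pooled gap statistics deviate from ideal
  Poisson at the sub-percent level (see above); analyses that pool ≥10⁵ gaps
  must expect this.
* NMR-STAR ingestion is out of scope; peak tables enter as CSV with columns
  `entry_id, direct_ppm, indirect1_ppm[, indirect2_ppm]`.
* Noise, apodization and phase errors of real spectrometer data are outside
  the synthetic generator's scope; conclusions about real spectra rest on
  the cited experimental literature, not on these simulations.
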