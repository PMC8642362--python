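# nusclust

Non-uniform sampling (NUS) schedules, blue-noise diagnostics and
compressed-sensing reconstruction for **clustered** NMR spectra.

Multidimensional NMR spends most of its measurement time stepping through the
indirect evolution dimensions point by point.  NUS cuts that cost by
measuring only m of the n Nyquist-grid points and reconstructing the rest —
classically with an ℓ1-minimizing compressed-sensing (CS) solver such as
iterative soft thresholding (IST).  CS theory says a purely random schedule
is optimal for generic sparse spectra, yet practitioners consistently prefer
*Poisson-gap* (PG) schedules, whose inter-point gaps are Poisson distributed
and optionally modulated along the grid.  The resolution of this tension is
that protein spectra are usually not just sparse but **clustered**: the peaks
of a cross-section occupy a narrow band of width Λ ≪ n.  Blue-noise
schedules push their point-spread-function artifacts away from the peak, so
clustered peaks sit in each other's low-artifact zones — and clustered
signals are amplitude-modulated in the time domain, which gap-restricted
sampling avoids hitting at its zero crossings.

`nusclust` implements this whole story as a tested library for spectroscopists
and CS researchers:

* **schedules** — unweighted/weighted random and Poisson-gap generators
  (quarter-sine, half-sine, exponential gap modulation; 1D and 2D
  anti-diagonal "add"-style), gap statistics, plain-text schedule I/O;
* **psf** — point spread functions, coherence μ(A), exact brute-force
  restricted-isometry constants on small instances;
* **signals** — five-component benchmark FIDs (spread/clustered ×
  sparse/Lorentzian, amplitudes 1:2:3:4:5) and synthetic chemical-shift
  peak-table fixtures;
* **reconstruct** — IST with decreasing threshold (IST-D, 200 iterations by
  default), virtual-echo mode, an exact Douglas–Rachford basis-pursuit
  oracle, global/local residual scoring;
* **nsp** — empirical probes of the clustered (Λ, K) null space property:
  heuristic violation search with convex polishing, LP certification on toy
  matrices, Monte-Carlo ℓ1 recovery rates;
* **clustering** — the per-cross-section clustering statistic
  H_j = 2·√(Σ_i σ²(δ_i^j)) / √(Σ_i SW_i²) on 0.02-ppm-binned peak tables;
* **experiments** — deterministic, config-driven runners emitting tidy CSV.

## Worked example

```python
import numpy as np
from nusclust import (Grid, generate_poisson_gap, coherence, gap_sizes,
                      make_scenario, synth_fid, sample_signal, NUSData, ist,
                      residual)

grid = Grid((256,))
sched = generate_poisson_gap(grid, 64, "quarter_sine", seed=7)
print("first points :", sched.indices[:10])
print("mean gap     :", round(float(np.mean(gap_sizes(sched))), 3))
print("coherence    :", round(coherence(sched), 4))

signal = synth_fid(make_scenario("clustered_sparse", 256), 256)
dense = generate_poisson_gap(grid, 128, "quarter_sine", seed=7)
rec = ist(NUSData(dense, sample_signal(signal, dense)))
r = residual(rec.spectrum, signal.spectrum())
print(f"IST residual : {r:.2e} % of the reference norm")
```

prints

```
first points : (0, 1, 2, 3, 5, 6, 7, 8, 9, 10)
mean gap     : 3.032
coherence    : 0.0889
IST residual : 1.68e-04 % of the reference norm
```

Reading the numbers: a quarter-sine-modulated PG schedule of 64/256 points
samples the early FID almost contiguously (first gaps are 0–1) and averages
the expected gap (n−m)/m = 3; its coherence 0.089 is *higher* than an
unweighted random schedule's (≈0.06 on average) — incoherence alone never
favors PG.  Yet the clustered five-peak signal at 50% sampling reconstructs
to 1.7·10⁻⁶ of the reference norm, i.e. exact recovery to solver precision.
The benchmark runner (`run_reconstruction_benchmark`) turns this single anecdote into
the full scheme × scenario × sampling-level comparison.

The same operations are scriptable from a shell:

```bash
nusclust generate --grid 256 --points 64 --scheme pg-quarter-sine --seed 7 -o sched.txt
nusclust coherence sched.txt --grid 256
nusclust psf sched.txt --grid 256 -o psf.csv
nusclust clustering peaks.csv -o hist.csv
nusclust run benchmark --config benchmark.yaml -o out/
```

Schedule files are plain text, one 0-based grid index per line (two columns
for 2D), compatible with common nuslist-style tooling.

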