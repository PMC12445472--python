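# Methods

## Model

`qrseg` performs multilevel thresholding on the two-dimensional histogram
of a gray-level image: the joint empirical distribution of a pixel's
intensity `x` and the rounded mean `y` of its 3×3 neighbourhood. Relative
to 1D-histogram thresholding (Otsu/Kapur lineage), the second axis adds
local spatial context, which separates regions that overlap in intensity
alone; the construction follows the Abutaleb lineage of 2D thresholding.

A candidate `X = (t1<…<tk | v1<…<vk)` places `k` row and `k` column
thresholds and keeps only the `k+1` diagonal rectangles
`[t_{i-1}+1, t_i] × [v_{i-1}+1, v_i]` (anchored at 0 and `L−1`). Cells off
the diagonal — typically edge and noise pixels whose local mean disagrees
with their intensity — are deliberately excluded from the objective.

Two objectives score a partition, both summed over rectangles:

* **Classical Rényi entropy** of order `α` of the global weights
  restricted to a rectangle: `(1/(1−α))·ln Σ w^α`. No per-rectangle
  renormalization is applied; the weights are the global `w = h/(MN)`.
* **Quantum Rényi entropy** of the rectangle's FRQI-style encoding. Each
  cell maps to a qubit angle `θ = (π/2)·w(x,y)`; a rectangle's amplitude
  sums `C = Σ cos θ`, `S = Σ sin θ` form the rank-one density operator
  `ρ = (C,S)(C,S)ᵀ`, scored by `(1/(1−α))·ln tr(ρ^α)` through the
  spectral decomposition of the 2×2 matrix. Because `ρ` has eigenvalues
  `{C²+S², 0}`, this equals `(α/(1−α))·ln(C²+S²)` — an identity the test
  suite checks to 1e-9.

Two modelling choices deserve emphasis, both exposed as options:

* `ρ` is used **unnormalized**, exactly as the outer product. Trace
  normalization first (option `rho_normalization="unit_trace"`) makes
  every non-empty rectangle a pure state whose Rényi entropy is
  identically zero, i.e. it destroys the fitness signal entirely; the
  literal operator is the only form under which the quantum objective
  ranks candidates at all.
* The cell sum runs over **all grid cells** of a rectangle by default
  (`empty_cell_policy="all_cells"`): zero-weight cells contribute
  `cos 0 = 1` to `C`, so rectangle *area* enters the quantum objective
  (`C ≈ area`, hence `QR ≈ (2α/(1−α))·Σ ln area_i` for thin spectra plus
  a mass-dependent correction). Under the default this drives the
  partition toward area-balanced rectangles moderated by where the mass
  sits. `occupied_only` restricts the sums to populated cells, making QR
  mass-driven like CR; both behaviours are tested.

With `α = 0.01` the classical power sum approaches the occupied-cell
count, so CR maximization favours partitions in which each rectangle
captures a whole histogram mode; small `α` emphasizes the support of the
distribution over its peaks.

## Segmented-image construction

Only the row (intensity) thresholds shape the output: class `i` collects
pixels with `t_{i-1} < f ≤ t_i` (thresholds close the *lower* class — the
same side convention the diagonal rectangles use, so a threshold sitting
on a populated level groups that level with the rectangle that scored
it), and each class is replaced by the rounded (half-up) mean of its
members. Empty classes emit no output level, so the output has at most
`k+1` distinct values; re-applying the same thresholds to a segmented
image reproduces it exactly. The column thresholds only shape the fitness
landscape — an asymmetry inherited from the method's definition and kept
deliberately.

## Optimization

The 2k-dimensional integer search space is explored through a continuous
relaxation of `[1, L−2]^{2k}`; every candidate is repaired (round
half-up, clip, sort, push duplicates upward with a final downward cap)
before evaluation, so the search only ever scores valid strictly
increasing threshold vectors.

* **PSO**: global-best topology, `c1 = c2 = 2`, inertia linearly
  interpolated from 0.9 to 0.4 across `max_iterations`; velocities
  clamped to `±(L−3)/2`, positions reflected at the bounds.
* **DE**: DE/rand/1/bin, `F = 0.8`, `CR = 0.9`, greedy selection (strict
  improvement replaces, ties keep the incumbent). With `CR = 0` no mutant
  coordinate is forced, so `F = 0, CR = 0` is an exact no-op control.
* **Exhaustive search**: enumerates all `C(L−2, k)²` candidates in
  lexicographic order (refusing above a configurable cap, default 1e7);
  it is the ground-truth oracle for small instances.

Both metaheuristics run `population = 30` and at most 1000 iterations,
stopping early after `stagnation_patience = 300` iterations without
global-best improvement. The patience default is deliberately a
substantial fraction of the inertia schedule: with `c1 + c2 = 4` the
swarm contracts only once inertia has decayed well below its starting
value, and a short patience (e.g. 100) reliably terminates PSO in its
coarse oscillatory phase one lattice step away from the optimum on
known-maximizer diagnostics. Ties in fitness resolve toward the
lexicographically smallest threshold vector, and all randomness flows
from one `numpy` generator seeded by `OptimizerConfig.seed`, so results
are bit-reproducible.

Degenerate partitions (a rectangle with no probability mass under the
active policy) receive the finite penalty −1e12 rather than −∞: strictly
dominated by every feasible value, but safe for the optimizers'
arithmetic. Emptiness is detected from exact integer occupancy counts,
not from floating-point power sums.

### Numerical notes

* Fitness evaluation inside the optimizers uses 2D prefix-sum (integral)
  tables over the per-cell summands, reducing each rectangle to four
  lookups; this matches direct summation to ~1e-12 relative and is what
  makes exhaustive search at `L = 32, k = 2` (≈1.9e5 candidates) and
  pipeline runs at `L = 256` fast.
* Eigenvalues of `ρ` below 1e-12 of the leading eigenvalue are clipped to
  exact zeros before the spectral power sum (the numerical form of the
  `0^α = 0` convention); without the clip, `(ε)^α` at small `α` would
  contribute O(1) spurious entropy.
* Local means and class means round half-up (`floor(x + 0.5)`); the
  half-up rule for fractional local means is this package's choice, as no
  canonical convention exists for binning them.

## Quality metrics

Nine reference/processed metrics with fixed, documented formulas (see the
`metrics` module docstring): PSNR (capped at 100 dB), SSIM (uniform 8×8
windows, population statistics, valid windows only), AMBE, CII and CIR
(3×3 local-contrast maps, reflect borders, ε = 1e-9), SD, edge density
(Sobel magnitude above its Otsu threshold), REC (relative Shannon-entropy
change of the 1D histograms, natural log), and SF (RMS of first
differences). AMBE is the only lower-is-better metric. CII/CIR/REC/edge
density have no single canonical definition in the literature; the ones
fixed here are internally consistent stand-ins, comparable within this
package but not across publications.

## Benchmark harness

`run_benchmark` executes the four combinations (PSO/DE × CR/QR) over an
image list and k grid, ranks methods per metric by mean (ties: lower
variance, then name), sums ranks into an overall rank (9 ≤ OR ≤ 36 for
four methods, lower is better), and runs pairwise two-sided Wilcoxon
signed-rank tests on the paired per-image values. The Wilcoxon statistic
is `W = min(R⁺, R⁻)` after dropping zero differences (average ranks for
ties); p-values use the exact sign-flip null (generating-polynomial
enumeration over doubled ranks) for n ≤ 25 and a tie-corrected normal
approximation with continuity correction above. Per-image failures are
recorded and skipped, never fatal.

## Synthetic data

The fixture generator emulates the one property of natural multimodal
photographs that 2D-histogram thresholding exploits: spatially coherent
regions of near-constant intensity. Classes are contiguous horizontal
bands (fractions respected to within one row) with additive rounded
Gaussian noise clipped to the gray range, plus a ground-truth label map.
Defaults — 128×128, class means (60, 128, 200), equal fractions, σ = 8 —
give three well-separated modes (gaps ≥ 8.5σ). What it does *not*
emulate: texture, gradients, lighting variation, and genuinely ambiguous
class boundaries; success on fixtures therefore demonstrates correctness
of the machinery and recoverability of well-separated structure, not
performance on difficult natural images.

Threshold recovery is scored as: each recovered row threshold lies
strictly between the adjacent true class means.

## Problem sizes

The shipped tests and the acceptance script run at deliberately modest
scale, chosen to exercise every claim while keeping the whole suite in
the low tens of seconds: oracle comparisons at `L = 32, k = 2`
(exhaustive enumeration of 189 225 candidates), closed-form and limit
checks on `L ∈ {4, 16, 64, 256}` histograms, pipeline runs on 128×128
fixtures at `k = 2`, and 10–20 seed repetitions for stochastic rates.

## Known limitations

* The quantum objective under the literal all-cells policy has a strong
  area-equalization component; on images whose classes are far from
  equal-sized it can be out-voted by geometry. The `occupied_only` policy
  is the mass-driven alternative.
* Iteration counts depend on the stagnation rule and are not comparable
  across implementations with different stopping criteria.
* The contrast-enhancement hook ships with identity, global histogram
  equalization and CLAHE only; it is a plug-in point, not a contribution.
* Only 2D (single-channel) rasters; the 3×3 window is fixed by design.
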