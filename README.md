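# qrseg

Multilevel gray-level image segmentation by thresholding the 2D
intensity/local-mean histogram, with the partition scored by **classical or
quantum Rényi entropy** and optimized by **particle swarm optimization
(PSO)**, **differential evolution (DE)**, or exhaustive search. Intended
for researchers and practitioners in (biomedical) image analysis who need
reproducible multilevel thresholding with spatial context, plus a
benchmarking harness to compare optimizer/entropy combinations.

## Method

For an M×N image `f(m,n)` with `L` gray levels, every pixel is paired with
the rounded mean of its in-bounds 3×3 neighbourhood, giving a joint
histogram `h(x,y)` over (intensity, local mean) and normalized weights

    w(x,y) = h(x,y) / (M·N).

A threshold vector `X = (t1<…<tk | v1<…<vk)` tiles the histogram diagonal
with `k+1` rectangles `DR_i` (off-diagonal mass — mostly edges and noise —
is ignored). Two objectives score a partition:

* **Classical Rényi (CR):**
  `CRα(DR_i) = (1/(1−α)) · ln Σ_{(x,y)∈DR_i} w(x,y)^α`, summed over the
  `k+1` rectangles.
* **Quantum Rényi (QR):** each cell is encoded as the single-qubit state
  `cos θ |0⟩ + sin θ |1⟩` with `θ = (π/2)·w(x,y)` (an FRQI-style encoding).
  Summing amplitudes over a rectangle gives `C = Σ cos θ`, `S = Σ sin θ`
  and the rank-one density operator `ρ_i = (C,S)(C,S)ᵀ`, scored by
  `QRα(DR_i) = (1/(1−α)) · ln tr(ρ_i^α)` via its spectral decomposition.

The optimal thresholds maximize the total entropy over all admissible
`X`; the winning row thresholds then partition the gray range and every
class is replaced by the rounded mean of its member pixels. Defaults:
`α = 0.01`, population 30, up to 1000 iterations, DE/rand/1/bin with
`F = 0.8`, `CR = 0.9`, PSO with `c1 = c2 = 2` and inertia 0.9 → 0.4.

A nine-metric quality suite (PSNR, SSIM, AMBE, CII, SD, edge density, REC,
CIR, SF) and a comparison harness (per-metric ranking with
lowest-variance tie-breaks, overall ranks, Wilcoxon signed-rank tests)
round out the tool.

## Worked example

Generate a synthetic three-class image (class means 60/128/200, Gaussian
noise σ=8) and segment it with two thresholds using PSO on the quantum
objective:

```sh
qrseg fixtures --out fx --count 1 --seed 3
qrseg segment --input fx/fixture_0003.png --output seg.png \
      --k 2 --entropy qr --optimizer pso --seed 1 --report rep.json
```

which prints

```
fixture_0003.png: k=2 PSO-QR thresholds=[84, 169]
```

The two recovered thresholds 84 and 169 fall between the true class means
(60 < 84 < 128 < 169 < 200), so the three classes are separated correctly;
`seg.png` contains exactly three gray levels (the class means). The JSON
report records the column thresholds, the reached fitness (0.539 here),
iteration count, per-stage timings and the nine quality metrics of the
segmented image against its reference (e.g. PSNR 30.08 dB, SSIM 0.546 for
this noisy fixture — the noise floor, not the segmentation, dominates
both).

The same pipeline is available as a library:

```python
from qrseg import FixtureSpec, make_piecewise_image, segment_image, EntropyParams

img, labels = make_piecewise_image(FixtureSpec(seed=3))
seg, result = segment_image(img, k=2, params=EntropyParams(mode="quantum"))
print(result.best_X.rows, result.best_fitness)
```

`qrseg benchmark --images fixtures --k 2,4,7 --seeds 5 --out bench/` runs
the full PSO/DE × CR/QR grid and writes per-run metrics, rank tables,
overall ranks and Wilcoxon tables as CSV.

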