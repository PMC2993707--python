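# bigauss

Quantification and deconvolution of asymmetric LC-MS chromatographic peaks
with bi-Gaussian mixture models and BIC model selection.

## The problem

In LC-MS metabolomics and proteomics, each metabolite or peptide produces an
extracted-ion chromatogram (EIC): intensity versus retention time at one m/z
value. Quantification requires turning that noisy trace into peak areas.
Two common approaches have well-known failure modes: summing raw ion counts
under-reports whenever intensities are missing (frequent in high-resolution
LC-FTMS traces), and symmetric Gaussian peak models misplace the summit and
bias the area whenever peaks tail — which they usually do. On top of that,
metabolites sharing an m/z value can partially overlap in retention time, so
the trace must be deconvolved into components.

`bigauss` addresses both problems with the bi-Gaussian peak model: two half
Gaussians with separate standard deviations σ₁ (left) and σ₂ (right) joined
at the summit α and scaled by δ,

    g(t) = δ/√(2π) · exp(−(t−α)²/2σ₁²)   for t <  α
    g(t) = δ/√(2π) · exp(−(t−α)²/2σ₂²)   for t ≥  α

with total peak area δ(σ₁+σ₂)/2. The package provides:

- **Single-peak fitting** robust to high noise: the summit is *not* the
  highest observed point but the root of A(τ)−B(τ), where A is the log-ratio
  of the trace's masses left/right of τ and B the log-ratio of the cube roots
  of its second moments about τ. Both equal log(σ₁/σ₂) at τ = α, and their
  difference is monotone, so the root is unique. σ₁, σ₂ follow as one-sided
  weighted RMS deviations, and δ as a fitted-value-weighted geometric mean of
  observed/fitted ratios.
- **Deconvolution** of overlapping peaks by an EM-like algorithm: kernel
  smoothing splits the trace at valleys into initial components; iterations
  then redistribute each observation among components in proportion to their
  fitted values (responsibilities), re-fit every component with the
  single-peak procedure, and prune components whose share of the fitted
  signal falls below a threshold.
- **Model selection**: the number of components is chosen by running the fit
  from several smoother bandwidths and keeping the model with the lowest
  BIC = N·log(RSS/N) + 4·J·log(N) (3 parameters per component for the
  symmetric Gaussian baseline).
- **Baselines and a simulator** reproducing the method's benchmark: traces
  x_i = Σ_j g_j(t_i)·e^{ε_i}·u_i with log-normal multiplicative noise
  (ε ~ N(0, ξ²)) and dropout (u_i = 0 with probability θ), classified by the
  valley-to-summit overlap ratio r.

## Worked example

```python
import bigauss as bg

# simulate a 3-peak asymmetric trace: noise SD 0.4 (log scale), 25% dropout
sim = bg.simulate_trace(bg.SimulationConfig(xi=0.4, theta=0.25, seed=11))

fit = bg.select_model(sim.trace)   # bandwidth scan + EM + BIC
print("selected J =", fit.J, " bandwidth =", round(fit.bandwidth, 3),
      " BIC =", round(fit.bic, 1))
for k, c in enumerate(sorted(fit.components, key=lambda c: c.alpha)):
    print(f"  peak {k}: alpha={c.alpha:.3f}  sigma1={c.sigma1:.3f}"
          f"  sigma2={c.sigma2:.3f}  area={c.area:.0f}")
print("true areas:", [round(a) for a in sim.true_areas])
```

prints

```
selected J = 3  bandwidth = 0.257  BIC = 1387.3
  peak 0: alpha=4.689  sigma1=0.190  sigma2=1.197  area=46002
  peak 1: alpha=8.360  sigma1=0.451  sigma2=0.731  area=113633
  peak 2: alpha=11.286  sigma1=0.190  sigma2=0.733  area=42199
true areas: [60000, 96000, 42000]
```

The pipeline recovers the correct number of components and areas within the
accuracy expected at this noise level (ξ = 0.4 means ~25% of intensities are
perturbed by 1.8-fold or more, and a quarter of the points are missing).

The same workflows are available from the shell:

```bash
bigauss simulate --xi 0.4 --theta 0.25 --seed 11 --output trace.tsv
bigauss fit --input trace.tsv --output peaks.tsv --method bigaussian
bigauss evaluate --replicates 20 --seed 1 --output benchmark.tsv
```

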