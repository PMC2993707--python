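# Methods

## The peak model

A chromatographic peak is modeled as a bi-Gaussian: two half-Gaussian
branches with standard deviations σ₁ (left) and σ₂ (right), joined
continuously at the summit α and scaled by δ, so the summit height is
δ/√(2π) and the area is δ(σ₁+σ₂)/2 (half-areas δσ₁/2 and δσ₂/2). The summit
point itself is assigned to the right branch; both branches coincide there,
so the convention is observationally irrelevant. δ is stored exactly as the
scaling factor; the area is always derived, never stored, so the two can
never disagree.

The model trades generality for robustness: with four parameters and
closed-form areas it can be estimated from the few dozen points a
high-resolution LC-MS ion trace typically provides, at noise levels far
above what classical chromatographic peak-shape estimators assume.

## Single-peak estimation

Intensities arrive at discrete times t₁ < … < t_n with local step sizes
Δt₁ = t₂−t₁, Δt_i = (t_{i+1}−t_{i−1})/2, Δt_n = t_n−t_{n−1}, turning the
curve into a step function. For a candidate split point τ:

- Â(τ) = log Σ_{t_i<τ} x_iΔt_i − log Σ_{t_i≥τ} x_iΔt_i
- B̂(τ) = (1/3)[log Σ_{t_i<τ} x_i(t_i−τ)²Δt_i − log Σ_{t_i≥τ} x_i(t_i−τ)²Δt_i]

Both converge to log(σ₁/σ₂) at τ = α, and the continuous difference A−B is
monotone in τ over the practical range of σ₁/σ₂ (verified against an
adaptive-quadrature oracle in the tests), so its root is unique. Â−B̂ is
evaluated at all midpoints between adjacent observed times — where the step
partition is exact — and the summit estimate interpolates linearly between
the largest value below zero and the smallest above zero. On noisy data the
profile can cross zero more than once; the interpolation pair is still
taken as the globally closest values on either side of zero. If no sign
change exists (a boundary or one-sided peak) the midpoint with the smallest
|Â−B̂| is used.

Given α̂, each σ̂ is the square root of the intensity-and-step weighted mean
of (t_i−α̂)² on its side (strictly left / right-inclusive, matching the
branch convention); a side with no positive mass mirrors the other side's
estimate, which keeps the fitter total when dropout empties a flank. δ̂ is
exp(Σ ẑ_i² log(x_i/ẑ_i) / Σ ẑ_i²) over points with x_i > 0, where ẑ_i is the
unscaled fitted value — a geometric mean computed on the log scale because
ion counts are highly skewed, with weights ẑ_i² concentrating on the summit
region. Natural logarithms are used throughout (the base cancels in the
root-finding but δ̂'s geometric mean needs a fixed convention). Weights are
normalized by the largest ẑ and the ratio is computed as log x − log ẑ so
far-tail underflow cannot poison the sum.

Equivariances (tested): shifting all times by c shifts α̂ by c and nothing
else; scaling all intensities by c scales δ̂ by c and nothing else.

## Zeros are missing observations

In high-resolution LC-FTMS ion traces a zero intensity is a missing
measurement, not a measured count of zero. The package applies this reading
consistently:

- the moment sums ignore zeros automatically (zero weight);
- δ̂ skips them (log 0 is undefined);
- the kernel smoother averages only positive points — including zeros would
  drag the smooth toward zero inside dropout holes and manufacture spurious
  valleys, inflating the initial component count;
- the residual sum of squares and the BIC's N count only points with
  observed (nonzero) intensities. This matters: at 50% dropout the
  squared residuals at dropout points would otherwise dominate the RSS
  (the generating model itself then scores worse than a flat underfit),
  and model selection would collapse toward too few components.

`FitConfig(exclude_zeros_from_n=False)` (CLI: `--include-zeros-in-N`)
restores the alternative reading in which zeros are genuine observations.

## Mixture deconvolution

1. A Nadaraya–Watson smoother with Gaussian kernel (SD = the bandwidth)
   is evaluated at the observed times; the trace is split into contiguous
   groups at the smoother's interior valleys (plateaus collapse to their
   centre point; smoothed values are snapped to 12 significant digits so
   float jitter cannot split a plateau). Each group seeds one component:
   α̂ fixed at the group's smoother peak for the initial σ/δ estimate only.
   Groups with fewer than three positive points cannot support a two-sided
   moment estimate and are merged into the neighbour across their higher
   valley.
2. Iterate: (a) compute each component's fitted values ẑ_ij; (b) prune
   components whose share Q_j = Σ_i ẑ_ij / Σ_kΣ_i ẑ_ik falls below the
   share threshold (default 0.05 — a component explaining under 5% of the
   fitted mass is treated as noise; pruning precedes the responsibility
   step, so responsibilities are always computed from survivors);
   (c) split each observation by responsibilities q_ij = ẑ_ij/Σ_k ẑ_ik and
   re-fit every component — including its summit, by the root-finding
   procedure — from (t_i, x_i·q_ij). Points where every ẑ underflows to
   zero are left unassigned for that iteration.

Because the re-fit step is moment-based rather than a likelihood ascent,
the iteration has no monotonicity guarantee and can oscillate on noisy
traces. The loop therefore tracks the best iterate by RSS over the observed
points and stops either when the largest relative parameter change drops
below `tol` (default 1e-4, max 100 iterations) or after 5 consecutive
iterations without RSS improvement, returning the best iterate. A
component whose re-fit fails from starvation keeps its previous parameters
and is left to the pruning rule; if pruning ever removes everything, the
fit falls back to a single peak on the full trace.

## Choosing the number of components

The smoother bandwidth controls the initial segmentation, and on noisy data
different bandwidths give different component counts. The fit is run from a
grid of bandwidths — by default 5 log-spaced values from 2× the median time
spacing to a third of the trace's span, a deliberately lenient range of
plausible peak widths — and the model minimizing

    BIC = N·log(RSS/N) + p·J·log(N)

is kept, with p = 4 per bi-Gaussian component and p = 3 for the symmetric
Gaussian baseline. Ties break toward fewer components, then the smaller
bandwidth. An RSS of exactly zero (noiseless interpolation) is clamped to
1e-12 × the signal energy to keep the criterion finite. With correlated
chromatographic errors BIC is a heuristic; it is validated by the
simulation benchmark rather than by asymptotic argument.

## Baselines

The Gaussian mixture baseline is the identical pipeline with σ₁ = σ₂
enforced as the pooled two-sided weighted second moment about α̂ and 3
parameters per component in the BIC. Signal summation quantifies each
valley-delimited segment as Σ x_iΔt_i of the raw intensities — the smoother
only draws the segment boundaries; whether the original comparison summed
raw or smoothed values is not recorded, and raw summation is the method the
name describes.

## The simulator and benchmark

Traces are drawn as x_i = Σ_j g_j(t_i)·e^{ε_i}·u_i with ε_i ~ N(0, ξ²) and
u_i = 0 with probability θ (so θ is exactly the expected fraction of zeroed
intensities). Defaults mirror the study conditions: ξ ∈ {0.2, 0.4, 0.6},
θ ∈ {0, 0.25, 0.5}, n = 100 uniformly spaced points spanning the summits
± 4 max σ — LC-MS traces carry far fewer points than classical
chromatograms. At ξ = 0.6 roughly 50% of intensities move by ≥1.5-fold and
25% by ≥2-fold (2(1−Φ(ln k/ξ)) tail probabilities).

Overlap between peaks is summarized by r = (lowest valley point between two
adjacent summits) / (lower of the two summit heights) on the noiseless
mixture, taking the largest r when there are several valleys; categories:
little r < 0.2, moderate 0.2 ≤ r < 0.5, strong 0.5 ≤ r < 0.75, severe
r ≥ 0.75. r is snapped to 12 significant digits so float jitter cannot flip
a boundary category.

The exact component-parameter table behind the original 864-setting grid is
not recorded here, so the default grid is the package's own construction,
chosen once: three components with left SD 0.4 min, shared asymmetry ratio
σ₂/σ₁ ∈ {1, 2, 3}, amplitudes δ = (1.0, 1.6, 0.7)×10⁵ (realistic ion-count
scale, unequal so the overlap ratio has a well-defined lower summit), and
summit spacings solved by a 1-D root-finder so the noiseless mixture hits
the midpoint of each overlap category (r = 0.10, 0.35, 0.625, 0.85). All of
it is overridable through `SimulationConfig` / `components_for_overlap`.

The benchmark (`evaluate_methods`) runs each method on identical seeded
replicates per setting and reports the correct-J selection rate and,
conditional on selecting the true J, the mean absolute percentage area
error with fitted components matched to truth by greedy nearest-summit
assignment (the original matching rule is not recorded); signed bias and
location/spread errors are also emitted. Signal summation has no model
selection, so a replicate counts as a success for it if any bandwidth in
the default grid yields the true number of segments. The acceptance script
uses 100 replicates per setting over the asymmetry {2, 3} × overlap
{0.10, 0.35} × ξ × θ grid — problem sizes chosen so the whole benchmark
runs in about a minute on one core while keeping the Monte-Carlo error on a
per-setting rate near 3 percentage points.

## What the simulator does and does not emulate

It reproduces multiplicative log-normal noise, missing intensities, peak
asymmetry and partial overlap — the four failure modes the method targets.
It does not emulate baseline drift, co-eluting chemical background,
detector saturation, retention-time warping across samples, or
heteroscedastic electronic noise at the trace floor. Passing benchmarks
therefore demonstrate robustness to noise/dropout/overlap under the bi-
Gaussian generative family, not end-to-end performance on raw instrument
data.

## Known limitations

- The summit search assumes a single dominant sign change of Â−B̂; heavily
  multimodal weighted traces inside the EM loop rely on the interpolation
  rule described above.
- The EM-like loop optimizes no single objective; the best-RSS safeguard
  bounds, but does not eliminate, sensitivity to initialization.
- BIC's error model (i.i.d. Gaussian residuals) is knowingly wrong for
  chromatographic data; its use is empirical.
- Raw mzML/mzXML parsing, retention-time alignment and cross-sample
  normalization are out of scope; input is a two-column delimited trace.
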