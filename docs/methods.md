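# Methods

## Model and derivation

Probe occurrences along a chromosome are modelled as a homogeneous
Poisson process with rate λ (probes per kb), so inter-probe gaps
wᵢ = sᵢ − sᵢ₋₁ are iid Exponential(λ); each probe carries a Gaussian
log2 intensity ratio. The chromosome is cut into n subintervals with
lengths tᵢ and probe counts Nᵢ ~ Poisson(λᵢtᵢ). The change-point
hypothesis states that after an unknown subinterval k the Gaussian mean
steps from μ₁ to μₙ (common variance σ²) and the occurrence rate from
λ_pre to λ_post.

Priors: uniform on k over 2..n−1, flat on (μ₁, μₙ), Jeffreys
p(σ²) ∝ 1/σ². Integrating the two-segment Gaussian likelihood over μ₁
(a Gaussian integral contributing m^(−1/2)), μₙ (contributing
(M−m)^(−1/2)) and σ² (a Gamma integral contributing
Γ((M−2)/2)·(R/2)^(−(M−2)/2) with R = A − B²/m − C²/(M−m)) gives the
marginal evidence

    g(k) = [m(M−m)]^(−1/2) · R^(−(M−2)/2),

where m = Σᵢ≤ₖ Nᵢ is the number of observations through subinterval k
and A, B, C are the sufficient statistics defined in the README. The
split is taken at the observation level — every log ratio enters the
evidence, not per-bin summaries. The full weight multiplies in the
count probability P(k) = Πᵢ Pois(Nᵢ; λ̂tᵢ) at the segment rate MLEs,
and the posterior is the normalised weight. Because the MAP maximises a
monotone transform of R(k) (up to the weak [m(M−m)]^(−1/2) prefactor
and the Poisson factor), the estimator is numerically close to the
least-squares change point; the posterior's value is the calibrated
probability it attaches to each candidate.

Candidates whose split leaves fewer than two observations on a side are
excluded (the flat-prior marginal is not integrable there), as are
splits with R ≤ 1e−12·max(A, 1) (exactly piecewise-constant data, where
the evidence diverges). All evidence is accumulated in log space and
normalised by softmax with max-subtraction. MAP ties break toward the
smallest k, making output deterministic.

### Rate regimes

The count model defaults to two regimes (pre: subintervals 1..k
inclusive; post: k+1..n). A three-regime variant — the change
subinterval k carrying its own rate — is available via
`rate_regimes=3`; the two-regime form is the default because the
change subinterval belongs to the pre-change segment under the locus
convention (τ = last probe of subinterval k) and one-interval rate
estimates are noisy.

## Numerical validation (quadrature oracle)

`cpcm.oracle.numeric_evidence` recomputes the Gaussian evidence by
tensor-product quadrature of likelihood × prior over a finite box in
(μ₁, μₙ, σ²), for sequences of at most 16 observations. Design points:

* σ² is integrated on the log scale, where its posterior peak has O(1)
  width; the 1/σ² prior cancels against the Jacobian.
* The mean dimensions use composite Gauss–Legendre panels graded
  geometrically toward the box centre (half-width fractions 1, 1/2, …,
  1/32), because the integrand's peak occupies a tiny fraction of the
  default box (mean ± 15 sample sd); a single global rule at the same
  node count leaves ~1e−2 relative error, the graded rule ~1e−6 at 128
  nodes per dimension.
* The truncation check integrates the six-slab shell between the box
  and a doubled box and raises if the shell holds more than 1e−6 of the
  total mass. Comparing two full-box quadratures instead would measure
  discretisation differences, not truncation. The default box
  (±15 sd, σ² within var×[1e−4, 1e4]) passes this check for the sizes
  the oracle accepts; the earlier, narrower σ² bound of var×100 was
  widened after the shell integral showed it truncates ~2e−6 of mass at
  M = 8 (the σ² posterior tail decays only polynomially).

The release gate asserts that log(numeric) − log(closed form) is
constant across all admissible splits m to within 1e−3 (measured spread
is ~1e−6 at default resolution).

## Binning and windows

* Equal-count binning places interior edges at the midpoint between the
  bounding probes of adjacent bins, so subinterval lengths reflect
  genomic extent; counts differ by at most one, surplus to leading
  bins. Equal-width binning errors out if a bin would be empty. Both
  enforce 1–300 observations per subinterval. Membership is half-open
  [left, right), final bin closed.
* Default n when unspecified: ⌊n_probes/10⌋ clipped to [3, n_probes]
  (~10 observations per bin keeps the per-bin evidence informative).
* Windows advance by step = round(window·(1−overlap)), clamped to
  window−1 so neighbouring windows always share at least one
  subinterval; the last window is end-aligned. Default window 20 at 50%
  overlap: every interior subinterval is interior to some window,
  mitigating window-edge effects.
* Calls from overlapping windows within one subinterval of each other
  are merged, keeping the higher posterior. An optional stability sweep
  (`stability_sweep`) re-runs the scan at window sizes {12, 15, 20, 25,
  30, 35} and reports calls declared at three or more sizes — a
  practical reading of "choose the window size where the posterior
  stabilises".
* Declaration threshold 0.5 on the maximum posterior (a probability
  exceeding one half); `estimate_change(cp, 0)` gives the pure MAP.

## Gap diagnostic

The homogeneous-Poisson assumption is checked by a Kolmogorov–Smirnov
statistic of the gaps against Exponential(1/mean gap). Since the rate
is estimated from the same data the plug-in null is anti-conservative,
so the p-value comes from a parametric bootstrap (default 500
replicates, seedable; the minimum attainable p-value is 1/(n_boot+1)).
Below 8 gaps the p-value is reported as undefined.

## Synthetic data generator

`simulate_compound_poisson` draws probe gaps iid exponential (rate
switching at the change boundary) or on a unit grid
(`spacing="equal"`), and Gaussian ratios with the pre-change parameters
through subinterval τ and post-change parameters after. Default study
conditions: mean shift 0.7 at common sd 0.15 — the strong end of the
0.36–0.7 mean-difference and 0.05–0.2 sd-difference ranges observed in
fibroblast aCGH benchmarks — one observation per subinterval, equal
spacing, 1,000 replicates, changes at n/4, n/2 and 3n/4. Replicate r of
a scenario is seeded by the pair (scenario seed, r), so any replicate
is reproducible in isolation.

What the generator does **not** emulate: outliers and heavy tails in
real log ratios, spatial autocorrelation from smoothing or dye bias,
variable probe quality, missing values, and within-segment trends.
Passing tests therefore demonstrate correctness of the estimator under
the model's own assumptions, not robustness to real-data artefacts.

## Estimator accuracy and its ceiling

At the default study conditions the shift is ≈4.7 within-segment sd.
The dominant error mode of the MAP is misassigning one of the two
observations adjacent to the boundary, with probability ≈ 2·Φ(−δ/2σ) ≈
2% — independent of sequence length. Exact-recovery frequency
consequently plateaus at ≈97–98.5% for n ≥ 20 (MSE ≈ 0.02–0.04, almost
entirely from ±1 misses); it does not approach 1 as n grows unless the
per-observation effect grows too. The simulation study, the acceptance
script and the examples all report values computed at run time under
these conditions.

## Problem sizes

Defaults used by the shipped studies: 1,000 replicates per scenario in
`scripts/acceptance.py` (15 scenarios, n up to 120; ~40 s on one CPU)
and 200 replicates in the reduced trend check; the quadrature oracle is
restricted to M ≤ 16 observations by design. These sizes are the
package's chosen balance between Monte-Carlo error (±0.5% on a 97%
frequency at 1,000 replicates) and turnaround.

## Known limitations

* Single change per window: a window straddling two true changes
  reports at most one; window sizes must be chosen so each window
  contains at most one aberration.
* The Poisson factor uses plug-in MLE rates, not a marginalised rate
  model, so it mildly double-uses the counts (as in the underlying
  derivation).
* No multiple-testing control across windows or chromosomes; the 0.5
  threshold is heuristic.
* Gain/loss labelling is left to the sign of the mean difference;
  absolute copy-number states are out of scope.
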