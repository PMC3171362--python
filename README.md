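# cpcm — Bayesian compound-Poisson change-point detection of CNV loci

`cpcm` locates DNA copy-number variation (CNV) breakpoints in aCGH-style
data. Array CGH reports, for every probe (clone/biomarker) with a known
genomic position, the log2 ratio of test to reference hybridisation
intensity; a copy-number gain or loss shows up as a step in the mean of
those ratios. Most segmentation methods use only the ratio sequence;
`cpcm` additionally models the probe *positions*, treating probe
occurrences along the chromosome as a homogeneous Poisson process, so
that probe density and spacing inform the call. It is aimed at anyone
segmenting log-ratio profiles — aCGH, and by extension other
position-indexed intensity data with step changes.

## Model

The chromosome (total length *T*) is divided into *n* non-overlapping
subintervals with lengths *t₁,…,tₙ* and probe counts *N₁,…,Nₙ*
(each subinterval must hold between 1 and 300 observations). The probe
count of subinterval *i* is Poisson(*λᵢtᵢ*), so inter-probe gaps are iid
exponential — a testable assumption (`exponentiality_diagnostic`).
Each probe's log2 ratio *Xⱼ* is Gaussian. Under the change-point
hypothesis there is an unknown subinterval *k* such that

* *Xⱼ* ~ N(μ₁, σ²) for probes in subintervals 1..k, and
  *Xⱼ* ~ N(μₙ, σ²) afterwards;
* the probe rate is λ_pre up to *k* and λ_post after.

With a flat prior on *k* (range 2..n−1), flat priors on (μ₁, μₙ) and the
Jeffreys prior p(σ²) ∝ 1/σ², the means and variance integrate out in
closed form. Writing *m* for the number of observations through
subinterval *k*, *M* for the total, A = Σⱼxⱼ², B = Σⱼ≤ₘxⱼ,
C = Σⱼ>ₘxⱼ, the posterior over candidates is

    p(k | data) ∝ [m(M−m)]^(−1/2) · (A − B²/m − C²/(M−m))^(−(M−2)/2) · P(k),

where P(k) is the probability of the observed counts N₁..Nₙ under
segment Poisson rates at their maximum-likelihood values
λ̂_pre = Σᵢ≤ₖNᵢ / Σᵢ≤ₖtᵢ, λ̂_post = Σᵢ>ₖNᵢ / Σᵢ>ₖtᵢ. The MAP candidate
k̂ is the declared change subinterval when its posterior exceeds a
threshold (default 0.5), and the reported genomic locus τ is the last
probe contained in subinterval k̂. The closed form is continuously
validated against direct numerical integration (`cpcm.oracle`).

Multiple aberrations on a chromosome are found by an overlapping
sliding-window scan (window sizes 12–35 subintervals, default 20 at 50%
overlap): each window is analysed with the single-change posterior and
duplicate calls from overlapping windows are merged.

## Worked example

`examples/` holds one short script per capability. Detecting the single
simulated change of `examples/single_change_detection.py` (20
subintervals, ratio mean stepping 0 → 0.7 at sd 0.15 after subinterval
10, exponential probe gaps at 1 probe/kb) prints:

```
candidate k :     2     3     4     5     6     7     8     9    10    11    12 ...
posterior   : 0.000 0.000 0.000 0.000 0.000 0.000 0.000 0.021 0.960 0.017 0.001 ...

MAP change subinterval k_hat = 10 (true: 10)
posterior at the MAP         = 0.9601
declared genomic locus tau   = 6.31 kb
```

The posterior concentrates on the true change subinterval (probability
0.96, well above the 0.5 declaration threshold), and τ = 6.31 kb is the
position of the last probe of the pre-change regime: the mean log2 ratio
shifts immediately after it. The other examples demonstrate the
sliding-window scan with BED export, the exponential-gap diagnostic, and
the simulation study of estimator accuracy.

The same analyses are available from the shell:

```bash
cpcm detect --input probes.tsv --chrom 9  --bins 12 --out-prefix chr9
cpcm scan   --input probes.tsv --chrom 17 --window 20 --bed --out-prefix chr17
cpcm simulate --scenario scenario.yaml --out report.tsv
```

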