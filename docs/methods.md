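# Methods

This note documents the models and procedures implemented in `admixhist`,
the parameters that matter, the design choices made where the design was
genuinely open, and the limitations a user should know before trusting the
output on real data.

## The ordering test (Admixture History Graph)

**Model.** Consider individuals from a population founded as a mixture of
two sources A and B, later receiving a pulse of a third source C. Writing an
individual's pre-pulse composition as (a_i, 1 − a_i) and its C proportion as
c_i, the observed Q row is ((1 − c_i) a_i, (1 − c_i)(1 − a_i), c_i). The
ratio r_i = q_iA / (q_iA + q_iB) = a_i is untouched by the pulse, so
cov(r, q_C) = cov(a, c), which is zero whenever the founding composition and
the later pulse vary independently across individuals. For the two wrong
orderings the analogous covariance is generically non-zero. The test
evaluates all three candidates of a trio and selects the one minimizing the
absolute covariance; for K > 3 components every trio of components is
evaluated (later events scale all trio components equally and so do not
break the zero-covariance property of embedded trios), and the full order is
peeled newest-first by counting, among the components still in play, which
one the trios fully contained in that set most often chose as recent.

**Choices.**
- The ratio is parameterized as A/(A+B) rather than A/B: bounded, defined
  whenever A + B > 0, and carrying the same independence property.
  Individuals with A + B = 0 are excluded (error if more than half are).
- Covariances are population (1/n) covariances. Selection compares absolute
  values, so the normalization cannot change the inferred order; the reported
  magnitudes match the worked 4-individual example (wrong orderings give
  |cov| ≈ 0.0106 there).
- Candidates whose covariance is undefined (zero variance in the candidate
  column or the ratio) are flagged and excluded from selection, never chosen
  silently.
- Per-trio `margin` is the second-smallest-to-smallest |cov| ratio (∞ when
  the smallest is exactly zero); vote ties during peeling are broken by the
  larger mean margin and an exact tie after that is an error rather than a
  guess.
- Components with mean proportion below `min_prop` (default 0.05) are
  dropped with a warning before ordering: below ~5% the covariance signal is
  too weak to rank reliably. A second warning fires when all component
  variances are within a factor of 2 of each other, the regime in which
  covariances are obscured.
- An optional permutation test reports, per trio, the probability that a
  random assignment of the candidate column across individuals yields an
  absolute covariance at most as small as observed
  (p = (1 + #{|cov_perm| ≤ |cov_obs|}) / (B + 1)).
- `run_consistency` aligns replicate clustering runs by maximal column
  correlation (Hungarian assignment; error below 0.8), infers a graph per
  run and reports the modal graph with the fraction of runs agreeing.

**Sample-size dependence (important limitation).** Under the panmictic
pulse model, a few generations after an event individuals no longer differ
in *expected* ancestry (pedigree variance decays as 2^−g); the cross-
individual variation that powers the test is block-sampling noise, of order
mean-block-length / genome-length. Both the discriminating covariance and
its estimation noise then scale with 1/genome-length, so the recovery rate
depends essentially only on the number of individuals n and the block-length
contrast between old and recent ancestries. Measured on the default
validation genome (8 × 128 cM) with founding at g=60 and a 30% pulse at
g=20: recovery ≈ 0.85 at n = 25 individuals, ≈ 0.98 at n = 50, ≈ 1.0 at
n = 200; K = 4 orders need substantially larger samples again. Real data
with genuine inter-individual admixture heterogeneity (recent or continuous
gene flow, substructure) carry far more signal than this worst case. The
package reports per-trio margins and permutation support so that borderline
orderings are visible rather than silently overconfident.

## Block signals, Haar spectra and the wavelet center

For dating, the panel is reduced to two populations: every ancestry older
than the event under study maps to population 1 (−1), the event's ancestry
to population 2 (+1), MASKED/UNRESOLVED windows to 0. Chromosomes carry 2^n
equal-genetic-width windows (the human default: 1024 windows on chromosomes
1–8, 512 on 9–18 and 20, 256 on 19, 21, 22), so the orthonormal Haar
transform applies exactly; with that convention the coefficient-count-
weighted per-scale powers sum to the population variance of the signal
(Parseval), which the tests verify to 1e-9.

Per-scale energies are pooled over haplotypes and chromosomes *on the
genetic block-width axis* (window width × 2^j cM), so mixed window schemes
combine coherently; the **wavelet center** is the energy-weighted mean
dyadic scale of the pooled normalized spectrum, expressed in dyadic steps
above the finest window width (equal to Σ j·p_j on a uniform grid). Older
events leave narrower blocks, moving energy to finer scales and lowering
the center; the relation is strictly monotone over g ∈ [10, 160] in the
validation runs (Spearman ρ ≈ −0.98).

Block-length summaries (per-ancestry run lengths, means, variances, CDFs)
are computed on the rasterized grid, so lengths are quantized to the window
width and runs are split at masked windows; comparisons against the
continuous closed form 100/(g(1−m)) cM are made either on the simulator's
continuous tracts or on a fine (0.125 cM) grid where quantization bias is
small. Midpoint rasterization at the default 0.5 cM window width inflates
mean run lengths by ~10–15% at g = 50 because sub-window tracts vanish and
sub-window gaps merge runs.

## The forward simulator

Discrete non-overlapping generations of N diploids; random mating with
replacement; each offspring haplotype is one meiosis of a uniformly drawn
parent with Poisson(L Morgans) crossovers placed uniformly on the genetic
map (no interference) and independent chromosome assortment. Migrants enter
as unadmixed individuals, a deterministic round(m·N) of the generation being
formed; continuous gene flow is a run of equal per-generation pulses.
Tracts are stored run-length-compressed as ancestry junctions; the kernel is
numba-compiled and draws its randomness in bulk per generation (children are
constructed in parent-sorted order purely for memory locality and permuted
back; parent assignments remain i.i.d.). A fixed seed reproduces the output
exactly.

The sampled cohort is returned in three matched forms: continuous tract
lists, a window-rasterized panel (window midpoint label), and a Q matrix of
genetic-length-weighted diploid ancestry fractions (consistent to 1e-9 with
the tracts). `apply_call_noise` models local-ancestry caller error by
reassigning each callable window to a uniformly random different label with
a given probability.

**What the generator emulates / does not.** It reproduces pulse and
continuous admixture, drift at finite N, recombination-driven tract-length
distributions (mean pulse-tract length matches 100/(g(1−m)) cM within a few
percent at N = 1000), and caller noise. It does not model crossover
interference, mutation or selection, phasing switch errors with spatial
structure, population substructure, or the reference-panel biases of real
local-ancestry inference — so passing validation here demonstrates the
statistical machinery, not robustness to every artifact of real calls.

**Default problem sizes.** The validation genome is desk-scale — 8
chromosomes × 128 cM, 256 windows (0.5 cM) each, N = 500 diploids, samples
of 20–50 individuals; the two-pulse sequential-dating validation uses
N = 300 with mask-matched calibration. These sizes were chosen as the
smallest at which the tract-length and spectral statistics are stable; the
ordering test's accuracy is genome-size-invariant (see above), so the
reduced genome does not weaken that check.

## Calibration and sequential dating

A calibration table records the mean and spread of the wavelet center over R
(≥ 20) single-pulse simulations per (g, m) cell, simulated under the same
genome, window grid, N and sample size as the data, and — crucially — with
the observed mask applied at the identical window positions to every
simulated signal. This is how the reduction in usable genome after masking
is taken into account; a length-matched randomized-mask mode (per-
haplotype circular shifts) is available as an alternative. Tables carry full
provenance (seed, N, R, grid scheme, mask fingerprint) and serialize to
JSON.

Estimation selects the m column nearest the observed admixture rate (the
fraction of population-2 windows among callable ones; no interpolation
across m — the center is nearly flat in m), enforces monotonicity of the
center–g means with an isotonic fit, and inverts by linear interpolation.
Centers outside the calibrated range raise a "beyond calibrated range"
error — dates near the resolution limit are reported as undatable rather
than extrapolated. Confidence intervals resample chromosomes with
replacement (200 draws), re-pool the spectrum and re-invert; the interval is
widened to contain the point estimate if needed. Generations convert to
years by a configurable generation time (default 29 years/generation,
recorded in every report).

`date_events` walks an inferred arrival order newest-first: merge older
components into population 1, estimate, mask the dated component, repeat;
the founding pair is finally dated against each other (the lower-proportion
member as population 2) under the cumulative mask. Components absent from
the graph (e.g. dropped below `min_prop`) are masked up front with a
warning. Dating refuses to continue once more than 80% of the genome is
masked. Measured on a founding-at-100 / pulse-at-25 history, the masked
older-event estimate is mildly biased (≈ −8%, from residual correlation
between mask placement and the underlying block process) but far closer to
truth than the naive unmasked two-way collapse (≈ −25%), which is the error
mode sequential masking exists to fix; single-pulse estimates are unbiased
to within ~3%.

## Numerical and degenerate-input conventions

- Q rows must sum to 1 within 1e-3 (rounded text output of upstream tools)
  and are renormalized exactly; larger deviations are rejected with the row
  index.
- Window grids are exact partitions (widths sum to the chromosome length to
  1e-9 cM); window counts must be powers of two.
- Tract files use 0-based half-open cM intervals; windowed files 0-based
  window indices; masks serialize as the literal token `MASKED`. Windowed
  round trips are lossless including posteriors; calls with posterior below
  the acceptance threshold (default 0.9) become UNRESOLVED on read.
- Constant (single-ancestry) signals yield all-zero Haar power and are an
  error at the pooling stage ("cannot date: single ancestry").
- All stochastic entry points take explicit seeds; identical seeds give
  byte-identical outputs (the simulator kernel uses numba's MT19937 stream).
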