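# Methods

## The measurement model

A chronological-lifespan competition assay mixes an RFP-tagged query strain
1:1 with a CFP-tagged wild-type reference, lets the co-culture reach
stationary phase, and then — at age zero (defined as day 5 post-inoculation)
and roughly every 2–3 days up to day 23 — inoculates a small aliquot
(5 µl into fresh medium) and reads both fluorescence channels plus OD600
every 3 h for 15 h of outgrowth.

The analysis rests on two exponential assumptions:

1. **Stationary phase.** Both populations die at constant exponential rates
   `r_x`, `r_wt` (per day), so `ln N_x(T)/N_wt(T)` is linear in age `T`.
2. **Outgrowth.** Both populations grow exponentially at `g_x`, `g_wt`
   (per hour) during the read window, so `ln R/C` is linear in outgrowth
   time `t`, and its value at a fixed `t*` equals the (log) viable-cell
   ratio at inoculation plus the constant `(g_x − g_wt) t*`.

Evaluating the log-ratio at a *fixed time* rather than a fixed density is
what decouples death-rate differences (the slope over ages, the quantity of
interest) from growth-rate differences (an intercept shift only). The
survival coefficient `s = r_wt − r_x` is bounded above by `r_wt`; beyond the
bound the implied mutant death rate is nonpositive and the half-life
`λ_x = ln2/(r_wt − s)` is reported as undefined (`NA`) with an
`exceeds_bound` flag.

## Stage-by-stage choices

**Background correction.** Each channel's background is modelled as an
affine function of OD600 (`a + b·OD`), fitted by OLS to the pooled readings
of single-color control wells that *lack* the channel's fluorophore. Affine
is the minimal model consistent with a density-dependent
autofluorescence/crosstalk term and is exactly invertible in tests; the
fitted OD range is stored and extrapolation beyond it flagged. Corrected
signals `RFP = RFPraw − RFPbg(OD)`, `CFP = CFPraw − CFPbg(OD)`; timepoints
where either corrected signal is nonpositive are dropped and counted.

**Interpolation at t\*.** `t* = 10 h` by default. Because `ln R/C` is
exactly linear in `t` in-model, linear interpolation between the flanking
reads is exact; if `t*` falls outside the read span, the nearest segment is
extended up to 1.5 h (covering one missing read), otherwise the age is
unusable (`too_few_points`). Values outside the calibrated dynamic range
[−3.5, 2.5] are *excluded* from the age regression, not clamped — they are
range limits of the instrument, not data. `calibrate_dynamic_range` can
re-derive the range from a defined-mixture dilution series (largest
contiguous stretch with local slope within 20 % of unity); the defaults are
retained unless a calibration overrides them.

**Survival fit.** Per well, the slope of `ln R/C^t*` vs age over ≥3 distinct
usable ages. The robust method is iteratively reweighted least squares with
Tukey bisquare weights, tuning constant 4.685 (95 % Gaussian efficiency),
scale re-estimated each iteration as MAD/0.6745 of the residuals. Standard
errors use the Street–Carroll–Ruppert sandwich (the MATLAB `robustfit`
convention): `σ̂² = s²·Σψ(u)²/(n−2) / (mean ψ′(u))²` applied to `(XᵀX)⁻¹`.
Degenerate case: when the residual scale collapses (a perfect line, possibly
after full rejection of a gross outlier) the iteration stops, points on the
line keep weight 1, rejected points weight 0, and the error reduces to the
classical OLS error over retained points. On outlier-free data the robust
fit coincides with OLS to machine precision; fits whose minimum weight drops
below 0.5 carry an `outlier_downweighted` flag (adaptive regrowth is
*detected* this way, never modelled in the fit). Plain OLS is available for
oracle comparisons.

**Batch normalization.** `s_corr = s_raw − center(s_raw of the batch's
WT-control wells)`. The center defaults to the *median* (the screen-wide
convention) with *mean* exposed as an option because the batch-illustration
protocol describes per-batch mean subtraction of eight WT controls — the two
conventions are a configuration choice, not silently resolved. Batches come
from the layout; they are never inferred. By construction the corrected WT
distribution is centered on zero per batch, which removes additive batch
effects entirely.

**Hit calling.** `Z = (L − 1)/sd(L_WT)` with the WT standard deviation taken
about the WT pool's own mean (robust to residual miscentering); two-tailed
normal p; Benjamini–Hochberg q (chosen as the standard q-value-compatible
FDR procedure, the screen statement naming only "FDR, q<0.05"); classes by
the sign of `L − 1` among q < 0.05. Short-lived calls with growth capacity
`G < 0.95` are flagged `growth_filtered` (a general growth defect can mimic
short survival); long-lived calls are never growth-filtered. A chi-square
goodness-of-fit check of the WT pool against a fitted normal
(equal-probability bins, ≥5 expected per bin, dof reduced by the two
estimated moments) is provided as a diagnostic gate for the Z machinery.

**Growth capacity.** `G = gr_x/gr_wt` from OLS of `ln(OD − blank)` over the
2–10 h window (≥3 positive points), referenced to the per-batch mean WT
rate. In co-culture the OD mixes both strains, so OD-derived `G` is an
approximation; an externally measured per-gene `G` table takes precedence
when supplied. Enrichment analyses default to the looser `G > 0.9` filter,
hit-list specificity to `G > 0.95` — both thresholds are exposed because the
two analyses historically used different cuts.

**GO enrichment.** Per term (5–60 measured genes after the `G` filter), the
term's `L` values are compared to the *entire* filtered data set — term
genes included in the background, matching the screen's definition — by a
two-sided Wilcoxon rank-sum test. Small samples (pooled ≤50, smaller sample
≤25) use exact enumeration of the permutation distribution, computed by
dynamic programming over doubled midranks so ties are handled exactly;
larger samples use the tie-corrected asymptotic test. The two-sided p is
`2·min(P(W≤w), P(W≥w))`, capped at 1.

**Condition confirmation.** A primary short/long call is confirmed in a
second condition (e.g. aging in water) when its second-condition `L` escapes
the central 95 % interval of that condition's WT replicate distribution *on
the matching side* — the one-sided reading of an interval rule whose
sidedness the original description leaves open.

**Epistasis.** Replicates pool by inverse variance (`w_i = 1/σ_i²`,
`σ̄ = (Σw_i)^(−1/2)`); marker-swap and single-knockout replicates are treated
identically. The neutral model is multiplicative by default
(`ε = L_xy − L_x L_y`), additive optionally; the two differ identically by
`(L_x−1)(L_y−1)`, which is why the additive definition biases deleterious
pairs positive. Errors propagate to first order (delta method) — validated
against Monte-Carlo resampling to within 10 % for σ ≤ 0.05; the omitted
second-order term `σ_x²σ_y²` is negligible at these error levels. Calls use
the normal `z` at the configured CI (1.96 at 95 %; a t-quantile on the
pooled replicate count is available), with no multiplicity correction —
interactions are per-pair CI statements. Positive interactions are oriented
from the larger to the smaller single-knockout effect (`|L − 1|`) when
`|L_x − L_y| > z·sqrt(σ_x² + σ_y²)`; both deviations are near-linear in `L`,
so the test is on the difference of the `L`s themselves.

**Profile clustering and network.** Gene × gene matrix of raw ε (symmetric,
diagonal masked, untested pairs missing). Distance between two genes is
`1 − Spearman ρ` over the partners *both* profiles cover, excluding the two
genes themselves (the mutual entry would let a single pair dominate);
missing entries are excluded pairwise rather than imputed, which would
fabricate rank structure, and a pair sharing fewer than 3 partners is an
error. Complete-linkage merging; the default cut is a height cut at 0.7 ×
the maximum merge height (no cut criterion is canonical; k-based cuts are
available). The network keeps one undirected edge per significant pair with
ε, sign and optional direction as attributes; module-level excess of
positive interactions is tested one-sided by Fisher's exact test on the
(within-module × positive-call) contingency over all scored pairs.

## The simulator

`synthetic_data` emulates the study conditions end to end: exponential death
from age zero with sampling at days 0, 2, 5, 7, 9, 12, 14, 16, 19, 21, 23;
5/700 dilution into outgrowth; reads at 3, 6, 9, 12, 15 h; shared hard
carrying capacity (a cap, not logistic dynamics — the pipeline only uses
exponential-phase reads, so the cap merely exercises QC); OD600 =
κ·cells + blank; per-channel signal = yield·own-cells + affine background of
OD; multiplicative log-normal noise on fluorescence and OD; scattered
WT-control, single-color and blank wells per batch; optional Poisson
inoculum sampling (default off so zero-noise closed forms hold exactly); and
optional adaptive regrowth (exponential viable-cell increase after a switch
age — the simplest mechanism producing the nonlinearity that the robust fit
and water-aging confirmation guard against).

Per-batch offsets `δ_b` model batch effects as an additive shift of the
measured log-ratio slope, implemented by perturbing the RFP-side death rate
in that batch (shifting both members of a co-culture would cancel in the
ratio and produce no batch effect at all). WT-median normalization must —
and does — remove them exactly.

Defaults are the study conditions where stated (ages, read times, inoculum,
a WT reference with a 21.7-day half-life, mix fraction 0.5). The assay's
measurement-noise magnitudes are not characterized anywhere, so the noise
defaults are this package's calibration choices, fixed once: 5 % CV on
fluorescence and OD (ordinary plate-reader repeatability, and the level at
which the parameter-recovery guarantee is stated) and a batch-offset SD of
0.005/day (comparable to the largest mutant effects, so normalization is a
nontrivial, testable step). Fluorescence yields, background coefficients and
OD-per-cell are arbitrary instrument units chosen so that signal dominates
background during the read window.

What the simulator does *not* emulate — and hence what passing tests do not
establish about real data: cell-to-cell heterogeneity within a well,
acetic-acid/aeration chemistry, strain–strain interactions beyond the shared
carrying capacity, non-exponential death kinetics, and lag-phase variation
beyond a fixed per-strain lag. Parameter recovery on simulated data
validates the inference machinery, not the biology of any particular strain.

## Problem sizes and numerical choices

The test suite and acceptance script size their simulations for desk-scale
runs, as the package's own verification choices: 96 strains × 11 ages × 5
reads for parameter recovery; 50 all-null screens of 380 strains + 40 WT
wells for FDR control; 2000 simulated pairs (plus 50k Monte-Carlo draws) for
epistasis calibration; exact-enumeration cross-checks at term ≤8 against
pooled backgrounds ≤25 and networks ≤20 genes. The false-call-rate check of
a correctly calibrated 95 % CI is asserted against the binomial sampling
envelope of the nominal 5 % level (`0.05 + 2·sqrt(0.05·0.95/n)`), since a
calibrated procedure sits *at* 5 % in expectation and a literal `≤ 5 %`
assertion on a finite simulation would fail half the time by construction.

Other numerics: `half_life(0, λ_wt)` returns `λ_wt` exactly (short-circuited
to avoid the `ln2/(ln2/λ)` floating-point round trip); IRLS convergence
tolerance 1e−10 relative with a 50-iteration cap; equal ranks use average
midranks everywhere; well labels are normalized to zero-padded `A01` form;
all ages are days since age zero (not days since inoculation), stated in
every written table header; missing values are written as `NA`; and every
pipeline run serializes its configuration and a SHA-256 manifest of outputs,
so identical config + seed reproduce byte-identical tables.

## Known limitations

* The survival model is deterministic two-rate exponential; Gompertz/Weibull
  survival and explicit adaptive-regrowth modelling are out of scope (the
  robust fit only down-weights and flags such wells).
* OD-derived growth capacity in co-culture is approximate (see above).
* The GO layer takes the gene→term mapping as given: no DAG propagation or
  term-similarity collapsing.
* Relative lifespans can exceed the `s ≤ r_wt` bound when measurement error
  is large; such records keep their `L` but an undefined half-life and an
  `exceeds_bound` flag, leaving the tension between the bound and extreme
  observed values visible rather than resolved.
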