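# Methods

## Scope and data model

`epiland` analyses combinatorially complete landscapes: all 2^n genotypes of
n biallelic loci, each with a measured enzyme function. Genotypes are 0/1
strings in the locus order declared by the landscape header (leftmost
character = first declared locus); internally they are integers with bit i
carrying the state of locus i. All analysis happens on log10 fold-changes
relative to the wild type: raw replicate values are averaged arithmetically
on the raw scale, divided by the wt mean, and log10-transformed, so
value(wt) = 0 exactly. Additive-scale traits (growth rates) are first mapped
through 10^v so that the subsequent normalization treats them
multiplicatively. Non-positive raw means are rejected rather than floored: a
pseudo-count would fabricate epistasis.

The built-in registry mirrors the structure of 41 published landscapes over
seven enzymes. Only the structural facts (loci per landscape, conditions per
study, trait class, subset flags) enter any computation; condition labels
that the compiled sources do not print (e.g. the full antibiotic panel, the
DHFR antifolates, MPH metals) are placeholders. Three flagged subsets are
carried: *reduced* (one landscape per enzyme/mutation set, to control
cross-landscape correlation), *structural* (kcat/KM, Ki and lysate-activity
readouts, 15 landscapes / 544 measurements, used for transition analysis)
and *adaptive* (11 landscapes whose condition is the presumed selection
pressure, used for path predictions). The adaptive set is a documented
approximation: the original figure identifies it only by subtitles.

## Effects

The SME of locus i in background b is log10 F(b, i→1) − log10 F(b, i→0). The
order-k EE of locus set S is the difference recursion over any pivot
j ∈ S; the implementation uses the lowest index, and a separate
inclusion–exclusion oracle (the full alternating sum over subsets of S,
including the background term) guards the identity in tests. The recursion
is the authoritative definition; the alternating sum follows algebraically
from it. Effects are computed on detilted values when the logistic
correction was selected, otherwise on the raw log10 values. All internal
math is double precision; report files round to 4 decimals at emission.

A landscape of n loci yields n·2^(n−1) SMEs and C(n,k)·2^(n−k) order-k EEs;
the census module evaluates these closed forms per registry entry and they
are verified against brute-force enumeration in the tests. Order-n
combinations occur in a single background and are flagged non-viable for
spread statistics.

## Global-epistasis correction

The correction models observed F as a four-parameter logistic of the
first-order background-averaged expectation F_add (OLS on the orthogonal
−1/+1 design). The logistic is compared with a linear null by AIC under iid
Gaussian errors, counting mean parameters plus one variance parameter
(k = 3 linear, k = 5 logistic); ties and non-convergence resolve to linear.
The fit is deterministic: U₀ = max F + 0.05·range, L₀ = min F − 0.05·range,
m₀ = median F_add, s₀ = 4/range(F_add). Fitted parameters are normalised to
U > L (the mirrored parameterisation with negated s is the same curve), so a
negative s simply denotes an increasing map.

Inversion (detilting) maps F′ = m − (1/s)·ln((F − L)/(U − F)); values outside
(L, U) are clamped to L+δ / U−δ with δ = 10⁻⁶(U − L) and counted. Detilted
values are re-centred on the wt so that value(wt) = 0 again, because all
downstream SME/EE math is wt-relative. A landscape is degenerate when more
than 90% of observed values lie within δ of a bound (binary collapse); the
90% cutoff and δ are explicit constants.

One subtlety motivates an extra refinement step. The first-order projection
of a nonlinearly squashed additive landscape is *not* an affine image of the
latent additive trait when the per-locus effects are heterogeneous, so a
single pass (fit F_add from observed F, then fit the logistic) cannot in
general reach a zero-residual solution even on noise-free squashed additive
data. `correct_global_epistasis` therefore iterates to self-consistency:
detilt with the current parameters, recompute F_add from the detilted
values, refit, until the parameters converge (tolerance 10⁻¹², cap 100
iterations). On noise-free squashed additive landscapes this recovers the
bound span exactly and removes all epistasis of order ≥ 2 to below 10⁻⁶. The
latent scale itself carries a gauge freedom — (m, s) trade off against an
affine rescaling of F_add — so detilted values match the generating latent
values exactly only when inverted with the generating parameters; what the
fitted pipeline guarantees, and what the tests assert, is the removal of all
non-additive structure.

## Heterogeneity

For each position (mutation × condition) and each combination (locus set ×
condition), three statistics summarise idiosyncrasy across backgrounds:

- **spread**: 2 × sample SD (n−1 denominator, appropriate at these small
  background counts); significant above τ = log10 1.5, with additional bins
  at log10 5 and log10 10. The thresholds are exact constants, not rounded
  decimals.
- **sign category**: positive-negative when both strict signs occur
  (regardless of neutrals); neutral-positive / neutral-negative when
  neutrals plus one strict sign; single-sign otherwise, *including*
  all-neutral units — this makes the four categories an exact partition.
- **wt vs average**: |wt-background effect − mean effect|, deviant above τ;
  sign-discrepant only when wt and mean are strictly opposite significant
  signs (significant-vs-neutral does not count), matching the rarity of that
  event in real data. A per-background variant counts every record whose
  effect deviates from its unit mean by more than τ.

τ = log10 1.5 is fixed. `derive_significance_threshold` exists to reproduce
its justification — the dataset median of per-genotype 2 SD of log10
replicate fold-changes — not to parameterise analyses. Note the median of a
2-replicate 2 SD statistic is ≈1.35σ, not 2σ; the test oracle is therefore a
Monte-Carlo simulation of the same statistic.

## Prediction

The biochemical model predicts log10 F(g) as the sum of wt-background
effects of all non-empty mutation subsets of g up to a maximum order; at
full order this is an exact decomposition (the grand identity, tested). The
background-averaged model is OLS with interaction columns (products of −1/+1
codes) up to the maximum order; the design is orthogonal on a complete
landscape, so truncation never changes retained coefficients and the
full-order fit equals the normalised Walsh–Hadamard transform (checked
against an explicit 2^n×2^n transform oracle). Absolute error is measured in
log10 units against the 1.5-fold line. Background-averaged residuals are
non-increasing in order (nested orthogonal least squares); biochemical AE is
*not* monotone in order, and the tests assert only the full-order identity.

The most accessible path is the greedy walk from wt that fixes, at each
step, the unfixed mutation with the highest resulting log10 F; ties break to
the lowest locus index, and the walk is total (it proceeds even if every
candidate decreases F, so non-adaptive landscapes still yield a defined
path). Endpoint predictions at order ≥ n are skipped as trivially exact.

## Transitions

For every locus set S with |S| = k ≥ 3 and every removable element, the pair
(EE_wt(S∖{j}), EE_wt(S)) is classified against τ: no_epistasis / no_change /
new_epistasis / change, the latter split into constructive (same sign) and
disruptive (opposite sign). Enhancing/diminishing is treated as synonymous
with constructive/disruptive. A landscape yields Σ_{k≥3} C(n,k)·k
transitions; the structural registry subset yields 1,027. Classification is
invariant under a simultaneous sign flip of both effects.

## Synthetic generator

The generator is the package's study-condition definition, not a tuning
knob. A latent log10 surface is built from per-locus additive effects
(explicit values, or one draw per locus from a stated normal — default
N(0.3, 0.3), reflecting mostly-beneficial adaptive mutations of a few fold)
plus planted interaction coefficients in one of two codings: *wt_background*
(a term contributes only when all its loci are mutated; these are exactly
the wt-background effects the recursion extracts) or *plus_minus_one* (the
Walsh basis; exactly the background-averaged betas). A documented conversion
maps either coding onto the other by evaluating the surface on the lattice
and re-extracting (inclusion–exclusion, or the normalised Hadamard
transform); planted coefficients are recovered exactly at zero noise by the
matching route, which is tested. Optional logistic squashing applies the
forward four-parameter map; replicate observations are 10^(latent + ε) with
ε ~ N(0, noise_sd²) per replicate, rescaled so the wt raw mean is 1. One
`numpy` Generator seeded from the single spec seed draws additive effects
first and noise second, so identical (spec, seed) is bit-identical.

What the generator does *not* emulate: genotype-dependent measurement error
(real assays are noisier near detection limits), missing or censored
genotypes, multi-allelic positions, and correlations between landscapes
sharing mutations. Passing tests on synthetic data therefore demonstrate
correctness of the estimators under the stated noise model, not robustness
to assay pathologies.

Under this model the wt-background EE of order k estimated from r replicates
has sampling SD σ·√(2^k/r) (an alternating sum of 2^k independent
log-values, each with SD σ/√r; the shared wt-normalisation offset and the
raw-scale-averaging bias cancel in the alternating sum), and the
background-averaged beta has SD σ/√(r·2^n) (orthogonal design). The
acceptance study verifies both by Monte-Carlo at 1,000 simulations,
σ ∈ {0, 0.05, 0.1}; problem sizes (n = 4, r = 2) keep the study well under a
minute while leaving the closed forms sharp.

## Known limitations

- The registry census reproduces published structure; running the
  heterogeneity/prediction/transition stages on the measured dataset
  requires the processed tables from the original publications, which are
  not redistributable here.
- The logistic is the only global-epistasis link (plus the linear null); no
  spline or I-spline alternatives.
- The iterative refinement assumes a single monotone global nonlinearity; on
  landscapes with genuine specific epistasis it simply converges to the best
  self-consistent logistic and leaves the residual epistasis in place, but
  no attempt is made to separate the two sources beyond model selection.
- Percentages in reports are rounded to 1 decimal, effect values to 4.
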