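# Methods

This note documents the statistical models and procedures implemented in
`refmix`, the assumptions behind them, every default parameter, and the
numerical choices made along the way.

## 1. Cq data model

The canonical unit of data is one Cq observation with fields
`analyte, source, sample, isolation_lab, isolation_rep, pcr_lab, plate,
well, cq, is_well_average`. Two laboratories appear throughout, labelled
BDL (the developing laboratory) and BRL (the reference laboratory); each
can act as RNA-isolation lab and as PCR-measurement lab, giving a crossover
with four pure-cell-line pathways plus mixture pathways. The
`(source, isolation_lab, pcr_lab)` triple identifies one of seven
measurement scenarios:

| scenario | source          | isolation | PCR |
|---------:|-----------------|-----------|-----|
| 1        | pure cell line  | BDL       | BDL |
| 2        | pure cell line  | BDL       | BRL |
| 3        | pure cell line  | BRL       | BDL |
| 4        | pure cell line  | BRL       | BRL |
| 5        | RNA mixture     | BRL       | BDL |
| 6        | RNA mixture     | BRL       | BRL |
| 7        | cell mixture    | BRL       | BRL |

Validation enforces Cq ∈ (0, 40] by default (a standard PCR run length);
non-numeric entries ("", NA, Undetermined) are handled by a configurable
missing policy (`drop`, `ceiling`, or `error`). Replicate wells within one
plate are averaged by `collapse_wells`; the well mean is the analysis unit
everywhere downstream, mirroring common qPCR practice of running triplicate
wells per (analyte, sample, plate).

## 2. Additive-abundance mixture prediction

Cq is, to good approximation, −log2 of starting template abundance (one
cycle = one doubling). If component `c` of a mixture contributes fraction
`φ_c` of total RNA mass and measures `Y_c` cycles alone, the mixture's
abundance is the φ-weighted sum of component abundances, so its predicted
Cq is

    M = −log2( Σ_c φ_c · 2^(−Y_c) ).

Assumptions: perfect and equal amplification efficiency across components
and in the mixture, no interaction between components, and fractions that
describe the analyte-relevant mass. The prediction is computed with
`scipy.special.logsumexp` in base-2 form, which is exact to machine
precision over the full plausible Cq range (verified against a 50-digit
evaluation); a naive `2**(-y)` sum would already suffice numerically for
Cq < 40 but the log-sum-exp form is safe for any input.

Two boundary identities follow directly and are tested: a mixture of
identical components predicts that same Cq, and a single-component design
reproduces the component.

## 3. Mixture-design search

A design pair (Mix1, Mix2) is evaluated per analyte by predicting both
mixture Cq values from pure-component profiles and placing the analyte at
the Bland-Altman point (mean Cq, ΔCq) with ΔCq = Cq(Mix1) − Cq(Mix2).
Negative ΔCq means the analyte is more abundant in Mix1.

- **Enumeration** — candidate mixtures are all distinct normalized points
  from a fraction grid (reciprocal ratio grids like 1:3:1 permutations, or
  a stars-and-bars simplex grid); candidate pairs are unordered
  combinations, de-duplicated under swapping.
- **Feasibility** — every target analyte must satisfy |ΔCq| ≤ 1 cycle
  (defensible measurement range for a difference claim: large enough to
  detect, small enough that both samples stay within the assay's working
  range) and both ΔCq signs must occur across analytes, so a measuring
  laboratory must distinguish directions, not just magnitudes.
- **Score** — the minimum pairwise Euclidean distance between analyte
  points in the (mean Cq, ΔCq) plane; maximizing it spreads the analytes
  so each one's designed difference is individually resolvable. Ranking is
  by descending score, ties broken by smaller max |ΔCq|.

With the default profiles the reciprocal (1:3:1, 3:1:1) pair of
(H226, H358, H460) ranks first; its normalized fractions are exactly
(0.2, 0.6, 0.2) and (0.6, 0.2, 0.2).

## 4. ΔCq and ΔΔCq statistics

ΔCq pairs Mix1 and Mix2 within the same plate (or within the same
isolation after averaging plates). ΔΔCq additionally subtracts the control
analyte's ΔCq measured on the same plate:

    ΔΔCq(target) = [Cq_t(Mix1) − Cq_c(Mix1)] − [Cq_t(Mix2) − Cq_c(Mix2)]

with miR-16 as the default control, chosen as the classic abundant,
stably-expressed miRNA control. Any additive per-plate (or per-sample
loading) shift cancels exactly in ΔΔCq; this invariance is tested to
1e-12. Summaries report mean, sample SD (n−1) and n per isolation, per
plate position, or pooled.

## 5. Factorial variance decomposition

The crossover is summarized by a full-factorial fixed-effects ANOVA of
collapsed Cq values on analyte, cell line, isolation lab, isolation
replicate and PCR lab, including all interactions. On balanced data the
sums of squares are computed exactly by inclusion–exclusion of cell means:
the effect of term `T` at an observation is Σ over subsets `S ⊆ T` of
(−1)^(|T|−|S|) times the `S`-cell mean, and SS(T) is the sum of squared
effects, with df(T) = Π (levels−1). These SS are orthogonal and sum to the
total SS (conservation is tested to 1e-8 relative, and each term against a
sequential least-squares oracle). On unbalanced data the package falls back
to sequential (Type-I) SS via `statsmodels`, with a logged warning that
results then depend on term order.

Mean squares are reported descriptively — the interest is which factors
carry variance (biology: analyte, cell line, and their interaction should
dominate by orders of magnitude) rather than formal F-tests, since the
design is saturated at the collapsed level.

## 6. Bayesian bias assessment

For one analyte at a time, collapsed Cq values are modelled as

    y = μ_cell + b_plate + u_iso + ε,

where `μ_cell` is a fixed mean per (source, isolation lab, PCR lab,
sample) cell, `b_plate ~ N(0, σ_plate²)` is a random plate effect,
`u_iso ~ N(0, σ_iso²)` a random isolation effect, and `ε ~ N(0, σ_e²)`
residual noise. Priors: N(0, 100²) on fixed means (diffuse on the Cq
scale) and half-normal(5) on all SDs. Terms with fewer than two observed
units are dropped automatically (with a warning), so the model adapts to
toy and partial designs.

Three documented variants probe prior sensitivity:

1. defaults (half-normal(5) on SDs);
2. half-Cauchy(2.5) on SDs (heavier tail, weaker shrinkage);
3. isolation effect non-hierarchical: fixed effects with a N(0, 10²)
   prior instead of a learned variance.

**Sampler.** A Gibbs-within-Metropolis scheme written with numpy: fixed
means and random effects have conjugate normal full conditionals; each log
SD takes a random-walk Metropolis step (step 0.3 with the Jacobian
correction). Because the fixed means and the sums of random effects are
jointly identified only through the data, plain Gibbs mixes slowly along
the translation direction (μ up, effects down); after each effect update
the sampler therefore draws a translation from its exact conditional and
shifts μ and the effects in opposite directions. This is a standard
recentering move; it leaves the posterior invariant and raises the
effective sample size of the cell means by an order of magnitude.
Default 4 chains × 5000 iterations with 1000 burn-in; chains are seeded
via `numpy.random.SeedSequence([seed, chain])`, and split-R̂ / ESS
diagnostics come from `arviz` (a warning is logged above R̂ = 1.05).

**Marginal-likelihood curves.** The quantity of interest is a linear
functional of the fixed means — e.g. the average ΔCq of a scenario, or the
difference of that average between two scenarios (a lab-effect contrast).
With the diffuse flat-ish prior on means, the marginal likelihood of the
data as a function of the functional's value is proportional to the
functional's posterior density (the Savage–Dickey ratio evaluated across a
grid). The package therefore takes the posterior draws of the functional,
estimates their density with a Gaussian KDE (Silverman bandwidth), and
normalizes the curve to max 1 on a grid of 201 points spanning the mode
± 4 posterior SDs. With one fixed mean and conjugate normal data this
reproduces the closed-form profile likelihood shape (tested to 1e-2
sup-norm; the KDE's Monte-Carlo noise scales as N^(−2/5) in the draw count
N, so that comparison uses ~3 million draws).

**Scenario comparison.** Curves are compared by peak location, sign
agreement, and an overlap coefficient: both curves are renormalized to
unit area on a common grid and the integral of their pointwise minimum is
taken (`numpy.trapezoid`); overlap below a configurable threshold
(default 0.25) flags peak separation. Identical curves give 1, disjoint
curves 0, and shifted Gaussian shapes match the 2Φ(−d/2) closed form.

## 7. Synthetic-data generator

The generator emulates the two-phase crossover at the Cq level:

- **Profiling phase** — three cell lines isolated at both labs
  (3 replicate isolations each) and measured at both labs: scenarios 1–4.
- **Mixture phase** — the designed pair prepared from 4 isolations at the
  reference lab; RNA mixtures measured at both PCR labs (scenarios 5–6) on
  3 replicate plates, cell mixtures at the reference lab only
  (scenario 7).

A well-level Cq is additive:
true mean + isolation-lab shift + PCR-lab shift + iso-occasion deviation
(σ_iso = 0.15) + plate deviation (σ_plate = 0.10) + well noise
(σ_well = 0.10), all in cycles — magnitudes typical of well-run qPCR,
where technical replication sits near a tenth of a cycle and isolation
batches vary somewhat more. Mixture true values are derived from the
(shifted) component means through the additive-abundance model, so every
designed ΔCq is known exactly and exported in a truth record.

Default cell-line means are chosen so the qualitative geometry of real
profiles holds: each target analyte has a distinct highest-expressing cell
line (H358 for miR-21 and miR-210, H226 for miR-126, H460 for miR-375),
miR-375/486 sit at the 35-cycle detection ceiling in H226 (values at the
ceiling are clipped and flagged, not dropped), mixture abundance ranks
miR-486 < miR-375 < miR-126 < miR-210 < miR-21, and all designed ΔCq fall
within ±1 cycle with both signs. Two systematic effects are injected:
miR-21 appears ~0.4 cycles more abundant when isolated at BRL (an
analyte-specific isolation-lab effect), and miR-126/miR-486 have
analyte × cell-line PCR-lab shifts (an interaction that moves their
mixture ΔCq between PCR labs).

Not emulated: amplification curves or fluorescence traces (Cq level only),
probe-specific efficiency differences, inter-run calibrators, or missing
wells. `simulate_paired_mixtures` bypasses component profiles and takes
per-analyte (Mix1, Mix2) true means directly — the cleanest calibration
input for the Bayesian assessment since its designed ΔCq is exact by
construction.

## 8. Problem sizes and reproducibility

Simulated studies default to the realistic study size (3–4 isolations,
3 plates, 3 wells, 6 analytes, 3 cell lines). MCMC defaults are 4 × 5000
iterations; the pipeline and examples run 2 × 1500–2000, which the
diagnostics show is ample for these small, well-identified designs. All
randomness flows through explicit integer seeds
(`numpy.random.default_rng` / `SeedSequence`), pipeline artifacts are
stamped with a hash of the full configuration, and reruns with the same
configuration are bit-identical.
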