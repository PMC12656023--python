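# Methods

## Model

The engine implements dose-additive cumulative risk assessment for PFAS
mixtures in food. Each compound's occurrence concentration (ng/kg food) is
scaled by its relative potency factor (RPF) against the index compound PFOA
(RPF = 1), derived upstream from benchmark doses for liver hypertrophy in
male rats. Potency-weighted estimated weekly intakes (EWI, ng/kg bw per week)
are

    EWI_i = C_i × RPF_i × (Q / 1000) / BW × 7

with Q the mean consumption of the food category in g/day and BW the standard
body weight of the consumer group. Per-category cumulative EWIs sum over
compounds, the total EWI sums over the four animal-derived food categories
(fish/seafood, meat, eggs, milk/dairy), and risk is characterised against the
EFSA 2020 group tolerable weekly intake, TWI = 4.4 ng/kg bw per week, as
%TWI = EWI/TWI × 100 and Hazard Index HI = total EWI / TWI (HI > 1 flags
potential concern). The concentration-based (CB) comparator path is the same
arithmetic with all RPFs set to 1; by construction it is bit-identical to the
PEQ path run with a unit RPF table, which is how it is tested.

Key assumptions inherited from the approach: dose addition across compounds
sharing the hepatic endpoint; the TWI (an immunotoxicity-based value for four
PFAS) is an acceptable anchor for a hepatic-potency-weighted sum; mean LB
occurrence combined with mean consumption approximates chronic exposure.

## RPF scenarios

Data-poor compounds carry a potency *range* from chain-length read-across
(flagged `read_across` in the table: PFHpS, PFPeS, PFTrDA; PFDA and PFHpA
also span ranges). Scenario resolution is coherent: `min` sets every
range-valued compound to its lower potency simultaneously, `max` to its
upper. Per-compound mixed scenarios are deliberately not enumerated — the
min/max pair brackets the cumulative result, which is what the reference
grids report.

One RPF is genuinely ambiguous in the source material: the printed grid gives
PFPeA a potency of 0, but the reported intakes carry nonzero PFPeA
PEQ-contributions consistent with RPF = 0.03. The shipped default table
(`data/rpf.csv`) uses 0.03 so that the bundled intake grids are internally
reproducible; the literal printed table is available via
`reference.rpf_assignments("printed")`. Compounds with RPF 0 (PFBS, PFHxA,
PFHpA at minimum) are retained: they contribute nothing to PEQ but still feed
the CB path. Compounds with an RPF but no occurrence record contribute
nothing and are never imputed.

## Censoring substitution and consumption weighting

Occurrence means from sample-level records use pure bound substitution, no
distributional imputation: LB assigns 0 to non-detects, UB assigns the LOQ,
falling back to the LOD when no LOQ is reported (LOQ is the reporting limit
in European monitoring data and the larger, conservative bound; the source
material says "LOD/LOQ" without ordering). A censored record with neither
limit is an error under UB. Mean consumption per category × group is
Σ(wᵢmᵢ)/Σwᵢ over surveys; the weight variable is an explicit input column
(subject counts by convention), since the source never states its weighting
variable.

## Units and numerical choices

Consumption is stored in g/day and converted to kg/day inside the intake term
(factor 1/1000, fixed and tested); concentrations in ng/kg food; EWIs in
ng/kg bw per week; TWI defaults to 4.4 and is overridable for sensitivity
analyses. All computation is in full double precision; sums use `math.fsum`.
Rounding exists only in the report layer: intakes and hazard indices print to
two decimals, %TWI to integer percent, both half-away-from-zero (implemented
with decimal `ROUND_HALF_UP`; values are non-negative by contract). The
half-away-from-zero choice is forced by the reference grids themselves, where
3.85/4.4 × 100 = 87.5 prints as 88%. Display percentages are computed from
unrounded EWIs, never from rounded display values — the reference grids round
components and cumulatives independently, which is why some rows differ from
their printed cumulative by ±0.01–0.02. An empty occurrence set for a
category yields a cumulative EWI of 0 with a logged warning, not an error.
The vectorised engine is checked against an independent pure-Python
per-record loop to 1e-12 relative tolerance.

## Reference grids and back-derived occurrence

Seven published grids ship as CSV (consumption; RPFs; per-compound intakes
with %TWI for milk, meat, eggs, fish; totals with the HI block), as verbatim
transcriptions guarded by recorded SHA-256 checksums and a self-check of
their internal identities (totals = Σ category cumulatives; HI = total/TWI to
two decimals; the toddler milk row sums exactly to its cumulative). The eggs
grid as published contains duplicated PFHpA/PFUnDA column blocks; the first
instance of each compound is kept (it is the one consistent with the printed
cumulative). The grids print intakes but not concentrations, so group-specific
concentrations are back-derived by inverting the intake equation on the
printed per-compound EWIs, preferring the max-scenario value with `rpf_max`:
that rounding direction reproduces the printed two-decimal intakes and all
eight hazard-index strings on forward recomputation (inverting from the min
scenario loses the toddler max HI to 7.90 vs 7.91). Compounds printed as 0.00
or with zero potency are not recoverable and get concentration 0; forward
totals consequently sit within ~0.03 ng/kg bw per week of the printed ones
(31.05 vs 31.07 for the toddler min total). Cross-group intakes do not scale
exactly as consumption/BW ratios (the upstream data evidently matched
occurrence subsets per group), so each group's back-derived occurrence is
kept independent and no cross-group ratio identity is asserted. CB headline
values are not asserted against the published grids at all: the CB rows print
only integer %TWI, too coarse to reconstruct.

## Synthetic generator

The generator emulates the *structure* of European PFAS monitoring data, not
its values: per compound × category, each sample is left-censored with
probability `censor_prob` (default 0.92, the censored fraction of the
underlying dataset) and otherwise drawn from a lognormal — heavy-tailed, so
the LB mean is set by a small fraction of high, quantifiable results. The
closed-form LB mean, (1 − p)·exp(μ + σ²/2), anchors recovery tests: at
n = 10⁴ the empirical LB mean must sit within 3 exact standard errors and the
censored fraction within the binomial 99% interval. The default scenario uses
15 compounds × 4 categories with per-category log-scale anchors chosen so LB
means land in the ng/kg range implied by the back-derived reference
occurrence (fish ≫ eggs > meat ≫ milk, long-chain above short-chain), with
sdlog = 1 and independence across compounds (no within-category correlation
structure is specified by the source, so none is modelled). Survey means are
gamma-distributed around the population mean (positive support, default CV
0.3) with integer subject-count weights drawn independently, so the weighted
mean is unbiased. Seeding uses `numpy.random.SeedSequence` with per-truth
spawned children, giving order-independent reproducibility.

What passing synthetic tests do **not** show about real data: real occurrence
has correlated compounds, category-specific censoring rates, LODs that vary
by laboratory and year, and food-consumption heterogeneity across countries
that a single weighted mean hides. The generator validates the pipeline's
arithmetic and its statistical plumbing, not the representativeness of any
particular exposure estimate.

## Problem sizes

The test suite and acceptance script run on the bundled grids (≤ 76 rows),
random tables of ≤ 1000 records for oracle equivalence, and Monte-Carlo draws
of n = 10⁴ for recovery checks — sizes at which every check is exact or has a
closed-form error bound, and the whole suite completes in seconds.

## Known limitations

- RPFs are taken as given; no benchmark-dose modelling, no endpoint other
  than hepatic toxicity, no uncertainty propagation on the RPFs beyond the
  min/max bracket.
- Mean-based chronic exposure only: no probabilistic (distributional) intake
  modelling, no high-consumer percentiles.
- The four flat food categories only; no food-classification hierarchy or
  recipe decomposition.
- The headline reproduction targets the LB scenario, as published; UB
  occurrence is supported by the engine but has no reference values to check
  against.
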