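# Methods

`iresscreen` analyses arrayed RNAi screens whose readout is the luminescence
of a transfected reporter mRNA — the concrete use case is a screen of human
kinases and phosphatases for regulators of VEGF IRES-driven (cap-independent)
translation, with a cap-driven reporter and an ATP assay as secondary
specificity and viability controls.  This note documents the statistical
procedures, the synthetic-data model used to test them, the defaults, and the
design decisions that were genuinely open.

## Primary-screen analysis

**Normalization.**  Raw per-well luminescence is expressed as percent of
control: each value on a plate is divided by the median of that plate's
scrambled-siRNA negative-control wells (four per plate by default) and
multiplied by 100, channel by channel.  Controls are normalized too, so the
anchoring invariant — scrambled median = 100 on every plate — is directly
checkable on the output.  The plate median absorbs multiplicative plate
effects exactly: rescaling a whole plate by any c > 0 leaves the normalized
values unchanged.  For an even number of control wells the median is the
midpoint of the two central values; the anchor then holds to floating-point
round-off (~1e-13 relative), which the tests check at 1e-9.

**Replicate aggregation.**  Each gene×siRNA reaction runs on three replicate
plates; its reaction score is the median of the three normalized values.
Plain medians, no trimming or outlier rejection.  Reactions with fewer than
`min_replicates` (default 2) surviving measurements are flagged unusable and
excluded from hit calling with a logged warning rather than an error, since
dropped wells are routine in plate screens.

**Hit calling.**  A reaction is an *Up* call when its score is ≥ the upper
cut-off and a *Down* call when ≤ the lower cut-off (defaults 250 and 80;
boundary values count as calls, an inclusive convention chosen so the round
published-style cut-offs are themselves callable).  A gene is a hit when at
least two of its three siRNAs agree in direction; mixed up+down never
qualifies.  The concordance rule is the screen's defence against
single-siRNA off-target effects.  Up hits are reported as negative
regulators of IRES activity (silencing de-represses the reporter), Down hits
as positive regulators.  Genes with exactly two usable reactions can still
be hits if both concur.

**Cut-off calibration.**  Besides the fixed default pair, cut-offs can be
derived from the score distribution for a target per-reaction hit rate r:
the Down cut-off is placed at quantile r/2 and the Up cut-off at quantile
1 − r/2 (the widest rank-symmetric pair), each rounded *outward* to a grid of
round numbers (default 10), widening further if boundary ties push the
inclusive beyond-fraction over the target, and finally clamped to bracket the
control level by at least one grid step.  Outward rounding guarantees the
achieved rate never exceeds the target.  Whether a published "<10 % hit
rate" refers to reactions or genes is ambiguous in general; calibration here
targets the per-reaction rate, and `summarize_screen` reports both.

## Secondary screen

Primary hits are re-assayed in three channels: the IRES reporter, a
cap-driven reporter, and ATP viability, each normalized per plate as above
and median-aggregated over replicate plates.  A gene is

* **confirmed** if its IRES score is again beyond the primary cut-offs in the
  primary direction (the primary cut-offs are reused for consistency);
* **IRES-specific** if confirmed and its cap score lies within ±`cap_tolerance`
  (default 0.25, i.e. 75–125 % of control) of the control level — knockdown
  leaves cap-dependent translation untouched;
* **viable** if its ATP score is ≥ `viability_floor` (default 0.70) of
  control.

The surviving "specific hits" are confirmed ∧ specific ∧ viable.  The
thresholds quantify "no effect on the cap reporter" and "no effect on
viability", which published screens state only qualitatively; both are
exposed as parameters, and the filter is monotone — tightening either never
grows the surviving set.  Hit genes lacking secondary data are listed as
untested, never silently dropped.

## Validation statistics

**Relative expression (qPCR).**  The efficiency-corrected ratio

    ratio = E_target^ΔCt_target / E_ref^ΔCt_ref,   ΔCt = mean Ct(control) − mean Ct(treated)

with amplification efficiencies E ∈ (1, 2] (2 = perfect doubling).  The sign
convention makes ratio > 1 mean up-regulation in the treated group.
Significance comes from fixed reallocation: treated/control labels of whole
samples (each sample's target and reference Cts move together) are randomly
permuted (default 2,000 iterations), the ratio recomputed, and the two-sided
p-value is the fraction of reallocations with |log ratio| at least the
observed value, with the (k+1)/(n+1) small-sample correction.  The ratio SD
is the spread (ddof=1) of leave-one-out jackknife ratios.  The exact
internals of the commonly used relative-expression randomization software
are unpublished; this scheme is a documented reconstruction with the
iteration count and seed exposed.  Under a simulated null the p-values are
uniform (KS-checked over 500 datasets in the acceptance suite).

**ELISA.**  Unpaired two-sample Student's t-test with pooled (equal)
variance, two-sided p from the t distribution with nA + nB − 2 df — the
"type 2" spreadsheet t-test.  Zero pooled variance uses the conventional
limits (p = 1 for equal means, p = 0 otherwise) and flags the result.
Group differences are also reported as the signed fractional change of the
treated mean relative to control.

## Annotation and reporting

Hit genes are assigned to coarse function groups from a user-supplied
gene→labels CSV, taking the highest-priority group in the fixed order
gene expression > tumorigenesis/angiogenesis > cell signaling > cell cycle >
other > unknown; unmapped genes are unknown.  Live ontology retrieval is out
of scope by design — group percentages depend on an annotation snapshot, so
the mapping is an explicit input.  Whole-percent summaries use
largest-remainder rounding and therefore always sum to 100.
`run_pipeline` chains all stages, writes every table as CSV plus a
`summary.json` and a plain-text report with the score histogram, and is
byte-deterministic for a fixed config.

## Synthetic-data model

The simulator emulates the screen's structure so every stage is testable
with known ground truth:

* **Geometry** — 96-well plates with four scrambled controls (corner wells),
  one FLuc-siRNA and one PLK1-siRNA positive-control well; 3 siRNAs/gene,
  each reaction on 3 replicate plates.  Plating is siRNA-set-major (all
  first siRNAs, then all second, then all third), as commercial libraries
  ship; a gene's reagents therefore sit on different plates and their scores
  do not share a control-median estimate — without this the gene-level null
  hit rate is inflated ~2–3× above the binomial closed form.
* **Signal** — raw = baseline × plate_effect × gene_effect × noise, with
  `plate_effect = exp(N(0, σ_plate))` (default σ = 0.10),
  unit-mean log-normal well noise at CV `noise_cv` (default 0.15; plate
  readers give strictly positive, right-skewed noise), and
  `gene_effect = 1 + k(m − 1)` for a planted regulator with effect
  multiplier m silenced at efficiency k.  Knockdown efficiencies are drawn
  uniformly per siRNA from (0.80, 0.95), a realistic range for validated
  silencer-select duplexes; sampling per siRNA reproduces the within-gene
  variability that motivates the ≥2-siRNA rule.  FLuc control wells are
  multiplied by 0.05 and PLK1 wells by 0.25 (reporter loss through growth
  arrest).  Well-level variance is not published for the modelled screen;
  `noise_cv` is a free parameter.
* **Secondary channels** — the per-gene multiplier applies directly (the
  re-test uses the validated reagent): IRES-specific regulators perturb only
  the IRES channel, non-specific regulators both reporter channels, and
  toxic genes multiply all three channels jointly (a PLK1-like gene with
  multiplier 0.25 shows ATP at 25 % of control).  Each channel plate is run
  in triplicate like the primary screen.
* **qPCR / ELISA** — control Cts at fixed baselines with Gaussian noise
  (default SD 0.15 cycles); treated target Cts shifted by
  −log(true_ratio)/log(E), reference Cts unshifted, so the generator is
  exactly invertible by the ratio estimator at zero noise.  ELISA draws
  Gaussian concentrations with the treated mean at
  control × (1 − percent_reduction).
* **Determinism** — all randomness flows from one seed through named
  `SeedSequence` child streams (library, knockdown, plate effects, well
  noise, secondary, qPCR, ELISA), so identical seed + config gives
  bit-identical tables and each generator is reproducible in isolation.

**What the simulator does not model:** spatial plate gradients (edge
effects), transfection-efficiency drift, reporter mRNA decay kinetics,
hypoxia response dynamics, or correlated off-target signatures.  Passing
tests therefore demonstrate that the analysis recovers truth under the
stated noise model, not that it is robust to systematic artefacts real
screens can show; spatial corrections (B-score/loess) are deliberately out
of scope.

## Problem sizes used in the checks

The statistical test suite uses a 10,000-gene null screen for hit-rate
calibration (per-reaction rate 10 % at empirical 5th/95th percentile
cut-offs; gene rate vs the closed form 2(3p²(1−p)+p³), p = 0.05 ≈ 1.45 %), a
400-gene screen with 80 planted regulators (effects ≥3× up or ≤0.33× down)
for sensitivity (≥0.9 at noise CV 0.15, derived from a pilot run of the
generator; exact recovery at zero noise), 1,000 randomized plates for the
normalization properties, and 500 null qPCR datasets for randomization-test
calibration.  `scripts/acceptance.py` re-runs the whole pipeline on a
1,000-gene screen (702 kinases + 298 phosphatases, 64 planted negative and
27 positive regulators, three IRES-specific non-toxic kinases among them and
one PLK1-like toxic gene) and reports the computed counts, rates and
validation estimates.

## Known limitations

* The calibration routine assumes a unimodal score distribution centred
  near 100; heavily skewed screens may need an asymmetric target split.
* The jackknife SD of the expression ratio is a convention, not the (unknown)
  estimator of the reference software; treat it as a spread indicator.
* The permutation p-value is discrete ((k+1)/(n+1)); with few samples per
  group its resolution is limited by the number of distinct reallocations.
* With ~9 % of genes planted as true regulators plus a ~2 % false-positive
  reaction rate at noise CV 0.15, the realized per-reaction hit rate on the
  acceptance screen is ~11 %; the <10 % figure of a real screen depends on
  its (unknown) true-regulator prevalence and noise level.
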