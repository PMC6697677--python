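# Methods

## The sponge (ceRNA) model and what is tested

A circRNA that carries miRNA response elements can sequester miRNAs.  Because
sequestration buffers miRNA *activity* without necessarily degrading the
miRNA, the model makes two directional predictions that the package turns
into statistics:

1. the abundance of a dysregulated circRNA's target miRNAs is *not* expected
   to shift (circRNA→miRNA contingency: expected null);
2. the mRNAs downstream of those miRNAs are expected to shift in the *same*
   direction as the circRNA — disinhibition under circRNA up-regulation,
   hyper-inhibition under down-regulation (circRNA→mRNA contingency:
   expected enrichment).

The direct miRNA→mRNA relation keeps the classical inverse rule.  These
three relevant-direction rules are defaults and can be overridden in the run
configuration.

## Differential expression

* **Fold change** is the ratio of arithmetic group means on the linear
  normalized-intensity scale.  This matches how averaged normalized signal
  values are conventionally compared in microarray scatter plots; a
  geometric-mean (log-scale) variant is available via ``log_scale_fc=True``
  since the scale convention of legacy array software is not always
  documented.
* **Test**: two-sided Mann–Whitney U.  For total sample size ≤ 12 the null
  distribution of the midrank sum is enumerated over all C(n₁+n₂, n₁)
  assignments, so ties are handled exactly; the two-sided p is the doubled
  smaller tail probability capped at 1 (equal-tail convention — stated
  explicitly because discrete U distributions admit alternatives).  Larger
  designs fall back to the normal approximation with midranks and tie
  correction.  At 4 vs 4 the attainable p-values form a 9-point set with
  minimum 2/70; the suite checks that null p-values are distributed over
  exactly that set.
* **Selection** uses raw p ≤ 0.05 plus the FC ≥ 1.5 filter.  BH FDR is
  computed over all callable features of a matrix and reported for
  transparency, not used for selection (at n = 4 vs 4 the discrete p floor
  makes FDR-based selection degenerate).
* Features with a nonpositive group mean are flagged and excluded from
  calling (NaN statistics, direction ``none``), never imputed.
* **Quantile normalization** maps every sample column onto the mean
  per-rank reference distribution; ties receive interpolated reference
  values.  Single-sample matrices pass through unchanged with a warning.

## Contingency statistics

* The downstream **universe defaults to every feature assayed** in the
  downstream layer.  Published marginals rarely pin down the exact universe
  an enrichment was computed over, so the choice is explicit and
  configurable rather than silently inherited.
* OR = ad/bc with the Woolf CI on the log scale.  Any zero *cell* triggers
  the Haldane–Anscombe +0.5 correction for OR/CI only, flagged in the
  result; a zero *margin* yields an undefined OR with p = 1 — degenerate
  tables are reported, not hidden.
* The p-value is always Pearson's chi-square without continuity correction
  (computed from the closed-form statistic), including for
  Haldane-corrected tables.
* The **adjusted model** is a logistic regression of the
  relevant-dysregulation indicator on two binary predictors: targeted by a
  dysregulated circRNA, targeted by a dysregulated miRNA (the miRNAs whose
  inverse effect would mimic the outcome direction).  Both predictors are
  always included — a univariate screening threshold would change nothing
  here since both predictors are the point of the adjustment — and a
  constant predictor is dropped, reducing the fit to the univariate model.
  (Quasi-)separation is detected by non-convergence or runaway coefficients
  and handled by a Firth-penalized (Jeffreys-prior) fit, flagged in the
  result, implemented in-package.

## Network construction and summaries

Triples are distinct (circRNA, miRNA, mRNA) tuples; the same circRNA–mRNA
pair bridged by two miRNAs counts twice, which is the only convention under
which triple counts can exceed distinct-mRNA counts.  Networks are built per
(time point, direction); bridging miRNAs appear only when they carry at
least one triple — they are emergent, not an input filter.  Degree
medians/IQRs use numpy's linear (fractional) quantile interpolation by
default, the convention under which quartile values like 54.25 arise; the
method is configurable.  SIF export writes the unique projected edges
(`sponges`, `targets`); GraphML additionally embeds the exact triple list so
re-import is lossless even for triple sets whose edge projection is not
join-closed.

## Enrichment

Fold enrichment (k/n)/(K/N) with a one-sided hypergeometric tail (or
optional Pearson chi-square).  Terms with zero query hits are omitted from
the emitted family and hence from the BH FDR, matching common annotation
servers and avoiding dilution by untestable terms.  The background defaults
to all assayed mRNAs, not the genome.  Ranking is per namespace by
descending fold enrichment among terms with p < 0.05 and FDR < 0.05; ties
break by ascending p, then term id.

## Synthetic data

The generator emulates a two-group, two-time-point tri-layer array study:

| parameter | default | rationale |
|---|---|---|
| layers (circ/miR/mRNA) | 1,000 / 100 / 5,000 | a ~1:7 scale-down of a full array (14,119 / 326 / 39,429) that keeps every statistic well-populated at interactive run times |
| n per group | 4 vs 4 | the small-n design the exact test targets |
| baseline log2 mean | U(6, 12) | typical microarray intensity range |
| noise_sd (log2) | 0.25 | a free choice — array replicate variance is rarely published; 0.25 makes a 1.5-fold change a ~3σ mean shift, i.e. calls are hard but attainable |
| frac planted up/down | 0.02 / 0.02 | ~20 planted circRNAs per direction, the scaled analogue of 55/46 dysregulated among 14,119 |
| circ_effect_fc / mrna_effect_fc | 4 / 2 | strong upstream effect, attenuated downstream propagation |
| penetrance | 0.5 | not every target responds |
| background_de_rate | 0.01 | disease-unrelated mRNA dysregulation |
| mre_cap | 5 | at most five target miRNAs per circRNA |
| miRNA out-degree | U{10..100} | "hundreds of targets" scaled to a 5,000-mRNA layer |

Planted up/down circRNAs shift case means by ±log2(4); miRNA case and
control means differ only by noise; each mRNA in the downstream closure of a
planted circRNA receives a concordant ±log2(2) shift with probability 0.5.
mRNAs reachable from both an up- and a down-planted circRNA are left
untouched so the truth record stays unambiguous.  One RNG stream per concern
(two maps, three layers, effect assignment) is split from the master seed,
so changing one layer's size does not perturb another layer's draws.

**What the simulator does not emulate** — probe-level artifacts, background
correction, intensity-dependent (heteroscedastic) variance, correlated
features, RNase R enrichment bias, batch effects, or sequence-determined
targeting.  Passing tests therefore demonstrate that the statistical
machinery recovers a planted sponge structure under idealized log-normal
noise; they do not certify performance on real arrays, where normalization
and correlation structure dominate.

## Problem sizes and numerical choices

Monte-Carlo suites use 50 replicate seeds at the default 1,000/100/5,000
configuration (the exact test is vectorized across features, so a full
replicate costs well under a second), 200 replicate universes of 2,000
features for null calibration, and brute-force oracles on instances small
enough to enumerate.  Exact-test comparisons use a 1e-9 slack on rank-sum
comparisons (midrank sums are exactly representable; the slack is
defensive).  Logistic fits cap Newton iterations at 200 with a 1e-8 step
tolerance.

## Known limitations

* Target maps are inputs (or simulated); no sequence-based MRE/seed-match
  prediction is performed, so real-data results inherit the upstream
  predictor's biases.
* The contingency universe and the enrichment background are analysis
  choices; published tables computed under unknown universes are comparable
  only qualitatively.
* The exact test's discreteness at 4 vs 4 means power is capped and FDR
  control is coarse; the package reports but does not select on FDR.
* Identifier matching is exact string equality; no alias resolution.
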