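# Methods

`sewagesense` implements a sequence-based assessment of human sewage pollution
in river networks. This note documents the models, the conventions and
defaults behind each stage, what the synthetic-data generator does and does
not emulate, and the design choices made where the procedure was genuinely
open.

## Source partitioning

Each dereplicated 16S amplicon sequence variant (ASV) is assigned to one of
four source categories by **full-length exact sequence matching** against
labeled reference databases, with precedence
`freshwater > human_stool > sewer > uncategorized`:

1. An ASV matching a freshwater reference (or flagged freshwater by an
   upstream taxonomy assignment supplied as a boolean column — both paths feed
   the same logic) is `freshwater`, even if it also matches a sewage-side
   reference.
2. Otherwise, an ASV matching a human-stool or sewer reference is admitted as
   `human_fecal` or `sewer` only if it passes the **percentile inclusion
   filter**: its 5th-percentile relative abundance across river samples must
   be *strictly* lower than the reference's 95th-percentile relative abundance
   across raw-sewage samples. The filter rejects cosmopolitan organisms that
   are abundant in rivers and merely present in sewage. When a sequence
   matches both a stool and a sewer reference, stool takes precedence (the
   more specific claim about origin); if the filter fails for the matched
   reference, the ASV falls to `uncategorized`.
3. Anything unmatched is `uncategorized` (presumed terrestrial/other).

Conventions, recorded in the partition output so results are auditable:

* Matching is exact string equality after uppercasing, full length, no
  reverse-complement search (amplicons are orientation-fixed by the primer
  protocol). Ambiguity codes are rejected at validation.
* Percentiles use linear interpolation between closest order statistics
  (numpy's default). Zeros count as observations: an ASV absent from most
  samples has river-p5 = 0, making the filter permissive for rare ASVs, which
  matches its intent. Samples with zero total reads are excluded (their
  proportions are undefined).

The per-sample **sewage proportion** is the summed relative abundance of
`sewer` + `human_fecal` ASVs (a flag restricts it to `sewer` only); this is
the quantity compared against the sequence-based threshold.

## HB quantification

The human *Bacteroides* (HB) qPCR marker is quantified through a log-linear
standard curve `Cq = slope * log10(CN/reaction) + intercept`, fitted by OLS;
amplification efficiency is `10^(-1/slope) - 1` and a warning is raised
outside [0.9, 1.1]. Replicate Cq values are averaged on the Cq scale before
back-calculation (replicate handling is otherwise an open convention).

Copy numbers per reaction convert to copies per 100 ml of river water by the
factor `extract_to_reactions x reporting_basis_ml / volume_filtered_ml`.
Defaults (250 ml filtered, 30 reaction-equivalents per extract, 100 ml
reporting basis) give a factor of 12, so the lowest quantifiable standard
(15 CN/reaction) corresponds to a LOQ of exactly 180 CN/100 ml. The
elution/template volumes behind the factor are a single calibrated constant,
exposed in `ConversionConstants` and never hard-coded in the arithmetic.

Samples fall into four contamination categories, boundaries inclusive upward:
`undetectable` (no amplification), `unquantifiable` (detected, < 180
CN/100 ml), `quantifiable` (180-7,800), `risk` (>= 7,800 CN/100 ml, the
concentration associated with an excess illness risk of 0.03 in prior
quantitative microbial risk assessment — consumed here as a constant, not
re-derived). Non-detects carry no numeric value; arithmetic on them raises
rather than silently substituting zero.

## Mass-balance threshold

A volumetric mass balance links the HB risk concentration to an expected
sewage-sequence relative abundance:

    f = C_river,HB / C_sewage,HB
    r = (C_sewage,cells * f) / (C_river,cells * (1 - f))          [ratio form]
    r = (C_sewage,cells * f) / (C_sewage,cells * f
                                + C_river,cells * (1 - f))  [composition form]

`f` is the volumetric sewage fraction and `r` the expected relative abundance
of sewage-derived sequences, assuming amplicon relative abundance tracks cell
relative abundance in the sampled volume. Both forms are provided: the ratio
form as conventionally printed, and the composition form, which is bounded in
[0, 1] and agrees with it to first order in `f`. The read simulator uses the
composition form (reads are a composition by construction).

`C_river,HB` is fixed at 7,800 CN/100 ml; the other three inputs are
independent log-normals (no correlation structure is asserted). The Monte
Carlo engine draws them `n_draws` times (default 100,000), computes `f` then
`r` per draw, **rejects** draws with `f >= 1` (physically meaningless;
clamping would bias `r` upward) and aborts if more than 10% are rejected, and
summarizes `r` by geometric mean and geometric SD. The central statistic is
configurable (geometric mean — equal to the median under log-normality —
median, or arithmetic mean) and recorded in the output.

Because `ln r = ln C_sewage,cells - ln C_river,cells + ln C_river,HB -
ln C_sewage,HB + ln(1/(1-f))`, the small-f regime makes `ln r` a sum of
independent normals; `analytic_smallf_approximation` returns the exact
geometric mean/GSD of that sum and serves as the simulation's oracle (tested:
central estimates agree within the 3-sigma/sqrt(n) CLT bound and GSDs within
1% whenever f's 99th percentile is below 0.05).

The shipped `example_monte_carlo_config` uses literature-plausible round
values — sewage HB ~7.8x10^6 CN/100 ml (GSD 3), sewage cells ~10^9/ml
(GSD 2), river cells ~10^7/ml (GSD 5, the dominant variance contribution) —
and is an *example*, not a site calibration: deployments should substitute
measured distributions. Under it the simulated threshold is ~10% with a ±1
GSD interval of roughly 1.3%-80% (recomputed by `scripts/acceptance.py`).

## Dual-threshold concordance

Samples are cross-classified by HB exceedance (a *quantified* value
>= 7,800 CN/100 ml; non-detects and below-LOQ detections are non-exceedance
because exceedance demands a quantified number) and sequence exceedance
(sewage proportion >= threshold, inclusive to mirror the HB side; default
0.18). The four quadrant counts and the agreement fraction
(below-both + above-both over total) summarize how well the sequence
proportion could substitute for the qPCR indicator.

## Indicator ASVs

For each ASV and group (typically the HB contamination categories, restricted
to urban samples so land-use community differences do not masquerade as
contamination signal):

* specificity `A` = group mean relative abundance / sum of group means
  (the group-size-corrected "IndVal.g" convention, robust to the unbalanced
  group sizes HB categories produce; a pooled-sum mode is available);
* sensitivity `B` = fraction of the group's samples where the ASV has
  count > 0.

Each ASV is scored in its best group (max `A x B`, ties broken by group name)
and reported *strong* when both components are >= 0.8 (inclusive — the
boundary convention is a flag). Samples belong to exactly one group; group
combinations and permutation p-values of the full indicator-value framework
are out of scope. Specificities for an ASV sum to 1 across groups whenever it
is present anywhere; sensitivity is invariant to abundance rescaling and
specificity to uniform depth normalization (both property-tested).

## Community metrics

Shannon diversity is `-sum p ln p` in nats (configurable base) and Simpson is
the complement form `1 - sum p^2`, the vegan conventions. Bray-Curtis is
computed on per-sample relative abundances by default because depths vary
(raw-count mode available); diversity uses proportions with no rarefaction,
recorded as the convention. PERMANOVA is the one-factor permutational MANOVA
on a distance matrix: pseudo-F from among/within sums of squared
dissimilarities, p-value by random label permutation with the (1 + hits) /
(1 + permutations) correction, or by exhaustive enumeration of distinct label
arrangements for small designs (exact p, identity included). The permutation
p is calibrated: type-I error at alpha = 0.05 over 1,000 null replicates
stays within 3 binomial SEs of nominal (part of the test suite). Multi-factor
designs are out of scope.

## Synthetic-data generator

The generator emulates the targeted survey design — 16 sites x 5 dates,
~50,000 reads/sample, 370-bp amplicons — with known ground truth:

* Reference sequences are random DNA over {A,C,G,T}, pairwise disjoint across
  the freshwater/sewer/stool databases; sewer and stool references carry a
  simulated sewage 95th-percentile relative abundance drawn log-uniformly
  over a configurable range (default 10^-4-10^-1, recorded in the database
  metadata).
* Per sample, `f` is log-normal (default GM 3x10^-4, GSD 4) truncated by
  rejection at 0.99 (the regime of interest is f << 1, and truncation avoids
  the `r` singularity); cell and sewage-HB concentrations are log-normal
  draws shared with the mass-balance defaults. The induced sewage read
  fractions span roughly 0.3%-30% across the bulk of samples. A
  pollution-free basin (`sewage_fraction_spec=None`) sets f = 0 exactly.
* Reads are multinomial at fixed depth from the composition
  `(1 - r) x background + r x sewage`, where the background profile spans
  freshwater references plus an unlabeled terrestrial pool (exercising the
  partitioner's `uncategorized` fallback) and both profiles are Dirichlet(0.5)
  draws. An optional Dirichlet overdispersion parameter adds compositional
  noise; the default is plain multinomial, the simplest model consistent with
  the relative-abundance assumption.
* True HB is `f x C_sewage,HB`; the observation applies multiplicative
  log-normal noise (default GSD 1.3) and LOD/LOQ censoring. The LOD defaults
  to half the LOQ in concentration units (90 CN/100 ml) — a stated convention,
  since only the LOQ has a defined value. Cq values are synthesized by
  inverting a ~98%-efficiency standard curve so the table round-trips through
  the quantification module.

Everything is a pure function of (config, seed); identical inputs give
bit-identical bundles.

**What passing tests on synthetic data do and do not show.** The generator
makes exact matching informative by construction (disjoint random references;
no sequencing error, chimeras, or shared sequences between true sources), so
ground-truth recovery demonstrates the correctness of the partitioning logic,
not the real-world discriminating power of the reference databases. Real
amplicons share sequences across habitats, contain errors, and have
phylogenetically structured abundances; none of that is modelled. Likewise
the noise-free HB coupling validates the threshold algebra, not field
variability of the marker.

## Numerical choices and degenerate inputs

* Percentile convention: linear interpolation, inclusive (see above).
* Strict inequality in the inclusion filter; equal percentiles exclude.
* Category boundaries 180 and 7,800 CN/100 ml are inclusive upward.
* `f > 1` in the mass balance warns (`DomainWarning`); `f >= 1` in the read
  fraction raises; Monte Carlo rejects rather than clamps.
* Zero-read samples: category proportions reported missing, diversity
  undefined (error for single vectors, NaN rows in tables), excluded from
  river percentiles.
* Degenerate log-normals (GSD = 1) are point masses, handled exactly (no
  sampling noise), which is how noise-free study conditions are expressed.
* Indicator tie-break: deterministic (score, then group name) so outputs are
  reproducible across runs.

## Problem sizes used in the bundled analyses

The test suite and `scripts/acceptance.py` run the full pipeline on the
default 16 x 5-sample survey at depth 50,000 (~360 ASVs), 100,000-draw Monte
Carlo simulations, 100 randomized partition instances against the brute-force
oracle, and 1,000 PERMANOVA null replicates at 99 permutations — sizes chosen
so the complete validation runs in well under a minute while keeping binomial
and CLT error bounds tight enough to be meaningful.

## Known limitations

* Exact matching cannot place reads from organisms absent from the reference
  databases; everything unmatched is `uncategorized`, so the sewage
  proportion is a lower bound with respect to database completeness.
* The mass balance treats total river cell concentration as stable; a
  concurrent influx of another biological contaminant would inflate the
  background and bias `r` downward.
* The Monte Carlo threshold inherits the (large) spread of its inputs; with
  the example configuration the ±1 GSD interval spans nearly two orders of
  magnitude, so the central threshold should be read as an order-of-magnitude
  benchmark.
* One-factor PERMANOVA only; no ordination, rarefaction, or figure rendering.
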