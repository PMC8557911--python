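# sewagesense

Sequence-based assessment of human sewage pollution in rivers and streams.

Routine water-quality monitoring relies on culturable fecal indicator
bacteria or single qPCR markers such as the human *Bacteroides* (HB) assay.
16S rRNA amplicon sequencing sees the *whole* bacterial community, including
hundreds of sewage-associated organisms at once — but needs a way to turn
community composition into a pollution verdict. `sewagesense` provides that
pipeline for microbial source-tracking and water-quality researchers:

* **Source partitioning** — assign each amplicon sequence variant (ASV) to
  `freshwater`, `human_fecal`, `sewer`, or `uncategorized` by full-length
  exact matching against labeled reference databases, with freshwater
  precedence and a percentile inclusion filter (an ASV matching a sewage-side
  reference is admitted only if its 5th-percentile relative abundance in
  river samples is below the reference's 95th-percentile relative abundance
  in raw sewage); summarize per-sample category proportions and the combined
  sewer + human-fecal "sewage proportion".
* **HB quantification** — convert qPCR Cq values to copy number (CN) per
  100 ml through a fitted standard curve (efficiency = 10^(−1/slope) − 1),
  with LOD/LOQ censoring (LOQ: 15 CN/reaction ≡ 180 CN/100 ml) and the
  four-way categorization *undetectable / unquantifiable / quantifiable /
  risk* (risk: ≥ 7,800 CN/100 ml).
* **Mass-balance threshold** — a Monte Carlo simulation over log-normal
  inputs converts the HB risk concentration into an expected sewage-sequence
  relative-abundance threshold via

      f = C_river,HB / C_sewage,HB
      r = (C_sewage,cells · f) / (C_river,cells · (1 − f))

  where *f* is the volumetric sewage fraction and *r* the sewage-sequence
  relative abundance, summarized as a geometric mean with a ±1 geometric-SD
  interval (an exact analytic small-*f* oracle validates the simulation).
* **Concordance** — cross-classify samples against the dual thresholds (HB
  concentration vs. sequence proportion) into four quadrants and tabulate
  agreement.
* **Indicator ASVs** — indicator-value components per ASV and HB category
  (specificity = group-mean abundance concentration, sensitivity = occurrence
  frequency), reporting ASVs with both ≥ 0.8.
* **Community metrics** — Shannon/Simpson alpha diversity, Bray-Curtis
  dissimilarity, and one-factor PERMANOVA with exact small-n enumeration.
* **Synthetic surveys** — a fully seeded generator produces reference
  databases, mixed river communities with known per-sample sewage fractions,
  and coupled, censored HB observations, so the entire pipeline is testable
  against ground truth without external data.

## Worked example

```python
import numpy as np
import sewagesense as ss
from sewagesense.synthetic_data import DEFAULT_SYNTHETIC_CURVE

# a synthetic 16-site x 5-date survey with known ground truth
cfg = ss.SyntheticConfig(seed=42)
bundle = ss.generate_bundle(cfg)

part = ss.partition(bundle["table"], *bundle["databases"])
print("ASVs per category:", part.summary())

sp = ss.sewage_proportion(bundle["table"], part)
print(f"sewage proportion: {100*sp.min():.2f}% - {100*sp.max():.2f}%")

hb = ss.quantify_table(bundle["qpcr"], DEFAULT_SYNTHETIC_CURVE)
print(hb["category"].value_counts().to_dict())

est = ss.run_monte_carlo(ss.example_monte_carlo_config(seed=42))
print(f"threshold r = {100*est.r_central:.1f}% "
      f"(+-1 GSD: {100*est.interval_lo:.1f}% - {100*est.interval_hi:.0f}%)")

results = [ss.HBResult(None if np.isnan(r.cn_per_100ml) else r.cn_per_100ml,
                       r.censor, sample_id=r.sample_id)
           for r in hb.itertuples()]
frame, counts = ss.classify_table(results, sp,
                                  ss.ThresholdPair(7800.0, est.r_central))
print(counts.to_dict())
```

prints

```
ASVs per category: {'freshwater': 150, 'human_fecal': 30, 'sewer': 100, 'uncategorized': 80}
sewage proportion: 0.02% - 96.20%
{'quantifiable': 51, 'risk': 25, 'unquantifiable': 2, 'undetectable': 2}
threshold r = 10.1% (+-1 GSD: 1.3% - 79%)
{'below_both': 39, 'hb_only': 11, 'seq_only': 16, 'above_both': 14, 'n_total': 80, 'agreement': 53, 'agreement_fraction': 0.6625}
```

Reading the output: every generated ASV is recovered in its true source
category (150 freshwater and 80 terrestrial/uncategorized background ASVs,
130 sewage-side ASVs); per-sample sewage proportions span four orders of
magnitude across the simulated pollution gradient; HB categorization places
most samples above the LOQ; the example Monte Carlo configuration puts the
sequence threshold near 10% with a wide ±1 GSD interval (dominated by river
cell-concentration variability); and the concordance table shows how the two
indicators agree (66% here — the survey's measurement noise and the
independent variability of cell concentrations drive the discordant
quadrants).

The same stages are available as shell commands (`sewagesense simulate |
partition | hb | threshold | concordance | indicators | diversity`); run
`sewagesense --help` for the file formats.

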