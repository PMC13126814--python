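# cldn5kit

Analysis toolkit for studying how claudin-5 splice isoforms reshape the
paracellular pores of the blood-brain barrier after ischemic stroke.
Claudin-5 appears in brain microvessels as several immunoreactive
species — the canonical ~35 kDa isoform 1, a ~25 kDa isoform 2 arising
from alternative splicing, and a ~10 kDa fragment — and the three parts
of this package mirror the three quantitative questions that raises:

1. **Pore-barrier quantification** (`profile_model`, `barrier_metrics`,
   `group_stats`): given axial profiles of pore radius r(z) and
   electrostatic potential V(z) sampled along the channel centerline of
   claudin tetramer *seams* (cis-dimer A/B × pore I/II, four replicate
   systems per isoform), compute the steric bottleneck r_min, the
   potential at the bottleneck V_bottleneck, barrier height, span,
   width at 1 kT/e, mouth slopes, signed areas and centroid, and the
   log-space permeability/selectivity indices

   PI_cat ∝ r_min² · e^(−V_bottleneck),  PI_anion ∝ r_min² · e^(+V_bottleneck),
   SI_elec = PI_anion / PI_cat,

   then compare isoform groups with bootstrap CIs (percentile, 10,000
   resamples by default), exact Mann-Whitney U tests and log-sum-exp
   ratios of group means that stay finite across tens of orders of
   magnitude.

2. **Splice-junction auditing** (`junction_audit`): a five-step
   validation of candidate junctions from spliced SAM alignments —
   donor/acceptor motif class (GT-AG / GC-AG / AT-AC / noncanonical) on
   the transcript strand, aligner-style per-motif filter emulation,
   annotation context (including *intra-exonic* events inside a
   single-exon gene), alignment-level inspection (unique support,
   overhang, MAPQ), and strand specificity from proper-pair SAM flags
   (99/147 vs 83/163) under the library protocol.

3. **Isoform-outcome correlation** (`outcome_correlation`): per-pair
   simple linear regression of outcomes (infarct, edema and hemorrhage
   volumes in mm³, 28-point neuroscore) on isoform densitometry, with
   Benjamini-Hochberg q-values across the family, a severe-hemorrhage
   sensitivity re-analysis (animals with hemorrhage > 5 mm³ excluded)
   and an advisory ROUT-style outlier screen.

`synthetic_data` generates seeded inputs for all three stages —
seam profiles matching isoform archetype targets, cohorts with planted
isoform-1 effects, and spliced read sets over a toy single-exon gene —
so the entire pipeline is testable without any external download.

## Worked example

```bash
cldn5kit all --seed 3 --out-dir run
```

runs the full synthetic pipeline and prints the headline summary:

```json
{
  "delta_r_min_iso2_minus_iso1": -15.870857328585775,
  "delta_v_bottleneck_iso2_minus_iso1": -56.667851548454166,
  "log10_pi_cat_ratio_iso2_over_iso1": 24.220127945468207,
  "n_junctions": 1,
  "junction_verdicts": ["genuine-candidate"],
  "n_correlation_pairs": 12,
  "severe_excluded": 8
}
```

Reading this: the simulated isoform-2 seams have a bottleneck ~16 Å
narrower and a positive barrier ~57 kT/e weaker than isoform 1, which
exponentiates into a ~10²⁴-fold higher cation-permeability index
(iso2/iso1) — the weaker electrostatic barrier overwhelms the narrower
lumen. The planted GC-AG junction is recovered and judged a genuine
candidate by all five audit steps, and 12 isoform-outcome regressions
were fitted, with 8 severe-hemorrhage animals excluded in the
sensitivity re-run. Per-stage tables (`seam_metrics.tsv`,
`group_comparison.json`, `junction_audit.json`, `correlations.json`,
`cohort.csv`) and a manifest with the seed and config hash land in
`run/`. Each stage is also available as its own subcommand
(`simulate-profiles`, `barrier`, `compare`, `junctions`, `audit`,
`simulate-cohort`, `correlate`) and as plain library functions.

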