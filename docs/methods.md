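# Methods

## Pore-barrier model

Each claudin tetramer *seam* (cis-dimer A or B crossed with pore I or
II; the design gives four replicate systems per isoform) is reduced to
a one-dimensional axial profile: positions z in Å along the pore
centerline (z increases toward the extracellular side; no origin is
imposed), pore radius r(z) in Å, and electrostatic potential V(z) in
kT/e (thermal energy per elementary charge; 1 kT/e ≈ 26.7 mV at
310 K). Computing r(z) and V(z) from three-dimensional structures is
out of scope — profiles are inputs, consumed as given on whatever grid
they were sampled (at least five nodes, strictly increasing z,
strictly positive radius). Between nodes the profile is treated as
piecewise linear, which makes every integral below exact and all
descriptors invariant under grid refinement.

Descriptors per seam:

* **Bottleneck**: r_min is the global radius minimum; ties break to
  the smallest z so output is deterministic. V_bottleneck is V sampled
  at that node. A single static profile per seam is used; no frame
  averaging is modelled.
* **Barrier height** is max V minus a baseline. The profile carries no
  absolute reference level, so the baseline is the mean of V at the
  two endpoints (the pore mouths). **Span** is max V − min V and can
  exceed the height when the profile dips negative.
* **Width at 1 kT/e** is the axial length of the contiguous interval
  containing the global V maximum where V ≥ 1 kT/e, with crossings
  located by linear interpolation (zero, flagged, when the barrier
  never reaches the threshold). **Mouth slopes** are the secant slopes
  of V from each threshold crossing to the peak. The literature names
  these metrics without defining them; these operational definitions
  are this package's, and the threshold is a parameter.
* **Signed areas** ∫max(V,0)dz and ∫max(−V,0)dz use the trapezoid rule
  with interpolated zero crossings (exact for piecewise-linear V); the
  **centroid** of the positive part uses the exact per-segment first
  moment of a linear function, so it too survives refinement to 1e-9.

Permeability indices combine the pore cross-section with a Boltzmann
factor of the bottleneck potential: PI_cat ∝ r_min²·e^(−V) for cations
and, by symmetry of the ion charge, PI_anion ∝ r_min²·e^(+V) (only the
cation form is conventional; the anion form is this package's choice).
SI_elec = PI_anion/PI_cat is an anion-preference index. Realistic
bottleneck potentials of 100–160 kT/e put the linear values at
10^±40 and beyond, so every index is computed and stored in log10;
linear values are never materialised, and ratios of group means are
evaluated by log-sum-exp.

## Group statistics

Built for the n = 4 per-isoform seam design:

* Group deltas are differences of arithmetic means (iso2 − iso1 by
  convention in the pipeline outputs).
* Confidence intervals are percentile bootstrap (default 10,000
  resamples, level 0.95), seeded; for a two-group delta both groups
  are resampled jointly and the difference of means is bootstrapped —
  bootstrap-of-difference rather than difference-of-bootstraps.
  BCa was deliberately not used: nothing in the target workflow
  requires more than the percentile interval, and its behaviour on
  n = 4 is easier to reason about.
* Mann-Whitney U is exact for combined samples of ≤ 12: mid-ranks are
  assigned to the pooled data and all C(n_a+n_b, n_a) rank assignments
  enumerated, giving the conditional distribution of U given the
  observed ties; the two-tailed p is the mass at or beyond the
  observed U and its reflection n_a·n_b − U. Larger samples use the
  tie-corrected normal approximation (scipy). The small-sample exact
  path matters because the 4 v 4 design's smallest possible two-tailed
  p is 2/70 ≈ 0.029 — the normal approximation is misleading there.
* Normality gating follows Shapiro-Wilk at α = 0.05; samples with
  n < 3 or zero variance cannot be tested and are flagged
  nonparametric.
* FDR is Benjamini-Hochberg step-up (statsmodels), reported as
  q-values alongside raw p-values.

## Outcome correlations

One ordinary-least-squares fit per (predictor, outcome) pair on
pairwise-complete observations (missingness is per-pair because real
cohort panels have varying N); slope p-values from the t statistic
with n−2 df; zero-residual fits report p = 0 with a degeneracy flag.
q-values are BH over the family of all pairs fitted in the run — which
correlations constitute "the family" is genuinely open, and the run's
full set is the least arbitrary choice. The severe-hemorrhage
sensitivity analysis removes animals with hemorrhage volume strictly
greater than 5 mm³ and refits everything; animals with a missing
volume are retained. The neuroscore is analysed as the raw 0–28 score
(28 = normal; lower is worse).

The ROUT-style outlier screen is a simplified re-creation of a
procedure specified only as implemented in proprietary software: a
Theil-Sen line refined by one Tukey-bisquare reweighted pass,
residuals scaled by 1.4826·MAD, two-sided t probabilities, and BH at
Q = 1% (configurable). Flags are advisory; no observation is ever
removed silently. It should not be expected to match the original
procedure point-for-point.

## Junction audit

Junctions come from reference-skip (N) CIGAR operations; M/=/X/D/N
consume reference, I and soft clips do not, hard clips are ignored.
Intron coordinates are 1-based with inclusive ends. A read's overhang
at a junction is the smaller of its aligned (M/=/X) base counts
flanking the skip. "Uniquely mapped" is operationalised as MAPQ ≥ a
threshold and NH tag ≤ 1. Motif classification reads the first and
last two intronic bases on the transcript strand (reverse-complemented
for minus-strand junctions); strand-unknown junctions are classified
on whichever single orientation yields a canonical or semi-canonical
class, and ambiguous cases are reported noncanonical with a flag.
Strand inference uses only the four proper-pair flags 99/147 (forward
fragment) and 83/163 (reverse); all other flags are uninformative, and
the fragment-to-transcript mapping (FR direct, RF inverted, unstranded
= unknown) is configuration, not inference, because library
strandedness generally cannot be recovered from flags alone. The
aligner-style filter emulates the shape of default junction filters —
minimum overhang 12 for GT-AG/GC-AG/AT-AC and 30 for noncanonical,
minimum unique support 1 and 3 respectively, boundaries inclusive —
as configurable thresholds; it does not claim bit-compatibility with
any aligner. A junction is a "genuine candidate" when its motif is at
least semi-canonical, at least one unique read supports it, and the
inferred strand matches the overlapping gene (unknown is accepted for
unstranded data).

## Synthetic data

The generators define the conditions every test and headline number is
computed under; all are pure functions of their arguments and a seed.

* **Seam profiles**: radius is a Gaussian constriction (mouth radius
  60 Å, width 8 Å) and potential a central Gaussian barrier (width
  6 Å) flanked by negative Gaussian wells at ±25 Å (width 3 Å) whose
  amplitude is solved so that span = max V − min V hits its target
  exactly; the wells are what let span exceed barrier height, as the
  isoform-2 profiles require (span 297.7 > barrier 100.6). Archetype
  targets default to the published group means (iso1: r_min 39.7 Å,
  V 159 kT/e, span 224 kT/e; iso2: 25.8 Å, 100.6 kT/e, 297.7 kT/e),
  so the pipeline's headline deltas are recovered by construction plus
  jitter — per-seam source values are unpublished, and matching the
  group means is the strongest statement the generator can make. At
  zero jitter every descriptor reproduces its target to 1e-6 relative;
  jitter multiplies each per-seam target by 1 + σ·N(0,1) (floored at
  0.05). What this does **not** emulate: real seam-to-seam correlation
  structure, asymmetric or multi-peaked barriers, radius-potential
  coupling — so passing tests show the descriptors and statistics are
  computed correctly, not that real claudin assemblies behave this way.
* **Cohort**: isoform densities are log-normal (β-actin-normalised
  ratios near 1); edema and infarct are linear in iso1 density
  (defaults 12 and 15 mm³ per density unit) plus Gaussian noise
  (sd 4 mm³, a moderate signal-to-noise that leaves slopes clearly but
  not trivially detectable at n = 50, the middle of a realistic
  per-panel range); the neuroscore decreases with iso1 (−8 points per
  unit), is rounded and clamped to [0, 28]. The severe subgroup
  (default 15% of animals, those with the highest iso1) gets
  hemorrhage > 5 mm³ increasing with iso1; everyone else's hemorrhage
  is small and isoform-independent, so excluding > 5 mm³ removes the
  association entirely — the planted version of a severe-driven
  correlation. Clamping and the |normal| hemorrhage baseline make two
  outcomes mildly non-normal; the type-I-error check carries a
  correspondingly widened binomial tolerance.
* **Spliced reads**: a uniform-random genome with the requested
  donor/acceptor dinucleotides planted at the intron ends (on the
  transcript strand of the gene), a single-exon gene spanning the
  junction ±500 bp, and paired 50-bp reads at fixed insert size
  (variability in fragment length adds nothing to the contracts under
  test). A chosen fraction of pairs splices across exactly the planted
  intron with uniformly drawn overhangs; flags follow the fragment
  orientation implied by gene strand and library protocol; an optional
  contamination fraction plants antisense pairs. No sequencing-error
  or base-quality model.

## Numerical and reporting choices

* Profile TSVs serialise floats at 17 significant digits so write/read
  round trips are exact identities.
* Sub-seeds for pipeline stages are derived from the run seed by
  hashing the stage name (SHA-256, reduced below 2^31), so stages are
  independently reproducible and adding a stage never perturbs
  another's stream.
* The headline log10 PI_cat group ratio of a single simulated 4 v 4
  draw has a standard deviation near 3 decades — 5% multiplicative
  jitter on a ~159 kT/e potential is exponentially leveraged — so the
  reported headline is the mean over 20 replicate simulated seam-set
  pairs (standard error ≈ 0.7), a stable estimator of the same
  quantity.
* Problem sizes used by the test suite and acceptance script (4 seams
  per isoform, 20 replicate pairs, 100 read pairs, cohorts of 20–50,
  500 bootstrap-coverage replications, 500 null cohorts, 1000
  randomized CIGARs) were chosen as the smallest sizes at which each
  statistical statement is sharp.

## Known limitations

* The permeability indices are barrier descriptors, not transport
  calculations: no ion-ion correlation, dielectric self-energy, or
  applied-potential physics. Group ratios of exponentiated quantities
  are dominated by the extreme seams and are reported in log10 for
  that reason.
* Exact published per-seam values and per-animal data are not
  available, so numerical agreement with published per-seam or
  per-animal statistics beyond the group-mean deltas cannot be — and
  is not — claimed.
* The aligner filter emulation and the ROUT approximation are
  intentionally simplified models of external tools' behaviour.
* Kruskal-Wallis/ANOVA machinery for multi-group animal comparisons is
  out of scope.
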