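# Methods

This note documents the models and numerical choices behind `suitbiome`:
what the synthetic generator emulates, how each analysis stage is
defined, which parameters matter, and what the tests do and do not
establish about real data.

## The synthetic study

The generator reproduces the *design* of a spacesuit swab campaign:
`n_sets = 7` assembled suit sets, each sampled at three components
(wrist joint WJ, inner gauntlet IG, outer gauntlet OG) on both sides
(L/R), each swab split into a PMA-treated and an untreated aliquot, plus
one PMA/untreated control-swab pair per set — 98 samples. Set 5 is
labelled MACES, all others EMU, mirroring a campaign dominated by EMU
suits with a smaller pressure-suit contingent.

### Composition model

The 660-taxon pool is partitioned into:

* a **core** of 150 taxa present in every suit sample (80% of the mass,
  weights from a concentrated Dirichlet so no core taxon is rare enough
  to drop out at the default depth);
* 13 **kitome** taxa (reagent contaminants): dominant in controls
  (≈ 2 000 expected reads per taxon per control), present at 0.5% total
  mass in suit samples;
* 30 **set-accessory** taxa per set (15% of mass), giving each set its
  own deterministic community signature;
* a reserve of **per-sample novel** taxa: each suit site draws 4 taxa
  (1.6% total mass) from this pool, modelling transient contaminants and
  driving continued union-curve growth.

Hierarchical dispersion is multiplicative: the set composition is the
base composition times independent mean-one gamma noise with shape
1/(2·`set_effect`), renormalized; each sample repeats this with
`component_effect`. The effect scales are therefore interpretable as the
order of Jensen–Shannon divergence they induce (defaults 0.05 and 0.02;
an effect of 0 switches that level off, and `set_effect = 0` also pools
the accessory blocks so sets become exchangeable). A gamma-multiplier was
chosen over re-drawing from a low-concentration Dirichlet because the
latter's lower tail collapses individual taxa to zero, which would
contradict the generator's guarantee that core taxa occur in every
sample; counts given the composition remain multinomial, with library
sizes Poisson(`reads_per_sample` = 500 000), so suit samples total ≈ 47 M
reads — the scale at which a 512-unique-marker filter leaves the intended
~150–200 species per sample.

Unique-marker counts are Poisson with mean `marker_rate` (800) markers
per 1 000 reads of the taxon; only the 512 threshold downstream gives
them meaning. PMA viability is a per-taxon Bernoulli(`viable_fraction` =
0.85) mask; core taxa are always viable (the core community is defined
on viable-cell profiles). In PMA aliquots non-viable taxa have their
proportions multiplied by 0.005 before renormalization, so their
expected PMA counts are well under 1% of the untreated counterpart.
Controls are 99% kitome plus 1% spillover of the set's composition.
Planted differential-abundance effects multiply a taxon's proportion by a
fold change in the targeted metadata group.

What the generator does **not** emulate: read-level error, human-read
contamination, classifier database bias, variable sequencing depth
across components, taxon-taxon correlations, and the long-tailed
abundance distributions of real communities. Passing tests therefore
demonstrate that the analysis recovers structure the model can express;
they say nothing about classifier artefacts or database-dependent counts.

### Clone genomes

Each clone group has an ancestor sequence (uniform random bases) copied
to its members with independent per-site substitutions at rate d/2,
where d is the group's **pairwise** divergence (two members then differ
at an expected d(1 − d/3) per site; substitutions always change the
base). Background genomes are independent random sequences — 150 kb by
default, long enough that 16-mer collisions between unrelated genomes
are negligible. Ten percent of background genomes deliberately violate
the completeness/contamination gate so the QC stage always has work.
There are no indels or rearrangements; the ANI estimator is calibrated
only against substitution divergence.

### AMR table

Each of 40 genes gets a length uniform in [300, 3000] bp and a
three-level ontology label (class, mechanism, group). A sample carries
Poisson(3) genes (outer gauntlet: doubled, reflecting higher exposure),
each with 1 + Poisson(50) reads. A per-class incidence scenario can be
planted exactly (classes present in a prescribed number of samples).

## Analysis definitions and numerical choices

* **Marker filter** is per (sample, taxon) cell: a taxon kept in one
  sample may be zeroed in another. This is the stricter reading of a
  per-sample classifier report and is recorded in the filter log.
* **Abundance filter**: floor relative to the sample's own total;
  "at least" semantics keep the boundary value. Filters are idempotent
  and commute with sample subsetting.
* **Kitome**: flagged when summed control reads strictly exceed 10 000;
  per-taxon `present_in_controls` uses any nonzero control read. Counts
  are never subtracted — downstream stages may exclude flagged taxa
  explicitly.
* **Entropy/JSD** use natural log with 0·ln 0 ≡ 0; profiles are
  union-aligned with zero fill. JSD itself (not its square root) is the
  distance, bounded by ln 2 ≈ 0.693.
* **Triplets** are built per (set, side) from whatever samples are
  selected; incomplete combinations are skipped, so the triplet count is
  data-dependent.
* **Control distances** are computed on raw (unfiltered) profiles: the
  marker filter reduces low-biomass controls to kitome taxa only, which
  would force every control–component divergence to the ln 2 ceiling.
* **Welch's t** uses the Welch–Satterthwaite degrees of freedom; a
  zero-variance comparison is reported as t = 0, p = 1. Note that
  pairwise distances sharing a sample are dependent, so p-values from
  distance comparisons are conservative under the null rather than
  exactly uniform (the classic motivation for permutation tests on
  distance matrices); the package follows the t-test convention of the
  study design it reproduces.
* **One-way ANOVA** with all observations identical is reported as the
  degenerate F = 0, p = 1 case.
* **Rarefaction**: 16 random subsets per pooled-group count x, drawn
  without replacement within a subset and independently across draws;
  at x = M every draw is the full group set, so the union endpoint
  equals total richness exactly. The log-model flattening rule is
  predicted slope at M below 1% of predicted richness at M (`slope_tol`
  = 0.01); a decreasing (intersection) curve is therefore always
  flattened, which matches its interpretation as a converging core
  estimate.
* **Differential abundance**: 128 Monte Carlo instances, Dirichlet prior
  0.5 (the canonical settings of the published procedure this follows),
  expected p = mean raw p over instances, BH applied once across taxa on
  expected p. Wilcoxon uses exact enumeration below 8 per group and the
  normal approximation with tie correction otherwise. The ">2 groups"
  branch is a Gaussian linear model on CLR values with a group factor,
  i.e. one-way ANOVA. Averaging p over instances makes the test
  deliberately conservative: null call rates in simulation are ≈ 0, far
  below the nominal 5%. Effect size (two groups) is the median over
  instances of the difference in group median CLR. The planted-effect
  power scenario pins the shifted taxon at the typical 1/K abundance so
  that detectability reflects the fold change rather than a lottery over
  base abundance.
* **ANI**: the shorter genome of a pair is cut into non-overlapping
  1 kb fragments; anchors are exact 16-mer matches sampled every 64 bp;
  the modal anchor diagonal places the fragment and a gap-free
  comparison scores it; fragments at ≥ 80% identity count as mapped;
  ANI is the mean mapped-fragment identity and coverage is mapped bases
  over the arithmetic mean of the two genome lengths (the literal
  "average lengths of the genomes"). Query = shorter genome makes the
  estimate symmetric by construction. Edge filters keep coverage ≥ 0.5
  and ANI ≥ 99.0 (boundaries inclusive; the Methods-style 99.0 is the
  default with 99.5 available via `--min-ani`). On planted data the
  estimator tracks divergence to within ~0.03 ANI points at 200 kb; the
  0.2-point contract leaves room for shorter genomes.
* **Strain components** are plain connected components; a component is
  "fully connected" when every member pair has a surviving edge.
  Singletons are kept (flagged), so components partition the retained
  genomes.
* **RPKM** divides by the sample's total (non-host) read count from
  metadata, not the AMR-mapped subtotal — the reading that matches
  "normalized by total reads per sample". Detection for incidence is
  reads > 0 with no RPKM floor.
* **Pipeline determinism**: one master seed; each stage derives its seed
  as SHA-256(seed:stage) mod 2³¹, so adding a stage never perturbs
  another stage's draws. Reruns are byte-identical; stage wall-clock
  timings are kept on the in-memory report object only.

## Problem sizes

Default experiment sizes were chosen so the whole suite and the
acceptance script run comfortably on a single CPU: 98 samples × 660
taxa at 0.5 M reads/sample for profile analyses; 52 genomes of 150 kb
for the strain scenario (20 replicates in the recovery check); 200 kb
genomes for ANI calibration; 10+10 samples × 200 taxa × 128 Monte Carlo
instances for the differential-abundance operating characteristics
(20 replicates); 100 structured and 200 null replicates for the
set-structure checks.

## Known limitations

* Substitution-only genome model: no indels, rearrangements or
  horizontal transfer; the fragment ANI would under-cover indel-rich
  real genomes.
* The Welch-on-distances null is conservative, not calibrated (see
  above); effect direction and magnitude, not the null p distribution,
  are the reliable outputs.
* Species-level only: higher-rank aggregation passes through untouched.
* The generator's kitome/control model is simple (fixed spillover); it
  exercises the flagging logic but not complex cross-contamination.
* Database-dependent quantities from real studies (absolute species
  counts, specific taxa) are outside what synthetic data can reproduce;
  comparisons to such numbers are qualitative.
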