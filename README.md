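# suitbiome

Analysis toolkit for surface metagenomes of spacesuits (and similar
low-biomass built environments), built around the question: **do the same
viable microbial strains live on physically connected but distinct suit
components** — the wrist joint (WJ), inner gauntlet (IG) and outer
gauntlet (OG) of an assembled suit "set"?

It is aimed at microbiologists and planetary-protection analysts working
with k-mer-classifier taxonomic profiles (per-sample read counts plus
unique-marker counts per taxon), paired PMA-treated / untreated swabs
(propidium monoazide masks DNA from membrane-compromised cells, so the
PMA aliquot approximates the viable community), control swabs, draft
genomes binned from assemblies, and antimicrobial-resistance (AMR) gene
counts. Because raw sequencing data for such studies is rarely practical
to re-process, the package ships a synthetic-data generator that emulates
the full study design with known ground truth, so every stage is testable
end to end.

## What it computes

* **Profile filters** — per-cell unique-marker floor (default: a taxon
  needs ≥ 512 unique marker k-mers in a sample), per-sample relative
  abundance floor (≥ 0.01%), and control-based "kitome" flagging (taxa
  whose summed control reads exceed 10 k are reported as likely reagent
  contaminants; counts are flagged, never subtracted).
* **Diversity** — alpha diversity as Shannon entropy
  H = −Σ pᵢ ln pᵢ of the sum-normalized profile; beta diversity as the
  Jensen–Shannon divergence JSD(p,q) = H(m) − ½[H(p) + H(q)], m = ½(p+q),
  natural log so 0 ≤ JSD ≤ ln 2. Samples from one (set, side) form a
  (WJ, IG, OG) triplet; within-set vs between-set distance distributions
  are compared with a two-sided Welch's t-test, controls likewise. A
  seeded UMAP embedding of the JSD matrix is available for exploration,
  and cosine similarity ranks profiles against reference body-site
  profiles.
* **Core community** — sample-based rarefaction over suit sets in union
  ("Any": taxa on at least one pooled sample) and intersection ("All":
  taxa on every pooled sample) modes, 16 random subsets per pooled-group
  count, with a logarithmic fit y = a + b ln x and a flattening call;
  prevalence-based core (≥ 90% of samples) and high-prevalence
  (all-but-one) taxa.
* **Differential abundance** — ALDEx2-style: per sample, Monte Carlo
  instances from Dirichlet(counts + ½), centered log-ratio transform,
  Wilcoxon rank-sum (two groups) or one-way ANOVA (more) per taxon per
  instance, expected p averaged over instances, Benjamini–Hochberg across
  taxa, calls at q ≤ 0.05.
* **Strain sharing** — draft genomes pass a completeness ≥ 50% /
  contamination ≤ 20% gate; every pair gets a fragment-mapping average
  nucleotide identity (1 kb fragments anchored by exact 16-mers, gap-free
  extension); pairs covering ≥ half the mean genome length at ANI ≥ 99%
  form edges, and connected components of that graph are candidate shared
  strains, reported with their suit locations.
* **AMR genes** — RPKM = reads / [(gene length/1000) × (sample
  reads/10⁶)], per-resistance-class sample incidence, and gene-richness
  rarefaction.

## Worked example

Run the complete pipeline on the default synthetic study (98 samples:
7 sets × 3 components × 2 sides × {PMA, untreated} + 7 control pairs,
660-taxon pool with a planted 150-taxon core, 13 kitome taxa, and two
planted clone-genome groups of 7 and 5 members at 0.5% divergence):

```bash
suitbiome run --seed 1 --outdir out/
```

`out/report.json` then contains (abridged):

```json
{
  "beta_diversity": {
    "mean_within_set_jsd": 0.0196,
    "mean_between_set_jsd": 0.1246,
    "welch_p": 1.07e-310,
    "n_triplets": 12
  },
  "core_community": {
    "core_size": 149,
    "intersection_asymptote": 145.0,
    "union_total": 399.0,
    "union_flattened": false,
    "intersection_flattened": true
  },
  "strains": {
    "n_multi_components": 2,
    "multi_component_sizes": [7, 5],
    "n_retained_genomes": 48
  },
  "kitome_flagged": 13
}
```

Reading this: components of the same suit set are far more similar to
each other (mean JSD 0.020) than to components of other sets (0.125), and
Welch's test rejects equality overwhelmingly — the set you sample
determines the community you see. The intersection ("All") rarefaction
curve flattens near 145–150 species, recovering the planted core
community, while the union ("Any") curve keeps rising — more sampling
would keep finding new accessory taxa. Both planted clone groups are
recovered as fully connected ANI components spanning 7 and 5 samples:
the shared-strain signature across wrist and gauntlet locations. All 13
planted reagent contaminants are flagged from the control swabs.

Every stage is also exposed as a library function
(`suitbiome.diversity.jsd_matrix`, `suitbiome.diff_abundance.run_da`,
`suitbiome.strain_match.ani_pair`, ...) and as CLI subcommands
(`suitbiome simulate|filter|diversity|rarefy|core|da|strains|amr`).

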