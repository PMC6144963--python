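# coimeta

A toolkit for COI-based eDNA metabarcoding of coastal metazoan communities:
amplicon read processing, reference-database curation, species-level
taxonomic assignment, reference-completeness audits, and the community
statistics used in spatio-temporal biodiversity surveys — together with a
fully ground-truthed synthetic amplicon generator that makes every stage
testable end to end.

## The problem

Environmental DNA (eDNA) metabarcoding amplifies a taxonomically
informative marker — here two overlapping fragments of mitochondrial
cytochrome c oxidase subunit I (COI1, a 313 nt insert; COI2, 325 nt) —
from filtered water samples and sequences millions of reads per sample.
Turning those reads into a community table requires a chain of decisions
whose behaviour is hard to validate on field data, because the truth is
unknown: pair merging (minimum 30 nt overlap), degenerate-primer
demultiplexing (both primers of the same marker must flank the read;
inserts < 270 nt are discarded), reference curation (terrestrial records
and records without a species-level name are removed), direct assignment
at ≥ 97 % identity with multi-hit curation, and OTU clustering at 97 %
similarity to measure how much of the community the reference database can
name at all.

`coimeta` implements that chain as a library plus CLI, and pairs it with a
synthetic-data module that plants a known community (log-normal abundances,
habitat/depth/season effect multipliers, river-borne freshwater species,
near-empty negative controls) so that every pipeline property — lossless
recovery, error tolerance, filter exactness, statistical calibration — is
checked against ground truth.

## Core methods

- **Identity**: semiglobal alignment with free terminal gaps on the
  reference (a 313 nt insert contained in a 650 nt barcode scores 1.0);
  identity = matches / aligned columns. Assignment keeps the single best
  species at ≥ 0.97; equal-best hits to several species are held out and
  tallied for curation.
- **OTU completeness**: abundance-sorted greedy centroid clustering at 97 %
  similarity, singletons removed; per phylum, the fraction of OTUs whose
  representative matches a reference in [0.97, 1.0] among those in
  [0.80, 1.0].
- **Community statistics**: Hellinger transformation
  y'ᵢⱼ = √(yᵢⱼ/Σⱼyᵢⱼ); PERMANOVA with pseudo-F =
  (SS_A/(a−1))/(SS_W/(N−a)) and label-permutation p-values; PCoA by Gower
  double-centering; SIMPER decomposition of between-group Bray–Curtis
  dissimilarity; Shannon H = −Σ pᵢ ln pᵢ; exact hypergeometric sample- and
  read-based accumulation curves; abundance-based Chao–Jaccard/Sørensen
  similarity with unseen-shared-species correction; randomized-block ANOVA
  and pooled-variance t tests for diversity contrasts.
- **Coverage audit**: for a species checklist and a reference snapshot,
  the fraction of species with any barcode record, and the fraction whose
  record contains both primer binding sites (IUPAC-aware, ≤ 2 mismatches,
  spacing within ±10 % of the expected insert).

## Worked example

```python
from coimeta.pipeline import run_synthetic_pipeline
from coimeta.simulate import SiteSpec, CommunityDesign, Effect, build_species_pool

marine = sorted(s.species_name for s in build_species_pool(seed=7)
                if s.habitat_class == "marine")[:10]
sites = [SiteSpec(f"WC{i}", "water_column") for i in range(4)] + \
        [SiteSpec(f"TP{i}", "tide_pool") for i in range(4)]
design = CommunityDesign(
    sites=sites, reads_per_sample=2000, error_rate=0.005, n_controls=2,
    seed=0, effects=[Effect("habitat", "tide_pool", tuple(marine), 3.0)],
)
res = run_synthetic_pipeline(design=design, fraction_with_barcode=0.5,
                             seed=7, run_otu_profile=True,
                             run_coverage=True, run_stats=True)
```

which prints (via the snippets in `res.stats`, `res.otu_profiles`,
`res.coverage`, `res.control_summary`):

```
samples: 18  curated references: 30
PERMANOVA (habitat, Hellinger distance): pseudo-F=10.96  R2=0.44  p=0.001
top SIMPER contributors:
  Genus001 species00: 20.1%  (cumulative 20.1%)
  Genus007 species05: 10.1%  (cumulative 30.2%)
  Genus000 species05: 8.1%  (cumulative 38.3%)
COI1: fraction of OTUs identifiable to species: 0.50
COI2: fraction of OTUs identifiable to species: 0.50
native checklist coverage (COI1): 0.50 with records, 0.50 with intact primer sites
        total_reads  percent_of_mean_sample  flagged
CTRL00            0                   0.000    False
CTRL01            1                   0.082    False
```

Reading: the ×3 abundance boost planted on ten species in tide pools is
detected (R² = 0.44, p = 0.001, the smallest value 999 permutations can
give), the boosted `Genus001 species00` dominates the SIMPER table, and —
with only half of the species pool carrying barcode records — almost
exactly half of the OTUs can be named to species, mirroring the planted
database incompleteness. The negative controls carry ≤ 1 stray read
(≪ 1 % of a real sample) and are not flagged.

A CLI covers the same stages: `coimeta simulate`, `coimeta coverage`,
`coimeta stats`, `coimeta run-all --config run.yaml`.

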