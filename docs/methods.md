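# Methods

This note documents the models, algorithms and numerical choices behind
`coimeta`, and what the synthetic-data experiments do and do not
demonstrate about real eDNA surveys.

## Synthetic amplicon model

**Barcodes.** Each mock species carries a 650 nt COI-like barcode laid out
as in the real Folmer region: the COI2 amplicon (forward site + 325 nt
insert + reverse site) sits upstream, and the COI1 forward primer site is
nested *inside* the COI2 insert, so the COI1 amplicon (26 + 313 + 26 nt)
overlaps it — two non-overlapping primer-flanked amplicons of these sizes
cannot fit in a barcode of realistic length, and nesting is how the locus
is actually organised. Primer binding sites are concrete per-genus
realizations of the degenerate primers (IUPAC codes sampled uniformly), so
primer matching is exercised with real degeneracy.

**Genus structure.** Species are organised into genera of 6. Within a
genus, species barcodes are independent mutants of a genus ancestor,
rejection-sampled until every congener pair's identity over *both* insert
windows lies in [0.805, 0.895] — below the 0.97 assignment threshold, but
inside the [0.80, 1.0) band used by the completeness profile. This is the
property that makes the half-reference experiment meaningful: a species
absent from the database still hits a congener at ~85 % and is counted as
"present but unnameable", as unbarcoded taxa are in real surveys. One
designated sister pair sits at ~98–99 % identity to exercise near-tie and
multiple-hit behaviour deterministically. Unrelated genera align at ≲ 60 %
identity. Two terrestrial species (their own genus) and one record without
a species-level name are always present so the curation filters have real
work to do.

**Communities.** True counts are multinomial(reads_per_sample, p) with p ∝
(log-normal base abundance, μ=0, σ=1) × (effect multipliers for the
sample's habitat/depth/season/site levels) × (per-sample log-normal jitter,
σ=0.25, representing sampling overdispersion). Freshwater species get
nonzero probability only in surface samples at river-influenced sites.
Negative controls are all-zero communities that receive 0–5 stray reads at
read synthesis (stray counts are folded back into the truth table so reads
emitted always equal truth counts).

**Reads.** Each read pair is the species' primer-flanked amplicon with iid
substitution errors applied once to the template; both mates are then cut
from the mutated template (forward prefix, reverse-complement prefix of
the reverse strand), so mates agree in their overlap and the per-insert
substitution count is exactly Binomial(insert length, error_rate). The
default error rate is 0.005/base — a realistic post-filter Illumina
substitution load; indels are off by default, which keeps identity
arithmetic analytic ((L−k)/L for k substitutions). Quality strings are a
fixed profile (Q38 with a mild ramp to Q25 over the last 30 cycles).

What this generator does *not* emulate: PCR chimeras, primer-template
mismatch amplification bias, tag jumping, indel sequencing error, copy
number and shedding-rate variation, or eDNA transport/decay. Passing tests
therefore demonstrate the correctness and calibration of the
*bioinformatic and statistical* chain under a controlled error model, not
field-level accuracy of eDNA surveys.

## Read processing

- **Quality trim**: sliding-window rule — cut at the start of the first
  window (default 4 nt) whose mean quality drops below 20, then keep
  individual bases past the cut while they stay ≥ 20 (the conventional
  trimmer behaviour); reads shorter than 100 nt are discarded. In the
  pipeline the trim acts as a pair filter: amplicon merging needs
  full-length mates, so a pair is dropped if either mate would be
  shortened.
- **Merging**: reverse mate is reverse-complemented; every overlap ≥ 30 nt
  is scored; the overlap minimising the mismatch fraction wins, ties going
  to the longer overlap; overlaps with > 25 % mismatches are rejected
  (pair stays unmerged and is excluded downstream). Consensus takes the
  higher-quality base at each mismatch, the forward base on quality ties.
- **Primer split**: anchored search — forward primer at the 5′ end,
  reverse-complemented reverse primer at the 3′ end, each within a ±2 nt
  slack window, IUPAC-aware, with ≤ `max_mismatches` mismatches per primer
  (function default 0; pipeline default 2, since at a realistic error rate
  a zero-tolerance match on 46–52 nt of primer would discard roughly a
  fifth of perfectly usable reads). An `N` in a read matches nothing
  (strict mode, configurable). Both primers must belong to the same
  marker; double or mixed marker hits are rejected as `ambiguous_marker`.
  The ≥ 270 nt length filter is applied to the primer-stripped insert
  (both true inserts, 313 and 325 nt, exceed it; the alternative
  pre-stripping interpretation is available via the threshold parameter).
- All scalar functions have vectorized batch twins used by the pipeline;
  the test suite asserts their equivalence on random inputs, and the
  per-sample read-fate partition (assigned per marker + rejected +
  unmerged + trim-discarded = input) is checked on every run.

## Assignment and completeness

- **Identity** is computed with edlib in semiglobal mode (terminal gaps on
  the reference free) as matches / aligned columns from the alignment
  path. A pigeonhole substring index (split the query into k+1 pieces; a
  hit within k edits must contain one piece verbatim) prunes the
  reference scan exactly — no hit inside the identity band can be missed —
  and banded alignment does the rest; references containing degenerate
  bases bypass the filter.
- **Assignment** dereplicates inserts across samples, aligns each unique
  sequence once, and propagates counts. Best identity ≥ 0.97 with a single
  best species → counted; equal-best identity to > 1 species → the read is
  held out of the matrix and the species set tallied in the multi-hit
  report (the survey practice is to resolve such cases by curating the
  reference, not by splitting counts — the exclusion-list loop is
  implemented and tested for convergence).
- **OTUs**: unique sequences sorted by descending abundance (lexicographic
  tie-break) join the first centroid at ≥ 97 % identity or found a new
  OTU; single-read OTUs are removed; the representative is the centroid.
  This greedy percent-identity clustering replaces d-based linkage
  clustering: the completeness profile only needs representative
  sequences, and 97 % similarity is a percent-identity criterion. The
  greedy pass is verified against a brute-force oracle on small inputs.
- **Profile**: per phylum, OTUs with best reference identity in
  [0.97, 1.0] over those in [0.80, 1.0]; OTUs below 0.80 are reported
  separately as out-of-range. The lower bound is configurable (0.85 is the
  common alternative convention).

## Statistics

- PERMANOVA uses SS_T = Σ_{i<j} d²ᵢⱼ/N, within-group sums scaled by group
  size, and permutes raw sample labels; p = (#{F_perm ≥ F_obs}+1)/(n_perm+1)
  with a mandatory seed. Permutation F values are computed in vectorized
  batches; an exhaustive mode enumerates all N! label orders for small N
  and is tested against a plain-loop oracle. The observed F is also
  cross-checked against scikit-bio's implementation.
- Ordination and testing default to Euclidean distance on
  Hellinger-transformed counts (the Hellinger distance), which suits
  zero-inflated count communities; SIMPER is defined on Bray–Curtis, whose
  pairwise decomposition it conserves to 1e-10. Both distances are
  configurable.
- PCoA reports negative eigenvalues (non-Euclidean input) and drops their
  axes rather than correcting them.
- Accumulation curves use the exact hypergeometric expectations
  E[S_t] = Σᵢ[1 − C(T−Oᵢ,t)/C(T,t)] (samples) and the analogous pooled-read
  form, evaluated with log-gamma for numerical safety; envelopes come from
  seeded resampling (sample-order permutations; multivariate
  hypergeometric subsampling of pooled reads).
- Chao abundance-based similarity follows the shared-species U/V
  estimators with the singleton/doubleton correction (f₊₂ = 0 replaced by
  1), clamped to ≤ 1; raw incidence Jaccard/Sørensen are reported
  alongside.
- Site-structured diversity contrasts use a randomized-block ANOVA (block
  = site, fitted by OLS with type-II tests) as a deliberate stand-in for a
  random-site mixed model — with one observation per site × level cell the
  two coincide in the F test for the fixed factor and REML adds nothing
  here. Season contrasts use the pooled-variance Student t; read
  abundances can be log₁₀-transformed.
- Shannon diversity uses the natural log (base configurable).

## Pipeline

Stages run in order simulate → process → assign (per marker) → profile →
coverage → stats, with per-sample read-fate conservation recorded in a
manifest (config hash, seed, counts per stage). The two markers are
processed independently and their community matrices summed over the
species union for the combined view. Negative controls are summarised
(total reads, percent of the mean real sample, flag above 1 %) and never
subtracted. All randomness flows from one `SeedSequence`, so a rerun with
the same configuration is bit-identical, including the gzipped FASTQ
(header mtime pinned to 0).

## Problem sizes

The validation experiments use desk-scale surveys chosen once: exact
recovery on 20 samples × 10⁴ error-free reads over 60 species; error
tolerance on 20 samples × 2 000 reads at 0.5 % substitution error;
PERMANOVA calibration on 500 exchangeable-null simulations (12 samples,
999 permutations) and power on 200 simulations of the planted ×3
tide-pool effect (10 species, 8+8 samples, 10⁴ reads); completeness
recovery over 20 seeds with half the pool barcoded (5 samples × 1 500
reads each). `scripts/acceptance.py` re-runs the same battery from a
single seed.

## Known limitations

- Identity, not phylogeny: assignment is nearest-neighbour at a fixed
  threshold; no LCA or placement logic.
- The multi-hit report identifies reference ambiguity but resolution is
  manual (exclusion lists), as in survey practice.
- The greedy OTU clustering is order-dependent by design (abundance-first);
  it is a completeness-profiling device, not a denoiser.
- Checklist matching is exact after case/whitespace normalization — no
  synonym or authority resolution.
- The degraded-tail quality model never triggers the trimmer by default;
  trimming logic is exercised by dedicated constructed fixtures instead.
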