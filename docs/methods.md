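# Methods

## Model

A community's average genome size (AGS) is the abundance-weighted mean of
its cellular members' genome sizes, AGS = Σ R<sub>i</sub>S<sub>i</sub> / Σ
R<sub>i</sub>; viral members are excluded from the definition because the
marker families that drive the estimator do not occur in viral genomes. For
an essential single-copy marker family *j*, each cell contributes exactly
one gene copy, so the per-base-pair rate at which a shotgun library samples
family *j* is inversely proportional to AGS. With R<sub>j</sub> = mapped
reads / library bp, the estimator is AGS<sub>j</sub> = C<sub>j</sub> /
R<sub>j</sub>, and the final estimate is a weighted average of the
per-family estimates after outlier removal.

The proportionality constant C<sub>j</sub> cannot be derived analytically —
it folds together the family's gene length, the read length, and the
acceptance region of the mapping cutoffs — so it is calibrated by
simulation (below).

Assumptions: reads are sampled approximately uniformly from member genomes
(the simulator treats genomes as circular for this reason); every cellular
member carries each marker exactly once; the translated search detects
marker-derived reads at the divergence levels present in the community
(robustness to novel taxa is measured explicitly by the holdout benchmark).

## Estimation pipeline

1. Optional QC: exact-duplicate removal, mean-Phred filter, ambiguous-base
   filter (in that order; off by default, `-d -m 5 -u 5` is the setting
   used for short-read human-microbiome-style data).
2. Downsample: first *n* reads of length ≥ *i*, each trimmed from the 3'
   end to exactly *i* bp (deterministic by design; the bootstrap is the
   only random sampler in the package).
3. Translated search of each read (six frames) against the marker protein
   database.
4. A read maps to family *j* iff its top-scoring hit (ties: lower E-value,
   then lexicographic target id) passes *j*'s trained cutoffs at length
   *i*: bit ≥ min bit score, coverage ≥ min coverage, identity ≤ max
   percent identity, all inclusive. Coverage is read-centric: aligned
   peptide columns / ⌊i/3⌋.
5. R<sub>j</sub>, AGS<sub>j</sub> = C<sub>j</sub>/R<sub>j</sub>; families
   with zero mapped reads are unestimable and excluded.
6. Outliers: |log₂(AGS<sub>j</sub> / median)| > 1 (a scale-free 2-fold
   rule). If flagging would leave fewer than `min_classified_families`
   (default 3) survivors, the families closest to the median are retained.
7. Weighted average with trained per-family weights, renormalized over
   survivors.

Genome equivalents = full-library bp / AGS. The library size used for
R<sub>j</sub> is the trimmed, downsampled *n·i* bp (the quantity the
constants were calibrated against); the library size used for genome
equivalents is the full pre-QC base count, because it normalizes
whole-library gene counts.

## Alignment engine

A self-contained k-mer-seeded Smith–Waterman replaces an external
translated-search tool: 5-aa exact seeds over a direct-address index,
two-hit-on-a-diagonal candidate filtering (one hit suffices when the
translated read yields fewer than 8 k-mers), then banded affine-gap
Smith–Waterman (±5 diagonals around the seed diagonals by default) with
full traceback, implemented as numba kernels. Scoring is BLOSUM62 with gap
open 11 / extend 1 (a gap of length g costs 11 + g); stop codons score the
matrix minimum. Bit scores use the conventional Karlin–Altschul constants
λ = 0.267, K = 0.041; E = m·n·2^(−bit) with m the translated read length
and n the database size in residues. Trained cutoffs are engine-specific;
an adapter (`align.read_external_hits`) accepts tabular hits from an
external translated search, in which case the model must be retrained with
that engine.

Numerical notes: percent identity counts identical residues over all
alignment columns including gaps; tie-breaks everywhere are deterministic;
reported hits require bit ≥ 15 by default (below the smallest grid cutoff,
so classification is unaffected by the reporting floor).

## Calibration (training)

For each read length, one error-free single-genome library per training
genome is simulated and aligned once; only per-read top hits are cached and
reused across the cutoff grid.

- **Cutoff grid**: bit {20…60 step 5} × coverage {0.40…0.95 step 0.05} ×
  max identity {80, 85, 90, 95, 98, 100} = 648 combinations by default
  (axes configurable). For each family and combination, a provisional
  C (median of true-AGS·R over libraries with R>0) is fitted and the median
  unsigned error of C/R across libraries is scored; libraries where the
  combination maps nothing count as infinitely wrong, which penalizes
  over-stringent cutoffs.
- **Selection rule**: among combinations whose median error is within one
  standard error of the minimum (SE = 1.2533·sd/√n over the per-library
  errors at the argmin), the *least stringent* one is chosen — lowest
  coverage, then highest max identity (an identity ceiling below 100
  rejects exact matches outright, so it is relaxed first), then lowest bit
  score, with one guard: the bit score is never relaxed below the
  Karlin–Altschul noise floor (the score at which a translated read
  expects ≤0.01 chance hits against the database). Chance alignments
  concentrate just above that floor and are unevenly distributed across
  loci, so admitting them skews the constant calibration. Rationale for
  least-stringent:
  on training data the top hits are near-identical self-hits, so large sets
  of combinations classify identical read sets and the objective cannot
  distinguish them; picking the most permissive member of the
  statistically-tied set keeps the acceptance region far from the data
  margin, so diverged (novel-taxon) homologs are still accepted at
  estimation time. This is the one-standard-error convention familiar from
  penalized regression, applied to a grid.
- **Constants**: with cutoffs fixed, C<sub>j</sub> = median over libraries
  of true-AGS·R<sub>j</sub> (libraries with R=0 excluded; fitting from
  fewer than 10 libraries is flagged low-confidence).
- **Weights**: simplex-constrained (w ≥ 0, Σw = 1) minimization of the
  median unsigned error of the weighted estimate across libraries, by
  Nelder–Mead from the uniform start with Euclidean projection onto the
  simplex (ftol 1e-6, ≤5000 evaluations). If the optimizer cannot beat the
  uniform weights they are returned unchanged, so the result never
  underperforms its start.

Training libraries can also be derived by 3'-trimming a single
maximum-length library (read counts preserved across lengths), which is how
`simulate_training_libraries` behaves when given several lengths; the
benchmark instead trains each length on its own libraries at the full
coverage so that short-read calibration is not starved of data at desk
scale.

## Synthetic data generator

The generator emulates prokaryote-like genomes: i.i.d. uniform background
DNA with exactly one copy of each marker family embedded at non-overlapping
uniform positions and strands, reverse-translated with uniform synonymous
codons (codon bias is invisible to a translated search). Marker proteins
evolve by uniform random substitution — per-genome divergence, or along a
three-level synthetic taxonomy (class/genus/species) at 2.5% substitution
per branch, giving ~5% / ~10% / ~15% divergence between sibling species /
genera / classes. Viral-like contaminants are pure random DNA. Communities
use uniform abundances (high complexity; Shannon entropy 4.32 bits for 20
members) or geometric series bisected to the 2.75-bit (medium) and
1.08-bit (low) tiers; the abundance vectors behind the printed entropies
are not uniquely determined, so the geometric family is a choice. Reads:
N<sub>ij</sub> = round(R<sub>i</sub>·G<sub>j</sub>·S<sub>i</sub>/L) per
genome, uniform circular start positions, uniform strand, constant Q30
qualities, and a uniform error model with substitutions:indels = 4:1
(indels are length-1, insertion/deletion equiprobable; reads are refilled
or truncated to exactly L after indels).

What the generator does not emulate: platform-specific error profiles and
quality decay, GC/coverage bias, paired ends, real gene architecture
(operons, conserved domains vs variable loops), or inter-family sequence
similarity. Passing benchmarks therefore demonstrate the calibration
machinery and the estimator's statistical behavior (inverse
proportionality, holdout robustness, contaminant bias law), not
performance on any particular sequencing platform — for real data the
model should be trained on real reference genomes with the same workflow.

## Benchmark study conditions

The accuracy benchmark (`agscensus.benchmark`, driven by
`scripts/acceptance.py`) uses: 30 families × 200 aa; 40 genomes of 100–500
kb in a 4-class × 2-genus × 5-species taxonomy; training on the 20 genomes
of the first two classes at 20× coverage per read length; 20
medium-complexity test communities of the 20 held-out genomes, ~100 000
error-free reads each, at read lengths 50/100/250/500 bp. Taxonomic
exclusion (species/genus/class) removes all marker sequences sharing a
community member's label at that level; it is applied by masking hits from
a single search against the full database, which is exactly equivalent to
searching the reduced database because seeding, scoring, and statistics
are strictly per-target. The 100-bp no-exclusion estimates double as the
100-bp entry of the read-length sweep. These sizes were chosen so the
entire benchmark (training plus 80 community estimations) runs in minutes
on one CPU while keeping per-community sampling noise well below the
effects being measured.

## Known limitations

- Trained cutoffs and constants are specific to the alignment engine and
  the marker database version; models must be retrained when either
  changes (the version tag is checked at load time).
- The estimator assumes marker-carrying cells dominate the library;
  marker-free reads (viruses, and to a lesser degree eukaryotes) inflate
  the estimate by ≈1/(1−v) at contaminant fraction v.
- Read lengths outside the trained set fall back to the largest trained
  length below the requested one — never upward — and at least ~300k reads
  are recommended for stable estimates on real data (the bootstrap
  dispersion utility quantifies this per sample).
- RPKG follows the printed formula exactly; note that for a single-copy
  gene its absolute scale is 1000/L per copy per cell (L = read length in
  bp), so cross-sample comparability, not the absolute value, is the
  meaningful property.
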