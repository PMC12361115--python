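# Methods

## Model and assumptions

`nuoscan` treats subunit annotation of a multi-subunit complex as a
post-processing problem over three signals:

1. **Genomic context.** Genes of one functional complex tend to be
   co-located on one strand with short intergenic gaps.  Hit-bearing genes on
   the same replicon and strand are clustered when separated by at most
   `max_gap` bp; the cluster relation is the transitive closure of the
   pairwise gap relation (implemented as a left-to-right sweep tracking the
   rightmost gene end, which handles nested and overlapping genes exactly).
   The intergenic gap between genes a, b (a starting first) is
   `max(0, b.start − a.end − 1)`; overlapping or book-ended genes count as 0.
   Clusters are operon-*like* only — no transcription-signal evidence is
   used.
2. **Score segregation.** For each subunit profile, log10 e-values of all
   hits form a mixture: a low-e-value component of genuine subunits and one
   or more high-e-value components of distant homologs.  Hits whose genes sit
   in *Complete* clusters (all required subunits present, fused genes
   resolved) overwhelmingly belong to the genuine component, so the mode of
   the KDE with the highest cluster-member density identifies it, and the
   first antimode to its right is a natural per-subunit cutoff.
3. **Protein length.** Genuine subunits have characteristic lengths; hits
   are additionally constrained to a per-profile length window.  When a hit
   carries a domain envelope, the envelope span is the length judged (a
   single-subunit domain inside a fused gene must not be judged by the fused
   protein's length); otherwise the whole protein length is used.

Classification assumes the subunit scheme is correct and complete for the
complex of interest.  The shipped default is the canonical prokaryotic
Complex I: subunits NuoA–NuoN; N-module {E,F,G} (NADH oxidation), Q-module
{B,C,D,H,I} (quinone reduction), P-module {A,J,K,L,M,N} (proton
translocation); fused profiles NuoCD and NuoBCD; `CI_like` reserved for the
exact missing sets {E,F} and {E,F,G}.  Other complexes can reuse the
machinery with a different YAML scheme.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| `max_gap` | 250 | bp | Complete-cluster counts plateau near this separation; the scan (0–500 by 25) lets users verify it on their own data |
| KDE bandwidth | Silverman's rule | log10 decades | robust default for unimodal-per-component mixtures; `--fixed-bandwidth` for exact reproducibility |
| KDE grid | 512 points over [min−4h, max+4h] | log10 | covers essentially all mass; trapezoidal integral ∈ [0.98, 1] |
| mode floor | 1% of peak density | — | local maxima below it are numerical wiggles, not populations |
| length percentiles | 1st–99th | aa | used only when the scheme supplies no reference range and ≥5 members exist |
| e-value floor | 1e-300 | — | applied at log-transform time only; raw parsed values are preserved |
| member pass guarantee | 99% | — | the final cutoff is never below the 99th percentile of member e-values |
| `min_species` | 10 | species | taxa below this are dropped from rank distributions |
| global default cutoff | 1e-7 | e-value | generic homology-search default, used only when a profile has too few values for a KDE |

## Numerical and design choices

- **Antimode over member-max.** The antimode tolerates stray members and
  places the cutoff where the genuine and decoy densities cross, rather than
  at the accidental maximum of a finite member sample.
- **Unimodal fallback.** When no antimode lies right of the member-dominated
  mode, no decoy population is visible; the cutoff is the larger of one
  decade past the member max and the right edge of the mode (density ≥ 1% of
  peak).  The mode-edge term matters because genuine hits of *split* operons
  are not cluster members by construction and may exceed the member max when
  members are few.
- **Fusion resolution.** A fused-profile hit expands to its mapped subunits.
  A gene hit by several single-subunit profiles contributes them all only if
  their merged domain envelopes overlap pairwise by at most 20% of the
  shorter envelope (tandem-domain signature); otherwise only the best
  e-value profile counts (paralog ambiguity).  The 20% tolerance is a
  configurable convention.
- **Copy number.** The number of disjoint gene-sets covering the required
  subunits is computed exactly by a memoized depth-first search over gene
  subunit-set types.  A greedy construction can undercount when one
  multi-subunit gene straddles two potential covers; the exact search is
  cheap at genome scale (tens of genes, 14 subunits) and falls back to the
  greedy bound only for absurdly large inputs.
- **Genome-level completeness** uses the union of subunits across clusters,
  so split arrangements still classify as complete; the arrangement field
  records single-cluster vs split separately.
- **Plasmid attribution**: `exclusive` when every retained hit gene is
  plasmid-borne, `complete` when plasmid-borne genes alone cover the
  required set, `partial` when some hit genes are plasmid-borne.  Replicon
  typing precedence: explicit metadata map, then a case-insensitive
  "plasmid" token in the replicon id, else unknown.
- **Chi-square**: Pearson statistic without continuity correction (tables
  are 4×k), expected counts from product marginals, Pearson residuals
  (O−E)/√E; zero-marginal rows/columns are dropped with a warning, as are
  columns below `--min-col-total`.  Species, not strains, are the counting
  unit.
- **Pipeline ordering**: cluster provisionally → derive thresholds → filter
  → re-cluster once → classify.  `--iterate` repeats filter/re-cluster to a
  fixpoint; the single pass is the default because decoy removal rarely
  changes membership twice.
- **E-value choice**: full-sequence e-values are used for thresholding;
  domtblout input also carries per-domain envelopes, which only affect
  fusion resolution and envelope-length checks.

## The synthetic population

The generator emulates exactly the structures the pipeline must recover, as
a *stated world* with fixed defaults: 40 species (~50 genomes; strains per
species 1/2/3 with probabilities 0.80/0.15/0.05), a variant mix of 30%
`Complete14`, 15% fused CD, 10% fused BCD, 10% `CI_like`, 15% `Incomplete`,
20% `Absent`; intra-operon gaps uniform on [0, 100] bp with distinct
neighbourhoods ≥ 2000 bp apart; genuine log10 e-values from N(−50, 2) and
decoys from N(−6, 2) (≥ 6 decades of separation); 3 decoys per genome in
expectation, 60% on the NuoB profile (mimicking hydrogenase cross-hits);
subunit lengths normal around E. coli values with 8% sd; 20% of complete
operons split, 5% dual-copy, 6% plasmid-borne; two genomes planted to fail
metadata curation.  The first ten species deterministically cover every
category (both C-I-like missing sets, dual-copy, plasmid-exclusive, split)
so a single default population exercises the full classifier.  Fused genes
are emitted as a fused-profile hit with probability 0.7, else as tandem
single-subunit domain hits on one gene, exercising the envelope-overlap
fusion path.

What the generator does **not** emulate: sequence content (no nucleotides or
proteins are produced), compositional biases, assembly fragmentation inside
operons, HMMER score/e-value covariance, overlapping genes within operons,
and inconsistent variants within a species.  A green end-to-end test
therefore establishes that the pipeline's logic recovers planted structure
under the stated noise model — not that the thresholds are optimal for any
particular real genome collection.

## Known limitations

- Per-subunit cutoffs depend on having enough hits per profile for a KDE;
  sparse profiles fall back to a generic 1e-7 cutoff with a logged warning.
- tblout input has no domain envelopes, so tandem-domain fusions collapse to
  the best-scoring subunit and envelope-length checks degrade to
  whole-protein length; prefer domtblout.
- The plateau detector follows a literal smallest-threshold rule, so a scan
  that is still flat at zero returns the first threshold; inspect
  `gap_scan.tsv` when in doubt.
- Taxonomy ranks are input columns; no lineage resolution is performed.
- Clusters are distance-defined; they may or may not correspond to
  transcriptional operons.
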