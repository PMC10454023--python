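# Methods

## The problem

`nucsurvey` re-implements, as a reusable and fully testable pipeline, a
genomic survey of two bacterial nucleotidase gene families: *ushA*-like
genes (periplasmic/cell-wall 5′-nucleotidase, UDP-sugar and CDP-alcohol
hydrolase) and *cpdB*-like genes (3′-nucleotidase, 2′,3′-cyclic-nucleotide
and dinucleotide phosphodiesterase). Both enzymes act on extracytoplasmic
nucleotides and are pro-virulent in several pathogens, which motivates
cataloguing where in the bacterial taxonomy each gene family occurs and how
strongly the two co-occur.

The original survey queried a live complete-genomes database with seven
protein probes via translated BLAST. Those per-taxon hit counts are a
function of a database snapshot and cannot be reproduced at desk scale.
What this package makes reproducible is the *method*: the translated
search with its explicit hit criterion, the hierarchical presence/absence
classification with completeness pruning, and the cross-probe
reconciliation arithmetic — exercised on synthetic genomes with planted,
divergence-controlled homologs, and on packaged transcriptions of the
published per-genome score tables and summary lists.

## Translated search

A probe protein is aligned against all six reading frames of every
replicon (genetic code 11; stop codons translate to `*`; a trailing
partial codon is dropped). Alignment is exhaustive Smith–Waterman with
affine gaps — no seeded two-hit heuristic, no E-values, no composition
adjustment or masking — delegated to Biopython's `PairwiseAligner` (C
kernel). Scoring follows the web-TBlastN defaults the survey relied on:

* BLOSUM62, gap open 11, gap extend 1. A length-*k* gap costs
  `11 + k` (BLAST convention); since `PairwiseAligner` charges its open
  score on the first gapped column, it is configured with open = −12,
  extend = −1.
* Stops score −4 against every residue and +1 against another stop (the
  values in the NCBI BLOSUM62 file), so an alignment may cross a stop at a
  penalty and a single alignment pass per frame suffices.
* Raw scores are normalised to bits with the gapped Karlin–Altschul
  constants for BLOSUM62-11/1, λ = 0.267 and K = 0.041:
  `bits = (λ·S − ln K) / ln 2`.

The best local alignment per (replicon, frame) is kept as an HSP when it
reaches a reporting floor of 50 bits. One `Hit` is produced per
(probe, genome): the best bit score is the maximum over all HSPs, and the
query coverage is the union of HSP query intervals **of the best-scoring
replicon only**, divided by the probe length — a planted gene is never
split across replicons, and this mirrors a per-subject "query cover". A
genomic hit requires **bit score > 150 and coverage > 70%, both strict**
(a score of exactly 151 with coverage 71% passes; 150 does not).

Whether coverage should be per best HSP or per subject union is not
decidable from the original description; the union was chosen, and with
single-gene plants the two coincide. Traceback determinism: the aligner's
first optimal path is reported, which is deterministic across runs and
platforms; no further tie-break policy is imposed.

Plasmid handling mirrors the `NOT plasmid [Title]` restriction used
against the live database: replicons whose FASTA description contains
"plasmid" contribute nothing when exclusion is on (the default).

## Survey and pruning

Genomes are attached to species-level taxa through a manifest
(accession, taxid, type-material flag); the taxonomy is an NCBI
taxdump-dialect tree restricted to the ladder phylum → class → order →
family → genus → species. Eligibility follows the type-material rule:
above genus rank only type-material genomes are analyzed, unless fewer
than five exist, in which case — and always at genus and species rank —
all genomes are used.

For each taxon the per-family status of every eligible genome is the OR
over that family's probes (five UshA-like, two CpdB-like), and the
fraction of positive genomes is classified into four levels: absent,
≤ 50% ("low"), > 50% but < 100% ("partial"), and 100% ("full"). A taxon
whose two levels are each absent-or-full is **complete**: descending
cannot change its interpretation, so the hierarchical survey prunes it.
Non-complete analyzed taxa are descended one rank at a time, in ascending
taxid order; species are terminal. Taxa with zero eligible genomes are
recorded as probed-without-genomes, excluded from level statistics, and
not descended (in these datasets their whole subtree is genome-free).
A curated taxon list can also be surveyed directly, without descent.

Per-(probe, genome) hits are cached by the search engine, so a genome
surveyed at several ranks is aligned exactly once.

## Reconciliation

Per-genome joint statuses fall into four categories (U+C+, U+C−, U−C+,
U−C−) whose counts always sum to the genome total. When a survey is
complete for one family only, the joint breakdown is still recoverable
from marginal counts by inclusion–exclusion:
`u_only = n_U − n_both`, `c_only = n_C − n_both`,
`neither = n_total − n_U − n_C + n_both`, with infeasible marginals
rejected. Complete taxa are partitioned the same way, keyed by "level is
not absent". Category percentages are rounded to one decimal with
sum-preserving largest-remainder apportionment: each category gets the
floor of its exact share in tenths of a percent and the leftover tenths
go to the largest fractional remainders, so the four percentages sum to
exactly 100.0. Plain nearest-value rounding does not have this property
— for the 590 complete taxa it would turn 231/590 = 39.1525% into 39.2
and make the table sum to 100.1 — whereas the sum-preserving rule
reproduces the published 70.5 / 31.4 / 39.1 / 21.7 / 7.8 split exactly.

Packaged fixtures transcribe: the 21-member probe panel metadata (with
the seven selected probes and their published lengths), the 590
complete taxa with their categories, the per-genome best-score tables for
the *E. coli* exception genomes, the avian-pathogenic *E. coli* genomes
and the *P. multocida* exceptions, and the species-level count vignettes.
The score tables are filtered on score only (their coverages had already
passed), and the borderline *P. multocida* genome with a best score of
exactly 151 is classified U-positive under the strict rule.

## Synthetic data

The generator emulates a complete-genomes database at desk scale: a
rank-complete toy taxonomy, a manifest with type-material flags (the
first genome of each species is always type material; others are flagged
at rate 0.5), and per-genome replicons of uniform-ACGT background with
planted homologs. Plants are made by mutating a probe protein to a target
identity (uniform substitutions, realized identity within one residue of
the target), back-translating through uniformly chosen synonymous codons
(code 11, terminal stop appended), and overwriting a non-overlapping
region of the chromosome — or of a plasmid when plasmid planting is
requested — on a uniformly chosen strand. Two decoy ORFs unrelated to any
probe are planted per genome. Every draw derives from one seed, so equal
configurations are byte-identical.

Each species receives a presence plan (fraction of genomes carrying a
U-family and a C-family gene) from a fixed twelve-entry cycle that covers
the four joint categories and all presence levels. The ground truth —
plant coordinates and expected per-genome statuses under perfect
recovery — is recorded, and `expected_survey` projects it through the
same eligibility and pruning bookkeeping to per-taxon expected levels.

Default scale: 2 phyla × 2 classes × 2 orders × 2 families × 2 genera ×
3 species × 4 genomes = 384 genomes of 20 kb, probes of 250 aa, planted
identity 1.0, 25% of genomes carrying a 5 kb plasmid. At this scale a
full pipeline run takes roughly five minutes on one CPU; unit tests use
one-phylum, 12-genome configurations. A perfect 250-aa plant scores
≈ 500 bits, far above the 150-bit threshold, while the best random
background alignment stays below the 50-bit reporting floor — which is
why recovery at identity 1.0 is exact, and is asserted as such.

What the synthetic datasets do *not* model: real base/codon composition,
repeats, gene structure (promoters, operons), sequencing error,
horizontal transfer, or homologs of intermediate identity between related
probes. Passing the recovery tests therefore demonstrates correct
bookkeeping, scoring and pruning — not search sensitivity on real
genomes. Sensitivity is characterised separately: detection of a 300-aa
plant is total down to 70% protein identity and decays monotonically
toward 30% (median over 20 seeds), consistent with the survey's own
caveat that the strict filter can miss distant true homologs.

## Numerical choices and degenerate inputs

* Identity realized at the protein level before back-translation; tests
  compare alignment-observed identity against planted identity with the
  small slack this implies.
* Presence levels are undefined for zero analyzed genomes (callers must
  exclude such taxa); inconsistent marginal counts raise an error rather
  than clamping.
* Sequences shorter than one codon translate to six empty frames without
  error; a genome with no non-excluded replicons yields an HSP-free,
  filter-failing hit.
* `classify_presence` puts exactly-50% in the low tier and is monotone in
  the hit count; the hit filter is strict on both thresholds and monotone
  in score and coverage.

## Known limitations

* One HSP (the optimal alignment) per frame: genuinely split hits in one
  frame (e.g. a gene interrupted by a long insertion) would under-report
  coverage. Irrelevant for the planted model, noted for real data.
* Karlin–Altschul constants are fixed rather than estimated per matrix;
  E-values are deliberately not computed (filtering is score+coverage
  only).
* The taxonomy layer does not model merged/deleted taxids or candidatus
  naming, and no live database access of any kind is provided.
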