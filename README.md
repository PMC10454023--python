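# nucsurvey

Survey of *ushA*-like and *cpdB*-like nucleotidase genes across a
bacterial taxonomy, as a reproducible desk-scale pipeline.

UshA (5′-nucleotidase / UDP-sugar hydrolase) and CpdB (3′-nucleotidase /
2′,3′-cyclic-nucleotide phosphodiesterase) are periplasmic or
cell-wall-bound enzymes, pro-virulent in several bacterial pathogens.
`nucsurvey` implements the machinery needed to chart where genes encoding
them occur in the bacterial taxonomy and how strongly the two families
co-occur:

* **Translated search** — exhaustive Smith–Waterman alignment of protein
  probes against all six reading frames of each replicon (BLOSUM62,
  affine gaps 11/1, genetic code 11), Karlin–Altschul bit scores
  (λ = 0.267, K = 0.041), and the hit criterion
  *bit score > 150 and query coverage > 70 %* (both strict). Plasmid
  replicons can be excluded, mirroring a `NOT plasmid [Title]` database
  restriction.
* **Probe panel** — all-vs-all relatedness matrix of a candidate panel by
  alignment bit score, connected-component grouping, and greedy set-cover
  selection of a minimal covering probe set. A packaged fixture carries
  the published 21-member panel metadata with its seven selected probes
  (five UshA-like, two CpdB-like).
* **Hierarchical survey** — per-taxon presence levels for each family
  (absent / ≤ 50 % / > 50 % but < 100 % / 100 % of analyzed genomes), the
  type-material eligibility rule, and phylum → species descent that
  prunes *complete* taxa (both families absent-or-100 %).
* **Reconciliation** — per-genome joint categories (U+C+, U+C−, U−C+,
  U−C−), inference of the joint breakdown from marginal counts, per-rank
  aggregation, and correlation percentages with sum-preserving
  (largest-remainder) one-decimal rounding.
* **Synthetic data** — seeded generator of toy taxonomies and genomes
  with planted, divergence-controlled probe homologs (forward/reverse
  strand, chromosome or plasmid) plus a ground-truth manifest, so every
  stage is testable without downloads.

## Worked example

```sh
cat > demo_cfg.json <<'JSON'
{"n_phyla": 1, "classes_per_phylum": 1, "orders_per_class": 1,
 "families_per_order": 1, "genera_per_family": 2, "species_per_genus": 2,
 "genomes_per_species": 3, "background_length": 6000}
JSON
nucsurvey simulate --seed 3 --out demo --config demo_cfg.json
nucsurvey survey --dataset demo --out demo/survey.tsv
nucsurvey reconcile --survey-table demo/survey.tsv --out-prefix demo/recon
```

`demo/survey.tsv` then contains one row per surveyed taxon:

```
taxid	rank	name	n_genomes	U	C	complete
3	phylum	Phylum_3	8	+<100	+<=50	0
4	class	Class_4	8	+<100	+<=50	0
5	order	Order_5	8	+<100	+<=50	0
6	family	Family_6	8	+<100	+<=50	0
7	genus	Genus_7	6	+<=50	+<=50	0
8	genus	Genus_8	6	+<=50	+<=50	0
9	species	Species_9	3	+100	+100	1
10	species	Species_10	3	-	-	1
11	species	Species_11	3	+100	-	1
12	species	Species_12	3	-	+100	1
```

Reading it: the single phylum is partial for U (more than half but not
all of its eligible genomes carry an *ushA*-like gene) and low for C, so
it is not complete and its class, order, family and genera are surveyed
in turn; the four species reproduce the planted plans — double positive,
double negative, U-only and C-only — and all four are complete, so
nothing would be descended further. `demo/recon_percentages.json`
reports the joint-category percentages over the complete taxa (here:
`pct_both`/`pct_u_only`/`pct_c_only`/`pct_neither` each 25.0, concordant
50.0).

The same objects are available as a library:

```python
from nucsurvey import SyntheticConfig, generate_dataset, hierarchical_survey

ds = generate_dataset(SyntheticConfig(seed=3))
results = hierarchical_survey(ds.tree, ds.manifest, ds.store(), ds.probes)
```

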