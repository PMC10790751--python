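# anigap — the intra-species ANI gap and natural units below the species

Large collections of bacterial genomes show a striking regularity:
within a named species (genomes sharing ANI > 95%), pairwise average
nucleotide identity values are scarce between ~99.2% and ~99.8%. That
gap separates tight clusters of near-identical genomes from the more
diverse background of the species and motivates data-driven
intra-species units:

| unit          | definition            | notes                                   |
|---------------|-----------------------|-----------------------------------------|
| genomospecies | ANI ≥ 95%             | the species-level cluster               |
| genomovar     | ANI ≥ 99.5%           | gap midpoint; whole-genome analogue of an MLST sequence type (ST) |
| strain        | ANI > 99.99%          | near-identical genomes                  |

`anigap` is an analysis pipeline for detecting that gap and delineating
the units, written for microbial genomics researchers who want each
step testable against ground truth. It provides:

* **`anigap.simulate`** — a synthetic species generator that plants
  known genomovar/strain structure, gene-content turnover with
  annotated vs hypothetical/mobile categories, and 7 MLST-style loci,
  emitting full truth tables (planted identity matrix, labels, tree,
  presence/absence).
* **`anigap.ani`** — fragment-based ANI (3 kb fragments, exact k-mer
  seeding + ungapped extension, bidirectional-mapping criterion): ANI is
  the mean identity over bidirectional fragment mappings and the shared
  genome fraction is bidirectional mappings over total query fragments.
  Plus reciprocal-best-hit shared-gene fractions.
* **`anigap.gapstats`** — uniform-null expected counts and deficit
  ratios, Hartigan's dip statistic (exact, oracle-validated) with
  Monte-Carlo p-values, KDE valley detection, per-species
  classification (gapped / shifted / clonal / no gap), the
  cross-species gap mode, subsampling, and the divergence-time closed
  form d/(k·μ·g).
* **`anigap.units`** — nested single-linkage clustering at
  95 / 99.5 / 99.99% ANI.
* **`anigap.sequence_typing`** — 7-locus ST assignment and pairwise
  precision/recall/F1 of STs against an ANI threshold.
* **`anigap.enrich`** — two-proportion z-test for mobile-gene
  enrichment among genes not shared between very close pairs.

## Worked example

Run the numbered analysis scripts from the repository root (each is a
thin driver over the library; later scripts read the outputs of earlier
ones from `results/`):

```sh
python analysis/01_simulate_species.py   # gapped / gapless / clonal species
python analysis/02_compute_ani.py        # all-vs-all fragment ANI
python analysis/03_gap_detection.py      # uniform null, KDE valleys, dip test
python analysis/04_delineate_units.py    # 95/99.5/99.99 clusters, ST concordance
python analysis/05_gene_content.py       # shared genes, mobile enrichment
```

Output of a full run (seed 1):

```
gapped: 32 genomes, 496 pairs, planted ANI 96.37-99.97, 0 pairs in (99.2, 99.8)
  planted gap: (99.147, 99.856), midpoint 99.502
uniform null, N=4,280,133 on [96,100]: 107,003.3 pairs per 0.1% bin; 642,019.9 expected in 99.2-99.8%
observed 235,527 in the gap -> deficit ratio 2.73x
gapped: gap_99.2_99.8 (dip=0.0418, p=0.0005, valleys at [99.46])
gapless: no_gap (dip=0.0099, p=0.994, valleys at [])
clonal: clonal
clusters: 1 genomospecies, 8 genomovars, 32 strains
genomovar partition equals planted labels: True
ST vs 99.5% ANI: precision=1.0 recall=1.0 f1=1.0
shared gene fraction: 0.959 for ANI>99.8 (48 pairs) vs 0.938 for 96-99.8 (448 pairs)
mobile fraction of non-shared genes: close 0.962 vs divergent 0.874; z=4.64, p=3.41e-06
```

Reading this: the simulated gapped species has no pair in the
99.2–99.8% window (the plant worked); the uniform-null numbers show
what an even distribution would predict for a published-scale
collection of 4.28 M pairs and how a 235,527-pair observation in the
gap is a ~2.7× deficit; KDE + dip classify the gapped species correctly
(valley at 99.46, dip p ≈ 5×10⁻⁴) while the gapless control stays
unclassified; single-linkage 99.5% clusters reproduce all 8 planted
genomovars; with locus mutations confined to genomovar boundaries, STs
and 99.5% clusters agree perfectly; and the genes that differ between
near-identical genomes are significantly enriched in
hypothetical/mobile functions (z-test).

The same stages are available as a CLI
(`anigap simulate|ani|gaps|classify|gapmode|cluster|type|concord|enrich|run`);
`anigap run --config cfg.toml --outdir out` executes the whole pipeline
and writes a machine-readable `summary.json` stamped with the config
hash.

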