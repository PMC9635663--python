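# phamkit

Assemble phage protein-coding genes into **phamilies** ("phams") — groups
of genes related by amino-acid sequence similarity — and audit, summarize
and report on the result. Phams are the working unit of comparative phage
genomics: phage genomes are pervasively mosaic, share no universal core
genes, and are full of short genes of unknown function, so genome
comparison proceeds gene-family-by-gene-family rather than by whole-genome
alignment. phamkit is aimed at phage genomics researchers who need pham
assembly with transparent, auditable criteria on desk-scale datasets, and
at tool builders who want the pipeline as a library.

## What it does

Given GenBank or FASTA inputs, phamkit:

1. translates CDS features (genetic code 11) and collapses identical
   protein sequences;
2. builds a homology graph from all-vs-all Smith–Waterman alignments
   (BLOSUM62, affine gaps −11/−1), keeping an edge when
   identity ≥ `min_seq_id`, bidirectional coverage ≥ `coverage` and
   Karlin–Altschul E-value ≤ `evalue`;
3. interprets the graph into clusters by one of three modes — greedy set
   cover, single linkage, or greedy incremental — optionally cascading
   from strict to relaxed thresholds;
4. optionally merges phams holding remote homologs via position-specific
   scoring profiles (half-bit log-odds columns
   `2·log₂((f_a + p_a)/(2·p_a))`) aligned against every sequence;
5. audits the phams: a member is a likely **false positive** if its length
   is < 60% of the longest member or its best within-pham normalized
   global score is < 0.5 half-bits per column; a **false negative** is a
   non-member hit of the pham representative at E ≤ 0.001, query coverage
   ≥ 60% and query length ≥ 60% of subject length;
6. reports consensus functions (synonym-normalized modal annotation) and,
   for one-genome-per-file inputs, pangenome summaries: core / soft-core /
   shell / cloud conservation (> 99 / > 95 / > 15 / > 0% of genomes), a
   Roary-style presence–absence matrix, and a genome → pham map.

A grid-search harness (`phamkit.gridsearch`) reproduces the two-stage
training procedure used to pick default clustering parameters: sweep the
sequence-stage grid and exclude any parameter set producing a pham with a
false positive, then sweep the profile-stage grid under a 0.5%
false-positive-rate cap, selecting the fewest-false-negative set each
time. A deterministic synthetic-data generator (`phamkit.fixtures`) plants
protein families at controlled identity, orphams, and the classic failure
modes (domain chaining, intein insertions, short fragments) so everything
is testable without downloads.

## Worked example

Generate three-family demo genomes and assemble them:

```sh
python -c "
from phamkit.fixtures import FixtureSpec, write_fixture
write_fixture(FixtureSpec(n_families=3, members_per_family=4,
                          family_identities=(0.9, 0.6, 0.4),
                          ancestor_length=120, n_orphams=3,
                          orpham_length=120, seed=11), 'demo/genomes')
"
phamkit demo/genomes/*.gbk --outdir demo/out --pangenome --align-phams
```

which logs:

```
INFO phamkit.clustering: assembled 6 phams from 15 genes (15 nonredundant)
INFO phamkit: QC: 0 false positives (rate 0.0000), 0 false negatives
INFO phamkit: 15 genes -> 6 phams (largest 4, 3 orphams); outputs in demo/out
```

The three planted families came back as three 4-member phams and the three
unrelated genes as orphams (single-gene phams), with a clean audit.
`demo/out/summary.txt` holds the dataset statistics:

```
phams	6
genes	15
mean_genes_per_pham	2.50
largest_pham	4
orphams	3
orpham_percent	50.0
```

`consensus_functions.csv` shows each pham's modal annotation after synonym
normalization — e.g. pham 2 is `terminase, large subunit` at 100% even
though one member was annotated "TerL":

```
pham_id,n_genes,consensus_function,consensus_proportion
1,4,portal,100.0
2,4,"terminase, large subunit",100.0
```

and `genome_pham_map.tsv` lists, per genome, the phams its genes fall in
(the three families are phams 1–3, present in all four genomes; each
orpham appears in one):

```
genome	phams
G1	1 2 3 4
G2	1 2 3 5
G3	1 2 3 6
G4	1 2 3
```

Per-pham FASTA files land in `demo/out/phams/`, aligned FASTAs in
`demo/out/pham_alignments/`, the audit in `qc_report.tsv`, and the
presence–absence matrix in `gene_presence_absence.csv`. An existing pham
assignment can be audited standalone:

```sh
phamkit-audit assignment.tsv --sequences all_genes.faa --out qc.tsv
```

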