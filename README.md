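# lossmap

Hierarchical trait-loss analysis on a fixed rooted phylogeny, plus
small-RNA signature statistics — with seeded synthetic-data generators so
every stage is testable without external downloads.

The package covers five analysis layers:

- **Irreversible event mapping** (`lossmap.dollo`): map losses of
  ancestrally present binary characters and single-origin gains of novel
  characters onto a rooted tree (single-gain, multiple-loss parsimony),
  with per-branch, per-tip-cumulative and shared-missing summaries.
- **Complement accounting** (`lossmap.complement`): expected character
  complements by phylogenetic node of origin, loss percentages, and
  precursor hairpin-length summaries from GFF3.
- **Association statistics** (`lossmap.stats`): OLS with R², Spearman
  partial rank correlation controlling a covariate, upper-tail
  hypergeometric over-representation and Benjamini–Hochberg adjustment.
- **Small-RNA signatures** (`lossmap.pirna`): 27–32 nt putative-piRNA
  length filter, opposite-strand 5′-overlap (ping-pong) profile, 2-kb
  window densities, cumulative coverage curve, and the permutation
  clustering ratio (windows covering 90% of shuffled positions divided by
  windows covering 90% of observed positions).
- **Synthetic data** (`lossmap.simulate`): seeded generators for matrices
  with branch-planted events (the event remapping recovers the planted
  counts exactly), clustered/ping-pong read sets, and species tables with
  planted linear relations. Presets `syndermata_busco` and
  `syndermata_mirna` encode the syndermatan case study.

I/O lives in `lossmap.io` (matrix TSV with `0/1/?` cells, Newick, BED6,
species/genome TSVs, deterministic JSON reports) and orchestration in
`lossmap.pipeline`.

## CLI

```sh
lossmap simulate-matrix --preset syndermata_busco --seed 1 \
    --out-matrix matrix.tsv --out-tree tree.nwk
lossmap map-losses --matrix matrix.tsv --tree tree.nwk --out losses.json

lossmap simulate-reads --contig c1:200000 --n-reads 5000 \
    --pingpong-fraction 0.3 --seed 2 --out reads.bed
printf 'c1\t200000\n' > genome.tsv
lossmap pirna-scan --bed reads.bed --genome genome.tsv --seed 3 --out scan.json

lossmap correlate --table species.tsv --x mirna_losses --y core_gene_losses \
    --partial-covariate n50
lossmap enrich --set genes.txt --ann term2gene.tsv --universe universe.txt \
    --out enrich.json
lossmap run --config run.cfg     # flat key=value config, all stages
```

Config keys for `run`: `matrix`, `tree`, `polarity`, `outgroups`,
`assignment`, `species_table`, `covariate`, `gene_set`, `annotations`,
`universe`, `bed`, `genome`, `window`, `fraction`, `shuffles`, `fdr`,
`seed`, `out_dir`, `stages`.

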