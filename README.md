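# plastomics

Structural analysis of circular plastid (chloroplast) genomes:

* **quadripartite partitioning** — exact inverted-repeat detection and
  LSC / IRa / SSC / IRb decomposition with composition summaries;
* **gene-status classification** — a four-way call
  (INTACT / PUTATIVE_PSEUDOGENE / TRUNCATED / DELETED) for a gene against a
  verified intact reference, backed by a self-contained affine-gap global
  aligner;
* **inversion detection** — signed gene-order permutations, collinear-block
  decomposition, greedy inversion-history reconstruction validated by an
  exact breadth-first reversal-distance oracle, and breakpoint localization
  to flanking intergenic spacers;
* **in-silico PCR screening** — primer-site search with a mismatch-count
  annealing model, amplicon prediction on the circle, and dual-pair
  presence/absence calls for inversion assays;
* **parsimony character mapping** — Fitch counts with missing data and a
  single-origin (synapomorphy) test for binary characters on a phylogeny;
* **a synthetic-plastome generator** — seeded, annotated quadripartite
  genomes with a legume-style gene catalog, three nested plantable
  inversions (~50 / 36 / 24 kb at full scale, anchored at named spacers
  and a planted 29-bp inverted repeat pair), planted primer-binding sites
  for the packaged assays, and an rps16 mutation spectrum — so the whole
  pipeline is testable without downloading anything.

## CLI

```sh
# generate the packaged 16-taxon screening panel (full or mini scale)
plastomics simulate --seed 1 --profile full --out panel/

# partition one genome and print summary statistics
plastomics partition panel/Maackia_fauriei.gb

# classify a gene against an intact reference copy
plastomics classify-gene panel/*.gb --gene rps16 --reference ref.gb

# infer inversion events relative to a reference genome
plastomics detect-inversions panel/Maackia_fauriei.gb --reference ref.gb

# screen a directory of genomes with the packaged inversion assays
plastomics pcr-screen --panel panel/

# parsimony-map binary characters on a Newick tree
plastomics map-character --tree tree.nwk --matrix states.tsv

# everything end to end on synthetic data, with a JSON report
plastomics run-all --seed 1 --profile mini --json-out report.json
```

Formats: GenBank flat files (minimal dialect) or FASTA plus a TSV feature
table; Newick trees; TSV/JSON outputs.  All internal coordinates are
0-based half-open; GenBank's 1-based inclusive intervals exist only at the
file boundary.  Origin-wrapping features round-trip through `join()`
locations.

## Layout

```
src/plastomics/
  io.py                GenBank/FASTA+table/Newick reading and writing
  synth.py             seeded synthetic plastome generator, inversions,
                       gene mutations, screening panel
  quadripartite.py     inverted-repeat detection and partitioning
  gene_status.py       locus extraction, global alignment, 4-way classifier
  rearrangement.py     signed permutations, LCBs, reversal distances,
                       inversion-history inference
  insilico_pcr.py      primer sites, amplicons, inversion screening
  character_mapping.py Fitch parsimony and the synapomorphy test
  assays.py            packaged primer sequences and assay definitions
  pipeline.py          seeded end-to-end pipeline and run report
  cli.py               click-based command-line interface
```
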