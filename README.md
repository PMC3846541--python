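# vdjcapture

Simulation and discovery of V(D)J recombinase-mediated rearrangements
from RSS-targeted capture sequencing.

Lymphocytes assemble antigen-receptor genes by V(D)J recombination: the
RAG recombinase cuts at recombination signal sequences (RSSs — a
`CACAGTG` heptamer and `ACAAAAACC` nonamer separated by a 12 or 23 nt
spacer) and joins gene segments by deletion or inversion, pairing one
12-spacer with one 23-spacer RSS (the 12/23 rule). The products are
coding joints (trimmed coding ends separated by untemplated N-region
nucleotides added by TdT) and, for inversions, precise RSS-RSS signal
joints. Off-target recombinase activity — cryptic-heptamer V-to-V
deletions, lineage-inappropriate joins, reciprocal translocations that
put oncogenes under antigen-receptor loci — drives lymphoid
malignancies. Capturing genomic DNA with baits tiled over RSSs and
sequencing paired-end reads surveys all of this without PCR primers
that anticipate particular rearrangements.

`vdjcapture` is a self-contained toolkit for that assay, aimed at
methods developers and immunogenomics analysts:

- **locus** — antigen-receptor locus models (segments + RSSs), motif
  scanning, tiled capture-bait design, deterministic synthetic genomes;
- **simulate** — truth-labelled recombinase products (deletion,
  inversion, V replacement, two-step V(D)J, reciprocal translocation)
  plus hybrid-capture enrichment and paired-end reads;
- **detect** — discordant-pair clustering and split-read remapping that
  recovers each breakpoint to a single base, with consensus junction
  sequences and segmental-duplication ambiguity flags;
- **annotate** — joint type (coding / signal / hybrid), N-region vs
  microhomology under a leftmost-shift convention, 12/23 compliance,
  frame and productivity, event category and lineage flags, and a
  per-derivative loss ledger for reciprocal translocations;
- **cli / pipeline** — `vdjcapture simulate | design-baits | detect |
  annotate | run-all` with a schema-checked configuration.

Breakpoints are reported in a canonical normal form (lower-coordinate
side first, seam left-shifted through junctional microhomology), so
detector output is directly comparable to simulator truth — the test
suite holds the pipeline to exact breakpoint equality across planted
panels of all event categories.

## Worked example

Simulate a DB-style t(14;18)-like reciprocal translocation (11 and 8 nt
N-regions, partner-chromosome breakpoints 12 bp apart), sequence it at
50x, and run detection and annotation:

```sh
vdjcapture run-all --preset db-t14-18 --seed 7 --outdir demo
```

```
simulated 1128 read pairs over 1 event(s); on-target fraction 0.48
2 junction call(s)
{"translocation": 2}
```

`demo/junctions.bedpe` holds the two derivative junctions, each pinned
to one base by split reads:

```
#chrom1   start1 end1  chrom2  start2 end2  name  score strand1 strand2 class            pairs splits resolution ambiguity micro n_seq
chr_BCL2  6988   6989  chr_IGH 5829   5830  jx000 13    +       +       interchromosomal 5     8      base-pair  unique    0     TGGTGTTAACG
chr_BCL2  7000   7001  chr_IGH 3969   3970  jx001 14    -       -       interchromosomal 5     9      base-pair  unique    0     TATAGTAC
```

`jx000` is the der(14)-like junction: 11 untemplated bases
(`TGGTGTTAACG`) between the partner chromosome and the IGH J cluster.
`jx001` is the der(18)-like junction with 8 untemplated bases, its IGH
side landing at a D-segment RSS (annotated as a signal end in
`demo/annotations.tsv`). The reciprocal ledger (`demo/ledger.json`)
accounts for the sequence on neither derivative:

```json
{"jx000|jx001": {"lost": {"chr_BCL2": 12, "chr_IGH": 1860},
                 "inserted": 19, "expected_derivative_total": 20765}}
```

12 bp are lost from the partner chromosome (the two breakpoints sit
12 bp apart) and 1860 bp from the synthetic IGH locus between the D and
J clusters; 19 inserted bases are the two N-regions. The same run is
byte-identical for a fixed seed.

The library surface mirrors the CLI, e.g.:

```python
from vdjcapture.presets import db_t14_18
from vdjcapture.pipeline import PipelineConfig, run_detection

scenario = db_t14_18(seed=7)
pairs, truth_map, stats = scenario.reads(coverage=50, seed=7)
calls = run_detection(scenario.model, pairs, PipelineConfig())
```

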