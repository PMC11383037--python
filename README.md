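# caspevo

Comparative evolutionary analysis of the caspase-1 gene locus.

The inflammatory caspases — caspase-1, its paralogs caspase-4/-5 (primates)
and caspase-11 (rodents), caspase-12, and the CARD-only genes — share one
syntenic locus and a tangled history of tandem duplication, pseudogenization,
whole-gene loss, and gene conversion. `caspevo` is a tested pipeline for
reconstructing that history from per-species locus sequences:

* **exon annotation** — locate reference exons in a locus by local alignment
  (megablast-like scoring, bit score > 100, full-exon identity ≥ 60%), assign
  hits to paralogs by synteny, and assemble in-frame CDSs;
* **gene status** — classify each homolog as present / partial in-frame /
  pseudogene / absent (a homolog with < 70% of reference exons is absent),
  with frameshift, premature-stop, and exon-loss lesion evidence and a
  shared-lesion heuristic that separates real pseudogenes from assembly
  errors;
* **conversion detection** — ≥ 1 kb intra-locus self-similarity blocks at
  ≥ 50% identity (seed-chain-extend), plus tree-based conversion calls from
  paralog intermixing under Jukes–Cantor distances;
* **gain/loss reconstruction** — Dollo parsimony (single gain, minimum loss
  branches) on the species tree, and duplication dating from node ages;
* **selection scans** — Nei–Gojobori (NG86) pairwise dN/dS with the
  dS ≤ 0.3 outgroup filter, recombination-breakpoint splitting, and a
  counting-based (SLAC-style) site test with a Bonferroni-corrected
  (3.33e-3) gene-level test;
* **cleavage-site scans** — conservation of the three aspartate self-cleavage
  sites with an alternate-aspartate window;
* **strain variants** — three-way conservation classification of inbred
  mouse/rat missense variants, per-strain avoid/caution/clean
  recommendations, and detection of frame-restoring "variants" that expose
  reference-assembly errors;
* **locus simulator** — a codon-level locus-evolution generator (HKY, per-site
  dN/dS by mutation-selection rejection, scripted duplication / loss /
  lesion / conversion events) whose exact truth log makes every stage
  testable without genome downloads.

## Worked example

Which common mouse lines are safe for caspase-11/-12 work? The bundled
strain-variant table answers directly:

```bash
caspevo variants --genes Casp11,Casp12 --out strains.tsv
# 16 strains, 8 flagged avoid
```

`strains.tsv` then contains one flag per strain: 8 of the 16 lines
(129S1_SvImJ, cAST_EiJ, pWK_PhJ, wSB_EiJ, aKR_J, cBA_J, nOD_ShiLtJ, IP_J)
carry caspase-11/-12 missense variants at conserved or untested sites and
are flagged `avoid`; sPRET_EiJ carries only variants whose alternate residue
is already found in other rodents (`caution`); and 7 lines (bALB_cJ,
c57BL_6NJ, a_J, nZO_HILtJ, fVB_NJ, dBA_2J, c3H_HeJ) carry no missense
variants in caspase-1, -11 or -12 (`clean`).

A full simulated pipeline run (annotation, status matrix, blocks, loss
reconstruction on an event-rich synthetic primate-like locus):

```bash
caspevo run --preset primate --scale 0.25 --seed 1 --out run1/
```

which prints the stage summary (block counts per species and per-gene loss
counts) and writes `run1/summary.json`, `run1/gene_status.tsv`, and a run
manifest.

## Layout

```
src/caspevo/
  core.py       shared types, config, FASTA/GFF3/Newick I/O
  sim.py        locus-evolution simulator + truth log
  annotate.py   exon hits, synteny assignment, CDS assembly
  status.py     lesions and four-way status calls
  blocks.py     similarity blocks, conversion calls, NJ trees
  events.py     Dollo reconstruction, duplication dating
  selection.py  NG86, breakpoint splitting, site/gene selection tests
  cleavage.py   aspartate cleavage-site scan
  variants.py   strain-variant classification (+ bundled tables/)
  pipeline.py   per-species chain and end-to-end driver
  cli.py        the `caspevo` command
```

See `docs/methods.md` for the models, parameter choices, and limitations.
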