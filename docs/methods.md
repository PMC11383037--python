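# Methods

This note records the models behind each stage, the parameters that matter,
and the design choices made where more than one defensible option existed.

## The locus simulator

The simulator is the package's source of ground truth. An ancestral locus is
laid out from a gene list (exon and intron lengths, strand, per-codon
dN/dS), separated by intergenic spacers; CDSs are random sense codons (ATG
start, single terminal stop), and paralog families are seeded by codon-wise
re-randomization of an earlier gene at a configurable divergence (default
0.2–0.3 per site), which is what makes CARD-like cross-matching and
conversion detectable downstream.

Sequences evolve down the species tree under HKY (default kappa = 4,
uniform base frequencies; branch lengths in expected substitutions per
site). Coding sites use mutation–selection rejection: a nonsynonymous
proposal at a site with ratio omega is accepted with probability
min(1, omega) and a synonymous proposal with min(1, 1/omega), so the
realized nonsynonymous/synonymous rate ratio equals omega on both sides
of 1 (a one-sided rejection rule cannot generate omega > 1 signal, because
acceptance saturates at 1). Proposals creating a premature stop, or hitting
the start or stop codon of an intact gene, are rejected; pseudogenized genes
evolve neutrally. Gene-scale events are *scripted* on named branches rather
than drawn from rates — tests need exact truth — and cover tandem
duplication (copy inserted next to its source, with flanks), whole-gene
loss, pseudogenizing lesions (frameshift indel, premature stop, exon loss),
in-frame truncation (the partial-gene class), gene-conversion tracts
(default ≥ 1 kb), and intergenic segmental duplications. The truth log
records every accepted substitution and every resolved event, so a species'
locus can be replayed from the ancestor exactly; identical config + seed is
byte-identical.

Two presets mirror the two regimes the analysis contrasts: `primate_like`
(event-rich: duplication + pseudogenization of the copy, clade and leaf
losses, a CARD-overwriting conversion, a truncation) and `rodent_like`
(event-poor: one pseudogenization, intergenic repeat insertions only, a
single caspase-4/11-like gene). At scale 1 the layout is ~350 kb; the test
suite and acceptance script run at scale 0.25 (~80 kb, identical coding
content), a problem size chosen so the full recovery benchmarks run in
seconds while leaving every detector's geometry (intergenic > conversion
tract > intron) intact. What the simulator does **not** emulate: transposon
families, GC/codon-usage bias, alignment-breaking structural variation
beyond the scripted events, and sequencing error; passing recovery tests
therefore demonstrates algorithmic correctness on clean data, not robustness
to raw-assembly artifacts.

## Exon annotation

Hits are scored two ways on purpose. The *bit score* comes from the best
local segment under megablast-like scoring (match +1, mismatch −2, gap open
−2, extend −1; bits = (0.625·S − ln 0.41)/ln 2), thresholded at 100 bits.
The *identity* is measured over the full-exon (glocal) alignment — the exon
aligned end-to-end inside the candidate window with free window overhangs —
counting gap columns as non-matches, thresholded at 0.60. The split matches
annotation-transfer semantics: a strong core cannot rescue an exon whose
overall similarity is too low. With +1/−2 scoring a full-span *local*
alignment needs > 2/3 identity, so a purely local identity could never
exercise the 0.5–0.6 threshold band. Note the glocal identity is a property
of the optimal alignment: regions below ~1/3 identity get gapped out rather
than aligned, so constructions for threshold tests use masked (N) tails,
whose identity contribution is exactly zero under any alignment.

Loci ≤ 8 kb are scanned exhaustively (iterative best-hit masking — complete
for any hit above threshold); larger loci use k-mer seeding (k = 11),
reliable down to roughly 70% identity. Synteny assignment walks overlapping
hit groups in locus order: unambiguous groups anchor their gene's slot;
ambiguous groups are resolved by continuation (extending a nearby cluster of
the same gene), tandem-copy adjacency (a candidate whose cluster sits within
`join_gap` = 5 kb and scores at least as well — recent duplicates sit next
to their source), and otherwise slot filling toward the upstream unoccupied
slot (logged). A final relabelling pass hands a displaced, non-tandem
duplicate cluster to a missing slot: this is exactly the gene-conversion
case, where the converted CARD matches its converting paralog better than
its own reference and only synteny preserves its identity. Exons still
missing after assignment are rescued by glocal alignment inside the interval
bracketed by flanking recovered exons, with the identity threshold only —
synteny vouches for the location, which is how genuinely diverged exons
(deep rodent comparisons) are recovered despite failing the bit score.

## Gene status

Decision order is fixed: (1) completeness (distinct exons found / reference
exons) < 0.70 ⇒ absent, whatever the remnant looks like; (2) lesion-free and
aligned over ≥ 95% of the reference CDS ⇒ present ("full length" needs a
tolerance; 95% absorbs terminal-codon variation); (3) lesion-free but
shorter ⇒ partial in-frame; (4) otherwise pseudogene. Lesions are read off a
global alignment with free end gaps, gap open −10 and extension −0.5: gap
opens priced well above a mismatch (cheap opens fabricate compensating
indel pairs that read as false frameshifts at high divergence) but long
extensions kept cheap (a genuine whole-exon deletion must still out-score
the null staggered alignment). Internal indels with length ≢ 0 (mod 3) are
frameshifts; in-frame stops upstream of the reference stop (frame tracked
through indels) are premature stops; internal gaps covering ≥ 80% of a
reference exon are exon losses; a missing ATG is a lost start. Terminal
overhangs are *not* lesions — they lower the aligned fraction instead,
which is what keeps cleanly truncated genes in the partial class. A lesion
unique to one assembly is flagged low-confidence; one shared at the
homologous position (± 3 bp) by another species supports a real event, and
strain evidence that every resequenced line restores the frame upgrades the
flag to a probable reference assembly error.

## Similarity blocks and conversion

Block detection is the algorithmic equivalent of an interactive self-dotplot:
exact k-mer seeds (k = 12), per-diagonal chaining (gap ≤ 200 bp, diagonal
band ±50), ungapped X-drop extension (drop 20), then a gapped edit-distance
identity over the chained span; blocks must be ≥ 1 kb at ≥ 50% identity,
with gaps counted as mismatches and both orientations searched. Tandem
copies whose extensions touch are trimmed at the facing ends rather than
discarded (adjacent duplicates are the most common real case); overlaps
≥ 20% of a block indicate a near-diagonal self-match and are dropped. The
k = 12 seeds make detection reliable above roughly 70% identity; a 50%-
identity tract with uniformly scattered differences is below the seedable
range (it contains almost no exact 12-mers), which is an explicit
limitation — the 50% threshold is binding for identity *measurement*, not
seeding sensitivity.

Tree-based conversion calls compare, for species s and paralogs (g, h), the
within-species cross-paralog distance d(g_s, h_s) against within-gene
cross-species distances (Jukes–Cantor). Inside a converted clade the
orthologs coalesce *after* the conversion, so they cannot serve as the
baseline; the detector therefore sweeps clades (preorder), calling a clade
converted when every member's cross-paralog distance beats its distance to
all orthologs *outside* the clade and outside previously called species.
Called species are merged into maximal fully-called clades — the event
count. If every species ends up called there is no unconverted reference
lineage left and the signal is an ancestral duplication, not conversion, so
no call is made.

## Gain/loss reconstruction

Dollo parsimony with a single gain: the origin is the MRCA of intact
species (pseudogene, partial, and absent all count as non-intact — the
reconstruction concerns loss of an intact gene, whatever the molecular
route), or a forced deeper origin when outside evidence says the gene is
ancestral. The minimum loss set is the set of maximal all-non-intact
subtrees under the origin; this set is unique, so no tie-breaking is ever
exercised (the brute-force comparison in the tests confirms minimality
exhaustively on small trees). Duplication ages are read off supplied node
ages: the duplicate arose on the stem branch of the clade that carries it,
giving a (parent age, origin age) interval, open-ended above the root.

## Selection analysis

Pairwise dN/dS is Nei–Gojobori counting: per-codon synonymous/nonsynonymous
site fractions (changes to stops count as nonsynonymous), pathway-averaged
substitution counts for multi-step codon differences (pathways through
stops excluded; all pathways used if every route is blocked), Jukes–Cantor
correction, saturation reported when a proportion reaches 3/4. Species
beyond pairwise dS 0.3 from the reference are dropped as outgroups before
tree-wide scans. Alignments are split at supplied recombination breakpoints
(snapped to codon boundaries, logged); breakpoints are an input — the
package does not infer them.

The site scan reconstructs ancestral codons by Fitch parsimony on the fixed
tree (missing/gapped leaves are wildcards; ties averaged uniformly over
optimal states, with substitution counts pathway-averaged as above). Each
site's inferred (N, S) counts are tested one-sided against a
*background-modulated* null: the segment-wide rate ratio — estimated from
the segment's total N and S counts relative to its mutational opportunity,
leave-one-site-out — applied to the site's own neutral nonsynonymous
fraction. This makes the site test a relative-rate test ("does this site
exceed the gene's background omega"), which is the operative question in a
pervasively purifying gene; a flat neutral-opportunity null has essentially
no per-site power at realistic tree depths because the effect size
saturates (~0.76 → ~0.93 expected nonsynonymous fraction even at omega = 4).
The binomial tail is evaluated through the regularized incomplete beta
function so fractional (pathway-averaged) counts are handled exactly. A
site is flagged at p ≤ 0.05 *and* N/S above the segment ratio. The
gene/segment-level test keeps the neutral-opportunity null (otherwise it
would be null by construction): a seeded Monte-Carlo (≥ 2000 draws) of the
total nonsynonymous count, judged against the Bonferroni-corrected level
3.33e-3 — so uniform elevation of a whole segment is the gene test's job
and localized excess is the site test's. Robustness re-runs repeat the scan
over an expected-fraction grid (composition-based vs uniform code-based)
and permutation seeds; a site is robust only if flagged under every
setting.

Calibration conditions (12 taxa, 300 codons, 20 replicates) use a balanced
tree with 0.35 substitutions/site per branch. That depth was fixed by a
design power calculation before the calibration suite was assembled:
detecting an omega = 4 site at alpha = 0.05 with ≥ 50% power needs on the
order of 18 cleanly inferred substitutions per site, which sets the total
tree length; parsimony undercounting at greater depths would erode rather
than add power. Measured under these conditions: site-level type-I error
≈ 0.2–0.3% (nominal 5%, conservative because of the segment-ratio side
condition), power at omega = 4 sites ≈ 70–78%, false flags < 1%, and no
neutral replicate significant at the gene level.

## Cleavage sites and strain variants

The cleavage-site scan lifts reference residue positions through the
protein alignment and reports, per species and site, the aligned residue
and any aspartate within ± 5 residues (gap columns skipped; nearest wins,
downstream breaking ties). The window size is configurable; 5 residues is a
deliberately generous definition of "nearby" for a protease cleavage site.

Variant classification is a three-way rule applied in fixed order to the
homologous alignment column across a comparison panel (default ≥ 10 close
species): alternate residue already present in another species ⇒ unlikely
to disrupt; column invariant ⇒ potential impact; otherwise unknown. Strict
invariance is the default ("highly conserved" operationalized as
invariant); a ≥ 90% near-invariance option exists but is off. Strain
recommendations count unknown variants toward avoidance — an untested
variant is not evidence of safety — which is also what makes the
recommendation monotone under reclassification. Frame restoration applies
the indel to the reference CDS and requires a codon-multiple length, no
internal stop, and a translation within 5% of the homolog median length; a
restoring indel carried by every strain is reported as a probable reference
assembly error. The bundled mouse and rat tables transcribe published
strain-variant tables including their shading classes; the caspase-12
status fixtures used for loss counting are *synthetic* reconstructions of
the described per-clade retention pattern (the per-species source table is
not redistributed here) and are labelled as such in their filenames and
headers.

## Numerical and degenerate-input conventions

All intervals are 0-based half-open internally; GFF3 I/O converts to
1-based closed. Ambiguity codes collapse to N (counted and logged); N never
matches. Omega is reported as undefined when dS = 0; JC distances are
undefined (saturated) at p ≥ 3/4. NJ trees use JC distances with saturated
pairs capped at 5.0 substitutions/site; bootstrap support is computed from
seeded column resampling. Overlapping hits for one exon keep the highest
score, then identity, then the leftmost; every threshold applied comes from
`PipelineConfig` and is logged by the pipeline driver.
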