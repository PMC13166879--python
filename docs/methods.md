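# Methods

## The analysis model

`nanohgt` treats a spirotrich macronuclear assembly as a set of independent
nanochromosomes. Three layers of analysis sit on top of that representation.

**Telomere scanning and contig classification.** A contig terminus carries a
telomere when a tandem run of at least `min_copies` copies of the 8-bp repeat
unit — the C-rich unit `CCCCAAAA`, its G-rich reverse complement, or any
rotation of either — begins (5′) or ends (3′) within `window` bp of the
terminus. Both orientations are tested at both ends, so classification is
invariant under reverse-complementing a contig. Defaults are
`min_copies = 2`, `window = 50` bp, `max_mismatch_per_unit = 0`: two exact
unit copies reproduce the short telomere tracts typical of spirotrichs while
keeping the chance match probability negligible (a 16-bp periodic match within
50 bp of an end; the measured false-positive rate on random 2-kb sequence is
0 in 1000 contigs). All four parameters are exposed on the CLI because real
assemblies may need looser settings (sequencing-error mismatches, trimmed
ends). Contigs are then classified both/one/none by telomere-capped ends; the
three classes partition the contig set.

**Assembly and gene statistics.** N50 is the length of the contig at which the
cumulative sum over descending lengths first reaches half the assembly; L50 is
the count of contigs in that prefix. GC content excludes ambiguous bases from
the denominator. GC skew is (G−C)/(G+C) per sliding window (defaults 20 kbp /
5 kbp step; tail windows keep their true span; windows without G or C report
0 with an `undefined` flag). Gene-architecture statistics count exons and
introns from the annotation; "intronless" means single-exon; one- and
two-gene fractions are computed among gene-bearing contigs. Gene density is
(protein-coding genes + `ncrna_count`) / Mbp — the inclusive definition is
available because published densities for these genomes typically fold
non-coding RNAs into the numerator, but it is never applied silently
(`ncrna_count` defaults to 0).

**Codon usage under reassignable codes.** CDS are spliced from CDS intervals
(minus-strand genes exon-joined then reverse-complemented); lengths not
divisible by 3 are flagged and excluded. Terminal codons are tallied
separately from internal ones: the last codon of a CDS reflects stop usage,
not synonymous choice, so RSCU uses internal counts only. RSCU for codon *c*
in a synonymous family of size *n* is `n·x_c / Σ x`, with zero-total families
reported as 0 and flagged. Stop-codon inference classifies each canonical
stop (TAA/TAG/TGA) from two observables: the fraction of CDS terminating in
it (`f_terminal`) and its in-frame density per 1000 internal codons
(`d_inframe`). A codon is a *stop* when `f_terminal ≥ 0.05` and
`d_inframe ≤ 0.2`; a *sense* codon when `d_inframe ≥ 1.0`; otherwise
*ambiguous*. The thresholds separate the two preset codes cleanly: under the
ciliate nuclear code TAA/TAG occur in frame at tens per 1000 codons while TGA
never does, and under the standard code all three appear only terminally.
The amino-acid identity of reassigned codons (glutamine, in ciliates) cannot
be established from a genome alone — it needs homolog-alignment evidence —
so the module reports sense/stop status only.

## Alien Index and identity profiling

The AI is the natural-log ratio of best-hit E-values,
`AI = ln(bbh_in + ε) − ln(bbh_out + ε)`, with ε = 1e-200 and a missing group
contributing E = 1. This is the standard best-hit construction; base,
pseudocount, missing value and threshold (default 0.05) are all configurable.
Hits labelled `self_lineage` (the recipient's own class) are excluded by
default so close relatives cannot mask a recent transfer; the ingroup is
eukaryotes outside that lineage, the outgroup prokaryotes. A query with no
informative hits gets AI = 0 flagged `no_evidence` rather than a
division-by-zero or a spurious call. AI is monotone: improving the outgroup
best hit never decreases AI, improving the ingroup best hit never increases
it.

Percent identity between a candidate and its homologs uses optimal global
alignment (affine gaps: a length-L gap costs `gap_open + (L−1)·gap_extend`,
defaults 10/1; BLOSUM62 with X scored 0 against everything; end gaps
penalized). Identity is identical columns over the full alignment length,
gap columns included in the denominator — the conservative convention; a
matched-columns-only denominator would only raise the numbers. Among
co-optimal alignments the aligner's first traceback is used; the *score* is
tie-independent (verified against exhaustive enumeration), while identity can
in principle differ between co-optimal tracebacks by a column or two.

## The validation cascade

Candidates are the AI-positive genes. Each enabled filter contributes a
boolean to a strict conjunction — the cascade is a falsification chain, and
an OR/score mode is deliberately not offered. Filter semantics and defaults:

| filter | pass condition | defaults |
|---|---|---|
| telomere | host contig classified `both` | scanner defaults above |
| spanning | ≥ `min_reads` alignments covering ≥ `min_cov_frac` of the contig with both ends within `end_slack` bp of the termini | 3 reads, 0.95, 50 bp |
| coverage | Spearman ρ(DNA, RNA windowed depth) ≥ `min_rho` and RNA breadth over CDS windows ≥ `min_rna_breadth` | 0.5, 0.8 |
| intronless | single exon | — |
| ciliate panel | ≤ `max_species` panel species with a hit at E ≤ `max_evalue` (boundary counts) | 0 species, 1e-5 |
| stress DE | ≥ 1 condition with abs log2FC ≥ `min_abs_log2fc` and FDR ≤ `max_fdr` | 1.0, 0.05 |
| tree | smallest clade holding the query and ≥ 1 other leaf contains only prokaryote leaves, support ≥ `min_support` | 70 |

`min_reads = 3` operationalizes "multiple" spanning reads; the 50-bp slack
tolerates soft-clipped read termini. DNA/RNA "consistency" has no canonical
definition, so a rank correlation was chosen for invariance to library-size
scaling, paired with an RNA-breadth requirement so that a silent
(RNA-absent) contig fails even when ρ is undefined; a constant track makes ρ
undefined (NaN, flagged) and the verdict then rests on breadth alone. In the
tree check, a clade with unparseable or sub-threshold support — or a query
hanging off the root of a star topology — returns `unresolved`, which does
not pass. Whether DE responsiveness is required or merely recorded is a
config toggle (`enabled`), since expression support is corroborating rather
than structural evidence. Each candidate's verdict row records every filter's
value or an explicit `disabled`, and enabling additional filters can only
shrink the call set (verified as a property test).

The nine-species reference panel used by the lineage-exclusion filter is a
user input (any proteome set representative of the recipient's phylum); the
simulator ships a fixed panel of nine well-known ciliates.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, at
the configured study conditions: 500 contigs with telomere-status fractions
(0.5254, 0.3212, 0.1534) and genes-per-contig probabilities
(0.6153, 0.2512, 0.1335) matching published spirotrich MAC architecture;
mean gene length 1495 bp; native GC 0.3832; ciliate nuclear code; 10 planted
alien genes at GC 0.55. Native genes are intronless with probability 0.59,
otherwise receive 2 + Poisson(0.83) exons (mean 1.75 exons overall) with
intron lengths ≈ N(78, 8) bp. The published gene-count distributions stop at
two genes per contig, so the "3+" category is realized as exactly three — a
free tail parameter held fixed. Gene sequences are sampled codon-by-codon
from a Dirichlet-smoothed codon table (concentration 200 around the
GC-implied base-composition weights, one draw per genome per composition),
start codon ATG, terminal codon from the code's stop set. Alien genes are
intronless and placed on both-telomere contigs, so every planted transfer
*can* survive the structural filters.

Margins make the screen's separability a construction, not an accident: the
hit table gives alien genes a best outgroup E-value at least 5 orders of
magnitude below the best ingroup E-value (and vice versa for natives), so
|AI| > 11 ≫ threshold + 1 on both sides. Spanning reads cover ≥ 96% of
supported contigs with ≤ 20 bp terminal trims; consistent coverage tracks
share a latent per-window profile (2% multiplicative noise) giving Spearman
ρ ≈ 1; responders get |log2FC| ∈ [2, 6] at FDR ≤ 1e-3 versus null rows at
|log2FC| ≤ 0.2, FDR ≥ 0.5; alien gene trees nest the query beside a
prokaryote leaf with support ≥ 90. Realistic confounders are planted on the
*native* side — background DE responders (10% of native genes), self-lineage
hit rows, natives lacking outgroup hits entirely, coverage-inconsistent
decoy contigs — so individual filters are exercised without breaking
end-to-end recovery.

A single root seed expands into per-stream substreams
(`SeedSequence(seed, spawn_key=(stream,))`; genome=0, hits=1, reads=2,
coverage=3, DE=4, trees=5; per-gene tree substreams key on the gene's index),
so adding a stream never perturbs another and identical config+seed yields
byte-identical bundles. The first draw on the genome stream is, by
documented contract, the per-contig telomere-status vector — tests recompute
it independently as an oracle.

What the generator does **not** emulate: read-level error models and quality
strings, chimeric or split alignments, IES/MDS rearrangement, paralogy and
gene families, compositional heterogeneity along a chromosome, taxonomically
realistic hit breadth, or DE count noise (the DE table is consumed, not
produced, by the pipeline — margins are planted directly). Passing tests
therefore demonstrate the pipeline's logic and bookkeeping, not its
robustness to borderline real-data signals; on real data the exposed
thresholds, not the defaults alone, carry the analysis.

## Numerical and interface choices

* Internal coordinates are 0-based half-open everywhere; GFF3 (1-based
  closed) conversion happens only at the file boundary. PAF/bedGraph are
  native 0-based half-open.
* PAF is the native alignment fixture format (text-only, no index); a SAM
  reader (via pysam) covers real data.
* Sequence/annotation parsing uses Biopython and gffutils; trees use
  dendropy; tables use pandas; ρ uses scipy. The AI statistic, telomere
  scanner, RSCU and the filter cascade are implemented here.
* Lowercase sequence is case-folded; N excluded from GC; duplicate contig
  IDs, out-of-bounds CDS (named per gene), unmapped taxa (warned, grouped
  as `other`) and malformed hit rows (reported with line numbers) are
  handled explicitly.
* Desk-scale problem sizes used by the test suite and the acceptance script:
  bundles of 50–500 contigs (10 seeds at the default 500/10-alien
  conditions for end-to-end recovery), 1000 random 2-kb contigs for the
  telomere false-positive rate, 20 seeds per genetic code for stop-set
  recovery, exhaustive alignment enumeration to length 3 plus a dense seeded
  sample to length 6, and exhaustive N50 multisets to size 5 plus a sample
  for sizes 6–8.

## Known limitations

* Telomere detection parameters for published assemblies are rarely stated;
  when reproducing printed telomere counts, residual discrepancies should be
  reported against the exposed scanner parameters rather than tuned away.
* The screen's conjunction semantics means a single noisy filter (e.g. low
  RNA coverage of a real transfer) vetoes the call; on real data, run with
  subsets of `enabled` filters and compare ledgers.
* `unresolved` tree verdicts fail the tree filter; rooting is taken from the
  Newick as given, and an unrooted or star topology cannot support nesting.
* Donor identification, transfer dating, dN/dS and gene-family dynamics are
  out of scope.
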