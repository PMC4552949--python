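# Methods

This note documents the models, parameter defaults and numerical choices
behind `lsgscan`, and what the synthetic-world tests do and do not show
about real data.

## Homology search and lineage classification

Queries are stratified by length — PAM30 below 30 aa, PAM70 from 30 to
70 aa inclusive, BLOSUM62 above — because short proteins need shallower
matrices to retain statistical power. The two boundary lengths are assigned
to the middle class; both bounds are configurable
(`PipelineConfig.length_class_bounds`).

Alignment is exact affine-gap Smith–Waterman dynamic programming
(`Bio.Align.PairwiseAligner` in local mode), not a seeded heuristic: at
desk scale full DP is affordable and removes seeding as a source of missed
hits. Gap penalties follow the community defaults per matrix (BLOSUM62
11/1, PAM70 10/1, PAM30 9/1, charged as open+k·extend for a gap of length
k). Substitution tables are rebuilt over the 20-letter alphabet plus 'X',
with 'X' scoring 0 against everything; any other letter is an input error.
No low-complexity masking is applied.

Significance uses the Karlin–Altschul expectation E = K·m·n·e^(−λS) with n
the concatenated length of the searched panel (database-style semantics,
matching how a BLAST database search would compose the statistic). λ and K
ship as fixed per-matrix constants approximating gapped BLAST practice
(BLOSUM62: 0.267/0.041; PAM30: 0.294/0.110; PAM70: 0.310/0.100); they are
deliberately constants rather than fitted quantities so results are
deterministic, and they are configurable. Hit/no-hit decisions at the
default cutoff of 10⁻⁵ are insensitive to their exact values at the scales
involved: true homologs in these screens score hundreds of raw units
(E ≪ 10⁻¹⁰) while unrelated proteins sit orders of magnitude above the
cutoff.

The label of a gene is defined by which panels contain hits — no hit
anywhere ⇒ SSG; hits only among congeners ⇒ GSG; any non-genus hit
(including the outgroup protein set) ⇒ EC — so screening order cannot
change the outcome; panels are nevertheless searched outermost-first with
short-circuiting because one vertebrate hit settles the question. The
outgroup set is treated as a non-genus panel and may contain focal-species
entries; panel loading excludes them by species tag. With several isoforms
per gene the call is conservative for specificity: EC if any isoform has a
non-genus hit, SSG only if all isoforms are hit-free.

## Gene characterization

Gene length is the genomic span (CDS envelope) and GC content is computed
over that full span including introns; both are configurable to spliced
coordinates (`gc_on_span`). SE is the sample SD (n−1 denominator) over
√n. The one-way ANOVA computes between/within sums of squares directly and
takes p from the F distribution; the degenerate all-identical case is
defined as F = 0, p = 1, and zero within-group variance with unequal means
as F = ∞, p = 0.

## Origin analysis

"Complete overlap" is read literally: a gene is TE-derived (respectively
duplication-derived) when its genomic span is fully contained in the union
of TE (paralog) intervals. The containment threshold defaults to 1.0 and is
exposed as a fraction because the literal reading is strict; overlap is
strand-ignorant since exaptation can be antisense. Containment is evaluated
as union-covered base pairs against `threshold × span` with a 10⁻¹²
guard so exact containment is never lost to float division. Category
totals use inclusion–exclusion, and percentages are rounded half-up to two
decimals to match conventional table formatting. The direction of the
containment test (gene-inside-annotation, not annotation-inside-gene) is a
documented choice.

## Retrogene and chimera screen

The screen proxies a TBLASTN → merge → FASTA → GENEWISE tool chain:

* **Translated search**: six-frame translation split at stop codons
  (internal stops truncate a frame); each stop-free segment of ≥ 15 aa is
  aligned against the query with the same local DP; E ≤ 10⁻³ with n the
  total translated length. Matches overlapping the query's own gene are
  self-hits and dropped.
* **Merging**: same-protein/chrom/strand matches merge transitively when
  the end-to-start gap is strictly below 40 bp; merged identity is the
  alignment-length-weighted mean, merged length the span in codons. Kept
  loci need identity > 30% and > 50 aa (both strict).
* **Parent assignment**: candidates are proteins whose genes have ≥ 2
  introns; the closest by alignment identity wins, with ties broken by
  parent CDS length then lexicographic id for determinism. Loci that
  overlap the assigned parent's own gene are discarded — re-aligning a
  candidate back to its parent's locus is the cheap equivalent of the
  flank re-verification step, and without it the parent's own locus is
  always its own best "retrocopy".
* **Intronless verification** (the GENEWISE stand-in): the parent's
  per-exon peptide blocks are aligned to the locus ± 10 kb flanks. All
  acceptable placements of every block are collected and a chain DP selects
  the best run of *consecutive* blocks that are *contiguous at the locus*
  (genomic gap within [−3, 30] nt — adjacent blocks of a true retrocopy
  abut, modulo one alignment-trimmed codon). A flat per-intron penalty
  (default 50 raw units) is charged for each matched block that cannot
  join the intronless chain. An earlier design penalised intron-like gaps
  without restricting the chain; that is not discriminative, because exon
  block scores are large enough to absorb any constant penalty, and
  paralogous loci (including the parent itself) then verify as "intronless".
  With the chain formulation an intron-containing locus reports at most one
  exon in its best run, hence `introns_in_match = 0`, and fails the
  acceptance rule below naturally. The reported score is in raw
  substitution-matrix units — not GENEWISE bits; the acceptance threshold
  of 35 is kept on this proxy scale and is configurable.
* **Acceptance**: score > 35, ≥ 2 parental introns inside the matched part
  of the parent, parent coverage > 40% (strict), plus a confirmation
  alignment of the recruited locus back to the parent. Overlapping accepted
  loci reached through different queries are deduplicated keeping the best
  score.
* **Chimeras**: an annotated gene whose CDS (exons only, UTRs excluded)
  overlaps a retro locus by > 50 bp is chimeric; > 90 bp sets a
  `possible_false_positive` flag — a flag, never a removal, because the
  two published thresholds overlap and both readings are preserved
  downstream. The call's parent gene is excluded, as is any gene whose CDS
  is ≥ 95% contained in the locus: that gene *is* the retrogene annotation
  (exact containment would be brittle, since local alignment may trim a few
  terminal residues off the called locus).

## Expression profiling

Placement filters run first (all four thresholds inclusive: ≥ 150 bp,
≥ 98%, ≥ 97%, ≥ 75%), then ambiguity resolution per transcript: if the
runner-up score is within 2% of the best — relative to the best, because an
absolute score difference is meaningless across transcript lengths — the
transcript is discarded entirely. EST support requires the union of
retained placements to overlap the gene span by strictly more than 100 bp.

RPKM uses the genomic span as gene length (consistent with
characterization; configurable to spliced length). A read counts for every
gene its interval overlaps by ≥ 1 bp; a unique-assignment mode is
available. "Expressed" defaults to RPKM > 0 — no positive cutoff is
assumed, and the generator's design (expressed genes always get ≥ 1 read,
unexpressed genes get none) makes this an exact oracle; the threshold is
prominent in the config for users with noisier data. Group comparisons use
Welch's t-test; degenerate zero-variance inputs resolve to (0, 1) for
identical constants and (±∞, 0) for different constants.

## Synthetic worlds

The generator plants, on one contig, everything the pipeline measures:

* **Homology structure**: EC genes get mutated homologs in every clade
  panel and in the outgroup set, GSG genes only among congeners, SSG genes
  nowhere. Default per-clade amino-acid substitution rates are 0.05 /
  0.15 / 0.25 / 0.35 (congener → vertebrate); validation requires them to
  be non-decreasing with clade distance (non-decreasing rather than
  strictly increasing so that the zero-divergence limit, where recovery
  must be exact, is a valid configuration). Substitution is uniform random
  replacement — only hit/no-hit detectability matters downstream, so a
  matrix-weighted model would add realism the consumers never see.
* **Gene architecture**: spliced CDS lengths and exon counts are drawn per
  class with EC > GSG > SSG scaling (defaults: base 300–900 nt and 1–3
  exons for SSG, ×1.7/+1 for GSG, ×3.0/+3 for EC), echoing the strong
  size/complexity ordering reported for real conserved versus young genes.
  Exons are codon-aligned; codons are drawn uniformly from the 61 non-stop
  codons (no codon-usage realism); background DNA is AT-rich (64% AT),
  giving genic GC ≈ 50% against a lower genomic baseline.
* **Origins**: TE/paralog intervals fully contain the flagged genes;
  background TEs (default 2 per 10 kb) are placed strictly intergenically
  so no gene is covered by accident. Duplication-flagged genes are also
  sequence near-copies (2% aa divergence) of a same-class sibling and
  inherit the sibling's exon structure — DNA-level duplicates preserve
  introns, and an intronless copy of a multi-exon gene would by definition
  be a retrogene, corrupting the planted negative set for the retro screen.
* **Retrogenes and chimeras**: parents are multi-exon (≥ 3 exons) SSGs, so
  every derived gene's lineage label is well-defined regardless of clade
  divergence. Standalone retrocopies (5% aa divergence by default,
  re-encoded reusing parent codons at unchanged positions) are annotated as
  single-exon genes; chimeric constructs place an unannotated retrocopy
  whose in-frame tail (default 75 bp, codon-aligned) is shared with a
  planted single-exon gene extending 225 bp beyond it.
* **Expression**: EST support and per-stage expression are planted at
  exact per-group counts (defaults 32.04% / 58.69% / 80.97% for
  SSG/GSG/EC, the prevalence ordering real transcript-support data shows),
  over 14 stages with mean read depths of 8–12 per expressed gene.
  Unexpressed genes receive zero reads.

Identical seeds give byte-identical output files; all randomness flows
from one `numpy` generator.

**What passing these tests does not show.** The generator has no indels, no
sequencing errors, no alternative splicing, no UTRs, no codon-usage or
repeat structure, and its TE track never partially overlaps genes. Perfect
recovery on planted worlds therefore validates the *bookkeeping and
thresholds* of the pipeline — boundary conditions, interval arithmetic,
statistics, determinism — not robustness to alignment ambiguity in real
genomes, where divergence, fragmented annotation and repeat-derived
homology make every stage noisier.

## Problem sizes and runtimes

Test worlds use 25–80 kb contigs with 10–29 genes and two species per
clade panel, keeping the whole suite under a minute of alignment work; the
acceptance script uses two 80 kb worlds (36 genes each, 6 retro loci, 14
stages) and finishes in about half a minute on one core. The CLI default
(500 kb, 42 annotated constructs) runs the full pipeline in about two
minutes, dominated by the six-frame translated search. These sizes are the
package's chosen study conditions; every threshold exercised is
size-independent.

## Known limitations

* The retrogene score scale is raw substitution-matrix units, so the
  threshold of 35 is not comparable to GENEWISE bit scores; it was kept at
  the published value on the proxy scale and exposed in the config.
* λ/K are shipped approximations, adequate for cutoff decisions but not
  for publication-grade E-values on real databases; substitute real BLAST
  output via `--hit-table` when exact statistics matter.
* `one_way_anova` and the group tables require ≥ 2 observations per group;
  groups smaller than that are omitted from ANOVA rather than imputed.
* The screen assumes retro loci do not overlap multi-exon genes (true of
  the generator; nested real-genome arrangements would need the chimera
  containment fraction revisited).
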