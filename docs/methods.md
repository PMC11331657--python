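# Methods

## Problem setting

Two shRNA knockdowns (each compared against a scrambled control by a
junction-count differential-splicing caller) yield five per-type event tables
(SE, RI, MXE, A3SS, A5SS) with per-event PSI replicates, ΔPSI, p-value and
Benjamini–Hochberg FDR. The questions this package answers are: which
significant events are *shared* between the two knockdowns, do the knockdowns
shift those events in the same direction, how strongly do the two ΔPSI
profiles correlate, what sequence composition surrounds the affected
exon–intron junctions, and whether isoform switching is coupled to
gene-level expression change.

## Event identity and matching

All coordinates are normalized to 0-based half-open intervals at the I/O
boundary (the dialect's `*_0base` starts are kept; its 1-based inclusive ends
equal 0-based exclusive ends; GTF starts are decremented). An event's
matching key is type-specific:

- **A3SS / A5SS** — gene id, gene symbol, long-exon, short-exon and
  flanking-exon intervals;
- **SE / RI / MXE** — the upstream- and downstream-exon start/end positions
  plus the cassette exon (SE), retained intron (RI) or both exclusive exons
  (MXE).

Contig and strand are part of every key: without them, events at identical
offsets on different chromosomes would collide. Matching is exact key
equality; no fuzzy overlap matching is attempted. Within one contrast,
duplicate keys (possible in caller output) are collapsed before matching by
keeping the record with the smallest FDR, tie-broken by smallest p-value and
then event id, so that matching is one-to-one.

Upstream/downstream are transcript-oriented: for minus-strand events the
transcript-upstream exon has the larger genomic coordinates, and the
retained-intron interval of an RI event is derived accordingly.

## Concordance and correlation

Events pass a strict FDR < 0.05 filter before matching. A matched pair is
*concordant* iff ΔPSI_a · ΔPSI_b > 0; a zero ΔPSI counts as non-concordant
rather than being excluded, which keeps the denominator equal to the number
of shared events. The concordant percentage is rounded half-up to one
decimal. The cross-knockdown association is the Pearson product-moment
correlation of (ΔPSI_a, ΔPSI_b) with its two-sided p-value (scipy); it is
undefined (an error, not a NaN) for fewer than three pairs or a constant
margin. ΔPSI is always taken from the table's difference column (group1 −
group2), never recomputed from replicate means, for faithfulness to the
consumed tool. Gene-level tallies (distinct gene ids among shared events,
top genes by event count with lexicographic tie-break) and exclusive Venn
region counts (2–5 sets, all 2^k − 1 regions) are reported alongside.

## Junction motifs

Junction cut points are derived per type in transcript orientation: the
donor (5'ss) of an exon is its transcript-end boundary, the acceptor (3'ss)
its transcript-start boundary. SE contributes the cassette exon's acceptor
and donor; RI the upstream exon's donor and downstream exon's acceptor; MXE
both sites of both exclusive exons; A5SS/A3SS both the long and the short
alternative site (either subset can be recovered from the per-window
metadata). Events enter at a strict FDR < 0.1.

Each junction yields a window of `flank` bases (default 25) on both sides of
the cut point — 50 nt total, 25 exonic + 25 intronic — reverse-complemented
for minus-strand events so sequences always read 5'→3' on the transcript.
Windows that would run off the contig are skipped and counted, not fatal.

The position probability matrix uses per-position frequencies with a
Laplace-style pseudocount (default 0.5, configurable):
p_i(b) = (n_i(b) + pc) / (N_i + 4·pc), with `N` bases excluded from both the
count and N_i rather than spread across bases. The PWM is log2(p/background)
against a uniform background by default; information content is
2 + Σ_b p·log2 p bits per position (0·log 0 := 0); the consensus takes the
highest-probability base with ties broken A < C < G < T. Composition
profiles report per-position base fractions and two aggregates: the G+C
fraction of the exonic half and the C+T fraction of the intronic half (the
polypyrimidine-tract signal at acceptors). The "probability calculation"
preceding the PWM is implemented as plain per-position frequency — a
background-corrected variant would only rescale the log-odds, not the
consensus.

## Isoform switching vs expression

Gene expression per condition is defined as the sum of its isoforms'
expression (self-consistent; avoids reconciling a separate gene-level
table). IF = isoform/gene expression, missing when the gene total is zero;
dIF = IF_kd − IF_ctrl. Within a gene and condition with positive expression
the IFs sum to 1 and the dIFs to 0. Single-isoform genes keep dIF = 0 and
stay in the join, keeping the denominator transparent. The
differential-expression filter is strict on both margins (q < 0.05 AND
|log2FC| > 0.6). The dIF–log2FC association is the Pearson correlation of
each gene's *switching isoform* — the isoform with the largest |dIF|, ties
broken by isoform id — against the gene's log2FC. The reduction to one
isoform per gene is not cosmetic: a gene's dIFs sum to zero, so correlating
every isoform against the same gene-level log2FC cancels identically and
would report R = 0 for any data. All joined genes enter the correlation (the
claim concerns the overall relationship); the DE-significant subset is
reported separately when large enough.

## Synthetic data: what it emulates, and what it does not

The generator's defaults are the study conditions of the analysed
comparison: 819 shared significant events distributed over 301 genes across
two contrasts with two replicates each, a direction-concordance rate of
0.827, a cross-contrast ΔPSI correlation of 0.89 with ΔPSI spread
(sd) 0.15, and strict-filter-friendly FDR distributions.

Planted structure:

- **Shared events** carry byte-identical keys in both contrasts and are
  significant (FDR ~ U(1e-6, 0.049)) in both — they model the shared members
  of the two significant sets, which is exactly what the matching stage
  counts. Contrast-unique background events are significant with a
  configurable probability (default 0.8); non-significant FDRs are
  U(0.05, 1), so the strict filters are unambiguous.
- **ΔPSI vectors** of shared events follow an equicorrelated multivariate
  normal (mean 0, sd 0.15, correlation ρ), clipped to [−0.9, 0.9] (≈6 sd, so
  clipping is rare and the planted correlation essentially unaffected) and
  rounded to 3 decimals as emitted. When `concordance_rate` is a number, a
  per-pair Bernoulli draw decides concordance and the non-first contrasts'
  signs are forced to match or oppose contrast A (magnitudes kept, so the
  marginal spread is intact); when it is `None`, signs are untouched and the
  planted correlation is preserved exactly — the mode used for correlation
  recovery. Planting the concordance rate and the correlation are therefore
  two modes of the same knob: sign enforcement breaks the bivariate-normal
  dependence and attenuates the measured R below the planted ρ, so each
  statistic is recovered under its own mode. (For orientation: under an
  untouched bivariate normal, the same-sign fraction is
  1/2 + arcsin(ρ)/π ≈ 0.849 at ρ = 0.89, already close to the planted
  default rate of 0.827.)
- **Replicate PSIs and junction counts** are generated by inverting the
  length-normalized PSI ratio at a random depth of 80–300 reads per
  replicate; the printed inclusion levels are recomputed from the integer
  counts, so parsed PSI and count-derived PSI agree within rounding.
  The table's difference column carries the planted ΔPSI.
- **The toy genome** plants, at every exon–intron boundary of every gene
  (event loci and fillers alike), a donor consensus (`GTAAG`) opening each
  intron and a C/T-rich tract ending in an acceptor consensus (`CAG`)
  closing it, with G/C-enriched exonic 25-mers upstream of donors.
  Alternative-site events carry the same structure at both their long and
  short sites. Exons are 60–140 bp, introns 60–140 bp, genes sit on both
  strands with 60–150 bp intergenic gaps; minus-strand genes are built in
  transcript orientation and reverse-complemented into the contig.
- **Expression tables** draw a per-gene pass/fail flag for the DE filter at
  a configured rate (passing genes get q ~ U(0, 0.049) and
  |log2FC| = 0.61 + Exp(0.8); failing genes get q ≥ 0.051), and per-gene
  isoform fractions from independent Dirichlet(2,…) draws per condition, so
  dIF is independent of log2FC by construction (a coupling knob exists for
  sensitivity checks).

Everything derives from one seed via spawned seed sequences (genome, events,
expression), so regeneration is byte-identical.

What the generator does **not** emulate: read-level sampling noise and the
caller's likelihood (FDRs are planted, not estimated), overdispersion and
depth–significance coupling, realistic gene structures (no UTRs, one
transcript per gene, uniform background composition), shared events that are
significant in only one contrast, and genome-scale coordinate sparsity.
Passing recovery tests therefore demonstrate that the *downstream* statistics
are computed correctly on tables with known structure — not that the upstream
caller would produce such tables from reads.

## Problem sizes and numerical choices

Recovery checks run at the study's own scale: correlation recovery at
n = 677 matched pairs over 100 seeds (mean within ±0.02 of the planted
0.89; per-seed sampling sd of r at this n is ≈0.008), concordance recovery
at n = 2000 against the exact binomial 99% interval, consensus recovery from
≥300 pooled windows, and dIF⟂log2FC at n = 500 genes over 100 seeds. The
matching oracle test compares against an O(n·m) brute force on 100 random
tables of up to 200 events. PPM rows are validated to sum to 1 within 1e-9;
log-odds of zero-probability cells are −inf (only reachable with
pseudocount 0).

## Known limitations

- Matching is exact-coordinate only; events shifted by annotation-version
  differences will not match (out of scope by design).
- The "cluster" used for aggregation is the exact-key event; gene-level
  tallies are reported alongside but are not the primary unit.
- The motif stage derives junctions from event coordinates and does not
  re-validate them against an annotation.
- Pearson correlation is used throughout; no rank-based alternative is
  exposed.
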