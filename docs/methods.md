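# Methods

This note documents the models and procedures implemented in
`picoannot`, the parameters that matter, the numerical choices, what the
synthetic-data generator does and does not emulate, and the known
limitations.

## Coordinates and containers

All in-memory coordinates are 0-based half-open intervals. GFF3 on disk
is 1-based closed; BED/bedGraph are 0-based half-open; conversion happens
only at the I/O boundary. A `GeneModel` is one transcript: sorted,
disjoint exons on one chromosome plus a CDS interval whose endpoints lie
inside exons and whose spliced length is a multiple of 3 (enforced at
read/validate time; violations raise errors naming the model). Splice
donor/acceptor dinucleotides are always reported on the transcribed
strand, because donor-usage statistics (GT vs GC vs AT) are
strand-relative. Non-ACGTN genome characters are coerced to N with a
logged warning rather than rejected, which tolerates draft assemblies;
scanning and ORF logic treat N as unmatchable.

## Transfrags, expression and extension

Transcribed segments are maximal runs of per-base, per-strand coverage at
depth ≥ `min_depth` (default 10 reads; the boundary is inclusive).
Segments become one spliced transfrag when a same-strand splice
junction's ends fall inside two segments — attachment tolerance is 0 bp,
since a genuinely supported junction implies covered flanks. Expression
is FPKM = fragments / (exonic kb × million assigned fragments) with an
`expressed` call at a configurable threshold (default 2000); only the
thresholding contract is modeled, not any isoform-deconvolution
likelihood, so the denominator is defined as fragments assigned to
annotated models.

Extension grows a model's terminal exons to the outer edges of
overlapping same-strand transfrags (never trimming, and truncating at a
same-strand neighbor's CDS with a log message), then repositions the ORF:
among all ATG→stop ORFs on the spliced transcript, the longest one
overlapping the original CDS wins, ties going to the most 5′ start.
Requiring overlap with the original CDS prevents a long spurious UTR ORF
from hijacking the frame. Extension runs twice (a transfrag only
reachable after round-1 growth is caught in round 2); a third round is
computed solely to log when a fixed point has not been reached.
Extension never merges models — loci where a spliced transfrag spans two
selected same-strand models, or covers less than half of one, are
emitted as machine-readable merge/break curation flags instead, because
a browser-based manual curation pass cannot be automated faithfully.

## Scoring and selection

The evidence weights are fixed constants of the scheme: intron evidence
+20 (all introns confirmed by an EST intron or junction at exact
coordinates on the same strand) / +5 (some) / −5 (none); +20 per intron
overlapping an Introner Element (counted once per intron regardless of
how many elements overlap it); +1 per peptide, downweighted to
1/n for a peptide mappable to n genomic locations; +10000 for previous
manual annotation; +20 flat if any directional cDNA clone has both mates
overlapping the model; +5 per transcript-supported UTR. Choices the
scheme itself leaves open, resolved here:

* **Single-exon models score 0 intron points.** "All introns confirmed"
  is vacuous for an intronless gene, and −5 would penalize legitimate
  single-exon genes.
* **The cDNA bonus is flat**, not per clone: it is a condition, not a sum.
* **UTR flags are evidence-derived**: a UTR counts only when ≥ 10 nt of
  exon beyond the CDS is covered by a same-strand transfrag or EST. The
  10-nt floor keeps 1–2-nt codon-trimming remnants from counting as UTRs.
* **Peptide points are exact rationals** (`fractions.Fraction`), so
  totals compare exactly and selection is independent of summation order.

Loci are connected components of the any-strand span-overlap graph
(computed by a sweep). Within a locus, two models conflict when (a) they
overlap on the same strand, or (b) their CDS intervals overlap on
opposite strands. Rule (b) is what lets convergent overlapping pairs
(COPs) — tail-to-tail genes sharing only 3′ UTR — be selected together.
Selection maximizes total score over conflict-free subsets exactly, by
depth-first search over independent sets with a
sum-of-positive-remaining bound; only positive-scoring models can enter
an optimum. Ties are broken deterministically by, in order: fewer models
(prefer the least-fragmented representation of a locus), longer summed
spliced CDS, more members with any nonzero evidence, lexicographically
smaller id tuple. A locus whose best combination is empty (every model
≤ 0) selects nothing by default — unsupported models are dropped — with
`allow_empty=False` available to keep the single best-ranked model.

A property worth knowing: under these literal weights, a locus whose
true gene has ≥ 4 introns can score higher as two split fragments,
because each fragment earns its own +20 "all introns confirmed" while
the cDNA and UTR bonuses roughly cancel. Peptides crossing the split and
the fewer-models tie-break mitigate this, and the merge curation flag
reports the remainder; in the closed-loop benchmark it costs ~1–2% of
loci.

## PWM p-values and scanning

Motif scores are log-odds in bits against a 0-order background,
discretized to 1e-3-bit integer bins. The null distribution of the
binned score is computed exactly by convolving the per-column score
distributions under the background; p-values are upper-tail sums and the
scan threshold is the smallest binned score whose tail is ≤ the p-value
cutoff. The discretization is shared between the p-value table and the
scanner, so a reported hit p-value is exactly the tail of its binned
score; the convolution is verified against brute-force enumeration of
all 4^w words at small widths. Both strands are scanned (the minus
strand via the reverse-complemented matrix); windows containing N are
unmatchable. Exhaustive enumeration would be infeasible beyond width
~12; the binned DP is exact at every width up to the stated bin size.

## ZOOPS motif discovery

Discovery uses the zero-or-one-occurrence-per-sequence mixture model:
each sequence contains a motif occurrence with probability γ, uniformly
positioned. EM is seeded from the most over-represented words (5 seeds
per width), with per-site posteriors in the E-step and
pseudocount-smoothed column updates plus a γ re-estimate in the M-step,
run to likelihood convergence (tolerance 1e-5, cap 60 iterations). A
candidate motif is accepted only if ≥ `min_sites` sequences (default 10)
carry a site at posterior > 0.5 **and** the site-built PWM has mean
per-column information ≥ 1 bit — the information floor is what makes
pure-random input return nothing. Accepted sites are masked (set to N)
before the next motif is sought, so co-occurring motifs are recovered as
distinct PWMs. Inputs larger than 600 sequences are subsampled with the
caller's seed; the procedure is otherwise deterministic. Discovery runs
on reading-strand intron sequences only; genome scanning is
double-stranded.

## Introner Element calling

Introns ≤ 500 nt (from gene models, or from multi-exon ESTs whose strand
was inferred from G[TC]/AG and AT/AN splice boundaries; strand-ambiguous
ESTs are discarded) are collapsed to exact-duplicate-free sequence sets
and clustered single-linkage, linking two sequences when global-alignment
identity (match 1, mismatch −1, gap −2) over the longer sequence reaches
80% and the shorter is ≥ 80% of the longer — identity is measured over
the longer sequence because that composes the identity and coverage
criteria into one bound. Scanning hits are concatenated when the
inter-hit gap is ≤ 49 nt (strictly < 50), matching the observed 0–49 nt
inter-motif spacing. A merged candidate is **complete** when it carries
every family motif exactly once in canonical order (on the minus strand,
canonical order is reversed genomic order); **complete_duplicated** when
all motifs are present with a repeat and the canonical order is embedded
as a subsequence; **partial** otherwise; candidates mixing two families
are **mixed**. All-motifs-out-of-order is deliberately partial, not
complete: ordered structure is part of the family definition. Location
classes are exon_overlap (any exon overlap — taking precedence, since
exon-overlapping elements are tabulated separately from intronic ones),
intronic same/opposite strand (full containment in an intron, inheriting
its donor type), else intergenic. Family statistics report counts,
intronic/intergenic/exon splits and GC-donor percentages per
family × completeness, plus IE-containing vs regular-spliceosomal-intron
donor usage. Donor-context position-frequency matrices are built over
the first 12 intron nt from a seeded subsample of ≤ 500 introns per
class (RSI-GT, RSI-GC, IE-GT, IE-GC), with a low-support warning below
10 members.

When discovery (rather than a motif file) drives scanning, each cluster
of ≥ 10 introns contributes up to 6 motifs and the per-cluster motif
sets act as families; motif selection is otherwise explicit user input,
ranked by information content by default.

## Synthetic data

The generator emulates a gene-dense picoeukaryote genome at desk scale.
Defaults (all overridable in `SimulationConfig`): i.i.d. background at
66% GC with an optional planted low-GC block (48% GC) mirroring a low-GC
chromosome region; ~57% of genes spliced with 2 + Poisson(1) exons
(≈3 exons per spliced gene); intron lengths ~Normal(180, 40) truncated
at 62 nt; coding lengths 900–2400 nt (mean ≈ 1650) with 40–150 nt 5′ and
80–250 nt 3′ UTRs, matching the organism-scale averages the pipeline is
meant for; intergenic gaps ≈ 40 + Exp(190) nt; regular splice donors GC
with probability 0.097, GT otherwise, acceptors AG. Introns are placed
inside the CDS (UTR introns are not modeled), and 5′ UTRs are generated
ATG-free so the true CDS is the unique repositioning target. Convergent
overlapping pairs can be planted at a configurable rate with 40–120 nt
3′ UTR overlap.

IE families are planted by overwriting eligible introns in place with
ordered, per-base-mutated motif instances (default divergence 2% per
base) separated by uniform gaps within [0, 49] (capped by the intron's
remaining budget), setting the donor to GC at the family's configured
fraction (0.46 for the four-motif family, 0.07 for the three-motif
family); partial elements drop a random ordered subset of motifs.
Scanning PWMs derived from the family consensus use a match probability
consistent with the planting divergence. Every planted element is
recorded in a ledger (family, interval, strand, completeness, motifs,
location, donor) that the recovery benchmarks compare against.

Evidence is generated noise-free by default (junction confirmation
probability 1, exon coverage 25× vs a 10× transcription floor, Poisson(4)
peptides per gene of 8–20 aa with a 10% multimapping rate, one paired
directional EST clone per gene covering 400 nt from each transcript
end). Peptides are assigned to every pool model whose CDS contains the
peptide's codons contiguously in frame, so frameshifted decoys genuinely
lose them. Decoys per true model: split at a random intron (p 0.5),
merge with the next same-strand neighbor within 600 nt (p 0.2), drop the
3′-terminal exon (p 0.5), shift the CDS frame (p 0.3); all decoys are
re-validated and pool ids are shuffled with a ledger mapping each pool
entry to its origin.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: sequencing error and read-level noise,
repeat families other than planted IEs, alternative splicing, UTR
introns, overlapping same-strand genes, compositional heterogeneity
beyond the single low-GC block, EST chimerism, and peptide
identification error. Detector false-positive behavior is therefore
measured against an i.i.d. background, which is the clean null for the
scanning statistics but optimistic for repeat-rich genomes.

## Problem sizes in the benchmarks

The test suite and `scripts/acceptance.py` run at desk scale, chosen so
the full suite completes in well under a minute of compute per stage:
selection is oracle-checked on 500 random loci of ≤ 12 models; p-values
on 50 PWMs of width ≤ 6 against 4^w enumeration; the closed loop uses
200 genes on 1 Mb with the full decoy spec; IE recovery uses a 1-Mb,
300-gene genome with 130 complete and 50 partial planted elements plus a
1-Mb element-free null; statistics conservation uses 100 random small
fixtures; low-GC detection uses a constructed 2.2-Mb chromosome with a
1.7-Mb 48%-GC block in 63%-GC context.

## Known limitations

* Selection is exact but exponential in the worst case; loci are small
  in practice and the positive-score restriction plus bounding keep the
  search fast, but an adversarial locus of many mutually-overlapping
  high-scoring models would be slow.
* Clustering is all-pairs global alignment (O(n²) alignments) — fine for
  thousands of short introns, not for millions.
* The ZOOPS finder searches a fixed width list rather than optimizing
  width per motif, and reports at most one occurrence per sequence by
  construction.
* FPKM is a thresholding contract only; no fragment assignment model is
  implemented.
* `complete_duplicated` requires the canonical order embedded as a
  subsequence; exotic rearranged duplications classify as partial.
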