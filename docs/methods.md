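# Methods

## Scope and model

`planticlip` implements the computational arm of a plant iCLIP study:
from truncation reads to a control-subtracted target list, with
companion RIP-seq/DEG/splicing integration. Read alignment, isoform
quantification and negative-binomial differential testing are treated
as upstream inputs (SAM or TSV alignments; count/TPM tables; p/q
values), as is conventional for this kind of pipeline: the package's
own contributions are the height-statistic permutation FDR, the
region-resolved bookkeeping around it, the pentamer Z-score, the
set-algebra reports and PSI quantification.

## Coordinate and region conventions

All internal coordinates are 0-based half-open; GFF3 (1-based
inclusive) is converted on read and BED output keeps the 0-based
convention. One representative model is kept per gene: the mRNA with
the longest summed exonic length, ties broken to the lexicographically
smallest transcript id (annotation formats do not generally mark a
canonical isoform, so the rule must be deterministic).

The four analysis regions are 5′ UTR, coding exons, introns, 3′ UTR.
"Exon" means coding sequence — UTR exonic intervals are never
double-counted — and the intron region is every gap between consecutive
exon intervals, *including* introns inside UTR genomic spans: the
partition is by splicing status first. This choice is configurable in
principle (an intron within a 5′ UTR is a genuinely ambiguous case) but
the default keeps regions mutually disjoint and complete over the
transcript span, which the tests assert.

Truncation sites: for a plus-strand read the crosslink is at
`start − 1`; for a minus-strand read at the half-open alignment `end`,
i.e. the base immediately 5′ of the read in transcript orientation.
Reads whose crosslink would fall outside the chromosome are dropped and
counted. A position overlapped by two same-strand genes is credited to
both (a `unique_assignment` flag drops such positions instead);
antisense events are excluded from tracks but tallied.

## The significance procedure

Heights are computed in concatenated region coordinates with a ±15-nt
window truncated at region ends, so windows never leak across genes or
region types but do bridge exon junctions. Observed tail probabilities
are kept as exact rationals (`fractions.Fraction`) — the FDR threshold
is a strict `<`, and exact arithmetic removes boundary flakiness.

Two deliberate interpretations, both surfaced as options:

* **μ_h, σ_h are moments of the background *tail probability* at height
  h**, not of raw counts, making FDR(h) a unit-free ratio of exceedance
  probabilities bounded near the intended 0–1 range. A
  `background_stat="counts"` mode implements the count reading.
* **N vs n_events.** N is the number of distinct occupied positions
  (so Σ n_h = N and P is a proper tail probability); what the
  background redistributes uniformly — with replacement, collisions
  accumulating — is the total event count. Both are carried in
  `HeightDistribution`.

Heights never reached in any background draw get μ = σ = 0 and hence
FDR = 0: a height the background cannot produce is unconditionally
significant. σ is the sample standard deviation across draws (ddof 1).

Reruns vary only the background RNG stream; observed data are fixed.
Defaults are 1000 reruns × 100 draws with a 95 % stability threshold.
The test suite and the acceptance script run 50 reruns × 25 draws — the
calibration and recovery behaviour is already stable at that depth, and
it keeps the suite fast; the defaults remain the full-depth values.

Replicate consensus requires the identical coordinate in all but one
replicate (R − 1 of R; both of 2). Control subtraction consolidates
each control group at a support of 2 replicates by default and removes
any gene owning a control consensus site; per-group thresholds are
configurable, and a single-replicate control group counts any site.

## Motif context

Windows are ±10 nt (21-nt RNA, T→U after strand resolution), clipped at
chromosome ends with a flag so downstream steps can drop clipped
windows. The pentamer Z-score slides a 5-nt frame with step 1;
frames containing N are skipped in both numerator and denominator.
Background windows are re-extracted from the genome at uniformly
simulated crosslink positions in the same genes/regions — not shuffled
observed sequences — through the identical extraction path. Pentamers
with zero background variance but nonzero observed excess are reported
as ±inf sentinels and rank on top. MEME itself is run by the user; the
package emits its observed/background FASTA inputs byte-reproducibly
under a fixed seed.

## Integration thresholds

RIP filter: TPM ≥ 5 (genes below are excluded outright), log₂ fold
change ≥ 0.5 and q < 0.001. The fold-change gate is `>=` by default
with a `strict` mode using `>` (the two published phrasings differ).
DEG filter: q < 0.05 and TPM > 1 in at least one genotype. Percentages
in overlap reports are rounded half away from zero at the requested
precision and are always recomputed from the counts.

The direction-of-regulation comparison uses a two-sided Mann–Whitney U
between each target group's log₂ fold changes and the full DEG
distribution — the comparison is rank-based and makes no distributional
assumption; the choice is recorded in the output. Groups with fewer
than two members are skipped with a flag.

PSI per genotype is the mean over replicates of per-replicate
inclusion-TPM / total-TPM (a pooled-TPM mode exists); replicates with
zero total TPM are dropped, events with no defined replicate in a
genotype are dropped, and single-isoform genes are excluded. The
significance gate is |ΔPSI| > 0.1 and p < 0.01 with p supplied
externally; the built-in fallback is an exhaustive replicate-label
permutation test whose smallest attainable p with 3 + 3 replicates is
1/20 = 0.05 — at that replicate count the p < 0.01 gate can only fire
with externally supplied p-values, which mirrors how such studies use a
dedicated splicing tool's statistics.

## Synthetic data

The generator emulates the study design rather than real sequencing
detail: 5 treatment iCLIP replicates plus two 2-replicate control
groups (free fluorophore, binding-dead variant); planted sites
receiving Poisson(signal_rate · depth) events against a uniform
Poisson background per (gene, region); 30-nt reads starting 1 nt
downstream of each event on the gene strand, emitted either as TSV
alignments (no aligner needed) or as barcoded FASTQ with UMI-tagged,
geometrically-replicated PCR duplicates; negative-binomial expression
tables (default dispersion 0.05, base mean 500, 3 replicates) with
planted log₂ effects; and two-isoform tables with binomial
inclusion counts at depth ~1000, giving per-replicate PSI noise of
about 0.016. Defaults follow the emulated design (replicate numbers,
20 background events per region ≈ 4 events per ±15-nt window, planted
signal about 10× that).

It does **not** model sequencing errors, crosslink-induced
deletions/mutations, fragment-length or positional biases, multimapping
or expression-level confounding of iCLIP sensitivity. Passing tests
therefore demonstrate correctness of the statistics and bookkeeping
under the pipeline's own assumptions, not robustness to those real-data
artefacts.

## Problem sizes and numerical choices

Tests and the acceptance script use desk-scale sizes chosen once:
calibration on 20 seeds with region length 2000 and 200 events at
50 × 25 rerun/draw depth; recovery on 6 genes × 5 replicates; oracle
equivalence on regions ≤ 30 nt with ≤ 6 events against brute-force
enumeration. Background draws use `numpy`'s PCG64 generator; all entry
points accept a `Generator` or integer seed and are bit-reproducible
under it. Degenerate inputs (empty tracks, zero events, empty regions)
return empty results rather than erroring, except where the input is
contradictory (events in a zero-length region).

## Known limitations

* Significance near a planted site spills onto neighbouring occupied
  positions whose ±15-nt windows cover the signal; consensus filtering
  reduces but does not remove this halo. Peak-width estimation is out
  of scope.
* The FDR is the published ratio statistic, not a frequency-calibrated
  false discovery rate; its null behaviour is characterised empirically
  by the calibration tests.
* Control subtraction removes whole genes, as published — a gene with
  one contaminated region loses its sites in all regions.
* Expression-table simulation uses equal library sizes; the TPM step
  normalises lengths but no between-sample normalisation is applied.
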