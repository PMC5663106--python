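"""From raw or aligned iCLIP reads to per-region crosslink tracks.

iCLIP libraries carry, at the 5' end of each read, an experimental
barcode (identifying the sample) interleaved with a random barcode (UMI)
that distinguishes unique cDNA molecules from PCR duplicates. Because
reverse transcription truncates at the crosslinked nucleotide, the base
one nucleotide upstream of the aligned read start (in transcript
orientation) marks the crosslink (XL) site; the rest of the read is
discarded.

The stages here are: demultiplexing + UMI deduplication, length/quality
filtering, truncation-site extraction from alignments (SAM or a TSV
fallback), and tallying of XL events into per-(gene, region) tracks.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

from .annotation_io import RegionPartition

#: (read_id, sequence, quality-string) triple, Phred+33.
FastqRecord = tuple[str, str, str]


@dataclass
class BarcodeLayout:
    """Positions of experimental-barcode and UMI bases at the read 5' end.

    ``experimental_positions`` and ``umi_positions`` are disjoint offsets
    into the read; ``samples`` maps the concatenated experimental-barcode
    string to a sample id. The whole barcode block (through the largest
    offset) is trimmed from retained reads.
    """

    experimental_positions: list[int]
    umi_positions: list[int]
    samples: dict[str, str]

    def __post_init__(self) -> None:
        if set(self.experimental_positions) & set(self.umi_positions):
            raise ValueError("experimental and UMI offsets must be disjoint")
        lengths = {len(b) for b in self.samples}
        if lengths and lengths != {len(self.experimental_positions)}:
            raise ValueError("sample barcodes must match the experimental offsets")

    @property
    def block_length(self) -> int:
        return max(self.experimental_positions + self.umi_positions) + 1

    def split(self, seq: str) -> tuple[str, str, str]:
        """(experimental barcode, UMI, insert) of one read sequence."""
        exp = "".join(seq[i] for i in self.experimental_positions)
        umi = "".join(seq[i] for i in self.umi_positions)
        return exp, umi, seq[self.block_length :]


@dataclass
class AlignedRead:
    read_id: str
    chrom: str
    strand: str
    start: int
    end: int
    unique: bool = True
    mismatches: int = 0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"read {self.read_id}: start must be < end")


@dataclass
class CrosslinkTrack:
    """Crosslink event counts at genomic positions of one (gene, region)."""

    sample_id: str
    gene_id: str
    region: str
    strand: str
    counts: dict[int, int] = field(default_factory=dict)

    @property
    def n_events(self) -> int:
        return sum(self.counts.values())

    @property
    def n_positions(self) -> int:
        return len(self.counts)


@dataclass
class DemuxResult:
    by_sample: dict[str, list[FastqRecord]]
    undetermined: list[FastqRecord]
    rejected: list[FastqRecord]
    duplicates_removed: dict[str, int]

    @property
    def total_routed(self) -> int:
        retained = sum(len(v) for v in self.by_sample.values())
        dups = sum(self.duplicates_removed.values())
        return retained + dups + len(self.undetermined) + len(self.rejected)


def read_fastq(handle) -> Iterator[FastqRecord]:
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    own = isinstance(handle, str)
    fh = open(handle) if own else handle
    try:
        for title, seq, qual in FastqGeneralIterator(fh):
            yield title.split()[0], seq, qual
    finally:
        if own:
            fh.close()


def write_fastq(records: Iterable[FastqRecord], handle) -> None:
    own = isinstance(handle, str)
    fh = open(handle, "w") if own else handle
    try:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
    finally:
        if own:
            fh.close()


def demultiplex_and_dedup(
    records: Iterable[FastqRecord], layout: BarcodeLayout
) -> DemuxResult:
    """Route reads by experimental barcode and collapse PCR duplicates.

    Reads with identical insert sequence *and* identical UMI are PCR
    duplicates; the first encountered representative is kept. Reads
    shorter than the barcode block go to ``rejected``; reads whose
    experimental barcode is not in the sample map go to ``undetermined``.
    Barcodes are trimmed from retained reads.
    """
    result = DemuxResult(
        by_sample={s: [] for s in layout.samples.values()},
        undetermined=[],
        rejected=[],
        duplicates_removed={s: 0 for s in layout.samples.values()},
    )
    seen: dict[str, set[tuple[str, str]]] = {s: set() for s in layout.samples.values()}
    for rid, seq, qual in records:
        if len(seq) < layout.block_length:
            result.rejected.append((rid, seq, qual))
            continue
        exp, umi, insert = layout.split(seq)
        sample = layout.samples.get(exp)
        if sample is None:
            result.undetermined.append((rid, seq, qual))
            continue
        key = (insert, umi)
        if key in seen[sample]:
            result.duplicates_removed[sample] += 1
            continue
        seen[sample].add(key)
        result.by_sample[sample].append((rid, insert, qual[layout.block_length :]))
    return result


def mean_phred(qual: str) -> float:
    return sum(ord(c) - 33 for c in qual) / len(qual)


def quality_filter(
    records: Iterable[FastqRecord],
    min_len: int = 15,
    min_q: float = 20.0,
    mode: str = "mean",
) -> tuple[list[FastqRecord], dict[str, int]]:
    """Drop reads shorter than ``min_len`` or failing the quality gate.

    ``mode='mean'`` requires mean Phred >= ``min_q``; ``mode='min'``
    requires every base to reach it. Returns kept reads and removal
    counters.
    """
    if mode not in ("mean", "min"):
        raise ValueError("mode must be 'mean' or 'min'")
    kept: list[FastqRecord] = []
    counters = {"too_short": 0, "low_quality": 0, "kept": 0}
    for rec in records:
        rid, seq, qual = rec
        if len(seq) != len(qual):
            raise ValueError(f"read {rid}: sequence/quality length mismatch")
        if len(seq) < min_len:
            counters["too_short"] += 1
            continue
        if mode == "mean":
            ok = mean_phred(qual) >= min_q
        else:
            ok = all(ord(c) - 33 >= min_q for c in qual)
        if not ok:
            counters["low_quality"] += 1
            continue
        counters["kept"] += 1
        kept.append(rec)
    return kept, counters


ALIGNMENT_TSV_COLUMNS = ("read_id", "chrom", "strand", "start", "end", "unique", "mismatches")


def read_alignments_tsv(handle) -> list[AlignedRead]:
    """Read the documented TSV alignment fallback (header required)."""
    own = isinstance(handle, str)
    fh = open(handle) if own else handle
    try:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != ALIGNMENT_TSV_COLUMNS:
            raise ValueError(
                f"alignment TSV header must be {ALIGNMENT_TSV_COLUMNS}, got {tuple(header)}"
            )
        reads = []
        for line in fh:
            if not line.strip():
                continue
            rid, chrom, strand, start, end, unique, mm = line.rstrip("\n").split("\t")
            reads.append(
                AlignedRead(
                    read_id=rid,
                    chrom=chrom,
                    strand=strand,
                    start=int(start),
                    end=int(end),
                    unique=unique in ("1", "True", "true"),
                    mismatches=int(mm),
                )
            )
        return reads
    finally:
        if own:
            fh.close()


def write_alignments_tsv(reads: Iterable[AlignedRead], handle) -> None:
    own = isinstance(handle, str)
    fh = open(handle, "w") if own else handle
    try:
        fh.write("\t".join(ALIGNMENT_TSV_COLUMNS) + "\n")
        for r in reads:
            fh.write(
                f"{r.read_id}\t{r.chrom}\t{r.strand}\t{r.start}\t{r.end}\t"
                f"{int(r.unique)}\t{r.mismatches}\n"
            )
    finally:
        if own:
            fh.close()


def read_alignments_sam(path: str) -> list[AlignedRead]:
    """Read alignments from SAM/BAM via pysam; NM tag gives mismatches."""
    import pysam

    reads = []
    with pysam.AlignmentFile(path, "r") as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            mapq_unique = aln.mapping_quality > 0 and not aln.is_secondary
            nm = aln.get_tag("NM") if aln.has_tag("NM") else 0
            reads.append(
                AlignedRead(
                    read_id=aln.query_name,
                    chrom=aln.reference_name,
                    strand="-" if aln.is_reverse else "+",
                    start=aln.reference_start,
                    end=aln.reference_end,
                    unique=mapq_unique,
                    mismatches=int(nm),
                )
            )
    return reads


def extract_truncation_sites(
    reads: Iterable[AlignedRead],
    chrom_lengths: Mapping[str, int] | None = None,
    max_mismatches: int = 3,
) -> tuple[list[tuple[str, str, int]], dict[str, int]]:
    """Crosslink positions: the base 5' of the read start in transcript orientation.

    Plus-strand reads map to ``start - 1``; minus-strand reads to ``end``
    (half-open end, i.e. the genomic base immediately 5' of the read on
    the minus strand). Non-unique reads, reads with too many mismatches,
    and sites falling outside the chromosome are dropped with counters.
    """
    sites: list[tuple[str, str, int]] = []
    counters = {"non_unique": 0, "too_many_mismatches": 0, "out_of_bounds": 0, "kept": 0}
    for r in reads:
        if not r.unique:
            counters["non_unique"] += 1
            continue
        if r.mismatches > max_mismatches:
            counters["too_many_mismatches"] += 1
            continue
        xl = r.start - 1 if r.strand == "+" else r.end
        if xl < 0:
            counters["out_of_bounds"] += 1
            continue
        if chrom_lengths is not None and xl >= chrom_lengths.get(r.chrom, float("inf")):
            counters["out_of_bounds"] += 1
            continue
        counters["kept"] += 1
        sites.append((r.chrom, r.strand, xl))
    return sites, counters


class _RegionIndex:
    """Interval lookup (chrom -> sorted intervals) for region assignment."""

    def __init__(self, partitions: Sequence[RegionPartition]):
        per_chrom: dict[str, list[tuple[int, int, str, str, str]]] = {}
        for part in partitions:
            for region, ivs in part.intervals.items():
                for s, e in ivs:
                    per_chrom.setdefault(part.chrom, []).append(
                        (s, e, part.gene_id, region, part.strand)
                    )
        self._starts: dict[str, list[int]] = {}
        self._items: dict[str, list[tuple[int, int, str, str, str]]] = {}
        for chrom, items in per_chrom.items():
            items.sort()
            self._items[chrom] = items
            self._starts[chrom] = [it[0] for it in items]

    def lookup(self, chrom: str, pos: int) -> list[tuple[str, str, str]]:
        """(gene_id, region, gene_strand) for every interval containing pos."""
        items = self._items.get(chrom)
        if not items:
            return []
        hits = []
        i = bisect_right(self._starts[chrom], pos) - 1
        # intervals are short and non-nested per gene; scan left while overlapping
        while i >= 0:
            s, e, gene, region, strand = items[i]
            if s <= pos < e:
                hits.append((gene, region, strand))
            elif pos - s > 100_000:  # far past any plausible interval
                break
            i -= 1
        return hits


def tally_crosslinks(
    xl_sites: Iterable[tuple[str, str, int]],
    partitions: Sequence[RegionPartition],
    sample_id: str = "sample",
    unique_assignment: bool = False,
) -> tuple[dict[tuple[str, str], CrosslinkTrack], dict[str, int]]:
    """Accumulate XL events into per-(gene, region) tracks.

    Events antisense to the owning gene go to an ``antisense`` counter
    and are excluded from tracks; events matching no region go to
    ``unassigned``. A position overlapped by several same-strand genes
    is credited to each, unless ``unique_assignment`` drops it instead.
    """
    index = _RegionIndex(partitions)
    tracks: dict[tuple[str, str], CrosslinkTrack] = {}
    counters = {"assigned": 0, "antisense": 0, "unassigned": 0, "ambiguous_dropped": 0}
    for chrom, strand, pos in xl_sites:
        hits = index.lookup(chrom, pos)
        sense = [(g, r, st) for g, r, st in hits if st == strand]
        if not hits:
            counters["unassigned"] += 1
            continue
        if not sense:
            counters["antisense"] += 1
            continue
        if unique_assignment and len({g for g, _, _ in sense}) > 1:
            counters["ambiguous_dropped"] += 1
            continue
        counters["assigned"] += 1
        for gene, region, gstrand in sense:
            key = (gene, region)
            track = tracks.get(key)
            if track is None:
                track = CrosslinkTrack(
                    sample_id=sample_id, gene_id=gene, region=region, strand=gstrand
                )
                tracks[key] = track
            track.counts[pos] = track.counts.get(pos, 0) + 1
    return tracks, counters


def write_bedgraph(
    tracks: Mapping[tuple[str, str], CrosslinkTrack],
    chrom_of: Mapping[str, str],
    handle,
) -> None:
    """Per-position crosslink counts as bedGraph lines."""
    own = isinstance(handle, str)
    fh = open(handle, "w") if own else handle
    try:
        for (gene, _region), track in sorted(tracks.items()):
            chrom = chrom_of[gene]
            for pos in sorted(track.counts):
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{track.counts[pos]}\n")
    finally:
        if own:
            fh.close()
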