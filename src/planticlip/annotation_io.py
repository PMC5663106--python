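"""Genome and annotation handling for region-resolved iCLIP analysis.

Crosslink-site significance is assessed separately for each transcript
region because expression (and hence read density) differs between them.
This module selects one representative gene model per gene and partitions
it into four analysis regions:

* ``utr5``  — exonic 5' UTR intervals,
* ``exon``  — the coding sequence (CDS) intervals,
* ``intron`` — every gap between consecutive exons, including introns
  that fall inside a UTR span (the partition is by splicing status first),
* ``utr3``  — exonic 3' UTR intervals.

All internal coordinates are 0-based half-open; GFF3 input (1-based,
inclusive) is converted on read, and BED output keeps the 0-based
convention.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import gffutils

REGIONS = ("utr5", "exon", "intron", "utr3")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class GFFParseError(ValueError):
    """Raised when a GFF3 line cannot be parsed; carries the line number."""


class AnnotationError(ValueError):
    """Raised for referential or structural problems in an annotation."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class Genome:
    """In-memory genome: chromosome id -> DNA string over {A,C,G,T,N}.

    Lookups outside ``[0, len)`` are rejected rather than silently clipped;
    window extraction handles boundary clipping explicitly.
    """

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {c: str(s).upper() for c, s in sequences.items()}
        for chrom, seq in self._seqs.items():
            if len(seq) == 0:
                raise AnnotationError(f"chromosome {chrom!r} has empty sequence")

    @classmethod
    def from_fasta(cls, path_or_handle) -> "Genome":
        from Bio import SeqIO

        records = SeqIO.parse(path_or_handle, "fasta")
        return cls({rec.id: str(rec.seq) for rec in records})

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def chroms(self) -> list[str]:
        return list(self._seqs)

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._seqs:
            raise AnnotationError(f"unknown chromosome {chrom!r}")
        seq = self._seqs[chrom]
        if not (0 <= start <= end <= len(seq)):
            raise AnnotationError(
                f"fetch [{start}, {end}) outside chromosome {chrom!r} "
                f"of length {len(seq)}"
            )
        return seq[start:end]


@dataclass
class TranscriptModel:
    """Representative gene model with genomic interval lists (0-based, half-open)."""

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exon_intervals: list[tuple[int, int]]
    cds_intervals: list[tuple[int, int]] = field(default_factory=list)
    utr5_intervals: list[tuple[int, int]] = field(default_factory=list)
    utr3_intervals: list[tuple[int, int]] = field(default_factory=list)

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exon_intervals)

    @property
    def span(self) -> tuple[int, int]:
        return self.exon_intervals[0][0], self.exon_intervals[-1][1]


@dataclass
class RegionPartition:
    """The four mutually disjoint analysis regions of one gene."""

    gene_id: str
    chrom: str
    strand: str
    intervals: dict[str, list[tuple[int, int]]]

    @property
    def region_length(self) -> dict[str, int]:
        return {r: sum(e - s for s, e in ivs) for r, ivs in self.intervals.items()}

    def contains(self, region: str, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.intervals[region])

    def locate(self, pos: int) -> str | None:
        """Region name containing a genomic position, or None."""
        for region in REGIONS:
            if self.contains(region, pos):
                return region
        return None

    def to_local(self, region: str, pos: int) -> int:
        """Map a genomic position to the concatenated region coordinate."""
        offset = 0
        for s, e in self.intervals[region]:
            if s <= pos < e:
                return offset + (pos - s)
            offset += e - s
        raise ValueError(f"position {pos} not in region {region!r} of {self.gene_id}")

    def to_genomic(self, region: str, local: int) -> int:
        offset = 0
        for s, e in self.intervals[region]:
            if local < offset + (e - s):
                return s + (local - offset)
            offset += e - s
        raise ValueError(f"local {local} beyond region {region!r} of {self.gene_id}")


def _validate_gff_lines(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise GFFParseError(
                f"GFF3 line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
            )
        try:
            start, end = int(fields[3]), int(fields[4])
        except ValueError:
            raise GFFParseError(f"GFF3 line {lineno}: non-integer coordinates") from None
        if start < 1 or end < start:
            raise GFFParseError(f"GFF3 line {lineno}: invalid interval {start}..{end}")
        if fields[6] not in "+-.":
            raise GFFParseError(f"GFF3 line {lineno}: invalid strand {fields[6]!r}")


_UTR5_TYPES = {"five_prime_UTR", "five_prime_utr", "5UTR"}
_UTR3_TYPES = {"three_prime_UTR", "three_prime_utr", "3UTR"}


def _merge_intervals(ivs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def load_transcript_models(gff_source, genome: Genome | None = None) -> list[TranscriptModel]:
    """Parse GFF3 and return one representative model per gene.

    The representative is the mRNA with the longest summed exonic length;
    ties break to the lexicographically smallest transcript id. When a
    genome is supplied, every transcript chromosome must exist in it.
    """
    if hasattr(gff_source, "read"):
        text = gff_source.read()
    else:
        try:
            with open(gff_source) as fh:
                text = fh.read()
        except (OSError, ValueError):
            text = str(gff_source)
    _validate_gff_lines(text)

    db = gffutils.create_db(
        io.StringIO(text).getvalue(),
        dbfn=":memory:",
        from_string=True,
        merge_strategy="create_unique",
        keep_order=True,
    )

    candidates: dict[str, list[TranscriptModel]] = {}
    for mrna in db.features_of_type(("mRNA", "transcript")):
        gene_id = mrna.attributes.get("Parent", [mrna.id])[0]
        if genome is not None and mrna.seqid not in genome:
            raise AnnotationError(
                f"mRNA {mrna.id!r} references unknown chromosome {mrna.seqid!r}"
            )
        exons, cds, u5, u3 = [], [], [], []
        for child in db.children(mrna, order_by="start"):
            iv = (child.start - 1, child.end)  # to 0-based half-open
            if child.featuretype == "exon":
                exons.append(iv)
            elif child.featuretype == "CDS":
                cds.append(iv)
            elif child.featuretype in _UTR5_TYPES:
                u5.append(iv)
            elif child.featuretype in _UTR3_TYPES:
                u3.append(iv)
        if not exons:
            # fall back to the union of annotated pieces
            exons = _merge_intervals(cds + u5 + u3)
        if not exons:
            continue
        model = TranscriptModel(
            gene_id=gene_id,
            transcript_id=mrna.id,
            chrom=mrna.seqid,
            strand=mrna.strand,
            exon_intervals=sorted(exons),
            cds_intervals=sorted(cds),
            utr5_intervals=sorted(u5),
            utr3_intervals=sorted(u3),
        )
        candidates.setdefault(gene_id, []).append(model)

    representatives = []
    for gene_id in sorted(candidates):
        models = candidates[gene_id]
        best = min(models, key=lambda m: (-m.exonic_length, m.transcript_id))
        representatives.append(best)
    return representatives


def partition_regions(model: TranscriptModel) -> RegionPartition:
    """Split a transcript into utr5/exon/intron/utr3 genomic intervals.

    ``exon`` means coding sequence; UTR exonic parts are never
    double-counted. Introns are all gaps between consecutive exon
    intervals, including those inside UTR spans.
    """
    exons = sorted(model.exon_intervals)
    for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
        if s2 < e1:
            raise AnnotationError(
                f"overlapping exon intervals in {model.transcript_id}: "
                f"[{s1},{e1}) and [{s2},{e2})"
            )
    introns = [(e1, s2) for (_, e1), (s2, _) in zip(exons, exons[1:]) if s2 > e1]
    return RegionPartition(
        gene_id=model.gene_id,
        chrom=model.chrom,
        strand=model.strand,
        intervals={
            "utr5": sorted(model.utr5_intervals),
            "exon": sorted(model.cds_intervals),
            "intron": introns,
            "utr3": sorted(model.utr3_intervals),
        },
    )


def extract_window(
    genome: Genome, chrom: str, strand: str, pos: int, flank: int
) -> tuple[str, bool]:
    """RNA window of up to ``2*flank + 1`` nt centred on a genomic position.

    Minus-strand windows are reverse-complemented before the T->U
    substitution. Windows are clipped at chromosome ends; the returned
    flag records whether clipping happened.
    """
    if chrom not in genome:
        raise AnnotationError(f"unknown chromosome {chrom!r}")
    chrom_len = genome.length(chrom)
    if not 0 <= pos < chrom_len:
        raise AnnotationError(f"position {pos} outside chromosome {chrom!r}")
    if flank < 0:
        raise ValueError("flank must be >= 0")
    start = max(0, pos - flank)
    end = min(chrom_len, pos + flank + 1)
    clipped = (end - start) < (2 * flank + 1)
    seq = genome.fetch(chrom, start, end)
    if strand == "-":
        seq = reverse_complement(seq)
    return seq.replace("T", "U"), clipped


def write_partitions_bed(partitions: Iterable[RegionPartition], handle) -> None:
    """BED6 dump of region partitions; name column is ``gene|region``."""
    own = isinstance(handle, str)
    fh = open(handle, "w") if own else handle
    try:
        for part in partitions:
            for region in REGIONS:
                for s, e in part.intervals[region]:
                    fh.write(
                        f"{part.chrom}\t{s}\t{e}\t{part.gene_id}|{region}\t0\t{part.strand}\n"
                    )
    finally:
        if own:
            fh.close()


def read_partitions_bed(handle) -> list[RegionPartition]:
    own = isinstance(handle, str)
    fh = open(handle) if own else handle
    try:
        acc: dict[str, RegionPartition] = {}
        for line in fh:
            if not line.strip():
                continue
            chrom, s, e, name, _, strand = line.rstrip("\n").split("\t")[:6]
            gene_id, region = name.rsplit("|", 1)
            part = acc.get(gene_id)
            if part is None:
                part = RegionPartition(
                    gene_id=gene_id,
                    chrom=chrom,
                    strand=strand,
                    intervals={r: [] for r in REGIONS},
                )
                acc[gene_id] = part
            part.intervals[region].append((int(s), int(e)))
        for part in acc.values():
            for region in REGIONS:
                part.intervals[region].sort()
        return list(acc.values())
    finally:
        if own:
            fh.close()
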