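"""Synthetic inputs with ground truth for desk-scale pipeline testing.

Emulates the statistical structure of a multi-replicate plant iCLIP /
RIP-seq / RNA-seq study: five treatment iCLIP replicates plus two
control genotypes (a free-fluorophore line and an RNA-binding-dead
variant), truncation reads concentrated at planted crosslink sites over
a uniform background, UMI-tagged PCR duplicates, negative-binomial
RIP/RNA-seq count tables with planted enrichment and differential
expression, and two-isoform TPM tables with planted delta-PSI shifts.

Every generator is fully deterministic under a fixed seed, and every
output round-trips through the package's own readers, so all pipeline
stages are testable end-to-end with no external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from .annotation_io import (
    Genome,
    RegionPartition,
    TranscriptModel,
    load_transcript_models,
    partition_regions,
    reverse_complement,
)
from .iclip_preprocess import AlignedRead, FastqRecord

READ_LENGTH = 30  # fixed simulated read length, nt


@dataclass
class GenePlan:
    """Structural plan of one synthetic gene (lengths in nt)."""

    utr5_len: int = 100
    cds_exon_lens: tuple[int, ...] = (200, 150, 250)
    intron_lens: tuple[int, ...] = (80, 120)
    utr3_len: int = 150

    def __post_init__(self) -> None:
        if len(self.intron_lens) != len(self.cds_exon_lens) - 1:
            raise ValueError("need one intron fewer than CDS exons")
        if min((self.utr5_len, self.utr3_len) + self.cds_exon_lens
               + (self.intron_lens or (1,))) <= 0:
            raise ValueError("all lengths must be > 0")

    @property
    def genomic_span(self) -> int:
        return (self.utr5_len + self.utr3_len + sum(self.cds_exon_lens)
                + sum(self.intron_lens))


@dataclass
class SyntheticTruth:
    """Planted ground truth for recovery testing."""

    planted_sites: list[dict] = field(default_factory=list)
    planted_motif: str = ""
    motif_offset: int = 0
    control_contaminated_genes: list[str] = field(default_factory=list)
    rip_enriched_genes: dict[str, float] = field(default_factory=dict)
    deg_genes: dict[str, float] = field(default_factory=dict)
    dpsi_events: dict[str, float] = field(default_factory=dict)

    def to_json(self, handle) -> None:
        own = isinstance(handle, str)
        fh = open(handle, "w") if own else handle
        try:
            json.dump(asdict(self), fh, indent=1)
        finally:
            if own:
                fh.close()

    @classmethod
    def from_json(cls, handle) -> "SyntheticTruth":
        own = isinstance(handle, str)
        fh = open(handle) if own else handle
        try:
            return cls(**json.load(fh))
        finally:
            if own:
                fh.close()


@dataclass
class SyntheticAnnotation:
    genome: Genome
    gff3: str
    models: list[TranscriptModel]
    partitions: dict[str, RegionPartition]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.genome.length(c) for c in self.genome.chroms()}


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def make_genome_and_annotation(
    n_genes: int = 10,
    plan: GenePlan | Sequence[GenePlan] | None = None,
    gc: float = 0.36,
    seed: int | np.random.Generator = 0,
    spacer: int = 200,
    chrom: str = "chr1",
) -> SyntheticAnnotation:
    """Random genome and matching GFF3 with one gene model per gene.

    Genes are laid out sequentially on one chromosome with ``spacer`` nt
    between them, alternating strands. Each gene has contiguous
    5'UTR + first CDS exon, internal CDS exons separated by introns, and
    last CDS exon + 3'UTR (on the minus strand the layout mirrors). The
    GFF3 round-trips through :func:`load_transcript_models`.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    plans: list[GenePlan]
    if plan is None:
        plans = [GenePlan() for _ in range(n_genes)]
    elif isinstance(plan, GenePlan):
        plans = [plan] * n_genes
    else:
        plans = list(plan)
        if len(plans) != n_genes:
            raise ValueError("need one plan per gene")

    total = spacer + sum(p.genomic_span + spacer for p in plans)
    seq = _random_dna(rng, total, gc)
    gff_lines = ["##gff-version 3"]
    cursor = spacer
    for i, gp in enumerate(plans):
        gene_id = f"G{i + 1:03d}"
        tid = f"{gene_id}.1"
        strand = "+" if i % 2 == 0 else "-"
        start = cursor
        # build 0-based half-open pieces in genomic order (5'->3' on plus)
        pieces: list[tuple[str, int, int]] = []
        pos = start
        utr_first = gp.utr5_len if strand == "+" else gp.utr3_len
        utr_last = gp.utr3_len if strand == "+" else gp.utr5_len
        cds_order = gp.cds_exon_lens if strand == "+" else gp.cds_exon_lens[::-1]
        intron_order = gp.intron_lens if strand == "+" else gp.intron_lens[::-1]
        pieces.append(("utr_first", pos, pos + utr_first))
        pos += utr_first
        for j, cds_len in enumerate(cds_order):
            pieces.append(("cds", pos, pos + cds_len))
            pos += cds_len
            if j < len(intron_order):
                pieces.append(("intron", pos, pos + intron_order[j]))
                pos += intron_order[j]
        pieces.append(("utr_last", pos, pos + utr_last))
        pos += utr_last
        end = pos
        cursor = end + spacer

        def feat(ftype: str, s: int, e: int, parent: str) -> str:
            return (f"{chrom}\tsynthetic\t{ftype}\t{s + 1}\t{e}\t.\t{strand}\t.\t"
                    f"ID={ftype}:{parent}:{s};Parent={parent}")

        gff_lines.append(
            f"{chrom}\tsynthetic\tgene\t{start + 1}\t{end}\t.\t{strand}\t.\tID={gene_id}"
        )
        gff_lines.append(
            f"{chrom}\tsynthetic\tmRNA\t{start + 1}\t{end}\t.\t{strand}\t.\t"
            f"ID={tid};Parent={gene_id}"
        )
        # exon features: merge UTRs with their flanking CDS exon
        exonic: list[tuple[int, int]] = []
        for kind, s, e in pieces:
            if kind == "intron":
                continue
            if exonic and exonic[-1][1] == s:
                exonic[-1] = (exonic[-1][0], e)
            else:
                exonic.append((s, e))
        for s, e in exonic:
            gff_lines.append(feat("exon", s, e, tid))
        for kind, s, e in pieces:
            if kind == "cds":
                gff_lines.append(feat("CDS", s, e, tid))
            elif kind == "utr_first":
                ftype = "five_prime_UTR" if strand == "+" else "three_prime_UTR"
                gff_lines.append(feat(ftype, s, e, tid))
            elif kind == "utr_last":
                ftype = "three_prime_UTR" if strand == "+" else "five_prime_UTR"
                gff_lines.append(feat(ftype, s, e, tid))

    genome = Genome({chrom: seq})
    gff3 = "\n".join(gff_lines) + "\n"
    models = load_transcript_models(gff3, genome)
    partitions = {m.gene_id: partition_regions(m) for m in models}
    return SyntheticAnnotation(genome=genome, gff3=gff3, models=models,
                               partitions=partitions)


def plant_sites(
    ann: SyntheticAnnotation,
    rng: np.random.Generator,
    genes: Sequence[str] | None = None,
    region: str = "utr3",
    sites_per_gene: int = 1,
    signal_rate: float = 10.0,
    motif: str = "",
    motif_offset: int = 0,
) -> list[dict]:
    """Choose planted crosslink positions (genomic) in the given region.

    Positions keep at least READ_LENGTH nt of downstream room so the
    truncation read fits inside the chromosome. If ``motif`` is given it
    is written into the genome starting ``motif_offset`` nt 3' of each
    site (on the gene strand).
    """
    genes = [m.gene_id for m in ann.models] if genes is None else list(genes)
    planted = []
    for gene in genes:
        part = ann.partitions[gene]
        L = part.region_length[region]
        if L == 0:
            continue
        locals_ = rng.choice(L, size=min(sites_per_gene, L), replace=False)
        for loc in np.sort(locals_):
            pos = part.to_genomic(region, int(loc))
            planted.append(dict(gene=gene, region=region, position=int(pos),
                                signal_rate=float(signal_rate)))
    if motif:
        chrom = ann.models[0].chrom
        seq = list(ann.genome._seqs[chrom])
        dna = motif.replace("U", "T")
        for site in planted:
            part = ann.partitions[site["gene"]]
            if part.strand == "+":
                start = site["position"] + motif_offset
                ins = dna
            else:
                ins = reverse_complement(dna)
                start = site["position"] - motif_offset - len(dna) + 1
            if 0 <= start and start + len(dna) <= len(seq):
                seq[start : start + len(dna)] = list(ins)
        ann.genome._seqs[chrom] = "".join(seq)
    return planted


def _events_to_reads(
    events: Sequence[tuple[str, str, int]],
    chrom_lengths: Mapping[str, int],
    replicate: str,
    read_len: int = READ_LENGTH,
) -> list[AlignedRead]:
    """Truncation reads starting 1 nt downstream (in transcript
    orientation) of each crosslink event."""
    reads = []
    for i, (chrom, strand, xl) in enumerate(events):
        if strand == "+":
            start = xl + 1
            end = min(start + read_len, chrom_lengths[chrom])
        else:
            end = xl
            start = max(end - read_len, 0)
        if end - start < 1:
            continue
        reads.append(
            AlignedRead(read_id=f"{replicate}:{i}", chrom=chrom, strand=strand,
                        start=start, end=end, unique=True, mismatches=0)
        )
    return reads


def simulate_iclip_reads(
    ann: SyntheticAnnotation,
    planted: Sequence[Mapping],
    n_replicates: int = 5,
    depth: float = 1.0,
    background_events_per_region: float = 20.0,
    control_groups: Mapping[str, int] | None = None,
    control_contaminated: Sequence[Mapping] = (),
    seed: int | np.random.Generator = 0,
    regions: Sequence[str] = ("utr5", "exon", "intron", "utr3"),
) -> tuple[dict[str, list[AlignedRead]], SyntheticTruth]:
    """Per-replicate truncation-read alignments with planted signal.

    Per replicate, each planted site receives Poisson(signal_rate *
    depth) events and every (gene, region) receives a uniform background
    of Poisson(background_events_per_region * depth) events spread over
    its positions. Control replicates (default two groups of two,
    emulating a free-fluorophore and a binding-dead line) carry
    background only, plus the ``control_contaminated`` sites. Returns
    ``{replicate_name: [AlignedRead, ...]}`` and the truth.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if control_groups is None:
        control_groups = {"gfp": 2, "rq": 2}
    chrom_lengths = ann.chrom_lengths

    def one_replicate(name: str, sites: Sequence[Mapping]) -> list[AlignedRead]:
        events: list[tuple[str, str, int]] = []
        for site in sites:
            part = ann.partitions[site["gene"]]
            n = rng.poisson(site["signal_rate"] * depth)
            events.extend([(part.chrom, part.strand, site["position"])] * int(n))
        for gene, part in ann.partitions.items():
            for region in regions:
                L = part.region_length[region]
                if L == 0:
                    continue
                n_bg = rng.poisson(background_events_per_region * depth)
                for loc in rng.integers(0, L, size=int(n_bg)):
                    pos = part.to_genomic(region, int(loc))
                    events.append((part.chrom, part.strand, pos))
        return _events_to_reads(events, chrom_lengths, name)

    reads: dict[str, list[AlignedRead]] = {}
    for r in range(1, n_replicates + 1):
        reads[f"treat_rep{r}"] = one_replicate(f"treat_rep{r}", planted)
    for group, n_reps in control_groups.items():
        for r in range(1, n_reps + 1):
            reads[f"{group}_rep{r}"] = one_replicate(
                f"{group}_rep{r}", control_contaminated
            )

    truth = SyntheticTruth(
        planted_sites=[dict(s) for s in planted],
        control_contaminated_genes=sorted({s["gene"] for s in control_contaminated}),
    )
    return reads, truth


def simulate_fastq(
    ann: SyntheticAnnotation,
    reads: Mapping[str, list[AlignedRead]],
    layout,
    sample_of_replicate: Mapping[str, str],
    pcr_dup_rate: float = 0.3,
    umi_len: int | None = None,
    seed: int | np.random.Generator = 0,
) -> list[FastqRecord]:
    """Barcoded FASTQ records (with PCR duplicates) from simulated alignments.

    Each molecule gets the experimental barcode of its sample and a
    random UMI; a geometric number of PCR copies (success probability
    ``1 - pcr_dup_rate``) duplicates the full read including the UMI.
    Sequences are taken from the genome, reverse-complemented for
    minus-strand reads, with the 1-nt truncation offset already encoded
    in the alignment coordinates.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    inv_samples = {v: k for k, v in layout.samples.items()}
    if umi_len is None:
        umi_len = len(layout.umi_positions)
    records: list[FastqRecord] = []
    bases = np.array(list("ACGT"))
    for rep, alns in sorted(reads.items()):
        sample = sample_of_replicate.get(rep)
        if sample is None:
            continue
        barcode = inv_samples[sample]
        for aln in alns:
            insert = ann.genome.fetch(aln.chrom, aln.start, aln.end)
            if aln.strand == "-":
                insert = reverse_complement(insert)
            umi = "".join(bases[rng.integers(0, 4, size=umi_len)])
            block = [""] * layout.block_length
            for i, off in enumerate(layout.experimental_positions):
                block[off] = barcode[i]
            for i, off in enumerate(layout.umi_positions):
                block[off] = umi[i]
            seq = "".join(block) + insert
            qual = "I" * len(seq)
            n_copies = rng.geometric(1.0 - pcr_dup_rate) if pcr_dup_rate > 0 else 1
            for c in range(int(n_copies)):
                records.append((f"{aln.read_id}:c{c}", seq, qual))
    order = rng.permutation(len(records))
    return [records[i] for i in order]


def simulate_expression_tables(
    genes: Sequence[str],
    n_replicates: int = 3,
    dispersion: float = 0.05,
    base_mean: float = 500.0,
    rip_enriched: Mapping[str, float] | None = None,
    deg_effects: Mapping[str, float] | None = None,
    dpsi_effects: Mapping[str, float] | None = None,
    isoform_depth: float = 1000.0,
    base_psi: float = 0.4,
    seed: int | np.random.Generator = 0,
):
    """Negative-binomial count tables and isoform TPMs with planted effects.

    Returns a dict with RIP counts, poly(A)-RNA counts, per-genotype
    RNA-seq counts (wt and a perturbed genotype), gene lengths, a
    two-isoform TPM table per genotype/replicate, event definitions, and
    the updated truth fields. ``rip_enriched`` / ``deg_effects`` map
    gene -> log2 effect; ``dpsi_effects`` map gene -> delta PSI of the
    inclusion isoform in the perturbed genotype.
    """
    import pandas as pd

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rip_enriched = dict(rip_enriched or {})
    deg_effects = dict(deg_effects or {})
    dpsi_effects = dict(dpsi_effects or {})
    genes = list(genes)

    def nb(mean: np.ndarray) -> np.ndarray:
        mean = np.maximum(mean, 1e-9)
        if dispersion <= 0:
            return rng.poisson(mean)
        n = 1.0 / dispersion
        p = n / (n + mean)
        return rng.negative_binomial(n, p)

    base = rng.lognormal(np.log(base_mean), 0.4, size=len(genes))
    lengths = pd.Series(rng.integers(500, 3000, size=len(genes)), index=genes,
                        name="length")

    def table(prefix: str, mean_vec: np.ndarray) -> pd.DataFrame:
        cols = {}
        for r in range(1, n_replicates + 1):
            cols[f"{prefix}{r}"] = nb(mean_vec)
        return pd.DataFrame(cols, index=genes)

    rip_mult = np.array([2.0 ** rip_enriched.get(g, 0.0) for g in genes])
    deg_mult = np.array([2.0 ** deg_effects.get(g, 0.0) for g in genes])
    tables = {
        "rip_counts": table("rip_", base * rip_mult),
        "polyA_counts": table("polyA_", base),
        "rnaseq_wt_counts": table("wt_", base),
        "rnaseq_mut_counts": table("mut_", base * deg_mult),
        "gene_lengths": lengths,
    }

    # two-isoform TPM table: inclusion isoform at base_psi in wt,
    # base_psi + dPSI in the perturbed genotype
    iso_rows = []
    events = []
    for g in genes:
        events.append(dict(event_id=f"ev_{g}", gene_id=g,
                           inclusion_isoforms=[f"{g}.i1"],
                           all_isoforms=[f"{g}.i1", f"{g}.i2"]))
    iso_index = [iso for g in genes for iso in (f"{g}.i1", f"{g}.i2")]
    data = {}
    for genotype in ("wt", "mut"):
        for r in range(1, n_replicates + 1):
            col = []
            for g in genes:
                psi = base_psi + (dpsi_effects.get(g, 0.0) if genotype == "mut" else 0.0)
                psi = min(max(psi, 0.0), 1.0)
                total = rng.poisson(isoform_depth)
                incl = rng.binomial(total, psi) if total > 0 else 0
                col.extend([float(incl), float(total - incl)])
            data[f"{genotype}_{r}"] = col
    tables["isoform_tpm"] = pd.DataFrame(data, index=iso_index)
    tables["events"] = events

    truth_fields = dict(
        rip_enriched_genes=rip_enriched,
        deg_genes=deg_effects,
        dpsi_events={f"ev_{g}": d for g, d in dpsi_effects.items()},
    )
    return tables, truth_fields
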