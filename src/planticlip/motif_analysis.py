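"""Sequence context around consensus crosslink sites.

Two complementary analyses of the binding landscape around crosslink
sites: preparation of observed/background FASTA inputs for de novo
motif discovery (MEME is run by the user), and a pentamer Z-score
enrichment statistic. Both extend each site by ``flank`` (default 10)
nucleotides on either side, giving 21-nt RNA windows, and compare
against windows drawn at uniformly simulated crosslink positions in the
same regions — re-extracted from the genome, not shuffled observed
sequences. Crosslinks antisense to the owning gene are removed first.

For the Z-score, a 5-nt frame slides with step 1 over every window;
pentamer frequencies are frame counts over total frames (frames
containing N are skipped in numerator and denominator), and

    Z(P) = (f_exp(P) - mu_f(P)) / sigma_f(P)

with mu_f/sigma_f the mean and standard deviation of the pentamer's
frequency over ``n_background`` independent background draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_io import Genome, RegionPartition, extract_window

DEFAULT_FLANK = 10
K = 5  # pentamers


@dataclass
class Window:
    seq: str
    gene_id: str
    position: int
    clipped: bool = False


@dataclass
class WindowSet:
    region: str
    windows: list[Window] = field(default_factory=list)

    def sequences(self) -> list[str]:
        return [w.seq for w in self.windows]

    def __len__(self) -> int:
        return len(self.windows)


def collect_windows(
    consensus_sites: Mapping[tuple[str, str], set[int]],
    genome: Genome,
    partitions: Mapping[str, RegionPartition],
    flank: int = DEFAULT_FLANK,
    drop_antisense: bool = True,
) -> dict[str, WindowSet]:
    """Extract strand-aware RNA windows around consensus sites, per region.

    ``consensus_sites`` maps (gene_id, region) to genomic positions.
    Antisense events are expected to have been excluded during tallying;
    with ``drop_antisense`` any site on a gene whose partition does not
    contain it sense-wise is skipped defensively.
    """
    out: dict[str, WindowSet] = {}
    for (gene, region), positions in sorted(consensus_sites.items()):
        part = partitions[gene]
        ws = out.setdefault(region, WindowSet(region=region))
        for pos in sorted(positions):
            if drop_antisense and part.locate(pos) is None:
                continue
            seq, clipped = extract_window(genome, part.chrom, part.strand, pos, flank)
            ws.windows.append(Window(seq=seq, gene_id=gene, position=pos, clipped=clipped))
    return {r: ws for r, ws in out.items() if len(ws)}


def count_pentamer_frames(sequences: Sequence[str]) -> tuple[dict[str, int], int]:
    """Sliding 5-nt frame counts over all windows; N-containing frames skipped."""
    counts: dict[str, int] = {}
    total = 0
    for seq in sequences:
        seq = seq.upper()
        for i in range(len(seq) - K + 1):
            frame = seq[i : i + K]
            if "N" in frame:
                continue
            counts[frame] = counts.get(frame, 0) + 1
            total += 1
    return counts, total


def pentamer_frequencies(sequences: Sequence[str]) -> dict[str, float]:
    counts, total = count_pentamer_frames(sequences)
    if total == 0:
        return {}
    return {p: c / total for p, c in counts.items()}


def uniform_window_sampler(
    genome: Genome,
    partitions: Mapping[str, RegionPartition],
    region: str,
    genes: Sequence[str],
    flank: int = DEFAULT_FLANK,
) -> Callable[[np.random.Generator, int], list[str]]:
    """Sampler of windows at uniform crosslink positions within a region.

    Positions are drawn uniformly over the concatenated region
    coordinates of the given genes (those where significant sites were
    identified), then windows are extracted through the same path as
    observed sites (strand-aware, T->U, clipping).
    """
    pool: list[tuple[str, int]] = []  # (gene, local position)
    for gene in genes:
        L = partitions[gene].region_length.get(region, 0)
        pool.extend((gene, i) for i in range(L))
    if not pool:
        raise ValueError(f"no positions available in region {region!r}")

    def sample(rng: np.random.Generator, n: int) -> list[str]:
        idx = rng.integers(0, len(pool), size=n)
        seqs = []
        for i in idx:
            gene, local = pool[i]
            part = partitions[gene]
            pos = part.to_genomic(region, local)
            seq, _ = extract_window(genome, part.chrom, part.strand, pos, flank)
            seqs.append(seq)
        return seqs

    return sample


def pentamer_zscores(
    observed_windows: Sequence[str],
    background_sampler: Callable[[np.random.Generator, int], list[str]] | None = None,
    background_draws: Sequence[Sequence[str]] | None = None,
    n_background: int = 100,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Pentamer enrichment Z-scores against a uniform background.

    Either pass ``background_sampler`` (called ``n_background`` times
    with the observed window count) or precomputed ``background_draws``
    (a list of window lists, one per draw). Pentamers with zero
    background variance get a +/-inf sentinel Z (flagged in the
    ``zero_variance`` column); downstream ranking treats +inf as top.
    Returns a DataFrame sorted by Z descending with columns
    pentamer, f_exp, mu_f, sigma_f, z, zero_variance.
    """
    if not observed_windows or all(len(w) < K for w in observed_windows):
        raise ValueError("need at least one window of length >= 5")
    f_exp = pentamer_frequencies(observed_windows)
    if background_draws is None:
        if background_sampler is None:
            raise ValueError("provide background_sampler or background_draws")
        rng = np.random.default_rng() if rng is None else rng
        background_draws = [
            background_sampler(rng, len(observed_windows)) for _ in range(n_background)
        ]
    draw_freqs = [pentamer_frequencies(d) for d in background_draws]

    pentamers = sorted(set(f_exp) | {p for d in draw_freqs for p in d})
    rows = []
    n_draws = len(draw_freqs)
    for p in pentamers:
        obs = f_exp.get(p, 0.0)
        vals = np.array([d.get(p, 0.0) for d in draw_freqs])
        mu = float(vals.mean()) if n_draws else 0.0
        sigma = float(vals.std(ddof=1)) if n_draws > 1 else 0.0
        if sigma > 0:
            z = (obs - mu) / sigma
            zero_var = False
        else:
            z = 0.0 if obs == mu else math.copysign(math.inf, obs - mu)
            zero_var = True
        rows.append(dict(pentamer=p, f_exp=obs, mu_f=mu, sigma_f=sigma, z=z,
                         zero_variance=zero_var))
    df = pd.DataFrame(rows, columns=["pentamer", "f_exp", "mu_f", "sigma_f", "z",
                                     "zero_variance"])
    return df.sort_values("z", ascending=False, kind="mergesort").reset_index(drop=True)


def write_meme_inputs(
    window_sets: Mapping[str, WindowSet],
    genome: Genome,
    partitions: Mapping[str, RegionPartition],
    observed_path,
    background_path,
    rng: np.random.Generator | None = None,
    flank: int = DEFAULT_FLANK,
) -> dict[str, int]:
    """Observed and simulated-background FASTA files for motif discovery.

    The background holds exactly as many records per region as the
    observed set, drawn uniformly in the same genes/regions and
    extracted through the same path (including T->U). Record ids are
    ``gene|region|pos`` (background ids carry a ``bg`` prefix).
    Returns per-region record counts; empty regions are omitted.
    """
    rng = np.random.default_rng() if rng is None else rng
    counts: dict[str, int] = {}
    with open(observed_path, "w") as obs_fh, open(background_path, "w") as bg_fh:
        for region in sorted(window_sets):
            ws = window_sets[region]
            if not len(ws):
                continue
            genes = sorted({w.gene_id for w in ws.windows})
            for w in ws.windows:
                obs_fh.write(f">{w.gene_id}|{region}|{w.position}\n{w.seq}\n")
            sampler = uniform_window_sampler(genome, partitions, region, genes, flank)
            for i, seq in enumerate(sampler(rng, len(ws))):
                bg_fh.write(f">bg|{region}|{i}\n{seq}\n")
            counts[region] = len(ws)
    return counts
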