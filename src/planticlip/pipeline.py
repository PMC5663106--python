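"""End-to-end target discovery from per-replicate alignments.

Convenience wiring of the per-module steps: truncation-site extraction,
per-(gene, region) tallying, permutation-FDR calling per replicate,
replicate consensus, and control subtraction. Each replicate is called
independently; counts are never merged across replicates before
calling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .iclip_preprocess import AlignedRead, extract_truncation_sites, tally_crosslinks
from .xl_caller import (
    CrosslinkSiteModel,
    consensus_by_gene,
    subtract_controls,
)
from .synthetic_data import SyntheticAnnotation


def call_replicate_sites(
    reads: Sequence[AlignedRead],
    ann: SyntheticAnnotation,
    rng: np.random.Generator,
    alpha: float = 0.05,
    n_draws: int = 100,
    n_reruns: int = 1000,
    stability: float = 0.95,
    flank: int = 15,
) -> dict[tuple[str, str], set[int]]:
    """Stable significant genomic positions per (gene, region) for one replicate."""
    sites, _ = extract_truncation_sites(reads, ann.chrom_lengths)
    tracks, _ = tally_crosslinks(sites, list(ann.partitions.values()))
    out: dict[tuple[str, str], set[int]] = {}
    for (gene, region), track in sorted(tracks.items()):
        res = CrosslinkSiteModel(track, ann.partitions[gene], flank=flank).fit(
            alpha=alpha, n_draws=n_draws, n_reruns=n_reruns,
            stability=stability, rng=rng,
        )
        positions = res.site_set().positions
        if positions:
            out[(gene, region)] = positions
    return out


@dataclass
class TargetDiscovery:
    """Outcome of consensus calling and control subtraction."""

    treatment_consensus: dict[tuple[str, str], set[int]]
    target_genes: set[str]
    target_sites: dict[tuple[str, str], set[int]] = field(default_factory=dict)


def iclip_target_discovery(
    reads_by_replicate: Mapping[str, Sequence[AlignedRead]],
    ann: SyntheticAnnotation,
    treatment_prefix: str = "treat",
    control_prefixes: Sequence[str] = ("gfp", "rq"),
    rng: np.random.Generator | None = None,
    control_min_support: int = 2,
    **fit_kwargs,
) -> TargetDiscovery:
    """Run the full caller on treatment and control groups and subtract.

    Replicates are grouped by name prefix (``<prefix>_repN``). Treatment
    consensus requires all-but-one replicates; each control group is
    consolidated at ``control_min_support`` and any gene with a control
    consensus site is removed.
    """
    rng = np.random.default_rng() if rng is None else rng
    per_rep = {
        name: call_replicate_sites(reads, ann, rng, **fit_kwargs)
        for name, reads in sorted(reads_by_replicate.items())
    }
    treatment = [s for name, s in per_rep.items()
                 if name.startswith(treatment_prefix)]
    consensus = consensus_by_gene(treatment)
    control_groups = [
        [s for name, s in per_rep.items() if name.startswith(prefix)]
        for prefix in control_prefixes
    ]
    control_groups = [g for g in control_groups if g]
    genes, sites = subtract_controls(consensus, control_groups,
                                     control_min_support=control_min_support)
    return TargetDiscovery(treatment_consensus=consensus,
                           target_genes=genes, target_sites=sites)
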