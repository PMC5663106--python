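"""Permutation-FDR significance calling of iCLIP crosslink sites.

The test statistic for a crosslink (XL) position x is its *height*
h(x): the sum of crosslink event counts within ``flank`` nucleotides of
x in concatenated region coordinates. Within one transcript region, the
observed heights define a distribution {n_1, ..., n_H} over the N
occupied positions, with exact tail probability

    P(h) = sum_{i >= h} n_i / N.

To discriminate signal from random accumulation, the same number of
events is redistributed uniformly over the region ``n_draws`` times
(with replacement, so collisions accumulate counts); mu_h and sigma_h
are the mean and standard deviation over draws of the random tail
probability at height h, and

    FDR(h) = (mu_h + sigma_h) / P(h).

A position is significant when FDR at its height falls below ``alpha``
(strictly). Because the background is stochastic, the whole procedure
is repeated ``n_reruns`` times with fresh backgrounds; positions
significant in at least a ``stability`` fraction of reruns are
retained. Downstream, positions must recur at the identical coordinate
in all but one replicate, and genes with consensus sites in control
libraries are removed.

``CrosslinkSiteModel`` / ``CrosslinkSiteResults`` wrap the procedure in
a fit/results pair; the underlying operations are also exposed as plain
functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_io import RegionPartition
from .iclip_preprocess import CrosslinkTrack

DEFAULT_FLANK = 15
DEFAULT_ALPHA = 0.05
DEFAULT_N_DRAWS = 100
DEFAULT_N_RERUNS = 1000
DEFAULT_STABILITY = 0.95


@dataclass
class HeightDistribution:
    """Observed height statistic of one region.

    ``heights`` maps each occupied position (local, concatenated region
    coordinate) to its height; ``n_h[h]`` counts occupied positions with
    height h. N is the number of occupied positions, ``n_events`` the
    total event count (what the background redistributes).
    """

    region_length: int
    heights: dict[int, int]
    n_h: dict[int, int]
    n_events: int

    @property
    def N(self) -> int:
        return len(self.heights)

    @property
    def H(self) -> int:
        return max(self.heights.values(), default=0)


def localize_track(
    track: CrosslinkTrack, partition: RegionPartition
) -> tuple[dict[int, int], int]:
    """Convert genomic track positions to concatenated region coordinates."""
    region_len = partition.region_length[track.region]
    local = {
        partition.to_local(track.region, pos): c for pos, c in track.counts.items()
    }
    return local, region_len


def _window_heights(counts: np.ndarray, flank: int) -> np.ndarray:
    """Sliding-window sum of counts with window +-flank, truncated at ends.

    Works on a 1-D count vector or a (draws, L) matrix row-wise.
    """
    counts = np.atleast_2d(counts)
    n, L = counts.shape
    csum = np.concatenate([np.zeros((n, 1), dtype=counts.dtype),
                           np.cumsum(counts, axis=1)], axis=1)
    idx = np.arange(L)
    lo = np.maximum(idx - flank, 0)
    hi = np.minimum(idx + flank + 1, L)
    out = csum[:, hi] - csum[:, lo]
    return out[0] if n == 1 and out.shape[0] == 1 else out


def compute_heights(
    counts: Mapping[int, int], region_length: int, flank: int = DEFAULT_FLANK
) -> HeightDistribution:
    """Height h(x) for every occupied position of one region.

    ``counts`` maps local (concatenated) positions to event counts.
    Windows are truncated at region ends and never leak across regions.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    if not counts:
        return HeightDistribution(region_length, {}, {}, 0)
    dense = np.zeros(region_length, dtype=np.int64)
    for pos, c in counts.items():
        if not 0 <= pos < region_length:
            raise ValueError(f"position {pos} outside region of length {region_length}")
        if c < 1:
            raise ValueError("stored positions must have count >= 1")
        dense[pos] = c
    win = _window_heights(dense, flank)
    heights = {pos: int(win[pos]) for pos in counts}
    n_h: dict[int, int] = {}
    for h in heights.values():
        n_h[h] = n_h.get(h, 0) + 1
    return HeightDistribution(region_length, heights, n_h, int(dense.sum()))


def tail_probability(dist: HeightDistribution) -> dict[int, Fraction]:
    """Exact tail probabilities P(h) = sum_{i>=h} n_i / N for h = 1..H."""
    if dist.N == 0:
        return {}
    out: dict[int, Fraction] = {}
    tail = 0
    for h in range(dist.H, 0, -1):
        tail += dist.n_h.get(h, 0)
        out[h] = Fraction(tail, dist.N)
    return dict(sorted(out.items()))


def _draw_tail_probs(
    region_length: int,
    n_events: int,
    n_draws: int,
    flank: int,
    max_h: int,
    rng: np.random.Generator,
    stat: str = "tailprob",
) -> np.ndarray:
    """Per-draw background tail statistics at heights 1..max_h.

    Returns an (n_draws, max_h) array; column h-1 holds, per draw, the
    fraction of that draw's occupied positions with height >= h
    (``stat='tailprob'``) or the raw number of such positions
    (``stat='counts'``).
    """
    out = np.zeros((n_draws, max_h), dtype=float)
    if n_events == 0 or max_h == 0:
        return out
    p = np.full(region_length, 1.0 / region_length)
    chunk = max(1, min(n_draws, int(4e6 // max(region_length, 1)) or 1))
    done = 0
    while done < n_draws:
        size = min(chunk, n_draws - done)
        draws = rng.multinomial(n_events, p, size=size)
        win = np.atleast_2d(_window_heights(draws, flank))
        occupied = draws > 0
        for j in range(size):
            hs = win[j][occupied[j]]
            n_occ = hs.size
            if n_occ == 0:
                continue
            # tail counts: number of occupied positions with height >= h
            hist = np.bincount(np.minimum(hs, max_h + 1), minlength=max_h + 2)
            tail = np.cumsum(hist[::-1])[::-1]
            vals = tail[1 : max_h + 1].astype(float)
            if stat == "tailprob":
                vals = vals / n_occ
            out[done + j] = vals
        done += size
    return out


def simulate_background(
    region_length: int,
    n_events: int,
    n_draws: int = DEFAULT_N_DRAWS,
    flank: int = DEFAULT_FLANK,
    rng: np.random.Generator | None = None,
    max_h: int | None = None,
    stat: str = "tailprob",
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform-background mean and sd of the tail statistic per height.

    Each draw places ``n_events`` events uniformly with replacement over
    the region, then computes heights and tail probabilities exactly as
    for observed data. Returns (mu, sigma) arrays indexed by height - 1,
    up to ``max_h`` (default: the largest height reached in any draw).
    Heights beyond every draw's maximum get mu = sigma = 0.
    """
    if region_length < 1:
        if n_events > 0:
            raise ValueError("region_length must be >= 1 when events exist")
        return np.zeros(0), np.zeros(0)
    rng = np.random.default_rng() if rng is None else rng
    if max_h is None:
        max_h = n_events  # heights cannot exceed the total event count
    tails = _draw_tail_probs(region_length, n_events, n_draws, flank, max_h, rng, stat)
    mu = tails.mean(axis=0)
    sigma = tails.std(axis=0, ddof=1) if n_draws > 1 else np.zeros(max_h)
    return mu, sigma


def fdr_per_height(
    p_obs: Mapping[int, Fraction], mu: np.ndarray, sigma: np.ndarray
) -> dict[int, float]:
    """FDR(h) = (mu_h + sigma_h) / P(h) for every observed height."""
    out: dict[int, float] = {}
    for h, p in p_obs.items():
        if p <= 0:
            raise ValueError(f"P_obs({h}) must be > 0")
        m = mu[h - 1] if h - 1 < len(mu) else 0.0
        s = sigma[h - 1] if h - 1 < len(sigma) else 0.0
        out[h] = float((m + s) / float(p))
    return out


@dataclass
class SignificantSiteSet:
    """Stable significant positions of one (sample, gene, region)."""

    sample_id: str
    gene_id: str
    region: str
    positions: set[int]
    stability: dict[int, float] = field(default_factory=dict)


def call_significant_sites(
    counts: Mapping[int, int],
    region_length: int,
    alpha: float = DEFAULT_ALPHA,
    n_draws: int = DEFAULT_N_DRAWS,
    n_reruns: int = DEFAULT_N_RERUNS,
    stability: float = DEFAULT_STABILITY,
    flank: int = DEFAULT_FLANK,
    rng: np.random.Generator | None = None,
    background_stat: str = "tailprob",
) -> tuple[set[int], dict[int, float]]:
    """Positions whose FDR < alpha in at least ``stability`` of reruns.

    The observed data are fixed; each rerun draws a fresh uniform
    background of ``n_draws`` draws and re-evaluates FDR(h) at every
    observed height. Returns (retained positions, per-position stability
    fraction over all reruns, retained or not).
    """
    rng = np.random.default_rng() if rng is None else rng
    dist = compute_heights(counts, region_length, flank)
    if dist.N == 0:
        return set(), {}
    p_obs = tail_probability(dist)
    obs_heights = sorted(p_obs)
    max_h = obs_heights[-1]
    p_arr = np.array([float(p_obs[h]) for h in obs_heights])

    sig_count = np.zeros(len(obs_heights), dtype=np.int64)
    for _ in range(n_reruns):
        tails = _draw_tail_probs(
            region_length, dist.n_events, n_draws, flank, max_h, rng, background_stat
        )
        mu = tails.mean(axis=0)
        sigma = tails.std(axis=0, ddof=1) if n_draws > 1 else np.zeros(max_h)
        fdr = (mu[[h - 1 for h in obs_heights]] + sigma[[h - 1 for h in obs_heights]]) / p_arr
        sig_count += fdr < alpha

    frac_by_height = {h: sig_count[i] / n_reruns for i, h in enumerate(obs_heights)}
    stab = {pos: float(frac_by_height[h]) for pos, h in dist.heights.items()}
    retained = {pos for pos, f in stab.items() if f >= stability}
    return retained, stab


class CrosslinkSiteModel:
    """Significance model for the crosslink track of one (gene, region).

    Built from a :class:`~planticlip.iclip_preprocess.CrosslinkTrack`
    plus its :class:`~planticlip.annotation_io.RegionPartition` (or from
    a raw local-coordinate count mapping via :meth:`from_counts`).
    ``fit`` runs the permutation-FDR procedure and returns a
    :class:`CrosslinkSiteResults`.
    """

    def __init__(
        self,
        track: CrosslinkTrack,
        partition: RegionPartition,
        flank: int = DEFAULT_FLANK,
    ):
        self.track = track
        self.partition = partition
        self.flank = flank
        self._local_counts, self._region_length = localize_track(track, partition)
        self._local_to_genomic = {
            loc: pos
            for pos, loc in (
                (p, partition.to_local(track.region, p)) for p in track.counts
            )
        }

    @classmethod
    def from_counts(
        cls,
        counts: Mapping[int, int],
        region_length: int,
        flank: int = DEFAULT_FLANK,
        sample_id: str = "sample",
        gene_id: str = "gene",
        region: str = "exon",
    ) -> "CrosslinkSiteModel":
        self = cls.__new__(cls)
        self.track = CrosslinkTrack(
            sample_id=sample_id, gene_id=gene_id, region=region, strand="+",
            counts=dict(counts),
        )
        self.partition = None
        self.flank = flank
        self._local_counts = dict(counts)
        self._region_length = region_length
        self._local_to_genomic = {p: p for p in counts}
        return self

    def fit(
        self,
        alpha: float = DEFAULT_ALPHA,
        n_draws: int = DEFAULT_N_DRAWS,
        n_reruns: int = DEFAULT_N_RERUNS,
        stability: float = DEFAULT_STABILITY,
        rng: np.random.Generator | None = None,
        background_stat: str = "tailprob",
    ) -> "CrosslinkSiteResults":
        rng = np.random.default_rng() if rng is None else rng
        dist = compute_heights(self._local_counts, self._region_length, self.flank)
        p_obs = tail_probability(dist)
        retained, stab = call_significant_sites(
            self._local_counts,
            self._region_length,
            alpha=alpha,
            n_draws=n_draws,
            n_reruns=n_reruns,
            stability=stability,
            flank=self.flank,
            rng=rng,
            background_stat=background_stat,
        )
        mu, sigma = simulate_background(
            self._region_length,
            dist.n_events,
            n_draws=n_draws,
            flank=self.flank,
            rng=rng,
            max_h=dist.H or 1,
            stat=background_stat,
        )
        fdr = fdr_per_height(p_obs, mu, sigma) if p_obs else {}
        return CrosslinkSiteResults(
            model=self,
            distribution=dist,
            p_obs=p_obs,
            mu=mu,
            sigma=sigma,
            fdr=fdr,
            retained=retained,
            stability_fraction=stab,
            params=dict(
                alpha=alpha,
                n_draws=n_draws,
                n_reruns=n_reruns,
                stability=stability,
                flank=self.flank,
                background_stat=background_stat,
            ),
        )


@dataclass
class CrosslinkSiteResults:
    """Fitted site calls with FDR diagnostics for one (gene, region)."""

    model: CrosslinkSiteModel
    distribution: HeightDistribution
    p_obs: dict[int, Fraction]
    mu: np.ndarray
    sigma: np.ndarray
    fdr: dict[int, float]
    retained: set[int]
    stability_fraction: dict[int, float]
    params: dict

    @property
    def sites(self) -> pd.DataFrame:
        """Per-position table: local/genomic coordinate, count, height, stability."""
        rows = []
        for pos, h in sorted(self.distribution.heights.items()):
            rows.append(
                dict(
                    position=self.model._local_to_genomic.get(pos, pos),
                    local_position=pos,
                    count=self.model._local_counts[pos],
                    height=h,
                    fdr=self.fdr.get(h, float("nan")),
                    stability=self.stability_fraction.get(pos, 0.0),
                    significant=pos in self.retained,
                )
            )
        return pd.DataFrame(
            rows,
            columns=[
                "position", "local_position", "count", "height",
                "fdr", "stability", "significant",
            ],
        )

    @property
    def fdr_table(self) -> pd.DataFrame:
        """Per-height table: n_h, P_obs, mu, sigma, FDR (one representative background)."""
        rows = []
        for h in sorted(self.p_obs):
            rows.append(
                dict(
                    height=h,
                    n_h=self.distribution.n_h.get(h, 0),
                    p_obs=float(self.p_obs[h]),
                    mu=float(self.mu[h - 1]) if h - 1 < len(self.mu) else 0.0,
                    sigma=float(self.sigma[h - 1]) if h - 1 < len(self.sigma) else 0.0,
                    fdr=self.fdr[h],
                )
            )
        return pd.DataFrame(rows, columns=["height", "n_h", "p_obs", "mu", "sigma", "fdr"])

    def site_set(self) -> SignificantSiteSet:
        genomic = {self.model._local_to_genomic.get(p, p) for p in self.retained}
        stab = {
            self.model._local_to_genomic.get(p, p): f
            for p, f in self.stability_fraction.items()
        }
        return SignificantSiteSet(
            sample_id=self.model.track.sample_id,
            gene_id=self.model.track.gene_id,
            region=self.model.track.region,
            positions=genomic,
            stability=stab,
        )

    def summary(self) -> str:
        d = self.distribution
        lines = [
            "Crosslink-site significance (permutation FDR on heights)",
            "=" * 56,
            f"gene/region:      {self.model.track.gene_id} / {self.model.track.region}",
            f"region length:    {d.region_length} nt",
            f"events / sites:   {d.n_events} events at {d.N} positions (max height {d.H})",
            f"alpha:            {self.params['alpha']} "
            f"({self.params['n_reruns']} reruns x {self.params['n_draws']} draws, "
            f"stability >= {self.params['stability']})",
            f"significant:      {len(self.retained)} stable positions",
        ]
        return "\n".join(lines)


def replicate_consensus(
    site_sets: Sequence[set[int] | SignificantSiteSet],
    min_support: int | None = None,
) -> set[int]:
    """Positions recurring at the identical coordinate across replicates.

    Default support is R - 1 ("all but one of the replicates"); with
    exactly two replicates both must agree.
    """
    R = len(site_sets)
    if R < 2:
        raise ValueError("replicate consensus needs at least 2 replicates")
    if min_support is None:
        min_support = 2 if R == 2 else R - 1
    counts: dict[int, int] = {}
    for s in site_sets:
        positions = s.positions if isinstance(s, SignificantSiteSet) else s
        for pos in positions:
            counts[pos] = counts.get(pos, 0) + 1
    return {pos for pos, c in counts.items() if c >= min_support}


def consensus_by_gene(
    replicate_site_sets: Sequence[Mapping[tuple[str, str], set[int]]],
    min_support: int | None = None,
) -> dict[tuple[str, str], set[int]]:
    """Per-(gene, region) replicate consensus across a sample group."""
    keys = set()
    for rep in replicate_site_sets:
        keys.update(rep)
    out: dict[tuple[str, str], set[int]] = {}
    for key in keys:
        sets = [rep.get(key, set()) for rep in replicate_site_sets]
        cons = replicate_consensus(sets, min_support)
        if cons:
            out[key] = cons
    return out


def subtract_controls(
    treatment_consensus: Mapping[tuple[str, str], set[int]],
    control_groups: Sequence[Sequence[Mapping[tuple[str, str], set[int]]]],
    control_min_support: int = 2,
) -> tuple[set[str], dict[tuple[str, str], set[int]]]:
    """Remove genes carrying consensus sites in any control group.

    Each control group (e.g. free-GFP plants, a binding-dead variant) is
    a sequence of per-replicate site-set mappings; a gene is flagged when
    any control group reaches ``control_min_support`` replicates at one
    position. Returns (retained gene ids, retained per-(gene, region)
    sites).
    """
    contaminated: set[str] = set()
    for group in control_groups:
        if len(group) < 2:
            # single-replicate control group: any site counts
            cons = {k: set(v) for k, v in (group[0].items() if group else [])}
        else:
            cons = consensus_by_gene(list(group), min_support=control_min_support)
        contaminated.update(gene for (gene, _r), sites in cons.items() if sites)
    retained_sites = {
        key: set(sites)
        for key, sites in treatment_consensus.items()
        if key[0] not in contaminated and sites
    }
    retained_genes = {gene for gene, _r in retained_sites}
    return retained_genes, retained_sites


def region_site_summary(
    consensus_sites: Mapping[tuple[str, str], set[int]],
    region_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Counts of consensus sites per region, raw and length-normalised,
    plus counts of genes per region combination."""
    from .annotation_io import REGIONS

    per_region = {r: 0 for r in REGIONS}
    combos: dict[str, set[str]] = {}
    gene_regions: dict[str, set[str]] = {}
    for (gene, region), sites in consensus_sites.items():
        per_region[region] = per_region.get(region, 0) + len(sites)
        gene_regions.setdefault(gene, set()).add(region)
    for gene, regions in gene_regions.items():
        combo = "+".join(sorted(regions))
        combos.setdefault(combo, set()).add(gene)
    rows = []
    for r in REGIONS:
        norm = (
            per_region[r] / region_lengths[r]
            if region_lengths and region_lengths.get(r)
            else float("nan")
        )
        rows.append(dict(kind="region_sites", key=r, count=per_region[r],
                         per_nt=norm))
    for combo in sorted(combos):
        rows.append(dict(kind="gene_region_combo", key=combo,
                         count=len(combos[combo]), per_nt=float("nan")))
    return pd.DataFrame(rows, columns=["kind", "key", "count", "per_nt"])
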