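"""Cross-referencing binding targets with RIP-seq, RNA-seq and splicing.

Crosslink-derived target transcripts are validated and extended by
orthogonal assays: RIP-seq enrichment over poly(A) RNA (expression and
fold-change/q-value gates), differential expression between genotypes,
overlap percentages between target sets, the direction of regulation of
bound differentially expressed genes, and percent-spliced-in (PSI)
quantification of alternative splicing events from isoform TPM tables.

Differential-expression statistics (log2 fold change, p/q values) are
consumed as inputs from upstream tools; a Benjamini-Hochberg fallback
recomputes q when only p is supplied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class TargetSet:
    """Named set of gene ids with provenance (iCLIP, RIP, DEG, ...)."""

    name: str
    members: frozenset[str]
    provenance: str = ""

    def __init__(self, name: str, members: Iterable[str], provenance: str = ""):
        self.name = name
        self.members = frozenset(members)
        self.provenance = provenance

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members

    def intersection(self, other: "TargetSet") -> "TargetSet":
        return TargetSet(
            f"{self.name}&{other.name}", self.members & other.members,
            provenance=f"intersection of {self.name} and {other.name}",
        )

    def union(self, other: "TargetSet") -> "TargetSet":
        return TargetSet(f"{self.name}|{other.name}", self.members | other.members)

    def difference(self, other: "TargetSet") -> "TargetSet":
        return TargetSet(f"{self.name}-{other.name}", self.members - other.members)


def round_half_away(x: float, decimals: int) -> float:
    """Round half away from zero at the given precision (printed-value style)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def bh_qvalues(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone in p)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def compute_tpm(counts: pd.DataFrame, effective_lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million from counts and effective lengths.

    TPM_i = 1e6 * (c_i / l_i) / sum_j (c_j / l_j); every column sums to 1e6.
    """
    lengths = effective_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(lengths[lengths.isna()].index[:3])
        raise ValueError(f"missing effective lengths, e.g. {missing}")
    if (lengths <= 0).any():
        raise ValueError("effective lengths must be > 0")
    rate = counts.div(lengths, axis=0)
    denom = rate.sum(axis=0)
    if (denom == 0).any():
        bad = list(denom[denom == 0].index)
        raise ValueError(f"all-zero counts column(s): {bad}")
    return rate.div(denom, axis=1) * 1e6


def _resolve_q(diff_stats: pd.DataFrame) -> pd.Series:
    if "qvalue" in diff_stats:
        return diff_stats["qvalue"]
    if "pvalue" in diff_stats:
        return pd.Series(bh_qvalues(diff_stats["pvalue"]), index=diff_stats.index)
    raise ValueError("diff_stats needs a 'qvalue' or 'pvalue' column")


def rip_enrichment_filter(
    diff_stats: pd.DataFrame,
    rip_tpm: pd.Series,
    min_tpm: float = 5.0,
    min_log2fc: float = 0.5,
    max_q: float = 0.001,
    strict: bool = False,
    name: str = "RIP",
) -> TargetSet:
    """RIP-seq targets: expressed, enriched over poly(A) RNA, significant.

    Genes with RIP TPM below ``min_tpm`` are excluded outright; the
    remaining members need log2 fold change >= ``min_log2fc`` (strictly
    > with ``strict=True``) and q < ``max_q``.
    """
    q = _resolve_q(diff_stats)
    lfc = diff_stats["log2fc"]
    tpm = rip_tpm.reindex(diff_stats.index)
    expressed = tpm >= min_tpm
    enriched = lfc > min_log2fc if strict else lfc >= min_log2fc
    members = diff_stats.index[expressed & enriched & (q < max_q)]
    return TargetSet(name, members, provenance="RIP-seq enrichment filter")


def deg_filter(
    diff_stats: pd.DataFrame,
    tpm_by_genotype: pd.DataFrame,
    max_q: float = 0.05,
    min_tpm: float = 1.0,
    name: str = "DEG",
) -> TargetSet:
    """Differentially expressed genes: q < max_q and TPM > min_tpm in
    at least one genotype (per-genotype replicate means)."""
    q = _resolve_q(diff_stats)
    expressed = (tpm_by_genotype.reindex(diff_stats.index) > min_tpm).any(axis=1)
    members = diff_stats.index[(q < max_q) & expressed]
    return TargetSet(name, members, provenance="differential expression filter")


def intersect_targets(
    set_a: TargetSet, set_b: TargetSet, decimals: int = 0
) -> dict:
    """Overlap report with percentages rounded at printed precision."""
    inter = set_a.members & set_b.members
    pct_a = round_half_away(100.0 * len(inter) / len(set_a), decimals) if len(set_a) else 0.0
    pct_b = round_half_away(100.0 * len(inter) / len(set_b), decimals) if len(set_b) else 0.0
    return {
        "name_a": set_a.name,
        "name_b": set_b.name,
        "n_a": len(set_a),
        "n_b": len(set_b),
        "n_intersection": len(inter),
        "pct_of_a": pct_a,
        "pct_of_b": pct_b,
    }


def crossref_summary(
    target_sets: Sequence[TargetSet],
    reference_sets: Sequence[TargetSet],
    decimals: int = 2,
) -> pd.DataFrame:
    """Overlap matrix: each target set against each reference set."""
    rows = []
    for ref in reference_sets:
        for ts in target_sets:
            inter = len(ts.members & ref.members)
            pct = round_half_away(100.0 * inter / len(ref), decimals) if len(ref) else 0.0
            rows.append(
                dict(
                    reference=ref.name,
                    target=ts.name,
                    n_reference=len(ref),
                    n_target=len(ts),
                    n_overlap=inter,
                    pct_of_reference=pct,
                )
            )
    return pd.DataFrame(
        rows,
        columns=["reference", "target", "n_reference", "n_target", "n_overlap",
                 "pct_of_reference"],
    )


def direction_summary(
    deg_log2fc: pd.Series,
    target_sets: Sequence[TargetSet],
) -> pd.DataFrame:
    """Up/down counts per target group and a two-sided Mann-Whitney U
    comparison of each group's log2 fold changes against all DEGs.

    Groups with fewer than two members present in the DEG table are
    skipped (p = NaN) with a warning column.
    """
    rows = []
    background = deg_log2fc.dropna()
    for ts in target_sets:
        vals = background.reindex(sorted(ts.members & set(background.index))).dropna()
        n_up = int((vals > 0).sum())
        n_down = int((vals < 0).sum())
        if len(vals) < 2:
            u, p, skipped = math.nan, math.nan, True
        else:
            u, p = sps.mannwhitneyu(vals, background, alternative="two-sided")
            skipped = False
        rows.append(
            dict(target=ts.name, n=len(vals), n_up=n_up, n_down=n_down,
                 u_statistic=u, pvalue=p, skipped=skipped)
        )
    return pd.DataFrame(
        rows, columns=["target", "n", "n_up", "n_down", "u_statistic", "pvalue",
                       "skipped"],
    )


@dataclass
class PsiEvent:
    """Percent-spliced-in of one alternative-splicing event.

    psi per genotype is the mean over replicates of per-replicate
    inclusion-TPM / total-TPM; delta_psi compares each genotype to the
    reference (wild type).
    """

    event_id: str
    gene_id: str
    inclusion_isoforms: frozenset[str]
    all_isoforms: frozenset[str]
    psi: dict[str, float] = field(default_factory=dict)
    delta_psi: dict[str, float] = field(default_factory=dict)
    pvalue: dict[str, float] = field(default_factory=dict)
    replicate_psi: dict[str, list[float]] = field(default_factory=dict)


def compute_psi(
    isoform_tpm: pd.DataFrame,
    event_definitions: Sequence[Mapping],
    sample_groups: Mapping[str, Sequence[str]],
    reference: str,
    pooled: bool = False,
) -> list[PsiEvent]:
    """PSI per genotype and delta-PSI vs the reference genotype.

    ``event_definitions`` entries need event_id, gene_id,
    inclusion_isoforms and all_isoforms; single-isoform genes are
    excluded. Replicates with zero total TPM give an undefined PSI and
    are dropped; an event with no defined replicate in a genotype is
    dropped entirely. ``pooled=True`` sums TPM over replicates instead
    of averaging per-replicate ratios.
    """
    if reference not in sample_groups:
        raise ValueError(f"reference genotype {reference!r} not in sample_groups")
    events: list[PsiEvent] = []
    for spec in event_definitions:
        incl = frozenset(spec["inclusion_isoforms"])
        alliso = frozenset(spec["all_isoforms"])
        if not incl <= alliso:
            raise ValueError(f"event {spec['event_id']}: inclusion must be <= all isoforms")
        if len(alliso) < 2:
            continue  # single annotated isoform: no event
        missing = alliso - set(isoform_tpm.index)
        if missing:
            raise ValueError(f"event {spec['event_id']}: unknown isoforms {sorted(missing)}")
        ev = PsiEvent(
            event_id=spec["event_id"], gene_id=spec["gene_id"],
            inclusion_isoforms=incl, all_isoforms=alliso,
        )
        ok = True
        for genotype, samples in sample_groups.items():
            incl_tpm = isoform_tpm.loc[sorted(incl), list(samples)].sum(axis=0)
            all_tpm = isoform_tpm.loc[sorted(alliso), list(samples)].sum(axis=0)
            if pooled:
                total = float(all_tpm.sum())
                if total == 0:
                    ok = False
                    break
                ev.psi[genotype] = float(incl_tpm.sum()) / total
                ev.replicate_psi[genotype] = []
            else:
                defined = all_tpm > 0
                ratios = (incl_tpm[defined] / all_tpm[defined]).tolist()
                if not ratios:
                    ok = False
                    break
                ev.replicate_psi[genotype] = [float(r) for r in ratios]
                ev.psi[genotype] = float(np.mean(ratios))
        if not ok:
            continue
        for genotype in sample_groups:
            if genotype != reference:
                ev.delta_psi[genotype] = ev.psi[genotype] - ev.psi[reference]
        events.append(ev)
    return events


def permutation_psi_pvalue(
    psi_a: Sequence[float], psi_b: Sequence[float], rng=None, n_perm: int = 1000
) -> float:
    """Replicate-label permutation p for |mean(a) - mean(b)|.

    Exhaustive over label reassignments when there are at most ~12
    replicates in total, else Monte Carlo. Includes the identity
    permutation, so p >= 1 / n_permutations.
    """
    a, b = list(psi_a), list(psi_b)
    pooled = a + b
    obs = abs(np.mean(a) - np.mean(b))
    n_a, n = len(a), len(pooled)
    idx = range(n)
    n_exhaustive = math.comb(n, n_a)
    if n_exhaustive <= 2000:
        hits = 0
        for combo in combinations(idx, n_a):
            sel = set(combo)
            ga = [pooled[i] for i in sel]
            gb = [pooled[i] for i in idx if i not in sel]
            if abs(np.mean(ga) - np.mean(gb)) >= obs - 1e-12:
                hits += 1
        return hits / n_exhaustive
    rng = np.random.default_rng() if rng is None else rng
    hits = 1  # identity permutation
    arr = np.array(pooled)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        stat = abs(arr[perm[:n_a]].mean() - arr[perm[n_a:]].mean())
        if stat >= obs - 1e-12:
            hits += 1
    return hits / (n_perm + 1)


def delta_psi_filter(
    events: Sequence[PsiEvent],
    genotype: str,
    min_abs_dpsi: float = 0.1,
    max_p: float = 0.01,
    pvalues: Mapping[str, float] | None = None,
    rng=None,
) -> list[PsiEvent]:
    """Significant splicing changes: |dPSI| > min_abs_dpsi and p < max_p.

    p-values are supplied externally per event id (e.g. from an isoform
    quantification tool) or fall back to the built-in replicate
    permutation test.
    """
    out = []
    for ev in events:
        if genotype not in ev.delta_psi:
            continue
        if pvalues is not None:
            if ev.event_id not in pvalues:
                raise ValueError(f"no p-value supplied for event {ev.event_id}")
            p = pvalues[ev.event_id]
        else:
            ref = next(g for g in ev.psi if g not in ev.delta_psi)
            p = permutation_psi_pvalue(
                ev.replicate_psi[genotype], ev.replicate_psi[ref], rng=rng
            )
        ev.pvalue[genotype] = float(p)
        if abs(ev.delta_psi[genotype]) > min_abs_dpsi and p < max_p:
            out.append(ev)
    return out


def events_table(events: Sequence[PsiEvent], genotype: str) -> pd.DataFrame:
    rows = [
        dict(
            event_id=ev.event_id,
            gene_id=ev.gene_id,
            psi=ev.psi.get(genotype, math.nan),
            delta_psi=ev.delta_psi.get(genotype, math.nan),
            pvalue=ev.pvalue.get(genotype, math.nan),
        )
        for ev in events
    ]
    return pd.DataFrame(rows, columns=["event_id", "gene_id", "psi", "delta_psi", "pvalue"])


def read_gene_list(handle) -> TargetSet:
    """One-gene-id-per-line text file -> TargetSet (e.g. a circadian list)."""
    own = isinstance(handle, str)
    fh = open(handle) if own else handle
    try:
        members = [line.strip() for line in fh if line.strip()]
        return TargetSet("gene_list", members, provenance="gene list file")
    finally:
        if own:
            fh.close()
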