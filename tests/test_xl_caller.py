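"""Height statistic, permutation FDR, rerun stability, consensus, controls."""

from fractions import Fraction

import numpy as np
import pytest

from planticlip.annotation_io import RegionPartition
from planticlip.iclip_preprocess import CrosslinkTrack
from planticlip.xl_caller import (
    CrosslinkSiteModel,
    call_significant_sites,
    compute_heights,
    consensus_by_gene,
    fdr_per_height,
    replicate_consensus,
    simulate_background,
    subtract_controls,
    tail_probability,
)

# ---------------------------------------------------------------- oracles


def brute_force_heights(counts: dict, region_length: int, flank: int) -> dict:
    """Independent nested-loop height computation."""
    out = {}
    for x in counts:
        h = 0
        for y, c in counts.items():
            if abs(x - y) <= flank:
                h += c
        out[x] = h
    return out


def brute_force_tail(heights: dict) -> dict:
    vals = list(heights.values())
    N = len(vals)
    return {h: Fraction(sum(1 for v in vals if v >= h), N)
            for h in range(1, max(vals) + 1)}


# ---------------------------------------------------------------- heights


def test_heights_worked_example():
    dist = compute_heights({10: 2, 12: 1}, region_length=100, flank=15)
    assert dist.heights == {10: 3, 12: 3}
    assert dist.n_h == {3: 2}
    assert dist.H == 3 and dist.N == 2 and dist.n_events == 3


def test_isolated_site():
    dist = compute_heights({50: 1}, region_length=100, flank=15)
    assert dist.heights == {50: 1} and dist.n_h == {1: 1} and dist.N == 1


def test_heights_sum_across_concatenated_exon_junction():
    """Two exons [0,100)+[200,300): sites 5 nt either side of the junction
    are 10 nt apart in concatenated coordinates and see each other."""
    part = RegionPartition(
        gene_id="g", chrom="c", strand="+",
        intervals={"utr5": [], "exon": [(0, 100), (200, 300)], "intron": [(100, 200)],
                   "utr3": []},
    )
    track = CrosslinkTrack("s", "g", "exon", "+", counts={95: 2, 204: 3})
    model = CrosslinkSiteModel(track, part)
    dist = compute_heights(model._local_counts, model._region_length, 15)
    # local coords: 95 and 104 -> distance 9 <= 15
    assert dist.heights == {95: 5, 104: 5}


def test_empty_track_gives_empty_distribution():
    dist = compute_heights({}, region_length=100)
    assert dist.N == 0 and tail_probability(dist) == {}


def test_window_does_not_cross_region_boundary():
    dist = compute_heights({0: 1, 99: 1}, region_length=100, flank=15)
    assert dist.heights == {0: 1, 99: 1}


# ---------------------------------------------------------------- tail prob


def test_tail_probability_worked_example():
    dist = compute_heights({0: 1, 30: 1, 60: 1, 90: 2}, region_length=100, flank=5)
    # heights 1,1,1,2 -> n_1=3, n_2=1
    p = tail_probability(dist)
    assert p[1] == 1 and p[2] == Fraction(1, 4)


def test_degenerate_single_height():
    counts = {i * 40: 5 for i in range(10)}
    dist = compute_heights(counts, region_length=400, flank=2)
    p = tail_probability(dist)
    assert p[5] == 1 and max(p) == 5


def test_tail_probability_monotone_non_increasing(rng):
    for _ in range(20):
        n = int(rng.integers(1, 10))
        counts = {}
        for pos in rng.integers(0, 50, size=n):
            counts[int(pos)] = counts.get(int(pos), 0) + 1
        dist = compute_heights(counts, region_length=50, flank=3)
        p = tail_probability(dist)
        hs = sorted(p)
        assert all(p[a] >= p[b] for a, b in zip(hs, hs[1:]))
        assert p[hs[0]] == 1  # smallest observed height has tail prob 1


def test_oracle_equivalence_small_regions(rng):
    """Heights and tail probabilities match brute force on regions <= 30 nt
    with <= 6 events, across many random fixtures."""
    for _ in range(300):
        L = int(rng.integers(1, 31))
        n_events = int(rng.integers(1, 7))
        flank = int(rng.integers(0, 16))
        counts = {}
        for pos in rng.integers(0, L, size=n_events):
            counts[int(pos)] = counts.get(int(pos), 0) + 1
        dist = compute_heights(counts, L, flank)
        assert dist.heights == brute_force_heights(counts, L, flank)
        assert tail_probability(dist) == brute_force_tail(dist.heights)


# ---------------------------------------------------------------- background


def test_background_zero_events():
    mu, sigma = simulate_background(100, 0, n_draws=10, rng=np.random.default_rng(0))
    assert np.all(mu == 0) and np.all(sigma == 0)


def test_background_deterministic_under_seed():
    a = simulate_background(50, 20, n_draws=30, rng=np.random.default_rng(42))
    b = simulate_background(50, 20, n_draws=30, rng=np.random.default_rng(42))
    assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


def test_background_mean_matches_independent_monte_carlo():
    """mu_1 agrees with a brute-force re-simulation using an independent
    generator (per-position loop, no shared code path)."""
    L, n_events, flank, n_draws = 50, 20, 15, 1000
    mu, _ = simulate_background(L, n_events, n_draws=n_draws, flank=flank,
                                rng=np.random.default_rng(1))
    # independent oracle: RandomState + explicit loops
    rs = np.random.RandomState(2)
    vals = []
    for _ in range(n_draws):
        positions = rs.randint(0, L, size=n_events)
        occupied = sorted(set(positions))
        # tail prob at h=1 is 1 whenever any position is occupied
        vals.append(1.0 if occupied else 0.0)
    se = np.std(vals, ddof=1) / np.sqrt(n_draws) + 1e-12
    assert abs(mu[0] - np.mean(vals)) <= 3 * se + 1e-9


def test_fdr_formula():
    p_obs = {1: Fraction(1), 2: Fraction(1, 4)}
    mu = np.array([0.04, 0.0])
    sigma = np.array([0.01, 0.0])
    fdr = fdr_per_height(p_obs, mu, sigma)
    assert fdr[1] == pytest.approx(0.05)
    assert fdr[2] == 0.0  # never reached in background


def test_significance_threshold_is_strict(rng):
    """FDR exactly at alpha is not significant; just below is."""
    counts = {50: 10}
    # a background never reaching h=10 gives FDR exactly 0; strict `<`
    # means alpha=0 retains nothing
    retained, stab = call_significant_sites(
        counts, 200, alpha=0.0, n_draws=5, n_reruns=10, rng=rng)
    assert retained == set()
    retained, stab = call_significant_sites(
        counts, 200, alpha=0.5, n_draws=5, n_reruns=10,
        rng=np.random.default_rng(0))
    assert 50 in retained


def test_strong_site_called_and_doubling_preserves_significance():
    counts = {100: 30, 40: 1, 160: 1}
    kwargs = dict(alpha=0.05, n_draws=25, n_reruns=50)
    r1, _ = call_significant_sites(counts, 500, rng=np.random.default_rng(3), **kwargs)
    doubled = {p: 2 * c for p, c in counts.items()}
    r2, _ = call_significant_sites(doubled, 500, rng=np.random.default_rng(3), **kwargs)
    assert 100 in r1
    assert r1 <= r2  # doubling all counts never removes a significant position


# ---------------------------------------------------------------- consensus


@pytest.mark.parametrize(
    "n_sets, n_with_pos, expected",
    [(5, 4, True), (5, 3, False), (2, 2, True), (2, 1, False)],
)
def test_replicate_consensus_support(n_sets, n_with_pos, expected):
    sets = [{7} if i < n_with_pos else set() for i in range(n_sets)]
    assert (7 in replicate_consensus(sets)) is expected


def test_consensus_requires_two_replicates():
    with pytest.raises(ValueError):
        replicate_consensus([{1}])


def test_subtract_controls_removes_exactly_contaminated_genes():
    genes = [f"g{i}" for i in range(10)]
    treatment = {(g, "utr3"): {100 + i} for i, g in enumerate(genes)}
    # controls: g3 and g7 have a site in both replicates of one group
    ctrl_rep = {("g3", "utr3"): {500}, ("g7", "exon"): {600}}
    control_groups = [[ctrl_rep, ctrl_rep], [{}, {}]]
    retained_genes, retained_sites = subtract_controls(treatment, control_groups)
    assert retained_genes == set(genes) - {"g3", "g7"}
    assert ("g3", "utr3") not in retained_sites
    assert retained_sites[("g0", "utr3")] == {100}


def test_control_site_in_single_replicate_does_not_remove_gene():
    treatment = {("gA", "utr3"): {10}}
    control_groups = [[{("gA", "utr3"): {99}}, {}]]  # support 1 < 2
    retained_genes, _ = subtract_controls(treatment, control_groups)
    assert retained_genes == {"gA"}


def test_model_results_surface(small_annotation, rng):
    part = small_annotation.partitions["G001"]
    pos = part.to_genomic("utr3", 50)
    track = CrosslinkTrack("s1", "G001", "utr3", part.strand,
                           counts={pos: 20, part.to_genomic("utr3", 10): 1})
    res = CrosslinkSiteModel(track, part).fit(n_draws=25, n_reruns=50, rng=rng)
    df = res.sites
    assert set(df.columns) >= {"position", "count", "height", "fdr", "stability",
                               "significant"}
    assert pos in set(df[df.significant].position)
    assert res.fdr_table.p_obs.iloc[0] == 1.0
    assert "significant" in res.summary()
    ss = res.site_set()
    assert pos in ss.positions and 0 <= ss.stability[pos] <= 1
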