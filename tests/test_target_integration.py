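"""TPM, enrichment/DEG gates, set algebra, regulation direction, PSI."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from planticlip.target_integration import (
    TargetSet,
    bh_qvalues,
    compute_psi,
    compute_tpm,
    crossref_summary,
    deg_filter,
    delta_psi_filter,
    direction_summary,
    intersect_targets,
    permutation_psi_pvalue,
    read_gene_list,
    rip_enrichment_filter,
    round_half_away,
)

# ----------------------------------------------------------------- TPM


def test_tpm_single_gene_is_one_million():
    tpm = compute_tpm(pd.DataFrame({"s": [100]}, index=["g"]),
                      pd.Series([500], index=["g"]))
    assert tpm.loc["g", "s"] == pytest.approx(1e6)


def test_tpm_length_normalisation():
    counts = pd.DataFrame({"s": [100, 100]}, index=["a", "b"])
    tpm = compute_tpm(counts, pd.Series([1000, 2000], index=["a", "b"]))
    assert tpm.loc["a", "s"] == pytest.approx(2e6 / 3)
    assert tpm.loc["b", "s"] == pytest.approx(1e6 / 3)
    assert tpm.sum().iloc[0] == pytest.approx(1e6, abs=1e-6)


def test_tpm_all_zero_column_rejected():
    with pytest.raises(ValueError, match="all-zero"):
        compute_tpm(pd.DataFrame({"s": [0, 0]}, index=["a", "b"]),
                    pd.Series([100, 100], index=["a", "b"]))


# ----------------------------------------------------------------- filters


def _stats(rows):
    return pd.DataFrame(rows, columns=["log2fc", "qvalue"],
                        index=[f"g{i}" for i in range(len(rows))])


@pytest.mark.parametrize(
    "tpm, log2fc, q, included",
    [
        (4.9, 2.0, 1e-6, False),   # expression gate excludes regardless of fc
        (5.0, 0.5, 5e-4, True),    # boundary: TPM >= 5 and log2fc >= 0.5 pass
        (10.0, 0.6, 5e-4, True),
        (10.0, 0.4, 1e-6, False),  # fails fold-change gate
        (10.0, 0.49, 1e-6, False),
        (10.0, 0.6, 0.001, False), # q must be strictly < 0.001
    ],
)
def test_rip_enrichment_gates(tpm, log2fc, q, included):
    stats = _stats([(log2fc, q)])
    tpm_s = pd.Series([tpm], index=stats.index)
    ts = rip_enrichment_filter(stats, tpm_s)
    assert ("g0" in ts) is included


def test_rip_strict_mode_excludes_boundary_fold_change():
    stats = _stats([(0.5, 1e-6)])
    tpm_s = pd.Series([10.0], index=stats.index)
    assert "g0" in rip_enrichment_filter(stats, tpm_s)
    assert "g0" not in rip_enrichment_filter(stats, tpm_s, strict=True)


@pytest.mark.parametrize(
    "q, tpms, included",
    [
        (0.04, (0.5, 1.2), True),   # expressed in one genotype suffices
        (0.06, (5.0, 5.0), False),  # q gate
        (0.01, (0.9, 0.8), False),  # expression gate (TPM strictly > 1)
        (0.01, (1.0, 1.0), False),
    ],
)
def test_deg_gates(q, tpms, included):
    stats = _stats([(1.0, q)])
    tpm_df = pd.DataFrame({"wt": [tpms[0]], "mut": [tpms[1]]}, index=stats.index)
    assert ("g0" in deg_filter(stats, tpm_df)) is included


def test_bh_recomputation_monotone():
    p = np.array([0.001, 0.2, 0.01, 0.04, 0.9])
    q = bh_qvalues(p)
    assert np.all(np.diff(q[np.argsort(p)]) >= 0)


# ----------------------------------------------------------------- set algebra


def _sets(n_a, n_b, n_inter):
    inter = [f"x{i}" for i in range(n_inter)]
    a = TargetSet("A", inter + [f"a{i}" for i in range(n_a - n_inter)])
    b = TargetSet("B", inter + [f"b{i}" for i in range(n_b - n_inter)])
    return a, b


def test_overlap_report_printed_precision():
    a, b = _sets(858, 2453, 452)
    rep = intersect_targets(a, b)
    assert rep["pct_of_a"] == 53 and rep["n_intersection"] == 452


def test_overlap_identity_and_disjoint():
    a = TargetSet("A", ["x", "y"])
    same = intersect_targets(a, TargetSet("B", ["x", "y"]))
    assert same["pct_of_a"] == 100 and same["pct_of_b"] == 100
    disjoint = intersect_targets(a, TargetSet("C", ["z"]))
    assert disjoint["pct_of_a"] == 0


def test_set_algebra_partition_identity(rng):
    a, b = _sets(120, 300, 47)
    rep = intersect_targets(a, b)
    assert rep["n_intersection"] + len(a.difference(b)) == len(a)


def test_rounding_half_away_from_zero():
    assert round_half_away(4.455, 2) == 4.46
    assert round_half_away(52.5, 0) == 53
    assert round_half_away(-2.5, 0) == -3


def test_crossref_summary_printed_values():
    deg = TargetSet("DEG", [f"d{i}" for i in range(2087 - 93)]
                    + [f"o{i}" for i in range(93)])
    iclip = TargetSet("iCLIP", [f"o{i}" for i in range(93)]
                      + [f"c{i}" for i in range(800)])
    df = crossref_summary([iclip], [deg])
    row = df.iloc[0]
    assert row.n_overlap == 93 and row.pct_of_reference == 4.46


def test_crossref_empty_target_set():
    ref = TargetSet("R", ["a", "b"])
    df = crossref_summary([TargetSet("T", [])], [ref])
    assert df.iloc[0].n_overlap == 0 and df.iloc[0].pct_of_reference == 0


def test_crossref_random_overlap_matches_hypergeometric(rng):
    """Random label permutation: mean overlap ~= |A||B|/|universe|."""
    universe = [f"g{i}" for i in range(400)]
    a_size, b_size = 60, 90
    expected = a_size * b_size / len(universe)
    overlaps = []
    for _ in range(100):
        perm = rng.permutation(universe)
        a = set(perm[:a_size])
        b = set(rng.permutation(universe)[:b_size])
        overlaps.append(len(a & b))
    se = np.std(overlaps, ddof=1) / 10
    assert abs(np.mean(overlaps) - expected) <= 3 * se


# ----------------------------------------------------------------- direction


def brute_force_u(x, y):
    u = 0.0
    for xi in x:
        for yi in y:
            u += 1.0 if xi > yi else (0.5 if xi == yi else 0.0)
    return u


def test_direction_counts_and_separation():
    lfc = pd.Series(
        [-1.0] * 50 + [1.0] * 50,
        index=[f"d{i}" for i in range(100)],
    )
    down = TargetSet("down", [f"d{i}" for i in range(50)])
    df = direction_summary(lfc, [down]).set_index("target")
    assert df.loc["down", "n_down"] == 50 and df.loc["down", "n_up"] == 0
    assert df.loc["down", "pvalue"] < 1e-6


def test_direction_identical_group_is_not_significant():
    lfc = pd.Series(np.linspace(-2, 2, 40), index=[f"g{i}" for i in range(40)])
    df = direction_summary(lfc, [TargetSet("all", lfc.index)])
    assert df.iloc[0].pvalue > 0.95


def test_direction_small_group_skipped():
    lfc = pd.Series([1.0, -1.0], index=["a", "b"])
    df = direction_summary(lfc, [TargetSet("tiny", ["a"])])
    assert df.iloc[0].skipped and math.isnan(df.iloc[0].pvalue)


def test_u_statistic_matches_bruteforce(rng):
    for _ in range(10):
        x = rng.normal(size=int(rng.integers(3, 16)))
        y = rng.normal(size=int(rng.integers(3, 16)))
        u, _ = sps.mannwhitneyu(x, y, alternative="two-sided")
        assert u == pytest.approx(brute_force_u(x, y))


# ----------------------------------------------------------------- PSI


def _psi_inputs(psis_by_col, gene="gA"):
    """Two-isoform TPM table; inclusion TPM = psi * 10, exclusion = rest."""
    idx = [f"{gene}.i1", f"{gene}.i2"]
    data = {col: [psi * 10.0, (1 - psi) * 10.0] for col, psi in psis_by_col.items()}
    tpm = pd.DataFrame(data, index=idx)
    events = [dict(event_id="ev1", gene_id=gene,
                   inclusion_isoforms=[f"{gene}.i1"], all_isoforms=idx)]
    return tpm, events


def test_psi_direct_ratio():
    tpm, events = _psi_inputs({"wt_1": 0.3})
    (ev,) = compute_psi(tpm, events, {"wt": ["wt_1"]}, reference="wt")
    assert ev.psi["wt"] == pytest.approx(0.3)


def test_psi_mean_over_replicates_and_delta():
    tpm, events = _psi_inputs({"wt_1": 0.2, "wt_2": 0.4, "m_1": 0.7, "m_2": 0.5})
    (ev,) = compute_psi(tpm, events, {"wt": ["wt_1", "wt_2"], "mut": ["m_1", "m_2"]},
                        reference="wt")
    assert ev.psi["wt"] == pytest.approx(0.3)
    assert ev.delta_psi["mut"] == pytest.approx(0.3)


def test_single_isoform_gene_excluded():
    tpm = pd.DataFrame({"wt_1": [5.0]}, index=["gB.i1"])
    events = [dict(event_id="e", gene_id="gB", inclusion_isoforms=["gB.i1"],
                   all_isoforms=["gB.i1"])]
    assert compute_psi(tpm, events, {"wt": ["wt_1"]}, reference="wt") == []


def test_zero_total_replicate_excluded():
    tpm, events = _psi_inputs({"wt_1": 0.3})
    tpm["wt_2"] = [0.0, 0.0]  # undefined replicate
    (ev,) = compute_psi(tpm, events, {"wt": ["wt_1", "wt_2"]}, reference="wt")
    assert ev.psi["wt"] == pytest.approx(0.3)
    tpm_all_zero = tpm.copy()
    tpm_all_zero["wt_1"] = [0.0, 0.0]
    assert compute_psi(tpm_all_zero, events, {"wt": ["wt_1", "wt_2"]},
                       reference="wt") == []


@pytest.mark.parametrize(
    "dpsi, p, significant",
    [(0.12, 0.005, True), (0.09, 1e-5, False), (0.12, 0.01, False)],
)
def test_delta_psi_filter_gates(dpsi, p, significant):
    tpm, events = _psi_inputs({"wt_1": 0.3, "m_1": 0.3 + dpsi})
    evs = compute_psi(tpm, events, {"wt": ["wt_1"], "mut": ["m_1"]}, reference="wt")
    out = delta_psi_filter(evs, "mut", pvalues={"ev1": p})
    assert (len(out) == 1) is significant


def test_delta_psi_boundary_is_strict():
    """|dPSI| exactly 0.1 does not pass the strict > gate."""
    from planticlip.target_integration import PsiEvent

    ev = PsiEvent(event_id="e", gene_id="g",
                  inclusion_isoforms=frozenset({"g.i1"}),
                  all_isoforms=frozenset({"g.i1", "g.i2"}),
                  psi={"wt": 0.25, "mut": 0.35},
                  delta_psi={"mut": 0.1})
    assert delta_psi_filter([ev], "mut", pvalues={"e": 1e-5}) == []


def test_permutation_pvalue_floor_and_separation():
    # 3v3 exhaustive: 20 label splits, identity always counted
    p_same = permutation_psi_pvalue([0.3, 0.3, 0.3], [0.3, 0.3, 0.3])
    assert p_same == 1.0
    p_sep = permutation_psi_pvalue([0.1, 0.11, 0.09], [0.9, 0.91, 0.89])
    assert p_sep == pytest.approx(2 / 20)  # both extreme assignments


def test_psi_complementary_groups_sum_to_one():
    tpm, _ = _psi_inputs({"wt_1": 0.3})
    idx = list(tpm.index)
    events = [
        dict(event_id="in", gene_id="gA", inclusion_isoforms=[idx[0]],
             all_isoforms=idx),
        dict(event_id="out", gene_id="gA", inclusion_isoforms=[idx[1]],
             all_isoforms=idx),
    ]
    evs = compute_psi(tpm, events, {"wt": ["wt_1"]}, reference="wt")
    assert sum(ev.psi["wt"] for ev in evs) == pytest.approx(1.0)
    assert all(0 <= ev.psi["wt"] <= 1 for ev in evs)


def test_gene_list_reader(tmp_path):
    path = tmp_path / "circadian.txt"
    path.write_text("g1\ng2\n\ng3\n")
    ts = read_gene_list(str(path))
    assert ts.members == frozenset({"g1", "g2", "g3"})
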