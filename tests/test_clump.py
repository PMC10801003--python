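"""LD r2, greedy clumping vs a brute-force oracle, the singleton rule,
and catalog co-localization."""

import numpy as np
import pandas as pd
import pytest

import pleionet as pn
from pleionet import clumping as cl
from pleionet.datatypes import MISSING, ClumpParams, QTLRegion, SimConfig

from conftest import make_geno


# ------------------------------------------------------------------- ld_r2

def test_ld_identical_markers():
    g = make_geno(np.array([[0, 0], [1, 1], [2, 2], [1, 1]]))
    assert pn.ld_r2(g, 0, 1) == pytest.approx(1.0)


def test_ld_perfect_negative_correlation():
    g1 = np.array([0, 1, 2, 0, 2])
    g = make_geno(np.column_stack([g1, 2 - g1]))
    assert pn.ld_r2(g, 0, 1) == pytest.approx(1.0)


def test_ld_hand_computed_value():
    g = make_geno(np.column_stack([[0, 0, 1, 2], [0, 1, 1, 2]]))
    assert pn.ld_r2(g, 0, 1) == pytest.approx(8 / 11, abs=1e-12)


def test_ld_monomorphic_is_missing():
    g = make_geno(np.column_stack([[1, 1, 1, 1], [0, 1, 2, 0]]))
    assert np.isnan(pn.ld_r2(g, 0, 1))


def test_ld_missing_dosages_use_shared_samples():
    a = np.array([0, 1, 2, MISSING, 2])
    b = np.array([0, 1, 2, 1, MISSING])
    g = make_geno(np.column_stack([a, b]))
    ok = (a != MISSING) & (b != MISSING)
    expected = np.corrcoef(a[ok], b[ok])[0, 1] ** 2
    assert pn.ld_r2(g, 0, 1) == pytest.approx(expected, abs=1e-12)
    assert pn.pairwise_r2(g, [0], [1])[0, 0] == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------- clump + oracle

def brute_force_clump(assoc, geno, params):
    """Literal greedy clumping: a dict-based reimplementation used as the
    independent oracle."""
    pos = dict(zip(geno.markers["id"], geno.markers["pos"]))
    chrom = dict(zip(geno.markers["id"], geno.markers["chrom"]))
    idx_of = {m: k for k, m in enumerate(geno.markers["id"])}
    rows = assoc.dropna(subset=["p"])
    order = sorted(rows.itertuples(),
                   key=lambda r: (r.p, str(chrom[r.id]), pos[r.id]))
    assigned = set()
    clumps = []
    for row in order:
        if row.p > params.p1 or row.id in assigned:
            continue
        members = [row.id]
        assigned.add(row.id)
        for other in order:
            if other.id in assigned or other.p > params.p2:
                continue
            if chrom[other.id] != chrom[row.id]:
                continue
            if abs(pos[other.id] - pos[row.id]) > params.window_kb * 1000:
                continue
            r2 = pn.ld_r2(geno, idx_of[row.id], idx_of[other.id])
            if np.isfinite(r2) and r2 >= params.r2_min:
                members.append(other.id)
                assigned.add(other.id)
        clumps.append((row.id, frozenset(members)))
    return clumps


def random_instance(seed, n_markers=None):
    rng = np.random.default_rng(seed)
    m = int(n_markers or rng.integers(20, 200))
    geno = pn.simulate_genotypes(SimConfig(
        n_samples=80, n_markers=m + 40,
        chrom_lengths=(("Chr1", 2_000_000), ("Chr2", 2_000_000)),
        maf_min=0.05, seed=seed))
    # random p-values with a spiked tail so some pass p1
    p = rng.uniform(0, 1, geno.n_markers)
    spike = rng.choice(geno.n_markers, size=max(2, geno.n_markers // 10), replace=False)
    p[spike] = 10.0 ** rng.uniform(-9, -2, len(spike))
    assoc = geno.markers[["chrom", "pos", "id"]].copy()
    assoc["p"] = p
    return geno, assoc


@pytest.mark.parametrize("seed", range(20))
def test_clump_matches_brute_force_oracle(seed):
    geno, assoc = random_instance(seed)
    params = ClumpParams(p1=1e-4, p2=1e-2, window_kb=300, r2_min=0.3)
    got = pn.clump(assoc, geno, params)
    ids = geno.markers["id"]
    got_sets = {(ids.iloc[c.index_marker], frozenset(ids.iloc[m] for m in c.members))
                for c in got}
    oracle = set(brute_force_clump(assoc, geno, params))
    assert got_sets == oracle


def test_single_marker_clump():
    geno, assoc = random_instance(3)
    assoc["p"] = 1.0
    assoc.loc[5, "p"] = 1e-8
    clumps = pn.clump(assoc, geno, ClumpParams())
    assert len(clumps) == 1
    assert clumps[0].members == [clumps[0].index_marker]


def test_two_linked_markers_form_one_clump():
    dup = np.repeat(np.random.default_rng(0).integers(0, 3, size=(40, 1)), 2, axis=1)
    geno = make_geno(dup, positions=[10_000, 20_000])
    assoc = geno.markers[["chrom", "pos", "id"]].copy()
    assoc["p"] = [1e-6, 1e-8]
    clumps = pn.clump(assoc, geno, ClumpParams())
    assert len(clumps) == 1
    assert geno.markers["pos"].iloc[clumps[0].index_marker] == 20_000
    assert len(clumps[0].members) == 2


def test_clump_no_marker_passing_p1_returns_empty():
    geno, assoc = random_instance(4)
    assoc["p"] = 0.5
    assert pn.clump(assoc, geno, ClumpParams()) == []


def test_clump_partition_and_index_minimality():
    geno, assoc = random_instance(7)
    params = ClumpParams(p1=1e-3, p2=1e-1, window_kb=500, r2_min=0.2)
    clumps = pn.clump(assoc, geno, params)
    p = dict(zip(assoc["id"], assoc["p"]))
    ids = geno.markers["id"]
    seen = []
    for c in clumps:
        seen.extend(c.members)
        idx_p = p[ids.iloc[c.index_marker]]
        assert all(idx_p <= p[ids.iloc[m]] for m in c.members)
    assert len(seen) == len(set(seen))


def test_threshold_monotonicity():
    geno, assoc = random_instance(9)
    loose = ClumpParams(p1=1e-4, p2=1e-1, window_kb=300, r2_min=0.3)
    tight = ClumpParams(p1=1e-4, p2=1e-3, window_kb=300, r2_min=0.3)
    n_loose = {c.index_marker: len(c.members) for c in pn.clump(assoc, geno, loose)}
    n_tight = {c.index_marker: len(c.members) for c in pn.clump(assoc, geno, tight)}
    for idx, n in n_tight.items():
        assert n_loose.get(idx, 0) >= n
    stricter_p1 = ClumpParams(p1=1e-6, p2=1e-1, window_kb=300, r2_min=0.3)
    assert len(pn.clump(assoc, geno, stricter_p1)) <= len(pn.clump(assoc, geno, loose))


# --------------------------------------------------------- singleton filter

def _clump_with_support(n_support, n_members=5):
    """A clump of n_members identical markers; n_support of the interval's
    markers sit below the singleton p threshold."""
    rng = np.random.default_rng(1)
    base = rng.integers(0, 3, size=(60, 1))
    dos = np.repeat(base, n_members, axis=1)
    geno = make_geno(dos, positions=[10_000 * (j + 1) for j in range(n_members)])
    assoc = geno.markers[["chrom", "pos", "id"]].copy()
    pvals = np.full(n_members, 1e-6)
    pvals[n_support:] = 1e-3  # above singleton_p but below p2
    assoc["p"] = pvals
    params = ClumpParams(singleton_p=2.5e-4, singleton_min_snps=5)
    clumps = pn.clump(assoc, geno, params)
    assert len(clumps) == 1
    return pn.apply_singleton_filter(clumps, assoc, geno, params, trait="T")


def test_singleton_five_supporting_snps_retained():
    regions = _clump_with_support(n_support=5)
    assert len(regions) == 1
    assert regions[0].min_p == pytest.approx(1e-6)


def test_singleton_four_supporting_snps_dropped():
    assert _clump_with_support(n_support=4) == []


def test_single_member_clump_dropped():
    geno, assoc = random_instance(5)
    assoc["p"] = 1.0
    assoc.loc[10, "p"] = 1e-9
    params = ClumpParams()
    regions = pn.apply_singleton_filter(pn.clump(assoc, geno, params),
                                        assoc, geno, params, trait="T")
    assert regions == []


def test_region_interval_is_member_span():
    regions = _clump_with_support(n_support=5)
    r = regions[0]
    assert (r.start, r.end) == (10_000, 50_000)
    assert r.start <= r.end


# ------------------------------------------------------------- colocalize

def qtl(id, trait, chrom, start, end, p=1e-8):
    return QTLRegion(id=id, trait=trait, chrom=chrom, start=start, end=end,
                     index_marker="m", member_markers=["m"], min_p=p)


def test_colocalize_overlapping_interval():
    qtls = [qtl("qPH_1", "PH", "Chr19", 44_629_039, 45_425_935)]
    catalog = pd.DataFrame([
        {"chrom": "Chr19", "start": 45_000_000, "end": 46_000_000, "name": "known1"},
    ])
    report, counts = pn.colocalize(qtls, catalog)
    assert report["co_located"].iloc[0]
    assert counts == {"co_located": 1, "novel": 0, "total": 1}


def test_colocalize_abutting_intervals_do_not_overlap():
    qtls = [qtl("q1", "T", "Chr1", 100, 200)]
    catalog = pd.DataFrame([{"chrom": "Chr1", "start": 201, "end": 300, "name": "k"}])
    report, counts = pn.colocalize(qtls, catalog)
    assert not report["co_located"].iloc[0]
    assert counts["novel"] == 1


def test_colocalize_containment():
    qtls = [qtl("q1", "T", "Chr1", 100, 1000)]
    catalog = pd.DataFrame([{"chrom": "Chr1", "start": 400, "end": 500, "name": "k"}])
    report, _ = pn.colocalize(qtls, catalog)
    assert report["co_located"].iloc[0]


def test_colocalize_unknown_chromosome_skipped(caplog):
    qtls = [qtl("q1", "T", "Chr1", 100, 1000)]
    catalog = pd.DataFrame([{"chrom": "ChrZ", "start": 100, "end": 500, "name": "k"}])
    with caplog.at_level("WARNING"):
        report, counts = pn.colocalize(qtls, catalog)
    assert "ChrZ" in caplog.text
    assert counts["co_located"] == 0


# ------------------------------------------------- environment-level merge

def test_merge_environment_regions_union_and_env_list():
    a = qtl("qT_1", "T", "Chr1", 100, 500, p=1e-8)
    a.environments = ("E1",)
    b = qtl("qT_2", "T", "Chr1", 400, 900, p=1e-6)
    b.environments = ("BLUE",)
    c = qtl("qT_3", "T", "Chr2", 100, 200, p=1e-7)
    merged = pn.merge_environment_regions([a, b, c])
    by_chrom = {m.chrom: m for m in merged}
    assert len(merged) == 2
    assert (by_chrom["Chr1"].start, by_chrom["Chr1"].end) == (100, 900)
    assert set(by_chrom["Chr1"].environments) == {"E1", "BLUE"}
    assert by_chrom["Chr1"].min_p == pytest.approx(1e-8)
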