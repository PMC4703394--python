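"""Sliding-window enrichment scan, merging, and classification."""

from math import comb

import numpy as np
import pytest

from tnspore.genome import GeneAnnotation, InsertionLibrary, find_ta_sites
from tnspore.windows import (EnrichedRegion, WindowResult, classify_region,
                             eligible_sites, merge_windows, scan)

from conftest import library_from_vector, spaced_ta_genome


@pytest.fixture
def track_index():
    return find_ta_sites(spaced_ta_genome(40))


def _track(index, ref_vec, sel_vec):
    ref = library_from_vector(index, ref_vec, "T0")
    sel = library_from_vector(index, sel_vec, "T5")
    return eligible_sites(ref, sel, index)


def test_eligible_sites_require_reads_in_both(track_index):
    ref = np.zeros(40, int)
    sel = np.zeros(40, int)
    ref[:20] = 5
    sel[20:] = 5
    assert len(_track(track_index, ref, sel)) == 0

    ref[:] = 3
    sel[:] = 7
    track = _track(track_index, ref, sel)
    assert track.positions.tolist() == track_index.positions.tolist()


def test_eligible_sites_match_set_oracle(track_index, rng):
    ref = rng.integers(0, 3, 40)
    sel = rng.integers(0, 3, 40)
    track = _track(track_index, ref, sel)
    expected = {int(p) for p, r, s in zip(track_index.positions, ref, sel)
                if r >= 1 and s >= 1}
    assert set(track.positions.tolist()) == expected


def test_identical_libraries_give_no_significant_windows(track_index, rng):
    v = rng.integers(1, 50, 40)
    windows = scan(_track(track_index, v, v))
    assert windows and not any(w.significant for w in windows)


def hypergeom_tail_p(k_window: int, n_high: int, window: int = 13) -> float:
    """Exact two-sided window p for the exact-tie construction.

    With the window's null sites exactly equal to their reference values and
    ``n_high`` enriched sites shared between both groups of size ``window``,
    the permutation rank-sum depends only on how many enriched values land
    in the selected group, which is hypergeometric.
    """
    N, K, n = 2 * window, n_high, window
    total = comb(N, n)
    dev_obs = abs(k_window - K * n / N)
    p = 0
    for x in range(max(0, n - (N - K)), min(K, n) + 1):
        if abs(x - K * n / N) >= dev_obs - 1e-9:
            p += comb(K, x) * comb(N - K, n - x)
    return p / total


def test_enriched_segment_detected_with_oracle_window_set():
    """40 eligible sites, a run of 13 (indices 9..21) carrying 10x selected
    signal on an otherwise exactly tied track: the significant windows are
    exactly those whose exact p and fold clear the thresholds, computed here
    by an independent hypergeometric closed form."""
    from tnspore.windows import EligibleSiteTrack
    positions = find_ta_sites(spaced_ta_genome(40)).positions
    ref = np.full(40, 10.0)
    sel = np.full(40, 10.0)
    enriched = set(range(9, 22))
    sel[list(enriched)] = 100.0
    track = EligibleSiteTrack(positions, ref, sel)
    windows = scan(track, window_size=13, p_max=0.02, fold_min_enrich=3.0)

    expected_sig = []
    for i in range(40 - 13 + 1):
        k = len(enriched & set(range(i, i + 13)))
        fold = (k * 100 + (13 - k) * 10) / (13 * 10)
        p = hypergeom_tail_p(k, k) if k else 1.0
        expected_sig.append(p <= 0.02 and fold >= 3.0)
    assert any(expected_sig) and not all(expected_sig)
    got_sig = [w.significant for w in windows]
    assert got_sig == expected_sig
    # the enriched core is covered by one merged region
    regions = merge_windows(windows)
    assert len(regions) == 1
    r = regions[0]
    assert r.start <= int(positions[9])
    assert r.end >= int(positions[21]) + 1


def test_window_p_matches_hypergeometric_oracle():
    from tnspore.windows import EligibleSiteTrack
    positions = find_ta_sites(spaced_ta_genome(13)).positions
    for k in (3, 6, 10, 13):
        ref = np.full(13, 10.0)
        sel = np.full(13, 10.0)
        sel[:k] = 100.0
        w = scan(EligibleSiteTrack(positions, ref, sel))[0]
        assert w.p_value == pytest.approx(hypergeom_tail_p(k, k), rel=1e-9)


def test_significance_requires_both_thresholds(track_index, rng):
    v = rng.integers(5, 15, 40)
    sel = v.copy()
    sel[:13] = v[:13] * 10
    track = _track(track_index, v, sel)
    # absurdly strict p threshold: fold clears, p cannot
    windows = scan(track, p_max=1e-12, fold_min_enrich=3.0)
    assert not any(w.significant for w in windows)
    # fold threshold above the enrichment: p clears, fold cannot
    windows = scan(track, p_max=0.02, fold_min_enrich=50.0)
    assert not any(w.significant for w in windows)


def test_short_track_warns_and_returns_empty(track_index, rng):
    v = np.zeros(40, int)
    v[:5] = 3
    with pytest.warns(UserWarning, match="window size"):
        assert scan(_track(track_index, v, v)) == []


def test_scan_invariant_to_depth_scaling(track_index, rng):
    ref = rng.integers(1, 30, 40)
    sel = rng.integers(1, 30, 40)
    a = scan(_track(track_index, ref, sel))
    b = scan(_track(track_index, ref * 9, sel))
    for wa, wb in zip(a, b):
        assert wa.p_value == pytest.approx(wb.p_value)
        assert wa.fold_enrichment == pytest.approx(wb.fold_enrichment)
        assert wa.significant == wb.significant


def _mk_window(i, sig, positions, w=13):
    return WindowResult(first_pos=int(positions[i]),
                        last_pos=int(positions[i + w - 1]), start_index=i,
                        window_size=w, p_value=0.01 if sig else 0.5,
                        fold_enrichment=5.0 if sig else 1.0, significant=sig)


def test_merge_windows_against_interval_union_oracle(rng):
    positions = find_ta_sites(spaced_ta_genome(60)).positions
    w = 13
    for _ in range(100):
        mask = rng.random(60 - w + 1) < 0.15
        windows = [_mk_window(i, bool(m), positions) for i, m in enumerate(mask)]
        regions = merge_windows(windows)
        # oracle: union of [i, i+w-1] index intervals of significant windows
        covered = set()
        for i, m in enumerate(mask):
            if m:
                covered.update(range(i, i + w))
        runs = []
        for i in sorted(covered):
            if runs and i <= runs[-1][1] + 1:
                runs[-1][1] = i
            else:
                runs.append([i, i])
        assert len(regions) == len(runs)
        for r, (lo, hi) in zip(regions, runs):
            assert r.first_site_index == lo and r.last_site_index == hi
            assert r.start == int(positions[lo])
            assert r.end == int(positions[hi]) + 1
        assert sum(r.member_window_count for r in regions) == int(mask.sum())


def test_merge_two_disjoint_windows(track_index):
    positions = track_index.positions
    windows = [_mk_window(0, True, positions), _mk_window(20, True, positions),
               _mk_window(5, False, positions)]
    regions = merge_windows(windows)
    assert len(regions) == 2


@pytest.mark.parametrize("gene,expected", [
    (GeneAnnotation("body", "body", 900, 1500, "+"), ("intragenic", "body")),
    (GeneAnnotation("down_plus", "down_plus", 1300, 1900, "+"), ("upstream", "down_plus")),
    (GeneAnnotation("down_minus", "down_minus", 200, 880, "-"), ("upstream", "down_minus")),
    (GeneAnnotation("far", "far", 5000, 6000, "+"), ("unassigned", None)),
])
def test_classify_region(gene, expected):
    region = EnrichedRegion(start=1000, end=1100, peak_fold=5.0, min_p=0.001,
                            member_window_count=3, first_site_index=0,
                            last_site_index=12)
    classify_region(region, [gene], upstream_bp=500)
    assert (region.classification, region.gene) == expected
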