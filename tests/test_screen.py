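"""Per-gene depletion screen: normalization, fold change, flags, thresholds."""

import numpy as np
import pytest

from tnspore.genome import GeneAnnotation, InsertionLibrary
from tnspore.screen import (NORM_SCALE, ScreenConfig, fold_change, normalize,
                            results_table, run_screen, volcano_table)
from tnspore.screen import GeneDepletionResult

from conftest import library_from_vector, spaced_ta_genome
from tnspore.genome import find_ta_sites


@pytest.fixture
def spaced_index():
    # 60 TA sites at positions 2, 6, ..., well separated
    return find_ta_sites(spaced_ta_genome(60))


def _genes_over_sites(index, genes_sites):
    """Build gene annotations covering runs of TA sites by index."""
    out = []
    for name, (i0, i1) in genes_sites.items():
        start = int(index.positions[i0]) - 1
        end = int(index.positions[i1]) + 2
        out.append(GeneAnnotation(name, name, start, end))
    return out


def test_normalize_identities(spaced_index, rng):
    ref = library_from_vector(spaced_index, rng.integers(1, 50, 60), "T0")
    sel = library_from_vector(spaced_index, rng.integers(1, 50, 60), "T24")
    rn, sn = normalize(ref, sel, spaced_index)
    assert rn.sum() == pytest.approx(NORM_SCALE)
    assert sn.sum() == pytest.approx(NORM_SCALE)
    # doubling every count of one library leaves its normalized vector fixed
    doubled = InsertionLibrary("T24", {p: 2 * c for p, c in sel.counts.items()})
    _rn2, sn2 = normalize(ref, doubled, spaced_index)
    assert np.allclose(sn, sn2)


def test_normalize_rejects_empty_library(spaced_index):
    ref = library_from_vector(spaced_index, np.ones(60), "T0")
    with pytest.raises(ValueError, match="zero mapped reads"):
        normalize(ref, InsertionLibrary("T24", {}), spaced_index)


def test_fold_change_rules():
    f, raw, flag = fold_change(1000, 40)
    assert f == pytest.approx(1001 / 41) and raw == pytest.approx(25.0)
    assert not flag
    assert fold_change(5, 5)[0] == 1.0
    f, raw, flag = fold_change(500, 0)
    assert f == pytest.approx(501.0) and raw == np.inf and flag


def _two_lib_screen(index, genes, ref_vec, sel_vec, config=None):
    ref = library_from_vector(index, ref_vec, "T0")
    sel = library_from_vector(index, sel_vec, "T24")
    return run_screen(ref, sel, genes, index, config or ScreenConfig())


def test_threshold_semantics(spaced_index, rng):
    """Significant p with fold below the cutoff is not a hit, and vice versa."""
    genes = _genes_over_sites(spaced_index, {"gA": (0, 19), "gB": (20, 39),
                                             "filler": (40, 59)})
    ref = np.concatenate([rng.integers(90, 111, 20),
                          rng.integers(90, 111, 20),
                          rng.integers(90, 111, 20)])
    sel = ref.copy()
    sel[:20] = (ref[:20] / 1.8).astype(int)       # clear shift, fold < 2
    sel[20:40] = (ref[20:40] * 0.01).astype(int)  # strong depletion
    res = {r.gene: r for r in _two_lib_screen(spaced_index, genes, ref, sel)}
    # normalization rescales; compare against the joint rule
    gA = res["gA"]
    assert gA.p_value < 0.05 and gA.fold_change < 2 and not gA.is_hit
    gB = res["gB"]
    assert gB.p_value < 0.05 and gB.fold_change > 2 and gB.is_hit


def test_low_coverage_flag_blocks_hit(spaced_index):
    genes = _genes_over_sites(spaced_index, {"sparse": (0, 19),
                                             "filler": (20, 59)})
    ref = np.zeros(60, int)
    ref[[2, 5, 8]] = 200            # only 3 occupied sites in "sparse"
    ref[20:] = 100
    sel = np.zeros(60, int)
    sel[20:] = 100
    res = {r.gene: r for r in _two_lib_screen(spaced_index, genes, ref, sel)}
    r = res["sparse"]
    assert "low_coverage" in r.flags and not r.is_hit


def test_dispersed_flag(spaced_index, rng):
    """Modest (<3x) reduction with insertions retained across the ORF."""
    genes = _genes_over_sites(spaced_index, {"gD": (0, 29), "filler": (30, 59)})
    ref = rng.integers(80, 121, 60)
    sel = ref.copy()
    sel[:30] = (ref[:30] * 0.45).astype(int)   # every site stays occupied
    res = {r.gene: r for r in _two_lib_screen(spaced_index, genes, ref, sel)}
    r = res["gD"]
    assert r.fold_change < 3 and "dispersed" in r.flags


def test_depth_scaling_invariance(spaced_index, rng):
    genes = _genes_over_sites(spaced_index, {"g1": (0, 19), "g2": (20, 39),
                                             "g3": (40, 59)})
    ref_vec = rng.integers(0, 60, 60)
    sel_vec = rng.integers(0, 60, 60)
    base = _two_lib_screen(spaced_index, genes, ref_vec, sel_vec)
    scaled = _two_lib_screen(spaced_index, genes, ref_vec * 13, sel_vec)
    for a, b in zip(base, scaled):
        assert a.gene == b.gene
        assert a.p_value == pytest.approx(b.p_value)
        assert a.u_stat == pytest.approx(b.u_stat)
        assert a.fold_change == pytest.approx(b.fold_change)
        assert a.is_hit == b.is_hit and a.flags == b.flags


def test_label_swap_reciprocity(spaced_index, rng):
    genes = _genes_over_sites(spaced_index, {"g1": (0, 29), "g2": (30, 59)})
    ref_vec = rng.integers(1, 60, 60)
    sel_vec = rng.integers(1, 60, 60)
    fwd = _two_lib_screen(spaced_index, genes, ref_vec, sel_vec)
    rev = _two_lib_screen(spaced_index, genes, sel_vec, ref_vec)
    for a in fwd:
        b = next(r for r in rev if r.gene == a.gene)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-9)
        assert a.raw_ratio == pytest.approx(1 / b.raw_ratio, rel=1e-9)


def test_results_sorted_by_p_and_row_count(spaced_index, rng):
    genes = _genes_over_sites(spaced_index, {"g1": (0, 19), "g2": (20, 39),
                                             "g3": (40, 59)})
    res = _two_lib_screen(spaced_index, genes, rng.integers(0, 40, 60),
                          rng.integers(0, 40, 60))
    ps = [r.p_value for r in res]
    assert ps == sorted(ps)
    df = results_table(res)
    assert len(df) == len(genes)
    assert list(df.columns)[:11] == ["gene", "locus_tag", "n_ta_sites",
                                     "t_ref_reads", "t_sel_reads",
                                     "fold_change", "u_stat", "p_value",
                                     "neg_log10_p", "flags", "is_hit"]


def test_gene_without_sites_is_flagged(spaced_index, rng):
    # a gene squeezed between two TA sites contains none
    lo = int(spaced_index.positions[0]) + 2
    genes = [GeneAnnotation("empty", "empty", lo, lo + 1),
             GeneAnnotation("ok", "ok", 1, int(spaced_index.positions[-1]) + 2)]
    res = _two_lib_screen(spaced_index, genes, rng.integers(1, 9, 60),
                          rng.integers(1, 9, 60))
    r = next(x for x in res if x.gene == "empty")
    assert "no_ta_sites" in r.flags and not r.is_hit and np.isnan(r.p_value)


def test_volcano_table_caps_and_values():
    rows = [
        GeneDepletionResult(gene="a", locus_tag="a", n_ta_sites=5,
                            t_ref_reads=10, t_sel_reads=10, t_ref_norm=10.0,
                            t_sel_norm=10.0, fold_change=1.0, raw_ratio=1.0,
                            u_stat=12.0, p_value=0.05),
        GeneDepletionResult(gene="b", locus_tag="b", n_ta_sites=5,
                            t_ref_reads=10, t_sel_reads=0, t_ref_norm=10.0,
                            t_sel_norm=0.0, fold_change=11.0,
                            raw_ratio=np.inf, u_stat=25.0, p_value=0.0),
    ]
    df = volcano_table(rows)
    assert df.loc[df.gene == "a", "neg_log10_p"].item() == pytest.approx(1.301, abs=1e-3)
    assert df.loc[df.gene == "b", "neg_log10_p"].item() == 320.0
    assert bool(df.loc[df.gene == "b", "p_capped"].item())
    assert len(df) == 2


def test_bh_column_is_optional(spaced_index, rng):
    genes = _genes_over_sites(spaced_index, {"g1": (0, 29), "g2": (30, 59)})
    res = _two_lib_screen(spaced_index, genes, rng.integers(1, 30, 60),
                          rng.integers(1, 30, 60))
    assert "bh_q" not in results_table(res).columns
    df = results_table(res, with_bh=True)
    assert "bh_q" in df.columns and (df["bh_q"] >= df["p_value"] - 1e-12).all()
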