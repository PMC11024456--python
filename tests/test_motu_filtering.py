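"""Global/per-sample MOTU filters, taxonomic scope, control screening."""

import numpy as np
import pandas as pd
import pytest

from metadiet import (ReplicateTable, SimConfig, default_markers, filter_global,
                      filter_min_proportion, filter_taxonomic_scope,
                      screen_controls, simulate_study)
from metadiet.motu_filtering import positive_control_leakage
from metadiet.tables_io import MotuRecord


def _rec(mid, length=50, clade="Spermatophyta", category="plant"):
    fg = "forb" if category == "plant" else "none"
    return MotuRecord(mid, "Sper01", length,
                      (("phylum", clade),), dietary_category=category,
                      functional_group=fg)


def _table(counts, motus):
    ids = [f"s{i+1}_R1" for i in range(np.shape(counts)[0])]
    df = pd.DataFrame(counts, index=ids, columns=motus)
    return ReplicateTable(counts=df,
                          replicate_to_sample={r: r.split("_")[0] for r in ids},
                          marker_id="Sper01")


class TestFilterGlobal:
    def test_total_read_boundary(self):
        # dataset-wide total of exactly 10 reads is dropped; 11 is kept
        t = _table([[10, 11]], ["m10", "m11"])
        recs = {"m10": _rec("m10"), "m11": _rec("m11")}
        out = filter_global(t, recs)
        assert out.motu_ids == ["m11"]

    def test_length_boundary(self):
        # 9 bp dropped, 10 bp kept
        t = _table([[100, 100]], ["short", "ok"])
        recs = {"short": _rec("short", length=9), "ok": _rec("ok", length=10)}
        out = filter_global(t, recs)
        assert out.motu_ids == ["ok"]

    def test_empty_table(self):
        t = _table(np.zeros((1, 0), dtype=int), [])
        out = filter_global(t, {})
        assert out.counts.shape == (1, 0)

    def test_idempotent_and_criterion_order_independent(self):
        rng = np.random.default_rng(0)
        t = _table(rng.integers(0, 30, (4, 6)), [f"m{i}" for i in range(6)])
        recs = {f"m{i}": _rec(f"m{i}", length=(5 if i % 3 == 0 else 20))
                for i in range(6)}
        once = filter_global(t, recs)
        twice = filter_global(once, recs)
        assert once.motu_ids == twice.motu_ids
        # applying length-only then reads-only equals the combined filter
        len_first = filter_global(t, recs, min_len=10, min_total_reads=0)
        both = filter_global(len_first, recs, min_len=0, min_total_reads=10)
        assert both.motu_ids == once.motu_ids


class TestFilterMinProportion:
    def test_hand_computed_renormalization(self):
        tbl = pd.DataFrame([[0.005, 0.495, 0.50]], index=["s1"], columns=list("abc"))
        out, empty = filter_min_proportion(tbl, 0.01)
        assert empty == []
        assert "a" not in out.columns
        assert out.loc["s1", "b"] == pytest.approx(0.495 / 0.995, abs=1e-12)
        assert out.loc["s1", "c"] == pytest.approx(0.50 / 0.995, abs=1e-12)

    def test_column_dropped_when_below_everywhere(self):
        tbl = pd.DataFrame([[0.004, 0.996], [0.006, 0.994]],
                           index=["s1", "s2"], columns=["rare", "common"])
        out, _ = filter_min_proportion(tbl, 0.01)
        assert list(out.columns) == ["common"]

    def test_noop_when_all_entries_above_threshold(self):
        tbl = pd.DataFrame([[0.3, 0.7], [0.5, 0.5]], index=["s1", "s2"],
                           columns=["a", "b"])
        out, _ = filter_min_proportion(tbl, 0.01)
        assert np.abs(out.to_numpy() - tbl.to_numpy()).max() < 1e-12

    def test_idempotent_and_entries_at_least_threshold(self):
        rng = np.random.default_rng(8)
        tbl = pd.DataFrame(rng.dirichlet(np.full(30, 0.3), size=10))
        tbl.columns = [f"m{i}" for i in range(30)]
        once, _ = filter_min_proportion(tbl, 0.01)
        twice, _ = filter_min_proportion(once, 0.01)
        assert np.abs(once.reindex(columns=twice.columns).to_numpy()
                      - twice.to_numpy()).max() < 1e-12
        nz = once.to_numpy()[once.to_numpy() > 0]
        assert nz.min() >= 0.01
        assert (once.to_numpy() > 0).sum() <= (tbl.to_numpy() > 0).sum()

    def test_emptied_rows_flagged_and_kept(self):
        tbl = pd.DataFrame([[0.004] * 250], index=["s1"],
                           columns=[f"m{i}" for i in range(250)])
        tbl = tbl.div(tbl.sum(axis=1), axis=0)
        out, empty = filter_min_proportion(tbl, 0.01)
        assert empty == ["s1"]
        assert "s1" in out.index


class TestTaxonomicScope:
    def test_out_of_scope_motu_dropped(self):
        t = _table([[5, 5]], ["plantA", "fungusB"])
        recs = {"plantA": _rec("plantA"),
                "fungusB": _rec("fungusB", clade="Agaricomycetes", category="mushroom")}
        out = filter_taxonomic_scope(t, recs, default_markers()["Sper01"])
        assert out.motu_ids == ["plantA"]

    def test_fungal_marker_keeps_both_clades(self):
        t = _table([[5, 5, 5]], ["mush", "lich", "plant"])
        recs = {"mush": _rec("mush", clade="Agaricomycetes", category="mushroom"),
                "lich": _rec("lich", clade="Lecanoromycetes", category="lichen"),
                "plant": _rec("plant")}
        out = filter_taxonomic_scope(t, recs, default_markers()["Fung01"])
        assert sorted(out.motu_ids) == ["lich", "mush"]

    def test_in_scope_table_unchanged(self):
        t = _table([[3, 4]], ["p1", "p2"])
        recs = {m: _rec(m) for m in ["p1", "p2"]}
        out = filter_taxonomic_scope(t, recs, default_markers()["Sper01"])
        pd.testing.assert_frame_equal(out.counts, t.counts)

    def test_missing_lineage_treated_out_of_scope(self):
        t = _table([[3, 4]], ["p1", "nolineage"])
        recs = {"p1": _rec("p1"),
                "nolineage": MotuRecord("nolineage", "Sper01", 50, ())}
        out = filter_taxonomic_scope(t, recs, default_markers()["Sper01"])
        assert out.motu_ids == ["p1"]

    def test_works_on_sample_tables(self):
        tbl = pd.DataFrame([[0.5, 0.5]], index=["s1"], columns=["p1", "x"])
        recs = {"p1": _rec("p1"), "x": _rec("x", clade="Arthropoda", category="arthropod")}
        out = filter_taxonomic_scope(tbl, recs, default_markers()["Sper01"])
        assert list(out.columns) == ["p1"]


class TestControls:
    def test_no_controls_warns_empty(self):
        t = _table([[5]], ["m1"])
        rep = screen_controls(t)
        assert rep.warning
        assert rep.negative_flags == []

    def test_positive_control_recovery_and_failure(self, small_study):
        t = small_study.tables["Sper01"]
        rep = screen_controls(t, records=small_study.records["Sper01"])
        assert rep.positive_recovered is True
        # zero out the positive control sequence -> control failure
        broken = t.counts.copy()
        broken.loc["CTRLPOS_Sper01_R1", "POSCTRL_Sper01"] = 0
        t2 = ReplicateTable(counts=broken, replicate_to_sample=t.replicate_to_sample,
                            marker_id=t.marker_id, control_flags=t.control_flags)
        rep2 = screen_controls(t2, records=small_study.records["Sper01"])
        assert rep2.positive_recovered is False
        assert "CTRLPOS_Sper01_R1" in rep2.control_failures

    def test_clean_negatives_not_flagged(self, small_study):
        cfg = SimConfig(n_per_cell=2, seed=21, tag_jump_rate=0.0)
        study = simulate_study(cfg)
        rep = screen_controls(study.tables["Sper01"], records=study.records["Sper01"])
        assert rep.negative_flags == []

    def test_tag_jump_rate_recovered_from_positive_controls(self):
        cfg = SimConfig(n_per_cell=7, species=("bank",), seed=99,
                        tag_jump_rate=0.02, outlier_replicate_rate=0.0,
                        replicate_failure_rate=0.0, reads_mean=2000.0,
                        junk_motus_per_marker=0)
        study = simulate_study(cfg)
        leak = positive_control_leakage(study.tables["Sper01"])
        assert leak == pytest.approx(0.02, abs=0.01)
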