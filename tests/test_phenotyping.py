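import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from timeprox import (AnalysisConfig, CellTable, assign_memberships,
                      compute_gates, compute_tertiles, enumerate_taxonomy,
                      gate_positivity)
from timeprox.phenotyping import (INDEX_LABEL, LINEAGES, SELECTORS,
                                  assign_levels, label_for)
from tests.test_io import make_cells


class TestTaxonomy:
    def test_exactly_88_unique_labels(self):
        labels = enumerate_taxonomy()
        assert len(labels) == 88
        assert len(set(labels)) == 88

    def test_lineage_major_order(self):
        labels = enumerate_taxonomy()
        assert labels[:11] == [label_for("CD8+", s) for s in SELECTORS]

    def test_named_subsets_present(self):
        labels = enumerate_taxonomy()
        # the index subset and its PD-1-high refinement
        assert "CD8+FoxP3+_PD1+" in labels
        assert "CD8+FoxP3+_PD1high" in labels
        # checkpoint-positive cells with no lineage marker
        assert "other_PD1+" in labels
        assert "other_PDL1+" in labels


class TestGating:
    def test_threshold_inclusive(self):
        df = make_cells(2)
        df.loc[0, "intensity_CD8"] = 5.0
        df.loc[1, "intensity_CD8"] = 4.99
        flags = gate_positivity(CellTable(df), {m: 5.0 for m in
                                                ("panCK", "CD163", "CD8", "FoxP3", "PD1", "PDL1")})
        assert flags["CD8"].tolist() == [True, False]

    def test_all_zero_slide_is_all_other(self, config):
        df = make_cells(4)
        for c in df.columns:
            if c.startswith("intensity_"):
                df[c] = 0.0
        table = CellTable(df)
        gates = compute_gates([table], config)
        mm = assign_memberships(table, gates, config)
        counts = mm.counts()
        assert counts["other_any"] == 4
        for lin in LINEAGES[:-1]:
            assert counts[label_for(lin, "any")] == 0


class TestTertiles:
    def test_nine_point_example(self):
        q = compute_tertiles(np.arange(1.0, 10.0))
        assert q == pytest.approx((11 / 3, 19 / 3))
        lev = assign_levels(np.arange(1.0, 10.0), np.ones(9, bool), q)
        assert list(lev) == ["low"] * 3 + ["mid"] * 3 + ["high"] * 3

    def test_identical_values_all_low(self):
        vals = np.full(10, 7.0)
        q = compute_tertiles(vals)
        lev = assign_levels(vals, np.ones(10, bool), q)
        assert set(lev) == {"low"}

    def test_fewer_than_three_degenerate(self):
        with pytest.warns(UserWarning, match="tertiles undefined"):
            q = compute_tertiles(np.array([10.0, 20.0]))
        assert q is None
        lev = assign_levels(np.array([10.0, 20.0]), np.ones(2, bool), q)
        assert list(lev) == ["low", "low"]

    @given(st.lists(st.floats(min_value=0.1, max_value=1e6), min_size=3,
                    max_size=60, unique=True))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_partition_sizes_balanced_when_distinct(self, values):
        vals = np.asarray(values)
        lev = assign_levels(vals, np.ones(len(vals), bool), compute_tertiles(vals))
        sizes = [int((lev == g).sum()) for g in ("low", "mid", "high")]
        assert sum(sizes) == len(vals)
        assert max(sizes) - min(sizes) <= 1


def _one_cell_table(intensities):
    df = make_cells(1)
    for m, v in intensities.items():
        df[f"intensity_{m}"] = v
    return CellTable(df)


class TestMembership:
    def test_hand_enumerated_double_positive(self, config):
        # CD8+FoxP3+, PD-1 in the top tertile, PD-L1 negative.  Tertile
        # boundaries come from a pooled reference population of 9 cells.
        ref = make_cells(9, slide="ref")
        ref["intensity_PD1"] = np.arange(10.0, 19.0)
        cell = _one_cell_table({"CD8": 10.0, "FoxP3": 10.0, "PD1": 18.5})
        gates = compute_gates([CellTable(ref), cell], config)
        mm = assign_memberships(cell, gates, config)
        expected = {label_for(lin, sel)
                    for lin in ("CD8+", "CD8+FoxP3+", "FoxP3+")
                    for sel in ("any", "PD1+", "PD1high", "PDL1-")}
        got = {l for l in mm.labels if mm.matrix[l].iloc[0]}
        assert got == expected

    def test_lineage_negative_pdl1_positive_cell(self, config):
        cell = _one_cell_table({"PDL1": 50.0})
        with pytest.warns(UserWarning):  # <3 positives: degenerate tertiles
            gates = compute_gates([cell], config)
        mm = assign_memberships(cell, gates, config)
        got = {l for l in mm.labels if mm.matrix[l].iloc[0]}
        assert got == {label_for("other", s)
                       for s in ("any", "PDL1+", "PDL1low", "PD1-")}

    def test_empty_slide_all_zero(self, config):
        table = CellTable(make_cells(0))
        with pytest.warns(UserWarning):
            gates = compute_gates([table], config)
        mm = assign_memberships(table, gates, config)
        assert mm.matrix.shape == (0, 88)

    def test_count_identities_on_simulated_slide(self, config, small_cohort):
        sid = next(iter(small_cohort.slides))
        table = small_cohort.slides[sid]
        gates = compute_gates([table], config)
        mm = assign_memberships(table, gates, config)
        c = mm.counts()
        assert c["CD8+_any"] == c["CD8+FoxP3-_any"] + c["CD8+FoxP3+_any"]
        assert c["FoxP3+_any"] == c["CD8+FoxP3+_any"] + c["CD8-FoxP3+_any"]
        for lin in LINEAGES:
            for cp in ("PD1", "PDL1"):
                any_ = c[label_for(lin, "any")]
                assert any_ == c[label_for(lin, f"{cp}-")] + c[label_for(lin, f"{cp}+")]
                assert c[label_for(lin, f"{cp}+")] == sum(
                    c[label_for(lin, f"{cp}{l}")] for l in ("low", "mid", "high"))

    def test_row_permutation_equivariance(self, config, small_cohort):
        sid = next(iter(small_cohort.slides))
        df = small_cohort.slides[sid].df
        perm = np.random.default_rng(0).permutation(len(df))
        t1 = CellTable(df, validate=False)
        t2 = CellTable(df.iloc[perm].reset_index(drop=True), validate=False)
        gates = compute_gates([t1], config)
        m1 = assign_memberships(t1, gates, config).matrix.to_numpy()
        m2 = assign_memberships(t2, gates, config).matrix.to_numpy()
        assert (m1[perm] == m2).all()

    def test_translation_invariance(self, config, small_cohort):
        sid = next(iter(small_cohort.slides))
        df = small_cohort.slides[sid].df
        shifted = df.assign(x_um=df.x_um + 1e4, y_um=df.y_um - 500.0)
        gates = compute_gates([CellTable(df, validate=False)], config)
        m1 = assign_memberships(CellTable(df, validate=False), gates, config)
        m2 = assign_memberships(CellTable(shifted, validate=False), gates, config)
        pd.testing.assert_frame_equal(m1.matrix, m2.matrix)
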