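"""MAP products: residue maps, histogram series, deviation maps and
conditioned histogram stacks."""

import numpy as np
import pytest

from conftest import make_table
from ramamap.maps import (
    build_conditioned_stack,
    build_deviation_map,
    build_histogram_series,
    build_residue_map,
    histogram_bin_edges,
)


class TestResidueMap:
    def test_matches_source_records(self, helix_table):
        rmap = build_residue_map(helix_table)
        assert rmap.shape == (4, 3)
        for _, row in helix_table.iterrows():
            assert rmap.loc[row["resid"], row["model"]] == row["R"]

    def test_signed_map_preserves_branch_sign(self):
        rows = [
            (1, "A", 1, "GLY", -75.0, 145.0),  # psi > phi: positive
            (1, "A", 2, "GLY", 145.0, -75.0),  # psi < phi: negative
        ]
        rmap = build_residue_map(make_table(rows), signed=True)
        assert rmap.loc[1, 1] > 0 > rmap.loc[2, 1]
        assert abs(rmap.loc[1, 1]) == pytest.approx(abs(rmap.loc[2, 1]))

    def test_single_model_single_column(self, helix_table):
        sub = helix_table[helix_table["model"] == 2]
        assert build_residue_map(sub).shape == (4, 1)

    def test_unknown_chain_lists_available(self, helix_table):
        with pytest.raises(KeyError, match="available chains.*A"):
            build_residue_map(helix_table, chain="Z")


class TestHistogramSeries:
    def test_point_mass_lands_in_one_bin(self):
        rows = [(1, "A", r, "ALA", -66.0, -45.6) for r in range(1, 6)]  # R = 0.345
        hist = build_histogram_series(make_table(rows))
        assert hist.shape == (100, 1)
        assert hist[1].to_numpy()[34] == pytest.approx(1.0)  # bin [0.34, 0.35)

    def test_uniform_spread_fills_every_bin(self):
        # 100 records at bin centers 0.005, 0.015, ..., 0.995
        rows = []
        for i, center in enumerate(np.arange(0.005, 1.0, 0.01)):
            s = center * 720.0 - 360.0  # phi+psi realizing that R
            rows.append((1, "A", i + 1, "ALA", s / 2, s / 2))
        hist = build_histogram_series(make_table(rows))
        np.testing.assert_allclose(hist[1].to_numpy(), 0.01, atol=1e-12)

    def test_r_of_one_counted_in_last_bin(self):
        rows = [(1, "A", 1, "ALA", 180.0, 180.0)]
        hist = build_histogram_series(make_table(rows))
        assert hist.iloc[-1, 0] == pytest.approx(1.0)

    def test_rows_normalized_and_undefined_excluded(self, rng):
        rows = [(m, "A", r, "ALA", *rng.uniform(-180, 180, 2))
                for m in (1, 2) for r in range(1, 30)]
        rows.append((1, "A", 99, "ALA", np.nan, np.nan))
        hist = build_histogram_series(make_table(rows))
        np.testing.assert_allclose(hist.sum(axis=0), 1.0, atol=1e-9)

    def test_model_without_defined_r_flagged_empty(self):
        rows = [(1, "A", 1, "ALA", 0.0, 0.0), (2, "A", 1, "ALA", np.nan, np.nan)]
        with pytest.warns(UserWarning, match="no defined"):
            hist = build_histogram_series(make_table(rows))
        assert hist[2].sum() == 0.0

    def test_bin_width_must_divide_range(self):
        with pytest.raises(ValueError):
            histogram_bin_edges(0.03)


class TestDeviationMap:
    def test_constant_trajectory_all_zero(self, helix_table):
        for mode in ("first", "previous"):
            dev = build_deviation_map(helix_table, mode=mode)
            np.testing.assert_allclose(dev.to_numpy(), 0.0, atol=1e-12)

    def test_single_jump_distinguishes_modes(self):
        # residue 1 jumps R 0.3 -> 0.7 at frame 5 of 8
        rows = []
        for m in range(1, 9):
            s = (0.7 if m >= 5 else 0.3) * 720.0 - 360.0
            rows.append((m, "A", 1, "ALA", s / 2, s / 2))
        table = make_table(rows)
        prev = build_deviation_map(table, mode="previous")
        first = build_deviation_map(table, mode="first")
        np.testing.assert_allclose(
            prev.loc[1].to_numpy(), [0, 0, 0, 0, 0.4, 0, 0, 0], atol=1e-9
        )
        np.testing.assert_allclose(
            first.loc[1].to_numpy(), [0, 0, 0, 0, 0.4, 0.4, 0.4, 0.4], atol=1e-9
        )

    def test_two_frame_modes_identical(self):
        rows = [(m, "A", r, "ALA", -57.0 * m, -47.0) for m in (1, 2) for r in (1, 2)]
        table = make_table(rows)
        a = build_deviation_map(table, mode="first")
        b = build_deviation_map(table, mode="previous")
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy())

    def test_previous_mode_invariant_under_time_reversal(self, rng):
        rows = [(m, "A", r, "ALA", *rng.uniform(-170, 170, 2))
                for m in range(1, 7) for r in (1, 2, 3)]
        table = make_table(rows)
        fwd = build_deviation_map(table, mode="previous").to_numpy()
        # physically reverse the frame order, then relabel 1..6
        import pandas as pd

        frames = [table[table["model"] == m].assign(model=7 - m)
                  for m in range(6, 0, -1)]
        rev_table = pd.concat(frames, ignore_index=True)
        rev = build_deviation_map(rev_table, mode="previous").to_numpy()
        # the multiset of nonzero |delta| per residue is reversal-invariant
        np.testing.assert_allclose(fwd[:, 1:], rev[:, 1:][:, ::-1], atol=1e-12)

    def test_single_model_warns_and_zeroes(self, helix_table):
        sub = helix_table[helix_table["model"] == 1]
        with pytest.warns(UserWarning, match="single-model"):
            dev = build_deviation_map(sub)
        np.testing.assert_allclose(dev.to_numpy(), 0.0)

    def test_invalid_mode_rejected(self, helix_table):
        with pytest.raises(ValueError):
            build_deviation_map(helix_table, mode="next")


class TestConditionedStack:
    def test_residue_types_at_distinct_loci(self):
        loci = {"ALA": 0.345, "GLY": 0.605, "PRO": 0.125}
        rows = []
        for i, (name, r) in enumerate(loci.items()):
            s = r * 720.0 - 360.0
            rows.append((1, "A", i + 1, name, s / 2, s / 2))
        stack = build_conditioned_stack(make_table(rows), condition="residue")
        assert set(stack.index) == set(loci)
        for name, r in loci.items():
            assert stack.loc[name].to_numpy()[int(r * 100)] == pytest.approx(1.0)

    def test_preceding_type_captures_pre_proline_shift(self):
        # residues before PRO pushed above R = 0.5; all others below
        sequence = ("ALA", "PRO", "ALA", "LEU", "ALA", "PRO")
        rows = []
        for m in (1, 2):
            for i, name in enumerate(sequence):
                before_pro = i + 1 < len(sequence) and sequence[i + 1] == "PRO"
                phi, psi = (75.0, 85.0) if before_pro else (-66.0, -45.6)
                rows.append((m, "A", i + 1, name, phi, psi))
        stack = build_conditioned_stack(make_table(rows), condition="preceding")
        centers = stack.columns.to_numpy(dtype=float)
        pro_row = stack.loc["PRO"].to_numpy()
        assert pro_row[centers > 0.5].sum() == pytest.approx(1.0)
        for other in set(stack.index) - {"PRO"}:
            row = stack.loc[other].to_numpy()
            if row.sum():
                assert row[centers > 0.5].sum() == 0.0

    @pytest.mark.filterwarnings("ignore:condition 'LEU'")  # last-in-chain: no follower
    def test_following_type_is_the_mirror_query(self):
        rows = [
            (1, "A", 1, "GLY", 0.0, 0.0),
            (1, "A", 2, "ALA", 75.0, 85.0),  # after GLY: R > 0.5
            (1, "A", 3, "LEU", -66.0, -45.6),
        ]
        stack = build_conditioned_stack(make_table(rows), condition="following")
        centers = stack.columns.to_numpy(dtype=float)
        gly_row = stack.loc["GLY"].to_numpy()
        assert gly_row[centers > 0.5].sum() == pytest.approx(1.0)

    def test_single_type_equals_global_histogram(self, helix_table):
        stack = build_conditioned_stack(helix_table, condition="residue")
        hist = build_histogram_series(
            helix_table.assign(model=1), bin_width=0.01
        )
        np.testing.assert_allclose(
            stack.loc["ALA"].to_numpy(), hist[1].to_numpy(), atol=1e-12
        )

    def test_empty_condition_kept_as_zero_row(self):
        rows = [
            (1, "A", 1, "ALA", 0.0, 0.0),
            (1, "A", 2, "CYS", np.nan, np.nan),
        ]
        with pytest.warns(UserWarning, match="CYS"):
            stack = build_conditioned_stack(make_table(rows), condition="residue")
        assert "CYS" in stack.index
        assert stack.loc["CYS"].sum() == 0.0
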