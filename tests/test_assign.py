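"""Scaling, background subtraction, dominance calls, assignment, merging."""

import math

import numpy as np
import pandas as pd
import pytest

import welltrace as wt
from welltrace.assign import AssignmentStatus, well_key
from welltrace.errors import ValidationError


def make_counts(matrix, beads=None, oligos=None):
    matrix = np.asarray(matrix, dtype=np.int64)
    beads = beads or [f"B{i:03d}" for i in range(matrix.shape[0])]
    oligos = oligos or [f"O{j:02d}" for j in range(matrix.shape[1])]
    return wt.BeadIndexCounts(beads, oligos, matrix)


class TestScaling:
    def test_arithmetic(self):
        counts = make_counts([[6, 2, 8, 4]])
        scaled = wt.scale_by_bead_total(counts)
        assert np.allclose(scaled.matrix[0], [0.30, 0.10, 0.40, 0.20])

    def test_zero_bead_flagged(self):
        scaled = wt.scale_by_bead_total(make_counts([[0, 0], [1, 1]]))
        assert scaled.zero_total.tolist() == [True, False]

    def test_rows_sum_to_one(self, rng):
        counts = make_counts(rng.integers(0, 50, size=(30, 8)))
        scaled = wt.scale_by_bead_total(counts)
        sums = scaled.matrix[~scaled.zero_total].sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)


class TestBackground:
    def test_mean_of_two_beads(self):
        scaled = wt.scale_by_bead_total(make_counts([[3, 7], [1, 9]]))
        assert np.allclose(wt.estimate_background(scaled), [0.2, 0.8])

    def test_single_bead_background_is_its_row(self):
        scaled = wt.scale_by_bead_total(make_counts([[1, 3]]))
        assert np.allclose(wt.estimate_background(scaled), scaled.matrix[0])

    def test_matches_loop_oracle(self, rng):
        scaled = wt.scale_by_bead_total(make_counts(rng.integers(0, 20, size=(25, 6))))
        bg = wt.estimate_background(scaled)
        keep = ~scaled.zero_total
        for j in range(6):
            expected = sum(scaled.matrix[i, j] for i in range(25) if keep[i]) / keep.sum()
            assert math.isclose(bg[j], expected, rel_tol=1e-12)

    def test_all_zero_errors(self):
        scaled = wt.scale_by_bead_total(make_counts([[0, 0]]))
        with pytest.raises(ValidationError):
            wt.estimate_background(scaled)

    def test_subtract_clamps_at_zero(self):
        scaled = wt.scale_by_bead_total(make_counts([[3, 1], [1, 3]]))
        corrected = wt.subtract_background(scaled, np.array([0.2, 0.2]))
        assert np.allclose(corrected.matrix, [[0.55, 0.05], [0.05, 0.55]])
        clamped = wt.subtract_background(scaled, np.array([0.9, 0.0]))
        assert clamped.matrix[1, 0] == 0.0  # 0.25 - 0.9 clamps to 0
        identity = wt.subtract_background(scaled, np.zeros(2))
        assert np.allclose(identity.matrix, scaled.matrix)


class TestCallAxis:
    def test_boundary_inclusive(self):
        call = wt.call_axis([0.9, 0.3], ["a", "b"], "X", threshold=3.0)
        assert call.passed and call.top_id == "a" and call.dominance_ratio == 3.0

    def test_below_boundary_fails(self):
        assert not wt.call_axis([0.8, 0.3], ["a", "b"], "X").passed

    def test_zero_second_passes_with_infinite_ratio(self):
        call = wt.call_axis([0.5, 0.0], ["a", "b"], "X")
        assert call.passed and math.isinf(call.dominance_ratio)

    def test_tie_at_top_fails(self):
        call = wt.call_axis([0.4, 0.4], ["a", "b"], "X")
        assert not call.passed and call.dominance_ratio == 1.0

    def test_all_zero_fails(self):
        call = wt.call_axis([0.0, 0.0], ["a", "b"], "X")
        assert not call.passed and call.top_id is None

    def test_single_oligo_axis(self):
        call = wt.call_axis([0.2], ["a"], "Z")
        assert call.passed and call.second_value == 0.0


def brute_force_assign(counts, layout, threshold=3.0):
    """Exhaustive reimplementation: explicit loops, direct maxima per axis."""
    n_beads, n_oligos = counts.counts.shape
    results = []
    totals = counts.counts.sum(axis=1)
    scaled = np.zeros_like(counts.counts, dtype=float)
    for i in range(n_beads):
        if totals[i]:
            scaled[i] = counts.counts[i] / totals[i]
    keep = totals > 0
    bg = np.array(
        [np.mean([scaled[i, j] for i in range(n_beads) if keep[i]]) for j in range(n_oligos)]
    )
    corrected = np.maximum(scaled - bg, 0.0)
    for i in range(n_beads):
        if not keep[i]:
            results.append(("zero_signal", None))
            continue
        triple = []
        ok = True
        for axis in "XYZ":
            pairs = [
                (corrected[i, j], oid)
                for j, oid in enumerate(counts.oligo_ids)
                if layout.oligos[oid].axis == axis
            ]
            vals = sorted((v for v, _ in pairs), reverse=True)
            top = vals[0]
            second = vals[1] if len(vals) > 1 else 0.0
            top_ids = [oid for v, oid in pairs if v == top]
            if top <= 0 or len(top_ids) > 1 or (second > 0 and top / second < threshold):
                ok = False
                break
            triple.append(top_ids[0])
        if not ok:
            results.append(("failed_dominance", None))
            continue
        well = layout.triple_to_well.get(tuple(triple))
        if well is None:
            results.append(("invalid_triple", None))
        else:
            results.append(("assigned", well))
    return results


class TestAssignBeads:
    def test_clean_triple_assigned(self, small_layout):
        triple = small_layout.well_to_triple[wt.WellPosition(3, 5)]
        oligos = small_layout.oligo_ids
        row = np.zeros(len(oligos), dtype=np.int64)
        for oid in triple:
            row[oligos.index(oid)] = 50
        counts = wt.BeadIndexCounts(["BEAD"], oligos, row[None, :])
        (a,) = wt.assign_beads(wt.scale_by_bead_total(counts), small_layout)
        assert a.status is AssignmentStatus.ASSIGNED
        assert a.well == (3, 5)

    def test_failing_one_axis_removes_bead(self, small_layout):
        """Dominance must hold on every axis; a z-axis tie alone is fatal."""
        triple = small_layout.well_to_triple[wt.WellPosition(0, 0)]
        oligos = small_layout.oligo_ids
        row = np.zeros(len(oligos), dtype=np.int64)
        for oid in triple:
            row[oligos.index(oid)] = 60
        other_z = small_layout.axis_oligo_ids("Z")[1]
        row[oligos.index(other_z)] = 60  # tie on z
        counts = wt.BeadIndexCounts(["BEAD"], oligos, row[None, :])
        (a,) = wt.assign_beads(wt.scale_by_bead_total(counts), small_layout)
        assert a.status is AssignmentStatus.FAILED_DOMINANCE
        x_call, y_call, z_call = a.calls
        assert x_call.passed and y_call.passed and not z_call.passed

    def test_unknown_oligo_rejected(self, small_layout):
        counts = wt.BeadIndexCounts(["B"], ["NOPE"], np.array([[1]]))
        with pytest.raises(ValidationError):
            wt.assign_beads(wt.scale_by_bead_total(counts), small_layout)

    def test_noiseless_sim_fully_recovered(self, noiseless_sim):
        assignments = wt.assign_from_counts(noiseless_sim.index_counts, noiseless_sim.layout)
        truth = noiseless_sim.truth.beads.set_index("barcode")
        assert len(assignments) >= 500
        for a in assignments:
            assert a.status is AssignmentStatus.ASSIGNED
            assert a.well == (
                truth.loc[a.bead_barcode, "row"],
                truth.loc[a.bead_barcode, "col"],
            )

    def test_matches_brute_force_oracle(self, rng):
        """Random small matrices agree with the exhaustive reimplementation."""
        layout = wt.build_layout(4, 4, 2, 2, seed=6)  # 2+2+4 = 8 oligos
        oligos = layout.oligo_ids
        for _ in range(300):
            n_beads = int(rng.integers(1, 10))
            counts = wt.BeadIndexCounts(
                [f"B{i}" for i in range(n_beads)],
                oligos,
                rng.integers(0, 12, size=(n_beads, len(oligos))),
            )
            got = wt.assign_from_counts(counts, layout)
            expected = brute_force_assign(counts, layout)
            assert [(a.status.value, a.well) for a in got] == expected

    def test_threshold_monotonicity(self, noisy_sim):
        """Raising the dominance threshold can only shrink the assigned set."""
        def assigned_set(threshold):
            return {
                a.bead_barcode
                for a in wt.assign_from_counts(
                    noisy_sim.index_counts, noisy_sim.layout, threshold
                )
                if a.status is AssignmentStatus.ASSIGNED
            }

        s3, s5, s10 = assigned_set(3.0), assigned_set(5.0), assigned_set(10.0)
        assert s10 <= s5 <= s3

    def test_bead_order_invariance(self, noisy_sim):
        counts = noisy_sim.index_counts
        perm = np.random.default_rng(0).permutation(counts.n_beads)
        shuffled = wt.BeadIndexCounts(
            [counts.bead_barcodes[i] for i in perm],
            counts.oligo_ids,
            counts.counts[perm],
        )
        base = {
            a.bead_barcode: (a.status, a.well)
            for a in wt.assign_from_counts(counts, noisy_sim.layout)
        }
        other = {
            a.bead_barcode: (a.status, a.well)
            for a in wt.assign_from_counts(shuffled, noisy_sim.layout)
        }
        assert base == other


class TestMergeAndAnnotate:
    def _assignments(self, layout, mapping):
        out = []
        for bead, well in mapping.items():
            calls = tuple(wt.call_axis([1.0], ["x"], ax) for ax in "XYZ")
            if well is None:
                out.append(
                    wt.BeadAssignment(bead, calls, AssignmentStatus.FAILED_DOMINANCE, None)
                )
            else:
                out.append(
                    wt.BeadAssignment(
                        bead, calls, AssignmentStatus.ASSIGNED, wt.WellPosition(*well)
                    )
                )
        return out

    def test_two_beads_summed(self, small_layout):
        dge = pd.DataFrame(
            {"b1": [3, 0], "b2": [5, 2]}, index=["gene_a", "gene_b"]
        )
        wells = wt.merge_by_well(
            dge, self._assignments(small_layout, {"b1": (0, 0), "b2": (0, 0)})
        )
        assert wells.counts.loc["gene_a", "0_0"] == 8
        assert wells.meta.loc["0_0", "n_beads_merged"] == 2

    def test_one_bead_per_well_is_relabeled_subset(self, small_layout):
        dge = pd.DataFrame(
            {"b1": [1, 2], "b2": [3, 4], "b3": [5, 6]}, index=["g1", "g2"]
        )
        wells = wt.merge_by_well(
            dge, self._assignments(small_layout, {"b1": (0, 0), "b2": (1, 1), "b3": None})
        )
        assert wells.n_wells == 2
        assert wells.counts["0_0"].tolist() == [1, 2]
        assert wells.counts["1_1"].tolist() == [3, 4]

    def test_conservation(self, noiseless_sim):
        """Total counts in the merged matrix equal the DGE totals of assigned beads."""
        assignments = wt.assign_from_counts(
            noiseless_sim.index_counts, noiseless_sim.layout
        )
        wells = wt.merge_by_well(noiseless_sim.dge, assignments)
        assigned = [
            a.bead_barcode
            for a in assignments
            if a.status is AssignmentStatus.ASSIGNED
            and a.bead_barcode in noiseless_sim.dge.columns
        ]
        assert wells.counts.to_numpy().sum() == noiseless_sim.dge[assigned].to_numpy().sum()

    def test_missing_bead_tallied(self, small_layout):
        dge = pd.DataFrame({"b1": [1]}, index=["g"])
        wells = wt.merge_by_well(
            dge, self._assignments(small_layout, {"b1": (0, 0), "ghost": (0, 1)})
        )
        assert wells.tallies["n_assigned_beads_missing_from_dge"] == 1

    def test_annotation(self, small_layout):
        dge = pd.DataFrame({"b1": [1], "b2": [1]}, index=["g"])
        wells = wt.merge_by_well(
            dge, self._assignments(small_layout, {"b1": (3, 5), "b2": (0, 0)})
        )
        log = pd.DataFrame(
            {
                "row": [3, 7],
                "col": [5, 7],
                "entity_label": ["cellA", "cellB"],
                "calcein_green": [1200.0, 90.0],
            }
        )
        annotated = wt.annotate_with_print_log(wells, log)
        assert annotated.meta.loc["3_5", "calcein_green"] == 1200.0
        assert annotated.meta.loc["3_5", "printed_entity"] == "cellA"
        assert annotated.tallies["dropout_wells"] == ["7_7"]
        assert annotated.tallies["unmatched_wells"] == ["0_0"]
        assert not annotated.meta.loc["0_0", "log_matched"]

    def test_empty_log_flags_all_unmatched(self, small_layout):
        dge = pd.DataFrame({"b1": [1]}, index=["g"])
        wells = wt.merge_by_well(dge, self._assignments(small_layout, {"b1": (0, 0)}))
        log = pd.DataFrame(columns=["row", "col", "entity_label", "ch"])
        annotated = wt.annotate_with_print_log(wells, log)
        assert not annotated.meta["log_matched"].any()

    def test_duplicate_log_entry_rejected(self, small_layout):
        dge = pd.DataFrame({"b1": [1]}, index=["g"])
        wells = wt.merge_by_well(dge, self._assignments(small_layout, {"b1": (0, 0)}))
        log = pd.DataFrame({"row": [0, 0], "col": [0, 0], "ch": [1.0, 2.0]})
        with pytest.raises(ValidationError, match="duplicate"):
            wt.annotate_with_print_log(wells, log)

    def test_annotations_match_simulator_truth(self, noiseless_sim):
        sim = noiseless_sim
        assignments = wt.assign_from_counts(sim.index_counts, sim.layout)
        wells = wt.annotate_with_print_log(
            wt.merge_by_well(sim.dge, assignments), sim.print_log
        )
        truth = sim.truth.wells
        for key in wells.meta.index:
            for ch in wells.channels:
                assert wells.meta.loc[key, ch] == pytest.approx(
                    truth.loc[key, f"true_{ch}"]
                )
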