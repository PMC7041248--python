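"""Bead-to-nanowell assignment and multi-bead merging.

The decoding algorithm, applied to a bead x coordinate-oligo UMI count
matrix:

1. scale each bead's counts by its total UMIs (row-normalise);
2. estimate per-oligo ambient background as the mean scaled value
   across all beads, and subtract it (clamped at zero);
3. within each axis (x, y, z), take the most abundant corrected oligo;
   the bead is kept only if, on every axis, the top oligo is at least
   ``dominance_threshold`` (default 3) times the second most abundant;
4. look the (x, y, z) triple up in the plate layout's inverse table to
   obtain the nanowell position.

Beads landing in the same nanowell are then merged: their digital gene
expression columns are summed into a single well column, which can be
annotated with the print-time fluorescence record for that position.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .counting import BeadIndexCounts
from .errors import ValidationError
from .layout import AXES, PlateLayout, WellPosition

DEFAULT_DOMINANCE_THRESHOLD = 3.0


class AssignmentStatus(str, enum.Enum):
    ASSIGNED = "assigned"
    FAILED_DOMINANCE = "failed_dominance"
    ZERO_SIGNAL = "zero_signal"
    INVALID_TRIPLE = "invalid_triple"


@dataclasses.dataclass
class ScaledIndexMatrix:
    """Row-normalised index counts; beads with zero total are flagged."""

    bead_barcodes: list[str]
    oligo_ids: list[str]
    matrix: np.ndarray  # (n_beads, n_oligos) floats
    zero_total: np.ndarray  # (n_beads,) bool; True = flagged, excluded downstream


@dataclasses.dataclass
class AxisCall:
    """Top-oligo call for one axis of one bead."""

    axis: str
    top_id: Optional[str]
    top_value: float
    second_value: float
    dominance_ratio: float  # inf when second_value == 0 and top_value > 0
    passed: bool


@dataclasses.dataclass
class BeadAssignment:
    bead_barcode: str
    calls: tuple[AxisCall, AxisCall, AxisCall]
    status: AssignmentStatus
    well: Optional[WellPosition]


def scale_by_bead_total(counts: BeadIndexCounts) -> ScaledIndexMatrix:
    """Normalise each bead's oligo counts to fractions of its total UMIs."""
    raw = counts.counts.astype(float)
    totals = raw.sum(axis=1)
    zero = totals == 0
    safe = np.where(zero, 1.0, totals)
    return ScaledIndexMatrix(
        bead_barcodes=list(counts.bead_barcodes),
        oligo_ids=list(counts.oligo_ids),
        matrix=raw / safe[:, None],
        zero_total=zero,
    )


def estimate_background(scaled: ScaledIndexMatrix) -> np.ndarray:
    """Per-oligo ambient level: mean scaled value over all unflagged beads."""
    keep = ~scaled.zero_total
    if not keep.any():
        raise ValidationError("cannot estimate background: no bead has any UMIs")
    return scaled.matrix[keep].mean(axis=0)


def subtract_background(
    scaled: ScaledIndexMatrix, background: np.ndarray
) -> ScaledIndexMatrix:
    """Subtract the ambient vector from every bead row, clamping at zero."""
    background = np.asarray(background, dtype=float)
    if background.shape != (len(scaled.oligo_ids),):
        raise ValidationError(
            f"background length {background.shape} does not match "
            f"{len(scaled.oligo_ids)} oligos"
        )
    return ScaledIndexMatrix(
        bead_barcodes=list(scaled.bead_barcodes),
        oligo_ids=list(scaled.oligo_ids),
        matrix=np.maximum(scaled.matrix - background[None, :], 0.0),
        zero_total=scaled.zero_total.copy(),
    )


def call_axis(
    values: Sequence[float],
    oligo_ids: Sequence[str],
    axis: str,
    threshold: float = DEFAULT_DOMINANCE_THRESHOLD,
) -> AxisCall:
    """Call the dominant oligo on one axis and apply the dominance filter.

    Passing requires a strictly positive top value at least ``threshold``
    times the runner-up ("at least": the boundary is inclusive). With a
    single oligo on the axis the runner-up is defined as 0. An exact tie
    at the top gives ratio 1 and fails any threshold > 1.
    """
    values = np.asarray(values, dtype=float)
    if len(values) != len(oligo_ids):
        raise ValidationError("axis values and oligo ids differ in length")
    if len(values) == 0:
        return AxisCall(axis, None, 0.0, 0.0, math.nan, False)
    order = np.argsort(values, kind="stable")
    top_ix = order[-1]
    top = float(values[top_ix])
    second = float(values[order[-2]]) if len(values) > 1 else 0.0
    if top <= 0.0:
        return AxisCall(axis, None, top, second, math.nan, False)
    ratio = math.inf if second == 0.0 else top / second
    passed = ratio >= threshold
    return AxisCall(axis, oligo_ids[top_ix], top, second, ratio, passed)


def assign_beads(
    corrected: ScaledIndexMatrix,
    layout: PlateLayout,
    threshold: float = DEFAULT_DOMINANCE_THRESHOLD,
) -> list[BeadAssignment]:
    """Assign each bead to a nanowell, or record why it was removed.

    A bead fails with ``failed_dominance`` if any of its three axis calls
    fails the dominance filter; a passing triple absent from the layout's
    lookup table yields ``invalid_triple``; beads flagged for zero total
    signal are ``zero_signal``.
    """
    unknown = set(corrected.oligo_ids) - set(layout.oligos)
    if unknown:
        raise ValidationError(
            f"count matrix contains oligo ids not in the layout: {sorted(unknown)}"
        )
    axis_cols = {
        axis: [
            (j, oid)
            for j, oid in enumerate(corrected.oligo_ids)
            if layout.oligos[oid].axis == axis
        ]
        for axis in AXES
    }
    out: list[BeadAssignment] = []
    for i, barcode in enumerate(corrected.bead_barcodes):
        calls = tuple(
            call_axis(
                corrected.matrix[i, [j for j, _ in axis_cols[axis]]],
                [oid for _, oid in axis_cols[axis]],
                axis,
                threshold,
            )
            for axis in AXES
        )
        if corrected.zero_total[i]:
            out.append(BeadAssignment(barcode, calls, AssignmentStatus.ZERO_SIGNAL, None))
            continue
        if not all(c.passed for c in calls):
            out.append(
                BeadAssignment(barcode, calls, AssignmentStatus.FAILED_DOMINANCE, None)
            )
            continue
        triple = tuple(c.top_id for c in calls)
        well = layout.lookup_position(triple)
        if well is None:
            out.append(
                BeadAssignment(barcode, calls, AssignmentStatus.INVALID_TRIPLE, None)
            )
        else:
            out.append(BeadAssignment(barcode, calls, AssignmentStatus.ASSIGNED, well))
    return out


def assign_from_counts(
    counts: BeadIndexCounts,
    layout: PlateLayout,
    threshold: float = DEFAULT_DOMINANCE_THRESHOLD,
) -> list[BeadAssignment]:
    """Run the full decode: scale, estimate/subtract background, assign."""
    scaled = scale_by_bead_total(counts)
    if (~scaled.zero_total).any():
        corrected = subtract_background(scaled, estimate_background(scaled))
    else:
        corrected = scaled
    return assign_beads(corrected, layout, threshold)


def assignments_frame(assignments: Iterable[BeadAssignment]) -> pd.DataFrame:
    """Tabulate assignments, one bead per row, for TSV export."""
    rows = []
    for a in assignments:
        rec = {
            "bead": a.bead_barcode,
            "status": a.status.value,
            "row": a.well.row if a.well else pd.NA,
            "col": a.well.col if a.well else pd.NA,
        }
        for call in a.calls:
            p = call.axis.lower()
            rec[f"{p}_top_id"] = call.top_id
            rec[f"{p}_top"] = call.top_value
            rec[f"{p}_second"] = call.second_value
            rec[f"{p}_ratio"] = call.dominance_ratio
        rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# merging and annotation


def well_key(row: int, col: int) -> str:
    return f"{row}_{col}"


@dataclasses.dataclass
class WellExpressionMatrix:
    """Gene x nanowell counts after merging beads, with per-well metadata.

    ``counts`` columns are well keys "<row>_<col>"; ``meta`` is indexed by
    the same keys with columns row, col, n_beads_merged, bead_barcodes
    plus, after print-log annotation, printed_entity and one column per
    fluorescence channel. ``channels`` names the fluorescence columns.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame
    channels: list[str] = dataclasses.field(default_factory=list)
    tallies: dict = dataclasses.field(default_factory=dict)

    @property
    def n_wells(self) -> int:
        return self.counts.shape[1]

    def genes_detected(self) -> pd.Series:
        """Number of genes with nonzero count in each well."""
        return (self.counts > 0).sum(axis=0)


def merge_by_well(
    dge: pd.DataFrame, assignments: Iterable[BeadAssignment]
) -> WellExpressionMatrix:
    """Sum the DGE columns of all beads assigned to the same nanowell.

    ``dge`` is genes x bead barcodes. Unassigned beads are excluded;
    assigned beads missing from the DGE are dropped and tallied. Counts
    are summed without cross-bead UMI re-deduplication.
    """
    by_well: dict[str, list] = {}
    meta_rows: dict[str, dict] = {}
    n_missing = 0
    for a in assignments:
        if a.status is not AssignmentStatus.ASSIGNED:
            continue
        if a.bead_barcode not in dge.columns:
            n_missing += 1
            continue
        key = well_key(a.well.row, a.well.col)
        by_well.setdefault(key, []).append(a.bead_barcode)
        meta_rows.setdefault(key, {"row": a.well.row, "col": a.well.col})

    keys = sorted(by_well, key=lambda k: (meta_rows[k]["row"], meta_rows[k]["col"]))
    if keys:
        cols = {k: dge[by_well[k]].sum(axis=1) for k in keys}
        counts = pd.DataFrame(cols, index=dge.index)
    else:
        counts = pd.DataFrame(index=dge.index)
    meta = pd.DataFrame(
        [
            {
                "row": meta_rows[k]["row"],
                "col": meta_rows[k]["col"],
                "n_beads_merged": len(by_well[k]),
                "bead_barcodes": ";".join(sorted(by_well[k])),
            }
            for k in keys
        ],
        index=pd.Index(keys, name="well"),
    )
    total_assigned = int(
        sum(
            dge[b].sum()
            for beads in by_well.values()
            for b in beads
        )
    )
    return WellExpressionMatrix(
        counts=counts,
        meta=meta,
        tallies={
            "n_wells_recovered": len(keys),
            "n_beads_merged": sum(len(v) for v in by_well.values()),
            "n_assigned_beads_missing_from_dge": n_missing,
            "total_counts": total_assigned,
        },
    )


def annotate_with_print_log(
    wells: WellExpressionMatrix, print_log: pd.DataFrame
) -> WellExpressionMatrix:
    """Attach print-time fluorescence and entity labels to recovered wells.

    The print log must use the layout's coordinate convention (0-based,
    row 0 at top) with columns row, col, entity_label and one column per
    fluorescence channel. Wells present in the log but not recovered by
    sequencing are reported as dropouts; recovered wells absent from the
    log are flagged unmatched (``log_matched`` False). Duplicate log
    entries for a position are an error.
    """
    for col in ("row", "col"):
        if col not in print_log.columns:
            raise ValidationError(f"print log is missing required column {col!r}")
    dup = print_log.duplicated(subset=["row", "col"])
    if dup.any():
        r = print_log.loc[dup].iloc[0]
        raise ValidationError(
            f"print log has duplicate entries for well ({int(r['row'])}, {int(r['col'])})"
        )
    channels = [
        c for c in print_log.columns if c not in ("row", "col", "entity_label", "species")
    ]
    log = print_log.copy()
    log.index = [well_key(int(r), int(c)) for r, c in zip(log["row"], log["col"])]

    meta = wells.meta.copy()
    meta["printed_entity"] = pd.NA
    if "entity_label" in log.columns:
        meta.loc[meta.index.intersection(log.index), "printed_entity"] = log[
            "entity_label"
        ].reindex(meta.index.intersection(log.index))
    for ch in channels:
        meta[ch] = log[ch].reindex(meta.index)
    meta["log_matched"] = meta.index.isin(log.index)

    dropouts = sorted(set(log.index) - set(meta.index))
    unmatched = sorted(set(meta.index) - set(log.index))
    tallies = dict(wells.tallies)
    tallies.update(
        {
            "n_log_entries": len(log),
            "n_dropout_wells": len(dropouts),
            "dropout_wells": dropouts,
            "n_unmatched_wells": len(unmatched),
            "unmatched_wells": unmatched,
        }
    )
    return WellExpressionMatrix(
        counts=wells.counts.copy(), meta=meta, channels=channels, tallies=tallies
    )


def write_well_matrix(wells: WellExpressionMatrix, counts_path, meta_path) -> None:
    wells.counts.to_csv(counts_path, sep="\t", index_label="gene")
    wells.meta.to_csv(meta_path, index_label="well")


def read_well_matrix(counts_path, meta_path) -> WellExpressionMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col="gene")
    meta = pd.read_csv(meta_path, index_col="well")
    known = {
        "row",
        "col",
        "n_beads_merged",
        "bead_barcodes",
        "printed_entity",
        "log_matched",
    }
    channels = [c for c in meta.columns if c not in known]
    return WellExpressionMatrix(counts=counts, meta=meta, channels=channels)
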