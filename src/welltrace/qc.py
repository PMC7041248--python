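"""Quality control and linked optical-expression analyses.

Covers the species-mixing (barnyard) readouts used to validate positional
decoding — per-well species purity, concordance with the planned printing
pattern, beads recovered per well, transcripts versus beads recovered —
plus the downstream linked analyses: minimum-gene cell filters,
sliding-window cell-state fractions along a fluorescence ordering, moving
averages of expression versus fluorescence, and sort enrichment factors.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .assign import AssignmentStatus, BeadAssignment, WellExpressionMatrix, well_key
from .errors import ValidationError

DEFAULT_PURITY_THRESHOLD = 0.90
MIXED_LABEL = "mixed"


def species_purity(
    wells: WellExpressionMatrix,
    gene_species_map: Mapping[str, str],
    threshold: float = DEFAULT_PURITY_THRESHOLD,
) -> tuple[pd.DataFrame, dict]:
    """Classify each well by the species its transcripts predominantly map to.

    ``gene_species_map`` assigns every gene to exactly one of two species.
    For each well, ``frac_a`` is the fraction of mapped transcripts from
    the alphabetically first species; a well is labelled that species
    when ``frac_a >= threshold``, the other when ``1 - frac_a >=
    threshold``, and "mixed" otherwise. Genes absent from the map and
    wells with zero mapped transcripts are excluded and tallied.

    Returns (calls frame indexed by well key with columns row, col,
    frac_a, label; tally dict).
    """
    if not 0.5 < threshold <= 1.0:
        raise ValidationError("purity threshold must be in (0.5, 1]")
    species = sorted(set(gene_species_map.values()))
    if len(species) != 2:
        raise ValidationError(f"need exactly two species in the map, got {species}")
    sp_a, sp_b = species

    genes = wells.counts.index
    mapped = genes.isin(gene_species_map.keys())
    n_unmapped_genes = int((~mapped).sum())
    sub = wells.counts.loc[mapped]
    is_a = np.array([gene_species_map[g] == sp_a for g in sub.index])

    total = sub.sum(axis=0)
    a_counts = sub.loc[is_a].sum(axis=0)
    has_counts = total > 0
    frac_a = (a_counts[has_counts] / total[has_counts]).astype(float)

    labels = pd.Series(MIXED_LABEL, index=frac_a.index, dtype=object)
    labels[frac_a >= threshold] = sp_a
    labels[(1.0 - frac_a) >= threshold] = sp_b

    calls = pd.DataFrame(
        {
            "row": wells.meta.loc[frac_a.index, "row"],
            "col": wells.meta.loc[frac_a.index, "col"],
            "frac_a": frac_a,
            "label": labels,
        }
    )
    calls.index.name = "well"
    tallies = {
        "species_a": sp_a,
        "species_b": sp_b,
        "n_unmapped_genes": n_unmapped_genes,
        "n_wells_zero_mapped": int((~has_counts).sum()),
        "n_wells_called": len(calls),
        "n_mixed": int((labels == MIXED_LABEL).sum()),
    }
    return calls, tallies


def pattern_concordance(
    calls: pd.DataFrame, plan: pd.DataFrame
) -> tuple[float, dict]:
    """Fraction of non-mixed species calls matching the planned pattern.

    ``plan`` needs columns row, col and species (the species planned at
    each position). Mixed wells are excluded from numerator and
    denominator and reported separately.
    """
    for col in ("row", "col", "species"):
        if col not in plan.columns:
            raise ValidationError(f"print plan is missing column {col!r}")
    planned = plan.set_index(
        [plan["row"].astype(int), plan["col"].astype(int)]
    )["species"]
    missing = [
        (int(r), int(c))
        for r, c in zip(calls["row"], calls["col"])
        if (int(r), int(c)) not in planned.index
    ]
    if missing:
        raise ValidationError(f"plan does not cover called wells {missing[:5]}")
    pure = calls[calls["label"] != MIXED_LABEL]
    n_mixed = len(calls) - len(pure)
    if len(pure) == 0:
        return float("nan"), {"n_compared": 0, "n_mixed_excluded": n_mixed}
    expected = np.array(
        [planned.loc[(int(r), int(c))] for r, c in zip(pure["row"], pure["col"])]
    )
    n_match = int((pure["label"].to_numpy() == expected).sum())
    tallies = {
        "n_compared": len(pure),
        "n_matching": n_match,
        "n_mixed_excluded": n_mixed,
    }
    return n_match / len(pure), tallies


def beads_recovered_per_well(
    assignments: Iterable[BeadAssignment], plan: pd.DataFrame
) -> tuple[pd.Series, pd.Series]:
    """Assigned beads per planned well, including zeros for dropouts.

    Returns (per-well count Series indexed by well key, histogram Series
    indexed by bead count).
    """
    keys = [well_key(int(r), int(c)) for r, c in zip(plan["row"], plan["col"])]
    per_well = pd.Series(0, index=pd.Index(keys, name="well"), dtype=int)
    for a in assignments:
        if a.status is not AssignmentStatus.ASSIGNED:
            continue
        k = well_key(a.well.row, a.well.col)
        if k in per_well.index:
            per_well[k] += 1
    hist = per_well.value_counts().sort_index()
    hist.index.name = "n_beads"
    return per_well, hist


def transcripts_by_beads_recovered(
    wells: WellExpressionMatrix, dge: Optional[pd.DataFrame] = None
) -> tuple[pd.DataFrame, Optional[pd.DataFrame]]:
    """Transcript totals grouped by the number of beads recovered per well.

    Returns a per-well frame (well, n_beads_merged, total_transcripts)
    and, when the bead-level DGE is supplied, a per-bead tidy frame
    (well, n_beads_merged, bead, transcripts) so per-bead yields can be
    compared across recovery groups.
    """
    per_well = pd.DataFrame(
        {
            "n_beads_merged": wells.meta["n_beads_merged"],
            "total_transcripts": wells.counts.sum(axis=0).reindex(wells.meta.index),
        }
    )
    per_well.index.name = "well"
    if dge is None:
        return per_well, None
    rows = []
    for key, rec in wells.meta.iterrows():
        for bead in str(rec["bead_barcodes"]).split(";"):
            if bead and bead in dge.columns:
                rows.append(
                    {
                        "well": key,
                        "n_beads_merged": rec["n_beads_merged"],
                        "bead": bead,
                        "transcripts": int(dge[bead].sum()),
                    }
                )
    return per_well, pd.DataFrame(rows)


def filter_cells_min_genes(
    wells: WellExpressionMatrix,
    min_genes: int,
    require_fluorescence: bool = False,
) -> WellExpressionMatrix:
    """Keep wells detecting at least ``min_genes`` genes (count > 0).

    With ``require_fluorescence``, wells lacking a matched print-log
    fluorescence record are also removed.
    """
    if min_genes < 0:
        raise ValidationError("min_genes must be >= 0")
    detected = wells.genes_detected()
    keep = detected[detected >= min_genes].index
    if require_fluorescence:
        if not wells.channels or "log_matched" not in wells.meta.columns:
            raise ValidationError(
                "require_fluorescence needs a print-log annotated matrix"
            )
        has_fluor = wells.meta["log_matched"] & (
            ~wells.meta[wells.channels].isna().any(axis=1)
        )
        keep = keep.intersection(wells.meta.index[has_fluor])
    keep = [k for k in wells.counts.columns if k in set(keep)]  # preserve order
    tallies = dict(wells.tallies)
    tallies["n_wells_filtered_out"] = wells.n_wells - len(keep)
    return WellExpressionMatrix(
        counts=wells.counts[keep],
        meta=wells.meta.loc[keep],
        channels=list(wells.channels),
        tallies=tallies,
    )


def sliding_window_state_fraction(
    order_key: Sequence[float],
    states: Sequence[str],
    window: int = 50,
) -> pd.DataFrame:
    """Per-state cell fractions in a sliding window along an ordering.

    Cells are sorted ascending by ``order_key`` (stable: ties keep input
    order) and a window of ``window`` cells slides by one cell; at each
    position the fraction of cells in each state is recorded. The result
    has ``n - window + 1`` rows, one column per state plus
    ``window_center`` (the mean order-key value in the window), and each
    row's state fractions sum to 1.
    """
    order_key = np.asarray(order_key, dtype=float)
    states = np.asarray(states, dtype=object)
    n = len(order_key)
    if len(states) != n:
        raise ValidationError("order_key and states differ in length")
    if window < 1:
        raise ValidationError("window must be >= 1")
    if n < window:
        raise ValidationError(f"need at least window={window} cells, got {n}")
    order = np.argsort(order_key, kind="stable")
    sorted_states = states[order]
    sorted_key = order_key[order]
    labels = sorted(set(states))
    onehot = np.stack([(sorted_states == s).astype(float) for s in labels], axis=1)
    # windowed sums via cumulative sums along the ordering
    csum = np.vstack([np.zeros(len(labels)), np.cumsum(onehot, axis=0)])
    win_counts = csum[window:] - csum[:-window]
    frame = pd.DataFrame(win_counts / window, columns=labels)
    kcs = np.concatenate([[0.0], np.cumsum(sorted_key)])
    frame.insert(0, "window_center", (kcs[window:] - kcs[:-window]) / window)
    return frame


def moving_average_expression(
    fluorescence: Sequence[float],
    expression: Sequence[float],
    bin: int = 30,
) -> pd.DataFrame:
    """Moving average of expression along increasing fluorescence.

    Cells are sorted ascending by fluorescence (stable) and the mean
    expression over a ``bin``-cell window sliding by one cell is
    returned, together with the mean fluorescence of each window.
    """
    fluorescence = np.asarray(fluorescence, dtype=float)
    expression = np.asarray(expression, dtype=float)
    n = len(fluorescence)
    if len(expression) != n:
        raise ValidationError("fluorescence and expression differ in length")
    if bin < 1:
        raise ValidationError("bin must be >= 1")
    if n < bin:
        raise ValidationError(f"need at least bin={bin} cells, got {n}")
    order = np.argsort(fluorescence, kind="stable")
    f = fluorescence[order]
    e = expression[order]
    ecs = np.concatenate([[0.0], np.cumsum(e)])
    fcs = np.concatenate([[0.0], np.cumsum(f)])
    return pd.DataFrame(
        {
            "mean_fluorescence": (fcs[bin:] - fcs[:-bin]) / bin,
            "mean_expression": (ecs[bin:] - ecs[:-bin]) / bin,
        }
    )


def enrichment_factor(pre_frequency: float, post_frequency: float) -> float:
    """Fold enrichment of a population by sorting: post / pre frequency."""
    if not 0.0 < pre_frequency <= 1.0 or not 0.0 < post_frequency <= 1.0:
        raise ValidationError("frequencies must be in (0, 1]")
    return post_frequency / pre_frequency


def build_qc_report(
    calls: pd.DataFrame,
    purity_tallies: dict,
    concordance: float,
    concordance_tallies: dict,
    beads_hist: pd.Series,
    threshold: float = DEFAULT_PURITY_THRESHOLD,
) -> dict:
    """Assemble the barnyard QC summary as a JSON-ready dict."""
    n = len(calls)
    n_pure = int((calls["label"] != MIXED_LABEL).sum())
    return {
        "n_wells_called": n,
        "purity_threshold": threshold,
        "fraction_pure": (n_pure / n) if n else float("nan"),
        "fraction_mixed": ((n - n_pure) / n) if n else float("nan"),
        "pattern_concordance": concordance,
        "species": [purity_tallies.get("species_a"), purity_tallies.get("species_b")],
        "purity_tallies": {
            k: v for k, v in purity_tallies.items() if isinstance(v, (int, float, str))
        },
        "concordance_tallies": concordance_tallies,
        "beads_per_well_histogram": {int(k): int(v) for k, v in beads_hist.items()},
    }


def format_qc_report(report: dict) -> str:
    """Human-readable rendering of :func:`build_qc_report` output."""
    lines = [
        "welltrace QC report",
        "-------------------",
        f"wells called:          {report['n_wells_called']}",
        f"purity threshold:      {report['purity_threshold']:.2f}",
        f"fraction pure:         {report['fraction_pure']:.4f}",
        f"fraction mixed:        {report['fraction_mixed']:.4f}",
        f"pattern concordance:   {report['pattern_concordance']:.4f}",
        f"species:               {report['species'][0]} / {report['species'][1]}",
        "beads per well:",
    ]
    for k, v in report["beads_per_well_histogram"].items():
        lines.append(f"  {k} bead(s): {v} wells")
    return "\n".join(lines) + "\n"
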