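"""Combinatorially indexed nanowell plate layouts.

A plate is tiled from fixed-size subarrays (14x14 by default). Every
nanowell is pre-loaded with three polyadenylated coordinate oligos, each
carrying an 8-base barcode: an *x* oligo selected by the well's column
within its subarray, a *y* oligo selected by its row within the subarray,
and a *z* oligo unique to the subarray tile. The x and y oligo sets are
shared across tiles, so a plate of R x C wells needs only
``subarray_cols + subarray_rows + n_tiles`` distinct oligos while giving
every well a unique (x, y, z) triple. The inverse lookup table maps a
triple back to the well it labels.

Coordinate convention: 0-based, row-major, row 0 at the top. Subarray
tiles are numbered row-major in the same orientation, and the z oligo
index follows the tile number.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import LayoutError, ParseError
from .seqtools import hamming, max_homopolymer_run, random_dna

AXES = ("X", "Y", "Z")

DEFAULT_OLIGO_LENGTH = 8
DEFAULT_MIN_HAMMING = 3
MAX_HOMOPOLYMER = 4  # no run of 5 or more identical bases


class WellPosition(NamedTuple):
    """0-based (row, col) position of a nanowell; row 0 is the top row."""

    row: int
    col: int


@dataclasses.dataclass(frozen=True)
class CoordinateOligo:
    """One coordinate oligo: an axis, its index along that axis, and its barcode.

    ``axis_index`` is the within-subarray column for X, the within-subarray
    row for Y, and the row-major subarray tile number for Z.
    """

    oligo_id: str
    axis: str
    axis_index: int
    sequence: str

    def __post_init__(self) -> None:
        if self.axis not in AXES:
            raise LayoutError(f"axis must be one of {AXES}, got {self.axis!r}")
        if self.axis_index < 0:
            raise LayoutError("axis_index must be >= 0")
        if len(self.sequence) != DEFAULT_OLIGO_LENGTH or set(self.sequence) - set("ACGT"):
            raise LayoutError(
                f"oligo sequence must be 8 bases over ACGT, got {self.sequence!r}"
            )


def generate_oligo_sequences(
    count: int,
    length: int = DEFAULT_OLIGO_LENGTH,
    min_hamming: int = DEFAULT_MIN_HAMMING,
    seed: int = 0,
    max_tries: Optional[int] = None,
) -> list[str]:
    """Design ``count`` barcode sequences by seeded rejection sampling.

    All returned sequences are distinct, pairwise Hamming distance
    >= ``min_hamming`` apart, and free of homopolymer runs of 5+ bases.
    The search budget is bounded; an infeasible request raises rather
    than looping forever.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    if min_hamming > length:
        raise ValueError("min_hamming cannot exceed sequence length")
    rng = np.random.default_rng(seed)
    budget = max_tries if max_tries is not None else max(20_000, 5_000 * count)
    accepted: list[str] = []
    for _ in range(budget):
        cand = random_dna(rng, length)
        if max_homopolymer_run(cand) > MAX_HOMOPOLYMER:
            continue
        if all(hamming(cand, s) >= min_hamming for s in accepted):
            accepted.append(cand)
            if len(accepted) == count:
                return accepted
    raise ValueError(
        f"could not design {count} length-{length} sequences with pairwise "
        f"Hamming >= {min_hamming} within {budget} tries ({len(accepted)} found)"
    )


@dataclasses.dataclass
class PlateLayout:
    """A fully indexed nanowell plate and its triple <-> position lookups."""

    n_rows: int
    n_cols: int
    subarray_rows: int
    subarray_cols: int
    oligos: dict[str, CoordinateOligo]
    well_to_triple: dict[WellPosition, tuple[str, str, str]]
    triple_to_well: dict[tuple[str, str, str], WellPosition]

    @property
    def n_wells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def n_subarrays(self) -> int:
        return (self.n_rows // self.subarray_rows) * (self.n_cols // self.subarray_cols)

    @property
    def oligo_ids(self) -> list[str]:
        """All oligo ids in axis order (X by index, Y by index, Z by index)."""
        return [o.oligo_id for o in sorted(self.oligos.values(), key=lambda o: (AXES.index(o.axis), o.axis_index))]

    def axis_oligo_ids(self, axis: str) -> list[str]:
        if axis not in AXES:
            raise ValueError(f"unknown axis {axis!r}")
        members = [o for o in self.oligos.values() if o.axis == axis]
        return [o.oligo_id for o in sorted(members, key=lambda o: o.axis_index)]

    def whitelist(self) -> dict[str, str]:
        """Map oligo sequence -> oligo id, for read matching."""
        return {o.sequence: o.oligo_id for o in self.oligos.values()}

    def lookup_position(self, triple: tuple[str, str, str]) -> Optional[WellPosition]:
        """Well labelled by ``triple``, or None if no well carries it."""
        return self.triple_to_well.get(tuple(triple))

    def validate(self) -> None:
        if len(self.triple_to_well) != len(self.well_to_triple):
            raise LayoutError("well -> triple mapping is not injective")
        for well, triple in self.well_to_triple.items():
            if self.triple_to_well.get(triple) != well:
                raise LayoutError(f"triple lookup is not the inverse at {well}")


def build_layout(
    n_rows: int,
    n_cols: int,
    subarray_rows: int = 14,
    subarray_cols: int = 14,
    seed: int = 0,
    sequences: Optional[Sequence[str]] = None,
) -> PlateLayout:
    """Build a plate layout of ``n_rows`` x ``n_cols`` wells from whole subarrays.

    Plate dimensions must be exact multiples of the subarray dimensions;
    partial tiles are rejected. Oligo barcodes are either supplied (x set,
    then y set, then z set, concatenated) or designed with
    :func:`generate_oligo_sequences` under ``seed``.
    """
    if n_rows <= 0 or n_cols <= 0 or subarray_rows <= 0 or subarray_cols <= 0:
        raise LayoutError("all dimensions must be positive")
    if n_rows % subarray_rows or n_cols % subarray_cols:
        raise LayoutError(
            f"plate dims ({n_rows}x{n_cols}) must be whole multiples of the "
            f"subarray dims ({subarray_rows}x{subarray_cols}); partial tiles "
            "are not supported"
        )
    tiles_down = n_rows // subarray_rows
    tiles_across = n_cols // subarray_cols
    n_z = tiles_down * tiles_across
    n_oligos = subarray_cols + subarray_rows + n_z

    if sequences is None:
        sequences = generate_oligo_sequences(n_oligos, seed=seed)
    elif len(sequences) != n_oligos:
        raise LayoutError(f"need {n_oligos} sequences, got {len(sequences)}")

    def width(n: int) -> int:
        return max(2, len(str(n - 1)))

    oligos: dict[str, CoordinateOligo] = {}
    seqs = iter(sequences)
    for axis, n in (("X", subarray_cols), ("Y", subarray_rows), ("Z", n_z)):
        for i in range(n):
            oid = f"{axis}{i:0{width(n)}d}"
            oligos[oid] = CoordinateOligo(oid, axis, i, next(seqs))

    x_ids = [o.oligo_id for o in oligos.values() if o.axis == "X"]
    y_ids = [o.oligo_id for o in oligos.values() if o.axis == "Y"]
    z_ids = [o.oligo_id for o in oligos.values() if o.axis == "Z"]

    well_to_triple: dict[WellPosition, tuple[str, str, str]] = {}
    for row in range(n_rows):
        for col in range(n_cols):
            tile = (row // subarray_rows) * tiles_across + (col // subarray_cols)
            triple = (x_ids[col % subarray_cols], y_ids[row % subarray_rows], z_ids[tile])
            well_to_triple[WellPosition(row, col)] = triple
    triple_to_well = {t: w for w, t in well_to_triple.items()}

    layout = PlateLayout(
        n_rows=n_rows,
        n_cols=n_cols,
        subarray_rows=subarray_rows,
        subarray_cols=subarray_cols,
        oligos=oligos,
        well_to_triple=well_to_triple,
        triple_to_well=triple_to_well,
    )
    layout.validate()
    return layout


# ---------------------------------------------------------------------------
# serialization

_LAYOUT_COLUMNS = ["row", "col", "x_id", "y_id", "z_id", "x_seq", "y_seq", "z_seq"]


def write_layout(layout: PlateLayout, path) -> None:
    """Write a layout as TSV, one well per row, with subarray dims in the header."""
    rows = []
    for well in sorted(layout.well_to_triple):
        x_id, y_id, z_id = layout.well_to_triple[well]
        rows.append(
            (
                well.row,
                well.col,
                x_id,
                y_id,
                z_id,
                layout.oligos[x_id].sequence,
                layout.oligos[y_id].sequence,
                layout.oligos[z_id].sequence,
            )
        )
    frame = pd.DataFrame(rows, columns=_LAYOUT_COLUMNS)
    with open(path, "w") as fh:
        fh.write(f"# subarray_rows={layout.subarray_rows}\n")
        fh.write(f"# subarray_cols={layout.subarray_cols}\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_layout(path) -> PlateLayout:
    """Read a layout TSV written by :func:`write_layout`, validating as it goes."""
    header: dict[str, int] = {}
    with open(path) as fh:
        while True:
            pos = fh.tell()
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            key, _, value = line[1:].strip().partition("=")
            header[key.strip()] = int(value)
        frame = pd.read_csv(fh, sep="\t", dtype={"row": int, "col": int})
    missing = set(_LAYOUT_COLUMNS) - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    try:
        subarray_rows = header["subarray_rows"]
        subarray_cols = header["subarray_cols"]
    except KeyError as exc:
        raise ParseError(f"{path}: missing '# {exc.args[0]}=' header line") from None

    n_rows = int(frame["row"].max()) + 1
    n_cols = int(frame["col"].max()) + 1
    oligos: dict[str, CoordinateOligo] = {}
    well_to_triple: dict[WellPosition, tuple[str, str, str]] = {}
    triple_to_well: dict[tuple[str, str, str], WellPosition] = {}
    tiles_across = n_cols // subarray_cols
    for i, rec in enumerate(frame.itertuples(index=False), start=len(header) + 2):
        well = WellPosition(int(rec.row), int(rec.col))
        if well in well_to_triple:
            raise ParseError(f"{path}: line {i}: duplicate well {tuple(well)}")
        triple = (rec.x_id, rec.y_id, rec.z_id)
        if triple in triple_to_well:
            raise ParseError(
                f"{path}: line {i}: triple {triple} already assigned to well "
                f"{tuple(triple_to_well[triple])}"
            )
        tile = (well.row // subarray_rows) * tiles_across + (well.col // subarray_cols)
        for oid, seq, axis, idx in (
            (rec.x_id, rec.x_seq, "X", well.col % subarray_cols),
            (rec.y_id, rec.y_seq, "Y", well.row % subarray_rows),
            (rec.z_id, rec.z_seq, "Z", tile),
        ):
            oligo = CoordinateOligo(oid, axis, idx, seq)
            if oid in oligos and oligos[oid] != oligo:
                raise ParseError(
                    f"{path}: line {i}: oligo {oid} redefined inconsistently"
                )
            oligos[oid] = oligo
        well_to_triple[well] = triple
        triple_to_well[triple] = well

    if len(well_to_triple) != n_rows * n_cols:
        raise ParseError(
            f"{path}: expected {n_rows * n_cols} wells for a {n_rows}x{n_cols} "
            f"plate, found {len(well_to_triple)}"
        )
    layout = PlateLayout(
        n_rows=n_rows,
        n_cols=n_cols,
        subarray_rows=subarray_rows,
        subarray_cols=subarray_cols,
        oligos=oligos,
        well_to_triple=well_to_triple,
        triple_to_well=triple_to_well,
    )
    layout.validate()
    return layout


def write_whitelist(layout: PlateLayout, path) -> None:
    """Write the oligo whitelist TSV (oligo_id, sequence, axis)."""
    recs = [
        (o.oligo_id, o.sequence, o.axis)
        for o in sorted(layout.oligos.values(), key=lambda o: (AXES.index(o.axis), o.axis_index))
    ]
    pd.DataFrame(recs, columns=["oligo_id", "sequence", "axis"]).to_csv(
        path, sep="\t", index=False
    )


def write_worklist(layout: PlateLayout, path, volume_nl: float = 2.0) -> None:
    """Export a generic spotter work-list: one dispense per (well, oligo).

    Each well receives its three coordinate oligos at ``volume_nl``
    nanoliters apiece (2 nl per dispense by default).
    """
    rows = []
    for well in sorted(layout.well_to_triple):
        for oid in layout.well_to_triple[well]:
            rows.append((well.row, well.col, oid, layout.oligos[oid].sequence, volume_nl))
    pd.DataFrame(
        rows, columns=["row", "col", "oligo_id", "sequence", "volume_nl"]
    ).to_csv(path, index=False)
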