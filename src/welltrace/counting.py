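"""Coordinate-oligo UMI counting from well-index library read pairs.

Read 1 carries the bead barcode followed by the UMI (Drop-Seq bead
design: 12 nt barcode + 8 nt UMI on a 25 bp read); read 2 carries the
8-base coordinate-oligo barcode at a configurable offset, padded with
poly-A. Counting collapses reads to one count per distinct
(bead, oligo, UMI) triple. Oligo barcodes are matched against the plate
whitelist allowing a bounded number of substitutions; the whitelist's
pairwise Hamming distance must exceed twice that bound so every
correction is unambiguous.
"""

from __future__ import annotations

import dataclasses
import gzip
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import ParseError, ValidationError
from .seqtools import hamming


@dataclasses.dataclass(frozen=True)
class ReadStructure:
    """Positions of the barcode, UMI and coordinate-oligo insert in a read pair."""

    barcode_len: int = 12
    umi_len: int = 8
    read1_len: int = 25
    read2_len: int = 75
    oligo_offset_in_read2: int = 0
    oligo_len: int = 8

    def __post_init__(self) -> None:
        if self.barcode_len + self.umi_len > self.read1_len:
            raise ValidationError("barcode_len + umi_len must fit in read 1")
        if self.oligo_offset_in_read2 + self.oligo_len > self.read2_len:
            raise ValidationError("oligo insert must fit in read 2")


def parse_read_pair(
    read1: str, read2: str, rs: ReadStructure
) -> Optional[tuple[str, str, str]]:
    """Slice (bead barcode, UMI, oligo insert) out of a read pair.

    Returns None when either read is too short to cover the needed slices;
    the caller tallies such skips.
    """
    if len(read1) < rs.barcode_len + rs.umi_len:
        return None
    if len(read2) < rs.oligo_offset_in_read2 + rs.oligo_len:
        return None
    barcode = read1[: rs.barcode_len]
    umi = read1[rs.barcode_len : rs.barcode_len + rs.umi_len]
    insert = read2[rs.oligo_offset_in_read2 : rs.oligo_offset_in_read2 + rs.oligo_len]
    return barcode, umi, insert


def validate_whitelist(whitelist: Mapping[str, str], max_mismatch: int = 1) -> None:
    """Require pairwise Hamming distance >= 2*max_mismatch + 1 between entries.

    This guarantees that a read within ``max_mismatch`` of one whitelist
    sequence cannot also be within ``max_mismatch`` of another.
    """
    seqs = list(whitelist)
    need = 2 * max_mismatch + 1
    for i, a in enumerate(seqs):
        for b in seqs[i + 1 :]:
            if hamming(a, b) < need:
                raise ValidationError(
                    f"whitelist sequences {a} ({whitelist[a]}) and {b} "
                    f"({whitelist[b]}) are {hamming(a, b)} apart; need >= {need} "
                    f"for unambiguous {max_mismatch}-mismatch matching"
                )


def match_oligo(
    insert: str, whitelist: Mapping[str, str], max_mismatch: int = 1
) -> Optional[str]:
    """Match an insert to a whitelist oligo id, tolerating substitutions.

    Exact match wins outright; otherwise the unique whitelist member
    within ``max_mismatch`` wins. Ambiguous or distant inserts return None.
    """
    hit = whitelist.get(insert)
    if hit is not None:
        return hit
    if max_mismatch == 0:
        return None
    best_id: Optional[str] = None
    for seq, oid in whitelist.items():
        if len(seq) != len(insert):
            continue
        if hamming(seq, insert) <= max_mismatch:
            if best_id is not None:
                return None  # ambiguous
            best_id = oid
    return best_id


@dataclasses.dataclass
class BeadIndexCounts:
    """Bead barcode x coordinate oligo matrix of deduplicated UMI counts."""

    bead_barcodes: list[str]
    oligo_ids: list[str]
    counts: np.ndarray  # (n_beads, n_oligos), non-negative ints
    tallies: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.bead_barcodes), len(self.oligo_ids)):
            raise ValidationError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.bead_barcodes)} beads x {len(self.oligo_ids)} oligos"
            )
        if self.counts.size and (
            (self.counts < 0).any() or not np.issubdtype(self.counts.dtype, np.integer)
        ):
            raise ValidationError("counts must be non-negative integers")

    @property
    def n_beads(self) -> int:
        return len(self.bead_barcodes)

    def to_long_frame(self) -> pd.DataFrame:
        """Nonzero entries in long (bead, oligo_id, count) form."""
        b, o = np.nonzero(self.counts)
        return pd.DataFrame(
            {
                "bead": [self.bead_barcodes[i] for i in b],
                "oligo_id": [self.oligo_ids[j] for j in o],
                "count": self.counts[b, o],
            }
        )

    def write_tsv(self, path) -> None:
        self.to_long_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, oligo_ids: Optional[Sequence[str]] = None) -> "BeadIndexCounts":
        frame = pd.read_csv(path, sep="\t")
        missing = {"bead", "oligo_id", "count"} - set(frame.columns)
        if missing:
            raise ParseError(f"{path}: missing columns {sorted(missing)}")
        beads = sorted(frame["bead"].astype(str).unique())
        if oligo_ids is None:
            oligo_ids = sorted(frame["oligo_id"].astype(str).unique())
        oligo_ids = list(oligo_ids)
        bead_ix = {b: i for i, b in enumerate(beads)}
        oligo_ix = {o: j for j, o in enumerate(oligo_ids)}
        counts = np.zeros((len(beads), len(oligo_ids)), dtype=np.int64)
        for rec in frame.itertuples(index=False):
            if rec.oligo_id not in oligo_ix:
                raise ParseError(f"{path}: unknown oligo id {rec.oligo_id!r}")
            counts[bead_ix[str(rec.bead)], oligo_ix[rec.oligo_id]] += int(rec.count)
        return cls(beads, oligo_ids, counts)

    def write_mtx(self, prefix) -> None:
        """Write MatrixMarket triple: <prefix>.mtx, .beads.txt, .oligos.txt."""
        scipy.io.mmwrite(f"{prefix}.mtx", scipy.sparse.coo_matrix(self.counts))
        with open(f"{prefix}.beads.txt", "w") as fh:
            fh.write("\n".join(self.bead_barcodes) + "\n")
        with open(f"{prefix}.oligos.txt", "w") as fh:
            fh.write("\n".join(self.oligo_ids) + "\n")

    @classmethod
    def read_mtx(cls, prefix) -> "BeadIndexCounts":
        counts = np.asarray(scipy.io.mmread(f"{prefix}.mtx").todense()).astype(np.int64)
        with open(f"{prefix}.beads.txt") as fh:
            beads = fh.read().split()
        with open(f"{prefix}.oligos.txt") as fh:
            oligos = fh.read().split()
        return cls(beads, oligos, counts)


def count_well_indexes(
    read_pairs: Iterable[tuple[str, str]],
    rs: ReadStructure,
    whitelist: Mapping[str, str],
    bead_whitelist: Optional[set] = None,
    max_mismatch: int = 1,
    oligo_ids: Optional[Sequence[str]] = None,
) -> BeadIndexCounts:
    """Stream read pairs into a deduplicated bead x oligo UMI count matrix.

    Each distinct (bead, oligo, UMI) triple contributes one count, so PCR
    and optical duplicates collapse. Reads that are too short, fail oligo
    matching, or (when ``bead_whitelist`` is given) come from unlisted
    beads are dropped and tallied. Bead rows are ordered by sorted
    barcode and oligo columns follow ``oligo_ids`` (default: sorted ids
    seen in the whitelist), so the result is invariant to read order.
    """
    validate_whitelist(whitelist, max_mismatch)
    if oligo_ids is None:
        oligo_ids = sorted(set(whitelist.values()))
    oligo_ids = list(oligo_ids)
    unknown = set(whitelist.values()) - set(oligo_ids)
    if unknown:
        raise ValidationError(f"whitelist ids missing from oligo_ids: {sorted(unknown)}")

    seen: dict[tuple[str, str], set[str]] = {}
    tallies = {
        "n_reads": 0,
        "n_short": 0,
        "n_oligo_unmatched": 0,
        "n_bead_filtered": 0,
        "n_counted_reads": 0,
    }
    for read1, read2 in read_pairs:
        tallies["n_reads"] += 1
        parsed = parse_read_pair(read1, read2, rs)
        if parsed is None:
            tallies["n_short"] += 1
            continue
        barcode, umi, insert = parsed
        if bead_whitelist is not None and barcode not in bead_whitelist:
            tallies["n_bead_filtered"] += 1
            continue
        oid = match_oligo(insert, whitelist, max_mismatch)
        if oid is None:
            tallies["n_oligo_unmatched"] += 1
            continue
        tallies["n_counted_reads"] += 1
        seen.setdefault((barcode, oid), set()).add(umi)

    beads = sorted({b for b, _ in seen})
    bead_ix = {b: i for i, b in enumerate(beads)}
    oligo_ix = {o: j for j, o in enumerate(oligo_ids)}
    counts = np.zeros((len(beads), len(oligo_ids)), dtype=np.int64)
    for (barcode, oid), umis in seen.items():
        counts[bead_ix[barcode], oligo_ix[oid]] = len(umis)
    tallies["n_umis"] = int(counts.sum())
    return BeadIndexCounts(beads, oligo_ids, counts, tallies=tallies)


# ---------------------------------------------------------------------------
# FASTQ and whitelist I/O


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def iter_fastq_pairs(path1, path2) -> Iterator[tuple[str, str]]:
    """Yield (read1, read2) sequences from paired FASTQ files (.gz ok)."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with _open_text(path1) as fh1, _open_text(path2) as fh2:
        it1 = FastqGeneralIterator(fh1)
        it2 = FastqGeneralIterator(fh2)
        for (t1, s1, _), (t2, s2, _) in zip(it1, it2):
            yield s1, s2
        # unequal lengths indicate truncated input
        for leftover in (it1, it2):
            if next(leftover, None) is not None:
                raise ParseError(f"paired FASTQ files {path1} / {path2} differ in length")


def load_whitelist(path) -> dict[str, str]:
    """Read a whitelist TSV (oligo_id, sequence[, axis]) to a seq -> id map."""
    frame = pd.read_csv(path, sep="\t")
    missing = {"oligo_id", "sequence"} - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if frame["sequence"].duplicated().any():
        dup = frame.loc[frame["sequence"].duplicated(), "sequence"].iloc[0]
        raise ParseError(f"{path}: duplicate whitelist sequence {dup!r}")
    return dict(zip(frame["sequence"], frame["oligo_id"]))
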