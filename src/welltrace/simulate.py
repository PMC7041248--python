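"""Synthetic nanowell printing experiments with ground truth.

Emulates the full experimental record consumed by the pipeline: a print
plan (which entity goes in which well), a print log with per-channel
fluorescence measured at dispense time, a bead-level digital gene
expression matrix, and the coordinate-oligo index counts (optionally
rendered as raw FASTQ read pairs). Every stochastic element — misprints,
bead loss, ambient index noise, transcript sampling, cross-contamination
— is driven from a single seed, so identical configurations reproduce
byte-identical output files.

Distributional choices: Poisson index UMIs (signal on the well's three
oligos, ambient everywhere else), gamma-Poisson (negative binomial)
transcript totals per cell split uniformly across the well's recovered
beads, and lognormal per-channel fluorescence per printed entity.
"""

from __future__ import annotations

import dataclasses
import gzip
import json
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .counting import BeadIndexCounts, ReadStructure
from .errors import ValidationError
from .layout import PlateLayout, build_layout, write_layout, write_whitelist
from .seqtools import BASES, mutate, random_dna


@dataclasses.dataclass(frozen=True)
class Entity:
    """A printable droplet type: label, species, and lognormal fluorescence.

    ``fluorescence`` maps channel name -> (median, sigma); intensities are
    drawn as ``median * exp(sigma * N(0, 1))``.
    """

    label: str
    species: str
    fluorescence: dict[str, tuple[float, float]]


DEFAULT_ENTITIES = (
    Entity(
        label="HEK293_calcein_green",
        species="human",
        fluorescence={"calcein_green": (3000.0, 0.35), "calcein_red": (40.0, 0.6)},
    ),
    Entity(
        label="NIH3T3_calcein_red",
        species="mouse",
        fluorescence={"calcein_green": (40.0, 0.6), "calcein_red": (2500.0, 0.35)},
    ),
)


@dataclasses.dataclass
class SimConfig:
    """Parameters of one synthetic experiment. ``seed`` is mandatory."""

    seed: int
    n_rows: int = 56
    n_cols: int = 42
    subarray_rows: int = 14
    subarray_cols: int = 14
    plan_pattern: str = "checkerboard"  # or "custom" with custom_plan
    custom_plan: Optional[pd.DataFrame] = None
    entities: tuple[Entity, ...] = DEFAULT_ENTITIES
    beads_per_well: int = 4
    bead_recovery_prob: float = 0.75
    ambient_index_rate: float = 0.05
    signal_index_umis: float = 60.0
    transcripts_per_cell_mean: float = 1500.0
    transcripts_dispersion: float = 2.0
    n_genes_per_species: int = 250
    cross_contamination_rate: float = 0.02
    misprint_rate: float = 0.005
    barcode_len: int = 12

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("a seed is mandatory")
        if self.beads_per_well < 1:
            raise ValidationError("beads_per_well must be >= 1")
        if not self.entities:
            raise ValidationError("at least one entity is required")
        for name, p in (
            ("bead_recovery_prob", self.bead_recovery_prob),
            ("cross_contamination_rate", self.cross_contamination_rate),
            ("misprint_rate", self.misprint_rate),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {p}")
        for name, r in (
            ("ambient_index_rate", self.ambient_index_rate),
            ("signal_index_umis", self.signal_index_umis),
            ("transcripts_per_cell_mean", self.transcripts_per_cell_mean),
            ("transcripts_dispersion", self.transcripts_dispersion),
        ):
            if r < 0:
                raise ValidationError(f"{name} must be >= 0, got {r}")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "entities" in raw:
            raw["entities"] = tuple(
                Entity(
                    label=e["label"],
                    species=e["species"],
                    fluorescence={
                        ch: (float(m), float(s))
                        for ch, (m, s) in e["fluorescence"].items()
                    },
                )
                for e in raw["entities"]
            )
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = dataclasses.asdict(self)
        raw.pop("custom_plan")
        raw["entities"] = [
            {
                "label": e["label"],
                "species": e["species"],
                "fluorescence": {ch: list(ms) for ch, ms in e["fluorescence"].items()},
            }
            for e in raw["entities"]
        ]
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


@dataclasses.dataclass
class SimTruth:
    """Ground truth: realized well contents and per-bead provenance."""

    wells: pd.DataFrame  # indexed by well key; plan, realized entity, fluor, beads
    beads: pd.DataFrame  # barcode, row, col, recovered, x_id, y_id, z_id


@dataclasses.dataclass
class SimExperiment:
    config: SimConfig
    layout: PlateLayout
    plan: pd.DataFrame
    print_log: pd.DataFrame
    dge: pd.DataFrame
    index_counts: BeadIndexCounts
    truth: SimTruth


def make_print_plan(
    layout: PlateLayout,
    pattern: str = "checkerboard",
    entities: Sequence[Entity] = DEFAULT_ENTITIES,
    custom_plan: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Plan which entity is printed to each well.

    ``checkerboard`` alternates the first two entities by (row + col)
    parity, the pattern used to validate positional decoding against the
    optical record; ``custom`` takes an explicit (row, col, entity_label)
    table.
    """
    if pattern == "checkerboard":
        if len(entities) < 2:
            raise ValidationError("checkerboard needs two entities")
        by_parity = {0: entities[0], 1: entities[1]}
        rows = [
            {
                "row": w.row,
                "col": w.col,
                "entity_label": by_parity[(w.row + w.col) % 2].label,
                "species": by_parity[(w.row + w.col) % 2].species,
            }
            for w in sorted(layout.well_to_triple)
        ]
        return pd.DataFrame(rows)
    if pattern == "custom":
        if custom_plan is None:
            raise ValidationError("custom pattern requires custom_plan")
        by_label = {e.label: e for e in entities}
        plan = custom_plan.copy()
        unknown = set(plan["entity_label"]) - set(by_label)
        if unknown:
            raise ValidationError(f"plan references unknown entities {sorted(unknown)}")
        plan["species"] = [by_label[l].species for l in plan["entity_label"]]
        return plan.reset_index(drop=True)
    raise ValidationError(f"unknown plan pattern {pattern!r}")


def _unique_barcodes(rng: np.random.Generator, n: int, length: int) -> list[str]:
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        bc = random_dna(rng, length)
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return out


def _split_across(
    rng: np.random.Generator, counts: np.ndarray, n_parts: int
) -> np.ndarray:
    """Split a count vector into ``n_parts`` uniformly (multinomial thinning)."""
    parts = np.zeros((n_parts, len(counts)), dtype=np.int64)
    remaining = counts.copy()
    for j in range(n_parts - 1):
        parts[j] = rng.binomial(remaining, 1.0 / (n_parts - j))
        remaining -= parts[j]
    parts[n_parts - 1] = remaining
    return parts


def simulate_experiment(config: SimConfig) -> SimExperiment:
    """Generate a complete synthetic experiment under ``config``.

    Per planned well: a misprint swaps the dispensed entity with
    probability ``misprint_rate`` (the log records the intended entity
    but the measured fluorescence of what was actually dispensed);
    ``beads_per_well`` beads are printed, each surviving library prep
    with ``bead_recovery_prob``; every recovered bead accrues
    Poisson(``signal_index_umis``) UMIs on each of its well's three
    coordinate oligos and Poisson(``ambient_index_rate``) on every other
    oligo; the cell's transcript total is negative binomial and split
    uniformly across the well's recovered beads, with a
    ``cross_contamination_rate`` fraction rehomed to random other beads.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    (r_misprint, r_fluor, r_beads, r_index, r_tx, r_contam) = [
        np.random.default_rng(c) for c in ss.spawn(6)
    ]
    layout = build_layout(
        cfg.n_rows, cfg.n_cols, cfg.subarray_rows, cfg.subarray_cols, seed=cfg.seed
    )
    plan = make_print_plan(layout, cfg.plan_pattern, cfg.entities, cfg.custom_plan)
    by_label = {e.label: e for e in cfg.entities}
    channels = sorted({ch for e in cfg.entities for ch in e.fluorescence})

    # --- misprints and fluorescence -------------------------------------
    n_wells = len(plan)
    swap = r_misprint.random(n_wells) < cfg.misprint_rate
    realized_labels = []
    for planned_label, do_swap in zip(plan["entity_label"], swap):
        if do_swap and len(cfg.entities) > 1:
            others = [e.label for e in cfg.entities if e.label != planned_label]
            realized_labels.append(others[r_misprint.integers(0, len(others))])
        else:
            realized_labels.append(planned_label)

    fluor = {ch: np.zeros(n_wells) for ch in channels}
    for i, label in enumerate(realized_labels):
        ent = by_label[label]
        for ch in channels:
            median, sigma = ent.fluorescence.get(ch, (0.0, 0.0))
            fluor[ch][i] = median * np.exp(sigma * r_fluor.standard_normal())

    print_log = pd.DataFrame(
        {
            "row": plan["row"].astype(int),
            "col": plan["col"].astype(int),
            "entity_label": plan["entity_label"],
            **{ch: fluor[ch] for ch in channels},
        }
    )

    # --- beads and recovery ---------------------------------------------
    k = cfg.beads_per_well
    all_barcodes = _unique_barcodes(r_beads, n_wells * k, cfg.barcode_len)
    recovered_flags = r_beads.random(n_wells * k) < cfg.bead_recovery_prob
    bead_rows = []
    for i, rec in enumerate(plan.itertuples(index=False)):
        triple = layout.well_to_triple[(int(rec.row), int(rec.col))]
        for j in range(k):
            ix = i * k + j
            bead_rows.append(
                {
                    "barcode": all_barcodes[ix],
                    "row": int(rec.row),
                    "col": int(rec.col),
                    "recovered": bool(recovered_flags[ix]),
                    "x_id": triple[0],
                    "y_id": triple[1],
                    "z_id": triple[2],
                    "well_ix": i,
                }
            )
    beads = pd.DataFrame(bead_rows)
    rec_beads = beads[beads["recovered"]].reset_index(drop=True)

    # --- coordinate-oligo index counts ----------------------------------
    oligo_ids = layout.oligo_ids
    oligo_ix = {oid: j for j, oid in enumerate(oligo_ids)}
    n_rec = len(rec_beads)
    if cfg.ambient_index_rate > 0:
        idx_counts = r_index.poisson(
            cfg.ambient_index_rate, size=(n_rec, len(oligo_ids))
        ).astype(np.int64)
    else:
        idx_counts = np.zeros((n_rec, len(oligo_ids)), dtype=np.int64)
    for i, rec in enumerate(rec_beads.itertuples(index=False)):
        for oid in (rec.x_id, rec.y_id, rec.z_id):
            idx_counts[i, oligo_ix[oid]] += r_index.poisson(cfg.signal_index_umis)

    # order beads by sorted barcode, matching count_well_indexes output
    bc_order = np.argsort(rec_beads["barcode"].to_numpy(), kind="stable")
    rec_beads = rec_beads.iloc[bc_order].reset_index(drop=True)
    idx_counts = idx_counts[bc_order]
    index_counts = BeadIndexCounts(
        bead_barcodes=list(rec_beads["barcode"]),
        oligo_ids=list(oligo_ids),
        counts=idx_counts,
        tallies={"simulated": True},
    )

    # --- transcripts ------------------------------------------------------
    genes: list[str] = []
    species_list = sorted({e.species for e in cfg.entities})
    gene_probs: dict[str, np.ndarray] = {}
    gene_slice: dict[str, slice] = {}
    for sp in species_list:
        start = len(genes)
        genes.extend(f"{sp.upper()}_{i:04d}" for i in range(cfg.n_genes_per_species))
        gene_slice[sp] = slice(start, len(genes))
        weights = r_tx.lognormal(mean=0.0, sigma=1.0, size=cfg.n_genes_per_species)
        gene_probs[sp] = weights / weights.sum()

    bead_col = {bc: i for i, bc in enumerate(index_counts.bead_barcodes)}
    dge_mat = np.zeros((len(genes), n_rec), dtype=np.int64)
    moved_total = np.zeros(len(genes), dtype=np.int64)
    beads_by_well = rec_beads.groupby("well_ix").groups

    r_nb = cfg.transcripts_dispersion
    mean_tx = cfg.transcripts_per_cell_mean
    for i, label in enumerate(realized_labels):
        well_beads = beads_by_well.get(i)
        if well_beads is None:
            continue  # all beads lost: the cell leaves no trace
        sp = by_label[label].species
        lam = r_tx.gamma(shape=r_nb, scale=mean_tx / r_nb) if r_nb > 0 else mean_tx
        total = int(r_tx.poisson(lam))
        if total == 0:
            continue
        gc = np.zeros(len(genes), dtype=np.int64)
        gc[gene_slice[sp]] = r_tx.multinomial(total, gene_probs[sp])
        if cfg.cross_contamination_rate > 0:
            n_move = int(r_contam.binomial(total, cfg.cross_contamination_rate))
            if n_move:
                moved = r_contam.multivariate_hypergeometric(gc, n_move)
                gc -= moved
                moved_total += moved
        barcodes_here = rec_beads.loc[well_beads, "barcode"].tolist()
        parts = _split_across(r_tx, gc, len(barcodes_here))
        for part, bc in zip(parts, barcodes_here):
            dge_mat[:, bead_col[bc]] += part

    if moved_total.sum() and n_rec:
        # ambient transcripts land on uniformly random recovered beads
        uniform = np.full(n_rec, 1.0 / n_rec)
        for g in np.flatnonzero(moved_total):
            dge_mat[g] += r_contam.multinomial(int(moved_total[g]), uniform)

    dge = pd.DataFrame(dge_mat, index=genes, columns=index_counts.bead_barcodes)

    # --- truth ------------------------------------------------------------
    bead_lists = (
        beads.groupby(["row", "col"])["barcode"].apply(lambda s: ";".join(sorted(s)))
    )
    rec_counts = (
        beads[beads["recovered"]].groupby(["row", "col"])["barcode"].count()
    )
    wells_truth = pd.DataFrame(
        {
            "row": plan["row"].astype(int),
            "col": plan["col"].astype(int),
            "planned_label": plan["entity_label"],
            "realized_label": realized_labels,
            "species": [by_label[l].species for l in realized_labels],
            **{f"true_{ch}": fluor[ch] for ch in channels},
        }
    )
    wells_truth.index = [
        f"{r}_{c}" for r, c in zip(wells_truth["row"], wells_truth["col"])
    ]
    wells_truth.index.name = "well"
    keyed = list(zip(wells_truth["row"], wells_truth["col"]))
    wells_truth["bead_barcodes"] = [bead_lists.get(kk, "") for kk in keyed]
    wells_truth["n_beads_printed"] = k
    wells_truth["n_beads_recovered"] = [int(rec_counts.get(kk, 0)) for kk in keyed]

    truth = SimTruth(wells=wells_truth, beads=beads.drop(columns="well_ix"))
    return SimExperiment(
        config=cfg,
        layout=layout,
        plan=plan,
        print_log=print_log,
        dge=dge,
        index_counts=index_counts,
        truth=truth,
    )


def gene_species_map(sim: SimExperiment) -> dict[str, str]:
    """Map each simulated gene to its species (by the gene-name prefix)."""
    return {g: g.split("_")[0].lower() for g in sim.dge.index}


# ---------------------------------------------------------------------------
# FASTQ rendering


def write_index_fastq(
    counts: BeadIndexCounts,
    rs: ReadStructure,
    path1,
    path2,
    reads_per_umi: int = 1,
    error_rate: float = 0.0,
    seed: int = 0,
    oligo_sequences: Optional[dict[str, str]] = None,
    layout: Optional[PlateLayout] = None,
) -> int:
    """Render an index-count matrix as a paired FASTQ well-index library.

    Each UMI of each (bead, oligo) pair emits ``reads_per_umi`` read
    pairs: read 1 is barcode + UMI padded with T to ``rs.read1_len``;
    read 2 carries the oligo 8-mer at ``rs.oligo_offset_in_read2`` padded
    with poly-A to ``rs.read2_len`` (coordinate oligos are
    polyadenylated). Substitution errors are applied at ``error_rate``
    per base. Returns the number of read pairs written.
    """
    if reads_per_umi < 1:
        raise ValidationError("reads_per_umi must be >= 1")
    if oligo_sequences is None:
        if layout is None:
            raise ValidationError("need oligo_sequences or a layout")
        oligo_sequences = {o.oligo_id: o.sequence for o in layout.oligos.values()}
    rng = np.random.default_rng(seed)

    def opener(path):
        path = str(path)
        return gzip.open(path, "wt") if path.endswith(".gz") else open(path, "w")

    n_written = 0
    with opener(path1) as fh1, opener(path2) as fh2:
        for i, barcode in enumerate(counts.bead_barcodes):
            for j, oid in enumerate(counts.oligo_ids):
                c = int(counts.counts[i, j])
                if c == 0:
                    continue
                umis: set[str] = set()
                while len(umis) < c:
                    umis.add(random_dna(rng, rs.umi_len))
                seq = oligo_sequences[oid]
                for umi in sorted(umis):
                    r1 = (barcode + umi).ljust(rs.read1_len, "T")
                    r2 = (
                        "A" * rs.oligo_offset_in_read2 + seq
                    ).ljust(rs.read2_len, "A")
                    for rep in range(reads_per_umi):
                        n_written += 1
                        name = f"@wt:{n_written}:{rep}"
                        o1 = mutate(rng, r1, error_rate)
                        o2 = mutate(rng, r2, error_rate)
                        fh1.write(f"{name}\n{o1}\n+\n{'I' * len(o1)}\n")
                        fh2.write(f"{name}\n{o2}\n+\n{'I' * len(o2)}\n")
    return n_written


def write_experiment(sim: SimExperiment, outdir) -> dict[str, str]:
    """Write every artifact of a simulated experiment to ``outdir``.

    Emits the layout TSV and oligo whitelist, print plan and print log
    CSVs, bead-level DGE TSV, long-format index counts TSV, and the
    ground truth (well and bead CSVs plus a JSON config echo). Returns
    the path map.
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "layout": os.path.join(outdir, "layout.tsv"),
        "whitelist": os.path.join(outdir, "whitelist.tsv"),
        "plan": os.path.join(outdir, "print_plan.csv"),
        "print_log": os.path.join(outdir, "print_log.csv"),
        "dge": os.path.join(outdir, "dge.tsv"),
        "index_counts": os.path.join(outdir, "index_counts.tsv"),
        "truth_wells": os.path.join(outdir, "truth_wells.csv"),
        "truth_beads": os.path.join(outdir, "truth_beads.csv"),
        "config": os.path.join(outdir, "sim_config.json"),
    }
    write_layout(sim.layout, paths["layout"])
    write_whitelist(sim.layout, paths["whitelist"])
    sim.plan.to_csv(paths["plan"], index=False)
    sim.print_log.to_csv(paths["print_log"], index=False)
    sim.dge.to_csv(paths["dge"], sep="\t", index_label="gene")
    sim.index_counts.write_tsv(paths["index_counts"])
    sim.truth.wells.to_csv(paths["truth_wells"], index_label="well")
    sim.truth.beads.to_csv(paths["truth_beads"], index=False)
    cfg = dataclasses.asdict(sim.config)
    cfg.pop("custom_plan")
    cfg["entities"] = [dataclasses.asdict(e) for e in sim.config.entities]
    with open(paths["config"], "w") as fh:
        json.dump(cfg, fh, indent=2, sort_keys=True, default=str)
    return paths
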