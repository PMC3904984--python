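"""Readers and writers for the desk-scale formats the pipeline uses.

FASTA for sequences (via Biopython), TSV for the species inventory and
per-gene call tables, Newick for trees, JSON for reports.  The
inventory schema matches the supplementary-table layout:

    species_id  order  lpla_n  lpla_c  lpla_fused  lipa  lipb  lipm
    lipl  e2  gcvh  lipoyl_only  oxygen_phenotype  [hgt_flagged]
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import DataError
from .pathway import (
    GENE_FAMILY_COLUMNS,
    OXYGEN_PHENOTYPES,
    SpeciesInventory,
    SystemCall,
)

logger = logging.getLogger(__name__)

INVENTORY_COLUMNS = (
    ("species_id", "order")
    + GENE_FAMILY_COLUMNS
    + ("oxygen_phenotype",)
)

PAPER_INVENTORY_RESOURCE = "paper_inventory.tsv"


def read_fasta(path) -> list[tuple[str, str]]:
    """Ordered (id, sequence) records; ids truncated at the first token.

    Sequences are uppercased; duplicate ids or an empty file raise
    :class:`DataError`.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id.split()[0]
        if name in seen:
            raise DataError(f"{path}: duplicate sequence id {name!r}")
        seen.add(name)
        records.append((name, str(rec.seq).upper()))
    if not records:
        raise DataError(f"{path}: no FASTA records")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 70) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(seq_records)


def _safe_count(value) -> int:
    if value is None or pd.isna(value):
        return 0
    return int(value)


def _inventory_from_frame(frame: pd.DataFrame, source: str) -> list[SpeciesInventory]:
    missing = [c for c in INVENTORY_COLUMNS if c not in frame.columns]
    if missing:
        raise DataError(f"{source}: missing column(s) {missing}")
    if frame.empty:
        raise DataError(f"{source}: empty inventory")
    inventories = []
    for row_number, row in enumerate(frame.itertuples(index=False), start=2):
        row = row._asdict()
        phenotype = str(row["oxygen_phenotype"]).strip()
        if phenotype not in OXYGEN_PHENOTYPES:
            logger.warning(
                "%s row %d: unknown phenotype %r mapped to 'unknown'",
                source, row_number, phenotype,
            )
            phenotype = "unknown"
        counts = {}
        for col in GENE_FAMILY_COLUMNS:
            value = int(row[col])
            if value < 0:
                raise DataError(f"{source} row {row_number}: negative count in {col}")
            counts[col] = value
        inventories.append(
            SpeciesInventory(
                species_id=str(row["species_id"]),
                order=str(row["order"]),
                oxygen_phenotype=phenotype,
                hgt_flagged=_safe_count(row.get("hgt_flagged", 0)),
                **counts,
            )
        )
    return inventories


def read_inventory(path) -> list[SpeciesInventory]:
    """Parse a species-inventory TSV (column order irrelevant)."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError as exc:
        raise DataError(f"{path}: empty inventory file") from exc
    return _inventory_from_frame(frame, str(path))


def write_inventory(inventories: Sequence[SpeciesInventory], path) -> None:
    rows = []
    for inv in inventories:
        row = {"species_id": inv.species_id, "order": inv.order}
        row.update({col: getattr(inv, col) for col in GENE_FAMILY_COLUMNS})
        row["oxygen_phenotype"] = inv.oxygen_phenotype
        row["hgt_flagged"] = inv.hgt_flagged
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_paper_inventory() -> list[SpeciesInventory]:
    """The shipped 147-species archaeal inventory fixture.

    A synthetic reconstruction of the study's supplementary inventory:
    row-level detail is invented but every published marginal count
    (genes and species per system, co-retention, single-system
    exclusivity, HGT flags) is reproduced exactly.
    """
    ref = resources.files("lipoarch").joinpath("fixtures", PAPER_INVENTORY_RESOURCE)
    with resources.as_file(ref) as path:
        return read_inventory(path)


def calls_to_frame(calls: Sequence[SystemCall]) -> pd.DataFrame:
    rows = []
    for call in calls:
        rows.append(
            {
                "species_id": call.species_id,
                "systems": ";".join(sorted(call.systems)) or "-",
                "complete_routes": ";".join(sorted(call.complete_routes)) or "-",
                "substrates": ";".join(sorted(call.substrates)) or "-",
                "exclusive_single_system": call.exclusive_single_system,
                "aerobiosis_prediction": call.aerobiosis_prediction,
                "audit": "; ".join(call.audit),
            }
        )
    return pd.DataFrame(rows)


def write_calls(calls: Sequence[SystemCall], path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)
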