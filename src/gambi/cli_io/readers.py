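"""Readers for the tabular and FASTA inputs."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO

from gambi._errors import GambiError
from gambi.core_index import EcologicalGroup, EcologicalGroupMap, StationSample
from gambi.primer_insilico import PrimerPair
from gambi.reference_library import SequenceRecord

logger = logging.getLogger(__name__)

_GROUP_TOKENS = {
    "I": EcologicalGroup.I,
    "II": EcologicalGroup.II,
    "III": EcologicalGroup.III,
    "IV": EcologicalGroup.IV,
    "V": EcologicalGroup.V,
    "NA": EcologicalGroup.UNASSIGNED,
    "UNASSIGNED": EcologicalGroup.UNASSIGNED,
    "": EcologicalGroup.UNASSIGNED,
}

TAXONOMY_RANKS = ("genus", "family", "order", "class", "phylum")


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def read_eg_table(path: str | Path) -> EcologicalGroupMap:
    """Species -> ecological group table (columns: species, phylum, group).

    Group tokens are I..V or NA; duplicate species rows with conflicting
    groups are an error, consistent duplicates are deduplicated.
    """
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    for col in ("species", "phylum", "group"):
        if col not in df.columns:
            raise GambiError(f"{path}: missing required column {col!r}")
    eg = EcologicalGroupMap()
    for row in df.itertuples(index=False):
        token = str(row.group).strip().upper()
        if token not in _GROUP_TOKENS:
            raise GambiError(f"{path}: unparseable group token {row.group!r} for {row.species!r}")
        eg.add(row.species, phylum=row.phylum, group=_GROUP_TOKENS[token])
    return eg


def read_taxonomy(path: str | Path) -> dict[str, dict[str, str]]:
    """Optional taxonomy columns (genus..phylum) from an extended species table."""
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    ranks = [r for r in TAXONOMY_RANKS if r in df.columns]
    if not ranks:
        raise GambiError(f"{path}: no taxonomy columns among {TAXONOMY_RANKS}")
    return {
        row["species"]: {r: row[r] for r in ranks} for _, row in df.iterrows()
    }


def read_abundance_matrix(path: str | Path) -> list[StationSample]:
    """Stations x species count matrix; first column is the station id.

    All-zero rows become azoic stations; negative or fractional cells are
    rejected with their address.
    """
    df = pd.read_csv(path, sep=_sep_for(path))
    if df.shape[1] < 2:
        raise GambiError(f"{path}: need a station_id column plus at least one species column")
    station_col = df.columns[0]
    species = list(df.columns[1:])
    samples = []
    for _, row in df.iterrows():
        station = str(row[station_col])
        counts = {}
        for sp in species:
            cell = row[sp]
            value = float(cell)
            if value != int(value):
                raise GambiError(
                    f"{path}: fractional count {cell!r} at station {station!r}, species {sp!r}"
                )
            if value < 0:
                raise GambiError(
                    f"{path}: negative count {cell!r} at station {station!r}, species {sp!r}"
                )
            if value > 0:
                counts[sp] = int(value)
        samples.append(StationSample(station_id=station, abundances=counts))
    return samples


def read_class_table(path: str | Path) -> dict[str, str]:
    """Per-station quality-class table (columns: station_id, quality_class)."""
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    for col in ("station_id", "quality_class"):
        if col not in df.columns:
            raise GambiError(f"{path}: missing required column {col!r}")
    return dict(zip(df["station_id"], df["quality_class"]))


def read_fasta(
    path: str | Path, marker: str = "", delimiter: str = "|"
) -> list[SequenceRecord]:
    """FASTA with ``>id|species|phylum`` headers; sequences upper-cased.

    Records failing the IUPAC alphabet check are rejected with the
    offending position.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.description.split(delimiter)
        rec_id = parts[0].strip()
        species = parts[1].strip() if len(parts) > 1 else rec_id
        phylum = parts[2].strip() if len(parts) > 2 else "unknown"
        records.append(
            SequenceRecord(
                id=rec_id, species=species, phylum=phylum, marker=marker, seq=str(rec.seq)
            )
        )
    return records


def read_primer_table(path: str | Path) -> list[PrimerPair]:
    """Primer-pair TSV/CSV with columns name, forward, reverse[, marker]."""
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    for col in ("name", "forward", "reverse"):
        if col not in df.columns:
            raise GambiError(f"{path}: missing required column {col!r}")
    return [
        PrimerPair(
            name=row["name"],
            forward=row["forward"],
            reverse=row["reverse"],
            marker=row.get("marker", ""),
        )
        for _, row in df.iterrows()
    ]
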