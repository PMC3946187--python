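"""Barcode reference-library audit: per-species sequence deduplication and
marker coverage of a species list.

Dedup follows a greedy longest-first clustering within each species: the
longest sequence founds a cluster, later sequences join when their identity
to the founder reaches the threshold (default 0.9), and the founder is the
representative.  Identity is matching positions over the shorter sequence
length under the best ungapped offset alignment.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from gambi._errors import GambiError
from gambi.core_index import EcologicalGroupMap, StationSample, normalize_name

IUPAC_NUCLEOTIDES = frozenset("ACGTRYSWKMBDHVN")


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    species: str
    phylum: str
    marker: str
    seq: str

    def __post_init__(self) -> None:
        seq = self.seq.upper()
        if not seq:
            raise GambiError(f"record {self.id!r}: empty sequence")
        bad = set(seq) - IUPAC_NUCLEOTIDES
        if bad:
            pos = min(i for i, c in enumerate(seq) if c in bad)
            raise GambiError(
                f"record {self.id!r}: non-IUPAC character {seq[pos]!r} at position {pos}"
            )
        object.__setattr__(self, "seq", seq)

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class DedupConfig:
    similarity_threshold: float = 0.9

    def __post_init__(self) -> None:
        if not (0.0 < self.similarity_threshold <= 1.0):
            raise GambiError("similarity threshold must be in (0, 1]")


def pairwise_identity(a: str, b: str) -> float:
    """Best ungapped offset alignment identity, normalized by the shorter length."""
    if len(a) < len(b):
        a, b = b, a  # a is the longer
    la, lb = len(a), len(b)
    A = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    B = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    best = 0
    # slide the shorter sequence across every offset of the longer, including overhangs
    for offset in range(-lb + 1, la):
        start = max(0, offset)
        end = min(la, offset + lb)
        matches = int((A[start:end] == B[start - offset : end - offset]).sum())
        if matches > best:
            best = matches
            if best == lb:
                break
    return best / lb


def dedup_cluster(
    records: Sequence[SequenceRecord], config: DedupConfig = DedupConfig()
) -> list[SequenceRecord]:
    """One representative (the longest member) per within-species cluster.

    Sequences are grouped per species only; records from different species
    never co-cluster.  Deterministic: length-descending order, ties broken
    by record id.
    """
    by_species: dict[str, list[SequenceRecord]] = defaultdict(list)
    for rec in records:
        by_species[normalize_name(rec.species)].append(rec)
    representatives: list[SequenceRecord] = []
    for key in sorted(by_species):
        members = sorted(by_species[key], key=lambda r: (-r.length, r.id))
        founders: list[SequenceRecord] = []
        for rec in members:
            for rep in founders:
                if pairwise_identity(rep.seq, rec.seq) >= config.similarity_threshold:
                    break
            else:
                founders.append(rec)
        representatives.extend(founders)
    return representatives


@dataclass
class CoverageReport:
    """Which listed species have barcodes, per marker and per phylum."""

    sequenced: dict[str, set[str]]  # marker -> normalized species names found in list
    overlap: set[str]  # species sequenced for every marker
    per_phylum: pd.DataFrame  # rows: phylum; columns: n_species, <marker>_n, <marker>_prop
    unknown_species: dict[str, set[str]]  # in library but not in the species list

    def proportion(self, marker: str) -> float:
        total = int(self.per_phylum["n_species"].sum())
        return len(self.sequenced[marker]) / total if total else 0.0


def coverage_report(
    species_list: EcologicalGroupMap,
    library: Mapping[str, Sequence[SequenceRecord]],
) -> CoverageReport:
    """Audit barcode coverage of a species list, per marker and per phylum."""
    listed = set(species_list.entries)
    phylum_of = {key: rec.phylum for key, rec in species_list.entries.items()}
    phyla = sorted(set(phylum_of.values()))
    sequenced: dict[str, set[str]] = {}
    unknown: dict[str, set[str]] = {}
    for marker, records in library.items():
        found = {normalize_name(r.species) for r in records}
        sequenced[marker] = found & listed
        unknown[marker] = found - listed
    overlap = set(listed)
    for found in sequenced.values():
        overlap &= found
    if not sequenced:
        overlap = set()
    rows = []
    for ph in phyla:
        members = {k for k, p in phylum_of.items() if p == ph}
        row: dict[str, object] = {"phylum": ph, "n_species": len(members)}
        for marker in sorted(sequenced):
            n = len(sequenced[marker] & members)
            row[f"{marker}_n"] = n
            row[f"{marker}_prop"] = n / len(members) if members else 0.0
        rows.append(row)
    per_phylum = pd.DataFrame(rows).set_index("phylum") if rows else pd.DataFrame()
    return CoverageReport(
        sequenced=sequenced,
        overlap=overlap,
        per_phylum=per_phylum,
        unknown_species=unknown,
    )


def sequenced_species_filter(
    samples: Sequence[StationSample],
    records: Sequence[SequenceRecord],
) -> list[str]:
    """Species in the station matrix with at least one library sequence.

    Feeds subset_analysis.subset_agreement as the 'sequenced-only' subset.
    """
    matrix_species = {}
    for s in samples:
        for sp in s.present_species():
            matrix_species.setdefault(normalize_name(sp), sp)
    sequenced = {normalize_name(r.species) for r in records}
    keep = sorted(set(matrix_species) & sequenced)
    if not keep:
        raise GambiError(
            f"no overlap between matrix species ({len(matrix_species)}) "
            f"and sequenced species ({len(sequenced)})"
        )
    return [matrix_species[k] for k in keep]
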