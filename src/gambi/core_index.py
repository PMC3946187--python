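"""Biotic index core: ecological-group bookkeeping, index values, quality classes.

The index is the weighted average of pollution-tolerance weights
(0, 1.5, 3, 4.5, 6) over the percentage composition of five ecological
groups (GI sensitive ... GV first-order opportunist).  Percentages count
individuals in abundance mode and species in presence mode.  Azoic samples
(no individuals at all) are assigned the conventional maximum of 7.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from gambi._errors import AzoicSampleError, GambiError, IndexNotComputableError

logger = logging.getLogger(__name__)

_WS = re.compile(r"\s+")


def normalize_name(name: str) -> str:
    """Canonical species-name key: trimmed, internal whitespace collapsed, casefolded."""
    return _WS.sub(" ", name.strip()).casefold()


class EcologicalGroup(str, Enum):
    I = "I"
    II = "II"
    III = "III"
    IV = "IV"
    V = "V"
    UNASSIGNED = "UNASSIGNED"


#: assigned groups in index order
ASSIGNED_GROUPS = (
    EcologicalGroup.I,
    EcologicalGroup.II,
    EcologicalGroup.III,
    EcologicalGroup.IV,
    EcologicalGroup.V,
)

#: pollution-tolerance weight of each assigned group
GROUP_WEIGHTS = np.array([0.0, 1.5, 3.0, 4.5, 6.0])

#: ordered quality-class tokens, least to most degraded
QUALITY_CLASSES = (
    "unpolluted",
    "slightly polluted",
    "moderately polluted",
    "heavily polluted",
    "extremely polluted",
)

#: upper bound of each class on the continuous index value (last class open-ended to 7)
CLASS_UPPER_BOUNDS = (1.2, 3.3, 5.0, 6.0, 7.0)

AZOIC_VALUE = 7.0


@dataclass(frozen=True)
class EGRecord:
    phylum: str
    group: EcologicalGroup


@dataclass
class EcologicalGroupMap:
    """Species -> (phylum, ecological group) lookup with normalized-name keys."""

    entries: dict[str, EGRecord] = field(default_factory=dict)
    #: display names keyed by normalized name
    display_names: dict[str, str] = field(default_factory=dict)

    def add(self, species: str, phylum: str, group: EcologicalGroup | str) -> None:
        key = normalize_name(species)
        group = EcologicalGroup(group)
        if key in self.entries:
            if self.entries[key].group is not group:
                raise GambiError(
                    f"conflicting group assignment for species {species!r}: "
                    f"{self.entries[key].group.value} vs {group.value}"
                )
            logger.warning("duplicate consistent entry for species %r deduplicated", species)
            return
        self.entries[key] = EGRecord(phylum=phylum, group=group)
        self.display_names[key] = _WS.sub(" ", species.strip())

    def group_of(self, species: str) -> EcologicalGroup:
        """Group for a species; names absent from the map are UNASSIGNED (warned once)."""
        rec = self.entries.get(normalize_name(species))
        if rec is None:
            logger.warning("species %r not in ecological-group map; treated as unassigned", species)
            return EcologicalGroup.UNASSIGNED
        return rec.group

    def phylum_of(self, species: str) -> str | None:
        rec = self.entries.get(normalize_name(species))
        return rec.phylum if rec else None

    def __contains__(self, species: str) -> bool:
        return normalize_name(species) in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def species(self) -> list[str]:
        return [self.display_names[k] for k in self.entries]


@dataclass
class StationSample:
    """Per-station abundance vector; azoic iff the total count is zero."""

    station_id: str
    abundances: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sp, count in self.abundances.items():
            if not isinstance(count, (int, np.integer)) or isinstance(count, bool):
                raise GambiError(
                    f"station {self.station_id!r}, species {sp!r}: count {count!r} is not an integer"
                )
            if count < 0:
                raise GambiError(
                    f"station {self.station_id!r}, species {sp!r}: negative count {count}"
                )

    @property
    def azoic(self) -> bool:
        return sum(self.abundances.values()) == 0

    @property
    def total_individuals(self) -> int:
        return sum(self.abundances.values())

    def present_species(self) -> list[str]:
        return [sp for sp, c in self.abundances.items() if c > 0]


@dataclass(frozen=True)
class GroupPercentages:
    """Percent composition over the five assigned groups (GI..GV); sums to 100."""

    pct: np.ndarray
    unassigned_fraction: float
    n_taxa_used: int

    def __post_init__(self) -> None:
        pct = np.asarray(self.pct, dtype=float)
        if pct.shape != (5,):
            raise GambiError("group percentages must be a length-5 vector")
        object.__setattr__(self, "pct", pct)


@dataclass(frozen=True)
class AmbiResult:
    station_id: str
    value: float
    mode: str
    quality_class: str
    azoic: bool
    unassigned_fraction: float
    n_taxa_used: int
    percentages: GroupPercentages | None = None


def classify_pollution(value: float) -> str:
    """Map a continuous index value in [0, 7] to its quality class.

    Continuous half-open binning on the unrounded value: <=1.2 unpolluted,
    <=3.3 slightly, <=5.0 moderately, <=6.0 heavily, else extremely polluted.
    """
    if not (0.0 <= value <= 7.0):
        raise GambiError(f"index value {value} outside [0, 7]")
    for cls, upper in zip(QUALITY_CLASSES, CLASS_UPPER_BOUNDS):
        if value <= upper:
            return cls
    return QUALITY_CLASSES[-1]  # pragma: no cover - unreachable for valid input


def group_percentages(
    sample: StationSample, eg: EcologicalGroupMap, mode: str = "abundance"
) -> GroupPercentages:
    """Percent composition of the five groups for one station.

    Abundance mode weights by individuals, presence mode counts species.
    Unassigned species are excluded from both numerator and denominator;
    the excluded fraction is reported alongside.
    """
    if mode not in ("abundance", "presence"):
        raise GambiError(f"unknown mode {mode!r}")
    if sample.azoic:
        raise AzoicSampleError(
            f"station {sample.station_id!r} is azoic; use compute_index for the azoic convention"
        )
    weights = np.zeros(5)
    unassigned_weight = 0.0
    n_taxa_used = 0
    for sp, count in sample.abundances.items():
        if count <= 0:
            continue
        w = float(count) if mode == "abundance" else 1.0
        g = eg.group_of(sp)
        if g is EcologicalGroup.UNASSIGNED:
            unassigned_weight += w
            continue
        weights[ASSIGNED_GROUPS.index(g)] += w
        n_taxa_used += 1
    total = weights.sum()
    if total == 0:
        raise IndexNotComputableError(
            f"station {sample.station_id!r}: index not computable (no assigned taxa)"
        )
    unassigned_fraction = unassigned_weight / (unassigned_weight + total)
    if unassigned_fraction > 0.2:
        logger.warning(
            "station %r: %.0f%% of %s unassigned; index reliability reduced",
            sample.station_id,
            100 * unassigned_fraction,
            "individuals" if mode == "abundance" else "species",
        )
    return GroupPercentages(
        pct=100.0 * weights / total,
        unassigned_fraction=unassigned_fraction,
        n_taxa_used=n_taxa_used,
    )


def compute_index(
    sample: StationSample, eg: EcologicalGroupMap, mode: str = "abundance"
) -> AmbiResult:
    """Index value and quality class for one station.

    value = (0*%GI + 1.5*%GII + 3*%GIII + 4.5*%GIV + 6*%GV) / 100 for
    non-azoic stations (range [0, 6]); azoic stations get value 7 and the
    'extremely polluted' class with the azoic flag set.
    """
    if sample.azoic:
        return AmbiResult(
            station_id=sample.station_id,
            value=AZOIC_VALUE,
            mode=mode,
            quality_class=QUALITY_CLASSES[-1],
            azoic=True,
            unassigned_fraction=0.0,
            n_taxa_used=0,
        )
    pcts = group_percentages(sample, eg, mode)
    value = float(GROUP_WEIGHTS @ pcts.pct / 100.0)
    if pcts.n_taxa_used <= 3:
        logger.warning(
            "station %r: only %d assigned taxa; index may be unreliable at very low richness",
            sample.station_id,
            pcts.n_taxa_used,
        )
    return AmbiResult(
        station_id=sample.station_id,
        value=value,
        mode=mode,
        quality_class=classify_pollution(value),
        azoic=False,
        unassigned_fraction=pcts.unassigned_fraction,
        n_taxa_used=pcts.n_taxa_used,
        percentages=pcts,
    )


def eg_heterogeneity_by_rank(
    eg: EcologicalGroupMap,
    taxonomy: Mapping[str, Mapping[str, str]],
    ranks: Iterable[str] = ("genus", "family", "order", "class", "phylum"),
) -> pd.DataFrame:
    """Per taxonomic rank, how many taxa contain species spanning 1..5 distinct groups.

    Unassigned species are excluded.  Rows are ranks, columns 1..5 count
    taxa whose member species belong to that many distinct ecological groups.
    """
    ranks = list(ranks)
    rows = {}
    for rank in ranks:
        taxon_groups: dict[str, set[EcologicalGroup]] = {}
        for key, rec in eg.entries.items():
            if rec.group is EcologicalGroup.UNASSIGNED:
                continue
            display = eg.display_names[key]
            tax = taxonomy.get(display) or taxonomy.get(key)
            if tax is None:
                raise GambiError(f"taxonomy missing for species {display!r}")
            taxon = tax[rank]
            taxon_groups.setdefault(taxon, set()).add(rec.group)
        counts = [0] * 5
        for groups in taxon_groups.values():
            counts[len(groups) - 1] += 1
        rows[rank] = counts
    return pd.DataFrame.from_dict(rows, orient="index", columns=[1, 2, 3, 4, 5]).rename_axis("rank")
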