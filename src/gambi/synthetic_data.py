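"""Synthetic inputs with the statistical structure the analysis assumes.

Communities are simulated along a pollution gradient: each species gets a
long-tailed baseline occurrence frequency and an ecological-group response
curve (logistic in pressure; sensitive groups decline, opportunists rise),
occupancy is Bernoulli(baseline x response) and abundances are geometric.
Barcode libraries cover a configurable fraction of species (uniform,
frequency-biased, or skewed toward one ecological group) with sequences
derived from a marker reference by per-site mutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from gambi._errors import GambiError
from gambi.core_index import (
    ASSIGNED_GROUPS,
    EcologicalGroup,
    EcologicalGroupMap,
    StationSample,
)
from gambi.primer_insilico import PrimerPair, reverse_complement
from gambi.reference_library import SequenceRecord

#: dominant phyla and their relative richness (long tail of minor phyla pooled)
PHYLA = ("Annelida", "Mollusca", "Arthropoda", "Echinodermata", "Cnidaria")
PHYLUM_WEIGHTS = (0.38, 0.26, 0.25, 0.06, 0.05)

#: uneven whole-list ecological-group proportions used by default
DEFAULT_EG_PROPORTIONS = (0.25, 0.20, 0.30, 0.15, 0.10)


@dataclass
class CommunityModelConfig:
    n_species: int = 300
    n_stations: int = 200
    eg_proportions: tuple[float, ...] = DEFAULT_EG_PROPORTIONS
    unassigned_fraction: float = 0.0
    pressure: np.ndarray | None = None  # per-station in [0,1]; default: linear ramp
    frequency_shape: float = 1.2  # sigma of the lognormal baseline-frequency law
    base_frequency_median: float = 0.10
    abundance_scale: float = 10.0  # mean individuals per present species
    seed: int = 0

    def __post_init__(self) -> None:
        props = np.asarray(self.eg_proportions, dtype=float)
        if props.shape != (5,):
            raise GambiError("eg_proportions must have exactly 5 entries")
        if (props < 0).any() or props.sum() <= 0:
            raise GambiError("eg_proportions must be non-negative and not all zero")
        if abs(props.sum() - 1.0) > 1e-9:
            raise GambiError("eg_proportions must sum to 1")
        if self.n_species <= 0 or self.n_stations <= 0:
            raise GambiError("n_species and n_stations must be positive")

    def station_pressures(self) -> np.ndarray:
        if self.pressure is not None:
            p = np.asarray(self.pressure, dtype=float)
            if p.shape != (self.n_stations,):
                raise GambiError("pressure must have one value per station")
            return p
        if self.n_stations == 1:
            return np.array([0.5])
        return np.linspace(0.0, 1.0, self.n_stations)


@dataclass
class EGResponseCurves:
    """Occupancy multiplier per group as a logistic function of pressure.

    p_g(x) = 1 / (1 + exp(-(a_g + b_g * x))).  Defaults: GI declines
    steeply, GII declines gently, GIII is flat, GIV rises, GV rises
    strongly — so p_V >= p_IV >= p_III >= p_II >= p_I at pressure 1.
    """

    intercepts: tuple[float, ...] = (1.0, 0.5, 0.0, -2.0, -4.0)
    slopes: tuple[float, ...] = (-4.0, -1.5, 0.0, 3.0, 7.0)

    def occupancy(self, pressure: np.ndarray | float) -> np.ndarray:
        x = np.atleast_1d(np.asarray(pressure, dtype=float))
        a = np.asarray(self.intercepts)
        b = np.asarray(self.slopes)
        return 1.0 / (1.0 + np.exp(-(a[None, :] + b[None, :] * x[:, None])))


def generate_eg_map(config: CommunityModelConfig) -> EcologicalGroupMap:
    """Seeded species list over the dominant phyla with multinomial group draws."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    eg = EcologicalGroupMap()
    tokens = list(ASSIGNED_GROUPS) + [EcologicalGroup.UNASSIGNED]
    probs = np.array(list(config.eg_proportions)) * (1.0 - config.unassigned_fraction)
    probs = np.append(probs, config.unassigned_fraction)
    group_draws = rng.choice(len(tokens), size=config.n_species, p=probs / probs.sum())
    phylum_draws = rng.choice(len(PHYLA), size=config.n_species, p=PHYLUM_WEIGHTS)
    for i in range(config.n_species):
        phylum = PHYLA[phylum_draws[i]]
        name = f"{phylum[:4]}ella g{phylum_draws[i]} sp{i:04d}"
        eg.add(name, phylum=phylum, group=tokens[group_draws[i]])
    return eg


def generate_gradient_communities(
    eg_map: EcologicalGroupMap,
    config: CommunityModelConfig,
    curves: EGResponseCurves = EGResponseCurves(),
) -> tuple[list[StationSample], np.ndarray]:
    """Station samples along the pressure gradient plus the true pressures.

    A station is azoic when no species happens to be present; nothing
    forces this.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    species = eg_map.species()
    S = len(species)
    group_idx = np.zeros(S, dtype=int)
    for j, sp in enumerate(species):
        g = eg_map.group_of(sp)
        # unassigned species respond like the flat mid-gradient group
        group_idx[j] = 2 if g is EcologicalGroup.UNASSIGNED else ASSIGNED_GROUPS.index(g)
    base_freq = np.clip(
        rng.lognormal(
            mean=np.log(config.base_frequency_median),
            sigma=config.frequency_shape,
            size=S,
        ),
        0.002,
        0.95,
    )
    pressures = config.station_pressures()
    occ = curves.occupancy(pressures)  # (n_stations, 5)
    prob_present = base_freq[None, :] * occ[:, group_idx]
    present = rng.random((config.n_stations, S)) < prob_present
    p_geo = min(1.0, 1.0 / max(config.abundance_scale, 1.0))
    abundances = rng.geometric(p_geo, size=present.shape)
    samples = []
    for i in range(config.n_stations):
        counts = {
            species[j]: int(abundances[i, j]) for j in np.flatnonzero(present[i])
        }
        samples.append(StationSample(station_id=f"st{i:04d}", abundances=counts))
    return samples, pressures


# ---------------------------------------------------------------------------
# barcode library simulation


@dataclass
class LibrarySimConfig:
    coverage_fraction: float = 0.15
    bias: str = "none"  # none | frequent | eg-skewed
    marker: str = "CO1"
    sequence_length: int = 700
    mutation_rate: float = 0.02
    n_sequences_per_species: int = 1
    eg_skew_group: EcologicalGroup = EcologicalGroup.III
    eg_skew_factor: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.coverage_fraction <= 1.0):
            raise GambiError("coverage_fraction must be in [0, 1]")
        if self.bias not in ("none", "frequent", "eg-skewed"):
            raise GambiError(f"unknown bias {self.bias!r}")


@dataclass
class SimulatedLibrary:
    records: list[SequenceRecord]
    covered_species: set[str]  # truth mask (display names)
    reference: SequenceRecord
    primer_pair: PrimerPair


#: (forward window, reverse window) planted on the marker reference, 0-based
_PRIMER_FWD_START = 30
_PRIMER_LEN = 20


def marker_reference(marker: str, seed: int, length: int = 700) -> SequenceRecord:
    """Deterministic random reference sequence for a marker."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303, _marker_code(marker)]))
    seq = "".join(rng.choice(list("ACGT"), size=length))
    return SequenceRecord(
        id=f"ref_{marker}", species=f"Reference {marker}", phylum="-", marker=marker, seq=seq
    )


def _marker_code(marker: str) -> int:
    return sum(ord(c) for c in marker)


def marker_primer_pair(reference: SequenceRecord, degenerate_positions: int = 2) -> PrimerPair:
    """Primer pair matching planted windows of a reference, mildly degenerate.

    Degenerate codes are chosen to contain the reference base, so the pair
    matches the reference perfectly by construction.
    """
    rng = np.random.default_rng(np.random.SeedSequence([_marker_code(reference.marker), 404]))
    widen = {"A": "R", "G": "R", "C": "Y", "T": "Y"}
    fwd_site = reference.seq[_PRIMER_FWD_START : _PRIMER_FWD_START + _PRIMER_LEN]
    rev_start = len(reference.seq) - _PRIMER_FWD_START - _PRIMER_LEN
    rev_site = reference.seq[rev_start : rev_start + _PRIMER_LEN]

    def degenerate(site: str) -> str:
        # never touch the 3'-proximal third so degeneracy cannot flip calls there
        positions = rng.choice(len(site) * 2 // 3, size=degenerate_positions, replace=False)
        chars = list(site)
        for p in positions:
            chars[p] = widen[chars[p]]
        return "".join(chars)

    return PrimerPair(
        name=f"{reference.marker}_pair",
        forward=degenerate(fwd_site),
        reverse=degenerate(reverse_complement(rev_site)),
        marker=reference.marker,
    )


def generate_barcode_library(
    eg_map: EcologicalGroupMap,
    species_frequencies: Mapping[str, float] | pd.DataFrame | None,
    config: LibrarySimConfig,
) -> SimulatedLibrary:
    """Simulated per-marker barcode library with a ground-truth coverage mask.

    Covered species are drawn uniformly, proportionally to occurrence
    frequency, or skewed toward one ecological group.  Each sequence is the
    marker reference mutated per site at ``mutation_rate`` (so primer sites
    degrade realistically).
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 505, _marker_code(config.marker)])
    )
    species = eg_map.species()
    n_cover = int(round(config.coverage_fraction * len(species)))
    freqs: dict[str, float] = {}
    if isinstance(species_frequencies, pd.DataFrame):
        freqs = dict(zip(species_frequencies["species"], species_frequencies["occurrences"]))
    elif species_frequencies:
        freqs = dict(species_frequencies)
    if config.bias == "none":
        weights = np.ones(len(species))
    elif config.bias == "frequent":
        if not freqs:
            raise GambiError("frequency-biased coverage requires species_frequencies")
        weights = np.array([float(freqs.get(sp, 0.0)) for sp in species])
        if weights.sum() == 0:
            raise GambiError("all species frequencies are zero")
    else:  # eg-skewed
        weights = np.array(
            [
                config.eg_skew_factor
                if eg_map.group_of(sp) is config.eg_skew_group
                else 1.0
                for sp in species
            ]
        )
    covered_idx = _weighted_sample_without_replacement(rng, weights, n_cover)
    covered = {species[j] for j in covered_idx}
    reference = marker_reference(config.marker, config.seed, config.sequence_length)
    ref_arr = np.frombuffer(reference.seq.encode("ascii"), dtype=np.uint8).copy()
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    records: list[SequenceRecord] = []
    for sp in sorted(covered):
        for k in range(config.n_sequences_per_species):
            seq_arr = ref_arr.copy()
            mutate = rng.random(len(seq_arr)) < config.mutation_rate
            for pos in np.flatnonzero(mutate):
                alternatives = bases[bases != seq_arr[pos]]
                seq_arr[pos] = rng.choice(alternatives)
            records.append(
                SequenceRecord(
                    id=f"{config.marker}_{sp.replace(' ', '_')}_{k}",
                    species=sp,
                    phylum=eg_map.phylum_of(sp) or "unknown",
                    marker=config.marker,
                    seq=seq_arr.tobytes().decode("ascii"),
                )
            )
    return SimulatedLibrary(
        records=records,
        covered_species=covered,
        reference=reference,
        primer_pair=marker_primer_pair(reference),
    )


def _weighted_sample_without_replacement(
    rng: np.random.Generator, weights: np.ndarray, size: int
) -> np.ndarray:
    if size == 0:
        return np.array([], dtype=int)
    if size > (weights > 0).sum():
        raise GambiError("not enough positively-weighted species to cover")
    # Efraimidis-Spirakis keys: reproducible weighted sampling without replacement
    keys = np.full(len(weights), -np.inf)
    positive = weights > 0
    u = rng.random(int(positive.sum()))
    keys[positive] = np.log(u) / weights[positive]
    return np.sort(np.argsort(keys)[::-1][:size])
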