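"""Species-subset analysis: frequency ranking, restricted-index agreement,
and the 100-replicate random-subset null for kappa significance.

The observed statistic is the kappa between presence-based quality classes
computed on the full species set and on a subset (most-frequent, sequenced,
or random).  Significance of the frequent-subset kappa comes from a
one-sided normal approximation to the random-subset null distribution,
with an empirical companion p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from gambi._errors import GambiError
from gambi.agreement import KappaResult, cohens_kappa, confusion_matrix
from gambi.core_index import (
    ASSIGNED_GROUPS,
    CLASS_UPPER_BOUNDS,
    GROUP_WEIGHTS,
    QUALITY_CLASSES,
    EcologicalGroup,
    EcologicalGroupMap,
    StationSample,
    normalize_name,
)


# ---------------------------------------------------------------------------
# frequency ranking


def species_frequency_ranking(samples: Sequence[StationSample]) -> pd.DataFrame:
    """Rank species by the number of stations where they occur.

    Descending occurrence count; ties broken by species name ascending.
    Columns: species, occurrences, relative_frequency, rank (1 = most frequent).
    """
    non_azoic = [s for s in samples if not s.azoic]
    if not non_azoic:
        raise GambiError("all stations are azoic; no species to rank")
    counts: dict[str, int] = {}
    for s in non_azoic:
        for sp in s.present_species():
            counts[sp] = counts.get(sp, 0) + 1
    table = pd.DataFrame(
        sorted(counts.items(), key=lambda kv: (-kv[1], normalize_name(kv[0]))),
        columns=["species", "occurrences"],
    )
    table["relative_frequency"] = table["occurrences"] / len(non_azoic)
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def top_fraction_species(ranking: pd.DataFrame, fraction: float) -> list[str]:
    """The round(fraction * S) most frequent species (at least one)."""
    if not (0.0 < fraction <= 1.0):
        raise GambiError(f"fraction {fraction} outside (0, 1]")
    k = max(1, int(round(fraction * len(ranking))))
    return ranking["species"].head(k).tolist()


# ---------------------------------------------------------------------------
# restriction


@dataclass
class RestrictionResult:
    samples: list[StationSample]
    newly_azoic: list[str]


def restrict_samples(
    samples: Sequence[StationSample], keep: Iterable[str]
) -> RestrictionResult:
    """Drop species outside ``keep``; flag stations that become empty."""
    keep_norm = {normalize_name(sp) for sp in keep}
    if not keep_norm:
        raise GambiError("keep set is empty")
    observed = {normalize_name(sp) for s in samples for sp in s.abundances}
    if observed and keep_norm.isdisjoint(observed):
        raise GambiError("keep set is disjoint from the species in the matrix")
    out: list[StationSample] = []
    newly_azoic: list[str] = []
    for s in samples:
        kept = {
            sp: c for sp, c in s.abundances.items() if normalize_name(sp) in keep_norm
        }
        restricted = StationSample(station_id=s.station_id, abundances=kept)
        if restricted.azoic and not s.azoic:
            newly_azoic.append(s.station_id)
        out.append(restricted)
    return RestrictionResult(samples=out, newly_azoic=newly_azoic)


# ---------------------------------------------------------------------------
# vectorized presence-mode classification (internal fast path; agrees with
# core_index.compute_index — see tests)


@dataclass
class _PresenceArrays:
    station_ids: list[str]
    species: list[str]  # normalized
    presence: np.ndarray  # (n_stations, S) bool
    group_onehot: np.ndarray  # (S, 5) float, zero rows for unassigned
    azoic: np.ndarray  # (n_stations,) bool


def _build_arrays(
    samples: Sequence[StationSample], eg: EcologicalGroupMap
) -> _PresenceArrays:
    species = sorted({normalize_name(sp) for s in samples for sp in s.present_species()})
    col = {sp: j for j, sp in enumerate(species)}
    presence = np.zeros((len(samples), len(species)), dtype=bool)
    for i, s in enumerate(samples):
        for sp in s.present_species():
            presence[i, col[normalize_name(sp)]] = True
    onehot = np.zeros((len(species), 5))
    for sp, j in col.items():
        g = eg.group_of(sp)
        if g is not EcologicalGroup.UNASSIGNED:
            onehot[j, ASSIGNED_GROUPS.index(g)] = 1.0
    return _PresenceArrays(
        station_ids=[s.station_id for s in samples],
        species=species,
        presence=presence,
        group_onehot=onehot,
        azoic=np.array([s.azoic for s in samples]),
    )


def _classes_under_mask(
    arrays: _PresenceArrays, keep_mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Presence-mode class index per station under a species mask.

    Returns (class_index, valid) where valid marks stations with at least
    one assigned kept species.
    """
    onehot = arrays.group_onehot * keep_mask[:, None]
    counts = arrays.presence @ onehot  # (n, 5) species counts per group
    totals = counts.sum(axis=1)
    valid = totals > 0
    values = np.zeros(len(totals))
    values[valid] = (counts[valid] @ GROUP_WEIGHTS) / totals[valid]
    class_idx = np.searchsorted(CLASS_UPPER_BOUNDS[:-1], values, side="left")
    return class_idx, valid


def _kappa_from_masks(
    arrays: _PresenceArrays, keep_mask: np.ndarray, exclude_azoic: bool = True
) -> tuple[KappaResult, int]:
    full_idx, full_valid = _classes_under_mask(
        arrays, np.ones(len(arrays.species), dtype=bool)
    )
    sub_idx, sub_valid = _classes_under_mask(arrays, keep_mask)
    comparable = full_valid & sub_valid
    if exclude_azoic:
        comparable &= ~arrays.azoic
    n_excluded = int((~comparable).sum())
    if comparable.sum() < 1:
        raise GambiError("fewer than one comparable station after restriction")
    labels_full = [QUALITY_CLASSES[i] for i in full_idx[comparable]]
    labels_sub = [QUALITY_CLASSES[i] for i in sub_idx[comparable]]
    return cohens_kappa(confusion_matrix(labels_full, labels_sub)), n_excluded


# ---------------------------------------------------------------------------
# subset agreement and the resampling null


@dataclass
class SubsetAgreement:
    kappa: KappaResult
    n_excluded: int


def subset_agreement(
    samples: Sequence[StationSample],
    eg: EcologicalGroupMap,
    keep: Iterable[str],
    exclude_azoic: bool = True,
) -> SubsetAgreement:
    """Kappa between full-species and subset-restricted presence classifications.

    Stations with no assigned species under either classification (and,
    by default, azoic stations) are excluded pairwise.
    """
    keep_norm = {normalize_name(sp) for sp in keep}
    if not keep_norm:
        raise GambiError("keep set is empty")
    arrays = _build_arrays(samples, eg)
    keep_mask = np.array([sp in keep_norm for sp in arrays.species])
    if not keep_mask.any():
        raise GambiError("keep set is disjoint from the species in the matrix")
    kappa, n_excluded = _kappa_from_masks(arrays, keep_mask, exclude_azoic)
    return SubsetAgreement(kappa=kappa, n_excluded=n_excluded)


@dataclass
class SubsetNullConfig:
    fraction: float
    n_replicates: int = 100
    seed: int = 0
    max_empty_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.fraction <= 1.0):
            raise GambiError(f"fraction {self.fraction} outside (0, 1]")
        if self.n_replicates < 2:
            raise GambiError("need at least 2 replicates")


def random_subset_null(
    samples: Sequence[StationSample],
    eg: EcologicalGroupMap,
    config: SubsetNullConfig,
) -> np.ndarray:
    """Null kappa distribution from random species subsets of the observed pool.

    Each replicate draws round(fraction * S) species uniformly without
    replacement from the species observed in the matrix and computes the
    subset-vs-full kappa.  Replicate i uses the seed substream
    ``SeedSequence([seed, i])`` so it is reproducible in isolation.
    Incomputable replicates are returned as NaN, not dropped.
    """
    arrays = _build_arrays(samples, eg)
    S = len(arrays.species)
    size = max(1, int(round(config.fraction * S)))
    if size > S:
        raise GambiError(f"subset size {size} exceeds species pool {S}")
    n_usable = int((~arrays.azoic).sum())
    out = np.full(config.n_replicates, np.nan)
    for i in range(config.n_replicates):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, i]))
        chosen = rng.choice(S, size=size, replace=False)
        mask = np.zeros(S, dtype=bool)
        mask[chosen] = True
        try:
            kappa, n_excluded = _kappa_from_masks(arrays, mask)
        except GambiError:
            continue
        if n_usable and (n_excluded / max(n_usable, 1)) > config.max_empty_fraction:
            # restriction emptied most stations: flagged but still reported
            pass
        out[i] = kappa.kappa
    return out


@dataclass
class SubsetPValue:
    p_parametric: float
    p_empirical: float
    null_mean: float
    null_sd: float
    n_null: int
    degenerate: bool = False


def subset_pvalue(observed: float, null: np.ndarray) -> SubsetPValue:
    """One-sided p-values for an observed kappa against a null distribution.

    Parametric: upper tail of Normal(mean(null), sd(null)) — can fall below
    the 1/n empirical floor.  Empirical: (1 + #{null >= observed}) / (n + 1).
    """
    null = np.asarray(null, dtype=float)
    null = null[~np.isnan(null)]
    if len(null) < 2:
        raise GambiError("need at least 2 non-missing null values")
    mean = float(null.mean())
    sd = float(null.std(ddof=1))
    degenerate = sd == 0.0
    if degenerate:
        p_par = 0.0 if observed > mean else (1.0 if observed < mean else 0.5)
    else:
        p_par = float(stats.norm.sf(observed, loc=mean, scale=sd))
    p_emp = (1 + int((null >= observed).sum())) / (len(null) + 1)
    return SubsetPValue(
        p_parametric=p_par,
        p_empirical=p_emp,
        null_mean=mean,
        null_sd=sd,
        n_null=len(null),
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# ecological-group composition of a subset


def eg_distribution(
    species: Iterable[str],
    eg: EcologicalGroupMap,
    weights: dict[str, float] | None = None,
) -> np.ndarray:
    """Proportion of each ecological group within a species subset.

    ``weights`` (e.g. station-occurrence counts) make the proportions
    frequency-weighted; omitted, every species counts once.  Unassigned
    species are dropped; sums to 1.
    """
    totals = np.zeros(5)
    for sp in species:
        g = eg.group_of(sp)
        if g is EcologicalGroup.UNASSIGNED:
            continue
        w = 1.0 if weights is None else float(weights.get(sp, weights.get(normalize_name(sp), 0.0)))
        totals[ASSIGNED_GROUPS.index(g)] += w
    s = totals.sum()
    if s == 0:
        raise GambiError("all species in the subset are unassigned (or zero-weighted)")
    return totals / s


# ---------------------------------------------------------------------------
# full report over fractions (used by the CLI and the acceptance script)


@dataclass
class SubsetKappaReport:
    fraction: float
    subset_size: int
    observed_kappa: float
    interpretation: str
    null_kappas: np.ndarray
    pvalue: SubsetPValue
    n_excluded: int = 0
    null_missing: int = 0


def analyze_fractions(
    samples: Sequence[StationSample],
    eg: EcologicalGroupMap,
    fractions: Sequence[float],
    n_replicates: int = 100,
    seed: int = 0,
) -> list[SubsetKappaReport]:
    """For each fraction: top-x% frequent subset kappa vs the random-subset null."""
    ranking = species_frequency_ranking(samples)
    reports = []
    for frac in fractions:
        keep = top_fraction_species(ranking, frac)
        observed = subset_agreement(samples, eg, keep)
        null = random_subset_null(
            samples, eg, SubsetNullConfig(fraction=frac, n_replicates=n_replicates, seed=seed)
        )
        pv = subset_pvalue(observed.kappa.kappa, null)
        reports.append(
            SubsetKappaReport(
                fraction=frac,
                subset_size=len(keep),
                observed_kappa=observed.kappa.kappa,
                interpretation=observed.kappa.interpretation,
                null_kappas=null,
                pvalue=pv,
                n_excluded=observed.n_excluded,
                null_missing=int(np.isnan(null).sum()),
            )
        )
    return reports
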