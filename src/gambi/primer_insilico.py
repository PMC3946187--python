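"""In-silico evaluation of degenerate primer pairs against a sequence library.

A primer base matches a template base iff their IUPAC expansion sets
intersect (liberal matching, avoiding false negatives on ambiguous
template bases).  Binding sites are scored with a position-weighted
mismatch scheme: mismatches cost 0.4 outside the 3' window, 1.0 inside it,
and 3.0 at the 3'-terminal base; a site amplifies when the total score is
at or below the threshold (default 1.0).  Sequences are only tested
against a primer pair when a local alignment to the marker reference
covers both annealing regions, so partial sequences never produce false
negatives.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from gambi._errors import GambiError
from gambi.core_index import normalize_name
from gambi.reference_library import SequenceRecord

# ---------------------------------------------------------------------------
# IUPAC machinery

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_BITS = {"A": 1, "C": 2, "G": 4, "T": 8}
IUPAC_MASKS: dict[str, int] = {
    code: sum(_BITS[b] for b in bases) for code, bases in IUPAC_SETS.items()
}

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


def reverse_complement(seq: str) -> str:
    try:
        return "".join(_COMPLEMENT[c] for c in reversed(seq.upper()))
    except KeyError as exc:
        raise GambiError(f"cannot complement non-IUPAC character {exc.args[0]!r}") from None


def degeneracy(primer: str) -> int:
    """Number of concrete sequences a degenerate primer expands to."""
    n = 1
    for c in primer.upper():
        n *= len(IUPAC_SETS[c])
    return n


def expand_degenerate(primer: str) -> list[str]:
    """All concrete ACGT sequences of a degenerate primer (oracle helper)."""
    return ["".join(p) for p in product(*(sorted(IUPAC_SETS[c]) for c in primer.upper()))]


def bases_match(primer_base: str, template_base: str) -> bool:
    """IUPAC set-intersection match."""
    return bool(IUPAC_MASKS[primer_base.upper()] & IUPAC_MASKS[template_base.upper()])


def _mask_array(seq: str) -> np.ndarray:
    return np.array([IUPAC_MASKS[c] for c in seq.upper()], dtype=np.uint8)


# ---------------------------------------------------------------------------
# configuration and primer pairs


@dataclass(frozen=True)
class PrimerScoringConfig:
    penalty_non3_mismatch: float = 0.4
    penalty_3prime_mismatch: float = 1.0
    penalty_final_base_mismatch: float = 3.0
    three_prime_window: int = 5
    amplify_threshold: float = 1.0

    def position_penalties(self, primer_length: int) -> np.ndarray:
        """Per-position mismatch penalty, 5'->3'."""
        if self.three_prime_window > primer_length:
            raise GambiError("3' window longer than the primer")
        pen = np.full(primer_length, self.penalty_non3_mismatch)
        if self.three_prime_window > 1:
            pen[-self.three_prime_window : -1] = self.penalty_3prime_mismatch
        pen[-1] = self.penalty_final_base_mismatch
        return pen


@dataclass
class PrimerPair:
    """A degenerate primer pair; both primers are given 5'->3'.

    The reverse primer is reverse-complemented once at construction so all
    matching happens on the forward strand of the template.  Reference
    coordinates (0-based half-open, outermost annealing positions) are
    filled in by :func:`locate_primer_region`.
    """

    name: str
    forward: str
    reverse: str
    marker: str = ""
    ref_start: int | None = None
    ref_end: int | None = None
    expected_amplicon_length: int | None = None

    def __post_init__(self) -> None:
        self.forward = self.forward.upper()
        self.reverse = self.reverse.upper()
        for primer, label in ((self.forward, "forward"), (self.reverse, "reverse")):
            if len(primer) < 10:
                raise GambiError(f"{label} primer of pair {self.name!r} shorter than 10 nt")
            bad = set(primer) - set(IUPAC_MASKS)
            if bad:
                raise GambiError(
                    f"{label} primer of pair {self.name!r}: non-IUPAC characters {sorted(bad)}"
                )
        self.reverse_rc = reverse_complement(self.reverse)


# ---------------------------------------------------------------------------
# binding-site scoring


def score_primer_binding(
    primer: str, site: str, config: PrimerScoringConfig = PrimerScoringConfig()
) -> float:
    """Mismatch score of a primer against an equal-length template window."""
    if len(primer) != len(site):
        raise GambiError(f"primer length {len(primer)} != site length {len(site)}")
    pen = config.position_penalties(len(primer))
    score = 0.0
    for p, t, w in zip(primer.upper(), site.upper(), pen):
        if not bases_match(p, t):
            score += w
    return float(score)


def _best_window(
    primer_mask: np.ndarray,
    template_mask: np.ndarray,
    penalties: np.ndarray,
    rightmost: bool = False,
) -> tuple[float, int]:
    """(best score, start) of the primer over all template windows.

    Ties resolve to the leftmost window, or the rightmost when requested
    (used for reverse-primer sites).
    """
    L = len(primer_mask)
    n = len(template_mask) - L + 1
    if n <= 0:
        return float("inf"), -1
    windows = np.lib.stride_tricks.sliding_window_view(template_mask, L)
    mismatch = (windows & primer_mask[None, :]) == 0
    scores = mismatch @ penalties
    if rightmost:
        start = int(len(scores) - 1 - np.argmin(scores[::-1]))
    else:
        start = int(np.argmin(scores))
    return float(scores[start]), start


def find_best_site(
    primer: str,
    template: str,
    config: PrimerScoringConfig = PrimerScoringConfig(),
    rightmost: bool = False,
) -> tuple[float, int]:
    """Best-scoring annealing window of a primer on a template forward strand."""
    return _best_window(
        _mask_array(primer),
        _mask_array(template),
        config.position_penalties(len(primer)),
        rightmost=rightmost,
    )


def locate_primer_region(
    reference: SequenceRecord,
    pair: PrimerPair,
    config: PrimerScoringConfig = PrimerScoringConfig(),
) -> tuple[int, int]:
    """Locate both annealing sites on a reference; store and return the outer span.

    The forward primer is matched as-is and the reverse primer as its
    reverse complement, both on the reference forward strand.  Coordinates
    are 0-based half-open over the outermost annealing positions.
    """
    f_score, f_start = find_best_site(pair.forward, reference.seq, config)
    r_score, r_start = find_best_site(pair.reverse_rc, reference.seq, config, rightmost=True)
    if f_score > config.amplify_threshold or r_score > config.amplify_threshold:
        raise GambiError(
            f"primer pair {pair.name!r} not locatable on reference {reference.id!r} "
            f"(forward score {f_score:.1f}, reverse score {r_score:.1f})"
        )
    r_end = r_start + len(pair.reverse_rc)
    f_end = f_start + len(pair.forward)
    if not (f_start < r_end):
        raise GambiError(f"primer pair {pair.name!r}: inverted orientation on reference")
    pair.ref_start, pair.ref_end = f_start, r_end
    pair.expected_amplicon_length = r_end - f_start
    return f_start, r_end


# ---------------------------------------------------------------------------
# testability: local alignment of library sequences to the reference


@dataclass(frozen=True)
class LocalAlignment:
    score: int
    q_start: int
    q_end: int
    r_start: int
    r_end: int


def best_local_alignment(
    query: str, reference: str, word_size: int = 11, match: int = 1, mismatch: int = -1
) -> LocalAlignment | None:
    """Best ungapped local alignment via seeded diagonals.

    Exact word seeds gate candidate diagonals; on each seeded diagonal the
    maximal-scoring segment (+1 match / -1 mismatch, IUPAC-aware) is found
    exactly.  Returns None when no seed exists.
    """
    q = query.upper()
    r = reference.upper()
    if len(q) < word_size or len(r) < word_size:
        return None
    ref_words: dict[str, list[int]] = defaultdict(list)
    for j in range(len(r) - word_size + 1):
        ref_words[r[j : j + word_size]].append(j)
    diagonals: set[int] = set()
    for i in range(len(q) - word_size + 1):
        for j in ref_words.get(q[i : i + word_size], ()):
            diagonals.add(j - i)
    if not diagonals:
        return None
    qm = _mask_array(q)
    rm = _mask_array(r)
    best: LocalAlignment | None = None
    for d in sorted(diagonals):
        q_lo = max(0, -d)
        q_hi = min(len(q), len(r) - d)
        if q_hi - q_lo < word_size:
            continue
        seg = np.where((qm[q_lo:q_hi] & rm[q_lo + d : q_hi + d]) != 0, match, mismatch)
        # maximal-scoring contiguous segment (Kadane with index tracking)
        best_sum, best_i, best_j = -1, 0, 0
        cur_sum, cur_i = 0, 0
        for k, v in enumerate(seg.tolist()):
            if cur_sum <= 0:
                cur_sum, cur_i = 0, k
            cur_sum += v
            if cur_sum > best_sum:
                best_sum, best_i, best_j = cur_sum, cur_i, k + 1
        if best is None or best_sum > best.score:
            best = LocalAlignment(
                score=best_sum,
                q_start=q_lo + best_i,
                q_end=q_lo + best_j,
                r_start=q_lo + best_i + d,
                r_end=q_lo + best_j + d,
            )
    return best


def testable_sequences(
    records: Sequence[SequenceRecord],
    pair: PrimerPair,
    reference: SequenceRecord,
    word_size: int = 11,
) -> list[SequenceRecord]:
    """Records whose alignment to the reference spans both annealing regions.

    Partial sequences missing a primer region are excluded rather than
    being allowed to produce false-negative amplification calls.
    """
    if pair.ref_start is None or pair.ref_end is None:
        raise GambiError(f"primer pair {pair.name!r} has no reference coordinates; "
                         "call locate_primer_region first")
    out = []
    for rec in records:
        aln = best_local_alignment(rec.seq, reference.seq, word_size=word_size)
        if aln is None:
            continue
        if aln.r_start <= pair.ref_start and aln.r_end >= pair.ref_end:
            out.append(rec)
    return out


# ---------------------------------------------------------------------------
# amplification prediction


@dataclass(frozen=True)
class AmplificationCall:
    sequence_id: str
    forward_score: float
    reverse_score: float
    amplifies: bool
    amplicon_start: int | None = None
    amplicon_end: int | None = None

    @property
    def amplicon_length(self) -> int | None:
        if self.amplicon_start is None or self.amplicon_end is None:
            return None
        return self.amplicon_end - self.amplicon_start


def predict_amplification(
    pair: PrimerPair,
    record: SequenceRecord,
    config: PrimerScoringConfig = PrimerScoringConfig(),
) -> AmplificationCall:
    """Amplification call for one template.

    Amplifies iff both best sites score at or below the threshold and the
    forward site lies upstream of the reverse site.  The amplicon spans the
    outer coordinates of both primers.
    """
    f_score, f_start = find_best_site(pair.forward, record.seq, config)
    r_score, r_start = find_best_site(pair.reverse_rc, record.seq, config, rightmost=True)
    f_end = f_start + len(pair.forward)
    r_end = r_start + len(pair.reverse_rc)
    ok_scores = f_score <= config.amplify_threshold and r_score <= config.amplify_threshold
    ok_orientation = f_start >= 0 and r_start >= 0 and f_end <= r_start
    if ok_scores and ok_orientation:
        return AmplificationCall(
            sequence_id=record.id,
            forward_score=f_score,
            reverse_score=r_score,
            amplifies=True,
            amplicon_start=f_start,
            amplicon_end=r_end,
        )
    return AmplificationCall(
        sequence_id=record.id,
        forward_score=f_score,
        reverse_score=r_score,
        amplifies=False,
    )


@dataclass
class SpeciesAmplificationSummary:
    per_species: dict[str, bool]  # display species name -> positive
    per_phylum: pd.DataFrame  # rows: phylum; columns: n_tested, n_positive, pct_positive
    n_tested: int

    def percent_positive(self) -> float:
        if not self.per_species:
            return float("nan")
        return 100.0 * sum(self.per_species.values()) / len(self.per_species)


def species_amplification_summary(
    calls: Sequence[AmplificationCall],
    records: Sequence[SequenceRecord],
) -> SpeciesAmplificationSummary:
    """Aggregate per-sequence calls to species and phyla.

    A species is positive when at least one of its sequences amplifies.
    Phyla with zero tested species are reported with pct_positive = NaN
    (untested), never as 0%.
    """
    by_id = {r.id: r for r in records}
    species_pos: dict[str, bool] = {}
    species_phylum: dict[str, str] = {}
    display: dict[str, str] = {}
    for call in calls:
        rec = by_id.get(call.sequence_id)
        if rec is None:
            raise GambiError(f"call references unknown sequence id {call.sequence_id!r}")
        key = normalize_name(rec.species)
        display.setdefault(key, rec.species)
        species_phylum.setdefault(key, rec.phylum)
        species_pos[key] = species_pos.get(key, False) or call.amplifies
    rows = []
    for ph in sorted(set(species_phylum.values())):
        members = [k for k, p in species_phylum.items() if p == ph]
        n_pos = sum(species_pos[k] for k in members)
        rows.append(
            {
                "phylum": ph,
                "n_tested": len(members),
                "n_positive": n_pos,
                "pct_positive": 100.0 * n_pos / len(members) if members else float("nan"),
            }
        )
    per_phylum = (
        pd.DataFrame(rows).set_index("phylum")
        if rows
        else pd.DataFrame(columns=["n_tested", "n_positive", "pct_positive"])
    )
    return SpeciesAmplificationSummary(
        per_species={display[k]: v for k, v in species_pos.items()},
        per_phylum=per_phylum,
        n_tested=len(species_pos),
    )
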