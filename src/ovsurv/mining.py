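"""Frequent contiguous (no-gap) treatment-substring mining.

A modified GSP: level-wise Apriori-style candidate generation, but support
is counted for *substrings* — the pattern's symbols must appear
consecutively in a patient's sequence.  If treatment W intervenes between
X and Y, the pair X->Y does not match.  Support is per patient (a patient
counts once however often the pattern recurs), and a pattern is frequent
when its count reaches ``ceil(minsup * |DB|)`` — the "at least" reading of
relative support.  A brute-force enumerator over all symbol tuples serves
as an independent oracle.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

from .cohort import PatientRecord


@dataclass(frozen=True)
class Pattern:
    """An ordered run of treatment symbols with its patient-level support."""

    symbols: tuple[str, ...]
    support_count: int
    relative_support: float


@dataclass(frozen=True)
class TreatmentSequenceDB:
    """Per-patient ordered treatment sequences (symbol, month offset)."""

    sequences: dict[str, tuple[tuple[str, float], ...]]
    alphabet: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.sequences)

    def symbols(self, patient_id: str) -> tuple[str, ...]:
        return tuple(s for s, _ in self.sequences[patient_id])


def build_sequence_db(
    cohort: list[PatientRecord], alphabet: tuple[str, ...] | None = None
) -> TreatmentSequenceDB:
    """One entry per patient, events stably sorted by month offset.

    Patients with no recorded treatments are kept with empty sequences and
    count toward |DB| (support is cohort-level prevalence).
    """
    if alphabet is None:
        alphabet = tuple(
            sorted({ev.treatment for rec in cohort for ev in rec.events})
        )
    sequences = {}
    for rec in cohort:
        ordered = sorted(rec.events, key=lambda ev: ev.month_offset)  # stable
        for ev in ordered:
            if ev.treatment not in alphabet:
                raise ValueError(
                    f"patient {rec.patient_id}: treatment {ev.treatment!r} not in alphabet"
                )
        sequences[rec.patient_id] = tuple((ev.treatment, ev.month_offset) for ev in ordered)
    return TreatmentSequenceDB(sequences=sequences, alphabet=alphabet)


def _contains_run(seq: tuple[str, ...], symbols: tuple[str, ...]) -> bool:
    k = len(symbols)
    return any(seq[i : i + k] == symbols for i in range(len(seq) - k + 1))


def substring_support(db: TreatmentSequenceDB, symbols) -> int:
    """Number of patients whose sequence contains ``symbols`` contiguously."""
    symbols = tuple(symbols)
    if not symbols:
        raise ValueError("pattern must be non-empty")
    return sum(
        _contains_run(tuple(s for s, _ in seq), symbols) for seq in db.sequences.values()
    )


def _min_count(minsup: float, n: int) -> int:
    # epsilon guards float artifacts: 0.05*140 = 7.000...001 must give 7, not 8
    return max(1, math.ceil(minsup * n - 1e-9))


def _sorted_patterns(counted: dict[tuple[str, ...], int], n: int) -> list[Pattern]:
    ordered = sorted(counted.items(), key=lambda kv: (len(kv[0]), -kv[1], kv[0]))
    return [Pattern(sym, c, c / n) for sym, c in ordered]


def mine_frequent_substrings(
    db: TreatmentSequenceDB, minsup: float, max_len: int | None = None
) -> list[Pattern]:
    """Level-wise no-gap GSP.

    L1 holds the frequent single symbols; candidates of length k+1 join two
    frequent k-patterns whose (k-1)-suffix and -prefix agree.  Contiguous
    sub-patterns of any candidate are frequent by construction (Apriori
    pruning is implicit in the join).  Output is sorted by (length, support
    descending, lexicographic) and includes length-1 patterns.
    """
    if not 0.0 < minsup <= 1.0:
        raise ValueError("minsup must lie in (0, 1]")
    n = len(db)
    if n == 0:
        raise ValueError("sequence database is empty")
    threshold = _min_count(minsup, n)

    counted: dict[tuple[str, ...], int] = {}
    level = []
    for sym in sorted(db.alphabet):
        c = substring_support(db, (sym,))
        if c >= threshold:
            counted[(sym,)] = c
            level.append((sym,))
    k = 1
    while level and (max_len is None or k < max_len):
        candidates = {
            a + (b[-1],)
            for a in level
            for b in level
            if a[1:] == b[:-1]
        }
        nxt = []
        for cand in sorted(candidates):
            c = substring_support(db, cand)
            if c >= threshold:
                counted[cand] = c
                nxt.append(cand)
        level = nxt
        k += 1
    return _sorted_patterns(counted, n)


def brute_force_frequent(
    db: TreatmentSequenceDB, minsup: float, max_len: int | None = None
) -> list[Pattern]:
    """Oracle: enumerate every symbol tuple up to ``max_len`` and scan.

    Guarded to at most 10^6 candidate tuples.
    """
    if not 0.0 < minsup <= 1.0:
        raise ValueError("minsup must lie in (0, 1]")
    n = len(db)
    if n == 0:
        return []
    if max_len is None:
        max_len = max((len(seq) for seq in db.sequences.values()), default=0)
    a = len(db.alphabet)
    total = sum(a**k for k in range(1, max_len + 1))
    if total > 10**6:
        raise ValueError(f"{total} candidate tuples exceed the 10^6 enumeration guard")
    threshold = _min_count(minsup, n)
    counted = {}
    for k in range(1, max_len + 1):
        for cand in itertools.product(sorted(db.alphabet), repeat=k):
            c = substring_support(db, cand)
            if c >= threshold:
                counted[cand] = c
    return _sorted_patterns(counted, n)
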