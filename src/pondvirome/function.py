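"""ORF functional annotation against SEED subsystems.

Each ORF is assigned the subsystem with the maximum summed bit score among
its (E-value-filtered, subsystem-labelled) hits; ties are broken
lexicographically and flagged.  Because the functional profile of a virome
should describe viral genes, assignments can be restricted to functions
supported by viral-reference (Phage SEED) hits, either strictly (sums
recomputed over viral-subject hits only; the default, immune to cellular
homolog contamination) or leniently (keep the assignment if any contributing
hit is viral).  Per-category rollups sum normalized ORF abundance.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .formats_io import FormatError, HitRecord


@dataclass(frozen=True)
class SubsystemAssignment:
    orf_id: str
    subsystem: str | None
    category: str | None
    sum_bit_score: float
    tie: bool


def read_subsystem_hierarchy(path: str | Path) -> dict[str, str]:
    """Read a two-column subsystem -> top-level category TSV."""
    mapping: dict[str, str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            mapping[fields[0]] = fields[1]
    return mapping


def _winning_subsystem(
    hits: Iterable[HitRecord],
) -> tuple[str | None, float, bool]:
    sums: dict[str, float] = defaultdict(float)
    for h in hits:
        if h.subject_subsystem is None:
            continue
        sums[h.subject_subsystem] += h.bit_score
    if not sums:
        return None, 0.0, False
    max_sum = max(sums.values())
    winners = sorted(s for s, v in sums.items() if v == max_sum)
    return winners[0], max_sum, len(winners) > 1


def assign_orf_subsystem(
    orf_id: str,
    hits_for_orf: Sequence[HitRecord],
    hierarchy: Mapping[str, str] | None = None,
) -> SubsystemAssignment:
    """Assign one ORF the subsystem with the maximum summed bit score.

    ``hits_for_orf`` should already be E-value filtered (E <= 1e-3 in the
    SEED searches); hits without a subsystem label are ignored.  Ties are
    broken by lexicographic subsystem order and flagged.  An ORF with no
    labelled hits comes back unassigned.
    """
    subsystem, score, tie = _winning_subsystem(hits_for_orf)
    category = None
    if subsystem is not None and hierarchy is not None:
        category = hierarchy.get(subsystem, subsystem)
    elif subsystem is not None:
        category = subsystem
    return SubsystemAssignment(orf_id, subsystem, category, score, tie)


def assign_all_subsystems(
    hits: Iterable[HitRecord],
    hierarchy: Mapping[str, str] | None = None,
) -> list[SubsystemAssignment]:
    """Group hits by query ORF and assign every ORF that has hits."""
    by_orf: dict[str, list[HitRecord]] = defaultdict(list)
    for h in hits:
        by_orf[h.query_id].append(h)
    return [
        assign_orf_subsystem(oid, by_orf[oid], hierarchy)
        for oid in sorted(by_orf)
    ]


def restrict_to_viral(
    assignments: Sequence[SubsystemAssignment],
    hits: Iterable[HitRecord],
    viral_subject_ids: set[str] | None = None,
    strict: bool = True,
    hierarchy: Mapping[str, str] | None = None,
) -> list[SubsystemAssignment]:
    """Keep only functions associated with viral-reference hits.

    A hit is viral if its ``subject_is_viral`` flag is set or its subject id
    is in ``viral_subject_ids``.  In strict mode, sums are recomputed over
    each ORF's viral hits only (the ORF is dropped if no viral hit remains).
    In lenient mode an ORF keeps its original assignment whenever at least
    one viral hit contributed to the winning subsystem.
    """
    viral_subject_ids = viral_subject_ids or set()

    def hit_is_viral(h: HitRecord) -> bool:
        return h.subject_is_viral or h.subject_id in viral_subject_ids

    by_orf: dict[str, list[HitRecord]] = defaultdict(list)
    for h in hits:
        by_orf[h.query_id].append(h)

    kept: list[SubsystemAssignment] = []
    for a in assignments:
        if a.subsystem is None:
            continue
        orf_hits = by_orf.get(a.orf_id, [])
        viral_hits = [h for h in orf_hits if hit_is_viral(h)]
        if strict:
            if not viral_hits:
                continue
            kept.append(assign_orf_subsystem(a.orf_id, viral_hits, hierarchy))
        else:
            if any(h.subject_subsystem == a.subsystem for h in viral_hits):
                kept.append(a)
    return kept


def rollup_function_abundance(
    assignments: Sequence[SubsystemAssignment],
    orf_abundances: Mapping[str, float],
) -> pd.DataFrame:
    """Sum normalized ORF abundance per top-level functional category.

    Fractions are over the total assigned ORF abundance mass.
    """
    groups: dict[str, float] = defaultdict(float)
    for a in assignments:
        if a.subsystem is None:
            continue
        if a.orf_id not in orf_abundances:
            raise KeyError(f"no abundance record for ORF {a.orf_id!r}")
        groups[a.category or a.subsystem] += orf_abundances[a.orf_id]
    total = sum(groups.values())
    rows = [
        (cat, groups[cat], groups[cat] / total if total > 0 else 0.0)
        for cat in sorted(groups, key=lambda c: (-groups[c], c))
    ]
    return pd.DataFrame(rows, columns=["category", "normalized_abundance",
                                       "fraction"])


def write_assignments(path: str | Path,
                      assignments: Sequence[SubsystemAssignment]) -> None:
    with open(path, "w") as handle:
        handle.write("orf_id\tsubsystem\tcategory\tsum_bit_score\ttie\n")
        for a in assignments:
            handle.write(
                f"{a.orf_id}\t{a.subsystem or ''}\t{a.category or ''}\t"
                f"{a.sum_bit_score}\t{int(a.tie)}\n"
            )
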