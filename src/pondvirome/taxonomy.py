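"""Contig taxonomy by the maximum-sum-bit-score rule.

Each contig is assigned the taxonomy ID whose summed bit score, over all
qualifying BLASTp hits of all the contig's ORFs, is largest.  Ties go to the
numerically smallest taxid and are flagged.  A small offline taxonomy table
(taxid, parent, rank, name) supports the viral test (does the lineage reach
a designated viral root?) and rank-level abundance rollups.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .formats_io import FormatError, HitRecord, Orf

#: BLASTp E-value cutoff used for SEED / Phage SEED searches.
DEFAULT_MAX_EVALUE = 1e-3

UNASSIGNED_LABEL = "no known homolog"


@dataclass(frozen=True)
class TaxonomyAssignment:
    contig_id: str
    taxid: int | None
    sum_bit_score: float
    tie: bool
    is_viral: bool


@dataclass
class TaxonomyNode:
    taxid: int
    parent: int
    rank: str
    name: str


@dataclass
class TaxonomyMap:
    """Offline taxid -> (name, parent, rank) lookup with viral roots.

    Parent chains must terminate at a self-parenting root; the viral test
    walks parents until it hits a designated viral root or a tree root.
    """

    nodes: dict[int, TaxonomyNode]
    viral_roots: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        for taxid, node in self.nodes.items():
            if node.parent not in self.nodes:
                raise ValueError(
                    f"taxid {taxid}: parent {node.parent} not in table"
                )
        # detect cycles / dangling chains once, up front
        for taxid in self.nodes:
            self._walk_to_root(taxid)

    def _walk_to_root(self, taxid: int) -> list[int]:
        chain = []
        seen = set()
        cur = taxid
        while True:
            if cur in seen:
                raise ValueError(f"taxonomy cycle at taxid {cur}")
            seen.add(cur)
            chain.append(cur)
            parent = self.nodes[cur].parent
            if parent == cur:
                return chain
            cur = parent

    def lineage(self, taxid: int) -> list[int]:
        """Taxids from ``taxid`` up to (and including) its root."""
        if taxid not in self.nodes:
            raise KeyError(f"unknown taxid {taxid}")
        return self._walk_to_root(taxid)

    def lineage_names(self, taxid: int) -> str:
        return ";".join(
            self.nodes[t].name for t in reversed(self.lineage(taxid))
        )

    def name(self, taxid: int) -> str:
        return self.nodes[taxid].name

    def ancestor_at_rank(self, taxid: int, rank: str) -> int | None:
        """Nearest ancestor (or self) with the requested rank, else None."""
        for t in self.lineage(taxid):
            if self.nodes[t].rank == rank:
                return t
        return None


def read_taxonomy_map(path: str | Path) -> TaxonomyMap:
    """Read a nodes TSV: taxid, parent_taxid, rank, name, is_viral_root."""
    nodes: dict[int, TaxonomyNode] = {}
    viral_roots: set[int] = set()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise FormatError(f"{path}:{lineno}: expected 5 columns")
            try:
                taxid, parent = int(fields[0]), int(fields[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if taxid in nodes:
                raise FormatError(f"{path}:{lineno}: duplicate taxid {taxid}")
            nodes[taxid] = TaxonomyNode(taxid, parent, fields[2], fields[3])
            if fields[4] in ("1", "true", "True"):
                viral_roots.add(taxid)
    return TaxonomyMap(nodes, viral_roots)


def write_taxonomy_map(path: str | Path, taxmap: TaxonomyMap) -> None:
    with open(path, "w") as handle:
        for taxid in sorted(taxmap.nodes):
            n = taxmap.nodes[taxid]
            viral = "1" if taxid in taxmap.viral_roots else "0"
            handle.write(f"{taxid}\t{n.parent}\t{n.rank}\t{n.name}\t{viral}\n")


def filter_hits(hits: Iterable[HitRecord],
                max_evalue: float = DEFAULT_MAX_EVALUE) -> list[HitRecord]:
    """Keep hits with E-value <= cutoff (inclusive), preserving order."""
    if max_evalue <= 0:
        raise ValueError("max_evalue must be > 0")
    return [h for h in hits if h.evalue <= max_evalue]


def assign_contig_taxonomy(
    orfs: Sequence[Orf],
    hits: Iterable[HitRecord],
    taxmap: TaxonomyMap | None = None,
    best_hit_only: bool = False,
) -> list[TaxonomyAssignment]:
    """Assign each contig the taxid with the maximum summed bit score.

    Bit scores of all taxid-annotated hits of all the contig's ORFs are
    summed per taxid (with ``best_hit_only`` only each ORF's single highest
    bit score per taxid enters the sum); the taxid with the largest sum
    wins.  Ties (>= 2 taxids sharing the maximum) are broken by the smaller
    taxid and flagged.  Contigs with no qualifying hits get ``taxid=None``.
    Hits referencing ORFs not in ``orfs`` are an error.
    """
    orf_to_contig = {o.id: o.contig_id for o in orfs}
    contigs = sorted({o.contig_id for o in orfs})
    # contig -> taxid -> summed bit score
    sums: dict[str, dict[int, float]] = {c: defaultdict(float) for c in contigs}
    best: dict[str, dict[tuple[str, int], float]] = {c: {} for c in contigs}
    for hit in hits:
        if hit.subject_taxid is None:
            continue
        if hit.query_id not in orf_to_contig:
            raise KeyError(f"hit references unknown ORF {hit.query_id!r}")
        cid = orf_to_contig[hit.query_id]
        if best_hit_only:
            key = (hit.query_id, hit.subject_taxid)
            prev = best[cid].get(key, 0.0)
            if hit.bit_score > prev:
                best[cid][key] = hit.bit_score
        else:
            sums[cid][hit.subject_taxid] += hit.bit_score
    if best_hit_only:
        for cid, per_orf in best.items():
            for (_, taxid), score in per_orf.items():
                sums[cid][taxid] += score

    assignments = []
    for cid in contigs:
        taxid_sums = sums[cid]
        if not taxid_sums:
            assignments.append(TaxonomyAssignment(cid, None, 0.0, False, False))
            continue
        max_sum = max(taxid_sums.values())
        winners = sorted(t for t, s in taxid_sums.items() if s == max_sum)
        winner = winners[0]
        viral = bool(taxmap and is_viral(winner, taxmap))
        assignments.append(TaxonomyAssignment(
            cid, winner, max_sum, tie=len(winners) > 1, is_viral=viral,
        ))
    return assignments


def is_viral(taxid: int, taxmap: TaxonomyMap) -> bool:
    """True iff walking parent links from taxid reaches a viral root."""
    return any(t in taxmap.viral_roots for t in taxmap.lineage(taxid))


def rollup_taxon_abundance(
    assignments: Sequence[TaxonomyAssignment],
    contig_abundances: Mapping[str, float],
    taxmap: TaxonomyMap,
    rank: str,
) -> pd.DataFrame:
    """Sum normalized abundance per ancestor group at the requested rank.

    Assigned contigs whose lineage lacks the rank are grouped under their
    own taxon name; unassigned contigs form a separate "no known homolog"
    group.  Fractions are over assigned + unassigned mass together, so they
    sum to 1 and total abundance is conserved.
    """
    groups: dict[str, float] = defaultdict(float)
    for a in assignments:
        if a.contig_id not in contig_abundances:
            raise KeyError(f"no abundance record for contig {a.contig_id!r}")
        abund = contig_abundances[a.contig_id]
        if a.taxid is None:
            groups[UNASSIGNED_LABEL] += abund
        else:
            anc = taxmap.ancestor_at_rank(a.taxid, rank)
            label = taxmap.name(anc) if anc is not None else taxmap.name(a.taxid)
            groups[label] += abund
    total = sum(groups.values())
    rows = [
        (label, groups[label], groups[label] / total if total > 0 else 0.0)
        for label in sorted(groups, key=lambda g: (-groups[g], g))
    ]
    return pd.DataFrame(rows, columns=["group", "normalized_abundance",
                                       "fraction"])


def assignment_summary(
    assignments: Sequence[TaxonomyAssignment],
    contig_abundances: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Assigned / viral fractions by contig count and by abundance mass."""
    n = len(assignments)
    out: dict[str, float] = {
        "n_contigs": float(n),
        "assigned_fraction_by_count": (
            sum(a.taxid is not None for a in assignments) / n if n else 0.0
        ),
        "viral_fraction_of_assigned_by_count": 0.0,
    }
    n_assigned = sum(a.taxid is not None for a in assignments)
    if n_assigned:
        out["viral_fraction_of_assigned_by_count"] = (
            sum(a.is_viral for a in assignments) / n_assigned
        )
    if contig_abundances is not None:
        total = sum(contig_abundances[a.contig_id] for a in assignments)
        assigned = sum(contig_abundances[a.contig_id]
                       for a in assignments if a.taxid is not None)
        viral = sum(contig_abundances[a.contig_id]
                    for a in assignments if a.is_viral)
        out["assigned_fraction_by_abundance"] = assigned / total if total else 0.0
        out["viral_fraction_of_assigned_by_abundance"] = (
            viral / assigned if assigned else 0.0
        )
    return out


def write_assignments(path: str | Path,
                      assignments: Sequence[TaxonomyAssignment],
                      taxmap: TaxonomyMap | None = None) -> None:
    with open(path, "w") as handle:
        handle.write("contig_id\ttaxid\tlineage\tsum_bit_score\ttie\tis_viral\n")
        for a in assignments:
            lineage = ""
            if a.taxid is not None and taxmap is not None:
                lineage = taxmap.lineage_names(a.taxid)
            handle.write(
                f"{a.contig_id}\t{'' if a.taxid is None else a.taxid}\t"
                f"{lineage}\t{a.sum_bit_score}\t{int(a.tie)}\t{int(a.is_viral)}\n"
            )
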