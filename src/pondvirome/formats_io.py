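"""Readers and writers for the external formats the pipeline touches.

Everything on disk is text: FASTA, SAM, samtools-depth three-column TSV,
BLAST tabular (outfmt 6 plus optional annotation columns), classic OTU
tables (rows = OTUs, columns = samples, trailing ``taxonomy`` column), and
MetaGene-style ORF coordinate tables.  All on-disk coordinates are 1-based
inclusive; parsing is strict and deterministic (same bytes, same values).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio.SeqIO.FastaIO import SimpleFastaParser


class FormatError(ValueError):
    """A file violated the expectations of its format."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Contig:
    """An assembled sequence; the unit taxonomy and coverage attach to."""

    id: str
    length: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"contig {self.id!r}: length must be >= 1")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"contig {self.id!r}: sequence length {len(self.sequence)} "
                f"!= declared length {self.length}"
            )


@dataclass(frozen=True)
class Orf:
    """A predicted gene on a contig, 1-based inclusive forward coordinates."""

    id: str
    contig_id: str
    start: int
    end: int
    strand: str
    peptide: str | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"ORF {self.id!r}: need 1 <= start <= end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"ORF {self.id!r}: strand must be '+' or '-'")


@dataclass(frozen=True)
class HitRecord:
    """One homology-search hit (one line of BLAST tabular output)."""

    query_id: str
    subject_id: str
    percent_identity: float  # as a fraction in [0, 1]
    alignment_length: int
    evalue: float
    bit_score: float
    subject_taxid: int | None = None
    subject_subsystem: str | None = None
    subject_is_viral: bool = False

    def __post_init__(self) -> None:
        if self.bit_score < 0:
            raise ValueError("bit_score must be >= 0")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")


@dataclass
class DepthProfile:
    """Per-base read depth over a contig; one entry per contig position."""

    contig_id: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if self.depth.ndim != 1:
            raise ValueError("depth must be a 1-D vector")
        if (self.depth < 0).any():
            raise ValueError(f"contig {self.contig_id!r}: negative depth")

    def __len__(self) -> int:
        return int(self.depth.shape[0])


@dataclass
class OtuTable:
    """Samples x OTUs count matrix with per-OTU taxonomy lineage strings."""

    sample_ids: list[str]
    otu_ids: list[str]
    counts: np.ndarray  # shape (n_samples, n_otus)
    taxonomy: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        """Counts as a DataFrame (rows = samples, columns = OTUs)."""
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into (id, sequence) pairs, in file order.

    The id is the header token before the first whitespace; sequences are
    uppercased.  An empty file and duplicate ids are errors.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    with open(path) as handle:
        for header, seq in SimpleFastaParser(handle):
            rid = header.split()[0] if header.split() else ""
            if not rid:
                raise FormatError(f"{path}: FASTA record with empty id")
            if rid in seen:
                raise FormatError(f"{path}: duplicate FASTA id {rid!r}")
            seen.add(rid)
            records.append((rid, seq.upper()))
    if not records:
        raise FormatError(f"{path}: empty FASTA file")
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]],
                width: int = 70) -> None:
    """Write (id, sequence) pairs as FASTA with fixed line wrapping."""
    with open(path, "w") as handle:
        for rid, seq in records:
            handle.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# BLAST tabular hits
# ---------------------------------------------------------------------------

#: The twelve standard columns of BLAST -outfmt 6.
BLAST6_COLUMNS = (
    "query_id", "subject_id", "percent_identity", "alignment_length",
    "mismatches", "gap_opens", "q_start", "q_end", "s_start", "s_end",
    "evalue", "bit_score",
)

#: Recognised optional trailing columns (annotation added by the pipeline).
EXTRA_HIT_COLUMNS = ("subject_taxid", "subject_subsystem", "subject_is_viral")


def read_tabular_hits(
    path: str | Path,
    schema: Sequence[str] = BLAST6_COLUMNS,
) -> list[HitRecord]:
    """Parse a tab-separated hit table into :class:`HitRecord` objects.

    ``schema`` names the column order; the default is the twelve standard
    BLAST outfmt-6 columns.  Optional trailing columns ``subject_taxid``,
    ``subject_subsystem`` and ``subject_is_viral`` are mapped onto the
    corresponding HitRecord fields.  Lines with the wrong column count or
    unparsable numeric fields raise with the offending line number.
    """
    schema = tuple(schema)
    for col in ("query_id", "subject_id", "evalue", "bit_score"):
        if col not in schema:
            raise ValueError(f"hit schema must include {col!r}")
    hits: list[HitRecord] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != len(schema):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(schema)} columns, "
                    f"got {len(fields)}"
                )
            row = dict(zip(schema, fields))
            try:
                taxid = row.get("subject_taxid")
                hits.append(HitRecord(
                    query_id=row["query_id"],
                    subject_id=row["subject_id"],
                    percent_identity=float(row.get("percent_identity", 0.0)) / 100.0,
                    alignment_length=int(row.get("alignment_length", 0)),
                    evalue=float(row["evalue"]),
                    bit_score=float(row["bit_score"]),
                    subject_taxid=None if taxid in (None, "", "NA") else int(taxid),
                    subject_subsystem=row.get("subject_subsystem") or None,
                    subject_is_viral=row.get("subject_is_viral", "0")
                    in ("1", "true", "True"),
                ))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return hits


def write_tabular_hits(path: str | Path, hits: Iterable[HitRecord],
                       schema: Sequence[str] = BLAST6_COLUMNS) -> None:
    """Write hits in the given column order (inverse of read_tabular_hits)."""
    with open(path, "w") as handle:
        for h in hits:
            values = {
                "query_id": h.query_id,
                "subject_id": h.subject_id,
                "percent_identity": f"{h.percent_identity * 100.0:.2f}",
                "alignment_length": str(h.alignment_length),
                "mismatches": "0",
                "gap_opens": "0",
                "q_start": "1",
                "q_end": str(max(h.alignment_length, 1)),
                "s_start": "1",
                "s_end": str(max(h.alignment_length, 1)),
                "evalue": repr(h.evalue),
                "bit_score": repr(h.bit_score),
                "subject_taxid": "" if h.subject_taxid is None else str(h.subject_taxid),
                "subject_subsystem": h.subject_subsystem or "",
                "subject_is_viral": "1" if h.subject_is_viral else "0",
            }
            handle.write("\t".join(values[c] for c in schema) + "\n")


# ---------------------------------------------------------------------------
# Depth profiles: samtools-depth TSV and SAM
# ---------------------------------------------------------------------------

def read_depth(
    path: str | Path,
    contig_lengths: Mapping[str, int],
) -> dict[str, DepthProfile]:
    """Read a samtools-depth style TSV (contig, 1-based position, depth).

    Positions absent from the file get depth 0 (samtools depth omits
    zero-depth positions by default); every contig in ``contig_lengths``
    gets a profile padded to its full length.
    """
    profiles = {
        cid: np.zeros(length, dtype=np.int64)
        for cid, length in contig_lengths.items()
    }
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            cid, pos_s, depth_s = fields
            if cid not in profiles:
                raise FormatError(f"{path}:{lineno}: unknown contig {cid!r}")
            try:
                pos, depth = int(pos_s), int(depth_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if depth < 0:
                raise FormatError(f"{path}:{lineno}: negative depth")
            if not 1 <= pos <= contig_lengths[cid]:
                raise FormatError(
                    f"{path}:{lineno}: position {pos} outside contig "
                    f"{cid!r} (length {contig_lengths[cid]})"
                )
            profiles[cid][pos - 1] = depth
    return {cid: DepthProfile(cid, vec) for cid, vec in profiles.items()}


def write_depth(path: str | Path, profiles: Mapping[str, DepthProfile],
                omit_zero: bool = True) -> None:
    """Write profiles as samtools-depth TSV, omitting zero rows by default."""
    with open(path, "w") as handle:
        for cid in profiles:
            depth = profiles[cid].depth
            for pos0, d in enumerate(depth):
                if omit_zero and d == 0:
                    continue
                handle.write(f"{cid}\t{pos0 + 1}\t{int(d)}\n")


#: CIGAR operations that consume the reference (M, D, N, =, X).
_REF_CONSUMING = frozenset({0, 2, 3, 7, 8})


def depth_from_sam(
    path: str | Path,
    contig_lengths: Mapping[str, int],
    count_full_read_length: bool = False,
) -> tuple[dict[str, DepthProfile], int]:
    """Compute per-base depth and total recruited bases from a SAM file.

    Only primary, mapped alignments are counted, so each read is recruited
    at most once.  Depth at a position is the number of counted alignments
    whose reference-consuming CIGAR operations cover it.  The recruited-base
    total is the sum of reference-aligned bases per counted alignment (or of
    full read lengths with ``count_full_read_length``); it feeds the per-Gbp
    abundance normalization.
    """
    profiles = {
        cid: np.zeros(length, dtype=np.int64)
        for cid, length in contig_lengths.items()
    }
    total_bases = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            cid = aln.reference_name
            if cid not in profiles:
                raise FormatError(
                    f"{path}: alignment to unknown contig {cid!r}"
                )
            vec = profiles[cid]
            pos = aln.reference_start  # 0-based
            ref_bases = 0
            for op, length in aln.cigartuples or ():
                if op in _REF_CONSUMING:
                    if pos + length > len(vec):
                        raise FormatError(
                            f"{path}: alignment overruns contig {cid!r}"
                        )
                    vec[pos:pos + length] += 1
                    pos += length
                    ref_bases += length
            if count_full_read_length:
                total_bases += aln.query_length or len(aln.query_sequence or "")
            else:
                total_bases += ref_bases
    return (
        {cid: DepthProfile(cid, vec) for cid, vec in profiles.items()},
        total_bases,
    )


# ---------------------------------------------------------------------------
# ORF coordinate tables (MetaGene-style)
# ---------------------------------------------------------------------------

def read_orf_table(path: str | Path) -> list[Orf]:
    """Read a five-column ORF table: orf_id, contig_id, start, end, strand."""
    orfs: list[Orf] = []
    seen: set[str] = set()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise FormatError(f"{path}:{lineno}: expected 5 columns")
            oid, cid, start_s, end_s, strand = fields
            if oid in seen:
                raise FormatError(f"{path}:{lineno}: duplicate ORF id {oid!r}")
            seen.add(oid)
            try:
                orfs.append(Orf(oid, cid, int(start_s), int(end_s), strand))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return orfs


def write_orf_table(path: str | Path, orfs: Iterable[Orf]) -> None:
    with open(path, "w") as handle:
        for o in orfs:
            handle.write(f"{o.id}\t{o.contig_id}\t{o.start}\t{o.end}\t{o.strand}\n")


# ---------------------------------------------------------------------------
# OTU tables
# ---------------------------------------------------------------------------

TAXONOMY_COLUMN = "taxonomy"


def read_otu_table(path: str | Path, require_taxonomy: bool = True) -> OtuTable:
    """Read a classic OTU table: OTU rows, sample columns, trailing taxonomy.

    Counts must parse as integers; duplicate OTU ids are an error.  With
    ``require_taxonomy=False`` a table without the trailing taxonomy column
    is accepted (taxonomy map left empty).
    """
    with open(path) as handle:
        text = handle.read()
    if not text.strip():
        raise FormatError(f"{path}: empty OTU table")
    df = pd.read_csv(io.StringIO(text), sep="\t", index_col=0, dtype=str)
    has_tax = len(df.columns) > 0 and df.columns[-1] == TAXONOMY_COLUMN
    if require_taxonomy and not has_tax:
        raise FormatError(
            f"{path}: missing trailing {TAXONOMY_COLUMN!r} column"
        )
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate OTU id(s) {dupes}")
    taxonomy: dict[str, str] = {}
    if has_tax:
        taxonomy = df[TAXONOMY_COLUMN].to_dict()
        df = df.drop(columns=[TAXONOMY_COLUMN])
    try:
        counts = df.astype(np.int64)
    except ValueError as exc:
        raise FormatError(f"{path}: non-integer count: {exc}") from exc
    if (counts.values < 0).any():
        raise FormatError(f"{path}: negative count")
    return OtuTable(
        sample_ids=[str(c) for c in counts.columns],
        otu_ids=[str(i) for i in counts.index],
        counts=counts.values.T.copy(),  # file is OTU x sample; store sample x OTU
        taxonomy=taxonomy,
    )


def write_otu_table(path: str | Path, table: OtuTable) -> None:
    """Write an OtuTable in the classic OTU-row dialect read_otu_table reads."""
    df = pd.DataFrame(
        table.counts.T, index=table.otu_ids, columns=table.sample_ids
    )
    if table.taxonomy:
        df[TAXONOMY_COLUMN] = [table.taxonomy.get(o, "") for o in table.otu_ids]
    df.index.name = "#OTU_ID"
    df.to_csv(path, sep="\t")
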