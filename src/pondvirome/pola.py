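"""Pol I (family A DNA polymerase) marker-gene lifestyle classification.

The residue at position 762 of Pol I (numbered on the *E. coli* reference)
separates phage replication strategies: phenylalanine (wildtype) or tyrosine
predicts a generally virulent (lytic) phage, while leucine predicts a
generally temperate (lysogenic) one.  To read that residue off an
environmental peptide, the peptide is aligned to a reference Pol I and its
residue in the alignment column of reference position 762 is taken —
provided the peptide spans the region of interest (reference positions
547–923, I547 to N923), so that the call is not an artefact of a fragment
boundary.

Candidate peptides are first filtered on homology-search support
(E <= 1e-5) and length (>= 100 aa).  Alignment is deterministic pairwise
semi-global alignment to the reference (BLOSUM62, gap open/extend 11/1 by
default): the peptide is aligned end-to-end while reference overhang is
free, so every reference position occupies exactly one alignment column.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .formats_io import HitRecord, write_fasta

GAP = "-"

VIRULENT = "virulent"
TEMPERATE = "temperate"
UNCLASSIFIED = "unclassified"

#: Residues at the 762 site diagnostic of lifestyle.
LIFESTYLE_BY_RESIDUE = {"F": VIRULENT, "Y": VIRULENT, "L": TEMPERATE}

DEFAULT_MIN_LENGTH = 100      # aa; inclusive
DEFAULT_MAX_EVALUE = 1e-5     # inclusive


@dataclass(frozen=True)
class RoiSpec:
    """The reference coordinate frame for the 762-site lifestyle call.

    Anchors (I at roi_start, F at site, N at roi_end — the I547/Phe762/N923
    contract of the *E. coli* IAI39 reference) are validated against the
    supplied reference peptide at construction, so a mis-indexed or wrong
    reference fails immediately.
    """

    reference_id: str
    reference_peptide: str
    roi_start: int = 547
    roi_end: int = 923
    site: int = 762
    expected_residues: tuple[str, str, str] = ("I", "F", "N")

    def __post_init__(self) -> None:
        if not self.roi_start < self.site < self.roi_end:
            raise ValueError("need roi_start < site < roi_end")
        if self.roi_end > len(self.reference_peptide):
            raise ValueError(
                f"reference peptide (length {len(self.reference_peptide)}) "
                f"shorter than roi_end {self.roi_end}"
            )
        anchors = (
            (self.roi_start, self.expected_residues[0]),
            (self.site, self.expected_residues[1]),
            (self.roi_end, self.expected_residues[2]),
        )
        for pos, expected in anchors:
            actual = self.reference_peptide[pos - 1]
            if actual != expected:
                raise ValueError(
                    f"reference {self.reference_id!r}: expected {expected!r} "
                    f"at position {pos}, found {actual!r}"
                )


@dataclass
class PairwiseRefAlignment:
    """A peptide aligned into reference coordinates (semi-global)."""

    reference_gapped: str
    query_gapped: str
    score: float
    #: query character (or gap) in the column of each reference position,
    #: index 0 = reference position 1.
    _by_ref_pos: list[str] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if len(self.reference_gapped) != len(self.query_gapped):
            raise ValueError("gapped strings must have equal length")
        if not self._by_ref_pos:
            self._by_ref_pos = [
                q for r, q in zip(self.reference_gapped, self.query_gapped)
                if r != GAP
            ]

    def query_at(self, reference_position: int) -> str:
        """Query residue (or gap) at a 1-based reference position."""
        if not 1 <= reference_position <= len(self._by_ref_pos):
            raise IndexError(
                f"reference position {reference_position} out of range "
                f"1..{len(self._by_ref_pos)}"
            )
        return self._by_ref_pos[reference_position - 1]


@dataclass(frozen=True)
class PolAClassification:
    orf_id: str
    peptide_length: int
    spans_roi: bool
    residue_762: str | None       # None when the peptide does not span
    lifestyle: str | None         # None when the peptide does not span
    normalized_abundance: float = 0.0


def make_aligner(matrix: str = "BLOSUM62", gap_open: int = 11,
                 gap_extend: int = 1) -> Align.PairwiseAligner:
    """Semi-global peptide-vs-reference aligner (reference overhang free).

    A gap of length k costs gap_open + k * gap_extend (the BLAST
    convention), except at the reference's ends where the unmatched
    reference overhang is free.
    """
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.mode = "global"
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    # free end gaps in the query row (reference extends past the peptide)
    aligner.open_left_deletion_score = 0
    aligner.extend_left_deletion_score = 0
    aligner.open_right_deletion_score = 0
    aligner.extend_right_deletion_score = 0
    return aligner


def filter_pola_candidates(
    peptides: Mapping[str, str],
    hits: Iterable[HitRecord],
    min_length: int = DEFAULT_MIN_LENGTH,
    max_evalue: float = DEFAULT_MAX_EVALUE,
) -> list[str]:
    """Ids of peptides with >= 1 qualifying Pol I hit and sufficient length.

    Both cutoffs are inclusive: a 100-aa peptide passes min_length 100 and a
    hit at exactly the E-value cutoff qualifies.
    """
    supported = {
        h.query_id for h in hits
        if h.evalue <= max_evalue and h.query_id in peptides
    }
    return [pid for pid in peptides
            if pid in supported and len(peptides[pid]) >= min_length]


def align_to_reference(
    peptide: str,
    roi: RoiSpec,
    aligner: Align.PairwiseAligner | None = None,
) -> PairwiseRefAlignment:
    """Align a peptide into the reference coordinate frame.

    Deterministic for fixed scoring: of the co-optimal tracebacks the
    aligner's canonical first one is taken.
    """
    if not peptide:
        raise ValueError("empty peptide")
    if aligner is None:
        aligner = make_aligner()
    aln = aligner.align(roi.reference_peptide, peptide)[0]
    return PairwiseRefAlignment(str(aln[0]), str(aln[1]), float(aln.score))


def residue_at_reference_position(alignment: PairwiseRefAlignment,
                                  position: int) -> str:
    """Query residue in the column of the reference's position-th residue."""
    return alignment.query_at(position)


def spans_roi(alignment: PairwiseRefAlignment, roi: RoiSpec) -> bool:
    """Does the peptide cover both ROI endpoints (non-gap at 547 and 923)?"""
    return (alignment.query_at(roi.roi_start) != GAP
            and alignment.query_at(roi.roi_end) != GAP)


def classify_lifestyle(residue: str | None) -> str:
    """F/Y -> virulent, L -> temperate, anything else -> unclassified."""
    if residue is None:
        return UNCLASSIFIED
    return LIFESTYLE_BY_RESIDUE.get(residue.upper(), UNCLASSIFIED)


def classify_peptides(
    peptides: Mapping[str, str],
    roi: RoiSpec,
    abundances: Mapping[str, float] | None = None,
    aligner: Align.PairwiseAligner | None = None,
) -> tuple[list[PolAClassification], dict[str, PairwiseRefAlignment]]:
    """Align every peptide and call its 762 residue and lifestyle.

    Peptides that do not span the ROI get ``spans_roi=False`` and no
    lifestyle call.  Returns the classifications plus the alignments (for
    the ROI export).
    """
    if aligner is None:
        aligner = make_aligner()
    abundances = abundances or {}
    classifications: list[PolAClassification] = []
    alignments: dict[str, PairwiseRefAlignment] = {}
    for pid in peptides:
        aln = align_to_reference(peptides[pid], roi, aligner)
        alignments[pid] = aln
        spanning = spans_roi(aln, roi)
        residue = aln.query_at(roi.site) if spanning else None
        classifications.append(PolAClassification(
            orf_id=pid,
            peptide_length=len(peptides[pid]),
            spans_roi=spanning,
            residue_762=residue,
            lifestyle=classify_lifestyle(residue) if spanning else None,
            normalized_abundance=float(abundances.get(pid, 0.0)),
        ))
    return classifications, alignments


def summarize_pola(
    classifications: Sequence[PolAClassification],
) -> pd.DataFrame:
    """Peptide count and total abundance per lifestyle class.

    Only spanning peptides enter; the three classes partition them, so the
    counts always sum to the number of spanning peptides.
    """
    counts: dict[str, int] = {VIRULENT: 0, TEMPERATE: 0, UNCLASSIFIED: 0}
    abund: dict[str, float] = {VIRULENT: 0.0, TEMPERATE: 0.0, UNCLASSIFIED: 0.0}
    for c in classifications:
        if not c.spans_roi:
            continue
        counts[c.lifestyle] += 1
        abund[c.lifestyle] += c.normalized_abundance
    return pd.DataFrame(
        {
            "lifestyle": [VIRULENT, TEMPERATE, UNCLASSIFIED],
            "peptide_count": [counts[k] for k in (VIRULENT, TEMPERATE,
                                                  UNCLASSIFIED)],
            "total_normalized_abundance": [abund[k] for k in
                                           (VIRULENT, TEMPERATE, UNCLASSIFIED)],
        }
    )


def roi_alignment_records(
    alignments: Mapping[str, PairwiseRefAlignment],
    roi: RoiSpec,
    spanning_only: bool = True,
) -> list[tuple[str, str]]:
    """ROI-restricted alignment rows in reference coordinates.

    Each record is the query residues (or gaps) at reference positions
    roi_start..roi_end, so all rows share one length and one coordinate
    frame — ready for external tree building.  Insertions relative to the
    reference are dropped.
    """
    records = [(roi.reference_id,
                roi.reference_peptide[roi.roi_start - 1:roi.roi_end])]
    for pid, aln in alignments.items():
        row = "".join(aln.query_at(p)
                      for p in range(roi.roi_start, roi.roi_end + 1))
        if spanning_only and (row[0] == GAP or row[-1] == GAP):
            continue
        records.append((pid, row))
    return records


def write_roi_alignment(path: str | Path,
                        alignments: Mapping[str, PairwiseRefAlignment],
                        roi: RoiSpec, spanning_only: bool = True) -> None:
    write_fasta(path, roi_alignment_records(alignments, roi, spanning_only))


def write_classifications(path: str | Path,
                          classifications: Sequence[PolAClassification]) -> None:
    with open(path, "w") as handle:
        handle.write("orf_id\tpeptide_length\tspans_roi\tresidue_762\t"
                     "lifestyle\tnormalized_abundance\n")
        for c in classifications:
            handle.write(
                f"{c.orf_id}\t{c.peptide_length}\t{int(c.spans_roi)}\t"
                f"{c.residue_762 or ''}\t{c.lifestyle or ''}\t"
                f"{c.normalized_abundance}\n"
            )


def run_pola_pipeline(
    peptides: Mapping[str, str],
    hits: Iterable[HitRecord],
    roi: RoiSpec,
    abundances: Mapping[str, float] | None = None,
    min_length: int = DEFAULT_MIN_LENGTH,
    max_evalue: float = DEFAULT_MAX_EVALUE,
    keep_list: set[str] | None = None,
    aligner: Align.PairwiseAligner | None = None,
) -> tuple[list[PolAClassification], dict[str, PairwiseRefAlignment],
           pd.DataFrame]:
    """Filter, align, classify and summarize in one pass.

    ``keep_list`` optionally restricts candidates to externally confirmed
    Pol I ids (e.g., from a conserved-domain check run elsewhere).
    """
    candidate_ids = filter_pola_candidates(peptides, hits, min_length,
                                           max_evalue)
    if keep_list is not None:
        candidate_ids = [pid for pid in candidate_ids if pid in keep_list]
    candidates = {pid: peptides[pid] for pid in candidate_ids}
    classifications, alignments = classify_peptides(
        candidates, roi, abundances, aligner
    )
    return classifications, alignments, summarize_pola(classifications)
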