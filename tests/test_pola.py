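"""Pol I residue-762 lifestyle classification against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from Bio.Align import substitution_matrices

from pondvirome import formats_io as fio
from pondvirome import pola as pa
from pondvirome import synthetic_data as syn

AA = list("ACDEFGHIKLMNPQRSTVWY")
B62 = substitution_matrices.load("BLOSUM62")
NEG = float("-inf")


def gotoh_semiglobal_score(target, query, open_cost=12, ext_cost=1):
    """Quadratic affine-gap DP, scored independently of the aligner.

    Semi-global: gaps in the query row at either end of the target (the
    reference overhang) are free; a gap of length k elsewhere costs
    open_cost + (k - 1) * ext_cost.
    """
    m, n = len(target), len(query)
    M = [[NEG] * (n + 1) for _ in range(m + 1)]
    X = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in query row
    Y = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in target row
    M[0][0] = 0.0
    for i in range(1, m + 1):
        X[i][0] = 0.0
    for j in range(1, n + 1):
        Y[0][j] = -(open_cost + (j - 1) * ext_cost)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = B62[target[i - 1], query[j - 1]]
            M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            if j == n:
                X[i][j] = max(M[i - 1][j], X[i - 1][j], Y[i - 1][j])
            else:
                X[i][j] = max(M[i - 1][j] - open_cost, X[i - 1][j] - ext_cost,
                              Y[i - 1][j] - open_cost)
            Y[i][j] = max(M[i][j - 1] - open_cost, Y[i][j - 1] - ext_cost,
                          X[i][j - 1] - open_cost)
    return max(M[m][n], X[m][n], Y[m][n])


# ---------------------------------------------------------------------------
# RoiSpec
# ---------------------------------------------------------------------------

class TestRoiSpec:
    def test_surrogate_satisfies_anchor_contract(self, roi):
        ref = roi.reference_peptide
        assert (ref[546], ref[761], ref[922]) == ("I", "F", "N")

    def test_wrong_anchor_rejected(self, roi):
        bad = list(roi.reference_peptide)
        bad[761] = "A"
        with pytest.raises(ValueError, match="762"):
            pa.RoiSpec("bad", "".join(bad))

    def test_short_reference_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            pa.RoiSpec("short", "IFN" * 100)


# ---------------------------------------------------------------------------
# Candidate filtering
# ---------------------------------------------------------------------------

def polA_hit(query, evalue):
    return fio.HitRecord(query, "polA_ref", 0.8, 150, evalue, 300.0)


class TestFilterCandidates:
    PEPTIDES = {"p100": "A" * 100, "p99": "A" * 99, "p150": "A" * 150}

    def test_length_cutoff_inclusive(self):
        hits = [polA_hit("p100", 1e-6), polA_hit("p99", 1e-6)]
        assert pa.filter_pola_candidates(self.PEPTIDES, hits) == ["p100"]

    def test_evalue_cutoff_inclusive(self):
        assert pa.filter_pola_candidates(
            self.PEPTIDES, [polA_hit("p150", 1e-5)]) == ["p150"]
        assert pa.filter_pola_candidates(
            self.PEPTIDES, [polA_hit("p150", 1e-4)]) == []

    def test_needs_at_least_one_qualifying_hit(self):
        assert pa.filter_pola_candidates(self.PEPTIDES, []) == []


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

class TestAlignToReference:
    def test_identity_alignment_gap_free_with_diagonal_score(self, roi):
        aln = pa.align_to_reference(roi.reference_peptide, roi)
        assert aln.query_gapped == roi.reference_peptide
        assert aln.reference_gapped == roi.reference_peptide
        expected = sum(B62[c, c] for c in roi.reference_peptide)
        assert aln.score == pytest.approx(expected)

    def test_single_deletion_yields_one_query_gap(self, roi):
        ref = roi.reference_peptide
        peptide = ref[:599] + ref[600:]
        aln = pa.align_to_reference(peptide, roi)
        assert aln.query_gapped.count(pa.GAP) == 1
        assert aln.reference_gapped == ref

    def test_empty_peptide_errors(self, roi):
        with pytest.raises(ValueError, match="empty"):
            pa.align_to_reference("", roi)

    def test_score_matches_quadratic_dp_oracle(self):
        rng = np.random.default_rng(17)
        aligner = pa.make_aligner()
        for _ in range(60):
            ref = "".join(rng.choice(AA, size=rng.integers(8, 30)))
            pep = "".join(rng.choice(AA, size=rng.integers(3, 18)))
            assert aligner.score(ref, pep) == pytest.approx(
                gotoh_semiglobal_score(ref, pep))


class TestResidueLookup:
    def test_identity_alignment_returns_reference_residue(self, roi):
        aln = pa.align_to_reference(roi.reference_peptide, roi)
        assert pa.residue_at_reference_position(aln, 762) == "F"
        assert pa.residue_at_reference_position(aln, 547) == "I"

    def test_gap_over_site(self):
        aln = pa.PairwiseRefAlignment("ABC", "A-C", 0.0)
        assert aln.query_at(2) == pa.GAP

    def test_position_out_of_range_errors(self):
        aln = pa.PairwiseRefAlignment("ABC", "ABC", 0.0)
        with pytest.raises(IndexError):
            aln.query_at(4)
        with pytest.raises(IndexError):
            aln.query_at(0)

    def test_planted_substitutions_recovered(self, roi):
        """Substitutions planted at known reference positions are read back
        at 100% despite ~10% random mutations elsewhere."""
        rng = np.random.default_rng(23)
        ref = roi.reference_peptide
        planted_positions = [560, 650, 762, 900]
        for _ in range(10):
            residues = list(ref)
            planted = {}
            for pos in planted_positions:
                new = AA[int(rng.integers(len(AA)))]
                residues[pos - 1] = new
                planted[pos] = new
            for j in range(len(residues)):
                if (j + 1) not in planted and rng.random() < 0.10:
                    choices = [a for a in AA if a != residues[j]]
                    residues[j] = choices[int(rng.integers(len(choices)))]
            aln = pa.align_to_reference("".join(residues), roi)
            for pos, expected in planted.items():
                assert pa.residue_at_reference_position(aln, pos) == expected


class TestSpansRoi:
    def test_full_reference_spans(self, roi):
        aln = pa.align_to_reference(roi.reference_peptide, roi)
        assert pa.spans_roi(aln, roi)

    def test_truncated_before_roi_end_does_not_span(self, roi):
        peptide = roi.reference_peptide[roi.roi_start - 1:900]
        aln = pa.align_to_reference(peptide, roi)
        assert not pa.spans_roi(aln, roi)

    def test_random_truncations_match_coordinate_bookkeeping(self, roi):
        """Fragment ref[a..b] spans iff a <= roi_start and b >= roi_end
        (substitution-free fragments keep reference coordinates)."""
        rng = np.random.default_rng(29)
        ref = roi.reference_peptide
        for _ in range(15):
            a = int(rng.integers(1, 700))
            b = int(rng.integers(a + 120, min(a + 900, len(ref)) + 1))
            aln = pa.align_to_reference(ref[a - 1:b], roi)
            assert pa.spans_roi(aln, roi) == (a <= roi.roi_start
                                              and b >= roi.roi_end)


# ---------------------------------------------------------------------------
# Lifestyle rule and summary
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("residue,expected", [
    ("F", pa.VIRULENT), ("Y", pa.VIRULENT), ("L", pa.TEMPERATE),
    ("W", pa.UNCLASSIFIED), ("-", pa.UNCLASSIFIED), (None, pa.UNCLASSIFIED),
])
def test_classify_lifestyle(residue, expected):
    assert pa.classify_lifestyle(residue) == expected


def test_reference_self_test(roi):
    """The reference peptide itself spans, reads F at 762, and is virulent."""
    (c,), _ = pa.classify_peptides({"ref_copy": roi.reference_peptide}, roi)
    assert c.spans_roi and c.residue_762 == "F" and c.lifestyle == pa.VIRULENT


class TestSummarize:
    def mk(self, residue, spans=True, abundance=1.0):
        return pa.PolAClassification(
            "o", 400, spans, residue if spans else None,
            pa.classify_lifestyle(residue) if spans else None, abundance)

    def test_counts(self):
        table = pa.summarize_pola([self.mk("F"), self.mk("L"), self.mk("L")])
        by = table.set_index("lifestyle").peptide_count
        assert (by[pa.VIRULENT], by[pa.TEMPERATE], by[pa.UNCLASSIFIED]) == (1, 2, 0)

    def test_empty(self):
        table = pa.summarize_pola([])
        assert table.peptide_count.sum() == 0

    def test_non_spanning_excluded_and_abundance_summed(self):
        table = pa.summarize_pola(
            [self.mk("F", abundance=2.5), self.mk("Y", spans=False)])
        assert table.peptide_count.sum() == 1
        by = table.set_index("lifestyle").total_normalized_abundance
        assert by[pa.VIRULENT] == 2.5


# ---------------------------------------------------------------------------
# End-to-end on the planted default set
# ---------------------------------------------------------------------------

def test_planted_class_structure_recovered_exactly(pola_default_run):
    """17 Phe + 27 Tyr peptides classify virulent and 184 Leu temperate,
    with nothing unclassified."""
    by = pola_default_run["summary"].set_index("lifestyle").peptide_count
    assert by[pa.VIRULENT] == 44
    assert by[pa.TEMPERATE] == 184
    assert by[pa.UNCLASSIFIED] == 0


def test_planted_residues_recovered_per_peptide(pola_default_run):
    truth = pd.read_csv(pola_default_run["files"].truth_tsv, sep="\t") \
              .set_index("orf_id")
    for c in pola_default_run["classifications"]:
        assert c.residue_762 == truth.loc[c.orf_id, "planted_residue"]


def test_partition_and_funnel(pola_default_run):
    classifications = pola_default_run["classifications"]
    summary = pola_default_run["summary"]
    n_spanning = sum(c.spans_roi for c in classifications)
    assert summary.peptide_count.sum() == n_spanning
    candidate_ids = set(pa.filter_pola_candidates(
        pola_default_run["peptides"], pola_default_run["hits"]))
    assert {c.orf_id for c in classifications} <= set(
        pola_default_run["peptides"])
    assert {c.orf_id for c in classifications} == candidate_ids


def test_roi_alignment_export(pola_default_run, roi, tmp_path):
    out = tmp_path / "roi.fasta"
    pa.write_roi_alignment(out, pola_default_run["alignments"], roi)
    records = fio.read_fasta(out)
    width = roi.roi_end - roi.roi_start + 1
    assert all(len(seq) == width for _, seq in records)
    assert records[0][0] == roi.reference_id
    n_spanning = sum(c.spans_roi
                     for c in pola_default_run["classifications"])
    assert len(records) == n_spanning + 1
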