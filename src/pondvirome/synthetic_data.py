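"""Synthetic pond-virome and 16S inputs with planted ground truth.

Three generators emulate the study design end to end, so every pipeline
stage has a parameter-recovery test that needs no download:

* a viral community — contigs with planted taxon labels and families, ORFs,
  reads (SAM) yielding planted per-contig coverage, and a hit table whose
  per-contig bit-score sums favour the planted taxid over decoys;
* a Pol I peptide set — fragments of a surrogate reference with the planted
  residue written at the 762 site, substitutions elsewhere, and an optional
  truncated (non-ROI-spanning) fraction;
* an OTU table — two filter-fraction groups over a late-season time course
  with planted shared/unique core membership, phylum labels and temporal
  trends.

All randomness flows through one seeded ``numpy`` Generator per call, so
identical spec + seed gives byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .formats_io import Orf, OtuTable, write_fasta, write_orf_table, write_otu_table
from .pola import RoiSpec

NUCLEOTIDES = np.array(list("ACGT"))
AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: NCBI-style ids used for the fixed taxonomy scaffold.
ROOT_TAXID = 1
BACTERIA_TAXID = 2
VIRUS_ROOT_TAXID = 10239
CAUDOVIRALES_TAXID = 28883


# ---------------------------------------------------------------------------
# Surrogate Pol I reference
# ---------------------------------------------------------------------------

_SURROGATE_SEED = 76_223  # fixed: the surrogate is a packaged constant

def surrogate_pola_reference(length: int = 1000) -> RoiSpec:
    """A fixed surrogate Pol I reference satisfying the ROI anchor contract.

    A seeded random peptide of length 1,000 with I, F and N written at
    positions 547, 762 and 923 — the same anchor contract as the *E. coli*
    IAI39 Pol I, without shipping the real sequence.  Deterministic across
    calls and platforms.
    """
    if length < 923:
        raise ValueError("surrogate reference must cover position 923")
    rng = np.random.default_rng(_SURROGATE_SEED)
    residues = rng.choice(AMINO_ACIDS, size=length)
    residues[547 - 1] = "I"
    residues[762 - 1] = "F"
    residues[923 - 1] = "N"
    return RoiSpec(reference_id="polA_surrogate_ref",
                   reference_peptide="".join(residues))


# ---------------------------------------------------------------------------
# Viral community
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaxonSpec:
    """One planted taxon: its contigs share a taxid, family and coverage."""

    taxid: int
    viral: bool
    n_contigs: int
    contig_length_range: tuple[int, int]
    planted_coverage: float
    planted_family: str

    def __post_init__(self) -> None:
        if self.planted_coverage <= 0:
            raise ValueError("planted_coverage must be > 0")
        lo, hi = self.contig_length_range
        if not 1 <= lo <= hi:
            raise ValueError("bad contig_length_range")


@dataclass(frozen=True)
class CommunitySpec:
    seed: int
    taxa: tuple[TaxonSpec, ...]
    orfs_per_contig: int = 3
    decoy_taxid_count: int = 3
    decoy_bitscore_fraction: float = 0.5
    read_length: int = 150
    tiled: bool = False  # exact tiling instead of uniform read placement

    def __post_init__(self) -> None:
        if not 0 < self.decoy_bitscore_fraction < 1:
            raise ValueError("decoy_bitscore_fraction must be in (0, 1) so "
                             "the planted taxid always wins the bit-score sum")
        if self.orfs_per_contig < 1:
            raise ValueError("orfs_per_contig must be >= 1")


#: Toy SEED-style subsystem hierarchy used for planted functional labels.
TOY_SUBSYSTEM_HIERARCHY: dict[str, str] = {
    "Phage capsid proteins": "Phages, Prophages, Transposable elements",
    "Phage tail fibers": "Phages, Prophages, Transposable elements",
    "Phage integrase": "Phages, Prophages, Transposable elements",
    "Ribonucleotide reduction": "Nucleosides and Nucleotides",
    "Purine biosynthesis": "Nucleosides and Nucleotides",
    "DNA replication": "DNA Metabolism",
    "Terminase": "Phages, Prophages, Transposable elements",
}


def default_community_spec(seed: int) -> CommunitySpec:
    """The community emulated by default: a Caudovirales-dominated virome.

    Family mixture follows the study system — Siphoviridae most abundant,
    then Myoviridae, then Podoviridae — plus a minor non-viral (bacterial)
    component standing in for cellular contamination.
    """
    return CommunitySpec(
        seed=seed,
        taxa=(
            TaxonSpec(5001, True, 8, (5_000, 20_000), 50.0, "Siphoviridae"),
            TaxonSpec(5002, True, 6, (5_000, 20_000), 10.0, "Myoviridae"),
            TaxonSpec(5003, True, 4, (5_000, 20_000), 5.0, "Podoviridae"),
            TaxonSpec(6001, False, 2, (5_000, 20_000), 2.0, "Comamonadaceae"),
        ),
    )


@dataclass
class CommunityFiles:
    """Paths of everything generate_community wrote."""

    contigs_fasta: Path
    orfs_tsv: Path
    sam: Path
    hits_tsv: Path
    taxonomy_tsv: Path
    hierarchy_tsv: Path
    truth_contigs_tsv: Path
    truth_orfs_tsv: Path


def _community_taxonomy_rows(spec: CommunitySpec,
                             decoy_taxids: Sequence[int]) -> list[tuple]:
    rows = [
        (ROOT_TAXID, ROOT_TAXID, "root", "root", 0),
        (BACTERIA_TAXID, ROOT_TAXID, "superkingdom", "Bacteria", 0),
        (VIRUS_ROOT_TAXID, ROOT_TAXID, "superkingdom", "Viruses", 1),
        (CAUDOVIRALES_TAXID, VIRUS_ROOT_TAXID, "order", "Caudovirales", 0),
    ]
    family_ids: dict[str, int] = {}
    next_id = 40000
    for taxon in spec.taxa:
        if taxon.planted_family not in family_ids:
            family_ids[taxon.planted_family] = next_id
            parent = CAUDOVIRALES_TAXID if taxon.viral else BACTERIA_TAXID
            rows.append((next_id, parent, "family", taxon.planted_family, 0))
            next_id += 1
        rows.append((taxon.taxid, family_ids[taxon.planted_family],
                     "species", f"taxon_{taxon.taxid}", 0))
    decoy_family = next_id
    rows.append((decoy_family, BACTERIA_TAXID, "family", "DecoyFamily", 0))
    for d in decoy_taxids:
        rows.append((d, decoy_family, "species", f"decoy_{d}", 0))
    return rows


def generate_community(spec: CommunitySpec, out_dir: str | Path) -> CommunityFiles:
    """Write a fully planted synthetic virome into ``out_dir``.

    Reads are placed uniformly (or tiled) so each contig's true mean depth
    matches its planted coverage up to read-count rounding; every ORF gets
    one planted hit (correct taxid, viral flag, subsystem) plus decoy hits
    whose bit scores are a fixed fraction of the planted hit's, so the
    planted taxid's per-contig bit-score sum strictly exceeds every decoy's.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    rl = spec.read_length

    decoy_taxids = [90_000 + i for i in range(spec.decoy_taxid_count)]
    subsystems = sorted(TOY_SUBSYSTEM_HIERARCHY)

    contigs: list[tuple[str, str]] = []
    orfs: list[Orf] = []
    sam_lines: list[str] = []
    hit_lines: list[str] = []
    truth_contigs: list[tuple] = []
    truth_orfs: list[tuple] = []

    for taxon in spec.taxa:
        lo, hi = taxon.contig_length_range
        if hi < rl:
            raise ValueError(
                f"taxon {taxon.taxid}: contigs (<= {hi} bp) shorter than "
                f"reads ({rl} bp)"
            )
        for k in range(taxon.n_contigs):
            cid = f"contig_{taxon.taxid}_{k:03d}"
            length = int(rng.integers(max(lo, rl), hi + 1))
            seq = "".join(rng.choice(NUCLEOTIDES, size=length))
            contigs.append((cid, seq))

            # reads: uniform starts (or exact tiling) at the planted depth
            if spec.tiled:
                cov = taxon.planted_coverage
                if cov != int(cov) or length % rl != 0:
                    raise ValueError(
                        "tiled mode needs integer coverage and contig "
                        "length divisible by read_length"
                    )
                starts = np.tile(np.arange(1, length + 1, rl), int(cov))
            else:
                n_reads = int(round(taxon.planted_coverage * length / rl))
                starts = np.sort(rng.integers(1, length - rl + 2, n_reads))
            for r, pos in enumerate(starts):
                read_seq = seq[pos - 1:pos - 1 + rl]
                sam_lines.append(
                    f"read_{cid}_{r:06d}\t0\t{cid}\t{pos}\t60\t{rl}M\t*\t0\t0"
                    f"\t{read_seq}\t*"
                )
            truth_contigs.append((cid, taxon.taxid, taxon.planted_family,
                                  int(taxon.viral), taxon.planted_coverage,
                                  len(starts)))

            # ORFs tile the contig in equal windows, alternating strand
            bounds = np.linspace(0, length, spec.orfs_per_contig + 1,
                                 dtype=int)
            for j in range(spec.orfs_per_contig):
                oid = f"{cid}_orf{j:02d}"
                start, end = int(bounds[j]) + 1, int(bounds[j + 1])
                strand = "+" if j % 2 == 0 else "-"
                orfs.append(Orf(oid, cid, start, end, strand))

                subsystem = subsystems[int(rng.integers(len(subsystems)))]
                planted_bit = round(float(rng.uniform(50.0, 200.0)), 4)
                aa_len = max((end - start + 1) // 3, 1)
                hit_lines.append(
                    f"{oid}\tref_{taxon.taxid}\t90.00\t{aa_len}\t0\t0\t1\t"
                    f"{aa_len}\t1\t{aa_len}\t1e-20\t{planted_bit}\t"
                    f"{taxon.taxid}\t{subsystem}\t{int(taxon.viral)}"
                )
                n_decoys = min(len(decoy_taxids), 2)
                decoys = rng.choice(decoy_taxids, size=n_decoys,
                                    replace=False)
                # decoy subsystems are distinct from the planted one and from
                # each other, so the planted subsystem's per-ORF sum also
                # strictly wins (mirrors the taxid guarantee)
                other_subs = rng.choice(
                    [s for s in subsystems if s != subsystem],
                    size=n_decoys, replace=False)
                for d, decoy_sub in zip(decoys, other_subs):
                    decoy_bit = round(planted_bit
                                      * spec.decoy_bitscore_fraction, 4)
                    hit_lines.append(
                        f"{oid}\tdecoy_ref_{d}\t40.00\t{aa_len}\t0\t0\t1\t"
                        f"{aa_len}\t1\t{aa_len}\t1e-5\t{decoy_bit}\t{d}\t"
                        f"{decoy_sub}\t0"
                    )
                truth_orfs.append((oid, cid, subsystem,
                                   TOY_SUBSYSTEM_HIERARCHY[subsystem]))

    files = CommunityFiles(
        contigs_fasta=out / "contigs.fasta",
        orfs_tsv=out / "orfs.tsv",
        sam=out / "reads.sam",
        hits_tsv=out / "hits.tsv",
        taxonomy_tsv=out / "taxonomy_nodes.tsv",
        hierarchy_tsv=out / "subsystem_hierarchy.tsv",
        truth_contigs_tsv=out / "truth_contigs.tsv",
        truth_orfs_tsv=out / "truth_orfs.tsv",
    )

    write_fasta(files.contigs_fasta, contigs)
    write_orf_table(files.orfs_tsv, orfs)
    with open(files.sam, "w") as handle:
        handle.write("@HD\tVN:1.6\tSO:unsorted\n")
        for cid, seq in contigs:
            handle.write(f"@SQ\tSN:{cid}\tLN:{len(seq)}\n")
        handle.write("\n".join(sam_lines) + "\n")
    with open(files.hits_tsv, "w") as handle:
        handle.write("\n".join(hit_lines) + "\n")
    with open(files.taxonomy_tsv, "w") as handle:
        for row in _community_taxonomy_rows(spec, decoy_taxids):
            handle.write("\t".join(str(v) for v in row) + "\n")
    with open(files.hierarchy_tsv, "w") as handle:
        for sub in sorted(TOY_SUBSYSTEM_HIERARCHY):
            handle.write(f"{sub}\t{TOY_SUBSYSTEM_HIERARCHY[sub]}\n")
    pd.DataFrame(
        truth_contigs,
        columns=["contig_id", "taxid", "family", "viral", "planted_coverage",
                 "n_reads"],
    ).to_csv(files.truth_contigs_tsv, sep="\t", index=False)
    pd.DataFrame(
        truth_orfs, columns=["orf_id", "contig_id", "subsystem", "category"],
    ).to_csv(files.truth_orfs_tsv, sep="\t", index=False)
    return files


# ---------------------------------------------------------------------------
# Pol I peptide sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PolASpec:
    """Planted Pol I class structure.

    Default class counts are the study's: 17 wildtype Phe762, 27 Tyr762
    (both virulent) and 184 temperate Leu762 spanning peptides.
    """

    seed: int
    n_phe: int = 17
    n_tyr: int = 27
    n_leu: int = 184
    n_other: int = 0
    mutation_rate: float = 0.05
    truncation_fraction: float = 0.0
    flank_range: tuple[int, int] = (0, 77)

    def __post_init__(self) -> None:
        if not 0 <= self.mutation_rate <= 0.1:
            raise ValueError("mutation_rate must be in [0, 0.1] to keep "
                             "peptides alignable")
        if not 0 <= self.truncation_fraction <= 1:
            raise ValueError("truncation_fraction must be in [0, 1]")
        if min(self.n_phe, self.n_tyr, self.n_leu, self.n_other) < 0:
            raise ValueError("class counts must be >= 0")


@dataclass
class PolAFiles:
    peptides_fasta: Path
    hits_tsv: Path
    truth_tsv: Path


_CLASS_RESIDUES = (("phe", "F"), ("tyr", "Y"), ("leu", "L"), ("other", "W"))
_LIFESTYLE_OF = {"F": "virulent", "Y": "virulent", "L": "temperate",
                 "W": "unclassified"}


def generate_pola_set(
    spec: PolASpec,
    out_dir: str | Path,
    roi: RoiSpec | None = None,
) -> PolAFiles:
    """Write planted Pol I peptides, their hit table and the truth table.

    Each peptide is the reference's ROI plus random flanks, with the
    planted residue written at the site homologous to 762 and random
    substitutions (never at the three anchor positions) elsewhere at
    ``mutation_rate``.  A ``truncation_fraction`` of peptides is cut before
    the ROI's right endpoint so it cannot span.  No indels are introduced,
    so planted labels are recoverable exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    roi = roi or surrogate_pola_reference()
    ref = roi.reference_peptide
    counts = {"phe": spec.n_phe, "tyr": spec.n_tyr, "leu": spec.n_leu,
              "other": spec.n_other}
    n_total = sum(counts.values())
    truncated = np.zeros(n_total, dtype=bool)
    n_trunc = int(round(spec.truncation_fraction * n_total))
    if n_trunc:
        truncated[rng.choice(n_total, size=n_trunc, replace=False)] = True

    peptides: list[tuple[str, str]] = []
    hit_lines: list[str] = []
    truth_rows: list[tuple] = []
    idx = 0
    flank_lo, flank_hi = spec.flank_range
    for cls, residue in _CLASS_RESIDUES:
        for i in range(counts[cls]):
            pid = f"pola_{cls}_{i:04d}"
            lf = int(rng.integers(flank_lo, flank_hi + 1))
            rf = int(rng.integers(flank_lo, flank_hi + 1))
            seg_start = roi.roi_start - 1 - lf  # 0-based in reference
            residues = list(ref[seg_start:roi.roi_end + rf])
            anchor_idx = {lf, lf + (roi.site - roi.roi_start),
                          lf + (roi.roi_end - roi.roi_start)}
            residues[lf + (roi.site - roi.roi_start)] = residue
            if spec.mutation_rate > 0:
                mask = rng.random(len(residues)) < spec.mutation_rate
                for j in np.flatnonzero(mask):
                    if j in anchor_idx:
                        continue
                    choices = [a for a in AMINO_ACIDS if a != residues[j]]
                    residues[j] = choices[int(rng.integers(len(choices)))]
            spanning = True
            if truncated[idx]:
                # cut before the ROI's right endpoint: cannot span
                cut = lf + (roi.roi_end - roi.roi_start) - 50
                residues = residues[:cut]
                spanning = False
            peptide = "".join(residues)
            peptides.append((pid, peptide))
            hit_lines.append(
                f"{pid}\t{roi.reference_id}\t85.00\t{len(peptide)}\t0\t0\t1\t"
                f"{len(peptide)}\t1\t{len(peptide)}\t1e-60\t{2 * len(peptide)}"
            )
            truth_rows.append((pid, cls, residue, _LIFESTYLE_OF[residue],
                               int(spanning), len(peptide)))
            idx += 1

    files = PolAFiles(
        peptides_fasta=out / "pola_peptides.fasta",
        hits_tsv=out / "pola_hits.tsv",
        truth_tsv=out / "pola_truth.tsv",
    )
    write_fasta(files.peptides_fasta, peptides)
    with open(files.hits_tsv, "w") as handle:
        handle.write("\n".join(hit_lines) + "\n")
    pd.DataFrame(
        truth_rows,
        columns=["orf_id", "class", "planted_residue", "planted_lifestyle",
                 "spans_roi", "length"],
    ).to_csv(files.truth_tsv, sep="\t", index=False)
    return files


# ---------------------------------------------------------------------------
# OTU tables
# ---------------------------------------------------------------------------

#: Phylum composition of the shared core in the emulated pond (OTU counts).
DEFAULT_SHARED_CORE_PHYLA: dict[str, int] = {
    "Actinobacteria": 127, "Proteobacteria": 82, "Bacteroidetes": 43,
    "TM7": 9, "OD1": 4, "Verrucomicrobia": 2, "Firmicutes": 2,
    "Chloroflexi": 2, "Cyanobacteria": 1, "WS5": 1, "SR1": 1, "GN02": 1,
    "Fusobacteria": 1, "Chlamydiae": 1,
}

#: Phylum composition of each fraction's unique core (OTU counts).
DEFAULT_UNIQUE_CORE_PHYLA: dict[str, dict[str, int]] = {
    "0.2um": {
        "Actinobacteria": 90, "Proteobacteria": 33, "Bacteroidetes": 23,
        "Verrucomicrobia": 2, "TM7": 1, "GN02": 1, "Chlamydiae": 1,
        "Spirochaetes": 1,
    },
    "1um": {
        "Proteobacteria": 78, "Actinobacteria": 16, "Bacteroidetes": 16,
        "Cyanobacteria": 6, "Firmicutes": 6, "Chloroflexi": 5, "TM7": 5,
        "Planctomycetes": 4, "Acidobacteria": 4, "Verrucomicrobia": 3,
        "Gemmatimonadetes": 2, "OD1": 1, "WS5": 1,
    },
}

_SPORADIC_PHYLA = ("Actinobacteria", "Proteobacteria", "Bacteroidetes",
                   "Cyanobacteria", "Firmicutes", "Planctomycetes",
                   "Verrucomicrobia", "Chloroflexi")


@dataclass(frozen=True)
class OtuTableSpec:
    """A two-fraction, three-month 16S survey with planted core structure.

    Defaults emulate the study scale: 7,489 OTUs of which 277 are core to
    both filter fractions, 152 unique to the 0.2 µm core and 147 unique to
    the 1 µm core, sampled monthly (October–December) with four replicate
    samples per fraction per month at ~60k reads each.
    """

    seed: int
    groups: tuple[str, ...] = ("1um", "0.2um")
    n_months: int = 3
    n_replicates: int = 4
    n_core_shared: int = 277
    n_core_unique: Mapping[str, int] = field(
        default_factory=lambda: {"1um": 147, "0.2um": 152})
    n_sporadic: int = 6913
    depth: int = 60000
    shared_core_phyla: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SHARED_CORE_PHYLA))
    unique_core_phyla: Mapping[str, Mapping[str, int]] = field(
        default_factory=lambda: {g: dict(d) for g, d in
                                 DEFAULT_UNIQUE_CORE_PHYLA.items()})
    #: month-index multiplier exp(coef * month) on OTUs of the phylum
    trend_coefficients: Mapping[str, float] = field(
        default_factory=lambda: {"Cyanobacteria": -0.8})

    @property
    def n_samples_per_group(self) -> int:
        return self.n_months * self.n_replicates


def _phyla_labels(phyla_counts: Mapping[str, int], n: int,
                  rng: np.random.Generator) -> list[str]:
    labels: list[str] = []
    for phylum in phyla_counts:
        labels.extend([phylum] * phyla_counts[phylum])
    if len(labels) < n:
        extra = rng.choice(np.array(_SPORADIC_PHYLA), size=n - len(labels))
        labels.extend(extra.tolist())
    return labels[:n]


def generate_otu_table(
    spec: OtuTableSpec,
    out_dir: str | Path | None = None,
) -> tuple[OtuTable, pd.DataFrame]:
    """Build a planted OTU table (and optionally write it with its truth).

    Core OTUs of a group get count >= 1 in every sample of that group by
    construction; unique-core and sporadic OTUs are forced absent from at
    least one sample of every other (respectively every) group, so core
    membership is exactly recoverable.  Counts are a log-normal abundance
    profile sampled multinomially at the per-sample depth.
    """
    rng = np.random.default_rng(spec.seed)
    sample_ids: list[str] = []
    sample_group: list[str] = []
    sample_month: list[int] = []
    for g in spec.groups:
        for m in range(spec.n_months):
            for r in range(spec.n_replicates):
                sample_ids.append(f"{g}_m{m}_r{r}")
                sample_group.append(g)
                sample_month.append(m)
    n_samples = len(sample_ids)
    group_rows = {g: [i for i, gg in enumerate(sample_group) if gg == g]
                  for g in spec.groups}

    otu_ids: list[str] = []
    otu_set: list[str] = []       # "shared" | f"unique_{g}" | "sporadic"
    otu_phylum: list[str] = []
    otu_forced_absent: list[set[int]] = []
    otu_guaranteed: list[set[int]] = []  # sample rows with guaranteed presence

    def add_otus(n: int, set_name: str, phyla: list[str],
                 guaranteed_rows: set[int], absent_from_groups: list[str]) -> None:
        for i in range(n):
            otu_ids.append(f"otu_{set_name}_{i:05d}")
            otu_set.append(set_name)
            otu_phylum.append(phyla[i])
            absent = {int(rng.choice(group_rows[g]))
                      for g in absent_from_groups}
            otu_forced_absent.append(absent)
            otu_guaranteed.append(guaranteed_rows)

    add_otus(spec.n_core_shared, "shared",
             _phyla_labels(spec.shared_core_phyla, spec.n_core_shared, rng),
             set(range(n_samples)), [])
    for g in spec.groups:
        n_unique = int(spec.n_core_unique.get(g, 0))
        others = [o for o in spec.groups if o != g]
        add_otus(n_unique, f"unique_{g}",
                 _phyla_labels(spec.unique_core_phyla.get(g, {}), n_unique, rng),
                 set(group_rows[g]), others)
    add_otus(spec.n_sporadic, "sporadic",
             _phyla_labels({}, spec.n_sporadic, rng),
             set(), list(spec.groups))

    n_otus = len(otu_ids)
    base_weight = rng.lognormal(mean=0.0, sigma=1.5, size=n_otus)
    trend_coef = np.array([spec.trend_coefficients.get(p, 0.0)
                           for p in otu_phylum])

    counts = np.zeros((n_samples, n_otus), dtype=np.int64)
    for s in range(n_samples):
        w = base_weight * np.exp(trend_coef * sample_month[s])
        guaranteed = np.array([s in otu_guaranteed[j] for j in range(n_otus)])
        absent = np.array([s in otu_forced_absent[j] for j in range(n_otus)])
        w[absent] = 0.0
        n_guaranteed = int(guaranteed.sum())
        drawn = rng.multinomial(spec.depth - n_guaranteed, w / w.sum())
        counts[s] = drawn + guaranteed.astype(np.int64)

    taxonomy = {
        oid: (f"k__Bacteria; p__{ph}; c__{ph}_c; o__{ph}_o; f__{ph}_f; "
              f"g__Genus_{oid}")
        for oid, ph in zip(otu_ids, otu_phylum)
    }
    table = OtuTable(sample_ids=sample_ids, otu_ids=otu_ids, counts=counts,
                     taxonomy=taxonomy)
    truth = pd.DataFrame({
        "otu_id": otu_ids, "set": otu_set, "phylum": otu_phylum,
    })
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_otu_table(out / "otu_table.tsv", table)
        truth.to_csv(out / "otu_truth.tsv", sep="\t", index=False)
    return table, truth
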