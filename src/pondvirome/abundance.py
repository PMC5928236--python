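"""Coverage and per-Gbp normalized abundance.

A feature's coverage is its mean per-base read depth (zero-depth positions
included).  To compare viromes sequenced at different effort, coverage is
divided by the giga base pairs of reads recruited back to the assembly, so
the reported unit is coverage per Gbp recruited.  One recruitment total is
shared by contig and ORF normalization within a sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .formats_io import DepthProfile, Orf


@dataclass(frozen=True)
class RecruitmentSummary:
    """Total bases recruited to the assembly for one sample."""

    sample_id: str
    total_recruited_bases: int

    def __post_init__(self) -> None:
        if self.total_recruited_bases < 0:
            raise ValueError("total_recruited_bases must be >= 0")

    @property
    def gbp(self) -> float:
        """Recruited bases in giga base pairs."""
        return self.total_recruited_bases / 1e9


@dataclass(frozen=True)
class AbundanceRecord:
    """Coverage and normalized abundance for one contig, ORF or peptide."""

    feature_id: str
    feature_kind: str  # {"contig", "orf", "peptide"}
    coverage: float
    normalized_abundance: float


def contig_coverage(profile: DepthProfile) -> float:
    """Mean per-base depth over all contig positions, zeros included."""
    if len(profile) == 0:
        raise ValueError(f"contig {profile.contig_id!r}: empty depth profile")
    return float(profile.depth.mean())


def orf_coverage(profile: DepthProfile, orf: Orf) -> float:
    """Mean depth over the ORF's start..end window (1-based inclusive).

    Strand-independent: an ORF on the minus strand with the same
    coordinates has the same coverage.
    """
    if orf.end > len(profile):
        raise ValueError(
            f"ORF {orf.id!r} (end {orf.end}) outside contig "
            f"{profile.contig_id!r} (length {len(profile)})"
        )
    return float(profile.depth[orf.start - 1:orf.end].mean())


def normalize_abundance(coverage: float, recruitment: RecruitmentSummary) -> float:
    """Coverage divided by giga base pairs of recruited reads."""
    if coverage < 0:
        raise ValueError("coverage must be >= 0")
    if recruitment.gbp <= 0:
        raise ValueError(
            f"sample {recruitment.sample_id!r}: no recruited bases; "
            "per-Gbp normalization is undefined"
        )
    return coverage / recruitment.gbp


def log2_abundance(normalized_abundance: float, pseudocount: float) -> float:
    """log2(abundance + pseudocount); presentational transform only."""
    if normalized_abundance < 0:
        raise ValueError("normalized_abundance must be >= 0")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    return math.log2(normalized_abundance + pseudocount)


def abundance_table(
    profiles: Mapping[str, DepthProfile],
    orfs: Iterable[Orf],
    recruitment: RecruitmentSummary,
) -> pd.DataFrame:
    """Per-contig and per-ORF abundance for one sample, as a tidy table.

    Columns: feature_id, feature_kind, coverage, gbp, normalized_abundance.
    """
    rows = []
    for cid in profiles:
        cov = contig_coverage(profiles[cid])
        rows.append((cid, "contig", cov, recruitment.gbp,
                     normalize_abundance(cov, recruitment)))
    for orf in orfs:
        if orf.contig_id not in profiles:
            raise KeyError(f"ORF {orf.id!r}: no depth profile for contig "
                           f"{orf.contig_id!r}")
        cov = orf_coverage(profiles[orf.contig_id], orf)
        rows.append((orf.id, "orf", cov, recruitment.gbp,
                     normalize_abundance(cov, recruitment)))
    return pd.DataFrame(
        rows,
        columns=["feature_id", "feature_kind", "coverage", "gbp",
                 "normalized_abundance"],
    )


def write_abundance_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_abundance_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
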