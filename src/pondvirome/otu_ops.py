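"""OTU-table operations for 16S community profiling.

Relative abundance, taxonomy-level collapse, the >1 % maximum-relative-
abundance display filter, rarefaction to an even depth, alpha diversity
(Shannon in bits, observed OTUs), Bray–Curtis dissimilarity and core-OTU
set algebra between sample groups (e.g., the 1 µm and 0.2 µm filter
fractions).  Core membership is presence (count > 0) on raw counts;
Shannon uses log base 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis as _braycurtis
from scipy.stats import entropy as _entropy

from .formats_io import OtuTable

#: Display filter: keep taxa whose max relative abundance exceeds 1 %.
DEFAULT_MAX_RELABUND_THRESHOLD = 0.01

LINEAGE_DELIMITER = ";"


@dataclass
class CoreResult:
    """Core OTUs per group, their intersection, and per-phylum breakdowns."""

    core_per_group: dict[str, set[str]]
    shared_core: set[str]
    unique_core_per_group: dict[str, set[str]]
    phylum_breakdown: dict[str, dict[str, int]] = field(default_factory=dict)


def relative_abundance(table: OtuTable) -> pd.DataFrame:
    """Per-sample fractions (rows = samples, columns = OTUs); rows sum to 1."""
    totals = table.sample_totals()
    zero = [s for s, t in zip(table.sample_ids, totals) if t == 0]
    if zero:
        raise ValueError(f"zero-total sample(s): {zero}")
    frame = table.to_frame()
    return frame.div(totals, axis=0)


def _lineage_fields(lineage: str) -> list[str]:
    return [f.strip() for f in lineage.split(LINEAGE_DELIMITER)]


def _named(fld: str) -> bool:
    # "p__" or "" are placeholders, not names
    return bool(fld) and not fld.endswith("__")


def collapse_taxonomy(table: OtuTable, rank: int) -> OtuTable:
    """Sum counts over OTUs sharing the lineage prefix down to ``rank``.

    ``rank`` counts lineage fields from the left (1 = domain, 6 = genus in
    the usual greengenes-style lineage).  OTUs unclassified at the rank are
    grouped under their deepest named ancestor.  Total counts are conserved.
    """
    if rank < 1:
        raise ValueError("rank must be >= 1")
    labels: list[str] = []
    for otu in table.otu_ids:
        lineage = table.taxonomy.get(otu)
        if lineage is None or not lineage.strip():
            raise ValueError(f"OTU {otu!r}: missing lineage string")
        fields = _lineage_fields(lineage)
        prefix = fields[:rank]
        while prefix and not _named(prefix[-1]):
            prefix = prefix[:-1]
        if not prefix:
            raise ValueError(f"OTU {otu!r}: no named rank in {lineage!r}")
        labels.append("; ".join(prefix))
    order = sorted(set(labels))
    index = {lab: i for i, lab in enumerate(order)}
    counts = np.zeros((len(table.sample_ids), len(order)), dtype=table.counts.dtype)
    for j, lab in enumerate(labels):
        counts[:, index[lab]] += table.counts[:, j]
    return OtuTable(
        sample_ids=list(table.sample_ids),
        otu_ids=order,
        counts=counts,
        taxonomy={lab: lab for lab in order},
    )


def filter_max_relabund(
    rel_table: pd.DataFrame,
    threshold: float = DEFAULT_MAX_RELABUND_THRESHOLD,
) -> pd.DataFrame:
    """Keep columns whose maximum over samples is strictly above threshold."""
    keep = rel_table.max(axis=0) > threshold
    return rel_table.loc[:, keep]


def rarefy(
    table: OtuTable,
    depth: int,
    seed: int | np.random.Generator,
) -> tuple[OtuTable, list[str]]:
    """Subsample each sample to an even depth, without replacement.

    Samples whose total is below ``depth`` are dropped and returned in the
    second element.  Subsampling is multivariate hypergeometric, so each
    retained sample's rarefied total equals ``depth`` exactly.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    totals = table.sample_totals()
    kept_idx = [i for i, t in enumerate(totals) if t >= depth]
    dropped = [s for i, s in enumerate(table.sample_ids) if i not in set(kept_idx)]
    new_counts = np.zeros((len(kept_idx), len(table.otu_ids)), dtype=np.int64)
    for row, i in enumerate(kept_idx):
        counts = table.counts[i].astype(np.int64)
        if totals[i] == depth:
            new_counts[row] = counts
        else:
            new_counts[row] = rng.multivariate_hypergeometric(counts, depth)
    rarefied = OtuTable(
        sample_ids=[table.sample_ids[i] for i in kept_idx],
        otu_ids=list(table.otu_ids),
        counts=new_counts,
        taxonomy=dict(table.taxonomy),
    )
    return rarefied, dropped


def shannon(counts_for_sample: Sequence[float] | np.ndarray) -> float:
    """Shannon diversity in bits: -sum p_i log2 p_i over non-zero OTUs."""
    counts = np.asarray(counts_for_sample, dtype=float)
    if counts.sum() <= 0:
        raise ValueError("sample total must be > 0")
    return float(_entropy(counts, base=2))


def observed_otus(counts_for_sample: Sequence[float] | np.ndarray) -> int:
    """Number of OTUs with a non-zero count."""
    return int(np.count_nonzero(np.asarray(counts_for_sample)))


def alpha_diversity(table: OtuTable) -> pd.DataFrame:
    """Shannon (bits) and observed OTUs per sample."""
    return pd.DataFrame({
        "sample_id": table.sample_ids,
        "shannon": [shannon(row) for row in table.counts],
        "observed_otus": [observed_otus(row) for row in table.counts],
    })


def bray_curtis(table: OtuTable) -> pd.DataFrame:
    """Pairwise Bray–Curtis dissimilarity, samples x samples.

    d(a, b) = sum|a_i - b_i| / sum(a_i + b_i); 0 for identical samples,
    1 for samples with disjoint OTU sets.
    """
    if len(table.sample_ids) < 2:
        raise ValueError("need >= 2 samples")
    counts = table.counts.astype(float)
    n = counts.shape[0]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if counts[i].sum() == 0 and counts[j].sum() == 0:
                raise ValueError(
                    f"Bray–Curtis undefined: samples "
                    f"{table.sample_ids[i]!r} and {table.sample_ids[j]!r} "
                    "are both all-zero"
                )
            dist[i, j] = dist[j, i] = _braycurtis(counts[i], counts[j])
    return pd.DataFrame(dist, index=table.sample_ids, columns=table.sample_ids)


def _phylum(lineage: str | None) -> str:
    if not lineage:
        return "unclassified"
    fields = _lineage_fields(lineage)
    if len(fields) >= 2 and _named(fields[1]):
        return fields[1].removeprefix("p__")
    return "unclassified"


def core_otus(
    table: OtuTable,
    groups: Mapping[str, Sequence[str]],
) -> CoreResult:
    """Core-OTU set algebra between sample groups.

    A group's core is the OTUs present (count > 0) in 100 % of the group's
    samples.  The shared core is the intersection over groups; a group's
    unique core is its core minus every other group's core.  The phylum
    breakdown counts OTUs per phylum within the shared and each unique core.
    """
    sample_index = {s: i for i, s in enumerate(table.sample_ids)}
    core_per_group: dict[str, set[str]] = {}
    for gname, samples in groups.items():
        if len(samples) == 0:
            raise ValueError(f"group {gname!r} is empty")
        missing = [s for s in samples if s not in sample_index]
        if missing:
            raise KeyError(f"group {gname!r}: unknown sample(s) {missing}")
        rows = table.counts[[sample_index[s] for s in samples]]
        present_everywhere = (rows > 0).all(axis=0)
        core_per_group[gname] = {
            otu for otu, p in zip(table.otu_ids, present_everywhere) if p
        }
    shared = set.intersection(*core_per_group.values())
    unique: dict[str, set[str]] = {}
    for gname, core in core_per_group.items():
        others = set().union(*(c for g, c in core_per_group.items()
                               if g != gname))
        unique[gname] = core - others

    breakdown: dict[str, dict[str, int]] = {}
    named_sets = {"shared": shared}
    named_sets.update({f"unique_{g}": s for g, s in unique.items()})
    for set_name, otus in named_sets.items():
        per_phylum: dict[str, int] = {}
        for otu in otus:
            ph = _phylum(table.taxonomy.get(otu))
            per_phylum[ph] = per_phylum.get(ph, 0) + 1
        breakdown[set_name] = per_phylum
    return CoreResult(
        core_per_group=core_per_group,
        shared_core=shared,
        unique_core_per_group=unique,
        phylum_breakdown=breakdown,
    )


def write_core_membership(path: str, result: CoreResult) -> None:
    """Core-OTU membership as a tidy TSV (set_name, otu_id)."""
    with open(path, "w") as handle:
        handle.write("set\totu_id\n")
        for otu in sorted(result.shared_core):
            handle.write(f"shared\t{otu}\n")
        for gname in sorted(result.unique_core_per_group):
            for otu in sorted(result.unique_core_per_group[gname]):
                handle.write(f"unique_{gname}\t{otu}\n")
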