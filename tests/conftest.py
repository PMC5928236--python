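import numpy as np
import pytest

from pondvirome import formats_io as fio
from pondvirome import synthetic_data as syn


@pytest.fixture(scope="session")
def community(tmp_path_factory):
    """One default synthetic community, generated once and parsed once."""
    out = tmp_path_factory.mktemp("community")
    files = syn.generate_community(syn.default_community_spec(seed=7), out)
    lengths = {cid: len(seq) for cid, seq in fio.read_fasta(files.contigs_fasta)}
    profiles, total_bases = fio.depth_from_sam(files.sam, lengths)
    return {
        "files": files,
        "lengths": lengths,
        "profiles": profiles,
        "total_bases": total_bases,
        "orfs": fio.read_orf_table(files.orfs_tsv),
        "hits": fio.read_tabular_hits(
            files.hits_tsv, fio.BLAST6_COLUMNS + fio.EXTRA_HIT_COLUMNS),
    }


@pytest.fixture(scope="session")
def roi():
    return syn.surrogate_pola_reference()


@pytest.fixture(scope="session")
def pola_default_run(tmp_path_factory, roi):
    """The default 17/27/184 Pol I set, classified once for the session."""
    from pondvirome import pola as pa

    out = tmp_path_factory.mktemp("pola")
    files = syn.generate_pola_set(syn.PolASpec(seed=202), out, roi)
    peptides = dict(fio.read_fasta(files.peptides_fasta))
    hits = fio.read_tabular_hits(files.hits_tsv)
    classifications, alignments, summary = pa.run_pola_pipeline(
        peptides, hits, roi)
    return {
        "files": files,
        "peptides": peptides,
        "hits": hits,
        "classifications": classifications,
        "alignments": alignments,
        "summary": summary,
    }


def random_small_contig_reads(rng, n_contigs=3, max_len=60, max_reads=25,
                              read_len=7):
    """Random contigs plus read placements for SAM/depth oracle tests."""
    contigs = {}
    reads = []
    for c in range(n_contigs):
        length = int(rng.integers(read_len, max_len + 1))
        cid = f"c{c}"
        contigs[cid] = "".join(
            "ACGT"[i] for i in rng.integers(0, 4, size=length))
        for r in range(int(rng.integers(0, max_reads + 1))):
            pos = int(rng.integers(1, length - read_len + 2))
            reads.append((f"r{c}_{r}", cid, pos, read_len))
    return contigs, reads


def write_sam(path, contigs, reads):
    with open(path, "w") as handle:
        handle.write("@HD\tVN:1.6\tSO:unsorted\n")
        for cid, seq in contigs.items():
            handle.write(f"@SQ\tSN:{cid}\tLN:{len(seq)}\n")
        for qname, cid, pos, rl in reads:
            seq = contigs[cid][pos - 1:pos - 1 + rl]
            handle.write(
                f"{qname}\t0\t{cid}\t{pos}\t60\t{rl}M\t*\t0\t0\t{seq}\t*\n")
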