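"""Exact junction matching and the >40-read SV presence rule."""

import numpy as np
import pytest
from Bio.Seq import Seq

from clonotrace.sv import (
    BreakpointJunction,
    JunctionCount,
    ManifestError,
    call_sv_presence,
    count_junction_reads,
    count_junctions_multi,
    genotype_sv_cell,
    reverse_complement,
)

JUNC = BreakpointJunction("SV_A", "ACGTACGTACGTACGTACGTACGTACGTAC", "deletion")


def oracle_count(reads, junction_seq, both_strands):
    """Independent per-read substring scan using Biopython's revcomp."""
    rc = str(Seq(junction_seq).reverse_complement())
    n = 0
    for read in reads:
        hit = junction_seq in read
        if both_strands:
            hit = hit or rc in read
        if hit:
            n += 1
    return n


def embed(rng, junction_seq, length=100):
    flank = "".join(rng.choice(list("ACGT"), size=length - len(junction_seq)))
    off = int(rng.integers(0, length - len(junction_seq) + 1))
    return flank[:off] + junction_seq + flank[off:]


def test_empty_read_set_matches_nothing():
    c = count_junction_reads([], JUNC)
    assert c.n_match == 0 and c.n_reads_scanned == 0


def test_embedded_junction_reads_are_counted_exactly(rng):
    reads = [embed(rng, JUNC.junction_seq) for _ in range(50)]
    reads += ["".join(rng.choice(list("ACGT"), size=100)) for _ in range(10)]
    c = count_junction_reads(reads, JUNC)
    assert c.n_match == oracle_count(reads, JUNC.junction_seq, True)
    assert c.n_match >= 50  # every embedded read must match


def test_reverse_complement_read_counts_only_with_both_strands():
    read = "TT" + reverse_complement(JUNC.junction_seq) + "GG"
    assert count_junction_reads([read], JUNC, both_strands=True).n_match == 1
    assert count_junction_reads([read], JUNC, both_strands=False).n_match == 0


def test_read_with_multiple_occurrences_counts_once():
    read = JUNC.junction_seq + "TTTT" + JUNC.junction_seq
    assert count_junction_reads([read], JUNC).n_match == 1


def test_ambiguous_bases_never_match():
    read = JUNC.junction_seq.replace("A", "N", 1)
    assert count_junction_reads([read], JUNC).n_match == 0


def test_counts_equal_naive_oracle_on_random_read_sets(rng):
    for _ in range(30):
        n = int(rng.integers(0, 120))
        reads = ["".join(rng.choice(list("ACGT"), size=60)) for _ in range(n)]
        for _ in range(int(rng.integers(0, 10))):
            reads.append(embed(rng, JUNC.junction_seq, 60))
        for strands in (True, False):
            c = count_junction_reads(reads, JUNC, both_strands=strands)
            assert c.n_match == oracle_count(reads, JUNC.junction_seq, strands)
            assert c.n_reads_scanned == len(reads)


def test_adding_reads_is_monotone(rng):
    reads = [embed(rng, JUNC.junction_seq) for _ in range(5)]
    base = count_junction_reads(reads, JUNC).n_match
    assert count_junction_reads(reads + [embed(rng, JUNC.junction_seq)], JUNC).n_match == base + 1
    junk = "".join(rng.choice(list("ACGT"), size=100))
    if JUNC.junction_seq not in junk and reverse_complement(JUNC.junction_seq) not in junk:
        assert count_junction_reads(reads + [junk], JUNC).n_match == base


def test_one_read_can_support_two_junctions():
    other = BreakpointJunction("SV_B", "GGGGCCCCGGGGCCCCGGGGCCCCGGGGCC", "inversion")
    read = JUNC.junction_seq + other.junction_seq
    counts = count_junctions_multi([read], [JUNC, other])
    assert [c.n_match for c in counts] == [1, 1]


@pytest.mark.parametrize(
    "n_match,min_reads,expected",
    [(41, 40, 1), (40, 40, 0), (0, 40, 0), (1, 0, 1), (0, 0, 0)],
)
def test_presence_call_is_strictly_greater_than(n_match, min_reads, expected):
    c = JunctionCount("SV_A", "cell", n_match, max(n_match, 1))
    assert call_sv_presence(c, min_reads) == expected


def test_negative_threshold_rejected():
    with pytest.raises(ValueError):
        call_sv_presence(JunctionCount("SV_A", "c", 5, 5), min_reads=-1)


def test_invalid_junction_sequence_rejected():
    with pytest.raises(ManifestError):
        BreakpointJunction("bad", "ACGTN" + "A" * 25, "deletion")
    with pytest.raises(ManifestError):
        BreakpointJunction("bad", "ACGT" * 8, "duplication")
    j = BreakpointJunction("short", "ACGT", "deletion")
    with pytest.raises(ManifestError):
        j.validate_length(30)


def test_genotype_sv_cell_from_fastq(tmp_path, rng):
    other = BreakpointJunction("SV_B", "GATCGATCGATCGATCGATCGATCGATCGA", "insertion")
    records = [(f"r{i}", embed(rng, JUNC.junction_seq)) for i in range(100)]
    records += [(f"b{i}", embed(rng, other.junction_seq)) for i in range(5)]
    path = tmp_path / "cell.fastq"
    from clonotrace.io import write_fastq

    write_fastq(str(path), records)
    result = genotype_sv_cell(str(path), [JUNC, other], min_reads=40, cell_id="c1")
    calls = {c.assay_id: (c.n_match, call) for c, call in result}
    assert calls["SV_A"] == (100, 1)
    assert calls["SV_B"] == (5, 0)
    again = genotype_sv_cell(str(path), [JUNC, other], min_reads=40, cell_id="c1")
    assert [c.n_match for c, _ in again] == [c.n_match for c, _ in result]


def test_genotype_sv_cell_empty_fastq(tmp_path):
    path = tmp_path / "empty.fastq"
    path.write_text("")
    for c, call in genotype_sv_cell(str(path), [JUNC]):
        assert c.n_match == 0 and call == 0


def test_genotype_sv_cell_requires_manifest():
    with pytest.raises(ManifestError):
        genotype_sv_cell([], [])
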