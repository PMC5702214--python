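"""Structural-variant genotyping by exact breakpoint-junction matching.

Each structural variant is assayed through the novel sequence created at its
breakpoint: a short junction k-mer (30 nt by default) that exists in the
rearranged genome but nowhere in the reference. A cell carries the SV if
strictly more than ``min_reads`` of its amplicon reads contain that k-mer as
an exact substring. Matching is exact — no mismatches, no indels — because
the junction sequence is bulk-confirmed and amplicon reads covering it are
expected to reproduce it verbatim; the read-count threshold (default 40)
absorbs cross-contamination and demultiplexing errors instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

SV_CLASSES = frozenset({"deletion", "insertion", "inversion", "translocation"})
DEFAULT_JUNCTION_LEN = 30
DEFAULT_MIN_READS = 40

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a plain ACGT string (case preserved per base)."""
    return seq.translate(_COMPLEMENT)[::-1]


class ManifestError(ValueError):
    """Raised when a target manifest entry violates its contract."""


@dataclass(frozen=True)
class BreakpointJunction:
    """One bulk-confirmed SV breakpoint, identified by its junction k-mer.

    Parameters
    ----------
    assay_id
        Unique identifier within a manifest.
    junction_seq
        Uppercase DNA spanning the breakpoint; length is validated against
        ``expected_len`` at manifest load (30 nt by default).
    sv_class
        One of deletion / insertion / inversion / translocation.
    span_kb
        Optional event size in kilobases, informational only.
    """

    assay_id: str
    junction_seq: str
    sv_class: str
    span_kb: float | None = None

    def __post_init__(self) -> None:
        if not self.assay_id:
            raise ManifestError("junction assay_id must be non-empty")
        if set(self.junction_seq) - set("ACGT"):
            bad = sorted(set(self.junction_seq) - set("ACGT"))
            raise ManifestError(
                f"junction {self.assay_id!r} contains non-ACGT symbols {bad}"
            )
        if self.sv_class not in SV_CLASSES:
            raise ManifestError(
                f"junction {self.assay_id!r}: unknown sv_class {self.sv_class!r}"
            )
        if self.span_kb is not None and not self.span_kb > 0:
            raise ManifestError(f"junction {self.assay_id!r}: span_kb must be > 0")

    def validate_length(self, expected_len: int = DEFAULT_JUNCTION_LEN) -> None:
        if len(self.junction_seq) != expected_len:
            raise ManifestError(
                f"junction {self.assay_id!r} has length {len(self.junction_seq)}, "
                f"expected {expected_len}"
            )


@dataclass(frozen=True)
class JunctionCount:
    """Junction-read tally for one (cell, assay) pair."""

    assay_id: str
    cell_id: str
    n_match: int
    n_reads_scanned: int

    def __post_init__(self) -> None:
        if self.n_match < 0 or self.n_reads_scanned < 0:
            raise ValueError("counts must be non-negative")


def count_junction_reads(
    reads: Iterable[str],
    junction: BreakpointJunction,
    both_strands: bool = True,
    cell_id: str = "",
) -> JunctionCount:
    """Count reads carrying ``junction.junction_seq`` as an exact substring.

    A read counts at most once even if the junction occurs several times
    within it. With ``both_strands`` (the default; sequencing is unstranded)
    a read containing the reverse complement of the junction also counts.
    Reads with ambiguous bases simply never match.
    """
    fwd = junction.junction_seq
    rev = reverse_complement(fwd) if both_strands else None
    n_match = 0
    n_scanned = 0
    for read in reads:
        n_scanned += 1
        if fwd in read or (rev is not None and rev in read):
            n_match += 1
    return JunctionCount(junction.assay_id, cell_id, n_match, n_scanned)


def count_junctions_multi(
    reads: Iterable[str],
    junctions: Sequence[BreakpointJunction],
    both_strands: bool = True,
    cell_id: str = "",
) -> list[JunctionCount]:
    """Single pass over ``reads`` counting every junction independently.

    A read matching two different junctions counts for both: assays are
    independent. Equivalent to calling :func:`count_junction_reads` per
    junction but scans the read set once.
    """
    targets = []
    for j in junctions:
        pats = [j.junction_seq]
        if both_strands:
            pats.append(reverse_complement(j.junction_seq))
        targets.append(pats)
    counts = [0] * len(junctions)
    n_scanned = 0
    for read in reads:
        n_scanned += 1
        for i, pats in enumerate(targets):
            if any(p in read for p in pats):
                counts[i] += 1
    return [
        JunctionCount(j.assay_id, cell_id, c, n_scanned)
        for j, c in zip(junctions, counts)
    ]


def call_sv_presence(count: JunctionCount, min_reads: int = DEFAULT_MIN_READS) -> int:
    """Binary SV call: present iff strictly more than ``min_reads`` matches."""
    if min_reads < 0:
        raise ValueError("min_reads must be non-negative")
    return int(count.n_match > min_reads)


def genotype_sv_cell(
    reads: Iterable[str] | str,
    junctions: Sequence[BreakpointJunction],
    min_reads: int = DEFAULT_MIN_READS,
    both_strands: bool = True,
    cell_id: str = "",
) -> list[tuple[JunctionCount, int]]:
    """Genotype every junction in a manifest for one cell.

    ``reads`` may be an iterable of read strings or a FASTQ path (plain or
    gzipped). Returns one ``(JunctionCount, call)`` pair per junction, in
    manifest order; deterministic for fixed input.
    """
    if not junctions:
        raise ManifestError("junction manifest is empty")
    if isinstance(reads, str):
        from .io import read_fastq_sequences

        reads = read_fastq_sequences(reads)
    counts = count_junctions_multi(reads, junctions, both_strands, cell_id)
    return [(c, call_sv_presence(c, min_reads)) for c in counts]
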