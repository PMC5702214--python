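"""Readers and writers for the formats the pipeline consumes and emits.

TSV tables (manifests, count tables, call tables, matrices) go through
pandas with explicit header validation; FASTQ goes through Biopython and
transparently handles gzip; per-cell genotype calls can be exported as a
minimal VCF 4.2; clone trees export to GraphML (via networkx) and DOT.
All genomic coordinates in user-facing files are 1-based, fully closed
(VCF convention).
"""

from __future__ import annotations

import gzip
import json
import hashlib
from typing import IO, Iterable, Iterator, Sequence

import pandas as pd
from Bio import SeqIO

from .qc import BinaryMatrix
from .snv import SnvSite
from .sv import BreakpointJunction, ManifestError


class ParseError(ValueError):
    """Malformed input file; message carries file name and location."""


def open_maybe_gzip(path: str, mode: str = "rt") -> IO:
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------- FASTQ


def read_fastq(path: str) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) from a plain or gzipped FASTQ file."""
    n = 0
    try:
        with open_maybe_gzip(path) as handle:
            for rec in SeqIO.parse(handle, "fastq"):
                n += 1
                yield rec.id, str(rec.seq).upper()
    except ValueError as exc:
        raise ParseError(
            f"{path}: malformed FASTQ near record {n + 1}: {exc}"
        ) from exc


def read_fastq_sequences(path: str) -> Iterator[str]:
    for _, seq in read_fastq(path):
        yield seq


def write_fastq(path: str, records: Iterable[tuple[str, str]]) -> None:
    op = gzip.open if path.endswith(".gz") else open
    with op(path, "wt") as out:
        for rid, seq in records:
            out.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------- TSV tables


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")


def read_tsv(path: str, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, required, path)
    return df


def read_junction_manifest(path: str, junction_len: int | None = 30) -> list[BreakpointJunction]:
    """Load SV junction manifest; junction length validated (default 30 nt)."""
    df = read_tsv(path, ["assay_id", "sv_class", "junction_seq"])
    juncs = []
    seen: set[str] = set()
    for i, r in enumerate(df.itertuples(index=False), start=2):
        if r.assay_id in seen:
            raise ManifestError(f"{path}: duplicate assay_id {r.assay_id!r} (line {i})")
        seen.add(r.assay_id)
        span = getattr(r, "span_kb", None)
        span = None if span is None or pd.isna(span) else float(span)
        j = BreakpointJunction(
            str(r.assay_id), str(r.junction_seq).upper(), str(r.sv_class), span
        )
        if junction_len is not None:
            j.validate_length(junction_len)
        juncs.append(j)
    return juncs


def write_junction_manifest(path: str, junctions: Sequence[BreakpointJunction]) -> None:
    pd.DataFrame(
        [
            (j.assay_id, j.sv_class, j.junction_seq, j.span_kb)
            for j in junctions
        ],
        columns=["assay_id", "sv_class", "junction_seq", "span_kb"],
    ).to_csv(path, sep="\t", index=False)


def read_snv_manifest(path: str) -> list[SnvSite]:
    df = read_tsv(path, ["assay_id", "chrom", "pos", "ref", "alt"])
    sites = []
    seen: set[str] = set()
    for i, r in enumerate(df.itertuples(index=False), start=2):
        if r.assay_id in seen:
            raise ManifestError(f"{path}: duplicate assay_id {r.assay_id!r} (line {i})")
        seen.add(r.assay_id)
        sites.append(
            SnvSite(str(r.assay_id), str(r.chrom), int(r.pos), str(r.ref), str(r.alt))
        )
    return sites


def write_snv_manifest(path: str, sites: Sequence[SnvSite]) -> None:
    pd.DataFrame(
        [(s.assay_id, s.chrom, s.pos, s.ref_base, s.alt_base) for s in sites],
        columns=["assay_id", "chrom", "pos", "ref", "alt"],
    ).to_csv(path, sep="\t", index=False)


def read_counts_table(path: str) -> pd.DataFrame:
    return read_tsv(path, ["cell_id", "assay_id", "alt_count", "depth"])


def read_cells_table(path: str) -> pd.DataFrame:
    df = read_tsv(path, ["cell_id", "visually_single"])
    df["visually_single"] = df["visually_single"].astype(bool)
    return df


def write_matrix(matrix: BinaryMatrix, path: str, mask_path: str | None = None) -> None:
    matrix.to_frame().rename_axis("cell_id").to_csv(path, sep="\t")
    if mask_path is not None:
        matrix.mask_frame().rename_axis("cell_id").to_csv(mask_path, sep="\t")


def read_matrix(path: str, mask_path: str | None = None) -> BinaryMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    mask = (
        pd.read_csv(mask_path, sep="\t", index_col=0).to_numpy()
        if mask_path is not None
        else pd.DataFrame(0, index=df.index, columns=df.columns).to_numpy()
    )
    return BinaryMatrix(
        [str(c) for c in df.index], [str(a) for a in df.columns], df.to_numpy(), mask
    )


# ---------------------------------------------------------------- VCF export


def write_vcf(
    path: str,
    sites: Sequence[SnvSite],
    calls: pd.DataFrame,
    cell_ids: Sequence[str],
) -> None:
    """Minimal VCF 4.2 export of per-cell binary SNV genotypes (GT 0/1).

    ``calls`` needs columns cell_id, assay_id, call; missing pairs export
    as ./. (no data).
    """
    lookup = {
        (str(r.cell_id), str(r.assay_id)): int(r.call)
        for r in calls.itertuples(index=False)
    }
    with open(path, "w") as out:
        out.write("##fileformat=VCFv4.2\n")
        out.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = []
        for s in sites:
            if s.chrom not in chroms:
                chroms.append(s.chrom)
        for c in chroms:
            out.write(f"##contig=<ID={c}>\n")
        out.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(cell_ids)
            + "\n"
        )
        for s in sorted(sites, key=lambda s: (chroms.index(s.chrom), s.pos)):
            gts = []
            for cell in cell_ids:
                call = lookup.get((cell, s.assay_id))
                gts.append("./." if call is None else ("0/1" if call else "0/0"))
            out.write(
                f"{s.chrom}\t{s.pos}\t{s.assay_id}\t{s.ref_base}\t{s.alt_base}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


# ---------------------------------------------------------------- graphs


def write_graphml(tree, path: str) -> None:
    import networkx as nx

    nx.write_graphml(tree.to_graph(), path)


def write_dot(tree, path: str) -> None:
    with open(path, "w") as out:
        out.write("graph clones {\n")
        for node in tree.nodes:
            out.write(
                f'  "{node.label}" [label="{node.label}\\n{node.n_cells} cells\\n'
                f'{node.n_snv} SNV / {node.n_sv} SV"];\n'
            )
        for a, b, w in tree.edges:
            out.write(f'  "{a}" -- "{b}" [label="{w:g}", weight={w:g}];\n')
        out.write("}\n")


def write_edge_list(tree, path: str) -> None:
    pd.DataFrame(tree.edges, columns=["node_a", "node_b", "weight"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------- checksums


def file_checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_run_manifest(path: str, config: dict, files: Sequence[str]) -> None:
    from . import __version__

    manifest = {
        "version": __version__,
        "config": config,
        "checksums": {f: file_checksum(f) for f in files},
    }
    with open(path, "w") as out:
        json.dump(manifest, out, indent=2, sort_keys=True)
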