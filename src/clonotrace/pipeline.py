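"""End-to-end orchestration: genotyping -> QC -> matrix -> EM -> tree.

Two entry points. :func:`analyze_tables` takes in-memory count tables (the
form the simulator produces and the form upstream aligners/callers reduce
to) and runs the full clonal-reconstruction analysis. :func:`run_pipeline`
is the file-based wrapper the CLI uses: it reads manifests, counts and
per-cell FASTQ files, runs the same analysis, and writes every stage's
output plus a run manifest with config and checksums.
"""

from __future__ import annotations

import dataclasses
import glob
import json
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import em, io, qc, snv, sv, tree as tree_mod


class StageError(RuntimeError):
    """A pipeline stage failed; message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Every threshold the pipeline applies, in one auditable place."""

    min_reads: int = sv.DEFAULT_MIN_READS
    both_strands: bool = True
    junction_len: int | None = sv.DEFAULT_JUNCTION_LEN
    min_alt_reads: int = snv.DEFAULT_MIN_ALT_READS
    min_vaf: float = snv.DEFAULT_MIN_VAF
    min_fraction: float = qc.DEFAULT_MIN_FRACTION
    min_depth: int = qc.DEFAULT_MIN_DEPTH
    k: int | str = "auto"
    k_max: int = em.DEFAULT_K_MAX
    n_restarts: int = em.DEFAULT_N_RESTARTS
    use_mask: bool = False
    poor_assay_prefilter: bool = False
    max_missing_fraction: float = qc.DEFAULT_MAX_MISSING_FRACTION
    doublet_tolerance: float = em.DEFAULT_DOUBLET_TOLERANCE
    distance: str = "hamming"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    """Everything the analysis computed, stage by stage."""

    config: RunConfig
    qc_table: pd.DataFrame  # cell_id, visually_single, fraction_covered, qc_pass
    snv_calls: pd.DataFrame
    sv_calls: pd.DataFrame
    matrix: qc.BinaryMatrix
    poor_assays_prefilter: list[str]
    k: int
    model: em.MixtureModel
    cluster_roles: dict[int, str]  # cluster index -> clone / doublet
    doublet_clusters: list[int]
    mutation_clusters: pd.DataFrame
    clone_nodes: list
    tree: tree_mod.CloneTree
    assignments: pd.DataFrame = field(default=None)  # cell_id, cluster, role


def _qc_cells(
    snv_counts: pd.DataFrame,
    cells: pd.DataFrame,
    snv_assay_ids: Sequence[str],
    cfg: RunConfig,
) -> pd.DataFrame:
    depth = snv_counts.pivot_table(
        index="cell_id", columns="assay_id", values="depth", aggfunc="first"
    )
    rows = []
    for rec in cells.itertuples(index=False):
        cov = (
            depth.loc[rec.cell_id].dropna().astype(int).to_dict()
            if rec.cell_id in depth.index
            else {}
        )
        cell = qc.CellRecord(str(rec.cell_id), bool(rec.visually_single), cov)
        passed, frac = qc.qc_cell(
            cell, snv_assay_ids, cfg.min_fraction, cfg.min_depth
        )
        rows.append((cell.cell_id, cell.visually_single, frac, passed))
    return pd.DataFrame(
        rows, columns=["cell_id", "visually_single", "fraction_covered", "qc_pass"]
    )


def analyze_tables(
    snv_counts: pd.DataFrame,
    sv_match_counts: pd.DataFrame,
    cells: pd.DataFrame,
    snv_sites: Sequence[snv.SnvSite],
    junctions: Sequence[sv.BreakpointJunction],
    config: RunConfig | None = None,
) -> PipelineResult:
    """Run genotyping, QC, matrix assembly, clustering and tree building.

    ``snv_counts``: cell_id, assay_id, alt_count, depth (one row per
    covered site per cell). ``sv_match_counts``: cell_id, assay_id,
    n_match (junction-read counts, from FASTQ scanning or the simulator).
    ``cells``: cell_id, visually_single.
    """
    cfg = config or RunConfig()
    snv_ids = [s.assay_id for s in snv_sites]
    sv_ids = [j.assay_id for j in junctions]

    # per-cell genotyping (vectorized; semantics match the scalar callers)
    snv_calls = snv_counts[["cell_id", "assay_id", "alt_count", "depth"]].copy()
    snv_calls["call"] = snv.call_snv_table(snv_calls, cfg.min_alt_reads, cfg.min_vaf)
    snv_calls["flag"] = "ok"
    sv_calls = sv_match_counts[["cell_id", "assay_id", "n_match"]].copy()
    sv_calls["call"] = (sv_calls["n_match"] > cfg.min_reads).astype(int)
    sv_calls["flag"] = "ok"

    qc_table = _qc_cells(snv_counts, cells, snv_ids, cfg)
    passing = qc_table.loc[qc_table["qc_pass"], "cell_id"].tolist()
    if not passing:
        raise StageError("qc-matrix", ValueError("no cells passed QC"))

    matrix = qc.build_matrix(snv_calls, sv_calls, passing, snv_ids, sv_ids)
    poor_pre: list[str] = []
    if cfg.poor_assay_prefilter:
        poor_pre = qc.flag_poor_assays(matrix, cfg.max_missing_fraction)
        matrix = matrix.drop_assays(poor_pre)

    k = em.estimate_k(matrix, cfg.k_max) if cfg.k == "auto" else int(cfg.k)
    model = em.fit_bernoulli_mixture(
        matrix,
        k,
        n_restarts=cfg.n_restarts,
        seed=cfg.seed,
        use_mask=cfg.use_mask,
    )
    doublets = em.flag_doublet_clusters(model, cfg.doublet_tolerance)
    roles = {
        c: ("doublet" if c in doublets else "clone") for c in range(model.K)
    }
    clone_clusters = [c for c in range(model.K) if roles[c] == "clone"]
    mutation_clusters = em.derive_mutation_clusters(
        model, matrix.assay_ids, clusters=clone_clusters
    )
    class_of = {a: "snv" for a in snv_ids}
    class_of.update({a: "sv" for a in sv_ids})
    nodes = tree_mod.consensus_genotypes(
        model,
        assay_classes=class_of,
        assay_ids=matrix.assay_ids,
        clusters=clone_clusters,
    )
    clone_tree = tree_mod.build_mst(nodes, cfg.distance)
    labels = model.labels
    assignments = pd.DataFrame(
        {
            "cell_id": matrix.cell_ids,
            "cluster": labels,
            "role": [roles[c] for c in labels],
        }
    )
    return PipelineResult(
        cfg,
        qc_table,
        snv_calls,
        sv_calls,
        matrix,
        poor_pre,
        k,
        model,
        roles,
        doublets,
        mutation_clusters,
        nodes,
        clone_tree,
        assignments,
    )


def genotype_sv_from_fastq_dir(
    fastq_dir: str,
    junctions: Sequence[sv.BreakpointJunction],
    both_strands: bool = True,
) -> pd.DataFrame:
    """Scan every ``<cell_id>.fastq[.gz]`` in a directory for junction reads."""
    paths = sorted(
        glob.glob(os.path.join(fastq_dir, "*.fastq"))
        + glob.glob(os.path.join(fastq_dir, "*.fastq.gz"))
    )
    if not paths:
        raise FileNotFoundError(f"no FASTQ files found in {fastq_dir}")
    rows = []
    for path in paths:
        cell_id = os.path.basename(path).replace(".fastq.gz", "").replace(
            ".fastq", ""
        )
        counts = sv.count_junctions_multi(
            io.read_fastq_sequences(path), junctions, both_strands, cell_id
        )
        for c in counts:
            rows.append((c.cell_id, c.assay_id, c.n_match, c.n_reads_scanned))
    return pd.DataFrame(
        rows, columns=["cell_id", "assay_id", "n_match", "n_reads_scanned"]
    )


def run_pipeline(
    outdir: str,
    snv_manifest: str,
    junction_manifest: str,
    counts: str,
    cells: str,
    fastq_dir: str | None = None,
    sv_counts: str | None = None,
    config: RunConfig | None = None,
) -> PipelineResult:
    """File-based pipeline: read inputs, analyze, write every stage output.

    Junction-read evidence comes either from ``fastq_dir`` (scanned with
    the exact-match counter) or from a precomputed ``sv_counts`` TSV with
    columns cell_id, assay_id, n_match. Outputs land in ``outdir`` along
    with ``run_manifest.json`` recording the version, the full config and
    a checksum per output file.
    """
    cfg = config or RunConfig()
    os.makedirs(outdir, exist_ok=True)

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:  # noqa: BLE001 - rethrown with stage name
            raise StageError(name, exc) from exc

    sites = stage("read-manifests", io.read_snv_manifest, snv_manifest)
    juncs = stage(
        "read-manifests", io.read_junction_manifest, junction_manifest, cfg.junction_len
    )
    snv_counts = stage("read-counts", io.read_counts_table, counts)
    cell_table = stage("read-cells", io.read_cells_table, cells)
    if fastq_dir is not None:
        sv_match = stage(
            "genotype-sv", genotype_sv_from_fastq_dir, fastq_dir, juncs, cfg.both_strands
        )
    elif sv_counts is not None:
        sv_match = stage("genotype-sv", io.read_tsv, sv_counts, ["cell_id", "assay_id", "n_match"])
    else:
        raise StageError("genotype-sv", ValueError("need fastq_dir or sv_counts"))

    result = analyze_tables(snv_counts, sv_match, cell_table, sites, juncs, cfg)

    outputs = []

    def emit(name, writer):
        path = os.path.join(outdir, name)
        writer(path)
        outputs.append(path)

    emit("sv_calls.tsv", lambda p: result.sv_calls.to_csv(p, sep="\t", index=False))
    emit("snv_calls.tsv", lambda p: result.snv_calls.to_csv(p, sep="\t", index=False))
    emit("qc.tsv", lambda p: result.qc_table.to_csv(p, sep="\t", index=False))
    emit("matrix.tsv", lambda p: io.write_matrix(result.matrix, p))
    emit(
        "mask.tsv",
        lambda p: result.matrix.mask_frame().rename_axis("cell_id").to_csv(p, sep="\t"),
    )
    emit("clusters.tsv", lambda p: result.assignments.to_csv(p, sep="\t", index=False))
    emit(
        "theta.tsv",
        lambda p: pd.DataFrame(
            result.model.theta, columns=result.matrix.assay_ids
        ).to_csv(p, sep="\t", index=False),
    )
    emit(
        "mutation_clusters.tsv",
        lambda p: result.mutation_clusters.to_csv(p, sep="\t", index=False),
    )
    emit(
        "model.json",
        lambda p: _write_model_json(p, result),
    )
    emit("tree_edges.tsv", lambda p: io.write_edge_list(result.tree, p))
    emit("tree.graphml", lambda p: io.write_graphml(result.tree, p))
    emit("tree.dot", lambda p: io.write_dot(result.tree, p))
    io.write_run_manifest(
        os.path.join(outdir, "run_manifest.json"), cfg.to_dict(), outputs
    )
    return result


def _write_model_json(path: str, result: PipelineResult) -> None:
    payload = {
        "K": result.model.K,
        "pi": result.model.pi.tolist(),
        "loglik_trace": result.model.loglik_trace,
        "converged": result.model.converged,
        "seed": result.config.seed,
        "doublet_clusters": result.doublet_clusters,
        "cluster_roles": {str(k): v for k, v in result.cluster_roles.items()},
        "config": result.config.to_dict(),
    }
    with open(path, "w") as out:
        json.dump(payload, out, indent=2)
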