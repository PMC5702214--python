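"""Synthetic single-cell amplicon-resequencing data with known truth.

The generator emulates the data regime of a targeted single-cell study of
a leukemia sample: ~128 whole-genome-amplified cells genotyped at ~41
bulk-confirmed SNV sites and ~36 SV breakpoint junctions, with two clones
descending from a common ancestor. Noise processes mirror what MDA-based
amplification does to genotypes: allelic dropout (false negatives, default
10% per present assay), spurious presence (default 1%), doublet chambers
whose genotype is the union of two clones (default 9.6% of cells), and a
fraction of assays that simply fail to amplify anywhere (default 6.3%).

Truth is generated first (clone tree, per-edge mutation sets, per-cell
clone labels and genotypes), then observations: negative-binomial depths
with binomial allele counts at SNV sites, Poisson junction-read counts for
SV assays, and optionally FASTQ reads with the junction 30-mer embedded in
random flanking sequence. Everything is deterministic given (config, seed).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .snv import SnvSite
from .sv import BreakpointJunction, reverse_complement

_CHROMS = [f"chr{i}" for i in range(1, 23)]
_BASES = "ACGT"


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition knobs; defaults mirror the observed leukemia regime."""

    seed: int = 0
    n_cells: int = 128
    n_snv: int = 41
    n_sv: int = 36
    k_clones: int = 2
    tree_shape: str = "star"  # "star": clones are siblings under the MRCA;
    # "random": each clone attaches to the MRCA or an earlier clone. Star is
    # the default because an ancestor-descendant doublet is genotypically
    # identical to the descendant (its union adds nothing), which makes the
    # planted doublet population unidentifiable by construction.
    clone_proportions: tuple[float, ...] | None = None
    mutations_per_edge: tuple[int, ...] | None = None
    ancestral_sv_only: bool = False
    ado_rate: float = 0.1
    fp_rate: float = 0.01
    doublet_rate: float = 0.096
    poor_assay_fraction: float = 0.063
    depth_mean: float = 100.0
    depth_dispersion: float = 2.0
    poor_depth_mean: float = 2.0
    alt_fraction: float = 0.5
    error_floor: float = 0.002
    sv_present_mean: float = 100.0
    sv_absent_mean: float = 1.0
    read_length: int = 150
    background_reads: int = 200
    junction_len: int = 30

    def __post_init__(self) -> None:
        for name in ("ado_rate", "fp_rate", "doublet_rate", "poor_assay_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.clone_proportions is not None:
            p = np.asarray(self.clone_proportions, dtype=float)
            if len(p) != self.k_clones or not np.isclose(p.sum(), 1.0):
                raise ValueError("clone_proportions must sum to 1 over k_clones")
        if self.read_length < self.junction_len:
            raise ValueError("read_length must be >= junction_len")


@dataclass
class Truth:
    """Ground truth: clone tree, mutation placement, cell labels, genotypes."""

    assay_ids: list[str]
    assay_classes: list[str]  # "snv" / "sv" per assay
    snv_sites: list[SnvSite]
    junctions: list[BreakpointJunction]
    tree_edges: list[tuple[str, str]]
    edge_mutations: dict[tuple[str, str], list[str]]
    clone_labels: list[str]
    clone_genotypes: dict[str, np.ndarray]
    cell_ids: list[str]
    cell_clones: list[str | tuple[str, str]]
    doublet_flags: np.ndarray
    poor_assays: list[str]
    genotypes: np.ndarray  # n_cells x J, pre-noise

    @property
    def cell_labels_3way(self) -> list[str]:
        """Truth label per cell: its clone, or "doublet" for mixed chambers."""
        return [
            "doublet" if d else str(c)
            for c, d in zip(self.cell_clones, self.doublet_flags)
        ]


@dataclass
class Observations:
    """Noisy measurements derived from a Truth under a SimulationConfig."""

    config: SimulationConfig
    truth: Truth
    effective_genotypes: np.ndarray  # after ADO/FP, before count sampling
    snv_counts: pd.DataFrame  # cell_id assay_id alt_count depth
    sv_match_counts: pd.DataFrame  # cell_id assay_id n_match
    cells: pd.DataFrame  # cell_id visually_single

    def sv_counts_wide(self) -> pd.DataFrame:
        return self.sv_match_counts.pivot(
            index="cell_id", columns="assay_id", values="n_match"
        )

    def fastq_records_for_cell(self, cell_index: int) -> list[tuple[str, str]]:
        """Deterministic (read_id, sequence) list for one cell.

        Junction-bearing reads embed the 30-mer at a uniform offset in
        random flanking sequence, on a random strand; background reads are
        random sequence rejection-sampled to contain no junction on either
        strand, so the exact-match counter has zero structural false
        positives by construction.
        """
        cfg = self.config
        truth = self.truth
        rng = np.random.default_rng([cfg.seed, 2, cell_index])
        cell_id = truth.cell_ids[cell_index]
        counts = {
            r.assay_id: int(r.n_match)
            for r in self.sv_match_counts[
                self.sv_match_counts["cell_id"] == cell_id
            ].itertuples(index=False)
        }
        forbidden = []
        for j in truth.junctions:
            forbidden.append(j.junction_seq)
            forbidden.append(reverse_complement(j.junction_seq))
        records: list[tuple[str, str]] = []
        idx = 0
        L, jl = cfg.read_length, cfg.junction_len
        for junc in truth.junctions:
            for _ in range(counts.get(junc.assay_id, 0)):
                offset = int(rng.integers(0, L - jl + 1))
                flanks = "".join(rng.choice(list(_BASES), size=L - jl))
                seq = flanks[:offset] + junc.junction_seq + flanks[offset:]
                if rng.random() < 0.5:
                    seq = reverse_complement(seq)
                records.append((f"{cell_id}_r{idx}", seq))
                idx += 1
        for _ in range(cfg.background_reads):
            for _attempt in range(20):
                seq = "".join(rng.choice(list(_BASES), size=L))
                if not any(f in seq for f in forbidden):
                    break
            records.append((f"{cell_id}_r{idx}", seq))
            idx += 1
        return records

    def write(self, outdir: str, fastq: bool = True, gzip_fastq: bool = False) -> None:
        """Write the dataset as TSV manifests, counts, metadata and FASTQ."""
        from . import io as ctio

        os.makedirs(outdir, exist_ok=True)
        truth_dir = os.path.join(outdir, "truth")
        man_dir = os.path.join(outdir, "manifests")
        os.makedirs(truth_dir, exist_ok=True)
        os.makedirs(man_dir, exist_ok=True)
        ctio.write_snv_manifest(
            os.path.join(man_dir, "snv_sites.tsv"), self.truth.snv_sites
        )
        ctio.write_junction_manifest(
            os.path.join(man_dir, "junctions.tsv"), self.truth.junctions
        )
        self.snv_counts.to_csv(
            os.path.join(outdir, "counts.tsv"), sep="\t", index=False
        )
        self.cells.to_csv(os.path.join(outdir, "cells.tsv"), sep="\t", index=False)
        edges = pd.DataFrame(
            [
                (p, c, len(self.truth.edge_mutations[(p, c)]))
                for p, c in self.truth.tree_edges
            ],
            columns=["parent", "child", "n_mutations"],
        )
        edges.to_csv(os.path.join(truth_dir, "tree_edges.tsv"), sep="\t", index=False)
        labels = pd.DataFrame(
            {
                "cell_id": self.truth.cell_ids,
                "clone": [
                    "+".join(c) if isinstance(c, tuple) else c
                    for c in self.truth.cell_clones
                ],
                "doublet": self.truth.doublet_flags.astype(int),
            }
        )
        labels.to_csv(os.path.join(truth_dir, "cell_labels.tsv"), sep="\t", index=False)
        geno = pd.DataFrame(
            self.truth.genotypes,
            index=pd.Index(self.truth.cell_ids, name="cell_id"),
            columns=self.truth.assay_ids,
        )
        geno.to_csv(os.path.join(truth_dir, "genotypes.tsv"), sep="\t")
        pd.DataFrame({"assay_id": self.truth.poor_assays}).to_csv(
            os.path.join(truth_dir, "poor_assays.tsv"), sep="\t", index=False
        )
        if fastq:
            cell_dir = os.path.join(outdir, "cells")
            os.makedirs(cell_dir, exist_ok=True)
            ext = ".fastq.gz" if gzip_fastq else ".fastq"
            for i, cell_id in enumerate(self.truth.cell_ids):
                ctio.write_fastq(
                    os.path.join(cell_dir, cell_id + ext),
                    self.fastq_records_for_cell(i),
                )


def _random_snv_sites(rng: np.random.Generator, n: int) -> list[SnvSite]:
    sites = []
    for i in range(n):
        ref, alt = rng.choice(list(_BASES), size=2, replace=False)
        sites.append(
            SnvSite(
                assay_id=f"SNV_{i + 1:03d}",
                chrom=str(rng.choice(_CHROMS)),
                pos=int(rng.integers(1, 250_000_000)),
                ref_base=str(ref),
                alt_base=str(alt),
            )
        )
    return sites


def _random_junctions(
    rng: np.random.Generator, n: int, length: int
) -> list[BreakpointJunction]:
    classes = ["deletion", "insertion", "inversion", "translocation"]
    seen: set[str] = set()
    juncs = []
    for i in range(n):
        while True:
            seq = "".join(rng.choice(list(_BASES), size=length))
            rc = reverse_complement(seq)
            if seq not in seen and rc not in seen:
                seen.add(seq)
                seen.add(rc)
                break
        juncs.append(
            BreakpointJunction(
                assay_id=f"SV_{i + 1:03d}",
                junction_seq=seq,
                sv_class=str(rng.choice(classes)),
                span_kb=float(np.round(rng.uniform(0.1, 520.0), 1)),
            )
        )
    return juncs


def simulate_truth(config: SimulationConfig) -> Truth:
    """Draw a clone tree, place mutations on its edges, and label cells.

    The tree has a germline root, a trunk edge to the clones' most recent
    common ancestor, and one edge per clone (each clone attaches to the
    ancestor or to an earlier clone). Every mutation sits on exactly one
    edge (infinite sites); a clone's genotype is the union of mutations on
    its root path. With ``ancestral_sv_only`` the trunk edge carries only
    SV assays, emulating a tumor whose initiating events were structural.
    Doublet cells are unions of two distinct clones' genotypes.
    """
    rng = np.random.default_rng([config.seed, 0])
    snv_sites = _random_snv_sites(rng, config.n_snv)
    junctions = _random_junctions(rng, config.n_sv, config.junction_len)
    assay_ids = [s.assay_id for s in snv_sites] + [j.assay_id for j in junctions]
    assay_classes = ["snv"] * config.n_snv + ["sv"] * config.n_sv
    J = len(assay_ids)
    col = {a: j for j, a in enumerate(assay_ids)}

    clone_labels = [f"clone_{k + 1}" for k in range(config.k_clones)]
    edges: list[tuple[str, str]] = [("germline", "ancestor")]
    parent_of = {"ancestor": "germline"}
    for k, label in enumerate(clone_labels):
        if config.tree_shape == "random":
            choices = ["ancestor"] + clone_labels[:k]
            parent = str(rng.choice(choices))
        else:
            parent = "ancestor"
        edges.append((parent, label))
        parent_of[label] = parent

    trunk = edges[0]
    edge_mutations: dict[tuple[str, str], list[str]] = {e: [] for e in edges}
    if config.mutations_per_edge is not None:
        counts = list(config.mutations_per_edge)
        if len(counts) != len(edges) or sum(counts) != J:
            raise ValueError(
                "mutations_per_edge must give one count per edge summing to "
                f"n_snv + n_sv = {J}"
            )
        pool_sv = [j.assay_id for j in junctions]
        pool_snv = [s.assay_id for s in snv_sites]
        rng.shuffle(pool_sv)
        rng.shuffle(pool_snv)
        if config.ancestral_sv_only:
            if counts[0] > len(pool_sv):
                raise ValueError("trunk edge cannot hold more mutations than SVs")
            edge_mutations[trunk] = [pool_sv.pop() for _ in range(counts[0])]
            pool = pool_snv + pool_sv
            rng.shuffle(pool)
            for e, c in zip(edges[1:], counts[1:]):
                edge_mutations[e] = [pool.pop() for _ in range(c)]
        else:
            pool = pool_snv + pool_sv
            rng.shuffle(pool)
            for e, c in zip(edges, counts):
                edge_mutations[e] = [pool.pop() for _ in range(c)]
    else:
        for a, cls in zip(assay_ids, assay_classes):
            if config.ancestral_sv_only and cls == "snv" and len(edges) > 1:
                e = edges[1 + int(rng.integers(0, len(edges) - 1))]
            else:
                e = edges[int(rng.integers(0, len(edges)))]
            edge_mutations[e].append(a)

    clone_genotypes: dict[str, np.ndarray] = {"germline": np.zeros(J, dtype=np.int8)}
    order = ["ancestor"] + clone_labels
    for node in order:
        parent = parent_of[node]
        g = clone_genotypes[parent].copy()
        for a in edge_mutations[(parent, node)]:
            g[col[a]] = 1
        clone_genotypes[node] = g

    props = (
        np.asarray(config.clone_proportions, dtype=float)
        if config.clone_proportions is not None
        else np.full(config.k_clones, 1.0 / config.k_clones)
    )
    cell_ids = [f"cell_{i + 1:04d}" for i in range(config.n_cells)]
    cell_clones: list[str | tuple[str, str]] = []
    doublet = np.zeros(config.n_cells, dtype=bool)
    genotypes = np.zeros((config.n_cells, J), dtype=np.int8)
    for i in range(config.n_cells):
        if config.k_clones >= 2 and rng.random() < config.doublet_rate:
            a, b = rng.choice(config.k_clones, size=2, replace=False, p=props)
            pair = tuple(sorted((clone_labels[a], clone_labels[b])))
            cell_clones.append(pair)
            doublet[i] = True
            genotypes[i] = (
                clone_genotypes[pair[0]] | clone_genotypes[pair[1]]
            )
        else:
            k = int(rng.choice(config.k_clones, p=props))
            cell_clones.append(clone_labels[k])
            genotypes[i] = clone_genotypes[clone_labels[k]]

    n_poor = int(round(config.poor_assay_fraction * J))
    poor = sorted(
        str(a) for a in rng.choice(assay_ids, size=n_poor, replace=False)
    )
    return Truth(
        assay_ids,
        assay_classes,
        snv_sites,
        junctions,
        edges,
        edge_mutations,
        clone_labels,
        clone_genotypes,
        cell_ids,
        cell_clones,
        doublet,
        poor,
        genotypes,
    )


def _nb_depths(rng, mean, dispersion, size):
    # scipy/numpy parameterization: n = dispersion, p = n / (n + mean)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def simulate_observations(truth: Truth, config: SimulationConfig) -> Observations:
    """Sample noisy per-cell measurements from a Truth.

    ADO and spurious presence flip the genotype before counts are drawn:
    each present assay drops with probability ``ado_rate``, each absent one
    appears with probability ``fp_rate``. Poorly amplifying assays never
    yield signal: their SNV depth is drawn at ``poor_depth_mean`` and their
    junction reads at the absent-assay rate in every cell. SNV depth is
    negative-binomial; alt reads are binomial at ``alt_fraction`` for
    carried (heterozygous) sites and ``error_floor`` otherwise. Junction
    reads are Poisson at the present/absent means.
    """
    rng = np.random.default_rng([config.seed, 1])
    n, J = truth.genotypes.shape
    poor = np.array([a in set(truth.poor_assays) for a in truth.assay_ids])

    eff = truth.genotypes.copy()
    drop = rng.random((n, J)) < config.ado_rate
    gain = rng.random((n, J)) < config.fp_rate
    eff = np.where(truth.genotypes == 1, (~drop).astype(np.int8), gain.astype(np.int8))
    eff[:, poor] = 0

    snv_idx = [j for j, c in enumerate(truth.assay_classes) if c == "snv"]
    sv_idx = [j for j, c in enumerate(truth.assay_classes) if c == "sv"]

    snv_rows = []
    for j in snv_idx:
        aid = truth.assay_ids[j]
        mean = config.poor_depth_mean if poor[j] else config.depth_mean
        depths = _nb_depths(rng, mean, config.depth_dispersion, n)
        p_alt = np.where(
            (eff[:, j] == 1) & ~poor[j], config.alt_fraction, config.error_floor
        )
        alts = rng.binomial(depths, p_alt)
        for i in range(n):
            snv_rows.append((truth.cell_ids[i], aid, int(alts[i]), int(depths[i])))
    snv_counts = pd.DataFrame(
        snv_rows, columns=["cell_id", "assay_id", "alt_count", "depth"]
    )

    sv_rows = []
    for j in sv_idx:
        aid = truth.assay_ids[j]
        lam = np.where(
            (eff[:, j] == 1) & ~poor[j],
            config.sv_present_mean,
            config.sv_absent_mean,
        )
        matches = rng.poisson(lam)
        for i in range(n):
            sv_rows.append((truth.cell_ids[i], aid, int(matches[i])))
    sv_match_counts = pd.DataFrame(sv_rows, columns=["cell_id", "assay_id", "n_match"])

    cells = pd.DataFrame(
        {"cell_id": truth.cell_ids, "visually_single": [True] * n}
    )
    return Observations(config, truth, eff, snv_counts, sv_match_counts, cells)


def simulate_dataset(config: SimulationConfig) -> Observations:
    """Convenience wrapper: truth + observations in one call."""
    return simulate_observations(simulate_truth(config), config)


def noiseless(config: SimulationConfig, depth_mean: float = 300.0) -> SimulationConfig:
    """A copy of ``config`` with every noise process switched off.

    High, tight depth and a zero error floor, no dropout, no spurious
    calls, no doublets, no failing assays — the regime in which the
    pipeline must recover truth exactly.
    """
    return replace(
        config,
        ado_rate=0.0,
        fp_rate=0.0,
        doublet_rate=0.0,
        poor_assay_fraction=0.0,
        error_floor=0.0,
        depth_mean=depth_mean,
        depth_dispersion=20.0,
    )
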