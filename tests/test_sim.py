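"""Simulator: truth construction, noise calibration, determinism."""

import numpy as np
import pandas as pd
import pytest

import clonotrace as ct
from clonotrace.sim import SimulationConfig, simulate_dataset, simulate_truth
from clonotrace.sv import reverse_complement


def test_truth_is_deterministic_given_seed():
    cfg = SimulationConfig(seed=42, n_cells=30, n_snv=8, n_sv=6)
    t1, t2 = simulate_truth(cfg), simulate_truth(cfg)
    assert (t1.genotypes == t2.genotypes).all()
    assert t1.cell_clones == t2.cell_clones
    assert [j.junction_seq for j in t1.junctions] == [
        j.junction_seq for j in t2.junctions
    ]


def test_observations_and_reads_are_deterministic():
    cfg = SimulationConfig(seed=7, n_cells=10, n_snv=6, n_sv=4, background_reads=20)
    o1, o2 = simulate_dataset(cfg), simulate_dataset(cfg)
    pd.testing.assert_frame_equal(o1.snv_counts, o2.snv_counts)
    pd.testing.assert_frame_equal(o1.sv_match_counts, o2.sv_match_counts)
    assert o1.fastq_records_for_cell(3) == o2.fastq_records_for_cell(3)


def test_single_clone_no_doublets_shares_one_genotype():
    cfg = SimulationConfig(seed=1, n_cells=20, k_clones=1, doublet_rate=0.0)
    truth = simulate_truth(cfg)
    assert (truth.genotypes == truth.genotypes[0]).all()
    assert not truth.doublet_flags.any()


def test_every_mutation_sits_on_exactly_one_edge():
    truth = simulate_truth(SimulationConfig(seed=3, k_clones=3))
    placed = [a for muts in truth.edge_mutations.values() for a in muts]
    assert sorted(placed) == sorted(truth.assay_ids)


def test_ancestral_sv_only_keeps_snvs_off_the_trunk():
    truth = simulate_truth(SimulationConfig(seed=5, ancestral_sv_only=True))
    trunk = truth.tree_edges[0]
    assert all(a.startswith("SV") for a in truth.edge_mutations[trunk])
    # consequently every SNV presence pattern excludes the trunk: no SNV is
    # carried by every clone
    snv_cols = [j for j, c in enumerate(truth.assay_classes) if c == "snv"]
    clone_geno = np.stack([truth.clone_genotypes[c] for c in truth.clone_labels])
    assert not (clone_geno[:, snv_cols].min(axis=0) == 1).any()


def test_doublet_genotype_is_union_of_its_pair():
    truth = simulate_truth(SimulationConfig(seed=9, doublet_rate=0.5))
    assert truth.doublet_flags.any()
    for i, (clone, dbl) in enumerate(zip(truth.cell_clones, truth.doublet_flags)):
        if dbl:
            a, b = clone
            union = truth.clone_genotypes[a] | truth.clone_genotypes[b]
            assert (truth.genotypes[i] == union).all()


def test_mutations_per_edge_must_sum_to_assay_count():
    with pytest.raises(ValueError, match="mutations_per_edge"):
        simulate_truth(SimulationConfig(seed=1, mutations_per_edge=(5, 5, 5)))


def test_mutations_per_edge_is_respected():
    cfg = SimulationConfig(seed=1, n_snv=10, n_sv=8, mutations_per_edge=(6, 7, 5))
    truth = simulate_truth(cfg)
    counts = [len(truth.edge_mutations[e]) for e in truth.tree_edges]
    assert counts == [6, 7, 5]


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(ado_rate=1.5)
    with pytest.raises(ValueError):
        SimulationConfig(clone_proportions=(0.9, 0.3))
    with pytest.raises(ValueError):
        SimulationConfig(read_length=20)


def test_realized_dropout_rate_is_calibrated():
    cfg = SimulationConfig(seed=13, n_cells=500, doublet_rate=0.0,
                           poor_assay_fraction=0.0)
    truth = simulate_truth(cfg)
    obs = ct.simulate_observations(truth, cfg)
    present = truth.genotypes == 1
    n = int(present.sum())
    dropped = int((obs.effective_genotypes[present] == 0).sum())
    rate = dropped / n
    sd = np.sqrt(cfg.ado_rate * (1 - cfg.ado_rate) / n)
    assert abs(rate - cfg.ado_rate) < 3 * sd
    absent = ~present
    fp = int((obs.effective_genotypes[absent] == 1).sum()) / int(absent.sum())
    sd_fp = np.sqrt(cfg.fp_rate * (1 - cfg.fp_rate) / int(absent.sum()))
    assert abs(fp - cfg.fp_rate) < 3 * sd_fp


def test_junction_read_counts_match_poisson_mean():
    cfg = SimulationConfig(seed=17, n_cells=300, ado_rate=0.0, fp_rate=0.0,
                           doublet_rate=0.0, poor_assay_fraction=0.0)
    truth = simulate_truth(cfg)
    obs = ct.simulate_observations(truth, cfg)
    wide = obs.sv_counts_wide()
    sv_cols = [a for a, c in zip(truth.assay_ids, truth.assay_classes) if c == "sv"]
    present_vals = []
    for i, cell in enumerate(truth.cell_ids):
        for j, a in enumerate(truth.assay_ids):
            if truth.assay_classes[j] == "sv" and truth.genotypes[i, j] == 1:
                present_vals.append(wide.loc[cell, a])
    present_vals = np.array(present_vals)
    se = np.sqrt(cfg.sv_present_mean / len(present_vals))
    assert abs(present_vals.mean() - cfg.sv_present_mean) < 3 * se


def test_fastq_reads_carry_planted_junction_counts():
    cfg = SimulationConfig(seed=23, n_cells=4, n_snv=4, n_sv=3,
                           background_reads=40, sv_present_mean=20.0)
    obs = simulate_dataset(cfg)
    wide = obs.sv_counts_wide()
    for i, cell in enumerate(obs.truth.cell_ids):
        reads = [seq for _, seq in obs.fastq_records_for_cell(i)]
        for junc in obs.truth.junctions:
            fwd, rc = junc.junction_seq, reverse_complement(junc.junction_seq)
            n = sum(1 for r in reads if fwd in r or rc in r)
            assert n == wide.loc[cell, junc.assay_id]


def test_poor_assays_yield_no_signal_anywhere():
    cfg = SimulationConfig(seed=29, n_cells=60, poor_assay_fraction=0.1)
    obs = simulate_dataset(cfg)
    assert len(obs.truth.poor_assays) == round(0.1 * (cfg.n_snv + cfg.n_sv))
    assert (obs.effective_genotypes[:, [
        obs.truth.assay_ids.index(a) for a in obs.truth.poor_assays
    ]] == 0).all()
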