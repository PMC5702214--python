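# clonotrace

Single-cell genotyping of SNVs **and** structural-variant breakpoints from
targeted amplicon resequencing, followed by clonal reconstruction.

## The problem

Bulk sequencing of a tumor finds its somatic variants but cannot say which
cells carry which ones. Amplicon resequencing of whole-genome-amplified
single cells can: each bulk-confirmed SNV site becomes an amplicon, and each
structural variant (SV) is assayed through the novel junction sequence
created at its breakpoint — a 30-nt k-mer that exists only in the rearranged
genome. Because both variant classes reduce to binary presence/absence calls
per cell, SNVs and SVs become equivalent contributors to one analysis, which
lets you order classes of mutational events in the tumor's history (e.g.
structural variation preceding point mutation in a leukemia).

`clonotrace` implements the computational half of that design for people who
already have the upstream outputs (per-cell reads and per-site read counts):

1. **SV genotyping** — count reads exactly containing each junction 30-mer
   (both strands); present iff `n_match > 40`.
2. **SNV genotyping** — present iff `alt_count >= 3` and
   `alt_count / depth > 1%` (strict), with bulk concordance of the base change.
3. **QC + matrix** — keep visually-single cells with >= 80% of SNV sites at
   >= 10X; pack calls into a binary cells × mutations matrix.
4. **Clonal inference** — model rows as a mixture of multivariate Bernoulli
   distributions, `P(x_i) = Σ_k π_k Π_j θ_kj^{x_ij}(1−θ_kj)^{1−x_ij}`, fit by
   EM with restarts; the number of clusters comes from average-linkage
   hierarchical clustering (Hamming distance) with a silhouette cut. Assays
   are grouped into mutation clusters by their presence pattern across clones
   (all-ones = ancestral, all-zeros = poorly performing assays), and clusters
   whose profile is the union of two clones are flagged as doublet chambers.
5. **Tree building** — clone consensus genotypes (θ thresholded at 0.5) plus
   a germline root, connected by the minimal spanning tree under Hamming
   distance.
6. **Simulator** — generates all of the above with known truth (clone tree,
   allelic dropout, false positives, doublets, failing assays, junction-
   bearing FASTQ reads), so every stage is testable at desk scale.

## Worked example

`examples/03_simulate_and_cluster.py` simulates the realistic regime —
128 cells from two clones, 41 SNV + 36 SV assays, 10% allelic dropout, 1%
false positives, 9.6% doublet chambers, 6.3% failing assays, ancestral trunk
carrying only SVs — and reconstructs it:

```text
cells passing QC: 128 / 128
matrix: 128 cells x 77 assays
doublet clusters flagged: [2]
cluster roles: {0: 'clone', 1: 'clone', 2: 'doublet'}
ARI vs planted labels: 1.000

mutation clusters (pattern across the two clone clusters):
label
clone-0-specific    28
clone-1-specific    27
ancestral           17
poor                 5
ancestral cluster is all SV: True
```

Reading it: all 128 cells meet the coverage QC; the mixture model separates
the two clones and puts the doublet chambers in their own cluster, which the
union test flags (adjusted Rand index 1.0 against the planted labels). The
77 assays fall into four mutation clusters: two clone-specific sets, an
ancestral set present in both clones — entirely structural variants, as
planted — and a "poor" set of assays that amplified nowhere. The other
examples show junction counting (`01`), the SNV filters (`02`), and the
clone tree (`04`).

Every stage is also a shell command:

```bash
clonotrace simulate --seed 42 --outdir sim/
clonotrace run-all --snv-manifest sim/manifests/snv_sites.tsv \
    --sv-manifest sim/manifests/junctions.tsv --counts sim/counts.tsv \
    --cells sim/cells.tsv --fastq-dir sim/cells --seed 42 --outdir out/
```

`out/` then holds per-stage TSVs (calls, QC, matrix, clusters, θ, mutation
clusters, tree edge list), `tree.graphml`/`tree.dot`, `model.json`, and a
`run_manifest.json` with the config and a checksum per output.

## Layout

```
src/clonotrace/   sv, snv, qc, em, tree, sim, pipeline, io, cli
examples/         one narrative script per capability
tests/            pytest suite (unit, property, acceptance)
scripts/          acceptance.py
docs/methods.md   models, parameters, design choices, limitations
```
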