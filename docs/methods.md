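# Methods

## Genotyping model

Both variant classes are reduced to binary per-cell presence calls from
amplicon read evidence.

**SV breakpoint junctions.** An SV is represented by the 30-nt sequence
spanning its breakpoint, which does not occur in the unrearranged genome.
A read supports the SV iff it contains that k-mer as an exact substring —
no mismatches or indels, because the junction is bulk-confirmed and the
amplicon is designed across it, so true reads reproduce it verbatim.
Sequencing is unstranded, so by default a read containing the reverse
complement also counts (`both_strands`, exposed as a flag). Each read
counts at most once per junction, a read may support several junctions
(assays are independent), and duplicate reads are counted — amplicon data
is PCR-duplicated by construction, so deduplication would discard the
signal the threshold is calibrated against. The call is present iff
`n_match > min_reads` (default 40, strict), a deliberately high bar that
absorbs cross-contamination and index-hopping rather than modeling them.

**SNV sites.** The upstream aligner/caller reduces each cell × site to
`(alt_count, depth)`; the confirmation filter accepts a site iff
`alt_count >= 3` (inclusive) and `alt_count / depth > 0.01` (strict), with
`depth` = all reads at the position. When the observed alternate base is
recorded it must equal the bulk-confirmed base (location + base-change
concordance). Zero depth is absent. Both thresholds are configuration.

**Cell QC.** A cell is retained iff it was visually confirmed to be a
single cell and at least 80% (inclusive) of target *SNV* sites reached
10X depth; SV assays do not count toward coverage. Calls for retained
cells form the binary matrix; (cell, assay) pairs with no usable data are
stored as 0 — the matrix itself has no missing state — with a companion
mask so the mixture model can optionally skip them (`use_mask`, off by
default).

## Clonal inference

Rows of the matrix are modeled as a K-component mixture of multivariate
Bernoulli distributions: cluster k carries assay j with probability
θ_kj independently across assays, with mixing weights π. Fitting is EM:

- E-step in log space: γ_ik ∝ π_k Π_j θ_kj^x (1−θ_kj)^(1−x).
- M-step: π_k = mean_i γ_ik; θ_kj = (Σ_i γ_ik x_ij + a)/(Σ_i γ_ik + a + b)
  with Jeffreys pseudocounts a = b = 0.5, which keep θ off {0, 1} and all
  log-likelihoods finite.
- With the mask enabled, masked entries are omitted from both the E-step
  products and the M-step sums.

Because the smoothed M-step maximizes a MAP objective (log-likelihood plus
a Beta(1.5, 1.5) log-prior on every θ_kj), the quantity EM provably never
decreases is that penalized objective, and that is what `loglik_trace`
records; the raw data log-likelihood can dip by a fraction of a nat in
early iterations and is reported separately as `data_loglik`. Convergence
is a relative change in the objective below `tol` (default 1e-6), capped
at `max_iter` (500). Initialization is `n_restarts` (default 20) random
Dirichlet responsibility matrices plus one deterministic anchor from the
hierarchical-clustering cut — the anchor gives a reproducible good start,
the restarts guard against local optima — and the best final objective
wins. K = 1 is closed-form (smoothed column means), no iteration.

**Choosing K.** Average-linkage agglomerative clustering under Hamming
distance; the dendrogram is cut at every k in 2..k_max (default 8) and the
k with the highest mean silhouette width wins; if no cut reaches 0.1 the
population is treated as homogeneous (K = 1). Linkage, metric and cut
criterion are package choices, exposed in configuration. Note that a
concentrated doublet population is a real cell cluster and the silhouette
criterion will legitimately count it; the pipeline reports clones as the
non-doublet clusters, so the number of *clones* is read after doublet
flagging, not from K alone.

**Mutation clusters.** Each assay's θ column is thresholded at 0.5
(inclusive) over the clone clusters into a presence pattern; assays with
identical patterns form a mutation cluster. All-ones is the ancestral
cluster, all-zeros collects poorly performing assays (the post-hoc route
to poor-assay detection; a mask-fraction pre-filter in the QC module is
available but off by default, since the clustering route needs no extra
threshold).

**Doublets.** A chamber with two cells produces the union of two clones'
genotypes, so a cluster d is flagged as doublets when its θ row is within
`tolerance` (default 0.15 mean absolute deviation) of the elementwise
maximum of two other clusters' rows, and is *not* within tolerance of any
single other cluster (a duplicated clone is a K-selection issue, not a
doublet). At least three clusters are required for the union to be
expressible. Flagged clusters are excluded from the tree.

## Clone tree

Non-doublet clusters are reduced to consensus genotypes (θ >= 0.5,
inclusive at the boundary) and an all-zero germline root is appended so
the tree is rootable. The complete graph over these genotypes under
genetic distance — Hamming by default, i.e. the number of discordant
assays; Jaccard optionally — is reduced to its minimal spanning tree with
Kruskal's algorithm, ties broken lexicographically on (weight, label_a,
label_b) for determinism. Node annotations carry cell counts and the
SNV/SV composition of the consensus mutations.

## Simulator

The generator emulates a targeted single-cell study of a two-clone tumor.
Defaults are the observed regime: 128 cells, 41 SNV + 36 SV assays, two
clones in equal proportion, 9.6% doublet chambers, 6.3% failing assays,
10% allelic dropout, 1% spurious presence. Truth first: a clone tree with
a germline root, a trunk edge to the clones' most recent common ancestor,
and one edge per clone. Clones are siblings under the MRCA by default
(`tree_shape="star"`); random attachment is available, but note that an
ancestor–descendant doublet is genotypically identical to the descendant
(the union adds nothing), so planted doublets are unidentifiable in chain
topologies — the star default keeps the study conditions well-posed.
Mutations are placed on edges under infinite sites; `ancestral_sv_only`
restricts the trunk to SV assays, reproducing a tumor whose initiating
events were structural. A cell's genotype is the union of the mutations on
its clone's root path; doublets take the union of two distinct clones.

Observations: dropout and spurious presence flip the genotype before
counts are drawn (dropout acts at the allele/genotype level, which is how
MDA failure manifests). SNV depth is negative binomial with mean 100X and
dispersion 2 — realistic over-dispersed amplicon coverage; neither value
is prescribed by the study design, they were fixed once as plausible —
and alt reads are Binomial(depth, 0.5) for carried heterozygous sites
versus Binomial(depth, 0.002) otherwise, an error floor chosen so the
3-read/1% filter is discriminative at these depths. Junction reads are
Poisson(100) for carried SVs and Poisson(1) otherwise (contamination
level). Failing ("poor") assays yield background-level signal in every
cell (depth drawn at mean 2X, junction reads at the absent rate). FASTQ
generation embeds each junction at a uniform offset in random 150-nt
reads on a random strand; background reads are rejection-sampled to
contain no junction on either strand, so the exact-match counter has zero
structural false positives in synthetic data. Everything is deterministic
given (config, seed), with independent substreams for truth, counts and
reads.

What the simulator does **not** model: base-level sequencing error beyond
the error floor, chimeric amplicons and primer artifacts, locus-specific
amplification bias (dropout is i.i.d. across cells and assays), real
genomic sequence context, or copy-number-dependent allele fractions.
Passing tests therefore demonstrate correctness of the genotyping rules
and the inference machinery under calibrated noise, not robustness to
every artifact of real amplicon data.

## Numerical and degenerate-input choices

- Strictness conventions are exact and tested at the boundary: SV present
  iff n_match > 40; SNV needs alt >= 3 and VAF > 1%; QC fraction >= 0.80;
  consensus/pattern thresholding at θ >= 0.5.
- VAF denominator is total depth at the position, not ref + alt.
- Coordinates are 1-based, fully closed (VCF convention) everywhere.
- Junction manifests are validated to 30 nt by default; other lengths are
  allowed explicitly (`junction_len`), since 30 is a design choice.
- Empty clusters during EM are legal (π → 0, clipped at 1e-300 in log
  space); K > n is an error; an all-identical matrix yields K = 1.
- A single cell, an empty FASTQ, or an empty counts table degrade to
  all-absent / no-data calls rather than errors; zero QC-passing cells is
  an error, since no matrix exists.
- Test-suite study sizes (30–200 cells per replicate, 100 replicates for
  the recovery study, 30 for the acceptance script) were chosen to give
  stable rates at interactive runtimes.

## Known limitations

- The mixture model treats assays as independent within a cluster; linked
  errors (e.g. a failed chip row) will masquerade as structure.
- K selection by silhouette is a heuristic; closely related clones below
  the noise floor merge, and a large doublet population reads as a
  cluster (by design — see above).
- The doublet union test needs both parent clones present among the
  clusters; a doublet of two unobserved clones cannot be flagged.
- The MST is built over clone consensus genotypes, not cells, and depicts
  distances, not ancestry: an internal ancestor with no surviving cells
  appears only through shared trunk mutations, not as a node.
- No imputation: masked entries are zeros unless the masked EM mode is
  chosen.
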