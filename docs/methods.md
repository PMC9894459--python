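# Methods

This note documents the models and numerical conventions implemented in
`mpass`, the defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the package's known limitations.

## 1. Proteome distance

### Best hits and scoring

Protein–protein similarity is the Smith–Waterman local alignment score
under BLOSUM62 with affine gap penalties (gap open 11, extension 1, so a
gap of length k costs 11 + k). Raw scores are converted to bit scores with
gapped Karlin–Altschul parameters (λ = 0.267, K = 0.041, the standard
values for this matrix/penalty combination), and e-values use
`query_length × total_target_residues` as the effective search space. A
query whose best alignment has e-value above 10 is a **no-hit**. These are
the defaults of the BLASTP searches the distance is calibrated against;
the alignment here is exact (no heuristic seeding), which at desk scale is
affordable and strictly more sensitive. An identical sequence pair always
aligns the same way, so scores are cached on the unordered sequence pair,
and `ScoreIndex` batches an all-against-all comparison into one pass over
unique sequences.

### Normalized average dissimilarity T

Per retained query gene g: s_g = best_score/self_score clipped to [0, 1]
(0 for no-hits), d_g = 1 − s_g. Direction A→B aggregates Σ w_g d_g / Σ w_g
with w_g the gene's k-tuple coverage; T is the arithmetic mean of the two
directions. Conventions fixed here, where the method lineage leaves room:

* **T is a dissimilarity** (0 = identical proteomes). The quantity is
  usually described as an "average similarity", but the distance transform
  must grow with divergence; the per-pair log also reports the raw
  weighted similarity 1 − T.
* **Self-score normalization** of per-gene similarity, the convention of
  average-sequence-similarity phylogenomics.
* **No-hit genes contribute d_g = 1**: sample-specific gene content is
  informative, and two metagenomes sharing no genes reach the maximal
  finite distance S(1) rather than an undefined one.
* **Symmetrization** is the arithmetic mean of the two directed averages.
* **Weight normalization is per direction**, so scaling one sample's
  coverages by any positive constant leaves T unchanged (sequencing depth
  is not a biological signal).

### Distance transform and calibration

S = const1·e^(const2·T), in percent Poisson-corrected 16S-equivalent
substitution rate; defaults const1 = 4.142, const2 = 2.824, a fixed
calibration against reference organisms spanning bacteria, archaea and
eukaryotes. Note S(0) = const1 > 0: the
transform has a floor at T = 0. The distance-matrix diagonal is stored as
0 (tree construction requires zero self-distance); the floor is a property
of the calibration, logged per pair rather than subtracted. Poisson
correction: S1′ = 1 − matched/(aln_len − gapped), S2′ = −ln(1 − S1′)·100;
S2′ is undefined when nothing aligns (error).

`estimate_constants` refits (const1, const2) from (T, S2′) points by
least squares on log S2′ — the model is exactly linear there — optionally
refined by nonlinear least squares on the original scale (default on; the
two agree for well-behaved data and the nonlinear step reduces the bias
that log-scale fitting gives large-S2′ points). Non-positive S2′ values
cannot enter the log fit and are excluded with a warning. Either
orientation of the regression can be computed by swapping the point
coordinates; the implemented orientation treats S2′ as the response.

## 2. Trees

`nj_tree` is the standard Saitou–Nei algorithm. Determinism: ties in the
Q-criterion are resolved toward the lexicographically smallest pair of
subtree labels (each subtree keyed by its smallest leaf). Negative branch
length estimates are clamped to 0. The result is unrooted; the root object
is the trifurcation left by the final join, and nothing downstream depends
on its position. On additive matrices NJ is consistent: the generating
topology is recovered exactly and branch lengths to numerical precision
(verified against 200 random trees in the test suite).

Newick serialization and the tree container are scikit-bio's `TreeNode`;
`read_newick` adds a pre-parse parenthesis check so malformed input
reports the offending character position. Bipartitions are computed on the
unrooted topology, canonicalized as the side not containing the smallest
leaf label, trivial splits excluded; the Robinson–Foulds symmetric
difference is the size of the symmetric set difference, with
multifurcating trees compared as-is (no forced binary resolution).
Weighted RF and bootstrap support are out of scope.

## 3. Environmental dendrograms

Each environmental variable is clustered separately: samples are points on
the real line, distance |x_i − x_j|, agglomerative clustering with
average (UPGMA; default), single, or complete linkage. How the original
analysis built its dendrograms is not specified anywhere we could follow,
so single-variable agglomerative clustering is this package's convention:
it is deterministic, standard, and invariant under positive affine
transforms of the variable (so units do not matter). Exact merge-height
ties are collapsed into polytopies instead of being resolved arbitrarily —
otherwise the symmetric difference between a tied dendrogram and the
metagenomic tree would count resolution artifacts. Samples with missing
values are dropped with a warning (fewer than 4 left is an error); a
constant column yields a star dendrogram with a warning by default.
`rank_env_parameters` reports one row per column, sorted by ascending
symmetric difference, ties alphabetical.

## 4. Synthetic communities

The generator reproduces the two benchmark designs used to validate the
method, at a scale that runs on one CPU in seconds.

**Genomes.** `make_genomes` builds n = 5 genomes of ~50 kb, each packing
~100 non-overlapping forward-strand ORFs (ATG…TAA, ≥ 100 translated
residues, 20–100 nt intergenic spacers). All species carry homologs of one
base gene set, independently mutated at 0.7 amino-acid substitutions per
site with codons re-drawn per species. The default divergence is chosen so
between-species best hits sit in the remote-homology regime: the genomes
stand in for species from different phyla, and a gene absent from a sample
should not be silently replaced by a strong cross-species hit. (At the
20–30% divergence typical of congeneric species, cross-species hits are
strong, and the test suite covers that regime separately.)

**Abundance vectors.** The three base vectors are
(0.297, 0.507, 0.116, 0.058, 0.022), (0.345, 0.244, 0.281, 0.088, 0.042)
and (0.526, 0.320, 0.042, 0.066, 0.046) — the benchmark's printed study
conditions, not tunables. `convergent_vectors` moves components above the
vector mean down and below it up, 5% per step compounded, renormalizing,
for 10 steps per group (30 samples, three groups, each drifting toward a
uniform community while retaining its ordering); a single-perturbation
±5% variant is available behind `cumulative=False`. The benchmark's prose
admits both readings; the cumulative one is normative here because the
deep-branching of the most-changed samples depends on it.
`gaussian_vectors` perturbs each component c by +|N(0, c)|/5 — noise
standard deviation equal to the component value, then scaled by one fifth;
the sentence defining it also admits |N(0, c/5)|, and this reading is
fixed here — renormalizing, 10 replicates per base vector.

**Reads.** `sample_reads` draws multinomial read counts per species
(probability ∝ abundance × genome length), uniform start positions,
random strand, flat per-base substitution errors. It stands in for an
empirical-error read simulator; quality-score modelling beyond flat
scores is out of scope.

**Recovered proteomes.** Two routes from a community to a `Proteome`:

* `community_proteome` — the assembly-free ideal: every ORF translated,
  coverage = abundance × scale, all records complete. Deterministic;
  zero-abundance species contribute nothing. Note that with strictly
  positive abundances two such proteomes contain identical sequences and
  their T is exactly 0 regardless of weights — abundance alone is
  invisible to the distance when gene recovery is perfect.
* `sequenced_proteome` — the sequencing-aware surrogate used by the
  benchmark: gene g of species s gets k-tuple coverage
  abundance_s × depth × efficiency_g and is lost when that falls below
  `min_coverage` (default depth 20, min 2). Per-gene efficiencies (set in
  `make_genomes`) follow a right-skewed density ∝ 1/c² on [1/6, 6], taken
  as exact quantiles in shuffled gene order: real per-gene assembly
  coverage varies around the genome average with a heavy tail of
  hard-to-assemble genes, and using representative quantiles makes each
  species' recovered-gene fraction a smooth deterministic function of its
  abundance rather than a ~100-gene random staircase. This is the route by
  which community composition reaches the distance in a real run (rare
  species assemble incompletely first); the defaults place the five base
  abundances across the sensitive range of that retention curve, as the
  original read-level simulation's depth did. `stochastic=True` adds
  Poisson noise to the realized coverages (seeded).

What the simulator does **not** emulate: chimeric contigs and strain
mixing, fragmented genes surviving as partials (recovery here is
all-or-nothing per gene), GC- or position-dependent read bias, real codon
usage, and paralogy within a genome. Passing the simulation benchmarks
therefore demonstrates that the pipeline propagates composition and
divergence signal correctly — not that any particular real dataset will
cluster cleanly.

## 5. Per-gene conservation traces

For a focal sample, the `top_n` (default 1000) highest-coverage proteins
(ties by id) are each searched against every other sample; the per-gene
distance is S_g = const1·e^(const2·d_g) with d_g the gene's own best-hit
dissimilarity — the proteome formula without averaging. Genes with no hit
get S(1). Each gene's profile across samples is correlated (Pearson) with
the patristic distance from the focal leaf: "branch length in the tree" is
read as patristic distance, the only per-sample scalar a per-sample
vector can be correlated against. Genes with r above 0.7 are flagged
tree-concordant; zero-variance profiles are excluded (r undefined). The
default d_g uses score ratios; an e-value mode (d_g from the capped
−log10 e-value of the best hit relative to the self-hit) is provided for
comparison but is non-normative — no published formula exists for it.
Downstream annotation of selected genes is out of scope; the matrix is
exported as TSV for external heatmap tools.

## 6. Pipeline and preprocessing

Read-level steps mirror standard practice: optional trimming to a fixed
length (5′ prefix kept; no default trimming — whether to trim is
chemistry-dependent and exposed as a flag), then seeded uniform
down-sampling of every sample to the smallest read count. Assembly and
gene calling are external by design; the pipeline invokes them only
through a declared command hook and is fully runnable from proteome FASTA
input. Protein filtering removes partial genes (missing start or stop,
read from header metadata — the gene caller, not this package, knows the
codons) and proteins shorter than 100 residues (strict <, so 100 is
kept). Header dialects cover assembler-style contig names
(`..._cov_8.31`), gene-caller `partial=XY` flags, and a native
`id|cov=…|complete` format; permissive parsing defaults unknown headers
to coverage 1 and complete, strict mode refuses them. All stages log
counts and parameters to a JSON run manifest; one seed drives all
randomness, so reruns are byte-identical.

## 7. Problem sizes used in the checks

The clade-recovery benchmark runs the full 30-sample design with 5
species × ~97 genes (~485 unique proteins, one exact all-against-all
alignment pass); NJ and Robinson–Foulds oracles use 200 random trees of
4–12 leaves; constant recovery uses 60 noiseless and 90 noisy points; the
gene-trace check uses 12 samples × 60 genes with 20 permutation controls.
These sizes keep the full suite under a minute of alignment work while
leaving each check's signal far from its threshold.

## 8. Known limitations

* The coverage-weighting convention (weights = k-tuple coverage,
  normalized per direction) is one reasonable reading of a procedure whose
  exact published form is in supplementary material not reproduced here;
  it is fixed and documented rather than configurable.
* The Karlin–Altschul parameters are constants for BLOSUM62/11/1; other
  scoring schemes reuse them as approximations, so e-values under
  non-default matrices are indicative only.
* S saturates at S(1) = const1·e^const2 ≈ 69.8: metagenomes beyond "no
  shared genes" cannot be distinguished, and branch lengths near the
  saturation regime compress.
* NJ is O(n³) in samples and the alignment pass O(genes²) in unique
  sequences; hundreds of samples or multi-Mb proteomes call for an
  external search engine behind the hit-table interface, which is left as
  an integration point (`HitTable` is engine-agnostic).
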