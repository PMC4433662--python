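# Methods

## Pipeline model and assumptions

The pipeline assumes a matched two-platform case/control design: one
pre-normalised gene expression matrix and one miRNA expression matrix over
the same samples (log-scale values are expected but not enforced), a
case/control label per sample, a multi-source miRNA→target evidence table,
and a list of gene identifiers annotated as transcription factors.
Identifier matching is exact string match after whitespace stripping;
probe collapsing, normalisation and symbol mapping are deliberately left
to upstream tooling. Rows with missing values are dropped rather than
imputed — with ~7 samples per group there is no basis for imputation.

### Differential calling

Two-sided pooled-variance Student's *t*-test per feature, raw *p* < 0.05
(strict), no multiple-testing correction by default. Rationale: at n = 7
vs 7 the pooled test is the textbook choice and the downstream stages use
the DEG set only inside enrichment tests, which are themselves
thresholded; Welch's test (`welch=True`) and Benjamini–Hochberg
(`correction="bh"`) are available for sensitivity analyses. A feature with
zero variance in both groups is reported as (t = 0, p = 1) when the means
agree and (t = ±inf, p = 0) otherwise, flagged `degenerate`, so batch runs
never abort.

### Coexpression network

Built on case samples only: the modules of interest are disease-state
coexpression structure. All measured genes are candidates (not only DEGs),
because the later enrichment filter needs non-DEGs in the universe to be
meaningful. An edge requires r > 0 *and* two-sided *p* < 0.05 from the
exact t transform of the correlation; the positive-only rule keeps all
edge weights nonnegative, which the cohesiveness objective requires
(`positive_only=False` admits |r| weights, with the signed r kept as an
attribute). For n = 7 case samples the implied critical correlation is
r ≈ 0.7545; with ~2.5% of null pairs passing, background edges are a real
feature of this design, not an artefact (see *Limitations*).

### Module detection

Cohesiveness of a node set V:

    f(V) = w_in / (w_in + w_bound + penalty * |V|)

with `penalty` modelling unobserved edges. Growth starts from each seed
(nodes in degree-descending order, ties by id, skipping nodes already
inside a kept module) and repeatedly applies the single best move — adding
a boundary node or removing a member — that strictly increases f, with
ties broken by smallest gene id and removals that would disconnect the
cluster disallowed. The result is a connected local optimum of f; an
exhaustive single-move check in the test suite verifies this on random
graphs. Note a singleton has f = 0, so a seed with any positive-weight
edge always absorbs at least one neighbour; undersized clusters are
discarded by `min_size` rather than returned as singletons.

Defaults (`penalty=2`, `min_size=3`, `min_density=0.3`,
`merge_overlap_omega=0.8`) follow the published defaults of the
cohesiveness-based clustering family; all are exposed in
`DetectionParams`. Genes of a cluster that fails the size/density filters
remain eligible as seeds — marking them covered was observed to let one
sprawling low-density cluster swallow a genuine module and then vanish.

Two merge passes follow: transitive unioning of kept clusters with match
coefficient ω(A,B) = |A∩B|²/(|A||B|) ≥ 0.8 (part of detection), then a
separate post-hoc pass merging any pair where the overlap exceeds one
third of the smaller module — iterated to a fixed point, largest overlap
fraction first (ties: larger combined size, then smallest member id).
The exact-one-third boundary does **not** merge. Merged modules get their
cohesiveness recomputed but are not re-grown.

### Enrichment and regulators

Enrichment p-values are exact hypergeometric upper tails
P(X ≥ k) computed via `scipy.stats.hypergeom.sf`; the universe for both
the DEG filter and miRNA-target enrichment is the coexpression-network
node set (modules live there; query sets are intersected with it).
Significance is strict *p* < α, with α ≥ 1 read as "filter disabled" so
the boundary configuration behaves as a no-op.

The consensus target map keeps a miRNA–gene pair supported by ≥ 2
prediction sources or an experimental flag; source names are opaque
strings, so any tool set works. Only differentially expressed miRNAs are
ever tested as regulators. A TF regulates a module when it is a member
with at least one within-module edge (`min_module_edges`, configurable);
since module members of a coexpression network almost always have
internal edges, this criterion is close to membership itself — it is kept
explicit and tunable rather than silently vacuous.

### Anticorrelation

Computed across all matched samples (cases + controls) by default: the
repression signature — miRNA up, targets down — expresses itself across
the cohort, and using both groups doubles the sample size at n = 7 + 7. A
cases-only option exists. The per-miRNA summary is the **median**
correlation over in-module targets (mean available), chosen for
robustness at tiny n.

## Synthetic data

Each planted module m follows a single-latent-factor model: member genes
are x = noise_sd·(λ·F_m + √(1−λ²)·ε) + baseline with F_m a per-sample
standard normal factor, so two members correlate at λ² in population and
the implied covariance is positive definite by construction. The module's
planted repressor miRNA loads with ρ < 0 on the same factor, giving a
population miRNA–target correlation of λ·ρ. Module genes are shifted
−3σ in cases and repressor miRNAs +3σ (the repressive narrative:
regulator up, targets down); a configurable 5% of background features
receives a ±3σ shift of random sign. Target evidence is drawn per source
with sensitivity 0.8 on true pairs and false-positive rate 0.01 on
non-pairs; experimentally validated rows appear under a curated-database
source name at rate 0.1 on true pairs. All randomness flows from the
single `seed`.

Default dimensions — 1,000 genes, 60 miRNAs, two 25-gene modules, 7 + 7
samples — were sized so a full pipeline run takes seconds on one CPU
while keeping the background-edge regime of a genome-scale matrix at
n = 7. The default loading λ = 0.98 (member correlation 0.96) is chosen
against the n = 7 critical correlation of 0.754: with 7 samples the
*realised* spread of a latent factor varies a lot, and weaker loadings
let a module's observed correlations fall below the edge threshold in an
appreciable fraction of cohorts. ρ = −0.82 puts the population
miRNA–target correlation at λ·ρ ≈ −0.80. The 3σ differential shift gives
the 7-vs-7 *t*-test ≈ 0.995 power per feature, so planted structure is
limited by the network stages, not by differential calling.

What the generator does **not** emulate: platform artefacts, probe
effects, heteroscedastic or heavy-tailed noise, correlated backgrounds,
batch structure, or miRNAs targeting multiple modules. Passing tests
demonstrate that the algorithmic chain recovers the structure it is
specified to recover under a clean factor model — not that real cohorts
of this size yield stable modules.

### Recovery scoring

Planted modules are scored by best-match Jaccard. Regulator
precision/recall matches an inferred module to the planted module it
*covers* best (fraction of planted genes contained, threshold 0.5) rather
than by Jaccard: at n = 7 the detected modules legitimately absorb
background genes whose small-sample profiles align with the module factor,
which dilutes Jaccard (typically to 0.3–0.6 at the default scale) without
impairing regulator identification. This absorption also mirrors the
module sizes reported in small-cohort studies of this kind and is the
main reason module boundaries from 7 samples should be read as cores plus
a halo, not exact gene lists.

## Numerical and determinism choices

* Greedy moves must improve f by more than 1e-12 (guards float cycling);
  cohesiveness is recomputed from the edge list for every returned module.
* Every stage is deterministic: sorted seed orders, sorted edge insertion,
  explicit tie-breaks, `%.12g` floats in TSVs, sorted JSON keys, and a
  timestamp-free log format, so identical configs give byte-identical
  output trees.
* GraphML round-trips weights at full repr precision.
* Correlation p-values use the exact t transform; |r| = 1 maps to p = 0.

## Limitations

* With 7 samples per group, ~2.5% of null gene pairs pass the edge
  threshold; module detection is therefore run on a graph with a dense
  random background, and detected modules carry a halo of background
  genes. Enrichment filtering, not module membership, is the reliable
  signal at this design size.
* The raw-p thresholds perform no multiple-testing control;
  the BH option exists but changes the stage-count narrative.
* Merged modules are not re-optimised after the one-third merge; their
  cohesiveness is bookkeeping, not an optimality claim.
* The TF criterion is correlational membership, not binding evidence.
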