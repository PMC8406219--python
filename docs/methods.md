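# Methods

`cprhab` reimplements, as a tested pipeline, a comparative-genomics workflow
for studying habitat transitions in three lineages of Candidate Phyla
Radiation (CPR) bacteria — Absconditabacteria, Gracilibacteria, and
Saccharibacteria — which occur in both environmental and animal-associated
microbiomes and are presumed episymbionts of other bacteria. The pipeline
consumes genome metadata, protein-family membership tables, ANI matrices,
marker-protein sequences, per-sample detection tables, and species trees; it
does not perform assembly, binning, gene prediction, read mapping, protein
clustering, or probabilistic reconciliation, all of which belong to external
tools whose outputs are its inputs.

## Genome quality control and dereplication

Completeness and contamination are estimated from a 43-gene single-copy
marker inventory appropriate for CPR bacteria (many universal markers are
genuinely absent in these lineages): completeness = 100·markers_present/43,
duplication = 100·markers_duplicated/43. The marker-derived estimate is
always recomputed from the counts, never taken from an input column, so
synthetic and real inputs follow the same code path. Genomes pass QC at
completeness ≥ 70% and duplication ≤ 10% (both bounds inclusive).

Dereplication at 99% ANI consumes an externally computed ANI matrix and uses
a greedy, deterministic procedure: genomes are visited best-first by the
score completeness − 5·duplication (ties: larger ORF count, then
lexicographic genome id); each genome joins the first already-chosen
representative at ANI ≥ threshold, else founds a new cluster. The external
dereplication tool this mirrors does not document its internal scoring, so
this explicit score is a stand-in chosen for reproducibility; every cluster
member is guaranteed ≥ threshold ANI to its representative, but members of
one cluster are not guaranteed mutually above threshold (true of any greedy
centroid scheme).

Genomes qualify for concatenated ribosomal-protein phylogenetics when at
least 8 of the 16 syntenic ribosomal proteins are present.

## Protein-family profiles

A protein family enters the analysis when it has ≥ 5 member *sequences*
(not genomes); per-genome copy number collapses to binary presence. The
consensus annotation of a family is the modal label among annotated members,
with the supporting fraction computed over **all** members (annotated or
not); the alternative convention (fraction over annotated members only)
would inflate support for sparsely annotated families. Annotation ties break
to the lexicographically smallest label.

Proteome similarity between genomes is the Jaccard distance on family
presence, ordinated by classical PCoA (Gower double-centering +
eigendecomposition). Because Jaccard distances are generally non-Euclidean,
negative eigenvalues can appear; variance fractions are computed over the
sum of **positive** eigenvalues only, with the negative total reported
separately, so the convention behind "axis 1 explains x%" is explicit.
Family modules are exposed by average-linkage hierarchical clustering of the
family columns under the same Jaccard metric (the combination used by
clustered heat-map tools); equal-distance merges follow scipy's
deterministic nearest-neighbor-chain order rather than a hand-rolled
lexicographic rule — the library's ordering is deterministic, which is what
matters for reproducibility.

## Enrichment and depletion

For each lineage independently, and for each (family, habitat) pair, the
in-group is the lineage's genomes from that habitat and the out-group its
genomes from all other habitats. The fold-enrichment ratio is
(k_in/n_in)/(k_out/n_out); families absent from the out-group but present in
the in-group are flagged EXCLUSIVE (infinite ratio), and families absent on
both sides are uninformative and omitted. Significance is a two-sided Fisher
exact test; all of a lineage's comparisons are corrected jointly by
Benjamini–Hochberg step-up FDR (pooling per lineage, not per habitat,
prevents unevenly sampled habitats from distorting each other's correction).
Classifications at q ≤ 0.05: **enriched** when ratio ≥ 5 or exclusive
(exclusive families still require significance — with a tiny in-group a
single exclusive carrier is not evidence); **depleted** when the in-fraction
is ≤ 0.10 and the out-fraction ≥ 0.50. The depletion boundary is implemented
inclusively (≤ 10%); a strict `<` reading exists and differs only for
families sitting exactly on the boundary. A family may be enriched in one
habitat and depleted in another; summaries count unique families per
lineage × habitat and overall.

The Fisher p-value sums hypergeometric probabilities of all tables sharing
the observed margins whose probability does not exceed the observed
table's. Up to a total of 10,000 observations the enumeration uses exact
integer weights C(n_in,a)·C(n_out,k−a), so probability ties are decided
exactly; beyond that a log-space fallback applies a 1e-7 relative tie
tolerance. BH q-values are the textbook step-up `min_{j≥i} m·p(j)/j`,
capped at 1, order-preserving.

## Co-occurrence analyses

Marker (rpS3-scale) protein sequences are clustered into species groups at
≥ 99% global identity by a greedy, length-sorted, first-fit procedure
(ties in length break by sequence id): deterministic and
input-order-invariant. Identity comes from a Needleman–Wunsch alignment
with match +1, mismatch −1, linear gap −1, and free terminal gaps;
identity = matches / alignment length counting internal gaps, with terminal
overhangs excluded. When several alignments tie on score the traceback is
made canonical by ordering the two sequences lexicographically, which keeps
identity symmetric. External clustering tools pin none of these choices
across versions, so the package pins its own.

Per-sample analyses: the **richness ratio** divides the count of distinct
symbiont species groups by the count of candidate-host groups, and is
UNDEFINED (excluded from ratio tables, flagged for absence analysis) when
the denominator lineage is undetected. **Exclusive co-occurrence** labels a
sample `exclusive-species` when exactly one symbiont group co-occurs with
exactly one host group, and `exclusive-order` when one symbiont group
co-occurs with ≥ 2 host groups that all share one known order-level label.
**Coverage profiles** sum member mean coverages per order (falling back to
the lowest available rank, with an explicit unknown label) after dropping
detections whose covered fraction is below 0.10; values are divided by the
smallest positive entry of the whole matrix and log10-transformed, mapping
the minimum to 0. Profile correlations are plain Pearson r with constant
profiles excluded and flagged. **Relative abundance** is stringently mapped
reads (≥ 99% identity) over total quality-filtered reads; genomes with
covered fraction < 0.10 are called absent regardless of mapped counts;
sequencing runs exceeding 100 million read pairs are flagged for
subsampling to 36 million reads; the representative sample per genome is
the argmax of abundance (ties: lexicographically smallest sample id). The
presence floor applies to the abundance and coverage-profile paths, not to
the detection-based co-occurrence path, which mirrors the two distinct
procedures being emulated.

## Gene flux

Reconciliation event tables carry real-valued expected counts per (family,
branch, event type), averaged over reconciliation samples; they are summed
without rounding. Transfers whose donor lies outside the designated ingroup
(an explicit leaf partition supplied with the tree, never inferred) are
recounted as **originations** — lateral transfer from outside the studied
lineages or de novo evolution. Terminal branches are excluded from the
per-branch summary but retained in a side table, and duplications pass
through separately, so total weight is conserved.

As a desk-scale verifiable stand-in for probabilistic reconciliation, the
package reconstructs each family's gain/loss history by two-state Sankoff
parsimony with asymmetric costs (default gain 2 : loss 1 — acquisitions are
rarer than losses in reduced genomes). The root is treated as ancestrally
absent, so a root-present labeling pays one gain on the root branch. Among
equal-cost labelings the reconstruction prefers fewer gains (tracked as a
lexicographic secondary objective in the DP), with remaining ties resolved
deterministically toward absence in a preorder sweep. Optimality is
verified against exhaustive enumeration of all internal labelings on trees
with ≤ 12 leaves. In parsimony-derived flux tables every gain is reported
as an origination and transfers as 0: without gene trees, transfer cannot
be distinguished from origination.

## Synthetic data and planted truth

The generators define the study conditions for all tests; one global seed
derives an independent substream per stage, so any stage can be rerun in
isolation byte-identically.

* **Genome sets**: per (lineage, habitat) group, true family content is
  Bernoulli — p_in for a planted family's own group, p_out for other
  genomes of its lineage, baseline 0.10 otherwise. Observed content, the
  43-marker inventory, and the rp16 inventory are all thinned by the same
  per-genome completeness draw (default U(0.7, 1.0)), coupling gene dropout
  to the completeness estimate the way real incomplete assemblies behave.
  Power and error-control checks use 40 in-group vs 200 out-group genomes
  with p_in = 0.6, p_out = 0.05 and 200 planted among 2,000 families, and a
  null design of 240 genomes with no habitat effect.
* **Communities**: host groups occur independently (p = 0.5); each symbiont
  is linked to one host and occurs with coupling probability 0.9 when its
  host is present, leak probability 0.05 otherwise; coverages are
  log-normal, covered fractions uniform.
* **Marker sequences**: random 20-letter centroids whose pairwise
  divergence is guaranteed ≥ the configured between-group divergence (5%)
  by mutating disjoint position blocks; members carry a **fixed**
  round(d·L) number of point substitutions (d = 0.5% within-group) rather
  than a binomial draw, so planted partitions are recoverable exactly —
  a binomial tail would occasionally push a member below the 99% identity
  threshold and make exact-recovery tests flaky for reasons unrelated to
  the clustering logic.
* **Gene content**: presence evolves root-to-leaves with at most one event
  per branch (gain probability 1−exp(−g·t) when absent, loss probability
  1−exp(−l·t) when present); a planted mode places exactly one gain per
  family on a random internal branch for homoplasy-free tests.

What the generators do **not** emulate: assembly artifacts, chimeric bins,
annotation errors correlated across families, phylogenetic autocorrelation
of gene content within habitats (genomes are exchangeable within groups),
compositional coupling between coverage and detection, and realistic ANI
structure (the synthetic ANI matrix has planted near-duplicate pairs on a
uniform background). Tests passing on these data therefore demonstrate the
correctness of the statistics and algorithms under the declared model, not
robustness to real-world artifacts.

## Numerical and design choices

* Fisher: exact integer arithmetic to n = 10,000; log-space with 1e-7
  relative tie tolerance beyond.
* PCoA: eigenvalues below max(1e-12, 1e-10·λ_max) are treated as zero;
  variance denominators use positive eigenvalues only.
* Dereplication and clustering tie-breaks are fixed and documented above.
* Pipeline determinism: every output carries a header with the config hash
  and seed; rerunning the same config is byte-identical (the run log
  contains no timestamps).
* In the pipeline's families stage, genomes with no family at all in the
  filtered matrix are excluded from the ordination (they have no defined
  Jaccard distance to anything); the library-level PCoA still raises on
  such genomes so the contract stays visible to direct callers.
* Default problem sizes (240-genome enrichment designs, 20/10-seed
  replicate counts, 12-leaf trees for exhaustive parsimony checks) were
  chosen so the planted effects are comfortably detectable while exhaustive
  oracles remain feasible.

## Known limitations

Greedy dereplication and greedy species-group clustering are order-dependent
heuristics (deterministic here, but not globally optimal partitions).
Parsimony flux underestimates transfer by construction. The enrichment
engine conditions on observed presence and does not model completeness as a
covariate; the completeness-thinning in the generator shows the resulting
power loss is acceptable at the default design, but heavily incomplete
genome sets will bias in-fractions downward on both sides of the ratio.
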