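# Methods

`phageflux` analyses homologous recombination in a set of co-linear
prophage genomes at two levels: genome-wide genetic flux between phage
populations, and per-gene recombination intensity.  This note documents
the models, the defaults and the design choices, and what the synthetic
data do and do not establish.

## Haplotype-copying model (chromosome painting)

Each genome in turn is the *recipient*; all other genomes form the
leave-one-out *donor* panel of size *k*.  Working on the biallelic core
SNPs (columns with no gaps or ambiguity codes in any sample), the hidden
state at SNP *l* is the donor currently being copied:

* initial distribution uniform `1/k`;
* between SNPs at alignment distance `d` the chain switches with
  probability `1 − exp(−λ d)` (`switch_scale` λ, per bp) and, conditional
  on a switch, picks the new donor uniformly — including the current one,
  the usual Li–Stephens simplification that keeps transitions closed-form;
* the recipient allele matches the copied donor's allele with probability
  `1 − θ_e` (`miscopy` θ_e).

Scaled forward–backward gives the per-site copy posterior and two
expectations per donor:

* **chunk counts** — expected number of maximal copied segments, counted
  as the initial-state posterior plus expected switch-*into* events
  (`P(state_l ≠ d, state_{l+1} = d)`), so self-switches never inflate
  counts; and
* **copied lengths** — posterior mass summed over SNPs.

Defaults (overridable): `miscopy = θ_w / (θ_w + 2k)` with
`θ_w = 1/Σ_{m<k} 1/m`, clipped to (1e-4, 0.49); `switch_scale` set so the
expected number of switches across the painted span is of order 10.  No
EM refinement is run: a single fixed-parameter pass is deterministic and
sufficient for chunk bookkeeping.

**Counts versus lengths.**  The co-ancestry matrix defaults to chunk
counts ("number of fragments", the quantity displayed in co-ancestry
heatmaps).  Count *shares*, however, are not a consistent estimator of the
genome fraction donated by a population: a segment copied from a group of
near-interchangeable donors is posterior-split across the group, and
switch events are allocated in proportion to group size, so count shares
drift toward larger donor populations.  Copied-length shares do not have
this panel-size effect (verified in the flux-recovery test, where length
shares recover a planted 25 % migrant fraction essentially unbiased while
count shares overshoot).  Flux *fraction* analyses therefore use
`coancestry(..., statistic="lengths")`; clustering uses the count matrix.

## Co-ancestry clustering

Individuals are clustered on the co-ancestry matrix by a conjugate
Dirichlet-multinomial model.  For recipient *r* and donor clusters
*b = 1..B* with aggregated counts `x_rb` (`n_r = Σ_b x_rb`), the score of a
partition is the log-probability of the full donor-resolved row, i.e. the
product of

1. the Dirichlet-multinomial marginal of the cluster aggregate
   (symmetric hyperparameter β, default 1), *including* its multinomial
   normalization `n_r!/Π_b x_rb!`, and
2. a uniform-multinomial spread of each aggregate over the cluster's
   donors (the recipient is excluded from its own cluster's donor count),

summed over recipients, with real-valued expected counts handled through
the continuous Γ extension.  The normalization and spread factors matter:
the aggregate-only marginal is maximal (exactly zero) for the one-cluster
partition on any data, because aggregation can only discard information —
only the full-row probability rewards splitting rows that differ.  Exact
numerical agreement with the original fineSTRUCTURE implementation is not
claimed; no "c" correction factor is applied by default (a scalar divisor
on the matrix is exposed in configuration by dividing X beforehand).

The sampler is Metropolis–Hastings over partitions with two move
families: reassigning one uniformly chosen individual to a uniformly
chosen cluster (including a fresh singleton), and merging two random
clusters / splitting one by a uniform random bipartition, each with the
exact Hastings correction.  Defaults are 100 000 burn-in plus 100 000
sampling iterations (the protocol used for the real data); validation
chains run scaled down at 5 000 + 5 000, which recovers planted 3 × 8
block structure in ≥ 18/20 seeds.  The highest-scoring partition visited
is kept as the MAP.  The merge tree greedily joins the cluster pair whose
merge loses the least score until one cluster remains (ties broken on the
lexicographically smallest label pair), serialized as Newick.

## Genetic flux

For recipient *r*, the fraction attributed to donor population *P* is
`Σ_{d∈P, d≠r} X[r,d] / Σ_{d≠r} X[r,d]`.  The denominator includes the
recipient's own population, so fractions over all donor populations sum
to one per recipient; an "other-populations-only" denominator is exposed
as an option.  Import views fix the recipient populations, export views
fix the donor populations — both are slices of the same per-recipient
table, and medians are taken over recipient × donor-population pairs.
Group contrasts use the two-sided Wilcoxon rank-sum test: exact null
distribution whenever `n1 + n2 ≤ 20` with no ties, otherwise a normal
approximation with tie and continuity corrections.

## Pan-genome

Genes are compared by best local protein alignment (BLOSUM62, gap open
−11 / extend −1) with percent identity normalized by the shorter sequence
— the blastp convention.  Clusters are connected components of the graph
thresholded at identity *i*, swept over 40–90 % with and without
paralogue splitting.  Component clustering deliberately replaces the
reference CD-HIT + BLAST + MCL stack: the analysis is a threshold sweep,
and components preserve its monotone structure (pan size is non-
decreasing in *i*) with far less machinery.  Paralogue splitting without
synteny information re-clusters any cluster holding two or more genes
from one genome by single linkage at `i + 10` (capped at 95), which
separates same-genome fragments while leaving orthologues together.
Categories: core = present in 100 % of genomes, soft-core ≥ 90 % (and
< 100 %), singleton = exactly one genome, shell otherwise.

Apparent paralogues in these phages are typically one gene interrupted by
an internal stop codon plus re-start, annotated as two fragments.  The
interrupted-gene screen concatenates same-genome co-members and aligns
the concatenation end-to-end against each single-copy member; identity
≥ 80 % normalized by the *longer* sequence flags fragments (a genuine
duplication doubles the concatenated length and cannot pass).  Nucleotide
CDSs are required to confirm reading frames; without them the screen is
skipped with a notice.

## Gene-level recombination

Gap-containing columns are removed first (complete deletion), matching
the convention of gene-level recombination toolboxes; multiallelic sites
are excluded from pairing.  Two biallelic sites are incompatible when all
four gametic types occur (the four-gamete test).  R_min is the
Hudson–Kaplan bound: all incompatible pairs become open intervals, and a
right-endpoint greedy scan keeps a maximal set of pairwise disjoint
intervals — provably the optimum for interval families, and verified
against an exhaustive minimum-breakpoint search on random instances.
Breakpoints are reported half-open in 0-based gap-filtered coordinates.

Per gene, nucleotide diversity π (mean pairwise difference per
gap-filtered site), the gap-filtered length L, and `y = R_min / L` feed
the regression `y_i = β0 + β1 π_i + β2 n_i + ε_i` with *n* the number of
aligned sequences, fit by OLS.  `R_min/L` uses the gap-filtered L — "per
gene length" is otherwise ambiguous — and the choice is configurable.
The residual ε_i, standardized by the residual SD, scores each gene's
recombination intensity after controlling for diversity; |z| > 2 flags
deviating genes.  If the design is rank deficient (constant *n*) the β2
term is dropped with a warning.

## Synthetic data

The simulator is a *mosaic-copying* generative model, not a coalescent:
K founder sequences diverge independently from a random ancestor at
`divergence` substitutions/site; each genome is a concatenation of
geometric segments (mean `mean_segment`, default 1 kb — short, frequent
imports in the style of highly recombinogenic *H. pylori* elements, which
also gives each genome enough segments for stable per-genome fractions),
each copied from a founder drawn from the genome's migration row, with
`mutation_rate` private noise added.  Defaults mirror the real panel:
four populations of 4, 12, 7 and 6 genomes and ~28 kb genomes.  This
matches the copying HMM's own assumptions, which is the point: flux
recovery becomes a clean parameter-recovery experiment.  It omits real
features — indels and alignment error, insertion sequences, selection,
shared ancestry within populations beyond a single founder — so passing
tests demonstrate correctness of the inference machinery, not robustness
to real-data artifacts.

The emitted ground truth includes the migration matrix, each genome's
realized founder fractions, and the *expected attributed flux*: the
migration matrix propagated through the donor-panel composition, since a
donor from any population may itself carry migrant material at a site and
share the attribution, `flux[a,b] = Σ_f M[a,f] · n_b' M[b,f] / Σ_c n_c'
M[c,f]` with leave-one-out sizes `n'`.  The two-population recovery
experiment uses pop sizes (5, 15) — a small recipient population facing a
large donor pool, as with the four hpEastAsia phages against the rest of
the panel — keeping that panel correction small (expected attribution
≈ 0.235 for a planted 0.25).

Gene families for the pan-genome are simulated by mutating an ancestral
protein independently per genome at a per-copy divergence of
`1 − sqrt(identity/100)`, so realized pairwise identity lands within a
few points of target at length ≥ 200; the interrupted-gene artifact emits
one carrier's copy as 5′/3′ fragments whose CDS carries an internal stop
and re-start.  Recombining gene alignments mix two divergent parents at
planted crossover positions, guaranteeing `R_min ≤ crossovers`.

All generators are byte-reproducible from their seeds.

## Numerical choices and limitations

* Forward–backward uses per-site scaling; outputs are finite for SNP
  tracks up to at least 1e5 sites.
* Major-allele coding breaks frequency ties toward the alphabetically
  first residue; coordinates are 0-based half-open internally.
* Duplicate genomes are detected by exact string identity of the aligned
  sequence; the first occurrence is retained.
* MCMC split proposals enumerate bipartitions via `2^m` terms — fine for
  the intended tens of genomes, not for thousands.
* The painting assumes gap-free, co-linear, pre-aligned genomes; running
  an aligner, phasing and imputation are out of scope.
* Pan-genome clustering is O(genes²) in alignments; intended for phage
  gene counts (tens to hundreds), not bacterial pan-genomes.
* Scaled-down problem sizes used in the validation suite (50 kb genomes,
  5 000 + 5 000 MCMC iterations, 12-site oracle instances) were chosen to
  keep each property demonstrable in seconds to minutes; all are package
  defaults or test parameters, not limits of the implementation.
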