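# Methods

## The Bernoulli product model for gene presence/absence

Observed presence of gene *i* in genome *j* is modeled as Bernoulli with
probability *p*<sub>i</sub>·*q*<sub>j</sub>: the gene's true frequency in
the species times the genome's gene recovery rate, assumed independent.
The two vectors are estimated jointly by maximizing

LL(X, p, q) = Σᵢⱼ xᵢⱼ log(pᵢqⱼ) + (1 − xᵢⱼ) log(1 − pᵢqⱼ)

with L-BFGS-B, box bounds [10⁻⁸, 1 − 10⁻⁸] on every variable, exact
analytic gradients

∂LL/∂pₖ = Σⱼ xₖⱼ/pₖ − (1 − xₖⱼ)qⱼ/(1 − pₖqⱼ),  and symmetrically for qₖ,

initial values *q* = 0.99 for every genome and *p* = the observed gene
frequencies.  Estimation is restricted to genes with observed frequency
above a floor (default 10%); rarer genes keep their observed frequency,
flagged `estimated = False`.  Such genes can never reach the core
threshold, so the exclusion is inert downstream.  Defaults: convergence
tolerance 10⁻⁹ on the relative log-likelihood change, iteration cap
15,000.  The fit is deterministic, and the final log-likelihood is
guaranteed not to fall below its value at the initialization point.

**Identifiability.** Only the products *p*<sub>i</sub>*q*<sub>j</sub> are
identifiable: scaling *p* by c and *q* by 1/c leaves the likelihood
unchanged wherever both stay in bounds.  Initializing every *q* at 0.99
pins the scale in practice (real collections contain near-complete
assemblies).  Tests therefore compare optimizers on the product matrix
*p q*ᵀ, and compare *p̂*, *q̂* to simulated truth only when the true
maximum *q* is close to 1.

**Core calling.** The species core genome is the set of genes with
*p̂* strictly greater than 0.9999.  A sharpness caveat: for a gene whose
true frequency is exactly 1, the likelihood score at the boundary has
expectation zero (absences arrive at rate 1 − qⱼ but each absence in a
genome with recovery q contributes −q/(1 − q) to the score, and
E[(1 − q)·q/(1 − q)] = q cancels the presence term), so with a few hundred
genomes a minority of true-core genes receive interior estimates around
0.96–0.999 and fall below the strict threshold.  Interior estimates
approach 1 as O(1/n), so the 0.9999 cut is designed for collections of
thousands of genomes; at desk-scale n the call is near-perfectly precise
(accessory genes are never called core) but not perfectly sensitive.
Recall at n = 200 is typically 0.75–0.9.

## Frequency-distribution fits

For benchmarking, per-gene frequencies are discretized into right-closed
bins of width 1/n (a frequency of exactly 1 falls in the last bin), the
histogram is restricted by the caller to frequencies above 0.9 (candidate
core genes), and a closed-form count model is fit: P(x) = k·x⁻ᵃ + c
(power; a > 1) or P(x) = k·e⁻ᵃˣ + c (exponential).  Following the
cumulative-fitting procedure, the model is fit not to P directly but to
the cumulative count F(x) (genes with frequency ≤ x), obtained from the
model by discrete summation over the bin grid; the observed F is scaled to
maximum 1 before least squares (initial guesses (1, 1, 2) for the power
model, (1, 1, 1) for the exponential; all parameters positive).  Because
of that scaling the linear parameters k and c are recovered up to division
by the total count, while the shape parameter a is scale-free.  Fitted
parameters are applied directly to P(x) and quality is reported as R² and
mean absolute error against the identically scaled counts.  Fewer than
four non-empty bins, or an optimizer failure, yields a flagged result
rather than an exception.

## Genome quality filtering

Four criteria, evaluated in a single pass against cohort statistics
computed over each species' full input cohort (no iterative refiltering):
contamination strictly < 10%, completeness strictly > 80%, contig count
≤ 3× the species median, assembly length within 3 population standard
deviations of the species mean.  A species qualifies with ≥ 50 passing
genomes (configurable; synthetic tests use smaller cohorts).  The contig
rule is an upper bound only — fewer contigs than the median is better, not
suspect.  For a single-genome species the length criterion is vacuous and
the genome is flagged `length_sd_undefined`.  Even-sized cohorts use the
mean of the two central values as the median.

## Species-tree extraction

Each species is represented in the genome-level phylogeny by the MRCA of
its genomes.  If that MRCA contains foreign leaves, every node of the tree
is scanned and the representative is the node maximizing the harmonic mean
of completeness (fraction of the species' genomes under the node) and
purity (fraction of the node's leaves belonging to the species); ties
break toward the root, then by node ID.  The exhaustive scan is a
deterministic superset of scanning the MRCA's children.  Each
representative's terminal branch is its original branch plus the median
node-to-leaf path distance to the species' genomes (measured from the
representative node itself).  Lineages not ancestral to a representative
are pruned and unary nodes collapsed by summing branch lengths; the result
is strictly binary, preserves path-length additivity between
representatives, and is a fixed point of the procedure (extracting species
from a species tree is the identity).  Nested representatives are an
error, reported with the offending pair.

## Ancestral reconstruction

Each orthogroup is a binary character on the species tree.  Ancestral
states minimize total event cost with gain (0→1) costing g and loss (1→0)
costing 1 — the single parameter g is literally the gain/loss penalty
ratio.  Branch lengths are ignored: Wagner parsimony counts events.  The
bottom-up dynamic program and top-down traceback resolve **every cost tie
toward absence**, which makes the root state a strict threshold in g: for
the three-leaf pattern (1,1,0) on ((A,B),C), root-present costs one loss
(1) and root-absent one gain (g), so the root flips to present only for
g > 1 — at the default grid, min_g = 1.05, not 1.0.  The sweep runs over
g ∈ {0.1, 0.15, …, 2.0}; root presence is verified monotone non-decreasing
in g for every orthogroup (a violation raises, since min_g would be
ill-defined), so ancestral cores are nested across the grid.  Orthogroups
absent from every species are reported with min_g = "never" rather than
dropped.  The DP is vectorized across orthogroups; an exhaustive
enumeration oracle (≤ 11 internal nodes) backs the tests.

## KEGG module evaluation

Module definition strings are parsed as boolean expressions with
precedence (high → low): parentheses, `-` (optional component), `+`
(AND/complex), `,` (OR), space.  Top-level spaces separate sequential
steps; inside parentheses a space joins subexpressions as AND, following
KEGG's informal convention.  Optional (`-`) components never affect
activity.  A step is active when its expression is satisfied by the
present KO set; a module is active when at least one step is, and
completeness is the fraction of active steps.  Multi-enzyme (`+`)
reactions require all non-optional components.  Parse errors report the
offending position.  Orthogroups map to KOs by the modal KO among their
annotated sequences, ties to the lexicographically smallest ID.

## Synthetic data

The generators produce every input with recorded ground truth, one
deterministic stream per operation derived from (seed, operation name):

- **Pangenome matrices**: entries Bernoulli(pᵢqⱼ).  The default frequency
  sampler puts a fraction f_core = 0.5 of genes at p = 1 and the rest
  Uniform(0.1, 1), mirroring the U-shaped frequency distributions of real
  pangenomes, in which roughly half the genes above the 10% estimation
  floor are core.  Default recovery sampler Uniform(0.9, 1).
- **QC metadata**: completeness = 100·q + clipped Gaussian noise (default
  SD 2 percentage points) — a linear link, chosen because the relation to
  marker-based completeness is reported only as a correlation; other
  fields are drawn from configured ranges.
- **Gene-content evolution**: along each branch of length t, present
  orthogroups are lost with probability 1 − e^(−loss·t) and absent pool
  members gained with probability 1 − e^(−gain·t), at most one event per
  branch and orthogroup.  This per-branch birth–death process is a test
  harness for the reconstruction, not a claim about how real gene content
  evolves.
- **Genome trees**: random sequential-join species topologies with
  exponential branch lengths, each species expanded into a clade of its
  genomes; a `scramble` fraction of genomes is regrafted elsewhere to
  emulate misplaced assemblies and exercise the non-monophyletic path.
- **Protein families**: ancestral random sequences with i.i.d. per-site
  substitutions (default 5%), for the greedy-clustering stand-in.

What the synthetic data does **not** emulate: linkage between genes,
phylogenetic correlation of recovery rates, horizontal transfer,
paralogy, or annotation noise.  Passing tests demonstrate correctness of
the algorithms under the model's own assumptions, not robustness to every
failure mode of real assemblies.

## Pipeline and determinism

The demo workflow (simulate → filter → estimate → call cores →
species tree → ancestral sweep → summaries) runs from one YAML
configuration whose defaults are the production values (10% / 80% / 3× /
3 SD / 50 genomes; floor 0.10; q₀ = 0.99; core 0.9999; grid 0.1–2.0 step
0.05).  Unknown configuration keys fail validation before any stage runs.
Every stage writes TSV/JSON outputs and a SHA-256 manifest; reruns with
the same configuration and seed are bit-identical, and the worker-thread
setting never changes results.  The demo sizes (tests use 6 species × 30
genomes; the default configuration 12 × 60, 120-orthogroup pool) were
chosen so a full run completes in seconds while every stage still has
non-trivial work.

## Clustering stand-in

Production pangenomes should come from CD-HIT (or any clusterer) via the
`.clstr` adapter.  The built-in greedy clusterer exists so the whole
pipeline is testable from sequences: length-descending greedy assignment
to the first cluster whose representative aligns at ≥ 80% identity
(exact matches / alignment columns, global alignment) over ≥ 80% of the
shorter sequence.  It reproduces the partition of well-separated families
but does not reproduce CD-HIT's word filters, tie behavior, or speed, and
should not be used for biological conclusions at scale.

## Known limitations

- Joint MLE recovers products pqᵀ; the p/q split rests on the q ≈ 1
  anchor, and the strict 0.9999 core threshold under-calls true cores at
  small n (see the sharpness caveat above).
- Wagner parsimony's tie and cost conventions are declared here
  (loss = 1, gain = g, ties → absent, lengths ignored); other
  implementations may break ties differently and shift min_g by one grid
  step.
- The KEGG grammar is a pragmatic reconstruction of an informally
  specified syntax; exotic constructs (nested optional complexes, `--`
  gaps) are out of scope.
- The curated, manual verification of missing reactions in metabolic
  reconstructions is not automatable and is out of scope.
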