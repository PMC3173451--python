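# Methods

This note documents the models, algorithms and design decisions behind
`mitoscreen`, in the order the pipeline runs them, followed by the synthetic
data model and known limitations.

## Staged homology filter

Hit tables are inputs; the package never executes a similarity search. A hit
record carries query, subject, E-value, bitscore and the best single HSP's
coverage of the *query* length (HSPs are not chained or tiled). The filter
stages are:

- **Seed assignment.** A seed protein is assigned to the ortholog group of
  its best hit among hits with E-value < `evalue_max` (10⁻¹⁰) and coverage
  > `seed_overlap_min` (0.50). "Best" is resolved by bitscore by default,
  with E-value and then subject id as tie-breaks; the ordering is
  configurable (`best_hit_order="evalue"`) because either convention is
  common in practice.
- **Environmental retrieval.** An environmental sequence becomes a candidate
  if at least one hit against the seed passes the same two thresholds.
- **Reciprocal confirmation.** A candidate is retained only if its *top*
  qualifying hit against the reference ortholog database (coverage
  > `reciprocal_overlap_min` = 0.70) belongs to the expected group. This is
  the paralog/distant-homolog guard.
- **Per-species deduplication** keeps the best-scoring member per species.
- **Dataset gate.** Only markers with strictly more than 500 first-search
  candidates proceed; smaller pools cannot support a diversity screen.

All three numeric thresholds are **strict** inequalities; the simulator
plants records at exactly 10⁻¹⁰, 0.50 and 0.70 so the tests pin that
behaviour down.

Alignment cleaning is a transparent gap-fraction column mask (drop columns
with gap fraction > 0.5 by default) that reports the kept-column index map,
so a block-based external masker can be substituted without touching
downstream code.

## Marker selection

**Coherence.** A marker tree is coherent when (a) the mitochondrial
sequences form one clade and (b) the reference and mitochondrial sequences
*jointly* form one clade against the outgroup. The joint reading of (b) is
deliberate: the mitochondrial lineage branches inside the alphaproteobacterial
radiation (sister to the Rickettsiales in coherent trees), so demanding an
alpha clade that excludes mitochondria would be unsatisfiable on exactly the
trees the screen is built for; what the criterion must catch is outgroup
intrusion and alpha sequences stranded outside the radiation — signatures of
horizontal transfer or systematic error. On unrooted trees monophyly means
presence of the corresponding bipartition.

**Order resolution.** Markers carried into the neighbour screen must
additionally recover every reference order as a clade on the reference tree.
A marker that cannot resolve the deep backbone cannot place a divergent
environmental lineage relative to the mitochondrial clade, so screening it
produces noise; this mirrors the practice of choosing screen markers for
their resolution of the deep divergences.

**Composition bias.** Genomes with AT-rich DNA are enriched in amino acids
from AT-rich codon families and depleted in those from GC-rich families. The
diagnostic computes, per taxon, the frequencies f_AT of the FYMINK set and
f_GC of the GARP set (gaps and ambiguity codes excluded from the
denominator) and reports the max−min spread across taxa. The amino-acid sets
are configurable; FYMINK/GARP is the established convention. A spread above
0.05 ("a few percent") flags the marker as bias-prone; the threshold is a
reporting default, not a hard filter.

## Diversity pruning

Faith's PD of a leaf subset is the branch-length sum of the minimal spanning
subtree, in the unrooted convention by default (only branches on paths
*between* subset members count); a `rooted_pd` flag includes the path to the
root. Greedy selection starts from the two leaves with the longest path
between them (or from a `must_keep` set, typically the reference taxa) and
repeatedly adds the leaf with the largest PD increment, implemented as a
multi-source sweep over the undirected tree (O(nk) total). Ties break
lexicographically, making selection deterministic. On trees the greedy
algorithm attains the exact optimum (Steel/Pardi); the test suite asserts
this by exhaustive enumeration over random trees. With a non-empty
`must_keep` the optimality guarantee applies only to the unconstrained
remainder. The default budget of 150 reflects what downstream Bayesian
analysis can digest; the guide tree defaults to the built-in NJ tree over
the candidate pool.

## Tree toolkit

- **Newick I/O**: hand-written parser reporting the character offset of any
  syntax error; internal node labels are preserved as support annotations
  (numeric when parseable) and never affect topology semantics; missing
  branch lengths default to 0.
- **Distances**: `p` (mismatch fraction, pairwise gap deletion), `poisson`
  (−ln(1−p)), and `jc20` (−ln(1 − 20p/19)), the 20-state Jukes–Cantor-type
  correction. `jc20` is the default backend's model: the Poisson correction
  compresses deep divergences (it ignores the 1/20 chance that a
  substitution restores the observed state), which in practice drags long
  isolated branches toward the outgroup — precisely the placement the screen
  cares about. Near-saturated pairs are capped at 7 substitutions/site
  instead of diverging.
- **Neighbor joining**: Saitou–Nei with deterministic tie-breaking
  (lexicographically smallest pair of cluster names) and negative estimated
  branch lengths clamped to zero. Exact recovery from additive matrices is
  part of the acceptance suite; an independent NJ implementation (dendropy)
  serves as a cross-check oracle in the tests, never as the implementation.
- **Rooting** bisects the branch separating a (bipartition-forming) outgroup
  from the rest; total branch length and all leaf-to-leaf path lengths are
  conserved exactly.
- **Tree samples**: majority-rule consensus after discarding a burn-in
  fraction (default 25 %) keeps exactly the splits with frequency > 0.5,
  annotated with that frequency; consensus branch lengths are not
  summarised. The max-diff statistic is the maximum absolute
  split-frequency difference between two samples, with ≤ 0.3 as the
  conventional convergence verdict.

## Jack-knife neighbour screen

Per replicate, `sample_size` (default 100) pool members are drawn uniformly
**with replacement** (so the sample may exceed the pool), the sampled
sequences are combined with the full reference alignment, a tree is inferred
by the configured backend and rooted with the outgroup. If the outgroup is
not recovered as a split in a replicate, rooting falls back to the first
outgroup member's pendant branch; a replicate whose inference fails outright
is skipped and counted, and more than 10 % failures abort the screen.

**Affiliation rule.** With `INSIDE_ONLY`, the flags are the environmental
leaves descending from the MRCA of the mitochondrial sequences. The default
`INSIDE_PLUS_SISTER` walks rootward from that MRCA and absorbs environmental
leaves from successive sister clades under three rules: a sister with no
reference or outgroup leaves is always absorbed; sisters whose reference
leaves all belong to one and the same order — the local sister group of the
mitochondrial clade, possibly recovered paraphyletically — are absorbed as
long as that order does not change; the first sister spanning two or more
orders ends the local neighbourhood, after which only purely environmental
sisters are absorbed ("deeply diverging" lineages that single-gene trees
place below the whole reference radiation), and any outgroup-containing
sister stops the walk. Under a polytomy the sister is the union of the
siblings. The sister group is thus included through topology alone, never by
naming it.

**Reproducibility filter.** A sequence enters the flagged set when it was
extracted in at least `min_flag_count` replicates (default 1) **and** in at
least `min_flag_rate` of the replicates that sampled it (default 0.5). The
majority-of-replicates rule is the screen's point: a placement that appears
once in many replicate trees is estimation noise, not affiliation. Flag
counts never exceed sampling counts, and results are bit-identical under a
fixed seed and backend.

**Coverage.** The probability that a given pool member is never drawn in
`r` replicates of `m` draws is (1 − 1/N)^{mr}; the closed form is validated
against Monte Carlo in the acceptance suite. At N = 1040, m = r = 100 it is
≈ 6.6 × 10⁻⁵.

**Scaffold concatenation.** Scaffolds carrying at least one flagged sequence
and more than one gene are concatenated in a fixed (alphabetical) marker
order, gap-filling markers a scaffold lacks; reference taxa are concatenated
in the same order, and 1-based inclusive partition boundaries are reported.
A scaffold listing the same marker twice raises a paralogy error.

## Clade assignment and abundance

Each environmental leaf takes the order of the strict majority of reference
leaves in the smallest clade containing the leaf and at least one reference
leaf; ties yield UNCLASSIFIED, which is kept first-class so percentages
never silently re-normalise. Clade fractions are percentages of *assigned*
leaves and sum to 100. Collapsed-clade summaries report (l, n): within-clade
branch length (stem excluded) and environmental leaf count. Rare-clade
fractions round to one decimal at the reporting layer only. The
overall-abundance product (clade percentage × assumed alphaproteobacterial
cell fraction, default 0.325) equates sequence fractions with cell
fractions and ignores copy number, genome size and sequencing depth — it is
an order-of-magnitude statement, nothing more.

## Synthetic data model

The generator emulates the statistical structure the analysis assumes, with
full truth labels:

- **Tree.** A rooted binary organism tree: six order-like reference clades
  (28 reference taxa by default), mitochondria (5 taxa) sister to the
  Rickettsiales-like order, a planted clade attached to their common stem
  with a fixed stem length (0.3 substitutions/site), and a 2-taxon outgroup
  across the root. Environmental organisms are additional leaves nested
  inside their order's clade. Within-clade branch lengths are exponential
  with mean 0.06; order stems and backbone internodes use mean 0.25 — the
  orders emulated are anciently diverged lineages whose long stems carry the
  deep signal, and without them no marker would resolve the backbone that
  the real marker-selection step demonstrably selects for.
- **Environmental pool.** `env_pool_size` (default 1000) gene sequences are
  drawn organism-wise from the order profile (SAR11-like 0.825,
  Rhodobacterales 0.093, Rhodospirillales 0.074, Rhizobiales 0.006,
  Rickettsiales 0.002 — the published survey proportions as a default, not
  an assertion), one 1–3-gene scaffold per organism over the five default
  markers. The planted clade adds `planted_fraction × env_pool_size`
  (default 20) further sequences spread over `planted_clade_size` (6)
  organism lineages, which may own several scaffolds.
- **Sequences.** A jump process: along a branch of length t, each site
  jumps with probability 1 − e^(−t) and redraws its residue from the
  governing stationary vector (uniform over 20 residues globally). Expected
  identity at path distance d is e^(−d) + (1 − e^(−d)) Σπ², which the tests
  verify at long sequence length. Lineages designated AT-biased (SAR11-like,
  Rickettsiales-like, mitochondria, planted) shift their stationary vector
  toward the FYMINK set with strength s; the default is s = 0 so that the
  baseline pool is compositionally neutral and bias is an explicit
  experimental dial. Alignments are gapless — indel evolution is out of
  scope and real data arrives pre-aligned.
- **Hit tables** are generated from truth (the filters, not the search, are
  under study): true orthologs receive comfortable same-group hits, decoy
  paralogs (at `decoy_rate`) receive cross-group top hits, and every
  emission contains boundary records at exactly 10⁻¹⁰, 0.50 and 0.70.
- **Determinism.** Every generation step draws from its own seed-derived
  substream, so outputs are byte-identical under a seed and individual
  operations reproduce the orchestrated run.

**What passing tests do and do not show.** The generator produces gapless,
equal-length, full-length sequences under a homogeneous-rate jump model with
clean truth labels; real environmental data adds fragmentary sequences,
alignment error, rate heterogeneity across sites and lineages, chimeric
assemblies and annotation noise. Recovery results on the simulator bound
what the pipeline can do under its own assumptions; they do not certify
performance on real surveys, where the inference backend (an external ML or
Bayesian engine can be registered) and the reproducibility thresholds do
more work.

## Problem sizes in the test and acceptance runs

The default generator (pool 1000, five markers, 500 residues) with 20
replicates per marker and three seeds keeps a full screen under a minute on
one CPU; the brute-force oracles run on 100–200 random trees of up to 12–20
leaves and 10⁶-trial Monte Carlo for the coverage formula. These sizes were
chosen to make the whole suite convenient to run locally while keeping every
estimate's standard error far below the tested margins.

## Known limitations

- The built-in backend is distance-based; deep, short internodes that ML or
  Bayesian methods might resolve can defeat NJ, which is why marker gating
  (coherence + order resolution) precedes the screen.
- The affiliation rule is topological and label-free but heuristic at the
  edges: a reference order nested incorrectly by the backend can open or
  close the neighbourhood wrongly in individual replicates; the
  majority-of-replicates filter, not the single-tree rule, carries the
  error control.
- Multiple HSPs per hit are not merged; coverage is the best single HSP's.
- The consensus tree carries support values only, no summarised branch
  lengths.
- The abundance product is a first-order approximation by construction.
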