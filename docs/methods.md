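# Methods

This note records the models, parameter choices, numerical conventions and
known limitations of the package, in the spirit of a methods appendix.

## Distances

K2P distances distinguish transition (`P`) and transversion (`Q`)
proportions over *compared sites* — positions where both sequences carry an
unambiguous A/C/G/T. Everything else (gaps, `N`, IUPAC ambiguity codes) is
removed pair by pair (pairwise deletion). Two guard rails keep estimates
honest:

- **Site floor** (default 100 compared sites, configurable): below it a
  pair is *missing*, never zero. Short overlaps otherwise produce wild
  estimates.
- **Saturation**: when `1 - 2P - Q <= 0` or `1 - 2Q <= 0` the log-distance
  is undefined; the pair is missing and the offending `P, Q` are carried in
  the error. Missing pairs are excluded from histograms, summaries and
  quantiles, with logged counts; tree building refuses incomplete
  submatrices rather than imputing.

Distances are stored as proportions; report columns multiply by 100
("% K2P", two decimals in as-published columns, four internally).

Among-species comparisons are restricted to congeners (no cross-genus
pairs), and the "lowest 5% of among-species variation" threshold is the
type-7 (linear-interpolation) quantile of the pooled among-congener
distances. Pooling across genera is a documented choice; a per-genus
variant would be straightforward but is not offered, since the survey
decision rules consume a single global threshold.

## Trees

The built-in tree method is Saitou–Nei neighbor-joining. It is implemented
in-package rather than delegated so that the advertised determinism
guarantee holds exactly: ties in the Q-criterion are broken by the lowest
(row, column) pair of the current working matrix, and negative branch
lengths are clamped to zero with a count kept on the tree. An independent
NJ implementation (scikit-bio) serves as a cross-check in the test suite.
Maximum-likelihood inference is deliberately out of scope; an externally
built newick tree can be supplied anywhere a tree is consumed and is the
fidelity path for users with ML machinery.

Bootstrap support resamples alignment columns with replacement under a
seeded generator, rebuilds NJ per replicate, and annotates each internal
bipartition of the point tree with its replicate frequency × 100.
Replicates in which some pair saturates are skipped (support is then a
frequency over successful replicates); if any single pair fails in more
than half the replicates the run errors, recommending subsetting.

Monophyly on unrooted trees is bipartition-based: a tip set is
monophyletic iff some edge separates it exactly from its complement (a set
whose complement is a single tip is therefore monophyletic). On rooted
trees, iff some node subtends exactly the set. Intruders are reported from
the smallest side/clade containing the target. Singleton and whole-tree
targets are "trivial" and count as monophyletic for decision rules.

## The reciprocal-monophyly test

The null is the uniform distribution over *labeled coalescent histories*
(sequences of pairwise merges), the "random branching" model. The dynamic
programme

    P(i, j) = [C(i,2) P(i-1,j) + C(j,2) P(i,j-1)] / C(i+j,2),  P(1,1) = 1

tracks the probability that all merges are within-group until each group
reaches one lineage. Arithmetic is exact (`fractions.Fraction`) up to a
total sample of 40, floating point beyond (the recursion is numerically
benign, but exactness is what makes the published-value and closed-form
checks meaningful). A brute-force enumerator walks every labeled history
(their number is ∏ C(k,2), so it is capped at 10 tips) and is used as the
oracle: recursion and enumeration agree exactly for every split of up to
8 tips, and `p(a,1) = 2/(a(a+1))` holds for a ≤ 30. Yule- or
uniform-topology nulls are not offered.

The test is applied to a species and its *sister*, defined operationally as
the congener at minimum inter-specific distance (ties broken
alphabetically), and only when both are monophyletic or trivial on the
tree — consistent with testing *reciprocal* monophyly.

## Delimitation conventions

- "Clusters with minimum pairwise distances higher than 1.5%" is
  operationalized as **single-linkage** components of the `d ≤ 1.5%` graph.
  Single linkage makes the between-cluster minimum guarantee literally
  true (every between-cluster minimum exceeds the threshold) and is the
  reading under which the stated cluster properties are theorems.
- "Sharing barcodes" has no standard numeric definition; the package
  triggers on either zero distance at the compared sites or mutual
  non-monophyly with interdigitated tips, and reports both flags
  separately.
- Rule (c)'s two triggers — intraspecific spread reaching the among-species
  5% quantile, and a sister closer than 1% K2P — are combined with OR by
  default (`rule_c_mode="and"` is available), and each trigger is flagged
  in the assessment.
- Singletons cannot fail the monophyly rule but can still share barcodes or
  fail rule (c); this mirrors how surveys list species sampled once.
- Category IV requires both ≥ 2 clusters above threshold and
  non-monophyly; monophyletic deep species are routed to the
  deep-divergence table instead.
- All thresholds (1.5% cluster, 1% sister, 5% quantile, α = 0.05) are
  config keys with these defaults.

## Geographic patterns

Area membership is declarative: a locality → area-code TSV (plus optional
explicit per-specimen codes, which win) over a controlled vocabulary of
Amazonian/Atlantic-Forest areas of endemism and neighbouring ecoregions.
No point-in-polygon computation is attempted. For the area-pair table,
clusters are recomputed at a separate report threshold (default 1.0%),
since surveys in practice tabulate some sub-1.5% splits; multi-area
clusters credit all their areas (cross-product rule), and the per-pair
range is the min/max K2P over specimen pairs from the two areas in
different clusters. Ranking is species count descending, ties alphabetical
— a total order, so outputs are deterministic.

## The simulator

`simgen` generates surveys under an isolation model: per-population
coalescent (pair rate `1/(2 N_e)`, times in generations), optional
two-population splits within species, and species joins either
simultaneous (scalar split time — a star radiation) or laddered (a list of
n−1 nondecreasing join times — a caterpillar). There is no migration,
recombination, rate heterogeneity or indel process; alignments are
gap-free by construction. Mutations follow the continuous-time K2P process
with transition/transversion rate ratio `kappa`, applied per site with the
closed-form branch transition probabilities; the root sequence is uniform
random under the same seed.

Defaults state a realistic congeneric panel: `2 mu t = 10%` between species
(among-congener distances concentrate in the 5–15% band typical of bird
COI), `theta = 4 N_e mu = 0.5%` within populations (most within-species
distances below 1%), 700 bp sequences (the usual COI barcode fragment),
and `kappa = 5` (a moderate avian mtDNA transition bias). Matching the
mutation model to the distance estimator is deliberate: the isolation-model
expectation `2 mu t + 4 N_e mu` is then the exact target for
estimator-consistency tests. What a green synthetic test does *not*
establish: robustness to alignment error, ambiguity codes, rate variation
among sites or lineages, or migration — real surveys contain all four.
msprime is used in the test suite as an independent check of genealogy
depths, never as the generator.

`populations_per_species` accepts a per-species list as well as a single
value so that a survey can contain exactly one internally structured
species — the recovery benchmark requires it.

## Numerical and determinism notes

- Every stochastic component (simulator, bootstrap) takes an explicit seed
  and uses its own `numpy` generator; identical inputs + config + seeds
  give byte-identical report files, and the run manifest (config, seeds,
  version, input checksums, drop counts) suffices to reproduce a run.
- K2P of identical sequences returns exactly `+0.0` (the `-0.0` from the
  log form is normalized away).
- NJ tie-breaking and cluster labelling (size-descending, then smallest
  member id) are fixed so that table ordering never depends on dict or
  hash order.

## Limitations

- No ML/Bayesian tree inference, model selection, or divergence dating.
- No formal model-based delimitation (GMYC, bPTP, BPP) and no
  character-based diagnostics; the package implements the distance/
  monophyly decision battery only.
- No multiple-testing correction across species for the
  reciprocal-monophyly test (surveys conventionally report raw p-values).
- The sharing and sister definitions are operational conventions; with
  very sparse sampling they can differ from expert judgement.
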