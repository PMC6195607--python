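# Methods

This note documents the models and procedures implemented in `redqueen`,
the choices made where the underlying descriptions left gaps, and what the
synthetic data used by the test-suite does and does not establish.

## 1. The coevolution model

Hosts are diploid for a single MHC-like locus.  An allele is a point on a
bounded integer grid (default 1000 x 1000) representing the physicochemical
binding properties of its molecule (its paratope); a parasite genotype is a
point on the same grid (its epitope).  Recognition is a Gaussian kernel of
the Euclidean distance d between paratope and epitope,

    P(recognition) = exp(-d^2 / (2 s^2)),

with kernel width `recognition_scale` s in grid units.  Only monotone decay
with distance is prescribed by the verbal model; the Gaussian form and its
width are this package's choices (see calibration below).

Each generation proceeds as:

1. **Parasite mutation** — each genotype is displaced, with probability
   `parasite_mut_rate`, by an isotropic Gaussian step (sd
   `mutation_step_scale`, default 10 grid units, rounded to the grid and
   reflected at the boundary).
2. **Seeding** — `seeding_fraction` of each parasite pool (default 1%) is
   replaced by genotypes drawn uniformly at random on the grid.  With the
   default pool of 10,000 this is exactly 100 entirely new, typically very
   divergent genotypes per generation.
3. **Fitness evaluation** — a host's score against one parasite species is
   the mean over the pool of the better of its two alleles' recognition
   probabilities (one matching receptor suffices); with several species the
   scores are averaged.  Host fitness is this mean recognised fraction
   raised to the `selection_strength` exponent.  A parasite's fitness is
   one minus the mean probability of being recognised across hosts.
4. **Host reproduction** — fitness-proportional sampling of 2N parents,
   random mating, each offspring inheriting one allele from each parent;
   alleles then mutate with probability `host_mut_rate` using the same step
   law as parasites.  If every host has zero fitness (possible with a very
   narrow kernel) recruitment falls back to uniform with a logged warning.
5. **Parasite recruitment** — fitness-proportional multinomial resampling,
   or uniform resampling when `parasite_selection` is off (the neutral
   parasite scenario).

Population sizes are conserved exactly; all coordinates remain on the grid
(reflecting boundary, non-toroidal).  All randomness flows through one
`numpy` generator per run, so a fixed seed reproduces a trajectory
bit-for-bit.

### Parameter defaults and their rationale

* `host_mut_rate = 0.05` per allele copy per generation.  The source model
  is quoted only as using a "very high (~1e-1)" MHC mutation rate without
  stating the unit.  Read per diploid individual, this is 0.05 per copy.
  We adopted the per-individual reading because it is the one under which
  the reconstruction actually reproduces the reported equilibrium (about
  8 supertypes and about 40 effective alleles in samples of 100
  individuals); under the per-copy reading (0.1) the model maintains
  100-130 effective alleles whenever four or more supertype clusters
  persist, across every kernel shape, mutation-step size and selection
  strength we examined.
* `parasite_mut_rate = 0.02` per genotype.  Unpublished in the source.
  Chosen so that, without seeding, the parasite pool coalesces onto a
  dominant genotype (mode share ~20%) that the host population chases —
  the qualitative regime described for the no-seeding scenario.  At 0.1
  the pool stays diffuse (mode share ~3%) and no dominant genotype exists.
  The seeded scenarios are insensitive to this value.
* `recognition_scale = 160`, `selection_strength = 2.75`.  Calibrated
  jointly, once, so that the original high-mutation scenario maintains its
  reported supertype and allele numbers at quasi-equilibrium; neither value
  is varied per scenario.
* `mutation_step_scale = 10` grid units: point mutations make local moves
  in physicochemical space, in contrast to seeded genotypes, which are
  uniform over the grid.
* One parasite generation per host generation; exposure defaults to the
  whole pool (an `exposure_sample` per host is available as config).

### Scenario presets

`original` (high mutation, 1% seeding, one parasite species, both selection
flags on) and four single-ingredient variants: `fig2a` /
`low_mut_large_pop` (host mutation 1e-3, parasite 1e-2, host population
100,000), `fig2b` / `neutral_parasites` (parasite selection off), `fig2c` /
`no_seeding`, and `fig2d` / `multi_parasite` (no seeding, 10 independent
parasite species).

### Problem sizes used by the tests and the acceptance script

Host population 1000 (inside the original scenario's 1e3-1e4 range),
parasite pool 2000 (scaled from 10,000; the seeding *fraction* is
unchanged), 1500 generations with statistics over the second half
(scenarios that equilibrate slowly run 2000-3000 generations).  These sizes
were fixed as the package's standard study conditions; the `SimConfig`
defaults keep the 10,000-strong parasite pool so that the seeding
arithmetic of the full-size model is preserved.

### Known divergences from the source's qualitative claims

With diploid hosts, heterozygote advantage floors the no-seeding and
very-low-mutation scenarios at roughly 1-3 substantial chasing clusters
rather than exactly one: a host carrying alleles in two packs out-competes
homozygotes, which stabilises a two-pack "pincer" on the parasite cloud.
We verified this persists to 8000 generations and at host population 4000.
The tests therefore assert the reconstruction's faithful analogue of the
described collapse — a dominant supertype holding most allele copies,
supertype counts far below the original scenario's, large centroid
displacement, and a dominant parasite genotype — rather than a literal
count of one.

## 2. Supertype delimitation, tracking, and diversity

Simulated supertypes are delimited by single-linkage clustering of allele
coordinates: two alleles share a supertype iff connected by a chain of
pairwise distances <= `supertype_threshold` (default 100 grid units, 10% of
the grid side).  Labels are deterministic (ordered by each cluster's
lexicographically smallest member); centroids are copy-count-weighted.
Lineages are tracked between consecutive snapshots by greedy
nearest-centroid matching within `match_radius` (default 150): first match
= persist/move, additional matches to the same ancestor = branch, unmatched
ancestors = loss.  Ties are broken by ascending distance, then larger
cluster.  "Effective number of alleles" is the inverse Simpson index
1/sum(p_i^2) over the 2n allele copies of a sample of n = 100 individuals.

## 3. Supertype population structure (Jost's D_EST)

Genotypes are (population, individual, allele) records.  Because up to nine
alleles amplify from an unknown number of loci, copy number is unknowable;
frequencies are therefore estimated from pooled occurrences, each allele
counted once per individual.  Pairwise Jost's D between demes is

    D = (H_T - H_S) / (1 - H_S) * n/(n-1),  n = 2,

with either plug-in ("naive") gene diversities or a Nei-Chesser-style
correction (per-deme unbiased n/(n-1) diversities and harmonic-mean sample
size in H_T; the default).  The corrected estimator can be negative for
identical small samples — the exact value for the shipped `identical`
fixture is -1/2 — while the naive estimator returns 0 there and 1 for fixed
differences.  Which estimator the original analysis used is not recorded;
both are provided and every pipeline function takes an `estimator`
argument.

The analysis computes each population's mean pairwise supertype-level D
("red dots"), and a permutation null ("blue dots" +/- SD) obtained by
reshuffling the allele -> supertype map over unique alleles (supertype
sizes preserved exactly; 1000 repeats by default).  Per-supertype
jackknifes drop all alleles of a focal supertype, drop individuals emptied
by that deletion, and drop populations left empty or supertype-monomorphic
(logged); summaries report the mean and SD of (red - blue) and the Spearman
concordance of jackknifed vs full red dots over shared populations.  Three
randomised-deletion controls ask whether a jackknife's effect is explained
by supertype size or frequency alone: deleting (1) an equally sized random
set of unique sequences, (2) an equal number of random occurrence records,
(3) per-population record counts matching the focal supertype's
per-population frequency.  A "supertype homozygote" is an individual whose
detected alleles all map to one supertype — the only reading consistent
with unknown zygosity.

## 4. Phylogenetics

Jukes-Cantor distances d = -(3/4) ln(1 - (4/3) p) use pairwise deletion
(columns with a gap or N in either sequence are excluded for that pair);
p >= 0.75 raises by default or is capped (configurable) — bootstrap
replicates cap, so resampling noise cannot abort a run.  Neighbour joining
is the Saitou-Nei algorithm with the Studier-Keppler Q criterion,
deterministic lowest-index tie-breaking, and negative branch lengths
clamped to zero; the result is an unrooted tree (trifurcating root).
Bootstrap support resamples alignment columns with replacement (500
replicates by default), rebuilds the tree, and maps bipartition frequencies
(as percentages) onto the original tree's internal edges by bipartition
identity, not node identity.  A supertype is monophyletic iff some edge of
the unrooted tree separates exactly its members; singletons are trivially
monophyletic and flagged as such.  Exact bit-level agreement with any
particular GUI phylogenetics program's tie-breaking or bootstrap RNG is out
of scope; the tests instead require exact topology recovery on additive
matrices and agreement with an independent NJ implementation on noisy ones.

## 5. Synthetic data

* **Alignments** (`gen_alignment`): sequences evolve down an explicit tree
  under the Jukes-Cantor process (matching the distance model used
  downstream), 209 columns by default.  In the `monophyletic_supertypes`
  scenario the tree is a star of supertype clades (deep stems, shallow
  within-clade branches), so supertypes are monophyletic by construction.
  In the `convergent_supertypes` scenario one tree spans all alleles and
  supertype membership is written into a few motif columns afterwards:
  members of a supertype are identical at those columns (a similarity
  criterion) while their ancestry crosses labels, so supertypes should
  *not* form clades.  The generating tree is returned as ground truth.
* **Genotype tables** (`gen_population_tables`): structured supertypes own
  population-private allele sets with Dirichlet-varying supertype weights
  per population; the optional outlier supertype shares one allele set
  across all populations at a fixed high frequency (default 0.4) — high
  frequency, no structure.  Ground truth (true weights, pools, outlier
  label) is returned.  Default sizes (6 populations x 20 individuals, 1-9
  alleles each) are a scaled-down image of a multi-population riverine
  fish MHC survey.
* **D fixtures** (`gen_dest_fixture`): two-population tables small enough
  to evaluate Jost's D by hand; expected values for both estimators are
  recorded with each fixture (`identical`: 0 and -1/2; `fixed_diff`: 1 and
  1; `mixed_7030`: 8/29 and 17/80).

What passing on synthetic data shows — and does not.  The generators
reproduce the *statistical structure* the analyses assume (population-
private alleles, an unstructured high-frequency supertype, clade-concordant
vs convergent supertype labels); they do not model recombination, gene
conversion, genotyping error, uneven sampling, or linkage between loci.
Results on them validate the machinery and its directional behaviour, not
any empirical claim about real populations, for which the original genotype
and sequence data would be required as input.

## 6. Numerical details

* Fitness evaluation deduplicates coordinates before computing the
  recognition matrix, so per-generation cost scales with the number of
  distinct paratopes/epitopes, not with population size.
* Supertype clustering uses a KD-tree neighbour query plus sparse connected
  components; identical results to brute-force chaining are enforced by
  test.
* The permutation null vectorises each repeat as a counts-matrix product
  with a permuted label indicator.
* Spearman concordance on constant vectors is defined as 1 when the two
  vectors are identical (the degenerate jackknife-of-absent-supertype
  case) and NaN otherwise.
* Estimator summaries for the simulation targets: the supertype-count
  target uses the median over seeds of per-seed mean post-burn-in counts
  (means avoid the coarse integer snapping of a median of medians); the
  effective-allele target uses the median over seeds of per-seed medians.
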