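# redqueen

Tools for asking whether MHC **supertypes** — clusters of MHC alleles with
similar antigen-binding properties — behave as stable units of balancing
selection that could explain trans-species polymorphism (TSP), or whether
the empirical and theoretical signals attributed to them dissolve on closer
inspection.  The package is aimed at evolutionary geneticists who want to
re-run that argument end to end on data they control.

It implements three connected analyses:

1. **An individual-based host–parasite coevolution model in paratope
   space** (`redqueen.coevo_sim`, `redqueen.supertypes`).  Host MHC alleles
   and parasite genotypes are coordinates on a 1000 × 1000 grid; a host
   recognises a parasite with probability exp(−d²/2s²) of their distance d.
   Hosts are diploid and reproduce sexually with fitness-proportional
   selection; parasites evolve by point mutation and, optionally, a 1%
   per-generation influx of uniformly random genotypes ("seeding").
   Scenario presets switch individual ingredients: lowered mutation rates,
   neutral parasites, no seeding, ten parasite species.  Supertypes are
   delimited by single-linkage clustering (threshold 100 grid units) and
   followed through time as persist/move/loss/branch lineage events;
   allelic diversity is the inverse Simpson index 1/Σp² ("effective number
   of alleles") in samples of 100 individuals.

2. **Supertype-level population structure** (`redqueen.popgen`).  From
   multi-population genotype tables (individual → set of alleles, up to 9
   per individual, loci unknowable) it computes each population's mean
   pairwise Jost's D_EST = (H_T − H_S)/(1 − H_S) · n/(n−1) at allele or
   supertype level, a permutation null that reshuffles the
   allele→supertype map while preserving supertype sizes, per-supertype
   jackknifes with Spearman concordance, three randomised-deletion
   controls, and supertype-homozygosity fractions.

3. **A supertype-monophyly test** (`redqueen.phylo`).  Jukes–Cantor
   distances (pairwise deletion), Saitou–Nei neighbour joining with
   deterministic tie-breaking, column-resampling bootstrap support mapped
   onto bipartitions, and an exact test of whether each supertype's alleles
   form a clade on the unrooted tree.

`redqueen.synthetic` generates every input the pipelines need — alignments
evolved under monophyletic vs convergent supertype scenarios, genotype
tables with tunable structure and an "outlier" unstructured high-frequency
supertype, and hand-checkable Jost's D fixtures — always together with the
ground truth, so the whole package is testable without downloads.

## Worked example

Run the original high-mutation scenario at the package's standard scaled
sizes and summarise what it maintains:

```python
import numpy as np
import redqueen as rq

records = rq.run_scenario(
    "original",
    dict(host_pop_size=1000, parasite_pop_size=2000,
         generations=1500, record_every=50),
    rng_seed=1,
)
late = [r for r in records if r.generation >= 750]
print("supertypes:", np.median([r.n_supertypes for r in late]))
print("effective alleles:", round(np.median(
    [r.effective_num_alleles for r in late]), 1))
```

```
supertypes: 6.0
effective alleles: 58.5
```

Six supertype clusters and ~58 effective alleles per 100-individual sample
persist at quasi-equilibrium under high mutation with parasite seeding —
the regime whose reported figures are roughly 8 supertypes and 40 alleles.
Switching the same run to the `no_seeding` preset collapses the population
to a dominant supertype chasing a concentrated parasite genotype across the
grid.

The same workflow from the shell, plus the popgen and phylogeny stages on
synthetic data:

```sh
redqueen simulate --scenario no_seeding --generations 2000 --seed 1 --out run/
redqueen synth tables --seed 2 --out data/
redqueen popgen --genotypes data/genotypes.csv --supertypes data/supertypes.csv \
    --reps 1000 --seed 1 --out popgen/
redqueen synth alignment --scenario convergent_supertypes --seed 3 --out aln/
redqueen phylo --fasta aln/alignment.fasta --supertypes aln/supertypes.csv \
    --bootstrap 500 --seed 1 --out tree/
redqueen reproduce-all --seed 1 --out everything/
```

`popgen` prints the supertype-homozygote percentage and writes the
observed-vs-expected structure table and the jackknife summary;
`phylo` prints how many supertypes are monophyletic (for a convergent
alignment, typically `0/8 supertypes monophyletic`) and writes the
Newick tree with bootstrap supports.

## Layout

```
src/redqueen/coevo_sim.py    simulator: config, kernels, generation step,
                             scenario presets, trajectory recording
src/redqueen/supertypes.py   supertype clustering, lineage tracking,
                             effective number of alleles
src/redqueen/popgen.py       Jost's D_EST, permutation null, jackknifes,
                             deletion controls, homozygosity
src/redqueen/phylo.py        JC distances, NJ, bootstrap, monophyly
src/redqueen/synthetic.py    generators with ground truth
src/redqueen/cli.py          `redqueen` command-line interface
docs/methods.md              models, defaults, calibration, limitations
```
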