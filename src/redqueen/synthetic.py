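"""Synthetic data with the statistical structure the analyses assume.

Three generator families, all seed-deterministic and all returning ground
truth alongside the data:

* :func:`gen_alignment` — aligned nucleotide sequences with supertype labels
  under two scenarios.  In the ``monophyletic_supertypes`` scenario sequences
  evolve down a tree whose clades coincide with supertypes (the pattern
  expected if supertypes are ancient allelic lineages).  In the
  ``convergent_supertypes`` scenario sequences evolve on one tree that
  crosses supertype boundaries while supertype membership is written into a
  few "functional" motif columns, so alleles of a supertype are similar at
  those columns but do not share ancestry.
* :func:`gen_population_tables` — multi-population genotype tables with
  population-differentiated supertypes (population-specific allele sets and
  Dirichlet-varying supertype weights) and optionally one high-frequency,
  deliberately unstructured outlier supertype whose alleles are shared at
  similar frequencies by every population.
* :func:`gen_dest_fixture` — tiny genotype tables whose pairwise Jost's D
  values are hand-computable, recorded alongside the fixture.

Sequence evolution uses the Jukes-Cantor substitution process, matching the
distance model applied downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from skbio import TreeNode

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignmentSpec:
    """Parameters of the alignment generator.

    ``within_divergence`` / ``between_divergence`` are expected substitutions
    per site on within-supertype branches and on the deep stems separating
    supertype clades (monophyletic scenario) or across the whole tree
    (convergent scenario).  Sizes default to a scaled-down image of an
    empirical MHC class II exon 2 dataset: tens of alleles, 209 aligned
    columns, around ten supertypes.
    """

    scenario: str = "monophyletic_supertypes"
    n_supertypes: int = 10
    alleles_per_supertype: int = 6
    seq_length: int = 209
    within_divergence: float = 0.01
    between_divergence: float = 0.3
    n_motif_columns: int = 4
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in ("monophyletic_supertypes",
                                 "convergent_supertypes"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.n_supertypes < 1 or self.alleles_per_supertype < 1:
            raise ValueError("sizes must be >= 1")
        if self.within_divergence < 0 or self.between_divergence < 0:
            raise ValueError("divergence parameters must be >= 0")
        if self.seq_length < self.n_motif_columns:
            raise ValueError("sequence shorter than the motif")
        if (self.scenario == "convergent_supertypes"
                and self.n_supertypes > 4**self.n_motif_columns):
            raise ValueError("too many supertypes for the motif width")


@dataclass(frozen=True)
class TableSpec:
    """Parameters of the genotype-table generator.

    Each structured supertype owns a private allele set; populations use
    disjoint subsets of it and weight supertypes by a Dirichlet draw
    (``structure_concentration`` — smaller means stronger differentiation).
    With ``outlier_supertype`` set, one additional supertype ("ST-out")
    carries ``outlier_frequency`` of every population's allele occurrences
    through the *same* shared alleles everywhere: high frequency, no
    population structure.
    """

    n_populations: int = 6
    individuals_per_population: int = 20
    alleles_per_individual: tuple[int, int] = (2, 6)
    n_structured_supertypes: int = 5
    alleles_per_supertype: int = 6
    outlier_supertype: bool = True
    outlier_frequency: float = 0.4
    structure_concentration: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.alleles_per_individual
        if not 1 <= lo <= hi <= 9:
            raise ValueError("alleles per individual must lie within 1-9")
        if not 0.0 < self.outlier_frequency < 1.0:
            raise ValueError("outlier_frequency must lie in (0, 1)")
        if self.n_populations < 1 or self.individuals_per_population < 1:
            raise ValueError("population sizes must be >= 1")


# ---------------------------------------------------------------------------
# Sequence evolution (Jukes-Cantor)
# ---------------------------------------------------------------------------

def _substitution_prob(branch_length: float) -> float:
    """P(site differs from parent) after ``branch_length`` expected subs."""
    return 0.75 * (1.0 - np.exp(-4.0 * branch_length / 3.0))


def _evolve(seq: np.ndarray, t: float, rng: np.random.Generator) -> np.ndarray:
    child = seq.copy()
    hit = rng.random(seq.shape[0]) < _substitution_prob(t)
    n = int(hit.sum())
    if n:
        # draw a base different from the current one, uniformly
        shift = rng.integers(1, 4, size=n)
        cur = np.searchsorted(BASES, child[hit])
        child[hit] = BASES[(cur + shift) % 4]
    return child


def _random_topology(names: list[str], rng: np.random.Generator,
                     branch_length) -> TreeNode:
    """Random binary topology by repeated joining of subtree pairs."""
    nodes = [TreeNode(name=n) for n in names]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        a.length = float(branch_length())
        b.length = float(branch_length())
        nodes.append(TreeNode(children=[a, b]))
    root = nodes[0]
    root.length = None
    return root


def _evolve_tree(
    tree: TreeNode, root_seq: np.ndarray, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}

    def recurse(node: TreeNode, seq: np.ndarray) -> None:
        for child in node.children:
            child_seq = _evolve(seq, child.length or 0.0, rng)
            if child.is_tip():
                out[child.name] = child_seq
            else:
                recurse(child, child_seq)

    recurse(tree, root_seq)
    return out


def gen_alignment(
    spec: AlignmentSpec,
) -> tuple[dict[str, str], pd.Series, TreeNode]:
    """Generate (alignment, allele -> supertype map, true tree).

    Allele ids are ``ST<k>_a<i>``; supertype labels ``ST<k>``.  The true
    tree carries the topology the sequences actually evolved on, so
    downstream tree inference can be scored against it.
    """
    rng = np.random.default_rng(spec.rng_seed)
    L = spec.seq_length
    root_seq = rng.choice(BASES, size=L)
    labels = {}
    names_by_st: dict[str, list[str]] = {}
    for k in range(spec.n_supertypes):
        st = f"ST{k + 1}"
        names_by_st[st] = [
            f"{st}_a{i + 1}" for i in range(spec.alleles_per_supertype)
        ]
        for n in names_by_st[st]:
            labels[n] = st

    if spec.scenario == "monophyletic_supertypes":
        clades = []
        for st, names in names_by_st.items():
            if len(names) == 1:
                clade = TreeNode(name=names[0])
            else:
                clade = _random_topology(
                    names, rng,
                    lambda: rng.uniform(0.5, 1.5) * spec.within_divergence,
                )
            clade.length = float(spec.between_divergence)
            clades.append(clade)
        tree = TreeNode(children=clades)
        seqs = _evolve_tree(tree, root_seq, rng)
    else:  # convergent: one tree across labels, motif columns define labels
        all_names = [n for ns in names_by_st.values() for n in ns]
        order = list(rng.permutation(all_names))
        tree = _random_topology(
            order, rng,
            lambda: rng.uniform(0.5, 1.5) * spec.between_divergence
            / max(spec.n_supertypes, 2),
        )
        seqs = _evolve_tree(tree, root_seq, rng)
        motif_cols = rng.choice(L, size=spec.n_motif_columns, replace=False)
        motifs = _distinct_motifs(spec.n_supertypes, spec.n_motif_columns,
                                  rng)
        for st, names in names_by_st.items():
            motif = motifs[st]
            for n in names:
                seqs[n][motif_cols] = motif

    alignment = {n: seqs[n].tobytes().decode() for n in sorted(seqs)}
    return alignment, pd.Series(labels, name="supertype"), tree


def _distinct_motifs(
    k: int, width: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    seen: set[bytes] = set()
    out: dict[str, np.ndarray] = {}
    i = 1
    while len(out) < k:
        m = rng.choice(BASES, size=width)
        key = m.tobytes()
        if key in seen:
            continue
        seen.add(key)
        out[f"ST{i}"] = m
        i += 1
    return out


# ---------------------------------------------------------------------------
# Genotype tables
# ---------------------------------------------------------------------------

def gen_population_tables(
    spec: TableSpec,
) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Generate (genotype table, supertype map, ground truth).

    The table is long-format (population, individual, allele).  Ground truth
    records per-population supertype weights, the per-population allele
    pools, and the outlier supertype's label (or None).
    """
    rng = np.random.default_rng(spec.rng_seed)
    st_labels = [f"ST{k + 1}" for k in range(spec.n_structured_supertypes)]
    outlier = "ST-out" if spec.outlier_supertype else None

    st_map: dict[str, str] = {}
    pool_weights: dict[str, dict[str, np.ndarray]] = {}
    pool_alleles: dict[str, dict[str, list[str]]] = {}
    pops = [f"pop{p + 1}" for p in range(spec.n_populations)]

    # structured supertypes: population-specific allele subsets
    per_pop = max(1, spec.alleles_per_supertype)
    for st in st_labels:
        for pop in pops:
            alleles = [f"{st}_{pop}_a{i + 1}" for i in range(per_pop)]
            pool_alleles.setdefault(pop, {})[st] = alleles
            for a in alleles:
                st_map[a] = st
            w = rng.dirichlet(np.ones(per_pop))
            pool_weights.setdefault(pop, {})[st] = w

    if outlier:
        shared = [f"{outlier}_a{i + 1}"
                  for i in range(spec.alleles_per_supertype)]
        for a in shared:
            st_map[a] = outlier
        shared_w = rng.dirichlet(np.ones(len(shared)) * 10.0)
        for pop in pops:
            pool_alleles[pop][outlier] = shared
            pool_weights[pop][outlier] = shared_w

    # per-population supertype weights
    true_weights: dict[str, pd.Series] = {}
    for pop in pops:
        w_struct = rng.dirichlet(
            np.full(len(st_labels), spec.structure_concentration)
        )
        if outlier:
            weights = np.concatenate(
                [w_struct * (1.0 - spec.outlier_frequency),
                 [spec.outlier_frequency]]
            )
            true_weights[pop] = pd.Series(weights, index=st_labels + [outlier])
        else:
            true_weights[pop] = pd.Series(w_struct, index=st_labels)

    lo, hi = spec.alleles_per_individual
    rows = []
    for pop in pops:
        sts = list(true_weights[pop].index)
        st_w = true_weights[pop].to_numpy()
        allele_names: list[str] = []
        allele_probs: list[float] = []
        for st, wst in zip(sts, st_w):
            names = pool_alleles[pop][st]
            w = pool_weights[pop][st]
            allele_names.extend(names)
            allele_probs.extend(wst * w)
        probs = np.asarray(allele_probs)
        probs = probs / probs.sum()
        for ind in range(spec.individuals_per_population):
            k = int(rng.integers(lo, hi + 1))
            k = min(k, len(allele_names))
            picked = rng.choice(len(allele_names), size=k, replace=False,
                                p=probs)
            for idx in picked:
                rows.append((pop, f"{pop}_ind{ind + 1}", allele_names[idx]))

    table = pd.DataFrame(rows, columns=["population", "individual", "allele"])
    truth = {
        "supertype_weights": pd.DataFrame(true_weights).T,
        "pool_alleles": pool_alleles,
        "outlier_supertype": outlier,
    }
    return table, pd.Series(st_map, name="supertype"), truth


# ---------------------------------------------------------------------------
# Hand-computable D_EST fixtures
# ---------------------------------------------------------------------------

def gen_dest_fixture(case_id: str) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Tiny two-population tables with hand-computed Jost's D.

    Cases
    -----
    ``identical``
        Both populations carry alleles a and b at 50/50 (4 individuals
        each).  Naive D = 0 exactly; the Nei-Chesser estimator is -1/2
        (H_S = (4/3)(1/2) = 2/3, H_T = 1/2 + H_S/8 = 7/12, so
        D = 2(7/12 - 2/3)/(1 - 2/3); its finite-sample correction makes
        identical small samples negative).
    ``fixed_diff``
        Population A fixed for a, population B fixed for b (8 single-allele
        individuals each): D = 1 under both estimators.
    ``mixed_7030``
        Frequencies (0.7, 0.3) vs (0.3, 0.7) from 10 occurrence records per
        population.  Naive: H_S = 0.42, H_T = 0.5, D = 2*(0.08/0.58) = 8/29.
        Nei-Chesser: H_S = 7/15, H_T = 157/300, D = 2*(17/300)/(160/300)
        = 17/80 = 0.2125.
    """
    if case_id == "identical":
        inds = {f"i{j}": alleles
                for j, alleles in enumerate([{"a"}, {"a"}, {"b"}, {"b"}])}
        table = {"A": dict(inds), "B": dict(inds)}
        expected = {"naive": 0.0, "nei_chesser": -0.5}
    elif case_id == "fixed_diff":
        table = {
            "A": {f"i{j}": {"a"} for j in range(8)},
            "B": {f"j{j}": {"b"} for j in range(8)},
        }
        expected = {"naive": 1.0, "nei_chesser": 1.0}
    elif case_id == "mixed_7030":
        table = {
            "A": {f"i{j}": ({"a"} if j < 7 else {"b"}) for j in range(10)},
            "B": {f"j{j}": ({"a"} if j < 3 else {"b"}) for j in range(10)},
        }
        expected = {"naive": 8.0 / 29.0, "nei_chesser": 17.0 / 80.0}
    else:
        raise ValueError(f"unknown fixture case {case_id!r}")

    rows = [
        (pop, ind, a)
        for pop, inds in table.items()
        for ind, alleles in inds.items()
        for a in sorted(alleles)
    ]
    df = pd.DataFrame(rows, columns=["population", "individual", "allele"])
    st_map = pd.Series({"a": "ST1", "b": "ST2"}, name="supertype")
    return df, st_map, expected


# ---------------------------------------------------------------------------
# Additive distance matrices for tree-inference oracles
# ---------------------------------------------------------------------------

def random_additive_matrix(
    n_taxa: int, rng: np.random.Generator
) -> tuple[list[str], np.ndarray, TreeNode]:
    """Random binary tree plus its exact path-length distance matrix.

    Branch lengths are uniform on (0.05, 1.0), so the matrix satisfies the
    four-point condition and neighbour joining must recover the topology
    exactly.
    """
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    names = [f"t{i + 1}" for i in range(n_taxa)]
    tree = _random_topology(list(names), rng,
                            lambda: rng.uniform(0.05, 1.0))
    D = np.zeros((n_taxa, n_taxa))
    tips = {t.name: t for t in tree.tips()}
    for i in range(n_taxa):
        for j in range(i + 1, n_taxa):
            d = tips[names[i]].distance(tips[names[j]])
            D[i, j] = D[j, i] = float(d)
    return names, D, tree
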