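"""Supertype-level population structure: Jost's D_EST with a permutation null.

The pipeline mirrors a standard critique of supertype-level balancing
selection claims.  Genotypes are tables of (population, individual, allele)
records; individuals may carry up to nine alleles across an unknown number of
co-amplifying loci, so copy number and true zygosity are unknowable and all
frequencies are estimated from pooled allele occurrences (each allele counted
once per individual).  The analysis computes:

* observed mean pairwise Jost's D_EST per population, at the allele or the
  supertype level (the "red dots");
* a permutation null in which allele->supertype labels are reshuffled over
  unique alleles, preserving supertype sizes ("blue dots": mean and SD over
  repeats);
* per-supertype jackknifes (drop all alleles of one supertype) with the mean
  and SD of the red-blue difference and the Spearman concordance of the
  jackknifed red dots with the full dataset's;
* three randomised-deletion controls (sequence-matched, frequency-matched,
  population-stratified) that ask whether a jackknife's effect is explained
  by supertype size or frequency alone;
* the fraction of supertype homozygotes (individuals whose alleles all map
  to one supertype), with optional exclusion of a focal supertype.

Jost's D for a pair of demes is D = (H_T - H_S) / (1 - H_S) * n/(n-1) with
n = 2 demes; both the plug-in ("naive") estimator and a Nei-Chesser-style
sample-size-corrected estimator of H_S and H_T are available.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

logger = logging.getLogger("redqueen")

TABLE_COLUMNS = ("population", "individual", "allele")


# ---------------------------------------------------------------------------
# Table handling
# ---------------------------------------------------------------------------

def as_table(table) -> pd.DataFrame:
    """Coerce input to a (population, individual, allele) record frame.

    Accepts a DataFrame with those columns or a nested mapping
    ``{population: {individual: iterable of alleles}}``.  Duplicate records
    (the same allele listed twice for one individual) are dropped: an allele
    occurrence counts once per individual.
    """
    if isinstance(table, pd.DataFrame):
        missing = set(TABLE_COLUMNS) - set(table.columns)
        if missing:
            raise ValueError(f"table lacks columns: {sorted(missing)}")
        df = table.loc[:, list(TABLE_COLUMNS)].copy()
    else:
        rows = []
        for pop, inds in table.items():
            for ind, alleles in inds.items():
                for a in alleles:
                    rows.append((pop, ind, a))
        df = pd.DataFrame(rows, columns=list(TABLE_COLUMNS))
    df = df.drop_duplicates()
    if df.empty:
        raise ValueError("genotype table is empty")
    per_ind = df.groupby(["population", "individual"])["allele"].size()
    if (per_ind > 9).any():
        warnings.warn("some individuals carry more than nine alleles")
    return df


def _map_series(st_map) -> pd.Series:
    if isinstance(st_map, pd.Series):
        return st_map
    if isinstance(st_map, pd.DataFrame):
        return st_map.set_index(st_map.columns[0])[st_map.columns[1]]
    return pd.Series(dict(st_map))


def _check_mapped(df: pd.DataFrame, st: pd.Series) -> None:
    unmapped = set(df["allele"]) - set(st.index)
    if unmapped:
        raise ValueError(
            f"alleles without a supertype label: {sorted(unmapped)[:10]}"
        )


def counts_matrix(
    table, level: str = "allele", st_map=None
) -> tuple[list, list, np.ndarray]:
    """Occurrence-count matrix (populations x units).

    Returns (population labels, unit labels, count matrix).  At
    ``level='supertype'`` allele occurrences are collapsed through
    ``st_map``; totals per population are preserved.
    """
    df = as_table(table)
    if level == "supertype":
        st = _map_series(st_map)
        _check_mapped(df, st)
        df = df.assign(unit=df["allele"].map(st))
    elif level == "allele":
        df = df.assign(unit=df["allele"])
    else:
        raise ValueError("level must be 'allele' or 'supertype'")
    pivot = (
        df.groupby(["population", "unit"]).size().unstack(fill_value=0)
    )
    return list(pivot.index), list(pivot.columns), pivot.to_numpy(float)


def unit_frequencies(
    table, pop, level: str = "allele", st_map=None
) -> pd.Series:
    """Frequency vector for one population from pooled allele occurrences."""
    pops, units, C = counts_matrix(table, level=level, st_map=st_map)
    if pop not in pops:
        raise ValueError(f"population {pop!r} absent or empty")
    row = C[pops.index(pop)]
    return pd.Series(row / row.sum(), index=units)


# ---------------------------------------------------------------------------
# Jost's D
# ---------------------------------------------------------------------------

def jost_dest(
    freqs_a,
    freqs_b,
    n_a: int,
    n_b: int,
    estimator: str = "nei_chesser",
) -> float:
    """Pairwise Jost's D between two demes.

    ``freqs_a``/``freqs_b`` are frequency vectors on a common unit index
    (arrays or aligned Series); ``n_a``/``n_b`` are the numbers of observed
    allele occurrences the frequencies were estimated from.

    estimator
        'naive': plug-in gene diversities H_S = mean(1 - sum p^2) and
        H_T = 1 - sum(mean p)^2.  'nei_chesser': per-deme diversities
        unbiased by n/(n-1), harmonic-mean sample size in H_T
        (H_T' = H_T + H_S'/(2 n_tilde)).  The corrected estimator can be
        slightly negative for identical samples.
    """
    if isinstance(freqs_a, pd.Series) or isinstance(freqs_b, pd.Series):
        fa = pd.Series(freqs_a)
        fb = pd.Series(freqs_b)
        idx = fa.index.union(fb.index)
        a = fa.reindex(idx, fill_value=0.0).to_numpy(float)
        b = fb.reindex(idx, fill_value=0.0).to_numpy(float)
    else:
        a = np.asarray(freqs_a, dtype=float)
        b = np.asarray(freqs_b, dtype=float)
        if a.shape != b.shape:
            raise ValueError("frequency vectors must share an index")
    if n_a < 1 or n_b < 1:
        raise ValueError("sample sizes must be >= 1")

    ja, jb = float(np.sum(a**2)), float(np.sum(b**2))
    mean_p = 0.5 * (a + b)
    jt = float(np.sum(mean_p**2))
    if estimator == "naive":
        hs = 1.0 - 0.5 * (ja + jb)
        ht = 1.0 - jt
    elif estimator == "nei_chesser":
        ha = (n_a / (n_a - 1.0)) * (1.0 - ja) if n_a > 1 else 0.0
        hb = (n_b / (n_b - 1.0)) * (1.0 - jb) if n_b > 1 else 0.0
        hs = 0.5 * (ha + hb)
        n_tilde = 2.0 / (1.0 / n_a + 1.0 / n_b)
        ht = 1.0 - jt + hs / (2.0 * n_tilde)
    else:
        raise ValueError("estimator must be 'naive' or 'nei_chesser'")
    if hs >= 1.0:
        warnings.warn("within-deme diversity saturated (H_S >= 1); D undefined")
        return float("nan")
    return (ht - hs) / (1.0 - hs) * 2.0


def _pairwise_dest_matrix(
    C: np.ndarray, estimator: str = "nei_chesser"
) -> np.ndarray:
    """All pairwise D_EST values from a populations-by-units count matrix."""
    n = C.sum(axis=1)
    P = C / n[:, None]
    k = C.shape[0]
    out = np.full((k, k), np.nan)
    for i, j in itertools.combinations(range(k), 2):
        d = jost_dest(P[i], P[j], int(n[i]), int(n[j]), estimator=estimator)
        out[i, j] = out[j, i] = d
    return out


def mean_pairwise_dest(
    table,
    level: str = "allele",
    st_map=None,
    estimator: str = "nei_chesser",
) -> pd.Series:
    """Each population's mean pairwise D_EST against all other populations."""
    pops, _, C = counts_matrix(table, level=level, st_map=st_map)
    if len(pops) < 2:
        raise ValueError("need at least two populations for pairwise D_EST")
    D = _pairwise_dest_matrix(C, estimator=estimator)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(D, axis=1)
    return pd.Series(means, index=pops, name="mean_pairwise_dest")


# ---------------------------------------------------------------------------
# Permutation null ("blue dots")
# ---------------------------------------------------------------------------

@dataclass
class StructureResult:
    """Observed vs randomised-expected supertype structure per population.

    ``frame`` has one row per population with columns ``observed`` (red
    dots), ``expected_mean`` and ``expected_sd`` (blue dots and error bars).
    """

    frame: pd.DataFrame
    n_reps: int
    estimator: str
    dropped_populations: list = field(default_factory=list)

    @property
    def populations(self) -> list:
        return list(self.frame.index)

    @property
    def observed(self) -> pd.Series:
        return self.frame["observed"]

    @property
    def expected_mean(self) -> pd.Series:
        return self.frame["expected_mean"]

    @property
    def red_minus_blue(self) -> pd.Series:
        return self.frame["observed"] - self.frame["expected_mean"]


def randomized_expectation(
    table,
    st_map,
    n_reps: int = 1000,
    rng: np.random.Generator | None = None,
    estimator: str = "nei_chesser",
) -> pd.DataFrame:
    """Null distribution of supertype-level mean pairwise D_EST.

    Each repeat permutes the allele->supertype assignment over the unique
    alleles present in the table (supertype sizes are preserved exactly),
    collapses allele counts to the permuted supertypes, and recomputes each
    population's mean pairwise D_EST.  Returns per-population mean and SD
    over repeats.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    st = _map_series(st_map)
    pops, alleles, C = counts_matrix(table, level="allele")
    _check_mapped(as_table(table), st)
    labels = st.reindex(alleles).to_numpy()
    st_names, st_idx = np.unique(labels, return_inverse=True)
    k = len(st_names)

    vals = np.empty((n_reps, len(pops)))
    for r in range(n_reps):
        perm = rng.permutation(len(alleles))
        indicator = np.zeros((len(alleles), k))
        indicator[np.arange(len(alleles)), st_idx[perm]] = 1.0
        S = C @ indicator  # pops x permuted supertypes
        D = _pairwise_dest_matrix(S, estimator=estimator)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            vals[r] = np.nanmean(D, axis=1)
    return pd.DataFrame(
        {
            "expected_mean": vals.mean(axis=0),
            "expected_sd": vals.std(axis=0, ddof=0),
        },
        index=pops,
    )


def structure_analysis(
    table,
    st_map,
    n_reps: int = 1000,
    rng: np.random.Generator | None = None,
    estimator: str = "nei_chesser",
) -> StructureResult:
    """Observed supertype-level structure plus its permutation expectation."""
    observed = mean_pairwise_dest(
        table, level="supertype", st_map=st_map, estimator=estimator
    )
    null = randomized_expectation(
        table, st_map, n_reps=n_reps, rng=rng, estimator=estimator
    )
    frame = pd.DataFrame({"observed": observed}).join(null)
    return StructureResult(frame=frame, n_reps=n_reps, estimator=estimator)


# ---------------------------------------------------------------------------
# Jackknife by supertype
# ---------------------------------------------------------------------------

def jackknife_supertype(
    table, st_map, focal_st
) -> tuple[pd.DataFrame, pd.Series, list]:
    """Remove every allele of ``focal_st`` from the table.

    Individuals whose alleles all belonged to the focal supertype (focal-
    supertype homozygotes) disappear with their alleles.  Populations left
    empty, or monomorphic at the supertype level, are dropped with a log
    entry and reported in the returned list.
    """
    df = as_table(table)
    st = _map_series(st_map)
    _check_mapped(df, st)
    if focal_st not in set(st.values):
        raise ValueError(f"unknown supertype {focal_st!r}")
    keep = df["allele"].map(st) != focal_st
    reduced = df.loc[keep].copy()

    dropped = []
    for pop, grp in reduced.groupby("population"):
        n_st = grp["allele"].map(st).nunique()
        if n_st < 2:
            dropped.append(pop)
    lost_pops = set(df["population"]) - set(reduced["population"])
    dropped.extend(sorted(lost_pops - set(dropped)))
    if dropped:
        logger.info(
            "jackknife of %r drops populations %s (empty or supertype-"
            "monomorphic)", focal_st, dropped,
        )
        reduced = reduced[~reduced["population"].isin(dropped)]
    if reduced.empty:
        raise ValueError("jackknife removed the entire dataset")
    reduced_map = st[st.index.isin(reduced["allele"])]
    return reduced, reduced_map, dropped


def jackknife_summary(
    full_result: StructureResult, jack_result: StructureResult
) -> tuple[float, float, float]:
    """Summarise one jackknifed dataset against the full analysis.

    Returns (mean, SD) of the jackknifed dataset's per-population
    (red - blue) differences, and the Spearman correlation between the
    jackknifed red dots and the full dataset's red dots over the shared
    populations.
    """
    shared = [
        p for p in jack_result.populations if p in set(full_result.populations)
    ]
    if not shared:
        raise ValueError("no shared populations between full and jackknife")
    diff = jack_result.red_minus_blue.loc[shared]
    red_full = full_result.observed.loc[shared]
    red_jack = jack_result.observed.loc[shared]
    if red_full.nunique() == 1 or red_jack.nunique() == 1:
        rho = 1.0 if red_full.equals(red_jack) else float("nan")
    else:
        rho = float(spearmanr(red_full, red_jack).statistic)
    return float(diff.mean()), float(diff.std(ddof=0)), rho


def jackknife_all(
    table,
    st_map,
    n_reps: int = 1000,
    rng: np.random.Generator | None = None,
    estimator: str = "nei_chesser",
    full_result: StructureResult | None = None,
) -> pd.DataFrame:
    """Jackknife every supertype in turn.

    One row per supertype with the mean and SD of (red - blue) in the
    jackknifed dataset, the Spearman rho of its red dots against the full
    dataset's, and any dropped populations.
    """
    rng = np.random.default_rng() if rng is None else rng
    st = _map_series(st_map)
    if full_result is None:
        full_result = structure_analysis(
            table, st_map, n_reps=n_reps, rng=rng, estimator=estimator
        )
    rows = []
    for focal in sorted(set(st[st.index.isin(as_table(table)["allele"])])):
        reduced, reduced_map, dropped = jackknife_supertype(
            table, st_map, focal
        )
        jack = structure_analysis(
            reduced, reduced_map, n_reps=n_reps, rng=rng, estimator=estimator
        )
        mean_d, sd_d, rho = jackknife_summary(full_result, jack)
        rows.append((focal, mean_d, sd_d, rho, ";".join(map(str, dropped))))
    return pd.DataFrame(
        rows,
        columns=["supertype", "mean_red_minus_blue", "sd_red_minus_blue",
                 "spearman_rho", "dropped_populations"],
    ).set_index("supertype")


# ---------------------------------------------------------------------------
# Randomised-deletion controls
# ---------------------------------------------------------------------------

DELETION_SCHEMES = ("sequence_matched", "frequency_matched",
                    "population_stratified")


def _delete_records(
    df: pd.DataFrame, st: pd.Series, focal_st, scheme: str,
    rng: np.random.Generator,
) -> pd.DataFrame:
    focal_alleles = [a for a in df["allele"].unique() if st[a] == focal_st]
    focal_mask = df["allele"].map(st) == focal_st
    if not focal_alleles:
        return df.copy()
    if scheme == "sequence_matched":
        pool = df["allele"].unique()
        victims = rng.choice(pool, size=len(focal_alleles), replace=False)
        return df[~df["allele"].isin(victims)].copy()
    if scheme == "frequency_matched":
        n_del = int(focal_mask.sum())
        if n_del > len(df):
            raise ValueError("deletion count exceeds available records")
        drop_idx = rng.choice(df.index.to_numpy(), size=n_del, replace=False)
        return df.drop(index=drop_idx)
    if scheme == "population_stratified":
        keep = []
        for pop, grp in df.groupby("population"):
            n_del = int((grp["allele"].map(st) == focal_st).sum())
            if n_del > len(grp):
                raise ValueError("deletion count exceeds available records")
            drop_idx = rng.choice(grp.index.to_numpy(), size=n_del,
                                  replace=False)
            keep.append(grp.drop(index=drop_idx))
        return pd.concat(keep)
    raise ValueError(f"unknown scheme {scheme!r}; choose from "
                     f"{DELETION_SCHEMES}")


def random_deletion_control(
    table,
    st_map,
    focal_st,
    scheme: str,
    n_reps: int = 100,
    rng: np.random.Generator | None = None,
    estimator: str = "nei_chesser",
    n_null_reps: int = 100,
    full_result: StructureResult | None = None,
) -> pd.DataFrame:
    """Distribution of jackknife-style summaries under randomised deletion.

    Per repeat: delete records according to ``scheme`` (matching the focal
    supertype's allele count, total frequency, or per-population frequency),
    drop emptied individuals and supertype-monomorphic populations, then
    recompute the (red - blue) summary and Spearman rho against the full
    dataset.  Returns one row per repeat.
    """
    rng = np.random.default_rng() if rng is None else rng
    df = as_table(table)
    st = _map_series(st_map)
    _check_mapped(df, st)
    if full_result is None:
        full_result = structure_analysis(
            table, st_map, n_reps=n_null_reps, rng=rng, estimator=estimator
        )
    rows = []
    for r in range(n_reps):
        reduced = _delete_records(df, st, focal_st, scheme, rng)
        # apply the same population-drop rule as the jackknife
        good_pops = [
            pop for pop, grp in reduced.groupby("population")
            if grp["allele"].map(st).nunique() >= 2
        ]
        reduced = reduced[reduced["population"].isin(good_pops)]
        if reduced["population"].nunique() < 2:
            rows.append((r, np.nan, np.nan, np.nan))
            continue
        res = structure_analysis(
            reduced, st, n_reps=n_null_reps, rng=rng, estimator=estimator
        )
        mean_d, sd_d, rho = jackknife_summary(full_result, res)
        rows.append((r, mean_d, sd_d, rho))
    return pd.DataFrame(
        rows, columns=["rep", "mean_red_minus_blue", "sd_red_minus_blue",
                       "spearman_rho"],
    ).set_index("rep")


# ---------------------------------------------------------------------------
# Supertype homozygosity
# ---------------------------------------------------------------------------

def st_homozygosity_fraction(
    table, st_map, exclude_st=None
) -> float:
    """Fraction of individuals whose alleles all map to one supertype.

    With unknown zygosity (alleles cannot be assigned to loci), a "supertype
    homozygote" is operationalised as an individual all of whose detected
    alleles belong to a single supertype.  ``exclude_st`` removes that
    supertype's alleles first; individuals emptied by the exclusion are
    dropped from the denominator.
    """
    df = as_table(table)
    st = _map_series(st_map)
    _check_mapped(df, st)
    if exclude_st is not None:
        df = df[df["allele"].map(st) != exclude_st]
        if df.empty:
            raise ValueError("exclusion emptied the genotype table")
    sts = df.assign(st=df["allele"].map(st))
    per_ind = sts.groupby(["population", "individual"])["st"].nunique()
    return float((per_ind == 1).mean())
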