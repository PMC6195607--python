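"""Jost's D_EST pipeline: estimators, permutation null, jackknife, controls."""

from __future__ import annotations

import itertools
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

import redqueen as rq
from redqueen import popgen, synthetic
from redqueen.popgen import as_table


def toy_table():
    """3 individuals, 2 populations, hand-countable frequencies."""
    return {
        "P1": {"i1": {"a", "b"}, "i2": {"a"}},
        "P2": {"j1": {"b", "c", "c"}},  # duplicate collapses to one record
    }


def fraction_jost_d(counts_a, counts_b, estimator):
    """Independent textbook evaluation of pairwise Jost's D with exact
    rational arithmetic: D = (Ht - Hs)/(1 - Hs) * n/(n-1), n = 2 demes."""
    na, nb = sum(counts_a.values()), sum(counts_b.values())
    units = sorted(set(counts_a) | set(counts_b))
    pa = {u: Fraction(counts_a.get(u, 0), na) for u in units}
    pb = {u: Fraction(counts_b.get(u, 0), nb) for u in units}
    ja = sum(p * p for p in pa.values())
    jb = sum(p * p for p in pb.values())
    jt = sum(((pa[u] + pb[u]) / 2) ** 2 for u in units)
    if estimator == "naive":
        hs = 1 - Fraction(ja + jb, 2)
        ht = 1 - jt
    else:
        ha = Fraction(na, na - 1) * (1 - ja)
        hb = Fraction(nb, nb - 1) * (1 - jb)
        hs = (ha + hb) / 2
        n_tilde = Fraction(2, 1) / (Fraction(1, na) + Fraction(1, nb))
        ht = 1 - jt + hs / (2 * n_tilde)
    return float((ht - hs) / (1 - hs) * 2)


class TestFrequencies:
    def test_single_individual_two_alleles(self):
        t = {"P": {"i": {"a", "b"}}, "Q": {"j": {"a"}}}
        f = rq.unit_frequencies(t, "P")
        assert f["a"] == pytest.approx(0.5)
        assert f["b"] == pytest.approx(0.5)

    def test_supertype_collapse_preserves_mass(self):
        st_map = {"a": "S1", "b": "S1", "c": "S2"}
        f_allele = rq.unit_frequencies(toy_table(), "P1")
        f_st = rq.unit_frequencies(toy_table(), "P1", level="supertype",
                                   st_map=st_map)
        assert f_st.sum() == pytest.approx(1.0)
        assert f_st["S1"] == pytest.approx(f_allele["a"] + f_allele["b"])

    def test_hand_counted_toy_table(self):
        f = rq.unit_frequencies(toy_table(), "P1")
        # P1 pools records a,b,a -> a: 2/3, b: 1/3
        assert f["a"] == pytest.approx(2 / 3)
        assert f["b"] == pytest.approx(1 / 3)
        f2 = rq.unit_frequencies(toy_table(), "P2")
        # duplicate c within one individual counts once -> b,c at 1/2
        assert f2["b"] == pytest.approx(0.5)
        assert f2["c"] == pytest.approx(0.5)

    def test_missing_population_rejected(self):
        with pytest.raises(ValueError):
            rq.unit_frequencies(toy_table(), "nope")


class TestJostD:
    def test_identical_demes_zero_naive(self):
        f = np.array([0.4, 0.6])
        assert rq.jost_dest(f, f, 10, 10, estimator="naive") == pytest.approx(0.0)

    def test_fixed_difference_is_one(self):
        a, b = np.array([1.0, 0.0]), np.array([0.0, 1.0])
        for est in ("naive", "nei_chesser"):
            assert rq.jost_dest(a, b, 8, 8, estimator=est) == pytest.approx(1.0)

    def test_symmetry(self):
        a, b = np.array([0.7, 0.3]), np.array([0.2, 0.8])
        for est in ("naive", "nei_chesser"):
            assert rq.jost_dest(a, b, 10, 12, estimator=est) == pytest.approx(
                rq.jost_dest(b, a, 12, 10, estimator=est)
            )

    @pytest.mark.parametrize("est", ["naive", "nei_chesser"])
    def test_matches_exact_rational_oracle(self, est):
        counts_a = {"a": 7, "b": 3}
        counts_b = {"a": 3, "b": 7}
        fa = np.array([0.7, 0.3])
        fb = np.array([0.3, 0.7])
        got = rq.jost_dest(fa, fb, 10, 10, estimator=est)
        assert got == pytest.approx(fraction_jost_d(counts_a, counts_b, est))

    def test_series_inputs_align_on_union_index(self):
        fa = pd.Series({"a": 0.5, "b": 0.5})
        fb = pd.Series({"b": 0.5, "c": 0.5})
        d = rq.jost_dest(fa, fb, 10, 10, estimator="naive")
        da = rq.jost_dest(np.array([0.5, 0.5, 0.0]),
                          np.array([0.0, 0.5, 0.5]), 10, 10,
                          estimator="naive")
        assert d == pytest.approx(da)

    def test_saturated_within_diversity_warns_nan(self):
        # two singleton alleles per deme, n = 2: unbiased Hs reaches 1
        a, b = np.array([0.5, 0.5, 0, 0]), np.array([0, 0, 0.5, 0.5])
        with pytest.warns(UserWarning, match="saturated"):
            d = rq.jost_dest(a, b, 2, 2, estimator="nei_chesser")
        assert np.isnan(d)

    def test_fixture_cases_match_recorded_values(self):
        for case in ("identical", "fixed_diff", "mixed_7030"):
            table, st_map, expected = synthetic.gen_dest_fixture(case)
            pops, units, C = popgen.counts_matrix(table)
            n = C.sum(axis=1)
            P = C / n[:, None]
            for est, value in expected.items():
                got = rq.jost_dest(P[0], P[1], int(n[0]), int(n[1]),
                                   estimator=est)
                assert got == pytest.approx(value), (case, est)


class TestMeanPairwise:
    def test_two_populations_equal_their_pairwise_value(self):
        table, st_map, _ = synthetic.gen_dest_fixture("mixed_7030")
        m = rq.mean_pairwise_dest(table, estimator="naive")
        assert m["A"] == pytest.approx(8 / 29)
        assert m["B"] == pytest.approx(m["A"])

    def test_identical_populations_all_zero(self):
        t = {p: {f"{p}{i}": {"a", "b"} for i in range(4)}
             for p in ("P", "Q", "R")}
        m = rq.mean_pairwise_dest(t, estimator="naive")
        assert np.allclose(m.to_numpy(), 0.0)

    def test_matches_exhaustive_pair_loop(self, rng):
        table, st_map, _ = synthetic.gen_population_tables(
            synthetic.TableSpec(n_populations=4,
                                individuals_per_population=8, rng_seed=5)
        )
        m = rq.mean_pairwise_dest(table, estimator="nei_chesser")
        pops, units, C = popgen.counts_matrix(table)
        n = C.sum(axis=1)
        P = C / n[:, None]
        for i, pop in enumerate(pops):
            vals = [
                rq.jost_dest(P[i], P[j], int(n[i]), int(n[j]))
                for j in range(len(pops)) if j != i
            ]
            assert m[pop] == pytest.approx(np.mean(vals))

    def test_single_population_rejected(self):
        with pytest.raises(ValueError):
            rq.mean_pairwise_dest({"P": {"i": {"a"}}})


class TestRandomizedExpectation:
    def test_one_allele_per_supertype_is_label_invariant(self, rng):
        table = {
            "P": {f"i{k}": {f"a{k % 3}"} for k in range(6)},
            "Q": {f"j{k}": {f"a{(k + 1) % 3}"} for k in range(6)},
        }
        st_map = {f"a{k}": f"S{k}" for k in range(3)}
        obs = rq.mean_pairwise_dest(table, level="supertype", st_map=st_map,
                                    estimator="naive")
        null = rq.randomized_expectation(table, st_map, n_reps=50, rng=rng,
                                         estimator="naive")
        assert np.allclose(null["expected_mean"], obs.to_numpy())
        assert np.allclose(null["expected_sd"], 0.0)

    def test_matches_exhaustive_enumeration(self, rng):
        # 4 alleles in 2 supertypes of 2: only 3 distinct partitions matter;
        # enumerate all 4! label permutations exactly
        table = {
            "P": {"i1": {"a"}, "i2": {"a"}, "i3": {"b"}, "i4": {"c"}},
            "Q": {"j1": {"c"}, "j2": {"d"}, "j3": {"d"}, "j4": {"b"}},
        }
        st_map = {"a": "S1", "b": "S1", "c": "S2", "d": "S2"}
        alleles = ["a", "b", "c", "d"]
        labels = ["S1", "S1", "S2", "S2"]
        per_pop = []
        for perm in itertools.permutations(range(4)):
            m = {alleles[i]: labels[perm[i]] for i in range(4)}
            per_pop.append(
                rq.mean_pairwise_dest(table, level="supertype", st_map=m,
                                      estimator="naive").to_numpy()
            )
        exact = np.mean(per_pop, axis=0)
        null = rq.randomized_expectation(table, st_map, n_reps=4000, rng=rng,
                                         estimator="naive")
        assert np.allclose(null["expected_mean"], exact, atol=0.02)

    def test_null_calibration_on_unstructured_labels(self):
        # labels random w.r.t. structure: observed should sit within +/-2 SD
        # of the permutation expectation for the vast majority of populations
        hits = trials = 0
        for seed in range(12):
            table, st_map, _ = synthetic.gen_population_tables(
                synthetic.TableSpec(n_populations=5,
                                    individuals_per_population=12,
                                    outlier_supertype=False, rng_seed=seed)
            )
            rng = np.random.default_rng(seed)
            labels = st_map.sample(frac=1.0, random_state=seed)
            shuffled = pd.Series(labels.to_numpy(), index=st_map.index)
            res = popgen.structure_analysis(table, shuffled, n_reps=60,
                                            rng=rng)
            z = (res.red_minus_blue.abs()
                 / res.frame["expected_sd"].clip(lower=1e-12))
            hits += int((z <= 2.0).sum())
            trials += len(z)
        assert hits / trials >= 0.85


class TestJackknife:
    def test_population_unchanged_when_supertype_absent(self):
        table = {
            "P": {"i1": {"a", "b"}, "i2": {"b"}},
            "Q": {"j1": {"a", "c"}, "j2": {"c", "b"}},
        }
        st_map = {"a": "S1", "b": "S2", "c": "S3"}
        reduced, rmap, dropped = rq.jackknife_supertype(table, st_map, "S3")
        p_rows = as_table(reduced).query("population == 'P'")
        assert set(p_rows["allele"]) == {"a", "b"}
        assert dropped == []

    def test_focal_homozygote_individuals_removed(self):
        table = {
            "P": {"i1": {"a"}, "i2": {"a", "b"}, "i3": {"b", "c"}},
            "Q": {"j1": {"b"}, "j2": {"c", "b"}},
        }
        st_map = {"a": "S1", "b": "S2", "c": "S3"}
        reduced, _, _ = rq.jackknife_supertype(table, st_map, "S1")
        inds = set(as_table(reduced)["individual"])
        assert "i1" not in inds and "i2" in inds

    def test_supertype_monomorphic_population_dropped_and_logged(self, caplog):
        # after removing S1, population C is homozygous for S2 -> dropped
        table = {
            "A": {"i1": {"a", "b"}, "i2": {"c", "a"}},
            "B": {"j1": {"b", "c"}, "j2": {"a", "c"}},
            "C": {"k1": {"a", "b2"}, "k2": {"b2"}},
        }
        st_map = {"a": "S1", "b": "S2", "b2": "S2", "c": "S3"}
        with caplog.at_level("INFO", logger="redqueen"):
            reduced, _, dropped = rq.jackknife_supertype(table, st_map, "S1")
        assert dropped == ["C"]
        assert "C" not in set(as_table(reduced)["population"])
        assert any("jackknife" in m for m in caplog.messages)

    def test_unknown_supertype_rejected(self):
        with pytest.raises(ValueError):
            rq.jackknife_supertype(toy_table(),
                                   {"a": "S1", "b": "S1", "c": "S2"}, "S9")

    def test_summary_rho_one_for_identical_observed(self, rng):
        table, st_map, _ = synthetic.gen_population_tables(
            synthetic.TableSpec(n_populations=4,
                                individuals_per_population=10, rng_seed=3)
        )
        full = popgen.structure_analysis(table, st_map, n_reps=20, rng=rng)
        m, s, rho = rq.jackknife_summary(full, full)
        assert rho == pytest.approx(1.0)
        assert m == pytest.approx(full.red_minus_blue.mean())

    def test_summary_rho_matches_rank_oracle(self, rng):
        def manual_spearman(x, y):
            def ranks(v):
                order = np.argsort(v)
                r = np.empty(len(v))
                r[order] = np.arange(1, len(v) + 1)
                # midranks for ties
                for val in np.unique(v):
                    mask = v == val
                    r[mask] = r[mask].mean()
                return r
            rx, ry = ranks(np.asarray(x)), ranks(np.asarray(y))
            rx -= rx.mean()
            ry -= ry.mean()
            return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))

        frame_a = pd.DataFrame(
            {"observed": [0.1, 0.5, 0.3, 0.2],
             "expected_mean": [0.2, 0.2, 0.2, 0.2],
             "expected_sd": [0.01] * 4},
            index=list("wxyz"),
        )
        frame_b = frame_a.copy()
        frame_b["observed"] = [0.4, 0.1, 0.2, 0.2]
        a = popgen.StructureResult(frame=frame_a, n_reps=1, estimator="naive")
        b = popgen.StructureResult(frame=frame_b, n_reps=1, estimator="naive")
        _, _, rho = rq.jackknife_summary(a, b)
        assert rho == pytest.approx(
            manual_spearman(frame_a["observed"], frame_b["observed"])
        )

    def test_no_shared_populations_rejected(self):
        fa = pd.DataFrame({"observed": [0.1], "expected_mean": [0.1],
                           "expected_sd": [0.0]}, index=["P"])
        fb = fa.copy()
        fb.index = ["Q"]
        a = popgen.StructureResult(frame=fa, n_reps=1, estimator="naive")
        b = popgen.StructureResult(frame=fb, n_reps=1, estimator="naive")
        with pytest.raises(ValueError):
            rq.jackknife_summary(a, b)


class TestDeletionControls:
    def setup_method(self):
        self.table, self.st_map, _ = synthetic.gen_population_tables(
            synthetic.TableSpec(n_populations=4,
                                individuals_per_population=10, rng_seed=7)
        )
        self.df = as_table(self.table)

    def test_sequence_matched_removes_exact_unique_count(self, rng):
        focal = "ST1"
        n_focal = self.st_map[self.st_map == focal].index.intersection(
            self.df["allele"].unique()
        ).size
        out = popgen._delete_records(self.df, self.st_map, focal,
                                     "sequence_matched", rng)
        removed = set(self.df["allele"]) - set(out["allele"])
        assert len(removed) == n_focal

    def test_frequency_matched_removes_exact_record_count(self, rng):
        focal = "ST2"
        n_occ = int((self.df["allele"].map(self.st_map) == focal).sum())
        out = popgen._delete_records(self.df, self.st_map, focal,
                                     "frequency_matched", rng)
        assert len(self.df) - len(out) == n_occ

    def test_population_stratified_matches_per_population_counts(self, rng):
        focal = "ST3"
        out = popgen._delete_records(self.df, self.st_map, focal,
                                     "population_stratified", rng)
        for pop, grp in self.df.groupby("population"):
            n_focal = int((grp["allele"].map(self.st_map) == focal).sum())
            n_kept = len(out[out["population"] == pop])
            assert len(grp) - n_kept == n_focal

    def test_absent_supertype_is_noop(self, rng):
        st_map = pd.concat(
            [self.st_map, pd.Series({"ghost": "ST-ghost"})]
        )
        for scheme in popgen.DELETION_SCHEMES:
            out = popgen._delete_records(self.df, st_map, "ST-ghost",
                                         scheme, rng)
            assert len(out) == len(self.df)

    def test_unknown_scheme_rejected(self, rng):
        with pytest.raises(ValueError):
            popgen._delete_records(self.df, self.st_map, "ST1", "bogus", rng)

    def test_control_returns_one_row_per_repeat(self, rng):
        out = rq.random_deletion_control(
            self.table, self.st_map, "ST1", "frequency_matched",
            n_reps=3, rng=rng, n_null_reps=10,
        )
        assert len(out) == 3
        assert {"mean_red_minus_blue", "spearman_rho"} <= set(out.columns)


class TestSupertypeHomozygosity:
    def test_all_mixed_individuals_zero(self):
        t = {"P": {"i1": {"a", "b"}, "i2": {"b", "c"}}}
        st = {"a": "S1", "b": "S2", "c": "S3"}
        assert rq.st_homozygosity_fraction(t, st) == 0.0

    def test_single_allele_individuals_one(self):
        t = {"P": {"i1": {"a"}, "i2": {"b"}}}
        st = {"a": "S1", "b": "S2"}
        assert rq.st_homozygosity_fraction(t, st) == 1.0

    def test_hand_counted_ten_individual_table(self):
        # 2 of 10 individuals carry alleles of a single supertype
        t = {"P": {}, "Q": {}}
        st = {"a1": "S1", "a2": "S1", "b": "S2", "c": "S3"}
        t["P"] = {
            "i1": {"a1", "a2"},   # homozygote (S1 only)
            "i2": {"a1", "b"},
            "i3": {"b", "c"},
            "i4": {"a2", "c"},
            "i5": {"c"},          # homozygote (S3 only)
        }
        t["Q"] = {
            "j1": {"a1", "b"}, "j2": {"b", "c"}, "j3": {"a2", "b"},
            "j4": {"a1", "c"}, "j5": {"b", "a2"},
        }
        assert rq.st_homozygosity_fraction(t, st) == pytest.approx(0.2)

    def test_exclusion_reveals_masked_homozygotes(self):
        # a ubiquitous supertype masks homozygosity at the others
        t = {"P": {
            "i1": {"x", "a1"}, "i2": {"x", "a2"}, "i3": {"x", "b"},
            "i4": {"x"},
        }}
        st = {"x": "S9", "a1": "S1", "a2": "S1", "b": "S2"}
        assert rq.st_homozygosity_fraction(t, st) == pytest.approx(0.25)
        # removing S9: i4 vanishes, the rest become single-supertype
        frac = rq.st_homozygosity_fraction(t, st, exclude_st="S9")
        assert frac == pytest.approx(1.0)

    def test_exclusion_emptying_table_rejected(self):
        t = {"P": {"i1": {"x"}}}
        with pytest.raises(ValueError):
            rq.st_homozygosity_fraction(t, {"x": "S9"}, exclude_st="S9")
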