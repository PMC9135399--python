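"""Complex database, association tests, and correlation pooling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import stats

from aneucomp.complexes import (
    ComplexDatabase,
    abundance_correlations,
    co_complex_partners,
    co_occurrence_by_correlation_class,
    co_occurrence_frequency,
    compare_correlation_groups,
    partner_enrichment_test,
    pool_correlations,
    promiscuity,
    subunit_association_test,
)


@pytest.fixture()
def toy_db():
    return ComplexDatabase({"C1": {"a", "b", "c"}, "C2": {"c", "d"}})


class TestDatabase:
    def test_partner_lookup(self, toy_db):
        assert co_complex_partners({"a"}, toy_db) == {"b", "c"}
        assert co_complex_partners({"z"}, toy_db) == set()
        assert co_complex_partners({"a", "b", "c", "d"}, toy_db) == set()

    def test_membership_index_consistent(self, toy_db):
        assert toy_db.membership("c") == {"C1", "C2"}
        assert toy_db.all_subunits == {"a", "b", "c", "d"}

    def test_singleton_complex_rejected(self):
        with pytest.raises(ValueError):
            ComplexDatabase({"C1": {"a"}})

    def test_gmt_round_trip(self, toy_db, tmp_path):
        db = ComplexDatabase(
            toy_db.complexes, {"C1": {"t1", "t2"}, "C2": {"t1"}}
        )
        path = tmp_path / "c.gmt"
        db.to_gmt(path)
        back = ComplexDatabase.from_gmt(path)
        assert back.complexes == db.complexes
        assert back.annotations == db.annotations

    def test_gmt_duplicate_subunit_deduplicated(self, tmp_path):
        path = tmp_path / "d.gmt"
        path.write_text("C1\tt\ta\ta\tb\n")
        with pytest.warns(UserWarning, match="duplicate"):
            db = ComplexDatabase.from_gmt(path)
        assert db.complexes["C1"] == {"a", "b"}

    def test_filtered(self, toy_db):
        small = toy_db.filtered(max_size=2)
        assert set(small.complexes) == {"C2"}
        dropped = toy_db.filtered(drop_proteins={"d"})
        assert set(dropped.complexes) == {"C1"}


class TestPromiscuity:
    @pytest.mark.parametrize("n,expected", [
        (6, "promiscuous"), (5, "non_promiscuous"), (0, "non_promiscuous"),
    ])
    def test_boundary(self, n, expected):
        db = ComplexDatabase({f"C{i}": {"p", f"x{i}"} for i in range(n)} or
                             {"C0": {"y", "z"}})
        assert promiscuity("p", db) == expected


class TestCoOccurrence:
    def test_forced_values(self):
        always = ComplexDatabase({f"C{i}": {"a", "b"} for i in range(3)})
        assert co_occurrence_frequency("a", "b", always) == 1.0
        never = ComplexDatabase({
            "C1": {"a", "x"}, "C2": {"a", "y"}, "C3": {"b", "x"}, "C4": {"b", "y"},
        })
        assert co_occurrence_frequency("a", "b", never) == 0.0
        quarter = ComplexDatabase({
            "C1": {"a", "b"}, "C2": {"a", "x"}, "C3": {"a", "y"}, "C4": {"b", "z"},
        })
        assert co_occurrence_frequency("a", "b", quarter) == 0.25

    def test_undefined_pair(self, toy_db):
        with pytest.raises(ValueError):
            co_occurrence_frequency("q", "r", toy_db)

    @settings(max_examples=50, deadline=None)
    @given(hst.data())
    def test_agrees_with_enumeration_and_symmetry(self, data):
        n_complexes = data.draw(hst.integers(2, 12))
        proteins = [f"p{i}" for i in range(8)]
        complexes = {}
        for k in range(n_complexes):
            members = data.draw(
                hst.sets(hst.sampled_from(proteins), min_size=2, max_size=5)
            )
            complexes[f"C{k}"] = members
        db = ComplexDatabase(complexes)
        a, b = data.draw(hst.sampled_from(proteins)), data.draw(hst.sampled_from(proteins))
        both = sum(1 for m in complexes.values() if a in m and b in m)
        either = sum(1 for m in complexes.values() if a in m or b in m)
        if either == 0:
            with pytest.raises(ValueError):
                co_occurrence_frequency(a, b, db)
            return
        assert co_occurrence_frequency(a, b, db) == both / either
        assert co_occurrence_frequency(a, b, db) == co_occurrence_frequency(b, a, db)
        # partner lookup agrees with enumeration as well
        want = {q for m in complexes.values() if a in m for q in m} - {a}
        assert co_complex_partners({a}, db) == want


class TestAssociationTests:
    def test_extreme_enrichment_matches_brute_force(self):
        db = ComplexDatabase({"C1": {"a", *(f"da{i}" for i in range(5))}})
        universe = {f"da{i}" for i in range(5)} | {f"bg{i}" for i in range(15)}
        da_other = {f"da{i}" for i in range(5)}
        resid, p = partner_enrichment_test(da_other, {"a"}, universe, db)
        table = np.array([[5.0, 0.0], [0.0, 15.0]])
        expected = table[0].sum() * table[:, 0].sum() / table.sum()
        assert resid == pytest.approx((5 - expected) / np.sqrt(expected), abs=1e-10)
        assert p < 0.05

    def test_empty_aneuploid_set_skipped(self, toy_db):
        with pytest.warns(UserWarning, match="skipped"):
            assert partner_enrichment_test({"a"}, set(), {"a", "b"}, toy_db) is None

    def test_subunit_association_all_subunits(self, toy_db):
        universe = {"a", "b", "c", "d", "e", "f", "g", "h"}
        resid, _ = subunit_association_test({"a", "b", "c", "d"}, universe, toy_db)
        assert resid > 0

    def test_null_calibration(self):
        """Independent partner/DA assignment keeps |residual| < 2 in >=95%."""
        hits = 0
        n_runs = 100
        for seed in range(n_runs):
            r = np.random.default_rng(seed)
            universe = {f"p{i}" for i in range(200)}
            partners = set(r.choice(sorted(universe), size=50, replace=False))
            db = ComplexDatabase(
                {"CX": partners | {"anchor"}}
            )
            da = set(r.choice(sorted(universe), size=40, replace=False))
            resid, _ = partner_enrichment_test(da, {"anchor"}, universe, db)
            hits += abs(resid) >= 2
        assert hits <= 5


def spearman_brute(x, y):
    """Pearson correlation of average ranks (textbook definition)."""
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    return np.corrcoef(rx, ry)[0, 1]


class TestCorrelations:
    def test_monotone_pairs(self):
        mat = pd.DataFrame(
            {
                "s1": [1.0, 10.0, 5.0], "s2": [2.0, 20.0, 4.0],
                "s3": [3.0, 30.0, 3.0], "s4": [4.0, 40.0, 2.0],
            },
            index=["a", "b", "c"],
        )
        table = abundance_correlations([("a", "b"), ("a", "c")], {"X": mat})
        rho = table.set_index("partner")["rho"]
        assert rho["b"] == pytest.approx(1.0)
        assert rho["c"] == pytest.approx(-1.0)

    def test_tie_rich_pair_matches_brute_force(self, rng):
        for _ in range(20):
            x = rng.integers(0, 4, size=8).astype(float)
            y = rng.integers(0, 4, size=8).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            mat = pd.DataFrame([x, y], index=["a", "b"],
                               columns=[f"s{i}" for i in range(8)])
            table = abundance_correlations([("a", "b")], {"X": mat})
            assert table["rho"].iloc[0] == pytest.approx(
                spearman_brute(x, y), abs=1e-10
            )

    def test_constant_vector_dropped(self):
        mat = pd.DataFrame(
            [[1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0]], index=["a", "b"],
            columns=list("wxyz"),
        )
        table = abundance_correlations([("a", "b")], {"X": mat})
        assert table.empty

    def test_pooling_max_rules(self):
        table = pd.DataFrame(
            {
                "aneuploid_protein": ["a", "a", "a"],
                "partner": ["b", "b", "b"],
                "cohort": ["X", "Y", "Z"],
                "rho": [0.3, -0.8, 0.5],
                "n_samples": [10, 10, 10],
            }
        )
        pooled = pool_correlations(table)
        assert len(pooled) == 1 and pooled["rho"].iloc[0] == 0.5
        pooled_abs = pool_correlations(table, absolute_max=True)
        assert pooled_abs["rho"].iloc[0] == -0.8

    def test_pooled_row_count_matches_distinct_pairs(self, rng):
        rows = []
        pair_ids = set()
        for i in range(30):
            a, b = f"a{i % 10}", f"b{i % 7}"
            pair_ids.add((a, b))
            rows.append((a, b, rng.choice(["X", "Y"]), rng.uniform(-1, 1), 10))
        table = pd.DataFrame(
            rows, columns=["aneuploid_protein", "partner", "cohort", "rho", "n_samples"]
        )
        assert len(pool_correlations(table)) == len(pair_ids)


class TestCompareGroups:
    def _table(self, rhos_a, rhos_b):
        rows = [("x", f"p{i}", "X", r, 10) for i, r in enumerate(rhos_a)]
        rows += [("y", f"q{i}", "X", r, 10) for i, r in enumerate(rhos_b)]
        t = pd.DataFrame(
            rows, columns=["aneuploid_protein", "partner", "cohort", "rho", "n_samples"]
        )
        return t, t["aneuploid_protein"] == "x", t["aneuploid_protein"] == "y"

    def test_separated_groups_significant(self):
        t, in_a, in_b = self._table([0.6] * 20, [0.0] * 20)
        p, med_a, med_b = compare_correlation_groups(t, in_a, in_b)
        assert p < 0.01 and med_a > med_b

    def test_label_permutation_null_uniform(self, rng):
        rhos = rng.uniform(-1, 1, 40)
        pvals = []
        for _ in range(200):
            labels = rng.permutation(np.repeat([0, 1], 20))
            t, _, _ = self._table(rhos[:20], rhos[20:])
            p, _, _ = compare_correlation_groups(t, labels == 0, labels == 1)
            pvals.append(p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_empty_group_rejected(self):
        t, in_a, _ = self._table([0.5] * 5, [0.1] * 5)
        with pytest.raises(ValueError):
            compare_correlation_groups(t, in_a, pd.Series(False, index=t.index))


class TestCoOccurrenceByClass:
    def test_all_same_frequency_p1(self):
        db = ComplexDatabase({f"C{i}": {f"a{i}", f"b{i}"} for i in range(12)})
        rows = [(f"a{i}", f"b{i}", "X", r, 10)
                for i, r in enumerate(np.linspace(-0.9, 0.9, 12))]
        table = pd.DataFrame(
            rows, columns=["aneuploid_protein", "partner", "cohort", "rho", "n_samples"]
        )
        dists, pvals = co_occurrence_by_correlation_class(table, db)
        assert all(np.all(v == 1.0) for v in dists.values() if len(v))
        assert all(p == 1.0 for p in pvals.values())
        assert all((v >= 0).all() and (v <= 1).all() for v in dists.values())

    def test_planted_co_membership_detected(self, rng):
        complexes = {}
        rows = []
        for i in range(40):  # high-rho pairs co-occur everywhere
            for k in range(3):
                complexes[f"H{i}_{k}"] = {f"ha{i}", f"hb{i}"}
            rows.append((f"ha{i}", f"hb{i}", "X", 0.7, 10))
        for i in range(40):  # uncorrelated pairs rarely together
            complexes[f"L{i}"] = {f"la{i}", f"lb{i}"}
            complexes[f"L{i}x"] = {f"la{i}", f"z{i}"}
            complexes[f"L{i}y"] = {f"lb{i}", f"w{i}"}
            rows.append((f"la{i}", f"lb{i}", "X", 0.0, 10))
        db = ComplexDatabase(complexes)
        table = pd.DataFrame(
            rows, columns=["aneuploid_protein", "partner", "cohort", "rho", "n_samples"]
        )
        _, pvals = co_occurrence_by_correlation_class(table, db)
        assert pvals[("positive", "non_correlated")] < 0.05
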