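"""Mixture fitting, bimodality diagnostics and hierarchical statistics.

The dip statistic is validated against a brute-force linear-programming
oracle that encodes the definition directly: minimize the sup-norm
distance d between the empirical CDF and a unimodal CDF, enumerating the
mode location (inside each inter-point gap, or at a data point with an
upward jump) and solving each case as an LP over the CDF values at the
data points.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import linprog

from beatlock import (
    MixturePopulationSpec,
    bimodality_tests,
    compare_groups,
    dip_test,
    fit_mixture,
    generate_population,
    hartigan_dip,
    hierarchical_summary,
)
from beatlock.popstats import (
    _density_crossing,
    dip_null_distribution,
    gap_statistic,
    silhouette_k2,
)


# --------------------------------------------------------------- dip oracle
def dip_lp(x):
    """Exact dip via linear programming (tiny-n oracle)."""
    x = np.sort(np.asarray(x, float))
    n = x.size
    xs, cnt = np.unique(x, return_counts=True)
    cum = np.cumsum(cnt)
    a = (cum - cnt) / n   # ECDF left limit at each unique point
    b = cum / n           # ECDF value at each unique point
    m = xs.size
    if m == 1:
        return 0.0

    def solve(convex_triples, concave_triples, boxes, mono_pairs, nvar):
        # vars: u_0..u_{nvar-2}, d (last); minimize d
        rows, rhs = [], []

        def row(coefs, r):
            rr = np.zeros(nvar)
            for i, c in coefs:
                rr[i] += c
            rows.append(rr)
            rhs.append(r)

        d = nvar - 1
        for i, lo, hi in boxes:
            row([(i, -1), (d, -1)], -lo)   # u_i + d >= lo
            row([(i, 1), (d, -1)], hi)     # u_i - d <= hi
        for i, j in mono_pairs:
            row([(i, 1), (j, -1)], 0)      # u_i <= u_j
        for (i, xi), (j, xj), (k, xk) in convex_triples:
            dx1, dx2 = xj - xi, xk - xj
            # slope(i,j) <= slope(j,k)
            row([(i, -1 / dx1), (j, 1 / dx1 + 1 / dx2), (k, -1 / dx2)], 0)
        for (i, xi), (j, xj), (k, xk) in concave_triples:
            dx1, dx2 = xj - xi, xk - xj
            row([(i, 1 / dx1), (j, -1 / dx1 - 1 / dx2), (k, 1 / dx2)], 0)
        c = np.zeros(nvar)
        c[d] = 1
        res = linprog(c, A_ub=np.array(rows), b_ub=np.array(rhs),
                      bounds=[(0, 1)] * nvar, method="highs")
        return res.fun if res.success else np.inf

    best = np.inf
    pt = [(i, xs[i]) for i in range(m)]

    # mode strictly inside gap (k-1, k), k = 1..m-1, plus all-convex /
    # all-concave (k = m / k = 0); U continuous at data points
    for k in range(m + 1):
        boxes = [(i, b[i], a[i]) for i in range(m)]
        mono = [(i, i + 1) for i in range(m - 1)]
        cvx = [(pt[i], pt[i + 1], pt[i + 2]) for i in range(k - 2)]
        ccv = [(pt[i], pt[i + 1], pt[i + 2]) for i in range(k, m - 2)]
        if 0 < k < m:
            variants = []
            if k >= 2:
                variants.append(("cvx", (pt[k - 2], pt[k - 1], pt[k])))
            if k <= m - 2:
                variants.append(("ccv", (pt[k - 1], pt[k], pt[k + 1])))
            if not variants:
                variants = [(None, None)]
        else:
            variants = [(None, None)]
        for kind, tri in variants:
            c2 = cvx + ([tri] if kind == "cvx" else [])
            v2 = ccv + ([tri] if kind == "ccv" else [])
            best = min(best, solve(c2, v2, boxes, mono, m + 1))

    # mode at data point j with an allowed jump: split value w = U(x_j^-)
    # as variable index m
    for j in range(m):
        w = m
        nvar = m + 2
        boxes = [(i, b[i], a[i]) for i in range(m) if i != j]
        boxes += [(j, b[j], b[j]), (w, a[j], a[j])]
        # the pair above encodes |u_j - b_j| <= d and |w - a_j| <= d
        mono = [(i, i + 1) for i in range(m - 1)]
        if j > 0:
            mono.append((j - 1, w))
        mono.append((w, j))
        wpt = (w, xs[j])
        cvx = [(pt[i], pt[i + 1], pt[i + 2]) for i in range(j - 2)]
        if j >= 2:
            cvx.append((pt[j - 2], pt[j - 1], wpt))
        ccv = [(pt[i], pt[i + 1], pt[i + 2]) for i in range(j, m - 2)]
        best = min(best, solve(cvx, ccv, boxes, mono, nvar))
    return best


class TestDip:
    def test_equally_spaced_grid_minimal_dip(self):
        for n in (5, 20, 101):
            assert hartigan_dip(np.arange(n)) == pytest.approx(1 / (2 * n))

    def test_two_point_masses_quarter(self):
        x = np.array([0.0] * 50 + [1.0] * 50)
        assert hartigan_dip(x) == pytest.approx(0.25)

    def test_degenerate_inputs(self):
        assert hartigan_dip(np.array([3.0])) == 0.0
        assert hartigan_dip(np.full(10, 2.0)) == 0.0

    def test_matches_lp_oracle_on_fuzz(self):
        rng = np.random.default_rng(0)
        for case in range(60):
            n = int(rng.integers(4, 22))
            kind = case % 4
            if kind == 0:
                x = rng.random(n)
            elif kind == 1:
                x = np.concatenate([rng.normal(0, 1, n // 2),
                                    rng.normal(4, 0.5, n - n // 2)])
            elif kind == 2:
                x = rng.integers(0, 4, n).astype(float)  # heavy ties
            else:
                x = np.exp(rng.normal(0, 1, n))
            assert hartigan_dip(x) == pytest.approx(dip_lp(x), abs=1e-9), \
                f"case {case}"

    def test_bimodal_small_p(self, dip_null_300):
        x = np.concatenate([np.random.default_rng(1).normal(0, 1, 150),
                            np.random.default_rng(2).normal(8, 1, 150)])
        d, p = dip_test(x, null_dips=dip_null_300)
        assert p <= 2 / (1 + dip_null_300.size)

    def test_null_calibration(self, dip_null_300):
        hits = 0
        for s in range(20):
            x = np.random.default_rng(100 + s).normal(0, 1, 300)
            _, p = dip_test(x, null_dips=dip_null_300)
            hits += p > 0.05
        assert hits >= 18

    def test_null_distribution_seeded(self):
        a = dip_null_distribution(50, n_boot=20, seed=3)
        b = dip_null_distribution(50, n_boot=20, seed=3)
        assert np.array_equal(a, b)


class TestMixture:
    def test_volume_means_resolved_as_two_components(self):
        hits = 0
        for s in range(20):
            x = generate_population(MixturePopulationSpec(
                (0.5, 0.5), (1161.0, 3014.0), (400.0, 800.0), 200, seed=s))
            fit = fit_mixture(x, seed=s)
            hits += fit.k_selected == 2
        assert hits >= 18

    def test_single_gaussian_prefers_one_component(self):
        hits = 0
        for s in range(20):
            x = np.random.default_rng(s).normal(0, 1, 200)
            hits += fit_mixture(x, seed=s).k_selected == 1
        assert hits >= 17

    def test_symmetric_crossing_is_midpoint(self):
        thr = _density_crossing((0.5, 0.5), (0.0, 4.0), (1.0, 1.0))
        assert thr == pytest.approx(2.0, abs=1e-9)

    def test_threshold_between_means_and_classify(self):
        x = generate_population(MixturePopulationSpec(
            (0.5, 0.5), (1161.0, 3014.0), (121.0, 245.0), 300, seed=7))
        fit = fit_mixture(x, seed=7)
        assert fit.k_selected == 2
        assert fit.means[0] < fit.threshold < fit.means[1]
        labels = fit.classify(x)
        # classification agrees with the nearer component mean
        nearer = (np.abs(x - fit.means[1])
                  < np.abs(x - fit.means[0])).astype(int)
        assert np.mean(labels == nearer) > 0.98

    def test_printed_fold_ratio(self):
        assert 3014.0 / 1161.0 == pytest.approx(2.6, abs=0.01)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            fit_mixture(np.arange(5))


class TestDiagnostics:
    def test_gap_statistic_separated_bimodal(self):
        x = np.concatenate([np.random.default_rng(0).normal(0, 0.5, 150),
                            np.random.default_rng(1).normal(6, 0.5, 150)])
        gap_k, table = gap_statistic(x, seed=0)
        assert gap_k == 2
        assert set(table.columns) == {"k", "gap", "s"}

    def test_silhouette_two_point_masses(self):
        x = np.array([0.0] * 20 + [5.0] * 20)
        assert silhouette_k2(x) == pytest.approx(1.0)

    def test_bimodality_report_keys(self, dip_null_300):
        x = np.concatenate([np.random.default_rng(5).normal(0, 1, 150),
                            np.random.default_rng(6).normal(7, 1, 150)])
        rep = bimodality_tests(x, seed=0, null_dips=dip_null_300, n_ref=20)
        assert {"dip", "dip_p", "gap_k", "silhouette_k2"} <= set(rep)
        assert rep["silhouette_k2"] > 0.5


class TestHierarchical:
    def test_single_animal_mean(self):
        cells = pd.DataFrame({"animal": ["a"] * 3, "group": ["g"] * 3,
                              "value": [1.0, 2.0, 3.0]})
        out = hierarchical_summary(cells, "value")
        assert len(out) == 1 and out["mean"].iloc[0] == 2.0
        assert out["n_cells"].iloc[0] == 3

    def test_unequal_cell_counts_unweighted(self):
        cells = pd.DataFrame({
            "animal": ["a"] * 10 + ["b"] * 2,
            "group": ["g"] * 12,
            "value": [1.0] * 10 + [5.0, 5.0]})
        out = hierarchical_summary(cells, "value")
        # each animal contributes one row regardless of its cell count
        assert sorted(out["mean"]) == [1.0, 5.0]

    def test_missing_animal_id_lists_rows(self):
        cells = pd.DataFrame({"animal": ["a", None, "b"],
                              "group": ["g"] * 3,
                              "value": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match=r"\[1\]"):
            hierarchical_summary(cells, "value")


def _per_animal(groups_values):
    rows = []
    for g, vals in groups_values.items():
        for i, v in enumerate(vals):
            rows.append({"group": g, "mean": v, "animal": f"{g}{i}"})
    return pd.DataFrame(rows)


class TestCompareGroups:
    def test_identical_groups_nonsignificant(self):
        df = _per_animal({"a": [1.0, 2.0, 3.0, 4.0],
                          "b": [1.0, 2.0, 3.0, 4.0]})
        res = compare_groups(df)
        assert res.test == "welch_t"
        assert res.p_value == pytest.approx(1.0)

    def test_welch_equals_student_under_equal_variance(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 8)
        welch = stats.ttest_ind(a, b, equal_var=False)
        student = stats.ttest_ind(a, b, equal_var=True)
        # equal n: the statistics coincide analytically
        assert welch.statistic == pytest.approx(student.statistic, abs=1e-10)

    def test_power_on_separated_groups(self):
        hits = 0
        for s in range(100):
            rng = np.random.default_rng(s)
            df = _per_animal({"a": rng.normal(0, 1, 6),
                              "b": rng.normal(3, 1, 6)})
            hits += compare_groups(df).p_value < 0.01
        assert hits >= 95

    def test_three_groups_uses_welch_anova_and_games_howell(self):
        rng = np.random.default_rng(1)
        df = _per_animal({"a": rng.normal(0, 1, 5),
                          "b": rng.normal(0, 2, 5),
                          "c": rng.normal(4, 1, 5)})
        res = compare_groups(df)
        assert res.test == "welch_anova"
        assert res.p_value < 0.05
        assert res.posthoc is not None and len(res.posthoc) == 3

    def test_games_howell_symmetric_in_group_order(self):
        rng = np.random.default_rng(2)
        data = {"a": rng.normal(0, 1, 5), "b": rng.normal(1, 2, 5),
                "c": rng.normal(2, 1, 5)}
        p1 = compare_groups(_per_animal(data)).posthoc
        rev = dict(reversed(list(data.items())))
        p2 = compare_groups(_per_animal(rev)).posthoc
        key = lambda df: {frozenset((r.A, r.B)): round(r.pval, 10)
                          for r in df.itertuples()}
        assert key(p1) == key(p2)

    def test_single_animal_group_rejected(self):
        df = _per_animal({"a": [1.0], "b": [1.0, 2.0]})
        with pytest.raises(ValueError):
            compare_groups(df)

    def test_naive_per_cell_test_inflates_type_i(self):
        # nested null: big between-animal spread, tiny within-animal
        naive_hits = nested_hits = 0
        reps = 300
        for s in range(reps):
            rng = np.random.default_rng(s)
            cells, per_animal = [], {"a": [], "b": []}
            for g in ("a", "b"):
                animal_means = rng.normal(0, 1, 4)
                per_animal[g] = animal_means
                for mu in animal_means:
                    cells.append(mu + 0.05 * rng.standard_normal(20))
            flat_a = np.concatenate(cells[:4])
            flat_b = np.concatenate(cells[4:])
            naive_hits += stats.ttest_ind(
                flat_a, flat_b, equal_var=False).pvalue < 0.05
            nested_hits += compare_groups(
                _per_animal(per_animal)).p_value < 0.05
        assert naive_hits / reps > 0.3          # pseudoreplication inflates
        assert nested_hits / reps < 0.10        # per-animal test is honest
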