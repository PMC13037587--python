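"""Population phenotyping and hierarchical group statistics.

Mixture modelling (Gaussian mixtures with BIC component selection and an
equal-density classification threshold between the two component means),
bimodality diagnostics (Hartigan's dip test with a bootstrap uniform
null, the gap statistic against a uniform reference, and the mean
silhouette at k = 2), and the nested summarize-then-test inference chain:
per-cell values are first averaged within each animal, animals are the
unit of inference, heteroskedasticity is screened with Brown–Forsythe,
and groups are compared with Welch's t test (two groups) or Welch's
ANOVA with Games–Howell post-hoc comparisons (more than two).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score
from sklearn.mixture import GaussianMixture


# ------------------------------------------------------------ mixture fit
@dataclass
class MixtureFit:
    k_selected: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    bic_by_k: dict
    threshold: float | None = None
    diagnostics: dict = field(default_factory=dict)

    def classify(self, values) -> np.ndarray:
        """0/1 labels for a two-component fit via the density threshold."""
        if self.k_selected != 2 or self.threshold is None:
            raise ValueError("classification requires a two-component fit")
        return (np.asarray(values, dtype=float) > self.threshold).astype(int)


def _density_crossing(w, mu, sd):
    """Equal-density point of two weighted Gaussians between their means."""
    lo, hi = mu[0], mu[1]

    def diff(x):
        return (w[0] * stats.norm.pdf(x, mu[0], sd[0])
                - w[1] * stats.norm.pdf(x, mu[1], sd[1]))

    try:
        return float(optimize.brentq(diff, lo, hi))
    except ValueError:
        return float(0.5 * (lo + hi))  # no sign change: midpoint fallback


def fit_mixture(values, k_max: int = 4, seed: int = 0,
                n_init: int = 10) -> MixtureFit:
    """Gaussian-mixture fit with BIC component selection.

    EM is run for k = 1..k_max with ``n_init`` restarts each; the k
    minimizing BIC is kept. For a two-component winner the classification
    threshold is the equal-density crossing of the two weighted component
    Gaussians, which always lies strictly between the component means.
    """
    x = np.asarray(values, dtype=float).reshape(-1, 1)
    if x.size < 10:
        raise ValueError("mixture fit requires at least 10 values")
    fits, bic_by_k = {}, {}
    for k in range(1, k_max + 1):
        gm = GaussianMixture(n_components=k, n_init=n_init,
                             random_state=seed, covariance_type="full")
        gm.fit(x)
        fits[k] = gm
        bic_by_k[k] = float(gm.bic(x))
    k_sel = min(bic_by_k, key=bic_by_k.get)
    gm = fits[k_sel]
    order = np.argsort(gm.means_.ravel())
    w = gm.weights_[order]
    mu = gm.means_.ravel()[order]
    sd = np.sqrt(gm.covariances_.reshape(-1)[order])
    thr = _density_crossing(w, mu, sd) if k_sel == 2 else None
    return MixtureFit(k_selected=k_sel, weights=w, means=mu, sds=sd,
                      bic_by_k=bic_by_k, threshold=thr)


# -------------------------------------------------------- dip statistic
def hartigan_dip(values) -> float:
    """Hartigan's dip statistic: sup-norm distance from the empirical CDF
    to the nearest unimodal CDF.

    Classic iterative construction: the greatest convex minorant and the
    least concave majorant of the ECDF are refined over a shrinking
    candidate modal interval; the deviations frozen outside the interval
    accumulate into the dip, and the loop stops when the gap between the
    two envelopes inside the interval no longer exceeds it. Exact
    (validated against a direct linear-programming formulation of the
    definition); O(n) per iteration after sorting.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 2 or x[0] == x[-1]:
        return 0.0
    low, high = 0, n - 1
    dip = 1.0  # count units; the dip is never below 1/(2n)

    # mn[j]: previous touch point of the greatest convex minorant through
    # (x, counts); mj[k]: next touch point of the least concave majorant
    mn = np.zeros(n, dtype=np.int64)
    for j in range(1, n):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            if mnj == 0:
                break
            mnmnj = mn[mnj]
            if ((x[j] - x[mnj]) * (mnj - mnmnj)
                    < (x[mnj] - x[mnmnj]) * (j - mnj)):
                break
            mn[j] = mnmnj
    mj = np.zeros(n, dtype=np.int64)
    mj[n - 1] = n - 1
    for k in range(n - 2, -1, -1):
        mj[k] = k + 1
        while True:
            mjk = mj[k]
            if mjk == n - 1:
                break
            mjmjk = mj[mjk]
            if ((x[mjk] - x[k]) * (mjmjk - mjk)
                    < (x[mjmjk] - x[mjk]) * (mjk - k)):
                break
            mj[k] = mjmjk

    while low < high:
        # touch points of the two envelopes restricted to [low, high];
        # the gcm list runs high -> low, the lcm list low -> high
        gcm = [high]
        while gcm[-1] > low:
            gcm.append(int(mn[gcm[-1]]))
        lcm = [low]
        while lcm[-1] < high:
            lcm.append(int(mj[lcm[-1]]))
        l_gcm, l_lcm = len(gcm), len(lcm)

        # largest vertical gap between minorant and majorant, walking both
        # touch-point lists upward from the low end of the interval
        ig, ih = l_gcm - 1, l_lcm - 1
        if l_gcm != 2 or l_lcm != 2:
            d = 0.0
            ix, iv = l_gcm - 2, 1
            while True:
                gcmix, lcmiv = gcm[ix], lcm[iv]
                if gcmix > lcmiv:
                    # deviation of an LCM corner above the GCM segment
                    gcmi1 = gcm[ix + 1]
                    dx = ((lcmiv - gcmi1 + 1)
                          - (x[lcmiv] - x[gcmi1]) * (gcmix - gcmi1)
                          / (x[gcmix] - x[gcmi1]))
                    iv += 1
                    if dx >= d:
                        d, ig, ih = dx, ix + 1, iv - 1
                else:
                    # deviation of a GCM corner below the LCM segment
                    lcmiv1 = lcm[iv - 1]
                    dx = ((x[gcmix] - x[lcmiv1]) * (lcmiv - lcmiv1)
                          / (x[lcmiv] - x[lcmiv1])
                          - (gcmix - 1 - lcmiv1))
                    ix -= 1
                    if dx >= d:
                        d, ig, ih = dx, ix + 1, iv
                ix = max(ix, 0)
                iv = min(iv, l_lcm - 1)
                if gcm[ix] == lcm[iv]:
                    break
        else:
            d = 1.0
        if d < dip:
            break

        # deviations of the ECDF from the envelopes outside the new modal
        # interval become final
        dip_l = 0.0
        for j in range(ig, l_gcm - 1):
            jb, je = gcm[j + 1], gcm[j]
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (jj - jb + 1) - (x[jj] - x[jb]) * c
                    dip_l = max(dip_l, t)
        dip_u = 0.0
        for j in range(ih, l_lcm - 1):
            jb, je = lcm[j], lcm[j + 1]
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (x[jj] - x[jb]) * c - (jj - jb - 1)
                    dip_u = max(dip_u, t)
        dip = max(dip, dip_l, dip_u)

        if low == gcm[ig] and high == lcm[ih]:
            break
        low, high = gcm[ig], lcm[ih]

    return dip / (2.0 * n)


def dip_null_distribution(n: int, n_boot: int = 10_000,
                          seed: int = 0) -> np.ndarray:
    """Bootstrap null dips from uniform samples of size n (Hartigan's
    calibration: the uniform is the least favorable unimodal null)."""
    rng = np.random.default_rng(seed)
    return np.array([hartigan_dip(rng.random(n)) for _ in range(n_boot)])


def dip_test(values, n_boot: int = 10_000, seed: int = 0,
             null_dips: np.ndarray | None = None):
    """(dip, p-value) against the bootstrap uniform null.

    A precomputed ``null_dips`` array (from :func:`dip_null_distribution`
    at the same sample size) can be reused across tests.
    """
    values = np.asarray(values, dtype=float)
    d = hartigan_dip(values)
    if null_dips is None:
        null_dips = dip_null_distribution(values.size, n_boot, seed)
    p = (1.0 + np.sum(null_dips >= d)) / (1.0 + null_dips.size)
    return d, float(p)


# ----------------------------------------------------- other diagnostics
def gap_statistic(values, k_max: int = 4, n_ref: int = 100, seed: int = 0):
    """Gap statistic with a uniform-box reference; returns (gap_k, table).

    gap(k) = E_ref[log W_k] - log W_k with W_k the within-cluster sum of
    squares from k-means; the selected k is the smallest with
    gap(k) >= gap(k+1) - s_{k+1}.
    """
    x = np.asarray(values, dtype=float).reshape(-1, 1)
    rng = np.random.default_rng(seed)
    lo, hi = x.min(), x.max()

    def log_wk(data, k):
        if k == 1:
            return float(np.log(np.sum((data - data.mean()) ** 2) + 1e-300))
        km = KMeans(n_clusters=k, n_init=5, random_state=seed).fit(data)
        return float(np.log(km.inertia_ + 1e-300))

    rows = []
    for k in range(1, k_max + 1):
        ref = np.array([
            log_wk(rng.uniform(lo, hi, x.size).reshape(-1, 1), k)
            for _ in range(n_ref)])
        gap = float(ref.mean() - log_wk(x, k))
        s_k = float(ref.std() * np.sqrt(1.0 + 1.0 / n_ref))
        rows.append({"k": k, "gap": gap, "s": s_k})
    table = pd.DataFrame(rows)
    gap_k = k_max
    for i in range(len(rows) - 1):
        if rows[i]["gap"] >= rows[i + 1]["gap"] - rows[i + 1]["s"]:
            gap_k = rows[i]["k"]
            break
    return gap_k, table


def silhouette_k2(values, seed: int = 0) -> float:
    """Mean silhouette of the k-means two-cluster split."""
    x = np.asarray(values, dtype=float).reshape(-1, 1)
    labels = KMeans(n_clusters=2, n_init=5, random_state=seed).fit_predict(x)
    if len(np.unique(labels)) < 2:
        return 0.0
    return float(silhouette_score(x, labels))


def bimodality_tests(values, seed: int = 0, n_boot: int = 10_000,
                     n_ref: int = 100, null_dips=None) -> dict:
    """Dip test, gap statistic and silhouette score in one report."""
    values = np.asarray(values, dtype=float)
    if values.size < 10:
        raise ValueError("bimodality tests require at least 10 values")
    d, p = dip_test(values, n_boot=n_boot, seed=seed, null_dips=null_dips)
    gap_k, gap_table = gap_statistic(values, n_ref=n_ref, seed=seed)
    return {
        "dip": d,
        "dip_p": p,
        "gap_k": gap_k,
        "gap_table": gap_table,
        "silhouette_k2": silhouette_k2(values, seed=seed),
    }


# -------------------------------------------------- hierarchical inference
@dataclass
class GroupComparison:
    groups: list
    n_animals: dict
    brown_forsythe_p: float
    test: str                       # "welch_t" | "welch_anova"
    statistic: float
    p_value: float
    df: float
    posthoc: pd.DataFrame | None = None


def hierarchical_summary(cells: pd.DataFrame, value_col: str,
                         animal_col: str = "animal",
                         group_cols=("group",)) -> pd.DataFrame:
    """Summarize per-cell values within each animal x condition.

    One row per animal and condition with the mean, SD and cell count;
    animals (not cells) are the downstream unit of inference, so unequal
    cell counts do not weight the group tests. Rows with a missing animal
    id are an error, reported by index.
    """
    group_cols = list(group_cols)
    missing = cells[animal_col].isna()
    if missing.any():
        raise ValueError(
            "missing animal id in rows "
            f"{cells.index[missing].tolist()}")
    g = cells.groupby([animal_col] + group_cols, sort=True)[value_col]
    out = g.agg(mean="mean", sd="std", n_cells="count").reset_index()
    return out


def compare_groups(per_animal: pd.DataFrame, value_col: str = "mean",
                   group_col: str = "group") -> GroupComparison:
    """Welch-family group comparison on per-animal summary values.

    Brown–Forsythe (Levene on median-centered values) screens for
    heteroskedasticity; two groups are compared with Welch's t test,
    more than two with Welch's ANOVA followed by Games–Howell pairwise
    comparisons (studentized-range reference, Welch–Satterthwaite df).
    """
    groups = sorted(per_animal[group_col].unique())
    if len(groups) < 2:
        raise ValueError("at least two groups are required")
    samples = [per_animal.loc[per_animal[group_col] == g, value_col]
               .to_numpy(dtype=float) for g in groups]
    n_animals = {g: s.size for g, s in zip(groups, samples)}
    if any(s.size < 2 for s in samples):
        raise ValueError("every group needs at least 2 animals")

    bf_stat, bf_p = stats.levene(*samples, center="median")

    if len(groups) == 2:
        res = stats.ttest_ind(samples[0], samples[1], equal_var=False)
        df = float(getattr(res, "df", np.nan))
        return GroupComparison(
            groups=groups, n_animals=n_animals,
            brown_forsythe_p=float(bf_p), test="welch_t",
            statistic=float(res.statistic), p_value=float(res.pvalue), df=df)

    import pingouin as pg

    long = per_animal[[group_col, value_col]].rename(
        columns={group_col: "group", value_col: "value"})
    aov = pg.welch_anova(data=long, dv="value", between="group")
    gh = pg.pairwise_gameshowell(data=long, dv="value", between="group")
    return GroupComparison(
        groups=groups, n_animals=n_animals,
        brown_forsythe_p=float(bf_p), test="welch_anova",
        statistic=float(aov["F"].iloc[0]),
        p_value=float(aov["p_unc"].iloc[0]),
        df=float(aov["ddof2"].iloc[0]),
        posthoc=gh)
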